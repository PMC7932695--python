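"""Single-sequence molecular-feature calculators.

These are the building blocks of the per-IDR feature vectors: physicochemical
scale means (Kyte-Doolittle hydropathy), the isoelectric point, amino-acid and
residue-class compositions, repeat and short-linear-motif consensus counts,
and the Z-score utilities used to assemble evolutionary signatures (mean and
log variance of each feature over a set of orthologous IDRs, standardized
against a simulated null).

The default catalog defines 82 named features; an evolutionary signature
therefore has 164 columns (a mean and a log-variance per feature).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "ProteinSequence",
    "FeatureDefinition",
    "TranslationError",
    "translate_dna",
    "net_charge",
    "isoelectric_point",
    "mean_hydropathy",
    "composition_fraction",
    "motif_count",
    "zscore_columns",
    "signature_zscore",
    "default_catalog",
    "signature_feature_names",
    "feature_profile",
    "evolutionary_signature",
    "compute_feature_frame",
    "apply_residue_map",
    "KYTE_DOOLITTLE",
    "PKA_TABLES",
    "LOW_HYDROPATHY_MAP",
    "LOW_PI_MAP",
    "HIGH_PI_MAP",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9, "R": -4.5,
}

# side-chain and terminal pKa sets; keys: Nterm, Cterm, C, D, E, H, K, R, Y
PKA_TABLES = {
    "dtaselect": dict(
        Nterm=8.0, Cterm=3.1, C=8.5, D=4.4, E=4.4, H=6.5, K=10.0, R=12.0, Y=10.0
    ),
    "bjellqvist": dict(
        Nterm=7.5, Cterm=3.55, C=9.0, D=4.05, E=4.45, H=5.98, K=10.0, R=12.0, Y=10.0
    ),
    "emboss": dict(
        Nterm=8.6, Cterm=3.6, C=8.5, D=3.9, E=4.1, H=6.5, K=10.8, R=12.5, Y=10.1
    ),
}
DEFAULT_PKA_TABLE = "dtaselect"

# mutation maps used for the Cox15 targeting-signal variants: swap the three
# most hydrophobic residues for the three least (Kyte-Doolittle), or shift the
# charge balance via R->E / acidic->R substitutions
LOW_HYDROPATHY_MAP = {"L": "N", "V": "K", "I": "R"}
LOW_PI_MAP = {"R": "E"}
HIGH_PI_MAP = {"E": "R", "D": "R"}


class TranslationError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinSequence:
    """An identified protein (or IDR) sequence over the 20 canonical letters."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty protein sequence")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"{self.id}: non-canonical residues {''.join(sorted(bad))!r} "
                "(sequence must be uppercase canonical amino acids)"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def count(self, residues: str) -> int:
        return sum(1 for a in self.residues if a in residues)


def translate_dna(dna: str, id: str = "seq") -> ProteinSequence:
    """Standard-code translation of a coding DNA string.

    The sequence must consist of A/C/G/T (case-insensitive) and have length
    divisible by three.  A single terminal stop codon is allowed and stripped;
    an internal stop is an error.
    """
    clean = dna.strip().upper()
    bad = set(clean) - set("ACGT")
    if bad:
        raise TranslationError(f"invalid DNA characters: {''.join(sorted(bad))!r}")
    if len(clean) == 0 or len(clean) % 3 != 0:
        raise TranslationError(f"DNA length {len(clean)} is not a positive multiple of 3")
    protein = str(Seq(clean).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise TranslationError(
            f"internal stop codon at codon {protein.index('*') + 1}"
        )
    if not protein:
        raise TranslationError("sequence encodes only a stop codon")
    return ProteinSequence(id, protein)


def net_charge(protein: ProteinSequence, pH: float, pka_table: str | dict = DEFAULT_PKA_TABLE) -> float:
    """Henderson-Hasselbalch net charge at the given pH.

    Positive groups: free N-terminus, H, K, R; negative groups: free
    C-terminus, D, E, C, Y.  Strictly decreasing in pH.
    """
    t = PKA_TABLES[pka_table] if isinstance(pka_table, str) else pka_table
    seq = protein.residues
    pos = 1.0 / (1.0 + 10.0 ** (pH - t["Nterm"]))
    for a in "HKR":
        pos += seq.count(a) / (1.0 + 10.0 ** (pH - t[a]))
    neg = 1.0 / (1.0 + 10.0 ** (t["Cterm"] - pH))
    for a in "DECY":
        neg += seq.count(a) / (1.0 + 10.0 ** (t[a] - pH))
    return pos - neg


def isoelectric_point(
    protein: ProteinSequence,
    pka_table: str | dict = DEFAULT_PKA_TABLE,
    tol: float = 0.005,
) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(protein, mid, pka_table) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def mean_hydropathy(protein: ProteinSequence, scale: dict | None = None) -> float:
    """Arithmetic mean of a per-residue scale (Kyte-Doolittle by default)."""
    s = scale or KYTE_DOOLITTLE
    return sum(s[a] for a in protein.residues) / len(protein)


def composition_fraction(protein: ProteinSequence, residue_set: str) -> float:
    """Fraction of residues belonging to ``residue_set``."""
    return protein.count(residue_set) / len(protein)


def _parse_pattern(pattern: str) -> list[str | None]:
    """Compile a consensus pattern into per-position residue sets.

    A dash-free pattern is a literal ("RGG").  Otherwise positions are
    dash-separated; alternatives within a position use "/" (e.g. "S/T-P"),
    and "x" matches any residue.
    """
    if not pattern:
        raise ValueError("empty motif pattern")
    if "-" not in pattern:
        positions = list(pattern)
    else:
        positions = pattern.split("-")
    compiled: list[str | None] = []
    for tok in positions:
        if not tok:
            raise ValueError(f"empty position in pattern {pattern!r}")
        if tok.lower() == "x":
            compiled.append(None)
            continue
        letters = "".join(tok.split("/"))
        bad = set(letters) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"invalid residues {''.join(sorted(bad))!r} in {pattern!r}")
        compiled.append(letters)
    return compiled


def motif_count(protein: ProteinSequence, pattern: str) -> int:
    """Non-overlapping left-to-right count of a consensus pattern."""
    compiled = _parse_pattern(pattern)
    L = len(compiled)
    seq = protein.residues
    n = 0
    i = 0
    while i + L <= len(seq):
        if all(p is None or seq[i + k] in p for k, p in enumerate(compiled)):
            n += 1
            i += L
        else:
            i += 1
    return n


def zscore_columns(matrix, ddof: int = 1):
    """Scale each column to mean 0 and unit (sample) variance.

    Accepts an ndarray or DataFrame; a constant column is an error naming the
    offending column.
    """
    df = isinstance(matrix, pd.DataFrame)
    values = matrix.to_numpy(dtype=float) if df else np.asarray(matrix, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=ddof)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        name = matrix.columns[zero[0]] if df else zero[0]
        raise ValueError(f"constant column {name!r} cannot be standardized")
    z = (values - mu) / sd
    if df:
        return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return z


def signature_zscore(observed: float, null_values: Sequence[float], ddof: int = 1) -> float:
    """(observed - mean(null)) / sd(null).

    Negative means the observed statistic is below the null expectation for
    the feature; positive means above.
    """
    null = np.asarray(null_values, dtype=float)
    if null.size < 2:
        raise ValueError("need at least 2 null values")
    sd = float(null.std(ddof=ddof))
    if sd == 0.0:
        raise ValueError("null distribution has zero spread")
    return (float(observed) - float(null.mean())) / sd


@dataclass(frozen=True)
class FeatureDefinition:
    """A named molecular feature computable from a single sequence."""

    name: str
    kind: str  # length | composition | scale-mean | motif-count | pI
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        kinds = ("length", "composition", "scale-mean", "motif-count", "pI")
        if self.kind not in kinds:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "scale-mean":
            missing = set(AMINO_ACIDS) - set(self.params["scale"])
            if missing:
                raise ValueError(f"scale for {self.name} missing {sorted(missing)}")
        if self.kind == "motif-count":
            _parse_pattern(self.params["pattern"])  # validate eagerly

    def evaluate(self, protein: ProteinSequence) -> float:
        if self.kind == "length":
            return float(len(protein))
        if self.kind == "composition":
            return composition_fraction(protein, self.params["residues"])
        if self.kind == "scale-mean":
            return mean_hydropathy(protein, self.params["scale"])
        if self.kind == "motif-count":
            return float(motif_count(protein, self.params["pattern"]))
        return isoelectric_point(protein, self.params.get("pka_table", DEFAULT_PKA_TABLE))


_NET_CHARGE_SCALE = {a: (1.0 if a in "KR" else -1.0 if a in "DE" else 0.0) for a in AMINO_ACIDS}

_CLASSES = {
    "frac_acidic": "DE",
    "frac_basic": "RK",
    "frac_charged": "DERK",
    "frac_aromatic": "FWY",
    "frac_aliphatic": "ILV",
    "frac_polar": "STNQCYH",
    "frac_small": "AGST",
}

_MOTIFS = {
    "cdk_consensus": "S/T-P",
    "cdk_full_consensus": "S/T-P-x-K/R",
    "ckii_consensus": "S/T-x-x-D/E",
    "ck1_consensus": "S/T-x-x-S/T",
    "pka_consensus": "R-R-x-S/T",
    "camk2_consensus": "R-x-x-S/T",
    "gsk3_consensus": "S-x-x-x-S",
    "mec1_consensus": "S/T-Q",
    "prk1_consensus": "L/I/V/M-x-x-Q-x-T-G",
    "ken_box": "K-E-N",
    "d_box": "R-x-x-L-x-x-x-x-N",
    "pip_box": "Q-x-x-L/I/M-x-x-F/Y-F/Y",
    "nls_monopartite": "K-K/R-x-K/R",
    "sumo_consensus": "I/V/L-K-x-D/E",
    "clathrin_box": "L-L/I-D/E-L/I-D/E",
    "er_retention": "K-D-E-L",
    "nes_like": "L-x-x-x-L-x-x-L/I",
    "ww_py_motif": "P-P-x-Y",
    "sh3_ligand": "P-x-x-P",
    "sik_14_3_3": "R-S-x-S-x-P",
    "rgg_motif": "RGG",
    "rg_dipeptide": "RG",
    "fg_repeat": "FG",
    "glfg_repeat": "GLFG",
    "kr_dipeptide": "KR",
    "acidic_run": "D/E-D/E-D/E",
    "basic_run": "K/R-K/R-K/R",
    "q_run": "Q-Q-Q-Q",
    "n_run": "N-N-N-N",
    "s_run": "S-S-S-S",
    "p_run": "P-P-P-P",
}


def default_catalog() -> list[FeatureDefinition]:
    """The default registry of 82 molecular features.

    Length, 20 single-residue compositions, 7 residue-class compositions,
    mean Kyte-Doolittle hydropathy, mean net charge, isoelectric point,
    20 per-residue doublet-repeat counts, and 31 consensus-motif counts.
    """
    cat = [FeatureDefinition("length", "length")]
    for a in AMINO_ACIDS:
        cat.append(FeatureDefinition(f"frac_{a}", "composition", {"residues": a}))
    for name, residues in _CLASSES.items():
        cat.append(FeatureDefinition(name, "composition", {"residues": residues}))
    cat.append(FeatureDefinition("kd_hydropathy", "scale-mean", {"scale": KYTE_DOOLITTLE}))
    cat.append(FeatureDefinition("net_charge", "scale-mean", {"scale": _NET_CHARGE_SCALE}))
    cat.append(FeatureDefinition("pI", "pI"))
    for a in AMINO_ACIDS:
        cat.append(FeatureDefinition(f"rep_{a}{a}", "motif-count", {"pattern": a + a}))
    for name, pattern in _MOTIFS.items():
        cat.append(FeatureDefinition(name, "motif-count", {"pattern": pattern}))
    return cat


def signature_feature_names(catalog: Sequence[FeatureDefinition] | None = None) -> list[str]:
    """Column names of an evolutionary signature: a mean and a log-variance
    per catalog feature (164 for the default 82-feature catalog)."""
    cat = catalog if catalog is not None else default_catalog()
    names = []
    for f in cat:
        names.append(f"{f.name}_mean")
        names.append(f"{f.name}_logvar")
    return names


def feature_profile(
    seqs: Sequence[ProteinSequence],
    catalog: Sequence[FeatureDefinition] | None = None,
    var_floor: float = 1e-12,
) -> np.ndarray:
    """Mean and log sample variance of each feature across a set of sequences
    (e.g. orthologous IDRs), interleaved per feature."""
    cat = catalog if catalog is not None else default_catalog()
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences for a mean/variance profile")
    values = np.array([[f.evaluate(s) for f in cat] for s in seqs])
    mean = values.mean(axis=0)
    logvar = np.log(np.maximum(values.var(axis=0, ddof=1), var_floor))
    out = np.empty(2 * len(cat))
    out[0::2] = mean
    out[1::2] = logvar
    return out


def evolutionary_signature(
    observed: Sequence[ProteinSequence],
    simulated_sets: Sequence[Sequence[ProteinSequence]],
    catalog: Sequence[FeatureDefinition] | None = None,
) -> np.ndarray:
    """Z-score the observed ortholog-set profile against simulated null sets.

    Each simulated set plays the role of one draw from the null model of IDR
    evolution; the signature is the per-column Z-score of the observed profile
    against the null profiles.  Columns whose null spread is zero get a 0.
    """
    cat = catalog if catalog is not None else default_catalog()
    obs = feature_profile(observed, cat)
    null = np.array([feature_profile(s, cat) for s in simulated_sets])
    if null.shape[0] < 2:
        raise ValueError("need at least 2 simulated sets")
    sd = null.std(axis=0, ddof=1)
    out = np.zeros_like(obs)
    ok = sd > 0.0
    out[ok] = (obs[ok] - null.mean(axis=0)[ok]) / sd[ok]
    return out


def compute_feature_frame(
    seqs: Iterable[ProteinSequence],
    features: Sequence[str] | None = None,
    catalog: Sequence[FeatureDefinition] | None = None,
) -> pd.DataFrame:
    """Per-sequence feature table (rows = sequence ids, columns = features)."""
    cat = catalog if catalog is not None else default_catalog()
    by_name = {f.name: f for f in cat}
    if features is None:
        chosen = list(cat)
    else:
        unknown = [f for f in features if f not in by_name]
        if unknown:
            raise ValueError(f"unknown features: {unknown}")
        chosen = [by_name[f] for f in features]
    seqs = list(seqs)
    data = [[f.evaluate(s) for f in chosen] for s in seqs]
    return pd.DataFrame(data, index=[s.id for s in seqs], columns=[f.name for f in chosen])


def apply_residue_map(protein: ProteinSequence, mapping: dict[str, str]) -> ProteinSequence:
    """Substitute every occurrence of the mapped residues (e.g. L->N, V->K,
    I->R for the low-hydrophobicity variant)."""
    residues = "".join(mapping.get(a, a) for a in protein.residues)
    return ProteinSequence(f"{protein.id}_mut", residues)
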