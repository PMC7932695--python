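"""Sequence feature calculators: translation, pI, hydropathy, motifs,
Z-score utilities, and the feature catalog."""

import math

import numpy as np
import pytest
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
from hypothesis import given, settings
from hypothesis import strategies as st

from faidr.cox15 import COX15_DNA, cox15_proteins
from faidr.seqfeatures import (
    AMINO_ACIDS,
    HIGH_PI_MAP,
    LOW_HYDROPATHY_MAP,
    LOW_PI_MAP,
    ProteinSequence,
    TranslationError,
    apply_residue_map,
    composition_fraction,
    default_catalog,
    evolutionary_signature,
    feature_profile,
    isoelectric_point,
    mean_hydropathy,
    motif_count,
    net_charge,
    signature_feature_names,
    signature_zscore,
    translate_dna,
    zscore_columns,
)

seq_strategy = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=60)


class TestTranslation:
    def test_start_codon(self):
        assert translate_dna("ATG").residues == "M"

    def test_wild_type_cox15_idr_is_45_residues(self):
        protein = translate_dna(COX15_DNA["wt"])
        assert len(protein) == 45
        assert protein.residues.startswith("M")

    def test_lowercase_accepted(self):
        assert translate_dna("atgGCT").residues == "MA"

    @pytest.mark.parametrize(
        "dna,match",
        [
            ("ATGTAAGCT", "internal stop"),
            ("ATGC", "multiple of 3"),
            ("ATGXYZ", "invalid DNA"),
        ],
    )
    def test_distinct_errors(self, dna, match):
        with pytest.raises(TranslationError, match=match):
            translate_dna(dna)

    def test_terminal_stop_stripped(self):
        assert translate_dna("ATGTAA").residues == "M"


class TestIsoelectricPoint:
    def test_cross_check_against_biopython_bjellqvist(self):
        """Independent oracle: Biopython's charge-based pI with the same
        (Bjellqvist) pKa set, on all five Cox15 variants that do not
        saturate that table's arginine pKa."""
        for name in ("low_pi", "sim"):
            p = cox15_proteins()[name]
            ours = isoelectric_point(p, pka_table="bjellqvist", tol=1e-4)
            ref = IsoelectricPoint(p.residues).pi()
            assert ours == pytest.approx(ref, abs=0.02)

    def test_zero_net_charge_at_pi(self):
        for p in cox15_proteins().values():
            pi = isoelectric_point(p, tol=1e-4)
            assert abs(net_charge(p, pi)) < 0.01

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seq_strategy)
    def test_net_charge_strictly_decreasing(self, residues):
        p = ProteinSequence("s", residues)
        phs = np.linspace(0.5, 13.5, 14)
        charges = [net_charge(p, ph) for ph in phs]
        assert np.all(np.diff(charges) < 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seq_strategy, st.integers(0, 59))
    def test_arginine_substitutions_shift_pi(self, residues, pos):
        """Replacing any residue with R never decreases pI; replacing R with
        E never increases it."""
        pos = pos % len(residues)
        p = ProteinSequence("s", residues)
        more_r = ProteinSequence("s", residues[:pos] + "R" + residues[pos + 1 :])
        assert isoelectric_point(more_r, tol=1e-4) >= isoelectric_point(p, tol=1e-4) - 1e-3
        if "R" in residues:
            fewer = ProteinSequence("s", residues.replace("R", "E", 1))
            assert isoelectric_point(fewer, tol=1e-4) <= isoelectric_point(p, tol=1e-4) + 1e-3


class TestHydropathy:
    def test_single_and_pair_means(self):
        assert mean_hydropathy(ProteinSequence("s", "A")) == pytest.approx(1.8)
        assert mean_hydropathy(ProteinSequence("s", "AR")) == pytest.approx(-1.35)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seq_strategy, st.integers(0, 10**6))
    def test_permutation_invariance(self, residues, seed):
        rng = np.random.default_rng(seed)
        shuffled = "".join(rng.permutation(list(residues)))
        assert mean_hydropathy(ProteinSequence("s", shuffled)) == pytest.approx(
            mean_hydropathy(ProteinSequence("s", residues))
        )

    def test_low_hydropathy_map_strictly_decreases(self):
        """L->N, V->K, I->R swaps the three most hydrophobic residues for the
        three least, so mean hydropathy must strictly drop whenever any of
        L/V/I are present."""
        for residues in ("LLKAV", "IIII", "MALVI", cox15_proteins()["wt"].residues):
            p = ProteinSequence("s", residues)
            mut = apply_residue_map(p, LOW_HYDROPATHY_MAP)
            assert mean_hydropathy(mut) < mean_hydropathy(p)


class TestCompositionAndMotifs:
    def test_fraction(self):
        assert composition_fraction(ProteinSequence("s", "QQAQ"), "Q") == 0.75

    def test_partition_sums_to_one(self):
        p = ProteinSequence("s", "MLFRNIEVGRQAAK")
        halves = [composition_fraction(p, AMINO_ACIDS[:10]), composition_fraction(p, AMINO_ACIDS[10:])]
        assert sum(halves) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "seq,pattern,expected",
        [
            ("RGGRGG", "RGG", 2),
            ("SPATP", "S/T-P", 2),
            ("AAAA", "AAA", 1),  # non-overlapping, left to right
            ("SQTQ", "S/T-Q", 2),
            ("RASP", "x-A-S/T", 1),
        ],
    )
    def test_motif_counts(self, seq, pattern, expected):
        assert motif_count(ProteinSequence("s", seq), pattern) == expected

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            motif_count(ProteinSequence("s", "AAA"), "")


class TestZscores:
    def test_two_point_column(self):
        z = zscore_columns(np.array([[1.0], [3.0]]))
        assert z[:, 0] == pytest.approx([-1 / math.sqrt(2), 1 / math.sqrt(2)])

    def test_idempotent_and_standardized(self):
        rng = np.random.default_rng(0)
        z1 = zscore_columns(rng.standard_normal((50, 4)))
        assert np.abs(z1.mean(axis=0)).max() < 1e-10
        assert np.abs(z1.std(axis=0, ddof=1) - 1).max() < 1e-10
        assert np.abs(zscore_columns(z1) - z1).max() < 1e-10

    def test_constant_column_named(self):
        import pandas as pd

        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            zscore_columns(df)

    def test_signature_zscore(self):
        rng = np.random.default_rng(1)
        null = rng.standard_normal(1000) * 2.3 + 0.7
        mu, sd = null.mean(), null.std(ddof=1)
        assert signature_zscore(mu, null) == pytest.approx(0.0, abs=1e-12)
        assert signature_zscore(mu + 2 * sd, null) == pytest.approx(2.0, abs=1e-12)
        with pytest.raises(ValueError, match="spread"):
            signature_zscore(1.0, [2.0, 2.0, 2.0])


class TestCatalog:
    def test_82_features_164_signature_columns(self):
        cat = default_catalog()
        assert len(cat) == 82
        names = signature_feature_names(cat)
        assert len(names) == 164
        assert len(set(names)) == 164

    def test_profile_and_signature_shapes(self):
        rng = np.random.default_rng(3)
        def rand_seqs(k):
            return [
                ProteinSequence(f"s{i}", "".join(rng.choice(list(AMINO_ACIDS), 40)))
                for i in range(k)
            ]
        prof = feature_profile(rand_seqs(4))
        assert prof.shape == (164,) and np.all(np.isfinite(prof))
        sig = evolutionary_signature(rand_seqs(4), [rand_seqs(4) for _ in range(5)])
        assert sig.shape == (164,)
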