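"""Cox15 N-terminal IDR variant sequences.

The N-terminal disordered region of yeast Cox15 (amino acids 1-45) is a
mitochondrial targeting signal whose function depends on sequence-distributed
features — elevated isoelectric point and hydrophobicity.  The five coding
DNA sequences below are the published genotypes of the GFP-tagged strains:
the wild-type IDR, a low-pI variant (every R mutated to E), a
low-hydrophobicity variant (L->N, V->K, I->R), an in-silico "evolved"
(simulated) IDR with no constraint on sequence-distributed features, and the
simulated IDR with its pI raised back (D/E->R).  They serve as worked-example
inputs for the sequence-feature calculators.
"""

from __future__ import annotations

from .seqfeatures import ProteinSequence, translate_dna

COX15_DNA: dict[str, str] = {
    "wt": (
        "ATGCTTTTCAGAAACATAGAAGTGGGCAGGCAGGCAGCTAAGCTATTAACGAGAACCTCGAGT"
        "CGTTTGGCCTGGCAAAGTATTGGGGCCTCAAGGAATATTTCTACCATCAGACAACAAATCAGA"
        "AAGACTCAA"
    ),
    "low_pi": (
        "ATGCTTTTCGAAAACATAGAAGTGGGCGAACAGGCAGCTAAGCTATTAACGGAAACCTCGAGT"
        "GAATTGGCCTGGCAAAGTATTGGGGCCTCAGAAAATATTTCTACCATCGAACAACAAATCGAA"
        "AAGACTCAA"
    ),
    "low_hydrophobicity": (
        "ATGAATTTCAGAAACAGAGAAAAGGGCAGGCAGGCAGCTAAGAATAATACGAGAACCTCGAGT"
        "CGTAATGCCTGGCAAAGTAGAGGGGCCTCAAGGAATAGATCTACCAGAAGACAACAAAGAAGA"
        "AAGACTCAA"
    ),
    "sim": (
        "ATGCTGCTGAGAAACGTTGAATCCTCCAAACCCGAAGCAAAACTAATTACCAGAGCTTCTTAC"
        "GCCGTGCCCAGGAAAATGAACAATTCATACTTGGGCGATAATACATTGAATAACCTGGTCTTA"
        "AAGAAGAGCTATCTTTTAGCTGTTCCCAGAAAGATTCCCACGATTCCAGCCAGTCTGCCGCAA"
        "ATTCGTGACAAGGAT"
    ),
    "sim_high_pi": (
        "ATGCTGCTGAGAAACGTTAGATCCTCCAAACCCAGAGCAAAACTAATTACCAGAGCTTCTTAC"
        "GCCGTGCCCAGGAAAATGAACAATTCATACTTGGGCAGAAATACATTGAATAACCTGGTCTTA"
        "AAGAAGAGCTATCTTTTAGCTGTTCCCAGAAAGATTCCCACGATTCCAGCCAGTCTGCCGCAA"
        "ATTCGTAGAAAGAGA"
    ),
}

# pI of each translated variant under the default pKa table, as reported for
# the corresponding strains
COX15_EXPECTED_PI: dict[str, float] = {
    "wt": 12.40,
    "low_pi": 4.04,
    "sim": 10.2,
    "sim_high_pi": 12.2,
}


def cox15_proteins() -> dict[str, ProteinSequence]:
    """Translate all five variant coding sequences."""
    return {name: translate_dna(dna, id=f"COX15_IDR1_{name}") for name, dna in COX15_DNA.items()}
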