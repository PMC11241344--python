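"""Pinned physicochemical data tables.

The seven three-class amino-acid partitions are the canonical Dubchak-style
groupings used by standard CTD (composition/transition/distribution)
implementations; they were cross-checked against the CTD literature before
being pinned here.  Classes are numbered 1..3 in the order the groups are
listed for each attribute, and the class semantics are recorded in
``PARTITION_CLASS_LABELS`` for reporting only — descriptor values depend
solely on the index.

The pKa set used for Henderson–Hasselbalch net-charge and isoelectric-point
calculations is the EMBOSS set.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# attribute -> (class1 residues, class2 residues, class3 residues)
PROPERTY_PARTITIONS: dict[str, tuple[str, str, str]] = {
    # polar / neutral / hydrophobic
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    # 0–2.78 / 2.95–4.0 / 4.03–8.08 (normalized van der Waals volume)
    "normalized_vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    # polarity value 4.9–6.2 / 8.0–9.2 / 10.4–13.0
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    # polarizability 0–0.108 / 0.128–0.186 / 0.219–0.409
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    # positive / neutral / negative
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    # helix / strand / coil propensity
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    # buried / exposed / intermediate
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

PARTITION_CLASS_LABELS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("polar", "neutral", "hydrophobic"),
    "normalized_vdw_volume": ("small", "medium", "large"),
    "polarity": ("low", "medium", "high"),
    "polarizability": ("low", "medium", "high"),
    "charge": ("positive", "neutral", "negative"),
    "secondary_structure": ("helix", "strand", "coil"),
    "solvent_accessibility": ("buried", "exposed", "intermediate"),
}

# EMBOSS pKa values.  Positive groups: N-terminus, K, R, H; negative groups:
# C-terminus, D, E, C, Y.
PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
}
POSITIVE_SIDE_CHAINS = "KRH"
NEGATIVE_SIDE_CHAINS = "DECY"

# Reference peptides printed in the CPP literature, shipped for fixtures and
# worked examples.  CPRE12 appears in print in two variants differing by one
# glutamine; both are kept verbatim and neither is used in numeric tests.
PENETRATIN = "RQIKIWFQNRRMKWKK"
MELITTIN = "GIGAVLKVLTTGLPALISWIKRKRQQ"
CPRE12_VARIANTS = ("SYQWQQIFYRSLDGSGAKE", "SYQWQIFYRSLDGSGAKE")


def _check_partitions() -> None:
    for name, groups in PROPERTY_PARTITIONS.items():
        joined = "".join(groups)
        if sorted(joined) != sorted(AMINO_ACIDS):
            raise AssertionError(f"partition {name!r} does not cover the 20 residues exactly")
        if any(len(g) == 0 for g in groups):
            raise AssertionError(f"partition {name!r} has an empty class")


_check_partitions()


def partition_class_map(name: str) -> dict[str, int]:
    """Residue -> class index (1, 2 or 3) for one attribute."""
    groups = PROPERTY_PARTITIONS[name]
    return {aa: k + 1 for k, group in enumerate(groups) for aa in group}
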