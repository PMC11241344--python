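"""Physicochemical sequence descriptors.

Three families:

* **CTD** — composition, transition and distribution of seven three-class
  physicochemical partitions of the 20 residues (hydrophobicity, normalized
  van der Waals volume, polarity, polarizability, charge, secondary-structure
  propensity, solvent accessibility).  21 values per partition (3 C + 3 T +
  15 D) = 147 values.
* **Instability index** — the dipeptide-weight sum
  ``II = (10/L) * sum_i DIWV(x_i, x_{i+1})`` over the published 400-entry
  DIWV table.
* **Global descriptors** — length, Henderson–Hasselbalch net charge at a
  given pH, charge density, isoelectric point, aromaticity, aliphatic index,
  hydrophobic ratio and molecular weight.

Distribution convention (pinned): for each class ``k`` with ``n_k`` member
residues, report ``100 * pos / L`` for the member at rank ``max(1,
ceil(f * n_k))`` for f in {0, 0.25, 0.50, 0.75, 1.0}; an absent class
contributes five zeros.  Reference CTD codes differ in this rounding, so the
convention here is explicit and the test oracle uses the same one.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import DIWV
from scipy.optimize import brentq

from ._tables import (
    NEGATIVE_SIDE_CHAINS,
    PKA,
    POSITIVE_SIDE_CHAINS,
    PROPERTY_PARTITIONS,
    partition_class_map,
)
from .sequence_io import Peptide, SequenceSet

logger = logging.getLogger(__name__)

PARTITION_NAMES = tuple(PROPERTY_PARTITIONS)
_CLASS_MAPS = {name: partition_class_map(name) for name in PARTITION_NAMES}

_DISTRIBUTION_FRACTIONS = (0.0, 0.25, 0.50, 0.75, 1.0)
_DISTRIBUTION_TAGS = ("first", "25", "50", "75", "100")

# Hydrophobic residues = class 3 of the hydrophobicity partition.
_HYDROPHOBIC = set(PROPERTY_PARTITIONS["hydrophobicity"][2])
_AROMATIC = set("FWY")
# Aliphatic-index weights (Ikai 1980): relative volumes of aliphatic side chains.
_ALIPHATIC_WEIGHTS = {"A": 1.0, "V": 2.9, "I": 3.9, "L": 3.9}

# Average residue masses (Da) and the mass of one water for peptide-bond
# condensation; standard monoisotopic-free average masses.
_RESIDUE_MASS = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155, "F": 147.1766,
    "G": 57.0519, "H": 137.1411, "I": 113.1594, "K": 128.1741, "L": 113.1594,
    "M": 131.1926, "N": 114.1038, "P": 97.1167, "Q": 128.1307, "R": 156.1875,
    "S": 87.0782, "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}
_WATER = 18.0153


def ctd_composition(p: Peptide, partition: str) -> tuple[float, float, float]:
    """Fraction of residues in each of the three classes of ``partition``."""
    cmap = _CLASS_MAPS[partition]
    counts = [0, 0, 0]
    for aa in p.seq:
        counts[cmap[aa] - 1] += 1
    L = len(p)
    return tuple(c / L for c in counts)


def ctd_transition(p: Peptide, partition: str) -> tuple[float, float, float]:
    """Frequency of adjacent class changes for pairs (1,2), (1,3), (2,3).

    Unordered: a 1->2 step and a 2->1 step both count toward T12.  A
    length-1 peptide has no adjacent pairs; defined as all zeros.
    """
    L = len(p)
    if L < 2:
        logger.warning("ctd_transition: length-1 peptide %r, returning zeros", p.id)
        return (0.0, 0.0, 0.0)
    cmap = _CLASS_MAPS[partition]
    classes = [cmap[aa] for aa in p.seq]
    pair_counts = {(1, 2): 0, (1, 3): 0, (2, 3): 0}
    for a, b in zip(classes, classes[1:]):
        if a != b:
            pair_counts[(min(a, b), max(a, b))] += 1
    return tuple(pair_counts[k] / (L - 1) for k in ((1, 2), (1, 3), (2, 3)))


def ctd_distribution(p: Peptide, partition: str) -> tuple[float, ...]:
    """Positional percentiles (first/25/50/75/100%) of each class, 15 values."""
    cmap = _CLASS_MAPS[partition]
    L = len(p)
    positions: dict[int, list[int]] = {1: [], 2: [], 3: []}
    for i, aa in enumerate(p.seq, start=1):
        positions[cmap[aa]].append(i)
    out: list[float] = []
    for k in (1, 2, 3):
        pos = positions[k]
        if not pos:
            out.extend([0.0] * 5)
            continue
        n_k = len(pos)
        for f in _DISTRIBUTION_FRACTIONS:
            rank = max(1, math.ceil(f * n_k))
            out.append(100.0 * pos[rank - 1] / L)
    return tuple(out)


def instability_index(p: Peptide) -> float:
    """Guruprasad instability index from the DIWV dipeptide weights."""
    L = len(p)
    if L < 2:
        raise ValueError(f"instability index undefined for length-1 peptide {p.id!r}")
    total = 0.0
    for a, b in zip(p.seq, p.seq[1:]):
        total += DIWV[a][b]
    return 10.0 / L * total


def net_charge(seq: str, ph: float = 7.0) -> float:
    """Henderson–Hasselbalch net charge including free termini."""
    pos = 1.0 / (1.0 + 10.0 ** (ph - PKA["Nterm"]))
    neg = 1.0 / (1.0 + 10.0 ** (PKA["Cterm"] - ph))
    for aa in seq:
        if aa in POSITIVE_SIDE_CHAINS:
            pos += 1.0 / (1.0 + 10.0 ** (ph - PKA[aa]))
        elif aa in NEGATIVE_SIDE_CHAINS:
            neg += 1.0 / (1.0 + 10.0 ** (PKA[aa] - ph))
    return pos - neg


def isoelectric_point(seq: str) -> float:
    """pH at which the net charge crosses zero (bisection on [0, 14])."""
    lo, hi = 1e-3, 14.0 - 1e-3
    if net_charge(seq, lo) < 0:  # all-acidic edge case: charge negative everywhere
        return lo
    if net_charge(seq, hi) > 0:
        return hi
    return brentq(lambda ph: net_charge(seq, ph), lo, hi, xtol=1e-9)


def molecular_weight(seq: str) -> float:
    return sum(_RESIDUE_MASS[aa] for aa in seq) + _WATER


def global_descriptors(p: Peptide, ph: float = 7.0) -> dict[str, float]:
    """Whole-sequence descriptors (length, charge, pI, aromaticity, ...)."""
    if not (0 < ph < 14):
        raise ValueError(f"pH must be in (0, 14), got {ph}")
    L = len(p)
    charge = net_charge(p.seq, ph)
    mw = molecular_weight(p.seq)
    return {
        "length": float(L),
        "net_charge": charge,
        "charge_density": charge / mw,
        "isoelectric_point": isoelectric_point(p.seq),
        "aromaticity": sum(aa in _AROMATIC for aa in p.seq) / L,
        "aliphatic_index": 100.0 * sum(_ALIPHATIC_WEIGHTS.get(aa, 0.0) for aa in p.seq) / L,
        "hydrophobic_ratio": sum(aa in _HYDROPHOBIC for aa in p.seq) / L,
        "molecular_weight": mw,
    }


def ctd_descriptor_names() -> list[str]:
    names: list[str] = []
    for part in PARTITION_NAMES:
        names.extend(f"{part}.C{k}" for k in (1, 2, 3))
        names.extend(f"{part}.T{a}{b}" for a, b in ((1, 2), (1, 3), (2, 3)))
        names.extend(
            f"{part}.D{k}.{tag}" for k in (1, 2, 3) for tag in _DISTRIBUTION_TAGS
        )
    return names


def descriptor_names(ph: float = 7.0) -> list[str]:
    dummy = Peptide("x", "AC")
    return ctd_descriptor_names() + ["instability_index"] + list(global_descriptors(dummy, ph))


def descriptor_vector(p: Peptide, ph: float = 7.0) -> dict[str, float]:
    """All descriptors for one peptide, keyed by stable descriptor names."""
    values: dict[str, float] = {}
    for part in PARTITION_NAMES:
        for k, v in zip((1, 2, 3), ctd_composition(p, part)):
            values[f"{part}.C{k}"] = v
        for (a, b), v in zip(((1, 2), (1, 3), (2, 3)), ctd_transition(p, part)):
            values[f"{part}.T{a}{b}"] = v
        dist = ctd_distribution(p, part)
        i = 0
        for k in (1, 2, 3):
            for tag in _DISTRIBUTION_TAGS:
                values[f"{part}.D{k}.{tag}"] = dist[i]
                i += 1
    values["instability_index"] = instability_index(p)
    values.update(global_descriptors(p, ph))
    return values


class FeatureMatrix:
    """Named descriptor columns x peptide rows, with an optional label vector."""

    def __init__(self, X: pd.DataFrame, y: pd.Series | None = None):
        if y is not None and len(y) != len(X):
            raise ValueError("label vector length does not match matrix rows")
        self.X = X
        self.y = y

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def __len__(self) -> int:
        return len(self.X)

    def select(self, names: list[str]) -> "FeatureMatrix":
        missing = [n for n in names if n not in self.X.columns]
        if missing:
            raise KeyError(f"unknown descriptor columns: {missing}")
        return FeatureMatrix(self.X[names].copy(), self.y)

    def to_frame(self) -> pd.DataFrame:
        df = self.X.copy()
        if self.y is not None:
            df.insert(0, "label", self.y)
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def read_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id")
        y = None
        if "label" in df.columns:
            y = df.pop("label")
        return cls(df, y)


def featurize(s: SequenceSet, ph: float = 7.0) -> FeatureMatrix:
    """Descriptor matrix for a sequence set; labels carried through.

    Raises with the offending record id if any peptide fails (e.g. length 1,
    for which the instability index is undefined).
    """
    rows: list[dict[str, float]] = []
    ids: list[str] = []
    for p in s:
        try:
            rows.append(descriptor_vector(p, ph))
        except Exception as exc:
            raise ValueError(f"featurize failed for record {p.id!r}: {exc}") from exc
        ids.append(p.id)
    names = descriptor_names(ph)
    X = pd.DataFrame(rows, index=ids, columns=names, dtype=float)
    if not np.isfinite(X.to_numpy()).all():
        bad = X.index[~np.isfinite(X.to_numpy()).all(axis=1)].tolist()
        raise ValueError(f"non-finite descriptor values for records {bad}")
    labels = [p.label for p in s]
    y = None
    if any(l is not None for l in labels):
        y = pd.Series(labels, index=ids, name="label")
    logger.info("featurize: %d peptides x %d descriptors", len(ids), X.shape[1])
    return FeatureMatrix(X, y)
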