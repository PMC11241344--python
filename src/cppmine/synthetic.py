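"""Synthetic peptide and proteome generators.

The labeled-set generator emulates the qualitative contrast between
cell-penetrating peptides and background peptides: the CPP-like class is
drawn from a residue-frequency table enriched in cationic (R, K) and
hydrophobic/aromatic (L, W) residues, the non-CPP class from a near-uniform
background.  ``signal_strength`` interpolates the CPP table toward the
background — 1.0 gives the full contrast, 0.0 makes the two classes
exchangeable — so classifier behaviour can be probed across the whole
separability range without downloading any real database.

What this emulates (and what it does not): real CPP sets differ from
background in charge and hydrophobic moment but also carry motif and
length structure that an i.i.d. residue model cannot reproduce; passing
tests demonstrate pipeline correctness and sensitivity to compositional
signal, not real-world predictive accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._tables import AMINO_ACIDS
from .sequence_io import CPP_LABEL, NON_CPP_LABEL, Peptide, SequenceSet

logger = logging.getLogger(__name__)

# CPP-like residue bias: R 0.20, K 0.15, W 0.08, L 0.10; the 16 remaining
# residues share the rest evenly.
_rest = (1.0 - (0.20 + 0.15 + 0.08 + 0.10)) / 16
CPP_BIAS: dict[str, float] = {
    aa: {"R": 0.20, "K": 0.15, "W": 0.08, "L": 0.10}.get(aa, _rest) for aa in AMINO_ACIDS
}
BACKGROUND: dict[str, float] = {aa: 0.05 for aa in AMINO_ACIDS}


@dataclass
class GeneratorConfig:
    n_per_class: int = 500
    length_range: tuple[int, int] = (5, 30)
    seed: int = 40
    signal_strength: float = 1.0
    cpp_bias: dict[str, float] = field(default_factory=lambda: dict(CPP_BIAS))
    background: dict[str, float] = field(default_factory=lambda: dict(BACKGROUND))

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo > hi or lo < 2:
            raise ValueError(f"invalid length_range {self.length_range}")
        if not (0 <= self.signal_strength <= 1):
            raise ValueError("signal_strength must be in [0, 1]")
        for name, table in (("cpp_bias", self.cpp_bias), ("background", self.background)):
            total = sum(table.values())
            if total <= 0:
                raise ValueError(f"{name}: degenerate frequency table")
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name}: frequencies sum to {total}, expected 1")


def _freq_array(table: dict[str, float]) -> np.ndarray:
    return np.array([table[aa] for aa in AMINO_ACIDS], dtype=float)


def _draw_peptides(rng, n, lengths, freqs) -> list[str]:
    letters = np.array(list(AMINO_ACIDS))
    return ["".join(rng.choice(letters, size=L, p=freqs)) for L in lengths]


def generate_labeled_set(cfg: GeneratorConfig) -> SequenceSet:
    """n_per_class CPP-like (label 1) + n_per_class background (label 0) peptides."""
    rng = np.random.default_rng(cfg.seed)
    bg = _freq_array(cfg.background)
    cpp = cfg.signal_strength * _freq_array(cfg.cpp_bias) + (1 - cfg.signal_strength) * bg
    lo, hi = cfg.length_range
    records: list[Peptide] = []
    for label, freqs, tag in ((CPP_LABEL, cpp, "cpp"), (NON_CPP_LABEL, bg, "bg")):
        lengths = rng.integers(lo, hi + 1, size=cfg.n_per_class)
        for i, seq in enumerate(_draw_peptides(rng, cfg.n_per_class, lengths, freqs)):
            records.append(Peptide(id=f"{tag}_{i:05d}", seq=seq, label=label))
    logger.info("generate_labeled_set: %d peptides/class, signal %.2f, seed %d",
                cfg.n_per_class, cfg.signal_strength, cfg.seed)
    return SequenceSet(records, provenance=f"synthetic(seed={cfg.seed}, signal={cfg.signal_strength})")


def generate_toy_proteome(
    n_proteins: int,
    length: int,
    spike: Peptide | None = None,
    seed: int = 40,
) -> SequenceSet:
    """Background-composition proteins, optionally carrying one spiked peptide.

    The spike is embedded verbatim in the first protein, preceded by a
    lysine and followed by a non-proline residue, so that when the spike
    itself starts with a non-proline residue, ends in K/R and contains no
    internal unblocked tryptic site it is recovered exactly by trypsin
    digestion.
    """
    rng = np.random.default_rng(seed)
    bg = _freq_array(BACKGROUND)
    proteins = _draw_peptides(rng, n_proteins, [length] * n_proteins, bg)
    if spike is not None:
        if len(spike) + 2 > length:
            raise ValueError(f"spike of length {len(spike)} does not fit in proteins of length {length}")
        if spike.seq[0] == "P" or spike.seq[-1] not in "KR":
            logger.warning("spike %r may not be exactly recoverable by trypsin", spike.id)
        host = proteins[0]
        budget = length - len(spike) - 1  # one residue for the left-flank K
        pos = int(rng.integers(0, budget + 1))
        post = host[pos + len(spike) + 1:]
        if post.startswith("P"):  # keep the right-hand tryptic site unblocked
            post = "A" + post[1:]
        proteins[0] = host[:pos] + "K" + spike.seq + post
        assert len(proteins[0]) == length
    records = [Peptide(id=f"prot_{i:04d}", seq=seq) for i, seq in enumerate(proteins)]
    return SequenceSet(records, provenance=f"toy_proteome(seed={seed})")
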