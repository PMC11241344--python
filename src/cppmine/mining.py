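"""In-silico proteome mining for CPP candidates.

Proteins are digested with the 35 ExPASy-style enzymatic cleavage rules
shipped with pyteomics; fragments within a length window (default 9-35 aa)
are pooled across rules, deduplicated, passed through a greedy
composition-diversity filter, featurized and ranked by the stacked model's
predicted CPP probability.

The diversity filter is a pinned interpretation of "amino-acid composition
diversity limited to 30%": candidates are scanned in input order and one is
dropped when the L1 distance between its 20-component composition-fraction
vector and that of any already-kept candidate is below the threshold
(default 0.30).  Setting the threshold to 0 disables the filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import parser as pyt_parser

from ._tables import AMINO_ACIDS
from .descriptors import featurize
from .ensemble import EnsembleResults
from .sequence_io import Peptide, SequenceSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CleavageRule:
    """A named enzymatic cleavage specification (regex site pattern)."""

    name: str
    pattern: str


CLEAVAGE_RULES: dict[str, CleavageRule] = {
    name: CleavageRule(name, pattern) for name, pattern in sorted(pyt_parser.expasy_rules.items())
}
logger.info("cleavage registry: %d rules", len(CLEAVAGE_RULES))


def get_rule(name: str) -> CleavageRule:
    try:
        return CLEAVAGE_RULES[name]
    except KeyError:
        raise KeyError(
            f"unknown cleavage rule {name!r}; registry: {sorted(CLEAVAGE_RULES)}"
        ) from None


def cleave(protein: Peptide, rule: CleavageRule | str, missed_cleavages: int = 0) -> list[Peptide]:
    """Ordered fragments of ``protein`` under ``rule``.

    With ``missed_cleavages = m`` every run of up to m+1 consecutive
    fragments is also emitted.  At m = 0 the fragments concatenate back to
    the protein.
    """
    if isinstance(rule, str):
        rule = get_rule(rule)
    frags = [
        Peptide(id=f"{protein.id}|{rule.name}|{pos}", seq=seq)
        for pos, seq in pyt_parser.icleave(protein.seq, rule.pattern, missed_cleavages, regex=True)
        if seq
    ]
    return frags


def enumerate_candidates(
    proteome: SequenceSet,
    rules: list[CleavageRule | str] | None = None,
    min_len: int = 9,
    max_len: int = 35,
    missed_cleavages: int = 0,
) -> SequenceSet:
    """Union of length-filtered fragments over all rules, deduplicated by
    sequence (first occurrence keeps its provenance id)."""
    if len(proteome) == 0:
        logger.warning("enumerate_candidates: empty proteome")
        return SequenceSet([], provenance="mined")
    rules = list(CLEAVAGE_RULES.values()) if rules is None else [
        get_rule(r) if isinstance(r, str) else r for r in rules
    ]
    seen: set[str] = set()
    out: list[Peptide] = []
    for protein in proteome:
        for rule in rules:
            for frag in cleave(protein, rule, missed_cleavages):
                if not (min_len <= len(frag) <= max_len) or frag.seq in seen:
                    continue
                seen.add(frag.seq)
                out.append(frag)
    logger.info("enumerate_candidates: %d unique candidates (%d-%d aa, %d rules)",
                len(out), min_len, max_len, len(rules))
    return SequenceSet(out, provenance="mined")


def composition_vector(seq: str) -> np.ndarray:
    counts = np.array([seq.count(aa) for aa in AMINO_ACIDS], dtype=float)
    return counts / len(seq)


def diversity_filter(candidates: SequenceSet, threshold: float = 0.30) -> SequenceSet:
    """Greedy composition-diversity filter (see module docstring).

    ``threshold = 0`` keeps everything; outside (0, 1] (other than 0) raises.
    """
    if threshold == 0:
        return candidates
    if not (0 < threshold <= 1):
        raise ValueError(f"diversity threshold must be 0 or in (0, 1], got {threshold}")
    kept: list[Peptide] = []
    kept_vecs: list[np.ndarray] = []
    for p in candidates:
        v = composition_vector(p.seq)
        if kept_vecs:
            dists = np.abs(np.stack(kept_vecs) - v).sum(axis=1)
            if dists.min() < threshold:
                continue
        kept.append(p)
        kept_vecs.append(v)
    logger.info("diversity_filter: %d -> %d at L1 threshold %.2f", len(candidates), len(kept), threshold)
    return SequenceSet(kept, provenance=candidates.provenance)


def mine(
    proteome: SequenceSet,
    results: EnsembleResults,
    top_k: int = 50,
    rules: list[CleavageRule | str] | None = None,
    min_len: int = 9,
    max_len: int = 35,
    diversity_threshold: float = 0.30,
    ph: float = 7.0,
) -> pd.DataFrame:
    """Digest, filter, featurize and rank; returns the top_k candidate table.

    Columns: sequence, source_id, rule, probability, predicted_class —
    sorted by probability descending (ties by sequence for determinism).
    """
    candidates = enumerate_candidates(proteome, rules, min_len, max_len)
    candidates = diversity_filter(candidates, diversity_threshold)
    if len(candidates) == 0:
        return pd.DataFrame(columns=["sequence", "source_id", "rule", "probability", "predicted_class"])
    features = featurize(candidates, ph=ph).select(results.feature_manifest)
    proba, pred = results.predict(features)
    source_ids, rule_names = zip(*((p.id.rsplit("|", 2)[0], p.id.rsplit("|", 2)[1]) for p in candidates))
    table = pd.DataFrame(
        {
            "sequence": candidates.sequences(),
            "source_id": source_ids,
            "rule": rule_names,
            "probability": proba,
            "predicted_class": pred,
        }
    ).sort_values(["probability", "sequence"], ascending=[False, True], kind="mergesort")
    return table.head(top_k).reset_index(drop=True)
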