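"""Independent brute-force oracles for cross-checking the implementation.

Everything here is deliberately written from the definitions, without
importing the implementation's computational code (the pinned data tables
are shared, since they are data, not logic).
"""

from __future__ import annotations

import math
import re

from Bio.SeqUtils.ProtParamData import DIWV

from cppmine._tables import PROPERTY_PARTITIONS

FRACTIONS = (0.0, 0.25, 0.50, 0.75, 1.0)


def composition(seq: str, partition: str) -> list[float]:
    groups = PROPERTY_PARTITIONS[partition]
    return [sum(1 for aa in seq if aa in g) / len(seq) for g in groups]


def transition(seq: str, partition: str) -> list[float]:
    if len(seq) < 2:
        return [0.0, 0.0, 0.0]
    groups = PROPERTY_PARTITIONS[partition]
    out = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        n = 0
        for k in range(len(seq) - 1):
            a, b = seq[k], seq[k + 1]
            if (a in groups[i] and b in groups[j]) or (a in groups[j] and b in groups[i]):
                n += 1
        out.append(n / (len(seq) - 1))
    return out


def distribution(seq: str, partition: str) -> list[float]:
    groups = PROPERTY_PARTITIONS[partition]
    out = []
    for g in groups:
        positions = [i + 1 for i, aa in enumerate(seq) if aa in g]
        if not positions:
            out.extend([0.0] * 5)
            continue
        for f in FRACTIONS:
            rank = max(1, math.ceil(f * len(positions)))
            out.append(100.0 * positions[rank - 1] / len(seq))
    return out


def instability(seq: str) -> float:
    total = 0.0
    for i in range(len(seq) - 1):
        total += DIWV[seq[i]][seq[i + 1]]
    return 10.0 / len(seq) * total


def net_charge(seq: str, ph: float, pka: dict) -> float:
    """Direct Henderson–Hasselbalch evaluation over the pinned pKa set."""
    total = 1.0 / (1.0 + 10.0 ** (ph - pka["Nterm"]))
    total -= 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - ph))
    for aa in seq:
        if aa in "KRH":
            total += 1.0 / (1.0 + 10.0 ** (ph - pka[aa]))
        elif aa in "DECY":
            total -= 1.0 / (1.0 + 10.0 ** (pka[aa] - ph))
    return total


def global_alignment_identities(a: str, b: str) -> tuple[float, set[int]]:
    """Exhaustive global alignment under match +1 / mismatch 0 / gap -1.

    Returns the optimal score and the set of match counts achievable by
    score-optimal alignments.  Exponential — tiny sequences only.
    """
    best: dict[tuple[int, int], dict[tuple[int, int], None]] = {}

    def rec(i: int, j: int) -> set[tuple[int, int]]:
        # returns set of (score, matches) reachable aligning a[i:] vs b[j:]
        key = (i, j)
        if key in best:
            return set(best[key])
        if i == len(a) and j == len(b):
            out = {(0, 0)}
        else:
            out = set()
            if i < len(a) and j < len(b):
                m = 1 if a[i] == b[j] else 0
                out |= {(s + m, c + m) for s, c in rec(i + 1, j + 1)}
            if i < len(a):
                out |= {(s - 1, c) for s, c in rec(i + 1, j)}
            if j < len(b):
                out |= {(s - 1, c) for s, c in rec(i, j + 1)}
        best[key] = dict.fromkeys(out)
        return out

    states = rec(0, 0)
    top = max(s for s, _ in states)
    return top, {c for s, c in states if s == top}


def confusion_metrics(truth, pred) -> dict:
    tp = fp = fn = tn = 0
    for t, p in zip(truth, pred):
        if p == 1 and t == 1:
            tp += 1
        elif p == 1 and t == 0:
            fp += 1
        elif p == 0 and t == 1:
            fn += 1
        else:
            tn += 1
    n = tp + fp + fn + tn
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    return {
        "accuracy": (tp + tn) / n,
        "precision": prec,
        "recall": rec,
        "f1": 2 * prec * rec / (prec + rec) if prec + rec else 0.0,
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


def roc_auc_pairs(truth, score) -> float:
    """Rank statistic by exhaustive pair counting; ties count one half."""
    pos = [s for t, s in zip(truth, score) if t == 1]
    neg = [s for t, s in zip(truth, score) if t == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def cleave_regex(seq: str, pattern: str) -> list[str]:
    """Split at every site matched by the (lookahead-style) cleavage regex."""
    sites = sorted({m.end() for m in re.finditer(pattern, seq) if 0 < m.end() < len(seq)})
    frags, prev = [], 0
    for s in sites:
        frags.append(seq[prev:s])
        prev = s
    frags.append(seq[prev:])
    return frags
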