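"""Peptide records: FASTA/TSV IO, curation and redundancy clustering.

Curation mirrors the standard preparation of CPP training sets: drop
sequences with non-natural residues, enforce a length window, deduplicate
(first occurrence wins), and optionally reduce redundancy with a CD-HIT-style
greedy incremental clustering at a pairwise-identity cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Align import PairwiseAligner

from ._tables import AMINO_ACIDS

logger = logging.getLogger(__name__)

_VALID = set(AMINO_ACIDS)

CPP_LABEL = 1
NON_CPP_LABEL = 0


class FastaParseError(ValueError):
    pass


@dataclass(frozen=True)
class Peptide:
    """A validated amino-acid sequence with optional identifier and label.

    ``label`` encodes the class: 1 for cell-penetrating (CPP), 0 for
    non-penetrating, ``None`` when unknown.
    """

    id: str
    seq: str
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"peptide {self.id!r}: empty sequence")
        if not self.seq.isupper():
            object.__setattr__(self, "seq", self.seq.upper())
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"peptide {self.id!r}: label must be 0/1/None, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_natural(self) -> bool:
        return set(self.seq) <= _VALID


@dataclass
class SequenceSet:
    """An ordered collection of peptides with a provenance tag."""

    records: list[Peptide] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def sequences(self) -> list[str]:
        return [p.seq for p in self.records]

    def class_counts(self) -> dict[int | None, int]:
        counts: dict[int | None, int] = {}
        for p in self.records:
            counts[p.label] = counts.get(p.label, 0) + 1
        return counts

    def subset(self, predicate) -> "SequenceSet":
        return SequenceSet([p for p in self.records if predicate(p)], self.provenance)


@dataclass
class CurationReport:
    kept: int = 0
    removed_nonnatural: int = 0
    removed_length: int = 0
    removed_duplicate: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "kept": self.kept,
            "removed_nonnatural": self.removed_nonnatural,
            "removed_length": self.removed_length,
            "removed_duplicate": self.removed_duplicate,
        }


def read_fasta(path) -> SequenceSet:
    """Read a FASTA file into a SequenceSet (sequences uppercased).

    Raises :class:`FastaParseError` when the file contains text before the
    first ``>`` header.  An empty file yields an empty set with a warning.
    """
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(f"{path}: line {lineno}: expected a '>' header before sequence data")
            break
    records = [
        Peptide(id=rec.id, seq=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return SequenceSet(records, provenance=str(path))


def write_fasta(s: SequenceSet, path) -> None:
    with open(path, "w") as handle:
        for p in s:
            handle.write(f">{p.id}\n{p.seq}\n")


def read_table(path) -> SequenceSet:
    """Read a labeled TSV with columns (id, sequence, label)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sequence": str})
    missing = {"id", "sequence"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    labels = df["label"] if "label" in df.columns else [None] * len(df)
    records = [
        Peptide(id=str(i), seq=str(s).upper(), label=None if l is None or l != l else int(l))
        for i, s, l in zip(df["id"], df["sequence"], labels)
    ]
    return SequenceSet(records, provenance=str(path))


def write_table(s: SequenceSet, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"id": [p.id for p in s], "sequence": [p.seq for p in s], "label": [p.label for p in s]}
    ).to_csv(path, sep="\t", index=False)


def curate(s: SequenceSet, min_len: int = 5, max_len: int = 61) -> tuple[SequenceSet, CurationReport]:
    """Keep natural-residue sequences within the length window, deduplicated.

    First occurrence of each sequence wins; the report counts removals per
    reason (a sequence failing several checks is counted once, in the order
    non-natural > length > duplicate).
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    report = CurationReport()
    seen: set[str] = set()
    kept: list[Peptide] = []
    for p in s:
        if not p.is_natural:
            report.removed_nonnatural += 1
            continue
        if not (min_len <= len(p) <= max_len):
            report.removed_length += 1
            continue
        if p.seq in seen:
            report.removed_duplicate += 1
            continue
        seen.add(p.seq)
        kept.append(p)
    report.kept = len(kept)
    logger.info("curate: %s", report.as_dict())
    return SequenceSet(kept, provenance=s.provenance), report


def _aligner() -> PairwiseAligner:
    # Pinned identity scoring: match +1, mismatch 0, gap -1, global alignment.
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = -1.0
    a.extend_gap_score = -1.0
    return a


def pairwise_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    """Global-alignment identity: exact matches / length of the shorter sequence."""
    aligner = aligner or _aligner()
    aln = aligner.align(a, b)[0]
    return aln.counts().identities / min(len(a), len(b))


def greedy_identity_cluster(s: SequenceSet, identity_cutoff: float = 0.45) -> SequenceSet:
    """CD-HIT-style greedy incremental clustering; returns representatives.

    Records are scanned longest-first; each joins the first cluster whose
    representative it matches at >= ``identity_cutoff`` identity, otherwise it
    founds a new cluster.  Output preserves the input order of the chosen
    representatives.
    """
    if not (0 < identity_cutoff <= 1):
        raise ValueError(f"identity_cutoff must be in (0, 1], got {identity_cutoff}")
    aligner = _aligner()
    reps: list[Peptide] = []
    for p in sorted(s.records, key=lambda q: -len(q)):
        if not any(pairwise_identity(p.seq, rep.seq, aligner) >= identity_cutoff for rep in reps):
            reps.append(p)
    order = {id(p): i for i, p in enumerate(s.records)}
    reps.sort(key=lambda p: order[id(p)])
    logger.info("greedy_identity_cluster: %d -> %d at cutoff %.2f", len(s), len(reps), identity_cutoff)
    return SequenceSet(reps, provenance=s.provenance)


def relabel(s: SequenceSet, label: int) -> SequenceSet:
    return SequenceSet([replace(p, label=label) for p in s], provenance=s.provenance)
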