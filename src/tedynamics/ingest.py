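"""Turn alignments into validated count structures.

The counting rules here decide every downstream number, so they are applied
explicitly and logged:

* only alignments strictly longer than 30 bp count (genomic reads);
* identity ("homology") filters of 0.80 for the TE and knob sets and 0.90
  for the gene set, applied whenever identity is available on the record;
* database priority is a total order KnobC > UTE > FGS -- a read matching
  the knob set is a knob hit regardless of its TE matches, and a read
  matching both TE and gene sets counts as a TE;
* within the TE set a read contributes at most one hit: several best-score
  positions inside one exemplar collapse to a single hit, while a best
  score tied across two or more distinct exemplars discards the read;
* siRNA reads are kept only with zero mismatches, and a read with k target
  exemplars contributes 1/k to each (fractional counting).

Classification of a read never depends on the order of its alignment
records.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .core import (
    ExemplarDB,
    LibraryCounts,
    SiRNALibrary,
    ValidationError,
)

TARGET_SETS = ("UTE", "FGS", "KnobC")
#: minimum identity per reference set, applied when identity is recorded
IDENTITY_THRESHOLDS = {"UTE": 0.80, "KnobC": 0.80, "FGS": 0.90}
MIN_ALIGNMENT_LENGTH_BP = 30  # strict: alignments must be > 30 bp


@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment of one read against one reference set."""

    read_id: str
    target_set: str  # UTE | FGS | KnobC
    target_id: str
    alignment_length: int  # bp on the read
    score: float = 0.0
    identity: float | None = None  # fraction; None when the aligner gave none
    mismatches: int = 0
    mate_index: int | None = None  # 1/2 for paired data

    def __post_init__(self) -> None:
        if self.target_set not in TARGET_SETS:
            raise ValidationError(
                f"read {self.read_id!r}: unknown target_set {self.target_set!r}"
            )
        if self.alignment_length < 0:
            raise ValidationError(
                f"read {self.read_id!r}: negative alignment length"
            )
        if self.identity is not None and not (0.0 <= self.identity <= 1.0):
            raise ValidationError(
                f"read {self.read_id!r}: identity must lie in [0, 1]"
            )


@dataclass
class CountingStats:
    """Per-filter bookkeeping for one counting pass."""

    n_reads: int = 0
    dropped_short: int = 0  # all alignments <= 30 bp
    dropped_identity: int = 0  # all alignments failed identity
    discarded_ties: int = 0  # best score tied across distinct exemplars
    unassigned: int = 0  # no passing alignment at all

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def _passing(alignments: Iterable[AlignmentRecord], stats: CountingStats | None):
    """Apply the length and identity filters, with bookkeeping."""
    records = list(alignments)
    long_enough = [a for a in records if a.alignment_length > MIN_ALIGNMENT_LENGTH_BP]
    if stats is not None and records and not long_enough:
        stats.dropped_short += 1
    passing = [
        a
        for a in long_enough
        if a.identity is None or a.identity >= IDENTITY_THRESHOLDS[a.target_set]
    ]
    if stats is not None and long_enough and not passing:
        stats.dropped_identity += 1
    return passing


def classify_read(
    alignments: Iterable[AlignmentRecord],
    db: ExemplarDB,
    stats: CountingStats | None = None,
) -> tuple[str, str | None]:
    """Assign one read under the priority and tie rules.

    Returns ``(target_set, target_id)`` where target_set is one of
    ``KnobC``, ``UTE``, ``FGS`` or ``unassigned`` (tie discards and
    filtered-out reads are unassigned; ties additionally increment the tie
    counter).  target_id is the exemplar for UTE hits, else None.
    """
    passing = _passing(alignments, stats)
    for a in passing:
        if a.target_set == "UTE" and a.target_id not in db:
            raise ValidationError(
                f"read {a.read_id!r} references unknown exemplar {a.target_id!r}"
            )
    by_set: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for a in passing:
        by_set[a.target_set].append(a)
    if by_set.get("KnobC"):
        return "KnobC", None
    ute = by_set.get("UTE")
    if ute:
        best = max(a.score for a in ute)
        best_targets = sorted({a.target_id for a in ute if a.score == best})
        if len(best_targets) >= 2:
            if stats is not None:
                stats.discarded_ties += 1
            return "unassigned", None
        return "UTE", best_targets[0]
    if by_set.get("FGS"):
        return "FGS", None
    if stats is not None:
        stats.unassigned += 1
    return "unassigned", None


def count_genomic_hits(
    alignments: Iterable[AlignmentRecord],
    db: ExemplarDB,
    accession_id: str = "library",
    mean_read_length: float = 100.0,
) -> tuple[LibraryCounts, CountingStats]:
    """Count genomic hits per exemplar from a stream of alignment records.

    Records are grouped by read id; each read contributes at most one hit,
    placed by :func:`classify_read`.
    """
    by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for a in alignments:
        by_read[a.read_id].append(a)
    stats = CountingStats(n_reads=len(by_read))
    hits: dict[str, float] = {e: 0.0 for e in db.ids}
    fgs = knob = 0.0
    for read_id in by_read:
        target_set, target_id = classify_read(by_read[read_id], db, stats)
        if target_set == "UTE":
            hits[target_id] += 1.0
        elif target_set == "FGS":
            fgs += 1.0
        elif target_set == "KnobC":
            knob += 1.0
    counts = LibraryCounts(
        accession_id=accession_id,
        hits=hits,
        fgs_hits=fgs,
        knob_hits=knob,
        mean_read_length=mean_read_length,
        n_reads_total=float(len(by_read)),
    )
    return counts, stats


def count_sirna_hits(
    alignments: Iterable[AlignmentRecord],
    db: ExemplarDB,
    size_class: int,
    accession_id: str = "library",
) -> SiRNALibrary:
    """Count siRNA hits with fractional multi-target allocation.

    Only zero-mismatch alignments are retained.  A read matching k distinct
    exemplars adds 1/k to each, so the library total equals the number of
    retained reads.  A read with no retained target contributes nothing.
    """
    if size_class not in (22, 24):
        raise ValidationError(f"size_class must be 22 or 24, got {size_class}")
    targets_by_read: dict[str, set[str]] = defaultdict(set)
    for a in alignments:
        if a.mismatches != 0:
            continue
        if a.target_id not in db:
            raise ValidationError(
                f"read {a.read_id!r} references unknown exemplar {a.target_id!r}"
            )
        targets_by_read[a.read_id].add(a.target_id)
    counts: dict[str, float] = {e: 0.0 for e in db.ids}
    for read_id, targets in targets_by_read.items():
        if not targets:
            continue
        share = 1.0 / len(targets)
        for t in targets:
            counts[t] += share
    return SiRNALibrary(accession_id=accession_id, size_class=size_class, counts=counts)


# -- paired-read genomic context -------------------------------------------


@dataclass
class PairedContext:
    """Per-exemplar genomic context from read pairs.

    For pairs with exactly one mate in an exemplar, the other mate's
    destination (another TE exemplar, the gene set, the knob set, or
    nowhere) is tallied; the four fractions sum to 1 whenever the
    denominator is positive.  Pairs with both mates in the same exemplar
    are excluded entirely (the measure is cross-feature context).
    """

    table: pd.DataFrame  # index exemplar_id; fraction_* columns + denominator

    def fractions(self, exemplar_id: str) -> pd.Series:
        return self.table.loc[exemplar_id]


_CONTEXT_COLS = ["fraction_te_other", "fraction_fgs", "fraction_knob", "fraction_unassigned"]


def paired_context(
    pair_assignments: Iterable[tuple[tuple[str, str | None], tuple[str, str | None]]],
    db: ExemplarDB,
) -> PairedContext:
    """Tally mate destinations for pairs anchored in each exemplar.

    Each element is ``((set1, id1), (set2, id2))`` as produced by
    :func:`classify_read` for the two mates.  Exemplars with no anchored
    pairs get missing (NaN) fractions, not zeros.
    """
    tallies = {e: defaultdict(float) for e in db.ids}
    for (set1, id1), (set2, id2) in pair_assignments:
        if set1 == "UTE" and set2 == "UTE" and id1 == id2:
            continue  # same-exemplar pair: excluded from numerator and denominator
        for anchor_id, other_set in (
            (id1 if set1 == "UTE" else None, (set2, id2)),
            (id2 if set2 == "UTE" else None, (set1, id1)),
        ):
            if anchor_id is None:
                continue
            oset, _ = other_set
            if oset == "UTE":
                key = "fraction_te_other"
            elif oset == "FGS":
                key = "fraction_fgs"
            elif oset == "KnobC":
                key = "fraction_knob"
            else:
                key = "fraction_unassigned"
            tallies[anchor_id][key] += 1.0
            tallies[anchor_id]["denominator"] += 1.0
    rows = {}
    for e in db.ids:
        denom = tallies[e].get("denominator", 0.0)
        if denom > 0:
            rows[e] = {c: tallies[e].get(c, 0.0) / denom for c in _CONTEXT_COLS}
        else:
            rows[e] = {c: float("nan") for c in _CONTEXT_COLS}
        rows[e]["denominator"] = denom
    table = pd.DataFrame.from_dict(rows, orient="index").reindex(db.ids)
    return PairedContext(table=table)


# -- SAM ingestion ----------------------------------------------------------


def read_sam_alignments(path, target_set: str) -> list[AlignmentRecord]:
    """Read alignment records from a SAM file mapped against one reference set.

    Libraries are mapped per database, so the reference set is stated by the
    caller.  Alignment length is taken from the CIGAR (aligned query bases),
    identity as (aligned - NM)/aligned when the NM tag is present, and the
    score from the AS tag (0 when absent); secondary records are kept so
    equal-score ties across exemplars can be detected downstream.
    """
    import pysam

    if target_set not in TARGET_SETS:
        raise ValidationError(f"unknown target_set {target_set!r}")
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            aligned = aln.query_alignment_length or 0
            nm = aln.get_tag("NM") if aln.has_tag("NM") else None
            identity = None
            if nm is not None and aligned > 0:
                identity = max(0.0, (aligned - nm) / aligned)
            score = float(aln.get_tag("AS")) if aln.has_tag("AS") else 0.0
            mate = None
            if aln.is_paired:
                mate = 1 if aln.is_read1 else 2
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    target_set=target_set,
                    target_id=aln.reference_name,
                    alignment_length=aligned,
                    score=score,
                    identity=identity,
                    mismatches=int(nm) if nm is not None else 0,
                    mate_index=mate,
                )
            )
    return records
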