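"""Core domain containers and their on-disk representations.

The analysis counts short reads against *exemplar* sequences, each standing
for one transposable-element (TE) subfamily.  Everything downstream --
abundance estimation, group classification, the chi-square tests and the
fold-change summaries -- consumes the three containers defined here:

* :class:`ExemplarDB` -- the exemplar reference set, one record per TE
  subfamily with its class (DNA or RNA), family code and length;
* :class:`LibraryCounts` -- per-accession genomic hit counts against the TE
  exemplar set plus the gene-set (FGS) and knob/centromere (KnobC) totals
  that serve as coverage proxies;
* :class:`SiRNALibrary` -- per-accession, per-size-class (22 / 24 nt)
  small-RNA hit counts, fractional because multi-target reads are split.

Exemplar databases travel as FASTA with ``id|class|family`` description
lines; count tables travel as TSV with a ``#key=value`` header block so a
round trip is lossless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CLASSES = ("DNA", "RNA")
SIZE_CLASSES = (22, 24)


class ValidationError(ValueError):
    """An input record or table violates a container invariant."""


class DegenerateInputError(ValueError):
    """An input is structurally valid but carries no usable signal."""


@dataclass(frozen=True)
class ExemplarRecord:
    """One TE subfamily exemplar."""

    exemplar_id: str
    te_class: str  # "DNA" or "RNA"
    family_code: str  # e.g. RLC, RLG, RLX, RIL, RST, or a DNA superfamily code
    length: int  # bp

    def __post_init__(self) -> None:
        if self.te_class not in VALID_CLASSES:
            raise ValidationError(
                f"exemplar {self.exemplar_id!r}: te_class must be one of "
                f"{VALID_CLASSES}, got {self.te_class!r}"
            )
        if self.length < 1:
            raise ValidationError(
                f"exemplar {self.exemplar_id!r}: length must be >= 1 bp, "
                f"got {self.length}"
            )

    @property
    def length_kb(self) -> float:
        return self.length / 1000.0


class ExemplarDB:
    """An ordered collection of unique :class:`ExemplarRecord`."""

    def __init__(self, records: Iterable[ExemplarRecord]):
        self._records: dict[str, ExemplarRecord] = {}
        for rec in records:
            if rec.exemplar_id in self._records:
                raise ValidationError(f"duplicate exemplar id {rec.exemplar_id!r}")
            self._records[rec.exemplar_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ExemplarRecord]:
        return iter(self._records.values())

    def __contains__(self, exemplar_id: str) -> bool:
        return exemplar_id in self._records

    def __getitem__(self, exemplar_id: str) -> ExemplarRecord:
        return self._records[exemplar_id]

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def lengths_kb(self) -> pd.Series:
        """Exemplar lengths in kb, indexed by exemplar id."""
        return pd.Series(
            {r.exemplar_id: r.length_kb for r in self}, name="length_kb", dtype=float
        )

    def classes(self) -> pd.Series:
        return pd.Series(
            {r.exemplar_id: r.te_class for r in self}, name="te_class", dtype=object
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exemplar_id": [r.exemplar_id for r in self],
                "te_class": [r.te_class for r in self],
                "family_code": [r.family_code for r in self],
                "length": [r.length for r in self],
            }
        ).set_index("exemplar_id")

    # -- FASTA round trip ---------------------------------------------------

    def to_fasta(self, path, sequences: Mapping[str, str] | None = None) -> None:
        """Write the database as FASTA, encoding metadata in the header.

        Headers take the form ``>id|class|family``.  When *sequences* is not
        given, a placeholder homopolymer of the recorded length is emitted so
        the record length stays authoritative.
        """
        records = []
        for rec in self:
            seq = (
                sequences[rec.exemplar_id]
                if sequences is not None
                else "N" * rec.length
            )
            if len(seq) != rec.length:
                raise ValidationError(
                    f"sequence for {rec.exemplar_id!r} has length {len(seq)}, "
                    f"record says {rec.length}"
                )
            name = f"{rec.exemplar_id}|{rec.te_class}|{rec.family_code}"
            records.append(SeqRecord(Seq(seq), id=name, description=""))
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path) -> "ExemplarDB":
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.id.split("|")
            if len(parts) != 3:
                raise ValidationError(
                    f"FASTA header {rec.id!r} is not of the form id|class|family"
                )
            exemplar_id, te_class, family = parts
            records.append(
                ExemplarRecord(exemplar_id, te_class, family, len(rec.seq))
            )
        return cls(records)


def _validate_counts(counts: Mapping[str, float], kind: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for exemplar_id, value in counts.items():
        if value < 0:
            raise ValidationError(
                f"{kind} count for {exemplar_id!r} is negative ({value})"
            )
        out[str(exemplar_id)] = float(value)
    return out


@dataclass
class LibraryCounts:
    """Genomic hit counts for one accession.

    ``hits`` maps exemplar id to the number of reads accepted to that
    exemplar (N_i); ``fgs_hits`` and ``knob_hits`` are the totals accepted to
    the gene set and the knob/centromere set, used downstream as library
    coverage proxies.  The UTE total R is always ``sum(hits.values())``.
    """

    accession_id: str
    hits: dict[str, float]
    fgs_hits: float = 0.0
    knob_hits: float = 0.0
    mean_read_length: float = 100.0
    n_reads_total: float = 0.0

    def __post_init__(self) -> None:
        self.hits = _validate_counts(self.hits, "genomic")
        for name in ("fgs_hits", "knob_hits", "mean_read_length", "n_reads_total"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def total_ute_hits(self) -> float:
        """R: the total number of reads mapped against the exemplar set."""
        return float(sum(self.hits.values()))

    def hit_series(self, db: "ExemplarDB | None" = None) -> pd.Series:
        """Per-exemplar hits as a Series; zero-filled over *db* if given."""
        s = pd.Series(self.hits, dtype=float, name="hits")
        if db is not None:
            s = s.reindex(db.ids, fill_value=0.0)
        return s


@dataclass
class SiRNALibrary:
    """Small-RNA hit counts of one size class (22 or 24 nt) for one accession.

    Counts are fractional: a read matching k exemplars contributes 1/k to
    each, so the counts still sum to the number of retained reads.
    """

    accession_id: str
    size_class: int
    counts: dict[str, float]

    _uq_cache: float | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.size_class not in SIZE_CLASSES:
            raise ValidationError(
                f"size_class must be one of {SIZE_CLASSES}, got {self.size_class}"
            )
        self.counts = _validate_counts(self.counts, "siRNA")

    @property
    def total_sirna_hits(self) -> float:
        return float(sum(self.counts.values()))

    def count_series(self, db: "ExemplarDB | None" = None) -> pd.Series:
        s = pd.Series(self.counts, dtype=float, name="sirna_hits")
        if db is not None:
            s = s.reindex(db.ids, fill_value=0.0)
        return s

    @property
    def upper_quartile(self) -> float:
        """Nearest-rank 75th percentile of the nonzero per-exemplar counts."""
        if self._uq_cache is None:
            nonzero = sorted(v for v in self.counts.values() if v > 0)
            if not nonzero:
                raise DegenerateInputError(
                    f"siRNA library {self.accession_id!r}/{self.size_class} nt "
                    "has no nonzero counts; upper quartile undefined"
                )
            rank = math.ceil(0.75 * len(nonzero))
            self._uq_cache = float(nonzero[rank - 1])
        return self._uq_cache


@dataclass
class AnalysisConfig:
    """Thresholds shared across the analysis stages.

    low_copy_threshold
        RPKM below which an exemplar is treated as having fewer than ~2
        genomic copies and excluded from classification (default 1.2,
        boundary value retained).
    fdr_q
        Benjamini-Hochberg q-value cutoff for the per-exemplar tests.
    alpha_group
        Significance level for the Kruskal-Wallis group comparisons and
        their pairwise letters.
    pseudocount
        Count-scale offset used when forming the 24:22 nt siRNA ratio so
        zero counts stay finite.
    """

    low_copy_threshold: float = 1.2
    fdr_q: float = 0.001
    alpha_group: float = 0.05
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.low_copy_threshold <= 0:
            raise ValidationError("low_copy_threshold must be positive")
        if not 0 < self.fdr_q < 1:
            raise ValidationError("fdr_q must lie in (0, 1)")
        if not 0 < self.alpha_group < 1:
            raise ValidationError("alpha_group must lie in (0, 1)")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be non-negative")


# -- TSV round trip ---------------------------------------------------------

_COUNT_COLUMNS = ("exemplar_id", "hits")


def write_counts_table(obj: LibraryCounts | SiRNALibrary, path) -> None:
    """Write a count container as TSV with a ``#key=value`` header block.

    Fractional counts are preserved to at least 9 decimal places.
    """
    lines = []
    if isinstance(obj, LibraryCounts):
        lines += [
            "#type=genomic",
            f"#accession={obj.accession_id}",
            f"#fgs_hits={obj.fgs_hits!r}",
            f"#knob_hits={obj.knob_hits!r}",
            f"#mean_read_length={obj.mean_read_length!r}",
            f"#n_reads_total={obj.n_reads_total!r}",
        ]
        counts = obj.hits
    elif isinstance(obj, SiRNALibrary):
        lines += [
            "#type=sirna",
            f"#accession={obj.accession_id}",
            f"#size_class={obj.size_class}",
        ]
        counts = obj.counts
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot serialise {type(obj).__name__}")
    lines.append("\t".join(_COUNT_COLUMNS))
    for exemplar_id, value in counts.items():
        lines.append(f"{exemplar_id}\t{value!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_counts_table(path) -> LibraryCounts | SiRNALibrary:
    """Read a table written by :func:`write_counts_table`."""
    meta: dict[str, str] = {}
    rows: list[tuple[str, float]] = []
    header_seen = False
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key] = value
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(fields) != _COUNT_COLUMNS:
                    raise ValidationError(
                        f"{path}: expected columns {_COUNT_COLUMNS}, got {fields}"
                    )
                header_seen = True
                continue
            if len(fields) != 2:
                raise ValidationError(f"{path}: malformed row {line!r}")
            value = float(fields[1])
            if value < 0:
                raise ValidationError(
                    f"{path}: negative count for exemplar {fields[0]!r}"
                )
            rows.append((fields[0], value))
    if not header_seen:
        raise ValidationError(f"{path}: missing column header line")
    seen: set[str] = set()
    for exemplar_id, _ in rows:
        if exemplar_id in seen:
            raise ValidationError(f"{path}: duplicate exemplar row {exemplar_id!r}")
        seen.add(exemplar_id)
    counts = dict(rows)
    kind = meta.get("type")
    if kind == "genomic":
        return LibraryCounts(
            accession_id=meta["accession"],
            hits=counts,
            fgs_hits=float(meta["fgs_hits"]),
            knob_hits=float(meta["knob_hits"]),
            mean_read_length=float(meta["mean_read_length"]),
            n_reads_total=float(meta["n_reads_total"]),
        )
    if kind == "sirna":
        return SiRNALibrary(
            accession_id=meta["accession"],
            size_class=int(meta["size_class"]),
            counts=counts,
        )
    raise ValidationError(f"{path}: unknown or missing #type header ({kind!r})")
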