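"""Seeded synthetic data with the count structure the analysis assumes.

The generator emulates the study design the package analyses: a maize-like
exemplar database whose DNA (class II) subfamilies have log-normal copy
numbers and whose RNA (class I) subfamilies split into a low-copy mode (R1)
and a high-copy mode (R2); genomic libraries allocated multinomially among a
gene compartment (FGS), a knob/centromere compartment (KnobC) and the
exemplars in proportion to copy number x length; siRNA libraries allocated
in proportion to copy number x per-group targeting rate, so that the
copy-number / siRNA proportionality null holds exactly in expectation unless
a per-exemplar deviation factor is set; and per-exemplar expression
log2 fold changes with group-specific means (the mop1 wild-type/mutant
contrast).

Reads are sampled multinomially, never Poisson, so per-library totals are
exact and conservation invariants hold to the count.  Every draw uses an RNG
stream derived from the master seed and a stable text label, so re-running
one component in isolation reproduces its output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import DegenerateInputError, ExemplarDB, ExemplarRecord, LibraryCounts, SiRNALibrary

GROUPS = ("D", "R1", "R2")

_DNA_FAMILIES = ("DTA", "DTC", "DTH", "DTM", "DTT")
_RNA_FAMILIES = ("RLC", "RLG", "RLX", "RIL", "RST")
# Relative family composition of the low- and high-copy retroelement groups
# (Copia, Gypsy, unknown-LTR, LINE L1, SINE), loosely following the maize
# exemplar set.
_R1_FAMILY_WEIGHTS = (95, 128, 110, 30, 2)
_R2_FAMILY_WEIGHTS = (52, 112, 28, 1, 5)


class ParameterError(ValueError):
    """A simulation parameter is out of range; the message names the field."""


def _per_group(value, name: str) -> dict[str, object]:
    """Broadcast a scalar/tuple to all groups, or validate a per-group dict."""
    if isinstance(value, Mapping):
        missing = [g for g in GROUPS if g not in value]
        if missing:
            raise ParameterError(f"{name}: missing entries for groups {missing}")
        return {g: value[g] for g in GROUPS}
    return {g: value for g in GROUPS}


def _per_accession(value, accessions, name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = [a for a in accessions if a not in value]
        if missing:
            raise ParameterError(f"{name}: missing entries for accessions {missing}")
        return {a: float(value[a]) for a in accessions}
    return {a: float(value) for a in accessions}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults reproduce the study conditions the analysis was designed for:
    841 DNA / 365 low-copy RNA / 198 high-copy RNA exemplars, gene and knob
    read fractions matching the three maize accessions, 100 bp reads, and
    mop1 expression effects of +1.2-fold (D), -1.6-fold (R1) and 1.03-fold
    (R2) stated as linear folds and converted to log2 internally.
    """

    seed: int = 0
    n_dna: int = 841
    n_r1: int = 365
    n_r2: int = 198
    #: per-group (mean, sd) of log exemplar length in bp
    length_params: dict = dc_field(
        default_factory=lambda: {
            "D": (np.log(3000.0), 0.5),
            "R1": (np.log(6000.0), 0.5),
            "R2": (np.log(9000.0), 0.5),
        }
    )
    #: per-group (mean, sd) of log true copy number
    copy_params: dict = dc_field(
        default_factory=lambda: {
            "D": (np.log(20.0), 1.0),
            "R1": (np.log(5.0), 0.8),
            "R2": (np.log(200.0), 0.8),
        }
    )
    accessions: tuple = ("B73", "PT", "OAXA")
    #: probability a genomic read falls in the gene compartment
    fgs_fraction: object = dc_field(
        default_factory=lambda: {"B73": 0.150, "PT": 0.170, "OAXA": 0.168}
    )
    #: probability a genomic read falls in the knob/centromere compartment
    knob_fraction: object = dc_field(
        default_factory=lambda: {"B73": 0.0612, "PT": 0.0126, "OAXA": 0.1114}
    )
    #: per-accession, per-group multiplier on true copy number (1 = shared truth)
    copy_factors: dict = dc_field(default_factory=dict)
    library_size: int = 1_000_000
    read_length: int = 100
    #: per-group expected siRNA hits per copy per size class (relative rates)
    sirna_rate_per_copy: dict = dc_field(
        default_factory=lambda: {"D": 1.0, "R1": 1.5, "R2": 0.25}
    )
    sirna_library_size: dict = dc_field(
        default_factory=lambda: {22: 1_000_000, 24: 1_000_000}
    )
    #: per-exemplar multiplicative deviation from copy-siRNA proportionality
    prop_deviation: dict = dc_field(default_factory=dict)
    #: optional Dirichlet-multinomial overdispersion for siRNA counts; None
    #: gives plain multinomial sampling
    sirna_overdispersion: float | None = None
    #: per-group (linear fold, sd in log2 units) of the mop1 expression shift;
    #: negative folds denote decreases (-1.6 => log2(1/1.6))
    fc_mop_params: dict = dc_field(
        default_factory=lambda: {"D": (1.2, 1.0), "R1": (-1.6, 1.0), "R2": (1.03, 1.0)}
    )

    def __post_init__(self) -> None:
        for name in ("n_dna", "n_r1", "n_r2", "library_size", "read_length"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name}: must be non-negative")
        self.length_params = _per_group(self.length_params, "length_params")
        self.copy_params = _per_group(self.copy_params, "copy_params")
        self.sirna_rate_per_copy = {
            g: float(v)
            for g, v in _per_group(self.sirna_rate_per_copy, "sirna_rate_per_copy").items()
        }
        self.fc_mop_params = _per_group(self.fc_mop_params, "fc_mop_params")
        self.fgs_fraction = _per_accession(self.fgs_fraction, self.accessions, "fgs_fraction")
        self.knob_fraction = _per_accession(self.knob_fraction, self.accessions, "knob_fraction")
        for acc in self.accessions:
            f, k = self.fgs_fraction[acc], self.knob_fraction[acc]
            if not (0.0 <= f <= 1.0):
                raise ParameterError(f"fgs_fraction[{acc}]: must lie in [0, 1]")
            if not (0.0 <= k <= 1.0):
                raise ParameterError(f"knob_fraction[{acc}]: must lie in [0, 1]")
            if f + k >= 1.0:
                raise ParameterError(
                    f"fgs_fraction+knob_fraction for {acc} must be < 1, got {f + k}"
                )
        for g, rate in self.sirna_rate_per_copy.items():
            if rate < 0:
                raise ParameterError(f"sirna_rate_per_copy[{g}]: must be non-negative")
        for sc, size in self.sirna_library_size.items():
            if sc not in (22, 24):
                raise ParameterError(f"sirna_library_size: unknown size class {sc}")
            if size < 0:
                raise ParameterError(f"sirna_library_size[{sc}]: must be non-negative")
        if self.sirna_overdispersion is not None and self.sirna_overdispersion <= 0:
            raise ParameterError("sirna_overdispersion: must be positive or None")

    def copy_factor(self, accession_id: str, group: str) -> float:
        per_acc = self.copy_factors.get(accession_id, {})
        if isinstance(per_acc, Mapping):
            return float(per_acc.get(group, 1.0))
        return float(per_acc)


@dataclass
class SyntheticTruth:
    """Ground truth of one generated study, for recovery tests."""

    #: per-exemplar true group label
    groups: pd.Series
    #: exemplar x accession true copy numbers
    copy_numbers: pd.DataFrame
    #: per-exemplar multiplicative deviation from copy-siRNA proportionality
    prop_factors: pd.Series

    def copies(self, accession_id: str) -> pd.Series:
        return self.copy_numbers[accession_id]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"true_group": self.groups, "prop_factor": self.prop_factors})
        for acc in self.copy_numbers.columns:
            out[f"copies_{acc}"] = self.copy_numbers[acc]
        return out

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="exemplar_id")


def _rng(seed: int, *labels: str) -> np.random.Generator:
    """One RNG stream per (seed, label...) pair, stable across runs."""
    keys = [zlib.crc32(lab.encode()) for lab in labels]
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *keys])


def generate_exemplar_db(config: SimulationConfig) -> tuple[ExemplarDB, SyntheticTruth]:
    """Draw the exemplar database and its ground truth.

    Returns the database (DNA-class records for group D, RNA-class for
    R1/R2, lengths log-normal per group) together with the
    :class:`SyntheticTruth` needed by the recovery tests.
    """
    rng = _rng(config.seed, "exemplar_db")
    records: list[ExemplarRecord] = []
    groups: dict[str, str] = {}
    copy_cols: dict[str, dict[str, float]] = {a: {} for a in config.accessions}
    prop: dict[str, float] = {}

    plan = (
        ("D", config.n_dna, "DNA", _DNA_FAMILIES, None),
        ("R1", config.n_r1, "RNA", _RNA_FAMILIES, _R1_FAMILY_WEIGHTS),
        ("R2", config.n_r2, "RNA", _RNA_FAMILIES, _R2_FAMILY_WEIGHTS),
    )
    for group, n, te_class, families, weights in plan:
        if n == 0:
            continue
        mu_l, sd_l = config.length_params[group]
        mu_c, sd_c = config.copy_params[group]
        lengths = np.maximum(rng.lognormal(mu_l, sd_l, size=n), 100.0).round().astype(int)
        copies = rng.lognormal(mu_c, sd_c, size=n)
        p = None
        if weights is not None:
            p = np.asarray(weights, dtype=float)
            p = p / p.sum()
        fams = rng.choice(families, size=n, p=p)
        for i in range(n):
            exemplar_id = f"{group}_{i:04d}"
            records.append(ExemplarRecord(exemplar_id, te_class, str(fams[i]), int(lengths[i])))
            groups[exemplar_id] = group
            prop[exemplar_id] = float(config.prop_deviation.get(exemplar_id, 1.0))
            for acc in config.accessions:
                copy_cols[acc][exemplar_id] = float(copies[i]) * config.copy_factor(acc, group)

    db = ExemplarDB(records)
    order = db.ids
    truth = SyntheticTruth(
        groups=pd.Series(groups, dtype=object).reindex(order),
        copy_numbers=pd.DataFrame(copy_cols).reindex(order),
        prop_factors=pd.Series(prop, dtype=float).reindex(order),
    )
    return db, truth


def simulate_genomic_hits(
    db: ExemplarDB,
    truth: SyntheticTruth,
    config: SimulationConfig,
    accession_id: str,
) -> LibraryCounts:
    """Allocate one genomic library multinomially.

    A read falls in the FGS / KnobC compartments with the accession's
    configured probabilities, otherwise among exemplars with probability
    proportional to true copy number x exemplar length.  The three totals
    sum exactly to ``library_size``.
    """
    if accession_id not in config.accessions:
        raise ParameterError(f"accession_id: unknown accession {accession_id!r}")
    rng = _rng(config.seed, "genomic", accession_id)
    ids = db.ids
    lengths = np.array([db[e].length for e in ids], dtype=float)
    copies = truth.copies(accession_id).reindex(ids).to_numpy()
    weights = copies * lengths
    f = config.fgs_fraction[accession_id]
    k = config.knob_fraction[accession_id]
    total_weight = weights.sum()
    if total_weight <= 0 and (1.0 - f - k) > 0:
        raise DegenerateInputError(
            "zero total exemplar weight: no reads can be allocated to the TE set"
        )
    p = np.concatenate(([f, k], (1.0 - f - k) * weights / total_weight))
    draws = rng.multinomial(config.library_size, p)
    hits = {e: float(c) for e, c in zip(ids, draws[2:])}
    return LibraryCounts(
        accession_id=accession_id,
        hits=hits,
        fgs_hits=float(draws[0]),
        knob_hits=float(draws[1]),
        mean_read_length=float(config.read_length),
        n_reads_total=float(config.library_size),
    )


def implied_fgs_length_bp(
    db: ExemplarDB, truth: SyntheticTruth, config: SimulationConfig, accession_id: str
) -> float:
    """Gene-set length consistent with the simulated read allocation.

    In the implied genome, compartments receive reads in proportion to their
    base-pair content, so a gene compartment drawing fraction f of the reads
    while the exemplars (total W = sum c_i L_i bp) draw 1-f-k has length
    f W / (1-f-k).  Passing this to the copy-number estimator makes the
    estimator's gene-set depth proxy exact in expectation.
    """
    f = config.fgs_fraction[accession_id]
    k = config.knob_fraction[accession_id]
    copies = truth.copies(accession_id)
    w = float(sum(copies[e] * db[e].length for e in db.ids))
    if 1.0 - f - k <= 0:
        raise ParameterError("fgs_fraction+knob_fraction must be < 1")
    return f * w / (1.0 - f - k)


def simulate_sirna_hits(
    db: ExemplarDB,
    truth: SyntheticTruth,
    config: SimulationConfig,
    accession_id: str,
    size_class: int,
) -> SiRNALibrary:
    """Allocate one siRNA library multinomially over exemplars.

    Expected counts are proportional to true copy number x the group's
    per-copy targeting rate x the exemplar's proportionality-deviation
    factor; with all deviation factors at 1 the copy-siRNA proportionality
    null holds exactly in expectation.
    """
    if size_class not in (22, 24):
        raise ParameterError(f"size_class: must be 22 or 24, got {size_class}")
    if accession_id not in config.accessions:
        raise ParameterError(f"accession_id: unknown accession {accession_id!r}")
    rng = _rng(config.seed, "sirna", accession_id, str(size_class))
    ids = db.ids
    copies = truth.copies(accession_id).reindex(ids).to_numpy()
    rates = np.array([config.sirna_rate_per_copy[truth.groups[e]] for e in ids])
    devs = truth.prop_factors.reindex(ids).to_numpy()
    weights = copies * rates * devs
    total = config.sirna_library_size[size_class]
    if weights.sum() <= 0:
        if total > 0:
            raise DegenerateInputError("zero total siRNA weight with a nonzero library size")
        counts = np.zeros(len(ids))
    else:
        p = weights / weights.sum()
        if config.sirna_overdispersion is not None:
            conc = p / config.sirna_overdispersion
            p = rng.dirichlet(np.maximum(conc, 1e-12))
        counts = rng.multinomial(total, p)
    return SiRNALibrary(
        accession_id=accession_id,
        size_class=size_class,
        counts={e: float(c) for e, c in zip(ids, counts)},
    )


def simulate_expression_fc(
    db: ExemplarDB, truth: SyntheticTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Draw per-exemplar expression log2 fold changes from group normals.

    Group means come from ``fc_mop_params`` linear folds: a fold f > 0 maps
    to log2(f), a fold f < 0 (a decrease) to log2(1/|f|).
    """
    rng = _rng(config.seed, "expression_fc")
    ids = db.ids
    values = np.empty(len(ids))
    for i, exemplar_id in enumerate(ids):
        fold, sd = config.fc_mop_params[truth.groups[exemplar_id]]
        mean = fold_to_log2(fold)
        values[i] = rng.normal(mean, sd) if sd > 0 else mean
    return pd.DataFrame({"exemplar_id": ids, "log2_fc": values}).set_index("exemplar_id")


def fold_to_log2(fold: float) -> float:
    """Convert a signed linear fold factor to log2 units.

    +1.2 (a 1.2-fold increase) gives log2(1.2); -1.6 (a 1.6-fold decrease)
    gives log2(1/1.6).  Zero is invalid.
    """
    if fold == 0:
        raise ParameterError("fc_mop_params: linear fold factor must be nonzero")
    return float(np.log2(fold) if fold > 0 else -np.log2(-fold))
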