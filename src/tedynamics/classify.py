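"""Classify exemplars into the D / R1 / R2 abundance groups.

DNA-class exemplars passing the low-copy RPKM filter form group D.  RNA
exemplars are bimodal in log abundance: a low-copy mode (R1) and a
high-copy mode (R2).  The split is found by fitting a two-component
Gaussian mixture to log RPKM by EM with fully deterministic initialization
(component means at the 25th/75th percentiles, equal weights, pooled
variance), and taking the threshold where the two posterior probabilities
are equal between the component means.  Exemplars failing the RPKM filter
are labelled LOW and excluded from classification.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import AnalysisConfig, DegenerateInputError, ExemplarDB, ValidationError

GROUP_LABELS = ("D", "R1", "R2", "LOW")

_EM_TOL = 1e-8
_EM_MAX_ITER = 500
_VARIANCE_FLOOR = 1e-6


@dataclass(frozen=True)
class LogNormalFit:
    """Maximum-likelihood log-normal fit with a KS distance to the EDF."""

    mu: float  # mean of log values
    sigma: float  # sd of log values (MLE, ddof=0)
    ks_distance: float
    n: int


def fit_lognormal_edf(values) -> LogNormalFit:
    """Fit a log-normal by maximum likelihood and report the KS distance.

    The MLE of a log-normal is the sample mean/sd of the log values.  The
    KS distance against the empirical distribution is reported for
    goodness-of-fit inspection, not thresholded.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 10:
        raise DegenerateInputError(f"need >= 10 values to fit, got {len(v)}")
    if np.any(v <= 0):
        raise ValidationError("log-normal fit requires strictly positive values")
    x = np.log(v)
    mu = float(x.mean())
    sigma = float(x.std(ddof=0))
    if sigma < 1e-12 * max(1.0, abs(mu)):
        sigma = 0.0  # numerically constant input
    if sigma > 0:
        ks = float(sps.kstest(v, sps.lognorm(s=sigma, scale=np.exp(mu)).cdf).statistic)
    else:
        # degenerate fit: point mass at exp(mu); sup-distance to the EDF
        ks = 0.0 if np.all(v == v[0]) else 1.0
    return LogNormalFit(mu=mu, sigma=sigma, ks_distance=ks, n=len(v))


@dataclass
class BimodalSplit:
    """Two-component mixture fit of log abundance and the R1/R2 threshold."""

    threshold: float  # on the RPKM scale
    means: tuple  # log-scale component means (low, high)
    sds: tuple
    weights: tuple
    converged: bool
    n_iter: int
    warning: str | None = None

    @property
    def log_threshold(self) -> float:
        return float(np.log(self.threshold))


def _posterior_equality_point(w, m, s) -> float:
    """Solve w1 N(x; m1, s1) = w2 N(x; m2, s2) between the two means."""
    (w1, w2), (m1, m2), (s1, s2) = w, m, s
    c = np.log(w1 / s1) - np.log(w2 / s2)
    # (x-m2)^2/(2 s2^2) - (x-m1)^2/(2 s1^2) + c = 0
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = -m2 / s2**2 + m1 / s1**2
    k = m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2) + c
    if abs(a) < 1e-12:  # equal variances: linear crossing
        if abs(b) < 1e-12:
            return 0.5 * (m1 + m2)
        return -k / b
    disc = b**2 - 4 * a * k
    if disc < 0:
        return 0.5 * (m1 + m2)
    roots = np.array([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
    inside = roots[(roots >= min(m1, m2)) & (roots <= max(m1, m2))]
    if len(inside):
        return float(inside[0])
    return float(roots[np.argmin(np.abs(roots - 0.5 * (m1 + m2)))])


def _two_means_1d(x: np.ndarray) -> tuple:
    """Deterministic 1-D 2-means (Lloyd, quantile init) for the EM fallback."""
    c1, c2 = np.percentile(x, 25), np.percentile(x, 75)
    for _ in range(100):
        assign = np.abs(x - c1) <= np.abs(x - c2)
        if assign.all() or (~assign).all():
            break
        n1, n2 = x[assign].mean(), x[~assign].mean()
        if n1 == c1 and n2 == c2:
            break
        c1, c2 = n1, n2
    return float(c1), float(c2)


def split_rna_bimodal(values, seed: int = 0) -> BimodalSplit:
    """Fit the two-component mixture on log values and locate the split.

    EM with deterministic initialization, so the result is a pure function
    of the value multiset (the input is sorted internally; *seed* is
    accepted for interface symmetry but never used).  If a component
    collapses below the variance floor the split falls back to the midpoint
    of deterministic 2-means centers, with a warning.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) < 20:
        raise DegenerateInputError(f"need >= 20 values to split, got {len(v)}")
    if np.any(v <= 0):
        raise ValidationError("bimodal split requires strictly positive values")
    x = np.log(v)
    m = np.array([np.percentile(x, 25), np.percentile(x, 75)])
    var = np.array([x.var(), x.var()])
    w = np.array([0.5, 0.5])
    if np.ptp(x) == 0:
        warnings.warn("degenerate input: all abundances equal; split at the common value")
        return BimodalSplit(
            threshold=float(np.exp(x[0])),
            means=(float(x[0]), float(x[0])),
            sds=(0.0, 0.0),
            weights=(0.5, 0.5),
            converged=True,
            n_iter=0,
            warning="degenerate",
        )
    prev_ll = -np.inf
    converged = False
    collapsed = False
    n_iter = 0
    for n_iter in range(1, _EM_MAX_ITER + 1):
        dens = np.stack(
            [w[k] * sps.norm.pdf(x, m[k], np.sqrt(var[k])) for k in range(2)]
        )
        total = dens.sum(axis=0)
        total = np.where(total <= 0, np.finfo(float).tiny, total)
        resp = dens / total
        ll = float(np.log(total).sum())
        nk = resp.sum(axis=1)
        if np.any(nk < 1e-10):
            collapsed = True
            break
        w = nk / len(x)
        m = (resp * x).sum(axis=1) / nk
        var = (resp * (x - m[:, None]) ** 2).sum(axis=1) / nk
        if np.any(var < _VARIANCE_FLOOR):
            collapsed = True
            break
        if prev_ll > -np.inf and abs(ll - prev_ll) <= _EM_TOL * abs(prev_ll):
            converged = True
            break
        prev_ll = ll
    warning = None
    if collapsed:
        c1, c2 = _two_means_1d(x)
        warning = "EM component collapsed; falling back to 2-means midpoint"
        warnings.warn(warning)
        log_thr = 0.5 * (c1 + c2)
        lo, hi = sorted((c1, c2))
        return BimodalSplit(
            threshold=float(np.exp(log_thr)),
            means=(lo, hi),
            sds=(float(np.sqrt(max(var[0], 0.0))), float(np.sqrt(max(var[1], 0.0)))),
            weights=(float(w[0]), float(w[1])),
            converged=False,
            n_iter=n_iter,
            warning=warning,
        )
    order = np.argsort(m)
    w, m, var = w[order], m[order], var[order]
    s = np.sqrt(var)
    if abs(m[1] - m[0]) < (s[0] + s[1]):
        warning = "components overlap heavily; the input may be unimodal"
        warnings.warn(warning)
    log_thr = _posterior_equality_point(tuple(w), tuple(m), tuple(s))
    return BimodalSplit(
        threshold=float(np.exp(log_thr)),
        means=(float(m[0]), float(m[1])),
        sds=(float(s[0]), float(s[1])),
        weights=(float(w[0]), float(w[1])),
        converged=converged,
        n_iter=n_iter,
        warning=warning,
    )


@dataclass
class GroupAssignment:
    """Per-exemplar group labels plus the fitted split."""

    groups: pd.Series  # exemplar_id -> D | R1 | R2 | LOW
    split_threshold: float  # RPKM units, the R1/R2 boundary
    dna_fit: LogNormalFit | None = None
    rna_split: BimodalSplit | None = None

    def counts(self) -> pd.Series:
        return self.groups.value_counts().reindex(GROUP_LABELS, fill_value=0)

    def to_frame(self, rpkm: pd.Series | None = None) -> pd.DataFrame:
        out = pd.DataFrame({"group": self.groups})
        if rpkm is not None:
            out["rpkm_te"] = rpkm.reindex(out.index)
        out.index.name = "exemplar_id"
        return out

    def to_tsv(self, path, rpkm: pd.Series | None = None) -> None:
        with open(path, "w") as fh:
            fh.write(f"#split_threshold={self.split_threshold!r}\n")
            self.to_frame(rpkm).to_csv(fh, sep="\t")


def assign_groups(
    abundance: pd.DataFrame,
    db: ExemplarDB,
    config: AnalysisConfig | None = None,
    seed: int = 0,
    split_threshold: float | None = None,
) -> GroupAssignment:
    """Assign every exemplar to D, R1, R2 or LOW.

    Filtering precedes classification: exemplars under the low-copy RPKM
    threshold are LOW regardless of class.  Passing DNA-class exemplars are
    D; passing RNA-class exemplars split into R1/R2 at *split_threshold*
    (fitted from this table's RNA abundances when not given -- pass a
    threshold to freeze group definitions from a reference accession).
    """
    config = config or AnalysisConfig()
    table = abundance.copy()
    if "passes_filter" not in table:
        table["passes_filter"] = table["rpkm_te"] >= config.low_copy_threshold
    classes = db.classes().reindex(table.index)
    rna_pass = table.loc[(classes == "RNA") & table["passes_filter"], "rpkm_te"]
    if rna_pass.empty:
        raise DegenerateInputError("no RNA-class exemplars pass the low-copy filter")
    dna_pass = table.loc[(classes == "DNA") & table["passes_filter"], "rpkm_te"]
    dna_fit = fit_lognormal_edf(dna_pass) if len(dna_pass) >= 10 else None
    rna_split = None
    if split_threshold is None:
        rna_split = split_rna_bimodal(rna_pass, seed=seed)
        split_threshold = rna_split.threshold
    groups = pd.Series("LOW", index=table.index, dtype=object, name="group")
    passing = table["passes_filter"]
    groups[passing & (classes == "DNA")] = "D"
    rna_passing = passing & (classes == "RNA")
    groups[rna_passing & (table["rpkm_te"] < split_threshold)] = "R1"
    groups[rna_passing & (table["rpkm_te"] >= split_threshold)] = "R2"
    return GroupAssignment(
        groups=groups,
        split_threshold=float(split_threshold),
        dna_fit=dna_fit,
        rna_split=rna_split,
    )


def agreement(assignments: dict) -> dict:
    """Cross-accession agreement of R1/R2 classification.

    Restricted to RNA exemplars classified R1 or R2 (non-LOW) in every
    compared accession.  Returns the overall fraction with identical labels
    across all accessions plus pairwise fractions.
    """
    if len(assignments) < 2:
        raise DegenerateInputError("need >= 2 assignments to compare")
    names = list(assignments)
    labels = pd.DataFrame({a: assignments[a].groups for a in names})
    rna = labels.isin(["R1", "R2"]).all(axis=1)
    shared = labels[rna]
    if shared.empty:
        raise DegenerateInputError("no exemplar is classified R1/R2 in all accessions")
    overall = float((shared.nunique(axis=1) == 1).mean())
    pairwise = {}
    for a, b in itertools.combinations(names, 2):
        both = labels[labels[[a, b]].isin(["R1", "R2"]).all(axis=1)]
        pairwise[(a, b)] = float((both[a] == both[b]).mean())
    return {"overall": overall, "pairwise": pairwise, "n_shared": int(rna.sum())}
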