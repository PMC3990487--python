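"""Hypothesis tests for abundance shifts and copy-siRNA proportionality.

Three per-exemplar chi-square statistics (all 1 df, no continuity
correction) compare two accessions A and B:

``chi2_std``
    Pearson chi-square on the 2x2 table (hits to the exemplar vs hits to
    all other exemplars, per accession).  With 1 df it is analytically
    identical to the squared two-proportion Z statistic.

``chi2_corr``
    Corrects for accessions carrying different overall TE fractions: under
    the null the probability that one of the T = n_A + n_B hits came from A
    is p = F_A/(F_A+F_B) with F the gene-set (FGS) coverage of each
    library, and the statistic is the normal approximation to that binomial,
    (n_A - T p)^2 / (T p (1-p)).

``chi2_prop``
    Tests the null that siRNA targeting per TE copy is equal between
    accessions.  The default ("delta") construction compares the observed
    log siRNA ratio ln(s_A/s_B) with its null expectation
    r = ln(n_A/n_B) - ln(F_A/F_B) + ln(sig_A/sig_B) (sig = total siRNA hits
    per library, standing in for the unknown siRNA coverages) and divides by
    the delta-method variance 1/s_A + 1/s_B + 1/n_A + 1/n_B, which
    propagates sampling noise from both the siRNA and genomic counts.  A
    "binomial" variant conditions on the siRNA total instead, ignoring
    genomic noise.

Exemplars with zero margins are flagged untestable and carry no p-value;
they are excluded from the Benjamini-Hochberg family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import AnalysisConfig, DegenerateInputError, ExemplarDB, LibraryCounts, SiRNALibrary


@dataclass(frozen=True)
class TestOutcome:
    """One test: statistic, chi-square(1) p-value, testability flag."""

    statistic: float
    p_value: float
    testable: bool = True

    @classmethod
    def untestable(cls) -> "TestOutcome":
        return cls(statistic=float("nan"), p_value=float("nan"), testable=False)


def _chi2_p(stat):
    return sps.chi2.sf(stat, df=1)


# -- scalar tests -----------------------------------------------------------


def chi2_std(n_a: float, rest_a: float, n_b: float, rest_b: float) -> TestOutcome:
    """Pearson chi-square on the 2x2 hits table, without continuity correction."""
    for v in (n_a, rest_a, n_b, rest_b):
        if v < 0:
            raise ValueError("cell counts must be non-negative")
    row_a, row_b = n_a + rest_a, n_b + rest_b
    if row_a <= 0 or row_b <= 0:
        raise DegenerateInputError("both accessions must have reads")
    if n_a + n_b == 0 or rest_a + rest_b == 0:
        return TestOutcome.untestable()
    n = row_a + row_b
    stat = n * (n_a * rest_b - n_b * rest_a) ** 2 / (
        row_a * row_b * (n_a + n_b) * (rest_a + rest_b)
    )
    return TestOutcome(float(stat), float(_chi2_p(stat)))


def chi2_corr(n_a: float, n_b: float, fgs_cov_a: float, fgs_cov_b: float) -> TestOutcome:
    """Coverage-corrected chi-square with null proportion from FGS coverage."""
    if fgs_cov_a <= 0 or fgs_cov_b <= 0:
        raise DegenerateInputError("FGS coverages must be positive")
    p = fgs_cov_a / (fgs_cov_a + fgs_cov_b)
    t = n_a + n_b
    if t == 0:
        return TestOutcome.untestable()
    stat = (n_a - t * p) ** 2 / (t * p * (1.0 - p))
    return TestOutcome(float(stat), float(_chi2_p(stat)))


def chi2_prop(
    n_a: float,
    n_b: float,
    s_a: float,
    s_b: float,
    fgs_cov_a: float,
    fgs_cov_b: float,
    sirna_cov_a: float,
    sirna_cov_b: float,
    variant: str = "delta",
) -> TestOutcome:
    """Chi-square test of copy-number / siRNA proportionality between accessions."""
    if variant not in ("delta", "binomial"):
        raise ValueError(f"unknown variant {variant!r}")
    for name, v in (("fgs", fgs_cov_a), ("fgs", fgs_cov_b), ("sirna", sirna_cov_a), ("sirna", sirna_cov_b)):
        if v <= 0:
            raise DegenerateInputError(f"{name} coverages must be positive")
    if min(n_a, n_b, s_a, s_b) < 1:
        return TestOutcome.untestable()
    r = np.log(n_a / n_b) - np.log(fgs_cov_a / fgs_cov_b) + np.log(sirna_cov_a / sirna_cov_b)
    if variant == "delta":
        stat = (np.log(s_a / s_b) - r) ** 2 / (1 / s_a + 1 / s_b + 1 / n_a + 1 / n_b)
    else:
        total = s_a + s_b
        p = np.exp(r) / (1.0 + np.exp(r))
        stat = (s_a - total * p) ** 2 / (total * p * (1.0 - p))
    return TestOutcome(float(stat), float(_chi2_p(stat)))


# -- FDR --------------------------------------------------------------------


def bh_fdr(p_values, q_threshold: float = 0.001) -> pd.DataFrame:
    """Benjamini-Hochberg step-up q-values with strict q < threshold flags.

    NaN entries (untestable exemplars) are excluded from the family size m
    and come back NaN / not significant.
    """
    p = pd.Series(p_values, dtype=float)
    q = pd.Series(np.nan, index=p.index, name="q_value")
    mask = p.notna()
    m = int(mask.sum())
    if m > 0:
        pv = p[mask].to_numpy()
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        qv = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(qv, 1.0)
        q[mask] = out
    return pd.DataFrame(
        {"p_value": p, "q_value": q, "significant": q < q_threshold}
    )


# -- per-exemplar tables ----------------------------------------------------


def compare_abundance(
    counts_a: LibraryCounts,
    counts_b: LibraryCounts,
    db: ExemplarDB,
    test: str = "corr",
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Run chi2_std or chi2_corr over every exemplar, with BH correction."""
    config = config or AnalysisConfig()
    n_a = counts_a.hit_series(db).to_numpy()
    n_b = counts_b.hit_series(db).to_numpy()
    t = n_a + n_b
    testable = t > 0
    stat = np.full(len(t), np.nan)
    if test == "std":
        r_a = counts_a.total_ute_hits - n_a
        r_b = counts_b.total_ute_hits - n_b
        n = counts_a.total_ute_hits + counts_b.total_ute_hits
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = (
                n
                * (n_a * r_b - n_b * r_a) ** 2
                / (counts_a.total_ute_hits * counts_b.total_ute_hits * t * (r_a + r_b))
            )
        testable = testable & ((r_a + r_b) > 0)
        stat[testable] = raw[testable]
    elif test == "corr":
        if counts_a.fgs_hits <= 0 or counts_b.fgs_hits <= 0:
            raise DegenerateInputError("both libraries need FGS hits for chi2_corr")
        p = counts_a.fgs_hits / (counts_a.fgs_hits + counts_b.fgs_hits)
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = (n_a - t * p) ** 2 / (t * p * (1.0 - p))
        stat[testable] = raw[testable]
    else:
        raise ValueError(f"unknown test {test!r}")
    p_value = np.where(np.isnan(stat), np.nan, _chi2_p(np.nan_to_num(stat)))
    table = pd.DataFrame(
        {
            "statistic": stat,
            "p_value": p_value,
            "testable": testable,
        },
        index=pd.Index(db.ids, name="exemplar_id"),
    )
    fdr = bh_fdr(table["p_value"], config.fdr_q)
    table["q_value"] = fdr["q_value"]
    table["significant"] = fdr["significant"]
    table["test_name"] = f"chi2_{test}"
    return table


def test_proportionality(
    counts_a: LibraryCounts,
    counts_b: LibraryCounts,
    sirna_a: SiRNALibrary,
    sirna_b: SiRNALibrary,
    db: ExemplarDB,
    config: AnalysisConfig | None = None,
    variant: str = "delta",
) -> pd.DataFrame:
    """Run chi2_prop over every exemplar, with BH correction."""
    config = config or AnalysisConfig()
    n_a = counts_a.hit_series(db).to_numpy()
    n_b = counts_b.hit_series(db).to_numpy()
    s_a = sirna_a.count_series(db).to_numpy()
    s_b = sirna_b.count_series(db).to_numpy()
    f_a, f_b = counts_a.fgs_hits, counts_b.fgs_hits
    sig_a, sig_b = sirna_a.total_sirna_hits, sirna_b.total_sirna_hits
    if min(f_a, f_b) <= 0 or min(sig_a, sig_b) <= 0:
        raise DegenerateInputError("coverages must be positive for chi2_prop")
    testable = np.minimum.reduce([n_a, n_b, s_a, s_b]) >= 1
    stat = np.full(len(n_a), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.log(n_a / n_b) - np.log(f_a / f_b) + np.log(sig_a / sig_b)
        if variant == "delta":
            raw = (np.log(s_a / s_b) - r) ** 2 / (1 / s_a + 1 / s_b + 1 / n_a + 1 / n_b)
        elif variant == "binomial":
            total = s_a + s_b
            p = np.exp(r) / (1.0 + np.exp(r))
            raw = (s_a - total * p) ** 2 / (total * p * (1.0 - p))
        else:
            raise ValueError(f"unknown variant {variant!r}")
    stat[testable] = raw[testable]
    p_value = np.where(np.isnan(stat), np.nan, _chi2_p(np.nan_to_num(stat)))
    table = pd.DataFrame(
        {"statistic": stat, "p_value": p_value, "testable": testable},
        index=pd.Index(db.ids, name="exemplar_id"),
    )
    fdr = bh_fdr(table["p_value"], config.fdr_q)
    table["q_value"] = fdr["q_value"]
    table["significant"] = fdr["significant"]
    table["test_name"] = f"chi2_prop_{variant}"
    return table


# -- group comparisons ------------------------------------------------------


@dataclass
class GroupComparison:
    """Kruskal-Wallis comparison of a variable across TE groups."""

    variable: str
    summaries: pd.DataFrame  # per-group n, median, q1, q3
    kw_statistic: float
    kw_p_value: float
    pairwise: pd.DataFrame  # group pairs, Dunn z, p, BH q
    letters: dict  # group -> letter string; shared letter = not different


def _compact_letters(groups: list[str], different: set[frozenset]) -> dict[str, str]:
    """Assign letters so groups share a letter iff no significant difference.

    Letters correspond to maximal cliques of the non-significance graph;
    group counts here are small, so subsets are enumerated directly.
    """
    cliques: list[set[str]] = []
    for r in range(len(groups), 0, -1):
        for subset in itertools.combinations(groups, r):
            s = set(subset)
            if any(s <= c for c in cliques):
                continue
            if all(
                frozenset((a, b)) not in different
                for a, b in itertools.combinations(subset, 2)
            ):
                cliques.append(s)
    cliques.sort(key=lambda c: min(groups.index(g) for g in c))
    letters = {g: "" for g in groups}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in clique:
            letters[g] += letter
    return letters


def group_compare(
    values: pd.Series, groups: pd.Series, alpha: float = 0.05, variable: str = "value"
) -> GroupComparison:
    """Kruskal-Wallis across groups plus Dunn pairwise letters.

    Missing values are dropped; pairwise comparisons are Dunn-type z tests
    on the pooled ranks (with tie correction), BH-adjusted at *alpha*.
    """
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    by_group = {g: sub["value"].to_numpy() for g, sub in df.groupby("group", sort=False)}
    by_group = {g: v for g, v in by_group.items() if len(v) >= 2}
    if len(by_group) < 2:
        raise DegenerateInputError("need at least two groups with >= 2 observations")
    names = list(by_group)
    samples = [by_group[g] for g in names]
    if np.ptp(np.concatenate(samples)) == 0:
        kw_stat, kw_p = 0.0, 1.0  # constant variable: no rank information
    else:
        kw_stat, kw_p = sps.kruskal(*samples)
    # Dunn z-tests on pooled ranks with tie correction
    pooled = np.concatenate(samples)
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    offsets = np.cumsum([0] + [len(s) for s in samples])
    mean_ranks = {
        g: ranks[offsets[i] : offsets[i + 1]].mean() for i, g in enumerate(names)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / len(by_group[g1]) + 1.0 / len(by_group[g2])))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z, "p_value": p})
    pairwise = pd.DataFrame(rows)
    fdr = bh_fdr(pairwise["p_value"], q_threshold=alpha)
    pairwise["q_value"] = fdr["q_value"]
    pairwise["significant"] = fdr["significant"]
    different = {
        frozenset((row.group1, row.group2))
        for row in pairwise.itertuples()
        if row.significant
    }
    # order groups by median for letter assignment
    medians = {g: float(np.median(by_group[g])) for g in names}
    ordered = sorted(names, key=lambda g: medians[g])
    letters = _compact_letters(ordered, different)
    summaries = pd.DataFrame(
        {
            g: {
                "n": len(by_group[g]),
                "q1": float(np.percentile(by_group[g], 25)),
                "median": medians[g],
                "q3": float(np.percentile(by_group[g], 75)),
            }
            for g in names
        }
    ).T
    return GroupComparison(
        variable=variable,
        summaries=summaries,
        kw_statistic=float(kw_stat),
        kw_p_value=float(kw_p),
        pairwise=pairwise,
        letters=letters,
    )


# -- log-scale correlation --------------------------------------------------


@dataclass(frozen=True)
class LogCorrelation:
    r_squared: float
    slope: float
    intercept: float
    n: int


def correlation_log(hits_a: pd.Series, hits_b: pd.Series) -> LogCorrelation:
    """OLS of log(hits_b) on log(hits_a) over shared nonzero exemplars."""
    a = pd.Series(hits_a, dtype=float)
    b = pd.Series(hits_b, dtype=float).reindex(a.index)
    mask = (a > 0) & (b > 0)
    if int(mask.sum()) < 3:
        raise DegenerateInputError(
            f"need >= 3 shared nonzero exemplars, got {int(mask.sum())}"
        )
    x = np.log(a[mask].to_numpy())
    y = np.log(b[mask].to_numpy())
    if np.ptp(x) == 0:
        raise DegenerateInputError("all nonzero hits identical in accession A")
    fit = sps.linregress(x, y)
    return LogCorrelation(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=int(mask.sum()),
    )
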