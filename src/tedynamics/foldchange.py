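"""Log2 fold changes between accessions and their group summaries.

Three per-exemplar fold-change variables compare accessions A and B:

* ``FC_TE``: genomic hits normalized by gene-set (FGS) coverage and mean
  read length, log2((N_iA lbar_A / F_A) / (N_iB lbar_B / F_B));
* ``FC_22`` / ``FC_24``: siRNA hits normalized by each library's upper
  quartile (the 75th nearest-rank percentile of nonzero per-exemplar
  counts), log2((S_iA/UQ_A) / (S_iB/UQ_B)).

Exemplars with zero hits (genomic) or zero siRNA hits in either accession
are excluded and come back missing, never zero.  All three variables are
antisymmetric in the accession order, and between two replicate libraries
of the same genome their per-group expectation is zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DegenerateInputError, ExemplarDB, LibraryCounts, SiRNALibrary


def fc_te(counts_a: LibraryCounts, counts_b: LibraryCounts, db: ExemplarDB) -> pd.Series:
    """Coverage-normalized genomic log2 fold change per exemplar.

    NaN where either accession has zero hits to the exemplar.  The mean
    read length is retained in the normalization even though it cancels
    when both libraries share a read length.
    """
    if counts_a.fgs_hits <= 0 or counts_b.fgs_hits <= 0:
        raise DegenerateInputError("both libraries need FGS hits to normalize FC_TE")
    n_a = counts_a.hit_series(db)
    n_b = counts_b.hit_series(db)
    norm_a = n_a * counts_a.mean_read_length / counts_a.fgs_hits
    norm_b = n_b * counts_b.mean_read_length / counts_b.fgs_hits
    valid = (n_a > 0) & (n_b > 0)
    out = pd.Series(np.nan, index=n_a.index, name="fc_te")
    out[valid] = np.log2(norm_a[valid] / norm_b[valid])
    return out


def upper_quartile(sirna: SiRNALibrary) -> float:
    """Nearest-rank 75th percentile of the nonzero per-exemplar counts."""
    return sirna.upper_quartile


def fc_sirna(sirna_a: SiRNALibrary, sirna_b: SiRNALibrary, db: ExemplarDB) -> pd.Series:
    """Upper-quartile-normalized siRNA log2 fold change per exemplar.

    NaN where either library has zero siRNA hits to the exemplar.
    """
    if sirna_a.size_class != sirna_b.size_class:
        raise ValueError("fold change compares libraries of the same size class")
    uq_a, uq_b = sirna_a.upper_quartile, sirna_b.upper_quartile
    s_a = sirna_a.count_series(db)
    s_b = sirna_b.count_series(db)
    valid = (s_a > 0) & (s_b > 0)
    out = pd.Series(np.nan, index=s_a.index, name=f"fc_{sirna_a.size_class}")
    out[valid] = np.log2((s_a[valid] / uq_a) / (s_b[valid] / uq_b))
    return out


def fc_table(
    counts_a: LibraryCounts,
    counts_b: LibraryCounts,
    sirna: dict | None,
    db: ExemplarDB,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """FC_TE plus FC_22/FC_24 (when siRNA libraries are given) in one table.

    *sirna* maps size class to an ``(A, B)`` library pair.
    """
    table = pd.DataFrame({"fc_te": fc_te(counts_a, counts_b, db)})
    for size_class, (lib_a, lib_b) in (sirna or {}).items():
        table[f"fc_{size_class}"] = fc_sirna(lib_a, lib_b, db)
    if groups is not None:
        table.insert(0, "group", groups.reindex(table.index))
    table.index.name = "exemplar_id"
    return table


@dataclass
class GroupFCSummary:
    """Per-group fold-change summaries plus pairwise Welch t-tests."""

    summaries: pd.DataFrame  # (group, variable) -> n, mean, median, mean_abs
    pairwise: pd.DataFrame  # per variable/group-pair Welch t on FC and |FC|


def group_fc_summary(fc: pd.DataFrame, groups: pd.Series) -> GroupFCSummary:
    """Summarize each FC variable within groups and test groups pairwise.

    Reports signed mean, median and mean absolute FC per group (group size
    after exclusions), and two-tailed Welch t-tests between groups on both
    the signed FC and |FC|; groups with fewer than two values are skipped
    with a warning column left missing.
    """
    fc_cols = [c for c in fc.columns if c.startswith("fc_")]
    labels = groups.reindex(fc.index)
    summary_rows = []
    pairwise_rows = []
    for col in fc_cols:
        by_group = {
            g: sub[col].dropna().to_numpy()
            for g, sub in fc.groupby(labels, sort=False)
            if g in ("D", "R1", "R2")
        }
        for g, v in by_group.items():
            summary_rows.append(
                {
                    "variable": col,
                    "group": g,
                    "n": len(v),
                    "mean_fc": float(np.mean(v)) if len(v) else np.nan,
                    "median_fc": float(np.median(v)) if len(v) else np.nan,
                    "mean_abs_fc": float(np.mean(np.abs(v))) if len(v) else np.nan,
                }
            )
        names = [g for g, v in by_group.items() if len(v) >= 2]
        for g1, g2 in itertools.combinations(names, 2):
            v1, v2 = by_group[g1], by_group[g2]
            t_signed, p_signed = sps.ttest_ind(v1, v2, equal_var=False)
            t_abs, p_abs = sps.ttest_ind(np.abs(v1), np.abs(v2), equal_var=False)
            pairwise_rows.append(
                {
                    "variable": col,
                    "group1": g1,
                    "group2": g2,
                    "t_signed": float(t_signed),
                    "p_signed": float(p_signed),
                    "t_abs": float(t_abs),
                    "p_abs": float(p_abs),
                }
            )
    return GroupFCSummary(
        summaries=pd.DataFrame(summary_rows),
        pairwise=pd.DataFrame(pairwise_rows),
    )


def join_expression_fc(
    fc_table: pd.Series,
    groups: pd.Series,
    ratio_24_22: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join an external expression log2-FC table onto the group labels.

    The fold changes are consumed as provided (log2), matched by exemplar
    id.  Returns ``(per_exemplar, per_group)`` where per_exemplar carries
    the matched FC, group label and (optionally) the 24:22 siRNA ratio for
    the FC-vs-ratio scatter, and per_group reports the mean log2 FC and
    the fraction of exemplars with decreased expression (FC < 0).
    Unmatched rows are dropped and counted in ``per_group.attrs``.
    """
    fc = pd.Series(fc_table, dtype=float)
    matched = fc.index.intersection(groups.index)
    if matched.empty:
        raise DegenerateInputError("no exemplar ids match between the FC table and groups")
    per_exemplar = pd.DataFrame(
        {"log2_fc": fc.loc[matched], "group": groups.loc[matched]}
    )
    if ratio_24_22 is not None:
        per_exemplar["ratio_24_22"] = ratio_24_22.reindex(matched)
    rows = []
    for g, sub in per_exemplar.groupby("group", sort=False):
        v = sub["log2_fc"].dropna()
        rows.append(
            {
                "group": g,
                "n": len(v),
                "mean_log2_fc": float(v.mean()) if len(v) else np.nan,
                "fraction_decreasing": float((v < 0).mean()) if len(v) else np.nan,
            }
        )
    per_group = pd.DataFrame(rows).set_index("group")
    per_group.attrs["n_unmatched"] = int(len(fc) - len(matched))
    return per_exemplar, per_group
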