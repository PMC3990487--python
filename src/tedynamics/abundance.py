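"""Per-exemplar abundance: RPKM, approximate copy number, per-copy ratios.

The central quantity is RPKM_TE, reads per kilobase of exemplar per million
exemplar-mapped reads:

    RPKM_i = N_i / (L_i[kb] * R / 1e6)

with N_i the hits to exemplar i, L_i its length and R the total hits to the
exemplar set.  RPKM_TE is the study's proxy for subfamily copy number; the
identity sum_i RPKM_i * L_i[kb] = 1e6 holds for any library.

An approximate absolute copy number uses the gene set as a depth anchor:
per-base genomic depth is estimated as d = H_FGS * lbar / Lambda_FGS (gene
hits times mean read length over total gene-set length), and then

    C_i = N_i * lbar / (L_i[bp] * d).

Exemplars with RPKM below the low-copy threshold (default 1.2, roughly two
copies) are flagged out of classification and group summaries.
"""

from __future__ import annotations

import pandas as pd

from .core import AnalysisConfig, DegenerateInputError, ExemplarDB, LibraryCounts, SiRNALibrary


def rpkm(counts: LibraryCounts, db: ExemplarDB) -> pd.DataFrame:
    """RPKM_TE per exemplar; exemplars absent from the counts get 0."""
    total = counts.total_ute_hits
    if total <= 0:
        raise DegenerateInputError(
            f"library {counts.accession_id!r} has no exemplar-mapped reads (R=0)"
        )
    hits = counts.hit_series(db)
    lengths_kb = db.lengths_kb()
    table = pd.DataFrame(
        {
            "te_class": db.classes(),
            "length_kb": lengths_kb,
            "hits": hits,
            "rpkm_te": hits / (lengths_kb * total / 1e6),
        }
    )
    table.index.name = "exemplar_id"
    return table


def sirna_rpkm(sirna: SiRNALibrary, db: ExemplarDB) -> pd.Series:
    """siRNA RPKM per exemplar, same formula over the siRNA library totals."""
    total = sirna.total_sirna_hits
    if total <= 0:
        raise DegenerateInputError(
            f"siRNA library {sirna.accession_id!r}/{sirna.size_class} nt is empty"
        )
    counts = sirna.count_series(db)
    return (counts / (db.lengths_kb() * total / 1e6)).rename(f"rpkm_{sirna.size_class}")


def copy_number(
    counts: LibraryCounts, db: ExemplarDB, fgs_total_length_bp: float
) -> pd.Series:
    """Approximate copy number per exemplar, anchored on gene-set depth."""
    if counts.fgs_hits <= 0:
        raise DegenerateInputError(
            f"library {counts.accession_id!r} has no gene-set hits; depth unknown"
        )
    if fgs_total_length_bp <= 0:
        raise DegenerateInputError("gene-set total length must be positive")
    lbar = counts.mean_read_length
    depth = counts.fgs_hits * lbar / fgs_total_length_bp
    if depth <= 0:
        raise DegenerateInputError("estimated gene-set depth is zero")
    hits = counts.hit_series(db)
    lengths_bp = db.lengths_kb() * 1000.0
    return (hits * lbar / (lengths_bp * depth)).rename("copy_number")


def abundance_table(
    counts: LibraryCounts,
    db: ExemplarDB,
    config: AnalysisConfig | None = None,
    fgs_total_length_bp: float | None = None,
) -> pd.DataFrame:
    """RPKM, optional copy number, and the low-copy filter flag in one table."""
    config = config or AnalysisConfig()
    table = rpkm(counts, db)
    if fgs_total_length_bp is not None:
        table["copy_number"] = copy_number(counts, db, fgs_total_length_bp)
    return filter_low_copy(table, config)


def filter_low_copy(table: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Flag exemplars below the low-copy RPKM threshold (boundary retained).

    Filtered exemplars stay in the table with ``passes_filter=False``; the
    operation is idempotent.
    """
    out = table.copy()
    out["passes_filter"] = out["rpkm_te"] >= config.low_copy_threshold
    return out


def sirna_per_copy(
    sirna: SiRNALibrary, abundance: pd.DataFrame, db: ExemplarDB
) -> pd.Series:
    """siRNA hits per TE copy: siRNA RPKM over RPKM_TE.

    Missing (NaN) where RPKM_TE is zero -- a ratio against an absent
    exemplar is undefined, not zero or infinite.
    """
    numerator = sirna_rpkm(sirna, db)
    denom = abundance["rpkm_te"].reindex(numerator.index)
    ratio = numerator / denom.where(denom > 0)
    return ratio.rename(f"sirna{sirna.size_class}_per_copy")


def expression_per_copy(
    expr_rpkm: pd.Series, abundance: pd.DataFrame
) -> pd.Series:
    """Expression per TE copy: expression RPKM over RPKM_TE (NaN at RPKM 0)."""
    denom = abundance["rpkm_te"].reindex(expr_rpkm.index)
    return (expr_rpkm / denom.where(denom > 0)).rename("expression_per_copy")


def ratio_24_22(
    sirna24: SiRNALibrary,
    sirna22: SiRNALibrary,
    db: ExemplarDB,
    config: AnalysisConfig | None = None,
) -> pd.Series:
    """Per-exemplar 24:22 nt siRNA ratio on the RPKM scale.

    Exemplar lengths cancel between numerator and denominator, leaving a
    ratio of library-normalized (counts-per-million) values.  The
    pseudocount (default 0.5) is added on that normalized count scale so
    the ratio stays finite for exemplars untargeted in one size class and
    equals exactly 1 when both counts are zero.
    """
    config = config or AnalysisConfig()
    eps = config.pseudocount
    if sirna24.total_sirna_hits <= 0 or sirna22.total_sirna_hits <= 0:
        raise DegenerateInputError("both siRNA libraries must contain reads")
    cpm24 = sirna24.count_series(db) / (sirna24.total_sirna_hits / 1e6)
    cpm22 = sirna22.count_series(db) / (sirna22.total_sirna_hits / 1e6)
    return ((cpm24 + eps) / (cpm22 + eps)).rename("ratio_24_22")
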