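"""End-to-end orchestration: from count tables to TSV reports.

The pipeline reproduces the full analysis on any set of accessions: per
accession abundance tables; group definitions on a designated reference
accession (with per-accession assignments and an agreement report);
pairwise standard / coverage-corrected / proportionality chi-square tests
with BH-FDR flags; fold-change tables and group summaries; Kruskal-Wallis
group comparisons with significance letters; log-scale correlations; and a
machine-readable manifest recording inputs, seed, versions and per-filter
counts.  Outputs are plain TSV plus one JSON manifest, and a rerun on the
same inputs and seed is byte-identical.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core import (
    AnalysisConfig,
    ExemplarDB,
    LibraryCounts,
    SiRNALibrary,
    ValidationError,
    read_counts_table,
)
from . import abundance as ab
from . import classify as cl
from . import foldchange as fc
from . import stats as st


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""


@dataclass
class PipelineConfig:
    """Everything one run needs, loadable from a flat key=value file."""

    exemplar_db: str
    genomic: dict  # accession -> path to genomic counts TSV
    sirna22: dict = field(default_factory=dict)  # accession -> path
    sirna24: dict = field(default_factory=dict)
    expression_fc: str | None = None  # optional TSV: exemplar_id, log2_fc
    reference_accession: str | None = None
    output_dir: str = "tedynamics_out"
    seed: int = 0
    low_copy_threshold: float = 1.2
    fdr_q: float = 0.001
    alpha_group: float = 0.05
    prop_test_variant: str = "delta"

    def analysis_config(self) -> AnalysisConfig:
        return AnalysisConfig(
            low_copy_threshold=self.low_copy_threshold,
            fdr_q=self.fdr_q,
            alpha_group=self.alpha_group,
        )

    def validate(self) -> None:
        paths = [self.exemplar_db, *self.genomic.values(), *self.sirna22.values(), *self.sirna24.values()]
        if self.expression_fc:
            paths.append(self.expression_fc)
        for p in paths:
            if not Path(p).exists():
                raise ValidationError(f"input file does not exist: {p}")
        if len(set(self.genomic)) != len(self.genomic):
            raise ValidationError("accession names must be unique")
        if self.reference_accession and self.reference_accession not in self.genomic:
            raise ValidationError(
                f"reference accession {self.reference_accession!r} has no genomic counts"
            )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file.

        Per-accession inputs use dotted keys, e.g.
        ``genomic.B73 = counts_B73.tsv`` and ``sirna22.B73 = ...``.
        """
        flat: dict[str, str] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            flat[key.strip()] = value.strip()
        kwargs: dict = {"genomic": {}, "sirna22": {}, "sirna24": {}}
        for key, value in flat.items():
            if "." in key:
                section, accession = key.split(".", 1)
                if section not in ("genomic", "sirna22", "sirna24"):
                    raise ValidationError(f"unknown config section {section!r}")
                kwargs[section][accession] = value
            elif key in ("seed",):
                kwargs[key] = int(value)
            elif key in ("low_copy_threshold", "fdr_q", "alpha_group"):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _write_tsv(frame: pd.DataFrame, path: Path, header_meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, value in (header_meta or {}).items():
            fh.write(f"#{key}={value}\n")
        frame.to_csv(fh, sep="\t", float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the output directory."""
    config.validate()
    cfg = config.analysis_config()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "tedynamics",
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            "exemplar_db": str(config.exemplar_db),
            "genomic": {a: str(p) for a, p in config.genomic.items()},
            "sirna22": {a: str(p) for a, p in config.sirna22.items()},
            "sirna24": {a: str(p) for a, p in config.sirna24.items()},
            "expression_fc": str(config.expression_fc) if config.expression_fc else None,
        },
        "parameters": {
            "low_copy_threshold": cfg.low_copy_threshold,
            "fdr_q": cfg.fdr_q,
            "alpha_group": cfg.alpha_group,
            "prop_test_variant": config.prop_test_variant,
            "reference_accession": config.reference_accession,
        },
        "stages": {},
    }

    def stage(name: str):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - report stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    db = stage("load")(lambda: ExemplarDB.from_fasta(config.exemplar_db))
    accessions = list(config.genomic)
    counts: dict[str, LibraryCounts] = {}
    sirna: dict[int, dict[str, SiRNALibrary]] = {22: {}, 24: {}}

    def load_counts():
        for acc, path in config.genomic.items():
            obj = read_counts_table(path)
            if not isinstance(obj, LibraryCounts):
                raise ValidationError(f"{path} is not a genomic counts table")
            counts[acc] = obj
        for size, section in ((22, config.sirna22), (24, config.sirna24)):
            for acc, path in section.items():
                obj = read_counts_table(path)
                if not isinstance(obj, SiRNALibrary) or obj.size_class != size:
                    raise ValidationError(f"{path} is not a {size} nt siRNA table")
                sirna[size][acc] = obj

    stage("load")(load_counts)

    # -- abundance ---------------------------------------------------------
    abundance_tables: dict[str, pd.DataFrame] = {}

    def run_abundance():
        for acc in accessions:
            table = ab.abundance_table(counts[acc], db, cfg)
            abundance_tables[acc] = table
            _write_tsv(table, outdir / f"abundance_{acc}.tsv", {"accession": acc})
        manifest["stages"]["abundance"] = {
            acc: {
                "n_exemplars": int(len(t)),
                "n_low_copy_filtered": int((~t["passes_filter"]).sum()),
            }
            for acc, t in abundance_tables.items()
        }

    stage("abundance")(run_abundance)

    # -- classification ----------------------------------------------------
    reference = config.reference_accession or accessions[0]
    assignments: dict[str, cl.GroupAssignment] = {}

    def run_classify():
        for acc in accessions:
            assignments[acc] = cl.assign_groups(
                abundance_tables[acc], db, cfg, seed=config.seed
            )
            assignments[acc].to_tsv(
                outdir / f"groups_{acc}.tsv", abundance_tables[acc]["rpkm_te"]
            )
        manifest["stages"]["classify"] = {
            acc: {
                "split_threshold": assignments[acc].split_threshold,
                "counts": {k: int(v) for k, v in assignments[acc].counts().items()},
            }
            for acc in accessions
        }
        if len(accessions) >= 2:
            agree = cl.agreement(assignments)
            rows = [
                {"accession_a": a, "accession_b": b, "agreement": frac}
                for (a, b), frac in agree["pairwise"].items()
            ]
            rows.append(
                {"accession_a": "ALL", "accession_b": "ALL", "agreement": agree["overall"]}
            )
            _write_tsv(
                pd.DataFrame(rows).set_index("accession_a"),
                outdir / "agreement.tsv",
                {"n_shared_rna": agree["n_shared"]},
            )
            manifest["stages"]["agreement"] = {
                "overall": agree["overall"],
                "n_shared_rna": agree["n_shared"],
            }

    stage("classify")(run_classify)
    ref_groups = assignments[reference].groups

    # -- pairwise tests ----------------------------------------------------
    def run_tests():
        info = {}
        for a, b in itertools.combinations(accessions, 2):
            for test in ("std", "corr"):
                table = st.compare_abundance(counts[a], counts[b], db, test, cfg)
                _write_tsv(table, outdir / f"test_{test}_{a}_vs_{b}.tsv")
                info[f"{test}:{a}-{b}"] = int(table["significant"].sum())
            for size in (22, 24):
                if a in sirna[size] and b in sirna[size]:
                    table = st.test_proportionality(
                        counts[a], counts[b], sirna[size][a], sirna[size][b],
                        db, cfg, config.prop_test_variant,
                    )
                    _write_tsv(table, outdir / f"test_prop{size}_{a}_vs_{b}.tsv")
                    info[f"prop{size}:{a}-{b}"] = int(table["significant"].sum())
        manifest["stages"]["tests"] = info

    stage("tests")(run_tests)

    # -- fold changes ------------------------------------------------------
    def run_fc():
        info = {}
        for a, b in itertools.combinations(accessions, 2):
            sirna_pairs = {
                size: (sirna[size][a], sirna[size][b])
                for size in (22, 24)
                if a in sirna[size] and b in sirna[size]
            }
            table = fc.fc_table(counts[a], counts[b], sirna_pairs, db, ref_groups)
            excluded = {
                c: int(table[c].isna().sum()) for c in table.columns if c.startswith("fc_")
            }
            _write_tsv(
                table,
                outdir / f"fc_{a}_vs_{b}.tsv",
                {"excluded_" + c: n for c, n in excluded.items()},
            )
            summary = fc.group_fc_summary(table, ref_groups)
            _write_tsv(
                summary.summaries.set_index(["variable", "group"]),
                outdir / f"fc_summary_{a}_vs_{b}.tsv",
            )
            if not summary.pairwise.empty:
                _write_tsv(
                    summary.pairwise.set_index(["variable", "group1", "group2"]),
                    outdir / f"fc_tests_{a}_vs_{b}.tsv",
                )
            info[f"{a}-{b}"] = excluded
        manifest["stages"]["fold_change"] = info

    stage("fold_change")(run_fc)

    # -- group comparisons on the reference accession ----------------------
    def run_group_compare():
        variables = {"length_kb": db.lengths_kb(), "rpkm_te": abundance_tables[reference]["rpkm_te"]}
        for size in (22, 24):
            if reference in sirna[size]:
                variables[f"sirna{size}_per_copy"] = ab.sirna_per_copy(
                    sirna[size][reference], abundance_tables[reference], db
                )
        if reference in sirna[22] and reference in sirna[24]:
            variables["ratio_24_22"] = ab.ratio_24_22(
                sirna[24][reference], sirna[22][reference], db, cfg
            )
        info = {}
        for name, values in variables.items():
            masked = values.where(ref_groups.reindex(values.index) != "LOW")
            comp = st.group_compare(masked, ref_groups, cfg.alpha_group, name)
            out = comp.summaries.copy()
            out["letters"] = pd.Series(comp.letters)
            _write_tsv(
                out,
                outdir / f"group_compare_{name}.tsv",
                {"kw_statistic": f"{comp.kw_statistic:.10g}", "kw_p": f"{comp.kw_p_value:.3e}"},
            )
            info[name] = {"kw_p": comp.kw_p_value, "letters": comp.letters}
        manifest["stages"]["group_compare"] = info

    stage("group_compare")(run_group_compare)

    # -- correlations ------------------------------------------------------
    def run_correlations():
        rows = []
        for a, b in itertools.combinations(accessions, 2):
            corr = st.correlation_log(counts[a].hit_series(db), counts[b].hit_series(db))
            rows.append(
                {
                    "accession_a": a,
                    "accession_b": b,
                    "r_squared": corr.r_squared,
                    "slope": corr.slope,
                    "intercept": corr.intercept,
                    "n": corr.n,
                }
            )
        if rows:
            _write_tsv(pd.DataFrame(rows).set_index("accession_a"), outdir / "correlations.tsv")
            manifest["stages"]["correlations"] = {
                f"{r['accession_a']}-{r['accession_b']}": r["r_squared"] for r in rows
            }

    if len(accessions) >= 2:
        stage("correlations")(run_correlations)

    # -- external expression FC (mop1-style) ------------------------------
    if config.expression_fc:
        def run_expression():
            table = pd.read_csv(config.expression_fc, sep="\t", comment="#").set_index(
                "exemplar_id"
            )
            ratio = None
            if reference in sirna[22] and reference in sirna[24]:
                ratio = ab.ratio_24_22(sirna[24][reference], sirna[22][reference], db, cfg)
            per_exemplar, per_group = fc.join_expression_fc(
                table["log2_fc"], ref_groups, ratio
            )
            _write_tsv(per_exemplar, outdir / "expression_fc_exemplars.tsv")
            _write_tsv(
                per_group,
                outdir / "expression_fc_groups.tsv",
                {"n_unmatched": per_group.attrs["n_unmatched"]},
            )
            manifest["stages"]["expression_fc"] = {
                "n_matched": int(len(per_exemplar)),
                "n_unmatched": per_group.attrs["n_unmatched"],
            }

        stage("expression_fc")(run_expression)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
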