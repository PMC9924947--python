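"""End-to-end orchestration: survival table + counts in, report bundle out.

``run_all`` chains the stages — phenotype table, phenotype-lifespan
regressions, per-strain differential expression, pathway-target O/E
enrichment, per-stressor gene-phenotype correlation, multi-stressor
membership, and the stress-vs-lifespan overlap table — writing every table
as tab-delimited text plus a machine-readable JSON summary.  The run is
deterministic given its inputs and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association import (expression_summaries, gene_phenotype_correlation,
                          multiplicity_counts, phenotype_lifespan_correlations,
                          significant_sets)
from .diffexpr import CountMatrix, de_gene_sets, de_test, expression_filter, normalize
from .enrichment import GeneSet, overlap_stats, pathway_target_enrichment
from .io import read_counts, read_gmt, read_survival, write_gmt, write_table
from .phenotypes import DEFAULT_ASSAY_PANEL, build_phenotype_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and switches of a full pipeline run."""

    survival_path: str
    counts_path: str
    metadata_path: str
    outdir: str
    pathway_gmt: str | None = None
    lifespan_set_gmt: str | None = None
    assay_panel: tuple = DEFAULT_ASSAY_PANEL
    alpha: float = 0.05
    fdr: float = 0.01
    correlation_method: str = "pearson"
    correlation_use_fdr: bool = False
    summary_mode: str = "fold_change"
    universe: list[str] | None = None   # default: expression-filtered genes
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.fdr < 1):
            raise ValueError("alpha and fdr must lie in (0, 1)")
        for p in (self.survival_path, self.counts_path, self.metadata_path,
                  self.pathway_gmt, self.lifespan_set_gmt):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _control_map(survival: pd.DataFrame) -> dict[str, str]:
    return (survival.drop_duplicates("strain")
            .set_index("strain")["control_group"].to_dict())


def run_all(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.outdir``.

    Returns the in-memory results keyed by stage name.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log", mode="w")
    logging.getLogger().addHandler(fh)
    logger.info("stresslink %s seed=%d config=%s",
                __version__, config.seed, config)

    results: dict = {}
    stage = "read inputs"
    try:
        survival = read_survival(config.survival_path)
        cm = read_counts(config.counts_path, config.metadata_path)
        control_of = _control_map(survival)
        controls = set(control_of.values())
        mutants = [s for s in control_of if s not in controls]

        stage = "phenotypes"
        pheno = build_phenotype_table(survival, config.assay_panel,
                                      alpha=config.alpha)
        write_table(pheno, out / "phenotypes.tsv")
        results["phenotypes"] = pheno

        stage = "phenotype-lifespan regression"
        fits = phenotype_lifespan_correlations(pheno)
        write_table(fits, out / "phenotype_lifespan_fits.tsv")
        results["fits"] = fits

        stage = "differential expression"
        universe = (list(config.universe) if config.universe is not None
                    else expression_filter(cm))
        de_up: dict[str, set] = {}
        de_tables: dict[str, pd.DataFrame] = {}
        for s in mutants:
            if s not in set(cm.metadata["strain"]):
                logger.warning("strain %s has no RNA-seq samples; skipped", s)
                continue
            de = de_test(cm, s, control_of[s], fdr=config.fdr)
            de = de.loc[de.index.intersection(universe)]
            de_tables[s] = de
            write_table(de, out / f"de_{s}.tsv")
            de_up[s], _ = de_gene_sets(de)
        results["de"] = de_tables

        stage = "pathway enrichment"
        if config.pathway_gmt is not None:
            pathways = {k: set(v) & set(universe)
                        for k, v in read_gmt(config.pathway_gmt).items()}
            enr = pathway_target_enrichment(de_up, pathways, universe)
            write_table(enr, out / "pathway_enrichment.tsv", index=False)
            results["pathway_enrichment"] = enr

        stage = "gene-phenotype correlation"
        summaries = expression_summaries(
            normalize(cm), cm.metadata, mode=config.summary_mode,
            control_of={s: control_of[s] for s in mutants})
        summaries = summaries.loc[summaries.index.intersection(universe)]
        stress_pos: dict[str, set] = {}
        corr_tables: dict[str, pd.DataFrame] = {}
        assay_cols = [f"{spec.assay}_endpoint" for spec in config.assay_panel
                      if f"{spec.assay}_endpoint" in pheno.columns]
        for col in assay_cols + ["lifespan_extension_pct"]:
            corr = gene_phenotype_correlation(
                summaries, pheno[col], method=config.correlation_method,
                alpha=config.alpha, use_fdr=config.correlation_use_fdr,
                phenotype_name=col)
            corr_tables[col] = corr
            write_table(corr, out / f"correlation_{col}.tsv")
            pos, _neg = significant_sets(corr)
            if col != "lifespan_extension_pct":
                stress_pos[col.removesuffix("_endpoint")] = pos
        results["correlations"] = corr_tables
        write_gmt({f"poscorr_{k}": v for k, v in stress_pos.items()},
                  out / "stress_correlated_sets.gmt")

        stage = "multiplicity"
        mult = multiplicity_counts(stress_pos)
        results["multiplicity"] = mult

        stage = "stress-lifespan overlap"
        if config.lifespan_set_gmt is not None:
            lifespan_sets = read_gmt(config.lifespan_set_gmt)
            life_pos = set.union(*lifespan_sets.values()) & set(universe)
        else:
            life_pos, _ = significant_sets(
                corr_tables["lifespan_extension_pct"])
        rows = []
        for assay, pos in stress_pos.items():
            if not pos:
                logger.warning("no positively correlated genes for %s", assay)
                continue
            res = overlap_stats(GeneSet(assay, pos),
                                GeneSet("lifespan", life_pos), universe)
            rows.append({"stressor": assay, "n_stress": res.n_a,
                         "n_lifespan": res.n_b, "observed": res.observed,
                         "expected": res.expected, "ratio": res.ratio,
                         "percent_overlap": res.percent_overlap,
                         "p_value": res.p_value})
        overlap_tab = pd.DataFrame(rows)
        write_table(overlap_tab, out / "stress_lifespan_overlap.tsv",
                    index=False)
        results["overlap"] = overlap_tab

        stage = "summary"
        summary = {
            "version": __version__,
            "seed": config.seed,
            "config": {k: str(v) for k, v in vars(config).items()},
            "n_strains": len(mutants),
            "n_genes_universe": len(universe),
            "phenotype_fits": fits.round(6).to_dict(orient="index"),
            "multiplicity_counts": {str(k): v for k, v in mult.items()},
            "overlap": overlap_tab.round(6).to_dict(orient="records"),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                     sort_keys=True))
        results["summary"] = summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage: {stage}") from exc
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()
    return results
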