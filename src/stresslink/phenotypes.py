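"""Strain-level phenotype table: lifespan extension, stress endpoints,
direction calls, normalized scores, combined score, resistance count.

Each stress assay is summarized by a single per-strain endpoint — either
the fraction of animals alive at a fixed time (heat, acute oxidative,
osmotic, anoxia) or the mean survival time (chronic oxidative, bacterial
pathogen) — and a significance call against the strain's matched control.
Per-assay endpoints are normalized so the most resistant strain scores
100%, averaged at equal weight into a combined stress survival score, and
the number of assays with significantly increased survival gives the
resistance count (0..panel size).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import survival as surv
from .simulate import LIFESPAN_ASSAY

logger = logging.getLogger(__name__)

ENDPOINT_KINDS = ("fraction_alive_at_t", "mean_survival")
TESTS = ("logrank", "gehan", "anova_dunnett", "t_test")


@dataclass(frozen=True)
class AssaySpec:
    """How one stress assay is scored and tested."""

    assay: str
    stressor: str
    endpoint: str                       # one of ENDPOINT_KINDS
    test: str                           # one of TESTS
    endpoint_time: float | None = None  # required for fraction endpoints
    unit: str = "hours"

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINT_KINDS:
            raise ValueError(f"unknown endpoint kind {self.endpoint!r}")
        if self.test not in TESTS:
            raise ValueError(f"unknown test {self.test!r}")
        if self.endpoint == "fraction_alive_at_t" and self.endpoint_time is None:
            raise ValueError(
                f"assay {self.assay!r}: fraction endpoint requires endpoint_time")


# default panel mirroring the six classic worm stress paradigms
DEFAULT_ASSAY_PANEL: tuple[AssaySpec, ...] = (
    AssaySpec("heat", "37C heat", "fraction_alive_at_t", "anova_dunnett", 10.0),
    AssaySpec("oxidative_chronic", "4 mM paraquat", "mean_survival",
              "logrank", unit="days"),
    AssaySpec("oxidative_acute", "300 uM juglone", "fraction_alive_at_t",
              "anova_dunnett", 10.0),
    AssaySpec("bacterial", "P. aeruginosa PA14", "mean_survival",
              "logrank", unit="days"),
    AssaySpec("osmotic", "450-500 mM NaCl", "fraction_alive_at_t",
              "anova_dunnett", 48.0),
    AssaySpec("anoxia", "72-96 h anoxia", "fraction_alive_at_t",
              "anova_dunnett", 72.0),
)


def lifespan_extension(mutant_mean: float, control_mean: float) -> float:
    """Percent lifespan extension of a mutant over its control."""
    if control_mean <= 0:
        raise ValueError("control mean lifespan must be positive")
    return 100.0 * (mutant_mean - control_mean) / control_mean


def direction_call(endpoint_mutant: float, endpoint_control: float,
                   p: float, alpha: float = 0.05) -> str:
    """'increased' / 'decreased' / 'unchanged' survival vs control."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if p < alpha and endpoint_mutant > endpoint_control:
        return "increased"
    if p < alpha and endpoint_mutant < endpoint_control:
        return "decreased"
    return "unchanged"


def relative_score(endpoints: pd.Series) -> pd.Series:
    """Per-assay scores as percent of the best strain (max -> 100%)."""
    vals = endpoints.astype(float)
    top = vals.max()
    if not np.isfinite(top) or top <= 0:
        raise ValueError("relative score undefined: no positive endpoint")
    return 100.0 * vals / top


def combined_score(scores) -> float:
    """Equal-weight mean of per-assay relative scores (0-100 scale).

    Missing assays are excluded with a warning, never imputed.
    """
    vals = pd.Series(list(scores), dtype=float)
    n_missing = int(vals.isna().sum())
    if n_missing:
        logger.warning("combined score: excluding %d missing assay scores",
                       n_missing)
        vals = vals.dropna()
    if vals.empty:
        raise ValueError("combined score undefined: no assay scores")
    return float(vals.mean())


def resistance_count(calls) -> int:
    """Number of stressors with significantly increased survival."""
    return int(sum(1 for c in calls if c == "increased"))


def _endpoint_value(records, spec: AssaySpec) -> float:
    if spec.endpoint == "fraction_alive_at_t":
        return surv.fraction_alive(records, spec.endpoint_time)
    return surv.mean_survival(records)


def _replicate_fractions(records, t: float) -> list[float]:
    by_rep: dict[str, list] = {}
    for r in records:
        by_rep.setdefault(r.replicate, []).append(r)
    return [surv.fraction_alive(rs, t) for _, rs in sorted(by_rep.items())]


def assay_endpoints(records, spec: AssaySpec, control_of: dict[str, str],
                    ) -> pd.DataFrame:
    """Endpoints and significance for every strain of one assay.

    ``records`` are all SurvivalRecords of one assay; ``control_of`` maps
    each mutant strain to its control strain id.  Proportion endpoints are
    tested by one-way ANOVA with Dunnett's comparison over replicate-level
    survival fractions (strains sharing a control enter one Dunnett family;
    a strain with its own dedicated control is tested by Student's t-test);
    time-to-event endpoints use ``spec``'s two-sample survival test.
    """
    by_strain: dict[str, list] = {}
    for r in records:
        by_strain.setdefault(r.strain, []).append(r)
    controls = set(control_of.values())
    mutants = [s for s in by_strain if s not in controls]
    for s in mutants:
        if control_of.get(s) not in by_strain:
            raise ValueError(
                f"assay {spec.assay!r}: control arm "
                f"{control_of.get(s)!r} missing for strain {s!r}")

    endpoint = {s: _endpoint_value(by_strain[s], spec) for s in by_strain}
    pvals: dict[str, float] = {}
    stats_: dict[str, float] = {}
    tests: dict[str, str] = {}

    if spec.test in ("logrank", "gehan"):
        fn = surv.logrank_test if spec.test == "logrank" \
            else surv.gehan_wilcoxon_test
        for s in mutants:
            res = fn(by_strain[s], by_strain[control_of[s]])
            pvals[s], stats_[s], tests[s] = res.p_value, res.statistic, res.test_name
    elif spec.test == "t_test":
        for s in mutants:
            fr_m = _replicate_fractions(by_strain[s], spec.endpoint_time)
            fr_c = _replicate_fractions(by_strain[control_of[s]],
                                        spec.endpoint_time)
            res = surv.students_t(fr_m, fr_c)
            pvals[s], stats_[s], tests[s] = res.p_value, res.statistic, res.test_name
    else:  # anova_dunnett families per shared control
        if spec.endpoint != "fraction_alive_at_t":
            raise ValueError("anova_dunnett applies to proportion endpoints")
        for ctrl in sorted(controls):
            fam = [s for s in mutants if control_of[s] == ctrl]
            if not fam:
                continue
            fr_c = _replicate_fractions(by_strain[ctrl], spec.endpoint_time)
            fr_m = [_replicate_fractions(by_strain[s], spec.endpoint_time)
                    for s in fam]
            if len(fam) == 1:
                res = surv.students_t(fr_m[0], fr_c)
                pvals[fam[0]] = res.p_value
                stats_[fam[0]] = res.statistic
                tests[fam[0]] = res.test_name
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    dr = surv.anova_dunnett(fr_c, fr_m)
                for s, p, t in zip(fam, dr.adjusted_p, dr.statistics):
                    pvals[s], stats_[s] = float(p), float(t)
                    tests[s] = "anova_dunnett"

    rows = []
    for s in mutants:
        rows.append({
            "strain": s, "assay": spec.assay,
            "endpoint": endpoint[s],
            "control_endpoint": endpoint[control_of[s]],
            "statistic": stats_[s], "p_value": pvals[s],
            "test": tests[s],
        })
    return pd.DataFrame(rows)


def build_phenotype_table(survival_table: pd.DataFrame,
                          panel=DEFAULT_ASSAY_PANEL,
                          alpha: float = 0.05,
                          lifespan_assay: str = LIFESPAN_ASSAY,
                          ) -> pd.DataFrame:
    """Full strain phenotype table from an individual-level survival table.

    One row per mutant strain: mean lifespan and % extension, per-assay
    endpoint / p / direction call / relative score, combined stress
    survival score, and resistance count.
    """
    from .simulate import survival_records

    control_of = (survival_table.drop_duplicates("strain")
                  .set_index("strain")["control_group"].to_dict())
    controls = set(control_of.values())
    mutants = [s for s in control_of if s not in controls]

    ls_tab = survival_table[survival_table["assay"] == lifespan_assay]
    if ls_tab.empty:
        raise ValueError(f"no records for lifespan assay {lifespan_assay!r}")
    ls_recs: dict[str, list] = {}
    for r in survival_records(ls_tab):
        ls_recs.setdefault(r.strain, []).append(r)

    pheno: dict[str, dict] = {
        s: {"strain": s, "control": control_of[s]} for s in mutants}
    for s in mutants:
        mean_m = surv.mean_survival(ls_recs[s])
        mean_c = surv.mean_survival(ls_recs[control_of[s]])
        pheno[s]["lifespan_mean"] = mean_m
        pheno[s]["lifespan_extension_pct"] = lifespan_extension(mean_m, mean_c)

    for spec in panel:
        tab = survival_table[survival_table["assay"] == spec.assay]
        if tab.empty:
            logger.warning("assay %r absent from survival table; skipped",
                           spec.assay)
            continue
        res = assay_endpoints(survival_records(tab), spec,
                              {s: control_of[s] for s in mutants})
        res = res.set_index("strain")
        rel = relative_score(res["endpoint"])
        for s in mutants:
            pheno[s][f"{spec.assay}_endpoint"] = res.loc[s, "endpoint"]
            pheno[s][f"{spec.assay}_p"] = res.loc[s, "p_value"]
            pheno[s][f"{spec.assay}_direction"] = direction_call(
                res.loc[s, "endpoint"], res.loc[s, "control_endpoint"],
                res.loc[s, "p_value"], alpha)
            pheno[s][f"{spec.assay}_score"] = rel.loc[s]

    for s in mutants:
        scores = [pheno[s].get(f"{spec.assay}_score") for spec in panel]
        pheno[s]["combined_score"] = combined_score(
            [x for x in scores if x is not None])
        pheno[s]["resistance_count"] = resistance_count(
            pheno[s].get(f"{spec.assay}_direction") for spec in panel)
    out = pd.DataFrame(list(pheno.values())).set_index("strain")
    return out
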