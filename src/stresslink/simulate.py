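"""Synthetic cohort generator with planted ground truth.

Emulates a panel study of long-lived C. elegans mutants: ~9 mutant strains
plus matched wild-type controls (one mutant reared with a separate
25 degC-development control), one lifespan assay and six stress assays per
strain, and bulk RNA-seq counts (negative binomial, batch structure,
6 biological replicates per strain).

The generative model
--------------------
Each strain s carries a lifespan trait L_s (its configured fractional
lifespan extension; 0 for wild type).  A shared robustness factor R_s = L_s
and independent stress-specific factors U_{s,a} combine into per-assay
stress traits

    T_{s,a} = w_a * R_s + (1 - w_a) * U_{s,a}

where the mixing weight w_a dials how much of a stressor's resistance is
driven by the same factor that drives longevity (w = 1: fully shared;
w = 0: fully stress-specific).  Death times are Weibull with a common shape
and a scale chosen so the mean survival in assay a is
baseline_a * (1 + coupling_a * T_{s,a}).  Censoring is independent uniform
over each animal's observation window.

Gene modules couple expression to the latent traits: mean counts follow

    mu_gs = baseline_g * 2 ** (beta_g * x_s + batch offset)

with x_s the module's target latent (R_s for shared drivers, L_s for
lifespan-only genes, U_{s,a} for stress-specific genes, nothing for null
genes) and counts ~ NB(mu, dispersion) with Var = mu + dispersion * mu^2.

Randomness is drawn from one pseudo-random stream per (strain, assay) and
per generation stage, each derived from the master seed, so output is
independent of generation order and byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .survival import SurvivalRecord

# default longevity effects (fractional lifespan extension) for the nine
# mutant strains of the emulated panel, smallest to largest
DEFAULT_LONGEVITY_EFFECTS: dict[str, float] = {
    "ife-2": 0.263,
    "clk-1": 0.334,
    "sod-2": 0.372,
    "eat-2": 0.456,
    "osm-5": 0.654,
    "nuo-6": 0.792,
    "isp-1": 0.838,
    "glp-1": 0.892,
    "daf-2": 1.384,
}

WILDTYPE = "WT"
WILDTYPE_ALT = "WT-25C"  # control reared at 25 degC during development
LIFESPAN_ASSAY = "lifespan"


@dataclass(frozen=True)
class SimAssay:
    """One stress paradigm: baseline survival scale and trait coupling."""

    name: str
    baseline_mean: float       # mean survival of wild type, assay units
    unit: str                  # "hours" or "days"
    coupling: float = 1.0      # d(mean)/d(trait) relative to baseline
    shared_weight: float = 0.6  # w_a: share of trait from the common factor


DEFAULT_STRESS_ASSAYS: tuple[SimAssay, ...] = (
    SimAssay("heat", 12.0, "hours", 0.6, 0.6),
    SimAssay("oxidative_chronic", 8.0, "days", 0.8, 0.7),
    SimAssay("oxidative_acute", 9.0, "hours", 0.6, 0.6),
    SimAssay("bacterial", 5.0, "days", 0.9, 0.95),
    SimAssay("osmotic", 55.0, "hours", 0.5, 0.5),
    SimAssay("anoxia", 80.0, "hours", 0.5, 0.6),
)


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with panel-realistic defaults."""

    strain_longevity_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LONGEVITY_EFFECTS))
    wt_lifespan_mean: float = 20.0            # days
    stress_assays: tuple[SimAssay, ...] = DEFAULT_STRESS_ASSAYS
    alt_temp_strain: str | None = "glp-1"     # uses the 25 degC-reared control
    n_worms_per_assay_arm: int = 60
    n_survival_replicates: int = 3
    weibull_shape: float = 3.0
    censor_rate: float = 0.05
    n_rnaseq_replicates: int = 6
    n_genes: int = 5000
    n_shared_driver: int = 200
    n_lifespan_only: int = 100
    n_stress_specific: int = 50               # per stress assay
    effect_size: float = 1.0                  # log2 units per unit trait
    nb_dispersion: float = 0.1
    batch_count: int = 2
    batch_log2_spread: float = 0.2            # max-min batch offset, log2
    shared_weight: float | None = None        # overrides every assay's w_a
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_worms_per_assay_arm <= 0 or self.n_genes <= 0:
            raise ValueError("sizes must be positive")
        if self.n_rnaseq_replicates <= 0 or self.n_survival_replicates <= 0:
            raise ValueError("replicate counts must be positive")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")
        if self.nb_dispersion < 0 or self.weibull_shape <= 0:
            raise ValueError("dispersion must be >= 0 and shape > 0")
        if self.wt_lifespan_mean <= 0:
            raise ValueError("wild-type lifespan mean must be positive")
        n_module = (self.n_shared_driver + self.n_lifespan_only
                    + self.n_stress_specific * len(self.stress_assays))
        if n_module > self.n_genes:
            raise ValueError(
                f"module sizes sum to {n_module} > n_genes={self.n_genes}")
        if self.shared_weight is not None:
            self.stress_assays = tuple(
                replace(a, shared_weight=self.shared_weight)
                for a in self.stress_assays)

    @property
    def mutant_strains(self) -> list[str]:
        return list(self.strain_longevity_effects)

    @property
    def all_strains(self) -> list[str]:
        strains = [WILDTYPE]
        if self.alt_temp_strain is not None:
            strains.append(WILDTYPE_ALT)
        return strains + self.mutant_strains

    def control_for(self, strain: str) -> str:
        if strain == self.alt_temp_strain or strain == WILDTYPE_ALT:
            return WILDTYPE_ALT
        return WILDTYPE


@dataclass
class CohortTruth:
    """Planted ground truth of a simulated cohort."""

    gene_module: dict[str, str]                 # gene -> module label
    coupling_lifespan: dict[str, float]         # gene -> beta on lifespan
    coupling_stress: dict[str, dict[str, float]]  # gene -> assay -> beta
    strain_traits: pd.DataFrame     # strains x (lifespan, shared, T_a, U_a)
    expected_mean_survival: pd.DataFrame        # strains x assays

    def module_genes(self, label: str) -> set[str]:
        return {g for g, m in self.gene_module.items() if m == label}


def _stream(seed: int, *keys: int) -> np.random.Generator:
    """Deterministic per-purpose RNG stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, *keys]))


def generate_survival_times(strain_scale: float, n: int, censor_rate: float,
                            rng: np.random.Generator | int,
                            shape: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Weibull death times with mean ``strain_scale`` and uniform censoring.

    Returns (times, events).  With probability ``censor_rate`` an animal is
    censored at a uniform time within its own observation window.  ``rng``
    may be a Generator or an integer seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if n <= 0:
        raise ValueError("n must be positive")
    if strain_scale <= 0:
        raise ValueError("strain_scale must be positive")
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must be in [0, 1)")
    lam = strain_scale / math.gamma(1.0 + 1.0 / shape)
    times = lam * rng.weibull(shape, size=n)
    times = np.maximum(times, 1e-9)
    events = np.ones(n, dtype=int)
    censor = rng.random(n) < censor_rate
    u = rng.random(n)
    times = np.where(censor, np.maximum(times * u, 1e-9), times)
    events[censor] = 0
    return times, events


def _strain_traits(config: SimConfig) -> pd.DataFrame:
    """Latent lifespan/shared/specific traits for every strain."""
    rng = _stream(config.seed, 0)
    rows = []
    max_eff = max(config.strain_longevity_effects.values(), default=1.0)
    for strain in config.all_strains:
        L = config.strain_longevity_effects.get(strain, 0.0)
        row = {"strain": strain, "lifespan": L, "shared": L}
        for assay in config.stress_assays:
            # specific factor: 0 for controls, symmetric for mutants so a
            # mutant can also show decreased resistance to single stressors
            U = 0.0 if strain in (WILDTYPE, WILDTYPE_ALT) \
                else float(rng.uniform(-max_eff / 2, max_eff / 2))
            w = assay.shared_weight
            row[f"U_{assay.name}"] = U
            row[f"T_{assay.name}"] = w * L + (1.0 - w) * U
        rows.append(row)
    return pd.DataFrame(rows).set_index("strain")


def _assign_modules(config: SimConfig) -> tuple[dict[str, str], dict[str, float],
                                                dict[str, dict[str, float]]]:
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    module: dict[str, str] = {}
    c_life: dict[str, float] = {}
    c_stress: dict[str, dict[str, float]] = {}
    beta = config.effect_size
    i = 0
    for g in genes[i:i + config.n_shared_driver]:
        module[g] = "shared_driver"
        c_life[g] = beta
        c_stress[g] = {a.name: beta * a.shared_weight
                       for a in config.stress_assays}
    i += config.n_shared_driver
    for g in genes[i:i + config.n_lifespan_only]:
        module[g] = "lifespan_only"
        c_life[g] = beta
        c_stress[g] = {a.name: 0.0 for a in config.stress_assays}
    i += config.n_lifespan_only
    for assay in config.stress_assays:
        for g in genes[i:i + config.n_stress_specific]:
            module[g] = f"specific_{assay.name}"
            c_life[g] = 0.0
            c_stress[g] = {a.name: beta * (1.0 - a.shared_weight)
                           if a.name == assay.name else 0.0
                           for a in config.stress_assays}
        i += config.n_stress_specific
    for g in genes[i:]:
        module[g] = "null"
        c_life[g] = 0.0
        c_stress[g] = {a.name: 0.0 for a in config.stress_assays}
    return module, c_life, c_stress


def generate_survival_table(config: SimConfig,
                            traits: pd.DataFrame) -> pd.DataFrame:
    """Survival records for every strain x assay arm, replicate-split."""
    assays = [(LIFESPAN_ASSAY, config.wt_lifespan_mean, 1.0, "lifespan")]
    assays += [(a.name, a.baseline_mean, a.coupling, f"T_{a.name}")
               for a in config.stress_assays]
    strain_idx = {s: i for i, s in enumerate(config.all_strains)}
    rows = []
    for strain in config.all_strains:
        for ai, (assay, baseline, coupling, trait_col) in enumerate(assays):
            trait = traits.loc[strain, trait_col] if trait_col != "lifespan" \
                else traits.loc[strain, "lifespan"]
            mean = baseline * (1.0 + coupling * trait)
            rng = _stream(config.seed, 1, strain_idx[strain], ai)
            times, events = generate_survival_times(
                mean, config.n_worms_per_assay_arm, config.censor_rate,
                rng, config.weibull_shape)
            for k, (t, e) in enumerate(zip(times, events)):
                rows.append({
                    "strain": strain,
                    "assay": assay,
                    "replicate": f"r{k % config.n_survival_replicates + 1}",
                    "animal_id": f"{strain}_{assay}_{k}",
                    "time": float(t),
                    "event": int(e),
                    "control_group": config.control_for(strain),
                })
    return pd.DataFrame(rows)


def generate_expression_counts(config: SimConfig, traits: pd.DataFrame,
                               module: dict[str, str],
                               c_life: dict[str, float],
                               c_stress: dict[str, dict[str, float]],
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB count matrix (genes x samples) and sample metadata."""
    genes = list(module)
    rng_base = _stream(config.seed, 2)
    baseline = np.exp(rng_base.normal(5.5, 1.5, size=len(genes)))
    # per-gene log2 response x_s for each strain, by module target
    assay_w = {a.name: a.shared_weight for a in config.stress_assays}
    target_col = []
    beta_vec = np.zeros(len(genes))
    for j, g in enumerate(genes):
        m = module[g]
        if m == "shared_driver":
            target_col.append("shared")
            beta_vec[j] = c_life[g]
        elif m == "lifespan_only":
            target_col.append("lifespan")
            beta_vec[j] = c_life[g]
        elif m.startswith("specific_"):
            a = m.removeprefix("specific_")
            target_col.append(f"U_{a}")
            beta_vec[j] = c_stress[g][a] / (1.0 - assay_w[a]) \
                if assay_w[a] < 1.0 else config.effect_size
        else:
            target_col.append("null")
            beta_vec[j] = 0.0

    if config.batch_count > 1:
        batch_offsets = np.linspace(-config.batch_log2_spread / 2,
                                    config.batch_log2_spread / 2,
                                    config.batch_count)
    else:
        batch_offsets = np.zeros(1)

    strain_idx = {s: i for i, s in enumerate(config.all_strains)}
    sample_ids, meta_rows, cols = [], [], []
    for strain in config.all_strains:
        x = np.array([traits.loc[strain, c] if c != "null" else 0.0
                      for c in target_col])
        log2mu_strain = np.log2(baseline) + beta_vec * x
        for rep in range(config.n_rnaseq_replicates):
            batch = rep % config.batch_count
            mu = 2.0 ** (log2mu_strain + batch_offsets[batch])
            rng = _stream(config.seed, 3, strain_idx[strain], rep)
            if config.nb_dispersion < 1e-8:
                counts = rng.poisson(mu)
            else:
                size = 1.0 / config.nb_dispersion
                counts = rng.negative_binomial(size, size / (size + mu))
            sid = f"{strain}_rep{rep + 1}"
            sample_ids.append(sid)
            cols.append(counts)
            meta_rows.append({"sample": sid, "strain": strain,
                              "batch": f"b{batch + 1}",
                              "replicate": f"rep{rep + 1}"})
    counts_df = pd.DataFrame(np.column_stack(cols), index=genes,
                             columns=sample_ids)
    counts_df.index.name = "gene"
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return counts_df, meta


def planted_gene_sets(config: SimConfig,
                      module: dict[str, str]) -> dict[str, set[str]]:
    """The planted modules as gene sets (GMT-exportable)."""
    sets: dict[str, set[str]] = {}
    for label in (["shared_driver", "lifespan_only"]
                  + [f"specific_{a.name}" for a in config.stress_assays]):
        members = {g for g, m in module.items() if m == label}
        if members:
            sets[label] = members
    return sets


def generate_cohort(config: SimConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                               dict[str, set[str]], CohortTruth]:
    """Full in-silico study: survival, counts, metadata, gene sets, truth."""
    traits = _strain_traits(config)
    module, c_life, c_stress = _assign_modules(config)
    survival = generate_survival_table(config, traits)
    counts, meta = generate_expression_counts(config, traits, module,
                                              c_life, c_stress)
    gene_sets = planted_gene_sets(config, module)

    assay_names = [LIFESPAN_ASSAY] + [a.name for a in config.stress_assays]
    exp_rows = {}
    for strain in config.all_strains:
        row = {LIFESPAN_ASSAY: config.wt_lifespan_mean
               * (1.0 + traits.loc[strain, "lifespan"])}
        for a in config.stress_assays:
            row[a.name] = a.baseline_mean * (
                1.0 + a.coupling * traits.loc[strain, f"T_{a.name}"])
        exp_rows[strain] = row
    expected = pd.DataFrame(exp_rows).T[assay_names]
    expected.index.name = "strain"

    truth = CohortTruth(gene_module=module, coupling_lifespan=c_life,
                        coupling_stress=c_stress, strain_traits=traits,
                        expected_mean_survival=expected)
    return survival, counts, meta, gene_sets, truth


def survival_records(table: pd.DataFrame) -> list[SurvivalRecord]:
    """Typed records from a survival table (one row per animal)."""
    return [SurvivalRecord(strain=r.strain, assay=r.assay,
                           replicate=r.replicate, time=float(r.time),
                           event=int(r.event),
                           control_group=getattr(r, "control_group", ""))
            for r in table.itertuples(index=False)]
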