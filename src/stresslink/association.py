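"""Correlation machinery: phenotype-vs-lifespan regression across strains,
per-gene expression-phenotype correlation, and multi-stressor membership.

The strain is the unit of observation throughout: with ~10 strains each
regression has few degrees of freedom, so per-gene significance at raw
p < 0.05 is deliberately permissive (the default) and Benjamini-Hochberg
q-values are available for stricter recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class RegressionFit:
    """Ordinary least-squares simple linear regression summary."""

    phenotype: str
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def linear_fit(x, y, name: str = "") -> RegressionFit:
    """OLS fit of y on x; slope p-value from the t distribution (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    if np.ptp(y) == 0:
        return RegressionFit(name, 0.0, float(y[0]), 0.0, 1.0, len(x))
    res = stats.linregress(x, y)
    return RegressionFit(name, float(res.slope), float(res.intercept),
                         float(res.rvalue ** 2), float(res.pvalue), len(x))


def phenotype_lifespan_correlations(pheno: pd.DataFrame,
                                    lifespan_col: str = "lifespan_extension_pct",
                                    ) -> pd.DataFrame:
    """Regression of lifespan extension on every phenotype column.

    One fit per per-assay endpoint plus the combined score and the
    resistance count; phenotypes with < 3 complete pairs are skipped.
    """
    cols = [c for c in pheno.columns if c.endswith("_endpoint")]
    cols += [c for c in ("combined_score", "resistance_count")
             if c in pheno.columns]
    rows = []
    for c in cols:
        sub = pheno[[c, lifespan_col]].dropna()
        if len(sub) < 3:
            logger.warning("phenotype %r: <3 complete pairs, skipped", c)
            continue
        fit = linear_fit(sub[c], sub[lifespan_col], name=c)
        rows.append({"phenotype": c, "slope": fit.slope,
                     "intercept": fit.intercept, "r2": fit.r2,
                     "p_value": fit.p_value, "n": fit.n})
    cols = ["phenotype", "slope", "intercept", "r2", "p_value", "n"]
    return pd.DataFrame(rows, columns=cols).set_index("phenotype")


def expression_summaries(counts_norm: pd.DataFrame, metadata: pd.DataFrame,
                         mode: str = "fold_change",
                         control_of: dict[str, str] | None = None,
                         pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-strain expression summary matrix (genes x strains).

    mode 'log_mean': mean over replicates of log2(normalized count + 1).
    mode 'fold_change': that mean minus the matched control's mean
    (log2 fold-change vs control), so strains with different rearing
    controls are each referenced to their own control.
    """
    if mode not in ("log_mean", "fold_change"):
        raise ValueError(f"unknown summary mode {mode!r}")
    log = np.log2(counts_norm + pseudocount)
    strain_of = metadata["strain"]
    means = log.T.groupby(strain_of).mean().T  # genes x strains
    if mode == "log_mean":
        return means
    if control_of is None:
        raise ValueError("fold_change mode requires a control mapping")
    out = {}
    for s, ctrl in control_of.items():
        if s == ctrl:
            continue
        out[s] = means[s] - means[ctrl]
    return pd.DataFrame(out)


def gene_phenotype_correlation(summaries: pd.DataFrame,
                               phenotype: pd.Series,
                               method: str = "pearson",
                               alpha: float = 0.05,
                               use_fdr: bool = False,
                               phenotype_name: str = "phenotype",
                               ) -> pd.DataFrame:
    """Correlate each gene's expression summary with a strain phenotype.

    Returns a per-gene table (r, r2, p, q, direction, significant).  Genes
    with zero expression variance across strains are excluded with a
    warning.  Significance is raw p < alpha by default; BH q < alpha when
    ``use_fdr`` is set.
    """
    strains = [s for s in summaries.columns if s in phenotype.index]
    if len(strains) < 4:
        raise ValueError("need >= 4 strains with phenotype and expression")
    X = summaries[strains].to_numpy(dtype=float)
    y = phenotype.loc[strains].to_numpy(dtype=float)
    if method == "spearman":
        X = stats.rankdata(X, axis=1)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")

    keep = X.std(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%d genes with zero variance across strains excluded",
                       n_dropped)
    genes = summaries.index[keep]
    X = X[keep]
    n = len(strains)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=1) * (yc ** 2).sum())
    r = (Xc @ yc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    q = bh_adjust(p)
    sig = (q < alpha) if use_fdr else (p < alpha)
    return pd.DataFrame({
        "phenotype": phenotype_name,
        "r": r, "r2": r ** 2, "p": p, "q": q,
        "direction": np.where(r >= 0, "positive", "negative"),
        "significant": sig,
    }, index=genes).rename_axis("gene")


def significant_sets(corr: pd.DataFrame) -> tuple[set[str], set[str]]:
    """(positively, negatively) correlated significant gene sets."""
    sig = corr[corr["significant"]]
    pos = set(sig.index[sig["direction"] == "positive"])
    neg = set(sig.index[sig["direction"] == "negative"])
    return pos, neg


def multiplicity_counts(sets: dict[str, set[str]]) -> dict[int, int]:
    """Exact-k membership decomposition of several gene sets.

    Returns {k: number of genes in exactly k of the sets}; the counts sum
    to the size of the union.
    """
    tally: dict[str, int] = {}
    for members in sets.values():
        for g in members:
            tally[g] = tally.get(g, 0) + 1
    out: dict[int, int] = {}
    for k in tally.values():
        out[k] = out.get(k, 0) + 1
    return dict(sorted(out.items()))
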