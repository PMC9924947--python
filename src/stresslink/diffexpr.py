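"""Count normalization and per-gene differential expression.

A deliberately simple DE stage: median-of-ratios size factors, a per-gene
linear model on log2(normalized count + 1) with an optional additive batch
covariate, and BH correction at a configurable FDR (default 0.01).  This
is not a negative-binomial GLM with shrinkage; externally computed DE
tables (e.g. from a dedicated count-model tool) can be imported through
``import_external_de`` and flow through the rest of the pipeline
unchanged.
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
class CountMatrix:
    """Gene x sample integer counts with per-sample metadata."""

    counts: pd.DataFrame     # genes x samples
    metadata: pd.DataFrame   # samples x (strain, batch, replicate)

    def __post_init__(self) -> None:
        c, m = self.counts, self.metadata
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ValueError("duplicate gene or sample ids")
        missing = set(c.columns) - set(m.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        for col in ("strain", "batch"):
            if col not in m.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        arr = c.to_numpy()
        if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be non-negative integers")
        self.metadata = m.loc[c.columns]

    def samples_of(self, strain: str) -> list[str]:
        return list(self.metadata.index[self.metadata["strain"] == strain])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one positive scalar per sample).

    For genes with nonzero counts in every sample, each sample's factor is
    the median ratio of its counts to the per-gene geometric mean.  If no
    gene is expressed everywhere, falls back to upper-quartile scaling.
    """
    arr = counts.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if allpos.sum() == 0:
        logger.warning("no gene expressed in all samples; "
                       "using upper-quartile normalization")
        uq = np.array([np.percentile(col[col > 0], 75) if (col > 0).any()
                       else 1.0 for col in arr.T])
        factors = uq / np.exp(np.mean(np.log(uq)))
    else:
        sub = arr[allpos]
        log_gm = np.mean(np.log(sub), axis=1, keepdims=True)
        ratios = np.log(sub) - log_gm
        factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(cm: CountMatrix) -> pd.DataFrame:
    """Counts divided by per-sample size factors."""
    return cm.counts / size_factors(cm.counts)


def expression_filter(cm: CountMatrix, min_mean: float = 1.0) -> list[str]:
    """Genes with mean normalized count >= min_mean in at least one strain.

    Defines the default analysis universe for overlap enrichment.
    """
    norm = normalize(cm)
    strain_means = norm.T.groupby(cm.metadata["strain"]).mean().T
    keep = (strain_means >= min_mean).any(axis=1)
    return list(norm.index[keep])


@dataclass
class DEResult:
    gene: str
    log2fc: float
    p: float
    q: float
    significant: bool


def de_test(cm: CountMatrix, strain: str, control: str,
            batch_covariate: bool = True, fdr: float = 0.01,
            pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene differential expression of ``strain`` vs ``control``.

    Tests log2(normalized count + pseudocount).  With the batch covariate
    an additive two-factor linear model (strain + batch) is fitted per
    gene; without it a Welch t-test compares the two arms.  BH-adjusted q
    across genes; 'significant' means q < fdr.  Returns a table with
    columns (log2fc, p, q, significant) indexed by gene.
    """
    sa, sc = cm.samples_of(strain), cm.samples_of(control)
    if len(sa) < 2 or len(sc) < 2:
        raise ValueError("need >= 2 replicates per arm")
    norm = normalize(CountMatrix(cm.counts[sa + sc],
                                 cm.metadata.loc[sa + sc]))
    y = np.log2(norm.to_numpy(dtype=float) + pseudocount)  # genes x samples
    is_mut = np.array([s in set(sa) for s in norm.columns], dtype=float)

    batches = cm.metadata.loc[list(norm.columns), "batch"]
    use_batch = batch_covariate and batches.nunique() > 1
    if use_batch:
        dummies = pd.get_dummies(batches, drop_first=True).to_numpy(float)
        X = np.column_stack([np.ones_like(is_mut), is_mut, dummies])
        n, p_par = X.shape
        XtX_inv = np.linalg.pinv(X.T @ X)
        beta = y @ X @ XtX_inv.T                    # genes x p
        resid = y - beta @ X.T
        df = n - np.linalg.matrix_rank(X)
        sigma2 = (resid ** 2).sum(axis=1) / df
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        lfc = beta[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df=df)
    else:
        ya, yc = y[:, is_mut == 1], y[:, is_mut == 0]
        lfc = ya.mean(axis=1) - yc.mean(axis=1)
        tstat, pvals = stats.ttest_ind(ya, yc, axis=1, equal_var=False)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
    q = bh_adjust(pvals)
    return pd.DataFrame({
        "log2fc": lfc, "p": pvals, "q": q, "significant": q < fdr,
    }, index=norm.index).rename_axis("gene")


def de_gene_sets(de: pd.DataFrame, fdr: float | None = None
                 ) -> tuple[set[str], set[str]]:
    """(upregulated, downregulated) significant genes, split by fc sign."""
    sig = de[de["q"] < fdr] if fdr is not None else de[de["significant"]]
    up = set(sig.index[sig["log2fc"] > 0])
    down = set(sig.index[sig["log2fc"] < 0])
    return up, down


def import_external_de(path, column_map: dict[str, str] | None = None,
                       fdr: float = 0.01, sep: str = "\t") -> pd.DataFrame:
    """Load an externally computed DE table (e.g. from a count-model tool).

    ``column_map`` maps the table's column names onto {'gene', 'log2fc',
    'p', 'q'}; 'q' is optional and recomputed by BH from 'p' if absent.
    Malformed numeric rows are reported with their row numbers.
    """
    tab = pd.read_csv(path, sep=sep)
    colmap = {v: k for k, v in (column_map or {}).items()}
    tab = tab.rename(columns=colmap)
    required = {"gene", "log2fc"}
    missing = required - set(tab.columns)
    if missing or not ({"p", "q"} & set(tab.columns)):
        need = sorted(missing | ({"p or q"} if not
                                 ({"p", "q"} & set(tab.columns)) else set()))
        raise ValueError(f"DE table missing columns: {need}")
    bad_rows = []
    for col in [c for c in ("log2fc", "p", "q") if c in tab.columns]:
        coerced = pd.to_numeric(tab[col], errors="coerce")
        bad_rows += list(tab.index[coerced.isna() & tab[col].notna()])
        tab[col] = coerced
    if bad_rows:
        raise ValueError(
            f"malformed numeric values in rows {sorted(set(bad_rows))[:10]}")
    tab = tab.set_index("gene")
    if "p" not in tab.columns:
        tab["p"] = tab["q"]
    if "q" not in tab.columns:
        tab["q"] = bh_adjust(tab["p"].to_numpy())
    tab["significant"] = tab["q"] < fdr
    return tab[["log2fc", "p", "q", "significant"]]
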