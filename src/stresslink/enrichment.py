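"""Observed/expected gene-set overlap enrichment and generic ORA.

For two gene sets A and B drawn from a universe of N genes, the overlap
expected under random selection is |A|*|B|/N; the observed/expected ratio
(fold enrichment) is > 1 when the sets share more genes than chance, and
the upper-tail hypergeometric probability P(X >= k) gives the significance
of the observed overlap k.  Over-representation analysis (ORA) applies the
same one-sided test to every term of a GMT-style term map with
Benjamini-Hochberg correction across terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSet:
    name: str
    members: frozenset[str]
    source: str = ""

    def __init__(self, name: str, members, source: str = ""):
        self.name = name
        self.members = frozenset(members)
        self.source = source

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class OverlapResult:
    """Overlap of two gene sets within a finite universe.

    ``percent_overlap`` is 100*k/|A| with A the designated reference set
    (by convention the first argument of overlap_stats).
    """

    n_a: int
    n_b: int
    universe_size: int
    observed: int
    expected: float
    ratio: float
    p_value: float
    percent_overlap: float
    name_a: str = ""
    name_b: str = ""


def expected_overlap(n_a: int, n_b: int, n_universe: int) -> float:
    """Mean overlap of two random sets of sizes n_a, n_b from N genes."""
    if n_universe <= 0:
        raise ValueError("universe size must be positive")
    if not (0 <= n_a <= n_universe and 0 <= n_b <= n_universe):
        raise ValueError("set sizes must lie within [0, N]")
    return n_a * n_b / n_universe


def hypergeom_pvalue(k: int, n_universe: int, n_a: int, n_b: int) -> float:
    """Upper-tail P(X >= k) for the overlap of random sets of sizes
    n_a and n_b in a universe of n_universe genes.

    Computed in log space internally (scipy's survival function), stable
    for universes of tens of thousands of genes.  k beyond min(|A|, |B|)
    is an impossible event with probability 0.
    """
    if n_a > n_universe or n_b > n_universe:
        raise ValueError("set size exceeds universe size")
    if k < 0:
        raise ValueError("overlap count must be >= 0")
    if k > min(n_a, n_b):
        return 0.0
    return float(hypergeom.sf(k - 1, n_universe, n_a, n_b))


def overlap_stats(set_a: GeneSet, set_b: GeneSet, universe) -> OverlapResult:
    """Observed/expected overlap statistics for two sets in a universe."""
    universe = frozenset(universe)
    stray = (set_a.members | set_b.members) - universe
    if stray:
        listing = ", ".join(sorted(stray)[:10])
        raise ValueError(f"{len(stray)} members outside universe: {listing}")
    n = len(universe)
    k = len(set_a.members & set_b.members)
    exp = expected_overlap(len(set_a), len(set_b), n)
    ratio = k / exp if exp > 0 else float("nan")
    pct = 100.0 * k / len(set_a) if len(set_a) else float("nan")
    return OverlapResult(
        n_a=len(set_a), n_b=len(set_b), universe_size=n, observed=k,
        expected=exp, ratio=ratio,
        p_value=hypergeom_pvalue(k, n, len(set_a), len(set_b)),
        percent_overlap=pct, name_a=set_a.name, name_b=set_b.name)


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def pathway_target_enrichment(de_sets: dict[str, set[str]],
                              pathway_sets: dict[str, set[str]],
                              universe) -> pd.DataFrame:
    """O/E enrichment of each strain's DE genes in each pathway target set.

    ``de_sets`` maps strain -> differentially expressed genes of one
    direction of change; each is compared with every pathway's target set.
    Empty DE sets yield a flagged row with undefined ratio.
    """
    universe = frozenset(universe)
    rows = []
    for strain, de in de_sets.items():
        for pname, targets in pathway_sets.items():
            if len(de) == 0:
                rows.append({"strain": strain, "pathway": pname,
                             "observed": 0, "expected": 0.0,
                             "ratio": float("nan"), "p_value": float("nan"),
                             "stars": "", "flag": "empty DE set"})
                continue
            res = overlap_stats(GeneSet(strain, de),
                                GeneSet(pname, targets), universe)
            rows.append({"strain": strain, "pathway": pname,
                         "observed": res.observed, "expected": res.expected,
                         "ratio": res.ratio, "p_value": res.p_value,
                         "stars": _stars(res.p_value), "flag": ""})
    return pd.DataFrame(rows)


def ora(term_map: dict[str, set[str]], query: GeneSet | set,
        universe, fdr_method: str = "fdr_bh") -> pd.DataFrame:
    """Over-representation of a query gene list in each term's gene set.

    One-sided hypergeometric (equivalently one-sided Fisher) p per term,
    BH q across terms.  Returns a table sorted by p.
    """
    universe = frozenset(universe)
    qmembers = query.members if isinstance(query, GeneSet) else frozenset(query)
    if not qmembers <= universe:
        raise ValueError("query contains genes outside the universe")
    if not term_map:
        return pd.DataFrame(columns=["term", "size", "observed", "expected",
                                     "ratio", "p", "q"]).set_index("term")
    rows = []
    for term, members in term_map.items():
        members = frozenset(members) & universe
        k = len(members & qmembers)
        exp = expected_overlap(len(members), len(qmembers), len(universe))
        rows.append({
            "term": term, "size": len(members), "observed": k,
            "expected": exp,
            "ratio": k / exp if exp > 0 else float("nan"),
            "p": hypergeom_pvalue(k, len(universe), len(members),
                                  len(qmembers)),
        })
    out = pd.DataFrame(rows).set_index("term")
    if fdr_method != "fdr_bh":
        raise ValueError("only Benjamini-Hochberg ('fdr_bh') is supported")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
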