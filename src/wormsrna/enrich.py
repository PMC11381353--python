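"""Gene-class enrichment of DE sets and class-level log2FC distributions.

Enrichment of a gene class within a DE set is tested with the two-tailed
Fisher exact test on the 2x2 table (overlap, rest of the DE set, rest of the
class, everything else), where the universe defaults to the genes tested in
the corresponding comparison.  The two-tailed p follows the point-probability
rule: the sum of the probabilities of all tables at most as probable as the
observed one.  The effect is summarized as log2((k/n)/(K/N)); an empty
overlap yields -infinity, rendered as the sentinel "-INF" in text output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .de import DEResult
from .quant import TestResult, two_sample_test


@dataclass
class EnrichmentResult:
    set_name: str
    class_name: str
    k: int            # overlap
    n: int            # DE-set size (within universe)
    K: int            # class size within universe
    N: int            # universe size
    odds_ratio: float
    p_two_tailed: float
    log2_enrichment: float
    fraction_of_set: float
    fraction_of_class: float

    def render_log2_enrichment(self) -> str:
        return "-INF" if math.isinf(self.log2_enrichment) else f"{self.log2_enrichment:.4f}"


def fisher_enrichment(
    de_set: set[str],
    class_set: set[str],
    universe: set[str],
    set_name: str = "de_set",
    class_name: str = "class",
) -> EnrichmentResult:
    """Two-tailed Fisher exact enrichment of ``class_set`` in ``de_set``.

    ``de_set`` must be a subset of ``universe``; class membership is
    intersected with the universe before counting.
    """
    if not universe:
        raise ValueError("universe is empty")
    if not de_set:
        raise ValueError("de_set is empty")
    if not de_set <= universe:
        raise ValueError("de_set must be a subset of the universe")
    cls = class_set & universe
    k = len(de_set & cls)
    n = len(de_set)
    K = len(cls)
    N = len(universe)
    table = [[k, n - k], [K - k, N - n - K + k]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    if k == 0:
        log2_enr = float("-inf")
    elif K == 0:
        raise ValueError("class has members in the DE set but none in the universe")
    else:
        log2_enr = math.log2((k / n) / (K / N))
    return EnrichmentResult(
        set_name, class_name, k, n, K, N,
        float(odds), float(p), log2_enr,
        fraction_of_set=k / n,
        fraction_of_class=k / K if K else float("nan"),
    )


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular export with the literal "-INF" sentinel for empty overlaps."""
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "class_name": [r.class_name for r in results],
            "k": [r.k for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p_two_tailed": [r.p_two_tailed for r in results],
            "log2_enrichment": [r.render_log2_enrichment() for r in results],
            "fraction_of_set": [r.fraction_of_set for r in results],
            "fraction_of_class": [r.fraction_of_class for r in results],
        }
    )


def enrichment_json(r: EnrichmentResult) -> dict:
    """JSON form: -infinity exported as null plus a flag."""
    inf = math.isinf(r.log2_enrichment)
    return {
        "set_name": r.set_name,
        "class_name": r.class_name,
        "k": r.k, "n": r.n, "K": r.K, "N": r.N,
        "odds_ratio": r.odds_ratio if math.isfinite(r.odds_ratio) else None,
        "p_two_tailed": r.p_two_tailed,
        "log2_enrichment": None if inf else r.log2_enrichment,
        "log2_enrichment_is_neg_inf": inf,
        "fraction_of_set": r.fraction_of_set,
        "fraction_of_class": r.fraction_of_class,
    }


@dataclass
class ClassLfcDistribution:
    """Per-gene log2FC values of one gene class in one comparison."""

    class_name: str
    comparison_id: str
    values: list[float]
    warning: str | None = None


def class_lfc_distribution(
    results: list[DEResult], class_set: set[str], class_name: str = "class"
) -> ClassLfcDistribution:
    """log2FC of tested genes in the class, ordered by gene_id."""
    by_gene = {
        r.gene_id: r.log2fc for r in results if not math.isnan(r.log2fc)
    }
    comparison = results[0].comparison_id if results else ""
    members = sorted(set(class_set) & set(by_gene))
    values = [by_gene[g] for g in members]
    warning = None if values else "class has no tested genes in this comparison"
    return ClassLfcDistribution(class_name, comparison, values, warning)


def compare_distributions(a: ClassLfcDistribution, b: ClassLfcDistribution) -> TestResult:
    """Two-sided Wilcoxon rank-sum between two class log2FC distributions."""
    if not a.values or not b.values:
        raise ValueError("cannot compare an empty log2FC distribution")
    return two_sample_test(a.values, b.values, test="wilcoxon_ranksum", tails="two")


def adjust_pvalues(ps, method: str = "BH") -> list[float]:
    """Multiple-comparison adjustment: BH step-up, Holm step-down, Bonferroni."""
    ps = list(ps)
    if not ps:
        return []
    arr = np.asarray(ps, dtype=float)
    if np.any((arr < 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "holm": "holm", "bonferroni": "bonferroni"}.get(method.lower())
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    _, adj, _, _ = multipletests(arr, method=key)
    return [float(x) for x in adj]
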