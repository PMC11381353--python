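"""RPM quantification, family/reference-gene normalization, and two-sample tests.

Reads per million (RPM) is the unit throughout: counts scaled by 1e6 over the
library total.  Cross-stage comparisons divide by a normalizer measured in the
same library — summed RPM of the mir-35 family (mir-35..mir-42) for small-RNA
classes, or the rpl-32 RPM for mRNA — making the summary a dimensionless ratio
that is invariant to sequencing depth and, for the family normalizer, robust
to stage-dependent differences in gonad-derived RNA content.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import CountMatrix


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizerSpec:
    """How a class-level summary is scaled within each sample.

    kind 'feature_family' divides by the summed RPM of ``member_ids`` (the
    mir-35 family use case); 'reference_gene' by a single gene's RPM (rpl-32);
    'none' is the identity.
    """

    kind: str = "none"
    member_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in ("none", "feature_family", "reference_gene"):
            raise ValueError(f"unknown normalizer kind {self.kind!r}")
        if self.kind != "none" and not self.member_ids:
            raise ValueError(f"normalizer kind {self.kind!r} requires member_ids")
        if self.kind == "reference_gene" and len(self.member_ids) != 1:
            raise ValueError("reference_gene normalizer takes exactly one gene id")


MIR35_FAMILY = frozenset(f"mir-{i}" for i in range(35, 43))


def rpm_normalize(counts: CountMatrix) -> CountMatrix:
    """Scale each column to reads per million of its library total."""
    if np.any(counts.library_totals <= 0):
        raise ValueError("library totals must be > 0 for RPM normalization")
    rpm = counts.counts * 1e6 / counts.library_totals[np.newaxis, :]
    return CountMatrix(list(counts.gene_ids), list(counts.sample_ids), rpm, counts.library_totals)


def normalizer_values(values: CountMatrix, spec: NormalizerSpec) -> np.ndarray:
    """Per-sample normalizer level: summed value of the member genes."""
    if spec.kind == "none":
        return np.ones(len(values.sample_ids))
    missing = spec.member_ids - set(values.gene_ids)
    if missing:
        raise ValueError(f"normalizer genes absent from matrix: {sorted(missing)}")
    idx = [values.gene_ids.index(g) for g in sorted(spec.member_ids)]
    denom = values.counts[idx, :].sum(axis=0)
    zero = np.flatnonzero(denom == 0)
    if zero.size:
        raise ValueError(
            f"normalizer level is zero in sample(s) {[values.sample_ids[i] for i in zero]}"
        )
    return denom


def normalize_by(values: CountMatrix, spec: NormalizerSpec) -> CountMatrix:
    """Divide every gene's per-sample value by the normalizer level."""
    denom = normalizer_values(values, spec)
    return CountMatrix(
        list(values.gene_ids),
        list(values.sample_ids),
        values.counts / denom[np.newaxis, :],
        values.library_totals,
    )


def class_sum(
    values: CountMatrix, gene_set: set[str], allow_missing: bool = True
) -> dict[str, float]:
    """Per-sample sum of values over a gene set.

    Genes absent from the matrix contribute 0 when ``allow_missing``;
    otherwise they are an error (listing the missing IDs).
    """
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    present = [g for g in values.gene_ids if g in gene_set]
    missing = gene_set - set(present)
    if missing and not allow_missing:
        raise ValueError(f"genes absent from matrix: {sorted(missing)}")
    idx = [values.gene_ids.index(g) for g in present]
    sums = values.counts[idx, :].sum(axis=0) if idx else np.zeros(len(values.sample_ids))
    return {s: float(v) for s, v in zip(values.sample_ids, sums)}


@dataclass
class NormalizedClassSummary:
    """One class-level value per sample: class sum / normalizer level."""

    class_name: str
    sample_id: str
    value: float
    normalizer: NormalizerSpec

    def __post_init__(self) -> None:
        if not (self.value >= 0 and math.isfinite(self.value)):
            raise ValueError(f"summary value must be finite and >= 0, got {self.value}")


def summarize_class(
    rpm: CountMatrix,
    gene_set: set[str],
    class_name: str,
    spec: NormalizerSpec = NormalizerSpec(),
    allow_missing: bool = True,
) -> list[NormalizedClassSummary]:
    """Class-level normalized summary per sample (one dot per replicate)."""
    denom = normalizer_values(rpm, spec)
    sums = class_sum(rpm, gene_set, allow_missing)
    return [
        NormalizedClassSummary(class_name, s, sums[s] / denom[j], spec)
        for j, s in enumerate(rpm.sample_ids)
    ]


# ---------------------------------------------------------------------------
# Two-sample tests
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    test_name: str
    tails: str
    statistic: float
    p: float
    n1: int
    n2: int
    df: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value out of range: {self.p}")


def _wilcoxon_exact_p(a: np.ndarray, b: np.ndarray, tails: str, direction: str) -> tuple[float, float]:
    """Exact rank-sum p by full enumeration of rank assignments.

    Uses midranks for ties.  Two-sided p sums the null probability of every
    assignment whose rank sum is at least as extreme (|W - E[W]| >= observed)
    as the data; one-sided sums the relevant tail.  Feasible for n1+n2 <= 10
    (at most C(10,5) = 252 assignments).
    """
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[:n1].sum())
    mu = n1 * (n1 + n2 + 1) / 2.0
    total = math.comb(n1 + n2, n1)
    n_ge = n_le = n_extreme = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        w = float(ranks[list(combo)].sum())
        if w >= w_obs - 1e-12:
            n_ge += 1
        if w <= w_obs + 1e-12:
            n_le += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            n_extreme += 1
    if tails == "two":
        p = n_extreme / total
    else:
        # group a greater -> large W
        p = (n_ge if direction == "a_greater" else n_le) / total
    return w_obs, min(p, 1.0)


def _wilcoxon_normal_p(a: np.ndarray, b: np.ndarray, tails: str, direction: str) -> tuple[float, float]:
    """Normal approximation with tie correction and continuity correction."""
    n1, n2 = len(a), len(b)
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    sd = math.sqrt(var)
    if tails == "two":
        z = (abs(w - mu) - 0.5) / sd
        p = 2 * stats.norm.sf(max(z, 0.0))
    elif direction == "a_greater":
        z = (w - mu - 0.5) / sd
        p = stats.norm.sf(z)
    else:
        z = (w - mu + 0.5) / sd
        p = stats.norm.cdf(z)
    return w, float(min(p, 1.0))


def two_sample_test(
    a,
    b,
    test: str = "welch_t",
    tails: str = "two",
    direction: str | None = None,
) -> TestResult:
    """Two-sample test as used for replicate-level bar-graph comparisons.

    ``test`` is one of 'welch_t' (unequal-variance t, Welch-Satterthwaite df),
    'student_t' (pooled variance) or 'wilcoxon_ranksum' (exact enumeration for
    n1+n2 <= 10, else normal approximation with tie and continuity
    corrections).  One-tailed tests need ``direction`` ('a_less'/'a_greater').
    Zero-variance degenerate inputs: equal means -> p=1, statistic 0; unequal
    means -> p=0, flagged degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    if tails == "one":
        if direction not in ("a_less", "a_greater"):
            raise ValueError("one-tailed test requires direction 'a_less' or 'a_greater'")
    n1, n2 = len(a), len(b)
    if test in ("welch_t", "student_t"):
        if n1 < 2 or n2 < 2:
            raise ValueError("t-tests require at least 2 values per group")
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            if a.mean() == b.mean():
                return TestResult(test, tails, 0.0, 1.0, n1, n2, df=float(n1 + n2 - 2))
            return TestResult(
                test, tails, math.copysign(math.inf, a.mean() - b.mean()),
                0.0, n1, n2, df=float(n1 + n2 - 2), degenerate=True,
            )
        equal_var = test == "student_t"
        alternative = "two-sided"
        if tails == "one":
            alternative = "less" if direction == "a_less" else "greater"
        res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
        df = float(res.df)
        return TestResult(test, tails, float(res.statistic), float(res.pvalue), n1, n2, df=df)
    if test == "wilcoxon_ranksum":
        if n1 < 1 or n2 < 1:
            raise ValueError("rank-sum test requires at least 1 value per group")
        direction = direction or "a_greater"
        if n1 + n2 <= 10:
            w, p = _wilcoxon_exact_p(a, b, tails, direction)
        else:
            w, p = _wilcoxon_normal_p(a, b, tails, direction)
        return TestResult(test, tails, w, p, n1, n2)
    raise ValueError(f"unknown test {test!r}")
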