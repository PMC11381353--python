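"""Negative-binomial differential expression and exclusive-set logic.

Two-group comparisons over a count matrix:

1. library scaling by median-of-ratios size factors;
2. per-gene NB dispersion by method-of-moments on normalized counts, shrunk
   on the log scale toward a fitted mean-dispersion trend a1/mean + a0, with
   shrinkage weight set by the residual degrees of freedom (few replicates ->
   strong shrinkage toward the trend);
3. Wald test of the log2 fold change, with the standard error taken from the
   NB log-link information (sum of weights mu/(1 + alpha*mu) per group);
4. Benjamini-Hochberg adjustment over all genes with positive base mean.

Up/down calls use strict inequalities on |log2FC| (> 1 / < -1 by default)
and an inclusive adjusted-p cutoff (<= 0.05).  The "exclusive" sets keep the
genes called in the combined genotype-x-temperature contrast and drop any
gene called, in either direction, in a single-factor contrast.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, SampleDesign

MIN_DISPERSION = 1e-8


@dataclass(frozen=True)
class Thresholds:
    """DE call cutoffs: strict |log2FC| bounds, inclusive adjusted-p level."""

    lfc_up: float = 1.0
    lfc_down: float = -1.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (self.lfc_down < 0 < self.lfc_up):
            raise ValueError("require lfc_down < 0 < lfc_up")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class DEResult:
    gene_id: str
    base_mean: float
    log2fc: float
    p: float
    p_adj: float
    comparison_id: str = ""


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios library scaling factors.

    Per gene with nonzero counts in every sample, compute the ratio of each
    sample's count to the gene's geometric mean; the factor is the per-sample
    median of those ratios.
    """
    mat = counts.counts
    all_nonzero = np.all(mat > 0, axis=1)
    if not np.any(all_nonzero):
        raise ValueError("no gene has nonzero counts in all samples; cannot estimate size factors")
    sub = mat[all_nonzero, :]
    log_geo_mean = np.mean(np.log(sub), axis=1)
    ratios = np.exp(np.log(sub) - log_geo_mean[:, None])
    factors = np.median(ratios, axis=0)
    if np.any(factors <= 0):
        raise ValueError("non-positive size factor")
    return factors


def _fit_dispersion_trend(means: np.ndarray, disps: np.ndarray) -> tuple[float, float]:
    """Fit disp = a1/mean + a0 by iteratively trimmed least squares.

    Genes whose moment dispersion is more than 16-fold off the current trend
    are dropped and the fit repeated, which keeps a handful of outlier genes
    from dragging the trend.  Coefficients are clamped non-negative with a
    floor on a0.
    """
    keep = np.ones(len(means), dtype=bool)
    a1, a0 = 0.0, max(float(np.median(disps)), MIN_DISPERSION)
    for _ in range(6):
        x = 1.0 / means[keep]
        y = disps[keep]
        design = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        a1, a0 = max(float(coef[0]), 0.0), max(float(coef[1]), MIN_DISPERSION)
        trend = a1 / means + a0
        new_keep = (disps < 16 * trend) & (disps > trend / 16)
        if not new_keep.any() or new_keep.sum() < 10:
            break
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
    return a1, a0


def _estimate_dispersions(
    norm: np.ndarray, groups: list[np.ndarray], prior_df: float = 6.0
) -> np.ndarray:
    """Per-gene NB dispersion: moments within groups, shrunk toward the trend.

    The moment estimate uses within-group variances pooled over both groups
    (so planted mean differences do not inflate dispersion).  Shrinkage is a
    log-scale weighted average of the gene estimate (weight = residual df)
    and the fitted trend (weight = prior_df): with n=2 per group the residual
    df is smallest and the shrinkage toward the trend is maximal.
    """
    n_samples = sum(len(g) for g in groups)
    resid_df = n_samples - len(groups)
    means = np.zeros(norm.shape[0])
    pooled_var = np.zeros(norm.shape[0])
    for idx in groups:
        gm = norm[:, idx].mean(axis=1)
        gv = norm[:, idx].var(axis=1, ddof=1)
        means += gm * len(idx)
        pooled_var += gv * (len(idx) - 1)
    means /= n_samples
    pooled_var /= max(resid_df, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = (pooled_var - means) / means**2
    informative = np.isfinite(mom) & (mom > 0)
    usable = means > 0
    fit_mask = informative & usable
    if fit_mask.sum() >= 10:
        a1, a0 = _fit_dispersion_trend(means[fit_mask], np.clip(mom[fit_mask], None, 10.0))
    else:
        a1, a0 = 0.0, max(
            float(np.median(mom[fit_mask])) if fit_mask.any() else 0.1, MIN_DISPERSION
        )
    trend = np.where(usable, a1 / np.maximum(means, 1e-12) + a0, a0)
    # A non-positive moment estimate carries no dispersion information
    # (sampled variance below the Poisson floor): such genes take the trend.
    mom = np.where(informative, np.clip(mom, MIN_DISPERSION, 10.0), trend)
    w_gene = resid_df
    log_shrunk = (w_gene * np.log(mom) + prior_df * np.log(trend)) / (w_gene + prior_df)
    return np.clip(np.exp(log_shrunk), MIN_DISPERSION, None)


def benjamini_hochberg(ps: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values, input order preserved."""
    ps = np.asarray(ps, dtype=float)
    m = len(ps)
    if m == 0:
        return ps.copy()
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def nb_differential(
    counts: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    thresholds: Thresholds = Thresholds(),
    comparison_id: str = "",
) -> list[DEResult]:
    """Wald test of log2(B/A) per gene under an NB model.

    ``group_a``/``group_b`` are sample ids in ``counts``.  Genes with zero
    counts in every selected sample are excluded from testing and reported
    with NaN statistics.  Returns one DEResult per gene, input order.
    """
    for s in group_a + group_b:
        if s not in counts.sample_ids:
            raise ValueError(f"sample {s!r} not in count matrix")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    if set(group_a) & set(group_b):
        raise ValueError("groups share samples")
    sub = counts.subset_samples(list(group_a) + list(group_b))
    idx_a = np.arange(len(group_a))
    idx_b = np.arange(len(group_a), len(group_a) + len(group_b))
    sf = size_factors(sub)
    norm = sub.counts / sf[None, :]
    base_mean = norm.mean(axis=1)
    tested = base_mean > 0

    alpha = _estimate_dispersions(norm, [idx_a, idx_b])
    mean_a = norm[:, idx_a].mean(axis=1)
    mean_b = norm[:, idx_b].mean(axis=1)
    # Fitted group means; a zero group mean gets a half-read-per-library floor
    # so the log-scale estimate stays finite (documented policy, not a
    # raw-ratio pseudocount on both sides).
    floor = 0.5 / np.array([len(idx_a)]), 0.5 / np.array([len(idx_b)])
    qa = np.where(mean_a > 0, mean_a, floor[0])
    qb = np.where(mean_b > 0, mean_b, floor[1])
    log2fc = np.log2(qb) - np.log2(qa)

    # Wald SE from NB log-link information: weight per sample mu/(1+alpha*mu)
    # with mu the fitted (scaled) mean for that sample's group.
    se = np.full(len(base_mean), np.nan)
    z = np.full(len(base_mean), np.nan)
    pvals = np.full(len(base_mean), np.nan)
    mu_a = qa[:, None] * sf[None, idx_a]
    mu_b = qb[:, None] * sf[None, idx_b]
    w_a = (mu_a / (1.0 + alpha[:, None] * mu_a)).sum(axis=1)
    w_b = (mu_b / (1.0 + alpha[:, None] * mu_b)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_ln = np.sqrt(1.0 / w_a + 1.0 / w_b)
    se = se_ln / math.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.clip(pvals, 0.0, 1.0)

    p_adj = np.full(len(base_mean), np.nan)
    p_adj[tested] = benjamini_hochberg(pvals[tested])

    n_excluded = int((~tested).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} all-zero gene(s) excluded from testing", stacklevel=2
        )
    if len(group_a) == 2 and len(group_b) == 2:
        warnings.warn(
            "n=2 per group: dispersion shrinkage toward the trend is maximal "
            "and power is limited",
            stacklevel=2,
        )
    results = []
    for i, g in enumerate(sub.gene_ids):
        if tested[i]:
            results.append(
                DEResult(g, float(base_mean[i]), float(log2fc[i]), float(pvals[i]),
                         float(p_adj[i]), comparison_id)
            )
        else:
            results.append(DEResult(g, 0.0, float("nan"), float("nan"), float("nan"), comparison_id))
    return results


def call_de(results: list[DEResult], thresholds: Thresholds = Thresholds()) -> tuple[set[str], set[str]]:
    """Threshold calls: up = lfc > lfc_up, down = lfc < lfc_down, p_adj <= alpha."""
    up, down = set(), set()
    for r in results:
        if math.isnan(r.p_adj):
            continue
        if r.p_adj <= thresholds.alpha:
            if r.log2fc > thresholds.lfc_up:
                up.add(r.gene_id)
            elif r.log2fc < thresholds.lfc_down:
                down.add(r.gene_id)
    return up, down


@dataclass
class ExclusiveSets:
    """Genes DE only in the combined contrast.

    A gene called in either direction in the heat-only or mutation-only
    contrast is excluded from both exclusive sets (direction-blind exclusion).
    """

    up_exclusive: set[str]
    down_exclusive: set[str]
    thresholds: Thresholds = field(default_factory=Thresholds)
    contrasts: tuple[str, ...] = ("heat_only", "mutation_only", "combined")


def exclusive_sets(
    heat_only: tuple[set[str], set[str]],
    mutation_only: tuple[set[str], set[str]],
    combined: tuple[set[str], set[str]],
    thresholds: Thresholds = Thresholds(),
) -> ExclusiveSets:
    """Set difference of the combined calls against both single-factor calls."""
    single = set().union(*heat_only, *mutation_only)
    return ExclusiveSets(
        up_exclusive=combined[0] - single,
        down_exclusive=combined[1] - single,
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# Contrast plumbing over a sample design
# ---------------------------------------------------------------------------

CONTRASTS: dict[str, tuple[tuple[str, int], tuple[str, int]]] = {
    # name -> (group A (genotype, temperature), group B)
    "heat_only": (("WT", 20), ("WT", 25)),
    "mutation_only": (("WT", 20), ("mut16", 20)),
    "combined": (("mut16", 20), ("mut16", 25)),
    # alternative definitions of the combined contrast, selectable in config
    "combined_vs_wt20": (("WT", 20), ("mut16", 25)),
    "combined_vs_wt25": (("WT", 25), ("mut16", 25)),
}


def contrast_groups(
    designs: list[SampleDesign],
    contrast: str,
    stage: str = "L4",
    assay: str = "mRNA",
) -> tuple[list[str], list[str]]:
    """Sample ids for groups A and B of a named contrast at one stage."""
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; known: {sorted(CONTRASTS)}")
    (ga, ta), (gb, tb) = CONTRASTS[contrast]
    a = [d.sample_id for d in designs
         if d.genotype == ga and d.temperature == ta and d.stage == stage and d.assay == assay]
    b = [d.sample_id for d in designs
         if d.genotype == gb and d.temperature == tb and d.stage == stage and d.assay == assay]
    if not a or not b:
        raise ValueError(f"contrast {contrast!r}: empty group at stage {stage}, assay {assay}")
    return a, b


def run_contrasts(
    counts: CountMatrix,
    designs: list[SampleDesign],
    thresholds: Thresholds = Thresholds(),
    stage: str = "L4",
    assay: str = "mRNA",
    combined: str = "combined",
) -> dict[str, list[DEResult]]:
    """The three-contrast analysis (heat-only, mutation-only, combined)."""
    out: dict[str, list[DEResult]] = {}
    for name in ("heat_only", "mutation_only", combined):
        a, b = contrast_groups(designs, name, stage, assay)
        key = "combined" if name == combined else name
        out[key] = nb_differential(counts, a, b, thresholds, comparison_id=key)
    return out


def results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    """DE table in the common column convention."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "baseMean": [r.base_mean for r in results],
            "log2FoldChange": [r.log2fc for r in results],
            "pvalue": [r.p for r in results],
            "padj": [r.p_adj for r in results],
        }
    )
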