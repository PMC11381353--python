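"""Seeded synthetic mRNA counts and small-RNA read tables with planted effects.

The generator emulates the structure of a 2 genotype (WT, mut16) x
2 temperature (20, 25 C) x 2 stage (L4, adult) bulk RNA-seq study of the
C. elegans germline:

* mRNA counts are negative-binomial around log-normal baselines, with
  class-wise planted log2 fold changes (by default the sperm-gene switch:
  down in mutant L4 at 25 C, up in mutant adult at 25 C) and a developmental
  baseline pattern (sperm genes high at L4, oogenesis genes high in adults);
* small-RNA reads are drawn per gene from class-specific 22G and 26G pools
  (length peaked at 22/26 nt, 5'G bias, antisense bias) plus a uniform
  background pool, thinned by depletion factors for 22G pools in the mutant
  (mutator-dependent classes only; CSR-1-class 22Gs are instead heat
  sensitive) and for 26G pools only under mutant x heat;
* the mir-35 family (8 members, equal abundance) and rpl-32 are
  condition-independent up to sampling noise, providing the cross-stage
  normalizers.

Read tables are emitted in aggregated form (one row per distinct
(gene, length, 5' base, orientation) with the multiplicity as the weight),
which downstream weight-additive tallies treat identically to per-read rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .de import ExclusiveSets
from .io import CountMatrix, GeneSetCollection, ReadAssignmentTable, SampleDesign

LENGTH_WINDOW = (18, 30)
BASES = ("A", "C", "G", "T")


def default_class_sizes() -> dict[str, int]:
    # Scaled-down (~1/10) versions of the study's curated list sizes.
    return {
        "sperm": 400,
        "oogenesis": 250,
        "sex_neutral": 200,
        "alg34_neg": 60,
        "alg34_pos": 60,
        "alg34_other": 100,
        "csr1": 360,
        "ergo1": 30,
    }


def default_class_overlaps() -> dict[tuple[str, str], int]:
    # ALG-3/4 target groups sit inside the sperm-enriched class; CSR-1
    # targets overlap the ALG-3/4 groups considerably, as in the study.
    # An overlap request names additional genes drawn from the parent class;
    # nested classes can push a realized pairwise overlap above the request.
    return {
        ("alg34_neg", "sperm"): 60,
        ("alg34_pos", "sperm"): 60,
        ("alg34_other", "sperm"): 100,
        ("csr1", "alg34_other"): 80,
        ("csr1", "alg34_neg"): 30,
        ("csr1", "alg34_pos"): 30,
        ("csr1", "sperm"): 100,  # beyond the ALG-3/4 overlap already inside sperm
        ("ergo1", "sperm"): 0,
    }


def default_effect_matrix() -> dict[tuple[str, str, int, str], float]:
    """Planted log2FC per (class, genotype, temperature, stage) vs same-stage WT/20."""
    return {
        ("sperm", "mut16", 25, "L4"): -1.5,
        ("sperm", "mut16", 25, "adult"): +2.0,
    }


@dataclass(frozen=True)
class SrnaClassSpec:
    """Expected small-RNA reads per gene per library for one gene class."""

    reads_22g: float
    reads_26g: float
    mutator_dependent: bool = True


def default_srna_spec() -> dict[str, SrnaClassSpec]:
    return {
        "sperm": SrnaClassSpec(40.0, 10.0, True),
        "oogenesis": SrnaClassSpec(40.0, 10.0, True),
        "sex_neutral": SrnaClassSpec(20.0, 4.0, True),
        "csr1": SrnaClassSpec(50.0, 2.0, False),
        "ergo1": SrnaClassSpec(20.0, 20.0, True),
    }


@dataclass(frozen=True)
class DepletionSpec:
    """Multiplicative thinning of small-RNA pools in the mutant.

    22G pools of mutator-dependent classes are thinned by ``d22_mut16`` in the
    mutant at either temperature, with the additional ``d22_heat_extra``
    multiplier at 25 C; 26G pools are thinned by ``d26_mut16_heat`` only in
    the mutant at 25 C.  CSR-1-class 22Gs are instead thinned by
    ``d22_csr1_heat`` at 25 C in both genotypes (heat-sensitive, mutator-
    independent).
    """

    d22_mut16: float = 0.25
    d22_heat_extra: float = 0.5
    d26_mut16_heat: float = 0.2
    d22_csr1_heat: float = 0.5

    def __post_init__(self) -> None:
        for v in (self.d22_mut16, self.d22_heat_extra, self.d26_mut16_heat, self.d22_csr1_heat):
            if not (0 < v <= 1):
                raise ValueError("depletion factors must lie in (0, 1]")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 2000
    class_sizes: dict[str, int] = field(default_factory=default_class_sizes)
    class_overlaps: dict[tuple[str, str], int] = field(default_factory=default_class_overlaps)
    n_replicates_l4: int = 2
    n_replicates_adult: int = 3
    stages: tuple[str, ...] = ("L4", "adult")
    depth: float = 1.0e6                 # expected mRNA library reads
    mrna_mu_log_mean: float = math.log(100.0)
    mrna_mu_log_sd: float = 1.5
    # curated classes are defined by expression enrichment in the emulated
    # study, so their members are expressed: their baselines are drawn from
    # the same log-normal left-truncated at this expected count.
    class_min_expression: float = 50.0
    dispersion: float = 0.05
    effect_matrix: dict[tuple[str, str, int, str], float] = field(
        default_factory=default_effect_matrix
    )
    srna_spec: dict[str, SrnaClassSpec] = field(default_factory=default_srna_spec)
    srna_background_reads: float = 2.0   # per gene per library, any length
    peak_length_prob: float = 0.9
    firstG_prob: float = 0.85
    antisense_prob: float = 0.95
    depletion: DepletionSpec = field(default_factory=DepletionSpec)
    mir35_members: int = 8
    mir35_reads_per_member: float = 2000.0
    rpl32_mean: float = 5000.0
    alg34_gene_mean: float = 300.0
    # developmental baseline multipliers (log2, relative to L4) applied in
    # every genotype/temperature: sperm transcripts fall after L4, oogenesis
    # transcripts rise.
    stage_baseline_log2: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("sperm", "adult"): -2.5,
            ("oogenesis", "L4"): -2.5,
        }
    )


@dataclass
class SimTruth:
    """Ground truth for recovery scoring."""

    planted_up: dict[str, set[str]]
    planted_down: dict[str, set[str]]
    class_membership: GeneSetCollection
    depletion: DepletionSpec
    effect_matrix: dict[tuple[str, str, int, str], float]


CONTRAST_CONDITIONS = {
    "heat_only": (("WT", 20), ("WT", 25)),
    "mutation_only": (("WT", 20), ("mut16", 20)),
    "combined": (("mut16", 20), ("mut16", 25)),
}


def build_class_membership(cfg: SimConfig) -> tuple[list[str], GeneSetCollection]:
    """Deterministically assign genes to classes with the requested overlaps.

    Classes are placed in a fixed order; each class first takes its requested
    overlap from already-placed classes (preferring genes not in any other
    class, so realized pairwise overlaps match the request exactly under the
    defaults) and fills the rest from unassigned genes.  Infeasible requests
    raise before any sampling.
    """
    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    order = ["sperm", "oogenesis", "sex_neutral", "alg34_neg", "alg34_pos",
             "alg34_other", "csr1", "ergo1"]
    for name in cfg.class_sizes:
        if name not in order:
            order.append(name)
    sets: dict[str, set[str]] = {}
    assigned: set[str] = set()
    unused = list(gene_ids)
    unused_pos = 0
    for name in order:
        size = cfg.class_sizes.get(name, 0)
        if size <= 0:
            continue
        members: set[str] = set()
        for (a, b), k in cfg.class_overlaps.items():
            if a != name or b not in sets or k <= 0:
                continue
            other_members = set().union(*(m for n, m in sets.items() if n != b)) if len(sets) > 1 else set()
            preferred = sorted(sets[b] - members - other_members)
            fallback = sorted(sets[b] - members - set(preferred))
            pool = preferred + fallback
            if len(pool) < k:
                raise ValueError(
                    f"infeasible overlap: {name} requests {k} genes from {b} "
                    f"but only {len(pool)} are available"
                )
            members.update(pool[:k])
        if len(members) > size:
            raise ValueError(f"class {name}: overlaps ({len(members)}) exceed size {size}")
        need = size - len(members)
        fresh: list[str] = []
        while len(fresh) < need and unused_pos < len(unused):
            g = unused[unused_pos]
            unused_pos += 1
            if g not in assigned:
                fresh.append(g)
        if len(fresh) < need:
            raise ValueError(f"infeasible class sizes: ran out of genes placing {name!r}")
        members.update(fresh)
        sets[name] = members
        assigned |= members
    named = {
        "mir35_family": {f"mir-{35 + i}" for i in range(cfg.mir35_members)},
        "reference": {"rpl-32"},
        "alg34_genes": {"alg-3", "alg-4"},
    }
    sets.update(named)
    collection = GeneSetCollection(sets, sources={k: "simulated" for k in sets})
    return gene_ids, collection


def make_design(cfg: SimConfig) -> list[SampleDesign]:
    designs: list[SampleDesign] = []
    for stage in cfg.stages:
        n_rep = cfg.n_replicates_l4 if stage == "L4" else cfg.n_replicates_adult
        for genotype in ("WT", "mut16"):
            for temp in (20, 25):
                for assay in ("mRNA", "smallRNA"):
                    for rep in range(1, n_rep + 1):
                        sid = f"{genotype}_{temp}_{stage}_{assay}_r{rep}"
                        designs.append(SampleDesign(sid, genotype, temp, stage, assay, rep))
    return designs


def _gene_effect(
    gene_id: str,
    membership: GeneSetCollection,
    effect_matrix: dict[tuple[str, str, int, str], float],
    genotype: str,
    temp: int,
    stage: str,
) -> float:
    """Planted log2FC of a gene in one condition; additive over classes."""
    total = 0.0
    for (cls, g, t, s), lfc in effect_matrix.items():
        if g == genotype and t == temp and s == stage and cls in membership and gene_id in membership[cls]:
            total += lfc
    return total


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[CountMatrix, ReadAssignmentTable, list[SampleDesign], SimTruth]:
    """Generate the full synthetic study: mRNA counts, small-RNA reads, design, truth."""
    rng = np.random.default_rng(cfg.seed)
    gene_ids, membership = build_class_membership(cfg)
    designs = make_design(cfg)

    mrna_genes = gene_ids + ["alg-3", "alg-4", "rpl-32"]
    baseline = np.exp(rng.normal(cfg.mrna_mu_log_mean, cfg.mrna_mu_log_sd, size=cfg.n_genes))
    # left-truncated redraw for curated-class members (expressed by definition)
    curated = set().union(
        *(membership[c] for c in membership.names() if c not in ("mir35_family", "reference", "alg34_genes"))
    )
    if cfg.class_min_expression > 0 and curated:
        from scipy import stats as _stats

        z_lo = (math.log(cfg.class_min_expression) - cfg.mrna_mu_log_mean) / cfg.mrna_mu_log_sd
        idx = [i for i, g in enumerate(gene_ids) if g in curated]
        draws = _stats.truncnorm.rvs(z_lo, np.inf, size=len(idx), random_state=rng)
        baseline[idx] = np.exp(cfg.mrna_mu_log_mean + cfg.mrna_mu_log_sd * draws)
    baseline = np.concatenate([baseline, [cfg.alg34_gene_mean, cfg.alg34_gene_mean, cfg.rpl32_mean]])

    # per-gene stage multiplier from the developmental baseline pattern
    stage_mult = {stage: np.ones(len(mrna_genes)) for stage in cfg.stages}
    for (cls, stage), lfc in cfg.stage_baseline_log2.items():
        if stage not in stage_mult:
            continue
        members = membership[cls] if cls in membership else set()
        for i, g in enumerate(mrna_genes):
            if g in members or (cls == "sperm" and g in ("alg-3", "alg-4")):
                stage_mult[stage][i] *= 2.0**lfc

    # alg-3/alg-4 follow the sperm switch pattern (named-gene effects)
    def planted_lfc(gene_id: str, genotype: str, temp: int, stage: str) -> float:
        lfc = _gene_effect(gene_id, membership, cfg.effect_matrix, genotype, temp, stage)
        if gene_id in ("alg-3", "alg-4"):
            lfc += cfg.effect_matrix.get(("sperm", genotype, temp, stage), 0.0)
        return lfc

    mrna_designs = [d for d in designs if d.assay == "mRNA"]
    counts = np.zeros((len(mrna_genes), len(mrna_designs)))
    depth_factor = cfg.depth / float(baseline.sum())
    nb_n = 1.0 / cfg.dispersion
    for j, d in enumerate(mrna_designs):
        lfc = np.array([planted_lfc(g, d.genotype, d.temperature, d.stage) for g in mrna_genes])
        mu = baseline * stage_mult[d.stage] * (2.0**lfc) * depth_factor
        p = nb_n / (nb_n + mu)
        counts[:, j] = rng.negative_binomial(nb_n, p)
    mrna = CountMatrix(
        mrna_genes, [d.sample_id for d in mrna_designs], counts, counts.sum(axis=0).clip(min=1.0)
    )

    srna = _simulate_srna(cfg, rng, membership, designs)

    planted_up: dict[str, set[str]] = {}
    planted_down: dict[str, set[str]] = {}
    for stage in cfg.stages:
        for name, ((ga, ta), (gb, tb)) in CONTRAST_CONDITIONS.items():
            key = f"{name}:{stage}"
            up, down = set(), set()
            for g in mrna_genes:
                delta = planted_lfc(g, gb, tb, stage) - planted_lfc(g, ga, ta, stage)
                if delta > 0:
                    up.add(g)
                elif delta < 0:
                    down.add(g)
            planted_up[key] = up
            planted_down[key] = down
    truth = SimTruth(planted_up, planted_down, membership, cfg.depletion, dict(cfg.effect_matrix))
    return mrna, srna, designs, truth


def _length_background(rng: np.random.Generator, n: int) -> np.ndarray:
    lo, hi = LENGTH_WINDOW
    return rng.integers(lo, hi + 1, size=n)


def _simulate_pool(
    rng: np.random.Generator,
    n_reads: int,
    peak_length: int | None,
    cfg: SimConfig,
    sirna_like: bool,
) -> dict[tuple[int, str, str], int]:
    """Draw attribute combinations for one gene's read pool; aggregated counts."""
    if n_reads == 0:
        return {}
    if peak_length is not None:
        at_peak = rng.random(n_reads) < cfg.peak_length_prob
        lengths = np.where(at_peak, peak_length, _length_background(rng, n_reads))
    else:
        lengths = _length_background(rng, n_reads)
    if sirna_like:
        is_g = rng.random(n_reads) < cfg.firstG_prob
        other = rng.choice(["A", "C", "T"], size=n_reads)
        firsts = np.where(is_g, "G", other)
        anti = rng.random(n_reads) < cfg.antisense_prob
    else:
        firsts = rng.choice(list(BASES), size=n_reads)
        anti = rng.random(n_reads) < 0.5
    out: dict[tuple[int, str, str], int] = {}
    for length, first, a in zip(lengths, firsts, anti):
        key = (int(length), str(first), "antisense" if a else "sense")
        out[key] = out.get(key, 0) + 1
    return out


def _simulate_srna(
    cfg: SimConfig,
    rng: np.random.Generator,
    membership: GeneSetCollection,
    designs: list[SampleDesign],
) -> ReadAssignmentTable:
    dep = cfg.depletion
    class_genes = {
        name: sorted(membership[name]) for name in cfg.srna_spec if name in membership
    }
    all_sirna_genes = sorted(set().union(*class_genes.values())) if class_genes else []
    gene_rates: dict[str, tuple[float, float]] = {}
    for g in all_sirna_genes:
        r22 = sum(cfg.srna_spec[c].reads_22g for c, mem in class_genes.items() if g in membership[c])
        r26 = sum(cfg.srna_spec[c].reads_26g for c, mem in class_genes.items() if g in membership[c])
        gene_rates[g] = (r22, r26)
    # alg-3/alg-4 are themselves siRNA targets with the sperm-class profile
    for g in ("alg-3", "alg-4"):
        spec = cfg.srna_spec.get("sperm", SrnaClassSpec(40.0, 10.0, True))
        gene_rates[g] = (spec.reads_22g, spec.reads_26g)

    mutator_dep = {
        g
        for c, spec in cfg.srna_spec.items()
        if spec.mutator_dependent and c in membership
        for g in membership[c]
    } | {"alg-3", "alg-4"}
    csr1_only = (membership["csr1"] if "csr1" in membership else set()) - mutator_dep

    background_genes = sorted(
        set(f"g{i:05d}" for i in range(cfg.n_genes)) | set(gene_rates) | {"rpl-32"}
    )
    mir_genes = sorted(membership["mir35_family"]) if "mir35_family" in membership else []

    rows: list[tuple] = []
    for d in designs:
        if d.assay != "smallRNA":
            continue
        mut = d.genotype == "mut16"
        hot = d.temperature == 25
        f22_mut = dep.d22_mut16 * (dep.d22_heat_extra if hot else 1.0) if mut else 1.0
        f22_csr1 = dep.d22_csr1_heat if hot else 1.0
        f26 = dep.d26_mut16_heat if (mut and hot) else 1.0
        for g in background_genes:
            r22, r26 = gene_rates.get(g, (0.0, 0.0))
            if r22 > 0:
                f = f22_mut if g in mutator_dep else (f22_csr1 if g in csr1_only else 1.0)
                n = rng.poisson(r22 * f)
                for (length, first, orient), k in _simulate_pool(rng, n, 22, cfg, True).items():
                    rows.append((d.sample_id, g, length, first, orient, float(k)))
            if r26 > 0:
                n = rng.poisson(r26 * f26)
                for (length, first, orient), k in _simulate_pool(rng, n, 26, cfg, True).items():
                    rows.append((d.sample_id, g, length, first, orient, float(k)))
            n_bg = rng.poisson(cfg.srna_background_reads)
            for (length, first, orient), k in _simulate_pool(rng, n_bg, None, cfg, False).items():
                rows.append((d.sample_id, g, length, first, orient, float(k)))
        for g in mir_genes:
            # mature miRNAs: sense-strand 22-nt reads, stable across conditions
            n = rng.poisson(cfg.mir35_reads_per_member)
            at_peak = rng.random(n) < cfg.peak_length_prob
            lengths = np.where(at_peak, 22, _length_background(rng, n))
            firsts = rng.choice(list(BASES), size=n, p=[0.3, 0.2, 0.25, 0.25])
            agg: dict[tuple[int, str], int] = {}
            for length, first in zip(lengths, firsts):
                key = (int(length), str(first))
                agg[key] = agg.get(key, 0) + 1
            for (length, first), k in agg.items():
                rows.append((d.sample_id, g, length, first, "sense", float(k)))
    df = pd.DataFrame(
        rows, columns=["sample_id", "gene_id", "length", "first_nt", "orientation", "weight"]
    )
    return ReadAssignmentTable(df)


def evaluate_recovery(
    called: ExclusiveSets, truth: SimTruth, stage: str = "L4"
) -> dict[str, float]:
    """Precision/recall of the exclusive sets against the planted truth.

    The reference sets are the genes planted in the combined contrast minus
    any gene also planted in a single-factor contrast (the exclusivity the
    pipeline is asked to recover).  Empty called sets give NaN precision.
    """
    singles = (
        truth.planted_up[f"heat_only:{stage}"]
        | truth.planted_down[f"heat_only:{stage}"]
        | truth.planted_up[f"mutation_only:{stage}"]
        | truth.planted_down[f"mutation_only:{stage}"]
    )
    ref_up = truth.planted_up[f"combined:{stage}"] - singles
    ref_down = truth.planted_down[f"combined:{stage}"] - singles
    if not ref_up and not ref_down:
        raise ValueError("no planted effects to recover")
    out: dict[str, float] = {}
    for direction, called_set, ref in (
        ("up", called.up_exclusive, ref_up),
        ("down", called.down_exclusive, ref_down),
    ):
        tp = len(called_set & ref)
        out[f"precision_{direction}"] = tp / len(called_set) if called_set else float("nan")
        out[f"recall_{direction}"] = tp / len(ref) if ref else float("nan")
    return out


def scaled_config(seed: int = 0, **overrides) -> SimConfig:
    """A smaller configuration for quick tests (fewer genes, same structure)."""
    sizes = {
        "sperm": 100, "oogenesis": 60, "sex_neutral": 40,
        "alg34_neg": 15, "alg34_pos": 15, "alg34_other": 25,
        "csr1": 90, "ergo1": 10,
    }
    overlaps = {
        ("alg34_neg", "sperm"): 15,
        ("alg34_pos", "sperm"): 15,
        ("alg34_other", "sperm"): 25,
        ("csr1", "alg34_other"): 20,
        ("csr1", "alg34_neg"): 8,
        ("csr1", "alg34_pos"): 8,
        ("csr1", "sperm"): 25,
        ("ergo1", "sperm"): 0,
    }
    base = SimConfig(
        seed=seed, n_genes=500, class_sizes=sizes, class_overlaps=overlaps,
        depth=2.5e5,
    )
    return replace(base, **overrides) if overrides else base
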