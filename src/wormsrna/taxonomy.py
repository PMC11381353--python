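"""Small-RNA class taxonomy: 22G/26G calls and size x first-nucleotide profiles.

In *C. elegans*, secondary endogenous siRNAs (22G-RNAs) are 22 nt long with a
5' guanine and antisense to their target transcript; primary 26G-RNAs are
26 nt with a 5' G, likewise antisense.  Classification here is purely over the
read attributes (length, 5' base, orientation relative to the assigned gene);
biogenesis is not modelled.  An optional flag admits 21-nt 5'G reads into the
22G class to account for reads shortened by one base during adapter trimming.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, ReadAssignmentTable, VALID_BASES

BASES = ("A", "C", "G", "T")


class SmallRNAClass(enum.Enum):
    TWENTYTWO_G = "22G"
    TWENTYSIX_G = "26G"
    OTHER = "other"


@dataclass(frozen=True)
class ClassificationConfig:
    """Rules applied when labelling a read.

    include_21nt_trimmed admits 21-nt 5'G reads into the 22G class (reads
    clipped by one base during trimming); require_antisense demands the read
    be antisense to its assigned gene, the orientation expected for siRNAs;
    length_window bounds the sizes retained in profiles and library totals.
    """

    include_21nt_trimmed: bool = False
    require_antisense: bool = True
    length_window: tuple[int, int] = (18, 30)

    def __post_init__(self) -> None:
        lo, hi = self.length_window
        if not (15 <= lo <= hi <= 40):
            raise ValueError(f"length_window must lie within [15, 40], got {self.length_window}")


def classify_read(
    length: int,
    first_nt: str,
    orientation: str,
    cfg: ClassificationConfig = ClassificationConfig(),
) -> SmallRNAClass:
    """Label one read as 22G, 26G or other."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if first_nt not in VALID_BASES:
        raise ValueError(f"first_nt must be one of A,C,G,T, got {first_nt!r}")
    if orientation not in ("sense", "antisense"):
        raise ValueError(f"orientation must be 'sense' or 'antisense', got {orientation!r}")
    if cfg.require_antisense and orientation != "antisense":
        return SmallRNAClass.OTHER
    if first_nt != "G":
        return SmallRNAClass.OTHER
    lengths_22 = (21, 22) if cfg.include_21nt_trimmed else (22,)
    if length in lengths_22:
        return SmallRNAClass.TWENTYTWO_G
    if length == 26:
        return SmallRNAClass.TWENTYSIX_G
    return SmallRNAClass.OTHER


def _class_mask(df: pd.DataFrame, cfg: ClassificationConfig, label: SmallRNAClass) -> pd.Series:
    """Vectorized classify_read == label over a read-record frame."""
    is_g = df["first_nt"] == "G"
    anti_ok = (df["orientation"] == "antisense") if cfg.require_antisense else True
    lengths_22 = (21, 22) if cfg.include_21nt_trimmed else (22,)
    is_22g = is_g & anti_ok & df["length"].isin(lengths_22)
    is_26g = is_g & anti_ok & (df["length"] == 26) & ~df["length"].isin(lengths_22)
    if label is SmallRNAClass.TWENTYTWO_G:
        return is_22g
    if label is SmallRNAClass.TWENTYSIX_G:
        return is_26g
    return ~(is_22g | is_26g)


@dataclass
class SizeNtProfile:
    """Weighted read tallies over length x 5'-base, raw and per-million."""

    scope: str
    lengths: list[int]
    counts: np.ndarray  # len(lengths) x 4, columns A,C,G,T
    library_total: float
    excluded_weight: float = 0.0
    empty_scope: bool = False

    @property
    def normalized(self) -> np.ndarray:
        return self.counts * 1e6 / self.library_total

    def to_dataframe(self, normalized: bool = False) -> pd.DataFrame:
        values = self.normalized if normalized else self.counts
        return pd.DataFrame(values, index=self.lengths, columns=list(BASES))

    def length_histogram(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def build_size_nt_profile(
    reads: ReadAssignmentTable,
    scope: str = "library",
    library_total: float | None = None,
    cfg: ClassificationConfig = ClassificationConfig(),
) -> SizeNtProfile:
    """Tally weighted reads into a (length x first-nt) matrix.

    ``scope`` is a gene_id or the string "library" (all reads).  Lengths
    outside ``cfg.length_window`` are excluded from the matrix but summed in
    ``excluded_weight``.  When ``library_total`` is omitted, the table's total
    weight is used.  A gene absent from the table yields an all-zero profile
    flagged ``empty_scope`` rather than an error.
    """
    if library_total is None:
        library_total = reads.total_weight() or 1.0
    if library_total <= 0:
        raise ValueError("library_total must be > 0")
    lo, hi = cfg.length_window
    lengths = list(range(lo, hi + 1))
    df = reads.records
    empty = False
    if scope != "library":
        df = df[df["gene_id"] == scope]
        empty = df.empty
    in_window = (df["length"] >= lo) & (df["length"] <= hi)
    excluded = float(df.loc[~in_window, "weight"].sum())
    df = df[in_window]
    counts = np.zeros((len(lengths), len(BASES)))
    if len(df):
        tallied = df.groupby(["length", "first_nt"])["weight"].sum()
        for (length, base), w in tallied.items():
            counts[length - lo, BASES.index(base)] = w
    return SizeNtProfile(scope, lengths, counts, float(library_total), excluded, empty)


def count_class_per_gene(
    reads: ReadAssignmentTable,
    cfg: ClassificationConfig = ClassificationConfig(),
    label: SmallRNAClass = SmallRNAClass.TWENTYTWO_G,
    gene_ids: list[str] | None = None,
    library_totals: dict[str, float] | None = None,
) -> CountMatrix:
    """Per-gene, per-library summed weight of reads of one class.

    Libraries are the distinct ``sample_id`` values in the table.  Library
    totals default to each library's total weighted reads inside the length
    window (the small-RNA per-million denominator), overridable per sample.
    """
    df = reads.records
    samples = reads.sample_ids or ["library"]
    if gene_ids is None:
        gene_ids = sorted(df["gene_id"].unique())
    mask = _class_mask(df, cfg, label)
    sub = df[mask]
    counts = np.zeros((len(gene_ids), len(samples)))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    sample_index = {s: j for j, s in enumerate(samples)}
    if len(sub):
        tallied = sub.groupby(["gene_id", "sample_id"])["weight"].sum()
        for (g, s), w in tallied.items():
            if g in gene_index:
                counts[gene_index[g], sample_index[s]] = w
    lo, hi = cfg.length_window
    if library_totals is None:
        in_win = df[(df["length"] >= lo) & (df["length"] <= hi)]
        totals_series = in_win.groupby("sample_id")["weight"].sum()
        totals = np.array([float(totals_series.get(s, 0.0)) or 1.0 for s in samples])
    else:
        totals = np.array([float(library_totals[s]) for s in samples])
    return CountMatrix(list(gene_ids), list(samples), counts, totals)


def count_family_per_library(
    reads: ReadAssignmentTable,
    member_ids: set[str],
    cfg: ClassificationConfig = ClassificationConfig(),
) -> dict[str, float]:
    """Total weighted reads per library mapping to a gene family, any class.

    Used for the mir-35-family denominator: every read mapping to a family
    member counts, sense or antisense, regardless of length or 5' base.
    """
    df = reads.records
    sub = df[df["gene_id"].isin(member_ids)]
    totals = sub.groupby("sample_id")["weight"].sum()
    return {s: float(totals.get(s, 0.0)) for s in reads.sample_ids}


@dataclass
class ClassCountSet:
    """22G/26G/other per-gene matrices over the same genes and libraries."""

    by_class: dict[str, CountMatrix] = field(default_factory=dict)

    def total(self) -> np.ndarray:
        return sum(cm.counts for cm in self.by_class.values())


def count_all_classes(
    reads: ReadAssignmentTable,
    cfg: ClassificationConfig = ClassificationConfig(),
    gene_ids: list[str] | None = None,
    library_totals: dict[str, float] | None = None,
) -> ClassCountSet:
    if gene_ids is None:
        gene_ids = sorted(reads.records["gene_id"].unique())
    return ClassCountSet(
        {
            label.value: count_class_per_gene(reads, cfg, label, gene_ids, library_totals)
            for label in SmallRNAClass
        }
    )
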