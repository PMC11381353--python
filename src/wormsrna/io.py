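"""Input/output for annotations, count matrices, read assignments and gene sets.

All genomic intervals are held 0-based half-open internally.  GFF3 input is
converted from its native 1-based inclusive convention; BED is taken as-is.
Tabular dialects are UTF-8, tab-separated, ``.`` decimal point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")
VALID_ORIENTATIONS = frozenset({"sense", "antisense"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene locus. ``start``/``end`` are 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")


def _check_unique_gene_ids(genes: Sequence[GeneModel]) -> None:
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise FormatError(f"duplicate gene_id in annotation: {g.gene_id}")
        seen.add(g.gene_id)


def read_gff3(path: str | Path, feature_types: tuple[str, ...] = ("gene",)) -> list[GeneModel]:
    """Read gene records from GFF3 (1-based inclusive -> 0-based half-open)."""
    genes: list[GeneModel] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 line has {len(fields)} fields, not 9")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in feature_types:
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            gene_id = attr_map.get("ID") or attr_map.get("gene_id")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: gene feature lacks ID attribute")
            gene_id = gene_id.removeprefix("gene:")
            biotype = attr_map.get("biotype", attr_map.get("gene_biotype", "protein_coding"))
            genes.append(
                GeneModel(gene_id, chrom, int(start) - 1, int(end), strand, biotype)
            )
    _check_unique_gene_ids(genes)
    return genes


def read_bed6(path: str | Path) -> list[GeneModel]:
    """Read gene intervals from BED6 (natively 0-based half-open)."""
    genes: list[GeneModel] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 needs 6 columns, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            genes.append(GeneModel(name, chrom, int(start), int(end), strand))
    _check_unique_gene_ids(genes)
    return genes


# ---------------------------------------------------------------------------
# Sample design
# ---------------------------------------------------------------------------

GENOTYPES = ("WT", "mut16")
TEMPERATURES = (20, 25)
STAGES = ("L4", "adult")
ASSAYS = ("mRNA", "smallRNA")


@dataclass(frozen=True)
class SampleDesign:
    """One sequencing library in the genotype x temperature x stage design."""

    sample_id: str
    genotype: str
    temperature: int
    stage: str
    assay: str
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.temperature not in TEMPERATURES:
            raise ValueError(f"temperature must be one of {TEMPERATURES}")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if self.assay not in ASSAYS:
            raise ValueError(f"assay must be one of {ASSAYS}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")

    @property
    def condition(self) -> tuple[str, int, str]:
        return (self.genotype, self.temperature, self.stage)


def read_sample_design(path: str | Path) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "genotype", "temperature", "stage", "assay", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: design table missing columns {sorted(missing)}")
    designs = [
        SampleDesign(
            row.sample_id, row.genotype, int(row.temperature), row.stage,
            row.assay, int(row.replicate),
        )
        for row in df.itertuples()
    ]
    keys = [(d.genotype, d.temperature, d.stage, d.assay, d.replicate) for d in designs]
    if len(set(keys)) != len(keys):
        raise FormatError(f"{path}: duplicate (genotype, temperature, stage, assay, replicate)")
    return designs


def write_sample_design(designs: Sequence[SampleDesign], path: str | Path) -> None:
    pd.DataFrame(
        [
            (d.sample_id, d.genotype, d.temperature, d.stage, d.assay, d.replicate)
            for d in designs
        ],
        columns=["sample_id", "genotype", "temperature", "stage", "assay", "replicate"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Genes x samples matrix of reads (or derived per-million values).

    ``library_totals`` may exceed column sums: a library's total includes reads
    outside the annotated genes.  They must be strictly positive.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    library_totals: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.library_totals = np.asarray(self.library_totals, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.library_totals.shape != (len(self.sample_ids),):
            raise ValueError("library_totals length must equal number of samples")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.library_totals <= 0):
            raise ValueError("library_totals must be > 0")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_id in count matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_id in count matrix")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, library_totals: Sequence[float] | None = None
    ) -> "CountMatrix":
        values = df.to_numpy(dtype=float)
        totals = (
            values.sum(axis=0) if library_totals is None else np.asarray(library_totals, float)
        )
        return cls(list(df.index), list(df.columns), values, totals)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(
            list(self.gene_ids), list(sample_ids),
            self.counts[:, idx], self.library_totals[idx],
        )

    def gene_row(self, gene_id: str) -> np.ndarray:
        return self.counts[self.gene_ids.index(gene_id), :]


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read the tab-separated count dialect.

    First column is ``gene_id``; the header row carries sample ids.  An
    optional comment line ``#total:<TAB>t1<TAB>t2...`` supplies per-library
    totals; otherwise totals default to column sums.
    """
    totals: list[float] | None = None
    header: list[str] | None = None
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#total:"):
                    totals = [float(x) for x in line.split("\t")[1:]]
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
                continue
            if len(fields) != len(header) + 1:
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {len(header) + 1})"
                )
            gene_ids.append(fields[0])
            try:
                values = [float(x) for x in fields[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric count") from exc
            if any(v < 0 for v in values):
                raise FormatError(f"{path}:{lineno}: negative count for {fields[0]}")
            rows.append(values)
    if header is None:
        raise FormatError(f"{path}: empty count matrix")
    if len(set(gene_ids)) != len(gene_ids):
        dup = next(g for g in gene_ids if gene_ids.count(g) > 1)
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    counts = np.asarray(rows, dtype=float).reshape(len(gene_ids), len(header))
    if totals is not None and len(totals) != len(header):
        raise FormatError(f"{path}: #total: line length does not match sample count")
    if totals is None:
        totals = list(counts.sum(axis=0))
    return CountMatrix(gene_ids, list(header), counts, np.asarray(totals))


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#total:\t" + "\t".join(_fmt_num(t) for t in cm.library_totals) + "\n")
        fh.write("gene_id\t" + "\t".join(cm.sample_ids) + "\n")
        for g, row in zip(cm.gene_ids, cm.counts):
            fh.write(g + "\t" + "\t".join(_fmt_num(v) for v in row) + "\n")


def _fmt_num(v: float) -> str:
    return repr(int(v)) if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# Read assignments
# ---------------------------------------------------------------------------

READ_COLUMNS = ["gene_id", "length", "first_nt", "orientation", "weight"]


@dataclass
class ReadAssignmentTable:
    """Per-read (or aggregated, via ``weight``) small-RNA gene assignments.

    Columns: ``gene_id, length, first_nt, orientation, weight`` plus an
    optional ``sample_id`` column identifying the library.  Identical records
    may be collapsed with their weights summed; every tally downstream is
    weight-additive, so the two representations are interchangeable.
    """

    records: pd.DataFrame
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in READ_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"read table missing columns {missing}")
        if "sample_id" not in df.columns:
            df = df.assign(sample_id="library")
        df = df[["sample_id"] + READ_COLUMNS].copy()
        df["length"] = df["length"].astype(int)
        df["weight"] = df["weight"].astype(float)
        if len(df):
            bad_nt = ~df["first_nt"].isin(list(VALID_BASES))
            if bad_nt.any():
                raise ValueError(
                    f"invalid first_nt values: {sorted(df.loc[bad_nt, 'first_nt'].unique())}"
                )
            bad_or = ~df["orientation"].isin(list(VALID_ORIENTATIONS))
            if bad_or.any():
                raise ValueError("orientation must be 'sense' or 'antisense'")
            if (df["length"] < 15).any() or (df["length"] > 40).any():
                raise ValueError("read length outside [15, 40] nt")
            if (df["weight"] <= 0).any():
                raise ValueError("weights must be > 0")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    def total_weight(self, sample_id: str | None = None) -> float:
        df = self.records
        if sample_id is not None:
            df = df[df["sample_id"] == sample_id]
        return float(df["weight"].sum())

    def for_sample(self, sample_id: str) -> "ReadAssignmentTable":
        return ReadAssignmentTable(
            self.records[self.records["sample_id"] == sample_id].reset_index(drop=True)
        )

    def canonical(self) -> pd.DataFrame:
        """Aggregate to one row per distinct record, deterministic order."""
        agg = (
            self.records.groupby(
                ["sample_id", "gene_id", "length", "first_nt", "orientation"],
                as_index=False,
            )["weight"].sum()
        )
        return agg.sort_values(
            ["sample_id", "gene_id", "length", "first_nt", "orientation"]
        ).reset_index(drop=True)

    def equivalent(self, other: "ReadAssignmentTable", tol: float = 1e-9) -> bool:
        a, b = self.canonical(), other.canonical()
        if len(a) != len(b):
            return False
        key_cols = ["sample_id", "gene_id", "length", "first_nt", "orientation"]
        if not a[key_cols].equals(b[key_cols]):
            return False
        return bool(np.allclose(a["weight"], b["weight"], rtol=tol, atol=tol))


def read_read_assignments_tsv(path: str | Path) -> ReadAssignmentTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "first_nt": str, "sample_id": str})
    missing = [c for c in READ_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: read-assignment table missing columns {missing}")
    try:
        return ReadAssignmentTable(df)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_read_assignments_tsv(table: ReadAssignmentTable, path: str | Path) -> None:
    df = table.records.copy()
    df["weight"] = df["weight"].map(_fmt_num)
    df.to_csv(path, sep="\t", index=False)


def read_read_assignments_sam(
    path: str | Path,
    annotation: Sequence[GeneModel],
    multi_overlap: str = "fractional",
    sample_id: str = "library",
) -> ReadAssignmentTable:
    """Assign aligned SAM records to genes by overlap on either strand.

    A read overlapping k genes receives weight 1/k at each (``fractional``);
    ``primary-only`` keeps the gene with the longest overlap, ties broken by
    lexicographic gene_id.  Read length is the number of bases in the record's
    sequence (the molecule's length, not the reference span); ``first_nt`` is
    the 5' base of the sequenced read, i.e. for a reverse-strand alignment the
    complement of the last stored (reference-forward) base.  Reads overlapping
    no gene are dropped and counted in the parse report.
    """
    import pysam

    if multi_overlap not in ("fractional", "primary-only"):
        raise ValueError("multi_overlap must be 'fractional' or 'primary-only'")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)

    rows: list[tuple] = []
    n_unassigned = 0
    n_unmapped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.query_sequence is None:
                n_unmapped += 1
                continue
            seq = rec.query_sequence  # stored reference-forward
            length = len(seq)
            if rec.is_reverse:
                first = seq[-1].translate(_COMPLEMENT).upper()
                read_strand = "-"
            else:
                first = seq[0].upper()
                read_strand = "+"
            if first not in VALID_BASES:
                raise FormatError(f"SAM read {rec.query_name}: 5' base {first!r} not in ACGT")
            chrom = rec.reference_name
            rstart, rend = rec.reference_start, rec.reference_end
            hits = [
                (min(g.end, rend) - max(g.start, rstart), g)
                for g in by_chrom.get(chrom, [])
                if g.start < rend and g.end > rstart
            ]
            if not hits:
                n_unassigned += 1
                continue
            if multi_overlap == "primary-only":
                hits.sort(key=lambda og: (-og[0], og[1].gene_id))
                hits = hits[:1]
            w = 1.0 if multi_overlap == "primary-only" else 1.0 / len(hits)
            for _overlap, g in hits:
                orientation = "sense" if read_strand == g.strand else "antisense"
                rows.append((sample_id, g.gene_id, length, first, orientation, w))
    df = pd.DataFrame(rows, columns=["sample_id"] + READ_COLUMNS)
    table = ReadAssignmentTable(df)
    table.report = {"unassigned": n_unassigned, "unmapped": n_unmapped}
    return table


def read_read_assignments(
    path: str | Path,
    format: str = "TSV",
    annotation: Sequence[GeneModel] | None = None,
    multi_overlap: str = "fractional",
    sample_id: str = "library",
) -> ReadAssignmentTable:
    """Dispatch on ``format`` ('TSV' or 'SAM'); SAM requires an annotation."""
    fmt = format.upper()
    if fmt == "TSV":
        table = read_read_assignments_tsv(path)
    elif fmt == "SAM":
        if annotation is None:
            raise ValueError("SAM input requires a gene annotation")
        table = read_read_assignments_sam(path, annotation, multi_overlap, sample_id)
    else:
        raise ValueError(f"unknown read-assignment format {format!r}")
    if annotation is not None and len(table):
        known = {g.gene_id for g in annotation}
        unknown = set(table.records["gene_id"]) - known
        if unknown:
            raise FormatError(f"read table references genes absent from annotation: {sorted(unknown)[:5]}")
    return table


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene-ID sets (pathway targets, tissue classes)."""

    sets: dict[str, set[str]]
    sources: dict[str, str] = field(default_factory=dict)
    parse_report: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return sorted(self.sets)

    def update(self, other: "GeneSetCollection") -> None:
        self.sets.update(other.sets)
        self.sources.update(other.sources)
        for k, v in other.parse_report.items():
            self.parse_report[k] = self.parse_report.get(k, 0) + v


def read_gene_sets(path: str | Path, format: str = "plain") -> GeneSetCollection:
    """Read gene sets from a one-ID-per-line file or a GMT file.

    Plain format: one gene id per line, set named after the file stem.
    GMT: tab-separated ``name<TAB>description<TAB>member...`` per line.
    Duplicated members are dropped and counted in ``parse_report``.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "plain":
        ids = [line.strip() for line in path.read_text(encoding="utf-8").splitlines()]
        ids = [x for x in ids if x]
        if not ids:
            raise FormatError(f"{path}: empty gene set")
        name = path.stem
        dedup = set(ids)
        return GeneSetCollection(
            {name: dedup},
            sources={name: str(path)},
            parse_report={name: len(ids) - len(dedup)},
        )
    if fmt == "gmt":
        sets: dict[str, set[str]] = {}
        sources: dict[str, str] = {}
        report: dict[str, int] = {}
        lines = path.read_text(encoding="utf-8").splitlines()
        if not any(line.strip() for line in lines):
            raise FormatError(f"{path}: empty gene set")
        for lineno, line in enumerate(lines, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            dedup = set(members)
            if not dedup:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = dedup
            sources[name] = desc or str(path)
            report[name] = len(members) - len(dedup)
        return GeneSetCollection(sets, sources=sources, parse_report=report)
    raise ValueError(f"unknown gene-set format {format!r}")


def write_gene_sets_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.names():
            src = collection.sources.get(name, "wormsrna")
            fh.write("\t".join([name, src] + sorted(collection.sets[name])) + "\n")


# ---------------------------------------------------------------------------
# JSON result export
# ---------------------------------------------------------------------------

def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
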