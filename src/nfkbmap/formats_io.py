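"""Readers/writers for the genomic and tabular formats used across the pipeline.

Conventions enforced at this boundary:

* all intervals are 0-based half-open (BED dialect); GFF3 input, which is
  1-based inclusive, is converted on load;
* strand affects only the TSS position of a gene (TSS = start for ``+``,
  end−1 for ``-``); binding-region intervals are strandless;
* region identity for set operations is ``(chrom, start, end)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """A file did not conform to its declared format."""


class ConfigError(ValueError):
    """Inconsistent or incomplete configuration of a reader or stage."""


# ---------------------------------------------------------------------------
# genomic regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A 0-based half-open genomic interval.

    ``summit`` is an optional bp offset from ``start`` (MACS narrowPeak
    convention); ``score`` an optional enrichment value.  Equality, ordering
    and hashing use ``(chrom, start, end)`` only.
    """

    chrom: str
    start: int
    end: int
    summit: int | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"negative start: {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise FormatError(f"end <= start: {self.chrom}:{self.start}-{self.end}")
        if self.summit is not None and not 0 <= self.summit < self.end - self.start:
            raise FormatError(
                f"summit offset {self.summit} outside region "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def abs_summit(self) -> int:
        """Absolute summit position; midpoint when no summit was recorded."""
        if self.summit is not None:
            return self.start + self.summit
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicRegion", min_overlap: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_overlap


def read_bed(path: str | Path) -> list[GenomicRegion]:
    """Read BED3/BED5/BED6 or MACS narrowPeak into regions, preserving order.

    For narrowPeak lines (10 columns) the 7th column (signalValue) is stored
    as ``score`` and the 10th as ``summit`` (−1 means absent).  For BED5/6 the
    5th column is stored as ``score``.
    """
    path = Path(path)
    regions: list[GenomicRegion] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            score: float | None = None
            summit: int | None = None
            if len(cols) >= 10:  # narrowPeak
                try:
                    score = float(cols[6])
                    s = int(cols[9])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad narrowPeak fields") from exc
                summit = None if s < 0 else s
            elif len(cols) >= 5:
                try:
                    score = float(cols[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            try:
                regions.append(
                    GenomicRegion(chrom, start, end, summit=summit, score=score)
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_bed(regions: Iterable[GenomicRegion], path: str | Path,
              names: Sequence[str] | None = None) -> None:
    """Write regions as narrowPeak when any summit is present, else BED5.

    ``names`` optionally fills the 4th (name) column, e.g. with pattern codes.
    """
    regions = list(regions)
    narrow = any(r.summit is not None for r in regions)
    with Path(path).open("w") as fh:
        for i, r in enumerate(regions):
            name = names[i] if names is not None else "."
            if narrow:
                summit = -1 if r.summit is None else r.summit
                score = 0.0 if r.score is None else r.score
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t.\t"
                    f"{score!r}\t-1\t-1\t{summit}\n"
                )
            else:
                score = 0.0 if r.score is None else r.score
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score!r}\n")


# ---------------------------------------------------------------------------
# chromatin loops
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Loop:
    """An unordered pair of loop anchors; anchors are stored sorted so that
    equality is symmetric in the anchor order."""

    anchor_a: GenomicRegion
    anchor_b: GenomicRegion

    def __post_init__(self) -> None:
        a, b = self.anchor_a, self.anchor_b
        if (b.chrom, b.start, b.end) < (a.chrom, a.start, a.end):
            object.__setattr__(self, "anchor_a", b)
            object.__setattr__(self, "anchor_b", a)

    @property
    def is_cis(self) -> bool:
        return self.anchor_a.chrom == self.anchor_b.chrom


def read_loops(path: str | Path, allow_trans: bool = False) -> list[Loop]:
    """Read a BEDPE (6+ column) file of anchor pairs.

    Trans-chromosomal pairs are rejected unless ``allow_trans``.
    """
    path = Path(path)
    loops: list[Loop] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(f"{path}:{lineno}: fewer than 6 BEDPE columns")
            try:
                a = GenomicRegion(cols[0], int(cols[1]), int(cols[2]))
                b = GenomicRegion(cols[3], int(cols[4]), int(cols[5]))
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            loop = Loop(a, b)
            if not loop.is_cis and not allow_trans:
                raise FormatError(
                    f"{path}:{lineno}: trans-chromosomal loop "
                    f"{a.chrom}<->{b.chrom} (allow_trans=False)"
                )
            loops.append(loop)
    return loops


def write_loops(loops: Iterable[Loop], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for lp in loops:
            a, b = lp.anchor_a, lp.anchor_b
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    """One gene with a single TSS and optional transcript structure.

    ``start``/``end`` span the transcribed gene body (0-based half-open);
    ``exons`` are half-open intervals within it; ``clusters`` are the
    transcript-cluster ids (microarray probe-set level) mapped to the gene.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    start: int = -1
    end: int = -1
    exons: tuple[tuple[int, int], ...] = ()
    clusters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: strand must be '+' or '-'")


class GeneAnnotation:
    """Container mapping genes and transcript clusters; one TSS per gene."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: dict[str, Gene] = {}
        self.cluster_to_gene: dict[str, str] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise FormatError(f"duplicate gene id {g.gene_id}")
            self.genes[g.gene_id] = g
            for tc in g.clusters:
                if tc in self.cluster_to_gene:
                    raise FormatError(
                        f"transcript cluster {tc} mapped to more than one gene"
                    )
                self.cluster_to_gene[tc] = g.gene_id
        self._tss_cache: dict[str, tuple[np.ndarray, list[str]]] = {}

    def __len__(self) -> int:
        return len(self.genes)

    def tss_by_chrom(self, chrom: str) -> tuple[np.ndarray, list[str]]:
        """Sorted TSS positions and gene ids for one chromosome (cached)."""
        if chrom not in self._tss_cache:
            items = sorted(
                (g.tss, g.gene_id) for g in self.genes.values() if g.chrom == chrom
            )
            pos = np.array([t for t, _ in items], dtype=np.int64)
            ids = [gid for _, gid in items]
            self._tss_cache[chrom] = (pos, ids)
        return self._tss_cache[chrom]

    def chroms(self) -> list[str]:
        return sorted({g.chrom for g in self.genes.values()})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tss": g.tss,
                "start": g.start,
                "end": g.end,
                "exons": ";".join(f"{a}-{b}" for a, b in g.exons),
                "clusters": ";".join(g.clusters),
            }
            for g in sorted(self.genes.values(), key=lambda g: g.gene_id)
        ]
        return pd.DataFrame(rows)


def read_annotation_tsv(path: str | Path) -> GeneAnnotation:
    """Read a tabular annotation: columns gene, chrom, strand, tss and
    optionally start, end, exons ("a-b;c-d"), clusters ("tc1;tc2")."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "strand": str})
    required = {"gene", "chrom", "strand", "tss"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: annotation needs columns {sorted(required)}")
    genes = []
    for row in df.itertuples(index=False):
        exons: tuple[tuple[int, int], ...] = ()
        if "exons" in df.columns and isinstance(row.exons, str) and row.exons:
            exons = tuple(
                (int(a), int(b))
                for a, b in (pair.split("-") for pair in row.exons.split(";"))
            )
        clusters: tuple[str, ...] = ()
        if "clusters" in df.columns and isinstance(row.clusters, str) and row.clusters:
            clusters = tuple(row.clusters.split(";"))
        genes.append(
            Gene(
                gene_id=row.gene,
                chrom=row.chrom,
                strand=row.strand,
                tss=int(row.tss),
                start=int(getattr(row, "start", -1)),
                end=int(getattr(row, "end", -1)),
                exons=exons,
                clusters=clusters,
            )
        )
    return GeneAnnotation(genes)


def write_annotation_tsv(ann: GeneAnnotation, path: str | Path) -> None:
    ann.to_frame().to_csv(path, sep="\t", index=False)


def read_annotation_gff3(path: str | Path) -> GeneAnnotation:
    """Read gene/exon features from GFF3 (1-based inclusive, converted here).

    The TSS is the 5' end of the gene feature by strand; ``mRNA``/transcript
    children provide transcript-cluster ids via their ``ID`` attributes.
    """
    path = Path(path)
    gene_rows: dict[str, dict] = {}
    exon_parent: list[tuple[str, int, int]] = []
    tx_parent: list[tuple[str, str]] = []
    tx_to_gene: dict[str, str] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 needs 9 columns")
            chrom, _, ftype, start1, end1, _, strand, _, attrs = cols
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            start, end = int(start1) - 1, int(end1)  # to 0-based half-open
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene without ID")
                gene_rows[gid] = dict(
                    chrom=chrom, strand=strand, start=start, end=end
                )
            elif ftype in ("mRNA", "transcript"):
                tid, parent = attr.get("ID"), attr.get("Parent")
                if tid and parent:
                    tx_parent.append((tid, parent))
                    tx_to_gene[tid] = parent
            elif ftype == "exon":
                parent = attr.get("Parent")
                if parent:
                    exon_parent.append((parent, start, end))
    genes = []
    for gid, info in gene_rows.items():
        clusters = tuple(t for t, p in tx_parent if p == gid)
        exon_ivs = sorted(
            (s, e)
            for p, s, e in exon_parent
            if p == gid or tx_to_gene.get(p) == gid
        )
        tss = info["start"] if info["strand"] == "+" else info["end"] - 1
        genes.append(
            Gene(gid, info["chrom"], info["strand"], tss,
                 start=info["start"], end=info["end"],
                 exons=tuple(exon_ivs), clusters=clusters)
        )
    return GeneAnnotation(genes)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """log2 expression values (rows × samples) with a sample→group mapping."""

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate row id: {dup}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ConfigError(f"samples absent from group mapping: {missing[:5]}")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise FormatError("expression matrix contains non-finite values")

    def samples_in_group(self, label: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == label]

    @property
    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.groups[s], None)
        return list(seen)


def read_expression(path: str | Path, groups: Mapping[str, str]) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column = row ids) and attach the
    sample→group mapping; every sample in the file must appear in ``groups``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, dict(groups))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sample id, group label (with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: group map needs 2 columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_group_map(groups: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(groups), "group": [groups[s] for s in groups]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON, a YAML subset) configuration mapping."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top-level config must be a mapping")
    return cfg


def almost_equal(a: float, b: float, tol: float = 1e-9) -> bool:
    return math.isclose(a, b, rel_tol=0.0, abs_tol=tol)
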