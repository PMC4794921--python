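"""Combinatorial occupancy analysis of multi-subunit binding-region sets.

Per-subunit peak sets are unified by single-linkage merging of overlapping
intervals; each unified region receives a 4-bit indicator vector over the
fixed subunit order (p50, p52, RelA, RelB) and a pattern code such as
``"1100"`` (p50+p52).  On top of the occupancy matrix the module computes
pattern frequencies, sharing/overlap statistics, TSS-distance histograms,
genomic-feature annotation, k-means clustering of summit-centred enrichment
profiles, and comparisons between two cistromes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.cluster import KMeans

from . import SUBUNITS
from .formats_io import GeneAnnotation, GenomicRegion

N_SUB = len(SUBUNITS)

#: the 15 non-empty 4-bit patterns, in descending binary order
ALL_PATTERNS = tuple(format(v, "04b") for v in range(15, 0, -1))


def pattern_code(indicators: Sequence[int] | Sequence[bool]) -> str:
    """4-character binary code in subunit order p50, p52, RelA, RelB."""
    if len(indicators) != N_SUB:
        raise ValueError(f"expected {N_SUB} indicators, got {len(indicators)}")
    if not any(indicators):
        raise ValueError("all-zero indicator vector has no pattern code")
    return "".join("1" if x else "0" for x in indicators)


def pattern_from_subunits(subunits: Iterable[str]) -> str:
    present = set(subunits)
    unknown = present - set(SUBUNITS)
    if unknown:
        raise ValueError(f"unknown subunit name(s): {sorted(unknown)}")
    return pattern_code([s in present for s in SUBUNITS])


@dataclass
class OccupancyMatrix:
    """Unified regions × 4 binary subunit indicators (p50, p52, RelA, RelB).

    ``profiles`` optionally maps each subunit to an (n_regions, n_bins)
    array of summit-centred enrichment-over-input values.
    """

    regions: list[GenomicRegion]
    indicators: np.ndarray
    profiles: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.indicators = np.asarray(self.indicators, dtype=bool)
        if self.indicators.shape != (len(self.regions), N_SUB):
            raise ValueError("indicator matrix shape mismatch")
        if len(self.regions) and not self.indicators.any(axis=1).all():
            raise ValueError("a unified region must bind at least one subunit")

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def codes(self) -> list[str]:
        return [pattern_code(row) for row in self.indicators]

    def subunit_column(self, subunit: str) -> np.ndarray:
        return self.indicators[:, SUBUNITS.index(subunit)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "summit": [r.abs_summit for r in self.regions],
            }
        )
        for j, s in enumerate(SUBUNITS):
            df[s] = self.indicators[:, j].astype(int)
        df["code"] = self.codes
        return df


def build_occupancy_matrix(
    peaksets: Mapping[str, Iterable[GenomicRegion]],
    min_overlap: int = 1,
) -> OccupancyMatrix:
    """Merge the union of all per-subunit peaks into unified regions.

    Single-linkage merging: two intervals fall into the same unified region
    when they overlap by at least ``min_overlap`` bp (directly or through a
    chain).  A subunit's indicator is set when at least one of its peaks
    overlaps the unified region.  The summit of a unified region is the
    summit of its highest-scoring member peak (midpoint fallback).
    """
    unknown = set(peaksets) - set(SUBUNITS)
    if unknown:
        raise ValueError(f"unknown subunit name(s): {sorted(unknown)}")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    tagged: list[tuple[GenomicRegion, str]] = []
    for sub, regs in peaksets.items():
        tagged.extend((r, sub) for r in regs)
    if not tagged:
        raise ValueError("all peak sets are empty")
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))

    merged_regions: list[GenomicRegion] = []
    indicator_rows: list[list[bool]] = []

    def flush(chrom: str, start: int, end: int,
              members: list[tuple[GenomicRegion, str]]) -> None:
        present = [False] * N_SUB
        for r, sub in members:
            present[SUBUNITS.index(sub)] = True
        best = max(
            (r for r, _ in members),
            key=lambda r: (-np.inf if r.score is None else r.score, -r.start),
        )
        if best.summit is not None:
            abs_summit = best.start + best.summit
        else:
            abs_summit = (start + end) // 2
        abs_summit = min(max(abs_summit, start), end - 1)
        merged_regions.append(
            GenomicRegion(chrom, start, end,
                          summit=abs_summit - start, score=best.score)
        )
        indicator_rows.append(present)

    cur_chrom, cur_start, cur_end = None, 0, 0
    cur_members: list[tuple[GenomicRegion, str]] = []
    for r, sub in tagged:
        joins = (
            cur_chrom == r.chrom and r.start <= cur_end - min_overlap
        )
        if joins:
            cur_end = max(cur_end, r.end)
            cur_members.append((r, sub))
        else:
            if cur_members:
                flush(cur_chrom, cur_start, cur_end, cur_members)
            cur_chrom, cur_start, cur_end = r.chrom, r.start, r.end
            cur_members = [(r, sub)]
    if cur_members:
        flush(cur_chrom, cur_start, cur_end, cur_members)

    return OccupancyMatrix(merged_regions, np.array(indicator_rows, dtype=bool))


@dataclass
class PatternFrequencyTable:
    """Counts and percentages of the observed non-empty patterns."""

    table: pd.DataFrame  # columns: code, count, pct
    total: int

    def __post_init__(self) -> None:
        assert int(self.table["count"].sum()) == self.total
        assert abs(float(self.table["pct"].sum()) - 100.0) < 1e-6


def pattern_frequencies(m: OccupancyMatrix) -> PatternFrequencyTable:
    if len(m) == 0:
        raise ValueError("empty occupancy matrix")
    counts = pd.Series(m.codes).value_counts()
    df = pd.DataFrame(
        {"code": counts.index, "count": counts.to_numpy()}
    )
    df = df.sort_values(["count", "code"], ascending=[False, True],
                        ignore_index=True)
    df["pct"] = df["count"] / len(m) * 100.0
    return PatternFrequencyTable(df, total=len(m))


@dataclass
class SharingStatistics:
    """Per-subunit sharing fraction and pairwise conditional overlap."""

    shared: dict[str, float]            # NaN when subunit absent
    pairwise: pd.DataFrame              # rows s, cols t: |s∧t| / |s|
    n_regions: int


def sharing_statistics(m: OccupancyMatrix) -> SharingStatistics:
    """shared(s): of the regions bound by s, the fraction also bound by at
    least one other subunit.  pairwise(s, t): of the regions bound by s, the
    fraction also bound by t."""
    if len(m) == 0:
        raise ValueError("empty occupancy matrix")
    ind = m.indicators
    shared: dict[str, float] = {}
    pairwise = pd.DataFrame(np.nan, index=list(SUBUNITS), columns=list(SUBUNITS))
    nsub = ind.sum(axis=1)
    for i, s in enumerate(SUBUNITS):
        has_s = ind[:, i]
        if not has_s.any():
            shared[s] = float("nan")
            continue
        shared[s] = float((nsub[has_s] >= 2).mean())
        for j, t in enumerate(SUBUNITS):
            pairwise.loc[s, t] = float(ind[has_s, j].mean())
    return SharingStatistics(shared, pairwise, len(m))


@dataclass
class TssDistanceProfile:
    """Histogram of signed summit-to-nearest-TSS distances."""

    counts: np.ndarray       # length nbins
    edges: np.ndarray        # length nbins + 1, spanning [-window, window]
    overflow: int            # regions beyond +-window
    distances: np.ndarray    # signed distance per region


def tss_distance_profile(
    m: OccupancyMatrix, ann: GeneAnnotation, window: int, nbins: int
) -> TssDistanceProfile:
    """Signed distance of each region summit to its nearest TSS (upstream
    negative with respect to the gene's strand), binned over ±window."""
    if window <= 0 or nbins < 1:
        raise ValueError("window must be > 0 and nbins >= 1")
    if len(ann) == 0:
        raise ValueError("empty gene annotation")
    dists = np.empty(len(m), dtype=np.int64)
    for i, r in enumerate(m.regions):
        pos, ids = ann.tss_by_chrom(r.chrom)
        if len(pos) == 0:
            # no gene on this chromosome: treat as beyond-window
            dists[i] = np.iinfo(np.int64).max // 2
            continue
        summit = r.abs_summit
        j = int(np.searchsorted(pos, summit))
        cand = [k for k in (j - 1, j) if 0 <= k < len(pos)]
        k = min(cand, key=lambda k: abs(summit - int(pos[k])))
        gene = ann.genes[ids[k]]
        raw = summit - gene.tss
        dists[i] = raw if gene.strand == "+" else -raw
    edges = np.linspace(-window, window, nbins + 1)
    inside = (dists >= -window) & (dists <= window)
    counts, _ = np.histogram(dists[inside], bins=edges)
    return TssDistanceProfile(
        counts=counts, edges=edges, overflow=int((~inside).sum()),
        distances=dists,
    )


def genomic_feature_annotation(
    region: GenomicRegion, ann: GeneAnnotation, promoter_window: int = 2000
) -> str:
    """Classify a region by its summit with precedence
    promoter > exon > intron > intergenic."""
    summit = region.abs_summit
    pos, ids = ann.tss_by_chrom(region.chrom)
    if len(pos):
        j = int(np.searchsorted(pos, summit))
        for k in (j - 1, j):
            if 0 <= k < len(pos) and abs(summit - int(pos[k])) <= promoter_window:
                return "promoter"
    in_intron = False
    for g in ann.genes.values():
        if g.chrom != region.chrom or g.start < 0 or not g.start <= summit < g.end:
            continue
        if any(a <= summit < b for a, b in g.exons):
            return "exon"
        in_intron = True
    return "intron" if in_intron else "intergenic"


def annotate_regions(
    m: OccupancyMatrix, ann: GeneAnnotation, promoter_window: int = 2000
) -> list[str]:
    return [genomic_feature_annotation(r, ann, promoter_window) for r in m.regions]


@dataclass
class ClusterProfile:
    """k-means partition of summit-centred occupancy profiles."""

    labels: np.ndarray                    # in 1..k, one per region
    k: int
    centers: dict[str, np.ndarray]        # subunit -> (k, nbins) mean profile
    wcss: float                           # within-cluster sum of squares
    cluster_pattern_pct: pd.DataFrame     # clusters × pattern codes, row %


def cluster_profiles(m: OccupancyMatrix, k: int = 8, seed: int = 0) -> ClusterProfile:
    """k-means (k-means++ init, 10 restarts, best SSE) on the concatenated
    4-subunit profile vectors; clusters are relabelled by decreasing size so
    the labelling is canonical for a fixed seed."""
    if m.profiles is None or any(s not in m.profiles for s in SUBUNITS):
        raise ValueError("cluster_profiles requires profiles for all 4 subunits")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(m):
        raise ValueError(f"k={k} exceeds number of regions ({len(m)})")
    X = np.hstack([np.asarray(m.profiles[s], dtype=float) for s in SUBUNITS])
    km = KMeans(n_clusters=k, n_init=10, init="k-means++", random_state=seed)
    raw = km.fit_predict(X)
    # canonical relabelling: by decreasing cluster size, ties by first index
    order = sorted(
        range(k),
        key=lambda c: (-int((raw == c).sum()), int(np.argmax(raw == c))),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([remap[c] for c in raw], dtype=int)
    nbins = X.shape[1] // N_SUB
    centers: dict[str, np.ndarray] = {}
    for j, s in enumerate(SUBUNITS):
        block = X[:, j * nbins: (j + 1) * nbins]
        centers[s] = np.vstack(
            [block[labels == c].mean(axis=0) for c in range(1, k + 1)]
        )
    codes = pd.Series(m.codes)
    tab = pd.crosstab(pd.Series(labels, name="cluster"), codes)
    pct = tab.div(tab.sum(axis=1), axis=0) * 100.0
    return ClusterProfile(
        labels=labels, k=k, centers=centers,
        wcss=float(km.inertia_), cluster_pattern_pct=pct,
    )


def attach_profiles(m: OccupancyMatrix, table: pd.DataFrame) -> OccupancyMatrix:
    """Attach summit-centred signal profiles from a tabular source.

    ``table`` needs columns chrom, start, end, subunit and bin columns
    ``b00..``; rows are matched to unified regions by exact
    (chrom, start, end).  Every region must have a profile for all 4
    subunits (profiles are expected on the unified regions themselves).
    """
    bin_cols = sorted(c for c in table.columns if c.startswith("b"))
    if not bin_cols:
        raise ValueError("profile table has no bin columns (b00..)")
    keyed = {
        (r.chrom, r.start, r.end, r.subunit): i
        for i, r in enumerate(table.itertuples(index=False))
    }
    mat = table[bin_cols].to_numpy(dtype=float)
    profiles: dict[str, np.ndarray] = {}
    for s in SUBUNITS:
        rows = np.empty((len(m), len(bin_cols)))
        for i, reg in enumerate(m.regions):
            key = (reg.chrom, reg.start, reg.end, s)
            if key not in keyed:
                raise ValueError(
                    f"missing profile for {reg.chrom}:{reg.start}-{reg.end} / {s}"
                )
            rows[i] = mat[keyed[key]]
        profiles[s] = rows
    m.profiles = profiles
    return m


@dataclass
class CistromeComparison:
    """Overlap of two occupancy matrices, subunit-wise and by pattern."""

    per_subunit: dict[str, float]       # fraction of A's s-regions hit in B
    mean_overlap: float                 # over subunits present in both
    patterns: pd.DataFrame              # side-by-side pattern percentages


def _interval_tree(regions: Iterable[GenomicRegion]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    return trees


def compare_cistromes(mA: OccupancyMatrix, mB: OccupancyMatrix) -> CistromeComparison:
    """overlap(s) = fraction of A's subunit-s regions intersecting (>=1 bp)
    at least one of B's subunit-s regions; the mean is taken over subunits
    with regions in both matrices."""
    if len(mA) == 0 or len(mB) == 0:
        raise ValueError("both occupancy matrices must be non-empty")
    per: dict[str, float] = {}
    used: list[float] = []
    for s in SUBUNITS:
        a_regs = [r for r, has in zip(mA.regions, mA.subunit_column(s)) if has]
        b_regs = [r for r, has in zip(mB.regions, mB.subunit_column(s)) if has]
        if not a_regs or not b_regs:
            per[s] = float("nan")
            continue
        trees = _interval_tree(b_regs)
        hit = sum(
            1 for r in a_regs
            if r.chrom in trees and trees[r.chrom].overlaps(r.start, r.end)
        )
        per[s] = hit / len(a_regs)
        used.append(per[s])
    fa, fb = pattern_frequencies(mA), pattern_frequencies(mB)
    pat = fa.table.set_index("code")[["count", "pct"]].join(
        fb.table.set_index("code")[["count", "pct"]],
        how="outer", lsuffix="_A", rsuffix="_B",
    ).fillna(0.0)
    return CistromeComparison(
        per_subunit=per,
        mean_overlap=float(np.mean(used)) if used else float("nan"),
        patterns=pat.reset_index(),
    )
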