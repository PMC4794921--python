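"""Synthetic toy datasets with planted ground truth for the whole pipeline.

The generator emulates, at desk scale, the statistical structure of the
three data layers the pipeline integrates:

* a 4-subunit cistrome — binding regions planted with controlled
  combinatorial pattern frequencies, placed proximal (±2 kb of a TSS) or
  distal (10–100 kb away, with a chromatin loop linking the region to its
  target promoter and a DHS site covering it);
* a 4-group knockdown transcriptome — per-gene regulation status drawn from
  a known logistic model on the gene's (pattern, stratum) binding features,
  expressed as mean shifts in the knockdown groups of a log2 intensity
  matrix;
* a multi-entity lymphoma expression panel with planted concordant and
  discordant target genes and a planted low-expression stratum.

Every function is deterministic given its seed.  Planted regions are kept
non-overlapping and clear of non-target TSSs, so the unified-region,
assignment and design-matrix layers reproduce the planted structure
exactly; the planted logistic coefficients are then recoverable by the
regression module, which is the pipeline's core parameter-recovery loop.
"""

from __future__ import annotations

import json
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from . import SUBUNITS
from .cistrome_combinatorics import ALL_PATTERNS
from .formats_io import ExpressionMatrix, Gene, GeneAnnotation, GenomicRegion, Loop

#: pattern frequencies of the default cistrome: p50/p52 dominate, 41 % of
#: regions bind p50 or p52 alone, exclusive prototypic dimers (1010/0101)
#: are rare (~2 % each) and RelA-containing patterns are the least frequent.
DEFAULT_PATTERN_FREQS: dict[str, float] = {
    "1000": 0.25, "0100": 0.16,
    "1100": 0.20, "1101": 0.12, "1111": 0.07, "1110": 0.02,
    "1010": 0.02, "0101": 0.02,
    "0110": 0.02, "0111": 0.02, "1011": 0.02, "1001": 0.02,
    "0010": 0.01, "0001": 0.03, "0011": 0.02,
}

#: generating log-odds coefficients per pathway over (pattern, stratum)
#: features: regulation is driven by combined p50/p52 binding (with or
#: without the Rel subunits), RelA-containing patterns act proximally only,
#: and the exclusive prototypic dimers carry no effect.
DEFAULT_BETA: dict[str, dict[str, float]] = {
    "canonical": {
        "1111|proximal": 2.0,
        "1101|proximal": 1.5,
        "1100|proximal": 1.0,
    },
    "noncanonical": {
        "1101|proximal": 1.5,
        "1101|distal": 1.5,
        "1100|proximal": 1.5,
        "1100|distal": 1.0,
        "1111|proximal": 1.0,
    },
}

DEFAULT_INTERCEPT: dict[str, float] = {"canonical": -2.0, "noncanonical": -1.5}

#: fraction of regulated genes that are activated (expression falls on
#: knockdown); the remainder are repressed.
DEFAULT_ACTIVATED_FRAC = 0.7

PROFILE_WINDOW = 500      # summit ± window covered by signal profiles, bp
PROFILE_NBINS = 50        # 20-bp bins


@dataclass
class SimTruth:
    """Planted ground truth of one synthetic dataset.

    ``regions`` is ordered by (chrom, start, end) so its row index equals
    the region index of the unified occupancy matrix built from the emitted
    peak sets.  ``genes`` is filled by :func:`draw_regulation` (or by
    :func:`simulate_knockdown_expression`).
    """

    regions: pd.DataFrame            # chrom,start,end,summit,pattern,stratum,gene
    beta: dict[str, dict[str, float]]
    intercept: dict[str, float]
    activated_frac: float
    seed: int
    loops: list[Loop] = field(default_factory=list)
    dhs: list[GenomicRegion] = field(default_factory=list)
    genes: pd.DataFrame | None = None
    sigma: float | None = None

    def gene_features(self) -> dict[str, set[str]]:
        """Per-gene set of '(pattern)|(stratum)' binding features."""
        feats: dict[str, set[str]] = {}
        for row in self.regions.itertuples(index=False):
            feats.setdefault(row.gene, set()).add(f"{row.pattern}|{row.stratum}")
        return feats

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "activated_frac": self.activated_frac,
            "sigma": self.sigma,
            "beta": self.beta,
            "intercept": self.intercept,
            "regions": self.regions.to_dict(orient="list"),
            "genes": None if self.genes is None
            else self.genes.reset_index().to_dict(orient="list"),
            "loops": [
                [lp.anchor_a.chrom, lp.anchor_a.start, lp.anchor_a.end,
                 lp.anchor_b.chrom, lp.anchor_b.start, lp.anchor_b.end]
                for lp in self.loops
            ],
            "dhs": [[r.chrom, r.start, r.end] for r in self.dhs],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        genes = None
        if payload["genes"] is not None:
            genes = pd.DataFrame(payload["genes"]).set_index("gene")
        return cls(
            regions=pd.DataFrame(payload["regions"]),
            beta=payload["beta"],
            intercept=payload["intercept"],
            activated_frac=payload["activated_frac"],
            seed=payload["seed"],
            loops=[
                Loop(GenomicRegion(a, b, c), GenomicRegion(d, e, f))
                for a, b, c, d, e, f in payload["loops"]
            ],
            dhs=[GenomicRegion(a, b, c) for a, b, c in payload["dhs"]],
            genes=genes,
            sigma=payload["sigma"],
        )


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(
    n_genes: int,
    chrom_length: int,
    seed: int,
    chrom: str = "chrS",
    clusters_per_gene: tuple[int, int] = (1, 3),
) -> GeneAnnotation:
    """Place ``n_genes`` genes on a single toy chromosome.

    Genes sit in evenly spaced slots with jittered TSSs (no collisions),
    alternating strands, each carrying 1–3 transcript clusters and a small
    exon structure.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    slot = chrom_length // n_genes
    if slot < 4000:
        raise ValueError(
            f"genome too small: {chrom_length} bp for {n_genes} genes "
            f"({slot} bp/gene; need >= 4000)"
        )
    rng = np.random.default_rng(seed)
    genes = []
    jitter = slot // 10
    for i in range(n_genes):
        gid = f"g{i + 1:05d}"
        tss = i * slot + slot // 2 + int(rng.integers(-jitter, jitter + 1))
        strand = "+" if i % 2 == 0 else "-"
        body_len = int(rng.integers(2000, min(8000, slot // 2) + 1))
        if strand == "+":
            start, end = tss, tss + body_len
        else:
            start, end = tss + 1 - body_len, tss + 1
        exons = ((start, start + 300), (end - 300, end))
        n_tc = int(rng.integers(clusters_per_gene[0], clusters_per_gene[1] + 1))
        clusters = tuple(f"{gid}.tc{j + 1}" for j in range(n_tc))
        genes.append(
            Gene(gid, chrom, strand, tss, start=start, end=end,
                 exons=exons, clusters=clusters)
        )
    return GeneAnnotation(genes)


# ---------------------------------------------------------------------------
# cistrome
# ---------------------------------------------------------------------------

def _profile_bins() -> np.ndarray:
    width = 2 * PROFILE_WINDOW // PROFILE_NBINS
    return np.arange(PROFILE_NBINS) * width - PROFILE_WINDOW + width / 2


def simulate_cistrome(
    annotation: GeneAnnotation,
    pattern_freqs: Mapping[str, float] | None = None,
    proximal_frac: float = 0.6,
    n_regions: int = 1000,
    seed: int = 0,
    region_width: int = 300,
    proximal_jitter: int = 2000,
    distal_range: tuple[int, int] = (10_000, 100_000),
    tss_clear: int = 6000,
    min_gap: int = 1000,
) -> tuple[dict[str, list[GenomicRegion]], pd.DataFrame, SimTruth]:
    """Plant ``n_regions`` binding regions with known patterns and placement.

    Pattern counts follow a multinomial over ``pattern_freqs`` (the 15
    non-empty 4-bit codes; must sum to 1).  Each region targets one gene:
    proximal placement is uniform within ±2 kb of its TSS; distal placement
    uniform in 10–100 kb with a loop linking the region to the promoter.
    Regions are non-overlapping, separated by ``min_gap`` and kept more than
    ``tss_clear`` bp away from every non-target TSS so downstream assignment
    is unambiguous.  Every planted region is covered by an emitted DHS site.

    Returns per-subunit peak lists, a per-(region, subunit) signal-profile
    table (high summit-centred enrichment iff the subunit is present), and
    the :class:`SimTruth` record (regions sorted by coordinate).
    """
    freqs = dict(DEFAULT_PATTERN_FREQS if pattern_freqs is None else pattern_freqs)
    unknown = set(freqs) - set(ALL_PATTERNS)
    if unknown:
        raise ValueError(f"unknown pattern code(s): {sorted(unknown)}")
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"pattern frequencies sum to {total}, expected 1")
    if not 0.0 <= proximal_frac <= 1.0:
        raise ValueError("proximal_frac must be in [0, 1]")
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")

    rng = np.random.default_rng(seed)
    patterns = sorted(freqs)
    counts = rng.multinomial(n_regions, [freqs[p] for p in patterns])
    planted_patterns = [p for p, c in zip(patterns, counts) for _ in range(c)]

    gene_ids = sorted(annotation.genes)
    by_chrom_tss: dict[str, np.ndarray] = {
        c: annotation.tss_by_chrom(c)[0] for c in annotation.chroms()
    }
    chrom_max: dict[str, int] = {
        c: max(g.end for g in annotation.genes.values() if g.chrom == c)
        + distal_range[1] + region_width
        for c in annotation.chroms()
    }
    occupied: dict[str, list[tuple[int, int]]] = {}

    def placeable(chrom: str, start: int, end: int) -> bool:
        ivs = occupied.setdefault(chrom, [])
        i = bisect_left(ivs, (start, end))
        if i > 0 and ivs[i - 1][1] + min_gap > start:
            return False
        if i < len(ivs) and ivs[i][0] < end + min_gap:
            return False
        return True

    def tss_clearance(chrom: str, summit: int, skip_tss: int | None) -> bool:
        pos = by_chrom_tss[chrom]
        j = int(np.searchsorted(pos, summit))
        for k in (j - 1, j, j + 1):
            if 0 <= k < len(pos):
                t = int(pos[k])
                if skip_tss is not None and t == skip_tss:
                    continue
                if abs(summit - t) <= tss_clear:
                    return False
        return True

    half = region_width // 2
    rows = []
    loops: list[Loop] = []
    dhs: list[GenomicRegion] = []
    for pattern in planted_patterns:
        placed = False
        for _ in range(300):
            gene = annotation.genes[gene_ids[int(rng.integers(len(gene_ids)))]]
            proximal = bool(rng.random() < proximal_frac)
            if proximal:
                summit = gene.tss + int(
                    rng.integers(-proximal_jitter, proximal_jitter + 1)
                )
                if not tss_clearance(gene.chrom, summit, skip_tss=gene.tss):
                    continue
            else:
                offset = int(rng.integers(distal_range[0], distal_range[1] + 1))
                sign = 1 if rng.random() < 0.5 else -1
                summit = gene.tss + sign * offset
                if not tss_clearance(gene.chrom, summit, skip_tss=None):
                    continue
            start, end = summit - half, summit - half + region_width
            if start < 0 or end > chrom_max[gene.chrom]:
                continue
            if not placeable(gene.chrom, start, end):
                continue
            insort(occupied[gene.chrom], (start, end))
            rows.append(
                {
                    "chrom": gene.chrom, "start": start, "end": end,
                    "summit": summit, "pattern": pattern,
                    "stratum": "proximal" if proximal else "distal",
                    "gene": gene.gene_id,
                }
            )
            if not proximal:
                loops.append(
                    Loop(
                        GenomicRegion(gene.chrom, start, end),
                        GenomicRegion(gene.chrom, gene.tss - 250, gene.tss + 250),
                    )
                )
            dhs.append(GenomicRegion(gene.chrom, max(0, start - 100), end + 100))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "could not place a region after 300 attempts; "
                "genome too crowded for n_regions"
            )

    regions = pd.DataFrame(rows).sort_values(
        ["chrom", "start", "end"], ignore_index=True
    )

    peaksets: dict[str, list[GenomicRegion]] = {s: [] for s in SUBUNITS}
    centers = _profile_bins()
    prof_rows = []
    for row in regions.itertuples(index=False):
        for j, s in enumerate(SUBUNITS):
            present = row.pattern[j] == "1"
            if present:
                peaksets[s].append(
                    GenomicRegion(
                        row.chrom, row.start, row.end,
                        summit=row.summit - row.start,
                        score=float(rng.uniform(5.0, 15.0)),
                    )
                )
            amp = float(rng.uniform(8.0, 12.0)) if present else 0.0
            noise = rng.normal(0.0, 0.1, PROFILE_NBINS)
            signal = amp * np.exp(-(centers ** 2) / (2 * 150.0 ** 2)) + np.abs(noise)
            prof = {
                "chrom": row.chrom, "start": row.start, "end": row.end,
                "subunit": s,
            }
            prof.update({f"b{i:02d}": float(v) for i, v in enumerate(signal)})
            prof_rows.append(prof)
    profiles = pd.DataFrame(prof_rows)

    truth = SimTruth(
        regions=regions,
        beta={k: dict(v) for k, v in DEFAULT_BETA.items()},
        intercept=dict(DEFAULT_INTERCEPT),
        activated_frac=DEFAULT_ACTIVATED_FRAC,
        seed=seed,
        loops=loops,
        dhs=sorted(dhs, key=lambda r: (r.chrom, r.start, r.end)),
    )
    return peaksets, profiles, truth


# ---------------------------------------------------------------------------
# regulation and knockdown expression
# ---------------------------------------------------------------------------

def draw_regulation(
    annotation: GeneAnnotation, truth: SimTruth, seed: int
) -> pd.DataFrame:
    """Draw per-gene regulation status from the generating logistic model.

    For each pathway, P(regulated) = expit(intercept + Σ β over the gene's
    (pattern, stratum) features); genes without binding regions are never
    regulated.  A regulated gene is activated with probability
    ``truth.activated_frac`` (shared across pathways), else repressed.
    Direct-target flags require a region whose pattern contains p50
    (canonical) or p52 (non-canonical).  Fills and returns ``truth.genes``.
    """
    rng = np.random.default_rng(seed)
    feats = truth.gene_features()
    rows = []
    for gid in sorted(annotation.genes):
        fs = feats.get(gid, set())
        row: dict[str, object] = {"gene": gid, "features": ";".join(sorted(fs))}
        any_reg = False
        for pathway in ("canonical", "noncanonical"):
            if fs:
                eta = truth.intercept[pathway] + sum(
                    truth.beta[pathway].get(f, 0.0) for f in fs
                )
                reg = bool(rng.random() < expit(eta))
            else:
                reg = False
            row[f"{pathway}_regulated"] = reg
            any_reg = any_reg or reg
        direction = (
            ("activated" if rng.random() < truth.activated_frac else "repressed")
            if any_reg else "none"
        )
        row["direction"] = direction
        for pathway, pos in (("canonical", 0), ("noncanonical", 1)):
            bound = any(f.split("|")[0][pos] == "1" for f in fs)
            row[f"direct_{pathway}"] = bool(row[f"{pathway}_regulated"]) and bound
            row[f"{pathway}_direction"] = (
                direction if row[f"{pathway}_regulated"] else "none"
            )
        rows.append(row)
    truth.genes = pd.DataFrame(rows).set_index("gene")
    return truth.genes


GROUP_LABELS = ("Group1", "Group2", "Group3", "Group4")


def simulate_knockdown_expression(
    annotation: GeneAnnotation,
    truth: SimTruth,
    n_reps: int = 3,
    effect_log2: float = 1.0,
    sigma: float = 0.25,
    seed: int = 0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.0,
) -> ExpressionMatrix:
    """Simulate the 4-group knockdown design at transcript-cluster level.

    Groups 1/2 are control and canonical (p50/RelA) knockdown, groups 3/4
    control and non-canonical (p52/RelB) knockdown; each group holds
    2 siRNA variants × ``n_reps`` replicates.  Genes activated by a pathway
    have their clusters shifted −``effect_log2`` in that pathway's knockdown
    group (expression falls on depletion); repressed genes are shifted
    +``effect_log2``.  All entries carry i.i.d. Normal(0, sigma) noise on a
    Normal(baseline_mean, baseline_sd) per-cluster baseline.

    Regulation status is drawn via :func:`draw_regulation` unless
    ``truth.genes`` is already populated.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    if truth.genes is None:
        draw_regulation(annotation, truth, seed=int(rng.integers(2 ** 31)))
    truth.sigma = sigma

    clusters = []
    for gid in sorted(annotation.genes):
        clusters.extend(annotation.genes[gid].clusters)
    n_per_group = 2 * n_reps
    columns = [
        f"s{g + 1}_{j + 1}" for g in range(4) for j in range(n_per_group)
    ]
    groups = {
        f"s{g + 1}_{j + 1}": GROUP_LABELS[g]
        for g in range(4) for j in range(n_per_group)
    }
    baseline = rng.normal(baseline_mean, baseline_sd, len(clusters))
    data = baseline[:, None] + rng.normal(
        0.0, sigma, (len(clusters), len(columns))
    )
    col_group = np.array([groups[c] for c in columns])
    genes_tbl = truth.genes
    for i, tc in enumerate(clusters):
        gid = annotation.cluster_to_gene[tc]
        row = genes_tbl.loc[gid]
        sign = None
        if row["direction"] == "activated":
            sign = -1.0
        elif row["direction"] == "repressed":
            sign = +1.0
        if sign is None:
            continue
        if bool(row["canonical_regulated"]):
            data[i, col_group == "Group2"] += sign * effect_log2
        if bool(row["noncanonical_regulated"]):
            data[i, col_group == "Group4"] += sign * effect_log2
    values = pd.DataFrame(data, index=pd.Index(clusters, name="cluster"),
                          columns=columns)
    return ExpressionMatrix(values, groups)


def simulate_two_group_matrix(
    n_rows: int,
    n_per_group: int,
    n_effect: int,
    effect_log2: float,
    sigma: float,
    seed: int,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.0,
) -> tuple[ExpressionMatrix, GeneAnnotation, list[str]]:
    """Minimal control-vs-knockdown matrix for calibration studies.

    The first ``n_effect`` rows get a control − knockdown difference of
    ``effect_log2`` (alternating sign by row); the rest are null.  Returns
    the matrix, a one-cluster-per-gene annotation, and the planted row ids.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    row_ids = [f"r{i + 1:05d}" for i in range(n_rows)]
    cols = [f"c{j + 1}" for j in range(n_per_group)] + [
        f"k{j + 1}" for j in range(n_per_group)
    ]
    groups = {c: ("control" if c.startswith("c") else "knockdown") for c in cols}
    baseline = rng.normal(baseline_mean, baseline_sd, n_rows)
    data = baseline[:, None] + rng.normal(0.0, sigma, (n_rows, len(cols)))
    planted = row_ids[:n_effect]
    for i in range(n_effect):
        sign = 1.0 if i % 2 == 0 else -1.0
        data[i, n_per_group:] -= sign * effect_log2
    values = pd.DataFrame(data, index=pd.Index(row_ids, name="cluster"),
                          columns=cols)
    genes = [
        Gene(f"gene_{rid}", "chrS", "+", 1000 + 10_000 * i,
             clusters=(rid,))
        for i, rid in enumerate(row_ids)
    ]
    return ExpressionMatrix(values, groups), GeneAnnotation(genes), planted


# ---------------------------------------------------------------------------
# lymphoma panel
# ---------------------------------------------------------------------------

REST_ENTITIES = ("DLBCL", "FL", "BL", "NLPHL", "GC_B")


@dataclass
class PanelTruth:
    """Planted structure of the synthetic lymphoma panel."""

    concordant: list[str]
    discordant: list[str]
    low_expressed: list[str]
    seed: int


def simulate_lymphoma_panel(
    targets: pd.DataFrame,
    n_hl: int = 10,
    n_other: int = 30,
    concordant_frac: float = 0.5,
    floor: float = 6.0,
    seed: int = 0,
    n_background: int = 120,
    low_frac: float = 0.1,
    effect_log2: float = 2.0,
    sigma: float = 0.25,
) -> tuple[ExpressionMatrix, PanelTruth]:
    """Simulate a HL-vs-other-entities expression panel over direct targets.

    ``targets`` is a :class:`~nfkbmap.knockdown_transcriptome.TargetGeneTable`
    table.  A ``concordant_frac`` fraction of the direct targets (rounded) is
    planted concordant — activated targets higher in HL columns, repressed
    targets lower — and the remaining targets are planted *discordant*
    (shifted the opposite way), so they are differentially expressed but
    fail the direction match.  ``low_frac`` of the background genes sit
    below the low-expression ``floor``.  Target baselines are kept above the
    floor so the filter never removes a planted target.
    """
    if n_hl < 2 or n_other < 2:
        raise ValueError("n_hl and n_other must each be >= 2")
    if not 0.0 <= concordant_frac <= 1.0:
        raise ValueError("concordant_frac must be in [0, 1]")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(seed)

    is_direct = targets["direct_canonical"] | targets["direct_noncanonical"]
    direct = targets.index[is_direct].tolist()
    directions = {}
    for g in direct:
        row = targets.loc[g]
        if row["direct_canonical"]:
            directions[g] = row["canonical_direction"]
        else:
            directions[g] = row["noncanonical_direction"]
    n_conc = int(round(concordant_frac * len(direct)))
    conc = sorted(
        rng.choice(np.array(sorted(direct)), size=n_conc, replace=False).tolist()
    ) if direct else []
    disc = sorted(set(direct) - set(conc))

    background = [f"bg{i + 1:04d}" for i in range(n_background)]
    n_low = int(round(low_frac * n_background))
    low = background[:n_low]

    rows = sorted(direct) + background
    cols = [f"HL_{j + 1}" for j in range(n_hl)] + [
        f"{REST_ENTITIES[j % len(REST_ENTITIES)]}_{j + 1}" for j in range(n_other)
    ]
    groups = {c: ("HL" if c.startswith("HL_") else c.split("_")[0]) for c in cols}

    baseline = np.empty(len(rows))
    for i, g in enumerate(rows):
        if g in low:
            baseline[i] = rng.normal(4.0, 0.5)
        elif g in directions:
            baseline[i] = max(float(rng.normal(8.5, 0.5)), 6.6)
        else:
            baseline[i] = rng.normal(8.0, 1.0)
    data = baseline[:, None] + rng.normal(0.0, sigma, (len(rows), len(cols)))
    hl_cols = np.array([c.startswith("HL_") for c in cols])
    for i, g in enumerate(rows):
        if g not in directions:
            continue
        concordant = g in conc
        up_in_hl = (directions[g] == "activated") == concordant
        data[i, hl_cols] += effect_log2 if up_in_hl else -effect_log2
    values = pd.DataFrame(data, index=pd.Index(rows, name="gene"), columns=cols)
    return (
        ExpressionMatrix(values, groups),
        PanelTruth(concordant=conc, discordant=disc, low_expressed=low, seed=seed),
    )
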