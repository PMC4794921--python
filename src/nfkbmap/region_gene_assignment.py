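"""Assignment of unified binding regions to genes (proximal / distal).

A region is linked *proximally* to every gene whose TSS lies within
±proximal_window of the region summit.  It is linked *distally* to a gene
when it overlaps one anchor of a chromatin loop whose other anchor lies
within proximal_window of the gene's TSS; when a DHS (open-chromatin) set is
supplied, distal links additionally require the region to overlap a DHS
site.  Proximal links stand on TSS distance alone.  A region may link to
several genes; regions with no link are simply absent from the link set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .cistrome_combinatorics import OccupancyMatrix
from .formats_io import GeneAnnotation, GenomicRegion, Loop


@dataclass(frozen=True)
class RegionGeneLink:
    """One (region, gene) assignment.

    ``distance`` is the signed bp distance from the region summit to the
    TSS, negative upstream of the gene with respect to its strand.
    ``stratum`` is ``proximal`` (|distance| <= proximal_window, evidence
    ``tss-window``) or ``distal`` (evidence ``loop``).
    """

    region_index: int
    gene_id: str
    stratum: str
    evidence: str
    distance: int


def _signed_distance(summit: int, tss: int, strand: str) -> int:
    return summit - tss if strand == "+" else tss - summit


def assign_regions(
    m: OccupancyMatrix,
    ann: GeneAnnotation,
    dhs: Sequence[GenomicRegion] = (),
    loops: Iterable[Loop] = (),
    proximal_window: int = 5000,
    max_distal: int = 250_000,
) -> list[RegionGeneLink]:
    """Link unified regions to genes; see module docstring for the rules."""
    if proximal_window >= max_distal:
        raise ValueError("proximal_window must be < max_distal")
    links: dict[tuple[int, str], RegionGeneLink] = {}

    summits = np.array([r.abs_summit for r in m.regions], dtype=np.int64)

    # --- proximal links: TSS within +-proximal_window of the summit -------
    for i, r in enumerate(m.regions):
        pos, ids = ann.tss_by_chrom(r.chrom)
        if len(pos) == 0:
            continue
        lo = int(np.searchsorted(pos, summits[i] - proximal_window, "left"))
        hi = int(np.searchsorted(pos, summits[i] + proximal_window, "right"))
        for k in range(lo, hi):
            gene = ann.genes[ids[k]]
            d = _signed_distance(int(summits[i]), gene.tss, gene.strand)
            links[(i, gene.gene_id)] = RegionGeneLink(
                i, gene.gene_id, "proximal", "tss-window", d
            )

    # --- distal links: loop anchors, optionally gated on DHS overlap ------
    loops = list(loops)
    if loops:
        region_tree: dict[str, IntervalTree] = {}
        for i, r in enumerate(m.regions):
            region_tree.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, i)
        dhs_tree: dict[str, IntervalTree] = {}
        for d_reg in dhs:
            dhs_tree.setdefault(d_reg.chrom, IntervalTree()).addi(
                d_reg.start, d_reg.end
            )

        def in_dhs(r: GenomicRegion) -> bool:
            if not dhs:
                return True
            tree = dhs_tree.get(r.chrom)
            return tree is not None and tree.overlaps(r.start, r.end)

        for lp in loops:
            for region_anchor, gene_anchor in (
                (lp.anchor_a, lp.anchor_b),
                (lp.anchor_b, lp.anchor_a),
            ):
                tree = region_tree.get(region_anchor.chrom)
                if tree is None:
                    continue
                hits = tree.overlap(region_anchor.start, region_anchor.end)
                if not hits:
                    continue
                pos, ids = ann.tss_by_chrom(gene_anchor.chrom)
                if len(pos) == 0:
                    continue
                lo = int(np.searchsorted(
                    pos, gene_anchor.start - proximal_window, "left"))
                hi = int(np.searchsorted(
                    pos, gene_anchor.end + proximal_window, "right"))
                for iv in hits:
                    i = iv.data
                    if not in_dhs(m.regions[i]):
                        continue
                    for k in range(lo, hi):
                        gene = ann.genes[ids[k]]
                        d = _signed_distance(
                            int(summits[i]), gene.tss, gene.strand)
                        if abs(d) <= proximal_window:
                            continue  # already covered by the proximal rule
                        if abs(d) > max_distal:
                            continue
                        links.setdefault(
                            (i, gene.gene_id),
                            RegionGeneLink(i, gene.gene_id, "distal", "loop", d),
                        )

    return sorted(
        links.values(), key=lambda ln: (ln.region_index, ln.gene_id)
    )


def links_to_frame(links: Iterable[RegionGeneLink], m: OccupancyMatrix) -> pd.DataFrame:
    codes = m.codes
    rows = [
        {
            "region_index": ln.region_index,
            "chrom": m.regions[ln.region_index].chrom,
            "start": m.regions[ln.region_index].start,
            "end": m.regions[ln.region_index].end,
            "code": codes[ln.region_index],
            "gene": ln.gene_id,
            "stratum": ln.stratum,
            "evidence": ln.evidence,
            "distance": ln.distance,
        }
        for ln in links
    ]
    return pd.DataFrame(
        rows,
        columns=["region_index", "chrom", "start", "end", "code",
                 "gene", "stratum", "evidence", "distance"],
    )
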