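"""Brute-force reference implementations used to cross-check the fast paths.

These oracles are deliberately naive (O(n²) pairwise overlap, union-find
merging, set algebra on explicit region sets) and share no code with the
package's sweep/interval-tree implementations.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from nfkbmap import SUBUNITS
from nfkbmap.formats_io import GenomicRegion


def overlap_len(a: GenomicRegion, b: GenomicRegion) -> int:
    if a.chrom != b.chrom:
        return 0
    return min(a.end, b.end) - max(a.start, b.start)


def brute_force_unify(
    peaksets: dict[str, list[GenomicRegion]], min_overlap: int = 1
) -> tuple[list[tuple[str, int, int]], list[str]]:
    """Union-find single-linkage merge over all pairwise overlaps.

    Returns sorted merged intervals and their 4-bit pattern codes.
    """
    items = [(r, s) for s, regs in peaksets.items() for r in regs]
    n = len(items)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            if overlap_len(items[i][0], items[j][0]) >= min_overlap:
                union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged = []
    for members in groups.values():
        regs = [items[i][0] for i in members]
        subs = {items[i][1] for i in members}
        code = "".join("1" if s in subs else "0" for s in SUBUNITS)
        merged.append(
            (regs[0].chrom, min(r.start for r in regs),
             max(r.end for r in regs), code)
        )
    merged.sort()
    return [(c, s, e) for c, s, e, _ in merged], [code for *_, code in merged]


def brute_force_pattern_counts(codes: list[str]) -> dict[str, int]:
    return dict(Counter(codes))


def brute_force_sharing(codes: list[str]) -> dict[str, float]:
    """shared(s) from explicit code strings."""
    out = {}
    for i, s in enumerate(SUBUNITS):
        with_s = [c for c in codes if c[i] == "1"]
        if not with_s:
            out[s] = float("nan")
            continue
        out[s] = sum(1 for c in with_s if c.count("1") >= 2) / len(with_s)
    return out


def brute_force_pairwise(codes: list[str]) -> dict[tuple[str, str], float]:
    out = {}
    for i, s in enumerate(SUBUNITS):
        with_s = [c for c in codes if c[i] == "1"]
        for j, t in enumerate(SUBUNITS):
            if not with_s:
                out[(s, t)] = float("nan")
            else:
                out[(s, t)] = sum(1 for c in with_s if c[j] == "1") / len(with_s)
    return out


def brute_force_compare(
    a_regions: list[GenomicRegion], a_codes: list[str],
    b_regions: list[GenomicRegion], b_codes: list[str],
) -> dict[str, float]:
    """Per-subunit fraction of A's subunit regions hit by any of B's."""
    out = {}
    for i, s in enumerate(SUBUNITS):
        a_s = [r for r, c in zip(a_regions, a_codes) if c[i] == "1"]
        b_s = [r for r, c in zip(b_regions, b_codes) if c[i] == "1"]
        if not a_s or not b_s:
            out[s] = float("nan")
            continue
        hit = sum(
            1 for ra in a_s if any(overlap_len(ra, rb) >= 1 for rb in b_s)
        )
        out[s] = hit / len(a_s)
    return out


def random_peaksets(
    seed: int,
    n_per_subunit: int = 50,
    span: int = 10_000,
    max_len: int = 400,
    chroms: tuple[str, ...] = ("chrS",),
) -> dict[str, list[GenomicRegion]]:
    rng = np.random.default_rng(seed)
    peaksets: dict[str, list[GenomicRegion]] = {}
    for s in SUBUNITS:
        regs = []
        n = int(rng.integers(1, n_per_subunit + 1))
        for _ in range(n):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, span))
            length = int(rng.integers(1, max_len))
            regs.append(
                GenomicRegion(chrom, start, start + length,
                              score=float(rng.uniform(0, 10)))
            )
        peaksets[s] = regs
    return peaksets


def bh_stepup(pvalues: list[float]) -> list[float]:
    """Hand-applied BH step-up: q_i = min_{j>=i}(p_(j) * m / j), on the
    sorted p-values, mapped back to input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q_sorted = [0.0] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = q_sorted[rank]
    return out
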