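"""Differential expression and direct-target calling for the knockdown design.

The expression design has four groups: Group1/Group2 are control and
p50/RelA (canonical) knockdown of experiment 1; Group3/Group4 are control
and p52/RelB (non-canonical) knockdown of experiment 2.  Each experiment is
tested strictly within itself (control vs knockdown, never pooled) with a
per-transcript-cluster two-sample t-test (Welch by default) and
Benjamini–Hochberg adjustment over all clusters tested in that experiment.

A gene is called regulated when at least one of its transcript clusters is
differential (q < alpha) with at least a ``min_diff`` (default 10 %)
expression difference on the linear scale, i.e. |Δlog2| >= log2(1+min_diff).
Direction follows the sign of control − knockdown: a positive difference
means expression falls when the subunits are depleted, i.e. the gene is
activated by NF-κB.

A *direct* target additionally requires binding: at least one assigned
region containing p50 for the canonical pathway, or p52 for the
non-canonical pathway.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import SUBUNITS
from .cistrome_combinatorics import OccupancyMatrix
from .formats_io import ExpressionMatrix, GeneAnnotation
from .region_gene_assignment import RegionGeneLink

PATHWAYS = ("canonical", "noncanonical")

#: knockdown subunit whose binding makes a regulated gene a *direct* target
PATHWAY_BOUND_SUBUNIT = {"canonical": "p50", "noncanonical": "p52"}


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def test_differential(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Row-wise two-sample t-test of group_a vs group_b with BH adjustment.

    Returns a frame indexed by row id with columns ``diff`` (mean_a −
    mean_b, log2), ``t``, ``pvalue``, ``qvalue``.  Rows with zero variance
    in both groups get p = 1 when the means are equal and p = 0 otherwise.
    Welch's unequal-variance test is the default; set ``equal_var=True``
    for the pooled-variance variant.
    """
    sa = expr.samples_in_group(group_a)
    sb = expr.samples_in_group(group_b)
    for label, ss in ((group_a, sa), (group_b, sb)):
        if len(ss) < 2:
            raise ValueError(f"group {label!r} has {len(ss)} sample(s); need >= 2")
    A = expr.values[sa].to_numpy(dtype=float)
    B = expr.values[sb].to_numpy(dtype=float)
    diff = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=equal_var)
        degenerate = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
        if degenerate.any():
            same = degenerate & (diff == 0)
            t = np.where(same, 0.0, t)
            p = np.where(same, 1.0, p)
            apart = degenerate & (diff != 0)
            t = np.where(apart, np.sign(diff) * np.inf, t)
            p = np.where(apart, 0.0, p)
    q = bh_adjust(p)
    return pd.DataFrame(
        {"diff": diff, "t": t, "pvalue": p, "qvalue": q},
        index=expr.values.index,
    )


def call_regulated_genes(
    results: pd.DataFrame,
    ann: GeneAnnotation,
    alpha: float = 0.05,
    min_diff: float = 0.10,
) -> pd.DataFrame:
    """Collapse per-cluster test results to per-gene regulation calls.

    A gene is regulated when at least one of its transcript clusters has
    q < alpha and |diff| >= log2(1 + min_diff).  The reported evidence is
    the qualifying cluster with the smallest q (ties: larger |diff|).
    Clusters not mapped to any gene are excluded with a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    log2_cut = math.log2(1.0 + min_diff)
    mapped = results.index.to_series().map(ann.cluster_to_gene)
    unmapped = results.index[mapped.isna()]
    if len(unmapped):
        warnings.warn(
            f"{len(unmapped)} transcript cluster(s) not mapped to a gene; "
            f"excluded (e.g. {unmapped[0]!r})",
            stacklevel=2,
        )
    res = results.loc[mapped.notna()].copy()
    res["gene"] = mapped.loc[mapped.notna()]
    rows = []
    for gene, sub in res.groupby("gene", sort=True):
        ok = sub[(sub["qvalue"] < alpha) & (sub["diff"].abs() >= log2_cut)]
        if len(ok):
            best = ok.sort_values(
                ["qvalue", "diff"],
                key=lambda s: s if s.name == "qvalue" else -s.abs(),
            ).iloc[0]
            rows.append(
                {
                    "gene": gene,
                    "regulated": True,
                    "direction": "activated" if best["diff"] > 0 else "repressed",
                    "best_cluster": best.name,
                    "best_q": float(best["qvalue"]),
                    "best_diff": float(best["diff"]),
                }
            )
        else:
            best = sub.sort_values("qvalue").iloc[0]
            rows.append(
                {
                    "gene": gene,
                    "regulated": False,
                    "direction": "none",
                    "best_cluster": best.name,
                    "best_q": float(best["qvalue"]),
                    "best_diff": float(best["diff"]),
                }
            )
    return pd.DataFrame(rows).set_index("gene")


@dataclass
class TargetGeneTable:
    """Per-gene regulation and direct-target status for both pathways.

    ``table`` is indexed by gene with columns
    ``{pathway}_regulated``, ``{pathway}_direction``, ``direct_{pathway}``;
    only genes regulated in at least one pathway are listed.  ``venn``
    counts direct targets in the four (pathway × direction) sets.
    """

    table: pd.DataFrame
    venn: dict[str, int]


def define_direct_targets(
    calls: Mapping[str, pd.DataFrame],
    links: Iterable[RegionGeneLink],
    m: OccupancyMatrix,
) -> TargetGeneTable:
    """Join per-pathway regulation calls with binding evidence.

    ``calls`` maps pathway name → the frame from :func:`call_regulated_genes`.
    A canonical direct target is regulated under p50/RelA knockdown and has
    at least one linked region with the p50 indicator set; non-canonical
    analogously with p52.
    """
    unknown = set(calls) - set(PATHWAYS)
    if unknown:
        raise ValueError(f"unknown pathway name(s): {sorted(unknown)}")
    bound: dict[str, dict[str, bool]] = {p: {} for p in PATHWAYS}
    n = len(m)
    for ln in links:
        if not 0 <= ln.region_index < n:
            raise ValueError(f"link region index {ln.region_index} out of range")
        for pathway, subunit in PATHWAY_BOUND_SUBUNIT.items():
            j = SUBUNITS.index(subunit)
            if m.indicators[ln.region_index, j]:
                bound[pathway][ln.gene_id] = True

    genes = sorted(
        set().union(*(set(df.index[df["regulated"]]) for df in calls.values()))
        if calls else set()
    )
    rows = []
    for gene in genes:
        row: dict[str, object] = {"gene": gene}
        for pathway in PATHWAYS:
            df = calls.get(pathway)
            if df is not None and gene in df.index and bool(df.loc[gene, "regulated"]):
                reg, direction = True, str(df.loc[gene, "direction"])
            else:
                reg, direction = False, "none"
            row[f"{pathway}_regulated"] = reg
            row[f"{pathway}_direction"] = direction
            row[f"direct_{pathway}"] = reg and bound[pathway].get(gene, False)
        rows.append(row)
    table = pd.DataFrame(
        rows,
        columns=["gene"]
        + [f"{p}_{c}" for p in PATHWAYS for c in ("regulated", "direction")]
        + [f"direct_{p}" for p in PATHWAYS],
    ).set_index("gene") if rows else pd.DataFrame(
        columns=[f"{p}_{c}" for p in PATHWAYS for c in ("regulated", "direction")]
        + [f"direct_{p}" for p in PATHWAYS]
    )
    venn = {}
    for pathway in PATHWAYS:
        for direction in ("activated", "repressed"):
            key = f"{pathway}_{direction}"
            if len(table):
                venn[key] = int(
                    (
                        table[f"direct_{pathway}"]
                        & (table[f"{pathway}_direction"] == direction)
                    ).sum()
                )
            else:
                venn[key] = 0
    return TargetGeneTable(table=table, venn=venn)
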