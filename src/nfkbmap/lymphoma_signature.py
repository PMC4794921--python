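"""Concordance of NF-κB target calls with a multi-entity lymphoma panel.

The panel (HL, other lymphoma entities, normal B cells; log2 intensities)
is first stripped of low-expression genes (mean over all samples below a
floor, default 6.0, strict less-than).  HL is then tested against all
remaining samples with the same per-row t-test / BH / ≥10 % difference rule
used for the knockdown data.  Direct NF-κB targets that are differential in
HL are kept when the change is *concordant*: activated by NF-κB and up in
HL, or repressed and down in HL.  Genes are classified canonical-only /
both / non-canonical-only from their direct-target flags, and a row-ordered
log2 submatrix is exported for heat-map display.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .formats_io import ExpressionMatrix
from .knockdown_transcriptome import TargetGeneTable, test_differential


def filter_low_expression(
    panel: ExpressionMatrix, floor: float = 6.0
) -> ExpressionMatrix:
    """Remove rows whose mean over *all* samples is below ``floor``
    (strict <); warns when nothing survives."""
    means = panel.values.mean(axis=1)
    keep = means >= floor
    if not keep.any():
        warnings.warn("all genes fall below the expression floor", stacklevel=2)
    return ExpressionMatrix(panel.values.loc[keep], dict(panel.groups))


def hl_vs_rest(
    panel: ExpressionMatrix,
    hl_label: str = "HL",
    alpha: float = 0.05,
    min_diff: float = 0.10,
    equal_var: bool = False,
) -> pd.DataFrame:
    """HL vs all-remaining differential expression at gene level.

    Returns a frame indexed by gene: ``diff`` (HL − rest, log2), ``qvalue``,
    ``called`` (q < alpha and |diff| >= log2(1+min_diff)), ``hl_direction``
    (up/down/none).
    """
    relabelled = ExpressionMatrix(
        panel.values,
        {s: (hl_label if g == hl_label else "rest")
         for s, g in panel.groups.items()},
    )
    res = test_differential(relabelled, hl_label, "rest", equal_var=equal_var)
    cut = math.log2(1.0 + min_diff)
    called = (res["qvalue"] < alpha) & (res["diff"].abs() >= cut)
    out = res[["diff", "t", "pvalue", "qvalue"]].copy()
    out["called"] = called
    out["hl_direction"] = "none"
    out.loc[called & (out["diff"] > 0), "hl_direction"] = "up"
    out.loc[called & (out["diff"] < 0), "hl_direction"] = "down"
    out.index.name = "gene"
    return out


PATHWAY_CLASS_ORDER = ("canonical-only", "both", "non-canonical-only")


@dataclass
class ConcordanceTable:
    """Concordant direct targets with pathway class and directions.

    ``table``: per gene — pathway_class, nfkb_direction, hl_direction,
    concordant flag.  ``heatmap``: log2 panel submatrix of the concordant
    genes, row-ordered by pathway class then NF-κB direction.
    """

    table: pd.DataFrame
    heatmap: pd.DataFrame | None


def concordant_targets(
    targets: TargetGeneTable,
    hl_de: pd.DataFrame,
    panel: ExpressionMatrix | None = None,
) -> ConcordanceTable:
    """Intersect direct targets with HL-differential genes; keep concordant.

    Concordant ⟺ (activated by NF-κB and up in HL) or (repressed and down).
    The NF-κB direction of a gene is taken over the pathways in which it is
    a direct target; genes whose two pathways disagree are excluded.
    """
    if len(targets.table) == 0 or len(hl_de) == 0:
        raise ValueError("targets and HL differential-expression calls "
                         "must be non-empty")
    rows = []
    for gene, row in targets.table.iterrows():
        dc, dn = bool(row["direct_canonical"]), bool(row["direct_noncanonical"])
        if not (dc or dn):
            continue
        dirs = set()
        if dc:
            dirs.add(row["canonical_direction"])
        if dn:
            dirs.add(row["noncanonical_direction"])
        if len(dirs) != 1:
            continue  # conflicting per-pathway directions
        nfkb_dir = dirs.pop()
        if gene not in hl_de.index or not bool(hl_de.loc[gene, "called"]):
            continue
        hl_dir = str(hl_de.loc[gene, "hl_direction"])
        concordant = (nfkb_dir == "activated" and hl_dir == "up") or (
            nfkb_dir == "repressed" and hl_dir == "down"
        )
        if not concordant:
            continue
        if dc and dn:
            pclass = "both"
        elif dc:
            pclass = "canonical-only"
        else:
            pclass = "non-canonical-only"
        rows.append(
            {
                "gene": gene, "pathway_class": pclass,
                "nfkb_direction": nfkb_dir, "hl_direction": hl_dir,
                "concordant": True,
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene", "pathway_class", "nfkb_direction",
                       "hl_direction", "concordant"]
    )
    if len(table):
        table["pathway_class"] = pd.Categorical(
            table["pathway_class"], categories=list(PATHWAY_CLASS_ORDER),
            ordered=True,
        )
        table = table.sort_values(
            ["pathway_class", "nfkb_direction", "gene"], ignore_index=True
        )
    heatmap = None
    if panel is not None and len(table):
        present = [g for g in table["gene"] if g in panel.values.index]
        heatmap = panel.values.loc[present]
    return ConcordanceTable(table=table.set_index("gene"), heatmap=heatmap)
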