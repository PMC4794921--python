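"""Logistic regression of regulation mode on combinatorial subunit occupancy.

Each gene with at least one assigned binding region contributes a row; the
predictors are binary indicators, one per observed (4-bit pattern code,
proximal/distal stratum) pair — the gene sets a feature when at least one of
its linked regions carries exactly that pattern in that stratum.  Four
outcome contrasts are supported:

* ``noncanonical-vs-none`` / ``canonical-vs-none`` — regulated genes of the
  named pathway against bound-but-unregulated genes (genes regulated only by
  the other pathway are excluded);
* ``canonical-vs-noncanonical`` — genes regulated by exactly one pathway;
* ``activated-vs-repressed`` — regulated genes only, by direction.

Coefficients of the maximum-likelihood fit are log odds ratios with Wald
95 % confidence intervals.  Features affected by (quasi-)perfect separation
— an empty cell in the feature × outcome table — are reported with a missing
estimate instead of a divergent one.  Bootstrap stability is the fraction of
gene-resampled refits in which a coefficient stays significant (P < 0.01);
coefficients with stability >= 0.90 are flagged stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cistrome_combinatorics import OccupancyMatrix
from .knockdown_transcriptome import PATHWAYS
from .region_gene_assignment import RegionGeneLink

CONTRASTS = (
    "noncanonical-vs-none",
    "canonical-vs-none",
    "canonical-vs-noncanonical",
    "activated-vs-repressed",
)

SIGNIFICANCE_LEVEL = 0.01
STABILITY_CUTOFF = 0.90


def feature_name(code: str, stratum: str) -> str:
    return f"{code}|{stratum}"


@dataclass
class PatternDesignMatrix:
    """Genes × (pattern, stratum) indicators with a binary outcome."""

    X: pd.DataFrame          # 0/1 indicators, index = gene ids
    y: pd.Series             # binary outcome aligned with X
    contrast: str
    not_observed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("X and y must share the same gene index")


def _gene_directions(regulation: pd.DataFrame) -> pd.Series:
    """Consolidated per-gene direction over the regulated pathways;
    conflicting directions yield 'conflict'."""
    out = {}
    for gene, row in regulation.iterrows():
        dirs = {
            row[f"{p}_direction"]
            for p in PATHWAYS
            if row.get(f"{p}_regulated", False)
        }
        if not dirs:
            out[gene] = "none"
        elif len(dirs) == 1:
            out[gene] = dirs.pop()
        else:
            out[gene] = "conflict"
    return pd.Series(out)


def build_design_matrix(
    links: Iterable[RegionGeneLink],
    m: OccupancyMatrix,
    regulation: pd.DataFrame,
    contrast: str,
    min_class: int = 10,
) -> PatternDesignMatrix:
    """Assemble the genes × (pattern, stratum) design for one contrast.

    ``regulation`` is indexed by gene with boolean ``{pathway}_regulated``
    and ``{pathway}_direction`` columns (e.g. ``TargetGeneTable.table``);
    linked genes absent from it count as unregulated.  Feature columns that
    are all-zero on the selected rows are dropped and recorded in
    ``not_observed``.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; one of {CONTRASTS}")
    codes = m.codes
    features: dict[str, set[str]] = {}
    linked_genes: set[str] = set()
    for ln in links:
        linked_genes.add(ln.gene_id)
        features.setdefault(ln.gene_id, set()).add(
            feature_name(codes[ln.region_index], ln.stratum)
        )

    def is_reg(gene: str, pathway: str) -> bool:
        if gene not in regulation.index:
            return False
        return bool(regulation.loc[gene, f"{pathway}_regulated"])

    rows: dict[str, int] = {}
    if contrast in ("noncanonical-vs-none", "canonical-vs-none"):
        pathway = contrast.split("-")[0]
        other = "canonical" if pathway == "noncanonical" else "noncanonical"
        for g in sorted(linked_genes):
            if is_reg(g, pathway):
                rows[g] = 1
            elif not is_reg(g, other):
                rows[g] = 0
            # regulated only by the other pathway: excluded
    elif contrast == "canonical-vs-noncanonical":
        for g in sorted(linked_genes):
            can, non = is_reg(g, "canonical"), is_reg(g, "noncanonical")
            if can != non:
                rows[g] = 1 if can else 0
    else:  # activated-vs-repressed
        directions = _gene_directions(regulation)
        for g in sorted(linked_genes):
            d = directions.get(g, "none")
            if d == "activated":
                rows[g] = 1
            elif d == "repressed":
                rows[g] = 0

    genes = list(rows)
    all_feats = sorted(
        {f for g in genes for f in features.get(g, ())},
        key=lambda f: (f.split("|")[0], f.split("|")[1] != "proximal"),
    )
    X = pd.DataFrame(0, index=pd.Index(genes, name="gene"),
                     columns=all_feats, dtype=int)
    for g in genes:
        for f in features.get(g, ()):
            X.loc[g, f] = 1
    y = pd.Series([rows[g] for g in genes], index=X.index, name=contrast)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if min(n0, n1) < min_class:
        raise ValueError(
            f"contrast {contrast!r} has class sizes {n1} vs {n0}; "
            f"need >= {min_class} in each — provide a larger input"
        )
    keep = [c for c in X.columns if X[c].any()]
    not_observed = [c for c in X.columns if c not in keep]
    return PatternDesignMatrix(X[keep], y, contrast, not_observed)


@dataclass
class RegressionReport:
    """Per-feature log-odds estimates, Wald CIs/P, and bootstrap stability.

    ``table`` is indexed by feature name with columns pattern, stratum,
    estimate, ci_low, ci_high, pvalue, significant, stability, stable,
    status (``ok`` | ``separated`` | ``not_observed``).  ``intercept``
    holds the fitted intercept (NaN when the fit failed entirely).
    """

    table: pd.DataFrame
    intercept: float
    contrast: str


def _separated_features(X: pd.DataFrame, y: pd.Series) -> list[str]:
    """Features with an empty cell in the feature × outcome 2×2 table, which
    drives the corresponding MLE coefficient to ±infinity."""
    bad = []
    yv = y.to_numpy(dtype=bool)
    for c in X.columns:
        xv = X[c].to_numpy(dtype=bool)
        if xv.sum() == 0:
            bad.append(c)
            continue
        n11 = int((xv & yv).sum())
        n10 = int((xv & ~yv).sum())
        if n11 == 0 or n10 == 0:
            bad.append(c)
    return bad


def _fit_ok(
    X: pd.DataFrame, y: pd.Series
) -> tuple[object | None, list[str]]:
    """Fit on the separation-cleaned design; returns (result, fitted columns).

    Columns are iteratively moved to the separated set when the fit fails to
    converge or produces a degenerate standard error.
    """
    cols = [c for c in X.columns if c not in _separated_features(X, y)]
    for _ in range(len(X.columns) + 1):
        if y.nunique() < 2:
            return None, []
        design = sm.add_constant(X[cols].astype(float), has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.Logit(y.astype(float), design)
                res = model.fit(disp=0, maxiter=200)
        except Exception:
            res = None
        if res is not None and bool(res.mle_retvals.get("converged", True)):
            bse = res.bse.drop("const", errors="ignore")
            wild = bse.index[(bse > 30) | (res.params.drop("const").abs() > 15)]
            if len(wild) == 0:
                return res, cols
            cols = [c for c in cols if c not in set(wild)]
        else:
            # drop the rarest remaining feature and retry
            if not cols:
                return None, []
            counts = X[cols].sum()
            cols = [c for c in cols if c != counts.idxmin()]
    return None, []


def fit_logistic(d: PatternDesignMatrix, ridge: float = 0.0) -> RegressionReport:
    """Maximum-likelihood logistic fit with intercept; Wald 95 % CIs.

    Features flagged by the separation pre-check (or dropped during the
    convergence loop) are reported with status ``separated`` and missing
    estimates; features never observed in the data carry status
    ``not_observed``.  ``ridge > 0`` switches to an L2-penalised fit
    (estimates only, no CIs), useful when separation is pervasive.
    """
    if d.y.nunique() < 2:
        raise ValueError("outcome has a single class; cannot fit")
    if ridge > 0:
        return _fit_ridge(d, ridge)
    res, fitted_cols = _fit_ok(d.X, d.y)
    rows = []
    if res is not None:
        ci = res.conf_int(alpha=0.05)
        intercept = float(res.params["const"])
    else:
        intercept = float("nan")
    for c in list(d.X.columns) + d.not_observed:
        code, stratum = c.split("|")
        if c in d.not_observed:
            status = "not_observed"
        elif res is not None and c in fitted_cols:
            status = "ok"
        else:
            status = "separated"
        if status == "ok":
            est = float(res.params[c])
            lo, hi = float(ci.loc[c, 0]), float(ci.loc[c, 1])
            p = float(res.pvalues[c])
            sig = p < SIGNIFICANCE_LEVEL
        else:
            est = lo = hi = p = float("nan")
            sig = False
        rows.append(
            {
                "feature": c, "pattern": code, "stratum": stratum,
                "estimate": est, "ci_low": lo, "ci_high": hi,
                "pvalue": p, "significant": sig,
                "stability": float("nan"), "stable": False,
                "status": status,
            }
        )
    table = pd.DataFrame(rows).set_index("feature")
    return RegressionReport(table=table, intercept=intercept, contrast=d.contrast)


def _fit_ridge(d: PatternDesignMatrix, ridge: float) -> RegressionReport:
    design = sm.add_constant(d.X.astype(float), has_constant="add")
    model = sm.GLM(d.y.astype(float), design, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit_regularized(alpha=ridge, L1_wt=0.0)
    rows = []
    for c in list(d.X.columns) + d.not_observed:
        code, stratum = c.split("|")
        observed = c in d.X.columns
        rows.append(
            {
                "feature": c, "pattern": code, "stratum": stratum,
                "estimate": float(res.params[c]) if observed else float("nan"),
                "ci_low": float("nan"), "ci_high": float("nan"),
                "pvalue": float("nan"), "significant": False,
                "stability": float("nan"), "stable": False,
                "status": "ok" if observed else "not_observed",
            }
        )
    return RegressionReport(
        table=pd.DataFrame(rows).set_index("feature"),
        intercept=float(res.params["const"]),
        contrast=d.contrast,
    )


def bootstrap_stability(
    d: PatternDesignMatrix,
    B: int = 1000,
    seed: int = 0,
    alpha: float = SIGNIFICANCE_LEVEL,
) -> pd.Series:
    """Fraction of gene-resampled refits in which each feature has P < alpha.

    Genes are resampled with replacement; features separated or absent in a
    resample count as not significant there.  Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(d.y)
    hits = pd.Series(0.0, index=d.X.columns)
    Xv, yv = d.X.to_numpy(), d.y.to_numpy()
    for _ in range(B):
        idx = rng.integers(0, n, n)
        Xb = pd.DataFrame(Xv[idx], columns=d.X.columns)
        yb = pd.Series(yv[idx])
        if yb.nunique() < 2:
            continue
        res, fitted_cols = _fit_ok(Xb, yb)
        if res is None:
            continue
        for c in fitted_cols:
            if float(res.pvalues[c]) < alpha:
                hits[c] += 1
    return hits / B


def add_stability(report: RegressionReport, stability: pd.Series) -> RegressionReport:
    """Return a copy of the report with stability fractions and flags filled."""
    table = report.table.copy()
    table["stability"] = stability.reindex(table.index)
    table["stable"] = table["stability"] >= STABILITY_CUTOFF
    return RegressionReport(table=table, intercept=report.intercept,
                            contrast=report.contrast)


def prototype_dimer_check(report: RegressionReport) -> pd.DataFrame:
    """Summary of the exclusive prototypic-dimer features p50-RelA (``1010``)
    and p52-RelB (``0101``) — the headline negative-control readout."""
    rows = []
    for code in ("1010", "0101"):
        sub = report.table[report.table["pattern"] == code]
        if len(sub) == 0:
            rows.append(
                {
                    "pattern": code, "stratum": "any",
                    "estimate": float("nan"), "pvalue": float("nan"),
                    "significant": False, "status": "not_observed",
                }
            )
            continue
        for feat, r in sub.iterrows():
            rows.append(
                {
                    "pattern": code, "stratum": r["stratum"],
                    "estimate": r["estimate"], "pvalue": r["pvalue"],
                    "significant": bool(r["significant"]),
                    "status": r["status"],
                }
            )
    return pd.DataFrame(rows)
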