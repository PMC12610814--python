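"""Mutation-vs-selection diagnostics: ENC-plot, PR2, neutrality, correlations.

Each diagnostic reduces the per-gene profiles to the summary a codon-usage
study reports: how far observed ENC sits from the GC3 null curve (and the
ENC-ratio census inside/outside the +/-0.05 window), where genes fall on the
PR2 plane relative to the unbiased centre (0.5, 0.5), the slope of the
GC12-on-GC3 neutrality regression, and Pearson correlation tables between
composition variables across genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .indices import GeneCUBProfile, profiles_to_frame

__all__ = ["ENCPlotResult", "NeutralityResult", "CorrelationTable",
           "enc_plot", "pr2_points", "neutrality", "correlation_table"]


@dataclass
class ENCPlotResult:
    """Per-gene ENC-plot coordinates and the ENC-ratio window census."""

    table: pd.DataFrame          # gene, GC3, ENC, ENC_exp, ENC_ratio, class
    window: float
    enc_threshold: float
    n_inside: int
    n_outside: int
    n_high_enc: int              # genes with observed ENC > threshold
    excluded: list               # genes with undefined ENC

    @property
    def n_defined(self) -> int:
        return self.n_inside + self.n_outside

    @property
    def frac_inside(self) -> float:
        return self.n_inside / self.n_defined if self.n_defined else float("nan")

    @property
    def frac_outside(self) -> float:
        return self.n_outside / self.n_defined if self.n_defined else float("nan")


def enc_plot(profiles, window: float = 0.05,
             enc_threshold: float = 45.0) -> ENCPlotResult:
    """ENC-ratio classification of a profiled gene set.

    ENC_ratio = (expected - observed)/expected per gene; |ratio| <= window
    is classified "inside" (mutation-dominated), otherwise "outside"
    (selection-dominated).  Genes with undefined ENC are excluded and
    reported.
    """
    if not profiles:
        raise ValueError("enc_plot needs at least one profiled gene")
    rows, excluded = [], []
    for p in profiles:
        if not math.isfinite(p.enc_obs):
            excluded.append(p.gene_id)
            continue
        rows.append({
            "gene": p.gene_id, "GC3": p.composition.gc3, "ENC": p.enc_obs,
            "ENC_exp": p.enc_exp, "ENC_ratio": p.enc_ratio,
            "class": "inside" if abs(p.enc_ratio) <= window else "outside",
        })
    table = pd.DataFrame(rows)
    n_in = int((table["class"] == "inside").sum()) if len(table) else 0
    n_out = len(table) - n_in
    n_high = int((table["ENC"] > enc_threshold).sum()) if len(table) else 0
    return ENCPlotResult(table=table, window=window,
                         enc_threshold=enc_threshold, n_inside=n_in,
                         n_outside=n_out, n_high_enc=n_high,
                         excluded=excluded)


def pr2_points(profiles, categories: dict | None = None) -> pd.DataFrame:
    """PR2-plot coordinates per gene with quadrant assignment.

    x = G3/(G3+C3), y = A3/(A3+T3); quadrants are named relative to the
    unbiased centre (0.5, 0.5), e.g. "lower_right" means G3 > C3 and
    T3 > A3.  Genes with an empty denominator get NaN on that axis and the
    quadrant "undefined".
    """
    rows = []
    for p in profiles:
        x, y = p.pr2_x, p.pr2_y
        if math.isfinite(x) and math.isfinite(y):
            vert = "upper" if y >= 0.5 else "lower"
            horiz = "right" if x >= 0.5 else "left"
            quad = f"{vert}_{horiz}"
        else:
            quad = "undefined"
        rows.append({"gene": p.gene_id, "x": x, "y": y, "quadrant": quad,
                     "category": (categories or {}).get(p.gene_id, "")})
    return pd.DataFrame(rows)


@dataclass
class NeutralityResult:
    """GC12-on-GC3 regression summary across genes."""

    table: pd.DataFrame          # gene, GC3, GC12
    slope: float
    intercept: float
    r: float
    p: float
    n_below_diagonal: int        # strictly below y = x
    n_above_diagonal: int        # on or above y = x (ties count as above)


def neutrality(profiles) -> NeutralityResult:
    """Neutrality plot: OLS of GC12 on GC3 with Pearson r and two-tailed p.

    A slope near 1 (genes tracking the diagonal) indicates mutation pressure
    dominates; near 0, selection.  With all GC3 identical the slope is
    undefined (NaN).
    """
    if len(profiles) < 3:
        raise ValueError("neutrality regression needs at least 3 genes")
    gc3 = np.array([p.composition.gc3 for p in profiles])
    gc12 = np.array([p.composition.gc12 for p in profiles])
    table = pd.DataFrame({"gene": [p.gene_id for p in profiles],
                          "GC3": gc3, "GC12": gc12})
    if np.allclose(gc3, gc3[0]):
        slope = intercept = r = p = float("nan")
    else:
        fit = stats.linregress(gc3, gc12)
        slope, intercept, r, p = fit.slope, fit.intercept, fit.rvalue, fit.pvalue
    below = int(np.sum(gc12 < gc3))
    return NeutralityResult(table=table, slope=slope, intercept=intercept,
                            r=r, p=p, n_below_diagonal=below,
                            n_above_diagonal=len(profiles) - below)


@dataclass
class CorrelationTable:
    """Pearson r / two-tailed p matrices between profile variables."""

    r: pd.DataFrame
    p: pd.DataFrame

    def stars(self) -> pd.DataFrame:
        """Significance marks as in the field's tables: * p<0.05, ** p<0.01."""
        def mark(p):
            if not math.isfinite(p):
                return ""
            if p < 0.01:
                return "**"
            if p < 0.05:
                return "*"
            return ""
        return self.p.map(mark)

    def annotated(self) -> pd.DataFrame:
        s = self.stars()
        return self.r.round(3).astype(str).add(" ").add(s).apply(
            lambda col: col.str.strip())


def correlation_table(profiles, rows, cols) -> CorrelationTable:
    """Pearson correlations across genes between two variable lists.

    Variables name columns of the profile frame (A, T, G, C, GC, A3...GC3,
    GC12, SCUO, ENC, CAI, MILC).  p-values come from the exact t transform
    of r with n-2 degrees of freedom, two-tailed; a zero-variance variable
    yields NaN for its pairs.
    """
    frame = (profiles if isinstance(profiles, pd.DataFrame)
             else profiles_to_frame(profiles))
    missing = [v for v in list(rows) + list(cols) if v not in frame.columns]
    if missing:
        raise KeyError(f"unknown profile variables: {missing}")
    if len(frame) < 3:
        raise ValueError("correlation table needs at least 3 genes")
    r = pd.DataFrame(index=list(rows), columns=list(cols), dtype=float)
    p = pd.DataFrame(index=list(rows), columns=list(cols), dtype=float)
    for a in rows:
        for b in cols:
            x, y = frame[a].to_numpy(float), frame[b].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                r.loc[a, b] = p.loc[a, b] = float("nan")
                continue
            res = stats.pearsonr(x[ok], y[ok])
            r.loc[a, b] = res.statistic
            p.loc[a, b] = res.pvalue
    return CorrelationTable(r=r, p=p)
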