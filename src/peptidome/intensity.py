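"""Log10 precursor-intensity comparisons across treatment panels.

Log10 transformation of precursor intensity is approximately normal, so
treatment means with standard errors, one-way ANOVA across treatments,
and an additive two-way ANOVA (treatment + peptide, Type II sums of
squares) are the comparison tools.  Quantile/box-plot style exports are
emitted as tables; rendering is left to the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.formula.api import ols

from .model import PSMRecord, TreatmentDesign, ValidationError


@dataclass(frozen=True)
class FactorEffect:
    name: str
    df: float
    sum_sq: float
    mean_sq: float
    F: float
    pvalue: float


@dataclass(frozen=True)
class AnovaResult:
    """Fixed-effects decomposition: per-factor effects plus residual."""

    factors: tuple
    residual_df: float
    residual_ss: float
    degenerate: bool = False
    ss_type: str = "I"

    def factor(self, name: str) -> FactorEffect:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)


def to_intensity_records(
    psms: Iterable[PSMRecord], design: TreatmentDesign | None = None
) -> pd.DataFrame:
    """Per-PSM log10 intensity table keyed by treatment, symbol, peptide."""
    design = design or TreatmentDesign.default_panel()
    rows = []
    for p in psms:
        label = design.label(p.treatment_id)  # raises on unknown id
        rows.append(
            {
                "treatment_id": p.treatment_id,
                "treatment_label": label,
                "gene_symbol": p.gene_symbol,
                "peptide": p.peptide,
                "log10_intensity": math.log10(p.precursor_intensity),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "treatment_id",
            "treatment_label",
            "gene_symbol",
            "peptide",
            "log10_intensity",
        ],
    )


def treatment_means(
    records: pd.DataFrame,
    symbol: str | None = None,
    peptide_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean / SE / N of log10 intensity per treatment.

    SE = sd/sqrt(n) with the n-1 (sample) standard deviation; emitted as
    missing when n = 1.  Treatments with no records are omitted; an
    empty restriction yields an empty table.
    """
    df = records
    if symbol is not None:
        df = df[df["gene_symbol"] == symbol]
    if peptide_subset is not None:
        df = df[df["peptide"].isin(set(peptide_subset))]
    if df.empty:
        return pd.DataFrame(columns=["treatment_id", "mean", "se", "n"])
    g = df.groupby("treatment_id")["log10_intensity"]
    out = pd.DataFrame(
        {
            "treatment_id": g.mean().index,
            "mean": g.mean().to_numpy(),
            "se": (g.std(ddof=1) / np.sqrt(g.size())).to_numpy(),
            "n": g.size().to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def anova_oneway(
    records: pd.DataFrame,
    response: str = "log10_intensity",
    factor: str = "treatment_id",
) -> AnovaResult:
    """One-way fixed-effects ANOVA via the explicit sum-of-squares
    decomposition: SS_total = SS_between + SS_within.

    Degenerate cases: equal group means give F = 0, p = 1; zero
    within-group variance with unequal means gives F = inf, p = 0 and a
    degeneracy flag.
    """
    groups = [g.to_numpy(dtype=float) for _, g in records.groupby(factor)[response]]
    if len(groups) < 2:
        raise ValidationError(f"anova_oneway needs >= 2 levels of {factor!r}")
    n = sum(len(g) for g in groups)
    if n - len(groups) < 1:
        raise ValidationError("at least one group must have >= 2 records")
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = n - len(groups)
    ms_between = ss_between / df_between
    degenerate = False
    if ss_within == 0.0:
        if math.isclose(ss_between, 0.0, abs_tol=1e-300):
            F, p = 0.0, 1.0
        else:
            F, p, degenerate = math.inf, 0.0, True
        ms_within = 0.0
    else:
        ms_within = ss_within / df_within
        F = ms_between / ms_within
        p = float(stats.f.sf(F, df_between, df_within))
        if ss_between == 0.0:
            F, p = 0.0, 1.0
    return AnovaResult(
        factors=(
            FactorEffect(factor, df_between, float(ss_between), float(ms_between), float(F), float(p)),
        ),
        residual_df=float(df_within),
        residual_ss=float(ss_within),
        degenerate=degenerate,
        ss_type="I",
    )


def anova_twoway(
    records: pd.DataFrame,
    response: str = "log10_intensity",
    factors: tuple[str, str] = ("treatment_id", "peptide"),
) -> AnovaResult:
    """Additive two-way fixed-effects ANOVA (no interaction), Type II SS.

    The additive model keeps the fit estimable when many factor-level
    cells are empty, which is the norm for treatment x peptide layouts.
    """
    fa, fb = factors
    for f in factors:
        if records[f].nunique() < 2:
            raise ValidationError(f"factor {f!r} has a single level")
    df = records[[response, fa, fb]].copy()
    df.columns = ["y", "A", "B"]
    y = df["y"].to_numpy(dtype=float)
    # total variation at rounding-noise level: constant response
    ss_total = float(((y - y.mean()) ** 2).sum())
    constant = ss_total <= 1e-24 * len(y) * (1.0 + y.mean() ** 2)
    model = ols("y ~ C(A) + C(B)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    effects = []
    for term, name in (("C(A)", fa), ("C(B)", fb)):
        row = table.loc[term]
        ss = float(row["sum_sq"])
        dof = float(row["df"])
        F, p = float(row["F"]), float(row["PR(>F)"])
        if constant:
            ss, F, p = 0.0, 0.0, 1.0
        elif math.isnan(F):  # zero residual variance: 0/0 or x/0
            if math.isclose(ss, 0.0, abs_tol=1e-24):
                F, p = 0.0, 1.0
            else:
                F, p = math.inf, 0.0
        effects.append(
            FactorEffect(
                name=name,
                df=dof,
                sum_sq=ss,
                mean_sq=ss / dof if dof else math.nan,
                F=F,
                pvalue=p,
            )
        )
    resid = table.loc["Residual"]
    return AnovaResult(
        factors=tuple(effects),
        residual_df=float(resid["df"]),
        residual_ss=float(resid["sum_sq"]),
        ss_type="II",
    )


def export_distribution(
    records: pd.DataFrame,
    group: str = "treatment_id",
    response: str = "log10_intensity",
) -> dict:
    """Per-group sorted samples and five-number box-plot summaries.

    Quantiles use linear interpolation between order statistics (the
    numpy default), stated in the returned metadata because the
    convention matters for small n.  Empty groups are omitted.
    """
    out = {"quantile_convention": "linear interpolation", "groups": {}}
    if records.empty:
        return out
    for key, g in records.groupby(group)[response]:
        vals = np.sort(g.to_numpy(dtype=float))
        if vals.size == 0:
            continue
        q = np.percentile(vals, [0, 25, 50, 75, 100])
        out["groups"][key] = {
            "sorted": vals,
            "min": float(q[0]),
            "q1": float(q[1]),
            "median": float(q[2]),
            "q3": float(q[3]),
            "max": float(q[4]),
            "n": int(vals.size),
        }
    return out
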