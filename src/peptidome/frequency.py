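"""Observation-frequency comparison: the core chi-square screen.

A protein's observation frequency is the number of retained
spectrum-to-peptide correlations attributed to its gene symbol in a
treatment.  Because the two arms are sampled to different depths, the
control counts are first rescaled by the ratio of total retained
correlations (case/control).  Each symbol is then screened with the
pseudocounted one-cell statistic

    chi2 = (count_case - corrected_control)^2 / (corrected_control + 1)

referred to the chi-square distribution at 1 degree of freedom for a
nominal p-value, with Benjamini-Hochberg FDR control within each
peptide stream.  Candidates are symbols with a corrected count
difference >= 9 and chi2 >= 25 (p <= 0.001) by default.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import prepare, select_engine, split_streams
from .model import (
    STREAMS,
    STYP,
    TRYP,
    FilterConfig,
    PSMRecord,
    SelectionConfig,
    StreamTotals,
    ValidationError,
)

# Smallest positive normal double: underflow floor keeping p in (0, 1].
_P_FLOOR = float(np.finfo(float).tiny)


def count_frequency(psms: Iterable[PSMRecord]) -> dict[str, int]:
    """Tally retained correlations per gene symbol.

    Each PSM contributes to exactly one symbol, so the counts sum to the
    number of input records.
    """
    counts: Counter[str] = Counter()
    for p in psms:
        if not p.gene_symbol:
            raise ValidationError(f"spectrum {p.spectrum_id}: empty gene_symbol")
        counts[p.gene_symbol] += 1
    return dict(counts)


def stream_totals(
    case_psms: Sequence[PSMRecord], control_psms: Sequence[PSMRecord]
) -> StreamTotals:
    """Retained-correlation totals: the normalization denominators."""
    return StreamTotals(total_case=len(case_psms), total_control=len(control_psms))


def correct_control(count_control: float, totals: StreamTotals) -> float:
    """Rescale a control count to the case sampling depth."""
    if count_control < 0:
        raise ValidationError("count_control must be >= 0")
    return count_control * totals.correction_factor


def chi_square_eq1(count_case: float, corrected_control: float) -> float:
    """The pseudocounted one-cell chi-square statistic.

    ``(case - corrected control)^2 / (corrected control + 1)``.  The +1
    pseudocount keeps the statistic finite for symbols absent from the
    control arm and makes it conservative at low counts.
    """
    if count_case < 0 or corrected_control < 0:
        raise ValidationError("counts must be >= 0")
    delta = count_case - corrected_control
    return (delta * delta) / (corrected_control + 1.0)


def chi2_pvalue(chi2: float, df: int = 1) -> float:
    """Upper-tail chi-square probability (nominal, df=1 by default).

    Floored at the smallest normal double so downstream FDR adjustment
    always receives p in (0, 1].
    """
    if chi2 < 0:
        raise ValidationError("chi2 must be >= 0")
    return max(float(stats.chi2.sf(chi2, df)), _P_FLOOR)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j on the sorted p-values, clipped
    to 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def average_chi_per_symbol(frame: pd.DataFrame) -> pd.DataFrame:
    """Aggregate accession-level rows to one row per (symbol, stream).

    Counts are summed across accessions; two chi-square summaries are
    emitted: ``chi2`` recomputed from the summed counts (so the Eq.-1
    identity holds for the aggregated row) and ``chi2_mean``, the
    arithmetic mean of the accession-level values (the per-symbol
    averaging used for headline tables).
    """
    if frame.empty:
        return pd.DataFrame(
            columns=[
                "gene_symbol",
                "stream",
                "count_case",
                "count_control",
                "corrected_control",
                "delta",
                "chi2",
                "chi2_mean",
                "n_accessions",
            ]
        )
    grouped = frame.groupby(["gene_symbol", "stream"], sort=True)
    out = grouped.agg(
        count_case=("count_case", "sum"),
        count_control=("count_control", "sum"),
        corrected_control=("corrected_control", "sum"),
        chi2_mean=("chi2", "mean"),
        n_accessions=("chi2", "size"),
    ).reset_index()
    out["delta"] = out["count_case"] - out["corrected_control"]
    out["chi2"] = [
        chi_square_eq1(c, cc)
        for c, cc in zip(out["count_case"], out["corrected_control"])
    ]
    cols = [
        "gene_symbol",
        "stream",
        "count_case",
        "count_control",
        "corrected_control",
        "delta",
        "chi2",
        "chi2_mean",
        "n_accessions",
    ]
    return out[cols]


def select_candidates(
    frame: pd.DataFrame,
    config: SelectionConfig | None = None,
    chi2_col: str = "chi2",
) -> pd.DataFrame:
    """Gate rows on delta >= delta_min AND chi2 >= chi2_min (inclusive).

    Returns the selected rows ordered by descending chi-square, ties by
    symbol.
    """
    config = config or SelectionConfig()
    mask = (frame["delta"] >= config.delta_min) & (frame[chi2_col] >= config.chi2_min)
    sel = frame.loc[mask].sort_values(
        [chi2_col, "gene_symbol"], ascending=[False, True], kind="stable"
    )
    return sel.reset_index(drop=True)


def _accession_level_frame(
    case_psms: Sequence[PSMRecord],
    control_psms: Sequence[PSMRecord],
    stream: str,
    totals: StreamTotals,
) -> pd.DataFrame:
    """Per (symbol, accession) counts and chi-square in one stream."""

    def tally(psms):
        c: Counter[tuple[str, str]] = Counter()
        for p in psms:
            if not p.gene_symbol:
                raise ValidationError(f"spectrum {p.spectrum_id}: empty gene_symbol")
            c[(p.gene_symbol, p.protein_accession)] += 1
        return c

    case_counts = tally(case_psms)
    control_counts = tally(control_psms)
    keys = sorted(set(case_counts) | set(control_counts))
    rows = []
    for symbol, accession in keys:
        cc = case_counts.get((symbol, accession), 0)
        ct = control_counts.get((symbol, accession), 0)
        corrected = correct_control(ct, totals)
        rows.append(
            {
                "gene_symbol": symbol,
                "protein_accession": accession,
                "stream": stream,
                "count_case": cc,
                "count_control": ct,
                "corrected_control": corrected,
                "delta": cc - corrected,
                "chi2": chi_square_eq1(cc, corrected),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_symbol",
            "protein_accession",
            "stream",
            "count_case",
            "count_control",
            "corrected_control",
            "delta",
            "chi2",
        ],
    )


def quantile_export(frame: pd.DataFrame) -> pd.DataFrame:
    """Sorted delta and chi-square columns for quantile-style plots."""
    return pd.DataFrame(
        {
            "delta_sorted": np.sort(frame["delta"].to_numpy()),
            "chi2_sorted": np.sort(frame["chi2"].to_numpy()),
        }
    )


def run_frequency_comparison(
    case_psms: Sequence[PSMRecord],
    control_psms: Sequence[PSMRecord],
    filter_cfg: FilterConfig | None = None,
    selection_cfg: SelectionConfig | None = None,
    count_engine: str = "SEQUEST",
):
    """Full two-arm screen: filter, dedup, split streams, count,
    correct, chi-square, BH FDR, per-symbol aggregation, selection.

    When both search engines appear in an arm, counting is restricted to
    the ``count_engine`` table (engine identity from the other engine is
    annotation only).  Returns ``(tables, metadata)`` where ``tables``
    maps stream -> per-symbol DataFrame carrying a ``selected`` flag,
    and ``metadata`` records totals and correction factors per stream.
    """
    filter_cfg = filter_cfg or FilterConfig()
    selection_cfg = selection_cfg or SelectionConfig()

    def prep(psms):
        engines = {p.engine for p in psms}
        if len(engines) > 1:
            psms = select_engine(psms, count_engine)
        return prepare(psms, filter_cfg)

    case_ready = prep(case_psms)
    control_ready = prep(control_psms)
    case_by_stream = dict(zip((TRYP, STYP), split_streams(case_ready)))
    control_by_stream = dict(zip((TRYP, STYP), split_streams(control_ready)))

    wanted = STREAMS if filter_cfg.stream_mode == "both" else (filter_cfg.stream_mode,)
    tables: dict[str, pd.DataFrame] = {}
    metadata = {
        "min_intensity": filter_cfg.min_intensity,
        "chi2_min": selection_cfg.chi2_min,
        "delta_min": selection_cfg.delta_min,
        "pvalue_note": "nominal (df=1)",
        "streams": {},
    }
    for stream in wanted:
        case_s = case_by_stream[stream]
        control_s = control_by_stream[stream]
        totals = stream_totals(case_s, control_s)
        if totals.total_control == 0:
            metadata["streams"][stream] = {
                "total_case": totals.total_case,
                "total_control": 0,
                "correction_factor": None,
                "note": "correction undefined: no retained control correlations",
            }
            tables[stream] = average_chi_per_symbol(pd.DataFrame())
            continue
        acc = _accession_level_frame(case_s, control_s, stream, totals)
        table = average_chi_per_symbol(acc)
        if not table.empty:
            table["pvalue"] = [chi2_pvalue(x) for x in table["chi2"]]
            table["qvalue"] = bh_fdr(table["pvalue"].to_numpy())
            selected = select_candidates(table, selection_cfg, chi2_col="chi2_mean")
            table["selected"] = table["gene_symbol"].isin(
                set(selected["gene_symbol"])
            )
            table = table.sort_values(
                ["chi2", "gene_symbol"], ascending=[False, True], kind="stable"
            ).reset_index(drop=True)
        else:
            table["pvalue"] = []
            table["qvalue"] = []
            table["selected"] = []
        tables[stream] = table
        metadata["streams"][stream] = {
            "total_case": totals.total_case,
            "total_control": totals.total_control,
            "correction_factor": totals.correction_factor,
        }
    return tables, metadata
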