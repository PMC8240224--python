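"""End-to-end orchestration of a two-arm comparison run.

Chains the retention filter, best-fit deduplication, stream splitting,
the chi-square frequency screen with FDR control, optional per-symbol
intensity ANOVA tables, and optional network summaries, writing every
result table plus a JSON manifest that captures the thresholds, totals
and correction factors needed to re-execute the run.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .frequency import run_frequency_comparison
from .intensity import anova_oneway, to_intensity_records, treatment_means
from .io import read_edge_list, read_psm_table
from .model import (
    FilterConfig,
    PSMRecord,
    SelectionConfig,
    TreatmentDesign,
    ValidationError,
)
from .network import graph_summary, subnetwork_by_selection


def run_full_comparison(
    case,
    control,
    out_dir,
    filter_cfg: FilterConfig | None = None,
    selection_cfg: SelectionConfig | None = None,
    design: TreatmentDesign | None = None,
    anova_symbols: Sequence[str] = (),
    edge_list_path=None,
) -> dict:
    """Run the full comparison and write a results bundle.

    ``case`` / ``control`` are PSM TSV paths or in-memory record lists.
    Returns the manifest dict (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    filter_cfg = filter_cfg or FilterConfig()
    selection_cfg = selection_cfg or SelectionConfig()
    design = design or TreatmentDesign.default_panel()

    def load(arg, name):
        if isinstance(arg, (str, Path)):
            path = Path(arg)
            if not path.exists():
                raise OSError(f"{name} PSM table not found: {path}")
            try:
                return read_psm_table(path)
            except ValidationError as exc:
                raise ValidationError(f"stage ingest[{name}]: {exc}") from exc
        return list(arg)

    case_psms: list[PSMRecord] = load(case, "case")
    control_psms: list[PSMRecord] = load(control, "control")

    tables, metadata = run_frequency_comparison(
        case_psms, control_psms, filter_cfg, selection_cfg
    )
    selected_by_stream = {}
    for stream, table in tables.items():
        table.to_csv(out / f"frequency_{stream}.tsv", sep="\t", index=False)
        sel = table.loc[table.get("selected", pd.Series(dtype=bool)) == True]  # noqa: E712
        sel_symbols = sel["gene_symbol"].tolist() if not sel.empty else []
        selected_by_stream[stream] = sel_symbols
        (out / f"selected_{stream}.txt").write_text(
            "\n".join(sel_symbols) + ("\n" if sel_symbols else ""), encoding="utf-8"
        )

    anova_written = []
    if anova_symbols:
        intensity = to_intensity_records(case_psms + control_psms, design)
        for symbol in anova_symbols:
            sub = intensity[intensity["gene_symbol"] == symbol]
            if sub.empty:
                continue
            means = treatment_means(sub)
            means.to_csv(out / f"means_{symbol}.tsv", sep="\t", index=False)
            try:
                res = anova_oneway(sub)
                rows = [
                    {
                        "factor": f.name,
                        "df": f.df,
                        "sum_sq": f.sum_sq,
                        "mean_sq": f.mean_sq,
                        "F": f.F,
                        "pvalue": f.pvalue,
                    }
                    for f in res.factors
                ] + [
                    {
                        "factor": "Residual",
                        "df": res.residual_df,
                        "sum_sq": res.residual_ss,
                        "mean_sq": float("nan"),
                        "F": float("nan"),
                        "pvalue": float("nan"),
                    }
                ]
                pd.DataFrame(rows).to_csv(
                    out / f"anova_{symbol}.tsv", sep="\t", index=False
                )
                anova_written.append(symbol)
            except ValidationError:
                # single treatment level etc.: means table still written
                pass

    graph_block = None
    if edge_list_path is not None:
        edges = read_edge_list(edge_list_path)
        full = graph_summary(edges)
        selected_all = sorted(
            {s for syms in selected_by_stream.values() for s in syms}
        )
        induced = subnetwork_by_selection(edges, selected_all)
        sub = graph_summary(induced)
        graph_block = {
            "full": full.__dict__,
            "selected_subnetwork": sub.__dict__,
        }

    manifest = {
        "package": "peptidome",
        "version": __version__,
        "python": platform.python_version(),
        "filter": {
            "min_intensity": filter_cfg.min_intensity,
            "stream_mode": filter_cfg.stream_mode,
            "dedup": filter_cfg.dedup_keys,
        },
        "selection": {
            "chi2_min": selection_cfg.chi2_min,
            "delta_min": selection_cfg.delta_min,
        },
        "design": {"case_id": design.case_id, "control_id": design.control_id},
        "frequency": metadata,
        "selected": selected_by_stream,
        "anova_symbols": anova_written,
        "graph": graph_block,
        "inputs": {
            "n_case_rows": len(case_psms),
            "n_control_rows": len(control_psms),
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
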