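"""Synthetic PSM-table generator with a ground-truth manifest.

The generator emulates the study design the analysis assumes: two arms
(12 case and 12 control patients by default), 10 step-gradient
fractions per patient, Poisson observation counts per peptide per
patient-fraction cell, log-normal precursor intensities straddling the
E4 retention threshold, redundant second charge-state correlations at
lower score, and an STY phospho stream.  Enriched symbols carry an
elevated Poisson rate in the case arm only; the truth manifest records
every symbol's stream, rates and enrichment flag so selection can be
scored for sensitivity and false-positive fraction.

Every draw comes from one ``numpy.random.default_rng(seed)``, so the
output is fully reproducible from ``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


import numpy as np
import pandas as pd

from .model import STYP, TRYP, PSMRecord, SelectionConfig, ValidationError
from .seqtools import tryptic_digest

# Residue frequencies tilted toward K/R (tryptic sites) and S/T/Y
# (phospho acceptors) so digests always yield usable peptides.
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_W = np.array(
    [8, 2, 5, 6, 4, 7, 2, 5, 7, 9, 2, 4, 4, 4, 7, 8, 6, 1, 3, 6], dtype=float
)
_AA_W /= _AA_W.sum()


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the generator.

    ``baseline_rate`` is the mean number of retained correlations per
    peptide per patient-fraction cell (Poisson).  Intensities are
    10^Normal(mean, sd) truncated at ``intensity_floor * 10**-0.5`` so
    a known fraction falls below the retention filter.
    """

    n_symbols: int = 200
    n_peptides_per_symbol: tuple[int, int] = (2, 4)
    n_patients_case: int = 12
    n_patients_control: int = 12
    n_fractions: int = 10
    baseline_rate: float = 2.0
    enriched_symbols: int = 20
    enrichment_ratio: float = 5.0
    phospho_fraction: float = 0.3
    log10_intensity_mean: float = 4.5
    log10_intensity_sd: float = 0.5
    intensity_floor: float = 10_000.0
    redundancy_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_symbols < 1:
            raise ValidationError("n_symbols must be >= 1")
        lo, hi = self.n_peptides_per_symbol
        if not 1 <= lo <= hi:
            raise ValidationError("n_peptides_per_symbol must be a valid range")
        if self.baseline_rate <= 0 or self.enrichment_ratio <= 0:
            raise ValidationError("rates must be > 0")
        if self.enriched_symbols > self.n_symbols:
            raise ValidationError("enriched_symbols cannot exceed n_symbols")
        for p in (self.phospho_fraction, self.redundancy_rate):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must lie in [0, 1]")
        if self.intensity_floor <= 0:
            raise ValidationError("intensity_floor must be > 0")
        if min(self.n_patients_case, self.n_patients_control, self.n_fractions) < 1:
            raise ValidationError("patients and fractions must be >= 1")


@dataclass(frozen=True)
class SimExperiment:
    """Generated experiment: two PSM tables, truth manifest, proteins."""

    case: list
    control: list
    truth: pd.DataFrame
    proteins: dict

    def __iter__(self):  # allow (case, control, truth) unpacking
        return iter((self.case, self.control, self.truth))


def _random_protein(rng, styp: bool, n_needed: int) -> tuple[str, list]:
    """A random parent sequence with >= n_needed usable tryptic
    peptides (length 6-26; containing S/T/Y when the symbol is STYP)."""
    for _ in range(200):
        length = int(rng.integers(120, 260))
        seq = "".join(rng.choice(_AA, size=length, p=_AA_W))
        peps = [
            t
            for t in tryptic_digest(seq)
            if 6 <= len(t[0]) <= 26 and (not styp or set(t[0]) & set("STY"))
        ]
        if len(peps) >= n_needed:
            return seq, peps
    raise ValidationError("could not generate a parent protein; widen the design")


def _arm_records(
    rng,
    arm: str,
    symbol: str,
    accession: str,
    peptides: list,
    stream: str,
    rate: float,
    n_patients: int,
    cfg: SimConfig,
    serial: list,
) -> list[PSMRecord]:
    n_pep = len(peptides)
    cells = n_patients * cfg.n_fractions
    counts = rng.poisson(rate, size=(n_pep, cells))
    total = int(counts.sum())
    if total == 0:
        return []
    pep_idx = np.repeat(np.arange(n_pep), counts.sum(axis=1))
    cell_idx = np.concatenate(
        [np.repeat(np.arange(cells), counts[i]) for i in range(n_pep)]
    )
    patients = cell_idx // cfg.n_fractions
    fractions = cell_idx % cfg.n_fractions
    log_floor = math.log10(cfg.intensity_floor) - 0.5
    log_i = np.maximum(
        rng.normal(cfg.log10_intensity_mean, cfg.log10_intensity_sd, total), log_floor
    )
    intensities = 10.0 ** log_i
    charges = rng.choice([2, 3], size=total)
    scores = rng.uniform(1.0, 5.0, size=total)
    dup_mask = rng.random(total) < cfg.redundancy_rate
    dup_drop = rng.uniform(0.1, 1.0, size=total)

    treatment = {
        ("case", TRYP): 3,
        ("case", STYP): 4,
        ("control", TRYP): 1,
        ("control", STYP): 2,
    }[(arm, stream)]
    prefix = "AD" if arm == "case" else "CT"

    # one phospho site per STYP PSM, uniformly over the peptide's S/T/Y
    sty_positions = [
        [i + 1 for i, a in enumerate(p[0]) if a in "STY"] for p in peptides
    ]
    records = []
    for k in range(total):
        pep, _, _ = peptides[pep_idx[k]]
        if stream == STYP:
            sites = sty_positions[pep_idx[k]]
            pos = int(sites[rng.integers(len(sites))])
            mods = frozenset({(pos, f"phospho_{pep[pos - 1]}")})
        else:
            mods = frozenset()
        serial[0] += 1
        sid = f"{arm}-{serial[0]:08d}"
        base = PSMRecord(
            spectrum_id=sid,
            sample_id=f"{prefix}{patients[k] + 1:02d}",
            fraction=f"F{fractions[k] + 1:02d}",
            treatment_id=treatment,
            peptide=pep,
            modifications=mods,
            charge=int(charges[k]),
            engine="SEQUEST",
            score=float(scores[k]),
            precursor_intensity=float(intensities[k]),
            protein_accession=accession,
            gene_symbol=symbol,
        )
        records.append(base)
        if dup_mask[k]:
            # redundant correlation of the same spectrum at the other
            # charge state, strictly lower score
            records.append(
                PSMRecord(
                    spectrum_id=sid,
                    sample_id=base.sample_id,
                    fraction=base.fraction,
                    treatment_id=treatment,
                    peptide=pep,
                    modifications=mods,
                    charge=5 - base.charge,
                    engine="SEQUEST",
                    score=float(scores[k] - dup_drop[k]),
                    precursor_intensity=base.precursor_intensity,
                    protein_accession=accession,
                    gene_symbol=symbol,
                )
            )
    return records


def simulate_experiment(config: SimConfig | None = None) -> SimExperiment:
    """Generate (case, control) PSM tables plus the truth manifest."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.n_peptides_per_symbol
    enriched_idx = set(
        rng.choice(cfg.n_symbols, size=cfg.enriched_symbols, replace=False).tolist()
        if cfg.enriched_symbols
        else []
    )
    case: list[PSMRecord] = []
    control: list[PSMRecord] = []
    truth_rows = []
    proteins: dict[str, str] = {}
    serial_case = [0]
    serial_control = [0]
    for s in range(cfg.n_symbols):
        symbol = f"SYM{s + 1:04d}"
        accession = f"ACC{s + 1:04d}.1"
        stream = STYP if rng.random() < cfg.phospho_fraction else TRYP
        n_pep = int(rng.integers(lo, hi + 1))
        seq, candidates = _random_protein(rng, stream == STYP, n_pep)
        pick = rng.choice(len(candidates), size=n_pep, replace=False)
        peptides = [candidates[i] for i in sorted(pick.tolist())]
        proteins[accession] = seq
        enriched = s in enriched_idx
        control_rate = cfg.baseline_rate
        case_rate = cfg.baseline_rate * (cfg.enrichment_ratio if enriched else 1.0)
        truth_rows.append(
            {
                "gene_symbol": symbol,
                "protein_accession": accession,
                "stream": stream,
                "case_rate": case_rate,
                "control_rate": control_rate,
                "enriched": bool(enriched and cfg.enrichment_ratio != 1.0),
            }
        )
        case.extend(
            _arm_records(
                rng, "case", symbol, accession, peptides, stream,
                case_rate, cfg.n_patients_case, cfg, serial_case,
            )
        )
        control.extend(
            _arm_records(
                rng, "control", symbol, accession, peptides, stream,
                control_rate, cfg.n_patients_control, cfg, serial_control,
            )
        )
    truth = pd.DataFrame(truth_rows)
    return SimExperiment(case=case, control=control, truth=truth, proteins=proteins)


def score_recovery(
    frequency_tables,
    truth: pd.DataFrame,
    selection_cfg: SelectionConfig | None = None,
) -> tuple[float, float]:
    """Score selection against the truth manifest.

    ``frequency_tables`` is either the stream->DataFrame dict returned
    by :func:`~peptidome.frequency.run_frequency_comparison` or a single
    per-symbol DataFrame with a ``selected`` column (or the columns
    needed to apply the selection gate).  Returns ``(sensitivity,
    false_positive_fraction)``.
    """
    from .frequency import select_candidates

    selection_cfg = selection_cfg or SelectionConfig()
    if isinstance(frequency_tables, dict):
        frames = [f for f in frequency_tables.values() if not f.empty]
        frame = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["gene_symbol", "delta", "chi2"]
        )
    else:
        frame = frequency_tables
    truth_symbols = set(truth["gene_symbol"])
    observed = set(frame["gene_symbol"]) if not frame.empty else set()
    stray = observed - truth_symbols
    if stray:
        raise ValidationError(
            f"records name symbols absent from the truth manifest: {sorted(stray)[:5]}"
        )
    if frame.empty:
        selected = set()
    elif "selected" in frame.columns:
        selected = set(frame.loc[frame["selected"], "gene_symbol"])
    else:
        chi2_col = "chi2_mean" if "chi2_mean" in frame.columns else "chi2"
        selected = set(
            select_candidates(frame, selection_cfg, chi2_col=chi2_col)["gene_symbol"]
        )
    enriched = set(truth.loc[truth["enriched"], "gene_symbol"])
    null = truth_symbols - enriched
    sensitivity = len(selected & enriched) / len(enriched) if enriched else 0.0
    fpf = len(selected & null) / len(null) if null else 0.0
    return sensitivity, fpf
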