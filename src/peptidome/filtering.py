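"""Retention rules applied to raw PSM tables before counting.

Three stages, always in this order: the E4 precursor-intensity floor,
best-fit-per-spectrum deduplication, then TRYP/STYP stream splitting.
The intensity threshold is inclusive (>=), and deduplication keeps the
highest-scoring correlation per spectrum with a deterministic tie-break
(lower charge, then lexicographically smaller peptide, then smaller
accession).
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .model import STYP, TRYP, FilterConfig, PSMRecord, ValidationError


def filter_min_intensity(
    psms: Sequence[PSMRecord], config: FilterConfig | None = None
) -> list[PSMRecord]:
    """Keep PSMs with precursor_intensity >= config.min_intensity."""
    config = config or FilterConfig()
    for p in psms:
        if not p.precursor_intensity > 0:
            raise ValidationError(
                f"spectrum {p.spectrum_id}: non-positive precursor intensity"
            )
    return [p for p in psms if p.precursor_intensity >= config.min_intensity]


def _dedup_rank(p: PSMRecord):
    # min() of this key == argmax score with the stated tie-break chain.
    return (-p.score, p.charge, p.peptide, p.protein_accession)


def dedup_best_fit(psms: Iterable[PSMRecord]) -> list[PSMRecord]:
    """One record per spectrum_id: the best engine fit.

    Output order follows the first appearance of each spectrum_id, which
    makes the operation idempotent.
    """
    best: dict[str, PSMRecord] = {}
    order: list[str] = []
    for p in psms:
        cur = best.get(p.spectrum_id)
        if cur is None:
            best[p.spectrum_id] = p
            order.append(p.spectrum_id)
        elif _dedup_rank(p) < _dedup_rank(cur):
            best[p.spectrum_id] = p
    return [best[s] for s in order]


def classify_stream(psm: PSMRecord) -> str:
    """STYP iff at least one S/T/Y phospho modification; TRYP otherwise.

    Acetylation, oxidation and neutral losses do not change the stream.
    """
    return STYP if psm.is_phospho else TRYP


def split_streams(psms: Iterable[PSMRecord]) -> tuple[list[PSMRecord], list[PSMRecord]]:
    """Partition into (TRYP, STYP) collections; no record lost."""
    tryp: list[PSMRecord] = []
    styp: list[PSMRecord] = []
    for p in psms:
        (styp if p.is_phospho else tryp).append(p)
    return tryp, styp


def select_engine(psms: Iterable[PSMRecord], engine: str) -> list[PSMRecord]:
    """Restrict to one search engine's correlations (counting uses the
    SEQUEST-attributed table when both engines are present)."""
    return [p for p in psms if p.engine == engine]


def prepare(psms: Sequence[PSMRecord], config: FilterConfig | None = None) -> list[PSMRecord]:
    """The fixed retention pipeline: intensity filter then best-fit dedup."""
    return dedup_best_fit(filter_min_intensity(psms, config))
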