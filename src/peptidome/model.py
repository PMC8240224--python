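"""Domain types shared by every pipeline stage.

The relational backbone of the analysis is the peptide-spectrum match
(PSM): one correlation of an MS/MS fragmentation spectrum to a candidate
peptide, carrying the precursor intensity, charge state, search-engine
score and the protein/gene attribution.  Everything downstream —
intensity filtering, best-fit deduplication, stream splitting,
observation-frequency counting and the chi-square screen — consumes
validated :class:`PSMRecord` collections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

PHOSPHO_TYPES = frozenset({"phospho_S", "phospho_T", "phospho_Y"})

#: The accepted post-translational modification vocabulary: STY
#: phosphorylation plus acetylation, methionine oxidation and neutral
#: losses of water or ammonia.  Anything else is rejected at ingestion.
MODIFICATION_TYPES = PHOSPHO_TYPES | {
    "acetyl",
    "oxidation_M",
    "loss_water",
    "loss_ammonia",
}

ENGINES = frozenset({"XTANDEM", "SEQUEST"})

CHARGES = frozenset({2, 3})

TRYP = "TRYP"
STYP = "STYP"
STREAMS = (TRYP, STYP)


class ValidationError(ValueError):
    """A record or parameter violates a domain invariant."""


class SchemaError(ValueError):
    """A tabular input is missing or misdeclaring required columns."""


@dataclass(frozen=True)
class PSMRecord:
    """One spectrum-to-peptide correlation.

    ``modifications`` is a frozenset of ``(position, type)`` pairs with
    1-based positions inside ``peptide``; phospho types must sit on the
    matching S/T/Y residue.
    """

    spectrum_id: str
    sample_id: str
    fraction: str
    treatment_id: int
    peptide: str
    modifications: frozenset = field(default_factory=frozenset)
    charge: int = 2
    engine: str = "SEQUEST"
    score: float = 0.0
    precursor_intensity: float = 1.0
    protein_accession: str = ""
    gene_symbol: str = ""

    def __post_init__(self):
        if not self.spectrum_id:
            raise ValidationError("spectrum_id must be non-empty")
        if not self.peptide:
            raise ValidationError("peptide must be non-empty")
        bad = set(self.peptide) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"peptide {self.peptide!r} contains non-amino-acid characters {sorted(bad)}"
            )
        if not 1 <= int(self.treatment_id) <= 26:
            raise ValidationError(f"treatment_id {self.treatment_id} outside 1-26")
        if self.charge not in CHARGES:
            raise ValidationError(f"charge {self.charge} not in {{2,3}}")
        if self.engine not in ENGINES:
            raise ValidationError(f"unknown engine {self.engine!r}")
        if not self.precursor_intensity > 0:
            raise ValidationError(
                f"precursor_intensity must be > 0, got {self.precursor_intensity}"
            )
        for pos, mtype in self.modifications:
            if mtype not in MODIFICATION_TYPES:
                raise ValidationError(f"unknown modification type {mtype!r}")
            if not 1 <= pos <= len(self.peptide):
                raise ValidationError(
                    f"modification position {pos} outside peptide of length {len(self.peptide)}"
                )
            if mtype in PHOSPHO_TYPES:
                residue = self.peptide[pos - 1]
                expected = mtype[-1]
                if residue != expected:
                    raise ValidationError(
                        f"{mtype} at position {pos} sits on {residue!r}, expected {expected!r}"
                    )

    @property
    def is_phospho(self) -> bool:
        return any(m in PHOSPHO_TYPES for _, m in self.modifications)


#: Fig.-4-style treatment panel: id -> human label.  Even-numbered ids are
#: the phosphopeptide (STYP) presentations of the preceding odd id.
DEFAULT_TREATMENT_LABELS = {
    1: "Alzheimer normal",
    2: "Alzheimer normal control STYP",
    3: "Alzheimer dementia",
    4: "Alzheimer dementia STYP",
    5: "Cancer breast",
    6: "Cancer breast STYP",
    7: "Cancer control",
    8: "Cancer control STYP",
    9: "Cancer ovarian",
    10: "Cancer ovarian STYP",
    11: "Ice Cold",
    12: "Ice Cold STYP",
    13: "Heart attack Arterial",
    14: "Heart attack Arterial STYP",
    15: "Heart attack normal control",
    16: "Heart attack normal control STYP",
    17: "Heart attack",
    18: "Heart attack STYP",
    19: "Multiple sclerosis normal control",
    20: "Multiple sclerosis normal control STYP",
    21: "Multiple sclerosis",
    22: "Multiple sclerosis STYP",
    23: "Sepsis",
    24: "Sepsis STYP",
    25: "Sepsis normal control",
    26: "Sepsis normal control STYP",
}


@dataclass(frozen=True)
class TreatmentDesign:
    """The treatment panel: id -> (label, stream), plus which id is the
    case arm and which the matched control.

    Defaults follow the 26-panel disease/control design with treatment 3
    (dementia) as case versus treatment 1 (matched normal) as control.
    """

    treatments: dict = field(default_factory=dict)
    case_id: int = 3
    control_id: int = 1

    def __post_init__(self):
        if len(set(self.treatments)) != len(self.treatments):
            raise ValidationError("treatment ids must be unique")

    @classmethod
    def default_panel(cls, case_id: int = 3, control_id: int = 1) -> "TreatmentDesign":
        mapping = {
            tid: (label, STYP if label.endswith("STYP") else TRYP)
            for tid, label in DEFAULT_TREATMENT_LABELS.items()
        }
        return cls(treatments=mapping, case_id=case_id, control_id=control_id)

    def label(self, treatment_id: int) -> str:
        try:
            return self.treatments[treatment_id][0]
        except KeyError:
            raise ValidationError(f"unknown treatment_id {treatment_id}") from None

    def stream(self, treatment_id: int) -> str:
        try:
            return self.treatments[treatment_id][1]
        except KeyError:
            raise ValidationError(f"unknown treatment_id {treatment_id}") from None


@dataclass(frozen=True)
class FilterConfig:
    """Retention rules applied before counting.

    ``min_intensity`` is the precursor-intensity floor in arbitrary
    counts (default 10,000 = E4); the threshold is inclusive.
    """

    min_intensity: float = 10_000.0
    dedup_keys: str = "max score; ties: lower charge, then peptide, then accession"
    stream_mode: str = "both"

    def __post_init__(self):
        if not self.min_intensity > 0:
            raise ValidationError("min_intensity must be > 0")
        if self.stream_mode not in {TRYP, STYP, "both"}:
            raise ValidationError(f"stream_mode must be TRYP, STYP or both")


@dataclass(frozen=True)
class SelectionConfig:
    """Candidate gate: corrected count difference >= delta_min AND
    chi-square >= chi2_min (both inclusive).  Defaults mirror the
    headline rule delta >= 9 with chi2 >= 25 (p <= 0.001 at 1 df)."""

    chi2_min: float = 25.0
    delta_min: float = 9.0


@dataclass(frozen=True)
class StreamTotals:
    """Total retained MS/MS correlations per arm; the normalization
    denominators that put case and control at equal sampling depth."""

    total_case: int
    total_control: int

    def __post_init__(self):
        if self.total_case < 0 or self.total_control < 0:
            raise ValidationError("stream totals must be >= 0")

    @property
    def correction_factor(self) -> float:
        if self.total_control == 0:
            raise ValidationError(
                "correction factor undefined: control total is zero"
            )
        return self.total_case / self.total_control


@dataclass(frozen=True)
class FrequencyRecord:
    """Per-symbol, per-stream observation-frequency comparison row.

    ``chi2`` is the pseudocounted one-cell statistic
    ``(count_case - corrected_control)^2 / (corrected_control + 1)``
    with ``pvalue`` its nominal df=1 upper tail and ``qvalue`` the BH
    adjustment within the stream.
    """

    gene_symbol: str
    stream: str
    count_case: int
    count_control: int
    corrected_control: float
    delta: float
    chi2: float
    pvalue: float
    qvalue: float

    def __post_init__(self):
        if not self.gene_symbol:
            raise ValidationError("gene_symbol must be non-empty")
        if self.stream not in STREAMS:
            raise ValidationError(f"stream must be one of {STREAMS}")
        if self.count_case < 0 or self.count_control < 0:
            raise ValidationError("counts must be >= 0")
        if self.chi2 < 0:
            raise ValidationError("chi2 must be >= 0")


FREQUENCY_COLUMNS = (
    "gene_symbol",
    "stream",
    "count_case",
    "count_control",
    "corrected_control",
    "delta",
    "chi2",
    "pvalue",
    "qvalue",
)

PSM_COLUMNS = (
    "spectrum_id",
    "sample_id",
    "fraction",
    "treatment_id",
    "peptide",
    "modifications",
    "charge",
    "engine",
    "score",
    "precursor_intensity",
    "protein_accession",
    "gene_symbol",
)
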