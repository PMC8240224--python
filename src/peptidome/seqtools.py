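"""Peptide-level sequence utilities.

In-silico tryptic digestion (cleave after K/R, not before P), fully
tryptic validation, peptide localization in a parent protein (1-based
inclusive coordinates), and Kyte-Doolittle sliding-window hydropathy
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .model import AMINO_ACIDS, ValidationError

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class PeptideLocation:
    """A peptide occurrence, 1-based inclusive; ``preceding`` /
    ``following`` are the flanking residues or None at a terminus."""

    accession: str | None
    start: int
    end: int
    preceding: str | None
    following: str | None


def _check_sequence(sequence: str) -> None:
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise ValidationError(f"illegal residues in sequence: {sorted(bad)}")


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """Positions i such that trypsin cleaves between sequence[i-1] and
    sequence[i] (0 < i < len): after K or R, not before P when the
    proline rule is on."""
    sites = []
    for i in range(1, len(sequence)):
        if sequence[i - 1] in "KR" and not (proline_rule and sequence[i] == "P"):
            sites.append(i)
    return sites


def tryptic_digest(
    sequence: str,
    missed_cleavages: int = 0,
    proline_rule: bool = True,
) -> list[tuple[str, int, int]]:
    """Digest a protein; returns ``(peptide, start, end)`` tuples with
    1-based inclusive coordinates, ordered by start then length.

    With ``missed_cleavages = m``, every concatenation of up to m+1
    adjacent zero-missed fragments is emitted.  The zero-missed
    peptides tile the sequence exactly.
    """
    if not sequence:
        return []
    _check_sequence(sequence)
    if missed_cleavages < 0:
        raise ValidationError("missed_cleavages must be >= 0")
    bounds = [0] + cleavage_sites(sequence, proline_rule) + [len(sequence)]
    fragments = [
        (sequence[a:b], a + 1, b) for a, b in zip(bounds[:-1], bounds[1:])
    ]
    out = []
    for i in range(len(fragments)):
        for m in range(missed_cleavages + 1):
            j = i + m
            if j >= len(fragments):
                break
            pep = "".join(f[0] for f in fragments[i : j + 1])
            out.append((pep, fragments[i][1], fragments[j][2]))
    out.sort(key=lambda t: (t[1], t[2]))
    return out


def is_fully_tryptic(
    sequence: str, peptide: str, start: int, proline_rule: bool = True
) -> bool:
    """True iff both peptide termini are tryptic (or protein termini).

    ``start`` is 1-based.  Raises if the peptide does not occur at
    ``start``.
    """
    end = start + len(peptide) - 1
    if start < 1 or end > len(sequence) or sequence[start - 1 : end] != peptide:
        raise ValidationError(
            f"peptide {peptide!r} does not occur at position {start}"
        )
    if start == 1:
        n_ok = True
    else:
        n_ok = sequence[start - 2] in "KR" and not (
            proline_rule and peptide[0] == "P"
        )
    if end == len(sequence):
        c_ok = True
    else:
        c_ok = peptide[-1] in "KR" and not (
            proline_rule and sequence[end] == "P"
        )
    return n_ok and c_ok


def locate_peptide(
    sequence: str, peptide: str, accession: str | None = None
) -> list[PeptideLocation]:
    """All occurrences of ``peptide`` in ``sequence``, 1-based
    inclusive; an absent peptide yields an empty list."""
    if not peptide:
        raise ValidationError("peptide must be non-empty")
    hits = []
    i = sequence.find(peptide)
    while i != -1:
        start, end = i + 1, i + len(peptide)
        hits.append(
            PeptideLocation(
                accession=accession,
                start=start,
                end=end,
                preceding=sequence[i - 1] if i > 0 else None,
                following=sequence[end] if end < len(sequence) else None,
            )
        )
        i = sequence.find(peptide, i + 1)
    return hits


def hydropathy_profile(
    sequence: str, window: int = 9, scale: dict | None = None
) -> np.ndarray:
    """Centered sliding-window mean hydropathy.

    Returns one value per position where the full window fits (length
    ``len(sequence) - window + 1``); index k corresponds to the window
    centered at residue k + (window+1)//2, 1-based.
    """
    _check_sequence(sequence)
    if window % 2 == 0:
        raise ValidationError("window must be odd")
    if window > len(sequence):
        raise ValidationError("window exceeds sequence length")
    scale = scale or KYTE_DOOLITTLE
    vals = np.array([scale[a] for a in sequence], dtype=float)
    kernel = np.ones(window) / window
    return np.convolve(vals, kernel, mode="valid")


def load_disc1_fixture() -> tuple[str, str]:
    """Load the bundled DISC1-like reference sequence.

    The bundled sequence is a synthetic stand-in (not the deposited
    isoform-a entry): it is constructed so that the two reported
    N-terminal-domain tryptic peptides sit at their published
    coordinates — MPGGGPQGAPAAAGGGGVSHRAGSRDCLPPAACFR at 1-35 and
    ARQCGLDSR at 83-91 — for localization and hydropathy examples.
    Returns ``(accession, sequence)``.
    """
    path = resources.files("peptidome").joinpath("data/disc1_synthetic.fasta")
    text = path.read_text(encoding="utf-8")
    lines = [l.strip() for l in text.splitlines() if l.strip()]
    accession = lines[0][1:].split()[0]
    return accession, "".join(lines[1:]).upper()
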