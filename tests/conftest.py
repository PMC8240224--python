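import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from peptidome.model import PSMRecord


@pytest.fixture
def make_psm():
    """Factory for valid PSMRecords with overridable fields."""

    counter = {"n": 0}

    def factory(**kwargs):
        counter["n"] += 1
        defaults = dict(
            spectrum_id=f"spec{counter['n']:04d}",
            sample_id="AD01",
            fraction="F01",
            treatment_id=3,
            peptide="ARQCGLDSR",
            modifications=frozenset(),
            charge=2,
            engine="SEQUEST",
            score=2.5,
            precursor_intensity=15_000.0,
            protein_accession="ACC0001.1",
            gene_symbol="DISC1",
        )
        defaults.update(kwargs)
        return PSMRecord(**defaults)

    return factory
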