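import pytest
from hypothesis import HealthCheck, settings

from motifgraph.sequence_io import TMSegment

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture
def make_segment():
    """Factory: a TM segment directly from a residue string."""

    def _make(residues: str, protein_id: str = "p1", start: int = 0,
              state: str = "TM") -> TMSegment:
        return TMSegment(protein_id, start, start + len(residues),
                         residues, state)

    return _make
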