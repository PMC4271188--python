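import pytest

from pepflux import AssayConditions, LiposomeParams
from pepflux.simulate import di_alanine, tri_alanine


@pytest.fixture
def standard_conditions() -> AssayConditions:
    """100-fold inward peptide gradient, no pH gradient: the reference
    stoichiometry-assay conditions (10 mM peptide inside, 0.1 mM outside,
    pH 6.8 both faces, 120 mM internal K+)."""
    return AssayConditions(ph_in=6.8, ph_out=6.8, pep_in=10.0, pep_out=0.1)


@pytest.fixture
def uptake_conditions() -> AssayConditions:
    """One-unit pH gradient (acid outside), symmetric K+ so the clamped
    voltage is zero: the steady-state radiolabel-uptake conditions."""
    return AssayConditions(
        ph_in=7.5, ph_out=6.5, pep_in=0.5, pep_out=0.5, k_in=75.0, k_out=75.0
    )


@pytest.fixture
def liposome() -> LiposomeParams:
    return LiposomeParams()


@pytest.fixture
def tri_ala():
    return tri_alanine(3)


@pytest.fixture
def di_ala():
    return di_alanine(5)
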