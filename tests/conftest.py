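import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mgm.core import MGMParameters
from mgm.generator import NucleusGeometry
from mgm.microdosimetry import BeamSpectrum
from mgm.repair import RepairModelParams
from mgm.sdd_io import DamageSiteRecord
from mgm.synthetic import GroundTruth, default_truth_params


@pytest.fixture(scope="session")
def truth_params() -> MGMParameters:
    return default_truth_params()


@pytest.fixture(scope="session")
def truth() -> GroundTruth:
    return GroundTruth(seed=1234)


@pytest.fixture(scope="session")
def nucleus() -> NucleusGeometry:
    return NucleusGeometry()


@pytest.fixture(scope="session")
def beam() -> BeamSpectrum:
    return BeamSpectrum.single(50.0)


@pytest.fixture(scope="session")
def repair_params() -> RepairModelParams:
    return RepairModelParams(d=1.0, C_half=8.0)


def make_record(
    track_id=0,
    chromosome_id=1,
    position=100,
    xyz=(0.0, 0.0, 0.0),
    sb1=1,
    sb2=1,
    bd=0,
    has_dsb=None,
    direct=None,
    indirect=None,
) -> DamageSiteRecord:
    """Record factory with sensible defaults (a simple DSB)."""
    if has_dsb is None:
        has_dsb = sb1 >= 1 and sb2 >= 1
    total = sb1 + sb2 + bd
    if direct is None and indirect is None:
        direct, indirect = total, 0
    elif direct is None:
        direct = total - indirect
    elif indirect is None:
        indirect = total - direct
    return DamageSiteRecord(
        track_id=track_id,
        chromosome_id=chromosome_id,
        genomic_position_bp=position,
        spatial_position_um=xyz,
        n_sb_strand1=sb1,
        n_sb_strand2=sb2,
        n_bd=bd,
        has_dsb=has_dsb,
        cause_direct=direct,
        cause_indirect=indirect,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
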