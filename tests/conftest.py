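import pytest

from hctnomo.core import ModelConfig, PatientProfile
from hctnomo.geometry import build_geometry


@pytest.fixture(scope="session")
def config():
    return ModelConfig()


@pytest.fixture
def infant_12kg():
    return PatientProfile(weight_kg=12.0)


@pytest.fixture
def infant_6kg():
    return PatientProfile(weight_kg=6.0)


@pytest.fixture(scope="session")
def pediatric_geom():
    return build_geometry("pediatric")


@pytest.fixture(scope="session")
def adult_geom():
    return build_geometry("adult")


class TwoCompartmentOracle:
    """Independent bookkeeping model: red cells and plasma as separate tallies.

    Deliberately avoids every closed form in the package; hematocrit is only
    ever the ratio of the tallies.  Used to cross-check the engine.
    """

    def __init__(self, bv, hct_pct):
        self.rbc = bv * hct_pct / 100.0
        self.plasma = bv - self.rbc

    @property
    def bv(self):
        return self.rbc + self.plasma

    @property
    def hct_pct(self):
        return self.rbc / (self.rbc + self.plasma) * 100.0

    def lose_whole_blood(self, v):
        # blood leaves carrying red cells at the current ratio
        frac = self.rbc / self.bv
        self.rbc -= v * frac
        self.plasma -= v * (1.0 - frac)

    def add_plasma(self, v):
        self.plasma += v

    def remove_plasma(self, v):
        self.plasma -= v

    def restore_to(self, bv_target):
        self.plasma = bv_target - self.rbc

    def add_whole_blood(self, v, donor_hct_pct):
        self.rbc += v * donor_hct_pct / 100.0
        self.plasma += v * (1.0 - donor_hct_pct / 100.0)

    def add_packed(self, v, unit_hct_frac):
        self.rbc += v * unit_hct_frac
        self.plasma += v * (1.0 - unit_hct_frac)


@pytest.fixture(scope="session")
def oracle_cls():
    return TwoCompartmentOracle
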