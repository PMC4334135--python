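import pytest

from metaseed.chem import Formula, monoisotopic_mass, mz_from_neutral_mass
from metaseed.compound_db import Compound, CompoundDB, build_mass_defect_model
from metaseed.peak_io import Peak, PeakTable, SampleDesign, SampleInfo
from metaseed.synthetic import SimulationConfig, make_mini_db, simulate_peak_table


@pytest.fixture(scope="session")
def glucose_mass() -> float:
    return monoisotopic_mass(Formula.parse("C6H12O6"))


@pytest.fixture
def tiny_db() -> CompoundDB:
    """Three compounds, two pathways, well-separated masses."""
    return CompoundDB([
        Compound("cpd1", "glucose", monoisotopic_mass(Formula.parse("C6H12O6")),
                 Formula.parse("C6H12O6"), frozenset({"P1"})),
        Compound("cpd2", "alanine", monoisotopic_mass(Formula.parse("C3H7NO2")),
                 Formula.parse("C3H7NO2"), frozenset({"P1", "P2"})),
        Compound("cpd3", "citrate", monoisotopic_mass(Formula.parse("C6H8O7")),
                 Formula.parse("C6H8O7"), frozenset({"P2"})),
    ])


@pytest.fixture
def design_2x2() -> SampleDesign:
    return SampleDesign({
        "c1": SampleInfo("control", 10.0, 1),
        "c2": SampleInfo("control", 10.0, 2),
        "t1": SampleInfo("treatment", 10.0, 1),
        "t2": SampleInfo("treatment", 10.0, 2),
    })


def make_peak(pid, mz, rt, values, design=None):
    samples = ["c1", "c2", "t1", "t2"]
    return Peak(pid, mz, rt, dict(zip(samples, values)))


@pytest.fixture
def peak_factory():
    return make_peak


@pytest.fixture(scope="session")
def sim_default():
    """One default synthetic dataset shared across tests (seed 11)."""
    cfg = SimulationConfig(seed=11)
    db = make_mini_db(cfg)
    table, truth = simulate_peak_table(db, cfg)
    model = build_mass_defect_model(db)
    return cfg, db, table, truth, model
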