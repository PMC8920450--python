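import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracle helpers

from midaflux.bodywater import enrichment_table
from midaflux.isotopes import IsotopeTable
from midaflux.lipogenesis import LipogenesisModel
from midaflux.simulate import default_upr_scenario, simulate_experiment
from midaflux.turnover import CohortDesign, ProteinTurnoverModel

COHORT_SEED = 101  # fixed seed for the shared synthetic cohort


def make_small_scenario(seed: int, ages=("young", "aged")):
    """Reduced cohort (3 pathways x 6 proteins + marker) for fast pipeline tests."""
    from midaflux.simulate import PathwaySpec, SimulationScenario, SpecialProteinSpec

    def eff(young_tun, aged_tun):
        return {("young", "control"): 1.0, ("young", "tunicamycin"): young_tun,
                ("aged", "control"): 0.9, ("aged", "tunicamycin"): 0.9 * aged_tun}

    pathways = (
        PathwaySpec("path:tst01", "Protein processing in endoplasmic reticulum", 6,
                    (0.08, 0.30), eff(2.6, 2.6)),
        PathwaySpec("path:tst02", "Ribosome", 6, (0.10, 0.60), eff(1.0, 0.6)),
        PathwaySpec("path:tst03", "Glycolysis / Gluconeogenesis", 6, (0.10, 0.60), eff(1.0, 0.65)),
    )
    marker = SpecialProteinSpec("SYNBIP", "path:tst01", 0.18, eff(2.0, 3.3))
    lipid_truth = {
        ("young", "control", "triglyceride"): 0.22,
        ("young", "tunicamycin", "triglyceride"): 0.11,
        ("aged", "control", "triglyceride"): 0.18,
        ("aged", "tunicamycin", "triglyceride"): 0.07,
    }
    return SimulationScenario(
        seed=seed,
        design=CohortDesign(ages=tuple(ages)),
        pathways=pathways,
        special_proteins=(marker,),
        peptides_mean=3.0,
        lipid_truth=lipid_truth,
    )


@pytest.fixture(scope="session")
def small_sim():
    return simulate_experiment(make_small_scenario(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def isotope_table():
    return IsotopeTable.default()


@pytest.fixture(scope="session")
def toy_table():
    """Two-isotope carbon/hydrogen table plus a mono-isotopic element."""
    return IsotopeTable({
        "C": {0: 0.9893, 1: 0.0107},
        "H": {0: 0.9999, 1: 0.0001},
        "X": {0: 1.0},
    })


@pytest.fixture(scope="session")
def default_sim():
    """The reference synthetic cohort with its default 1% measurement noise."""
    return simulate_experiment(default_upr_scenario(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def noiseless_sim():
    return simulate_experiment(default_upr_scenario(seed=COHORT_SEED).noiseless())


@pytest.fixture(scope="session")
def fitted(default_sim):
    bw = enrichment_table(default_sim.body_water, default_sim.standards)
    return ProteinTurnoverModel(default_sim.peptides, CohortDesign(), bw).fit()


@pytest.fixture(scope="session")
def fitted_noiseless(noiseless_sim):
    bw = enrichment_table(noiseless_sim.body_water, noiseless_sim.standards)
    return ProteinTurnoverModel(noiseless_sim.peptides, CohortDesign(), bw).fit()


@pytest.fixture(scope="session")
def dnl_fitted(default_sim):
    bw = enrichment_table(default_sim.body_water, default_sim.standards)
    return LipogenesisModel(default_sim.lipids, bw).fit()
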