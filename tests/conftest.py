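"""Shared fixtures: the default scenario and the (expensive) experiment suite.

The full counterfactual suite — eleven 1780–2014 integrations of the
24-column grid — is computed once per session and shared by every test
that needs equilibrated run output.
"""

import warnings

import numpy as np
import pytest

from isofe.column_model import ModelParams, build_scenario
from isofe.experiments import ExperimentSpec, build_suite, run_experiment, run_suite
from isofe.forcing_synth import SOURCES, ScenarioParams

SEED = 1

#: representative columns for the two seasonal-contrast regions: an
#: open-ocean north-west subpolar (Fe-limited) column and a mid-gyre
#: subtropical (nitrogen-limited) column.
REGION_FE_LIMITED = 1
REGION_N_LIMITED = 20


@pytest.fixture(scope="session")
def scenario():
    return build_scenario(seed=SEED)


@pytest.fixture(scope="session")
def suite_runs(scenario):
    """The default 11-experiment suite on the default grid."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_suite(scenario, build_suite())


@pytest.fixture(scope="session")
def standard_run(suite_runs):
    return suite_runs["standard"]


@pytest.fixture(scope="session")
def noalpha_pair(scenario):
    """Standard and no-anthro runs with both fractionation factors at 1
    (the endmember-only pathway of the fractionation share)."""
    no_anthro = {s: s != "anthro" for s in SOURCES}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        std = run_experiment(scenario, ExperimentSpec(
            "standard-noalpha", alpha_uptake=1.0, alpha_ligand=1.0))
        noa = run_experiment(scenario, ExperimentSpec(
            "no-anthro-noalpha", sources_on=no_anthro,
            alpha_uptake=1.0, alpha_ligand=1.0))
    return std, noa


def climatology(ds, years=5):
    """Monthly climatology over the final ``years`` simulated years."""
    last = int(ds.year.max())
    sub = ds.where(ds.year > last - years, drop=True)
    return sub.groupby("month").mean("time")
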