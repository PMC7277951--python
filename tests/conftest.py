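import numpy as np
import pytest

from mzldt import run_study, synthgen
from mzldt.io_model import MetaboliteDB, PathwayDB


@pytest.fixture(scope="session")
def sim_default():
    """The reference synthetic cohort (40 pathways × 8 metabolites, 20+20)."""
    return synthgen.simulate_dataset(synthgen.SimConfig(seed=1))


@pytest.fixture(scope="session")
def study_default(sim_default):
    """Full pipeline run on the reference cohort (reduced permutation draws)."""
    return run_study(
        sim_default.spectra,
        sim_default.metabolite_db,
        sim_default.pathway_db,
        sim_default.groups,
        n_draws=2000,
        seed=1,
    )


@pytest.fixture
def toy_pdb():
    return PathwayDB(
        pathway_ids=("pw1", "pw2", "pw3"),
        names=("Alpha", "Beta", "Gamma"),
        members=(
            frozenset({"m1", "m2", "m3"}),
            frozenset({"m3", "m4"}),
            frozenset({"m5", "m6", "m7", "m8"}),
        ),
    )


@pytest.fixture
def toy_db():
    return MetaboliteDB(
        ids=("m1", "m2", "m3"),
        names=("glucose", "alanine", "urea"),
        masses=np.array([180.0634, 89.0477, 60.0324]),
        xrefs=("C00031", "C00041", "C00086"),
    )
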