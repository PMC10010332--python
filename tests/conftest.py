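import numpy as np
import pytest

from lesionscope.simulate import SimConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def mutation_sim():
    """Paired-lesion mutation tables with truth, generated once."""
    from lesionscope.simulate import sim_lesion_pair_mutations

    return sim_lesion_pair_mutations(SimConfig(seed=11))


@pytest.fixture(scope="session")
def tcr_sim():
    """Contig + cell tables with planted clonotype truth."""
    from lesionscope.simulate import sim_clonotype_tables

    return sim_clonotype_tables(SimConfig(seed=12))


@pytest.fixture(scope="session")
def cohort_sim():
    """503-patient cohort with planted response groups."""
    from lesionscope.simulate import sim_cohort

    return sim_cohort(SimConfig(seed=13))
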