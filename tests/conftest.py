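import pytest

from urbanvar.data_model import ComparisonRecord


def make_record(
    record_id="r1",
    study_id="s1",
    pair_id="p1",
    species="Parus major",
    trait="clutch_size",
    season=2000,
    mean_urban=5.0,
    sd_urban=1.2,
    n_urban=30,
    mean_nonurban=6.0,
    sd_nonurban=1.0,
    n_nonurban=25,
    **kwargs,
):
    return ComparisonRecord(
        record_id=record_id,
        study_id=study_id,
        population_pair_id=pair_id,
        species=species,
        trait=trait,
        season=season,
        mean_urban=mean_urban,
        sd_urban=sd_urban,
        n_urban=n_urban,
        mean_nonurban=mean_nonurban,
        sd_nonurban=sd_nonurban,
        n_nonurban=n_nonurban,
        **kwargs,
    )


@pytest.fixture
def record():
    return make_record()


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated comparison dataset shared across tests."""
    from urbanvar.synthetic_data import SimulationParams, simulate_dataset

    params = SimulationParams(seed=20240915, n_species=12, n_studies=18)
    records, truth = simulate_dataset(params)
    return records, truth


@pytest.fixture(scope="session")
def small_A(small_dataset):
    from urbanvar.phylo import correlation_from_newick

    _, truth = small_dataset
    return correlation_from_newick(truth.tree_newick)
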