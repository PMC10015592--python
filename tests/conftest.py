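import pytest

from bcrclone import clonotyping, mutations
from bcrclone.simulate import SimulationConfig, build_germline_set, simulate_repertoire


@pytest.fixture(scope="session")
def germlines():
    return build_germline_set(n_per_family=2, seed=7)


@pytest.fixture(scope="session")
def repertoire():
    """A small simulated repertoire with study-shaped defaults."""
    cfg = SimulationConfig(seed=11, n_clones=150)
    airr, truth_records, truth_clones, germline_set = simulate_repertoire(cfg)
    return {
        "config": cfg,
        "airr": airr,
        "truth_records": truth_records,
        "truth_clones": truth_clones,
        "germlines": germline_set,
    }


@pytest.fixture(scope="session")
def analysis(repertoire):
    """Deduplicated records with germlines, profiles and clonotypes."""
    unique = clonotyping.deduplicate(repertoire["airr"])
    unique = mutations.fill_germlines(unique, repertoire["germlines"])
    profiles = mutations.profiles_frame(unique, repertoire["germlines"])
    clonotypes, membership = clonotyping.define_cdr3_clonotypes(unique)
    grouped = clonotyping.group_clones(unique)
    return {
        "unique": unique,
        "profiles": profiles,
        "clonotypes": clonotypes,
        "membership": membership,
        "grouped": grouped,
    }
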