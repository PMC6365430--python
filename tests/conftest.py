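import numpy as np
import pytest

from lactopan.orthology import OrthologGroup
from lactopan.pangenome import PresenceMatrix
from lactopan.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """12-strain noiseless simulated collection used across module tests."""
    return simulate(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    from lactopan.pipeline import run_pipeline

    ds = small_dataset
    return run_pipeline(
        ds.all_genes,
        ds.strains,
        coverage=ds.coverage,
        label_tables={"genotype": ds.genotype_labels, "niche": ds.niche_labels},
        n_perm=199,
        seed=7,
    )


def make_og(og_id, members, pseudo=(), strains=None):
    """Helper: build an OrthologGroup from strain -> gene list, with some
    strains' members flagged all-pseudo."""
    strains = strains if strains is not None else sorted(members)
    states = {}
    for s in strains:
        if s not in members or not members[s]:
            states[s] = "absent"
        elif s in pseudo:
            states[s] = "pseudo"
        else:
            states[s] = "present"
    single = all(len(members.get(s, [])) == 1 for s in strains)
    return OrthologGroup(og_id=og_id, members={k: list(v) for k, v in members.items()},
                         states=states, single_copy=single)


def matrix_from_rows(strain_rows, og_ids):
    """Helper: presence matrix from {strain: row string over '0','P','1'}."""
    decode = {"0": 0, "P": 1, "1": 2}
    strains = sorted(strain_rows)
    cells = np.array(
        [[decode[c] for c in strain_rows[s]] for s in strains], dtype=np.int8
    )
    return PresenceMatrix(strains, list(og_ids), cells)
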