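import numpy as np
import pytest

from polysite import synthdata as sd
from polysite import structure as st


@pytest.fixture(scope="session")
def helix():
    """Ideal alpha helix, 14 residues, proline-free, CB side chains."""
    return sd.generate_backbone(14, "helix", seed=11, sequence="ADKLMNEQRSTVWY")


@pytest.fixture(scope="session")
def helix_featurized(helix):
    torsions = st.compute_torsions(helix)
    hbonds = st.assign_hbonds(helix)
    ss = st.assign_secondary_structure(helix, hbonds)
    feats = st.build_node_features(helix, torsions, ss, hbonds)
    return torsions, hbonds, ss, feats


@pytest.fixture(scope="session")
def sheet():
    """Two antiparallel ideal strands docked into a hydrogen-bonded pair."""
    return sd.generate_antiparallel_sheet(6, seed=0)


@pytest.fixture(scope="session")
def small_corpus():
    """30-protein corpus, used by training/model tests."""
    spec = sd.SyntheticSpec(n_proteins=30, seed=7)
    return sd.generate_corpus(spec)


@pytest.fixture(scope="session")
def small_records(small_corpus):
    from polysite.pipeline import records_from_corpus

    return records_from_corpus(small_corpus)


@pytest.fixture(scope="session")
def smoke_benchmark():
    """3-seed desk-scale training benchmark; shared because each run trains
    a full model on a fresh 200-protein corpus."""
    from polysite.benchmark import smoke_median

    return smoke_median((1, 2, 3), keep_results=True)


def random_rigid(rng):
    """Uniformly random rotation (QR of a Gaussian) plus a translation."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.uniform(-20, 20, 3)
    return q, t
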