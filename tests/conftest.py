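import numpy as np
import pytest

from gpcrscreen import apf, fixtures
from gpcrscreen.ligands import Ligand, embed_3d
from gpcrscreen.sequences import ReceptorSequence, TMAnnotation


@pytest.fixture(scope="session")
def scale():
    return fixtures.load_table("eisenberg")


@pytest.fixture(scope="session")
def small_receptor():
    return fixtures.make_receptor(
        fixtures.SyntheticReceptorSpec(seed=11, helix_length_range=(20, 26))
    )


@pytest.fixture(scope="session")
def small_ligands():
    """Four embedded actives + six decoys; session-scoped (embedding is slow)."""
    spec = fixtures.SyntheticLigandSpec(n_actives=4, n_decoys=6, seed=7)
    return fixtures.make_library(spec)


@pytest.fixture(scope="session")
def ethanol():
    return embed_3d(Ligand.from_smiles("ethanol", "CCO"), seed=3)


@pytest.fixture
def toy_field():
    """Small all-zero 7-channel field centred on the origin."""
    grids = np.zeros((apf.N_CHANNELS, 9, 9, 9))
    return apf.PropertyField(origin=np.array([-2.0, -2.0, -2.0]), spacing=0.5,
                             grids=grids)


def make_annotated(residues: str, helix_spans):
    """Helper: wrap residues + (start, end) spans into sequence structures."""
    seq = ReceptorSequence(id="toy", residues=residues)
    tms = tuple(
        TMAnnotation(f"TM{i + 1}", s, e) for i, (s, e) in enumerate(helix_spans)
    )
    anchors = {t.helix_id: (t.start + t.end) // 2 for t in tms}
    return seq, tms, anchors
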