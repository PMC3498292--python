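import numpy as np
import pytest

from pbflex.ensemble_io import AtomRecord, Frame, StructureEnsemble
from pbflex.pb_alphabet import PBPrototypeTable
from pbflex.synthetic_ensembles import GeneratorSpec, generate_ensemble


@pytest.fixture(scope="session")
def pb_table() -> PBPrototypeTable:
    return PBPrototypeTable.load_default()


def make_ensemble(coords_per_frame, atom_names=None, residue_numbers=None,
                  residue_names=None, elements=None, times=None, replica="r1",
                  label=""):
    """Hand-built ensemble from raw coordinate stacks (test helper)."""
    coords_per_frame = [np.asarray(c, float) for c in coords_per_frame]
    n = coords_per_frame[0].shape[0]
    atom_names = atom_names or [f"C{i}" for i in range(n)]
    residue_numbers = residue_numbers or list(range(1, n + 1))
    residue_names = residue_names or ["ALA"] * n
    elements = elements or [nm[0] for nm in atom_names]
    topology = [
        AtomRecord(i + 1, atom_names[i], residue_names[i], residue_numbers[i], "A", elements[i])
        for i in range(n)
    ]
    times = times if times is not None else [100.0 * (i + 1) for i in range(len(coords_per_frame))]
    frames = [Frame(c, t, replica) for c, t in zip(coords_per_frame, times)]
    return StructureEnsemble(topology, frames, label=label)


@pytest.fixture()
def helix_ensemble() -> StructureEnsemble:
    """Noise-free 12-residue all-helical (PB m) ensemble, 5 frames."""
    spec = GeneratorSpec(n_residues=12, n_frames=5, recipes=(("m" * 12, 1.0),), seed=11)
    return generate_ensemble(spec)


@pytest.fixture()
def extended_ensemble() -> StructureEnsemble:
    """Noise-free 11-residue extended (PB d) ensemble, 3 frames."""
    spec = GeneratorSpec(n_residues=11, n_frames=3, recipes=(("d" * 11, 1.0),), seed=7)
    return generate_ensemble(spec)
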