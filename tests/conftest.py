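import numpy as np
import pytest

from structbind.model_io import Atom, Residue, StructureModel
from structbind.simulate import build_bdna_duplex, place_tf_blob


def single_atom_model(radius_name="CA", element="C") -> StructureModel:
    return StructureModel(
        "one",
        [("X", "protein")],
        [Residue("X", 1, "GLY")],
        [Atom("X", 1, radius_name, element, 0.0, 0.0, 0.0)],
    )


def random_toy_model(rng: np.random.Generator, n_atoms: int) -> StructureModel:
    """A random cluster of carbon pseudo-atoms in a 10-angstrom box."""
    residues = [Residue("X", i + 1, "GLY") for i in range(n_atoms)]
    coords = rng.uniform(0, 10, size=(n_atoms, 3))
    atoms = [
        Atom("X", i + 1, "CA", "C", *coords[i]) for i in range(n_atoms)
    ]
    return StructureModel("toy", [("X", "protein")], residues, atoms)


@pytest.fixture(scope="session")
def duplex40():
    return build_bdna_duplex("ACGTACGTAC" * 4)


@pytest.fixture(scope="session")
def complex40(duplex40):
    return place_tf_blob(duplex40, 21, 10, model_id="complex40")


@pytest.fixture
def genome_fasta(tmp_path):
    """A 100-bp single-contig FASTA with known sequence."""
    seq = ("ACGT" * 25)
    path = tmp_path / "genome.fa"
    path.write_text(">chr1\n" + "\n".join(seq[i:i + 60] for i in range(0, 100, 60)) + "\n")
    return path, seq
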