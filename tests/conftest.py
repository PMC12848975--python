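import numpy as np
import pytest

from foldgo.structgraph import ContactGraph, ResidueChain

# Hand-written 3-residue PDB fixture: consecutive Cα at 3.8 Å spacing.
THREE_RESIDUE_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  TRP A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""

# Same fixture with the middle residue lacking its Cα (only N present).
MISSING_CA_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  N   GLY A   2       3.800   0.000   0.000  1.00  0.00           N
ATOM      3  CA  TRP A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""

# Five-term toy ontology: root ← A ← B; root ← C with C also part_of A,
# plus one obsolete term that must be dropped.
TOY_OBO = """\
format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: term A
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: term B
namespace: biological_process
is_a: GO:0000002 ! term A

[Term]
id: GO:0000004
name: term C
namespace: biological_process
is_a: GO:0000001 ! root
relationship: part_of GO:0000002 ! term A

[Term]
id: GO:0000005
name: gone
namespace: biological_process
is_obsolete: true
"""


@pytest.fixture
def pdb_file(tmp_path):
    path = tmp_path / "ABC.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


@pytest.fixture
def toy_obo(tmp_path):
    path = tmp_path / "toy.obo"
    path.write_text(TOY_OBO)
    return path


@pytest.fixture
def path_graph():
    """0 – 1 – 2."""
    return ContactGraph(n_nodes=3, edges=np.array([[0, 1], [1, 2]]))


@pytest.fixture
def triangle_graph():
    return ContactGraph(n_nodes=3, edges=np.array([[0, 1], [1, 2], [0, 2]]))


@pytest.fixture
def star_graph():
    """Center 0 with leaves 1..4."""
    return ContactGraph(
        n_nodes=5, edges=np.array([[0, 1], [0, 2], [0, 3], [0, 4]])
    )


def random_chain(n: int, seed: int) -> ResidueChain:
    """Loose random coil for graph-construction tests (not self-avoiding)."""
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.cumsum(3.8 * steps, axis=0)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
    return ResidueChain(protein_id=f"R{seed}", sequence=seq, coords=coords)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic dataset shared by the slower integration tests."""
    from foldgo.synthetic import SyntheticSpec, gen_dataset

    return gen_dataset(
        SyntheticSpec(n_proteins=12, min_residues=30, max_residues=45, seed=7)
    )
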