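"""Residue chains, Cα contact graphs, and one-hot residue encodings.

A protein structure is reduced to the ordered list of its Cα positions.
Two residues are in contact when their Cα atoms lie strictly closer than a
distance cutoff (10 Å by default), which turns each protein into an
undirected residue graph. Residue identities are encoded as a fixed-width
26-dimensional one-hot scheme: the 20 standard amino acids followed by six
special tokens for non-standard or ambiguous residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

#: Alphabet for the 26-d one-hot encoding: 20 standard amino acids in the
#: conventional single-letter order, then six special tokens. ``X`` is the
#: unknown/catch-all token; any character outside the alphabet maps to it.
ALPHABET: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY") + tuple("BZJUOX")
AA_TO_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}
UNKNOWN_TOKEN = "X"
N_TOKENS = len(ALPHABET)

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # ambiguous / non-standard residues that have their own token
    "ASX": "B", "GLX": "Z", "XLE": "J", "SEC": "U", "PYL": "O",
    "UNK": "X",
}


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed into a residue chain."""


@dataclass(frozen=True)
class ResidueChain:
    """One protein: residue sequence plus per-residue Cα coordinates (Å)."""

    protein_id: str
    sequence: str
    coords: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {coords.shape}")
        if len(self.sequence) != coords.shape[0]:
            raise ValueError(
                f"sequence length {len(self.sequence)} != number of "
                f"coordinates {coords.shape[0]}"
            )
        if coords.shape[0] < 1:
            raise ValueError("a residue chain needs at least one residue")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class ContactGraph:
    """Undirected residue graph; edges are unordered 0-based index pairs."""

    n_nodes: int
    edges: np.ndarray  # (E, 2) int, each row sorted i < j, rows unique

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        edges = np.sort(edges, axis=1)
        edges = np.unique(edges, axis=0) if edges.size else edges
        object.__setattr__(self, "edges", edges)
        if edges.size:
            if edges.min() < 0 or edges.max() >= self.n_nodes:
                raise ValueError("edge index out of range")
            if np.any(edges[:, 0] == edges[:, 1]):
                raise ValueError("self-edges are not allowed")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}

    def neighbors(self) -> list[np.ndarray]:
        """Sorted neighbor array per node."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j in self.edges:
            nbrs[i].append(int(j))
            nbrs[j].append(int(i))
        return [np.array(sorted(n), dtype=np.int64) for n in nbrs]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


@dataclass(frozen=True)
class OneHotMatrix:
    """N×26 binary residue-identity matrix with its alphabet."""

    values: np.ndarray
    alphabet: tuple[str, ...] = field(default=ALPHABET)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[1] != len(self.alphabet):
            raise ValueError(
                f"one-hot matrix must have {len(self.alphabet)} columns"
            )
        if not np.allclose(values.sum(axis=1), 1.0):
            raise ValueError("each one-hot row must sum to exactly 1")


def _residue_letter(resname: str) -> str:
    return _THREE_TO_ONE.get(resname.strip().upper(), UNKNOWN_TOKEN)


def parse_structure(path: str | Path, chain_select: str = "first") -> ResidueChain:
    """Parse a PDB or mmCIF file into a :class:`ResidueChain`.

    One residue is emitted per position that carries a Cα atom, in chain
    order; residues lacking a Cα are skipped with a warning. For disordered
    atoms the first alternate location is used. ``chain_select`` is either a
    chain identifier or ``"first"`` (the first chain of the first model).
    """
    from Bio.PDB import MMCIFParser, PDBParser

    path = Path(path)
    suffix = path.suffix.lower()
    parser = (
        MMCIFParser(QUIET=True)
        if suffix in {".cif", ".mmcif"}
        else PDBParser(QUIET=True)
    )
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises heterogeneous exception types
        raise StructureParseError(f"cannot parse structure file {path}: {exc}")

    model = next(structure.get_models(), None)
    if model is None:
        raise StructureParseError(f"no model in structure file {path}")

    chains = list(model.get_chains())
    if not chains:
        raise StructureParseError(f"no chain in structure file {path}")
    if chain_select == "first":
        chain = chains[0]
    else:
        by_id = {c.id: c for c in chains}
        if chain_select not in by_id:
            raise StructureParseError(
                f"chain {chain_select!r} not found in {path} "
                f"(available: {sorted(by_id)})"
            )
        chain = by_id[chain_select]

    letters: list[str] = []
    coords: list[np.ndarray] = []
    for residue in chain.get_residues():
        if residue.id[0].strip():  # heteroatoms / waters
            continue
        if "CA" not in residue:
            logger.warning(
                "%s: residue %s %s lacks a CA atom; skipped",
                path.name, residue.get_resname(), residue.id[1],
            )
            continue
        atom = residue["CA"]
        if atom.is_disordered():
            atom = sorted(atom.disordered_get_list(), key=lambda a: a.get_altloc())[0]
        letters.append(_residue_letter(residue.get_resname()))
        coords.append(np.asarray(atom.get_coord(), dtype=float))

    if not coords:
        raise StructureParseError(f"selected chain in {path} has no Cα atoms")
    return ResidueChain(
        protein_id=path.stem, sequence="".join(letters), coords=np.vstack(coords)
    )


def build_contact_graph(chain: ResidueChain, threshold: float = 10.0) -> ContactGraph:
    """Build the Cα contact graph: edge {i, j} iff dist(i, j) < threshold.

    The inequality is strict — a pair at exactly the cutoff distance is not
    in contact. Self-pairs are excluded; sequence neighbors are treated like
    any other pair.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not np.all(np.isfinite(chain.coords)):
        raise ValueError("coordinates must be finite")
    n = chain.n_residues
    if n == 1:
        return ContactGraph(n_nodes=1, edges=np.empty((0, 2), dtype=np.int64))
    dense = squareform(pdist(chain.coords))
    ii, jj = np.where(np.triu(dense < threshold, k=1))
    return ContactGraph(n_nodes=n, edges=np.column_stack([ii, jj]))


def encode_one_hot(chain: ResidueChain) -> OneHotMatrix:
    """Encode the residue sequence as an N×26 one-hot matrix.

    Characters outside the alphabet are absorbed by the unknown token and
    logged.
    """
    n = chain.n_residues
    values = np.zeros((n, N_TOKENS), dtype=float)
    unknown_idx = AA_TO_INDEX[UNKNOWN_TOKEN]
    for i, aa in enumerate(chain.sequence.upper()):
        idx = AA_TO_INDEX.get(aa)
        if idx is None:
            logger.info(
                "%s: residue %r at position %d mapped to unknown token",
                chain.protein_id, aa, i,
            )
            idx = unknown_idx
        values[i, idx] = 1.0
    return OneHotMatrix(values=values)


def write_edge_list(graph: ContactGraph, path: str | Path) -> None:
    """Write a contact graph as a two-column 0-based edge-list TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# n_nodes={graph.n_nodes}\n")
        fh.write("node_i\tnode_j\n")
        for i, j in graph.edges:
            fh.write(f"{i}\t{j}\n")


def read_edge_list(path: str | Path) -> ContactGraph:
    path = Path(path)
    n_nodes = None
    edges: list[tuple[int, int]] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "n_nodes=" in line:
                    n_nodes = int(line.split("n_nodes=")[1])
                continue
            if not line or line.startswith("node_i"):
                continue
            i, j = line.split("\t")
            edges.append((int(i), int(j)))
    if n_nodes is None:
        raise ValueError(f"edge-list file {path} lacks an n_nodes header")
    return ContactGraph(
        n_nodes=n_nodes,
        edges=np.array(edges, dtype=np.int64).reshape(-1, 2),
    )


def write_one_hot(matrix: OneHotMatrix, path: str | Path) -> None:
    """Write a one-hot matrix as TSV with a sidecar ``.alphabet`` file."""
    path = Path(path)
    np.savetxt(path, matrix.values, fmt="%d", delimiter="\t")
    path.with_suffix(path.suffix + ".alphabet").write_text(
        "".join(matrix.alphabet) + "\n"
    )
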