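"""Gene Ontology label machinery.

Parses the ontology (OBO) and annotation (GAF) inputs, keeps only
experimentally supported annotations, propagates each annotation to all of
its is_a / part_of ancestors (the true-path rule), and builds the per-branch
binary label matrices used for training: a term is retained in a branch's
label space when at least ``min_count`` distinct proteins carry it after
propagation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

BRANCHES = ("BP", "MF", "CC")
_NAMESPACE_TO_BRANCH = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}

#: Experimental evidence codes trusted by default. The printed source list
#: includes "TA", which is not a valid GO evidence code; it is read as TAS.
EXPERIMENTAL_CODES = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "IC", "TAS"}
)

_CLOSURE_RELATIONS = ("is_a", "part_of")


class OboParseError(ValueError):
    """Raised for malformed or cyclic ontology files."""


@dataclass(frozen=True)
class GoDag:
    """GO DAG: term → parents via is_a/part_of, term → branch, branch roots."""

    terms: frozenset[str]
    parents: dict[str, frozenset[str]]
    namespace: dict[str, str]  # term → BP / MF / CC
    roots: frozenset[str]

    def ancestors(self, term: str, include_roots: bool = False) -> set[str]:
        """All is_a/part_of ancestors of ``term`` (excluding itself)."""
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t in out:
                continue
            out.add(t)
            stack.extend(self.parents.get(t, ()))
        if not include_roots:
            out -= self.roots
        return out

    def leaves(self) -> set[str]:
        """Terms that are not a parent of any other term."""
        all_parents = {p for ps in self.parents.values() for p in ps}
        return set(self.terms) - all_parents

    def branch_terms(self, branch: str) -> set[str]:
        return {
            t for t in self.terms
            if self.namespace.get(t) == branch and t not in self.roots
        }


@dataclass(frozen=True)
class LabelSpace:
    """Ordered retained terms of one branch at a frequency threshold."""

    branch: str
    terms: tuple[str, ...]
    min_count: int

    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}


@dataclass(frozen=True)
class LabelMatrix:
    """P×L binary protein-by-term matrix aligned to a LabelSpace."""

    proteins: tuple[str, ...]
    values: np.ndarray
    space: LabelSpace

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.int8)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.proteins), len(self.space.terms)):
            raise ValueError("label matrix shape does not match proteins × terms")
        if not np.isin(values, (0, 1)).all():
            raise ValueError("label matrix must be binary")


def parse_obo(path: str | Path) -> GoDag:
    """Parse an OBO ontology into a :class:`GoDag`.

    Obsolete terms are dropped. is_a and part_of relationships are retained
    as parent edges; other relationship types are ignored. Raises
    :class:`OboParseError` on malformed files or cycles.
    """
    path = Path(path)
    try:
        graph = obonet.read_obo(str(path), ignore_obsolete=True)
    except Exception as exc:
        raise OboParseError(f"cannot parse OBO file {path}: {exc}")

    terms = set(graph.nodes)
    parents: dict[str, set[str]] = {t: set() for t in terms}
    # obonet edges run child → parent, keyed by relationship type
    for child, parent, rel in graph.edges(keys=True):
        if rel in _CLOSURE_RELATIONS and parent in terms:
            parents[child].add(parent)

    closure = nx.DiGraph()
    closure.add_nodes_from(terms)
    for child, ps in parents.items():
        closure.add_edges_from((child, p) for p in ps)
    if not nx.is_directed_acyclic_graph(closure):
        cycle = nx.find_cycle(closure)
        raise OboParseError(f"ontology contains a cycle: {cycle}")

    namespace: dict[str, str] = {}
    for t in terms:
        ns = graph.nodes[t].get("namespace", "biological_process")
        namespace[t] = _NAMESPACE_TO_BRANCH.get(ns, "BP")
    roots = frozenset(t for t in terms if not parents[t])
    return GoDag(
        terms=frozenset(terms),
        parents={t: frozenset(ps) for t, ps in parents.items()},
        namespace=namespace,
        roots=roots,
    )


def read_gaf(path: str | Path) -> pd.DataFrame:
    """Read a GAF 2.x file into (protein_id, term_id, evidence) rows.

    Comment lines start with ``!``. Rows carrying a NOT qualifier are
    dropped and logged. Duplicate (protein, term) pairs are deduplicated,
    keeping the first evidence code seen.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="!",
        header=None,
        dtype=str,
        usecols=[1, 3, 4, 6],
        names=["protein_id", "qualifier", "term_id", "evidence"],
    )
    negated = df["qualifier"].fillna("").str.contains("NOT")
    if negated.any():
        logger.info("dropping %d NOT-qualified annotation rows", int(negated.sum()))
    df = df.loc[~negated, ["protein_id", "term_id", "evidence"]]
    return df.drop_duplicates(subset=["protein_id", "term_id"]).reset_index(drop=True)


def filter_evidence(
    table: pd.DataFrame, codes: frozenset[str] | set[str] = EXPERIMENTAL_CODES
) -> pd.DataFrame:
    """Keep only annotation rows whose evidence code is in ``codes``."""
    return table[table["evidence"].isin(codes)].reset_index(drop=True)


def propagate_labels(table: pd.DataFrame, dag: GoDag) -> pd.DataFrame:
    """Propagate annotations to all ancestors (true-path rule).

    Every (protein, term) row implies (protein, ancestor) for each is_a /
    part_of ancestor of the term, excluding the namespace roots. Unknown
    terms are dropped with a log message. The result is deduplicated;
    propagated rows inherit the evidence code of the row that produced them.
    The operation is idempotent and never removes existing rows.
    """
    known = table["term_id"].isin(dag.terms)
    if not known.all():
        dropped = sorted(table.loc[~known, "term_id"].unique())
        logger.warning("dropping annotations to unknown terms: %s", dropped)
        table = table[known]

    anc_cache: dict[str, set[str]] = {}
    rows: list[tuple[str, str, str]] = []
    for protein, term, evidence in table.itertuples(index=False):
        if term not in anc_cache:
            anc_cache[term] = dag.ancestors(term, include_roots=False)
        rows.append((protein, term, evidence))
        rows.extend((protein, a, evidence) for a in anc_cache[term])
    out = pd.DataFrame(rows, columns=["protein_id", "term_id", "evidence"])
    return (
        out.drop_duplicates(subset=["protein_id", "term_id"])
        .reset_index(drop=True)
    )


def build_label_space(
    table: pd.DataFrame, dag: GoDag, branch: str, min_count: int
) -> LabelSpace:
    """Retain branch terms annotated to ≥ ``min_count`` distinct proteins.

    ``table`` must already be propagated. Terms are ordered by descending
    protein count, ties broken by term id, so label columns are stable.
    Namespace roots are never retained.
    """
    if branch not in BRANCHES:
        raise ValueError(f"branch must be one of {BRANCHES}")
    branch_terms = dag.branch_terms(branch)
    sub = table[table["term_id"].isin(branch_terms)]
    counts = sub.groupby("term_id")["protein_id"].nunique()
    kept = counts[counts >= min_count]
    if kept.empty:
        logger.warning(
            "no %s term reaches min_count=%d; label space is empty",
            branch, min_count,
        )
    ordered = sorted(kept.items(), key=lambda kv: (-kv[1], kv[0]))
    return LabelSpace(
        branch=branch, terms=tuple(t for t, _ in ordered), min_count=min_count
    )


def build_label_matrix(
    table: pd.DataFrame,
    space: LabelSpace,
    drop_unannotated: bool = True,
) -> LabelMatrix:
    """Binary protein×term matrix over a label space.

    ``table`` must be propagated. Proteins with no annotation inside the
    space are dropped by default (logged); with ``drop_unannotated=False``
    they are kept as all-zero rows.
    """
    if not space.terms:
        raise ValueError("label space is empty")
    term_idx = space.index()
    proteins = sorted(table["protein_id"].unique())
    prot_idx = {p: i for i, p in enumerate(proteins)}
    values = np.zeros((len(proteins), len(space.terms)), dtype=np.int8)
    for protein, term in zip(table["protein_id"], table["term_id"]):
        j = term_idx.get(term)
        if j is not None:
            values[prot_idx[protein], j] = 1
    if drop_unannotated:
        keep = values.any(axis=1)
        if not keep.all():
            logger.info(
                "dropping %d proteins with no label in the %s space",
                int((~keep).sum()), space.branch,
            )
        proteins = [p for p, k in zip(proteins, keep) if k]
        values = values[keep]
    return LabelMatrix(proteins=tuple(proteins), values=values, space=space)


def is_dag_consistent(matrix: LabelMatrix, dag: GoDag) -> bool:
    """Check the true-path rule inside the label space: child=1 ⇒ ancestor=1."""
    idx = matrix.space.index()
    for term, j in idx.items():
        anc_in_space = [idx[a] for a in dag.ancestors(term) if a in idx]
        for a in anc_in_space:
            if np.any(matrix.values[:, j] > matrix.values[:, a]):
                return False
    return True


def save_label_matrix(matrix: LabelMatrix, prefix: str | Path) -> None:
    """Write values as TSV plus a JSON sidecar with orders and metadata."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".tsv"), matrix.values, fmt="%d", delimiter="\t")
    sidecar = {
        "proteins": list(matrix.proteins),
        "terms": list(matrix.space.terms),
        "branch": matrix.space.branch,
        "min_count": matrix.space.min_count,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_label_matrix(prefix: str | Path) -> LabelMatrix:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    values = np.loadtxt(prefix.with_suffix(".tsv"), dtype=np.int8, delimiter="\t")
    values = values.reshape(len(sidecar["proteins"]), len(sidecar["terms"]))
    return LabelMatrix(
        proteins=tuple(sidecar["proteins"]),
        values=values,
        space=LabelSpace(
            branch=sidecar["branch"],
            terms=tuple(sidecar["terms"]),
            min_count=sidecar["min_count"],
        ),
    )
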