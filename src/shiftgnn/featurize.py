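"""Environment-graph featurization of conformer geometries.

A conformer becomes a graph whose nodes are atoms and whose directed edges
link every atom pair closer than a distance cutoff (default 5 angstroms,
strict).  Each edge carries its interatomic distance expanded over a grid
of Gaussian radial basis functions (RBFs),

    e_ij[k] = exp(-(d_ij - k*mu)^2 / delta),   k = 0 .. n_basis-1,

with grid spacing ``mu`` (default 0.1 A) and width ``delta`` (default
0.04 A^2), so the 256 centers cover 0-25.5 A and in particular the whole
0-5 A range that can appear under the cutoff.  The graph depends on the
geometry only through interatomic distances, which makes everything built
on it invariant to rigid motions by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .molio import NUCLEUS_ELEMENT, SUPPORTED_ELEMENTS, Conformer, Molecule

#: fixed element -> node index vocabulary shared by all models
ELEMENT_INDEX = {sym: i for i, sym in enumerate(SUPPORTED_ELEMENTS)}


@dataclass(frozen=True)
class RBFParams:
    """Gaussian radial-basis grid for distance featurization."""

    n_basis: int = 256
    width: float = 0.04  # delta, A^2
    spacing: float = 0.1  # mu, A
    cutoff: float = 5.0  # A, strict upper bound on edge length

    def __post_init__(self):
        if self.n_basis < 1:
            raise ValueError("n_basis must be >= 1")
        if min(self.width, self.spacing, self.cutoff) <= 0:
            raise ValueError("width, spacing and cutoff must be positive")

    @property
    def centers(self) -> np.ndarray:
        return self.spacing * np.arange(self.n_basis)


@dataclass
class EnvironmentGraph:
    """Distance-featurized neighborhood graph of one conformer."""

    node_elements: np.ndarray  # (N,) int, index into SUPPORTED_ELEMENTS
    edge_src: np.ndarray  # (E,) int, receiving atom i of edge (i, j)
    edge_dst: np.ndarray  # (E,) int, sending atom j
    edge_dist: np.ndarray  # (E,) float64, A
    edge_rbf: np.ndarray  # (E, n_basis) float64
    target_mask: np.ndarray  # (N,) bool, atoms of the nucleus of interest
    nucleus: str
    molecule_id: str = ""

    @property
    def n_atoms(self) -> int:
        return self.node_elements.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_src.shape[0]

    @property
    def target_indices(self) -> np.ndarray:
        return np.flatnonzero(self.target_mask)


def rbf_expand(d: float | np.ndarray, params: RBFParams = RBFParams()) -> np.ndarray:
    """Expand distance(s) ``d`` over the Gaussian RBF grid.

    Returns shape ``(n_basis,)`` for a scalar or ``(m, n_basis)`` for an
    array of m distances.  Every component lies in (0, 1]; component k
    peaks at d = k*mu.
    """
    d_arr = np.atleast_1d(np.asarray(d, dtype=np.float64))
    if np.any(d_arr <= 0):
        raise ValueError("distances must be positive (self-pairs are excluded)")
    out = np.exp(-((d_arr[:, None] - params.centers[None, :]) ** 2) / params.width)
    return out[0] if np.isscalar(d) or np.ndim(d) == 0 else out


def build_graph(
    conf: Conformer,
    mol: Molecule,
    params: RBFParams = RBFParams(),
    nucleus: str = "C13",
) -> EnvironmentGraph:
    """Build the environment graph of ``conf`` for one nucleus.

    Edges are exactly the ordered pairs (i, j), i != j, with d_ij strictly
    below ``params.cutoff``; the target mask marks atoms whose element
    matches the nucleus (H for 1H, C for 13C).
    """
    conf.validate(mol)
    if nucleus not in NUCLEUS_ELEMENT:
        raise ValueError(f"unknown nucleus {nucleus!r}")
    unsupported = sorted({e for e in mol.elements if e not in ELEMENT_INDEX})
    if unsupported:
        raise ValueError(f"{mol.id}: unsupported elements {unsupported}")

    node_elements = np.array([ELEMENT_INDEX[e] for e in mol.elements], dtype=np.int64)
    dmat = squareform(pdist(conf.coords))
    src, dst = np.nonzero((dmat < params.cutoff) & ~np.eye(mol.n_atoms, dtype=bool))
    dists = dmat[src, dst]
    edge_rbf = (
        rbf_expand(dists, params)
        if dists.size
        else np.zeros((0, params.n_basis), dtype=np.float64)
    )
    target_elem = NUCLEUS_ELEMENT[nucleus]
    mask = np.array([e == target_elem for e in mol.elements], dtype=bool)
    return EnvironmentGraph(
        node_elements=node_elements,
        edge_src=src.astype(np.int64),
        edge_dst=dst.astype(np.int64),
        edge_dist=dists,
        edge_rbf=edge_rbf,
        target_mask=mask,
        nucleus=nucleus,
        molecule_id=mol.id,
    )


@dataclass
class GraphBatch:
    """Several environment graphs merged into one disjoint union.

    ``label_atoms``/``label_values`` address the labelled subset of atoms
    in the merged node numbering; training losses are taken over them.
    """

    graph: EnvironmentGraph
    graph_slices: list[tuple[int, int]] = field(default_factory=list)
    label_atoms: np.ndarray = None
    label_values: np.ndarray = None


def batch_graphs(
    graphs: list[EnvironmentGraph],
    labels: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> GraphBatch:
    """Merge graphs into one with offset node indices.

    ``labels[g]`` is a pair (atom indices, shift values) local to graph g.
    """
    if not graphs:
        raise ValueError("empty graph list")
    nucleus = graphs[0].nucleus
    if any(g.nucleus != nucleus for g in graphs):
        raise ValueError("cannot batch graphs for different nuclei")
    offsets = np.cumsum([0] + [g.n_atoms for g in graphs])
    merged = EnvironmentGraph(
        node_elements=np.concatenate([g.node_elements for g in graphs]),
        edge_src=np.concatenate([g.edge_src + o for g, o in zip(graphs, offsets)]),
        edge_dst=np.concatenate([g.edge_dst + o for g, o in zip(graphs, offsets)]),
        edge_dist=np.concatenate([g.edge_dist for g in graphs]),
        edge_rbf=np.vstack([g.edge_rbf for g in graphs]),
        target_mask=np.concatenate([g.target_mask for g in graphs]),
        nucleus=nucleus,
        molecule_id="|".join(g.molecule_id for g in graphs),
    )
    slices = [(int(offsets[i]), int(offsets[i + 1])) for i in range(len(graphs))]
    batch = GraphBatch(graph=merged, graph_slices=slices)
    if labels is not None:
        atoms, values = [], []
        for (idx, y), off in zip(labels, offsets):
            atoms.append(np.asarray(idx, dtype=np.int64) + off)
            values.append(np.asarray(y, dtype=np.float64))
        batch.label_atoms = np.concatenate(atoms)
        batch.label_values = np.concatenate(values)
    return batch


def graph_to_json(graph: EnvironmentGraph, path: str | Path) -> None:
    """Dump nodes, edges and distances as debug JSON."""
    payload = {
        "molecule_id": graph.molecule_id,
        "nucleus": graph.nucleus,
        "node_elements": [SUPPORTED_ELEMENTS[i] for i in graph.node_elements],
        "edges": [
            [int(i), int(j), round(float(d), 9)]
            for i, j, d in zip(graph.edge_src, graph.edge_dst, graph.edge_dist)
        ],
        "target_atoms": [int(i) for i in graph.target_indices],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
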