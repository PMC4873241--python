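"""Cell-network topologies and gap-junctional coupling terms.

A :class:`Topology` is an undirected graph over cell indices with two
per-edge coupling strengths: ``g`` (electrical coupling, μS/cm²) and ``D``
(cytosolic-calcium diffusion, s⁻¹).  Generators cover the architectures of
interest: isolated cells, pairs, periodic chains (capillary-like strands),
cliques (tight clusters), periodic Moore-neighborhood lattices (monolayers),
honeycomb node/strut lattices (microengineered hexagonal networks) and
rectangular strips of given cell width (linear patterns).

Electrical coupling enters the membrane-potential equation as
``-(g/C_m) * Σ_j (v_i - v_j)`` with membrane specific capacitance
``C_m = 1 μF/cm²``, so a printed strength of 1000 μS/cm² acts as a rate of
1000 s⁻¹.  Calcium diffusion enters the cytosolic-calcium equation as
``-D * Σ_j (c_i - c_j)``.  Both terms are pairwise antisymmetric, so the
network neither creates nor destroys calcium or charge.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Topology",
    "build_topology",
    "coupling_terms",
    "coupling_matrices",
    "blocker_transform",
    "read_edge_list",
    "degree_summary",
    "DEFAULT_G",
    "DEFAULT_D",
    "MEMBRANE_CAPACITANCE",
]

#: Default electrical coupling strength for coupled cells (μS/cm²).
DEFAULT_G = 1000.0
#: Default cytosolic calcium diffusion coupling (s⁻¹); an artifact default,
#: chosen so diffusive stabilization extinguishes clique oscillations at the
#: observed clique size (see docs/methods.md).
DEFAULT_D = 0.105
#: Membrane specific capacitance used to convert g (μS/cm²) to a rate (s⁻¹).
MEMBRANE_CAPACITANCE = 1.0


class TopologyError(ValueError):
    """Invalid topology specification."""


@dataclass(frozen=True)
class Topology:
    """Cell adjacency plus per-edge coupling strengths.

    Parameters
    ----------
    n_cells:
        Number of cells (indices ``0 .. n_cells-1``).
    edges:
        Tuple of unordered index pairs ``(i, j)`` with ``i < j``.
    g:
        Per-edge electrical coupling strengths, μS/cm² (same order as edges).
    D:
        Per-edge calcium diffusion strengths, s⁻¹.
    label:
        Generator name (``single``, ``pair``, ``ring``, ...).
    """

    n_cells: int
    edges: tuple[tuple[int, int], ...]
    g: tuple[float, ...]
    D: tuple[float, ...]
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise TopologyError("n_cells must be >= 1")
        seen = set()
        for (i, j) in self.edges:
            if i == j:
                raise TopologyError(f"self-edge on cell {i}")
            if not (0 <= i < self.n_cells and 0 <= j < self.n_cells):
                raise TopologyError(f"edge ({i},{j}) outside [0,{self.n_cells})")
            if i > j:
                raise TopologyError("edges must be stored with i < j")
            if (i, j) in seen:
                raise TopologyError(f"duplicate edge ({i},{j})")
            seen.add((i, j))
        if len(self.g) != len(self.edges) or len(self.D) != len(self.edges):
            raise TopologyError("g/D must have one entry per edge")
        if any(x < 0 for x in self.g) or any(x < 0 for x in self.D):
            raise TopologyError("coupling strengths must be >= 0")

    # -- convenience views -------------------------------------------------
    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_cells, dtype=int)
        for (i, j) in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def neighbors(self, i: int) -> list[int]:
        out = [j for (a, j) in self.edges if a == i]
        out += [a for (a, j) in self.edges if j == i]
        return sorted(out)

    def to_graph(self) -> nx.Graph:
        gr = nx.Graph()
        gr.add_nodes_from(range(self.n_cells))
        for (i, j), ge, de in zip(self.edges, self.g, self.D):
            gr.add_edge(i, j, g=ge, D=de)
        return gr


def _from_graph(gr: nx.Graph, n: int, g: float, D: float, label: str) -> Topology:
    edges = tuple(sorted((min(i, j), max(i, j)) for i, j in gr.edges()))
    return Topology(n, edges, (g,) * len(edges), (D,) * len(edges), label)


def build_topology(
    kind: str,
    *,
    n: int | None = None,
    rows: int | None = None,
    cols: int | None = None,
    width: int | None = None,
    length: int | None = None,
    rings: int | None = None,
    g: float = DEFAULT_G,
    D: float = DEFAULT_D,
) -> Topology:
    """Build a named topology.

    ``kind`` is one of ``single``, ``pair``, ``ring``, ``clique``, ``torus``,
    ``hexagonal``, ``strip``.  ``ring``/``clique`` take ``n``; ``torus`` takes
    ``rows`` and ``cols`` (periodic Moore adjacency, 8 neighbors each);
    ``hexagonal`` takes ``rings`` (honeycomb of node and strut cells);
    ``strip`` takes ``width`` and ``length`` (rectangular lattice, periodic
    along its length, open across its width).
    """
    if kind == "single":
        return Topology(1, (), (), (), "single")
    if kind == "pair":
        return Topology(2, ((0, 1),), (g,), (D,), "pair")
    if kind == "ring":
        if n is None or n < 3:
            raise TopologyError("ring requires n >= 3")
        edges = tuple(sorted((i, (i + 1) % n) if i < (i + 1) % n else ((i + 1) % n, i) for i in range(n)))
        return Topology(n, edges, (g,) * n, (D,) * n, "ring")
    if kind == "clique":
        if n is None or n < 1:
            raise TopologyError("clique requires n >= 1")
        gr = nx.complete_graph(n)
        return _from_graph(gr, n, g, D, "clique")
    if kind == "torus":
        if rows is None or cols is None or rows < 1 or cols < 1:
            raise TopologyError("torus requires rows >= 1 and cols >= 1")
        ncell = rows * cols
        gr = nx.Graph()
        gr.add_nodes_from(range(ncell))
        for r in range(rows):
            for c in range(cols):
                i = r * cols + c
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == 0 and dc == 0:
                            continue
                        j = ((r + dr) % rows) * cols + (c + dc) % cols
                        if i != j:
                            gr.add_edge(i, j)
        return _from_graph(gr, ncell, g, D, "torus")
    if kind == "hexagonal":
        if rings is None or rings < 1:
            raise TopologyError("hexagonal requires rings >= 1")
        gr = nx.hexagonal_lattice_graph(rings, rings)
        gr = nx.convert_node_labels_to_integers(gr, ordering="sorted")
        return _from_graph(gr, gr.number_of_nodes(), g, D, "hexagonal")
    if kind == "strip":
        if width is None or width < 1:
            raise TopologyError("strip requires width >= 1")
        if length is None:
            length = 9
        if length < 3:
            raise TopologyError("strip requires length >= 3")
        ncell = width * length
        gr = nx.Graph()
        gr.add_nodes_from(range(ncell))
        # Moore adjacency, periodic along the strip length, open across width:
        # interior cells of a wide strip approach 8 neighbors, a width-1 strip
        # is the periodic chain with 2 neighbors.
        for x in range(length):
            for y in range(width):
                i = x * width + y
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        if dx == 0 and dy == 0:
                            continue
                        yy = y + dy
                        if not (0 <= yy < width):
                            continue
                        j = ((x + dx) % length) * width + yy
                        if i != j:
                            gr.add_edge(i, j)
        return _from_graph(gr, ncell, g, D, "strip")
    raise TopologyError(
        f"unknown topology kind {kind!r}; valid kinds: single, pair, ring, "
        "clique, torus, hexagonal, strip"
    )


def coupling_matrices(topo: Topology) -> tuple[np.ndarray, np.ndarray]:
    """Weighted graph Laplacians ``(L_g, L_D)``.

    ``L_g`` carries the electrical strengths converted to rates
    (g / C_m, s⁻¹); ``L_D`` carries the diffusion strengths (s⁻¹).  The
    coupling input for cell *i* is ``-(L @ x)[i]`` for the respective state.
    """
    n = topo.n_cells
    Lg = np.zeros((n, n))
    LD = np.zeros((n, n))
    for (i, j), ge, de in zip(topo.edges, topo.g, topo.D):
        gr = ge / MEMBRANE_CAPACITANCE
        Lg[i, i] += gr
        Lg[j, j] += gr
        Lg[i, j] -= gr
        Lg[j, i] -= gr
        LD[i, i] += de
        LD[j, j] += de
        LD[i, j] -= de
        LD[j, i] -= de
    return Lg, LD


def coupling_terms(
    c: np.ndarray, v: np.ndarray, topo: Topology
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell coupling inputs ``(ca_input μM/s, v_input mV/s)``.

    For cell *i*: ``v_input = -Σ_j (g/C_m)(v_i - v_j)`` and
    ``ca_input = -Σ_j D (c_i - c_j)`` over neighbors *j*.  Both vanish for
    isolated cells and sum to zero over the network.
    """
    c = np.asarray(c, dtype=float)
    v = np.asarray(v, dtype=float)
    if c.shape != (topo.n_cells,) or v.shape != (topo.n_cells,):
        raise ValueError(
            f"state vectors must have shape ({topo.n_cells},); "
            f"got c{c.shape}, v{v.shape}"
        )
    ca = np.zeros(topo.n_cells)
    vv = np.zeros(topo.n_cells)
    # edge-difference form: exactly antisymmetric, exactly zero on equal states
    for (i, j), ge, de in zip(topo.edges, topo.g, topo.D):
        gr = ge / MEMBRANE_CAPACITANCE
        dc = c[i] - c[j]
        dv = v[i] - v[j]
        ca[i] -= de * dc
        ca[j] += de * dc
        vv[i] -= gr * dv
        vv[j] += gr * dv
    return ca, vv


def blocker_transform(topo: Topology) -> Topology:
    """Gap-junction blocker: zero every coupling strength, keep the edges.

    Models 18β-glycyrrhetinic acid treatment, which abolishes gap junctional
    communication without changing which cells touch.
    """
    ne = topo.n_edges
    return replace(topo, g=(0.0,) * ne, D=(0.0,) * ne, label=topo.label + "+blocker")


def read_edge_list(path_or_buffer, *, g: float = DEFAULT_G, D: float = DEFAULT_D,
                   label: str = "custom") -> Topology:
    """Read a topology from a whitespace-separated edge-list file.

    Two integer columns (0-based cell indices); optional third and fourth
    columns override ``g`` and ``D`` per edge.  Lines starting with ``#`` are
    comments.
    """
    if isinstance(path_or_buffer, (str,)):
        fh = open(path_or_buffer)
        close = True
    else:
        fh, close = path_or_buffer, False
    edges, gs, Ds = [], [], []
    try:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise TopologyError(f"edge line needs >= 2 columns: {line!r}")
            i, j = int(parts[0]), int(parts[1])
            ge = float(parts[2]) if len(parts) > 2 else g
            de = float(parts[3]) if len(parts) > 3 else D
            edges.append((min(i, j), max(i, j)))
            gs.append(ge)
            Ds.append(de)
    finally:
        if close:
            fh.close()
    n = 1 + max((max(e) for e in edges), default=0)
    order = np.argsort([e[0] * n + e[1] for e in edges])
    return Topology(
        n,
        tuple(edges[k] for k in order),
        tuple(gs[k] for k in order),
        tuple(Ds[k] for k in order),
        label,
    )


def degree_summary(topo: Topology) -> pd.DataFrame:
    """Per-cell degree and neighbor list as a DataFrame (CSV-exportable)."""
    deg = topo.degrees()
    rows = [
        {"cell": i, "degree": int(deg[i]),
         "neighbors": " ".join(map(str, topo.neighbors(i)))}
        for i in range(topo.n_cells)
    ]
    return pd.DataFrame(rows)
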