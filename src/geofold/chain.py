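"""Geometric state of a chain of spheres and the contact networks built on it.

A :class:`BeadChain` holds the positions and radii of ``N`` spheres whose
order defines the backbone of the chain; the same container carries Cα
coordinates when a chain is built from a protein structure.  A
:class:`ContactNetwork` is the symmetric, zero-diagonal adjacency over the
``N`` beads (or residues) — the object every downstream metric operates on.

Coordinates are stored in model units (bead diameter ≈ 1); a single
``unit_scale`` converts to Å when model aggregates are compared with
protein residue networks (the mean PRN link length, ≈ 5.066 Å, is the
conventional choice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "BeadChain",
    "ContactNetwork",
    "make_straight_chain",
    "pairwise_distances",
    "violates_exclusion",
    "write_xyz",
    "read_xyz",
    "write_edges_csv",
    "read_edges_csv",
]

#: Default relative overlap tolerance: the folding dynamics cannot maintain
#: exact tangency, and 1e-3 of a contact distance is far below anything that
#: could change contact topology.
DEFAULT_TOL_OVERLAP = 1e-3


@dataclass
class BeadChain:
    """Ordered chain of spheres: positions (N, 3), per-bead radii (N,).

    Chain order defines the backbone; node indexing is 0-based.

    Parameters
    ----------
    positions
        ``(N, 3)`` float array, model units (or Å when loaded from a PDB).
    radii
        ``(N,)`` positive floats; default convention is radius 0.5
        (unit diameter).
    unit_scale
        Physical length per model unit in Å; 1.0 for raw model output.
    """

    positions: np.ndarray
    radii: np.ndarray
    unit_scale: float = 1.0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.radii = np.ascontiguousarray(self.radii, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if self.radii.shape != (self.positions.shape[0],):
            raise ValueError("radii must be an (N,) array matching positions")
        if self.positions.shape[0] < 2:
            raise ValueError("a chain needs at least 2 beads")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be positive")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def __len__(self) -> int:
        return self.n_beads

    def copy(self) -> "BeadChain":
        return BeadChain(self.positions.copy(), self.radii.copy(), self.unit_scale)

    def contact_distances(self) -> np.ndarray:
        """(N, N) matrix of pairwise contact distances r_i + r_j."""
        return self.radii[:, None] + self.radii[None, :]


@dataclass
class ContactNetwork:
    """Symmetric, zero-diagonal contact graph over ``n_nodes`` beads/residues.

    Edges are unordered 0-based index pairs.  When the network is derived
    from a chain process the backbone edges {i, i+1} are always present.
    """

    n_nodes: int
    edges: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("need at least one node")
        self.edges = {self._key(i, j) for (i, j) in self.edges}

    @staticmethod
    def _key(i: int, j: int) -> tuple:
        if i == j:
            raise ValueError("self-loops are not allowed")
        return (int(i), int(j)) if i < j else (int(j), int(i))

    @classmethod
    def backbone(cls, n_nodes: int) -> "ContactNetwork":
        """Path graph 0-1-2-…-(N-1): the unfolded chain's network."""
        return cls(n_nodes, {(i, i + 1) for i in range(n_nodes - 1)})

    def has_edge(self, i: int, j: int) -> bool:
        return self._key(i, j) in self.edges

    def add_edge(self, i: int, j: int) -> None:
        k = self._key(i, j)
        if not (0 <= k[0] < self.n_nodes and 0 <= k[1] < self.n_nodes):
            raise ValueError(f"edge {k} out of range for {self.n_nodes} nodes")
        self.edges.add(k)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix with zero diagonal."""
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.float64)
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def edge_array(self) -> np.ndarray:
        """(E, 2) int64 array of sorted edge pairs, lexicographically ordered."""
        if not self.edges:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(sorted(self.edges), dtype=np.int64)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    def copy(self) -> "ContactNetwork":
        return ContactNetwork(self.n_nodes, set(self.edges))


def make_straight_chain(N: int, a: float = 0.0, seed: int = 0) -> BeadChain:
    """Initial state: a straight chain of ``N`` touching spheres on the x-axis.

    With heterogeneity ``a`` ∈ [0, 0.5] the bead diameters are drawn
    uniformly from [1 − a, 1 + a] (mean diameter 1); ``a = 0`` gives the
    homogeneous unit-diameter chain.  Consecutive beads touch, i.e. the
    bond length between beads i and i+1 is r_i + r_{i+1} (exactly 1 for
    the homogeneous chain).

    Raises
    ------
    ValueError
        If ``N < 2`` or ``a`` is outside [0, 0.5].
    """
    if N < 2:
        raise ValueError(f"chain length must be >= 2, got {N}")
    if not 0.0 <= a <= 0.5:
        raise ValueError(f"heterogeneity a must lie in [0, 0.5], got {a}")
    rng = np.random.default_rng(seed)
    if a == 0.0:
        radii = np.full(N, 0.5)
    else:
        radii = rng.uniform(1.0 - a, 1.0 + a, size=N) / 2.0
    x = np.zeros(N)
    # bond i -> i+1 has length r_i + r_{i+1}: beads tangent along the axis
    x[1:] = np.cumsum(radii[:-1] + radii[1:])
    positions = np.column_stack([x, np.zeros(N), np.zeros(N)])
    return BeadChain(positions, radii)


def pairwise_distances(chain: BeadChain) -> np.ndarray:
    """Symmetric (N, N) Euclidean distance matrix d_ij = ‖x_i − x_j‖."""
    return squareform(pdist(chain.positions))


def violates_exclusion(
    chain: BeadChain, tol_overlap: float = DEFAULT_TOL_OVERLAP
) -> tuple:
    """Check the volume-exclusion constraint.

    Returns ``(violated, pairs)`` where ``violated`` is True iff some pair
    (i, j) satisfies ``d_ij < (r_i + r_j)(1 − tol_overlap)``, and ``pairs``
    lists the offending (i, j) index pairs.
    """
    if tol_overlap < 0:
        raise ValueError("tol_overlap must be >= 0")
    d = pairwise_distances(chain)
    contact = chain.contact_distances()
    bad = d < contact * (1.0 - tol_overlap)
    np.fill_diagonal(bad, False)
    ii, jj = np.nonzero(np.triu(bad, k=1))
    pairs = [(int(i), int(j)) for i, j in zip(ii, jj)]
    return (len(pairs) > 0, pairs)


# ---------------------------------------------------------------------------
# plain-text I/O: XYZ for coordinates, CSV edge lists for networks
# ---------------------------------------------------------------------------


def write_xyz(chain: BeadChain, path, comment: str = "geofold chain") -> None:
    """Write bead coordinates in XYZ format (element tag "C" per bead)."""
    with open(path, "w") as fh:
        fh.write(f"{chain.n_beads}\n{comment}\n")
        for x, y, z in chain.positions:
            fh.write(f"C {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path, radii: np.ndarray | None = None) -> BeadChain:
    """Read an XYZ file back into a BeadChain (unit radii unless given)."""
    with open(path) as fh:
        n = int(fh.readline().strip())
        fh.readline()  # comment
        coords = []
        for _ in range(n):
            parts = fh.readline().split()
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
    positions = np.array(coords)
    if radii is None:
        radii = np.full(n, 0.5)
    return BeadChain(positions, radii)


def write_edges_csv(net: ContactNetwork, path) -> None:
    """Write the edge list as two-column CSV ``i,j`` (0-based, i < j)."""
    with open(path, "w") as fh:
        fh.write("i,j\n")
        for i, j in sorted(net.edges):
            fh.write(f"{i},{j}\n")


def read_edges_csv(path, n_nodes: int | None = None) -> ContactNetwork:
    """Read a two-column ``i,j`` CSV edge list.

    ``n_nodes`` defaults to ``max index + 1``.
    """
    edges = set()
    with open(path) as fh:
        header = fh.readline().strip().lower()
        if header.replace(" ", "") != "i,j":
            raise ValueError(f"expected header 'i,j', got {header!r}")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            i_s, j_s = line.split(",")
            edges.add((int(i_s), int(j_s)))
    if n_nodes is None:
        n_nodes = max((max(e) for e in edges), default=0) + 1
    return ContactNetwork(n_nodes, edges)
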