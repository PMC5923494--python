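"""Hexagon-shaped hexagonal lattice of cells.

The monolayer is modelled as a hexagon-shaped patch of a hexagonal grid:
every interior cell touches exactly ``k = 6`` neighbors, and a patch with
``side`` cells per edge contains ``3*side**2 - 3*side + 1`` cells (the
centered-hexagonal numbers).  Sites are addressed by axial coordinates
``(q, r)`` with the hex distance ``max(|q|, |r|, |q+r|)`` from the center
bounded by ``side - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

#: axial-coordinate offsets of the six hexagonal neighbors
AXIAL_DIRECTIONS = ((1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1))


def n_sites_for_side(side: int) -> int:
    """Number of cells in a hexagon-shaped patch with ``side`` cells per edge."""
    return 3 * side * side - 3 * side + 1


@dataclass(frozen=True)
class HexLattice:
    """Immutable container for site coordinates and adjacency.

    Attributes
    ----------
    side : cells per edge of the hexagonal patch.
    coords : ``(n_sites, 2)`` integer axial coordinates ``(q, r)``.
    adjacency : ``(n_sites, 6)`` neighbor site indices, padded with ``-1``
        where a boundary cell has fewer than six neighbors.
    degrees : number of actual neighbors per site.
    k : nominal neighbor count of an interior cell (6).
    """

    side: int
    coords: np.ndarray
    adjacency: np.ndarray
    degrees: np.ndarray
    k: int = 6
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        """Neighbor indices of site ``i`` (boundary cells have fewer than k)."""
        row = self.adjacency[i]
        return row[row >= 0]

    @property
    def center_index(self) -> int:
        """Index of the central site (axial origin)."""
        return self._cache["center"]

    def adjacency_matrix(self) -> sparse.csr_matrix:
        """Symmetric 0/1 adjacency matrix in CSR format."""
        if "adj_csr" not in self._cache:
            n = self.n_sites
            rows = np.repeat(np.arange(n), self.degrees)
            cols = self.adjacency[self.adjacency >= 0]
            a = sparse.csr_matrix(
                (np.ones(rows.size), (rows, cols)), shape=(n, n)
            )
            self._cache["adj_csr"] = a
        return self._cache["adj_csr"]

    def exchange_matrix(self, m: float) -> sparse.csr_matrix:
        """One-step virion exchange operator ``I + (m/k)(A - D)``.

        Each site sends a fraction ``m/k`` of its load to every existing
        neighbor (no-flux boundary: boundary cells exchange only across
        their existing edges, with the divisor kept at ``k``).  The
        operator conserves the lattice total exactly and leaves uniform
        fields unchanged on the interior.
        """
        key = ("exchange", float(m))
        if key not in self._cache:
            n = self.n_sites
            a = self.adjacency_matrix()
            d = sparse.diags(self.degrees.astype(float))
            ident = sparse.identity(n, format="csr")
            self._cache[key] = (ident + (m / self.k) * (a - d)).tocsr()
        return self._cache[key]


def build_hex_lattice(side: int) -> HexLattice:
    """Construct the hexagon-shaped hexagonal lattice with ``side`` cells/edge.

    Parameters
    ----------
    side : number of cells along each of the six edges (``side >= 1``).

    Returns
    -------
    HexLattice with ``3*side**2 - 3*side + 1`` sites and symmetric
    adjacency; interior cells have exactly six neighbors.
    """
    if side < 1:
        raise ValueError(f"side must be >= 1, got {side}")
    radius = side - 1
    coords = []
    for q in range(-radius, radius + 1):
        for r in range(max(-radius, -q - radius), min(radius, -q + radius) + 1):
            coords.append((q, r))
    coords = np.array(coords, dtype=np.int64)
    index = {(int(q), int(r)): i for i, (q, r) in enumerate(coords)}
    n = coords.shape[0]
    adjacency = np.full((n, 6), -1, dtype=np.int64)
    degrees = np.zeros(n, dtype=np.int64)
    for i, (q, r) in enumerate(coords):
        d = 0
        for dq, dr in AXIAL_DIRECTIONS:
            j = index.get((int(q) + dq, int(r) + dr))
            if j is not None:
                adjacency[i, d] = j
                d += 1
        degrees[i] = d
    lat = HexLattice(side=side, coords=coords, adjacency=adjacency, degrees=degrees)
    lat._cache["center"] = index[(0, 0)]
    return lat
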