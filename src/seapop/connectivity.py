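"""Dispersal-probability matrices, multi-generation powering, networks.

Orientation convention (the classic source of bugs, fixed here once):
``P[i, j]`` is the probability that a propagule released in *source*
cell ``j`` ends in *destination* cell ``i`` — destination-row,
source-column.  Columns are sub-stochastic: the deficit from 1 is the
fraction of particles lost offshore, to deep cells, or over the open
boundary.  Powering ``P^n`` composes ``n`` successive dispersal events
("multi-generation connectivity"); no renormalisation is applied, so
entries underflow toward zero exactly as absolute probabilities do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core import PairwiseMatrix
from .dispersal import TrajectorySet
from .seascape import SitePlacement


@dataclass
class ConnectivityMatrix:
    """Cell-to-cell dispersal probabilities (destination row, source column)."""

    cells: np.ndarray  # flat grid indices, ordered
    P: np.ndarray
    generation: int = 1

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=int)
        self.P = np.asarray(self.P, dtype=float)
        n = len(self.cells)
        if self.P.shape != (n, n):
            raise ValueError("P must be square over the cell list")
        if self.generation < 1:
            raise ValueError("generation must be >= 1")
        if np.any(self.P < 0) or np.any(self.P > 1):
            raise ValueError("entries must be probabilities in [0, 1]")
        if np.any(self.P.sum(axis=0) > 1 + 1e-9):
            raise ValueError("columns must sum to at most 1")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.P, index=self.cells, columns=self.cells).to_csv(path)


@dataclass
class SiteConnectivity:
    """Site-aggregated connectivities: directed D and symmetrised S."""

    sites: list[str]
    D: np.ndarray  # D[a, b] = probability b -> a (destination row)

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.sites)
        if self.D.shape != (n, n):
            raise ValueError("D shape mismatch")

    @property
    def S(self) -> np.ndarray:
        """Direction-averaged symmetric connectivity."""
        return 0.5 * (self.D + self.D.T)

    @property
    def n_directed_pairs(self) -> int:
        n = len(self.sites)
        return n * (n - 1)


def assemble(trajectories: TrajectorySet, cells: np.ndarray) -> ConnectivityMatrix:
    """Tally trajectories into a single-event dispersal matrix.

    ``P[i, j]`` = (# trajectories from cells[j] ending in cells[i]) /
    (# released from cells[j]).  Trajectories ending LOST or in a cell
    not in ``cells`` (e.g. deep water) count toward the column deficit.
    """
    cells = np.asarray(cells, dtype=int)
    n = len(cells)
    pos = {int(c): k for k, c in enumerate(cells)}
    src = np.array([pos.get(int(c), -1) for c in trajectories.start_cell])
    if np.any(src < 0):
        bad = sorted(set(trajectories.start_cell[src < 0].tolist()))
        raise ValueError(f"trajectories start in cells not in the list: {bad[:5]}")
    released = np.bincount(src, minlength=n)
    zero = np.flatnonzero(released == 0)
    if len(zero):
        raise ValueError(f"cells with zero releases: {cells[zero].tolist()[:5]}")
    dst = np.array([pos.get(int(c), -1) for c in trajectories.end_cell])
    ok = dst >= 0
    counts = np.zeros((n, n))
    np.add.at(counts, (dst[ok], src[ok]), 1)
    return ConnectivityMatrix(cells, counts / released[None, :], generation=1)


def power(matrix: ConnectivityMatrix, n: int) -> ConnectivityMatrix:
    """``P^n``: connectivity over n successive dispersal events.

    Computed in double precision with no renormalisation; tiny entries
    underflow toward zero, preserving the absolute-probability scale.
    """
    if n < 1:
        raise ValueError("power must be >= 1")
    Pn = np.linalg.matrix_power(matrix.P, n)
    Pn = np.clip(Pn, 0.0, 1.0)  # guard tiny negative round-off
    return ConnectivityMatrix(matrix.cells, Pn, generation=matrix.generation * n)


def aggregate_sites(matrix: ConnectivityMatrix, placement: SitePlacement) -> SiteConnectivity:
    """Average the 5x5 cell blocks of each site pair into site connectivities.

    ``D[a, b]`` is the mean of ``P[i in cells_a, j in cells_b]`` — the
    mean probability that a propagule from a cell of site b settles in a
    cell of site a.  The diagonal is stored but excluded from analyses.
    """
    pos = {int(c): k for k, c in enumerate(matrix.cells)}
    idx: dict[str, np.ndarray] = {}
    for lab in placement.labels:
        block = placement.release_cells[lab]
        missing = [int(c) for c in block if int(c) not in pos]
        if missing:
            raise ValueError(f"site {lab}: cells missing from matrix: {missing}")
        idx[lab] = np.array([pos[int(c)] for c in block])
    n = len(placement.labels)
    D = np.zeros((n, n))
    for a, la in enumerate(placement.labels):
        for b, lb in enumerate(placement.labels):
            D[a, b] = matrix.P[np.ix_(idx[la], idx[lb])].mean()
    return SiteConnectivity(list(placement.labels), D)


def build_network(conn: SiteConnectivity, threshold: float) -> nx.Graph:
    """Thresholded connectivity network.

    An edge joins two sites when the directed connectivity clears the
    threshold in at least one direction; it is classed ``bidirectional``
    when both directions clear it and ``monodirectional`` otherwise.
    Edge weight is the larger of the two directed values.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    g = nx.Graph()
    g.add_nodes_from(conn.sites)
    n = len(conn.sites)
    for a in range(n):
        for b in range(a + 1, n):
            ab, ba = conn.D[b, a], conn.D[a, b]  # a->b lands in row b
            if max(ab, ba) >= threshold:
                g.add_edge(
                    conn.sites[a],
                    conn.sites[b],
                    weight=float(max(ab, ba)),
                    direction="bidirectional" if min(ab, ba) >= threshold else "monodirectional",
                )
    return g


def network_to_edgelist(g: nx.Graph, path) -> None:
    """Write the network as a TSV edge list (source, target, weight, class)."""
    rows = [
        {"source": a, "target": b, "weight": d["weight"], "class": d["direction"]}
        for a, b, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight", "class"]).to_csv(
        path, sep="\t", index=False
    )


def connectivity_to_distance(conn: SiteConnectivity, floor: float = 1e-60) -> PairwiseMatrix:
    """Distance-like transform of symmetric connectivity: -log10(max(S, floor)).

    Monotone decreasing in connectivity, so high exchange maps to short
    distance; the floor bounds the transform for zero/underflowed
    entries.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    d = -np.log10(np.maximum(conn.S, floor))
    np.fill_diagonal(d, 0.0)
    return PairwiseMatrix(list(conn.sites), d, kind="conn_distance")


def migration_from_connectivity(
    conn: SiteConnectivity,
    m_total: float,
    site_scaling: str = "uniform",
    m_floor_frac: float = 0.15,
    floor: float = 1e-60,
) -> np.ndarray:
    """Per-generation deme migration matrix shaped by directed connectivity.

    Row ``a`` gives the source distribution for offspring recruiting to
    deme ``a``: off-diagonal entries are proportional to the directed
    connectivities into ``a`` (``D[a, b]``), scaled so immigrants total
    the row's immigration rate; the diagonal is the complement.  A site
    with no inward connectivity falls back to a uniform immigrant row
    (with a warning).

    ``site_scaling`` sets how each row's immigration rate relates to the
    site's *absolute* inward connectivity:

    - ``"uniform"``: every row receives exactly ``m_total`` immigrants —
      only the relative source shares carry connectivity information.
    - ``"log"``: rows receive between ``m_floor_frac * m_total`` and
      ``m_total``, log-linearly in total inward connectivity, so
      oceanographically isolated sites also receive fewer migrants in
      total.  This preserves the isolation signal that drives the
      connectivity-differentiation relationship.
    """
    if not 0 < m_total < 1:
        raise ValueError("m_total must be in (0, 1)")
    if site_scaling not in ("uniform", "log"):
        raise ValueError("site_scaling must be 'uniform' or 'log'")
    n = len(conn.sites)
    D = conn.D.copy()
    np.fill_diagonal(D, 0.0)
    totals = D.sum(axis=1)
    if site_scaling == "log":
        x = np.log10(np.maximum(totals, floor))
        span = x.max() - x.min()
        z = (x - x.min()) / span if span > 0 else np.ones(n)
        m_row = m_total * (m_floor_frac + z * (1.0 - m_floor_frac))
    else:
        m_row = np.full(n, m_total)
    M = np.zeros((n, n))
    for a in range(n):
        if totals[a] <= 0:
            warnings.warn(
                f"site {conn.sites[a]} has zero inward connectivity; uniform fallback"
            )
            share = np.full(n, 1.0 / (n - 1))
            share[a] = 0.0
        else:
            share = D[a] / totals[a]
        M[a] = m_row[a] * share
        M[a, a] = 1.0 - m_row[a]
    return M
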