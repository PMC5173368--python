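"""Distance-band neighbor graphs and global spatial autocorrelation tests.

Implements Moran's I for interval data and the single-colour (presence-
presence, "BB") join-count statistic for binary data on distance-band
neighbor graphs over projected point coordinates, with the classical
randomization / non-free-sampling null moments, and multi-scale profiles
("correlograms") across increasing distance bands.

Weights coding styles follow the usual convention: ``B`` binary, ``W``
row-standardized, ``C`` globally standardized so all weights sum to the
number of connected nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from scipy.stats import norm

__all__ = [
    "NeighborGraph",
    "MoranResult",
    "JoinCountResult",
    "ScaleProfile",
    "build_graph",
    "morans_i",
    "join_count_bb",
    "scale_profile",
    "default_bands",
]

Style = Literal["W", "B", "C"]


@dataclass
class NeighborGraph:
    """Symmetric distance-band neighbor relation with coded weights.

    ``i ~ j`` iff ``0 < dist(i, j) <= band_m``. ``weights`` holds the coded
    (possibly asymmetric, e.g. row-standardized) weight matrix; island rows
    (nodes with no neighbor inside the band) are all-zero.
    """

    n: int
    band_m: float
    style: Style
    weights: sp.csr_matrix
    islands: np.ndarray  # boolean mask, True where the node has no neighbor

    @property
    def n_islands(self) -> int:
        return int(self.islands.sum())

    @property
    def all_islands(self) -> bool:
        return bool(self.islands.all())


def build_graph(coords: np.ndarray, band_m: float, style: Style = "W") -> NeighborGraph:
    """Build the distance-band neighbor graph over projected points.

    Distances are planar Euclidean on meter coordinates. The band is
    half-open ``(0, band_m]``: coincident points are never neighbors of each
    other, the upper bound is inclusive.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array of projected meters")
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least two points")
    if band_m <= 0:
        raise ValueError("band_m must be positive")
    if np.allclose(coords, coords[0]):
        raise ValueError("all points coincident; neighbor graph undefined")
    if style not in ("W", "B", "C"):
        raise ValueError(f"unknown style {style!r}")

    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=band_m, output_type="ndarray")
    if pairs.size:
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d > 0.0]
    if pairs.size == 0:
        weights = sp.csr_matrix((n, n))
        return NeighborGraph(n=n, band_m=float(band_m), style=style,
                             weights=weights, islands=np.ones(n, dtype=bool))

    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    adj = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    degree = np.asarray(adj.sum(axis=1)).ravel()
    islands = degree == 0

    if style == "B":
        weights = adj
    elif style == "W":
        inv = np.zeros(n)
        inv[~islands] = 1.0 / degree[~islands]
        weights = sp.diags(inv) @ adj
    else:  # C: globally standardized, total weight = number of connected nodes
        n_active = int((~islands).sum())
        weights = adj * (n_active / adj.sum())
    return NeighborGraph(n=n, band_m=float(band_m), style=style,
                         weights=sp.csr_matrix(weights), islands=islands)


def _active_weights(graph: NeighborGraph) -> tuple[sp.csr_matrix, np.ndarray]:
    """Submatrix over connected (non-island) nodes and the active mask.

    Islands carry zero weight rows/columns, so dropping them changes only
    the effective n and the mean-centering of the values, which is exactly
    the intended island policy for the null moments.
    """
    active = ~graph.islands
    w = graph.weights[active][:, active]
    return sp.csr_matrix(w), active


def _s_constants(w: sp.csr_matrix) -> tuple[float, float, float]:
    s0 = float(w.sum())
    wt = w + w.T
    s1 = 0.5 * float(wt.multiply(wt).sum())
    row = np.asarray(w.sum(axis=1)).ravel()
    col = np.asarray(w.sum(axis=0)).ravel()
    s2 = float(((row + col) ** 2).sum())
    return s0, s1, s2


@dataclass
class MoranResult:
    """Moran's I with randomization-null moments.

    ``I`` ranges from -1 (perfect dispersion) to +1 (perfect correlation),
    0 indicating a spatially random pattern; the null expectation is
    ``-1/(n-1)`` for ``n`` connected nodes.
    """

    I: float
    expected: float
    variance: float
    z: float
    p_two_sided: float
    n: int  # connected nodes used
    n_islands: int = 0

    @property
    def ci95(self) -> tuple[float, float]:
        half = 1.96 * np.sqrt(self.variance)
        return (self.I - half, self.I + half)


def morans_i(graph: NeighborGraph, values: np.ndarray) -> MoranResult:
    """Global Moran's I of ``values`` on a neighbor graph.

    ``I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i**2`` with ``z`` the
    mean-centered values over connected nodes. Expectation, variance and the
    two-sided normal p-value are computed under the randomization
    (permutation-moment) null. Raises for constant values, whose statistic
    is undefined.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (graph.n,):
        raise ValueError(f"values length {values.shape} != graph n {graph.n}")
    if graph.all_islands:
        raise ValueError("every node is an island at this band; I undefined")
    w, active = _active_weights(graph)
    x = values[active]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 connected nodes")
    z = x - x.mean()
    m2 = float(z @ z)
    if m2 == 0.0:
        raise ValueError("values are constant over connected nodes; Moran's I undefined")

    s0, s1, s2 = _s_constants(w)
    i_stat = (n / s0) * float(z @ (w @ z)) / m2
    expected = -1.0 / (n - 1)
    b2 = n * float((z ** 4).sum()) / (m2 ** 2)
    num = (n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
           - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0))
    den = (n - 1) * (n - 2) * (n - 3) * s0 * s0
    variance = max(num / den - expected * expected, 0.0)
    if variance > 0:
        zscore = (i_stat - expected) / np.sqrt(variance)
        p = 2.0 * norm.sf(abs(zscore))
    else:
        zscore, p = np.nan, np.nan
    return MoranResult(I=i_stat, expected=expected, variance=variance,
                       z=zscore, p_two_sided=p, n=n, n_islands=graph.n_islands)


@dataclass
class JoinCountResult:
    """Weighted presence-presence join count with non-free-sampling moments.

    ``bb = 0.5 * sum_ij w_ij x_i x_j`` for a binary vector ``x``; the null
    mean and variance condition on the observed number of presences
    (hypergeometric sampling without replacement). The p-value is one-sided
    for an excess of presence-presence joins (clustering).
    """

    bb: float
    expected: float
    variance: float
    z: float
    p_one_sided: float
    n: int
    n_present: int
    degenerate: bool = False
    n_islands: int = 0

    @property
    def ci95(self) -> tuple[float, float]:
        half = 1.96 * np.sqrt(self.variance)
        return (self.bb - half, self.bb + half)


def join_count_bb(graph: NeighborGraph, presence: np.ndarray) -> JoinCountResult:
    presence = np.asarray(presence)
    if presence.shape != (graph.n,):
        raise ValueError(f"presence length {presence.shape} != graph n {graph.n}")
    uniq = np.unique(presence)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError("presence must be binary 0/1")
    if graph.all_islands:
        raise ValueError("every node is an island at this band; join count undefined")
    w, active = _active_weights(graph)
    x = presence[active].astype(float)
    n = x.size
    n1 = int(x.sum())
    bb = 0.5 * float(x @ (w @ x))

    if n1 == 0 or n1 == n or n < 4:
        return JoinCountResult(bb=bb, expected=np.nan, variance=np.nan, z=np.nan,
                               p_one_sided=np.nan, n=n, n_present=n1,
                               degenerate=True, n_islands=graph.n_islands)

    s0, s1, s2 = _s_constants(w)
    # falling-factorial sampling probabilities of drawing 2, 3, 4 distinct
    # presences without replacement
    p2 = n1 * (n1 - 1) / (n * (n - 1))
    p3 = n1 * (n1 - 1) * (n1 - 2) / (n * (n - 1) * (n - 2))
    p4 = n1 * (n1 - 1) * (n1 - 2) * (n1 - 3) / (n * (n - 1) * (n - 2) * (n - 3))
    expected = 0.5 * s0 * p2
    e_bb2 = 0.25 * (s1 * p2 + (s2 - 2.0 * s1) * p3 + (s0 * s0 + s1 - s2) * p4)
    variance = max(e_bb2 - expected * expected, 0.0)
    if variance > 0:
        zscore = (bb - expected) / np.sqrt(variance)
        p = norm.sf(zscore)
    else:
        zscore, p = np.nan, np.nan
    return JoinCountResult(bb=bb, expected=expected, variance=variance, z=zscore,
                           p_one_sided=p, n=n, n_present=n1,
                           n_islands=graph.n_islands)


def default_bands(coords: np.ndarray, n_bands: int = 20) -> np.ndarray:
    """Equally spaced distance thresholds from the 1st percentile of pairwise
    distances to the maximal pairwise extent of the point set."""
    coords = np.asarray(coords, dtype=float)
    d = pdist(coords)
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("all points coincident")
    lo = float(np.percentile(d, 1))
    hi = float(d.max())
    if n_bands == 1:
        return np.array([hi])
    return np.linspace(lo, hi, n_bands)


@dataclass
class ScaleProfile:
    """Per-band autocorrelation results across increasing spatial scales."""

    bands: np.ndarray
    results: list  # MoranResult | JoinCountResult | None per band
    islands_per_band: list[int] = field(default_factory=list)
    stat: str = "moran"
    style: Style = "W"

    def to_frame(self):
        import pandas as pd

        rows = []
        for band, res, isl in zip(self.bands, self.results, self.islands_per_band):
            if res is None:
                rows.append({"band_m": band, "n_islands": isl})
                continue
            lo, hi = res.ci95
            row = {"band_m": band, "n_islands": isl, "n": res.n,
                   "expected": res.expected, "variance": res.variance,
                   "z": res.z, "ci_lo": lo, "ci_hi": hi}
            if isinstance(res, MoranResult):
                row["estimate"] = res.I
                row["p"] = res.p_two_sided
            else:
                row["estimate"] = res.bb
                row["p"] = res.p_one_sided
                row["degenerate"] = res.degenerate
            rows.append(row)
        return pd.DataFrame(rows)


def scale_profile(coords: np.ndarray, values: np.ndarray,
                  stat: Literal["moran", "joincount"] = "moran",
                  bands: Sequence[float] | None = None,
                  n_bands: int = 20, style: Style = "W") -> ScaleProfile:
    """Compute Moran's I or the BB join count across increasing distance bands.

    The default band rule uses :func:`default_bands` (20 equal thresholds up
    to the maximal pairwise distance). Bands where the statistic is
    undefined (all islands, constant values over connected nodes) are
    recorded as ``None`` rather than aborting the profile.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 points for a profile")
    if bands is None:
        bands = default_bands(coords, n_bands=n_bands)
    bands = np.asarray(bands, dtype=float)
    if bands.size == 0:
        raise ValueError("empty band list")
    if not np.all(np.diff(bands) > 0) and bands.size > 1:
        raise ValueError("bands must be strictly increasing")

    results: list = []
    islands: list[int] = []
    for band in bands:
        graph = build_graph(coords, band, style=style)
        islands.append(graph.n_islands)
        try:
            if stat == "moran":
                results.append(morans_i(graph, values))
            elif stat == "joincount":
                results.append(join_count_bb(graph, values))
            else:
                raise ValueError(f"unknown stat {stat!r}")
        except ValueError:
            results.append(None)
    return ScaleProfile(bands=bands, results=results, islands_per_band=islands,
                        stat=stat, style=style)
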