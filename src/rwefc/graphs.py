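"""Graph-theory metrics on the RWE synchronization matrix.

The non-symmetric RWE matrix W is a dissimilarity (0 = identical spectral
profiles).  It is symmetrized by averaging into a distance matrix D, and
inverted/normalized into a similarity matrix S = 1 - D / max(D) (off-diagonal
max; diagonal kept at zero).  Strength-type metrics (clustering coefficient,
connection density) are computed on S; path-type metrics (characteristic path
length and efficiency) use D directly as edge length.

Twelve scalar features per epoch: eight per-electrode clustering
coefficients, CPL, CPE, connection density and the small-world index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import CANONICAL_CHANNELS

LEFT_INDICES = tuple(range(4))
RIGHT_INDICES = tuple(range(4, 8))

GRAPH_FEATURE_NAMES = tuple(f"cc_{ch}" for ch in CANONICAL_CHANNELS) + (
    "cpl",
    "cpe",
    "cd",
    "sw",
)


@dataclass(frozen=True)
class SynchronizationGraph:
    """Similarity (S) and distance (D) views of one epoch's connectivity."""

    similarity: np.ndarray
    distance: np.ndarray


@dataclass(frozen=True)
class GraphMetricSet:
    cc: np.ndarray  # one value per electrode
    cpl: float
    cpe: float
    cd: float
    sw: float

    @property
    def values(self) -> np.ndarray:
        """The 12 scalars in the fixed feature order: cc x8, cpl, cpe, cd, sw."""
        return np.concatenate([self.cc, [self.cpl, self.cpe, self.cd, self.sw]])


@dataclass(frozen=True)
class HemisphericConnectivity:
    """Mean raw RWE over within-left, within-right and cross-hemisphere pairs."""

    lmc: float
    rmc: float
    imc: float


def to_graph(W: np.ndarray) -> SynchronizationGraph:
    """Symmetrize W into distance D and invert/normalize into similarity S."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("connectivity matrix must be square")
    n = W.shape[0]
    D = 0.5 * (W + W.T)
    np.fill_diagonal(D, 0.0)
    off = ~np.eye(n, dtype=bool)
    d_max = D[off].max() if n > 1 else 0.0
    if d_max > 0:
        S = 1.0 - D / d_max
    else:  # degenerate: all channels identical
        S = np.zeros_like(D)
    np.fill_diagonal(S, 0.0)
    return SynchronizationGraph(similarity=S, distance=D)


def clustering_coefficients(graph: SynchronizationGraph | np.ndarray) -> np.ndarray:
    """Weighted clustering coefficient per node on S (geometric mean of
    triangle weights; weights already normalized to [0, 1])."""
    S = graph.similarity if isinstance(graph, SynchronizationGraph) else np.asarray(graph, float)
    return _batched_cc(S[None])[0]


def _batched_cc(S: np.ndarray) -> np.ndarray:
    """Clustering coefficients for a (batch, n, n) stack of similarity matrices."""
    root = np.cbrt(S)
    triangles = np.einsum("...ij,...jk,...ki->...i", root, root, root)
    degree = (S > 0).sum(axis=-1)
    denom = degree * (degree - 1)
    return np.where(denom > 0, triangles / np.maximum(denom, 1), 0.0)


def shortest_path_matrix(D: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances (Floyd-Warshall; supports batches)."""
    P = np.array(D, dtype=float, copy=True)
    n = P.shape[-1]
    for k in range(n):
        via = P[..., :, k, None] + P[..., None, k, :]
        P = np.minimum(P, via)
    return P


def characteristic_path_length(graph: SynchronizationGraph | np.ndarray) -> float:
    """Mean shortest-path distance over all unordered node pairs of D."""
    D = graph.distance if isinstance(graph, SynchronizationGraph) else np.asarray(graph, float)
    P = shortest_path_matrix(D)
    iu = np.triu_indices(D.shape[0], k=1)
    return float(P[iu].mean())


def path_efficiency(graph: SynchronizationGraph | np.ndarray, epsilon: float = 1e-12) -> float:
    """Mean inverse shortest-path distance (global efficiency); zero-length
    paths are capped at 1/epsilon."""
    D = graph.distance if isinstance(graph, SynchronizationGraph) else np.asarray(graph, float)
    P = shortest_path_matrix(D)
    iu = np.triu_indices(D.shape[0], k=1)
    return float((1.0 / np.maximum(P[iu], epsilon)).mean())


def connection_density(graph: SynchronizationGraph, tau: float | None = None) -> float:
    """Fraction of unordered pairs whose similarity exceeds ``tau``.

    Default ``tau`` is the median off-diagonal similarity of the epoch's own
    graph, which centers the density near 0.5 and makes it sensitive to the
    shape of the similarity distribution rather than its location.
    """
    S = graph.similarity
    iu = np.triu_indices(S.shape[0], k=1)
    vals = S[iu]
    if tau is None:
        tau = float(np.median(vals))
    return float((vals > tau).mean())


def small_world(
    graph: SynchronizationGraph, n_random: int = 20, seed: int | np.random.Generator = 0
) -> float:
    """Small-world index: (mean CC / null CC) / (CPL / null CPL).

    The null ensemble preserves the weight multiset and graph size: the 28
    off-diagonal weights of S (and the corresponding entries of D) are
    shuffled with a seeded generator, ``n_random`` times.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S, D = graph.similarity, graph.distance
    n = S.shape[0]
    iu = np.triu_indices(n, k=1)
    s_vals, d_vals = S[iu], D[iu]

    base_cc = float(clustering_coefficients(graph).mean())
    base_cpl = characteristic_path_length(graph)

    perms = np.stack([rng.permutation(s_vals.size) for _ in range(n_random)])
    S_rand = np.zeros((n_random, n, n))
    D_rand = np.zeros((n_random, n, n))
    S_rand[:, iu[0], iu[1]] = s_vals[perms]
    D_rand[:, iu[0], iu[1]] = d_vals[perms]
    S_rand += np.swapaxes(S_rand, 1, 2)
    D_rand += np.swapaxes(D_rand, 1, 2)

    cc_rand = float(_batched_cc(S_rand).mean())
    P_rand = shortest_path_matrix(D_rand)
    cpl_rand = float(P_rand[:, iu[0], iu[1]].mean())

    if base_cpl == 0 or cc_rand == 0 or cpl_rand == 0:
        raise ValueError("degenerate graph: small-world index undefined")
    return (base_cc / cc_rand) / (base_cpl / cpl_rand)


def graph_features(
    W: np.ndarray,
    tau: float | None = None,
    n_random: int = 20,
    seed: int | np.random.Generator = 0,
) -> GraphMetricSet:
    """The 12 graph features of one connectivity matrix, in documented order."""
    graph = to_graph(W)
    return GraphMetricSet(
        cc=clustering_coefficients(graph),
        cpl=characteristic_path_length(graph),
        cpe=path_efficiency(graph),
        cd=connection_density(graph, tau=tau),
        sw=small_world(graph, n_random=n_random, seed=seed),
    )


def _ordered_pair_mean(W: np.ndarray, rows, cols) -> float:
    vals = [W[i, j] for i in rows for j in cols if i != j]
    return float(np.mean(vals))


def hemispheric_means(W: np.ndarray) -> HemisphericConnectivity:
    """LMC / RMC / IMC: mean raw RWE over the 12 ordered within-left pairs,
    12 within-right pairs and 32 cross-hemisphere pairs."""
    W = np.asarray(W, dtype=float)
    cross = [W[i, j] for i in LEFT_INDICES for j in RIGHT_INDICES]
    cross += [W[i, j] for i in RIGHT_INDICES for j in LEFT_INDICES]
    return HemisphericConnectivity(
        lmc=_ordered_pair_mean(W, LEFT_INDICES, LEFT_INDICES),
        rmc=_ordered_pair_mean(W, RIGHT_INDICES, RIGHT_INDICES),
        imc=float(np.mean(cross)),
    )
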