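"""Band energies, relative wavelet energy distributions and RWE connectivity.

The five EEG rhythms used throughout are delta (0.5-4 Hz), theta (4-8 Hz),
alpha (8-12 Hz), beta (12-20 Hz) and gamma (20-50 Hz).  Each channel of an
epoch is summarized by the relative energy it carries in each rhythm -- a
five-point probability distribution.  Relative Wavelet Entropy (RWE) between
two channels is the Kullback-Leibler divergence between their distributions
(natural log): zero for identical spectral profiles, positive otherwise, and
generally asymmetric, which is why the 8x8 connectivity matrix carries 56
informative off-diagonal entries.

Two interchangeable band-energy backends are provided:

``"wavelet"`` (default)
    Wavelet-packet decomposition (Daubechies-4, depth 6), summing squared
    coefficients of the frequency-ordered terminal nodes; nodes whose nominal
    ~3.9 Hz bin straddles a band edge are weighted by fractional overlap.
``"bandpass"``
    5th-order zero-phase Butterworth band-pass per rhythm, summing squared
    samples.  Serves as the independent cross-check of the wavelet route.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import signal as sps

from .recording import Epoch

#: Rhythm name -> (low, high) edge in Hz, in the fixed feature order.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 20.0),
    "gamma": (20.0, 50.0),
}
BAND_NAMES = tuple(BANDS)
N_BANDS = len(BANDS)

WAVELET = "db4"
WPT_LEVEL = 6


def wpt_frequency_order(level: int) -> list[int]:
    """Natural-order indices of wavelet-packet leaves sorted by frequency.

    Leaves come out of a repeated (approximation, detail) split in natural
    binary order; the frequency ordering follows the Gray-code traversal in
    which every detail branch flips the orientation of its subtree.
    """
    paths = [""]
    for _ in range(level):
        nxt = []
        for i, p in enumerate(paths):
            nxt.extend([p + "a", p + "d"] if i % 2 == 0 else [p + "d", p + "a"])
        paths = nxt
    return [int(p.replace("a", "0").replace("d", "1"), 2) for p in paths]


def _wpt_bin_energies(data: np.ndarray, level: int = WPT_LEVEL, wavelet: str = WAVELET) -> np.ndarray:
    """Energies of the 2**level frequency-ordered terminal bins, batched over
    leading axes of ``data``."""
    coeffs = [np.asarray(data, dtype=float)]
    for _ in range(level):
        nxt = []
        for c in coeffs:
            a, d = pywt.dwt(c, wavelet, axis=-1)
            nxt.extend([a, d])
        coeffs = nxt
    energies = np.stack([np.sum(c * c, axis=-1) for c in coeffs], axis=-1)
    return energies[..., wpt_frequency_order(level)]


def _band_overlap_weights(rate: float, level: int = WPT_LEVEL) -> np.ndarray:
    """(n_bands, n_bins) fractional overlap of each nominal bin with each band."""
    n_bins = 2**level
    width = (rate / 2.0) / n_bins
    edges = np.arange(n_bins + 1) * width
    weights = np.zeros((N_BANDS, n_bins))
    for b, (lo, hi) in enumerate(BANDS.values()):
        overlap = np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo)
        weights[b] = np.clip(overlap, 0.0, None) / width
    return weights


def band_energies(
    data: np.ndarray,
    rate: float,
    backend: str = "wavelet",
    bands: dict[str, tuple[float, float]] = BANDS,
) -> np.ndarray:
    """Per-band signal energies, shape ``(..., 5)`` for ``(..., n_samples)`` input."""
    data = np.asarray(data, dtype=float)
    if backend == "wavelet":
        if bands is not BANDS:
            raise ValueError("the wavelet backend uses the standard band table")
        bins = _wpt_bin_energies(data)
        return bins @ _band_overlap_weights(rate).T
    if backend == "bandpass":
        nyq = rate / 2.0
        out = np.empty(data.shape[:-1] + (len(bands),))
        for b, (lo, hi) in enumerate(bands.values()):
            sos = sps.butter(5, [lo / nyq, min(hi, nyq * 0.99) / nyq], "bandpass", output="sos")
            filtered = sps.sosfiltfilt(sos, data, axis=-1)
            out[..., b] = np.sum(filtered * filtered, axis=-1)
        return out
    raise ValueError(f"unknown band-energy backend {backend!r}")


def relative_energies(energies: np.ndarray) -> np.ndarray:
    """Normalize band energies to a probability vector p_j = E_j / sum(E)."""
    energies = np.asarray(energies, dtype=float)
    total = energies.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("degenerate epoch: zero total band energy")
    return energies / total


def rwe(p: np.ndarray, q: np.ndarray, epsilon: float = 1e-12) -> float:
    """Relative wavelet entropy sum_j p_j ln(p_j / q_j) between two relative
    band-energy distributions (0*ln(0/x) taken as 0; q floored at ``epsilon``
    and renormalized to keep the divergence finite)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} is not a normalized distribution (sum={v.sum()})")
    qf = np.maximum(q, epsilon)
    qf = qf / qf.sum()
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / qf[mask])))


def _channel_distributions(epoch: Epoch, rate: float, backend: str) -> np.ndarray:
    energies = band_energies(epoch.data, rate, backend=backend)
    totals = energies.sum(axis=-1)
    if np.any(totals <= 0):
        from .recording import CANONICAL_CHANNELS

        bad = int(np.argmax(totals <= 0))
        label = CANONICAL_CHANNELS[bad] if epoch.data.shape[0] == 8 else str(bad)
        raise ValueError(f"channel {label} has zero band energy")
    return energies / totals[:, None]


def connectivity_matrix(
    epoch: Epoch, rate: float = 500.0, backend: str = "wavelet", epsilon: float = 1e-12
) -> np.ndarray:
    """8x8 non-symmetric RWE functional connectivity matrix.

    Row a is the reference electrode (the "true" distribution of the KL
    divergence), column b the comparison electrode; the diagonal is zero.
    """
    P = _channel_distributions(epoch, rate, backend)
    return rwe_matrix(P, epsilon=epsilon)


def rwe_matrix(P: np.ndarray, epsilon: float = 1e-12) -> np.ndarray:
    """RWE between all ordered pairs of rows of a distribution matrix."""
    P = np.asarray(P, dtype=float)
    Q = np.maximum(P, epsilon)
    Q = Q / Q.sum(axis=-1, keepdims=True)
    logP = np.where(P > 0, np.log(np.maximum(P, epsilon)), 0.0)
    # W[a, b] = sum_j P[a, j] * (log P[a, j] - log Q[b, j])
    self_term = np.sum(np.where(P > 0, P * logP, 0.0), axis=-1)
    cross = P @ np.log(Q).T
    W = self_term[:, None] - cross
    np.fill_diagonal(W, 0.0)
    return np.maximum(W, 0.0)


def fc_features(W: np.ndarray) -> np.ndarray:
    """Row-major flattening of the off-diagonal entries (56 values for 8x8)."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if W.shape != (n, n):
        raise ValueError("connectivity matrix must be square")
    return W[~np.eye(n, dtype=bool)].ravel()


def energy_ratio_features(
    epoch: Epoch, rate: float = 500.0, backend: str = "wavelet"
) -> np.ndarray:
    """45 rhythm energy ratios: five whole-EEG ratios (band energy pooled over
    all channels over pooled total) followed by five per electrode in
    canonical channel order.  Every 5-block sums to one."""
    energies = band_energies(epoch.data, rate, backend=backend)
    whole = relative_energies(energies.sum(axis=0))
    per_channel = relative_energies(energies)
    return np.concatenate([whole, per_channel.ravel()])


def assemble_feature_vector(
    fc: np.ndarray, graph: np.ndarray, energy: np.ndarray
) -> np.ndarray:
    """Concatenate the three blocks into the ordered 113-element descriptor."""
    fc = np.asarray(fc, dtype=float).ravel()
    graph = np.asarray(graph, dtype=float).ravel()
    energy = np.asarray(energy, dtype=float).ravel()
    for name, block, expect in (("fc", fc, 56), ("graph", graph, 12), ("energy", energy, 45)):
        if block.size != expect:
            raise ValueError(f"{name} block has {block.size} values, expected {expect}")
    vec = np.concatenate([fc, graph, energy])
    if not np.all(np.isfinite(vec)):
        raise ValueError("feature vector contains non-finite entries")
    return vec
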