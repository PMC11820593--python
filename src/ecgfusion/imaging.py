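"""Encode 1-D ECG segments as GADF / MTF / RP images.

Three complementary encodings of a (compressed) segment are stacked
into one RGB image:

* **GADF** (Gramian angular difference field): rescale the series to
  [-1, 1], map each value to a polar angle ``phi = arccos(x)``, and set
  ``G[i, j] = sin(phi_i - phi_j)``. The diagonal is exactly zero and
  the matrix is antisymmetric; peaks and troughs map to +-90 degrees.
* **MTF** (Markov transition field): quantile-bin the series into Q
  states, fit a first-order Markov chain on adjacent samples, and set
  ``M[i, j]`` to the transition probability from the state of sample i
  to the state of sample j.
* **RP** (recurrence plot): delay-embed the series (default m=1, tau=1,
  i.e. raw amplitudes) and mark pairs closer than a threshold eps:
  ``R[i, j] = H(eps - ||x_i - x_j||)``; symmetric with unit diagonal.
  The default ``eps = 30`` is meant for ADC-unit amplitudes.

A 1800-point segment is first compressed to 100 points by piecewise
aggregate approximation (PAA, mean over 18-sample frames) so each
matrix is natively 100 x 100; a "resize" mode that encodes at full
length and bilinearly downscales is available instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = [
    "ImagingConfig",
    "ImageTriplet",
    "encode_segment",
    "gadf",
    "mtf",
    "paa_compress",
    "rp",
    "stack_rgb",
]


@dataclass(frozen=True)
class ImagingConfig:
    """Image-encoding parameters (defaults: 100 x 100, Q=8, eps=30)."""

    image_size: int = 100
    mtf_bins: int = 8
    rp_epsilon: float = 30.0
    rp_embedding_m: int = 1
    rp_delay_tau: int = 1
    compression: str = "paa"
    #: factor applied to the segment before RP so that ``rp_epsilon``
    #: is compared against ADC-unit amplitudes (1.0 = use raw values)
    rp_amplitude_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.image_size < 2:
            raise ValueError("image_size must be >= 2")
        if self.mtf_bins < 2:
            raise ValueError("mtf_bins must be >= 2")
        if self.rp_epsilon < 0:
            raise ValueError("rp_epsilon must be nonnegative")
        if self.rp_embedding_m < 1 or self.rp_delay_tau < 1:
            raise ValueError("rp embedding dimension and delay must be >= 1")
        if self.compression not in ("paa", "resize"):
            raise ValueError("compression must be 'paa' or 'resize'")


@dataclass
class ImageTriplet:
    """GADF, MTF and RP matrices of one segment plus their RGB stack."""

    gadf: np.ndarray
    mtf: np.ndarray
    rp: np.ndarray

    @property
    def rgb(self) -> np.ndarray:
        return stack_rgb(self)

    def save_png(self, path: str) -> None:
        Image.fromarray(self.rgb, mode="RGB").save(path)


def paa_compress(segment: np.ndarray, m: int) -> np.ndarray:
    """Piecewise aggregate approximation to ``m`` points (frame means).

    If the length is not divisible by ``m`` the final frame is padded
    with the last sample value before averaging.
    """
    x = np.asarray(segment, dtype=np.float64)
    if m < 1:
        raise ValueError("m must be positive")
    if x.size < m:
        raise ValueError(f"cannot compress {x.size} samples to {m} frames")
    frame = -(-x.size // m)  # ceil
    if x.size % m:
        x = np.concatenate([x, np.full(frame * m - x.size, x[-1])])
    return x.reshape(m, -1).mean(axis=1)


def _rescale_unit(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("constant series cannot be angle-encoded (zero range)")
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def gadf(series: np.ndarray, rescale: bool = True) -> np.ndarray:
    """Gramian angular difference field of a series.

    ``G = sin(phi_i - phi_j)`` computed as the outer-product expansion
    ``sin phi_i cos phi_j - cos phi_i sin phi_j``, which makes the zero
    diagonal and antisymmetry exact in floating point. With
    ``rescale=False`` the input is taken as already lying in [-1, 1].
    """
    x = np.asarray(series, dtype=np.float64)
    if rescale:
        x = _rescale_unit(x)
    elif x.min() < -1 or x.max() > 1:
        raise ValueError("rescale=False requires values in [-1, 1]")
    phi = np.arccos(np.clip(x, -1.0, 1.0))
    s, c = np.sin(phi), np.cos(phi)
    return np.outer(s, c) - np.outer(c, s)


def _quantile_states(x: np.ndarray, q: int) -> tuple[np.ndarray, int]:
    """Quantile-bin ``x`` into at most ``q`` states; empty bins merge."""
    edges = np.quantile(x, np.linspace(0, 1, q + 1)[1:-1])
    states = np.searchsorted(edges, x, side="right")
    # Relabel to consecutive integers so duplicate edges (merged empty
    # bins) do not leave gaps.
    uniq, states = np.unique(states, return_inverse=True)
    return states, uniq.size


def mtf(
    series: np.ndarray, Q: int = 8, return_transitions: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Markov transition field with ``Q`` quantile bins.

    The underlying transition matrix W is row-stochastic; a state never
    observed as a transition source (only the final sample's state can
    be such) keeps a self-transition of 1. ``return_transitions=True``
    also returns W.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.size < 2:
        raise ValueError("series must have at least 2 samples")
    if Q < 2:
        raise ValueError("Q must be >= 2")
    states, n_states = _quantile_states(x, Q)
    W = np.zeros((n_states, n_states))
    np.add.at(W, (states[:-1], states[1:]), 1.0)
    rowsum = W.sum(axis=1)
    for a in np.where(rowsum == 0)[0]:
        W[a, a] = 1.0
        rowsum[a] = 1.0
    W /= rowsum[:, None]
    field = W[np.ix_(states, states)]
    return (field, W) if return_transitions else field


def rp(
    series: np.ndarray,
    epsilon: float = 30.0,
    m: int = 1,
    tau: int = 1,
) -> np.ndarray:
    """Binary recurrence plot with threshold ``epsilon``.

    Delay-embeds into vectors ``x_i = (x_i, x_{i+tau}, ...,
    x_{i+(m-1)tau})`` and sets ``R[i, j] = 1`` iff the Euclidean
    distance between ``x_i`` and ``x_j`` is at most ``epsilon``.
    """
    x = np.asarray(series, dtype=np.float64)
    n_vec = x.size - (m - 1) * tau
    if n_vec < 2:
        raise ValueError("embedding (m, tau) incompatible with series length")
    emb = np.stack([x[k * tau : k * tau + n_vec] for k in range(m)], axis=1)
    d2 = np.sum((emb[:, None, :] - emb[None, :, :]) ** 2, axis=-1)
    return (d2 <= epsilon**2).astype(np.uint8)


def stack_rgb(triplet: ImageTriplet) -> np.ndarray:
    """Stack GADF/MTF/RP into an 8-bit RGB image (R/G/B channel order).

    Linear maps [-1,1] -> [0,255] (GADF), [0,1] -> [0,255] (MTF) and
    {0,1} -> {0,255} (RP), rounded half-up.
    """
    g, m, r = triplet.gadf, triplet.mtf, triplet.rp
    if not (g.shape == m.shape == r.shape) or g.ndim != 2:
        raise ValueError("GADF, MTF and RP matrices must share a square shape")

    def _round_half_up(v: np.ndarray) -> np.ndarray:
        return np.floor(v + 0.5).astype(np.uint8)

    out = np.empty((*g.shape, 3), dtype=np.uint8)
    out[..., 0] = _round_half_up(np.clip((g + 1.0) / 2.0, 0, 1) * 255.0)
    out[..., 1] = _round_half_up(np.clip(m, 0, 1) * 255.0)
    out[..., 2] = _round_half_up(r.astype(np.float64) * 255.0)
    return out


def _bilinear_resize(mat: np.ndarray, size: int) -> np.ndarray:
    img = Image.fromarray(mat.astype(np.float32), mode="F")
    return np.asarray(img.resize((size, size), Image.BILINEAR), dtype=np.float64)


def encode_segment(
    segment: np.ndarray, cfg: ImagingConfig | None = None
) -> ImageTriplet:
    """Encode one segment as an :class:`ImageTriplet` per ``cfg``.

    In "paa" mode the segment is compressed first and all three
    encodings see the 100-point series (RP on amplitude-scaled values,
    GADF/MTF on the series itself, which they normalize internally); in
    "resize" mode encodings run at full length and are downscaled,
    except RP which is thresholded after resizing the distance field
    would lose binarity — RP is re-binarized at 0.5.
    """
    cfg = cfg or ImagingConfig()
    x = np.asarray(segment, dtype=np.float64)
    if cfg.compression == "paa":
        series = paa_compress(x, cfg.image_size)
        g = gadf(series)
        m = mtf(series, cfg.mtf_bins)
        r = rp(
            series * cfg.rp_amplitude_gain,
            cfg.rp_epsilon,
            cfg.rp_embedding_m,
            cfg.rp_delay_tau,
        )
    else:
        g = _bilinear_resize(gadf(x), cfg.image_size)
        m = _bilinear_resize(mtf(x, cfg.mtf_bins), cfg.image_size)
        r_full = rp(
            x * cfg.rp_amplitude_gain,
            cfg.rp_epsilon,
            cfg.rp_embedding_m,
            cfg.rp_delay_tau,
        )
        r = (_bilinear_resize(r_full, cfg.image_size) >= 0.5).astype(np.uint8)
    return ImageTriplet(gadf=g, mtf=m, rp=r)
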