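"""Spatial coupling kernels: long-range excitatory connectivity and the
optional spread of local external inputs.

The connectivity kernel C(x) is a (possibly anisotropic) Gaussian on the
module lattice, normalized to sum 1 so that a uniform rate field produces a
unit-weight drive.  The input kernel G(x) is normalized so that the *sum of
squares* is 1, which preserves the local variance of the spread noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConnectivityKernel", "InputKernel",
           "build_connectivity_kernel", "build_input_kernel"]


@dataclass
class ConnectivityKernel:
    offsets: np.ndarray   # (K, 2) integer displacements
    weights: np.ndarray   # (K,) coupling C(x), sums to 1
    distances: np.ndarray  # (K,) Euclidean |x| in grid units
    delay_ms: np.ndarray  # (K,) conduction delay D*|x| in ms

    def delay_steps(self, dt_ms: float) -> np.ndarray:
        """Per-offset delay rounded to integration steps; zero at the origin."""
        return np.rint(self.delay_ms / dt_ms).astype(np.int64)

    def fourier(self, qx, qy, sigma=0.0, delay_slope_ms=None):
        """Lattice Fourier transform C(q, sigma) including conduction delays.

        ``sigma`` is the complex growth rate in 1/ms units (use 1j*omega with
        omega in rad/ms).  Delays enter as exp(-sigma * D * |x|).
        """
        phase = np.exp(
            -1j * (np.asarray(qx)[..., None] * self.offsets[:, 0]
                   + np.asarray(qy)[..., None] * self.offsets[:, 1])
            - np.asarray(sigma)[..., None] * self.delay_ms
        )
        return (phase * self.weights).sum(axis=-1)


@dataclass
class InputKernel:
    offsets: np.ndarray
    weights: np.ndarray  # G(x)/Z with sum of squares = 1
    z: float             # normalization constant Z = (sum G^2)^(1/2)


def _gaussian_offsets(lx: float, ly: float, truncation_radius: float):
    if lx < 0 or ly < 0:
        raise ValueError("kernel ranges must be nonnegative")
    if truncation_radius < 0:
        raise ValueError("truncation radius must be nonnegative")
    if lx == 0 and ly == 0:
        return np.zeros((1, 2), dtype=np.int64), np.ones(1)
    r = int(np.floor(truncation_radius))
    axis = np.arange(-r, r + 1)
    X, Y = np.meshgrid(axis, axis, indexing="ij")
    keep = np.hypot(X, Y) <= truncation_radius
    if not keep.any():
        raise ValueError("truncation removed every kernel offset")
    # a zero range along one axis confines the kernel to the other axis
    wx = np.exp(-X[keep] ** 2 / lx**2) if lx > 0 else (X[keep] == 0) * 1.0
    wy = np.exp(-Y[keep] ** 2 / ly**2) if ly > 0 else (Y[keep] == 0) * 1.0
    w = wx * wy
    keep2 = w > 0
    offsets = np.stack([X[keep][keep2], Y[keep][keep2]], axis=1).astype(np.int64)
    return offsets, w[keep2]


def build_connectivity_kernel(lx: float, ly: float | None = None, *,
                              delay_slope_ms: float = 0.0,
                              truncation_radius: float | None = None,
                              ) -> ConnectivityKernel:
    """Gaussian connectivity kernel C(x) ~ exp(-x^2/lx^2 - y^2/ly^2).

    Weights are renormalized to sum 1 after truncation (default truncation at
    |x| <= 4*max(lx, ly), where dropped weights are below e^-16).  Delays grow
    linearly with Euclidean distance at ``delay_slope_ms`` per grid unit.
    """
    if ly is None:
        ly = lx
    if truncation_radius is None:
        truncation_radius = 4.0 * max(lx, ly)
    offsets, w = _gaussian_offsets(lx, ly, truncation_radius)
    w = w / w.sum()
    dist = np.hypot(offsets[:, 0], offsets[:, 1]).astype(float)
    return ConnectivityKernel(
        offsets=offsets, weights=w, distances=dist,
        delay_ms=delay_slope_ms * dist,
    )


def build_input_kernel(lx: float | None, ly: float | None = None, *,
                       truncation_radius: float | None = None) -> InputKernel:
    """Local-input spread kernel G(x), normalized so sum of squares is 1.

    ``lx=None`` (or both ranges zero) gives the point kernel: each module
    receives its own independent noise source only.
    """
    if lx is None:
        return InputKernel(offsets=np.zeros((1, 2), dtype=np.int64),
                           weights=np.ones(1), z=1.0)
    if ly is None:
        ly = lx
    if lx < 0 or ly < 0 or (lx == 0) != (ly == 0):
        raise ValueError("input-kernel ranges must both be positive, or use "
                         "the point kernel (lx=None or lx=ly=0)")
    if lx == 0:
        return InputKernel(offsets=np.zeros((1, 2), dtype=np.int64),
                           weights=np.ones(1), z=1.0)
    if truncation_radius is None:
        truncation_radius = 4.0 * max(lx, ly)
    offsets, w = _gaussian_offsets(lx, ly, truncation_radius)
    z = float(np.sqrt((w**2).sum()))
    return InputKernel(offsets=offsets, weights=w / z, z=z)
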