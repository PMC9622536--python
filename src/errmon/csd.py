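"""Spherical-spline surface Laplacian (current source density).

Scalp potentials are interpolated with a spherical spline and the surface
Laplacian of the spline is evaluated at the electrodes, detaching the
signal from the recording reference and sharpening focal activity.  With
stiffness ``m`` and N Legendre terms,

    g(x) = 1/(4*pi) * sum_{n=1..N} (2n+1) / (n(n+1))^m     * P_n(x)
    h(x) = 1/(4*pi) * sum_{n=1..N} (2n+1) / (n(n+1))^(m-1) * P_n(x)

where x is the cosine of the inter-electrode angle.  The spline solves

    [G + lambda*I  1] [c ]   [v]
    [1^T           0] [c0] = [0]

per sample vector v, and CSD = (H @ c) / r^2 in µV/cm² for a head radius
r in cm.  Adding a constant to all channels leaves the output unchanged,
and a spatially constant potential maps to zero.
"""

from __future__ import annotations

import warnings

import numpy as np
from numpy.polynomial import legendre as npleg

from . import montage
from .containers import EpochSet

DEFAULT_M = 4
DEFAULT_LAMBDA = 1e-5
DEFAULT_N_LEGENDRE = 50
DEFAULT_HEAD_RADIUS_CM = 10.0


def gh_kernels(
    cosang: np.ndarray, m: int = DEFAULT_M, n_legendre: int = DEFAULT_N_LEGENDRE
) -> tuple[np.ndarray, np.ndarray]:
    """G and H kernel matrices for a matrix of inter-electrode cosines."""
    n = np.arange(1, n_legendre + 1, dtype=float)
    factor = (2 * n + 1) / (4 * np.pi)
    cg = np.concatenate([[0.0], factor / (n * (n + 1)) ** m])
    ch = np.concatenate([[0.0], factor / (n * (n + 1)) ** (m - 1)])
    return npleg.legval(cosang, cg), npleg.legval(cosang, ch)


def csd_matrices(
    positions: np.ndarray,
    m: int = DEFAULT_M,
    lam: float = DEFAULT_LAMBDA,
    n_legendre: int = DEFAULT_N_LEGENDRE,
) -> tuple[np.ndarray, np.ndarray]:
    """Factorized pieces: augmented spline system A and the H kernel."""
    cosang = montage.cosine_distances(positions)
    off = cosang[~np.eye(len(cosang), dtype=bool)]
    if np.any(off > 1 - 1e-12):
        raise ValueError("duplicate electrode positions")
    G, H = gh_kernels(cosang, m=m, n_legendre=n_legendre)
    n_ch = len(positions)
    A = np.empty((n_ch + 1, n_ch + 1))
    A[:n_ch, :n_ch] = G + lam * np.eye(n_ch)
    A[:n_ch, n_ch] = 1.0
    A[n_ch, :n_ch] = 1.0
    A[n_ch, n_ch] = 0.0
    return A, H


def surface_laplacian(
    data: np.ndarray,
    positions: np.ndarray,
    m: int = DEFAULT_M,
    lam: float = DEFAULT_LAMBDA,
    n_legendre: int = DEFAULT_N_LEGENDRE,
    head_radius_cm: float = DEFAULT_HEAD_RADIUS_CM,
) -> np.ndarray:
    """CSD transform of ``data`` (..., n_channels, n_samples) in µV.

    ``positions`` are unit-sphere electrode coordinates; output is in
    µV/cm² for the given head radius.
    """
    data = np.asarray(data, float)
    n_ch = positions.shape[0]
    if data.shape[-2] != n_ch:
        raise ValueError("channel axis does not match positions")
    A, H = csd_matrices(positions, m=m, lam=lam, n_legendre=n_legendre)
    flat = np.moveaxis(data, -2, 0).reshape(n_ch, -1)
    rhs = np.vstack([flat, np.zeros((1, flat.shape[1]))])
    sol = np.linalg.solve(A, rhs)
    out_flat = (H @ sol[:n_ch]) / head_radius_cm**2
    out = out_flat.reshape((n_ch,) + data.shape[:-2] + data.shape[-1:])
    return np.moveaxis(out, 0, -2)


def csd_transform(
    epochs: EpochSet,
    m: int = DEFAULT_M,
    lam: float = DEFAULT_LAMBDA,
    n_legendre: int = DEFAULT_N_LEGENDRE,
    head_radius_cm: float = DEFAULT_HEAD_RADIUS_CM,
) -> EpochSet:
    """CSD-transform the scalp channels of an epoch set.

    Mastoid and EOG channels carry no scalp-surface information after the
    Laplacian and are dropped.  The reference flag becomes ``"csd"`` and
    units become µV/cm².
    """
    if epochs.reference == "csd":
        warnings.warn("epochs already CSD-transformed; no-op")
        return epochs.copy()
    scalp = epochs.scalp_channels
    if len(scalp) < 3:
        raise ValueError("CSD needs at least 3 scalp electrodes")
    pos = montage.unit_positions(scalp)
    picks = epochs.scalp_picks()
    out_data = surface_laplacian(
        epochs.data[:, picks, :], pos,
        m=m, lam=lam, n_legendre=n_legendre, head_radius_cm=head_radius_cm,
    ).astype(epochs.data.dtype)
    out = epochs.copy(data=out_data, reference="csd")
    out.channels = scalp
    out.log(f"csd: m={m}, lambda={lam}, {n_legendre} Legendre terms, "
            f"r={head_radius_cm} cm; dropped non-scalp channels")
    return out
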