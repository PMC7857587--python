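"""Electron-electron distance distributions and dipolar time traces.

For each ensemble frame the pairwise distances between the two sites'
paramagnetic centers are histogrammed with weight p_i * p_j. Frame
histograms are averaged (optionally with user weights, after discarding
frames whose steric partition function falls below a cutoff), smoothed with
a unit-area Gaussian low-pass filter, and converted to a dipolar evolution
signal

    S(t) = sum_r P(r) K(r, t) dr

with the analytical powder-average kernel

    K(r, t) = sqrt(pi / (6 w t)) [cos(wt) FrC(sqrt(6wt/pi))
                                  + sin(wt) FrS(sqrt(6wt/pi))]

where FrC/FrS are the Fresnel cosine/sine integrals and
w = (mu0/4pi) g^2 muB^2 / (hbar r^3) the dipolar frequency. The
background-corrected experimental form factor is modelled as
V(t) = 1 + lambda (S(t) - 1) with modulation depth lambda.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import fresnel

from .constants import DIPOLAR_PREFACTOR
from .placement import PlacementResult

logger = logging.getLogger(__name__)

#: distance-grid defaults: r in [0, R_MAX] nm with bin width DR
R_MAX_DEFAULT = 12.0
DR_DEFAULT = 0.05
#: time-grid defaults, microseconds
T_MIN_DEFAULT = 0.01
T_MAX_DEFAULT = 5.5
DT_DEFAULT = 0.01
#: Gaussian low-pass filter standard deviation, nm (0.5 Angstrom)
FILTER_STDEV_DEFAULT = 0.05
#: admissible modulation-depth range
LAMBDA_MIN, LAMBDA_MAX = 0.02, 0.5
#: frames with min(Z_A, Z_B) below this are discarded from the ensemble
Z_CUTOFF_DEFAULT = 0.05


class EmptyEnsembleError(Exception):
    """Every frame was excluded by the steric-partition-function cutoff."""


def r_grid(r_max: float = R_MAX_DEFAULT, dr: float = DR_DEFAULT) -> np.ndarray:
    """Bin-center grid for distance histograms: r_k = (k + 1/2) dr < r_max."""
    n = int(round(r_max / dr))
    return (np.arange(n) + 0.5) * dr


def t_grid(
    t_min: float = T_MIN_DEFAULT,
    t_max: float = T_MAX_DEFAULT,
    dt: float = DT_DEFAULT,
) -> np.ndarray:
    """Time grid in microseconds, inclusive of both endpoints."""
    n = int(round((t_max - t_min) / dt))
    return t_min + np.arange(n + 1) * dt


@dataclass
class DistanceDistribution:
    """P(r) on a fixed grid of bin centers, unit integral (sum P dr = 1)."""

    r: np.ndarray  # bin centers, nm
    density: np.ndarray  # nm^-1

    @property
    def dr(self) -> float:
        return float(self.r[1] - self.r[0])

    def integral(self) -> float:
        return float(self.density.sum() * self.dr)

    def mode(self) -> float:
        """Bin center carrying the largest probability mass."""
        return float(self.r[int(np.argmax(self.density))])


@dataclass
class DeerTimeTrace:
    """Dipolar signal S(t) and form factor V(t) = 1 + lam (S - 1)."""

    t: np.ndarray  # microseconds
    S: np.ndarray
    V: np.ndarray
    lam: float


# ---------------------------------------------------------------------------
# distance distributions


def frame_distribution(
    placement_a: PlacementResult,
    placement_b: PlacementResult,
    r_max: float = R_MAX_DEFAULT,
    dr: float = DR_DEFAULT,
) -> np.ndarray:
    """Weighted pair-distance histogram of one frame, as a density (nm^-1).

    Every rotamer pair (i at site A, j at site B) deposits weight p_i * p_j
    into the half-open bin [k dr, (k+1) dr) containing |c_i - c_j|. Pairs at
    or beyond r_max are dropped with a warning. Both placements must have
    Z > 0 (defined probabilities).
    """
    if placement_a.p is None or placement_b.p is None:
        raise ValueError("frame_distribution requires placements with Z > 0")
    n = int(round(r_max / dr))
    diff = placement_a.centers[:, None, :] - placement_b.centers[None, :, :]
    dist = np.linalg.norm(diff, axis=2).ravel()
    w = np.outer(placement_a.p, placement_b.p).ravel()
    k = np.floor(dist / dr).astype(int)
    inside = k < n
    dropped = w[~inside].sum()
    if dropped > 0:
        logger.warning(
            "frame %d: dropped probability %.3g beyond r_max = %g nm",
            placement_a.frame_index, dropped, r_max,
        )
    hist = np.bincount(k[inside], weights=w[inside], minlength=n)[:n]
    return hist / dr


def ensemble_distribution(
    per_frame: np.ndarray,
    z_pairs: np.ndarray,
    frame_weights: np.ndarray | None = None,
    z_cutoff: float = Z_CUTOFF_DEFAULT,
    r_max: float = R_MAX_DEFAULT,
    dr: float = DR_DEFAULT,
) -> DistanceDistribution:
    """Frame-weighted average distribution after the Z cutoff.

    ``per_frame`` is an (M, n_bins) stack of frame densities; ``z_pairs``
    an (M, 2) array of the per-frame steric partition functions of the two
    sites. Frames with min(Z_A, Z_B) < z_cutoff are excluded and the
    remaining weights renormalized (uniform when absent).
    """
    per_frame = np.atleast_2d(np.asarray(per_frame, dtype=float))
    M = per_frame.shape[0]
    z_pairs = np.asarray(z_pairs, dtype=float).reshape(M, -1)
    keep = z_pairs.min(axis=1) >= z_cutoff
    if frame_weights is None:
        w = np.ones(M)
    else:
        w = np.asarray(frame_weights, dtype=float)
        if w.shape != (M,):
            raise ValueError(f"expected {M} frame weights, got shape {w.shape}")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("frame weights must be non-negative with a positive sum")
    w = np.where(keep, w, 0.0)
    total = w.sum()
    if total == 0.0:
        raise EmptyEnsembleError(
            f"all {M} frames excluded by Z cutoff {z_cutoff} (or zero weights)"
        )
    logger.info("ensemble average over %d/%d frames (Z cutoff %g)", int(keep.sum()), M, z_cutoff)
    density = (w / total) @ per_frame
    return DistanceDistribution(r=r_grid(r_max, dr), density=density)


def lowpass_filter(
    dist: DistanceDistribution, filter_stdev: float = FILTER_STDEV_DEFAULT
) -> DistanceDistribution:
    """Convolve P(r) with a unit-area Gaussian of standard deviation sigma.

    The discrete kernel is truncated at 6 sigma and normalized to unit sum,
    so probability mass is conserved away from the grid edges; the result is
    renormalized to unit integral. ``filter_stdev = 0`` is the identity.
    """
    if filter_stdev < 0:
        raise ValueError("filter_stdev must be >= 0")
    if filter_stdev == 0:
        return DistanceDistribution(r=dist.r.copy(), density=dist.density.copy())
    dr = dist.dr
    half = int(np.ceil(round(6.0 * filter_stdev / dr, 9)))
    x = np.arange(-half, half + 1) * dr
    kernel = np.exp(-0.5 * (x / filter_stdev) ** 2)
    kernel /= kernel.sum()
    density = np.convolve(dist.density, kernel, mode="same")
    total = density.sum() * dr
    if total > 0:
        density = density / total
    return DistanceDistribution(r=dist.r.copy(), density=density)


# ---------------------------------------------------------------------------
# dipolar signal


def dipolar_frequency(r: float | np.ndarray) -> np.ndarray:
    """Electron-electron dipolar angular frequency (rad/s) at distance r (nm)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    return DIPOLAR_PREFACTOR / (r * 1e-9) ** 3


def deer_kernel(r: float | np.ndarray, t: float | np.ndarray) -> np.ndarray:
    """Powder-averaged dipolar kernel K(r, t); r in nm, t in microseconds.

    Fresnel-integral closed form of K = int_0^1 cos((3x^2 - 1) w t) dx,
    the average of cos over isotropic label orientations. K(r, 0) = 1 by the
    continuous limit and |K| <= 1 everywhere.
    """
    omega = dipolar_frequency(r)
    phi = omega * np.asarray(t, dtype=float) * 1e-6
    phi = np.asarray(phi, dtype=float)
    small = phi < 1e-12
    phi_safe = np.where(small, 1.0, phi)
    z = np.sqrt(6.0 * phi_safe / np.pi)
    s, c = fresnel(z)
    K = np.sqrt(np.pi / (6.0 * phi_safe)) * (np.cos(phi_safe) * c + np.sin(phi_safe) * s)
    K = np.where(small, 1.0, K)
    return np.clip(K, -1.0, 1.0)


def dipolar_signal(dist: DistanceDistribution, t: np.ndarray) -> np.ndarray:
    """Back-calculated dipolar evolution S(t) = sum_r P(r) K(r, t) dr.

    The sum runs over the histogram bins carrying probability (P > 0), each
    represented by its bin-center distance; with unit-integral P this gives
    S -> 1 as t -> 0.
    """
    support = dist.density > 0
    if not support.any():
        raise ValueError("distance distribution carries no probability mass")
    r_sup = dist.r[support]
    p_sup = dist.density[support]
    K = deer_kernel(r_sup[:, None], np.asarray(t)[None, :])
    return (p_sup[:, None] * K).sum(axis=0) * dist.dr


def form_factor(S: np.ndarray, lam: float) -> np.ndarray:
    """Form factor V(t) = 1 + lam (S(t) - 1) for modulation depth lam."""
    if not LAMBDA_MIN <= lam <= LAMBDA_MAX:
        raise ValueError(
            f"modulation depth {lam} outside [{LAMBDA_MIN}, {LAMBDA_MAX}]"
        )
    return 1.0 + lam * (np.asarray(S) - 1.0)


def fit_modulation_depth(
    t_exp: np.ndarray,
    v_exp: np.ndarray,
    t_pred: np.ndarray,
    s_pred: np.ndarray,
) -> float:
    """Least-squares modulation depth from an experimental form factor.

    The predicted S is interpolated linearly onto the experimental time
    points and lambda = sum (V_exp - 1)(S - 1) / sum (S - 1)^2, clipped to
    the admissible range [0.02, 0.5] (a warning is emitted when clipping).
    """
    t_exp = np.asarray(t_exp, dtype=float)
    s = np.interp(t_exp, np.asarray(t_pred, dtype=float), np.asarray(s_pred, dtype=float))
    ds = s - 1.0
    denom = float(ds @ ds)
    if denom < 1e-300:
        raise ValueError("predicted signal is constant 1; modulation depth undefined")
    lam = float((np.asarray(v_exp, dtype=float) - 1.0) @ ds / denom)
    if not LAMBDA_MIN <= lam <= LAMBDA_MAX:
        clipped = float(np.clip(lam, LAMBDA_MIN, LAMBDA_MAX))
        warnings.warn(
            f"fitted modulation depth {lam:.4g} clipped to {clipped:.4g}",
            stacklevel=2,
        )
        lam = clipped
    return lam


def time_trace(
    dist: DistanceDistribution,
    lam: float,
    t_min: float = T_MIN_DEFAULT,
    t_max: float = T_MAX_DEFAULT,
    dt: float = DT_DEFAULT,
) -> DeerTimeTrace:
    """Dipolar signal and form factor of a distribution on the default grid."""
    t = t_grid(t_min, t_max, dt)
    S = dipolar_signal(dist, t)
    return DeerTimeTrace(t=t, S=S, V=form_factor(S, lam), lam=lam)
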