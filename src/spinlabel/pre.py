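"""Paramagnetic relaxation enhancement: Gamma_2 rates and HSQC intensity ratios.

The unpaired electron of the nitroxide enhances the transverse relaxation of
nearby backbone amide protons, R2_ox = R2_red + Gamma_2. The enhancement
follows Solomon-Bloembergen,

    Gamma_2 = (1/15) (mu0/4pi)^2 gammaI^2 g^2 muB^2 s_e(s_e+1)
              [4 J(0) + 3 J(omega_I)],

with a model-free spectral density that factors out the radial average over
the rotamer states,

    J(w) = <r^-6> [S^2 tau_c / (1 + w^2 tau_c^2)
                   + (1 - S^2) tau_t / (1 + w^2 tau_t^2)].

The generalized order parameter splits into radial and angular parts,
S^2 = S2_radial * S2_angular, computed from the rotamer-state geometry of
each frame:

    S2_radial  = <r^-3>^2 / <r^-6>
    S2_angular = sum_ij (3/2 cos^2 Omega_ij - 1/2) p_i p_j.

Per-frame rates are averaged over the ensemble (Z-filtered, optionally
reweighted) and converted to HSQC peak-intensity ratios

    I_para / I_dia = R2_red exp(-Gamma_2 t_d) / (R2_red + Gamma_2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import PRE_PREFACTOR
from .deer import Z_CUTOFF_DEFAULT
from .placement import PlacementResult

logger = logging.getLogger(__name__)


@dataclass
class PREParameters:
    """Timescales and acquisition parameters of the PRE experiment.

    tau_c : effective correlation time (s), 1/tau_c = 1/tau_r + 1/tau_s with
        tau_r the protein rotational correlation time and tau_s the electron
        relaxation time; for nitroxides tau_s >> tau_r so tau_c ~ tau_r.
    tau_t : total internal correlation time (s), additionally folding in the
        label's internal motion: 1/tau_t = 1/tau_c + 1/tau_i. Hence
        tau_t <= tau_c.
    t_d : total INEPT evolution delay of the HSQC experiment (s).
    r2_dia : transverse relaxation rate of the diamagnetic (reduced) state (1/s).
    larmor_MHz : proton Larmor frequency nu_I (MHz); omega_I = 2 pi nu_I.
    """

    tau_c: float = 2e-9
    tau_t: float = 2e-10
    t_d: float = 1e-2
    r2_dia: float = 12.6
    larmor_MHz: float = 750.0

    def __post_init__(self) -> None:
        for name in ("tau_c", "tau_t", "t_d", "larmor_MHz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.r2_dia < 0:
            raise ValueError("r2_dia must be >= 0")
        if self.tau_t > self.tau_c:
            raise ValueError(
                f"tau_t ({self.tau_t}) must not exceed tau_c ({self.tau_c})"
            )

    @property
    def omega_I(self) -> float:
        """Proton Larmor angular frequency, rad/s."""
        return 2.0 * np.pi * self.larmor_MHz * 1e6


@dataclass
class PREResult:
    """Ensemble PRE prediction for one labelled site.

    ``residues`` lists the target residue numbers; ``gamma2`` and ``ratio``
    are the ensemble averages (NaN marks residues without an amide proton or
    sites excluded in every frame). ``per_frame_gamma2`` is (M, N_res) and
    ``z`` the per-frame steric partition function of the labelled site.
    """

    residues: np.ndarray
    gamma2: np.ndarray
    ratio: np.ndarray
    per_frame_gamma2: np.ndarray
    z: np.ndarray
    params: PREParameters
    skipped_residues: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# per-frame building blocks


def electron_proton_distances(
    placement: PlacementResult, protons: dict[int, np.ndarray]
) -> dict[int, np.ndarray]:
    """Distances (nm) from each rotamer's paramagnetic center to each amide H.

    ``protons`` maps residue number -> H coordinate (3,). Residues lacking an
    amide proton must already be absent from the mapping (they are skipped
    upstream and recorded).
    """
    if placement.p is None:
        raise ValueError("placement has Z = 0; distances are not meaningful")
    if not protons:
        raise ValueError("no target amide protons supplied")
    return {
        res: np.linalg.norm(placement.centers - np.asarray(h), axis=1)
        for res, h in protons.items()
    }


def order_parameters(
    r: np.ndarray, unit_vectors: np.ndarray, p: np.ndarray
) -> tuple[float, float, float, float]:
    """Radial/angular order parameters and inverse-distance moments.

    ``r`` (nm) are the R proton-electron distances, ``unit_vectors`` the
    (R, 3) unit displacement directions, ``p`` the rotamer probabilities.
    Returns (S2_radial, S2_angular, <r^-6> in nm^-6, <r^-3> in nm^-3) with

        S2_radial  = <r^-3>^2 / <r^-6>
        S2_angular = sum_ij (3/2 cos^2 Omega_ij - 1/2) p_i p_j,

    cos Omega_ij the angle cosine between directions i and j. Both order
    parameters lie in [0, 1]; a single state gives exactly 1.
    """
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(r == 0):
        raise ValueError("zero electron-proton distance (degenerate geometry)")
    mean_r3inv = float(p @ r**-3)
    mean_r6inv = float(p @ r**-6)
    s2_radial = mean_r3inv**2 / mean_r6inv

    u = np.asarray(unit_vectors, dtype=float)
    cos = u @ u.T
    s2_angular = float(p @ (1.5 * cos**2 - 0.5) @ p)
    return s2_radial, s2_angular, mean_r6inv, mean_r3inv


def gamma2(mean_r6inv: float, s2: float, params: PREParameters) -> float:
    """Transverse PRE rate (1/s) from <r^-6> (nm^-6) and order parameter S^2."""
    if not 0.0 <= s2 <= 1.0 + 1e-12:
        raise ValueError(f"S^2 = {s2} outside [0, 1]")
    if mean_r6inv <= 0:
        raise ValueError("<r^-6> must be positive")

    def j_reduced(w: float) -> float:
        return s2 * params.tau_c / (1.0 + (w * params.tau_c) ** 2) + (
            1.0 - s2
        ) * params.tau_t / (1.0 + (w * params.tau_t) ** 2)

    r6_m = mean_r6inv * 1e54  # nm^-6 -> m^-6
    return PRE_PREFACTOR * r6_m * (4.0 * j_reduced(0.0) + 3.0 * j_reduced(params.omega_I))


def frame_gamma2(
    placement: PlacementResult,
    protons: dict[int, np.ndarray],
    params: PREParameters,
) -> dict[int, float]:
    """Gamma_2 per target residue for one frame of the ensemble.

    For each amide proton the rotamer-state geometry yields the radial and
    angular order parameters (S^2 = S2_radial * S2_angular) and <r^-6>; the
    angular average is taken within the frame, across rotamers.
    """
    if placement.p is None:
        raise ValueError("placement has Z = 0")
    out: dict[int, float] = {}
    for res, h in protons.items():
        vec = placement.centers - np.asarray(h)
        r = np.linalg.norm(vec, axis=1)
        if np.any(r == 0):
            raise ValueError(f"electron center coincides with proton of residue {res}")
        u = vec / r[:, None]
        s2_rad, s2_ang, r6inv, _ = order_parameters(r, u, placement.p)
        out[res] = gamma2(r6inv, min(s2_rad * s2_ang, 1.0), params)
    return out


def single_point_gamma2(
    electron: np.ndarray, protons: dict[int, np.ndarray], params: PREParameters
) -> dict[int, float]:
    """Gamma_2 per residue for a fixed single-point electron (S^2 = 1).

    Used by the C-beta approximation, where the electron sits at the labelled
    residue's C-beta atom and there is no internal rotamer averaging.
    """
    out: dict[int, float] = {}
    for res, h in protons.items():
        r = float(np.linalg.norm(np.asarray(h) - np.asarray(electron)))
        if r == 0:
            raise ValueError(f"electron position coincides with proton of residue {res}")
        out[res] = gamma2(r**-6, 1.0, params)
    return out


# ---------------------------------------------------------------------------
# ensemble averaging and observables


def ensemble_gamma2(
    per_frame_gamma2: np.ndarray,
    z_values: np.ndarray,
    frame_weights: np.ndarray | None = None,
    z_cutoff: float = Z_CUTOFF_DEFAULT,
) -> np.ndarray:
    """Frame-weighted <Gamma_2> per residue after the Z cutoff.

    ``per_frame_gamma2`` is (M, N_res); frames with Z < z_cutoff are
    excluded and weights renormalized (uniform when absent). If every frame
    is excluded the result is NaN for all residues (a missing value, not an
    exception). NaN columns (residues without protons) stay NaN.
    """
    g = np.atleast_2d(np.asarray(per_frame_gamma2, dtype=float))
    M = g.shape[0]
    z = np.asarray(z_values, dtype=float).reshape(M)
    if frame_weights is None:
        w = np.ones(M)
    else:
        w = np.asarray(frame_weights, dtype=float)
        if w.shape != (M,):
            raise ValueError(f"expected {M} frame weights, got shape {w.shape}")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("frame weights must be non-negative with a positive sum")
    w = np.where(z >= z_cutoff, w, 0.0)
    total = w.sum()
    if total == 0.0:
        logger.warning("all %d frames excluded by Z cutoff %g; <Gamma_2> is missing", M, z_cutoff)
        return np.full(g.shape[1], np.nan)
    return (w / total) @ g


def intensity_ratio(
    gamma2_values: float | np.ndarray, params: PREParameters
) -> np.ndarray:
    """HSQC peak-intensity ratio I_para/I_dia from Gamma_2 (elementwise).

    ratio = R2_red exp(-Gamma_2 t_d) / (R2_red + Gamma_2); Gamma_2 = 0 gives
    1, and the ratio decays monotonically to 0 as Gamma_2 grows. Missing
    (NaN) rates propagate to missing ratios.
    """
    g = np.asarray(gamma2_values, dtype=float)
    if np.any(g[~np.isnan(g)] < 0):
        raise ValueError("Gamma_2 must be >= 0")
    with np.errstate(invalid="ignore"):
        out = params.r2_dia * np.exp(-g * params.t_d) / (params.r2_dia + g)
    return out
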