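"""Rotamer placement: backbone superposition, steric energies, Boltzmann weights.

The probe conformers are rigidly superposed onto the labelled residue's
backbone (N, CA, C) triad. The total probability of rotamer i combines the
library's intrinsic weight with an on-the-fly external (steric) energy,

    p_i = p_int_i exp(-eps_ext_i) / Z,   Z = sum_i p_int_i exp(-eps_ext_i),

where eps_ext_i (in kT) is a 6-12 Lennard-Jones sum over heavy-atom pairs
between the probe and the surrounding protein within a distance cutoff, with
pair sigmas scaled down to mimic the soft repulsion used in rotamer-library
modelling. Z, the steric partition function, quantifies how well the probe
fits at the site: low Z flags sterically occluded positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .constants import kt_kj_mol
from .library_io import LJParameterTable, RotamerLibrary, TRIAD_AREA_MIN

logger = logging.getLogger(__name__)

#: external energies above this (kT) are treated as a hard clash (weight 0)
EPS_CLASH = 700.0

#: default heavy-atom pair cutoff for the external energy, nm
DEFAULT_CUTOFF = 1.0

#: default pair-sigma scaling factor
DEFAULT_SIGMA_SCALING = 0.5


class GeometryError(Exception):
    """Degenerate geometry (e.g. collinear backbone triad)."""


@dataclass
class LabeledSite:
    """A spin-labelled position in the protein for the current frame.

    ``triad_coords`` holds the N, CA, C positions (3 x 3, nm) of the residue
    as numbered in the input structure.
    """

    residue_number: int
    chain_id: str
    triad_coords: np.ndarray

    def __post_init__(self) -> None:
        tc = np.asarray(self.triad_coords, dtype=float)
        if tc.shape != (3, 3):
            raise GeometryError("triad_coords must be 3 x 3 (N, CA, C)")
        area = 0.5 * np.linalg.norm(np.cross(tc[1] - tc[0], tc[2] - tc[0]))
        if area <= TRIAD_AREA_MIN:
            raise GeometryError(
                f"collinear backbone triad at residue {self.residue_number}"
            )
        self.triad_coords = tc


@dataclass
class PlacementResult:
    """Per-frame outcome of placing a rotamer library at one site."""

    centers: np.ndarray  # (R, 3) paramagnetic-center positions, nm
    eps_ext: np.ndarray  # (R,) external energies, kT (+inf = clash)
    p: np.ndarray | None  # (R,) total probabilities, None when Z == 0
    Z: float
    site: LabeledSite
    frame_index: int = 0


# ---------------------------------------------------------------------------
# rigid superposition


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R and translation t minimizing |R x + t - y|^2.

    Least-squares fit of the three equally weighted triad points; reflections
    are excluded by the determinant correction.
    """
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, tc - R @ mc


def fit_rotamers(lib: RotamerLibrary, site: LabeledSite) -> np.ndarray:
    """Superpose every conformer's backbone triad onto the site triad.

    Returns the (R, A, 3) transformed coordinates (nm). Each conformer is
    transformed by the rigid (rotation + translation, no reflection or
    scaling) least-squares fit of its own (N, CA, C) triad onto
    ``site.triad_coords``. The post-fit triad RMSD is logged.
    """
    out = np.empty_like(lib.conformers)
    rmsd_max = 0.0
    for k in range(lib.n_rotamers):
        tri = lib.conformers[k, lib.backbone_triad]
        R, t = _kabsch(tri, site.triad_coords)
        out[k] = lib.conformers[k] @ R.T + t
        dev = out[k, lib.backbone_triad] - site.triad_coords
        rmsd_max = max(rmsd_max, float(np.sqrt((dev**2).sum() / 3.0)))
    logger.debug(
        "fit %d rotamers at residue %s: max triad RMSD %.2e nm",
        lib.n_rotamers, site.residue_number, rmsd_max,
    )
    return out


def paramagnetic_centers(conformers: np.ndarray, lib: RotamerLibrary) -> np.ndarray:
    """Midpoints of the nitroxide N-O bond, (R, 3) in nm."""
    i, j = lib.nitroxide_pair
    return 0.5 * (conformers[:, i, :] + conformers[:, j, :])


# ---------------------------------------------------------------------------
# external energy


def external_energy(
    conformer: np.ndarray,
    conformer_classes: list[str],
    environment: np.ndarray,
    environment_classes: list[str],
    lj: LJParameterTable,
    temperature: float = 298.0,
    cutoff: float = DEFAULT_CUTOFF,
    sigma_scaling: float = DEFAULT_SIGMA_SCALING,
) -> float:
    """Steric 6-12 energy of one conformer against the protein, in kT.

    Sums 4 eps_ij [(sigma'_ij/d)^12 - (sigma'_ij/d)^6] over heavy-atom pairs
    with d <= cutoff, sigma'_ij = sigma_scaling * (sigma_i + sigma_j)/2 and
    eps_ij = sqrt(eps_i eps_j) (Lorentz-Berthelot). Energies above
    ``EPS_CLASH`` kT come back as +inf (hard clash).
    """
    e = external_energies(
        np.asarray(conformer)[None, :, :], conformer_classes,
        environment, environment_classes, lj,
        temperature=temperature, cutoff=cutoff, sigma_scaling=sigma_scaling,
    )
    return float(e[0])


def external_energies(
    conformers: np.ndarray,
    conformer_classes: list[str],
    environment: np.ndarray,
    environment_classes: list[str],
    lj: LJParameterTable,
    temperature: float = 298.0,
    cutoff: float = DEFAULT_CUTOFF,
    sigma_scaling: float = DEFAULT_SIGMA_SCALING,
) -> np.ndarray:
    """Vectorized :func:`external_energy` over an (R, A, 3) conformer stack."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not 0 < sigma_scaling <= 1:
        raise ValueError("sigma_scaling must be in (0, 1]")
    conformers = np.asarray(conformers, dtype=float)
    R = conformers.shape[0]
    environment = np.asarray(environment, dtype=float).reshape(-1, 3)
    if environment.shape[0] == 0 or conformers.shape[1] == 0:
        return np.zeros(R)

    eps_a, sig_a = lj.lookup(conformer_classes)
    eps_b, sig_b = lj.lookup(environment_classes)
    eps_ij = np.sqrt(np.outer(eps_a, eps_b))  # kJ/mol
    sig_ij = sigma_scaling * 0.5 * (sig_a[:, None] + sig_b[None, :])  # nm

    kt = kt_kj_mol(temperature)
    out = np.empty(R)
    for k in range(R):
        d = cdist(conformers[k], environment)
        mask = d <= cutoff
        if not mask.any():
            out[k] = 0.0
            continue
        with np.errstate(divide="ignore", over="ignore"):
            s6 = (sig_ij[mask] / d[mask]) ** 6
            e_kj = np.sum(4.0 * eps_ij[mask] * (s6 * s6 - s6))
        out[k] = e_kj / kt
    out[out > EPS_CLASH] = np.inf
    return out


# ---------------------------------------------------------------------------
# Boltzmann weighting


def boltzmann_weights(
    p_int: np.ndarray, eps_ext: np.ndarray
) -> tuple[np.ndarray | None, float]:
    """Total rotamer probabilities and steric partition function.

    Z = sum_i p_int_i exp(-eps_ext_i); p_i = p_int_i exp(-eps_ext_i) / Z.
    ``eps_ext`` is in kT and may contain +inf (excluded rotamers). When every
    rotamer clashes (Z == 0) the probabilities are undefined and ``None`` is
    returned for p.
    """
    p_int = np.asarray(p_int, dtype=float)
    eps_ext = np.asarray(eps_ext, dtype=float)
    with np.errstate(over="ignore"):
        boltz = np.exp(-eps_ext)
    boltz[np.isinf(eps_ext) & (eps_ext > 0)] = 0.0
    w = p_int * boltz
    Z = float(w.sum())
    if Z == 0.0:
        return None, 0.0
    return w / Z, Z


def place_rotamers(
    lib: RotamerLibrary,
    site: LabeledSite,
    environment: np.ndarray,
    environment_classes: list[str],
    lj: LJParameterTable,
    temperature: float = 298.0,
    cutoff: float = DEFAULT_CUTOFF,
    sigma_scaling: float = DEFAULT_SIGMA_SCALING,
    frame_index: int = 0,
) -> PlacementResult:
    """Full placement at one site for one frame: fit, energies, weights, centers.

    The probe's own backbone-triad atoms are excluded from the energy sum —
    after superposition they coincide with the labelled residue's backbone,
    which remains part of the environment.
    """
    fitted = fit_rotamers(lib, site)
    heavy = lib.heavy_mask.copy()
    heavy[lib.backbone_triad] = False
    classes = [e for e, h in zip(lib.elements, heavy) if h]
    eps_ext = external_energies(
        fitted[:, heavy, :], classes, environment, environment_classes, lj,
        temperature=temperature, cutoff=cutoff, sigma_scaling=sigma_scaling,
    )
    p, Z = boltzmann_weights(lib.p_int, eps_ext)
    return PlacementResult(
        centers=paramagnetic_centers(fitted, lib),
        eps_ext=eps_ext,
        p=p,
        Z=Z,
        site=site,
        frame_index=frame_index,
    )


def site_z_scan(
    triads: dict[int, np.ndarray],
    environments: dict[int, tuple[np.ndarray, list[str]]],
    lib: RotamerLibrary,
    lj: LJParameterTable,
    temperature: float = 298.0,
    cutoff: float = DEFAULT_CUTOFF,
    sigma_scaling: float = DEFAULT_SIGMA_SCALING,
) -> tuple[dict[int, float], dict[int, str]]:
    """Steric partition function per candidate labelling site.

    ``triads`` maps residue number -> (3, 3) N/CA/C coordinates and
    ``environments`` maps residue number -> (heavy-atom coordinates, classes).
    Per-residue failures are recorded and the scan continues; returns
    (Z by residue in input order, failure messages by residue).
    """
    z_values: dict[int, float] = {}
    failures: dict[int, str] = {}
    for resnum, triad in triads.items():
        try:
            site = LabeledSite(resnum, "", np.asarray(triad))
            env, env_classes = environments[resnum]
            res = place_rotamers(
                lib, site, env, env_classes, lj,
                temperature=temperature, cutoff=cutoff, sigma_scaling=sigma_scaling,
            )
            z_values[resnum] = res.Z
        except Exception as exc:  # scan must survive bad sites
            failures[resnum] = str(exc)
            z_values[resnum] = float("nan")
            logger.warning("Z scan failed at residue %s: %s", resnum, exc)
    return z_values, failures
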