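"""Deterministic synthetic structures, rotamer bundles and traces for testing.

Every generator is a pure function of its arguments (fixed seed => byte
identical text output), emitting the same standard formats the engine reads:
PDB topologies and multi-model PDB trajectories, rotamer bundles (weights
text + topology + conformers + YAML manifest), and two-column time traces.
The chemistry is deliberately schematic — a pseudo-nitroxide probe with a
backbone triad, an arm and an N-O pair — because the targets of the tests
are the placement, weighting and back-calculation mathematics, not MTSSL
itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import deer as deer_mod
from .library_io import RotamerLibrary, write_library

#: canonical local backbone triad, nm: CA at the origin, N along -x,
#: C in the xy-plane with an N-CA-C angle of 111.2 degrees
_CANONICAL_N = np.array([-0.1458, 0.0, 0.0])
_CANONICAL_CA = np.zeros(3)
_CANONICAL_C = 0.1525 * np.array(
    [np.cos(np.deg2rad(180.0 - 111.2)), np.sin(np.deg2rad(180.0 - 111.2)), 0.0]
)

#: nitroxide N-O bond length used by the synthetic probes, nm
_NO_BOND = 0.12


@dataclass
class FixtureRecipe:
    """Parameters of a synthetic-structure recipe (all lengths in nm)."""

    seed: int = 0
    n_residues: int = 10
    geometry: str = "ideal-helix"  # or "extended"
    n_frames: int = 1


# ---------------------------------------------------------------------------
# internal-coordinate backbone builder


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """Position a new atom bonded to c given the a-b-c frame (NeRF)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _backbone_torsions(geometry: str) -> tuple[float, float]:
    if geometry == "ideal-helix":
        return -57.0, -47.0
    if geometry == "extended":
        return -120.0, 120.0
    raise ValueError(f"unknown geometry {geometry!r}")


def build_backbone(n_residues: int, geometry: str = "ideal-helix") -> list[dict]:
    """Idealized poly-alanine backbone with N, H, CA, CB, C, O per residue.

    Standard bond lengths/angles with (phi, psi) from the geometry tag;
    omega = 180. Coordinates in Angstrom, as placed in the PDB output.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    phi, psi = _backbone_torsions(geometry)
    residues: list[dict] = []
    # first residue seeded explicitly in the xy-plane
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    c = ca + 1.525 * np.array(
        [np.cos(np.deg2rad(180 - 111.2)), np.sin(np.deg2rad(180 - 111.2)), 0.0]
    )
    prev_c = None
    for i in range(n_residues):
        if i > 0:
            n = _place_atom(residues[-1]["N"], ca_prev, prev_c, 1.329, 116.2, psi)
            ca = _place_atom(ca_prev, prev_c, n, 1.458, 121.7, 180.0)
            c = _place_atom(prev_c, n, ca, 1.525, 111.2, phi)
        o = _place_atom(n, ca, c, 1.231, 120.5, psi + 180.0)
        cb = _place_atom(c, n, ca, 1.530, 110.5, 122.5)
        if prev_c is None:
            h_dir = -(ca - n) / np.linalg.norm(ca - n)
            h_dir = h_dir + np.array([0.0, 0.0, 0.6])
            h_dir /= np.linalg.norm(h_dir)
        else:
            u1 = (ca - n) / np.linalg.norm(ca - n)
            u2 = (prev_c - n) / np.linalg.norm(prev_c - n)
            h_dir = -(u1 + u2)
            h_dir /= np.linalg.norm(h_dir)
        h = n + 0.98 * h_dir
        residues.append({"N": n, "H": h, "CA": ca, "CB": cb, "C": c, "O": o})
        ca_prev, prev_c = ca, c
    return residues


_ATOM_ORDER = ("N", "H", "CA", "CB", "C", "O")
_ELEMENTS = {"N": "N", "H": "H", "CA": "C", "CB": "C", "C": "C", "O": "O"}


def _pdb_model(residues: list[dict], chain: str = "A", start_serial: int = 1) -> str:
    lines = []
    serial = start_serial
    for resid, atoms in enumerate(residues, start=1):
        for name in _ATOM_ORDER:
            if name not in atoms:
                continue
            x, y, z = atoms[name]
            name4 = name if len(name) >= 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name4}ALA {chain}{resid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{_ELEMENTS[name]:>2s}\n"
            )
            serial += 1
    return "".join(lines)


def make_structure(recipe: FixtureRecipe) -> str:
    """PDB text of an idealized single-chain backbone (one model)."""
    residues = build_backbone(recipe.n_residues, recipe.geometry)
    return _pdb_model(residues) + "END\n"


# ---------------------------------------------------------------------------
# toy rotamer libraries


def toy_library(
    R: int,
    weights: np.ndarray | None = None,
    arm_length: float = 0.7,
    spread: float = 0.1,
    seed: int = 0,
    directions: np.ndarray | None = None,
    name: str | None = None,
) -> RotamerLibrary:
    """In-memory synthetic rotamer library with R pseudo-nitroxide conformers.

    Each conformer shares the canonical backbone triad and carries an arm
    carbon plus a nitroxide N-O pair whose midpoint sits ``arm_length`` nm
    (jittered by ``spread``) from CA along a seeded random direction.
    Explicit unit ``directions`` (R, 3) override the random draw, enabling
    exactly constructed geometries.
    """
    if R < 1:
        raise ValueError("need at least one rotamer")
    rng = np.random.default_rng(seed)
    if directions is None:
        v = rng.normal(size=(R, 3))
        # bias away from the backbone plane so arms point "outward"
        v[:, 2] = np.abs(v[:, 2]) + 0.5
        directions = v / np.linalg.norm(v, axis=1, keepdims=True)
    else:
        directions = np.asarray(directions, dtype=float)
        directions = directions / np.linalg.norm(directions, axis=1, keepdims=True)
        if directions.shape != (R, 3):
            raise ValueError("directions must be (R, 3)")
    lengths = arm_length + spread * rng.uniform(-1.0, 1.0, size=R)

    atoms = [
        ("N", "N", True),
        ("CA", "C", True),
        ("C", "C", True),
        ("C1", "C", True),
        ("N1", "N", True),
        ("O1", "O", True),
    ]
    conformers = np.empty((R, len(atoms), 3))
    for k in range(R):
        mid = _CANONICAL_CA + lengths[k] * directions[k]
        # N-O bond perpendicular to the arm so the midpoint stays put
        perp = np.cross(directions[k], [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(directions[k], [1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        conformers[k, 0] = _CANONICAL_N
        conformers[k, 1] = _CANONICAL_CA
        conformers[k, 2] = _CANONICAL_C
        conformers[k, 3] = _CANONICAL_CA + 0.5 * lengths[k] * directions[k]
        conformers[k, 4] = mid - 0.5 * _NO_BOND * perp
        conformers[k, 5] = mid + 0.5 * _NO_BOND * perp

    if weights is None:
        p = np.full(R, 1.0 / R)
    else:
        weights = np.asarray(weights, dtype=float)
        p = weights / weights.sum()
    return RotamerLibrary(
        name=name or f"toy-nitroxide-{R}",
        atoms=atoms,
        conformers=conformers,
        p_int=p,
        backbone_triad=np.array([0, 1, 2]),
        nitroxide_pair=np.array([4, 5]),
    )


def make_toy_library(
    directory: str | Path,
    R: int,
    weights: np.ndarray | None = None,
    arm_length: float = 0.7,
    spread: float = 0.1,
    seed: int = 0,
    conformer_format: str = "pdb",
    name: str | None = None,
) -> Path:
    """Write a synthetic rotamer bundle to *directory*; returns the manifest path."""
    lib = toy_library(
        R, weights=weights, arm_length=arm_length, spread=spread, seed=seed, name=name
    )
    return write_library(lib, directory, conformer_format=conformer_format)


# ---------------------------------------------------------------------------
# two-state trajectory


def _site_residue(offset_nm: np.ndarray) -> dict:
    """A minimal residue whose N/CA/C replicate the canonical library triad.

    Identical orientation at every site makes the rotamer superposition a
    pure translation, so inter-site center distances equal the CA-CA
    separation exactly.
    """
    shift = 10.0 * np.asarray(offset_nm)  # nm -> Angstrom
    n = 10.0 * _CANONICAL_N + shift
    ca = 10.0 * _CANONICAL_CA + shift
    c = 10.0 * _CANONICAL_C + shift
    o = c + np.array([0.0, 0.0, 1.231])
    return {"N": n, "CA": ca, "C": c, "O": o}


def make_two_state_trajectory(
    directory: str | Path,
    d1: float,
    d2: float,
    f: float,
    n_frames: int = 2,
    prefix: str = "twostate",
) -> tuple[Path, Path, np.ndarray]:
    """Topology + multi-model trajectory toggling between two site separations.

    Two labelled residues (resid 1 and 2, chain A) sit with identically
    oriented backbone triads separated by d1 nm in state 1 and d2 nm in
    state 2. The first round(f * n_frames) frames are state 1; with the
    returned per-frame weights (state-1 frames sharing mass f, state-2
    frames sharing 1 - f) the ensemble P(r) carries exactly mass f at d1 and
    1 - f at d2.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("mixing fraction must be in [0, 1]")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if 0.0 < f < 1.0 and n_frames < 2:
        raise ValueError("a genuine mixture needs at least 2 frames")
    n1 = int(round(f * n_frames))
    if f > 0.0:
        n1 = max(n1, 1)
    if f < 1.0:
        n1 = min(n1, n_frames - 1)
    weights = np.empty(n_frames)
    if 0 < n1:
        weights[:n1] = f / n1
    if n1 < n_frames:
        weights[n1:] = (1.0 - f) / (n_frames - n1)

    def model(d: float) -> str:
        res_a = _site_residue(np.zeros(3))
        res_b = _site_residue(np.array([d, 0.0, 0.0]))
        lines = []
        serial = 1
        for resid, res in ((1, res_a), (2, res_b)):
            for atom_name in ("N", "CA", "C", "O"):
                x, y, z = res[atom_name]
                name4 = f" {atom_name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name4}ALA A{resid:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                    f"{_ELEMENTS[atom_name]:>2s}\n"
                )
                serial += 1
        return "".join(lines)

    top_path = directory / f"{prefix}.pdb"
    traj_path = directory / f"{prefix}_traj.pdb"
    top_path.write_text(model(d1 if n1 > 0 else d2) + "END\n")
    parts = []
    for k in range(n_frames):
        parts.append(f"MODEL     {k + 1:4d}\n")
        parts.append(model(d1 if k < n1 else d2))
        parts.append("ENDMDL\n")
    parts.append("END\n")
    traj_path.write_text("".join(parts))
    return top_path, traj_path, weights


# ---------------------------------------------------------------------------
# synthetic DEER traces


def make_synthetic_trace(
    dist: deer_mod.DistanceDistribution,
    lam: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_min: float = deer_mod.T_MIN_DEFAULT,
    t_max: float = deer_mod.T_MAX_DEFAULT,
    dt: float = deer_mod.DT_DEFAULT,
) -> tuple[np.ndarray, np.ndarray]:
    """(t, V) form-factor series V = 1 + lam (S - 1) + seeded Gaussian noise."""
    t = deer_mod.t_grid(t_min, t_max, dt)
    S = deer_mod.dipolar_signal(dist, t)
    V = 1.0 + lam * (S - 1.0)
    if noise_sd > 0:
        V = V + np.random.default_rng(seed).normal(0.0, noise_sd, size=V.shape)
    return t, V


def delta_distribution(
    r0: float,
    r_max: float = deer_mod.R_MAX_DEFAULT,
    dr: float = deer_mod.DR_DEFAULT,
) -> deer_mod.DistanceDistribution:
    """Unit-mass distribution concentrated in the bin containing r0."""
    grid = deer_mod.r_grid(r_max, dr)
    density = np.zeros_like(grid)
    density[int(r0 // dr)] = 1.0 / dr
    return deer_mod.DistanceDistribution(r=grid, density=density)
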