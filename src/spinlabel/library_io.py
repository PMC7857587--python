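"""Rotamer-library bundles: loading, validation, writing.

A rotamer library describes the conformational ensemble of a covalently
attached paramagnetic probe (e.g. a nitroxide spin label) as a finite set of
conformers, each with an intrinsic Boltzmann probability obtained from
conformational analysis of the free probe. A bundle on disk consists of

* a weights text file — one non-negative real per line, line k giving the
  intrinsic weight of rotamer k (blank lines and ``#`` comments ignored);
* a topology file (PDB) naming the probe atoms;
* a conformer coordinate file (DCD, or a multi-model PDB accepted as a
  text-only dialect) with one frame per rotamer, all frames in a common
  canonical backbone frame;
* an entry in a YAML manifest mapping the library name to these files and to
  the atom names of the backbone triad (N, CA, C) and of the nitroxide N/O.

Coordinates are stored internally in nm (PDB/DCD files are Angstrom).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import MDAnalysis as mda
import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: paths in a manifest entry are resolved relative to the manifest file
MANIFEST_KEYS = ("weights", "topology", "trajectory")

#: sanity bounds for an N-O bond length, nm
NO_BOND_MIN, NO_BOND_MAX = 0.1, 0.2

#: triangle area below which a backbone triad counts as collinear, nm^2
TRIAD_AREA_MIN = 1e-6


class LibraryError(Exception):
    """Malformed or inconsistent rotamer-library bundle."""


@dataclass
class RotamerLibrary:
    """In-memory rotamer library in a canonical backbone frame.

    Attributes
    ----------
    name : str
        Library identifier (manifest key).
    atoms : list of (name, element, heavy) tuples
        Ordered probe atoms; ``heavy`` flags non-hydrogens.
    conformers : (R, A, 3) ndarray
        Conformer coordinates in nm.
    p_int : (R,) ndarray
        Intrinsic Boltzmann probabilities, normalized to 1.
    backbone_triad : (3,) int ndarray
        Indices of the probe's N, CA, C atoms used for superposition.
    nitroxide_pair : (2,) int ndarray
        Indices of the nitroxide N and O atoms carrying the unpaired electron.
    """

    name: str
    atoms: list[tuple[str, str, bool]]
    conformers: np.ndarray
    p_int: np.ndarray
    backbone_triad: np.ndarray
    nitroxide_pair: np.ndarray

    @property
    def n_rotamers(self) -> int:
        return self.conformers.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.conformers.shape[1]

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a[2] for a in self.atoms], dtype=bool)

    @property
    def elements(self) -> list[str]:
        return [a[1] for a in self.atoms]

    def eps_int(self) -> np.ndarray:
        """Internal energies in kT obtained by Boltzmann inversion of p_int."""
        with np.errstate(divide="ignore"):
            return -np.log(self.p_int)


@dataclass
class LJParameterTable:
    """Per-atom-class 6-12 Lennard-Jones parameters.

    ``epsilon`` in kJ/mol, ``sigma`` in nm, keyed by atom class (element
    symbol for the default table). Pairs combine by Lorentz-Berthelot rules:
    arithmetic-mean sigma, geometric-mean epsilon.
    """

    params: dict[str, tuple[float, float]]
    combining_rule: str = "lorentz-berthelot"

    def __post_init__(self) -> None:
        for cls, (eps, sig) in self.params.items():
            if eps < 0:
                raise ValueError(f"epsilon < 0 for class {cls!r}")
            if sig <= 0:
                raise ValueError(f"sigma <= 0 for class {cls!r}")

    def lookup(self, classes: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Vector of (epsilon, sigma) for a sequence of atom classes."""
        try:
            eps = np.array([self.params[c][0] for c in classes])
            sig = np.array([self.params[c][1] for c in classes])
        except KeyError as exc:
            raise KeyError(f"no Lennard-Jones parameters for atom class {exc}") from None
        return eps, sig


def default_lj_table() -> LJParameterTable:
    """Element-keyed LJ table with representative CHARMM36-like values.

    Coarse per-element parameters (kJ/mol, nm) standing in for full
    force-field atom typing; a user-supplied table overrides.
    """
    return LJParameterTable(
        params={
            "C": (0.29288, 0.3564),
            "N": (0.83680, 0.3296),
            "O": (0.50208, 0.3029),
            "S": (1.88280, 0.3563),
        }
    )


# ---------------------------------------------------------------------------
# bundle I/O


def read_weights(path: Path) -> np.ndarray:
    """Read one non-negative weight per line; '#' comments and blanks ignored."""
    values = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            values.append(float(line))
        except ValueError:
            raise LibraryError(f"{path}:{lineno}: not a number: {line!r}") from None
    if not values:
        raise LibraryError(f"{path}: no weights found")
    return np.asarray(values)


def _resolve_entry(name: str, manifest: Path) -> dict:
    manifest = Path(manifest)
    if not manifest.exists():
        raise FileNotFoundError(f"manifest not found: {manifest}")
    doc = yaml.safe_load(manifest.read_text())
    if not isinstance(doc, dict) or name not in doc:
        raise LibraryError(f"library {name!r} not listed in {manifest}")
    entry = dict(doc[name])
    for key in MANIFEST_KEYS:
        if key not in entry:
            raise LibraryError(f"manifest entry {name!r} lacks {key!r}")
        entry[key] = manifest.parent / entry[key]
        if not entry[key].exists():
            raise FileNotFoundError(f"{key} file missing for {name!r}: {entry[key]}")
    entry.setdefault("triad", {"N": "N", "CA": "CA", "C": "C"})
    entry.setdefault("nitroxide", {"N": "N1", "O": "O1"})
    return entry


def load_library(name: str, manifest: str | Path) -> RotamerLibrary:
    """Load and validate the rotamer-library bundle registered under *name*.

    Intrinsic weights are renormalized to sum to 1 on load. Raises
    :class:`LibraryError` on row/frame count mismatch or failed validation,
    ``FileNotFoundError`` on missing bundle files.
    """
    entry = _resolve_entry(name, Path(manifest))
    weights = read_weights(entry["weights"])

    u = mda.Universe(str(entry["topology"]), str(entry["trajectory"]))
    n_frames = len(u.trajectory)
    if len(weights) != n_frames:
        raise LibraryError(
            f"{name!r}: {len(weights)} weights but {n_frames} conformer frames"
        )

    names = [n.strip() for n in u.atoms.names]
    try:
        elements = [e.capitalize() for e in u.atoms.elements]
    except (AttributeError, mda.exceptions.NoDataError):
        elements = [mda.topology.guessers.guess_atom_element(n) for n in names]
    atoms = [(n, e, e != "H") for n, e in zip(names, elements)]

    def index_of(atom_name: str, role: str) -> int:
        hits = [i for i, n in enumerate(names) if n == atom_name]
        if len(hits) != 1:
            raise LibraryError(
                f"{name!r}: {role} atom {atom_name!r} matched {len(hits)} atoms"
            )
        return hits[0]

    triad = np.array(
        [index_of(entry["triad"][k], f"triad {k}") for k in ("N", "CA", "C")]
    )
    nitroxide = np.array(
        [index_of(entry["nitroxide"][k], f"nitroxide {k}") for k in ("N", "O")]
    )

    conformers = np.empty((n_frames, len(names), 3))
    for i, _ in enumerate(u.trajectory):
        conformers[i] = u.atoms.positions / 10.0  # Angstrom -> nm

    lib = RotamerLibrary(
        name=name,
        atoms=atoms,
        conformers=conformers,
        p_int=weights / weights.sum(),
        backbone_triad=triad,
        nitroxide_pair=nitroxide,
    )
    report = validate_library(lib)
    if report:
        raise LibraryError(f"{name!r}: " + "; ".join(report))
    logger.info("loaded library %r: %d rotamers, %d atoms", name, lib.n_rotamers, lib.n_atoms)
    return lib


def validate_library(lib: RotamerLibrary) -> list[str]:
    """Report violated library invariants; empty list means the library is valid."""
    report: list[str] = []
    if lib.p_int.ndim != 1 or len(lib.p_int) != lib.n_rotamers:
        report.append("weight count does not match conformer count")
    if np.any(lib.p_int < 0):
        report.append("negative weight in p_int")
    elif abs(lib.p_int.sum() - 1.0) > 1e-9:
        report.append("p_int does not sum to 1")
    if lib.conformers.ndim != 3 or lib.conformers.shape[2] != 3:
        report.append("conformers array is not R x A x 3")
        return report
    if len(lib.atoms) != lib.n_atoms:
        report.append("atom list length does not match coordinate array")

    tri = lib.conformers[:, lib.backbone_triad, :]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    if np.any(areas <= TRIAD_AREA_MIN):
        report.append("collinear backbone triad")

    no = np.linalg.norm(
        lib.conformers[:, lib.nitroxide_pair[0]] - lib.conformers[:, lib.nitroxide_pair[1]],
        axis=1,
    )
    if np.any((no < NO_BOND_MIN) | (no > NO_BOND_MAX)):
        report.append("nitroxide bond length outside [0.1, 0.2] nm")
    return report


# ---------------------------------------------------------------------------
# bundle writing (round-trip support and synthetic-bundle emission)

_PDB_LINE = (
    "ATOM  {serial:5d} {name:<4s}{res:<4s}{chain:1s}{resid:4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}\n"
)


def _pdb_atom_line(serial, name, x, y, z, elem, resname="RTM", chain="X", resid=1):
    name4 = name if len(name) >= 4 else f" {name:<3s}"
    return _PDB_LINE.format(
        serial=serial, name=name4, res=resname, chain=chain, resid=resid,
        x=x, y=y, z=z, occ=1.0, b=0.0, elem=elem,
    )


def write_library(
    lib: RotamerLibrary, directory: str | Path, conformer_format: str = "pdb"
) -> Path:
    """Write *lib* as a bundle under *directory* and return the manifest path.

    ``conformer_format`` selects the coordinate dialect: ``"pdb"`` writes a
    multi-model PDB (text), ``"dcd"`` a DCD trajectory.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    wpath = directory / f"{lib.name}_weights.txt"
    tpath = directory / f"{lib.name}.pdb"
    if conformer_format == "pdb":
        cpath = directory / f"{lib.name}_conformers.pdb"
    elif conformer_format == "dcd":
        cpath = directory / f"{lib.name}_conformers.dcd"
    else:
        raise ValueError(f"unknown conformer format {conformer_format!r}")

    wpath.write_text("".join(f"{w:.12g}\n" for w in lib.p_int))

    def model_text(coords_nm: np.ndarray) -> str:
        lines = []
        for i, ((name, elem, _), xyz) in enumerate(zip(lib.atoms, coords_nm), start=1):
            x, y, z = 10.0 * xyz  # nm -> Angstrom
            lines.append(_pdb_atom_line(i, name, x, y, z, elem))
        return "".join(lines)

    tpath.write_text(model_text(lib.conformers[0]) + "END\n")

    if conformer_format == "pdb":
        parts = []
        for k in range(lib.n_rotamers):
            parts.append(f"MODEL     {k + 1:4d}\n")
            parts.append(model_text(lib.conformers[k]))
            parts.append("ENDMDL\n")
        parts.append("END\n")
        cpath.write_text("".join(parts))
    else:
        u = mda.Universe(str(tpath))
        with mda.Writer(str(cpath), n_atoms=lib.n_atoms) as w:
            for k in range(lib.n_rotamers):
                u.atoms.positions = 10.0 * lib.conformers[k]
                w.write(u.atoms)

    triad_names = {k: lib.atoms[i][0] for k, i in zip(("N", "CA", "C"), lib.backbone_triad)}
    nox_names = {k: lib.atoms[i][0] for k, i in zip(("N", "O"), lib.nitroxide_pair)}
    manifest = directory / f"{lib.name}.yml"
    manifest.write_text(
        yaml.safe_dump(
            {
                lib.name: {
                    "weights": wpath.name,
                    "topology": tpath.name,
                    "trajectory": cpath.name,
                    "triad": triad_names,
                    "nitroxide": nox_names,
                }
            },
            sort_keys=False,
        )
    )
    return manifest


def builtin_manifest() -> Path:
    """Manifest of the bundled synthetic toy library shipped with the package."""
    return Path(__file__).parent / "data" / "libraries.yml"
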