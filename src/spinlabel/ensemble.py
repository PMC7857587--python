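"""Ensemble engine: frame iteration, site resolution, DEER/PRE pipelines, outputs.

Reads a topology (PDB) plus an optional trajectory (XTC, DCD, or multi-model
PDB) through MDAnalysis, places the rotamer library at the labelled site(s)
frame by frame, and drives the DEER and PRE back-calculations including
Z-cutoff filtering and optional frame reweighting. Coordinates are handled
internally in nm; residues are addressed by the numbering of the input file.

Output files (written when an output directory is given):

* ``res-<i>-<j>.dat``        r (nm), raw P(r), filtered P(r)
* ``res-<i>-<j>-trace.dat``  t (us), S(t), V(t)
* ``res-Z-<i>-<j>.dat``      frame, Z_A, Z_B
* ``res-<i>-<j>.h5``         per-frame histograms and Z values
* ``res-<site>.dat``         residue, <Gamma_2> (1/s), I_para/I_dia
* ``res-Z-<site>.dat``       frame, Z
* ``res-<site>.h5``          per-frame Gamma_2 and Z
* ``*-run.yml``              run manifest (all parameters) for reproducibility
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import h5py
import MDAnalysis as mda
import numpy as np
import yaml

from . import deer as deer_mod
from . import pre as pre_mod
from .deer import (
    DR_DEFAULT,
    DT_DEFAULT,
    FILTER_STDEV_DEFAULT,
    LAMBDA_MAX,
    R_MAX_DEFAULT,
    T_MAX_DEFAULT,
    T_MIN_DEFAULT,
    Z_CUTOFF_DEFAULT,
    DeerTimeTrace,
    DistanceDistribution,
)
from .library_io import LJParameterTable, RotamerLibrary, default_lj_table
from .placement import (
    DEFAULT_CUTOFF,
    DEFAULT_SIGMA_SCALING,
    LabeledSite,
    PlacementResult,
    place_rotamers,
    site_z_scan,
)
from .pre import PREParameters, PREResult

logger = logging.getLogger(__name__)

#: heavy backbone atoms retained in the labelled residue's environment
BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}
#: accepted amide-proton atom names
AMIDE_H_NAMES = ("H", "HN")


class SiteLookupError(Exception):
    """Residue/chain could not be resolved unambiguously in the topology."""


@dataclass
class EnsembleSpec:
    """Input ensemble: topology, optional trajectory, stride, weights, defaults."""

    topology: str | Path
    trajectory: str | Path | None = None
    stride: int = 1
    frame_weights: np.ndarray | str | Path | None = None
    temperature: float = 298.0
    z_cutoff: float = Z_CUTOFF_DEFAULT

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def load_universe(spec: EnsembleSpec) -> mda.Universe:
    top = str(spec.topology)
    if spec.trajectory is None:
        return mda.Universe(top)
    return mda.Universe(top, str(spec.trajectory))


def iterate_frames(spec: EnsembleSpec, universe: mda.Universe | None = None):
    """Yield (frame_index, all-atom coordinates in nm) honoring the stride."""
    u = universe if universe is not None else load_universe(spec)
    count = 0
    for ts in u.trajectory[:: spec.stride]:
        yield ts.frame, u.atoms.positions / 10.0
        count += 1
    logger.info("iterated %d frames (stride %d)", count, spec.stride)


def resolve_frame_weights(spec: EnsembleSpec, n_frames: int) -> np.ndarray | None:
    """Materialize the spec's frame weights and check them against n_frames."""
    fw = spec.frame_weights
    if fw is None:
        return None
    if isinstance(fw, (str, Path)):
        fw = np.loadtxt(fw, ndmin=1)
    fw = np.asarray(fw, dtype=float)
    if fw.shape != (n_frames,):
        raise ValueError(
            f"frame-weight list has shape {fw.shape} but {n_frames} frames were selected"
        )
    if np.any(fw < 0) or not np.any(fw > 0):
        raise ValueError("frame weights must be non-negative with a positive sum")
    return fw


# ---------------------------------------------------------------------------
# topology bookkeeping


def _elements(atoms: mda.AtomGroup) -> np.ndarray:
    try:
        return np.array([e.capitalize() for e in atoms.elements])
    except (AttributeError, mda.exceptions.NoDataError):
        return np.array(
            [mda.topology.guessers.guess_atom_element(n) for n in atoms.names]
        )


def resolve_site(u: mda.Universe, residue_number: int, chain_id: str | None):
    """Resolve (residue number, chain) to a unique residue.

    With ``chain_id`` None, a match is accepted only if the residue number is
    unique across chains; ambiguity raises rather than silently picking the
    first chain.
    """
    residues = u.residues[u.residues.resids == residue_number]
    if chain_id:
        try:
            chains = residues.chainIDs
        except (AttributeError, mda.exceptions.NoDataError):
            chains = residues.segids
        residues = residues[np.asarray(chains) == chain_id]
    if len(residues) == 0:
        raise SiteLookupError(
            f"residue {residue_number} (chain {chain_id or 'any'}) not found in topology"
        )
    if len(residues) > 1:
        raise SiteLookupError(
            f"residue {residue_number} is ambiguous across chains; specify a chain ID"
        )
    res = residues[0]
    icodes = getattr(res, "icode", "")
    if icodes and icodes.strip():
        raise SiteLookupError("insertion codes are not supported")
    return res


@dataclass
class _SiteContext:
    """Per-site index bookkeeping, valid for every frame of one Universe."""

    site_resnum: int
    chain_id: str
    triad_idx: np.ndarray  # global indices of N, CA, C
    env_idx: np.ndarray  # global indices of environment heavy atoms
    env_classes: list[str]


def _site_context(u: mda.Universe, residue_number: int, chain_id: str | None) -> _SiteContext:
    res = resolve_site(u, residue_number, chain_id)
    names = [n.strip() for n in res.atoms.names]
    triad_idx = []
    for want in ("N", "CA", "C"):
        hits = [res.atoms[i].index for i, n in enumerate(names) if n == want]
        if len(hits) != 1:
            raise SiteLookupError(
                f"residue {residue_number}: backbone atom {want!r} matched {len(hits)} atoms"
            )
        triad_idx.append(hits[0])

    protein = u.select_atoms("protein") if hasattr(u, "select_atoms") else u.atoms
    if len(protein) == 0:
        protein = u.atoms
    elements = _elements(protein)
    heavy = elements != "H"
    own = np.isin(protein.indices, res.atoms.indices)
    backbone = np.array([n.strip() in BACKBONE_NAMES for n in protein.names])
    keep = heavy & (~own | backbone)
    env = protein[keep]
    return _SiteContext(
        site_resnum=residue_number,
        chain_id=chain_id or "",
        triad_idx=np.array(triad_idx),
        env_idx=env.indices,
        env_classes=list(elements[keep]),
    )


def _place_at(
    ctx: _SiteContext,
    coords_nm: np.ndarray,
    lib: RotamerLibrary,
    lj: LJParameterTable,
    temperature: float,
    cutoff: float,
    sigma_scaling: float,
    frame_index: int,
) -> PlacementResult:
    site = LabeledSite(ctx.site_resnum, ctx.chain_id, coords_nm[ctx.triad_idx])
    return place_rotamers(
        lib, site, coords_nm[ctx.env_idx], ctx.env_classes, lj,
        temperature=temperature, cutoff=cutoff, sigma_scaling=sigma_scaling,
        frame_index=frame_index,
    )


# ---------------------------------------------------------------------------
# DEER pipeline


@dataclass
class DeerPrediction:
    """Full DEER back-calculation for one pair of labelled sites."""

    raw: DistanceDistribution
    filtered: DistanceDistribution
    trace: DeerTimeTrace
    frames: np.ndarray  # frame indices
    z: np.ndarray  # (M, 2) per-frame (Z_A, Z_B)
    per_frame: np.ndarray  # (M, n_bins) frame densities
    lam: float


def run_deer(
    spec: EnsembleSpec,
    residues: tuple[int, int],
    library: RotamerLibrary,
    chains: tuple[str | None, str | None] = (None, None),
    lj: LJParameterTable | None = None,
    r_max: float = R_MAX_DEFAULT,
    dr: float = DR_DEFAULT,
    filter_stdev: float = FILTER_STDEV_DEFAULT,
    t_min: float = T_MIN_DEFAULT,
    t_max: float = T_MAX_DEFAULT,
    dt: float = DT_DEFAULT,
    lam: float | None = None,
    fit_trace: tuple[np.ndarray, np.ndarray] | str | Path | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    sigma_scaling: float = DEFAULT_SIGMA_SCALING,
    output_dir: str | Path | None = None,
) -> DeerPrediction:
    """Predict the electron-electron distance distribution and dipolar trace.

    The two labelled positions are treated independently: each site's steric
    energies ignore the other site's rotamers. The modulation depth of the
    form factor is ``lam`` if given, else fitted to the experimental form
    factor ``fit_trace`` (two-column time/V data or arrays), else the
    maximal admissible depth 0.5. ``lam`` and ``fit_trace`` are mutually
    exclusive.
    """
    if lam is not None and fit_trace is not None:
        raise ValueError("specify either a fixed modulation depth or a trace to fit, not both")
    if residues[0] == residues[1] and (chains[0] or "") == (chains[1] or ""):
        raise SiteLookupError(
            "identical residue and chain for both labels; same-site pairs need distinct chains"
        )
    lj = lj if lj is not None else default_lj_table()

    u = load_universe(spec)
    ctx_a = _site_context(u, residues[0], chains[0])
    ctx_b = _site_context(u, residues[1], chains[1])

    frames, z_rows, hists = [], [], []
    n_bins = int(round(r_max / dr))
    for frame_index, coords in iterate_frames(spec, u):
        pa = _place_at(ctx_a, coords, library, lj, spec.temperature, cutoff, sigma_scaling, frame_index)
        pb = _place_at(ctx_b, coords, library, lj, spec.temperature, cutoff, sigma_scaling, frame_index)
        frames.append(frame_index)
        z_rows.append((pa.Z, pb.Z))
        if pa.p is None or pb.p is None:
            hists.append(np.zeros(n_bins))
        else:
            hists.append(deer_mod.frame_distribution(pa, pb, r_max=r_max, dr=dr))
    frames = np.array(frames)
    z = np.array(z_rows)
    per_frame = np.array(hists)

    weights = resolve_frame_weights(spec, len(frames))
    raw = deer_mod.ensemble_distribution(
        per_frame, z, frame_weights=weights, z_cutoff=spec.z_cutoff, r_max=r_max, dr=dr
    )
    filtered = deer_mod.lowpass_filter(raw, filter_stdev)

    tg = deer_mod.t_grid(t_min, t_max, dt)
    S = deer_mod.dipolar_signal(filtered, tg)
    if lam is None and fit_trace is not None:
        if isinstance(fit_trace, (str, Path)):
            data = np.loadtxt(fit_trace)
            t_exp, v_exp = data[:, 0], data[:, 1]
        else:
            t_exp, v_exp = fit_trace
        lam = deer_mod.fit_modulation_depth(t_exp, v_exp, tg, S)
        logger.info("fitted modulation depth lambda = %.4f", lam)
    elif lam is None:
        lam = LAMBDA_MAX
    trace = DeerTimeTrace(t=tg, S=S, V=deer_mod.form_factor(S, lam), lam=lam)

    pred = DeerPrediction(
        raw=raw, filtered=filtered, trace=trace,
        frames=frames, z=z, per_frame=per_frame, lam=lam,
    )
    if output_dir is not None:
        write_deer_outputs(
            pred, Path(output_dir), residues,
            run_params={
                "residues": list(residues),
                "chains": [c or "" for c in chains],
                "library": library.name,
                "temperature": spec.temperature,
                "z_cutoff": spec.z_cutoff,
                "stride": spec.stride,
                "sigma_scaling": sigma_scaling,
                "cutoff_nm": cutoff,
                "r_max": r_max, "dr": dr,
                "filter_stdev": filter_stdev,
                "t_min": t_min, "t_max": t_max, "dt": dt,
                "lambda": lam,
            },
        )
    return pred


def write_deer_outputs(
    pred: DeerPrediction,
    directory: Path,
    residues: tuple[int, int],
    run_params: dict | None = None,
) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    tag = f"{residues[0]}-{residues[1]}"
    np.savetxt(
        directory / f"res-{tag}.dat",
        np.column_stack([pred.raw.r, pred.raw.density, pred.filtered.density]),
        header="r_nm P_raw P_filtered",
    )
    np.savetxt(
        directory / f"res-{tag}-trace.dat",
        np.column_stack([pred.trace.t, pred.trace.S, pred.trace.V]),
        header=f"t_us S V (lambda = {pred.lam:.6g})",
    )
    np.savetxt(
        directory / f"res-Z-{tag}.dat",
        np.column_stack([pred.frames, pred.z]),
        header="frame Z_A Z_B", fmt=["%d", "%.8e", "%.8e"],
    )
    with h5py.File(directory / f"res-{tag}.h5", "w") as h5:
        h5.create_dataset("frames", data=pred.frames)
        h5.create_dataset("z", data=pred.z)
        h5.create_dataset("histograms", data=pred.per_frame, compression="gzip")
        h5.attrs["dr"] = pred.raw.dr
        h5.attrs["r_max"] = float(pred.raw.r[-1] + 0.5 * pred.raw.dr)
    if run_params is not None:
        (directory / f"res-{tag}-run.yml").write_text(yaml.safe_dump(run_params, sort_keys=False))


def deer_from_records(
    h5path: str | Path,
    frame_weights: np.ndarray | None = None,
    z_cutoff: float = Z_CUTOFF_DEFAULT,
    filter_stdev: float = FILTER_STDEV_DEFAULT,
) -> tuple[DistanceDistribution, DistanceDistribution]:
    """Recompute the ensemble P(r) from a per-frame container (reweighting path)."""
    with h5py.File(h5path, "r") as h5:
        per_frame = h5["histograms"][...]
        z = h5["z"][...]
        dr = float(h5.attrs["dr"])
        r_max = float(h5.attrs["r_max"])
    raw = deer_mod.ensemble_distribution(
        per_frame, z, frame_weights=frame_weights, z_cutoff=z_cutoff, r_max=r_max, dr=dr
    )
    return raw, deer_mod.lowpass_filter(raw, filter_stdev)


# ---------------------------------------------------------------------------
# PRE pipeline


def _amide_protons(
    u: mda.Universe, exclude_resnum: int
) -> tuple[dict[int, int], list[int]]:
    """Map residue number -> global index of its amide H; list skipped residues."""
    protein = u.select_atoms("protein")
    if len(protein) == 0:
        protein = u.atoms
    protons: dict[int, int] = {}
    skipped: list[int] = []
    for res in protein.residues:
        if res.resid == exclude_resnum:
            continue
        names = [n.strip() for n in res.atoms.names]
        idx = None
        for cand in AMIDE_H_NAMES:
            hits = [res.atoms[i].index for i, n in enumerate(names) if n == cand]
            if len(hits) == 1:
                idx = hits[0]
                break
        if idx is None:
            skipped.append(int(res.resid))
        else:
            protons[int(res.resid)] = idx
    if skipped:
        logger.info("residues without amide H skipped: %s", skipped)
    return protons, skipped


def run_pre(
    spec: EnsembleSpec,
    residue: int,
    library: RotamerLibrary | None,
    params: PREParameters,
    chain: str | None = None,
    lj: LJParameterTable | None = None,
    mode: str = "rotamer",
    cutoff: float = DEFAULT_CUTOFF,
    sigma_scaling: float = DEFAULT_SIGMA_SCALING,
    output_dir: str | Path | None = None,
) -> PREResult:
    """Predict per-residue <Gamma_2> and HSQC intensity ratios for one site.

    ``mode="rotamer"`` places the library and uses the model-free order
    parameters; ``mode="cbeta"`` puts a single-point electron at the labelled
    residue's C-beta (S^2 = 1, no steric evaluation, Z recorded as 1).
    Frames whose site Z falls below ``spec.z_cutoff`` are excluded from the
    ensemble average; fully excluded sites yield NaN (missing), not errors.
    """
    if mode not in ("rotamer", "cbeta"):
        raise ValueError(f"unknown PRE mode {mode!r}")
    u = load_universe(spec)
    protons_idx, skipped = _amide_protons(u, residue)
    if not protons_idx:
        raise SiteLookupError("no amide protons found in topology")
    residues_out = np.array(sorted(protons_idx))

    if mode == "cbeta":
        res = resolve_site(u, residue, chain)
        names = [n.strip() for n in res.atoms.names]
        cb = [res.atoms[i].index for i, n in enumerate(names) if n == "CB"]
        if len(cb) != 1:
            raise SiteLookupError(
                f"residue {residue} has no unique CB atom (glycine is unsupported)"
            )
        cb_idx = cb[0]
    else:
        if library is None:
            raise ValueError("rotamer mode requires a rotamer library")
        lj = lj if lj is not None else default_lj_table()
        ctx = _site_context(u, residue, chain)

    frames, z_list, rows = [], [], []
    for frame_index, coords in iterate_frames(spec, u):
        frames.append(frame_index)
        protons = {r: coords[i] for r, i in protons_idx.items()}
        if mode == "cbeta":
            g = pre_mod.single_point_gamma2(coords[cb_idx], protons, params)
            z_list.append(1.0)
        else:
            placement = _place_at(
                ctx, coords, library, lj, spec.temperature, cutoff, sigma_scaling, frame_index
            )
            z_list.append(placement.Z)
            if placement.p is None:
                rows.append(np.full(len(residues_out), np.nan))
                continue
            g = pre_mod.frame_gamma2(placement, protons, params)
        rows.append(np.array([g[r] for r in residues_out]))

    per_frame = np.array(rows)
    z = np.array(z_list)
    weights = resolve_frame_weights(spec, len(frames))
    mean_g = pre_mod.ensemble_gamma2(per_frame, z, frame_weights=weights, z_cutoff=spec.z_cutoff)
    result = PREResult(
        residues=residues_out,
        gamma2=mean_g,
        ratio=pre_mod.intensity_ratio(mean_g, params),
        per_frame_gamma2=per_frame,
        z=z,
        params=params,
        skipped_residues=skipped,
    )
    if output_dir is not None:
        write_pre_outputs(
            result, Path(output_dir), residue, frames=np.array(frames),
            run_params={
                "residue": residue,
                "chain": chain or "",
                "mode": mode,
                "library": library.name if library is not None else None,
                "temperature": spec.temperature,
                "z_cutoff": spec.z_cutoff,
                "stride": spec.stride,
                "sigma_scaling": sigma_scaling,
                "cutoff_nm": cutoff,
                **{k: float(v) for k, v in asdict(params).items()},
            },
        )
    return result


def write_pre_outputs(
    result: PREResult,
    directory: Path,
    site: int,
    frames: np.ndarray,
    run_params: dict | None = None,
) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(
        directory / f"res-{site}.dat",
        np.column_stack([result.residues, result.gamma2, result.ratio]),
        header="residue Gamma2_per_s I_para_over_I_dia",
        fmt=["%d", "%.8e", "%.8e"],
    )
    np.savetxt(
        directory / f"res-Z-{site}.dat",
        np.column_stack([frames, result.z]),
        header="frame Z", fmt=["%d", "%.8e"],
    )
    with h5py.File(directory / f"res-{site}.h5", "w") as h5:
        h5.create_dataset("frames", data=frames)
        h5.create_dataset("z", data=result.z)
        h5.create_dataset("gamma2", data=result.per_frame_gamma2, compression="gzip")
        h5.create_dataset("residues", data=result.residues)
    if run_params is not None:
        (directory / f"res-{site}-run.yml").write_text(yaml.safe_dump(run_params, sort_keys=False))


def pre_from_records(
    h5path: str | Path,
    params: PREParameters,
    frame_weights: np.ndarray | None = None,
    z_cutoff: float = Z_CUTOFF_DEFAULT,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Recompute (residues, <Gamma_2>, ratios) from a per-frame container."""
    with h5py.File(h5path, "r") as h5:
        per_frame = h5["gamma2"][...]
        z = h5["z"][...]
        residues = h5["residues"][...]
    mean_g = pre_mod.ensemble_gamma2(per_frame, z, frame_weights=frame_weights, z_cutoff=z_cutoff)
    return residues, mean_g, pre_mod.intensity_ratio(mean_g, params)


# ---------------------------------------------------------------------------
# site scan


def scan_sites(
    spec: EnsembleSpec,
    candidate_residues: list[int],
    library: RotamerLibrary,
    lj: LJParameterTable | None = None,
    chain: str | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    sigma_scaling: float = DEFAULT_SIGMA_SCALING,
) -> tuple[dict[int, float], dict[int, str]]:
    """Steric partition function per candidate site on the first frame.

    A design aid for site-directed spin labelling: positions with low Z
    cannot accommodate the probe without steric strain. Per-residue failures
    are recorded and the scan continues.
    """
    lj = lj if lj is not None else default_lj_table()
    u = load_universe(spec)
    u.trajectory[0]
    coords = u.atoms.positions / 10.0
    triads: dict[int, np.ndarray] = {}
    environments: dict[int, tuple[np.ndarray, list[str]]] = {}
    failures: dict[int, str] = {}
    for resnum in candidate_residues:
        try:
            ctx = _site_context(u, resnum, chain)
        except SiteLookupError as exc:
            failures[resnum] = str(exc)
            continue
        triads[resnum] = coords[ctx.triad_idx]
        environments[resnum] = (coords[ctx.env_idx], ctx.env_classes)
    z_values, scan_failures = site_z_scan(
        triads, environments, library, lj,
        temperature=spec.temperature, cutoff=cutoff, sigma_scaling=sigma_scaling,
    )
    for resnum, msg in failures.items():
        z_values[resnum] = float("nan")
    return (
        {r: z_values.get(r, float("nan")) for r in candidate_residues},
        {**failures, **scan_failures},
    )
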