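"""Frame iteration, site resolution, and the composed DEER/PRE pipelines."""

import numpy as np
import pytest

import spinlabel as sl
from spinlabel.ensemble import (
    EnsembleSpec,
    SiteLookupError,
    deer_from_records,
    iterate_frames,
    pre_from_records,
    resolve_site,
    run_deer,
    run_pre,
    scan_sites,
)
from spinlabel.fixtures import (
    FixtureRecipe,
    make_structure,
    make_two_state_trajectory,
    toy_library,
)
from spinlabel.pre import PREParameters


@pytest.fixture(scope="module")
def two_state(tmp_path_factory):
    d = tmp_path_factory.mktemp("twostate")
    top, traj, w = make_two_state_trajectory(d, d1=2.0, d2=4.0, f=0.5, n_frames=2)
    return top, traj, w


@pytest.fixture(scope="module")
def multiframe_pdb(tmp_path_factory):
    """10-model helix trajectory (rigid; all models identical)."""
    d = tmp_path_factory.mktemp("frames")
    model = make_structure(FixtureRecipe(n_residues=8)).replace("END\n", "")
    parts = []
    for k in range(10):
        parts.append(f"MODEL     {k + 1:4d}\n{model}ENDMDL\n")
    path = d / "traj.pdb"
    path.write_text("".join(parts) + "END\n")
    top = d / "top.pdb"
    top.write_text(make_structure(FixtureRecipe(n_residues=8)))
    return top, path


class TestIterateFrames:
    def test_frame_count(self, multiframe_pdb):
        top, traj = multiframe_pdb
        spec = EnsembleSpec(topology=top, trajectory=traj)
        frames = [i for i, _ in iterate_frames(spec)]
        assert frames == list(range(10))

    def test_stride_selection(self, multiframe_pdb):
        top, traj = multiframe_pdb
        spec = EnsembleSpec(topology=top, trajectory=traj, stride=2)
        assert [i for i, _ in iterate_frames(spec)] == [0, 2, 4, 6, 8]

    def test_single_structure_is_one_frame(self, helix_pdb):
        frames = list(iterate_frames(EnsembleSpec(topology=helix_pdb)))
        assert len(frames) == 1
        assert frames[0][1].shape == (72, 3)

    def test_twenty_model_ensemble(self, tmp_path):
        model = make_structure(FixtureRecipe(n_residues=5)).replace("END\n", "")
        text = "".join(f"MODEL     {k:4d}\n{model}ENDMDL\n" for k in range(1, 21))
        path = tmp_path / "nmr.pdb"
        path.write_text(text + "END\n")
        spec = EnsembleSpec(topology=path)
        assert len(list(iterate_frames(spec))) == 20


class TestSiteResolution:
    def test_missing_residue_named_in_error(self, helix_pdb):
        import MDAnalysis as mda

        with pytest.raises(SiteLookupError, match="99"):
            resolve_site(mda.Universe(str(helix_pdb)), 99, None)

    def test_same_site_pair_rejected(self, helix_pdb, lib1):
        spec = EnsembleSpec(topology=helix_pdb)
        with pytest.raises(SiteLookupError, match="distinct chains"):
            run_deer(spec, residues=(5, 5), library=lib1)


class TestRunDeer:
    def test_rigid_pair_mode_at_known_distance(self, two_state, lib1):
        top, _, _ = two_state
        spec = EnsembleSpec(topology=top)  # single frame at separation 2 nm
        pred = run_deer(spec, residues=(1, 2), library=lib1)
        assert abs(pred.filtered.mode() - 2.0) <= 0.05
        assert pred.raw.integral() == pytest.approx(1.0, abs=1e-9)
        assert pred.filtered.integral() == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_frames_match_single_frame(self, two_state, lib1):
        top, _, _ = two_state
        single = run_deer(EnsembleSpec(topology=top), residues=(1, 2), library=lib1)
        # trajectory with both frames in state d1 = the topology state
        dup = run_deer(
            EnsembleSpec(topology=top, trajectory=None), residues=(1, 2), library=lib1
        )
        np.testing.assert_allclose(single.filtered.density, dup.filtered.density)

    def test_degenerate_weights_equal_single_frame(self, two_state, lib1):
        top, traj, _ = two_state
        both = run_deer(
            EnsembleSpec(topology=top, trajectory=traj, frame_weights=np.array([1.0, 0.0])),
            residues=(1, 2), library=lib1,
        )
        first_only = run_deer(EnsembleSpec(topology=top), residues=(1, 2), library=lib1)
        np.testing.assert_allclose(both.raw.density, first_only.raw.density, atol=1e-12)

    def test_two_state_masses_and_peaks(self, two_state, lib1):
        top, traj, _ = two_state
        pred = run_deer(EnsembleSpec(topology=top, trajectory=traj), residues=(1, 2), library=lib1)
        masses = pred.raw.density * 0.05
        k1, k2 = np.argsort(masses)[-2:]
        np.testing.assert_allclose(sorted(masses[[k1, k2]]), [0.5, 0.5], atol=1e-9)
        peaks = sorted(pred.raw.r[[k1, k2]])
        assert abs(peaks[0] - 2.0) <= 0.05 and abs(peaks[1] - 4.0) <= 0.05

    def test_uniform_explicit_weights_equal_absent(self, two_state, lib1):
        top, traj, _ = two_state
        a = run_deer(EnsembleSpec(topology=top, trajectory=traj), residues=(1, 2), library=lib1)
        b = run_deer(
            EnsembleSpec(topology=top, trajectory=traj, frame_weights=np.array([0.5, 0.5])),
            residues=(1, 2), library=lib1,
        )
        np.testing.assert_allclose(a.filtered.density, b.filtered.density, atol=1e-15)

    def test_conflicting_lambda_inputs_rejected(self, two_state, lib1):
        top, _, _ = two_state
        with pytest.raises(ValueError, match="not both"):
            run_deer(
                EnsembleSpec(topology=top), residues=(1, 2), library=lib1,
                lam=0.1, fit_trace=(np.array([0.1]), np.array([1.0])),
            )

    def test_outputs_written_and_batch_recomputation_agrees(self, two_state, lib1, tmp_path):
        top, traj, _ = two_state
        out = tmp_path / "out"
        pred = run_deer(
            EnsembleSpec(topology=top, trajectory=traj), residues=(1, 2),
            library=lib1, output_dir=out,
        )
        for fname in ("res-1-2.dat", "res-1-2-trace.dat", "res-Z-1-2.dat", "res-1-2.h5"):
            assert (out / fname).exists()
        raw, filtered = deer_from_records(out / "res-1-2.h5")
        np.testing.assert_allclose(raw.density, pred.raw.density, atol=1e-12)
        np.testing.assert_allclose(filtered.density, pred.filtered.density, atol=1e-12)
        data = np.loadtxt(out / "res-1-2.dat")
        np.testing.assert_allclose(data[:, 2], pred.filtered.density, atol=1e-6)


class TestRunPre:
    params = PREParameters()

    def test_single_frame_matches_closed_form_chain(self, helix_pdb, lib5):
        """Oracle: explicit per-residue recomputation outside the engine."""
        import MDAnalysis as mda

        from spinlabel.library_io import default_lj_table
        from spinlabel.placement import LabeledSite, place_rotamers
        from spinlabel.pre import frame_gamma2, intensity_ratio

        spec = EnsembleSpec(topology=helix_pdb)
        result = run_pre(spec, residue=6, library=lib5, params=self.params)

        u = mda.Universe(str(helix_pdb))
        coords = u.atoms.positions / 10.0
        names = [n.strip() for n in u.atoms.names]
        resids = u.atoms.resids
        triad = np.array(
            [coords[i] for want in ("N", "CA", "C") for i, (n, r) in
             enumerate(zip(names, resids)) if n == want and r == 6]
        )
        site = LabeledSite(6, "", triad)
        env_idx = [
            i for i, (n, r, el) in enumerate(zip(names, resids, u.atoms.elements))
            if el != "H" and (r != 6 or n in ("N", "CA", "C", "O"))
        ]
        placement = place_rotamers(
            lib5, site, coords[env_idx],
            [u.atoms.elements[i].capitalize() for i in env_idx], default_lj_table(),
        )
        protons = {
            int(r): coords[i]
            for i, (n, r) in enumerate(zip(names, resids)) if n == "H" and r != 6
        }
        oracle = frame_gamma2(placement, protons, self.params)
        for j, res in enumerate(result.residues):
            assert result.gamma2[j] == pytest.approx(oracle[res], rel=1e-9)
            assert result.ratio[j] == pytest.approx(
                float(intensity_ratio(oracle[res], self.params)), rel=1e-9
            )

    def test_distant_protons_barely_relax(self, extended_pdb, lib1):
        spec = EnsembleSpec(topology=extended_pdb)
        result = run_pre(spec, residue=1, library=lib1, params=self.params)
        protons_far = result.residues >= 25  # > 3.5 nm down the extended chain
        assert protons_far.any()
        assert np.all(result.ratio[protons_far] > 0.99)

    def test_uniform_weights_equal_absent(self, multiframe_pdb, lib5):
        top, traj = multiframe_pdb
        a = run_pre(EnsembleSpec(topology=top, trajectory=traj), residue=4,
                    library=lib5, params=self.params)
        b = run_pre(
            EnsembleSpec(topology=top, trajectory=traj, frame_weights=np.full(10, 0.1)),
            residue=4, library=lib5, params=self.params,
        )
        np.testing.assert_allclose(a.gamma2, b.gamma2, atol=1e-12)

    def test_labelled_residue_excluded_from_targets(self, helix_pdb, lib5):
        result = run_pre(EnsembleSpec(topology=helix_pdb), residue=6,
                         library=lib5, params=self.params)
        assert 6 not in result.residues

    def test_outputs_and_batch_recomputation(self, helix_pdb, lib5, tmp_path):
        out = tmp_path / "pre"
        result = run_pre(EnsembleSpec(topology=helix_pdb), residue=6, library=lib5,
                         params=self.params, output_dir=out)
        assert (out / "res-6.dat").exists() and (out / "res-Z-6.dat").exists()
        residues, mean_g, ratios = pre_from_records(out / "res-6.h5", self.params)
        np.testing.assert_array_equal(residues, result.residues)
        np.testing.assert_allclose(mean_g, result.gamma2, atol=1e-12)
        np.testing.assert_allclose(ratios, result.ratio, atol=1e-12)

    def test_cbeta_mode_matches_single_point_formula(self, helix_pdb):
        import MDAnalysis as mda

        from spinlabel.pre import single_point_gamma2

        result = run_pre(EnsembleSpec(topology=helix_pdb), residue=6, library=None,
                         params=self.params, mode="cbeta")
        u = mda.Universe(str(helix_pdb))
        coords = u.atoms.positions / 10.0
        names = [n.strip() for n in u.atoms.names]
        resids = u.atoms.resids
        cb = next(coords[i] for i, (n, r) in enumerate(zip(names, resids))
                  if n == "CB" and r == 6)
        protons = {int(r): coords[i] for i, (n, r) in enumerate(zip(names, resids))
                   if n == "H" and r != 6}
        oracle = single_point_gamma2(cb, protons, self.params)
        for j, res in enumerate(result.residues):
            assert result.gamma2[j] == pytest.approx(oracle[res], rel=1e-12)

    def test_cbeta_and_rotamer_modes_differ(self, helix_pdb, lib5):
        rla = run_pre(EnsembleSpec(topology=helix_pdb), residue=6, library=lib5,
                      params=self.params)
        cb = run_pre(EnsembleSpec(topology=helix_pdb), residue=6, library=None,
                     params=self.params, mode="cbeta")
        # the probe arm displaces the electron from C-beta; rates must differ
        assert not np.allclose(rla.gamma2, cb.gamma2, rtol=0.05)


class TestFramePermutation:
    def test_permuting_frames_and_weights_preserves_outputs(self, tmp_path, lib1):
        top, traj, w = make_two_state_trajectory(
            tmp_path / "a", d1=2.0, d2=4.0, f=0.25, n_frames=4
        )
        top2, traj2, _ = make_two_state_trajectory(
            tmp_path / "b", d1=4.0, d2=2.0, f=0.75, n_frames=4
        )  # same frames in reversed state order
        w2 = np.array([w[3], w[2], w[1], w[0]])
        a = run_deer(EnsembleSpec(topology=top, trajectory=traj, frame_weights=w),
                     residues=(1, 2), library=lib1)
        b = run_deer(EnsembleSpec(topology=top2, trajectory=traj2, frame_weights=w2),
                     residues=(1, 2), library=lib1)
        np.testing.assert_allclose(a.filtered.density, b.filtered.density, atol=1e-12)


class TestScanSites:
    def test_scan_matches_per_site_recomputation(self, helix_pdb, lib5):
        spec = EnsembleSpec(topology=helix_pdb)
        candidates = list(range(2, 12))
        z_values, failures = scan_sites(spec, candidates, lib5)
        assert not failures
        assert list(z_values) == candidates  # stable ordering
        for res in (3, 6, 9):
            solo, _ = scan_sites(spec, [res], lib5)
            assert z_values[res] == pytest.approx(solo[res], rel=1e-12)

    def test_failures_recorded_scan_continues(self, helix_pdb, lib5):
        z_values, failures = scan_sites(
            EnsembleSpec(topology=helix_pdb), [6, 99], lib5
        )
        assert np.isfinite(z_values[6])
        assert np.isnan(z_values[99]) and "99" in failures[99]


class TestFrameWeightValidation:
    def test_wrong_length_rejected(self, two_state, lib1):
        top, traj, _ = two_state
        spec = EnsembleSpec(topology=top, trajectory=traj, frame_weights=np.ones(3))
        with pytest.raises(ValueError, match="frame"):
            run_deer(spec, residues=(1, 2), library=lib1)

    def test_negative_weights_rejected(self, two_state, lib1):
        top, traj, _ = two_state
        spec = EnsembleSpec(
            topology=top, trajectory=traj, frame_weights=np.array([1.0, -0.5])
        )
        with pytest.raises(ValueError, match="non-negative"):
            run_deer(spec, residues=(1, 2), library=lib1)

    def test_weight_file_accepted(self, two_state, lib1, tmp_path):
        top, traj, _ = two_state
        wfile = tmp_path / "w.txt"
        wfile.write_text("0.5\n0.5\n")
        spec = EnsembleSpec(topology=top, trajectory=traj, frame_weights=wfile)
        pred = run_deer(spec, residues=(1, 2), library=lib1)
        assert pred.raw.integral() == pytest.approx(1.0, abs=1e-9)
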