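import dataclasses

import numpy as np
import pytest

from sctgen.gamma import DoseGrid
from sctgen.metrics import roi_stats
from sctgen.phantom import (
    LABEL_BONE,
    LABEL_LUNG,
    LABEL_SOFT,
    ArtifactSpec,
    PhantomSpec,
    artifact_fields,
    generate_phantom,
    make_dataset,
    simulate_cbct,
    synthesize_dose,
)


class TestGeneratePhantom:
    def test_default_lung_mean_matches_reference_ct(self):
        ct, roi = generate_phantom(PhantomSpec(seed=3))
        stats = roi_stats(ct, roi)
        mu, sd = stats["lung"]
        n = (np.round(roi.voxels) == LABEL_LUNG).sum()
        assert abs(mu - (-755.0)) < 2 * 40.0 / np.sqrt(n) + 1.0

    def test_deterministic_given_seed(self):
        a, la = generate_phantom(PhantomSpec(seed=9))
        b, lb = generate_phantom(PhantomSpec(seed=9))
        np.testing.assert_array_equal(a.voxels, b.voxels)
        np.testing.assert_array_equal(la.voxels, lb.voxels)

    def test_label_counts_match_independent_voxelization(self):
        """ROI voxel counts agree with direct membership enumeration."""
        spec = PhantomSpec(shape=(3, 40, 40))
        _, roi = generate_phantom(spec)
        nz, ny, nx = spec.shape
        cx, cy = (nx - 1) / 2, (ny - 1) / 2
        ax, ay = spec.body_axes[0] * nx, spec.body_axes[1] * ny
        counts = {LABEL_LUNG: 0, LABEL_BONE: 0, LABEL_SOFT: 0}
        for yy in range(ny):
            for xx in range(nx):
                body = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1
                if not body:
                    continue
                in_bone = (xx - (cx + spec.spine_center[0] * nx)) ** 2 + (
                    yy - (cy + spec.spine_center[1] * ny)
                ) ** 2 <= (spec.spine_radius * nx) ** 2
                for i in range(spec.n_ribs):
                    th = np.pi * (0.15 + 0.7 * i / (spec.n_ribs - 1))
                    for sgn in (1, -1):
                        rx = cx + sgn * 0.92 * ax * np.sin(th)
                        ry = cy - 0.92 * ay * np.cos(th)
                        in_bone |= (xx - rx) ** 2 + (yy - ry) ** 2 <= (
                            spec.rib_radius * nx
                        ) ** 2
                in_lung = False
                for fx, fy in spec.lung_centers:
                    lax, lay = spec.lung_axes[0] * nx, spec.lung_axes[1] * ny
                    in_lung |= ((xx - (cx + fx * nx)) / lax) ** 2 + (
                        (yy - (cy + fy * ny)) / lay
                    ) ** 2 <= 1
                if in_bone:
                    counts[LABEL_BONE] += 1
                elif in_lung:
                    counts[LABEL_LUNG] += 1
                else:
                    counts[LABEL_SOFT] += 1
        lab = np.round(roi.voxels[0]).astype(int)
        for value, expected in counts.items():
            assert (lab == value).sum() == expected

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            generate_phantom(dataclasses.replace(PhantomSpec(), lung_axes=(0.0, 0.0)))


class TestSimulateCBCT:
    def test_zero_spec_is_bitexact_identity(self, small_phantom):
        ct, roi = small_phantom
        zero = ArtifactSpec(lung_shift=0, cupping_amplitude=0, streak_count=0,
                            shading_amplitude=0, noise_sd=0)
        out = simulate_cbct(ct, zero, labels=roi)
        np.testing.assert_array_equal(out.voxels, ct.voxels)

    def test_pure_lung_shift_moves_lung_mean(self, small_phantom):
        ct, roi = small_phantom
        spec = ArtifactSpec(lung_shift=-145.0, cupping_amplitude=0, streak_count=0,
                            shading_amplitude=0, noise_sd=0)
        out = simulate_cbct(ct, spec, labels=roi)
        before = roi_stats(ct, roi)["lung"][0]
        after = roi_stats(out, roi)["lung"][0]
        assert after - before == pytest.approx(-145.0, abs=1.0)  # clip effects only

    def test_default_spec_lung_near_cbct_reference(self):
        ct, roi = generate_phantom(PhantomSpec(seed=21))
        cbct = simulate_cbct(ct, ArtifactSpec(seed=21), labels=roi)
        assert roi_stats(cbct, roi)["lung"][0] == pytest.approx(-900.0, abs=60.0)

    def test_components_additive_before_clip(self, small_phantom):
        ct, roi = small_phantom
        spec = ArtifactSpec(seed=4, noise_sd=0)  # noise excluded: not per-component seeded
        fields = artifact_fields(ct, spec, labels=roi)
        total = sum(fields.values())
        # each component alone, re-derived from the same composite fields
        assert set(fields) == {"lung_shift", "cupping", "streaks", "shading"}
        np.testing.assert_allclose(
            total,
            fields["lung_shift"] + fields["cupping"] + fields["streaks"] + fields["shading"],
        )
        out = simulate_cbct(ct, spec, labels=roi)
        np.testing.assert_allclose(
            out.voxels, np.clip(ct.voxels + total, -1000, 1500), atol=1e-9
        )

    def test_deterministic_given_seed(self, small_phantom):
        ct, roi = small_phantom
        a = simulate_cbct(ct, ArtifactSpec(seed=8), labels=roi)
        b = simulate_cbct(ct, ArtifactSpec(seed=8), labels=roi)
        np.testing.assert_array_equal(a.voxels, b.voxels)


class TestMakeDataset:
    def test_file_counts_and_manifest(self, tiny_dataset):
        recs = tiny_dataset["records"]
        assert len(recs) == 3
        assert {r["split"] for r in recs} == {"train", "test"}
        root = tiny_dataset["_root"]
        import os

        files = os.listdir(root)
        assert sum(f.startswith("ct_") for f in files) == 3
        assert sum(f.startswith("cbct_") for f in files) == 3
        assert sum(f.startswith("roi_") for f in files) == 3

    def test_same_seed_reproduces_voxel_data(self, tmp_path):
        spec = dataclasses.replace(PhantomSpec(), shape=(3, 24, 24))
        m1 = make_dataset(tmp_path / "a", 2, phantom_spec=spec, seed=3)
        m2 = make_dataset(tmp_path / "b", 2, phantom_spec=spec, seed=3)
        assert [r["seed"] for r in m1["records"]] == [r["seed"] for r in m2["records"]]
        from sctgen.volume_io import load_volume

        v1 = load_volume(tmp_path / "a" / m1["records"][0]["cbct"])
        v2 = load_volume(tmp_path / "b" / m2["records"][0]["cbct"])
        np.testing.assert_array_equal(v1.voxels, v2.voxels)

    def test_refuses_nonempty_directory(self, tmp_path):
        spec = dataclasses.replace(PhantomSpec(), shape=(2, 24, 24))
        make_dataset(tmp_path / "d", 1, phantom_spec=spec)
        with pytest.raises(FileExistsError):
            make_dataset(tmp_path / "d", 1, phantom_spec=spec)

    def test_unpaired_flag_recorded(self, tmp_path):
        spec = dataclasses.replace(PhantomSpec(), shape=(2, 24, 24))
        m = make_dataset(tmp_path / "u", 1, phantom_spec=spec, paired=False)
        assert m["paired"] is False


class TestSynthesizeDose:
    def test_max_at_target_and_nonnegative(self):
        d = synthesize_dose((32.0, 32.0, 8.0), 12.0, (5, 17, 17), spacing=(4, 4, 4))
        assert isinstance(d, DoseGrid)
        assert d.dose.min() >= 0
        zmax, ymax, xmax = np.unravel_index(d.dose.argmax(), d.shape)
        assert (xmax * 4, ymax * 4, zmax * 4) == (32, 32, 8)
        assert d.dose.max() == pytest.approx(5000 * 1.02)

    def test_radial_symmetry(self):
        d = synthesize_dose((16.0, 16.0, 16.0), 8.0, (9, 9, 9), spacing=(4, 4, 4))
        c = 4
        vals = [d.dose[c, c, c + 2], d.dose[c, c, c - 2], d.dose[c + 2, c, c],
                d.dose[c - 2, c, c], d.dose[c, c + 2, c], d.dose[c, c - 2, c]]
        assert np.ptp(vals) < 1e-9

    def test_target_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            synthesize_dose((500.0, 0.0, 0.0), 5.0, (4, 8, 8), spacing=(4, 4, 4))


def test_cohort_tissue_orderings_over_many_seeds():
    """CBCT lung and soft-tissue means fall below their CT counterparts."""
    ct_lung, cb_lung, ct_soft, cb_soft = [], [], [], []
    for seed in range(20):
        ct, roi = generate_phantom(dataclasses.replace(
            PhantomSpec(), shape=(4, 48, 48), seed=seed))
        cbct = simulate_cbct(ct, ArtifactSpec(seed=seed), labels=roi)
        s_ct, s_cb = roi_stats(ct, roi), roi_stats(cbct, roi)
        ct_lung.append(s_ct["lung"][0])
        cb_lung.append(s_cb["lung"][0])
        ct_soft.append(s_ct["soft_tissue"][0])
        cb_soft.append(s_cb["soft_tissue"][0])
    assert np.mean(cb_lung) < np.mean(ct_lung)
    assert np.mean(cb_soft) < np.mean(ct_soft)
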