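"""Synthetic cohort generator: determinism, planted truth, noise structure."""

import numpy as np
import pytest

from betapet import roi
from betapet.behavior import DEFAULT_THRESHOLD, binarize_activity, percent_freezing
from betapet.synthetic import (
    BoutParams,
    SynthConfig,
    build_mask_set,
    calibration_config,
    generate_activity_trace,
    generate_cohort,
    read_fixtures,
    validate_manifest,
    write_fixtures,
)
from conftest import cohort_delta_table, zero_noise_config


class TestConfigValidation:
    def test_defaults_are_valid(self):
        SynthConfig().validate()

    @pytest.mark.parametrize(
        "overrides, field",
        [
            ({"n_con": 0}, "n_con"),
            ({"sd_voxel": -0.1}, "sd_voxel"),
            ({"frame_rate_hz": 0.0}, "frame_rate_hz"),
        ],
    )
    def test_invalid_fields_named_in_error(self, overrides, field):
        with pytest.raises(ValueError, match=field):
            SynthConfig(**overrides).validate()

    def test_effect_map_must_cover_regions(self):
        cfg = SynthConfig(effect_map={"CON": {"BA": 0.1}, "LS": {"BA": 0.0}})
        with pytest.raises(ValueError, match="effect_map"):
            cfg.validate()

    def test_footprint_outside_grid_rejected(self):
        cfg = calibration_config(seed=0)
        bad = cfg.region_specs[0].__class__("BA", (4, 40), (2, 7), (2, 5))
        cfg.region_specs = [bad]
        with pytest.raises(ValueError, match="z_range"):
            cfg.validate()


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = calibration_config(seed=99, n_con=2, n_ls=2)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.subject_id == sb.subject_id
            for sess in ("F1", "F3"):
                assert np.array_equal(sa.scans[sess].voxels, sb.scans[sess].voxels)
            for sess in ("F1", "F2", "F3"):
                assert np.array_equal(sa.traces[sess].scores, sb.traces[sess].scores)
            assert sa.truth.planted_increment == sb.truth.planted_increment

    def test_different_seed_differs(self):
        a = generate_cohort(calibration_config(seed=1, n_con=2, n_ls=2))
        b = generate_cohort(calibration_config(seed=2, n_con=2, n_ls=2))
        assert not np.array_equal(
            a.subjects[0].scans["F1"].voxels, b.subjects[0].scans["F1"].voxels
        )


class TestPlantedEffects:
    def test_zero_noise_downstream_delta_equals_planted(self, zero_noise_cohort):
        delta = cohort_delta_table(zero_noise_cohort)
        truth = {s.subject_id: s.truth.planted_increment for s in zero_noise_cohort.subjects}
        for (subject, region), grp in delta.groupby(["subject", "region"]):
            assert np.allclose(grp["delta_suv"], truth[subject][region], atol=1e-10)

    def test_null_cohort_mean_delta_within_3_se(self):
        # all effects zero, voxel noise only: region means should sit at 0
        cfg = zero_noise_config(
            seed=21, n_con=10, n_ls=10, sd_voxel=0.05,
            effect_map={g: {c: 0.0 for c in r} for g, r in SynthConfig().effect_map.items()},
        )
        delta = cohort_delta_table(generate_cohort(cfg))
        per_subject = roi.subject_region_mean(delta)
        for region, grp in per_subject.groupby("region"):
            m = grp["delta_suv"].to_numpy()
            se = m.std(ddof=1) / np.sqrt(m.size)
            assert abs(m.mean()) < 3 * se + 1e-12

    def test_noise_scaling_is_monotone(self):
        # raising sd_voxel raises the variance of per-slice delta records
        spreads = []
        for sd in (0.02, 0.05, 0.10):
            cfg = zero_noise_config(seed=8, n_con=3, n_ls=3, sd_voxel=sd)
            delta = cohort_delta_table(generate_cohort(cfg))
            spreads.append(delta["delta_suv"].std())
        assert spreads[0] < spreads[1] < spreads[2]


class TestActivityTraces:
    def test_target_one_is_fully_inactive(self):
        t = generate_activity_trace(BoutParams(1.0, 5.0), 10.0, 30.0, 0)
        assert (t.scores < DEFAULT_THRESHOLD).all()

    def test_target_zero_is_fully_active(self):
        t = generate_activity_trace(BoutParams(0.0, 5.0), 10.0, 30.0, 0)
        assert (t.scores >= DEFAULT_THRESHOLD).all()

    def test_empirical_freezing_matches_target(self):
        # stationary-renewal construction: expectation equals the target
        target = 0.45
        fracs = []
        for rep in range(400):
            t = generate_activity_trace(BoutParams(target, 4.0), 10.0, 120.0, 1000 + rep)
            s = binarize_activity(t, DEFAULT_THRESHOLD)
            fracs.append(s.inactive.mean())
        fracs = np.asarray(fracs)
        se = fracs.std(ddof=1) / np.sqrt(fracs.size)
        assert abs(fracs.mean() - target) < 3 * se

    def test_session_percent_freezing_tracks_planted_truth(self, paper_scale_cohort):
        subj = paper_scale_cohort.subjects[0]
        s = binarize_activity(subj.traces["F3"], DEFAULT_THRESHOLD)
        pct = percent_freezing(s).session_pct
        assert pct == pytest.approx(100 * subj.truth.planted_freezing["F3"], abs=20)

    def test_nonpositive_durations_rejected(self):
        with pytest.raises(ValueError):
            generate_activity_trace(BoutParams(0.5, 3.0), 10.0, -5.0, 0)
        with pytest.raises(ValueError):
            generate_activity_trace(BoutParams(0.5, 3.0), 0.0, 5.0, 0)


@pytest.fixture(scope="module")
def written(tmp_path_factory, zero_noise_cohort):
    out = tmp_path_factory.mktemp("fixtures")
    manifest = write_fixtures(zero_noise_cohort, out)
    return out, manifest


class TestFixtures:
    def test_manifest_lists_one_pair_per_subject(self, written):
        _, manifest = written
        for entry in manifest["subjects"].values():
            assert set(entry["volumes"]) == {"F1", "F3"}
            assert set(entry["traces"]) == {"F1", "F2", "F3"}

    def test_round_trip_reproduces_cohort(self, written, zero_noise_cohort):
        out, _ = written
        back = read_fixtures(out)
        orig = {s.subject_id: s for s in zero_noise_cohort.subjects}
        for subj in back.subjects:
            ref = orig[subj.subject_id]
            assert subj.group == ref.group
            for sess in ("F1", "F3"):
                assert np.allclose(
                    subj.scans[sess].voxels, ref.scans[sess].voxels, atol=1e-5
                )  # float32 storage
            assert subj.truth.planted_increment == pytest.approx(
                ref.truth.planted_increment
            )
        assert np.array_equal(back.brain_mask, zero_noise_cohort.brain_mask)
        for code, mask in back.mask_set.regions.items():
            assert np.array_equal(mask, zero_noise_cohort.mask_set.regions[code])

    def test_missing_volume_detected_by_name(self, tmp_path, zero_noise_cohort):
        write_fixtures(zero_noise_cohort, tmp_path)
        victim = zero_noise_cohort.subjects[1].subject_id
        (tmp_path / "volumes" / f"{victim}_F3.nii").unlink()
        with pytest.raises(FileNotFoundError, match=victim):
            validate_manifest(tmp_path)


def test_mask_set_geometry():
    cfg = SynthConfig()
    masks = build_mask_set(cfg)
    # BA spans 12 coronal slices and splits left/right about the midline
    assert len(masks.slices("BA")) == 12
    ba = masks.regions["BA"]
    assert ba[: cfg.midline_x].any() and ba[cfg.midline_x:].any()
    assert not masks.bilateral["PLC"] and not masks.bilateral["ILC"]
    assert masks.expected_record_count() == 12 * 2 + 6 + 6 + 6 * 2 * 5
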