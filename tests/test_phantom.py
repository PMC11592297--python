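"""Phantom generator: frames, cohorts, fixtures and their ground truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from sonoderm import (
    CohortSpec,
    PhantomSpec,
    generate_cohort,
    generate_frame,
    load_fixture,
    rasterize_mask,
    thickness_profile,
    write_fixture,
)
from sonoderm.phantom import BASELINE_SPREADS, CohortBundle, fixture_hashes
from sonoderm.pipeline import extract_features_batch

#: Small geometry used by cohort-level simulations (entry 5 px, SLEB 10 px,
#: dermis ~39 px at 0.04 mm/px) so replicated cohorts stay cheap.
SMALL = PhantomSpec(
    height_px=112,
    width_px=128,
    axial_spacing_mm_per_px=0.04,
    surface_offset_px=12,
    seed=0,
)


class TestGenerateFrame:
    def test_noise_free_layers_are_constant_rectangles(self, noise_free_frame, noise_free_spec):
        frame, anns = noise_free_frame
        for ann in anns:
            mask = rasterize_mask(ann, frame)
            vals = frame.pixels[mask]
            mu = noise_free_spec.mean_intensity_per_layer[ann.layer_name]
            assert (vals == int(np.floor(mu + 0.5))).all()  # half-up rounding

    def test_noise_free_thickness_within_one_pixel(self, noise_free_frame, noise_free_spec):
        frame, anns = noise_free_frame
        spec = noise_free_spec
        targets = {
            "entry_echo": spec.entry_thickness_mm,
            "sleb": spec.sleb_thickness_mm,
            "dermis": spec.dermis_thickness_mm,
        }
        for ann in anns:
            got = thickness_profile(ann, frame).mean_mm
            assert got == pytest.approx(
                targets[ann.layer_name], abs=spec.axial_spacing_mm_per_px
            )

    def test_absent_sleb(self):
        spec = dataclasses.replace(SMALL, sleb_thickness_mm=0.0)
        _, anns = generate_frame(spec)
        names = [a.layer_name for a in anns]
        assert names == ["entry_echo", "dermis"]
        # dermis abuts the entry echo
        assert anns[1].upper_edge == anns[0].lower_edge

    def test_determinism_bit_identical(self):
        f1, _ = generate_frame(dataclasses.replace(SMALL, seed=42))
        f2, _ = generate_frame(dataclasses.replace(SMALL, seed=42))
        assert (f1.pixels == f2.pixels).all()

    def test_layer_overflow_names_layer(self):
        with pytest.raises(ValueError, match="dermis"):
            PhantomSpec(height_px=64, dermis_thickness_mm=5.0)

    def test_painted_mask_fidelity(self):
        # annotations are the exact boundaries used to paint: with speckle
        # off, the dermis region is exactly the dermis-valued pixels
        spec = dataclasses.replace(
            SMALL, speckle_shape=None,
            mean_intensity_per_layer={"entry_echo": 200.0, "sleb": 30.0, "dermis": 80.0},
        )
        frame, anns = generate_frame(spec)
        dermis = next(a for a in anns if a.layer_name == "dermis")
        mask = rasterize_mask(dermis, frame)
        assert ((frame.pixels == 80) == mask).all()

    def test_mean_intensity_monotone_in_spec(self):
        # noise-free: extracted MPI equals the configured layer mean exactly
        for mu in (20.0, 60.0, 140.0):
            spec = dataclasses.replace(
                SMALL, speckle_shape=None, roughness_amplitude_px=0.0,
                thickness_jitter_px=0.0,
                mean_intensity_per_layer={"entry_echo": 200.0, "sleb": mu, "dermis": 80.0},
            )
            frame, anns = generate_frame(spec)
            sleb = next(a for a in anns if a.layer_name == "sleb")
            assert frame.pixels[rasterize_mask(sleb, frame)].mean() == mu

    def test_roughness_monotone_in_amplitude(self):
        from sonoderm import surface_roughness

        means = []
        for amp in (0.5, 2.0, 5.0):
            srs = []
            for seed in range(50):
                spec = dataclasses.replace(SMALL, roughness_amplitude_px=amp, seed=seed)
                _, anns = generate_frame(spec)
                srs.append(surface_roughness(anns[0]))
            means.append(np.mean(srs))
        assert means[0] < means[1] < means[2]


class TestGenerateCohort:
    def test_unknown_effect_feature_lists_valid_names(self):
        with pytest.raises(ValueError, match="thickness, mpi, sr"):
            CohortSpec(
                n_markers=4, stage_counts={1: 4}, visits=[0, 12], n_controls=0,
                per_feature_effect={("glcm_energy", "sleb", 12): -1.0},
                base_spec=SMALL,
            )

    def test_no_controls_is_clean(self):
        cspec = CohortSpec(n_markers=5, stage_counts={1: 5}, visits=[0, 4],
                           n_controls=0, base_spec=SMALL, seed=3)
        bundle = generate_cohort(cspec)
        assert (bundle.table["arm"] == "treated").all()
        assert len(bundle.frames) == 10

    def test_sleb_shift_recovers_target_ratio(self):
        # week-12 latent SLEB mean thickness set to 0.575x baseline
        target_ratio = 0.2325 / 0.4039
        shift_mm = (0.2325 - 0.4039)
        eff = shift_mm / BASELINE_SPREADS[("thickness", "sleb")]
        cspec = CohortSpec(
            n_markers=40, stage_counts={1: 40}, visits=[0, 12], n_controls=0,
            per_feature_effect={("thickness", "sleb", 12): eff},
            base_spec=SMALL, seed=11,
        )
        bundle = generate_cohort(cspec)
        means = {0: [], 12: []}
        for _, row in bundle.table.iterrows():
            frame = bundle.frames[row["frame_id"]]
            for ann in bundle.annotations[row["frame_id"]]:
                if ann.layer_name == "sleb":
                    means[row["week"]].append(thickness_profile(ann, frame).mean_mm)
        ratio = np.mean(means[12]) / np.mean(means[0])
        assert ratio == pytest.approx(target_ratio, rel=0.10)

    def test_null_cohort_rejection_rate_at_alpha(self):
        """With all effects zero the paired Wilcoxon on extracted thickness
        rejects at ~alpha (replicated null cohorts, 99% binomial band)."""
        from sonoderm import wilcoxon_signed_rank
        from sonoderm.stats import InsufficientDataError

        n_seeds, alpha = 400, 0.05
        rejections = 0
        for seed in range(n_seeds):
            cspec = CohortSpec(n_markers=8, stage_counts={1: 8}, visits=[0, 4],
                               n_controls=0, base_spec=SMALL, seed=seed)
            bundle = generate_cohort(cspec)
            vals = {0: {}, 4: {}}
            for _, row in bundle.table.iterrows():
                frame = bundle.frames[row["frame_id"]]
                ann = bundle.annotations[row["frame_id"]][0]  # entry echo
                vals[row["week"]][row["marker_id"]] = thickness_profile(ann, frame).mean_mm
            markers = sorted(vals[0])
            before = [vals[0][m] for m in markers]
            after = [vals[4][m] for m in markers]
            try:
                res = wilcoxon_signed_rank(before, after, alpha)
            except InsufficientDataError:
                continue
            rejections += res.p_two_sided < alpha
        rate = rejections / n_seeds
        band = 2.576 * np.sqrt(alpha * (1 - alpha) / n_seeds)
        assert abs(rate - alpha) <= band


class TestFixtureIO:
    def _bundle(self, seed=5):
        cspec = CohortSpec(n_markers=3, stage_counts={1: 3}, visits=[0, 4],
                           n_controls=1, base_spec=SMALL, seed=seed)
        return generate_cohort(cspec)

    def test_round_trip_features_identical(self, tmp_path):
        bundle = self._bundle()
        manifest = write_fixture(bundle, tmp_path / "fx")
        reloaded = load_fixture(manifest)
        t0 = extract_features_batch(bundle).table
        t1 = extract_features_batch(reloaded).table
        pd.testing.assert_frame_equal(t0, t1)

    def test_manifest_regenerate_identical_hashes(self, tmp_path):
        bundle = self._bundle()
        m1 = write_fixture(bundle, tmp_path / "a")
        regenerated = generate_cohort(load_fixture(m1).cspec)
        write_fixture(regenerated, tmp_path / "b")
        h1 = fixture_hashes(tmp_path / "a")
        h2 = fixture_hashes(tmp_path / "b")
        assert h1 == h2

    def test_empty_bundle(self, tmp_path):
        cols = ["marker_id", "patient_id", "stage", "week", "akasi", "site", "arm", "frame_id"]
        empty = CohortBundle({}, {}, pd.DataFrame(columns=cols),
                             CohortSpec(n_markers=0, stage_counts={}, visits=[0],
                                        n_controls=0, base_spec=SMALL))
        manifest = write_fixture(empty, tmp_path / "e")
        import json
        assert json.loads(manifest.read_text())["frames"] == []
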