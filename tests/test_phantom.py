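"""Phantom determinism, the table-height geometry model, and cohort structure."""

import dataclasses

import numpy as np
import pytest

from scoutreid import phantom as ph
from tests.conftest import neutral_params


class TestMakePatient:
    def test_deterministic(self):
        assert ph.make_patient(42, "P001") == ph.make_patient(42, "P001")

    def test_distinct_ids_give_distinct_latents(self):
        a, b = ph.make_patient(42, "P001"), ph.make_patient(42, "P002")
        assert any(
            getattr(a, f.name) != getattr(b, f.name)
            for f in dataclasses.fields(a)
            if f.name != "patient_id"
        )

    def test_distinct_seeds_give_distinct_latents(self):
        a, b = ph.make_patient(41, "P001"), ph.make_patient(42, "P001")
        assert any(
            getattr(a, f.name) != getattr(b, f.name) for f in dataclasses.fields(a)
        )

    def test_empty_id_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            ph.make_patient(42, "")


class TestExamParams:
    def test_deterministic(self, latent):
        a = ph.sample_exam_params(latent, "S-like", 1, 7)
        b = ph.sample_exam_params(latent, "S-like", 1, 7)
        assert a == b

    def test_unknown_vendor_rejected(self, latent):
        with pytest.raises(ValueError, match="vendor"):
            ph.sample_exam_params(latent, "X-like", 0, 7)

    def test_table_offset_sd_matches_declared_normal(self, latent):
        # S-like declares dh ~ Normal(mu, 14); Monte-Carlo SD within 14 +/- 0.5
        draws = np.array(
            [
                ph.sample_exam_params(latent, "S-like", k, 123).table_offset_dh
                for k in range(10_000)
            ]
        )
        assert abs(draws.std() - 14.0) < 0.5

    def test_zero_rates_give_neutral_toggles(self, latent):
        rates = ph.NuisanceRates(0.0, 0.0, 0.0, 0.0)
        for k in range(5):
            p = ph.sample_exam_params(latent, "G-like", k, 9, rates)
            assert p.scan_range_shift == 0.0
            assert p.lung_inflation == 1.0
            assert p.gas_blobs == ()
            assert p.arms_raised


class TestGeometry:
    def test_scale_is_one_at_centered_table(self):
        assert ph.GeometryModel().scale(0.0) == 1.0

    def test_degenerate_offset_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ph.transversal_scale_factor(600.0, d0=600.0)
        with pytest.raises(ValueError):
            ph.GeometryModel(sid=1000, d0=600).scale(-600.0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ph.GeometryModel(sid=500.0, d0=600.0)

    def test_render_width_follows_magnification(self, latent):
        # dh = +23 mm, d0 = 600 -> width ratio 600/577, within 1 pixel
        img0 = ph.render_exam(latent, neutral_params(dh=0.0))
        img23 = ph.render_exam(latent, neutral_params(dh=23.0))
        w0 = ph.silhouette_width_mm(img0, 1.0)
        w23 = ph.silhouette_width_mm(img23, 1.0)
        expected = 600.0 / 577.0
        assert abs(w23 - w0 * expected) < 2.0  # one S-like pixel

    @pytest.mark.parametrize("dh1,dh2", [(-50.0, 20.0), (10.0, 50.0), (-23.0, 23.0)])
    def test_width_ratio_between_any_two_offsets(self, latent, dh1, dh2):
        w1 = ph.silhouette_width_mm(ph.render_exam(latent, neutral_params(dh=dh1)), 1.0)
        w2 = ph.silhouette_width_mm(ph.render_exam(latent, neutral_params(dh=dh2)), 1.0)
        expected = (600.0 - dh1) / (600.0 - dh2)
        assert abs(w2 / w1 - expected) < 2.0 / w1  # within one pixel of width


class TestRender:
    def test_bit_identical_rerender(self, latent, clean_render):
        again = ph.render_exam(latent, neutral_params())
        np.testing.assert_array_equal(clean_render.pixels, again.pixels)

    def test_vendor_grids_and_spacing(self, latent):
        s = ph.render_exam(latent, neutral_params("S-like"))
        g = ph.render_exam(latent, neutral_params("G-like"))
        assert s.shape == (280, 280) and s.pixel_spacing == (2.0, 2.0)
        assert g.shape == (964, 883) and g.pixel_spacing == (0.55, 0.60)

    def test_same_physical_width_different_histograms_across_vendors(self, latent):
        s = ph.render_exam(latent, neutral_params("S-like"))
        g = ph.render_exam(latent, neutral_params("G-like"))
        ws = ph.silhouette_width_mm(s, 1.0)
        wg = ph.silhouette_width_mm(g, 1.0)
        assert abs(ws - wg) < 2.0  # one coarse pixel in mm
        hs, _ = np.histogram(s.pixels / 65535.0, bins=32, range=(0, 1), density=True)
        hg, _ = np.histogram(g.pixels / 65535.0, bins=32, range=(0, 1), density=True)
        assert np.abs(hs - hg).sum() > 1.0  # contrast processing differs

    def test_degenerate_table_offset_rejected(self, latent):
        with pytest.raises(ValueError, match="degenerate"):
            ph.render_exam(latent, neutral_params(dh=700.0))


class TestCohort:
    def test_manifest_deterministic_and_conserves_exams(self):
        spec = ph.CohortSpec(n_patients=12, exams_per_patient=3, master_seed=7)
        m1, im1 = ph.generate_cohort(spec)
        m2, im2 = ph.generate_cohort(spec)
        assert m1.equals(m2)
        np.testing.assert_array_equal(im1[0].pixels, im2[0].pixels)
        n_trainval = (m1.split != "test").sum()
        assert len(m1) == len(im1)
        # every trainval patient contributes exams_per_patient exams
        tv = m1[m1.split != "test"]
        assert (tv.groupby("patient_id").size() == 3).all()

    def test_no_patient_in_two_splits(self):
        spec = ph.CohortSpec(n_patients=16, master_seed=3)
        m, _ = ph.generate_cohort(spec)
        trainval = set(m[m.split.isin(["train", "val"])].patient_id)
        test = set(m[m.split == "test"].patient_id)
        assert not trainval & test

    def test_test_patients_have_baseline_and_at_most_two_exams(self):
        spec = ph.CohortSpec(n_patients=16, master_seed=3, followup_fraction=0.5)
        m, _ = ph.generate_cohort(spec)
        test = m[m.split == "test"]
        sizes = test.groupby("patient_id").size()
        assert sizes.max() <= 2
        assert (test.groupby("patient_id").role.apply(lambda r: "baseline" in set(r))).all()

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            ph.generate_cohort(ph.CohortSpec(n_patients=4, split=(0.25, 0.05, 0.7)))

    def test_bad_split_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ph.CohortSpec(n_patients=10, split=(0.5, 0.2, 0.2))

    def test_written_cohort_round_trips(self, tmp_path):
        from scoutreid.io_preproc import read_image

        spec = ph.CohortSpec(n_patients=8, master_seed=1)
        m, images = ph.generate_cohort(spec, out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        back = read_image(m.path[0])
        np.testing.assert_array_equal(back.pixels, images[0].pixels)


class TestIdentityStructure:
    def test_same_patient_correlation_exceeds_different(self):
        """Mean pixel-wise correlation is higher within than between patients
        over a small cohort — the signal the extractor must learn."""
        from scoutreid.io_preproc import preprocess

        spec = ph.CohortSpec(n_patients=20, master_seed=11, split=(0.0, 0.0, 1.0), followup_fraction=1.0)
        m, images = ph.generate_cohort(spec)
        X = np.stack([preprocess(i).pixels.astype(float).ravel() for i in images])
        X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        C = (X @ X.T) / X.shape[1]
        ids = m.patient_id.to_numpy()
        same = ids[:, None] == ids[None, :]
        off = ~np.eye(len(X), dtype=bool)
        assert C[same & off].mean() > C[~same].mean()
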