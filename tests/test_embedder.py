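"""AdaCos closed forms, smoothed cross entropy, and extractor training behavior."""

import numpy as np
import pandas as pd
import pytest

from scoutreid import phantom as ph
from scoutreid.embedder import (
    AdaCosHead,
    ScoutEmbedder,
    SmallConvBackbone,
    adacos_logits,
    smooth_ce_loss,
)
from scoutreid.io_preproc import preprocess


def unit_rows(X):
    return X / np.linalg.norm(X, axis=1, keepdims=True)


class TestAdaCos:
    def test_initial_scale_closed_form(self):
        rng = np.random.default_rng(0)
        assert AdaCosHead(3, 8, rng).s == pytest.approx(np.sqrt(2) * np.log(2))
        assert AdaCosHead(100, 8, rng).s == pytest.approx(np.sqrt(2) * np.log(99))

    def test_fewer_than_three_classes_rejected(self):
        with pytest.raises(ValueError, match="3 classes"):
            AdaCosHead(2, 8, np.random.default_rng(0))

    def test_embeddings_on_class_weights_give_s_ln_bavg(self):
        """theta_med = 0 -> divisor cos(0) = 1, so s = ln(B_avg)."""
        rng = np.random.default_rng(1)
        head = AdaCosHead(5, 8, rng)
        labels = np.arange(5)
        emb = head.W.value[labels].copy()  # exactly on the class weights
        s_prev = head.s
        cos = emb @ head.W.value.T
        e = np.exp(s_prev * cos)
        e[np.arange(5), labels] = 0.0
        expected_s = np.log(e.sum(axis=1).mean())
        logits, head = adacos_logits(emb, labels, head, train=True)
        assert head.s == pytest.approx(expected_s, abs=1e-12)

    def test_large_target_angle_clamped_to_pi_over_4(self):
        """theta_med = pi/2 -> clamped, divisor cos(pi/4) = sqrt(2)/2."""
        rng = np.random.default_rng(2)
        head = AdaCosHead(4, 4, rng)
        head.W.value = np.eye(4)
        labels = np.arange(4)
        emb = np.roll(np.eye(4), 1, axis=1)  # orthogonal to own class: theta = pi/2
        s_prev = head.s
        cos = emb @ head.W.value.T
        e = np.exp(s_prev * cos)
        e[np.arange(4), labels] = 0.0
        expected_s = np.log(e.sum(axis=1).mean()) / (np.sqrt(2) / 2)
        head.forward(emb, labels, train=True)
        assert head.s == pytest.approx(expected_s, abs=1e-12)

    def test_eval_mode_freezes_state(self):
        rng = np.random.default_rng(3)
        head = AdaCosHead(5, 6, rng)
        emb = unit_rows(rng.normal(size=(4, 6)))
        s_before = head.s
        head.forward(emb, None, train=False)
        assert head.s == s_before

    def test_non_normalized_input_warned_and_normalized(self):
        rng = np.random.default_rng(4)
        head = AdaCosHead(4, 6, rng)
        emb = rng.normal(size=(3, 6)) * 5
        with pytest.warns(UserWarning, match="non-normalized"):
            logits = head.forward(emb, None, train=False)
        assert np.abs(logits / head.s).max() <= 1 + 1e-9


class TestSmoothCE:
    def test_zero_smoothing_equals_standard_ce(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(6, 4))
        labels = rng.integers(0, 4, size=6)
        loss, _ = smooth_ce_loss(logits, labels, 0.0)
        z = logits - logits.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        assert loss == pytest.approx(-logp[np.arange(6), labels].mean(), abs=1e-12)

    @pytest.mark.parametrize("eps", [0.0, 0.05, 0.3])
    def test_uniform_logits_give_ln_c(self, eps):
        loss, _ = smooth_ce_loss(np.zeros((3, 7)), np.array([0, 1, 2]), eps)
        assert loss == pytest.approx(np.log(7), abs=1e-12)

    def test_loss_decreases_with_logit_scale_when_correct(self):
        labels = np.array([0, 1])
        base = np.array([[1.0, -1.0, -1.0], [-1.0, 1.0, -1.0]])
        losses = [smooth_ce_loss(c * base, labels, 0.0)[0] for c in (0.5, 1, 2, 4)]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_gradient_matches_numerical(self):
        rng = np.random.default_rng(5)
        logits = rng.normal(size=(3, 4))
        labels = np.array([0, 2, 1])
        _, grad = smooth_ce_loss(logits, labels, 0.05)
        eps = 1e-6
        for i in (0, 1):
            for j in (0, 3):
                logits[i, j] += eps
                up, _ = smooth_ce_loss(logits, labels, 0.05)
                logits[i, j] -= 2 * eps
                dn, _ = smooth_ce_loss(logits, labels, 0.05)
                logits[i, j] += eps
                assert grad[i, j] == pytest.approx((up - dn) / (2 * eps), abs=1e-6)

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(ValueError):
            smooth_ce_loss(np.zeros((1, 3)), np.array([0]), 1.0)


@pytest.fixture(scope="module")
def tiny_cohort():
    """Eight phantom patients, two train + one held-out exam each."""
    spec = ph.CohortSpec(
        n_patients=8, exams_per_patient=3, master_seed=5, split=(2 / 3, 1 / 3, 0.0)
    )
    manifest, images = ph.generate_cohort(spec)
    X = np.stack([preprocess(i).pixels for i in images])
    y = manifest.patient_id.to_numpy()
    train = manifest.split == "train"
    val = manifest.split == "val"
    return X[train], y[train], X[val], y[val]


@pytest.fixture(scope="module")
def fitted(tiny_cohort):
    Xt, yt, Xv, yv = tiny_cohort
    emb = ScoutEmbedder(epochs=100, batch_size=16, lr_init=0.02, lr_final=0.002, random_state=0)
    emb.fit(Xt, yt, X_val=Xv, y_val=yv)
    return emb


class TestTraining:
    def test_loss_decreases(self, fitted):
        h = fitted.history_
        assert h.loss.iloc[-1] < h.loss.iloc[0]

    def test_adacos_scale_finite_positive_throughout(self, fitted):
        s = fitted.history_.adacos_s
        assert np.all(np.isfinite(s)) and np.all(s > 0)

    def test_history_records_diagnostics(self, fitted):
        h = fitted.history_
        for col in ("loss", "lr", "adacos_s", "val_acc1", "genuine_mean", "impostor_mean",
                    "genuine_sd", "impostor_sd"):
            assert col in h.columns

    def test_same_seed_reproduces_loss_curve(self, tiny_cohort):
        Xt, yt, _, _ = tiny_cohort
        runs = []
        for _ in range(2):
            e = ScoutEmbedder(epochs=3, batch_size=12, random_state=11)
            e.fit(Xt, yt)
            runs.append(e.history_.loss.to_numpy())
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_genuine_impostor_gap_grows(self, fitted):
        h = fitted.history_
        gap0 = h.genuine_mean.iloc[0] - h.impostor_mean.iloc[0]
        gap1 = h.genuine_mean.iloc[-1] - h.impostor_mean.iloc[-1]
        assert gap1 > gap0

    def test_capacity_overfits_four_patient_training_set(self):
        """The desk backbone must reach ACC1 = 1.0 on its own 4-patient
        training set within 100 epochs (capacity sanity)."""
        spec = ph.CohortSpec(n_patients=4, exams_per_patient=3, master_seed=9, split=(1.0, 0.0, 0.0))
        manifest, images = ph.generate_cohort(spec)
        X = np.stack([preprocess(i).pixels for i in images])
        y = manifest.patient_id.to_numpy()
        emb = ScoutEmbedder(epochs=100, batch_size=12, lr_init=0.02, lr_final=0.002,
                            similarity_diag_every=20, random_state=0)
        emb.fit(X, y, X_val=X, y_val=y)
        assert emb.history_.val_acc1.max() == 1.0

    def test_fewer_than_three_patients_rejected(self, tiny_cohort):
        Xt, yt, _, _ = tiny_cohort
        mask = np.isin(yt, np.unique(yt)[:2])
        with pytest.raises(ValueError, match="3 training patients"):
            ScoutEmbedder(epochs=1).fit(Xt[mask], yt[mask])

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ScoutEmbedder().fit(np.zeros((0, 384, 256)), np.array([]))


class TestExtract:
    def test_batch_size_invariance(self, fitted, tiny_cohort):
        Xt = tiny_cohort[0]
        one_by_one = np.concatenate([fitted._embed(Xt[i : i + 1], False) for i in range(4)])
        batched = fitted._embed(Xt[:4], False)
        np.testing.assert_allclose(one_by_one, batched, atol=1e-10)

    def test_duplicate_images_identical_vectors(self, fitted, tiny_cohort):
        Xt = tiny_cohort[0]
        F = fitted.transform(np.stack([Xt[0], Xt[0]]))
        np.testing.assert_array_equal(F[0], F[1])

    def test_output_dimension_configurable(self, fitted):
        assert fitted.transform(np.zeros((1, 384, 256), dtype=np.uint8)).shape == (1, 64)

    def test_wrong_input_shape_rejected(self, fitted):
        with pytest.raises(ValueError, match="rows"):
            fitted.transform(np.zeros((384, 256)))

    def test_unfitted_transform_rejected(self):
        with pytest.raises(ValueError, match="not fitted"):
            ScoutEmbedder().transform(np.zeros((1, 384, 256)))


class TestCheckpoint:
    def test_save_load_round_trip_preserves_embeddings(self, fitted, tiny_cohort, tmp_path):
        Xt = tiny_cohort[0]
        p = tmp_path / "ckpt.npz"
        fitted.save(p)
        back = ScoutEmbedder.load(p)
        np.testing.assert_allclose(back.transform(Xt[:3]), fitted.transform(Xt[:3]), atol=1e-6)
        assert list(back.classes_) == list(fitted.classes_)


class TestBackboneContract:
    def test_feature_dim_and_determinism(self):
        rng = np.random.default_rng(0)
        bb = SmallConvBackbone(feature_dim=32, width=4, rng=rng)
        x = np.random.default_rng(1).normal(size=(2, 384, 256, 1)).astype(np.float32)
        a = bb.forward(x, train=False)
        b = bb.forward(x, train=False)
        assert a.shape == (2, 32)
        np.testing.assert_array_equal(a, b)
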