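"""Deep-metric-learning feature extractor with an AdaCos classifier head.

Training attaches a nonlinear projection head (linear - ReLU - batch norm -
linear) and an adaptive cosine-softmax (AdaCos) metric layer to a pluggable
backbone, one class per training patient.  AdaCos scales cosine logits by a
factor that it re-estimates from batch statistics every step, so the
cosine-softmax needs no manually tuned scale or margin:

    s_0 = sqrt(2) * ln(C - 1)
    B_avg = mean_i sum_{k != y_i} exp(s * cos theta_ik)
    theta_med = median_i theta_{i, y_i}
    s <- ln(B_avg) / cos(min(pi/4, theta_med))

At inference the head is dropped by default and the backbone's feature
vector (1280-d at full scale, configurable at desk scale) is the patient
representation compared by cosine similarity.

The full-scale backbone of the method this package implements is
EfficientNetV2-L; any callable satisfying :class:`BackboneContract` can be
plugged in.  The built-in desk-scale reference backbone is a small conv
net (stem pooling + 4 conv blocks + global average pooling) written on
the package's NumPy layer stack.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import _nn
from .augment import AugmentConfig, augment_pipeline

__all__ = [
    "AdaCosHead",
    "BackboneContract",
    "SmallConvBackbone",
    "ProjectionHead",
    "TrainConfig",
    "ScoutEmbedder",
    "adacos_logits",
    "smooth_ce_loss",
    "train_extractor",
]


# ---------------------------------------------------------------------------
# AdaCos


class AdaCosHead:
    """Adaptive cosine-softmax state: C unit class weights and the scale s."""

    def __init__(self, n_classes: int, dim: int, rng: np.random.Generator):
        if n_classes < 3:
            raise ValueError(
                f"AdaCos needs >= 3 classes (s0 = sqrt(2) ln(C-1) degenerates), got {n_classes}"
            )
        self.n_classes = n_classes
        self.dim = dim
        W = rng.normal(0.0, 1.0, size=(n_classes, dim))
        self.W = _nn.Param(W / np.linalg.norm(W, axis=1, keepdims=True), decay=False)
        self.s = float(np.sqrt(2.0) * np.log(n_classes - 1))
        self._emb: np.ndarray | None = None

    def forward(self, emb: np.ndarray, labels: np.ndarray | None, train: bool) -> np.ndarray:
        """Cosine logits scaled by s; in training mode s is re-estimated first.

        ``emb`` must be row-normalized (the embedder guarantees it); class
        weights are unit vectors, so ``emb @ W.T`` is cos(theta).
        """
        norms = np.linalg.norm(emb, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            warnings.warn("AdaCos received non-normalized embeddings; normalizing", stacklevel=2)
            emb = emb / (norms[:, None] + 1e-12)
        cos = emb @ self.W.value.T
        if train:
            if labels is None:
                raise ValueError("labels required in training mode")
            idx = np.arange(len(labels))
            with np.errstate(over="ignore"):
                e = np.exp(self.s * np.clip(cos, -1.0, 1.0))
            e[idx, labels] = 0.0
            b_avg = max(float(e.sum(axis=1).mean()), 1e-12)
            theta_med = float(np.median(np.arccos(np.clip(cos[idx, labels], -1.0, 1.0))))
            self.s = float(np.log(b_avg) / np.cos(min(np.pi / 4.0, theta_med)))
            if not np.isfinite(self.s) or self.s <= 0:
                raise FloatingPointError(f"AdaCos scale became invalid: {self.s}")
        self._emb = emb
        self._cos = cos
        return self.s * cos

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Gradient w.r.t. the embeddings; accumulates dW (s treated as constant)."""
        self.W.grad += self.s * (dlogits.T @ self._emb)
        return self.s * (dlogits @ self.W.value)

    def renormalize(self):
        """Project class weights back to the unit sphere after an optimizer step."""
        self.W.value /= np.linalg.norm(self.W.value, axis=1, keepdims=True) + 1e-12

    def params(self):
        return [self.W]


def adacos_logits(
    embeddings: np.ndarray,
    labels: np.ndarray | None,
    state: AdaCosHead,
    train: bool = True,
) -> tuple[np.ndarray, AdaCosHead]:
    """Functional wrapper: ``(logits, updated state)``; eval freezes the state."""
    logits = state.forward(embeddings, labels, train)
    return logits, state


def smooth_ce_loss(
    logits: np.ndarray, labels: np.ndarray, epsilon: float = 0.05
) -> tuple[float, np.ndarray]:
    """Label-smoothed cross entropy; returns (loss, dloss/dlogits).

    Uniform smoothing: t = (1 - eps) * onehot + eps / C, so with eps = 0
    this reduces to standard cross entropy and with uniform logits the
    loss is ln C for any eps.
    """
    if not 0.0 <= epsilon < 1.0:
        raise ValueError(f"label smoothing must be in [0, 1), got {epsilon}")
    n, c = logits.shape
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    t = np.full((n, c), epsilon / c)
    t[np.arange(n), labels] += 1.0 - epsilon
    loss = float(-(t * logp).sum(axis=1).mean())
    dlogits = (np.exp(logp) - t) / n
    return loss, dlogits


# ---------------------------------------------------------------------------
# backbones


class BackboneContract:
    """Pluggable feature extractor: (N, H, W, 1) -> (N, feature_dim).

    Implementations expose ``forward(x, train)``, ``backward(dout)``,
    ``params()`` and ``feature_dim``; deterministic given weights and
    input.  The full-scale method uses an EfficientNetV2-L backbone with
    feature_dim = 1280; the desk-scale reference below keeps the same
    contract at a size trainable on a laptop CPU.
    """

    feature_dim: int

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[_nn.Param]:  # pragma: no cover
        raise NotImplementedError


class SmallConvBackbone(BackboneContract):
    """Desk-scale reference: pooling stem, 4 conv blocks, global pooling.

    ``stem_pool`` sets the stem's pooling factor so different working
    resolutions land on the same internal grid: 384 x 256 at 2 mm with
    ``stem_pool=4`` and 192 x 128 at 4 mm with ``stem_pool=2`` both
    give the first conv a 96 x 64 map at 8 mm per cell.
    """

    def __init__(
        self,
        feature_dim: int = 64,
        width: int = 8,
        rng: np.random.Generator | None = None,
        stem_pool: int = 4,
    ):
        rng = rng or np.random.default_rng(0)
        self.feature_dim = feature_dim
        w = width
        self.net = _nn.Sequential(
            _nn.AvgPool2d(stem_pool),  # -> 96x64 at the default sizes
            _nn.Conv2d(1, w, 3, rng),
            _nn.BatchNorm(w),
            _nn.ReLU(),
            _nn.AvgPool2d(2),  # 48x32
            _nn.Conv2d(w, 2 * w, 3, rng),
            _nn.BatchNorm(2 * w),
            _nn.ReLU(),
            _nn.AvgPool2d(2),  # 24x16
            _nn.Conv2d(2 * w, 4 * w, 3, rng),
            _nn.BatchNorm(4 * w),
            _nn.ReLU(),
            _nn.AvgPool2d(2),  # 12x8
            # final block has no ReLU: rectified channels are all-positive,
            # and their common mode would dominate cosine similarity
            _nn.Conv2d(4 * w, feature_dim, 3, rng),
            _nn.BatchNorm(feature_dim),
            _nn.GlobalAvgPool(),
        )

    def forward(self, x, train):
        return self.net.forward(x, train)

    def backward(self, dout):
        return self.net.backward(dout)

    def params(self):
        return self.net.params()


class ProjectionHead:
    """linear -> ReLU -> batch norm -> linear, used during training only."""

    def __init__(self, d_in: int, hidden: int, d_out: int, rng: np.random.Generator):
        self.d_out = d_out
        self.net = _nn.Sequential(
            _nn.Linear(d_in, hidden, rng),
            _nn.ReLU(),
            _nn.BatchNorm(hidden, ndim=2),
            _nn.Linear(hidden, d_out, rng),
        )

    def forward(self, x, train):
        return self.net.forward(x, train)

    def backward(self, dout):
        return self.net.backward(dout)

    def params(self):
        return self.net.params()


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults are the method's printed settings).

    Batch size 20; label smoothing 0.05; cosine learning-rate decay from
    0.005 to 0.0005 without warmup; momentum-SGD with momentum 0.8 and
    weight decay 0.002.  The sharpness-aware wrapper (neighborhood
    rho = 2.0) is available via ``optimizer="sam"``; plain SGD is the
    desk-scale default.
    """

    epochs: int = 30
    batch_size: int = 20
    label_smoothing: float = 0.05
    lr_init: float = 0.005
    lr_final: float = 0.0005
    momentum: float = 0.8
    weight_decay: float = 0.002
    optimizer: str = "sgd"  # "sgd" | "sam"
    sam_rho: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.optimizer not in ("sgd", "sam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


class ScoutEmbedder(TransformerMixin, BaseEstimator):
    """Trainable patient-embedding extractor (sklearn fit/transform API).

    ``fit(X, y)`` trains backbone + projection head + AdaCos on image
    array ``X`` (n, rows, cols) with patient labels ``y``; ``transform``
    returns one embedding per image.  By default the deployed extractor
    is the bare backbone (the head is dropped at inference); set
    ``use_head_at_inference=True`` to keep it.

    Parameters mirror :class:`TrainConfig` plus the desk-backbone size
    knobs.  Pass ``X_val, y_val`` to ``fit`` to record the per-epoch
    validation diagnostics (ACC1 and genuine/impostor similarity stats).
    """

    def __init__(
        self,
        feature_dim: int = 64,
        width: int = 8,
        stem_pool: int = 4,
        head_hidden: int = 64,
        embed_dim: int = 64,
        use_head_at_inference: bool = False,
        epochs: int = 30,
        batch_size: int = 20,
        label_smoothing: float = 0.05,
        lr_init: float = 0.005,
        lr_final: float = 0.0005,
        momentum: float = 0.8,
        weight_decay: float = 0.002,
        optimizer: str = "sgd",
        sam_rho: float = 2.0,
        augment: AugmentConfig | None = None,
        backbone_factory=None,
        similarity_diag_every: int = 1,
        random_state: int = 0,
    ):
        self.feature_dim = feature_dim
        self.width = width
        self.stem_pool = stem_pool
        self.head_hidden = head_hidden
        self.embed_dim = embed_dim
        self.use_head_at_inference = use_head_at_inference
        self.epochs = epochs
        self.batch_size = batch_size
        self.label_smoothing = label_smoothing
        self.lr_init = lr_init
        self.lr_final = lr_final
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.optimizer = optimizer
        self.sam_rho = sam_rho
        self.augment = augment
        self.backbone_factory = backbone_factory
        self.similarity_diag_every = similarity_diag_every
        self.random_state = random_state

    # -- internals -----------------------------------------------------

    @staticmethod
    def _equalize(img: np.ndarray) -> np.ndarray:
        """256-bin histogram equalization (CDF lookup) for 8-bit-range images."""
        q = np.clip(np.round(img), 0, 255).astype(np.uint8)
        cdf = np.cumsum(np.bincount(q.ravel(), minlength=256)).astype(np.float32)
        cdf /= cdf[-1]
        return cdf[q]

    @classmethod
    def _prepare(cls, X: np.ndarray) -> np.ndarray:
        """Input adapter: per-image histogram equalization, then
        standardization.

        Vendors apply their own monotone tone curves (contrast
        correction, dynamic-range compression); equalizing each image's
        histogram maps any monotone remapping of the same scene to
        nearly the same input, so the desk-scale backbone does not have
        to spend its small capacity learning tone-curve invariance.
        """
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError(f"expected (n, rows, cols) image array, got shape {X.shape}")
        X = np.stack([cls._equalize(x) for x in X])
        m = X.mean(axis=(1, 2), keepdims=True)
        s = X.std(axis=(1, 2), keepdims=True) + 1e-6
        return ((X - m) / s)[:, :, :, None]

    def _forward_train(self, xb, yb):
        feats = self.backbone_.forward(xb, train=True)
        proj = self.head_.forward(feats, train=True)
        emb = self.norm_.forward(proj, train=True)
        logits = self.adacos_.forward(emb, yb, train=True)
        loss, dlogits = smooth_ce_loss(logits, yb, self.label_smoothing)
        demb = self.adacos_.backward(dlogits)
        dproj = self.norm_.backward(demb)
        dfeat = self.head_.backward(dproj)
        self.backbone_.backward(dfeat)
        return loss

    def _embed_prepared(self, xs: np.ndarray, use_head: bool, batch: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(xs), batch):
            feats = self.backbone_.forward(xs[i : i + batch], train=False)
            if use_head:
                feats = self.head_.forward(feats, train=False)
            out.append(feats)
        return np.concatenate(out, axis=0)

    def _embed(self, X: np.ndarray, use_head: bool, batch: int = 64) -> np.ndarray:
        return self._embed_prepared(self._prepare(X), use_head, batch)

    def _val_diagnostics(self, xv, y_val, xt, y_train, with_similarity: bool):
        """Validation ACC1 through the frozen AdaCos head, plus (every
        ``similarity_diag_every`` epochs) the genuine/impostor
        cosine-similarity statistics between validation and training
        images — the per-epoch overfitting diagnostic.  ``xv``/``xt``
        are already prepared network inputs."""
        emb_v = self._embed_prepared(xv, use_head=True)
        emb_v = emb_v / (np.linalg.norm(emb_v, axis=1, keepdims=True) + 1e-12)
        pred = np.argmax(emb_v @ self.adacos_.W.value.T, axis=1)
        out = {"val_acc1": float(np.mean(pred == y_val))}
        if not with_similarity:
            return out

        feat_v = self._embed_prepared(xv, use_head=self.use_head_at_inference)
        feat_t = self._embed_prepared(xt, use_head=self.use_head_at_inference)
        fv = feat_v / (np.linalg.norm(feat_v, axis=1, keepdims=True) + 1e-12)
        ft = feat_t / (np.linalg.norm(feat_t, axis=1, keepdims=True) + 1e-12)
        S = fv @ ft.T
        same = y_val[:, None] == y_train[None, :]
        gen, imp = S[same], S[~same]
        out.update(
            {
                "genuine_mean": float(gen.mean()),
                "genuine_sd": float(gen.std()),
                "impostor_mean": float(imp.mean()),
                "impostor_sd": float(imp.std()),
            }
        )
        return out

    def _probe_diagnostics(self, xq, yq, xg, yg):
        """Genuine/impostor cosine statistics on held-out identities."""
        fq = self._embed_prepared(xq, use_head=self.use_head_at_inference)
        fg = self._embed_prepared(xg, use_head=self.use_head_at_inference)
        fq = fq / (np.linalg.norm(fq, axis=1, keepdims=True) + 1e-12)
        fg = fg / (np.linalg.norm(fg, axis=1, keepdims=True) + 1e-12)
        S = fq @ fg.T
        same = yq[:, None] == yg[None, :]
        return {
            "probe_genuine_mean": float(S[same].mean()),
            "probe_impostor_mean": float(S[~same].mean()),
        }

    # -- sklearn API ---------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None, probe=None):
        """Train the extractor.

        ``probe``, if given, is a tuple ``(X_query, y_query, X_gallery,
        y_gallery)`` of images of patients *disjoint* from training;
        every ``similarity_diag_every`` epochs the history records the
        genuine/impostor cosine statistics between their embeddings
        (``probe_genuine_mean``, ``probe_impostor_mean``).  Unlike the
        validation diagnostic, which shares patients with training,
        this measures how the representation behaves on unseen
        identities — the collapse of probe impostor similarity toward
        the genuine level is the overtraining signature.
        """
        y = np.asarray(y)
        if len(y) == 0:
            raise ValueError("empty training set")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        if n_classes < 3:
            raise ValueError(f"need >= 3 training patients (classes), got {n_classes}")
        counts = np.bincount(y_enc)
        if counts.min() < 1:
            raise ValueError("every class needs at least one image")
        if X_val is not None:
            yv = np.asarray(y_val)
            lut = {c: i for i, c in enumerate(self.classes_)}
            if not set(yv).issubset(lut):
                raise ValueError("validation labels must be training patients")
            yv_enc = np.array([lut[c] for c in yv])

        rng = np.random.default_rng(np.random.SeedSequence([self.random_state & 0x7FFFFFFF, 0xE3B]))
        factory = self.backbone_factory or (
            lambda r: SmallConvBackbone(self.feature_dim, self.width, r, self.stem_pool)
        )
        self.backbone_ = factory(rng)
        self.head_ = ProjectionHead(self.backbone_.feature_dim, self.head_hidden, self.embed_dim, rng)
        self.norm_ = _nn.L2Normalize()
        self.adacos_ = AdaCosHead(n_classes, self.embed_dim, rng)

        params = self.backbone_.params() + self.head_.params() + self.adacos_.params()
        base = _nn.SGD(params, self.lr_init, self.momentum, self.weight_decay)
        sam = _nn.SAMWrapper(base, self.sam_rho) if self.optimizer == "sam" else None

        xs = self._prepare(X)
        xv = None  # validation inputs prepared lazily, once
        xp = None
        if probe is not None:
            xq_p, yq_p, xg_p, yg_p = probe
            xp = (self._prepare(xq_p), np.asarray(yq_p), self._prepare(xg_p), np.asarray(yg_p))
        n = len(xs)
        steps_per_epoch = max(1, int(np.ceil(n / self.batch_size)))
        total_steps = self.epochs * steps_per_epoch
        step = 0
        history = []
        for epoch in range(self.epochs):
            perm = rng.permutation(n)
            losses = []
            for b in range(steps_per_epoch):
                idx = perm[b * self.batch_size : (b + 1) * self.batch_size]
                if len(idx) == 0:
                    continue
                if self.augment is not None:
                    aug = np.stack(
                        [
                            augment_pipeline(np.asarray(X[i], dtype=np.float32), self.augment, rng)
                            for i in idx
                        ]
                    )
                    xb = self._prepare(aug)
                else:
                    xb = xs[idx]
                yb = y_enc[idx]
                base.lr = _nn.cosine_lr(step, total_steps, self.lr_init, self.lr_final)
                if sam is None:
                    base.zero_grad()
                    loss = self._forward_train(xb, yb)
                    base.step()
                else:
                    sam.zero_grad()
                    loss = self._forward_train(xb, yb)
                    sam.first_step()
                    self._forward_train(xb, yb)
                    sam.second_step()
                self.adacos_.renormalize()
                losses.append(loss)
                step += 1
            rec = {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "lr": base.lr,
                "adacos_s": self.adacos_.s,
            }
            with_sim = epoch % self.similarity_diag_every == 0 or epoch == self.epochs - 1
            if X_val is not None and len(X_val) > 0:
                if xv is None:
                    xv = self._prepare(X_val)
                rec.update(self._val_diagnostics(xv, yv_enc, xs, y_enc, with_sim))
            if xp is not None and with_sim:
                rec.update(self._probe_diagnostics(*xp))
            history.append(rec)
        self.history_ = pd.DataFrame(history)
        self.n_features_in_ = xs.shape[2] * xs.shape[3]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "backbone_"):
            raise ValueError("ScoutEmbedder is not fitted")
        return self._embed(X, use_head=self.use_head_at_inference)

    # -- checkpointing --------------------------------------------------

    def _state_arrays(self) -> list[np.ndarray]:
        """All learnable parameters plus batch-norm running statistics,
        in a deterministic order."""
        arrays = [p.value for p in self.backbone_.params() + self.head_.params() + self.adacos_.params()]
        for net in (self.backbone_.net, self.head_.net):
            for layer in net.layers:
                if isinstance(layer, _nn.BatchNorm):
                    arrays.extend([layer.running_mean, layer.running_var])
        return arrays

    def save(self, path) -> None:
        """Checkpoint: weights + running stats + config snapshot + classes."""
        import json

        np.savez(
            path,
            *self._state_arrays(),
            _config=json.dumps({k: v for k, v in self.get_params().items()
                                if not callable(v) and not hasattr(v, "__dict__")}),
            _classes=np.asarray(self.classes_).astype(str),
            _adacos_s=np.array(self.adacos_.s),
        )

    @classmethod
    def load(cls, path) -> "ScoutEmbedder":
        import json

        with np.load(path, allow_pickle=False) as f:
            config = json.loads(str(f["_config"]))
            est = cls(**config)
            # rebuild the architecture with a throwaway fit-free init
            rng = np.random.default_rng(0)
            factory = est.backbone_factory or (
                lambda r: SmallConvBackbone(est.feature_dim, est.width, r, est.stem_pool)
            )
            est.backbone_ = factory(rng)
            est.head_ = ProjectionHead(est.backbone_.feature_dim, est.head_hidden, est.embed_dim, rng)
            est.norm_ = _nn.L2Normalize()
            est.classes_ = f["_classes"]
            est.adacos_ = AdaCosHead(max(len(est.classes_), 3), est.embed_dim, rng)
            est.adacos_.s = float(f["_adacos_s"])
            arrays = est._state_arrays()
            for i, arr in enumerate(arrays):
                arr[...] = f[f"arr_{i}"]
        return est


def train_extractor(
    images: np.ndarray,
    labels: np.ndarray,
    val_images: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
    config: TrainConfig | None = None,
    augment: AugmentConfig | None = None,
    **backbone_kwargs,
) -> tuple[ScoutEmbedder, pd.DataFrame]:
    """Thin functional wrapper: train an extractor, return it with its history."""
    cfg = config or TrainConfig()
    emb = ScoutEmbedder(
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        label_smoothing=cfg.label_smoothing,
        lr_init=cfg.lr_init,
        lr_final=cfg.lr_final,
        momentum=cfg.momentum,
        weight_decay=cfg.weight_decay,
        optimizer=cfg.optimizer,
        sam_rho=cfg.sam_rho,
        augment=augment,
        random_state=cfg.seed,
        **backbone_kwargs,
    )
    emb.fit(images, labels, X_val=val_images, y_val=val_labels)
    return emb, emb.history_
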