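"""Gallery enrollment and cosine-similarity matching.

The gallery holds one baseline embedding per patient (the earliest exam).
Each follow-up query is compared against every gallery entry by cosine
similarity and the gallery is ranked in descending order; the patient of
the top-ranked image is the re-identification answer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "Gallery",
    "SimilarityMatrix",
    "GalleryMatcher",
    "cosine_similarity_matrix",
    "rank_gallery",
    "identify",
]


def _check_nonzero(X: np.ndarray, what: str) -> None:
    norms = np.linalg.norm(X, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"{what} contains zero vector(s) at index {bad[0]}")


@dataclass
class Gallery:
    """Enrolled baseline embeddings: one row per patient, ids unique."""

    embeddings: np.ndarray
    patient_ids: np.ndarray
    vendors: np.ndarray | None = None

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        self.patient_ids = np.asarray(self.patient_ids)
        if len(self.patient_ids) != len(self.embeddings):
            raise ValueError("ids and embeddings length mismatch")
        if len(np.unique(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("gallery patient_ids must be unique (one baseline per patient)")
        _check_nonzero(self.embeddings, "gallery")


@dataclass
class SimilarityMatrix:
    """Queries x gallery cosine similarities with label/vendor annotation."""

    values: np.ndarray  # (N_q, N_g) in [-1, 1]
    query_ids: np.ndarray | None = None
    gallery_ids: np.ndarray | None = None
    query_vendors: np.ndarray | None = None
    gallery_vendors: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("similarity values must be finite")
        if self.values.min() < -1.0 - 1e-9 or self.values.max() > 1.0 + 1e-9:
            raise ValueError("cosine similarities must lie in [-1, 1]")

    @property
    def shape(self):
        return self.values.shape


def cosine_similarity_matrix(Q: np.ndarray, G: np.ndarray) -> np.ndarray:
    """S[i, j] = <q_i, g_j> / (||q_i|| ||g_j||); rejects zero vectors."""
    Q = np.asarray(Q, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    _check_nonzero(Q, "queries")
    _check_nonzero(G, "gallery")
    Qn = Q / np.linalg.norm(Q, axis=1, keepdims=True)
    Gn = G / np.linalg.norm(G, axis=1, keepdims=True)
    return np.clip(Qn @ Gn.T, -1.0, 1.0)


def rank_gallery(S: np.ndarray, query_index: int) -> np.ndarray:
    """Gallery indices in descending similarity; ties broken by ascending index."""
    row = np.asarray(S)[query_index]
    return np.argsort(-row, kind="stable")


def identify(
    S: np.ndarray, gallery_ids: np.ndarray, k: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Per-query top-k gallery patient ids and their similarity scores.

    Scores come back in non-increasing order per query; the top-1 score
    is the quantity an alert threshold would inspect.
    """
    S = np.asarray(S)
    n_g = S.shape[1]
    if not 1 <= k <= n_g:
        raise ValueError(f"k must be in [1, {n_g}], got {k}")
    order = np.argsort(-S, axis=1, kind="stable")[:, :k]
    ids = np.asarray(gallery_ids)[order]
    scores = np.take_along_axis(S, order, axis=1)
    return ids, scores


class GalleryMatcher(BaseEstimator):
    """sklearn-style matcher: ``fit`` enrolls the gallery, ``predict`` re-identifies.

    Embeddings are L2-normalized once at enrollment so matching is a
    single matrix product; results are identical to unnormalized cosine
    similarity.  ``multi_enroll="max"`` allows several images per patient
    with max-score fusion (off by default — the baseline policy is one
    image per patient).
    """

    def __init__(self, multi_enroll: str = "off"):
        self.multi_enroll = multi_enroll

    def fit(self, X, y, vendors=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if self.multi_enroll == "off":
            self.gallery_ = Gallery(X, y, None if vendors is None else np.asarray(vendors))
        elif self.multi_enroll == "max":
            _check_nonzero(X, "gallery")
            self.gallery_ = Gallery.__new__(Gallery)
            self.gallery_.embeddings = X
            self.gallery_.patient_ids = y
            self.gallery_.vendors = None if vendors is None else np.asarray(vendors)
        else:
            raise ValueError(f"unknown multi_enroll {self.multi_enroll!r}")
        g = self.gallery_.embeddings
        self._gn = g / np.linalg.norm(g, axis=1, keepdims=True)
        return self

    def similarity(self, X, query_ids=None, query_vendors=None) -> SimilarityMatrix:
        X = np.asarray(X, dtype=np.float64)
        _check_nonzero(X, "queries")
        qn = X / np.linalg.norm(X, axis=1, keepdims=True)
        S = np.clip(qn @ self._gn.T, -1.0, 1.0)
        if self.multi_enroll == "max":
            ids, inv = np.unique(self.gallery_.patient_ids, return_inverse=True)
            fused = np.full((S.shape[0], len(ids)), -1.0)
            np.maximum.at(fused.T, inv, S.T)
            return SimilarityMatrix(fused, query_ids, ids, query_vendors, None)
        return SimilarityMatrix(
            S,
            query_ids,
            self.gallery_.patient_ids,
            query_vendors,
            self.gallery_.vendors,
        )

    def predict(self, X) -> np.ndarray:
        """Top-1 patient id per query."""
        sm = self.similarity(X)
        ids, _ = identify(sm.values, sm.gallery_ids, k=1)
        return ids[:, 0]

    def identify(self, X, k: int = 1):
        sm = self.similarity(X)
        return identify(sm.values, sm.gallery_ids, k=k)

    def save(self, path: str | Path, fingerprint: str = "") -> Path:
        """Persist the gallery as a portable NPZ archive.

        ``fingerprint`` identifies the extractor that produced the
        embeddings (e.g. a config hash) so stale galleries can be
        detected at match time.
        """
        path = Path(path)
        g = self.gallery_
        np.savez(
            path,
            embeddings=g.embeddings,
            patient_ids=g.patient_ids.astype(str),
            vendors=(g.vendors if g.vendors is not None else np.array([])).astype(str),
            fingerprint=np.array(fingerprint),
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "GalleryMatcher":
        with np.load(Path(path), allow_pickle=False) as f:
            vendors = f["vendors"] if f["vendors"].size else None
            m = cls()
            m.fit(f["embeddings"], f["patient_ids"], vendors)
        return m
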