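"""Identification-accuracy evaluation and statistical comparison.

Implements the biometric identification protocol: top-K accuracy (ACC@K),
the cumulative match characteristic (CMC) curve, stratification by the
(baseline vendor, follow-up vendor) combination with pooled same-vendor /
different-vendor groups, genuine vs impostor score distributions, and two
statistical tests — the unpaired two-proportion Z-test and McNemar's
chi-squared test for paired proportions (delegated to statsmodels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .matcher import SimilarityMatrix

__all__ = [
    "TestResult",
    "EvalReport",
    "query_ranks",
    "topk_accuracy",
    "cmc_curve",
    "score_distributions",
    "stratified_eval",
    "two_proportion_ztest",
    "mcnemar_test",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    inputs: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# ranking metrics


def query_ranks(
    S: np.ndarray, query_labels: np.ndarray, gallery_labels: np.ndarray
) -> np.ndarray:
    """1-based rank of each query's true patient in the similarity ordering.

    Ties are broken by ascending gallery index (same rule as the
    matcher).  Queries whose patient is not enrolled get rank 0: they
    are flagged rather than silently dropped, and the accuracy
    functions exclude and report them.
    """
    S = np.asarray(S)
    ql = np.asarray(query_labels)
    gl = np.asarray(gallery_labels)
    order = np.argsort(-S, axis=1, kind="stable")
    ranked_labels = gl[order]
    ranks = np.zeros(len(ql), dtype=int)
    for i, lab in enumerate(ql):
        hits = np.flatnonzero(ranked_labels[i] == lab)
        if hits.size:
            ranks[i] = hits[0] + 1
    return ranks


def topk_accuracy(
    S: np.ndarray,
    query_labels: np.ndarray,
    gallery_labels: np.ndarray,
    k: int = 1,
) -> float:
    """Fraction of queries whose true patient is within the top-K entries."""
    if k < 1:
        raise ValueError(f"K must be >= 1, got {k}")
    ranks = query_ranks(S, query_labels, gallery_labels)
    enrolled = ranks > 0
    if not enrolled.any():
        raise ValueError("no query has its patient enrolled in the gallery")
    if not enrolled.all():
        warnings.warn(
            f"{int((~enrolled).sum())} query(ies) not enrolled; excluded from accuracy",
            stacklevel=2,
        )
    return float(np.mean(ranks[enrolled] <= k))


def cmc_curve(
    S: np.ndarray,
    query_labels: np.ndarray,
    gallery_labels: np.ndarray,
    k_max: int | None = None,
) -> np.ndarray:
    """Cumulative match characteristic: ACC@K for K = 1..k_max (non-decreasing)."""
    S = np.asarray(S)
    k_max = k_max or S.shape[1]
    if k_max > S.shape[1]:
        raise ValueError(f"k_max={k_max} exceeds gallery size {S.shape[1]}")
    ranks = query_ranks(S, query_labels, gallery_labels)
    ranks = ranks[ranks > 0]
    return np.array([np.mean(ranks <= k) for k in range(1, k_max + 1)])


def score_distributions(
    S: np.ndarray, query_labels: np.ndarray, gallery_labels: np.ndarray
) -> dict:
    """Genuine vs impostor similarity statistics.

    Genuine entries pair a query with its own patient's gallery image;
    all other entries are impostor pairs.  ``overlap`` reports whether
    the genuine minimum dips below the impostor maximum (score-range
    overlap between the two populations).
    """
    S = np.asarray(S)
    same = np.asarray(query_labels)[:, None] == np.asarray(gallery_labels)[None, :]
    gen, imp = S[same], S[~same]
    if gen.size == 0 or imp.size == 0:
        raise ValueError("need at least one genuine and one impostor pair")
    return {
        "genuine_mean": float(gen.mean()),
        "genuine_sd": float(gen.std()),
        "genuine_n": int(gen.size),
        "impostor_mean": float(imp.mean()),
        "impostor_sd": float(imp.std()),
        "impostor_n": int(imp.size),
        "genuine_min": float(gen.min()),
        "impostor_max": float(imp.max()),
        "overlap": bool(gen.min() < imp.max()),
    }


@dataclass
class EvalReport:
    """Full identification report (overall, per vendor cell, pooled groups)."""

    acc: dict  # {K: ACC@K} overall
    cmc: np.ndarray
    cells: dict  # {(baseline_vendor, followup_vendor): {"n", "acc1", "acc10"}}
    same_vendor: dict  # pooled {"n", "acc1", "acc10"}
    different_vendor: dict
    scores: dict  # genuine/impostor stats
    errors: list  # queries whose true patient fell outside top-K
    n_queries: int = 0
    n_untagged: int = 0
    footer: str = "p-values are reported raw (no multiple-testing adjustment)"

    def as_dict(self) -> dict:
        return {
            "acc": {str(k): v for k, v in self.acc.items()},
            "cmc": self.cmc.tolist(),
            "cells": {f"{a}->{b}": v for (a, b), v in self.cells.items()},
            "same_vendor": self.same_vendor,
            "different_vendor": self.different_vendor,
            "scores": self.scores,
            "errors": self.errors,
            "n_queries": self.n_queries,
            "n_untagged": self.n_untagged,
            "footer": self.footer,
        }


def _group_acc(S, ql, gl, mask, ks=(1, 10)):
    out = {"n": int(mask.sum())}
    for k in ks:
        key = f"acc{k}"
        if mask.sum() == 0:
            out[key] = float("nan")
        else:
            out[key] = topk_accuracy(S[mask], np.asarray(ql)[mask], gl, min(k, S.shape[1]))
    return out


def stratified_eval(
    sm: SimilarityMatrix,
    error_k: int = 10,
    k_max: int | None = None,
) -> EvalReport:
    """Evaluate a labeled similarity matrix with vendor stratification.

    Produces overall ACC1/ACC10 and the CMC, one cell per
    (baseline_vendor, follow-up_vendor) combination, pooled same- and
    different-vendor groups, genuine/impostor score statistics, and the
    list of queries whose true patient fell outside the top ``error_k``
    (with their top score — the raw material of an error audit).
    Queries without a vendor tag are counted under ``n_untagged`` and
    kept in the overall numbers.
    """
    S = sm.values
    ql, gl = sm.query_ids, sm.gallery_ids
    if ql is None or gl is None:
        raise ValueError("similarity matrix must carry query and gallery ids")
    n_q, n_g = S.shape
    ks = sorted({1, min(10, n_g)})
    acc = {k: topk_accuracy(S, ql, gl, k) for k in ks}
    cmc = cmc_curve(S, ql, gl, k_max)
    scores = score_distributions(S, ql, gl)

    # vendor stratification: the gallery vendor of each query's own baseline
    cells: dict = {}
    same = {"n": 0, "acc1": float("nan"), "acc10": float("nan")}
    diff = {"n": 0, "acc1": float("nan"), "acc10": float("nan")}
    n_untagged = 0
    if sm.query_vendors is not None and sm.gallery_vendors is not None:
        gv_by_id = dict(zip(np.asarray(gl), np.asarray(sm.gallery_vendors)))
        qv = np.asarray(sm.query_vendors)
        base_v = np.array([gv_by_id.get(pid, "") for pid in np.asarray(ql)])
        tagged = (qv != "") & (base_v != "")
        n_untagged = int((~tagged).sum())
        for bv in np.unique(base_v[tagged]):
            for fv in np.unique(qv[tagged]):
                mask = tagged & (base_v == bv) & (qv == fv)
                if mask.any():
                    cells[(bv, fv)] = _group_acc(S, ql, gl, mask)
        same = _group_acc(S, ql, gl, tagged & (base_v == qv))
        diff = _group_acc(S, ql, gl, tagged & (base_v != qv))

    ranks = query_ranks(S, ql, gl)
    top1 = np.take_along_axis(S, np.argsort(-S, axis=1, kind="stable")[:, :1], axis=1)[:, 0]
    errors = [
        {"query": str(np.asarray(ql)[i]), "rank": int(ranks[i]), "top1_score": float(top1[i])}
        for i in np.flatnonzero((ranks == 0) | (ranks > error_k))
    ]
    return EvalReport(
        acc=acc,
        cmc=cmc,
        cells=cells,
        same_vendor=same,
        different_vendor=diff,
        scores=scores,
        errors=errors,
        n_queries=n_q,
        n_untagged=n_untagged,
    )


# ---------------------------------------------------------------------------
# statistical tests


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Unpaired two-proportion Z-test with pooled variance, two-sided.

    Z = (p1 - p2) / sqrt(phat (1 - phat) (1/n1 + 1/n2)) with
    phat = (k1 + k2) / (n1 + n2).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not 0 <= k <= n:
            raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    phat = (k1 + k2) / (n1 + n2)
    inputs = {"k1": k1, "n1": n1, "k2": k2, "n2": n2}
    if phat in (0.0, 1.0):
        warnings.warn("pooled proportion is 0 or 1: zero variance, p set to 1", stacklevel=2)
        return TestResult(0.0, 1.0, "two-proportion z (pooled)", inputs)
    from statsmodels.stats.proportion import proportions_ztest

    z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return TestResult(float(z), float(p), "two-proportion z (pooled)", inputs)


def mcnemar_test(b: int, c: int, correction: bool = True, exact: str = "auto") -> TestResult:
    """McNemar's test on discordant-pair counts b and c.

    Default: chi-squared statistic (|b - c| - 1)^2 / (b + c) with
    continuity correction, 1 df.  ``exact="auto"`` switches to the exact
    binomial test when b + c < 25; ``"never"`` forces the chi-squared
    form, ``"always"`` the binomial.  Both variants are reported in
    ``inputs`` for transparency.
    """
    if b < 0 or c < 0:
        raise ValueError(f"discordant counts must be >= 0, got b={b}, c={c}")
    if b + c == 0:
        raise ValueError("no discordant pairs: McNemar's test is undefined")
    table = [[0, b], [c, 0]]
    use_exact = (exact == "always") or (exact == "auto" and b + c < 25)
    res_chi2 = _sm_mcnemar(table, exact=False, correction=correction)
    res_exact = _sm_mcnemar(table, exact=True)
    res = res_exact if use_exact else res_chi2
    return TestResult(
        float(res.statistic),
        float(res.pvalue),
        "mcnemar exact-binomial"
        if use_exact
        else "mcnemar chi-squared" + (" (continuity-corrected)" if correction else ""),
        {
            "b": b,
            "c": c,
            "chi2_statistic": float(res_chi2.statistic),
            "chi2_p": float(res_chi2.pvalue),
            "exact_p": float(res_exact.pvalue),
        },
    )
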