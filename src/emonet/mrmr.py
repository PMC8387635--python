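"""Max-relevance min-redundancy (mRMR) feature selection.

Relevance of a candidate set S for class label c is the mean mutual
information D(S, c) = (1/|S|) Σ I(f_i; c); redundancy is the mean pairwise
mutual information R(S) = (1/|S|²) Σ I(f_i; f_j). The greedy incremental
rule implemented here is the standard first-order optimisation of the two:
step 1 picks argmax I(f; c), and step k picks

    argmax_f  I(f; c) − (1/|S|) Σ_{s in S} I(f; s)        (difference, MID)

with the quotient form I(f;c) / ((1/|S|) Σ I(f;s)) available as ``miq``.
Continuous connectivity features are discretized by equal-frequency binning
(3 bins by default, the convention of the original mRMR formulation) and
mutual information is the plug-in estimate on empirical joint counts, in
bits. Ties break toward the lowest feature index, making the selection
fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeError

__all__ = ["mutual_information", "discretize_equal_frequency",
           "mrmr_select", "SelectionResult"]


def _codes(v: np.ndarray) -> tuple[np.ndarray, int]:
    """Map arbitrary discrete values to consecutive integer codes."""
    _, codes = np.unique(np.asarray(v), return_inverse=True)
    return codes.astype(np.intp), int(codes.max()) + 1 if codes.size else 0


def mutual_information(x, y) -> float:
    """Plug-in mutual information of two discrete sequences, in bits."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.shape != y.shape:
        raise ShapeError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.size < 2:
        raise ShapeError("need at least 2 observations")
    xc, kx = _codes(x)
    yc, ky = _codes(y)
    joint = np.bincount(xc * ky + yc, minlength=kx * ky).reshape(kx, ky)
    return _mi_from_counts(joint[None, :, :])[0]


def _mi_from_counts(joint: np.ndarray) -> np.ndarray:
    """MI in bits from a stack of joint count tables (p x kx x ky)."""
    n = joint.sum(axis=(1, 2), keepdims=True).astype(float)
    p = joint / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * (np.log2(p) - np.log2(px) - np.log2(py))
    return np.where(joint > 0, terms, 0.0).sum(axis=(1, 2))


def discretize_equal_frequency(X: np.ndarray, bins: int = 3) -> np.ndarray:
    """Column-wise equal-frequency quantile binning to integer codes 0..bins-1."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if bins < 2:
        raise ValueError("need at least 2 bins")
    qs = np.quantile(X, np.arange(1, bins) / bins, axis=0)  # (bins-1, p)
    codes = np.empty(X.shape, dtype=np.intp)
    for j in range(X.shape[1]):
        codes[:, j] = np.searchsorted(qs[:, j], X[:, j], side="right")
    return codes


def _mi_all_columns(codes: np.ndarray, n_bins: int,
                    yc: np.ndarray, ky: int) -> np.ndarray:
    """I(column_j; y) for every column of an integer-coded matrix, in bits."""
    n, p = codes.shape
    idx = codes * ky + yc[:, None] + np.arange(p) * (n_bins * ky)
    joint = np.bincount(idx.ravel(), minlength=p * n_bins * ky)
    return _mi_from_counts(joint.reshape(p, n_bins, ky))


@dataclass
class SelectionResult:
    """Ordered greedy selection with its per-step diagnostics."""

    selected: list[int]
    relevance: list[float]       # I(f_k; c) of each pick
    redundancy: list[float]      # mean I(f_k; f_s) over prior picks (0 for k=1)
    score_trace: list[float]     # greedy objective value of each pick
    feature_names: list[str] | None = None
    criterion: str = "mid"
    bins: int = 3
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"selected": [int(i) for i in self.selected],
             "relevance_bits": [float(v) for v in self.relevance],
             "redundancy_bits": [float(v) for v in self.redundancy],
             "score_trace": [float(v) for v in self.score_trace],
             "criterion": self.criterion,
             "bins": self.bins}
        if self.feature_names is not None:
            d["selected_names"] = [self.feature_names[i] for i in self.selected]
        return d


def mrmr_select(X: np.ndarray, y: np.ndarray, m: int = 10, *,
                bins: int = 3, criterion: str = "mid",
                feature_names: list[str] | None = None,
                discretize: bool = True) -> SelectionResult:
    """Greedy mRMR selection of ``m`` features.

    ``X`` holds continuous features (discretized internally) or, with
    ``discretize=False``, pre-binned integer codes. Deterministic: ties
    break toward the lowest column index.
    """
    X = np.asarray(X)
    y = np.asarray(y).ravel()
    if X.ndim != 2:
        raise ShapeError("feature matrix must be 2-D")
    if X.shape[0] != y.size:
        raise ShapeError(f"{X.shape[0]} rows vs {y.size} labels")
    if m < 1:
        raise ValueError("m must be >= 1")
    if criterion not in ("mid", "miq"):
        raise ValueError(f"unknown criterion {criterion!r}")
    n, p = X.shape
    if m > p:
        warnings.warn(f"m={m} > {p} features; selecting all", stacklevel=2)
        m = p
    codes = discretize_equal_frequency(X, bins) if discretize else X.astype(np.intp)
    n_bins = int(codes.max()) + 1
    yc, ky = _codes(y)

    relevance_all = _mi_all_columns(codes, n_bins, yc, ky)
    selected: list[int] = []
    red_sum = np.zeros(p)
    relevance, redundancy, trace = [], [], []
    remaining = np.ones(p, dtype=bool)
    for step in range(m):
        if step == 0:
            score = relevance_all.copy()
            mean_red = np.zeros(p)
        else:
            mean_red = red_sum / len(selected)
            if criterion == "mid":
                score = relevance_all - mean_red
            else:  # miq: guard the zero-redundancy denominator
                score = relevance_all / np.maximum(mean_red, 1e-12)
        score = np.where(remaining, score, -np.inf)
        # ties (including float-level near-ties between equivalent joint
        # tables) break toward the lowest feature index
        pick = int(np.flatnonzero(score >= score.max() - 1e-9)[0])
        selected.append(pick)
        relevance.append(float(relevance_all[pick]))
        redundancy.append(float(mean_red[pick]))
        trace.append(float(score[pick]))
        remaining[pick] = False
        if step < m - 1:
            pc, pk = _codes(codes[:, pick])
            red_sum += _mi_all_columns(codes, n_bins, pc, pk)
    return SelectionResult(selected, relevance, redundancy, trace,
                           feature_names, criterion, bins)
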