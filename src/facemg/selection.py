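"""Mutual information and feature ranking (mRMR and recognition accuracy).

Mutual information is estimated with an equal-width histogram: each
continuous variable is discretized into ``bins`` bins over its own range and

    MI(A;B) = sum_{a,b} p(a,b) log2( p(a,b) / (p(a) p(b)) )

is evaluated over the non-empty cells of the joint histogram, in bits.  A
normalized variant divides by sqrt(H(A) H(B)), giving 1 for a variable with
itself; the normalized form is what feature-correlation matrices display,
while the raw form feeds the mRMR criterion.

mRMR (minimum redundancy, maximum relevance) scores a feature set A against
a class variable C by the difference between its mean relevance

    D(A, C) = (1/|A|)   sum_{f in A} MI(f; C)

and its mean pairwise redundancy

    R(A) = (1/|A|^2) sum_{f_i, f_j in A} MI(f_i; f_j),

and seeks max_A (D - R).  The set-level maximization is combinatorial, so
the canonical greedy incremental scheme is used: the first feature maximizes
relevance, and each subsequent feature f maximizes
MI(f; C) - (1/|S|) sum_{s in S} MI(f; s) over the already-selected set S.

RA ranking simply orders features by their individual classification test
accuracy, best first.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from facemg.features import FeatureSet

__all__ = [
    "MIMatrix",
    "RankingResult",
    "mutual_information",
    "class_mutual_information",
    "mi_matrix",
    "feature_class_relevance",
    "mrmr_rank",
    "ra_rank",
]


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width binning of a vector over its own range.

    A constant vector lands entirely in bin 0.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        return np.zeros(x.size, dtype=np.intp)
    edges = np.linspace(lo, hi, bins + 1)
    idx = np.searchsorted(edges, x, side="right") - 1
    return np.clip(idx, 0, bins - 1)


def _mi_from_joint(joint: np.ndarray) -> tuple[float, float, float]:
    """(MI, H(A), H(B)) in bits from a joint count table.

    Marginals are formed from the integer counts (exact sums) and the MI
    sum uses exact order-independent accumulation, so that
    MI(A;B) == MI(B;A) bit-for-bit despite the transposed joint table.
    """
    total = joint.sum()
    p = joint / total
    pa = joint.sum(axis=1) / total
    pb = joint.sum(axis=0) / total
    nz = p > 0
    outer = np.outer(pa, pb)
    mi = math.fsum((p[nz] * np.log2(p[nz] / outer[nz])).tolist())
    ha = float(-np.sum(pa[pa > 0] * np.log2(pa[pa > 0])))
    hb = float(-np.sum(pb[pb > 0] * np.log2(pb[pb > 0])))
    return max(mi, 0.0), ha, hb


def _joint_counts(ia: np.ndarray, ib: np.ndarray, na: int, nb: int) -> np.ndarray:
    flat = ia * nb + ib
    return np.bincount(flat, minlength=na * nb).reshape(na, nb).astype(float)


def mutual_information(
    a: np.ndarray,
    b: np.ndarray,
    bins: int = 10,
    normalized: bool = False,
) -> float:
    """Histogram mutual information between two sample vectors, in bits.

    With ``normalized=True`` the result is MI / sqrt(H(A) H(B)); a pair of
    zero-entropy (constant) vectors normalizes to 1, and a single constant
    vector against a varying one gives 0 (both with a warning, since
    normalization is undefined there).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    ia = _discretize(a, bins)
    ib = _discretize(b, bins)
    mi, ha, hb = _mi_from_joint(_joint_counts(ia, ib, bins, bins))
    if not normalized:
        return mi
    if ha == 0.0 and hb == 0.0:
        warnings.warn("both vectors constant; normalized MI defined as 1")
        return 1.0
    denom = np.sqrt(ha * hb)
    if denom == 0.0:
        warnings.warn("one vector constant; normalized MI defined as 0")
        return 0.0
    return mi / denom


def class_mutual_information(
    x: np.ndarray, labels: np.ndarray, bins: int = 10
) -> float:
    """Raw MI (bits) between a binned continuous feature and a class label.

    The label is treated as its own categorical variable (no binning).
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if x.size != labels.size:
        raise ValueError("length mismatch between feature and labels")
    ix = _discretize(x, bins)
    _, ic = np.unique(labels, return_inverse=True)
    nc = int(ic.max()) + 1
    mi, _, _ = _mi_from_joint(_joint_counts(ix, ic, bins, nc))
    return mi


@dataclass
class MIMatrix:
    """Symmetric matrix of pairwise feature MI, optionally subject-averaged."""

    values: pd.DataFrame
    normalized: bool
    bins: int
    subjects_averaged: int = 1

    def to_csv(self, path) -> None:
        self.values.to_csv(path)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = pair
        return float(self.values.loc[i, j])


def _feature_vector(fs: FeatureSet) -> np.ndarray:
    """Concatenate a feature's channels (channel blocks, ch1 then ch2 ...)."""
    return fs.matrix.ravel(order="F")


def mi_matrix(
    single_sets: Mapping[str, FeatureSet] | Sequence[Mapping[str, FeatureSet]],
    bins: int = 10,
    normalized: bool = True,
) -> MIMatrix:
    """Pairwise MI between single features, averaged over subjects.

    ``single_sets`` is one subject's ``{feature: FeatureSet}`` mapping or a
    sequence of them (one per subject).  Per subject each feature's channels
    are concatenated into one vector before pairwise MI.
    """
    if isinstance(single_sets, Mapping):
        per_subject = [single_sets]
    else:
        per_subject = list(single_sets)
    if not per_subject:
        raise ValueError("no feature sets given")
    names = list(per_subject[0].keys())
    if len(names) < 2:
        raise ValueError("need at least 2 feature sets")
    acc = np.zeros((len(names), len(names)))
    for sets in per_subject:
        if list(sets.keys()) != names:
            raise ValueError("subjects disagree on feature names")
        vecs = {}
        ref_rows = None
        for name in names:
            fs = sets[name]
            if ref_rows is None:
                ref_rows = fs.n_rows
            elif fs.n_rows != ref_rows:
                raise ValueError("feature sets have mismatched row counts")
            vecs[name] = _feature_vector(fs)
        for i, a in enumerate(names):
            acc[i, i] += 1.0
            for j in range(i + 1, len(names)):
                v = mutual_information(vecs[a], vecs[names[j]], bins, normalized)
                acc[i, j] += v
                acc[j, i] += v
    acc /= len(per_subject)
    return MIMatrix(
        values=pd.DataFrame(acc, index=names, columns=names),
        normalized=normalized,
        bins=bins,
        subjects_averaged=len(per_subject),
    )


def feature_class_relevance(
    single_sets: Mapping[str, FeatureSet] | Sequence[Mapping[str, FeatureSet]],
    bins: int = 10,
) -> dict[str, float]:
    """Raw MI between each feature and the gesture label, subject-averaged."""
    if isinstance(single_sets, Mapping):
        per_subject = [single_sets]
    else:
        per_subject = list(single_sets)
    names = list(per_subject[0].keys())
    rel = {n: 0.0 for n in names}
    for sets in per_subject:
        for name in names:
            fs = sets[name]
            labels = np.tile(fs.row_labels, fs.n_columns)
            rel[name] += class_mutual_information(_feature_vector(fs), labels, bins)
    return {n: v / len(per_subject) for n, v in rel.items()}


@dataclass
class RankingResult:
    """Ordered feature names with the per-step criterion values."""

    order: tuple[str, ...]
    scores: pd.DataFrame
    criterion: str

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "order": list(self.order),
            "scores": self.scores.to_dict(orient="list"),
        }


def mrmr_rank(
    relevance: Mapping[str, float],
    redundancy: pd.DataFrame | MIMatrix,
) -> RankingResult:
    """Greedy incremental mRMR ordering of all candidate features.

    The recorded scores give, for each prefix set A of the ordering, the
    set-level relevance D(A,C), redundancy R(A) (including self-MI diagonal
    terms, as the set formula prescribes) and the criterion D - R.
    """
    red = redundancy.values if isinstance(redundancy, MIMatrix) else redundancy
    candidates = sorted(relevance)
    if not candidates:
        raise ValueError("empty candidate set")
    missing = [c for c in candidates if c not in red.index or c not in red.columns]
    if missing:
        raise ValueError(f"redundancy matrix missing features: {missing}")

    selected: list[str] = []
    remaining = list(candidates)
    step_gain: list[float] = []
    while remaining:
        if not selected:
            scores = {f: relevance[f] for f in remaining}
        else:
            scores = {
                f: relevance[f]
                - float(np.mean([red.loc[f, s] for s in selected]))
                for f in remaining
            }
        # highest score wins; ties broken alphabetically
        best = min(remaining, key=lambda f: (-scores[f], f))
        step_gain.append(scores[best])
        selected.append(best)
        remaining.remove(best)

    d_vals, r_vals = [], []
    for k in range(1, len(selected) + 1):
        prefix = selected[:k]
        d_vals.append(float(np.mean([relevance[f] for f in prefix])))
        r_vals.append(
            float(
                np.mean(
                    [red.loc[fi, fj] for fi in prefix for fj in prefix]
                )
            )
        )
    scores_df = pd.DataFrame(
        {
            "feature": selected,
            "step_gain": step_gain,
            "D": d_vals,
            "R": r_vals,
            "D_minus_R": [d - r for d, r in zip(d_vals, r_vals)],
        }
    )
    return RankingResult(order=tuple(selected), scores=scores_df, criterion="MRMR")


def ra_rank(per_feature_accuracies: Mapping[str, float]) -> RankingResult:
    """Rank features by individual recognition accuracy, best first.

    Ties are broken alphabetically so the ordering is deterministic.
    """
    if not per_feature_accuracies:
        raise ValueError("empty accuracy map")
    order = sorted(
        per_feature_accuracies, key=lambda f: (-per_feature_accuracies[f], f)
    )
    scores_df = pd.DataFrame(
        {
            "feature": order,
            "accuracy": [per_feature_accuracies[f] for f in order],
        }
    )
    return RankingResult(order=tuple(order), scores=scores_df, criterion="RA")
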