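"""Experiment orchestration: splits, normalization, evaluation, reports.

Reproduces the full study design on synthetic data: for every subject and
every single time-domain feature, the 390-row feature set is shuffled,
split 300/90 into train/test, min-max normalized to the unit cube (so the
classifier's 0.5-radius initial neurons are meaningful), classified with a
one-epoch VEBF network, and scored (train/test accuracy, mean absolute
error = 100 - test accuracy, per-gesture accuracy, row-stochastic confusion
matrix in percent, training time).  Features are then ranked by mRMR and by
recognition accuracy, and the k-feature combinations (k = 2..10) built from
each ranking are evaluated the same way.
"""

from __future__ import annotations

import time
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from facemg.features import (
    FEATURE_NAMES,
    FeatureConfig,
    FeatureSet,
    build_all_feature_sets,
    combine_feature_sets,
)
from facemg.preprocess import DEFAULT_BAND, DEFAULT_WINDOW_MS
from facemg.selection import (
    feature_class_relevance,
    mi_matrix,
    mrmr_rank,
    ra_rank,
)
from facemg.synthetic import (
    SimulationConfig,
    default_profiles,
    generate_dataset,
)
from facemg.vebf import Network, TrainConfig, train_one_pass

__all__ = [
    "SplitSpec",
    "EvaluationReport",
    "ExperimentConfig",
    "minmax_normalize",
    "stratified_split",
    "evaluate",
    "train_and_evaluate",
    "run_experiment",
]


def _label_key(label) -> tuple:
    s = str(label)
    return (len(s), s)  # natural order for G1..G10


@dataclass(frozen=True)
class SplitSpec:
    """Shuffled train/test split sizes (default 300/90 of the 390 rows)."""

    n_train: int = 300
    n_test: int = 90
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("n_train and n_test must be positive")


def _largest_remainder(quota: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to ``quota`` summing to ``total``."""
    exact = quota / quota.sum() * total
    base = np.floor(exact).astype(int)
    short = total - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:short]] += 1
    return base


def stratified_split(features: FeatureSet, spec: SplitSpec) -> tuple[FeatureSet, FeatureSet]:
    """Seeded shuffle then split; stratification preserves class proportions.

    Train and test are disjoint; with a balanced 390-row, 10-class set and
    the default 300/90 split, every class contributes exactly 30 train and
    9 test rows.  The returned train rows are in shuffled (class-mixed)
    order, which is the order the one-pass classifier consumes.
    """
    n = features.n_rows
    if spec.n_train + spec.n_test > n:
        raise ValueError(
            f"n_train + n_test = {spec.n_train + spec.n_test} exceeds {n} rows"
        )
    rng = np.random.default_rng(spec.seed)
    if not spec.stratified:
        perm = rng.permutation(n)
        train_idx = perm[: spec.n_train]
        test_idx = perm[spec.n_train : spec.n_train + spec.n_test]
        return features.select_rows(train_idx), features.select_rows(test_idx)

    classes = sorted(set(features.row_labels.tolist()), key=_label_key)
    counts = np.array([np.sum(features.row_labels == c) for c in classes])
    if spec.n_train < len(classes):
        raise ValueError("stratified split needs n_train >= number of classes")
    n_train_c = _largest_remainder(counts, spec.n_train)
    remaining = counts - n_train_c
    n_test_c = _largest_remainder(remaining, spec.n_test)
    n_test_c = np.minimum(n_test_c, remaining)

    train_parts, test_parts = [], []
    for c, ntr, nte in zip(classes, n_train_c, n_test_c):
        idx = np.flatnonzero(features.row_labels == c)
        idx = rng.permutation(idx)
        train_parts.append(idx[:ntr])
        test_parts.append(idx[ntr : ntr + nte])
    train_idx = rng.permutation(np.concatenate(train_parts))
    test_idx = rng.permutation(np.concatenate(test_parts))
    return features.select_rows(train_idx), features.select_rows(test_idx)


def minmax_normalize(
    train: FeatureSet, test: FeatureSet
) -> tuple[FeatureSet, FeatureSet, dict]:
    """Column-wise min-max scaling fitted on the training set.

    Each column maps v -> (v - min_train) / (max_train - min_train); a
    constant training column maps to 0.0 everywhere (with a warning), and
    test values may land outside [0, 1] (no clipping).  The scaler record
    (per-column min/max) is returned for reuse.
    """
    if train.n_rows == 0:
        raise ValueError("empty training set")
    if train.column_meta != test.column_meta:
        raise ValueError("train and test column metadata differ")
    lo = train.matrix.min(axis=0)
    hi = train.matrix.max(axis=0)
    span = hi - lo
    degenerate = span == 0
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} constant training column(s) mapped to 0.0"
        )
    safe = np.where(degenerate, 1.0, span)

    def _apply(fs: FeatureSet) -> FeatureSet:
        m = (fs.matrix - lo) / safe
        m[:, degenerate] = 0.0
        return FeatureSet(m, fs.row_labels.copy(), list(fs.column_meta), fs.subject)

    scaler = {
        "columns": train.column_names,
        "min": lo.tolist(),
        "max": hi.tolist(),
    }
    return _apply(train), _apply(test), scaler


@dataclass
class EvaluationReport:
    """Classification metrics for one feature (or combination) on one split."""

    feature_label: str
    test_accuracy: float
    mean_absolute_error: float
    per_gesture_accuracy: dict
    confusion: pd.DataFrame  # row-stochastic, percent
    train_accuracy: float | None = None
    training_time: float | None = None  # seconds, informational only
    n_neurons: int | None = None

    def to_dict(self, include_timing: bool = True) -> dict:
        d = {
            "feature_label": self.feature_label,
            "train_accuracy": self.train_accuracy,
            "test_accuracy": self.test_accuracy,
            "mean_absolute_error": self.mean_absolute_error,
            "per_gesture_accuracy": dict(self.per_gesture_accuracy),
            "confusion": {
                str(r): {str(c): float(v) for c, v in row.items()}
                for r, row in self.confusion.iterrows()
            },
            "n_neurons": self.n_neurons,
        }
        if include_timing:
            d["training_time"] = self.training_time
        return d


def _confusion_percent(
    y_true: Sequence, y_pred: Sequence, classes: Sequence
) -> pd.DataFrame:
    classes = list(classes)
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)))
    for t, p in zip(y_true, y_pred):
        counts[idx[t], idx[p]] += 1
    row_tot = counts.sum(axis=1, keepdims=True)
    row_tot[row_tot == 0] = 1.0
    return pd.DataFrame(100.0 * counts / row_tot, index=classes, columns=classes)


def evaluate(
    network: Network, test: FeatureSet, feature_label: str = ""
) -> EvaluationReport:
    """Score a trained network on a labeled test feature set."""
    if test.n_rows == 0:
        raise ValueError("empty test set")
    missing = set(map(str, test.row_labels.tolist())) - set(map(str, network.classes))
    if missing:
        raise ValueError(f"network has no neurons for classes {sorted(missing)}")
    y_true = test.row_labels.tolist()
    y_pred = network.predict_batch(test.matrix).tolist()
    classes = sorted(set(map(str, network.classes)) | set(map(str, y_true)), key=_label_key)
    correct = sum(str(t) == str(p) for t, p in zip(y_true, y_pred))
    acc = 100.0 * correct / len(y_true)
    confusion = _confusion_percent(
        [str(t) for t in y_true], [str(p) for p in y_pred], classes
    )
    per_gesture = {
        c: float(confusion.loc[c, c])
        for c in classes
        if str(c) in set(map(str, y_true))
    }
    return EvaluationReport(
        feature_label=feature_label or "",
        test_accuracy=acc,
        mean_absolute_error=100.0 - acc,
        per_gesture_accuracy=per_gesture,
        confusion=confusion,
        n_neurons=len(network.neurons),
    )


def train_and_evaluate(
    features: FeatureSet,
    split: SplitSpec,
    train_config: TrainConfig = TrainConfig(),
    feature_label: str = "",
) -> EvaluationReport:
    """Split, normalize, train one epoch, and score train and test sets."""
    train_fs, test_fs = stratified_split(features, split)
    train_n, test_n, _ = minmax_normalize(train_fs, test_fs)
    t0 = time.perf_counter()
    network = train_one_pass(train_n.matrix, train_n.row_labels.tolist(), train_config)
    elapsed = time.perf_counter() - t0
    report = evaluate(network, test_n, feature_label)
    train_pred = network.predict_batch(train_n.matrix).tolist()
    train_correct = sum(
        str(t) == str(p) for t, p in zip(train_n.row_labels.tolist(), train_pred)
    )
    report.train_accuracy = 100.0 * train_correct / train_n.n_rows
    report.training_time = elapsed
    return report


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to rerun the full multi-subject experiment."""

    n_subjects: int = 10
    features: tuple[str, ...] = FEATURE_NAMES
    seed: int = 0
    class_separation: float = 1.0
    noise_floor: float = 0.02
    band: tuple[float, float] = DEFAULT_BAND
    window_ms: float = DEFAULT_WINDOW_MS
    ssc_epsilon: float = 0.02
    bins: int = 10
    n_train: int = 300
    n_test: int = 90
    stratified: bool = True
    initial_width: float = 0.5
    merge_enabled: bool = True
    merge_gamma: float = 1.0
    criteria: tuple[str, ...] = ("MRMR", "RA")
    k_range: tuple[int, ...] = tuple(range(2, 11))

    def __post_init__(self) -> None:
        unknown = [f for f in self.features if f.upper() not in FEATURE_NAMES]
        if unknown:
            raise ValueError(f"unknown feature names in config: {unknown}")
        bad = [c for c in self.criteria if c.upper() not in ("MRMR", "RA")]
        if bad:
            raise ValueError(f"unknown ranking criteria: {bad}")


def _derived_seed(*parts) -> int:
    """Stable sub-seed below 2**31 from arbitrary labeled parts."""
    acc = 0
    for p in parts:
        acc = zlib.crc32(str(p).encode(), acc)
    return acc & 0x7FFFFFFF


def _averaged(reports: list[EvaluationReport], label: str) -> dict:
    test = np.array([r.test_accuracy for r in reports])
    train = np.array([r.train_accuracy for r in reports])
    classes = list(reports[0].confusion.index)
    mean_conf = sum(r.confusion.loc[classes, classes] for r in reports) / len(reports)
    per_gesture = {c: float(mean_conf.loc[c, c]) for c in classes}
    return {
        "feature_label": label,
        "mean_train_accuracy": float(train.mean()),
        "mean_test_accuracy": float(test.mean()),
        "sd_test_accuracy": float(test.std(ddof=1)) if len(reports) > 1 else 0.0,
        "mean_absolute_error": float(100.0 - test.mean()),
        "per_gesture_accuracy": per_gesture,
        "mean_confusion": {
            str(r): {str(c): float(v) for c, v in row.items()}
            for r, row in mean_conf.iterrows()
        },
        "mean_training_time": float(np.mean([r.training_time for r in reports])),
        "per_subject_test_accuracy": [float(v) for v in test],
    }


def run_experiment(config: ExperimentConfig = ExperimentConfig()) -> dict:
    """Run the full study on synthetic data and return the report bundle.

    For each synthetic subject: generate the dataset, extract every single
    feature, train/evaluate per feature; then rank features by RA (mean
    test accuracy) and mRMR (MI quantities averaged over subjects), build
    the k-feature combinations per ranking and evaluate them the same way.
    Deterministic given the config (timing fields aside).
    """
    features = tuple(f.upper() for f in config.features)
    feat_cfg = FeatureConfig(ssc_epsilon=config.ssc_epsilon)
    train_cfg = TrainConfig(
        initial_width=config.initial_width,
        merge_enabled=config.merge_enabled,
        merge_gamma=config.merge_gamma,
        seed=config.seed,
    )
    subjects = [f"S{i + 1}" for i in range(config.n_subjects)]
    profiles = default_profiles()

    sets_by_subject: list[dict[str, FeatureSet]] = []
    for subject in subjects:
        sim = SimulationConfig(
            noise_floor=config.noise_floor,
            class_separation=config.class_separation,
            seed=config.seed,
            band=config.band,
        )
        dataset = generate_dataset(profiles, sim, subject)
        sets_by_subject.append(
            build_all_feature_sets(
                dataset,
                feat_cfg,
                features=features,
                window_ms=config.window_ms,
                band=config.band,
            )
        )

    def _split(subject: str, label: str) -> SplitSpec:
        return SplitSpec(
            n_train=config.n_train,
            n_test=config.n_test,
            stratified=config.stratified,
            seed=_derived_seed(config.seed, subject, label),
        )

    single: dict[str, dict] = {}
    per_subject_reports: dict[str, list[EvaluationReport]] = {f: [] for f in features}
    for subject, sets in zip(subjects, sets_by_subject):
        for f in features:
            rep = train_and_evaluate(
                sets[f], _split(subject, f), train_cfg, feature_label=f
            )
            per_subject_reports[f].append(rep)
    for f in features:
        single[f] = _averaged(per_subject_reports[f], f)
        single[f]["per_subject"] = [
            r.to_dict() for r in per_subject_reports[f]
        ]

    rankings: dict[str, dict] = {}
    orders: dict[str, tuple[str, ...]] = {}
    if "RA" in [c.upper() for c in config.criteria]:
        ra = ra_rank({f: single[f]["mean_test_accuracy"] for f in features})
        rankings["RA"] = ra.to_dict()
        orders["RA"] = ra.order
    if "MRMR" in [c.upper() for c in config.criteria]:
        relevance = feature_class_relevance(sets_by_subject, bins=config.bins)
        redundancy = mi_matrix(sets_by_subject, bins=config.bins, normalized=False)
        mrmr = mrmr_rank(relevance, redundancy.values)
        rankings["MRMR"] = mrmr.to_dict()
        orders["MRMR"] = mrmr.order
    nmi = mi_matrix(sets_by_subject, bins=config.bins, normalized=True)

    combinations: dict[str, dict] = {}
    for crit, order in orders.items():
        combinations[crit] = {}
        for k in config.k_range:
            if k > len(order):
                continue
            label = f"C{k}[{crit}]"
            reports = []
            for subject, sets in zip(subjects, sets_by_subject):
                combo = combine_feature_sets(sets, order, k)
                reports.append(
                    train_and_evaluate(
                        combo, _split(subject, label), train_cfg, feature_label=label
                    )
                )
            entry = _averaged(reports, label)
            entry["features"] = list(order[:k])
            combinations[crit][f"C{k}"] = entry

    return {
        "config": asdict(config),
        "subjects": subjects,
        "single": single,
        "rankings": rankings,
        "mi_matrix": {
            "normalized": True,
            "bins": config.bins,
            "values": {
                str(r): {str(c): float(v) for c, v in row.items()}
                for r, row in nmi.values.iterrows()
            },
        },
        "combinations": combinations,
    }


def bundle_to_json(bundle: dict, include_timing: bool = False) -> str:
    """Serialize a report bundle; timing fields stripped by default so that
    identical configs produce byte-identical output."""
    import json

    def _strip(obj):
        if isinstance(obj, dict):
            return {
                k: _strip(v)
                for k, v in obj.items()
                if include_timing or "time" not in str(k)
            }
        if isinstance(obj, list):
            return [_strip(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return json.dumps(_strip(bundle), indent=2, sort_keys=True)
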