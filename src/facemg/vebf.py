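"""Versatile elliptic basis function neural network (VEBFNN).

A one-epoch incremental classifier.  Each hidden unit ("neuron") is a
hyperellipsoid with center C, per-axis widths A = (a_1..a_d) and an
orientation given by the orthonormal eigenbasis {u_i} of the covariance of
the samples it has absorbed.  Its activation at x is

    psi(x) = sum_i ((x - C)^T u_i)^2 / a_i^2  -  1,

so psi <= 0 means the ellipsoid covers x (psi = -1 exactly at the center).

Training is a single ordered pass.  For each labeled sample the nearest
same-class neuron (Euclidean center distance) is tentatively updated — its
mean and covariance absorb the sample through exact recursive (streaming)
moment updates, and the eigenbasis is refreshed — and the update is
committed only if the updated neuron covers the sample (psi <= 0);
otherwise a fresh neuron is created at the sample.  Widths stay fixed at
the initial radius throughout: coverage grows by basis rotation, not by
inflation.  An optional merging step pools same-class neurons whose centers
come close, keeping the network compact.  Each sample is touched exactly
once and then discarded, which makes training both fast and suitable for
online use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Neuron",
    "Network",
    "TrainConfig",
    "activation",
    "update_mean",
    "update_covariance",
    "orthonormal_basis",
    "train_one_pass",
    "merge_neurons",
    "predict",
]

_SYM_TOL = 1e-8


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    initial_width
        Radius of the initial hypersphere every new neuron starts with
        (0.5 by default, matched to min-max normalized inputs in [0, 1]).
    merge_enabled / merge_gamma
        Merging pools two same-class neurons whose center distance is at
        most ``merge_gamma`` times the sum of their mean widths.
    seed
        Recorded for provenance only; training itself is deterministic.
    """

    initial_width: float = 0.5
    merge_enabled: bool = True
    merge_gamma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_width <= 0:
            raise ValueError("initial_width must be positive")
        if self.merge_gamma < 0:
            raise ValueError("merge_gamma must be >= 0")


@dataclass(eq=False)
class Neuron:
    """One hyperellipsoid hidden unit Omega_k = (C, S, N, A, d)."""

    center: np.ndarray
    covariance: np.ndarray
    count: int
    widths: np.ndarray
    class_label: object
    basis: np.ndarray = field(default=None)  # columns are u_i
    eigenvalues: np.ndarray = field(default=None)
    creation_index: int = 0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.basis is None or self.eigenvalues is None:
            self.eigenvalues, self.basis = orthonormal_basis(self.covariance)
        else:
            self.basis = np.asarray(self.basis, dtype=float)
            self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if np.any(self.widths <= 0):
            raise ValueError("widths must be positive")
        if self.count < 1:
            raise ValueError("count must be >= 1")

    @property
    def dim(self) -> int:
        return self.center.size


@dataclass(eq=False)
class Network:
    """Ordered collection of neurons (order of creation) plus metadata."""

    neurons: list[Neuron]
    classes: tuple
    input_dim: int

    def predict(self, x: np.ndarray):
        return predict(x, self)

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([predict(x, self) for x in X], dtype=object)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "input_dim": self.input_dim,
            "classes": [str(c) for c in self.classes],
            "neurons": [
                {
                    "center": n.center.tolist(),
                    "covariance": n.covariance.tolist(),
                    "count": int(n.count),
                    "widths": n.widths.tolist(),
                    "class": str(n.class_label),
                    "creation_index": int(n.creation_index),
                }
                for n in self.neurons
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "Network":
        text = str(text_or_path)
        if "\n" not in text:  # a path, not serialized JSON
            p = Path(text)
            if p.exists():
                text = p.read_text()
        payload = json.loads(text)
        neurons = [
            Neuron(
                center=np.array(d["center"]),
                covariance=np.array(d["covariance"]),
                count=d["count"],
                widths=np.array(d["widths"]),
                class_label=d["class"],
                creation_index=d["creation_index"],
            )
            for d in payload["neurons"]
        ]
        return cls(
            neurons=neurons,
            classes=tuple(payload["classes"]),
            input_dim=payload["input_dim"],
        )


def activation(x: np.ndarray, neuron: Neuron) -> float:
    """Hyperellipsoid output psi(x); psi <= 0 means the neuron covers x."""
    x = np.asarray(x, dtype=float)
    if x.shape != neuron.center.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {neuron.center.shape}")
    proj = neuron.basis.T @ (x - neuron.center)
    return float(np.sum((proj / neuron.widths) ** 2) - 1.0)


def update_mean(mu_old: np.ndarray, n: int, x_new: np.ndarray) -> np.ndarray:
    """Streaming mean: mu_new = (n mu_old + x_new) / (n + 1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mu_old = np.asarray(mu_old, dtype=float)
    x_new = np.asarray(x_new, dtype=float)
    return (n / (n + 1.0)) * mu_old + x_new / (n + 1.0)


def update_covariance(
    tau_old: np.ndarray,
    mu_old: np.ndarray,
    mu_new: np.ndarray,
    n: int,
    x_new: np.ndarray,
) -> np.ndarray:
    """Streaming population covariance absorbing one sample.

    tau_new = (n/(n+1)) tau_old + theta, with
    theta = x x^T/(n+1) - mu_new mu_new^T + mu_old mu_old^T
            - mu_old mu_old^T/(n+1),
    which equals the batch population covariance of all n+1 samples seen.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    tau_old = np.asarray(tau_old, dtype=float)
    if not np.allclose(tau_old, tau_old.T, atol=_SYM_TOL):
        raise ValueError("tau_old is not symmetric")
    mu_old = np.asarray(mu_old, dtype=float)
    mu_new = np.asarray(mu_new, dtype=float)
    x_new = np.asarray(x_new, dtype=float)
    theta = (
        np.outer(x_new, x_new) / (n + 1.0)
        - np.outer(mu_new, mu_new)
        + np.outer(mu_old, mu_old)
        - np.outer(mu_old, mu_old) / (n + 1.0)
    )
    tau = (n / (n + 1.0)) * tau_old + theta
    return (tau + tau.T) / 2.0  # clamp numerical asymmetry


def orthonormal_basis(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenbasis of a symmetric PSD matrix, eigenvalues descending.

    Signs are fixed so each vector's largest-magnitude component is
    positive; for S = 0 this reduces to the standard basis.  ``eigh``
    always returns a complete orthonormal set, so rank-deficient matrices
    need no special completion.
    """
    S = np.asarray(S, dtype=float)
    if not np.all(np.isfinite(S)):
        raise ValueError("covariance contains non-finite entries")
    if not np.allclose(S, S.T, atol=_SYM_TOL):
        raise ValueError("covariance is not symmetric")
    if not S.any():
        d = S.shape[0]
        return np.zeros(d), np.eye(d)
    w, v = np.linalg.eigh((S + S.T) / 2.0)
    order = np.argsort(w, kind="stable")[::-1]
    w = w[order]
    v = v[:, order]
    for i in range(v.shape[1]):
        j = int(np.argmax(np.abs(v[:, i])))
        if v[j, i] < 0:
            v[:, i] = -v[:, i]
    return w, v


def _new_neuron(x: np.ndarray, label, config: TrainConfig, index: int) -> Neuron:
    d = x.size
    return Neuron(
        center=x.copy(),
        covariance=np.zeros((d, d)),
        count=1,
        widths=np.full(d, config.initial_width),
        class_label=label,
        creation_index=index,
    )


def merge_neurons(ni: Neuron, nj: Neuron, config: TrainConfig = TrainConfig()) -> Neuron:
    """Pool two same-class neurons into one.

    The merged neuron carries the batch mean and population covariance of
    the union of the samples both absorbed (exact moment pooling), widths
    reset to the initial radius, and the earlier creation index.
    """
    if ni.class_label != nj.class_label:
        raise ValueError("cannot merge neurons of different classes")
    if ni.dim != nj.dim:
        raise ValueError("dimension mismatch")
    n, m = ni.count, nj.count
    total = n + m
    mu = (n * ni.center + m * nj.center) / total
    # pooled second moment: E[xx^T] = S + mu mu^T per group
    second = (
        n * (ni.covariance + np.outer(ni.center, ni.center))
        + m * (nj.covariance + np.outer(nj.center, nj.center))
    ) / total
    cov = second - np.outer(mu, mu)
    cov = (cov + cov.T) / 2.0
    return Neuron(
        center=mu,
        covariance=cov,
        count=total,
        widths=np.full(ni.dim, config.initial_width),
        class_label=ni.class_label,
        creation_index=min(ni.creation_index, nj.creation_index),
    )


def _merge_pass(neurons: list[Neuron], new: Neuron, config: TrainConfig) -> list[Neuron]:
    """Try to merge the newest neuron with a close same-class neuron."""
    for i, other in enumerate(neurons):
        if other is new or other.class_label != new.class_label:
            continue
        dist = float(np.linalg.norm(other.center - new.center))
        gate = config.merge_gamma * (
            float(np.mean(other.widths)) + float(np.mean(new.widths))
        )
        if dist <= gate:
            merged = merge_neurons(other, new, config)
            out = [n for n in neurons if n is not other and n is not new]
            out.append(merged)
            out.sort(key=lambda n: n.creation_index)
            return out
    return neurons


def train_one_pass(
    samples: Sequence[np.ndarray] | np.ndarray,
    labels: Sequence,
    config: TrainConfig = TrainConfig(),
) -> Network:
    """Train a VEBF network in a single ordered pass over the data.

    Every sample is consumed exactly once.  The nearest same-class neuron
    is tentatively updated on copies of its statistics; the update is
    committed iff the refreshed ellipsoid covers the sample, otherwise a
    new neuron is created at the sample.  Deterministic for a fixed input
    order.
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    y = list(labels)
    if X.shape[0] != len(y):
        raise ValueError(f"{X.shape[0]} samples but {len(y)} labels")
    if X.shape[0] == 0:
        raise ValueError("need at least one training sample")

    neurons: list[Neuron] = []
    next_index = 0
    for x, t in zip(X, y):
        same_class = [n for n in neurons if n.class_label == t]
        if not same_class:
            new = _new_neuron(x, t, config, next_index)
            next_index += 1
            neurons.append(new)
            if config.merge_enabled:
                neurons = _merge_pass(neurons, new, config)
            continue
        # nearest same-class neuron by Euclidean center distance
        nearest = min(
            same_class,
            key=lambda n: (float(np.linalg.norm(x - n.center)), n.creation_index),
        )
        # tentative update on copies
        mu_new = update_mean(nearest.center, nearest.count, x)
        tau_new = update_covariance(
            nearest.covariance, nearest.center, mu_new, nearest.count, x
        )
        eigvals, basis = orthonormal_basis(tau_new)
        trial = Neuron(
            center=mu_new,
            covariance=tau_new,
            count=nearest.count + 1,
            widths=nearest.widths.copy(),
            class_label=t,
            basis=basis,
            eigenvalues=eigvals,
            creation_index=nearest.creation_index,
        )
        if activation(x, trial) <= 0:
            neurons[neurons.index(nearest)] = trial
        else:
            new = _new_neuron(x, t, config, next_index)
            next_index += 1
            neurons.append(new)
            if config.merge_enabled:
                neurons = _merge_pass(neurons, new, config)

    classes = tuple(dict.fromkeys(y))
    return Network(neurons=neurons, classes=classes, input_dim=X.shape[1])


def predict(x: np.ndarray, network: Network):
    """Class of the neuron with minimal psi(x); ties go to the earliest neuron."""
    if not network.neurons:
        raise ValueError("empty network")
    x = np.asarray(x, dtype=float)
    best = min(
        network.neurons,
        key=lambda n: (activation(x, n), n.creation_index),
    )
    return best.class_label
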