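"""Supervised spatial filtering for single-trial ERP detection (xDAWN).

The filter seeks channel-space directions w maximizing the ratio of evoked-
response power to total signal power,

    w* = argmax_w  (w' Se w) / (w' Sx w),

where Se is the covariance of the class-average (evoked) response of the
target class and Sx the covariance of the whole training signal.  Solved in
batch form as a symmetric-definite generalized eigenvalue problem with a
small ridge on Sx; components are ordered by decreasing objective value and
sign-fixed so the largest-magnitude loading is positive.  Applying the
filter is a plain matrix multiplication, reducing c channels to a few
virtual channels (four for both the P300 and the MRCP branch here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["SpatialFilterModel", "fit_xdawn", "apply_spatial_filter"]


@dataclass
class SpatialFilterModel:
    weights: np.ndarray       # (n_channels_in, n_components)
    eigenvalues: np.ndarray   # objective value per component, descending
    n_components: int
    training_meta: dict

    def save(self, path) -> None:
        np.savez(
            path,
            weights=self.weights,
            eigenvalues=self.eigenvalues,
            n_components=self.n_components,
        )

    @classmethod
    def load(cls, path) -> "SpatialFilterModel":
        d = np.load(path)
        return cls(
            d["weights"], d["eigenvalues"], int(d["n_components"]), {}
        )


def fit_xdawn(
    epochs,
    labels,
    target_label,
    n_components: int = 4,
    ridge: float = 1e-9,
) -> SpatialFilterModel:
    """Fit the spatial filter on labeled epochs.

    ``epochs`` is a sequence of (n_samples x n_channels) arrays with one
    label each; the evoked response is estimated as the plain average over
    epochs of ``target_label``.  Deterministic given input order.  A ridge
    proportional to ``ridge * tr(Sx)/c`` is always added to the total
    covariance; rank-deficient data therefore solves cleanly (with a warning
    if the ridge dominates).
    """
    import warnings

    epochs = [np.asarray(e, dtype=np.float64) for e in epochs]
    if not epochs:
        raise ValueError("no epochs")
    shape = epochs[0].shape
    if any(e.shape != shape for e in epochs):
        raise ValueError("all epochs must have the same shape")
    labels = list(labels)
    targets = [e for e, l in zip(epochs, labels) if l == target_label]
    if len(targets) < 2:
        raise ValueError("need >= 2 epochs of the target class")
    c = shape[1]
    if not (1 <= n_components <= c):
        raise ValueError("n_components must be in [1, n_channels]")

    evoked = np.mean(targets, axis=0)               # (n_samples, c)
    s_e = evoked.T @ evoked / evoked.shape[0]
    x_all = np.concatenate(epochs, axis=0)
    s_x = x_all.T @ x_all / x_all.shape[0]

    scale = np.trace(s_x) / c
    if scale <= 0:
        scale = 1.0
        warnings.warn("total covariance is zero; filter is arbitrary")
    eps = ridge * scale
    # guard against numerically singular Sx
    try:
        evals, evecs = linalg.eigh(s_e, s_x + eps * np.eye(c))
    except linalg.LinAlgError:
        warnings.warn("rank-deficient covariance; increasing regularization")
        eps = max(eps * 1e6, 1e-12 * scale)
        evals, evecs = linalg.eigh(s_e, s_x + eps * np.eye(c))

    order = np.argsort(evals)[::-1][:n_components]
    w = evecs[:, order]
    vals = evals[order]
    # reproducible sign: largest-magnitude loading positive
    for k in range(w.shape[1]):
        j = np.argmax(np.abs(w[:, k]))
        if w[j, k] < 0:
            w[:, k] = -w[:, k]
    return SpatialFilterModel(
        weights=w,
        eigenvalues=vals,
        n_components=n_components,
        training_meta={
            "n_epochs": len(epochs),
            "n_target": len(targets),
            "target_label": target_label,
            "ridge": eps,
        },
    )


def apply_spatial_filter(segment: np.ndarray, model: SpatialFilterModel) -> np.ndarray:
    """Project (n_samples x n_channels) data onto the filter components."""
    segment = np.asarray(segment, dtype=np.float64)
    if segment.ndim != 2 or segment.shape[1] != model.weights.shape[0]:
        raise ValueError(
            f"segment has shape {segment.shape}, filter expects "
            f"{model.weights.shape[0]} channels"
        )
    return segment @ model.weights
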