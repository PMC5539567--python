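"""Feature extraction and standardization for the ERP branches.

P300: each spatially filtered 1000 ms window (25 samples x 4 components) is
described by local straight-line features -- the least-squares slope of every
400 ms subsegment, shifted by 120 ms (6 subsegments per component, 24 values,
channel-major order, slopes in uV/s).  MRCP: the filtered 200 ms window
(5 x 4) is flattened channel-major into a 20-dimensional vector.  Both are
standardized element-wise with the training-set mean and sample standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StandardizationModel",
    "slope_projection",
    "local_straight_line_features",
    "flatten_mrcp",
    "fit_standardization",
    "standardize",
]


def slope_projection(
    n_samples: int = 25,
    sub_len_s: float = 0.400,
    shift_s: float = 0.120,
    fs: float = 25.0,
) -> np.ndarray:
    """Matrix Q (n_sub x n_samples) with Q @ x = per-subsegment LS slopes.

    The least-squares slope of samples x_i at times t_i is
    sum((t_i - tbar)(x_i - xbar)) / sum((t_i - tbar)^2), a linear functional
    of x; stacking one row per subsegment start (0, 120, ..., 600 ms) gives
    a single projection matrix applied to each component.
    """
    sub = int(round(sub_len_s * fs))
    shift = int(round(shift_s * fs))
    if sub < 2 or shift < 1 or sub > n_samples:
        raise ValueError("degenerate subsegment layout")
    n_sub = (n_samples - sub) // shift + 1
    t = np.arange(sub) / fs
    tc = t - t.mean()
    row = tc / (tc @ tc)          # slope weights for one subsegment
    q = np.zeros((n_sub, n_samples))
    for j in range(n_sub):
        q[j, j * shift : j * shift + sub] = row
    return q


def local_straight_line_features(
    segment: np.ndarray,
    sub_len_s: float = 0.400,
    shift_s: float = 0.120,
    fs: float = 25.0,
) -> np.ndarray:
    """24-dim slope features of a 25 x 4 filtered window (channel-major)."""
    segment = np.asarray(segment, dtype=np.float64)
    if segment.ndim != 2:
        raise ValueError("segment must be (n_samples, n_components)")
    q = slope_projection(segment.shape[0], sub_len_s, shift_s, fs)
    slopes = q @ segment          # (n_sub, n_components)
    return slopes.T.reshape(-1)   # channel-major: component 0's slopes first


def flatten_mrcp(segment: np.ndarray) -> np.ndarray:
    """Flatten a 5 x 4 filtered window channel-major into 20 values."""
    segment = np.asarray(segment, dtype=np.float64)
    if segment.ndim != 2:
        raise ValueError("segment must be (n_samples, n_components)")
    return segment.T.reshape(-1)


@dataclass
class StandardizationModel:
    """Element-wise training-set mean and sample std (sigma=0 -> 1)."""

    mu: np.ndarray
    sigma: np.ndarray

    def save(self, path) -> None:
        np.savez(path, mu=self.mu, sigma=self.sigma)

    @classmethod
    def load(cls, path) -> "StandardizationModel":
        d = np.load(path)
        return cls(d["mu"], d["sigma"])


def fit_standardization(vectors: np.ndarray) -> StandardizationModel:
    """Fit element-wise mean/std on training feature vectors (rows)."""
    import warnings

    x = np.asarray(vectors, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 training vectors")
    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=1)
    # constant features: sigma is zero up to rounding of the mean
    degenerate = sigma <= 1e-12 * np.maximum(1.0, np.abs(mu))
    if np.any(degenerate):
        warnings.warn("degenerate (constant) feature: sigma=0 replaced by 1")
        sigma = np.where(degenerate, 1.0, sigma)
    return StandardizationModel(mu, sigma)


def standardize(v: np.ndarray, model: StandardizationModel) -> np.ndarray:
    """(v - mu) / sigma element-wise; works on one vector or a batch."""
    v = np.asarray(v, dtype=np.float64)
    if v.shape[-1] != model.mu.shape[0]:
        raise ValueError("feature dimension mismatch")
    return (v - model.mu) / model.sigma
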