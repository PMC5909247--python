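"""sLORETA distributed inverse solution on the spherical source grid.

The minimum-norm kernel is T = K' (K K' + alpha H)^+ with K the
CAR-referenced lead field and H the average-reference centering operator
(the identity on the zero-mean sensor subspace).  The minimum-norm estimate
j_hat = T v is then standardized voxel-wise by the resolution matrix
R = T K: the reported activity is the quadratic form

    S_v = j_hat_v' (R_vv)^+ j_hat_v        (free 3D orientation)

which is dimensionless, non-negative, and has exactly zero localization
error for noiseless single-dipole data — the defining property of sLORETA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forward_model import LeadField, SourceGrid

__all__ = [
    "InverseConfig",
    "InverseOperator",
    "SourceImage",
    "compute_inverse_operator",
    "localize",
    "window_average",
]


@dataclass(frozen=True)
class InverseConfig:
    """Regularization (relative to mean sensor-covariance trace) and
    orientation handling."""

    alpha: float = 1e-3
    orientation: str = "free"  # {"free", "fixed-radial"}
    #: eigenvalue floor for pseudo-inverting the 3x3 resolution blocks,
    #: relative to each block's largest eigenvalue
    block_floor: float = 1e-10

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.orientation not in ("free", "fixed-radial"):
            raise ValueError("orientation must be 'free' or 'fixed-radial'")


@dataclass
class InverseOperator:
    kernel: np.ndarray       # (V*3, C) or (V, C) for fixed orientation
    resolution: np.ndarray   # (V, 3, 3) or (V,) diagonal for fixed
    resolution_pinv: np.ndarray
    labels: tuple[str, ...]
    grid: SourceGrid
    config: InverseConfig


@dataclass
class SourceImage:
    """Standardized (dimensionless, >= 0) activity per voxel."""

    values: np.ndarray  # (V,)
    grid: SourceGrid
    window_ms: tuple[float, float] | None = None

    @property
    def peak_voxel(self) -> int:
        return int(np.argmax(self.values))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.grid.positions, columns=["x_cm", "y_cm", "z_cm"])
        df.insert(0, "voxel", np.arange(self.grid.n_voxels))
        df["value"] = self.values
        return df


def _radial_gain(lf: LeadField) -> np.ndarray:
    """Collapse the 3-orientation gain to radial orientation per voxel."""
    pos = lf.grid.positions
    norm = np.linalg.norm(pos, axis=1)
    r_hat = np.where(norm[:, None] > 0, pos / np.maximum(norm, 1e-12)[:, None],
                     np.array([0.0, 0.0, 1.0]))
    return np.einsum("cvk,vk->cv", lf.gain, r_hat)


def compute_inverse_operator(leadfield: LeadField,
                             cfg: InverseConfig = InverseConfig()) -> InverseOperator:
    """Minimum-norm kernel with sLORETA resolution blocks.

    Requires a CAR-referenced lead field (the centering operator H is the
    natural regularization metric on average-referenced data).
    """
    if leadfield.reference != "CAR":
        raise ValueError("sLORETA requires a CAR-referenced lead field")
    if cfg.alpha < 0:
        raise ValueError("alpha must be >= 0")

    if cfg.orientation == "fixed-radial":
        K = _radial_gain(leadfield)  # (C, V)
    else:
        K = leadfield.gain2d  # (C, V*3)
    C = K.shape[0]
    H = np.eye(C) - np.ones((C, C)) / C
    gram = K @ K.T
    lam = cfg.alpha * np.trace(gram) / C
    # M = gram + lam*H is singular at least along the constant vector (CAR
    # null space): pseudo-invert by eigendecomposition with a relative
    # eigenvalue cutoff.
    w, Q = np.linalg.eigh(gram + lam * H)
    keep = w > 1e-12 * w.max()
    winv = np.where(keep, 1.0 / np.where(keep, w, 1.0), 0.0)
    M = (Q * winv) @ Q.T
    T = K.T @ M  # (V*3, C) or (V, C)

    V = leadfield.grid.n_voxels
    if cfg.orientation == "fixed-radial":
        R = np.einsum("vc,cv->v", T, K)  # scalar resolution per voxel
        floor = cfg.block_floor * np.max(R)
        with np.errstate(divide="ignore"):
            Rinv = np.where(R > floor, 1.0 / np.maximum(R, floor), 0.0)
    else:
        Tv = T.reshape(V, 3, C)
        Kv = np.transpose(K.reshape(C, V, 3), (1, 0, 2))  # (V, C, 3)
        R = np.einsum("vic,vcj->vij", Tv, Kv)  # (V, 3, 3)
        R = 0.5 * (R + np.transpose(R, (0, 2, 1)))
        Rinv = _block_pinv(R, cfg.block_floor)
    return InverseOperator(T, R, Rinv, leadfield.labels, leadfield.grid, cfg)


def _block_pinv(R: np.ndarray, rel_floor: float) -> np.ndarray:
    """Pseudo-inverse of symmetric 3x3 blocks with a relative eigenvalue floor."""
    w, Q = np.linalg.eigh(R)
    wmax = np.maximum(w[:, -1], 0.0)
    floor = rel_floor * np.maximum(wmax, 1e-300)[:, None]
    keep = w > floor
    winv = np.where(keep, 1.0 / np.where(keep, w, 1.0), 0.0)
    return np.einsum("vik,vk,vjk->vij", Q, winv, Q)


def localize(topography: np.ndarray, operator: InverseOperator,
             window_ms: tuple[float, float] | None = None) -> SourceImage:
    """Standardized source image of a CAR-referenced sensor topography."""
    v = np.asarray(topography, float)
    if v.shape != (len(operator.labels),):
        raise ValueError("topography length does not match operator channels")
    if operator.config.orientation == "fixed-radial":
        j = operator.kernel @ v  # (V,)
        values = j ** 2 * operator.resolution_pinv
    else:
        V = operator.grid.n_voxels
        j = (operator.kernel @ v).reshape(V, 3)
        values = np.einsum("vi,vij,vj->v", j, operator.resolution_pinv, j)
    return SourceImage(np.maximum(values, 0.0), operator.grid, window_ms)


def window_average(evoked, window_ms: tuple[float, float]) -> np.ndarray:
    """Mean over the window's samples per channel (closed interval)."""
    mask = evoked.time_mask(*window_ms)
    if not mask.any():
        raise ValueError("window contains no samples")
    return evoked.data[:, mask].mean(axis=1)
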