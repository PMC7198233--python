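"""Quadratic polynomial calibration between camera and projector coordinates.

Stimuli are designed in the camera frame and must be rendered by a projector
with its own pixel grid.  The two frames are related by a quadratic
polynomial map: for reference points ``(xcam, ycam) -> (xpro, ypro)`` we form
the n x 6 design matrix

    X = [1, x, y, x*x, x*y, y*y]

(elementwise products) and the n x 3 target matrix ``Y = [1, xpro, ypro]``,
then fit the 6 x 3 coefficient matrix ``T`` by least squares, ``Y = X T``.
The quadratic basis absorbs offsets, rotations, anisotropic scaling, and
mild nonlinear warping between the optical paths.

Coordinates are 0-based pixel indices with pixel centers on integers,
origin at the image top-left, x rightward, y downward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RefPointSet",
    "PolyMap",
    "DegenerateCalibrationError",
    "build_design_matrix",
    "fit_map",
    "apply_map",
]

#: relative singular-value cutoff below which the design is declared degenerate
RANK_RTOL = 1e-10

BASIS_NAME = "quad6"
N_BASIS = 6


class DegenerateCalibrationError(ValueError):
    """Raised when reference points cannot determine the quadratic map."""


def _as_finite_vector(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class RefPointSet:
    """Manually aligned reference-point pairs in camera and projector pixels."""

    cam_x: np.ndarray
    cam_y: np.ndarray
    pro_x: np.ndarray
    pro_y: np.ndarray

    def __post_init__(self):
        for name in ("cam_x", "cam_y", "pro_x", "pro_y"):
            object.__setattr__(self, name, _as_finite_vector(getattr(self, name), name))
        lengths = {len(self.cam_x), len(self.cam_y), len(self.pro_x), len(self.pro_y)}
        if len(lengths) != 1:
            raise ValueError(f"reference vectors have mismatched lengths: {lengths}")
        if self.n < N_BASIS:
            raise ValueError(
                f"need at least {N_BASIS} reference points to determine the "
                f"6-parameter-per-axis quadratic map, got {self.n}"
            )

    @property
    def n(self) -> int:
        return len(self.cam_x)

    @classmethod
    def from_csv(cls, path) -> "RefPointSet":
        df = pd.read_csv(path)
        return cls(
            df["cam_x"].to_numpy(),
            df["cam_y"].to_numpy(),
            df["pro_x"].to_numpy(),
            df["pro_y"].to_numpy(),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"cam_x": self.cam_x, "cam_y": self.cam_y,
             "pro_x": self.pro_x, "pro_y": self.pro_y}
        ).to_csv(path, index=False)


@dataclass
class PolyMap:
    """Fitted camera->projector transform.

    Attributes
    ----------
    T : (6, 3) ndarray
        Coefficients mapping the quadratic camera basis onto
        ``[1, xpro, ypro]``.
    residual : float
        Root-mean-square fit error over the reference points, in projector
        pixels (computed over the two coordinate columns).
    """

    T: np.ndarray
    residual: float
    basis: str = field(default=BASIS_NAME)

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        if self.T.shape != (N_BASIS, 3):
            raise ValueError(f"T must be {N_BASIS}x3, got {self.T.shape}")
        if self.residual < 0:
            raise ValueError("residual must be non-negative")

    def __call__(self, cam_x, cam_y):
        return apply_map(self, cam_x, cam_y)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"basis": self.basis, "T": self.T.tolist(), "residual": self.residual},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "PolyMap":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        if d.get("basis", BASIS_NAME) != BASIS_NAME:
            raise ValueError(f"unsupported basis {d.get('basis')!r}")
        return cls(T=np.array(d["T"], dtype=float), residual=float(d["residual"]))


def build_design_matrix(cam_x, cam_y) -> np.ndarray:
    """Quadratic Vandermonde design matrix ``[1, x, y, x*x, x*y, y*y]``.

    Parameters
    ----------
    cam_x, cam_y : array-like
        Equal-length coordinate vectors; must be finite.

    Returns
    -------
    (n, 6) ndarray
    """
    x = _as_finite_vector(cam_x, "cam_x")
    y = _as_finite_vector(cam_y, "cam_y")
    if x.shape != y.shape:
        raise ValueError(f"cam_x and cam_y lengths differ: {x.size} vs {y.size}")
    return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])


def _normalizer_matrix(mx: float, my: float, sx: float, sy: float) -> np.ndarray:
    """6x6 matrix A with X_norm = X_raw @ A for u=(x-mx)/sx, v=(y-my)/sy.

    Each column expresses one normalized basis term
    [1, u, v, u*u, u*v, v*v] as a combination of the raw basis
    [1, x, y, x*x, x*y, y*y].
    """
    A = np.zeros((6, 6))
    A[0, 0] = 1.0
    # u = (x - mx)/sx
    A[[0, 1], 1] = [-mx / sx, 1.0 / sx]
    # v = (y - my)/sy
    A[[0, 2], 2] = [-my / sy, 1.0 / sy]
    # u*u = (x^2 - 2 mx x + mx^2)/sx^2
    A[[0, 1, 3], 3] = [mx**2 / sx**2, -2 * mx / sx**2, 1.0 / sx**2]
    # u*v = (xy - my x - mx y + mx my)/(sx sy)
    A[[0, 1, 2, 4], 4] = [mx * my / (sx * sy), -my / (sx * sy), -mx / (sx * sy), 1.0 / (sx * sy)]
    # v*v
    A[[0, 2, 5], 5] = [my**2 / sy**2, -2 * my / sy**2, 1.0 / sy**2]
    return A


def fit_map(refs: RefPointSet, normalize: bool = True) -> PolyMap:
    """Fit the 6x3 quadratic transform by least squares on reference pairs.

    Parameters
    ----------
    refs : RefPointSet
        At least six reference point pairs in general position.
    normalize : bool
        Center and scale camera coordinates before fitting and fold the
        normalization back into ``T`` (improves conditioning when pixel
        coordinates run into the thousands).  Default on.

    Raises
    ------
    DegenerateCalibrationError
        If the design matrix is numerically rank-deficient (e.g. collinear
        reference points), judged by a relative singular-value cutoff of
        ``RANK_RTOL``.
    """
    if normalize:
        mx, my = refs.cam_x.mean(), refs.cam_y.mean()
        sx = refs.cam_x.std() or 1.0
        sy = refs.cam_y.std() or 1.0
        u = (refs.cam_x - mx) / sx
        v = (refs.cam_y - my) / sy
        X = build_design_matrix(u, v)
    else:
        X = build_design_matrix(refs.cam_x, refs.cam_y)

    Y = np.column_stack([np.ones(refs.n), refs.pro_x, refs.pro_y])

    # SVD-based solve: Vandermonde bases are ill-conditioned, so normal
    # equations are avoided deliberately.
    T_fit, _, rank, sv = np.linalg.lstsq(X, Y, rcond=RANK_RTOL)
    if rank < N_BASIS:
        raise DegenerateCalibrationError(
            f"design matrix rank {rank} < {N_BASIS}: reference points are "
            "degenerate (collinear or otherwise non-generic); smallest/largest "
            f"singular value ratio = {sv[-1] / sv[0]:.2e}"
        )

    if normalize:
        T = _normalizer_matrix(mx, my, sx, sy) @ T_fit
    else:
        T = T_fit

    fitted = build_design_matrix(refs.cam_x, refs.cam_y) @ T
    err = fitted[:, 1:] - Y[:, 1:]
    residual = float(np.sqrt(np.mean(err**2)))
    return PolyMap(T=T, residual=residual)


def apply_map(pmap: PolyMap, cam_x, cam_y):
    """Map camera coordinates through a fitted transform.

    Returns ``(pro_x, pro_y)`` with the same shape as the inputs; scalars in,
    scalars out.
    """
    if not isinstance(pmap, PolyMap):
        raise TypeError("apply_map requires a fitted PolyMap")
    scalar = np.isscalar(cam_x) and np.isscalar(cam_y)
    out = build_design_matrix(np.atleast_1d(cam_x), np.atleast_1d(cam_y)) @ pmap.T
    pro_x, pro_y = out[:, 1], out[:, 2]
    if scalar:
        return float(pro_x[0]), float(pro_y[0])
    return pro_x, pro_y
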