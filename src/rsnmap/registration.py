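"""Landmark-based serial-section registration.

Serial tissue sections are aligned by placing matched landmark points on a
source and a target section and fitting a smooth 2D coordinate map. The
warp family is the thin-plate spline (TPS): an affine part plus radial
terms U(r) = r^2 log r, the minimiser of bending energy among interpolants.
With regularisation lambda = 0 the warp passes exactly through the
landmarks, matching the semantics of manually placed correspondence
points; lambda > 0 trades landmark fidelity for smoothness.

Once fitted, the warp transfers coordinates — and through them region
labels or mask distances — from the source section onto the target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "LandmarkWarp",
    "fit_landmark_warp",
    "apply_warp",
    "warp_residuals",
    "transfer_across_sections",
]


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r, evaluated from squared radii (0 at r = 0)."""
    out = np.zeros_like(r2)
    pos = r2 > 0
    # r^2 log r = 0.5 * r^2 log r^2
    out[pos] = 0.5 * r2[pos] * np.log(r2[pos])
    return out


@dataclass
class LandmarkWarp:
    """Fitted thin-plate-spline coordinate map between two sections."""

    source: np.ndarray  # (n, 2) landmark positions on the source section
    target: np.ndarray  # (n, 2) matched positions on the target section
    regularization: float
    radial_coef: np.ndarray  # (n, 2)
    affine_coef: np.ndarray  # (3, 2): rows constant, x, y

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return apply_warp(self, points)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "source": self.source.tolist(),
            "target": self.target.tolist(),
            "regularization": self.regularization,
            "radial_coef": self.radial_coef.tolist(),
            "affine_coef": self.affine_coef.tolist(),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkWarp":
        d = json.loads(Path(path).read_text())
        return cls(
            source=np.asarray(d["source"], dtype=float),
            target=np.asarray(d["target"], dtype=float),
            regularization=float(d["regularization"]),
            radial_coef=np.asarray(d["radial_coef"], dtype=float),
            affine_coef=np.asarray(d["affine_coef"], dtype=float),
        )


def fit_landmark_warp(
    source: np.ndarray, target: np.ndarray, regularization: float = 0.0
) -> LandmarkWarp:
    """Fit a TPS warp from matched landmark pairs.

    Solves the standard augmented linear system [[K + lambda*I, P],
    [P^T, 0]] with side conditions that remove the affine ambiguity of the
    radial part. Requires >= 3 non-collinear source landmarks; duplicate
    source landmarks with conflicting targets are rejected at lambda = 0.
    """
    src = np.asarray(source, dtype=float).reshape(-1, 2)
    dst = np.asarray(target, dtype=float).reshape(-1, 2)
    if src.shape != dst.shape:
        raise ValueError("source and target landmark arrays differ in shape")
    n = len(src)
    if n < 3:
        raise ValueError("need at least 3 landmark pairs")
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    # collinearity check: rank of centred source coordinates
    centred = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(src).max())) < 2:
        raise ValueError("source landmarks are collinear; warp is underdetermined")
    if regularization == 0.0:
        uniq = {}
        for s, t in zip(map(tuple, src), map(tuple, dst)):
            if s in uniq and uniq[s] != t:
                raise ValueError(
                    f"duplicate source landmark {s} with conflicting targets"
                )
            uniq[s] = t
        if len(uniq) < n:
            # exact duplicates carry no extra information; drop them
            src = np.array(list(uniq.keys()))
            dst = np.array(list(uniq.values()))
            n = len(src)

    d2 = ((src[:, None, :] - src[None, :, :]) ** 2).sum(axis=2)
    K = _tps_kernel(d2) + regularization * np.eye(n)
    P = np.column_stack([np.ones(n), src])
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    b = np.zeros((n + 3, 2))
    b[:n] = dst
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate landmark configuration") from exc
    return LandmarkWarp(
        source=src,
        target=dst,
        regularization=regularization,
        radial_coef=sol[:n],
        affine_coef=sol[n:],
    )


def apply_warp(warp: LandmarkWarp, points: np.ndarray) -> np.ndarray:
    """Map points through the fitted warp."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return pts.copy()
    d2 = ((pts[:, None, :] - warp.source[None, :, :]) ** 2).sum(axis=2)
    U = _tps_kernel(d2)
    P = np.column_stack([np.ones(len(pts)), pts])
    return U @ warp.radial_coef + P @ warp.affine_coef


def warp_residuals(warp: LandmarkWarp, pairs_source: np.ndarray, pairs_target: np.ndarray) -> float:
    """Root-mean-square Euclidean residual (µm) on held-out pairs.

    Used as the registration-quality score: sections whose residual
    exceeds a chosen cutoff are excluded from cross-section analyses.
    """
    src = np.asarray(pairs_source, dtype=float).reshape(-1, 2)
    dst = np.asarray(pairs_target, dtype=float).reshape(-1, 2)
    if len(src) == 0:
        raise ValueError("need at least one held-out pair")
    if src.shape != dst.shape:
        raise ValueError("held-out source/target arrays differ in shape")
    mapped = apply_warp(warp, src)
    return float(np.sqrt(np.mean(np.sum((mapped - dst) ** 2, axis=1))))


def transfer_across_sections(points: np.ndarray, warp: LandmarkWarp, target):
    """Map points into the target section's frame and annotate them there.

    ``target`` is either a (grid, labels) tuple — region labels are looked
    up at the warped coordinates — or a :class:`~rsnmap.masks.DensityMask`,
    in which case distances to the mask are returned.
    """
    from .masks import DensityMask, distance_to_mask
    from .regions import assign_cell_regions

    mapped = apply_warp(warp, points)
    if isinstance(target, DensityMask):
        return distance_to_mask(mapped, target)
    grid, labels = target
    return assign_cell_regions(mapped, grid, labels)
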