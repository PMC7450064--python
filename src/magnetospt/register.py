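"""Fiducial-based nonreflective similarity registration.

Overlaying a tracked trajectory onto an image acquired in a second modality
(for example a super-resolution reconstruction of the cytoskeleton) requires
mapping one coordinate frame onto the other. With corresponding fiducial
markers visible in both frames, the standard model is the nonreflective
similarity transform: uniform scale `s`, rotation `θ` and translation `t`,

    p' = s · R(θ) · p + t,        det(s·R) = s² > 0,

which preserves shape and handedness. The least-squares fit over n point
pairs has a closed form in the four parameters (s·cosθ, s·sinθ, t_x, t_y);
solving in those variables makes the fit exact for n = 2 and excludes
reflections by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SimilarityTransform:
    """Nonreflective similarity map p ↦ scale·R(rotation)·p + translation.

    ``rotation`` is in radians; with the image axis convention used
    throughout (x rightward, y downward) a positive rotation takes (1, 0)
    to (0, 1).
    """

    scale: float = 1.0
    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be positive (reflection not allowed)")

    @property
    def matrix(self) -> np.ndarray:
        """The 2x2 linear part s·R(θ); its determinant is s² > 0."""
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return apply_transform(self, points)

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        inv_rot = -self.rotation
        c, s = np.cos(inv_rot), np.sin(inv_rot)
        R_inv = inv_scale * np.array([[c, -s], [s, c]])
        t = -R_inv @ np.asarray(self.translation)
        return SimilarityTransform(inv_scale, inv_rot, (t[0], t[1]))


def apply_transform(t: SimilarityTransform, points: np.ndarray) -> np.ndarray:
    """Apply the similarity map elementwise to (N, 2) or (2,) points."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    out = np.atleast_2d(pts) @ t.matrix.T + np.asarray(t.translation)
    return out[0] if single else out


def fit_similarity(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Least-squares nonreflective similarity mapping ``src`` onto ``dst``.

    Parameters
    ----------
    src, dst : (N, 2) arrays of corresponding points, N >= 2.
        Correspondence is by row order; no automatic matching.

    Returns
    -------
    SimilarityTransform minimizing ``Σ |t(src_i) - dst_i|²`` over scale > 0,
    rotation and translation. Reflections are excluded by the parametrization
    itself, so mirrored inputs yield the best proper-rotation fit with a
    nonzero residual rather than a flipped map.

    Raises
    ------
    ValueError
        On fewer than 2 points, mismatched counts, or all-coincident ``src``.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.ndim != 2 or src.shape[1] != 2 or dst.shape != src.shape:
        raise ValueError("src and dst must be matching (N, 2) arrays")
    n = src.shape[0]
    if n < 2:
        raise ValueError("at least 2 point pairs are required")
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    denom = float(np.sum(src_c**2))
    if denom == 0.0:
        raise ValueError("src points are all coincident; transform is degenerate")
    # closed form for the complex regression dst_c ≈ (a + i b) src_c
    a = float(np.sum(src_c * dst_c)) / denom
    b = float(np.sum(src_c[:, 0] * dst_c[:, 1] - src_c[:, 1] * dst_c[:, 0])) / denom
    scale = float(np.hypot(a, b))
    if scale == 0.0:
        raise ValueError("degenerate fit: dst has no component along src")
    rotation = float(np.arctan2(b, a))
    c, s = np.cos(rotation), np.sin(rotation)
    R = scale * np.array([[c, -s], [s, c]])
    t = dst.mean(axis=0) - R @ src.mean(axis=0)
    return SimilarityTransform(scale, rotation, (float(t[0]), float(t[1])))


def registration_residual(t: SimilarityTransform, src: np.ndarray, dst: np.ndarray) -> float:
    """Root-mean-square distance |t(src_i) − dst_i| in the units of the inputs."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.size == 0:
        raise ValueError("cannot compute a residual for empty point sets")
    if src.shape != dst.shape:
        raise ValueError("src and dst must have matching shapes")
    diff = apply_transform(t, src) - dst
    return float(np.sqrt(np.mean(np.sum(np.atleast_2d(diff) ** 2, axis=1))))
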