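"""Reflex visual attention: DOG saliency on the gradient norm, focus points,
and log-polar local views.

The front-end has no learned component. Candidate fixation points are the
maxima of a difference-of-Gaussians filtering of the image-gradient norm,
which concentrates on corners and line terminations (limb extremities, head
contour). Around each focus point a log-polar resampling of the image is
taken, making the resulting feature vector tolerant to small rotations and
scale changes of the pattern (they become near-circular shifts of the grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class FocusPoint:
    row: int
    col: int
    saliency: float


@dataclass(frozen=True)
class LocalView:
    """Flat log-polar patch (``n_rings * n_angles`` values in [0, 1])."""

    values: np.ndarray
    center: FocusPoint


def gradient_norm(image: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean norm of the central-difference gradient.

    Borders are handled by reflection, so a constant image maps to an exactly
    zero field everywhere including the edges.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    padded = np.pad(image, 1, mode="reflect")
    gr = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    gc = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    return np.hypot(gr, gc)


def dog_saliency(field: np.ndarray, sigma1: float = 1.0, sigma2: float = 2.0) -> np.ndarray:
    """Difference-of-Gaussians band-pass of a scalar field (reflect border)."""
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("sigmas must be positive")
    if sigma2 <= sigma1:
        raise ValueError("sigma2 must exceed sigma1")
    field = np.asarray(field, dtype=np.float64)
    return (ndimage.gaussian_filter(field, sigma1, mode="reflect")
            - ndimage.gaussian_filter(field, sigma2, mode="reflect"))


def detect_focus_points(saliency: np.ndarray, n_points: int = 20,
                        suppression_radius: int = 6) -> list[FocusPoint]:
    """Greedy descending-saliency selection with Chebyshev non-max suppression.

    Candidates are the strictly positive pixels; a candidate is suppressed if
    it lies within ``suppression_radius`` (Chebyshev) of an accepted point.
    Ties in saliency are broken by row-major (row, col) order so the result is
    deterministic. Fewer than ``n_points`` survivors yield a shorter list.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    sal = np.asarray(saliency, dtype=np.float64)
    rows, cols = np.nonzero(sal > 0)
    if rows.size == 0:
        return []
    vals = sal[rows, cols]
    # sort by (-saliency, row, col); lexsort's last key is primary
    order = np.lexsort((cols, rows, -vals))
    picked: list[FocusPoint] = []
    pr = np.empty(0, dtype=np.int64)
    pc = np.empty(0, dtype=np.int64)
    for i in order:
        r, c = int(rows[i]), int(cols[i])
        if pr.size and np.any(np.maximum(np.abs(pr - r), np.abs(pc - c)) <= suppression_radius):
            continue
        picked.append(FocusPoint(r, c, float(vals[i])))
        pr = np.append(pr, r)
        pc = np.append(pc, c)
        if len(picked) == n_points:
            break
    return picked


def log_polar_view(image: np.ndarray, center: FocusPoint, r_max: float = 56.0,
                   n_rings: int = 16, n_angles: int = 16, subsamples: int = 3) -> LocalView:
    """Sample a log-polar grid around a focus point (bilinear interpolation).

    Ring radii grow geometrically from 1 to ``r_max``; angles are uniform on
    the circle. Each output cell averages a ``subsamples x subsamples``
    sub-grid in (log r, angle) space, which keeps the sparse outer rings from
    aliasing (at large radii neighbouring point samples would otherwise be
    tens of pixels apart). ``subsamples=1`` reduces to plain point sampling.
    Samples falling outside the image take the nearest border value. The flat
    output is ring-major: ``values[k * n_angles + a]``, so a rotation of the
    underlying pattern shifts entries along the angle axis and a rescaling
    shifts them along the ring axis.
    """
    image = np.asarray(image, dtype=np.float64)
    if r_max < 2:
        raise ValueError("r_max must be >= 2")
    if subsamples < 1:
        raise ValueError("subsamples must be >= 1")
    if not (0 <= center.row < image.shape[0] and 0 <= center.col < image.shape[1]):
        raise ValueError("focus point lies outside the image")
    # fractional ring/angle coordinates of the sub-samples, centred on the cell
    ks = (np.arange(n_rings * subsamples) + 0.5) / subsamples - 0.5
    radii = r_max ** (ks / (n_rings - 1)) if n_rings > 1 else np.ones(subsamples)
    ang = 2.0 * np.pi * ((np.arange(n_angles * subsamples) + 0.5) / subsamples - 0.5) / n_angles
    rr = center.row - radii[:, None] * np.sin(ang)[None, :]
    cc = center.col + radii[:, None] * np.cos(ang)[None, :]
    vals = ndimage.map_coordinates(image, [rr.ravel(), cc.ravel()], order=1, mode="nearest")
    vals = vals.reshape(n_rings, subsamples, n_angles, subsamples).mean(axis=(1, 3))
    return LocalView(np.clip(vals.ravel(), 0.0, 1.0), center)


def extract_views(image: np.ndarray, *, sigma1: float = 1.0, sigma2: float = 2.0,
                  n_points: int = 20, suppression_radius: int = 6,
                  r_max: float = 56.0, n_rings: int = 16, n_angles: int = 16) -> list[LocalView]:
    """Full reflex pathway for one frame: saliency -> focus points -> views."""
    sal = dog_saliency(gradient_norm(image), sigma1, sigma2)
    points = detect_focus_points(sal, n_points, suppression_radius)
    return [log_polar_view(image, p, r_max, n_rings, n_angles) for p in points]
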