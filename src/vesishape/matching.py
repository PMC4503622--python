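"""Match observed vesicle silhouettes to shape-library entries.

The study compared micrographs with simulated shapes by eye; this
module automates that step with a reconstructed metric (no matching
criterion exists in the source protocol, and the result metadata says
so): both silhouettes are normalized — centroid-centered, scaled to
unit equivalent radius, principal-axis aligned — and compared by the
root-mean-square difference of their radial profiles over matched polar
angles, with the 180-degree rotation and reflection ambiguities
resolved by taking the best of the four alignments.

Non-star-shaped observed contours (radial profile multivalued about the
centroid) fall back to an arc-length curvature-signature distance and
are flagged in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_ANGLES = 360

METRIC_NOTE = ("radial-profile RMS metric; reconstruction — the original "
               "comparison was a manual, qualitative pick")


class NoMatchError(ValueError):
    """Candidate set empty (e.g. after the measured-v restriction)."""


@dataclass
class MatchResult:
    """Best-matching library entry for one observed silhouette."""

    da: float
    v: float
    distance: float
    shape_class: str | None
    mm_ratio: float
    runner_up: list = field(default_factory=list)  # [(da, v, distance), ...]
    star_shaped: bool = True
    metric_note: str = METRIC_NOTE


# --------------------------------------------------------------------------
# polygon utilities
# --------------------------------------------------------------------------


def _polygon_moments(pts: np.ndarray):
    """Area, centroid and central second moments of a closed polygon."""
    x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * np.sum(cross)
    cx = np.sum((x + x1) * cross) / (6.0 * area)
    cy = np.sum((y + y1) * cross) / (6.0 * area)
    ixx = np.sum((y * y + y * y1 + y1 * y1) * cross) / 12.0
    iyy = np.sum((x * x + x * x1 + x1 * x1) * cross) / 12.0
    ixy = np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross) / 24.0
    ixx -= area * cy * cy
    iyy -= area * cx * cx
    ixy -= area * cx * cy
    return abs(area), cx, cy, ixx, iyy, ixy


def _resample_closed(pts: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to n points equally spaced in arc length."""
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    t = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(t, s, closed[:, 0])
    out[:, 1] = np.interp(t, s, closed[:, 1])
    return out


def normalize_contour(pts: np.ndarray, n_angles: int = N_ANGLES):
    """Radial profile of a closed contour after pose/scale normalization.

    Returns ``(profile, star_shaped)``; the profile is sampled at
    ``n_angles`` equal polar angles about the area centroid, with the
    major principal axis along angle zero and radii scaled to unit
    equivalent radius.  ``star_shaped`` is False when the profile is
    multivalued (the fallback metric should be used).
    """
    pts = _resample_closed(np.asarray(pts, dtype=float), 4 * n_angles)
    area, cx, cy, ixx, iyy, ixy = _polygon_moments(pts)
    if area <= 0:
        raise ValueError("degenerate contour")
    q = pts - [cx, cy]
    angle = 0.5 * np.arctan2(2.0 * ixy, iyy - ixx)
    c, s = np.cos(-angle), np.sin(-angle)
    q = q @ np.array([[c, -s], [s, c]]).T
    if np.ptp(q[:, 0]) < np.ptp(q[:, 1]):  # put the long axis on x
        q = q[:, ::-1] * [1.0, -1.0]
    q /= np.sqrt(area / np.pi)

    theta = np.arctan2(q[:, 1], q[:, 0])
    r = np.hypot(q[:, 0], q[:, 1])
    bins = ((theta + np.pi) / (2.0 * np.pi) * n_angles).astype(int) % n_angles
    prof = np.full(n_angles, np.nan)
    star = True
    for b in range(n_angles):
        sel = bins == b
        if not sel.any():
            continue
        rs = r[sel]
        if rs.max() - rs.min() > 0.05 * max(rs.mean(), 1e-9):
            star = False
        prof[b] = rs.mean()
    missing = np.isnan(prof)
    if missing.any():
        idx = np.arange(n_angles)
        prof[missing] = np.interp(idx[missing], idx[~missing], prof[~missing],
                                  period=n_angles)
    return prof, star


def curvature_signature(pts: np.ndarray, n: int = 256) -> np.ndarray:
    """Scale-normalized curvature along the arc-length-resampled contour."""
    p = _resample_closed(np.asarray(pts, dtype=float), n)
    perim = np.sum(np.linalg.norm(np.diff(np.vstack([p, p[:1]]), axis=0), axis=1))
    p = p * (2.0 * np.pi / perim)  # unit-circle perimeter normalization
    d1 = (np.roll(p, -1, axis=0) - np.roll(p, 1, axis=0)) * 0.5
    d2 = np.roll(p, -1, axis=0) - 2.0 * p + np.roll(p, 1, axis=0)
    num = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    den = (d1[:, 0] ** 2 + d1[:, 1] ** 2) ** 1.5
    return num / np.maximum(den, 1e-12)


def _profile_distance(p1: np.ndarray, p2: np.ndarray) -> float:
    """RMS distance minimized over the 180-degree and mirror ambiguities."""
    n = len(p1)
    half = n // 2
    candidates = (p2, np.roll(p2, half), p2[::-1], np.roll(p2[::-1], half))
    return min(float(np.sqrt(np.mean((p1 - c) ** 2))) for c in candidates)


def _signature_distance(s1: np.ndarray, s2: np.ndarray) -> float:
    best = np.inf
    for cand in (s2, s2[::-1]):
        # cyclic alignment via FFT cross-correlation
        f1, f2 = np.fft.rfft(s1), np.fft.rfft(cand)
        corr = np.fft.irfft(f1 * np.conj(f2), n=len(s1))
        shift = int(np.argmax(corr))
        d = float(np.sqrt(np.mean((s1 - np.roll(cand, shift)) ** 2)))
        best = min(best, d)
    return best


# --------------------------------------------------------------------------
# library silhouettes
# --------------------------------------------------------------------------


def solution_silhouette(solution, n: int = 1024) -> np.ndarray:
    """Closed cross-section polygon (plane through the symmetry axis)."""
    from .classify import meridian_profile

    p = meridian_profile(solution.shape, n=n)
    right = np.column_stack([p.rho, p.z])
    left = np.column_stack([-p.rho[::-1], p.z[::-1]])
    return np.vstack([right, left])


def _mask_to_contour(mask: np.ndarray) -> np.ndarray:
    from skimage import measure as skmeasure

    contours = skmeasure.find_contours(np.asarray(mask, dtype=float), 0.5)
    if not contours:
        raise ValueError("mask contains no contour")
    contour = max(contours, key=len)
    return contour[:, ::-1]  # (row, col) -> (x, y)


def match_to_library(observed, library, measured_v: float | None = None,
                     v_tolerance: float = 0.03, n_runner_up: int = 5) -> MatchResult:
    """Nearest library entry for an observed mask or contour.

    ``observed`` is a 2-D boolean mask or an (N, 2) contour in any
    units/pose — the metric is invariant to rotation, translation and
    uniform scaling.  With ``measured_v`` given, candidates are
    restricted to entries with |v - measured_v| <= ``v_tolerance``.
    Ties break deterministically toward the lowest da, then lowest v.
    """
    observed = np.asarray(observed)
    if observed.ndim == 2 and observed.shape[1] == 2 and observed.dtype.kind == "f":
        contour = observed
    else:
        contour = _mask_to_contour(observed)
    prof_obs, star = normalize_contour(contour)
    sig_obs = None if star else curvature_signature(contour)

    candidates = []
    for (da, v), sol in sorted(library.entries.items()):
        if not sol.converged:
            continue
        if measured_v is not None and abs(v - measured_v) > v_tolerance:
            continue
        candidates.append(((da, v), sol))
    if not candidates:
        raise NoMatchError("no converged library entries in the candidate set")

    scored = []
    for (da, v), sol in candidates:
        sil = solution_silhouette(sol)
        if star:
            prof_lib, _ = normalize_contour(sil)
            d = _profile_distance(prof_obs, prof_lib)
        else:
            d = _signature_distance(sig_obs, curvature_signature(sil))
        scored.append((d, da, v, sol))
    scored.sort(key=lambda t: (round(t[0], 12), t[1], t[2]))
    d, da, v, sol = scored[0]
    from .classify import silhouette_mm_ratio

    return MatchResult(
        da=da, v=v, distance=d, shape_class=sol.shape_class,
        mm_ratio=silhouette_mm_ratio(sol) if sol.converged else float("nan"),
        runner_up=[(b, c, a) for a, b, c, _ in scored[1:1 + n_runner_up]],
        star_shaped=star,
    )
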