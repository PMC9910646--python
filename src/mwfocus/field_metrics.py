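"""Quantitative focusing diagnostics.

All metrics operate on the field *amplitude* |E| (not intensity |E|²) — an
intensity-based FWHM would be a factor √2 narrower — and are invariant to
global amplitude scaling and global phase rotation of the phasor field.

Profiles along a cut are sampled either through a caller-supplied exact
field evaluator (analytic superposition, preferred) or by linear
interpolation of the stored grid samples.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

from .array_geometry import ArrayLayout
from .dipole_fields import FieldGrid
from .focusing_optimizer import DipoleSolution

__all__ = [
    "FocusReport",
    "fwhm_along",
    "contrast_ratio",
    "contrast_point",
    "steering_report",
    "neighbor_phase_shifts",
    "amplitude_profile",
]

#: Sentinel returned when no half-max crossing exists inside the grid.
FWHM_UNDEFINED = float("nan")


@dataclasses.dataclass
class FocusReport:
    """Summary of one realized focus."""

    peak_location: np.ndarray
    peak_magnitude: float
    fwhm_by_cut: dict
    contrast_at: dict
    phase_shift_stats: dict | None = None
    extras: dict = dataclasses.field(default_factory=dict)


def _amplitude_interpolator(field: FieldGrid):
    amp = np.linalg.norm(field.E, axis=1)
    lin = LinearNDInterpolator(field.points, amp)
    near = NearestNDInterpolator(field.points, amp)

    def f(pts):
        v = lin(pts)
        bad = np.isnan(v)
        if np.any(bad):
            v[bad] = near(np.atleast_2d(pts)[bad])
        return v

    return f


def amplitude_profile(
    field: FieldGrid,
    focus: np.ndarray,
    direction: np.ndarray,
    evaluator=None,
    n_samples: int = 801,
    extent: float | None = None,
):
    """|E| sampled along the line focus + t·direction.

    Returns (t, amplitude) with t spanning the grid extent (or ±`extent`).
    `evaluator`, if given, maps (N,3) points to (N,3) complex E exactly.
    """
    focus = np.asarray(focus, float).reshape(3)
    d = np.asarray(direction, float).reshape(3)
    d = d / np.linalg.norm(d)
    if extent is None:
        rel = field.points - focus
        extent = float(np.max(np.abs(rel @ d)))
    t = np.linspace(-extent, extent, n_samples)
    pts = focus[None, :] + t[:, None] * d[None, :]
    if evaluator is not None:
        amp = np.linalg.norm(np.atleast_2d(evaluator(pts)), axis=1)
    else:
        amp = _amplitude_interpolator(field)(pts)
    return t, amp


def fwhm_along(
    field: FieldGrid,
    focus: np.ndarray,
    direction: np.ndarray,
    evaluator=None,
    n_samples: int = 801,
) -> float:
    """Full width at half maximum of |E| along the line through `focus`.

    The peak is taken as the local maximum nearest the focus; the width is
    the distance between the two half-max crossings bracketing it, located
    by linear interpolation.  Returns NaN (documented sentinel) if either
    crossing lies outside the grid — an unfocused field.
    """
    t, amp = amplitude_profile(field, focus, direction, evaluator, n_samples)
    # local maximum nearest t=0
    i0 = int(np.argmin(np.abs(t)))
    i = i0
    while 0 < i < len(t) - 1:
        if amp[i + 1] > amp[i]:
            i += 1
        elif amp[i - 1] > amp[i]:
            i -= 1
        else:
            break
    peak = amp[i]
    half = peak / 2.0
    # march outward for the crossings
    right = FWHM_UNDEFINED
    for j in range(i, len(t) - 1):
        if amp[j + 1] < half <= amp[j]:
            right = t[j] + (t[j + 1] - t[j]) * (amp[j] - half) / (amp[j] - amp[j + 1])
            break
    left = FWHM_UNDEFINED
    for j in range(i, 0, -1):
        if amp[j - 1] < half <= amp[j]:
            left = t[j] - (t[j] - t[j - 1]) * (amp[j] - half) / (amp[j] - amp[j - 1])
            break
    return float(right - left)


def contrast_ratio(
    field: FieldGrid,
    focus: np.ndarray,
    distance: float,
    evaluator=None,
    shell_halfwidth: float | None = None,
) -> float:
    """Peak |E| at `focus` over the mean |E| on the spherical shell at
    `distance` (± half a grid cell by default)."""
    focus = np.asarray(focus, float).reshape(3)
    if shell_halfwidth is None:
        d = np.linalg.norm(field.points[1] - field.points[0])
        shell_halfwidth = d / 2.0 if d > 0 else distance * 0.05
    r = np.linalg.norm(field.points - focus, axis=1)
    shell = np.abs(r - distance) <= shell_halfwidth
    if not np.any(shell):
        raise ValueError("no grid points on the requested shell")
    if evaluator is not None:
        peak = float(np.linalg.norm(np.atleast_2d(evaluator(focus[None, :])), axis=1)[0])
        shell_amp = np.linalg.norm(np.atleast_2d(evaluator(field.points[shell])), axis=1)
    else:
        interp = _amplitude_interpolator(field)
        peak = float(interp(focus[None, :])[0])
        shell_amp = np.linalg.norm(field.E[shell], axis=1)
    return peak / float(np.mean(shell_amp))


def contrast_point(
    field: FieldGrid,
    focus: np.ndarray,
    direction: np.ndarray,
    distance: float,
    evaluator=None,
) -> float:
    """Peak |E| at `focus` over the mean |E| at the two points ±`distance`
    along the cut direction (the 1D-cut reading of "N cm away")."""
    focus = np.asarray(focus, float).reshape(3)
    d = np.asarray(direction, float).reshape(3)
    d = d / np.linalg.norm(d)
    pts = np.stack([focus, focus + distance * d, focus - distance * d])
    if evaluator is not None:
        amp = np.linalg.norm(np.atleast_2d(evaluator(pts)), axis=1)
    else:
        amp = _amplitude_interpolator(field)(pts)
    return float(amp[0] / np.mean(amp[1:]))


def _peak_location(field: FieldGrid, evaluator=None) -> tuple[np.ndarray, float]:
    amp = np.linalg.norm(field.E, axis=1)
    i = int(np.argmax(amp))
    return field.points[i].copy(), float(amp[i])


def steering_report(
    solutions: list[DipoleSolution],
    fields: list[FieldGrid],
    direction: np.ndarray = (1.0, 1.0, 0.0),
    center_index: int = 0,
    evaluators: list | None = None,
) -> list[FocusReport]:
    """Per-target focus summaries with peak ratios relative to the entry at
    `center_index`: amplitude ratio and intensity (|E|²) ratio."""
    if len(solutions) != len(fields):
        raise ValueError("one field per solution required")
    evaluators = evaluators or [None] * len(fields)
    peaks = []
    reports = []
    for fg, ev in zip(fields, evaluators):
        loc, mag = _peak_location(fg, ev)
        peaks.append((loc, mag))
    ref_mag = peaks[center_index][1]
    for (loc, mag), fg, sol, ev in zip(peaks, fields, solutions, evaluators):
        fwhm = fwhm_along(fg, loc, np.asarray(direction, float), evaluator=ev)
        reports.append(
            FocusReport(
                peak_location=loc,
                peak_magnitude=mag,
                fwhm_by_cut={"diagonal": fwhm},
                contrast_at={},
                extras={
                    "amplitude_ratio_vs_center": mag / ref_mag,
                    "intensity_ratio_vs_center": (mag / ref_mag) ** 2,
                    "alpha": sol.alpha,
                },
            )
        )
    return reports


def neighbor_phase_shifts(
    solution: DipoleSolution,
    layout: ArrayLayout,
    floor: float = 0.01,
) -> dict:
    """Phase difference between nearest-neighbor transmitters.

    For each element above the reporting floor (moment magnitude ≥
    `floor` × the maximum element magnitude — phase is meaningless for the
    many near-dark elements), its nearest neighbor by geodesic (chord)
    distance is found among the kept elements; per-axis phase differences
    are wrapped to (−π, π].  Returns min/median/max of the absolute shifts.
    """
    if layout.count < 2:
        raise ValueError("need at least two transmitters")
    m = solution.M_opt.reshape(layout.count, 3)
    mags = np.linalg.norm(m, axis=1)
    keep = mags >= floor * np.max(mags)
    idx = np.flatnonzero(keep)
    if idx.size < 2:
        return {"min": 0.0, "median": 0.0, "max": 0.0, "n_pairs": 0}
    pos = layout.positions[idx]
    shifts = []
    for a in range(idx.size):
        d = np.linalg.norm(pos - pos[a], axis=1)
        d[a] = np.inf
        b = int(np.argmin(d))
        for ax in range(3):
            ma, mb = m[idx[a], ax], m[idx[b], ax]
            if abs(ma) == 0 or abs(mb) == 0:
                continue
            dphi = np.angle(ma) - np.angle(mb)
            dphi = (dphi + np.pi) % (2.0 * np.pi) - np.pi
            shifts.append(abs(dphi))
    shifts = np.array(shifts)
    return {
        "min": float(np.min(shifts)),
        "median": float(np.median(shifts)),
        "max": float(np.max(shifts)),
        "n_pairs": int(shifts.size),
    }
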