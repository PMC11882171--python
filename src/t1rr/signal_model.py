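"""Spoiled gradient-echo (SPGR/FLASH) signal physics.

The steady-state SPGR signal at repetition time ``TR`` and flip angle
``alpha`` for a tissue with longitudinal relaxation time ``T1`` and
equilibrium magnetization ``M0`` is

    SI = M0 * sin(alpha) * (1 - E1) / (1 - cos(alpha) * E1),
    E1 = exp(-TR / T1).

From two acquisitions at distinct flip angles and fixed TR, the signal
equation linearizes (DESPOT1): plotting ``y = SI / sin(alpha)`` against
``x = SI / tan(alpha)`` gives a line of slope ``E1``, so

    T1 = -TR / ln(slope),       M0 = (y - slope * x) / (1 - slope).

This module provides the forward model, the closed-form two-point
inversion, the Ernst angle, and the flip-angle pair that maximizes
T1 precision (the pair whose signals both equal 71% of the Ernst-angle
signal).  All angles are degrees at the API surface; TR and T1 are in
milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import bisect

__all__ = [
    "AcquisitionParams",
    "TissueState",
    "DualAngleFit",
    "spgr_signal",
    "fit_t1_dual_angle",
    "ernst_angle",
    "optimal_fa_pair",
    "T1_BOUNDS_MS",
]

#: Physical-plausibility window for fitted T1 at 1.5 T (ms).  Fits outside
#: this window are flagged invalid rather than clamped to the boundary.
T1_BOUNDS_MS = (1.0, 5000.0)


@dataclass(frozen=True)
class AcquisitionParams:
    """Geometry and timing of a (simulated or scanner) FLASH acquisition.

    Parameters
    ----------
    tr : float
        Repetition time in ms, > 0.
    flip_angles : tuple of float
        Nominal flip angles in degrees, each in (0, 90].  A single-series
        object carries one angle; a dual-angle protocol carries two.
    pixel_spacing : (float, float)
        In-plane pixel size in mm, (row, column).
    matrix : (int, int)
        Image matrix (rows, columns).
    """

    tr: float
    flip_angles: tuple[float, ...]
    pixel_spacing: tuple[float, float] = (1.5, 1.5)
    matrix: tuple[int, int] = (208, 256)

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError(f"tr must be > 0 ms, got {self.tr}")
        fas = tuple(float(a) for a in self.flip_angles)
        if not 1 <= len(fas) <= 2:
            raise ValueError("flip_angles must hold one or two angles")
        for a in fas:
            if not 0 < a <= 90:
                raise ValueError(f"flip angle {a} outside (0, 90] degrees")
        object.__setattr__(self, "flip_angles", fas)
        object.__setattr__(self, "pixel_spacing", tuple(float(s) for s in self.pixel_spacing))
        object.__setattr__(self, "matrix", tuple(int(n) for n in self.matrix))
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError("pixel_spacing must be positive")
        if any(n <= 0 for n in self.matrix):
            raise ValueError("matrix must be positive")

    def geometry_mismatch(self, other: "AcquisitionParams") -> str | None:
        """Name of the first differing geometric attribute, or None."""
        for attr in ("matrix", "pixel_spacing", "tr"):
            if getattr(self, attr) != getattr(other, attr):
                return attr
        return None


@dataclass(frozen=True)
class TissueState:
    """A tissue voxel: T1 (ms, > 0) and equilibrium magnetization M0 (>= 0)."""

    t1: float
    m0: float = 1.0

    def __post_init__(self) -> None:
        if self.t1 <= 0:
            raise ValueError(f"t1 must be > 0 ms, got {self.t1}")
        if self.m0 < 0:
            raise ValueError(f"m0 must be >= 0, got {self.m0}")

    def e1(self, tr: float) -> float:
        """Longitudinal recovery factor exp(-TR/T1), in (0, 1)."""
        if tr <= 0:
            raise ValueError(f"tr must be > 0 ms, got {tr}")
        return float(np.exp(-tr / self.t1))

    def signal(self, flip_angle: float, tr: float) -> float:
        """SPGR signal of this tissue at the given flip angle (deg) and TR (ms)."""
        return float(spgr_signal(self.m0, self.t1, flip_angle, tr))


def spgr_signal(m0, t1, flip_angle, tr):
    """Steady-state SPGR signal intensity.

    Parameters are broadcast together, so any of them may be an array
    (e.g. per-pixel M0/T1 maps with a per-pixel effective flip angle).

    Parameters
    ----------
    m0 : array_like
        Equilibrium magnetization, arbitrary units, >= 0.
    t1 : array_like
        Longitudinal relaxation time in ms, > 0.
    flip_angle : array_like
        Flip angle in degrees, in [0, 180].
    tr : float
        Repetition time in ms, > 0.

    Returns
    -------
    ndarray or float
        Signal intensity in the units of ``m0``.
    """
    m0 = np.asarray(m0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    alpha = np.asarray(flip_angle, dtype=float)
    if tr <= 0:
        raise ValueError(f"tr must be > 0 ms, got {tr}")
    if np.any(t1 <= 0):
        raise ValueError("t1 must be > 0 ms everywhere")
    if np.any((alpha < 0) | (alpha > 180)):
        raise ValueError("flip_angle must lie in [0, 180] degrees")
    a = np.deg2rad(alpha)
    e1 = np.exp(-tr / t1)
    si = m0 * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)
    if si.ndim == 0:
        return float(si)
    return si


class DualAngleFit(NamedTuple):
    """Result of the two-point DESPOT1 inversion (arrays or scalars)."""

    t1: np.ndarray | float
    m0: np.ndarray | float
    valid: np.ndarray | bool


def fit_t1_dual_angle(si1, si2, alpha1: float, alpha2: float, tr: float,
                      t1_bounds: tuple[float, float] = T1_BOUNDS_MS) -> DualAngleFit:
    """Closed-form T1/M0 from two SPGR signals at distinct flip angles.

    Pixels where the inversion is undefined or unphysical are flagged
    ``valid=False`` and carry NaN: zero/degenerate signals (the two
    linearized points coincide), a slope outside (0, 1) (noise, air,
    inflow), or a T1 outside ``t1_bounds``.

    Parameters
    ----------
    si1, si2 : array_like
        Signal intensities at ``alpha1`` and ``alpha2`` (broadcastable).
    alpha1, alpha2 : float
        Flip angles in degrees, distinct, each in (0, 90].
    tr : float
        Repetition time in ms.
    t1_bounds : (float, float)
        Plausibility window in ms; fits outside are invalidated.

    Returns
    -------
    DualAngleFit
        ``(t1, m0, valid)``; scalars in, scalars out.
    """
    if tr <= 0:
        raise ValueError(f"tr must be > 0 ms, got {tr}")
    for a in (alpha1, alpha2):
        if not 0 < a <= 90:
            raise ValueError(f"flip angle {a} outside (0, 90] degrees")
    if alpha1 == alpha2:
        raise ValueError("dual-angle fit requires two distinct flip angles")

    si1 = np.asarray(si1, dtype=float)
    si2 = np.asarray(si2, dtype=float)
    scalar = si1.ndim == 0 and si2.ndim == 0
    a1, a2 = np.deg2rad(alpha1), np.deg2rad(alpha2)

    with np.errstate(divide="ignore", invalid="ignore"):
        y1, x1 = si1 / np.sin(a1), si1 / np.tan(a1)
        y2, x2 = si2 / np.sin(a2), si2 / np.tan(a2)
        dx = x2 - x1
        slope = np.where(dx != 0, (y2 - y1) / np.where(dx != 0, dx, 1.0), np.nan)
        valid = (dx != 0) & (slope > 0) & (slope < 1)
        t1 = np.where(valid, -tr / np.log(np.where(valid, slope, 0.5)), np.nan)
        m0 = np.where(valid, (y1 - slope * x1) / (1.0 - slope), np.nan)

    lo, hi = t1_bounds
    valid = valid & (t1 >= lo) & (t1 <= hi)
    t1 = np.where(valid, t1, np.nan)
    m0 = np.where(valid, m0, np.nan)

    if scalar:
        return DualAngleFit(float(t1), float(m0), bool(valid))
    return DualAngleFit(t1, m0, valid)


def ernst_angle(t1: float, tr: float) -> float:
    """Flip angle (degrees) maximizing the SPGR signal: arccos(exp(-TR/T1))."""
    if t1 <= 0 or tr <= 0:
        raise ValueError("t1 and tr must be > 0 ms")
    return float(np.degrees(np.arccos(np.exp(-tr / t1))))


def optimal_fa_pair(t1: float, tr: float, signal_fraction: float = 0.71,
                    xtol: float = 1e-8) -> tuple[float, float]:
    """Flip-angle pair whose signals both equal a fraction of the Ernst signal.

    Precision of a two-point T1 fit over a narrow T1 range is maximized by
    acquiring at the two angles where the signal falls to 71% of its
    Ernst-angle maximum, one on each side of the Ernst angle.  The two
    roots are bracketed by the Ernst angle (the signal is monotone on each
    branch) and found by bisection.

    Returns
    -------
    (alpha_low, alpha_high) : degrees, with alpha_low < Ernst < alpha_high.

    Raises
    ------
    RuntimeError
        If a root is not bracketed on (0, 90] (e.g. the high-angle signal
        never falls below the target fraction before 90 degrees).
    """
    if not 0 < signal_fraction < 1:
        raise ValueError("signal_fraction must be in (0, 1)")
    a_e = ernst_angle(t1, tr)
    target = signal_fraction * spgr_signal(1.0, t1, a_e, tr)

    def f(alpha: float) -> float:
        return spgr_signal(1.0, t1, alpha, tr) - target

    eps = 1e-6
    for bracket, name in (((eps, a_e), "low"), ((a_e, 90.0), "high")):
        if f(bracket[0]) * f(bracket[1]) > 0:
            raise RuntimeError(
                f"{name}-angle root not bracketed on {bracket} for "
                f"t1={t1} ms, tr={tr} ms (Ernst angle {a_e:.2f} deg)")
    low = bisect(f, eps, a_e, xtol=xtol)
    high = bisect(f, a_e, 90.0, xtol=xtol)
    return float(low), float(high)
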