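"""Annual-rate-of-change (ARC) arithmetic.

The ARC between two positive levels ``y_start`` (year t) and ``y_end``
(year t+n) is the constant exponential rate, expressed in percent per year,

    ARC = 100 * ln(y_end / y_start) / n .

Projecting forward at a constant ARC is the inverse operation,
``y0 * exp(ARC/100 * k)``, so ``project(y0, arc(y0, y1, n), n) == y1`` up to
floating-point rounding.  Both functions are unit-agnostic: they apply
equally to mortality rates (deaths per 1,000 livebirths) and to coverage
proportions.  The caller chooses the year-count convention; throughout this
package ``n`` is the plain difference of calendar years (2003->2014 gives 11,
2014->2022 gives 8, 2022->2025 gives 3).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["arc", "project", "clamp_coverage", "COVERAGE_FLOOR", "COVERAGE_CEIL"]

#: Coverage proportions are kept inside [COVERAGE_FLOOR, COVERAGE_CEIL]:
#: projections never claim literally universal (100%) coverage — the most
#: ambitious scale-up rule targets 99% — and never exactly zero.
COVERAGE_FLOOR = 0.001
COVERAGE_CEIL = 0.99


def arc(y_start, y_end, n_years):
    """Annual rate of change, in percent per year, between two levels.

    Parameters
    ----------
    y_start, y_end : float or array-like
        Positive levels at the start and end of the interval.
    n_years : int
        Number of years between the two levels (>= 1).

    Returns
    -------
    float or ndarray
        ``100 * ln(y_end / y_start) / n_years``; negative iff the level fell.
    """
    y_start = np.asarray(y_start, dtype=float)
    y_end = np.asarray(y_end, dtype=float)
    if np.any(y_start <= 0) or np.any(y_end <= 0):
        raise ValueError("arc() requires strictly positive levels")
    if n_years < 1:
        raise ValueError("n_years must be a positive integer")
    out = 100.0 * np.log(y_end / y_start) / float(n_years)
    return float(out) if out.ndim == 0 else out


def project(y0, arc_value, k_years):
    """Level after ``k_years`` of constant exponential change at ``arc_value``.

    ``arc_value`` is in percent per year, as returned by :func:`arc`.
    """
    y0 = np.asarray(y0, dtype=float)
    if np.any(y0 <= 0):
        raise ValueError("project() requires a strictly positive baseline")
    if k_years < 0:
        raise ValueError("k_years must be nonnegative")
    arc_value = np.asarray(arc_value, dtype=float)
    out = y0 * np.exp(arc_value / 100.0 * float(k_years))
    return float(out) if out.ndim == 0 else out


def clamp_coverage(value):
    """Clip a coverage proportion into ``[0.001, 0.99]``.

    The 0.99 ceiling mirrors the universal-coverage cap used by the
    scale-up scenarios; the floor keeps log-scale arithmetic defined.
    """
    value = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(value)):
        raise ValueError("coverage must be finite")
    out = np.clip(value, COVERAGE_FLOOR, COVERAGE_CEIL)
    return float(out) if out.ndim == 0 else out
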