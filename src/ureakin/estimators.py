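"""Classical linearisations of the Michaelis-Menten law and rate conversion.

The Lineweaver-Burk (1/v vs 1/S), Eadie-Hofstee (v vs v/S) and Hanes-Woolf
(S/v vs S) transforms each turn the rate law v = V_max S / (K_M + S) into a
straight line whose slope and intercept encode (V_max, K_M).  On noise-free
rate-law data all three recover the generating parameters exactly; on noisy
data they are qualitative cross-checks, not precision estimators, and the
regressions here are deliberately plain unweighted least squares.

The bridge from the normalised maximum rate to an absolute one is
V_max = kbar_V * k_S with the substrate transport constant k_S = D / (l t).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model_core import KineticParameters, TransportModel, steady_state_substrate

__all__ = [
    "RatePoint",
    "vmax_from_normalized",
    "lineweaver_burk",
    "eadie_hofstee",
    "hanes_woolf",
    "rates_from_fit",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RatePoint:
    """One (substrate concentration, reaction rate) observation.

    Both must be strictly positive: every linearisation divides by S or v.
    """

    s: float  # mol/L
    v: float  # mol/(L s)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.s) and self.s > 0):
            raise ValueError(f"s must be finite and > 0, got {self.s!r}")
        if not (np.isfinite(self.v) and self.v > 0):
            raise ValueError(f"v must be finite and > 0, got {self.v!r}")


def vmax_from_normalized(kbar_v: float, transport: TransportModel) -> float:
    """Absolute maximum rate V_max = kbar_V * k_S, in mol/(L s).

    ``k_S`` comes from the transport model, either directly or as
    ``D / (l * t)``.
    """
    if not np.isfinite(kbar_v) or kbar_v < 0:
        raise ValueError(f"kbar_v must be finite and >= 0, got {kbar_v!r}")
    return kbar_v * transport.substrate_rate_constant()


def _prepare(points: Sequence[RatePoint]) -> tuple[np.ndarray, np.ndarray]:
    if len(points) < 2:
        raise ValueError("need at least 2 rate points")
    s = np.array([p.s for p in points])
    v = np.array([p.v for p in points])
    if np.unique(s).size < 2:
        raise ValueError("singular design: all substrate concentrations equal")
    return s, v


def _line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def lineweaver_burk(points: Sequence[RatePoint]) -> tuple[float, float]:
    """(V_max, K_M) from the double-reciprocal plot 1/v vs 1/S."""
    s, v = _prepare(points)
    slope, intercept = _line(1.0 / s, 1.0 / v)
    if intercept == 0:
        raise ValueError("zero intercept: V_max undefined")
    return 1.0 / intercept, slope / intercept


def eadie_hofstee(points: Sequence[RatePoint]) -> tuple[float, float]:
    """(V_max, K_M) from the v vs v/S plot (intercept V_max, slope -K_M)."""
    s, v = _prepare(points)
    slope, intercept = _line(v / s, v)
    return intercept, -slope


def hanes_woolf(points: Sequence[RatePoint]) -> tuple[float, float]:
    """(V_max, K_M) from the S/v vs S plot (slope 1/V_max)."""
    s, v = _prepare(points)
    slope, intercept = _line(s, s / v)
    if slope == 0:
        raise ValueError("zero slope: V_max undefined")
    return 1.0 / slope, intercept / slope


def rates_from_fit(
    params: KineticParameters,
    transport: TransportModel,
    s_b_grid: Sequence[float],
) -> list[RatePoint]:
    """Model reaction rates over a grid of bulk concentrations.

    For each bulk value the layer substrate concentration S is taken from
    the steady-state substrate balance and the rate evaluated as
    ``V_max * S / (K_M + S)`` with V_max from :func:`vmax_from_normalized`.
    This is the bridge from a fitted (K_M, kbar_V) pair to the (S, v) pairs
    the graphical estimators consume; feeding the output back into any of
    the three linearisations returns the generating parameters to machine
    precision.  Zero-concentration grid values are skipped with a log
    notice (the transforms are undefined there).
    """
    v_max = vmax_from_normalized(params.kbar_v, transport)
    s_b_arr = np.asarray(s_b_grid, dtype=float)
    if np.any(~np.isfinite(s_b_arr)) or np.any(s_b_arr < 0):
        raise ValueError("grid values must be finite and >= 0")
    points = []
    n_skipped = 0
    for s_b in s_b_arr:
        if s_b == 0:
            n_skipped += 1
            continue
        s = float(steady_state_substrate(s_b, params))
        points.append(RatePoint(s=s, v=v_max * s / (params.k_m + s)))
    if n_skipped:
        logger.info(
            "rates_from_fit: skipped %d zero-concentration grid value(s)",
            n_skipped,
        )
    return points
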