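"""Steady-state chemistry and kinetics of a pH-based potentiometric enzyme sensor.

The sensing element is an enzyme layer immobilised on a pH-sensitive surface.
Substrate at bulk concentration ``S_B`` exchanges with the layer at a
first-order transport rate, is consumed there by Michaelis-Menten kinetics,
and the protolytic reaction products (an acid HA/A- couple and a base
B/BH+ couple) shift the local proton concentration away from the bulk value.
A pH buffer in the medium (the W couple) opposes that shift.

Under the steady-state approximation the layer concentrations obey algebraic
balances instead of ODEs.  Two of them matter here:

* the substrate balance, whose positive root gives the layer substrate
  concentration ``S`` as a closed form in ``S_B``, ``K_M`` and the
  normalised maximum rate ``kbar_V = V_max / k_S``;
* the proton balance, an implicit equation ``F(H) = 0`` coupling proton
  transport, buffer speciation and the acid/base products of the reaction,
  whose root gives the surface proton concentration and hence the surface pH
  the sensor reads out.

All concentrations are handled internally in mol/L; file and CLI interfaces
convert from mM on ingest.  Proton concentrations are restricted to the
physical window ``[1e-14, 1]`` mol/L (pH 0-14).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "H_MIN",
    "H_MAX",
    "SolverError",
    "BufferSystem",
    "ProductSystem",
    "KineticParameters",
    "TransportModel",
    "SurfaceState",
    "Chemistry",
    "steady_state_substrate",
    "surface_balance_residual",
    "solve_surface_h",
    "solve_surface_h_many",
    "quartic_root_oracle",
    "response_curve",
    "response_curve_table",
]

#: physical proton-concentration window, mol/L (pH 14 .. pH 0)
H_MIN = 1e-14
H_MAX = 1.0

#: number of points in the log-spaced bracketing scan of the proton balance
_SCAN_POINTS = 200


class SolverError(RuntimeError):
    """Raised when the proton-balance root cannot be located unambiguously."""


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class BufferSystem:
    """The pH-buffering acid/base couple of the bulk medium.

    Parameters
    ----------
    c_wb : float
        Total buffer concentration, mol/L.
    ka_w : float
        Acid dissociation constant of the buffer couple, mol/L.
    ph_b : float
        Bulk pH, dimensionless; must lie strictly inside (0, 14).
    kbar_w : float
        Buffer transport rate constant normalised by the substrate
        transport constant, dimensionless.  Equal transport rates for all
        species give the default of 1.
    """

    c_wb: float
    ka_w: float
    ph_b: float
    kbar_w: float = 1.0

    def __post_init__(self) -> None:
        for name in ("c_wb", "ka_w", "ph_b", "kbar_w"):
            _require_finite(name, getattr(self, name))
        if self.c_wb < 0:
            raise ValueError(f"c_wb must be >= 0, got {self.c_wb}")
        if self.ka_w <= 0:
            raise ValueError(f"ka_w must be > 0, got {self.ka_w}")
        if not (0.0 < self.ph_b < 14.0):
            raise ValueError(f"ph_b must be in (0, 14), got {self.ph_b}")
        if self.kbar_w <= 0:
            raise ValueError(f"kbar_w must be > 0, got {self.kbar_w}")

    @property
    def h_b(self) -> float:
        """Bulk proton concentration 10**(-ph_b), mol/L."""
        return 10.0 ** (-self.ph_b)


@dataclass(frozen=True)
class ProductSystem:
    """Protolytic products of the enzymatic reaction.

    ``n_a`` molecules of a weak acid (HA/A- couple, dissociation constant
    ``ka_a``) and ``n_b`` molecules of a weak base (BH+/B couple, constant
    ``ka_b``) are produced per substrate molecule converted.  For urea
    hydrolysis by urease the stoichiometry is one carbonic-acid/bicarbonate
    unit and two ammonium/ammonia units per urea.

    ``n_z`` and ``n_x`` record non-protolytic products and co-substrates for
    bookkeeping only; they do not enter the proton balance.
    """

    n_a: float
    ka_a: float
    n_b: float
    ka_b: float
    n_z: float = 0.0  # documentation only, no proton-balance term
    n_x: float = 0.0  # documentation only (e.g. water consumed)

    def __post_init__(self) -> None:
        for name in ("n_a", "ka_a", "n_b", "ka_b"):
            _require_finite(name, getattr(self, name))
        if self.n_a < 0 or self.n_b < 0:
            raise ValueError("stoichiometric coefficients must be >= 0")
        if self.n_a == 0 and self.n_b == 0:
            raise ValueError("at least one protolytic product is required")
        if self.ka_a <= 0 or self.ka_b <= 0:
            raise ValueError("dissociation constants must be > 0")


@dataclass(frozen=True)
class KineticParameters:
    """The two fitted kinetic quantities.

    ``k_m`` is the apparent Michaelis-Menten constant (mol/L) and ``kbar_v``
    the maximum reaction rate normalised by the substrate transport rate
    constant, ``V_max / k_S``, which carries units of concentration (mol/L)
    in this framework.  ``kbar_v = 0`` is admitted as the exact no-reaction
    limit; fitted values are strictly positive and confined to the
    optimiser box.
    """

    k_m: float
    kbar_v: float

    def __post_init__(self) -> None:
        _require_finite("k_m", self.k_m)
        _require_finite("kbar_v", self.kbar_v)
        if self.k_m <= 0:
            raise ValueError(f"k_m must be > 0, got {self.k_m}")
        if self.kbar_v < 0:
            raise ValueError(f"kbar_v must be >= 0, got {self.kbar_v}")


@dataclass(frozen=True)
class TransportModel:
    """Transport rate constants of the enzyme layer.

    ``kbar_h`` is the proton transport constant normalised by the substrate
    one (1 when all species move at the same rate).  The absolute substrate
    transport constant ``k_s`` (1/s) is only needed to convert the
    normalised maximum rate into an absolute ``V_max``; it may be given
    directly or derived as ``D / (l * t)`` from the substrate diffusion
    constant ``d`` (cm^2/s) and the layer length ``l`` and thickness ``t``
    (cm).
    """

    kbar_h: float = 1.0
    k_s: float | None = None
    d: float | None = None
    l: float | None = None
    t: float | None = None

    def __post_init__(self) -> None:
        _require_finite("kbar_h", self.kbar_h)
        if self.kbar_h <= 0:
            raise ValueError(f"kbar_h must be > 0, got {self.kbar_h}")
        if self.k_s is not None and self.k_s <= 0:
            raise ValueError(f"k_s must be > 0, got {self.k_s}")
        for name in ("d", "l", "t"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")

    def substrate_rate_constant(self) -> float:
        """Return ``k_s`` in 1/s, deriving ``D/(l*t)`` when not given directly."""
        if self.k_s is not None:
            return self.k_s
        if self.d is None or self.l is None or self.t is None:
            raise ValueError(
                "k_s unavailable: provide k_s directly or all of d, l, t"
            )
        return self.d / (self.l * self.t)


@dataclass(frozen=True)
class SurfaceState:
    """Steady-state composition of the enzyme layer at one bulk concentration.

    Attributes
    ----------
    s : float
        Layer substrate concentration, mol/L, ``0 <= s <= s_b``.
    h : float
        Surface proton concentration, mol/L, within [1e-14, 1].
    ha : float
        Proton concentration normalised by the acid product's dissociation
        constant, ``h / ka_a`` (dimensionless).
    ph_surface : float
        ``-log10(h)``.
    """

    s: float
    h: float
    ha: float
    ph_surface: float


@dataclass(frozen=True)
class Chemistry:
    """Bundle of the medium chemistry and transport configuration."""

    buffer: BufferSystem
    products: ProductSystem
    transport: TransportModel = field(default_factory=TransportModel)
    label: str = ""

    def with_buffer(self, **kwargs) -> "Chemistry":
        return replace(self, buffer=replace(self.buffer, **kwargs))


# ---------------------------------------------------------------------------
# steady-state substrate balance
# ---------------------------------------------------------------------------

def steady_state_substrate(s_b, params: KineticParameters):
    """Layer substrate concentration at steady state.

    Solves the quadratic substrate balance

        ``S_B - S - kbar_V * S / (K_M + S) = 0``

    for its unique non-negative root.  The evaluation uses the
    numerically stable branch of the quadratic formula, so the balance is
    zeroed to machine precision even when ``K_M + kbar_V >> S_B``.

    Accepts a scalar or array ``s_b`` (mol/L) and returns the same shape.
    """
    s_b = np.asarray(s_b, dtype=float)
    if not np.all(np.isfinite(s_b)):
        raise ValueError("s_b must be finite")
    if np.any(s_b < 0):
        raise ValueError("s_b must be >= 0")
    k_m, kv = params.k_m, params.kbar_v
    b = k_m + kv - s_b
    sq = np.sqrt(b * b + 4.0 * k_m * s_b)
    # b > 0: avoid cancellation in (-b + sq) by rationalising the numerator
    with np.errstate(divide="ignore", invalid="ignore"):
        s_pos = 2.0 * k_m * s_b / (b + sq)
    s_neg = 0.5 * (sq - b)
    s = np.where(b > 0, s_pos, s_neg)
    s = np.clip(s, 0.0, s_b)
    return s if s.ndim else float(s)


# ---------------------------------------------------------------------------
# implicit proton balance
# ---------------------------------------------------------------------------

def surface_balance_residual(
    ha,
    s_b,
    buffer: BufferSystem,
    products: ProductSystem,
    params: KineticParameters,
    transport: TransportModel,
):
    """Evaluate the steady-state proton balance at normalised concentration Ha.

    The balance sums three proton fluxes into the layer (mol/L scaled):
    direct proton transport ``kbar_H * (H_B - H)``, release from the buffer
    couple as its speciation re-equilibrates, and net production by the
    protolytic reaction products, weighted by the Michaelis-Menten
    saturation ``S / (K_M + S)`` at the steady-state layer substrate
    concentration.  The surface proton concentration is the root of this
    residual.

    ``ha`` is ``H / ka_a``; scalars or arrays broadcast.
    """
    ha = np.asarray(ha, dtype=float)
    if np.any(~np.isfinite(ha)) or np.any(ha <= 0):
        raise ValueError("ha must be finite and > 0")
    h = ha * products.ka_a
    h_b = buffer.h_b
    s = steady_state_substrate(s_b, params)
    rate = params.kbar_v * s / (params.k_m + s)
    transport_term = transport.kbar_h * (h_b - h)
    buffer_term = buffer.kbar_w * buffer.c_wb * (
        h_b / (h_b + buffer.ka_w) - h / (h + buffer.ka_w)
    )
    reaction_term = rate * (
        products.n_a * products.ka_a / (products.ka_a + h)
        - products.n_b * h / (h + products.ka_b)
    )
    out = transport_term + buffer_term + reaction_term
    return out if out.ndim else float(out)


def _residual_prime_h(h, s_b, buffer, products, params, transport):
    """d(residual)/dH; strictly negative on (0, inf)."""
    s = steady_state_substrate(s_b, params)
    rate = params.kbar_v * s / (params.k_m + s)
    return (
        -transport.kbar_h
        - buffer.kbar_w * buffer.c_wb * buffer.ka_w / (h + buffer.ka_w) ** 2
        - rate * products.n_a * products.ka_a / (products.ka_a + h) ** 2
        - rate * products.n_b * products.ka_b / (h + products.ka_b) ** 2
    )


def _scalar_residual(s_b, buffer, products, params, transport):
    """Float-only residual closure for root refinement (no array overhead)."""
    h_b = buffer.h_b
    s = float(steady_state_substrate(s_b, params))
    rate = params.kbar_v * s / (params.k_m + s)
    ka_w, ka_a, ka_b = buffer.ka_w, products.ka_a, products.ka_b
    kbar_h = transport.kbar_h
    cw = buffer.kbar_w * buffer.c_wb
    alpha_b = h_b / (h_b + ka_w)
    n_a, n_b = products.n_a, products.n_b

    def f(h: float) -> float:
        return (
            kbar_h * (h_b - h)
            + cw * (alpha_b - h / (h + ka_w))
            + rate * (n_a * ka_a / (ka_a + h) - n_b * h / (h + ka_b))
        )

    return f


def _scan_brackets(f_grid: np.ndarray, h_grid: np.ndarray) -> list[tuple[float, float]]:
    """Sign-change intervals of a residual sampled on a grid."""
    sign = np.sign(f_grid)
    zeros = np.nonzero(sign == 0.0)[0]
    nz = np.nonzero(sign)[0]
    crossings = nz[:-1][sign[nz[:-1]] * sign[nz[1:]] < 0] if nz.size > 1 else np.array([], int)
    brackets: list[tuple[float, float]] = [(h_grid[i], h_grid[i]) for i in zeros]
    for i in crossings:
        # bracket between the last nonzero point before and the next after
        j = nz[nz > i][0]
        brackets.append((h_grid[i], h_grid[j]))
    brackets.sort()
    return brackets


def _solve_one(s_b, buffer, products, params, transport, f_grid, h_grid) -> SurfaceState:
    brackets = _scan_brackets(f_grid, h_grid)
    if len(brackets) == 0:
        raise SolverError(
            "proton balance has no sign change on the physical bracket "
            f"H in [{H_MIN:g}, {H_MAX:g}] mol/L at S_B = {s_b:g} mol/L; "
            f"endpoint residuals {f_grid[0]:+.3e} and {f_grid[-1]:+.3e}"
        )
    if len(brackets) > 1:
        raise SolverError(
            f"proton balance changes sign {len(brackets)} times on the "
            f"physical bracket at S_B = {s_b:g} mol/L; refusing to pick a "
            "root silently - check the chemistry configuration"
        )
    h_lo, h_hi = brackets[0]
    if h_lo == h_hi:  # exact zero on the scan grid
        h = h_lo
    else:
        f = _scalar_residual(s_b, buffer, products, params, transport)
        h = brentq(
            f, h_lo, h_hi, xtol=1e-30, rtol=4 * np.finfo(float).eps, maxiter=200
        )
    s = float(steady_state_substrate(s_b, params))
    return SurfaceState(s=s, h=h, ha=h / products.ka_a, ph_surface=-math.log10(h))


def solve_surface_h(
    s_b: float,
    buffer: BufferSystem,
    products: ProductSystem,
    params: KineticParameters,
    transport: TransportModel,
) -> SurfaceState:
    """Solve the proton balance for the surface state at one bulk concentration.

    The root is bracketed by a 200-point log-spaced scan of the residual
    over the physical window ``H in [1e-14, 1]`` mol/L and refined by
    Brent's method to machine relative tolerance.  Exactly one sign change
    is required: zero sign changes or more than one raise
    :class:`SolverError` rather than silently picking a root (for every
    physically sensible chemistry the residual is strictly decreasing in H,
    so multiplicity signals a misconfiguration).
    """
    if not math.isfinite(s_b) or s_b < 0:
        raise ValueError(f"s_b must be finite and >= 0, got {s_b!r}")
    h_grid = np.logspace(math.log10(H_MIN), math.log10(H_MAX), _SCAN_POINTS)
    f_grid = surface_balance_residual(
        h_grid / products.ka_a, s_b, buffer, products, params, transport
    )
    return _solve_one(s_b, buffer, products, params, transport, f_grid, h_grid)


def solve_surface_h_many(
    s_b_values: Sequence[float],
    buffer: BufferSystem,
    products: ProductSystem,
    params: KineticParameters,
    transport: TransportModel,
) -> list[SurfaceState]:
    """Vectorised counterpart of :func:`solve_surface_h`.

    The bracketing scan for all bulk concentrations is evaluated as one
    broadcast array operation; each root is then refined individually.
    Solver failures are re-raised with the offending grid value named.
    """
    s_b_arr = np.asarray(s_b_values, dtype=float)
    if s_b_arr.ndim != 1:
        raise ValueError("s_b_values must be one-dimensional")
    if not np.all(np.isfinite(s_b_arr)) or np.any(s_b_arr < 0):
        raise ValueError("all bulk concentrations must be finite and >= 0")
    h_grid = np.logspace(math.log10(H_MIN), math.log10(H_MAX), _SCAN_POINTS)
    f_matrix = surface_balance_residual(
        h_grid[None, :] / products.ka_a,
        s_b_arr[:, None],
        buffer,
        products,
        params,
        transport,
    )
    states = []
    for i, s_b in enumerate(s_b_arr):
        try:
            states.append(
                _solve_one(
                    float(s_b), buffer, products, params, transport,
                    f_matrix[i], h_grid,
                )
            )
        except SolverError as err:
            raise SolverError(
                f"surface-pH solve failed at grid value S_B = {s_b:g} mol/L: {err}"
            ) from err
    return states


# ---------------------------------------------------------------------------
# polynomial oracle
# ---------------------------------------------------------------------------

def quartic_root_oracle(
    s_b: float,
    buffer: BufferSystem,
    products: ProductSystem,
    params: KineticParameters,
    transport: TransportModel,
) -> list[float]:
    """All physical roots of the proton balance via its polynomial expansion.

    Clearing the three denominators ``(H + Ka_W)(H + Ka_A)(H + Ka_B)`` turns
    the proton balance into a degree-4 polynomial in H.  Its real positive
    roots are found from the companion matrix, polished with a few Newton
    steps on the *unexpanded* residual, and accepted only if that residual
    is below 1e-8 times the natural magnitude scale of its additive terms —
    clearing denominators can manufacture spurious roots at the pole
    locations, and those fail the guard.

    Returns the accepted roots as normalised concentrations ``Ha = H/Ka_A``,
    sorted ascending.  This routine shares no code path with
    :func:`solve_surface_h` and serves as its independent cross-check.
    """
    if not math.isfinite(s_b) or s_b < 0:
        raise ValueError(f"s_b must be finite and >= 0, got {s_b!r}")
    ka_a, ka_b = products.ka_a, products.ka_b
    ka_w, h_b = buffer.ka_w, buffer.h_b
    s = float(steady_state_substrate(s_b, params))
    rate = params.kbar_v * s / (params.k_m + s)

    lin_w = np.array([1.0, ka_w])
    lin_a = np.array([1.0, ka_a])
    lin_b = np.array([1.0, ka_b])
    # transport term: kbar_h (h_b - H) (H+Ka_W)(H+Ka_A)(H+Ka_B)
    p1 = transport.kbar_h * np.polymul(
        np.array([-1.0, h_b]), np.polymul(np.polymul(lin_w, lin_a), lin_b)
    )
    # buffer term: c_wb kbar_w [alpha_B(h_b) (H+Ka_W) - H] (H+Ka_A)(H+Ka_B)
    alpha_b = h_b / (h_b + ka_w)
    p2 = buffer.kbar_w * buffer.c_wb * np.polymul(
        np.polyadd(alpha_b * lin_w, np.array([-1.0, 0.0])),
        np.polymul(lin_a, lin_b),
    )
    # reaction term: rate [n_a Ka_A (H+Ka_B) - n_b H (H+Ka_A)] (H+Ka_W)
    p3 = rate * np.polymul(
        np.polyadd(
            products.n_a * ka_a * lin_b,
            np.polymul(np.array([-products.n_b, 0.0]), lin_a),
        ),
        lin_w,
    )
    poly = np.polyadd(np.polyadd(p1, p2), p3)
    roots = np.roots(poly)

    # magnitude scale of the unexpanded residual's additive terms
    def scale_at(h: float) -> float:
        return (
            transport.kbar_h * max(h_b, h)
            + buffer.kbar_w * buffer.c_wb
            + rate * (products.n_a + products.n_b)
        )

    f = _scalar_residual(s_b, buffer, products, params, transport)

    accepted: list[float] = []
    for root in roots:
        if abs(root.imag) > 1e-8 * max(abs(root.real), 1e-300):
            continue
        h = float(root.real)
        if h <= 0:
            continue
        # a few damped Newton polishes on the unexpanded residual
        for _ in range(6):
            fp = _residual_prime_h(h, s_b, buffer, products, params, transport)
            if fp == 0:
                break
            step = f(h) / fp
            h_new = h - step
            if h_new <= 0:
                h_new = h / 2.0
            if abs(h_new - h) <= 1e-16 * h:
                h = h_new
                break
            h = h_new
        if abs(f(h)) > 1e-8 * scale_at(h):
            continue  # spurious root introduced by clearing denominators
        ha = h / ka_a
        if any(abs(ha - prev) <= 1e-6 * max(ha, prev) for prev in accepted):
            continue
        accepted.append(ha)
    return sorted(accepted)


# ---------------------------------------------------------------------------
# response curve
# ---------------------------------------------------------------------------

def response_curve(
    s_b_grid: Sequence[float],
    buffer: BufferSystem,
    products: ProductSystem,
    params: KineticParameters,
    transport: TransportModel,
    medium_label: str = "",
):
    """Model-predicted calibration curve over a grid of bulk concentrations.

    Applies :func:`solve_surface_h` pointwise (via the vectorised scan) and
    returns a :class:`~ureakin.dataset.CalibrationDataset` preserving the
    input order, duplicates included.  For the urea presets (net base
    production, ``n_b > n_a`` near neutral pH) the predicted surface pH is
    non-decreasing in ``S_B``.
    """
    from .dataset import CalibrationDataset  # deferred: dataset has no runtime dep on us

    states = solve_surface_h_many(s_b_grid, buffer, products, params, transport)
    chem = Chemistry(buffer=buffer, products=products, transport=transport,
                     label=medium_label)
    return CalibrationDataset(
        s_b=np.asarray(s_b_grid, dtype=float),
        ph=np.array([st.ph_surface for st in states]),
        medium_label=medium_label,
        chemistry=chem,
        canonical=False,
        provenance={
            "kind": "model_response_curve",
            "k_m": params.k_m,
            "kbar_v": params.kbar_v,
        },
    )


def response_curve_table(
    s_b_grid: Sequence[float],
    buffer: BufferSystem,
    products: ProductSystem,
    params: KineticParameters,
    transport: TransportModel,
):
    """Model curve as a table with the full surface state per grid point.

    Columns: ``s_b_mM`` (bulk substrate, mM), ``pH_surface``,
    ``S_layer_mM`` (layer substrate, mM), ``H_surface_M`` (proton
    concentration, mol/L).
    """
    import pandas as pd

    states = solve_surface_h_many(s_b_grid, buffer, products, params, transport)
    return pd.DataFrame(
        {
            "s_b_mM": np.asarray(s_b_grid, dtype=float) * 1e3,
            "pH_surface": [st.ph_surface for st in states],
            "S_layer_mM": [st.s * 1e3 for st in states],
            "H_surface_M": [st.h for st in states],
        }
    )
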