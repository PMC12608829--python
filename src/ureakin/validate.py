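"""Self-contained invariant battery runnable from the CLI.

A fast smoke check of the model's structural guarantees on randomised
chemistries: the zero-substrate fixed point, steady-state substrate
consistency, agreement between the bracketed root and the polynomial
oracle, and response monotonicity for the urea stoichiometry.
"""

from __future__ import annotations

import numpy as np

from .config import load_chemistry
from .model_core import (
    KineticParameters,
    quartic_root_oracle,
    response_curve,
    solve_surface_h,
    steady_state_substrate,
)

__all__ = ["run_validation"]


def _random_chemistry(rng: np.random.Generator):
    from .model_core import BufferSystem, ProductSystem, TransportModel

    buffer = BufferSystem(
        c_wb=10.0 ** rng.uniform(-5, -2),
        ka_w=10.0 ** rng.uniform(-9, -5),
        ph_b=rng.uniform(5.0, 9.0),
        kbar_w=10.0 ** rng.uniform(-0.5, 0.5),
    )
    products = ProductSystem(
        n_a=float(rng.integers(1, 3)),
        ka_a=10.0 ** rng.uniform(-8, -4),
        n_b=float(rng.integers(1, 3)),
        ka_b=10.0 ** rng.uniform(-11, -8),
    )
    transport = TransportModel(kbar_h=10.0 ** rng.uniform(-0.5, 0.5))
    params = KineticParameters(
        k_m=10.0 ** rng.uniform(-4, -1), kbar_v=10.0 ** rng.uniform(-8, -2)
    )
    s_b = float(10.0 ** rng.uniform(-5, -1.3))
    return buffer, products, params, transport, s_b


def run_validation(seed: int = 0, n_random: int = 50) -> dict[str, bool]:
    """Run the invariant battery; returns {check name: passed}."""
    rng = np.random.default_rng(seed)
    checks: dict[str, bool] = {}
    pbs = load_chemistry("pbs_urea")
    params = KineticParameters(k_m=10.88e-3, kbar_v=2.2e-4)

    state0 = solve_surface_h(0.0, pbs.buffer, pbs.products, params, pbs.transport)
    checks["zero_substrate_fixed_point"] = (
        abs(state0.ph_surface - pbs.buffer.ph_b) < 1e-9
    )

    ok = True
    for _ in range(n_random):
        k_m = 10.0 ** rng.uniform(-4, -1)
        kv = 10.0 ** rng.uniform(-8, -2)
        s_b = 10.0 ** rng.uniform(-5, -1)
        p = KineticParameters(k_m=k_m, kbar_v=kv)
        s = steady_state_substrate(s_b, p)
        balance = s_b - s - kv * s / (k_m + s)
        ok &= abs(balance) < 1e-10 * max(s_b, k_m)
    checks["steady_state_consistency"] = bool(ok)

    ok = True
    for _ in range(n_random):
        buffer, products, p, transport, s_b = _random_chemistry(rng)
        state = solve_surface_h(s_b, buffer, products, p, transport)
        roots = quartic_root_oracle(s_b, buffer, products, p, transport)
        ok &= any(abs(r - state.ha) < 1e-8 * state.ha for r in roots)
    checks["oracle_equivalence"] = bool(ok)

    grid = np.geomspace(1e-4, 5e-2, 10)
    curve = response_curve(grid, pbs.buffer, pbs.products, params, pbs.transport)
    checks["urea_response_monotone"] = bool(np.all(np.diff(curve.ph) >= -1e-12))

    tiny = KineticParameters(k_m=10.88e-3, kbar_v=1e-14)
    curve0 = response_curve(grid, pbs.buffer, pbs.products, tiny, pbs.transport)
    checks["no_reaction_limit"] = bool(
        np.all(np.abs(curve0.ph - pbs.buffer.ph_b) < 1e-6)
    )
    return checks
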