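"""Synthetic calibration data with the statistical structure the fit assumes.

No public measurement set accompanies this sensor model, so every stage of
the pipeline is exercised on generated data: pH-vs-concentration calibration
tables (model response plus additive Gaussian pH noise) and raw
constant-capacitance voltage traces (exponential settling toward the
voltage encoding the model pH, plus Gaussian voltage noise).

Defaults mirror the experimental design the model targets: urea from
0.1 to 50 mM plus a zero point, bulk pH 7.4, a PBS-like 0.33 mM buffer, a
sensor sensitivity of 33 mV per pH unit (mid-range of typical 30-35 mV
readouts), and pH noise of 0.02 units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import CalibrationDataset
from .model_core import Chemistry, KineticParameters, solve_surface_h_many
from .preprocessing import DEFAULT_WINDOW, SensorCalibration, VoltageTrace, ph_to_voltage

__all__ = ["DEFAULT_GRID", "TraceOptions", "GeneratorSpec",
           "generate_dataset", "generate_voltage_traces"]

#: default bulk-concentration grid, mol/L: zero plus 0.1-50 mM
DEFAULT_GRID = (0.0, 1e-4, 3e-4, 1e-3, 3e-3, 1e-2, 3e-2, 5e-2)


@dataclass(frozen=True)
class TraceOptions:
    """Shape of synthetic CONCAP voltage traces.

    ``duration`` defaults to twelve settling times so the trailing-window
    average sits within ``exp(-10)`` of the target voltage, and the default
    sampling keeps well over the 100 samples the reduction window needs.
    """

    sampling_rate: float = 2.0  # Hz
    duration: float = 600.0  # s
    settling_tau: float = 50.0  # s
    voltage_noise_sd: float = 5e-4  # V
    cal: SensorCalibration | None = None  # derived from the chemistry if None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.duration <= 0 or self.settling_tau <= 0:
            raise ValueError("sampling_rate, duration and settling_tau must be > 0")
        if self.voltage_noise_sd < 0:
            raise ValueError("voltage_noise_sd must be >= 0")


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything needed to generate one synthetic calibration experiment."""

    chemistry: Chemistry
    truth: KineticParameters
    s_b_grid: Sequence[float] = DEFAULT_GRID
    noise_sd_ph: float = 0.02
    seed: int = 0
    trace_options: TraceOptions = field(default_factory=TraceOptions)

    def __post_init__(self) -> None:
        grid = np.asarray(self.s_b_grid, dtype=float)
        if np.any(~np.isfinite(grid)) or np.any(grid < 0):
            raise ValueError("grid values must be finite and >= 0")
        if self.noise_sd_ph < 0:
            raise ValueError("noise_sd_ph must be >= 0")

    def calibration(self) -> SensorCalibration:
        """The voltage map used for trace synthesis (33 mV/pH by default)."""
        if self.trace_options.cal is not None:
            return self.trace_options.cal
        return SensorCalibration(
            ph0=self.chemistry.buffer.ph_b, v0=0.5, s_ph=0.033
        )


def _model_ph(spec: GeneratorSpec) -> np.ndarray:
    chem = spec.chemistry
    states = solve_surface_h_many(
        np.asarray(spec.s_b_grid, dtype=float),
        chem.buffer, chem.products, spec.truth, chem.transport,
    )
    return np.array([st.ph_surface for st in states])


def generate_dataset(spec: GeneratorSpec) -> CalibrationDataset:
    """Model response curve plus seeded additive Gaussian pH noise.

    With ``noise_sd_ph = 0`` the output equals the noise-free model curve
    exactly; with a fixed seed the output is bit-reproducible.  The
    generating truth is recorded in the dataset provenance so recovery
    studies can score themselves.
    """
    ph_model = _model_ph(spec)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd_ph, size=ph_model.shape)
    return CalibrationDataset(
        s_b=np.asarray(spec.s_b_grid, dtype=float),
        ph=ph_model + noise,
        medium_label=spec.chemistry.label,
        chemistry=spec.chemistry,
        provenance={
            "kind": "synthetic_dataset",
            "truth_k_m": spec.truth.k_m,
            "truth_kbar_v": spec.truth.kbar_v,
            "noise_sd_ph": spec.noise_sd_ph,
            "seed": spec.seed,
        },
    )


def generate_voltage_traces(spec: GeneratorSpec) -> list[VoltageTrace]:
    """Synthetic CONCAP traces, one per grid concentration.

    Each trace settles exponentially from the starting voltage ``V0``
    toward the voltage encoding the noise-free model pH,

        ``V(t) = V_target + (V0 - V_target) exp(-t / tau) + eta(t)``,

    with seeded Gaussian sample noise ``eta``.  The trace noise — not the
    pH noise of :func:`generate_dataset` — is the error source for
    end-to-end pipeline tests.
    """
    opts = spec.trace_options
    n_samples = int(np.floor(opts.duration * opts.sampling_rate))
    if n_samples < DEFAULT_WINDOW:
        raise ValueError(
            f"duration x sampling_rate gives {n_samples} samples; at least "
            f"{DEFAULT_WINDOW} are required by the reduction window"
        )
    cal = spec.calibration()
    ph_model = _model_ph(spec)
    rng = np.random.default_rng(spec.seed)
    times = np.arange(n_samples) / opts.sampling_rate
    traces = []
    for s_b, ph in zip(np.asarray(spec.s_b_grid, dtype=float), ph_model):
        v_target = ph_to_voltage(ph, cal)
        decay = (cal.v0 - v_target) * np.exp(-times / opts.settling_tau)
        eta = rng.normal(0.0, opts.voltage_noise_sd, size=n_samples)
        traces.append(
            VoltageTrace(
                times=times,
                voltages=v_target + decay + eta,
                s_b=float(s_b),
                sensor_id="synthetic-1",
                medium_label=spec.chemistry.label,
            )
        )
    return traces
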