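"""Raw sensor-trace reduction: constant-capacitance voltage to calibration pH.

In constant-capacitance (CONCAP) mode the instrument records the bias
voltage holding the sensor capacitance fixed; after the enzymatic reaction
reaches a pseudo steady state the trace settles to a plateau.  The plateau
is estimated as the arithmetic mean of the last 100 samples, and converted
to pH through the linear sensor map

    pH = pH0 + (V0 - Vx) / S_pH

where (pH0, V0) are the urea-free starting point and S_pH the sensitivity
in volts per pH unit.  With the positive-S_pH convention used throughout
this package, alkalinisation of the surface (the urease response) shows up
as a voltage *decrease*.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import CalibrationDataset
from .model_core import Chemistry

__all__ = [
    "DEFAULT_WINDOW",
    "VoltageTrace",
    "SensorCalibration",
    "concap_reduce",
    "voltage_to_ph",
    "build_dataset",
    "load_traces",
    "write_traces",
]

#: number of trailing samples averaged to the plateau voltage
DEFAULT_WINDOW = 100


@dataclass
class VoltageTrace:
    """One CONCAP recording at a single bulk substrate concentration."""

    times: np.ndarray  # s, strictly increasing
    voltages: np.ndarray  # V
    s_b: float  # mol/L
    sensor_id: str = ""
    medium_label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.times.shape != self.voltages.shape or self.times.ndim != 1:
            raise ValueError("times and voltages must be 1-D and equal length")
        if len(self.times) < DEFAULT_WINDOW:
            raise ValueError(
                f"trace needs at least {DEFAULT_WINDOW} samples for the "
                f"plateau average, got {len(self.times)}"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.isfinite(self.s_b) or self.s_b < 0:
            raise ValueError(f"s_b must be finite and >= 0, got {self.s_b!r}")


@dataclass(frozen=True)
class SensorCalibration:
    """Linear voltage-to-pH map of the transducer."""

    ph0: float  # starting pH (urea-free)
    v0: float  # starting voltage, V
    s_ph: float  # sensitivity, V per pH unit; nonzero

    def __post_init__(self) -> None:
        if not (0.0 < self.ph0 < 14.0):
            raise ValueError(f"ph0 must be in (0, 14), got {self.ph0}")
        if self.s_ph == 0 or not np.isfinite(self.s_ph):
            raise ValueError("s_ph must be nonzero and finite")


def concap_reduce(
    trace: VoltageTrace,
    window: int = DEFAULT_WINDOW,
    drift_warn_slope: float | None = None,
) -> float:
    """Plateau voltage: mean of the last ``window`` samples of the trace.

    Raises rather than shrinking the window when the trace is too short.
    If ``drift_warn_slope`` (V/s) is given, a warning is emitted when the
    straight-line slope over the window exceeds it in magnitude — a hint
    that the pseudo steady state had not been reached.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    if len(trace.voltages) < window:
        raise ValueError(
            f"trace has {len(trace.voltages)} samples, fewer than the "
            f"averaging window of {window}"
        )
    tail_t = trace.times[-window:]
    tail_v = trace.voltages[-window:]
    if drift_warn_slope is not None:
        slope = np.polyfit(tail_t, tail_v, 1)[0]
        if abs(slope) > drift_warn_slope:
            warnings.warn(
                f"trace at S_B = {trace.s_b:g} mol/L drifts at "
                f"{slope:.3e} V/s over the averaging window",
                stacklevel=2,
            )
    return float(np.mean(tail_v))


def voltage_to_ph(vx: float, cal: SensorCalibration) -> float:
    """Linear voltage-to-pH conversion, ``pH0 + (V0 - Vx) / S_pH``."""
    return cal.ph0 + (cal.v0 - vx) / cal.s_ph


def ph_to_voltage(ph: float, cal: SensorCalibration) -> float:
    """Inverse of :func:`voltage_to_ph` (used by the trace generator)."""
    return cal.v0 - cal.s_ph * (ph - cal.ph0)


def build_dataset(
    traces: list[VoltageTrace],
    cal: SensorCalibration | None = None,
    chemistry: Chemistry | None = None,
    s_ph: float | None = None,
    window: int = DEFAULT_WINDOW,
) -> CalibrationDataset:
    """Reduce a set of traces to a canonical calibration dataset.

    Each trace is collapsed to its plateau voltage and converted to pH.
    When ``cal`` is omitted, the zero-concentration trace defines the
    starting point: its plateau becomes ``V0`` and the bulk pH of
    ``chemistry`` becomes ``pH0`` (both ``chemistry`` and the sensitivity
    ``s_ph`` are then required).

    All traces must share a sensor id and have distinct concentrations.
    """
    if not traces:
        raise ValueError("no traces given")
    ids = {t.sensor_id for t in traces}
    if len(ids) > 1:
        raise ValueError(f"traces come from different sensors: {sorted(ids)}")
    dupes = [s for s, k in Counter(t.s_b for t in traces).items() if k > 1]
    if dupes:
        raise ValueError(
            "duplicate bulk concentrations (mol/L): "
            + ", ".join(f"{v:g}" for v in sorted(dupes))
        )
    if cal is None:
        zero = [t for t in traces if t.s_b == 0]
        if not zero:
            raise ValueError(
                "no explicit calibration and no zero-concentration trace "
                "to define (pH0, V0)"
            )
        if chemistry is None or s_ph is None:
            raise ValueError(
                "deriving the calibration from the zero-concentration trace "
                "requires both `chemistry` (for pH0) and `s_ph`"
            )
        cal = SensorCalibration(
            ph0=chemistry.buffer.ph_b,
            v0=concap_reduce(zero[0], window=window),
            s_ph=s_ph,
        )
    ordered = sorted(traces, key=lambda t: t.s_b)
    s_b = np.array([t.s_b for t in ordered])
    ph = np.array(
        [voltage_to_ph(concap_reduce(t, window=window), cal) for t in ordered]
    )
    labels = {t.medium_label for t in ordered if t.medium_label}
    return CalibrationDataset(
        s_b=s_b,
        ph=ph,
        medium_label=labels.pop() if len(labels) == 1 else "",
        chemistry=chemistry,
        provenance={
            "kind": "concap_reduction",
            "window": window,
            "sensor_id": ordered[0].sensor_id,
            "cal": {"ph0": cal.ph0, "v0": cal.v0, "s_ph": cal.s_ph},
        },
    )


# ---------------------------------------------------------------------------
# file interface: one CSV per trace plus a JSON manifest
# ---------------------------------------------------------------------------

def write_traces(traces: list[VoltageTrace], out_dir: str | Path) -> Path:
    """Write trace CSVs (columns time_s, voltage_V) and a manifest JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"sensor_id": traces[0].sensor_id if traces else "", "traces": {}}
    for i, trace in enumerate(traces):
        name = f"trace_{i:03d}.csv"
        pd.DataFrame(
            {"time_s": trace.times, "voltage_V": trace.voltages}
        ).to_csv(out_dir / name, index=False)
        manifest["traces"][name] = {
            "s_b_mM": trace.s_b * 1e3,
            "medium_label": trace.medium_label,
        }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def load_traces(manifest_path: str | Path) -> list[VoltageTrace]:
    """Read traces back from a manifest written by :func:`write_traces`."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    traces = []
    for name, meta in sorted(manifest["traces"].items()):
        frame = pd.read_csv(manifest_path.parent / name)
        traces.append(
            VoltageTrace(
                times=frame["time_s"].to_numpy(dtype=float),
                voltages=frame["voltage_V"].to_numpy(dtype=float),
                s_b=float(meta["s_b_mM"]) * 1e-3,
                sensor_id=manifest.get("sensor_id", ""),
                medium_label=meta.get("medium_label", ""),
            )
        )
    return traces
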