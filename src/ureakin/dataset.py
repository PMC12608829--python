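"""Calibration datasets: ordered (bulk concentration, surface pH) points.

The dataset is the fit's observable surface.  Canonical datasets — the ones
the fitting routines accept — are sorted by bulk concentration with strictly
increasing, duplicate-free values.  Model response curves relax that (they
preserve the caller's grid order, duplicates included) by constructing with
``canonical=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .model_core import Chemistry

__all__ = ["CalibrationDataset"]


@dataclass
class CalibrationDataset:
    """Ordered (S_B, pH) calibration points plus chemistry context.

    Parameters
    ----------
    s_b : array-like
        Bulk substrate concentrations, mol/L, all >= 0.
    ph : array-like
        Observed (or model) surface pH values, each in (0, 14).
    medium_label : str
        Free-text description of the medium (e.g. ``"PBS"``).
    chemistry : Chemistry, optional
        Buffer/product/transport configuration the points refer to; required
        by the fitting routines.
    canonical : bool
        When true (default), points are sorted by ``s_b`` and duplicate
        concentrations raise ``ValueError``.
    provenance : dict
        Free-form metadata (generator truth, seeds, file origins ...).
    """

    s_b: np.ndarray
    ph: np.ndarray
    medium_label: str = ""
    chemistry: "Chemistry | None" = None
    canonical: bool = True
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s_b = np.atleast_1d(np.asarray(self.s_b, dtype=float))
        self.ph = np.atleast_1d(np.asarray(self.ph, dtype=float))
        if self.s_b.shape != self.ph.shape or self.s_b.ndim != 1:
            raise ValueError("s_b and ph must be one-dimensional and equal length")
        if len(self.s_b) == 0:
            raise ValueError("dataset must contain at least one point")
        if not np.all(np.isfinite(self.s_b)) or not np.all(np.isfinite(self.ph)):
            raise ValueError("dataset values must be finite")
        if np.any(self.s_b < 0):
            raise ValueError("bulk concentrations must be >= 0")
        if np.any(self.ph <= 0) or np.any(self.ph >= 14):
            raise ValueError("pH values must lie strictly inside (0, 14)")
        if self.canonical:
            order = np.argsort(self.s_b, kind="stable")
            self.s_b = self.s_b[order]
            self.ph = self.ph[order]
            dupes = self.s_b[:-1][np.diff(self.s_b) == 0]
            if dupes.size:
                raise ValueError(
                    "duplicate bulk concentrations (mol/L): "
                    + ", ".join(f"{v:g}" for v in np.unique(dupes))
                )

    def __len__(self) -> int:
        return len(self.s_b)

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.s_b.tolist(), self.ph.tolist()))

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with concentrations in mM (the file-interface unit)."""
        return pd.DataFrame({"s_b_mM": self.s_b * 1e3, "pH": self.ph})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        medium_label: str = "",
        chemistry: "Chemistry | None" = None,
    ) -> "CalibrationDataset":
        """Read a calibration table with columns ``s_b_mM`` and ``pH``."""
        frame = pd.read_csv(path)
        missing = {"s_b_mM", "pH"} - set(frame.columns)
        if missing:
            raise ValueError(
                f"{path}: missing required columns {sorted(missing)}"
            )
        return cls(
            s_b=frame["s_b_mM"].to_numpy(dtype=float) * 1e-3,
            ph=frame["pH"].to_numpy(dtype=float),
            medium_label=medium_label,
            chemistry=chemistry,
            provenance={"source": str(path)},
        )
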