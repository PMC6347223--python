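"""Per-cell descriptors of a filament network.

Three scalar parameters summarise the F-actin network of one cell from its
table of detected straight filaments (length l_i, width w_i, orientation
angle alpha_i to the horizontal):

* circular standard deviation  ``nu = sqrt(-2 ln R)``  where
  ``R = (1/n) * sqrt((sum sin a_i)^2 + (sum cos a_i)^2)`` is the normalised
  resultant length of the orientations taken as unit vectors — small nu
  means parallel filaments, large nu a branched/isotropic network;
* F-actin content  ``F = sum l_i * w_i``  (um^2), an area proxy for the
  total amount of polymerised actin;
* mean filament length  ``L = (1/n) * sum l_i``  (um).

Angles are stored in degrees in [0, 180) ("angle to the horizontal") and
converted to radians only inside trigonometric calls.  Orientations are used
literally as unit vectors — no axial doubling — matching the measurement
convention the descriptors were defined under; pass ``doubled_angles=True``
to use the axial-statistics variant instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Filament",
    "FilamentSet",
    "CellMetrics",
    "resultant_length",
    "circular_std",
    "f_actin_content",
    "mean_filament_length",
    "cell_metrics",
    "UndefinedMetricsError",
]

#: below this resultant length nu is reported as +inf instead of raising,
#: so cohort processing can continue (such cells are excluded downstream)
R_FLOOR = 1e-12

FILAMENT_COLUMNS = ["length_um", "width_um", "theta_deg", "x_um", "y_um"]


class UndefinedMetricsError(ValueError):
    """Raised when a metric requiring n >= 1 filaments is asked of an empty set."""


@dataclass(frozen=True)
class Filament:
    """One detected straight filament segment."""

    length_um: float
    width_um: float
    theta_deg: float
    x_um: float = 0.0
    y_um: float = 0.0

    def __post_init__(self) -> None:
        if not self.length_um > 0:
            raise ValueError(f"length_um must be > 0, got {self.length_um}")
        if not self.width_um > 0:
            raise ValueError(f"width_um must be > 0, got {self.width_um}")
        if not (0.0 <= self.theta_deg < 180.0):
            raise ValueError(f"theta_deg must lie in [0, 180), got {self.theta_deg}")


@dataclass
class FilamentSet:
    """All filaments of one cell at one stage, as parallel arrays."""

    cell_id: str = ""
    lengths_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    widths_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    thetas_deg: np.ndarray = field(default_factory=lambda: np.empty(0))
    x_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    y_um: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.lengths_um = np.asarray(self.lengths_um, dtype=float)
        self.widths_um = np.asarray(self.widths_um, dtype=float)
        self.thetas_deg = np.asarray(self.thetas_deg, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        n = len(self.lengths_um)
        for name in ("widths_um", "thetas_deg", "x_um", "y_um"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} has length {len(getattr(self, name))}, expected {n}")

    @property
    def n(self) -> int:
        return len(self.lengths_um)

    def __len__(self) -> int:
        return self.n

    @classmethod
    def from_filaments(cls, filaments: Iterable[Filament], cell_id: str = "") -> "FilamentSet":
        fl = list(filaments)
        return cls(
            cell_id=cell_id,
            lengths_um=np.array([f.length_um for f in fl]),
            widths_um=np.array([f.width_um for f in fl]),
            thetas_deg=np.array([f.theta_deg for f in fl]),
            x_um=np.array([f.x_um for f in fl]),
            y_um=np.array([f.y_um for f in fl]),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cell_id: str = "") -> "FilamentSet":
        return cls(
            cell_id=cell_id or (str(df["cell_id"].iloc[0]) if "cell_id" in df and len(df) else ""),
            lengths_um=df["length_um"].to_numpy(dtype=float),
            widths_um=df["width_um"].to_numpy(dtype=float),
            thetas_deg=df["theta_deg"].to_numpy(dtype=float),
            x_um=df["x_um"].to_numpy(dtype=float) if "x_um" in df else np.zeros(len(df)),
            y_um=df["y_um"].to_numpy(dtype=float) if "y_um" in df else np.zeros(len(df)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "length_um": self.lengths_um,
                "width_um": self.widths_um,
                "theta_deg": self.thetas_deg,
                "x_um": self.x_um,
                "y_um": self.y_um,
            }
        )

    def validate(self) -> None:
        if np.any(self.lengths_um <= 0):
            raise ValueError("all filament lengths must be > 0")
        if np.any(self.widths_um <= 0):
            raise ValueError("all filament widths must be > 0")
        if np.any((self.thetas_deg < 0) | (self.thetas_deg >= 180)):
            raise ValueError("all orientations must lie in [0, 180) degrees")


@dataclass(frozen=True)
class CellMetrics:
    """The descriptor triple (nu, F, L) plus filament count for one observation.

    ``defined`` is False for an empty filament set, in which case nu and L are
    NaN and only F (= 0, the empty sum) is meaningful.  ``nu_rad`` may be
    +inf when the resultant length underflows (isotropy limit).
    """

    n: int
    resultant_R: float
    nu_rad: float
    F_um2: float
    L_um: float
    defined: bool

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "R": self.resultant_R,
            "nu_rad": self.nu_rad,
            "F_um2": self.F_um2,
            "L_um": self.L_um,
            "defined": self.defined,
        }


def _as_angles(angles: Sequence[float] | np.ndarray) -> np.ndarray:
    a = np.asarray(angles, dtype=float)
    if a.ndim != 1:
        a = a.ravel()
    return a


def resultant_length(angles_deg: Sequence[float] | np.ndarray, doubled_angles: bool = False) -> float:
    """Normalised resultant length R of orientations taken as unit vectors.

    R = 1 for perfectly parallel angles, R -> 0 for isotropic orientations.
    """
    a = _as_angles(angles_deg)
    if a.size == 0:
        raise UndefinedMetricsError("resultant length is undefined for an empty angle set")
    rad = np.deg2rad(a)
    if doubled_angles:
        rad = 2.0 * rad
    r = math.hypot(float(np.sin(rad).sum()), float(np.cos(rad).sum())) / a.size
    return min(r, 1.0)


def circular_std(angles_deg: Sequence[float] | np.ndarray, doubled_angles: bool = False) -> float:
    """Circular standard deviation nu = sqrt(-2 ln R), in radians.

    Returns +inf when R underflows below ``R_FLOOR`` (fully isotropic set);
    callers flag such cells rather than aborting the cohort.
    """
    r = resultant_length(angles_deg, doubled_angles=doubled_angles)
    if r < R_FLOOR:
        return math.inf
    if r >= 1.0:
        return 0.0
    return math.sqrt(-2.0 * math.log(r))


def f_actin_content(fs: FilamentSet) -> float:
    """F = sum(l_i * w_i) in um^2; the empty sum is 0."""
    return float(np.dot(fs.lengths_um, fs.widths_um))


def mean_filament_length(fs: FilamentSet) -> float:
    """L = (1/n) sum(l_i) in um."""
    if fs.n == 0:
        raise UndefinedMetricsError("mean filament length is undefined for an empty set")
    return float(fs.lengths_um.mean())


def cell_metrics(fs: FilamentSet, doubled_angles: bool = False) -> CellMetrics:
    """Bundle (n, R, nu, F, L); ``defined=False`` when the set is empty."""
    if fs.n == 0:
        return CellMetrics(n=0, resultant_R=math.nan, nu_rad=math.nan,
                           F_um2=0.0, L_um=math.nan, defined=False)
    r = resultant_length(fs.thetas_deg, doubled_angles=doubled_angles)
    return CellMetrics(
        n=fs.n,
        resultant_R=r,
        nu_rad=circular_std(fs.thetas_deg, doubled_angles=doubled_angles),
        F_um2=f_actin_content(fs),
        L_um=mean_filament_length(fs),
        defined=True,
    )


def metrics_frame(filament_table: pd.DataFrame, doubled_angles: bool = False) -> pd.DataFrame:
    """Per-cell metrics for a long filament table (cell_id, stage, length_um, ...).

    Returns one row per (cell_id, stage) with columns
    n, R, nu_rad, F_um2, L_um, defined.
    """
    keys = [k for k in ("cell_id", "stage") if k in filament_table.columns]
    if not keys:
        raise ValueError("filament table must carry a cell_id column")
    rows = []
    for key, grp in filament_table.groupby(keys, sort=True):
        fs = FilamentSet.from_frame(grp)
        m = cell_metrics(fs, doubled_angles=doubled_angles)
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(m.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
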