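"""Paired pre/post alteration scoring and damage-class assignment.

Each cell is imaged before cryopreservation and again after thawing; the
descriptors (nu, F, L) are computed at both stages and combined into signed
percentage alterations

    delta = 100 * (after / before - 1)

whose absolute values average to the total alteration

    delta_T = (|delta_F| + |delta_L| + |delta_nu|) / 3.

Class assignment is gated by the Annexin-V apoptosis readout: a cell is
apoptosis-positive when the standard deviation of its Annexin fluorescence
exceeds 6000 a.u.  Apoptosis-negative cells are class I regardless of
delta_T; positive cells fall into class I (delta_T <= 10), II (10-20) or
III (> 20); cells that lost surface contact during cryopreservation are
"detached" and have no post-thaw measurement.

Boundary ties (delta_T exactly 10 or 20) go to the lower class — the
conservative damage call.  A non-detached post observation with zero
detected filaments is classed III with a flag: total F-actin loss is the
most severe alteration, and excluding such cells would drop exactly the
most damaged ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import CellMetrics, FilamentSet, cell_metrics

__all__ = [
    "CLASS_I", "CLASS_II", "CLASS_III", "CLASS_DETACHED",
    "ClassThresholds", "CellObservation", "AlterationRecord", "ExclusionError",
    "percent_alteration", "total_alteration", "annexin_sd", "apoptosis_gate",
    "classify_cell", "pair_and_score", "score_cohort",
]

CLASS_I = "I"
CLASS_II = "II"
CLASS_III = "III"
CLASS_DETACHED = "detached"
CLASS_ORDER = [CLASS_I, CLASS_II, CLASS_III, CLASS_DETACHED]


class ExclusionError(ValueError):
    """A cell that cannot be scored; carries the exclusion reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class ClassThresholds:
    """Configurable class boundaries with the published defaults."""

    lower_pct: float = 10.0     # class I / II boundary on delta_T
    upper_pct: float = 20.0     # class II / III boundary on delta_T
    annexin_sd_au: float = 6000.0  # apoptosis gate on Annexin intensity SD

    def __post_init__(self) -> None:
        if not (0 < self.lower_pct < self.upper_pct):
            raise ValueError("need 0 < lower_pct < upper_pct")
        if self.annexin_sd_au < 0:
            raise ValueError("annexin_sd_au must be >= 0")


@dataclass
class CellObservation:
    """One cell at one stage (pre or post)."""

    cell_id: str
    stage: str                      # "pre" | "post"
    condition: str = ""
    recovery_min: int = 0
    replicate_id: str = ""
    filaments: Optional[FilamentSet] = None
    annexin_sd_au: Optional[float] = None   # absent pre-thaw by design
    detached: bool = False                  # post only

    def metrics(self) -> CellMetrics:
        if self.filaments is None:
            raise ExclusionError(f"{self.cell_id}/{self.stage}: no filament data")
        return cell_metrics(self.filaments)


@dataclass(frozen=True)
class AlterationRecord:
    cell_id: str
    condition: str
    recovery_min: int
    replicate_id: str
    delta_F: float
    delta_L: float
    delta_nu: float
    delta_T: float
    apoptotic: bool
    assigned_class: str
    excluded_reason: Optional[str] = None

    def as_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "replicate": self.replicate_id,
            "condition": self.condition,
            "recovery_min": self.recovery_min,
            "delta_F": self.delta_F,
            "delta_L": self.delta_L,
            "delta_nu": self.delta_nu,
            "delta_T": self.delta_T,
            "apoptotic": self.apoptotic,
            "assigned_class": self.assigned_class,
            "excluded_reason": self.excluded_reason or "",
        }


def percent_alteration(before: float, after: float) -> float:
    """Signed percentage alteration 100*(after/before - 1); requires before > 0."""
    if not (math.isfinite(before) and before > 0):
        raise ExclusionError(f"pre-stage value must be finite and > 0, got {before}")
    if not math.isfinite(after):
        raise ExclusionError(f"post-stage value is not finite: {after}")
    return 100.0 * (after / before - 1.0)


def total_alteration(delta_F: float, delta_L: float, delta_nu: float) -> float:
    """delta_T = mean of the absolute alterations; all three must be finite."""
    for name, v in (("delta_F", delta_F), ("delta_L", delta_L), ("delta_nu", delta_nu)):
        if not math.isfinite(v):
            raise ExclusionError(f"{name} is not finite: {v}")
    return (abs(delta_F) + abs(delta_L) + abs(delta_nu)) / 3.0


def annexin_sd(pixels: Sequence[float] | np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """Population standard deviation of Annexin intensities inside the mask.

    With no mask the whole frame is used.  Requires >= 2 pixels.
    """
    px = np.asarray(pixels, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != px.shape:
            raise ValueError(f"mask shape {mask.shape} != image shape {px.shape}")
        px = px[mask]
    px = px.ravel()
    if px.size < 2:
        raise ValueError(f"need at least 2 pixels, got {px.size}")
    return float(np.std(px, ddof=0))


def apoptosis_gate(sd_au: float, threshold_au: float = 6000.0) -> bool:
    """Apoptosis-positive iff the intensity SD is strictly above the threshold."""
    if sd_au < 0:
        raise ValueError(f"intensity SD must be >= 0, got {sd_au}")
    return sd_au > threshold_au


def classify_cell(
    delta_T: Optional[float],
    apoptotic: bool,
    detached: bool,
    thresholds: ClassThresholds = ClassThresholds(),
) -> str:
    """Assign class I/II/III/detached; ties on the boundaries go down."""
    if detached:
        return CLASS_DETACHED
    if not apoptotic:
        return CLASS_I
    if delta_T is None or not math.isfinite(delta_T):
        raise ExclusionError("non-detached cell without a finite delta_T")
    if delta_T <= thresholds.lower_pct:
        return CLASS_I
    if delta_T <= thresholds.upper_pct:
        return CLASS_II
    return CLASS_III


def pair_and_score(
    pre: CellObservation,
    post: CellObservation,
    thresholds: ClassThresholds = ClassThresholds(),
) -> AlterationRecord:
    """Score one identical-cell pre/post pair and assign its class.

    Detached post observations short-circuit to the detached class with NaN
    alteration values.  A non-detached post with zero filaments is classed
    III and flagged ``total_f_actin_loss``.
    """
    if pre.cell_id != post.cell_id:
        raise ValueError(f"cell_id mismatch: {pre.cell_id!r} vs {post.cell_id!r}")
    common = dict(cell_id=pre.cell_id, condition=pre.condition,
                  recovery_min=pre.recovery_min, replicate_id=pre.replicate_id)

    if post.detached:
        return AlterationRecord(**common, delta_F=math.nan, delta_L=math.nan,
                                delta_nu=math.nan, delta_T=math.nan,
                                apoptotic=False, assigned_class=CLASS_DETACHED)

    m_pre = pre.metrics()
    if not m_pre.defined:
        raise ExclusionError(f"{pre.cell_id}: pre-stage metrics undefined (no filaments)")
    sd = post.annexin_sd_au if post.annexin_sd_au is not None else 0.0
    apop = apoptosis_gate(sd, thresholds.annexin_sd_au)

    m_post = post.metrics()
    if not m_post.defined:
        # complete loss of the network: the most severe alteration
        return AlterationRecord(**common, delta_F=-100.0, delta_L=math.nan,
                                delta_nu=math.nan, delta_T=math.nan,
                                apoptotic=apop,
                                assigned_class=CLASS_III if apop else CLASS_I,
                                excluded_reason="total_f_actin_loss")

    if not (math.isfinite(m_pre.nu_rad) and math.isfinite(m_post.nu_rad)):
        raise ExclusionError(f"{pre.cell_id}: non-finite circular SD")
    d_f = percent_alteration(m_pre.F_um2, m_post.F_um2)
    d_l = percent_alteration(m_pre.L_um, m_post.L_um)
    if m_pre.nu_rad == 0.0:
        raise ExclusionError(f"{pre.cell_id}: pre-stage nu is 0, delta_nu undefined")
    d_nu = percent_alteration(m_pre.nu_rad, m_post.nu_rad)
    d_t = total_alteration(d_f, d_l, d_nu)
    cls = classify_cell(d_t, apop, detached=False, thresholds=thresholds)
    return AlterationRecord(**common, delta_F=d_f, delta_L=d_l, delta_nu=d_nu,
                            delta_T=d_t, apoptotic=apop, assigned_class=cls)


def score_cohort(
    pairs: Sequence[tuple[CellObservation, Optional[CellObservation]]],
    thresholds: ClassThresholds = ClassThresholds(),
) -> pd.DataFrame:
    """Score every (pre, post) pair; a missing post observation means detached.

    Returns the alterations table; cells raising an exclusion are kept as
    rows with NaN deltas and the reason in ``excluded_reason``.
    """
    rows = []
    for pre, post in pairs:
        if post is None:
            post = CellObservation(cell_id=pre.cell_id, stage="post",
                                   condition=pre.condition, recovery_min=pre.recovery_min,
                                   replicate_id=pre.replicate_id, detached=True)
        try:
            rec = pair_and_score(pre, post, thresholds)
        except ExclusionError as exc:
            rec = AlterationRecord(
                cell_id=pre.cell_id, condition=pre.condition,
                recovery_min=pre.recovery_min, replicate_id=pre.replicate_id,
                delta_F=math.nan, delta_L=math.nan, delta_nu=math.nan,
                delta_T=math.nan, apoptotic=False, assigned_class="",
                excluded_reason=exc.reason)
        rows.append(rec.as_dict())
    return pd.DataFrame(rows)
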