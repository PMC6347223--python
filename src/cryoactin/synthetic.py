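"""Synthetic paired pre/post cohorts of filament networks with cryo-damage.

The generator emulates the study design this package analyses: adherent
cells imaged once before cryopreservation and once after thawing, 15 cells
per replicate, three replicates, four conditions (an untreated control, slow
freezing at two cooling rates, and vitrification) crossed with three
post-thaw recovery times (0, 15, 120 min).

Each cell starts as a ground-truth network of straight filaments (log-normal
lengths, truncated-normal widths, wrapped-normal orientations, centroids in
an elliptical footprint).  Cryo-damage is applied by three phenomenological
operators motivated by the morphologies seen in cryopreserved cells:

* buckling — a bent filament is detected as several shorter segments with
  jittered orientations (raises nu, lowers L, preserves F at zero jitter);
* depolymerization — random filament loss plus circular "holes" in the
  network (lowers F);
* cracking — filaments crossing a crack line are split with a gap removed
  (lowers L, never raises F).

Damage severities per condition x recovery time are a free configuration
surface with shipped presets that qualitatively mimic the published damage
patterns; no quantitative generative model of cryo-injury exists, so the
presets are illustrative.  Every non-detached damaged cell carries a planted
ground-truth class computed from its realised alterations, nudged (via an
exact width rescale of the post network) to keep a configurable margin from
the 10%/20% class boundaries.  Apoptosis is coupled deterministically to
damage by default (damaged => Annexin-positive), because the classification
presupposes that gate; the coupling is overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .classify import (
    CLASS_DETACHED,
    CellObservation,
    ClassThresholds,
    classify_cell,
    percent_alteration,
    total_alteration,
)
from .metrics import FilamentSet, cell_metrics

__all__ = [
    "DamageSeverity", "StratumParams", "GeneratorConfig", "Cohort",
    "sample_orientations", "generate_cell_filaments",
    "apply_buckling", "apply_depolymerization", "apply_cracking",
    "generate_annexin_pixels", "generate_cohort",
    "MILD_DAMAGE", "SEVERE_DAMAGE", "default_damage_presets",
]

CONDITIONS = ("control", "slow_1C", "slow_10C", "vitrified")
RECOVERY_TIMES_MIN = (0, 15, 120)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class DamageSeverity:
    """Severity parameters for the three damage operators applied together."""

    buckle_fraction: float = 0.0
    buckle_k: int = 2
    buckle_jitter_deg: float = 0.0
    removal_fraction: float = 0.0
    n_holes: int = 0
    hole_radius_um: float = 3.0
    n_cracks: int = 0
    crack_gap_um: float = 1.0


#: slight disruption: partial buckling and mild filament loss
MILD_DAMAGE = DamageSeverity(buckle_fraction=0.35, buckle_k=2, buckle_jitter_deg=12.0,
                             removal_fraction=0.08)
#: severe disruption: widespread buckling, strong loss, holes and cracks
SEVERE_DAMAGE = DamageSeverity(buckle_fraction=0.7, buckle_k=3, buckle_jitter_deg=25.0,
                               removal_fraction=0.30, n_holes=2, hole_radius_um=4.0,
                               n_cracks=2, crack_gap_um=1.5)


@dataclass(frozen=True)
class StratumParams:
    """Per condition x recovery-time damage incidence."""

    p_damaged: float = 0.0       # probability a (non-detached) cell is damaged
    p_severe: float = 0.0        # among damaged cells, probability of severe damage
    detach_probability: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_damaged", "p_severe", "detach_probability"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def default_damage_presets() -> dict:
    """Shipped presets qualitatively mimicking the published damage patterns:

    the gentler cooling rate preserves most networks immediately after
    thawing but deteriorates during recovery; the faster rate damages and
    detaches far more cells; vitrification preserves structure best with
    detachment appearing late.  Illustrative, not quantitative claims.
    """
    return {
        ("control", 0): StratumParams(), ("control", 15): StratumParams(),
        ("control", 120): StratumParams(),
        ("slow_1C", 0): StratumParams(0.11, 0.0, 0.0),
        ("slow_1C", 15): StratumParams(0.35, 0.35, 0.20),
        ("slow_1C", 120): StratumParams(0.40, 0.45, 0.24),
        ("slow_10C", 0): StratumParams(0.37, 0.45, 0.045),
        ("slow_10C", 15): StratumParams(0.45, 0.50, 0.40),
        ("slow_10C", 120): StratumParams(0.55, 0.60, 0.31),
        ("vitrified", 0): StratumParams(0.27, 0.30, 0.0),
        ("vitrified", 15): StratumParams(0.22, 0.40, 0.04),
        ("vitrified", 120): StratumParams(0.18, 0.40, 0.244),
    }


@dataclass
class GeneratorConfig:
    """Study-design constants and distributional parameters of the simulator.

    Lengths are log-normal (log-mean ``mu_log_len`` of the um scale), widths
    truncated normal with a strictly positive lower bound, orientations
    wrapped normal folded to [0, 180) degrees.  ``margin_pct`` is the
    guaranteed distance of every planted Annexin-positive cell's delta_T
    from the 10/20 class boundaries.
    """

    n_cells_per_replicate: int = 15
    n_replicates: int = 3
    conditions: tuple = CONDITIONS
    recovery_times_min: tuple = RECOVERY_TIMES_MIN
    filament_count_range: tuple = (60, 120)
    mu_log_len: float = math.log(8.0)   # median filament length 8 um
    sigma_log_len: float = 0.4
    mu_width_um: float = 0.4
    sigma_width_um: float = 0.08
    min_width_um: float = 0.05
    mean_theta_deg: float = 90.0
    sigma_theta_rad: float = 0.45
    cell_semi_axes_um: tuple = (30.0, 20.0)
    damage_params: dict = field(default_factory=default_damage_presets)
    mild_damage: DamageSeverity = MILD_DAMAGE
    severe_damage: DamageSeverity = SEVERE_DAMAGE
    # small acquisition-noise perturbation applied to undamaged post networks
    undamaged_length_jitter: float = 0.02
    undamaged_angle_jitter_deg: float = 2.0
    apoptosis_coupling: str = "damaged_positive"   # or "always_negative"
    annexin_positive_sd_range: tuple = (8000.0, 14000.0)
    annexin_negative_sd_range: tuple = (500.0, 3000.0)
    annexin_n_pixels: int = 256
    margin_pct: float = 2.0
    thresholds: ClassThresholds = field(default_factory=ClassThresholds)
    min_crack_piece_um: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells_per_replicate < 1 or self.n_replicates < 1:
            raise ValueError("design counts must be >= 1")
        lo, hi = self.filament_count_range
        if not (0 <= lo <= hi):
            raise ValueError(f"bad filament_count_range {self.filament_count_range}")
        if self.sigma_log_len <= 0 or self.sigma_width_um <= 0:
            raise ValueError("distribution scales must be > 0")
        if self.mu_width_um <= 0 or self.min_width_um <= 0:
            raise ValueError("widths must be > 0")
        if self.sigma_theta_rad < 0:
            raise ValueError("sigma_theta_rad must be >= 0")
        if min(self.cell_semi_axes_um) <= 0:
            raise ValueError("cell semi-axes must be > 0")
        if self.margin_pct < 0:
            raise ValueError("margin_pct must be >= 0")
        if self.apoptosis_coupling not in ("damaged_positive", "always_negative"):
            raise ValueError(f"unknown apoptosis_coupling {self.apoptosis_coupling!r}")
        for key, sp in self.damage_params.items():
            if not isinstance(sp, StratumParams):
                raise ValueError(f"damage_params[{key}] must be StratumParams")


# ---------------------------------------------------------------------------
# primitive samplers

def sample_orientations(n: int, mean_deg: float, sigma_rad: float, seed) -> np.ndarray:
    """Draw n orientations from a wrapped normal, folded into [0, 180) degrees.

    The underlying draws are mean + N(0, sigma) on the circle; the closed
    form R = exp(-sigma^2/2) makes the circular SD of the unfolded draws
    exactly sigma.  Folding into the half-turn convention of "angle to the
    horizontal" flips tail vectors and is applied last.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if sigma_rad < 0:
        raise ValueError(f"sigma_rad must be >= 0, got {sigma_rad}")
    rng = _rng(seed)
    draws_deg = mean_deg + np.rad2deg(rng.normal(0.0, sigma_rad, size=n))
    return np.mod(draws_deg, 180.0)


def _sample_in_ellipse(n: int, semi_axes: tuple, rng: np.random.Generator) -> tuple:
    a, b = semi_axes
    r = np.sqrt(rng.random(n))
    phi = rng.uniform(0, 2 * np.pi, n)
    return a * r * np.cos(phi), b * r * np.sin(phi)


def generate_cell_filaments(cfg: GeneratorConfig, seed) -> FilamentSet:
    """Draw one ground-truth filament network from the configured distributions."""
    cfg.validate()
    rng = _rng(seed)
    lo, hi = cfg.filament_count_range
    n = int(rng.integers(lo, hi + 1))
    lengths = rng.lognormal(cfg.mu_log_len, cfg.sigma_log_len, n)
    # truncated normal widths by resampling below the bound
    widths = rng.normal(cfg.mu_width_um, cfg.sigma_width_um, n)
    bad = widths < cfg.min_width_um
    while np.any(bad):
        widths[bad] = rng.normal(cfg.mu_width_um, cfg.sigma_width_um, int(bad.sum()))
        bad = widths < cfg.min_width_um
    thetas = sample_orientations(n, cfg.mean_theta_deg, cfg.sigma_theta_rad, rng)
    x, y = _sample_in_ellipse(n, cfg.cell_semi_axes_um, rng)
    return FilamentSet(cell_id="", lengths_um=lengths, widths_um=widths,
                       thetas_deg=thetas, x_um=x, y_um=y)


# ---------------------------------------------------------------------------
# damage operators

def apply_buckling(fs: FilamentSet, fraction: float, k_segments: int,
                   jitter_sd_deg: float, seed) -> FilamentSet:
    """Fragment a Bernoulli(fraction) subset of filaments into k sub-segments.

    Sub-segment lengths partition the parent length (uniform Dirichlet),
    widths equal the parent width (so F is conserved exactly at zero
    jitter), orientations are the parent angle plus normal jitter folded to
    [0, 180), and centroids are placed along the parent axis.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    if k_segments < 2:
        raise ValueError(f"k_segments must be >= 2, got {k_segments}")
    if jitter_sd_deg < 0:
        raise ValueError(f"jitter_sd_deg must be >= 0, got {jitter_sd_deg}")
    rng = _rng(seed)
    sel = rng.random(fs.n) < fraction
    L, W, T, X, Y = [], [], [], [], []
    for i in range(fs.n):
        l, w, t = fs.lengths_um[i], fs.widths_um[i], fs.thetas_deg[i]
        cx, cy = fs.x_um[i], fs.y_um[i]
        if not sel[i]:
            L.append(l); W.append(w); T.append(t); X.append(cx); Y.append(cy)
            continue
        parts = rng.dirichlet(np.ones(k_segments)) * l
        ux, uy = math.cos(math.radians(t)), math.sin(math.radians(t))
        edges = np.concatenate([[0.0], np.cumsum(parts)])
        mids = (edges[:-1] + edges[1:]) / 2.0 - l / 2.0
        jit = rng.normal(0.0, jitter_sd_deg, k_segments) if jitter_sd_deg > 0 else np.zeros(k_segments)
        for j in range(k_segments):
            L.append(parts[j]); W.append(w)
            T.append((t + jit[j]) % 180.0)
            X.append(cx + mids[j] * ux); Y.append(cy + mids[j] * uy)
    return FilamentSet(cell_id=fs.cell_id, lengths_um=np.array(L), widths_um=np.array(W),
                       thetas_deg=np.array(T), x_um=np.array(X), y_um=np.array(Y))


def apply_depolymerization(fs: FilamentSet, removal_fraction: float,
                           hole_centers: Sequence[tuple] = (),
                           hole_radius_um: float = 0.0, seed=None) -> FilamentSet:
    """Delete a Bernoulli(removal_fraction) subset plus all filaments whose
    centroid lies inside any hole disc."""
    if not (0.0 <= removal_fraction <= 1.0):
        raise ValueError(f"removal_fraction must lie in [0, 1], got {removal_fraction}")
    if hole_radius_um < 0:
        raise ValueError(f"hole_radius_um must be >= 0, got {hole_radius_um}")
    rng = _rng(seed)
    keep = rng.random(fs.n) >= removal_fraction
    for hx, hy in hole_centers:
        d2 = (fs.x_um - hx) ** 2 + (fs.y_um - hy) ** 2
        keep &= d2 > hole_radius_um ** 2
    return FilamentSet(cell_id=fs.cell_id, lengths_um=fs.lengths_um[keep],
                       widths_um=fs.widths_um[keep], thetas_deg=fs.thetas_deg[keep],
                       x_um=fs.x_um[keep], y_um=fs.y_um[keep])


def apply_cracking(fs: FilamentSet, crack_lines: Sequence[tuple], gap_um: float,
                   min_piece_um: float = 0.5) -> FilamentSet:
    """Split every filament crossing a crack line, removing gap_um around the
    intersection; collinear pieces shorter than min_piece_um are dropped.

    ``crack_lines`` is a sequence of ((x0, y0), (x1, y1)) segments in um.
    """
    if gap_um < 0:
        raise ValueError(f"gap_um must be >= 0, got {gap_um}")
    cracks = [LineString([tuple(p0), tuple(p1)]) for p0, p1 in crack_lines]
    # pieces as (t_start, t_end) arclength intervals along each parent axis
    L, W, T, X, Y = [], [], [], [], []
    for i in range(fs.n):
        l, w, t = fs.lengths_um[i], fs.widths_um[i], fs.thetas_deg[i]
        cx, cy = fs.x_um[i], fs.y_um[i]
        ux, uy = math.cos(math.radians(t)), math.sin(math.radians(t))
        p0 = (cx - l / 2 * ux, cy - l / 2 * uy)
        p1 = (cx + l / 2 * ux, cy + l / 2 * uy)
        seg = LineString([p0, p1])
        pieces = [(0.0, l)]
        for crack in cracks:
            inter = seg.intersection(crack)
            if inter.is_empty:
                continue
            pts = [inter] if inter.geom_type == "Point" else list(getattr(inter, "geoms", []))
            for pt in pts:
                if pt.geom_type != "Point":
                    continue
                s = math.hypot(pt.x - p0[0], pt.y - p0[1])  # arclength of the hit
                new_pieces = []
                for (a, b) in pieces:
                    if a < s < b:
                        new_pieces.append((a, s - gap_um / 2))
                        new_pieces.append((s + gap_um / 2, b))
                    else:
                        new_pieces.append((a, b))
                pieces = new_pieces
        for (a, b) in pieces:
            plen = b - a
            if plen < min_piece_um or plen <= 0:
                continue
            mid = (a + b) / 2.0 - l / 2.0
            L.append(plen); W.append(w); T.append(t)
            X.append(cx + mid * ux); Y.append(cy + mid * uy)
    return FilamentSet(cell_id=fs.cell_id, lengths_um=np.array(L), widths_um=np.array(W),
                       thetas_deg=np.array(T), x_um=np.array(X), y_um=np.array(Y))


def generate_annexin_pixels(positive: bool, target_sd: Optional[float], n_pixels: int,
                            seed, sd_range_positive=(8000.0, 14000.0),
                            sd_range_negative=(500.0, 3000.0)) -> np.ndarray:
    """Synthetic Annexin-channel intensities with an exact population SD.

    When ``target_sd`` is None it is drawn from the configured range for the
    requested apoptosis polarity; the realised sample SD equals the target
    exactly (the draw is rescaled), so the 6000 a.u. gate behaves
    predictably on generated cells.
    """
    if n_pixels < 2:
        raise ValueError(f"n_pixels must be >= 2, got {n_pixels}")
    rng = _rng(seed)
    if target_sd is None:
        lo, hi = sd_range_positive if positive else sd_range_negative
        target_sd = float(rng.uniform(lo, hi))
    if target_sd < 0:
        raise ValueError(f"target_sd must be >= 0, got {target_sd}")
    mean = 1000.0 + 4.0 * target_sd   # keep intensities comfortably positive
    if target_sd == 0:
        return np.full(n_pixels, mean)
    x = rng.normal(0.0, 1.0, n_pixels)
    x = x - x.mean()
    sd = x.std(ddof=0)
    if sd == 0:   # astronomically unlikely; regenerate deterministically
        x = np.linspace(-1, 1, n_pixels)
        sd = x.std(ddof=0)
    return mean + x * (target_sd / sd)


# ---------------------------------------------------------------------------
# cohort assembly

def _ground_truth_deltas(pre: FilamentSet, post: FilamentSet) -> tuple:
    mp, ma = cell_metrics(pre), cell_metrics(post)
    d_f = percent_alteration(mp.F_um2, ma.F_um2)
    d_l = percent_alteration(mp.L_um, ma.L_um)
    d_nu = percent_alteration(mp.nu_rad, ma.nu_rad)
    return d_f, d_l, d_nu, total_alteration(d_f, d_l, d_nu)


def _enforce_margin(pre: FilamentSet, post: FilamentSet, thresholds: ClassThresholds,
                    margin: float) -> FilamentSet:
    """Rescale post widths so delta_T keeps >= margin from both class
    boundaries; the rescale moves only delta_F, exactly."""
    d_f, d_l, d_nu, d_t = _ground_truth_deltas(pre, post)
    eps = 0.5
    for boundary in (thresholds.lower_pct, thresholds.upper_pct):
        if abs(d_t - boundary) >= margin:
            continue
        target = boundary + margin + eps if d_t >= boundary else boundary - margin - eps
        new_abs_df = abs(d_f) + 3.0 * (target - d_t)
        sign = -1.0 if d_f <= 0 else 1.0
        if new_abs_df < 0:       # cannot shrink |delta_F| below zero: push up instead
            target = boundary + margin + eps
            new_abs_df = abs(d_f) + 3.0 * (target - d_t)
        if sign < 0 and new_abs_df >= 100.0:   # would require non-positive F
            sign = 1.0
        F_pre = cell_metrics(pre).F_um2
        F_target = F_pre * (1.0 + sign * new_abs_df / 100.0)
        F_post = cell_metrics(post).F_um2
        post = replace_widths(post, post.widths_um * (F_target / F_post))
        d_f, d_l, d_nu, d_t = _ground_truth_deltas(pre, post)
    return post


def replace_widths(fs: FilamentSet, widths: np.ndarray) -> FilamentSet:
    return FilamentSet(cell_id=fs.cell_id, lengths_um=fs.lengths_um.copy(),
                       widths_um=np.asarray(widths, dtype=float),
                       thetas_deg=fs.thetas_deg.copy(),
                       x_um=fs.x_um.copy(), y_um=fs.y_um.copy())


def _perturb_undamaged(fs: FilamentSet, cfg: GeneratorConfig, rng) -> FilamentSet:
    """Small acquisition-noise wiggle for undamaged cells (keeps delta_T low)."""
    jl = cfg.undamaged_length_jitter
    lengths = fs.lengths_um * np.exp(rng.normal(0.0, jl, fs.n)) if jl > 0 else fs.lengths_um.copy()
    ja = cfg.undamaged_angle_jitter_deg
    thetas = (fs.thetas_deg + rng.normal(0.0, ja, fs.n)) % 180.0 if ja > 0 else fs.thetas_deg.copy()
    return FilamentSet(cell_id=fs.cell_id, lengths_um=lengths, widths_um=fs.widths_um.copy(),
                       thetas_deg=thetas, x_um=fs.x_um.copy(), y_um=fs.y_um.copy())


def _apply_damage(fs: FilamentSet, sev: DamageSeverity, cfg: GeneratorConfig,
                  rng: np.random.Generator) -> FilamentSet:
    out = fs
    if sev.buckle_fraction > 0:
        out = apply_buckling(out, sev.buckle_fraction, sev.buckle_k,
                             sev.buckle_jitter_deg, rng)
    holes = []
    if sev.n_holes > 0:
        hx, hy = _sample_in_ellipse(sev.n_holes, cfg.cell_semi_axes_um, rng)
        holes = list(zip(hx, hy))
    if sev.removal_fraction > 0 or holes:
        out = apply_depolymerization(out, sev.removal_fraction, holes,
                                     sev.hole_radius_um, rng)
    if sev.n_cracks > 0:
        a, b = cfg.cell_semi_axes_um
        cracks = []
        for _ in range(sev.n_cracks):
            phi = rng.uniform(0, 2 * np.pi, 2)
            cracks.append(((a * np.cos(phi[0]), b * np.sin(phi[0])),
                           (a * np.cos(phi[1]), b * np.sin(phi[1]))))
        out = apply_cracking(out, cracks, sev.crack_gap_um, cfg.min_crack_piece_um)
    return out


@dataclass
class Cohort:
    """A generated paired cohort: observations plus its tabular views."""

    config: GeneratorConfig
    pairs: list                     # [(pre: CellObservation, post: CellObservation|None)]
    manifest: pd.DataFrame          # one row per cell
    filament_table: pd.DataFrame    # long table, one row per filament per stage
    ground_truth: pd.DataFrame      # per-cell planted deltas and class


def generate_cohort(cfg: Optional[GeneratorConfig] = None, seed: Optional[int] = None) -> Cohort:
    """Generate the full paired cohort under the configured design.

    Determinism: identical (config, seed) yields bit-identical tables.  The
    global seed fans out through a spawned child sequence per cell, in the
    fixed iteration order condition -> recovery time -> replicate -> cell.
    """
    cfg = cfg if cfg is not None else GeneratorConfig()
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    root = np.random.SeedSequence(seed)
    n_strata = len(cfg.conditions) * len(cfg.recovery_times_min) * cfg.n_replicates
    cell_total = n_strata * cfg.n_cells_per_replicate
    children = root.spawn(cell_total)

    pairs, man_rows, fil_rows, gt_rows = [], [], [], []
    idx = 0
    for cond in cfg.conditions:
        for t in cfg.recovery_times_min:
            sp = cfg.damage_params.get((cond, t), StratumParams())
            for rep in range(1, cfg.n_replicates + 1):
                rep_id = f"R{rep}"
                for c in range(1, cfg.n_cells_per_replicate + 1):
                    rng = np.random.default_rng(children[idx])
                    idx += 1
                    cell_id = f"{cond}_t{t:03d}_{rep_id}_c{c:02d}"
                    pre_fs = generate_cell_filaments(cfg, rng)
                    pre_fs.cell_id = cell_id
                    pre = CellObservation(cell_id=cell_id, stage="pre", condition=cond,
                                          recovery_min=t, replicate_id=rep_id,
                                          filaments=pre_fs)

                    detached = bool(rng.random() < sp.detach_probability)
                    if detached:
                        pairs.append((pre, None))
                        man_rows.append(dict(cell_id=cell_id, replicate=rep_id,
                                             condition=cond, recovery_min=t,
                                             detached=True, annexin_sd=np.nan,
                                             planted_class=CLASS_DETACHED))
                        gt_rows.append(dict(cell_id=cell_id, delta_F=np.nan, delta_L=np.nan,
                                            delta_nu=np.nan, delta_T=np.nan,
                                            planted_class=CLASS_DETACHED))
                        _append_filaments(fil_rows, cell_id, "pre", pre_fs)
                        continue

                    damaged = bool(rng.random() < sp.p_damaged)
                    if damaged:
                        sev = cfg.severe_damage if rng.random() < sp.p_severe else cfg.mild_damage
                        post_fs = _apply_damage(pre_fs, sev, cfg, rng)
                    else:
                        post_fs = _perturb_undamaged(pre_fs, cfg, rng)

                    apop = damaged if cfg.apoptosis_coupling == "damaged_positive" else False
                    if apop and post_fs.n > 0:
                        post_fs = _enforce_margin(pre_fs, post_fs, cfg.thresholds,
                                                  cfg.margin_pct)
                    post_fs.cell_id = cell_id
                    annexin = generate_annexin_pixels(
                        apop, None, cfg.annexin_n_pixels, rng,
                        cfg.annexin_positive_sd_range, cfg.annexin_negative_sd_range)
                    sd = float(np.std(annexin, ddof=0))
                    post = CellObservation(cell_id=cell_id, stage="post", condition=cond,
                                           recovery_min=t, replicate_id=rep_id,
                                           filaments=post_fs, annexin_sd_au=sd,
                                           detached=False)
                    pairs.append((pre, post))

                    if post_fs.n == 0:
                        d_f, d_l, d_nu, d_t = -100.0, np.nan, np.nan, np.nan
                        planted = "III" if apop else "I"
                    else:
                        d_f, d_l, d_nu, d_t = _ground_truth_deltas(pre_fs, post_fs)
                        planted = classify_cell(d_t, apop, False, cfg.thresholds)
                    man_rows.append(dict(cell_id=cell_id, replicate=rep_id, condition=cond,
                                         recovery_min=t, detached=False, annexin_sd=sd,
                                         planted_class=planted))
                    gt_rows.append(dict(cell_id=cell_id, delta_F=d_f, delta_L=d_l,
                                        delta_nu=d_nu, delta_T=d_t, planted_class=planted))
                    _append_filaments(fil_rows, cell_id, "pre", pre_fs)
                    _append_filaments(fil_rows, cell_id, "post", post_fs)

    manifest = pd.DataFrame(man_rows)
    filament_table = pd.DataFrame(
        fil_rows, columns=["cell_id", "stage", "length_um", "width_um",
                           "theta_deg", "x_um", "y_um"])
    ground_truth = pd.DataFrame(gt_rows)
    return Cohort(config=cfg, pairs=pairs, manifest=manifest,
                  filament_table=filament_table, ground_truth=ground_truth)


def _append_filaments(rows: list, cell_id: str, stage: str, fs: FilamentSet) -> None:
    for i in range(fs.n):
        rows.append(dict(cell_id=cell_id, stage=stage,
                         length_um=fs.lengths_um[i], width_um=fs.widths_um[i],
                         theta_deg=fs.thetas_deg[i], x_um=fs.x_um[i], y_um=fs.y_um[i]))
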