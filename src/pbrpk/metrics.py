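"""Summary metrics: iso-dose twist, MRDC and the albumin enhancement factor.

*Twist* quantifies hot/cold competition: on a (hot, cold) injection grid,
each iso-dose contour is fitted with a straight line (orthogonal regression
on range-standardized axes, so the angle is independent of axis units and
resolution) and the twist of a level is the angle between its line and the
line of the lowest-dose contour, folded into [0°, 90°].  Vertical contours
mean no competition (dose independent of cold amount); saturation tilts
them.

*MRDC* (maximum relative dose change) compares the best fractionated
schedule against the single bolus:  (Dose(n*,τ*) − Dose_single)/Dose_single.

*EF* (enhancement factor) is the tumor/OAR dose ratio at a given albumin
affinity normalized by the same ratio with albumin binding disabled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .errors import ValidationError


@dataclass
class DoseGrid:
    """Dose (Gy) tabulated over an ascending hot × cold injection grid."""

    hot: np.ndarray  # nmol, ascending
    cold: np.ndarray  # nmol, ascending
    dose: np.ndarray  # (len(hot), len(cold)) Gy
    organ: str = ""

    def __post_init__(self):
        self.hot = np.asarray(self.hot, dtype=float)
        self.cold = np.asarray(self.cold, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if np.any(np.diff(self.hot) <= 0) or np.any(np.diff(self.cold) <= 0):
            raise ValidationError("grid axes must be strictly increasing")
        if self.dose.shape != (len(self.hot), len(self.cold)):
            raise ValidationError("dose table shape must be (len(hot), len(cold))")
        if np.any(self.dose < 0):
            raise ValidationError("dose must be >= 0")
        # payload monotonicity: more hot at fixed cold should not lower dose
        dh = np.diff(self.dose, axis=0)
        tol = 1e-9 * max(self.dose.max(), 1.0)
        if np.any(dh < -tol):
            warnings.warn(
                f"dose grid {self.organ!r} is not monotone in the hot amount",
                stacklevel=2,
            )


@dataclass
class IsoDoseContour:
    level: float  # Gy
    points: np.ndarray  # (k, 2) in (hot, cold) coordinates

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2:
            raise ValidationError("a contour needs at least 2 points")


@dataclass
class TwistProfile:
    levels: np.ndarray  # Gy, ascending
    twist_deg: np.ndarray  # [0, 90], twist of the reference level is 0
    reference_level: float

    @property
    def max_twist(self) -> float:
        return float(np.max(self.twist_deg))


@dataclass
class MRDCResult:
    organ: str
    baseline_dose: float  # Gy, single bolus
    best_n: int
    best_tau: float
    best_dose: float
    mrdc: float


@dataclass
class EFCurve:
    kd_alb: np.ndarray  # nmol/L, as given
    ef: np.ndarray
    tumor_dose: np.ndarray
    oar_dose: np.ndarray
    tumor_baseline: float  # K_D^alb = inf
    oar_baseline: float
    oar: str = ""


def extract_isodose_contours(grid: DoseGrid, levels) -> list[IsoDoseContour]:
    """Marching-squares contours; the longest polyline per level is kept.

    Levels outside the grid's dose range are skipped with a warning.
    """
    out: list[IsoDoseContour] = []
    lo, hi = float(grid.dose.min()), float(grid.dose.max())
    for level in levels:
        if not (lo < level < hi):
            warnings.warn(
                f"iso-dose level {level:g} outside the grid range ({lo:g}, {hi:g}); skipped",
                stacklevel=2,
            )
            continue
        polys = measure.find_contours(grid.dose, level)
        polys = [p for p in polys if len(p) >= 2]
        if not polys:
            warnings.warn(f"no contour found at level {level:g}", stacklevel=2)
            continue
        longest = max(polys, key=lambda p: _poly_length(p))
        # find_contours returns fractional (row, col) indices; map to axis values
        hot_pts = np.interp(longest[:, 0], np.arange(len(grid.hot)), grid.hot)
        cold_pts = np.interp(longest[:, 1], np.arange(len(grid.cold)), grid.cold)
        out.append(IsoDoseContour(level=float(level), points=np.column_stack([hot_pts, cold_pts])))
    return out


def _poly_length(p: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))


def fit_contour_line(
    contour: IsoDoseContour,
    hot_range: tuple[float, float] | None = None,
    cold_range: tuple[float, float] | None = None,
) -> float:
    """Direction angle (degrees, [0°, 180°)) of the TLS line through a contour.

    Orthogonal (total-least-squares) regression: neither axis is a response
    variable.  Axes are standardized by their sweep range first, so the
    angle does not depend on the units or spans of the two axes; 90° means
    a vertical contour (dose independent of the cold amount).
    """
    pts = contour.points
    if len(pts) < 2:
        raise ValidationError("cannot fit a line through fewer than 2 points")
    h, c = pts[:, 0].copy(), pts[:, 1].copy()
    h_span = (hot_range[1] - hot_range[0]) if hot_range else (h.max() - h.min())
    c_span = (cold_range[1] - cold_range[0]) if cold_range else (c.max() - c.min())
    x = h / h_span if h_span > 0 else h * 0.0
    y = c / c_span if c_span > 0 else c * 0.0
    xy = np.column_stack([x - x.mean(), y - y.mean()])
    if not np.any(np.abs(xy) > 0):
        raise ValidationError("degenerate contour: all points coincide")
    # principal direction of the centred point cloud
    _, _, vt = np.linalg.svd(xy, full_matrices=False)
    dx, dy = vt[0]
    ang = float(np.degrees(np.arctan2(dy, dx))) % 180.0
    return ang


def compute_twist(
    grid: DoseGrid, levels=None, n_levels: int = 9
) -> TwistProfile:
    """Twist per iso-dose level, relative to the lowest extractable level.

    Default levels are interior deciles of the grid's dose range.
    """
    if levels is None:
        lo, hi = float(grid.dose.min()), float(grid.dose.max())
        levels = np.linspace(lo, hi, n_levels + 2)[1:-1]
    levels = np.sort(np.asarray(list(levels), dtype=float))
    contours = extract_isodose_contours(grid, levels)
    if len(contours) < 2:
        raise ValidationError("need at least 2 extractable iso-dose contours for twist")
    hot_range = (grid.hot[0], grid.hot[-1])
    cold_range = (grid.cold[0], grid.cold[-1])
    angles = np.array(
        [fit_contour_line(c, hot_range, cold_range) for c in contours]
    )
    used_levels = np.array([c.level for c in contours])
    ref = angles[0]
    delta = np.abs(angles - ref)
    twist = np.minimum(delta, 180.0 - delta)  # fold into [0, 90]
    return TwistProfile(levels=used_levels, twist_deg=twist, reference_level=float(used_levels[0]))


def compute_mrdc(dose_table: dict[tuple[int, float], float], baseline: float, organ: str = "") -> MRDCResult:
    """Best schedule in *dose_table* relative to the single-bolus baseline.

    Keys are (n injections, τ minutes).  Ties are broken toward the
    smallest n, then the smallest τ.
    """
    if baseline <= 0:
        raise ValidationError("baseline dose must be > 0")
    if not dose_table:
        raise ValidationError("dose table is empty")
    best_key, best_dose = None, -np.inf
    for key in sorted(dose_table, key=lambda k: (k[0], k[1])):
        if dose_table[key] > best_dose:  # strict: ties keep the smaller (n, tau)
            best_key, best_dose = key, dose_table[key]
    if baseline >= best_dose:  # the single bolus itself is optimal
        best_key, best_dose = (1, 0.0), baseline
    return MRDCResult(
        organ=organ,
        baseline_dose=baseline,
        best_n=int(best_key[0]),
        best_tau=float(best_key[1]),
        best_dose=float(best_dose),
        mrdc=(best_dose - baseline) / baseline,
    )


def compute_ef(
    tumor_doses: dict[float, float],
    oar_doses: dict[float, float],
    tumor_base: float,
    oar_base: float,
    oar: str = "",
) -> EFCurve:
    """Enhancement factor per K_D^alb sample (element-wise ratio of ratios)."""
    if tumor_base <= 0 or oar_base <= 0:
        raise ValidationError("baseline doses must be > 0")
    if set(tumor_doses) != set(oar_doses):
        raise ValidationError("tumor and OAR dose maps must share the same K_D samples")
    kd = np.array(sorted(tumor_doses), dtype=float)
    tum = np.array([tumor_doses[k] for k in kd])
    oar_d = np.array([oar_doses[k] for k in kd])
    if np.any(oar_d <= 0):
        raise ValidationError("OAR dose must be > 0 at every sample")
    ef = (tum / oar_d) / (tumor_base / oar_base)
    return EFCurve(
        kd_alb=kd,
        ef=ef,
        tumor_dose=tum,
        oar_dose=oar_d,
        tumor_baseline=tumor_base,
        oar_baseline=oar_base,
        oar=oar,
    )
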