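"""Real-time PCR standard-curve analytics.

A dilution series (template quantity in ng, threshold cycle Ct) is fit
by ordinary least squares of Ct on log10(quantity). The slope gives the
amplification efficiency E = (10^(-1/slope) - 1) x 100: a perfectly
doubling reaction has slope -1/log10(2) ~ -3.32 and E = 100%. The
detection limit is the smallest tested quantity still called before the
cycle cutoff, with a curve-extrapolated quantity at the cutoff reported
alongside.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class QpcrError(ValueError):
    pass


@dataclass
class DilutionSeries:
    label: str
    points: list[tuple[float, float]]   # (quantity_ng, ct); ct may be NaN = no call
    is_ntc: bool = False

    def __post_init__(self) -> None:
        for q, _ in self.points:
            if not q > 0:
                raise QpcrError(f"{self.label}: quantities must be positive, got {q}")

    @property
    def detected_points(self) -> list[tuple[float, float]]:
        return [(q, ct) for q, ct in self.points if not math.isnan(ct)]


@dataclass(frozen=True)
class StandardCurve:
    label: str
    slope: float                # cycles per log10(ng)
    intercept: float            # cycles at 1 ng
    r_squared: float
    efficiency_percent: float | None
    efficiency_rounded: int | None
    n_points: int


def round_half_away(x: float) -> int:
    """Round halves away from zero (99.5 -> 100, 130.5 -> 131)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def fit_standard_curve(series: DilutionSeries) -> StandardCurve:
    """OLS fit of Ct on log10(quantity in ng).

    Points without a Ct call are dropped with a warning; at least two
    distinct quantities are required. R^2 is the squared Pearson
    correlation of (log10 q, Ct).
    """
    pts = series.detected_points
    if len(pts) < len(series.points):
        logger.warning("%s: dropped %d point(s) without Ct", series.label, len(series.points) - len(pts))
    if len(pts) < 2:
        raise QpcrError(f"{series.label}: need >=2 points with Ct calls")
    q = np.array([p[0] for p in pts])
    ct = np.array([p[1] for p in pts])
    if np.unique(q).size < 2:
        raise QpcrError(f"{series.label}: degenerate dilution (all quantities equal)")
    res = stats.linregress(np.log10(q), ct)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue) ** 2
    if slope < 0:
        eff = efficiency_from_slope(slope)
        eff_round = round_half_away(eff)
    else:
        eff, eff_round = None, None
    return StandardCurve(series.label, slope, intercept, r2, eff, eff_round, len(pts))


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency in percent: (10^(-1/slope) - 1) x 100."""
    if slope >= 0:
        raise QpcrError(f"efficiency undefined for non-negative slope {slope}")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


@dataclass(frozen=True)
class DetectionLimit:
    observed_lod_ng: float | None       # smallest tested quantity with Ct < cutoff
    extrapolated_lod_ng: float          # quantity whose fitted Ct equals the cutoff
    detected: bool


def detection_limit(series: DilutionSeries, ct_cutoff: float = 40.0, curve: StandardCurve | None = None) -> DetectionLimit:
    """Detection-limit bookkeeping at a Ct cutoff (default 40 cycles)."""
    if curve is None:
        curve = fit_standard_curve(series)
    detected = [q for q, ct in series.detected_points if ct < ct_cutoff]
    extrapolated = 10.0 ** ((ct_cutoff - curve.intercept) / curve.slope)
    if not detected:
        return DetectionLimit(None, extrapolated, False)
    return DetectionLimit(min(detected), extrapolated, True)


def dilution_plan(top_mass: float, fold: float = 10.0, n: int = 6) -> list[float]:
    """Geometric dilution series top_mass / fold^k for k = 0..n-1."""
    if top_mass <= 0 or fold <= 1:
        raise QpcrError("top_mass must be > 0 and fold > 1")
    return [top_mass / fold**k for k in range(n)]


# ---------------------------------------------------------------- I/O ----

def read_ct_csv(path) -> list[DilutionSeries]:
    """Read a Ct table CSV (columns: label, quantity_ng, ct) into one
    DilutionSeries per label, preserving row order."""
    df = pd.read_csv(path)
    required = {"label", "quantity_ng", "ct"}
    if not required.issubset(df.columns):
        raise QpcrError(f"{path}: expected columns {sorted(required)}")
    series = []
    for label, grp in df.groupby("label", sort=False):
        pts = [(float(q), float(ct)) for q, ct in zip(grp["quantity_ng"], grp["ct"])]
        series.append(DilutionSeries(str(label), pts))
    return series


def curve_report(series_list: list[DilutionSeries], ct_cutoff: float = 40.0) -> pd.DataFrame:
    """Assay-by-assay report: Ct per tested quantity, efficiency, R^2,
    slope and observed LOD — the standard-curve summary table."""
    rows = []
    for s in series_list:
        curve = fit_standard_curve(s)
        lod = detection_limit(s, ct_cutoff, curve)
        row = {"assay": s.label}
        for q, ct in s.points:
            row[f"ct_{q:g}ng"] = ct
        row.update(
            {
                "efficiency": curve.efficiency_rounded,
                "r_squared": curve.r_squared,
                "slope": curve.slope,
                "intercept": curve.intercept,
                "lod_ng": lod.observed_lod_ng,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("assay")


def load_reference_curves() -> list[DilutionSeries]:
    """The published five-assay dilution series bundled with the package
    (15 ng to 1.5 pg, Ct at each step for each target species)."""
    ref = importlib.resources.files("scarkit.data").joinpath("reference_ct_table.csv")
    with importlib.resources.as_file(ref) as path:
        return read_ct_csv(path)
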