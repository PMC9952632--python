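"""WSS-derived hemodynamic indices and threshold-based risk classification.

Given the wall shear vector tau_w(t) over one cardiac cycle of period T:

* TAWSS (tau_abs) = (1/T) ∫ |tau_w| dt          — time-averaged magnitude;
* tau_mean        = |(1/T) ∫ tau_w dt|          — magnitude of the average;
* OSI             = 0.5 (1 - tau_mean/tau_abs)  — 0 unidirectional, 0.5 fully
  reversing;
* RRT             = 1 / (TAWSS (1 - 2 OSI))     — near-wall residence proxy.

Time integrals use the composite trapezoid rule with periodic wrap (the
sample at t0+T closes against the one at t0), which is exact in the mean for
uniformly sampled trigonometric signals.  Atheroprone regions are classified
by the conventional thresholds TAWSS < 0.4 Pa, OSI > 0.25, RRT > 5 Pa^-1
(strict inequalities), with areas summed over wall facets; flow-extension
surfaces are numerical scaffolding and excluded from area statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meshing import LabeledMesh
from .wallshear import WallShearField

#: Facets with tau_abs below this are flagged "OSI undefined" (set to 0).
OSI_EPS = 1e-12
#: RRT sentinel used where TAWSS (1 - 2 OSI) vanishes.
RRT_CAP = 1e6


def _periodic_weights(times: np.ndarray, period: float) -> np.ndarray:
    """Trapezoid weights on (t0, t0+T] with the last sample wrapping to t0."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("empty or invalid time series")
    if len(times) == 1:
        return np.array([period])
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise ValueError("snapshot times must be strictly increasing")
    wrap = period - (times[-1] - times[0])
    if wrap <= 0:
        raise ValueError("snapshot times span more than one period")
    w = np.empty(len(times))
    w[1:-1] = 0.5 * (dt[:-1] + dt[1:])
    w[0] = 0.5 * (dt[0] + wrap)
    w[-1] = 0.5 * (dt[-1] + wrap)
    return w


def compute_tawss(wss: WallShearField) -> np.ndarray:
    """(1/T) ∫ |tau_w| dt per facet, periodic trapezoid over the snapshots."""
    w = _periodic_weights(wss.times, wss.period)
    return np.einsum("s,sf->f", w, wss.magnitudes) / wss.period


def compute_mean_shear(wss: WallShearField) -> np.ndarray:
    """|(1/T) ∫ tau_w dt| per facet — vector average first, magnitude second."""
    w = _periodic_weights(wss.times, wss.period)
    mean_vec = np.einsum("s,sfd->fd", w, wss.tractions) / wss.period
    return np.linalg.norm(mean_vec, axis=1)


def compute_osi(tawss: np.ndarray, tau_mean: np.ndarray):
    """OSI = 0.5 (1 - tau_mean / tau_abs); facets with vanishing tau_abs are
    flagged undefined and set to 0.  Returns (osi, undefined_mask)."""
    tawss = np.asarray(tawss, dtype=float)
    tau_mean = np.asarray(tau_mean, dtype=float)
    undefined = tawss < OSI_EPS
    ratio = np.divide(tau_mean, tawss, out=np.ones_like(tawss),
                      where=~undefined)
    osi = 0.5 * (1.0 - ratio)
    osi[undefined] = 0.0
    return np.clip(osi, 0.0, 0.5), undefined


def compute_rrt(tawss: np.ndarray, osi: np.ndarray):
    """RRT = 1 / (TAWSS (1 - 2 OSI)); singular facets are capped and flagged.

    Returns (rrt, infinite_mask): where the denominator vanishes (fully
    reversing shear or zero TAWSS) the value is the RRT_CAP sentinel and the
    flag is set.
    """
    denom = np.asarray(tawss, dtype=float) * (1.0 - 2.0 * np.asarray(osi))
    infinite = denom < OSI_EPS
    rrt = np.divide(1.0, denom, out=np.full_like(denom, RRT_CAP),
                    where=~infinite)
    rrt = np.minimum(rrt, RRT_CAP)
    return rrt, infinite


@dataclass
class IndexMaps:
    """Per-facet index maps over the wall, with singularity flags."""

    tawss: np.ndarray
    tau_mean: np.ndarray
    osi: np.ndarray
    rrt: np.ndarray
    facet_areas: np.ndarray
    facet_ids: np.ndarray
    osi_undefined: np.ndarray
    rrt_infinite: np.ndarray
    facet_regions: np.ndarray | None = None
    region_names: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "facet": self.facet_ids,
            "area_m2": self.facet_areas,
            "tawss_Pa": self.tawss,
            "tau_mean_Pa": self.tau_mean,
            "osi": self.osi,
            "rrt_Pa_inv": self.rrt,
            "rrt_infinite": self.rrt_infinite,
        })
        if self.facet_regions is not None:
            df["region"] = [self.region_names[r] for r in self.facet_regions]
        return df


def compute_index_maps(wss: WallShearField) -> IndexMaps:
    """All four maps from one WallShearField, mutually consistent by identity."""
    tawss = compute_tawss(wss)
    tau_mean = compute_mean_shear(wss)
    osi, osi_undef = compute_osi(tawss, tau_mean)
    rrt, rrt_inf = compute_rrt(tawss, osi)
    return IndexMaps(tawss=tawss, tau_mean=tau_mean, osi=osi, rrt=rrt,
                     facet_areas=wss.facet_areas, facet_ids=wss.facet_ids,
                     osi_undefined=osi_undef, rrt_infinite=rrt_inf,
                     facet_regions=wss.facet_regions,
                     region_names=list(wss.region_names))


# ---------------------------------------------------------------------------
# risk regions


@dataclass(frozen=True)
class RiskThresholds:
    """Atheroprone-region thresholds (strict inequalities)."""

    tawss_low: float = 0.4   # Pa, risk where TAWSS < this
    osi_high: float = 0.25   # risk where OSI > this
    rrt_high: float = 5.0    # Pa^-1, risk where RRT > this

    def __post_init__(self):
        if min(self.tawss_low, self.osi_high, self.rrt_high) <= 0:
            raise ValueError("thresholds must be positive")


#: Anatomical regions counted as true vessel wall (extensions are scaffolding).
WALL_REGIONS_EXCLUDED = ("extension_inlet", "extension_outlet")


@dataclass
class RiskRegionReport:
    """Per-criterion masks, areas and per-anatomical-region breakdown."""

    criteria: dict          # name -> {"mask", "area_cm2", "fraction"}
    wall_area_cm2: float
    by_region: pd.DataFrame  # columns: criterion, region, area_cm2, fraction

    def to_frame(self) -> pd.DataFrame:
        rows = [{"criterion": k, "region": "all",
                 "area_cm2": v["area_cm2"], "fraction": v["fraction"]}
                for k, v in self.criteria.items()]
        return pd.concat([pd.DataFrame(rows), self.by_region],
                         ignore_index=True)


def classify_risk_regions(maps: IndexMaps, mesh: LabeledMesh,
                          thresholds: RiskThresholds | None = None
                          ) -> RiskRegionReport:
    """Threshold the index maps and integrate facet areas per criterion.

    RRT facets flagged infinite count as exceeding the RRT threshold.  Areas
    are reported in cm^2 and as fractions of the analyzed wall (extension
    surfaces excluded); a per-anatomical-region breakdown is included when the
    mesh carries region labels.
    """
    thresholds = thresholds or RiskThresholds()
    region_names = maps.region_names
    if maps.facet_regions is not None and region_names:
        excluded = np.array([region_names[r] in WALL_REGIONS_EXCLUDED
                             for r in maps.facet_regions])
    else:
        excluded = np.zeros(len(maps.tawss), dtype=bool)
    keep = ~excluded
    areas = maps.facet_areas
    wall_area = float(areas[keep].sum())

    masks = {
        f"TAWSS<{thresholds.tawss_low}Pa": (maps.tawss < thresholds.tawss_low),
        f"OSI>{thresholds.osi_high}": (maps.osi > thresholds.osi_high),
        f"RRT>{thresholds.rrt_high}Pa-1": ((maps.rrt > thresholds.rrt_high)
                                           | maps.rrt_infinite),
    }
    criteria = {}
    rows = []
    for name, mask in masks.items():
        m = mask & keep
        area = float(areas[m].sum())
        criteria[name] = {"mask": m, "area_cm2": area * 1e4,
                          "fraction": area / wall_area if wall_area else 0.0}
        if maps.facet_regions is not None and region_names:
            for rid, rname in enumerate(region_names):
                if rname in WALL_REGIONS_EXCLUDED:
                    continue
                sel = m & (maps.facet_regions == rid)
                reg_area = float(areas[keep & (maps.facet_regions == rid)].sum())
                rows.append({"criterion": name, "region": rname,
                             "area_cm2": float(areas[sel].sum()) * 1e4,
                             "fraction": (float(areas[sel].sum()) / reg_area
                                          if reg_area > 0 else 0.0)})
    by_region = pd.DataFrame(rows, columns=["criterion", "region",
                                            "area_cm2", "fraction"])
    return RiskRegionReport(criteria=criteria, wall_area_cm2=wall_area * 1e4,
                            by_region=by_region)
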