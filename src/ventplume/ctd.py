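"""CTD profile handling: backgrounds, anomalies, plume delineation, stratification.

A hydrothermal plume is detected in the water column as anomalies of
turbidity, temperature, and redox potential relative to background
profiles fitted from reference casts taken away from the vent. The
vertical interval of the non-buoyant plume and the buoyancy frequency N
of the ambient stratification are the observational inputs to the
plume-rise power inversion.

Depth convention throughout: meters below sea level, positive downward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seawater import sigma0

#: Canonical CTD column names; missing optional columns are allowed.
CTD_COLUMNS = [
    "depth_m",
    "temperature_C",
    "salinity",
    "sigma",
    "turbidity_NTU",
    "eh_offset_mV",
]


class PropertyMissingError(KeyError):
    """Requested water-column property not present in a cast."""


class DepthRangeError(ValueError):
    """Queried depth outside the fitted background's covered range."""


@dataclass
class CtdCast:
    """One CTD cast: ordered records of depth and water properties.

    ``data`` must contain ``depth_m`` and ``temperature_C``; ``salinity``
    is required only when density has to be derived. Records are sorted
    by depth on construction.
    """

    cast_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        if "depth_m" not in df.columns or "temperature_C" not in df.columns:
            raise ValueError("cast needs at least depth_m and temperature_C columns")
        if (df["depth_m"] <= 0).any():
            raise ValueError("depths must be strictly positive (meters below sea level)")
        t = df["temperature_C"]
        if ((t < -2) | (t > 40)).any():
            raise ValueError("temperature outside the plausible seawater range [-2, 40] degC")
        self.data = df.sort_values("depth_m", kind="mergesort").reset_index(drop=True)

    def has_property(self, name: str) -> bool:
        return name in self.data.columns and self.data[name].notna().any()

    def property_values(self, name: str) -> pd.DataFrame:
        """Depth/value pairs for one property, NaNs dropped.

        ``sigma`` is derived from T/S via the surface-referenced seawater
        equation of state when the cast carries no density channel.
        """
        if name == "sigma" and not self.has_property("sigma"):
            if not self.has_property("salinity"):
                raise PropertyMissingError(
                    f"cast {self.cast_id}: no sigma and no salinity to derive it from"
                )
            out = self.data[["depth_m"]].copy()
            out["sigma"] = sigma0(self.data["salinity"], self.data["temperature_C"])
            return out.dropna().reset_index(drop=True)
        if not self.has_property(name):
            raise PropertyMissingError(f"cast {self.cast_id}: property {name!r} not recorded")
        return (
            self.data[["depth_m", name]].dropna().reset_index(drop=True)
        )

    @property
    def depth_range(self) -> tuple[float, float]:
        d = self.data["depth_m"]
        return float(d.min()), float(d.max())


def read_cast_csv(path: str | Path, cast_id: str | None = None) -> CtdCast:
    """Read one cast from CSV (header as in :data:`CTD_COLUMNS`; extras ignored)."""
    path = Path(path)
    df = pd.read_csv(path)
    keep = [c for c in CTD_COLUMNS if c in df.columns]
    return CtdCast(cast_id=cast_id or path.stem, data=df[keep])


@dataclass
class BackgroundProfile:
    """Piecewise-linear background of one property vs depth, with residual scatter.

    Fitted as per-depth-bin medians over reference casts; ``sd`` is the
    n-1 standard deviation of pooled reference values in each bin, a
    per-depth noise scale for anomaly thresholding.
    """

    property_name: str
    depth_grid: np.ndarray
    values: np.ndarray
    residual_sd: np.ndarray

    def _check_range(self, depths: np.ndarray) -> None:
        lo, hi = self.depth_grid[0], self.depth_grid[-1]
        if (depths < lo).any() or (depths > hi).any():
            raise DepthRangeError(
                f"queried depth outside background range [{lo:.1f}, {hi:.1f}] m "
                "(no extrapolation)"
            )

    def value(self, depth_m: np.ndarray | float) -> np.ndarray:
        d = np.atleast_1d(np.asarray(depth_m, dtype=float))
        self._check_range(d)
        return np.interp(d, self.depth_grid, self.values)

    def sd(self, depth_m: np.ndarray | float) -> np.ndarray:
        d = np.atleast_1d(np.asarray(depth_m, dtype=float))
        self._check_range(d)
        return np.interp(d, self.depth_grid, self.residual_sd)


@dataclass(frozen=True)
class PlumeInterval:
    """Contiguous depth interval of above-threshold anomalies."""

    property_name: str
    top_depth_m: float
    bottom_depth_m: float
    peak_anomaly: float
    peak_depth_m: float

    @property
    def vertical_extent_m(self) -> float:
        return self.bottom_depth_m - self.top_depth_m


def fit_background(
    reference_casts: Sequence[CtdCast],
    property_name: str,
    bin_width_m: float = 50.0,
) -> BackgroundProfile:
    """Fit a background profile from reference casts.

    Bins records into ``bin_width_m`` depth bins. Within each bin every
    cast contributes its median (robust to residual plume contamination
    of individual references); the background value is the median of
    those per-cast medians and the residual SD their n-1 standard
    deviation across casts. Linear interpolation between bin centers; no
    extrapolation outside the covered range.
    """
    if not reference_casts:
        raise ValueError("at least one reference cast required")
    frames = []
    for i, cast in enumerate(reference_casts):
        f = cast.property_values(property_name)
        f["_cast"] = i
        frames.append(f)
    pooled = pd.concat(frames, ignore_index=True)
    if len(pooled) < 5:
        raise ValueError("need at least 5 records across reference casts")

    depths = pooled["depth_m"].to_numpy()
    values = pooled[property_name].to_numpy()
    cast_idx = pooled["_cast"].to_numpy()
    lo, hi = depths.min(), depths.max()
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width_m)))
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(depths, edges) - 1, 0, n_bins - 1)

    centers, meds, sds = [], [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        per_cast = [
            np.median(values[mask & (cast_idx == c)])
            for c in np.unique(cast_idx[mask])
        ]
        centers.append(depths[mask].mean())
        meds.append(np.median(per_cast))
        sds.append(np.std(per_cast, ddof=1) if len(per_cast) > 1 else 0.0)
    centers = np.asarray(centers)
    # pin endpoints to the full covered range so every observed depth is queryable
    grid = np.concatenate(([lo], centers, [hi]))
    vals = np.concatenate(([meds[0]], meds, [meds[-1]]))
    sd = np.concatenate(([sds[0]], sds, [sds[-1]]))
    grid, uniq = np.unique(grid, return_index=True)
    return BackgroundProfile(property_name, grid, vals[uniq], sd[uniq])


def anomaly(cast: CtdCast, background: BackgroundProfile, property_name: str) -> pd.DataFrame:
    """Observed minus background at matched depths; sign preserved.

    Redox anomalies come out negative (reduced plume water), turbidity
    and temperature anomalies positive. Depths outside the background's
    range are dropped; no overlap at all is an error.
    """
    obs = cast.property_values(property_name)
    lo, hi = background.depth_grid[0], background.depth_grid[-1]
    inside = obs[(obs["depth_m"] >= lo) & (obs["depth_m"] <= hi)]
    if inside.empty:
        raise DepthRangeError(
            f"cast {cast.cast_id} has no depth overlap with the background profile"
        )
    d = inside["depth_m"].to_numpy()
    out = pd.DataFrame(
        {
            "depth_m": d,
            "anomaly": inside[property_name].to_numpy() - background.value(d),
            "residual_sd": background.sd(d),
        }
    )
    return out.reset_index(drop=True)


def delineate_plume(
    anomaly_series: pd.DataFrame,
    property_name: str = "",
    threshold: float | None = None,
    k_sd: float = 3.0,
) -> PlumeInterval | None:
    """Longest contiguous depth run of anomalies exceeding a threshold.

    The threshold is either an absolute anomaly magnitude (``threshold``)
    or ``k_sd`` times the per-depth background residual SD (default,
    k=3: a sharp plume signal stands well above instrument noise).
    Exceedance is judged on |anomaly| so that negative redox anomalies
    delineate like positive turbidity ones. Ties between equal-length
    runs go to the deepest run (plumes are bottom-sourced). Returns
    ``None`` when nothing exceeds the threshold.
    """
    df = anomaly_series.sort_values("depth_m", kind="mergesort").reset_index(drop=True)
    a = df["anomaly"].to_numpy()
    if threshold is not None:
        thr = np.full(len(df), float(threshold))
    else:
        if "residual_sd" not in df.columns:
            raise ValueError("k-SD thresholding needs a residual_sd column")
        thr = k_sd * df["residual_sd"].to_numpy()
    exceed = np.abs(a) > thr
    if not exceed.any():
        return None

    # enumerate contiguous runs of exceedance
    edges = np.flatnonzero(np.diff(np.concatenate(([0], exceed.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]
    depths = df["depth_m"].to_numpy()
    extents = depths[stops - 1] - depths[starts]
    # longest extent; tie-break toward the deepest run
    best = int(np.lexsort((starts, extents))[-1])
    s, e = starts[best], stops[best]
    seg = slice(s, e)
    peak_i = s + int(np.argmax(np.abs(a[seg])))
    return PlumeInterval(
        property_name=property_name,
        top_depth_m=float(depths[s]),
        bottom_depth_m=float(depths[e - 1]),
        peak_anomaly=float(a[peak_i]),
        peak_depth_m=float(depths[peak_i]),
    )


def buoyancy_frequency(
    cast: CtdCast,
    depth_window: tuple[float, float],
    rho0: float = 1028.0,
    g: float = 9.81,
) -> float:
    """Brunt-Vaisala frequency N (s-1) over a depth window.

    Fits a least-squares line to density vs depth inside the window and
    takes N^2 = (g/rho0) * d(rho)/d(depth) — with depth positive down,
    stable stratification has density increasing downward and N^2 > 0.
    An unstable window returns 0 with a warning.
    """
    lo, hi = sorted(depth_window)
    dens = cast.property_values("sigma")
    sel = dens[(dens["depth_m"] >= lo) & (dens["depth_m"] <= hi)]
    if len(sel) < 3:
        raise ValueError("need at least 3 density records inside the window")
    slope = np.polyfit(sel["depth_m"], sel["sigma"], 1)[0]  # kg m-3 per m, >0 if stable
    n_sq = g / rho0 * slope
    if n_sq <= 0:
        # tolerate round-off on an exactly uniform profile; warn on real inversions
        if n_sq < -1e-15:
            warnings.warn(
                "density decreases with depth in the window (unstable); N set to 0",
                stacklevel=2,
            )
        return 0.0
    return float(np.sqrt(n_sq))
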