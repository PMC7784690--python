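"""GPPT inference chain: activity coefficients, segment rates and
Michaelis–Menten model selection.

The chain mirrors the field analysis of in-situ CH4 oxidation:

1. Each discrete extraction-phase tracer (Ar) sample is matched to the
   quasi-continuous CH4 record and converted to relative concentrations
   C* = (C − C_bg)/(C_inj − C_bg) (:func:`build_points`).
2. The first-order *activity coefficient* k (h⁻¹) is the negative slope
   of ln(C*_CH4 / C*_Ar) against the transformed (plug-flow) reaction
   time t* (:func:`estimate_activity`).
3. Sliding windows of three consecutive samples give local activities
   and running-average concentrations, hence segment-wise volumetric
   oxidation rates R_ox = k_local · C̄ (:func:`segment_rates`).
4. A Michaelis–Menten model R_ox = Vmax·C/(Km + C) is fitted to the
   (C̄, R_ox) pairs and compared with a linear model by AIC; when the
   linear model wins, no MM parameters are reported
   (:func:`fit_kinetics`).  Pairs from several mounds can be pooled
   (:func:`pooled_fit`).
5. Whole-mound oxidation rates divided by pmoA-derived methanotroph cell
   numbers give cell-specific rates (:func:`cell_specific_rate`).

A thin statsmodels-style layer (:class:`GpptKinetics` /
:class:`GpptKineticsResults`) wraps the chain for interactive use.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .simulate import GpptDataset, transformed_time
from .units import mixing_ratio_to_umol_per_l

__all__ = [
    "KineticPoint",
    "ActivityFit",
    "SegmentRate",
    "KineticFit",
    "MoundRecord",
    "build_points",
    "estimate_activity",
    "segment_rates",
    "fit_kinetics",
    "pooled_fit",
    "cell_specific_rate",
    "GpptKinetics",
    "GpptKineticsResults",
]


@dataclass
class KineticPoint:
    """One tracer-matched observation during extraction."""

    t_e: float  # elapsed extraction time, s
    t_star: float  # transformed reaction time, h
    c_rel_ar: float  # relative Ar concentration (dimensionless)
    c_rel_ch4: float  # relative CH4 concentration (dimensionless)
    c_ch4: float  # dimensional CH4 concentration, µmol (l air)-1
    usable: bool = True  # both relative concentrations > 0

    def log_ratio(self) -> float:
        if not self.usable:
            raise ValueError("log-ratio undefined for non-positive relative concentrations")
        return float(np.log(self.c_rel_ch4 / self.c_rel_ar))


@dataclass
class ActivityFit:
    """First-order activity coefficient from the log-ratio regression."""

    k: float  # h-1 (may be <= 0; flagged, not suppressed)
    k_se: float
    r2: float
    n: int
    no_detectable_oxidation: bool = False


@dataclass
class SegmentRate:
    """Running-average concentration and local oxidation rate of a segment."""

    c_bar: float  # µmol l-1
    k_local: float  # h-1
    r_ox: float  # µmol l-1 h-1  (== k_local * c_bar)


@dataclass
class KineticFit:
    """Michaelis–Menten vs linear model comparison for one (C̄, R_ox) set."""

    km: Optional[float]
    vmax: Optional[float]
    km_se: Optional[float]
    vmax_se: Optional[float]
    aic_mm: Optional[float]
    lin_slope: float
    lin_intercept: float
    aic_lin: float
    selected_model: str  # "michaelis_menten" | "linear"
    segments: List[SegmentRate] = field(default_factory=list)
    mm_converged: bool = True

    def predict(self, c):
        """Selected-model rate at concentration c (µmol l⁻¹)."""
        c = np.asarray(c, dtype=float)
        if self.selected_model == "michaelis_menten":
            return self.vmax * c / (self.km + c)
        return self.lin_intercept + self.lin_slope * c


@dataclass
class MoundRecord:
    """Physical covariates of one mound."""

    mound_id: str
    species: str  # Mn | Ms | Tp
    location: str  # core | periphery | beneath | surrounding
    dry_mass: float  # g
    micro_porosity: float
    macro_porosity: float
    water_content: float
    volume: float  # l

    def __post_init__(self):
        if self.species not in {"Mn", "Ms", "Tp"}:
            raise ValueError(f"unknown species {self.species!r}")
        if self.location not in {"core", "periphery", "beneath", "surrounding"}:
            raise ValueError(f"unknown location {self.location!r}")
        for name in ("micro_porosity", "macro_porosity", "water_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dry_mass <= 0 or self.volume <= 0:
            raise ValueError("dry_mass and volume must be positive")


def build_points(
    dataset: GpptDataset,
    match_window: float = 5.0,
    temperature: Optional[float] = None,
    agg: str = "median",
) -> List[KineticPoint]:
    """Match extraction-phase Ar samples to the 1 Hz CH4 record.

    For every extraction Ar sample, the CH4 value is the aggregate of the
    1 Hz readings within ±``match_window`` s of the sample time (the
    window median by default: for an odd, symmetric window it returns the
    central reading exactly on a noise-free monotone series, and under
    multiplicative lognormal noise it is unbiased in log space, which is
    the space the downstream regression works in; ``agg="mean"`` selects
    the arithmetic mean).  Relative concentrations are normalised to the
    background/injectate span per species; the dimensional CH4
    concentration uses the ideal-gas conversion at the configured
    temperature.  Points with a non-positive relative concentration are
    retained but flagged unusable for the log-ratio.
    """
    if agg not in {"median", "mean"}:
        raise ValueError("agg must be 'median' or 'mean'")
    cfg = dataset.config_echo
    if temperature is None:
        temperature = cfg.temperature
    if dataset.background is None:
        raise ValueError("dataset lacks a background record")
    ch4_bg, ar_bg = dataset.background
    if cfg.ch4_inj <= ch4_bg or cfg.ar_inj <= ar_bg:
        raise ValueError("injection concentration must exceed background")

    ext_ar = dataset.extraction_ar()
    if len(ext_ar) < 3:
        raise ValueError("need >= 3 extraction-phase Ar samples")
    t_ch4 = dataset.ch4_series["time_s"].to_numpy(float)
    v_ch4 = dataset.ch4_series["ch4_ppmv"].to_numpy(float)

    points = []
    for t_s, ar in zip(ext_ar["time_s"].to_numpy(float), ext_ar["ar_fraction"].to_numpy(float)):
        mask = np.abs(t_ch4 - t_s) <= match_window
        if not mask.any():
            raise ValueError(f"no CH4 readings within ±{match_window} s of t={t_s}")
        window = v_ch4[mask]
        ch4 = float(np.median(window) if agg == "median" else np.mean(window))
        t_e = t_s - cfg.t_inj
        c_rel_ch4 = (ch4 - ch4_bg) / (cfg.ch4_inj - ch4_bg)
        c_rel_ar = (ar - ar_bg) / (cfg.ar_inj - ar_bg)
        points.append(
            KineticPoint(
                t_e=float(t_e),
                t_star=float(transformed_time(t_e, cfg.t_inj)) / 3600.0,
                c_rel_ar=c_rel_ar,
                c_rel_ch4=c_rel_ch4,
                c_ch4=float(mixing_ratio_to_umol_per_l(ch4, temperature)),
                usable=(c_rel_ch4 > 0 and c_rel_ar > 0),
            )
        )
    return points


def estimate_activity(points: Sequence[KineticPoint]) -> ActivityFit:
    """Activity coefficient k from the log-ratio regression.

    Ordinary least squares of ln(C*_CH4/C*_Ar) on t* over the usable
    points; k is the negative slope.  A non-positive k̂ is reported with
    the ``no_detectable_oxidation`` flag rather than truncated, so
    downstream correlations stay unbiased.
    """
    usable = [p for p in points if p.usable]
    if len(usable) < 3:
        raise ValueError("need >= 3 usable points (positive relative concentrations)")
    t = np.array([p.t_star for p in usable])
    y = np.array([p.log_ratio() for p in usable])
    if np.ptp(t) == 0:
        raise ValueError("zero variance in transformed time")
    res = stats.linregress(t, y)
    k = -float(res.slope)
    return ActivityFit(
        k=k,
        k_se=float(res.stderr),
        r2=float(res.rvalue**2),
        n=len(usable),
        no_detectable_oxidation=(k <= 0),
    )


def segment_rates(
    points: Sequence[KineticPoint], overlapping: bool = True
) -> List[SegmentRate]:
    """Segment-wise oxidation rates from sliding 3-point windows.

    Each window of three consecutive usable points yields a local
    activity k_local (negative slope of the three log-ratio points
    against t*), a running-average concentration C̄ (mean of the three
    dimensional CH4 values) and the rate R_ox = k_local·C̄.  Windows that
    would span a flagged (unusable) point are skipped.  Overlapping
    windows give n−2 segments from n points; ``overlapping=False``
    selects disjoint windows instead.
    """
    pts = list(points)
    if sum(p.usable for p in pts) < 3:
        raise ValueError("need >= 3 usable consecutive extraction points")
    step = 1 if overlapping else 3
    segments = []
    i = 0
    while i + 3 <= len(pts):
        trio = pts[i : i + 3]
        if all(p.usable for p in trio):
            t = np.array([p.t_star for p in trio])
            y = np.array([p.log_ratio() for p in trio])
            res = stats.linregress(t, y)
            k_local = -float(res.slope)
            c_bar = float(np.mean([p.c_ch4 for p in trio]))
            segments.append(SegmentRate(c_bar=c_bar, k_local=k_local, r_ox=k_local * c_bar))
            i += step
        else:
            i += 1
    if not segments:
        raise ValueError("no window of 3 consecutive usable points")
    return segments


def _aic(rss: float, n: int, n_params: int) -> float:
    """Gaussian-likelihood AIC, n·ln(RSS/n) + 2·(p+1), shared by both models."""
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * (n_params + 1)


def _fit_mm_nls(c: np.ndarray, r: np.ndarray, max_restarts: int = 5):
    """Nonlinear least squares for (Km, Vmax) in log-parameterisation.

    Positivity is enforced by optimising (ln Km, ln Vmax).  Start values
    are Km⁰ = median(C̄), Vmax⁰ = 1.5·max(R_ox), with up to
    ``max_restarts`` deterministic jittered restarts before declaring
    non-convergence.  Standard errors come from the Gauss–Newton
    covariance, delta-transformed back to the natural scale.
    """

    def resid(theta):
        km, vmax = np.exp(theta)
        return vmax * c / (km + c) - r

    r_max = max(float(r.max()), 1e-12)
    x0 = np.log([max(float(np.median(c)), 1e-9), 1.5 * r_max])
    # parameters confined to a generous physical range (1e-8..1e6 µmol/l
    # and µmol/l/h); a solution escaping it means the saturation is not
    # identifiable from the data (Km -> infinity degeneracy)
    lo, hi = np.log(1e-8), np.log(1e6)
    rng = np.random.default_rng(0)
    best = None
    for attempt in range(max_restarts + 1):
        start = x0 if attempt == 0 else x0 + rng.normal(0.0, 0.5, size=2)
        start = np.clip(start, lo + 1.0, hi - 1.0)
        try:
            sol = least_squares(resid, start, bounds=(lo, hi),
                                xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=500)
        except Exception:
            continue
        if not sol.success or not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or np.any(best.x > hi - 1e-6):
        return None
    km, vmax = np.exp(best.x)
    rss = float(2.0 * best.cost)
    n, p = len(c), 2
    se_km = se_vmax = float("nan")
    if n > p:
        jtj = best.jac.T @ best.jac
        try:
            cov_log = np.linalg.inv(jtj) * rss / (n - p)
            if cov_log[0, 0] >= 0:
                se_km = float(km * np.sqrt(cov_log[0, 0]))
            if cov_log[1, 1] >= 0:
                se_vmax = float(vmax * np.sqrt(cov_log[1, 1]))
        except np.linalg.LinAlgError:
            pass
    return {"km": float(km), "vmax": float(vmax), "km_se": se_km, "vmax_se": se_vmax, "rss": rss}


def fit_kinetics(
    segments: Sequence[SegmentRate],
    intercept: bool = False,
    max_restarts: int = 5,
) -> KineticFit:
    """Fit Michaelis–Menten and linear models to (C̄, R_ox) pairs and
    select by AIC.

    Both models are scored with the identical Gaussian-likelihood AIC,
    n·ln(RSS/n) + 2(p+1), so the comparison is coherent.  When the MM
    fit fails to converge, or the linear AIC is lower, the linear model
    is selected and no MM parameters are reported.
    """
    segs = list(segments)
    if len(segs) < 3:
        raise ValueError("need >= 3 segments")
    c = np.array([s.c_bar for s in segs])
    r = np.array([s.r_ox for s in segs])
    if np.unique(c).size < 2:
        raise ValueError("degenerate segments: constant concentration")

    if intercept:
        lin = stats.linregress(c, r)
        lin_slope, lin_intercept = float(lin.slope), float(lin.intercept)
        rss_lin = float(np.sum((lin_intercept + lin_slope * c - r) ** 2))
        p_lin = 2
    else:
        lin_slope = float(np.sum(c * r) / np.sum(c * c))
        lin_intercept = 0.0
        rss_lin = float(np.sum((lin_slope * c - r) ** 2))
        p_lin = 1
    aic_lin = _aic(rss_lin, len(segs), p_lin)

    mm = _fit_mm_nls(c, r, max_restarts=max_restarts)
    if mm is None:
        return KineticFit(
            km=None, vmax=None, km_se=None, vmax_se=None, aic_mm=None,
            lin_slope=lin_slope, lin_intercept=lin_intercept, aic_lin=aic_lin,
            selected_model="linear", segments=segs, mm_converged=False,
        )
    aic_mm = _aic(mm["rss"], len(segs), 2)
    if aic_mm < aic_lin:
        return KineticFit(
            km=mm["km"], vmax=mm["vmax"], km_se=mm["km_se"], vmax_se=mm["vmax_se"],
            aic_mm=aic_mm, lin_slope=lin_slope, lin_intercept=lin_intercept,
            aic_lin=aic_lin, selected_model="michaelis_menten", segments=segs,
        )
    return KineticFit(
        km=None, vmax=None, km_se=None, vmax_se=None, aic_mm=aic_mm,
        lin_slope=lin_slope, lin_intercept=lin_intercept, aic_lin=aic_lin,
        selected_model="linear", segments=segs,
    )


def pooled_fit(
    per_mound: Sequence[KineticFit],
    include_linear_mounds: bool = False,
    intercept: bool = False,
) -> KineticFit:
    """Single MM fit to the concatenated (C̄, R_ox) pairs of many mounds.

    Mounds whose individual AIC selection was linear are excluded by
    default, mirroring the pooled analysis "excluding mounds with linear
    behaviour"; pass ``include_linear_mounds=True`` to keep them.
    """
    fits = list(per_mound)
    if not fits:
        raise ValueError("empty pool")
    pooled_segments: List[SegmentRate] = []
    for f in fits:
        if include_linear_mounds or f.selected_model == "michaelis_menten":
            pooled_segments.extend(f.segments)
    if not pooled_segments:
        raise ValueError("no mound contributes segments to the pool")
    return fit_kinetics(pooled_segments, intercept=intercept)


def cell_specific_rate(
    mound_rate: float,
    dry_mass: float,
    copies_per_g: float,
    copies_per_cell: float = 2.0,
) -> float:
    """Cell-specific CH4 oxidation rate, mol CH4 cell⁻¹ h⁻¹.

    ``mound_rate`` is the whole-mound oxidation rate in µmol CH4 h⁻¹,
    divided by the methanotroph cell inventory estimated from pmoA copy
    numbers (``copies_per_g`` per g dry material over ``dry_mass`` g,
    assuming ``copies_per_cell`` pmoA copies per cell, default 2).
    """
    if mound_rate <= 0 or dry_mass <= 0 or copies_per_g <= 0 or copies_per_cell <= 0:
        raise ValueError("all inputs must be positive")
    cells = copies_per_g / copies_per_cell * dry_mass
    return mound_rate * 1e-6 / cells


# ---------------------------------------------------------------------------
# Model / Results layer
# ---------------------------------------------------------------------------


class GpptKinetics:
    """Kinetic model of one mound's GPPT record.

    Parameters
    ----------
    dataset : GpptDataset
    match_window : float
        Half-width (s) of the CH4-matching window around each Ar sample.
    temperature : float, optional
        Overrides the dataset temperature for unit conversion.
    intercept : bool
        Fit the comparison linear model through the origin (default) or
        with an intercept.  The through-origin null follows from the
        construction of the segment rates: R_ox = k_local·C̄ vanishes at
        zero concentration, so the no-saturation alternative to
        Michaelis–Menten is direct proportionality.
    overlapping : bool
        Sliding (default) or disjoint 3-point segment windows.
    agg : str
        Window aggregate for CH4 matching, "median" (default) or "mean".
    """

    def __init__(
        self,
        dataset: GpptDataset,
        match_window: float = 5.0,
        temperature: Optional[float] = None,
        intercept: bool = False,
        overlapping: bool = True,
        agg: str = "median",
    ):
        self.dataset = dataset
        self.match_window = match_window
        self.temperature = temperature
        self.intercept = intercept
        self.overlapping = overlapping
        self.agg = agg

    @classmethod
    def from_csv(cls, ch4_path, ar_path, background=None, config=None, **kwargs):
        """Build the model from the on-disk CSV dialect (see gpptkin.io)."""
        from .io import read_gppt_dataset

        dataset = read_gppt_dataset(ch4_path, ar_path, background=background, config=config)
        return cls(dataset, **kwargs)

    def fit(self) -> "GpptKineticsResults":
        points = build_points(
            self.dataset,
            match_window=self.match_window,
            temperature=self.temperature,
            agg=self.agg,
        )
        activity = estimate_activity(points)
        segments = segment_rates(points, overlapping=self.overlapping)
        kinetics = fit_kinetics(segments, intercept=self.intercept)
        return GpptKineticsResults(self, points, activity, kinetics)


class GpptKineticsResults:
    """Inference products of :meth:`GpptKinetics.fit`.

    Attributes
    ----------
    points : list of KineticPoint
    activity : ActivityFit
    kinetics : KineticFit
    """

    def __init__(self, model, points, activity, kinetics):
        self.model = model
        self.points = points
        self.activity = activity
        self.kinetics = kinetics

    @property
    def mound_id(self) -> str:
        return self.model.dataset.mound_id

    @property
    def segments(self) -> List[SegmentRate]:
        return self.kinetics.segments

    def to_dict(self) -> dict:
        k = self.kinetics
        return {
            "mound_id": self.mound_id,
            "activity": {
                "k": self.activity.k,
                "k_se": self.activity.k_se,
                "r2": self.activity.r2,
                "n": self.activity.n,
                "no_detectable_oxidation": self.activity.no_detectable_oxidation,
            },
            "segments": [
                {"c_bar": s.c_bar, "k_local": s.k_local, "r_ox": s.r_ox} for s in k.segments
            ],
            "kinetics": {
                "km": k.km,
                "vmax": k.vmax,
                "km_se": k.km_se,
                "vmax_se": k.vmax_se,
                "aic_mm": k.aic_mm,
                "lin_slope": k.lin_slope,
                "lin_intercept": k.lin_intercept,
                "aic_lin": k.aic_lin,
                "selected_model": k.selected_model,
                "mm_converged": k.mm_converged,
            },
        }

    def summary(self) -> str:
        """Plain-text summary table of the fitted kinetics."""
        a, k = self.activity, self.kinetics
        buf = _io.StringIO()
        w = buf.write
        w(f"GPPT kinetic fit — mound {self.mound_id}\n")
        w("=" * 54 + "\n")
        flag = "  [no detectable oxidation]" if a.no_detectable_oxidation else ""
        w(f"activity k        {a.k:10.4f} ± {a.k_se:.4f} h⁻¹  (r²={a.r2:.4f}, n={a.n}){flag}\n")
        w(f"segments          {len(k.segments):10d}\n")
        w(f"selected model    {k.selected_model:>10s}  (AIC MM={_fmt(k.aic_mm)}, linear={k.aic_lin:.2f})\n")
        if k.selected_model == "michaelis_menten":
            w(f"Km                {k.km:10.3f} ± {_fmt(k.km_se)} µmol l⁻¹\n")
            w(f"Vmax              {k.vmax:10.3f} ± {_fmt(k.vmax_se)} µmol l⁻¹ h⁻¹\n")
        else:
            w(f"linear slope      {k.lin_slope:10.4f} h⁻¹   intercept {k.lin_intercept:.4f} µmol l⁻¹ h⁻¹\n")
            if not k.mm_converged:
                w("note: MM fit did not converge; linear fallback\n")
        return buf.getvalue()

    def plot(self, ax=None):
        """Scatter the (C̄, R_ox) segments with the selected-model curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = np.array([s.c_bar for s in self.segments])
        r = np.array([s.r_ox for s in self.segments])
        ax.plot(c, r, "o", label="segments")
        grid = np.linspace(0, c.max() * 1.05, 200)
        ax.plot(grid, self.kinetics.predict(grid), "-", label=self.kinetics.selected_model)
        ax.set_xlabel("CH4 concentration (µmol l⁻¹)")
        ax.set_ylabel("R_ox (µmol l⁻¹ h⁻¹)")
        ax.set_title(f"mound {self.mound_id}")
        ax.legend()
        return ax


def _fmt(x) -> str:
    return "n/a" if x is None or (isinstance(x, float) and not np.isfinite(x)) else f"{x:.2f}"
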