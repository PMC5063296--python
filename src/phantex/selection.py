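"""The three-criterion parameter selection.

A heterogeneity parameter is kept only if it is

1. volume independent — its value over concentric spherical VOIs on a
   homogeneous phantom image is flat (category A, "converging") above a
   minimal volume (~30 ml) in log-log space;
2. reproducible — the replicate coefficient of variation over independent
   scans stays below 10% in (almost) all acquisition-time x reconstruction
   cells;
3. sensitive — it responds by at least a configurable relative change when
   the imaged pattern moves between its homogeneous and most heterogeneous
   states in the dual-isotope dynamic series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .segmentation import spherical_voi
from .texture import PARAMETERS, compute_all_features

__all__ = [
    "CategoryLabel",
    "categorize_replicate_curves",
    "ReproducibilityReport",
    "SensitivityProfile",
    "SelectionConfig",
    "SelectionReport",
    "volume_dependence_curves",
    "categorize_curve",
    "reproducibility_analysis",
    "sensitivity_profiles",
    "sensitivity_score",
    "select_parameters",
]


@dataclass(frozen=True)
class CategoryLabel:
    """Volume-dependence class with its fit diagnostics.

    label: 'A' converging, 'B' positive slope, 'C' random-like,
    'D' negative slope; slope/r2/scatter refer to the log10-log10 line fit
    above the minimal volume (scatter = RMS residual of the fit, i.e. the
    flat-region fit quality: a flat but erratic curve is random-like, not
    converging).
    """

    label: str
    slope: float
    r2: float
    n_points: int
    scatter: float = 0.0
    shifted: bool = False  # non-positive values were offset before the log


def volume_dependence_curves(
    image,
    center_mm: tuple[float, float, float],
    volumes_ml: Sequence[float],
    within: np.ndarray | None = None,
    n_levels: int = 64,
) -> pd.DataFrame:
    """Feature values on concentric spherical VOIs.

    Returns a DataFrame indexed by achieved VOI volume (ml, strictly
    increasing) with one column per parameter.  Requested volumes are
    sorted internally.
    """
    vols = sorted(float(v) for v in volumes_ml)
    rows = []
    idx = []
    for v in vols:
        voi = spherical_voi(image, center_mm, v, within=within)
        fv = compute_all_features(image, voi, n_levels=n_levels)
        rows.append(fv.values)
        idx.append(fv.volume_ml)
    df = pd.DataFrame(rows, index=pd.Index(idx, name="volume_ml"))
    return df[~df.index.duplicated()]


def categorize_curve(
    volumes_ml: Sequence[float],
    values: Sequence[float],
    v_min_ml: float = 30.0,
    slope_tol: float = 0.065,
    r2_min: float = 0.8,
    scatter_tol: float = 0.015,
) -> CategoryLabel:
    """Classify one parameter's volume curve by its log-log fit above v_min.

    A (converging) needs both a flat fit (|slope| <= slope_tol) and a quiet
    flat region (RMS log-residual <= scatter_tol); a well-fit
    (R^2 >= r2_min) positive/negative slope gives B/D; anything else —
    erratic whether flat or sloped — is C (random-like).  Points from
    repeated acquisitions (several scanners) may share volumes; all are
    pooled into one fit.
    """
    slope, r2, scatter, n, shifted = _loglog_fit(volumes_ml, values, v_min_ml)
    label = _label_from_diagnostics(slope, r2, scatter, slope_tol, r2_min, scatter_tol)
    return CategoryLabel(label, slope, r2, n, scatter, shifted)


def categorize_replicate_curves(
    curves: Sequence[tuple[Sequence[float], Sequence[float]]],
    v_min_ml: float = 30.0,
    slope_tol: float = 0.065,
    r2_min: float = 0.8,
    scatter_tol: float = 0.015,
) -> CategoryLabel:
    """Classify from several curves of the same parameter (e.g. one per
    scanner): each curve is fitted separately — the scanners sit at
    different absolute levels — and the diagnostics are averaged before
    thresholding."""
    if not curves:
        raise ValueError("no curves given")
    fits = [_loglog_fit(v, y, v_min_ml) for v, y in curves]
    slope = float(np.mean([f[0] for f in fits]))
    r2 = float(np.mean([f[1] for f in fits]))
    scatter = float(np.mean([f[2] for f in fits]))
    n = int(sum(f[3] for f in fits))
    shifted = any(f[4] for f in fits)
    label = _label_from_diagnostics(slope, r2, scatter, slope_tol, r2_min, scatter_tol)
    return CategoryLabel(label, slope, r2, n, scatter, shifted)


def _loglog_fit(volumes_ml, values, v_min_ml):
    v = np.asarray(volumes_ml, dtype=float)
    y = np.asarray(values, dtype=float)
    sel = v >= v_min_ml
    if sel.sum() < 4:
        raise ValueError("need at least 4 curve points above the minimal volume")
    v, y = v[sel], y[sel]

    shifted = False
    if (y <= 0).any():
        rng = float(y.max() - y.min())
        y = y - y.min() + (1e-6 * rng if rng > 0 else 1.0)
        shifted = True
    if np.allclose(y, y[0]):
        return 0.0, 1.0, 0.0, int(sel.sum()), shifted

    lx, ly = np.log10(v), np.log10(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(((ly - pred) ** 2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    scatter = float(np.sqrt(ss_res / len(ly)))
    return float(slope), float(r2), scatter, int(sel.sum()), shifted


def _label_from_diagnostics(slope, r2, scatter, slope_tol, r2_min, scatter_tol):
    if abs(slope) <= slope_tol and scatter <= scatter_tol:
        return "A"
    if abs(slope) > slope_tol and r2 >= r2_min:
        return "B" if slope > 0 else "D"
    return "C"


@dataclass
class ReproducibilityReport:
    """Replicate CV per parameter per (setting, acquisition time) cell."""

    cells: pd.DataFrame  # columns: setting, acq_time_s, param, mean, sd, cv

    def cv_table(self, param: str) -> pd.DataFrame:
        t = self.cells[self.cells["param"] == param]
        return t.pivot(index="setting", columns="acq_time_s", values="cv")

    def fraction_below(self, cv_max: float = 0.10) -> pd.Series:
        """Per parameter: fraction of grid cells with replicate CV < cv_max."""
        ok = self.cells.assign(ok=self.cells["cv"] < cv_max)
        return ok.groupby("param")["ok"].mean()

    def worst_cv(self) -> pd.Series:
        return self.cells.groupby("param")["cv"].max()

    def best_cv(self) -> pd.Series:
        return self.cells.groupby("param")["cv"].min()


def reproducibility_analysis(replicate_features: pd.DataFrame) -> ReproducibilityReport:
    """Replicate mean/SD/CV per (setting, acquisition time, parameter).

    ``replicate_features`` is long-form with columns
    (setting, acq_time_s, replicate, param, value); each cell needs >= 2
    replicates.  Cells with zero mean get CV = NaN and are flagged.
    """
    req = {"setting", "acq_time_s", "replicate", "param", "value"}
    if not req.issubset(replicate_features.columns):
        raise ValueError(f"replicate table must have columns {sorted(req)}")
    g = replicate_features.groupby(["setting", "acq_time_s", "param"])["value"]
    if (g.count() < 2).any():
        raise ValueError("every (setting, time, param) cell needs >= 2 replicates")
    stats = g.agg(mean="mean", sd=lambda s: s.std(ddof=1)).reset_index()
    with np.errstate(divide="ignore", invalid="ignore"):
        stats["cv"] = np.where(
            stats["mean"] != 0, (stats["sd"] / stats["mean"]).abs(), np.nan
        )
    return ReproducibilityReport(cells=stats)


@dataclass
class SensitivityProfile:
    """Per-parameter time series over the dual-isotope dynamic series."""

    profiles: pd.DataFrame  # index: frame time (min), columns: parameters
    homogeneous_index: int  # positional index of the CoV-minimum frame

    @property
    def homogeneous_time_min(self) -> float:
        return float(self.profiles.index[self.homogeneous_index])


def sensitivity_profiles(series, mask, n_levels: int = 64) -> SensitivityProfile:
    """Feature time series over a dynamic series with one frozen VOI.

    The homogeneous frame is found empirically as the CoV minimum over the
    series (the equal-activity point of the two isotopes), never assumed at
    a fixed time.
    """
    if len(series) == 0:
        raise ValueError("empty dynamic series")
    rows, times = [], []
    for img in series:
        fv = compute_all_features(img, mask, n_levels=n_levels)
        rows.append(fv.values)
        times.append(float(img.provenance.get("frame_time_min", len(times))))
    df = pd.DataFrame(rows, index=pd.Index(times, name="frame_time_min"))
    hom = int(np.argmin(df["CoV"].to_numpy()))
    return SensitivityProfile(profiles=df, homogeneous_index=hom)


def sensitivity_score(profile: Sequence[float], homogeneous_index: int) -> float:
    """Relative change between the homogeneous and most heterogeneous frame.

    score = |v_het - v_hom| / |v_hom| with the most heterogeneous frame the
    one farthest from the homogeneous value; a zero-range profile scores 0
    and a zero homogeneous value falls back to the profile range as the
    denominator.
    """
    y = np.asarray(profile, dtype=float)
    if y.size == 0:
        raise ValueError("empty profile")
    v_hom = y[homogeneous_index]
    rng = float(y.max() - y.min())
    if rng == 0:
        return 0.0
    v_het = y[int(np.argmax(np.abs(y - v_hom)))]
    denom = abs(v_hom) if abs(v_hom) > 0 else rng
    return float(abs(v_het - v_hom) / denom)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the three criteria."""

    v_min_ml: float = 30.0
    slope_tol: float = 0.065
    r2_min: float = 0.8
    scatter_tol: float = 0.015
    cv_max: float = 0.10
    cell_pass_fraction: float = 0.75  # "almost all" cells
    s_min: float = 0.20


@dataclass
class SelectionReport:
    """Per-parameter verdicts of the three criteria and the final set."""

    table: pd.DataFrame  # per parameter: category, diagnostics, verdicts
    selected: list[str]
    config: SelectionConfig = field(default_factory=SelectionConfig)

    def summary(self) -> str:
        cols = [
            "category", "slope", "frac_cells_ok", "worst_cv", "sensitivity",
            "volume_ok", "repro_ok", "sensitivity_ok", "selected",
        ]
        with pd.option_context("display.width", 120, "display.precision", 3):
            head = self.table[cols].to_string()
        return (
            f"{head}\n\nselected ({len(self.selected)}): "
            + ", ".join(self.selected)
        )

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "config": self.config.__dict__,
            "parameters": {
                p: {k: (v if not isinstance(v, np.generic) else v.item())
                    for k, v in row.items()}
                for p, row in self.table.to_dict(orient="index").items()
            },
        }


def select_parameters(
    categories: Mapping[str, CategoryLabel],
    repro_report: ReproducibilityReport,
    sensitivity_scores: Mapping[str, float],
    config: SelectionConfig | None = None,
) -> SelectionReport:
    """Combine the three criteria conjunctively into the final selection."""
    cfg = config or SelectionConfig()
    missing = [
        p for p in PARAMETERS
        if p not in categories or p not in sensitivity_scores
    ]
    repro_params = set(repro_report.cells["param"])
    missing += [p for p in PARAMETERS if p not in repro_params]
    if missing:
        raise ValueError(f"missing stage results for: {sorted(set(missing))}")

    frac = repro_report.fraction_below(cfg.cv_max)
    worst = repro_report.worst_cv()
    rows = {}
    for p in PARAMETERS:
        cat = categories[p]
        sens = float(sensitivity_scores[p])
        vol_ok = cat.label == "A"
        rep_ok = bool(frac[p] >= cfg.cell_pass_fraction)
        sen_ok = bool(sens >= cfg.s_min)
        rows[p] = {
            "category": cat.label,
            "slope": cat.slope,
            "r2": cat.r2,
            "frac_cells_ok": float(frac[p]),
            "worst_cv": float(worst[p]),
            "sensitivity": sens,
            "volume_ok": vol_ok,
            "repro_ok": rep_ok,
            "sensitivity_ok": sen_ok,
            "selected": vol_ok and rep_ok and sen_ok,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "param"
    selected = [p for p in PARAMETERS if rows[p]["selected"]]
    return SelectionReport(table=table, selected=selected, config=cfg)
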