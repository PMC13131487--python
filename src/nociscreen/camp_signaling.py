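"""GloSensor cAMP plate-assay summaries.

Live HEK293 cells co-expressing a luminescent cAMP reporter and a candidate
GPCR are read on a plate reader: baseline luminescence is acquired before any
compound, an agonist (or vehicle) is added, then isoproterenol stimulates
adenylate cyclase through endogenous β-adrenergic receptors and luminescence
is followed for 5–20 min. A Gi/o-coupled receptor — agonist-activated or
constitutively active when over-expressed — suppresses the iso-stimulated
cAMP rise; a Gs-coupled receptor amplifies cAMP signaling.

All times are relative to isoproterenol addition at t = 0. Each well is
normalized to its own pre-compound baseline, which cancels per-well detector
gain and reporter load; conditions are then compared as ratios of mean
normalized responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "WellSeries",
    "NormalizedResponse",
    "normalize_well",
    "dose_response_table",
    "constitutive_index",
    "fit_four_param_logistic",
    "read_plate",
    "write_plate",
]

# Luminescence is read 5–20 min after isoproterenol addition.
DEFAULT_RESPONSE_WINDOW = (300.0, 1200.0)
DEFAULT_CALL_MARGIN = 0.2  # |index − 1| must exceed this for a coupling call


@dataclass
class WellSeries:
    """One well's luminescence time series (times relative to iso at t=0)."""

    well_id: str
    receptor: str  # receptor name, or "vector" for empty-vector controls
    agonist: str  # agonist name, or "none"
    dose: float  # molar concentration, 0 for vehicle
    time_s: np.ndarray
    rlu: np.ndarray
    replicate_index: int = 0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.rlu = np.asarray(self.rlu, dtype=float)
        if self.time_s.shape != self.rlu.shape:
            raise ValueError("time_s and rlu must have the same length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.rlu < 0):
            raise ValueError("RLU must be nonnegative")
        if self.dose < 0:
            raise ValueError("dose must be nonnegative")
        if not np.any(self.time_s < 0):
            raise ValueError("well needs at least one pre-treatment sample")


@dataclass(frozen=True)
class NormalizedResponse:
    well_id: str
    response: float  # dimensionless; NaN when degenerate
    degenerate: bool  # True when the baseline mean was zero


def normalize_well(
    series: WellSeries,
    baseline_window: tuple[float, float] | None = None,
    response_window: tuple[float, float] = DEFAULT_RESPONSE_WINDOW,
    summary: str = "max",
) -> NormalizedResponse:
    """Baseline-normalized response of one well.

    ``response = summary(RLU over response_window) / mean(RLU over
    baseline_window)``. The summary is the peak by default (robust to slow
    reporter kinetics); ``summary="mean"`` averages over the window. The
    baseline window defaults to all pre-treatment samples (t < 0). A zero
    baseline flags the well as degenerate (response NaN) rather than raising.
    """
    t = series.time_s
    if baseline_window is None:
        base_mask = t < 0
    else:
        base_mask = (t >= baseline_window[0]) & (t < baseline_window[1])
    resp_mask = (t >= response_window[0]) & (t <= response_window[1])
    if not base_mask.any():
        raise ValueError(f"well {series.well_id}: empty baseline window")
    if not resp_mask.any():
        raise ValueError(f"well {series.well_id}: empty response window")
    baseline = float(series.rlu[base_mask].mean())
    if baseline <= 0:
        return NormalizedResponse(series.well_id, math.nan, degenerate=True)
    window = series.rlu[resp_mask]
    value = float(window.max() if summary == "max" else window.mean())
    return NormalizedResponse(series.well_id, value / baseline, degenerate=False)


def _mean_normalized(wells: Sequence[WellSeries], **kwargs) -> tuple[float, int]:
    responses = [
        r.response for r in (normalize_well(w, **kwargs) for w in wells)
        if not r.degenerate
    ]
    if not responses:
        raise ValueError("no non-degenerate wells in group")
    return float(np.mean(responses)), len(responses)


def dose_response_table(
    wells: Sequence[WellSeries], warn: bool = True, **normalize_kwargs
) -> pd.DataFrame:
    """Per-dose mean ± dispersion of normalized responses, sorted by dose.

    All wells must share one (receptor, agonist) condition. The returned
    frame has columns ``dose, mean_response, sd_response, n`` plus a
    ``trend`` attribute in ``{"decreasing", "increasing", "none",
    "undefined"}``: the sign of the Spearman rank correlation between dose
    and per-dose mean response ("undefined" with a single dose).
    """
    if not wells:
        raise ValueError("no wells supplied")
    conditions = {(w.receptor, w.agonist) for w in wells}
    if len(conditions) != 1:
        raise ValueError(f"wells span multiple conditions: {sorted(conditions)}")
    rows = []
    for w in wells:
        r = normalize_well(w, **normalize_kwargs)
        rows.append({"dose": w.dose, "response": r.response,
                     "degenerate": r.degenerate})
    df = pd.DataFrame(rows)
    df = df[~df["degenerate"]]
    table = (
        df.groupby("dose")["response"]
        .agg(mean_response="mean", sd_response="std", n="size")
        .reset_index()
        .sort_values("dose", ignore_index=True)
    )
    if warn and (len(table) < 2 or (table["n"] < 2).any()):
        import warnings

        warnings.warn(
            "dose-response table has <2 doses or <2 replicates per dose",
            stacklevel=2,
        )
    if len(table) < 2:
        trend = "undefined"
    elif table["mean_response"].nunique() == 1:
        trend = "none"
    else:
        rho = stats.spearmanr(table["dose"], table["mean_response"]).statistic
        trend = "decreasing" if rho < 0 else ("increasing" if rho > 0 else "none")
    table.attrs["trend"] = trend
    return table


def fit_four_param_logistic(
    dose: Sequence[float], response: Sequence[float]
) -> dict[str, float]:
    """4PL refinement of a dose-response table: fit
    ``bottom + (top − bottom) / (1 + (d / ic50)^hill)`` over positive doses.

    Returns the fitted ``top, bottom, ic50, hill``. Needs ≥4 positive-dose
    points.
    """
    d = np.asarray(dose, dtype=float)
    y = np.asarray(response, dtype=float)
    pos = d > 0
    if pos.sum() < 4:
        raise ValueError("4PL fit needs at least 4 positive-dose points")
    d, y = d[pos], y[pos]

    def f(x, top, bottom, ic50, hill):
        return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)

    p0 = (float(y.max()), float(y.min()), float(np.median(d)), 1.0)
    bounds = ([0.0, 0.0, d.min() / 100.0, 0.1], [np.inf, np.inf, d.max() * 100.0, 10.0])
    popt, _ = optimize.curve_fit(f, d, y, p0=p0, bounds=bounds, maxfev=20000)
    return dict(zip(("top", "bottom", "ic50", "hill"), map(float, popt)))


def constitutive_index(
    receptor_wells: Sequence[WellSeries],
    vector_wells: Sequence[WellSeries],
    call_margin: float = DEFAULT_CALL_MARGIN,
    **normalize_kwargs,
) -> tuple[float, str]:
    """Ligand-independent coupling index of an over-expressed receptor.

    ``index = mean normalized receptor response / mean normalized vector
    response`` under identical stimulation. Qualitative call: ``Gi-like`` if
    index < 1 − margin (the receptor suppresses iso-stimulated cAMP),
    ``Gs-like`` if index > 1 + margin, ``none`` otherwise. The margin is a
    fixed effect-size criterion; replicate dispersion should be reported
    alongside.
    """
    if not receptor_wells or not vector_wells:
        raise ValueError("both well groups must be non-empty")
    receptor_mean, _ = _mean_normalized(receptor_wells, **normalize_kwargs)
    vector_mean, _ = _mean_normalized(vector_wells, **normalize_kwargs)
    index = receptor_mean / vector_mean
    if index < 1.0 - call_margin:
        call = "Gi-like"
    elif index > 1.0 + call_margin:
        call = "Gs-like"
    else:
        call = "none"
    return index, call


def write_plate(wells: Sequence[WellSeries], path) -> None:
    """Tidy plate table: well_id, receptor, agonist, dose, replicate, time_s, RLU."""
    pd.concat(
        [
            pd.DataFrame(
                {
                    "well_id": w.well_id,
                    "receptor": w.receptor,
                    "agonist": w.agonist,
                    "dose": w.dose,
                    "replicate_index": w.replicate_index,
                    "time_s": w.time_s,
                    "rlu": w.rlu,
                }
            )
            for w in wells
        ],
        ignore_index=True,
    ).to_csv(path, index=False)


def read_plate(path) -> list[WellSeries]:
    df = pd.read_csv(path)
    wells = []
    for well_id, grp in df.groupby("well_id", sort=False):
        grp = grp.sort_values("time_s")
        wells.append(
            WellSeries(
                well_id=str(well_id),
                receptor=str(grp["receptor"].iloc[0]),
                agonist=str(grp["agonist"].iloc[0]),
                dose=float(grp["dose"].iloc[0]),
                time_s=grp["time_s"].to_numpy(),
                rlu=grp["rlu"].to_numpy(),
                replicate_index=int(grp["replicate_index"].iloc[0]),
            )
        )
    return wells
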