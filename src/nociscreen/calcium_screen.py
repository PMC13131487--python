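"""KCl-pulse calcium-imaging excitability scoring and drug-effect classification.

Dissociated DRG neurons expressing a genetically encoded calcium indicator are
depolarized with repeated KCl pulses; the evoked calcium transient is a
surrogate for neuronal excitability. The first two pulses establish each
cell's baseline excitability, a candidate agonist is applied during the
interval before the third pulse, and the remaining pulses monitor washout.

Per trial, excitability ``e`` is the maximum ΔF/F within the response window.
Cells whose two baseline trials differ by ≥15% (relative to their mean) fail
quality control and are excluded. For the rest, the drug-trial excitability
relative to the baseline mean, ``r = e_drug / mean(e0, e1)``, classifies the
cell: inhibited if ``r < 0.85``, enhanced if ``r > 1.15``, unchanged
otherwise (strict inequalities — a cell at exactly 85% is unchanged).

Raw fluorescence has no absolute meaning, so every quantity here is invariant
to multiplying a trace by a positive gain. F₀ is estimated per trial as the
mean fluorescence over a short window immediately preceding each pulse onset,
which makes the scoring robust to slow baseline drift across the ~25 min
session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProtocolError",
    "DegenerateBaselineError",
    "InvalidMeasurementError",
    "StimulusProtocol",
    "CellTrace",
    "TrialExcitability",
    "CellClassification",
    "PopulationSummary",
    "compute_dff",
    "trial_excitability",
    "qc_baseline",
    "classify_cell",
    "stratify_by_diameter",
    "classify_trace",
    "classify_population",
    "summarize_population",
    "washout_check",
    "read_protocol",
    "write_protocol",
    "read_traces",
    "write_traces",
    "classifications_frame",
    "INHIBITED_THRESHOLD",
    "ENHANCED_THRESHOLD",
    "QC_MAX_RELATIVE_DIFF",
    "SMALL_DIAMETER_UM",
    "LARGE_DIAMETER_UM",
]

# Classification rule constants (fractions of the two-trial baseline mean).
INHIBITED_THRESHOLD = 0.85  # inhibited iff e_drug/baseline < 0.85 (strict)
ENHANCED_THRESHOLD = 1.15  # enhanced iff e_drug/baseline > 1.15 (strict)
QC_MAX_RELATIVE_DIFF = 0.15  # QC pass iff |e0-e1|/mean(e0,e1) < 0.15 (strict)

# Soma-diameter strata (μm): small < 25, medium 25–35 inclusive, large > 35.
SMALL_DIAMETER_UM = 25.0
LARGE_DIAMETER_UM = 35.0

LABELS = ("inhibited", "enhanced", "unchanged", "excluded")
STRATA = ("small", "medium", "large", "unknown")


class ProtocolError(ValueError):
    """Invalid stimulus protocol (non-positive durations, bad ordering...)."""


class DegenerateBaselineError(ValueError):
    """A trial's pre-pulse baseline fluorescence is non-positive or missing."""


class InvalidMeasurementError(ValueError):
    """A physically impossible measurement (e.g. non-positive diameter)."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing of repeated KCl pulses and the drug-coincident trial.

    Parameters
    ----------
    pulse_onsets_s
        Strictly increasing KCl pulse onset times in seconds.
    pulse_duration_s
        Duration of each KCl pulse (s).
    drug_trial_index
        0-based index of the pulse delivered together with the drug. At
        least two baseline trials must precede it (index ≥ 2).
    sampling_rate_hz
        Nominal acquisition rate of the fluorescence movie (Hz).
    response_window_s
        Length of the per-trial scoring window starting at pulse onset.
        Defaults to ``pulse_duration_s + 15`` s, which captures the transient
        peak without bleeding into the next baseline window.
    f0_window_s
        Length of the per-trial F₀ baseline window immediately preceding each
        pulse onset (s).
    drug_preapplication_s
        How long the drug is perfused before the drug-coincident pulse (s);
        the drug window spans this interval plus the pulse itself.
    """

    pulse_onsets_s: tuple[float, ...]
    pulse_duration_s: float
    drug_trial_index: int
    sampling_rate_hz: float = 1.0
    response_window_s: float | None = None
    f0_window_s: float = 10.0
    drug_preapplication_s: float = 300.0

    def __post_init__(self) -> None:
        onsets = tuple(float(t) for t in self.pulse_onsets_s)
        object.__setattr__(self, "pulse_onsets_s", onsets)
        if len(onsets) < 3:
            raise ProtocolError("protocol needs at least 3 pulses")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ProtocolError("pulse onsets must be strictly increasing")
        if self.pulse_duration_s <= 0:
            raise ProtocolError("pulse_duration_s must be positive")
        if self.sampling_rate_hz <= 0:
            raise ProtocolError("sampling_rate_hz must be positive")
        if self.f0_window_s <= 0:
            raise ProtocolError("f0_window_s must be positive")
        if self.response_window_s is None:
            object.__setattr__(
                self, "response_window_s", self.pulse_duration_s + 15.0
            )
        if self.response_window_s <= 0:
            raise ProtocolError("response_window_s must be positive")
        if not 2 <= self.drug_trial_index < len(onsets):
            raise ProtocolError(
                "drug_trial_index must leave two baseline trials before the "
                f"drug trial and address an existing pulse; got "
                f"{self.drug_trial_index} with {len(onsets)} pulses"
            )
        # Overlapping response windows would double-count a transient.
        for a, b in zip(onsets, onsets[1:]):
            if a + self.response_window_s > b:
                raise ProtocolError("response windows overlap between pulses")

    @property
    def n_trials(self) -> int:
        return len(self.pulse_onsets_s)

    @property
    def drug_window_s(self) -> tuple[float, float]:
        """(start, end) of drug perfusion: the pre-pulse application interval
        plus the drug-coincident pulse itself."""
        onset = self.pulse_onsets_s[self.drug_trial_index]
        return (onset - self.drug_preapplication_s, onset + self.pulse_duration_s)

    def response_window(self, trial_index: int) -> tuple[float, float]:
        onset = self.pulse_onsets_s[trial_index]
        return (onset, onset + self.response_window_s)

    def baseline_window(self, trial_index: int) -> tuple[float, float]:
        onset = self.pulse_onsets_s[trial_index]
        return (onset - self.f0_window_s, onset)


@dataclass
class CellTrace:
    """One cell's raw fluorescence time series.

    ``diameter_um`` may be ``None`` when the soma diameter was not measured;
    such cells still participate in unstratified summaries.
    """

    cell_id: str
    time_s: np.ndarray
    F: np.ndarray
    diameter_um: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.time_s.shape != self.F.shape:
            raise ValueError("time_s and F must have the same length")
        if self.time_s.size and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("F must be finite")


@dataclass(frozen=True)
class TrialExcitability:
    cell_id: str
    trial_index: int
    e: float  # max ΔF/F within the trial's response window


@dataclass(frozen=True)
class CellClassification:
    cell_id: str
    qc_pass: bool
    label: str  # inhibited | enhanced | unchanged | excluded
    baseline_e: float = math.nan  # mean of trials 0 and 1
    relative_excitability: float = math.nan  # e_drug / baseline_e
    stratum: str = "unknown"
    exclusion_reason: str | None = None
    washout_ratio: float | None = None
    trial_e: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if (self.label == "excluded") != (not self.qc_pass):
            raise ValueError("label is 'excluded' iff qc_pass is False")


@dataclass(frozen=True)
class PopulationSummary:
    """Counts and QC-passing fractions for one classified population.

    ``fractions_defined`` is False when every cell was excluded, in which
    case the fraction fields are NaN rather than raising.
    """

    n_total: int
    n_excluded: int
    n_inhibited: int
    n_enhanced: int
    n_unchanged: int
    fraction_inhibited: float
    fraction_enhanced: float
    fractions_defined: bool
    mean_relative_excitability: float
    per_stratum: Mapping[str, "PopulationSummary"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (
            self.n_inhibited + self.n_enhanced + self.n_unchanged
            != self.n_total - self.n_excluded
        ):
            raise ValueError("classification counts do not conserve n_total")


# ---------------------------------------------------------------------------
# per-trial ΔF/F and excitability
# ---------------------------------------------------------------------------

def compute_dff(trace: CellTrace, protocol: StimulusProtocol) -> pd.DataFrame:
    """Per-trial ΔF/F over each response window.

    For each trial, F₀ is the mean raw fluorescence over the pre-onset
    baseline window and ΔF/F(t) = (F(t) − F₀)/F₀ over the response window
    (onset inclusive, end exclusive).

    Returns a tidy frame with columns ``cell_id, trial_index, time_s, dff``.

    Raises
    ------
    DegenerateBaselineError
        If any trial's F₀ is non-positive (the cell should be excluded with
        a reason, which :func:`classify_trace` does).
    ValueError
        If the trace does not span a baseline or response window.
    """
    t, f = trace.time_s, trace.F
    rows: list[pd.DataFrame] = []
    for i in range(protocol.n_trials):
        b0, b1 = protocol.baseline_window(i)
        base = f[(t >= b0) & (t < b1)]
        if base.size == 0:
            raise ValueError(
                f"trace {trace.cell_id!r} has no samples in the F0 window "
                f"of trial {i}"
            )
        f0 = float(base.mean())
        if f0 <= 0:
            raise DegenerateBaselineError(
                f"trace {trace.cell_id!r}: non-positive F0 ({f0:g}) in "
                f"trial {i}"
            )
        r0, r1 = protocol.response_window(i)
        mask = (t >= r0) & (t < r1)
        if not mask.any():
            raise ValueError(
                f"trace {trace.cell_id!r} has no samples in the response "
                f"window of trial {i}"
            )
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": trace.cell_id,
                    "trial_index": i,
                    "time_s": t[mask],
                    "dff": (f[mask] - f0) / f0,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def trial_excitability(
    dff: pd.DataFrame, protocol: StimulusProtocol
) -> list[TrialExcitability]:
    """Per-trial excitability: the maximum ΔF/F within each response window.

    The max is taken as-is (no clipping), so an all-negative window yields a
    negative excitability.
    """
    out: list[TrialExcitability] = []
    for (cell_id, trial_index), grp in dff.groupby(
        ["cell_id", "trial_index"], sort=True
    ):
        if grp.empty:
            raise ValueError(f"empty response window for {cell_id}/{trial_index}")
        out.append(
            TrialExcitability(
                cell_id=str(cell_id),
                trial_index=int(trial_index),
                e=float(grp["dff"].max()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# the classification rules
# ---------------------------------------------------------------------------

def qc_baseline(e0: float, e1: float, denominator: str = "mean") -> bool:
    """Baseline-comparability QC: the two pre-drug trials must agree.

    Pass iff ``|e0 − e1| / denom < 0.15`` (strict). ``denominator`` is
    ``"mean"`` (default, symmetric in trial order) or ``"first"``. Degenerate
    inputs (non-positive or non-finite denominator) fail QC rather than raise.
    """
    if not (math.isfinite(e0) and math.isfinite(e1)):
        return False
    if denominator == "mean":
        denom = (e0 + e1) / 2.0
    elif denominator == "first":
        denom = e0
    else:
        raise ValueError("denominator must be 'mean' or 'first'")
    if denom <= 0:
        return False
    return abs(e0 - e1) / denom < QC_MAX_RELATIVE_DIFF


def classify_cell(e0: float, e1: float, e_drug: float) -> tuple[str, float]:
    """Apply the 15% drug-effect rule to one QC-passing cell.

    Returns ``(label, relative_excitability)`` where relative excitability is
    ``r = e_drug / mean(e0, e1)``: inhibited iff r < 0.85, enhanced iff
    r > 1.15, unchanged otherwise (boundaries are unchanged). A non-positive
    baseline cannot be normalized against and yields ``("excluded", nan)``.
    """
    baseline = (e0 + e1) / 2.0
    if baseline <= 0 or not math.isfinite(baseline):
        return "excluded", math.nan
    r = e_drug / baseline
    if r < INHIBITED_THRESHOLD:
        return "inhibited", r
    if r > ENHANCED_THRESHOLD:
        return "enhanced", r
    return "unchanged", r


def stratify_by_diameter(diameter_um: float | None) -> str:
    """Soma-diameter stratum: small (<25 μm), medium (25–35 μm, inclusive),
    large (>35 μm), or unknown for a missing measurement."""
    if diameter_um is None or (
        isinstance(diameter_um, float) and math.isnan(diameter_um)
    ):
        return "unknown"
    if diameter_um <= 0:
        raise InvalidMeasurementError(
            f"non-positive soma diameter: {diameter_um!r} μm"
        )
    if diameter_um < SMALL_DIAMETER_UM:
        return "small"
    if diameter_um <= LARGE_DIAMETER_UM:
        return "medium"
    return "large"


def washout_check(
    excitabilities: Sequence[float], protocol: StimulusProtocol
) -> float | None:
    """Washout recovery: mean post-drug-trial excitability / baseline mean.

    Report-only — no classification depends on it. Returns ``None`` when the
    protocol has no post-drug trials or the baseline is non-positive.
    """
    post = list(excitabilities[protocol.drug_trial_index + 1 :])
    if not post:
        return None
    baseline = (excitabilities[0] + excitabilities[1]) / 2.0
    if baseline <= 0:
        return None
    return float(np.mean(post) / baseline)


def classify_trace(
    trace: CellTrace,
    protocol: StimulusProtocol,
    qc_denominator: str = "mean",
) -> CellClassification:
    """Run the full per-cell pipeline: ΔF/F → per-trial e → QC → 15% rule."""
    stratum = stratify_by_diameter(trace.diameter_um)
    try:
        dff = compute_dff(trace, protocol)
    except DegenerateBaselineError:
        return CellClassification(
            cell_id=trace.cell_id,
            qc_pass=False,
            label="excluded",
            stratum=stratum,
            exclusion_reason="degenerate_baseline",
        )
    e_records = trial_excitability(dff, protocol)
    e = [rec.e for rec in sorted(e_records, key=lambda r: r.trial_index)]
    e0, e1, e_drug = e[0], e[1], e[protocol.drug_trial_index]
    baseline = (e0 + e1) / 2.0
    washout = washout_check(e, protocol)
    if not qc_baseline(e0, e1, denominator=qc_denominator):
        return CellClassification(
            cell_id=trace.cell_id,
            qc_pass=False,
            label="excluded",
            baseline_e=baseline,
            stratum=stratum,
            exclusion_reason="baseline_qc",
            washout_ratio=washout,
            trial_e=tuple(e),
        )
    label, r = classify_cell(e0, e1, e_drug)
    if label == "excluded":
        return CellClassification(
            cell_id=trace.cell_id,
            qc_pass=False,
            label="excluded",
            baseline_e=baseline,
            stratum=stratum,
            exclusion_reason="nonpositive_baseline",
            washout_ratio=washout,
            trial_e=tuple(e),
        )
    return CellClassification(
        cell_id=trace.cell_id,
        qc_pass=True,
        label=label,
        baseline_e=baseline,
        relative_excitability=r,
        stratum=stratum,
        washout_ratio=washout,
        trial_e=tuple(e),
    )


def classify_population(
    traces: Iterable[CellTrace],
    protocol: StimulusProtocol,
    qc_denominator: str = "mean",
) -> list[CellClassification]:
    return [classify_trace(tr, protocol, qc_denominator) for tr in traces]


def _summarize(classifications: Sequence[CellClassification]) -> PopulationSummary:
    n_total = len(classifications)
    counts = {lab: 0 for lab in LABELS}
    rels: list[float] = []
    for c in classifications:
        counts[c.label] += 1
        if c.qc_pass and math.isfinite(c.relative_excitability):
            rels.append(c.relative_excitability)
    n_pass = n_total - counts["excluded"]
    defined = n_pass > 0
    return PopulationSummary(
        n_total=n_total,
        n_excluded=counts["excluded"],
        n_inhibited=counts["inhibited"],
        n_enhanced=counts["enhanced"],
        n_unchanged=counts["unchanged"],
        fraction_inhibited=counts["inhibited"] / n_pass if defined else math.nan,
        fraction_enhanced=counts["enhanced"] / n_pass if defined else math.nan,
        fractions_defined=defined,
        mean_relative_excitability=float(np.mean(rels)) if rels else math.nan,
    )


def summarize_population(
    classifications: Sequence[CellClassification],
) -> PopulationSummary:
    """Population summary with per-stratum breakdowns.

    Fractions are over QC-passing cells. When every cell is excluded the
    fraction fields are NaN and ``fractions_defined`` is False. Per-stratum
    summaries cover cells with a known stratum; missing diameters never drop
    a cell from the unstratified summary.
    """
    if not classifications:
        raise ValueError("summarize_population needs at least one classification")
    overall = _summarize(classifications)
    per_stratum = {
        s: _summarize([c for c in classifications if c.stratum == s])
        for s in ("small", "medium", "large")
        if any(c.stratum == s for c in classifications)
    }
    return replace(overall, per_stratum=per_stratum)


def classifications_frame(
    classifications: Sequence[CellClassification],
) -> pd.DataFrame:
    """Flatten classifications into a tidy table (one row per cell)."""
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in classifications],
            "qc_pass": [c.qc_pass for c in classifications],
            "label": [c.label for c in classifications],
            "baseline_e": [c.baseline_e for c in classifications],
            "relative_excitability": [
                c.relative_excitability for c in classifications
            ],
            "stratum": [c.stratum for c in classifications],
            "exclusion_reason": [c.exclusion_reason for c in classifications],
            "washout_ratio": [c.washout_ratio for c in classifications],
        }
    )


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def write_protocol(protocol: StimulusProtocol, path: str | Path) -> None:
    """Write a protocol as plain-text ``key = value`` lines (lossless)."""
    lines = [
        "pulse_onsets_s = " + ",".join(repr(x) for x in protocol.pulse_onsets_s),
        f"pulse_duration_s = {protocol.pulse_duration_s!r}",
        f"drug_trial_index = {protocol.drug_trial_index}",
        f"sampling_rate_hz = {protocol.sampling_rate_hz!r}",
        f"response_window_s = {protocol.response_window_s!r}",
        f"f0_window_s = {protocol.f0_window_s!r}",
        f"drug_preapplication_s = {protocol.drug_preapplication_s!r}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_protocol(path: str | Path) -> StimulusProtocol:
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()
    try:
        return StimulusProtocol(
            pulse_onsets_s=tuple(
                float(x) for x in kv["pulse_onsets_s"].split(",")
            ),
            pulse_duration_s=float(kv["pulse_duration_s"]),
            drug_trial_index=int(kv["drug_trial_index"]),
            sampling_rate_hz=float(kv.get("sampling_rate_hz", 1.0)),
            response_window_s=(
                float(kv["response_window_s"])
                if "response_window_s" in kv
                else None
            ),
            f0_window_s=float(kv.get("f0_window_s", 10.0)),
            drug_preapplication_s=float(kv.get("drug_preapplication_s", 300.0)),
        )
    except KeyError as exc:
        raise ProtocolError(f"protocol file missing key: {exc}") from exc


def write_traces(traces: Sequence[CellTrace], path: str | Path) -> None:
    """Tidy delimited trace table: cell_id, time_s, F, diameter_um."""
    frames = [
        pd.DataFrame(
            {
                "cell_id": tr.cell_id,
                "time_s": tr.time_s,
                "F": tr.F,
                "diameter_um": (
                    tr.diameter_um if tr.diameter_um is not None else np.nan
                ),
            }
        )
        for tr in traces
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["cell_id", "time_s", "F", "diameter_um"])
    )
    df.to_csv(path, index=False)


def read_traces(path: str | Path) -> list[CellTrace]:
    df = pd.read_csv(path)
    traces = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("time_s")
        d = grp["diameter_um"].iloc[0]
        traces.append(
            CellTrace(
                cell_id=str(cell_id),
                time_s=grp["time_s"].to_numpy(),
                F=grp["F"].to_numpy(),
                diameter_um=None if pd.isna(d) else float(d),
            )
        )
    return traces
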