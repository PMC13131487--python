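"""Synthetic inputs with planted ground truth for every pipeline stage.

Every generator here emulates one of the raw data families the analysis
consumes — per-cell calcium traces under a KCl pulse protocol, gene ×
DRG-subtype expression summaries, GloSensor cAMP plate wells, paw-luminance
sessions, pinprick trials, and optically evoked EPSC sweep series — with
explicit noise models, effect sizes and responder fractions, so downstream
classifiers can be tested against known truth without any recorded data.

Randomness: each generator consumes a single root seed through
``numpy.random.SeedSequence``; internally independent streams are spawned in
a fixed order (e.g. responder flags, amplitudes, diameters, noise), so an
identical configuration, seed included, reproduces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calcium_screen import (
    CellTrace,
    ProtocolError,
    StimulusProtocol,
    stratify_by_diameter,
)
from .camp_signaling import WellSeries
from .behavior_metrics import LuminanceSession, PinprickTrial
from .ephys_metrics import OepscSeries

__all__ = [
    "SimConfig",
    "generate_protocol",
    "simulate_population",
    "simulate_expression_matrix",
    "default_subtype_annotation",
    "simulate_camp_wells",
    "simulate_dose_response_plate",
    "simulate_luminance_session",
    "simulate_pinprick_trials",
    "simulate_oepsc_series",
]

# Stratum mixture: (weight, mean μm, sd μm), truncated at 0.
DEFAULT_DIAMETERS: Mapping[str, tuple[float, float, float]] = {
    "small": (0.45, 20.0, 2.5),
    "medium": (0.35, 30.0, 2.5),
    "large": (0.20, 40.0, 3.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulated calcium-imaging population.

    Defaults are the reference screening conditions: 500 cells of which 40%
    respond to the drug with their drug-trial transient halved, 1% additive
    Gaussian noise on raw fluorescence (fraction of baseline F), and a mild
    1%/min linear baseline drift.
    """

    seed: int = 0
    n_cells: int = 500
    responder_fraction: float = 0.4
    effect_multiplier: float = 0.5
    noise_sd: float = 0.01
    drift_per_min: float = 0.01
    transient_decay_s: float = 8.0
    baseline_f: float = 100.0
    transient_amplitude_mean: float = 2.0  # peak ΔF/F of the KCl transient
    transient_amplitude_sd: float = 0.5
    transient_amplitude_min: float = 0.2
    diameter_distribution: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DIAMETERS)
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.transient_decay_s <= 0:
            raise ValueError("transient_decay_s must be positive")
        if self.effect_multiplier <= 0:
            raise ValueError("effect_multiplier must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        weights = [w for w, _, _ in self.diameter_distribution.values()]
        if not weights or abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("diameter stratum weights must sum to 1")


def generate_protocol(
    n_pulses: int = 5,
    pulse_duration_s: float = 15.0,
    inter_pulse_s: float = 300.0,
    drug_trial_index: int = 2,
    lead_in_s: float = 15.0,
    sampling_rate_hz: float = 1.0,
) -> StimulusProtocol:
    """KCl pulse protocol: a short lead-in, then evenly spaced pulses.

    ``inter_pulse_s`` is the onset-to-onset spacing (a 15 s pulse followed by
    285 s of washout gives the default 300 s). The drug-coincident pulse is
    the third (index 2) by default, with the drug perfused for the 5 min
    preceding it.
    """
    if n_pulses < 3:
        raise ProtocolError("need at least 3 pulses (two baseline + drug)")
    if pulse_duration_s <= 0 or inter_pulse_s <= 0 or lead_in_s < 0:
        raise ProtocolError("durations must be positive")
    onsets = tuple(lead_in_s + i * inter_pulse_s for i in range(n_pulses))
    return StimulusProtocol(
        pulse_onsets_s=onsets,
        pulse_duration_s=pulse_duration_s,
        drug_trial_index=drug_trial_index,
        sampling_rate_hz=sampling_rate_hz,
        drug_preapplication_s=min(300.0, inter_pulse_s),
    )


def _draw_diameters(
    rng: np.random.Generator,
    n: int,
    distribution: Mapping[str, tuple[float, float, float]],
) -> tuple[np.ndarray, np.ndarray]:
    strata = list(distribution)
    weights = np.array([distribution[s][0] for s in strata])
    idx = rng.choice(len(strata), size=n, p=weights / weights.sum())
    d = np.empty(n)
    for k, s in enumerate(strata):
        _, mu, sd = distribution[s]
        sel = idx == k
        draw = rng.normal(mu, sd, size=int(sel.sum()))
        # truncate at 0 by redrawing (vanishingly rare at realistic μ/σ)
        while np.any(draw <= 0):
            bad = draw <= 0
            draw[bad] = rng.normal(mu, sd, size=int(bad.sum()))
        d[sel] = draw
    # the ground-truth stratum is derived from the drawn diameter (mixture
    # tails can cross the 25/35 μm boundaries), matching the analysis rule
    return d, np.array([stratify_by_diameter(x) for x in d])


def simulate_population(
    config: SimConfig, protocol: StimulusProtocol
) -> tuple[list[CellTrace], pd.DataFrame]:
    """Simulate a KCl-pulsed population of indicator-expressing neurons.

    Each trace is ``F0·(1 + drift·t/60) + F0·a_i·exp(−(t−onset)/τ)`` summed
    over pulses (instantaneous rise at onset), plus i.i.d. Gaussian noise of
    sd ``noise_sd·F0``. Responders have their drug-trial amplitude multiplied
    by ``effect_multiplier``.

    Returns the traces and a ground-truth frame with columns
    ``cell_id, responder, diameter_um, stratum, amplitude``.
    """
    n = config.n_cells
    truth_cols = ["cell_id", "responder", "diameter_um", "stratum", "amplitude"]
    if n == 0:
        return [], pd.DataFrame(columns=truth_cols)

    ss = np.random.SeedSequence(config.seed)
    rng_resp, rng_amp, rng_diam, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    responder = rng_resp.random(n) < config.responder_fraction
    amp = rng_amp.normal(
        config.transient_amplitude_mean, config.transient_amplitude_sd, size=n
    )
    amp = np.maximum(amp, config.transient_amplitude_min)
    diam, stratum = _draw_diameters(rng_diam, n, config.diameter_distribution)

    dt = 1.0 / protocol.sampling_rate_hz
    t_end = protocol.pulse_onsets_s[-1] + protocol.response_window_s + 15.0
    t = np.arange(0.0, t_end, dt)

    f0 = config.baseline_f
    f = np.broadcast_to(
        f0 * (1.0 + config.drift_per_min * t / 60.0), (n, t.size)
    ).copy()
    decay = np.empty_like(t)
    for i, onset in enumerate(protocol.pulse_onsets_s):
        np.multiply(
            np.exp(-(np.maximum(t - onset, 0.0)) / config.transient_decay_s),
            t >= onset,
            out=decay,
        )
        trial_amp = amp.copy()
        if i == protocol.drug_trial_index:
            trial_amp[responder] *= config.effect_multiplier
        f += f0 * trial_amp[:, None] * decay[None, :]
    if config.noise_sd > 0:
        f += rng_noise.normal(0.0, config.noise_sd * f0, size=f.shape)

    width = max(4, len(str(n - 1)))
    ids = [f"cell{i:0{width}d}" for i in range(n)]
    traces = [
        CellTrace(cell_id=ids[i], time_s=t, F=f[i], diameter_um=float(diam[i]))
        for i in range(n)
    ]
    truth = pd.DataFrame(
        {
            "cell_id": ids,
            "responder": responder,
            "diameter_um": diam,
            "stratum": stratum,
            "amplitude": amp,
        }
    )
    return traces, truth


# ---------------------------------------------------------------------------
# gene × subtype expression matrices
# ---------------------------------------------------------------------------

def default_subtype_annotation() -> pd.DataFrame:
    """The mouse DRG subtype taxonomy used throughout: six CGRP+ subtypes,
    A/C-LTMRs, proprioceptors, and three 'other' classes that neither
    qualify nor disqualify a gene in the restriction screen."""
    rows = [
        ("CGRP_Bmpr1b", "CGRP", "CGRP+ Bmpr1b+ A-HTMR"),
        ("CGRP_Smr2", "CGRP", "CGRP+ Smr2+ A-HTMR"),
        ("CGRP_Sstr2", "CGRP", "CGRP+ Sstr2+ C-heat"),
        ("CGRP_MrgprA3", "CGRP", "CGRP+ MrgprA3+ C-HTMR/heat"),
        ("CGRP_eps_Oprk1", "CGRP", "CGRP-epsilon Oprk1+"),
        ("CGRP_theta_Adra2a", "CGRP", "CGRP-theta Adra2a+"),
        ("A_LTMR", "LTMR", "A-fiber LTMR"),
        ("C_LTMR", "LTMR", "C-fiber LTMR"),
        ("proprioceptor", "proprioceptor", "proprioceptor"),
        ("TrpM8", "other", "TrpM8+ cold thermoreceptor"),
        ("MrgprD", "other", "MrgprD+ C-HTMR/heat"),
        ("Sst", "other", "Sst+ C-HTMR/pruriceptor"),
    ]
    return pd.DataFrame(rows, columns=["subtype_id", "class", "display_name"])


def simulate_expression_matrix(
    n_genes: int,
    subtypes: pd.DataFrame,
    planted_restricted: Sequence[str],
    dropout: float = 0.0,
    seed: int = 0,
    on_threshold: float = 0.1,
    off_threshold: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene × subtype expression with a planted CGRP-restricted gene set.

    Planted genes are expressed (≥ ``on_threshold``) in at least one CGRP+
    subtype and below ``off_threshold`` in every LTMR/proprioceptor subtype.
    Half of the remaining genes are decoys expressed in both CGRP+ and LTMR
    subtypes (restriction violators); the rest are background genes below the
    on-threshold everywhere. Gene ids are ``g0000, g0001, ...``; planted ids
    must belong to this universe.

    ``dropout`` zeroes entries at random, except that each planted gene keeps
    one guaranteed on-subtype entry and each decoy keeps its violating LTMR
    entry, so the planted set stays exactly recoverable by construction at
    any dropout level.

    Returns ``(matrix, truth)`` where truth has columns ``gene, role`` with
    role in {planted, decoy, background}.
    """
    if not 0.0 <= dropout <= 1.0:
        raise ValueError("dropout must be a fraction in [0, 1]")
    genes = [f"g{i:04d}" for i in range(n_genes)]
    universe = set(genes)
    missing = [g for g in planted_restricted if g not in universe]
    if missing:
        raise ValueError(f"planted genes not in universe: {missing}")
    classes = subtypes.set_index("subtype_id")["class"]
    cgrp_cols = list(classes.index[classes == "CGRP"])
    off_cols = list(classes.index[classes.isin(["LTMR", "proprioceptor"])])
    ltmr_cols = list(classes.index[classes == "LTMR"])
    if not cgrp_cols or not ltmr_cols:
        raise ValueError("annotation needs ≥1 CGRP and ≥1 LTMR subtype")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cols = list(subtypes["subtype_id"])
    # background: everywhere strictly below both thresholds
    low = 0.5 * min(on_threshold, off_threshold)
    values = rng.uniform(0.0, low, size=(n_genes, len(cols)))
    mat = pd.DataFrame(values, index=genes, columns=cols)

    hi = lambda size: rng.uniform(max(on_threshold, 0.5), 2.0, size=size)

    # entries that carry the planted guarantee are shielded from dropout:
    # each planted gene keeps one on-subtype entry, each decoy keeps its
    # violating LTMR entry, so the screen's truth never depends on dropout.
    protected: list[tuple[str, str]] = []
    planted = list(planted_restricted)
    for g in planted:
        k = rng.integers(1, len(cgrp_cols) + 1)
        on_subset = rng.choice(cgrp_cols, size=k, replace=False)
        mat.loc[g, on_subset] = hi(k)
        mat.loc[g, off_cols] = rng.uniform(0.0, low, size=len(off_cols))
        protected.append((g, str(on_subset[0])))

    others = [g for g in genes if g not in set(planted)]
    decoys = others[: len(others) // 2]
    for g in decoys:
        mat.loc[g, rng.choice(cgrp_cols)] = hi(1)
        ltmr = str(rng.choice(ltmr_cols))
        mat.loc[g, ltmr] = hi(1)
        protected.append((g, ltmr))

    if dropout > 0:
        keep_mask = rng.random(mat.shape) >= dropout
        for (g, c) in protected:
            keep_mask[genes.index(g), cols.index(c)] = True
        mat = mat.where(keep_mask, 0.0)

    role = pd.Series("background", index=genes, name="role")
    role[planted] = "planted"
    role[decoys] = "decoy"
    truth = role.rename_axis("gene").reset_index()
    return mat, truth


# ---------------------------------------------------------------------------
# GloSensor cAMP plate wells
# ---------------------------------------------------------------------------

def simulate_camp_wells(
    receptor: str,
    response_scale: float,
    n_replicates: int = 6,
    seed: int = 0,
    agonist: str = "none",
    dose: float = 0.0,
    baseline_rlu: float = 1000.0,
    iso_fold: float = 5.0,
    rise_tau_s: float = 240.0,
    noise_cv: float = 0.03,
    well_prefix: str = "",
) -> list[WellSeries]:
    """Replicate wells of one receptor/agonist/dose condition.

    Time is relative to isoproterenol addition at t = 0; the compound is
    added at t = −300 s and baseline luminescence is sampled before that.
    Post-iso luminescence rises exponentially toward
    ``baseline · iso_fold · response_scale`` — constitutive or
    agonist-induced Gi coupling is planted as ``response_scale < 1``,
    Gs-like amplification as ``> 1``. Each well has its own detector gain
    (lognormal) and multiplicative noise of CV ``noise_cv``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    t = np.arange(-360.0, 1201.0, 30.0)
    rise = np.where(t > 0, 1.0 - np.exp(-np.maximum(t, 0.0) / rise_tau_s), 0.0)
    wells = []
    for rep in range(n_replicates):
        gain = rng.lognormal(mean=0.0, sigma=0.1)
        clean = gain * baseline_rlu * (
            1.0 + (iso_fold * response_scale - 1.0) * rise
        )
        rlu = clean * (1.0 + rng.normal(0.0, noise_cv, size=t.size))
        wells.append(
            WellSeries(
                well_id=f"{well_prefix}{receptor}_{agonist}_{dose:g}_{rep}",
                receptor=receptor,
                agonist=agonist,
                dose=dose,
                time_s=t.copy(),
                rlu=np.maximum(rlu, 0.0),
                replicate_index=rep,
            )
        )
    return wells


def simulate_dose_response_plate(
    receptor: str,
    agonist: str,
    ic50: float,
    doses: Sequence[float],
    max_suppression: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
    **kwargs,
) -> list[WellSeries]:
    """Hill-type agonist suppression of the iso-stimulated cAMP response.

    Response scale at dose d is ``floor + (1 − floor)/(1 + d/ic50)`` with
    ``floor = max_suppression`` (the residual response at saturating dose),
    so the planted IC50 is the half-maximal-inhibition dose.
    """
    wells = []
    ss = np.random.SeedSequence(seed)
    for child, dose in zip(ss.spawn(len(doses)), doses):
        scale = max_suppression + (1.0 - max_suppression) / (1.0 + dose / ic50) \
            if dose > 0 else 1.0
        wells.extend(
            simulate_camp_wells(
                receptor,
                response_scale=scale,
                n_replicates=n_replicates,
                seed=int(child.generate_state(1)[0] % (2**31)),
                agonist=agonist,
                dose=dose,
                **kwargs,
            )
        )
    return wells


# ---------------------------------------------------------------------------
# behavior: paw luminance and pinprick
# ---------------------------------------------------------------------------

def simulate_luminance_session(
    seed: int = 0,
    duration_s: float = 1800.0,
    fps: float = 25.0,
    ipsi_factor: float = 0.6,
    base_luminance: float = 50.0,
    noise_sd: float = 2.0,
    locomotion_fraction: float = 0.3,
    block_s: float = 10.0,
    locomoting_speed: float = 6.0,
    resting_speed: float = 0.5,
) -> tuple[LuminanceSession, pd.DataFrame]:
    """A paw-luminance recording session with planted weight-bearing asymmetry.

    The full-length defaults reproduce the standard session: 30 min at
    25 fps, i.e. 45,000 frames. Ipsilateral luminance is reduced by
    ``ipsi_factor`` relative to the contralateral paw. Locomotion alternates
    in blocks of ``block_s``; ground truth per-frame state labels are
    returned alongside.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = int(round(duration_s * fps))
    block = max(1, int(round(block_s * fps)))
    n_blocks = -(-n // block)
    state_blocks = rng.random(n_blocks) < locomotion_fraction
    locomoting = np.repeat(state_blocks, block)[:n]
    speed = np.where(
        locomoting,
        rng.normal(locomoting_speed, 0.5, size=n),
        rng.normal(resting_speed, 0.2, size=n),
    )
    speed = np.maximum(speed, 0.0)
    ipsi = np.maximum(
        base_luminance * ipsi_factor + rng.normal(0.0, noise_sd, size=n), 0.0
    )
    contra = np.maximum(
        base_luminance + rng.normal(0.0, noise_sd, size=n), 0.0
    )
    session = LuminanceSession(ipsi=ipsi, contra=contra, fps=fps, speed=speed)
    truth = pd.DataFrame(
        {"frame": np.arange(n), "locomoting": locomoting, "speed": speed}
    )
    return session, truth


def simulate_pinprick_trials(
    n_trials: int = 5,
    seed: int = 0,
    peak_contact_v: float = 2.0,
    accel_peak_v: float = 0.3,
    responds: bool = True,
    fs_hz: float = 1000.0,
    noise_sd_v: float = 0.005,
) -> tuple[list[PinprickTrial], pd.DataFrame]:
    """Pinprick trials with synchronized button/contact/accelerometer channels.

    Each trial: button press at 0.2 s, pin-to-skin contact at a jittered
    onset near 0.5 s held for 50 ms at ``peak_contact_v``, and (for
    responders) an accelerometer ramp from 0 to ``accel_peak_v`` over 0.3 s
    starting at contact. Ground truth carries the planted contact onset.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    dt = 1.0 / fs_hz
    t = np.arange(0.0, 2.0, dt)
    trials, rows = [], []
    for k in range(n_trials):
        onset = 0.5 + float(rng.integers(0, 100)) * dt
        contact = np.where((t >= onset) & (t < onset + 0.05), peak_contact_v, 0.0)
        accel = np.zeros_like(t)
        if responds:
            ramp = np.clip((t - onset) / 0.3, 0.0, 1.0)
            accel = accel_peak_v * ramp * np.exp(
                -np.maximum(t - onset - 0.3, 0.0) / 0.2
            )
            accel[t < onset] = 0.0
        if noise_sd_v > 0:
            accel = np.abs(accel + rng.normal(0.0, noise_sd_v, size=t.size))
        trials.append(
            PinprickTrial(
                button_time_s=0.2,
                time_s=t.copy(),
                contact_v=contact,
                accel_v=accel,
            )
        )
        rows.append({"trial": k, "contact_onset_s": onset, "responds": responds})
    return trials, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# slice electrophysiology: oEPSC sweep series
# ---------------------------------------------------------------------------

def simulate_oepsc_series(
    seed: int = 0,
    suppression: float = 0.6,
    noise_sd: float = 0.05,
    baseline_s: float = 600.0,
    drug_s: float = 600.0,
    washout_s: float = 0.0,
    sweep_interval_s: float = 30.0,
    amplitude_pa: float = 100.0,
    resistance_drift: float = 0.05,
) -> OepscSeries:
    """Optically evoked EPSC amplitudes sampled every 30 s.

    Sweeps during the drug application are multiplied by ``suppression``;
    multiplicative Gaussian sweep noise has sd ``noise_sd``. The stability
    series (monitored input/series resistance) drifts linearly by
    ``resistance_drift`` (fraction of the initial value) over the recording.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    total = baseline_s + drug_s + washout_s
    times = np.arange(0.0, total, sweep_interval_s)
    drug_on = baseline_s
    drug_off = baseline_s + drug_s
    scale = np.where(
        (times >= drug_on) & (times < drug_off), suppression, 1.0
    )
    # persistent effect through washout unless washout_s == 0
    scale = np.where(times >= drug_off, suppression, scale)
    amps = amplitude_pa * scale * (1.0 + rng.normal(0.0, noise_sd, times.size))
    stability = 100.0 * (1.0 + resistance_drift * times / max(total, 1.0))
    return OepscSeries(
        sweep_times_s=times,
        amplitudes_pA=np.abs(amps),
        drug_on_time_s=drug_on,
        drug_off_time_s=drug_off,
        stability=stability,
    )
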