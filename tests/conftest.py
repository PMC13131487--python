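import numpy as np
import pytest
from hypothesis import settings

from nociscreen import calcium_screen as cal

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def short_protocol() -> cal.StimulusProtocol:
    """Compact 3-pulse protocol (drug on trial 2) for hand-built traces."""
    return cal.StimulusProtocol(
        pulse_onsets_s=(15.0, 75.0, 135.0),
        pulse_duration_s=15.0,
        drug_trial_index=2,
        sampling_rate_hz=1.0,
        response_window_s=30.0,
        f0_window_s=10.0,
    )


def make_trace(
    cell_id: str,
    protocol: cal.StimulusProtocol,
    trial_peaks: list[float],
    f0: float = 100.0,
    diameter_um: float | None = 30.0,
    gain: float = 1.0,
) -> cal.CellTrace:
    """Flat-baseline trace whose per-trial max ΔF/F equals trial_peaks.

    The transient is a 3-sample plateau at the peak starting one sample
    after pulse onset, so the window max is exactly f0 * (1 + peak).
    """
    t = np.arange(
        0.0,
        protocol.pulse_onsets_s[-1] + protocol.response_window_s + 5.0,
        1.0 / protocol.sampling_rate_hz,
    )
    f = np.full_like(t, f0)
    for onset, peak in zip(protocol.pulse_onsets_s, trial_peaks):
        mask = (t >= onset + 1) & (t < onset + 4)
        f[mask] = f0 * (1.0 + peak)
    return cal.CellTrace(
        cell_id=cell_id, time_s=t, F=gain * f, diameter_um=diameter_um
    )


@pytest.fixture
def make_flat_trace(short_protocol):
    def _make(cell_id, trial_peaks, **kwargs):
        return make_trace(cell_id, short_protocol, trial_peaks, **kwargs)

    return _make
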