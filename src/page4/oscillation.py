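"""Peak-based oscillation metrics: period, amplitude, treatment quench time.

Period estimation is deliberately peak-based (mean spacing of prominent
local maxima) rather than spectral: the circuit's limit cycle is strongly
anharmonic, and peak spacing is robust to the relaxation-type waveform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .circuit import Trajectory

__all__ = ["OscillationSummary", "detect_period", "quench_time", "QUENCH_NEVER"]

#: sentinel returned by :func:`quench_time` when the signal never quenches
QUENCH_NEVER = float("inf")

#: peak prominence threshold, as a fraction of the post-burn-in range
PROMINENCE_FRAC = 0.05

#: a signal oscillates if peak-to-peak amplitude exceeds this fraction of
#: its mean and at least three peaks are present
MIN_REL_AMPLITUDE = 0.01


@dataclass(frozen=True)
class OscillationSummary:
    """Summary of a (possibly absent) oscillation in one species."""

    is_oscillating: bool
    period: float | None          # h; None when not oscillating
    amplitude: float              # peak-to-peak over the analysis window
    peak_times: np.ndarray        # h, strictly increasing

    def __post_init__(self):
        if self.is_oscillating and not (self.period and self.period > 0):
            raise ValueError("oscillating summary requires a positive period")


def detect_period(traj: Trajectory, species: str = "H",
                  burn_in: float = 0.0) -> OscillationSummary:
    """Estimate the oscillation period of one species after ``burn_in``.

    Peaks are local maxima with prominence at least 5% of the
    post-burn-in range; the period is the mean spacing of successive
    peaks. With fewer than three peaks, or with peak-to-peak amplitude
    under 1% of the mean, the signal is flagged as non-oscillating
    (``period=None``) rather than raising.
    """
    x = traj.species(species)
    mask = traj.times >= burn_in
    if mask.sum() < 10:
        raise ValueError("trajectory too short after burn_in")
    t, x = traj.times[mask], x[mask]
    rng = float(np.ptp(x))
    mean = float(np.mean(x))
    flat = OscillationSummary(False, None, rng, np.empty(0))
    if rng <= MIN_REL_AMPLITUDE * max(abs(mean), 1e-300):
        return flat
    idx, _ = find_peaks(x, prominence=PROMINENCE_FRAC * rng)
    if idx.size < 3:
        return flat
    peak_times = t[idx]
    period = float(np.mean(np.diff(peak_times)))
    return OscillationSummary(True, period, rng, peak_times)


def quench_time(traj: Trajectory, species: str, t_on: float,
                frac: float = 0.05) -> float:
    """First time after ``t_on`` at which the oscillation has quenched.

    Quenching is declared at the first grid time ``t >= t_on`` such that
    the peak-to-peak range of ``species`` within the sliding window
    ``[t, t + T]`` drops below ``frac`` times the pre-treatment
    peak-to-peak amplitude, where ``T`` is the pre-treatment period.
    Returns ``inf`` if the window never contracts that far; raises if no
    pre-treatment oscillation exists to define the reference amplitude.
    """
    pre = detect_period(_window(traj, traj.times[0], t_on), species)
    if not pre.is_oscillating:
        raise ValueError("no pre-treatment oscillation before t_on")
    period, ref_amp = pre.period, pre.amplitude
    x = traj.species(species)
    t = traj.times
    start = int(np.searchsorted(t, t_on))
    win = max(2, int(round(period / (t[1] - t[0]))))
    for i in range(start, t.size - win):
        seg = x[i:i + win + 1]
        if np.ptp(seg) < frac * ref_amp:
            return float(t[i])
    return QUENCH_NEVER


def _window(traj: Trajectory, t0: float, t1: float) -> Trajectory:
    m = (traj.times >= t0) & (traj.times < t1)
    return Trajectory(times=traj.times[m], states=traj.states[m],
                      params_id=traj.params_id, protocol_id=traj.protocol_id)
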