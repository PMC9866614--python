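"""Synthetic labeled EDA cohorts with class-dependent spectral structure.

The generator follows the minimal standard electrodermal model: a slowly
drifting tonic level with skin-conductance responses (SCRs) superposed as
bi-exponential pulses arriving as a Poisson process, plus broadband sensor
noise. The three affective states differ in the statistics the spectral
features exploit:

* **stress** — frequent, large SCRs at a constant rate with little noise:
  energy concentrates at low frequencies (low half-energy frequency) and
  consecutive segments look alike (low windowed variance);
* **amusement** — bursty: the SCR rate itself is redrawn every minute, so
  segments within a window differ strongly (high windowed variance);
* **baseline** — sparse small SCRs under the highest broadband noise, so
  relatively more energy sits at high frequencies (high half-energy
  frequency).

Effect sizes are deliberately large so the class structure is unambiguous:
these cohorts test pipeline wiring and feature-direction signs, not any
real dataset's absolute accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .signal_io import LabeledSignal


@dataclass(frozen=True)
class StateParams:
    """Per-state event and noise statistics.

    rate_per_min
        SCR arrival rate, events per minute.
    amp_median, amp_sigma
        Median (µS) and log-space dispersion of the log-normal SCR
        amplitude distribution.
    noise_sd
        Broadband Gaussian noise standard deviation, µS.
    """

    rate_per_min: float
    amp_median: float
    amp_sigma: float
    noise_sd: float


@dataclass(frozen=True)
class GeneratorParams:
    """Cohort-level generator settings; defaults define the study conditions."""

    fs: float = 4.0
    n_subjects: int = 6
    #: ordered (state, duration seconds) blocks per subject
    block_plan: tuple[tuple[str, float], ...] = (
        ("baseline", 600.0),
        ("amusement", 300.0),
        ("stress", 600.0),
    )
    states: dict[str, StateParams] = field(
        default_factory=lambda: {
            "baseline": StateParams(rate_per_min=2.0, amp_median=0.3, amp_sigma=0.5, noise_sd=0.12),
            "amusement": StateParams(rate_per_min=4.0, amp_median=0.7, amp_sigma=0.5, noise_sd=0.04),
            "stress": StateParams(rate_per_min=8.0, amp_median=0.8, amp_sigma=0.3, noise_sd=0.02),
        }
    )
    tau_r: float = 0.75  # SCR rise time constant, s
    tau_d: float = 3.0  # SCR decay time constant, s
    tonic_low: float = 2.0  # subject tonic offset drawn uniform in [low, high] µS
    tonic_high: float = 20.0
    drift_sd: float = 0.005  # tonic random-walk step SD, µS
    #: amusement rate is redrawn every this many seconds (log-normal around
    #: the state's base rate with this log-space dispersion); other states
    #: keep a constant rate
    burst_interval_s: float = 60.0
    burst_sigma: float = 2.0
    floor_uS: float = 0.05  # conductance is clipped to stay above this
    seed: int = 0


def scr_pulse(
    amplitude: float,
    tau_r: float = 0.75,
    tau_d: float = 3.0,
    fs: float = 4.0,
    duration: float = 20.0,
) -> np.ndarray:
    """Bi-exponential SCR waveform h(t) = A (e^(-t/tau_d) - e^(-t/tau_r)).

    Scaled so the sampled peak equals ``amplitude``; zero at t = 0 and
    non-negative throughout. The continuous-time peak sits at
    t* = tau_r*tau_d/(tau_d - tau_r) * ln(tau_d/tau_r). A degenerate kernel
    (tau_r ~ tau_d) returns zeros with a warning.
    """
    t = np.arange(int(round(duration * fs))) / fs
    shape = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    peak = shape.max()
    if peak <= 1e-12:
        warnings.warn("degenerate SCR kernel (tau_r ~ tau_d); returning zeros")
        return np.zeros_like(t)
    return amplitude * shape / peak


def draw_poisson_events(rng: np.random.Generator, rate_per_min: float, duration_s: float) -> np.ndarray:
    """Event times (seconds) of a homogeneous Poisson process on [0, duration)."""
    n = rng.poisson(rate_per_min / 60.0 * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def simulate_subject(params: GeneratorParams, subject_index: int) -> LabeledSignal:
    """One subject's labeled conductance trace; deterministic given (seed, index)."""
    rng = np.random.default_rng(params.seed + subject_index)
    fs = params.fs
    n_total = int(round(sum(d for _, d in params.block_plan) * fs))
    phasic = np.zeros(n_total)
    labels = np.empty(n_total, dtype=object)
    noise_sd = np.zeros(n_total)

    pulse_unit = scr_pulse(1.0, params.tau_r, params.tau_d, fs)
    block_start_s = 0.0
    for state, dur in params.block_plan:
        sp = params.states[state]
        i0 = int(round(block_start_s * fs))
        i1 = int(round((block_start_s + dur) * fs))
        labels[i0:i1] = state
        noise_sd[i0:i1] = sp.noise_sd

        if state == "amusement":
            # bursty: redraw the rate every burst interval
            event_times = []
            chunk_edges = np.arange(0.0, dur, params.burst_interval_s)
            for c0 in chunk_edges:
                c_dur = min(params.burst_interval_s, dur - c0)
                rate = sp.rate_per_min * rng.lognormal(0.0, params.burst_sigma)
                event_times.append(c0 + draw_poisson_events(rng, rate, c_dur))
            event_times = np.concatenate(event_times)
        else:
            event_times = draw_poisson_events(rng, sp.rate_per_min, dur)

        amps = rng.lognormal(np.log(sp.amp_median), sp.amp_sigma, size=len(event_times))
        for t_ev, amp in zip(event_times, amps):
            start = int(round((block_start_s + t_ev) * fs))
            end = min(start + len(pulse_unit), n_total)
            phasic[start:end] += amp * pulse_unit[: end - start]
        block_start_s += dur

    tonic = rng.uniform(params.tonic_low, params.tonic_high)
    drift = np.cumsum(rng.normal(0.0, params.drift_sd, size=n_total))
    noise = rng.normal(0.0, 1.0, size=n_total) * noise_sd
    samples = np.clip(tonic + drift + phasic + noise, params.floor_uS, None)
    return LabeledSignal(
        subject_id=f"sim{subject_index:02d}", samples=samples, labels=labels, fs=fs
    )


def simulate_cohort(params: GeneratorParams = GeneratorParams()) -> list[LabeledSignal]:
    """Independent subjects with distinct tonic levels; seeds are seed + index."""
    return [simulate_subject(params, i) for i in range(params.n_subjects)]
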