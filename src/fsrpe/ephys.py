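"""Synthetic spike trains and waveforms with planted encoding structure.

Every neuron is an inhomogeneous Poisson process whose rate is a baseline
plus planted signal components active in a latency window after an alignment
event.  Regressors per signal type (all derived from the attached RL model
trace):

* ``outcome`` — the reward indicator (1 on rewarded trials);
* ``pRPE``    — the RPE on correct trials (positive there), 0 on errors;
* ``nRPE``    — minus the RPE on error trials (so the regressor grows as the
                RPE becomes more negative), 0 on correct trials;
* ``uRPE``    — |RPE| on all trials (surprise);
* ``transfer`` — a color-onset response on trial n+1 scaled by
                (1 - |RPE| of trial n), active only when trial n chose the
                neuron's preferred color: the attention-transfer signature.

A feature condition (e.g. ``color=c1``) restricts a signal to trials on which
that feature was chosen.  Ground truth is carried on the neuron so the
classifier and population statistics can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import DIMENSIONS, FEATURE_NAMES, SessionBehavior

AREAS = ("ACC", "dlPFC", "CD", "VS")
SIGNAL_TYPES = ("outcome", "pRPE", "nRPE", "uRPE", "transfer")

# per-event simulation windows (s relative to the event)
EVENT_WINDOWS = {"outcome": (-0.7, 1.7), "color_on": (-0.6, 0.6)}
_SIGNAL_EVENT = {"outcome": "outcome", "pRPE": "outcome", "nRPE": "outcome",
                 "uRPE": "outcome", "transfer": "color_on"}

WAVEFORM_STEP_S = 25e-6  # 40 kHz digitization
WAVEFORM_N_SAMPLES = 48


@dataclass(frozen=True)
class PlantedSignal:
    signal: str                      # one of SIGNAL_TYPES
    gain: float                      # Hz per unit regressor
    latency: float = 0.2             # s after the alignment event
    duration: float = 0.4            # s
    dimension: str | None = None     # feature condition, e.g. ("color", "c1")
    feature: str | None = None

    def __post_init__(self) -> None:
        if self.signal not in SIGNAL_TYPES:
            raise ValueError(f"unknown signal type {self.signal!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if (self.dimension is None) != (self.feature is None):
            raise ValueError("dimension and feature must be given together")
        if self.dimension is not None and self.dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r}")


@dataclass(frozen=True)
class NeuronProfile:
    """Ground-truth description of a synthetic neuron."""

    area: str = "ACC"
    baseline_hz: float = 5.0
    signals: tuple[PlantedSignal, ...] = ()
    waveform_class: str = "broad"    # 'narrow' or 'broad'

    def __post_init__(self) -> None:
        if self.baseline_hz <= 0:
            raise ValueError("baseline must be positive")
        if self.area not in AREAS:
            raise ValueError(f"unknown area {self.area!r}")


@dataclass
class NeuronRecording:
    """Per-trial spike times aligned to named events, plus the waveform."""

    neuron_id: int
    area: str
    spikes: dict[str, list[np.ndarray]]
    waveform: np.ndarray
    session: SessionBehavior
    profile: NeuronProfile | None = None

    def n_trials(self) -> int:
        return self.session.n_trials


def _trial_regressors(trace: pd.DataFrame) -> dict[str, np.ndarray]:
    rpe = trace["rpe"].to_numpy(dtype=float)
    rewarded = trace["rewarded"].to_numpy(dtype=int)
    correct = rewarded == 1
    return {
        "outcome": rewarded.astype(float),
        "pRPE": np.where(correct, rpe, 0.0),
        "nRPE": np.where(~correct, -rpe, 0.0),
        "uRPE": np.abs(rpe),
    }


def _transfer_regressor(trace: pd.DataFrame, sig: PlantedSignal) -> np.ndarray:
    """Trial-(n+1) color-onset drive from trial n's RPE and chosen color."""
    rpe = np.abs(trace["rpe"].to_numpy(dtype=float))
    reg = np.zeros(len(trace))
    block = trace["block"].to_numpy()
    sess = trace["session"].to_numpy()
    prev_match = trace[sig.dimension].to_numpy()[:-1] == sig.feature
    consecutive = (block[1:] == block[:-1]) & (sess[1:] == sess[:-1])
    reg[1:] = np.where(prev_match & consecutive,
                       np.clip(1.0 - rpe[:-1], 0.0, None), 0.0)
    return reg


def simulate_neuron(profile: NeuronProfile, session: SessionBehavior,
                    trace: pd.DataFrame, seed: int,
                    neuron_id: int = 0) -> NeuronRecording:
    """Generate one neuron's spikes for every trial of the session.

    ``trace`` is the RPE-annotated trial table (see ``rl.rpe_trace``) aligned
    row-for-row with the session's trials.  Each alignment event gets an
    independent spike train over its simulation window; the rate is floored
    at zero after summing planted components.
    """
    if trace is None or len(trace) != session.n_trials:
        raise ValueError("rpe trace missing or not aligned to session trials")
    rng = np.random.default_rng(seed)
    regs = _trial_regressors(trace)
    n = session.n_trials

    # Per event, collect (per-trial extra rate, window) of each signal.
    per_event: dict[str, list[tuple[np.ndarray, float, float]]] = {
        ev: [] for ev in EVENT_WINDOWS
    }
    for sig in profile.signals:
        if sig.signal == "transfer":
            reg = _transfer_regressor(trace, sig)
        else:
            reg = regs[sig.signal].copy()
            if sig.dimension is not None:
                match = trace[sig.dimension].to_numpy() == sig.feature
                reg = np.where(match, reg, 0.0)
        per_event[_SIGNAL_EVENT[sig.signal]].append(
            (sig.gain * reg, sig.latency, sig.latency + sig.duration))

    spikes: dict[str, list[np.ndarray]] = {}
    for ev, (w0, w1) in EVENT_WINDOWS.items():
        comps = per_event[ev]
        trains = []
        for t in range(n):
            if not comps:
                m = rng.poisson(profile.baseline_hz * (w1 - w0))
                trains.append(np.sort(rng.uniform(w0, w1, size=m)))
                continue
            # merge components: piecewise-constant rate over breakpoints
            cuts = sorted({w0, w1, *(np.clip(x, w0, w1)
                                     for c in comps for x in (c[1], c[2]))})
            seg_spikes = []
            for lo, hi in zip(cuts[:-1], cuts[1:]):
                rate = profile.baseline_hz
                for extra, a, b in comps:
                    if lo >= a and hi <= b:
                        rate += extra[t]
                rate = max(rate, 0.0)
                m = rng.poisson(rate * (hi - lo))
                seg_spikes.append(rng.uniform(lo, hi, size=m))
            trains.append(np.sort(np.concatenate(seg_spikes)))
        spikes[ev] = trains

    waveform = simulate_waveform(profile.waveform_class,
                                 seed=int(rng.integers(2**31)))
    return NeuronRecording(neuron_id=neuron_id, area=profile.area,
                           spikes=spikes, waveform=waveform,
                           session=session, profile=profile)


# waveform templates: biphasic, negative trough then positive peak.
# durations in ms; trough->peak gap separates narrow from broad classes.
WAVEFORM_TEMPLATES = {
    "narrow": {"trough_t": 0.15, "peak_gap": 0.20, "trough_w": 0.06,
               "peak_w": 0.10, "peak_amp": 0.45},
    "broad": {"trough_t": 0.15, "peak_gap": 0.50, "trough_w": 0.10,
              "peak_w": 0.22, "peak_amp": 0.55},
}


def waveform_template(wf_class: str,
                      n_samples: int = WAVEFORM_N_SAMPLES) -> np.ndarray:
    """Noiseless class template (unit trough depth)."""
    p = WAVEFORM_TEMPLATES[wf_class]
    t = np.arange(n_samples) * WAVEFORM_STEP_S * 1e3  # ms
    trough = -np.exp(-0.5 * ((t - p["trough_t"]) / p["trough_w"]) ** 2)
    peak_t = p["trough_t"] + p["peak_gap"]
    peak = p["peak_amp"] * np.exp(-0.5 * ((t - peak_t) / p["peak_w"]) ** 2)
    return trough + peak


def simulate_waveform(wf_class: str, seed: int, noise_sd: float = 0.02,
                      n_samples: int = WAVEFORM_N_SAMPLES) -> np.ndarray:
    """Class template plus sample noise and a random amplitude scale."""
    rng = np.random.default_rng(seed)
    scale = rng.lognormal(0.0, 0.2)
    return scale * (waveform_template(wf_class, n_samples)
                    + rng.normal(0.0, noise_sd, size=n_samples))


@dataclass(frozen=True)
class PopulationGroup:
    """A homogeneous group of neurons to simulate."""

    count: int
    profile: NeuronProfile
    latency_sd: float = 0.0   # per-neuron jitter on planted latencies (s)


def simulate_population(groups: list[PopulationGroup],
                        session: SessionBehavior, trace: pd.DataFrame,
                        seed: int) -> tuple[list[NeuronRecording], pd.DataFrame]:
    """Simulate a population and return it with its ground-truth table.

    The truth table has one row per planted signal (neurons without signals
    contribute no rows) with columns neuron, area, signal, dimension,
    feature, gain, latency, duration, waveform_class.
    """
    rng = np.random.default_rng(seed)
    recs, truth_rows = [], []
    nid = 0
    for grp in groups:
        for _ in range(grp.count):
            prof = grp.profile
            if grp.latency_sd > 0 and prof.signals:
                jit = [PlantedSignal(
                    signal=s.signal, gain=s.gain,
                    latency=max(0.0, s.latency + rng.normal(0, grp.latency_sd)),
                    duration=s.duration, dimension=s.dimension,
                    feature=s.feature) for s in prof.signals]
                prof = NeuronProfile(area=prof.area,
                                     baseline_hz=prof.baseline_hz,
                                     signals=tuple(jit),
                                     waveform_class=prof.waveform_class)
            rec = simulate_neuron(prof, session, trace,
                                  seed=int(rng.integers(2**31)), neuron_id=nid)
            recs.append(rec)
            for s in prof.signals:
                truth_rows.append({
                    "neuron": nid, "area": prof.area, "signal": s.signal,
                    "dimension": s.dimension, "feature": s.feature,
                    "gain": s.gain, "latency": s.latency,
                    "duration": s.duration,
                    "waveform_class": prof.waveform_class,
                })
            nid += 1
    cols = ["neuron", "area", "signal", "dimension", "feature", "gain",
            "latency", "duration", "waveform_class"]
    truth = pd.DataFrame(truth_rows, columns=cols)
    return recs, truth
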