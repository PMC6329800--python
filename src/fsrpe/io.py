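"""Plain-text readers and writers for every pipeline artifact.

All tables are tab-delimited with a header row; model fits and run reports
are YAML.  Formats:

* trial table — one row per trial, columns: session, block, trial, color,
  location, motion, rewarded, rewarded_color, t_stim_on, t_color_on,
  t_motion_on, t_dim, t_outcome (times in s; trial indices 0-based within
  block).
* spikes — rows (neuron, trial, alignment_event, spike_time_s).
* waveforms — neuron x sample matrix, first column 'neuron'.
* labels / ground truth / statistics — flat delimited tables as produced by
  the corresponding modules.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .task import TRIAL_COLUMNS, SessionBehavior
from .ephys import NeuronRecording, EVENT_WINDOWS

SEP = "\t"


class ValidationError(ValueError):
    """Structured input-validation failure."""


def write_trials(sessions, path) -> None:
    if isinstance(sessions, SessionBehavior):
        sessions = [sessions]
    table = pd.concat([s.trials for s in sessions], ignore_index=True)
    table.to_csv(path, sep=SEP, index=False)


def read_trials(path) -> list[SessionBehavior]:
    table = pd.read_csv(path, sep=SEP)
    missing = set(TRIAL_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"trial table missing columns {sorted(missing)}")
    sessions = []
    for sid, sub in table.groupby("session", sort=True):
        sub = sub.reset_index(drop=True)
        rewarded_colors = (sub.groupby("block")["rewarded_color"]
                           .first().to_dict())
        sessions.append(SessionBehavior(trials=sub,
                                        rewarded_colors=rewarded_colors,
                                        session_id=int(sid)))
    return sessions


def write_spikes(recs: list[NeuronRecording], path) -> None:
    rows = []
    for rec in recs:
        for event, trains in rec.spikes.items():
            for trial, sp in enumerate(trains):
                for t in sp:
                    rows.append((rec.neuron_id, trial, event, t))
    table = pd.DataFrame(rows, columns=["neuron", "trial", "alignment_event",
                                        "spike_time_s"])
    table.to_csv(path, sep=SEP, index=False)


def read_spikes(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep=SEP)
    need = {"neuron", "trial", "alignment_event", "spike_time_s"}
    missing = need - set(table.columns)
    if missing:
        raise ValidationError(f"spike table missing columns {sorted(missing)}")
    return table


def spikes_to_recordings(spikes: pd.DataFrame, session: SessionBehavior,
                         areas: dict[int, str] | None = None,
                         waveforms: pd.DataFrame | None = None
                         ) -> list[NeuronRecording]:
    """Rebuild recordings from the flat spike table (one session)."""
    n_trials = session.n_trials
    recs = []
    for nid, sub in spikes.groupby("neuron", sort=True):
        trains = {ev: [np.empty(0)] * n_trials for ev in EVENT_WINDOWS}
        for (ev, trial), g in sub.groupby(["alignment_event", "trial"]):
            if trial >= n_trials:
                raise ValidationError(
                    f"neuron {nid}: spike references missing trial {trial}")
            trains.setdefault(ev, [np.empty(0)] * n_trials)
            trains[ev][int(trial)] = np.sort(g["spike_time_s"].to_numpy())
        wf = np.empty(0)
        if waveforms is not None and nid in waveforms.index:
            wf = waveforms.loc[nid].to_numpy(dtype=float)
        recs.append(NeuronRecording(
            neuron_id=int(nid), area=(areas or {}).get(int(nid), "ACC"),
            spikes=trains, waveform=wf, session=session))
    return recs


def write_waveforms(recs: list[NeuronRecording], path) -> None:
    mat = pd.DataFrame({rec.neuron_id: rec.waveform for rec in recs}).T
    mat.index.name = "neuron"
    mat.to_csv(path, sep=SEP)


def read_waveforms(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=SEP, index_col="neuron")


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep=SEP, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=SEP)


def write_yaml(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def validate_inputs(trial_path=None, spike_path=None,
                    waveform_path=None) -> list[str]:
    """Schema and referential-integrity checks; returns diagnostics.

    An empty list means every provided file passed.  Checks: required
    columns, strictly increasing event times per trial, reward consistency
    with the deterministic schedule, and that every spike row's trial exists
    in the trial table.
    """
    diagnostics: list[str] = []
    sessions = None
    if trial_path is not None:
        try:
            sessions = read_trials(trial_path)
        except (ValidationError, OSError) as e:
            diagnostics.append(f"trials: {e}")
    if sessions:
        for s in sessions:
            times = s.trials[["t_stim_on", "t_color_on", "t_motion_on",
                              "t_dim", "t_outcome"]].to_numpy()
            tmin = np.minimum(times[:, 1], times[:, 2])
            tmax = np.maximum(times[:, 1], times[:, 2])
            seq = np.stack([times[:, 0], tmin, tmax, times[:, 3],
                            times[:, 4]], axis=1)
            bad = np.where(~np.all(np.diff(seq, axis=1) > 0, axis=1))[0]
            for i in bad[:5]:
                diagnostics.append(
                    f"trials: session {s.session_id} row {i}: event times "
                    "not strictly increasing")
            mismatch = (s.trials["rewarded"] !=
                        (s.trials["color"] == s.trials["rewarded_color"])
                        .astype(int))
            for i in np.where(mismatch)[0][:5]:
                diagnostics.append(
                    f"trials: session {s.session_id} row {i}: reward "
                    "inconsistent with deterministic schedule")
    if spike_path is not None:
        try:
            spikes = read_spikes(spike_path)
        except (ValidationError, OSError) as e:
            diagnostics.append(f"spikes: {e}")
        else:
            if sessions:
                n_trials = {s.session_id: s.n_trials for s in sessions}
                max_t = max(n_trials.values())
                bad = spikes[spikes["trial"] >= max_t]
                for _, row in bad.head(5).iterrows():
                    diagnostics.append(
                        f"spikes: neuron {row['neuron']} references missing "
                        f"trial {row['trial']}")
    if waveform_path is not None:
        try:
            read_waveforms(waveform_path)
        except (ValueError, KeyError, OSError) as e:
            diagnostics.append(f"waveforms: {e}")
    return diagnostics
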