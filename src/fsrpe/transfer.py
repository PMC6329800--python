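"""Attention-transfer analysis: does a color-specific RPE neuron's color-onset
response grow after trials with small prediction errors (i.e. after learning)?

For each neuron the 25% of eligible trials with the largest and the 25% with
the smallest |RPE| (trial n) are extracted, split by whether trial n chose
the neuron's preferred color, and the normalized firing-rate change around
color onset on trial n+1,

    delta = (r_post - r_pre) / (r_post + r_pre)   in [-1, 1],

is averaged per condition.  Across neurons the low- vs high-RPE contrast is
tested with paired t tests within the preferred and nonpreferred conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ephys import NeuronRecording

CONDITIONS = ("low_pref", "high_pref", "low_nonpref", "high_nonpref")


@dataclass(frozen=True)
class TransferConfig:
    fraction: float = 0.25
    pre_window: tuple[float, float] = (-0.5, 0.0)
    post_window: tuple[float, float] = (0.0, 0.5)
    min_trials: int = 8


def _eligible_trials(trace: pd.DataFrame, sign: str) -> np.ndarray:
    """Trial class matching the neuron's signal type."""
    correct = trace["rewarded"].to_numpy(dtype=int) == 1
    if sign == "pRPE":
        return correct
    if sign == "nRPE":
        return ~correct
    if sign == "uRPE":
        return np.ones(len(trace), dtype=bool)
    raise ValueError(f"unknown signal sign {sign!r}")


def select_extreme_rpe_trials(trace: pd.DataFrame, sign: str,
                              fraction: float = 0.25,
                              eligible: np.ndarray | None = None
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the lowest- and highest-|RPE| quartiles of eligible trials.

    Each set holds floor(fraction * n_eligible) trials; ties are broken by
    trial order (stable sort).
    """
    if eligible is None:
        eligible = _eligible_trials(trace, sign)
    idx = np.where(eligible)[0]
    if len(idx) < 8:
        raise ValueError(f"only {len(idx)} eligible trials")
    mag = np.abs(trace["rpe"].to_numpy(dtype=float)[idx])
    order = idx[np.argsort(mag, kind="stable")]
    k = int(np.floor(fraction * len(idx)))
    return order[:k], order[-k:]


def color_onset_rate_change(rec: NeuronRecording, trial_n: np.ndarray,
                            cfg: TransferConfig = TransferConfig()
                            ) -> float | None:
    """Mean normalized rate change at color onset on trials n+1.

    Only consecutive within-block pairs are used; returns None when no valid
    n+1 trial exists.  delta is 0 when both window rates are 0.
    """
    trials = rec.session.trials
    block = trials["block"].to_numpy()
    nxt = trial_n + 1
    ok = (nxt < len(trials))
    ok[ok] &= block[nxt[ok]] == block[trial_n[ok]]
    nxt = nxt[ok]
    if len(nxt) == 0:
        return None
    deltas = []
    (a0, a1), (b0, b1) = cfg.pre_window, cfg.post_window
    for t in nxt:
        sp = rec.spikes["color_on"][t]
        r_pre = ((sp >= a0) & (sp < a1)).sum() / (a1 - a0)
        r_post = ((sp >= b0) & (sp < b1)).sum() / (b1 - b0)
        tot = r_pre + r_post
        deltas.append(0.0 if tot == 0 else (r_post - r_pre) / tot)
    return float(np.mean(deltas))


def neuron_transfer(rec: NeuronRecording, trace: pd.DataFrame,
                    sign: str, preferred_feature: str,
                    dimension: str = "color",
                    cfg: TransferConfig = TransferConfig()) -> dict | None:
    """Per-condition delta for one color-specific RPE neuron, or None."""
    eligible = _eligible_trials(trace, sign)
    chosen = trace[dimension].to_numpy()
    out = {}
    for prev, tag in ((chosen == preferred_feature, "pref"),
                      (chosen != preferred_feature, "nonpref")):
        try:
            low, high = select_extreme_rpe_trials(trace, sign, cfg.fraction,
                                                  eligible & prev)
        except ValueError:
            return None
        d_low = color_onset_rate_change(rec, low, cfg)
        d_high = color_onset_rate_change(rec, high, cfg)
        if d_low is None or d_high is None:
            return None
        out[f"low_{tag}"] = d_low
        out[f"high_{tag}"] = d_high
    return out


def _hedges_g_paired(x: np.ndarray, y: np.ndarray) -> float:
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0
    g = d.mean() / sd
    return g * (1.0 - 3.0 / (4.0 * n - 5.0))  # small-sample correction


def transfer_contrast(results: list[dict]) -> pd.DataFrame:
    """Paired low- vs high-RPE contrasts across neurons.

    One row per condition (preferred / nonpreferred previous color) with the
    paired t statistic, p-value and Hedges' g, plus a one-sample row testing
    whether delta is positive overall.
    """
    if len(results) < 2:
        raise ValueError("need at least two neurons with both conditions")
    rows = []
    for tag in ("pref", "nonpref"):
        low = np.array([r[f"low_{tag}"] for r in results])
        high = np.array([r[f"high_{tag}"] for r in results])
        diff = low - high
        if diff.std(ddof=0) == 0:
            # all-zero differences: a flat contrast (t = 0, p = 1); a
            # constant nonzero difference has degenerate variance and is
            # reported as not evaluable.
            flat = bool(np.all(diff == 0))
            rows.append({"condition": tag, "mean_low": float(low.mean()),
                         "mean_high": float(high.mean()),
                         "t": 0.0 if flat else None,
                         "p": 1.0 if flat else None,
                         "hedges_g": 0.0 if flat else None, "n": len(low),
                         "evaluable": flat})
            continue
        t, p = stats.ttest_rel(low, high)
        rows.append({"condition": tag, "mean_low": float(low.mean()),
                     "mean_high": float(high.mean()), "t": float(t),
                     "p": float(p), "hedges_g": _hedges_g_paired(low, high),
                     "n": len(low), "evaluable": True})
    alld = np.concatenate([[r[c] for c in CONDITIONS] for r in results])
    t1, p1 = stats.ttest_1samp(alld, 0.0)
    rows.append({"condition": "overall_delta_gt0", "mean_low": None,
                 "mean_high": None, "t": float(t1), "p": float(p1 / 2.0),
                 "hedges_g": None, "n": len(alld), "evaluable": True})
    return pd.DataFrame(rows)
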