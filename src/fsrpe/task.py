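"""Feature-based reversal-learning task engine.

Simulates the behavioral paradigm: on every trial two peripheral stimuli are
shown, one of each color, at opposite locations and with opposite motion
directions.  Only color is linked to reward, deterministically, and the
rewarded color reverses unannounced between blocks.  A block ends once the
running accuracy over the last 12 trials reaches 90% (checked from trial 30
on) or after 100 trials.

The module also provides an ideal-observer learning criterion (a binomial
state-space smoother) and descriptive behavioral summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DIMENSIONS = ("color", "location", "motion")
FEATURE_NAMES = {
    "color": ("c1", "c2"),
    "location": ("L", "R"),
    "motion": ("up", "down"),
}

TRIAL_COLUMNS = [
    "session", "block", "trial", "color", "location", "motion",
    "rewarded", "rewarded_color",
    "t_stim_on", "t_color_on", "t_motion_on", "t_dim", "t_outcome",
]


class ConfigError(ValueError):
    """Raised for invalid task configuration."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the reversal-learning task.

    Defaults mirror the published paradigm: 3 stimulus dimensions with 2
    features each, block length 30-100 trials, block change once the running
    accuracy over the last 12 trials reaches 0.90, color as the only
    reward-relevant dimension, and per-event timing ranges in seconds.
    """

    n_dimensions: int = 3
    features_per_dimension: int = 2
    block_len_min: int = 30
    block_len_max: int = 100
    criterion_rate: float = 0.90
    criterion_window: int = 12
    reward_relevant_dimension: str = "color"
    fixation_range: tuple[float, float] = (0.5, 0.9)
    first_feature_delay: float = 0.4
    second_feature_range: tuple[float, float] = (0.5, 0.9)
    dimming_range: tuple[float, float] = (0.4, 1.0)

    def __post_init__(self) -> None:
        if self.n_dimensions != 3 or self.features_per_dimension != 2:
            raise ConfigError("task is defined for 3 dimensions x 2 features")
        if self.block_len_min > self.block_len_max:
            raise ConfigError("block_len_min must be <= block_len_max")
        if self.criterion_window > self.block_len_min:
            raise ConfigError("criterion_window must be <= block_len_min")
        if self.reward_relevant_dimension not in DIMENSIONS:
            raise ConfigError(f"unknown dimension {self.reward_relevant_dimension!r}")
        if not 0 < self.criterion_rate <= 1:
            raise ConfigError("criterion_rate must be in (0, 1]")


@dataclass
class SessionBehavior:
    """One session: an ordered trial table plus per-block annotations.

    ``trials`` uses the canonical column layout (see ``TRIAL_COLUMNS``);
    features are stored by name ('c1'/'c2', 'L'/'R', 'up'/'down').
    ``learning_trials`` maps block id to the ideal-observer learning trial
    (0-based, within block) or ``None`` for blocks never learned.
    """

    trials: pd.DataFrame
    rewarded_colors: dict[int, str] = field(default_factory=dict)
    learning_trials: dict[int, int | None] = field(default_factory=dict)
    session_id: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def block_ids(self) -> list[int]:
        return sorted(self.rewarded_colors)

    def block_outcomes(self, block: int) -> np.ndarray:
        sel = self.trials["block"] == block
        return self.trials.loc[sel, "rewarded"].to_numpy(dtype=int)

    def learned_blocks(self) -> list[int]:
        return [b for b, lt in self.learning_trials.items() if lt is not None]

    def annotate_learning(self, chance: float = 0.5) -> "SessionBehavior":
        """Fill ``learning_trials`` for every block using the ideal observer."""
        for b in self.block_ids:
            self.learning_trials[b] = learning_trial(self.block_outcomes(b), chance)
        return self


def _chosen_features_codes(trials: pd.DataFrame) -> np.ndarray:
    """Integer codes (n_trials, 3) of the chosen color/location/motion."""
    out = np.empty((len(trials), 3), dtype=np.int64)
    for d, dim in enumerate(DIMENSIONS):
        f0 = FEATURE_NAMES[dim][0]
        out[:, d] = (trials[dim].to_numpy() != f0).astype(np.int64)
    return out


def generate_session(
    config: TaskConfig,
    agent,
    seed: int,
    n_blocks: int = 9,
    session_id: int = 0,
    first_rewarded_color: str | None = None,
) -> SessionBehavior:
    """Simulate one session of the reversal task.

    ``agent`` is any object with ``choose(stimuli, rng) -> int`` and
    ``observe(chosen_features, reward)`` methods plus ``reset()``; ``stimuli``
    is a pair of feature triples (color, location, motion codes 0/1).  The
    rewarded color alternates between consecutive blocks and the reward
    schedule is deterministic: R = 1 iff the chosen color matches the block's
    rewarded color.
    """
    rng = np.random.default_rng(seed)
    agent.reset()
    if first_rewarded_color is None:
        rewarded_code = int(rng.integers(2))
    else:
        rewarded_code = FEATURE_NAMES["color"].index(first_rewarded_color)

    rows = []
    rewarded_colors: dict[int, str] = {}
    for block in range(n_blocks):
        rewarded_colors[block] = FEATURE_NAMES["color"][rewarded_code]
        recent: list[int] = []
        trial = 0
        while True:
            loc_a = int(rng.integers(2))
            mot_a = int(rng.integers(2))
            # stimulus 0 carries color c1; the other stimulus is the
            # featurewise complement (other color, location, motion)
            stimuli = ((0, loc_a, mot_a), (1, 1 - loc_a, 1 - mot_a))
            choice = agent.choose(stimuli, rng)
            chosen = stimuli[choice]
            reward = int(chosen[0] == rewarded_code)
            agent.observe(chosen, reward)

            t_fix = rng.uniform(*config.fixation_range)
            t_stim_on = t_fix
            t_first = t_stim_on + config.first_feature_delay
            t_second = t_first + rng.uniform(*config.second_feature_range)
            # which feature (color or motion) appears first is counterbalanced
            if rng.integers(2) == 0:
                t_color_on, t_motion_on = t_first, t_second
            else:
                t_color_on, t_motion_on = t_second, t_first
            t_dim = t_second + rng.uniform(*config.dimming_range)
            t_outcome = t_dim + 0.3  # outcome delivered at end of dimming

            rows.append({
                "session": session_id, "block": block, "trial": trial,
                "color": FEATURE_NAMES["color"][chosen[0]],
                "location": FEATURE_NAMES["location"][chosen[1]],
                "motion": FEATURE_NAMES["motion"][chosen[2]],
                "rewarded": reward,
                "rewarded_color": FEATURE_NAMES["color"][rewarded_code],
                "t_stim_on": t_stim_on, "t_color_on": t_color_on,
                "t_motion_on": t_motion_on, "t_dim": t_dim,
                "t_outcome": t_outcome,
            })
            recent.append(reward)
            trial += 1
            if trial >= config.block_len_min:
                window = recent[-config.criterion_window:]
                if np.mean(window) >= config.criterion_rate:
                    break
            if trial >= config.block_len_max:
                break
        rewarded_code = 1 - rewarded_code  # uncued reversal

    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return SessionBehavior(trials=trials, rewarded_colors=rewarded_colors,
                           session_id=session_id)


class RandomAgent:
    """Uniform-random chooser; useful as a null behavioral model."""

    def reset(self) -> None:  # no internal state
        pass

    def choose(self, stimuli, rng) -> int:
        return int(rng.integers(2))

    def observe(self, chosen, reward) -> None:
        pass


class OmniscientAgent:
    """Always picks the currently rewarded color (needs the schedule).

    Only usable through :func:`generate_session_with_oracle`-style wiring: it
    tracks reward feedback to infer the rewarded color, which under the
    deterministic schedule it learns after one trial and never forgets until
    feedback contradicts it.
    """

    def __init__(self) -> None:
        self.best_color: int | None = None

    def reset(self) -> None:
        self.best_color = None

    def choose(self, stimuli, rng) -> int:
        if self.best_color is None:
            return int(rng.integers(2))
        return 0 if stimuli[0][0] == self.best_color else 1

    def observe(self, chosen, reward) -> None:
        self.best_color = chosen[0] if reward else 1 - chosen[0]


def learning_trial(
    outcomes: np.ndarray,
    chance: float = 0.5,
    sigma: float = 0.05,
    conf: float = 0.95,
    grid_size: int = 199,
) -> int | None:
    """Ideal-observer learning trial of a block (0-based) or ``None``.

    Implements a binomial state-space smoother: the latent probability-correct
    follows a reflected Gaussian random walk (step SD ``sigma``) on a grid in
    (0, 1), observations are Bernoulli.  The posterior over the latent
    probability is computed by forward-backward recursion; the learning trial
    is the earliest trial whose lower ``conf`` posterior bound exceeds
    ``chance`` and stays above chance for the rest of the block.
    """
    outcomes = np.asarray(outcomes, dtype=int)
    n = len(outcomes)
    if n < 5:
        raise ValueError("need at least 5 outcomes")
    grid = np.linspace(0.005, 0.995, grid_size)
    # reflected-walk transition matrix, rows normalized
    diff = grid[None, :] - grid[:, None]
    trans = np.exp(-0.5 * (diff / sigma) ** 2)
    trans /= trans.sum(axis=1, keepdims=True)

    like = np.where(outcomes[:, None] == 1, grid[None, :], 1.0 - grid[None, :])
    # forward pass
    alpha = np.empty((n, grid_size))
    prior = np.full(grid_size, 1.0 / grid_size)
    for t in range(n):
        pred = prior if t == 0 else alpha[t - 1] @ trans
        a = pred * like[t]
        alpha[t] = a / a.sum()
    # backward pass
    beta = np.empty((n, grid_size))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        b = trans @ (like[t + 1] * beta[t + 1])
        beta[t] = b / b.sum()
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)

    cdf = np.cumsum(post, axis=1)
    lo_idx = np.argmax(cdf >= (1.0 - conf), axis=1)
    lower = grid[lo_idx]
    above = lower > chance
    # earliest trial from which the bound stays above chance
    ok = np.logical_and.accumulate(above[::-1])[::-1]
    if not ok.any():
        return None
    return int(np.argmax(ok))


def behavior_summary(session: SessionBehavior, chance: float = 0.5) -> dict:
    """Descriptive statistics of one session.

    Returns repeat probabilities after correct trials (per dimension), block
    counts and lengths, and the fraction of learned blocks (annotating
    learning trials if not yet done).  Repeat probabilities are computed over
    consecutive within-block trial pairs; ``None`` when no such pair exists.
    """
    trials = session.trials
    if len(trials) < 2:
        return {
            "p_repeat_color": None, "p_repeat_location": None,
            "p_repeat_motion": None, "n_blocks": len(session.block_ids),
            "mean_block_length": float(len(trials)),
            "median_block_length": float(len(trials)),
            "fraction_learned": None,
        }
    if not session.learning_trials:
        session.annotate_learning(chance)

    prev_ok = (trials["rewarded"].to_numpy()[:-1] == 1)
    same_block = trials["block"].to_numpy()[1:] == trials["block"].to_numpy()[:-1]
    mask = prev_ok & same_block
    out: dict = {}
    for dim in DIMENSIONS:
        vals = trials[dim].to_numpy()
        rep = vals[1:] == vals[:-1]
        out[f"p_repeat_{dim}"] = float(rep[mask].mean()) if mask.any() else None

    lengths = trials.groupby("block").size()
    learned = session.learned_blocks()
    out.update({
        "n_blocks": len(session.block_ids),
        "mean_block_length": float(lengths.mean()),
        "median_block_length": float(lengths.median()),
        "fraction_learned": len(learned) / len(session.block_ids),
    })
    return out
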