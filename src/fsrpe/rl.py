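"""Feature-based reinforcement-learning model family.

Five variants of a delta-rule learner over six feature values (two features in
each of three stimulus dimensions):

* ``F-NS``      — feature-nonselective: every chosen feature updated equally.
* ``F-S``       — feature-selective: only color values are learned and used.
* ``F-DW``      — dimension-weighted: chosen-feature updates and stimulus
                  values are gated by learned dimension weights.
* ``F-Dec``     — F-NS plus decay of the nonchosen stimulus' feature values.
* ``F-DW-Dec``  — dimension weighting and decay combined.

The value of a stimulus is the weight-gated sum of its feature values,
choices are softmax in the value difference with inverse temperature beta,
and the trial-wise reward prediction error is RPE = R - V of the chosen
stimulus.  Dimension weights track each dimension's predictiveness, measured
as the absolute difference between its two feature values, with learning
rate phi (the weighting parameter is called alpha in some accounts; phi is
used here).  Decay pulls nonchosen-stimulus feature values back toward the
prior V0 at rate (1 - omega) per trial.

Fitting is maximum likelihood with a short simplex warm-start followed by
bounded L-BFGS-B from multiple start points; the trial loop is compiled with
numba and cross-checked against the pure-Python reference in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize

from .task import SessionBehavior, _chosen_features_codes

VARIANTS = ("F-NS", "F-S", "F-DW", "F-Dec", "F-DW-Dec")
_VARIANT_CODE = {v: i for i, v in enumerate(VARIANTS)}
# free parameters per variant, in canonical order (eta, beta, phi, omega)
_FREE = {
    "F-NS": ("eta", "beta"),
    "F-S": ("eta", "beta"),
    "F-DW": ("eta", "beta", "phi"),
    "F-Dec": ("eta", "beta", "omega"),
    "F-DW-Dec": ("eta", "beta", "phi", "omega"),
}
PARAM_BOUNDS = {"eta": (0.0, 1.0), "beta": (0.0, 20.0),
                "phi": (0.0, 1.0), "omega": (0.0, 1.0)}
_PROB_FLOOR = 1e-9


class DataError(ValueError):
    """Raised for malformed trial data."""


class FitError(RuntimeError):
    """Raised when no optimizer start converges."""


@dataclass(frozen=True)
class ModelSpec:
    """A model variant with (possibly unfitted) parameter values."""

    variant: str = "F-DW-Dec"
    eta: float = 0.3
    beta: float = 3.0
    phi: float = 0.5
    omega: float = 0.9
    v0: float = 0.5

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise DataError(f"unknown variant {self.variant!r}")
        for name in ("eta", "phi", "omega"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise DataError(f"{name} must lie in [0, 1]")
        if self.beta < 0:
            raise DataError("beta must be >= 0")

    @property
    def free_parameters(self) -> tuple[str, ...]:
        return _FREE[self.variant]

    @property
    def k(self) -> int:
        return len(self.free_parameters)

    def with_values(self, values: np.ndarray) -> "ModelSpec":
        kw = dict(variant=self.variant, eta=self.eta, beta=self.beta,
                  phi=self.phi, omega=self.omega, v0=self.v0)
        for name, v in zip(self.free_parameters, values):
            kw[name] = float(v)
        return ModelSpec(**kw)

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [PARAM_BOUNDS[p] for p in self.free_parameters]


class ModelState:
    """Mutable learner state: six feature values and three dimension weights.

    This is the readable reference implementation of the update rules; the
    numba kernel below replicates it for fitting speed.
    """

    def __init__(self, spec: ModelSpec) -> None:
        self.spec = spec
        self.V = np.full((3, 2), spec.v0)
        self.w = np.full(3, 1.0 / 3.0)

    def stimulus_value(self, stimulus) -> float:
        """Weight-gated sum of the stimulus' feature values.

        F-S uses the color value alone; unweighted variants use fixed
        uniform weights (each 1/3).
        """
        c, l, m = _check_stimulus(stimulus)
        if self.spec.variant == "F-S":
            return float(self.V[0, c])
        return float(self.w[0] * self.V[0, c] + self.w[1] * self.V[1, l]
                     + self.w[2] * self.V[2, m])

    def choice_probabilities(self, stimuli) -> np.ndarray:
        va = self.stimulus_value(stimuli[0])
        vb = self.stimulus_value(stimuli[1])
        b = self.spec.beta
        p0 = 1.0 / (1.0 + np.exp(-b * (va - vb)))
        return np.array([p0, 1.0 - p0])

    def update(self, chosen, reward: int) -> float:
        """Apply one trial's learning step; returns the RPE = R - V(chosen)."""
        if reward not in (0, 1):
            raise DataError("reward must be 0 or 1")
        spec = self.spec
        c, l, m = _check_stimulus(chosen)
        rpe = reward - self.stimulus_value(chosen)
        feats = (c, l, m)
        # chosen-feature delta-rule step, clipped to the value range: a
        # feature whose value already sits near a bound can otherwise
        # overshoot when the stimulus value is pulled away by other features
        if spec.variant == "F-S":
            self.V[0, c] = min(1.0, max(0.0, self.V[0, c] + spec.eta * rpe))
        else:
            weighted = spec.variant in ("F-DW", "F-DW-Dec")
            for d in range(3):
                g = self.w[d] if weighted else 1.0
                v = self.V[d, feats[d]] + spec.eta * g * rpe
                self.V[d, feats[d]] = min(1.0, max(0.0, v))
        if spec.variant in ("F-Dec", "F-DW-Dec"):
            for d in range(3):
                j = 1 - feats[d]
                self.V[d, j] = spec.omega * self.V[d, j] + (1 - spec.omega) * spec.v0
        if spec.variant in ("F-DW", "F-DW-Dec"):
            self.update_dimension_weights()
        return float(rpe)

    def update_dimension_weights(self) -> None:
        """Move weights toward each dimension's share of predictiveness.

        Predictiveness of a dimension is |V_f1 - V_f2|; the update is a
        convex step of size phi toward the normalized shares (uniform target
        when all shares vanish), then renormalized.
        """
        phi = self.spec.phi
        s = np.abs(self.V[:, 0] - self.V[:, 1])
        total = s.sum()
        target = s / total if total > 0 else np.full(3, 1.0 / 3.0)
        self.w = (1 - phi) * self.w + phi * target
        self.w /= self.w.sum()


def _check_stimulus(stimulus):
    c, l, m = stimulus
    for v in (c, l, m):
        if v not in (0, 1):
            raise DataError(f"unknown feature id {v!r}")
    return int(c), int(l), int(m)


# --------------------------------------------------------------------------
# fast likelihood kernel

@njit(cache=False)
def _nll_kernel(feats, rewards, session_ix, include,
                variant, eta, beta, phi, omega, v0):
    """Negative log likelihood over trials, with per-trial traces.

    feats: (n, 3) chosen-feature codes; session_ix: session index per trial
    (state resets when it changes); include: 0/1 mask selecting which trials
    contribute to the summed NLL (all trials always drive the state).
    Returns (nll, V_chosen, rpe, p_choice).
    """
    n = feats.shape[0]
    V = np.full((3, 2), v0)
    w = np.full(3, 1.0 / 3.0)
    vtrace = np.empty(n)
    rtrace = np.empty(n)
    ptrace = np.empty(n)
    nll = 0.0
    last_sess = -1
    for t in range(n):
        if session_ix[t] != last_sess:
            V[:, :] = v0
            w[:] = 1.0 / 3.0
            last_sess = session_ix[t]
        c = feats[t, 0]
        l = feats[t, 1]
        m = feats[t, 2]
        if variant == 1:  # F-S
            v_ch = V[0, c]
            v_un = V[0, 1 - c]
        else:
            v_ch = w[0] * V[0, c] + w[1] * V[1, l] + w[2] * V[2, m]
            v_un = (w[0] * V[0, 1 - c] + w[1] * V[1, 1 - l]
                    + w[2] * V[2, 1 - m])
        p = 1.0 / (1.0 + np.exp(-beta * (v_ch - v_un)))
        if p < _PROB_FLOOR:
            p = _PROB_FLOOR
        ptrace[t] = p
        vtrace[t] = v_ch
        r = rewards[t]
        rpe = r - v_ch
        rtrace[t] = rpe
        if include[t]:
            nll -= np.log(p)
        # learning step (clipped to the value range)
        if variant == 1:
            v_new = V[0, c] + eta * rpe
            V[0, c] = min(1.0, max(0.0, v_new))
        else:
            for d in range(3):
                f = feats[t, d]
                if variant == 2 or variant == 4:
                    g = w[d]
                else:
                    g = 1.0
                v_new = V[d, f] + eta * g * rpe
                V[d, f] = min(1.0, max(0.0, v_new))
        if variant == 3 or variant == 4:
            for d in range(3):
                j = 1 - feats[t, d]
                V[d, j] = omega * V[d, j] + (1.0 - omega) * v0
        if variant == 2 or variant == 4:
            total = 0.0
            s = np.empty(3)
            for d in range(3):
                s[d] = abs(V[d, 0] - V[d, 1])
                total += s[d]
            wsum = 0.0
            for d in range(3):
                tgt = s[d] / total if total > 0 else 1.0 / 3.0
                w[d] = (1.0 - phi) * w[d] + phi * tgt
                wsum += w[d]
            for d in range(3):
                w[d] /= wsum
    return nll, vtrace, rtrace, ptrace


def _stack_sessions(sessions) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    if isinstance(sessions, SessionBehavior):
        sessions = [sessions]
    if len(sessions) == 0:
        raise DataError("need at least one session")
    frames, feats, rewards, sess_ix = [], [], [], []
    for i, s in enumerate(sessions):
        frames.append(s.trials)
        feats.append(_chosen_features_codes(s.trials))
        r = s.trials["rewarded"].to_numpy(dtype=np.float64)
        if not np.isin(r, (0.0, 1.0)).all():
            raise DataError("rewards must be 0 or 1")
        rewards.append(r)
        sess_ix.append(np.full(len(s.trials), i, dtype=np.int64))
    return (np.vstack(feats), np.concatenate(rewards),
            np.concatenate(sess_ix), pd.concat(frames, ignore_index=True))


def negative_log_likelihood(spec: ModelSpec, sessions, include=None) -> float:
    """Summed -log P(chosen) over all (included) trials of the sessions.

    State evolves trial-by-trial across block boundaries (reversals are
    uncued to the model) and resets at session boundaries.  Choice
    probabilities are floored at 1e-9.
    """
    feats, rewards, sess_ix, _ = _stack_sessions(sessions)
    if include is None:
        include = np.ones(len(rewards), dtype=np.int64)
    nll, _, _, p = _nll_kernel(feats, rewards, sess_ix,
                               np.asarray(include, dtype=np.int64),
                               _VARIANT_CODE[spec.variant], spec.eta,
                               spec.beta, spec.phi, spec.omega, spec.v0)
    if (p <= _PROB_FLOOR).any():
        warnings.warn("choice probability floored at 1e-9", RuntimeWarning)
    return float(nll)


def rpe_trace(spec: ModelSpec, sessions) -> pd.DataFrame:
    """Trial table joined with per-trial model traces.

    Adds columns ``V_chosen``, ``rpe``, ``p_choice``, ``model_variant``.
    RPE = R - V(chosen stimulus), exactly.
    """
    feats, rewards, sess_ix, table = _stack_sessions(sessions)
    _, v, r, p = _nll_kernel(feats, rewards, sess_ix,
                             np.ones(len(rewards), dtype=np.int64),
                             _VARIANT_CODE[spec.variant], spec.eta,
                             spec.beta, spec.phi, spec.omega, spec.v0)
    out = table.copy()
    out["V_chosen"] = v
    out["rpe"] = r
    out["p_choice"] = p
    out["model_variant"] = spec.variant
    return out


@dataclass
class ModelFit:
    """Result of an MLE fit (and optionally cross-validation)."""

    spec: ModelSpec
    nll: float
    n_trials: int
    seed: int
    starts: list[dict] = field(default_factory=list)
    cv_test_ll: np.ndarray | None = None

    @property
    def aic(self) -> float:
        return 2.0 * self.spec.k + 2.0 * self.nll

    @property
    def mean_test_ll(self) -> float | None:
        if self.cv_test_ll is None:
            return None
        return float(np.mean(self.cv_test_ll))

    def to_dict(self) -> dict:
        d = {"variant": self.spec.variant, "nll": self.nll, "aic": self.aic,
             "n_trials": self.n_trials, "seed": self.seed,
             "parameters": {p: getattr(self.spec, p)
                            for p in self.spec.free_parameters},
             "n_starts": len(self.starts)}
        if self.cv_test_ll is not None:
            d["cv_test_ll"] = [float(x) for x in self.cv_test_ll]
            d["mean_test_ll"] = self.mean_test_ll
        return d


def fit_mle(template: ModelSpec, sessions, seed: int = 0,
            n_starts: int = 10, simplex_maxiter: int = 20,
            include=None) -> ModelFit:
    """Multi-start maximum-likelihood fit of one model variant.

    Each start runs a short Nelder-Mead warm-up (at most ``simplex_maxiter``
    iterations) and hands its best point to bounded L-BFGS-B; the winning
    start gets a final tight-tolerance polish.  Start points are drawn
    uniformly within the parameter bounds from ``seed`` (the first start is
    the template's own values), so refits with the same seed are identical.
    The default of 10 starts is deliberate: with the dimension-weighted
    decay variants the likelihood is shallow and locally wiggly in the
    weighting parameter, and fewer starts visibly under-converge.
    """
    feats, rewards, sess_ix, _ = _stack_sessions(sessions)
    if include is None:
        include = np.ones(len(rewards), dtype=np.int64)
    include = np.asarray(include, dtype=np.int64)
    code = _VARIANT_CODE[template.variant]
    names = template.free_parameters
    bounds = np.array(template.bounds)

    def objective(x: np.ndarray) -> float:
        x = np.clip(x, bounds[:, 0], bounds[:, 1])
        kw = {"eta": template.eta, "beta": template.beta,
              "phi": template.phi, "omega": template.omega}
        for nm, v in zip(names, x):
            kw[nm] = v
        nll, _, _, _ = _nll_kernel(feats, rewards, sess_ix, include, code,
                                   kw["eta"], kw["beta"], kw["phi"],
                                   kw["omega"], template.v0)
        return nll

    rng = np.random.default_rng(seed)
    x0s = [np.array([getattr(template, nm) for nm in names])]
    for _ in range(n_starts - 1):
        x0s.append(bounds[:, 0] + rng.random(len(names))
                   * (bounds[:, 1] - bounds[:, 0]))

    starts, best = [], None
    for x0 in x0s:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            warm = minimize(objective, x0, method="Nelder-Mead",
                            options={"maxiter": simplex_maxiter})
            res = minimize(objective, np.clip(warm.x, bounds[:, 0], bounds[:, 1]),
                           method="L-BFGS-B", bounds=bounds)
        ok = bool(res.success) or np.isfinite(res.fun)
        starts.append({"x0": x0.tolist(), "x": res.x.tolist(),
                       "nll": float(res.fun), "converged": ok})
        if ok and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError(f"no start converged for {template.variant}: {starts}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        polish = minimize(objective, np.clip(best.x, bounds[:, 0], bounds[:, 1]),
                          method="L-BFGS-B", bounds=bounds,
                          options={"ftol": 1e-12, "gtol": 1e-9})
    if np.isfinite(polish.fun) and polish.fun <= best.fun:
        best = polish
    spec = template.with_values(np.clip(best.x, bounds[:, 0], bounds[:, 1]))
    return ModelFit(spec=spec, nll=float(best.fun),
                    n_trials=int(include.sum()), seed=seed, starts=starts)


def cross_validate(template: ModelSpec, sessions, split: float = 0.8,
                   reps: int = 50, seed: int = 0,
                   n_starts: int = 3) -> pd.DataFrame:
    """Block-wise 80/20 cross-validation.

    Each repetition assigns a random ``1 - split`` fraction of blocks to the
    test set, fits on the training trials only (the learner's state still
    runs through every trial in order, so no trials are dropped from the
    state dynamics) and evaluates log-likelihood on the held-out trials.
    Returns one row per repetition with columns ``test_ll`` and
    ``n_test_trials``.
    """
    if isinstance(sessions, SessionBehavior):
        sessions = [sessions]
    blocks = [(i, b) for i, s in enumerate(sessions) for b in s.block_ids]
    if len(blocks) < 5:
        raise DataError("need at least 5 blocks for cross-validation")
    feats, rewards, sess_ix, table = _stack_sessions(sessions)
    block_of_trial = list(zip(sess_ix.tolist(), table["block"].tolist()))
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round((1.0 - split) * len(blocks))))
    rows = []
    for rep in range(reps):
        test_blocks = set(map(tuple, rng.permutation(np.array(blocks))[:n_test].tolist()))
        is_test = np.array([bt in test_blocks for bt in block_of_trial])
        train = (~is_test).astype(np.int64)
        fit = fit_mle(template, sessions, seed=int(rng.integers(2**31)),
                      n_starts=n_starts, include=train)
        test_nll = negative_log_likelihood(fit.spec, sessions,
                                           include=is_test.astype(np.int64))
        rows.append({"rep": rep, "test_ll": -test_nll,
                     "n_test_trials": int(is_test.sum())})
    return pd.DataFrame(rows)


def compare_models(fits: list[ModelFit]) -> pd.DataFrame:
    """Ranking table of fitted variants on the same data.

    Flags the AIC-best and (when cross-validation results are present) the
    CV-best variant.  AIC = 2k + 2 NLL.
    """
    n = {f.n_trials for f in fits}
    if len(n) != 1:
        raise DataError("fits compare different datasets (trial counts differ)")
    rows = [{"variant": f.spec.variant, "k": f.spec.k, "nll": f.nll,
             "aic": f.aic, "mean_test_ll": f.mean_test_ll} for f in fits]
    table = pd.DataFrame(rows)
    table["aic_best"] = table["aic"] == table["aic"].min()
    if table["mean_test_ll"].notna().all():
        table["cv_best"] = table["mean_test_ll"] == table["mean_test_ll"].max()
    return table.sort_values("aic").reset_index(drop=True)


class RLAgent:
    """Choice generator backed by a :class:`ModelState`, for task simulation."""

    def __init__(self, spec: ModelSpec) -> None:
        self.spec = spec
        self.state = ModelState(spec)

    def reset(self) -> None:
        self.state = ModelState(self.spec)

    def choose(self, stimuli, rng) -> int:
        p = self.state.choice_probabilities(stimuli)
        return int(rng.random() >= p[0])

    def observe(self, chosen, reward) -> None:
        self.state.update(chosen, reward)
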