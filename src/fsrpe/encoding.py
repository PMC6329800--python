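"""Time-resolved encoding classification of single neurons.

Firing rates in 200 ms windows stepped by 25 ms across the outcome epoch
(-0.5 to +1.5 s) are rank-correlated with model-derived reward prediction
errors: positive RPEs on correct trials (pRPE), negative RPEs on error
trials (nRPE, coded so that firing rises as the RPE becomes more negative),
and the absolute RPE with the outcome sign partialed out (uRPE, surprise).
A neuron encodes a signal when at least four consecutive post-outcome bins
are significant with the required sign while no run of more than two
same-sign significant bins precedes the outcome.  Feature-specific encoding
additionally requires the two per-feature correlation maps (e.g. color-1
vs color-2 chosen) to differ in at least four consecutive bins by the
Fisher z-test, overlapping an encoding run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .task import DIMENSIONS, FEATURE_NAMES
from .ephys import NeuronRecording

RPE_SIGNALS = ("pRPE", "nRPE", "uRPE")


@dataclass(frozen=True)
class BinningConfig:
    """Sliding-window configuration for the outcome epoch.

    The default step of 50 ms keeps the consecutive-bin run criterion
    conservative (windows stepped by 25 ms overlap by 87.5%, which lets a
    single noise excursion span many bins and inflates whole-neuron false
    positives roughly sixfold; see the methods note).  A 25 ms step is
    available for finer latency resolution.
    """

    alignment: str = "outcome"
    window: float = 0.200
    step: float = 0.050
    t_start: float = -0.500
    t_stop: float = 1.500

    def __post_init__(self) -> None:
        if self.window <= 0 or self.step <= 0 or self.step > self.window:
            raise ValueError("need 0 < step <= window")

    @property
    def starts(self) -> np.ndarray:
        """Window start times (-0.5 .. +1.3; 73 bins at the 25 ms step)."""
        n = int(round((self.t_stop - self.window - self.t_start) / self.step)) + 1
        return self.t_start + self.step * np.arange(n)

    @property
    def centers(self) -> np.ndarray:
        return self.starts + self.window / 2.0

    @property
    def post_mask(self) -> np.ndarray:
        """Bins whose window lies entirely after the outcome event."""
        return self.starts >= 0.0

    @property
    def n_bins(self) -> int:
        return len(self.starts)


@dataclass(frozen=True)
class ClassifierConfig:
    """All statistical thresholds, at their published defaults."""

    alpha: float = 0.05
    z_threshold: float = 1.96
    min_run: int = 4            # consecutive significant bins to encode
    max_pre_run: int = 2        # allowed pre-outcome consecutive bins
    min_trials: int = 15        # per correlation analysis
    min_usable_trials: int = 40
    min_rate_hz: float = 0.5
    feedback_epoch: tuple[float, float] = (0.0, 1.5)
    nrpe_opposite: bool = False  # alternative nRPE convention (rate drops)


@dataclass
class EncodingMap:
    """Per-bin correlation statistics for one regressor on one trial set."""

    r: np.ndarray
    p: np.ndarray
    n: int
    regressor: str
    evaluable: bool = True
    note: str = ""

    def significant(self, alpha: float, positive: bool) -> np.ndarray:
        sig = self.p < alpha
        return sig & (self.r > 0 if positive else self.r < 0)


@dataclass
class EncodingWindow:
    start_bin: int
    length: int
    bin_times: np.ndarray      # centers of the run's bins (s)
    r_peak: float


@dataclass
class NeuronLabelSet:
    """Classification outcome for one neuron."""

    neuron_id: int
    area: str
    included: bool
    exclusion_reasons: list[str] = field(default_factory=list)
    outcome_flag: bool = False          # epoch-mean regression decision
    outcome: EncodingWindow | None = None  # run-based window (latency analyses)
    nonspecific: dict[str, EncodingWindow | None] = field(default_factory=dict)
    feature_specific: dict = field(default_factory=dict)
    # feature_specific[(sign, dimension)] = (preferred_feature, EncodingWindow) | None

    def is_feature_specific(self, sign: str, dimension: str | None = None) -> bool:
        items = self.feature_specific.items()
        return any(v is not None for (s, d), v in items
                   if s == sign and (dimension is None or d == dimension))

    def nonspecific_only(self, sign: str) -> bool:
        """Nonspecific for this sign and not feature-specific for it.

        Feature-specific and nonspecific populations are kept disjoint for
        comparison analyses: a neuron counts as nonspecific only when it
        cannot also be identified as feature-specific.
        """
        return (self.nonspecific.get(sign) is not None
                and not self.is_feature_specific(sign))


# --------------------------------------------------------------------------
# rates and correlations

def bin_rates(rec: NeuronRecording, cfg: BinningConfig) -> np.ndarray:
    """Trial x bin firing-rate matrix (Hz), rate = count / window."""
    starts = cfg.starts
    stops = starts + cfg.window
    trains = rec.spikes[cfg.alignment]
    out = np.empty((len(trains), cfg.n_bins))
    for i, sp in enumerate(trains):
        out[i] = np.searchsorted(sp, stops) - np.searchsorted(sp, starts)
    return out / cfg.window


def _rank_columns(x: np.ndarray) -> np.ndarray:
    """Average ranks down each column (ties share the mean rank)."""
    return stats.rankdata(x, axis=0)


def _pearson_columns(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Pearson r of vector x against each column of y; 0 for constant cols."""
    xc = x - x.mean()
    yc = y - y.mean(axis=0)
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((yc ** 2).sum(axis=0))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (yc * xc[:, None]).sum(axis=0) / denom, 0.0)
    return np.clip(r, -1.0, 1.0)


def _t_pvalues(r: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p for correlation coefficients via the t approximation."""
    if df <= 0:
        return np.ones_like(r)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r ** 2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df)


def rank_correlation_map(rates: np.ndarray, x: np.ndarray,
                         regressor: str = "") -> EncodingMap:
    """Spearman correlation of each bin's rates with regressor ``x``.

    Ties receive average ranks; constant columns give r = 0, p = 1.
    """
    n = len(x)
    rr = _rank_columns(rates)
    rx = stats.rankdata(x)
    r = _pearson_columns(rr, rx)
    return EncodingMap(r=r, p=_t_pvalues(r, n - 2), n=n, regressor=regressor)


def partial_rank_correlation_map(rates: np.ndarray, x: np.ndarray,
                                 covariate: np.ndarray,
                                 regressor: str = "") -> EncodingMap:
    """Spearman partial correlation of rates with ``x`` given ``covariate``.

    Used for surprise: x = |RPE|, covariate = outcome sign (+/-1).  Falls
    back to a plain rank correlation when the covariate is constant.
    """
    if np.all(covariate == covariate[0]):
        m = rank_correlation_map(rates, x, regressor)
        m.note = "constant covariate; plain rank correlation"
        return m
    n = len(x)
    rr = _rank_columns(rates)
    rx = stats.rankdata(x)
    rz = stats.rankdata(covariate)
    r_xy = _pearson_columns(rr, rx)
    r_yz = _pearson_columns(rr, rz)
    r_xz = _pearson_columns(rx[:, None], rz)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt((1.0 - r_xz ** 2) * (1.0 - r_yz ** 2))
        r = np.where(denom > 0, (r_xy - r_xz * r_yz) / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    return EncodingMap(r=r, p=_t_pvalues(r, n - 3), n=n, regressor=regressor)


def fisher_z_compare(r1: float | np.ndarray, n1: int,
                     r2: float | np.ndarray, n2: int):
    """Z statistic for the difference of two independent correlations.

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(N1-3) + 1/(N2-3)).  |Z| > 1.96
    marks a significant bin-wise difference at p < 0.05.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need N > 3 in both groups")
    z1 = np.arctanh(np.clip(r1, -1 + 1e-15, 1 - 1e-15))
    z2 = np.arctanh(np.clip(r2, -1 + 1e-15, 1 - 1e-15))
    return (z1 - z2) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))


# --------------------------------------------------------------------------
# run detection

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each maximal run of True."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i - start))
            start = None
    if start is not None:
        out.append((start, len(mask) - start))
    return out


def detect_encoding(emap: EncodingMap, cfg: BinningConfig,
                    ccfg: ClassifierConfig,
                    positive: bool = True) -> EncodingWindow | None:
    """First qualifying encoding run, or None.

    Requires >= ``min_run`` consecutive significant post-outcome bins of the
    correct sign and vetoes the neuron when more than ``max_pre_run``
    consecutive same-sign significant bins occur before the outcome.
    """
    if not emap.evaluable:
        return None
    sig = emap.significant(ccfg.alpha, positive)
    post = cfg.post_mask
    pre_runs = _runs(sig & ~post)
    if any(length > ccfg.max_pre_run for _, length in pre_runs):
        return None
    post_idx = np.where(post)[0]
    sig_post = sig[post_idx]
    for start, length in _runs(sig_post):
        if length >= ccfg.min_run:
            bins = post_idx[start:start + length]
            return EncodingWindow(
                start_bin=int(bins[0]), length=int(length),
                bin_times=cfg.centers[bins],
                r_peak=float(emap.r[bins][np.argmax(np.abs(emap.r[bins]))]))
    return None


# --------------------------------------------------------------------------
# trial masks and signal conventions

def _signal_setup(trace: pd.DataFrame, sign: str, ccfg: ClassifierConfig):
    """(trial mask, regressor, covariate or None, positive-correlation flag)."""
    rpe = trace["rpe"].to_numpy(dtype=float)
    correct = trace["rewarded"].to_numpy(dtype=int) == 1
    if sign == "pRPE":
        return correct, rpe, None, True
    if sign == "nRPE":
        # firing rises as the RPE grows more negative => negative Spearman r
        # with the (negative-valued) RPE; the opposite convention flips it.
        return ~correct, rpe, None, ccfg.nrpe_opposite
    if sign == "uRPE":
        cov = np.where(correct, 1.0, -1.0)
        return np.ones(len(rpe), bool), np.abs(rpe), cov, True
    raise ValueError(f"unknown signal sign {sign!r}")


def signal_map(rates: np.ndarray, trace: pd.DataFrame, sign: str,
               ccfg: ClassifierConfig,
               extra_mask: np.ndarray | None = None) -> tuple[EncodingMap, bool]:
    """EncodingMap for one RPE signal on (optionally restricted) trials.

    Returns the map and the sign convention (True when encoding means a
    positive correlation).  Maps with fewer than ``min_trials`` trials are
    marked not evaluable.
    """
    mask, reg, cov, positive = _signal_setup(trace, sign, ccfg)
    if extra_mask is not None:
        mask = mask & extra_mask
    n = int(mask.sum())
    if n < ccfg.min_trials:
        m = EncodingMap(r=np.zeros(rates.shape[1]), p=np.ones(rates.shape[1]),
                        n=n, regressor=sign, evaluable=False,
                        note=f"only {n} trials")
        return m, positive
    if cov is None:
        m = rank_correlation_map(rates[mask], reg[mask], sign)
    else:
        m = partial_rank_correlation_map(rates[mask], reg[mask], cov[mask], sign)
    return m, positive


# --------------------------------------------------------------------------
# neuron-level decisions

def include_neuron(rec: NeuronRecording, trace: pd.DataFrame,
                   ccfg: ClassifierConfig = ClassifierConfig(),
                   cfg: BinningConfig = BinningConfig()) -> tuple[bool, list[str], np.ndarray]:
    """Inclusion decision plus the usable-trial mask.

    A neuron passes when its mean feedback-epoch (0-1.5 s) rate is at least
    0.5 Hz and it has >= 40 choice trials with RPEs in blocks learned to
    criterion (unlearned blocks are discarded entirely).
    """
    reasons = []
    t0, t1 = ccfg.feedback_epoch
    counts = np.array([((sp >= t0) & (sp < t1)).sum()
                       for sp in rec.spikes[cfg.alignment]])
    rate = counts.mean() / (t1 - t0)
    if rate < ccfg.min_rate_hz:
        reasons.append("rate")

    session = rec.session
    if not session.learning_trials:
        session.annotate_learning()
    learned = set(session.learned_blocks())
    usable = trace["block"].isin(learned).to_numpy()
    if not learned:
        reasons.append("no learned blocks")
    elif usable.sum() < ccfg.min_usable_trials:
        reasons.append("trials")
    return (len(reasons) == 0), reasons, usable


def outcome_encoding(rates: np.ndarray, trace: pd.DataFrame,
                     cfg: BinningConfig = BinningConfig(),
                     ccfg: ClassifierConfig = ClassifierConfig(),
                     epoch: tuple[float, float] = (0.1, 0.7)):
    """Outcome (rewarded vs unrewarded) encoding decision.

    The headline test regresses each neuron's mean rate in the 0.1-0.7 s
    epoch on the reward indicator (flagged when the slope is significant at
    alpha); a per-bin regression map with the same run rule as the RPE
    analyses supports the latency analysis.  Returns
    ``(flagged, window, map)``; the window may be absent even when the
    epoch test flags the neuron (and is what latency analyses consume).
    """
    outcomes = trace["rewarded"].to_numpy(dtype=float)
    if len(np.unique(outcomes)) < 2:
        return None, None, None
    in_epoch = (cfg.starts >= epoch[0]) & (cfg.starts + cfg.window <= epoch[1])
    mean_rate = rates[:, in_epoch].mean(axis=1)
    slope_res = stats.linregress(outcomes, mean_rate)
    flagged = slope_res.pvalue < ccfg.alpha

    # per-bin linear regression == Pearson correlation with the indicator
    r = _pearson_columns(rates, outcomes)
    emap = EncodingMap(r=r, p=_t_pvalues(r, len(outcomes) - 2),
                       n=len(outcomes), regressor="outcome")
    sig = emap.p < ccfg.alpha  # either direction counts for outcome
    pre_ok = not any(length > ccfg.max_pre_run
                     for _, length in _runs(sig & ~cfg.post_mask))
    window = None
    if pre_ok:
        post_idx = np.where(cfg.post_mask)[0]
        for start, length in _runs(sig[post_idx]):
            if length >= ccfg.min_run:
                bins = post_idx[start:start + length]
                window = EncodingWindow(
                    start_bin=int(bins[0]), length=int(length),
                    bin_times=cfg.centers[bins],
                    r_peak=float(r[bins][np.argmax(np.abs(r[bins]))]))
                break
    return bool(flagged), window, emap


def classify_feature_specific(rates: np.ndarray, trace: pd.DataFrame,
                              sign: str, dimension: str,
                              cfg: BinningConfig = BinningConfig(),
                              ccfg: ClassifierConfig = ClassifierConfig()):
    """Feature-specific decision for one signal sign and dimension.

    Splits trials by the chosen feature of ``dimension``, builds the two
    encoding maps, and flags the neuron when (a) at least ``min_run``
    consecutive post-outcome bins differ by the Fisher z-test at
    ``z_threshold`` and (b) at least one feature value has a qualifying
    encoding run overlapping that z-run.  Returns
    ``(preferred_feature, EncodingWindow)`` or ``None``.
    """
    f1, f2 = FEATURE_NAMES[dimension]
    chosen = trace[dimension].to_numpy()
    maps, windows = {}, {}
    for feat in (f1, f2):
        emap, positive = signal_map(rates, trace, sign, ccfg,
                                    extra_mask=(chosen == feat))
        if not emap.evaluable:
            return None
        maps[feat] = emap
        windows[feat] = detect_encoding(emap, cfg, ccfg, positive)

    z = fisher_z_compare(maps[f1].r, maps[f1].n, maps[f2].r, maps[f2].n)
    zsig = np.abs(z) > ccfg.z_threshold
    post_idx = np.where(cfg.post_mask)[0]
    z_runs = [(post_idx[s], length) for s, length in _runs(zsig[post_idx])
              if length >= ccfg.min_run]
    if not z_runs:
        return None

    def overlaps(win: EncodingWindow) -> bool:
        wb = set(range(win.start_bin, win.start_bin + win.length))
        return any(wb & set(range(zs, zs + zl)) for zs, zl in z_runs)

    candidates = [(feat, win) for feat, win in windows.items()
                  if win is not None and overlaps(win)]
    if not candidates:
        return None
    # preferred feature: the qualifying window with the strongest peak |R|
    feat, win = max(candidates, key=lambda fw: abs(fw[1].r_peak))
    return feat, win


def classify_neuron(rec: NeuronRecording, trace: pd.DataFrame,
                    cfg: BinningConfig = BinningConfig(),
                    ccfg: ClassifierConfig = ClassifierConfig()) -> NeuronLabelSet:
    """Full classification of one neuron.

    Applies inclusion, then the outcome test, the pooled (nonspecific) RPE
    tests for each sign, and the feature-specific tests for every sign x
    dimension combination, all on usable trials (learned blocks only).
    """
    included, reasons, usable = include_neuron(rec, trace, ccfg, cfg)
    labels = NeuronLabelSet(neuron_id=rec.neuron_id, area=rec.area,
                            included=included, exclusion_reasons=reasons)
    if not included:
        return labels
    rates_all = bin_rates(rec, cfg)[usable]
    sub = trace.loc[usable].reset_index(drop=True)

    flagged, window, _ = outcome_encoding(rates_all, sub, cfg, ccfg)
    labels.outcome_flag = bool(flagged)
    labels.outcome = window
    for sign in RPE_SIGNALS:
        emap, positive = signal_map(rates_all, sub, sign, ccfg)
        labels.nonspecific[sign] = detect_encoding(emap, cfg, ccfg, positive)
        for dim in DIMENSIONS:
            labels.feature_specific[(sign, dim)] = classify_feature_specific(
                rates_all, sub, sign, dim, cfg, ccfg)
    return labels


def labels_table(labels: list[NeuronLabelSet]) -> pd.DataFrame:
    """Flat delimited-friendly table of all flags across neurons."""
    rows = []
    for lab in labels:
        if not lab.included:
            rows.append({"neuron": lab.neuron_id, "area": lab.area,
                         "included": False,
                         "exclusion": ";".join(lab.exclusion_reasons),
                         "signal": None, "dimension": None,
                         "preferred_feature": None, "window_start_s": None,
                         "window_len_s": None, "r_peak": None,
                         "nonspecific_only": None})
            continue

        def row(signal, dimension, feat, win, excl=None):
            step = float(np.diff(win.bin_times[:2])[0]) if win.length > 1 else 0.0
            return {"neuron": lab.neuron_id, "area": lab.area,
                    "included": True, "exclusion": "",
                    "signal": signal, "dimension": dimension,
                    "preferred_feature": feat,
                    "window_start_s": float(win.bin_times[0]),
                    "window_len_s": float(win.length * step),
                    "r_peak": win.r_peak, "nonspecific_only": excl}

        if lab.outcome is not None:
            rows.append(row("outcome", None, None, lab.outcome))
        for sign in RPE_SIGNALS:
            win = lab.nonspecific.get(sign)
            if win is not None:
                rows.append(row(sign, "pooled", None, win,
                                excl=lab.nonspecific_only(sign)))
            for dim in DIMENSIONS:
                fs = lab.feature_specific.get((sign, dim))
                if fs is not None:
                    feat, w = fs
                    rows.append(row(sign, dim, feat, w))
    cols = ["neuron", "area", "included", "exclusion", "signal", "dimension",
            "preferred_feature", "window_start_s", "window_len_s", "r_peak",
            "nonspecific_only"]
    return pd.DataFrame(rows, columns=cols)
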