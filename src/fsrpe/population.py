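"""Population-level statistics over classified neurons.

Latency of a signal class is summarized by pooling, across neurons, the time
bins of the first qualifying encoding run (optionally every significant bin),
building the normalized cumulative distribution, and reading off its
25%-crossing time.  Distributions are compared with two-sample
Kolmogorov-Smirnov tests under Bonferroni-Holm correction plus companion
rank-sum tests; crossing times with a label-permutation randomization test.
Prevalence of feature-specific encoding across the three stimulus dimensions
is assessed by bootstrap against an exchangeable-dimension null, and its
area profile by the color-tuning index

    I_col = (P_col - (P_loc + P_mot)/2) / (P_col + P_loc + P_mot),

which is 1 when only color-specific neurons exist, -0.5 when none are
color-specific, and 0 under a uniform split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .task import DIMENSIONS


@dataclass
class LatencyDistribution:
    """Pooled significant-bin times of one group of neurons."""

    group: str
    bin_times: np.ndarray          # pooled multiset, sorted
    per_neuron: list[np.ndarray] = field(default_factory=list)

    @property
    def cumulative(self) -> tuple[np.ndarray, np.ndarray]:
        t = np.sort(self.bin_times)
        return t, np.arange(1, len(t) + 1) / len(t)

    def crossing_time(self, q: float = 0.25) -> float:
        """Earliest pooled bin time at which the cumulative sum reaches q."""
        t, c = self.cumulative
        return float(t[np.searchsorted(c, q)])


def latency_distribution(labels, signal_of, group: str = "",
                         mode: str = "first_run") -> LatencyDistribution:
    """Pool encoding-bin times over neurons.

    ``signal_of`` maps a NeuronLabelSet to an EncodingWindow (or a list of
    windows) or None; neurons mapping to None are skipped.  ``mode`` is
    'first_run' (the latency-test convention: bins of the first qualifying
    run only) — window objects already hold exactly those bins — and exists
    to document the distinction from pooling every significant bin, which a
    caller can get by passing all windows per neuron.
    """
    per_neuron = []
    for lab in labels:
        win = signal_of(lab)
        if win is None:
            continue
        wins = win if isinstance(win, (list, tuple)) else [win]
        bins = np.concatenate([w.bin_times for w in wins])
        if mode == "first_run":
            bins = wins[0].bin_times
        per_neuron.append(np.asarray(bins, dtype=float))
    if not per_neuron:
        raise ValueError(f"no flagged neurons in group {group!r}")
    return LatencyDistribution(group=group,
                               bin_times=np.sort(np.concatenate(per_neuron)),
                               per_neuron=per_neuron)


def compare_latencies_ks(groups: list[LatencyDistribution],
                         alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise KS tests with Holm correction, plus rank-sum companions."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g.bin_times) < 2:
            raise ValueError(f"group {g.group!r} has fewer than 2 bins")
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            ks = stats.ks_2samp(a.bin_times, b.bin_times)
            rs = stats.ranksums(a.bin_times, b.bin_times)
            rows.append({"group_a": a.group, "group_b": b.group,
                         "D": ks.statistic, "p_ks": ks.pvalue,
                         "ranksum_stat": rs.statistic, "p_ranksum": rs.pvalue})
    table = pd.DataFrame(rows)
    for col in ("p_ks", "p_ranksum"):
        rej, adj, _, _ = multipletests(table[col], alpha=alpha, method="holm")
        table[col + "_holm"] = adj
        table[("significant" if col == "p_ks" else "significant_ranksum")] = rej
    return table


def quantile_crossing_test(a: LatencyDistribution, b: LatencyDistribution,
                           q: float = 0.25, n: int = 500,
                           seed: int = 0) -> tuple[float, float]:
    """Randomization test for a difference in q-crossing times.

    Neurons (not bins) are permuted between the two groups; the two-sided
    p-value uses the (b+1)/(n+1) estimator.  Returns (observed difference,
    p-value).
    """
    rng = np.random.default_rng(seed)
    observed = a.crossing_time(q) - b.crossing_time(q)
    pool = a.per_neuron + b.per_neuron
    na = len(a.per_neuron)
    idx = np.arange(len(pool))
    null = np.empty(n)
    for i in range(n):
        rng.shuffle(idx)
        ga = np.sort(np.concatenate([pool[k] for k in idx[:na]]))
        gb = np.sort(np.concatenate([pool[k] for k in idx[na:]]))
        ca = ga[np.searchsorted(np.arange(1, len(ga) + 1) / len(ga), q)]
        cb = gb[np.searchsorted(np.arange(1, len(gb) + 1) / len(gb), q)]
        null[i] = ca - cb
    p = (np.sum(np.abs(null) >= abs(observed)) + 1.0) / (n + 1.0)
    return float(observed), float(p)


def prevalence_bootstrap(dimension_labels: list[str], n_total: int,
                         n: int = 10000, seed: int = 0,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Is any dimension's feature-specific prevalence above expectation?

    ``dimension_labels`` holds one dimension name per feature-specific
    neuron (a neuron contributes once per feature-specific signal);
    ``n_total`` is the population size the proportions refer to.  The null
    redraws each label uniformly from the three dimensions (exchangeable
    dimensions) and flags a dimension whose observed proportion exceeds the
    one-sided upper (1 - alpha) bound of its null distribution.
    """
    if len(dimension_labels) == 0:
        raise ValueError("no feature-specific neurons in scope")
    rng = np.random.default_rng(seed)
    n_fs = len(dimension_labels)
    counts = {d: dimension_labels.count(d) for d in DIMENSIONS}
    draws = rng.integers(0, 3, size=(n, n_fs))
    null_props = np.stack([(draws == d).sum(axis=1) / n_total
                           for d in range(3)], axis=1)
    rows = []
    for d, dim in enumerate(DIMENSIONS):
        obs = counts[dim] / n_total
        upper = float(np.quantile(null_props[:, d], 1.0 - alpha))
        rows.append({"dimension": dim, "observed": obs, "upper_bound": upper,
                     "flagged": obs > upper})
    return pd.DataFrame(rows)


def color_tuning_index(p_col: float, p_loc: float, p_mot: float) -> float | None:
    """I_col in [-0.5, 1]; positive means color-dominant prevalence."""
    total = p_col + p_loc + p_mot
    if total == 0:
        return None
    return (p_col - (p_loc + p_mot) / 2.0) / total


def tuning_index_area_test(table: pd.DataFrame, n: int = 10000,
                           seed: int = 0, alpha: float = 0.05) -> pd.DataFrame:
    """Area-label randomization test of the color-tuning index.

    ``table`` needs columns ``area`` and ``dimension`` with one row per
    feature-specific neuron.  For each area the observed I_col is compared
    with the two-sided (1 - alpha) interval of I_col values computed from
    area-shuffled labels (same area sizes).
    """
    areas = sorted(table["area"].unique())
    if len(areas) < 2:
        raise ValueError("need at least two areas")
    rng = np.random.default_rng(seed)
    dims = table["dimension"].to_numpy()
    area_arr = table["area"].to_numpy()

    def icol(mask: np.ndarray) -> float | None:
        sub = dims[mask]
        return color_tuning_index(*(float((sub == d).sum()) for d in DIMENSIONS))

    rows = []
    for area in areas:
        mask = area_arr == area
        observed = icol(mask)
        size = int(mask.sum())
        null = []
        for _ in range(n):
            pick = rng.choice(len(dims), size=size, replace=False)
            m = np.zeros(len(dims), dtype=bool)
            m[pick] = True
            v = icol(m)
            if v is not None:
                null.append(v)
        lo, hi = np.quantile(null, [alpha / 2, 1 - alpha / 2])
        rows.append({"area": area, "I_col": observed, "ci_low": float(lo),
                     "ci_high": float(hi),
                     "flagged": observed is not None
                     and not (lo <= observed <= hi)})
    return pd.DataFrame(rows)
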