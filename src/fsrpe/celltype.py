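"""Putative cell-class assignment from action-potential waveform shape.

Cortical units are split into narrow-spiking (putative interneurons) and
broad-spiking (putative pyramidal cells) using the peak-to-trough duration
and time to repolarization; striatal units use the trough (peak) width at
half amplitude and the initial slope of valley decay (ISVD).  The two
standardized features are projected onto the first principal component and
split at the antimode of the PC1 histogram.  A chi-square ratio test then
asks whether feature-specific RPE encoding is enriched in one class relative
to the full population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .ephys import WAVEFORM_STEP_S


class FeatureExtractionError(ValueError):
    """Waveform has no usable trough/peak landmarks."""


@dataclass(frozen=True)
class WaveformFeatures:
    duration_ms: float          # cortical: trough-to-peak; striatal: peak width
    second_ms_or_slope: float   # cortical: time to repolarization (ms);
                                # striatal: ISVD (amplitude fraction / ms)
    region_kind: str            # 'cortical' or 'striatal'


def _interp_waveform(w: np.ndarray, upsample: int = 10):
    t = np.arange(len(w)) * WAVEFORM_STEP_S * 1e3  # ms
    tf = np.linspace(t[0], t[-1], len(w) * upsample)
    return tf, np.interp(tf, t, w)


def extract_features(waveform: np.ndarray, region_kind: str,
                     repolarization_fraction: float = 0.25,
                     isvd_window_ms: float = 0.1) -> WaveformFeatures:
    """Landmark features on the (upsampled) waveform.

    Cortical: trough-to-peak interval and the time from the peak back down to
    ``repolarization_fraction`` of the peak amplitude.  Striatal: width of
    the trough at half its amplitude and the initial recovery slope over the
    first ``isvd_window_ms`` after the trough (amplitude normalized to the
    trough depth).  Raises :class:`FeatureExtractionError` for monophasic
    shapes.
    """
    t, w = _interp_waveform(np.asarray(waveform, dtype=float))
    i_tr = int(np.argmin(w))
    if w[i_tr] >= 0 or i_tr >= len(w) - 2:
        raise FeatureExtractionError("no trough before end of waveform")
    after = w[i_tr:]
    i_pk = i_tr + int(np.argmax(after))
    if w[i_pk] <= 0:
        raise FeatureExtractionError("no positive peak after trough")

    if region_kind == "cortical":
        duration = t[i_pk] - t[i_tr]
        thresh = repolarization_fraction * w[i_pk]
        below = np.where(w[i_pk:] <= thresh)[0]
        if len(below) == 0:
            repol = t[-1] - t[i_pk]  # truncated tail: lower bound
        else:
            repol = t[i_pk + below[0]] - t[i_pk]
        return WaveformFeatures(float(duration), float(repol), region_kind)
    if region_kind == "striatal":
        half = 0.5 * w[i_tr]
        inside = np.where(w <= half)[0]
        width = t[inside[-1]] - t[inside[0]]
        j = np.searchsorted(t, t[i_tr] + isvd_window_ms)
        j = min(j, len(w) - 1)
        isvd = ((w[j] - w[i_tr]) / abs(w[i_tr])) / (t[j] - t[i_tr])
        return WaveformFeatures(float(width), float(isvd), region_kind)
    raise ValueError(f"unknown region kind {region_kind!r}")


@dataclass
class PCASplit:
    labels: np.ndarray          # 'narrow' / 'broad' per unit
    pc1: np.ndarray
    split_point: float
    low_confidence: bool


def classify_by_pca(features: list[WaveformFeatures]) -> PCASplit:
    """Two-class split on the first principal component of the two features.

    The split point is the kernel-density antimode between the two largest
    modes of the PC1 histogram; when the density is unimodal the median is
    used and the result flagged low-confidence.  Labels are oriented so that
    'narrow' is the class with the shorter duration feature.
    """
    if len(features) < 20:
        raise ValueError("need at least 20 units")
    X = np.array([[f.duration_ms, f.second_ms_or_slope] for f in features])
    Xs = StandardScaler().fit_transform(X)
    pc1 = PCA(n_components=1).fit_transform(Xs)[:, 0]

    kde = stats.gaussian_kde(pc1)
    grid = np.linspace(pc1.min(), pc1.max(), 512)
    dens = kde(grid)
    # local maxima / minima of the smoothed density
    is_max = np.r_[False, (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:]),
                   False]
    maxima = np.where(is_max)[0]
    low_conf = False
    if len(maxima) >= 2:
        top2 = sorted(maxima[np.argsort(dens[maxima])[-2:]])
        seg = slice(top2[0], top2[1] + 1)
        split = float(grid[top2[0] + np.argmin(dens[seg])])
    else:
        split = float(np.median(pc1))
        low_conf = True

    side = pc1 <= split
    mean_dur_low = X[side, 0].mean() if side.any() else np.inf
    mean_dur_high = X[~side, 0].mean() if (~side).any() else np.inf
    narrow_is_low = mean_dur_low <= mean_dur_high
    labels = np.where(side == narrow_is_low, "narrow", "broad")
    return PCASplit(labels=labels, pc1=pc1, split_point=split,
                    low_confidence=low_conf)


def enrichment_test(class_labels: np.ndarray,
                    encoding_flags: np.ndarray) -> dict:
    """Chi-square ratio test of narrow/broad composition among encoders.

    Compares the narrow:broad split of the flagged subset against the full
    population (2x2 table flagged x class, chi-square without continuity
    correction) and reports the phi coefficient.
    """
    class_labels = np.asarray(class_labels)
    flags = np.asarray(encoding_flags, dtype=bool)
    table = np.array([
        [np.sum(flags & (class_labels == "narrow")),
         np.sum(flags & (class_labels == "broad"))],
        [np.sum(~flags & (class_labels == "narrow")),
         np.sum(~flags & (class_labels == "broad"))],
    ], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return {"evaluable": False, "table": table}
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    a, b = table[0]
    c, d = table[1]
    phi = (a * d - b * c) / np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    n_narrow = (class_labels == "narrow").sum()
    n_broad = (class_labels == "broad").sum()
    return {
        "evaluable": True, "chi2": float(chi2), "p": float(p),
        "phi": float(phi), "table": table,
        "ratio_flagged": float(a / b) if b else np.inf,
        "ratio_population": float(n_narrow / n_broad) if n_broad else np.inf,
    }


def classify_units(waveforms: list[np.ndarray],
                   region_kind: str) -> tuple[np.ndarray, PCASplit]:
    """Extract features and split a set of units; failures are 'unidentified'."""
    feats, ok_idx = [], []
    for i, w in enumerate(waveforms):
        try:
            feats.append(extract_features(w, region_kind))
            ok_idx.append(i)
        except FeatureExtractionError:
            continue
    split = classify_by_pca(feats)
    labels = np.full(len(waveforms), "unidentified", dtype=object)
    labels[np.array(ok_idx)] = split.labels
    return labels, split
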