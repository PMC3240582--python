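"""The three track normalizations and empirical-FDR thresholding.

1. Depth scaling: every bin is rescaled as if 10 million tags had been
   sequenced.
2. Noise normalization: scores below a *critical value* — the score above
   which the experimental score histogram always exceeds the control's — are
   treated as shared, non-specific noise; a multiplicative normalizer c for
   the experimental track is fitted by maximizing the correlation between the
   sub-critical score histograms, with the ratio X/Y of the two histograms'
   modal scores as the analytic estimate and grid centre.
3. Background subtraction: adjusted(b) = max(0, c * exp(b) - ctrl(b)).

The enrichment-calling threshold is the smallest adjusted score s whose
empirical FDR — the number of bins an exchange null says should reach s by
chance over the number of experimental bins reaching s — falls below alpha
(default 0.001).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .scoring import BinTrack


class NoCrossingError(RuntimeError):
    """The experimental and control score histograms never cross (e.g. the
    tracks are identical): the datasets are not comparable by this scheme."""


@dataclass
class NoiseNormalization:
    critical: float
    X: float  # modal sub-critical score of the control histogram
    Y: float  # modal sub-critical score of the experimental histogram
    ratio_estimate: float  # X / Y
    c: float  # correlation-maximizing normalizer actually applied
    method: str  # "correlation-max" | "ratio" | "unit-fallback"

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("normalizer must be positive")


@dataclass
class AdjustedTrack:
    """Background-subtracted scores plus the FDR curve and chosen threshold."""

    scores: Dict[str, np.ndarray]
    bin_size: int
    normalization: Optional[NoiseNormalization] = None
    alpha: Optional[float] = None
    threshold: Optional[float] = None
    fdr_curve: Optional[pd.DataFrame] = None  # columns: score, fdr_raw, fdr
    flags: list = field(default_factory=list)

    def flat(self) -> np.ndarray:
        return np.concatenate([self.scores[c] for c in sorted(self.scores)])

    def reported(self) -> Dict[str, np.ndarray]:
        """Adjusted scores with sub-threshold bins zeroed (all zeros when no
        threshold was attainable)."""
        if self.threshold is None:
            return {c: np.zeros_like(a) for c, a in self.scores.items()}
        return {c: np.where(a >= self.threshold, a, 0.0) for c, a in self.scores.items()}

    def regions(self) -> pd.DataFrame:
        """Merged runs of above-threshold bins as chrom/start/end (bp)."""
        rows = []
        for chrom, arr in self.scores.items():
            mask = arr >= self.threshold if self.threshold is not None else np.zeros_like(arr, bool)
            if not mask.any():
                continue
            d = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
            starts = np.flatnonzero(d == 1)
            ends = np.flatnonzero(d == -1)
            for s, e in zip(starts, ends):
                rows.append((chrom, int(s) * self.bin_size, int(e) * self.bin_size))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def depth_normalize(track: BinTrack, target: float = 1e7) -> BinTrack:
    """Rescale every bin as if ``target`` tags had been sequenced. Idempotent:
    a track already depth-normalized is returned unchanged (copy)."""
    out = track.copy()
    if track.depth_normalized:
        return out
    if track.tag_total <= 0:
        raise ValueError("cannot depth-normalize a track with zero tag total")
    f = target / track.tag_total
    for arr in out.scores.values():
        arr *= f
    out.depth_normalized = True
    return out


def _positive_scores(track: BinTrack) -> np.ndarray:
    v = track.flat()
    return v[v > 0]


def _histogram(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    return np.histogram(values, bins=edges)[0]


def _shared_edges(exp_v: np.ndarray, ctrl_v: np.ndarray,
                  binwidth: Optional[float]) -> np.ndarray:
    hi = max(exp_v.max(initial=0.0), ctrl_v.max(initial=0.0))
    if hi <= 0:
        raise ValueError("no positive scores to histogram")
    if binwidth is None:
        # Freedman-Diaconis on the control's positive scores
        q75, q25 = np.percentile(ctrl_v, [75, 25]) if len(ctrl_v) else (0, 0)
        binwidth = 2 * (q75 - q25) / max(len(ctrl_v), 1) ** (1 / 3)
        if binwidth <= 0:
            binwidth = hi / 100
    return np.arange(0, hi + 2 * binwidth, binwidth)


def critical_value(exp: BinTrack, ctrl: BinTrack,
                   hist_binwidth: Optional[float] = None) -> float:
    """Right-most crossing point of the two positive-score histograms: the
    largest histogram cell at which the control bin-count still matches or
    exceeds the experimental one, with the experimental count strictly larger
    in every occupied cell above. Scores at or below it are noise."""
    ev, cv = _positive_scores(exp), _positive_scores(ctrl)
    if len(ev) == 0 or len(cv) == 0:
        raise ValueError("empty track")
    edges = _shared_edges(ev, cv, hist_binwidth)
    he, hc = _histogram(ev, edges), _histogram(cv, edges)
    occupied = np.flatnonzero((he + hc) > 0)
    for j in occupied[::-1]:
        if hc[j] >= he[j]:
            if j == occupied[-1]:
                raise NoCrossingError(
                    "control matches or exceeds the experimental histogram in its "
                    "top occupied cell; the datasets show no enrichment region")
            return float((edges[j] + edges[j + 1]) / 2)
    raise NoCrossingError("experimental histogram dominates everywhere; no crossing")


def noise_normalizer(exp: BinTrack, ctrl: BinTrack, critical: float,
                     hist_binwidth: Optional[float] = None,
                     grid: Tuple[float, float, int] = (0.5, 2.0, 81)) -> NoiseNormalization:
    """Fit the noise normalizer c on sub-critical scores.

    c is chosen by grid search maximizing the Pearson correlation between the
    histograms of (c * exp) and ctrl restricted to scores below the critical
    value; the ratio X/Y of the modal histogram scores centres the grid and is
    reported alongside.
    """
    ev, cv = _positive_scores(exp), _positive_scores(ctrl)
    cv_sub = cv[cv < critical]
    ev_sub = ev[ev < critical]
    if len(cv_sub) == 0 or len(ev_sub) == 0:
        raise ValueError("no sub-critical scores; critical value implausible")
    edges = _shared_edges(ev_sub, cv_sub, hist_binwidth)
    hc = _histogram(cv_sub, edges)
    he = _histogram(ev_sub, edges)
    centers = (edges[:-1] + edges[1:]) / 2
    X = float(centers[np.argmax(hc)])
    Y = float(centers[np.argmax(he)])
    ratio = X / Y if Y > 0 else 1.0

    hc_occ = hc[(hc + he) > 0]
    if np.count_nonzero(hc) < 2 or len(hc_occ) < 3:
        warnings.warn("degenerate sub-critical histograms; falling back to X/Y ratio")
        return NoiseNormalization(critical, X, Y, ratio, ratio, "ratio")

    best_c, best_r = ratio, -np.inf
    for c in ratio * np.geomspace(grid[0], grid[1], grid[2]):
        scaled = c * ev
        h = _histogram(scaled[scaled < critical], edges)
        if h.std() == 0 or hc.std() == 0:
            continue
        r = float(np.corrcoef(h, hc)[0, 1])
        if r > best_r:
            best_r, best_c = r, float(c)
    if not np.isfinite(best_r):
        warnings.warn("correlation search failed; falling back to X/Y ratio")
        return NoiseNormalization(critical, X, Y, ratio, ratio, "ratio")
    return NoiseNormalization(critical, X, Y, ratio, best_c, "correlation-max")


def subtract_background(exp: BinTrack, ctrl: BinTrack,
                        norm: NoiseNormalization) -> AdjustedTrack:
    """adjusted(b) = max(0, c * exp(b) - ctrl(b))."""
    if exp.layout_bins != ctrl.layout_bins:
        raise ValueError("experimental and control tracks have different bin layouts")
    scores = {c: np.maximum(0.0, norm.c * exp.scores[c] - ctrl.scores[c])
              for c in exp.scores}
    return AdjustedTrack(scores, exp.bin_size, norm)


def fdr_threshold(exp_adj: AdjustedTrack, null_adj: AdjustedTrack,
                  alpha: float = 0.001) -> AdjustedTrack:
    """Empirical-FDR threshold selection.

    FDR(s) = #{null bins >= s} / #{experimental bins >= s}, evaluated at every
    occupied positive adjusted score, then monotonized (running minimum over
    thresholds below, so the curve is non-increasing in s). The threshold is
    the smallest s with FDR(s) < alpha; when no score qualifies the track is
    flagged and nothing is reported.
    """
    ev = np.sort(exp_adj.flat())
    nv = np.sort(null_adj.flat())
    pos = ev[ev > 0]
    exp_adj.alpha = alpha
    if len(pos) == 0:
        exp_adj.threshold = None
        exp_adj.flags.append("no positive adjusted scores; no reportable signal")
        return exp_adj
    s = np.unique(pos)
    n_exp = len(ev) - np.searchsorted(ev, s, side="left")
    n_null = len(nv) - np.searchsorted(nv, s, side="left")
    raw = n_null / n_exp
    mono = np.minimum.accumulate(raw)  # non-increasing in s
    exp_adj.fdr_curve = pd.DataFrame({"score": s, "fdr_raw": raw, "fdr": mono,
                                      "n_exp": n_exp, "n_null": n_null})
    below = np.flatnonzero(mono < alpha)
    if len(below) == 0:
        exp_adj.threshold = None
        exp_adj.flags.append(f"no adjusted score reaches FDR < {alpha}")
    else:
        exp_adj.threshold = float(s[below[0]])
    return exp_adj


def normalize_pair(exp: BinTrack, ctrl: BinTrack, alpha: float = 0.001,
                   hist_binwidth: Optional[float] = None) -> AdjustedTrack:
    """Full normalization chain: depth scaling, noise normalization (with a
    unit-normalizer fallback when the histograms never cross, the expected
    situation for two draws from the same background), role-swapped exchange
    null, and FDR thresholding."""
    e = depth_normalize(exp)
    c = depth_normalize(ctrl)
    try:
        crit = critical_value(e, c, hist_binwidth)
        norm = noise_normalizer(e, c, crit, hist_binwidth)
    except NoCrossingError:
        norm = NoiseNormalization(float("nan"), float("nan"), float("nan"),
                                  1.0, 1.0, "unit-fallback")
    adj = subtract_background(e, c, norm)
    # exchange null: identical subtraction with the dataset roles swapped
    null_scores = {ch: np.maximum(0.0, c.scores[ch] - norm.c * e.scores[ch])
                   for ch in e.scores}
    null = AdjustedTrack(null_scores, e.bin_size, norm)
    return fdr_threshold(adj, null, alpha)
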