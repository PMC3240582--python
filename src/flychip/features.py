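"""Where score mass sits: genomic-feature maps, percentile compositions,
transposon-class densities and external-track correlations."""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .models import DEFAULT_BIN_SIZE, GeneModel, TransposonCopy, n_bins
from .scoring import BinTrack

# precedence-ordered labels (higher code wins a bin)
LABELS = ("intergenic", "intron", "utr3", "utr5", "cds", "transposon")
_CODE = {name: i for i, name in enumerate(LABELS)}


@dataclass
class FeatureMap:
    """Per-bin genomic feature labels and genome-wide label fractions."""

    bin_labels: Dict[str, np.ndarray]
    fractions: pd.Series
    bin_size: int = DEFAULT_BIN_SIZE

    def flat(self) -> np.ndarray:
        return np.concatenate([self.bin_labels[c] for c in sorted(self.bin_labels)])


def _paint(arr: np.ndarray, start: int, end: int, code: int) -> None:
    s, e = max(0, start), min(len(arr), end)
    if e > s:
        np.maximum(arr[s:e], code, out=arr[s:e])


def build_feature_map(genes: Sequence[GeneModel], transposons: Sequence[TransposonCopy],
                      layout: Dict[str, int],
                      bin_size: int = DEFAULT_BIN_SIZE) -> FeatureMap:
    """Label every bin by the highest-precedence feature overlapping it:
    transposon > CDS > 5'UTR > 3'UTR > intron > intergenic."""
    bp = {c: np.zeros(l, dtype=np.int8) for c, l in layout.items()}
    for g in genes:
        if g.chrom not in bp:
            raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
        arr = bp[g.chrom]
        for t in g.transcripts:
            if t.end > layout[g.chrom]:
                raise ValueError(f"transcript {t.tx_id} beyond chromosome end")
            _paint(arr, t.start, t.end, _CODE["intron"])
            for (s, e) in t.exons:
                if t.cds is None:
                    _paint(arr, s, e, _CODE["cds"])
                    continue
                cs, ce = t.cds
                if e <= cs or s >= ce:  # fully untranslated exon
                    upstream = (e <= cs) if g.strand == "+" else (s >= ce)
                    _paint(arr, s, e, _CODE["utr5" if upstream else "utr3"])
                else:
                    if s < cs:
                        _paint(arr, s, cs, _CODE["utr5" if g.strand == "+" else "utr3"])
                    if e > ce:
                        _paint(arr, ce, e, _CODE["utr3" if g.strand == "+" else "utr5"])
                    _paint(arr, max(s, cs), min(e, ce), _CODE["cds"])
    for c in transposons:
        _paint(bp[c.chrom], c.start, c.end, _CODE["transposon"])

    labels = {}
    for c, arr in bp.items():
        nb = n_bins(len(arr), bin_size)
        padded = np.zeros(nb * bin_size, dtype=np.int8)
        padded[:len(arr)] = arr
        labels[c] = padded.reshape(nb, bin_size).max(axis=1)
    flat = np.concatenate(list(labels.values()))
    fractions = pd.Series({name: float(np.mean(flat == _CODE[name])) for name in LABELS})
    return FeatureMap(labels, fractions, bin_size)


def percentile_composition(track: BinTrack, fmap: FeatureMap, n: int = 100) -> pd.DataFrame:
    """Bins ranked ascending by score into n equal-count groups (stable order:
    ties stay in genomic order); per group, the percentage of bins carrying
    each feature label. Long format: percentile, label, percent."""
    scores = track.flat()
    labels = fmap.flat()
    if len(scores) != len(labels):
        raise ValueError("track and feature map have different layouts")
    if n > len(scores):
        raise ValueError("more percentiles than bins")
    order = np.argsort(scores, kind="stable")
    rows = []
    for p, grp in enumerate(np.array_split(order, n), 1):
        lab = labels[grp]
        for name in LABELS:
            rows.append((p, name, 100.0 * np.mean(lab == _CODE[name])))
    return pd.DataFrame(rows, columns=["percentile", "label", "percent"])


def score_fraction_by_feature(track: BinTrack, fmap: FeatureMap) -> pd.Series:
    """Fraction of total track score mass per feature label."""
    scores = track.flat()
    labels = fmap.flat()
    total = scores.sum()
    if total <= 0:
        raise ValueError("all-zero track: score fractions undefined")
    return pd.Series({name: float(scores[labels == _CODE[name]].sum() / total)
                      for name in LABELS})


def transposon_class_density(track: BinTrack, copies: Sequence[TransposonCopy]) -> pd.DataFrame:
    """Per transposon class (family): total score over member-copy bins, total
    length (bp), and density = score / length."""
    if not copies:
        raise ValueError("no transposon classes annotated")
    bs = track.bin_size
    acc: Dict[str, Tuple[float, int]] = {}
    for c in copies:
        if c.length <= 0:
            raise ValueError(f"zero-length transposon copy in class {c.family}")
        arr = track.scores[c.chrom]
        b0, b1 = c.start // bs, (c.end - 1) // bs + 1
        score = float(arr[b0:min(b1, len(arr))].sum())
        s, l = acc.get(c.family, (0.0, 0))
        acc[c.family] = (s + score, l + c.length)
    out = pd.DataFrame(
        [(fam, s, l, s / l) for fam, (s, l) in sorted(acc.items())],
        columns=["family", "score", "length", "density"]).set_index("family")
    return out


def mark_correlation_matrix(tables: Dict[str, pd.DataFrame]) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r (and t-test p-values) between marks' per-class
    densities. Zero-variance marks yield NaN entries with a warning."""
    marks = list(tables)
    common = sorted(set.intersection(*(set(t.index) for t in tables.values())))
    if len(common) < 3:
        raise ValueError("need at least 3 shared transposon classes")
    vecs = {m: tables[m].loc[common, "density"].to_numpy() for m in marks}
    r = pd.DataFrame(np.eye(len(marks)), index=marks, columns=marks)
    p = pd.DataFrame(np.zeros((len(marks), len(marks))), index=marks, columns=marks)
    for i, a in enumerate(marks):
        for j, b in enumerate(marks):
            if j <= i:
                continue
            if np.std(vecs[a]) == 0 or np.std(vecs[b]) == 0:
                warnings.warn(f"zero-variance density vector; r undefined for {a} vs {b}")
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            rr, pp = stats.pearsonr(vecs[a], vecs[b])
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    return r, p


def window_track_means(track: BinTrack, windows: pd.DataFrame) -> np.ndarray:
    """Mean bin score of the track under each chrom/start/end window."""
    bs = track.bin_size
    out = np.empty(len(windows))
    for i, row in enumerate(windows.itertuples(index=False)):
        arr = track.scores[row.chrom]
        b0, b1 = row.start // bs, (row.end - 1) // bs + 1
        out[i] = float(arr[b0:min(b1, len(arr))].mean())
    return out


def windowed_percentile_correlation(track: BinTrack, external: pd.DataFrame,
                                    n: int = 100) -> Tuple[float, pd.DataFrame]:
    """External-platform concordance: windows (chrom/start/end/score) are
    ranked by the external score into n percentiles; Pearson r is computed
    between per-percentile mean external and mean track scores."""
    if len(external) < n:
        raise ValueError(f"need at least {n} windows")
    track_means = window_track_means(track, external)
    order = np.argsort(external["score"].to_numpy(), kind="stable")
    rows = []
    for pct, grp in enumerate(np.array_split(order, n), 1):
        rows.append((pct, float(external["score"].to_numpy()[grp].mean()),
                     float(track_means[grp].mean())))
    df = pd.DataFrame(rows, columns=["percentile", "external_mean", "track_mean"])
    r = float(stats.pearsonr(df["external_mean"], df["track_mean"])[0])
    return r, df
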