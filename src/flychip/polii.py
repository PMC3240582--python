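"""Promoter-proximal polII stalling, read-level 5-bp positioning, splice
junction occupancy, slowing-gene detection and splice-variant comparison.

Stalling index: SI = (mean adjusted polII over TSS-500..TSS+500) /
(mean over TSS+750..TSS+2500), with bins shared by two genes' windows masked
out of both means. Read-level positioning bins depth-scaled tag 5' counts
into 5-bp windows around anchors, subtracting the equally scaled mock
counts: positive values mean enrichment over the mock background, negative
depletion.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .models import GeneModel
from .normalize import AdjustedTrack
from .simulate import junction_anchor_table

PROMOTER_WINDOW = (-500, 500)
BODY_WINDOW = (750, 2500)


def _window_bins(gene: GeneModel, window: Tuple[int, int], bin_size: int,
                 n_chrom_bins: int, tss: Optional[int] = None) -> np.ndarray:
    """Bin indices covered by a strand-oriented window around the gene's TSS,
    truncated at chromosome ends."""
    tss = gene.tss if tss is None else tss
    lo, hi = window
    if gene.strand == "+":
        start, end = tss + lo, tss + hi
    else:
        start, end = tss - hi + 1, tss - lo + 1
    b0 = max(0, start) // bin_size
    b1 = (min(end, n_chrom_bins * bin_size) - 1) // bin_size + 1
    return np.arange(max(0, b0), max(0, min(b1, n_chrom_bins)))


def promoter_body_scores(polii_adj: AdjustedTrack, genes: Sequence[GeneModel],
                         promoter: Tuple[int, int] = PROMOTER_WINDOW,
                         body: Tuple[int, int] = BODY_WINDOW) -> pd.DataFrame:
    """Per-gene promoter and gene-body mean adjusted polII scores with
    mutual-overlap masking: a bin inside the promoter-or-body window of two
    genes is excluded from both means.

    Returns one row per gene: promoter_score, body_score, stalling_index,
    flags. SI is +inf when the body is silent but the promoter is not, NaN
    when both are zero.
    """
    bs = polii_adj.bin_size
    nb = {c: len(a) for c, a in polii_adj.scores.items()}
    claimed: Dict[str, np.ndarray] = {c: np.zeros(n, dtype=np.int32) for c, n in nb.items()}
    windows = []
    for g in genes:
        pb = _window_bins(g, promoter, bs, nb[g.chrom])
        bb = _window_bins(g, body, bs, nb[g.chrom])
        windows.append((g, pb, bb))
        both = np.union1d(pb, bb)
        claimed[g.chrom][both] += 1

    rows = []
    for g, pb, bb in windows:
        arr = polii_adj.scores[g.chrom]
        mask = claimed[g.chrom]
        flags = []
        p_ok = pb[mask[pb] == 1]
        b_ok = bb[mask[bb] == 1]
        if len(p_ok) < len(pb) or len(b_ok) < len(bb):
            flags.append("overlap-masked")
        p = float(arr[p_ok].mean()) if len(p_ok) else np.nan
        b = float(arr[b_ok].mean()) if len(b_ok) else np.nan
        if len(p_ok) == 0 or len(b_ok) == 0:
            flags.append("window fully masked")
        if np.isnan(p) or np.isnan(b):
            si = np.nan
        elif b > 0:
            si = p / b
        elif p > 0:
            si = np.inf
        else:
            si = np.nan
        rows.append((g.gene_id, p, b, si, ";".join(flags)))
    return pd.DataFrame(rows, columns=["gene_id", "promoter_score", "body_score",
                                       "stalling_index", "flags"]).set_index("gene_id")


def classify_polii(records: pd.DataFrame, thr_promoter: float = 5.0,
                   thr_elong: float = 3.0, thr_stall: float = 10.0,
                   thr_none: float = 1.0) -> pd.DataFrame:
    """Gene classes from promoter score and stalling index:
    elongating (promoter >= 5, SI < 3), stalled (promoter >= 5, SI > 10),
    no_polII (promoter and body < 1), otherwise unclassified."""
    p = records["promoter_score"]
    b = records["body_score"]
    si = records["stalling_index"]
    out = records.copy()
    cls = np.full(len(records), "unclassified", dtype=object)
    cls[(p < thr_none) & (b < thr_none)] = "no_polII"
    cls[(p >= thr_promoter) & (si < thr_elong)] = "elongating"
    cls[(p >= thr_promoter) & (si > thr_stall)] = "stalled"
    out["class"] = cls
    return out


# ------------------------------------------------------------ read positioning


@dataclass
class PositionHistogram:
    """Depth-normalized 5-bp read-count difference (ChIP minus mock) around a
    set of anchors, separated by read orientation relative to the gene."""

    bin_size: int
    flank: int
    labels: np.ndarray  # left edge of each oriented bin
    sense: np.ndarray
    antisense: np.ndarray
    n_anchors: int

    def values(self, orientation: str) -> np.ndarray:
        if orientation == "sense":
            return self.sense
        if orientation == "antisense":
            return self.antisense
        raise ValueError("orientation must be 'sense' or 'antisense'")


def _oriented_offsets(pos: np.ndarray, anchor: int, strand: str) -> np.ndarray:
    return pos - anchor if strand == "+" else anchor - pos


def _anchored_counts(tags: pd.DataFrame, anchors: pd.DataFrame, flank: int,
                     bin_size: int) -> Tuple[np.ndarray, np.ndarray]:
    """Raw 5' read counts per oriented bin, (sense, antisense)."""
    nb = 2 * flank // bin_size
    sense = np.zeros(nb)
    anti = np.zeros(nb)
    by_cs = {key: np.sort(grp["pos"].to_numpy())
             for key, grp in tags.groupby(["chrom", "strand"])}
    for a in anchors.itertuples(index=False):
        for read_strand in "+-":
            pos = by_cs.get((a.chrom, read_strand))
            if pos is None:
                continue
            lo = np.searchsorted(pos, a.pos - flank)
            hi = np.searchsorted(pos, a.pos + flank)
            offs = _oriented_offsets(pos[lo:hi], a.pos, a.strand)
            offs = offs[(offs >= -flank) & (offs < flank)]
            idx = (offs + flank) // bin_size
            target = sense if read_strand == a.strand else anti
            np.add.at(target, idx, 1.0)
    return sense, anti


def position_histogram(chip_tags: pd.DataFrame, mock_tags: pd.DataFrame,
                       anchors: pd.DataFrame, flank: int = 1000, bin_size: int = 5,
                       chip_total: Optional[float] = None,
                       mock_total: Optional[float] = None) -> PositionHistogram:
    """Strand-resolved read positioning around anchors (chrom/pos/strand rows):
    per 5-bp bin, depth-scaled ChIP 5' count minus depth-scaled mock count."""
    if len(mock_tags) == 0:
        raise ValueError("empty mock tag set: depth normalization impossible")
    chip_total = float(chip_total if chip_total is not None else len(chip_tags))
    mock_total = float(mock_total if mock_total is not None else len(mock_tags))
    cs, ca = _anchored_counts(chip_tags, anchors, flank, bin_size)
    ms, ma = _anchored_counts(mock_tags, anchors, flank, bin_size)
    fc, fm = 1e7 / chip_total, 1e7 / mock_total
    labels = np.arange(-flank, flank, bin_size)
    return PositionHistogram(bin_size, flank, labels, cs * fc - ms * fm,
                             ca * fc - ma * fm, len(anchors))


def mode_offset(hist: PositionHistogram, window: Tuple[int, int] = (0, 200),
                orientation: str = "sense") -> Optional[int]:
    """Left-edge label of the maximal bin within the search window. Ties are
    broken toward the anchor (smaller |bin center|), then toward the smaller
    offset. None when the window carries no signal."""
    v = hist.values(orientation)
    in_win = (hist.labels >= window[0]) & (hist.labels < window[1])
    if not in_win.any() or np.all(v[in_win] == 0):
        return None
    labels = hist.labels[in_win]
    vals = v[in_win]
    best = vals.max()
    ties = labels[vals == best]
    centers = ties + hist.bin_size / 2.0
    return int(ties[np.lexsort((ties, np.abs(centers)))[0]])


def ks_compare(ends_a: np.ndarray, ends_b: np.ndarray) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on read end positions."""
    if len(ends_a) < 5 or len(ends_b) < 5:
        warnings.warn("KS sample size < 5: asymptotic p-value unreliable")
    res = stats.ks_2samp(ends_a, ends_b)
    return float(res.statistic), float(res.pvalue)


def tag_three_prime(tags: pd.DataFrame, read_len: int = 35) -> pd.DataFrame:
    """Tag table with 5' positions replaced by 3' end positions (5' + L-1 on
    the read strand)."""
    out = tags.copy()
    d = np.where(out["strand"].to_numpy() == "+", read_len - 1, -(read_len - 1))
    out["pos"] = out["pos"].to_numpy() + d
    return out


# ------------------------------------------------------------------ junctions


def junction_profiles(chip_tags: pd.DataFrame, mock_tags: pd.DataFrame,
                      genes: Sequence[GeneModel], flank: int = 300, bin_size: int = 5,
                      min_tss_distance: int = 500,
                      chip_total: Optional[float] = None,
                      mock_total: Optional[float] = None
                      ) -> Dict[str, PositionHistogram]:
    """Normalized polII read profiles anchored at exon->intron and
    intron->exon junctions, oriented in the transcription direction (negative
    offsets are upstream of the junction). Junctions within
    ``min_tss_distance`` of the TSS are excluded so the promoter footprint
    does not contaminate the junction signal."""
    out = {}
    for kind in ("exon_intron", "intron_exon"):
        anchors = junction_anchor_table(genes, kind, min_tss_distance)
        if len(anchors) == 0:
            raise ValueError(f"no usable {kind} junctions")
        out[kind] = position_histogram(chip_tags, mock_tags, anchors, flank,
                                       bin_size, chip_total, mock_total)
    return out


def detect_slowing_genes(chip_tags: pd.DataFrame, mock_tags: pd.DataFrame,
                         genes: Sequence[GeneModel], tau: float = 2.0,
                         window: Tuple[int, int] = (-120, -60), bin_size: int = 5,
                         min_tss_distance: int = 500,
                         chip_total: Optional[float] = None,
                         mock_total: Optional[float] = None) -> Set[str]:
    """Genes whose exon-side polII at exon->intron junctions exceeds tau times
    their gene-body level.

    Per gene: the mean normalized (ChIP minus mock, depth-scaled) 5-bp count
    over the exon-side window of its exon->intron junctions, compared with the
    median normalized count over the gene body. Genes with fewer than two
    exons, or without a positive body baseline, are not eligible.
    """
    if len(mock_tags) == 0:
        raise ValueError("empty mock tag set")
    chip_total = float(chip_total if chip_total is not None else len(chip_tags))
    mock_total = float(mock_total if mock_total is not None else len(mock_tags))
    fc, fm = 1e7 / chip_total, 1e7 / mock_total

    def binned_norm(gene_tags_c, gene_tags_m, start, end):
        nb = max(1, (end - start) // bin_size)
        edges = start + np.arange(nb + 1) * bin_size
        hc = np.histogram(gene_tags_c, bins=edges)[0] * fc
        hm = np.histogram(gene_tags_m, bins=edges)[0] * fm
        return hc - hm

    chip_by = {c: np.sort(g["pos"].to_numpy()) for c, g in chip_tags.groupby("chrom")}
    mock_by = {c: np.sort(g["pos"].to_numpy()) for c, g in mock_tags.groupby("chrom")}
    flagged: Set[str] = set()
    for g in genes:
        if max(len(t.exons) for t in g.transcripts) < 2:
            continue
        anchors = junction_anchor_table([g], "exon_intron", min_tss_distance)
        if len(anchors) == 0:
            continue
        cpos = chip_by.get(g.chrom, np.empty(0))
        mpos = mock_by.get(g.chrom, np.empty(0))
        body = binned_norm(cpos[(cpos >= g.start) & (cpos < g.end)],
                           mpos[(mpos >= g.start) & (mpos < g.end)], g.start, g.end)
        body_median = float(np.median(body))
        if body_median <= 0:
            continue
        win_vals = []
        for a in anchors.itertuples(index=False):
            if a.strand == "+":
                lo, hi = a.pos + window[0], a.pos + window[1]
            else:
                lo, hi = a.pos - window[1] + 1, a.pos - window[0] + 1
            win_vals.append(binned_norm(cpos[(cpos >= lo) & (cpos < hi)],
                                        mpos[(mpos >= lo) & (mpos < hi)], lo, hi))
        mean_win = float(np.mean(np.concatenate(win_vals)))
        if mean_win >= tau * body_median:
            flagged.add(g.gene_id)
    return flagged


def splice_variant_test(flagged: Sequence[str], rest: Sequence[str],
                        genes: Sequence[GeneModel],
                        quantity: str = "variants") -> dict:
    """Two-sided Mann-Whitney comparison of per-gene splice-variant counts
    (or exon counts) between a flagged gene set and the remaining genes,
    with medians and quartiles for each group."""
    by_id = {g.gene_id: g for g in genes}

    def counts(ids):
        if quantity == "variants":
            return np.array([len(by_id[i].transcripts) for i in ids], dtype=float)
        if quantity == "exons":
            return np.array([max(len(t.exons) for t in by_id[i].transcripts)
                             for i in ids], dtype=float)
        raise ValueError("quantity must be 'variants' or 'exons'")

    a, b = counts(list(flagged)), counts(list(rest))
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each gene set needs at least 3 members")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    q = lambda x: (float(np.percentile(x, 25)), float(np.percentile(x, 75)))
    return {
        "U": float(u), "p": float(p),
        "flagged_mean": float(a.mean()), "rest_mean": float(b.mean()),
        "flagged_median": float(np.median(a)), "rest_median": float(np.median(b)),
        "flagged_quartiles": q(a), "rest_quartiles": q(b),
        "n_flagged": len(a), "n_rest": len(b),
    }
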