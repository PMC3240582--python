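"""Expression-stratified metagene profiles, TSS-window summaries and gene
feature tables.

Profiles are strand-oriented (downstream of the anchor is positive on the
gene strand) and averaged with symmetric trimming so a handful of extreme
genes cannot dominate a group mean. Unique-tag (U) score tracks are the
intended input: multi-mapping weight near transposon copies would otherwise
bleed into promoter averages.
"""
from __future__ import annotations

import math
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import GeneModel, TransposonCopy
from .scoring import BinTrack

ANCHORS = ("tss", "midpoint", "txend")

#: Named TSS windows (mark, start offset, end offset in bp, gene-strand
#: oriented, half-open) used as the 10-input chromatin signature.
DEFAULT_TSS_WINDOWS: Dict[str, Tuple[str, int, int]] = {
    "H3K4me3_U": ("H3K4me3", -500, 0),
    "H3K4me3_D": ("H3K4me3", 0, 500),
    "H3K9me3_T": ("H3K9me3", -100, 400),
    "H3K9me3_U": ("H3K9me3", -750, -250),
    "H3K9ac_U": ("H3K9ac", -500, 0),
    "H3K9ac_D": ("H3K9ac", 0, 500),
    "H3K27me3": ("H3K27me3", -250, 250),
    "HP1a": ("HP1a", -100, 400),
    "polII_T": ("polII", -100, 100),
    "polII_D": ("polII", 100, 400),
}


def expression_groups(expr: pd.Series, n: int = 10) -> pd.DataFrame:
    """Rank-based equal-count expression grouping (group sizes differ by at
    most one; ties broken by stable gene order). Columns: expression, group."""
    if n > len(expr):
        raise ValueError("more groups than genes")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValueError("expression values must be finite")
    order = np.argsort(expr.to_numpy(), kind="stable")
    group = np.empty(len(expr), dtype=int)
    for g, idx in enumerate(np.array_split(order, n), 1):
        group[idx] = g
    return pd.DataFrame({"expression": expr.to_numpy(), "group": group},
                        index=expr.index)


def _anchor_positions(gene: GeneModel, anchor: str) -> Tuple[int, ...]:
    if anchor == "tss":
        return gene.tss_positions()
    if anchor == "midpoint":
        return gene.midpoints()
    if anchor == "txend":
        return gene.txend_positions()
    raise ValueError(f"anchor must be one of {ANCHORS}")


def trimmed_mean(values: np.ndarray, trim: float) -> float:
    """Mean after dropping floor(trim * n) values from each end; NaNs (e.g.
    truncated windows at chromosome ends) are ignored."""
    v = np.sort(values[~np.isnan(values)])
    if len(v) == 0:
        return float("nan")
    t = int(math.floor(trim * len(v)))
    if 2 * t >= len(v):
        return float(np.mean(v))
    return float(np.mean(v[t:len(v) - t]))


def gene_profile(track: BinTrack, gene: GeneModel, anchor: str,
                 offsets: np.ndarray) -> np.ndarray:
    """Per-offset track values for one gene, averaged over all annotated
    anchor positions (multi-TSS genes contribute their per-anchor mean once)."""
    rows = []
    for a in _anchor_positions(gene, anchor):
        pos = a + gene.direction * offsets
        rows.append(track.values_at(gene.chrom, pos))
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.vstack(rows), axis=0)


def metagene(track: BinTrack, genes: Sequence[GeneModel], anchor: str = "tss",
             flank: int = 2000, step: int = 10, trim: float = 0.05,
             groups: Optional[pd.Series] = None) -> pd.DataFrame:
    """Trimmed-mean metagene profile per expression group.

    ``trim`` is the fraction trimmed from *each* end of the per-offset gene
    distribution (0.05/side = 10% of genes in total). Long format:
    anchor, group, offset, mean, n_genes.
    """
    offsets = np.arange(-flank, flank + 1, step)
    ids = [g.gene_id for g in genes]
    if groups is None:
        groups = pd.Series("all", index=ids)
    mat = np.vstack([gene_profile(track, g, anchor, offsets) for g in genes])
    rows = []
    for label in pd.unique(groups.loc[ids]):
        member = np.array([groups.loc[i] == label for i in ids])
        ng = int(member.sum())
        if trim > 0 and ng * trim < 1:
            raise ValueError(
                f"group {label!r} has {ng} genes; too few to trim {trim:.0%} per side")
        sub = mat[member]
        for j, off in enumerate(offsets):
            rows.append((anchor, label, int(off), trimmed_mean(sub[:, j], trim), ng))
    return pd.DataFrame(rows, columns=["anchor", "group", "offset", "mean", "n_genes"])


def tss_window_means(tracks: Dict[str, BinTrack], genes: Sequence[GeneModel],
                     windows: Optional[Dict[str, Tuple[str, int, int]]] = None
                     ) -> pd.DataFrame:
    """Per-gene mean scores over named strand-oriented TSS windows. Windows
    running off a chromosome end are truncated (mean over the scored part)."""
    windows = windows if windows is not None else DEFAULT_TSS_WINDOWS
    for name, (_, lo, hi) in windows.items():
        if hi <= lo:
            raise ValueError(f"window {name!r} has non-positive width")
    out = {}
    for name, (mark, lo, hi) in windows.items():
        if mark not in tracks:
            raise KeyError(f"no track for mark {mark!r} (window {name!r})")
        track = tracks[mark]
        col = []
        for g in genes:
            vals = []
            for tss in g.tss_positions():
                pos = tss + g.direction * np.arange(lo, hi)
                v = track.values_at(g.chrom, pos)
                v = v[~np.isnan(v)]  # truncated at chromosome ends
                vals.append(v.mean() if len(v) else np.nan)
            col.append(float(np.nanmean(vals)))
        out[name] = col
    return pd.DataFrame(out, index=[g.gene_id for g in genes])


def fold_change_percentiles(expr_wt: pd.Series, expr_kd: pd.Series,
                            n: int = 100) -> pd.DataFrame:
    """Rank genes by knockdown/wild-type expression ratio into equal-count
    percentiles. Genes with zero wild-type expression are excluded (flagged in
    the 'excluded' attribute of the returned frame)."""
    common = expr_wt.index.intersection(expr_kd.index)
    wt = expr_wt.loc[common]
    kd = expr_kd.loc[common]
    excluded = list(common[wt == 0])
    keep = wt != 0
    ratio = (kd[keep] / wt[keep]).astype(float)
    if n > len(ratio):
        raise ValueError("more percentiles than usable genes")
    order = np.argsort(ratio.to_numpy(), kind="stable")
    pct = np.empty(len(ratio), dtype=int)
    for g, idx in enumerate(np.array_split(order, n), 1):
        pct[idx] = g
    df = pd.DataFrame({"ratio": ratio.to_numpy(), "percentile": pct}, index=ratio.index)
    df.attrs["excluded"] = excluded
    return df


def gene_features(genes: Sequence[GeneModel], transposons: Sequence[TransposonCopy],
                  layout: Dict[str, int], expression: Optional[pd.Series] = None,
                  centromeres: Optional[Dict[str, int]] = None,
                  flank: int = 2000, density_window: int = 100_000) -> pd.DataFrame:
    """Per-gene structural feature table: length, exon count/density, embedded
    genes (sense/antisense), local gene density, transposon densities
    upstream/within/downstream, splice-variant count, and (when centromere
    coordinates are supplied) distance to the centromere."""
    te_by_chrom: Dict[str, list] = {}
    for t in transposons:
        te_by_chrom.setdefault(t.chrom, []).append((t.start, t.end))

    def te_fraction(chrom: str, s: int, e: int) -> float:
        s, e = max(0, s), min(layout[chrom], e)
        if e <= s:
            return 0.0
        covered = 0
        for ts, te in te_by_chrom.get(chrom, []):
            covered += max(0, min(te, e) - max(ts, s))
        return covered / (e - s)

    rows = []
    for g in genes:
        length = g.end - g.start
        n_exons = max(len(t.exons) for t in g.transcripts)
        emb_sense = emb_anti = 0
        near = 0
        center = (g.start + g.end) // 2
        for other in genes:
            if other.gene_id == g.gene_id or other.chrom != g.chrom:
                continue
            if other.start >= g.start and other.end <= g.end:
                if other.strand == g.strand:
                    emb_sense += 1
                else:
                    emb_anti += 1
            oc = (other.start + other.end) // 2
            if abs(oc - center) <= density_window // 2:
                near += 1
        if g.strand == "+":
            up = (g.start - flank, g.start)
            down = (g.end, g.end + flank)
        else:
            up = (g.end, g.end + flank)
            down = (g.start - flank, g.start)
        dist_cen = np.nan
        if centromeres and g.chrom in centromeres:
            cen = centromeres[g.chrom]
            dist_cen = min(abs(g.start - cen), abs(g.end - cen))
        rows.append({
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "expression": float(expression.get(g.gene_id, np.nan)) if expression is not None else np.nan,
            "length": length,
            "n_exons": n_exons,
            "exon_density": n_exons / (length / 1000.0),
            "embedded_sense": emb_sense,
            "embedded_antisense": emb_anti,
            "gene_density": near * (100_000 / density_window),
            "dist_centromere": dist_cen,
            "te_density_upstream": te_fraction(g.chrom, *up),
            "te_density_within": te_fraction(g.chrom, g.start, g.end),
            "te_density_downstream": te_fraction(g.chrom, *down),
            "splice_variants": len(g.transcripts),
        })
    return pd.DataFrame(rows).set_index("gene_id")
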