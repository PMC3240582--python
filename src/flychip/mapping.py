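"""Iterative best-tier Hamming mapping of fixed-length reads.

Reads are mapped with increasing mismatch allowance (rounds m = 0, 1, 2, ...)
until the majority of input reads are placed or the allowance cap is reached.
Every best-tier site is retained; a tag mapped to k sites carries multiplicity
k for downstream 1/k weighting. Matching is exact (no heuristics): round 0
uses a rolling-hash index of all genomic read-length words, later rounds use
pigeonhole seeding (a read with <= m mismatches over m+1 disjoint segments
matches at least one segment exactly), so every site at the minimal mismatch
tier is found. Ambiguous bases count as mismatches at every site.
"""
from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import MappedTag, MappingStats
from .simulate import encode

_HASH_BASE = np.uint64(1099511628211)


def _word_hashes(codes: np.ndarray, word: int) -> np.ndarray:
    """Polynomial hash of every length-``word`` window of a code array
    (uint64 wraparound arithmetic is intentional)."""
    n = len(codes) - word + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    h = np.zeros(n, dtype=np.uint64)
    p = np.uint64(1)
    c = codes.astype(np.uint64)
    with np.errstate(over="ignore"):
        for j in range(word):
            h += c[j:j + n] * p
            p = p * _HASH_BASE
    return h


def _hash_one(codes: np.ndarray, word: int) -> np.uint64:
    return _word_hashes(codes[:word], word)[0]


class GenomeIndex:
    """Sorted rolling-hash indexes over a genome, per word length."""

    def __init__(self, genome: Dict[str, str]):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("empty genome")
        self.chroms = list(genome)
        self.codes = {c: encode(s) for c, s in genome.items()}
        self.lengths = {c: len(s) for c, s in genome.items()}
        self._offsets = {}
        off = 0
        for c in self.chroms:
            self._offsets[c] = off
            off += self.lengths[c]
        self._bounds = np.array([self._offsets[c] for c in self.chroms] + [off])
        self._indexes: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}

    def _index_for(self, word: int) -> Tuple[np.ndarray, np.ndarray]:
        if word not in self._indexes:
            hashes, positions = [], []
            for c in self.chroms:
                h = _word_hashes(self.codes[c], word)
                hashes.append(h)
                positions.append(np.arange(len(h), dtype=np.int64) + self._offsets[c])
            h = np.concatenate(hashes) if hashes else np.empty(0, dtype=np.uint64)
            pos = np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)
            order = np.argsort(h, kind="stable")
            self._indexes[word] = (h[order], pos[order])
        return self._indexes[word]

    def locate(self, flat: int) -> Tuple[str, int]:
        i = int(np.searchsorted(self._bounds, flat, side="right")) - 1
        c = self.chroms[i]
        return c, flat - self._offsets[c]

    def candidates(self, codes: np.ndarray, word: int) -> np.ndarray:
        """Flat genomic start positions whose word-hash equals the query's."""
        h_sorted, pos = self._index_for(word)
        h = _hash_one(codes, word)
        lo = np.searchsorted(h_sorted, h, side="left")
        hi = np.searchsorted(h_sorted, h, side="right")
        return pos[lo:hi]

    def mismatches(self, flat_start: int, read_codes: np.ndarray) -> Optional[int]:
        """Hamming distance of the read against the genome at a flat position,
        or None if the window crosses a chromosome boundary."""
        if flat_start < 0 or flat_start >= self._bounds[-1]:
            return None
        chrom, p = self.locate(flat_start)
        L = self.lengths[chrom]
        if p < 0 or p + len(read_codes) > L:
            return None
        seg = self.codes[chrom][p:p + len(read_codes)]
        return int(np.count_nonzero(seg != read_codes))


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    rc = codes[::-1].copy()
    acgt = rc < 4
    rc[acgt] = 3 - rc[acgt]
    return rc


def _segments(read_len: int, n_parts: int) -> List[Tuple[int, int]]:
    base, rem = divmod(read_len, n_parts)
    segs, off = [], 0
    for i in range(n_parts):
        ln = base + (1 if i < rem else 0)
        segs.append((off, ln))
        off += ln
    return segs


def _sites_at_tier(index: GenomeIndex, fwd: np.ndarray, rc: np.ndarray,
                   allowance: int, read_len: int) -> Tuple[List[Tuple[str, int, str]], int]:
    """All sites with minimal mismatch count <= allowance for one read.

    Returns (sites, best_mismatches); sites empty when nothing is within the
    allowance. Minus-strand sites report the genomic position of the read's
    5' base (rightmost base of the match).
    """
    best = allowance + 1
    found: Dict[Tuple[str, int, str], int] = {}
    for strand, codes in (("+", fwd), ("-", rc)):
        cands: set = set()
        if allowance == 0:
            cands.update(int(x) for x in index.candidates(codes, read_len))
        else:
            for off, ln in _segments(read_len, allowance + 1):
                for hit in index.candidates(codes[off:off + ln], ln):
                    cands.add(int(hit) - off)
        for flat in cands:
            mm = index.mismatches(flat, codes)
            if mm is None or mm > allowance:
                continue
            chrom, p = index.locate(flat)
            five = p if strand == "+" else p + read_len - 1
            found[(chrom, five, strand)] = mm
            best = min(best, mm)
    sites = sorted(k for k, v in found.items() if v == best)
    return sites, (best if sites else -1)


def map_iterative(reads: Sequence[Tuple[str, str]], genome: Dict[str, str],
                  max_mismatch: int = 5, majority: float = 0.6,
                  read_len: int = 35, max_ambiguous: int = 5,
                  max_sites: Optional[int] = None) -> Tuple[List[MappedTag], MappingStats]:
    """Map reads with iteratively relaxed mismatch allowance.

    Rounds m = 0..max_mismatch admit reads whose best hit has exactly m
    mismatches; iteration stops once the cumulative mapped fraction exceeds
    ``majority``. Reads with >= ``max_ambiguous`` ambiguous bases are dropped
    up front. ``max_sites`` optionally discards tags mapping to more than that
    many best-tier sites.
    """
    index = GenomeIndex(genome)
    stats = MappingStats(total_reads=len(reads))
    if not reads:
        return [], stats

    prepared = []
    for rid, seq in reads:
        if len(seq) != read_len:
            raise ValueError(f"read {rid}: expected length {read_len}, got {len(seq)}")
        codes = encode(seq)
        # read ambiguity code 5 never equals a genome code (0-4)
        codes = np.where(codes == 4, np.uint8(5), codes)
        if int(np.count_nonzero(codes == 5)) >= max_ambiguous:
            stats.dropped_ambiguous += 1
            continue
        prepared.append((rid, codes, _revcomp_codes(codes)))

    kept = len(prepared)
    tags: List[MappedTag] = []
    unmapped = prepared
    for allowance in range(max_mismatch + 1):
        stats.final_allowance = allowance
        still = []
        for rid, fwd, rc in unmapped:
            sites, mm = _sites_at_tier(index, fwd, rc, allowance, read_len)
            if sites:
                if max_sites is not None and len(sites) > max_sites:
                    continue  # hyper-repetitive tag discarded
                tags.append(MappedTag(rid, tuple(sites), mm))
            else:
                still.append((rid, fwd, rc))
        unmapped = still
        frac = len(tags) / kept if kept else 0.0
        stats.rounds.append((allowance, frac))
        if frac > majority:
            break

    stats.unique_count = sum(1 for t in tags if t.k == 1)
    stats.multiple_count = sum(1 for t in tags if t.k > 1)
    return tags, stats


# ------------------------------------------------------------------ tag table


def to_tag_table(tags: Sequence[MappedTag]) -> pd.DataFrame:
    """One row per mapping site: read_id, chrom, pos, strand, mismatches, k."""
    rows = [(t.read_id, c, p, s, t.mismatches, t.k)
            for t in tags for (c, p, s) in t.sites]
    return pd.DataFrame(rows, columns=["read_id", "chrom", "pos", "strand",
                                       "mismatches", "k"])


def tags_from_table(table: pd.DataFrame) -> List[MappedTag]:
    tags = []
    for rid, grp in table.groupby("read_id", sort=False):
        sites = tuple(sorted(zip(grp["chrom"], grp["pos"].astype(int), grp["strand"])))
        tags.append(MappedTag(str(rid), sites, int(grp["mismatches"].iloc[0])))
    return tags


def table_from_origins(origins: pd.DataFrame) -> pd.DataFrame:
    """Treat a simulator true-origin table as a uniquely-mapped tag table."""
    t = origins[["read_id", "chrom", "pos", "strand"]].copy()
    t["mismatches"] = 0
    t["k"] = 1
    return t
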