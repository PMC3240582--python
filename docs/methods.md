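# Methods

## Model and pipeline

The package analyzes single-end short-read ChIP-seq (35-nt tags) on a compact,
repeat-rich genome. The chain is: tag mapping → bin scoring → normalization →
downstream analytics, with a synthetic-data generator supplying inputs whose
truth is known.

### Tag mapping

Reads are mapped by exact best-tier Hamming search: round *m* = 0, 1, 2, …
admits reads whose best genomic match (either strand) has ≤ *m* mismatches;
iteration stops once the cumulative mapped fraction exceeds the majority
threshold (default 0.6) or the allowance cap (default 5) is reached. Round 0
uses a rolling-hash index of every genomic 35-mer (hash collisions are
verified by direct comparison); later rounds use pigeonhole seeding — a read
with ≤ *m* mismatches matches at least one of *m*+1 disjoint segments
exactly — so the search is exhaustive, not heuristic. All sites at the
minimal mismatch tier are retained; a tag with *k* sites carries weight 1/*k*
per site in U+M mode and is excluded in U mode. Reads with ≥ 5 ambiguous
bases are dropped; an ambiguous base in a kept read counts as a mismatch at
every site. Indel alignment is deliberately out of scope: downstream scoring
is indifferent to how sites were found, and the synthetic data contains no
indels. Mapped fraction is measured against reads surviving the ambiguity
filter.

### Bin scoring (tag extension)

The genome is tiled into 50-bp bins (the final partial bin counts per
chromosome; the six BDGP R5 euchromatic arm lengths are embedded as
constants for genome-scale window arithmetic). Each mapped site contributes
to the bin containing its 5' position and the nine bins in the fragment's 3'
direction, with weights `w[i] = P(L > i·50)` — the survival function of the
fragment-length distribution, *not* renormalized to sum to 1. Consequence:
total raw track score = Σw × (number of contributing tags), up to
chromosome-end truncation. The first bin receives `w[0]` even when the tag
starts mid-bin (bin-resolution scheme, no sub-bin proration). Minus-strand
sites extend toward decreasing coordinates. The default fragment-length
distribution is triangular on 100–500 bp with mode 200 bp, a shearing-gel
mono/di/poly-nucleosome profile; it is a plain configurable pmf.

### Normalization and thresholding

1. **Depth**: bins × 10⁷ / tag_total; idempotent via a flag on the track.
2. **Noise normalizer**: histograms of positive bin scores (zeros are
   excluded — on a mostly empty genome they would swamp the histogram; the
   noise structure of interest lives in the occupied bins). The *critical
   value* is the right-most histogram cell where the control count still
   matches or exceeds the experimental count, with the experimental count
   strictly larger in every occupied cell above; if no such region exists
   (e.g. identical tracks, or two draws from the same background) the
   datasets have no enrichment signature and the convenience wrapper
   `normalize_pair` falls back to c = 1, the true value under exchangeable
   noise. The normalizer c maximizes the Pearson correlation between the
   sub-critical histograms of (c·exp) and ctrl over a geometric grid centred
   on the X/Y ratio of the two histograms' modal scores; degenerate
   histograms fall back to X/Y with a warning. Default histogram binwidth is
   Freedman–Diaconis on the control's positive scores.
3. **Subtraction**: `adjusted(b) = max(0, c·exp(b) − ctrl(b))`.
4. **Empirical FDR**: the null is the role-swapped subtraction
   `max(0, ctrl − c·exp)` — an exchange null computable without extra data;
   a split-control null can be substituted by passing any AdjustedTrack.
   `FDR(s) = #{null ≥ s} / #{exp ≥ s}` evaluated at every occupied positive
   adjusted score and monotonized by a running minimum so the curve is
   non-increasing in s (a raw count ratio need not be monotone); the
   threshold is the smallest s with FDR(s) < α (default 0.001). Reported
   tracks zero the sub-threshold bins; merged runs of surviving bins are
   exported as BED, tracks as fixedStep WIG.

### Downstream analytics

- **Feature map**: each bin takes the highest-precedence overlapping label
  (transposon > CDS > 5'UTR > 3'UTR > intron > intergenic). Precedence, not
  bp majority, decides mixed bins; the labels partition the genome so
  per-percentile compositions sum to 100%. Percentile composition sorts bins
  ascending by score with a stable sort (ties stay in genomic order) into
  equal-count groups.
- **Metagene profiles**: strand-oriented offsets around TSS / transcript
  midpoint / TxEnd at 10-bp steps over ±2 kb; per expression group the mean
  is trimmed by 5% of genes per side (10% total; configurable — the
  alternative reading of "10% per end" is one argument away). Multi-TSS
  genes contribute the average over their anchors once. Genes near
  chromosome ends contribute truncated windows (NaN-aware trimming) rather
  than being dropped. U-mode tracks are the intended input near repeats.
- **polII stalling**: promoter = TSS ± 500 bp, body = +750..+2500 bp; bins
  claimed by two genes' promoter-or-body windows are masked from both means.
  SI = promoter/body, +∞ when the body is silent but the promoter is not —
  such genes classify as stalled, which is the intended reading of SI > 10.
  Classification operates on *reported* (FDR-thresholded) adjusted scores,
  which is what makes the absolute thresholds (5, 3, 10, 1) meaningful: noise
  bins are zeroed, so silent genes sit at exactly 0.
- **5-bp positioning**: depth-scaled ChIP 5'-position counts minus
  depth-scaled mock counts per oriented 5-bp bin, separated by read
  orientation relative to the gene (subtraction, not ratio — the sign
  convention "positive = enriched, negative = depleted" requires it). Bins
  are labeled by their left edge on the gene-oriented axis; `mode_offset`
  breaks ties toward the anchor, then toward the smaller offset.
- **Junctions**: anchors are the transcription-direction boundaries of
  internal exons; offset 0 is the first base past the boundary, negative
  offsets are upstream (the exon side of exon→intron junctions, the intron
  side of intron→exon junctions). Junctions within 500 bp of the TSS are
  excluded so the promoter footprint cannot masquerade as junction signal.
  The slowing-gene detector flags genes whose mean normalized polII in the
  exon-side window [−120, −60] of their exon→intron junctions is at least
  τ (default 2) times their gene-body median; genes with < 2 exons or
  without a positive body baseline are ineligible. This detector is an
  explicit operationalization — no published quantitative rule exists for
  the selection it mimics.
- **Signatures/ANN**: gene × feature matrices from 10 named TSS windows or
  6 marks × 19 positions (−450..+450 bp in 50-bp steps, 114 inputs),
  z-standardized, zero-variance features dropped. Clustering is agglomerative
  (correlation distance, average linkage, cut at k); expression is displayed
  per cluster but never enters the metric. The network is input → 2 → 3 → 1
  with logistic hidden units and a linear output (scikit-learn MLPRegressor,
  lbfgs), trained per run on a seeded random half of genes and evaluated on
  the other half. Accuracy is defined as 1 − mean|pred − true|/10 on the
  0–10 expression scale (no standard definition exists for this quantity;
  Pearson r is reported alongside). Importance is Garson-style:
  |W₁|·|W₂|·|W₃| summed over paths per input, normalized to 1, averaged over
  runs with the between-run sd.

## The synthetic-data generator

`build_world` draws random chromosomes, plants transposon families (copies
are a consensus mutated at rate 1 − identity, so 100% identity yields exact
duplicates and genuinely multi-mapping reads), places non-overlapping genes
with exon structure and an optional exon-skipping splice variant, and assigns
lognormal expression with a silent fraction and planted polII classes
(stalled / elongating / none) plus a junction-slowing gene subset. Mark
models are additive rate landscapes over read 5' positions — background per
bp, Gaussian TSS footprints (a footprint parameter f concentrates 5' ends in
the 5-bp window [f, f+5)), expression-scaled gene-body rates, per-family
transposon affinities, junction-anchored Gaussians — with multiplicative
depletion notches applied last. Sampling is an exact multinomial over
(chromosome, strand), reads are the first 35 bases from the fragment 5' end,
reads crossing a chromosome end are discarded and resampled, base-call
errors are substitutions only, and qualities are constant 'I'. Everything is
deterministic per seed.

What the generator does **not** emulate: realistic base composition, PCR
duplicates, mappability structure beyond the planted repeats, paired ends,
chromatin-accessibility-correlated background (available only as an explicit
bias array), or indels. Passing recovery tests therefore demonstrates the
*analytical* machinery — weighting, extension arithmetic, normalization
calibration, strand handling, planted-signal localization — not robustness
to the full noise anatomy of real libraries.

### Default study conditions

The polII factory models encode strong, well-separated classes: a stalled
promoter captures on the order of 1% of the library on a megabase-scale
world (footprint weight 30,000 vs background 1/bp), elongating promoters
carry 15% of that footprint plus an expression-scaled body rate (800 per kb
per expression unit), silent genes only background. Class-recovery and
positioning analyses use 2×10⁵-tag libraries on 2-Mb worlds with 60 genes;
the FDR-calibration analysis uses three 5×10⁵-tag uniform libraries on a
10-Mb world per seed triplet, averaged over 10 triplets. These sizes keep a
full run in seconds per seed while leaving each planted effect many standard
errors clear of its recovery threshold.

## Numerical choices and degenerate inputs

- FDR monotonization runs from low scores upward (running minimum), making
  the curve non-increasing in s; the threshold is then the smallest score
  whose raw FDR clears α.
- `critical_value` raises on identical tracks (no crossing) rather than
  inventing one; `noise_normalizer` requires a usable sub-critical histogram
  and falls back to the X/Y ratio when it is degenerate.
- Trimmed means drop ⌊trim·n⌋ values per side; groups too small to trim at
  all (n·trim < 1) raise rather than silently untrimming.
- `mode_offset` on an all-zero window returns None; zero-width TSS windows
  raise; empty mock libraries raise (depth normalization impossible).
- Tag tables, not read sets, are the interchange format between stages, so
  simulator true-origin tables can stand in for mapper output when an
  analysis does not exercise mapping itself.

## Known limitations

- The mismatch rounds are exact but per-read Python loops; they are sized
  for desk-scale genomes (≤ tens of Mb), not whole mammalian genomes.
- The exchange null is conservative when the experimental library is mostly
  signal (little noise mass to swap); a split-control null is the documented
  alternative.
- The slowing-gene criterion and the ANN accuracy definition are package
  choices; both are parameters, not claims about any external dataset.
- U+M scoring spreads a multi-tag's weight uniformly over its best-tier
  sites; no expectation-maximization reassignment is attempted.
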