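# flychip

Multi-mapping-aware ChIP-seq bin scoring, empirical-FDR background
subtraction, and promoter/polII analytics for compact genomes — with a
synthetic-data generator that plants known truth, so every stage of the
pipeline is testable end to end without external downloads.

## The problem

Short-read ChIP-seq of a repeat-rich genome (the motivating case is whole-fly
*Drosophila melanogaster* chromatin) poses three linked analysis problems:

1. **Multi-mapping reads.** Transposon families carry near-identical copies,
   so a large fraction of 35-nt tags cannot be placed uniquely. Discarding
   them blinds the analysis to heterochromatic marks; the pipeline instead
   retains every best-tier site and weights a *k*-site tag 1/*k* per site
   ("U+M" scoring), alongside a unique-only ("U") mode for analyses near
   repeats.
2. **A tag is not a fragment.** Only the first 35 nt of each precipitated
   fragment is sequenced. Scores are therefore extended from each tag's 5'
   position in the fragment's 3' direction across ten 50-bp bins using the
   survival function of the fragment-length distribution:
   `w[i] = P(L > i·50)`.
3. **Non-specific background.** Tracks are depth-scaled to 10 million tags,
   rescaled by a noise normalizer `c` fitted on sub-critical scores (below
   the *critical value*, the score above which the experimental score
   histogram always exceeds the mock control's), background-subtracted as
   `adjusted = max(0, c·exp − ctrl)`, and thresholded at empirical
   FDR < 0.001, where `FDR(s) = #{null bins ≥ s} / #{experimental bins ≥ s}`
   with a role-swapped exchange null.

On top of the adjusted tracks the package implements the downstream
analytics: genomic-feature and transposon-class score distributions,
expression-stratified metagene profiles around TSS / gene midpoint / TxEnd,
RNA polII stalling classification (stalling index
`SI = promoter / body`, promoter = TSS±500 bp, body = +750..+2500 bp;
stalled: promoter ≥ 5 ∧ SI > 10; elongating: promoter ≥ 5 ∧ SI < 3;
no polII: both < 1), strand-resolved 5-bp read positioning around TSSs and
splice junctions, slowing-gene detection, and TSS chromatin-signature
clustering with a small feed-forward network (input → 2 → 3 → 1) predicting
quantitative expression, including Garson weight attribution of input
importance.

## Worked example

```python
import flychip as fc

world = fc.build_world(fc.WorldConfig(
    chrom_lengths={"chr1": 1_000_000, "chr2": 1_000_000},
    n_genes=60, expression_mu=2.5, expression_sigma=0.3), seed=5)
matrix = fc.build_score_matrix(fc.FragmentLengthDist.triangular())

chip = fc.simulate_mark_tags(world, fc.stalled_polii_mark(), 200_000, seed=6)
mock = fc.simulate_control_tags(world, 200_000, seed=7)

exp  = fc.score_table(fc.table_from_origins(chip.origins), matrix, "U", world.layout)
ctrl = fc.score_table(fc.table_from_origins(mock.origins), matrix, "U", world.layout)
adj  = fc.normalize_pair(exp, ctrl, alpha=0.001)

rec = fc.promoter_body_scores(fc.AdjustedTrack(adj.reported(), adj.bin_size), world.genes)
print(fc.classify_polii(rec)["class"].value_counts().to_dict())
```

prints

```
{'no_polII': 22, 'elongating': 22, 'stalled': 16}
```

— the planted class of every one of the 60 genes (22 silent, 22 elongating,
16 stalled in this world) recovered from the adjusted track alone. Running
`examples/03_stalling_and_positioning.py` extends this with read-level
positioning and prints the stalled footprint's modal 5-bp bin at `+35` bp
downstream of the TSS, the planted location. The other scripts in
`examples/` walk through simulation/mapping, track normalization, and
signature clustering with the expression-predicting network; each prints the
quantities it computes and a line on what they mean.

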