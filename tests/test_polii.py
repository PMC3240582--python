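"""Stalling index, polII classification, 5-bp positioning, junction profiles,
slowing-gene detection and the splice-variant comparison."""
import numpy as np
import pandas as pd
import pytest

import flychip as fc
from conftest import constant_track


def _gene(gid, chrom, strand, start, end, exons=None, n_tx=1):
    exons = exons or [(start, end)]
    txs = tuple(fc.Transcript(f"{gid}.t{i+1}", start, end, tuple(exons))
                for i in range(n_tx))
    return fc.GeneModel(gid, chrom, strand, txs)


def _adj(scores, chrom="c", bin_size=50):
    return fc.AdjustedTrack({chrom: np.asarray(scores, dtype=float)}, bin_size)


def test_constant_track_gives_unit_stalling_index():
    gene = _gene("g", "c", "+", 5_000, 12_000)
    adj = _adj(np.full(400, 8.0))
    rec = fc.promoter_body_scores(adj, [gene])
    assert rec.loc["g", "promoter_score"] == pytest.approx(8.0)
    assert rec.loc["g", "body_score"] == pytest.approx(8.0)
    assert rec.loc["g", "stalling_index"] == pytest.approx(1.0)


def test_promoter_body_windows_and_ratio():
    """Promoter mean 60 against body mean 5 gives SI = 12."""
    scores = np.zeros(400)
    tss = 5_000
    scores[(tss - 500) // 50:(tss + 500) // 50] = 60.0
    scores[(tss + 750) // 50:(tss + 2_500) // 50] = 5.0
    rec = fc.promoter_body_scores(_adj(scores), [_gene("g", "c", "+", tss, tss + 7_000)])
    assert rec.loc["g", "promoter_score"] == pytest.approx(60.0)
    assert rec.loc["g", "body_score"] == pytest.approx(5.0)
    assert rec.loc["g", "stalling_index"] == pytest.approx(12.0)


def test_overlapping_windows_masked_from_both_genes():
    """Two genes with overlapping promoters: shared bins are excluded from both
    means; remaining bins reproduce a hand computation."""
    g1 = _gene("g1", "c", "+", 5_000, 11_000)
    g2 = _gene("g2", "c", "+", 5_600, 11_600)  # promoters overlap on 5100-6100
    scores = np.arange(400, dtype=float)  # bin b has score b
    rec = fc.promoter_body_scores(_adj(scores), [g1, g2])
    # g1 promoter bins 90..110; g2 promoter bins 102..122 -> shared 102..110
    # is masked; g1 body bins (5750-7500 = 115..150) overlap g2's promoter
    # tail and body start as well
    g1p = [b for b in range(90, 110) if not 102 <= b < 122]
    own = set(range(90, 110)) | set(range(115, 150))
    other = set(range(102, 122)) | set(range(127, 162))
    g1p = [b for b in range(90, 110) if b not in other]
    g1b = [b for b in range(115, 150) if b not in other]
    assert rec.loc["g1", "promoter_score"] == pytest.approx(np.mean(g1p))
    assert rec.loc["g1", "body_score"] == pytest.approx(np.mean(g1b))
    assert "overlap-masked" in rec.loc["g1", "flags"]


def test_minus_strand_windows_are_mirrored():
    scores = np.zeros(400)
    tss = 10_000  # minus-strand gene spanning 3000-10001, TSS at 10000
    gene = _gene("g", "c", "-", 3_000, 10_001)
    # promoter covers genomic (9500, 10500] -> bins 190..210;
    # body covers (7500, 9250] -> bins 150..185
    scores[190:211] = 40.0
    scores[150:186] = 4.0
    rec = fc.promoter_body_scores(_adj(scores), [gene])
    assert rec.loc["g", "promoter_score"] == pytest.approx(40.0)
    assert rec.loc["g", "body_score"] == pytest.approx(4.0)


def test_classification_rules_and_exclusivity():
    rec = pd.DataFrame({
        "promoter_score": [10.0, 60.0, 0.5, 6.0, 8.0, 0.2],
        "body_score": [5.0, 5.0, 0.5, 1.2, 0.0, 3.0],
    }, index=[f"g{i}" for i in range(6)])
    rec["stalling_index"] = np.where(
        rec["body_score"] > 0, rec["promoter_score"] / rec["body_score"], np.inf)
    cls = fc.classify_polii(rec)["class"]
    assert cls["g0"] == "elongating"  # SI = 2
    assert cls["g1"] == "stalled"  # SI = 12
    assert cls["g2"] == "no_polII"
    assert cls["g3"] == "unclassified"  # promoter 6, SI = 5
    assert cls["g4"] == "stalled"  # body 0, promoter high -> SI = +inf
    assert cls["g5"] == "unclassified"  # promoter < 1 but body >= 1
    assert set(cls.unique()) <= {"elongating", "stalled", "no_polII", "unclassified"}


def test_planted_class_recovery_exceeds_95_percent(polii_world, matrix):
    chip = fc.simulate_mark_tags(polii_world, fc.stalled_polii_mark(), 200_000,
                                 seed=71, emit_reads=False)
    mock = fc.simulate_control_tags(polii_world, 200_000, seed=72, emit_reads=False)
    e = fc.score_table(fc.table_from_origins(chip.origins), matrix, "U",
                       polii_world.layout)
    c = fc.score_table(fc.table_from_origins(mock.origins), matrix, "U",
                       polii_world.layout)
    adj = fc.normalize_pair(e, c)
    reported = fc.AdjustedTrack(adj.reported(), adj.bin_size)
    rec = fc.promoter_body_scores(reported, polii_world.genes)
    cls = fc.classify_polii(rec)["class"]
    truth = polii_world.truth["class"].replace({"none": "no_polII"})
    assert (cls == truth).mean() >= 0.95


def test_position_histogram_self_normalizes_to_zero(polii_world):
    mock = fc.simulate_control_tags(polii_world, 50_000, seed=73, emit_reads=False)
    anchors = pd.DataFrame(
        [(g.chrom, g.tss, g.strand) for g in polii_world.genes[:20]],
        columns=["chrom", "pos", "strand"])
    h = fc.position_histogram(mock.origins, mock.origins, anchors)
    assert np.allclose(h.sense, 0.0) and np.allclose(h.antisense, 0.0)
    with pytest.raises(ValueError):
        fc.position_histogram(mock.origins, mock.origins.iloc[:0], anchors)


def test_depth_scaling_leaves_histogram_invariant(polii_world):
    """Doubling the mock library depth does not shift the normalized values."""
    chip = fc.simulate_mark_tags(polii_world, fc.stalled_polii_mark(), 50_000,
                                 seed=74, emit_reads=False)
    mock1 = fc.simulate_control_tags(polii_world, 50_000, seed=75, emit_reads=False)
    mock2 = fc.simulate_control_tags(polii_world, 100_000, seed=76, emit_reads=False)
    gmap = polii_world.genes_by_id()
    stalled = polii_world.truth.index[polii_world.truth["class"] == "stalled"]
    anchors = pd.DataFrame([(gmap[i].chrom, gmap[i].tss, gmap[i].strand)
                            for i in stalled], columns=["chrom", "pos", "strand"])
    h1 = fc.position_histogram(chip.origins, mock1.origins, anchors)
    h2 = fc.position_histogram(chip.origins, mock2.origins, anchors)
    # same modal bin and closely matching values despite 2x mock depth
    assert fc.mode_offset(h1, (0, 200)) == fc.mode_offset(h2, (0, 200))
    scale = np.abs(h1.sense).max()
    assert np.abs(h1.sense - h2.sense).max() < 0.15 * scale


def test_mode_offset_singleton_and_tie_rules():
    labels = np.arange(-1_000, 1_000, 5)
    v = np.zeros(len(labels))
    v[labels == 30] = 4.0  # single nonzero bin [30, 35)
    h = fc.PositionHistogram(5, 1_000, labels, v, np.zeros_like(v), 1)
    assert fc.mode_offset(h, (0, 200)) == 30
    # symmetric tie at -40 and +35: bin [35,40) center 37.5 equals |-40+2.5|;
    # the smaller offset wins
    v2 = np.zeros(len(labels))
    v2[labels == 35] = 2.0
    v2[labels == -40] = 2.0
    h2 = fc.PositionHistogram(5, 1_000, labels, v2, np.zeros_like(v2), 1)
    assert fc.mode_offset(h2, (-200, 200)) == -40
    assert fc.mode_offset(h2, (0, 200)) == 35
    assert fc.mode_offset(h, (500, 600)) is None  # all-zero window


def test_planted_footprints_recovered_at_5bp_resolution(polii_world):
    mock = fc.simulate_control_tags(polii_world, 200_000, seed=77, emit_reads=False)
    gmap = polii_world.genes_by_id()
    for model, klass, planted in [
            (fc.stalled_polii_mark(), "stalled", 35),
            (fc.elongating_polii_mark(), "elongating", 45)]:
        chip = fc.simulate_mark_tags(polii_world, model, 200_000, seed=78,
                                     emit_reads=False)
        ids = polii_world.truth.index[polii_world.truth["class"] == klass]
        anchors = pd.DataFrame([(gmap[i].chrom, gmap[i].tss, gmap[i].strand)
                                for i in ids], columns=["chrom", "pos", "strand"])
        h = fc.position_histogram(chip.origins, mock.origins, anchors)
        assert fc.mode_offset(h, (0, 200)) == planted
        assert fc.mode_offset(h, (0, 200), "antisense") == planted


def test_ks_compare_trivial_and_shifted():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 20, 500)
    d, p = fc.ks_compare(a, a)
    assert d == 0.0 and p == 1.0
    d2, p2 = fc.ks_compare(a, a + 10)
    assert p2 < 0.01
    with pytest.warns(UserWarning):
        fc.ks_compare(a[:3], a[:4])


def test_ks_null_pvalues_roughly_uniform():
    rng = np.random.default_rng(1)
    ps = []
    for _ in range(200):
        ps.append(fc.ks_compare(rng.normal(0, 1, 80), rng.normal(0, 1, 80))[1])
    ps = np.asarray(ps)
    # calibration: mean ~0.5 and no excess of small p-values
    assert 0.4 < ps.mean() < 0.6
    assert (ps < 0.05).mean() < 0.12


def test_junction_profiles_recover_planted_extrema(polii_world):
    model = fc.MarkModel(
        name="polII", background_rate=1.0, body_rate=800.0,
        junction_signals=(fc.JunctionSignal("exon_intron", -90.0, 10.0, 3_000.0),),
        junction_depletions=(fc.JunctionDepletion("intron_exon", -30.0, 15.0, 0.05),))
    chip = fc.simulate_mark_tags(polii_world, model, 200_000, seed=79, emit_reads=False)
    mock = fc.simulate_control_tags(polii_world, 200_000, seed=80, emit_reads=False)
    prof = fc.junction_profiles(chip.origins, mock.origins, polii_world.genes)
    ei = prof["exon_intron"]
    total = ei.sense + ei.antisense
    assert ei.labels[np.argmax(total)] == -90
    ie = prof["intron_exon"]
    trough = ie.labels[np.argmin(ie.sense + ie.antisense)]
    assert -45 <= trough <= -15
    with pytest.raises(ValueError):
        fc.junction_profiles(chip.origins, mock.origins,
                             [_gene("single", "chr1", "+", 1_000, 2_000)])


def test_uniform_model_has_flat_junction_profiles(polii_world):
    chip = fc.simulate_control_tags(polii_world, 100_000, seed=81, emit_reads=False)
    mock = fc.simulate_control_tags(polii_world, 100_000, seed=82, emit_reads=False)
    prof = fc.junction_profiles(chip.origins, mock.origins, polii_world.genes)
    ei = prof["exon_intron"]
    vals = ei.sense + ei.antisense
    # pure noise around zero: no bin stands far outside the fluctuation band
    assert np.abs(vals.mean()) < 3 * vals.std()


def test_slowing_gene_detection(polii_world):
    model = fc.MarkModel(
        name="polII", background_rate=0.2, body_rate=800.0,
        junction_signals=(fc.JunctionSignal("exon_intron", -90.0, 10.0, 5_000.0,
                                            slowing_only=True),))
    chip = fc.simulate_mark_tags(polii_world, model, 200_000, seed=83, emit_reads=False)
    mock = fc.simulate_control_tags(polii_world, 200_000, seed=84, emit_reads=False)
    truth_slow = set(polii_world.truth.index[polii_world.truth["slowing"]])
    eligible = {g.gene_id for g in polii_world.genes
                if max(len(t.exons) for t in g.transcripts) >= 2
                and polii_world.expression[g.gene_id] > 0
                and len(fc.junction_anchor_table([g], "exon_intron", 500))}
    flagged = fc.detect_slowing_genes(chip.origins, mock.origins, polii_world.genes,
                                      tau=2.0)
    assert truth_slow & eligible <= flagged | (truth_slow - eligible)
    recovered = len(flagged & truth_slow) / max(len(truth_slow & eligible), 1)
    false_rate = len(flagged - truth_slow) / max(len(eligible - truth_slow), 1)
    assert recovered >= 0.8
    assert false_rate <= 0.2
    # tau = inf flags nothing
    assert fc.detect_slowing_genes(chip.origins, mock.origins, polii_world.genes,
                                   tau=np.inf) == set()


def test_splice_variant_test_symmetry_and_power():
    rng = np.random.default_rng(2)
    genes = []
    for i in range(300):
        n_tx = 1 + rng.poisson(0.5)
        genes.append(_gene(f"g{i}", "c", "+", 1_000 + 5_000 * i,
                           3_000 + 5_000 * i, n_tx=n_tx))
    ids = [g.gene_id for g in genes]
    same = fc.splice_variant_test(ids[:100], ids[:100], genes)
    assert same["p"] == pytest.approx(1.0, abs=0.05)
    # planted +1 mean variant count in the flagged set
    flagged_genes = [_gene(f"f{i}", "c", "+", 10_000_000 + 5_000 * i,
                           10_002_000 + 5_000 * i, n_tx=2 + rng.poisson(0.5))
                     for i in range(100)]
    res = fc.splice_variant_test([g.gene_id for g in flagged_genes], ids,
                                 genes + flagged_genes)
    assert res["p"] < 0.01
    assert res["flagged_mean"] > res["rest_mean"]
    with pytest.raises(ValueError):
        fc.splice_variant_test(ids[:2], ids, genes)
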