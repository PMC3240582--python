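import numpy as np
import pandas as pd
import pytest

import flychip as fc


@pytest.fixture(scope="session")
def small_world():
    """Compact two-chromosome world with perfect-identity transposon families
    (forces multi-mapping reads)."""
    cfg = fc.WorldConfig(chrom_lengths={"chrA": 150_000, "chrB": 150_000},
                         n_genes=12, n_transposon_families=2, copies_per_family=4,
                         family_identity=1.0, gene_length=(2_000, 5_000))
    return fc.build_world(cfg, seed=11)


@pytest.fixture(scope="session")
def frag_tri():
    return fc.FragmentLengthDist.triangular()


@pytest.fixture(scope="session")
def matrix(frag_tri):
    return fc.build_score_matrix(frag_tri)


@pytest.fixture(scope="session")
def polii_world():
    """Megabase-scale world with strongly separated planted polII classes."""
    cfg = fc.WorldConfig(chrom_lengths={"chr1": 1_000_000, "chr2": 1_000_000},
                         n_genes=60, expression_mu=2.5, expression_sigma=0.3)
    return fc.build_world(cfg, seed=5)


def uniform_track(world, matrix, n_tags, seed, mode="U+M"):
    sim = fc.simulate_control_tags(world, n_tags, seed=seed, emit_reads=False)
    return fc.score_table(fc.table_from_origins(sim.origins), matrix, mode, world.layout)


def constant_track(layout, value, tag_total=10_000_000, mode="U", bin_size=50):
    scores = {c: np.full(fc.n_bins(l, bin_size), float(value)) for c, l in layout.items()}
    return fc.BinTrack(scores, tag_total, mode, bin_size=bin_size, depth_normalized=True)


def track_from_flat(values, mode="U", tag_total=10_000_000, chrom="chrZ", bin_size=50):
    arr = np.asarray(values, dtype=float)
    return fc.BinTrack({chrom: arr}, tag_total, mode, bin_size=bin_size,
                       depth_normalized=True)


@pytest.fixture
def make_uniform_track(matrix):
    def _make(world, n_tags=50_000, seed=0, mode="U+M"):
        return uniform_track(world, matrix, n_tags, seed, mode)
    return _make
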