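"""Coordinate engine and exon-architecture annotation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from m6asupp import (
    TranscriptModel, classify_site, dist_to_nearest_ejc, ejc_density,
    ejc_sites, internal_exon_length_stats, load_gtf, metagene_coordinate,
)
from m6asupp.annotation import (
    NoncodingTranscriptError, TranscriptValidationError,
)
from m6asupp.formats import write_gtf
from m6asupp.simulate import lognormal_quantile

from conftest import make_random_model


# ----------------------------------------------------------------------
# GTF loading and coordinate maps
# ----------------------------------------------------------------------

def _naive_gtf_lengths(path):
    """Independent line-by-line oracle: transcript length = sum of exon
    interval lengths."""
    lengths = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            tid = f[8].split('transcript_id "')[1].split('"')[0]
            lengths[tid] = lengths.get(tid, 0) + int(f[4]) - int(f[3]) + 1
    return lengths


def test_load_gtf_two_exon_plus(tmp_path):
    p = tmp_path / "toy.gtf"
    p.write_text(
        'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        'chr1\tx\texon\t301\t400\t.\t+\t.\tgene_id "g"; transcript_id "t";\n')
    t = load_gtf(str(p))["t"]
    assert t.length == 200
    assert t.junctions == (100,)
    assert t.map_to_genome(0) == 100
    assert t.map_to_genome(100) == 300  # first base after the junction


def test_load_gtf_minus_strand_reversed(tmp_path):
    p = tmp_path / "toy.gtf"
    p.write_text(
        'chr1\tx\texon\t101\t200\t.\t-\t.\tgene_id "g"; transcript_id "t";\n'
        'chr1\tx\texon\t301\t400\t.\t-\t.\tgene_id "g"; transcript_id "t";\n')
    t = load_gtf(str(p))["t"]
    assert t.exons == ((300, 400), (100, 200))
    assert t.map_to_genome(0) == 399
    assert t.map_to_transcript(399) == 0


def test_load_gtf_mixed_strand_rejected(tmp_path):
    p = tmp_path / "bad.gtf"
    p.write_text(
        'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        'chr1\tx\texon\t301\t400\t.\t-\t.\tgene_id "g"; transcript_id "t";\n')
    with pytest.raises(TranscriptValidationError):
        load_gtf(str(p))


def test_gtf_roundtrip_lengths_vs_naive_oracle(tmp_path, rng):
    models = {}
    for i in range(50):
        m = make_random_model(rng, tid=f"T{i}", n_exons=int(rng.integers(1, 6)))
        models[m.transcript_id] = m
    path = tmp_path / "rand.gtf"
    write_gtf(models, path)
    loaded = load_gtf(str(path))
    oracle = _naive_gtf_lengths(path)
    assert set(loaded) == set(models)
    for tid, t in loaded.items():
        assert t.length == oracle[tid] == models[tid].length
        assert t.exons == models[tid].exons
        assert (t.cds_start, t.cds_end) == \
            (models[tid].cds_start, models[tid].cds_end)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_coordinate_roundtrip_identity(seed):
    """inverse(map(pos)) == pos for every position, both strands."""
    m = make_random_model(np.random.default_rng(seed))
    for pos in range(m.length):
        assert m.map_to_transcript(m.map_to_genome(pos)) == pos


def test_map_out_of_range_and_intronic(three_exon):
    with pytest.raises(IndexError):
        three_exon.map_to_genome(600)
    with pytest.raises(IndexError):
        three_exon.map_to_transcript(350)  # intronic


# ----------------------------------------------------------------------
# Site classification
# ----------------------------------------------------------------------

def test_classify_internal_site(three_exon):
    arch = classify_site(three_exon, 250)
    assert arch.exon_class == "internal"
    assert arch.exon_length == 100
    assert arch.dist_3ss == 50
    assert arch.dist_5ss == 49


def test_classify_last_exon_proximal(three_exon):
    arch = classify_site(three_exon, 320)  # 20 nt into the last exon
    assert arch.exon_class == "last"
    assert arch.last_exon_offset == 20
    assert arch.last_exon_proximal is True
    arch_deep = classify_site(three_exon, 300 + 150)
    assert arch_deep.last_exon_proximal is False


def test_exon_class_partition_matches_exon_lengths(rng):
    m = make_random_model(rng, n_exons=5)
    counts = {}
    for pos in range(m.length):
        c = classify_site(m, pos).exon_class
        counts[c] = counts.get(c, 0) + 1
    lens = m.exon_lengths
    assert counts["first"] == lens[0]
    assert counts["last"] == lens[-1]
    assert counts["internal"] == sum(lens[1:-1])


def test_internal_splice_distance_identity(rng):
    m = make_random_model(rng, n_exons=5)
    for pos in range(m.length):
        arch = classify_site(m, pos)
        if arch.exon_class == "internal":
            assert arch.dist_3ss + arch.dist_5ss == arch.exon_length - 1


# ----------------------------------------------------------------------
# Metagene
# ----------------------------------------------------------------------

def test_metagene_boundaries(three_exon):
    assert metagene_coordinate(three_exon, three_exon.cds_start) == 1.0
    assert metagene_coordinate(three_exon, three_exon.cds_end) == 2.0
    assert metagene_coordinate(three_exon, 0) == 0.0


def test_metagene_monotone(three_exon):
    vals = [metagene_coordinate(three_exon, p) for p in range(three_exon.length)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))
    assert all(0 <= v < 3 for v in vals)


def test_metagene_noncoding_rejected():
    t = TranscriptModel("t", "g", "c", "+", ((0, 100),))
    with pytest.raises(NoncodingTranscriptError):
        metagene_coordinate(t, 10)


def test_metagene_segment_occupancy(three_exon, rng):
    """Uniform positions fall into the three segments proportionally to the
    segment lengths (Monte-Carlo)."""
    n = 100_000
    pos = rng.integers(0, three_exon.length, size=n)
    coords = np.array([metagene_coordinate(three_exon, int(p)) for p in pos])
    cs, ce, L = three_exon.cds_start, three_exon.cds_end, three_exon.length
    expected = np.array([cs, ce - cs, L - ce]) / L
    observed = np.array([(coords < 1).mean(),
                         ((coords >= 1) & (coords < 2)).mean(),
                         (coords >= 2).mean()])
    assert np.allclose(observed, expected, atol=0.01)


# ----------------------------------------------------------------------
# EJC geometry
# ----------------------------------------------------------------------

def test_ejc_sites_positions(three_exon):
    assert ejc_sites(three_exon) == [176, 276]  # 200-24, 300-24


def test_ejc_sites_single_exon_empty():
    t = TranscriptModel("t", "g", "c", "+", ((0, 500),))
    assert ejc_sites(t) == []


def test_ejc_sites_clamped_to_short_exon_start():
    # middle exon of length 10: EJC for its 3' junction clamps to its start
    t = TranscriptModel("t", "g", "c", "+", ((0, 100), (200, 210), (300, 400)))
    sites = ejc_sites(t)
    assert sites == [100 - 24, 100]  # second junction at 110, clamped to 100


def test_ejc_sites_count_and_order(rng):
    for _ in range(20):
        m = make_random_model(rng)
        s = ejc_sites(m)
        assert len(s) == m.n_exons - 1
        assert all(b > a for a, b in zip(s, s[1:]))


def test_dist_to_nearest_ejc(three_exon, rng):
    assert dist_to_nearest_ejc(three_exon, 176) == 0
    # brute-force oracle on random models
    for _ in range(10):
        m = make_random_model(rng, n_exons=int(rng.integers(2, 6)))
        sites = ejc_sites(m)
        for pos in rng.integers(0, m.length, size=20):
            expect = min(abs(int(pos) - e) for e in sites)
            assert dist_to_nearest_ejc(m, int(pos)) == expect
    # EJC-free transcript -> absent
    t1 = TranscriptModel("t", "g", "c", "+", ((0, 300),))
    assert dist_to_nearest_ejc(t1, 100) is None


def test_dist_grows_linearly_in_last_exon(three_exon):
    # past the final EJC (at 276), distance increases 1:1 with offset
    d = [dist_to_nearest_ejc(three_exon, p) for p in range(276, 600)]
    assert d == list(range(len(d)))


# ----------------------------------------------------------------------
# EJC density
# ----------------------------------------------------------------------

def test_ejc_density_examples():
    # 5 exons of 400 nt each, CDS spanning the full 2000 nt -> 2.5 /kb
    exons = tuple((i * 500, i * 500 + 400) for i in range(5))
    t = TranscriptModel("t", "g", "c", "+", exons, cds_start=0, cds_end=2000)
    assert ejc_density(t) == pytest.approx(2.5)
    t1 = TranscriptModel("t", "g", "c", "+", ((0, 1000),), cds_start=0,
                         cds_end=1000)
    assert ejc_density(t1) == pytest.approx(1.0)
    with pytest.raises(NoncodingTranscriptError):
        ejc_density(TranscriptModel("t", "g", "c", "+", ((0, 100),)))


def test_ejc_density_vs_bruteforce(rng):
    for _ in range(20):
        m = make_random_model(rng, coding=True, n_exons=int(rng.integers(1, 7)))
        if m.cds_start is None:  # tiny transcript, no room for a CDS
            continue
        cs, ce = m.cds_start, m.cds_end
        n = sum(1 for i in range(m.n_exons)
                if max(m._tstarts[i], cs) <
                min(m._tstarts[i] + m.exon_lengths[i], ce))
        assert ejc_density(m) == pytest.approx(n / ((ce - cs) / 1000))


def test_ejc_density_split_invariance():
    """Splitting an exon at a CDS-internal point changes density by exactly
    +1/(CDS kb)."""
    t = TranscriptModel("t", "g", "c", "+", ((0, 1000),), cds_start=100,
                        cds_end=900)
    split = TranscriptModel("t", "g", "c", "+", ((0, 500), (600, 1100)),
                            cds_start=100, cds_end=900)
    assert ejc_density(split) - ejc_density(t) == pytest.approx(1 / 0.8)


# ----------------------------------------------------------------------
# Internal exon length statistics
# ----------------------------------------------------------------------

def test_internal_exon_median():
    models = [TranscriptModel(f"t{i}", "g", "c", "+",
                              ((0, 10), (100, 100 + ln), (500, 600)))
              for i, ln in enumerate((60, 100, 246))]
    stats = internal_exon_length_stats(models)
    assert stats[50] == pytest.approx(100)


def test_internal_exon_dedup_shared_exon():
    shared = ((0, 10), (100, 250), (500, 600))
    m1 = TranscriptModel("t1", "g", "c", "+", shared)
    m2 = TranscriptModel("t2", "g", "c", "+", shared)
    m3 = TranscriptModel("t3", "g", "c", "+", ((0, 10), (100, 150), (500, 600)))
    stats = internal_exon_length_stats([m1, m2, m3])
    # lengths {150, 50}: the shared 150-nt exon counts once -> median 100
    assert stats[50] == pytest.approx(100)
    with pytest.raises(ValueError):
        internal_exon_length_stats([TranscriptModel("t", "g", "c", "+", ((0, 9),))])


def test_lognormal_p90_p10_matches_closed_form(rng):
    """The p90/p10 ratio of the pure log-normal component matches the
    closed-form quantile ratio within 5% at n=10,000."""
    meanlog, sdlog = np.log(110.0), 0.42
    draws = rng.lognormal(meanlog, sdlog, size=10_000)
    p10, p90 = np.percentile(draws, [10, 90])
    expected = lognormal_quantile(0.9, meanlog, sdlog) / \
        lognormal_quantile(0.1, meanlog, sdlog)
    assert abs((p90 / p10) / expected - 1) < 0.05
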