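"""Deletion/duplication callers, conserved-region algebra and gene overlap."""
from __future__ import annotations

import math

import numpy as np
import pytest

from homeoscan import structvar as sv
from homeoscan.regions import GenomicInterval
from homeoscan.simulate import Gene

from _util import track


def flat(depth, n=3000):
    return track("chr1", np.full(n, depth))


def test_simple_gap_is_called():
    test = track("chr1", np.r_[np.full(700, 25), np.zeros(1500, int),
                               np.full(800, 25)])
    ctrl = flat(25)
    regions = sv.detect_deletions(test, ctrl, scale=1.0)
    assert [str(r.interval) for r in regions] == ["chr1:700-2200"]
    assert regions[0].max_test_depth < 3


def test_short_gap_rejected():
    test = track("chr1", np.r_[np.full(1000, 25), np.zeros(900, int),
                               np.full(1100, 25)])
    assert sv.detect_deletions(test, flat(25), scale=1.0) == []


def test_interior_high_base_splits_run():
    """A single base at the test threshold splits the run; both halves are
    re-tested independently."""
    depth = np.r_[np.full(400, 25), np.zeros(2401, int), np.full(199, 25)]
    depth[400 + 1200] = 3  # not < 3: breaks the run
    test = track("chr1", depth)
    regions = sv.detect_deletions(test, flat(25), scale=1.0)
    assert [(r.interval.start, r.interval.end) for r in regions] == \
        [(400, 1600), (1601, 2801)]


def test_control_endpoint_rule():
    test = track("chr1", np.r_[np.full(700, 25), np.zeros(1500, int),
                               np.full(800, 25)])
    ctrl_depth = np.full(3000, 25)
    ctrl_depth[700] = 19  # first base of the run fails the control bound
    assert sv.detect_deletions(test, track("chr1", ctrl_depth),
                               scale=1.0) == []


def test_control_interior_checkpoint_rule():
    """Control depth >= 20 at both ends is not enough: an interior point at
    least 200 bp from either end must also reach the bound."""
    test = track("chr1", np.r_[np.full(700, 25), np.zeros(1500, int),
                               np.full(800, 25)])
    ctrl_depth = np.full(3000, 25)
    ctrl_depth[900:2000] = 19  # whole interior window below the bound
    assert sv.detect_deletions(test, track("chr1", ctrl_depth),
                               scale=1.0) == []
    ctrl_depth[1500] = 20  # a single qualifying interior point rescues it
    assert len(sv.detect_deletions(test, track("chr1", ctrl_depth),
                                   scale=1.0)) == 1


def test_normalization_precedes_thresholds():
    """A test library half the control size has its depths doubled before
    the < 3 rule: raw depth 2 becomes 4 and is no longer 'near zero'."""
    t = track("chr1", np.r_[np.full(700, 12), np.full(1500, 2),
                            np.full(800, 12)], library_size=500)
    c = flat(25)
    c = track("chr1", c.depth, library_size=1000)
    assert sv.detect_deletions(t, c) == []


def test_duplication_peak_on_doubled_coverage():
    depth = np.full(20000, 40)
    depth[8000:10000] = 80
    test = track("chr1", depth)
    peaks = sv.detect_duplications(test, flat(40, 20000), scale=1.0)
    assert len(peaks) == 1
    iv = peaks[0].interval
    assert abs(iv.start - 8000) <= 200 and abs(iv.end - 10000) <= 200
    assert peaks[0].fold_enrichment == pytest.approx(2.0, abs=0.05)


def test_no_peaks_when_test_equals_control():
    assert sv.detect_duplications(flat(40, 20000), flat(40, 20000),
                                  scale=1.0) == []


def test_peak_p_value_equals_direct_poisson_tail():
    """Window with read-equivalent count 160 against lambda 80: the p-value
    is the directly summed Poisson upper tail."""
    depth = np.full(20000, 40)
    depth[1000:1200] = 80
    test = track("chr1", depth)
    peaks = sv.detect_duplications(test, flat(40, 20000), scale=1.0)
    assert len(peaks) == 1
    lam, k = 80.0, 160
    # oracle: direct pmf summation, P[Pois(80) >= 160]
    logpmf = [-lam + i * math.log(lam) - math.lgamma(i + 1)
              for i in range(k, 600)]
    tail = math.fsum(math.exp(x) for x in logpmf)
    assert peaks[0].p_value == pytest.approx(tail, rel=1e-9)


def test_window_larger_than_chromosome_raises():
    with pytest.raises(ValueError):
        sv.detect_duplications(flat(40, 100), flat(40, 100), window=500,
                               scale=1.0)


def test_conserved_region_intersection_examples():
    sets = {"a1": [GenomicInterval("chr1", 100, 400)],
            "a2": [GenomicInterval("chr1", 200, 600)]}
    out = sv.conserved_regions(sets, ["a1", "a2"], [], min_len=50)
    assert [(iv.start, iv.end) for iv in out] == [(200, 400)]
    sets["d1"] = [GenomicInterval("chr1", 150, 500)]
    assert sv.conserved_regions(sets, ["a1", "a2"], ["d1"], min_len=50) == []


def test_conserved_regions_match_per_base_oracle():
    rng = np.random.default_rng(4)
    L = 10_000
    sets = {}
    for acc in ("a1", "a2", "a3", "d1"):
        ivs = []
        for _ in range(20):
            s = int(rng.integers(0, L - 500))
            ivs.append(GenomicInterval("chr1", s, s + int(rng.integers(50, 500))))
        sets[acc] = ivs
    req, exc = ["a1", "a2", "a3"], ["d1"]
    got = sv.conserved_regions(sets, req, exc, min_len=100)
    # oracle: per-base boolean evaluation
    bits = np.ones(L, dtype=bool)
    for a in req:
        b = np.zeros(L, dtype=bool)
        for iv in sets[a]:
            b[iv.start:iv.end] = True
        bits &= b
    for iv in sets["d1"]:
        bits[iv.start:iv.end] = False
    expected = []
    padded = np.concatenate(([False], bits, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s >= 100:
            expected.append((int(s), int(e)))
    assert [(iv.start, iv.end) for iv in got] == expected
    # order invariance
    got2 = sv.conserved_regions(sets, req[::-1], exc, min_len=100)
    assert got == got2


def _gene(gid, start, end):
    return Gene(gid, "chr1", start, end, "+", ((start, end),))


def test_gene_overlap_boundary_is_inclusive():
    genes = [_gene("g1", 1000, 2000)]
    half = [GenomicInterval("chr1", 1000, 1500)]
    assert len(sv.gene_overlap(half, genes)) == 1
    just_under = [GenomicInterval("chr1", 1000, 1499)]
    assert sv.gene_overlap(just_under, genes) == []


def test_gene_overlap_complete_flag():
    genes = [_gene("g1", 1000, 2000)]
    spanning = [GenomicInterval("chr1", 900, 2100)]
    out = sv.gene_overlap(spanning, genes)
    assert out[0].complete and out[0].overlap_fraction == 1.0
    # full coverage from two abutting pieces is not 'complete'
    pieces = [GenomicInterval("chr1", 900, 1500),
              GenomicInterval("chr1", 1500, 2100)]
    out = sv.gene_overlap(pieces, genes)
    assert out[0].overlap_fraction == 1.0 and not out[0].complete


# ---------------------------------------------------------------------------
# recovery on the simulated cohort


def test_planted_deletions_recovered_with_tight_breakpoints(
        cohort, sim_cfg, diploid_coverage):
    """Every planted group-conserved deletion is recovered in every A
    accession with breakpoint error <= read length, and the conserved
    intersection reproduces the planted set."""
    control = diploid_coverage["D1"]
    del_sets = {}
    for acc in ("A1", "A2"):
        ivs = []
        for chrom in cohort.reference.chroms:
            ivs += [r.interval for r in sv.detect_deletions(
                diploid_coverage[acc][chrom], control[chrom], accession=acc)]
        del_sets[acc] = ivs
        for planted in cohort.truth.conserved_deletions:
            hits = [iv for iv in ivs if iv.overlaps(planted)]
            assert len(hits) == 1
            assert abs(hits[0].start - planted.start) <= sim_cfg.read_length
            assert abs(hits[0].end - planted.end) <= sim_cfg.read_length
    conserved = sv.conserved_regions(del_sets, ["A1", "A2"], [], min_len=1000)
    assert len(conserved) == len(cohort.truth.conserved_deletions)


def test_no_deletions_called_on_unperturbed_genome(cohort, diploid_coverage):
    """Specificity: the second D accession (no planted events) yields zero
    calls against the D control."""
    for chrom in cohort.reference.chroms:
        calls = sv.detect_deletions(diploid_coverage["D2"][chrom],
                                    diploid_coverage["D1"][chrom])
        assert calls == []


def test_planted_duplications_recovered_with_twofold_enrichment(
        cohort, diploid_coverage):
    control = diploid_coverage["D1"]
    peaks = []
    for chrom in cohort.reference.chroms:
        peaks += sv.detect_duplications(diploid_coverage["A1"][chrom],
                                        control[chrom])
    for planted in cohort.truth.conserved_duplications:
        hits = [p for p in peaks if p.interval.overlaps(planted)]
        assert hits, f"planted duplication {planted} not recovered"
        covered = sum(min(p.interval.end, planted.end)
                      - max(p.interval.start, planted.start) for p in hits)
        assert covered / planted.length > 0.8
        for p in hits:
            assert p.fold_enrichment == pytest.approx(2.0, abs=0.3)
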