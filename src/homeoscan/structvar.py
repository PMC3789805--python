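"""Coverage-based structural variation: deletions, duplications, overlap.

Deletion calling follows the coverage-gap rule: a maximal run of near-zero
test coverage (normalized depth < 3 at every base) at least 1000 bp long,
where the control sample has depth >= 20 at the run's first and last base
and at >= 1 interior base at least 200 bp from both ends.  Library-size
normalization is applied to the test track before thresholding, so the
thresholds compare possibly fractional depths (strict ``<`` for the test
bound, ``>=`` for the control bound).

Duplication calling is a deliberately simplified control-vs-test Poisson
peak caller: fixed windows, a local rate taken as the maximum of the
genome-wide control rate and two surrounding background scales, an
upper-tail Poisson p-value per window, and merging of adjacent significant
windows.  It makes no attempt at fragment-size model building — read-level
shifting is meaningless for WGS coverage.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .pileup import CoverageTrack, normalize_track
from .regions import GenomicInterval, merge_intervals
from .simulate import Gene


@dataclass
class DeletionRegion:
    interval: GenomicInterval
    accession: str
    control_depth_start: float
    control_depth_end: float
    max_test_depth: float


@dataclass
class DuplicationPeak:
    interval: GenomicInterval
    fold_enrichment: float
    p_value: float


@dataclass
class GeneOverlap:
    gene_id: str
    interval: GenomicInterval  # the gene span
    overlap_fraction: float
    complete: bool  # one single interval spans the whole gene


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as half-open (start, end)."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def detect_deletions(test: CoverageTrack, control: CoverageTrack,
                     min_len: int = 1000, control_min: float = 20.0,
                     test_lt: float = 3.0, interior_offset: int = 200,
                     accession: str = "", scale: float | None = None
                     ) -> list[DeletionRegion]:
    """Coverage-gap deletion calls on one chromosome (see module docstring)."""
    if len(test) != len(control):
        raise ValueError("test and control tracks differ in length")
    if scale is None:
        scale = normalize_track(test, control)
    tdepth = test.depth * scale
    cdepth = control.depth
    out: list[DeletionRegion] = []
    for s, e in _runs(tdepth < test_lt):
        if e - s < min_len:
            continue
        if cdepth[s] < control_min or cdepth[e - 1] < control_min:
            continue
        lo, hi = s + interior_offset, e - interior_offset  # half-open interior
        if lo >= hi or not np.any(cdepth[lo:hi] >= control_min):
            continue
        out.append(DeletionRegion(
            GenomicInterval(test.chrom, s, e), accession,
            float(cdepth[s]), float(cdepth[e - 1]),
            float(tdepth[s:e].max())))
    return out


def _window_sums(depth: np.ndarray, window: int) -> np.ndarray:
    nwin = len(depth) // window
    return depth[:nwin * window].reshape(nwin, window).sum(axis=1)


def _background_rate(cdepth: np.ndarray, centers: np.ndarray,
                     span: int) -> np.ndarray:
    """Mean control depth in a span-bp window centered per test window."""
    csum = np.concatenate(([0], np.cumsum(cdepth, dtype=np.float64)))
    lo = np.clip(centers - span // 2, 0, len(cdepth))
    hi = np.clip(centers + span // 2, 0, len(cdepth))
    width = np.maximum(hi - lo, 1)
    return (csum[hi] - csum[lo]) / width


def detect_duplications(test: CoverageTrack, control: CoverageTrack,
                        window: int = 200,
                        local_bg_windows: tuple[int, int] = (1000, 10000),
                        p_threshold: float = 1e-5, min_fold: float = 1.5,
                        read_length: int = 100,
                        scale: float | None = None) -> list[DuplicationPeak]:
    """Poisson peak calling of test-over-control coverage enrichment.

    Per fixed window the local rate is the max of the genome-wide control
    rate and the control rate in the surrounding background windows, scaled
    to the window; observed and expected coverage sums are converted to
    read-equivalent counts (divided by ``read_length``) before the Poisson
    upper tail is evaluated.
    """
    if len(test) != len(control):
        raise ValueError("test and control tracks differ in length")
    if window > len(test):
        raise ValueError("window larger than chromosome")
    if scale is None:
        scale = normalize_track(test, control)
    tdepth = test.depth * scale
    cdepth = control.depth.astype(np.float64)
    nwin = len(test) // window
    if nwin == 0:
        return []
    tsum = _window_sums(tdepth, window)
    genome_rate = cdepth.mean()
    centers = (np.arange(nwin) * window + window // 2)
    rate = np.full(nwin, genome_rate)
    for span in local_bg_windows:
        rate = np.maximum(rate, _background_rate(cdepth, centers, span))
    lam = rate * window / read_length
    k = np.floor(tsum / read_length).astype(np.int64)
    pvals = sps.poisson.sf(k - 1, lam)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(lam > 0, (tsum / read_length) / lam, np.inf)
    signif = (pvals < p_threshold) & (fold >= min_fold)
    peaks: list[DuplicationPeak] = []
    for ws, we in _runs(signif):
        tot_obs = tsum[ws:we].sum() / read_length
        tot_exp = lam[ws:we].sum()
        peaks.append(DuplicationPeak(
            GenomicInterval(test.chrom, ws * window, we * window),
            float(tot_obs / tot_exp) if tot_exp > 0 else float("inf"),
            float(pvals[ws:we].min())))
    return peaks


def conserved_regions(interval_sets: dict[str, list[GenomicInterval]],
                      required_group: list[str], excluded_group: list[str],
                      min_len: int = 1000) -> list[GenomicInterval]:
    """Base-level intersection over all required accessions minus the union
    of excluded accessions, re-segmented into maximal intervals of length
    >= ``min_len``.  Order-invariant in the accession lists."""
    if not required_group:
        raise ValueError("need at least one required accession")
    req = {a: merge_intervals([iv for iv in interval_sets.get(a, [])])
           for a in required_group}
    exc = merge_intervals([iv for a in excluded_group
                           for iv in interval_sets.get(a, [])])
    chroms = sorted({iv.chrom for ivs in req.values() for iv in ivs})
    out: list[GenomicInterval] = []
    for chrom in chroms:
        # breakpoint sweep: evaluate membership on elementary segments
        bps: set[int] = set()
        per_acc = {}
        for a in required_group:
            ivs = [iv for iv in req[a] if iv.chrom == chrom]
            per_acc[a] = ivs
            for iv in ivs:
                bps.update((iv.start, iv.end))
        exc_ivs = [iv for iv in exc if iv.chrom == chrom]
        for iv in exc_ivs:
            bps.update((iv.start, iv.end))
        cuts = sorted(bps)
        if len(cuts) < 2:
            continue

        def _covered(ivs, p):
            starts = [iv.start for iv in ivs]
            import bisect
            i = bisect.bisect_right(starts, p) - 1
            return i >= 0 and ivs[i].end > p

        seg_keep = []
        for s, e in zip(cuts[:-1], cuts[1:]):
            inside = all(_covered(per_acc[a], s) for a in required_group)
            if inside and not _covered(exc_ivs, s):
                seg_keep.append(GenomicInterval(chrom, s, e))
        out.extend(iv for iv in merge_intervals(seg_keep) if iv.length >= min_len)
    return sorted(out)


def gene_overlap(intervals: list[GenomicInterval], genes: list[Gene],
                 min_frac: float = 0.5) -> list[GeneOverlap]:
    """Per gene, the fraction of its length covered by the interval union;
    reported when >= ``min_frac`` (inclusive).  ``complete`` marks genes
    spanned end-to-end by one single interval."""
    merged = merge_intervals(intervals)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    raw_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        raw_by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GeneOverlap] = []
    for g in genes:
        cov = 0
        for iv in by_chrom.get(g.chrom, []):
            cov += max(0, min(iv.end, g.end) - max(iv.start, g.start))
        frac = cov / g.length
        if frac < min_frac:
            continue
        complete = any(iv.start <= g.start and g.end <= iv.end
                       for iv in raw_by_chrom.get(g.chrom, []))
        out.append(GeneOverlap(g.gene_id, g.interval, frac, complete))
    return out


def write_bed(intervals: list[GenomicInterval], path: str,
              names: list[str] | None = None) -> None:
    """0-based half-open BED."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"region{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
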