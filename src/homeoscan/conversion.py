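"""Nonreciprocal homoeologous conversion detection in the tetraploid.

Method 1 works site by site on the SNP index: at an index site (a, d), both
subgenome genotypes carrying the A allele marks an A_T-biased conversion
(the D_T copy was overwritten), both carrying the D allele a D_T-biased
one.  The reciprocal single-swap pattern (A_T hom d while D_T hom a) is a
categorization artifact, flagged ``double_swap`` without a direction; any
third allele is flagged ``novel_allele``.  Note the direction requires BOTH
subgenomes homogenized — a converted tract makes the two copies identical.

Method 2 works on categorized-coverage with coverage-gap (deletion-caller)
semantics at relaxed thresholds: inside the presence mask (bases covered in
both diploid genome groups), a maximal run of >= 1 kbp where one
subgenome's depth is < 4 at every base, trimmed to the span delimited by
the other subgenome reaching >= 15 (its first and last such base), with
>= 1 further interior point >= 200 bp from both ends at >= 15, is called a
conversion toward the high subgenome (duplicated there, deleted in the
other).  The high-side bound is not a per-base requirement: categorized
coverage legitimately dips wherever a read span contains no diagnostic
site, and decays across tract boundaries.

Method 1 is confounded by autapomorphic substitutions in the diploids — a
genotype pattern identical to conversion arises with no conversion at all —
which is why the cross-tabulation against method-2 regions matters.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import BASES
from .homoeosnp import GenotypeArray, SnpIndex
from .pileup import CoverageTrack
from .regions import GenomicInterval
from .simulate import AT_BIASED, DT_BIASED

CLEAN = "clean"
DOUBLE_SWAP = "double_swap"
NOVEL_ALLELE = "novel_allele"


@dataclass
class SnpConversionCall:
    chrom: str
    pos: int
    direction: str | None  # AT_biased / DT_biased; None when flagged
    at_call: str
    dt_call: str
    flag: str


@dataclass
class ConversionRegion:
    interval: GenomicInterval
    direction: str
    mean_high_depth: float
    mean_low_depth: float
    n_index_snps_contained: int = 0


def detect_snp_conversions(index: SnpIndex,
                           at_genotypes: dict[str, GenotypeArray],
                           dt_genotypes: dict[str, GenotypeArray],
                           ) -> list[SnpConversionCall]:
    """Method 1: homoeo-SNP genotype patterns in the two subgenomes.

    Only homozygous calls in both subgenomes produce output; missing or
    heterozygous calls give no call at that site.
    """
    out: list[SnpConversionCall] = []
    for chrom, (pos, aa, dd) in index.data.items():
        at = at_genotypes[chrom]
        dt = dt_genotypes[chrom]
        at1 = at.a1[pos]
        dt1 = dt.a1[pos]
        both_hom = (at.is_hom[pos]) & (dt.is_hom[pos])
        novel = both_hom & (((at1 != aa) & (at1 != dd))
                            | ((dt1 != aa) & (dt1 != dd)))
        at_bias = both_hom & ~novel & (at1 == aa) & (dt1 == aa)
        dt_bias = both_hom & ~novel & (at1 == dd) & (dt1 == dd)
        swap = both_hom & ~novel & (at1 == dd) & (dt1 == aa)
        for sel, direction, flag in ((at_bias, AT_BIASED, CLEAN),
                                     (dt_bias, DT_BIASED, CLEAN),
                                     (swap, None, DOUBLE_SWAP),
                                     (novel, None, NOVEL_ALLELE)):
            for i in np.flatnonzero(sel):
                out.append(SnpConversionCall(
                    chrom, int(pos[i]), direction,
                    BASES[at1[i]], BASES[dt1[i]], flag))
    out.sort(key=lambda c: (c.chrom, c.pos))
    return out


def presence_mask(coverage_by_accession: dict[str, CoverageTrack],
                  min_depth: float = 1.0) -> np.ndarray:
    """Bases where every diploid accession has depth >= ``min_depth`` — the
    only territory where homoeo-SNPs and conversion calls are defined."""
    tracks = list(coverage_by_accession.values())
    if not tracks:
        raise ValueError("no coverage tracks supplied")
    mask = np.ones(len(tracks[0]), dtype=bool)
    for t in tracks:
        if len(t) != len(mask):
            raise ValueError("coverage tracks differ in length")
        mask &= t.depth >= min_depth
    return mask


def detect_coverage_conversions(at_track: CoverageTrack,
                                dt_track: CoverageTrack,
                                mask: np.ndarray,
                                min_len: int = 1000,
                                high_min: float = 15.0,
                                low_lt: float = 4.0,
                                interior_offset: int = 200,
                                at_scale: float = 1.0,
                                dt_scale: float = 1.0,
                                ) -> list[ConversionRegion]:
    """Method 2: reciprocal coverage gain/loss in the categorized tracks
    (see module docstring for the run/endpoint rules)."""
    from .structvar import _runs

    if len(at_track) != len(dt_track) or len(mask) != len(at_track):
        raise ValueError("mask/track length mismatch")
    at = at_track.depth * at_scale
    dt = dt_track.depth * dt_scale
    out: list[ConversionRegion] = []
    for high, low, direction in ((at, dt, AT_BIASED), (dt, at, DT_BIASED)):
        for s, e in _runs(mask & (low < low_lt)):
            if e - s < min_len:
                continue
            # categorized coverage decays across a tract boundary (boundary-
            # spanning reads vote with their majority side), so trim the run
            # to the span actually delimited by confident high-side coverage
            hi_idx = np.flatnonzero(high[s:e] >= high_min) + s
            if len(hi_idx) == 0:
                continue
            s2, e2 = int(hi_idx[0]), int(hi_idx[-1]) + 1
            if e2 - s2 < min_len:
                continue
            lo_b, hi_b = s2 + interior_offset, e2 - interior_offset
            if lo_b >= hi_b or not np.any(high[lo_b:hi_b] >= high_min):
                continue
            out.append(ConversionRegion(
                GenomicInterval(at_track.chrom, s2, e2), direction,
                float(high[s2:e2].mean()), float(low[s2:e2].mean())))
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return out


@dataclass
class CrosstabSummary:
    per_region: list[tuple[ConversionRegion, int, int, int]]
    total_index_snps_in_regions: int
    total_still_homoeo_in_tetraploid: int
    total_method1_calls_in_regions: int


def crosstab_methods(snp_calls: list[SnpConversionCall],
                     regions: list[ConversionRegion],
                     index: SnpIndex,
                     tetraploid_index: SnpIndex | None = None
                     ) -> CrosstabSummary:
    """Cross-tabulate the two detectors per method-2 region.

    For each region: the number of diploid index sites it contains, how many
    of those are still segregating as homoeo-SNPs between the tetraploid
    subgenomes (homogenized tracts should contain none), and how many
    method-1 calls fall inside.
    """
    call_pos: dict[str, np.ndarray] = {}
    for c in snp_calls:
        call_pos.setdefault(c.chrom, [])
    for c in snp_calls:
        call_pos[c.chrom].append(c.pos)
    call_pos = {c: np.sort(np.asarray(p, dtype=np.int64))
                for c, p in call_pos.items()}
    per_region = []
    tot_idx = tot_tet = tot_m1 = 0
    for r in regions:
        iv = r.interval
        pos, _, _ = index.chrom(iv.chrom)
        n_idx = int(np.searchsorted(pos, iv.end) - np.searchsorted(pos, iv.start))
        n_tet = 0
        if tetraploid_index is not None:
            tpos, _, _ = tetraploid_index.chrom(iv.chrom)
            n_tet = int(np.searchsorted(tpos, iv.end)
                        - np.searchsorted(tpos, iv.start))
        cp = call_pos.get(iv.chrom, np.empty(0, dtype=np.int64))
        n_m1 = int(np.searchsorted(cp, iv.end) - np.searchsorted(cp, iv.start))
        r.n_index_snps_contained = n_idx
        per_region.append((r, n_idx, n_tet, n_m1))
        tot_idx += n_idx
        tot_tet += n_tet
        tot_m1 += n_m1
    return CrosstabSummary(per_region, tot_idx, tot_tet, tot_m1)


def write_regions_tsv(regions: list[ConversionRegion], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart0\tend0\tdirection\tmean_high\tmean_low\t"
                 "n_index_snps\n")
        for r in regions:
            iv = r.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.direction}\t"
                     f"{r.mean_high_depth:.2f}\t{r.mean_low_depth:.2f}\t"
                     f"{r.n_index_snps_contained}\n")
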