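"""Per-base allele counts and coverage from alignments.

Two input routes share one result type: a CIGAR-aware walker over SAM/BAM
records (via pysam) for real alignment files, and a vectorized fast path for
the generator's gapless :class:`~homeoscan.simulate.ReadSet` objects.  All
callers downstream consume the :class:`PileupTable` / :class:`CoverageTrack`
produced here.

Rules: allele counts include only M/=/X-aligned A/C/G/T bases; coverage
counts every reference-consuming op (M/=/X/D); unmapped and secondary
records are skipped.  No mapping- or base-quality filter is applied by
default (``min_mapq`` exists but defaults to 0), and duplicates are kept.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from ._seq import encode


class PileupError(ValueError):
    pass


@dataclass
class AlleleCounts:
    """Counts of the four bases at one position (0-based internally)."""

    chrom: str
    pos: int
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


class PileupTable:
    """Allele counts for a whole chromosome as a (4, L) matrix."""

    def __init__(self, chrom: str, counts: np.ndarray):
        if counts.shape[0] != 4:
            raise PileupError("counts matrix must have 4 base rows")
        self.chrom = chrom
        self.counts = counts

    def __len__(self) -> int:
        return self.counts.shape[1]

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def at(self, pos: int) -> AlleleCounts:
        col = self.counts[:, pos]
        return AlleleCounts(self.chrom, pos,
                            {b: int(col[i]) for i, b in enumerate("ACGT")})


@dataclass
class CoverageTrack:
    """Read depth per reference base; ``library_size`` is the library's total
    aligned (reference-consuming) bases, shared by all chromosomes."""

    chrom: str
    depth: np.ndarray
    library_size: int

    def __len__(self) -> int:
        return len(self.depth)


# ---------------------------------------------------------------------------
# SAM/BAM route

_REF_CONSUMING_COVER = {0, 2, 7, 8}  # M, D, =, X
_ALIGNED_OPS = {0, 7, 8}             # M, =, X


def _iter_records(alignments, min_mapq: int = 0):
    """Yield usable pysam records from a path or an open iterable."""
    if isinstance(alignments, (str, bytes)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            yield from _iter_records(fh, min_mapq)
        return
    for rec in alignments:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.mapping_quality < min_mapq:
            continue
        yield rec


def _check_cigar(rec) -> None:
    qlen = sum(n for op, n in rec.cigartuples or []
               if op in (0, 1, 4, 7, 8))  # query-consuming ops
    if rec.query_sequence is not None and qlen != len(rec.query_sequence):
        raise PileupError(
            f"CIGAR consumes {qlen} query bases but sequence of "
            f"{rec.query_name!r} has {len(rec.query_sequence)}")


def build_pileup(alignments, reference_lengths: dict[str, int],
                 min_mapq: int = 0) -> dict[str, PileupTable]:
    """Allele counts per position from SAM/BAM records.

    ``alignments`` may be a path or an iterable of pysam records.  Bases
    aligned through M/=/X are counted; deletions contribute nothing; non-ACGT
    bases are ignored.
    """
    mats = {c: np.zeros((4, L), dtype=np.int32)
            for c, L in reference_lengths.items()}
    for rec in _iter_records(alignments, min_mapq):
        chrom = rec.reference_name
        if chrom not in mats:
            raise PileupError(f"chromosome {chrom!r} absent from reference")
        _check_cigar(rec)
        codes = encode(rec.query_sequence)
        mat = mats[chrom]
        qpos = 0
        rpos = rec.reference_start
        for op, n in rec.cigartuples:
            if op in _ALIGNED_OPS:
                b = codes[qpos:qpos + n]
                r = np.arange(rpos, rpos + n)
                keep = b < 4
                np.add.at(mat, (b[keep], r[keep]), 1)
                qpos += n
                rpos += n
            elif op in (1, 4):   # I, S consume query only
                qpos += n
            elif op in (2, 3):   # D, N consume reference only
                rpos += n
    return {c: PileupTable(c, m) for c, m in mats.items()}


def build_coverage(alignments, reference_lengths: dict[str, int],
                   min_mapq: int = 0) -> dict[str, CoverageTrack]:
    """Per-base read depth; a base is covered by M/=/X/D ops."""
    diffs = {c: np.zeros(L + 1, dtype=np.int64)
             for c, L in reference_lengths.items()}
    aligned_bases = 0
    for rec in _iter_records(alignments, min_mapq):
        chrom = rec.reference_name
        if chrom not in diffs:
            raise PileupError(f"chromosome {chrom!r} absent from reference")
        diff = diffs[chrom]
        rpos = rec.reference_start
        for op, n in rec.cigartuples:
            if op in _REF_CONSUMING_COVER:
                diff[rpos] += 1
                diff[rpos + n] -= 1
                rpos += n
                if op != 2:
                    aligned_bases += n
            elif op == 3:
                rpos += n
    return {c: CoverageTrack(c, np.cumsum(d[:-1]).astype(np.int32),
                             aligned_bases)
            for c, d in diffs.items()}


# ---------------------------------------------------------------------------
# fast path for simulated gapless reads

_CHUNK = 262144


def pileup_readset(rs, reference_lengths: dict[str, int]
                   ) -> dict[str, PileupTable]:
    """Vectorized pileup of a gapless fixed-length ReadSet."""
    chroms = list(reference_lengths)
    mats = {}
    rl = rs.read_length
    offs = np.arange(rl, dtype=np.int64)
    for ci, chrom in enumerate(rs.chroms):
        L = reference_lengths[chrom]
        flat = np.zeros(4 * L, dtype=np.int64)
        sel = np.flatnonzero(rs.chrom_idx == ci)
        for lo in range(0, len(sel), _CHUNK):
            idx = sel[lo:lo + _CHUNK]
            pos = rs.ref_start[idx, None] + offs
            base = rs.seqs[idx].astype(np.int64)
            flat += np.bincount((base * L + pos).ravel(), minlength=4 * L)
        mats[chrom] = PileupTable(chrom, flat.reshape(4, L).astype(np.int32))
    for chrom in chroms:
        if chrom not in mats:
            mats[chrom] = PileupTable(
                chrom, np.zeros((4, reference_lengths[chrom]), dtype=np.int32))
    return mats


def coverage_readset(rs, reference_lengths: dict[str, int]
                     ) -> dict[str, CoverageTrack]:
    """Vectorized coverage of a gapless fixed-length ReadSet."""
    rl = rs.read_length
    mapped = rs.chrom_idx >= 0
    library_size = int(mapped.sum()) * rl
    tracks = {}
    for ci, chrom in enumerate(rs.chroms):
        L = reference_lengths[chrom]
        starts = rs.ref_start[(rs.chrom_idx == ci)]
        diff = np.zeros(L + 1, dtype=np.int64)
        np.add.at(diff, starts, 1)
        np.add.at(diff, starts + rl, -1)
        tracks[chrom] = CoverageTrack(chrom, np.cumsum(diff[:-1]).astype(np.int32),
                                      library_size)
    for chrom in reference_lengths:
        if chrom not in tracks:
            tracks[chrom] = CoverageTrack(
                chrom, np.zeros(reference_lengths[chrom], dtype=np.int32),
                library_size)
    return tracks


def normalize_track(test: CoverageTrack, control: CoverageTrack) -> float:
    """Scale factor equalizing library sizes: control size / test size."""
    if test.library_size == 0 or control.library_size == 0:
        raise PileupError("cannot normalize a zero-size library")
    return control.library_size / test.library_size
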