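"""Small builders shared by the unit tests."""
from __future__ import annotations

import numpy as np
import pysam

from homeoscan.homoeosnp import GenotypeArray
from homeoscan.pileup import CoverageTrack


def write_sam(path, lengths: dict[str, int], records) -> str:
    """records: (qname, chrom, pos0, cigar, seq, flag); chrom None = unmapped."""
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": c, "LN": L} for c, L in lengths.items()],
    })
    chroms = list(lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for qname, chrom, pos, cigar, seq, flag in records:
            a = pysam.AlignedSegment(header)
            a.query_name = qname
            a.query_sequence = seq
            a.flag = flag
            if flag & 4 or chrom is None:
                a.reference_id = -1
                a.reference_start = -1
            else:
                a.reference_id = chroms.index(chrom)
                a.reference_start = pos
                a.cigarstring = cigar
                a.mapping_quality = 60
            fh.write(a)
    return str(path)


def genotype_array(chrom: str, length: int,
                   calls: dict[int, tuple[int, int]]) -> GenotypeArray:
    """GenotypeArray with nocall everywhere except the given positions."""
    a1 = np.full(length, -1, dtype=np.int8)
    a2 = np.full(length, -1, dtype=np.int8)
    depth = np.zeros(length, dtype=np.int64)
    for pos, (x, y) in calls.items():
        a1[pos], a2[pos] = x, y
        depth[pos] = 20
    return GenotypeArray(chrom, a1, a2, depth)


def track(chrom: str, depth, library_size: int | None = None) -> CoverageTrack:
    depth = np.asarray(depth, dtype=np.int32)
    if library_size is None:
        library_size = int(depth.sum())
    return CoverageTrack(chrom, depth, library_size)
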