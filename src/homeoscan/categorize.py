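"""Assignment of aligned reads to the A or D (sub)genome via the SNP index.

Each read votes once per index site its alignment covers with an aligned
base: the A allele votes A, the D allele votes D, any other base does not
vote.  The majority decides; a read covering no index site is
``uncat_no_snp``; ties — including reads whose only covering bases are
third alleles — are ``uncat_conflict`` rather than being broken.  Votes are
unweighted and come only from M/=/X-aligned bases.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pysam

from ._seq import encode
from .homoeosnp import SnpIndex

CAT_A = "A"
CAT_D = "D"
UNCAT_NO_SNP = "uncat_no_snp"
UNCAT_CONFLICT = "uncat_conflict"
CATEGORIES = (CAT_A, CAT_D, UNCAT_NO_SNP, UNCAT_CONFLICT)


@dataclass
class CategorizedRead:
    read_id: str
    category: str
    n_index_sites_overlapped: int
    votes_a: int
    votes_d: int


@dataclass
class CategorizationStats:
    """Partition fractions, plus a truth-based error rate when available."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in CATEGORIES})
    error_rate: float | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        return {c: (n / t if t else 0.0) for c, n in self.counts.items()}

    @property
    def n_categorized(self) -> int:
        return self.counts[CAT_A] + self.counts[CAT_D]


def _decide(votes_a: int, votes_d: int, n_sites: int) -> str:
    if n_sites == 0:
        return UNCAT_NO_SNP
    if votes_a > votes_d:
        return CAT_A
    if votes_d > votes_a:
        return CAT_D
    return UNCAT_CONFLICT


def categorize_read(rec, index: SnpIndex) -> CategorizedRead:
    """Categorize one pysam alignment record (CIGAR-aware)."""
    if rec.is_unmapped:
        return CategorizedRead(rec.query_name, UNCAT_NO_SNP, 0, 0, 0)
    pos, aa, dd = index.chrom(rec.reference_name)
    lo = np.searchsorted(pos, rec.reference_start)
    hi = np.searchsorted(pos, rec.reference_end)
    if hi <= lo:
        return CategorizedRead(rec.query_name, UNCAT_NO_SNP, 0, 0, 0)
    wanted = dict(zip(pos[lo:hi].tolist(), range(lo, hi)))
    codes = encode(rec.query_sequence)
    votes_a = votes_d = n_sites = 0
    qpos = 0
    rpos = rec.reference_start
    for op, n in rec.cigartuples:
        if op in (0, 7, 8):  # aligned bases vote
            for r in range(rpos, rpos + n):
                i = wanted.get(r)
                if i is None:
                    continue
                n_sites += 1
                b = codes[qpos + (r - rpos)]
                if b == aa[i]:
                    votes_a += 1
                elif b == dd[i]:
                    votes_d += 1
            qpos += n
            rpos += n
        elif op in (1, 4):
            qpos += n
        elif op in (2, 3):  # bases opposite a deletion do not vote
            rpos += n
    return CategorizedRead(rec.query_name, _decide(votes_a, votes_d, n_sites),
                           n_sites, votes_a, votes_d)


# ---------------------------------------------------------------------------
# vectorized route for simulated ReadSets


def categorize_readset(rs, index: SnpIndex) -> tuple[np.ndarray, CategorizationStats]:
    """Categorize a gapless ReadSet; returns per-read category codes
    (0=A, 1=D, 2=no_snp, 3=conflict) and the aggregate stats."""
    rl = rs.read_length
    cat = np.full(rs.n, 2, dtype=np.uint8)
    for ci, chrom in enumerate(rs.chroms):
        pos, aa, dd = index.chrom(chrom)
        sel = np.flatnonzero(rs.chrom_idx == ci)
        if len(sel) == 0:
            continue
        starts = rs.ref_start[sel]
        lo = np.searchsorted(pos, starts)
        hi = np.searchsorted(pos, starts + rl)
        n_sites = (hi - lo).astype(np.int64)
        total = int(n_sites.sum())
        if total == 0:
            continue
        read_of_pair = np.repeat(np.arange(len(sel)), n_sites)
        base_idx = np.arange(total) - np.repeat(
            np.cumsum(n_sites) - n_sites, n_sites)
        site_idx = np.repeat(lo, n_sites) + base_idx
        offs = pos[site_idx] - starts[read_of_pair]
        bases = rs.seqs[sel[read_of_pair], offs]
        va = np.bincount(read_of_pair[bases == aa[site_idx]], minlength=len(sel))
        vd = np.bincount(read_of_pair[bases == dd[site_idx]], minlength=len(sel))
        local = np.full(len(sel), 2, dtype=np.uint8)
        overlapped = n_sites > 0
        local[overlapped & (va == vd)] = 3
        local[va > vd] = 0
        local[vd > va] = 1
        cat[sel] = local
    stats = CategorizationStats()
    codes_to_cat = [CAT_A, CAT_D, UNCAT_NO_SNP, UNCAT_CONFLICT]
    bc = np.bincount(cat, minlength=4)
    for code, name in enumerate(codes_to_cat):
        stats.counts[name] = int(bc[code])
    return cat, stats


def estimate_error_rate_readsets(categorized: list[tuple[np.ndarray, str]]
                                 ) -> float:
    """Wrong-genome rate over categorized reads.

    ``categorized`` pairs each category-code array with the truth group
    ('A' or 'D') of its library.
    """
    wrong = assigned = 0
    for cat, group in categorized:
        a = int(np.sum(cat == 0))
        d = int(np.sum(cat == 1))
        assigned += a + d
        wrong += d if group == "A" else a
    if assigned == 0:
        raise ValueError("no categorized reads; error rate undefined")
    return wrong / assigned


# ---------------------------------------------------------------------------
# file route


def categorize_file(sam_path: str, index: SnpIndex, outdir: str,
                    prefix: str | None = None
                    ) -> tuple[dict[str, str], CategorizationStats]:
    """Partition a SAM/BAM into A / D / uncategorized outputs.

    Every input record lands in exactly one output; headers are preserved
    with an added @PG line.  Returns the output paths and the stats.
    """
    if prefix is None:
        prefix = os.path.splitext(os.path.basename(sam_path))[0]
    os.makedirs(outdir, exist_ok=True)
    stats = CategorizationStats()
    paths = {k: os.path.join(outdir, f"{prefix}.{k}.sam")
             for k in ("A", "D", "uncat")}
    with pysam.AlignmentFile(sam_path, check_sq=False) as fin:
        hd = fin.header.to_dict()
        hd.setdefault("PG", []).append(
            {"ID": "homeoscan-categorize", "PN": "homeoscan"})
        header = pysam.AlignmentHeader.from_dict(hd)
        outs = {k: pysam.AlignmentFile(p, "w", header=header)
                for k, p in paths.items()}
        try:
            for rec in fin:
                cr = categorize_read(rec, index)
                stats.counts[cr.category] += 1
                dest = cr.category if cr.category in ("A", "D") else "uncat"
                outs[dest].write(rec)
        finally:
            for fh in outs.values():
                fh.close()
    return paths, stats


def estimate_error_rate(sam_groups: list[tuple[str, str]], index: SnpIndex
                        ) -> float:
    """File-based error rate: ``sam_groups`` pairs SAM paths with their true
    group label."""
    wrong = assigned = 0
    for path, group in sam_groups:
        with pysam.AlignmentFile(path, check_sq=False) as fin:
            for rec in fin:
                cr = categorize_read(rec, index)
                if cr.category in (CAT_A, CAT_D):
                    assigned += 1
                    if cr.category != group:
                        wrong += 1
    if assigned == 0:
        raise ValueError("no categorized reads; error rate undefined")
    return wrong / assigned
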