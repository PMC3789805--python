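"""Genotype calling and the conserved homoeo-SNP index.

The genotype rule: a site needs depth >= 10 to be callable; with the two
most frequent bases major/minor, the call is heterozygous when the minor
allele fraction is at least 0.40 (inclusive), otherwise homozygous for the
major base.  Ties between equally frequent bases break by the fixed base
order A<C<G<T.

A homoeo-SNP is recorded at a reference position when every accession with
coverage there is homozygous, all A-group accessions share one base, all
D-group accessions share another, and the two bases differ.  At least one
accession per group must have coverage; a site where an entire group is
uncallable cannot satisfy the unanimity rule and is skipped.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import BASES
from .pileup import AlleleCounts, PileupTable

NOCALL = -1


@dataclass
class GenotypeCall:
    """Per-accession per-site call."""

    chrom: str
    pos: int
    state: str  # 'hom', 'het' or 'nocall'
    alleles: tuple[str, ...]  # () for nocall, (b,) for hom, (major, minor) het
    depth: int
    minor_allele_fraction: float


class GenotypeArray:
    """Vectorized genotypes for one chromosome.

    ``a1``/``a2`` hold allele codes per position (-1 = nocall); homozygous
    sites have a1 == a2, heterozygous sites a1 != a2 with a1 the major
    allele.
    """

    def __init__(self, chrom: str, a1: np.ndarray, a2: np.ndarray,
                 depth: np.ndarray):
        self.chrom = chrom
        self.a1 = a1
        self.a2 = a2
        self.depth = depth

    def __len__(self) -> int:
        return len(self.a1)

    @property
    def called(self) -> np.ndarray:
        return self.a1 >= 0

    @property
    def is_hom(self) -> np.ndarray:
        return (self.a1 >= 0) & (self.a1 == self.a2)

    @property
    def is_het(self) -> np.ndarray:
        return (self.a1 >= 0) & (self.a1 != self.a2)


def call_genotypes(pt: PileupTable, min_depth: int = 10,
                   min_maf: float = 0.40) -> GenotypeArray:
    """Vectorized genotype calling over a whole chromosome."""
    counts = pt.counts
    depth = counts.sum(axis=0)
    # stable argsort on descending counts keeps base order A<C<G<T among ties
    order = np.argsort(-counts, axis=0, kind="stable")
    major = order[0]
    minor = order[1]
    cols = np.arange(counts.shape[1])
    minor_n = counts[minor, cols]
    with np.errstate(divide="ignore", invalid="ignore"):
        maf = np.where(depth > 0, minor_n / depth, 0.0)
    callable_ = depth >= min_depth
    het = callable_ & (minor_n > 0) & (maf >= min_maf)
    a1 = np.where(callable_, major, NOCALL).astype(np.int8)
    a2 = np.where(callable_, np.where(het, minor, major), NOCALL).astype(np.int8)
    return GenotypeArray(pt.chrom, a1, a2, depth)


def call_genotype(counts: AlleleCounts, min_depth: int = 10,
                  min_maf: float = 0.40) -> GenotypeCall:
    """Single-site genotype call (the scalar form of :func:`call_genotypes`)."""
    depth = counts.depth
    if depth < min_depth:
        return GenotypeCall(counts.chrom, counts.pos, "nocall", (), depth, 0.0)
    ranked = sorted(BASES, key=lambda b: (-counts.counts[b], b))
    major, minor = ranked[0], ranked[1]
    maf = counts.counts[minor] / depth
    if counts.counts[minor] > 0 and maf >= min_maf:
        return GenotypeCall(counts.chrom, counts.pos, "het", (major, minor),
                            depth, maf)
    return GenotypeCall(counts.chrom, counts.pos, "hom", (major,), depth, maf)


# ---------------------------------------------------------------------------
# the index


@dataclass(frozen=True)
class HomoeoSnp:
    """One diagnostic fixed difference between the A and D genome groups."""

    chrom: str
    pos: int
    a_allele: str
    d_allele: str

    def __post_init__(self):
        if self.a_allele == self.d_allele:
            raise ValueError("homoeo-SNP alleles must differ")
        if self.a_allele not in BASES or self.d_allele not in BASES:
            raise ValueError("alleles must be A/C/G/T")


class SnpIndex:
    """Sorted unique homoeo-SNP catalog, keyed by chromosome.

    Stored as arrays (pos int64, a_allele/d_allele uint8 codes); positions
    are strictly increasing within each chromosome.
    """

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                 provenance: tuple[str, ...] = ()):
        for chrom, (pos, aa, dd) in data.items():
            if len(pos) and np.any(np.diff(pos) <= 0):
                raise ValueError(f"index positions not strictly increasing "
                                 f"on {chrom}")
            if np.any(aa == dd):
                raise ValueError("a_allele == d_allele in index")
        self.data = data
        self.provenance = tuple(provenance)

    def __len__(self) -> int:
        return sum(len(pos) for pos, _, _ in self.data.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, SnpIndex):
            return NotImplemented
        if set(self.data) != set(other.data):
            return False
        return all(
            np.array_equal(self.data[c][k], other.data[c][k])
            for c in self.data for k in range(3))

    def sites(self):
        """Iterate :class:`HomoeoSnp` records in coordinate order."""
        for chrom in self.data:
            pos, aa, dd = self.data[chrom]
            for p, a, d in zip(pos, aa, dd):
                yield HomoeoSnp(chrom, int(p), BASES[a], BASES[d])

    def chrom(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if chrom in self.data:
            return self.data[chrom]
        e = np.empty(0, dtype=np.int64)
        return e, e.astype(np.uint8), e.astype(np.uint8)

    # -- persistence -------------------------------------------------------

    def write_tsv(self, path: str) -> None:
        """Native dialect: ``chrom pos0 a_allele d_allele``."""
        with open(path, "w") as fh:
            fh.write("#chrom\tpos0\ta_allele\td_allele\n")
            for s in self.sites():
                fh.write(f"{s.chrom}\t{s.pos}\t{s.a_allele}\t{s.d_allele}\n")

    @classmethod
    def read_tsv(cls, path: str) -> "SnpIndex":
        from ._seq import _ENCODE

        rows: dict[str, list[tuple[int, int, int]]] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 4 or parts[2] not in BASES or parts[3] not in BASES:
                    raise ValueError(f"{path}:{ln}: malformed index line")
                rows.setdefault(parts[0], []).append(
                    (int(parts[1]), _ENCODE[ord(parts[2])], _ENCODE[ord(parts[3])]))
        data = {}
        for chrom, items in rows.items():
            arr = np.array(items, dtype=np.int64)
            data[chrom] = (arr[:, 0],
                           arr[:, 1].astype(np.uint8),
                           arr[:, 2].astype(np.uint8))
        return cls(data)

    def write_vcf(self, path: str, reference_lengths: dict[str, int] | None = None
                  ) -> None:
        """VCF 4.2 dialect: REF = D allele, ALT = A allele, with an INFO tag
        recording the direction of the diagnostic difference."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=HSD,Number=0,Type=Flag,'
                     'Description="Homoeo-SNP: REF is the D allele, ALT the A allele">\n')
            if reference_lengths:
                for c, L in reference_lengths.items():
                    fh.write(f"##contig=<ID={c},length={L}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for s in self.sites():
                fh.write(f"{s.chrom}\t{s.pos + 1}\t.\t{s.d_allele}\t"
                         f"{s.a_allele}\t.\tPASS\tHSD\n")

    @classmethod
    def read_vcf(cls, path: str) -> "SnpIndex":
        from ._seq import _ENCODE

        rows: dict[str, list[tuple[int, int, int]]] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 5:
                    raise ValueError(f"{path}:{ln}: malformed VCF line")
                chrom, pos1, _, ref, alt = parts[:5]
                if ref not in BASES or alt not in BASES:
                    raise ValueError(f"{path}:{ln}: non-SNP record")
                rows.setdefault(chrom, []).append(
                    (int(pos1) - 1, _ENCODE[ord(alt)], _ENCODE[ord(ref)]))
        data = {}
        for chrom, items in rows.items():
            arr = np.array(items, dtype=np.int64)
            data[chrom] = (arr[:, 0],
                           arr[:, 1].astype(np.uint8),
                           arr[:, 2].astype(np.uint8))
        return cls(data)


def call_homoeo_snps(genotypes: dict[str, dict[str, GenotypeArray]],
                     groups: dict[str, str]) -> SnpIndex:
    """Build the index from per-accession genotypes.

    ``genotypes`` maps accession -> chrom -> :class:`GenotypeArray`;
    ``groups`` maps accession -> 'A' or 'D'.  Implements the unanimity rule
    (see module docstring).  Raises if either group is empty.
    """
    accs_a = [a for a, g in groups.items() if g == "A"]
    accs_d = [a for a, g in groups.items() if g == "D"]
    if not accs_a or not accs_d:
        raise ValueError("need at least one accession in each of groups A and D")
    chroms = list(next(iter(genotypes.values())).keys())
    data = {}
    for chrom in chroms:
        L = len(genotypes[accs_a[0]][chrom])
        ok = np.ones(L, dtype=bool)
        group_allele = {}
        for grp, accs in (("A", accs_a), ("D", accs_d)):
            any_called = np.zeros(L, dtype=bool)
            lo = np.full(L, 127, dtype=np.int8)
            hi = np.full(L, -1, dtype=np.int8)
            for acc in accs:
                ga = genotypes[acc][chrom]
                called = ga.called
                het = ga.is_het
                ok &= ~het  # every covered accession must be homozygous
                any_called |= called
                a = ga.a1
                lo = np.where(called & (a < lo), a, lo)
                hi = np.where(called & (a > hi), a, hi)
            ok &= any_called & (lo == hi)
            group_allele[grp] = hi  # == lo wherever ok
        ok &= group_allele["A"] != group_allele["D"]
        pos = np.flatnonzero(ok).astype(np.int64)
        data[chrom] = (pos,
                       group_allele["A"][pos].astype(np.uint8),
                       group_allele["D"][pos].astype(np.uint8))
    return SnpIndex(data, provenance=tuple(sorted(groups)))


# ---------------------------------------------------------------------------
# summaries


_TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


class TsTvTable:
    """4x4 directional substitution counts; rows = A allele, cols = D allele."""

    def __init__(self, counts: np.ndarray):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (4, 4) or np.any(np.diag(counts) != 0):
            raise ValueError("need a 4x4 table with an empty diagonal")
        self.counts = counts

    @classmethod
    def from_cells(cls, cells: dict[tuple[str, str], int]) -> "TsTvTable":
        """Build from {(a_allele, d_allele): count} cells."""
        m = np.zeros((4, 4), dtype=np.int64)
        for (a, d), n in cells.items():
            m[BASES.index(a), BASES.index(d)] = n
        return cls(m)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def transitions(self) -> int:
        return int(sum(self.counts[i, j] for i, j in _TRANSITIONS))

    @property
    def transversions(self) -> int:
        return self.total - self.transitions

    @property
    def ratio(self) -> float | None:
        """Ts/Tv ratio; None when there are no transversions."""
        if self.transversions == 0:
            return None
        return self.transitions / self.transversions


def tally_ts_tv(index: SnpIndex) -> tuple[TsTvTable, float | None]:
    if len(index) == 0:
        raise ValueError("empty index")
    m = np.zeros((4, 4), dtype=np.int64)
    for _, (pos, aa, dd) in index.data.items():
        np.add.at(m, (aa.astype(np.int64), dd.astype(np.int64)), 1)
    table = TsTvTable(m)
    return table, table.ratio


def gc_fraction_at_snps(index: SnpIndex) -> tuple[float, float]:
    """Fractions of index sites whose A (resp. D) allele is G or C."""
    if len(index) == 0:
        raise ValueError("empty index")
    gc_a = gc_d = 0
    for _, (pos, aa, dd) in index.data.items():
        gc_a += int(np.sum((aa == 1) | (aa == 2)))
        gc_d += int(np.sum((dd == 1) | (dd == 2)))
    n = len(index)
    return gc_a / n, gc_d / n


def snp_density(index: SnpIndex, genome_length: int) -> float:
    """Bases per homoeo-SNP."""
    if len(index) == 0:
        raise ValueError("empty index")
    return genome_length / len(index)


def summary_report(index: SnpIndex, genome_length: int) -> dict:
    table, ratio = tally_ts_tv(index)
    gc_a, gc_d = gc_fraction_at_snps(index)
    return {
        "n_snps": len(index),
        "ts_tv_ratio": ratio,
        "gc_fraction_a": gc_a,
        "gc_fraction_d": gc_d,
        "bases_per_snp": snp_density(index, genome_length),
    }
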