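"""Synthetic cohort generator with known truth.

Emulates the study system: a D-like reference genome, diverged A-group and
D-group diploid accessions separated by fixed inter-genome differences
(homoeo-SNPs, ~1 per 32.3 bases), an allotetraploid whose two subgenomes
descend from the A and D progenitors and carry autapomorphic substitutions
and planted homoeologous conversion tracts, plus short-read sequencing with
known per-read origins.  Every downstream caller is validated against the
:class:`TruthSet` this module records.

Coordinates are 0-based half-open internally; 1-based conventions appear
only in the SAM/GFF3 writers.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pysam

from ._seq import BASES, decode, decode_rows, revcomp
from .regions import GenomicInterval

AT_BIASED = "AT_biased"
DT_BIASED = "DT_biased"

_STOP_CODONS = ("TAA", "TAG", "TGA")


class PlacementError(ValueError):
    """Raised when requested features cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """All knobs of the generator; the defaults are the study conditions.

    Rates are per-base probabilities, lengths in bases, coverage in fold.
    ``seed`` fixes every output bit-for-bit.
    """

    genome_length: int = 1_000_000
    n_chromosomes: int = 2
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (300, 1500)
    homoeo_snp_rate: float = 1.0 / 32.3
    allele_snp_rate_A: float = 0.004
    allele_snp_rate_D: float = 0.0005
    het_rate_A: float = 0.005
    het_rate_D: float = 0.0002
    n_accessions_A: int = 2
    n_accessions_D: int = 2
    deletion_count: int = 8
    deletion_length_range: tuple[int, int] = (1500, 4000)
    duplication_count: int = 4
    duplication_length_range: tuple[int, int] = (2000, 5000)
    tetraploid_autapomorphy_rate: float = 0.005
    conversion_tract_count: int = 6
    conversion_tract_length_range: tuple[int, int] = (1200, 3000)
    conversion_direction_bias: float = 0.8  # fraction of tracts D_T-biased
    coverage: float = 40.0
    read_length: int = 100
    base_error_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        rates = [
            self.homoeo_snp_rate, self.allele_snp_rate_A, self.allele_snp_rate_D,
            self.het_rate_A, self.het_rate_D, self.tetraploid_autapomorphy_rate,
            self.base_error_rate, self.conversion_direction_bias,
        ]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        for lo, hi in (self.gene_length_range, self.deletion_length_range,
                       self.duplication_length_range,
                       self.conversion_tract_length_range):
            if not (0 < lo <= hi):
                raise ValueError("length ranges must be positive and ordered")
        if self.genome_length <= 0 or self.n_chromosomes <= 0:
            raise ValueError("genome_length and n_chromosomes must be positive")
        if self.read_length <= 0 or self.coverage < 0:
            raise ValueError("read_length must be positive, coverage >= 0")
        if self.n_accessions_A < 1 or self.n_accessions_D < 1:
            raise ValueError("need at least one accession per group")

    def replace(self, **kw) -> "SimConfig":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kw)
        return SimConfig(**d)


# ---------------------------------------------------------------------------
# reference genome and gene annotation


class Reference:
    """Ordered chromosome sequences as uint8 code arrays."""

    def __init__(self, seqs: dict[str, np.ndarray]):
        self.seqs = seqs
        self.chroms = list(seqs)

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.seqs[chrom]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.seqs.values())

    def write_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, arr in self.seqs.items():
                fh.write(f">{chrom}\n")
                s = decode(arr)
                for i in range(0, len(s), width):
                    fh.write(s[i:i + width] + "\n")

    @classmethod
    def read_fasta(cls, path: str) -> "Reference":
        from Bio import SeqIO

        from ._seq import encode

        seqs = {rec.id: encode(str(rec.seq)) for rec in SeqIO.parse(path, "fasta")}
        return cls(seqs)


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene; ``exons`` are CDS segments in genomic order."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def _chrom_lengths(cfg: SimConfig) -> dict[str, int]:
    base = cfg.genome_length // cfg.n_chromosomes
    lens = [base] * cfg.n_chromosomes
    lens[-1] += cfg.genome_length - base * cfg.n_chromosomes
    return {f"chr{i + 1:02d}": L for i, L in enumerate(lens)}


def _random_cds_codes(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    """Uint8 codes of a CDS: ATG, non-stop middle codons, one stop."""
    from ._seq import encode

    non_stop = [a + b + c
                for a in BASES for b in BASES for c in BASES
                if a + b + c not in _STOP_CODONS]
    mids = rng.integers(0, len(non_stop), n_codons - 2)
    stop = _STOP_CODONS[rng.integers(0, 3)]
    cds = "ATG" + "".join(non_stop[i] for i in mids) + stop
    return encode(cds)


def simulate_reference(cfg: SimConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[Reference, list[Gene]]:
    """Random reference chromosomes plus non-overlapping translatable genes.

    Genes are packed into equal slots along each chromosome; each gene is a
    single- or two-exon CDS that starts with ATG, ends with a stop codon and
    contains no internal stop, written onto the chosen strand.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 10])
    lengths = _chrom_lengths(cfg)
    seqs = {c: rng.integers(0, 4, L).astype(np.uint8) for c, L in lengths.items()}
    ref = Reference(seqs)

    genes: list[Gene] = []
    if cfg.n_genes == 0:
        return ref, genes
    # distribute genes over chromosomes proportionally to length
    chroms = list(lengths)
    total = sum(lengths.values())
    per = {c: int(round(cfg.n_genes * lengths[c] / total)) for c in chroms}
    drift = cfg.n_genes - sum(per.values())
    per[chroms[0]] += drift
    gid = 0
    for chrom in chroms:
        n = per[chrom]
        if n <= 0:
            continue
        slot = lengths[chrom] // n
        max_span = cfg.gene_length_range[1] + 200 + 6  # worst case with intron
        if slot < max_span + 2:
            raise PlacementError(
                f"cannot pack {n} genes of span <= {max_span} bp into "
                f"{lengths[chrom]} bp of {chrom}"
            )
        for k in range(n):
            gid += 1
            cds_len = 3 * int(rng.integers(cfg.gene_length_range[0] // 3,
                                           cfg.gene_length_range[1] // 3 + 1))
            has_intron = rng.random() < 0.3 and cds_len > 60
            intron_len = int(rng.integers(50, 201)) if has_intron else 0
            span = cds_len + intron_len
            offset = int(rng.integers(0, slot - span))
            start = k * slot + offset
            end = start + span
            strand = "+" if rng.random() < 0.5 else "-"
            cds = _random_cds_codes(cds_len // 3, rng)
            genomic = cds if strand == "+" else revcomp(cds)
            if has_intron:
                cut = int(rng.integers(1, cds_len))  # genomic split point
                exons = ((start, start + cut), (start + cut + intron_len, end))
                ref[chrom][start:start + cut] = genomic[:cut]
                ref[chrom][start + cut + intron_len:end] = genomic[cut:]
            else:
                exons = ((start, end),)
                ref[chrom][start:end] = genomic
            genes.append(Gene(f"gene{gid:04d}", chrom, start, end, strand, exons))
    return ref, genes


def write_gff3(genes: list[Gene], path: str, source: str = "homeoscan") -> None:
    """GFF3 (1-based closed) with gene/mRNA/CDS features and phase."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\t{source}\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n")
            exons = g.exons if g.strand == "+" else tuple(reversed(g.exons))
            done = 0
            for i, (s, e) in enumerate(exons):
                phase = (3 - done % 3) % 3
                fh.write(f"{g.chrom}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                         f"{phase}\tID={mrna}.cds{i + 1};Parent={mrna}\n")
                done += e - s


# ---------------------------------------------------------------------------
# truth bookkeeping


@dataclass(frozen=True)
class ConversionTract:
    interval: GenomicInterval
    direction: str  # AT_BIASED or DT_BIASED


@dataclass
class TruthSet:
    """Everything the generator planted; the oracle for every detector."""

    homoeo_snps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict)  # chrom -> (pos, a_allele, d_allele)
    allele_snps: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = field(
        default_factory=dict)  # accession -> chrom -> (pos, alt)
    het_sites: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = field(
        default_factory=dict)
    deletions: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    duplications: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    conserved_deletions: list[GenomicInterval] = field(default_factory=list)
    conserved_duplications: list[GenomicInterval] = field(default_factory=list)
    conversion_tracts: list[ConversionTract] = field(default_factory=list)
    autapomorphies: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = field(
        default_factory=dict)  # subgenome -> chrom -> (pos, alt)
    resampled_collisions: int = 0

    def n_homoeo_snps(self) -> int:
        return sum(len(p) for p, _, _ in self.homoeo_snps.values())

    def n_het(self, accession: str) -> int:
        return sum(len(p) for p, _ in self.het_sites.get(accession, {}).values())

    def n_allele_snps(self, accession: str) -> int:
        return sum(len(p) for p, _ in self.allele_snps.get(accession, {}).values())

    def homoeo_positions(self, chrom: str) -> np.ndarray:
        if chrom in self.homoeo_snps:
            return self.homoeo_snps[chrom][0]
        return np.empty(0, dtype=np.int64)

    def write(self, outdir) -> None:
        """Tab-separated truth files with documented headers."""
        import os

        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "homoeo_snps.tsv"), "w") as fh:
            fh.write("#chrom\tpos0\ta_allele\td_allele\n")
            for chrom, (pos, aa, dd) in self.homoeo_snps.items():
                for p, a, d in zip(pos, aa, dd):
                    fh.write(f"{chrom}\t{p}\t{BASES[a]}\t{BASES[d]}\n")
        with open(os.path.join(outdir, "variants.tsv"), "w") as fh:
            fh.write("#accession\tkind\tchrom\tpos0\talt\n")
            for store, kind in ((self.allele_snps, "allele_snp"),
                                (self.het_sites, "het"),
                                (self.autapomorphies, "autapomorphy")):
                for acc, per_chrom in store.items():
                    for chrom, (pos, alt) in per_chrom.items():
                        for p, a in zip(pos, alt):
                            fh.write(f"{acc}\t{kind}\t{chrom}\t{p}\t{BASES[a]}\n")
        with open(os.path.join(outdir, "regions.tsv"), "w") as fh:
            fh.write("#kind\tchrom\tstart0\tend0\tdetail\n")
            for iv in self.conserved_deletions:
                fh.write(f"deletion\t{iv.chrom}\t{iv.start}\t{iv.end}\tgroup_A\n")
            for iv in self.conserved_duplications:
                fh.write(f"duplication\t{iv.chrom}\t{iv.start}\t{iv.end}\tgroup_A\n")
            for t in self.conversion_tracts:
                fh.write(f"conversion\t{t.interval.chrom}\t{t.interval.start}\t"
                         f"{t.interval.end}\t{t.direction}\n")


@dataclass
class Accession:
    """A diploid accession (or tetraploid subgenome) in reference coordinates."""

    name: str
    group: str  # 'A', 'D', 'AT' or 'DT'
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]]
    deletions: list[GenomicInterval] = field(default_factory=list)
    duplications: list[GenomicInterval] = field(default_factory=list)

    def sequence(self, chrom: str, hap: int = 0) -> np.ndarray:
        return self.haplotypes[chrom][hap]


# ---------------------------------------------------------------------------
# divergence


def _place_intervals(rng: np.random.Generator, lengths: dict[str, int],
                     count: int, length_range: tuple[int, int],
                     occupied: list[GenomicInterval], margin: int = 2000,
                     ) -> list[GenomicInterval]:
    """Rejection-sample non-overlapping intervals away from chromosome ends."""
    chroms = list(lengths)
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: list[GenomicInterval] = []
    tries = 0
    while len(placed) < count:
        tries += 1
        if tries > 1000 * max(count, 1):
            raise PlacementError(
                f"could not place {count} intervals of {length_range} bp "
                f"without overlap")
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        hi = lengths[chrom] - margin - L
        if hi <= margin:
            continue
        s = int(rng.integers(margin, hi))
        iv = GenomicInterval(chrom, s, s + L)
        pad = GenomicInterval(chrom, max(0, s - margin), s + L + margin)
        if any(pad.overlaps(o) for o in occupied + placed):
            continue
        placed.append(iv)
    return sorted(placed)


def _mask_positions(length: int, exclude: list[np.ndarray],
                    exclude_ivs: list[GenomicInterval], chrom: str) -> np.ndarray:
    """All positions on a chromosome minus excluded points and intervals."""
    keep = np.ones(length, dtype=bool)
    for pos in exclude:
        keep[pos] = False
    for iv in exclude_ivs:
        if iv.chrom == chrom:
            keep[iv.start:iv.end] = False
    return np.flatnonzero(keep)


def _sample_sites(rng: np.random.Generator, allowed: np.ndarray,
                  rate: float) -> np.ndarray:
    """Binomial draw of site count, then positions without replacement.

    Choosing without replacement realises the "resample on collision" rule
    exactly: planted sites never collide by construction.
    """
    n = rng.binomial(len(allowed), rate)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    return np.sort(rng.choice(allowed, size=n, replace=False))


def _shift_alleles(rng: np.random.Generator, ref_alleles: np.ndarray) -> np.ndarray:
    return ((ref_alleles + rng.integers(1, 4, len(ref_alleles))) % 4).astype(np.uint8)


def diverge_genomes(reference: Reference, cfg: SimConfig
                    ) -> tuple[list[Accession], list[Accession], TruthSet]:
    """Plant fixed A/D differences, group-conserved structural variants and
    per-accession private variation.

    Homoeo-SNPs are fixed differences shared by every A accession relative to
    the D-like reference; allele-SNPs and heterozygous sites are private per
    accession, drawn at the group rates (A rates exceed D rates, mirroring
    the A >> D diversity contrast).  Each accession draws from its own RNG
    stream keyed by (seed, accession index), so adding accessions never
    perturbs existing ones.
    """
    cfg.validate()
    truth = TruthSet()
    lengths = reference.lengths
    rng = np.random.default_rng([cfg.seed, 20])

    dels = _place_intervals(rng, lengths, cfg.deletion_count,
                            cfg.deletion_length_range, [])
    dups = _place_intervals(rng, lengths, cfg.duplication_count,
                            cfg.duplication_length_range, list(dels))
    truth.conserved_deletions = dels
    truth.conserved_duplications = dups

    # fixed inter-genome differences, disjoint from deletion interiors
    for chrom, L in lengths.items():
        hit = rng.random(L) < cfg.homoeo_snp_rate
        for iv in dels:
            if iv.chrom == chrom:
                hit[iv.start:iv.end] = False
        pos = np.flatnonzero(hit).astype(np.int64)
        d_allele = reference[chrom][pos]
        a_allele = _shift_alleles(rng, d_allele)
        truth.homoeo_snps[chrom] = (pos, a_allele, d_allele)

    group_specs = (
        [("A", f"A{i + 1}", i) for i in range(cfg.n_accessions_A)]
        + [("D", f"D{i + 1}", cfg.n_accessions_A + i)
           for i in range(cfg.n_accessions_D)]
    )
    accessions_a: list[Accession] = []
    accessions_d: list[Accession] = []
    for group, name, idx in group_specs:
        acc_rng = np.random.default_rng([cfg.seed, 21, idx])
        snp_rate = cfg.allele_snp_rate_A if group == "A" else cfg.allele_snp_rate_D
        het_rate = cfg.het_rate_A if group == "A" else cfg.het_rate_D
        haplotypes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        truth.allele_snps[name] = {}
        truth.het_sites[name] = {}
        for chrom, L in lengths.items():
            h_pos, h_a, _ = truth.homoeo_snps[chrom]
            excl_ivs = dels if group == "A" else []
            allowed = _mask_positions(L, [h_pos], excl_ivs, chrom)
            n_snp = acc_rng.binomial(len(allowed), snp_rate)
            n_het = acc_rng.binomial(len(allowed), het_rate)
            both = acc_rng.choice(allowed, size=n_snp + n_het, replace=False)
            snp_pos = np.sort(both[:n_snp])
            het_pos = np.sort(both[n_snp:])
            base = reference[chrom].copy()
            if group == "A":
                base[h_pos] = h_a
            snp_alt = _shift_alleles(acc_rng, base[snp_pos])
            het_alt = _shift_alleles(acc_rng, base[het_pos])
            h0 = base
            h0[snp_pos] = snp_alt
            h1 = h0.copy()
            h1[het_pos] = het_alt
            haplotypes[chrom] = (h0, h1)
            truth.allele_snps[name][chrom] = (snp_pos, snp_alt)
            truth.het_sites[name][chrom] = (het_pos, het_alt)
        acc = Accession(name, group, haplotypes,
                        deletions=list(dels) if group == "A" else [],
                        duplications=list(dups) if group == "A" else [])
        truth.deletions[name] = acc.deletions
        truth.duplications[name] = acc.duplications
        (accessions_a if group == "A" else accessions_d).append(acc)
    return accessions_a, accessions_d, truth


def ancestral_progenitors(reference: Reference, truth: TruthSet
                          ) -> tuple[Accession, Accession]:
    """The A and D progenitor genomes: fixed differences only, no private
    variation.  The A progenitor carries the group-conserved deletions and
    duplications (they predate the polyploidization event)."""
    hap_a: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    hap_d: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, arr in reference.seqs.items():
        pos, a_allele, _ = truth.homoeo_snps[chrom]
        a = arr.copy()
        a[pos] = a_allele
        hap_a[chrom] = (a, a)
        d = arr.copy()
        hap_d[chrom] = (d, d)
    a_prog = Accession("A_progenitor", "A", hap_a,
                       deletions=list(truth.conserved_deletions),
                       duplications=list(truth.conserved_duplications))
    d_prog = Accession("D_progenitor", "D", hap_d)
    return a_prog, d_prog


def make_tetraploid(a_progenitor: Accession, d_progenitor: Accession,
                    cfg: SimConfig, truth: TruthSet,
                    at_name: str = "Tetra.AT", dt_name: str = "Tetra.DT",
                    ) -> tuple[Accession, Accession]:
    """Derive the allotetraploid subgenomes from the two progenitors.

    Each subgenome receives autapomorphic substitutions at
    ``tetraploid_autapomorphy_rate``; conversion tracts then overwrite one
    subgenome's sequence with the other's current sequence, homogenizing the
    tract.  Tracts are restricted to regions present in both progenitors
    (outside the planted deletions and duplications) — a tract requested on
    absent territory is a placement error.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 22])
    lengths = {c: len(s) for c, (s, _) in a_progenitor.haplotypes.items()}

    at_seqs = {c: h[0].copy() for c, h in a_progenitor.haplotypes.items()}
    dt_seqs = {c: h[0].copy() for c, h in d_progenitor.haplotypes.items()}

    # autapomorphies may hit homoeo-SNP positions: an A_T substitution onto
    # the D allele is precisely the pattern that mimics a conversion
    for sub, seqs in ((at_name, at_seqs), (dt_name, dt_seqs)):
        truth.autapomorphies[sub] = {}
        for chrom, L in lengths.items():
            excl = a_progenitor.deletions  # keep both subgenomes comparable
            allowed = _mask_positions(L, [], excl, chrom)
            pos = _sample_sites(rng, allowed, cfg.tetraploid_autapomorphy_rate)
            alt = _shift_alleles(rng, seqs[chrom][pos])
            seqs[chrom][pos] = alt
            truth.autapomorphies[sub][chrom] = (pos, alt)

    occupied = list(a_progenitor.deletions) + list(a_progenitor.duplications)
    tracts = _place_intervals(rng, lengths, cfg.conversion_tract_count,
                              cfg.conversion_tract_length_range, occupied)
    for iv in tracts:
        if any(iv.overlaps(o) for o in
               a_progenitor.deletions + d_progenitor.deletions):
            raise PlacementError(
                f"conversion tract {iv} overlaps a region absent in a progenitor")
        direction = DT_BIASED if rng.random() < cfg.conversion_direction_bias \
            else AT_BIASED
        if direction == AT_BIASED:  # D_T tract overwritten by A_T sequence
            dt_seqs[iv.chrom][iv.start:iv.end] = at_seqs[iv.chrom][iv.start:iv.end]
        else:
            at_seqs[iv.chrom][iv.start:iv.end] = dt_seqs[iv.chrom][iv.start:iv.end]
        truth.conversion_tracts.append(ConversionTract(iv, direction))

    at = Accession(at_name, "AT", {c: (s, s) for c, s in at_seqs.items()},
                   deletions=list(a_progenitor.deletions),
                   duplications=list(a_progenitor.duplications))
    dt = Accession(dt_name, "DT", {c: (s, s) for c, s in dt_seqs.items()})
    truth.deletions[at_name] = at.deletions
    truth.duplications[at_name] = at.duplications
    return at, dt


# ---------------------------------------------------------------------------
# physical genomes and read simulation


@dataclass
class PhysicalGenome:
    """The sequenced molecule of one accession: the reference-coordinate
    haplotypes with deletions excised and tandem duplications repeated,
    concatenated segment by segment."""

    accession: str
    chroms: list[str]
    segments: list[tuple[str, int, int]]  # (chrom, ref_start, ref_end)
    seg_offsets: np.ndarray  # physical start of each segment, plus total
    hap_seqs: tuple[np.ndarray, np.ndarray]

    @property
    def length(self) -> int:
        return int(self.seg_offsets[-1])


def physical_genome(acc: Accession, reference: Reference) -> PhysicalGenome:
    segments: list[tuple[str, int, int]] = []
    for chrom in reference.chroms:
        L = reference.lengths[chrom]
        dels = sorted(iv for iv in acc.deletions if iv.chrom == chrom)
        kept: list[tuple[int, int]] = []
        cur = 0
        for iv in dels:
            if iv.start > cur:
                kept.append((cur, iv.start))
            cur = iv.end
        if cur < L:
            kept.append((cur, L))
        # tandem duplication of [s, e): ... s..e, s..e, e... realised by
        # splitting the containing segment into [a, e) + [s, b)
        for dup in sorted(iv for iv in acc.duplications if iv.chrom == chrom):
            out: list[tuple[int, int]] = []
            for (a, b) in kept:
                if a <= dup.start and dup.end <= b:
                    out.append((a, dup.end))
                    out.append((dup.start, b))
                else:
                    out.append((a, b))
            kept = out
        segments.extend((chrom, a, b) for a, b in kept)
    offsets = np.zeros(len(segments) + 1, dtype=np.int64)
    for i, (_, a, b) in enumerate(segments):
        offsets[i + 1] = offsets[i] + (b - a)
    haps = []
    for h in range(2):
        parts = [acc.haplotypes[c][h][a:b] for c, a, b in segments]
        haps.append(np.concatenate(parts) if parts
                    else np.empty(0, dtype=np.uint8))
    return PhysicalGenome(acc.name, reference.chroms, segments, offsets,
                          (haps[0], haps[1]))


@dataclass
class ReadSet:
    """Simulated reads plus their true origins (the read-origin records).

    ``ref_start``/``chrom_idx`` are -1 for reads that span a planted
    breakpoint and therefore have no gapless reference placement; the SAM
    writer emits those unmapped.
    """

    accession: str
    read_length: int
    chroms: list[str]
    seqs: np.ndarray        # (n, read_length) uint8, observed bases
    chrom_idx: np.ndarray   # int32, -1 = unmapped
    ref_start: np.ndarray   # int64, -1 = unmapped
    hap: np.ndarray
    origin: np.ndarray | None = None  # per-read origin label index
    origin_labels: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return len(self.ref_start)

    def qname(self, i: int) -> str:
        return f"{self.accession}.{i}"

    def subset(self, mask: np.ndarray, accession: str | None = None
               ) -> "ReadSet":
        return ReadSet(
            accession or self.accession, self.read_length, self.chroms,
            self.seqs[mask], self.chrom_idx[mask], self.ref_start[mask],
            self.hap[mask],
            origin=None if self.origin is None else self.origin[mask],
            origin_labels=self.origin_labels)


_ERR_CHUNK = 131072  # fixed so that outputs never depend on memory layout


def simulate_reads(phys: PhysicalGenome, cfg: SimConfig, stream: int,
                   coverage: float | None = None) -> ReadSet:
    """Uniform single-end reads with i.i.d. base errors.

    Read count is ``ceil(coverage * physical_length / read_length)``.  Reads
    whose span crosses a segment junction (a planted deletion or duplication
    breakpoint) are flagged unmappable.
    """
    cov = cfg.coverage if coverage is None else coverage
    if cov <= 0:
        raise ValueError("coverage must be positive")
    rl = cfg.read_length
    if rl > phys.length or any(b - a < 1 for _, a, b in phys.segments):
        raise ValueError("read_length exceeds available sequence")
    rng = np.random.default_rng([cfg.seed, 30, stream])
    n = math.ceil(cov * phys.length / rl)
    starts = rng.integers(0, phys.length - rl + 1, n)
    hap = rng.integers(0, 2, n).astype(np.uint8)

    seqs = np.empty((n, rl), dtype=np.uint8)
    offs = np.arange(rl)
    for lo in range(0, n, _ERR_CHUNK):
        hi = min(lo + _ERR_CHUNK, n)
        win = starts[lo:hi, None] + offs
        block = np.empty((hi - lo, rl), dtype=np.uint8)
        for h in (0, 1):
            m = hap[lo:hi] == h
            block[m] = phys.hap_seqs[h][win[m]]
        seqs[lo:hi] = block

    if cfg.base_error_rate > 0:
        for lo in range(0, n, _ERR_CHUNK):
            hi = min(lo + _ERR_CHUNK, n)
            mask = rng.random((hi - lo, rl)) < cfg.base_error_rate
            k = int(mask.sum())
            if k:
                shift = rng.integers(1, 4, k)
                block = seqs[lo:hi]
                block[mask] = (block[mask] + shift) % 4
                seqs[lo:hi] = block

    seg_idx = np.searchsorted(phys.seg_offsets, starts, side="right") - 1
    fits = starts + rl <= phys.seg_offsets[seg_idx + 1]
    seg_chrom = np.array([phys.chroms.index(c) for c, _, _ in phys.segments],
                         dtype=np.int32)
    seg_ref = np.array([a for _, a, _ in phys.segments], dtype=np.int64)
    chrom_idx = np.where(fits, seg_chrom[seg_idx], -1).astype(np.int32)
    ref_start = np.where(
        fits, seg_ref[seg_idx] + (starts - phys.seg_offsets[seg_idx]), -1)
    return ReadSet(phys.accession, rl, phys.chroms, seqs, chrom_idx, ref_start,
                   hap)


def merge_readsets(readsets: list[ReadSet], accession: str,
                   labels: list[str] | None = None) -> ReadSet:
    """Pool reads (e.g. the two tetraploid subgenomes into one library),
    recording each read's origin label."""
    if labels is None:
        labels = [rs.accession for rs in readsets]
    chroms = readsets[0].chroms
    origin = np.concatenate([
        np.full(rs.n, i, dtype=np.uint8) for i, rs in enumerate(readsets)])
    return ReadSet(
        accession, readsets[0].read_length, chroms,
        np.concatenate([rs.seqs for rs in readsets]),
        np.concatenate([rs.chrom_idx for rs in readsets]),
        np.concatenate([rs.ref_start for rs in readsets]),
        np.concatenate([rs.hap for rs in readsets]),
        origin=origin, origin_labels=tuple(labels))


def write_fastq(rs: ReadSet, path: str, qual_char: str = "D") -> None:
    """Constant-quality FASTQ (Phred 35)."""
    qual = qual_char * rs.read_length
    names = [rs.qname(i) for i in range(rs.n)]
    seq_strings = decode_rows(rs.seqs)
    with open(path, "w") as fh:
        for name, seq in zip(names, seq_strings):
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def write_truth_alignments(rs: ReadSet, reference: Reference, path: str,
                           qual: int = 35) -> None:
    """Write the generator's own gapless alignments as coordinate-sorted SAM.

    Substitution-only genomes guarantee an all-match CIGAR; breakpoint-
    crossing reads are emitted unmapped (flag 4), placed after the mapped
    records.
    """
    order = np.lexsort((rs.ref_start, np.where(rs.chrom_idx < 0,
                                               np.iinfo(np.int32).max,
                                               rs.chrom_idx)))
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": reference.lengths[c]} for c in reference.chroms],
        "PG": [{"ID": "homeoscan-sim", "PN": "homeoscan"}],
    })
    qual_arr = np.full(rs.read_length, qual, dtype=np.uint8)
    cigar = [(0, rs.read_length)]
    seq_strings = decode_rows(rs.seqs)
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for i in order:
            a = pysam.AlignedSegment(header)
            a.query_name = rs.qname(int(i))
            a.query_sequence = seq_strings[i]
            a.query_qualities = qual_arr
            if rs.chrom_idx[i] < 0:
                a.is_unmapped = True
                a.reference_id = -1
                a.reference_start = -1
            else:
                a.flag = 0
                a.reference_id = int(rs.chrom_idx[i])
                a.reference_start = int(rs.ref_start[i])
                a.cigartuples = cigar
                a.mapping_quality = 60
            out.write(a)


# ---------------------------------------------------------------------------
# one-call cohort


@dataclass
class SimulatedCohort:
    """A full synthetic study: reference, annotation, diploid accessions of
    both groups, the tetraploid subgenomes, reads and the truth."""

    cfg: SimConfig
    reference: Reference
    genes: list[Gene]
    accessions_a: list[Accession]
    accessions_d: list[Accession]
    tetraploid_at: Accession
    tetraploid_dt: Accession
    truth: TruthSet
    readsets: dict[str, ReadSet]  # diploid accessions + pooled "Tetra"

    @property
    def groups(self) -> dict[str, str]:
        g = {a.name: "A" for a in self.accessions_a}
        g.update({d.name: "D" for d in self.accessions_d})
        return g


def simulate_cohort(cfg: SimConfig, with_tetraploid: bool = True,
                    with_reads: bool = True) -> SimulatedCohort:
    """Run the whole generator under one seed."""
    cfg.validate()
    reference, genes = simulate_reference(cfg)
    acc_a, acc_d, truth = diverge_genomes(reference, cfg)
    if with_tetraploid:
        a_prog, d_prog = ancestral_progenitors(reference, truth)
        at, dt = make_tetraploid(a_prog, d_prog, cfg, truth)
    else:
        at = dt = None
    readsets: dict[str, ReadSet] = {}
    if with_reads:
        for i, acc in enumerate(acc_a + acc_d):
            phys = physical_genome(acc, reference)
            readsets[acc.name] = simulate_reads(phys, cfg, stream=i)
        if with_tetraploid:
            # total tetraploid coverage = cfg.coverage, split over subgenomes
            rs_at = simulate_reads(physical_genome(at, reference), cfg,
                                   stream=100, coverage=cfg.coverage / 2)
            rs_dt = simulate_reads(physical_genome(dt, reference), cfg,
                                   stream=101, coverage=cfg.coverage / 2)
            readsets["Tetra"] = merge_readsets([rs_at, rs_dt], "Tetra",
                                               labels=["AT", "DT"])
    return SimulatedCohort(cfg, reference, genes, acc_a, acc_d, at, dt, truth,
                           readsets)


def write_cohort(cohort: SimulatedCohort, outdir: str) -> None:
    """Materialise the cohort on disk: FASTA, GFF3, FASTQ, SAM, truth TSVs."""
    import os

    os.makedirs(outdir, exist_ok=True)
    cohort.reference.write_fasta(os.path.join(outdir, "reference.fa"))
    write_gff3(cohort.genes, os.path.join(outdir, "genes.gff3"))
    cohort.truth.write(os.path.join(outdir, "truth"))
    with open(os.path.join(outdir, "groups.tsv"), "w") as fh:
        fh.write("#accession\tgroup\tsam\n")
        for name, rs in cohort.readsets.items():
            group = cohort.groups.get(name, "tetraploid")
            fh.write(f"{name}\t{group}\t{name}.sam\n")
    for name, rs in cohort.readsets.items():
        write_fastq(rs, os.path.join(outdir, f"{name}.fastq"))
        write_truth_alignments(rs, cohort.reference,
                               os.path.join(outdir, f"{name}.sam"))
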