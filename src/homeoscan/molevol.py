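"""Pseudo-genomes, CDS extraction and pairwise molecular evolution.

dN/dS follows Nei & Gojobori's unweighted pathway-counting estimator:
synonymous site counts per codon from the fraction of one-step changes that
preserve the amino acid (changes to a stop codon count as nonsynonymous, so
S + N = 3 per codon); observed differences per codon pair are averaged over
all minimal mutational pathways, excluding pathways that pass through a
stop codon; the Jukes–Cantor correction d = -(3/4)·ln(1 - (4/3)p) converts
proportions to rates.  Pairs are gapless equal-length codon sequences — the
pseudo-genome construction guarantees substitution-only alignments.

The standard nuclear genetic code is used throughout (via Biopython's codon
table).
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from ._seq import decode, encode, revcomp
from .simulate import Gene, Reference

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"
STOP_CODONS = tuple(standard_dna_table.stop_codons)
_BASES = "ACGT"

OK = "ok"
INSUFFICIENT = "insufficient_polymorphism"
SATURATED = "saturated"


def translate(codon: str) -> str:
    return _CODON_TABLE[codon]


# per-codon synonymous site count (sum over positions of the fraction of
# one-step changes preserving the amino acid; stops excluded as targets)
_SYN_SITES: dict[str, float] = {}
for _codon, _aa in _CODON_TABLE.items():
    if _aa == "*":
        continue
    s = 0.0
    for _i in range(3):
        for _b in _BASES:
            if _b == _codon[_i]:
                continue
            mut = _codon[:_i] + _b + _codon[_i + 1:]
            if _CODON_TABLE[mut] == _aa:  # change to stop is nonsynonymous
                s += 1 / 3
    _SYN_SITES[_codon] = s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences between two codons, averaged
    over minimal mutational pathways that avoid stop intermediates."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        through_stop = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if _CODON_TABLE[nxt] == "*" and nxt != c2:
                through_stop = True
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, through_stop))
    usable = [(s, n) for s, n, ts in paths if not ts]
    if not usable:
        warnings.warn(
            f"all pathways between {c1} and {c2} pass through a stop codon; "
            "averaging over the full enumeration", stacklevel=2)
        usable = [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    return sd, nd


_PAIR_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def _pair_counts_cached(c1: str, c2: str) -> tuple[float, float]:
    key = (c1, c2) if c1 <= c2 else (c2, c1)
    if key not in _PAIR_CACHE:
        _PAIR_CACHE[key] = _pathway_counts(*key)
    return _PAIR_CACHE[key]


@dataclass
class MolEvolEstimate:
    """Pairwise NG86 estimate for one gene."""

    gene_id: str
    sd: float  # observed synonymous differences (pathway-averaged)
    nd: float
    s_sites: float  # synonymous site count (pair-averaged)
    n_sites: float
    dn: float | None
    ds: float | None
    omega: float | None
    status: str
    n_codons: int = 0


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86_dnds(cds1: str, cds2: str, gene_id: str = "") -> MolEvolEstimate:
    """NG86 dN/dS between two gapless equal-length coding sequences.

    A trailing stop codon (in either sequence) is trimmed before counting;
    codon pairs containing an internal stop or a non-ACGT base are skipped.
    ``omega`` is reported only for status ``ok``: at least one observed
    difference and dS > 0 ("sufficient polymorphism"); proportions >= 0.75
    are flagged saturated (the correction diverges).
    """
    if len(cds1) != len(cds2):
        raise ValueError("coding sequences differ in length")
    if len(cds1) % 3:
        raise ValueError("length not divisible by 3")
    cod1 = [cds1[i:i + 3] for i in range(0, len(cds1), 3)]
    cod2 = [cds2[i:i + 3] for i in range(0, len(cds2), 3)]
    if cod1 and (cod1[-1] in STOP_CODONS or cod2[-1] in STOP_CODONS):
        cod1, cod2 = cod1[:-1], cod2[:-1]
    sd = nd = 0.0
    s1 = s2 = 0.0
    used = 0
    for c1, c2 in zip(cod1, cod2):
        if (c1 in STOP_CODONS or c2 in STOP_CODONS
                or any(b not in _BASES for b in c1 + c2)):
            continue
        used += 1
        s1 += _SYN_SITES[c1]
        s2 += _SYN_SITES[c2]
        psd, pnd = _pair_counts_cached(c1, c2)
        sd += psd
        nd += pnd
    s_sites = (s1 + s2) / 2
    n_sites = 3 * used - s_sites
    if used == 0 or sd + nd == 0:
        return MolEvolEstimate(gene_id, sd, nd, s_sites, n_sites,
                               0.0 if used else None, 0.0 if used else None,
                               None, INSUFFICIENT, used)
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = _jc(ps)
    dn = _jc(pn)
    if ds is None or dn is None:
        return MolEvolEstimate(gene_id, sd, nd, s_sites, n_sites, dn, ds,
                               None, SATURATED, used)
    if ds == 0:
        return MolEvolEstimate(gene_id, sd, nd, s_sites, n_sites, dn, ds,
                               None, INSUFFICIENT, used)
    return MolEvolEstimate(gene_id, sd, nd, s_sites, n_sites, dn, ds,
                           dn / ds, OK, used)


# ---------------------------------------------------------------------------
# pseudo-genomes and CDS extraction


@dataclass
class PseudoGenome:
    """The reference with one genome's diagnostic alleles substituted in."""

    seqs: dict[str, np.ndarray]
    substitutions: dict[str, tuple[np.ndarray, np.ndarray]]  # pos, allele

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.seqs[chrom]


def build_pseudo_genome(reference: Reference,
                        allele_map: dict[str, tuple[np.ndarray, np.ndarray]]
                        ) -> PseudoGenome:
    """Substitute alleles into the reference; pure substitution, reversible
    given the map.  ``allele_map``: chrom -> (positions, allele codes)."""
    seqs = {}
    for chrom, arr in reference.seqs.items():
        out = arr.copy()
        if chrom in allele_map:
            pos, allele = allele_map[chrom]
            if len(pos) and (pos.min() < 0 or pos.max() >= len(arr)):
                raise ValueError(f"substitution position out of range on {chrom}")
            out[pos] = allele
        seqs[chrom] = out
    return PseudoGenome(seqs, dict(allele_map))


def pseudo_genome_from_index(reference: Reference, index, genome: str = "A"
                             ) -> PseudoGenome:
    """Pseudo-A (or pseudo-D) genome from a SNP index."""
    allele_map = {}
    for chrom, (pos, aa, dd) in index.data.items():
        allele_map[chrom] = (pos, aa if genome == "A" else dd)
    return build_pseudo_genome(reference, allele_map)


class CdsError(ValueError):
    pass


def extract_cds(genome, gene: Gene) -> str:
    """Spliced CDS of a gene, reverse-complemented for minus-strand genes.

    ``genome`` is a Reference, PseudoGenome, or chrom->array mapping.
    A CDS whose length is not divisible by 3 is a :class:`CdsError` (callers
    skip and log such genes).
    """
    seqs = genome.seqs if hasattr(genome, "seqs") else genome
    arr = np.concatenate([seqs[gene.chrom][s:e] for s, e in gene.exons])
    if len(arr) % 3:
        raise CdsError(f"{gene.gene_id}: CDS length {len(arr)} not divisible by 3")
    if gene.strand == "-":
        arr = revcomp(arr)
    return decode(arr)


# ---------------------------------------------------------------------------
# start/stop codon screens


@dataclass
class StopCodonReport:
    gene_id: str
    finding: str  # premature_stop / disrupted_start / altered_stop / no_stop
    position_fraction: float  # position along the CDS, in (0, 1]
    within_last_10pct: bool


def find_premature_stops(cds: str, gene_id: str = "",
                         tail_fraction: float = 0.10) -> list[StopCodonReport]:
    """Every in-frame stop strictly before the final codon.

    ``within_last_10pct`` marks stops in the 3' tail (position fraction
    > 1 - tail_fraction); such stops are conventionally ignored as likely
    annotation artifacts.
    """
    n = len(cds) // 3
    out = []
    for i in range(n - 1):
        if cds[3 * i:3 * i + 3] in STOP_CODONS:
            frac = (i + 1) / n
            out.append(StopCodonReport(gene_id, "premature_stop", frac,
                                       frac > 1 - tail_fraction))
    return out


def find_start_stop_changes(cds_test: str, cds_reference: str,
                            gene_id: str = "") -> list[StopCodonReport]:
    """Disrupted starts, altered stops and missing annotated stops."""
    if len(cds_test) != len(cds_reference):
        raise ValueError("sequences differ in length")
    out = []
    n = len(cds_reference) // 3
    if n == 0:
        return out
    ref_start, test_start = cds_reference[:3], cds_test[:3]
    if translate(ref_start) != translate(test_start):
        out.append(StopCodonReport(gene_id, "disrupted_start", 1 / n, False))
    ref_last = cds_reference[-3:]
    test_last = cds_test[-3:]
    if ref_last not in STOP_CODONS:
        out.append(StopCodonReport(gene_id, "no_stop", 1.0, True))
    elif test_last not in STOP_CODONS:
        out.append(StopCodonReport(gene_id, "altered_stop", 1.0, True))
    return out


# ---------------------------------------------------------------------------
# per-gene driver


def gene_estimates(genome1, genome2, genes: list[Gene]
                   ) -> tuple[list[MolEvolEstimate], list[str]]:
    """NG86 estimates for every gene extractable from both genomes; returns
    (estimates, skipped gene ids)."""
    ests, skipped = [], []
    for g in genes:
        try:
            c1 = extract_cds(genome1, g)
            c2 = extract_cds(genome2, g)
        except CdsError:
            skipped.append(g.gene_id)
            continue
        ests.append(ng86_dnds(c1, c2, gene_id=g.gene_id))
    return ests, skipped


def write_estimates_tsv(estimates: list[MolEvolEstimate], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#gene\tsd\tnd\tS\tN\tdN\tdS\tomega\tstatus\n")
        for e in estimates:
            def fmt(x):
                return "NA" if x is None else f"{x:.6f}"
            fh.write(f"{e.gene_id}\t{e.sd:.4f}\t{e.nd:.4f}\t{e.s_sites:.2f}\t"
                     f"{e.n_sites:.2f}\t{fmt(e.dn)}\t{fmt(e.ds)}\t"
                     f"{fmt(e.omega)}\t{e.status}\n")
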