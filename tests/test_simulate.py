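"""Generator correctness: determinism, planted-variant accounting,
coordinate soundness and read/alignment consistency."""
from __future__ import annotations

import math

import numpy as np
import pysam
import pytest

from homeoscan import molevol as me
from homeoscan.simulate import (AT_BIASED, DT_BIASED, PlacementError,
                                SimConfig, ancestral_progenitors,
                                diverge_genomes, make_tetraploid,
                                physical_genome, simulate_cohort,
                                simulate_reads, simulate_reference,
                                write_cohort)

TINY = SimConfig(genome_length=50_000, n_chromosomes=1, n_genes=10,
                 deletion_count=2, duplication_count=1,
                 conversion_tract_count=2, seed=3)


def test_reference_genes_are_translatable():
    """Every generated gene must begin with ATG, end with a stop codon and
    contain no internal stop on its coding strand."""
    ref, genes = simulate_reference(TINY)
    assert len(genes) == TINY.n_genes
    ivs = sorted((g.chrom, g.start, g.end) for g in genes)
    for a, b in zip(ivs, ivs[1:]):
        assert a[0] != b[0] or a[2] <= b[1]  # non-overlapping
    for g in genes:
        cds = me.extract_cds(ref, g)
        assert len(cds) % 3 == 0
        assert cds[:3] == "ATG"
        assert cds[-3:] in me.STOP_CODONS
        assert not me.find_premature_stops(cds)


def test_zero_genes_gives_empty_annotation():
    ref, genes = simulate_reference(TINY.replace(n_genes=0))
    assert genes == []
    assert ref.total_length == TINY.genome_length


def test_outputs_byte_identical_under_same_seed(tmp_path):
    """The full file tree (FASTA, GFF3, FASTQ, SAM, truth) reproduces
    bit-for-bit under an identical configuration."""
    small = TINY.replace(coverage=5.0)
    for d in ("a", "b"):
        write_cohort(simulate_cohort(small), tmp_path / d)
    for rel in ("reference.fa", "genes.gff3", "A1.fastq", "A1.sam",
                "truth/homoeo_snps.tsv", "truth/regions.tsv"):
        assert (tmp_path / "a" / rel).read_bytes() == \
            (tmp_path / "b" / rel).read_bytes()


def test_planted_homoeo_count_matches_binomial_expectation(cohort, sim_cfg):
    deleted = sum(iv.length for iv in cohort.truth.conserved_deletions)
    n = sim_cfg.genome_length - deleted
    p = sim_cfg.homoeo_snp_rate
    mean, sd = n * p, math.sqrt(n * p * (1 - p))
    assert abs(cohort.truth.n_homoeo_snps() - mean) < 3 * sd


def test_heterozygosity_rate_contrast_between_groups():
    """With the study-style het-rate contrast (A >> D), planted het counts
    reproduce the ratio of the binomial means."""
    cfg = TINY.replace(het_rate_A=0.13, het_rate_D=0.003, n_genes=0,
                       deletion_count=0, duplication_count=0)
    _, _, truth = diverge_genomes(simulate_reference(cfg)[0], cfg)
    ratio = truth.n_het("A1") / truth.n_het("D1")
    assert 30 < ratio < 60  # binomial means ratio ~43


def test_zero_rates_give_reference_identical_accessions():
    cfg = TINY.replace(homoeo_snp_rate=0, allele_snp_rate_A=0,
                       allele_snp_rate_D=0, het_rate_A=0, het_rate_D=0,
                       deletion_count=0, duplication_count=0)
    ref, _ = simulate_reference(cfg)
    acc_a, acc_d, _ = diverge_genomes(ref, cfg)
    for acc in acc_a + acc_d:
        for chrom in ref.chroms:
            assert np.array_equal(acc.sequence(chrom, 0), ref[chrom])
            assert np.array_equal(acc.sequence(chrom, 1), ref[chrom])


def test_truth_substitutions_reconstruct_accessions(cohort):
    """Coordinate soundness: reference + truth records = accession
    haplotypes, exactly."""
    truth = cohort.truth
    for acc in cohort.accessions_a + cohort.accessions_d:
        for chrom in cohort.reference.chroms:
            seq = cohort.reference[chrom].copy()
            if acc.group == "A":
                pos, aa, _ = truth.homoeo_snps[chrom]
                seq[pos] = aa
            spos, salt = truth.allele_snps[acc.name][chrom]
            seq[spos] = salt
            assert np.array_equal(seq, acc.sequence(chrom, 0))
            hpos, halt = truth.het_sites[acc.name][chrom]
            seq = seq.copy()
            seq[hpos] = halt
            assert np.array_equal(seq, acc.sequence(chrom, 1))


def test_conversion_tract_homogenizes_subgenomes(cohort):
    at, dt = cohort.tetraploid_at, cohort.tetraploid_dt
    for t in cohort.truth.conversion_tracts:
        iv = t.interval
        a = at.sequence(iv.chrom)[iv.start:iv.end]
        d = dt.sequence(iv.chrom)[iv.start:iv.end]
        assert np.array_equal(a, d)


def test_tetraploid_without_changes_equals_progenitor():
    cfg = TINY.replace(tetraploid_autapomorphy_rate=0.0,
                       conversion_tract_count=0)
    ref, _ = simulate_reference(cfg)
    _, _, truth = diverge_genomes(ref, cfg)
    a_prog, d_prog = ancestral_progenitors(ref, truth)
    at, dt = make_tetraploid(a_prog, d_prog, cfg, truth)
    for chrom in ref.chroms:
        assert np.array_equal(at.sequence(chrom), a_prog.sequence(chrom))
        assert np.array_equal(dt.sequence(chrom), ref[chrom])


def test_tract_direction_bias_is_respected():
    cfg = SimConfig(genome_length=400_000, n_chromosomes=1, n_genes=0,
                    deletion_count=0, duplication_count=0,
                    conversion_tract_count=20, conversion_direction_bias=0.8,
                    conversion_tract_length_range=(1000, 2000), seed=11)
    ref, _ = simulate_reference(cfg)
    _, _, truth = diverge_genomes(ref, cfg)
    at, dt = make_tetraploid(*ancestral_progenitors(ref, truth), cfg, truth)
    n_dt = sum(t.direction == DT_BIASED for t in truth.conversion_tracts)
    assert len(truth.conversion_tracts) == 20
    assert 10 <= n_dt <= 20  # 16 +/- 3 binomial SD


def test_read_count_and_exactness_without_errors():
    cfg = TINY.replace(base_error_rate=0.0, coverage=3.0)
    ref, _ = simulate_reference(cfg)
    acc_a, _, truth = diverge_genomes(ref, cfg)
    phys = physical_genome(acc_a[0], ref)
    rs = simulate_reads(phys, cfg, stream=0)
    assert rs.n == math.ceil(cfg.coverage * phys.length / cfg.read_length)
    for i in range(0, rs.n, 97):
        if rs.chrom_idx[i] < 0:
            continue
        chrom = rs.chroms[rs.chrom_idx[i]]
        s = rs.ref_start[i]
        src = acc_a[0].sequence(chrom, int(rs.hap[i]))[s:s + rs.read_length]
        assert np.array_equal(rs.seqs[i], src)


def test_base_error_rate_recovered(cohort, sim_cfg):
    """Observed mismatch fraction against the source haplotype lies within
    3 binomial SDs of the configured error rate."""
    acc = cohort.accessions_d[0]
    rs = cohort.readsets[acc.name]
    mism = total = 0
    sel = np.flatnonzero(rs.chrom_idx >= 0)[:20000]
    for chrom_i, chrom in enumerate(rs.chroms):
        idx = sel[rs.chrom_idx[sel] == chrom_i]
        for h in (0, 1):
            ii = idx[rs.hap[idx] == h]
            if not len(ii):
                continue
            win = rs.ref_start[ii, None] + np.arange(rs.read_length)
            src = acc.sequence(chrom, h)[win]
            mism += int((rs.seqs[ii] != src).sum())
            total += src.size
    p = mism / total
    # a planted error can coincide with the original base? no: errors always
    # change the base, so p estimates the error rate directly
    sd = math.sqrt(sim_cfg.base_error_rate * (1 - sim_cfg.base_error_rate)
                   / total)
    assert abs(p - sim_cfg.base_error_rate) < 3 * sd


def test_breakpoint_reads_are_unmapped(cohort):
    """Reads crossing a planted deletion/duplication junction carry no
    reference placement; no mapped A-group read lies inside a deletion."""
    name = cohort.accessions_a[0].name
    rs = cohort.readsets[name]
    assert (rs.chrom_idx < 0).any()
    for iv in cohort.truth.conserved_deletions:
        ci = rs.chroms.index(iv.chrom)
        inside = ((rs.chrom_idx == ci) & (rs.ref_start >= iv.start)
                  & (rs.ref_start + rs.read_length <= iv.end))
        assert not inside.any()


def test_truth_sam_round_trips_through_pysam(tmp_path, cohort):
    rs = cohort.readsets[cohort.accessions_d[0].name]
    path = tmp_path / "d.sam"
    from homeoscan.simulate import write_truth_alignments

    write_truth_alignments(rs, cohort.reference, str(path))
    seen = 0
    with pysam.AlignmentFile(str(path)) as fh:
        assert list(fh.references) == cohort.reference.chroms
        for rec in fh:
            seen += 1
            i = int(rec.query_name.split(".")[-1])
            if rec.is_unmapped:
                assert rs.chrom_idx[i] < 0
            else:
                assert rec.reference_start == rs.ref_start[i]
                assert rec.cigarstring == f"{rs.read_length}M"
    assert seen == rs.n


def test_infeasible_gene_packing_raises():
    with pytest.raises(PlacementError):
        simulate_reference(SimConfig(genome_length=5_000, n_chromosomes=1,
                                     n_genes=10))


def test_invalid_rates_rejected():
    with pytest.raises(ValueError):
        SimConfig(base_error_rate=1.5).validate()
    with pytest.raises(ValueError):
        SimConfig(gene_length_range=(0, 10)).validate()
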