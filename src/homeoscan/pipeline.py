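"""End-to-end orchestration from a single configuration.

``run_all`` drives the stages in dependency order — pileup -> index ->
categorize -> structvar / conversion / molevol / phylo — from files on
disk, writing every output family plus a deterministic run manifest.
``demo`` first materialises a synthetic cohort and then runs the whole
pipeline on it.  All stage thresholds default to the study values and are
visible in one place (:class:`RunConfig`).
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from . import categorize as cat
from . import conversion as conv
from . import homoeosnp as hs
from . import molevol as me
from . import phylo as ph
from . import pileup as pu
from . import structvar as sv
from .regions import GenomicInterval
from .simulate import Gene, Reference, SimConfig, simulate_cohort, write_cohort

log = logging.getLogger("homeoscan")

ALL_STAGES = ("pileup", "index", "categorize", "structvar", "conversion",
              "molevol", "phylo")
_DEPS = {
    "pileup": (),
    "index": ("pileup",),
    "categorize": ("index",),
    "structvar": ("pileup",),
    "conversion": ("categorize", "structvar"),
    "molevol": ("index",),
    "phylo": ("pileup", "index"),
}


@dataclass
class RunConfig:
    """Paths, stage toggles and every stage threshold (study defaults)."""

    reference: str = ""
    annotation: str = ""
    groups_file: str = ""   # TSV: accession, group (A/D/tetraploid), sam path
    out_dir: str = "homeoscan_out"
    stages: dict = field(default_factory=lambda: {s: True for s in ALL_STAGES})
    min_depth: int = 10
    min_maf: float = 0.40
    sv_min_len: int = 1000
    sv_control_min: float = 20.0
    sv_test_lt: float = 3.0
    sv_interior_offset: int = 200
    conv_high_min: float = 15.0
    conv_low_lt: float = 4.0
    gene_overlap_min_frac: float = 0.5
    stop_tail_fraction: float = 0.10
    dup_window: int = 200
    dup_p_threshold: float = 1e-5
    dup_min_fold: float = 1.5
    read_length: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown configuration key {k!r}")
            if k == "stages":
                cfg.stages.update(v)
            else:
                setattr(cfg, k, v)
        return cfg


def read_groups(path: str) -> list[tuple[str, str, str]]:
    out = []
    base = os.path.dirname(os.path.abspath(path))
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            acc, group, sam = line.rstrip("\n").split("\t")
            if not os.path.isabs(sam):
                sam = os.path.join(base, sam)
            out.append((acc, group, sam))
    return out


def read_gff3(path: str) -> list[Gene]:
    """Reconstruct gene models (CDS exons, strand) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for g in db.features_of_type("gene"):
        exons = []
        for cds in db.children(g, featuretype="CDS", order_by="start"):
            exons.append((cds.start - 1, cds.end))
        if not exons:
            continue
        genes.append(Gene(g.id, g.seqid, g.start - 1, g.end, g.strand,
                          tuple(sorted(exons))))
    return genes


def _md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _resolve_stages(requested: dict) -> list[str]:
    enabled = []
    for s in ALL_STAGES:
        if not requested.get(s, True):
            log.info("stage %s disabled; skipping it and its dependents", s)
            continue
        if all(dep in enabled for dep in _DEPS[s]):
            enabled.append(s)
        else:
            log.info("stage %s skipped: upstream disabled", s)
    return enabled


def run_all(cfg: RunConfig) -> dict:
    """Run the configured stages; returns the manifest dictionary."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    for p, what in ((cfg.reference, "reference"), (cfg.annotation, "annotation"),
                    (cfg.groups_file, "groups file")):
        if not os.path.exists(p):
            raise FileNotFoundError(f"{what} not found: {p}")
    stages = _resolve_stages(cfg.stages)
    manifest: dict = {
        "tool": "homeoscan",
        "config": {k: v for k, v in asdict(cfg).items() if k != "stages"},
        "stages_run": stages,
        "inputs": {},
        "counts": {},
    }
    reference = Reference.read_fasta(cfg.reference)
    genes = read_gff3(cfg.annotation)
    groups = read_groups(cfg.groups_file)
    manifest["inputs"] = {os.path.basename(p): _md5(p)
                          for p in [cfg.reference, cfg.annotation]
                          + [sam for _, _, sam in groups]}
    lengths = reference.lengths
    diploids = [(a, g, p) for a, g, p in groups if g in ("A", "D")]
    tetras = [(a, g, p) for a, g, p in groups if g not in ("A", "D")]
    group_of = {a: g for a, g, _ in diploids}

    results: dict = {"reference": reference, "genes": genes}
    pileups: dict[str, dict[str, pu.PileupTable]] = {}
    coverages: dict[str, dict[str, pu.CoverageTrack]] = {}
    genotypes: dict[str, dict[str, hs.GenotypeArray]] = {}

    if "pileup" in stages:
        for acc, _, sam in diploids:
            pileups[acc] = pu.build_pileup(sam, lengths)
            coverages[acc] = pu.build_coverage(sam, lengths)
            genotypes[acc] = {c: hs.call_genotypes(pt, cfg.min_depth, cfg.min_maf)
                              for c, pt in pileups[acc].items()}
            log.info("pileup: %s done", acc)
        manifest["counts"]["accessions_piled"] = len(pileups)

    index = None
    if "index" in stages:
        index = hs.call_homoeo_snps(genotypes, group_of)
        index.write_tsv(os.path.join(cfg.out_dir, "homoeo_snp_index.tsv"))
        index.write_vcf(os.path.join(cfg.out_dir, "homoeo_snp_index.vcf"),
                        lengths)
        rep = hs.summary_report(index, reference.total_length)
        with open(os.path.join(cfg.out_dir, "index_summary.tsv"), "w") as fh:
            for k, v in rep.items():
                fh.write(f"{k}\t{v}\n")
        manifest["counts"]["homoeo_snps"] = len(index)
        log.info("index: %d homoeo-SNPs", len(index))

    sub_genotypes: dict[str, dict[str, hs.GenotypeArray]] = {}
    sub_coverage: dict[str, dict[str, pu.CoverageTrack]] = {}
    if "categorize" in stages and tetras:
        for acc, _, sam in tetras:
            paths, stats = cat.categorize_file(
                sam, index, os.path.join(cfg.out_dir, "categorized"),
                prefix=acc)
            manifest["counts"][f"categorized_{acc}"] = stats.counts
            for sub in ("A", "D"):
                pt = pu.build_pileup(paths[sub], lengths)
                sub_genotypes[f"{acc}.{sub}T"] = {
                    c: hs.call_genotypes(p, cfg.min_depth, cfg.min_maf)
                    for c, p in pt.items()}
                sub_coverage[f"{acc}.{sub}T"] = pu.build_coverage(paths[sub],
                                                                 lengths)
            log.info("categorize: %s -> %s", acc, stats.fractions)

    conserved_dels: list[GenomicInterval] = []
    conserved_dups: list[GenomicInterval] = []
    if "structvar" in stages:
        a_accs = [a for a, g, _ in diploids if g == "A"]
        d_accs = [a for a, g, _ in diploids if g == "D"]
        control = coverages[d_accs[0]]
        del_sets: dict[str, list[GenomicInterval]] = {}
        dup_sets: dict[str, list[GenomicInterval]] = {}
        for acc in a_accs + d_accs[1:]:
            dels, dups = [], []
            for chrom in lengths:
                dels += [r.interval for r in sv.detect_deletions(
                    coverages[acc][chrom], control[chrom], cfg.sv_min_len,
                    cfg.sv_control_min, cfg.sv_test_lt,
                    cfg.sv_interior_offset, accession=acc)]
                dups += [p.interval for p in sv.detect_duplications(
                    coverages[acc][chrom], control[chrom], cfg.dup_window,
                    p_threshold=cfg.dup_p_threshold,
                    min_fold=cfg.dup_min_fold,
                    read_length=cfg.read_length)]
            del_sets[acc] = dels
            dup_sets[acc] = dups
        conserved_dels = sv.conserved_regions(del_sets, a_accs, d_accs[1:],
                                              cfg.sv_min_len)
        conserved_dups = sv.conserved_regions(dup_sets, a_accs, d_accs[1:],
                                              cfg.sv_min_len)
        sv.write_bed(conserved_dels,
                     os.path.join(cfg.out_dir, "conserved_deletions.bed"))
        sv.write_bed(conserved_dups,
                     os.path.join(cfg.out_dir, "conserved_duplications.bed"))
        overlaps = sv.gene_overlap(conserved_dels, genes,
                                   cfg.gene_overlap_min_frac)
        with open(os.path.join(cfg.out_dir, "deleted_genes.tsv"), "w") as fh:
            fh.write("#gene\toverlap_fraction\tcomplete\n")
            for o in overlaps:
                fh.write(f"{o.gene_id}\t{o.overlap_fraction:.3f}\t"
                         f"{int(o.complete)}\n")
        manifest["counts"]["conserved_deletions"] = len(conserved_dels)
        manifest["counts"]["conserved_duplications"] = len(conserved_dups)
        manifest["counts"]["genes_deleted_ge_frac"] = len(overlaps)
        log.info("structvar: %d conserved deletions, %d duplications",
                 len(conserved_dels), len(conserved_dups))

    if "conversion" in stages and sub_coverage:
        acc = tetras[0][0]
        at_cov = sub_coverage[f"{acc}.AT"]
        dt_cov = sub_coverage[f"{acc}.DT"]
        at_gt = sub_genotypes[f"{acc}.AT"]
        dt_gt = sub_genotypes[f"{acc}.DT"]
        snp_calls = conv.detect_snp_conversions(index, at_gt, dt_gt)
        tetra_index = hs.call_homoeo_snps(
            {f"{acc}.AT": at_gt, f"{acc}.DT": dt_gt},
            {f"{acc}.AT": "A", f"{acc}.DT": "D"})
        regions: list[conv.ConversionRegion] = []
        for chrom in lengths:
            mask = conv.presence_mask(
                {a: coverages[a][chrom] for a, _, _ in diploids})
            regions += conv.detect_coverage_conversions(
                at_cov[chrom], dt_cov[chrom], mask, cfg.sv_min_len,
                cfg.conv_high_min, cfg.conv_low_lt)
        xtab = conv.crosstab_methods(snp_calls, regions, index, tetra_index)
        conv.write_regions_tsv(regions,
                               os.path.join(cfg.out_dir,
                                            "conversion_regions.tsv"))
        sv.write_bed([r.interval for r in regions],
                     os.path.join(cfg.out_dir, "conversion_regions.bed"),
                     [r.direction for r in regions])
        manifest["counts"]["method1_calls"] = len(
            [c for c in snp_calls if c.flag == conv.CLEAN])
        manifest["counts"]["method2_regions"] = len(regions)
        manifest["counts"]["index_snps_in_regions"] = (
            xtab.total_index_snps_in_regions)
        manifest["counts"]["still_homoeo_in_regions"] = (
            xtab.total_still_homoeo_in_tetraploid)
        log.info("conversion: %d method-1 calls, %d method-2 regions",
                 manifest["counts"]["method1_calls"], len(regions))

    if "molevol" in stages:
        pseudo_a = me.pseudo_genome_from_index(reference, index, "A")
        ests, skipped = me.gene_estimates(pseudo_a, reference, genes)
        me.write_estimates_tsv(ests,
                               os.path.join(cfg.out_dir, "dnds_a_vs_d.tsv"))
        stops = []
        for g in genes:
            try:
                cds_a = me.extract_cds(pseudo_a, g)
                cds_d = me.extract_cds(reference, g)
            except me.CdsError:
                continue
            stops += me.find_premature_stops(cds_a, g.gene_id,
                                             cfg.stop_tail_fraction)
            stops += me.find_start_stop_changes(cds_a, cds_d, g.gene_id)
        with open(os.path.join(cfg.out_dir, "stop_codon_report.tsv"), "w") as fh:
            fh.write("#gene\tfinding\tposition_fraction\twithin_last_10pct\n")
            for srep in stops:
                fh.write(f"{srep.gene_id}\t{srep.finding}\t"
                         f"{srep.position_fraction:.3f}\t"
                         f"{int(srep.within_last_10pct)}\n")
        manifest["counts"]["genes_estimated"] = len(ests)
        manifest["counts"]["genes_skipped_cds"] = len(skipped)
        log.info("molevol: %d genes estimated", len(ests))

    if "phylo" in stages:
        all_gt = dict(genotypes)
        all_gt.update(sub_genotypes)
        gm = ph.matrix_from_genotypes(all_gt, conserved_dups)
        dm = ph.pairwise_distances(gm)
        dm.write_phylip(os.path.join(cfg.out_dir, "distances.phy"))
        tree = ph.neighbor_joining(dm)
        with open(os.path.join(cfg.out_dir, "tree.nwk"), "w") as fh:
            fh.write(tree.newick() + "\n")
        het = ph.heterozygosity_summary(gm, genes)
        with open(os.path.join(cfg.out_dir, "heterozygosity.tsv"), "w") as fh:
            fh.write("#taxon\tn_het\tpct\tgenic_n\tgenic_pct\t"
                     "nongenic_n\tnongenic_pct\n")
            for taxon, row in het.items():
                fh.write(f"{taxon}\t{row['genome']['n']}\t"
                         f"{row['genome']['pct']:.2f}\t{row['genic']['n']}\t"
                         f"{row['genic']['pct']:.2f}\t{row['nongenic']['n']}\t"
                         f"{row['nongenic']['pct']:.2f}\n")
        clades = {"All A": [a for a, g, _ in diploids if g == "A"],
                  "All D": [a for a, g, _ in diploids if g == "D"]}
        for a, _, _ in diploids:
            clades[a] = [a]
        for sub in sub_genotypes:
            clades[sub] = [sub]
        attrib = ph.attribute_snps_to_branches(gm, clades)
        with open(os.path.join(cfg.out_dir, "branch_snps.tsv"), "w") as fh:
            fh.write("#branch\tsnps\n")
            for label, n in attrib.items():
                fh.write(f"{label}\t{n}\n")
        manifest["counts"]["polymorphic_sites"] = gm.n_sites
        log.info("phylo: %d taxa, %d sites", len(gm.taxa), gm.n_sites)

    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def demo(out_dir: str, sim_cfg: SimConfig | None = None,
         run_cfg: RunConfig | None = None) -> dict:
    """Build a synthetic cohort and run the whole pipeline on its files."""
    if sim_cfg is None:
        sim_cfg = SimConfig(genome_length=150_000, n_chromosomes=1,
                            n_genes=30, coverage=40.0, deletion_count=3,
                            duplication_count=2, conversion_tract_count=3,
                            seed=0)
    data_dir = os.path.join(out_dir, "data")
    cohort = simulate_cohort(sim_cfg)
    write_cohort(cohort, data_dir)
    cfg = run_cfg or RunConfig()
    cfg.reference = os.path.join(data_dir, "reference.fa")
    cfg.annotation = os.path.join(data_dir, "genes.gff3")
    cfg.groups_file = os.path.join(data_dir, "groups.tsv")
    cfg.out_dir = os.path.join(out_dir, "results")
    cfg.read_length = sim_cfg.read_length
    cfg.seed = sim_cfg.seed
    return run_all(cfg)
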