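"""Distance scoring, neighbor-joining (with an independent NJ cross-check),
branch attribution and heterozygosity summaries."""
from __future__ import annotations

import numpy as np
import pytest

from homeoscan import phylo as ph
from homeoscan.simulate import Gene

from _util import genotype_array

A, C, G, T = 0, 1, 2, 3


def gm_from_rows(rows: dict[str, list], mask=None) -> ph.GenotypeMatrix:
    """rows: taxon -> list of (a1, a2) or None per site."""
    taxa = list(rows)
    n_sites = len(next(iter(rows.values())))
    geno = np.full((len(taxa), n_sites, 2), -1, dtype=np.int8)
    for t, calls in enumerate(rows.values()):
        for s, call in enumerate(calls):
            if call is not None:
                geno[t, s] = call
    chroms = np.array(["chr1"] * n_sites, dtype=object)
    pos = np.arange(n_sites, dtype=np.int64)
    return ph.GenotypeMatrix(taxa, chroms, pos, geno,
                             None if mask is None else np.asarray(mask))


def test_distance_scoring_rules():
    gm = gm_from_rows({
        "x": [(A, A)] * 10,
        "y": [(C, C), (G, G)] + [(A, A)] * 8,
    })
    dm = ph.pairwise_distances(gm)
    assert dm.values[0, 1] == pytest.approx(0.20)
    same = gm_from_rows({"x": [(A, A)] * 5, "y": [(A, A)] * 5})
    assert ph.pairwise_distances(same).values[0, 1] == 0.0


def test_het_scoring_half_vs_strict():
    gm = gm_from_rows({"x": [(A, A)], "y": [(A, G)]})
    assert ph.pairwise_distances(gm, "half").values[0, 1] == 0.5
    assert ph.pairwise_distances(gm, "strict").values[0, 1] == 1.0
    # identical hets are identical genotypes
    gm2 = gm_from_rows({"x": [(A, G)], "y": [(A, G)]})
    assert ph.pairwise_distances(gm2).values[0, 1] == 0.0


def test_missing_sites_excluded_and_empty_overlap_raises():
    gm = gm_from_rows({"x": [(A, A), None, (C, C)],
                       "y": [(A, A), (G, G), None]})
    assert ph.pairwise_distances(gm).values[0, 1] == 0.0
    gm2 = gm_from_rows({"x": [(A, A), None], "y": [None, (G, G)]})
    with pytest.raises(ValueError):
        ph.pairwise_distances(gm2)


ADDITIVE = ph.DistanceMatrix(
    ["A", "B", "C", "D"],
    np.array([[0, 3, 6, 7], [3, 0, 7, 8], [6, 7, 0, 3], [7, 8, 3, 0]],
             dtype=float))


def test_nj_recovers_additive_four_taxon_tree():
    """The classic additive matrix: split AB|CD, internal edge 4, leaf
    edges (1, 2, 1, 2)."""
    tree = ph.neighbor_joining(ADDITIVE)
    assert tree.splits() == {frozenset({frozenset({"A", "B"}),
                                        frozenset({"C", "D"})})}
    edges = {}

    def walk(node, parent_len=None):
        if not node.children:
            edges[node.name] = parent_len
        for child, bl in node.children:
            walk(child, bl)
        if node.children and parent_len is not None:
            edges["internal"] = parent_len

    walk(tree.root)
    assert edges["A"] == pytest.approx(1.0)
    assert edges["B"] == pytest.approx(2.0)
    assert edges["C"] == pytest.approx(1.0)
    assert edges["D"] == pytest.approx(2.0)
    assert edges["internal"] == pytest.approx(4.0)


def test_nj_three_taxa_closed_form():
    dm = ph.DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]],
                                    dtype=float))
    tree = ph.neighbor_joining(dm)
    lens = {c.name: bl for c, bl in tree.root.children}
    assert lens == {"a": pytest.approx(1.0), "b": pytest.approx(3.0),
                    "c": pytest.approx(5.0)}


def test_nj_invariant_under_taxon_permutation():
    perm = [2, 0, 3, 1]
    taxa = [ADDITIVE.taxa[i] for i in perm]
    vals = ADDITIVE.values[np.ix_(perm, perm)]
    t1 = ph.neighbor_joining(ADDITIVE)
    t2 = ph.neighbor_joining(ph.DistanceMatrix(taxa, vals))
    assert t1.splits() == t2.splits()


def test_nj_agrees_with_independent_implementation():
    """Cross-check the topology against scikit-bio's NJ on a noisy
    tree-like 6-taxon matrix."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    rng = np.random.default_rng(8)
    # distances generated from a known tree with mild noise
    base = {"a": 0.0, "b": 0.02, "c": 0.35, "d": 0.37, "e": 0.80, "f": 0.83}
    taxa = list(base)
    n = len(taxa)
    vals = np.zeros((n, n))
    tree_dist = {
        ("a", "b"): 0.04, ("a", "c"): 0.30, ("a", "d"): 0.32,
        ("b", "c"): 0.30, ("b", "d"): 0.32, ("c", "d"): 0.06,
        ("a", "e"): 0.60, ("a", "f"): 0.62, ("b", "e"): 0.60,
        ("b", "f"): 0.62, ("c", "e"): 0.58, ("c", "f"): 0.60,
        ("d", "e"): 0.58, ("d", "f"): 0.60, ("e", "f"): 0.05,
    }
    for (x, y), d in tree_dist.items():
        i, j = taxa.index(x), taxa.index(y)
        noisy = d * (1 + 0.02 * rng.standard_normal())
        vals[i, j] = vals[j, i] = noisy
    mine = ph.neighbor_joining(ph.DistanceMatrix(taxa, vals))
    ref = nj(SkbioDM(vals, ids=taxa))
    ref_splits = set()
    for node in ref.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < n - 1:
            ref_splits.add(frozenset({side, frozenset(taxa) - side}))
    assert mine.splits() == ref_splits


def test_nj_rejects_asymmetric_matrix():
    with pytest.raises(ValueError):
        ph.DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], dtype=float))


def test_branch_attribution_patterns():
    gm = gm_from_rows({
        "A1": [(T, T), (G, G), (T, T), (A, A)],
        "A2": [(T, T), (A, A), (T, T), (A, A)],
        "D1": [(C, C), (A, A), (C, C), (A, A)],
        "D2": [(C, C), (A, A), (T, T), (A, A)],
    })
    clades = {"All A": ["A1", "A2"], "A2": ["A2"], "All D": ["D1", "D2"]}
    counts = ph.attribute_snps_to_branches(gm, clades)
    # site 0: A group vs D group -> "All A" (and complementarily All D;
    # both clades match the same bipartition, each counts it)
    assert counts["All A"] == 1 and counts["All D"] == 1
    # site 1: only A1 differs; no 'A1' clade defined -> unassigned
    # site 2: splits the D clade -> unassigned; site 3: monomorphic
    assert counts["A2"] == 0
    assert counts["unassigned"] == 2
    assert counts["total"] == 3


def test_attribution_conservation(cohort, diploid_genotypes, tetra_split):
    all_gt = dict(diploid_genotypes)
    all_gt["Tetra.AT"] = tetra_split["AT"]["genotypes"]
    all_gt["Tetra.DT"] = tetra_split["DT"]["genotypes"]
    gm = ph.matrix_from_genotypes(all_gt)
    clades = {"All A": ["A1", "A2"], "All D": ["D1", "D2"],
              "A1": ["A1"], "A2": ["A2"], "D1": ["D1"], "D2": ["D2"],
              "AT": ["Tetra.AT"], "DT": ["Tetra.DT"]}
    counts = ph.attribute_snps_to_branches(gm, clades)
    # conservation: assigned + unassigned = total polymorphic unmasked sites
    assert counts["assigned"] + counts["unassigned"] == counts["total"]
    per_clade = sum(v for k, v in counts.items()
                    if k not in ("total", "unassigned", "assigned"))
    assert counts["assigned"] <= per_clade  # clades may share a pattern
    assert counts["assigned"] > 0


def test_clade_must_be_subset_of_taxa():
    gm = gm_from_rows({"x": [(A, A)], "y": [(C, C)]})
    with pytest.raises(ValueError):
        ph.attribute_snps_to_branches(gm, {"bad": ["z"]})


def test_heterozygosity_summary_arithmetic():
    rows = {"x": [(A, G)] * 5 + [(A, A)] * 45,
            "y": [(A, A)] * 50}
    gm = gm_from_rows(rows)
    genes = [Gene("g1", "chr1", 0, 2, "+", ((0, 2),))]
    het = ph.heterozygosity_summary(gm, genes)
    x = het["x"]
    assert x["genome"]["n"] == 5
    assert x["genome"]["pct"] == pytest.approx(10.0)
    assert x["genic"]["n"] == 2
    assert x["nongenic"]["n"] == 3
    assert het["y"]["genome"]["n"] == 0


def test_group_heterozygosity_contrast_on_cohort(cohort, diploid_genotypes):
    """A-group accessions are far more heterozygous than D-group ones
    (>10x), mirroring the planted rate contrast."""
    gm = ph.matrix_from_genotypes(diploid_genotypes)
    het = ph.heterozygosity_summary(gm)
    pct = {t: het[t]["genome"]["pct"] for t in gm.taxa}
    assert min(pct["A1"], pct["A2"]) > 10 * max(pct["D1"], pct["D2"])


def test_cohort_tree_groups_subgenomes_with_their_progenitors(
        cohort, diploid_genotypes, tetra_split):
    """Parameter recovery: NJ on the cohort distance matrix separates the
    A-side taxa (diploids + A_T) from the D-side taxa."""
    all_gt = dict(diploid_genotypes)
    all_gt["Tetra.AT"] = tetra_split["AT"]["genotypes"]
    all_gt["Tetra.DT"] = tetra_split["DT"]["genotypes"]
    gm = ph.matrix_from_genotypes(all_gt)
    dm = ph.pairwise_distances(gm)
    tree = ph.neighbor_joining(dm)
    expect = frozenset({frozenset({"A1", "A2", "Tetra.AT"}),
                        frozenset({"D1", "D2", "Tetra.DT"})})
    assert expect in tree.splits()


def test_distances_scale_with_planted_divergence():
    """Doubling the fixed-difference rate doubles the A-vs-D distance."""
    from homeoscan.simulate import SimConfig, diverge_genomes, \
        simulate_reference

    dists = []
    for rate in (0.01, 0.02):
        cfg = SimConfig(genome_length=80_000, n_chromosomes=1, n_genes=0,
                        homoeo_snp_rate=rate, deletion_count=0,
                        duplication_count=0, conversion_tract_count=0,
                        het_rate_A=0.001, het_rate_D=0.001,
                        allele_snp_rate_A=0.001, allele_snp_rate_D=0.001,
                        seed=31)
        ref, _ = simulate_reference(cfg)
        acc_a, acc_d, truth = diverge_genomes(ref, cfg)
        # genotypes straight from the truth haplotypes (no sequencing)
        from homeoscan.homoeosnp import GenotypeArray

        gts = {}
        for acc in acc_a + acc_d:
            h0 = acc.sequence("chr01", 0).astype(np.int8)
            h1 = acc.sequence("chr01", 1).astype(np.int8)
            gts[acc.name] = {"chr01": GenotypeArray(
                "chr01", np.minimum(h0, h1), np.maximum(h0, h1),
                np.full(len(h0), 40))}
        gm = ph.matrix_from_genotypes(gts)
        dm = ph.pairwise_distances(gm)
        i, j = gm.taxa.index("A1"), gm.taxa.index("D1")
        # distances are per polymorphic site; rescale to per-base
        per_base = dm.values[i, j] * gm.n_sites / cfg.genome_length
        dists.append(per_base)
    assert dists[1] / dists[0] == pytest.approx(2.0, rel=0.15)
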