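"""Distances, neighbor-joining and branch-attributed SNP summaries.

The distance between two taxa is the mean per-site score over sites where
both have genotype calls: identical genotypes score 0, homozygous calls for
different bases score 1, and differing genotypes that still share an allele
(a het against one of its own alleles) score 0.5 by default (switchable to
strict 0/1).  Neighbor-joining is the standard Saitou–Nei agglomeration
with deterministic tie-breaking by taxon name and negative branch lengths
clamped to zero with the deficit moved to the sibling edge.

The tetraploid subgenomes enter the matrix as two separate taxa.  Branch
attribution is performed against a supplied clade structure (the accepted
topology), not against the inferred tree.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regions import GenomicInterval

MISSING = -1


class GenotypeMatrix:
    """Taxa x sites genotypes: allele-pair codes with -1 = missing.

    ``geno`` has shape (n_taxa, n_sites, 2); homozygous sites repeat the
    allele.  ``mask`` marks excluded sites (e.g. within conserved
    duplications); masked sites are never used downstream.
    """

    def __init__(self, taxa: list[str], chroms: np.ndarray, positions: np.ndarray,
                 geno: np.ndarray, mask: np.ndarray | None = None):
        n_taxa, n_sites, two = geno.shape
        if two != 2 or n_taxa != len(taxa) or n_sites != len(positions):
            raise ValueError("genotype matrix shape mismatch")
        self.taxa = list(taxa)
        self.chroms = np.asarray(chroms)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.geno = geno
        self.mask = (np.zeros(n_sites, dtype=bool) if mask is None
                     else np.asarray(mask, dtype=bool))

    @property
    def n_sites(self) -> int:
        return self.geno.shape[1]

    def called(self, t: int) -> np.ndarray:
        return self.geno[t, :, 0] >= 0

    def is_het(self, t: int) -> np.ndarray:
        return (self.geno[t, :, 0] >= 0) & (self.geno[t, :, 0] != self.geno[t, :, 1])


def matrix_from_genotypes(genotype_arrays: dict[str, dict[str, "GenotypeArray"]],
                          masked_regions: list[GenomicInterval] = (),
                          ) -> GenotypeMatrix:
    """Collect the polymorphic sites across taxa into a matrix.

    ``genotype_arrays``: taxon -> chrom -> GenotypeArray (from the genotype
    caller).  Sites where at least two called taxa disagree (or any taxon is
    het) enter the matrix; sites inside ``masked_regions`` are masked.
    """
    taxa = list(genotype_arrays)
    chroms = list(next(iter(genotype_arrays.values())).keys())
    all_chrom, all_pos, cols = [], [], []
    for chrom in chroms:
        a1 = np.stack([genotype_arrays[t][chrom].a1 for t in taxa])
        a2 = np.stack([genotype_arrays[t][chrom].a2 for t in taxa])
        called = a1 >= 0
        lo = np.where(called, a1, 127).min(axis=0)
        hi = np.where(called, a1, -1).max(axis=0)
        any_het = ((a1 != a2) & called).any(axis=0)
        poly = (called.sum(axis=0) >= 2) & ((lo != hi) | any_het)
        pos = np.flatnonzero(poly)
        all_chrom.append(np.full(len(pos), chrom, dtype=object))
        all_pos.append(pos.astype(np.int64))
        cols.append(np.stack([a1[:, pos], a2[:, pos]], axis=2))
    chrom_arr = np.concatenate(all_chrom)
    pos_arr = np.concatenate(all_pos)
    geno = np.concatenate(cols, axis=1)
    mask = np.zeros(len(pos_arr), dtype=bool)
    for iv in masked_regions:
        mask |= (chrom_arr == iv.chrom) & (pos_arr >= iv.start) & (pos_arr < iv.end)
    return GenotypeMatrix(taxa, chrom_arr, pos_arr, geno, mask)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.values = v

    def write_phylip(self, path: str) -> None:
        """Lower-triangular PHYLIP format with 10-character names."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for i, t in enumerate(self.taxa):
                row = " ".join(f"{self.values[i, j]:.6f}" for j in range(i))
                fh.write(f"{t[:10]:<10}{(' ' + row) if row else ''}\n")


def pairwise_distances(gm: GenotypeMatrix, het_scoring: str = "half"
                       ) -> DistanceMatrix:
    """Mean per-site difference score over co-called unmasked sites."""
    if len(gm.taxa) < 2:
        raise ValueError("need at least two taxa")
    if het_scoring not in ("half", "strict"):
        raise ValueError("het_scoring must be 'half' or 'strict'")
    n = len(gm.taxa)
    unmasked = ~gm.mask
    vals = np.zeros((n, n))
    for i in range(n):
        gi = gm.geno[i]
        ci = gi[:, 0] >= 0
        for j in range(i + 1, n):
            gj = gm.geno[j]
            both = ci & (gj[:, 0] >= 0) & unmasked
            if not both.any():
                raise ValueError(
                    f"no co-observed sites for {gm.taxa[i]} and {gm.taxa[j]}")
            same = (gi[:, 0] == gj[:, 0]) & (gi[:, 1] == gj[:, 1])
            share = ((gi[:, 0:1] == gj[:, 0:2]) | (gi[:, 1:2] == gj[:, 0:2])
                     ).any(axis=1)
            if het_scoring == "half":
                score = np.where(same, 0.0, np.where(share, 0.5, 1.0))
            else:
                score = np.where(same, 0.0, 1.0)
            vals[i, j] = vals[j, i] = score[both].mean()
    return DistanceMatrix(gm.taxa, vals)


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class TreeNode:
    name: str | None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c._nwk()}:{bl:.6f}" for c, bl in self.children)
        return f"({inner})" + (self.name or "")


@dataclass
class PhyloTree:
    root: TreeNode

    @property
    def taxa(self) -> list[str]:
        return sorted(self.root.leaves())

    def newick(self) -> str:
        return self.root.newick()

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions (as the smaller-side leaf sets are not
        canonical, each split is the frozenset of one side's leaves together
        with its complement)."""
        all_leaves = frozenset(self.root.leaves())
        out = set()

        def walk(node):
            if not node.children:
                return frozenset([node.name])
            below = frozenset()
            for c, _ in node.children:
                side = walk(c)
                if 1 < len(side) < len(all_leaves) - 1:
                    out.add(frozenset({side, all_leaves - side}))
                below = below | side
            return below

        walk(self.root)
        return out


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei NJ with the standard Q criterion.

    Ties in Q break on the sorted pair of taxon names (for internal nodes,
    the lexicographically smallest descendant leaf).  A negative branch
    length is clamped to zero and its deficit moved onto the sibling edge.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least three taxa")
    d = dm.values.astype(float).copy()
    nodes = [TreeNode(t) for t in dm.taxa]
    labels = [t for t in dm.taxa]  # tie-break keys
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                key = (q[ii, jj], *sorted((labels[active[ii]],
                                           labels[active[jj]])))
                if best is None or key < best[0]:
                    best = (key, ii, jj)
        _, ii, jj = best
        i, j = active[ii], active[jj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ii] - r[jj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = TreeNode(None, [(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to the remaining taxa
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        for uu in active:
            if uu in (i, j):
                continue
            d[k, uu] = d[uu, k] = 0.5 * (d[i, uu] + d[j, uu] - dij)
        nodes.append(new)
        labels.append(min(labels[i], labels[j]))
        active = [u for u in active if u not in (i, j)] + [k]
    # resolve the final three nodes around an unrooted center
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    lens = [max(x, 0.0) for x in (la, lb, lc)]
    order = sorted(range(3), key=lambda t: labels[active[t]])
    root = TreeNode(None, [(nodes[active[t]], lens[t]) for t in order])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# branch attribution and heterozygosity


def attribute_snps_to_branches(gm: GenotypeMatrix,
                               clades: dict[str, list[str]]
                               ) -> dict[str, int]:
    """Count sites whose allele pattern matches exactly one labeled clade.

    A site is attributed to clade C when all members of C are called and
    homozygous for one shared allele, every other called taxon is homozygous
    for a single different allele, and no called taxon is heterozygous.
    All other patterns fall into ``unassigned``.  The returned dict also
    carries ``unassigned`` and ``total`` (polymorphic unmasked sites
    considered).
    """
    for label, members in clades.items():
        if not set(members) <= set(gm.taxa):
            raise ValueError(f"clade {label!r} is not a subset of the taxa")
    idx = {t: k for k, t in enumerate(gm.taxa)}
    n_taxa = len(gm.taxa)
    a1 = gm.geno[:, :, 0]
    a2 = gm.geno[:, :, 1]
    called = a1 >= 0
    hom = called & (a1 == a2)
    any_het = (called & (a1 != a2)).any(axis=0)
    unmasked = ~gm.mask
    lo = np.where(called, a1, 127).min(axis=0)
    hi = np.where(called, a1, -1).max(axis=0)
    polymorphic = unmasked & (called.sum(axis=0) >= 2) & ((lo != hi) | any_het)
    usable = polymorphic & ~any_het & (~called | hom).all(axis=0)
    counts = {label: 0 for label in clades}
    assigned = np.zeros(gm.n_sites, dtype=bool)
    for label, members in clades.items():
        mem = np.zeros(n_taxa, dtype=bool)
        mem[[idx[t] for t in members]] = True
        others = ~mem
        mem_called = called[mem].all(axis=0)
        # one shared allele inside the clade
        in_lo = np.where(called[mem], a1[mem], 127).min(axis=0)
        in_hi = np.where(called[mem], a1[mem], -1).max(axis=0)
        out_called = called[others]
        out_lo = np.where(out_called, a1[others], 127).min(axis=0)
        out_hi = np.where(out_called, a1[others], -1).max(axis=0)
        out_any = out_called.any(axis=0)
        hit = (usable & mem_called & (in_lo == in_hi) & out_any
               & (out_lo == out_hi) & (in_lo != out_lo))
        counts[label] = int(hit.sum())
        assigned |= hit
    counts["assigned"] = int(assigned.sum())
    counts["unassigned"] = int((polymorphic & ~assigned).sum())
    counts["total"] = int(polymorphic.sum())
    return counts


def heterozygosity_summary(gm: GenotypeMatrix,
                           genes: list | None = None) -> dict[str, dict]:
    """Per-taxon heterozygous-site counts and percentages, split by gene
    membership.  Denominators are each taxon's observable (called, unmasked)
    sites within the partition."""
    genic = np.zeros(gm.n_sites, dtype=bool)
    if genes:
        for g in genes:
            genic |= ((gm.chroms == g.chrom) & (gm.positions >= g.start)
                      & (gm.positions < g.end))
    unmasked = ~gm.mask
    out = {}
    for k, taxon in enumerate(gm.taxa):
        called = gm.called(k) & unmasked
        het = gm.is_het(k) & unmasked

        def cell(sel):
            obs = int((called & sel).sum())
            n = int((het & sel).sum())
            return {"n": n, "observable": obs,
                    "pct": 100.0 * n / obs if obs else 0.0}

        out[taxon] = {
            "genome": cell(np.ones(gm.n_sites, dtype=bool)),
            "genic": cell(genic),
            "nongenic": cell(~genic),
        }
    return out
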