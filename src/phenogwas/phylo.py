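"""Region phylogenetics: biallelic SNPs -> pseudo-alignment -> NJ tree.

Biallelic SNPs in a genomic region (1-based inclusive coordinates) are
extracted from a haploid VCF and concatenated into a pseudo-alignment, one
character per locus per strain: the reference base, the alternate base, or a
gap for missing calls. Pairwise p-distances (mismatches over comparable
sites, gaps pairwise-deleted) feed a classical Saitou-Nei neighbor-joining
agglomeration. On an additive distance matrix NJ recovers the generating
topology and branch lengths exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class PseudoAlignment:
    """Per-strain character strings over an ordered list of SNP loci."""

    loci: list[tuple[str, int]]  # (chrom, 1-based pos), strictly increasing
    sequences: dict[str, str]  # strain -> string over loci (ref/alt base or gap)

    def __post_init__(self):
        n = len(self.loci)
        for strain, seq in self.sequences.items():
            if len(seq) != n:
                raise ValueError(f"sequence length mismatch for {strain}")
        positions = [p for _, p in self.loci]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("loci must be strictly increasing in position")

    @property
    def strains(self) -> list[str]:
        return list(self.sequences)

    def to_fasta(self, path: str | Path) -> None:
        lines = []
        for strain, seq in self.sequences.items():
            lines.append(f">{strain}")
            lines.append(seq)
        Path(path).write_text("\n".join(lines) + "\n")


def extract_region_biallelic(
    vcf_path: str | Path, chrom: str, start: int, end: int
) -> PseudoAlignment:
    """Pseudo-alignment of the biallelic SNPs in ``chrom:start-end``.

    Coordinates are 1-based inclusive. Only sites with a single-base REF and
    exactly one single-base ALT are kept; indels and multiallelic records are
    dropped. Missing calls become gap characters.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    strains = list(vcf.samples)
    loci: list[tuple[str, int]] = []
    columns: list[list[str]] = []
    for rec in vcf:
        if rec.CHROM != chrom or not (start <= rec.POS <= end):
            continue
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue
        alleles = (rec.REF, rec.ALT[0])
        col = []
        for gt in rec.genotypes:
            allele = gt[0]
            col.append(alleles[allele] if allele in (0, 1) else GAP)
        loci.append((rec.CHROM, rec.POS))
        columns.append(col)
    if not loci:
        raise ValueError(f"no biallelic SNPs in {chrom}:{start}-{end}")
    order = np.argsort([p for _, p in loci], kind="stable")
    loci = [loci[i] for i in order]
    columns = [columns[i] for i in order]
    sequences = {
        strain: "".join(columns[j][i] for j in range(len(loci)))
        for i, strain in enumerate(strains)
    }
    return PseudoAlignment(loci=loci, sequences=sequences)


def pairwise_distance(aln: PseudoAlignment) -> DistanceMatrix:
    """p-distance matrix with pairwise deletion of gap positions.

    distance = mismatches / sites where both strains have a base. A pair with
    zero comparable sites is an error.
    """
    strains = aln.strains
    if len(strains) < 3:
        raise ValueError("need at least 3 strains for a distance matrix")
    chars = np.array([list(aln.sequences[s]) for s in strains])
    present = chars != GAP
    n = len(strains)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise ValueError(
                    f"no comparable sites between {strains[i]} and {strains[j]}"
                )
            mismatches = int((chars[i][both] != chars[j][both]).sum())
            d[i, j] = d[j, i] = mismatches / comparable
    return DistanceMatrix(d, ids=strains)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classical Saitou-Nei neighbor joining, deterministic.

    Agglomerates on the Q-matrix; ties are broken by the lexicographically
    smallest pair of current node labels (internal nodes are labelled by the
    sorted concatenation of their leaf labels). Negative branch lengths are
    clamped to zero and the clamped deficit logged. Returns an unrooted tree
    (trifurcating root) as an skbio TreeNode.
    """
    d = np.asarray(dm.data, dtype=float)
    if d.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValueError("distance matrix must be non-negative")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    # sort key per active node: lexicographically smallest pair wins ties
    keys: list[str] = [str(i) for i in dm.ids]
    active = list(range(len(nodes)))
    d = d.copy()
    clamped_total = 0.0

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((keys[active[a]], keys[active[b]]))), a, b)
            for a, b in ties
            if a < b
        )
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = d[i, j]
        li = 0.5 * dij + (row_sums[ai] - row_sums[bi]) / (2.0 * (r - 2))
        lj = dij - li
        for node, length in ((nodes[i], li), (nodes[j], lj)):
            if length < 0:
                clamped_total += -length
        li, lj = max(li, 0.0), max(lj, 0.0)
        nodes[i].length, nodes[j].length = float(li), float(lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_key = min(keys[i], keys[j])
        # distances from the new node to every other active node
        others = [k for k in active if k not in (i, j)]
        new_d = {k: 0.5 * (d[i, k] + d[j, k] - dij) for k in others}
        nodes.append(parent)
        keys.append(new_key)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k, v in new_d.items():
            d[-1, k] = d[k, -1] = max(v, 0.0)
        active = others + [len(nodes) - 1]

    # final three nodes join at an unrooted (trifurcating) center
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for length in (la, lb, lc):
        if length < 0:
            clamped_total += -length
    nodes[a].length = float(max(la, 0.0))
    nodes[b].length = float(max(lb, 0.0))
    nodes[c].length = float(max(lc, 0.0))
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    if clamped_total > 0:
        logger.info(
            "clamped negative NJ branch lengths; total deficit %.3g", clamped_total
        )
    return root


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def leaf_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the leaf set, for topology comparison.

    Each internal edge splits the leaves in two; the smaller-side-sorted
    frozenset of one side identifies the split regardless of rooting.
    """
    leaves = frozenset(leaf.name for leaf in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            splits.add(min(side, leaves - side, key=sorted))
    return splits


def path_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (sum of branch lengths)."""
    return tree.tip_tip_distances()


def region_tree(
    vcf_path: str | Path, chrom: str, start: int, end: int
) -> tuple[PseudoAlignment, DistanceMatrix, TreeNode]:
    """Full region pipeline: extract SNPs, distances, NJ tree."""
    aln = extract_region_biallelic(vcf_path, chrom, start, end)
    dm = pairwise_distance(aln)
    return aln, dm, neighbor_joining(dm)
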