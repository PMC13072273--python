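"""Gene screening by phylogenetic concordance.

Short PCR markers must sit in genes whose local genealogy tracks the species
tree, otherwise a "diagnostic" allele may reflect a discordant gene history.
The screen keeps genes whose longest transcript exceeds 2 kb, rebuilds each
gene's tree from per-sample consensus sequences, and ranks genes by
Robinson-Foulds distance to the species tree; low-RF genes become targets.

Gene trees are neighbor-joining on pairwise p-distance.  NJ is deterministic
and fast at the panel-design scale, and the screening signal is topological
concordance, not branch-length accuracy; externally computed Newick gene
trees can be supplied instead for parity with likelihood-based workflows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .io_formats import GeneModel, VariantTable, MISSING

logger = logging.getLogger(__name__)

# two-allele sets -> IUPAC ambiguity code
IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
_COMP = str.maketrans("ACGTRYSWKMN", "TGCAYRSWMKN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class GeneAlignment:
    gene_id: str
    sequences: dict[str, str]  # sample -> equal-length sequence

    def __post_init__(self) -> None:
        lens = {len(s) for s in self.sequences.values()}
        if len(lens) > 1:
            raise ValueError(f"unequal sequence lengths in {self.gene_id}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))


@dataclass
class GeneScreenRecord:
    gene_id: str
    transcript_len: int
    rf_distance: int
    rank: int = 0


def select_long_transcript_genes(genes: Sequence[GeneModel],
                                 min_len: int = 2000) -> list[GeneModel]:
    """Keep genes whose longest transcript strictly exceeds ``min_len`` bp."""
    return [g for g in genes if g.longest_transcript_len > min_len]


def build_sample_consensus(sample: str, gene: GeneModel,
                           ref: Mapping[str, str], vt: VariantTable) -> str:
    """Longest-transcript consensus sequence for one sample.

    Exons of the longest transcript are concatenated in genomic order with
    the sample's homozygous alternate SNPs substituted and heterozygous sites
    written as IUPAC ambiguity codes; minus-strand transcripts are
    reverse-complemented.  Indel alleles are skipped with a warning.
    """
    contig = ref[gene.contig]
    _, exons = gene.longest_transcript
    col = vt.samples.index(sample)
    # variants on this contig keyed by 1-based position
    on_contig = np.flatnonzero(vt.contig == gene.contig)
    by_pos: dict[int, int] = {int(vt.pos[i]): int(i) for i in on_contig}

    parts: list[str] = []
    for start, end in exons:
        if start < 1 or end > len(contig):
            raise ValueError(f"exon {start}-{end} outside contig {gene.contig}")
        seq = list(contig[start - 1:end])
        for p in range(start, end + 1):
            i = by_pos.get(p)
            if i is None:
                continue
            alleles = (vt.ref[i], *vt.alt[i])
            a, b = vt.genotypes[i, col]
            if a == MISSING or b == MISSING:
                continue
            ba, bb = alleles[a], alleles[b]
            if len(ba) != 1 or len(bb) != 1 or len(vt.ref[i]) != 1:
                logger.warning("indel at %s:%d skipped in consensus",
                               gene.contig, p)
                continue
            if ba == bb:
                base = ba
            else:
                base = IUPAC[frozenset((ba, bb))]
            seq[p - start] = base
        parts.append("".join(seq))
    out = "".join(parts)
    return revcomp(out) if gene.strand == "-" else out


def build_gene_alignment(gene: GeneModel, ref: Mapping[str, str],
                         vt: VariantTable) -> GeneAlignment:
    return GeneAlignment(gene.gene_id, {
        s: build_sample_consensus(s, gene, ref, vt) for s in vt.samples})


def p_distance_matrix(aln: GeneAlignment) -> DistanceMatrix:
    """Pairwise p-distance; ambiguous/N columns excluded per pair."""
    names = list(aln.sequences)
    arr = np.array([list(aln.sequences[n]) for n in names])
    plain = np.isin(arr, list("ACGT"))
    n = len(names)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        ok = plain[i] & plain[j]
        denom = int(ok.sum())
        dij = float((arr[i, ok] != arr[j, ok]).sum() / denom) if denom else 0.0
        d[i, j] = d[j, i] = dij
    return DistanceMatrix(d, names)


def build_gene_tree(aln: GeneAlignment) -> TreeNode:
    """Neighbor-joining tree on p-distance; star-like input is flagged."""
    if len(aln.sequences) < 4:
        raise ValueError("gene tree needs >= 4 samples")
    dm = p_distance_matrix(aln)
    if np.allclose(dm.data, 0.0):
        logger.warning("all sequences identical for %s: star topology",
                       aln.gene_id)
    tree = nj(dm)
    # NJ can emit tiny negative branch lengths; clamp for downstream writers
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------

def _bipartitions(tree: TreeNode, leaves: frozenset[str]) -> set[frozenset[frozenset[str]]]:
    """Non-trivial bipartitions of an unrooted tree, as side-set pairs."""
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(frozenset((side, other)))
    return out


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """RF distance: bipartitions present in exactly one tree.

    Both trees are pruned to their shared leaf set first (>= 4 leaves
    required for a defined comparison).
    """
    l1 = {t.name for t in t1.tips()}
    l2 = {t.name for t in t2.tips()}
    shared = frozenset(l1 & l2)
    if len(shared) < 4:
        raise ValueError("RF needs >= 4 shared leaves")
    if shared != l1:
        t1 = t1.shear(shared)
    if shared != l2:
        t2 = t2.shear(shared)
    b1 = _bipartitions(t1, shared)
    b2 = _bipartitions(t2, shared)
    return len(b1 ^ b2)


def species_tree_from_alignments(alignments: Sequence[GeneAlignment]) -> TreeNode:
    """NJ species tree from the concatenation of screened gene alignments."""
    samples = list(alignments[0].sequences)
    concat = {s: "".join(a.sequences[s] for a in alignments) for s in samples}
    return build_gene_tree(GeneAlignment("concatenated", concat))


def screen_genes(genes: Sequence[GeneModel], ref: Mapping[str, str],
                 vt: VariantTable, species_tree: TreeNode | None = None,
                 min_len: int = 2000) -> tuple[list[GeneScreenRecord], TreeNode]:
    """Length filter, gene trees, and RF ranking against the species tree.

    If no species tree is supplied one is built by NJ on the concatenated
    screened transcripts.  Returns records sorted by (RF, -length, gene id)
    with 1-based ranks, plus the species tree used.
    """
    kept = select_long_transcript_genes(genes, min_len)
    if not kept:
        raise ValueError("no gene passes the transcript-length filter")
    alignments = [build_gene_alignment(g, ref, vt) for g in kept]
    if species_tree is None:
        species_tree = species_tree_from_alignments(alignments)
    records = []
    for g, aln in zip(kept, alignments):
        tree = build_gene_tree(aln)
        rf = robinson_foulds(tree, species_tree)
        records.append(GeneScreenRecord(g.gene_id, g.longest_transcript_len, rf))
    records.sort(key=lambda r: (r.rf_distance, -r.transcript_len, r.gene_id))
    for i, r in enumerate(records, start=1):
        r.rank = i
    return records, species_tree


def correlate_length_rf(records: Sequence[GeneScreenRecord]) -> tuple[float, float]:
    """Pearson r (and two-sided p) between transcript length and RF distance."""
    if len(records) < 3:
        raise ValueError("correlation needs >= 3 records")
    x = np.array([r.transcript_len for r in records], dtype=float)
    y = np.array([r.rf_distance for r in records], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in length or RF")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def select_target_genes(records: Sequence[GeneScreenRecord],
                        quantile: float = 0.25,
                        rf_max: int | None = None) -> set[str]:
    """Gene ids in the lowest-RF quantile (or under an absolute RF cutoff).

    The quantile threshold is inclusive, so RF ties at the boundary are all
    selected; with ``rf_max`` set the absolute cutoff takes precedence.
    """
    if not records:
        return set()
    if rf_max is not None:
        return {r.gene_id for r in records if r.rf_distance <= rf_max}
    rfs = np.array([r.rf_distance for r in records], dtype=float)
    cut = np.quantile(rfs, quantile)
    return {r.gene_id for r in records if r.rf_distance <= cut}


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")
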