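"""Synthetic reference, annotation, genotype and mtDNA generator with planted
population structure and diagnostic sites.

The generator emulates the study conditions every other module expects: a
handful of geographically isolated populations from a hierarchical split
(two clades, Balding-Nichols-style drift of allele frequencies), a compact
annotated reference with long (>2 kb transcript) and short genes, planted
population-diagnostic fixed differences inside the exons of designated
target genes, and a mitochondrial alignment whose haplotype sharing pattern
is configured explicitly.  It is a frequency model, not a genealogical
simulator: there is no recombination map, linkage, or coalescent history.

All outputs are reproducible bit-exact from (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (GeneModel, PopulationMap, VariantTable,
                         write_fasta, write_population_map,
                         write_variant_table)

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study-scale scenario: 3 populations x 8 samples, 10 planted diagnostic
    sites per population at focal HAF 1.0 with opposite fixation elsewhere,
    2000 background SNPs with hierarchical drift structure."""

    seed: int = 0
    n_pops: int = 3
    samples_per_pop: int = 8
    contig_length: int = 60_000
    n_genes: int = 6
    n_target_genes: int = 2
    transcript_len: int = 2_400
    n_background_sites: int = 2_000
    n_planted_per_pop: int = 10
    planted_focal_haf: float = 1.0
    background_maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    mt_len: int = 16_545
    mt_haplotypes_per_pop: int = 2
    mt_shared_haplotype_pairs: tuple[tuple[str, str], ...] = (("pop2", "pop3"),)
    # drift intensities (Fst-like) of the two-level population tree
    clade_fst: float = 0.15
    pop_fst: float = 0.05
    # background SNP density in exons relative to intergenic sequence
    # (purifying selection keeps exons comparatively invariant)
    exon_background_fraction: float = 0.2
    # amplicon flank kept clear of contig ends for planted sites
    flank_margin: int = 900
    # optional extras
    include_outgroup: bool = False
    outgroup_samples: int = 4
    # the outgroup stands in for a separate species: strongly drifted, hence
    # nearly fixed at most sites that are polymorphic within the ingroup
    outgroup_fst: float = 0.2
    geneflow: tuple[str, str, float] | None = None  # (donor, recipient, frac)

    @property
    def pop_labels(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_pops)]


@dataclass
class SimScenario:
    """In-memory result of a full simulation."""

    config: SimConfig
    reference: dict[str, str]
    genes: list[GeneModel]
    target_gene_ids: list[str]
    variant_table: VariantTable
    population_map: PopulationMap
    truth: list[tuple[str, int, str, str]]  # (contig, pos, focal pop, allele)
    mt_alignment: dict[str, str]


# ---------------------------------------------------------------------------
# Reference + annotation
# ---------------------------------------------------------------------------

def simulate_reference_and_annotation(cfg: SimConfig, rng: np.random.Generator
                                      ) -> tuple[dict[str, str], list[GeneModel]]:
    """Random reference contig and gene models.

    Genes are laid out left to right with generous margins; target/long genes
    get two transcripts (the longest summing ``transcript_len`` > 2000 bp),
    short genes a single transcript of half that length.  Strands alternate
    to exercise reverse-complement consensus extraction.
    """
    n_long = max(cfg.n_target_genes, cfg.n_genes - max(1, cfg.n_genes // 3))
    gene_span = 4_000
    gap = 2_000
    needed = 2 * cfg.flank_margin + 200 + cfg.n_genes * (gene_span + gap)
    if cfg.contig_length < needed:
        raise ValueError(f"contig_length {cfg.contig_length} cannot pack "
                         f"{cfg.n_genes} genes (need >= {needed})")
    seq = "".join(rng.choice(BASES, size=cfg.contig_length))
    genes: list[GeneModel] = []
    cursor = cfg.flank_margin + 100
    exon = cfg.transcript_len // 3
    for k in range(cfg.n_genes):
        gid = f"gene{k + 1:02d}"
        strand = "+" if k % 2 == 0 else "-"
        start = cursor
        if k < n_long:
            # three exons with introns; a shorter second transcript
            e1 = (start, start + exon - 1)
            e2 = (start + exon + 400, start + 2 * exon + 399)
            e3 = (start + 2 * exon + 800, start + 3 * exon + 799)
            transcripts = [(f"{gid}.t1", [e1, e2, e3]),
                           (f"{gid}.t2", [e1, e2])]
        else:
            half = cfg.transcript_len // 4
            e1 = (start, start + half - 1)
            e2 = (start + half + 300, start + 2 * half + 299)
            transcripts = [(f"{gid}.t1", [e1, e2])]
        genes.append(GeneModel(gene_id=gid, contig="chr1", strand=strand,
                               transcripts=transcripts))
        cursor = start + gene_span + gap
    return {"chr1": seq}, genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        exons_all = g.exon_intervals()
        lo, hi = min(s for s, _ in exons_all), max(e for _, e in exons_all)
        lines.append(f"{g.contig}\tsnptrace\tgene\t{lo}\t{hi}\t.\t{g.strand}"
                     f"\t.\tID={g.gene_id}")
        for tid, exons in g.transcripts:
            tlo, thi = min(s for s, _ in exons), max(e for _, e in exons)
            lines.append(f"{g.contig}\tsnptrace\tmRNA\t{tlo}\t{thi}\t.\t"
                         f"{g.strand}\t.\tID={tid};Parent={g.gene_id}")
            for n, (s, e) in enumerate(exons, start=1):
                lines.append(f"{g.contig}\tsnptrace\texon\t{s}\t{e}\t.\t"
                             f"{g.strand}\t.\tID={tid}.e{n};Parent={tid}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _drift(p: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols draw of a descendant allele frequency."""
    if fst <= 0:
        return p
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    return np.clip(rng.beta(np.maximum(a, 1e-3), np.maximum(b, 1e-3)),
                   0.01, 0.99)


def simulate_population_genotypes(cfg: SimConfig, reference: dict[str, str],
                                  genes: Sequence[GeneModel],
                                  rng: np.random.Generator
                                  ) -> tuple[VariantTable, PopulationMap,
                                             list[tuple[str, int, str, str]],
                                             list[str]]:
    """Planted diagnostic sites + structured background SNPs.

    Background allele frequencies drift down a two-clade population tree;
    each background site is guaranteed at least one heterozygous called
    genotype, so no background site can pass an opposite-fixation screen at
    HAF threshold 1.0.  Planted sites are fully genotyped with the focal
    population homozygous-alternate at ``planted_focal_haf`` (heterozygous
    remainder) and every other population homozygous-reference.
    """
    contig = "chr1"
    seq = reference[contig]
    pops = cfg.pop_labels
    samples = [f"{p}_s{i + 1}" for p in pops for i in range(cfg.samples_per_pop)]
    assignments = {f"{p}_s{i + 1}": p for p in pops
                   for i in range(cfg.samples_per_pop)}
    if cfg.include_outgroup:
        for i in range(cfg.outgroup_samples):
            samples.append(f"outgroup_s{i + 1}")
            assignments[f"outgroup_s{i + 1}"] = "outgroup"
    pm = PopulationMap(assignments)
    n_samples = len(samples)
    pop_cols = {p: np.array([k for k, s in enumerate(samples)
                             if assignments[s] == p]) for p in pm.populations}

    # -- position pools ----------------------------------------------------
    target_ids = [g.gene_id for g in genes[:cfg.n_target_genes]]
    target_exon_pos: list[int] = []
    for g in genes[:cfg.n_target_genes]:
        for s, e in g.longest_transcript[1]:
            target_exon_pos.extend(range(s, e + 1))
    target_exon_pos = [p for p in target_exon_pos
                       if cfg.flank_margin < p <= len(seq) - cfg.flank_margin]
    exonic = np.zeros(len(seq) + 1, dtype=bool)
    for g in genes:
        for s, e in g.exon_intervals():
            exonic[s:e + 1] = True

    n_planted = cfg.n_planted_per_pop * cfg.n_pops
    planted_pos = np.sort(rng.choice(target_exon_pos, size=n_planted,
                                     replace=False))
    pool = np.setdiff1d(np.arange(1, len(seq) + 1), planted_pos)
    keep = rng.random(pool.size) <= np.where(exonic[pool],
                                             cfg.exon_background_fraction, 1.0)
    pool = pool[keep]
    bg_pos = np.sort(rng.choice(pool, size=cfg.n_background_sites,
                                replace=False))

    # -- planted sites -----------------------------------------------------
    planted_rows = []
    truth: list[tuple[str, int, str, str]] = []
    focal_cycle = [pops[i % cfg.n_pops] for i in range(n_planted)]
    rng.shuffle(focal_cycle)
    for pos, focal in zip(planted_pos, focal_cycle):
        ref_base = seq[pos - 1]
        alt_base = rng.choice([b for b in "ACGT" if b != ref_base])
        g = np.zeros((n_samples, 2), dtype=np.int8)
        cols = pop_cols[focal]
        n_hom = int(np.ceil(cfg.planted_focal_haf * len(cols)))
        hom_cols = rng.permutation(cols)[:n_hom]
        het_cols = np.setdiff1d(cols, hom_cols)
        g[hom_cols] = 1
        g[het_cols, 1] = 1
        planted_rows.append((int(pos), ref_base, alt_base, g))
        truth.append((contig, int(pos), focal, alt_base))

    # -- background sites --------------------------------------------------
    bg_rows = []
    n_clade_a = int(np.ceil(cfg.n_pops / 2))
    for pos in bg_pos:
        ref_base = seq[pos - 1]
        alt_base = rng.choice([b for b in "ACGT" if b != ref_base])
        minor = rng.uniform(*cfg.background_maf_range)
        p0 = minor if rng.random() < 0.5 else 1.0 - minor
        p_clade = {0: _drift(np.array(p0), cfg.clade_fst, rng),
                   1: _drift(np.array(p0), cfg.clade_fst, rng)}
        freqs = {}
        for i, pop in enumerate(pops):
            clade = 0 if i < n_clade_a else 1
            freqs[pop] = float(_drift(p_clade[clade], cfg.pop_fst, rng))
        if cfg.include_outgroup:
            freqs["outgroup"] = float(_drift(np.array(p0), cfg.outgroup_fst,
                                             rng))
        if cfg.geneflow is not None:
            donor, recipient, frac = cfg.geneflow
            if rng.random() < frac:
                freqs[recipient] = freqs[donor]
        g = np.zeros((n_samples, 2), dtype=np.int8)
        for pop, cols in pop_cols.items():
            draws = rng.random((len(cols), 2)) < freqs[pop]
            g[cols] = draws.astype(np.int8)
        # missingness on background calls only
        if cfg.missing_rate > 0:
            miss = rng.random(n_samples) < cfg.missing_rate
            g[miss] = -1
        # construction bound: at least one called heterozygote per site, so
        # no background site is oppositely fixed at HAF threshold 1.0
        dosage = g.sum(axis=1)
        called = np.all(g != -1, axis=1)
        if not np.any(called & (dosage == 1)):
            cand = np.flatnonzero(called)
            if cand.size == 0:
                g[:] = 0
                g[0, 1] = 1
            else:
                g[rng.choice(cand)] = (0, 1)
        bg_rows.append((int(pos), ref_base, alt_base, g))

    rows = sorted(planted_rows + bg_rows, key=lambda r: r[0])
    n_sites = len(rows)
    geno = np.stack([r[3] for r in rows])
    info = {
        "QD": rng.uniform(15, 35, n_sites),
        "MQ": rng.uniform(50, 60, n_sites),
        "FS": rng.uniform(0, 5, n_sites),
        "HaplotypeScore": rng.uniform(0, 5, n_sites),
        "MQRankSum": rng.uniform(-2, 2, n_sites),
        "ReadPosRankSum": rng.uniform(-2, 2, n_sites),
    }
    vt = VariantTable(
        samples=samples,
        contig=np.array([contig] * n_sites, dtype=object),
        pos=np.array([r[0] for r in rows], dtype=np.int64),
        ref=np.array([r[1] for r in rows], dtype=object),
        alt=[(r[2],) for r in rows],
        genotypes=geno,
        info=info,
    )
    return vt, pm, truth, target_ids


# ---------------------------------------------------------------------------
# mtDNA
# ---------------------------------------------------------------------------

def simulate_mt_haplotypes(cfg: SimConfig, pm: PopulationMap,
                           rng: np.random.Generator) -> dict[str, str]:
    """Aligned mitogenome per sample with a configured sharing pattern.

    Each population carries ``mt_haplotypes_per_pop`` haplotypes derived from
    a population backbone (10 private backbone mutations) by 3 further
    private mutations each; for every configured shared pair (A, B) the
    first haplotype of B is replaced by the first haplotype of A.  Mutated
    positions are disjoint across haplotypes, so all non-shared haplotypes
    are distinct by construction.
    """
    if cfg.mt_len < 100:
        raise ValueError("mt_len must be >= 100")
    ancestral = "".join(rng.choice(BASES, size=cfg.mt_len))
    pops = [p for p in pm.populations]
    n_slots = len(pops) * (10 + 3 * cfg.mt_haplotypes_per_pop)
    positions = rng.choice(cfg.mt_len, size=n_slots, replace=False)
    cursor = 0

    def mutate(seq: str, k: int) -> str:
        nonlocal cursor
        s = list(seq)
        for _ in range(k):
            p = positions[cursor]
            cursor += 1
            s[p] = {"A": "G", "G": "A", "C": "T", "T": "C"}[s[p]]
        return "".join(s)

    pool: dict[str, list[str]] = {}
    for pop in pops:
        backbone = mutate(ancestral, 10)
        pool[pop] = [mutate(backbone, 3)
                     for _ in range(cfg.mt_haplotypes_per_pop)]
    for a, b in cfg.mt_shared_haplotype_pairs:
        if a in pool and b in pool:
            pool[b][0] = pool[a][0]
    out = {}
    for pop in pops:
        members = pm.members(pop)
        for i, sample in enumerate(members):
            out[sample] = pool[pop][i % len(pool[pop])]
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate_scenario(cfg: SimConfig | None = None) -> SimScenario:
    """Run the full generator from ``cfg.seed``."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    reference, genes = simulate_reference_and_annotation(cfg, rng)
    vt, pm, truth, target_ids = simulate_population_genotypes(
        cfg, reference, genes, rng)
    mt = simulate_mt_haplotypes(cfg, pm, rng)
    return SimScenario(config=cfg, reference=reference, genes=genes,
                       target_gene_ids=target_ids, variant_table=vt,
                       population_map=pm, truth=truth, mt_alignment=mt)


def write_scenario(scn: SimScenario, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, GFF3, VCF, popmap, mt alignment and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fasta",
        "gff": outdir / "annotation.gff3",
        "vcf": outdir / "variants.vcf",
        "popmap": outdir / "popmap.txt",
        "mt": outdir / "mt_alignment.fasta",
        "truth": outdir / "planted_truth.tsv",
    }
    write_fasta(scn.reference, paths["reference"])
    write_gff3(scn.genes, paths["gff"])
    write_variant_table(scn.variant_table, paths["vcf"])
    write_population_map(scn.population_map, paths["popmap"])
    write_fasta(scn.mt_alignment, paths["mt"])
    lines = ["contig\tpos\tfocal_pop\tfocal_allele"]
    lines += [f"{c}\t{p}\t{pop}\t{a}" for c, p, pop, a in scn.truth]
    paths["truth"].write_text("\n".join(lines) + "\n")
    return paths
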