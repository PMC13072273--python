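"""Readers, writers and variant filters for the formats the pipeline touches.

The in-memory variant container is :class:`VariantTable`: a site-major numpy
genotype array plus per-site INFO annotations.  Coordinates are 1-based closed
at the I/O surface (VCF/GFF convention); internal helpers that slice numpy
arrays or reference strings convert to 0-based half-open at the boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: INFO keys consumed by the hard filters, in canonical order.
HARD_FILTER_KEYS = ("QD", "MQ", "FS", "HaplotypeScore", "MQRankSum", "ReadPosRankSum")

MISSING = -1


class FormatError(ValueError):
    """Malformed input file (VCF/GFF/popmap)."""


@dataclass(frozen=True)
class HardFilterThresholds:
    """Variant-quality and frequency cutoffs.

    Hard-filter inequalities are strict as conventionally printed (a site with
    QD exactly 2.0 survives); minor-allele-frequency and call-rate bounds are
    inclusive (vcftools semantics).
    """

    qd_min: float = 2.0
    mq_min: float = 40.0
    fs_max: float = 60.0
    haplotype_score_max: float = 13.0
    mq_rank_sum_min: float = -12.5
    read_pos_rank_sum_min: float = -8.0
    maf_min: float = 0.05
    call_rate_min: float = 0.9

    def __post_init__(self) -> None:
        vals = [self.qd_min, self.mq_min, self.fs_max, self.haplotype_score_max,
                self.mq_rank_sum_min, self.read_pos_rank_sum_min,
                self.maf_min, self.call_rate_min]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all thresholds must be finite")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")
        if not 0.0 <= self.call_rate_min <= 1.0:
            raise ValueError("call_rate_min must lie in [0, 1]")


@dataclass
class VariantTable:
    """Samples x sites diploid genotype table with per-site INFO annotations.

    Attributes
    ----------
    samples : list of str
        Unique sample identifiers; column order is fixed across sites.
    contig, pos, ref : numpy arrays, one entry per site
        ``pos`` is 1-based.
    alt : list of tuples
        Alternate alleles per site; biallelic sites have a single entry.
    genotypes : int8 array of shape (n_sites, n_samples, 2)
        Allele indices (0 = ref); ``-1`` marks a missing allele.
    info : dict of str -> float array
        Per-site numeric annotations; ``nan`` where absent.
    """

    samples: list[str]
    contig: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: list[tuple[str, ...]]
    genotypes: np.ndarray
    info: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("duplicated sample identifiers")
        if np.any(self.pos <= 0):
            raise FormatError("positions must be strictly positive")
        n_alleles = 1 + np.array([len(a) for a in self.alt])
        if np.any(self.genotypes >= n_alleles[:, None, None]):
            raise FormatError("genotype allele index out of range")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def is_biallelic(self) -> np.ndarray:
        return np.array([len(a) == 1 for a in self.alt])

    def take(self, index: np.ndarray) -> "VariantTable":
        """Subset sites by boolean mask or integer index, order preserved."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return VariantTable(
            samples=self.samples,
            contig=self.contig[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=[self.alt[i] for i in index],
            genotypes=self.genotypes[index],
            info={k: v[index] for k, v in self.info.items()},
        )

    def called_mask(self) -> np.ndarray:
        """(n_sites, n_samples) bool: genotype fully called."""
        return np.all(self.genotypes != MISSING, axis=2)

    def alt_dosage(self) -> np.ndarray:
        """(n_sites, n_samples) float alt-allele dosage, nan where missing.

        Defined for biallelic sites; allele indices > 1 would distort dosages.
        """
        g = self.genotypes.astype(float)
        g[g == MISSING] = np.nan
        return g.sum(axis=2)

    def allele_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt frequency, call rate) over non-missing alleles."""
        called = self.genotypes != MISSING
        n_called_alleles = called.sum(axis=(1, 2))
        alt_count = ((self.genotypes > 0) & called).sum(axis=(1, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(n_called_alleles > 0, alt_count / n_called_alleles, np.nan)
        call_rate = np.all(called, axis=2).mean(axis=1)
        return af, call_rate


@dataclass(frozen=True)
class PopulationMap:
    """sample id -> population label."""

    assignments: Mapping[str, str]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p, None)
        return list(seen)

    def members(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def sample_indices(self, vt: VariantTable) -> dict[str, np.ndarray]:
        """Population -> array of column indices into ``vt.samples``."""
        col = {s: i for i, s in enumerate(vt.samples)}
        out: dict[str, list[int]] = {p: [] for p in self.populations}
        for s, p in self.assignments.items():
            if s in col:
                out[p].append(col[s])
        return {p: np.array(ix, dtype=int) for p, ix in out.items()}


@dataclass
class GeneModel:
    """Gene with transcripts given as ordered lists of 1-based closed exons."""

    gene_id: str
    contig: str
    strand: str
    transcripts: list[tuple[str, list[tuple[int, int]]]]

    @property
    def longest_transcript_len(self) -> int:
        return max(self._tlen(exons) for _, exons in self.transcripts)

    @property
    def longest_transcript(self) -> tuple[str, list[tuple[int, int]]]:
        # deterministic tie-break: longest, then lexicographic transcript id
        return max(self.transcripts, key=lambda t: (self._tlen(t[1]), t[0]))

    def exon_intervals(self) -> list[tuple[int, int]]:
        """Union of exon intervals over all transcripts (unmerged)."""
        out = []
        for _, exons in self.transcripts:
            out.extend(exons)
        return out

    @staticmethod
    def _tlen(exons: Sequence[tuple[int, int]]) -> int:
        return sum(e - s + 1 for s, e in exons)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_variant_table(path: str | Path, multiallelic: str = "split") -> VariantTable:
    """Read a VCF into a :class:`VariantTable`.

    Parameters
    ----------
    multiallelic : {"split", "drop", "keep"}
        ``split`` (default) expands a k-allele record into k biallelic records
        at the same position; genotype alleles referring to a *different* alt
        become missing in each split record.  ``drop`` discards multiallelic
        records; ``keep`` retains them verbatim.
    """
    if multiallelic not in ("split", "drop", "keep"):
        raise ValueError(f"unknown multiallelic policy {multiallelic!r}")
    path = str(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise FormatError("VCF has no sample columns (GT field required)")
    if len(set(samples)) != len(samples):
        raise FormatError("duplicated sample ids in VCF header")

    contigs: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[tuple[str, ...]] = []
    geno: list[np.ndarray] = []
    info: dict[str, list[float]] = {k: [] for k in HARD_FILTER_KEYS}

    def push(record, alts: tuple[str, ...], g: np.ndarray) -> None:
        contigs.append(record.CHROM)
        pos.append(record.POS)
        ref.append(record.REF)
        alt.append(alts)
        geno.append(g)
        for k in HARD_FILTER_KEYS:
            v = record.INFO.get(k)
            info[k].append(np.nan if v is None else float(v))

    for rec in vcf:
        raw = rec.genotypes
        if raw is None:
            raise FormatError(f"record {rec.CHROM}:{rec.POS} lacks GT")
        g = np.array([[a if a is not None and a >= 0 else MISSING for a in gt[:2]]
                      for gt in raw], dtype=np.int8)
        alts = tuple(rec.ALT)
        if len(alts) <= 1 or multiallelic == "keep":
            push(rec, alts, g)
        elif multiallelic == "drop":
            continue
        else:  # split
            for k, a in enumerate(alts, start=1):
                gk = g.copy()
                other = (gk > 0) & (gk != k)
                gk[other] = MISSING
                gk[gk == k] = 1
                push(rec, (a,), gk)

    n = len(pos)
    return VariantTable(
        samples=samples,
        contig=np.array(contigs, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=alt,
        genotypes=(np.stack(geno) if n else
                   np.empty((0, len(samples), 2), dtype=np.int8)),
        info={k: np.array(v, dtype=float) for k, v in info.items()},
    )


def write_variant_table(vt: VariantTable, path: str | Path) -> None:
    """Write the table as uncompressed VCF v4.2 (GT only)."""
    lines = ["##fileformat=VCFv4.2", "##source=snptrace"]
    for c in dict.fromkeys(vt.contig):
        lines.append(f"##contig=<ID={c}>")
    for k in vt.info:
        lines.append(f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(vt.samples))
    for i in range(vt.n_sites):
        kv = []
        for k, arr in vt.info.items():
            if np.isfinite(arr[i]):
                kv.append(f"{k}={arr[i]:g}")
        gts = []
        for a, b in vt.genotypes[i]:
            fa = "." if a == MISSING else str(int(a))
            fb = "." if b == MISSING else str(int(b))
            gts.append(f"{fa}/{fb}")
        lines.append("\t".join([
            str(vt.contig[i]), str(int(vt.pos[i])), ".", str(vt.ref[i]),
            ",".join(vt.alt[i]) or ".", ".", "PASS", ";".join(kv) or ".",
            "GT", *gts,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def apply_hard_filters(vt: VariantTable,
                       th: HardFilterThresholds | None = None) -> VariantTable:
    """Remove sites violating any variant-quality inequality.

    A site is removed iff any of QD < qd_min, MQ < mq_min, FS > fs_max,
    HaplotypeScore > haplotype_score_max, MQRankSum < mq_rank_sum_min,
    ReadPosRankSum < read_pos_rank_sum_min holds.  Absent annotations pass
    their sub-filter (GATK VariantFiltration behaviour: a missing annotation
    cannot trigger removal).
    """
    th = th or HardFilterThresholds()
    n = vt.n_sites

    def get(key: str) -> np.ndarray:
        return vt.info.get(key, np.full(n, np.nan))

    with np.errstate(invalid="ignore"):
        bad = (
            (get("QD") < th.qd_min)
            | (get("MQ") < th.mq_min)
            | (get("FS") > th.fs_max)
            | (get("HaplotypeScore") > th.haplotype_score_max)
            | (get("MQRankSum") < th.mq_rank_sum_min)
            | (get("ReadPosRankSum") < th.read_pos_rank_sum_min)
        )
    return vt.take(~bad)


def apply_frequency_filters(vt: VariantTable,
                            th: HardFilterThresholds | None = None) -> VariantTable:
    """Retain sites with MAF >= maf_min and call rate >= call_rate_min.

    Both boundaries inclusive.  MAF is computed over non-missing alleles; a
    site with all genotypes missing is removed with a warning.
    """
    th = th or HardFilterThresholds()
    af, call_rate = vt.allele_frequencies()
    all_missing = np.isnan(af)
    if np.any(all_missing):
        logger.warning("%d site(s) with all genotypes missing removed",
                       int(all_missing.sum()))
    with np.errstate(invalid="ignore"):
        maf = np.minimum(af, 1.0 - af)
        keep = (~all_missing) & (maf >= th.maf_min) & (call_rate >= th.call_rate_min)
    return vt.take(keep)


# ---------------------------------------------------------------------------
# Popmap / GFF3
# ---------------------------------------------------------------------------

def read_population_map(path: str | Path) -> PopulationMap:
    """Read a two-column whitespace-delimited sample/population file."""
    assignments: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"popmap line {ln}: expected 2 columns, got {len(parts)}")
        sample, pop = parts
        if sample in assignments:
            raise FormatError(f"popmap line {ln}: sample {sample!r} listed twice")
        assignments[sample] = pop
    return PopulationMap(assignments)


def write_population_map(pm: PopulationMap, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{s}\t{p}\n" for s, p in pm.assignments.items()))


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 into :class:`GeneModel` records.

    Exons are grouped under mRNA features via Parent attributes, mRNAs under
    genes.  Exons whose parent cannot be resolved are skipped with a warning;
    inverted coordinates raise :class:`FormatError`.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = []
            for e in db.children(t, featuretype="exon", order_by="start"):
                if e.end < e.start:
                    raise FormatError(
                        f"exon with end < start at {e.seqid}:{e.start}-{e.end}")
                exons.append((e.start, e.end))
            if exons:
                transcripts.append((t.id, exons))
        if not transcripts:
            logger.warning("gene %s has no transcript with exons; skipped", g.id)
            continue
        genes.append(GeneModel(gene_id=g.id, contig=g.seqid,
                               strand=g.strand if g.strand in "+-" else "+",
                               transcripts=transcripts))
    # orphan exons: present in file but unreachable from any gene
    n_exons_linked = sum(len(ex) for gm in genes for _, ex in gm.transcripts)
    n_exons_total = sum(1 for _ in db.features_of_type("exon"))
    if n_exons_total > n_exons_linked:
        logger.warning("%d exon(s) with no resolvable parent skipped",
                       n_exons_total - n_exons_linked)
    return genes


def read_fasta(path: str | Path) -> dict[str, str]:
    """Contig id -> uppercase sequence."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
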