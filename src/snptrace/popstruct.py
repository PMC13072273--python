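"""Population structure: IBS kinship, genotype PCA, Patterson's D and f4-ratio.

These statistics delineate the traceable genetic populations that the marker
screen later targets, and flag gene flow that could erode fixed differences.
All operations work on biallelic :class:`~snptrace.io_formats.VariantTable`
genotypes coded as alt-allele dosage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import PopulationMap, VariantTable


@dataclass
class KinshipMatrix:
    """Pairwise normalized IBS similarity.

    ``raw`` holds the mean per-site allele-sharing fraction (values in
    {0, 0.5, 1} per site); ``values`` is min-max normalized so the smallest
    off-diagonal entry maps to 0 and self-similarity to 1.  Pairs with no
    shared non-missing site are NaN and listed in ``undefined_pairs``.
    """

    labels: list[str]
    values: np.ndarray
    raw: np.ndarray
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class PcaResult:
    labels: list[str]
    coordinates: np.ndarray          # samples x components
    variance_fraction: np.ndarray    # per component, non-increasing


@dataclass
class DStatResult:
    """ABBA-BABA result for (P1, P2, P3; outgroup)."""

    trio: tuple[str, str, str]
    outgroup: str
    abba: float
    baba: float
    d: float
    z: float
    p: float
    n_blocks: int
    n_sites: int
    defined: bool = True


@dataclass
class F4RatioResult:
    """Admixture fraction alpha = f4(A,O;X,C) / f4(A,O;B,C).

    X is modelled as a mixture of a B-related and a C-related source; A is an
    unadmixed reference on the B side and O the outgroup.  alpha estimates the
    B-derived ancestry proportion of X.
    """

    a: str
    b: str
    x: str
    c: str
    outgroup: str
    alpha: float
    numerator: float
    denominator: float
    defined: bool = True


def _dosage(vt: VariantTable) -> np.ndarray:
    return vt.alt_dosage()


def compute_ibs_kinship(vt: VariantTable) -> KinshipMatrix:
    """Normalized identity-by-state kinship over all sample pairs.

    Per shared non-missing site, the IBS fraction between two diploid
    genotypes is (number of alleles identical by state)/2, i.e. 1 for
    identical genotypes, 0.5 for one shared allele, 0 for opposite
    homozygotes; raw kinship is the mean over sites.
    """
    if vt.n_samples < 2:
        raise ValueError("kinship needs at least 2 samples")
    d = _dosage(vt)  # sites x samples, nan = missing
    n = vt.n_samples
    raw = np.full((n, n), np.nan)
    undefined = []
    for i in range(n):
        for j in range(i, n):
            both = ~np.isnan(d[:, i]) & ~np.isnan(d[:, j])
            if not both.any():
                undefined.append((vt.samples[i], vt.samples[j]))
                continue
            ibs = 1.0 - np.abs(d[both, i] - d[both, j]) / 2.0
            raw[i, j] = raw[j, i] = ibs.mean()
    off = raw[~np.eye(n, dtype=bool)]
    finite = off[np.isfinite(off)]
    lo = finite.min() if finite.size else 0.0
    if lo >= 1.0:
        values = np.where(np.isfinite(raw), 1.0, np.nan)
    else:
        values = (raw - lo) / (1.0 - lo)
    return KinshipMatrix(labels=list(vt.samples), values=values, raw=raw,
                         undefined_pairs=undefined)


def compute_pca(vt: VariantTable, n_components: int = 3,
                patterson_scaling: bool = False) -> PcaResult:
    """PCA of the 0/1/2 dosage matrix, mean-imputed and column-centered.

    ``patterson_scaling`` additionally divides each site column by
    sqrt(p(1-p)) with p the alt-allele frequency.  Variance fractions are
    eigenvalues over the total variance of the centered matrix.
    """
    if vt.n_samples < 2 or vt.n_sites < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 sites")
    d = _dosage(vt).T  # samples x sites
    col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    idx = np.where(np.isnan(d))
    d[idx] = col_mean[idx[1]]
    x = d - col_mean
    if patterson_scaling:
        p = col_mean / 2.0
        scale = np.sqrt(np.clip(p * (1 - p), 1e-12, None))
        x = x / scale
    max_k = min(x.shape)
    if n_components > max_k:
        import logging
        logging.getLogger(__name__).warning(
            "n_components clipped from %d to %d", n_components, max_k)
        n_components = max_k
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    ev = s ** 2
    total = ev.sum()
    frac = ev / total if total > 0 else np.zeros_like(ev)
    coords = u[:, :n_components] * s[:n_components]
    return PcaResult(labels=list(vt.samples), coordinates=coords,
                     variance_fraction=frac[:n_components])


# ---------------------------------------------------------------------------
# D and f4
# ---------------------------------------------------------------------------

def _derived_freqs(vt: VariantTable, pm: PopulationMap, pops: list[str],
                   outgroup: str, outgroup_poly_max: float = 0.1
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site derived-allele frequencies for ``pops`` + outgroup.

    Polarization: the outgroup's major allele is taken as ancestral; sites
    where the outgroup minor-allele frequency exceeds ``outgroup_poly_max``
    are dropped, as are sites where any population has no called genotype.
    Returns (freqs with shape len(pops)+1 x n_used_sites, used site index).
    """
    bia = vt.is_biallelic()
    idx = pm.sample_indices(vt)
    for label in [*pops, outgroup]:
        if label not in idx or len(idx[label]) == 0:
            raise ValueError(f"population {label!r} absent from popmap")
    d = _dosage(vt)  # sites x samples

    def pop_freq(label: str) -> tuple[np.ndarray, np.ndarray]:
        sub = d[:, idx[label]]
        n = np.sum(~np.isnan(sub), axis=1) * 2
        with np.errstate(invalid="ignore"):
            f = np.nansum(sub, axis=1) / n
        return f, n

    fo, no = pop_freq(outgroup)
    usable = bia & (no > 0)
    freqs = []
    for label in pops:
        f, n = pop_freq(label)
        usable &= n > 0
        freqs.append(f)
    out_minor = np.minimum(fo, 1 - fo)
    usable &= out_minor <= outgroup_poly_max
    # orient so the outgroup major allele is ancestral (derived freq = freq of
    # the allele rarer in the outgroup)
    flip = fo > 0.5
    stacked = np.vstack(freqs + [fo])
    stacked = np.where(flip[None, :], 1.0 - stacked, stacked)
    used = np.flatnonzero(usable)
    return stacked[:, used], used


def compute_d_statistic(vt: VariantTable, pm: PopulationMap,
                        p1: str, p2: str, p3: str, outgroup: str,
                        block_size: int = 1000,
                        outgroup_poly_max: float = 0.1) -> DStatResult:
    """Patterson's D for the arrangement (((P1,P2),P3),outgroup).

    abba = sum (1-f1) f2 f3 (1-f4); baba = sum f1 (1-f2) f3 (1-f4), with f the
    per-population derived-allele frequencies.  D = (abba-baba)/(abba+baba).
    Z is a delete-one block jackknife over contiguous site blocks.
    """
    freqs, used = _derived_freqs(vt, pm, [p1, p2, p3], outgroup,
                                 outgroup_poly_max)
    f1, f2, f3, f4 = freqs
    abba_s = (1 - f1) * f2 * f3 * (1 - f4)
    baba_s = f1 * (1 - f2) * f3 * (1 - f4)
    abba, baba = float(abba_s.sum()), float(baba_s.sum())
    tot = abba + baba
    if tot == 0:
        return DStatResult((p1, p2, p3), outgroup, abba, baba, np.nan, np.nan,
                           np.nan, 0, len(used), defined=False)
    d = (abba - baba) / tot

    n = len(abba_s)
    n_blocks = max(1, int(np.ceil(n / block_size)))
    if n_blocks < 2 or d == 0.0:
        return DStatResult((p1, p2, p3), outgroup, abba, baba, d,
                           0.0 if d == 0.0 else np.nan,
                           1.0 if d == 0.0 else np.nan,
                           n_blocks, len(used), defined=True)
    bounds = np.linspace(0, n, n_blocks + 1).astype(int)
    d_j = []
    for k in range(n_blocks):
        mask = np.ones(n, dtype=bool)
        mask[bounds[k]:bounds[k + 1]] = False
        a, b = abba_s[mask].sum(), baba_s[mask].sum()
        d_j.append((a - b) / (a + b) if a + b > 0 else 0.0)
    d_j = np.array(d_j)
    m = n_blocks
    var = (m - 1) / m * np.sum((d_j - d_j.mean()) ** 2)
    se = np.sqrt(var)
    z = d / se if se > 0 else np.inf * np.sign(d)
    p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return DStatResult((p1, p2, p3), outgroup, abba, baba, d, float(z),
                       float(p), n_blocks, len(used), defined=True)


def compute_f4_ratio(vt: VariantTable, pm: PopulationMap,
                     a: str, b: str, x: str, c: str, outgroup: str,
                     outgroup_poly_max: float = 0.1) -> F4RatioResult:
    """f4-ratio admixture estimate alpha = f4(A,O;X,C)/f4(A,O;B,C)."""
    labels = [a, b, x, c]
    if len({a, b, x, c, outgroup}) != 5:
        raise ValueError("f4-ratio requires five distinct labels")
    freqs, _ = _derived_freqs(vt, pm, labels, outgroup, outgroup_poly_max)
    fa, fb, fx, fc, fo = freqs
    num = float(np.sum((fa - fo) * (fx - fc)))
    den = float(np.sum((fa - fo) * (fb - fc)))
    if den == 0:
        return F4RatioResult(a, b, x, c, outgroup, np.nan, num, den,
                             defined=False)
    return F4RatioResult(a, b, x, c, outgroup, num / den, num, den)
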