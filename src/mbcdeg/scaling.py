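"""Per-sample scaling for the four MBCdeg normalization variants.

The clustering model consumes a per-sample *log scaling offset* ``o_j``.
The four variants differ only in how that offset is computed:

* variant 1 — upper-quartile (UQ): centered log 75th percentiles,
* variant 2 — DEGES *size factors* (mean-one effective library sizes),
* variant 3 — CPM: centered log library sizes,
* variant 4 — DEGES *normalization factors* (geometric-mean-one TMM-style
  factors computed after eliminating potential DEGs).

Variant 4 deliberately feeds the bare log normalization factors — without
the library-size component — into the clustering model. Everything needed
for that (TMM, a two-group NB likelihood-ratio screen, the DEG elimination
loop) is implemented here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .counts_io import CountMatrix, GroupDesign
from .nbmix import _nb_loglik

__all__ = [
    "NormalizationFactors",
    "SizeFactors",
    "ScalingOffsets",
    "library_sizes",
    "uq_offsets",
    "cpm_offsets",
    "tmm_factors",
    "potential_deg_pvalues",
    "deges_factors",
    "size_factors_from",
    "offsets_for_variant",
]

logger = logging.getLogger(__name__)

# TMM constants: the de-facto standard trimming fractions and
# inverse-asymptotic-variance weighting.
LOGRATIO_TRIM = 0.30
SUM_TRIM = 0.05


@dataclass(frozen=True)
class NormalizationFactors:
    """Multiplicative library-size corrections, rescaled to geometric mean 1.

    Effective library size = library size x factor (edgeR convention).
    """

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError("normalization factors must be positive and finite")
        vals = vals / np.exp(np.mean(np.log(vals)))
        object.__setattr__(self, "values", vals)
        assert abs(np.exp(np.mean(np.log(vals))) - 1.0) < 1e-9


@dataclass(frozen=True)
class SizeFactors:
    """Normalized effective library sizes, rescaled to arithmetic mean 1."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError("size factors must be positive and finite")
        vals = vals / vals.mean()
        object.__setattr__(self, "values", vals)
        assert abs(vals.mean() - 1.0) < 1e-9


@dataclass(frozen=True)
class ScalingOffsets:
    """Per-sample natural-log scaling offsets fed into the clustering model."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(vals)):
            raise ValueError("scaling offsets must be finite")
        object.__setattr__(self, "values", vals)


def library_sizes(cm: CountMatrix) -> np.ndarray:
    """Column totals N_j; errors on an all-zero sample."""
    N = cm.values.sum(axis=0).astype(float)
    if np.any(N <= 0):
        bad = cm.sample_ids[int(np.argmin(N))]
        raise ValueError(f"sample {bad!r} has zero total count")
    return N


def _expressed_mask(cm: CountMatrix) -> np.ndarray:
    return cm.values.sum(axis=1) > 0


def uq_offsets(cm: CountMatrix) -> ScalingOffsets:
    """Upper-quartile offsets (variant 1).

    o_j = ln(q75_j) - mean_j ln(q75_j), where q75_j is the 75th percentile
    of column j over genes with nonzero total count across all samples.
    """
    mask = _expressed_mask(cm)
    sub = cm.values[mask].astype(float)
    q75 = np.percentile(sub, 75, axis=0)
    if np.any(q75 <= 0):
        bad = cm.sample_ids[int(np.argmin(q75))]
        raise ValueError(
            f"sample {bad!r} has a zero 75th percentile after filtering unexpressed genes; "
            "filter low-count genes more aggressively before normalizing"
        )
    logq = np.log(q75)
    return ScalingOffsets(logq - logq.mean())


def cpm_offsets(cm: CountMatrix) -> ScalingOffsets:
    """Library-size (CPM) offsets (variant 3): centered log column totals."""
    logN = np.log(library_sizes(cm))
    return ScalingOffsets(logN - logN.mean())


def _tmm_pair(yj, yr, Nj, Nr) -> float:
    """log2 TMM factor of sample j against reference r.

    Over genes with nonzero counts in both samples, trim the top and bottom
    LOGRATIO_TRIM fraction by M (log ratio) and SUM_TRIM fraction by A
    (log abundance), then take the weighted mean of M with
    inverse-asymptotic-variance weights.
    """
    pos = (yj > 0) & (yr > 0)
    yj = yj[pos]
    yr = yr[pos]
    n = yj.size
    if n == 0:
        logger.warning("TMM: no genes shared between sample and reference; factor set to 1")
        return 0.0
    pj = yj / Nj
    pr = yr / Nr
    M = np.log2(pj / pr)
    A = 0.5 * np.log2(pj * pr)
    w = 1.0 / ((Nj - yj) / (Nj * yj) + (Nr - yr) / (Nr * yr))
    loM = math.floor(n * LOGRATIO_TRIM) + 1
    hiM = n + 1 - loM
    loA = math.floor(n * SUM_TRIM) + 1
    hiA = n + 1 - loA
    rM = stats.rankdata(M)
    rA = stats.rankdata(A)
    keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    if not keep.any():
        logger.warning("TMM: no genes survive trimming; factor set to 1")
        return 0.0
    return float(np.sum(w[keep] * M[keep]) / np.sum(w[keep]))


def tmm_factors(cm: CountMatrix, ref: int | None = None, gene_mask=None) -> NormalizationFactors:
    """Trimmed-mean-of-M-values normalization factors.

    Parameters
    ----------
    ref :
        Reference column index. If omitted, the column whose
        75th-percentile/library-size ratio is closest to the across-sample
        mean of that ratio is used.
    gene_mask :
        Optional boolean mask restricting which genes enter the trimmed
        mean (used by the DEG elimination step). Library sizes are always
        computed from all genes.
    """
    if cm.n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    N = library_sizes(cm)
    y = cm.values.astype(float)
    if gene_mask is None:
        sub = y
    else:
        gene_mask = np.asarray(gene_mask, dtype=bool)
        if gene_mask.shape != (cm.n_genes,):
            raise ValueError("gene_mask length must equal the number of genes")
        if not gene_mask.any():
            raise ValueError("gene_mask excludes every gene")
        sub = y[gene_mask]
    if ref is None:
        ratio = np.percentile(sub, 75, axis=0) / N
        ref = int(np.argmin(np.abs(ratio - ratio.mean())))
    log2f = np.zeros(cm.n_samples)
    with np.errstate(divide="ignore", over="ignore"):
        for j in range(cm.n_samples):
            if j == ref:
                continue
            log2f[j] = _tmm_pair(sub[:, j], sub[:, ref], N[j], N[ref])
    return NormalizationFactors(2.0 ** log2f)


def _pooled_common_dispersion(z: np.ndarray, design: GroupDesign) -> float:
    """Method-of-moments NB dispersion pooled over all genes and groups."""
    num = 0.0
    den = 0.0
    for i in range(design.n_groups):
        cols = design.members(i)
        if cols.size < 2:
            continue
        m = z[:, cols].mean(axis=1)
        v = z[:, cols].var(axis=1, ddof=1)
        df = cols.size - 1
        num += df * np.sum(v - m)
        den += df * np.sum(m ** 2)
    if den <= 0:
        return 1e-6
    return max(1e-6, num / den)


def _nb_mean_mle(y: np.ndarray, s: np.ndarray, phi: float, n_iter: int = 60) -> np.ndarray:
    """Per-gene MLE of the NB mean level mu with exposures s (mean_j = mu*s_j).

    Fisher scoring on eta = ln(mu); the score is monotone in eta so this
    converges quickly. Genes with zero totals collapse to the lower clip.
    """
    tot = y.sum(axis=1)
    mu0 = np.maximum(tot / s.sum(), 1e-10)
    eta = np.log(mu0)
    for _ in range(n_iter):
        m = np.exp(eta)[:, None] * s[None, :]
        denom = 1.0 + phi * m
        score = ((y - m) / denom).sum(axis=1)
        info = (m / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -4.0, 4.0)
        eta = np.maximum(eta + step, np.log(1e-12))
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.exp(eta)


def potential_deg_pvalues(
    cm: CountMatrix, design: GroupDesign, nf: NormalizationFactors
) -> np.ndarray:
    """Per-gene two-group NB likelihood-ratio p-values (the DEG screen).

    A common dispersion is estimated by pooled method of moments on
    effective-library-size-scaled counts (floored at 1e-6). Null: one mean
    across groups with per-sample effective-library-size exposures;
    alternative: one mean per group. The statistic is referred to the
    chi-square distribution with 1 df. Genes with zero total count get p=1.
    """
    if design.n_groups != 2:
        raise ValueError("the potential-DEG screen supports two-group designs only")
    N = library_sizes(cm)
    eff = N * nf.values
    s = eff / eff.mean()
    y = cm.values.astype(float)
    phi = _pooled_common_dispersion(y / s[None, :], design)

    mu0 = _nb_mean_mle(y, s, phi)
    ll0 = _nb_loglik(y, mu0[:, None] * s[None, :], phi).sum(axis=1)
    ll1 = np.zeros(cm.n_genes)
    for i in range(2):
        cols = design.members(i)
        mu_i = _nb_mean_mle(y[:, cols], s[cols], phi)
        ll1 += _nb_loglik(y[:, cols], mu_i[:, None] * s[None, cols], phi).sum(axis=1)
    lrt = np.maximum(2.0 * (ll1 - ll0), 0.0)
    p = stats.chi2.sf(lrt, df=1)
    p[y.sum(axis=1) == 0] = 1.0
    return p


def deges_factors(
    cm: CountMatrix,
    design: GroupDesign,
    fdr: float = 0.1,
    floor_pdeg: float = 0.05,
    iterations: int = 1,
) -> NormalizationFactors:
    """DEG-elimination (DEGES) normalization factors.

    TMM on all genes gives interim factors; the NB likelihood-ratio screen
    flags potential DEGs at Benjamini-Hochberg FDR ``fdr`` (at minimum the
    ``floor(G * floor_pdeg)`` smallest-p genes); TMM is then recomputed with
    the flagged genes excluded from the trimmed mean (library sizes still
    use all genes). The screen/recompute cycle runs ``iterations`` times.
    """
    if design.n_groups != 2:
        raise ValueError("DEGES normalization supports two-group designs only")
    nf = tmm_factors(cm)
    G = cm.n_genes
    floor_n = int(math.floor(G * floor_pdeg))
    for _ in range(max(1, int(iterations))):
        p = potential_deg_pvalues(cm, design, nf)
        padj = stats.false_discovery_control(p, method="bh")
        sel = padj < fdr
        if int(sel.sum()) < floor_n:
            order = np.argsort(p, kind="stable")
            sel = np.zeros(G, dtype=bool)
            sel[order[:floor_n]] = True
        if sel.all():
            raise ValueError("cannot normalize: no candidate non-DEGs")
        nf = tmm_factors(cm, gene_mask=~sel)
    return nf


def size_factors_from(nf: NormalizationFactors, libsizes) -> SizeFactors:
    """Convert normalization factors to size factors.

    e_j = N_j * f_j (effective library size); s_j = e_j / mean(e).
    """
    libsizes = np.asarray(libsizes, dtype=float)
    if libsizes.shape != nf.values.shape:
        raise ValueError("library sizes and factors have mismatched lengths")
    e = libsizes * nf.values
    return SizeFactors(e / e.mean())


def offsets_for_variant(cm: CountMatrix, design: GroupDesign, variant: int) -> ScalingOffsets:
    """Log scaling offsets for one of the four MBCdeg variants."""
    if variant == 1:
        return uq_offsets(cm)
    if variant == 2:
        sf = size_factors_from(deges_factors(cm, design), library_sizes(cm))
        return ScalingOffsets(np.log(sf.values))
    if variant == 3:
        return cpm_offsets(cm)
    if variant == 4:
        return ScalingOffsets(np.log(deges_factors(cm, design).values))
    raise ValueError(f"unknown variant {variant!r}; expected 1, 2, 3 or 4")
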