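"""Genotype → exon-skipping association.

The skipping phenotype is |1 − SI| (ratio-mode SI).  Each (SNP, exon) pair from
the linking stage is tested by ordinary least squares of the phenotype on the
additive allele dosage; multiple testing is controlled with Storey q-values
(π0 estimated by a cubic smoother over a λ grid, falling back to π0 = 1 — i.e.
Benjamini–Hochberg — for small batches).  Also provided: the unpaired
two-tailed t-test used for per-genotype group comparisons, and pairwise LD
(r², D′) estimated from unphased dosages by the standard two-locus EM.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, SnpRecord
from .splicing import SIMatrix
from .transcripts import SkippedExonLink

log = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "LdResult",
    "TTestResult",
    "default_exon_id",
    "associate",
    "qvalues",
    "estimate_pi0",
    "filter_hits",
    "genotype_group_ttest",
    "pairwise_ld",
]


@dataclass
class AssociationResult:
    """OLS fit of |1−SI| on counted-allele dosage for one (SNP, exon) pair."""

    snp_id: str
    exon_id: str
    beta: float = math.nan
    intercept: float = math.nan
    p_value: float = math.nan
    r_squared: float = math.nan
    q_value: float = math.nan
    n_used: int = 0
    skipping_allele: str = ""
    testable: bool = True


@dataclass(frozen=True)
class LdResult:
    """Pairwise linkage disequilibrium between two SNPs."""

    snp_a: str
    snp_b: str
    r2: float
    d_prime: float
    n_used: int
    defined: bool = True


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int
    testable: bool = True


def default_exon_id(gene_id: str, interval: tuple[int, int]) -> str:
    """Canonical exon feature name used to join links with expression features."""
    return f"{gene_id}:{interval[0]}-{interval[1]}"


def _pairs_from_links(
    links: Iterable, si_exons: set[str]
) -> list[tuple[str, str]]:
    pairs = []
    dropped = 0
    for item in links:
        if isinstance(item, SkippedExonLink):
            exon_id = default_exon_id(item.gene_id, item.exon_interval)
            pair = (item.snp_id, exon_id)
        else:
            pair = (str(item[0]), str(item[1]))
        if pair[1] in si_exons:
            pairs.append(pair)
        else:
            dropped += 1
    if dropped:
        log.info("associate: %d linked exons absent from the SI matrix", dropped)
    # preserve order, drop duplicates
    seen: set[tuple[str, str]] = set()
    out = []
    for p in pairs:
        if p not in seen:
            seen.add(p)
            out.append(p)
    return out


def associate(
    genotypes: GenotypeMatrix,
    si: SIMatrix,
    links: Iterable,
    snp_records: Mapping[str, SnpRecord] | None = None,
    compute_q: bool = True,
) -> list[AssociationResult]:
    """Test each linked (SNP, exon) pair for association of dosage with |1−SI|.

    ``links`` may be SkippedExonLink objects (exons are matched to SI features
    by the canonical "gene:start-end" name) or explicit (snp_id, exon_id)
    pairs.  Missing genotypes/SI are dropped pairwise.  Pairs with < 3 complete
    samples or a monomorphic dosage are flagged untestable and excluded from
    the FDR computation.  ``skipping_allele`` is the allele whose dosage
    increases the phenotype.
    """
    phenotype = si.skipping_phenotype()
    pairs = _pairs_from_links(links, set(si.exon_ids))
    shared = [s for s in genotypes.sample_ids if s in set(si.sample_ids)]
    results = []
    for snp_id, exon_id in pairs:
        res = AssociationResult(snp_id=snp_id, exon_id=exon_id)
        if snp_id not in genotypes.dosages.index:
            res.testable = False
            results.append(res)
            continue
        d = genotypes.dosages.loc[snp_id, shared].to_numpy(dtype=float)
        y = phenotype.loc[exon_id, shared].to_numpy(dtype=float)
        keep = ~(np.isnan(d) | np.isnan(y))
        d, y = d[keep], y[keep]
        res.n_used = int(keep.sum())
        if res.n_used < 3 or np.unique(d).size < 2:
            res.testable = False
            results.append(res)
            continue
        fit = stats.linregress(d, y)
        res.beta = float(fit.slope)
        res.intercept = float(fit.intercept)
        res.p_value = float(fit.pvalue)
        res.r_squared = float(fit.rvalue) ** 2
        counted = genotypes.counted_allele.get(snp_id, "")
        if snp_records is not None and snp_id in snp_records:
            rec = snp_records[snp_id]
            other = rec.ref_allele if counted == rec.alt_allele else rec.alt_allele
        else:
            other = "other"
        res.skipping_allele = counted if res.beta > 0 else other
        results.append(res)
    if compute_q:
        testable = [r for r in results if r.testable]
        if testable:
            qs = qvalues(np.array([r.p_value for r in testable]))
            for r, q in zip(testable, qs):
                r.q_value = float(q)
    return results


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Estimate the null proportion π0 by the smoother method.

    Raw estimates π0(λ) = #{p > λ} / (m(1−λ)) on the λ grid 0.05..0.95 are
    smoothed with a cubic fit; the smoothed value at the largest λ, clipped to
    (0, 1], is returned.  Returns 1.0 when the fit is unusable.
    """
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    raw = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    try:
        coef = np.polyfit(lambdas, raw, deg=3)
        pi0 = float(np.polyval(coef, lambdas.max()))
    except Exception:  # degenerate fit
        return 1.0
    if not np.isfinite(pi0) or pi0 <= 0:
        return 1.0
    return min(pi0, 1.0)


def qvalues(p_values: Sequence[float], pi0: float | None = None, min_n_smoother: int = 100) -> np.ndarray:
    """Storey q-values for a batch of p-values.

    With fewer than ``min_n_smoother`` p-values (or on smoother failure) π0
    falls back to 1, making the result identical to Benjamini–Hochberg
    step-up adjusted p-values.  Output order matches input order and q is
    monotone nondecreasing in the p-value ranks.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p) if p.size >= min_n_smoother else 1.0
    if not 0 < pi0 <= 1:
        raise ValueError(f"pi0 must be in (0, 1], got {pi0}")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def filter_hits(
    results: Sequence[AssociationResult],
    p_max: float = 0.05,
    fdr_max: float = 0.10,
    r2_min: float = 0.03,
) -> list[AssociationResult]:
    """Apply the reporting filter p < 0.05, q < 0.10, R² > 0.03 (all strict)."""
    return [
        r
        for r in results
        if r.testable and r.p_value < p_max and r.q_value < fdr_max and r.r_squared > r2_min
    ]


def genotype_group_ttest(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = True
) -> TTestResult:
    """Unpaired two-tailed t-test between SI (or |1−SI|) values of two genotype groups.

    Welch's unequal-variance form by default; ``welch=False`` pools variances.
    Groups with n < 2, or two degenerate groups with unequal constants, are
    untestable.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return TTestResult(math.nan, math.nan, a.size, b.size, testable=False)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, a.size, b.size)
        return TTestResult(math.nan, math.nan, a.size, b.size, testable=False)
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(float(t), float(p), a.size, b.size)


def _em_haplotype_freqs(ga: np.ndarray, gb: np.ndarray, max_iter: int = 200, tol: float = 1e-10):
    """Two-locus haplotype frequencies (p11, p12, p21, p22) from unphased dosages.

    Dosages count "allele 1" copies at each locus; only the double-heterozygote
    phase is latent and resolved iteratively.
    """
    n = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            n[i, j] = np.sum((ga == i) & (gb == j))
    total = 2.0 * n.sum()
    pa = (2 * n[2].sum() + n[1].sum()) / total
    pb = (2 * n[:, 2].sum() + n[:, 1].sum()) / total
    p11, p12, p21, p22 = pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)
    for _ in range(max_iter):
        denom = p11 * p22 + p12 * p21
        cis = p11 * p22 / denom if denom > 0 else 0.5
        c11 = 2 * n[2, 2] + n[2, 1] + n[1, 2] + cis * n[1, 1]
        c12 = 2 * n[2, 0] + n[2, 1] + n[1, 0] + (1 - cis) * n[1, 1]
        c21 = 2 * n[0, 2] + n[1, 2] + n[0, 1] + (1 - cis) * n[1, 1]
        c22 = 2 * n[0, 0] + n[0, 1] + n[1, 0] + cis * n[1, 1]
        new = np.array([c11, c12, c21, c22]) / total
        if np.max(np.abs(new - np.array([p11, p12, p21, p22]))) < tol:
            p11, p12, p21, p22 = new
            break
        p11, p12, p21, p22 = new
    return p11, p12, p21, p22


def pairwise_ld(
    genotypes: GenotypeMatrix, snp_a: str, snp_b: str, min_shared: int = 10
) -> LdResult:
    """Estimate r² and D′ between two SNPs from unphased dosages via EM.

    Requires ≥ ``min_shared`` samples typed at both SNPs; monomorphic SNPs give
    an undefined (flagged) result.
    """
    ga = genotypes.dosages.loc[snp_a].to_numpy(dtype=float)
    gb = genotypes.dosages.loc[snp_b].to_numpy(dtype=float)
    keep = ~(np.isnan(ga) | np.isnan(gb))
    ga, gb = ga[keep].astype(int), gb[keep].astype(int)
    n_used = int(keep.sum())
    if n_used < min_shared:
        raise ValueError(f"{snp_a}/{snp_b}: only {n_used} shared samples (< {min_shared})")
    if np.unique(ga).size < 2 or np.unique(gb).size < 2:
        return LdResult(snp_a, snp_b, math.nan, math.nan, n_used, defined=False)
    p11, p12, p21, p22 = _em_haplotype_freqs(ga, gb)
    pa, pb = p11 + p12, p11 + p21
    d = p11 - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom <= 0:
        return LdResult(snp_a, snp_b, math.nan, math.nan, n_used, defined=False)
    r2 = d * d / denom
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    d_prime = abs(d) / dmax if dmax > 0 else math.nan
    return LdResult(snp_a, snp_b, float(min(r2, 1.0)), float(min(d_prime, 1.0)), n_used)
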