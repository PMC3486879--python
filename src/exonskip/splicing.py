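"""Splicing Index (SI) computation, per-individual skip calls, and mapping of
array exons onto model exons.

SI is the per-sample ratio of exon-level intensity to the gene-level intensity
of the host gene: 1 means the exon is included in proportion to the gene's
overall expression, and |1−SI| quantifies skipping.  An exon is called skipped
in a sample when its SI leaves the (0.8, 1.2) band (strict inequalities).  A
log2 variant of the statistic is available behind ``mode`` for completeness;
the skip-call thresholds assume ratio mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "SIMatrix",
    "ExonMapping",
    "compute_si",
    "call_skipped",
    "select_frequently_skipped",
    "map_array_exons",
]


@dataclass
class SIMatrix:
    """Exon × sample Splicing Index values with the exon→gene assignment."""

    values: pd.DataFrame  # index = exon_ids, columns = sample_ids
    exon_to_gene: dict[str, str]
    mode: str = "ratio"

    @property
    def exon_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def skipping_phenotype(self) -> pd.DataFrame:
        """|1 − SI|, the exon-skipping phenotype used for genotype association."""
        if self.mode != "ratio":
            raise ValueError("the |1−SI| phenotype is defined on ratio-mode SI")
        return (1.0 - self.values).abs()


@dataclass(frozen=True)
class ExonMapping:
    """An accepted correspondence between an array exon and a model exon."""

    array_exon_id: str
    model_exon: tuple[int, int]
    overlap_frac_array: float
    overlap_frac_model: float

    def __post_init__(self) -> None:
        for f in (self.overlap_frac_array, self.overlap_frac_model):
            if not 0.0 <= f <= 1.0:
                raise ValueError("overlap fractions must be within [0, 1]")


def compute_si(
    exon_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    exon_to_gene: Mapping[str, str],
    mode: str = "ratio",
    gene_floor: float | None = None,
) -> SIMatrix:
    """Compute SI = exon intensity / gene intensity per exon per sample.

    ``mode='log2_ratio'`` returns log2 of the ratio instead.  Gene intensities
    below ``gene_floor`` (default 1e-6 × the median gene intensity) yield NaN,
    excluding those cells from downstream calls and association.
    """
    if mode not in {"ratio", "log2_ratio"}:
        raise ValueError(f"unknown SI mode {mode!r}")
    unmapped = [e for e in exon_expr.feature_ids if e not in exon_to_gene]
    if unmapped:
        raise ValueError(f"exons with no gene mapping: {unmapped[:10]}")
    missing_genes = sorted(
        {exon_to_gene[e] for e in exon_expr.feature_ids} - set(gene_expr.feature_ids)
    )
    if missing_genes:
        raise ValueError(f"genes absent from gene-level matrix: {missing_genes[:10]}")

    samples = [s for s in exon_expr.sample_ids if s in set(gene_expr.sample_ids)]
    if len(samples) < len(exon_expr.sample_ids):
        log.warning("compute_si: %d samples lack gene-level data", len(exon_expr.sample_ids) - len(samples))
    ex = exon_expr.values[samples]
    genes = [exon_to_gene[e] for e in ex.index]
    gv = gene_expr.values.loc[genes, samples].to_numpy(dtype=float)
    if gene_floor is None:
        med = float(np.nanmedian(gene_expr.values.to_numpy(dtype=float)))
        gene_floor = 1e-6 * med if med > 0 else 1e-12
    denom = np.where(gv >= gene_floor, gv, np.nan)
    si = ex.to_numpy(dtype=float) / denom
    if mode == "log2_ratio":
        si = np.log2(np.where(si > 0, si, np.nan))
    values = pd.DataFrame(si, index=ex.index, columns=samples)
    return SIMatrix(values, {e: exon_to_gene[e] for e in ex.index}, mode=mode)


def call_skipped(si: SIMatrix, lower: float = 0.8, upper: float = 1.2) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample skip calls: SI < lower or SI > upper, strictly.

    Returns (boolean exon × sample matrix, per-exon count of calling samples).
    NaN SI never calls.
    """
    if lower >= upper:
        raise ValueError(f"lower threshold {lower} must be below upper {upper}")
    v = si.values
    calls = (v < lower) | (v > upper)
    calls = calls & v.notna()
    return calls, calls.sum(axis=1)


def select_frequently_skipped(
    skip_counts: pd.Series,
    n_samples: int,
    top_fraction: float = 0.10,
    min_individuals: int | None = None,
) -> list[str]:
    """Exons skipped in strictly more than the threshold number of individuals.

    The threshold is ``min_individuals`` when given, otherwise
    ``top_fraction × n_samples`` (e.g. 18 for 176 samples at the default 10%).
    """
    if min_individuals is None:
        threshold = int(top_fraction * n_samples)
    else:
        threshold = min_individuals
    return [str(e) for e, c in skip_counts.items() if c > threshold]


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def map_array_exons(
    array_exons: Mapping[str, tuple[int, int]],
    model_exons: Sequence[tuple[int, int]],
    min_array_frac: float = 0.95,
    min_model_frac: float = 0.90,
) -> list[ExonMapping]:
    """Map array exons to model exons by reciprocal-overlap fractions.

    A pair is accepted when overlap/array_length > min_array_frac AND
    overlap/model_length > min_model_frac (strict).  When several model exons
    qualify for one array exon, the pair maximizing the summed fractions wins.
    """
    out = []
    for aid, a in array_exons.items():
        alen = a[1] - a[0]
        if alen <= 0:
            raise ValueError(f"array exon {aid} has non-positive length")
        best: ExonMapping | None = None
        for m in model_exons:
            mlen = m[1] - m[0]
            if mlen <= 0:
                raise ValueError(f"model exon {m} has non-positive length")
            ov = _overlap(a, m)
            fa, fm = ov / alen, ov / mlen
            if fa > min_array_frac and fm > min_model_frac:
                cand = ExonMapping(aid, tuple(m), fa, fm)
                if best is None or (cand.overlap_frac_array + cand.overlap_frac_model
                                    > best.overlap_frac_array + best.overlap_frac_model):
                    best = cand
        if best is not None:
            out.append(best)
    return out
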