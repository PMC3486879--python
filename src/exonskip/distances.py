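"""Distance-to-exon computations and distribution comparisons.

Distances are measured to the splice-site-side exon boundary as the number of
bases strictly between the SNP and the boundary (a SNP at the first intronic
base is at distance 0).  "Nearest exon" is taken over the union of exon
boundaries of the gene(s) in whose intron the SNP lies, not genome-wide; a
genome-wide mode over all supplied genes is available behind a flag.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel, SnpRecord
from .transcripts import SkippedExonLink, host_genes

__all__ = [
    "nearest_exon_distance",
    "skipped_exon_distance",
    "compare_distributions",
    "summarize",
    "distance_table",
]


def _gap(pos: int, exon: tuple[int, int]) -> int:
    """Bases strictly between an intronic position and an exon boundary (0 if inside)."""
    s, e = exon
    if pos < s:
        return s - pos - 1
    if pos >= e:
        return pos - e
    return 0


def nearest_exon_distance(
    snp: SnpRecord,
    genes: Sequence[GeneModel],
    genome_wide: bool = False,
    strand_filter: bool = True,
) -> int | None:
    """Minimum gap from an intronic SNP to any exon boundary of its host gene(s).

    Returns None (flagged, excluded upstream) when the SNP is intronic in no
    supplied gene and ``genome_wide`` is off.
    """
    if genome_wide:
        pool = [g for g in genes if g.chrom == snp.chrom]
    else:
        pool = host_genes(snp, genes, strand_filter=strand_filter)
    if not pool:
        return None
    return min(_gap(snp.pos, ex) for g in pool for ex in g.exon_union)


def skipped_exon_distance(link: SkippedExonLink) -> int:
    """Gap between an ISE SNP and the nearer boundary of its linked skipped exon."""
    if not link.is_skipped:
        raise ValueError(f"{link.snp_id}: link does not point at a skipped exon")
    return link.distance_bp


def compare_distributions(sample_a: Sequence[float], sample_b: Sequence[float]):
    """Two-sample Kolmogorov–Smirnov test between two distance samples.

    Requires n ≥ 5 in both samples; scipy chooses the exact p-value for small
    samples and the asymptotic one otherwise.  Degenerate constant samples
    covering a single common value are flagged by returning D = 0, p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("both samples need n >= 5")
    if np.unique(a).size == 1 and np.unique(b).size == 1 and a[0] == b[0]:
        return 0.0, 1.0
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def summarize(table: pd.DataFrame, value_col: str = "distance_bp", group_col: str = "group") -> pd.DataFrame:
    """Per-group mean, median and SD (n−1 denominator) of distances, in bp.

    Single-value groups report SD as missing.
    """
    if table.empty:
        raise ValueError("empty distance table")
    rows = []
    for grp, sub in table.groupby(group_col, sort=True):
        v = sub[value_col].to_numpy(dtype=float)
        rows.append(
            {
                "group": grp,
                "n": v.size,
                "mean_bp": float(np.mean(v)),
                "median_bp": float(np.median(v)),
                "sd_bp": float(np.std(v, ddof=1)) if v.size > 1 else math.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def distance_table(
    snps: Iterable[SnpRecord],
    genes: Sequence[GeneModel],
    links: Sequence[SkippedExonLink] = (),
    group_labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-SNP distance table behind the group summaries.

    One row per SNP with a defined nearest-exon distance; the skipped-exon
    distance column is filled only for SNPs with a skipped-exon link (the
    minimum over their skipped links).
    """
    skip_dist: dict[str, int] = {}
    for ln in links:
        if ln.is_skipped:
            d = skip_dist.get(ln.snp_id)
            skip_dist[ln.snp_id] = ln.distance_bp if d is None else min(d, ln.distance_bp)
    rows = []
    for snp in snps:
        d = nearest_exon_distance(snp, genes)
        if d is None:
            continue
        rows.append(
            {
                "snp_id": snp.snp_id,
                "distance_to_nearest_exon": d,
                "distance_to_skipped_exon": skip_dist.get(snp.snp_id, math.nan),
                "group": (group_labels or {}).get(snp.snp_id, "all_intronic"),
            }
        )
    return pd.DataFrame(rows)
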