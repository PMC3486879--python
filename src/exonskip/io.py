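"""Typed containers and readers/writers for every external format the pipeline touches.

All genomic coordinates are stored 0-based half-open internally; conversions to and
from 1-based conventions (GTF, VCF) happen only at the I/O boundary.  Chromosome
names are normalized by stripping a leading ``chr`` prefix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

__all__ = [
    "SnpRecord",
    "TranscriptModel",
    "GeneModel",
    "MotifSet",
    "ExpressionMatrix",
    "GenotypeMatrix",
    "TraitSnpCatalog",
    "normalize_chrom",
    "read_gene_models",
    "write_gene_models",
    "read_snps",
    "write_snps",
    "read_motif_set",
    "write_motif_set",
    "read_expression",
    "write_expression",
    "read_genotypes",
    "write_genotypes",
    "read_trait_catalog",
    "write_trait_catalog",
    "read_fasta",
    "write_fasta",
]


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so hg-style and Ensembl-style names compare equal."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic single-nucleotide variant.

    ``pos`` is the 0-based genomic coordinate of the variant base.  ``maf`` is the
    folded minor-allele frequency (≤ 0.5) or ``None`` when unknown.  ``strand`` is
    the strand the variant was reported on (dbSNP-style); it is only consulted by
    the host-gene strand filter when linking SNPs to exons.
    """

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    snp_class: str = "intronic"
    maf: float | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 0:
            raise ValueError(f"{self.snp_id}: negative position {self.pos}")
        for name in ("ref_allele", "alt_allele"):
            a = getattr(self, name)
            if a not in VALID_BASES:
                raise ValueError(f"{self.snp_id}: {name} {a!r} is not a single A/C/G/T base")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref and alt alleles are identical")
        if self.snp_class not in {"intronic", "exonic", "intergenic", "other"}:
            raise ValueError(f"{self.snp_id}: unknown snp_class {self.snp_class!r}")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(
                f"{self.snp_id}: MAF {self.maf} outside [0, 0.5]; fold frequencies upstream"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.snp_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class TranscriptModel:
    """One spliced isoform: an ordered, non-overlapping set of exon intervals."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has zero exons")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"{self.transcript_id}: bad exon interval [{s}, {e})")
            if s < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class GeneModel:
    """All isoforms of one gene; members share gene_id, chromosome and strand."""

    gene_id: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "transcripts", tuple(self.transcripts))
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene has no transcripts")
        first = self.transcripts[0]
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise ValueError(f"{self.gene_id}: member transcript has gene_id {t.gene_id}")
            if t.chrom != first.chrom or t.strand != first.strand:
                raise ValueError(f"{self.gene_id}: transcripts disagree on chrom/strand")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def exon_union(self) -> tuple[tuple[int, int], ...]:
        """Sorted union of distinct exon intervals over all isoforms."""
        return tuple(sorted({ex for t in self.transcripts for ex in t.exons}))


@dataclass(frozen=True)
class MotifSet:
    """A named, deduplicated set of hexamer motifs (uppercase, A/C/G/T only)."""

    name: str
    motifs: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "motifs", frozenset(m.upper() for m in self.motifs))
        for m in self.motifs:
            if len(m) != 6:
                raise ValueError(f"motif {m!r} is not 6 bases long")
            if set(m) - VALID_BASES:
                raise ValueError(f"motif {m!r} contains non-ACGT characters")

    def __contains__(self, motif: str) -> bool:
        return motif in self.motifs

    def __len__(self) -> int:
        return len(self.motifs)

    def union(self, other: "MotifSet", name: str | None = None) -> "MotifSet":
        return MotifSet(name or f"{self.name}+{other.name}", self.motifs | other.motifs)


@dataclass
class ExpressionMatrix:
    """Feature × sample non-negative intensity matrix (normalized upstream)."""

    values: pd.DataFrame  # index = feature_ids, columns = sample_ids

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValueError("expression matrix contains negative values")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate feature or sample IDs in expression matrix")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GenotypeMatrix:
    """SNP × sample dosage matrix counting copies of the declared counted allele.

    Dosages are 0/1/2 or NaN (missing).  ``counted_allele`` maps each snp_id to the
    base whose copies the dosage counts.
    """

    dosages: pd.DataFrame  # index = snp_ids, columns = sample_ids, float with NaN
    counted_allele: dict[str, str]

    def __post_init__(self) -> None:
        arr = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.asarray(self.dosages.index)[np.where(~ok)[0][:5]]
            raise ValueError(f"dosages outside {{0,1,2,missing}} at SNPs {list(bad)}")
        missing = set(self.dosages.index) - set(self.counted_allele)
        if missing:
            raise ValueError(f"no counted allele declared for {sorted(missing)[:5]}")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.columns)


@dataclass
class TraitSnpCatalog:
    """(snp_id, trait) records, e.g. an emulated GWAS-catalog extract."""

    records: pd.DataFrame  # columns snp_id, trait

    def __post_init__(self) -> None:
        self.records = self.records.loc[:, ["snp_id", "trait"]].drop_duplicates()

    @property
    def snp_ids(self) -> set[str]:
        return set(self.records["snp_id"])


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

_GENEPRED_MIN_FIELDS = 10


def _parse_genepred_line(line: str, lineno: int) -> TranscriptModel:
    f = line.rstrip("\n").split("\t")
    if len(f) < _GENEPRED_MIN_FIELDS:
        raise ValueError(f"genePred line {lineno}: expected ≥{_GENEPRED_MIN_FIELDS} fields, got {len(f)}")
    try:
        n_exons = int(f[7])
        starts = [int(x) for x in f[8].rstrip(",").split(",") if x]
        ends = [int(x) for x in f[9].rstrip(",").split(",") if x]
    except ValueError as exc:
        raise ValueError(f"genePred line {lineno}: {exc}") from None
    if n_exons == 0 or not starts:
        raise ValueError(f"genePred line {lineno}: transcript {f[0]} has zero exons")
    if len(starts) != n_exons or len(ends) != n_exons:
        raise ValueError(f"genePred line {lineno}: exonCount does not match exon lists")
    gene_id = f[10] if len(f) > 10 and f[10] else f[0]
    return TranscriptModel(
        transcript_id=f[0],
        gene_id=gene_id,
        chrom=f[1],
        strand=f[2],
        exons=tuple(zip(starts, ends)),
    )


def _group_genes(transcripts: Iterable[TranscriptModel]) -> list[GeneModel]:
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    return [GeneModel(g, tuple(ts)) for g, ts in by_gene.items()]


def read_gene_models(path: str | Path, dialect: str = "genepred") -> list[GeneModel]:
    """Read transcript models and group them into GeneModels.

    genePred intervals are already 0-based half-open; GTF 1-based closed exon lines
    are converted.  Transcripts are grouped by gene_id.
    """
    path = Path(path)
    if dialect == "genepred":
        transcripts = []
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                transcripts.append(_parse_genepred_line(line, i))
        return _group_genes(transcripts)
    if dialect == "gtf":
        import pyranges

        df = pyranges.read_gtf(str(path)).df
        exons = df[df["Feature"] == "exon"]
        if exons.empty:
            raise ValueError(f"{path}: no exon features in GTF")
        transcripts = []
        for (gid, tid), grp in exons.groupby(["gene_id", "transcript_id"], sort=False):
            grp = grp.sort_values("Start")
            transcripts.append(
                TranscriptModel(
                    transcript_id=str(tid),
                    gene_id=str(gid),
                    chrom=str(grp["Chromosome"].iloc[0]),
                    strand=str(grp["Strand"].iloc[0]),
                    exons=tuple(zip(grp["Start"].astype(int), grp["End"].astype(int))),
                )
            )
        return _group_genes(transcripts)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_gene_models(genes: Sequence[GeneModel], path: str | Path, dialect: str = "genepred") -> None:
    path = Path(path)
    if dialect == "genepred":
        with open(path, "w") as fh:
            for g in genes:
                for t in g.transcripts:
                    starts = ",".join(str(s) for s, _ in t.exons) + ","
                    ends = ",".join(str(e) for _, e in t.exons) + ","
                    s0, e0 = t.span
                    fh.write(
                        "\t".join(
                            [t.transcript_id, t.chrom, t.strand, str(s0), str(e0),
                             str(s0), str(e0), str(len(t.exons)), starts, ends, t.gene_id]
                        )
                        + "\n"
                    )
    elif dialect == "gtf":
        with open(path, "w") as fh:
            for g in genes:
                for t in g.transcripts:
                    for s, e in t.exons:
                        attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                        fh.write(
                            f"{t.chrom}\texonskip\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                        )
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")


# ---------------------------------------------------------------------------
# SNPs
# ---------------------------------------------------------------------------

SNP_TSV_COLUMNS = ["snp_id", "chrom", "pos", "ref_allele", "alt_allele", "snp_class", "maf", "strand"]


def read_snps(path: str | Path, dialect: str = "tabular") -> list[SnpRecord]:
    """Read biallelic SNVs from a VCF (subset) or tabular file.

    Multi-allelic and indel records are skipped; the number skipped is logged.
    VCF POS (1-based) is converted to the internal 0-based convention.  In VCF
    mode the optional INFO keys MAF, CLASS and STRAND are honoured.
    """
    path = Path(path)
    records: list[SnpRecord] = []
    n_skipped = 0
    if dialect == "vcf":
        from cyvcf2 import VCF

        for v in VCF(str(path)):
            if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
                n_skipped += 1
                continue
            if v.REF not in VALID_BASES or v.ALT[0] not in VALID_BASES:
                n_skipped += 1
                continue
            maf = v.INFO.get("MAF")
            records.append(
                SnpRecord(
                    snp_id=v.ID or f"{v.CHROM}:{v.POS}",
                    chrom=v.CHROM,
                    pos=v.POS - 1,
                    ref_allele=v.REF,
                    alt_allele=v.ALT[0],
                    snp_class=v.INFO.get("CLASS") or "intronic",
                    maf=round(float(maf), 6) if maf is not None else None,
                    strand=v.INFO.get("STRAND") or "+",
                )
            )
    elif dialect == "tabular":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        for col in ("snp_id", "chrom", "pos", "ref_allele", "alt_allele"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        for row in df.itertuples(index=False):
            ref, alt = str(row.ref_allele), str(row.alt_allele)
            if len(ref) != 1 or len(alt) != 1 or {ref, alt} - VALID_BASES:
                n_skipped += 1
                continue
            maf = getattr(row, "maf", None)
            if maf is not None and pd.isna(maf):
                maf = None
            records.append(
                SnpRecord(
                    snp_id=str(row.snp_id),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref_allele=ref,
                    alt_allele=alt,
                    snp_class=str(getattr(row, "snp_class", "intronic")),
                    maf=float(maf) if maf is not None else None,
                    strand=str(getattr(row, "strand", "+")),
                )
            )
    else:
        raise ValueError(f"unknown SNP dialect {dialect!r}")
    if n_skipped:
        log.info("read_snps: skipped %d non-SNV/multi-allelic records from %s", n_skipped, path)
    if not records:
        log.warning("read_snps: zero records retained from %s", path)
    return records


def write_snps(snps: Sequence[SnpRecord], path: str | Path, dialect: str = "tabular") -> None:
    path = Path(path)
    if dialect == "tabular":
        df = pd.DataFrame(
            [
                (s.snp_id, s.chrom, s.pos, s.ref_allele, s.alt_allele, s.snp_class,
                 "" if s.maf is None else s.maf, s.strand)
                for s in snps
            ],
            columns=SNP_TSV_COLUMNS,
        )
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Folded minor allele frequency">\n')
            fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="SNP class">\n')
            fh.write('##INFO=<ID=STRAND,Number=1,Type=String,Description="Reported strand">\n')
            for chrom in sorted({s.chrom for s in snps}):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for s in sorted(snps, key=lambda s: (s.chrom, s.pos)):
                info = f"CLASS={s.snp_class};STRAND={s.strand}"
                if s.maf is not None:
                    info = f"MAF={s.maf:g};" + info
                fh.write(f"{s.chrom}\t{s.pos + 1}\t{s.snp_id}\t{s.ref_allele}\t{s.alt_allele}\t.\t.\t{info}\n")
    else:
        raise ValueError(f"unknown SNP dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Motifs, expression, genotypes, trait catalog, FASTA
# ---------------------------------------------------------------------------


def read_motif_set(path: str | Path, name: str | None = None) -> MotifSet:
    """Read a plain-text motif list, one 6-mer per line; reject malformed lines."""
    path = Path(path)
    motifs: set[str] = set()
    bad: list[str] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            m = line.strip().upper()
            if not m or m.startswith("#"):
                continue
            if len(m) != 6 or set(m) - VALID_BASES:
                bad.append(f"line {i}: {m!r}")
            else:
                motifs.add(m)
    if bad:
        raise ValueError(f"{path}: invalid motif lines: " + "; ".join(bad))
    return MotifSet(name or path.stem, frozenset(motifs))


def write_motif_set(motifs: MotifSet, path: str | Path) -> None:
    Path(path).write_text("".join(m + "\n" for m in sorted(motifs.motifs)))


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return ExpressionMatrix(df.astype(float))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="feature_id")


def read_genotypes(path: str | Path, counted_allele_policy: str = "column") -> GenotypeMatrix:
    """Read a dosage TSV: first column snp_id, ``counted_allele`` column, then samples.

    ``counted_allele_policy`` — "column": take the counted allele from a
    ``counted_allele`` column (required); "alt": all dosages count an alt allele
    declared elsewhere, the column is then optional and defaults to 'N'.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    if "counted_allele" in df.columns:
        counted = df["counted_allele"].astype(str).to_dict()
        df = df.drop(columns=["counted_allele"])
    elif counted_allele_policy == "alt":
        counted = {s: "N" for s in df.index}
    else:
        raise ValueError(f"{path}: missing counted_allele column")
    return GenotypeMatrix(df.astype(float), counted)


def write_genotypes(gt: GenotypeMatrix, path: str | Path) -> None:
    out = gt.dosages.copy()
    out.insert(0, "counted_allele", [gt.counted_allele[s] for s in out.index])
    # integer-format dosages where nonmissing so the round trip is exact
    out.to_csv(path, sep="\t", index_label="snp_id", float_format="%g")


def read_trait_catalog(path: str | Path) -> TraitSnpCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"snp_id", "trait"}.issubset(df.columns):
        raise ValueError(f"{path}: trait catalog needs snp_id and trait columns")
    return TraitSnpCatalog(df)


def write_trait_catalog(catalog: TraitSnpCatalog, path: str | Path) -> None:
    catalog.records.to_csv(path, sep="\t", index=False)


class GenomeAccessor:
    """Thin wrapper over pyfaidx with chrom-name normalization.

    ``fetch(chrom, start, end)`` returns the uppercase plus-strand sequence for the
    0-based half-open interval, padded with ``N`` beyond contig bounds.
    """

    def __init__(self, fasta) -> None:
        self._fasta = fasta
        self._names = {normalize_chrom(name): name for name in fasta.keys()}

    def __contains__(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self._names

    def length(self, chrom: str) -> int:
        key = normalize_chrom(chrom)
        if key not in self._names:
            raise KeyError(f"chromosome {chrom!r} absent from genome")
        return len(self._fasta[self._names[key]])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        n = self.length(chrom)
        left_pad = max(0, -start)
        right_pad = max(0, end - n)
        s = max(start, 0)
        e = min(end, n)
        seq = str(self._fasta[self._names[normalize_chrom(chrom)]][s:e]).upper() if e > s else ""
        return "N" * left_pad + seq + "N" * right_pad


def read_fasta(path: str | Path) -> GenomeAccessor:
    from pyfaidx import Fasta

    return GenomeAccessor(Fasta(str(path)))


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
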