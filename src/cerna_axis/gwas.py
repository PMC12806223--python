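"""GWAS risk-SNP annotation of axis member genes.

Summary statistics (SNP id, chromosome, 1-based position, odds ratio,
p-value) are filtered to risk SNPs (OR > 1, p < 0.05 by default) and
intersected with gene genomic spans. Spans are stored 0-based half-open
internally (the BED convention); GFF3 1-based inclusive coordinates are
converted on load, and GWAS positions are converted at the single point
of comparison, so a SNP at 1-based position ``pos`` hits a span iff
``start <= pos - 1 < end`` after flank extension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GwasRecord",
    "GeneSpan",
    "normalize_chrom",
    "load_gwas",
    "load_gene_spans",
    "filter_risk",
    "map_snps",
]


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` so ``chr1`` and ``1`` compare equal."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class GwasRecord:
    """One GWAS summary row; ``pos`` is 1-based."""

    snp_id: str
    chrom: str
    pos: int
    odds_ratio: float
    p: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1")
        if self.odds_ratio <= 0:
            raise ValueError(f"{self.snp_id}: odds ratio must be positive")
        if not 0 <= self.p <= 1:
            raise ValueError(f"{self.snp_id}: p must be in [0, 1]")


@dataclass(frozen=True)
class GeneSpan:
    """A gene's genomic interval, 0-based half-open."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.gene}: empty span [{self.start}, {self.end})"
            )


DEFAULT_GWAS_COLUMNS = {
    "snp": "snp",
    "chrom": "chr",
    "pos": "pos",
    "odds_ratio": "OR",
    "p": "p",
}


def load_gwas(
    path: str | Path, columns: dict[str, str] | None = None
) -> list[GwasRecord]:
    """Parse a GWAS summary TSV; positions are 1-based.

    ``columns`` maps the logical names (snp, chrom, pos, odds_ratio, p) to
    the file's column headers. Rows with non-numeric OR/p/pos are rejected
    and counted in one warning.
    """
    cols = dict(DEFAULT_GWAS_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    records: list[GwasRecord] = []
    n_rejected = 0
    for _, row in df.iterrows():
        try:
            records.append(
                GwasRecord(
                    snp_id=str(row[cols["snp"]]),
                    chrom=normalize_chrom(row[cols["chrom"]]),
                    pos=int(row[cols["pos"]]),
                    odds_ratio=float(row[cols["odds_ratio"]]),
                    p=float(row[cols["p"]]),
                )
            )
        except (TypeError, ValueError):
            n_rejected += 1
    if n_rejected:
        warnings.warn(
            f"{path}: rejected {n_rejected} unparsable GWAS row(s)", stacklevel=2
        )
    return records


def load_gene_spans(path: str | Path, format: str = "bed") -> list[GeneSpan]:
    """Load gene spans from BED (0-based half-open) or GFF3 (1-based
    inclusive, converted). Multiple intervals for one gene (transcripts)
    collapse to their union interval."""
    raw: dict[str, list[tuple[str, int, int, str]]] = {}
    if format == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype=str
        )
        if df.shape[1] < 4:
            raise ValueError(f"{path}: BED needs chrom, start, end, name")
        for _, row in df.iterrows():
            strand = str(row[5]) if df.shape[1] > 5 else "."
            raw.setdefault(str(row[3]), []).append(
                (normalize_chrom(row[0]), int(row[1]), int(row[2]), strand)
            )
    elif format == "gff3":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 9:
            raise ValueError(f"{path}: malformed GFF3")
        for _, row in df.iterrows():
            attrs = dict(
                kv.split("=", 1) for kv in str(row[8]).split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or attrs.get("gene_id")
            if name is None:
                raise ValueError(f"{path}: GFF3 feature without Name/ID")
            # GFF3 is 1-based inclusive -> 0-based half-open
            raw.setdefault(name, []).append(
                (normalize_chrom(row[0]), int(row[3]) - 1, int(row[4]), str(row[6]))
            )
    else:
        raise ValueError(f"format must be 'bed' or 'gff3', got {format!r}")

    spans = []
    for gene, ivals in raw.items():
        chroms = {c for c, _, _, _ in ivals}
        if len(chroms) > 1:
            raise ValueError(f"{gene}: intervals on multiple chromosomes {chroms}")
        spans.append(
            GeneSpan(
                gene=gene,
                chrom=next(iter(chroms)),
                start=min(s for _, s, _, _ in ivals),
                end=max(e for _, _, e, _ in ivals),
                strand=ivals[0][3],
            )
        )
    return spans


def filter_risk(
    records: list[GwasRecord],
    or_thresh: float = 1.0,
    p_thresh: float = 0.05,
) -> list[GwasRecord]:
    """Keep risk SNPs: odds ratio strictly above ``or_thresh`` and p
    strictly below ``p_thresh`` (a SNP at OR = 1.0 exactly is not risk)."""
    return [r for r in records if r.odds_ratio > or_thresh and r.p < p_thresh]


def map_snps(
    spans: list[GeneSpan],
    risk: list[GwasRecord],
    flank: int = 0,
) -> tuple[dict[str, int], dict[str, list[str]]]:
    """Count risk SNPs overlapping each gene span (interval-indexed).

    A SNP at 1-based ``pos`` hits a span iff
    ``start - flank <= pos - 1 < end + flank``. Every input gene appears
    in the result, with count 0 when nothing overlaps. Returns
    ``(counts, snp_ids)``; SNP id lists are sorted.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    trees: dict[str, IntervalTree] = {}
    for sp in spans:
        trees.setdefault(sp.chrom, IntervalTree()).addi(
            sp.start - flank, sp.end + flank, sp.gene
        )
    hits: dict[str, list[str]] = {sp.gene: [] for sp in spans}
    for rec in risk:
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        for iv in tree.at(rec.pos - 1):
            hits[iv.data].append(rec.snp_id)
    snp_ids = {g: sorted(ids) for g, ids in hits.items()}
    counts = {g: len(ids) for g, ids in snp_ids.items()}
    return counts, snp_ids
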