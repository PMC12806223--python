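"""Two-group negative-binomial differential expression on RNA counts.

Implements a self-contained, documented simplification of the standard
RNA-seq workflow: median-of-ratios size factors, a per-gene log2 fold
change on normalized group means (with a pseudocount so near-zero groups
yield large but finite values), a method-of-moments NB dispersion
estimate, and a Wald test whose standard error comes from the delta
method under the NB variance model. External DE tables (e.g. DESeq2
output) can be imported verbatim via :func:`import_de_table`, and the
fold-change/p-value gating that defines the DE-lncRNA/DE-miRNA/DE-mRNA
sets lives in :func:`classify_de`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "DEResult",
    "DESets",
    "size_factors",
    "de_test",
    "classify_de",
    "import_de_table",
    "export_de_table",
]

GENE_CLASSES = ("lncRNA", "miRNA", "mRNA")


@dataclass
class ExpressionMatrix:
    """Raw counts (genes x samples) with a two-group design and gene classes.

    ``counts`` is a DataFrame indexed by gene ID with sample columns;
    ``sample_group`` maps each sample to ``"case"`` or ``"control"``;
    ``gene_class`` maps each gene to lncRNA/miRNA/mRNA.
    """

    counts: pd.DataFrame
    sample_group: dict[str, str]
    gene_class: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        for s in self.counts.columns:
            if s not in self.sample_group:
                raise ValueError(f"sample {s!r} has no group assignment")
            if self.sample_group[s] not in ("case", "control"):
                raise ValueError(f"group for {s!r} must be 'case' or 'control'")
        for grp in ("case", "control"):
            n = sum(1 for s in self.counts.columns if self.sample_group[s] == grp)
            if n < 2:
                raise ValueError(f"need >= 2 samples in group {grp!r}, have {n}")
        missing = [g for g in self.counts.index if g not in self.gene_class]
        if missing:
            raise ValueError(f"genes without class annotation: {missing[:5]}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.sample_group[s] == group]

    @classmethod
    def from_files(
        cls,
        counts_path: str | Path,
        samples_path: str | Path,
        gene_class_path: str | Path,
    ) -> "ExpressionMatrix":
        """Load counts TSV (first column gene id), samples TSV (sample, group)
        and gene-class TSV (gene, class)."""
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t")
        classes = pd.read_csv(gene_class_path, sep="\t")
        return cls(
            counts=counts,
            sample_group=dict(zip(samples.iloc[:, 0].astype(str), samples.iloc[:, 1])),
            gene_class=dict(zip(classes.iloc[:, 0].astype(str), classes.iloc[:, 1])),
        )


@dataclass
class DEResult:
    """Per-gene differential-expression call (case over control)."""

    gene: str
    log2fc: float
    stat: float
    p: float
    padj: float | None = None
    direction: str = "ns"  # set by classify_de
    gene_class: str | None = None


def size_factors(
    counts: pd.DataFrame, allow_pseudocount: bool = False
) -> pd.Series:
    """Median-of-ratios per-sample scale factors.

    For each sample the factor is the median, over genes with strictly
    positive counts in *all* samples, of count / geometric-mean-across-
    samples. When no gene is positive everywhere (sparse data), pass
    ``allow_pseudocount=True`` to add 0.5 to every count for the factor
    computation only.
    """
    mat = counts.to_numpy(dtype=float)
    if allow_pseudocount:
        mat = mat + 0.5
    eligible = (mat > 0).all(axis=1)
    if not eligible.any():
        raise ValueError(
            "no gene has positive counts in every sample; rerun with "
            "allow_pseudocount=True to add 0.5 to all counts for "
            "size-factor estimation"
        )
    sub = mat[eligible]
    log_geo_mean = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo_mean)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _mom_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Method-of-moments NB dispersion per gene, combined across groups.

    For NB, var = mu + alpha * mu^2, so alpha = (var - mu) / mu^2 within
    each group. The per-group estimates are combined by taking their
    elementwise maximum -- a deliberately conservative choice: at small
    group sizes the moment estimate is noisy, and averaging lets genes
    with one underestimated group slip through with inflated Wald
    statistics. The result is floored at 1e-8 (under-dispersed genes
    degrade to near-Poisson).
    """
    alpha = np.full(norm.shape[0], -np.inf)
    for idx in groups:
        sub = norm[:, idx]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            est = np.where(mu > 0, (var - mu) / np.maximum(mu, 1e-300) ** 2, 0.0)
        alpha = np.maximum(alpha, est)
    return np.maximum(alpha, 1e-8)


def de_test(matrix: ExpressionMatrix, pseudocount: float = 0.5) -> list[DEResult]:
    """Per-gene NB Wald test of case vs control.

    Counts are normalized by size factors; ``log2fc`` is
    ``log2((mean_case + pc) / (mean_control + pc))`` on normalized means.
    The Wald statistic is log2fc over a delta-method SE under the NB
    variance model (``var = mu + alpha mu^2`` on the raw scale), with a
    two-sided p-value from the standard normal reference. Genes with zero
    counts in every sample are dropped with a warning. BH-adjusted
    p-values are filled in across all tested genes.
    """
    counts = matrix.counts
    nonzero = counts.sum(axis=1) > 0
    if (~nonzero).any():
        warnings.warn(
            f"dropping {int((~nonzero).sum())} gene(s) with all-zero counts",
            stacklevel=2,
        )
        counts = counts.loc[nonzero]
    sf = size_factors(counts)
    case = matrix.samples_in("case")
    ctrl = matrix.samples_in("control")
    if counts[case].to_numpy().sum() == 0 or counts[ctrl].to_numpy().sum() == 0:
        raise ValueError("one group has all-zero total counts")

    raw = counts.to_numpy(dtype=float)
    s = sf.to_numpy()
    norm = raw / s
    cols = list(counts.columns)
    idx_case = np.array([cols.index(c) for c in case])
    idx_ctrl = np.array([cols.index(c) for c in ctrl])

    alpha = _mom_dispersion(norm, [idx_case, idx_ctrl])
    mu_case = norm[:, idx_case].mean(axis=1)
    mu_ctrl = norm[:, idx_ctrl].mean(axis=1)
    log2fc = np.log2(mu_case + pseudocount) - np.log2(mu_ctrl + pseudocount)

    # Var(mean of K_j/s_j) = n^-2 sum_j (mu/s_j + alpha mu^2) under NB.
    def _var_mean(mu: np.ndarray, idx: np.ndarray) -> np.ndarray:
        inv_s = (1.0 / s[idx]).sum()
        n = len(idx)
        return (mu * inv_s + n * alpha * mu**2) / n**2

    ln2sq = np.log(2.0) ** 2
    se2 = (
        _var_mean(mu_case, idx_case) / (mu_case + pseudocount) ** 2
        + _var_mean(mu_ctrl, idx_ctrl) / (mu_ctrl + pseudocount) ** 2
    ) / ln2sq
    se = np.sqrt(np.maximum(se2, 1e-300))
    wald = log2fc / se
    pvals = 2.0 * stats.norm.sf(np.abs(wald))
    padj = multipletests(pvals, method="fdr_bh")[1]

    return [
        DEResult(
            gene=g,
            log2fc=float(log2fc[i]),
            stat=float(wald[i]),
            p=float(pvals[i]),
            padj=float(padj[i]),
            gene_class=matrix.gene_class.get(g),
        )
        for i, g in enumerate(counts.index)
    ]


@dataclass
class DESets:
    """DE calls partitioned by gene class and direction.

    ``direction``/``log2fc``/``p`` index every *DE* gene; ``by_class`` maps
    each gene class to its up/down sets, mirroring summaries of the form
    "771 dysregulated lncRNAs (505 up / 266 down)".
    """

    by_class: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    direction: dict[str, str] = field(default_factory=dict)
    log2fc: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)

    @property
    def genes(self) -> set[str]:
        return set(self.direction)

    def counts_summary(self) -> dict[str, dict[str, int]]:
        return {
            cls: {
                "up": len(d.get("up", set())),
                "down": len(d.get("down", set())),
                "total": len(d.get("up", set())) + len(d.get("down", set())),
            }
            for cls, d in sorted(self.by_class.items())
        }


def classify_de(
    results: list[DEResult],
    lfc_thresh: float = 2.0,
    p_thresh: float = 0.05,
    use_padj: bool = False,
) -> DESets:
    """Gate DE calls at ``|log2fc| > lfc_thresh`` and ``p < p_thresh``.

    Both inequalities are strict, matching the printed thresholds; a gene
    exactly at the fold-change boundary is not called. ``use_padj``
    switches the p gate to the BH-adjusted value. Mutates each result's
    ``direction`` and returns the partitioned sets.
    """
    if not results:
        raise ValueError("empty result list")
    if lfc_thresh <= 0:
        raise ValueError("lfc_thresh must be positive")
    if not 0 < p_thresh <= 1:
        raise ValueError("p_thresh must be in (0, 1]")
    sets = DESets()
    for r in results:
        pval = r.padj if use_padj else r.p
        if use_padj and r.padj is None:
            raise ValueError(f"gene {r.gene}: padj requested but absent")
        if pval is not None and pval < p_thresh and abs(r.log2fc) > lfc_thresh:
            r.direction = "up" if r.log2fc > 0 else "down"
        else:
            r.direction = "ns"
        if r.direction != "ns":
            cls = r.gene_class or "unknown"
            sets.by_class.setdefault(cls, {}).setdefault(r.direction, set()).add(
                r.gene
            )
            sets.direction[r.gene] = r.direction
            sets.log2fc[r.gene] = r.log2fc
            sets.p[r.gene] = pval
    return sets


def import_de_table(
    path: str | Path, gene_class: dict[str, str] | None = None
) -> list[DEResult]:
    """Read an external DE table (columns gene, log2FoldChange, pvalue;
    padj optional), e.g. DESeq2 output written with row names as a column.

    Rows with missing p-values are kept with p = 1 and a warning, so they
    can never pass the DE gate but remain visible downstream.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "log2FoldChange", "pvalue"):
        if col not in df.columns:
            raise ValueError(f"{path}: mandatory column {col!r} missing")
    n_na = int(df["pvalue"].isna().sum())
    if n_na:
        warnings.warn(f"{path}: {n_na} row(s) with NA pvalue set to p=1", stacklevel=2)
    results = []
    for _, row in df.iterrows():
        gene = str(row["gene"])
        p = float(row["pvalue"]) if pd.notna(row["pvalue"]) else 1.0
        padj = None
        if "padj" in df.columns and pd.notna(row["padj"]):
            padj = float(row["padj"])
        results.append(
            DEResult(
                gene=gene,
                log2fc=float(row["log2FoldChange"]),
                stat=float(row["stat"]) if "stat" in df.columns and pd.notna(row.get("stat")) else float("nan"),
                p=p,
                padj=padj,
                gene_class=gene_class.get(gene) if gene_class else None,
            )
        )
    return results


def export_de_table(results: list[DEResult], path: str | Path) -> pd.DataFrame:
    """Write DE results as TSV (gene, class, log2fc, stat, p, padj, direction)."""
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "class": [r.gene_class for r in results],
            "log2FoldChange": [r.log2fc for r in results],
            "stat": [r.stat for r in results],
            "pvalue": [r.p for r in results],
            "padj": [r.padj for r in results],
            "direction": [r.direction for r in results],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return df
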