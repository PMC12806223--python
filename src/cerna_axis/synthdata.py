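"""Synthetic, ground-truth-labeled inputs for the whole pipeline.

Generates interaction tables across several pseudo-source databases, an
NB count matrix for a two-group cohort, gene spans on one pseudo-
chromosome, and a GWAS summary table -- all with planted ceRNA axes
(lncRNA/mRNA up, miRNA down in cases) and direction-concordant decoy
axes that a correct pipeline must filter out. Every draw flows through a
single seeded generator, so identical configs produce byte-identical
files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix
from .gwas import GeneSpan

__all__ = ["SimConfig", "GroundTruth", "simulate_reference", "simulate_counts",
           "simulate_gwas", "write_dataset"]


@dataclass
class SimConfig:
    """Generator knobs; defaults describe the emulated study conditions.

    Six case and six control samples mirror a small case--control RNA-seq
    cohort; ``lfc_planted = 4`` puts planted members well past the
    ``|log2FC| > 2`` gate while staying estimable at this sample size;
    ``dispersion = 0.1`` is a typical bulk RNA-seq overdispersion.
    """

    n_lnc: int = 30
    n_mi: int = 12
    n_m: int = 40
    n_planted_axes: int = 5
    n_decoy_axes: int = 5
    edge_density: float = 0.05
    n_case: int = 6
    n_control: int = 6
    base_mean: float = 500.0
    dispersion: float = 0.1
    lfc_planted: float = 4.0
    frac_snp_genes: float = 1.0
    max_snps_per_gene: int = 4
    n_noise_snps: int = 60
    span_length: int = 2000
    span_gap: int = 1000
    sources: tuple[str, ...] = ("dbA", "dbB", "dbC")
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_lnc, self.n_mi, self.n_m) < 1:
            raise ValueError("node counts must be positive")
        if not 0 <= self.edge_density <= 1:
            raise ValueError("edge_density must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        need = self.n_planted_axes + self.n_decoy_axes
        if need > min(self.n_lnc, self.n_mi, self.n_m):
            raise ValueError(
                f"{need} planted+decoy axes need {need} nodes per class; "
                f"have ({self.n_lnc}, {self.n_mi}, {self.n_m})"
            )
        if len(self.sources) < 2:
            raise ValueError("need >= 2 pseudo-sources")

    # Harmonized node ids (what the pipeline sees after ID normalization).
    def lnc_ids(self) -> list[str]:
        return [f"LNC{i:04d}" for i in range(self.n_lnc)]

    def mi_ids(self) -> list[str]:
        return [f"mir-{i:04d}-5p" for i in range(self.n_mi)]

    def m_ids(self) -> list[str]:
        return [f"GENE{i:04d}" for i in range(self.n_m)]


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring."""

    planted_axes: list[tuple[str, str, str]] = field(default_factory=list)
    decoy_axes: list[tuple[str, str, str]] = field(default_factory=list)
    planted_snps: dict[str, list[str]] = field(default_factory=dict)
    sample_scalings: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.planted_axes) & set(self.decoy_axes):
            raise ValueError("planted and decoy axes overlap")

    def planted_members(self) -> tuple[set[str], set[str], set[str]]:
        lnc = {a[0] for a in self.planted_axes}
        mi = {a[1] for a in self.planted_axes}
        m = {a[2] for a in self.planted_axes}
        return lnc, mi, m

    def decoy_members(self) -> tuple[set[str], set[str], set[str]]:
        lnc = {a[0] for a in self.decoy_axes}
        mi = {a[1] for a in self.decoy_axes}
        m = {a[2] for a in self.decoy_axes}
        return lnc, mi, m

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "planted_axes": [list(a) for a in self.planted_axes],
                    "decoy_axes": [list(a) for a in self.decoy_axes],
                    "planted_snps": self.planted_snps,
                    "sample_scalings": self.sample_scalings,
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            planted_axes=[tuple(a) for a in d["planted_axes"]],
            decoy_axes=[tuple(a) for a in d["decoy_axes"]],
            planted_snps=d["planted_snps"],
            sample_scalings=d.get("sample_scalings", {}),
        )


def _raw_mi(mi: str) -> str:
    """Database-style raw form of a harmonized miRNA id."""
    return "hsa-miR-" + mi[len("mir-"):]


def simulate_reference(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[tuple[str, str], pd.DataFrame], GroundTruth]:
    """Interaction tables per (source, edge_class) plus the ground truth.

    Background bipartite edges are Erdos-Renyi at ``edge_density`` over
    all (lnc, mi) and (mi, m) pairs; each lands in one source, and a
    random ~30% subset in two (a known support >= 2 subset). Planted and
    decoy axis edges are written to the first two sources. miRNA ids are
    written in database style (``hsa-miR-...``) to exercise
    harmonization.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lnc, mi, m = config.lnc_ids(), config.mi_ids(), config.m_ids()
    npa, nde = config.n_planted_axes, config.n_decoy_axes
    truth = GroundTruth(
        planted_axes=[(lnc[i], mi[i], m[i]) for i in range(npa)],
        decoy_axes=[(lnc[npa + i], mi[npa + i], m[npa + i]) for i in range(nde)],
    )

    edges: dict[str, set[tuple[str, str, str]]] = {s: set() for s in config.sources}
    guaranteed = [(a, b, "lnc_mi") for a, b, _ in truth.planted_axes + truth.decoy_axes]
    guaranteed += [(b, c, "mi_m") for _, b, c in truth.planted_axes + truth.decoy_axes]
    for a, b, ec in guaranteed:
        for s in config.sources[:2]:
            edges[s].add((a, b, ec))

    for side, pairs in (("lnc_mi", [(a, b) for a in lnc for b in mi]),
                        ("mi_m", [(b, c) for b in mi for c in m])):
        draws = rng.random(len(pairs))
        for (a, b), u in zip(pairs, draws):
            if u < config.edge_density:
                primary = config.sources[int(rng.integers(len(config.sources)))]
                edges[primary].add((a, b, side) if side == "lnc_mi" else (a, b, side))
                if rng.random() < 0.3:
                    others = [s for s in config.sources if s != primary]
                    edges[others[int(rng.integers(len(others)))]].add((a, b, side))

    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for s in config.sources:
        for ec in ("lnc_mi", "mi_m"):
            rows = sorted((a, b) for a, b, e in edges[s] if e == ec)
            if ec == "lnc_mi":
                df = pd.DataFrame(
                    [(a, _raw_mi(b)) for a, b in rows], columns=["lncRNA", "miRNA"]
                )
            else:
                df = pd.DataFrame(
                    [(b, _raw_mi(a)) for a, b in rows], columns=["gene", "miRNA"]
                )
            if not df.empty:
                tables[(s, ec)] = df
    return tables, truth


def simulate_counts(
    config: SimConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """NB counts for all network genes under the planted design.

    counts ~ NB(mean = base_mean * s_j * 2^(beta * x), dispersion) with
    per-sample factors s_j log-uniform in [0.5, 2] (recorded in
    ``truth.sample_scalings``); beta is +lfc_planted for planted
    lncRNA/mRNA members, -lfc_planted for planted miRNAs, +lfc_planted
    for every decoy member (concordant), and 0 for background genes;
    x is the case indicator.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    genes = config.lnc_ids() + config.mi_ids() + config.m_ids()
    classes = (
        ["lncRNA"] * config.n_lnc + ["miRNA"] * config.n_mi + ["mRNA"] * config.n_m
    )
    p_lnc, p_mi, p_m = truth.planted_members()
    d_lnc, d_mi, d_m = truth.decoy_members()
    beta = np.zeros(len(genes))
    for i, g in enumerate(genes):
        if g in p_lnc or g in p_m or g in d_lnc or g in d_mi or g in d_m:
            beta[i] = config.lfc_planted
        elif g in p_mi:
            beta[i] = -config.lfc_planted

    samples = [f"case{i + 1}" for i in range(config.n_case)] + [
        f"ctrl{i + 1}" for i in range(config.n_control)
    ]
    x = np.array([1.0] * config.n_case + [0.0] * config.n_control)
    log_s = rng.uniform(np.log(0.5), np.log(2.0), size=len(samples))
    s = np.exp(log_s)
    truth.sample_scalings = {smp: float(v) for smp, v in zip(samples, s)}

    mu = config.base_mean * s[None, :] * 2.0 ** (beta[:, None] * x[None, :])
    r = 1.0 / config.dispersion
    counts = rng.negative_binomial(n=r, p=r / (r + mu))
    return ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        sample_group={
            smp: ("case" if xi == 1.0 else "control") for smp, xi in zip(samples, x)
        },
        gene_class=dict(zip(genes, classes)),
    )


def simulate_gwas(
    config: SimConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[list[GeneSpan], pd.DataFrame]:
    """Non-overlapping gene spans on one pseudo-chromosome plus GWAS rows.

    Risk SNPs (OR in (1.05, 1.3), p < 0.05) are planted inside the spans
    of ``frac_snp_genes`` of the planted lncRNA/mRNA members and recorded
    in ``truth.planted_snps``; noise SNPs that fail the risk filter (OR
    below 1, or p >= 0.05) are scattered everywhere else.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    genes = config.lnc_ids() + config.mi_ids() + config.m_ids()
    spans = []
    pitch = config.span_length + config.span_gap
    for i, g in enumerate(genes):
        start = i * pitch
        spans.append(
            GeneSpan(gene=g, chrom="1", start=start, end=start + config.span_length)
        )
    by_gene = {sp.gene: sp for sp in spans}

    p_lnc, _, p_m = truth.planted_members()
    snp_genes = sorted(p_lnc | p_m)
    n_take = int(round(config.frac_snp_genes * len(snp_genes)))
    snp_genes = snp_genes[:n_take]

    rows = []
    counter = 0
    truth.planted_snps = {}
    for g in snp_genes:
        sp = by_gene[g]
        k = int(rng.integers(1, config.max_snps_per_gene + 1))
        ids = []
        for _ in range(k):
            counter += 1
            pos = int(rng.integers(sp.start + 1, sp.end + 1))  # 1-based within span
            rows.append(
                {
                    "snp": f"rs{counter:06d}",
                    "chr": "chr1",
                    "pos": pos,
                    "OR": round(float(rng.uniform(1.05, 1.3)), 4),
                    "p": float(f"{rng.uniform(1e-6, 0.049):.3e}"),
                }
            )
            ids.append(f"rs{counter:06d}")
        truth.planted_snps[g] = sorted(ids)

    genome_end = len(genes) * pitch
    for _ in range(config.n_noise_snps):
        counter += 1
        pos = int(rng.integers(1, genome_end + 1))
        if rng.random() < 0.5:
            odds, p = float(rng.uniform(0.7, 0.95)), float(rng.uniform(0.0, 1.0))
        else:
            odds, p = float(rng.uniform(1.05, 1.5)), float(rng.uniform(0.05, 1.0))
        rows.append(
            {
                "snp": f"rs{counter:06d}",
                "chr": "chr1",
                "pos": pos,
                "OR": round(odds, 4),
                "p": float(f"{p:.3e}"),
            }
        )
    gwas = pd.DataFrame(rows, columns=["snp", "chr", "pos", "OR", "p"])
    return spans, gwas


def write_dataset(config: SimConfig, outdir: str | Path) -> GroundTruth:
    """Generate every pipeline input under ``outdir``; returns the truth.

    Files: ``interactions_<source>_<edge_class>.tsv``, ``counts.tsv``,
    ``samples.tsv``, ``gene_class.tsv``, ``genes.bed``, ``gwas.tsv`` and
    ``ground_truth.json``. Deterministic for a given config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    tables, truth = simulate_reference(config, rng)
    expr = simulate_counts(config, truth, rng)
    spans, gwas = simulate_gwas(config, truth, rng)

    for (source, ec), df in sorted(tables.items()):
        df.to_csv(outdir / f"interactions_{source}_{ec}.tsv", sep="\t", index=False)
    expr.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene")
    pd.DataFrame(
        {"sample": list(expr.counts.columns),
         "group": [expr.sample_group[s] for s in expr.counts.columns]}
    ).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"gene": list(expr.counts.index),
         "class": [expr.gene_class[g] for g in expr.counts.index]}
    ).to_csv(outdir / "gene_class.tsv", sep="\t", index=False)
    with open(outdir / "genes.bed", "w") as fh:
        for sp in spans:
            fh.write(f"chr{sp.chrom}\t{sp.start}\t{sp.end}\t{sp.gene}\t0\t.\n")
    gwas.to_csv(outdir / "gwas.tsv", sep="\t", index=False)
    truth.to_json(outdir / "ground_truth.json")
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)
    return truth
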