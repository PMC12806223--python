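"""End-to-end pipeline orchestration: config, stages, run report.

``run_pipeline`` wires the four stages together -- reference-network
assembly, differential expression (or import of an external DE table),
disease-network filtering with axis enumeration, and GWAS risk-SNP
annotation -- writing every stage output plus ``report.json`` with
node/edge/axis counts at each step.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cerna import (
    axes_to_frame,
    correlation_filter,
    direction_filter,
    enumerate_axes,
    prune_mirnas,
    score_axes,
    subset_network,
)
from .diffexpr import (
    ExpressionMatrix,
    classify_de,
    de_test,
    export_de_table,
    import_de_table,
)
from .gwas import filter_risk, load_gene_spans, load_gwas, map_snps
from .refnet import build_reference, load_interaction_table

logger = logging.getLogger("cerna_axis")

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]


@dataclass
class InteractionInput:
    path: str
    edge_class: str
    source: str
    columns: list[str] | None = None


@dataclass
class RunConfig:
    """All pipeline inputs, thresholds and toggles, with defaults matching
    the published gates (|log2FC| > 2, p < 0.05 for DE; OR > 1, p < 0.05
    for risk SNPs)."""

    # inputs
    interactions: list[InteractionInput] = field(default_factory=list)
    counts: str | None = None
    samples: str | None = None
    gene_class: str | None = None
    de_table: str | None = None
    gene_spans: str | None = None
    span_format: str = "bed"
    gwas: str | None = None
    # DE stage
    lfc_thresh: float = 2.0
    p_thresh: float = 0.05
    use_padj: bool = False
    pseudocount: float = 0.5
    # reference stage
    min_support: int = 1
    # correlation stage (optional)
    use_correlation_filter: bool = False
    require_pos_corr: bool = False
    corr_method: str = "spearman"
    min_abs_rho: float = 0.3
    corr_p: float = 0.05
    # gwas stage
    use_gwas: bool = True
    or_thresh: float = 1.0
    gwas_p_thresh: float = 0.05
    flank: int = 0
    # scoring
    score_weights: list[float] = field(default_factory=lambda: [1.0, 1.0, 1.0, 1.0])
    score_cap: float = 10.0
    # run
    seed: int = 0
    outdir: str = "results"


class ConfigError(ValueError):
    """Aggregates every config violation into one human-readable error."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


_RANGES = {
    "lfc_thresh": (0.0, float("inf"), "exclusive-min"),
    "p_thresh": (0.0, 1.0, "exclusive-min"),
    "corr_p": (0.0, 1.0, "exclusive-min"),
    "gwas_p_thresh": (0.0, 1.0, "exclusive-min"),
    "min_abs_rho": (0.0, 1.0, "inclusive"),
    "or_thresh": (0.0, float("inf"), "inclusive"),
    "flank": (0, float("inf"), "inclusive"),
    "min_support": (1, float("inf"), "inclusive"),
    "pseudocount": (0.0, float("inf"), "inclusive"),
    "score_cap": (0.0, float("inf"), "exclusive-min"),
}


def validate_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected with a
    suggestion, all violations are reported together, and every default
    is materialized in the returned config."""
    if data is None:
        data = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(["config root must be a mapping"])

    known = {f.name for f in dataclasses.fields(RunConfig)}
    problems: list[str] = []
    clean: dict = {}
    for key, value in data.items():
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            problems.append(f"unknown key {key!r}{suffix}")
            continue
        clean[key] = value

    if "interactions" in clean:
        try:
            clean["interactions"] = [
                entry if isinstance(entry, InteractionInput) else InteractionInput(**entry)
                for entry in clean["interactions"]
            ]
        except TypeError as exc:
            problems.append(f"interactions entries malformed: {exc}")
            clean.pop("interactions")

    cfg = RunConfig(**clean)
    for name, (lo, hi, mode) in _RANGES.items():
        v = getattr(cfg, name)
        ok = lo < v <= hi if mode == "exclusive-min" else lo <= v <= hi
        if not ok:
            bound = f"({lo}, {hi}]" if mode == "exclusive-min" else f"[{lo}, {hi}]"
            problems.append(f"{name} = {v} outside allowed range {bound}")
    if cfg.corr_method not in ("spearman", "pearson"):
        problems.append(f"corr_method must be spearman or pearson, got {cfg.corr_method!r}")
    if cfg.span_format not in ("bed", "gff3"):
        problems.append(f"span_format must be bed or gff3, got {cfg.span_format!r}")
    if len(cfg.score_weights) != 4 or any(w < 0 for w in cfg.score_weights):
        problems.append("score_weights must be four non-negative numbers")
    if problems:
        raise ConfigError(problems)
    return cfg


def _stage(report: dict, name: str, **counts) -> None:
    report["stages"][name] = counts
    logger.info("%s: %s", name, ", ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(config: RunConfig) -> dict:
    """Execute reference -> DE -> network filters -> axes -> GWAS.

    Writes reference edge lists, the DE table, the filtered disease
    network (TSV + GraphML), the ranked axis table with SNP annotation,
    and ``report.json``. Returns the report dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "stages": {},
                    "config": _config_dict(config)}

    # --- stage 1: reference network ---------------------------------
    if not config.interactions:
        raise ValueError("refnet stage: no interaction tables configured")
    try:
        records = []
        for spec in config.interactions:
            cols = tuple(spec.columns) if spec.columns else None
            records.extend(
                load_interaction_table(
                    spec.path, spec.edge_class, spec.source, columns=cols
                )
            )
        ref = build_reference(records, min_support=config.min_support)
    except Exception as exc:
        raise RuntimeError(f"refnet stage failed: {exc}") from exc
    ref.write(outdir)
    _stage(report, "reference", n_records=len(records),
           n_lnc_mi_edges=ref.n_lnc_mi, n_mi_m_edges=ref.n_mi_m)

    # --- stage 2: differential expression ----------------------------
    expr: ExpressionMatrix | None = None
    try:
        if config.de_table:
            results = import_de_table(config.de_table)
        else:
            if not (config.counts and config.samples and config.gene_class):
                raise ValueError("need counts+samples+gene_class or de_table")
            expr = ExpressionMatrix.from_files(
                config.counts, config.samples, config.gene_class
            )
            results = de_test(expr, pseudocount=config.pseudocount)
        de_sets = classify_de(
            results,
            lfc_thresh=config.lfc_thresh,
            p_thresh=config.p_thresh,
            use_padj=config.use_padj,
        )
    except Exception as exc:
        raise RuntimeError(f"diffexpr stage failed: {exc}") from exc
    export_de_table(results, outdir / "de_table.tsv")
    summary = de_sets.counts_summary()
    _stage(report, "diffexpr", n_tested=len(results),
           n_de=len(de_sets.genes),
           **{f"{cls}_{d}": n for cls, dd in summary.items()
              for d, n in dd.items() if d != "total"})

    # --- stage 3: disease network + axes ------------------------------
    try:
        net = subset_network(ref, de_sets)
        _stage(report, "overlap", **net.counts())
        net = direction_filter(net)
        _stage(report, "direction_filter", **net.counts())
        if config.use_correlation_filter:
            if expr is None:
                raise ValueError("correlation filter needs a count matrix")
            net = correlation_filter(
                net, expr, method=config.corr_method,
                min_abs_rho=config.min_abs_rho, corr_p=config.corr_p,
            )
            _stage(report, "correlation_filter", **net.counts())
        net = prune_mirnas(net)
        counts = net.counts()
        # the final-network miRNA tally is reported both as edge count and
        # as distinct-miRNA count, since either reading is of interest
        _stage(report, "prune_mirnas", n_mirna_nodes=counts["n_miRNA"],
               n_mirna_edges=counts["n_lnc_mi_edges"] + counts["n_mi_m_edges"],
               **counts)
        axes = enumerate_axes(
            net, expr=expr, require_pos_corr=config.require_pos_corr,
            method=config.corr_method, min_abs_rho=config.min_abs_rho,
            corr_p=config.corr_p,
        )
        _stage(report, "enumerate_axes", n_axes=len(axes))
    except Exception as exc:
        raise RuntimeError(f"cerna stage failed: {exc}") from exc

    net.to_edge_frame().to_csv(
        outdir / "disease_network_edges.tsv", sep="\t", index=False
    )
    try:
        import networkx as nx

        nx.write_graphml(net.to_networkx(), outdir / "disease_network.graphml")
    except ImportError:  # pragma: no cover
        pass

    # --- stage 4: GWAS annotation -------------------------------------
    if config.use_gwas and config.gene_spans and config.gwas:
        try:
            spans = load_gene_spans(config.gene_spans, format=config.span_format)
            gwas_records = load_gwas(config.gwas)
            risk = filter_risk(
                gwas_records, or_thresh=config.or_thresh,
                p_thresh=config.gwas_p_thresh,
            )
            counts_by_gene, snps_by_gene = map_snps(
                spans, risk, flank=config.flank
            )
        except Exception as exc:
            raise RuntimeError(f"gwas stage failed: {exc}") from exc
        for ax in axes:
            ax.n_risk_snps_lnc = counts_by_gene.get(ax.lncrna, 0)
            ax.n_risk_snps_m = counts_by_gene.get(ax.mrna, 0)
        axis_genes = sorted(
            {a.lncrna for a in axes} | {a.mrna for a in axes}
        )
        with open(outdir / "axis_snp_annotation.tsv", "w") as fh:
            fh.write("gene\tn_risk_snps\tsnp_ids\n")
            for g in axis_genes:
                fh.write(
                    f"{g}\t{counts_by_gene.get(g, 0)}\t"
                    f"{';'.join(snps_by_gene.get(g, []))}\n"
                )
        _stage(report, "gwas", n_gwas_rows=len(gwas_records),
               n_risk_snps=len(risk),
               n_axis_genes_with_snps=sum(
                   1 for g in axis_genes if counts_by_gene.get(g, 0) > 0
               ))

    axes = score_axes(
        axes, weights=tuple(config.score_weights), cap=config.score_cap
    )
    axes_to_frame(axes).to_csv(outdir / "axes_ranked.tsv", sep="\t", index=False)
    _stage(report, "score", n_axes_ranked=len(axes))

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
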