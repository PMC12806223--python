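import numpy as np
import pandas as pd
import pytest

from cerna_axis.cerna import DiseaseNetwork, NodeDE
from cerna_axis.pipeline import InteractionInput, RunConfig
from cerna_axis.synthdata import GroundTruth, SimConfig, write_dataset


@pytest.fixture
def make_dataset(tmp_path):
    """Factory writing a full synthetic dataset and its run config."""

    def _make(seed: int = 0, outname: str = "out", **cfg_kwargs):
        d = tmp_path / f"sim{seed}"
        truth = write_dataset(SimConfig(seed=seed, **cfg_kwargs), d)
        interactions = []
        for p in sorted(d.glob("interactions_*.tsv")):
            parts = p.stem.split("_")
            interactions.append(
                InteractionInput(
                    path=str(p),
                    edge_class="_".join(parts[2:]),
                    source=parts[1],
                )
            )
        run_cfg = RunConfig(
            interactions=interactions,
            counts=str(d / "counts.tsv"),
            samples=str(d / "samples.tsv"),
            gene_class=str(d / "gene_class.tsv"),
            gene_spans=str(d / "genes.bed"),
            gwas=str(d / "gwas.tsv"),
            outdir=str(d / outname),
            seed=seed,
        )
        return d, truth, run_cfg

    return _make


def random_disease_network(
    rng: np.random.Generator,
    n_lnc: int = 12,
    n_mi: int = 8,
    n_m: int = 15,
    density: float = 0.25,
) -> DiseaseNetwork:
    """A random annotated disease network for filter oracles."""
    lnc = [f"L{i}" for i in range(n_lnc)]
    mi = [f"mi{i}" for i in range(n_mi)]
    m = [f"M{i}" for i in range(n_m)]
    net = DiseaseNetwork()
    for n in lnc + mi + m:
        cls = "lncRNA" if n.startswith("L") else "miRNA" if n.startswith("mi") else "mRNA"
        direction = "up" if rng.random() < 0.5 else "down"
        net.nodes[n] = NodeDE(
            node_class=cls,
            direction=direction,
            log2fc=float(rng.normal(0, 4)),
            p=float(rng.uniform(0, 0.05)),
        )
    for a in lnc:
        for b in mi:
            if rng.random() < density:
                net.lnc_mi[(a, b)] = {"src"}
    for b in mi:
        for c in m:
            if rng.random() < density:
                net.mi_m[(b, c)] = {"src"}
    net._drop_orphans()
    return net


def null_matrix(
    seed: int,
    n_genes: int = 2000,
    dispersion: float = 0.1,
    base_mean: float = 500.0,
    n_planted: int = 0,
    lfc: float = 4.0,
):
    """6 vs 6 NB count matrix with planted per-sample scalings; the first
    ``n_planted`` genes get a 2**lfc case shift. Returns (matrix, scalings)."""
    from cerna_axis.diffexpr import ExpressionMatrix

    rng = np.random.default_rng(seed)
    s = np.exp(rng.uniform(np.log(0.5), np.log(2.0), 12))
    r = 1.0 / dispersion
    mu = base_mean * s[None, :] * np.ones((n_genes, 1))
    if n_planted:
        mu[:n_planted, :6] *= 2.0**lfc
    counts = rng.negative_binomial(r, r / (r + mu))
    df = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(12)],
    )
    em = ExpressionMatrix(
        counts=df,
        sample_group={f"s{j}": ("case" if j < 6 else "control") for j in range(12)},
        gene_class={f"g{i}": "mRNA" for i in range(n_genes)},
    )
    return em, s
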