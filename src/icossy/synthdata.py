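"""Synthetic two-phenotype expression datasets with a planted differential
module.

The generator emulates the kind of input the pipeline is built for: a
modular gene interaction network (dense Erdos-Renyi blocks joined in a
ring by sparse cross edges), per-sample expression values with gene-level
Gaussian noise, and one planted module whose genes shift coordinately
between the two phenotype classes.  Everything is derived from a single
seed, so two calls with the same configuration produce byte-identical
files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import ChipMap, ExpressionMatrix, GeneNetwork, PhenotypeLabels
from . import io as _io

__all__ = ["SynthConfig", "SynthDataset", "generate", "write_dataset", "planted_genes"]


@dataclass
class SynthConfig:
    """Study conditions for the planted-module simulation.

    delta is the coordinated expression shift (in expression units) applied
    to planted-module genes in class-2 samples; sigma is the per-observation
    Gaussian noise sd, so delta = 2 * sigma is a two-sigma effect.
    """

    n_modules: int = 6
    module_size: int = 10
    inter_module_edges: int = 2
    n_samples_per_class: int = 20
    delta: float = 2.0
    sigma: float = 1.0
    planted_module_index: int = 0
    probes_per_gene: int = 2
    coordinated: bool = True
    intra_edge_prob: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.module_size < 5:
            raise ValueError("module_size must be >= 5 so five representatives exist")
        if not (0 <= self.planted_module_index < self.n_modules):
            raise ValueError("planted_module_index out of range")
        if not (1 <= self.probes_per_gene <= 3):
            raise ValueError("probes_per_gene must lie in 1..3")
        if self.n_samples_per_class < 2:
            raise ValueError("need >= 2 samples per class")


@dataclass
class SynthDataset:
    network: GeneNetwork
    expression: ExpressionMatrix
    labels: PhenotypeLabels
    chip: ChipMap
    planted_genes: frozenset


def _module_genes(cfg: SynthConfig, module: int) -> list[str]:
    return [f"M{module}G{j:02d}" for j in range(cfg.module_size)]


def planted_genes(cfg: SynthConfig) -> frozenset:
    return frozenset(_module_genes(cfg, cfg.planted_module_index))


def generate(cfg: SynthConfig) -> SynthDataset:
    """Build network, expression matrix, labels and probe map in memory.

    Network: ``n_modules`` blocks, each a spanning cycle plus Erdos-Renyi
    edges at probability ``intra_edge_prob`` (dense, hence recovered intact
    by the decomposition), joined in a ring by ``inter_module_edges`` random
    cross edges per adjacent pair.  Expression: gene baseline ~ N(8, 1);
    each probe observation = baseline + N(0, sigma), plus delta for
    planted-module genes in class-2 samples (all planted genes shift the
    same direction when ``coordinated``; alternating signs otherwise).
    """
    rng = np.random.default_rng(cfg.seed)
    modules = [_module_genes(cfg, i) for i in range(cfg.n_modules)]

    g = nx.Graph()
    for genes in modules:
        g.add_nodes_from(genes)
        for a, b in zip(genes, genes[1:] + genes[:1]):  # spanning cycle keeps it connected
            g.add_edge(a, b)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if rng.random() < cfg.intra_edge_prob:
                    g.add_edge(genes[i], genes[j])
    for i in range(cfg.n_modules):
        nxt = modules[(i + 1) % cfg.n_modules]
        for _ in range(cfg.inter_module_edges):
            g.add_edge(str(rng.choice(modules[i])), str(rng.choice(nxt)))
    network = GeneNetwork(g, source_tag=f"synthetic(seed={cfg.seed})")

    genes = [gene for mod in modules for gene in mod]
    planted = planted_genes(cfg)
    signs = {}
    for k, gene in enumerate(sorted(planted)):
        signs[gene] = 1.0 if (cfg.coordinated or k % 2 == 0) else -1.0

    n = cfg.n_samples_per_class
    sample_ids = [f"S{k + 1:03d}" for k in range(2 * n)]
    class_names = ("CLASS1", "CLASS2")
    assignment = {s: class_names[0] if k < n else class_names[1] for k, s in enumerate(sample_ids)}
    labels = PhenotypeLabels(sample_ids, class_names, assignment)

    baselines = {gene: 8.0 + rng.standard_normal() for gene in genes}
    probe_rows = []
    probe_ids = []
    descriptions = []
    probe_to_gene = {}
    is_class2 = np.array([assignment[s] == class_names[1] for s in sample_ids])
    for gene in genes:
        shift = cfg.delta * signs.get(gene, 0.0) * is_class2
        for j in range(cfg.probes_per_gene):
            probe = f"{gene}_probe{j + 1}"
            noise = rng.normal(0.0, cfg.sigma, size=2 * n)
            probe_rows.append(baselines[gene] + shift + noise)
            probe_ids.append(probe)
            descriptions.append(gene)
            probe_to_gene[probe] = gene
    expression = ExpressionMatrix(
        pd.DataFrame(np.vstack(probe_rows), index=probe_ids, columns=sample_ids),
        pd.Series(descriptions, index=probe_ids),
    )
    chip = ChipMap(probe_to_gene)
    return SynthDataset(network, expression, labels, chip, planted)


def write_dataset(ds: SynthDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the four standard files (GCT, CLS, CHIP, SIF) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gct": outdir / "expression.gct",
        "cls": outdir / "phenotypes.cls",
        "chip": outdir / "probes.chip",
        "sif": outdir / "network.sif",
    }
    _io.write_gct(ds.expression, paths["gct"])
    _io.write_cls(ds.labels, paths["cls"])
    _io.write_chip(ds.chip, paths["chip"])
    _io.write_sif(ds.network, paths["sif"])
    return paths
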