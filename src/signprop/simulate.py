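"""Synthetic interactomes and annotation tables with planted structure.

Real sign-gene data couple three statistical features this generator
reproduces at desk scale: (1) a heavy-tailed (scale-free) interaction
network; (2) diseases carrying one to a few causal genes, with signs shared
across diseases so that a sign's gene set is a multi-disease union; (3) a
topological signal — sign gene sets form modules of tunable internal edge
density, and dominant-inheritance genes sit among the hubs while recessive
genes sit in the periphery.  Every output is a pure function of the
configuration (including its seed), so fixtures regenerate byte-identically.

The generator plants structure by *adding* within-module edges to the
scale-free backbone (never removing), so module_density is a monotone knob
for the compactness statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .io import (
    AssociationSet,
    DiseaseMeta,
    GeneNetwork,
    Ontology,
    read_associations,
    read_network,
    read_ontology,
    write_network,
)

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "generate_network",
    "plant_annotations",
    "emit_fixture",
    "load_fixture",
]

_ONSETS = ("congenital", "neonatal", "infantile", "childhood", "juvenile", "adult")
_PROGRESSIONS = ("nonprogressive", "slow", "progressive", "rapid")
_FREQUENCIES = ("hallmark", "typical", "occasional")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; all randomness flows from ``rng_seed``.

    ``mono_weight`` is the probability a disease is monogenic; otherwise its
    gene count is uniform on 2..``max_genes_per_disease``.  ``hub_bias`` is
    the per-gene probability that a dominant (AD) disease draws from the top
    degree decile and a recessive (AR) disease from the bottom degree half;
    the remainder is drawn uniformly.  ``module_density`` is the probability
    that each absent within-sign gene pair receives a planted edge.
    """

    n_nodes: int = 5000
    attachment: int = 3
    n_diseases: int = 300
    mono_weight: float = 0.9
    max_genes_per_disease: int = 5
    n_signs: int = 40
    diseases_per_sign: tuple[int, int] = (5, 15)
    module_density: float = 0.1
    hub_bias: float = 0.5
    n_classes: int = 18
    frequency_mix: tuple[float, float, float] = (0.2, 0.5, 0.3)
    n_function_terms: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 100:
            raise ValueError("n_nodes must be >= 100")
        if self.attachment < 1:
            raise ValueError("attachment must be >= 1")
        for name in ("n_diseases", "n_signs", "n_classes", "max_genes_per_disease"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("mono_weight", "module_density", "hub_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.diseases_per_sign
        if not 1 <= lo <= hi:
            raise ValueError("diseases_per_sign must be an increasing positive range")
        if abs(sum(self.frequency_mix) - 1.0) > 1e-9:
            raise ValueError("frequency_mix must sum to 1")


@dataclass
class SyntheticDataset:
    """A generated study: augmented network, tables, ontology, ground truth."""

    network: GeneNetwork
    associations: AssociationSet
    ontology: Ontology
    ground_truth: pd.DataFrame
    config: SimulationConfig
    subroot: str = "PA:0000001"


def _gene_id(i: int) -> str:
    return f"G{i:05d}"


def generate_network(cfg: SimulationConfig) -> GeneNetwork:
    """Scale-free (preferential-attachment) interactome, connected by growth.

    ``attachment`` new links per arriving node; attachment = 1 yields a
    tree.  Node ids are zero-padded gene labels so orderings are stable.
    """
    g = nx.barabasi_albert_graph(cfg.n_nodes, cfg.attachment, seed=cfg.rng_seed)
    g = nx.relabel_nodes(g, {i: _gene_id(i) for i in g.nodes})
    nx.set_edge_attributes(g, 1.0, "weight")
    return GeneNetwork(g)


def _draw_disease_genes(
    rng: np.random.Generator,
    size: int,
    inheritance: str,
    nodes: np.ndarray,
    top_decile: np.ndarray,
    bottom_half: np.ndarray,
    hub_bias: float,
) -> list[str]:
    pool = top_decile if inheritance == "AD" else bottom_half
    chosen: list[str] = []
    taken: set[str] = set()
    while len(chosen) < size:
        src = pool if rng.random() < hub_bias else nodes
        g = str(rng.choice(src))
        if g not in taken:
            taken.add(g)
            chosen.append(g)
    return chosen


def plant_annotations(
    net: GeneNetwork, cfg: SimulationConfig
) -> SyntheticDataset:
    """Plant diseases, signs, metadata and modules onto a network copy.

    Diseases are AD or AR with equal probability; their genes are placed by
    degree according to ``hub_bias``.  Each sign is attached to a random
    block of diseases, its gene union is densified at ``module_density``,
    and the two-level ontology (phenotypic-abnormality-style subroot ->
    ``n_classes`` classes -> signs) is emitted alongside a ground-truth
    table of every planted (sign, disease, gene) triple.
    """
    # two independent streams: module planting must not perturb the
    # disease/sign structure, so sweeping module_density is a paired
    # comparison on identical annotations
    seeds = np.random.SeedSequence(cfg.rng_seed).spawn(2)
    rng = np.random.default_rng(seeds[0])
    rng_mod = np.random.default_rng(seeds[1])
    aug = net.subgraph_copy()
    nodes = np.array(net.node_list())
    if cfg.max_genes_per_disease > len(nodes):
        raise ValueError("requested disease gene sets larger than the network")
    degrees = np.array([net.degree(g) for g in nodes])
    order = np.argsort(-degrees, kind="stable")
    n_top = max(1, len(nodes) // 10)
    top_decile = nodes[order[:n_top]]
    bottom_half = nodes[order[len(nodes) // 2 :]]

    assoc = AssociationSet(gene_functions={})
    truth_rows: list[dict] = []

    # --- diseases ---------------------------------------------------------
    disease_ids = [f"D{i:04d}" for i in range(cfg.n_diseases)]
    for d in disease_ids:
        inheritance = "AD" if rng.random() < 0.5 else "AR"
        size = (
            1
            if rng.random() < cfg.mono_weight
            else int(rng.integers(2, cfg.max_genes_per_disease + 1))
        )
        genes = _draw_disease_genes(
            rng, size, inheritance, nodes, top_decile, bottom_half, cfg.hub_bias
        )
        assoc.disease_genes[d] = set(genes)
        n_onsets = 2 if rng.random() < 0.2 else 1
        onsets = frozenset(
            str(o) for o in rng.choice(_ONSETS, size=n_onsets, replace=False)
        )
        assoc.disease_meta[d] = DiseaseMeta(
            inheritance=inheritance,
            onset=onsets,
            progression=str(rng.choice(_PROGRESSIONS)),
        )

    # --- ontology: subroot -> classes -> signs ----------------------------
    subroot = "PA:0000001"
    class_ids = [f"CL:{i:07d}" for i in range(cfg.n_classes)]
    sign_ids = [f"SG:{i:07d}" for i in range(cfg.n_signs)]
    parents: dict[str, set[str]] = {subroot: set()}
    names = {subroot: "Phenotypic abnormality"}
    for i, c in enumerate(class_ids):
        parents[c] = {subroot}
        names[c] = f"Abnormality class {i}"
    for i, s in enumerate(sign_ids):
        parents[s] = {class_ids[i % cfg.n_classes]}
        names[s] = f"Clinical sign {i}"
    onto = Ontology(parents, names)

    # --- signs: disease blocks, frequencies, planted modules --------------
    lo, hi = cfg.diseases_per_sign
    freq_p = np.array(cfg.frequency_mix)
    for s in sign_ids:
        n_dis = int(rng.integers(lo, min(hi, cfg.n_diseases) + 1))
        block = rng.choice(cfg.n_diseases, size=n_dis, replace=False)
        sign_genes: set[str] = set()
        for di in sorted(block):
            d = disease_ids[di]
            freq = str(rng.choice(_FREQUENCIES, p=freq_p))
            assoc.disease_signs.setdefault(d, {})[s] = freq
            for g in sorted(assoc.disease_genes[d]):
                sign_genes.add(g)
                truth_rows.append(
                    {
                        "sign": s,
                        "sign_class": parents[s] and sorted(parents[s])[0],
                        "disease": d,
                        "gene": g,
                        "inheritance": assoc.disease_meta[d].inheritance,
                        "frequency": freq,
                    }
                )
        # densify the sign module on the augmented copy
        if cfg.module_density > 0:
            members = sorted(sign_genes)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    if not aug.has_edge(members[i], members[j]):
                        if rng_mod.random() < cfg.module_density:
                            aug.add_edge(members[i], members[j], 1.0)

    # --- gene functions ----------------------------------------------------
    fn_ids = [f"FN:{i:04d}" for i in range(cfg.n_function_terms)]
    annotated = sorted({g for gs in assoc.disease_genes.values() for g in gs})
    for g in annotated:
        assoc.gene_functions[g] = {str(rng.choice(fn_ids))}

    truth = pd.DataFrame(
        truth_rows,
        columns=["sign", "sign_class", "disease", "gene", "inheritance", "frequency"],
    ).drop_duplicates(ignore_index=True)
    return SyntheticDataset(
        network=aug,
        associations=assoc,
        ontology=onto,
        ground_truth=truth,
        config=cfg,
        subroot=subroot,
    )


# ---------------------------------------------------------------------------
# Fixture round-trip


def emit_fixture(out_dir: str | Path, dataset: SyntheticDataset) -> dict[str, Path]:
    """Write the dataset in the package's standard TSV formats.

    Emits network.tsv, ontology.tsv, disease_genes.tsv, disease_signs.tsv,
    disease_meta.tsv, gene_functions.tsv, ground_truth.tsv and config.yaml.
    All rows are sorted, so identical configurations produce byte-identical
    directories.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.tsv" for name in (
        "network", "ontology", "disease_genes", "disease_signs",
        "disease_meta", "gene_functions", "ground_truth",
    )}
    write_network(dataset.network, paths["network"])

    with paths["ontology"].open("w") as fh:
        fh.write("child\tparent\n")
        for child in sorted(dataset.ontology.parents):
            for parent in sorted(dataset.ontology.parents[child]):
                fh.write(f"{child}\t{parent}\n")

    assoc = dataset.associations
    with paths["disease_genes"].open("w") as fh:
        fh.write("disease_id\tgene_id\n")
        for d in sorted(assoc.disease_genes):
            for g in sorted(assoc.disease_genes[d]):
                fh.write(f"{d}\t{g}\n")

    with paths["disease_signs"].open("w") as fh:
        fh.write("disease_id\tterm_id\tfrequency\n")
        for d in sorted(assoc.disease_signs):
            for t in sorted(assoc.disease_signs[d]):
                fh.write(f"{d}\t{t}\t{assoc.disease_signs[d][t]}\n")

    with paths["disease_meta"].open("w") as fh:
        fh.write("disease_id\tinheritance\tonset\tprogression\n")
        for d in sorted(assoc.disease_meta):
            m = assoc.disease_meta[d]
            fh.write(f"{d}\t{m.inheritance}\t{';'.join(sorted(m.onset))}\t{m.progression}\n")

    with paths["gene_functions"].open("w") as fh:
        fh.write("gene_id\tfunction_term\tnamespace\n")
        for g in sorted(assoc.gene_functions or {}):
            for t in sorted(assoc.gene_functions[g]):
                fh.write(f"{g}\t{t}\tsynthetic\n")

    dataset.ground_truth.sort_values(
        ["sign", "disease", "gene"], ignore_index=True
    ).to_csv(paths["ground_truth"], sep="\t", index=False)

    cfg_path = out / "config.yaml"
    cfg_dict = asdict(dataset.config)
    cfg_dict["diseases_per_sign"] = list(dataset.config.diseases_per_sign)
    cfg_dict["frequency_mix"] = list(dataset.config.frequency_mix)
    cfg_path.write_text(yaml.safe_dump(cfg_dict, sort_keys=True))
    paths["config"] = cfg_path
    return paths


def load_fixture(fixture_dir: str | Path) -> tuple[GeneNetwork, AssociationSet, Ontology]:
    """Re-read an emitted fixture into in-memory objects."""
    d = Path(fixture_dir)
    net = read_network(d / "network.tsv")
    onto = read_ontology(d / "ontology.tsv", dialect="tsv")
    fn = d / "gene_functions.tsv"
    assoc = read_associations(
        d / "disease_genes.tsv",
        d / "disease_signs.tsv",
        d / "disease_meta.tsv",
        fn if fn.exists() else None,
    )
    return net, assoc, onto
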