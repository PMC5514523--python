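"""From disease-level annotations to non-redundant sign -> gene test sets.

Sign-gene pairs arise indirectly: a gene is linked to a clinical sign when
some disease it causes is annotated with that sign.  Disease annotations
are first closed upward over the ontology (a disease showing 'Ketosis' also
shows every ancestor abnormality), the per-term gene unions are formed, and
the panel keeps only terms with enough genes that have no qualifying, more
specific descendant — the redundancy-removal step that yields a flat set of
maximally specific testable signs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .io import AssociationSet, GeneNetwork, Ontology

logger = logging.getLogger(__name__)

__all__ = [
    "SignGeneSet",
    "SignPanel",
    "propagate_annotations",
    "build_sign_gene_sets",
    "select_panel",
    "restrict_to_network",
    "compactness",
    "classify_diseases",
    "write_panel",
    "write_compactness_report",
]

# decreasing prevalence; smaller index = more frequent
_FREQ_ORDER = {"hallmark": 0, "typical": 1, "occasional": 2, "unknown": 3}


@dataclass
class SignGeneSet:
    """Genes linked to one sign, with the diseases that contributed each."""

    term: str
    genes: set[str] = field(default_factory=set)
    source_diseases: dict[str, set[str]] = field(default_factory=dict)

    def add(self, gene: str, disease: str) -> None:
        self.genes.add(gene)
        self.source_diseases.setdefault(gene, set()).add(disease)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SignPanel:
    """Non-redundant collection of sign gene sets above a size threshold."""

    sets: dict[str, SignGeneSet]
    min_genes: int

    @property
    def terms(self) -> set[str]:
        return set(self.sets)

    def n_pairs(self) -> int:
        return sum(len(s) for s in self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)


def propagate_annotations(
    assoc: AssociationSet, onto: Ontology
) -> dict[str, dict[str, str]]:
    """Close disease sign annotations upward over the ontology.

    Returns disease -> {term: frequency class} where the term set is the
    annotated terms plus all their ancestors, and a propagated ancestor
    inherits the best (most prevalent) frequency class among the annotated
    descendants below it.  Closed under the ancestor relation by
    construction, so applying it twice changes nothing.
    """
    expanded: dict[str, dict[str, str]] = {}
    for disease, sign_map in assoc.disease_signs.items():
        out: dict[str, str] = {}
        for term, freq in sign_map.items():
            if term not in onto:
                raise KeyError(
                    f"term {term!r} annotated to disease {disease!r} is not in the ontology"
                )
            for t in onto.ancestors(term, include_self=True):
                prev = out.get(t)
                if prev is None or _FREQ_ORDER[freq] < _FREQ_ORDER[prev]:
                    out[t] = freq
        expanded[disease] = out
    return expanded


def build_sign_gene_sets(
    expanded: dict[str, dict[str, str]], assoc: AssociationSet
) -> dict[str, SignGeneSet]:
    """Union each term's genes over the diseases annotated with it.

    Diseases without causal genes contribute nothing; terms annotated to no
    gene-bearing disease are absent from the output.
    """
    sets: dict[str, SignGeneSet] = {}
    for disease, term_map in expanded.items():
        genes = assoc.disease_genes.get(disease)
        if not genes:
            continue
        for term in term_map:
            sgs = sets.setdefault(term, SignGeneSet(term=term))
            for g in genes:
                sgs.add(g, disease)
    return sets


def select_panel(
    sets: dict[str, SignGeneSet],
    onto: Ontology,
    min_genes: int = 25,
    subroot: str | None = None,
) -> SignPanel:
    """Keep the most specific terms with at least ``min_genes`` genes.

    Candidate terms are those at or below ``subroot`` (default: the
    ontology root, i.e. the whole phenotypic-abnormality sub-ontology).  A
    passing term is excluded when any proper descendant also passes — the
    survivors are mutually non-redundant: no panel term is an ancestor of
    another.
    """
    if subroot is None:
        subroot = onto.root
    if subroot not in onto:
        raise KeyError(f"subroot {subroot!r} not in ontology")
    in_scope = onto.descendants(subroot, include_self=True)
    passing = {
        t for t, s in sets.items() if t in in_scope and len(s.genes) >= min_genes
    }
    keep = {
        t
        for t in passing
        if not (onto.descendants(t) & passing)
    }
    return SignPanel(sets={t: sets[t] for t in sorted(keep)}, min_genes=min_genes)


def restrict_to_network(panel: SignPanel, net: GeneNetwork) -> SignPanel:
    """Intersect every panel set with the interactome nodes.

    Sets left with fewer than two genes cannot support leave-one-out (an
    empty seed) and are dropped with a warning.
    """
    nodes = net.nodes
    kept: dict[str, SignGeneSet] = {}
    for term, sgs in panel.sets.items():
        genes = sgs.genes & nodes
        if len(genes) < 2:
            logger.warning(
                "sign %s reduced to %d network gene(s); dropped from panel",
                term,
                len(genes),
            )
            continue
        kept[term] = SignGeneSet(
            term=term,
            genes=genes,
            source_diseases={g: set(sgs.source_diseases[g]) for g in genes},
        )
    return SignPanel(sets=kept, min_genes=panel.min_genes)


def compactness(sgs: SignGeneSet, net: GeneNetwork) -> float:
    """Fraction of the sign's genes adjacent to at least one other member.

    The paper-style module statistic: genes at network distance 1 from
    another gene of the same sign, over all the sign's genes.
    """
    if not sgs.genes:
        raise ValueError(f"sign {sgs.term!r} has no genes")
    if not sgs.genes <= net.nodes:
        missing = sorted(sgs.genes - net.nodes)[:5]
        raise KeyError(f"sign genes not in network: {missing}")
    n_close = sum(
        1 for g in sgs.genes if net.neighbors(g) & (sgs.genes - {g})
    )
    return n_close / len(sgs.genes)


def classify_diseases(
    assoc: AssociationSet, net: GeneNetwork
) -> dict[str, str]:
    """Monogenic vs oligogenic by the count of interactome-mappable genes.

    Exactly one network gene -> monogenic; more than one -> oligogenic; none
    -> excluded from the mapping.  Each disease id is classified
    independently (no phenotypic-series aggregation).
    """
    nodes = net.nodes
    out: dict[str, str] = {}
    for disease, genes in assoc.disease_genes.items():
        n = len(genes & nodes)
        if n == 1:
            out[disease] = "monogenic"
        elif n > 1:
            out[disease] = "oligogenic"
    return out


def write_panel(panel: SignPanel, path: str | Path) -> None:
    """Export as TSV: term_id, gene_id, ';'-joined source disease ids."""
    with Path(path).open("w") as fh:
        fh.write("term_id\tgene_id\tsource_disease_ids\n")
        for term in sorted(panel.sets):
            sgs = panel.sets[term]
            for gene in sorted(sgs.genes):
                diseases = ";".join(sorted(sgs.source_diseases.get(gene, ())))
                fh.write(f"{term}\t{gene}\t{diseases}\n")


def read_panel(path: str | Path, min_genes: int = 0) -> SignPanel:
    """Re-read a panel exported by :func:`write_panel`."""
    sets: dict[str, SignGeneSet] = {}
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["term_id", "gene_id"]:
            raise ValueError(f"{path}: unexpected panel header {header}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            term, gene = parts[0], parts[1]
            diseases = parts[2].split(";") if len(parts) > 2 and parts[2] else []
            sgs = sets.setdefault(term, SignGeneSet(term=term))
            sgs.genes.add(gene)
            sgs.source_diseases[gene] = set(diseases)
    return SignPanel(sets=sets, min_genes=min_genes)


def write_compactness_report(
    panel: SignPanel, net: GeneNetwork, path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("term_id\tn_genes\tcompactness\n")
        for term in sorted(panel.sets):
            sgs = panel.sets[term]
            fh.write(f"{term}\t{len(sgs)}\t{compactness(sgs, net):.6f}\n")
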