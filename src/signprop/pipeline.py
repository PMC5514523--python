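"""Convenience chains over the module API.

These compose the standard workflow — ancestor closure, term-gene unions,
most-specific panel selection, interactome restriction — so callers
(command line, scripts, notebooks) do not repeat the five-step recipe.
"""

from __future__ import annotations

from .annotate import (
    SignPanel,
    build_sign_gene_sets,
    propagate_annotations,
    restrict_to_network,
    select_panel,
)
from .io import AssociationSet, GeneNetwork, Ontology

__all__ = ["build_sign_panel"]


def build_sign_panel(
    net: GeneNetwork,
    assoc: AssociationSet,
    onto: Ontology,
    min_genes: int = 25,
    subroot: str | None = None,
) -> SignPanel:
    """Annotation tables -> network-restricted, non-redundant sign panel.

    The size threshold is applied before interactome restriction, matching
    the convention that a sign qualifies by its annotated gene count and is
    then evaluated only on the genes present in the network.
    """
    expanded = propagate_annotations(assoc, onto)
    sets = build_sign_gene_sets(expanded, assoc)
    panel = select_panel(sets, onto, min_genes=min_genes, subroot=subroot)
    return restrict_to_network(panel, net)
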