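"""Tissue-specific network construction.

A tissue qualifies for a network when strictly more than half of the curated
signaling proteins are assigned to it. Each qualifying tissue yields two
induced subgraphs: one keeping only proteins expressed in that tissue
(``ANNOTATED_ONLY``) and one additionally keeping proteins with no expression
record at all (``WITH_UNANNOTATED``). A protein expressed elsewhere but not
in this tissue is excluded under both variants — only proteins with an
entirely empty assignment count as unannotated.
"""

from __future__ import annotations

from .errors import UsageError
from .model import ExpressionAssignment, SignalingNetwork, TissueNetwork, Variant


def eligible_tissues(
    assignment: ExpressionAssignment, signaling_ids: frozenset[str] | set[str]
) -> frozenset[str]:
    """Organ systems with > half of the signaling proteins assigned."""
    signaling_ids = set(signaling_ids)
    counts: dict[str, int] = {}
    for protein in signaling_ids:
        for tissue in assignment.get(protein):
            counts[tissue] = counts.get(tissue, 0) + 1
    threshold = len(signaling_ids) / 2
    return frozenset(t for t, c in counts.items() if c > threshold)


def build_tissue_network(
    network: SignalingNetwork,
    assignment: ExpressionAssignment,
    tissue: str,
    variant: Variant,
) -> TissueNetwork:
    """Induced subgraph of ``network`` for one eligible organ system."""
    variant = Variant(variant)
    if tissue not in eligible_tissues(assignment, network.signaling_ids):
        raise UsageError(
            f"tissue {tissue!r} is not eligible (not assigned to more than "
            "half of the signaling proteins)"
        )
    keep = set()
    for protein_id in network.signaling_ids:
        assigned = assignment.get(protein_id)
        if tissue in assigned:
            keep.add(protein_id)
        elif not assigned and variant is Variant.WITH_UNANNOTATED:
            keep.add(protein_id)
    graph = network.graph().subgraph(keep).copy()
    proteins = network.proteins
    return TissueNetwork(
        tissue=tissue,
        variant=variant,
        graph=graph,
        ligands=frozenset(p for p in keep if proteins[p].is_ligand),
        tfs=frozenset(p for p in keep if proteins[p].is_tf),
    )
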