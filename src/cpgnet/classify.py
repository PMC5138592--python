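"""Cross-talk detection and CPG / non-CPG classification.

A protein participates in cross-talk when a neighbor (in either edge
direction) carries a pathway annotation the protein itself lacks: a protein
already annotated to both pathways is not a bridge between them. A paralog
group is a critical paralog group (CPG) when at least one member is
flow-critical in some tissue AND at least one member (not necessarily the
same one) is a cross-talk protein. Members of CPGs are critical paralogs
(CP), members of other groups are paralog proteins (PP), and signaling
proteins with no group are OTHER. Grouped paralogs outside the curated
network inherit their group's CP/PP label even though they carry no network
metrics.
"""

from __future__ import annotations

from typing import Iterable

from .model import ClassificationTable, SignalingNetwork
from .paralogs import ParalogGroupSet

CPG = "CPG"
NON_CPG = "NON_CPG"
CP = "CP"
PP = "PP"
OTHER = "OTHER"


def crosstalk_proteins(network: SignalingNetwork) -> frozenset[str]:
    """Proteins with a neighbor annotated to a pathway they lack."""
    flagged: set[str] = set()
    proteins = network.proteins
    for source, target in network.edges:
        ps, pt = proteins[source].pathways, proteins[target].pathways
        if pt - ps:
            flagged.add(source)
        if ps - pt:
            flagged.add(target)
    return frozenset(flagged)


def classify_groups(
    group_set: ParalogGroupSet,
    flow_critical: Iterable[str],
    crosstalk: Iterable[str],
) -> ClassificationTable:
    """Label groups CPG / non-CPG and proteins CP / PP / OTHER."""
    flow_critical = frozenset(flow_critical)
    crosstalk = frozenset(crosstalk)
    group_label: dict[str, str] = {}
    protein_label: dict[str, str] = {}
    for gid, group in group_set.groups.items():
        is_cpg = bool(group.members & flow_critical) and bool(
            group.members & crosstalk
        )
        group_label[gid] = CPG if is_cpg else NON_CPG
        member_label = CP if is_cpg else PP
        for member in group.members:
            protein_label[member] = member_label
    for protein in group_set.ungrouped:
        protein_label[protein] = OTHER
    return ClassificationTable(
        group_label=group_label,
        protein_label=protein_label,
        crosstalk=crosstalk,
        flow_critical=flow_critical,
    )
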