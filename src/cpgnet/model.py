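"""Domain types shared by every pipeline stage.

The central object is a :class:`SignalingNetwork`: a directed graph over
proteins, each carrying pathway labels and ligand / transcription-factor role
flags. Signaling flow runs from ligands (source nodes) through mediators to
transcription factors (sink nodes). Proteins outside the curated signaling
set (paralogs pulled in only through paralogy evidence) may appear in the
protein table but carry no edges, no pathways and no role flags.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .errors import DataError, UsageError

#: Annotation families that map a protein to a set of opaque feature IDs.
FEATURE_TYPES = ("TF_REGULATOR", "MIRNA", "GO_BP", "GO_MF", "DISEASE")
#: Annotation families that are bare per-protein boolean flags.
FLAG_TYPES = ("CANCER_DRIVER", "DRUG_TARGET")


class Variant(str, enum.Enum):
    """Tissue-network inclusion variant for proteins without expression data."""

    ANNOTATED_ONLY = "ANNOTATED_ONLY"
    WITH_UNANNOTATED = "WITH_UNANNOTATED"


@dataclass(frozen=True)
class Protein:
    """One protein of the curated network or a paralog outside it."""

    id: str
    pathways: frozenset[str] = frozenset()
    is_ligand: bool = False
    is_tf: bool = False
    in_signaling_set: bool = True

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("protein id must be a non-empty string")
        if not self.in_signaling_set and (
            self.pathways or self.is_ligand or self.is_tf
        ):
            raise DataError(
                f"protein {self.id!r}: outside the signaling set but carries "
                "pathways or role flags"
            )


@dataclass
class SignalingNetwork:
    """Directed signaling network with per-protein pathway and role labels.

    ``edges`` only ever connect proteins with ``in_signaling_set`` set; no
    self-loops, no duplicates. ``graph()`` exposes the curated subnetwork as a
    :class:`networkx.DiGraph` (isolated signaling proteins included).
    """

    proteins: dict[str, Protein]
    edges: set[tuple[str, str]]
    _graph: nx.DiGraph | None = field(default=None, repr=False, compare=False)

    def validate(self) -> None:
        for source, target in self.edges:
            if source == target:
                raise DataError(f"self-loop on {source!r}")
            for endpoint in (source, target):
                protein = self.proteins.get(endpoint)
                if protein is None:
                    raise DataError(
                        f"edge ({source!r}, {target!r}) references unknown "
                        f"protein {endpoint!r}"
                    )
                if not protein.in_signaling_set:
                    raise DataError(
                        f"edge ({source!r}, {target!r}) touches {endpoint!r}, "
                        "which is outside the signaling set"
                    )

    @property
    def signaling_ids(self) -> frozenset[str]:
        return frozenset(
            p.id for p in self.proteins.values() if p.in_signaling_set
        )

    @property
    def ligands(self) -> frozenset[str]:
        return frozenset(p.id for p in self.proteins.values() if p.is_ligand)

    @property
    def tfs(self) -> frozenset[str]:
        return frozenset(p.id for p in self.proteins.values() if p.is_tf)

    def graph(self) -> nx.DiGraph:
        """Directed graph over the signaling proteins (cached)."""
        if self._graph is None:
            g = nx.DiGraph()
            g.add_nodes_from(self.signaling_ids)
            g.add_edges_from(self.edges)
            self._graph = g
        return self._graph


@dataclass
class AnnotationTable:
    """Typed protein -> feature-set map (or per-protein flag set).

    For flag families (``CANCER_DRIVER``, ``DRUG_TARGET``) each flagged
    protein maps to the singleton set holding the family name; ``flagged``
    gives the flagged proteins directly. Proteins absent from ``features``
    have the empty feature set.
    """

    feature_type: str
    features: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        allowed = FEATURE_TYPES + FLAG_TYPES
        if self.feature_type not in allowed:
            raise UsageError(
                f"unknown feature_type {self.feature_type!r}; "
                f"allowed: {', '.join(allowed)}"
            )
        for protein, feats in self.features.items():
            if "" in feats:
                raise DataError(
                    f"empty feature id for protein {protein!r} "
                    f"in {self.feature_type} table"
                )

    def get(self, protein_id: str) -> frozenset[str]:
        return self.features.get(protein_id, frozenset())

    @property
    def flagged(self) -> frozenset[str]:
        return frozenset(p for p, feats in self.features.items() if feats)


@dataclass
class ExpressionAssignment:
    """Protein -> organ-system assignment after raw-tissue consolidation."""

    tissue_map: dict[str, str]
    assignment: dict[str, frozenset[str]]

    def validate(self) -> None:
        organs = set(self.tissue_map.values())
        for protein, systems in self.assignment.items():
            extra = systems - organs
            if extra:
                raise DataError(
                    f"protein {protein!r} assigned to organ systems absent "
                    f"from the tissue map: {sorted(extra)}"
                )

    def get(self, protein_id: str) -> frozenset[str]:
        return self.assignment.get(protein_id, frozenset())

    @property
    def organ_systems(self) -> frozenset[str]:
        return frozenset(self.tissue_map.values())


@dataclass
class TissueNetwork:
    """Induced subgraph of the signaling network for one organ system."""

    tissue: str
    variant: Variant
    graph: nx.DiGraph
    ligands: frozenset[str]
    tfs: frozenset[str]


@dataclass
class EssentialityResult:
    """Per-tissue removal-reachability essentiality.

    ``broken_pairs[v]`` holds the (ligand, TF) pairs that are reachable in the
    intact tissue graph but not after removing ``v``; pairs with ``v`` as an
    endpoint never count.
    """

    tissue: str
    variant: Variant
    broken_pairs: dict[str, frozenset[tuple[str, str]]]

    @property
    def essential(self) -> frozenset[str]:
        return frozenset(v for v, pairs in self.broken_pairs.items() if pairs)


@dataclass
class ClassificationTable:
    """Group labels (CPG / NON_CPG) and protein labels (CP / PP / OTHER)."""

    group_label: dict[str, str]
    protein_label: dict[str, str]
    crosstalk: frozenset[str]
    flow_critical: frozenset[str]

    def proteins_with_label(self, label: str) -> frozenset[str]:
        return frozenset(
            p for p, lab in self.protein_label.items() if lab == label
        )

    @property
    def cps(self) -> frozenset[str]:
        return self.proteins_with_label("CP")

    @property
    def pps(self) -> frozenset[str]:
        return self.proteins_with_label("PP")

    @property
    def others(self) -> frozenset[str]:
        return self.proteins_with_label("OTHER")


def as_bool(value: str | bool) -> bool:
    """Parse a TSV boolean field ('1'/'0', 'true'/'false', case-insensitive)."""
    if isinstance(value, bool):
        return value
    text = value.strip().lower()
    if text in ("1", "true", "yes"):
        return True
    if text in ("0", "false", "no", ""):
        return False
    raise DataError(f"cannot parse boolean field {value!r}")
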