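"""Readers and writers for every flat file the pipeline touches.

All files are UTF-8, tab-separated, one header row; lines starting with '#'
are comments. Writers emit rows in sorted order so that serialization is
bit-stable and a write/read round trip reproduces the in-memory object.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, MappingError, ReferentialError, UsageError
from .model import (
    FEATURE_TYPES,
    FLAG_TYPES,
    AnnotationTable,
    ExpressionAssignment,
    Protein,
    SignalingNetwork,
    as_bool,
)

log = logging.getLogger(__name__)

OrthoRecord = tuple[str, str]  # (group_id, protein_id)
InparanoidRecord = tuple[str, str, str, str]  # (species_a, gene_a, species_b, gene_b)


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    return df


def _write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# signaling network


def read_network(node_table_path: str | Path, edge_table_path: str | Path) -> SignalingNetwork:
    """Read a directed signaling network from a node table and an edge table.

    Duplicate edges are collapsed (with a log line); self-loops and edges
    touching unknown or non-signaling proteins are rejected.
    """
    nodes = _read_tsv(
        node_table_path,
        ["id", "pathways", "is_ligand", "is_tf", "in_signaling_set"],
    )
    proteins: dict[str, Protein] = {}
    for row in nodes.itertuples(index=False):
        if row.id in proteins:
            raise FormatError(f"{node_table_path}: duplicate protein id {row.id!r}")
        pathways = frozenset(p for p in row.pathways.split(";") if p)
        try:
            proteins[row.id] = Protein(
                id=row.id,
                pathways=pathways,
                is_ligand=as_bool(row.is_ligand),
                is_tf=as_bool(row.is_tf),
                in_signaling_set=as_bool(row.in_signaling_set),
            )
        except Exception as exc:  # invariant violations surface as FormatError
            raise FormatError(f"{node_table_path}: {exc}") from exc

    edge_df = _read_tsv(edge_table_path, ["source", "target"])
    edges: set[tuple[str, str]] = set()
    n_dup = 0
    for row in edge_df.itertuples(index=False):
        edge = (row.source, row.target)
        if row.source == row.target:
            raise FormatError(
                f"{edge_table_path}: self-loop edge {row.source!r} -> {row.target!r}"
            )
        for endpoint in edge:
            protein = proteins.get(endpoint)
            if protein is None:
                raise ReferentialError(
                    f"{edge_table_path}: edge {edge!r} references unknown node "
                    f"{endpoint!r}"
                )
            if not protein.in_signaling_set:
                raise ReferentialError(
                    f"{edge_table_path}: edge {edge!r} touches {endpoint!r}, "
                    "which is outside the signaling set"
                )
        if edge in edges:
            n_dup += 1
            continue
        edges.add(edge)
    if n_dup:
        log.info("collapsed %d duplicate edge record(s)", n_dup)

    network = SignalingNetwork(proteins=proteins, edges=edges)
    network.validate()
    return network


def write_network(
    network: SignalingNetwork,
    node_table_path: str | Path,
    edge_table_path: str | Path,
) -> None:
    _write_tsv(
        node_table_path,
        ["id", "pathways", "is_ligand", "is_tf", "in_signaling_set"],
        (
            (
                p.id,
                ";".join(sorted(p.pathways)),
                int(p.is_ligand),
                int(p.is_tf),
                int(p.in_signaling_set),
            )
            for p in sorted(network.proteins.values(), key=lambda p: p.id)
        ),
    )
    _write_tsv(edge_table_path, ["source", "target"], sorted(network.edges))


# ---------------------------------------------------------------------------
# paralogy sources


def read_orthodb(path: str | Path, focal_taxon: str = "9606") -> list[OrthoRecord]:
    """Read group-per-row paralogy records, keeping only the focal taxon.

    Returns (group_id, protein_id) records in file order, duplicates removed.
    """
    df = _read_tsv(path, ["og_id", "tax_id", "gene_id"])
    records: list[OrthoRecord] = []
    seen: set[OrthoRecord] = set()
    for row in df.itertuples(index=False):
        if row.tax_id != focal_taxon:
            continue
        record = (row.og_id, row.gene_id)
        if record in seen:
            continue
        seen.add(record)
        records.append(record)
    if not records:
        log.warning("%s: no records for focal taxon %s", path, focal_taxon)
    return records


def write_orthodb(
    records: Iterable[tuple[str, str, str]], path: str | Path
) -> None:
    """Write raw (og_id, tax_id, gene_id) rows."""
    _write_tsv(path, ["og_id", "tax_id", "gene_id"], records)


def read_inparanoid(paths: Sequence[str | Path] | str | Path) -> list[InparanoidRecord]:
    """Read pairwise similarity records from one or more files.

    The two (species, gene) endpoints of each pair are unordered: (a, b) and
    (b, a) rows collapse to one canonically ordered record.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    records: list[InparanoidRecord] = []
    seen: set[tuple] = set()
    header = ["species_a", "gene_a", "species_b", "gene_b"]
    for path in paths:
        with open(path, encoding="utf-8") as fh:
            saw_header = False
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if not saw_header:
                    missing = [c for c in header if c not in fields]
                    if missing:
                        raise FormatError(
                            f"{path}: missing required column(s): "
                            f"{', '.join(missing)}"
                        )
                    index = [fields.index(c) for c in header]
                    saw_header = True
                    continue
                if len(fields) < len(header) or any(
                    not fields[i].strip() for i in index
                ):
                    raise FormatError(
                        f"{path} line {lineno}: expected 4 non-empty fields"
                    )
                sa, ga, sb, gb = (fields[i].strip() for i in index)
                left, right = sorted([(sa, ga), (sb, gb)])
                key = (left, right)
                if key in seen:
                    continue
                seen.add(key)
                records.append((left[0], left[1], right[0], right[1]))
    return records


def write_inparanoid(records: Iterable[InparanoidRecord], path: str | Path) -> None:
    _write_tsv(path, ["species_a", "gene_a", "species_b", "gene_b"], records)


# ---------------------------------------------------------------------------
# expression


def read_expression(
    expression_path: str | Path, tissue_map_path: str | Path
) -> ExpressionAssignment:
    """Read per-protein raw-tissue expression and consolidate to organ systems.

    Raw tissues absent from the tissue map raise a :class:`MappingError`
    naming every offending tissue.
    """
    map_df = _read_tsv(tissue_map_path, ["raw_tissue", "organ_system"])
    tissue_map = {
        row.raw_tissue: row.organ_system for row in map_df.itertuples(index=False)
    }
    expr_df = _read_tsv(expression_path, ["protein_id", "raw_tissue"])
    unmapped = sorted(
        set(expr_df["raw_tissue"]) - set(tissue_map)
    )
    if unmapped:
        raise MappingError(
            f"{expression_path}: raw tissue(s) without organ-system mapping: "
            f"{', '.join(unmapped)}"
        )
    assignment: dict[str, set[str]] = {}
    for row in expr_df.itertuples(index=False):
        assignment.setdefault(row.protein_id, set()).add(
            tissue_map[row.raw_tissue]
        )
    result = ExpressionAssignment(
        tissue_map=tissue_map,
        assignment={p: frozenset(s) for p, s in assignment.items()},
    )
    result.validate()
    return result


def write_expression(
    assignment: ExpressionAssignment,
    expression_path: str | Path,
    tissue_map_path: str | Path,
) -> None:
    """Serialize an assignment using one representative raw tissue per organ."""
    _write_tsv(
        tissue_map_path,
        ["raw_tissue", "organ_system"],
        sorted(assignment.tissue_map.items()),
    )
    representative: dict[str, str] = {}
    for raw, organ in sorted(assignment.tissue_map.items()):
        representative.setdefault(organ, raw)
    rows = []
    for protein in sorted(assignment.assignment):
        for organ in sorted(assignment.assignment[protein]):
            rows.append((protein, representative[organ]))
    _write_tsv(expression_path, ["protein_id", "raw_tissue"], rows)


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str | Path, feature_type: str) -> AnnotationTable:
    """Read a protein -> feature table of the stated annotation family.

    Flag families expect a bare ``protein_id`` column (presence = flagged).
    """
    if feature_type not in FEATURE_TYPES + FLAG_TYPES:
        raise UsageError(
            f"unknown feature_type {feature_type!r}; allowed: "
            f"{', '.join(FEATURE_TYPES + FLAG_TYPES)}"
        )
    features: dict[str, set[str]] = {}
    if feature_type in FLAG_TYPES:
        df = _read_tsv(path, ["protein_id"])
        for row in df.itertuples(index=False):
            features.setdefault(row.protein_id, set()).add(feature_type)
    else:
        df = _read_tsv(path, ["protein_id", "feature_id"])
        for row in df.itertuples(index=False):
            if not row.feature_id:
                raise FormatError(
                    f"{path}: empty feature_id for protein {row.protein_id!r}"
                )
            features.setdefault(row.protein_id, set()).add(row.feature_id)
    return AnnotationTable(
        feature_type=feature_type,
        features={p: frozenset(s) for p, s in features.items()},
    )


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    if table.feature_type in FLAG_TYPES:
        _write_tsv(
            path, ["protein_id"], ((p,) for p in sorted(table.flagged))
        )
    else:
        rows = [
            (p, f)
            for p in sorted(table.features)
            for f in sorted(table.features[p])
        ]
        _write_tsv(path, ["protein_id", "feature_id"], rows)
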