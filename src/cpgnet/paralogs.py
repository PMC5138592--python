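"""Paralog-group construction and source merging.

Two complementary paralogy sources feed the pipeline: group-per-row records
(an orthologous-group table restricted to the focal taxon) and pairwise
similarity records (focal-species genes connected through a path of pairwise
similarities across species form one group). Candidate groups from both
sources are merged into a disjoint partition: every protein is assigned to
its candidate group with the highest score

    D = n / m

where n is the number of group members in the curated signaling set and m
the total member count. Exact D ties are broken by the larger n, remaining
ties by the lexicographically smallest group id. Groups are rebuilt from the
assignments; rebuilt groups with fewer than two members dissolve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import networkx as nx

from .errors import UsageError
from .io import InparanoidRecord, OrthoRecord

log = logging.getLogger(__name__)

ORTHODB = "ORTHODB"
INPARANOID = "INPARANOID"
MERGED = "MERGED"

#: Named scorers for the group distance measure. ``n`` = signaling members,
#: ``m`` = all members. The default is the signaling-member ratio.
SCORERS: dict[str, Callable[[int, int], float]] = {
    "ratio": lambda n, m: n / m,
}


@dataclass(frozen=True)
class ParalogGroup:
    """A set of focal-species proteins clustered as mutual paralogs.

    ``n``, ``D`` are populated once the group is scored against the curated
    signaling protein set.
    """

    group_id: str
    members: frozenset[str]
    source: str
    n: int | None = None
    D: float | None = None

    @property
    def m(self) -> int:
        return len(self.members)


@dataclass
class ParalogGroupSet:
    """Disjoint paralog groups plus the signaling proteins left ungrouped."""

    groups: dict[str, ParalogGroup]
    ungrouped: frozenset[str]

    def member_to_group(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for gid, group in self.groups.items():
            for member in group.members:
                out[member] = gid
        return out

    def partition(self) -> frozenset[frozenset[str]]:
        return frozenset(g.members for g in self.groups.values())


def orthodb_groups(records: Iterable[OrthoRecord]) -> list[ParalogGroup]:
    """One group per orthologous-group id with at least two focal members."""
    members: dict[str, set[str]] = {}
    for group_id, protein_id in records:
        members.setdefault(group_id, set()).add(protein_id)
    return [
        ParalogGroup(group_id=gid, members=frozenset(ms), source=ORTHODB)
        for gid, ms in sorted(members.items())
        if len(ms) >= 2
    ]


def inparanoid_groups(
    pair_records: Iterable[InparanoidRecord], focal_species: str = "9606"
) -> list[ParalogGroup]:
    """Groups from connected components of the pairwise-similarity graph.

    Nodes are (species, gene) pairs; an edge joins the two endpoints of each
    record. Within each component, the focal-species genes (if at least two)
    form one group — focal genes may be connected only through genes of other
    species. Group ids are assigned deterministically from the sorted member
    lists, so input order never matters.
    """
    graph = nx.Graph()
    for sa, ga, sb, gb in pair_records:
        graph.add_edge((sa, ga), (sb, gb))
    member_sets = []
    for component in nx.connected_components(graph):
        focal = sorted(g for (s, g) in component if s == focal_species)
        if len(focal) >= 2:
            member_sets.append(focal)
    member_sets.sort()
    return [
        ParalogGroup(
            group_id=f"IP{i:04d}", members=frozenset(ms), source=INPARANOID
        )
        for i, ms in enumerate(member_sets)
    ]


def score_group(
    group: ParalogGroup,
    signaling_ids: frozenset[str] | set[str],
    scorer: str | Callable[[int, int], float] = "ratio",
) -> ParalogGroup:
    """Return a scored copy of ``group`` (fields ``n`` and ``D`` populated).

    Groups with no signaling member cannot be scored and are rejected.
    """
    if group.m < 2:
        raise UsageError(f"group {group.group_id!r} has fewer than 2 members")
    n = len(group.members & set(signaling_ids))
    if n == 0:
        raise UsageError(
            f"group {group.group_id!r} has no signaling member; "
            "discard it before scoring"
        )
    fn = SCORERS[scorer] if isinstance(scorer, str) else scorer
    return replace(group, n=n, D=fn(n, group.m))


def _scored_candidates(
    groups: Iterable[ParalogGroup],
    signaling_ids: frozenset[str] | set[str],
    scorer: str | Callable[[int, int], float],
) -> list[ParalogGroup]:
    out = []
    for group in groups:
        if not (group.members & set(signaling_ids)):
            log.debug("dropping group %s: no signaling member", group.group_id)
            continue
        out.append(score_group(group, signaling_ids, scorer))
    return out


def assign_protein(
    candidates: Sequence[ParalogGroup], d_tol: float = 0.0
) -> ParalogGroup:
    """Pick the winning candidate group for one protein.

    Highest D wins; candidates within ``d_tol`` of the best D count as tied
    and are decided by the larger n, then the smaller group id.
    """
    if not candidates:
        raise UsageError("no candidate groups")
    best_d = max(g.D for g in candidates)
    tied = [g for g in candidates if g.D >= best_d - d_tol]
    return min(tied, key=lambda g: (-g.n, g.group_id))


def merge_sources(
    orthodb_list: Iterable[ParalogGroup],
    inparanoid_list: Iterable[ParalogGroup],
    signaling_ids: frozenset[str] | set[str],
    scorer: str | Callable[[int, int], float] = "ratio",
    d_tol: float = 0.0,
) -> ParalogGroupSet:
    """Merge candidate groups from both sources into a disjoint partition."""
    if not signaling_ids:
        raise UsageError("signaling_ids must be non-empty")
    signaling_ids = frozenset(signaling_ids)
    candidates = _scored_candidates(
        orthodb_list, signaling_ids, scorer
    ) + _scored_candidates(inparanoid_list, signaling_ids, scorer)

    # Candidate ids must be unique for deterministic tie-breaking.
    by_id: dict[str, ParalogGroup] = {}
    for group in candidates:
        gid = group.group_id
        if gid in by_id and by_id[gid].members != group.members:
            gid = f"{group.source[:2]}:{group.group_id}"
        by_id[gid] = replace(group, group_id=gid)

    membership: dict[str, list[ParalogGroup]] = {}
    for group in by_id.values():
        for member in group.members:
            membership.setdefault(member, []).append(group)

    assigned: dict[str, set[str]] = {}
    for protein in sorted(membership):
        winner = assign_protein(membership[protein], d_tol=d_tol)
        assigned.setdefault(winner.group_id, set()).add(protein)

    groups: dict[str, ParalogGroup] = {}
    for gid in sorted(assigned):
        members = frozenset(assigned[gid])
        if len(members) < 2 or not (members & signaling_ids):
            continue  # dissolved: members fall back to ungrouped below
        groups[gid] = score_group(
            ParalogGroup(group_id=gid, members=members, source=MERGED),
            signaling_ids,
            scorer,
        )

    grouped = frozenset().union(*(g.members for g in groups.values())) if groups else frozenset()
    ungrouped = signaling_ids - grouped
    return ParalogGroupSet(groups=groups, ungrouped=ungrouped)


# ---------------------------------------------------------------------------
# serialization


def write_groups(group_set: ParalogGroupSet, groups_path, ungrouped_path) -> None:
    from .io import _write_tsv  # local import to avoid cycle at module load

    rows = []
    for gid in sorted(group_set.groups):
        g = group_set.groups[gid]
        for member in sorted(g.members):
            rows.append((gid, member, g.source, g.n, g.m, f"{g.D:.6g}"))
    _write_tsv(
        groups_path, ["group_id", "member_id", "source", "n", "m", "D"], rows
    )
    _write_tsv(
        ungrouped_path, ["protein_id"], ((p,) for p in sorted(group_set.ungrouped))
    )


def read_groups(groups_path, ungrouped_path) -> ParalogGroupSet:
    from .io import _read_tsv

    df = _read_tsv(groups_path, ["group_id", "member_id", "source", "n", "m", "D"])
    rows_by_gid: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        info = rows_by_gid.setdefault(
            row.group_id,
            {"members": set(), "source": row.source, "n": int(row.n), "D": float(row.D)},
        )
        info["members"].add(row.member_id)
    groups = {
        gid: ParalogGroup(
            group_id=gid,
            members=frozenset(info["members"]),
            source=info["source"],
            n=info["n"],
            D=info["D"],
        )
        for gid, info in rows_by_gid.items()
    }
    udf = _read_tsv(ungrouped_path, ["protein_id"])
    return ParalogGroupSet(
        groups=groups, ungrouped=frozenset(udf["protein_id"])
    )
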