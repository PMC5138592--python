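"""Synthetic signaling datasets with planted critical paralog groups.

The generator emits every input file the pipeline consumes — network tables,
both paralogy file shapes, tissue expression, annotation tables — together
with truth tables, so the whole analysis is testable without any database
download.

Construction guarantees (at the zero-noise defaults) that the pipeline
recovers the planted structure exactly:

* Each pathway is a layered DAG: ligands -> mediator layers -> transcription
  factors, with *complete bipartite* wiring between consecutive layers.
  Every interior layer holds at least two proteins, so removing any single
  node never disconnects a ligand -> TF pair: backbone proteins are never
  essential.
* A planted essential member is a regular mediator ``c`` plus a private
  ligand -> c -> TF attachment. The private ligand/TF pair is expressed only
  in the group's designated tissues, where removing ``c`` is the only way to
  break their pairs — so the tissue-specific essential sets are exactly the
  planted ones.
* Cross-talk edges are added only in redundant *bundles* of two parallel
  edges whose sources share a layer (and likewise the targets), so
  cross-pathway signal flow always has two node-disjoint routes and
  cross-talk never creates accidental essential proteins. Cross-talk truth
  is exactly the set of bundle endpoints.
* Unannotated proteins (no expression record) are drawn only from unreserved
  filler mediators, capped so every layer keeps two expressed members; hence
  the two tissue-inclusion variants yield identical essential sets.
* Paralog-group truth is split across the two paralogy sources: groups
  alternate between a group-per-row encoding and a pairwise-similarity chain
  (every fifth group appears in both), so the merge step does real work.

Before emission the generator re-verifies every planted essential member
with its own breadth-first reachability check and fails loudly on any
violation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from . import io as cio
from .errors import DataError, ParameterError
from .model import (
    AnnotationTable,
    ExpressionAssignment,
    Protein,
    SignalingNetwork,
)

DEFAULT_ORGAN_SYSTEMS = (
    "adipose_soft_tissue",
    "blood",
    "cardiovascular",
    "cns",
    "ear",
    "endocrine",
    "eye",
    "gastrointestinal",
    "kidney_urinary",
    "liver_and_gall",
    "lymphoid_immune",
    "musculoskeletal",
    "pancreas",
    "pns",
    "reproductive_female",
    "reproductive_male",
    "respiratory",
    "skin",
)

DEFAULT_PATHWAYS = ("RTK", "TGFB", "NOTCH", "WNT", "HH", "JAKSTAT", "NHR")

#: File layout written by :func:`write_dataset` and consumed by the CLI.
DATASET_FILES = {
    "nodes": "nodes.tsv",
    "edges": "edges.tsv",
    "orthodb": "orthodb.tsv",
    "inparanoid": "inparanoid.tsv",
    "expression": "expression.tsv",
    "tissue_map": "tissue_map.tsv",
    "TF_REGULATOR": "ann_tf_regulator.tsv",
    "MIRNA": "ann_mirna.tsv",
    "GO_BP": "ann_go_bp.tsv",
    "GO_MF": "ann_go_mf.tsv",
    "DISEASE": "ann_disease.tsv",
    "CANCER_DRIVER": "ann_cancer_driver.tsv",
    "DRUG_TARGET": "ann_drug_target.tsv",
}


def _default_features_per_protein() -> dict[str, int]:
    return {"TF_REGULATOR": 3, "MIRNA": 3, "GO_BP": 4, "GO_MF": 3, "DISEASE": 1}


def _default_flag_rates() -> dict[str, dict[str, float]]:
    # Per-class base rates for the boolean annotations; the CP/PP contrasts
    # mirror the disease-gene, cancer-driver and drug-target proportions the
    # method is meant to expose.
    return {
        "DISEASE_GENE": {"CP": 0.41, "PP": 0.21, "OTHER": 0.37},
        "CANCER_DRIVER": {"CP": 0.172, "PP": 0.082, "OTHER": 0.15},
        "DRUG_TARGET": {"CP": 0.16, "PP": 0.04, "OTHER": 0.10},
    }


@dataclass
class GeneratorParams:
    """Knobs of the synthetic-data generator.

    Defaults describe the study conditions: seven pathways of ~94 proteins
    each (~700 signaling proteins with the private ligand/TF attachments),
    60 paralog groups of 2-4 members of which a third are planted critical,
    18 organ systems, and 22.5% of signaling proteins without expression
    records. Noise knobs default to zero so that planted truth is recovered
    exactly; raising them degrades recovery on purpose.
    """

    seed: int = 0
    n_pathways: int = 7
    proteins_per_pathway: int = 94
    ligand_fraction: float = 0.032
    tf_fraction: float = 0.032
    n_layers: int = 11
    intra_edge_prob: float = 0.05
    crosstalk_edge_prob: float = 0.15
    n_groups: int = 60
    group_size_geom_p: float = 0.6
    outside_paralog_prob: float = 0.5
    planted_cpg_fraction: float = 1 / 3
    noncpg_crosstalk_fraction: float = 0.5
    noncpg_bottleneck_fraction: float = 0.5
    n_tissues: int = 18
    raw_tissues_per_organ: int = 7
    tissue_coverage_prob: float = 1.0
    unannotated_fraction: float = 0.225
    bottleneck_tissues_max: int = 3
    features_per_protein: dict[str, int] = field(
        default_factory=_default_features_per_protein
    )
    base_specific_features: int = 1
    specificity_boost: int = 2
    tf_activity_rate_cp: float = 0.5
    tf_activity_rate_bg: float = 0.15
    centrality_boost: int = 8
    flag_rates: dict[str, dict[str, float]] = field(
        default_factory=_default_flag_rates
    )
    focal_taxon: str = "9606"
    # noise knobs (0 = exact recovery)
    expression_dropout: float = 0.0
    annotation_noise: float = 0.0

    def validate(self) -> None:
        probs = {
            "ligand_fraction": self.ligand_fraction,
            "tf_fraction": self.tf_fraction,
            "intra_edge_prob": self.intra_edge_prob,
            "crosstalk_edge_prob": self.crosstalk_edge_prob,
            "group_size_geom_p": self.group_size_geom_p,
            "outside_paralog_prob": self.outside_paralog_prob,
            "planted_cpg_fraction": self.planted_cpg_fraction,
            "noncpg_crosstalk_fraction": self.noncpg_crosstalk_fraction,
            "noncpg_bottleneck_fraction": self.noncpg_bottleneck_fraction,
            "tissue_coverage_prob": self.tissue_coverage_prob,
            "unannotated_fraction": self.unannotated_fraction,
            "expression_dropout": self.expression_dropout,
            "annotation_noise": self.annotation_noise,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {value}")
        if self.n_pathways < 2:
            raise ParameterError("need at least 2 pathways for cross-talk")
        if self.n_layers < 3:
            raise ParameterError("need at least 3 mediator layers")
        n_lig = max(2, round(self.ligand_fraction * self.proteins_per_pathway))
        n_tf = max(2, round(self.tf_fraction * self.proteins_per_pathway))
        mediators = self.proteins_per_pathway - n_lig - n_tf
        if mediators < 2 * self.n_layers:
            raise ParameterError(
                "proteins_per_pathway too small: every mediator layer needs "
                "at least 2 proteins"
            )
        if self.n_tissues < 1 or self.bottleneck_tissues_max < 1:
            raise ParameterError("need at least one tissue")
        if self.n_groups < 1:
            raise ParameterError("need at least one paralog group")


@dataclass
class TruthTables:
    """Planted ground truth, consistent with the emitted files."""

    groups: dict[str, frozenset[str]]
    group_label: dict[str, str]
    protein_label: dict[str, str]
    essential_by_tissue: dict[str, frozenset[str]]
    crosstalk: frozenset[str]

    def partition(self) -> frozenset[frozenset[str]]:
        return frozenset(self.groups.values())


@dataclass
class SyntheticDataset:
    params: GeneratorParams
    network: SignalingNetwork
    orthodb_rows: list[tuple[str, str, str]]
    inparanoid_records: list[tuple[str, str, str, str]]
    tissue_map: dict[str, str]
    expression_rows: list[tuple[str, str]]
    annotations: dict[str, AnnotationTable]
    truth: TruthTables

    @property
    def assignment(self) -> ExpressionAssignment:
        out: dict[str, set[str]] = {}
        for protein, raw in self.expression_rows:
            out.setdefault(protein, set()).add(self.tissue_map[raw])
        return ExpressionAssignment(
            tissue_map=dict(self.tissue_map),
            assignment={p: frozenset(s) for p, s in out.items()},
        )


def _pop_random(rng: np.random.Generator, pool: list[str]) -> str:
    idx = int(rng.integers(len(pool)))
    return pool.pop(idx)


def _pop_in_layer(
    rng: np.random.Generator,
    pool: list[str],
    loc: dict[str, tuple[str, int]],
    where: tuple[str, int],
) -> str | None:
    candidates = [i for i, x in enumerate(pool) if loc[x] == where]
    if not candidates:
        return None
    idx = candidates[int(rng.integers(len(candidates)))]
    return pool.pop(idx)


def _pop_with_partner(
    rng: np.random.Generator,
    pool: list[str],
    loc: dict[str, tuple[str, int]],
) -> tuple[str, str]:
    """Pop a mediator plus a second free mediator from the same layer.

    Cross-talk edges are planted in same-layer pairs so that cross-pathway
    flow always has two node-disjoint routes; both endpoints are reserved
    together to guarantee the pair exists.
    """
    order = list(rng.permutation(len(pool)))
    for idx in order:
        u = pool[idx]
        partners = [x for x in pool if x is not u and loc[x] == loc[u]]
        if partners:
            partner = partners[int(rng.integers(len(partners)))]
            pool.remove(u)
            pool.remove(partner)
            return u, partner
    raise ParameterError("no same-layer mediator pair left for cross-talk")


def generate(params: GeneratorParams | None = None, **overrides) -> SyntheticDataset:
    """Generate a complete labeled dataset; ``seed`` fully determines it."""
    if params is None:
        params = GeneratorParams(**overrides)
    elif overrides:
        raise ParameterError("pass either params or keyword overrides, not both")
    params.validate()
    rng = np.random.default_rng(params.seed)

    if params.n_pathways <= len(DEFAULT_PATHWAYS):
        pathways = list(DEFAULT_PATHWAYS[: params.n_pathways])
    else:
        pathways = [f"PW{i}" for i in range(params.n_pathways)]

    n_lig = max(2, round(params.ligand_fraction * params.proteins_per_pathway))
    n_tf = max(2, round(params.tf_fraction * params.proteins_per_pathway))
    n_med = params.proteins_per_pathway - n_lig - n_tf

    proteins: dict[str, Protein] = {}
    edges: set[tuple[str, str]] = set()
    ligands_by_pw: dict[str, list[str]] = {}
    tfs_by_pw: dict[str, list[str]] = {}
    layers_by_pw: dict[str, list[list[str]]] = {}
    loc: dict[str, tuple[str, int]] = {}  # mediator -> (pathway, layer index)

    for pw in pathways:
        ligs = [f"{pw}_L{i}" for i in range(n_lig)]
        tfs = [f"{pw}_T{i}" for i in range(n_tf)]
        base, extra = divmod(n_med, params.n_layers)
        layers: list[list[str]] = []
        counter = 0
        for k in range(params.n_layers):
            size = base + (1 if k < extra else 0)
            layer = [f"{pw}_M{k}_{j}" for j in range(size)]
            counter += size
            layers.append(layer)
            for node in layer:
                loc[node] = (pw, k)
        ligands_by_pw[pw] = ligs
        tfs_by_pw[pw] = tfs
        layers_by_pw[pw] = layers
        for lig in ligs:
            proteins[lig] = Protein(lig, frozenset({pw}), is_ligand=True)
        for tf in tfs:
            proteins[tf] = Protein(tf, frozenset({pw}), is_tf=True)
        for layer in layers:
            for node in layer:
                proteins[node] = Protein(node, frozenset({pw}))
        # complete bipartite wiring between consecutive layers
        chain = [ligs] + layers + [tfs]
        for upper, lower in zip(chain, chain[1:]):
            for u in upper:
                for w in lower:
                    edges.add((u, w))
        # sparse forward skip edges (extra redundancy, degree variance)
        for k, layer in enumerate(layers):
            for node in layer:
                if rng.random() < params.intra_edge_prob:
                    later = [
                        x for kk in range(k + 2, params.n_layers)
                        for x in layers[kk]
                    ] + tfs
                    if later:
                        edges.add((node, later[int(rng.integers(len(later)))]))

    # ------------------------------------------------------------------
    # paralog groups with planted roles
    n_cpg = round(params.n_groups * params.planted_cpg_fraction)
    n_noncpg = params.n_groups - n_cpg
    n_type_a = round(n_noncpg * params.noncpg_crosstalk_fraction)
    n_type_b = n_noncpg - n_type_a
    n_type_b_bn = round(n_type_b * params.noncpg_bottleneck_fraction)

    free = sorted(loc)  # unreserved mediators
    group_members: dict[str, frozenset[str]] = {}
    group_label: dict[str, str] = {}
    group_net: dict[str, list[str]] = {}
    bottleneck_of: dict[str, str] = {}  # gid -> designated essential member
    cross_member_of: dict[str, str] = {}  # gid -> designated cross-talk member
    bundle_partner: dict[str, str] = {}  # gid -> reserved same-layer partner
    outside_counter = 0

    for i in range(params.n_groups):
        gid = f"G{i:03d}"
        if i < n_cpg:
            kind = "CPG"
        elif i < n_cpg + n_type_a:
            kind = "TYPE_A"  # redundant placements, cross-talking member
        elif i < n_cpg + n_type_a + n_type_b_bn:
            kind = "TYPE_B_BN"  # essential member but no cross-talk
        else:
            kind = "TYPE_B"  # neither
        size = 2 + min(int(rng.geometric(params.group_size_geom_p)) - 1, 2)
        min_net = 2 if kind == "CPG" else 1
        n_outside = (
            1
            if size - 1 >= min_net and rng.random() < params.outside_paralog_prob
            else 0
        )
        n_net = size - n_outside
        if len(free) < n_net + 1:
            raise ParameterError(
                "not enough free mediators for the requested group structure"
            )
        net: list[str] = []
        if kind == "CPG":
            bottleneck_of[gid] = _pop_random(rng, free)
            net.append(bottleneck_of[gid])
        if kind in ("CPG", "TYPE_A"):
            # the cross-talking member is reserved together with its
            # same-layer bundle partner (the partner stays outside the group)
            cross, partner = _pop_with_partner(rng, free, loc)
            cross_member_of[gid] = cross
            bundle_partner[gid] = partner
            net.append(cross)
        while len(net) < n_net:
            net.append(_pop_random(rng, free))
        if kind == "TYPE_B_BN":
            bottleneck_of[gid] = net[0]
        outside = []
        for _ in range(n_outside):
            outside.append(f"PX{outside_counter:04d}")
            outside_counter += 1
        group_members[gid] = frozenset(net + outside)
        group_label[gid] = "CPG" if kind == "CPG" else "NON_CPG"
        group_net[gid] = net
        for p in outside:
            proteins[p] = Protein(p, in_signaling_set=False)

    # ------------------------------------------------------------------
    # private ligand -> c -> TF attachments for planted essential members
    if params.n_tissues == 18:
        organs = list(DEFAULT_ORGAN_SYSTEMS)
    else:
        organs = [f"organ_{i:02d}" for i in range(params.n_tissues)]
    bottleneck_organs: dict[str, tuple[str, ...]] = {}
    trio_of: dict[str, tuple[str, str]] = {}  # gid -> (private ligand, private TF)
    for gid in sorted(bottleneck_of):
        c = bottleneck_of[gid]
        pw = loc[c][0]
        lx, tx = f"{gid}_LX", f"{gid}_TX"
        proteins[lx] = Protein(lx, frozenset({pw}), is_ligand=True)
        proteins[tx] = Protein(tx, frozenset({pw}), is_tf=True)
        edges.add((lx, c))
        edges.add((c, tx))
        trio_of[gid] = (lx, tx)
        n_org = 1 + int(rng.integers(params.bottleneck_tissues_max))
        chosen = rng.choice(len(organs), size=min(n_org, len(organs)), replace=False)
        bottleneck_organs[gid] = tuple(sorted(organs[j] for j in chosen))

    # extra within-pathway edges through the planted CPG bottlenecks
    for gid in sorted(bottleneck_of):
        if group_label[gid] != "CPG":
            continue
        c = bottleneck_of[gid]
        pw, k = loc[c]
        sources = ligands_by_pw[pw] + [
            x for kk in range(0, k - 1) for x in layers_by_pw[pw][kk]
        ]
        targets = [
            x for kk in range(k + 2, params.n_layers)
            for x in layers_by_pw[pw][kk]
        ] + tfs_by_pw[pw]
        budget = params.centrality_boost
        rng.shuffle(sources)
        for src in sources:
            if budget == 0:
                break
            if (src, c) not in edges:
                edges.add((src, c))
                budget -= 1
        rng.shuffle(targets)
        for tgt in targets:
            if budget == 0:
                break
            if (c, tgt) not in edges:
                edges.add((c, tgt))
                budget -= 1

    # ------------------------------------------------------------------
    # cross-talk bundles: two parallel edges, sources sharing a layer,
    # targets sharing a layer, between two distinct pathways
    crosstalk_truth: set[str] = set()

    def _add_bundle(u1: str, u2: str) -> bool:
        pw_u = loc[u1][0]
        others = [pw for pw in pathways if pw != pw_u]
        rng.shuffle(others)
        for pw_v in others:
            layer_order = list(rng.permutation(params.n_layers))
            for layer_v in layer_order:
                v1 = _pop_in_layer(rng, free, loc, (pw_v, int(layer_v)))
                if v1 is None:
                    continue
                v2 = _pop_in_layer(rng, free, loc, (pw_v, int(layer_v)))
                if v2 is None:
                    free.append(v1)
                    free.sort()
                    continue
                edges.add((u1, v1))
                edges.add((u2, v2))
                crosstalk_truth.update((u1, u2, v1, v2))
                return True
        return False

    for gid in sorted(cross_member_of):
        if not _add_bundle(cross_member_of[gid], bundle_partner[gid]):
            raise ParameterError("no free cross-talk target pair available")
    for pw_a in pathways:
        for pw_b in pathways:
            if pw_a == pw_b or rng.random() >= params.crosstalk_edge_prob:
                continue
            pair = None
            by_layer: dict[int, list[str]] = {}
            for x in free:
                if loc[x][0] == pw_a:
                    by_layer.setdefault(loc[x][1], []).append(x)
            layers_ok = [k for k, xs in sorted(by_layer.items()) if len(xs) >= 2]
            if not layers_ok:
                continue  # background bundles are best-effort
            layer = layers_ok[int(rng.integers(len(layers_ok)))]
            picks = rng.choice(len(by_layer[layer]), size=2, replace=False)
            pair = (by_layer[layer][picks[0]], by_layer[layer][picks[1]])
            free.remove(pair[0])
            free.remove(pair[1])
            if not _add_bundle(pair[0], pair[1]):
                free.extend(pair)
                free.sort()

    # ------------------------------------------------------------------
    # tissue expression
    raw_by_organ = {
        organ: [f"{organ}_t{j}" for j in range(params.raw_tissues_per_organ)]
        for organ in organs
    }
    tissue_map = {
        raw: organ for organ in organs for raw in raw_by_organ[organ]
    }
    signaling = sorted(p.id for p in proteins.values() if p.in_signaling_set)
    trio_nodes = {x for pair in trio_of.values() for x in pair}
    reserved = (
        set().union(*(group_members[g] for g in group_members))
        | crosstalk_truth
        | trio_nodes
        | set(bottleneck_of.values())
    )
    n_unannotated = round(params.unannotated_fraction * len(signaling))
    layer_budget = {
        (pw, k): len(layers_by_pw[pw][k]) - 2
        for pw in pathways
        for k in range(params.n_layers)
    }
    unannotated: set[str] = set()
    candidates = [p for p in signaling if p in loc and p not in reserved]
    rng.shuffle(candidates)
    for p in candidates:
        if len(unannotated) >= n_unannotated:
            break
        if layer_budget[loc[p]] > 0:
            layer_budget[loc[p]] -= 1
            unannotated.add(p)

    keep_prob = params.tissue_coverage_prob * (1 - params.expression_dropout)
    organs_of: dict[str, tuple[str, ...]] = {}
    designated = {
        x: bottleneck_organs[gid]
        for gid, pair in trio_of.items()
        for x in pair
    }
    for p in signaling:
        if p in unannotated:
            organs_of[p] = ()
        elif p in designated:
            organs_of[p] = designated[p]
        elif p in bottleneck_of.values() or keep_prob >= 1.0:
            organs_of[p] = tuple(organs)
        else:
            organs_of[p] = tuple(
                o for o in organs if rng.random() < keep_prob
            )
    expression_rows: list[tuple[str, str]] = []
    for p in signaling:
        for organ in organs_of[p]:
            raws = raw_by_organ[organ]
            expression_rows.append((p, raws[int(rng.integers(len(raws)))]))

    # ------------------------------------------------------------------
    # protein labels
    protein_label: dict[str, str] = {}
    for gid, members in group_members.items():
        lab = "CP" if group_label[gid] == "CPG" else "PP"
        for member in members:
            protein_label[member] = lab
    for p in signaling:
        protein_label.setdefault(p, "OTHER")

    # ------------------------------------------------------------------
    # annotations
    feature_types = ("TF_REGULATOR", "MIRNA", "GO_BP", "GO_MF", "DISEASE")
    boosted = {"MIRNA", "GO_BP"}
    bg_pool = {
        ft: [f"{ft.lower()}_bg{j}" for j in range(150)] for ft in feature_types
    }
    features: dict[str, dict[str, set[str]]] = {ft: {} for ft in feature_types}
    flags: dict[str, set[str]] = {"CANCER_DRIVER": set(), "DRUG_TARGET": set()}
    disease_gene: set[str] = set()

    universe = sorted(set(signaling) | set(protein_label))
    for p in universe:
        lab = protein_label.get(p, "OTHER")
        if rng.random() < params.flag_rates["DISEASE_GENE"][lab]:
            disease_gene.add(p)
        if rng.random() < params.flag_rates["CANCER_DRIVER"][lab]:
            flags["CANCER_DRIVER"].add(p)
        if rng.random() < params.flag_rates["DRUG_TARGET"][lab]:
            flags["DRUG_TARGET"].add(p)

    def _add(ft: str, p: str, feats: Iterable[str]) -> None:
        features[ft].setdefault(p, set()).update(feats)

    for gid in sorted(group_members):
        members = sorted(group_members[gid])
        is_cpg = group_label[gid] == "CPG"
        for ft in feature_types:
            n_core = params.features_per_protein[ft]
            core = [f"{ft.lower()}_{gid}_core{j}" for j in range(n_core)]
            for idx, member in enumerate(members):
                if ft == "DISEASE":
                    if member not in disease_gene:
                        continue
                    _add(ft, member, core)
                    if is_cpg:
                        _add(
                            ft,
                            member,
                            [
                                f"disease_{gid}_{member}_s{j}"
                                for j in range(params.specificity_boost)
                            ],
                        )
                    continue
                _add(ft, member, core)
                n_spec = params.base_specific_features + (
                    params.specificity_boost if is_cpg and ft in boosted else 0
                )
                _add(
                    ft,
                    member,
                    [f"{ft.lower()}_{gid}_{member}_s{j}" for j in range(n_spec)],
                )

    grouped = set().union(*group_members.values())
    tf_activity = "go_mf_tf_activity"
    for p in universe:
        lab = protein_label.get(p, "OTHER")
        if p not in grouped:
            for ft in feature_types:
                if ft == "DISEASE":
                    continue
                pool = bg_pool[ft]
                picks = rng.choice(
                    len(pool),
                    size=min(params.features_per_protein[ft], len(pool)),
                    replace=False,
                )
                _add(ft, p, [pool[j] for j in picks])
            if p in disease_gene:
                n_dis = 1 + int(rng.random() < 0.5)
                picks = rng.choice(len(bg_pool["DISEASE"]), size=n_dis, replace=False)
                _add("DISEASE", p, [bg_pool["DISEASE"][j] for j in picks])
        rate = (
            params.tf_activity_rate_cp if lab == "CP" else params.tf_activity_rate_bg
        )
        if rng.random() < rate:
            _add("GO_MF", p, [tf_activity])
        if params.annotation_noise > 0:
            for ft in feature_types:
                if rng.random() < params.annotation_noise:
                    pool = bg_pool[ft]
                    _add(ft, p, [pool[int(rng.integers(len(pool)))]])

    annotations = {
        ft: AnnotationTable(
            feature_type=ft,
            features={p: frozenset(s) for p, s in features[ft].items()},
        )
        for ft in feature_types
    }
    for flag, members in flags.items():
        annotations[flag] = AnnotationTable(
            feature_type=flag,
            features={p: frozenset({flag}) for p in sorted(members)},
        )

    # ------------------------------------------------------------------
    # paralogy encodings: alternate sources, every fifth group in both
    orthodb_rows: list[tuple[str, str, str]] = []
    inparanoid_records: list[tuple[str, str, str, str]] = []
    for i, gid in enumerate(sorted(group_members)):
        members = sorted(group_members[gid])
        in_orthodb = i % 2 == 0 or i % 5 == 4
        in_inparanoid = i % 2 == 1 or i % 5 == 4
        if in_orthodb:
            for member in members:
                orthodb_rows.append((gid, params.focal_taxon, member))
            orthodb_rows.append((gid, "10090", f"mm_{gid}"))
        if in_inparanoid:
            for j, (a, b) in enumerate(zip(members, members[1:])):
                bridge = ("10090", f"mm_{gid}_{j}")
                for pair in (
                    ((params.focal_taxon, a), bridge),
                    (bridge, (params.focal_taxon, b)),
                ):
                    left, right = sorted(pair)
                    inparanoid_records.append(
                        (left[0], left[1], right[0], right[1])
                    )
    # decoys: singleton orthologous groups and a component with no focal gene
    for j, p in enumerate(free[:2]):
        orthodb_rows.append((f"OGS{j}", params.focal_taxon, p))
    inparanoid_records.append(("10090", "mm_decoy", "10116", "rn_decoy"))

    network = SignalingNetwork(proteins=proteins, edges=edges)
    network.validate()

    truth = TruthTables(
        groups=group_members,
        group_label=group_label,
        protein_label=protein_label,
        essential_by_tissue={
            organ: frozenset(
                bottleneck_of[gid]
                for gid in bottleneck_of
                if organ in bottleneck_organs[gid]
            )
            for organ in organs
        },
        crosstalk=frozenset(crosstalk_truth),
    )

    dataset = SyntheticDataset(
        params=params,
        network=network,
        orthodb_rows=orthodb_rows,
        inparanoid_records=inparanoid_records,
        tissue_map=tissue_map,
        expression_rows=expression_rows,
        annotations=annotations,
        truth=truth,
    )
    _verify_plants(dataset, bottleneck_of, trio_of, bottleneck_organs, organs_of)
    return dataset


# ---------------------------------------------------------------------------
# generation-time self-checks (independent of the analysis modules)


def _bfs_reaches(
    adjacency: dict[str, list[str]], source: str, target: str, banned: str | None
) -> bool:
    stack, seen = [source], {source}
    while stack:
        node = stack.pop()
        if node == target:
            return True
        for nxt in adjacency.get(node, ()):
            if nxt != banned and nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return False


def _verify_plants(
    dataset: SyntheticDataset,
    bottleneck_of: dict[str, str],
    trio_of: dict[str, tuple[str, str]],
    bottleneck_organs: dict[str, tuple[str, ...]],
    organs_of: dict[str, tuple[str, ...]],
) -> None:
    """Re-derive the planted facts with a plain BFS; fail loudly on mismatch."""
    edges = dataset.network.edges
    per_organ_adj: dict[str, dict[str, list[str]]] = {}

    def adj_for(organ: str) -> dict[str, list[str]]:
        if organ not in per_organ_adj:
            present = {
                p for p, orgs in organs_of.items() if organ in orgs
            }
            adjacency: dict[str, list[str]] = {}
            for u, v in edges:
                if u in present and v in present:
                    adjacency.setdefault(u, []).append(v)
            per_organ_adj[organ] = adjacency
        return per_organ_adj[organ]

    for gid, c in bottleneck_of.items():
        lx, tx = trio_of[gid]
        for organ in bottleneck_organs[gid]:
            adjacency = adj_for(organ)
            if not _bfs_reaches(adjacency, lx, tx, banned=None):
                raise DataError(
                    f"plant check failed: {lx}->{tx} unreachable in {organ}"
                )
            if _bfs_reaches(adjacency, lx, tx, banned=c):
                raise DataError(
                    f"plant check failed: {c} is not essential for "
                    f"{lx}->{tx} in {organ}"
                )

    # cross-talk truth must equal the flags derivable from the edge list
    derived: set[str] = set()
    proteins = dataset.network.proteins
    for u, v in edges:
        if proteins[v].pathways - proteins[u].pathways:
            derived.add(u)
        if proteins[u].pathways - proteins[v].pathways:
            derived.add(v)
    if derived != set(dataset.truth.crosstalk):
        raise DataError("plant check failed: cross-talk truth mismatch")


# ---------------------------------------------------------------------------
# serialization


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict:
    """Write all input and truth files plus a digest manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    f = DATASET_FILES
    cio.write_network(
        dataset.network, directory / f["nodes"], directory / f["edges"]
    )
    cio.write_orthodb(dataset.orthodb_rows, directory / f["orthodb"])
    cio.write_inparanoid(
        dataset.inparanoid_records, directory / f["inparanoid"]
    )
    cio._write_tsv(
        directory / f["tissue_map"],
        ["raw_tissue", "organ_system"],
        sorted(dataset.tissue_map.items()),
    )
    cio._write_tsv(
        directory / f["expression"],
        ["protein_id", "raw_tissue"],
        dataset.expression_rows,
    )
    for ft, table in dataset.annotations.items():
        cio.write_annotations(table, directory / f[ft])

    truth = dataset.truth
    cio._write_tsv(
        directory / "truth_groups.tsv",
        ["group_id", "member_id", "group_label"],
        (
            (gid, member, truth.group_label[gid])
            for gid in sorted(truth.groups)
            for member in sorted(truth.groups[gid])
        ),
    )
    cio._write_tsv(
        directory / "truth_essential.tsv",
        ["tissue", "protein_id"],
        (
            (tissue, p)
            for tissue in sorted(truth.essential_by_tissue)
            for p in sorted(truth.essential_by_tissue[tissue])
        ),
    )
    cio._write_tsv(
        directory / "truth_crosstalk.tsv",
        ["protein_id"],
        ((p,) for p in sorted(truth.crosstalk)),
    )
    cio._write_tsv(
        directory / "truth_protein_labels.tsv",
        ["protein_id", "label"],
        sorted(truth.protein_label.items()),
    )

    digests = {}
    for path in sorted(directory.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        digests[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {"params": asdict(dataset.params), "files": digests}
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
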