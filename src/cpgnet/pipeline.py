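"""End-to-end orchestration of the critical-paralog-group analysis.

Stage order: paralog groups -> tissue networks -> flow criticality ->
classification -> network metrics -> annotation specificity -> statistics.
Every stage writes its tables into the output directory; ``summary.json``
collects the headline counts (groups, flow-critical groups, CPGs, CP/PP/OTHER
proteins) and per-stage timings.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import io as cio
from .classify import classify_groups, crosstalk_proteins
from .criticality import (
    centrality_table,
    critical_in_flow,
    essential_in_tissue,
    group_dispersion,
)
from .errors import CpgnetError, UsageError
from .model import (
    FEATURE_TYPES,
    FLAG_TYPES,
    ClassificationTable,
    Variant,
)
from .paralogs import (
    ParalogGroupSet,
    inparanoid_groups,
    merge_sources,
    orthodb_groups,
    write_groups,
)
from .simulate import DATASET_FILES
from .specificity import specificity_profile
from .stats import results_to_frame, run_comparisons

log = logging.getLogger(__name__)

_CONFIG_KEYS = {
    "node_table",
    "edge_table",
    "orthodb",
    "inparanoid",
    "expression",
    "tissue_map",
    "ann_tf_regulator",
    "ann_mirna",
    "ann_go_bp",
    "ann_go_mf",
    "ann_disease",
    "ann_cancer_driver",
    "ann_drug_target",
    "focal_taxon",
    "focal_species",
    "variant",
    "scorer",
    "d_tol",
    "yates",
    "outdir",
    "seed",
}

_ANN_KEYS = {
    "TF_REGULATOR": "ann_tf_regulator",
    "MIRNA": "ann_mirna",
    "GO_BP": "ann_go_bp",
    "GO_MF": "ann_go_mf",
    "DISEASE": "ann_disease",
    "CANCER_DRIVER": "ann_cancer_driver",
    "DRUG_TARGET": "ann_drug_target",
}


@dataclass
class PipelineConfig:
    node_table: str
    edge_table: str
    orthodb: str
    inparanoid: str
    expression: str
    tissue_map: str
    annotations: dict[str, str] = field(default_factory=dict)
    focal_taxon: str = "9606"
    focal_species: str = "9606"
    variant: Variant = Variant.ANNOTATED_ONLY
    scorer: str = "ratio"
    d_tol: float = 0.0
    yates: bool = False
    outdir: str = "cpgnet_out"
    seed: int = 0

    @classmethod
    def from_dataset_dir(cls, directory: str | Path, **overrides) -> "PipelineConfig":
        """Config pointing at a dataset laid out by ``cpgnet simulate``."""
        directory = Path(directory)
        f = DATASET_FILES
        annotations = {
            ft: str(directory / f[ft]) for ft in FEATURE_TYPES + FLAG_TYPES
        }
        return cls(
            node_table=str(directory / f["nodes"]),
            edge_table=str(directory / f["edges"]),
            orthodb=str(directory / f["orthodb"]),
            inparanoid=str(directory / f["inparanoid"]),
            expression=str(directory / f["expression"]),
            tissue_map=str(directory / f["tissue_map"]),
            annotations=annotations,
            **overrides,
        )

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file (``#`` comments allowed)."""
        values: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise UsageError(f"{path} line {lineno}: expected key = value")
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in _CONFIG_KEYS:
                    raise UsageError(f"{path} line {lineno}: unknown key {key!r}")
                values[key] = value.strip()
        annotations = {
            ft: values.pop(key)
            for ft, key in _ANN_KEYS.items()
            if key in values
        }
        kwargs: dict[str, Any] = dict(values)
        if "variant" in kwargs:
            kwargs["variant"] = Variant(kwargs["variant"])
        if "d_tol" in kwargs:
            kwargs["d_tol"] = float(kwargs["d_tol"])
        if "seed" in kwargs:
            kwargs["seed"] = int(kwargs["seed"])
        if "yates" in kwargs:
            kwargs["yates"] = kwargs["yates"].lower() in ("1", "true", "yes")
        kwargs["annotations"] = annotations
        kwargs.update(overrides)
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise UsageError(str(exc)) from exc

    def validate_paths(self) -> None:
        paths = [
            self.node_table,
            self.edge_table,
            self.orthodb,
            self.inparanoid,
            self.expression,
            self.tissue_map,
            *self.annotations.values(),
        ]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise UsageError(
                "missing input file(s): " + ", ".join(sorted(missing))
            )


@dataclass
class PipelineResult:
    config: PipelineConfig
    group_set: ParalogGroupSet
    classification: ClassificationTable
    classification_alt: ClassificationTable
    essentiality: dict[Variant, list]
    centralities: pd.DataFrame
    group_sd: pd.DataFrame
    specificity: pd.DataFrame
    comparisons: pd.DataFrame
    summary: dict[str, Any]


def run_all(config: PipelineConfig) -> PipelineResult:
    """Execute every stage; on failure, mark the output directory FAILED."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    timings: dict[str, float] = {}
    try:
        config.validate_paths()

        def tick(name: str) -> None:
            nonlocal stage, t0
            timings[stage] = round(time.perf_counter() - t0, 3)
            log.info("stage %-12s %6.2fs", stage, timings[stage])
            stage, t0 = name, time.perf_counter()

        t0 = time.perf_counter()

        # -- inputs
        stage = "read"
        network = cio.read_network(config.node_table, config.edge_table)
        ortho = cio.read_orthodb(config.orthodb, focal_taxon=config.focal_taxon)
        inpara = cio.read_inparanoid(config.inparanoid)
        assignment = cio.read_expression(config.expression, config.tissue_map)
        annotations = {
            ft: cio.read_annotations(path, ft)
            for ft, path in sorted(config.annotations.items())
        }
        signaling = network.signaling_ids
        tick("groups")

        # -- paralog groups
        group_set = merge_sources(
            orthodb_groups(ortho),
            inparanoid_groups(inpara, focal_species=config.focal_species),
            signaling,
            scorer=config.scorer,
            d_tol=config.d_tol,
        )
        write_groups(
            group_set, outdir / "groups.tsv", outdir / "ungrouped.tsv"
        )
        tick("tissues")

        # -- tissue networks and essentiality, both inclusion variants
        from .tissues import build_tissue_network, eligible_tissues

        tissues = sorted(eligible_tissues(assignment, signaling))
        if not tissues:
            raise UsageError("no eligible tissues")
        essentiality: dict[Variant, list] = {}
        tissue_rows = []
        for variant in Variant:
            essentiality[variant] = []
            for tissue in tissues:
                tn = build_tissue_network(network, assignment, tissue, variant)
                tissue_rows.append(
                    (
                        tissue,
                        variant.value,
                        tn.graph.number_of_nodes(),
                        tn.graph.number_of_edges(),
                    )
                )
                essentiality[variant].append(essential_in_tissue(tn))
        cio._write_tsv(
            outdir / "tissue_summary.tsv",
            ["tissue", "variant", "n_nodes", "n_edges"],
            tissue_rows,
        )
        cio._write_tsv(
            outdir / "essentiality.tsv",
            ["tissue", "variant", "protein_id", "n_broken_pairs"],
            (
                (res.tissue, res.variant.value, p, len(pairs))
                for variant in Variant
                for res in essentiality[variant]
                for p, pairs in sorted(res.broken_pairs.items())
            ),
        )
        tick("classify")

        # -- classification under the configured variant, plus the mirror
        crosstalk = crosstalk_proteins(network)
        flow = {
            variant: critical_in_flow(essentiality[variant])
            for variant in Variant
        }
        main_variant = Variant(config.variant)
        alt_variant = (
            Variant.WITH_UNANNOTATED
            if main_variant is Variant.ANNOTATED_ONLY
            else Variant.ANNOTATED_ONLY
        )
        classification = classify_groups(
            group_set, flow[main_variant], crosstalk
        )
        classification_alt = classify_groups(
            group_set, flow[alt_variant], crosstalk
        )
        member_of = group_set.member_to_group()
        cio._write_tsv(
            outdir / "classification.tsv",
            ["protein_id", "group_id", "protein_label", "is_crosstalk", "is_flow_critical"],
            (
                (
                    p,
                    member_of.get(p, ""),
                    label,
                    int(p in crosstalk),
                    int(p in flow[main_variant]),
                )
                for p, label in sorted(classification.protein_label.items())
            ),
        )
        cio._write_tsv(
            outdir / "group_classification.tsv",
            ["group_id", "group_label", "n_members", "n_crosstalk", "n_flow_critical"],
            (
                (
                    gid,
                    classification.group_label[gid],
                    group_set.groups[gid].m,
                    len(group_set.groups[gid].members & crosstalk),
                    len(group_set.groups[gid].members & flow[main_variant]),
                )
                for gid in sorted(group_set.groups)
            ),
        )
        disagreements = [
            (gid, classification.group_label[gid], classification_alt.group_label[gid])
            for gid in sorted(group_set.groups)
            if classification.group_label[gid] != classification_alt.group_label[gid]
        ]
        cio._write_tsv(
            outdir / "variant_disagreement.tsv",
            ["group_id", f"label_{main_variant.value}", f"label_{alt_variant.value}"],
            disagreements,
        )
        tick("metrics")

        # -- centralities on the full network, group dispersions
        graph = network.graph()
        table = centrality_table(graph, network.ligands, network.tfs)
        centralities = pd.DataFrame(table).sort_index()
        centralities.index.name = "protein_id"
        centralities.to_csv(outdir / "metrics.tsv", sep="\t")
        sd_rows = []
        for metric in centralities.columns:
            sds = group_dispersion(group_set, table[metric])
            for gid, sd in sorted(sds.items()):
                sd_rows.append(
                    {
                        "group_id": gid,
                        "group_label": classification.group_label[gid],
                        "metric": metric,
                        "sd": sd,
                    }
                )
        group_sd = pd.DataFrame(
            sd_rows, columns=["group_id", "group_label", "metric", "sd"]
        )
        group_sd.to_csv(outdir / "group_sd.tsv", sep="\t", index=False)
        tick("specificity")

        # -- annotation specificity per group
        feature_annotations = {
            ft: t for ft, t in annotations.items() if ft in FEATURE_TYPES
        }
        specificity = specificity_profile(
            group_set, feature_annotations, classification
        )
        specificity.to_csv(outdir / "specificity.tsv", sep="\t", index=False)
        tick("stats")

        # -- statistical battery
        comparisons = run_comparisons(
            centralities,
            group_sd,
            specificity,
            annotations,
            classification,
            yates=config.yates,
        )
        report = results_to_frame(comparisons)
        report.to_csv(outdir / "report.tsv", sep="\t", index=False)
        report.to_json(outdir / "report.json", orient="records", indent=2)
        tick("summary")

        n_flow_groups = sum(
            1
            for g in group_set.groups.values()
            if g.members & flow[main_variant]
        )
        summary = {
            "n_signaling_proteins": len(signaling),
            "n_groups": len(group_set.groups),
            "n_grouped_proteins": sum(
                g.m for g in group_set.groups.values()
            ),
            "n_flow_critical_groups": n_flow_groups,
            "n_cpgs": sum(
                1 for lab in classification.group_label.values() if lab == "CPG"
            ),
            "n_cps": len(classification.cps),
            "n_pps": len(classification.pps),
            "n_others": len(classification.others),
            "n_crosstalk_proteins": len(crosstalk),
            "n_eligible_tissues": len(tissues),
            "n_variant_disagreements": len(disagreements),
            "timings_s": timings,
        }
        with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return PipelineResult(
            config=config,
            group_set=group_set,
            classification=classification,
            classification_alt=classification_alt,
            essentiality=essentiality,
            centralities=centralities,
            group_sd=group_sd,
            specificity=specificity,
            comparisons=report,
            summary=summary,
        )
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\n{exc}\n")
        if isinstance(exc, CpgnetError):
            raise type(exc)(f"stage {stage!r}: {exc}") from exc
        raise
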