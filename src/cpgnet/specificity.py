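"""Per-group annotation-specificity scoring.

A feature (transcriptional regulator, miRNA, GO term, disease, ...) is
*specific* within a paralog group when not every member carries it. The
group's score for one annotation family is the number of specific
protein-feature incidences, summed over members, divided by the group size
m — "specific features per protein". Members without any annotation record
count in the denominator. A variant counting distinct specific features
(rather than incidences) is available behind a flag.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .model import AnnotationTable, ClassificationTable
from .paralogs import ParalogGroup, ParalogGroupSet


def specific_feature_score(
    group: ParalogGroup,
    annotation: AnnotationTable,
    distinct: bool = False,
) -> float:
    """Specific protein-feature incidences per group member."""
    feature_sets = [annotation.get(member) for member in group.members]
    universal = frozenset.intersection(*feature_sets)
    if distinct:
        count = len(frozenset.union(*feature_sets) - universal)
    else:
        count = sum(len(fs - universal) for fs in feature_sets)
    return count / group.m


def specificity_profile(
    group_set: ParalogGroupSet,
    annotations: Mapping[str, AnnotationTable],
    classification: ClassificationTable,
    distinct: bool = False,
) -> pd.DataFrame:
    """One score per (group, annotation family), labeled CPG / NON_CPG."""
    rows = []
    for gid in sorted(group_set.groups):
        group = group_set.groups[gid]
        label = classification.group_label.get(gid, "NON_CPG")
        for feature_type in sorted(annotations):
            score = specific_feature_score(
                group, annotations[feature_type], distinct=distinct
            )
            rows.append(
                {
                    "group_id": gid,
                    "group_label": label,
                    "feature_type": feature_type,
                    "score": score,
                }
            )
    return pd.DataFrame(
        rows, columns=["group_id", "group_label", "feature_type", "score"]
    )
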