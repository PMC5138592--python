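"""Statistical battery comparing CP / PP / OTHER and CPG / non-CPG groups.

Rank-based comparisons use the two-sided Wilcoxon rank-sum (Mann-Whitney)
test — exact null distribution for small tie-free samples, normal
approximation with tie and continuity correction otherwise — mirrored by the
two-sample Kolmogorov-Smirnov test. Categorical proportions use Pearson's
chi-square on 2x2 tables (no continuity correction by default). Annotation
enrichment uses upper-tail hypergeometric tests with Benjamini-Hochberg
adjustment within one annotation family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import UsageError
from .model import AnnotationTable, ClassificationTable

#: Sample-size ceiling (per sample) for the exact Wilcoxon null distribution.
EXACT_WILCOXON_CUTOFF = 20


@dataclass
class ComparisonResult:
    comparison: str
    test: str
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    groups: tuple[str, ...] = ()
    feature: str | None = None

    @property
    def star(self) -> str:
        p = self.adjusted_p if self.adjusted_p is not None else self.p_value
        if p < 0.001:
            return "***"
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return ""


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    exact_cutoff: int = EXACT_WILCOXON_CUTOFF,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (U statistic of x, p).

    The exact null distribution is used when both samples have at most
    ``exact_cutoff`` observations and there are no ties; otherwise the normal
    approximation with tie correction and continuity correction applies.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise UsageError("wilcoxon_rank_sum requires non-empty samples")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = (
        "exact"
        if tie_free and x.size <= exact_cutoff and y.size <= exact_cutoff
        else "asymptotic"
    )
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided asymptotic two-sample Kolmogorov-Smirnov test."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise UsageError("ks_two_sample requires non-empty samples")
    res = sps.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def chi2_2x2(
    table: Sequence[Sequence[int]], yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square with df = 1 on a 2x2 table of counts."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise UsageError("chi2_2x2 requires a 2x2 table of non-negative counts")
    a, b = arr[0]
    c, d = arr[1]
    n = arr.sum()
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise UsageError("chi2_2x2 requires positive row and column margins")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2)
    stat = n * diff**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(stat), float(sps.chi2.sf(stat, df=1))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    if len(p_values) == 0:
        return np.array([])
    return multipletests(p_values, method="fdr_bh")[1]


def hypergeom_enrichment(
    target_ids: Iterable[str],
    background_ids: Iterable[str],
    annotation: AnnotationTable,
) -> list[ComparisonResult]:
    """Upper-tail hypergeometric enrichment of each feature in the target set.

    The background is the full protein universe of the analysis (signaling
    proteins plus their grouped paralogs); the target must be a subset of it.
    BH adjustment is applied across the features of this annotation family.
    """
    target = frozenset(target_ids)
    background = frozenset(background_ids)
    if not target <= background:
        raise UsageError("target set must be a subset of the background")
    hits_by_feature: dict[str, set[str]] = {}
    for protein in background:
        for feat in annotation.get(protein):
            hits_by_feature.setdefault(feat, set()).add(protein)
    results = []
    for feat in sorted(hits_by_feature):
        hits = hits_by_feature[feat]
        overlap = len(hits & target)
        p = float(
            sps.hypergeom.sf(
                overlap - 1, len(background), len(hits), len(target)
            )
        )
        results.append(
            ComparisonResult(
                comparison=f"{annotation.feature_type} enrichment",
                test="HYPERGEOM",
                statistic=float(overlap),
                p_value=min(p, 1.0),
                feature=feat,
            )
        )
    adjusted = bh_adjust([r.p_value for r in results])
    for result, adj in zip(results, adjusted):
        result.adjusted_p = float(adj)
    return results


# ---------------------------------------------------------------------------
# the full battery


def _rank_pair(
    name: str, x: Sequence[float], y: Sequence[float], labels: tuple[str, str]
) -> list[ComparisonResult]:
    out = []
    stat_w, p_w = wilcoxon_rank_sum(x, y)
    out.append(
        ComparisonResult(name, "WILCOXON", stat_w, p_w, groups=labels)
    )
    stat_k, p_k = ks_two_sample(x, y)
    out.append(ComparisonResult(name, "KS", stat_k, p_k, groups=labels))
    return out


def run_comparisons(
    centralities: pd.DataFrame,
    group_sd: pd.DataFrame,
    specificity: pd.DataFrame,
    annotations: Mapping[str, AnnotationTable],
    classification: ClassificationTable,
    yates: bool = False,
) -> list[ComparisonResult]:
    """The full comparison battery.

    * each centrality: CP vs PP, CP vs OTHER, PP vs OTHER (Wilcoxon + KS)
    * within-group SD of each centrality: CPG vs non-CPG
    * specificity per annotation family: CPG vs non-CPG
    * disease-gene / cancer-driver / drug-target proportions across the
      three protein classes (chi-square, pairwise)
    * diseases per protein across the three classes (Wilcoxon)
    * GO molecular-function enrichment of CPs against the full background

    ``centralities`` is indexed by protein id with one column per metric;
    ``group_sd`` has columns group_id, group_label, metric, sd; ``specificity``
    comes from :func:`cpgnet.specificity.specificity_profile`.
    """
    if not classification.protein_label:
        raise UsageError("classification is empty")
    for name, frame in (
        ("centralities", centralities),
        ("group_sd", group_sd),
        ("specificity", specificity),
    ):
        if frame is None:
            raise UsageError(f"missing upstream table: {name}")

    results: list[ComparisonResult] = []
    class_members = {
        label: sorted(
            classification.proteins_with_label(label) & set(centralities.index)
        )
        for label in ("CP", "PP", "OTHER")
    }
    pairs = (("CP", "PP"), ("CP", "OTHER"), ("PP", "OTHER"))

    # (i) centralities across protein classes
    for metric in centralities.columns:
        for la, lb in pairs:
            xa = centralities.loc[class_members[la], metric].to_numpy()
            xb = centralities.loc[class_members[lb], metric].to_numpy()
            if xa.size and xb.size:
                results.extend(
                    _rank_pair(f"{metric}: {la} vs {lb}", xa, xb, (la, lb))
                )

    # (ii) within-group dispersion, CPG vs non-CPG
    for metric in sorted(group_sd["metric"].unique()):
        sub = group_sd[group_sd["metric"] == metric]
        x = sub.loc[sub["group_label"] == "CPG", "sd"].to_numpy()
        y = sub.loc[sub["group_label"] == "NON_CPG", "sd"].to_numpy()
        if x.size and y.size:
            results.extend(
                _rank_pair(
                    f"group SD of {metric}: CPG vs non-CPG",
                    x,
                    y,
                    ("CPG", "NON_CPG"),
                )
            )

    # (iii) specificity per annotation family, CPG vs non-CPG
    for feature_type in sorted(specificity["feature_type"].unique()):
        sub = specificity[specificity["feature_type"] == feature_type]
        x = sub.loc[sub["group_label"] == "CPG", "score"].to_numpy()
        y = sub.loc[sub["group_label"] == "NON_CPG", "score"].to_numpy()
        if x.size and y.size:
            results.extend(
                _rank_pair(
                    f"{feature_type} specificity: CPG vs non-CPG",
                    x,
                    y,
                    ("CPG", "NON_CPG"),
                )
            )

    # (iv) categorical proportions across protein classes
    universe = set(classification.protein_label)
    categorical: dict[str, frozenset[str]] = {}
    if "DISEASE" in annotations:
        categorical["disease gene"] = annotations["DISEASE"].flagged & universe
    for flag, label in (("CANCER_DRIVER", "cancer driver"), ("DRUG_TARGET", "drug target")):
        if flag in annotations:
            categorical[label] = annotations[flag].flagged & universe
    all_class_members = {
        label: classification.proteins_with_label(label)
        for label in ("CP", "PP", "OTHER")
    }
    for prop, positives in categorical.items():
        for la, lb in pairs:
            na, nb = len(all_class_members[la]), len(all_class_members[lb])
            ka = len(all_class_members[la] & positives)
            kb = len(all_class_members[lb] & positives)
            if min(na, nb) == 0:
                continue
            try:
                stat, p = chi2_2x2(
                    [[ka, na - ka], [kb, nb - kb]], yates=yates
                )
            except UsageError:
                continue  # degenerate margin (e.g. nobody flagged)
            results.append(
                ComparisonResult(
                    f"{prop} proportion: {la} vs {lb}",
                    "CHI2",
                    stat,
                    p,
                    groups=(la, lb),
                )
            )

    # (v) diseases per protein across classes
    if "DISEASE" in annotations:
        disease = annotations["DISEASE"]
        counts = {
            label: [len(disease.get(p)) for p in sorted(members)]
            for label, members in all_class_members.items()
        }
        for la, lb in pairs:
            if counts[la] and counts[lb]:
                stat, p = wilcoxon_rank_sum(counts[la], counts[lb])
                results.append(
                    ComparisonResult(
                        f"diseases per protein: {la} vs {lb}",
                        "WILCOXON",
                        stat,
                        p,
                        groups=(la, lb),
                    )
                )

    # (vi) GO molecular-function enrichment of CPs
    if "GO_MF" in annotations:
        cps = classification.cps & universe
        if cps:
            results.extend(
                hypergeom_enrichment(cps, universe, annotations["GO_MF"])
            )

    return results


def results_to_frame(results: Iterable[ComparisonResult]) -> pd.DataFrame:
    rows = [
        {
            "comparison": r.comparison,
            "test": r.test,
            "feature": r.feature or "",
            "statistic": r.statistic,
            "p_value": r.p_value,
            "adjusted_p": "" if r.adjusted_p is None else r.adjusted_p,
            "star": r.star,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "comparison",
            "test",
            "feature",
            "statistic",
            "p_value",
            "adjusted_p",
            "star",
        ],
    )
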