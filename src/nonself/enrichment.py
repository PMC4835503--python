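"""Categorical enrichment of annotations in response sets.

Fold enrichment is the ratio of proportions (observed/|set|) /
(genome_count/universe); significance is the two-tailed Fisher exact test
on the 2x2 [in-set & in-category, in-set & not, out-of-set & in-category,
neither]. Depletions (fold < 1) are reported with the same two-tail p.
Benjamini-Hochberg adjusted p-values accompany every multi-row table.

The universe size (number of annotated genes behind the proportions) is
always an explicit argument — enrichment folds are meaningless without a
stated denominator, and different analyses legitimately use different
universes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import ContingencyResult, ResponseSet, ValidationError, logger
from .sets import build_response_set, fisher_exact_2x2


@dataclass(frozen=True)
class EnrichmentRow:
    """One category x one gene set: counts, fold, two-tail p, direction."""

    category: str
    genome_count: int
    set_size: int
    observed: int
    fold: float
    p_two_tail: float

    @property
    def direction(self) -> str:
        return "enriched" if self.fold >= 1 else "depleted"

    @property
    def fold_defined(self) -> bool:
        return self.fold == self.fold  # not NaN


def category_enrichment(
    response_set: ResponseSet | frozenset[str],
    category_members: Iterable[str],
    universe_size: int,
    category: str = "",
) -> EnrichmentRow:
    """Fisher-exact enrichment of one category in one gene set."""
    members = (response_set.members if isinstance(response_set, ResponseSet)
               else frozenset(response_set))
    cat = frozenset(category_members)
    if len(members | cat) > universe_size:
        raise ValidationError("universe smaller than the union of the sets")
    observed = len(members & cat)
    a = observed
    b = len(members) - observed
    c = len(cat) - observed
    d = universe_size - a - b - c
    if len(cat) == 0 or len(members) == 0:
        logger.warning("category_enrichment: empty set or category %r", category)
        fold = float("nan")
    else:
        fold = (observed / len(members)) / (len(cat) / universe_size)
    p = fisher_exact_2x2(a, b, c, d)
    return EnrichmentRow(category=category, genome_count=len(cat),
                         set_size=len(members), observed=observed,
                         fold=fold, p_two_tail=p)


def enrichment_table(
    sets: Mapping[str, ResponseSet],
    categories: Mapping[str, Iterable[str]],
    universe_size: int,
) -> pd.DataFrame:
    """All categories x all sets, with BH-adjusted p per table."""
    rows = []
    for set_label, rs in sorted(sets.items()):
        for cat_label, cat_members in sorted(categories.items()):
            r = category_enrichment(rs, cat_members, universe_size, cat_label)
            rows.append({"set": set_label, "category": cat_label,
                         "genome_count": r.genome_count,
                         "observed": r.observed, "fold": r.fold,
                         "direction": r.direction, "p": r.p_two_tail})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


@dataclass(frozen=True)
class SweepRow:
    """Enrichment of one category at one |log2FC| threshold."""

    threshold: float
    observed: int
    set_size: int
    fold: float
    p_two_tail: float


def sweep_thresholds(
    records,
    direction: str,
    category_members: Iterable[str],
    thresholds: Sequence[float],
    max_p: float,
    universe_size: int,
) -> list[SweepRow]:
    """Rebuild the response set at each ascending threshold and re-test.

    Observed counts are non-increasing in the threshold because the sets
    are nested.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValidationError("thresholds must be ascending")
    records = list(records)
    cat = frozenset(category_members)
    out = []
    for thr in thresholds:
        rs = build_response_set(records, direction, thr, max_p)
        r = category_enrichment(rs, cat, universe_size)
        out.append(SweepRow(threshold=thr, observed=r.observed,
                            set_size=r.set_size, fold=r.fold,
                            p_two_tail=r.p_two_tail))
    return out


def sm_cluster_summary(
    cluster_map: Mapping[str, str],
    up_sets: Mapping[str, ResponseSet],
    universe_size: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Secondary-metabolite cluster expression summaries.

    Returns (per_cluster, summary): per cluster and condition the number of
    up-regulated genes; and per condition the number of clusters with >= 1
    and >= 3 up-regulated genes, the total up-regulated cluster genes, and
    the Fisher enrichment of the pooled cluster gene set.
    """
    clusters = sorted(set(cluster_map.values()))
    conds = sorted(up_sets)
    genes_by_cluster: dict[str, set[str]] = {c: set() for c in clusters}
    for g, c in cluster_map.items():
        genes_by_cluster[c].add(g)
    all_cluster_genes = frozenset(cluster_map)

    per_rows = []
    for c in clusters:
        row: dict = {"cluster": c, "n_genes": len(genes_by_cluster[c])}
        for cond in conds:
            row[f"n_up_{cond}"] = len(genes_by_cluster[c] & up_sets[cond].members)
        per_rows.append(row)
    per_cluster = pd.DataFrame(per_rows)

    sum_rows = []
    for cond in conds:
        ups = [len(genes_by_cluster[c] & up_sets[cond].members) for c in clusters]
        enr = category_enrichment(up_sets[cond], all_cluster_genes,
                                  universe_size, "SM_cluster_genes")
        sum_rows.append({"condition": cond,
                         "n_cluster_genes_up": sum(ups),
                         "clusters_ge1": sum(1 for u in ups if u >= 1),
                         "clusters_ge3": sum(1 for u in ups if u >= 3),
                         "fold": enr.fold, "p": enr.p_two_tail})
    return per_cluster, pd.DataFrame(sum_rows)


def updown_bias(
    category_genes: Iterable[str],
    up_set: ResponseSet,
    down_set: ResponseSet,
) -> ContingencyResult:
    """Are category genes more up- than down-regulated?

    Two-sided binomial test of n_up against 1/2 of the regulated category
    genes. Genes in both sets (possible when the sets come from different
    pooled tables) are excluded.
    """
    cat = frozenset(category_genes)
    n_up = len(cat & up_set.members - down_set.members)
    n_down = len(cat & down_set.members - up_set.members)
    n = n_up + n_down
    if n == 0:
        logger.warning("updown_bias: no regulated genes in category")
        return ContingencyResult(a=0, b=0, c=0, d=0, fold=float("nan"),
                                 p_two_tail=float("nan"), method="binomial")
    p = float(stats.binomtest(n_up, n, 0.5).pvalue)
    ratio = n_up / n_down if n_down else float("nan")
    return ContingencyResult(a=n_up, b=n_down, c=0, d=0, fold=ratio,
                             p_two_tail=p, method="binomial")


def common_core_report(
    up_sets: Mapping[str, ResponseSet],
    down_sets: Mapping[str, ResponseSet],
    annotations: Mapping[str, Iterable[str]],
    min_occurrence: int = 5,
) -> pd.DataFrame:
    """Annotation terms of the genes regulated in *all* conditions.

    Terms are counted within the all-conditions intersection of the up sets
    and, separately, of the down sets, and reported when seen at least
    ``min_occurrence`` times in either direction.
    """
    if len(up_sets) < 2 or len(down_sets) < 2:
        raise ValidationError("common_core_report needs >= 2 conditions")
    common_up = frozenset.intersection(*(s.members for s in up_sets.values()))
    common_down = frozenset.intersection(*(s.members for s in down_sets.values()))

    def term_counts(genes: frozenset[str]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in genes:
            for t in annotations.get(g, ()):
                counts[t] = counts.get(t, 0) + 1
        return counts

    up_counts = term_counts(common_up)
    down_counts = term_counts(common_down)
    terms = sorted(set(up_counts) | set(down_counts))
    rows = [
        {"term": t, "n_common_up": up_counts.get(t, 0),
         "n_common_down": down_counts.get(t, 0)}
        for t in terms
        if up_counts.get(t, 0) >= min_occurrence
        or down_counts.get(t, 0) >= min_occurrence
    ]
    return pd.DataFrame(rows, columns=["term", "n_common_up", "n_common_down"])
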