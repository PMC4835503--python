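"""Response sets and cross-condition overlap statistics.

A response set is the set of genes up- (log2FC > t, p < alpha) or down-
(log2FC < -t, p < alpha) regulated in one condition, with strict
inequalities on both thresholds. Note a documented ambiguity in the
literature between thresholds stated on the fold-change scale ("FC > 2")
and on the log2 scale ("log2FC > 2"); this module always takes the log2
value, and the CLI offers a --min-fc convenience flag that converts.

The overlap machinery covers: pooling time points, 2/3-way Venn counts,
condition-specific fractions, Fisher/chi-square overlap tests against a
stated gene universe, per-gene magnitude-bias sign tests, fold-change
concordance, and threshold-sweep overlap profiles against a reference
response (e.g. vegetative incompatibility).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    ContingencyResult,
    ExpressionRecord,
    ResponseSet,
    ValidationError,
    logger,
)

#: How formatted reports print a p-value indistinguishable from zero.
P_ZERO_REPR = "<1e-300"


def format_p(p: float) -> str:
    return P_ZERO_REPR if p < 1e-300 else f"{p:.3g}"


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def build_response_set(
    records: Iterable[ExpressionRecord],
    direction: str,
    min_abs_log2fc: float,
    max_p: float,
    label: str | None = None,
) -> ResponseSet:
    """Select genes past the thresholds, strictly, in one direction."""
    if min_abs_log2fc < 0:
        raise ValidationError("min_abs_log2fc must be >= 0")
    if direction not in ("up", "down"):
        raise ValidationError(f"direction must be up/down, got {direction!r}")
    records = list(records)
    seen: set[str] = set()
    for r in records:
        if r.gene_id in seen:
            raise ValidationError(f"duplicate record for gene {r.gene_id}")
        seen.add(r.gene_id)
    if direction == "up":
        members = {r.gene_id for r in records
                   if r.log2fc > min_abs_log2fc and r.p_value < max_p}
    else:
        members = {r.gene_id for r in records
                   if r.log2fc < -min_abs_log2fc and r.p_value < max_p}
    if label is None:
        cond = records[0].condition if records else "unnamed"
        label = f"{cond}_{direction}"
    return ResponseSet(label=label, direction=direction,
                       min_abs_log2fc=min_abs_log2fc, max_p=max_p,
                       members=frozenset(members))


def pool_conditions(set_a: ResponseSet, set_b: ResponseSet,
                    label: str | None = None) -> ResponseSet:
    """Union of two same-direction sets (e.g. the 2 h and 6 h time points)."""
    if set_a.direction != set_b.direction:
        raise ValidationError(
            f"cannot pool {set_a.direction} with {set_b.direction} sets"
        )
    return ResponseSet(
        label=label or f"{set_a.label}+{set_b.label}",
        direction=set_a.direction,
        min_abs_log2fc=set_a.min_abs_log2fc,
        max_p=set_a.max_p,
        members=set_a.members | set_b.members,
    )


@dataclass(frozen=True)
class VennSummary:
    """Mutually exclusive region counts for 2 or 3 sets.

    Regions are keyed by membership tuples of booleans aligned with
    ``labels``; e.g. for 3 sets, (True, True, False) counts genes in the
    first two sets only. The all-False region is not represented (it would
    be the complement of the union).
    """

    labels: tuple[str, ...]
    region_counts: dict[tuple[bool, ...], int]

    def count(self, *membership: bool) -> int:
        return self.region_counts.get(tuple(membership), 0)

    def union_size(self) -> int:
        return sum(self.region_counts.values())

    def set_size(self, i: int) -> int:
        return sum(n for key, n in self.region_counts.items() if key[i])


def venn(sets: Sequence[ResponseSet]) -> VennSummary:
    """Exhaustive region counts for 2 or 3 same-direction sets."""
    if len(sets) not in (2, 3):
        raise ValidationError("venn supports exactly 2 or 3 sets")
    if len({s.direction for s in sets}) != 1:
        raise ValidationError("venn requires same-direction sets")
    union = frozenset().union(*(s.members for s in sets))
    counts: dict[tuple[bool, ...], int] = {
        key: 0 for key in product([True, False], repeat=len(sets))
        if any(key)
    }
    for g in union:
        key = tuple(g in s.members for s in sets)
        counts[key] += 1
    return VennSummary(labels=tuple(s.label for s in sets), region_counts=counts)


def specific_fraction(set_a: ResponseSet, set_b: ResponseSet) -> float:
    """Percent of A's members absent from B: 100 * |A \\ B| / |A|.

    NaN (with a warning) when A is empty.
    """
    if set_a.direction != set_b.direction:
        raise ValidationError("specific_fraction requires same-direction sets")
    if len(set_a) == 0:
        logger.warning("specific_fraction: empty reference set %s", set_a.label)
        return float("nan")
    return 100.0 * len(set_a.members - set_b.members) / len(set_a)


def overlap_test(
    set_a: ResponseSet | frozenset[str],
    set_b: ResponseSet | frozenset[str],
    universe_size: int,
    method: str = "fisher_exact",
) -> ContingencyResult:
    """Test whether two gene sets overlap more than expected by chance.

    2x2 over the universe: [in both, A only, B only, neither]. Fold is the
    observed overlap over the independence expectation |A|·|B|/universe.
    """
    mem_a = set_a.members if isinstance(set_a, ResponseSet) else frozenset(set_a)
    mem_b = set_b.members if isinstance(set_b, ResponseSet) else frozenset(set_b)
    n_union = len(mem_a | mem_b)
    if n_union > universe_size:
        raise ValidationError(
            f"universe size {universe_size} smaller than union {n_union}"
        )
    a = len(mem_a & mem_b)
    b = len(mem_a) - a
    c = len(mem_b) - a
    d = universe_size - a - b - c
    expected = len(mem_a) * len(mem_b) / universe_size if universe_size else 0.0
    fold = a / expected if expected > 0 else float("nan")
    if method == "fisher_exact":
        p = fisher_exact_2x2(a, b, c, d)
    elif method == "chi_square":
        table = np.array([[a, b], [c, d]])
        if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
            p = 1.0
        else:
            p = float(stats.chi2_contingency(table, correction=True)[1])
    else:
        raise ValidationError(f"unknown method {method!r}")
    return ContingencyResult(a=a, b=b, c=c, d=d, fold=fold, p_two_tail=p,
                             method=method)


@dataclass(frozen=True)
class MagnitudeBias:
    """Which of two conditions regulates shared genes more strongly."""

    n_greater_in_a: int
    n_greater_in_b: int
    n_tied: int
    test: ContingencyResult

    @property
    def n_shared(self) -> int:
        return self.n_greater_in_a + self.n_greater_in_b + self.n_tied


def magnitude_bias(
    records_a: Iterable[ExpressionRecord],
    records_b: Iterable[ExpressionRecord],
    shared: Iterable[str],
    test: str = "binomial",
) -> MagnitudeBias:
    """Per shared gene, compare |log2FC| between two conditions.

    Ties are counted separately and excluded from the test. The default is
    a two-sided binomial sign test of greater-in-A counts against 1/2; a
    Fisher variant (greater-in-A/greater-in-B vs an even split) is offered
    because such counts are sometimes tested that way, with the table
    construction left unstated.
    """
    shared = set(shared)
    if not shared:
        raise ValidationError("magnitude_bias: empty shared gene set")
    lfc_a = {r.gene_id: r.log2fc for r in records_a}
    lfc_b = {r.gene_id: r.log2fc for r in records_b}
    missing = shared - (set(lfc_a) & set(lfc_b))
    if missing:
        raise ValidationError(
            f"shared gene(s) missing from a table: {sorted(missing)[:5]}"
        )
    n_a = n_b = n_t = 0
    for g in shared:
        da, db = abs(lfc_a[g]), abs(lfc_b[g])
        if da > db:
            n_a += 1
        elif db > da:
            n_b += 1
        else:
            n_t += 1
    n_informative = n_a + n_b
    if test == "binomial":
        p = (stats.binomtest(n_a, n_informative, 0.5).pvalue
             if n_informative else 1.0)
        method = "binomial"
    elif test == "fisher":
        half = n_informative / 2
        p = fisher_exact_2x2(n_a, n_b, math.floor(half), math.ceil(half))
        method = "fisher_exact"
    else:
        raise ValidationError(f"unknown magnitude-bias test {test!r}")
    ratio = n_a / n_b if n_b else float("nan")
    result = ContingencyResult(a=n_a, b=n_b, c=n_t, d=0, fold=ratio,
                               p_two_tail=float(p), method=method)
    return MagnitudeBias(n_greater_in_a=n_a, n_greater_in_b=n_b, n_tied=n_t,
                         test=result)


def fc_concordance(
    records_a: Iterable[ExpressionRecord],
    records_b: Iterable[ExpressionRecord],
    shared: Iterable[str],
    method: str = "spearman",
) -> float:
    """Correlation of log2FC across two conditions on shared genes.

    NaN (with a warning) when either side has zero variance.
    """
    shared = sorted(set(shared))
    if len(shared) < 3:
        raise ValidationError("fc_concordance needs >= 3 shared genes")
    lfc_a = {r.gene_id: r.log2fc for r in records_a}
    lfc_b = {r.gene_id: r.log2fc for r in records_b}
    x = np.array([lfc_a[g] for g in shared])
    y = np.array([lfc_b[g] for g in shared])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("fc_concordance: zero variance in one condition")
        return float("nan")
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ValidationError(f"unknown correlation method {method!r}")


def threshold_profile_overlap(
    tables: Mapping[str, Sequence[ExpressionRecord]],
    thresholds: Sequence[float],
    reference: Mapping[str, ResponseSet],
    universe_size: int,
    max_p: float,
) -> pd.DataFrame:
    """Percent of each condition's response also in a reference response,
    across ascending |log2FC| thresholds.

    ``reference`` maps direction -> reference set (typically the VI up and
    down sets at the base threshold). Rows where the condition set is empty
    are flagged (``overlap_pct`` NaN, ``is_empty`` True).
    """
    if list(thresholds) != sorted(thresholds):
        raise ValidationError("thresholds must be ascending")
    rows = []
    for thr, direction, (cond, records) in product(
        thresholds, ("up", "down"), sorted(tables.items())
    ):
        rs = build_response_set(records, direction, thr, max_p,
                                label=f"{cond}_{direction}_t{thr}")
        ref = reference[direction]
        if len(rs) == 0:
            rows.append({"threshold": thr, "direction": direction,
                         "condition": cond, "n_genes": 0,
                         "n_in_reference": 0, "overlap_pct": float("nan"),
                         "fisher_p": float("nan"), "is_empty": True})
            continue
        n_in_ref = len(rs.members & ref.members)
        test = overlap_test(rs, ref, universe_size)
        rows.append({"threshold": thr, "direction": direction,
                     "condition": cond, "n_genes": len(rs),
                     "n_in_reference": n_in_ref,
                     "overlap_pct": 100.0 * n_in_ref / len(rs),
                     "fisher_p": test.p_two_tail, "is_empty": False})
    return pd.DataFrame(rows)


def table1_summary(
    sets_by_condition: Mapping[str, dict[str, ResponseSet]],
    records_by_condition: Mapping[str, Sequence[ExpressionRecord]],
) -> pd.DataFrame:
    """Per-condition set sizes and maximum |log2FC|, one row per direction."""
    rows = []
    for cond, sets in sets_by_condition.items():
        recs = records_by_condition.get(cond, [])
        for direction, rs in sets.items():
            member_fcs = [r.log2fc for r in recs if r.gene_id in rs.members]
            extreme = (max(member_fcs) if direction == "up" else min(member_fcs)) \
                if member_fcs else float("nan")
            rows.append({"condition": cond, "direction": direction,
                         "n_genes": len(rs), "max_log2fc": extreme})
    return pd.DataFrame(rows)
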