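"""Reciprocal-best-hit orthology and cross-species response overlap.

Two genes are called orthologs when each is the other's best-scoring
cross-species hit. Best hits are chosen by highest bitscore, ties broken by
lower e-value, then by lexicographically smaller subject id, so the outcome
never depends on input row order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .model import ContingencyResult, ResponseSet, ValidationError, logger
from .sets import fisher_exact_2x2, overlap_test


def best_hits(table: pd.DataFrame) -> dict[str, str]:
    """Best subject per query from a directed similarity table.

    Columns: qseqid, sseqid, bitscore, optionally evalue (absent e-values
    are treated as equal and the tie falls through to the subject id).
    """
    if len(table) == 0:
        raise ValidationError("best_hits: empty similarity table")
    df = table.copy()
    if "evalue" not in df.columns:
        df["evalue"] = 0.0
    df = df.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    first = df.drop_duplicates("qseqid", keep="first")
    # log ties resolved lexicographically
    top = df.merge(
        first[["qseqid", "bitscore", "evalue"]], on=["qseqid", "bitscore", "evalue"]
    )
    n_tied = (top.groupby("qseqid").size() > 1).sum()
    if n_tied:
        logger.info("best_hits: %d quer%s with score+evalue ties broken "
                    "lexicographically", n_tied, "y" if n_tied == 1 else "ies")
    return dict(zip(first["qseqid"].astype(str), first["sseqid"].astype(str)))


def reciprocal_best_hits(
    table_ab: pd.DataFrame, table_ba: pd.DataFrame
) -> list[tuple[str, str]]:
    """Ortholog pairs (a, b) with best(a) = b and best(b) = a."""
    best_ab = best_hits(table_ab)
    best_ba = best_hits(table_ba)
    pairs = [
        (a, b) for a, b in sorted(best_ab.items())
        if best_ba.get(b) == a
    ]
    return pairs


@dataclass(frozen=True)
class CrossOverlapRow:
    """Overlap of one species-A response set with a species-B response,
    through the ortholog pairing."""

    label_a: str
    n_set_a: int
    n_set_a_with_ortholog: int
    n_set_b_with_ortholog: int
    overlap: int
    fold: float
    p_two_tail: float


def cross_species_overlap(
    pairs: Iterable[tuple[str, str]],
    set_a: Iterable[str],
    set_b: ResponseSet | Iterable[str],
    n_orthologs: int | None = None,
    label_a: str = "",
) -> CrossOverlapRow:
    """Count ortholog pairs regulated in both species and test enrichment.

    The universe is the set of ortholog pairs (``n_orthologs``, defaulting
    to the number of pairs given). Expected overlap under independence is
    |A∩pairs|·|B∩pairs| / n_orthologs; the p-value is the two-tailed Fisher
    exact test on the 2x2 over pairs.
    """
    pairs = list(pairs)
    if n_orthologs is None:
        n_orthologs = len(pairs)
    if n_orthologs == 0:
        raise ValidationError("cross_species_overlap: zero ortholog universe")
    mem_a = frozenset(set_a)
    mem_b = (set_b.members if isinstance(set_b, ResponseSet)
             else frozenset(set_b))
    a_side = frozenset(a for a, _ in pairs if a in mem_a)
    b_side = frozenset(b for _, b in pairs if b in mem_b)
    overlap = sum(1 for a, b in pairs if a in mem_a and b in mem_b)
    n_a, n_b = len(a_side), len(b_side)
    expected = n_a * n_b / n_orthologs
    fold = overlap / expected if expected > 0 else float("nan")
    a = overlap
    b = n_a - overlap
    c = n_b - overlap
    d = n_orthologs - a - b - c
    p = fisher_exact_2x2(a, b, c, d)
    return CrossOverlapRow(label_a=label_a, n_set_a=len(mem_a),
                           n_set_a_with_ortholog=n_a,
                           n_set_b_with_ortholog=n_b, overlap=overlap,
                           fold=fold, p_two_tail=p)


def down_up_ratio(
    up_overlap: int, up_total: int, down_overlap: int, down_total: int
) -> tuple[float, ContingencyResult]:
    """Ratio of down- to up-regulated overlap proportions, with Fisher test.

    ratio = (down_overlap/down_total) / (up_overlap/up_total); the test is
    the two-tailed Fisher exact on [[up_overlap, up_total - up_overlap],
    [down_overlap, down_total - down_overlap]]. The ratio is NaN (flagged)
    when up_overlap is zero.
    """
    if up_total <= 0 or down_total <= 0:
        raise ValidationError("down_up_ratio: totals must be positive")
    if up_overlap == 0:
        logger.warning("down_up_ratio: zero up overlap; ratio undefined")
        ratio = float("nan")
    else:
        ratio = (down_overlap / down_total) / (up_overlap / up_total)
    p = fisher_exact_2x2(up_overlap, up_total - up_overlap,
                         down_overlap, down_total - down_overlap)
    result = ContingencyResult(
        a=up_overlap, b=up_total - up_overlap,
        c=down_overlap, d=down_total - down_overlap,
        fold=ratio, p_two_tail=p, method="fisher_exact",
    )
    return ratio, result


def cross_overlap_report(
    pairs: list[tuple[str, str]],
    sets_a: Mapping[str, frozenset[str]],
    sets_b: Mapping[str, ResponseSet],
    n_orthologs: int | None = None,
) -> pd.DataFrame:
    """Table-style report: every species-A set against every species-B set,
    plus a down/up ratio row per (A up, A down) pairing with matching
    species-B direction."""
    rows = []
    for label_a, mem_a in sorted(sets_a.items()):
        for label_b, rs_b in sorted(sets_b.items()):
            r = cross_species_overlap(pairs, mem_a, rs_b, n_orthologs, label_a)
            rows.append({"set_a": label_a, "set_b": label_b,
                         "n_a_orth": r.n_set_a_with_ortholog,
                         "n_b_orth": r.n_set_b_with_ortholog,
                         "overlap": r.overlap, "fold": r.fold,
                         "p": r.p_two_tail})
    return pd.DataFrame(rows)
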