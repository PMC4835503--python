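"""Gene versatility: classification, quantile binning, and the 0..n+1 index.

Versatility is a gene's propensity to be gained or lost over evolution,
proxied by the number of genera in which a homolog is found. Genes with a
single (self) hit are orphans; genes with an ortholog in a distant
ascomycete belong to the fungal core genome; the remaining genes are ranked
into ``n_bins`` near-equal-occupancy bins by ascending hit count. The
versatility index is 0 for orphans, the bin number for binned genes, and
``n_bins + 1`` for core genes — low index means lineage-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .model import ResponseSet, ValidationError, logger

ORPHAN = "orphan"
CORE = "core"


def bin_label(k: int) -> str:
    return f"bin{k}"


@dataclass(frozen=True)
class VersatilityAssignment:
    """Per-gene category (orphan / bin k / core) and integer index."""

    category: dict[str, str]  # gene_id -> ORPHAN | "bin<k>" | CORE
    index: dict[str, int]  # gene_id -> 0..n_bins+1
    n_bins: int

    def categories_ordered(self) -> list[str]:
        return [ORPHAN] + [bin_label(k) for k in range(1, self.n_bins + 1)] + [CORE]

    def to_frame(self, hits: Mapping[str, int] | None = None) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "category": c, "index": self.index[g],
             "n_hits": (hits or {}).get(g, pd.NA)}
            for g, c in sorted(self.category.items())
        ]
        return pd.DataFrame(rows, columns=["gene_id", "category", "index", "n_hits"])


def classify_genes(
    hits: Mapping[str, int], core_ids: Iterable[str]
) -> tuple[set[str], set[str], set[str]]:
    """Partition genes into (orphan, core, remaining).

    Core membership (orthology in a distant species) takes precedence over
    the hit count: a core gene is core even with a single hit. Orphans are
    non-core genes whose product hit only itself.
    """
    core = set(core_ids)
    missing = core - set(hits)
    if missing:
        raise ValidationError(
            f"core gene(s) absent from hit-count table: {sorted(missing)[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    orphan = {g for g, n in hits.items() if n == 1 and g not in core}
    remaining = {g for g in hits if g not in core and g not in orphan}
    return orphan, core, remaining


def bin_remaining(
    remaining_hits: Mapping[str, int],
    n_bins: int = 10,
    keep_ties_together: bool = False,
) -> dict[str, int]:
    """Assign each remaining gene a bin 1..n_bins by ascending hit count.

    Default mode balances occupancy exactly (bin sizes differ by at most
    one, larger bins first), breaking hit-count ties deterministically by
    gene id. With ``keep_ties_together`` genes sharing a hit count are never
    split across a bin boundary, at the price of unequal bins.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    n = len(remaining_hits)
    if n < n_bins:
        raise ValidationError(f"{n} genes cannot fill {n_bins} bins")
    order = sorted(remaining_hits, key=lambda g: (remaining_hits[g], g))
    base, extra = divmod(n, n_bins)
    sizes = [base + 1] * extra + [base] * (n_bins - extra)
    bounds = []
    stop = 0
    for s in sizes:
        stop += s
        bounds.append(stop)

    assignment: dict[str, int] = {}
    if not keep_ties_together:
        start = 0
        for k, stop in enumerate(bounds, start=1):
            for g in order[start:stop]:
                assignment[g] = k
            start = stop
        return assignment

    # Tie-preserving mode: a run of equal hit counts goes entirely to the
    # bin owning the run's midpoint position in the balanced layout.
    import bisect

    i = 0
    while i < n:
        j = i
        h = remaining_hits[order[i]]
        while j < n and remaining_hits[order[j]] == h:
            j += 1
        mid = (i + j - 1) // 2
        k = bisect.bisect_right(bounds, mid) + 1
        for g in order[i:j]:
            assignment[g] = min(k, n_bins)
        i = j
    return assignment


def versatility_index(
    orphan: set[str], core: set[str], bins: Mapping[str, int], n_bins: int
) -> dict[str, int]:
    """Index 0 for orphans, bin number for binned genes, n_bins+1 for core."""
    index = {g: 0 for g in orphan}
    index.update({g: n_bins + 1 for g in core})
    index.update(bins)
    return index


def assign_versatility(
    hits: Mapping[str, int],
    core_ids: Iterable[str],
    n_bins: int = 10,
    keep_ties_together: bool = False,
) -> VersatilityAssignment:
    """Full assignment: classify, bin the remaining genes, index everything."""
    orphan, core, remaining = classify_genes(hits, core_ids)
    bins = bin_remaining({g: hits[g] for g in remaining}, n_bins,
                         keep_ties_together=keep_ties_together)
    index = versatility_index(orphan, core, bins, n_bins)
    category = {g: ORPHAN for g in orphan}
    category.update({g: CORE for g in core})
    category.update({g: bin_label(k) for g, k in bins.items()})
    logger.debug("versatility: %d orphan, %d core, %d binned",
                 len(orphan), len(core), len(bins))
    return VersatilityAssignment(category=category, index=index, n_bins=n_bins)


def category_regulation_counts(
    assignment: VersatilityAssignment, up: ResponseSet, down: ResponseSet
) -> pd.DataFrame:
    """Per versatility category, how many genes are up- and down-regulated.

    Genes absent from the assignment are ignored; totals over categories
    therefore equal the sizes of the sets restricted to assigned genes.
    """
    cats = assignment.categories_ordered()
    n_up = {c: 0 for c in cats}
    n_down = {c: 0 for c in cats}
    for g in up.members:
        c = assignment.category.get(g)
        if c is not None:
            n_up[c] += 1
    for g in down.members:
        c = assignment.category.get(g)
        if c is not None:
            n_down[c] += 1
    return pd.DataFrame(
        {"category": cats,
         "n_up": [n_up[c] for c in cats],
         "n_down": [n_down[c] for c in cats]}
    )
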