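"""Chromosomal landscapes: sliding windows, region calling, coincidence.

Windows are fixed-size spans of consecutive gene ordinals; for each window
we record the mean versatility index and, per condition, the fraction of
window genes in that condition's up-regulated set. Regions of clustered
lineage-specific genes ("versatility troughs": window mean index below the
chromosome mean minus one standard deviation) and of clustered up-regulated
genes ("expression hotspots": up-fraction above mean plus one SD) are
called per chromosome, merged, filtered by a minimum gene span, and
labelled alphabetically genome-wide.
"""

from __future__ import annotations

import string
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    GeneRecord,
    GenomicRegion,
    ResponseSet,
    ValidationError,
    chromosome_sizes,
    logger,
)
from .versatility import VersatilityAssignment

TROUGH = "versatility_trough"
HOTSPOT = "expression_hotspot"


def window_profiles(
    genes: Sequence[GeneRecord],
    assignment: VersatilityAssignment,
    up_sets: Mapping[str, ResponseSet],
    window: int = 100,
    step: int = 1,
) -> pd.DataFrame:
    """Sliding-window means of versatility index and up-regulated fractions.

    One row per window with columns ``chromosome``, ``start``, ``end``
    (closed 1-based ordinals), ``mean_index`` and ``frac_<condition>`` for
    every up set. Chromosomes shorter than the window are skipped with a
    warning.
    """
    if window < 2:
        raise ValidationError("window must be >= 2")
    if step < 1:
        raise ValidationError("step must be >= 1")
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in sorted(genes, key=lambda g: (g.chromosome, g.ordinal)):
        by_chrom.setdefault(g.chromosome, []).append(g)

    conds = sorted(up_sets)
    frames = []
    for chrom, chrom_genes in sorted(by_chrom.items()):
        n = len(chrom_genes)
        if n < window:
            logger.warning("chromosome %s has %d < %d genes; skipped",
                           chrom, n, window)
            continue
        idx = np.array([assignment.index[g.gene_id] for g in chrom_genes],
                       dtype=float)
        starts = np.arange(0, n - window + 1, step)
        # cumulative sums give every window mean in O(n)
        csum = np.concatenate([[0.0], np.cumsum(idx)])
        mean_index = (csum[starts + window] - csum[starts]) / window
        cols = {
            "chromosome": chrom,
            "start": starts + 1,
            "end": starts + window,
            "mean_index": mean_index,
        }
        for cond in conds:
            member = np.array(
                [g.gene_id in up_sets[cond].members for g in chrom_genes],
                dtype=float,
            )
            mcsum = np.concatenate([[0.0], np.cumsum(member)])
            cols[f"frac_{cond}"] = (mcsum[starts + window] - mcsum[starts]) / window
        frames.append(pd.DataFrame(cols))
    if not frames:
        return pd.DataFrame(
            columns=["chromosome", "start", "end", "mean_index"]
            + [f"frac_{c}" for c in conds]
        )
    return pd.concat(frames, ignore_index=True)


def _merge_runs(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent closed ordinal intervals."""
    if not spans:
        return []
    spans = sorted(spans)
    merged = [spans[0]]
    for s, e in spans[1:]:
        ps, pe = merged[-1]
        if s <= pe + 1:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def _call_extreme_regions(
    profiles: pd.DataFrame,
    value_col: str,
    side: str,
    kind: str,
    min_run: int,
    condition: str | None = None,
) -> list[GenomicRegion]:
    """Runs of windows beyond the per-chromosome mean -/+ SD threshold."""
    regions: list[GenomicRegion] = []
    for chrom, df in profiles.groupby("chromosome", sort=True):
        vals = df[value_col].to_numpy(dtype=float)
        mu, sd = float(np.mean(vals)), float(np.std(vals))
        if sd == 0:
            logger.warning("%s: zero variance in %s; no %s regions",
                           chrom, value_col, kind)
            continue
        qual = vals < mu - sd if side == "low" else vals > mu + sd
        spans = [
            (int(df["start"].iloc[i]), int(df["end"].iloc[i]))
            for i in np.flatnonzero(qual)
        ]
        for s, e in _merge_runs(spans):
            if e - s + 1 >= min_run:
                regions.append(GenomicRegion(chromosome=str(chrom), start=s,
                                             end=e, kind=kind,
                                             condition=condition))
    return regions


def _region_label(i: int) -> str:
    """a..z, then aa, ab, ... for overflow."""
    letters = string.ascii_lowercase
    if i < 26:
        return letters[i]
    return letters[(i // 26) - 1] + letters[i % 26]


def label_regions(regions: list[GenomicRegion]) -> list[GenomicRegion]:
    """Alphabetical genome-wide labels by (chromosome, start)."""
    ordered = sorted(regions, key=lambda r: (r.chromosome, r.start))
    return [
        GenomicRegion(chromosome=r.chromosome, start=r.start, end=r.end,
                      kind=r.kind, condition=r.condition,
                      label=_region_label(i))
        for i, r in enumerate(ordered)
    ]


def call_versatility_troughs(
    profiles: pd.DataFrame | None = None,
    genes: Sequence[GeneRecord] | None = None,
    assignment: VersatilityAssignment | None = None,
    mode: str = "window",
    min_run: int = 5,
) -> list[GenomicRegion]:
    """Call clustered low-versatility (lineage-specific) regions.

    In ``window`` mode the mean-minus-SD threshold is applied to window
    means from ``profiles``; in ``gene`` mode it is applied to raw per-gene
    indices (needs ``genes`` and ``assignment``). Regions spanning fewer
    than ``min_run`` genes are dropped; surviving regions are labelled
    alphabetically genome-wide.
    """
    if mode == "window":
        if profiles is None:
            raise ValidationError("window mode requires profiles")
        regions = _call_extreme_regions(profiles, "mean_index", "low",
                                        TROUGH, min_run)
    elif mode == "gene":
        if genes is None or assignment is None:
            raise ValidationError("gene mode requires genes and assignment")
        rows = [
            {"chromosome": g.chromosome, "start": g.ordinal, "end": g.ordinal,
             "mean_index": assignment.index[g.gene_id]}
            for g in genes
        ]
        regions = _call_extreme_regions(pd.DataFrame(rows), "mean_index",
                                        "low", TROUGH, min_run)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return label_regions(regions)


def call_expression_hotspots(
    profiles: pd.DataFrame, condition: str, min_run: int = 5
) -> list[GenomicRegion]:
    """Call runs of windows unusually dense in up-regulated genes."""
    col = f"frac_{condition}"
    if col not in profiles.columns:
        raise ValidationError(f"profiles lack column {col!r}")
    regions = _call_extreme_regions(profiles, col, "high", HOTSPOT, min_run,
                                    condition=condition)
    return label_regions(regions)


def region_coincidence(
    troughs: Sequence[GenomicRegion],
    hotspots_by_condition: Mapping[str, Sequence[GenomicRegion]],
    min_overlap: int = 1,
) -> pd.DataFrame:
    """For each trough, which conditions' hotspots overlap it.

    A trough coincides when it shares at least ``min_overlap`` genes with a
    hotspot of at least one condition. One row per trough with a boolean
    per condition and a summary ``coincides`` column.
    """
    conds = sorted(hotspots_by_condition)
    rows = []
    for t in sorted(troughs, key=lambda r: (r.chromosome, r.start)):
        row: dict = {"label": t.label, "chromosome": t.chromosome,
                     "start": t.start, "end": t.end}
        hit_any = False
        for cond in conds:
            hit = any(t.overlap_genes(h) >= min_overlap
                      for h in hotspots_by_condition[cond])
            row[f"hotspot_{cond}"] = hit
            hit_any = hit_any or hit
        row["coincides"] = hit_any
        rows.append(row)
    return pd.DataFrame(rows)


def flag_telomeric(
    regions: Sequence[GenomicRegion],
    genes: Sequence[GeneRecord],
    margin: int = 100,
) -> pd.DataFrame:
    """Flag regions within ``margin`` genes of either chromosome end."""
    sizes = chromosome_sizes(genes)
    rows = []
    for r in regions:
        n = sizes.get(r.chromosome, 0)
        telomeric = r.start <= margin or r.end > n - margin
        rows.append({"label": r.label, "chromosome": r.chromosome,
                     "start": r.start, "end": r.end, "telomeric": telomeric})
    return pd.DataFrame(rows)
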