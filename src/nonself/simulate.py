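"""Seeded synthetic-data generator with known ground truth.

Emulates the statistical structure of a filamentous-fungus genome
responding to two antagonistic bacteria and to vegetative incompatibility
(VI), so every pipeline stage can be tested end-to-end without real data:

* a genome of ~10,635 genes on 7 chromosomes with 3,297 core genes, 640
  orphans and 6,698 versatile genes, carrying 19 implanted clusters of
  lineage-specific genes (8 telomeric) plus category annotations (216 TFs,
  77 NLRs, 35 secondary-metabolite clusters totalling 470 genes, secreted
  proteins, autophagy and histidine-kinase genes);
* five differential-expression tables (two bacteria x two time points, and
  pooled VI) with correlated up/down responses between the bacteria,
  larger magnitudes in one condition, partial overlap with VI that decays
  at high fold changes, up-regulation biased toward low-versatility genes
  and toward implanted hotspot regions (13 of the 19 clusters), and
  down-regulation enriched in core genes;
* a paired second proteome with directed similarity tables whose
  reciprocal best hits recover a known ortholog map.

Determinism: every output table draws from its own RNG stream derived from
the master seed and a fixed label, so adding a table never perturbs the
others, and identical seeds give byte-identical files.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .model import ExpressionRecord, GeneRecord, ValidationError, logger, validate_genome
from .versatility import assign_versatility

# ---------------------------------------------------------------------------
# RNG streams


def _stream(seed: int, label: str) -> np.random.Generator:
    """Independent, label-addressed RNG stream from the master seed."""
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


# ---------------------------------------------------------------------------
# Parameters and truth


@dataclass
class GenomeParams:
    """Genome composition; defaults are the study conditions."""

    n_genes: int = 10635
    n_chrom: int = 7
    n_core: int = 3297
    n_orphan: int = 640
    region_length: int = 60
    in_region_orphan_frac: float = 0.45
    in_region_core_frac: float = 0.05
    n_tf: int = 216
    n_nlr: int = 77
    n_hk: int = 12
    n_autophagy: int = 18
    n_sm_clusters: int = 35
    n_sm_genes: int = 470
    n_secreted: int = 801


#: Pooled response-set sizes and per-time-point sizes, as fractions of the
#: genome; these mirror the study's Table-1-style design (e.g. 1847 of
#: 10635 genes up-regulated in the pooled response to the avirulent
#: bacterium).
_RATE = 1.0 / 10635.0


@dataclass
class ExpressionParams:
    """Differential-expression structure; defaults are the study conditions."""

    base_up_rate: float = 1847 * _RATE       # pooled VsSf up
    base_down_rate: float = 1882 * _RATE     # pooled VsSf down
    sm_up_ratio: float = 1668 / 1847         # |VsSm up| / |VsSf up|
    sm_down_ratio: float = 1615 / 1882
    vi_up_ratio: float = 1913 / 1847
    vi_down_ratio: float = 1923 / 1882
    # fraction of the VsSm set absent from the VsSf set
    specific_frac_sm_up: float = 211 / 1668
    specific_frac_sm_down: float = 153 / 1615
    cond_correlation: float | None = None    # overrides specific fracs if set
    # per-time-point set sizes as fractions of the pooled set
    tp_up_frac_sf: tuple[float, float] = (1232 / 1847, 1325 / 1847)
    tp_up_frac_sm: tuple[float, float] = (1091 / 1668, 1289 / 1668)
    tp_down_frac_sf: tuple[float, float] = (838 / 1882, 1605 / 1882)
    tp_down_frac_sm: tuple[float, float] = (781 / 1615, 1458 / 1615)
    magnitude_ratio: float = 1.2             # VsSf over VsSm on shared genes
    magnitude_noise_sd: float = 0.15
    vi_overlap_odds: float = 3.0             # VI sampling odds for bacterial genes
    up_index_slope: float = 0.8              # up weight grows as index falls
    down_index_slope: float = 1.6            # down weight grows as index rises
    hotspot_boost: float = 6.0
    sm_up_boost: float = 1.8                 # secondary-metabolite cluster genes
    ssp_up_boost: float = 1.8                # SSP genes, bacterial conditions only
    ssp_mag_scale: float = 1.25              # SSP bacterial magnitudes scaled up
    base_mag_mean: float = 2.2
    base_mag_sd: float = 1.5
    vi_shared_mag_mean: float = 0.8          # bacterial magnitudes of VI-shared genes
    vi_shared_mag_sd: float = 0.8
    mag_floor: float = 2.05
    max_abs_log2fc: float = 11.5
    null_sd: float = 0.7

    def __post_init__(self) -> None:
        for name in ("base_up_rate", "base_down_rate", "specific_frac_sm_up",
                     "specific_frac_sm_down"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.magnitude_ratio <= 0:
            raise ValidationError("magnitude_ratio must be > 0")
        if self.cond_correlation is not None:
            if not (0.0 <= self.cond_correlation <= 1.0):
                raise ValidationError("cond_correlation must be in [0, 1]")
            self.specific_frac_sm_up = 1.0 - self.cond_correlation
            self.specific_frac_sm_down = 1.0 - self.cond_correlation


@dataclass
class SyntheticTruth:
    """Everything needed to recompute expected summaries without re-reading
    the generated tables."""

    seed: int
    genome_params: dict = field(default_factory=dict)
    regions: list = field(default_factory=list)  # implanted low-versatility regions
    hotspot_regions: dict = field(default_factory=dict)  # condition -> regions
    categories: dict = field(default_factory=dict)  # label -> gene id list
    expression_params: dict = field(default_factory=dict)
    pools: dict = field(default_factory=dict)  # "<cond>_<dir>" -> gene id list
    ortholog_map: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class GenomeBundle:
    genes: list[GeneRecord]
    hits: dict[str, int]
    core_ids: frozenset[str]
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Genome


def _chromosome_sizes(n_genes: int, n_chrom: int) -> list[int]:
    weights = np.linspace(1.5, 0.9, n_chrom)
    raw = weights / weights.sum() * n_genes
    sizes = np.floor(raw).astype(int)
    for i in range(n_genes - int(sizes.sum())):
        sizes[i % n_chrom] += 1
    return [int(s) for s in sizes]


def default_region_spec(n_genes: int = 10635, n_chrom: int = 7,
                        region_length: int = 60) -> list[tuple[str, int, int]]:
    """The study-like layout: 19 low-versatility regions, 8 telomeric.

    One telomeric region at the start of every chromosome plus one at the
    end of chromosome 1; one interior region at 40% of every chromosome;
    a second interior region at 70% of chromosomes 1-4.
    """
    sizes = _chromosome_sizes(n_genes, n_chrom)
    spec: list[tuple[str, int, int]] = []
    for c in range(n_chrom):
        chrom = str(c + 1)
        n = sizes[c]
        spec.append((chrom, 1, region_length))
        spec.append((chrom, int(0.4 * n), region_length))
        if c == 0:
            spec.append((chrom, n - region_length + 1, region_length))
        if c < 4:
            spec.append((chrom, int(0.7 * n), region_length))
    return sorted(spec)


def default_hotspot_spec(
    region_spec: Sequence[tuple[str, int, int]],
    n_genes: int = 10635,
    n_chrom: int = 7,
    region_length: int = 60,
) -> dict[str, list[tuple[str, int, int]]]:
    """Which regions carry implanted up-regulation hotspots.

    The interior low-versatility regions (11 of them) plus the telomeric
    regions of chromosomes 1 and 2 — 13 in all, at least one per
    chromosome — are boosted in every condition; two further background
    regions are boosted only in VsSf and two only in VI (condition-specific
    hotspots away from any versatility cluster).
    """
    sizes = _chromosome_sizes(n_genes, n_chrom)
    shared = [r for r in region_spec if r[1] not in (1, sizes[int(r[0]) - 1] - region_length + 1)]
    shared += [r for r in region_spec if r[1] == 1 and r[0] in ("1", "2")]
    extra_sf = [(str(c), int(0.85 * sizes[c - 1]), region_length)
                for c in (5, 6) if c <= n_chrom]
    extra_vi = [(str(c), int(0.85 * sizes[c - 1]), region_length)
                for c in (7,) if c <= n_chrom]
    extra_vi += [(str(4), int(0.15 * sizes[3]), region_length)] if n_chrom >= 4 else []
    return {
        "VsSf": sorted(shared) + extra_sf,
        "VsSm": sorted(shared),
        "VI": sorted(shared) + extra_vi,
    }


def _in_regions_mask(chrom: np.ndarray, ordinal: np.ndarray,
                     regions: Sequence[tuple[str, int, int]]) -> np.ndarray:
    mask = np.zeros(len(chrom), dtype=bool)
    for c, start, length in regions:
        mask |= (chrom == c) & (ordinal >= start) & (ordinal < start + length)
    return mask


def generate_genome(
    n_genes: int = 10635,
    n_chrom: int = 7,
    n_core: int = 3297,
    n_orphan: int = 640,
    region_spec: Sequence[tuple[str, int, int]] | None = None,
    seed: int = 0,
    params: GenomeParams | None = None,
) -> GenomeBundle:
    """Generate gene records, hit counts and the core-gene list.

    Orphans get a single (self) hit; core genes draw hit counts from a
    high range; other genes draw from a broad distribution, except inside
    the implanted regions where non-core genes draw from the low tail,
    producing clusters of lineage-specific genes.
    """
    p = params or GenomeParams(n_genes=n_genes, n_chrom=n_chrom,
                               n_core=n_core, n_orphan=n_orphan)
    if p.n_core + p.n_orphan > p.n_genes:
        raise ValidationError("n_core + n_orphan exceeds n_genes")
    sizes = _chromosome_sizes(p.n_genes, p.n_chrom)
    if region_spec is None:
        region_spec = default_region_spec(p.n_genes, p.n_chrom, p.region_length)
    for c, start, length in region_spec:
        if int(c) > p.n_chrom or start < 1 or start + length - 1 > sizes[int(c) - 1]:
            raise ValidationError(f"region {(c, start, length)} does not fit")

    chrom = np.concatenate([
        np.full(sizes[c], str(c + 1), dtype=object) for c in range(p.n_chrom)
    ])
    ordinal = np.concatenate([np.arange(1, s + 1) for s in sizes])
    gene_ids = np.array(
        [f"g{c}.{o:05d}" for c, o in zip(chrom, ordinal)], dtype=object
    )
    in_region = _in_regions_mask(chrom, ordinal, region_spec)
    n_in = int(in_region.sum())

    rng = _stream(seed, "genome")
    # statuses: 0 orphan, 1 core, 2 remaining
    status = np.full(p.n_genes, 2, dtype=int)
    n_orph_in = min(int(round(p.in_region_orphan_frac * n_in)), p.n_orphan)
    n_core_in = min(int(round(p.in_region_core_frac * n_in)), p.n_core)
    inside = np.flatnonzero(in_region)
    outside = np.flatnonzero(~in_region)
    inside_shuffled = rng.permutation(inside)
    status[inside_shuffled[:n_orph_in]] = 0
    status[inside_shuffled[n_orph_in:n_orph_in + n_core_in]] = 1
    n_orph_out = p.n_orphan - n_orph_in
    n_core_out = p.n_core - n_core_in
    if n_orph_out + n_core_out > len(outside):
        raise ValidationError("regions too large for requested core/orphan counts")
    outside_shuffled = rng.permutation(outside)
    status[outside_shuffled[:n_orph_out]] = 0
    status[outside_shuffled[n_orph_out:n_orph_out + n_core_out]] = 1

    # hit counts
    hits = np.ones(p.n_genes, dtype=int)
    core_mask = status == 1
    hits[core_mask] = rng.integers(60, 251, core_mask.sum())
    rem_mask = status == 2
    rem_out = rem_mask & ~in_region
    rem_in = rem_mask & in_region
    hits[rem_out] = np.clip(
        2 + np.round(np.exp(rng.normal(3.0, 1.1, rem_out.sum()))).astype(int),
        2, 500,
    )
    hits[rem_in] = rng.integers(2, 6, rem_in.sum())

    # categories: disjoint class tags, contiguous SM clusters, secretion
    tag_rng = _stream(seed, "categories")
    tags = (["TF"] * p.n_tf + ["NLR"] * p.n_nlr + ["HK"] * p.n_hk
            + ["autophagy"] * p.n_autophagy)
    tagged = tag_rng.choice(p.n_genes, size=len(tags), replace=False)
    categories: list[set[str]] = [set() for _ in range(p.n_genes)]
    for pos, tag in zip(tagged, tags):
        categories[pos].add(tag)

    cluster_sizes = _partition_total(tag_rng, p.n_sm_genes, p.n_sm_clusters,
                                     low=5, high=25)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    sm_starts = _place_blocks(tag_rng, sizes, cluster_sizes, region_spec)
    for k, ((ci, start), length) in enumerate(zip(sm_starts, cluster_sizes), 1):
        for pos in range(offsets[ci] + start - 1, offsets[ci] + start - 1 + length):
            categories[pos].add(f"SM{k:02d}")

    secreted = np.zeros(p.n_genes, dtype=bool)
    secreted[tag_rng.choice(p.n_genes, size=p.n_secreted, replace=False)] = True
    lengths = np.where(
        secreted,
        np.exp(tag_rng.normal(5.65, 0.6, p.n_genes)),
        np.exp(tag_rng.normal(6.1, 0.5, p.n_genes)),
    )
    lengths = np.clip(np.round(lengths), 60, 5000).astype(int)

    genes = [
        GeneRecord(gene_id=str(gene_ids[i]), chromosome=str(chrom[i]),
                   ordinal=int(ordinal[i]), protein_length=int(lengths[i]),
                   is_secreted=bool(secreted[i]),
                   categories=frozenset(categories[i]))
        for i in range(p.n_genes)
    ]
    genes = validate_genome(genes)
    hit_table = {str(g): int(h) for g, h in zip(gene_ids, hits)}
    core_ids = frozenset(str(g) for g in gene_ids[core_mask])

    cat_truth: dict[str, list[str]] = {}
    for i, cats in enumerate(categories):
        for cat in cats:
            cat_truth.setdefault(cat, []).append(str(gene_ids[i]))
    truth = SyntheticTruth(
        seed=seed,
        genome_params=asdict(p),
        regions=[list(r) for r in region_spec],
        categories={k: sorted(v) for k, v in cat_truth.items()},
    )
    logger.info("generated genome: %d genes, %d chromosomes, %d regions",
                p.n_genes, p.n_chrom, len(region_spec))
    return GenomeBundle(genes=genes, hits=hit_table, core_ids=core_ids,
                        truth=truth)


def _partition_total(rng: np.random.Generator, total: int, parts: int,
                     low: int, high: int) -> list[int]:
    """Random part sizes in [low, high] summing exactly to ``total``."""
    if not (parts * low <= total <= parts * high):
        raise ValidationError(
            f"cannot split {total} into {parts} parts within [{low}, {high}]"
        )
    sizes = rng.integers(low, high + 1, parts)
    diff = total - int(sizes.sum())
    step = 1 if diff > 0 else -1
    i = 0
    while diff != 0:
        k = i % parts
        if low <= sizes[k] + step <= high:
            sizes[k] += step
            diff -= step
        i += 1
    return [int(s) for s in sizes]


def _place_blocks(
    rng: np.random.Generator,
    chrom_sizes: Sequence[int],
    block_sizes: Sequence[int],
    avoid: Sequence[tuple[str, int, int]],
) -> list[tuple[int, int]]:
    """Non-overlapping (chrom_index, start) placements for contiguous blocks,
    avoiding the implanted regions."""
    taken: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(chrom_sizes))}
    for c, s, ln in avoid:
        taken[int(c) - 1].append((s, s + ln - 1))
    placements = []
    for length in block_sizes:
        for _ in range(1000):
            ci = int(rng.integers(0, len(chrom_sizes)))
            start = int(rng.integers(1, chrom_sizes[ci] - length + 1))
            end = start + length - 1
            if all(end < s or start > e for s, e in taken[ci]):
                taken[ci].append((start, end))
                placements.append((ci, start))
                break
        else:
            raise ValidationError("could not place all gene clusters")
    return placements


# ---------------------------------------------------------------------------
# Expression


def _weighted_sample(rng: np.random.Generator, candidates: np.ndarray,
                     weights: np.ndarray, size: int) -> np.ndarray:
    """Weighted sampling without replacement via the Gumbel top-k trick
    (equivalent to successive weighted draws)."""
    if size > len(candidates):
        raise ValidationError("sample size exceeds candidate pool")
    if size == 0:
        return candidates[:0]
    keys = np.log(weights) + rng.gumbel(size=len(candidates))
    return candidates[np.argsort(-keys)[:size]]


def generate_expression(
    bundle: GenomeBundle,
    params: ExpressionParams | None = None,
    seed: int = 0,
    hotspot_spec: Mapping[str, Sequence[tuple[str, int, int]]] | None = None,
) -> tuple[dict[str, list[ExpressionRecord]], SyntheticTruth]:
    """Generate the five condition tables with known regulated pools.

    Pool construction: the VsSf pools are weighted samples of the genome
    (weight rising as versatility falls for up, rising with versatility
    for down, boosted inside hotspot regions); the VsSm pools share genes
    with VsSf except for a configurable specific fraction; the VI pools
    preferentially resample the bacterial pools at configurable odds.
    Magnitudes: regulated |log2FC| is a floor-shifted folded Gaussian
    capped at ``max_abs_log2fc``; VsSf magnitudes scale VsSm magnitudes by
    ``magnitude_ratio`` on shared genes; bacterial magnitudes of genes also
    in the VI pool are drawn from a low range so the bacteria-VI overlap
    decays as the fold-change threshold rises. Unregulated genes get
    near-zero log2FC and uniform p-values.
    """
    p = params or ExpressionParams()
    genes = bundle.genes
    n = len(genes)
    ids = np.array([g.gene_id for g in genes], dtype=object)
    chrom = np.array([g.chromosome for g in genes], dtype=object)
    ordinal = np.array([g.ordinal for g in genes])

    assignment = assign_versatility(bundle.hits, bundle.core_ids)
    index = np.array([assignment.index[g] for g in ids], dtype=float)
    n_bins = assignment.n_bins

    if hotspot_spec is None:
        gp = bundle.truth.genome_params
        hotspot_spec = default_hotspot_spec(
            bundle.truth.regions or default_region_spec(
                gp.get("n_genes", n), gp.get("n_chrom", 7)),
            gp.get("n_genes", n), gp.get("n_chrom", 7),
            gp.get("region_length", 60),
        )
    hot_masks = {
        cond: _in_regions_mask(chrom, ordinal, regions)
        for cond, regions in hotspot_spec.items()
    }

    sm_mask = np.array(
        [any(c.startswith("SM") for c in g.categories) for g in genes])
    ssp_mask = np.array([g.is_ssp() for g in genes])

    w_up = 1.0 + p.up_index_slope * (n_bins + 1 - index) / (n_bins + 1)
    w_up = np.where(sm_mask, w_up * p.sm_up_boost, w_up)
    # SSP up-bias is a feature of the bacterial responses, not of VI
    w_up_bact = np.where(ssp_mask, w_up * p.ssp_up_boost, w_up)
    w_down = 1.0 + p.down_index_slope * index / (n_bins + 1)

    rng = _stream(seed, "expression")

    n_sf_up = int(round(p.base_up_rate * n))
    n_sf_down = int(round(p.base_down_rate * n))
    n_sm_up = int(round(n_sf_up * p.sm_up_ratio))
    n_sm_down = int(round(n_sf_down * p.sm_down_ratio))
    n_vi_up = int(round(n_sf_up * p.vi_up_ratio))
    n_vi_down = int(round(n_sf_down * p.vi_down_ratio))

    all_pos = np.arange(n)

    def boost(w: np.ndarray, cond: str) -> np.ndarray:
        return np.where(hot_masks.get(cond, False), w * p.hotspot_boost, w)

    # pooled up sets
    sf_up = _weighted_sample(rng, all_pos, boost(w_up_bact, "VsSf"), n_sf_up)
    sf_up_set = set(sf_up.tolist())
    n_sm_spec = int(round(p.specific_frac_sm_up * n_sm_up))
    shared_up = _weighted_sample(rng, sf_up, boost(w_up_bact, "VsSm")[sf_up],
                                 n_sm_up - n_sm_spec)
    sm_cand = np.array([i for i in all_pos if i not in sf_up_set])
    sm_spec_up = _weighted_sample(rng, sm_cand,
                                  boost(w_up_bact, "VsSm")[sm_cand],
                                  n_sm_spec)
    sm_up = np.concatenate([shared_up, sm_spec_up])
    sm_up_set = set(sm_up.tolist())

    # pooled down sets, disjoint from the up pools
    up_union = sf_up_set | sm_up_set
    down_cand = np.array([i for i in all_pos if i not in up_union])
    sf_down = _weighted_sample(rng, down_cand, w_down[down_cand], n_sf_down)
    sf_down_set = set(sf_down.tolist())
    n_sm_spec_d = int(round(p.specific_frac_sm_down * n_sm_down))
    shared_down = _weighted_sample(rng, sf_down, w_down[sf_down],
                                   n_sm_down - n_sm_spec_d)
    sm_cand_d = np.array([i for i in down_cand if i not in sf_down_set])
    sm_spec_down = _weighted_sample(rng, sm_cand_d, w_down[sm_cand_d],
                                    n_sm_spec_d)
    sm_down = np.concatenate([shared_down, sm_spec_down])
    sm_down_set = set(sm_down.tolist())
    down_union = sf_down_set | sm_down_set

    # VI pools: odds-boosted resampling of the bacterial pools
    vi_w_up = boost(w_up, "VI").copy()
    bact_up = np.array(sorted(up_union), dtype=int)
    vi_w_up[bact_up] *= p.vi_overlap_odds
    vi_up_cand = np.array([i for i in all_pos if i not in down_union])
    vi_up = _weighted_sample(rng, vi_up_cand, vi_w_up[vi_up_cand], n_vi_up)
    vi_up_set = set(vi_up.tolist())

    vi_w_down = w_down.copy()
    bact_down = np.array(sorted(down_union), dtype=int)
    vi_w_down[bact_down] *= p.vi_overlap_odds
    vi_down_cand = np.array(
        [i for i in all_pos if i not in up_union and i not in vi_up_set]
    )
    vi_down = _weighted_sample(rng, vi_down_cand, vi_w_down[vi_down_cand],
                               n_vi_down)
    vi_down_set = set(vi_down.tolist())

    # magnitudes (absolute log2FC) per pooled condition
    def draw_mag(pos: np.ndarray, in_vi: np.ndarray) -> np.ndarray:
        lo = p.mag_floor + np.abs(
            rng.normal(p.vi_shared_mag_mean, p.vi_shared_mag_sd, len(pos)))
        hi = p.mag_floor + np.abs(
            rng.normal(p.base_mag_mean, p.base_mag_sd, len(pos)))
        return np.minimum(np.where(in_vi, lo, hi), p.max_abs_log2fc)

    mag: dict[str, np.ndarray] = {}
    in_vi_sf_up = np.array([i in vi_up_set for i in sf_up])
    base_sf_up = draw_mag(sf_up, in_vi_sf_up)
    base_sf_up = np.minimum(
        np.where(ssp_mask[sf_up], base_sf_up * p.ssp_mag_scale, base_sf_up),
        p.max_abs_log2fc,
    )
    # VsSm magnitude on shared genes = VsSf magnitude / ratio (+ noise)
    mag["VsSf_up"] = base_sf_up
    sm_mag = np.empty(len(sm_up))
    shared_mask = np.isin(sm_up, sf_up)
    sf_pos = {g: k for k, g in enumerate(sf_up)}
    shared_idx = np.array([sf_pos[g] for g in sm_up[shared_mask]], dtype=int) \
        if shared_mask.any() else np.array([], dtype=int)
    noise = rng.normal(0.0, p.magnitude_noise_sd, int(shared_mask.sum()))
    sm_mag[shared_mask] = np.clip(
        base_sf_up[shared_idx] / p.magnitude_ratio + noise,
        p.mag_floor, p.max_abs_log2fc,
    )
    spec_mag = draw_mag(
        sm_up[~shared_mask],
        np.array([i in vi_up_set for i in sm_up[~shared_mask]], dtype=bool),
    )
    sm_mag[~shared_mask] = np.minimum(
        np.where(ssp_mask[sm_up[~shared_mask]], spec_mag * p.ssp_mag_scale,
                 spec_mag),
        p.max_abs_log2fc,
    )
    mag["VsSm_up"] = sm_mag

    in_vi_sf_down = np.array([i in vi_down_set for i in sf_down])
    base_sf_down = draw_mag(sf_down, in_vi_sf_down)
    mag["VsSf_down"] = base_sf_down
    smd_mag = np.empty(len(sm_down))
    shared_mask_d = np.isin(sm_down, sf_down)
    sfd_pos = {g: k for k, g in enumerate(sf_down)}
    shared_idx_d = np.array([sfd_pos[g] for g in sm_down[shared_mask_d]],
                            dtype=int) if shared_mask_d.any() else np.array([], dtype=int)
    noise_d = rng.normal(0.0, p.magnitude_noise_sd, int(shared_mask_d.sum()))
    smd_mag[shared_mask_d] = np.clip(
        base_sf_down[shared_idx_d] / p.magnitude_ratio + noise_d,
        p.mag_floor, p.max_abs_log2fc,
    )
    smd_mag[~shared_mask_d] = draw_mag(
        sm_down[~shared_mask_d],
        np.array([i in vi_down_set for i in sm_down[~shared_mask_d]], dtype=bool),
    )
    mag["VsSm_down"] = smd_mag

    mag["VI_up"] = np.minimum(
        p.mag_floor + np.abs(rng.normal(p.base_mag_mean, p.base_mag_sd,
                                        len(vi_up))),
        p.max_abs_log2fc,
    )
    mag["VI_down"] = np.minimum(
        p.mag_floor + np.abs(rng.normal(p.base_mag_mean, p.base_mag_sd,
                                        len(vi_down))),
        p.max_abs_log2fc,
    )

    # split bacterial pools over the two time points
    def split_timepoints(pool: np.ndarray, fracs: tuple[float, float]
                         ) -> tuple[set[int], set[int]]:
        m = len(pool)
        n1, n2 = int(round(fracs[0] * m)), int(round(fracs[1] * m))
        n_both = max(n1 + n2 - m, 0)
        perm = rng.permutation(pool)
        both = set(perm[:n_both].tolist())
        only1 = set(perm[n_both:n_both + (n1 - n_both)].tolist())
        only2 = set(perm[n_both + (n1 - n_both):].tolist())
        return both | only1, both | only2

    sf_up_2h, sf_up_6h = split_timepoints(sf_up, p.tp_up_frac_sf)
    sm_up_2h, sm_up_6h = split_timepoints(sm_up, p.tp_up_frac_sm)
    sf_down_2h, sf_down_6h = split_timepoints(sf_down, p.tp_down_frac_sf)
    sm_down_2h, sm_down_6h = split_timepoints(sm_down, p.tp_down_frac_sm)

    pool_mag: dict[tuple[str, int], float] = {}
    sign: dict[tuple[str, int], float] = {}

    def register(pool: np.ndarray, mags: np.ndarray, s: float,
                 key: str) -> None:
        for g, m in zip(pool, mags):
            pool_mag[(key, int(g))] = float(m)
            sign[(key, int(g))] = s

    register(sf_up, mag["VsSf_up"], +1.0, "VsSf")
    register(sf_down, mag["VsSf_down"], -1.0, "VsSf")
    register(sm_up, mag["VsSm_up"], +1.0, "VsSm")
    register(sm_down, mag["VsSm_down"], -1.0, "VsSm")
    register(vi_up, mag["VI_up"], +1.0, "VI")
    register(vi_down, mag["VI_down"], -1.0, "VI")

    cond_members = {
        "VsSf2h": ("VsSf", sf_up_2h | sf_down_2h),
        "VsSf6h": ("VsSf", sf_up_6h | sf_down_6h),
        "VsSm2h": ("VsSm", sm_up_2h | sm_down_2h),
        "VsSm6h": ("VsSm", sm_up_6h | sm_down_6h),
        "VI": ("VI", vi_up_set | vi_down_set),
    }

    tables: dict[str, list[ExpressionRecord]] = {}
    for cond, (key, members) in cond_members.items():
        crng = _stream(seed, f"expression/{cond}")
        lfc = crng.normal(0.0, p.null_sd, n)
        pvals = crng.uniform(0.0, 1.0, n)
        # an unregulated gene that draws a small p keeps a sub-threshold FC
        # (the common low-count case: significant but weak), so thresholded
        # sets recover the truth pools exactly at the default cutoffs
        lfc = np.where(pvals < 0.012, np.clip(lfc, -1.9, 1.9), lfc)
        jitter = crng.normal(1.0, 0.05, n)
        member_p = np.power(10.0, -crng.uniform(2.3, 12.0, n))
        for i in sorted(members):
            m = pool_mag[(key, i)] * max(jitter[i], 0.9)
            lfc[i] = sign[(key, i)] * float(np.clip(m, p.mag_floor,
                                                    p.max_abs_log2fc))
            pvals[i] = float(member_p[i])
        # pool members not regulated at this time point stay sub-threshold
        pool_members = {g for (k, g) in pool_mag if k == key}
        for i in pool_members - members:
            lfc[i] = float(np.clip(lfc[i], -1.9, 1.9))
        tables[cond] = [
            ExpressionRecord(gene_id=str(ids[i]), condition=cond,
                             log2fc=float(lfc[i]), p_value=float(pvals[i]))
            for i in range(n)
        ]

    truth = SyntheticTruth(
        seed=seed,
        genome_params=bundle.truth.genome_params,
        regions=bundle.truth.regions,
        hotspot_regions={c: [list(r) for r in regs]
                         for c, regs in hotspot_spec.items()},
        categories=bundle.truth.categories,
        expression_params={k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(p).items()},
        pools={
            "VsSf_up": sorted(str(ids[i]) for i in sf_up),
            "VsSf_down": sorted(str(ids[i]) for i in sf_down),
            "VsSm_up": sorted(str(ids[i]) for i in sm_up),
            "VsSm_down": sorted(str(ids[i]) for i in sm_down),
            "VI_up": sorted(str(ids[i]) for i in vi_up),
            "VI_down": sorted(str(ids[i]) for i in vi_down),
        },
        ortholog_map=bundle.truth.ortholog_map,
    )
    logger.info("generated expression for %d conditions", len(tables))
    return tables, truth


# ---------------------------------------------------------------------------
# Similarity / orthology


def generate_similarity(
    bundle: GenomeBundle,
    n_other: int | None = None,
    ortholog_frac: float = 0.6,
    noise: float = 0.03,
    seed: int = 0,
):
    """Directed similarity tables for a paired proteome with known orthologs.

    True ortholog pairs receive mutually highest scores; decoy hits are
    added per query, and with probability ``noise`` per direction a decoy
    outranks the true hit (breaking that pair's reciprocity).
    Returns (table_ab, table_ba, true_ortholog_map).
    """
    import pandas as pd

    if not (0.0 <= ortholog_frac <= 1.0):
        raise ValidationError("ortholog_frac must be in [0, 1]")
    if not (0.0 <= noise <= 1.0):
        raise ValidationError("noise must be in [0, 1]")
    ids_a = [g.gene_id for g in bundle.genes]
    if n_other is None:
        n_other = len(ids_a)
    ids_b = [f"B{i:05d}" for i in range(1, n_other + 1)]
    rng = _stream(seed, "similarity")

    n_pairs = int(round(ortholog_frac * min(len(ids_a), n_other)))
    a_sel = rng.choice(len(ids_a), size=n_pairs, replace=False)
    b_sel = rng.choice(n_other, size=n_pairs, replace=False)
    pairs = {ids_a[i]: ids_b[j] for i, j in zip(a_sel, b_sel)}

    rows_ab, rows_ba = [], []
    for a, b in pairs.items():
        score = float(rng.uniform(300.0, 1000.0))
        rows_ab.append((a, b, round(score, 1)))
        rows_ba.append((b, a, round(score, 1)))
        for direction, rows, q, others in (
            ("ab", rows_ab, a, ids_b), ("ba", rows_ba, b, ids_a),
        ):
            n_decoy = int(rng.poisson(2.0))
            for _ in range(n_decoy):
                s = others[int(rng.integers(0, len(others)))]
                if s == (b if direction == "ab" else a):
                    continue
                rows.append((q, s, round(float(rng.uniform(50.0, 0.9 * score)), 1)))
            if rng.uniform() < noise:
                s = others[int(rng.integers(0, len(others)))]
                if s != (b if direction == "ab" else a):
                    rows.append((q, s, round(score * float(rng.uniform(1.01, 1.1)), 1)))
    # unpaired queries get decoy-only hits, aimed at genes whose true best
    # hit is elsewhere so decoys can never create a reciprocal pair
    unpaired_a = [a for a in ids_a if a not in pairs]
    paired_b = sorted(pairs.values())
    paired_a = sorted(pairs)
    unpaired_b = [b for b in ids_b if b not in set(paired_b)]
    for q_list, others, rows in ((unpaired_a, paired_b, rows_ab),
                                 (unpaired_b, paired_a, rows_ba)):
        if not others:
            continue
        for q in q_list:
            if rng.uniform() < 0.5:
                s = others[int(rng.integers(0, len(others)))]
                rows.append((q, s, round(float(rng.uniform(50.0, 250.0)), 1)))

    def to_frame(rows) -> pd.DataFrame:
        df = pd.DataFrame(rows, columns=["qseqid", "sseqid", "bitscore"])
        df = (df.sort_values(["qseqid", "sseqid", "bitscore"],
                             ascending=[True, True, False])
                .drop_duplicates(["qseqid", "sseqid"], keep="first")
                .reset_index(drop=True))
        df["evalue"] = np.power(10.0, -df["bitscore"] / 10.0)
        return df

    logger.info("generated similarity tables: %d true pairs", n_pairs)
    return to_frame(rows_ab), to_frame(rows_ba), pairs
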