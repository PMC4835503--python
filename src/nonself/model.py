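"""Domain types shared by every stage of the pipeline.

The coordinate system throughout is the *gene ordinal*: the 1-based rank of a
gene along its chromosome. All window and region computations are in gene
units, not base pairs, because the landscape statistics (100-gene sliding
windows, contiguous-gene region calls) are defined on gene ranks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger("nonself")

#: Proteins shorter than this many amino acids count as "small"; a small
#: secreted protein (SSP) is a candidate effector/defensin.
SSP_MAX_LENGTH = 250

#: Default differential-expression thresholds: |log2FC| > 2 and p < 0.01,
#: both strict.
DEFAULT_MIN_ABS_LOG2FC = 2.0
DEFAULT_MAX_P = 0.01

#: The five condition labels of the study design: two bacteria at two time
#: points each, plus the pooled vegetative-incompatibility response.
CONDITIONS = ("VsSf2h", "VsSf6h", "VsSm2h", "VsSm6h", "VI")
POOLED_CONDITIONS = ("VsSf", "VsSm", "VI")


class ValidationError(ValueError):
    """An input violated a domain invariant."""


class FormatError(ValueError):
    """A file could not be parsed (missing column, bad value...)."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene: its position (chromosome + ordinal rank) and annotations.

    ``categories`` holds flat labels: Pfam accessions, GO ids, class tags
    (``TF``, ``NLR``, ``HK``, ``autophagy``) and secondary-metabolite cluster
    ids (``SM01``...). SSP status is derived, never stored: a gene encodes a
    small secreted protein iff it is secreted and its product is shorter
    than :data:`SSP_MAX_LENGTH` amino acids.
    """

    gene_id: str
    chromosome: str
    ordinal: int
    protein_length: int
    is_secreted: bool = False
    categories: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.ordinal < 1:
            raise ValidationError(f"{self.gene_id}: ordinal must be >= 1")
        if self.protein_length < 1:
            raise ValidationError(f"{self.gene_id}: protein_length must be >= 1")

    def is_ssp(self, max_length: int = SSP_MAX_LENGTH) -> bool:
        return self.is_secreted and self.protein_length < max_length


@dataclass(frozen=True)
class ExpressionRecord:
    """Differential expression of one gene in one condition vs control."""

    gene_id: str
    condition: str
    log2fc: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(
                f"{self.gene_id} ({self.condition}): p_value {self.p_value} "
                "outside [0, 1]"
            )


@dataclass(frozen=True)
class ResponseSet:
    """A direction-specific differentially-expressed gene set.

    Built at stated thresholds; an up and a down set built from the same
    table at the same thresholds are disjoint by construction.
    """

    label: str
    direction: str  # "up" or "down"
    min_abs_log2fc: float
    max_p: float
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValidationError(f"direction must be up/down, got {self.direction}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.members


@dataclass(frozen=True)
class ContingencyResult:
    """A 2x2 test: counts (a, b, c, d), fold enrichment, two-tail p.

    ``fold`` is NaN (and ``fold_defined`` False) when an expected count is
    zero. The layout of (a, b, c, d) is operation-specific and documented at
    each call site; ``p_two_tail`` is always a two-sided p-value.
    """

    a: int
    b: int
    c: int
    d: int
    fold: float
    p_two_tail: float
    method: str  # fisher_exact | chi_square | binomial

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def fold_defined(self) -> bool:
        return not math.isnan(self.fold)


@dataclass(frozen=True)
class GenomicRegion:
    """A called interval of gene ordinals (closed, 1-based) on one chromosome.

    ``kind`` is ``versatility_trough`` (run of lineage-specific genes, i.e.
    low versatility index) or ``expression_hotspot`` (run of windows dense in
    up-regulated genes, with ``condition`` naming the response).
    """

    chromosome: str
    start: int
    end: int
    kind: str
    condition: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"region start {self.start} > end {self.end}")

    @property
    def n_genes(self) -> int:
        return self.end - self.start + 1

    def overlap_genes(self, other: "GenomicRegion") -> int:
        if self.chromosome != other.chromosome:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class RunConfig:
    """All tunables of a pipeline run, loadable from YAML/JSON.

    Thresholds are on the log2 scale (``min_abs_log2fc``); window/step/min_run
    are in gene units.
    """

    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC
    max_p: float = DEFAULT_MAX_P
    window: int = 100
    step: int = 1
    min_run: int = 5
    n_bins: int = 10
    ssp_max_length: int = SSP_MAX_LENGTH
    telomere_margin: int = 100
    universe_size: int | None = None
    seed: int = 0
    input_paths: dict = field(default_factory=dict)
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.min_abs_log2fc < 0:
            raise ValidationError("min_abs_log2fc must be >= 0")
        if not (0 < self.max_p <= 1):
            raise ValidationError("max_p must be in (0, 1]")
        if self.window < 2:
            raise ValidationError("window must be >= 2")
        if self.n_bins < 2:
            raise ValidationError("n_bins must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise FormatError(f"{path}: config must be a mapping")
        return cls.from_dict(data)


def validate_genome(records: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Sort by (chromosome, ordinal) and enforce the genome invariants.

    Within each chromosome, ordinals must be unique and form 1..n with no
    gaps.
    """
    recs = sorted(records, key=lambda r: (r.chromosome, r.ordinal))
    seen_ids: set[str] = set()
    by_chrom: dict[str, list[int]] = {}
    for r in recs:
        if r.gene_id in seen_ids:
            raise ValidationError(f"duplicate gene_id {r.gene_id}")
        seen_ids.add(r.gene_id)
        by_chrom.setdefault(r.chromosome, []).append(r.ordinal)
    for chrom, ords in by_chrom.items():
        if len(set(ords)) != len(ords):
            dup = sorted(o for o in set(ords) if ords.count(o) > 1)
            raise ValidationError(
                f"chromosome {chrom}: duplicate ordinal(s) {dup}"
            )
        if ords != list(range(1, len(ords) + 1)):
            raise ValidationError(
                f"chromosome {chrom}: ordinals must be 1..{len(ords)} with no gaps"
            )
    return recs


def genome_gene_ids(records: Iterable[GeneRecord]) -> frozenset[str]:
    return frozenset(r.gene_id for r in records)


def chromosome_sizes(records: Iterable[GeneRecord]) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for r in records:
        sizes[r.chromosome] = max(sizes.get(r.chromosome, 0), r.ordinal)
    return sizes


def setup_logging(verbose: bool = False) -> None:
    """Stage-tagged logging to stderr."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
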