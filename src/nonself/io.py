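"""Readers and writers for the pipeline's tabular formats.

All tables are tab-delimited with a header line; ``#`` comment lines are
ignored. Regions are additionally exported as BED on gene-ordinal
coordinates: a closed 1-based ordinal interval [start, end] becomes the
0-based half-open BED interval [start-1, end).
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    ExpressionRecord,
    FormatError,
    GeneRecord,
    GenomicRegion,
    ResponseSet,
    ValidationError,
    logger,
    validate_genome,
)

_GENE_COLUMNS = ["gene_id", "chromosome", "ordinal", "protein_length", "is_secreted", "categories"]
_EXPR_COLUMNS = ["gene_id", "log2fc", "p_value"]


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str},
                     float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    raise FormatError(f"cannot parse boolean value {v!r}")


def read_gene_table(path: str | Path, format: str = "tsv") -> list[GeneRecord]:
    """Read the gene table (TSV or GFF3) into validated, sorted records.

    TSV columns: gene_id, chromosome, ordinal, protein_length, is_secreted,
    categories (semicolon-separated labels, may be empty). In GFF3 mode,
    ordinals are assigned per chromosome by ascending start coordinate and
    annotations are taken from the attribute column.
    """
    if format == "gff3":
        return _read_gene_gff3(path)
    if format != "tsv":
        raise ValueError(f"unknown gene-table format {format!r}")
    df = _read_tsv(path, _GENE_COLUMNS[:4])
    records = []
    for row in df.itertuples(index=False):
        cats: frozenset[str] = frozenset()
        if "categories" in df.columns:
            raw = getattr(row, "categories")
            if isinstance(raw, str) and raw.strip():
                cats = frozenset(c.strip() for c in raw.split(";") if c.strip())
        secreted = False
        if "is_secreted" in df.columns:
            secreted = _parse_bool(getattr(row, "is_secreted"))
        records.append(
            GeneRecord(
                gene_id=str(row.gene_id),
                chromosome=str(row.chromosome),
                ordinal=int(row.ordinal),
                protein_length=int(row.protein_length),
                is_secreted=secreted,
                categories=cats,
            )
        )
    return validate_genome(records)


def _read_gene_gff3(path: str | Path) -> list[GeneRecord]:
    """Gene records from GFF3 ``gene`` features, ordinals by ascending start."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    per_chrom: dict[str, list] = {}
    for feat in db.features_of_type("gene"):
        per_chrom.setdefault(feat.seqid, []).append(feat)
    records = []
    for chrom, feats in per_chrom.items():
        feats.sort(key=lambda f: (f.start, f.id))
        for ordinal, f in enumerate(feats, start=1):
            attrs = f.attributes
            gene_id = (attrs.get("ID") or [f.id])[0]
            plen = int((attrs.get("protein_length") or [1])[0])
            secreted = _parse_bool((attrs.get("is_secreted") or ["false"])[0])
            raw_cats = (attrs.get("categories") or [""])[0]
            cats = frozenset(c.strip() for c in raw_cats.split(";") if c.strip())
            records.append(
                GeneRecord(gene_id=gene_id, chromosome=str(chrom), ordinal=ordinal,
                           protein_length=plen, is_secreted=secreted, categories=cats)
            )
    return validate_genome(records)


def write_gene_table(records: Iterable[GeneRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "chromosome": r.chromosome,
            "ordinal": r.ordinal,
            "protein_length": r.protein_length,
            "is_secreted": r.is_secreted,
            "categories": ";".join(sorted(r.categories)),
        }
        for r in sorted(records, key=lambda r: (r.chromosome, r.ordinal))
    ]
    pd.DataFrame(rows, columns=_GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_expression_table(path: str | Path, condition: str) -> list[ExpressionRecord]:
    """Read a per-condition DE table (gene_id, log2fc, p_value).

    Rejects non-numeric log2fc and out-of-range p-values with the offending
    line number, and duplicated gene ids by name.
    """
    df = _read_tsv(path, _EXPR_COLUMNS)
    records = []
    seen: set[str] = set()
    # +2: header line and 1-based numbering. Comment lines shift numbering,
    # so recover real line numbers only when no comments precede data.
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2
        gid = str(row.gene_id)
        if gid in seen:
            raise ValidationError(f"{path}: duplicated gene_id {gid!r}")
        seen.add(gid)
        try:
            lfc = float(row.log2fc)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path} line {line_no}: non-numeric log2fc {row.log2fc!r}"
            ) from None
        try:
            p = float(row.p_value)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path} line {line_no}: non-numeric p_value {row.p_value!r}"
            ) from None
        if not (0.0 <= p <= 1.0):
            raise ValidationError(
                f"{path} line {line_no}: p_value {p} outside [0, 1]"
            )
        records.append(ExpressionRecord(gene_id=gid, condition=condition,
                                        log2fc=lfc, p_value=p))
    return records


def write_expression_table(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    rows = [{"gene_id": r.gene_id, "log2fc": r.log2fc, "p_value": r.p_value}
            for r in records]
    pd.DataFrame(rows, columns=_EXPR_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_hit_counts(path: str | Path) -> dict[str, int]:
    """Gene id -> number of genus-level homolog hits (self included, so >= 1)."""
    df = _read_tsv(path, ["gene_id", "n_hits"])
    hits: dict[str, int] = {}
    for row in df.itertuples(index=False):
        gid = str(row.gene_id)
        if gid in hits:
            raise ValidationError(f"{path}: duplicated gene_id {gid!r}")
        n = int(row.n_hits)
        if n < 1:
            raise ValidationError(f"{path}: {gid} has n_hits {n} < 1")
        hits[gid] = n
    return hits


def write_hit_counts(hits: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(
        sorted(hits.items()), columns=["gene_id", "n_hits"]
    ).to_csv(path, sep="\t", index=False)


def read_id_list(path: str | Path) -> frozenset[str]:
    """One gene id per line (core-genome membership and similar lists)."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return frozenset(ids)


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(ids):
            fh.write(gid + "\n")


def read_similarity_table(path: str | Path) -> pd.DataFrame:
    """Directed similarity hits in BLAST outfmt-6-like TSV.

    Required columns: qseqid, sseqid, bitscore; evalue optional.
    """
    df = _read_tsv(path, ["qseqid", "sseqid", "bitscore"])
    if df.duplicated(["qseqid", "sseqid"]).any():
        raise ValidationError(f"{path}: duplicate (qseqid, sseqid) pair")
    if (df["bitscore"] < 0).any():
        raise ValidationError(f"{path}: negative bitscore")
    return df


def write_response_set(rs: ResponseSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# label={rs.label}\tdirection={rs.direction}\t"
                 f"min_abs_log2fc={rs.min_abs_log2fc}\tmax_p={rs.max_p}\n")
        fh.write("gene_id\n")
        for gid in sorted(rs.members):
            fh.write(gid + "\n")


def read_response_set(path: str | Path) -> ResponseSet:
    meta: dict[str, str] = {}
    members = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for part in line[1:].strip().split("\t"):
                    if "=" in part:
                        k, v = part.split("=", 1)
                        meta[k] = v
            elif line and line != "gene_id":
                members.append(line)
    try:
        return ResponseSet(
            label=meta["label"], direction=meta["direction"],
            min_abs_log2fc=float(meta["min_abs_log2fc"]),
            max_p=float(meta["max_p"]), members=frozenset(members),
        )
    except KeyError as e:
        raise FormatError(f"{path}: missing response-set metadata {e}") from None


def regions_to_bed(regions: Sequence[GenomicRegion]) -> str:
    """BED text on gene-ordinal coordinates (0-based half-open)."""
    lines = ["# gene-ordinal coordinates: 0-based half-open (ordinal i -> [i-1, i))"]
    for r in sorted(regions, key=lambda r: (r.chromosome, r.start)):
        name = r.label or r.kind
        if r.condition:
            name = f"{name}|{r.condition}"
        lines.append(f"{r.chromosome}\t{r.start - 1}\t{r.end}\t{name}")
    return "\n".join(lines) + "\n"


def write_regions(regions: Sequence[GenomicRegion], out_dir: str | Path,
                  stem: str) -> None:
    out_dir = Path(out_dir)
    (out_dir / f"{stem}.bed").write_text(regions_to_bed(regions))
    rows = [
        {"chromosome": r.chromosome, "start": r.start, "end": r.end,
         "kind": r.kind, "condition": r.condition or "", "label": r.label or ""}
        for r in sorted(regions, key=lambda r: (r.chromosome, r.start))
    ]
    pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "kind", "condition", "label"]
    ).to_csv(out_dir / f"{stem}.tsv", sep="\t", index=False)


def write_results(tables: dict[str, pd.DataFrame],
                  regions: dict[str, Sequence[GenomicRegion]],
                  out_dir: str | Path,
                  config: dict | None = None) -> list[Path]:
    """Write all result tables (TSV), region sets (BED + TSV) and a run log."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as e:
        raise OSError(f"output directory {out_dir} is not writable: {e}") from e

    written: list[Path] = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    for stem, regs in regions.items():
        write_regions(regs, out_dir, stem)
        written.extend([out_dir / f"{stem}.bed", out_dir / f"{stem}.tsv"])
    log = {
        "config": config or {},
        "python": platform.python_version(),
        "outputs": [p.name for p in written],
    }
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, default=str) + "\n")
    written.append(log_path)
    logger.info("wrote %d files to %s", len(written), out_dir)
    return written
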