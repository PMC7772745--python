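"""Core annotation join: candidate loci x feature database within a window.

Each candidate interval is expanded by a symmetric flank ``w`` (clipped at
position 1) and every database feature sharing at least one base with the
expanded interval, on the same normalized chromosome, becomes one output
row. A candidate with no overlapping feature contributes no rows but is
retained in the per-candidate summary with a hit count of zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import CandidateLocus, FeatureDatabase

logger = logging.getLogger("qtlannot")

__all__ = ["AnnotationQuery", "AnnotationResult", "annotate_loci", "brute_force_overlap"]

_GENE_COLS = ["gene_id", "gene_name", "biotype", "strand", "gene_start", "gene_end"]
_QTL_COLS = ["qtl_id", "trait_name", "qtl_class", "qtl_start", "qtl_end"]


@dataclass
class AnnotationQuery:
    """Annotation parameters: symmetric window in bp and the feature kind."""

    window_w: int
    feature_kind: str | None = None  # "genes" or "qtls"; inferred from the db if None

    def __post_init__(self) -> None:
        if self.window_w < 0:
            raise ValueError(f"window_w must be >= 0, got {self.window_w}")
        if self.feature_kind not in (None, "genes", "qtls"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")


@dataclass
class AnnotationResult:
    """Row-join of candidates x overlapping features, plus per-candidate counts.

    ``rows`` has one row per (candidate, feature) pair: the candidate's
    coordinate columns, all passthrough metadata columns, then the feature
    columns. ``summary`` has one row per input candidate including zero-hit
    candidates.
    """

    rows: pd.DataFrame
    summary: pd.DataFrame

    def __len__(self) -> int:
        return len(self.rows)


def _coord_columns(candidates: list[CandidateLocus]) -> list[str]:
    if candidates and all(c.is_marker for c in candidates):
        return ["CHR", "BP"]
    return ["CHR", "BP1", "BP2"]


def _candidate_fields(locus: CandidateLocus, coord_cols: list[str]) -> dict:
    if coord_cols == ["CHR", "BP"]:
        out = {"CHR": locus.chrom, "BP": locus.start_bp}
    else:
        out = {"CHR": locus.chrom, "BP1": locus.start_bp, "BP2": locus.end_bp}
    out.update(locus.meta)
    return out


def _feature_fields(rec, kind: str) -> dict:
    if kind == "genes":
        return {
            "gene_id": rec.gene_id,
            "gene_name": rec.gene_name,
            "biotype": rec.biotype,
            "strand": rec.strand,
            "gene_start": rec.start,
            "gene_end": rec.end,
        }
    return {
        "qtl_id": rec.qtl_id,
        "trait_name": rec.trait_name,
        "qtl_class": rec.qtl_class,
        "qtl_start": rec.start,
        "qtl_end": rec.end,
    }


def _assemble(
    candidates: list[CandidateLocus],
    hits_per_candidate: list[list],
    kind: str,
) -> AnnotationResult:
    coord_cols = _coord_columns(candidates)
    meta_cols: list[str] = []
    for c in candidates:
        for k in c.meta:
            if k not in meta_cols:
                meta_cols.append(k)
    feat_cols = _GENE_COLS if kind == "genes" else _QTL_COLS

    rows = []
    summary = []
    for locus, hits in zip(candidates, hits_per_candidate):
        cand = _candidate_fields(locus, coord_cols)
        summary.append({**{k: cand.get(k) for k in coord_cols}, "n_hits": len(hits)})
        for rec in sorted(hits, key=lambda r: (r.start, r.end)):
            rows.append({**cand, **_feature_fields(rec, kind)})
    columns = coord_cols + meta_cols + feat_cols
    rows_df = pd.DataFrame(rows, columns=columns)
    summary_df = pd.DataFrame(summary, columns=coord_cols + ["n_hits"])
    return AnnotationResult(rows=rows_df, summary=summary_df)


def _check_chromosomes(candidates, db) -> None:
    cand_chroms = {c.chrom for c in candidates}
    if db.chromosomes() and cand_chroms and not (cand_chroms & db.chromosomes()):
        logger.warning(
            "no shared chromosome labels between candidates (%s) and database (%s); "
            "result will be empty — check chromosome naming",
            sorted(cand_chroms)[:5],
            sorted(db.chromosomes())[:5],
        )


def _as_query(query: AnnotationQuery | int) -> AnnotationQuery:
    if isinstance(query, AnnotationQuery):
        return query
    return AnnotationQuery(window_w=int(query))


def annotate_loci(
    candidates: list[CandidateLocus],
    db: FeatureDatabase,
    query: AnnotationQuery | int,
) -> AnnotationResult:
    """Join candidates against the feature database within ``query.window_w``.

    A feature overlaps a candidate when ``feature.start <= candidate.end + w``
    and ``feature.end >= candidate.start - w`` (>= 1 shared base on closed
    intervals); the expanded interval is clipped at position 1. Candidate
    input order is preserved; features within a candidate are ordered by
    start position.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    query = _as_query(query)
    _check_chromosomes(candidates, db)
    w = query.window_w
    hits = [
        db.query(c.chrom, max(1, c.start_bp - w), c.end_bp + w) for c in candidates
    ]
    return _assemble(candidates, hits, db.kind)


def brute_force_overlap(
    candidates: list[CandidateLocus],
    db: FeatureDatabase,
    query: AnnotationQuery | int,
) -> AnnotationResult:
    """Reference implementation of :func:`annotate_loci` by exhaustive scan.

    O(candidates x features); identical output contract. Used as the test
    oracle for the indexed join.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    query = _as_query(query)
    _check_chromosomes(candidates, db)
    w = query.window_w
    hits_per_candidate = []
    for c in candidates:
        lo = max(1, c.start_bp - w)
        hi = c.end_bp + w
        hits_per_candidate.append(
            [r for r in db.records if r.chrom == c.chrom and r.start <= hi and r.end >= lo]
        )
    return _assemble(candidates, hits_per_candidate, db.kind)
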