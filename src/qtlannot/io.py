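"""Input/output layer: candidate tables, Ensembl-style GTF, Animal-QTLdb-style GFF.

Coordinates are 1-based inclusive everywhere, matching the GTF/GFF
convention; candidate BP values are interpreted on the same scale as
database coordinates. Chromosome labels are normalized (leading ``chr`` /
``Chr.`` prefixes stripped, numeric labels canonicalized) so that candidate
tables written with bare numbers join correctly against databases that
write ``Chr.5``.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from urllib.parse import unquote

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("qtlannot")

__all__ = [
    "CandidateLocus",
    "GeneRecord",
    "QTLRecord",
    "FeatureDatabase",
    "normalize_chrom",
    "import_gtf",
    "import_qtl_gff",
    "read_candidates",
    "write_table",
]


def normalize_chrom(label: object) -> str:
    """Normalize a chromosome label to a bare canonical string.

    Strips a leading ``chr`` / ``Chr`` / ``Chr.`` prefix (case-insensitive),
    canonicalizes numeric labels (``05`` -> ``5``) and upper-cases sex
    chromosomes and other non-numeric labels.
    """
    s = str(label).strip()
    low = s.lower()
    if low.startswith("chr."):
        s = s[4:]
    elif low.startswith("chr"):
        s = s[3:]
    s = s.strip()
    if s.isdigit():
        s = str(int(s))
    else:
        s = s.upper()
    return s


@dataclass
class CandidateLocus:
    """One query row: a marker (point) or an interval on a chromosome.

    ``meta`` carries every extra input column (study, trait, model, ...)
    unmodified, in input order; it is passed through to annotation output.
    """

    chrom: str
    start_bp: int
    end_bp: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("candidate locus has an empty chromosome label")
        if self.start_bp < 1:
            raise ValueError(f"start_bp must be >= 1, got {self.start_bp}")
        if self.end_bp < self.start_bp:
            raise ValueError(
                f"end_bp ({self.end_bp}) < start_bp ({self.start_bp}) on "
                f"chromosome {self.chrom}"
            )

    @property
    def is_marker(self) -> bool:
        return self.start_bp == self.end_bp


@dataclass
class GeneRecord:
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    gene_name: str = ""
    biotype: str = ""
    attrs: dict = field(default_factory=dict)


@dataclass
class QTLRecord:
    chrom: str
    start: int
    end: int
    qtl_id: str
    trait_name: str
    qtl_class: str
    attrs: dict = field(default_factory=dict)


class FeatureDatabase:
    """A collection of gene or QTL records with a per-chromosome interval index.

    The index maps the 1-based closed record interval [start, end] onto the
    half-open convention of :class:`intervaltree.IntervalTree` by storing
    ``(start, end + 1)``; queries do the symmetric conversion, so a query
    returns exactly the records sharing >= 1 bp with the query interval.
    """

    def __init__(self, records: list, kind: str, provenance: dict | None = None):
        if kind not in ("genes", "qtls"):
            raise ValueError(f"kind must be 'genes' or 'qtls', got {kind!r}")
        self.records = list(records)
        self.kind = kind
        self.provenance = provenance or {}
        self._index: dict[str, IntervalTree] = {}
        for i, rec in enumerate(self.records):
            tree = self._index.setdefault(rec.chrom, IntervalTree())
            tree.addi(rec.start, rec.end + 1, i)

    def __len__(self) -> int:
        return len(self.records)

    def chromosomes(self) -> set[str]:
        return set(self._index)

    def query(self, chrom: str, start: int, end: int) -> list:
        """Records on ``chrom`` overlapping the closed interval [start, end]."""
        tree = self._index.get(normalize_chrom(chrom))
        if tree is None:
            return []
        hits = tree.overlap(start, end + 1)
        idx = sorted(iv.data for iv in hits)
        return [self.records[i] for i in idx]

    def to_frame(self) -> pd.DataFrame:
        """Flat tabular view of the records (one row per record)."""
        if self.kind == "genes":
            cols = ["chrom", "start", "end", "strand", "gene_id", "gene_name", "biotype"]
        else:
            cols = ["chrom", "start", "end", "qtl_id", "trait_name", "qtl_class"]
        return pd.DataFrame(
            [{c: getattr(r, c) for c in cols} for r in self.records], columns=cols
        )


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attrs(text: str) -> dict:
    attrs = dict(_GTF_ATTR_RE.findall(text))
    if not attrs:
        # tolerate unquoted `key value;` pairs
        for chunk in text.strip().strip(";").split(";"):
            parts = chunk.strip().split(None, 1)
            if len(parts) == 2:
                attrs[parts[0]] = parts[1].strip('"')
    return attrs


def _parse_gff_attrs(text: str) -> dict:
    """Parse `key=value;key=value` attributes; values are percent-decoded once."""
    attrs = {}
    for chunk in text.strip().strip(";").split(";"):
        if "=" not in chunk:
            continue
        key, _, val = chunk.partition("=")
        attrs[key.strip()] = unquote(val.strip()).strip('"')
    return attrs


def _read_feature_lines(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature database file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _finalize(records, drops: Counter, kind: str, path, n_lines: int) -> FeatureDatabase:
    provenance = {
        "source": str(path),
        "data_lines": n_lines,
        "records_kept": len(records),
        "records_dropped": sum(drops.values()),
        "drop_reasons": dict(drops),
    }
    if drops:
        logger.warning(
            "%s: dropped %d of %d lines (%s)",
            path,
            sum(drops.values()),
            n_lines,
            dict(drops),
        )
    if n_lines > 0 and not records:
        # a file with data lines but nothing usable is an input error; a file
        # with no data lines at all is a legitimate empty database
        raise ValueError(f"no usable records parsed from {path}")
    return FeatureDatabase(records, kind=kind, provenance=provenance)


def import_gtf(path: str | Path, feature_type: str = "gene") -> FeatureDatabase:
    """Load gene records from a 9-column Ensembl-style GTF.

    Only lines whose feature-type column equals ``feature_type`` (default
    ``gene``) become records; comment lines are skipped; malformed lines are
    dropped with a logged warning and counted in the database provenance.
    """
    records: list[GeneRecord] = []
    drops: Counter = Counter()
    seen_ids: set[str] = set()
    n_lines = 0
    for lineno, line in _read_feature_lines(path):
        n_lines += 1
        fields = line.split("\t")
        if len(fields) != 9:
            drops["not_9_columns"] += 1
            continue
        seqid, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
        if ftype != feature_type:
            drops["other_feature_type"] += 1
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            drops["non_numeric_coordinates"] += 1
            continue
        if end < start or start < 1:
            drops["invalid_interval"] += 1
            continue
        attrs = _parse_gtf_attrs(attr_s)
        gene_id = attrs.get("gene_id", "")
        if not gene_id:
            drops["missing_gene_id"] += 1
            continue
        if gene_id in seen_ids:
            drops["duplicate_gene_id"] += 1
            continue
        seen_ids.add(gene_id)
        records.append(
            GeneRecord(
                chrom=normalize_chrom(seqid),
                start=start,
                end=end,
                strand=strand if strand in "+-" else "unknown",
                gene_id=gene_id,
                gene_name=attrs.get("gene_name", ""),
                biotype=attrs.get("gene_biotype", attrs.get("biotype", "")),
                attrs=attrs,
            )
        )
    return _finalize(records, drops, "genes", path, n_lines)


# feature-type column suffixes that encode a QTL class, e.g. `Milk_QTL`,
# `Reproduction_Association` -> classes "Milk", "Reproduction"
_CLASS_SUFFIXES = ("_QTL", "_Association", "_eQTL")


def _class_from_feature_type(ftype: str) -> str:
    for suf in _CLASS_SUFFIXES:
        if ftype.lower().endswith(suf.lower()):
            return ftype[: -len(suf)].replace("_", " ")
    return ""


def import_qtl_gff(path: str | Path, class_attr: str = "trait_type") -> FeatureDatabase:
    """Load QTL records from a GFF-style file in the Animal QTLdb dialect.

    The dialect writes ``Chr.N`` sequence ids, ``key=value;`` attributes with
    percent-encoded values, and encodes the QTL class either in the
    feature-type column (``Milk_QTL``) or in a ``trait_type`` attribute.
    Records without numeric coordinates are dropped (never imputed) and
    counted in the provenance.
    """
    records: list[QTLRecord] = []
    drops: Counter = Counter()
    n_lines = 0
    for lineno, line in _read_feature_lines(path):
        n_lines += 1
        fields = line.split("\t")
        if len(fields) != 9:
            drops["not_9_columns"] += 1
            continue
        seqid, _source, ftype, start_s, end_s, _score, _strand, _frame, attr_s = fields
        try:
            start, end = int(float(start_s)), int(float(end_s))
        except ValueError:
            drops["missing_coordinates"] += 1
            continue
        if end < start or start < 1:
            drops["invalid_interval"] += 1
            continue
        attrs = _parse_gff_attrs(attr_s)
        qtl_id = attrs.get("QTL_ID", attrs.get("ID", ""))
        if not qtl_id:
            drops["missing_qtl_id"] += 1
            continue
        trait_name = attrs.get("Name", "")
        if not trait_name:
            drops["missing_trait_name"] += 1
            continue
        qtl_class = _class_from_feature_type(ftype) or attrs.get(class_attr, "")
        if not qtl_class:
            drops["missing_qtl_class"] += 1
            continue
        records.append(
            QTLRecord(
                chrom=normalize_chrom(seqid),
                start=start,
                end=end,
                qtl_id=str(qtl_id),
                trait_name=trait_name,
                qtl_class=qtl_class,
                attrs=attrs,
            )
        )
    return _finalize(records, drops, "qtls", path, n_lines)


def read_candidates(path: str | Path) -> list[CandidateLocus]:
    """Read a candidate-locus table (delimited text with a header).

    Accepts either a marker schema (CHR, BP) or an interval schema
    (CHR, BP1, BP2), matched case-insensitively; when both are present the
    interval schema wins and BP is ignored with a logged warning. Every other
    column is carried through as metadata in input order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"candidate table not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python")
    colmap = {c.lower(): c for c in df.columns}
    if "chr" not in colmap:
        raise ValueError(
            f"{path}: no CHR column found; expected columns (CHR, BP) for "
            f"markers or (CHR, BP1, BP2) for intervals; got {list(df.columns)}"
        )
    chr_col = colmap["chr"]
    interval = "bp1" in colmap and "bp2" in colmap
    marker = "bp" in colmap
    if not interval and not marker:
        raise ValueError(
            f"{path}: expected columns (CHR, BP) for markers or "
            f"(CHR, BP1, BP2) for intervals; got {list(df.columns)}"
        )
    if interval and marker:
        logger.warning("%s: both BP and BP1/BP2 present; interval schema wins, BP ignored", path)
    used = {chr_col}
    if interval:
        used |= {colmap["bp1"], colmap["bp2"], colmap.get("bp", chr_col)}
    else:
        used |= {colmap["bp"]}
    meta_cols = [c for c in df.columns if c not in used]

    loci = []
    for i, row in df.iterrows():
        if interval:
            bp1, bp2 = int(row[colmap["bp1"]]), int(row[colmap["bp2"]])
            if bp2 < bp1:
                raise ValueError(
                    f"{path} row {i + 1}: BP2 ({bp2}) < BP1 ({bp1})"
                )
            start, end = bp1, bp2
        else:
            start = end = int(row[colmap["bp"]])
        loci.append(
            CandidateLocus(
                chrom=normalize_chrom(row[chr_col]),
                start_bp=start,
                end_bp=end,
                meta={c: row[c] for c in meta_cols},
            )
        )
    return loci


def write_table(
    rows: pd.DataFrame,
    path: str | Path,
    header_comments: list[str] | None = None,
) -> None:
    """Write a tabular result as tab-separated UTF-8 with a header row.

    Optional ``header_comments`` are emitted first as ``#``-prefixed lines
    (used by the CLI for run provenance). Numbers are serialized with
    ``repr`` precision so extreme p-values (1e-171) round-trip exactly.
    """
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            for line in header_comments or []:
                fh.write(f"# {line}\n")
            rows.to_csv(fh, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"cannot write table to {path}: {exc}") from exc


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table` (comments skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")
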