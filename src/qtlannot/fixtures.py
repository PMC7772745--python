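"""Deterministic synthetic genomes, gene/QTL databases and candidate tables.

The generator emulates the shape of the real inputs: an Ensembl-style GTF
of genes, an Animal-QTLdb-style GFF of QTL records with heterogeneous spans
(point QTLs through multi-megabase linkage blocks) carrying trait names and
coarse trait classes, and a delimited candidate table with a grouping
column. Trait labels are assigned at random from a catalog of relative
abundances; optionally one trait is planted at elevated density inside the
candidate windows so that enrichment recovery can be tested against known
truth. All randomness flows through one ``numpy.random.default_rng`` seeded
from the spec; the same seed yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from urllib.parse import quote

import numpy as np
import pandas as pd

from .io import CandidateLocus, FeatureDatabase, GeneRecord, QTLRecord

__all__ = [
    "FixtureSpec",
    "FixtureTruth",
    "DEFAULT_TRAIT_CATALOG",
    "simulate_records",
    "build_databases",
    "generate_fixture",
    "toy_worked_examples",
]

# (trait name, QTL class, relative abundance) — a small catalog in the style
# of a livestock QTL database, spanning the six coarse classes.
DEFAULT_TRAIT_CATALOG: tuple = (
    ("Milk yield", "Milk", 2.0),
    ("Milk protein percentage", "Milk", 1.5),
    ("Scrotal circumference", "Reproduction", 1.0),
    ("Calving ease", "Reproduction", 1.0),
    ("Marbling score", "Meat_and_Carcass", 1.0),
    ("Somatic cell count", "Health", 1.0),
    ("Average daily gain", "Production", 1.0),
    ("Stature", "Exterior", 0.5),
)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``planted_enrichment`` is an optional ``(trait_name, multiplier)`` pair:
    QTL records overlapping a candidate window receive that trait with its
    abundance scaled by ``multiplier`` (re-normalized), creating a known
    enrichment signal. ``window_w`` is the flank used both for planting and
    for the ground-truth hit lists.
    """

    seed: int = 0
    n_chrom: int = 3
    chrom_length: int = 5_000_000
    n_genes: int = 150
    n_qtls: int = 400
    trait_catalog: tuple = DEFAULT_TRAIT_CATALOG
    n_candidates: int = 25
    candidate_span: tuple = (10_000, 100_000)
    window_w: int = 50_000
    planted_enrichment: tuple | None = None  # (trait_name, density multiplier)
    group_labels: tuple = ("studyA", "studyB")

    def __post_init__(self) -> None:
        if self.n_chrom < 1 or self.chrom_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        for count in (self.n_genes, self.n_qtls, self.n_candidates):
            if count < 0:
                raise ValueError("counts must be >= 0")
        if any(ab <= 0 for _, _, ab in self.trait_catalog):
            raise ValueError("trait abundances must be > 0")
        if self.planted_enrichment is not None:
            trait, mult = self.planted_enrichment
            if mult < 1:
                raise ValueError("planted density multiplier must be >= 1")
            if trait not in {t for t, _, _ in self.trait_catalog}:
                raise ValueError(f"planted trait {trait!r} not in the trait catalog")
        if self.candidate_span[0] < 1 or self.candidate_span[1] > self.chrom_length:
            raise ValueError("candidate span must fit within the chromosome")
        if self.window_w < 0:
            raise ValueError("window_w must be >= 0")


@dataclass
class FixtureTruth:
    """Ground truth for one generated dataset.

    ``gene_hits`` / ``qtl_hits`` map candidate index (input order) to the
    sorted feature ids overlapping that candidate expanded by the spec's
    window. ``counts`` holds the per-(trait, chromosome) and genome-wide
    hypergeometric quadruples (k, K, n, N) under unique-record semantics.
    """

    gene_hits: dict = field(default_factory=dict)
    qtl_hits: dict = field(default_factory=dict)
    counts: pd.DataFrame = field(default_factory=pd.DataFrame)


def _draw_interval(rng, length: int, span: int) -> tuple[int, int]:
    span = min(span, length)
    start = int(rng.integers(1, length - span + 2))
    return start, start + span - 1


def _qtl_span(rng, length: int) -> int:
    # mixed spans: points, small intervals, large blocks
    u = rng.random()
    if u < 0.3:
        return 1
    if u < 0.8:
        return int(rng.integers(1_000, 100_001))
    return int(rng.integers(100_000, min(2_000_000, length) + 1))


def simulate_records(spec: FixtureSpec):
    """Generate candidates, genes and QTL records in memory.

    Returns ``(candidates, genes, qtls)`` lists of the domain types.
    """
    rng = np.random.default_rng(spec.seed)
    chroms = [str(c) for c in range(1, spec.n_chrom + 1)]
    L = spec.chrom_length

    candidates = []
    for i in range(spec.n_candidates):
        chrom = chroms[int(rng.integers(len(chroms)))]
        span = int(rng.integers(spec.candidate_span[0], spec.candidate_span[1] + 1))
        start, end = _draw_interval(rng, L, span)
        group = spec.group_labels[i % len(spec.group_labels)] if spec.group_labels else None
        meta = {"study": group} if group else {}
        candidates.append(CandidateLocus(chrom=chrom, start_bp=start, end_bp=end, meta=meta))

    genes = []
    for i in range(spec.n_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        span = int(rng.integers(2_000, 200_001))
        start, end = _draw_interval(rng, L, span)
        genes.append(
            GeneRecord(
                chrom=chrom,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                gene_id=f"SYNG{i + 1:06d}",
                gene_name=f"GENE{i + 1}",
                biotype="protein_coding",
            )
        )

    # candidate windows per chromosome, for planted-density trait assignment
    windows: dict[str, list[tuple[int, int]]] = {}
    for c in candidates:
        windows.setdefault(c.chrom, []).append(
            (max(1, c.start_bp - spec.window_w), c.end_bp + spec.window_w)
        )

    names = [t for t, _, _ in spec.trait_catalog]
    classes = {t: cl for t, cl, _ in spec.trait_catalog}
    base = np.array([ab for _, _, ab in spec.trait_catalog], dtype=float)
    base /= base.sum()
    if spec.planted_enrichment is not None:
        trait, mult = spec.planted_enrichment
        boosted = base.copy()
        boosted[names.index(trait)] *= mult
        boosted /= boosted.sum()
    else:
        boosted = base

    qtls = []
    for i in range(spec.n_qtls):
        chrom = chroms[int(rng.integers(len(chroms)))]
        span = _qtl_span(rng, L)
        start, end = _draw_interval(rng, L, span)
        inside = any(start <= hi and end >= lo for lo, hi in windows.get(chrom, []))
        probs = boosted if inside else base
        trait = names[int(rng.choice(len(names), p=probs))]
        qtls.append(
            QTLRecord(
                chrom=chrom,
                start=start,
                end=end,
                qtl_id=str(100_000 + i),
                trait_name=trait,
                qtl_class=classes[trait].replace("_", " "),
            )
        )
    return candidates, genes, qtls


def build_databases(genes, qtls):
    """Index the generated records as in-memory feature databases."""
    gene_db = FeatureDatabase(genes, kind="genes") if genes else None
    qtl_db = FeatureDatabase(qtls, kind="qtls") if qtls else None
    return gene_db, qtl_db


def _truth(spec: FixtureSpec, candidates, genes, qtls) -> FixtureTruth:
    w = spec.window_w
    gene_hits, qtl_hits = {}, {}
    for i, c in enumerate(candidates):
        lo, hi = max(1, c.start_bp - w), c.end_bp + w
        gene_hits[i] = sorted(
            g.gene_id for g in genes if g.chrom == c.chrom and g.start <= hi and g.end >= lo
        )
        qtl_hits[i] = sorted(
            q.qtl_id for q in qtls if q.chrom == c.chrom and q.start <= hi and q.end >= lo
        )

    annotated = {qid for ids in qtl_hits.values() for qid in ids}
    by_id = {q.qtl_id: q for q in qtls}
    rows = []
    scopes = [("genome", None)] + [(c, c) for c in sorted({q.chrom for q in qtls})]
    for label, chrom in scopes:
        in_scope = [q for q in qtls if chrom is None or q.chrom == chrom]
        ann_scope = [by_id[i] for i in annotated if chrom is None or by_id[i].chrom == chrom]
        n, N = len(ann_scope), len(in_scope)
        for trait in sorted({q.trait_name for q in ann_scope}):
            k = sum(q.trait_name == trait for q in ann_scope)
            K = sum(q.trait_name == trait for q in in_scope)
            rows.append({"trait": trait, "chrom": label, "k": k, "K": K, "n": n, "N": N})
    return FixtureTruth(
        gene_hits=gene_hits,
        qtl_hits=qtl_hits,
        counts=pd.DataFrame(rows, columns=["trait", "chrom", "k", "K", "n", "N"]),
    )


def _write_gtf(genes, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("#!genome synthetic\n")
        for g in genes:
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                f'gene_biotype "{g.biotype}";'
            )
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def _write_qtl_gff(qtls, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("##gff-version 2.5\n")
        for q in qtls:
            ftype = q.qtl_class.replace(" ", "_") + "_QTL"
            attrs = f"QTL_ID={q.qtl_id};Name={quote(q.trait_name)};trait_ID={q.qtl_id}"
            fh.write(f"Chr.{q.chrom}\tsynthetic\t{ftype}\t{q.start}\t{q.end}\t.\t.\t.\t{attrs}\n")


def _write_candidates(candidates, path: Path) -> None:
    rows = []
    for c in candidates:
        rows.append({"CHR": c.chrom, "BP1": c.start_bp, "BP2": c.end_bp, **c.meta})
    pd.DataFrame(rows).to_csv(path, index=False)


def generate_fixture(spec: FixtureSpec, outdir: str | Path) -> FixtureTruth:
    """Write ``candidates.csv``, ``genes.gtf``, ``qtls.gff`` and truth tables.

    The same spec (including seed) yields byte-identical files. The returned
    truth is also written as ``truth_counts.tsv`` and ``truth_hits.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    candidates, genes, qtls = simulate_records(spec)
    _write_candidates(candidates, outdir / "candidates.csv")
    _write_gtf(genes, outdir / "genes.gtf")
    _write_qtl_gff(qtls, outdir / "qtls.gff")
    truth = _truth(spec, candidates, genes, qtls)
    truth.counts.to_csv(outdir / "truth_counts.tsv", sep="\t", index=False)
    hits = pd.DataFrame(
        [
            {
                "candidate": i,
                "gene_ids": ",".join(truth.gene_hits[i]),
                "qtl_ids": ",".join(truth.qtl_hits[i]),
            }
            for i in range(len(candidates))
        ]
    )
    hits.to_csv(outdir / "truth_hits.tsv", sep="\t", index=False)
    return truth


def toy_worked_examples() -> dict[str, Path]:
    """Paths to the bundled micro-fixtures.

    * ``candidates`` + ``genes``: three candidate regions each overlapping
      exactly four genes, so the annotation join yields 12 rows.
    * ``ab_overlap``: a two-group table where group A holds 10 unique IDs,
      group B holds 5, and 5 are shared (the 50% / 100% asymmetry case).
    * ``enrichment_counts``: per-(trait, chromosome) hypergeometric count
      quadruples in the shape produced by the enrichment step.
    """
    base = resources.files("qtlannot").joinpath("data")
    return {
        "candidates": Path(str(base.joinpath("three_regions_candidates.csv"))),
        "genes": Path(str(base.joinpath("twelve_genes.gtf"))),
        "ab_overlap": Path(str(base.joinpath("ab_overlap.tsv"))),
        "enrichment_counts": Path(str(base.joinpath("enrichment_counts.tsv"))),
    }
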