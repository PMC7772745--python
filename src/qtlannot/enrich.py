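"""QTL enrichment: upper-tail hypergeometric tests per trait or class.

The model: within a scope (the whole genome or one chromosome) the database
holds N QTL records of which K belong to a given trait; the annotation step
"draws" n of those records into the candidate regions, of which k belong to
the trait. Under the null of no association between trait labels and
candidate regions, k follows a hypergeometric distribution and the
enrichment p-value is the upper tail P(X >= k).

The tail is summed in log space (log-gamma terms combined with logsumexp):
the strongest enrichments in real QTL databases reach p ~ 1e-171, far below
the underflow point of naive floating-point products.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .annotate import AnnotationResult
from .io import FeatureDatabase

logger = logging.getLogger("qtlannot")

__all__ = [
    "hypergeom_upper_tail",
    "adjust_pvalues",
    "qtl_enrich",
    "enrichment_bubble_data",
    "permutation_pvalue",
    "ENRICH_COLUMNS",
]

ENRICH_COLUMNS = [
    "QTL",
    "CHR",
    "N_QTLs",
    "N_QTLs_db",
    "Total_annotated_QTLs",
    "Total_QTLs_db",
    "pvalue",
    "adj.pval",
    "QTL_type",
    "richness",
]


def _log_pmf(i: np.ndarray, K: int, n: int, N: int) -> np.ndarray:
    # log C(K,i) + log C(N-K, n-i) - log C(N, n)
    return (
        gammaln(K + 1)
        - gammaln(i + 1)
        - gammaln(K - i + 1)
        + gammaln(N - K + 1)
        - gammaln(n - i + 1)
        - gammaln(N - K - (n - i) + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


# population size up to which the tail is summed in exact integer arithmetic;
# beyond it the log-gamma path keeps the cost bounded
_EXACT_LIMIT = 100_000


def hypergeom_pmf(k: int, K: int, n: int, N: int) -> float:
    """Exact point mass P(X = k), correctly rounded to double precision."""
    from fractions import Fraction
    from math import comb

    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= k <= K <= N and 0 <= n <= N and k <= n):
        raise ValueError(
            f"invalid hypergeometric parameters (k={k}, K={K}, n={n}, N={N})"
        )
    if n - k > N - K:
        return 0.0
    return float(Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n)))


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(population N, successes K, draws n).

    For populations up to 100,000 the tail is a ratio of exact big-integer
    binomial sums, converted to a correctly rounded double at the very end,
    so values far below 1e-300 remain representable down to the smallest
    subnormal double. Larger populations fall back to a log-space sum of
    log-gamma point masses combined with logsumexp, which never underflows
    above ~1e-308 scale either.
    """
    from fractions import Fraction
    from math import comb

    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= k <= K <= N and 0 <= n <= N and k <= n):
        raise ValueError(
            f"invalid hypergeometric parameters (k={k}, K={K}, n={n}, N={N}): "
            "require 0 <= k <= K <= N, 0 <= n <= N, k <= n"
        )
    support_lo = max(0, n + K - N)
    if k <= support_lo:
        return 1.0
    hi = min(K, n)
    if N <= _EXACT_LIMIT:
        numer = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, hi + 1))
        return float(Fraction(numer, comb(N, n)))
    i = np.arange(k, hi + 1)
    return float(np.exp(logsumexp(_log_pmf(i, K, n, N))))


def permutation_pvalue(
    k: int, K: int, n: int, N: int, n_perm: int = 10_000, rng=None
) -> float:
    """Monte-Carlo cross-check of :func:`hypergeom_upper_tail`.

    Permutes trait labels by drawing from the same null (n draws without
    replacement from N with K successes) and reports the add-one estimate
    (1 + #{X >= k}) / (1 + n_perm). Offered as a sanity check; the analytic
    tail is the default and is exact.
    """
    rng = np.random.default_rng(rng)
    draws = rng.hypergeometric(K, N - K, n, size=n_perm)
    return (1 + int((draws >= k).sum())) / (1 + n_perm)


_PADJ_METHODS = {"BH": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm"}


def adjust_pvalues(pvalues, method: str = "BH") -> list[float]:
    """Multiple-testing adjustment (BH / bonferroni / holm / none).

    Output order matches input order; adjusted values are capped at 1.
    """
    pvals = np.asarray(list(pvalues), dtype=float)
    if pvals.size and ((pvals < 0).any() or (pvals > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none" or pvals.size == 0:
        return pvals.tolist()
    if method not in _PADJ_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_PADJ_METHODS)} or 'none'")
    return multipletests(pvals, method=_PADJ_METHODS[method])[1].tolist()


def _annotation_frame(annotation) -> pd.DataFrame:
    if isinstance(annotation, AnnotationResult):
        return annotation.rows
    return annotation


def qtl_enrich(
    annotation,
    db: FeatureDatabase,
    enrich_type: str = "genome",
    by: str = "trait",
    chr_subset: list | None = None,
    padj_method: str = "BH",
) -> pd.DataFrame:
    """Hypergeometric QTL enrichment per trait or QTL class.

    Parameters
    ----------
    annotation
        An :class:`AnnotationResult` from the QTL join, or an equivalent
        DataFrame with columns ``CHR``, ``qtl_id``, ``trait_name``,
        ``qtl_class``.
    db
        The QTL database the annotation was made against; supplies the
        background counts K and N.
    enrich_type
        ``"genome"``: one test per trait over the whole database.
        ``"chromosome"``: one test per (trait, chromosome), with all four
        counts restricted to that chromosome.
    by
        Group records by ``"trait"`` (trait_name) or ``"class"`` (qtl_class).
    chr_subset
        Optional chromosome labels restricting which chromosomes are tested
        (chromosome scope only).
    padj_method
        Correction applied over exactly the emitted tests.

    Records are deduplicated by ``qtl_id`` within each scope before counting
    (several markers hitting one record count it once); traits with k = 0 in
    scope are not tested. Rows are sorted by ascending p-value, ties broken
    by trait name.
    """
    if enrich_type not in ("genome", "chromosome"):
        raise ValueError(f"enrich_type must be 'genome' or 'chromosome', got {enrich_type!r}")
    if by not in ("trait", "class"):
        raise ValueError(f"by must be 'trait' or 'class', got {by!r}")
    key = "trait_name" if by == "trait" else "qtl_class"

    ann = _annotation_frame(annotation)
    empty = pd.DataFrame(columns=ENRICH_COLUMNS)
    empty.attrs["n_tests"] = 0
    if ann.empty:
        logger.warning("empty annotation: no enrichment tests emitted")
        return empty
    for col in ("CHR", "qtl_id", "trait_name", "qtl_class"):
        if col not in ann.columns:
            raise KeyError(f"annotation lacks required column {col!r}")

    dbf = db.to_frame()
    if enrich_type == "genome":
        if chr_subset is not None:
            logger.warning("chr_subset is ignored for genome-wide enrichment")
        scopes = [("genome", ann, dbf)]
    else:
        chroms = sorted(ann["CHR"].astype(str).unique())
        if chr_subset is not None:
            from .io import normalize_chrom

            wanted = {normalize_chrom(c) for c in chr_subset}
            chroms = [c for c in chroms if c in wanted]
        scopes = [
            (c, ann[ann["CHR"].astype(str) == c], dbf[dbf["chrom"].astype(str) == c])
            for c in chroms
        ]

    out_rows = []
    for scope_label, ann_s, db_s in scopes:
        ann_u = ann_s.drop_duplicates(subset="qtl_id")
        db_u = db_s.drop_duplicates(subset="qtl_id")
        n = len(ann_u)
        N = len(db_u)
        db_counts = db_u.groupby(key).size()
        for group, sub in ann_u.groupby(key, sort=True):
            k = len(sub)
            K = int(db_counts.get(group, 0))
            if K == 0:
                raise ValueError(
                    f"annotated {by} {group!r} has no records in the database "
                    f"within scope {scope_label!r}: annotation/database mismatch"
                )
            if k > K:
                raise ValueError(
                    f"{by} {group!r} in scope {scope_label!r}: annotated count "
                    f"k={k} exceeds database count K={K} after deduplication; "
                    "the annotation was not made against this database"
                )
            if by == "trait":
                qtl_type = db_u.loc[db_u[key] == group, "qtl_class"].mode().iloc[0]
            else:
                qtl_type = group
            out_rows.append(
                {
                    "QTL": group,
                    "CHR": scope_label,
                    "N_QTLs": k,
                    "N_QTLs_db": K,
                    "Total_annotated_QTLs": n,
                    "Total_QTLs_db": N,
                    "pvalue": hypergeom_upper_tail(k, K, n, N),
                    "QTL_type": qtl_type,
                    "richness": k / K,
                }
            )

    res = pd.DataFrame(out_rows)
    res["adj.pval"] = adjust_pvalues(res["pvalue"], method=padj_method)
    res = res.sort_values(["pvalue", "QTL"], kind="mergesort").reset_index(drop=True)
    res = res[ENRICH_COLUMNS]
    res.attrs["n_tests"] = len(res)
    res.attrs["padj_method"] = padj_method
    return res


def enrich_from_counts(counts: pd.DataFrame, padj_method: str = "BH") -> pd.DataFrame:
    """Run the hypergeometric test on precomputed count quadruples.

    ``counts`` needs columns ``QTL``, ``CHR``, ``N_QTLs`` (k), ``N_QTLs_db``
    (K), ``Total_annotated_QTLs`` (n), ``Total_QTLs_db`` (N) and optionally
    ``QTL_type``. Useful when the counting was done elsewhere and only the
    test is needed.
    """
    req = ["QTL", "CHR", "N_QTLs", "N_QTLs_db", "Total_annotated_QTLs", "Total_QTLs_db"]
    for col in req:
        if col not in counts.columns:
            raise KeyError(f"counts table lacks required column {col!r}")
    res = counts.copy()
    res["pvalue"] = [
        hypergeom_upper_tail(r.N_QTLs, r.N_QTLs_db, r.Total_annotated_QTLs, r.Total_QTLs_db)
        for r in res.itertuples()
    ]
    res["adj.pval"] = adjust_pvalues(res["pvalue"], method=padj_method)
    if "QTL_type" not in res.columns:
        res["QTL_type"] = ""
    res["richness"] = res["N_QTLs"] / res["N_QTLs_db"]
    res = res.sort_values(["pvalue", "QTL"], kind="mergesort").reset_index(drop=True)
    res = res[ENRICH_COLUMNS]
    res.attrs["n_tests"] = len(res)
    res.attrs["padj_method"] = padj_method
    return res


def enrichment_bubble_data(
    rows: pd.DataFrame, top: int = 10, p_col: str = "pvalue"
) -> pd.DataFrame:
    """Plot-ready table for the enrichment bubble plot.

    Keeps the ``top`` rows by ascending ``p_col``; x is the richness factor
    k/K, bubble size is the annotated count k, and color is -log10 p so
    darker bubbles are more significant.
    """
    if rows.empty:
        raise ValueError("enrichment table is empty")
    if top < 1:
        raise ValueError(f"top must be >= 1, got {top}")
    if p_col not in ("pvalue", "adj.pval"):
        raise ValueError(f"p_col must be 'pvalue' or 'adj.pval', got {p_col!r}")
    if top > len(rows):
        logger.warning("top=%d exceeds %d available rows; using all rows", top, len(rows))
        top = len(rows)
    sel = rows.sort_values([p_col, "QTL"], kind="mergesort").head(top)
    labels = [
        q if c == "genome" else f"{q} (CHR {c})" for q, c in zip(sel["QTL"], sel["CHR"])
    ]
    with np.errstate(divide="ignore"):
        color = -np.log10(sel[p_col].to_numpy(dtype=float))
    return pd.DataFrame(
        {
            "label": labels,
            "richness": sel["richness"].to_numpy(),
            "size": sel["N_QTLs"].to_numpy(),
            "neg_log10_p": color,
        }
    )
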