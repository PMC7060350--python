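"""Massively parallel reporter assay: allele-specific activity calling.

Variant-bearing 150 bp constructs drive a barcoded reporter; DNA (input)
and RNA (output) barcode counts per tag measure per-allele activity.  The
analysis path is: count tags from reads, filter low-coverage tags
(DNA >= 30, RNA >= 4), compute log(RNA/DNA) expression, median-center,
normalize per-%GC means to zero, exclude tags carrying blackballed 5-mers
(sequence artifacts whose mean expression deviates by more than 0.15),
re-center, and test allele A vs allele B tags with a two-sided pooled
Student's t-test.  A variant is an allelic hit when at least two replicates
reach BH FDR < 0.1 and the direction agrees across all tested replicates.

Lentiviral (L-MPRA) and transfection (T-MPRA) deliveries share this code
path and differ only in the tables fed in.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "count_tags",
    "normalize_expression",
    "blackball_5mers",
    "tag_expression",
    "test_allelic_activity",
    "call_mpra_hits",
    "analyze_mpra",
]

MIN_DNA_READS = 30
MIN_RNA_READS = 4
BLACKBALL_THRESHOLD = 0.15
MIN_GOOD_TAGS = 80
HIT_FDR = 0.1


def _hamming(a: str, b: str) -> int:
    return sum(c1 != c2 for c1, c2 in zip(a, b))


def count_tags(
    reads: Iterable[str],
    tag_map: Mapping[str, tuple] | pd.DataFrame,
    constant_region: str,
    *,
    tag_length: int = 20,
    max_constant_mismatches: int = 4,
) -> pd.Series:
    """Count sequencing reads per known tag.

    A read is structured as the constant region followed by the tag.  It is
    counted iff the constant region matches with Hamming distance at most
    ``max_constant_mismatches`` and the tag region matches a known tag
    exactly.  Duplicate tags in the map are an error.
    """
    if isinstance(tag_map, pd.DataFrame):
        tags = list(tag_map["tag"])
    else:
        tags = list(tag_map)
    if len(tags) != len(set(tags)):
        raise ValueError("tag map contains duplicate tag sequences")
    counts = dict.fromkeys(tags, 0)
    k = len(constant_region)
    for read in reads:
        if _hamming(read[:k], constant_region) > max_constant_mismatches:
            continue
        tag = read[k:k + tag_length]
        if tag in counts:
            counts[tag] += 1
    return pd.Series(counts, name="count")


def normalize_expression(
    table: pd.DataFrame,
    rna_col: str,
    *,
    min_dna: int = MIN_DNA_READS,
    min_rna: int = MIN_RNA_READS,
    orientation: str = "rna_over_dna",
    gc_col: str = "gc",
) -> pd.DataFrame:
    """Filtered, median-centered, GC-normalized per-tag expression.

    Expression is the natural log of RNA/DNA from raw counts ("dna_over_rna"
    flips the sign), computed only for tags passing the coverage filters
    (DNA >= ``min_dna``, RNA >= ``min_rna``).  The global median is
    subtracted, then the mean within every integer %GC bin is subtracted, so
    after the step the median (pre-GC) and every per-%GC mean are zero.

    Returns a copy of ``table`` with ``expression`` (NaN for excluded tags),
    ``kept`` and ``reason`` columns.
    """
    out = table.copy()
    dna = out["dna"].to_numpy(dtype=float)
    rna = out[rna_col].to_numpy(dtype=float)
    kept = (dna >= min_dna) & (rna >= min_rna)
    if not kept.any():
        raise ValueError("no tags pass the DNA/RNA coverage filters")
    reason = np.where(dna < min_dna, "low_dna",
                      np.where(rna < min_rna, "low_rna", ""))
    expr = np.full(len(out), np.nan)
    with np.errstate(divide="ignore"):
        ratio = np.log(rna[kept] / dna[kept])
    if orientation == "dna_over_rna":
        ratio = -ratio
    elif orientation != "rna_over_dna":
        raise ValueError("orientation must be 'rna_over_dna' or 'dna_over_rna'")
    ratio = ratio - np.median(ratio)
    gc = np.rint(out.loc[kept, gc_col].to_numpy(dtype=float)).astype(int)
    centered = pd.Series(ratio).groupby(gc).transform(lambda x: x - x.mean())
    expr[kept] = centered.to_numpy()
    out["expression"] = expr
    out["kept"] = kept
    out["reason"] = reason
    return out


def blackball_5mers(
    tags: Sequence[str],
    expression: Sequence[float],
    *,
    threshold: float = BLACKBALL_THRESHOLD,
) -> tuple[set[str], np.ndarray]:
    """Detect artifact 5-mers and flag the tags that contain them.

    A 5-mer is blackballed when the absolute mean expression over all tags
    containing it (forward strand substring match) exceeds ``threshold``.
    Returns the blackballed set and a boolean mask of contaminated tags.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    per_tag_kmers = []
    for tag, e in zip(tags, expression):
        kmers = {tag[i:i + 5] for i in range(len(tag) - 4)}
        per_tag_kmers.append(kmers)
        if np.isnan(e):
            continue
        for k in kmers:
            sums[k] = sums.get(k, 0.0) + e
            counts[k] = counts.get(k, 0) + 1
    bad = {k for k in sums if abs(sums[k] / counts[k]) > threshold}
    mask = np.array([bool(kmers & bad) for kmers in per_tag_kmers])
    return bad, mask


def tag_expression(
    table: pd.DataFrame,
    rna_col: str,
    *,
    blackballed: set[str] | None = None,
    **norm_kwargs,
) -> tuple[pd.DataFrame, set[str]]:
    """Full per-replicate tag expression path.

    Order: coverage filter -> log ratio -> median center -> GC normalize ->
    blackball -> re-center.  If ``blackballed`` is given (e.g. the union
    across replicates) it is applied instead of being re-detected.
    Returns the annotated table and the blackball set used.
    """
    out = normalize_expression(table, rna_col, **norm_kwargs)
    if blackballed is None:
        blackballed, _ = blackball_5mers(out["tag"], out["expression"])
    if blackballed:
        contaminated = out["tag"].map(
            lambda t: any(b in t for b in blackballed)
        ).to_numpy()
        drop = contaminated & out["kept"].to_numpy()
        out.loc[drop, "kept"] = False
        out.loc[drop, "reason"] = "blackballed"
        out.loc[drop, "expression"] = np.nan
        kept = out["kept"].to_numpy()
        out.loc[kept, "expression"] -= out.loc[kept, "expression"].median()
    return out, blackballed


def test_allelic_activity(
    expr_a: Sequence[float],
    expr_b: Sequence[float],
) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t-test between allele tag sets.

    Returns ``(t, p)`` with ``df = nA + nB - 2``.  Degenerate zero-variance
    input with equal means gives ``(0.0, 1.0)``.
    """
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 tags per allele to test")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def call_mpra_hits(
    results: pd.DataFrame,
    *,
    fdr: float = HIT_FDR,
    min_significant_replicates: int = 2,
) -> pd.DataFrame:
    """Combine per-replicate allelic tests into variant hit flags.

    ``results`` is long-form with columns ``variant``, ``replicate``, ``t``,
    ``p`` and ``tested``.  BH FDR is computed per replicate across tested
    variants.  A variant is a hit iff it reaches FDR < ``fdr`` in at least
    ``min_significant_replicates`` replicates and the sign of ``t`` agrees
    across all replicates in which it was tested.
    """
    res = results[results["tested"]].copy()
    if res.empty:
        return pd.DataFrame(columns=["variant", "n_tested", "n_significant",
                                     "consistent", "hit"])
    res["fdr"] = np.nan
    for rep, idx in res.groupby("replicate").groups.items():
        res.loc[idx, "fdr"] = multipletests(res.loc[idx, "p"], method="fdr_bh")[1]
    rows = []
    for variant, sub in res.groupby("variant", sort=True):
        n_sig = int((sub["fdr"] < fdr).sum())
        signs = np.sign(sub["t"].to_numpy())
        consistent = bool(len(set(signs[signs != 0])) <= 1 and not np.any(signs == 0))
        n_tested = len(sub)
        hit = (n_tested >= 2 and n_sig >= min_significant_replicates and consistent)
        rows.append((variant, n_tested, n_sig, consistent, hit))
    return pd.DataFrame(rows, columns=["variant", "n_tested", "n_significant",
                                       "consistent", "hit"])


def analyze_mpra(
    table: pd.DataFrame,
    rna_cols: Sequence[str] | None = None,
    *,
    ref_allele: str = "ref",
    min_good_tags: int = MIN_GOOD_TAGS,
    fdr: float = HIT_FDR,
    **norm_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end MPRA allelic analysis for one delivery mode.

    ``table`` needs columns ``tag``, ``variant``, ``allele``, ``gc``,
    ``dna`` and one count column per RNA replicate (default: all columns
    starting with ``rna``).  Blackballed 5-mers are detected per replicate
    and unioned (artifacts are sequence-intrinsic), then each replicate is
    re-normalized under the union.  Each non-reference allele is tested
    against the reference; variants need at least ``min_good_tags`` good
    tags across the two alleles and two tags per allele in a replicate to be
    tested there.

    Returns ``(variant_results, replicate_tests)`` where the first holds the
    combined hit calls and the second the long-form per-replicate tests.
    """
    if rna_cols is None:
        rna_cols = [c for c in table.columns if c.startswith("rna")]
    if len(rna_cols) < 2:
        raise ValueError("need >= 2 RNA replicates")
    first_pass = [tag_expression(table, c, **norm_kwargs) for c in rna_cols]
    union: set[str] = set()
    for _, bset in first_pass:
        union |= bset
    normed = [tag_expression(table, c, blackballed=union, **norm_kwargs)[0]
              for c in rna_cols]

    rows = []
    variants = sorted(table["variant"].unique())
    for rep, (col, df) in enumerate(zip(rna_cols, normed), start=1):
        good = df[df["kept"]]
        for variant in variants:
            sub = good[good["variant"] == variant]
            alleles = sorted(sub["allele"].unique())
            if ref_allele not in alleles:
                rows.append((variant, rep, None, np.nan, np.nan, False))
                continue
            others = [a for a in alleles if a != ref_allele]
            ref_expr = sub.loc[sub["allele"] == ref_allele, "expression"].to_numpy()
            for alt in others:
                alt_expr = sub.loc[sub["allele"] == alt, "expression"].to_numpy()
                tested = (len(ref_expr) + len(alt_expr) >= min_good_tags
                          and len(ref_expr) >= 2 and len(alt_expr) >= 2)
                if tested:
                    t, p = test_allelic_activity(alt_expr, ref_expr)
                else:
                    t, p = np.nan, np.nan
                rows.append((variant, rep, alt, t, p, tested))
    tests = pd.DataFrame(rows, columns=["variant", "replicate", "allele",
                                        "t", "p", "tested"])
    calls = call_mpra_hits(tests, fdr=fdr)
    # variants never tested anywhere are reported untestable, not misses
    tested_variants = set(calls["variant"])
    extra = [(v, 0, 0, False, False) for v in variants if v not in tested_variants]
    if extra:
        calls = pd.concat(
            [calls, pd.DataFrame(extra, columns=calls.columns)], ignore_index=True
        ).sort_values("variant", ignore_index=True)
    return calls, tests
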