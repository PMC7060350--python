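"""Enrichment of assay hits for GWAS signal, and variant prioritization.

For each assay we summarize its per-SNP binary hit track against the tag
SNPs (or fine-mapping credible sets) of the locus:

- ``n_H``  -- assayed SNPs called hits;
- ``n_T``  -- recoverable tag SNPs: tags with at least one assayed SNP in
  their tight-LD set (tags whose whole LD set went unassayed are excluded
  so the assay is not penalized for technical failures);
- ``n_TH`` -- recovered tag SNPs: tags whose LD set contains a hit.

Pseudo-precision is ``n_TH / n_H`` (can exceed 1: one causal SNP may tag
several associations) and pseudo-recall ``n_TH / n_T``.  Significance comes
from empirical nulls: the genomic-shift null circularly rotates the hit
vector along the assayed SNPs (preserving hit clustering) and uses every
one of the n-1 possible rotations; the permutation null shuffles hit labels.
The empirical p is the fraction of null draws with both pseudo-precision
and pseudo-recall at least as high as observed, which reduces to an
``n_TH`` exceedance because ``n_H`` and ``n_T`` are invariant under both
randomizations.  Fold enrichment compares the observed pseudo-precision to
the null mean, with a quantile-ratio 95% CI whose upper bound is infinite
when the 2.5th null percentile is zero.

High-priority variants are those hit by CRISPRi, or hit by T-MPRA while
lying in accessible chromatin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HitTrack",
    "EnrichmentResult",
    "enrichment_counts",
    "pseudo_precision_recall",
    "shift_null",
    "permutation_null",
    "evaluate_track",
    "fold_enrichment",
    "restrict_accessible",
    "prioritize_variants",
    "haplotype_summary",
    "interval_track",
    "hichip_track",
    "atac_similarity",
    "load_prioritized_variants",
    "HICHIP_SCORE_THRESHOLD",
]

HICHIP_SCORE_THRESHOLD = 20.0


@dataclass
class HitTrack:
    """Binary per-SNP hit status for one assay, aligned to the variant table.

    ``assayed`` marks SNPs the assay actually tested; hits are only allowed
    on assayed SNPs.  The SNP ordering is genomic position order.
    """

    name: str
    hits: np.ndarray
    assayed: np.ndarray

    def __post_init__(self) -> None:
        self.hits = np.asarray(self.hits, dtype=bool)
        self.assayed = np.asarray(self.assayed, dtype=bool)
        if self.hits.shape != self.assayed.shape:
            raise ValueError("hits and assayed masks must have equal length")
        if np.any(self.hits & ~self.assayed):
            raise ValueError("a SNP cannot be a hit without being assayed")


@dataclass
class EnrichmentResult:
    """Observed counts, null distribution and derived enrichment statistics."""

    assay: str
    n_H: int
    n_T: int
    n_TH: int
    pseudo_precision: float
    pseudo_recall: float
    null_n_TH: np.ndarray = field(repr=False)
    p_value: float = np.nan
    fold: float = np.nan
    fold_ci: tuple[float, float] = (np.nan, np.nan)

    @property
    def null_pseudo_precision(self) -> np.ndarray:
        return self.null_n_TH / self.n_H

    @property
    def null_pseudo_recall(self) -> np.ndarray:
        return self.null_n_TH / self.n_T


def _membership(sets: Mapping[str, Iterable[str]],
                snp_ids: Sequence[str]) -> tuple[list[str], np.ndarray]:
    index = {s: i for i, s in enumerate(snp_ids)}
    names = list(sets)
    M = np.zeros((len(names), len(snp_ids)), dtype=bool)
    for i, name in enumerate(names):
        for member in sets[name]:
            j = index.get(member)
            if j is not None:
                M[i, j] = True
    return names, M


def enrichment_counts(
    track: HitTrack,
    sets: Mapping[str, Iterable[str]],
    snp_ids: Sequence[str],
) -> tuple[int, int, int]:
    """(n_H, n_T, n_TH) for a hit track against tag LD sets or credible sets.

    ``sets`` maps a tag SNP (or credible-set id) to its member SNP ids.
    Tags with no assayed member are excluded from both n_T and n_TH.
    """
    if len(track.hits) != len(snp_ids):
        raise ValueError("track not aligned to the variant table")
    if not track.assayed.any():
        raise ValueError("track has no assayed SNPs")
    _, M = _membership(sets, snp_ids)
    n_H = int(track.hits.sum())
    recoverable = (M & track.assayed[None, :]).any(axis=1)
    recovered = (M & track.hits[None, :]).any(axis=1)
    return n_H, int(recoverable.sum()), int((recovered & recoverable).sum())


def pseudo_precision_recall(counts: tuple[int, int, int]) -> tuple[float, float]:
    """(pseudo_precision, pseudo_recall) = (n_TH/n_H, n_TH/n_T); NaN on 0/0."""
    n_H, n_T, n_TH = counts
    pp = n_TH / n_H if n_H > 0 else np.nan
    pr = n_TH / n_T if n_T > 0 else np.nan
    return pp, pr


def _null_setup(track, sets, snp_ids):
    assayed_idx = np.flatnonzero(track.assayed)
    n = len(assayed_idx)
    ids = [snp_ids[i] for i in assayed_idx]
    _, M = _membership(sets, ids)
    keep = M.any(axis=1)                    # recoverable sets only
    M = M[keep]
    h = track.hits[assayed_idx]
    obs = int((M @ h > 0).sum())
    return M, h, obs, n


def shift_null(
    track: HitTrack,
    sets: Mapping[str, Iterable[str]],
    snp_ids: Sequence[str],
) -> EnrichmentResult:
    """Genomic-shift empirical null and p-value for one assay track.

    Hit status is reassigned by circularly shifting the hit vector along
    the assayed SNPs (in genomic order) by every offset 0 < i < n, giving a
    deterministic null of exactly n-1 draws.  The p-value is the fraction
    of draws whose pseudo-precision and pseudo-recall both reach the
    observed values; as n_H and n_T are shift-invariant this is an n_TH
    exceedance, with ties counted (p is never 0 and never below 1/(n-1)).
    """
    M, h, obs, n = _null_setup(track, sets, snp_ids)
    if n < 3:
        raise ValueError("shift null needs >= 3 assayed SNPs")
    null = np.empty(n - 1, dtype=int)
    for i in range(1, n):
        null[i - 1] = int((M @ np.roll(h, i) > 0).sum())
    return _finish(track, sets, snp_ids, null, obs)


def permutation_null(
    track: HitTrack,
    sets: Mapping[str, Iterable[str]],
    snp_ids: Sequence[str],
    *,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """Permutation empirical null: shuffle hit labels among assayed SNPs."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    M, h, obs, n = _null_setup(track, sets, snp_ids)
    null = np.empty(n_perm, dtype=int)
    for k in range(n_perm):
        null[k] = int((M @ rng.permutation(h) > 0).sum())
    return _finish(track, sets, snp_ids, null, obs)


def _finish(track, sets, snp_ids, null, obs) -> EnrichmentResult:
    n_H, n_T, n_TH = enrichment_counts(track, sets, snp_ids)
    assert n_TH == obs
    pp, pr = pseudo_precision_recall((n_H, n_T, n_TH))
    # empirical p floored at one draw: never 0, at least 1/n_draws
    p = max(int((null >= obs).sum()), 1) / len(null)
    res = EnrichmentResult(
        assay=track.name, n_H=n_H, n_T=n_T, n_TH=n_TH,
        pseudo_precision=pp, pseudo_recall=pr,
        null_n_TH=null, p_value=p,
    )
    res.fold, res.fold_ci = fold_enrichment(pp, res.null_pseudo_precision)
    return res


def evaluate_track(
    track: HitTrack,
    sets: Mapping[str, Iterable[str]],
    snp_ids: Sequence[str],
    *,
    null: str = "shift",
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Run the configured empirical null for one track."""
    if null == "shift":
        return shift_null(track, sets, snp_ids)
    if null == "permutation":
        return permutation_null(track, sets, snp_ids, n_perm=n_perm, seed=seed)
    raise ValueError("null must be 'shift' or 'permutation'")


def fold_enrichment(
    pp_obs: float,
    null_pp: np.ndarray,
) -> tuple[float, tuple[float, float]]:
    """Fold = observed pseudo-precision over the null mean, with 95% CI.

    The CI divides the observed value by the null 97.5th / 2.5th
    percentiles; the upper bound is infinite when the 2.5th percentile is
    zero, and the fold itself infinite (flagged by the caller) when the
    null mean is zero.
    """
    null_pp = np.asarray(null_pp, dtype=float)
    if null_pp.size == 0:
        raise ValueError("null distribution is empty")
    mean = null_pp.mean()
    fold = np.inf if mean == 0 else pp_obs / mean
    q_lo, q_hi = np.quantile(null_pp, [0.025, 0.975])
    hi = np.inf if q_lo == 0 else pp_obs / q_lo
    lo = np.inf if q_hi == 0 else pp_obs / q_hi
    return float(fold), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Track construction and restriction
# ---------------------------------------------------------------------------

def interval_track(
    name: str,
    snp_positions: Sequence[int],
    intervals: pd.DataFrame,
    *,
    assayed: np.ndarray | None = None,
) -> HitTrack:
    """Hit iff the SNP lies in any interval (1-based inclusive start/end)."""
    pos = np.asarray(snp_positions)
    hits = np.zeros(len(pos), dtype=bool)
    for _, row in intervals.iterrows():
        hits |= (pos >= row["start"]) & (pos <= row["end"])
    assayed = np.ones(len(pos), dtype=bool) if assayed is None else assayed
    return HitTrack(name=name, hits=hits & assayed, assayed=assayed)


def hichip_track(
    snp_positions: Sequence[int],
    fragments: pd.DataFrame,
    *,
    threshold: float = HICHIP_SCORE_THRESHOLD,
    name: str = "HiChIP",
) -> HitTrack:
    """Promoter-interaction hit track from per-fragment normalized scores.

    A SNP is a hit iff it falls in a fragment with normalized interaction
    score >= ``threshold`` (inclusive); every SNP covered by any fragment
    counts as assayed.
    """
    pos = np.asarray(snp_positions)
    assayed = np.zeros(len(pos), dtype=bool)
    hits = np.zeros(len(pos), dtype=bool)
    for _, row in fragments.iterrows():
        inside = (pos >= row["start"]) & (pos <= row["end"])
        assayed |= inside
        if row["score"] >= threshold:
            hits |= inside
    return HitTrack(name=name, hits=hits, assayed=assayed)


def restrict_accessible(track: HitTrack, accessible: np.ndarray) -> HitTrack:
    """Restrict a track to SNPs in accessible chromatin.

    The assayed mask is intersected with the accessibility flags; hits
    outside accessibility drop out.  Counts and nulls must be recomputed on
    the restricted track.
    """
    accessible = np.asarray(accessible, dtype=bool)
    assayed = track.assayed & accessible
    if not assayed.any():
        raise ValueError("no assayed SNPs remain after accessibility restriction")
    return HitTrack(name=f"{track.name}|accessible",
                    hits=track.hits & assayed, assayed=assayed)


def prioritize_variants(
    crispri: HitTrack,
    t_mpra: HitTrack,
    accessible: np.ndarray,
) -> np.ndarray:
    """Two-criteria high-priority flags.

    A variant is high priority iff it is a CRISPRi hit (regardless of
    accessibility) or a T-MPRA hit lying in accessible chromatin.
    """
    accessible = np.asarray(accessible, dtype=bool)
    return crispri.hits | (t_mpra.hits & accessible)


def haplotype_summary(
    variant_table: pd.DataFrame,
    tracks: Mapping[str, HitTrack],
    haplotype_members: Mapping[int, Iterable[str]],
    high_priority: np.ndarray,
) -> pd.DataFrame:
    """Per-haplotype hit matrix: one row per (haplotype, SNP) with per-assay
    status (hit / assayed-no-hit / untested), total hit counts and the
    high-priority flag."""
    idx = {s: i for i, s in enumerate(variant_table["id"])}
    rows = []
    for hap, members in sorted(haplotype_members.items()):
        for snp in sorted(members, key=lambda s: idx.get(s, -1)):
            i = idx.get(snp)
            if i is None:
                continue
            row = {"haplotype": hap, "snp": snp,
                   "pos": variant_table["pos"].iloc[i]}
            total = 0
            for name, tr in tracks.items():
                status = ("hit" if tr.hits[i]
                          else "tested" if tr.assayed[i] else "untested")
                row[name] = status
                total += int(tr.hits[i])
            row["n_hits"] = total
            row["high_priority"] = bool(high_priority[i])
            rows.append(row)
    return pd.DataFrame(rows)


def atac_similarity(counts_a: Sequence[float], counts_b: Sequence[float]) -> float:
    """Pearson correlation of log(count + 0.5) over a shared region set."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 shared regions")
    return float(np.corrcoef(np.log(a + 0.5), np.log(b + 0.5))[0, 1])


# ---------------------------------------------------------------------------
# Curated prioritized-variant table
# ---------------------------------------------------------------------------

def load_prioritized_variants() -> pd.DataFrame:
    """Load the curated high-priority variant table for the TNFAIP3 locus.

    Columns: ``snp_id``, ``traits``, ``ukbb_cs_95`` (UK Biobank 95%
    credible-set annotations, empty when absent), ``haplotypes``
    (comma-separated ids) and ``criteria``.
    """
    ref = resources.files("varlocus.data") / "tnfaip3_prioritized_variants.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    return df


def prioritized_haplotype_ids(table: pd.DataFrame) -> set[str]:
    """Distinct haplotype identifiers among the prioritized variants."""
    ids: set[str] = set()
    for entry in table["haplotypes"]:
        ids |= {x.strip() for x in str(entry).split(",") if x.strip()}
    return ids


def credible_set_supported(table: pd.DataFrame) -> pd.DataFrame:
    """Prioritized variants with UK Biobank 95% credible-set support."""
    return table[table["ukbb_cs_95"].str.len() > 0]
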