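"""CRISPRi/CRISPRa FlowFISH screen model.

Cells carrying a tiled guide library are stained for the target mRNA and
sorted into six expression bins: 30% of cells on each extreme of the
expression distribution, each extreme split into three contiguous ~10%
bins, with the outermost 0.1% of cells excluded.  Guide counts per bin are
the data; the model assumes cells carrying a guide have normally
distributed log expression with the population variance and a guide-specific
mean shift ``mu`` (in sigma units).  Per-guide means are estimated by
maximum likelihood over the bin-count profile, turned into z-scores against
the non-targeting guides, combined per element with Stouffer's method and
scaled by a matched non-targeting null, and elements are called when both
selected replicates pass FDR < sqrt(0.1) in the same direction.

The module also implements the Hsu mismatch-weight specificity score used
to select guides with acceptable genome-wide off-target profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

__all__ = [
    "HSU_MISMATCH_WEIGHTS",
    "offtarget_hit_score",
    "aggregate_guide_specificity",
    "select_guides",
    "SortModel",
    "fit_sort_model",
    "bin_probabilities",
    "estimate_guide_effects",
    "guide_zscores",
    "element_stats",
    "call_regulatory_elements",
    "snp_hits_from_elements",
    "ELEMENT_FDR_PER_REPLICATE",
]

#: Position-specific mismatch weights (PAM-distal position 0 .. PAM-proximal 19).
HSU_MISMATCH_WEIGHTS = np.array(
    [0.0, 0.0, 0.014, 0.0, 0.0, 0.395, 0.317, 0.0, 0.389, 0.079,
     0.445, 0.508, 0.613, 0.851, 0.732, 0.828, 0.615, 0.804, 0.685, 0.583]
)

#: Per-replicate FDR bound; both replicates below sqrt(0.1) gives a combined
#: FDR below 0.1.
ELEMENT_FDR_PER_REPLICATE = np.sqrt(0.1)


# ---------------------------------------------------------------------------
# Guide specificity
# ---------------------------------------------------------------------------

def offtarget_hit_score(mismatch_positions: Iterable[int]) -> float:
    """Score a single genomic off-target site from its mismatch positions.

    The score is the product of ``(1 - W[e])`` over mismatched positions
    ``e`` of the 20-mer, a distance factor ``1 / (((19 - dbar)/19) * 4 + 1)``
    where ``dbar`` is the mean pairwise distance between mismatches, and
    ``1 / n_mm**2``.  For a single mismatch ``dbar`` is taken as 19, so the
    distance factor is 1.  Returns a value in [0, 1]; higher means the
    off-target site is more likely to be cut.
    """
    positions = sorted(set(int(p) for p in mismatch_positions))
    if not positions:
        raise ValueError("a scored off-target hit must have >= 1 mismatch")
    if positions[0] < 0 or positions[-1] > 19:
        raise ValueError(f"mismatch positions must lie in [0, 19], got {positions}")
    n_mm = len(positions)
    weight_term = float(np.prod(1.0 - HSU_MISMATCH_WEIGHTS[positions]))
    if n_mm == 1:
        dbar = 19.0
    else:
        arr = np.asarray(positions, dtype=float)
        diffs = np.abs(arr[:, None] - arr[None, :])
        dbar = diffs[np.triu_indices(n_mm, k=1)].mean()
    distance_term = 1.0 / (((19.0 - dbar) / 19.0) * 4.0 + 1.0)
    return weight_term * distance_term / n_mm**2


def aggregate_guide_specificity(hit_scores: Iterable[float]) -> float:
    """Aggregate per-site hit scores into a guide specificity in (0, 100].

    Hit scores (fractions in [0, 1]) are put on a 0-100 scale and combined
    as ``S_guide = 100 * 100 / (100 + sum(S_hit))``, so the specificity
    itself lives on the 0-100 scale: a guide with no predicted off-target
    sites scores 100 and a single consensus-strength hit halves it to 50.
    """
    total = 100.0 * float(np.sum(np.fromiter(hit_scores, dtype=float)))
    return 100.0 * 100.0 / (100.0 + total)


def select_guides(
    guides: pd.DataFrame,
    matches: pd.DataFrame,
    locus: tuple[int, int],
    *,
    max_perfect_offtargets: int = 3,
) -> pd.DataFrame:
    """Apply the library selection filters to candidate guides.

    ``guides`` needs columns ``guide`` and ``sequence``; ``matches`` lists
    genomic matches with columns ``guide``, ``position``, ``n_mismatches``
    and ``intended`` (exactly one intended site per guide, which must lie
    inside ``locus``).  A guide is dropped when it has any non-intended
    match inside the locus interval, or more than ``max_perfect_offtargets``
    perfect (0-mismatch) non-intended matches anywhere.  Surviving guides
    get a ``sequence_synth`` column with a G prepended when the spacer does
    not already start with one.
    """
    lo, hi = locus
    keep = []
    for gid, sub in matches.groupby("guide", sort=False):
        intended = sub[sub["intended"]]
        if intended.empty or not (
            (intended["position"] >= lo) & (intended["position"] <= hi)
        ).any():
            raise ValueError(f"guide {gid!r} has no intended site inside the locus")
        off = sub[~sub["intended"]]
        near = (off["position"] >= lo) & (off["position"] <= hi)
        if near.any():
            continue
        if (off["n_mismatches"] == 0).sum() > max_perfect_offtargets:
            continue
        keep.append(gid)
    out = guides[guides["guide"].isin(keep)].copy()
    out["sequence_synth"] = [
        s if s.startswith("G") else "G" + s for s in out["sequence"]
    ]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Sort model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SortModel:
    """Mapping from sort-bin design fractions to standard-normal intervals.

    ``bounds`` holds the (low, high) z boundaries for each of the six bins;
    ``capture`` the fraction of all cells each bin captures (design fraction
    minus the outer-tail trim on the extreme bins).  All guide means are
    expressed in units of the global log-expression standard deviation, so
    sigma is 1 by construction.
    """

    bounds: np.ndarray          # (6, 2)
    capture: np.ndarray         # (6,)
    bin_fractions: tuple
    tail_trim: float


def fit_sort_model(
    bin_fractions: Sequence[float] = (0.1,) * 6,
    tail_trim: float = 0.001,
) -> SortModel:
    """Place the six sort bins on the standard normal distribution.

    The first three fractions cover the low-expression 30% tail and the last
    three the high tail; ``tail_trim`` is the fraction of the most extreme
    cells excluded on each side by the sorter gates.
    """
    f = np.asarray(bin_fractions, dtype=float)
    if f.shape != (6,) or np.any(f <= 0) or np.any(f >= 1):
        raise ValueError("need six bin fractions in (0, 1)")
    low, high = f[:3].sum(), f[3:].sum()
    if not (np.isclose(low, 0.30, atol=0.02) and np.isclose(high, 0.30, atol=0.02)):
        raise ValueError(
            f"bin fractions must cover two ~30% tails (got {low:.3f}, {high:.3f})"
        )
    q_low = np.concatenate([[tail_trim], np.cumsum(f[:3])])
    q_high = np.concatenate([1.0 - high + np.cumsum(np.concatenate([[0.0], f[3:5]])),
                             [1.0 - tail_trim]])
    edges_q = np.concatenate([q_low, q_high])  # 8 cumulative points
    with np.errstate(divide="ignore"):
        edges_z = stats.norm.ppf(edges_q)
    bounds = np.stack(
        [np.concatenate([edges_z[:3], edges_z[4:7]]),
         np.concatenate([edges_z[1:4], edges_z[5:8]])],
        axis=1,
    )
    capture = np.concatenate([np.diff(edges_q[:4]), np.diff(edges_q[4:])])
    return SortModel(bounds=bounds, capture=capture,
                     bin_fractions=tuple(f), tail_trim=float(tail_trim))


def bin_probabilities(model: SortModel, mu: np.ndarray) -> np.ndarray:
    """Fraction of a guide's cells landing in each bin given mean shift mu.

    Returns an array of shape ``(len(mu), 6)``; rows do not sum to 1 because
    only ~60% of cells are sorted.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    lo = model.bounds[:, 0][None, :]
    hi = model.bounds[:, 1][None, :]
    return stats.norm.cdf(hi - mu[:, None]) - stats.norm.cdf(lo - mu[:, None])


# ---------------------------------------------------------------------------
# Per-guide expression means
# ---------------------------------------------------------------------------

BIN_COLUMNS = [f"bin{i}" for i in range(1, 7)]


def _profile_loglik(counts_row: np.ndarray, model: SortModel,
                    weights: np.ndarray, depth: np.ndarray):
    """Return f(mu) -> multinomial log likelihood for one guide (oracle hook)."""
    scale = depth / weights

    def loglik(mu: float) -> float:
        f = bin_probabilities(model, np.array([mu]))[0]
        p = scale * f
        p = p / p.sum()
        return float(np.sum(counts_row * np.log(p)))

    return loglik


def estimate_guide_effects(
    screen: pd.DataFrame,
    model: SortModel,
    *,
    pseudocount_per_reads: float = 100_000.0,
    refine: int = 40,
    abundance_col: str | None = "unsorted",
    bounds: tuple[float, float] = (-6.0, 6.0),
    coarse_step: float = 0.01,
    fine_step: float = 0.0005,
) -> pd.DataFrame:
    """Maximum-likelihood per-guide mean log-expression shifts (sigma units).

    ``screen`` holds one replicate with columns ``bin1..bin6`` (and
    optionally ``unsorted`` abundance counts).  For each guide the expected
    read share in bin ``b`` is proportional to ``depth_b * f_b(mu) / w_b``
    where ``f_b`` is the normal-bin occupancy, ``depth_b`` the total reads
    sequenced in the bin and ``w_b`` the library-wide occupancy of the bin
    (initialised to the design capture fractions).  A pseudocount of one
    read per ``pseudocount_per_reads`` total bin reads is added before
    fitting, acting as a prior of no expression change.  With ``refine > 0``
    the library occupancy ``w_b`` is iteratively re-estimated from the
    abundance-weighted occupancy implied by the current fits (up to
    ``refine`` fixed-point iterations on a coarse grid, stopping early on
    convergence), which removes the compositional bias that appears when a
    non-negligible fraction of guides shares a true effect.

    Returns a copy of ``screen`` with a ``mu_hat`` column.
    """
    counts = screen[BIN_COLUMNS].to_numpy(dtype=float)
    if np.any(counts < 0):
        raise ValueError("bin counts must be non-negative")
    depth = counts.sum(axis=0)
    if np.any(depth / max(len(counts), 1) < 1):
        warnings.warn("sequencing depth below ~1 expected read per guide per bin",
                      stacklevel=2)
    counts = counts + depth / pseudocount_per_reads

    if abundance_col is not None and abundance_col in screen.columns:
        abundance = screen[abundance_col].to_numpy(dtype=float) + 1.0
    else:
        abundance = np.ones(len(counts))
    abundance = abundance / abundance.sum()

    weights = model.capture.copy()
    lo, hi = bounds
    for _ in range(refine):
        mu0 = _coarse_mle(counts, model, weights, depth, lo, hi, coarse_step)
        occupancy = bin_probabilities(model, mu0)
        new_w = (abundance[:, None] * occupancy).sum(axis=0)
        delta = np.abs(new_w - weights).max()
        weights = new_w
        if delta < 1e-7:
            break
    mu_hat = _grid_mle(counts, model, weights, depth, lo, hi,
                       coarse_step, fine_step)
    out = screen.copy()
    out["mu_hat"] = np.clip(mu_hat, lo, hi)
    return out


def _coarse_mle(counts, model, weights, depth, lo, hi, coarse_step,
                chunk: int = 4096) -> np.ndarray:
    scale = depth / weights
    grid = np.arange(lo, hi + coarse_step / 2, coarse_step)
    f = bin_probabilities(model, grid)                   # (M, 6)
    p = f * scale[None, :]
    p = p / p.sum(axis=1, keepdims=True)
    logp = np.log(np.maximum(p, 1e-300))
    mu0 = np.empty(len(counts))
    for start in range(0, len(counts), chunk):
        block = counts[start:start + chunk]
        ll = block @ logp.T                              # (g, M)
        mu0[start:start + chunk] = grid[np.argmax(ll, axis=1)]
    return mu0


def _grid_mle(counts, model, weights, depth, lo, hi, coarse_step, fine_step,
              chunk: int = 4096) -> np.ndarray:
    scale = depth / weights
    mu0 = _coarse_mle(counts, model, weights, depth, lo, hi, coarse_step, chunk)
    # local refinement around the coarse optimum
    offsets = np.arange(-coarse_step, coarse_step + fine_step / 2, fine_step)
    mu_hat = np.empty(len(counts))
    for start in range(0, len(counts), chunk):
        block = counts[start:start + chunk]
        mus = np.clip(mu0[start:start + chunk, None] + offsets[None, :], lo, hi)
        f = bin_probabilities(model, mus.ravel()).reshape(*mus.shape, 6)
        p = f * scale[None, None, :]
        p = p / p.sum(axis=2, keepdims=True)
        ll = np.einsum("gb,gmb->gm", block, np.log(np.maximum(p, 1e-300)))
        mu_hat[start:start + chunk] = np.take_along_axis(
            mus, np.argmax(ll, axis=1)[:, None], axis=1
        )[:, 0]
    return mu_hat


def fit_single_guide(counts_row: np.ndarray, model: SortModel,
                     *, weights: np.ndarray | None = None,
                     depth: np.ndarray | None = None,
                     bounds: tuple[float, float] = (-6.0, 6.0)) -> float:
    """Fit one guide's mean with a bounded scalar optimizer (no grids)."""
    counts_row = np.asarray(counts_row, dtype=float)
    w = model.capture if weights is None else weights
    d = np.ones(6) if depth is None else depth
    loglik = _profile_loglik(counts_row, model, w, d)
    res = minimize_scalar(lambda m: -loglik(m), bounds=bounds, method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def guide_zscores(fitted: pd.DataFrame, *, standardize: bool = True) -> pd.DataFrame:
    """z-score guide effects against the non-targeting distribution.

    Non-targeting rows are those with ``targeting == False``.  The mean of
    the non-targeting ``mu_hat`` is always subtracted; with ``standardize``
    the result is additionally divided by the non-targeting standard
    deviation so z is scale-free.
    """
    nt = fitted.loc[~fitted["targeting"], "mu_hat"]
    if nt.empty:
        raise ValueError("no non-targeting guides to normalize against")
    center = nt.mean()
    scale = nt.std(ddof=1) if standardize else 1.0
    if scale == 0:
        raise ValueError("non-targeting mu_hat has zero variance")
    out = fitted.copy()
    out["z"] = (out["mu_hat"] - center) / scale
    return out


# ---------------------------------------------------------------------------
# Element statistics
# ---------------------------------------------------------------------------

def _nt_stouffer_sd(nt_z: np.ndarray, n: int, rng: np.random.Generator,
                    n_draws: int = 10) -> float:
    """SD of non-targeting Stouffer z at group size n.

    Built by repeatedly shuffling the non-targeting z-scores and partitioning
    them into groups of ``n``; with ``n_draws`` passes each non-targeting
    guide contributes ``n_draws`` times in total.
    """
    if n > len(nt_z):
        raise ValueError(f"element has {n} guides but only {len(nt_z)} "
                         "non-targeting guides are available")
    zs = []
    for _ in range(n_draws):
        perm = rng.permutation(nt_z)
        n_groups = len(perm) // n
        groups = perm[: n_groups * n].reshape(n_groups, n)
        zs.append(groups.sum(axis=1) / np.sqrt(n))
    return float(np.concatenate(zs).std(ddof=1))


def element_stats(
    guides: pd.DataFrame,
    *,
    direction: str = "down",
    seed: int = 0,
    nt_draws: int = 10,
    min_nontargeting: int = 50,
) -> pd.DataFrame:
    """Per-element significance and effect z-scores for one replicate.

    ``guides`` needs columns ``element``, ``z`` and ``targeting``.  For each
    element, the raw Stouffer z (sum of guide z over sqrt(n)) is scaled by
    the SD of non-targeting Stouffer z-scores computed at the same group
    size; the effect z is the plain mean of guide z.  One-tailed p-values
    are taken in the assay direction (``"down"`` for CRISPRi repression,
    ``"up"`` for CRISPRa activation) and BH-adjusted across elements.
    """
    if direction not in {"down", "up"}:
        raise ValueError("direction must be 'down' or 'up'")
    nt_z = guides.loc[~guides["targeting"], "z"].to_numpy(dtype=float)
    if len(nt_z) < min_nontargeting:
        raise ValueError(
            f"need >= {min_nontargeting} non-targeting guides, got {len(nt_z)}"
        )
    grouped = guides[guides["targeting"]].groupby("element", sort=True)["z"]
    rows = []
    scale_cache: dict[int, float] = {}
    rng = np.random.default_rng(seed)
    sizes = sorted({len(z) for _, z in grouped})
    for n in sizes:
        scale_cache[n] = _nt_stouffer_sd(nt_z, n, rng, n_draws=nt_draws)
    for element, z in grouped:
        z = z.to_numpy(dtype=float)
        n = len(z)
        raw = z.sum() / np.sqrt(n)
        sig = raw / scale_cache[n]
        p = stats.norm.cdf(sig) if direction == "down" else stats.norm.sf(sig)
        rows.append((element, n, z.mean(), raw, sig, p))
    out = pd.DataFrame(
        rows, columns=["element", "n_guides", "effect_z", "raw_stouffer_z",
                       "sig_z", "p"]
    )
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def call_regulatory_elements(
    replicates: Sequence[pd.DataFrame],
    *,
    direction: str = "down",
    promoter_element: str | None = "promoter",
) -> pd.DataFrame:
    """Combine replicate element statistics into hit calls.

    With more than two replicates, the two kept are those where the promoter
    positive-control element shows the strongest effect in the expected
    direction.  An element is a hit when both kept replicates have
    BH FDR < sqrt(0.1) and the effect direction is identical.
    """
    if len(replicates) < 2:
        raise ValueError("need >= 2 replicates to call elements")
    sign = -1.0 if direction == "down" else 1.0
    reps = list(replicates)
    if len(reps) > 2:
        if promoter_element is None:
            raise ValueError("promoter control element required to pick replicates")
        strengths = []
        for df in reps:
            row = df[df["element"] == promoter_element]
            if row.empty:
                raise ValueError(f"promoter control {promoter_element!r} missing")
            strengths.append(sign * float(row["effect_z"].iloc[0]))
        order = np.argsort(strengths)[::-1][:2]
        reps = [reps[i] for i in sorted(order)]
    a, b = reps[0].set_index("element"), reps[1].set_index("element")
    elements = a.index.intersection(b.index)
    out = pd.DataFrame(index=elements)
    out["fdr_rep1"], out["fdr_rep2"] = a.loc[elements, "fdr"], b.loc[elements, "fdr"]
    out["effect_z_rep1"] = a.loc[elements, "effect_z"]
    out["effect_z_rep2"] = b.loc[elements, "effect_z"]
    same_dir = np.sign(out["effect_z_rep1"]) == np.sign(out["effect_z_rep2"])
    out["hit"] = (
        (out["fdr_rep1"] < ELEMENT_FDR_PER_REPLICATE)
        & (out["fdr_rep2"] < ELEMENT_FDR_PER_REPLICATE)
        & same_dir
    )
    return out.reset_index().rename(columns={"index": "element"})


def snp_hits_from_elements(
    hit_elements: pd.DataFrame,
    snp_positions: Sequence[int],
    *,
    pad: int = 100,
) -> np.ndarray:
    """Flag SNPs inside the targeted footprint of any hit element.

    ``hit_elements`` needs 1-based inclusive ``start``/``end`` columns (rows
    restricted to hit elements).  The footprint extends ``pad`` bp on either
    side, boundaries inclusive: for CRISPRi tiling this is the peak +/- 100
    bp; for CRISPRa, where elements are already the SNP +/- 25 bp windows,
    use ``pad=0``.
    """
    pos = np.asarray(snp_positions)
    flags = np.zeros(len(pos), dtype=bool)
    for _, row in hit_elements.iterrows():
        flags |= (pos >= row["start"] - pad) & (pos <= row["end"] + pad)
    return flags
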