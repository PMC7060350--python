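"""Predicted transcription-factor binding perturbation via GOMER scoring.

Each variant's reference and alternate flanking sequences are scored with
an occupancy model: every window on both strands binds independently with
probability proportional to its PWM affinity, and the sequence-level
binding probability is one minus the probability that no window is bound.
A variant disrupts a motif when the region is bound on at least one allele
(log score above a per-PWM calibrated threshold) and the absolute
difference in log binding score between alleles is at least 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PWM",
    "MotifCall",
    "read_meme",
    "write_meme",
    "gomer_log_binding_score",
    "calibrate_bound_threshold",
    "call_motif_disruption",
    "tf_chip_motif_hit",
]

_ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
_COMP = {0: 3, 1: 2, 2: 1, 3: 0, -1: -1}

MIN_LOG_DELTA = 0.1  # minimum |delta log binding score| for a disruption call


@dataclass
class PWM:
    """Position weight matrix of per-position ACGT probabilities.

    Probabilities are floored at ``floor`` and columns renormalized, so all
    entries are strictly positive and each position sums to one.
    """

    name: str
    probs: np.ndarray            # (L, 4)
    floor: float = 1e-3

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("PWM must be (L, 4) over ACGT")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")
        p = np.maximum(p, self.floor)
        self.probs = p / p.sum(axis=1, keepdims=True)

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in np.argmax(self.probs, axis=1))


@dataclass
class MotifCall:
    """Per-variant, per-TF motif disruption decision."""

    variant: str
    tf: str
    log_score_ref: float
    log_score_alt: float
    bound_ref: bool
    bound_alt: bool
    disrupted: bool

    @property
    def delta(self) -> float:
        return abs(self.log_score_ref - self.log_score_alt)


# ---------------------------------------------------------------------------
# MEME minimal format
# ---------------------------------------------------------------------------

def read_meme(path: str) -> list[PWM]:
    """Parse PWMs from a MEME minimal-format motif file."""
    pwms: list[PWM] = []
    name = None
    rows: list[list[float]] = []
    in_matrix = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                if name is not None and rows:
                    pwms.append(PWM(name=name, probs=np.array(rows)))
                name = line.split()[1]
                rows, in_matrix = [], False
            elif line.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix and line:
                parts = line.split()
                if len(parts) == 4:
                    rows.append([float(x) for x in parts])
                else:
                    in_matrix = False
            elif in_matrix and not line:
                in_matrix = False
    if name is not None and rows:
        pwms.append(PWM(name=name, probs=np.array(rows)))
    if not pwms:
        raise ValueError(f"no motifs found in {path}")
    return pwms


def write_meme(pwms: Iterable[PWM], path: str) -> None:
    """Write PWMs in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, -1) for c in seq.upper()], dtype=int)


def _window_log_odds(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Sum of per-position log odds for every window (N bases contribute 0)."""
    L = log_odds.shape[0]
    n_win = len(codes) - L + 1
    out = np.zeros(n_win)
    for j in range(L):
        col = codes[j:j + n_win]
        vals = np.where(col >= 0, log_odds[j, np.clip(col, 0, 3)], 0.0)
        out += vals
    return out


def gomer_log_binding_score(
    pwm: PWM,
    sequence: str,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> float:
    """Natural-log occupancy score of a sequence under an occupancy model.

    Each window ``w`` (both strands) binds with probability
    ``p_w = r_w / r_max`` where ``r_w`` is the PWM-to-background likelihood
    ratio of the window and ``r_max`` that of the consensus sequence (the
    fixed scaling that maps affinities onto probabilities).  The score is
    ``log(1 - prod_w(1 - p_w))``.  Ambiguous bases (N) score as background.
    """
    codes = _encode(sequence)
    L = len(pwm)
    if len(codes) < L:
        raise ValueError(
            f"sequence length {len(codes)} shorter than motif length {L}"
        )
    log_odds = np.log(pwm.probs / np.asarray(background, dtype=float)[None, :])
    max_lo = np.max(log_odds, axis=1).sum()
    fwd = _window_log_odds(codes, log_odds)
    rc = np.array([_COMP[c] for c in codes])[::-1]
    rev = _window_log_odds(rc, log_odds)
    log_p = np.concatenate([fwd, rev]) - max_lo          # log p_w <= 0
    log_not_bound = np.log1p(-np.minimum(np.exp(log_p), 1 - 1e-16)).sum()
    return float(np.log(-np.expm1(log_not_bound)))


def calibrate_bound_threshold(
    max_allele_log_scores: Sequence[float],
    *,
    quantile: float = 0.05,
) -> float:
    """Per-PWM bound threshold from the variant universe.

    The threshold is the 5th percentile of per-variant best-allele log
    scores, so that >95% of common-variant regions qualify as bound.
    """
    scores = np.asarray(max_allele_log_scores, dtype=float)
    if len(scores) < 100:
        warnings.warn("calibrating a bound threshold on < 100 variants",
                      stacklevel=2)
    return float(np.quantile(scores, quantile))


def call_motif_disruption(
    pwm: PWM,
    flank_ref: str,
    flank_alt: str,
    bound_threshold: float,
    *,
    variant: str = "",
    ref_allele: str | None = None,
    var_index: int | None = None,
    min_delta: float = MIN_LOG_DELTA,
) -> MotifCall:
    """Decide whether a variant disrupts a TF's binding.

    Flanks must be centered on the variant and of equal length.  The call is
    ``disrupted`` iff the region is bound (log score >= ``bound_threshold``)
    on at least one allele and ``|delta log score| >= min_delta``
    (inclusive).
    """
    if len(flank_ref) != len(flank_alt):
        raise ValueError("ref/alt flanks must have equal length")
    if ref_allele is not None:
        idx = len(flank_ref) // 2 if var_index is None else var_index
        if flank_ref[idx].upper() != ref_allele.upper():
            raise ValueError(
                f"flank center {flank_ref[idx]!r} does not match the "
                f"reference allele {ref_allele!r}"
            )
    s_ref = gomer_log_binding_score(pwm, flank_ref)
    s_alt = gomer_log_binding_score(pwm, flank_alt)
    bound_ref = s_ref >= bound_threshold
    bound_alt = s_alt >= bound_threshold
    disrupted = (bound_ref or bound_alt) and abs(s_ref - s_alt) >= min_delta
    return MotifCall(variant=variant, tf=pwm.name,
                     log_score_ref=s_ref, log_score_alt=s_alt,
                     bound_ref=bound_ref, bound_alt=bound_alt,
                     disrupted=disrupted)


def tf_chip_motif_hit(
    variant_pos: int,
    chip_intervals: pd.DataFrame,
    motif_calls: Iterable[MotifCall],
    *,
    same_tf: bool = True,
) -> bool:
    """Combine motif disruption with TF ChIP occupancy evidence.

    ``chip_intervals`` needs 1-based inclusive columns ``tf``, ``start``,
    ``end``.  With ``same_tf`` (default) the disrupted motif's TF must have
    a ChIP interval covering the variant; otherwise any TF's interval
    suffices.
    """
    disrupted_tfs = {c.tf for c in motif_calls if c.disrupted}
    if not disrupted_tfs:
        return False
    cover = chip_intervals[
        (chip_intervals["start"] <= variant_pos)
        & (chip_intervals["end"] >= variant_pos)
    ]
    if cover.empty:
        return False
    if not same_tf:
        return True
    return bool(disrupted_tfs & set(cover["tf"]))
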