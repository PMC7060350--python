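"""Seeded synthetic-data generators for every pipeline input.

The generators emulate the statistical structure the analysis assumes, with
known ground truth, so the whole pipeline can be exercised and calibrated
without any external data:

- a phased genotype panel with block LD (founder-pattern copulas, planted
  tag SNPs with tight-LD partners, all MAFs > 0.01);
- six-bin FlowFISH guide counts from the same generative model the
  estimator assumes (normal log expression per cell, quantile sort bins,
  negative-binomial reads around expected bin occupancy);
- MPRA barcode tables (~250 tags per allele) with allele effects, GC bias
  and planted artifact 5-mers;
- positionally clustered binary assay-hit tracks;
- PWMs and per-variant flank pairs with planted motif disruptions.

Each generator draws from its own RNG stream seeded from
``SimConfig.seed`` plus a stable per-module offset, so outputs are
bit-identical for a given seed and adding a generator does not perturb the
others.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import flowfish as ff
from .ldmap import PhasedPanel
from .motif import PWM, write_meme

__all__ = [
    "SimConfig", "GenotypeParams", "FlowfishParams", "MpraParams",
    "TrackParams", "MotifParams", "GroundTruth",
    "simulate_genotype_panel", "simulate_flowfish_screen",
    "simulate_mpra_counts", "simulate_assay_hit_tracks",
    "simulate_motif_inputs", "simulate_locus",
    "write_vcf", "write_bed", "write_fasta", "write_manifest",
]

# stable RNG stream offsets per generator
_STREAM = {"genotypes": 1, "flowfish": 2, "mpra": 3, "tracks": 4, "motifs": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % 2**31, _STREAM[stream]])


@dataclass
class GenotypeParams:
    n_snps: int = 120
    n_samples: int = 500            # diploid, phased
    block_size: int = 8             # SNPs per LD block
    n_tags: int = 6
    n_causal: int = 3
    flip_noise_max: float = 0.04    # per-SNP copula flip rate within a block
    min_gap: int = 150              # bp between adjacent SNPs
    max_gap: int = 400
    locus_start: int = 10_000


@dataclass
class FlowfishParams:
    n_elements: int = 12
    guides_per_element: int = 30    # ~30 tiled guides per element
    n_nontargeting: int = 6000
    effect_size: float = -1.0       # sigma units for true regulatory elements
    promoter_effect: float = -2.0
    depth_per_bin: int = 1_000_000
    unsorted_depth: int = 1_000_000
    nb_size: float = 10.0           # negative-binomial dispersion (size)
    n_replicates: int = 2
    bin_fractions: tuple = (0.1,) * 6
    tail_trim: float = 0.001
    direction: str = "down"         # CRISPRi represses


@dataclass
class MpraParams:
    tags_per_allele: int = 250      # ~250 barcodes per allele
    allele_effect: float = 0.5      # log units for causal variants
    gc_bias: float = 0.02           # log units per %GC away from 45
    artifact_5mers: tuple = ("ACGCG",)
    artifact_effect: float = 0.5
    dna_depth_per_tag: float = 100.0
    rna_depth_per_tag: float = 100.0
    nb_size: float = 10.0
    tag_noise_sd: float = 0.05
    n_replicates: int = 3


@dataclass
class TrackParams:
    cluster_len: int = 5            # SNPs per positional hit run
    sensitivity: float = 1.0        # P(causal SNP's cluster is hit)
    background: float = 0.02        # P(a background run starts at a SNP)
    assay_rate: float = 1.0         # P(a SNP is assayed)


@dataclass
class MotifParams:
    motif_length: int = 8
    consensus_prob: float = 0.92
    flank_length: int = 31          # centered on the variant
    n_disrupting: int = 10
    n_neutral: int = 90


@dataclass
class SimConfig:
    """All synthetic study conditions; the seed fixes every output."""

    seed: int = 0
    genotypes: GenotypeParams = field(default_factory=GenotypeParams)
    flowfish: FlowfishParams = field(default_factory=FlowfishParams)
    mpra: MpraParams = field(default_factory=MpraParams)
    tracks: TrackParams = field(default_factory=TrackParams)
    motifs: MotifParams = field(default_factory=MotifParams)

    def __post_init__(self) -> None:
        if self.genotypes.n_samples < 20:
            raise ValueError("need >= 20 samples for a meaningful panel")
        for name, v in (("n_snps", self.genotypes.n_snps),
                        ("block_size", self.genotypes.block_size),
                        ("tags_per_allele", self.mpra.tags_per_allele)):
            if v < 1:
                raise ValueError(f"{name} must be positive")
        if self.mpra.tags_per_allele < 2:
            raise ValueError("tags_per_allele must be >= 2")


@dataclass
class GroundTruth:
    """Planted truth for a simulated locus."""

    causal_snps: list[str] = field(default_factory=list)
    tag_snps: list[str] = field(default_factory=list)
    blocks: list[list[str]] = field(default_factory=list)
    element_effects: dict[str, float] = field(default_factory=dict)
    allele_effects: dict[str, float] = field(default_factory=dict)
    disrupted_variants: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Genotype panel
# ---------------------------------------------------------------------------

def simulate_genotype_panel(
    cfg: SimConfig,
    *,
    copy_snp: bool = False,
) -> tuple[PhasedPanel, GroundTruth]:
    """Phased haplotype panel with block LD and planted tag SNPs.

    Each LD block shares a latent founder indicator per haplotype; a SNP's
    alleles copy that indicator with a per-SNP flip noise, so within-block
    r2 is high and between-block r2 ~ 0.  The first SNP of a tag block is
    the tag and its second SNP is a noise-free partner (r2 = 1 > 0.8).
    All emitted SNPs have empirical MAF > 0.01 (resampled, or an error for
    degenerate configurations).  With ``copy_snp`` the second SNP of every
    block is an exact copy of the first.
    """
    g = cfg.genotypes
    rng = _rng(cfg.seed, "genotypes")
    n_hap = 2 * g.n_samples
    n_blocks = int(np.ceil(g.n_snps / g.block_size))
    if g.n_tags > n_blocks:
        raise ValueError("more tag SNPs requested than LD blocks")
    tag_blocks = np.linspace(0, n_blocks - 1, g.n_tags).astype(int) if g.n_tags else []

    columns, block_members = [], []
    snp_idx = 0
    names = []
    for b in range(n_blocks):
        size = min(g.block_size, g.n_snps - b * g.block_size)
        p = rng.uniform(0.1, 0.5)
        latent = rng.random(n_hap) < p
        members = []
        for j in range(size):
            is_anchor = j < 2 and (b in tag_blocks or copy_snp or size < 3)
            eps = 0.0 if is_anchor else rng.uniform(0.0, g.flip_noise_max)
            for _ in range(50):
                flips = rng.random(n_hap) < eps
                col = latent ^ flips
                maf = min(col.mean(), 1 - col.mean())
                if maf > 0.01:
                    break
            else:
                raise ValueError(
                    f"degenerate config: block {b} cannot reach MAF > 0.01"
                )
            columns.append(col.astype(np.uint8))
            names.append(f"snp{snp_idx:04d}")
            members.append(names[-1])
            snp_idx += 1
        block_members.append(members)

    gaps = rng.integers(g.min_gap, g.max_gap + 1, size=g.n_snps)
    positions = g.locus_start + np.cumsum(gaps)
    snps = pd.DataFrame({
        "id": names, "pos": positions,
        "ref": rng.choice(list("ACGT"), size=g.n_snps),
        "alt": rng.choice(list("ACGT"), size=g.n_snps),
    })
    # ref != alt
    same = snps["ref"] == snps["alt"]
    snps.loc[same, "alt"] = [
        "A" if r != "A" else "C" for r in snps.loc[same, "ref"]
    ]
    panel = PhasedPanel(
        snps=snps, haplotypes=np.column_stack(columns),
        samples=[f"sample{i:04d}" for i in range(g.n_samples)],
        populations=np.array(["SIM"] * g.n_samples),
    )
    tags = [block_members[b][0] for b in tag_blocks]
    causal = []
    for b in tag_blocks[: g.n_causal]:
        members = block_members[b]
        causal.append(members[1] if len(members) > 1 else members[0])
    truth = GroundTruth(causal_snps=causal, tag_snps=tags, blocks=block_members)
    return panel, truth


# ---------------------------------------------------------------------------
# FlowFISH screen
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_flowfish_screen(
    cfg: SimConfig,
    elements: pd.DataFrame,
    effects: Mapping[str, float],
    *,
    rng: np.random.Generator | None = None,
) -> tuple[list[pd.DataFrame], ff.SortModel]:
    """Guide-by-bin count tables for a sorted-cell screen.

    ``elements`` needs columns ``element``, ``start``, ``end``; ``effects``
    gives each element's true mean shift in sigma units (elements absent
    from the mapping have effect 0).  A ``promoter`` positive-control
    element is appended automatically.  Cells carrying a guide have normal
    log expression centered at the element effect; the sorter captures the
    configured bin fractions and reads per bin are negative binomial around
    the expected bin occupancy share of each guide.

    Returns one DataFrame per replicate (columns ``guide``, ``element``,
    ``targeting``, ``unsorted``, ``bin1..bin6``) and the sort model used.
    """
    p = cfg.flowfish
    rng = _rng(cfg.seed, "flowfish") if rng is None else rng
    model = ff.fit_sort_model(p.bin_fractions, p.tail_trim)

    records = []
    for _, row in elements.iterrows():
        eff = float(effects.get(row["element"], 0.0))
        for k in range(p.guides_per_element):
            records.append((f"{row['element']}_g{k:03d}", row["element"], True, eff))
    for k in range(p.guides_per_element):
        records.append((f"promoter_g{k:03d}", "promoter", True, p.promoter_effect))
    for k in range(p.n_nontargeting):
        records.append((f"NT_{k:05d}", None, False, 0.0))
    guides = pd.DataFrame(records, columns=["guide", "element", "targeting", "mu"])

    if p.depth_per_bin / len(guides) < 1:
        warnings.warn("bin depth too low to expect 1 read per guide per bin",
                      stacklevel=2)
    occupancy = ff.bin_probabilities(model, guides["mu"].to_numpy())  # (G, 6)

    replicates = []
    for _ in range(p.n_replicates):
        abundance = rng.lognormal(mean=0.0, sigma=0.3, size=len(guides))
        abundance /= abundance.sum()
        cell_share = abundance[:, None] * occupancy
        expected = p.depth_per_bin * cell_share / cell_share.sum(axis=0, keepdims=True)
        counts = _nb_draw(rng, expected, p.nb_size)
        rep = guides[["guide", "element", "targeting"]].copy()
        rep["unsorted"] = _nb_draw(rng, p.unsorted_depth * abundance, p.nb_size)
        for b in range(6):
            rep[f"bin{b + 1}"] = counts[:, b]
        replicates.append(rep)
    return replicates, model


# ---------------------------------------------------------------------------
# MPRA counts
# ---------------------------------------------------------------------------

def _random_tags(rng: np.random.Generator, n: int, length: int = 20) -> list[str]:
    bases = np.array(list("ACGT"))
    tags: set[str] = set()
    while len(tags) < n:
        draw = rng.integers(0, 4, size=(n - len(tags), length))
        for row in draw:
            tags.add("".join(bases[row]))
    out = sorted(tags)[:n]
    rng.shuffle(out)
    return out


def simulate_mpra_counts(
    cfg: SimConfig,
    variants: Sequence[str],
    allele_effects: Mapping[str, float] | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Barcode tag table with DNA input and replicate RNA output counts.

    Each variant gets ``tags_per_allele`` random 20-mer tags per allele
    (``ref``/``alt``).  RNA counts are negative binomial around
    ``dna * exp(allele_effect + gc_bias * (gc - 45) + artifact + tag noise)``
    rescaled to the RNA library depth; ``allele_effects`` gives the alt-
    versus-ref log effect per variant (default 0).  Planted artifact 5-mers
    shift any tag containing them.
    """
    p = cfg.mpra
    rng = _rng(cfg.seed, "mpra") if rng is None else rng
    allele_effects = dict(allele_effects or {})
    rows = []
    n_total = len(variants) * 2 * p.tags_per_allele
    tags = _random_tags(rng, n_total)
    i = 0
    for variant in variants:
        gc = int(np.clip(np.rint(rng.normal(45, 8)), 25, 75))
        for allele in ("ref", "alt"):
            eff = allele_effects.get(variant, 0.0) if allele == "alt" else 0.0
            for _ in range(p.tags_per_allele):
                rows.append((tags[i], variant, allele, gc, eff))
                i += 1
    df = pd.DataFrame(rows, columns=["tag", "variant", "allele", "gc", "true_effect"])

    artifact = np.zeros(len(df))
    for mer in p.artifact_5mers:
        has = df["tag"].str.contains(mer, regex=False).to_numpy()
        artifact = artifact + p.artifact_effect * has
    tag_noise = rng.normal(0.0, p.tag_noise_sd, size=len(df))
    log_activity = (df["true_effect"].to_numpy()
                    + p.gc_bias * (df["gc"].to_numpy() - 45.0)
                    + artifact + tag_noise)

    dna = _nb_draw(rng, np.full(len(df), p.dna_depth_per_tag), p.nb_size)
    df["dna"] = dna
    for r in range(1, p.n_replicates + 1):
        rate = np.maximum(dna, 0.5) * np.exp(log_activity)
        rate = rate / rate.sum() * (p.rna_depth_per_tag * len(df))
        df[f"rna{r}"] = _nb_draw(rng, rate, p.nb_size)
    return df


# ---------------------------------------------------------------------------
# Assay-hit tracks
# ---------------------------------------------------------------------------

def simulate_assay_hit_tracks(
    cfg: SimConfig,
    positions: Sequence[int],
    causal_indices: Sequence[int],
    *,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary hit/assayed vectors with positionally clustered hits.

    Hits occur in runs of ``cluster_len`` adjacent SNPs: each causal SNP
    seeds a run (with probability ``sensitivity``) centered on it, and a
    background run starts at any SNP with probability ``background``.
    SNPs are assayed independently with probability ``assay_rate``; hits
    are restricted to assayed SNPs.
    """
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be sorted strictly increasing")
    t = cfg.tracks
    rng = _rng(cfg.seed, "tracks") if rng is None else rng
    n = len(positions)
    hits = np.zeros(n, dtype=bool)
    half = t.cluster_len // 2
    for i in causal_indices:
        if rng.random() < t.sensitivity:
            hits[max(0, i - half): i + t.cluster_len - half] = True
    starts = np.flatnonzero(rng.random(n) < t.background)
    for s in starts:
        hits[s: s + t.cluster_len] = True
    assayed = rng.random(n) < t.assay_rate
    return hits & assayed, assayed


# ---------------------------------------------------------------------------
# Motif inputs
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def simulate_motif_inputs(
    cfg: SimConfig,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[list[PWM], pd.DataFrame]:
    """One information-rich PWM plus per-variant ref/alt flank pairs.

    Disrupting variants sit inside a planted consensus site at an
    information-rich column, with the alternate allele the worst base of
    that column.  Neutral variants carry a consensus site away from the
    variant position (so the region is bound but the variant lies outside
    the site) and a ref/alt substitution at the uncovered center.
    """
    m = cfg.motifs
    rng = _rng(cfg.seed, "motifs") if rng is None else rng
    L = m.motif_length
    probs = np.full((L, 4), (1.0 - m.consensus_prob) / 3.0)
    consensus_idx = rng.integers(0, 4, size=L)
    probs[np.arange(L), consensus_idx] = m.consensus_prob
    pwm = PWM(name="TF1", probs=probs)
    consensus = pwm.consensus
    bases = "ACGT"

    center = m.flank_length // 2
    rows = []
    for k in range(m.n_disrupting):
        col = L // 2                       # informative column hosting the variant
        start = center - col
        seq = list(_random_seq(rng, m.flank_length))
        seq[start:start + L] = list(consensus)
        ref_base = consensus[col]
        worst = bases[int(np.argmin(pwm.probs[col]))]
        ref = "".join(seq)
        seq[center] = worst
        alt = "".join(seq)
        rows.append((f"mvar{k:03d}", ref_base, worst, ref, alt, True))
    for k in range(m.n_neutral):
        seq = list(_random_seq(rng, m.flank_length))
        seq[:L] = list(consensus)          # bound site away from the variant
        ref_base = seq[center]
        alt_base = bases[(bases.index(ref_base) + 1 + int(rng.integers(0, 3))) % 4]
        ref = "".join(seq)
        seq[center] = alt_base
        alt = "".join(seq)
        rows.append((f"mvar{m.n_disrupting + k:03d}", ref_base, alt_base,
                     ref, alt, False))
    flanks = pd.DataFrame(
        rows, columns=["variant", "ref", "alt", "flank_ref", "flank_alt",
                       "disrupting"]
    )
    return [pwm], flanks


# ---------------------------------------------------------------------------
# Whole-locus orchestration
# ---------------------------------------------------------------------------

def simulate_locus(cfg: SimConfig) -> dict:
    """Generate a complete synthetic locus for the end-to-end pipeline.

    Returns a dict with the panel, ground truth, regulatory elements (one
    per causal SNP plus inert decoys), FlowFISH replicate tables, the MPRA
    tag table, and an accessibility mask covering all causal SNPs plus a
    random accessible background.
    """
    panel, truth = simulate_genotype_panel(cfg)
    rng = _rng(cfg.seed, "tracks")

    pos = panel.snps.set_index("id")["pos"]
    elements = []
    for i, snp in enumerate(truth.causal_snps):
        elements.append((f"elem{i:02d}", int(pos[snp]) - 30, int(pos[snp]) + 30))
        truth.element_effects[f"elem{i:02d}"] = cfg.flowfish.effect_size
    # inert decoy elements past the SNP span (clear of every footprint)
    n_decoys = max(cfg.flowfish.n_elements - len(elements), 0)
    hi = int(panel.snps["pos"].max())
    for j in range(n_decoys):
        c = hi + 500 + 400 * j
        elements.append((f"decoy{j:02d}", c - 30, c + 30))
        truth.element_effects[f"decoy{j:02d}"] = 0.0
    elements_df = pd.DataFrame(elements, columns=["element", "start", "end"])

    screens, sort_model = simulate_flowfish_screen(
        cfg, elements_df, truth.element_effects
    )

    for snp in truth.causal_snps:
        truth.allele_effects[snp] = cfg.mpra.allele_effect
    tag_table = simulate_mpra_counts(cfg, panel.snp_ids, truth.allele_effects)

    accessible = rng.random(len(panel.snps)) < 0.3
    causal_idx = [panel.snp_ids.index(s) for s in truth.causal_snps]
    accessible[causal_idx] = True

    return {
        "config": cfg,
        "panel": panel,
        "truth": truth,
        "elements": elements_df,
        "flowfish_replicates": screens,
        "sort_model": sort_model,
        "mpra_tags": tag_table,
        "accessible": accessible,
    }


# ---------------------------------------------------------------------------
# Writers (plain-text interchange formats)
# ---------------------------------------------------------------------------

def write_vcf(panel: PhasedPanel, path: str | Path, *, chrom: str = "chrS") -> None:
    """Write the panel as a phased VCF (GT only)."""
    H = panel.haplotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        for j, row in panel.snps.iterrows():
            gts = "\t".join(
                f"{H[2 * i, j]}|{H[2 * i + 1, j]}" for i in range(len(panel.samples))
            )
            fh.write(f"{chrom}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n")


def write_bed(intervals: pd.DataFrame, path: str | Path,
              *, chrom: str = "chrS") -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for _, row in intervals.iterrows():
            name = row.get("element", row.get("name", "."))
            score = row.get("score", 0)
            fh.write(f"{chrom}\t{int(row['start']) - 1}\t{int(row['end'])}\t"
                     f"{name}\t{score}\n")


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    seqio_write(records, str(path), "fasta")


def write_manifest(truth: GroundTruth, cfg: SimConfig, path: str | Path) -> None:
    """JSON ground-truth manifest for a simulated locus."""
    payload = {
        "seed": cfg.seed,
        "causal_snps": truth.causal_snps,
        "tag_snps": truth.tag_snps,
        "blocks": truth.blocks,
        "element_effects": truth.element_effects,
        "allele_effects": truth.allele_effects,
        "disrupted_variants": truth.disrupted_variants,
        "config": asdict(cfg),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_locus(sim: dict, outdir: str | Path) -> None:
    """Write every synthetic input of a simulated locus to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(sim["panel"], outdir / "panel.vcf")
    write_bed(sim["elements"], outdir / "elements.bed")
    for i, rep in enumerate(sim["flowfish_replicates"], start=1):
        rep.to_csv(outdir / f"flowfish_rep{i}.tsv", sep="\t", index=False)
    sim["mpra_tags"].to_csv(outdir / "mpra_tags.tsv", sep="\t", index=False)
    pwms, flanks = simulate_motif_inputs(sim["config"])
    write_meme(pwms, outdir / "motifs.meme")
    seqs = {}
    for _, row in flanks.iterrows():
        seqs[f"{row['variant']}_ref"] = row["flank_ref"]
        seqs[f"{row['variant']}_alt"] = row["flank_alt"]
    write_fasta(seqs, outdir / "flanks.fasta")
    flanks.to_csv(outdir / "motif_flanks.tsv", sep="\t", index=False)
    write_manifest(sim["truth"], sim["config"], outdir / "truth.json")
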