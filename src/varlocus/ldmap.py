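"""Linkage disequilibrium, tag-SNP expansion, and haplotype merging.

Starting from a phased genotype panel for a locus, this module computes
pairwise r-squared from haplotype frequencies, expands GWAS tag SNPs into
tight-LD sets (r2 > 0.8 by default), merges overlapping sets into
independent disease-associated haplotypes (within a population by any
shared SNP, across populations by shared tag SNPs), and estimates the
population frequency of each haplotype's joint minor-allele configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PhasedPanel",
    "Haplotype",
    "read_vcf",
    "filter_panel",
    "hwe_exact_p",
    "compute_r2",
    "ld_expand_tags",
    "merge_haplotypes",
    "haplotype_frequency",
    "haplotype_table",
]


@dataclass
class PhasedPanel:
    """Phased biallelic SNVs for a locus.

    ``snps`` has columns ``id``, ``pos`` (1-based, strictly increasing),
    ``ref``, ``alt``.  ``haplotypes`` is a (2 * n_samples, n_snps) 0/1
    matrix; rows 2i and 2i+1 are the two phased haplotypes of sample i.
    ``populations`` labels each sample.
    """

    snps: pd.DataFrame
    haplotypes: np.ndarray
    samples: list[str]
    populations: np.ndarray

    def __post_init__(self) -> None:
        pos = self.snps["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError("SNP positions must be strictly increasing")
        if self.haplotypes.shape != (2 * len(self.samples), len(self.snps)):
            raise ValueError("haplotype matrix shape does not match snps/samples")
        vals = np.unique(self.haplotypes)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("haplotype entries must be 0/1 (filter missing first)")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["id"])

    def hap_rows(self, pop: str | None = None) -> np.ndarray:
        """Haplotype matrix restricted to one population (or all)."""
        if pop is None:
            return self.haplotypes
        mask = np.repeat(self.populations == pop, 2)
        if not mask.any():
            raise ValueError(f"no samples in population {pop!r}")
        return self.haplotypes[mask]

    def maf(self, pop: str | None = None) -> np.ndarray:
        freq = self.hap_rows(pop).mean(axis=0)
        return np.minimum(freq, 1.0 - freq)


@dataclass
class Haplotype:
    """A merged set of SNPs in tight LD with one or more tag SNPs."""

    id: int
    members: set[str]
    tags: set[str]
    populations: set[str]
    members_by_pop: dict[str, set[str]] = field(default_factory=dict)
    frequency: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Input and filtering
# ---------------------------------------------------------------------------

def read_vcf(path: str, population_map: Mapping[str, str] | None = None) -> PhasedPanel:
    """Read a phased VCF into a PhasedPanel (biallelic SNVs only).

    Missing alleles are imputed to the major allele with a warning;
    ``population_map`` assigns a population label per sample (default
    ``"ALL"``).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, cols = [], []
    n_missing = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        gts = np.array(var.genotypes)           # (n, 3) [a0, a1, phased]
        if not np.all(gts[:, 2]):
            raise ValueError(f"unphased genotype at {var.ID or var.POS}")
        alleles = gts[:, :2].astype(float).ravel()
        missing = alleles < 0
        if missing.any():
            n_missing += int(missing.sum())
            major = 1.0 if np.nanmean(np.where(missing, np.nan, alleles)) > 0.5 else 0.0
            alleles[missing] = major
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", var.POS, var.REF, var.ALT[0]))
        cols.append(alleles.astype(np.uint8))
    if n_missing:
        warnings.warn(f"imputed {n_missing} missing alleles to the major allele",
                      stacklevel=2)
    snps = pd.DataFrame(rows, columns=["id", "pos", "ref", "alt"])
    pops = np.array([population_map.get(s, "ALL") if population_map else "ALL"
                     for s in samples])
    return PhasedPanel(snps=snps, haplotypes=np.column_stack(cols),
                       samples=samples, populations=pops)


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg equilibrium p-value (Wigginton et al. style).

    Two-sided: the probability of observing a heterozygote count at least as
    unlikely as the one seen, under the exact conditional distribution given
    allele counts.
    """
    n = n_het + n_hom1 + n_hom2
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n == 0:
        return 1.0
    # exact conditional distribution of het count given rare-allele count
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if (mid % 2) != (n_rare % 2):
        mid += 1
    probs = {mid: 1.0}
    het, hom_r, hom_c = mid, (n_rare - mid) // 2, n - mid - (n_rare - mid) // 2
    h, r, c = het, hom_r, hom_c
    while h >= 2:
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (r + 1) * (c + 1))
        h, r, c = h - 2, r + 1, c + 1
    h, r, c = het, hom_r, hom_c
    while h <= n_rare - 2 and r > 0 and c > 0:
        probs[h + 2] = probs[h] * 4.0 * r * c / ((h + 2) * (h + 1))
        h, r, c = h + 2, r - 1, c - 1
    total = sum(probs.values())
    p_obs = probs.get(n_het, 0.0) / total
    return min(1.0, sum(p for p in probs.values() if p / total <= p_obs + 1e-12) / total)


def filter_panel(
    panel: PhasedPanel,
    *,
    min_maf: float = 0.01,
    hwe_alpha: float = 0.01,
) -> PhasedPanel:
    """Drop SNPs with MAF <= min_maf or exact-HWE p <= hwe_alpha."""
    maf = panel.maf()
    keep = maf > min_maf
    H = panel.haplotypes
    for j in np.flatnonzero(keep):
        g = H[0::2, j] + H[1::2, j]
        p = hwe_exact_p(int((g == 1).sum()), int((g == 0).sum()), int((g == 2).sum()))
        if p <= hwe_alpha:
            keep[j] = False
    return PhasedPanel(
        snps=panel.snps.loc[keep].reset_index(drop=True),
        haplotypes=H[:, keep],
        samples=panel.samples,
        populations=panel.populations,
    )


# ---------------------------------------------------------------------------
# LD and haplotypes
# ---------------------------------------------------------------------------

def compute_r2(panel: PhasedPanel, pop: str | None = None) -> pd.DataFrame:
    """Pairwise haplotype-frequency r2 between all SNPs of the panel.

    Computed on phased haplotypes as ``D^2 / (pA qA pB qB)``, which for 0/1
    haplotype columns equals the squared Pearson correlation.  Monomorphic
    SNPs get NaN rows/columns.
    """
    H = panel.hap_rows(pop).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r = np.atleast_2d(np.corrcoef(H.T))
    r2 = r**2
    mono = H.std(axis=0) == 0
    r2[mono, :] = np.nan
    r2[:, mono] = np.nan
    return pd.DataFrame(r2, index=panel.snp_ids, columns=panel.snp_ids)


def ld_expand_tags(
    r2: pd.DataFrame,
    tags: Iterable[str],
    threshold: float = 0.8,
) -> dict[str, set[str]]:
    """Expand each tag SNP into its tight-LD set {tag} + {s : r2(s, tag) > t}.

    The inequality is strict.  Tags absent from the panel are skipped with a
    warning; NaN r2 (monomorphic partners) never qualifies.
    """
    sets: dict[str, set[str]] = {}
    for tag in tags:
        if tag not in r2.index:
            warnings.warn(f"tag SNP {tag!r} absent from panel; skipped", stacklevel=2)
            continue
        col = r2[tag]
        partners = set(col.index[(col > threshold).to_numpy(dtype=bool)])
        partners.discard(tag)
        sets[tag] = {tag} | partners
    return sets


def merge_haplotypes(
    ld_sets: Mapping[str, Mapping[str, set[str]]] | Mapping[str, set[str]],
    positions: Mapping[str, int] | None = None,
) -> list[Haplotype]:
    """Merge tight-LD sets into independent haplotypes.

    ``ld_sets`` maps population -> tag -> LD set (a plain tag -> set mapping
    is treated as a single population).  Within a population, sets sharing
    any SNP are merged transitively (connected components of the overlap
    graph); across populations, haplotypes sharing a tag SNP are merged.
    Output haplotypes are ordered by their leftmost member position when
    ``positions`` is given, else by smallest member id.
    """
    if ld_sets and not isinstance(next(iter(ld_sets.values())), Mapping):
        ld_sets = {"ALL": ld_sets}  # type: ignore[assignment]

    g = nx.Graph()
    for pop, tag_sets in ld_sets.items():  # type: ignore[union-attr]
        for tag in tag_sets:
            g.add_node((pop, tag))
        tags = list(tag_sets)
        for i, t1 in enumerate(tags):
            for t2 in tags[i + 1:]:
                if tag_sets[t1] & tag_sets[t2]:
                    g.add_edge((pop, t1), (pop, t2))
    # cross-population: same tag SNP id
    by_tag: dict[str, list] = {}
    for node in g.nodes:
        by_tag.setdefault(node[1], []).append(node)
    for nodes in by_tag.values():
        for a, b in zip(nodes, nodes[1:]):
            g.add_edge(a, b)

    haplotypes = []
    for comp in nx.connected_components(g):
        members: set[str] = set()
        tags: set[str] = set()
        pops: set[str] = set()
        by_pop: dict[str, set[str]] = {}
        for pop, tag in comp:
            s = set(ld_sets[pop][tag])  # type: ignore[index]
            members |= s
            tags.add(tag)
            pops.add(pop)
            by_pop.setdefault(pop, set()).update(s)
        haplotypes.append(
            Haplotype(id=-1, members=members, tags=tags, populations=pops,
                      members_by_pop=by_pop)
        )
    if positions is not None:
        haplotypes.sort(key=lambda h: min(positions[m] for m in h.members))
    else:
        haplotypes.sort(key=lambda h: min(h.members))
    for i, h in enumerate(haplotypes, start=1):
        h.id = i
    return haplotypes


def haplotype_frequency(
    panel: PhasedPanel,
    members: Iterable[str],
    pop: str | None = None,
) -> float:
    """Frequency of the joint minor-allele configuration across haplotypes.

    The minor allele of each member SNP is determined in the queried
    population; the returned value is the fraction of phased haplotypes
    carrying the minor allele at every member simultaneously.
    """
    members = list(members)
    ids = panel.snp_ids
    missing = [m for m in members if m not in ids]
    if missing:
        raise KeyError(f"member SNP(s) not genotyped: {missing}")
    idx = [ids.index(m) for m in members]
    H = panel.hap_rows(pop)[:, idx]
    freq = H.mean(axis=0)
    minor = np.where(freq <= 0.5, 1, 0)
    return float(np.all(H == minor[None, :], axis=1).mean())


def haplotype_table(
    panel: PhasedPanel,
    haplotypes: Sequence[Haplotype],
    *,
    min_frequency: float = 0.005,
) -> pd.DataFrame:
    """Summary table of merged haplotypes with per-population frequencies."""
    rows = []
    for h in haplotypes:
        for pop in sorted(h.populations):
            f = haplotype_frequency(panel, h.members_by_pop.get(pop, h.members), pop)
            h.frequency[pop] = f
        rows.append({
            "haplotype": h.id,
            "n_members": len(h.members),
            "members": ",".join(sorted(h.members)),
            "tags": ",".join(sorted(h.tags)),
            "populations": ",".join(sorted(h.populations)),
            "min_frequency": min(h.frequency.values()),
            "rare_flag": min(h.frequency.values()) <= min_frequency,
        })
    return pd.DataFrame(rows)
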