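"""Genetic diversity statistics: segregating sites, multiallelic fraction,
nucleotide diversity (θπ), Watterson's estimator (θw) and Tajima's D.

Haplotype matrices are (n_haplotypes, n_sites) integer matrices of allele
indices (0 = reference, 1..3 = alternates, -1 = missing). Diploid genotypes
are decomposed into 2n haplotype rows; because every estimator used here is a
function of per-site allele counts only, phase does not affect the values.

Missing-data convention: at each site, pairs with a missing member contribute
no difference (the site is dropped for that pair) and the denominator stays
the full number of haplotype pairs; Tajima constants use the number of
haplotype rows (the region-wide modal sample size).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix, SampleMetadata, VariantTable

MISSING = -1


@dataclass
class DiversityStats:
    """Per (population, region) summary; per-site θ estimates."""

    n: int                       # haplotype sample size (2 x diploids)
    L: int                       # region length in bp
    S: int                       # segregating sites
    multiallelic_fraction: float  # NaN when S == 0
    theta_pi: float
    theta_w: float
    tajima_d: float              # NaN (undefined) when S == 0
    variant_density: float       # S / L

    def to_dict(self) -> dict:
        return asdict(self)


def _allele_counts(haps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site counts of each allele index and of non-missing calls.

    Returns (counts, m) with counts shape (max_allele + 1, n_sites) and m the
    per-site non-missing totals.
    """
    haps = np.asarray(haps)
    max_allele = int(haps.max(initial=0))
    counts = np.stack([(haps == a).sum(axis=0) for a in range(max_allele + 1)])
    m = counts.sum(axis=0)
    return counts, m


def count_segregating(variants: VariantTable, genotypes: GenotypeMatrix,
                      sample_idx=None) -> tuple[int, float]:
    """Count segregating sites and the fraction with more than two alleles.

    A site is segregating when at least two distinct non-missing alleles are
    observed within the sample subset. Returns (0, NaN) when nothing
    segregates.
    """
    if sample_idx is None:
        sample_idx = np.arange(genotypes.n_samples)
    sample_idx = np.asarray(sample_idx)
    if sample_idx.size == 0:
        raise ValueError("empty sample subset")
    haps = genotypes.take_samples(sample_idx).to_haplotypes()
    counts, _ = _allele_counts(haps)
    n_distinct = (counts > 0).sum(axis=0)
    S = int((n_distinct >= 2).sum())
    if S == 0:
        return 0, float("nan")
    multi = int((n_distinct > 2).sum())
    return S, multi / S


def segregating_sites(haps: np.ndarray) -> int:
    counts, _ = _allele_counts(haps)
    return int(((counts > 0).sum(axis=0) >= 2).sum())


def mean_pairwise_difference(haps: np.ndarray) -> float:
    """Π: mean number of differences over all n(n-1)/2 haplotype pairs.

    Multiallelic sites contribute through the full heterozygosity term
    (all cross-allele pairs count as differences).
    """
    haps = np.asarray(haps)
    n = haps.shape[0]
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    counts, m = _allele_counts(haps)
    diff_pairs = (m.astype(float) ** 2 - (counts.astype(float) ** 2).sum(axis=0)) / 2.0
    total_pairs = n * (n - 1) / 2.0
    return float(diff_pairs.sum() / total_pairs)


def nucleotide_diversity(haps: np.ndarray, L: int) -> float:
    """θπ per site: mean pairwise difference divided by region length L."""
    if L < np.asarray(haps).shape[1]:
        raise ValueError("L smaller than the number of sites")
    return mean_pairwise_difference(haps) / L


def harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i ** power for i in range(1, n)))


def watterson_theta(S: int, n: int, L: int) -> float:
    """θw per site = S / (a1 L), a1 = sum_{i<n} 1/i."""
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    if S == 0:
        return 0.0
    return S / (harmonic(n) * L)


def tajima_constants(n: int) -> dict[str, float]:
    """The 1989 normalizing constants for a sample of n haplotypes."""
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(haps: np.ndarray, L: int | None = None) -> float:
    """Tajima's D from a haplotype matrix; NaN (undefined) when S = 0.

    D = (Π - S/a1) / sqrt(e1 S + e2 S (S-1)) with Π the total (not per-site)
    mean pairwise difference.
    """
    haps = np.asarray(haps)
    n = haps.shape[0]
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    S = segregating_sites(haps)
    if S == 0:
        return float("nan")
    pi_total = mean_pairwise_difference(haps)
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return float((pi_total - S / k["a1"]) / np.sqrt(var))


def diversity_stats(variants: VariantTable, genotypes: GenotypeMatrix,
                    sample_idx, L: int) -> DiversityStats:
    """All diversity statistics for one sample subset over one region."""
    sample_idx = np.asarray(sample_idx)
    if sample_idx.size == 0:
        raise ValueError("empty sample subset")
    S, multi_frac = count_segregating(variants, genotypes, sample_idx)
    haps = genotypes.take_samples(sample_idx).to_haplotypes()
    n = haps.shape[0]
    if S == 0:
        return DiversityStats(n=n, L=L, S=0, multiallelic_fraction=float("nan"),
                              theta_pi=0.0, theta_w=0.0, tajima_d=float("nan"),
                              variant_density=0.0)
    return DiversityStats(
        n=n, L=L, S=S, multiallelic_fraction=multi_frac,
        theta_pi=nucleotide_diversity(haps, L),
        theta_w=watterson_theta(S, n, L),
        tajima_d=tajimas_d(haps, L),
        variant_density=S / L,
    )


def diversity_table(variants: VariantTable, genotypes: GenotypeMatrix,
                    metadata: list[SampleMetadata], L: int,
                    region_name: str = "region",
                    by: str = "site_species") -> pd.DataFrame:
    """One row of diversity statistics per population.

    ``by`` is "site_species" (default), "site" or "species".
    """
    rows = []
    for pop, idx in group_samples(metadata, by).items():
        stats = diversity_stats(variants, genotypes, idx, L)
        row = {"population": pop, "region": region_name}
        row.update(stats.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def group_samples(metadata: list[SampleMetadata], by: str = "site_species"
                  ) -> dict[str, np.ndarray]:
    """Sample index groups keyed by population label, in first-seen order."""
    keys = []
    for m in metadata:
        if by == "site":
            keys.append(m.site)
        elif by == "species":
            keys.append(m.species)
        elif by == "site_species":
            keys.append(f"{m.site}:{m.species}")
        elif by == "zone":
            keys.append(m.zone)
        else:
            raise ValueError(f"unknown grouping {by!r}")
    groups: dict[str, list[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    return {k: np.array(v) for k, v in groups.items()}
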