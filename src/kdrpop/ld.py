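"""Two-locus linkage disequilibrium from unphased diploid genotypes.

Haplotype frequencies are estimated by EM maximum likelihood under
Hardy-Weinberg equilibrium (the classic two-locus estimator of the Hill 1974
lineage). Each locus is first collapsed to a biallelic dosage of a focal
allele — at the triallelic V402L site each mutant nucleotide (g>t and g>c) is
analyzed in turn against all other alleles pooled, which is how the
402L(g>t) vs 1527T and 402L(g>c) vs 1527T comparisons are constructed.

Only the double-heterozygote cell of the 3x3 genotype-count table is
phase-ambiguous; the E-step splits it between the coupling (AB/ab) and
repulsion (Ab/aB) configurations, and the M-step re-estimates the four
haplotype frequencies. Allele-frequency margins are invariant under the
update, so the fitted frequencies always reproduce the data margins exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix, SampleMetadata, VariantTable
from .diversity import group_samples

MISSING = -1


@dataclass
class LDResult:
    """EM-fitted two-locus haplotype frequencies and summary LD statistics."""

    f_AB: float
    f_Ab: float
    f_aB: float
    f_ab: float
    p_A: float
    p_B: float
    D: float
    r2: float          # NaN when not defined (monomorphic margin)
    n: int
    iterations: int
    converged: bool
    defined: bool
    saddle: bool = False
    loglik: list[float] = field(default_factory=list, repr=False)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([self.f_AB, self.f_Ab, self.f_aB, self.f_ab])


def collapse_to_biallelic(calls: np.ndarray, focal: int) -> np.ndarray:
    """0/1/2 dosage of a focal mutant allele; all other alleles pooled.

    ``calls`` has shape (n_samples, 2); -1 marks missing. The focal allele
    must be a named mutant (index >= 1): the reference is never a focal
    allele in the resistance tables.
    """
    calls = np.asarray(calls)
    if focal < 1:
        raise ValueError("focal allele must be a mutant (index >= 1), not ref")
    dosage = (calls == focal).sum(axis=1).astype(np.int64)
    dosage[(calls == MISSING).any(axis=1)] = MISSING
    return dosage


def two_locus_counts(dos1: np.ndarray, dos2: np.ndarray) -> np.ndarray:
    """3x3 table n[g, h] of joint dosages; missing-at-either excluded."""
    dos1 = np.asarray(dos1)
    dos2 = np.asarray(dos2)
    ok = (dos1 >= 0) & (dos2 >= 0)
    counts = np.zeros((3, 3), dtype=np.int64)
    for g, h in zip(dos1[ok], dos2[ok]):
        counts[g, h] += 1
    return counts


def _cell_probs(f: np.ndarray) -> np.ndarray:
    """Genotype-cell probabilities under HWE for f = (f_AB, f_Ab, f_aB, f_ab)."""
    fAB, fAb, faB, fab = f
    p = np.empty((3, 3))
    p[2, 2] = fAB ** 2
    p[2, 1] = 2 * fAB * fAb
    p[2, 0] = fAb ** 2
    p[1, 2] = 2 * fAB * faB
    p[1, 1] = 2 * fAB * fab + 2 * fAb * faB
    p[1, 0] = 2 * fAb * fab
    p[0, 2] = faB ** 2
    p[0, 1] = 2 * faB * fab
    p[0, 0] = fab ** 2
    return p


def log_likelihood(counts: np.ndarray, f: np.ndarray) -> float:
    p = _cell_probs(f)
    mask = counts > 0
    with np.errstate(divide="ignore"):
        lp = np.log(p[mask])
    return float((counts[mask] * lp).sum())


def em_haplotype_frequencies(counts: np.ndarray, tol: float = 1e-10,
                             max_iter: int = 1000) -> LDResult:
    """EM maximum-likelihood haplotype frequencies from a 3x3 dosage table.

    Initialization is at linkage equilibrium f_XY = p_X p_Y; iteration stops
    when max |Δf| < tol. When either margin is monomorphic the result is
    flagged ``defined=False`` and r² is NaN. When every individual is a double
    heterozygote the likelihood is flat between coupling and repulsion and the
    equilibrium start is a stationary point: the result is reported as D = 0
    with ``saddle=True``.
    """
    counts = np.asarray(counts)
    if counts.shape != (3, 3):
        raise ValueError("counts must be a 3x3 table")
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    n = int(counts.sum())
    if n == 0:
        raise ValueError("empty count table")

    g = np.arange(3)
    p_A = float((counts.sum(axis=1) * g).sum() / (2 * n))
    p_B = float((counts.sum(axis=0) * g).sum() / (2 * n))

    if p_A in (0.0, 1.0) or p_B in (0.0, 1.0):
        f = np.array([p_A * p_B, p_A * (1 - p_B), (1 - p_A) * p_B,
                      (1 - p_A) * (1 - p_B)])
        return LDResult(*f, p_A=p_A, p_B=p_B, D=0.0, r2=float("nan"), n=n,
                        iterations=0, converged=True, defined=False,
                        loglik=[log_likelihood(counts, f)])

    # haplotype counts contributed by phase-unambiguous cells
    n11 = counts[1, 1]
    cAB = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    cAb = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    caB = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    cab = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]

    f = np.array([p_A * p_B, p_A * (1 - p_B), (1 - p_A) * p_B,
                  (1 - p_A) * (1 - p_B)])
    ll = [log_likelihood(counts, f)]
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        denom = f[0] * f[3] + f[1] * f[2]
        w = 0.5 if denom == 0 else f[0] * f[3] / denom  # coupling weight
        f_new = np.array([
            (cAB + w * n11) / (2 * n),
            (cAb + (1 - w) * n11) / (2 * n),
            (caB + (1 - w) * n11) / (2 * n),
            (cab + w * n11) / (2 * n),
        ])
        delta = float(np.abs(f_new - f).max())
        f = f_new
        ll.append(log_likelihood(counts, f))
        if delta < tol:
            converged = True
            break

    D = float(f[0] - p_A * p_B)
    denom = p_A * (1 - p_A) * p_B * (1 - p_B)
    r2 = float(D * D / denom)
    saddle = bool(n11 == n)
    return LDResult(*f, p_A=p_A, p_B=p_B, D=D, r2=r2, n=n,
                    iterations=iterations, converged=converged, defined=True,
                    saddle=saddle, loglik=ll)


def phased_r2(hap1: np.ndarray, hap2: np.ndarray) -> float:
    """Count-based r² from phased binary haplotype columns (the oracle route).

    NaN when either column is monomorphic.
    """
    hap1 = np.asarray(hap1, dtype=float)
    hap2 = np.asarray(hap2, dtype=float)
    p_A = hap1.mean()
    p_B = hap2.mean()
    if p_A in (0.0, 1.0) or p_B in (0.0, 1.0):
        return float("nan")
    f_AB = (hap1 * hap2).mean()
    D = f_AB - p_A * p_B
    return float(D * D / (p_A * (1 - p_A) * p_B * (1 - p_B)))


def ld_pair(genotypes: GenotypeMatrix, variants: VariantTable,
            locus1: tuple[str, int], focal1: int,
            locus2: tuple[str, int], focal2: int,
            sample_idx=None, tol: float = 1e-10) -> LDResult:
    """EM LD between a focal allele at each of two loci for a sample subset."""
    i1 = variants.index_of(*locus1)
    i2 = variants.index_of(*locus2)
    calls = genotypes.calls
    if sample_idx is not None:
        calls = calls[np.asarray(sample_idx)]
    d1 = collapse_to_biallelic(calls[:, i1], focal1)
    d2 = collapse_to_biallelic(calls[:, i2], focal2)
    return em_haplotype_frequencies(two_locus_counts(d1, d2), tol=tol)


def ld_table(genotypes: GenotypeMatrix, variants: VariantTable,
             panel, metadata: list[SampleMetadata],
             species: str = "An_coluzzii", min_n: int = 10,
             render_undefined_as_zero: bool = False
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site and species-pooled r² between each V402L mutant and 1527T.

    Returns (wide, long): the wide table mirrors the published layout
    (population, n, r² for 402L(g>c) vs 1527T and 402L(g>t) vs 1527T); the
    long table carries haplotype frequencies, D and convergence diagnostics.
    Undefined r² (monomorphic margin) renders as NA unless
    ``render_undefined_as_zero`` is set.
    """
    locus_402 = panel.locus("402")
    locus_1527 = panel.locus("1527")
    # allele index of each mutant within the 402 alt list
    gt_idx = 1 + locus_402.alts.index(locus_402.mutant_allele("L1"))
    gc_idx = 1 + locus_402.alts.index(locus_402.mutant_allele("L2"))
    t_idx = 1 + locus_1527.alts.index(locus_1527.mutant_allele("T"))
    key_402 = (locus_402.contig, locus_402.pos)
    key_1527 = (locus_1527.contig, locus_1527.pos)

    keep = [i for i, m in enumerate(metadata) if m.species == species]
    sites = group_samples([metadata[i] for i in keep], by="site")
    groups = {site: np.asarray(keep)[idx] for site, idx in sites.items()}
    groups[species] = np.asarray(keep)  # pooled row, published-table convention

    wide_rows, long_rows = [], []
    for pop, idx in groups.items():
        if idx.size == 0:
            continue
        row = {"population": pop, "n": int(idx.size),
               "low_n": bool(idx.size < min_n)}
        for label, focal in [("r2_402Lgc_vs_1527T", gc_idx),
                             ("r2_402Lgt_vs_1527T", gt_idx)]:
            res = ld_pair(genotypes, variants, key_402, focal, key_1527, t_idx,
                          sample_idx=idx)
            value = res.r2
            if not res.defined and render_undefined_as_zero:
                value = 0.0
            row[label] = value
            long_rows.append({
                "population": pop, "pair": label, "n": res.n,
                "f_AB": res.f_AB, "f_Ab": res.f_Ab, "f_aB": res.f_aB,
                "f_ab": res.f_ab, "p_A": res.p_A, "p_B": res.p_B,
                "D": res.D, "r2": res.r2, "iterations": res.iterations,
                "converged": res.converged, "defined": res.defined,
                "saddle": res.saddle,
            })
        wide_rows.append(row)
    return pd.DataFrame(wide_rows), pd.DataFrame(long_rows)
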