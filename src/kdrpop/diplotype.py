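"""The kdr three-locus panel (995 / 402 / 1527), haplotype labelling,
diplotype-group classification, group frequencies, and the clustering / PCA
views of genotype structure.

Haplotypes are labelled by one allele label per panel locus in the fixed
order 995, 402, 1527 — e.g. "FVI" (995F + 402V + 1527I, the classic kdr
background), "LL1T" (wild-type 995 with the g>t V402L mutant plus 1527T).
A diplotype is the unordered pair of haplotype labels an individual carries;
five named groups plus a catch-all "OD" (other diplotypes) cover the
observed combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core_io import GenotypeMatrix, SampleMetadata, VariantTable

MISSING = -1

#: the five named diplotype groups, as canonically ordered label pairs
NAMED_GROUPS = {
    ("FVI", "FVI"): "FVI/FVI",
    ("FL1T", "LVI"): "FL1T/LVI",
    ("FL2T", "LVI"): "FL2T/LVI",
    ("LL1T", "LL1T"): "LL1T/LL1T",
    ("LL1T", "LL2T"): "LL1T/LL2T",
}
OD = "OD"

#: preference order for phase-ambiguous unphased genotypes: the coupling rule
#: places the resistance alleles (995F, 402L, 1527T) on the same haplotype,
#: so the triple heterozygote is named FL1T/LVI rather than FVI/LL1T.
COUPLING_PREFERENCE = ["FL1T/LVI", "FL2T/LVI", "FVI/FVI", "LL1T/LL1T",
                       "LL1T/LL2T"]

GROUP_ORDER = ["FVI/FVI", "FL1T/LVI", "FL2T/LVI", "LL1T/LL1T", "LL1T/LL2T", OD]


@dataclass(frozen=True)
class PanelLocus:
    """One panel site with its allele -> label map (index 0 = reference)."""

    name: str
    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    labels: tuple[str, ...]  # labels[i] for allele index i

    def __post_init__(self):
        if len(self.labels) != 1 + len(self.alts):
            raise ValueError(f"locus {self.name}: one label per allele required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"locus {self.name}: labels must be unique")

    def label_of(self, allele_index: int) -> str:
        if not 0 <= allele_index < len(self.labels):
            raise ValueError(
                f"allele index {allele_index} not in panel map for locus "
                f"{self.name}")
        return self.labels[allele_index]

    def allele_of(self, label: str) -> int:
        return self.labels.index(label)

    def mutant_allele(self, label: str) -> str:
        """Nucleotide of a mutant label (e.g. 'L1' -> the g>t base)."""
        idx = self.allele_of(label)
        if idx == 0:
            raise ValueError(f"{label!r} is the reference label")
        return self.alts[idx - 1]


@dataclass(frozen=True)
class KdrPanel:
    """Exactly three loci in fixed order 995, 402, 1527."""

    loci: tuple[PanelLocus, PanelLocus, PanelLocus]

    def __post_init__(self):
        if len(self.loci) != 3:
            raise ValueError("panel must have exactly three loci")

    def locus(self, name: str) -> PanelLocus:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(name)

    def variant_indices(self, variants: VariantTable) -> list[int]:
        return [variants.index_of(l.contig, l.pos) for l in self.loci]

    def haplotype_labels(self) -> list[str]:
        """All combinatorially possible haplotype labels, locus order fixed."""
        return ["".join(combo) for combo in
                product(*[loc.labels for loc in self.loci])]

    def parse_label(self, label: str) -> tuple[int, int, int]:
        """Haplotype label -> allele indices at the three loci."""
        alleles = []
        rest = label
        for loc in self.loci:
            for tok in sorted(loc.labels, key=len, reverse=True):
                if rest.startswith(tok):
                    alleles.append(loc.allele_of(tok))
                    rest = rest[len(tok):]
                    break
            else:
                raise ValueError(f"cannot parse haplotype label {label!r}")
        if rest:
            raise ValueError(f"cannot parse haplotype label {label!r}")
        return tuple(alleles)


def default_kdr_panel() -> KdrPanel:
    """The shipped kdr panel.

    The 995 site is modelled as one triallelic locus (ref L; alt1 995F; alt2
    995S) and 402 as the triallelic V402L site (g>t = L1, g>c = L2). Panel
    coordinates are configurable; the published coordinates for this gene are
    internally inconsistent across sources, and the 1527 position shipped
    here is a synthetic placeholder within the Vgsc span.
    """
    return KdrPanel(loci=(
        PanelLocus("995", "2L", 2422652, "A", ("T", "C"), ("L", "F", "S")),
        PanelLocus("402", "2L", 23921228, "G", ("T", "C"), ("V", "L1", "L2")),
        PanelLocus("1527", "2L", 2429745, "T", ("C",), ("I", "T")),
    ))


def default_ace1_panel() -> dict:
    """The Ace1 organophosphate-resistance site (G280S) and gene span."""
    return {
        "locus": PanelLocus("280", "2R", 3492074, "G", ("A",), ("G", "S")),
        "gene_span": ("2R", 3483099, 3497400),
    }


def label_haplotype(alleles, panel: KdrPanel) -> str:
    """Label one haplotype from its allele indices at the three panel loci."""
    alleles = tuple(int(a) for a in alleles)
    if any(a == MISSING for a in alleles):
        raise ValueError("all three panel loci must be called")
    return "".join(loc.label_of(a) for loc, a in zip(panel.loci, alleles))


def _canonical_pair(h1: str, h2: str) -> tuple[str, str]:
    return tuple(sorted((h1, h2)))


def group_of_pair(h1: str, h2: str) -> str:
    return NAMED_GROUPS.get(_canonical_pair(h1, h2), OD)


@dataclass
class DiplotypeCall:
    sample_id: str
    group: str
    hap_pair: tuple[str, str] | None = None  # unordered; None when unresolvable
    ambiguous: bool = False                  # only possible for unphased input
    missing: bool = False


def _phase_resolutions(genotype) -> set[tuple[str, str]]:
    """All unordered haplotype-pair label resolutions of an unphased genotype.

    ``genotype`` is a per-locus sequence of unordered label pairs.
    """
    resolutions = set()
    for choice in product(*[((a, b), (b, a)) for a, b in genotype]):
        h1 = "".join(c[0] for c in choice)
        h2 = "".join(c[1] for c in choice)
        resolutions.add(_canonical_pair(h1, h2))
    return resolutions


def classify_diplotype(sample_id: str, calls: np.ndarray, panel: KdrPanel,
                       phased: bool) -> DiplotypeCall:
    """Classify one individual from its calls at the three panel loci.

    ``calls`` has shape (3, 2): allele-index pairs at 995, 402, 1527 in panel
    order. Phased input maps directly to a haplotype pair; unphased input is
    matched against the per-locus allele multisets implied by the named
    groups, with phase-ambiguous matches resolved by the coupling rule and
    flagged ``ambiguous``.
    """
    calls = np.asarray(calls)
    if calls.shape != (3, 2):
        raise ValueError("expected calls of shape (3, 2)")
    if (calls == MISSING).any():
        return DiplotypeCall(sample_id, OD, missing=True)

    if phased:
        h1 = label_haplotype(calls[:, 0], panel)
        h2 = label_haplotype(calls[:, 1], panel)
        return DiplotypeCall(sample_id, group_of_pair(h1, h2),
                             hap_pair=_canonical_pair(h1, h2))

    genotype = [tuple(loc.label_of(int(a)) for a in pair)
                for loc, pair in zip(panel.loci, calls)]
    resolutions = _phase_resolutions(genotype)
    groups = {NAMED_GROUPS.get(pair, OD) for pair in resolutions}
    named = [g for g in COUPLING_PREFERENCE if g in groups]
    ambiguous = len(groups) > 1
    if not named:
        pair = min(resolutions) if len(resolutions) == 1 else None
        return DiplotypeCall(sample_id, OD, hap_pair=pair, ambiguous=ambiguous)
    group = named[0]
    pair = next(p for p, g in NAMED_GROUPS.items() if g == group)
    return DiplotypeCall(sample_id, group, hap_pair=pair, ambiguous=ambiguous)


def classify_cohort(variants: VariantTable, genotypes: GenotypeMatrix,
                    samples: list[str], panel: KdrPanel) -> list[DiplotypeCall]:
    idx = panel.variant_indices(variants)
    calls = genotypes.calls[:, idx]          # (n, 3, 2)
    phased = genotypes.phased[:, idx].all(axis=1)
    return [classify_diplotype(samples[i], calls[i], panel, bool(phased[i]))
            for i in range(len(samples))]


def diplotype_frequencies(calls: list[DiplotypeCall],
                          metadata: list[SampleMetadata],
                          by: str = "site_species") -> pd.DataFrame:
    """Group frequencies per population; denominator = classified samples."""
    from .diversity import group_samples
    groups = group_samples(metadata, by)
    rows = []
    for pop, idx in groups.items():
        pop_calls = [calls[i] for i in idx]
        n = len(pop_calls)
        if n == 0:
            continue
        for group in GROUP_ORDER:
            count = sum(c.group == group for c in pop_calls)
            rows.append({"population": pop, "group": group, "count": count,
                         "n": n, "frequency": count / n})
    return pd.DataFrame(rows)


def calls_to_frame(calls: list[DiplotypeCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": c.sample_id, "group": c.group,
        "hap1": c.hap_pair[0] if c.hap_pair else "",
        "hap2": c.hap_pair[1] if c.hap_pair else "",
        "ambiguous": c.ambiguous, "missing": c.missing,
    } for c in calls])


# ---------------------------------------------------------------------------
# clustering and PCA views


def unordered_genotype_codes(genotypes: GenotypeMatrix) -> np.ndarray:
    """Encode each call as a sex- and phase-insensitive unordered genotype.

    Codes are a * 8 + b with (a, b) the sorted allele pair; any missing
    allele makes the site code negative.
    """
    lo = genotypes.calls.min(axis=2).astype(np.int64)
    hi = genotypes.calls.max(axis=2).astype(np.int64)
    codes = lo * 8 + hi
    codes[(genotypes.calls == MISSING).any(axis=2)] = -1
    return codes


def genotype_clustering(genotypes: GenotypeMatrix
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """UPGMA clustering on Hamming distances between unordered genotypes.

    Returns (linkage matrix Z, leaf order, kept sample indices); all-missing
    samples are excluded.
    """
    codes = unordered_genotype_codes(genotypes)
    kept = np.flatnonzero((codes >= 0).any(axis=1))
    if kept.size < 2:
        raise ValueError("need at least 2 samples with calls")
    codes = codes[kept]
    dist = (codes[:, None, :] != codes[None, :, :]).sum(axis=2).astype(float)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(Z)
    return Z, order, kept


def cut_tree(Z: np.ndarray, k: int) -> np.ndarray:
    return hierarchy.fcluster(Z, t=k, criterion="maxclust")


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left = rec(node.left)
        right = rec(node.right)
        dl = node.dist - (0 if node.left.is_leaf() else node.left.dist)
        dr = node.dist - (0 if node.right.is_leaf() else node.right.dist)
        return f"({left}:{dl / 2:.6g},{right}:{dr / 2:.6g})"

    return rec(tree) + ";"


def dosage_matrix(variants: VariantTable, genotypes: GenotypeMatrix
                  ) -> tuple[np.ndarray, list[str]]:
    """Per-alt dosage columns (multiallelic sites collapse to one column per
    alt, keeping the triallelic 402 signal); missing calls become NaN."""
    cols, names = [], []
    calls = genotypes.calls
    miss = (calls == MISSING).any(axis=2)
    for j in range(variants.n_variants):
        for a, alt in enumerate(variants.alts[j], start=1):
            d = (calls[:, j, :] == a).sum(axis=1).astype(float)
            d[miss[:, j]] = np.nan
            cols.append(d)
            names.append(f"{variants.contig[j]}:{variants.pos[j]}:{alt}")
    X = np.column_stack(cols) if cols else np.empty((genotypes.n_samples, 0))
    return X, names


def pca_dosage(X: np.ndarray, maf_min: float = 0.01, n_components: int = 10
               ) -> tuple[np.ndarray, np.ndarray]:
    """PCA of a dosage matrix with Patterson scaling.

    Each column is centered by its mean and scaled by sqrt(p(1-p)) with
    p = mean dosage / 2; NaN entries are mean-imputed. The sign convention
    makes each component's largest-magnitude loading positive. Returns
    (coordinates, explained-variance fractions).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mu, X)
    p = mu / 2.0
    maf = np.minimum(p, 1 - p)
    keep = maf >= maf_min
    if not keep.any():
        raise ValueError("no site passes the MAF filter")
    X = X[:, keep]
    p = p[keep]
    scale = np.sqrt(p * (1 - p))
    ok = scale > 0
    if not ok.any():
        raise ValueError("zero-variance matrix after filtering")
    Xs = (X[:, ok] - 2 * p[ok]) / scale[ok]
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    k = min(n_components, s.size)
    # sign convention: largest-magnitude loading positive per component
    for c in range(k):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    coords = U[:, :k] * s[:k]
    total = (s ** 2).sum()
    evr = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return coords, evr


def cluster_map_order(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """UPGMA row and column orders for a variants x populations frequency
    matrix (the clustered-heatmap view); identity for single rows/columns."""
    M = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix must be finite")

    def order_axis(A: np.ndarray) -> np.ndarray:
        if A.shape[0] < 2:
            return np.arange(A.shape[0])
        d = np.sqrt(((A[:, None, :] - A[None, :, :]) ** 2).sum(axis=2))
        Z = hierarchy.linkage(squareform(d, checks=False), method="average")
        return hierarchy.leaves_list(Z)

    return order_axis(M), order_axis(M.T)
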