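"""Synthetic cohort generator with retained ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, without claiming realism beyond it:

* each individual's two kdr-panel haplotypes are drawn i.i.d. from a
  population-specific haplotype-class mixture (random union of gametes =
  Hardy-Weinberg pairing, the assumption behind the EM LD estimator);
* neutral background sites are drawn from the standard neutral site
  frequency spectrum, Pr(k) ∝ 1/k, unlinked to the panel and to each other;
* each haplotype class optionally carries a fixed set of private marker
  mutations so haplotype networks are non-degenerate;
* modal copy-number calls are drawn per sample per gene from configured
  amp/del frequencies, with amplifications at baseline + 1 + geometric.

Everything is reproducible from a single integer seed; the drawn truth
(haplotype label pairs, per-population class frequencies, implied two-locus
r², per-entry CNV states) is returned alongside the emitted files.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .core_io import (CopyNumberTable, GeneAnnotation, GenotypeMatrix,
                      SampleMetadata, VariantTable)
from .diplotype import KdrPanel, default_kdr_panel
from .ld import phased_r2

import pandas as pd

FREQ_TOL = 1e-9


@dataclass
class CNSpec:
    """Per-gene CNV rates: amp/del probabilities per sample and the geometric
    parameter for how many extra copies an amplification adds."""

    amp_freq: float = 0.0
    del_freq: float = 0.0
    amp_geom_p: float = 0.5

    def __post_init__(self):
        if not (0 <= self.amp_freq <= 1 and 0 <= self.del_freq <= 1):
            raise ValueError("amp_freq and del_freq must be in [0, 1]")
        if self.amp_freq + self.del_freq > 1:
            raise ValueError("amp_freq + del_freq must be <= 1")
        if not 0 < self.amp_geom_p <= 1:
            raise ValueError("amp_geom_p must be in (0, 1]")


@dataclass
class PopulationSpec:
    """One simulated population: a (species, site) cohort."""

    name: str
    species: str
    site: str
    zone: str
    n_samples: int
    kdr_hap_freqs: dict[str, float]
    sex_ratio: float = 0.5           # fraction female
    n_background_sites: int = 0
    cn_specs: dict[str, CNSpec] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError(f"population {self.name}: n_samples must be > 0")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError(f"population {self.name}: bad sex_ratio")
        total = sum(self.kdr_hap_freqs.values())
        if abs(total - 1.0) > FREQ_TOL:
            raise ValueError(
                f"population {self.name}: haplotype frequencies sum to "
                f"{total}, not 1")


@dataclass
class SyntheticTruth:
    """Generator-retained ground truth for oracle tests."""

    hap_labels: list[tuple[str, str]]            # phased pair per sample
    pop_hap_freqs: dict[str, dict[str, float]]   # realized class frequencies
    pop_r2: dict[str, dict[str, float]]          # phased r² per allele pair
    cn_states: pd.DataFrame | None = None        # sample, gene, state, cn

    def to_json(self) -> dict:
        out = {
            "hap_labels": [list(p) for p in self.hap_labels],
            "pop_hap_freqs": self.pop_hap_freqs,
            "pop_r2": self.pop_r2,
        }
        if self.cn_states is not None:
            out["cn_states"] = self.cn_states.to_dict(orient="records")
        return out


def simulate_neutral_sites(n_haplotypes: int, S: int,
                           seed: int | np.random.Generator) -> np.ndarray:
    """(n_haplotypes x S) 0/1 matrix of independent neutral segregating sites.

    Each site's derived-allele count k is drawn from Pr(k) ∝ 1/k on
    {1, ..., n-1}; a uniformly random subset of k haplotypes carries the
    derived allele, so every column is polymorphic by construction.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    if S < 0:
        raise ValueError("S must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    out = np.zeros((n_haplotypes, S), dtype=np.int8)
    if S == 0:
        return out
    k_values = np.arange(1, n_haplotypes)
    probs = (1.0 / k_values)
    probs /= probs.sum()
    ks = rng.choice(k_values, size=S, p=probs)
    for j, k in enumerate(ks):
        carriers = rng.choice(n_haplotypes, size=k, replace=False)
        out[carriers, j] = 1
    return out


def _hap_r2_from_labels(labels: np.ndarray, panel: KdrPanel) -> dict[str, float]:
    """Phased-count r² between each 402 mutant and 1527T from drawn labels."""
    alleles = np.array([panel.parse_label(l) for l in labels.ravel()])
    out = {}
    t = (alleles[:, 2] == panel.loci[2].allele_of("T")).astype(int)
    for name, lab in [("r2_402Lgt_vs_1527T", "L1"),
                      ("r2_402Lgc_vs_1527T", "L2")]:
        a = (alleles[:, 1] == panel.loci[1].allele_of(lab)).astype(int)
        out[name] = phased_r2(a, t)
    return out


def private_mutation_positions(class_labels: list[str], k: int,
                               base_pos: int = 23950000,
                               stride: int = 1000) -> dict[str, list[int]]:
    """Deterministic marker positions for each haplotype class (sorted class
    order), independent of the seed so reruns share coordinates."""
    return {lab: [base_pos + i * stride + j for j in range(k)]
            for i, lab in enumerate(sorted(class_labels))}


def simulate_kdr_cohort(specs: list[PopulationSpec], seed: int,
                        panel: KdrPanel | None = None,
                        region: tuple[str, int, int] = ("2L", 2358158, 2431617),
                        n_private_mutations: int = 2
                        ) -> tuple[VariantTable, GenotypeMatrix,
                                   list[SampleMetadata], SyntheticTruth]:
    """Simulate a phased multi-population cohort at the kdr panel.

    Background sites are private to their population (reference elsewhere);
    the genotype matrix is fully phased and missingness-free. Deterministic
    for a fixed (specs, seed).
    """
    panel = panel or default_kdr_panel()
    for spec in specs:
        for lab in spec.kdr_hap_freqs:
            panel.parse_label(lab)  # raises on unknown labels
    rng = np.random.default_rng(seed)

    all_classes = sorted({lab for s in specs for lab in s.kdr_hap_freqs})
    priv = private_mutation_positions(all_classes, n_private_mutations) \
        if n_private_mutations > 0 else {}

    contig, rstart, rend = region
    reserved = {loc.pos for loc in panel.loci if loc.contig == contig}
    reserved |= {p for ps in priv.values() for p in ps}

    # draw per-population labels, sexes and background columns
    n_total = sum(s.n_samples for s in specs)
    metadata: list[SampleMetadata] = []
    hap_labels: list[tuple[str, str]] = []
    pop_rows: dict[str, np.ndarray] = {}
    background: list[tuple[int, np.ndarray, np.ndarray]] = []  # pos, col, rows
    row = 0
    taken_positions = set(reserved)
    for spec in specs:
        rows = np.arange(row, row + spec.n_samples)
        pop_rows[spec.name] = rows
        row += spec.n_samples
        labels = sorted(spec.kdr_hap_freqs)
        probs = np.array([spec.kdr_hap_freqs[l] for l in labels])
        probs = probs / probs.sum()
        drawn = rng.choice(labels, size=(spec.n_samples, 2), p=probs)
        hap_labels.extend(tuple(p) for p in drawn)
        for i in range(spec.n_samples):
            sex = "F" if rng.random() < spec.sex_ratio else "M"
            metadata.append(SampleMetadata(
                sample_id=f"{spec.name}_{i:04d}", species=spec.species,
                site=spec.site, zone=spec.zone, sex=sex))
        if spec.n_background_sites > 0:
            pool = np.setdiff1d(np.arange(rstart, rend + 1),
                                np.fromiter(taken_positions, dtype=np.int64))
            pos = np.sort(rng.choice(pool, size=spec.n_background_sites,
                                     replace=False))
            taken_positions.update(int(p) for p in pos)
            mat = simulate_neutral_sites(2 * spec.n_samples,
                                         spec.n_background_sites, rng)
            for j in range(spec.n_background_sites):
                background.append((int(pos[j]), mat[:, j], rows))

    # assemble the variant table: panel + private markers + background
    bases = np.array(list("ACGT"))
    records = []  # (pos, ref, alts, effects, filler)
    for loc in panel.loci:
        eff = {"995": ("L995F", "L995S"), "402": ("V402L", "V402L"),
               "1527": ("I1527T",)}[loc.name]
        records.append((loc.pos, loc.ref, loc.alts, eff, ("panel", loc)))
    for lab in sorted(priv):
        for p in priv[lab]:
            ref, alt = "A", "G"
            records.append((p, ref, (alt,), ("intronic",), ("private", lab)))
    for pos, col, rows in background:
        ref, alt = rng.choice(bases, size=2, replace=False)
        records.append((pos, str(ref), (str(alt),), ("intronic",),
                        ("background", (col, rows))))
    records.sort(key=lambda r: r[0])

    variants = VariantTable(
        contig=[contig] * len(records),
        pos=np.array([r[0] for r in records]),
        ref=[r[1] for r in records],
        alts=[r[2] for r in records],
        effect_labels=[r[3] for r in records],
    )

    calls = np.zeros((n_total, len(records), 2), dtype=np.int16)
    hap_alleles = np.array([[panel.parse_label(h) for h in pair]
                            for pair in hap_labels])       # (n, 2, 3)
    for j, rec in enumerate(records):
        kind, payload = rec[4]
        if kind == "panel":
            locus_i = [l.name for l in panel.loci].index(payload.name)
            calls[:, j, 0] = hap_alleles[:, 0, locus_i]
            calls[:, j, 1] = hap_alleles[:, 1, locus_i]
        elif kind == "private":
            lab = payload
            for c in (0, 1):
                carrier = np.array([pair[c] == lab for pair in hap_labels])
                calls[carrier, j, c] = 1
        else:
            col, rows = payload
            calls[rows, j, 0] = col[0::2]
            calls[rows, j, 1] = col[1::2]

    genotypes = GenotypeMatrix(calls, phased=True)
    genotypes.validate_against(variants)

    pop_hap_freqs, pop_r2 = {}, {}
    for spec in specs:
        rows = pop_rows[spec.name]
        drawn = np.array([hap_labels[i] for i in rows])
        flat = drawn.ravel()
        pop_hap_freqs[spec.name] = {
            lab: float((flat == lab).mean()) for lab in sorted(set(flat))}
        pop_r2[spec.name] = _hap_r2_from_labels(drawn, panel)

    truth = SyntheticTruth(hap_labels=hap_labels, pop_hap_freqs=pop_hap_freqs,
                           pop_r2=pop_r2)
    return variants, genotypes, metadata, truth


def simulate_cn_table(specs: list[PopulationSpec],
                      annotation: list[GeneAnnotation], seed: int,
                      metadata: list[SampleMetadata]
                      ) -> tuple[CopyNumberTable, pd.DataFrame]:
    """Modal copy-number calls per sample per configured gene.

    Baseline is 2 on autosomes and on the X for females, 1 on the X for
    males; deletions draw a CN uniformly below baseline, amplifications draw
    baseline + 1 + Geometric(p) - 1 extra copies. Returns the table plus a
    truth frame of drawn states.
    """
    genes = {g.gene_id: g for g in annotation}
    for spec in specs:
        unknown = sorted(set(spec.cn_specs) - set(genes))
        if unknown:
            raise ValueError(
                f"population {spec.name}: cn_specs reference unknown genes "
                f"{unknown}")
    rng = np.random.default_rng(seed)
    by_pop: dict[tuple[str, str], list[SampleMetadata]] = {}
    for m in metadata:
        by_pop.setdefault((m.species, m.site), []).append(m)
    rows, truth_rows = [], []
    for spec in specs:
        members = by_pop.get((spec.species, spec.site), [])
        for m in members:
            for gene_id in sorted(spec.cn_specs):
                cs = spec.cn_specs[gene_id]
                base = 1 if (genes[gene_id].contig == "X" and m.sex == "M") \
                    else 2
                u = rng.random()
                if u < cs.del_freq:
                    state = "del"
                    cn = int(rng.integers(0, base))
                elif u < cs.del_freq + cs.amp_freq:
                    state = "amp"
                    cn = base + int(rng.geometric(cs.amp_geom_p))
                else:
                    state = "normal"
                    cn = base
                rows.append({"sample_id": m.sample_id, "gene_id": gene_id,
                             "cn": cn})
                truth_rows.append({"sample_id": m.sample_id,
                                   "gene_id": gene_id, "state": state,
                                   "cn": cn})
    entries = pd.DataFrame(rows, columns=["sample_id", "gene_id", "cn"])
    truth = pd.DataFrame(truth_rows,
                         columns=["sample_id", "gene_id", "state", "cn"])
    return CopyNumberTable(entries), truth


# ---------------------------------------------------------------------------
# cohort configuration


@dataclass
class CohortConfig:
    populations: list[PopulationSpec]
    annotation: list[GeneAnnotation]
    region: tuple[str, int, int]
    n_private_mutations: int = 2


def load_cohort_config(path_or_builtin: str) -> CohortConfig:
    """Load a cohort configuration from YAML.

    ``"builtin:default_cohort"`` loads the packaged configuration emulating
    the study design: eight collection sites across three ecological zones,
    An. gambiae s.s. essentially fixed for FVI, An. coluzzii segregating for
    LVI/FVI/LL1T/FL1T plus rare g>c classes, An. arabiensis mixing FVI and
    SVI, and CNV rates at a handful of detoxification genes.
    """
    if path_or_builtin.startswith("builtin:"):
        name = path_or_builtin.split(":", 1)[1]
        ref = importlib.resources.files("kdrpop.data") / f"{name}.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path_or_builtin) as fh:
            raw = yaml.safe_load(fh)
    populations = []
    for p in raw["populations"]:
        cn_specs = {g: CNSpec(**v) for g, v in (p.get("cn_specs") or {}).items()}
        populations.append(PopulationSpec(
            name=p["name"], species=p["species"], site=p["site"],
            zone=p["zone"], n_samples=int(p["n_samples"]),
            kdr_hap_freqs={k: float(v) for k, v in p["kdr_hap_freqs"].items()},
            sex_ratio=float(p.get("sex_ratio", 0.5)),
            n_background_sites=int(p.get("n_background_sites", 0)),
            cn_specs=cn_specs))
    annotation = [GeneAnnotation(g["gene_id"], g["gene_name"], g["family"],
                                 g["contig"], int(g["start"]), int(g["end"]))
                  for g in raw.get("genes", [])]
    region = raw.get("region", {"contig": "2L", "start": 2358158,
                                "end": 2431617})
    return CohortConfig(
        populations=populations, annotation=annotation,
        region=(region["contig"], int(region["start"]), int(region["end"])),
        n_private_mutations=int(raw.get("n_private_mutations", 2)))


def simulate_cohort(config: CohortConfig, seed: int
                    ) -> tuple[VariantTable, GenotypeMatrix,
                               list[SampleMetadata], CopyNumberTable,
                               SyntheticTruth]:
    """Full cohort: genotypes plus copy-number calls, one seed for both."""
    ss = np.random.SeedSequence(seed)
    s_geno, s_cn = (int(c.generate_state(1)[0] % (2 ** 31))
                    for c in ss.spawn(2))
    variants, genotypes, metadata, truth = simulate_kdr_cohort(
        config.populations, s_geno, region=config.region,
        n_private_mutations=config.n_private_mutations)
    cn_table, cn_truth = simulate_cn_table(config.populations,
                                           config.annotation, s_cn, metadata)
    truth.cn_states = cn_truth
    return variants, genotypes, metadata, cn_table, truth
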