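"""End-to-end orchestration: run every analysis stage from one configuration
and emit all tables, the network, a run log and a checksum manifest.

Identical configuration + seed gives identical manifests: floating-point
table cells are printed with 6 significant digits and every other output is
integer or text, so checksums are stable across reruns.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cnv as cnv_mod
from . import core_io, diplotype, diversity, hapnet, ld, variant_effects
from .synthetic_data import CohortConfig, load_cohort_config, simulate_cohort


class ConfigError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    """Either a synthetic cohort spec or a set of real input paths."""

    output_dir: str
    synthetic: str | None = None          # cohort-config path or builtin:name
    vcf: str | None = None
    metadata: str | None = None
    annotation: str | None = None
    cn_table: str | None = None
    region: tuple[str, int, int] = ("2L", 2358158, 2431617)
    min_freq: float = 0.05
    ld_min_n: int = 10
    pca_maf: float = 0.01
    hapnet_epsilon: int = 0

    def __post_init__(self):
        real = [self.vcf, self.metadata]
        if self.synthetic is not None and any(p is not None for p in real):
            raise ConfigError("config must use synthetic OR real inputs, "
                              "not both")
        if self.synthetic is None:
            missing = [n for n, p in [("vcf", self.vcf),
                                      ("metadata", self.metadata)]
                       if p is None]
            if missing:
                raise ConfigError(f"real-input config missing: {missing}")
            for name in ("vcf", "metadata", "annotation", "cn_table",
                         "synthetic"):
                p = getattr(self, name)
                if p is not None and not str(p).startswith("builtin:") \
                        and not Path(p).exists():
                    raise ConfigError(f"{name} path does not exist: {p}")


def load_analysis_config(path: str) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    region = raw.get("region")
    kw = dict(
        output_dir=raw["output_dir"],
        synthetic=(raw.get("synthetic") or {}).get("cohort_config"),
        min_freq=float(raw.get("thresholds", {}).get("min_freq", 0.05)),
        ld_min_n=int(raw.get("thresholds", {}).get("ld_min_n", 10)),
        pca_maf=float(raw.get("thresholds", {}).get("pca_maf", 0.01)),
        hapnet_epsilon=int(raw.get("thresholds", {}).get("hapnet_epsilon", 0)),
    )
    for name in ("vcf", "metadata", "annotation", "cn_table"):
        kw[name] = (raw.get("inputs") or {}).get(name)
    if region:
        kw["region"] = (region["contig"], int(region["start"]),
                        int(region["end"]))
    return AnalysisConfig(**kw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunContext:
    outdir: Path
    seed: int
    log_lines: list[str] = field(default_factory=list)
    outputs: list[Path] = field(default_factory=list)

    def log(self, msg: str) -> None:
        self.log_lines.append(msg)

    def register(self, path: Path) -> None:
        self.outputs.append(path)


def run_full_analysis(config: AnalysisConfig, seed: int = 0) -> dict:
    """Run all stages in dependency order; returns the manifest dict.

    Any stage failure aborts with the stage name; partial outputs are kept
    next to a FAILED marker file.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx = RunContext(outdir=outdir, seed=seed)
    config_repr = json.dumps(config.__dict__, sort_keys=True, default=str)
    config_hash = hashlib.sha256(config_repr.encode()).hexdigest()[:16]
    ctx.log(f"seed={seed} config_hash={config_hash}")

    stage = "inputs"
    try:
        t0 = time.perf_counter()
        data = _stage_inputs(config, ctx)
        ctx.log(f"stage={stage} seconds={time.perf_counter() - t0:.2f}")
        for stage, fn in [("diversity", _stage_diversity),
                          ("frequencies", _stage_frequencies),
                          ("diplotypes", _stage_diplotypes),
                          ("ld", _stage_ld),
                          ("network", _stage_network),
                          ("cnv", _stage_cnv)]:
            t0 = time.perf_counter()
            fn(config, ctx, data)
            ctx.log(f"stage={stage} seconds={time.perf_counter() - t0:.2f}")
    except Exception as err:
        (outdir / "FAILED").write_text(f"stage={stage}\nerror={err}\n")
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    manifest = {p.name: _sha256(p) for p in sorted(ctx.outputs)}
    manifest_path = outdir / "manifest.json"
    core_io.write_json(str(manifest_path), manifest)
    (outdir / "run.log").write_text("\n".join(ctx.log_lines) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_inputs(config: AnalysisConfig, ctx: RunContext) -> dict:
    panel = diplotype.default_kdr_panel()
    if config.synthetic is not None:
        cohort: CohortConfig = load_cohort_config(config.synthetic)
        variants, genotypes, metadata, cn_table, truth = simulate_cohort(
            cohort, ctx.seed)
        region = cohort.region
        annotation = cohort.annotation
        out_vcf = ctx.outdir / "cohort.vcf"
        core_io.write_genotype_vcf(str(out_vcf), variants, genotypes,
                                   [m.sample_id for m in metadata])
        core_io.write_metadata(str(ctx.outdir / "metadata.tsv"), metadata)
        core_io.write_cn_table(str(ctx.outdir / "cn_table.tsv"), cn_table)
        core_io.write_gene_annotation(str(ctx.outdir / "genes.tsv"),
                                      annotation)
        core_io.write_json(str(ctx.outdir / "truth.json"), truth.to_json())
        for name in ("cohort.vcf", "metadata.tsv", "cn_table.tsv",
                     "genes.tsv"):
            ctx.register(ctx.outdir / name)
    else:
        variants, genotypes, samples = core_io.read_genotype_vcf(config.vcf)
        metadata = core_io.read_metadata(config.metadata)
        order = {m.sample_id: i for i, m in enumerate(metadata)}
        missing = [s for s in samples if s not in order]
        if missing:
            raise ConfigError(f"VCF samples absent from metadata: "
                              f"{missing[:5]}")
        metadata = [metadata[order[s]] for s in samples]
        annotation = core_io.read_gene_annotation(config.annotation) \
            if config.annotation else []
        cn_table = core_io.read_cn_table(config.cn_table, annotation or None) \
            if config.cn_table else core_io.CopyNumberTable()
        truth = None
        region = config.region
    return {"variants": variants, "genotypes": genotypes,
            "metadata": metadata, "annotation": annotation,
            "cn_table": cn_table, "truth": truth, "panel": panel,
            "region": region}


def _stage_diversity(config, ctx, data):
    region = data["region"]
    L = region[2] - region[1] + 1
    mask = data["variants"].region_mask(*region)
    variants = data["variants"].take(mask)
    genotypes = data["genotypes"].take_variants(mask)
    table = diversity.diversity_table(variants, genotypes, data["metadata"],
                                      L=L, region_name=f"{region[0]}:"
                                      f"{region[1]}-{region[2]}")
    path = ctx.outdir / "diversity.tsv"
    core_io.write_table(str(path), table)
    ctx.register(path)


def _stage_frequencies(config, ctx, data):
    groups = diversity.group_samples(data["metadata"], by="site_species")
    df = variant_effects.allele_frequencies(
        data["variants"], data["genotypes"], groups, min_freq=config.min_freq)
    df = variant_effects.add_cumulative_402(df, data["panel"])
    path = ctx.outdir / "allele_frequencies.tsv"
    core_io.write_table(str(path), df)
    ctx.register(path)


def _stage_diplotypes(config, ctx, data):
    variants, genotypes = data["variants"], data["genotypes"]
    metadata, panel = data["metadata"], data["panel"]
    samples = [m.sample_id for m in metadata]
    calls = diplotype.classify_cohort(variants, genotypes, samples, panel)
    core_io.write_table(str(ctx.outdir / "diplotype_calls.tsv"),
                        diplotype.calls_to_frame(calls))
    freqs = diplotype.diplotype_frequencies(calls, metadata)
    core_io.write_table(str(ctx.outdir / "diplotype_frequencies.tsv"), freqs)

    Z, order, kept = diplotype.genotype_clustering(genotypes)
    newick = diplotype.linkage_to_newick(Z, [samples[i] for i in kept])
    (ctx.outdir / "diplotype_dendrogram.nwk").write_text(newick + "\n")

    X, _names = diplotype.dosage_matrix(variants, genotypes)
    coords, evr = diplotype.pca_dosage(X, maf_min=config.pca_maf)
    import pandas as pd
    pca_df = pd.DataFrame({"sample_id": samples})
    for c in range(coords.shape[1]):
        pca_df[f"PC{c + 1}"] = coords[:, c]
    core_io.write_table(str(ctx.outdir / "pca_coordinates.tsv"), pca_df)
    core_io.write_json(str(ctx.outdir / "pca_explained_variance.json"),
                       [float(v) for v in evr])

    # cluster-map orders over the per-population panel-allele frequencies
    groups = diversity.group_samples(metadata, by="site_species")
    idx = panel.variant_indices(variants)
    freq_rows, row_names = [], []
    for loc, j in zip(panel.loci, idx):
        for a, alt in enumerate(variants.alts[j], start=1):
            row = []
            for pop, sidx in groups.items():
                sub = genotypes.calls[np.asarray(sidx), j]
                called = (sub != core_io.MISSING).sum()
                row.append((sub == a).sum() / called if called else 0.0)
            freq_rows.append(row)
            row_names.append(f"{loc.name}:{alt}")
    M = np.array(freq_rows)
    r_order, c_order = diplotype.cluster_map_order(M)
    pops = list(groups)
    core_io.write_json(str(ctx.outdir / "cluster_map_order.json"), {
        "rows": [row_names[i] for i in r_order],
        "columns": [pops[i] for i in c_order]})
    for name in ("diplotype_calls.tsv", "diplotype_frequencies.tsv",
                 "diplotype_dendrogram.nwk", "pca_coordinates.tsv",
                 "pca_explained_variance.json", "cluster_map_order.json"):
        ctx.register(ctx.outdir / name)
    data["diplotype_calls"] = calls


def _stage_ld(config, ctx, data):
    wide, long = ld.ld_table(data["genotypes"], data["variants"],
                             data["panel"], data["metadata"],
                             min_n=config.ld_min_n)
    core_io.write_table(str(ctx.outdir / "ld_table.tsv"), wide)
    core_io.write_table(str(ctx.outdir / "ld_diagnostics.tsv"), long)
    ctx.register(ctx.outdir / "ld_table.tsv")
    ctx.register(ctx.outdir / "ld_diagnostics.tsv")


def _stage_network(config, ctx, data):
    variants, genotypes = data["variants"], data["genotypes"]
    metadata, panel = data["metadata"], data["panel"]
    # restrict to the kdr panel plus the class-private marker block
    keep = sorted(set(panel.variant_indices(variants)) | {
        j for j in range(variants.n_variants)
        if variants.pos[j] >= 23950000})
    haps = genotypes.take_variants(keep).to_haplotypes()
    calls = data.get("diplotype_calls")
    species = np.repeat([m.species for m in metadata], 2)
    group = np.repeat([c.group for c in calls] if calls
                      else ["NA"] * len(metadata), 2)
    uniq, mult, tallies = hapnet.collapse_haplotypes(
        haps, {"species": list(species), "group": list(group)})
    net = hapnet.median_joining(uniq, epsilon=config.hapnet_epsilon,
                                multiplicities=mult, tallies=tallies)
    (ctx.outdir / "haplotype_network.dot").write_text(
        hapnet.network_to_dot(net, color_by="species"))
    core_io.write_json(str(ctx.outdir / "haplotype_network_nodes.json"),
                       hapnet.node_tallies_json(net))
    ctx.register(ctx.outdir / "haplotype_network.dot")
    ctx.register(ctx.outdir / "haplotype_network_nodes.json")


def _stage_cnv(config, ctx, data):
    if len(data["cn_table"].entries) == 0:
        return
    calls = cnv_mod.classify_cnv(data["cn_table"], data["metadata"],
                                 data["annotation"])
    core_io.write_table(str(ctx.outdir / "cnv_calls.tsv"), calls)
    freqs = cnv_mod.cnv_frequencies(calls, data["metadata"])
    core_io.write_table(str(ctx.outdir / "cnv_frequencies.tsv"), freqs)
    summary = cnv_mod.cnv_gene_summary(calls, data["annotation"])
    core_io.write_table(str(ctx.outdir / "cnv_gene_summary.tsv"), summary)
    scatter = cnv_mod.cnv_scatter_export(calls, data["metadata"],
                                         data["annotation"])
    core_io.write_table(str(ctx.outdir / "cnv_scatter.tsv"), scatter)
    for name in ("cnv_calls.tsv", "cnv_frequencies.tsv",
                 "cnv_gene_summary.tsv", "cnv_scatter.tsv"):
        ctx.register(ctx.outdir / name)
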