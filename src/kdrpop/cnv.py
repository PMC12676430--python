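"""Copy-number variation: per-gene amp/del/normal state classification,
per-population frequencies, and gene-family / chromosome-arm burden summaries.

Modal copy-number calls are inputs (CNV discovery from sequencing depth is
upstream of this package). The expected baseline is 2 on autosomes and for
females on the X, and 1 for hemizygous males on the X. A copy number of 0 is
a complete deletion and counts as del; any CN above baseline counts as amp
regardless of magnitude (the magnitude is retained for scatter exports).
"""

from __future__ import annotations

import pandas as pd

from .core_io import (CopyNumberTable, GeneAnnotation, SampleMetadata,
                      ValidationError)


def baseline_cn(contig: str, sex: str) -> int:
    return 1 if (contig == "X" and sex == "M") else 2


def classify_cnv(cn_table: CopyNumberTable, metadata: list[SampleMetadata],
                 annotation: list[GeneAnnotation]) -> pd.DataFrame:
    """One row per (sample, gene) entry with its baseline and amp/del/normal
    state. Raises when an X-linked entry belongs to a sample of unknown sex.
    """
    sex = {m.sample_id: m.sex for m in metadata}
    genes = {g.gene_id: g for g in annotation}
    cn_table.validate_against(metadata, annotation)
    rows = []
    for r in cn_table.entries.itertuples():
        gene = genes[r.gene_id]
        if gene.contig == "X" and r.sample_id not in sex:
            raise ValidationError(
                f"X-linked CN entry for sample {r.sample_id!r} without sex")
        base = baseline_cn(gene.contig, sex[r.sample_id])
        state = "amp" if r.cn > base else ("del" if r.cn < base else "normal")
        rows.append({"sample_id": r.sample_id, "gene_id": r.gene_id,
                     "cn": int(r.cn), "baseline": base, "state": state})
    return pd.DataFrame(rows,
                        columns=["sample_id", "gene_id", "cn", "baseline",
                                 "state"])


def cnv_frequencies(calls: pd.DataFrame, metadata: list[SampleMetadata],
                    by: str = "site_species") -> pd.DataFrame:
    """amp/del frequency per (gene, population).

    The denominator is the number of samples with a call for the gene in the
    population; (gene, population) cells with zero calls are omitted.
    """
    from .diversity import group_samples
    groups = group_samples(metadata, by)
    sample_pop = {}
    for pop, idx in groups.items():
        for i in idx:
            sample_pop[metadata[i].sample_id] = pop
    if len(calls) == 0:
        return pd.DataFrame(columns=["gene_id", "population", "n",
                                     "amp_freq", "del_freq"])
    df = calls.copy()
    df["population"] = df.sample_id.map(sample_pop)
    rows = []
    for (gene, pop), sub in df.groupby(["gene_id", "population"], sort=True):
        n = len(sub)
        rows.append({
            "gene_id": gene, "population": pop, "n": n,
            "amp_freq": (sub.state == "amp").sum() / n,
            "del_freq": (sub.state == "del").sum() / n,
        })
    return pd.DataFrame(rows)


def cnv_gene_summary(calls: pd.DataFrame, annotation: list[GeneAnnotation]
                     ) -> pd.DataFrame:
    """Counts of distinct genes with >=1 amp call, >=1 del call and >=1 CNV of
    either kind, per gene family and chromosome arm (plus a TOTAL row).

    The union identity (amp-genes ∪ del-genes = CNV-genes) holds by
    construction and is re-checked here.
    """
    genes = {g.gene_id: g for g in annotation}
    unknown = sorted(set(calls.gene_id) - set(genes)) if len(calls) else []
    if unknown:
        raise ValidationError(f"calls reference unknown gene(s): {unknown[:5]}")
    amp_genes = set(calls[calls.state == "amp"].gene_id) if len(calls) else set()
    del_genes = set(calls[calls.state == "del"].gene_id) if len(calls) else set()
    cnv_genes = amp_genes | del_genes
    rows = []
    families = sorted({genes[g].family for g in cnv_genes} | {"CYP", "COE", "GST"})
    contigs = sorted({genes[g].contig for g in cnv_genes})
    for fam in families:
        for ctg in contigs:
            sel = {g for g in cnv_genes
                   if genes[g].family == fam and genes[g].contig == ctg}
            if not sel:
                continue
            rows.append({
                "family": fam, "contig": ctg,
                "n_amp_genes": len(sel & amp_genes),
                "n_del_genes": len(sel & del_genes),
                "n_cnv_genes": len(sel),
            })
    rows.append({"family": "TOTAL", "contig": "all",
                 "n_amp_genes": len(amp_genes),
                 "n_del_genes": len(del_genes),
                 "n_cnv_genes": len(cnv_genes)})
    df = pd.DataFrame(rows, columns=["family", "contig", "n_amp_genes",
                                     "n_del_genes", "n_cnv_genes"])
    total = df[df.family == "TOTAL"].iloc[0]
    assert total.n_cnv_genes == len(amp_genes | del_genes)
    by_arm = df[df.family != "TOTAL"]
    if len(by_arm):
        assert by_arm.n_cnv_genes.sum() == total.n_cnv_genes
    return df


def cnv_scatter_export(calls: pd.DataFrame, metadata: list[SampleMetadata],
                       annotation: list[GeneAnnotation]) -> pd.DataFrame:
    """Long-format (gene position, CN, species) export for the genome-wide
    copy-number scatter view."""
    species = {m.sample_id: m.species for m in metadata}
    genes = {g.gene_id: g for g in annotation}
    if len(calls) == 0:
        return pd.DataFrame(columns=["gene_id", "family", "contig", "start",
                                     "sample_id", "species", "cn", "state"])
    df = calls.copy()
    df["species"] = df.sample_id.map(species)
    df["family"] = df.gene_id.map(lambda g: genes[g].family)
    df["contig"] = df.gene_id.map(lambda g: genes[g].contig)
    df["start"] = df.gene_id.map(lambda g: genes[g].start)
    return df[["gene_id", "family", "contig", "start", "sample_id", "species",
               "cn", "state"]]
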