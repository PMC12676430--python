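"""Reading and validation of genotypes, sample metadata, gene annotations and
copy-number tables.

All genomic coordinates are 1-based inclusive (VCF convention). Multiallelic
VCF records are kept as single variant rows with multiple alternate alleles;
they are never split into biallelic rows, because the triallelic V402L site is
a first-class object in this analysis. Missing genotype calls are encoded as
allele index -1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

SPECIES = ("An_coluzzii", "An_gambiae_ss", "An_arabiensis")
ZONES = ("Sudanian", "Sudano_Sahelian", "Sahelian")
SEXES = ("F", "M")
CONTIGS = ("2L", "2R", "3L", "3R", "X")
GENE_FAMILIES = ("CYP", "COE", "GST", "other")
NUCLEOTIDES = frozenset("ACGT")

MISSING = -1


class ValidationError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True)
class SampleMetadata:
    """One mosquito sample: species, collection site, ecological zone, sex."""

    sample_id: str
    species: str
    site: str
    zone: str
    sex: str

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValidationError(
                f"unknown species {self.species!r} for sample {self.sample_id!r}; "
                f"expected one of {SPECIES}"
            )
        if self.zone not in ZONES:
            raise ValidationError(
                f"unknown zone {self.zone!r} for sample {self.sample_id!r}"
            )
        if self.sex not in SEXES:
            raise ValidationError(
                f"unknown sex {self.sex!r} for sample {self.sample_id!r}"
            )


@dataclass
class VariantTable:
    """Columnar table of variant sites.

    ``alts`` holds 1-3 single-nucleotide alternates per site; ``effect_labels``
    (optional) holds one label per alternate, e.g. ``"L995F"``, ``"synonymous"``
    or ``"intronic"``.
    """

    contig: list[str]
    pos: np.ndarray  # int64, 1-based
    ref: list[str]
    alts: list[tuple[str, ...]]
    effect_labels: list[tuple[str, ...]] | None = None

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.validate()

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def validate(self) -> None:
        n = self.n_variants
        if not (len(self.contig) == len(self.ref) == len(self.alts) == n):
            raise ValidationError("variant table columns have inconsistent lengths")
        if self.effect_labels is not None and len(self.effect_labels) != n:
            raise ValidationError("effect_labels length mismatch")
        for i in range(n):
            if self.ref[i] not in NUCLEOTIDES:
                raise ValidationError(f"bad ref allele {self.ref[i]!r} at row {i}")
            alts = self.alts[i]
            if not 1 <= len(alts) <= 3 or len(set(alts)) != len(alts):
                raise ValidationError(f"bad alt alleles {alts!r} at row {i}")
            for a in alts:
                if a not in NUCLEOTIDES:
                    raise ValidationError(f"bad alt allele {a!r} at row {i}")
                if a == self.ref[i]:
                    raise ValidationError(f"alt equals ref at row {i}")
        # positions strictly increasing within each contig
        for ctg in dict.fromkeys(self.contig):
            p = self.pos[[c == ctg for c in self.contig]]
            if np.any(np.diff(p) <= 0):
                raise ValidationError(
                    f"positions not strictly increasing on contig {ctg}"
                )

    def n_alleles(self) -> np.ndarray:
        """1 + number of alts per site."""
        return np.array([1 + len(a) for a in self.alts], dtype=np.int64)

    def region_mask(self, contig: str, start: int | None = None,
                    end: int | None = None) -> np.ndarray:
        m = np.array([c == contig for c in self.contig], dtype=bool)
        if start is not None:
            m &= self.pos >= start
        if end is not None:
            m &= self.pos <= end
        return m

    def take(self, idx) -> "VariantTable":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return VariantTable(
            contig=[self.contig[i] for i in idx],
            pos=self.pos[idx],
            ref=[self.ref[i] for i in idx],
            alts=[self.alts[i] for i in idx],
            effect_labels=None if self.effect_labels is None
            else [self.effect_labels[i] for i in idx],
        )

    def index_of(self, contig: str, pos: int) -> int:
        for i in range(self.n_variants):
            if self.contig[i] == contig and int(self.pos[i]) == int(pos):
                return i
        raise KeyError(f"no variant at {contig}:{pos}")


@dataclass
class GenotypeMatrix:
    """Diploid calls, shape (n_samples, n_variants, 2), allele indices, -1 missing.

    ``phased`` is a boolean matrix of the same leading shape: True where the
    two alleles of a call are in known chromosomal order.
    """

    calls: np.ndarray
    phased: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.ndim != 3 or self.calls.shape[2] != 2:
            raise ValidationError("calls must have shape (n_samples, n_variants, 2)")
        if isinstance(self.phased, (bool, np.bool_)):
            self.phased = np.full(self.calls.shape[:2], bool(self.phased))
        self.phased = np.asarray(self.phased, dtype=bool)
        if self.phased.shape != self.calls.shape[:2]:
            raise ValidationError("phased flags shape mismatch")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    def validate_against(self, variants: VariantTable) -> None:
        if self.n_variants != variants.n_variants:
            raise ValidationError("genotype/variant table shape mismatch")
        limit = variants.n_alleles()[None, :, None]
        bad = (self.calls >= limit) | ((self.calls < 0) & (self.calls != MISSING))
        if np.any(bad):
            s, v, _ = np.argwhere(bad)[0]
            raise ValidationError(
                f"allele index out of range at sample {s}, variant {v}"
            )

    def take_samples(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls[idx], self.phased[idx])

    def take_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(self.calls[:, idx], self.phased[:, idx])

    def to_haplotypes(self) -> np.ndarray:
        """Interleave the two chromosomes into a (2 n_samples, n_variants) matrix."""
        n, s, _ = self.calls.shape
        return self.calls.transpose(0, 2, 1).reshape(2 * n, s)


def _parse_region(region: str) -> tuple[str, int | None, int | None]:
    if ":" not in region:
        return region, None, None
    ctg, span = region.split(":", 1)
    start, end = span.replace(",", "").split("-")
    return ctg, int(start), int(end)


def read_genotype_vcf(path: str, region: str | None = None
                      ) -> tuple[VariantTable, GenotypeMatrix, list[str]]:
    """Read a VCF 4.x file into a VariantTable + GenotypeMatrix.

    Multiallelic records stay as single rows. ``region`` is ``contig`` or
    ``contig:start-end`` with 1-based inclusive bounds; the filter is applied
    in-memory so plain-text VCFs need no index.
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    ctg = start = end = None
    if region is not None:
        ctg, start, end = _parse_region(region)

    contigs, poss, refs, alts_l, calls, phased = [], [], [], [], [], []
    seen_contigs = set()
    for rec in vcf:
        seen_contigs.add(rec.CHROM)
        if ctg is not None:
            if rec.CHROM != ctg:
                continue
            if start is not None and not (start <= rec.POS <= end):
                continue
        contigs.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts_l.append(tuple(rec.ALT))
        g = np.array([gt[:3] for gt in rec.genotypes], dtype=np.int16)
        calls.append(g[:, :2])
        phased.append(g[:, 2].astype(bool))
    vcf.close()

    if ctg is not None and ctg not in seen_contigs:
        warnings.warn(f"region contig {ctg!r} absent from VCF; returning 0 variants")

    if not poss:
        variants = VariantTable([], np.empty(0, dtype=np.int64), [], [])
        geno = GenotypeMatrix(
            np.empty((len(samples), 0, 2), dtype=np.int16),
            np.empty((len(samples), 0), dtype=bool),
        )
        return variants, geno, samples

    variants = VariantTable(contigs, np.array(poss), refs, alts_l)
    geno = GenotypeMatrix(
        np.stack(calls, axis=1), np.stack(phased, axis=1)
    )
    geno.validate_against(variants)
    return variants, geno, samples


def write_genotype_vcf(path: str, variants: VariantTable, genotypes: GenotypeMatrix,
                       samples: list[str]) -> None:
    """Write a minimal VCF 4.2 file; '|' marks phased calls, '/' unphased."""
    genotypes.validate_against(variants)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for ctg in dict.fromkeys(variants.contig):
            fh.write(f"##contig=<ID={ctg}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j in range(variants.n_variants):
            row = [variants.contig[j], str(int(variants.pos[j])), ".",
                   variants.ref[j], ",".join(variants.alts[j]), ".", "PASS", ".", "GT"]
            for i in range(genotypes.n_samples):
                a, b = genotypes.calls[i, j]
                sep = "|" if genotypes.phased[i, j] else "/"
                sa = "." if a == MISSING else str(int(a))
                sb = "." if b == MISSING else str(int(b))
                row.append(sa + sep + sb)
            fh.write("\t".join(row) + "\n")


def read_metadata(path: str) -> list[SampleMetadata]:
    """Read the tab-separated sample metadata table (mandatory header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "species", "site", "zone", "sex"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(SampleMetadata(row.sample_id, row.species,
                                          row.site, row.zone, row.sex))
        except ValidationError as err:
            raise ValidationError(f"metadata row {i}: {err}") from None
    ids = [r.sample_id for r in records]
    dupes = sorted({s for s in ids if ids.count(s) > 1})
    if dupes:
        raise ValidationError(f"duplicate sample_id(s): {dupes}")
    site_zone: dict[str, str] = {}
    for r in records:
        if site_zone.setdefault(r.site, r.zone) != r.zone:
            raise ValidationError(f"site {r.site!r} maps to more than one zone")
    return records


def write_metadata(path: str, records: list[SampleMetadata]) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tspecies\tsite\tzone\tsex\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.species}\t{r.site}\t{r.zone}\t{r.sex}\n")


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    gene_name: str
    family: str
    contig: str
    start: int
    end: int

    def __post_init__(self):
        if self.family not in GENE_FAMILIES:
            raise ValidationError(f"unknown gene family {self.family!r}")
        if self.contig not in CONTIGS:
            raise ValidationError(f"unknown contig {self.contig!r}")
        if self.start > self.end:
            raise ValidationError(f"start > end for gene {self.gene_id}")


def read_gene_annotation(path: str) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "gene_name": str,
                                            "family": str, "contig": str})
    required = ["gene_id", "gene_name", "family", "contig", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"gene annotation missing columns: {missing}")
    genes = [GeneAnnotation(r.gene_id, r.gene_name, r.family, r.contig,
                            int(r.start), int(r.end)) for r in df.itertuples()]
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate gene_id in annotation")
    return genes


def write_gene_annotation(path: str, genes: list[GeneAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgene_name\tfamily\tcontig\tstart\tend\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.gene_name}\t{g.family}\t{g.contig}"
                     f"\t{g.start}\t{g.end}\n")


@dataclass
class CopyNumberTable:
    """Sparse per-sample per-gene modal copy numbers.

    Missing (sample, gene) pairs are "no call" and are excluded from frequency
    denominators downstream.
    """

    entries: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["sample_id", "gene_id", "cn"]))

    def __post_init__(self):
        df = self.entries
        if list(df.columns) != ["sample_id", "gene_id", "cn"]:
            raise ValidationError("CN table needs columns sample_id, gene_id, cn")
        if len(df) and (df.cn < 0).any():
            bad = df[df.cn < 0].iloc[0]
            raise ValidationError(
                f"negative copy number for ({bad.sample_id}, {bad.gene_id})")
        self.entries = df.astype({"sample_id": str, "gene_id": str, "cn": np.int64})

    def validate_against(self, metadata: list[SampleMetadata],
                         annotation: list[GeneAnnotation]) -> None:
        samples = {m.sample_id for m in metadata}
        genes = {g.gene_id for g in annotation}
        bad_s = sorted(set(self.entries.sample_id) - samples)
        if bad_s:
            raise ValidationError(f"unknown sample_id(s) in CN table: {bad_s[:5]}")
        bad_g = sorted(set(self.entries.gene_id) - genes)
        if bad_g:
            raise ValidationError(f"unknown gene_id(s) in CN table: {bad_g[:5]}")


def read_cn_table(path: str,
                  annotation: list[GeneAnnotation] | None = None) -> CopyNumberTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene_id": str})
    required = ["sample_id", "gene_id", "cn"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"CN table missing columns: {missing}")
    table = CopyNumberTable(df[required].copy())
    if annotation is not None:
        genes = {g.gene_id for g in annotation}
        bad = sorted(set(table.entries.gene_id) - genes)
        if bad:
            raise ValidationError(f"unknown gene_id(s) in CN table: {bad[:5]}")
    return table


def write_cn_table(path: str, table: CopyNumberTable) -> None:
    table.entries.to_csv(path, sep="\t", index=False)


def write_table(path: str, df: pd.DataFrame, float_fmt: str = "%.6g") -> None:
    """Write a result table as TSV with fixed float formatting (stable diffs)."""
    df.to_csv(path, sep="\t", index=False, float_format=float_fmt)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(path: str, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
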