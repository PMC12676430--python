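"""Codon-level effect annotation against a transcript model, and
per-population amino-acid-level allele frequencies.

Effect labels follow the community convention ``<refAA><codonIndex><altAA>``
(e.g. L995F), with the codon index counted within the supplied transcript's
coding sequence. Numbering conventions for this gene have drifted over the
years (the classic kdr site has carried both a 995 and a legacy 1014 index);
no numbering is hard-coded — an alias map can rename labels for display.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .core_io import GenotypeMatrix, SampleMetadata, VariantTable

MISSING = -1

_AA_CHANGE = re.compile(r"^[A-Z*]\d+[A-Z*]$")


@dataclass
class TranscriptModel:
    """Coding exons of one transcript plus the reference sequence.

    ``exons`` are 1-based inclusive genomic spans in ascending genomic order;
    ``ref_seq`` is the forward-strand reference starting at genomic position
    ``ref_start``. The concatenated exon sequence (reverse-complemented for
    minus-strand transcripts) must be a whole number of codons.
    """

    transcript_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    ref_seq: str
    ref_start: int = 1

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap")
        if self.cds_length() % 3 != 0:
            raise ValueError("CDS length not divisible by 3")
        self.ref_seq = self.ref_seq.upper()

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def ref_base(self, pos: int) -> str:
        i = pos - self.ref_start
        if not 0 <= i < len(self.ref_seq):
            raise ValueError(f"position {pos} outside the reference sequence")
        return self.ref_seq[i]

    def cds_positions(self) -> list[int]:
        """Genomic positions in CDS (5'->3' transcript) order."""
        pos = [p for s, e in self.exons for p in range(s, e + 1)]
        return pos[::-1] if self.strand == "-" else pos

    def cds_index(self, pos: int) -> int | None:
        """0-based index within the CDS, or None if the position is intronic."""
        offset = 0
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        for s, e in exons:
            if s <= pos <= e:
                within = (pos - s) if self.strand == "+" else (e - pos)
                return offset + within
            offset += e - s + 1
        return None

    def cds_sequence(self) -> str:
        seq = "".join(self.ref_base(p) for p in
                      (pos for s, e in self.exons for pos in range(s, e + 1)))
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def annotate_effects(variants: VariantTable, tx: TranscriptModel
                     ) -> VariantTable:
    """Label every alt allele as intronic / synonymous / an AA substitution.

    Multiallelic sites are annotated per alt independently; minus-strand
    transcripts use reverse-complemented alleles. Raises if a variant's ref
    allele disagrees with the reference sequence.
    """
    cds = tx.cds_sequence()
    labels: list[tuple[str, ...]] = []
    for j in range(variants.n_variants):
        pos = int(variants.pos[j])
        if variants.contig[j] != tx.contig:
            labels.append(tuple("intronic" for _ in variants.alts[j]))
            continue
        idx = tx.cds_index(pos)
        if idx is None:
            labels.append(tuple("intronic" for _ in variants.alts[j]))
            continue
        if tx.ref_base(pos) != variants.ref[j]:
            raise ValueError(
                f"ref allele mismatch at {tx.contig}:{pos}: variant table has "
                f"{variants.ref[j]}, reference sequence has {tx.ref_base(pos)}")
        codon_i, within = divmod(idx, 3)
        codon = cds[3 * codon_i: 3 * codon_i + 3]
        aa_ref = str(Seq(codon).translate())
        site_labels = []
        for alt in variants.alts[j]:
            base = alt.translate(_COMPLEMENT) if tx.strand == "-" else alt
            mutated = codon[:within] + base + codon[within + 1:]
            aa_alt = str(Seq(mutated).translate())
            if aa_alt == aa_ref:
                site_labels.append("synonymous")
            else:
                site_labels.append(f"{aa_ref}{codon_i + 1}{aa_alt}")
        labels.append(tuple(site_labels))
    return VariantTable(list(variants.contig), variants.pos.copy(),
                        list(variants.ref), list(variants.alts),
                        effect_labels=labels)


def read_transcript(exons_path: str, fasta_path: str) -> TranscriptModel:
    """Load a transcript from a tab-separated exon table plus a FASTA.

    The exon table needs columns transcript_id, contig, strand, start, end
    (one row per coding exon); the FASTA record whose id matches the contig
    supplies the reference, taken to start at genomic position 1 unless the
    record id is ``contig:start``.
    """
    from Bio import SeqIO
    df = pd.read_csv(exons_path, sep="\t", dtype={"transcript_id": str,
                                                  "contig": str, "strand": str})
    if df.transcript_id.nunique() != 1:
        raise ValueError("exon table must describe exactly one transcript")
    contig = df.contig.iloc[0]
    ref_seq, ref_start = None, 1
    for rec in SeqIO.parse(fasta_path, "fasta"):
        name, _, start = rec.id.partition(":")
        if name == contig:
            ref_seq = str(rec.seq)
            ref_start = int(start) if start else 1
            break
    if ref_seq is None:
        raise ValueError(f"no FASTA record for contig {contig!r}")
    return TranscriptModel(
        transcript_id=df.transcript_id.iloc[0], contig=contig,
        strand=df.strand.iloc[0],
        exons=[(int(r.start), int(r.end)) for r in df.itertuples()],
        ref_seq=ref_seq, ref_start=ref_start)


def is_nonsynonymous(label: str | None) -> bool:
    return bool(label) and label not in ("synonymous", "intronic") \
        and _AA_CHANGE.match(label) is not None


def allele_frequencies(variants: VariantTable, genotypes: GenotypeMatrix,
                       groups: dict[str, np.ndarray],
                       min_freq: float | None = 0.05) -> pd.DataFrame:
    """Per-population alt-allele frequencies.

    frequency = alt alleles among non-missing calls / non-missing alleles.
    When ``min_freq`` is set, a (variant, alt) row is kept only if its
    frequency reaches the threshold in at least one population (the
    permissive max-over-populations rule). Populations with zero called
    alleles at a site get a NaN frequency, flagged ``undefined``.
    """
    if any(len(np.asarray(idx)) == 0 for idx in groups.values()):
        raise ValueError("empty population group")
    rows = []
    calls = genotypes.calls
    for pop, idx in groups.items():
        sub = calls[np.asarray(idx)]            # (m, S, 2)
        called = (sub != MISSING).sum(axis=(0, 2)).astype(float)
        for j in range(variants.n_variants):
            eff = variants.effect_labels[j] if variants.effect_labels else None
            for a, alt in enumerate(variants.alts[j], start=1):
                count = int((sub[:, j, :] == a).sum())
                total = int(called[j])
                freq = count / total if total else float("nan")
                rows.append({
                    "population": pop, "contig": variants.contig[j],
                    "pos": int(variants.pos[j]), "alt": alt,
                    "effect": eff[a - 1] if eff else "",
                    "count": count, "total": total, "frequency": freq,
                    "undefined": total == 0,
                })
    df = pd.DataFrame(rows)
    if min_freq is not None and len(df):
        key = ["contig", "pos", "alt"]
        max_freq = df.groupby(key)["frequency"].transform("max")
        df = df[(max_freq >= min_freq) | max_freq.isna()].reset_index(drop=True)
    return df


def add_cumulative_402(freq_df: pd.DataFrame, panel) -> pd.DataFrame:
    """Append one derived row per population: the cumulative V402L frequency
    (g>t plus g>c), the quantity comparable with the 1527T frequency."""
    locus = panel.locus("402")
    site = freq_df[(freq_df.contig == locus.contig) &
                   (freq_df.pos == locus.pos)]
    extra = []
    for pop, sub in site.groupby("population", sort=False):
        extra.append({
            "population": pop, "contig": locus.contig, "pos": locus.pos,
            "alt": "+".join(locus.alts), "effect": "V402L_cumulative",
            "count": int(sub["count"].sum()),
            "total": int(sub["total"].max()) if len(sub) else 0,
            "frequency": float(sub["frequency"].sum()),
            "undefined": bool(sub["undefined"].any()),
        })
    return pd.concat([freq_df, pd.DataFrame(extra)], ignore_index=True)


def effect_summary(variants: VariantTable, genotypes: GenotypeMatrix | None
                   = None, sample_idx=None) -> dict:
    """Site-level effect composition of a segregating-site set.

    Reports the number of sites, how many carry at least one non-synonymous
    alt, and the corresponding fraction. When a genotype matrix is given,
    only sites segregating in the (optional) sample subset are counted;
    otherwise every row of the variant table counts as segregating.
    """
    if variants.effect_labels is None:
        raise ValueError("variant table has no effect labels")
    if genotypes is not None:
        from .diversity import count_segregating, _allele_counts
        idx = np.arange(genotypes.n_samples) if sample_idx is None \
            else np.asarray(sample_idx)
        haps = genotypes.take_samples(idx).to_haplotypes()
        counts, _ = _allele_counts(haps)
        seg = (counts > 0).sum(axis=0) >= 2
    else:
        seg = np.ones(variants.n_variants, dtype=bool)
    n_sites = int(seg.sum())
    nonsyn = sum(1 for j in np.flatnonzero(seg)
                 if any(is_nonsynonymous(l) for l in variants.effect_labels[j]))
    return {
        "n_sites": n_sites,
        "n_non_synonymous": nonsyn,
        "non_synonymous_fraction": nonsyn / n_sites if n_sites else float("nan"),
    }
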