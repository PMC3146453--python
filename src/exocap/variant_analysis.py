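"""Classification and quality summaries of high-confidence variant calls.

A high-confidence consensus genotype differing from the reference is
either a *fixed difference* (homozygous for a non-reference allele) or a
*heterozygous SNP* (an IUPAC ambiguity genotype). This module computes
the study-style summaries: per-individual variant counts and rates,
concordance with a table of known variants (dbSNP-like), transition/
transversion ratios, per-gene counts over the candidate set, concordance
with Sanger resequencing of selected windows, stability of call sets
across the genotyper's variant-rate parameter, and per-chromosome
distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dna import alleles_of, is_transition
from .genotyping import ConsensusCall
from .read_processing import TargetIndex
from .util import percent

__all__ = [
    "VariantCall",
    "VariantSummary",
    "classify_variants",
    "summarize",
    "dbsnp_concordance",
    "titv_ratio",
    "per_gene_counts",
    "load_sanger_table",
    "compare_to_sanger",
    "callset_overlap",
    "chromosome_distribution",
    "write_variants_vcf",
    "write_variants_tsv",
    "read_known_variants",
]

FIXED = "fixed_difference"
HETEROZYGOUS = "heterozygous_snp"


@dataclass(frozen=True)
class VariantCall:
    chromosome: str
    position: int  # 1-based in reports; stored 1-based here
    reference_base: str
    genotype: str  # IUPAC
    variant_class: str  # FIXED or HETEROZYGOUS
    depth: int
    quality: int
    gene_id: str | None = None

    @property
    def alleles(self) -> frozenset[str]:
        return alleles_of(self.genotype)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chromosome, self.position, self.genotype)


@dataclass(frozen=True)
class VariantSummary:
    """Per-individual variant summary (counts and 2-decimal percentages)."""

    n_heterozygous: int
    n_fixed: int
    n_genotyped_bases: int
    dbsnp_position_matches: int | None = None
    dbsnp_allele_mismatches: int | None = None

    @property
    def n_total(self) -> int:
        return self.n_heterozygous + self.n_fixed

    @property
    def percent_total(self) -> float:
        return percent(self.n_total, self.n_genotyped_bases)

    @property
    def dbsnp_match_percent(self) -> float | None:
        if self.dbsnp_position_matches is None:
            return None
        return percent(self.dbsnp_position_matches, self.n_total)

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "heterozygous_snps": self.n_heterozygous,
                "fixed_differences": self.n_fixed,
                "total_differences": self.n_total,
                "percent_total": self.percent_total,
                "total_genotyped_bases": self.n_genotyped_bases,
                "dbsnp_position_matches": self.dbsnp_position_matches,
                "dbsnp_match_percent": self.dbsnp_match_percent,
                "dbsnp_allele_mismatches": self.dbsnp_allele_mismatches,
            }
        )


def classify_variants(
    calls: Iterable[ConsensusCall],
    targets: TargetIndex | None = None,
) -> list[VariantCall]:
    """Drop reference-homozygous calls; class the rest.

    Calls with genotypes outside the diploid ACGT/two-allele IUPAC codes
    are skipped with a warning. If a target index is given, each variant
    is annotated with the gene of the target exon containing it.
    """
    out: list[VariantCall] = []
    for c in calls:
        try:
            alleles = alleles_of(c.genotype)
        except ValueError:
            warnings.warn(
                f"{c.chromosome}:{c.position + 1}: genotype {c.genotype!r} skipped"
            )
            continue
        if alleles == frozenset(c.reference_base):
            continue
        cls = HETEROZYGOUS if len(alleles) == 2 else FIXED
        gene_id = None
        if targets is not None:
            hits = targets.containing(c.chromosome, c.position)
            if hits:
                gene_id = hits[0].gene_id
        out.append(
            VariantCall(
                chromosome=c.chromosome,
                position=c.position + 1,
                reference_base=c.reference_base,
                genotype=c.genotype,
                variant_class=cls,
                depth=c.depth,
                quality=c.quality,
                gene_id=gene_id,
            )
        )
    return out


def summarize(
    variants: Iterable[VariantCall],
    n_genotyped_bases: int,
    dbsnp_position_matches: int | None = None,
    dbsnp_allele_mismatches: int | None = None,
) -> VariantSummary:
    if n_genotyped_bases <= 0:
        raise ValueError("n_genotyped_bases must be positive")
    variants = list(variants)
    return VariantSummary(
        n_heterozygous=sum(1 for v in variants if v.variant_class == HETEROZYGOUS),
        n_fixed=sum(1 for v in variants if v.variant_class == FIXED),
        n_genotyped_bases=n_genotyped_bases,
        dbsnp_position_matches=dbsnp_position_matches,
        dbsnp_allele_mismatches=dbsnp_allele_mismatches,
    )


def dbsnp_concordance(
    variants: Sequence[VariantCall],
    known_variants: Mapping[tuple[str, int], frozenset[str]],
) -> tuple[int, int, float]:
    """(position matches, allele mismatches, match percent of all variants).

    A position match is a called variant at a known-variant position; an
    allele mismatch is a position match whose genotype allele set is
    disjoint from the known alleles. Coordinates must share the same
    (1-based) convention; no conversion heuristics are applied.
    """
    matches = 0
    mismatches = 0
    for v in variants:
        known = known_variants.get((v.chromosome, v.position))
        if known is None:
            continue
        matches += 1
        if not (v.alleles & known):
            mismatches += 1
    pct = percent(matches, len(variants)) if variants else 0.0
    return matches, mismatches, pct


def titv_ratio(het_variants: Iterable[VariantCall]) -> float | None:
    """Transitions / transversions among heterozygous SNPs (None if no Tv).

    A heterozygote carrying the reference allele contributes its single
    ref<->alt substitution; the rare heterozygote with two non-reference
    alleles contributes each ref->alt substitution with weight 1/2.
    """
    ts = 0.0
    tv = 0.0
    for v in het_variants:
        if v.variant_class != HETEROZYGOUS:
            raise ValueError("titv_ratio expects heterozygous variants only")
        alts = v.alleles - {v.reference_base}
        weight = 1.0 / len(alts)
        for alt in alts:
            if is_transition(v.reference_base, alt):
                ts += weight
            else:
                tv += weight
    if tv == 0:
        return None
    return ts / tv


def per_gene_counts(
    variants: Iterable[VariantCall],
    targets: TargetIndex,
    candidate_gene_ids: Iterable[str],
) -> tuple[dict[str, int], int, tuple[int, int]]:
    """Heterozygous-SNP counts per gene.

    Returns (per-gene het counts, off-target het count, and the pair
    (number of candidate genes with >= 1 het SNP, het SNPs in candidate
    genes)). Variants outside every target are tallied in the off-target
    bucket with a warning.
    """
    candidate = set(candidate_gene_ids)
    counts: dict[str, int] = {}
    off_target = 0
    for v in variants:
        if v.variant_class != HETEROZYGOUS:
            continue
        gene = v.gene_id
        if gene is None:
            hits = targets.containing(v.chromosome, v.position - 1)
            gene = hits[0].gene_id if hits else None
        if gene is None:
            warnings.warn(
                f"het SNP {v.chromosome}:{v.position} outside all targets"
            )
            off_target += 1
            continue
        counts[gene] = counts.get(gene, 0) + 1
    cand_hit = sum(1 for g in counts if g in candidate)
    cand_het = sum(n for g, n in counts.items() if g in candidate)
    return counts, off_target, (cand_hit, cand_het)


# ---------------------------------------------------------------------------
# Sanger verification


def load_sanger_table(path=None) -> pd.DataFrame:
    """The packaged Sanger verification table (or an external TSV).

    Columns: sample, chrom, sanger_start, sanger_stop, position, reference,
    sanger, maq (the pipeline genotype), gene.
    """
    if path is None:
        ref = resources.files("exocap.data").joinpath("sanger_verification.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype={"chrom": str})
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    bad = (df.position < df.sanger_start) | (df.position > df.sanger_stop)
    if bad.any():
        raise ValueError("Sanger record position outside its sequencing window")
    return df


def compare_to_sanger(
    records: pd.DataFrame,
    pipeline_genotypes: Mapping[tuple[str, int], str] | None = None,
) -> dict[str, dict]:
    """Per-sample concordance of pipeline calls with Sanger genotypes.

    Concordant: pipeline genotype equals the Sanger genotype (IUPAC,
    case-insensitive). False positive: the pipeline called a variant where
    the Sanger genotype equals the reference base. If
    ``pipeline_genotypes`` is given it overrides the table's pipeline
    column (positions 1-based).
    """
    out: dict[str, dict] = {}
    for sample, grp in records.groupby("sample", sort=True):
        concordant = 0
        false_pos = 0
        detail: list[dict] = []
        for row in grp.itertuples(index=False):
            sanger = str(row.sanger).upper()
            ref = str(row.reference).upper()
            for g in (sanger, ref):
                alleles_of(g)  # malformed IUPAC -> ValueError
            if pipeline_genotypes is not None:
                pipeline = pipeline_genotypes.get((str(row.chrom), int(row.position)))
                pipeline = (pipeline or ref).upper()
            else:
                pipeline = str(row.maq).upper()
            alleles_of(pipeline)
            if pipeline == sanger:
                concordant += 1
            else:
                if sanger == ref and pipeline != ref:
                    false_pos += 1
                detail.append(
                    {
                        "chrom": str(row.chrom),
                        "position": int(row.position),
                        "reference": ref,
                        "sanger": sanger,
                        "pipeline": pipeline,
                        "gene": row.gene,
                    }
                )
        out[str(sample)] = {
            "concordant": concordant,
            "false_positives": false_pos,
            "discordant": detail,
        }
    return out


# ---------------------------------------------------------------------------
# call-set stability and chromosome distribution


def callset_overlap(
    callsets: Sequence[Sequence[VariantCall]],
) -> tuple[int, int, np.ndarray]:
    """Intersection of call sets identified by (chrom, pos, genotype).

    Returns (calls shared by all sets, that count as a whole percent of
    the first set, and the pairwise shared-count matrix).
    """
    if not callsets:
        raise ValueError("need at least one call set")
    keysets = [frozenset(v.key for v in cs) for cs in callsets]
    shared = set(keysets[0])
    for ks in keysets[1:]:
        shared &= ks
    n_shared = len(shared)
    frac = (
        int(round(100.0 * n_shared / len(keysets[0]))) if keysets[0] else 100
    )
    n = len(keysets)
    pairwise = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            pairwise[i, j] = len(keysets[i] & keysets[j])
    return n_shared, frac, pairwise


def chromosome_distribution(
    variants: Iterable[VariantCall], chromosomes: Sequence[str]
) -> pd.DataFrame:
    """Counts of total differences and het SNPs per chromosome."""
    idx = {c: i for i, c in enumerate(chromosomes)}
    total = np.zeros(len(chromosomes), dtype=int)
    het = np.zeros(len(chromosomes), dtype=int)
    for v in variants:
        if v.chromosome not in idx:
            raise ValueError(f"variant on unknown chromosome {v.chromosome!r}")
        total[idx[v.chromosome]] += 1
        if v.variant_class == HETEROZYGOUS:
            het[idx[v.chromosome]] += 1
    return pd.DataFrame(
        {
            "chromosome": list(chromosomes),
            "total_differences": total,
            "heterozygous_snps": het,
        }
    )


# ---------------------------------------------------------------------------
# I/O


def write_variants_tsv(variants: Sequence[VariantCall], path) -> None:
    pd.DataFrame(
        {
            "chrom": [v.chromosome for v in variants],
            "pos": [v.position for v in variants],
            "ref": [v.reference_base for v in variants],
            "genotype": [v.genotype for v in variants],
            "class": [v.variant_class for v in variants],
            "qual": [v.quality for v in variants],
            "depth": [v.depth for v in variants],
            "gene": [v.gene_id or "." for v in variants],
        }
    ).to_csv(path, sep="\t", index=False)


def write_variants_vcf(variants: Sequence[VariantCall], path) -> None:
    """Minimal single-sample VCF 4.2 with GT, DP and GQ."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for v in sorted(variants, key=lambda v: (v.chromosome, v.position)):
            alts = sorted(v.alleles - {v.reference_base})
            allele_idx = {v.reference_base: 0, **{a: i for i, a in enumerate(alts, 1)}}
            if len(v.alleles) == 1:
                a = next(iter(v.alleles))
                pair = (a, a)
            else:
                pair = tuple(sorted(v.alleles, key=lambda a: allele_idx[a]))
            gt = f"{allele_idx[pair[0]]}/{allele_idx[pair[1]]}"
            fh.write(
                f"{v.chromosome}\t{v.position}\t.\t{v.reference_base}\t"
                f"{','.join(alts)}\t{v.quality}\tPASS\tGT:DP:GQ\t"
                f"{gt}:{v.depth}:{v.quality}\n"
            )


def read_known_variants(path) -> dict[tuple[str, int], frozenset[str]]:
    """Known-variant table as VCF or 3-column TSV (chrom, pos, alleles).

    Positions are 1-based; alleles comma-separated in the TSV form.
    """
    known: dict[tuple[str, int], frozenset[str]] = {}
    with open(path) as fh:
        first = fh.readline()
        is_vcf = first.startswith("##fileformat=VCF")
        fh.seek(0)
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if is_vcf:
                chrom, pos = f[0], int(f[1])
                alleles = frozenset([f[3].upper()]) | frozenset(
                    a.upper() for a in f[4].split(",")
                )
            else:
                chrom, pos = f[0], int(f[1])
                alleles = frozenset(a.strip().upper() for a in f[2].split(","))
            key = (chrom, pos)
            known[key] = known.get(key, frozenset()) | alleles
    return known
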