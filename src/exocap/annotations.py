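"""Reading and writing reference annotation files.

GFF3 is the canonical annotation format here (gene + exon +
five_prime_UTR features); a BED12 representation is also supported,
where the thin 5' portion (before thickStart on '+', after thickEnd on
'-') marks the exon carrying the 5' UTR.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .target_design import AnnotationError, GeneModel

__all__ = [
    "write_gff3",
    "read_gff3",
    "write_bed12",
    "read_bed12",
    "write_fasta",
    "read_fasta",
    "write_gene_list",
    "read_gene_list",
]


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            fh.write(
                f"{g.chromosome}\texocap\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons):
                fh.write(
                    f"{g.chromosome}\texocap\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
            us, ue = g.exons[g.utr5_exon]
            fh.write(
                f"{g.chromosome}\texocap\tfive_prime_UTR\t{us + 1}\t{ue}\t.\t"
                f"{g.strand}\t.\tParent={g.gene_id}\n"
            )


def _gff_attrs(field: str) -> dict[str, str]:
    out = {}
    for item in field.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise AnnotationError(f"malformed GFF3 line: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
            iv = (int(start) - 1, int(end))
            a = _gff_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise AnnotationError("gene feature without ID")
                genes[gid] = {"chrom": chrom, "strand": strand, "exons": [], "utr": None}
                order.append(gid)
            elif ftype == "exon":
                gid = a.get("Parent")
                if gid not in genes:
                    raise AnnotationError(f"exon with unknown Parent {gid!r}")
                genes[gid]["exons"].append(iv)
            elif ftype == "five_prime_UTR":
                gid = a.get("Parent")
                if gid not in genes:
                    raise AnnotationError(f"five_prime_UTR with unknown Parent {gid!r}")
                genes[gid]["utr"] = iv
    out: list[GeneModel] = []
    for gid in order:
        rec = genes[gid]
        exons = tuple(sorted(rec["exons"]))
        if rec["utr"] is None:
            raise AnnotationError(f"gene {gid} lacks a five_prime_UTR feature")
        us, ue = rec["utr"]
        utr_idx = next(
            (i for i, (s, e) in enumerate(exons) if s <= us and ue <= e), None
        )
        if utr_idx is None:
            raise AnnotationError(f"gene {gid}: 5' UTR not contained in any exon")
        out.append(GeneModel(gid, rec["chrom"], rec["strand"], exons, utr_idx))
    return out


def write_bed12(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            us, ue = g.exons[g.utr5_exon]
            # thin region = the 5' UTR exon
            thick_start, thick_end = (ue, g.end) if g.strand == "+" else (g.start, us)
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, _ in g.exons)
            fh.write(
                f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{thick_start}\t{thick_end}\t0\t{len(g.exons)}\t{sizes},\t{starts},\n"
            )


def read_bed12(path) -> list[GeneModel]:
    out: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise AnnotationError("BED12 requires 12 columns")
            chrom, start, _end, gid, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (start + off, start + off + size) for off, size in zip(starts, sizes)
            )
            utr_idx = 0 if strand == "+" else len(exons) - 1
            out.append(GeneModel(gid, chrom, strand, exons, utr_idx))
    return out


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out


def write_gene_list(gene_ids: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for gid in gene_ids:
            fh.write(f"{gid}\n")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
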