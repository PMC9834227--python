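"""Readers and writers for the standard formats the pipeline exchanges:
FASTA/GTF/VCF for the reference side, MatrixMarket trios for count and
genotype matrices, TSV for everything tabular."""

from __future__ import annotations

import textwrap
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import io as scipy_io
from scipy import sparse

from .annotation import TranscriptModel
from .genotype import VariantSite


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            fh.write("\n".join(textwrap.wrap(seq, 60)))
            fh.write("\n")
    pysam.faidx(str(path))


def read_fasta(path: str | Path) -> dict[str, str]:
    import pyfaidx

    with pyfaidx.Fasta(str(path)) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_gtf(annotation: Iterable[TranscriptModel], path: str | Path, source: str = "dropgeno") -> None:
    """Write exon features, converting internal 0-based half-open intervals
    back to the GTF's 1-based inclusive convention."""
    with open(path, "w") as fh:
        for tx in annotation:
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'canonical "{str(tx.canonical).lower()}";'
            )
            for s, e in tx.exons:
                fh.write(
                    f"{tx.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


def write_vcf(variants: Sequence[VariantSite], path: str | Path, contigs: Mapping[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write('##INFO=<ID=ROLE,Number=1,Type=String,Description="Variant role">\n')
        fh.write('##INFO=<ID=POPDB,Number=0,Type=Flag,Description="Present in population database">\n')
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            info = f"GENE={v.gene_id or '.'};ROLE={v.role}"
            if v.in_population_db:
                info += ";POPDB"
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n")


def read_vcf(path: str | Path) -> list[VariantSite]:
    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if len(rec.ref) != 1 or len(alt) != 1 or alt not in "ACGT":
                    continue  # SNVs only
                info = dict(rec.info)
                variants.append(
                    VariantSite(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene_id=str(info.get("GENE", "")).replace(".", ""),
                        role=str(info.get("ROLE", "germline")),
                        in_population_db=bool(info.get("POPDB", False)),
                    )
                )
    return variants


def write_counts_mtx(counts: pd.DataFrame, outdir: str | Path) -> None:
    """Write a genes x cells count DataFrame as the market-matrix trio
    (matrix.mtx, features.tsv, barcodes.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy_io.mmwrite(str(outdir / "matrix.mtx"), sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(counts.columns).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)


def read_counts_mtx(outdir: str | Path) -> pd.DataFrame:
    outdir = Path(outdir)
    mat = scipy_io.mmread(str(outdir / "matrix.mtx")).toarray().astype(np.int64)
    genes = pd.read_csv(outdir / "features.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(outdir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    return pd.DataFrame(mat, index=genes, columns=barcodes)


def write_genotype_matrices(matrices, outdir: str | Path) -> None:
    """Genotyper output as two MTX matrices sharing barcodes/variants axes,
    plus a long-form calls TSV."""
    from .genotype import CALL_LABELS

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy_io.mmwrite(str(outdir / "ref.mtx"), matrices.ref_umis)
    scipy_io.mmwrite(str(outdir / "alt.mtx"), matrices.alt_umis)
    pd.Series(matrices.barcodes).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)
    pd.DataFrame(
        [
            {
                "variant": v.id, "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "gene_id": v.gene_id, "role": v.role, "in_population_db": v.in_population_db,
            }
            for v in matrices.variants
        ]
    ).to_csv(outdir / "variants.tsv", sep="\t", index=False)
    rows, cols = np.nonzero(matrices.calls)
    calls = pd.DataFrame(
        {
            "barcode": [matrices.barcodes[i] for i in rows],
            "variant": [matrices.variants[j].id for j in cols],
            "call": [CALL_LABELS[int(matrices.calls[i, j])] for i, j in zip(rows, cols)],
        }
    )
    calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
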