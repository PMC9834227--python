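"""Synthetic droplet snRNA-seq data with known genotype truth.

Emulates what the genotyping analyses assume about real 10x-style data:
end-biased capture (a fixed-length read anchored at the captured transcript
end), per-cell-type negative-binomial expression, a mosaic variant carried
by a Bernoulli-sampled subset of cells, internal poly-A mispriming, per-base
sequencing error, and UMI duplication. Reads are written directly as tagged,
coordinate-sorted alignments (as they would arrive from Cell Ranger), and a
truth table records every cell's mutant status and every read's origin so
downstream stages can be checked by parameter recovery.

The simulated genome deliberately contains no spontaneous A-homopolymer
longer than two bases, so internal poly-A capture sites exist exactly where
the configuration injects them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import TranscriptModel, canonical_by_gene
from .genotype import VariantSite
from .mispriming import scan_polyA

_BASES = np.frombuffer(b"ACGT", dtype="S1")

THREE_PRIME = "three_prime"
FIVE_PRIME = "five_prime"
DEFAULT_READ_LENGTH = {THREE_PRIME: 91, FIVE_PRIME: 90}


@dataclass(frozen=True)
class CellType:
    name: str
    germ_layer: str
    proportion: float


#: brain cell-type mix loosely patterned on a cortical resection
DEFAULT_CELL_TYPES = (
    CellType("Microglia", "mesoderm", 0.10),
    CellType("ExcitatoryNeurons", "ectoderm", 0.30),
    CellType("Interneurons", "ectoderm", 0.10),
    CellType("Astrocytes", "ectoderm", 0.20),
    CellType("Oligodendrocytes", "ectoderm", 0.20),
    CellType("OPC", "ectoderm", 0.10),
)


@dataclass(frozen=True)
class PolyASpec:
    """An internal A-homopolymer to inject into one transcript."""

    gene: int  # gene index
    tx_coord: int  # spliced position of the run's first base
    run_length: int = 10


@dataclass(frozen=True)
class VariantPlacement:
    """Where to put an injected variant, in spliced coordinates."""

    gene: int
    tx_coord: int
    role: str = "somatic_candidate"


@dataclass(frozen=True)
class ExpressionModel:
    """Negative-binomial mean per (gene, cell type) and a common dispersion."""

    means: tuple[tuple[float, ...], ...]  # genes x cell types
    dispersion: float = 2.0

    def mean(self, gene_idx: int, type_idx: int) -> float:
        return self.means[gene_idx][type_idx]

    @classmethod
    def random(
        cls,
        n_genes: int,
        cell_types: Sequence[CellType],
        rng: np.random.Generator,
        mean_range: tuple[float, float] = (0.5, 5.0),
        dispersion: float = 2.0,
        marker_genes: Mapping[int, str] | None = None,
        marker_mean: float = 8.0,
    ) -> "ExpressionModel":
        """Log-uniform means per gene shared across cell types, with optional
        marker genes expressed in a single cell type only."""
        lo, hi = mean_range
        base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
        means = np.tile(base[:, None], (1, len(cell_types)))
        # mild per-type variation so types are not identical
        means *= np.exp(rng.normal(0.0, 0.2, size=means.shape))
        if marker_genes:
            type_idx = {ct.name: i for i, ct in enumerate(cell_types)}
            for g, ct_name in marker_genes.items():
                means[g, :] = 0.0
                means[g, type_idx[ct_name]] = marker_mean
        return cls(tuple(map(tuple, means.round(6))), dispersion)


@dataclass(frozen=True)
class SimConfig:
    n_cells: int = 500
    cell_types: tuple[CellType, ...] = DEFAULT_CELL_TYPES
    n_genes: int = 8
    transcript_length_range: tuple[int, int] = (800, 2500)
    kit_end: str = THREE_PRIME
    read_length: Optional[int] = None  # default 91 (3') / 90 (5')
    capture_decay: float = 0.0  # nt scale of exponential end-bias; 0 = exact end
    mispriming_rate: float = 0.05
    error_rate: float = 0.001
    mosaic_fraction: float = 0.05
    mutant_cell_types: Optional[tuple[str, ...]] = None  # None = all types
    expression_model: Optional[ExpressionModel] = None
    marker_genes: Optional[Mapping[int, str]] = None
    nb_mean_range: tuple[float, float] = (0.5, 5.0)
    nb_dispersion: float = 2.0
    internal_polyA: tuple[PolyASpec, ...] = ()
    exon_layout: Optional[tuple[tuple[int, ...], ...]] = None  # explicit exon lengths per gene
    variants: tuple[VariantPlacement, ...] = (VariantPlacement(0, 50, "somatic_candidate"),)
    umi_length: int = 10
    umi_duplicate_rate: float = 0.2  # expected extra reads per molecule (Poisson)
    polyA_min_run: int = 6
    polyA_window: int = 10
    polyA_min_frac: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(ct.proportion for ct in self.cell_types) - 1.0) > 1e-8:
            raise ValueError("cell-type proportions must sum to 1")
        if not 0.0 <= self.mosaic_fraction <= 1.0:
            raise ValueError("mosaic_fraction must lie in [0, 1]")
        for name, rate in (
            ("mispriming_rate", self.mispriming_rate),
            ("error_rate", self.error_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.kit_end not in (THREE_PRIME, FIVE_PRIME):
            raise ValueError(f"kit_end must be {THREE_PRIME} or {FIVE_PRIME}")
        if self.resolved_read_length <= 0:
            raise ValueError("read_length must be > 0")
        if self.n_genes < 1 or self.n_cells < 1:
            raise ValueError("n_genes and n_cells must be >= 1")
        if self.transcript_length_range[0] < self.resolved_read_length:
            raise ValueError("transcripts must be at least one read long")

    @property
    def resolved_read_length(self) -> int:
        return self.read_length if self.read_length is not None else DEFAULT_READ_LENGTH[self.kit_end]

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible generator per pipeline stage."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class SimTruth:
    cell_table: pd.DataFrame  # barcode, cell_type, germ_layer, is_mutant
    read_table: pd.DataFrame  # read_id, barcode, umi, gene, origin_site, allele_carried
    variant_table: pd.DataFrame  # variant, gene, true_vaf, n_mutant_cells


def gene_name(i: int) -> str:
    return f"GENE{i:03d}"


def _random_sequence(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random sequence with no A-run longer than 2 (so the poly-A scanner
    never fires on background sequence)."""
    draws = rng.integers(0, 4, size=n)
    seq = np.empty(n, dtype="S1")
    run = 0
    non_a = np.frombuffer(b"CGT", dtype="S1")
    for i in range(n):
        if run >= 2:
            seq[i] = non_a[draws[i] % 3]
            run = 0
        else:
            seq[i] = _BASES[draws[i]]
            run = run + 1 if seq[i] == b"A" else 0
    return seq


def make_reference(config: SimConfig) -> tuple[dict[str, str], list[TranscriptModel]]:
    """Miniature genome plus one canonical transcript per gene.

    Gene 0 always has two exons (spliced arithmetic is exercised) and gene 1,
    when present, sits on the minus strand. Injected internal A-runs are
    written into the genome so the transcript sequence carries them at the
    requested spliced coordinates.
    """
    rng = config.rng(0)
    lo, hi = config.transcript_length_range
    chrom = "chr1"
    cursor = 100
    pieces: list[np.ndarray] = [_random_sequence(100, rng)]
    annotation: list[TranscriptModel] = []
    for g in range(config.n_genes):
        if config.exon_layout is not None and g < len(config.exon_layout):
            exon_lens = list(config.exon_layout[g])
        else:
            tx_len = int(rng.integers(lo, hi + 1))
            multi_exon = g == 0 or rng.random() < 0.5
            if multi_exon and tx_len >= 200:
                split = int(rng.integers(100, tx_len - 99))
                exon_lens = [split, tx_len - split]
            else:
                exon_lens = [tx_len]
        strand = "-" if g == 1 else ("+" if g == 0 else ("+", "-")[int(rng.integers(2))])
        exons = []
        for k, el in enumerate(exon_lens):
            exons.append((cursor, cursor + el))
            pieces.append(_random_sequence(el, rng))
            cursor += el
            if k < len(exon_lens) - 1:
                intron = int(rng.integers(100, 501))
                pieces.append(_random_sequence(intron, rng))
                cursor += intron
        gap = int(rng.integers(150, 400))
        pieces.append(_random_sequence(gap, rng))
        cursor += gap
        annotation.append(
            TranscriptModel(
                transcript_id=f"TX{g:03d}",
                gene_id=gene_name(g),
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
                canonical=True,
            )
        )
    genome_arr = np.concatenate(pieces)

    for spec in config.internal_polyA:
        tx = annotation[spec.gene]
        if spec.tx_coord + spec.run_length > tx.length:
            raise ValueError(f"A-run at {spec.tx_coord} exceeds transcript {tx.transcript_id}")
        for k in range(spec.run_length):
            gpos = tx.transcript_to_genomic(spec.tx_coord + k)  # 1-based
            genome_arr[gpos - 1] = b"A" if tx.strand == "+" else b"T"

    genome = {chrom: genome_arr.tobytes().decode()}
    return genome, annotation


def place_variants(
    config: SimConfig,
    genome: Mapping[str, str],
    annotation: Sequence[TranscriptModel],
) -> list[VariantSite]:
    """Materialize the configured variant placements as genomic SNVs whose
    ref allele matches the genome."""
    out = []
    for p in config.variants:
        tx = annotation[p.gene]
        tx_coord = p.tx_coord if p.tx_coord >= 0 else tx.length + p.tx_coord
        gpos = tx.transcript_to_genomic(tx_coord)
        ref = genome[tx.chrom][gpos - 1].upper()
        alt = "C" if ref != "C" else "G"
        out.append(
            VariantSite(
                chrom=tx.chrom, pos=gpos, ref=ref, alt=alt,
                gene_id=tx.gene_id, role=p.role,
            )
        )
    return out


def _assign_cell_types(config: SimConfig, rng: np.random.Generator) -> list[str]:
    """Deterministic largest-remainder allocation of cells to types, then a
    seeded shuffle."""
    n = config.n_cells
    raw = [ct.proportion * n for ct in config.cell_types]
    base = [int(x) for x in raw]
    remainder = n - sum(base)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:remainder]:
        base[i] += 1
    labels = list(
        itertools.chain.from_iterable([ct.name] * k for ct, k in zip(config.cell_types, base))
    )
    return [labels[i] for i in rng.permutation(n)]


def _barcodes(n: int, rng: np.random.Generator, length: int = 16) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def simulate_cells(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell-type negative-binomial counts and the cell truth table.

    Returns (counts, cell_table): counts is genes x cells; cell_table has
    one row per barcode with its type, germ layer and mutant flag (Bernoulli
    with the configured mosaic fraction, optionally restricted to a subset
    of cell types).
    """
    rng = config.rng(1)
    types = _assign_cell_types(config, rng)
    barcodes = _barcodes(config.n_cells, rng)
    layer = {ct.name: ct.germ_layer for ct in config.cell_types}
    eligible = (
        np.ones(config.n_cells, dtype=bool)
        if config.mutant_cell_types is None
        else np.array([t in config.mutant_cell_types for t in types])
    )
    is_mutant = (rng.random(config.n_cells) < config.mosaic_fraction) & eligible

    model = config.expression_model or ExpressionModel.random(
        config.n_genes, config.cell_types, rng,
        mean_range=config.nb_mean_range, dispersion=config.nb_dispersion,
        marker_genes=config.marker_genes,
    )
    type_idx = {ct.name: i for i, ct in enumerate(config.cell_types)}
    counts = np.zeros((config.n_genes, config.n_cells), dtype=np.int64)
    for g in range(config.n_genes):
        for c in range(config.n_cells):
            mu = model.mean(g, type_idx[types[c]])
            if mu <= 0:
                continue
            r = model.dispersion
            counts[g, c] = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(
        counts, index=[gene_name(g) for g in range(config.n_genes)], columns=barcodes
    )
    cell_table = pd.DataFrame(
        {
            "barcode": barcodes,
            "cell_type": types,
            "germ_layer": [layer[t] for t in types],
            "is_mutant": is_mutant,
        }
    )
    return counts_df, cell_table


def _apply_errors(seq: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    if error_rate <= 0:
        return seq
    hits = np.nonzero(rng.random(seq.size) < error_rate)[0]
    for i in hits:
        choices = [b for b in _BASES if b != seq[i]]
        seq[i] = choices[int(rng.integers(3))]
    return seq


def simulate_reads(
    counts: pd.DataFrame,
    cell_table: pd.DataFrame,
    genome: Mapping[str, str],
    annotation: Sequence[TranscriptModel],
    variants: Sequence[VariantSite],
    config: SimConfig,
    bam_path: str | Path,
) -> pd.DataFrame:
    """Emit one end-biased read per captured molecule (plus UMI duplicates)
    as a coordinate-sorted, indexed, CB/UB-tagged BAM. Returns the read
    truth table.

    Capture model: one capture event per molecule. With probability
    ``mispriming_rate`` (when the transcript has a usable internal A-site)
    the capture point is an internal site chosen uniformly; otherwise the
    annotated transcript end, displaced inward by a truncated exponential
    offset of scale ``capture_decay`` (0 = exactly the end). The read covers
    read_length nt upstream of the capture point for the 3' chemistry and
    downstream of it for the 5' chemistry, spliced back to genomic blocks.
    Molecules from mutant cells carry the alt base on the template before
    per-base error is applied.
    """
    rng = config.rng(2)
    rl = config.resolved_read_length
    canon = canonical_by_gene(annotation)
    chrom_names = sorted({tx.chrom for tx in annotation})
    chrom_len = {c: len(genome[c]) for c in chrom_names}

    # per-gene geometry, variant projections, and usable internal sites
    gene_ctx: dict[str, dict] = {}
    for gid, tx in canon.items():
        seq = tx.spliced_sequence(genome)
        sites = scan_polyA(
            seq, config.polyA_min_run, config.polyA_window, config.polyA_min_frac,
            transcript_id=tx.transcript_id,
        )
        if config.kit_end == THREE_PRIME:
            usable = [s.tx_coord for s in sites if s.tx_coord >= rl]
        else:
            usable = [s.tx_coord for s in sites if s.tx_coord + rl <= tx.length]
        gene_ctx[gid] = {"tx": tx, "sites": usable, "variants": []}
    for v in variants:
        ctx = gene_ctx.get(v.gene_id)
        tx_coord = ctx["tx"].genomic_to_transcript(v.pos) if ctx else None
        if tx_coord is None:
            raise ValueError(
                f"variant {v.id} is not covered by any simulated transcript exon"
            )
        ctx["variants"].append(v)

    is_mutant = dict(zip(cell_table["barcode"], cell_table["is_mutant"]))
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": chrom_len[c]} for c in chrom_names],
        }
    )
    tid = {c: i for i, c in enumerate(chrom_names)}

    records: list[tuple[int, int, pysam.AlignedSegment]] = []
    truth_rows: list[dict] = []
    serial = 0
    for gid in counts.index:
        ctx = gene_ctx[gid]
        tx: TranscriptModel = ctx["tx"]
        L = tx.length
        gene_variants: list[VariantSite] = ctx["variants"]
        gene_counts = counts.loc[gid]
        for barcode, n_mol in gene_counts.items():
            if n_mol == 0:
                continue
            mutant = bool(is_mutant[barcode])
            for _ in range(int(n_mol)):
                umi = "".join("ACGT"[b] for b in rng.integers(0, 4, size=config.umi_length))
                use_internal = bool(ctx["sites"]) and rng.random() < config.mispriming_rate
                if use_internal:
                    c = ctx["sites"][int(rng.integers(len(ctx["sites"])))]
                    origin = f"internal_polyA@{c}"
                    tx_span = (c - rl, c) if config.kit_end == THREE_PRIME else (c, c + rl)
                else:
                    origin = "transcript_end"
                    offset = 0
                    if config.capture_decay > 0:
                        offset = min(int(rng.exponential(config.capture_decay)), L - rl)
                    if config.kit_end == THREE_PRIME:
                        tx_span = (L - offset - rl, L - offset)
                    else:
                        tx_span = (offset, offset + rl)
                blocks = tx.transcript_blocks(*tx_span)
                chrom_seq = genome[tx.chrom]
                template = np.frombuffer(
                    "".join(chrom_seq[s:e] for s, e in blocks).upper().encode(), dtype="S1"
                ).copy()
                carries_alt = False
                if mutant:
                    off = 0
                    for s, e in blocks:
                        for v in gene_variants:
                            if s <= v.pos - 1 < e:
                                template[off + (v.pos - 1 - s)] = v.alt.encode()
                                carries_alt = True
                        off += e - s
                n_extra = int(rng.poisson(config.umi_duplicate_rate))
                base_serial = serial
                for _dup in range(1 + n_extra):
                    # sequencing error is per read; the alt template is shared
                    seq = _apply_errors(template.copy(), config.error_rate, rng)
                    a = pysam.AlignedSegment(header)
                    a.query_name = f"r{serial:08d}"
                    serial += 1
                    a.query_sequence = seq.tobytes().decode()
                    a.reference_id = tid[tx.chrom]
                    a.reference_start = blocks[0][0]
                    a.mapping_quality = 60
                    cigar = []
                    for k, (s, e) in enumerate(blocks):
                        if k:
                            cigar.append((3, s - blocks[k - 1][1]))  # N
                        cigar.append((0, e - s))  # M
                    a.cigartuples = cigar
                    a.query_qualities = pysam.qualitystring_to_array("I" * rl)
                    if config.kit_end == FIVE_PRIME:
                        a.is_reverse = tx.strand == "-"
                    else:
                        a.is_reverse = tx.strand == "+"
                    a.set_tag("CB", f"{barcode}-1")
                    a.set_tag("UB", umi)
                    a.set_tag("GX", gid)
                    records.append((a.reference_id, a.reference_start, a))
                truth_rows.append(
                    {
                        "read_id": f"r{base_serial:08d}",
                        "barcode": barcode,
                        "umi": umi,
                        "gene": gid,
                        "origin_site": origin,
                        "allele_carried": "alt" if carries_alt else "ref",
                        "n_duplicates": n_extra,
                    }
                )

    records.sort(key=lambda t: (t[0], t[1], t[2].query_name))
    bam_path = str(bam_path)
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
        for _, _, a in records:
            bam.write(a)
    pysam.index(bam_path)
    return pd.DataFrame(
        truth_rows,
        columns=[
            "read_id", "barcode", "umi", "gene", "origin_site", "allele_carried", "n_duplicates",
        ],
    )


def build_truth(
    cell_table: pd.DataFrame,
    read_table: pd.DataFrame,
    variants: Sequence[VariantSite],
) -> SimTruth:
    n = len(cell_table)
    variant_table = pd.DataFrame(
        {
            "variant": [v.id for v in variants],
            "gene": [v.gene_id for v in variants],
            "true_vaf": [
                float(cell_table["is_mutant"].sum()) / n if n else float("nan")
                for _ in variants
            ],
            "n_mutant_cells": [int(cell_table["is_mutant"].sum()) for _ in variants],
        }
    )
    return SimTruth(cell_table.copy(), read_table.copy(), variant_table)


def write_truth(truth: SimTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.cell_table.to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
    truth.read_table.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    truth.variant_table.to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)


def read_truth(outdir: str | Path) -> SimTruth:
    outdir = Path(outdir)
    return SimTruth(
        pd.read_csv(outdir / "truth_cells.tsv", sep="\t"),
        pd.read_csv(outdir / "truth_reads.tsv", sep="\t"),
        pd.read_csv(outdir / "truth_variants.tsv", sep="\t"),
    )


def simulate_dataset(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full generator and write every artifact a real experiment
    would provide: FASTA + GTF, VCF of injected variants, tagged BAM, MTX
    count trio, cell-metadata TSV and truth tables."""
    from . import io as dgio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, annotation = make_reference(config)
    variants = place_variants(config, genome, annotation)
    counts, cell_table = simulate_cells(config)
    bam = outdir / "alignments.bam"
    read_table = simulate_reads(counts, cell_table, genome, annotation, variants, config, bam)
    truth = build_truth(cell_table, read_table, variants)

    dgio.write_fasta(genome, outdir / "genome.fa")
    dgio.write_gtf(annotation, outdir / "annotation.gtf")
    dgio.write_vcf(variants, outdir / "variants.vcf", {c: len(s) for c, s in genome.items()})
    dgio.write_counts_mtx(counts, outdir / "counts")
    cell_table.rename(columns={"cell_type": "cluster"}).drop(columns=["is_mutant"]).to_csv(
        outdir / "cell_metadata.tsv", sep="\t", index=False
    )
    write_truth(truth, outdir)
    return {
        "bam": bam,
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "vcf": outdir / "variants.vcf",
        "counts": outdir / "counts",
        "cell_metadata": outdir / "cell_metadata.tsv",
        "truth": outdir,
    }
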