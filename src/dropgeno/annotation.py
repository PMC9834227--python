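"""Transcript models and spliced-coordinate arithmetic.

Variant positions in genomic (VCF, 1-based) coordinates are projected into
the spliced coordinate frame of one canonical transcript per gene, where
"distance to the 5'/3' end" is meaningful for end-biased capture chemistry.
All internal coordinates are 0-based half-open; GTF input (1-based
inclusive) is converted on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import gffutils

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """Stranded exon structure of one transcript.

    exons are genomic intervals, 0-based half-open, sorted by start,
    non-overlapping, all on ``chrom``. Transcript (spliced) coordinates run
    5' -> 3' along the mRNA: position 0 is the cap site, so on the minus
    strand it maps to the *last* genomic base of the last exon.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    canonical: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        starts = [e[0] for e in self.exons]
        if starts != sorted(starts):
            object.__setattr__(self, "exons", tuple(sorted(self.exons)))
        prev_end = -1
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon [{s},{e}) in {self.transcript_id}")
            if s < prev_end:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
            prev_end = e
        if self.length <= 0:
            raise ValueError(f"transcript {self.transcript_id} has zero length")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def genomic_to_transcript(self, pos: int) -> Optional[int]:
        """Project a 1-based genomic position to a 0-based spliced coordinate.

        Returns None for intronic positions and for positions outside the
        transcript span (the latter additionally logged as "outside").
        """
        pos0 = pos - 1
        lo, hi = self.span
        if pos0 < lo or pos0 >= hi:
            log.debug("position %s:%d outside transcript %s", self.chrom, pos, self.transcript_id)
            return None
        offset = 0
        plus_coord = None
        for s, e in self.exons:
            if s <= pos0 < e:
                plus_coord = offset + (pos0 - s)
                break
            offset += e - s
        if plus_coord is None:
            return None  # intronic
        if self.strand == "+":
            return plus_coord
        return self.length - 1 - plus_coord

    def transcript_to_genomic(self, tx_coord: int) -> int:
        """Inverse projection: spliced coordinate -> 1-based genomic position."""
        if not 0 <= tx_coord < self.length:
            raise ValueError(f"tx_coord {tx_coord} outside [0,{self.length})")
        plus_coord = tx_coord if self.strand == "+" else self.length - 1 - tx_coord
        offset = 0
        for s, e in self.exons:
            exon_len = e - s
            if plus_coord < offset + exon_len:
                return s + (plus_coord - offset) + 1
            offset += exon_len
        raise AssertionError("unreachable: exon walk exhausted")

    def transcript_blocks(self, tx_start: int, tx_end: int) -> list[tuple[int, int]]:
        """Genomic alignment blocks (0-based half-open, ascending) covering
        the spliced interval [tx_start, tx_end)."""
        if not 0 <= tx_start < tx_end <= self.length:
            raise ValueError(f"bad tx interval [{tx_start},{tx_end}) for length {self.length}")
        if self.strand == "+":
            plus_lo, plus_hi = tx_start, tx_end
        else:
            plus_lo, plus_hi = self.length - tx_end, self.length - tx_start
        blocks = []
        offset = 0
        for s, e in self.exons:
            exon_len = e - s
            a = max(plus_lo, offset)
            b = min(plus_hi, offset + exon_len)
            if a < b:
                blocks.append((s + a - offset, s + b - offset))
            offset += exon_len
        return blocks

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        """Sense-strand mRNA sequence from a chrom -> sequence mapping
        (a dict or a pyfaidx.Fasta both work)."""
        chrom_seq = str(genome[self.chrom])
        seq = "".join(chrom_seq[s:e] for s, e in self.exons)
        return reverse_complement(seq) if self.strand == "-" else seq.upper()


@dataclass(frozen=True)
class VariantDistance:
    """Spliced location of a variant on its canonical transcript."""

    variant: "object"  # VariantSite; kept loose to avoid a circular import
    transcript_id: str
    tx_coord: Optional[int]  # None when intronic
    dist_5p: Optional[int]
    dist_3p: Optional[int]

    @property
    def intronic(self) -> bool:
        return self.tx_coord is None


def distance_to_ends(tx_coord: int, tx: TranscriptModel) -> tuple[int, int]:
    """(dist_5p, dist_3p) of a spliced coordinate; a variant at the cap
    site has dist_5p = 0 and the two distances sum to length - 1."""
    if not 0 <= tx_coord < tx.length:
        raise ValueError(f"tx_coord {tx_coord} outside transcript of length {tx.length}")
    return tx_coord, tx.length - 1 - tx_coord


def load_annotation(
    gtf_path: str,
    mane_ids: Optional[Iterable[str]] = None,
) -> list[TranscriptModel]:
    """Load exon structures from a GTF and flag one canonical transcript
    per gene.

    The canonical transcript is the MANE-listed one when ``mane_ids`` is
    given and matches; otherwise the longest (spliced length), ties broken
    by lexicographically smallest transcript_id. Genes with no exon
    records are skipped with a warning.
    """
    mane = set(mane_ids) if mane_ids else set()
    db = gffutils.create_db(
        gtf_path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        tx_id = exon.attributes["transcript_id"][0]
        gene_id = exon.attributes.get("gene_id", [tx_id])[0]
        rec = by_tx.setdefault(
            tx_id, {"gene_id": gene_id, "chrom": exon.seqid, "strand": exon.strand, "exons": []}
        )
        # GTF is 1-based inclusive; convert to 0-based half-open
        rec["exons"].append((exon.start - 1, exon.end))

    transcripts: dict[str, list[TranscriptModel]] = {}
    for tx_id, rec in by_tx.items():
        tx = TranscriptModel(
            transcript_id=tx_id,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(sorted(rec["exons"])),
        )
        transcripts.setdefault(tx.gene_id, []).append(tx)

    out: list[TranscriptModel] = []
    for gene_id, txs in sorted(transcripts.items()):
        chosen = None
        if mane:
            hits = [t for t in txs if t.transcript_id in mane]
            if hits:
                chosen = hits[0]
        if chosen is None:
            if mane:
                log.warning("no MANE transcript for %s; falling back to longest", gene_id)
            chosen = min(txs, key=lambda t: (-t.length, t.transcript_id))
        for t in sorted(txs, key=lambda t: t.transcript_id):
            out.append(
                t if t.transcript_id != chosen.transcript_id
                else TranscriptModel(
                    t.transcript_id, t.gene_id, t.chrom, t.strand, t.exons, canonical=True
                )
            )
    return out


def canonical_by_gene(annotation: Iterable[TranscriptModel]) -> dict[str, TranscriptModel]:
    return {t.gene_id: t for t in annotation if t.canonical}


def filter_intronic(
    variants: Sequence["object"],
    annotation: Iterable[TranscriptModel],
) -> tuple[list[VariantDistance], list[tuple["object", str]]]:
    """Partition variants into exonic ones (with spliced distances on the
    canonical transcript of their gene) and dropped ones with a reason."""
    canon = canonical_by_gene(annotation)
    kept: list[VariantDistance] = []
    dropped: list[tuple[object, str]] = []
    for v in variants:
        tx = canon.get(v.gene_id)
        if tx is None:
            dropped.append((v, "no transcript"))
            continue
        tx_coord = tx.genomic_to_transcript(v.pos)
        if tx_coord is None:
            dropped.append((v, "intronic"))
            continue
        d5, d3 = distance_to_ends(tx_coord, tx)
        kept.append(VariantDistance(v, tx.transcript_id, tx_coord, d5, d3))
    return kept, dropped


def kit_distance(vd: VariantDistance, kit_end: str) -> int:
    """The end distance relevant to a chemistry: dist_5p for the 5' kit,
    dist_3p for the 3' kit."""
    if vd.intronic:
        raise ValueError("intronic variant has no end distance")
    if kit_end in ("five_prime", "5p"):
        return vd.dist_5p
    if kit_end in ("three_prime", "3p"):
        return vd.dist_3p
    raise ValueError(f"unknown kit_end {kit_end!r}")
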