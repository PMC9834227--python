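"""Per-cell allele counting at a priori known variant positions.

Given barcode/UMI-tagged alignments (Cell Ranger-style BAM with CB/UB tags)
and a list of single-nucleotide variants, count reference- and alternate-
supporting UMIs per (cell, variant) and derive a three-way call —
the same interface a VarTrix run provides downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import sparse

log = logging.getLogger(__name__)

# three-way call codes
NO_CALL = 0
REF = 1
ALT = 2
CALL_LABELS = {NO_CALL: "no_call", REF: "ref", ALT: "alt"}

_BASES = frozenset("ACGT")
_SUFFIX_RE = re.compile(r"-\d+$")


def normalize_barcode(barcode: str) -> str:
    """Strip a trailing Cell Ranger GEM-well suffix such as '-1'."""
    return _SUFFIX_RE.sub("", barcode)


@dataclass(frozen=True)
class VariantSite:
    """One a priori variant position (single-nucleotide substitution)."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    gene_id: str = ""
    patient_id: str = ""
    role: str = "germline"  # somatic_candidate | germline | null_set
    in_population_db: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref.upper() not in _BASES or self.alt.upper() not in _BASES:
            raise ValueError(f"only SNVs supported, got {self.ref}>{self.alt}")
        if self.ref.upper() == self.alt.upper():
            raise ValueError("ref and alt alleles must differ")
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class CountingParams:
    min_mapping_quality: int = 30
    min_base_quality: int = 20
    valid_barcodes: Optional[frozenset[str]] = None
    umi_consensus: str = "majority"  # majority (ties discarded) | any
    call_policy: str = "alt_dominant"  # alt_dominant | consensus
    primary_alignments_only: bool = True

    def __post_init__(self) -> None:
        if self.min_mapping_quality < 0 or self.min_base_quality < 0:
            raise ValueError("quality thresholds must be >= 0")
        if self.umi_consensus not in ("majority", "any"):
            raise ValueError(f"unknown umi_consensus {self.umi_consensus!r}")
        if self.call_policy not in ("alt_dominant", "consensus"):
            raise ValueError(f"unknown call_policy {self.call_policy!r}")
        if self.valid_barcodes is not None:
            self.valid_barcodes = frozenset(normalize_barcode(b) for b in self.valid_barcodes)


@dataclass
class GenotypeMatrices:
    """Sparse cells x variants ref/alt UMI counts plus three-way calls."""

    barcodes: list[str]
    variants: list[VariantSite]
    ref_umis: sparse.csr_matrix
    alt_umis: sparse.csr_matrix
    calls: np.ndarray  # int8, codes NO_CALL/REF/ALT
    both_mask: np.ndarray  # cells with ref and alt evidence at a site

    def __post_init__(self) -> None:
        shape = (len(self.barcodes), len(self.variants))
        for m in (self.ref_umis, self.alt_umis):
            if m.shape != shape:
                raise ValueError(f"matrix shape {m.shape} != {shape}")
        assert not np.logical_and(
            self.calls != NO_CALL,
            (self.ref_umis + self.alt_umis).toarray() == 0,
        ).any(), "call without coverage"

    @property
    def coverage(self) -> sparse.csr_matrix:
        """UMI-level coverage: ref + alt UMIs per (cell, variant)."""
        return self.ref_umis + self.alt_umis

    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]


def call_genotypes(
    ref_umis: sparse.spmatrix, alt_umis: sparse.spmatrix, policy: str = "alt_dominant"
) -> tuple[np.ndarray, np.ndarray]:
    """Three-way call per (cell, variant).

    alt_dominant: ALT if any alt UMI, else REF if any ref UMI, else NO_CALL.
    consensus: same calls, but cells with both alleles observed are flagged
    in the returned both-mask (they are still reported ALT — a true mosaic
    carrier transcribes both alleles and the three-way scheme has no "both"
    category). The mask is returned under either policy for audit.
    """
    if policy not in ("alt_dominant", "consensus"):
        raise ValueError(f"unknown call policy {policy!r}")
    r = np.asarray(ref_umis.todense()) if sparse.issparse(ref_umis) else np.asarray(ref_umis)
    a = np.asarray(alt_umis.todense()) if sparse.issparse(alt_umis) else np.asarray(alt_umis)
    calls = np.full(r.shape, NO_CALL, dtype=np.int8)
    calls[r >= 1] = REF
    calls[a >= 1] = ALT
    both = (r >= 1) & (a >= 1)
    return calls, both


def _read_passes(read: pysam.AlignedSegment, params: CountingParams) -> bool:
    if read.is_unmapped:
        return False
    if params.primary_alignments_only and (read.is_secondary or read.is_supplementary):
        return False
    if read.mapping_quality < params.min_mapping_quality:
        return False
    return read.has_tag("CB") and read.has_tag("UB")


def _base_at(read: pysam.AlignedSegment, pos0: int) -> Optional[tuple[str, int]]:
    """Query base and quality aligned to reference position pos0, or None if
    a deletion/refskip spans it."""
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos == pos0:
            qual = read.query_qualities[qpos] if read.query_qualities is not None else 255
            return read.query_sequence[qpos].upper(), qual
    return None


def _umi_vote(votes: list[str], consensus: str) -> Optional[str]:
    n_alt = votes.count("alt")
    n_ref = votes.count("ref")
    if consensus == "any":
        return "alt" if n_alt else ("ref" if n_ref else None)
    if n_alt > n_ref:
        return "alt"
    if n_ref > n_alt:
        return "ref"
    return None  # tie discarded


def count_alleles(
    bam_path: str,
    variants: Sequence[VariantSite],
    params: Optional[CountingParams] = None,
) -> GenotypeMatrices:
    """Count ref/alt UMIs per cell at each variant position.

    Every passing read overlapping the position is binned by (CB, UB); each
    UMI contributes at most one allele vote after consensus. Reads lacking
    tags, failing quality thresholds, or whose base is neither allele are
    discarded, as are alignments whose deletion or splice gap spans the
    position.
    """
    params = params or CountingParams()
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt))

    with pysam.AlignmentFile(bam_path, "rb") as bam:
        if not bam.has_index():
            raise FileNotFoundError(f"BAM index missing for {bam_path}; run samtools index")
        header_refs = set(bam.references)
        per_variant: list[dict[str, tuple[int, int]]] = []
        observed: set[str] = set()
        for v in variants:
            if v.chrom not in header_refs:
                log.warning("variant %s: chrom absent from BAM header; all NO_CALL", v.id)
                per_variant.append({})
                continue
            pileups: dict[tuple[str, str], list[str]] = {}
            for read in bam.fetch(v.chrom, v.pos - 1, v.pos):
                if not _read_passes(read, params):
                    continue
                cb = normalize_barcode(read.get_tag("CB"))
                if params.valid_barcodes is not None and cb not in params.valid_barcodes:
                    continue
                hit = _base_at(read, v.pos - 1)
                if hit is None:
                    continue
                base, qual = hit
                if qual < params.min_base_quality:
                    continue
                if base == v.ref:
                    pileups.setdefault((cb, read.get_tag("UB")), []).append("ref")
                elif base == v.alt:
                    pileups.setdefault((cb, read.get_tag("UB")), []).append("alt")
            counts: dict[str, tuple[int, int]] = {}
            for (cb, _ub), votes in pileups.items():
                allele = _umi_vote(votes, params.umi_consensus)
                if allele is None:
                    continue
                r, a = counts.get(cb, (0, 0))
                counts[cb] = (r + 1, a) if allele == "ref" else (r, a + 1)
            observed.update(counts)
            per_variant.append(counts)

    if params.valid_barcodes is not None:
        barcodes = sorted(params.valid_barcodes)
    else:
        barcodes = sorted(observed)
    index = {b: i for i, b in enumerate(barcodes)}

    shape = (len(barcodes), len(variants))
    ref_m = sparse.lil_matrix(shape, dtype=np.int32)
    alt_m = sparse.lil_matrix(shape, dtype=np.int32)
    for j, counts in enumerate(per_variant):
        for cb, (r, a) in counts.items():
            i = index[cb]
            if r:
                ref_m[i, j] = r
            if a:
                alt_m[i, j] = a
    ref_csr, alt_csr = ref_m.tocsr(), alt_m.tocsr()
    calls, both = call_genotypes(ref_csr, alt_csr, params.call_policy)
    return GenotypeMatrices(barcodes, list(variants), ref_csr, alt_csr, calls, both)


def annotate_calls(
    matrices: GenotypeMatrices,
    cell_metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Long-form (barcode, variant, call) table joined to cell metadata.

    ``cell_metadata`` is indexed by barcode (or has a 'barcode' column);
    barcode suffixes like '-1' are normalized on both sides before joining.
    The join is inner; unmatched barcodes on either side are logged.
    Raises when no barcode overlaps, which usually indicates a whitelist or
    suffix mismatch.
    """
    meta = cell_metadata.copy()
    if "barcode" in meta.columns:
        meta = meta.set_index("barcode")
    meta.index = [normalize_barcode(str(b)) for b in meta.index]

    matrix_bcs = [normalize_barcode(b) for b in matrices.barcodes]
    shared = set(matrix_bcs) & set(meta.index)
    if not shared:
        raise ValueError(
            "no barcodes shared between genotype matrix and metadata; "
            "check for a barcode suffix mismatch (e.g. trailing '-1')"
        )
    n_only_matrix = len(set(matrix_bcs) - shared)
    n_only_meta = len(set(meta.index) - shared)
    if n_only_matrix or n_only_meta:
        log.info(
            "annotate_calls: %d matrix-only and %d metadata-only barcodes dropped",
            n_only_matrix, n_only_meta,
        )

    rows = []
    ref_arr = np.asarray(matrices.ref_umis.todense())
    alt_arr = np.asarray(matrices.alt_umis.todense())
    for i, bc in enumerate(matrix_bcs):
        if bc not in shared:
            continue
        for j, v in enumerate(matrices.variants):
            rows.append(
                {
                    "barcode": bc,
                    "variant": v.id,
                    "call": CALL_LABELS[int(matrices.calls[i, j])],
                    "ref_umis": int(ref_arr[i, j]),
                    "alt_umis": int(alt_arr[i, j]),
                }
            )
    long = pd.DataFrame(rows)
    return long.join(meta, on="barcode", how="inner")
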