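"""Independent brute-force pileup used as an oracle for the genotyper.

Deliberately shares no code path with dropgeno.genotype.count_alleles:
it scans every read linearly (no index, no fetch-by-region) and re-derives
query/reference alignment by walking the CIGAR by hand.
"""

from __future__ import annotations

import re

import pysam

_SUFFIX = re.compile(r"-\d+$")


def _cigar_walk(read):
    """Yield (query_index, reference_position) for aligned bases only."""
    q = 0
    r = read.reference_start
    for op, ln in read.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            for k in range(ln):
                yield q + k, r + k
            q += ln
            r += ln
        elif op in (1, 4):  # I, S consume query
            q += ln
        elif op in (2, 3):  # D, N consume reference
            r += ln
        # H, P consume neither


def brute_force_counts(bam_path, variants, params):
    """(cell, variant) -> (ref_umis, alt_umis) dict computed by exhaustive scan."""
    votes: dict[tuple[int, str, str], list[str]] = {}
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            if params.primary_alignments_only and (read.is_secondary or read.is_supplementary):
                continue
            if read.mapping_quality < params.min_mapping_quality:
                continue
            if not (read.has_tag("CB") and read.has_tag("UB")):
                continue
            cb = _SUFFIX.sub("", read.get_tag("CB"))
            if params.valid_barcodes is not None and cb not in params.valid_barcodes:
                continue
            ub = read.get_tag("UB")
            chrom = read.reference_name
            aligned = dict((r, q) for q, r in _cigar_walk(read))
            for j, v in enumerate(variants):
                if v.chrom != chrom:
                    continue
                qpos = aligned.get(v.pos - 1)
                if qpos is None:
                    continue
                quals = read.query_qualities
                qual = quals[qpos] if quals is not None else 255
                if qual < params.min_base_quality:
                    continue
                base = read.query_sequence[qpos].upper()
                if base == v.ref:
                    votes.setdefault((j, cb, ub), []).append("ref")
                elif base == v.alt:
                    votes.setdefault((j, cb, ub), []).append("alt")

    counts: dict[tuple[str, int], tuple[int, int]] = {}
    for (j, cb, _ub), vs in votes.items():
        n_ref, n_alt = vs.count("ref"), vs.count("alt")
        if params.umi_consensus == "any":
            allele = "alt" if n_alt else "ref"
        elif n_alt > n_ref:
            allele = "alt"
        elif n_ref > n_alt:
            allele = "ref"
        else:
            continue
        r, a = counts.get((cb, j), (0, 0))
        counts[(cb, j)] = (r + 1, a) if allele == "ref" else (r, a + 1)
    return counts
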