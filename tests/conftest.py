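from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
import pytest

from dropgeno.genotype import VariantSite


@pytest.fixture()
def variant():
    return VariantSite(chrom="chr1", pos=500, ref="A", alt="C", gene_id="GENE000")


def make_bam(path, reads, chrom_lengths=None):
    """Write a coordinate-sorted, indexed BAM from simple read dicts.

    Each read dict: name, chrom, start (0-based), seq, and optionally
    cigar (defaults to all-match), mapq (60), baseq (40), cb, ub, flags.
    """
    chrom_lengths = chrom_lengths or {"chr1": 100_000}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": ln} for c, ln in chrom_lengths.items()],
        }
    )
    tid = {c: i for i, c in enumerate(chrom_lengths)}
    segs = []
    for rd in reads:
        a = pysam.AlignedSegment(header)
        a.query_name = rd["name"]
        a.reference_id = tid[rd.get("chrom", "chr1")]
        a.reference_start = rd["start"]
        a.query_sequence = rd["seq"]
        a.cigartuples = rd.get("cigar", [(0, len(rd["seq"]))])
        a.mapping_quality = rd.get("mapq", 60)
        a.query_qualities = pysam.qualitystring_to_array(
            chr(rd.get("baseq", 40) + 33) * len(rd["seq"])
        )
        a.flag = rd.get("flags", 0)
        if rd.get("cb"):
            a.set_tag("CB", rd["cb"])
        if rd.get("ub"):
            a.set_tag("UB", rd["ub"])
        segs.append(a)
    segs.sort(key=lambda a: (a.reference_id, a.reference_start, a.query_name))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for a in segs:
            bam.write(a)
    pysam.index(str(path))
    return path


@pytest.fixture()
def bam_factory(tmp_path):
    def factory(reads, name="fixture.bam", chrom_lengths=None):
        return make_bam(tmp_path / name, reads, chrom_lengths)

    return factory


def random_fixture_reads(rng, variant, n_reads, barcodes):
    """Randomized reads around a variant position: mixed alleles, qualities,
    flags, missing tags, and deletions/splices spanning the site."""
    reads = []
    pos0 = variant.pos - 1
    other = next(b for b in "ACGT" if b not in (variant.ref, variant.alt))
    for i in range(n_reads):
        start = int(rng.integers(max(0, pos0 - 60), pos0 + 20))
        length = int(rng.integers(30, 80))
        base_choice = rng.choice(["ref", "alt", "other"], p=[0.5, 0.35, 0.15])
        shape = rng.choice(["match", "del", "splice", "away"], p=[0.7, 0.1, 0.1, 0.1])
        seq = "".join(rng.choice(list("ACGT"), size=length))
        cigar = [(0, length)]
        if shape == "match" and start <= pos0 < start + length:
            base = {"ref": variant.ref, "alt": variant.alt, "other": other}[base_choice]
            seq = seq[: pos0 - start] + base + seq[pos0 - start + 1:]
        elif shape in ("del", "splice"):
            # first segment matches, a gap spans the variant, rest matches
            left = min(max(1, pos0 - start), length - 1)
            right = length - left
            gap = int(rng.integers(5, 30))
            cigar = [(0, left), (2 if shape == "del" else 3, gap), (0, right)]
        reads.append(
            {
                "name": f"q{i:05d}",
                "start": start,
                "seq": seq,
                "cigar": cigar,
                "mapq": int(rng.choice([0, 10, 30, 60], p=[0.05, 0.1, 0.15, 0.7])),
                "baseq": int(rng.choice([5, 20, 40], p=[0.1, 0.2, 0.7])),
                "cb": None if rng.random() < 0.05 else str(rng.choice(barcodes)) + "-1",
                "ub": None if rng.random() < 0.05 else "".join(rng.choice(list("ACGT"), size=6)),
                "flags": int(rng.choice([0, 256, 2048], p=[0.9, 0.05, 0.05])),
            }
        )
    return reads
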