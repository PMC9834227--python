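"""Synthetic data generator: reference construction, cell sampling, read
geometry, genotype truth, determinism."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
import pytest

from dropgeno.simulate import (
    PolyASpec,
    SimConfig,
    SimTruth,
    VariantPlacement,
    build_truth,
    make_reference,
    place_variants,
    read_truth,
    simulate_cells,
    simulate_reads,
    write_truth,
)


def small_config(**kw):
    defaults = dict(n_cells=60, n_genes=3, seed=3, mispriming_rate=0.0,
                    error_rate=0.0, umi_duplicate_rate=0.0)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestMakeReference:
    def test_minimal_single_exon_gene(self):
        cfg = SimConfig(n_genes=1, n_cells=1, exon_layout=((1000,),), variants=())
        genome, ann = make_reference(cfg)
        assert len(genome["chr1"]) >= 1000
        (tx,) = ann
        assert len(tx.exons) == 1 and tx.length == 1000

    def test_two_exon_length_is_sum(self):
        cfg = SimConfig(n_genes=1, n_cells=1, exon_layout=((200, 300),), variants=())
        _, ann = make_reference(cfg)
        assert ann[0].length == 500
        assert len(ann[0].exons) == 2

    def test_injected_polyA_run_lands_at_spliced_coordinate(self):
        cfg = SimConfig(
            n_genes=2, n_cells=1, exon_layout=((600, 600), (1200,)),
            internal_polyA=(PolyASpec(0, 500, 10), PolyASpec(1, 300, 8)),
            variants=(),
        )
        genome, ann = make_reference(cfg)
        seq0 = ann[0].spliced_sequence(genome)
        assert seq0[500:510] == "A" * 10
        seq1 = ann[1].spliced_sequence(genome)
        assert seq1[300:308] == "A" * 8

    def test_background_sequence_has_no_spurious_sites(self):
        from dropgeno.mispriming import scan_polyA

        genome, ann = make_reference(small_config(n_genes=5))
        for tx in ann:
            assert scan_polyA(tx.spliced_sequence(genome)) == []

    def test_exons_lie_within_chromosome(self):
        genome, ann = make_reference(small_config(n_genes=6))
        n = len(genome["chr1"])
        assert all(0 <= s < e <= n for tx in ann for s, e in tx.exons)
        assert any(len(tx.exons) > 1 for tx in ann)
        assert {tx.strand for tx in ann} == {"+", "-"}

    def test_variant_placement_matches_genome(self):
        cfg = small_config(variants=(VariantPlacement(0, 100), VariantPlacement(1, 7, "null_set")))
        genome, ann = make_reference(cfg)
        for v, p in zip(place_variants(cfg, genome, ann), cfg.variants):
            assert genome[v.chrom][v.pos - 1].upper() == v.ref
            assert ann[p.gene].genomic_to_transcript(v.pos) == p.tx_coord


class TestSimulateCells:
    @pytest.mark.parametrize("fraction, expected", [(0.0, 0), (1.0, 1000)])
    def test_mosaic_extremes(self, fraction, expected):
        _, cells = simulate_cells(small_config(n_cells=1000, mosaic_fraction=fraction))
        assert cells["is_mutant"].sum() == expected

    def test_mosaic_fraction_within_binomial_bounds(self):
        n = 10_000
        _, cells = simulate_cells(small_config(n_cells=n, mosaic_fraction=0.05))
        sd = np.sqrt(0.05 * 0.95 / n)
        assert abs(cells["is_mutant"].mean() - 0.05) < 3 * sd

    def test_mutant_flag_restricted_to_cell_types(self):
        _, cells = simulate_cells(
            small_config(n_cells=2000, mosaic_fraction=0.5, mutant_cell_types=("Microglia",))
        )
        assert cells.loc[cells["is_mutant"], "cell_type"].eq("Microglia").all()
        assert cells["is_mutant"].sum() > 0

    def test_cell_type_proportions(self):
        _, cells = simulate_cells(small_config(n_cells=1000))
        counts = cells["cell_type"].value_counts()
        assert counts["ExcitatoryNeurons"] == 300  # largest-remainder allocation

    def test_reproducible_with_fixed_seed(self):
        c1, t1 = simulate_cells(small_config())
        c2, t2 = simulate_cells(small_config())
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1, t2)


def _simulate(tmp_path, cfg, name="sim.bam"):
    genome, ann = make_reference(cfg)
    variants = place_variants(cfg, genome, ann)
    counts, cells = simulate_cells(cfg)
    reads = simulate_reads(counts, cells, genome, ann, variants, cfg, tmp_path / name)
    return genome, ann, variants, counts, cells, reads


class TestSimulateReads:
    def test_variant_far_from_end_never_covered(self, tmp_path):
        # 3' kit, variant 2000 nt from the captured (3') end of a 3000 nt transcript
        cfg = small_config(
            exon_layout=((3000,),), n_genes=1,
            variants=(VariantPlacement(0, 3000 - 1 - 2000),),
        )
        genome, ann, variants, *_ = _simulate(tmp_path, cfg)
        v = variants[0]
        with pysam.AlignmentFile(str(tmp_path / "sim.bam")) as bam:
            assert sum(1 for _ in bam.fetch(v.chrom, v.pos - 1, v.pos)) == 0

    def test_variant_near_end_covered_by_every_molecule(self, tmp_path):
        cfg = small_config(
            exon_layout=((3000,),), n_genes=1,
            variants=(VariantPlacement(0, 3000 - 1 - 50),),  # 50 nt from the 3' end
        )
        genome, ann, variants, counts, cells, reads = _simulate(tmp_path, cfg)
        v = variants[0]
        n_molecules = int(counts.sum().sum())
        with pysam.AlignmentFile(str(tmp_path / "sim.bam")) as bam:
            n_over = sum(1 for _ in bam.fetch(v.chrom, v.pos - 1, v.pos))
        assert n_over == n_molecules > 0

    def test_read_lengths_exact_and_blocks_respect_exons(self, tmp_path):
        cfg = small_config(n_genes=3, variants=())
        genome, ann, *_ = _simulate(tmp_path, cfg)
        exonic = {
            tx.chrom: set()
            for tx in ann
        }
        for tx in ann:
            for s, e in tx.exons:
                exonic[tx.chrom].update(range(s, e))
        rl = cfg.resolved_read_length
        n = 0
        with pysam.AlignmentFile(str(tmp_path / "sim.bam")) as bam:
            for read in bam.fetch(until_eof=True):
                n += 1
                assert read.query_length == rl
                for pos in read.get_reference_positions():
                    assert pos in exonic[read.reference_name]
        assert n > 0

    def test_no_alt_base_from_non_mutant_cells_without_error(self, tmp_path):
        cfg = small_config(
            n_cells=150, mosaic_fraction=0.3, exon_layout=((1500,),), n_genes=1,
            variants=(VariantPlacement(0, 1500 - 1 - 30),),
        )
        genome, ann, variants, counts, cells, reads = _simulate(tmp_path, cfg)
        v = variants[0]
        mutants = set(cells.loc[cells["is_mutant"], "barcode"])
        with pysam.AlignmentFile(str(tmp_path / "sim.bam")) as bam:
            seen_alt = seen_mutant_alt = 0
            for read in bam.fetch(v.chrom, v.pos - 1, v.pos):
                pairs = dict((r, q) for q, r in read.get_aligned_pairs(matches_only=True))
                q = pairs.get(v.pos - 1)
                if q is None:
                    continue
                base = read.query_sequence[q]
                bc = read.get_tag("CB").removesuffix("-1")
                if base == v.alt:
                    seen_alt += 1
                    assert bc in mutants
                if bc in mutants:
                    assert base == v.alt
                    seen_mutant_alt += 1
        assert seen_alt == seen_mutant_alt > 0

    def test_internal_polyA_site_rescues_mid_transcript_variant(self, tmp_path):
        # variant 40 nt upstream of a 10-A site, both far from either end
        cfg = small_config(
            n_cells=200, exon_layout=((2500,),), n_genes=1,
            internal_polyA=(PolyASpec(0, 1000, 10),),
            variants=(VariantPlacement(0, 960),),
            mispriming_rate=0.5,
        )
        genome, ann, variants, counts, cells, reads = _simulate(tmp_path, cfg)
        v = variants[0]
        internal = reads["origin_site"].str.startswith("internal_polyA").sum()
        assert internal > 0
        with pysam.AlignmentFile(str(tmp_path / "sim.bam")) as bam:
            assert sum(1 for _ in bam.fetch(v.chrom, v.pos - 1, v.pos)) > 0

    def test_read_starts_decay_from_captured_end(self, tmp_path):
        cfg = small_config(
            n_cells=400, exon_layout=((2000,),), n_genes=1, variants=(),
            capture_decay=30.0,
        )
        genome, ann, *_ = _simulate(tmp_path, cfg)
        L = ann[0].length
        ends = []
        with pysam.AlignmentFile(str(tmp_path / "sim.bam")) as bam:
            for read in bam.fetch(until_eof=True):
                # 3' kit, + strand single exon: capture offset from the 3' end
                ends.append(L - read.reference_end + ann[0].exons[0][0])
        ends = np.array(ends)
        near = (ends < 30).sum()
        far = ((ends >= 30) & (ends < 60)).sum()
        assert near > far > 0  # exponential-ish decay of capture offsets

    def test_variant_outside_any_transcript_rejected(self, tmp_path):
        from dropgeno.genotype import VariantSite

        cfg = small_config(n_genes=1, exon_layout=((1200,),), variants=())
        genome, ann = make_reference(cfg)
        counts, cells = simulate_cells(cfg)
        bogus = VariantSite("chr1", 5, "A", "C", gene_id="GENE000")
        bogus = VariantSite("chr1", 5, genome["chr1"][4].upper(),
                            "C" if genome["chr1"][4].upper() != "C" else "G",
                            gene_id="GENE000")
        with pytest.raises(ValueError, match="not covered"):
            simulate_reads(counts, cells, genome, ann, [bogus], cfg, tmp_path / "x.bam")

    def test_byte_identical_reruns(self, tmp_path):
        from dropgeno.pipeline import file_checksum

        cfg = small_config(variants=(VariantPlacement(0, 100),), error_rate=0.01,
                           mispriming_rate=0.1, umi_duplicate_rate=0.3)
        _simulate(tmp_path, cfg, "a.bam")
        _simulate(tmp_path, cfg, "b.bam")
        assert file_checksum(tmp_path / "a.bam") == file_checksum(tmp_path / "b.bam")


class TestTruth:
    def test_round_trip(self, tmp_path):
        cfg = small_config(variants=(VariantPlacement(0, 100),))
        genome, ann, variants, counts, cells, reads = _simulate(tmp_path, cfg)
        truth = build_truth(cells, reads, variants)
        write_truth(truth, tmp_path / "truth")
        back = read_truth(tmp_path / "truth")
        pd.testing.assert_frame_equal(truth.cell_table, back.cell_table)
        pd.testing.assert_frame_equal(truth.read_table, back.read_table)
        pd.testing.assert_frame_equal(truth.variant_table, back.variant_table)

    def test_empty_truth_writes_headers(self, tmp_path):
        empty = SimTruth(
            pd.DataFrame(columns=["barcode", "cell_type", "germ_layer", "is_mutant"]),
            pd.DataFrame(columns=["read_id", "barcode", "umi", "gene", "origin_site",
                                  "allele_carried", "n_duplicates"]),
            pd.DataFrame(columns=["variant", "gene", "true_vaf", "n_mutant_cells"]),
        )
        write_truth(empty, tmp_path / "truth")
        back = read_truth(tmp_path / "truth")
        assert back.cell_table.empty and list(back.cell_table.columns)[0] == "barcode"

    def test_every_bam_barcode_in_cell_table(self, tmp_path):
        cfg = small_config(variants=())
        genome, ann, variants, counts, cells, reads = _simulate(tmp_path, cfg)
        known = set(cells["barcode"])
        with pysam.AlignmentFile(str(tmp_path / "sim.bam")) as bam:
            for read in bam.fetch(until_eof=True):
                assert read.get_tag("CB").removesuffix("-1") in known

    def test_true_vaf_definition(self, tmp_path):
        cfg = small_config(n_cells=80, mosaic_fraction=0.25, variants=(VariantPlacement(0, 60),))
        genome, ann, variants, counts, cells, reads = _simulate(tmp_path, cfg)
        truth = build_truth(cells, reads, variants)
        assert truth.variant_table["true_vaf"].iloc[0] == cells["is_mutant"].mean()
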