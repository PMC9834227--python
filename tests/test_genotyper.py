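"""Per-cell allele counting against hand-computed pileups and the
independent brute-force oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dropgeno.genotype import (
    ALT,
    NO_CALL,
    REF,
    CountingParams,
    VariantSite,
    annotate_calls,
    call_genotypes,
    count_alleles,
)

from _bruteforce import brute_force_counts

POS0 = 499  # variant chr1:500


def read_at(name, cb, ub, base, variant, **kw):
    """A 31-nt read whose base at the variant position is ``base``."""
    start = POS0 - 15
    seq = "G" * 15 + base + "G" * 15
    return {"name": name, "start": start, "seq": seq, "cb": cb + "-1", "ub": ub, **kw}


class TestCountAlleles:
    def test_empty_bam_known_barcodes_all_no_call(self, bam_factory, variant):
        bam = bam_factory([])
        params = CountingParams(valid_barcodes=frozenset({"AAA", "CCC", "GGG"}))
        m = count_alleles(str(bam), [variant], params)
        assert m.barcodes == ["AAA", "CCC", "GGG"]
        assert (m.calls == NO_CALL).all()
        assert m.ref_umis.nnz == 0 and m.alt_umis.nnz == 0

    def test_hand_pileup(self, bam_factory, variant):
        # cell A: two UMIs, one alt read each; cell B: one ref UMI; cell C: nothing
        reads = [
            read_at("r1", "AAA", "U1", variant.alt, variant),
            read_at("r2", "AAA", "U2", variant.alt, variant),
            read_at("r3", "CCC", "U3", variant.ref, variant),
        ]
        bam = bam_factory(reads)
        params = CountingParams(valid_barcodes=frozenset({"AAA", "CCC", "GGG"}))
        m = count_alleles(str(bam), [variant], params)
        assert m.calls[:, 0].tolist() == [ALT, REF, NO_CALL]
        assert m.alt_umis.toarray()[:, 0].tolist() == [2, 0, 0]
        assert m.ref_umis.toarray()[:, 0].tolist() == [0, 1, 0]

    def test_umi_majority_vote(self, bam_factory, variant):
        reads = [
            read_at("r1", "AAA", "U1", variant.alt, variant),
            read_at("r2", "AAA", "U1", variant.alt, variant),
            read_at("r3", "AAA", "U1", variant.ref, variant),
        ]
        m = count_alleles(str(bam_factory(reads)), [variant], CountingParams())
        assert m.alt_umis.toarray().sum() == 1
        assert m.ref_umis.toarray().sum() == 0

    def test_umi_tie_discarded_under_majority_counted_under_any(self, bam_factory, variant):
        reads = [
            read_at("r1", "AAA", "U1", variant.alt, variant),
            read_at("r2", "AAA", "U1", variant.ref, variant),
        ]
        bam = bam_factory(reads)
        m = count_alleles(str(bam), [variant], CountingParams(umi_consensus="majority"))
        assert m.coverage.sum() == 0
        m = count_alleles(str(bam), [variant], CountingParams(umi_consensus="any"))
        assert m.alt_umis.toarray().sum() == 1

    @pytest.mark.parametrize(
        "kw, note",
        [
            ({"mapq": 10}, "low mapping quality"),
            ({"baseq": 5}, "low base quality"),
            ({"flags": 256}, "secondary alignment"),
            ({"flags": 2048}, "supplementary alignment"),
            ({"cb": None}, "missing CB tag"),
            ({"ub": None}, "missing UB tag"),
        ],
    )
    def test_filtered_reads_contribute_nothing(self, bam_factory, variant, kw, note):
        rd = read_at("r1", "AAA", "U1", variant.alt, variant)
        rd.update(kw)
        m = count_alleles(str(bam_factory([rd])), [variant], CountingParams())
        assert m.coverage.sum() == 0, note

    def test_mismatching_base_discarded(self, bam_factory, variant):
        other = next(b for b in "ACGT" if b not in (variant.ref, variant.alt))
        m = count_alleles(
            str(bam_factory([read_at("r1", "AAA", "U1", other, variant)])),
            [variant],
            CountingParams(),
        )
        assert m.coverage.sum() == 0

    def test_deletion_spanning_position_discarded(self, bam_factory, variant):
        rd = {
            "name": "r1", "start": POS0 - 10, "seq": "G" * 20,
            "cigar": [(0, 10), (2, 5), (0, 10)],  # deletion spans the site
            "cb": "AAA-1", "ub": "U1",
        }
        m = count_alleles(str(bam_factory([rd])), [variant], CountingParams())
        assert m.coverage.sum() == 0

    def test_missing_index_is_explicit_error(self, tmp_path, bam_factory, variant):
        bam = bam_factory([read_at("r1", "AAA", "U1", variant.ref, variant)])
        (tmp_path / "fixture.bam.bai").unlink()
        with pytest.raises(FileNotFoundError, match="index"):
            count_alleles(str(bam), [variant], CountingParams())

    def test_unknown_chrom_gives_all_no_call_column(self, bam_factory, variant):
        odd = VariantSite("chrUn", 100, "A", "C")
        bam = bam_factory([read_at("r1", "AAA", "U1", variant.alt, variant)])
        m = count_alleles(str(bam), [variant, odd], CountingParams())
        j = m.variant_ids().index(odd.id)
        assert (m.calls[:, j] == NO_CALL).all()
        assert (m.calls != NO_CALL).sum() == 1  # the real variant still called

    def test_read_order_permutation_invariance(self, bam_factory, variant, tmp_path):
        rng = np.random.default_rng(11)
        from conftest import make_bam, random_fixture_reads

        reads = random_fixture_reads(rng, variant, 120, ["AAA", "CCC", "GGG"])
        m1 = count_alleles(str(make_bam(tmp_path / "a.bam", reads)), [variant], CountingParams())
        rng.shuffle(reads)
        m2 = count_alleles(str(make_bam(tmp_path / "b.bam", reads)), [variant], CountingParams())
        assert (m1.ref_umis != m2.ref_umis).nnz == 0
        assert (m1.alt_umis != m2.alt_umis).nnz == 0

    def test_matches_brute_force_oracle(self, tmp_path, variant):
        from conftest import make_bam, random_fixture_reads

        rng = np.random.default_rng(5)
        params = CountingParams()
        for trial in range(5):
            reads = random_fixture_reads(rng, variant, 300, ["AAA", "CCC", "GGG", "TTT"])
            bam = make_bam(tmp_path / f"t{trial}.bam", reads)
            m = count_alleles(str(bam), [variant], params)
            oracle = brute_force_counts(bam, [variant], params)
            got = {
                (bc, 0): (int(m.ref_umis[i, 0]), int(m.alt_umis[i, 0]))
                for i, bc in enumerate(m.barcodes)
                if m.ref_umis[i, 0] or m.alt_umis[i, 0]
            }
            assert got == oracle

    def test_umi_coverage_bounded_by_distinct_pairs(self, tmp_path, variant):
        from conftest import make_bam, random_fixture_reads

        rng = np.random.default_rng(17)
        reads = random_fixture_reads(rng, variant, 400, ["AAA", "CCC"])
        bam = make_bam(tmp_path / "cov.bam", reads)
        m = count_alleles(str(bam), [variant], CountingParams(min_mapping_quality=0, min_base_quality=0))
        n_pairs = len({(r["cb"], r["ub"]) for r in reads if r["cb"] and r["ub"]})
        assert m.coverage.sum() <= n_pairs


class TestCallGenotypes:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [(0, 0, NO_CALL), (3, 1, ALT), (3, 0, REF), (0, 2, ALT)],
    )
    def test_alt_dominant(self, ref, alt, expected):
        calls, both = call_genotypes(np.array([[ref]]), np.array([[alt]]), "alt_dominant")
        assert calls[0, 0] == expected
        assert both[0, 0] == (ref >= 1 and alt >= 1)

    def test_consensus_flags_both(self):
        calls, both = call_genotypes(np.array([[2, 0, 1]]), np.array([[1, 3, 0]]), "consensus")
        assert calls.tolist() == [[ALT, ALT, REF]]
        assert both.tolist() == [[True, False, False]]


class TestAnnotateCalls:
    def _matrices(self, bam_factory, variant):
        reads = [
            read_at("r1", "AAA", "U1", variant.alt, variant),
            read_at("r2", "CCC", "U2", variant.ref, variant),
        ]
        return count_alleles(
            str(bam_factory(reads)),
            [variant],
            CountingParams(valid_barcodes=frozenset({"AAA", "CCC", "GGG"})),
        )

    def test_disjoint_barcodes_error(self, bam_factory, variant):
        m = self._matrices(bam_factory, variant)
        meta = pd.DataFrame({"cluster": ["x"]}, index=["TTT"])
        with pytest.raises(ValueError, match="suffix"):
            annotate_calls(m, meta)

    def test_exact_match_with_suffix_normalization(self, bam_factory, variant):
        m = self._matrices(bam_factory, variant)
        meta = pd.DataFrame({"cluster": ["x", "y", "z"]}, index=["AAA-1", "CCC-1", "GGG-1"])
        table = annotate_calls(m, meta)
        assert len(table) == 3  # 3 barcodes x 1 variant
        assert set(table["call"]) == {"alt", "ref", "no_call"}

    def test_metadata_superset_keeps_matrix_barcodes(self, bam_factory, variant):
        m = self._matrices(bam_factory, variant)
        meta = pd.DataFrame(
            {"cluster": list("wxyz")}, index=["AAA", "CCC", "GGG", "TTT"]
        )
        table = annotate_calls(m, meta)
        assert sorted(table["barcode"].unique()) == ["AAA", "CCC", "GGG"]
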