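"""Clumping, cis windows, confounder exclusion, strength, Steiger."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrlipid.gwas_io import SummaryRecord, two_sided_p
from mrlipid.instruments import (
    ConfounderTable,
    GeneRegion,
    InstrumentSelectionError,
    LDMatrix,
    clump,
    exclude_confounder_snps,
    instrument_strength,
    read_gene_regions,
    read_ld_matrix,
    select_genomewide,
    select_region,
    steiger_filter,
    write_ld_matrix,
)

from conftest import make_iset


def srec(snp, pval, chrom="1", pos=1_000_000, beta=0.1, se=0.01):
    return SummaryRecord(
        snp_id=snp, chrom=chrom, pos=pos, effect_allele="A", other_allele="G",
        beta=beta, se=se, pval=pval, eaf=0.3, n=300_000,
    )


def ld_from_pairs(ids, pairs):
    """Symmetric LD matrix with r for the given id pairs, 0 elsewhere."""
    n = len(ids)
    r = np.eye(n)
    index = {s: i for i, s in enumerate(ids)}
    for a, b, val in pairs:
        r[index[a], index[b]] = r[index[b], index[a]] = val
    return LDMatrix(list(ids), r)


def brute_force_clump(records, ld, r2_threshold, window_kb):
    """Independent greedy oracle: explicit stepwise enumeration."""
    remaining = sorted(
        records, key=lambda r: (r.pval if r.pval is not None else 1.0, r.snp_id)
    )
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best.snp_id)
        survivors = []
        for other in remaining:
            same_window = (
                other.chrom == best.chrom
                and abs(other.pos - best.pos) <= window_kb * 1000
            )
            if same_window and ld.r2(best.snp_id, other.snp_id) >= r2_threshold:
                continue
            survivors.append(other)
        remaining = survivors
    return kept


class TestClump:
    def test_independent_snps_all_retained(self):
        recs = [srec(f"rs{i}", 1e-9, pos=1_000_000 + i * 1000) for i in range(3)]
        ld = ld_from_pairs([r.snp_id for r in recs], [])
        assert sorted(clump(recs, ld, 0.001, 10_000)) == [r.snp_id for r in recs]

    def test_greedy_steps_by_hand(self):
        # s1 best, retires s2 (r2 = 0.25 >= 0.001); s3 independent
        recs = [
            srec("s1", 1e-10, pos=1_000_000),
            srec("s2", 1e-9, pos=1_100_000),
            srec("s3", 1e-8, pos=1_200_000),
        ]
        ld = ld_from_pairs(["s1", "s2", "s3"], [("s1", "s2", 0.5)])
        assert clump(recs, ld, 0.001, 10_000) == ["s1", "s3"]

    def test_tie_broken_by_ascending_id(self):
        recs = [
            srec("rsB", 1e-9, pos=1_000_000),
            srec("rsA", 1e-9, pos=1_001_000),
        ]
        ld = ld_from_pairs(["rsB", "rsA"], [("rsB", "rsA", 1.0)])
        assert clump(recs, ld, 0.001, 10_000) == ["rsA"]

    def test_window_limits_retirement(self):
        # perfect LD but outside the window: both retained
        recs = [
            srec("s1", 1e-10, pos=1_000_000),
            srec("s2", 1e-9, pos=30_000_000),
        ]
        ld = ld_from_pairs(["s1", "s2"], [("s1", "s2", 1.0)])
        assert clump(recs, ld, 0.001, 10_000) == ["s1", "s2"]

    def test_missing_ld_dropped_with_warning(self):
        recs = [srec("s1", 1e-10), srec("s2", 1e-9, pos=1_100_000)]
        ld = ld_from_pairs(["s1"], [])
        with pytest.warns(UserWarning, match="s2"):
            assert clump(recs, ld, 0.001, 10_000) == ["s1"]

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_oracle_and_order_invariant(self, data):
        n = data.draw(st.integers(2, 20))
        ids = [f"rs{i:02d}" for i in range(n)]
        pvals = [data.draw(st.floats(1e-30, 1e-8)) for _ in range(n)]
        pos = [1_000_000 + i * data.draw(st.integers(1, 2000)) * 1000 for i in range(n)]
        recs = [srec(ids[i], pvals[i], pos=pos[i]) for i in range(n)]
        # random sparse LD
        pairs = []
        for i in range(n):
            for j in range(i + 1, n):
                if data.draw(st.booleans()):
                    pairs.append((ids[i], ids[j], data.draw(st.floats(0, 0.99))))
        # build a valid (not necessarily PSD, irrelevant here) r matrix
        r = np.eye(n)
        idx = {s: k for k, s in enumerate(ids)}
        for a, b, v in pairs:
            r[idx[a], idx[b]] = r[idx[b], idx[a]] = v
        ld = LDMatrix(ids, r)
        threshold = data.draw(st.sampled_from([0.001, 0.01, 0.2]))
        result = clump(recs, ld, threshold, 10_000)
        assert result == brute_force_clump(recs, ld, threshold, 10_000)
        # mutually below threshold (within-window pairs)
        for i, a in enumerate(result):
            for b in result[i + 1:]:
                ra = next(x for x in recs if x.snp_id == a)
                rb = next(x for x in recs if x.snp_id == b)
                if abs(ra.pos - rb.pos) <= 10_000_000:
                    assert ld.r2(a, b) < threshold
        shuffled = list(recs)
        data.draw(st.randoms(use_true_random=False)).shuffle(shuffled)
        assert clump(shuffled, ld, threshold, 10_000) == result


class TestSelection:
    def _outcome(self, recs):
        return [
            SummaryRecord(
                snp_id=r.snp_id, chrom=r.chrom, pos=r.pos,
                effect_allele="A", other_allele="G",
                beta=0.01, se=0.02, pval=0.6, eaf=0.3, n=337_199,
            )
            for r in recs
        ]

    def test_p_filter_excludes_weak_snps(self):
        recs = [srec(f"rs{i}", 1e-9, pos=1_000_000 + i * 1_000_000) for i in range(3)]
        recs += [srec("rs90", 1e-6, pos=9_000_000), srec("rs91", 1e-7, pos=11_000_000)]
        ld = ld_from_pairs([r.snp_id for r in recs], [])
        iset = select_genomewide(recs, self._outcome(recs), ld)
        assert sorted(iset.snp_ids) == ["rs0", "rs1", "rs2"]

    def test_no_instruments_at_threshold_raises(self):
        recs = [srec("rs1", 1e-3)]
        ld = ld_from_pairs(["rs1"], [])
        with pytest.raises(InstrumentSelectionError, match="threshold"):
            select_genomewide(recs, self._outcome(recs), ld)

    def test_region_window_closed_interval(self):
        region = GeneRegion("GENE", "1", 1000, 2000, window_kb=100)
        inside = srec("rs_in", 1e-9, pos=101_999)
        boundary = srec("rs_bd", 1e-9, pos=102_000)
        outside = srec("rs_out", 1e-9, pos=102_001)
        third = srec("rs_3rd", 1e-9, pos=1500)
        recs = [inside, boundary, outside, third]
        ld = ld_from_pairs([r.snp_id for r in recs], [])
        iset = select_region(recs, self._outcome(recs), region, ld)
        assert sorted(iset.snp_ids) == ["rs_3rd", "rs_bd", "rs_in"]

    def test_insufficient_cis_instruments_reports_count(self):
        region = GeneRegion("GENE", "1", 1000, 2000, window_kb=100)
        recs = [srec(f"rs{i}", 1e-9, pos=1500 + i) for i in range(3)]
        ids = [r.snp_id for r in recs]
        # all pairwise r2 = 0.25 >= threshold 0.2: one survivor
        ld = ld_from_pairs(ids, [(a, b, 0.5) for i, a in enumerate(ids)
                                 for b in ids[i + 1:]])
        with pytest.raises(InstrumentSelectionError, match="1 retained"):
            select_region(recs, self._outcome(recs), region, ld, r2_threshold=0.2)

    def test_region_monotone_in_window(self, paper_study):
        exposure = paper_study.exposures["LDL-C"]
        region = paper_study.regions[1]  # PCSK9-like block
        wide = select_region(
            exposure, paper_study.outcome, region, paper_study.ld,
            r2_threshold=0.2,
        )
        narrow_region = GeneRegion(
            region.gene, region.chrom, region.start, region.end, window_kb=0
        )
        narrow = select_region(
            exposure, paper_study.outcome, narrow_region, paper_study.ld,
            r2_threshold=0.2,
        )
        assert set(narrow.snp_ids) <= set(wide.snp_ids)

    def test_genomewide_matches_brute_force_oracle(self, paper_study):
        exposure = paper_study.exposures["LDL-C"]
        iset = select_genomewide(
            exposure, paper_study.outcome, paper_study.ld, exposure_name="LDL-C"
        )
        significant = [
            r for r in exposure
            if (r.pval if r.pval is not None else two_sided_p(r.beta / r.se)) < 5e-8
        ]
        oracle = brute_force_clump(significant, paper_study.ld, 0.001, 10_000)
        assert sorted(iset.snp_ids) == sorted(oracle)

    def test_retained_count_monotone_in_p_threshold(self, paper_study):
        exposure = paper_study.exposures["LDL-C"]
        counts = []
        for p in (5e-8, 5e-10, 5e-12):
            iset = select_genomewide(
                exposure, paper_study.outcome, paper_study.ld, p_threshold=p
            )
            counts.append(iset.nsnp)
        assert counts == sorted(counts, reverse=True)


class TestConfounderExclusion:
    def test_empty_table_is_identity(self):
        iset = make_iset([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
        out = exclude_confounder_snps(
            iset, ConfounderTable(), ["blood pressure"]
        )
        assert out.snp_ids == iset.snp_ids

    def test_tagged_snp_dropped(self):
        iset = make_iset([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
        table = ConfounderTable({iset.snp_ids[0]: {"hypertension"}})
        out = exclude_confounder_snps(
            iset, table, ["blood pressure", "hypertension"]
        )
        assert out.snp_ids == iset.snp_ids[1:]
        assert out.selection_params["confounder_dropped"] == [iset.snp_ids[0]]

    def test_substring_matching(self):
        iset = make_iset([0.1], [0.05], [0.01])
        table = ConfounderTable({iset.snp_ids[0]: {"Systolic Blood Pressure"}})
        out = exclude_confounder_snps(iset, table, ["blood pressure"])
        assert not out.snp_ids
        exact = exclude_confounder_snps(
            iset, table, ["blood pressure"], mode="exact"
        )
        assert exact.snp_ids == iset.snp_ids


class TestStrength:
    def test_f_statistic_arithmetic(self):
        iset = make_iset([0.1], [0.05], [0.01], sx=[0.01], n_exp=10_000)
        out = instrument_strength(iset)
        assert out["F"][0] == pytest.approx(100.0)
        assert out["r2"][0] == pytest.approx(100.0 / 10_098.0)
        assert not out["weak"][0]

    def test_weak_flag_below_ten(self):
        iset = make_iset([0.03], [0.01], [0.01], sx=[0.01])
        out = instrument_strength(iset)
        assert out["F"][0] == pytest.approx(9.0)
        assert out["weak"][0]

    def test_small_sample_rejected(self):
        iset = make_iset([0.1], [0.05], [0.01], n_exp=2)
        with pytest.raises(InstrumentSelectionError):
            instrument_strength(iset)


class TestSteiger:
    def test_exposure_dominant_direction(self):
        # strong exposure association, null outcome association
        iset = make_iset([0.14], [0.001], [0.02], sx=[0.01],
                         n_exp=100_000, n_out=300_000)
        filtered, results = steiger_filter(iset)
        assert results[0].direction_ok
        assert results[0].r2_exp > results[0].r2_out
        assert filtered.nsnp == 1

    def test_symmetric_case_is_not_forward(self):
        iset = make_iset([0.1], [0.1], [0.01], sx=[0.01],
                         n_exp=100_000, n_out=100_000)
        filtered, results = steiger_filter(iset)
        assert results[0].z == pytest.approx(0.0, abs=1e-12)
        assert results[0].pval == pytest.approx(1.0)
        assert not results[0].direction_ok
        assert filtered.nsnp == 0

    def test_sign_flip_invariance(self):
        iset_pos = make_iset([0.1, 0.2], [0.05, -0.02], [0.02, 0.02],
                             sx=[0.01, 0.01])
        iset_neg = make_iset([-0.1, 0.2], [-0.05, -0.02], [0.02, 0.02],
                             sx=[0.01, 0.01])
        _, res_pos = steiger_filter(iset_pos)
        _, res_neg = steiger_filter(iset_neg)
        for a, b in zip(res_pos, res_neg):
            assert a.r2_exp == pytest.approx(b.r2_exp)
            assert a.z == pytest.approx(b.z)

    def test_small_n_rejected(self):
        iset = make_iset([0.1], [0.05], [0.01], n_exp=3)
        with pytest.raises(InstrumentSelectionError):
            steiger_filter(iset)

    def test_generator_instruments_all_forward(self, paper_study):
        iset = select_genomewide(
            paper_study.exposures["LDL-C"], paper_study.outcome, paper_study.ld
        )
        filtered, results = steiger_filter(iset)
        assert all(r.direction_ok for r in results)
        assert filtered.nsnp == iset.nsnp


class TestFileFormats:
    def test_ld_matrix_round_trip(self, tmp_path, rng):
        a = rng.uniform(-0.9, 0.9, size=(4, 4))
        r = (a + a.T) / 2
        np.fill_diagonal(r, 1.0)
        ld = LDMatrix([f"rs{i}" for i in range(4)], r)
        path = tmp_path / "ld.tsv"
        write_ld_matrix(ld, path)
        back = read_ld_matrix(path)
        assert back.snp_ids == ld.snp_ids
        np.testing.assert_allclose(back.r, ld.r)

    def test_gene_region_reader_one_based(self, tmp_path):
        path = tmp_path / "regions.tsv"
        path.write_text("# gene chrom start end\nHMGCR\t5\t100\t200\n")
        regions = read_gene_regions(path, window_kb=1)
        assert regions[0].gene == "HMGCR"
        assert regions[0].contains("5", 100) and regions[0].contains("5", 200)
        assert regions[0].window_start == 100 - 1000

    def test_ld_matrix_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            LDMatrix(["a", "b"], np.array([[0.9, 0.2], [0.2, 1.0]]))
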