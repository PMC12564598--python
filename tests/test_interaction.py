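import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sgascreen import (
    GeneAnnotation, GeneMeasurement, InteractionRecord, LibraryLayout,
    call_hits, collate_measurements, compare_conditions, compute_gis,
    exclude_linked, interaction_pvalue, interval_distance, make_grid,
    parse_locus, score_measurements, welch_log2_pvalue,
)
from sgascreen.interaction import EXCL_LINKED, HIT_NEGATIVE, HIT_NONE, HIT_POSITIVE

positive_sizes = st.lists(
    st.floats(min_value=1.0, max_value=1e4, allow_nan=False), min_size=2,
    max_size=12,
)


def _measurement(q, c, gene="g1", cond="untreated"):
    return GeneMeasurement(gene_id=gene, condition=cond,
                           query_sizes=list(q), control_sizes=list(c))


class TestCollate:
    def _plates(self, sizes_by_plate, background="query", cond="untreated"):
        out = []
        for rep, val in enumerate(sizes_by_plate, start=1):
            out.append(make_grid(np.full((2, 2), float(val)),
                                 plate_id="P01", condition=cond,
                                 background=background, replicate=rep))
        return out

    def test_pools_across_replicates(self):
        layout = LibraryLayout({("P01", 1, 1): "g1", ("P01", 1, 2): "EMPTY",
                                ("P01", 2, 1): "EMPTY", ("P01", 2, 2): "EMPTY"})
        plates = self._plates([400, 410, 390])
        for p, v in zip(plates, (400, 410, 390)):
            p.size[:] = 1.0
            p.size[0, 0] = v
        ms = collate_measurements(plates, layout)
        assert len(ms) == 1
        assert ms[0].query_sizes == [400, 410, 390]
        assert ms[0].control_sizes == []

    def test_masked_replicate_contributes_nothing(self):
        layout = LibraryLayout({("P01", 1, 1): "g1"})
        plates = self._plates([400, 410, 390])
        plates[1].mask[0, 0] = True
        plates[1].mask_reason[0, 0] = "small"
        ms = collate_measurements(plates, layout)
        assert ms[0].query_sizes == [400, 390]

    def test_pooled_counts_match_enumeration(self, rng):
        # replicate spots + replicates + both backgrounds, vs a direct walk
        genes = [f"g{i}" for i in range(6)]
        layout_entries = {}
        for i, g in enumerate(genes):
            layout_entries[("P01", 1 + i // 3, 1 + (i % 3) * 2)] = g
            layout_entries[("P01", 1 + i // 3, 2 + (i % 3) * 2)] = g
        layout = LibraryLayout(layout_entries)
        plates = []
        for background in ("query", "control"):
            for rep in (1, 2):
                size = rng.uniform(100, 800, (2, 6))
                size[rng.random((2, 6)) < 0.2] = 0.0
                plates.append(make_grid(size, plate_id="P01",
                                        background=background, replicate=rep))
        ms = {m.gene_id: m for m in collate_measurements(plates, layout)}
        for gene in genes:
            expected_q, expected_c = [], []
            for grid in plates:
                for (pid, r, c), g in layout_entries.items():
                    if g != gene:
                        continue
                    if not grid.mask[r - 1, c - 1]:
                        target = (expected_q if grid.background == "query"
                                  else expected_c)
                        target.append(grid.size[r - 1, c - 1])
            assert sorted(ms[gene].query_sizes) == sorted(expected_q)
            assert sorted(ms[gene].control_sizes) == sorted(expected_c)


class TestGis:
    def test_equal_sizes_give_zero(self):
        assert compute_gis(_measurement([400] * 3, [400] * 3)) == 0.0

    def test_doubling_gives_one(self):
        assert compute_gis(_measurement([800] * 3, [400] * 3)) == 1.0

    @given(q=positive_sizes, c=positive_sizes)
    @settings(max_examples=50, deadline=None)
    def test_matches_geometric_mean_ratio_oracle(self, q, c):
        gis = compute_gis(_measurement(q, c))
        gm = lambda xs: math.exp(sum(math.log(x) for x in xs) / len(xs))
        assert gis == pytest.approx(math.log2(gm(q) / gm(c)), abs=1e-12)

    @given(q=positive_sizes, c=positive_sizes)
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_swap(self, q, c):
        a = compute_gis(_measurement(q, c))
        b = compute_gis(_measurement(c, q))
        assert a == pytest.approx(-b, abs=1e-12)

    @given(q=positive_sizes, c=positive_sizes,
           factor=st.floats(min_value=0.01, max_value=100))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_common_rescaling(self, q, c, factor):
        a = compute_gis(_measurement(q, c))
        b = compute_gis(_measurement([x * factor for x in q],
                                     [x * factor for x in c]))
        assert a == pytest.approx(b, abs=1e-9)

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            compute_gis(_measurement([400], [400, 400]))


class TestWelchPvalue:
    def test_identical_sides_give_p_one(self):
        assert interaction_pvalue(_measurement([400] * 3, [400] * 3)) == 1.0

    def test_separated_degenerate_sides_highly_significant(self):
        p = interaction_pvalue(_measurement([512] * 3, [256] * 3))
        assert p < 0.001

    def test_matches_scipy_on_nondegenerate_data(self, rng):
        for _ in range(20):
            q = rng.lognormal(6, 0.2, 5)
            c = rng.lognormal(6, 0.3, 7)
            ours = welch_log2_pvalue(q, c)
            ref = stats.ttest_ind(np.log2(q), np.log2(c), equal_var=False).pvalue
            assert ours == pytest.approx(ref, rel=1e-10)

    def test_type_one_error_calibrated_under_null(self, rng):
        # 10,000 null genes; 3 biological replicates x 4 replicate spots
        # per side (the screen's pooled design), sigma_log2 = 0.15
        n = 10_000
        q = 400 * 2 ** rng.normal(0, 0.15, (n, 12))
        c = 400 * 2 ** rng.normal(0, 0.15, (n, 12))
        ps = np.array([welch_log2_pvalue(q[i], c[i]) for i in range(n)])
        rate = float(np.mean(ps < 0.1))
        assert 0.08 <= rate <= 0.12


class TestLinkageExclusion:
    ann = GeneAnnotation({
        "near": ("chrII", 1_200_000, 1_201_000),
        "other_chrom": ("chrI", 1_200_000, 1_201_000),
        "boundary": ("chrII", 1_252_001, 1_253_000),
        "inside": ("chrII", 1_000_500, 1_001_000),
    })
    locus = ("chrII", 1_000_000, 1_002_000)

    def _recs(self, genes):
        return [InteractionRecord(g, "untreated", 0.5, 0.01, 12, 12)
                for g in genes]

    def test_gene_within_window_excluded(self):
        recs = exclude_linked(self._recs(["near"]), self.locus, self.ann)
        assert recs[0].excluded and recs[0].exclusion_reason == EXCL_LINKED

    def test_same_position_other_chromosome_retained(self):
        recs = exclude_linked(self._recs(["other_chrom"]), self.locus, self.ann)
        assert not recs[0].excluded

    def test_boundary_distance_retained_strict(self):
        # closest-endpoint distance 250,001 >= 250 kb -> retained
        recs = exclude_linked(self._recs(["boundary"]), self.locus, self.ann)
        assert not recs[0].excluded

    def test_overlapping_gene_distance_zero_excluded(self):
        recs = exclude_linked(self._recs(["inside"]), self.locus, self.ann)
        assert recs[0].excluded

    def test_unannotated_gene_retained_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="sgascreen"):
            recs = exclude_linked(self._recs(["mystery"]), self.locus, self.ann)
        assert not recs[0].excluded
        assert "lack coordinates" in caplog.text

    def test_interval_distance_arithmetic(self):
        assert interval_distance((1_000_000, 1_002_000),
                                 (1_200_000, 1_201_000)) == 198_000
        assert interval_distance((10, 20), (15, 30)) == 0
        assert interval_distance((15, 30), (1, 5)) == 10

    def test_parse_locus(self):
        assert parse_locus("chrII:1,000,000-1,002,000") == \
            ("chrII", 1_000_000, 1_002_000)
        with pytest.raises(ValueError):
            parse_locus("chrII:200-100")


class TestCallHits:
    def _rec(self, gis, p, excluded=False):
        return InteractionRecord("g1", "untreated", gis, p, 12, 12,
                                 excluded=excluded,
                                 exclusion_reason="linked" if excluded else "none")

    @pytest.mark.parametrize("gis,p,expected", [
        (0.20, 0.05, HIT_POSITIVE),
        (-0.20, 0.05, HIT_NEGATIVE),
        (-0.16, 0.20, HIT_NONE),     # p fails
        (0.15, 0.05, HIT_NONE),      # threshold is strict
        (-0.15, 0.05, HIT_NONE),
        (0.10, 0.001, HIT_NONE),     # GIS fails
        (0.20, 0.1, HIT_NONE),       # p threshold is strict
    ])
    def test_threshold_logic(self, gis, p, expected):
        assert call_hits([self._rec(gis, p)])[0].hit_class == expected

    def test_excluded_records_never_hits(self):
        rec = call_hits([self._rec(2.0, 1e-10, excluded=True)])[0]
        assert rec.hit_class == HIT_NONE


class TestScoreMeasurements:
    def test_insufficient_reps_excluded_not_scored(self):
        ms = [_measurement([400], [400, 400], gene="low"),
              _measurement([400] * 3, [400] * 3, gene="ok")]
        recs = {r.gene_id: r for r in score_measurements(ms, min_reps=2)}
        assert recs["low"].excluded
        assert recs["low"].exclusion_reason == "insufficient_reps"
        assert recs["low"].gis is None
        assert not recs["ok"].excluded and recs["ok"].gis == 0.0


class TestCompareConditions:
    def _records(self, cond, hits_pos, hits_neg, background):
        out = []
        for g in background:
            if g in hits_pos:
                rec = InteractionRecord(g, cond, 0.5, 0.01, 12, 12,
                                        hit_class=HIT_POSITIVE)
            elif g in hits_neg:
                rec = InteractionRecord(g, cond, -0.5, 0.01, 12, 12,
                                        hit_class=HIT_NEGATIVE)
            else:
                rec = InteractionRecord(g, cond, 0.0, 0.9, 12, 12,
                                        hit_class=HIT_NONE)
            out.append(rec)
        return out

    def test_identical_hit_sets(self):
        bg = [f"g{i}" for i in range(100)]
        pos, neg = set(bg[:10]), set(bg[10:25])
        a = self._records("untreated", pos, neg, bg)
        b = self._records("CAP", pos, neg, bg)
        cmp = compare_conditions(a, b)
        assert cmp.shared_positive == pos and cmp.shared_negative == neg
        assert cmp.fisher_positive.p_value < 1e-10

    def test_disjoint_hit_sets(self):
        bg = [f"g{i}" for i in range(100)]
        a = self._records("untreated", set(bg[:10]), set(), bg)
        b = self._records("CAP", set(bg[10:20]), set(), bg)
        cmp = compare_conditions(a, b)
        assert cmp.shared_positive == set()
        assert cmp.fisher_positive.intersection == 0

    def test_intersections_match_set_oracle(self, rng):
        bg = [f"g{i}" for i in range(200)]
        pa = set(rng.choice(bg, 30, replace=False))
        pb = set(rng.choice(bg, 40, replace=False))
        a = self._records("untreated", pa, set(), bg)
        b = self._records("CAP", pb, set(), bg)
        cmp = compare_conditions(a, b)
        assert cmp.shared_positive == pa & pb
        assert len(cmp.background_genes) == 200
        assert cmp.fisher_positive.set_sizes == (len(pa), len(pb))

    def test_background_is_genes_scored_in_both(self):
        bg = [f"g{i}" for i in range(50)]
        a = self._records("untreated", {"g1"}, set(), bg)
        b = self._records("CAP", {"g1"}, set(), bg)
        # g1..g9 unscored in condition B
        for r in b[:10]:
            r.excluded = True
            r.gis = None
        cmp = compare_conditions(a, b)
        assert len(cmp.background_genes) == 40

    def test_empty_background_is_hard_error(self):
        a = self._records("untreated", set(), set(), ["g1"])
        b = self._records("CAP", set(), set(), ["g2"])
        with pytest.raises(ValueError, match="background"):
            compare_conditions(a, b)
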