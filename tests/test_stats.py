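"""Nonparametric statistics layer against brute-force oracles."""

import numpy as np
import pytest
from scipy.stats import norm

from neuroscreen.detection import ScreeningRecord
from neuroscreen.errors import DegenerateInputError
from neuroscreen.stats import (
    GroupedVariable,
    derive_screening_variables,
    dunns_posthoc,
    kruskal_wallis,
    lilliefors,
    run_stats,
    spearman,
    summarize_median_iqr,
)


# ---------------------------------------------------------------------------
# brute-force oracles (independent of scipy's test implementations)


def rank_with_ties(pooled):
    """Average ranks computed by direct enumeration."""
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kruskal_oracle(groups):
    """Tie-corrected H evaluated from the textbook rank-sum formula."""
    pooled = [x for g in groups for x in g]
    n = len(pooled)
    ranks = rank_with_ties(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = sum(ranks[start : start + len(g)])
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    from collections import Counter

    ties = sum(t**3 - t for t in Counter(pooled).values())
    return h / (1.0 - ties / (n**3 - n)) if ties else h


def dunn_oracle(groups):
    """Pairwise Dunn z from first principles."""
    pooled = [x for g in groups for x in g]
    n = len(pooled)
    ranks = rank_with_ties(pooled)
    means, sizes = [], []
    start = 0
    for g in groups:
        means.append(sum(ranks[start : start + len(g)]) / len(g))
        sizes.append(len(g))
        start += len(g)
    from collections import Counter

    tie_term = sum(t**3 - t for t in Counter(pooled).values()) / (12.0 * (n - 1))
    zs = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = ((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])) ** 0.5
            zs[(i, j)] = (means[i] - means[j]) / se
    return zs


def spearman_oracle(x, y):
    """Pearson correlation of average ranks, by direct computation."""
    rx, ry = rank_with_ties(list(x)), rank_with_ties(list(y))
    mx, my = np.mean(rx), np.mean(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


def median_iqr_oracle(values):
    """Sort-and-interpolate quantiles (linear rule) from scratch."""
    x = sorted(values)
    n = len(x)

    def q(p):
        pos = p * (n - 1)
        lo = int(np.floor(pos))
        hi = min(lo + 1, n - 1)
        return x[lo] + (pos - lo) * (x[hi] - x[lo])

    return q(0.5), q(0.25), q(0.75)


# ---------------------------------------------------------------------------


class TestLilliefors:
    def test_normal_sample_not_rejected(self):
        x = np.random.default_rng(1).standard_normal(500)
        _d, p = lilliefors(x)
        assert p > 0.05

    def test_uniform_sample_rejected(self):
        x = np.random.default_rng(2).uniform(0.0, 1.0, size=500)
        _d, p = lilliefors(x)
        assert p < 0.01

    def test_constant_sample_degenerate(self):
        with pytest.raises(DegenerateInputError):
            lilliefors([2.0, 2.0, 2.0, 2.0])

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            lilliefors([1.0, 2.0, 3.0])

    def test_agrees_with_statsmodels_statistic(self, rng):
        # statistic (not p) cross-checked against the independent implementation
        from statsmodels.stats.diagnostic import lilliefors as sm_lill

        x = rng.standard_normal(60)
        d_ours, _ = lilliefors(x)
        d_sm, _ = sm_lill(x, dist="norm")
        assert d_ours == pytest.approx(d_sm, abs=1e-10)


class TestKruskalWallis:
    def test_textbook_example_h_7_2(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2, abs=1e-9)

    def test_matches_oracle_with_ties(self, rng):
        groups = [list(rng.integers(0, 6, size=k).astype(float)) for k in (8, 11, 9)]
        h, _p = kruskal_wallis(groups)
        assert h == pytest.approx(kruskal_oracle(groups), abs=1e-9)

    def test_identical_groups_give_zero_h(self):
        h, _ = kruskal_wallis([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_invariant_under_label_permutation(self, rng):
        data = list(rng.normal(size=12))
        h1, _ = kruskal_wallis([data[:4], data[4:8], data[8:]])
        h2, _ = kruskal_wallis([data[8:], data[:4], data[4:8]])
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        groups = [rng.normal(size=7), rng.normal(size=9) + 0.5]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0, 3.0, 4.0, 5.0]])


class TestDunn:
    def test_z_matches_brute_force_oracle(self, rng):
        groups = [list(rng.integers(0, 8, size=k).astype(float)) for k in (6, 9, 7)]
        table = dunns_posthoc(groups, adjust="none")
        zs = dunn_oracle(groups)
        for (i, j), z in zs.items():
            row = table[(table.group1 == f"group{i}") & (table.group2 == f"group{j}")]
            assert row.z.iloc[0] == pytest.approx(z, abs=1e-9)
            assert row.p_raw.iloc[0] == pytest.approx(2 * norm.sf(abs(z)), abs=1e-12)

    def test_identical_groups_have_no_significant_pairs(self):
        g = [1.0, 2.0, 3.0, 4.0]
        table = dunns_posthoc([g, g, g])
        assert not table.significant.any()

    def test_adjusted_p_never_below_raw(self, rng):
        groups = [rng.normal(loc=m, size=8) for m in (0.0, 0.5, 2.0, 3.0)]
        for method in ("bonferroni", "holm", "none"):
            table = dunns_posthoc(groups, adjust=method)
            assert np.all(table.p_adj.to_numpy() >= table.p_raw.to_numpy() - 1e-15)

    def test_unknown_adjustment_rejected(self):
        with pytest.raises(ValueError):
            dunns_posthoc([[1.0, 2.0], [3.0, 4.0]], adjust="fdr_tsbh")


class TestSpearman:
    def test_monotone_increasing_gives_plus_one(self):
        x = [1.0, 2.0, 5.0, 9.0, 11.0]
        r, _ = spearman(x, [v**3 + 1 for v in x])
        assert r == pytest.approx(1.0)

    def test_monotone_decreasing_gives_minus_one(self):
        x = [1.0, 2.0, 5.0, 9.0, 11.0]
        r, _ = spearman(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_tied_sample_matches_rank_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 7.0]
        y = [0.0, 1.0, 3.0, 3.0, 2.0, 5.0, 5.0, 6.0]
        r, _ = spearman(x, y)
        assert r == pytest.approx(spearman_oracle(x, y), abs=1e-9)

    def test_confidence_interval_brackets_r(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(scale=0.5, size=40)
        r, _p, (lo, hi) = spearman(x, y, ci=True)
        assert lo < r < hi
        assert -1.0 <= lo and hi <= 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0])


class TestMedianIqr:
    def test_simple_median(self):
        med, q1, q3 = summarize_median_iqr([1, 2, 3, 4, 5])
        assert (med, q1, q3) == (3.0, 2.0, 4.0)

    def test_single_value_collapses(self):
        assert summarize_median_iqr([7.5]) == (7.5, 7.5, 7.5)

    def test_matches_sort_and_interpolate_oracle(self, rng):
        for n in (2, 5, 10, 33):
            x = rng.normal(size=n)
            got = summarize_median_iqr(x)
            want = median_iqr_oracle(x)
            assert got == pytest.approx(want, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_median_iqr([])


def make_record(pattern, u=0, b=0, m=0, ub=0, bb=0, mb=0, n_cells=10, extra_neurites=0, **kw):
    n_with = u + b + m
    n_neur = u + 2 * b + 3 * m + extra_neurites
    return ScreeningRecord(
        image_id=kw.get("image_id", "img"),
        pattern_name=pattern,
        n_cells=n_cells,
        n_cells_with_neurites=n_with,
        n_neurites=n_neur,
        mean_neurite_length_um=kw.get("mean_len", 30.0),
        n_unipolar=u, n_bipolar=b, n_multipolar=m,
        n_unipolar_branched=ub, n_bipolar_branched=bb, n_multipolar_branched=mb,
        alignment_vesselness=kw.get("ves", 40.0),
        alignment_fft=kw.get("fft", 38.0),
        alignment_chord=kw.get("chord", 42.0),
    )


class TestDeriveScreeningVariables:
    def test_polarity_ratios(self):
        recs = [make_record("D450L180", u=4, b=1, m=0)]
        out, _qc = derive_screening_variables(recs)
        assert out["b_u_ratio"].groups["D450L180"][0] == pytest.approx(0.25)
        assert out["m_u_ratio"].groups["D450L180"][0] == pytest.approx(0.0)

    def test_zero_unipolar_ratio_missing_not_infinite(self):
        recs = [make_record("FLAT_PS", u=0, b=2, m=1), make_record("FLAT_PS", u=2, b=1, m=0)]
        out, qc = derive_screening_variables(recs)
        # the undefined image is dropped, not propagated as inf
        assert len(out["b_u_ratio"].groups["FLAT_PS"]) == 1
        assert qc["missing_values"]["b_u_ratio"] == 1

    def test_differentiated_fraction(self):
        recs = [make_record("D200L100", u=2, b=1, m=1, n_cells=10)]
        out, _ = derive_screening_variables(recs)
        assert out["differentiated_fraction"].groups["D200L100"][0] == pytest.approx(0.4)

    def test_image_without_cells_excluded_and_logged(self):
        rec = make_record("FLAT_PDMS", n_cells=0, u=0, b=0, m=0, mean_len=float("nan"))
        out, qc = derive_screening_variables([rec])
        assert qc["excluded_images_no_cells"] == 1
        assert out == {}

    def test_grouped_variable_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            GroupedVariable("x", {"a": np.array([1.0, np.inf])})


class TestRunStats:
    def test_null_battery_keeps_type_one_error_in_check(self, rng):
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            groups = [rng.standard_normal(10) for _ in range(3)]
            _h, p = kruskal_wallis(groups)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_sim <= 0.08

    def test_reports_cover_multigroup_variables(self, rng):
        recs = [
            make_record("D450L180", u=3, b=2, m=1, image_id=f"a{i}",
                        ves=70 + rng.normal(), mean_len=40 + rng.normal())
            for i in range(6)
        ] + [
            make_record("FLAT_PDMS", u=4, b=1, m=0, image_id=f"b{i}",
                        ves=33 + rng.normal(), mean_len=30 + rng.normal())
            for i in range(6)
        ]
        variables, _qc = derive_screening_variables(recs)
        reports = run_stats(variables)
        by_name = {r.variable: r for r in reports}
        assert "alignment_vesselness" in by_name
        rep = by_name["alignment_vesselness"]
        assert rep.kruskal_p < 0.01  # 37-point separation must be detected
        assert set(rep.median_iqr) == {"D450L180", "FLAT_PDMS"}
        assert rep.to_text().startswith("== alignment_vesselness ==")

    def test_stats_layer_adds_no_spurious_correlation(self, rng):
        # independent variables on a null battery stay uncorrelated
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        r, _ = spearman(x, y)
        assert abs(r) < 0.2
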