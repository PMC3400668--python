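"""Correlations, factorial ANOVA (incl. missing cell) and Duncan letters."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from swimkit import duncan_letters, factorial_anova, p_from_r, pearson_with_p
from swimkit.errors import (
    DegenerateInputError,
    InestimableTermError,
    InsufficientDataError,
)
from swimkit.stats import _duncan_lsr


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = pearson_with_p(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_printed_population_level_anchor(self):
        # Ucrit-Vmax across the five sites: r = 0.367, n = 5
        assert p_from_r(0.367, 5) == pytest.approx(0.544, abs=1e-3)

    def test_p_symmetric_in_sign(self):
        assert p_from_r(0.42, 12) == p_from_r(-0.42, 12)

    def test_null_r_gives_p_one(self):
        assert p_from_r(0.0, 30) == pytest.approx(1.0)

    def test_matches_scipy_pearsonr(self, rng):
        x = rng.normal(size=25)
        y = 0.4 * x + rng.normal(size=25)
        res = pearson_with_p(x, y)
        ref_r, ref_p = sps.pearsonr(x, y)
        assert res.r == pytest.approx(ref_r, abs=1e-12)
        assert res.p == pytest.approx(ref_p, abs=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        res1 = pearson_with_p(x, y)
        res2 = pearson_with_p(3.0 * x + 7.0, 0.5 * y - 2.0)
        assert res2.r == pytest.approx(res1.r, abs=1e-12)
        assert res2.p == pytest.approx(res1.p, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_with_p(np.ones(5), np.arange(5.0))


def balanced_two_way_oracle(df):
    """Closed-form balanced 2x2 ANOVA decomposition."""
    grand = df.y.mean()
    ss_a = sum(len(g) * (g.y.mean() - grand) ** 2 for _, g in df.groupby("A"))
    ss_b = sum(len(g) * (g.y.mean() - grand) ** 2 for _, g in df.groupby("B"))
    ss_cells = sum(len(g) * (g.y.mean() - grand) ** 2 for _, g in df.groupby(["A", "B"]))
    ss_ab = ss_cells - ss_a - ss_b
    sse = sum(((g.y - g.y.mean()) ** 2).sum() for _, g in df.groupby(["A", "B"]))
    df_res = len(df) - df.A.nunique() * df.B.nunique()
    mse = sse / df_res
    return {"A": ss_a, "B": ss_b, "A:B": ss_ab}, mse, df_res


class TestFactorialAnova:
    def _balanced(self, rng, effects=(1.0, 0.5, 0.0), n=6):
        rows = []
        for a in [-1, 1]:
            for b in [-1, 1]:
                mu = effects[0] * a + effects[1] * b + effects[2] * a * b
                for _ in range(n):
                    rows.append(dict(A=f"a{a}", B=f"b{b}", y=mu + rng.normal()))
        return pd.DataFrame(rows)

    def test_balanced_design_matches_closed_form_oracle(self, rng):
        df = self._balanced(rng)
        res = factorial_anova(df, "y", ["A", "B"])
        ss_oracle, mse, df_res = balanced_two_way_oracle(df)
        assert res.residual_df == df_res
        for term, ss in ss_oracle.items():
            row = res.table.loc[term]
            assert row["ss"] == pytest.approx(ss, rel=1e-9)
            assert row["F"] == pytest.approx((ss / 1) / mse, rel=1e-9)
            assert row["p"] == pytest.approx(float(sps.f.sf(ss / mse, 1, df_res)), abs=1e-12)

    def test_constant_response_gives_zero_f_unit_p(self, rng):
        df = self._balanced(rng)
        df["y"] = 5.0
        res = factorial_anova(df, "y", ["A", "B"])
        assert (res.table["F"] == 0).all()
        assert (res.table["p"] == 1).all()

    def test_invariant_to_level_relabelling(self, rng):
        df = self._balanced(rng)
        res1 = factorial_anova(df, "y", ["A", "B"])
        relabel = df.assign(A=df.A.map({"a-1": "zebra", "a1": "ant"}))
        res2 = factorial_anova(relabel, "y", ["A", "B"])
        np.testing.assert_allclose(res1.table["ss"], res2.table["ss"], rtol=1e-9)

    def test_missing_cell_drops_one_interaction_contrast(self, rng):
        rows = []
        cells = [("lower", "main"), ("lower", "tributary"), ("middle", "main"),
                 ("middle", "tributary"), ("upper", "main")]
        for reach, stream in cells:
            for _ in range(6):
                rows.append(dict(reach=reach, stream=stream, y=rng.normal()))
        res = factorial_anova(pd.DataFrame(rows), "y", ["reach", "stream"])
        assert len(res.dropped_contrasts) == 1
        assert res.dropped_contrasts[0].startswith("reach:stream")
        assert res.table.loc["reach:stream", "df"] == 1  # 2 contrasts - 1 inestimable
        assert res.table.loc["reach", "df"] == 2
        assert res.table.loc["stream", "df"] == 1

    def test_fully_inestimable_term_raises_naming_missing_cell(self, rng):
        # only diagonal cells observed: interaction completely aliased
        rows = []
        for lev, (a, b) in enumerate([("a1", "b1"), ("a2", "b2")]):
            for _ in range(5):
                rows.append(dict(A=a, B=b, y=rng.normal() + lev))
        with pytest.raises(InestimableTermError, match="missing cells"):
            factorial_anova(pd.DataFrame(rows), "y", ["A", "B"])

    def test_three_way_terms_present(self, rng):
        rows = []
        for a, b, c in itertools.product("xy", "uv", "pq"):
            for _ in range(3):
                rows.append(dict(A=a, B=b, C=c, y=rng.normal()))
        res = factorial_anova(pd.DataFrame(rows), "y", ["A", "B", "C"])
        assert set(res.table.index) == {"A", "B", "C", "A:B", "A:C", "B:C", "A:B:C"}

    def test_type_one_error_calibrated(self, rng):
        hits = {"A": 0, "B": 0, "A:B": 0}
        n_rep = 300
        for _ in range(n_rep):
            df = self._balanced(rng, effects=(0, 0, 0), n=5)
            res = factorial_anova(df, "y", ["A", "B"])
            for term in hits:
                hits[term] += res.table.loc[term, "p"] < 0.05
        for term, h in hits.items():
            assert 0.02 <= h / n_rep <= 0.08, term


def duncan_oracle(groups, values, alpha=0.05):
    """Exhaustive ranked-pair oracle: every stretch tested against its own
    least significant range, with the containment protection rule applied by
    explicit recursion over all stretches."""
    s = pd.Series(np.asarray(values, float), index=list(groups))
    means = s.groupby(level=0).mean().sort_values(ascending=False)
    counts = s.groupby(level=0).count()
    k = len(means)
    df_res = int(counts.sum()) - k
    mse = float(((s - s.groupby(level=0).transform("mean")) ** 2).sum()) / df_res
    n_h = k / float((1.0 / counts).sum())
    m = means.to_numpy()

    import functools

    @functools.lru_cache(maxsize=None)
    def nonsig(i, j):
        if i == j:
            return True
        span = j - i + 1
        if m[i] - m[j] <= _duncan_lsr(span, df_res, mse, n_h, alpha):
            return True
        # protected if any strictly containing stretch is non-significant
        return any(
            nonsig(a, b)
            for a in range(0, i + 1)
            for b in range(j, k)
            if (a, b) != (i, j)
        )

    # maximal non-significant stretches -> letter partition
    stretches = [(i, j) for i in range(k) for j in range(i, k) if nonsig(i, j)]
    maximal = [
        (a, b) for a, b in stretches
        if not any(c <= a and b <= d and (c, d) != (a, b) for c, d in stretches)
    ]
    maximal.sort()
    letters = {g: "" for g in means.index}
    for idx, (a, b) in enumerate(maximal):
        for pos in range(a, b + 1):
            letters[means.index[pos]] += "abcdefghijklmnopqrstuvwxyz"[idx]
    return letters


class TestDuncan:
    def test_identical_groups_share_a_single_letter(self):
        g = ["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3
        v = [5.0, 5.0, 5.0] * 3
        res = duncan_letters(g, v)
        assert all(lett == "a" for lett in res.letters.values())

    def test_widely_separated_groups_get_distinct_letters(self, rng):
        g = ["lo"] * 5 + ["hi"] * 5
        v = np.concatenate([rng.normal(0, 0.1, 5), rng.normal(50, 0.1, 5)])
        res = duncan_letters(g, v)
        assert res.letters["hi"] == "a"
        assert res.letters["lo"] == "b"

    def test_letters_form_contiguous_staircase(self, rng):
        for seed in range(20):
            r = np.random.default_rng(seed)
            g = np.repeat([f"g{i}" for i in range(5)], 6)
            v = r.normal(np.repeat(r.uniform(0, 3, 5), 6), 1.0)
            res = duncan_letters(g, v)
            ordered = [res.letters[grp] for grp in res.means.index]
            for letter in set("".join(ordered)):
                where = [i for i, ls in enumerate(ordered) if letter in ls]
                assert where == list(range(min(where), max(where) + 1))

    def test_matches_exhaustive_ranked_pair_oracle(self):
        mismatches = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            g = np.repeat([f"g{i}" for i in range(5)], 5)
            v = r.normal(np.repeat(r.uniform(0, 4, 5), 5), 1.0)
            ours = duncan_letters(g, v).letters
            oracle = duncan_oracle(g, v)
            if ours != oracle:
                mismatches += 1
        assert mismatches == 0

    def test_group_with_single_observation_rejected(self):
        with pytest.raises(InsufficientDataError):
            duncan_letters(["a", "a", "b"], [1.0, 2.0, 3.0])

    def test_duncan_level_increases_with_span(self):
        # the span-p comparison runs at 1-(1-alpha)^(p-1), so ranges widen
        lsrs = [_duncan_lsr(p, 20, 1.0, 5.0, 0.05) for p in range(2, 6)]
        assert all(b > a for a, b in zip(lsrs, lsrs[1:]))
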