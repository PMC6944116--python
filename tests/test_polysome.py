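"""Moderated statistics and candidate-selection rules.

The empirical-Bayes machinery is checked gene-by-gene against an
independently coded scalar implementation of the variance shrinkage and
log-odds formulas, plus analytic limits (no shrinkage -> ordinary t).
Set-level operations are checked against brute-force comprehensions.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.optimize import brentq
from scipy.special import digamma, polygamma

from uvg2.polysome import (
    classify_regulation,
    intersect_platforms,
    log_cpm,
    moderated_stats,
    select_differential,
    squeeze_variances,
    subtract_g2,
)

from conftest import make_dataset


# ---------------------------------------------------------------------------
# Independent scalar oracle: plain-float recoding of the moderated model
# ---------------------------------------------------------------------------

def oracle_moderated(xa_rows, xb_rows, proportion):
    """Scalar (per-gene loop, python floats) moderated t and B."""
    n1, n2 = len(xa_rows[0]), len(xb_rows[0])
    d = n1 + n2 - 2
    logfc, s2 = [], []
    for ra, rb in zip(xa_rows, xb_rows):
        ma = sum(ra) / n1
        mb = sum(rb) / n2
        logfc.append(ma - mb)
        ss = sum((v - ma) ** 2 for v in ra) + sum((v - mb) ** 2 for v in rb)
        s2.append(ss / d)
    # prior estimation by moment matching of log variances
    z = [math.log(v) for v in s2 if v > 0]
    e = [zi - float(digamma(d / 2)) + math.log(d / 2) for zi in z]
    emean = sum(e) / len(e)
    evar = sum((ei - emean) ** 2 for ei in e) / (len(e) - 1) - float(
        polygamma(1, d / 2)
    )
    if evar > 0:
        d0 = 2.0 * brentq(
            lambda x: float(polygamma(1, x)) - evar, 1e-6, 1e8, xtol=1e-12
        )
        s0 = math.exp(emean + float(digamma(d0 / 2)) - math.log(d0 / 2))
    else:
        d0 = float("inf")
        s0 = math.exp(emean)
    v_g = 1.0 / n1 + 1.0 / n2
    tmod, s2post = [], []
    for fc, v in zip(logfc, s2):
        sp = s0 if math.isinf(d0) else (d0 * s0 + d * v) / (d0 + d)
        s2post.append(sp)
        tmod.append(fc / math.sqrt(sp * v_g))
    nu = d0 + d
    null_m2 = nu / (nu - 2.0) if (not math.isinf(nu) and nu > 2) else 1.0
    m2 = sum(ti**2 for ti in tmod) / len(tmod)
    v0 = max(v_g * (m2 / null_m2 - 1.0) / proportion, 0.0)
    r = v_g / (v_g + v0)
    bs = []
    for ti in tmod:
        base = math.log(proportion / (1 - proportion)) + 0.5 * math.log(r)
        if math.isinf(nu):
            bs.append(base + ti**2 * (1 - r) / 2.0)
        else:
            bs.append(
                base
                + (nu + 1.0) / 2.0 * math.log((ti**2 + nu) / (ti**2 * r + nu))
            )
    return logfc, tmod, bs


class TestModeratedStats:
    def test_matches_scalar_oracle(self):
        """50-gene fixture: vectorized path equals the scalar recoding of the
        shrinkage and log-odds formulas to 1e-8."""
        ds = make_dataset(n_genes=50, seed=3)
        res = moderated_stats(ds, ("UVG2", "AS", "polysome"), prior_de_proportion=0.01)
        frame = ds.to_frame()
        xa = frame[ds.samples_for("UVG2", "polysome")].to_numpy()
        xb = frame[ds.samples_for("AS", "polysome")].to_numpy()
        logfc, tmod, bs = oracle_moderated(xa.tolist(), xb.tolist(), 0.01)
        np.testing.assert_allclose(res["log2fc"], logfc, atol=1e-8)
        np.testing.assert_allclose(res["t"], tmod, atol=1e-8)
        np.testing.assert_allclose(res["B"], bs, atol=1e-8)

    def test_rnaseq_uses_log_cpm(self):
        ds = make_dataset(n_genes=40, seed=5, platform="rnaseq")
        res = moderated_stats(ds, ("UVG2", "AS", "polysome"))
        counts = ds.to_frame()
        lc = pd.DataFrame(
            log_cpm(counts.to_numpy()), index=counts.index, columns=counts.columns
        )
        a = lc[ds.samples_for("UVG2", "polysome")].mean(axis=1)
        b = lc[ds.samples_for("AS", "polysome")].mean(axis=1)
        np.testing.assert_allclose(res["log2fc"], a - b, atol=1e-10)

    def test_identical_groups_zero(self):
        ds = make_dataset(n_genes=10, seed=1, noise_sd=0.3)
        frame = ds.to_frame()
        # copy AS values into UVG2 so the two groups are identical
        for sa, su in zip(
            ds.samples_for("AS", "polysome"), ds.samples_for("UVG2", "polysome")
        ):
            frame[su] = frame[sa]
        ds2 = make_dataset(n_genes=10, seed=1)
        ds2.values = frame.to_numpy()
        res = moderated_stats(ds2, ("UVG2", "AS", "polysome"))
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["t"], 0.0, atol=1e-12)

    def test_no_shrinkage_limit_is_ordinary_t(self):
        """With prior df 0 the posterior variance is the sample variance and
        the moderated t collapses to the equal-variance two-sample t."""
        rng = np.random.default_rng(2)
        xa = rng.normal(0, 1, (30, 4))
        xb = rng.normal(0.5, 1, (30, 4))
        d = 6
        s2 = (
            ((xa - xa.mean(1, keepdims=True)) ** 2).sum(1)
            + ((xb - xb.mean(1, keepdims=True)) ** 2).sum(1)
        ) / d
        s2_post = squeeze_variances(s2, d, 0.0, 123.4)  # prior variance irrelevant
        tmod = (xa.mean(1) - xb.mean(1)) / np.sqrt(s2_post * (0.25 + 0.25))
        t_ref = sps.ttest_ind(xa, xb, axis=1, equal_var=True).statistic
        np.testing.assert_allclose(tmod, t_ref, atol=1e-10)

    def test_sign_consistency_and_finite_B(self):
        ds = make_dataset(n_genes=60, seed=9)
        res = moderated_stats(ds, ("UVG2", "AS", "total"))
        assert np.all(np.isfinite(res["B"]))
        nz = res["log2fc"] != 0
        assert np.all(np.sign(res["t"][nz]) == np.sign(res["log2fc"][nz]))

    def test_too_few_replicates_raises(self):
        ds = make_dataset(n_rep=2)
        keep = [s for s in ds.sample_ids if s != "UVG2_polysome_r2"]
        sub = ds.to_frame()[keep]
        ds2 = make_dataset(n_rep=2)
        ds2.gene_ids = list(sub.index)
        ds2.sample_ids = keep
        ds2.values = sub.to_numpy()
        with pytest.raises(ValueError, match="replicates"):
            moderated_stats(ds2, ("UVG2", "AS", "polysome"))


class TestSelection:
    def test_empty_stats(self):
        assert select_differential(pd.DataFrame(columns=["log2fc", "B"])) == set()

    def test_forced_example(self):
        stats = pd.DataFrame(
            {
                "log2fc": [np.log2(2.5), np.log2(3.0), np.log2(1.5)],
                "B": [1.2, -0.5, 2.0],
            },
            index=["g1", "g2", "g3"],
        )
        assert select_differential(stats, 2.0, 0.0) == {"g1"}

    @given(
        st.lists(
            st.tuples(
                st.floats(-4, 4, allow_nan=False), st.floats(-5, 5, allow_nan=False)
            ),
            min_size=0,
            max_size=30,
        ),
        st.floats(1.0, 4.0),
        st.floats(-1.0, 2.0),
        st.floats(0.0, 2.0),
        st.floats(0.0, 2.0),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_monotone_in_cutoffs(self, rows, fc, b, dfc, db):
        """Raising either cutoff never adds genes."""
        stats = pd.DataFrame(
            rows, columns=["log2fc", "B"], index=[f"g{i}" for i in range(len(rows))]
        )
        loose = select_differential(stats, fc, b)
        tight = select_differential(stats, fc + dfc, b + db)
        assert tight <= loose

    def test_subtract_g2_disjoint_and_forced(self):
        uv_stats = pd.DataFrame({"log2fc": [2.1, 1.5]}, index=["a", "b"])
        g2_stats = pd.DataFrame({"log2fc": [2.0, -1.4]}, index=["a", "b"])
        # disjoint lists: unchanged
        assert subtract_g2({"a"}, uv_stats, {"b"}, g2_stats, 1.0) == {"a"}
        # same sign, difference 0.1 < 1.0: removed
        assert subtract_g2({"a"}, uv_stats, {"a"}, g2_stats, 1.0) == set()
        # opposite sign never removed
        assert subtract_g2({"b"}, uv_stats, {"b"}, g2_stats, 10.0) == {"b"}

    def test_subtract_g2_missing_stats_raises(self):
        empty = pd.DataFrame(columns=["log2fc"])
        with pytest.raises(ValueError, match="missing"):
            subtract_g2({"a"}, empty, set(), empty, 1.0)

    def test_subtract_g2_brute_force(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(200)]
        uv = pd.DataFrame({"log2fc": rng.normal(0, 2, 200)}, index=genes)
        g2 = pd.DataFrame({"log2fc": rng.normal(0, 2, 200)}, index=genes)
        uv_set = set(rng.choice(genes, 80, replace=False))
        g2_set = set(rng.choice(genes, 60, replace=False))
        got = subtract_g2(uv_set, uv, g2_set, g2, 1.0)
        expected = {
            g
            for g in uv_set
            if not (
                g in g2_set
                and np.sign(uv.at[g, "log2fc"]) == np.sign(g2.at[g, "log2fc"])
                and abs(uv.at[g, "log2fc"] - g2.at[g, "log2fc"]) < 1.0
            )
        }
        assert got == expected

    def test_intersect_platforms(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(1000)]
        rs = set(rng.choice(genes, 50, replace=False))
        ma = set(rng.choice(genes, 200, replace=False)) | rs
        inter, containment = intersect_platforms(ma, rs)
        assert inter == rs and containment == 1.0
        inter, containment = intersect_platforms({"a"}, {"b"})
        assert inter == set() and containment == 0.0
        ma2 = set(rng.choice(genes, 200, replace=False))
        inter, containment = intersect_platforms(ma2, rs)
        assert inter == (ma2 & rs)
        assert containment == len(ma2 & rs) / len(rs)


class TestClassifyRegulation:
    def _stats(self, rows):
        return pd.DataFrame(rows, columns=["log2fc", "B"], index=[f"g{i}" for i in range(len(rows))])

    def test_forced_translational_only(self):
        total = self._stats([[np.log2(1.1), -1.0]])
        poly = self._stats([[np.log2(3.0), 2.0]])
        classes, summary = classify_regulation(total, poly)
        assert classes["g0"] == "translational-only"
        assert summary["fraction_polysome_not_total"] == 1.0

    def test_all_pass_both(self):
        both = self._stats([[2.0, 1.0], [-2.0, 3.0]])
        classes, summary = classify_regulation(both, both)
        assert (classes == "both").all()
        assert summary["fraction_polysome_not_total"] == 0.0
        assert summary["fraction_total_not_polysome"] == 0.0

    def test_universe_mismatch_raises(self):
        with pytest.raises(ValueError, match="universe"):
            classify_regulation(self._stats([[1, 1]]), self._stats([[1, 1], [1, 1]]))

    def test_pipeline_equals_brute_force_filter(self):
        """select -> subtract -> intersect equals one brute-force filter."""
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(300)]

        def rand_stats():
            return pd.DataFrame(
                {"log2fc": rng.normal(0, 1.5, 300), "B": rng.normal(0, 2, 300)},
                index=genes,
            )

        uv_ma, g2_ma, uv_rs, g2_rs = (rand_stats() for _ in range(4))
        sel = lambda s: select_differential(s, 2.0, 0.0)
        got, _ = intersect_platforms(
            subtract_g2(sel(uv_ma), uv_ma, sel(g2_ma), g2_ma, 1.0),
            subtract_g2(sel(uv_rs), uv_rs, sel(g2_rs), g2_rs, 1.0),
        )

        def brute(uv, g2):
            out = set()
            for g in genes:
                pass_uv = abs(uv.at[g, "log2fc"]) >= 1.0 and uv.at[g, "B"] > 0
                pass_g2 = abs(g2.at[g, "log2fc"]) >= 1.0 and g2.at[g, "B"] > 0
                if not pass_uv:
                    continue
                if (
                    pass_g2
                    and np.sign(uv.at[g, "log2fc"]) == np.sign(g2.at[g, "log2fc"])
                    and abs(uv.at[g, "log2fc"] - g2.at[g, "log2fc"]) < 1.0
                ):
                    continue
                out.add(g)
            return out

        assert got == (brute(uv_ma, g2_ma) & brute(uv_rs, g2_rs))
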