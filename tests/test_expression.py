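"""TMM normalization, CPM filtering and the Welch t-test DE rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncreg.expression import (
    CountMatrix,
    cpm,
    de_ttest,
    expressed_filter,
    tmm_factors,
)


def make_cm(values, groups=None, tissue="liver"):
    values = pd.DataFrame(
        values,
        index=[f"T{i}" for i in range(values.shape[0])],
        columns=[f"S{j}" for j in range(values.shape[1])],
    )
    n = values.shape[1]
    if groups is None:
        groups = ["highFE"] * (n // 2) + ["lowFE"] * (n - n // 2)
    meta = pd.DataFrame({"tissue": tissue, "group": groups}, index=values.columns)
    return CountMatrix(values, meta)


def tmm_oracle(x, ref_idx, logratio_trim=0.3, sum_trim=0.05):
    """Independent direct-formula TMM implementation (loops, no shortcuts)."""
    lib = x.sum(axis=0)
    factors = []
    for j in range(x.shape[1]):
        obs, ref = x[:, j].astype(float), x[:, ref_idx].astype(float)
        keep = (obs > 0) & (ref > 0)
        obs, ref = obs[keep], ref[keep]
        m = np.log2((obs / lib[j]) / (ref / lib[ref_idx]))
        a = 0.5 * np.log2((obs / lib[j]) * (ref / lib[ref_idx]))
        w = (lib[j] - obs) / (lib[j] * obs) + (lib[ref_idx] - ref) / (
            lib[ref_idx] * ref
        )
        n = len(m)
        if n == 0 or np.max(np.abs(m)) < 1e-6:
            factors.append(1.0)
            continue
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
        rm, ra = stats.rankdata(m), stats.rankdata(a)
        sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        f = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
        factors.append(2.0**f)
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


def test_cpm_rejects_nonpositive_factors():
    cm = make_cm(np.full((3, 2), 10))
    with pytest.raises(ValueError):
        cpm(cm, pd.Series([1.0, -1.0], index=cm.values.columns))


def test_count_matrix_validation():
    with pytest.raises(ValueError):
        make_cm(np.array([[0, 5], [0, 5]]))  # first library empty
    with pytest.raises(ValueError):
        make_cm(np.array([[-1, 5], [2, 5]]))


def test_cpm_value_and_column_sums():
    rng = np.random.default_rng(0)
    cm = make_cm(rng.integers(1, 1000, size=(50, 6)))
    c = cpm(cm)
    assert np.allclose(c.sum(axis=0), 1e6)
    j = cm.values.columns[0]
    assert c.loc["T0", j] == pytest.approx(
        cm.values.loc["T0", j] / cm.lib_size[j] * 1e6
    )


def test_cpm_scale_invariance_under_library_doubling():
    rng = np.random.default_rng(1)
    x = rng.negative_binomial(5, 0.01, size=(300, 6))
    cm1 = make_cm(x)
    x2 = x.copy()
    x2[:, 0] *= 2
    cm2 = make_cm(x2)
    c1 = cpm(cm1, tmm_factors(cm1))
    c2 = cpm(cm2, tmm_factors(cm2))
    ratio = (c2.iloc[:, 0] / c1.iloc[:, 0]).replace([np.inf], np.nan).dropna()
    # depth cancels exactly; the TMM precision weights shift by well under 1%
    assert np.allclose(ratio, 1.0, rtol=0.02)


def test_tmm_identical_columns_give_unit_factors():
    col = np.arange(1, 101)
    cm = make_cm(np.tile(col[:, None], (1, 4)))
    assert np.allclose(tmm_factors(cm), 1.0)


def test_tmm_constant_m_gives_closed_form_factor():
    """If every shared transcript has M = -1 the factor ratio is exactly 1/2.

    Construction: the test sample doubles every shared count and carries a
    private ballast transcript sized so its library is 4x the reference;
    then M = log2((2x/4N)/(x/N)) = -1 for every shared transcript, and the
    trimmed weighted mean of a constant is that constant.
    """
    rng = np.random.default_rng(2)
    base = rng.negative_binomial(10, 0.01, size=400) + 1
    n_ref = base.sum()
    x = np.zeros((401, 2), dtype=int)
    x[:400, 0] = base
    x[:400, 1] = base * 2
    x[400, 1] = 2 * n_ref  # ballast: zero in the reference sample
    f = tmm_factors(make_cm(x))
    assert f.iloc[1] / f.iloc[0] == pytest.approx(0.5, rel=1e-9)


def test_tmm_uniform_depth_change_is_a_no_op():
    """Doubling every count of one sample changes composition not at all."""
    rng = np.random.default_rng(12)
    base = rng.negative_binomial(10, 0.01, size=400)
    x = np.tile(base[:, None], (1, 4))
    x[:, 3] = base * 2
    f = tmm_factors(make_cm(x))
    assert np.allclose(f, 1.0)


def test_tmm_matches_direct_formula_oracle():
    rng = np.random.default_rng(3)
    x = rng.negative_binomial(5, 0.01, size=(500, 8))
    x[:, 2] = (x[:, 2] * 3.1).astype(int)
    cm = make_cm(x)
    mine = tmm_factors(cm).to_numpy()
    lib = x.sum(axis=0)
    uq = np.array(
        [np.quantile(x[:, j][x[:, j] > 0] / lib[j], 0.75) for j in range(8)]
    )
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    oracle = tmm_oracle(x, ref_idx)
    assert np.allclose(mine, oracle, atol=1e-8)


def test_tmm_invariant_to_transcript_order():
    rng = np.random.default_rng(4)
    x = rng.negative_binomial(5, 0.02, size=(200, 5))
    cm = make_cm(x)
    perm = rng.permutation(200)
    cm_perm = CountMatrix(cm.values.iloc[perm], cm.sample_meta)
    assert np.allclose(tmm_factors(cm), tmm_factors(cm_perm))


def test_tmm_geometric_mean_is_one():
    rng = np.random.default_rng(5)
    cm = make_cm(rng.negative_binomial(5, 0.01, size=(300, 7)))
    f = tmm_factors(cm)
    assert np.prod(f) ** (1 / len(f)) == pytest.approx(1.0, abs=1e-12)


def test_expressed_filter_boundary_and_monotonicity():
    n = 18
    x = np.zeros((3, n), dtype=int)
    x[0, :] = 1000  # always expressed
    x[1, :9] = 1000  # exactly half the samples
    cm = make_cm(x, groups=["highFE"] * 9 + ["lowFE"] * 9)
    kept = expressed_filter(cm)["liver"]
    assert kept == {"T0", "T1"}  # all-zero T2 dropped, boundary T1 kept
    stricter = expressed_filter(cm, min_cpm=1e9)["liver"]
    assert stricter <= kept


def test_expressed_filter_recovers_planted_tissue_profiles(small_study):
    from lncreg.expression import tmm_factors

    truth = small_study.truth
    for tissue, cm in small_study.counts.items():
        kept = expressed_filter(cm, tmm_factors(cm))[tissue]
        for tid, tissues_on in truth.tissue_profile.items():
            assert (tid in kept) == (tissue in tissues_on), (tid, tissue)


def test_de_identical_groups_p_is_one():
    rng = np.random.default_rng(6)
    half = rng.negative_binomial(5, 0.01, size=(100, 4))
    x = np.concatenate([half, half], axis=1)  # lowFE columns copy highFE
    cm = make_cm(x, groups=["highFE"] * 4 + ["lowFE"] * 4)
    res = de_ttest(cm)
    assert np.allclose(res["p"], 1.0)
    assert not res["de_flag"].any()


def test_de_type_one_error_rate_under_null():
    """Rejection rate at p<0.01 is ~1% over 2000 null transcripts."""
    rng = np.random.default_rng(7)
    x = rng.negative_binomial(20, 0.02, size=(2000, 18))
    cm = make_cm(x, groups=["highFE"] * 9 + ["lowFE"] * 9)
    res = de_ttest(cm)
    rate = res["de_flag"].mean()
    sd = np.sqrt(0.01 * 0.99 / 2000)
    assert abs(rate - 0.01) < 3 * sd + 1e-9


def test_de_power_at_planted_effect():
    """|log2FC| = 2 at n = 9 vs 9 and moderate dispersion: power > 0.8."""
    rng = np.random.default_rng(8)
    n, fc = 9, 4.0
    mean_a, disp = 100.0, 0.1
    r = 1 / disp
    n_de, n_null = 200, 1800
    null = rng.negative_binomial(r, r / (r + mean_a), size=(n_null, 2 * n))
    a = rng.negative_binomial(r, r / (r + mean_a), size=(n_de, n))
    b = rng.negative_binomial(r, r / (r + mean_a * fc), size=(n_de, n))
    x = np.vstack([np.concatenate([a, b], axis=1), null])
    cm = make_cm(x, groups=["highFE"] * n + ["lowFE"] * n)
    res = de_ttest(cm)
    power = res["de_flag"].iloc[:n_de].mean()
    assert power > 0.8


def test_de_requires_two_samples_per_group():
    x = np.ones((5, 3), dtype=int) * 10
    cm = make_cm(x, groups=["highFE", "lowFE", "lowFE"])
    with pytest.raises(ValueError):
        de_ttest(cm)
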