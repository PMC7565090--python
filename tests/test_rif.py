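"""Regulatory Impact Factor scoring: manual oracle, symmetry, recovery."""

import numpy as np
import pandas as pd
import pytest

from lncreg.expression import cpm, tmm_factors
from lncreg.rif import rif_scores
from lncreg.simulate import SimulationConfig, generate_counts


def frame(data, samples):
    return pd.DataFrame(data, columns=samples)


def test_identical_conditions_zero_rif1():
    rng = np.random.default_rng(0)
    x = pd.DataFrame(
        rng.standard_normal((10, 6)) + 8,
        index=[f"R{i}" for i in range(4)] + [f"T{i}" for i in range(6)],
    )
    res = rif_scores(x, x.copy(), [f"R{i}" for i in range(4)], [f"T{i}" for i in range(6)])
    assert np.allclose(res["rif1_raw"], 0.0)
    assert np.allclose(res["rif2_raw"], 0.0)
    assert not res["key_flag"].any()


def test_manual_two_regulator_oracle():
    """Spreadsheet-style evaluation of the formulas on a 2x2x4 case."""
    idx = ["r1", "r2", "t1", "t2"]
    a = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [4.0, 3.0, 2.0, 1.0],
         [1.5, 2.1, 2.9, 4.2],
         [2.0, 2.0, 3.0, 3.0]],
        index=idx,
    )
    b = pd.DataFrame(
        [[2.0, 1.0, 4.0, 3.0],
         [1.0, 1.5, 2.0, 2.5],
         [3.0, 1.0, 1.0, 3.0],
         [5.0, 4.0, 3.0, 2.0]],
        index=idx,
    )
    res = rif_scores(a, b, ["r1", "r2"], ["t1", "t2"]).set_index("regulator")

    def pearson(u, v):
        return np.corrcoef(u, v)[0, 1]

    rif1_manual, rif2_manual = {}, {}
    for reg in ("r1", "r2"):
        acc1 = acc2 = 0.0
        for tgt in ("t1", "t2"):
            e1, e2 = a.loc[tgt].mean(), b.loc[tgt].mean()
            pif = 0.5 * (e1 + e2) * (e1 - e2)
            r1 = pearson(a.loc[reg], a.loc[tgt])
            r2 = pearson(b.loc[reg], b.loc[tgt])
            acc1 += pif * (r1 - r2) ** 2
            acc2 += (e1 * r1) ** 2 - (e2 * r2) ** 2
        rif1_manual[reg] = acc1 / 2
        rif2_manual[reg] = acc2 / 2
    for reg in ("r1", "r2"):
        assert res.loc[reg, "rif1_raw"] == pytest.approx(rif1_manual[reg])
        assert res.loc[reg, "rif2_raw"] == pytest.approx(rif2_manual[reg])


def test_zscores_standardized_across_regulators():
    rng = np.random.default_rng(1)
    idx = [f"r{i}" for i in range(20)] + [f"t{i}" for i in range(5)]
    a = pd.DataFrame(rng.standard_normal((25, 8)) + 6, index=idx)
    b = pd.DataFrame(rng.standard_normal((25, 8)) + 6, index=idx)
    res = rif_scores(a, b, idx[:20], idx[20:])
    assert res["rif1_z"].mean() == pytest.approx(0.0, abs=1e-12)
    assert res["rif1_z"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)
    assert res["rif2_z"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)


def test_rif2_sign_flips_when_conditions_swap():
    rng = np.random.default_rng(2)
    idx = [f"r{i}" for i in range(6)] + [f"t{i}" for i in range(4)]
    a = pd.DataFrame(rng.standard_normal((10, 7)) + 5, index=idx)
    b = pd.DataFrame(rng.standard_normal((10, 7)) + 5, index=idx)
    fwd = rif_scores(a, b, idx[:6], idx[6:])
    rev = rif_scores(b, a, idx[:6], idx[6:])
    assert np.allclose(fwd["rif2_raw"], -rev["rif2_raw"])


def test_invariant_under_target_order():
    rng = np.random.default_rng(3)
    idx = [f"r{i}" for i in range(5)] + [f"t{i}" for i in range(6)]
    a = pd.DataFrame(rng.standard_normal((11, 9)) + 4, index=idx)
    b = pd.DataFrame(rng.standard_normal((11, 9)) + 4, index=idx)
    t = idx[5:]
    r1 = rif_scores(a, b, idx[:5], t)
    r2 = rif_scores(a, b, idx[:5], list(reversed(t)))
    pd.testing.assert_frame_equal(r1, r2)


def test_input_validation():
    rng = np.random.default_rng(4)
    idx = ["r1", "r2", "t1", "t2"]
    a = pd.DataFrame(rng.standard_normal((4, 4)), index=idx)
    b = pd.DataFrame(rng.standard_normal((4, 4)), index=idx)
    with pytest.raises(ValueError):
        rif_scores(a, b, ["r1"], ["t1"])  # <2 targets
    with pytest.raises(ValueError):
        rif_scores(a.iloc[:, :2], b, ["r1"], ["t1", "t2"])  # <3 samples
    with pytest.raises(KeyError):
        rif_scores(a, b, ["r1", "missing"], ["t1", "t2"])


def test_zero_variance_regulator_gets_zero_correlations():
    idx = ["r1", "r2", "t1", "t2"]
    rng = np.random.default_rng(5)
    a = pd.DataFrame(rng.standard_normal((4, 5)) + 3, index=idx)
    b = pd.DataFrame(rng.standard_normal((4, 5)) + 3, index=idx)
    a.loc["r1"] = 2.0  # flat in condition A
    res = rif_scores(a, b, ["r1", "r2"], ["t1", "t2"]).set_index("regulator")
    assert np.isfinite(res.loc["r1", "rif1_raw"])


def test_planted_regulators_outrank_decoys_at_study_n(small_cfg):
    """At the study's 9 vs 9 design, planted regulators' mean |z| exceeds
    the decoys' mean |z| (rank-based recovery, not top-1)."""
    counts, truth = generate_counts(small_cfg)
    cm = counts["liver"]
    logc = cpm(cm, tmm_factors(cm), log2=True)
    meta = cm.sample_meta
    a_cols = meta.index[meta["group"] == "highFE"]
    b_cols = meta.index[meta["group"] == "lowFE"]
    novel = [i for i in cm.values.index if i.startswith("TCONS")]
    mrna = [i for i in cm.values.index if i.startswith("MRNA")]
    res = rif_scores(logc[a_cols], logc[b_cols], novel, mrna)
    res["absmax"] = np.maximum(res["rif1_z"].abs(), res["rif2_z"].abs())
    planted = res[res["regulator"].isin(truth.true_regulators)]["absmax"]
    decoys = res[~res["regulator"].isin(truth.true_regulators)]["absmax"]
    assert planted.mean() > decoys.mean()
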