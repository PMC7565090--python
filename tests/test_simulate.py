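"""Synthetic-data generator: determinism, NB moments, planted structure."""

import numpy as np
import pytest

from lncreg.orf import max_orf_length, reverse_complement
from lncreg.simulate import (
    SimulationConfig,
    generate_annotation,
    generate_counts,
    generate_sequences,
    simulate_study,
)


def test_config_invariants():
    with pytest.raises(ValueError):
        SimulationConfig(class_mix={"j": 0.6, "u": 0.6})
    with pytest.raises(ValueError):
        SimulationConfig(n_novel=5, n_de=4, n_regulators=3)
    with pytest.raises(ValueError):
        SimulationConfig(nb_dispersion=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(n_samples_per_group=1)
    with pytest.raises(ValueError):
        SimulationConfig(wiring_r_high=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(class_mix={"q": 1.0})


def test_zero_novel_is_empty():
    cfg = SimulationConfig(seed=0, n_novel=0, n_de=0, n_regulators=0)
    ref, novel, truth = generate_annotation(cfg)
    assert novel == [] and truth.true_class == {}
    assert len(ref) == cfg.n_ref_genes


def test_annotation_geometry_valid(small_study):
    for t in small_study.reference + small_study.novel:
        for a, b in zip(t.exons, t.exons[1:]):
            assert a.end <= b.start  # sorted, non-overlapping
        assert t.length > 0


def test_exact_copy_gets_equals_code():
    from lncreg.classify import classify_transcript

    cfg = SimulationConfig(seed=3, n_novel=4, class_mix={"=": 1.0},
                           n_de=0, n_regulators=0)
    ref, novel, truth = generate_annotation(cfg)
    for t in novel:
        assert classify_transcript(t, ref).code == "="


def test_requested_orf_is_exact_and_unique():
    cfg = SimulationConfig(seed=5, n_novel=6, class_mix={"u": 1.0},
                           n_de=0, n_regulators=0)
    _, novel, _ = generate_annotation(cfg)
    spec = {novel[0].id: 0, novel[1].id: 90, novel[2].id: 300}
    seqs = generate_sequences(novel, spec, seed=5)
    for tid, want in spec.items():
        assert max_orf_length(seqs[tid]) == want
    # ORF 0 means no start codon on either strand
    s0 = seqs[novel[0].id]
    assert "ATG" not in s0 and "ATG" not in reverse_complement(s0)


def test_incompatible_orf_request_errors():
    cfg = SimulationConfig(seed=6, n_novel=2, class_mix={"u": 1.0},
                           n_de=0, n_regulators=0)
    _, novel, _ = generate_annotation(cfg)
    with pytest.raises(ValueError):
        generate_sequences(novel, {novel[0].id: novel[0].length}, seed=6)
    with pytest.raises(ValueError):
        generate_sequences(novel, {novel[0].id: 31}, seed=6)  # not codon-sized


def test_counts_deterministic_and_integer(small_cfg):
    c1, t1 = generate_counts(small_cfg)
    c2, t2 = generate_counts(small_cfg)
    for tissue in c1:
        assert c1[tissue].values.equals(c2[tissue].values)
        assert (c1[tissue].values.values >= 0).all()
        assert c1[tissue].values.dtypes.apply(
            lambda d: np.issubdtype(d, np.integer)
        ).all()
    assert t1.true_de == t2.true_de and t1.true_regulators == t2.true_regulators


def test_study_files_byte_identical_under_same_seed(tmp_path):
    cfg = SimulationConfig(seed=11, n_novel=20, n_de=2, n_regulators=1, n_mrna=30)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    simulate_study(cfg).write(d1)
    simulate_study(cfg).write(d2)
    files1 = sorted(p.name for p in d1.iterdir())
    assert files1 == sorted(p.name for p in d2.iterdir())
    for name in files1:
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name


def test_different_seeds_differ(tmp_path):
    cfg_a = SimulationConfig(seed=1, n_novel=10, n_de=0, n_regulators=0)
    cfg_b = SimulationConfig(seed=2, n_novel=10, n_de=0, n_regulators=0)
    sa = generate_sequences(generate_annotation(cfg_a)[1], seed=1)
    sb = generate_sequences(generate_annotation(cfg_b)[1], seed=2)
    assert sa != sb


def test_nb_moments_match_parameterization():
    """Empirical mean/variance of 10,000 draws agree with NB moments."""
    rng = np.random.default_rng(0)
    mean, phi = 80.0, 0.1
    r = 1 / phi
    draws = rng.negative_binomial(r, r / (r + mean), size=10_000)
    assert draws.mean() == pytest.approx(mean, rel=0.05)
    assert draws.var() == pytest.approx(mean + phi * mean**2, rel=0.1)


def test_null_config_type_one_rate():
    """No planted effects: t-test rejections at p<0.01 stay near 1%."""
    from lncreg.expression import de_ttest, tmm_factors

    cfg = SimulationConfig(
        seed=21, n_novel=0, n_de=0, n_regulators=0, n_tissue_specific=0,
        n_mrna=2000, tissues=("liver",),
    )
    counts, _ = generate_counts(cfg, novel_ids=[])
    cm = counts["liver"]
    res = de_ttest(cm, tmm_factors(cm))
    rate = res["de_flag"].mean()
    sd = np.sqrt(0.01 * 0.99 / 2000)
    assert abs(rate - 0.01) <= 3 * sd


def test_planted_de_fold_change_realized(small_cfg):
    counts, truth = generate_counts(small_cfg)
    cm = counts["muscle"]
    meta = cm.sample_meta
    a = cm.values[meta.index[meta["group"] == "highFE"]].mean(axis=1)
    b = cm.values[meta.index[meta["group"] == "lowFE"]].mean(axis=1)
    ratios = np.array([b[tid] / max(a[tid], 1) for tid in sorted(truth.true_de)])
    # planted 2^2 on the lowFE side; 9-sample noise spreads individual ratios
    assert (ratios > 1.5).all()
    assert np.median(ratios) > 2.5


def test_ground_truth_ids_exist(small_study):
    ids = {t.id for t in small_study.novel}
    truth = small_study.truth
    assert set(truth.true_class) == ids
    assert truth.true_de <= ids
    assert truth.true_regulators <= ids
    assert truth.planted_qtl_overlaps <= ids
    assert set(truth.true_sponges) <= ids
    assert truth.true_precursors <= ids
    mrna = set(small_study.mrna_ids)
    for tg in truth.regulator_targets.values():
        assert set(tg) <= mrna
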