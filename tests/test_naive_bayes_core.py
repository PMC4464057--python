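import numpy as np
import pytest

from tnbayes import (
    LabeledDataset,
    SyntheticSpec,
    brute_force_posterior,
    classify,
    condition_diagnostics,
    estimate_model,
    fit,
    generate_synthetic,
    posterior_probabilities,
    score,
    score_matrix,
    tally_counts,
)
from tnbayes.naive_bayes_core import ClassCounts, NBModel, SmoothingParams

from conftest import conditional_rates, random_model


# ---------------------------------------------------------------- counting

def test_tally_counts_toy():
    data = LabeledDataset.from_string_labels(
        np.array([[1, 0], [1, 1]], dtype=np.uint8), ["a", "a"]
    )
    counts = tally_counts(data)
    assert counts.n_total == 2
    np.testing.assert_array_equal(counts.n_class, [2])
    np.testing.assert_array_equal(counts.n_present, [[2, 1]])


def test_tally_counts_matches_double_loop(rng):
    X = (rng.random((50, 20)) < 0.3).astype(np.uint8)
    y = rng.integers(0, 3, size=50)
    data = LabeledDataset(X, y, ("a", "b", "c"))
    counts = tally_counts(data)
    for j in range(3):
        for l in range(20):
            brute = sum(int(X[i, l]) for i in range(50) if y[i] == j)
            assert counts.n_present[j, l] == brute
    # row order must not matter
    perm = rng.permutation(50)
    shuffled = tally_counts(LabeledDataset(X[perm], y[perm], ("a", "b", "c")))
    np.testing.assert_array_equal(shuffled.n_present, counts.n_present)


def test_single_class_counts_ok_but_model_rejected():
    data = LabeledDataset.from_string_labels(np.eye(2, dtype=np.uint8), ["a", "a"])
    counts = tally_counts(data)
    assert counts.n_class.size == 1
    with pytest.raises(ValueError, match="two classes"):
        estimate_model(counts)


# ---------------------------------------------------------------- estimation

def test_laplace_smoothed_rate_substitution():
    # N_lj = 3 present out of N_wj = 3 with alpha = beta = 1 gives 4/5
    counts = ClassCounts(6, np.array([3, 3]), np.array([[3], [0]]), ("a", "b"))
    model = estimate_model(counts)
    prior = np.exp(model.log_prior)
    p_feat = (prior[:, None] * np.exp(model.log_post_present)).sum(axis=0)
    cond = np.exp(model.log_post_present) * p_feat[None, :] / prior[:, None]
    assert cond[0, 0] == pytest.approx(0.8, abs=1e-12)  # (3+1)/(3+2)
    assert cond[1, 0] == pytest.approx(0.2, abs=1e-12)  # (0+1)/(3+2)


def test_empirical_prior_from_printed_counts():
    counts = ClassCounts(
        4658, np.array([268, 4390]), np.zeros((2, 1), dtype=int), ("VEGFR2", "rest")
    )
    model = estimate_model(counts)
    assert np.exp(model.log_prior[0]) == pytest.approx(268 / 4658)
    assert np.exp(model.log_prior[0]) == pytest.approx(0.057535, abs=5e-7)


def test_mirrored_counts_are_symmetric():
    counts = ClassCounts(20, np.array([10, 10]), np.array([[7, 2], [3, 8]]), ("a", "b"))
    model = estimate_model(counts)
    np.testing.assert_allclose(
        model.log_post_present[0], model.log_post_absent[1], rtol=0, atol=1e-12
    )


def test_uniform_prior_mode():
    counts = ClassCounts(30, np.array([10, 20]), np.array([[5], [5]]), ("a", "b"))
    model = estimate_model(counts, prior_mode="uniform")
    np.testing.assert_allclose(np.exp(model.log_prior), [0.5, 0.5])


def test_per_feature_posterior_normalisation(rng):
    for _ in range(5):
        model = random_model(rng, n_classes=4, n_features=12)
        for table in (model.log_post_present, model.log_post_absent):
            np.testing.assert_allclose(
                np.exp(table).sum(axis=0), 1.0, rtol=0, atol=1e-10
            )


def test_zero_counts_stay_finite():
    counts = ClassCounts(10, np.array([5, 5]), np.array([[0, 5], [0, 0]]), ("a", "b"))
    model = estimate_model(counts)
    for arr in (model.log_post_present, model.log_post_absent, model.log_prior):
        assert np.isfinite(arr).all()


def test_nonpositive_smoothing_rejected():
    with pytest.raises(ValueError, match="strictly positive"):
        SmoothingParams(np.array([1.0, 0.0]), np.array([1.0, 1.0]))


# ---------------------------------------------------------------- scoring

def snb_score_reference(model, x):
    """Standalone Bernoulli NB discriminant (explicit loop)."""
    out = np.empty(model.n_classes)
    for j in range(model.n_classes):
        s = 0.0
        for l in range(model.n_features):
            s += x[l] * model.log_post_present[j, l]
            s += (1 - x[l]) * model.log_post_absent[j, l]
        out[j] = s - (model.n_features - 1) * model.log_prior[j]
    return out


def lcmnb_score_reference(model, x):
    """Standalone presence-only discriminant (explicit loop)."""
    out = np.empty(model.n_classes)
    for j in range(model.n_classes):
        s = sum(x[l] * model.log_post_present[j, l] for l in range(model.n_features))
        out[j] = s - (model.n_features - 1) * model.log_prior[j]
    return out


def test_taper_limits_recover_snb_and_lcmnb(rng):
    """lambda=1 and lambda=0 reproduce the two standalone scorers."""
    for _ in range(20):
        model = random_model(rng, n_classes=3, n_features=10)
        x = (rng.random(10) < 0.4).astype(np.uint8)
        np.testing.assert_allclose(
            score(model, x, 1.0).scores, snb_score_reference(model, x), rtol=0, atol=1e-9
        )
        np.testing.assert_allclose(
            score(model, x, 0.0).scores, lcmnb_score_reference(model, x), rtol=0, atol=1e-9
        )


def test_score_validates_inputs(rng):
    model = random_model(rng)
    x = np.zeros(model.n_features, dtype=np.uint8)
    with pytest.raises(ValueError, match="lambda"):
        score(model, x, 1.5)
    with pytest.raises(ValueError, match="lambda"):
        score(model, x, -0.1)
    with pytest.raises(ValueError, match="length"):
        score(model, np.zeros(model.n_features + 1, dtype=np.uint8), 1.0)
    # the strictness can be lifted for research use
    assert np.isfinite(score(model, x, 1.5, strict_lambda=False).scores).all()


def test_posterior_matches_brute_force_at_full_taper(rng):
    model, counts = random_model(rng, n_classes=3, n_features=8, return_counts=True)
    prior = np.exp(model.log_prior)
    cond = conditional_rates(counts)
    for _ in range(50):
        x = (rng.random(8) < 0.5).astype(np.uint8)
        expected = brute_force_posterior(cond, prior, x)
        got = posterior_probabilities(model, x, 1.0)
        np.testing.assert_allclose(got, expected, rtol=0, atol=1e-9)
        assert got.sum() == pytest.approx(1.0, abs=1e-12)


def test_posterior_uniform_for_symmetric_model():
    counts = ClassCounts(20, np.array([10, 10]), np.array([[4, 6], [4, 6]]), ("a", "b"))
    model = estimate_model(counts)
    np.testing.assert_allclose(
        posterior_probabilities(model, np.array([1, 0]), 0.7), [0.5, 0.5], atol=1e-12
    )


def test_classify_argmax_and_tie_rule():
    # asymmetric: class b dominates on the present feature
    counts = ClassCounts(20, np.array([10, 10]), np.array([[2, 5], [8, 5]]), ("a", "b"))
    model = estimate_model(counts)
    assert classify(model, np.array([1, 0]), 1.0) == 1
    # fully symmetric model and pattern: tie broken toward the first class
    sym = estimate_model(
        ClassCounts(20, np.array([10, 10]), np.array([[4, 6], [4, 6]]), ("a", "b"))
    )
    assert classify(sym, np.array([1, 1]), 1.0) == 0


def test_classify_agrees_with_brute_force_on_synthetic():
    data, theta = generate_synthetic(
        SyntheticSpec(J=3, L=12, n_per_class=70, n_informative=6, base_rate=0.15,
                      signal_rate=0.7, block_size=1, block_corr=0.0, seed=2)
    )
    model = fit(data)
    prior = np.exp(model.log_prior)
    cond = conditional_rates(tally_counts(data))
    preds = classify(model, data.patterns, 1.0)
    for i in range(data.n_patterns):
        brute = int(np.argmax(brute_force_posterior(cond, prior, data.patterns[i])))
        assert preds[i] == brute


def test_brute_force_posterior_single_feature():
    post = brute_force_posterior(np.array([[0.8], [0.2]]), np.array([0.5, 0.5]), np.array([1]))
    np.testing.assert_allclose(post, [0.8, 0.2])
    absent = brute_force_posterior(
        np.array([[0.3, 0.3], [0.3, 0.3]]), np.array([0.5, 0.5]), np.array([0, 0])
    )
    np.testing.assert_allclose(absent, [0.5, 0.5])


# ---------------------------------------------------------------- diagnostics

def test_condition_diagnostics_symmetric_and_all_present():
    counts = ClassCounts(20, np.array([10, 10]), np.array([[4, 6], [4, 6]]), ("a", "b"))
    model = estimate_model(counts)
    diag = condition_diagnostics(model, np.array([[1, 0], [1, 1]]))
    # symmetric model: absent term identical across classes
    np.testing.assert_allclose(diag.absent_range, [0.0, 0.0], atol=1e-12)
    # all-present pattern: absent term vanishes
    np.testing.assert_allclose(diag.absent_abs[1], [0.0, 0.0], atol=1e-15)


def test_absence_dominates_in_sparse_regime():
    data, _ = generate_synthetic(
        SyntheticSpec(J=3, L=2000, n_per_class=50, n_informative=30, base_rate=0.02,
                      signal_rate=0.3, block_size=1, block_corr=0.0, seed=4)
    )
    model = fit(data)
    diag = condition_diagnostics(model, data.patterns)
    dominated = (diag.absent_abs > diag.present_abs).all(axis=1)
    assert dominated.mean() > 0.9


# ---------------------------------------------------------------- persistence

def test_model_json_round_trip_exact(tmp_path, rng):
    model = random_model(rng, n_classes=4, n_features=7)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = NBModel.from_json(path)
    np.testing.assert_array_equal(back.log_prior, model.log_prior)
    np.testing.assert_array_equal(back.log_post_present, model.log_post_present)
    np.testing.assert_array_equal(back.log_post_absent, model.log_post_absent)
    assert back.class_names == model.class_names
    x = (rng.random(7) < 0.5).astype(np.uint8)
    np.testing.assert_array_equal(
        score_matrix(back, x, 0.3), score_matrix(model, x, 0.3)
    )


def test_parameter_recovery_improves_with_n():
    spec = dict(J=3, L=60, n_informative=15, base_rate=0.1, signal_rate=0.45,
                block_size=1, block_corr=0.0, seed=12)
    errs = []
    for n in (100, 2000):
        data, theta = generate_synthetic(SyntheticSpec(n_per_class=n, **spec))
        cond = conditional_rates(tally_counts(data))
        errs.append(np.abs(cond - theta).max())
    assert errs[1] < errs[0]
    assert errs[1] <= 0.05
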