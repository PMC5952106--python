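"""Profile cohort generation, validation scores, and sequential synthesis."""

from dataclasses import replace

import numpy as np
import pytest

from miprofile import (
    CLASSIFICATION_VARS,
    PROFILES,
    ValidationModel,
    generate_profile_cohort,
    generate_validation_scores,
    synthesize_dataset,
)
from miprofile.cohort import (
    CalibrationError,
    ConfigError,
    DEFAULT_PROFILE_MEANS,
    ProfileSpec,
    calibrate_separability,
    _oob_accuracy,
    default_cohort_config,
)
from miprofile.tabular_io import SchemaError


def test_default_cohort_counts_and_completeness():
    table = generate_profile_cohort(default_cohort_config(seed=3))
    assert table.n == 198
    counts = table.df["label"].value_counts()
    assert counts["PoorDecoder"] == 58
    assert counts["PoorComprehender"] == 27
    assert counts["GenerallyPoorReader"] == 14
    assert counts["Control"] == 99
    assert table.is_complete()


def test_cohort_determinism():
    cfg = default_cohort_config(seed=42)
    assert generate_profile_cohort(cfg).equals(generate_profile_cohort(cfg))
    other = generate_profile_cohort(default_cohort_config(seed=43))
    assert not generate_profile_cohort(cfg).equals(other)


def test_degenerate_zero_covariance_reproduces_means():
    cfg = default_cohort_config(seed=0)
    specs = [
        replace(s, covariance=np.zeros((6, 6)), age_sd=0.0) for s in cfg.profile_specs
    ]
    cfg = replace(cfg, profile_specs=specs, site_effects=np.zeros(8))
    table = generate_profile_cohort(cfg)
    for spec in specs:
        rows = table.df[table.df["label"] == spec.name]
        np.testing.assert_allclose(
            rows[list(CLASSIFICATION_VARS)].to_numpy(),
            np.tile(spec.mean_vector, (len(rows), 1)),
            atol=1e-9,
        )


def test_non_psd_covariance_rejected():
    cfg = default_cohort_config(seed=0)
    bad = -np.eye(6)
    with pytest.raises(ConfigError):
        replace(cfg.profile_specs[0], covariance=bad)


def test_sample_covariance_converges_to_configured():
    """Frobenius distance of the sample covariance shrinks with n."""
    cfg = default_cohort_config(seed=9)
    spec = replace(cfg.profile_specs[3], prevalence_count=10_000)  # Controls
    cfg = replace(
        cfg,
        profile_specs=[spec] + [replace(s, prevalence_count=1) for s in cfg.profile_specs[:3]],
        site_effects=np.zeros(8),
    )
    table = generate_profile_cohort(cfg)
    rows = table.df[table.df["label"] == "Control"]
    sample = np.cov(rows[["age", *CLASSIFICATION_VARS]].to_numpy().T)
    frob = np.linalg.norm(sample - spec.covariance) / np.linalg.norm(spec.covariance)
    assert frob < 0.05


def test_validation_scores_zero_noise_hit_configured_means():
    table = generate_profile_cohort(default_cohort_config(seed=5))
    model = ValidationModel(loading=0.0, resid_sd=0.0)
    out = generate_validation_scores(table, model)
    for p in PROFILES:
        rows = out.df[out.df["label"] == p]
        for var in ("piq", "elision"):
            np.testing.assert_allclose(rows[var], model.means[p][var], atol=1e-9)


def test_validation_scores_profile_orderings_and_moments():
    """Large-n check: configured orderings hold and means land within 3 SE."""
    cfg = default_cohort_config(seed=6)
    cfg = replace(
        cfg, profile_specs=[replace(s, prevalence_count=2500) for s in cfg.profile_specs]
    )
    table = generate_profile_cohort(cfg)
    model = ValidationModel(seed=6)
    out = generate_validation_scores(table, model)
    means = out.df.groupby("label")[["piq", "spelling", "elision", "digit_span"]].mean()
    # Controls highest everywhere; Generally Poor Readers lowest on piq/digit span
    for var in ("piq", "spelling", "elision", "digit_span"):
        assert means.loc["Control", var] == means[var].max()
    assert means.loc["GenerallyPoorReader", "piq"] == means["piq"].min()
    assert means.loc["GenerallyPoorReader", "digit_span"] == means["digit_span"].min()
    assert means.loc["PoorComprehender", "elision"] > means.loc["PoorDecoder", "elision"]
    # Monte-Carlo moment check (mean deviation from profile mean is 0 in expectation)
    n = 2500
    for p in PROFILES:
        se = np.sqrt(model.loading**2 * 0.6 + model.resid_sd**2) / np.sqrt(n)
        assert abs(means.loc[p, "piq"] - model.means[p]["piq"]) < 3 * se + 0.3


def test_validation_scores_require_labels():
    table = generate_profile_cohort(default_cohort_config(seed=5))
    df = table.df.drop(columns=["label"])
    from miprofile import BehavioralTable

    with pytest.raises(SchemaError):
        generate_validation_scores(BehavioralTable(df))


def test_synthesize_counts_and_determinism(training_cohort):
    synth = synthesize_dataset(training_cohort, n_per_profile=125, seed=7)
    assert synth.n == 500
    assert (synth.df["label"].value_counts() == 125).all()
    again = synthesize_dataset(training_cohort, n_per_profile=125, seed=7)
    assert synth.equals(again)


def test_synthesize_never_reproduces_source_rows(training_cohort):
    synth = synthesize_dataset(training_cohort, n_per_profile=125, seed=8)
    cols = ["age", *CLASSIFICATION_VARS]
    merged = synth.df[cols].merge(training_cohort.df[cols], on=cols, how="inner")
    assert len(merged) == 0


def test_synthesize_preserves_profile_means_and_correlations(training_cohort):
    """Synthetic moments track the source: means within 3 SE, correlations
    within +/-0.15 element-wise when averaged over repeated syntheses."""
    src = training_cohort.df
    n_rep = 40
    corr_acc = np.zeros((5, 5))
    mean_err_checked = False
    for k in range(n_rep):
        synth = synthesize_dataset(training_cohort, n_per_profile=125, seed=100 + k)
        corr_acc += np.corrcoef(synth.df[list(CLASSIFICATION_VARS)].to_numpy().T)
        if k == 0:
            for p in PROFILES:
                s_rows = src[src["label"] == p][list(CLASSIFICATION_VARS)]
                o_rows = synth.df[synth.df["label"] == p][list(CLASSIFICATION_VARS)]
                se = s_rows.std().to_numpy() / np.sqrt(len(o_rows))
                assert (
                    np.abs(o_rows.mean().to_numpy() - s_rows.mean().to_numpy())
                    < 3 * se + 3 * s_rows.std().to_numpy() / np.sqrt(len(s_rows))
                ).all()
            mean_err_checked = True
    assert mean_err_checked
    src_corr = np.corrcoef(src[list(CLASSIFICATION_VARS)].to_numpy().T)
    assert np.abs(corr_acc / n_rep - src_corr).max() < 0.15


def test_synthesize_tree_conditionals(training_cohort):
    """Tree-based conditionals: same counts and determinism, and profile
    means still track the source."""
    synth = synthesize_dataset(training_cohort, n_per_profile=50, seed=9, conditionals="tree")
    assert synth.n == 200
    assert synth.equals(
        synthesize_dataset(training_cohort, n_per_profile=50, seed=9, conditionals="tree")
    )
    src = training_cohort.df
    for p in ("Control", "GenerallyPoorReader"):
        s_mean = src[src["label"] == p]["verbal_iq"].mean()
        o_mean = synth.df[synth.df["label"] == p]["verbal_iq"].mean()
        assert abs(o_mean - s_mean) < 6.0


def test_synthesize_rejects_incomplete_source(training_cohort):
    broken = training_cohort.copy()
    broken.df.loc[0, "ran"] = np.nan
    with pytest.raises(SchemaError):
        synthesize_dataset(broken, seed=1)


def test_separation_scale_monotonically_improves_accuracy():
    """Wider between-profile separation never hurts classifier accuracy
    (5-point grid, out-of-bag estimate)."""
    cfg = default_cohort_config(seed=12)
    accs = [_oob_accuracy(cfg, s) for s in (0.5, 0.9, 1.3, 1.9, 2.6)]
    assert all(b >= a for a, b in zip(accs, accs[1:]))


def test_calibration_reaches_perfect_accuracy_when_trivially_separable():
    """Profiles many SDs apart: target accuracy 1.0 is attainable."""
    cfg = default_cohort_config(seed=13)
    specs = [
        replace(
            s,
            prevalence_count=8,
            covariance=np.diag([1.0] + [4.0] * 5),
            mean_vector=100.0 + 10.0 * (np.asarray(s.mean_vector) - 100.0),
        )
        for s in cfg.profile_specs
    ]
    cfg = replace(cfg, profile_specs=specs, site_effects=np.zeros(8))
    calibrated, achieved = calibrate_separability(
        cfg, 1.0, n_trees_final=60, n_trees_search=40
    )
    assert achieved == 1.0


def test_calibration_unreachable_target_reports_best():
    cfg = default_cohort_config(seed=14)
    specs = [
        replace(s, prevalence_count=6, mean_vector=np.full(5, 100.0))
        for s in cfg.profile_specs
    ]
    cfg = replace(cfg, profile_specs=specs)  # zero separation at any scale
    with pytest.raises(CalibrationError) as err:
        calibrate_separability(cfg, 0.99, n_trees_final=40, n_trees_search=30, max_refine=1)
    assert 0.0 <= err.value.best_accuracy < 0.99
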