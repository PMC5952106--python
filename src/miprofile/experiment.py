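"""Orchestration of the simulation grid and the real-data-style pipeline.

The grid crosses missingness rates (0–50%) with the three imputation
methods over replicate synthetic datasets: each replicate synthesizes a
500-row cohort from the calibrated training fixture, induces MAR
missingness in three randomly selected variables, imputes with every
method, classifies each completed dataset with the trained random
forest, and scores efficiency and classification degradation against
the same replicate's complete data.  Results are accumulated as means
with SEM across replicates; the whole grid is reproducible from one
root seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_int_seed
from .classifier import (
    ClassifierModel,
    ClassificationResult,
    classify,
    classify_imputed,
    confusion_metrics,
    train_classifier,
)
from .cohort import synthesize_dataset
from .imputation import IMPUTATION_METHODS, ImputationSet, efficiency, impute
from .missingness import default_mechanism, induce_mar
from .pooling import pooled_anova, pooled_profile_means
from .tabular_io import (
    ELIGIBLE_MISSING_VARS,
    PROFILES,
    VALIDATION_VARS,
    BehavioralTable,
)

DEFAULT_RATES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class SimulationReport:
    """Tidy summaries of a simulation grid run."""

    reduction: pd.DataFrame  # method, rate, metric, mean, sem, n
    efficiency: pd.DataFrame  # method, rate, variable, mean, sem, n
    conditional: pd.DataFrame  # replicate, rate, missing_variable, profile, reduction
    baseline_accuracy: float
    n_datasets: int
    failures: list = field(default_factory=list)


def _per_class_accuracy(pred: np.ndarray, truth: np.ndarray) -> dict:
    return {
        c: float((pred[truth == c] == c).mean()) if (truth == c).any() else np.nan
        for c in PROFILES
    }


def run_simulation_grid(
    training: BehavioralTable,
    n_datasets: int = 100,
    methods: tuple[str, ...] = IMPUTATION_METHODS,
    rates: tuple[float, ...] = DEFAULT_RATES,
    seed: int = 0,
    m: int = 10,
    n_per_profile: int = 125,
    model: ClassifierModel | None = None,
    imputer_params: dict | None = None,
    fixed_selection: tuple[str, ...] | None = None,
) -> SimulationReport:
    """Run the rates x methods grid over replicate synthetic datasets.

    ``imputer_params`` maps method name to extra keyword arguments (e.g.
    smaller forests for desk-scale runs).  ``fixed_selection`` pins the
    three missing variables instead of re-drawing them per replicate.
    Per-cell failures are recorded and skipped rather than aborting.
    """
    imputer_params = imputer_params or {}
    if model is None:
        model = train_classifier(training, seed=seed, tune=False, mtry=2)
    red_rows, eff_rows, cond_rows, failures = [], [], [], []
    base_accs = []
    for r in range(n_datasets):
        synth = synthesize_dataset(
            training, n_per_profile=n_per_profile, seed=child_int_seed(seed, "synth", r)
        )
        truth = synth.labels.to_numpy()
        base_pred = classify(model, synth)
        base_summary = confusion_metrics(base_pred, truth)
        base_class_acc = _per_class_accuracy(base_pred, truth)
        base_accs.append(base_summary.accuracy)
        for rate in rates:
            if rate == 0.0:
                for method in methods:
                    red_rows.append(
                        {"replicate": r, "method": method, "rate": rate, "metric": "accuracy", "value": 0.0}
                    )
                continue
            mech = default_mechanism(
                rate,
                synth.site_levels,
                seed=child_int_seed(seed, "mech", r, int(rate * 100)),
                selected_variables=fixed_selection,
            )
            masked, mask_obj = induce_mar(synth, mech)
            for method in methods:
                try:
                    imps = impute(
                        masked,
                        method,
                        m=1 if method == "mean_replacement" else m,
                        seed=child_int_seed(seed, "impute", r, int(rate * 100), method),
                        **imputer_params.get(method, {}),
                    )
                    eff = efficiency(imps, synth)
                    for v in mech.selected_variables:
                        eff_rows.append(
                            {"replicate": r, "method": method, "rate": rate, "variable": v, "value": eff[v]}
                        )
                    accs, sens_list, spec_list, class_accs = [], [], [], []
                    for t in imps.tables:
                        pred = classify(model, t)
                        s = confusion_metrics(pred, truth)
                        accs.append(s.accuracy)
                        sens_list.append(s.sensitivity)
                        spec_list.append(s.specificity)
                        class_accs.append(_per_class_accuracy(pred, truth))
                    red_rows.append(
                        {
                            "replicate": r, "method": method, "rate": rate,
                            "metric": "accuracy",
                            "value": 100.0 * (base_summary.accuracy - float(np.mean(accs))),
                        }
                    )
                    for c in PROFILES:
                        red_rows.append(
                            {
                                "replicate": r, "method": method, "rate": rate,
                                "metric": f"sensitivity:{c}",
                                "value": 100.0
                                * (base_summary.sensitivity[c] - float(np.mean([s[c] for s in sens_list]))),
                            }
                        )
                        red_rows.append(
                            {
                                "replicate": r, "method": method, "rate": rate,
                                "metric": f"specificity:{c}",
                                "value": 100.0
                                * (base_summary.specificity[c] - float(np.mean([s[c] for s in spec_list]))),
                            }
                        )
                    if method == "missforest":
                        mean_class_acc = {
                            c: float(np.mean([a[c] for a in class_accs])) for c in PROFILES
                        }
                        for v in mech.selected_variables:
                            for c in PROFILES:
                                cond_rows.append(
                                    {
                                        "replicate": r, "rate": rate, "missing_variable": v,
                                        "profile": c,
                                        "reduction": 100.0 * (base_class_acc[c] - mean_class_acc[c]),
                                    }
                                )
                except Exception as exc:  # per-cell isolation
                    failures.append({"replicate": r, "rate": rate, "method": method, "error": str(exc)})

    red = pd.DataFrame(red_rows)
    reduction = (
        red.groupby(["method", "rate", "metric"])["value"]
        .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0, n="count")
        .reset_index()
    )
    eff = pd.DataFrame(eff_rows)
    eff_summary = (
        eff.groupby(["method", "rate", "variable"])["value"]
        .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0, n="count")
        .reset_index()
        if len(eff)
        else pd.DataFrame(columns=["method", "rate", "variable", "mean", "sem", "n"])
    )
    return SimulationReport(
        reduction=reduction,
        efficiency=eff_summary,
        conditional=pd.DataFrame(cond_rows),
        baseline_accuracy=float(np.mean(base_accs)),
        n_datasets=n_datasets,
        failures=failures,
    )


def conditional_accuracy(report: SimulationReport) -> pd.DataFrame:
    """Per (profile, missing variable, rate) mean accuracy reduction.

    Averages the per-profile accuracy reduction over the replicates in
    which each variable was among the three selected missing variables;
    combinations never selected are absent (reported missing).
    """
    if report.conditional.empty:
        return pd.DataFrame(columns=["profile", "missing_variable", "rate", "mean", "sem", "n"])
    return (
        report.conditional.groupby(["profile", "missing_variable", "rate"])["reduction"]
        .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0, n="count")
        .reset_index()
    )


@dataclass
class RealStyleResult:
    classification: ClassificationResult
    profile_counts: pd.DataFrame  # Table-1 style: per-profile mean +/- SD over imputations
    complete_case_labels: np.ndarray
    complete_case_counts: pd.Series
    complete_case_n: int
    mi_n: int
    pooled_means: pd.DataFrame
    validation_stats: pd.DataFrame


def run_real_style_pipeline(
    train_table: BehavioralTable,
    test_table: BehavioralTable,
    seed: int = 0,
    m: int = 10,
    tune: bool = False,
    imputer_params: dict | None = None,
) -> RealStyleResult:
    """Train on the complete cohort, missForest-impute and classify the test set.

    Emits the multiply-imputed branch (per-profile mean ± SD counts,
    consensus labels, pooled profile means) alongside a complete-case
    branch that classifies only the rows with no missing classification
    feature, plus pooled one-way ANOVA validation statistics for both
    branches when validation scores are present.
    """
    overlap = set(train_table.df["id"]) & set(test_table.df["id"])
    if overlap:
        raise ValueError(f"train and test share participant ids: {sorted(overlap)[:5]}")
    model = train_classifier(train_table, seed=seed, tune=tune, mtry=2)
    imps = impute(
        test_table, "missforest", m=m, seed=child_int_seed(seed, "real-impute"),
        **(imputer_params or {}),
    )
    result = classify_imputed(model, imps)
    feature_cols = list(ELIGIBLE_MISSING_VARS)
    cc_mask = test_table.df[feature_cols].notna().all(axis=1).to_numpy()
    cc_df = test_table.df.loc[cc_mask].reset_index(drop=True)
    cc_table = BehavioralTable(cc_df, test_table.sex_levels, test_table.site_levels)
    cc_labels = classify(model, cc_table)
    cc_counts = pd.Series(
        {c: int((cc_labels == c).sum()) for c in PROFILES}, name="complete_case"
    )
    pooled_means = pooled_profile_means(imps, result.pooled_labels)

    val_rows = []
    if test_table.has_validation:
        cc_set = ImputationSet(method="complete_case", tables=[cc_table])
        for v in VALIDATION_VARS:
            for branch, tset, lab in (
                ("MI", imps, result.pooled_labels),
                ("ACA", cc_set, cc_labels),
            ):
                try:
                    res = pooled_anova(tset, lab, v)
                    val_rows.append(
                        {"variable": v, "branch": branch, "n": res["n"], "F": res["F"],
                         "eta_squared": res["eta_squared"], "p": res["p"],
                         "pairwise": "; ".join(res["pairwise"])}
                    )
                except Exception as exc:
                    val_rows.append({"variable": v, "branch": branch, "error": str(exc)})
    return RealStyleResult(
        classification=result,
        profile_counts=result.profile_counts,
        complete_case_labels=cc_labels,
        complete_case_counts=cc_counts,
        complete_case_n=int(cc_mask.sum()),
        mi_n=test_table.n,
        pooled_means=pooled_means,
        validation_stats=pd.DataFrame(val_rows),
    )


def report(
    sim_report: SimulationReport,
    outdir,
    manifest: dict | None = None,
    make_plots: bool = True,
) -> dict:
    """Write tidy CSVs, figure panels, and a run manifest under ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    sim_report.reduction.to_csv(outdir / "reduction_curves.csv", index=False)
    written["reduction"] = outdir / "reduction_curves.csv"
    sim_report.efficiency.to_csv(outdir / "efficiency_curves.csv", index=False)
    written["efficiency"] = outdir / "efficiency_curves.csv"
    cond = conditional_accuracy(sim_report)
    cond.to_csv(outdir / "conditional_accuracy.csv", index=False)
    written["conditional"] = outdir / "conditional_accuracy.csv"
    manifest = dict(manifest or {})
    manifest.update(
        {
            "n_datasets": sim_report.n_datasets,
            "baseline_accuracy": sim_report.baseline_accuracy,
            "n_failures": len(sim_report.failures),
        }
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    written["manifest"] = outdir / "manifest.json"
    if make_plots:
        try:
            written.update(_plots(sim_report, cond, outdir))
        except Exception:  # plotting is best-effort
            pass
    return written


def _plots(sim_report: SimulationReport, cond: pd.DataFrame, outdir) -> dict:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = {}
    fig, ax = plt.subplots(figsize=(5, 4))
    acc = sim_report.reduction.query("metric == 'accuracy'")
    for method, sub in acc.groupby("method"):
        sub = sub.sort_values("rate")
        ax.errorbar(100 * sub["rate"], sub["mean"], yerr=sub["sem"], label=method, marker="o")
    ax.set_xlabel("% missingness")
    ax.set_ylabel("accuracy reduction (points)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "reduction_curves.png", dpi=110)
    plt.close(fig)
    written["reduction_png"] = outdir / "reduction_curves.png"

    if len(sim_report.efficiency):
        fig, ax = plt.subplots(figsize=(5, 4))
        eff = sim_report.efficiency.groupby(["method", "rate"])["mean"].mean().reset_index()
        for method, sub in eff.groupby("method"):
            sub = sub.sort_values("rate")
            ax.plot(100 * sub["rate"], sub["mean"], label=method, marker="o")
        ax.axhline(1.0, color="gray", lw=0.8, ls="--")
        ax.set_xlabel("% missingness")
        ax.set_ylabel("efficiency (variance ratio)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "efficiency_curves.png", dpi=110)
        plt.close(fig)
        written["efficiency_png"] = outdir / "efficiency_curves.png"

    if len(cond):
        profiles = sorted(cond["profile"].unique())
        fig, axes = plt.subplots(1, len(profiles), figsize=(3.2 * len(profiles), 3.2), sharey=True)
        for ax, profile in zip(np.atleast_1d(axes), profiles):
            sub = cond[cond["profile"] == profile]
            for v, ss in sub.groupby("missing_variable"):
                ss = ss.sort_values("rate")
                ax.plot(100 * ss["rate"], ss["mean"], marker="o", label=v)
            ax.set_title(profile, fontsize=9)
            ax.set_xlabel("% missingness")
        np.atleast_1d(axes)[0].set_ylabel("accuracy reduction (points)")
        np.atleast_1d(axes)[-1].legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / "conditional_accuracy.png", dpi=110)
        plt.close(fig)
        written["conditional_png"] = outdir / "conditional_accuracy.png"
    return written
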