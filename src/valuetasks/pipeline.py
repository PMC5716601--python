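"""End-to-end analysis pipeline on a synthetic cohort.

Stages mirror the study's analysis path: simulate the cohort; model-free
regressions per task; fit all candidate value functions per subject and
task; family-wise comparison of 'same value function in every task' against
'different'; model-level selection within the winning family; parameter-
sharing comparison for the CES selfishness and concavity parameters on
pooled three-task data; cross-task choice prediction (balanced accuracy);
and the convergence / trial-efficiency analysis under native and optimized
trial orders.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from . import bms as bms_mod
from . import design as design_mod
from .cohort import CohortConfig, SubjectDataset, simulate_cohort
from .fitting import (
    PriorSpec,
    SharedParameterModel,
    ValueTaskModel,
    partition_label,
    sharing_partitions,
)
from .observation import TASKS
from .value_models import MODEL_NAMES, get_spec

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ModelFreeResult",
    "model_free_analysis",
    "fit_evidence_matrices",
    "full_model_comparison",
    "parameter_sharing_comparison",
    "cross_task_prediction",
    "convergence_analysis",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Scales and options of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    models: tuple[str, ...] = MODEL_NAMES
    prior: PriorSpec = field(default_factory=PriorSpec)
    n_restarts: int = 4
    seed: int = 0
    out_dir: str = "results"
    convergence_subjects: int = 8  # subjects entering the convergence stage
    convergence_task: str = "rating"
    xp_samples: int = 200_000

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig(**d["cohort"])
        if "prior" in d and isinstance(d["prior"], dict):
            d["prior"] = PriorSpec(**d["prior"])
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)


@dataclass
class ModelFreeResult:
    """Design-factor regressions, fatigue checks and response-distribution
    curvature, per subject and task, with group-level summaries."""

    coefficients: pd.DataFrame  # subject, task, term, estimate
    fatigue: pd.DataFrame  # subject, task, term, estimate
    quadratic: pd.DataFrame  # subject, task, quad_coef
    group_summary: pd.DataFrame  # task, term, mean, sem, tstat, pvalue


def _one_sample_rows(df: pd.DataFrame, value_col: str, by) -> pd.DataFrame:
    rows = []
    for keys, sub in df.groupby(list(by)):
        vals = sub[value_col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            continue
        t, p = st.ttest_1samp(vals, 0.0)
        rows.append(
            dict(
                zip(by, keys if isinstance(keys, tuple) else (keys,)),
                mean=vals.mean(),
                sem=st.sem(vals),
                tstat=t,
                pvalue=p,
                n=len(vals),
            )
        )
    return pd.DataFrame(rows)


def model_free_analysis(datasets: list[SubjectDataset]) -> ModelFreeResult:
    """Regressions of responses on gain, donation and their interaction.

    Ratings and forces use OLS; choices use a logistic regression on the
    left-minus-right differences of the same regressors.  Residuals of the
    linear regressions are regressed on trial and session index (fatigue
    check), and a second-order polynomial is fitted to each subject's
    response histogram (risk-attitude check).  Group-level one-sample t
    statistics are reported for every term.
    """
    coef_rows, fat_rows, quad_rows = [], [], []
    for ds in datasets:
        for task in ("rating", "force"):
            df = ds.task(task)
            x = df[["gain_left", "donation_left"]].to_numpy(dtype=float)
            X = sm.add_constant(
                np.column_stack([x, x[:, 0] * x[:, 1]])
            )
            y = df["response"].to_numpy(dtype=float)
            fit = sm.OLS(y, X).fit()
            for term, est in zip(("const", "G", "D", "GxD"), fit.params):
                coef_rows.append(
                    {"subject": ds.subject, "task": task, "term": term, "estimate": est}
                )
            Z = sm.add_constant(
                df[["trial", "session"]].to_numpy(dtype=float)
            )
            fat = sm.OLS(fit.resid, Z).fit()
            for term, est in zip(("const", "trial", "session"), fat.params):
                fat_rows.append(
                    {"subject": ds.subject, "task": task, "term": term, "estimate": est}
                )
            lo, hi = (0.0, 10.0) if task == "rating" else (10.0, 100.0)
            hist, edges = np.histogram(y, bins=10, range=(lo, hi), density=True)
            centers = 0.5 * (edges[:-1] + edges[1:])
            cs = (centers - centers.mean()) / centers.std()
            quad = np.polyfit(cs, hist / hist.sum(), 2)
            quad_rows.append(
                {"subject": ds.subject, "task": task, "quad_coef": quad[0]}
            )
        dfc = ds.task("choice")
        dg = dfc["gain_left"] - dfc["gain_right"]
        dd = dfc["donation_left"] - dfc["donation_right"]
        dgd = dfc["gain_left"] * dfc["donation_left"] - dfc["gain_right"] * dfc["donation_right"]
        Xc = np.column_stack([dg, dd, dgd])
        Xc = Xc / np.array([100.0, 100.0, 10000.0])  # unit-scale for stability
        yc = dfc["response"].to_numpy(dtype=float)
        try:
            fit = sm.Logit(yc, sm.add_constant(Xc)).fit(disp=0, maxiter=200)
            params = fit.params
        except Exception:  # separation or non-convergence: flagged as NaN
            logger.warning("logistic regression failed for subject %s", ds.subject)
            params = np.full(4, np.nan)
        for term, est, scale in zip(
            ("const", "G", "D", "GxD"), params, (1.0, 100.0, 100.0, 10000.0)
        ):
            coef_rows.append(
                {
                    "subject": ds.subject,
                    "task": "choice",
                    "term": term,
                    "estimate": est / scale,
                }
            )
    coefficients = pd.DataFrame(coef_rows)
    fatigue = pd.DataFrame(fat_rows)
    quadratic = pd.DataFrame(quad_rows)
    group = _one_sample_rows(
        coefficients[coefficients["term"] != "const"], "estimate", ("task", "term")
    )
    fat_group = _one_sample_rows(
        fatigue[fatigue["term"] != "const"], "estimate", ("task", "term")
    )
    fat_group["term"] = "fatigue_" + fat_group["term"].astype(str)
    quad_group = _one_sample_rows(
        quadratic.rename(columns={"quad_coef": "estimate"}).assign(term="quadratic"),
        "estimate",
        ("task", "term"),
    )
    group_summary = pd.concat([group, fat_group, quad_group], ignore_index=True)
    return ModelFreeResult(coefficients, fatigue, quadratic, group_summary)


def fit_evidence_matrices(
    datasets: list[SubjectDataset],
    models=MODEL_NAMES,
    prior: PriorSpec | None = None,
    n_restarts: int = 4,
    seed: int = 0,
    tasks=TASKS,
    return_fits: bool = False,
):
    """Fit every (model x task x subject) cell; return per-task evidence
    matrices (subjects x models DataFrames) and, optionally, the fit objects.

    Failed cells are logged and recorded as NaN; downstream comparisons drop
    subjects with incomplete rows (listwise).
    """
    prior = prior or PriorSpec()
    evidence = {t: {} for t in tasks}
    fits = {}
    for si, ds in enumerate(datasets):
        for task in tasks:
            df = ds.task(task)
            row = {}
            for mi, name in enumerate(models):
                fit_seed = (seed * 1_000_003 + si * 101 + mi * 7 + hash(task) % 97) % (2**31)
                try:
                    res = ValueTaskModel(df, name, task, prior=prior).fit(
                        n_restarts=n_restarts, seed=fit_seed
                    )
                    row[name] = res.log_evidence
                    if return_fits:
                        fits[(ds.subject, task, name)] = res
                except Exception as exc:
                    logger.warning(
                        "fit failed: subject %s task %s model %s: %s",
                        ds.subject, task, name, exc,
                    )
                    row[name] = np.nan
            evidence[task][ds.subject] = row
    mats = {
        t: pd.DataFrame.from_dict(evidence[t], orient="index").loc[
            [d.subject for d in datasets], list(models)
        ]
        for t in tasks
    }
    return (mats, fits) if return_fits else mats


def full_model_comparison(
    datasets: list[SubjectDataset],
    models=MODEL_NAMES,
    prior: PriorSpec | None = None,
    n_restarts: int = 4,
    seed: int = 0,
    xp_samples: int = 200_000,
    evidence=None,
) -> dict:
    """The study's first model comparison, on synthetic data.

    Builds the combined task-wise model space (12^3 columns for the full
    space), runs 'same'-vs-'different' family inference, and a model-level
    BMS restricted to the 'same' family to name the winning value function.
    """
    if evidence is None:
        evidence = fit_evidence_matrices(
            datasets, models=models, prior=prior, n_restarts=n_restarts, seed=seed
        )
    complete = None
    for t, df in evidence.items():
        ok = df.notna().all(axis=1)
        complete = ok if complete is None else (complete & ok)
    dropped = [s for s, keep in complete.items() if not keep]
    if dropped:
        logger.warning("dropping subjects with failed fits: %s", dropped)
    evidence = {t: df.loc[complete] for t, df in evidence.items()}
    combined = bms_mod.build_combined_space(evidence)
    families = bms_mod.same_family_labels(combined)
    family = bms_mod.family_inference(combined, families, xp_samples=xp_samples)
    same_cols = families["same"]
    within = bms_mod.rfx_bms(
        combined[same_cols].set_axis(
            [c.split("|")[0] for c in same_cols], axis=1
        ),
        xp_samples=xp_samples,
    )
    winner = within.model_names[int(np.argmax(within.expected_frequency))]
    return {
        "evidence_by_task": evidence,
        "combined": combined,
        "family": family,
        "within_same": within,
        "winning_model": winner,
        "dropped_subjects": dropped,
    }


def parameter_sharing_comparison(
    datasets: list[SubjectDataset],
    model: str = "ces",
    roles: tuple[str, ...] = ("alpha", "delta"),
    prior: PriorSpec | None = None,
    n_restarts: int = 4,
    seed: int = 0,
    xp_samples: int = 200_000,
) -> dict:
    """Pooled three-task fits under the five parameter-sharing partitions.

    For each role (CES selfishness ``alpha``, concavity ``delta``) the five
    partitions of {force, rating, choice} are fitted per subject on pooled
    data, their evidences compared by RFX-BMS.  Per-task parameter estimates
    (from the all-distinct partition) give cross-task Pearson and Spearman
    correlations.
    """
    prior = prior or PriorSpec()
    partitions = sharing_partitions()
    out: dict = {"roles": {}}
    all_task_fits = []
    for si, ds in enumerate(datasets):
        all_task_fits.append(
            {
                t: ValueTaskModel(ds.task(t), model, t, prior=prior).fit(
                    n_restarts=n_restarts,
                    seed=(seed * 999_979 + si * 257 + hash(t) % 83) % (2**31),
                )
                for t in TASKS
            }
        )
    for ri, role in enumerate(roles):
        lme = {}
        per_task_params: dict[str, dict] = {}
        for si, ds in enumerate(datasets):
            data_by_task = {t: ds.task(t) for t in TASKS}
            task_fits = all_task_fits[si]
            row = {}
            for pi, part in enumerate(partitions):
                m = SharedParameterModel(data_by_task, model, role, part, prior=prior)
                fit_seed = (seed * 999_983 + si * 131 + ri * 17 + pi) % (2**31)
                res = m.fit(
                    n_restarts=max(1, n_restarts // 2),
                    seed=fit_seed,
                    start_values=m.assemble_start(task_fits),
                )
                row[partition_label(part)] = res.log_evidence
                if len(part) == len(TASKS):  # all-distinct: per-task estimates
                    per_task_params[ds.subject] = {
                        t: res.params[f"{role}[{t}]"] for t in TASKS
                    }
            lme[ds.subject] = row
        lme_df = pd.DataFrame.from_dict(lme, orient="index")
        sel = bms_mod.rfx_bms(lme_df, xp_samples=xp_samples)
        params_df = pd.DataFrame.from_dict(per_task_params, orient="index")
        corr_rows = []
        for i, t1 in enumerate(TASKS):
            for t2 in TASKS[i + 1:]:
                r_p, p_p = st.pearsonr(params_df[t1], params_df[t2])
                r_s, p_s = st.spearmanr(params_df[t1], params_df[t2])
                corr_rows.append(
                    {
                        "pair": f"{t1}-{t2}",
                        "pearson_r": r_p,
                        "pearson_p": p_p,
                        "spearman_r": r_s,
                        "spearman_p": p_s,
                    }
                )
        out["roles"][role] = {
            "log_evidence": lme_df,
            "bms": sel,
            "winning_partition": sel.model_names[int(np.argmax(sel.expected_frequency))],
            "per_task_params": params_df,
            "cross_task_correlations": pd.DataFrame(corr_rows),
        }
    return out


def cross_task_prediction(
    datasets: list[SubjectDataset],
    prior: PriorSpec | None = None,
    n_restarts: int = 4,
    seed: int = 0,
    model: str = "ces",
) -> pd.DataFrame:
    """Predict each subject's choices from rating- and force-derived values.

    The value function fitted to one task provides value differences for the
    choice pairs; predicted side is the softmax mode (threshold 0.5, i.e.
    the sign of the difference).  Balanced accuracy is the mean of
    sensitivity and specificity; a logistic regression of choices on the
    value difference provides the temperature (inverse slope).
    """
    prior = prior or PriorSpec()
    spec = get_spec(model)
    rows = []
    for si, ds in enumerate(datasets):
        choice = ds.task("choice")
        y = choice["response"].to_numpy(dtype=float)
        if y.min() == y.max():
            logger.warning(
                "subject %s chose one side on every trial; balanced accuracy undefined",
                ds.subject,
            )
            continue
        for source in ("rating", "force"):
            fit_seed = (seed * 7_654_321 + si * 13 + hash(source) % 89) % (2**31)
            res = ValueTaskModel(ds.task(source), spec, source, prior=prior).fit(
                n_restarts=n_restarts, seed=fit_seed
            )
            vparams = {k: res.params[k] for k in spec.param_names}
            dv = spec.value(
                vparams, choice["gain_left"], choice["donation_left"]
            ) - spec.value(vparams, choice["gain_right"], choice["donation_right"])
            pred_left = dv > 0
            sens = np.mean(pred_left[y == 1]) if np.any(y == 1) else np.nan
            spec_ = np.mean(~pred_left[y == 0]) if np.any(y == 0) else np.nan
            bal_acc = 0.5 * (sens + spec_)
            try:
                lfit = sm.Logit(y, dv.reshape(-1, 1)).fit(disp=0, maxiter=200)
                slope = float(lfit.params[0])
                temperature = 1.0 / slope if slope > 0 else np.nan
            except Exception:
                temperature = np.nan
            rows.append(
                {
                    "subject": ds.subject,
                    "source": source,
                    "balanced_accuracy": bal_acc,
                    "temperature": temperature,
                }
            )
    return pd.DataFrame(rows)


def convergence_analysis(
    datasets: list[SubjectDataset],
    task: str = "rating",
    model: str = "ces",
    prior: PriorSpec | None = None,
    seed: int = 0,
    max_subjects: int | None = None,
) -> pd.DataFrame:
    """Native vs optimized trial order: 5%-threshold trial counts.

    Each subject's value model is fitted on the full task data; the posterior
    variance trace is then accumulated trial by trial (Fisher information at
    the MAP) in the native randomized order and in the informativeness-
    optimized order, and the threshold trial is the last with a relative
    precision gain above 5%.
    """
    rows = []
    for si, ds in enumerate(datasets[: max_subjects or len(datasets)]):
        trials = ds.task(task)
        rng = np.random.default_rng((seed, si))
        full = ValueTaskModel(trials, model, task, prior=prior).fit(
            n_restarts=4, seed=(seed * 31 + si) % (2**31)
        )
        orders = {
            "native": trials,
            "optimized": design_mod.optimized_order(trials, results=full, rng=rng),
        }
        for order_name, ordered in orders.items():
            ts, sigmas = design_mod.information_sigma_trace(ordered, full)
            trace = design_mod.convergence_trace(sigmas, trials=ts)
            rows.append(
                {
                    "subject": ds.subject,
                    "task": task,
                    "order": order_name,
                    "threshold_trial": trace.threshold_trial,
                }
            )
    return pd.DataFrame(rows)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write CSV/JSON artifacts plus a summary.

    Fully reproducible from the master seed.  Any stage failure aborts with
    the stage name; artifacts written so far are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.cohort.seed = config.seed
    report: dict = {}
    timings: dict[str, float] = {}
    stage = "simulate"
    try:
        t0 = time.time()
        datasets, table = simulate_cohort(config.cohort, out / "trial_table.csv")
        timings[stage] = time.time() - t0
        logger.info("simulated %d subjects (%.1fs)", len(datasets), timings[stage])

        stage = "model_free"
        t0 = time.time()
        mf = model_free_analysis(datasets)
        mf.coefficients.to_csv(out / "model_free_coefficients.csv", index=False)
        mf.group_summary.to_csv(out / "model_free_group_summary.csv", index=False)
        timings[stage] = time.time() - t0

        stage = "model_comparison"
        t0 = time.time()
        comparison = full_model_comparison(
            datasets,
            models=config.models,
            prior=config.prior,
            n_restarts=config.n_restarts,
            seed=config.seed,
            xp_samples=config.xp_samples,
        )
        for t, df in comparison["evidence_by_task"].items():
            df.to_csv(out / f"evidence_{t}.csv")
        fam = comparison["family"]
        within = comparison["within_same"]
        _write_json(
            out / "model_comparison.json",
            {
                "family_names": fam.family_names,
                "family_Ef": fam.expected_frequency,
                "family_Xp": fam.exceedance_probability,
                "within_same_models": within.model_names,
                "within_same_Ef": within.expected_frequency,
                "within_same_Xp": within.exceedance_probability,
                "winning_model": comparison["winning_model"],
                "dropped_subjects": comparison["dropped_subjects"],
            },
        )
        timings[stage] = time.time() - t0

        stage = "parameter_sharing"
        t0 = time.time()
        winner = comparison["winning_model"]
        sharing_model = winner if winner == "ces" else "ces"
        sharing = parameter_sharing_comparison(
            datasets,
            model=sharing_model,
            prior=config.prior,
            n_restarts=config.n_restarts,
            seed=config.seed,
            xp_samples=config.xp_samples,
        )
        sharing_out = {}
        for role, r in sharing["roles"].items():
            r["log_evidence"].to_csv(out / f"sharing_evidence_{role}.csv")
            r["cross_task_correlations"].to_csv(
                out / f"cross_task_correlations_{role}.csv", index=False
            )
            sharing_out[role] = {
                "partitions": r["bms"].model_names,
                "Ef": r["bms"].expected_frequency,
                "Xp": r["bms"].exceedance_probability,
                "winning_partition": r["winning_partition"],
            }
        _write_json(out / "parameter_sharing.json", sharing_out)
        timings[stage] = time.time() - t0

        stage = "cross_task_prediction"
        t0 = time.time()
        prediction = cross_task_prediction(
            datasets,
            prior=config.prior,
            n_restarts=config.n_restarts,
            seed=config.seed,
        )
        prediction.to_csv(out / "cross_task_prediction.csv", index=False)
        timings[stage] = time.time() - t0

        stage = "convergence"
        t0 = time.time()
        convergence = convergence_analysis(
            datasets,
            task=config.convergence_task,
            prior=config.prior,
            seed=config.seed,
            max_subjects=config.convergence_subjects,
        )
        convergence.to_csv(out / "convergence.csv", index=False)
        timings[stage] = time.time() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = {
        "seed": config.seed,
        "n_subjects": config.cohort.n_subjects,
        "winning_model": comparison["winning_model"],
        "same_family_Ef": float(
            fam.to_series()["same"] if "same" in fam.family_names else np.nan
        ),
        "same_family_Xp": float(
            fam.to_series("exceedance_probability")["same"]
        ),
        "sharing": {
            role: sharing_out[role]["winning_partition"] for role in sharing_out
        },
        "balanced_accuracy": prediction.groupby("source")["balanced_accuracy"]
        .mean()
        .to_dict(),
        "convergence_mean_threshold": convergence.groupby("order")["threshold_trial"]
        .mean()
        .to_dict(),
    }
    for k, v in timings.items():
        logger.info("stage %s took %.2fs", k, v)
    _write_json(out / "summary.json", report)
    lines = [
        "valuetasks pipeline summary",
        "===========================",
        f"seed: {config.seed}; subjects: {config.cohort.n_subjects}",
        f"'same' family: Ef={report['same_family_Ef']:.3f} "
        f"Xp={report['same_family_Xp']:.3f}",
        f"winning value function within 'same': {report['winning_model']}",
        *(
            f"sharing winner for {role}: {win}"
            for role, win in report["sharing"].items()
        ),
        *(
            f"balanced accuracy from {src}: {acc:.3f}"
            for src, acc in report["balanced_accuracy"].items()
        ),
        *(
            f"mean 5%-threshold trial ({order} order): {v:.1f}"
            for order, v in report["convergence_mean_threshold"].items()
        ),
    ]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return {
        "datasets": datasets,
        "model_free": mf,
        "comparison": comparison,
        "sharing": sharing,
        "prediction": prediction,
        "convergence": convergence,
        "report": report,
    }
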