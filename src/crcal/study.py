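"""Monte Carlo study harness for validating the calibration method.

Six study designs are provided, matching the validation studies of the
method: spline knot selection, a correctly specified model with and without
censoring, omission of a quadratic term, omission of a main effect, and a
shift of outcome incidence between derivation and validation populations.
Each study draws replicate samples from a configured data-generating
process, fits the (correct or deliberately mis-specified) Fine-Gray model,
assesses calibration at five evaluation times (the 10th/25th/50th/75th/90th
percentiles of event or observed time in a super-population), and
aggregates metrics and mean calibration curves with 2.5th/97.5th percentile
bands across replicates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import calibration_curve
from .errors import ConvergenceError, CrcalError
from .finegray import expand_weighted, fit_weighted_cox, predict_cif
from .simulate import DGPConfig, calibrate_censoring_rate, evaluation_times, generate

STUDY_NAMES = (
    "knot_selection",
    "censoring",
    "correct_no_censoring",
    "quadratic",
    "omitted_main_effect",
    "validation_shift",
)
TIME_LABELS = ("t10", "t25", "t50", "t75", "t90")


@dataclass
class Scenario:
    """One resolved cell of a study's factor grid."""

    study_name: str
    label: str
    dgp: DGPConfig  # template; seed is overwritten per replicate
    knot_counts: tuple[int, ...] = (3,)
    model_covariates: list[str] | None = None  # None = all covariates
    factors: dict = field(default_factory=dict)


def scenario_grid(study_name: str, correct_model: bool = False) -> list[Scenario]:
    """The factor grid of one study design.

    ``correct_model=True`` swaps the deliberately mis-specified fitted model
    of the omitted-main-effect study for the full two-covariate model
    (the matched baseline); it has no effect on the other studies.
    """
    if study_name not in STUDY_NAMES:
        raise ValueError(f"unknown study {study_name!r}; choose from {STUDY_NAMES}")
    scenarios: list[Scenario] = []
    if study_name == "knot_selection":
        for p in (0.25, 0.5, 0.75):
            scenarios.append(
                Scenario(
                    study_name,
                    f"p={p}",
                    DGPConfig(n=1000, p=p, beta1=1.0, beta2=0.25),
                    knot_counts=(3, 4, 5),
                    factors={"p": p},
                )
            )
    elif study_name == "censoring":
        for p, cens in itertools.product((0.25, 0.5, 0.75), (0.0, 0.2, 0.4, 0.6)):
            scenarios.append(
                Scenario(
                    study_name,
                    f"p={p},censoring={cens}",
                    DGPConfig(n=2000, p=p, beta1=1.0, beta2=0.25, censor_proportion=cens),
                    factors={"p": p, "censor_proportion": cens},
                )
            )
    elif study_name in ("correct_no_censoring", "quadratic"):
        quad = study_name == "quadratic"
        for n, b1, p in itertools.product((500, 1000, 2000), (0.25, 0.5, 1.0), (0.25, 0.5, 0.75)):
            scenarios.append(
                Scenario(
                    study_name,
                    f"N={n},beta1={b1},p={p}",
                    DGPConfig(n=n, p=p, beta1=b1, beta2=0.25, quadratic=quad),
                    factors={"sample_n": n, "beta1": b1, "p": p},
                )
            )
    elif study_name == "omitted_main_effect":
        for rho, b2s in itertools.product((0.0, 0.25, 0.5, 0.75), (0.25, 0.5, 1.0)):
            scenarios.append(
                Scenario(
                    study_name,
                    f"rho={rho},beta2={b2s}",
                    DGPConfig(
                        n=1000, p=0.5,
                        two_covariate={"rho": rho, "beta2_second": b2s},
                    ),
                    model_covariates=None if correct_model else ["x1"],
                    factors={"rho": rho, "beta2_second": b2s},
                )
            )
    elif study_name == "validation_shift":
        for pv in (0.3, 0.4, 0.5, 0.6, 0.7):
            scenarios.append(
                Scenario(
                    study_name,
                    f"p_validation={pv}",
                    DGPConfig(n=1000, p=0.5, beta1=0.5, beta2=0.25, p_validation=pv),
                    factors={"p_validation": pv},
                )
            )
    return scenarios


@dataclass
class StudySpec:
    """A study to run: design name, scale, and reproducibility seeds.

    The factor grids are fixed by the design; ``subset`` optionally
    restricts the grid to cells whose factors match (e.g.
    ``{"p": [0.5]}``).  ``replicates`` defaults to a desk-scale 100 (the
    full-scale studies use 1000); ``superpop_n`` sizes the super-population
    used for evaluation times and censoring calibration.
    """

    study_name: str
    replicates: int = 100
    master_seed: int = 0
    superpop_n: int = 100_000
    sample_n: int | None = None
    subset: dict | None = None
    time_indices: tuple[int, ...] = (0, 1, 2, 3, 4)
    correct_model: bool = False

    def resolve_scenarios(self) -> list[Scenario]:
        grid = scenario_grid(self.study_name, correct_model=self.correct_model)
        if self.subset:
            grid = [
                s
                for s in grid
                if all(s.factors.get(k) in v for k, v in self.subset.items())
            ]
        if self.sample_n is not None:
            grid = [replace(s, dgp=replace(s.dgp, n=self.sample_n)) for s in grid]
        return grid


@dataclass
class ReplicateRecord:
    seed: int
    beta: np.ndarray | None
    model_converged: bool
    # one entry per (time, n_knots): metric values and the display curve
    entries: list[dict] = field(default_factory=list)
    failure: str | None = None


def _derive_seed(master_seed: int, scenario_index: int, rep_index: int) -> int:
    ss = np.random.SeedSequence([master_seed, scenario_index, rep_index])
    return int(ss.generate_state(1)[0] % (2**31))


def run_replicate(scenario: Scenario, times, seed: int,
                  knot_counts: tuple[int, ...] | None = None) -> ReplicateRecord:
    """Draw one sample, fit the scenario's model, assess calibration.

    For the validation-shift design the model is fit in a derivation sample
    generated with the derivation incidence and assessed in an
    independently generated validation sample with the shifted incidence.
    Fit failures are recorded on the result, never raised.
    """
    knot_counts = scenario.knot_counts if knot_counts is None else knot_counts
    dgp = replace(scenario.dgp, seed=seed)
    record = ReplicateRecord(seed=seed, beta=None, model_converged=False)
    try:
        if scenario.study_name == "validation_shift":
            derivation = generate(replace(dgp, p_validation=None))
            eval_data = generate(replace(dgp, seed=seed + 1))
        else:
            derivation = generate(dgp)
            eval_data = derivation
        names = scenario.model_covariates or derivation.covariate_names
        deriv_rows = expand_weighted(derivation)
        fit = fit_weighted_cox(deriv_rows, names)
        record.beta = fit.coefficients
        record.model_converged = fit.converged
        if not fit.converged:
            record.failure = "prediction model did not converge"
            return record
        eval_rows = (
            deriv_rows if eval_data is derivation else expand_weighted(eval_data)
        )
        X_eval = eval_data.covariate_matrix(names)
    except (CrcalError, np.linalg.LinAlgError, ValueError) as exc:
        record.failure = f"{type(exc).__name__}: {exc}"
        return record

    for t_idx, t0 in enumerate(times):
        preds = predict_cif(fit, X_eval, float(t0))
        for k in knot_counts:
            entry = {"time_index": t_idx, "t0": float(t0), "n_knots": k}
            try:
                res = calibration_curve(
                    eval_data, preds, n_knots=k, expansion=eval_rows
                )
                entry.update(res.metrics.as_dict())
                entry["curve_predicted"] = res.curve_predicted
                entry["curve_observed"] = res.curve_observed
                entry["failure"] = None
            except (CrcalError, ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
                entry["failure"] = f"{type(exc).__name__}: {exc}"
            record.entries.append(entry)
    return record


@dataclass
class ScenarioResult:
    """Aggregated results of one scenario across replicates."""

    scenario: Scenario
    times: np.ndarray
    time_indices: tuple[int, ...]
    metrics: pd.DataFrame  # per replicate x time x knot count
    curves: dict  # (time_index, n_knots) -> DataFrame(predicted, mean, lo, hi)
    n_replicates: int
    n_failed: int


def _aggregate_curves(entries: list[dict], grid_size: int = 100) -> pd.DataFrame | None:
    """Mean curve with 2.5/97.5 percentile bands on a common grid.

    The common grid spans the union of the replicates' displayed ranges
    (each the 1st-99th percentile of its predicted risks), clipped to
    [0, 1]; each replicate contributes where its own curve is defined.
    """
    ok = [e for e in entries if e.get("failure") is None]
    if not ok:
        return None
    lo = min(e["curve_predicted"][0] for e in ok)
    hi = max(e["curve_predicted"][-1] for e in ok)
    grid = np.linspace(max(lo, 0.0), min(hi, 1.0), grid_size)
    stack = np.full((len(ok), grid_size), np.nan)
    for i, e in enumerate(ok):
        cp, co = e["curve_predicted"], e["curve_observed"]
        inside = (grid >= cp[0]) & (grid <= cp[-1])
        stack[i, inside] = np.interp(grid[inside], cp, co)
    with np.errstate(all="ignore"):
        mean = np.nanmean(stack, axis=0)
        band_lo = np.nanpercentile(stack, 2.5, axis=0)
        band_hi = np.nanpercentile(stack, 97.5, axis=0)
    return pd.DataFrame(
        {"predicted": grid, "mean": mean, "lo": band_lo, "hi": band_hi,
         "n_curves": np.sum(~np.isnan(stack), axis=0)}
    )


def run_scenario(
    scenario: Scenario, spec: StudySpec, scenario_index: int
) -> ScenarioResult:
    """Run all replicates of one scenario and aggregate."""
    dgp = scenario.dgp
    if dgp.censor_proportion > 0 and dgp.censor_rate is None:
        rate = calibrate_censoring_rate(
            replace(dgp, seed=spec.master_seed),
            dgp.censor_proportion,
            superpop_n=min(spec.superpop_n, 200_000),
        )
        dgp = replace(dgp, censor_rate=rate)
    times_all = evaluation_times(
        replace(dgp, seed=spec.master_seed, p_validation=None), spec.superpop_n
    )
    times = times_all[list(spec.time_indices)]
    scenario = replace(scenario, dgp=dgp)

    rows = []
    n_failed = 0
    curve_entries: dict[tuple[int, int], list[dict]] = {}
    for r in range(spec.replicates):
        seed = _derive_seed(spec.master_seed, scenario_index, r)
        rec = run_replicate(scenario, times, seed)
        if rec.failure is not None:
            n_failed += 1
            continue
        any_entry_failed = False
        for e in rec.entries:
            t_idx = spec.time_indices[e["time_index"]]
            if e["failure"] is not None:
                any_entry_failed = True
                continue
            rows.append(
                {
                    "replicate": r,
                    "time_index": t_idx,
                    "time_label": TIME_LABELS[t_idx],
                    "t0": e["t0"],
                    "n_knots": e["n_knots"],
                    "ICI": e["ICI"],
                    "E50": e["E50"],
                    "E90": e["E90"],
                    "Emax": e["Emax"],
                }
            )
            curve_entries.setdefault((t_idx, e["n_knots"]), []).append(e)
        if any_entry_failed:
            n_failed += 1
    curves = {
        key: _aggregate_curves(entries) for key, entries in curve_entries.items()
    }
    return ScenarioResult(
        scenario=scenario,
        times=times,
        time_indices=spec.time_indices,
        metrics=pd.DataFrame(rows),
        curves=curves,
        n_replicates=spec.replicates,
        n_failed=n_failed,
    )


def run_study(spec: StudySpec) -> list[ScenarioResult]:
    """Run every grid cell of a study (optionally restricted by ``subset``)."""
    return [
        run_scenario(s, spec, i) for i, s in enumerate(spec.resolve_scenarios())
    ]


def summarize(results: list[ScenarioResult]) -> pd.DataFrame:
    """Tidy per-scenario/time/knot summary of the calibration metrics.

    Means and standard deviations across replicates; SD is NaN when only a
    single replicate converged.
    """
    if not results:
        raise ValueError("no results to summarize")
    out = []
    for res in results:
        if res.metrics.empty:
            continue
        grouped = res.metrics.groupby(["time_index", "time_label", "t0", "n_knots"])
        for (t_idx, t_lab, t0, k), g in grouped:
            row = {
                "study": res.scenario.study_name,
                "scenario": res.scenario.label,
                **res.scenario.factors,
                "time_index": t_idx,
                "time_label": t_lab,
                "t0": t0,
                "n_knots": k,
                "n_replicates": len(g),
                "n_failed": res.n_failed,
            }
            for m in ("ICI", "E50", "E90", "Emax"):
                row[f"mean_{m}"] = g[m].mean()
                row[f"sd_{m}"] = g[m].std(ddof=1) if len(g) > 1 else np.nan
            out.append(row)
    return pd.DataFrame(out)


def write_results(results: list[ScenarioResult], out_dir) -> None:
    """Write per-scenario metric and curve CSVs plus a summary table."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, res in enumerate(results):
        tag = f"{res.scenario.study_name}_{i:02d}"
        res.metrics.to_csv(out / f"{tag}_metrics.csv", index=False)
        for (t_idx, k), curve in res.curves.items():
            if curve is not None:
                curve.to_csv(
                    out / f"{tag}_curve_{TIME_LABELS[t_idx]}_k{k}.csv", index=False
                )
    summarize(results).to_csv(out / "summary.csv", index=False)
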