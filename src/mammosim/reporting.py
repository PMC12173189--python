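"""Orchestration: run a fit or a full strategy comparison and write artifacts.

Every CSV artifact starts with comment lines carrying the master seed and the
configuration hash, so a run is reconstructable from its outputs.
"""

from __future__ import annotations

import logging
import os

import pandas as pd

from . import evaluation
from .config import RunConfig
from .estimation import TumorSizeData, fit_mle
from .natural_history import simulate_natural_history
from .screening import apply_screening, natural_history_outcomes

__all__ = ["run_fit", "run_compare"]

log = logging.getLogger("mammosim")


def _write_csv(df: pd.DataFrame, path: str, header_lines) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def run_fit(
    data_path,
    out_dir,
    constrain_equal: bool = True,
    z_multiplier: float = 1.645,
):
    """Fit the symptomatic-size model to a diameter CSV and write artifacts.

    Writes ``fit_result.json`` and an estimates table ``fit_table.csv``;
    raises on unreadable input or non-convergence (callers map this to a
    nonzero exit).
    """
    data = TumorSizeData.from_csv(data_path)
    fit = fit_mle(data, constrain_equal=constrain_equal, z_multiplier=z_multiplier)
    log.info(
        "fit on %d sizes: eta=%.4g b=%.4g loglik=%.3f converged=%s (%s)",
        data.n, fit.eta_hat, fit.b_hat, fit.log_lik, fit.converged, fit.message,
    )
    if not fit.converged:
        raise RuntimeError(f"maximum-likelihood fit did not converge: {fit.message}")
    os.makedirs(out_dir, exist_ok=True)
    fit.to_json(os.path.join(out_dir, "fit_result.json"))
    _write_csv(
        fit.to_table(),
        os.path.join(out_dir, "fit_table.csv"),
        [f"source={os.path.basename(str(data_path))}", f"n_obs={data.n}",
         f"z_multiplier={z_multiplier}"],
    )
    return fit


def run_compare(config: RunConfig, out_dir=None):
    """Simulate one shared natural history and evaluate every scenario on it.

    Writes ``strategy_metrics.csv`` (one row per scenario), a per-scenario
    descriptive table ``descriptive_summary.csv`` (detection-age and size-bin
    summaries for both arms) and ``natural_history_summary.csv`` (onset,
    doubling-time and presence-time summaries).  Returns the three frames.
    """
    out_dir = config.output_dir if out_dir is None else out_dir
    os.makedirs(out_dir, exist_ok=True)
    header = [f"seed={config.seed}", f"config_hash={config.config_hash()}"]

    log.info("simulating natural history: %d individuals", config.cohort.n_individuals)
    hist = simulate_natural_history(
        config.cohort, config.onset, config.growth, config.detection, config.seed
    )
    no_screen = natural_history_outcomes(hist)

    metric_rows, desc_rows, nh_rows = [], [], []
    onset_all = hist.onset_age[hist.has_onset]
    nh_rows.append({"scenario": "-", "quantity": "onset_age", "group": "all_onset",
                    **evaluation.summary_stats(onset_all).as_dict()})

    for sc in config.scenarios:
        log.info("scenario %s: %s", sc.name, sc.policy)
        screened = apply_screening(hist, sc.policy, sc.sensitivity, sc.attendance)
        m = evaluation.strategy_metrics(no_screen, screened, sc.policy)
        metric_rows.append(
            {
                "scenario": sc.name,
                "start_age": sc.policy.start_age,
                "end_age": sc.policy.end_age,
                "interval": sc.policy.interval,
                "attendance": sc.attendance.mode,
                "sensitivity": sc.sensitivity.scenario_label,
                **m.as_dict(),
            }
        )
        win_scr = evaluation.in_window(screened, sc.policy)
        win_abs = evaluation.in_window(no_screen, sc.policy)
        for arm, out, win in (("no_screening", no_screen, win_abs),
                              ("screening", screened, win_scr)):
            ages = evaluation.age_summary(out, restrict=win)
            sizes = evaluation.size_category_table(out.detection_diameter[win])
            desc_rows.append(
                {
                    "scenario": sc.name, "arm": arm, "n_diagnosed": sizes.total,
                    "mean_age": ages.mean, "q1_age": ages.q1, "median_age": ages.median,
                    "q3_age": ages.q3,
                    **{f"n_{lab}": c for lab, c in zip(
                        ("0_9", "10_19", "20_50", "gt50"), sizes.counts)},
                    **{f"pct_{lab}": p for lab, p in zip(
                        ("0_9", "10_19", "20_50", "gt50"), sizes.percentages)},
                }
            )
        for grp, stats in evaluation.doubling_time_summary(hist, screened, restrict=win_scr).items():
            nh_rows.append({"scenario": sc.name, "quantity": "doubling_time_days",
                            "group": grp, **stats.as_dict()})
        if (screened.mode[win_scr] == 2).any():
            nh_rows.append(
                {"scenario": sc.name, "quantity": "presence_time_years", "group": "interval",
                 **evaluation.presence_time_summary(hist, screened, restrict=win_scr).as_dict()}
            )

    metrics = pd.DataFrame(metric_rows)
    descriptive = pd.DataFrame(desc_rows)
    nat_hist = pd.DataFrame(nh_rows)
    _write_csv(metrics, os.path.join(out_dir, "strategy_metrics.csv"), header)
    _write_csv(descriptive, os.path.join(out_dir, "descriptive_summary.csv"), header)
    _write_csv(nat_hist, os.path.join(out_dir, "natural_history_summary.csv"), header)
    return metrics, descriptive, nat_hist
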