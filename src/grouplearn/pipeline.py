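"""Seeded end-to-end orchestration: simulate -> analyze -> report.

``run_pipeline`` produces every analysis artifact from a single
:class:`~grouplearn.io.RunConfig` and writes a machine-readable summary
whose bytes depend only on the config (including its seed), so identical
runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assimilation as asm
from . import blockstats as bs
from .design import build_agents, build_schedule, validate_design
from .io import RunConfig, read_trials, write_trials
from .simulate import cohort_designs, simulate_cohort

log = logging.getLogger("grouplearn")


def analyze_trials(trials: pd.DataFrame, config: RunConfig) -> dict:
    """Run the full statistical pipeline on a trial table.

    Returns a nested dict of results (divergence tables and ANOVAs for both
    blocks, assimilation series with last-trial Wilcoxon and logarithmic
    regression).  The tables themselves are included under DataFrame keys
    for export by the caller.
    """
    n = int(trials["participant_id"].nunique())
    designs = cohort_designs(
        int(trials["participant_id"].max()) + 1, config.design
    )

    results: dict = {"n_participants": n}
    for block in (1, 2):
        if not (trials["block"] == block).any():
            continue
        table = bs.divergence_table(
            trials,
            designs,
            block=block,
            pseudocount=config.pseudocount,
            block2_agent_set=config.block2_agent_set,
        )
        anova = bs.rm_anova_2x2(table)
        posthoc = bs.posthoc_level_tests(table)
        results[f"block{block}"] = {
            "table": table,
            "anova": anova.to_dict(),
            "posthoc": {lvl: vars(t) for lvl, t in posthoc.items()},
        }

    series = asm.assimilation_series(
        trials,
        designs,
        pseudocount=config.pseudocount,
        pairwise=config.assimilation_pairwise,
    )
    wilcoxon = asm.last_trial_test(series)
    diff = asm.condition_difference_series(series)
    regression = asm.fit_log_regression(diff)
    miss_rate = float(trials["missed"].mean())
    results["assimilation"] = {
        "series": series,
        "diff_series": diff,
        "wilcoxon": vars(wilcoxon),
        "log_regression": vars(regression),
    }
    results["miss_fraction"] = miss_rate
    results["designs"] = designs
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _figures(results: dict, trials: pd.DataFrame, outdir: Path) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    designs = results["designs"]
    points = asm.prediction_points(trials, designs)

    fig, ax = plt.subplots(figsize=(6, 6))
    for cond, color in (("Logo", "tab:orange"), ("NoLogo", "tab:blue")):
        sub = points[points["condition"] == cond]
        xy = sub[["p_color", "p_shape"]].to_numpy()
        try:
            (gx, gy), dens, _ = asm.kde_scott(xy, grid_size=80)
            ax.contour(gx, gy, dens, levels=6, colors=color)
        except ValueError:
            pass
        ax.scatter(xy[:, 0], xy[:, 1], s=8, alpha=0.4, color=color, label=cond)
    ax.set_xlabel("P(color = A) of prediction distribution")
    ax.set_ylabel("P(shape = A) of prediction distribution")
    ax.legend()
    fig.savefig(outdir / "prediction_kde.png", dpi=120)
    plt.close(fig)
    written.append("prediction_kde.png")

    series = results["assimilation"]["series"]
    diff = results["assimilation"]["diff_series"]
    reg = results["assimilation"]["log_regression"]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for cond, color in (("Logo", "tab:orange"), ("NoLogo", "tab:blue")):
        m = series[series["condition"] == cond].groupby("k")["dispersion_bits"].mean()
        ax.plot(m.index, m.to_numpy(), color=color, label=cond)
    ax.scatter(diff["k"], diff["mean_diff_bits"], s=12, color="k",
               label="NoLogo - Logo")
    kk = np.linspace(1, diff["k"].max(), 200)
    ax.plot(kk, reg["beta0"] + reg["beta1"] * np.log(kk), "k-")
    ax.set_xlabel("presentation index k")
    ax.set_ylabel("dispersion (bits)")
    ax.legend()
    fig.savefig(outdir / "assimilation_timecourse.png", dpi=120)
    plt.close(fig)
    written.append("assimilation_timecourse.png")
    return written


def run_pipeline(config: RunConfig, trials: pd.DataFrame | None = None) -> dict:
    """Simulate (unless ``trials`` is supplied), analyze, and write the
    report bundle to ``config.output_dir``.

    Returns the summary dict also written to ``summary.json``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    cfg_dict = config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()[:16]

    if trials is None:
        log.info("simulating %d participants (seed %d)", config.n_participants, config.seed)
        trials = simulate_cohort(
            config.n_participants, config.learner, config.design, config.seed
        )
        write_trials(trials, outdir / "trials.csv")

    # design validation for participant 0's variant
    cfg0 = config.design.variant_for(0)
    agents0 = build_agents(cfg0)
    rng0 = np.random.default_rng(config.seed)
    report = validate_design(agents0, build_schedule(agents0, cfg0, rng0), cfg0)
    if not report.passed:
        log.warning("design validation failures: %s", report.failures())

    log.info("analyzing %d trials", len(trials))
    results = analyze_trials(trials, config)

    for block in (1, 2):
        if f"block{block}" in results:
            results[f"block{block}"]["table"].to_csv(
                outdir / f"divergence_block{block}.csv", index=False
            )
    results["assimilation"]["series"].to_csv(
        outdir / "assimilation_series.csv", index=False
    )
    results["assimilation"]["diff_series"].to_csv(
        outdir / "assimilation_diff.csv", index=False
    )

    figures = []
    if config.make_figures:
        figures = _figures(results, trials, outdir)

    summary = {
        "config": cfg_dict,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "design_valid": report.passed,
        "n_participants": results["n_participants"],
        "miss_fraction": results["miss_fraction"],
        "figures": figures,
    }
    for block in (1, 2):
        key = f"block{block}"
        if key in results:
            summary[key] = {
                "anova": results[key]["anova"],
                "posthoc": results[key]["posthoc"],
            }
    summary["assimilation"] = {
        "wilcoxon": results["assimilation"]["wilcoxon"],
        "log_regression": results["assimilation"]["log_regression"],
    }
    summary = _jsonable(summary)
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("wrote %s", outdir / "summary.json")
    return summary
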