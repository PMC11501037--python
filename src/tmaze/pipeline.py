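"""End-to-end orchestration: trial logs in, analysis bundle out.

``run_pipeline`` chains the full decision-profiling analysis — inclusion
filter, choice descriptors, archetypal analysis with semantic labels,
per-animal reinforcement-learning fits with nested-model comparison, the
requested counterfactual simulations, and home-cage metrics correlated with
archetypal composition — writing every table as delimited text plus a
structured run manifest.  Inputs are either files (trial log, event log) or
a synthetic-generation block; a master seed is mandatory, and every
stochastic stage derives its child seed from it, so a rerun with the same
config reproduces every table byte for byte.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from . import __version__
from .archetypes import composition_table, fit_archetypes, label_archetypes
from .choice_simulator import (
    attribution_study,
    cross_context_prediction,
    delta_v_sweep,
)
from .descriptors import descriptor_matrix
from .rl_model import FitConfig, compare_models, fit_mouse, fit_reduced
from .synthetic_cohort import generate_cohort
from .tracking_metrics import correlate_with_composition, metrics_table, read_event_log
from .trial_data import Cohort, filter_by_trial_rate, read_trial_log, write_trial_log

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "report_group_stats"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips through YAML."""

    out_dir: str = "tmaze_run"
    master_seed: int | None = None
    trial_log: str | None = None
    event_log: str | None = None
    synthetic: dict | None = None  # e.g. {"n_per_profile": 20}
    min_trials_per_day: float = 5.0
    descriptor_scaling: str = "minmax"
    aa_k: int = 3
    aa_restarts: int = 10
    aa_tol: float = 1e-8
    fit_n_starts: int = 20
    fit_tol: float = 1e-8
    v0_fit: float = 0.0
    sweep: dict | None = None  # {"dv_grid": [...], "n_replicates": int}
    attribution_modes: list = field(default_factory=list)
    cross_context: bool = False
    verbose: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic is not None:
        n = cfg.synthetic.get("n_per_profile", 20)
        cohort, events, manifest = generate_cohort(n, seed=cfg.master_seed)
        return cohort, events, manifest
    if cfg.trial_log is None:
        raise ValueError("config needs either a trial_log path or a synthetic block")
    cohort = read_trial_log(cfg.trial_log)
    events = read_event_log(cfg.event_log) if cfg.event_log else None
    return cohort, events, None


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the full analysis chain; returns the in-memory bundle.

    Writes to ``cfg.out_dir``: ``trials.csv``, ``descriptors.csv``,
    ``composition.csv``, ``fits.csv``, and — when configured — ``sweep.csv``,
    ``attribution_<mode>.csv``, ``cross_context.csv``, ``metrics.csv``,
    ``correlations.csv``, ``regressions.csv``, plus ``run_manifest.yaml``
    and ``summary.txt``.  Aborts with :class:`PipelineError` naming the
    failing stage; a FAILED marker file is left next to any partial output.
    """
    if cfg.master_seed is None:
        raise ValueError("config.master_seed is required: refusing silent nondeterminism")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {}
    timings: dict[str, float] = {}
    stage = "load"
    try:
        t0 = time.perf_counter()
        cohort, events, manifest = _load_inputs(cfg)
        cohort = filter_by_trial_rate(cohort, cfg.min_trials_per_day)
        if len(cohort) == 0:
            raise ValueError("no animal passes the trial-rate filter")
        write_trial_log(cohort, out / "trials.csv")
        if manifest is not None:
            manifest.to_csv(out / "ground_truth.csv", index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "descriptors"
        t0 = time.perf_counter()
        dmat = descriptor_matrix(cohort, scaling=cfg.descriptor_scaling)
        dmat.to_frame().to_csv(out / "descriptors.csv")
        timings[stage] = time.perf_counter() - t0

        stage = "archetypes"
        t0 = time.perf_counter()
        model = fit_archetypes(
            dmat.values, k=cfg.aa_k, n_restarts=cfg.aa_restarts,
            tol=cfg.aa_tol, seed=cfg.master_seed,
        )
        labels = label_archetypes(model, dmat) if cfg.aa_k == 3 else None
        comp = composition_table(model, dmat.mouse_ids, labels)
        comp.to_csv(out / "composition.csv")
        with open(out / "archetype_model.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "Z_scaled": model.Z.tolist(),
                    "Z_raw": dmat.unscale(model.Z).tolist(),
                    "rss": float(model.rss),
                    "labels": labels,
                    "seed": cfg.master_seed,
                },
                fh, sort_keys=False,
            )
        timings[stage] = time.perf_counter() - t0

        stage = "fit"
        t0 = time.perf_counter()
        fit_rows = []
        for i, rec in enumerate(cohort):
            fc = FitConfig(n_starts=cfg.fit_n_starts, tol=cfg.fit_tol,
                           seed=cfg.master_seed + i, v0=cfg.v0_fit)
            full = fit_mouse(rec, fc)
            red = fit_reduced(rec, fc)
            cmpres = compare_models(full, red)
            fit_rows.append({
                "mouse_id": rec.mouse_id,
                "alpha": full.triplet.alpha, "beta": full.triplet.beta,
                "chi": full.triplet.chi, "nll": full.nll, "bic": full.bic,
                "converged": full.converged,
                "alpha_reduced": red.triplet.alpha, "beta_reduced": red.triplet.beta,
                "nll_reduced": red.nll, "bic_reduced": red.bic,
                "delta_bic": cmpres["delta_bic"], "lrt_p": cmpres["lrt_p"],
                "n_trials": rec.n_trials,
                "trials_per_day": rec.trials_per_day,
                "label": comp.loc[rec.mouse_id, "nearest"],
            })
        fits = pd.DataFrame(fit_rows)
        fits.to_csv(out / "fits.csv", index=False)
        bundle["fits"] = fits
        timings[stage] = time.perf_counter() - t0

        triplets_by_group = {
            g: [tuple(r) for r in sub[["alpha", "beta", "chi"]].to_numpy()]
            for g, sub in fits.groupby("label")
        }
        from .rl_model import LatentTriplet

        triplets_by_group = {
            g: [LatentTriplet(*t) for t in ts] for g, ts in triplets_by_group.items()
        }

        if cfg.sweep is not None:
            stage = "sweep"
            t0 = time.perf_counter()
            sw = delta_v_sweep(
                triplets_by_group,
                dv_grid=cfg.sweep.get("dv_grid", (-1.0, 0.0, 1.0, 2.0, 3.0)),
                n_replicates=cfg.sweep.get("n_replicates", 200),
                seed=cfg.master_seed,
            )
            sw.table.to_csv(out / "sweep.csv", index=False)
            bundle["sweep"] = sw
            timings[stage] = time.perf_counter() - t0

        for mode in cfg.attribution_modes:
            stage = f"attribution:{mode}"
            t0 = time.perf_counter()
            res = attribution_study(fits, mode, seed=cfg.master_seed)
            res.per_animal.to_csv(out / f"attribution_{mode}.csv", index=False)
            bundle[f"attribution_{mode}"] = res
            timings[stage] = time.perf_counter() - t0

        if cfg.cross_context:
            stage = "cross_context"
            t0 = time.perf_counter()
            trips = [LatentTriplet(r.alpha, r.beta, r.chi) for r in fits.itertuples()]
            cc = cross_context_prediction(
                trips, labels=list(fits["label"]), seed=cfg.master_seed
            )
            cc.to_csv(out / "cross_context.csv", index=False)
            bundle["cross_context"] = cc
            timings[stage] = time.perf_counter() - t0

        if events is not None:
            stage = "tracking"
            t0 = time.perf_counter()
            mt = metrics_table(events)
            mt.to_csv(out / "metrics.csv")
            corr, reg = correlate_with_composition(mt, comp)
            corr.to_csv(out / "correlations.csv", index=False)
            reg.to_csv(out / "regressions.csv", index=False)
            bundle["metrics"] = mt
            bundle["correlations"] = corr
            timings[stage] = time.perf_counter() - t0

        bundle.update({"cohort": cohort, "descriptors": dmat,
                       "archetypes": model, "composition": comp})

        with open(out / "run_manifest.yaml", "w") as fh:
            yaml.safe_dump(
                {"tmaze_version": __version__, "master_seed": cfg.master_seed,
                 "config": asdict(cfg), "timings_s": timings},
                fh, sort_keys=False,
            )
        counts = comp["nearest"].value_counts()
        with open(out / "summary.txt", "w") as fh:
            fh.write(f"animals analysed: {len(cohort)}\n")
            fh.write("archetype counts: "
                     + ", ".join(f"{k}={v}" for k, v in counts.items()) + "\n")
            fh.write(f"archetypal RSS: {model.rss:.6g}\n")
            fh.write(f"median fitted alpha={fits.alpha.median():.3f} "
                     f"beta={fits.beta.median():.3f} chi={fits.chi.median():.3f}\n")
        return bundle
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage!r}: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc


def report_group_stats(
    values: pd.DataFrame,
    value_col: str,
    group_col: str = "label",
    test: str = "mannwhitney",
) -> pd.DataFrame:
    """Pairwise nonparametric group comparisons with Holm correction.

    A thin reporting helper delegating to scipy rank tests and the
    statsmodels Holm procedure; one row per group pair with the statistic,
    raw and adjusted p.  Pairs with a group of fewer than two observations
    get NaN statistics.
    """
    groups = {g: sub[value_col].dropna().to_numpy()
              for g, sub in values.groupby(group_col)}
    names = sorted(groups)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = groups[names[i]], groups[names[j]]
            if len(a) < 2 or len(b) < 2:
                stat, p = np.nan, np.nan
            elif test == "mannwhitney":
                stat, p = sstats.mannwhitneyu(a, b, alternative="two-sided")
            elif test == "wilcoxon":
                stat, p = sstats.wilcoxon(a, b)
            else:
                raise ValueError(f"unknown test {test!r}")
            rows.append({"group_1": names[i], "group_2": names[j],
                         "test": test, "statistic": float(stat), "p_raw": float(p)})
    df = pd.DataFrame(rows)
    if len(df) == 0:
        return df
    mask = df["p_raw"].notna()
    adj = np.full(len(df), np.nan)
    if mask.any():
        adj[mask.to_numpy()] = multipletests(df.loc[mask, "p_raw"], method="holm")[1]
    df["p_holm"] = adj
    return df
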