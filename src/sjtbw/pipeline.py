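"""End-to-end study pipeline: trials -> curves -> indices -> inference.

``run_study`` takes a :class:`StudyConfig`, obtains a trial table (simulated
or read from CSV), applies trial selection, pools each participant's sessions
within a condition, fits the Gaussian simultaneity curve, derives
binding-window indices, and runs the inferential battery: the paired Wilcoxon
comparison of HWHH between conditions with effect sizes and post-hoc power,
Spearman correlations of any perceptual-dimension ratings with HWHH, and an
a-priori two-group sample-size calculation from the observed group summaries.

The report is a plain dict serialisable to JSON (floats at 10 significant
digits, so identical configurations reproduce byte-identical files) with
companion TSV tables for spreadsheet use.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .inferential import (
    GroupSummary,
    PairedSummary,
    cohens_d_pooled,
    cohens_dz,
    effect_size_r,
    no_correlation_test,
    spearman_rho,
    wilcoxon_signed_rank,
)
from .io import read_ratings_csv, read_trials_csv, write_trials_csv
from .power import (
    power_correlation_exact,
    power_wilcoxon_matched,
    sample_size_wmw,
)
from .psychometric import FitError, fit_gaussian, goodness_of_fit, tbw_indices
from .synthetic_observer import (
    CohortConfig,
    simulate_cohort,
    simulate_ratings,
)
from .trial_prep import bin_trials, default_window_edges, select_trials

logger = logging.getLogger("sjtbw")

GOF_WARN_THRESHOLD = 0.4


@dataclass
class StudyConfig:
    """Configuration of one pipeline run.

    ``mode`` is "simulate" (generate a cohort) or "read" (load trial CSVs).
    In read mode ``trials_path`` must exist; ``ratings_path`` is optional in
    both modes (simulate mode synthesises one rating dimension when
    ``simulate_ratings`` is true).
    """

    mode: str = "simulate"
    trials_path: Optional[str] = None
    ratings_path: Optional[str] = None
    n_participants: int = 10
    n_sessions_per_condition: int = 3
    between_condition_correlation: float = 0.71
    simulate_ratings: bool = True
    window_edges_ms: Optional[list[float]] = None
    session_pooling: str = "pooled"  # "pooled" | "per_session"
    alpha: float = 0.05
    power_target: float = 0.80
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "read"):
            raise ValueError("mode must be 'simulate' or 'read'")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.mode == "read":
            if not self.trials_path:
                raise ValueError("read mode requires trials_path")
            if not Path(self.trials_path).exists():
                raise FileNotFoundError(self.trials_path)
        if self.session_pooling not in ("pooled", "per_session"):
            raise ValueError("session_pooling must be 'pooled' or 'per_session'")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StudyConfig":
        return cls(**json.loads(text))

    def sha256(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _round_floats(obj: Any, sig: int = 10) -> Any:
    """Round all floats to ``sig`` significant digits for stable serialisation."""
    if isinstance(obj, float):
        if not math.isfinite(obj):
            return None
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), sig)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _fit_one(trials: pd.DataFrame, edges: np.ndarray) -> dict[str, Any]:
    selection = select_trials(trials)
    binned = bin_trials(selection, edges)
    fit = fit_gaussian(binned)
    gof = goodness_of_fit(binned, fit)
    idx = tbw_indices(fit, binned)
    if math.isfinite(gof) and gof < GOF_WARN_THRESHOLD:
        logger.warning("goodness-of-fit %.3f below %.1f", gof,
                       GOF_WARN_THRESHOLD)
    return {
        "selection": {
            "n_total": selection.n_total,
            "n_retained": selection.n_retained,
            "adoption_rate": selection.adoption_rate,
        },
        "fit": {"a": fit.a, "b": fit.b, "c": fit.c, "sse": fit.sse,
                "converged": fit.converged,
                "n_windows_used": fit.n_windows_used},
        "goodness_of_fit": gof,
        "indices": {
            "hwhh_s": idx.hwhh_s, "fwhh_s": idx.fwhh_s,
            "sigma_s": idx.sigma_s, "width75_s": idx.width75_s,
            "jnd75_s": idx.jnd75_s, "delta50_s": idx.delta50_s,
        },
        "binned": binned,
    }


def _comparison_block(hwhh: pd.DataFrame, conditions: Sequence[str],
                      alpha: float) -> dict[str, Any]:
    wide = hwhh.pivot(index="participant_id", columns="condition",
                      values="hwhh_s")
    complete = wide.dropna()
    n_incomplete = len(wide) - len(complete)
    c1, c2 = conditions
    x1 = complete[c1].to_numpy()
    x2 = complete[c2].to_numpy()
    def _sd(v: np.ndarray) -> float:
        return float(v.std(ddof=1)) if len(v) >= 2 else float("nan")

    out: dict[str, Any] = {
        "conditions": [c1, c2],
        "n_pairs": len(complete),
        "n_incomplete_pairs": n_incomplete,
        "mean": {c1: float(x1.mean()), c2: float(x2.mean())},
        "sd": {c1: _sd(x1), c2: _sd(x2)},
    }
    n_entered = 2 * len(complete)  # participants x conditions convention
    try:
        wres = wilcoxon_signed_rank(x1, x2)
        out["wilcoxon"] = {"W": wres.W, "z": wres.z,
                           "p_two_sided": wres.p_two_sided,
                           "p_exact": wres.p_exact,
                           "n_nonzero": wres.n_nonzero}
        out["effect_size_r"] = effect_size_r(wres.z, n_entered)
    except ValueError as exc:
        out["wilcoxon"] = {"error": str(exc)}
    try:
        summary = PairedSummary.from_pairs(x1, x2)
        out["rho_between_conditions"] = summary.rho
        dz = cohens_dz(summary)
        out["cohens_dz"] = dz
        pres = power_wilcoxon_matched(dz, n_entered, alpha=alpha)
        out["posthoc_power"] = pres.power
    except ValueError as exc:
        out["cohens_dz"] = None
        out["posthoc_power"] = None
        out["effect_size_error"] = str(exc)
    # a-priori two-group sample size from the observed group summaries
    g1 = GroupSummary(mean=out["mean"][c1], sd=out["sd"][c1], n=len(complete))
    g2 = GroupSummary(mean=out["mean"][c2], sd=out["sd"][c2], n=len(complete))
    try:
        d = cohens_d_pooled(g1, g2)
        if not math.isfinite(d) or d <= 0:
            raise ValueError("group effect size not estimable")
        ss = sample_size_wmw(d, alpha=alpha)
        out["a_priori"] = {"cohens_d_pooled": d, "n_total": ss.n_total,
                           "n_per_group": ss.n_group_1,
                           "achieved_power": ss.achieved_power}
    except ValueError as exc:
        out["a_priori"] = {"error": str(exc)}
    return out


def _correlation_block(hwhh: pd.DataFrame, ratings: pd.DataFrame,
                       alpha: float) -> dict[str, Any]:
    merged = ratings.merge(hwhh, on=["participant_id", "condition"],
                           how="inner")
    blocks: dict[str, Any] = {}
    for dim, sub in merged.groupby("dimension"):
        rho = spearman_rho(sub["value"].to_numpy(), sub["hwhh_s"].to_numpy())
        block: dict[str, Any] = {"rho": rho, "n": len(sub)}
        if math.isfinite(rho) and abs(rho) < 1.0 and len(sub) >= 4:
            res = no_correlation_test(rho, len(sub))
            block.update(t=res.t, df=res.df, p_two_sided=res.p_two_sided,
                         strength_label=res.strength_label)
            block["posthoc_power"] = power_correlation_exact(
                rho, len(sub), alpha=alpha).power
        blocks[str(dim)] = block
    return blocks


def run_study(config: StudyConfig) -> dict[str, Any]:
    """Run the full analysis chain and return the study report dict.

    Deterministic given the config (including its seed).  Per-participant
    fit failures are recorded in the report and the comparison proceeds on
    the complete pairs.
    """
    edges = (np.asarray(config.window_edges_ms, dtype=float)
             if config.window_edges_ms is not None else default_window_edges())

    ratings = None
    if config.mode == "simulate":
        cohort = CohortConfig(
            n_participants=config.n_participants,
            n_sessions_per_condition=config.n_sessions_per_condition,
            between_condition_correlation=config.between_condition_correlation,
            seed=config.seed,
        )
        trials, truth = simulate_cohort(cohort, return_truth=True)
        if config.simulate_ratings:
            ratings = simulate_ratings(truth, seed=config.seed + 1)
    else:
        trials = read_trials_csv(config.trials_path)
    if config.ratings_path:
        ratings = read_ratings_csv(config.ratings_path)

    conditions = list(pd.unique(trials["condition"]))
    participants_out = []
    hwhh_rows = []
    binned_rows = []
    selection_by_condition: dict[str, dict[str, float]] = {}
    for cond in conditions:
        cond_trials = trials[trials["condition"] == cond]
        sel = select_trials(cond_trials)
        selection_by_condition[cond] = {
            "n_total": sel.n_total, "n_retained": sel.n_retained,
            "adoption_rate": sel.adoption_rate,
        }
    for (pid, cond), sub in trials.groupby(["participant_id", "condition"],
                                           sort=True):
        entry: dict[str, Any] = {"participant_id": pid, "condition": cond}
        try:
            result = _fit_one(sub, edges)
        except (FitError, ValueError) as exc:
            logger.warning("fit failed for %s/%s: %s", pid, cond, exc)
            entry["error"] = str(exc)
            participants_out.append(entry)
            continue
        binned = result.pop("binned")
        bf = binned.to_frame()
        bf.insert(0, "condition", cond)
        bf.insert(0, "participant_id", pid)
        binned_rows.append(bf)
        entry.update(result)
        participants_out.append(entry)
        hwhh_rows.append({"participant_id": pid, "condition": cond,
                          "hwhh_s": result["indices"]["hwhh_s"]})

    hwhh = pd.DataFrame(hwhh_rows)
    report: dict[str, Any] = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config_sha256": config.sha256(),
        },
        "n_trials_input": int(len(trials)),
        "selection_by_condition": selection_by_condition,
        "participants": participants_out,
    }
    if len(conditions) == 2 and len(hwhh) > 0:
        report["comparison"] = _comparison_block(hwhh, conditions, config.alpha)
    if ratings is not None and len(hwhh) > 0:
        report["correlations"] = _correlation_block(hwhh, ratings, config.alpha)

    report = _round_floats(report)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        _participants_tsv(participants_out).to_csv(
            out / "participant_indices.tsv", sep="\t", index=False,
            float_format="%.10g")
        if binned_rows:
            pd.concat(binned_rows, ignore_index=True).to_csv(
                out / "binned_rates.tsv", sep="\t", index=False,
                float_format="%.10g")
        if config.mode == "simulate":
            write_trials_csv(trials, out / "trials.csv")
    return report


def _participants_tsv(entries: list[dict[str, Any]]) -> pd.DataFrame:
    rows = []
    for e in entries:
        row: dict[str, Any] = {"participant_id": e["participant_id"],
                               "condition": e["condition"]}
        if "error" in e:
            row["error"] = e["error"]
        else:
            row.update({f"fit_{k}": v for k, v in e["fit"].items()})
            row["goodness_of_fit"] = e["goodness_of_fit"]
            row.update(e["indices"])
            row["adoption_rate"] = e["selection"]["adoption_rate"]
        rows.append(row)
    return pd.DataFrame(rows)
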