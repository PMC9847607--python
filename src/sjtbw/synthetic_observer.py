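"""Synthetic observers for olfactory-gustatory simultaneity-judgment tasks.

No raw trial data accompany the study design this package analyses, so this
module generates them: trial sequences with the design's constraints (23
nominal SOA steps, 92 trials per session, each step four times, never the
same step twice in a row), apparatus jitter between nominal and actual SOA,
occasional missing responses, and per-observer Gaussian simultaneity curves

    P(simultaneous | t) = a * exp(-(t - b)^2 / (2 c^2)),   t in seconds,

the same model the analysis fits back.  A cohort draws per-participant
(a, b, c) from hyperpriors, with the Gaussian width c correlated between the
two conditions through a Gaussian copula so that paired effect sizes behave
like real within-subject data.

Randomness: every public entry point takes a single integer seed; cohort
simulation splits it into per-participant streams with
``numpy.random.SeedSequence.spawn`` so any sub-unit is reproducible on its
own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trial_prep import (
    NOMINAL_SOA_STEPS_MS,
    RESPONSE_NONE,
    RESPONSE_SIMULTANEOUS,
    RESPONSE_SUCCESSIVE,
    TRIAL_COLUMNS,
    TrialRecord,
)

TRIALS_PER_SEQUENCE = 92
REPEATS_PER_SOA = 4
#: Training SOAs in presentation order (ms).
TRAINING_SOAS_MS = (0, -800, 400, 800, -400)


@dataclass(frozen=True)
class ObserverModel:
    """Generative parameters of one simulated observer.

    Parameters
    ----------
    amplitude
        Peak simultaneous-response probability ``a`` (0-1).
    center_s
        Point of subjective simultaneity ``b``, in seconds of SOA.
    width_s
        Gaussian scale ``c`` in seconds; larger means a wider temporal
        binding window.
    lapse_rate
        Probability of giving no response on a trial.
    jitter_sd_ms
        SD of the Gaussian discrepancy between nominal and actual SOA.
    """

    amplitude: float
    center_s: float
    width_s: float
    lapse_rate: float = 0.0
    jitter_sd_ms: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError(f"amplitude must be in [0, 1], got {self.amplitude}")
        if not self.width_s > 0.0:
            raise ValueError(f"width_s must be positive, got {self.width_s}")
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ValueError(f"lapse_rate must be in [0, 1), got {self.lapse_rate}")
        if self.jitter_sd_ms < 0.0:
            raise ValueError(f"jitter_sd_ms must be >= 0, got {self.jitter_sd_ms}")

    def p_simultaneous(self, t_s: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t_s, dtype=float)
        return self.amplitude * np.exp(
            -((t - self.center_s) ** 2) / (2.0 * self.width_s**2)
        )


@dataclass(frozen=True)
class ObserverPrior:
    """Hyperprior from which per-participant observer parameters are drawn.

    Widths are lognormal (positivity), amplitudes truncated normal on [0, 1];
    moments are matched so ``width_mean_s``/``width_sd_s`` are the actual mean
    and SD of the lognormal.  Lapse rate and jitter are fixed cohort-wide.
    """

    amplitude_mean: float
    amplitude_sd: float
    center_mean_s: float
    center_sd_s: float
    width_mean_s: float
    width_sd_s: float
    lapse_rate: float = 0.0
    jitter_sd_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.width_mean_s <= 0 or self.width_sd_s < 0:
            raise ValueError("width hyperprior needs positive mean, sd >= 0")
        if self.amplitude_sd < 0 or self.center_sd_s < 0:
            raise ValueError("hyperprior SDs must be >= 0")

    def _lognorm_params(self) -> tuple[float, float]:
        # moment-matched lognormal: mean m, sd s -> (mu, sigma) of log
        m, s = self.width_mean_s, self.width_sd_s
        if s == 0:
            return math.log(m), 0.0
        sigma2 = math.log1p((s / m) ** 2)
        mu = math.log(m) - sigma2 / 2.0
        return mu, math.sqrt(sigma2)

    def width_from_uniform(self, u: np.ndarray) -> np.ndarray:
        """Lognormal quantile transform; used by the cohort copula."""
        mu, sigma = self._lognorm_params()
        if sigma == 0.0:
            return np.full_like(np.asarray(u, dtype=float), math.exp(mu))
        return np.exp(mu + sigma * stats.norm.ppf(u))

    def draw_amplitude(self, rng: np.random.Generator) -> float:
        if self.amplitude_sd == 0.0:
            return float(np.clip(self.amplitude_mean, 0.0, 1.0))
        lo = (0.0 - self.amplitude_mean) / self.amplitude_sd
        hi = (1.0 - self.amplitude_mean) / self.amplitude_sd
        return float(stats.truncnorm.rvs(lo, hi, loc=self.amplitude_mean,
                                         scale=self.amplitude_sd,
                                         random_state=rng))

    def draw_center(self, rng: np.random.Generator) -> float:
        return float(rng.normal(self.center_mean_s, self.center_sd_s))


def reference_condition_priors() -> dict[str, ObserverPrior]:
    """Default hyperpriors for the two odor-taste congruency conditions.

    Group-level curve shapes follow the study design this generator emulates:
    the congruent (soy-sauce odor + saline) condition has a wider, slightly
    odor-leading curve (a = 0.73, b = -0.16 s, c mean 0.44 s) than the
    incongruent (cherry-leaf odor + saline) condition (a = 0.76, b = -0.11 s,
    c mean 0.32 s); width SDs reproduce the reported between-participant
    spread of the binding-window index.  Lapse rate 1% matches ~99% trial
    adoption; 30-ms jitter is a modeling choice for the apparatus noise.
    """
    return {
        "congruent": ObserverPrior(
            amplitude_mean=0.73, amplitude_sd=0.12,
            center_mean_s=-0.16, center_sd_s=0.10,
            width_mean_s=0.44, width_sd_s=0.195,
            lapse_rate=0.01, jitter_sd_ms=30.0,
        ),
        "incongruent": ObserverPrior(
            amplitude_mean=0.76, amplitude_sd=0.12,
            center_mean_s=-0.11, center_sd_s=0.10,
            width_mean_s=0.32, width_sd_s=0.10,
            lapse_rate=0.01, jitter_sd_ms=30.0,
        ),
    }


@dataclass
class CohortConfig:
    """Design of a simulated cohort.

    ``between_condition_correlation`` is the target Spearman correlation of
    per-participant widths across the two conditions, realised through a
    Gaussian copula.
    """

    n_participants: int = 10
    n_sessions_per_condition: int = 3
    condition_priors: dict[str, ObserverPrior] = field(
        default_factory=reference_condition_priors)
    between_condition_correlation: float = 0.71
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_sessions_per_condition < 1:
            raise ValueError("n_sessions_per_condition must be >= 1")
        if not -1.0 <= self.between_condition_correlation <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")
        if len(self.condition_priors) != 2:
            raise ValueError("exactly two condition priors are required")


def make_test_sequence(seed: int | np.random.Generator) -> list[int]:
    """Randomised 92-trial SOA sequence for one test session.

    Each of the 23 nominal steps appears exactly four times and the same SOA
    never occurs on consecutive trials.  Permutations are resampled until the
    no-repeat constraint holds (always feasible: no step exceeds 4/92 of the
    sequence), so the result is deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    pool = np.repeat(NOMINAL_SOA_STEPS_MS, REPEATS_PER_SOA)
    while True:
        perm = rng.permutation(pool)
        if not np.any(perm[1:] == perm[:-1]):
            return [int(x) for x in perm]


def make_training_sequence() -> list[int]:
    """The fixed five-trial training order of nominal SOAs (ms)."""
    return list(TRAINING_SOAS_MS)


def simulate_trials(
    observer: ObserverModel,
    sequence: Sequence[float],
    seed: int | np.random.Generator,
    participant_id: str = "P01",
    condition: str = "congruent",
    session: int = 1,
) -> list[TrialRecord]:
    """Simulate one observer's responses to a sequence of nominal SOAs.

    Actual SOA = nominal + Normal(0, jitter_sd_ms).  With probability
    ``lapse_rate`` the trial yields no response; otherwise the probability of
    a "simultaneous" judgment is the observer's Gaussian curve evaluated at
    the actual SOA (in seconds).
    """
    if len(sequence) == 0:
        raise ValueError("sequence must be nonempty")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    nominal = np.asarray(sequence, dtype=float)
    actual = nominal + rng.normal(0.0, observer.jitter_sd_ms, size=len(nominal)) \
        if observer.jitter_sd_ms > 0 else nominal.copy()
    p_sim = np.asarray(observer.p_simultaneous(actual / 1000.0))
    u_lapse = rng.random(len(nominal))
    u_resp = rng.random(len(nominal))
    records = []
    for i in range(len(nominal)):
        if u_lapse[i] < observer.lapse_rate:
            resp = RESPONSE_NONE
        elif u_resp[i] < p_sim[i]:
            resp = RESPONSE_SIMULTANEOUS
        else:
            resp = RESPONSE_SUCCESSIVE
        records.append(TrialRecord(
            participant_id=participant_id, condition=condition,
            session=session, trial_index=i + 1,
            nominal_soa_ms=float(nominal[i]), actual_soa_ms=float(actual[i]),
            response=resp,
        ))
    return records


def _gauss_copula_rho(spearman_rho: float) -> float:
    """Latent normal correlation giving the requested Spearman correlation."""
    return 2.0 * math.sin(math.pi * spearman_rho / 6.0)


def draw_cohort_parameters(config: CohortConfig) -> pd.DataFrame:
    """Draw per-participant observer parameters for both conditions.

    Widths in the two conditions share a Gaussian copula at the configured
    rank correlation; amplitudes and centers are drawn independently per
    condition.  Returns one row per participant x condition with columns
    amplitude, center_s, width_s, lapse_rate, jitter_sd_ms.
    """
    names = list(config.condition_priors)
    rho_g = _gauss_copula_rho(config.between_condition_correlation)
    if not -1.0 <= rho_g <= 1.0:  # cannot happen for |rho_s| <= 1, kept as guard
        raise ValueError("infeasible correlation target")
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_participants)
    rows = []
    for p, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        z1 = rng.standard_normal()
        z2 = rho_g * z1 + math.sqrt(max(0.0, 1.0 - rho_g**2)) \
            * rng.standard_normal()
        u = stats.norm.cdf([z1, z2])
        pid = f"P{p + 1:02d}"
        for cond, ui in zip(names, u):
            prior = config.condition_priors[cond]
            width = float(prior.width_from_uniform(np.array([ui]))[0])
            rows.append({
                "participant_id": pid,
                "condition": cond,
                "amplitude": prior.draw_amplitude(rng),
                "center_s": prior.draw_center(rng),
                "width_s": width,
                "lapse_rate": prior.lapse_rate,
                "jitter_sd_ms": prior.jitter_sd_ms,
            })
    return pd.DataFrame(rows)


def simulate_cohort(
    config: CohortConfig,
    return_truth: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every trial of a cohort.

    Each participant contributes ``92 x n_sessions`` trials per condition.
    Per-participant parameters are drawn once and shared across that
    participant's sessions; every session gets a freshly randomised
    92-trial sequence.

    With ``return_truth=True`` also returns the generating parameter table
    from :func:`draw_cohort_parameters` (useful for recovery studies).
    """
    truth = draw_cohort_parameters(config)
    # trial streams disjoint from the parameter streams: keyed sub-seed
    trial_streams = np.random.SeedSequence((config.seed, 1)).spawn(
        config.n_participants)

    names = list(config.condition_priors)
    frames = []
    for p in range(config.n_participants):
        pid = f"P{p + 1:02d}"
        rng = np.random.default_rng(trial_streams[p])
        for cond in names:
            row = truth[(truth["participant_id"] == pid)
                        & (truth["condition"] == cond)].iloc[0]
            obs = ObserverModel(
                amplitude=min(1.0, float(row["amplitude"])),
                center_s=float(row["center_s"]),
                width_s=float(row["width_s"]),
                lapse_rate=float(row["lapse_rate"]),
                jitter_sd_ms=float(row["jitter_sd_ms"]),
            )
            for sess in range(1, config.n_sessions_per_condition + 1):
                seq = make_test_sequence(rng)
                recs = simulate_trials(obs, seq, rng, participant_id=pid,
                                       condition=cond, session=sess)
                frames.append(pd.DataFrame(
                    [(r.participant_id, r.condition, r.session, r.trial_index,
                      r.nominal_soa_ms, r.actual_soa_ms, r.response)
                     for r in recs],
                    columns=TRIAL_COLUMNS))
    trials = pd.concat(frames, ignore_index=True)
    if return_truth:
        return trials, truth
    return trials


def simulate_ratings(
    truth: pd.DataFrame,
    seed: int,
    dimension: str = "congruency_with_saltiness",
    slope: float = 1.2,
    noise_sd: float = 0.6,
) -> pd.DataFrame:
    """Synthetic perceptual-dimension ratings on the study's 0-6 scale.

    Ratings increase monotonically with the participant's generative binding
    window width (plus Gaussian noise), emulating the observed positive
    association between odor-taste congruency and window width.  This is
    deliberately simple plumbing so the correlation branch of the pipeline
    can be exercised end to end.
    """
    rng = np.random.default_rng(seed)
    w = truth["width_s"].to_numpy(dtype=float)
    z = (w - w.mean()) / (w.std() if w.std() > 0 else 1.0)
    value = np.clip(3.0 + slope * z + rng.normal(0.0, noise_sd, len(w)), 0.0, 6.0)
    return pd.DataFrame({
        "participant_id": truth["participant_id"],
        "condition": truth["condition"],
        "dimension": dimension,
        "value": value,
    })
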