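"""Synthetic clinical-study generator mirroring the trial design.

Two cohorts are emulated: an intermittent-administration (IA) cohort
(default 43 children, 89 fever episodes, q8h dosing) and a
continuous-infusion (CI) cohort (default 38 children, 68 episodes, a
100 mg/kg loading bolus followed by 300 mg/kg/day over 24 h).  CI episodes
contribute two or three samples drawn from protocol windows (post-load
peak, distribution phase, steady state); IA episodes contribute samples at
end-of-infusion, mid-interval and trough of a near-steady-state dosing
interval.

The error model compounds three log-normal/normal levels: a per-episode
clearance random effect (cohort-specific omega), a per-child residual-
error magnitude (log-normal, omega_err) and proportional residual noise.
Observations falling below the 0.5 mg/L limit of quantification are
truncated at the limit and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import LOQ_MG_L, EpisodeRecord
from .pk_model import PopulationParameters, simulate_profiles
from .regimens import DEFAULT_BOLUS_DURATION_H, InfusionEvent, build_regimen
from .virtual_population import TwoPieceLogNormal, calibrate_weight_model

__all__ = ["StudyDesign", "generate_study", "summarize_study"]


@dataclass(frozen=True)
class StudyDesign:
    """Cohort sizes, sampling windows and generator options."""

    n_children_ia: int = 43
    n_episodes_ia: int = 89
    n_children_ci: int = 38
    n_episodes_ci: int = 68
    daily_dose_per_kg: float = 300.0
    loading_mg_per_kg: float = 100.0
    bolus_duration: float = DEFAULT_BOLUS_DURATION_H
    ia_interval: float = 8.0
    #: CI protocol sampling windows (h): post-load peak, distribution, steady state
    ci_windows: tuple[tuple[float, float], ...] = (
        (2.0 / 60.0, 0.5),
        (0.5, 1.5),
        (12.0, 24.0),
    )
    #: probability that a CI episode contributes 3 (vs 2) samples
    p_three_samples_ci: float = 0.4
    #: IA samples: offsets within a near-steady-state dosing interval
    ia_interval_start: float = 24.0
    max_episodes_per_child: int = 4
    #: probability of a >30 min CI disruption handled by re-loading
    interruption_prob: float = 0.0
    weight_model: TwoPieceLogNormal = field(default_factory=calibrate_weight_model)
    weights_ia: tuple[float, ...] | None = None
    weights_ci: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        for coh in ("ia", "ci"):
            n_children = getattr(self, f"n_children_{coh}")
            n_episodes = getattr(self, f"n_episodes_{coh}")
            if n_children < 0 or n_episodes < n_children:
                raise ValueError("episode counts must be >= children counts >= 0")
        if not 0 <= self.p_three_samples_ci <= 1:
            raise ValueError("p_three_samples_ci must lie in [0, 1]")
        if not 0 <= self.interruption_prob <= 1:
            raise ValueError("interruption_prob must lie in [0, 1]")
        prev_end = 0.0
        for lo, hi in self.ci_windows:
            if not (0 <= lo < hi):
                raise ValueError("sampling windows must be positive and ordered")
            if lo < prev_end:
                raise ValueError("sampling windows must not overlap")
            prev_end = hi
        if self.max_episodes_per_child < 1:
            raise ValueError("max_episodes_per_child must be at least 1")


def _assign_episodes(n_children: int, n_episodes: int, max_per: int, rng) -> np.ndarray:
    """Episodes per child: one each, remainder spread randomly up to max_per."""
    if n_children == 0:
        return np.zeros(0, dtype=int)
    counts = np.ones(n_children, dtype=int)
    extra = n_episodes - n_children
    if extra > n_children * (max_per - 1):
        raise ValueError("episode total exceeds children * max_episodes_per_child")
    for _ in range(extra):
        open_idx = np.flatnonzero(counts < max_per)
        counts[open_idx[rng.integers(open_idx.size)]] += 1
    return counts


def _ci_events(design: StudyDesign, weight: float, rng) -> tuple[tuple[InfusionEvent, ...], bool]:
    """CI loading bolus + 24 h constant infusion, optionally interrupted."""
    reg = build_regimen(
        "CI", design.daily_dose_per_kg, weight, n_days=1,
        loading_mg_per_kg=design.loading_mg_per_kg,
        bolus_duration=design.bolus_duration,
    )
    interrupted = design.interruption_prob > 0 and rng.random() < design.interruption_prob
    if not interrupted:
        return reg.events, False
    load, infusion = reg.events
    t_break = rng.uniform(6.0, 12.0)
    gap = rng.uniform(0.5, 2.0)
    t_resume = t_break + gap
    rate = infusion.rate
    part1 = InfusionEvent(infusion.start, t_break - infusion.start, rate * (t_break - infusion.start))
    reload = InfusionEvent(t_resume, design.bolus_duration, design.loading_mg_per_kg * weight)
    end = infusion.start + infusion.duration
    part2 = InfusionEvent(t_resume, end - t_resume, rate * (end - t_resume))
    return (load, part1, reload, part2), True


def _ia_events(design: StudyDesign, weight: float) -> tuple[InfusionEvent, ...]:
    horizon_days = int(np.ceil((design.ia_interval_start + design.ia_interval) / 24.0))
    reg = build_regimen(
        "IA_q8h" if design.ia_interval == 8.0 else "IA_q6h",
        design.daily_dose_per_kg, weight, n_days=horizon_days,
        bolus_duration=design.bolus_duration,
    )
    end = design.ia_interval_start + design.ia_interval
    return tuple(ev for ev in reg.events if ev.start < end)


def _sample_times_ci(design: StudyDesign, rng) -> np.ndarray:
    three = rng.random() < design.p_three_samples_ci
    windows = list(design.ci_windows)
    if not three:
        drop = rng.integers(len(windows))
        windows = [w for i, w in enumerate(windows) if i != drop]
    return np.sort([rng.uniform(lo, hi) for lo, hi in windows])


def _sample_times_ia(design: StudyDesign) -> np.ndarray:
    t0, tau = design.ia_interval_start, design.ia_interval
    return np.array([
        t0 + design.bolus_duration,     # end of infusion
        t0 + tau / 2.0,                 # mid interval
        t0 + tau - 1.0 / 12.0,          # trough (just before next dose)
    ])


def generate_study(
    design: StudyDesign,
    truth: PopulationParameters | None = None,
    seed: np.random.Generator | int | None = None,
) -> list[EpisodeRecord]:
    """Simulate one synthetic study dataset under the given true parameters.

    Per episode a clearance random effect is drawn with the cohort's omega;
    per child an error-magnitude factor exp(kappa), kappa ~ N(0, omega_err^2),
    scales the cohort's proportional residual SD.  Observations are
    model predictions times (1 + eps) truncated below at the limit of
    quantification (flagged).
    """
    truth = truth or PopulationParameters()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    episodes: list[EpisodeRecord] = []
    for cohort in ("IA", "CI"):
        n_children = getattr(design, f"n_children_{cohort.lower()}")
        n_episodes = getattr(design, f"n_episodes_{cohort.lower()}")
        supplied = getattr(design, f"weights_{cohort.lower()}")
        if supplied is not None:
            if len(supplied) != n_children:
                raise ValueError(f"{cohort}: supplied weight list must match n_children")
            weights = np.asarray(supplied, dtype=float)
        else:
            weights = design.weight_model.sample(n_children, rng)
        counts = _assign_episodes(n_children, n_episodes, design.max_episodes_per_child, rng)
        omega = truth.omega_cl(cohort)
        sigma = truth.sigma(cohort)
        kappas = rng.normal(0.0, truth.omega_err, size=n_children)
        ep_no = 0
        for child in range(n_children):
            w = float(weights[child])
            s_child = sigma * np.exp(kappas[child])
            for _ in range(counts[child]):
                ep_no += 1
                eta = rng.normal(0.0, omega) if omega > 0 else 0.0
                if cohort == "CI":
                    events, _ = _ci_events(design, w, rng)
                    times = _sample_times_ci(design, rng)
                else:
                    events = _ia_events(design, w)
                    times = _sample_times_ia(design)
                f_cl = (w / 70.0) ** truth.exp_cl
                f_v = (w / 70.0) ** truth.exp_v
                pred = simulate_profiles(
                    truth.cl_70 * f_cl * np.exp(eta),
                    truth.vc_70 * f_v, truth.q1_70 * f_cl, truth.vp1_70 * f_v,
                    truth.q2_70 * f_cl, truth.vp2_70 * f_v,
                    np.array([ev.start for ev in events]),
                    np.array([ev.duration for ev in events]),
                    np.array([ev.amount for ev in events]),
                    times,
                )[0]
                eps = rng.normal(0.0, s_child, size=times.size) if s_child > 0 else np.zeros(times.size)
                obs = pred * (1.0 + eps)
                bloq = obs < LOQ_MG_L
                obs = np.where(bloq, LOQ_MG_L, obs)
                episodes.append(
                    EpisodeRecord(
                        episode_id=f"{cohort}-{ep_no:03d}",
                        cohort=cohort,
                        weight=w,
                        events=events,
                        times=times,
                        concentrations=obs,
                        bloq=bloq,
                        child_id=f"{cohort}-C{child + 1:03d}",
                    )
                )
    return episodes


def summarize_study(dataset) -> pd.DataFrame:
    """Per-cohort design summary: children, episodes, samples, weights."""
    dataset = list(dataset)
    rows = []
    for cohort in ("IA", "CI"):
        eps = [ep for ep in dataset if ep.cohort == cohort]
        weights = np.array(sorted({(ep.child_id, ep.weight) for ep in eps}),
                           dtype=object)
        w = np.array([float(x[1]) for x in weights]) if len(weights) else np.array([])
        n_samples = int(sum(ep.times.size for ep in eps))
        rows.append(
            {
                "cohort": cohort,
                "n_children": len({ep.child_id for ep in eps}),
                "n_episodes": len(eps),
                "n_samples": n_samples,
                "samples_per_episode_median": float(np.median([ep.times.size for ep in eps])) if eps else 0.0,
                "weight_median_kg": float(np.median(w)) if w.size else np.nan,
                "weight_iqr_lo_kg": float(np.percentile(w, 25)) if w.size else np.nan,
                "weight_iqr_hi_kg": float(np.percentile(w, 75)) if w.size else np.nan,
                "n_bloq": int(sum(ep.bloq.sum() for ep in eps)),
            }
        )
    return pd.DataFrame(rows)
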