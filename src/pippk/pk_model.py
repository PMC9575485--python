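"""Three-compartment piperacillin disposition model with allometric scaling.

The structural model is a linear mammillary three-compartment model: a
central compartment exchanging drug with a slow and a rapid peripheral
compartment, with first-order elimination from the central compartment.
Typical parameter values refer to a 70 kg individual and are scaled to
body weight with fixed allometric exponents (0.75 for clearances, 1.0
for volumes).  Between-episode variability is carried on clearance as a
log-normal random effect; all concentrations are unbound piperacillin
in mg/L.

Profiles for piecewise-constant infusion schedules are solved exactly:
the rate matrix of a mammillary model is symmetrizable by a diagonal
volume transform, so each constant-rate segment is propagated through a
real eigendecomposition (no time-stepping error).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .regimens import Regimen

REFERENCE_WEIGHT_KG = 70.0

__all__ = [
    "REFERENCE_WEIGHT_KG",
    "PopulationParameters",
    "IndividualParameters",
    "ConcentrationProfile",
    "allometric_scale",
    "sample_individual",
    "simulate_profile",
    "simulate_profiles",
    "steady_state_css",
    "fraction_time_above",
    "time_above_threshold",
]


@dataclass(frozen=True)
class PopulationParameters:
    """Population PK parameters: typical values at 70 kg plus variability.

    Variability terms are standard deviations on the natural-log scale
    (a value of 0.481 corresponds to the "48.1%" convention used for
    log-normal random effects).  ``sigma_*`` are proportional residual
    error SDs and ``omega_err`` is the log-scale SD of the
    between-individual variability in residual-error magnitude.
    """

    cl_70: float = 14.24      # elimination clearance, L/h at 70 kg
    vc_70: float = 5.953      # central volume, L at 70 kg
    q1_70: float = 0.1943     # inter-compartmental clearance (slow), L/h
    vp1_70: float = 3.537     # peripheral volume (slow), L
    q2_70: float = 27.45      # inter-compartmental clearance (rapid), L/h
    vp2_70: float = 7.329     # peripheral volume (rapid), L
    exp_cl: float = 0.75      # allometric exponent for clearances
    exp_v: float = 1.0        # allometric exponent for volumes
    omega_cl_ia: float = 0.180   # between-episode CL variability, IA cohort
    omega_cl_ci: float = 0.481   # between-episode CL variability, CI cohort
    omega_err: float = 0.307     # IIV in residual-error magnitude (log SD)
    sigma_ia: float = 0.275      # proportional residual error SD, IA cohort
    sigma_ci: float = 0.500      # proportional residual error SD, CI cohort

    def __post_init__(self) -> None:
        for name in (
            "cl_70", "vc_70", "q1_70", "vp1_70", "q2_70", "vp2_70",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("exp_cl", "exp_v"):
            if not 0 < getattr(self, name) < 2:
                raise ValueError(f"{name} must lie in (0, 2)")
        for name in (
            "omega_cl_ia", "omega_cl_ci", "omega_err", "sigma_ia", "sigma_ci",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def omega_cl(self, cohort: str) -> float:
        """Between-episode clearance variability for a cohort ('IA'/'CI')."""
        return {"IA": self.omega_cl_ia, "CI": self.omega_cl_ci}[_cohort(cohort)]

    def sigma(self, cohort: str) -> float:
        """Proportional residual-error SD for a cohort ('IA'/'CI')."""
        return {"IA": self.sigma_ia, "CI": self.sigma_ci}[_cohort(cohort)]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParameters":
        return cls(**d)

    def to_file(self, path: str | Path) -> None:
        """Write parameters as a flat key-value YAML (JSON-compatible) file."""
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "PopulationParameters":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if not text.lstrip().startswith("{") else json.loads(text)
        return cls.from_dict(data)

    def update(self, **kwargs) -> "PopulationParameters":
        return replace(self, **kwargs)


def _cohort(cohort: str) -> str:
    c = str(cohort).upper()
    if c not in ("IA", "CI"):
        raise ValueError(f"unknown cohort {cohort!r}; expected 'IA' or 'CI'")
    return c


@dataclass(frozen=True)
class IndividualParameters:
    """Body-weight-scaled PK parameters for one child / fever episode."""

    weight: float  # kg
    cl: float      # L/h
    vc: float      # L
    q1: float      # L/h
    vp1: float     # L
    q2: float      # L/h
    vp2: float     # L
    eta_cl: float = 0.0  # realized log-scale deviation on CL

    def __post_init__(self) -> None:
        for name in ("weight", "cl", "vc", "q1", "vp1", "q2", "vp2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ConcentrationProfile:
    """Unbound concentration-time course on a strictly increasing time grid."""

    times: np.ndarray           # h
    concentrations: np.ndarray  # mg/L

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and concentrations must be 1-D of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < -1e-9):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", np.maximum(c, 0.0))


def allometric_scale(pop: PopulationParameters, weight: float) -> IndividualParameters:
    """Scale typical 70 kg parameters to an individual's body weight.

    Clearances scale with (weight/70)**exp_cl and volumes with
    (weight/70)**exp_v; the returned individual carries no random effect
    (``eta_cl = 0``).
    """
    if not weight > 0:
        raise ValueError("weight must be strictly positive")
    f_cl = (weight / REFERENCE_WEIGHT_KG) ** pop.exp_cl
    f_v = (weight / REFERENCE_WEIGHT_KG) ** pop.exp_v
    return IndividualParameters(
        weight=weight,
        cl=pop.cl_70 * f_cl,
        vc=pop.vc_70 * f_v,
        q1=pop.q1_70 * f_cl,
        vp1=pop.vp1_70 * f_v,
        q2=pop.q2_70 * f_cl,
        vp2=pop.vp2_70 * f_v,
        eta_cl=0.0,
    )


def sample_individual(
    pop: PopulationParameters,
    weight: float,
    omega_cl: float,
    rng: np.random.Generator | int | None = None,
) -> IndividualParameters:
    """Draw one individual: typical scaled parameters with a log-normal
    deviation on clearance (``cl = typical * exp(eta)``, eta ~ N(0, omega^2)).
    """
    if omega_cl < 0:
        raise ValueError("omega_cl must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    typical = allometric_scale(pop, weight)
    eta = float(rng.normal(0.0, omega_cl)) if omega_cl > 0 else 0.0
    return replace(typical, cl=typical.cl * np.exp(eta), eta_cl=eta)


# ---------------------------------------------------------------------------
# Exact linear-system solver for piecewise-constant infusion input
# ---------------------------------------------------------------------------

def _eigensystem(cl, vc, q1, vp1, q2, vp2):
    """Real eigendecomposition of the stacked rate matrices.

    Amount-space rate matrix K (d A/dt = K A + input) is similarity-
    transformed with D = diag(1/sqrt(V)) into a symmetric matrix, so
    eigenvalues are real and eigh applies.  Returns (lam, Q, d) with
    K = D^-1 (Q lam Q^T) D and d the diagonal of D, all stacked (n, ...).
    """
    cl, vc, q1, vp1, q2, vp2 = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(x, dtype=float)) for x in (cl, vc, q1, vp1, q2, vp2))
    )
    n = cl.shape[0]
    k10 = cl / vc
    k12, k21 = q1 / vc, q1 / vp1
    k13, k31 = q2 / vc, q2 / vp2
    K = np.zeros((n, 3, 3))
    K[:, 0, 0] = -(k10 + k12 + k13)
    K[:, 0, 1] = k21
    K[:, 0, 2] = k31
    K[:, 1, 0] = k12
    K[:, 1, 1] = -k21
    K[:, 2, 0] = k13
    K[:, 2, 2] = -k31
    d = 1.0 / np.sqrt(np.stack([vc, vp1, vp2], axis=-1))  # (n, 3)
    S = K * (d[:, :, None] / d[:, None, :])
    S = 0.5 * (S + np.swapaxes(S, 1, 2))  # symmetrize away rounding noise
    lam, Q = np.linalg.eigh(S)
    return lam, Q, d


def _phi1(lam: np.ndarray, tau) -> np.ndarray:
    """(exp(lam*tau) - 1)/lam with the lam -> 0 limit handled."""
    x = lam * tau
    small = np.abs(x) < 1e-10
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(small, tau * (1.0 + 0.5 * x), (np.exp(x) - 1.0) / np.where(lam == 0, 1.0, lam))
    return out


def simulate_profiles(
    cl,
    vc,
    q1,
    vp1,
    q2,
    vp2,
    event_starts,
    event_durations,
    event_amounts,
    times,
    return_amounts: bool = False,
):
    """Vectorized exact simulation for a batch of individuals.

    Parameters are broadcastable 1-D arrays of length ``n`` (individuals).
    ``event_starts``/``event_durations`` are shared across individuals
    (length ``e``); ``event_amounts`` is ``(e,)`` or ``(n, e)`` in mg.
    ``times`` (h, non-decreasing, >= 0) is shared.  Returns central
    concentrations ``(n, m)`` in mg/L, or compartment amounts
    ``(n, m, 3)`` in mg when ``return_amounts`` is set.

    Overlapping events superpose (rates add).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be 1-D")
    if times.size and times[0] < 0:
        raise ValueError("times must be non-negative")
    if times.size >= 2 and np.any(np.diff(times) < 0):
        raise ValueError("times must be non-decreasing")
    starts = np.atleast_1d(np.asarray(event_starts, dtype=float))
    durs = np.atleast_1d(np.asarray(event_durations, dtype=float))
    if np.any(starts < 0):
        raise ValueError("event start times must be non-negative")
    if np.any(durs <= 0):
        raise ValueError("event durations must be strictly positive")

    lam, Q, d = _eigensystem(cl, vc, q1, vp1, q2, vp2)
    n = lam.shape[0]
    vc_arr = np.broadcast_to(np.atleast_1d(np.asarray(vc, dtype=float)), (n,))

    amounts = np.asarray(event_amounts, dtype=float)
    if amounts.ndim == 1:
        amounts = np.broadcast_to(amounts, (n, amounts.shape[0]))
    if np.any(amounts < 0):
        raise ValueError("event amounts must be non-negative")
    rates = amounts / durs  # (n, e)

    # segment boundaries: every event edge plus the end of the grid
    t_end = times[-1] if times.size else 0.0
    edges = np.unique(np.concatenate([[0.0], starts, starts + durs, [t_end]]))
    edges = edges[edges <= t_end + 1e-12]
    if edges[-1] < t_end:
        edges = np.append(edges, t_end)

    # state in eigen-coordinates: w = Q^T (d * A); starts at zero amounts
    w = np.zeros((n, 3))
    Q0 = Q[:, 0, :]                     # first row of Q (n, 3)
    d0 = d[:, 0]                        # (n,)
    out_c = np.empty((n, times.size)) if not return_amounts else None
    out_a = np.empty((n, times.size, 3)) if return_amounts else None

    for t0, t1 in zip(edges[:-1], edges[1:]):
        h = t1 - t0
        active = (starts <= t0 + 1e-12) & (starts + durs > t0 + 1e-12)
        rate = rates[:, active].sum(axis=1) if active.any() else np.zeros(n)
        # input vector u = (rate, 0, 0); eigen-coords w_u = Q^T (d * u)
        w_u = Q0 * (d0 * rate)[:, None]  # (n, 3)

        sel = (times >= t0 - 1e-12) & (times < t1 - 1e-12)
        if t1 == edges[-1]:
            sel = (times >= t0 - 1e-12) & (times <= t1 + 1e-12)
        if sel.any():
            tau = times[sel] - t0  # (m_s,)
            e = np.exp(lam[:, :, None] * tau[None, None, :])        # (n, 3, m)
            p1 = _phi1(lam[:, :, None], tau[None, None, :])         # (n, 3, m)
            w_t = e * w[:, :, None] + p1 * w_u[:, :, None]          # (n, 3, m)
            if return_amounts:
                # A = (Q w_t) / d
                A = np.einsum("nij,njm->nim", Q, w_t) / d[:, :, None]
                out_a[:, sel, :] = np.moveaxis(A, 1, 2)
            else:
                c = np.einsum("nj,njm->nm", Q0, w_t) / d0[:, None]  # central amount
                out_c[:, sel] = c / vc_arr[:, None]
        # advance state to t1
        eh = np.exp(lam * h)
        w = eh * w + _phi1(lam, h) * w_u

    result = out_a if return_amounts else np.maximum(out_c, 0.0)
    return result


def simulate_profile(
    ind: IndividualParameters,
    schedule: Regimen,
    times,
) -> ConcentrationProfile:
    """Exact unbound concentration-time profile for one individual.

    ``schedule`` may be a :class:`~pippk.regimens.Regimen` or any object
    with an ``events`` sequence of infusion events.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    events = schedule.events
    starts = np.array([ev.start for ev in events], dtype=float)
    durs = np.array([ev.duration for ev in events], dtype=float)
    amts = np.array([ev.amount for ev in events], dtype=float)
    conc = simulate_profiles(
        ind.cl, ind.vc, ind.q1, ind.vp1, ind.q2, ind.vp2,
        starts, durs, amts, t_sorted,
    )[0]
    # return in the caller's order only if strictly increasing; the profile
    # container enforces monotone time
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    return ConcentrationProfile(times=t_sorted, concentrations=conc)


def steady_state_css(ind: IndividualParameters, rate: float) -> float:
    """Steady-state concentration for a constant-rate infusion: rate / CL."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return rate / ind.cl


# ---------------------------------------------------------------------------
# Time above a threshold
# ---------------------------------------------------------------------------

def time_above_threshold(times, conc, threshold: float):
    """Time (h) with concentration strictly above ``threshold``.

    ``conc`` may be ``(m,)`` or batched ``(n, m)``; crossing times within
    each sampling interval are located by linear interpolation.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    dt = np.diff(t)
    c0, c1 = c[..., :-1], c[..., 1:]
    hi = np.maximum(c0, c1)
    lo = np.minimum(c0, c1)
    frac = np.zeros_like(hi)
    full = lo > threshold
    frac[full] = 1.0
    cross = (hi > threshold) & ~full
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (hi - threshold) / (hi - lo)
    frac[cross] = f[cross]
    return (frac * dt).sum(axis=-1)


def fraction_time_above(
    profile: ConcentrationProfile,
    threshold: float,
    window: tuple[float, float],
) -> float:
    """Fraction of ``window`` with concentration strictly above ``threshold``.

    The window must lie within the profile's time span; concentrations at
    the window edges are obtained by linear interpolation.
    """
    w0, w1 = float(window[0]), float(window[1])
    if not w1 > w0:
        raise ValueError("window must have positive length")
    t, c = profile.times, profile.concentrations
    if w0 < t[0] - 1e-12 or w1 > t[-1] + 1e-12:
        raise ValueError("window must lie within the profile time span")
    mask = (t > w0) & (t < w1)
    tt = np.concatenate([[w0], t[mask], [w1]])
    cc = np.concatenate([[np.interp(w0, t, c)], c[mask], [np.interp(w1, t, c)]])
    return float(time_above_threshold(tt, cc, threshold) / (w1 - w0))
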