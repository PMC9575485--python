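"""Virtual pediatric population for Monte-Carlo dosing simulations.

Generates children aged 2-18 years with balanced sexes and body weights
from a two-piece log-normal distribution calibrated to printed population
quantiles (default: median 42.7 kg, 2.5th-97.5th percentiles 12.6-94.2 kg).
Weight groups <25 / 25-50 / 50-75 / >=75 kg are attached for stratified
reporting.  Age and sex do not enter the PK model (body weight is the only
covariate); they are generated for reporting fidelity only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DEFAULT_WEIGHT_QUANTILES",
    "WEIGHT_GROUP_EDGES",
    "WEIGHT_GROUP_LABELS",
    "TwoPieceLogNormal",
    "assign_weight_group",
    "calibrate_weight_model",
    "generate_population",
    "load_population",
    "save_population",
]

#: (2.5th, 50th, 97.5th) body-weight percentiles of the simulated population, kg
DEFAULT_WEIGHT_QUANTILES = (12.6, 42.7, 94.2)

WEIGHT_GROUP_EDGES = (25.0, 50.0, 75.0)
WEIGHT_GROUP_LABELS = ("<25", "25-50", "50-75", ">=75")

_Z975 = norm.ppf(0.975)


@dataclass(frozen=True)
class TwoPieceLogNormal:
    """Log-weight is normal with a common median and piece-wise SD.

    ``log(W) = log_median + sd_lower * Z`` for Z < 0 and
    ``log_median + sd_upper * Z`` for Z >= 0, Z ~ N(0, 1).  Quantiles below
    and above the median are therefore exact log-normal quantiles with the
    respective SD.
    """

    log_median: float
    sd_lower: float
    sd_upper: float

    def quantile(self, p):
        p = np.asarray(p, dtype=float)
        z = norm.ppf(p)
        sd = np.where(z < 0, self.sd_lower, self.sd_upper)
        return np.exp(self.log_median + sd * z)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(n)
        sd = np.where(z < 0, self.sd_lower, self.sd_upper)
        return np.exp(self.log_median + sd * z)


def calibrate_weight_model(
    q2_5: float = DEFAULT_WEIGHT_QUANTILES[0],
    q50: float = DEFAULT_WEIGHT_QUANTILES[1],
    q97_5: float = DEFAULT_WEIGHT_QUANTILES[2],
) -> TwoPieceLogNormal:
    """Invert the three printed quantiles into a two-piece log-normal."""
    if not (0 < q2_5 < q50 < q97_5):
        raise ValueError("quantiles must be positive and strictly increasing")
    return TwoPieceLogNormal(
        log_median=float(np.log(q50)),
        sd_lower=float(np.log(q50 / q2_5) / _Z975),
        sd_upper=float(np.log(q97_5 / q50) / _Z975),
    )


def assign_weight_group(weights) -> np.ndarray:
    """Half-open weight bins [0,25), [25,50), [50,75), [75, inf)."""
    w = np.asarray(weights, dtype=float)
    idx = np.searchsorted(np.asarray(WEIGHT_GROUP_EDGES), w, side="right")
    return np.asarray(WEIGHT_GROUP_LABELS, dtype=object)[idx]


def generate_population(
    n: int,
    model: TwoPieceLogNormal | None = None,
    seed: np.random.Generator | int | None = None,
    age_range: tuple[float, float] = (2.0, 18.0),
) -> pd.DataFrame:
    """Generate ``n`` virtual children (id, age, sex, weight, weight group).

    Sexes alternate for an exactly balanced distribution; ages are uniform
    on ``age_range``; weights are i.i.d. from the calibrated weight model.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    model = model or calibrate_weight_model()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ages = rng.uniform(age_range[0], age_range[1], size=n)
    weights = model.sample(n, rng)
    sexes = np.where(np.arange(n) % 2 == 0, "M", "F")
    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "age_years": ages,
            "sex": sexes,
            "weight_kg": weights,
            "weight_group": assign_weight_group(weights),
        }
    )


def load_population(path: str | Path) -> pd.DataFrame:
    """Read an externally supplied population CSV (id, age_years, sex, weight_kg)."""
    df = pd.read_csv(path)
    required = {"id", "age_years", "sex", "weight_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"population CSV missing columns: {sorted(missing)}")
    if (df["weight_kg"] <= 0).any():
        raise ValueError("weights must be strictly positive")
    df = df.copy()
    df["weight_group"] = assign_weight_group(df["weight_kg"].to_numpy())
    return df


def save_population(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["id", "age_years", "sex", "weight_kg", "weight_group"]
    df[cols].to_csv(path, index=False)
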