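"""Two-sample t-test power and minimum group size via the noncentral t.

For equal groups of n with common SD sigma and a true difference delta, the
test statistic follows a noncentral t distribution with ``df = 2n - 2`` and
noncentrality ``(delta / sigma) * sqrt(n / 2)``. Power is the probability
mass of that distribution beyond the central-t critical value (both tails
for a two-sided test). A Monte-Carlo oracle on normal samples is provided
as an independent check of the analytic curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to a two-sample t-test power calculation."""

    delta: float              # true group difference, days
    sd: float                 # common within-group SD, days
    n_per_group: int
    alpha: float = 0.05
    sides: int = 2

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.sides not in (1, 2):
            raise ValueError("sides must be 1 or 2")


def power_two_sample_t(spec: PowerSpec) -> float:
    """Exact power of the equal-n two-sample t test under ``spec``."""
    df = 2 * spec.n_per_group - 2
    nc = (spec.delta / spec.sd) * math.sqrt(spec.n_per_group / 2.0)
    if spec.sides == 2:
        tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
        return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
    tcrit = stats.t.ppf(1.0 - spec.alpha, df)
    return float(stats.nct.sf(tcrit, df, nc))


def min_group_size(
    delta: float,
    sd: float,
    target_power: float = 0.80,
    alpha: float = 0.05,
    sides: int = 2,
    n_max: int = 10_000,
) -> int:
    """Smallest per-group n achieving at least ``target_power``.

    Power is monotone in n, so a linear scan from n = 2 suffices; an
    unreachable target within ``n_max`` raises.
    """
    if not (alpha < target_power < 1):
        raise ValueError("target_power must lie in (alpha, 1)")
    for n in range(2, n_max + 1):
        if power_two_sample_t(PowerSpec(delta, sd, n, alpha, sides)) >= target_power:
            return n
    raise ValueError(f"target power {target_power} not reachable with n <= {n_max}")


def monte_carlo_power(
    spec: PowerSpec, reps: int = 10_000, seed: int | None = 0
) -> tuple[float, float]:
    """Monte-Carlo estimate of the power, with its binomial standard error.

    Simulates ``reps`` pairs of Normal(0, sd) / Normal(delta, sd) samples of
    size ``n_per_group`` and reports the rejection fraction of the
    corresponding pooled-variance t test at ``alpha``.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, spec.sd, size=(reps, spec.n_per_group))
    b = rng.normal(spec.delta, spec.sd, size=(reps, spec.n_per_group))
    n = spec.n_per_group
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp = np.sqrt((va + vb) / 2.0)
    t = (b.mean(axis=1) - a.mean(axis=1)) / (sp * math.sqrt(2.0 / n))
    df = 2 * n - 2
    if spec.sides == 2:
        reject = np.abs(t) > stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    else:
        reject = t > stats.t.ppf(1.0 - spec.alpha, df)
    p_hat = float(reject.mean())
    se = math.sqrt(max(p_hat * (1.0 - p_hat), 1e-12) / reps)
    return p_hat, se


def power_curve(delta: float, sd: float, n_values, alpha: float = 0.05, sides: int = 2):
    """Analytic power over a grid of group sizes, as (n, power) pairs."""
    return [
        (int(n), power_two_sample_t(PowerSpec(delta, sd, int(n), alpha, sides)))
        for n in n_values
    ]
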