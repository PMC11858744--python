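"""Participant-resampling bootstrap: CIs, difference tests, bias tests.

For each test/reference pair the pooled participant responses are resampled
with replacement (N draws, N = number of participants who saw that pair),
independently per pair, and the psychometric model is refitted; repeating
this (5000 iterations by default) yields bootstrap distributions of w and p
from which percentile confidence intervals, mean differences and empirical
p-values derive.

Each iteration gets its own RNG stream derived from the root seed by a
counter-based spawn, so draws for iteration i never depend on how many
iterations were requested.

Reported p-values come in two flavors: ``p_empirical`` is the two-sided
resampling tail with (r+1)/(B+1) smoothing (floored at 1/(B+1), so it cannot
resolve below the Monte-Carlo granularity), while ``p_normal`` is a two-sided
normal tail computed from the mean and SD of the difference draws and serves
as the headline value for very small probabilities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .data import ResponseRow, ResponseTable, ValidationError
from .psychometric import FitConstraints, fit

logger = logging.getLogger(__name__)

DEFAULT_ITERATIONS = 5000


@dataclass(frozen=True)
class BootstrapSample:
    """Refitted (w, p) draws for one group's response table."""

    iterations: int
    w_draws: np.ndarray
    p_draws: np.ndarray
    converged: np.ndarray  # bool per iteration
    seed: int
    mode: str

    def __post_init__(self) -> None:
        if not (len(self.w_draws) == len(self.p_draws) == self.iterations):
            raise ValidationError("draw arrays must match the iteration count")

    def draws(self, parameter: str) -> np.ndarray:
        if parameter == "w":
            return self.w_draws
        if parameter == "p":
            return self.p_draws
        raise ValidationError(f"unknown parameter {parameter!r}")


@dataclass(frozen=True)
class IntervalEstimate:
    """Percentile bootstrap interval plus the draw mean."""

    level: float
    lower: float
    upper: float
    mean: float

    def __post_init__(self) -> None:
        if not 0 < self.level < 100:
            raise ValidationError("level must be in (0, 100)")
        if self.lower > self.upper:
            raise ValidationError("lower > upper")

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class DifferenceTest:
    """Mean difference of two bootstrap distributions with CI and p-values."""

    delta: float
    ci: IntervalEstimate
    p_empirical: float
    p_normal: float
    n_comparisons: int
    alpha_corrected: float
    significant: bool


def _resample_row(row: ResponseRow, rng: np.random.Generator) -> int:
    # n draws with replacement from n binary responses (k ones) is exactly a
    # Binomial(n, k/n) count; sampling the count directly avoids materializing
    # the resampled response vector.
    return int(rng.binomial(row.n_total, row.k_thicker / row.n_total))


def bootstrap_fit(
    table: ResponseTable,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    mode: str = "fixed_p",
    constraints: FitConstraints | None = None,
    true_reference: float | None = None,
) -> BootstrapSample:
    """Resample participant responses per pair and refit, ``iterations`` times.

    ``table`` must retain the per-response participant record (as produced by
    :func:`viscoweber.data.aggregate`); each iteration draws, independently
    for every row, ``n_total`` responses with replacement and refits the
    model in the requested mode.  Deterministic given ``seed``.
    """
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    if mode == "fixed_p" and true_reference is None:
        true_reference = table.reference_viscosity
    w_draws = np.empty(iterations)
    p_draws = np.empty(iterations)
    conv = np.zeros(iterations, dtype=bool)
    opt_ok = np.zeros(iterations, dtype=bool)
    for i in range(iterations):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        rows = []
        for row in table.rows:
            k_star = _resample_row(row, rng)
            rows.append(
                ResponseRow(
                    row.test_viscosity, row.test_appearance, k_star, row.n_total
                )
            )
        resampled = ResponseTable(table.group_label, table.reference_viscosity, tuple(rows))
        result = fit(resampled, mode=mode, constraints=constraints,
                     true_reference=true_reference)
        w_draws[i] = result.params.w
        p_draws[i] = result.params.p
        conv[i] = result.converged
        opt_ok[i] = result.optimizer_success
    n_bad = int(iterations - conv.sum())
    if opt_ok.sum() == 0:
        raise ValidationError("no bootstrap iteration converged")
    if n_bad > 0.2 * iterations:
        warnings.warn(
            f"{n_bad}/{iterations} bootstrap iterations did not converge "
            "(bound-pinned or degenerate refits)",
            stacklevel=2,
        )
    return BootstrapSample(iterations, w_draws, p_draws, conv, seed, mode)


def percentile_interval(draws: np.ndarray, level: float = 95.0) -> IntervalEstimate:
    """Empirical percentile interval at ``level`` percent, plus the mean."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ValidationError("need at least 2 draws")
    tail = (100.0 - level) / 2.0
    lower, upper = np.percentile(draws, [tail, 100.0 - tail])
    return IntervalEstimate(level, float(lower), float(upper), float(draws.mean()))


def exclude_poor_fit(interval: IntervalEstimate, max_width: float = 2.0) -> bool:
    """Exclusion rule for Weber fractions: drop a fit whose 95% CI spans 2 or
    more units.  Returns True when the fit should be excluded."""
    return interval.width >= max_width


def _difference_from_draws(
    diffs: np.ndarray,
    level: float,
    alpha: float,
    n_comparisons: int,
) -> DifferenceTest:
    b = diffs.size
    ci = percentile_interval(diffs, level)
    delta = float(diffs.mean())
    frac_le = (np.sum(diffs <= 0) + 1) / (b + 1)
    frac_ge = (np.sum(diffs >= 0) + 1) / (b + 1)
    p_emp = float(min(1.0, 2.0 * min(frac_le, frac_ge)))
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        p_norm = 1.0 if delta == 0.0 else 0.0
    else:
        p_norm = float(2.0 * norm.sf(abs(delta) / sd))
    alpha_corrected = alpha / n_comparisons
    return DifferenceTest(
        delta=delta,
        ci=ci,
        p_empirical=p_emp,
        p_normal=p_norm,
        n_comparisons=n_comparisons,
        alpha_corrected=alpha_corrected,
        significant=bool(p_norm < alpha_corrected),
    )


def difference_test(
    sample_a: BootstrapSample,
    sample_b: BootstrapSample,
    parameter: str = "w",
    level: float = 99.0,
    alpha: float = 0.01,
    n_comparisons: int = 1,
) -> DifferenceTest:
    """Bootstrap test of a parameter difference between two independent fits.

    Differences are taken draw-by-draw (iteration i of A minus iteration i of
    B); because iteration order is exchangeable this is an independent
    pairing.  Significance uses ``p_normal`` against the Bonferroni-corrected
    alpha.
    """
    if sample_a.iterations != sample_b.iterations:
        raise ValidationError("bootstrap samples must have equal iteration counts")
    diffs = sample_a.draws(parameter) - sample_b.draws(parameter)
    return _difference_from_draws(diffs, level, alpha, n_comparisons)


def bias_test(
    sample: BootstrapSample,
    true_reference: float,
    level: float = 99.0,
    alpha: float = 0.01,
    n_comparisons: int = 1,
) -> DifferenceTest:
    """Test whether the fitted PSE deviates from the true reference.

    Operates on the draws of (p - reference); positive delta means the test
    stimulus must exceed the reference viscosity to be perceived as equal.
    Requires a free-p bootstrap sample.
    """
    if sample.mode != "free_p":
        raise ValidationError("bias_test requires a free_p bootstrap sample")
    diffs = sample.p_draws - float(true_reference)
    return _difference_from_draws(diffs, level, alpha, n_comparisons)
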