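"""Barcode-pool complexity, infection MOI, and barcode-collision math.

Three small models used when designing a clonal barcoding experiment:

* a coverage-based lower bound on the number of distinct barcodes in the
  plasmid pool, from the singleton fraction of a read sample (Good's sample
  coverage, C-hat = 1 - f1/n, N-hat = D / C-hat);
* a Poisson model of retroviral infection, recovering the multiplicity of
  infection from the fraction of cells infected (m = -ln(1 - f));
* the generalized birthday problem: the probability that any two of c
  infected cells independently received the same barcode from a pool of N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LibraryComplexity",
    "InfectionModel",
    "estimate_complexity",
    "complexity_recovery_sim",
    "moi_model",
    "prob_any_shared_barcode",
    "barcode_sharing_sim",
]


@dataclass(frozen=True)
class LibraryComplexity:
    n: int
    """Sample size (reads)."""
    D: int
    """Distinct barcodes observed."""
    f1: int
    """Barcodes observed exactly once."""
    coverage: float
    """Estimated sample coverage, 1 - f1/n."""
    N_hat: float
    """Coverage-based lower bound on pool complexity, D / coverage."""


@dataclass(frozen=True)
class InfectionModel:
    m: float
    """Multiplicity of infection (mean integrations per cell)."""
    p_n: np.ndarray
    """Poisson probabilities of n = 0..k integrations per cell."""

    @property
    def frac_multiple_among_infected(self) -> float:
        """Fraction of infected cells carrying two or more barcodes."""
        p0, p1 = self.p_n[0], self.p_n[1]
        infected = 1.0 - p0
        if infected == 0:
            return 0.0
        return (infected - p1) / infected


def estimate_complexity(n: int, D: int, f1: int) -> LibraryComplexity:
    """Lower-bound pool complexity from sample coverage.

    Coverage C-hat = 1 - f1/n estimates the total probability mass of the
    observed classes; N-hat = D / C-hat then bounds the number of classes
    from below (rare classes missed by the sample are not extrapolated).
    """
    if n <= 0:
        raise ValueError("sample size n must be positive")
    if not (0 <= f1 <= D <= n):
        raise ValueError("require 0 <= f1 <= D <= n")
    coverage = 1.0 - f1 / n
    if coverage <= 0:
        raise ValueError("all reads are singletons: coverage is zero, cannot estimate")
    return LibraryComplexity(n=n, D=D, f1=f1, coverage=coverage, N_hat=D / coverage)


def complexity_recovery_sim(
    N_true: int, n: int, reps: int = 100, seed: int | None = None
) -> dict[str, object]:
    """Calibration of the coverage estimator by resampling.

    For each rep, draw ``n`` reads uniformly (with replacement) from
    ``N_true`` equally abundant classes, tabulate D and f1, and apply
    :func:`estimate_complexity`.  Returns the per-rep N_hat values and the
    summary of N_hat / N_true.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    n_hats = np.empty(reps)
    for r in range(reps):
        draws = rng.integers(0, N_true, size=n)
        counts = np.bincount(draws, minlength=N_true)
        D = int((counts > 0).sum())
        f1 = int((counts == 1).sum())
        n_hats[r] = estimate_complexity(n, D, f1).N_hat
    ratio = n_hats / N_true
    return {
        "N_hat": n_hats,
        "ratio_median": float(np.median(ratio)),
        "ratio_q10": float(np.quantile(ratio, 0.1)),
        "ratio_q90": float(np.quantile(ratio, 0.9)),
    }


def moi_model(frac_infected: float, k_max: int = 10) -> InfectionModel:
    """Poisson infection model from the observed infected fraction.

    P(0 integrations) = exp(-m) = 1 - frac_infected, so
    m = -ln(1 - frac_infected); the returned ``p_n`` gives the Poisson pmf
    at 0..k_max integrations per cell.
    """
    if not (0 <= frac_infected < 1):
        raise ValueError("frac_infected must be in [0, 1)")
    m = -np.log1p(-frac_infected)
    p_n = stats.poisson.pmf(np.arange(k_max + 1), m)
    return InfectionModel(m=float(m), p_n=p_n)


def prob_any_shared_barcode(N: int, c: int) -> float:
    """Probability that any two of c cells share a barcode from a pool of N.

    Birthday-problem form: P = 1 - prod_{i=0}^{c-1} (N - i)/N, with the
    product accumulated in log space to avoid underflow at c ~ 1400.
    """
    if N <= 0 or c < 0:
        raise ValueError("require N > 0 and c >= 0")
    if c > N:
        return 1.0
    log_p_unique = np.sum(np.log1p(-np.arange(c) / N))
    return float(-np.expm1(log_p_unique))


def barcode_sharing_sim(
    N: int, c: int, reps: int = 500_000, seed: int | None = None
) -> dict[int, float]:
    """Empirical pmf of the number of cells sharing any barcode.

    Each rep draws ``c`` barcodes uniformly with replacement from ``N``;
    the statistic is the number of cells whose barcode occurs >= 2 times in
    the draw.  Returns {k: P(k cells involved in sharing)}.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    tallies: dict[int, int] = {}
    chunk = max(1, min(reps, 10_000_000 // max(c, 1)))
    done = 0
    while done < reps:
        b = min(chunk, reps - done)
        draws = rng.integers(0, N, size=(b, c))
        draws.sort(axis=1)
        dup_right = np.zeros((b, c), dtype=bool)
        dup_right[:, 1:] = draws[:, 1:] == draws[:, :-1]
        dup_left = np.zeros((b, c), dtype=bool)
        dup_left[:, :-1] = dup_right[:, 1:]
        shared = (dup_right | dup_left).sum(axis=1)
        for k, cnt in zip(*np.unique(shared, return_counts=True)):
            tallies[int(k)] = tallies.get(int(k), 0) + int(cnt)
        done += b
    return {k: v / reps for k, v in sorted(tallies.items())}
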