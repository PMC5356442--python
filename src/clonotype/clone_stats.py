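"""Statistical tests for clone lineage potential, state bias and stability.

Two read-count tests operate on un-normalized, replicate-summed reads per
clone per state per time point:

* the bi-lineage test asks whether a clone's reads in the minority state
  exceed what sort contamination alone would produce if the clone were
  single-lineage — an upper binomial tail with success probability pC
  (the contamination-attributable fraction of that state's reads);
* the bias test asks whether a clone's E/M read split differs from the
  population split — a chi-squared goodness-of-fit with one degree of
  freedom.

Both are corrected by Benjamini-Hochberg FDR.  Permutation machinery tests
the significance of Pearson correlations (stability across weeks, and the
narrow-sense heritability between subcloned and pooled phenotypes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContaminationProbs",
    "PermutationResult",
    "contamination_probabilities",
    "bilineage_test",
    "bias_test",
    "bh_fdr",
    "permutation_correlation",
    "heritability",
]


@dataclass(frozen=True)
class ContaminationProbs:
    """Per-time-point probabilities of a read being mis-called by the sort.

    pC_e(t): probability of an epithelial read appearing in the
    mesenchymal-sorted library, were every cell epithelial; computed as
    E'/(E + E') where E = (1-sigma_e) x (epithelial-sorted read total) and
    E' = sigma_m x (mesenchymal-sorted read total).  pC_m symmetric.
    """

    pC_e: dict[int, float]
    pC_m: dict[int, float]


def contamination_probabilities(
    sum_re_by_t: Mapping[int, float],
    sum_rm_by_t: Mapping[int, float],
    sigma_e_by_t: Mapping[int, float],
    sigma_m_by_t: Mapping[int, float],
) -> ContaminationProbs:
    pC_e, pC_m = {}, {}
    for t in sum_re_by_t:
        se, sm = sigma_e_by_t[t], sigma_m_by_t[t]
        re_sum, rm_sum = sum_re_by_t[t], sum_rm_by_t[t]
        if not (0 <= se < 1 and 0 <= sm < 1):
            raise ValueError("sigma values must be in [0, 1)")
        E = (1 - se) * re_sum
        E_prime = sm * rm_sum
        M = (1 - sm) * rm_sum
        M_prime = se * re_sum
        if E + E_prime == 0 or M + M_prime == 0:
            raise ValueError(f"no reads at time point {t}: pC undefined")
        pC_e[t] = E_prime / (E + E_prime)
        pC_m[t] = M_prime / (M + M_prime)
    return ContaminationProbs(pC_e=pC_e, pC_m=pC_m)


def _binom_upper_tail(x: np.ndarray, n: np.ndarray, p: float) -> np.ndarray:
    """P(X >= x) for X ~ Binomial(n, p) (inclusive upper tail)."""
    return stats.binom.sf(x - 1, n, p)


def bilineage_test(
    reads_e: pd.DataFrame,
    reads_m: pd.DataFrame,
    probs: ContaminationProbs,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Classify clones as mono_E / mono_M / bilineage / indeterminate.

    ``reads_e`` and ``reads_m`` are clone x time point tables of summed raw
    reads.  Per clone and time point, the null "all cells epithelial" is
    scored by the upper binomial tail at x = r_m with n = r_e + r_m and
    p = pC_e(t); symmetrically for "all mesenchymal".  All states and time
    points form one BH family at the given FDR.  A clone is mono-lineage in
    a state if the opposite null is rejected at every time point and its
    own null at none; bi-lineage if both nulls are rejected at one or more
    common time points.  Time points where a clone has zero total reads are
    excluded and flagged.
    """
    timepoints = list(reads_e.columns)
    clones = reads_e.index
    p_reject_e = {}  # p for H0 "all epithelial"
    p_reject_m = {}
    valid = {}
    for t in timepoints:
        re_t = reads_e[t].to_numpy(dtype=float)
        rm_t = reads_m[t].to_numpy(dtype=float)
        n = re_t + rm_t
        ok = n > 0
        p_e = np.full(len(clones), np.nan)
        p_m = np.full(len(clones), np.nan)
        p_e[ok] = _binom_upper_tail(rm_t[ok], n[ok], probs.pC_e[t])
        p_m[ok] = _binom_upper_tail(re_t[ok], n[ok], probs.pC_m[t])
        p_reject_e[t] = p_e
        p_reject_m[t] = p_m
        valid[t] = ok

    flat_p, keys = [], []
    for t in timepoints:
        for name, arr in (("e", p_reject_e[t]), ("m", p_reject_m[t])):
            for i, p in enumerate(arr):
                if np.isfinite(p):
                    flat_p.append(p)
                    keys.append((t, name, i))
    rejected_flat = bh_fdr(np.array(flat_p), alpha=fdr)
    rej = {
        (t, name): np.zeros(len(clones), dtype=bool) for t in timepoints for name in "em"
    }
    for (t, name, i), r in zip(keys, rejected_flat):
        rej[(t, name)][i] = r

    rows = []
    for i, clone in enumerate(clones):
        ts = [t for t in timepoints if valid[t][i]]
        rej_e = [rej[(t, "e")][i] for t in ts]  # evidence of M progeny
        rej_m = [rej[(t, "m")][i] for t in ts]  # evidence of E progeny
        if not ts:
            call = "indeterminate"
        elif any(re_ and rm_ for re_, rm_ in zip(rej_e, rej_m)):
            call = "bilineage"
        elif all(rej_m) and not any(rej_e):
            call = "mono_E"
        elif all(rej_e) and not any(rej_m):
            call = "mono_M"
        else:
            call = "indeterminate"
        row = {"clone": clone, "call": call, "n_timepoints_tested": len(ts)}
        for t in timepoints:
            row[f"p_all_e_t{t}"] = p_reject_e[t][i]
            row[f"p_all_m_t{t}"] = p_reject_m[t][i]
            row[f"reject_all_e_t{t}"] = bool(rej[(t, "e")][i])
            row[f"reject_all_m_t{t}"] = bool(rej[(t, "m")][i])
        rows.append(row)
    return pd.DataFrame(rows).set_index("clone")


def bias_test(
    reads_e: pd.DataFrame,
    reads_m: pd.DataFrame,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Chi-squared test of each clone's state split against the population.

    Expected reads split the clone's total by the population's state read
    proportions at that time point; the statistic
    (r_e - E_e)^2/E_e + (r_m - E_m)^2/E_m is referred to the upper tail of
    chi-squared with one degree of freedom.  BH correction pools all clones
    and time points; a clone is called biased if rejected at every time
    point (time points with zero expected reads are skipped and flagged).
    """
    timepoints = list(reads_e.columns)
    clones = reads_e.index
    pvals = {}
    valid = {}
    for t in timepoints:
        re_t = reads_e[t].to_numpy(dtype=float)
        rm_t = reads_m[t].to_numpy(dtype=float)
        tot_e, tot_m = re_t.sum(), rm_t.sum()
        share_e = tot_e / (tot_e + tot_m)
        n = re_t + rm_t
        exp_e = n * share_e
        exp_m = n * (1 - share_e)
        ok = (exp_e > 0) & (exp_m > 0)
        x = np.full(len(clones), np.nan)
        x[ok] = (re_t[ok] - exp_e[ok]) ** 2 / exp_e[ok] + (
            rm_t[ok] - exp_m[ok]
        ) ** 2 / exp_m[ok]
        p = np.full(len(clones), np.nan)
        p[ok] = stats.chi2.sf(x[ok], df=1)
        pvals[t] = p
        valid[t] = ok

    flat_p, keys = [], []
    for t in timepoints:
        for i, p in enumerate(pvals[t]):
            if np.isfinite(p):
                flat_p.append(p)
                keys.append((t, i))
    rejected_flat = bh_fdr(np.array(flat_p), alpha=fdr)
    rej = {t: np.zeros(len(clones), dtype=bool) for t in timepoints}
    for (t, i), r in zip(keys, rejected_flat):
        rej[t][i] = r

    rows = []
    for i, clone in enumerate(clones):
        ts = [t for t in timepoints if valid[t][i]]
        biased = bool(ts) and all(rej[t][i] for t in ts)
        row = {"clone": clone, "biased": biased, "n_timepoints_tested": len(ts)}
        for t in timepoints:
            row[f"p_t{t}"] = pvals[t][i]
            row[f"reject_t{t}"] = bool(rej[t][i])
        rows.append(row)
    return pd.DataFrame(rows).set_index("clone")


def bh_fdr(pvalues: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at FDR alpha."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


@dataclass(frozen=True)
class PermutationResult:
    rho: float
    reps: int
    exceed: int
    """Number of permutations with correlation >= observed."""

    @property
    def p_value(self) -> float:
        return (self.exceed + 1) / (self.reps + 1)


def permutation_correlation(
    x: Sequence[float],
    y: Sequence[float],
    reps: int = 1_000_000,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation test of a Pearson correlation (upper tail).

    Shuffles the pairing of y against x ``reps`` times; the empirical p is
    (#{rho_perm >= rho_obs} + 1)/(reps + 1), which floors at 1/(reps+1)
    rather than zero.  The raw exceed count is also exposed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-d with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    rng = np.random.default_rng(seed)
    n = len(x)
    xc = (x - x.mean()) / (x.std() * np.sqrt(n))
    yc = (y - y.mean()) / (y.std() * np.sqrt(n))
    rho_obs = float(np.dot(xc, yc))
    exceed = 0
    chunk = max(1, min(reps, 20_000_000 // n))
    done = 0
    while done < reps:
        b = min(chunk, reps - done)
        perms = rng.permuted(np.tile(yc, (b, 1)), axis=1)
        rho_perm = perms @ xc
        exceed += int((rho_perm >= rho_obs).sum())
        done += b
    return PermutationResult(rho=rho_obs, reps=reps, exceed=exceed)


def heritability(
    pooled_log2_em: pd.Series,
    subclone_log2_em: pd.Series,
    reps: int = 100_000,
    seed: int | None = None,
) -> tuple[float, PermutationResult]:
    """Narrow-sense heritability of the clone phenotype.

    The Pearson correlation between each subcloned population's log2(E/M)
    and the same clone's log2(E/M) in the parental pool, matched by
    barcode; unmatched barcodes are dropped.  Significance by permutation
    of the barcode labels.
    """
    common = pooled_log2_em.index.intersection(subclone_log2_em.index)
    if len(common) < 3:
        raise ValueError("need at least 3 matched clones")
    result = permutation_correlation(
        pooled_log2_em.loc[common].to_numpy(),
        subclone_log2_em.loc[common].to_numpy(),
        reps=reps,
        seed=seed,
    )
    return result.rho, result
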