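"""Normalized, contamination-corrected clone state abundances and phenotypes.

Read counts from each sorted library are turned into clone sizes per state
per time point: counts are normalized by library depth and scaled by the
population state fraction at the sort (60% epithelial / 40% mesenchymal by
default) so that epithelial plus mesenchymal abundances sum to one at each
time point; the expected contribution of mis-sorted cells is subtracted
using the post-sort purity measurements (sigma); sorted replicates are
averaged.  From the resulting E and M abundances the module derives each
clone's fraction epithelial, log2(E/M), growth rate, and the population's
binned-ratio Shannon entropy; a flow-cytometry gating routine phenotypes
single-cell clones against a dye-labelled control pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from clonotype.barcode_io import LibrarySpec

__all__ = [
    "SortSpec",
    "CloneStateMatrix",
    "normalize_counts",
    "correct_contamination",
    "phenotype_metrics",
    "growth_rates",
    "ratio_entropy",
    "gate_flow_clone",
]


@dataclass(frozen=True)
class SortSpec:
    """Sort conditions: mis-sort fractions, state split, population model."""

    sigma_e_by_t: Mapping[int, float]
    sigma_m_by_t: Mapping[int, float]
    state_fraction_e: float = 0.6
    pop_size_t0: float = 2.9e7
    doublings_per_week: float = 3.0
    pseudo_value: float = 1e-6

    def __post_init__(self):
        for sig in (*self.sigma_e_by_t.values(), *self.sigma_m_by_t.values()):
            if not (0 <= sig < 1):
                raise ValueError("sigma values must be in [0, 1)")

    @property
    def state_fraction_m(self) -> float:
        return 1.0 - self.state_fraction_e


@dataclass
class CloneStateMatrix:
    """Clone sizes per state per time point (barcode x timepoint)."""

    E: pd.DataFrame
    M: pd.DataFrame
    pseudo_value: float = 1e-6
    pseudo_flags: dict[str, pd.DataFrame] = field(default_factory=dict)
    """Per state, boolean barcode x timepoint marks of floored entries."""

    @property
    def timepoints(self) -> list[int]:
        return list(self.E.columns)

    @property
    def barcodes(self) -> pd.Index:
        return self.E.index


def _specs_by_library(specs: Sequence[LibrarySpec]) -> dict[str, LibrarySpec]:
    return {s.library_id: s for s in specs}


def normalize_counts(
    table: Mapping[str, Mapping[str, int]],
    specs: Sequence[LibrarySpec],
    spec: SortSpec,
) -> pd.DataFrame:
    """Per-library normalized clone abundances (pre contamination correction).

    value = (reads / library total) * state fraction, so that summing the
    epithelial and mesenchymal libraries of a time point gives one.
    Barcodes absent from a library receive the pseudo-value.
    Returns a barcode x library_id frame over the union of barcodes.
    """
    by_lib = _specs_by_library(specs)
    barcodes = sorted(set().union(*[set(t) for t in table.values()]))
    cols = {}
    for library_id in sorted(table):
        counts = table[library_id]
        lib_spec = by_lib[library_id]
        total = sum(counts.values())
        if total == 0:
            raise ValueError(f"library {library_id} has no reads")
        frac = (
            spec.state_fraction_e if lib_spec.state == "E" else spec.state_fraction_m
        )
        s = pd.Series(counts, dtype=float) / total * frac
        cols[library_id] = s.reindex(barcodes).fillna(spec.pseudo_value)
    return pd.DataFrame(cols)


def correct_contamination(
    normalized: pd.DataFrame,
    table: Mapping[str, Mapping[str, int]],
    specs: Sequence[LibrarySpec],
    spec: SortSpec,
) -> CloneStateMatrix:
    """Subtract the expected mis-sorted contribution and average replicates.

    For each clone and time point, the value subtracted from an
    epithelial-sorted library is (the clone's average fraction of total
    reads across that time point's mesenchymal-sorted libraries) x
    sigma_e(t), and symmetrically for mesenchymal libraries.  Entries
    brought to <= 0 are floored at the pseudo-value; sorted replicates are
    then combined by their mean.  Correction never increases an entry.
    """
    by_lib = _specs_by_library(specs)
    timepoints = sorted({s.timepoint for s in by_lib.values() if s.library_id in normalized})
    for t in timepoints:
        if t not in spec.sigma_e_by_t or t not in spec.sigma_m_by_t:
            raise ValueError(f"missing sigma for time point {t}")

    # raw read fraction of each clone in each library
    raw_cols = {}
    for library_id in normalized.columns:
        s = pd.Series(table[library_id], dtype=float)
        raw_cols[library_id] = (s / s.sum()).reindex(normalized.index).fillna(0.0)
    raw_frac = pd.DataFrame(raw_cols)

    e_frames, m_frames = {}, {}
    flags_e = pd.DataFrame(False, index=normalized.index, columns=timepoints)
    flags_m = flags_e.copy()
    for t in timepoints:
        libs_t = [s for s in by_lib.values() if s.timepoint == t and s.library_id in normalized]
        e_libs = [s.library_id for s in libs_t if s.state == "E"]
        m_libs = [s.library_id for s in libs_t if s.state == "M"]
        mean_frac_in_m = raw_frac[m_libs].mean(axis=1)
        mean_frac_in_e = raw_frac[e_libs].mean(axis=1)
        corrected_e = normalized[e_libs].sub(
            mean_frac_in_m * spec.sigma_e_by_t[t], axis=0
        )
        corrected_m = normalized[m_libs].sub(
            mean_frac_in_e * spec.sigma_m_by_t[t], axis=0
        )
        floored_e = corrected_e <= 0
        floored_m = corrected_m <= 0
        corrected_e = corrected_e.where(~floored_e, spec.pseudo_value)
        corrected_m = corrected_m.where(~floored_m, spec.pseudo_value)
        e_frames[t] = corrected_e.mean(axis=1)
        m_frames[t] = corrected_m.mean(axis=1)
        flags_e[t] = floored_e.any(axis=1)
        flags_m[t] = floored_m.any(axis=1)

    return CloneStateMatrix(
        E=pd.DataFrame(e_frames),
        M=pd.DataFrame(m_frames),
        pseudo_value=spec.pseudo_value,
        pseudo_flags={"E": flags_e, "M": flags_m},
    )


def phenotype_metrics(matrix: CloneStateMatrix) -> pd.DataFrame:
    """Fraction epithelial and log2(E/M) per time point, plus the average.

    fraction = E/(E+M); log2_em = log2(E/M); the time-average is the
    arithmetic mean of the per-time-point log ratios (i.e. the geometric
    average of the ratios).  Normalization factors cancel in both.
    """
    out = {}
    for t in matrix.timepoints:
        e, m = matrix.E[t], matrix.M[t]
        out[f"fraction_epithelial_t{t}"] = e / (e + m)
        out[f"log2_em_t{t}"] = np.log2(e / m)
    df = pd.DataFrame(out, index=matrix.barcodes)
    log_cols = [c for c in df.columns if c.startswith("log2_em_")]
    df["log2_em_avg"] = df[log_cols].mean(axis=1)
    df["fraction_epithelial_avg"] = df[
        [c for c in df.columns if c.startswith("fraction_epithelial_")]
    ].mean(axis=1)
    return df


def growth_rates(matrix: CloneStateMatrix, spec: SortSpec) -> pd.DataFrame:
    """Per-clone growth rate k_c in doublings/week.

    The population grows from ``pop_size_t0`` at ``doublings_per_week``;
    each clone's cell number at time t is its fraction of the normalized
    total times the population size.  For each later time point the
    interval rate is log2(N_t / N_0) / weeks-elapsed, and k_c is the mean
    of the interval rates.  Clones present only as pseudo-values at the
    first time point are flagged unreliable.
    """
    timepoints = matrix.timepoints
    if len(timepoints) < 2:
        raise ValueError("growth rates require at least two time points")
    t0 = timepoints[0]
    sizes = {}
    for t in timepoints:
        frac = (matrix.E[t] + matrix.M[t]) / (matrix.E[t] + matrix.M[t]).sum()
        weeks = (t - t0) / 7.0
        pop = spec.pop_size_t0 * 2.0 ** (spec.doublings_per_week * weeks)
        sizes[t] = frac * pop
    n0 = sizes[t0]
    rates = []
    for t in timepoints[1:]:
        weeks = (t - t0) / 7.0
        rates.append(np.log2(sizes[t] / n0) / weeks)
    k = pd.concat(rates, axis=1).mean(axis=1)
    unreliable = (matrix.E[t0] <= matrix.pseudo_value) & (
        matrix.M[t0] <= matrix.pseudo_value
    )
    return pd.DataFrame({"k_c": k, "unreliable": unreliable})


def ratio_entropy(log2_em_values: Sequence[float], bin_width: float = 1.0) -> float:
    """Shannon entropy (bits) of clones binned by log2(E/M).

    Bins of ``bin_width`` (a two-fold change in ratio per bin) anchored at
    the minimum value and covering the maximum; H = -sum p_i log2 p_i over
    non-empty bins.
    """
    values = np.asarray(log2_em_values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("ratio_entropy requires at least one finite value")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return 0.0
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges[-1] <= hi:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, _ = np.histogram(values, bins=edges)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def gate_flow_clone(
    events: pd.DataFrame,
    gate_proportions: tuple[float, float] = (0.6, 0.4),
    pseudo_count: float = 1.0,
) -> dict[str, float]:
    """Phenotype a single-cell clone from mixed flow events.

    ``events`` must carry ``intensity`` and a boolean ``control`` column
    (the dye-labelled parental pool mixed with the clone).  Gate thresholds
    are set on the control events so the E (high) and M (low) gates contain
    ``gate_proportions`` of control cells; clone events are then classified
    by the same thresholds.  Returns counts, fraction epithelial, and
    log2(E/M) with ``pseudo_count`` added to empty gates.
    """
    if "control" not in events or events["control"].nunique() < 2:
        raise ValueError("events must contain both control and clone populations")
    control = events.loc[events["control"], "intensity"]
    clone = events.loc[~events["control"], "intensity"]
    if len(control) < 100 or len(clone) < 100:
        raise ValueError("need at least 100 events in control and clone")
    prop_e, prop_m = gate_proportions
    if not np.isclose(prop_e + prop_m, 1.0):
        raise ValueError("gate proportions must sum to 1")
    threshold = float(control.quantile(prop_m))  # top prop_e of control is E
    n_e = int((clone > threshold).sum())
    n_m = int((clone <= threshold).sum())
    e = n_e if n_e > 0 else pseudo_count
    m = n_m if n_m > 0 else pseudo_count
    return {
        "threshold": threshold,
        "n_e": n_e,
        "n_m": n_m,
        "fraction_epithelial": n_e / (n_e + n_m),
        "log2_em": float(np.log2(e / m)),
    }
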