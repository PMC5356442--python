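"""Clone growth / state-transition simulator for combination-therapy design.

A simulated tumour is a set of clones, each carrying an intrinsic
equilibrium epithelial:mesenchymal ratio R_i (equivalently a fraction
epithelial f_i = R_i/(1+R_i)), a doubling time D_i, and real-valued cell
counts per state.  Fifteen time points model one day.  Each time point
applies, in order:

1. growth   — each state multiplied by 2**(1/D_i);
2. switching — cells change state with per-division probabilities
   P(e->m) = psi*(1-f_i) and P(m->e) = psi*f_i (psi = 0.2, i.e. 20% of
   cells switch state per division, with the ratio of the two
   probabilities equal to R_i so that R_i is a fixed point), spread
   uniformly over the D_i time points of one division;
3. treatment — during a treatment block, the targeted state loses
   ``kill_frac`` of its cells and the other state kill_frac/selectivity
   (default selectivity 10).

A course of therapy is 30 treated time points (2 days) followed by 20
rest points.  Population dynamics are deterministic; the randomness across
replicate simulations comes from seeding the tumour by resampling observed
clones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "POINTS_PER_DAY",
    "TREAT_BLOCK",
    "REST_BLOCK",
    "Tumour",
    "TreatmentSchedule",
    "SimResult",
    "read_empirical_table",
    "build_tumour",
    "advance_growth",
    "advance_differentiation",
    "apply_treatment",
    "run_schedule",
    "schedule_library",
]

POINTS_PER_DAY = 15
TREAT_BLOCK = 30
REST_BLOCK = 20


@dataclass
class Tumour:
    """Vectorized clone state: arrays shaped (reps, clones)."""

    N_e: np.ndarray
    N_m: np.ndarray
    frac_e: np.ndarray
    """Equilibrium fraction epithelial f_i = R_i/(1+R_i) per clone."""
    D: np.ndarray
    """Doubling time in simulation time points."""

    @property
    def total(self) -> np.ndarray:
        return self.N_e + self.N_m

    def copy(self) -> "Tumour":
        return Tumour(
            N_e=self.N_e.copy(),
            N_m=self.N_m.copy(),
            frac_e=self.frac_e.copy(),
            D=self.D.copy(),
        )


@dataclass(frozen=True)
class TreatmentSchedule:
    """Ordered (mode, duration) blocks; modes are treat_E / treat_M / rest."""

    name: str
    blocks: tuple[tuple[str, int], ...]

    def __post_init__(self):
        for mode, duration in self.blocks:
            if mode not in ("treat_E", "treat_M", "rest"):
                raise ValueError(f"unknown schedule mode {mode!r}")
            if duration <= 0:
                raise ValueError("block durations must be positive")

    @property
    def total_points(self) -> int:
        return sum(d for _, d in self.blocks)

    @property
    def treated_points(self) -> int:
        return sum(d for m, d in self.blocks if m != "rest")


@dataclass
class SimResult:
    """Per-plasticity-bin fold changes and total survival, with quantiles."""

    schedule: str
    bin_edges: np.ndarray
    median_fc_quantiles: pd.DataFrame
    """Rows q10/q50/q90, columns fraction-epithelial bins."""
    total_cells_quantiles: dict[str, float]
    per_rep_totals: np.ndarray = field(repr=False)
    per_rep_bin_median_fc: np.ndarray = field(repr=False)

    @property
    def median_total_cells(self) -> float:
        return self.total_cells_quantiles["q50"]


def read_empirical_table(path: str | Path) -> pd.DataFrame:
    """Read a simulator seed table (TSV).

    Requires columns clone_id, fraction_epithelial, doubling_time (days),
    initial_cells — the schema written by
    :func:`clonotype.synthetic_data.gen_empirical_clone_table`.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"clone_id", "fraction_epithelial", "doubling_time", "initial_cells"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"empirical table missing columns: {sorted(missing)}")
    return df


def build_tumour(
    table: pd.DataFrame,
    n_clones: int = 500,
    reps: int = 1,
    seed: int | None = None,
) -> Tumour:
    """Seed a tumour by resampling observed clones with replacement.

    Each simulated clone copies the fraction epithelial, doubling time and
    starting cell count of a randomly chosen observed clone; starting cells
    are split between states at the clone's fraction epithelial.
    """
    if len(table) == 0:
        raise ValueError("empirical clone table is empty")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(table), size=(reps, n_clones))
    frac = table["fraction_epithelial"].to_numpy()[idx]
    cells = table["initial_cells"].to_numpy(dtype=float)[idx]
    days = table["doubling_time"].to_numpy(dtype=float)[idx]
    return Tumour(
        N_e=cells * frac,
        N_m=cells * (1 - frac),
        frac_e=frac,
        D=days * POINTS_PER_DAY,
    )


def advance_growth(tumour: Tumour, dt: float = 1.0) -> None:
    """Exponential growth: each state multiplied by 2**(dt/D_i)."""
    g = 2.0 ** (dt / tumour.D)
    tumour.N_e *= g
    tumour.N_m *= g


def advance_differentiation(tumour: Tumour, psi: float = 0.2) -> None:
    """One time point of state switching; conserves N_e + N_m.

    Per-division switching probabilities psi*(1-f) (e->m) and psi*f (m->e)
    are divided across the D_i time points of one division.  Clones at
    their equilibrium split are unchanged; perturbed clones relax back.
    State-pure clones (f = 0 or 1) have an empty source state on one side
    and a zero rate on the other, so they never transition.
    """
    if not (0 <= psi <= 1):
        raise ValueError("psi must be in [0, 1]")
    p_em = psi * (1.0 - tumour.frac_e) / tumour.D
    p_me = psi * tumour.frac_e / tumour.D
    flux = tumour.N_m * p_me - tumour.N_e * p_em
    tumour.N_e += flux
    tumour.N_m -= flux


def apply_treatment(
    tumour: Tumour,
    target: str,
    kill_frac: float,
    selectivity: float = 10.0,
) -> None:
    """Kill ``kill_frac`` of the targeted state, 1/selectivity of the other."""
    if not (0 <= kill_frac < 1):
        raise ValueError("kill_frac must be in [0, 1)")
    if selectivity < 1:
        raise ValueError("selectivity must be >= 1")
    off = kill_frac / selectivity
    if target == "E":
        tumour.N_e *= 1.0 - kill_frac
        tumour.N_m *= 1.0 - off
    elif target == "M":
        tumour.N_m *= 1.0 - kill_frac
        tumour.N_e *= 1.0 - off
    else:
        raise ValueError("target must be 'E' or 'M'")


def run_schedule(
    tumour: Tumour,
    schedule: TreatmentSchedule,
    kill_frac: float = 0.142,
    selectivity: float = 10.0,
    psi: float = 0.2,
    n_bins: int = 10,
) -> SimResult:
    """Run a treatment schedule and summarize enrichment and survival.

    Each time point applies growth, then switching, then (in treatment
    blocks) the kill.  Per clone, fc_i = total cells at the end / total at
    the start; clones are binned by their equilibrium fraction epithelial
    and the median fc per bin recorded per replicate; reported are the
    0.1/0.5/0.9 quantiles over replicates of the bin medians and of total
    surviving cells.  The input tumour is not modified.
    """
    state = tumour.copy()
    start_total = state.total
    for mode, duration in schedule.blocks:
        for _ in range(duration):
            advance_growth(state)
            advance_differentiation(state, psi=psi)
            if mode == "treat_E":
                apply_treatment(state, "E", kill_frac, selectivity)
            elif mode == "treat_M":
                apply_treatment(state, "M", kill_frac, selectivity)
    fc = state.total / start_total

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_idx = np.clip(np.digitize(tumour.frac_e, edges) - 1, 0, n_bins - 1)
    reps = fc.shape[0]
    bin_medians = np.full((reps, n_bins), np.nan)
    for b in range(n_bins):
        mask = bin_idx == b
        for r in range(reps):
            vals = fc[r][mask[r]]
            if vals.size:
                bin_medians[r, b] = np.median(vals)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        # bins with no clones in any replicate are reported as NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        quantiles = np.nanquantile(bin_medians, [0.1, 0.5, 0.9], axis=0)
    totals = state.total.sum(axis=1)
    q10, q50, q90 = np.quantile(totals, [0.1, 0.5, 0.9])
    return SimResult(
        schedule=schedule.name,
        bin_edges=edges,
        median_fc_quantiles=pd.DataFrame(
            quantiles,
            index=["q10", "q50", "q90"],
            columns=[f"{edges[b]:.1f}-{edges[b+1]:.1f}" for b in range(n_bins)],
        ),
        total_cells_quantiles={"q10": q10, "q50": q50, "q90": q90},
        per_rep_totals=totals,
        per_rep_bin_median_fc=bin_medians,
    )


def _course(mode: str, treat: int = TREAT_BLOCK, rest: int = REST_BLOCK):
    return ((mode, treat), ("rest", rest))


def schedule_library(
    n_treatments: int = 6,
    cycles: int = 1,
    treat_block: int = TREAT_BLOCK,
    rest_block: int = REST_BLOCK,
) -> dict[str, TreatmentSchedule]:
    """Named schedule builders over ``n_treatments`` courses per cycle.

    mono_E / mono_M: every course the same agent.  sequential: the first
    half epithelial-specific, the second half mesenchymal-specific.
    imbalanced_7E1M / imbalanced_1E7M: seven courses of one agent and one
    of the other.  alternating: agents alternate course by course;
    alternating_2x doubles the alternation rate while halving block
    durations, so the total dose is unchanged.  ``cycles`` repeats the
    whole pattern.
    """
    if n_treatments % 2:
        raise ValueError("n_treatments must be even")

    def build(name: str, modes: Sequence[str], treat=treat_block, rest=rest_block):
        blocks: list[tuple[str, int]] = []
        for _ in range(cycles):
            for m in modes:
                blocks.extend(_course(m, treat, rest))
        return TreatmentSchedule(name=name, blocks=tuple(blocks))

    half = n_treatments // 2
    lib = {
        "mono_E": build("mono_E", ["treat_E"] * n_treatments),
        "mono_M": build("mono_M", ["treat_M"] * n_treatments),
        "sequential": build(
            "sequential", ["treat_E"] * half + ["treat_M"] * half
        ),
        "alternating": build(
            "alternating", ["treat_E", "treat_M"] * half
        ),
        "alternating_2x": build(
            "alternating_2x",
            ["treat_E", "treat_M"] * n_treatments,
            treat=treat_block // 2,
            rest=rest_block // 2,
        ),
        "imbalanced_7E1M": build(
            "imbalanced_7E1M", ["treat_E"] * 7 + ["treat_M"]
        ),
        "imbalanced_1E7M": build(
            "imbalanced_1E7M", ["treat_M"] * 7 + ["treat_E"]
        ),
        "rest_only": TreatmentSchedule(
            name="rest_only",
            blocks=tuple([("rest", (treat_block + rest_block) * n_treatments * cycles)]),
        ),
    }
    return lib
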