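"""Generators for every input the clone-tracking pipeline consumes.

The generators emulate a clonal barcoding experiment on a breast-cancer
line containing epithelial (keratin 8/18 high) and mesenchymal (low) cell
states: a pool of random 14-nt barcodes, a population of barcoded clones
whose log2(E/M) ratios are log-normally spread, FACS-sorted sequencing
libraries with sort contamination and PCR/sequencing point errors,
flow-cytometry events for single-cell clone phenotyping, expression
matrices with whole-chromosome copy-number blocks, and the empirical clone
table that seeds the treatment simulator.  Every artifact is emitted with
its ground truth so downstream recovery can be tested.

The named preset :func:`preset_mda157` fixes the population to the headline
marginals of the MDA-MB-157 experiment this package models: ~64% of clones
mesenchymal-biased, ~60% of cells epithelial, cross-week stability of the
clone log-ratio ~0.89, and binned-ratio Shannon entropy ~3.5 bits.  The
calibration is analytic (see docs/methods.md) and frozen here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from clonotype.barcode_io import LibrarySpec, ReadLayout

__all__ = [
    "SyntheticTruth",
    "SortSimConfig",
    "SortedRun",
    "gen_barcode_library",
    "design_index_sequences",
    "gen_clonal_population",
    "gen_sorted_read_libraries",
    "gen_flow_events",
    "gen_scrna_dataset",
    "gen_empirical_clone_table",
    "preset_mda157",
    "MDA157",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# The mda157 population constants below were calibrated jointly (and then
# frozen) so that deep count tables pushed through the quantification
# pipeline — including the pseudo-value floors that give single-lineage
# clones extreme log ratios — reproduce the headline marginals of the
# modelled experiment: binned-ratio Shannon entropy ~3.5 bits (set by the
# sd), 64% mesenchymal-biased clones (the mean/sd ratio), cross-week
# Pearson of clone log-ratios ~0.89 (the total fluctuation variance), 81%
# of clones moving < 0.15 in fraction epithelial over two weeks (the
# fluctuation mixture weight), and ~60% epithelial cells population-wide
# (the clone-size tilt).  See docs/methods.md for the calibration account.

#: sd of log2(E/M) across clones.
LOG2EM_SD_MDA157 = 1.8
#: mean of log2(E/M): sigma * Phi^-1(0.36), placing 64% of mixed clones
#: below zero (mesenchymal-biased).
LOG2EM_MEAN_MDA157 = -0.35846 * LOG2EM_SD_MDA157
#: rms per-time-point fluctuation of a clone's log-ratio.
LOG2EM_TAU_MDA157 = 1.5 * LOG2EM_SD_MDA157 * math.sqrt(1 / 0.89 - 1)
#: the fluctuation is a scale mixture (most clones wobble little, a
#: minority a lot): sd TAU_SMALL with probability TAU_WEIGHT, else the
#: variance-completing larger sd.
LOG2EM_TAU_SMALL_MDA157 = 0.3
LOG2EM_TAU_WEIGHT_MDA157 = 0.8
#: log-size tilt toward epithelial-biased clones (epithelial-biased clones
#: tend to be larger), giving ~60% epithelial cells population-wide.
SIZE_TILT_MDA157 = 0.529
#: per-base substitution rate on the barcode making mutated reads average
#: 1.7 bp from their parent: solves 14 p / (1 - (1-p)^14) = 1.7.
ERROR_RATE_MDA157 = 0.09049


@dataclass
class SyntheticTruth:
    """Ground truth for one barcoded clone."""

    clone_id: str
    barcode: str
    true_log2_em: float
    """Clone-intrinsic log2(epithelial/mesenchymal); NaN for pure clones."""
    true_fraction_epithelial: float
    doubling_rate: float
    """Growth rate in doublings/week."""
    initial_cells: int
    pure_state: str | None = None
    """'E' or 'M' for single-lineage clones, else None."""


@dataclass
class SortSimConfig:
    """Conditions of a simulated sort-and-sequence run."""

    sigma_e_by_t: Mapping[int, float]
    """Mis-sort fraction of the E gate (true M cells) per time point (days)."""
    sigma_m_by_t: Mapping[int, float]
    state_fraction_e: float = 0.6
    read_depth: int = 80_000
    """Reads per library (one library = one sorted replicate)."""
    error_rate: float = ERROR_RATE_MDA157
    """Per-base substitution rate on the barcode portion of a read."""
    flank_error_rate: float = 0.005
    """Per-base substitution rate on index and flank bases."""
    log2em_tau: float = LOG2EM_TAU_MDA157
    """rms of the per-time-point fluctuation of each clone's log-ratio."""
    log2em_tau_small: float = LOG2EM_TAU_SMALL_MDA157
    """sd of the narrow fluctuation component of the scale mixture."""
    log2em_tau_weight: float = LOG2EM_TAU_WEIGHT_MDA157
    """probability of the narrow component."""
    pop_size_t0: float = 2.9e7
    seed: int = 0

    def __post_init__(self):
        for sig in (*self.sigma_e_by_t.values(), *self.sigma_m_by_t.values()):
            if not (0 <= sig < 0.5):
                raise ValueError("mis-sort fractions must be in [0, 0.5)")
        if not (0 < self.state_fraction_e < 1):
            raise ValueError("state_fraction_e must be in (0, 1)")

    @property
    def state_fraction_m(self) -> float:
        return 1.0 - self.state_fraction_e


def gen_barcode_library(n_barcodes: int, length: int = 14, seed: int | None = None) -> list[str]:
    """Sample uniform-random DNA barcodes (with replacement).

    Random 14-mers average 3/4 * 14 = 10.5 pairwise mismatches, matching
    the separation observed when sequencing a random barcode plasmid pool.
    """
    if n_barcodes < 1 or length < 1:
        raise ValueError("n_barcodes and length must be positive")
    rng = np.random.default_rng(seed)
    arr = _BASES[rng.integers(0, 4, size=(n_barcodes, length))]
    return [row.tobytes().decode() for row in arr]


def design_index_sequences(
    n: int, length: int = 6, min_dist: int = 3, seed: int = 0
) -> list[str]:
    """Greedily pick n random index sequences pairwise >= min_dist apart."""
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not design enough index sequences")
        cand = rng.integers(0, 4, size=length)
        if all((cand != c).sum() >= min_dist for c in chosen):
            chosen.append(cand)
    return [_BASES[c].tobytes().decode() for c in chosen]


def gen_clonal_population(
    n_clones: int,
    log2em_mean: float = LOG2EM_MEAN_MDA157,
    log2em_sd: float = LOG2EM_SD_MDA157,
    growth_mean: float = 3.0,
    growth_sd: float = 0.45,
    size_log_sd: float = 0.8,
    size_tilt: float = SIZE_TILT_MDA157,
    total_cells: float = 2.9e7,
    pure_e_fraction: float = 0.03,
    pure_m_fraction: float = 0.07,
    barcode_length: int = 14,
    seed: int | None = None,
) -> list[SyntheticTruth]:
    """Generate a clonal population with known plasticity ground truth.

    log2(E/M) is Normal(log2em_mean, log2em_sd) across clones; growth rates
    are Normal truncated > 0 (doublings/week); clone sizes are log-normal
    with a log-linear tilt ``size_tilt`` toward epithelial-biased clones
    (epithelial-biased clones tend to be larger, which is what makes the
    population ~60% epithelial while most clones are mesenchymal-biased).
    A configurable fraction of clones is single-lineage, flagged via
    ``pure_state`` rather than infinite log-ratios.
    """
    if log2em_sd < 0 or growth_sd < 0:
        raise ValueError("sd parameters must be >= 0")
    if n_clones == 0:
        return []
    rng = np.random.default_rng(seed)
    barcodes = gen_barcode_library(
        n_clones, length=barcode_length, seed=rng.integers(2**31)
    )
    l2em = rng.normal(log2em_mean, log2em_sd, size=n_clones)
    growth = rng.normal(growth_mean, growth_sd, size=n_clones)
    while (growth <= 0).any():  # truncation by redraw
        bad = growth <= 0
        growth[bad] = rng.normal(growth_mean, growth_sd, size=bad.sum())

    n_pure_e = int(round(pure_e_fraction * n_clones))
    n_pure_m = int(round(pure_m_fraction * n_clones))
    pure = np.array([None] * n_clones, dtype=object)
    pure_idx = rng.choice(n_clones, size=n_pure_e + n_pure_m, replace=False)
    pure[pure_idx[:n_pure_e]] = "E"
    pure[pure_idx[n_pure_e:]] = "M"

    log_size = size_tilt * (l2em - log2em_mean) + rng.normal(
        0.0, size_log_sd, size=n_clones
    )
    sizes = np.exp(log_size)
    sizes = np.maximum(1, np.round(sizes / sizes.sum() * total_cells)).astype(np.int64)

    clones = []
    for i in range(n_clones):
        if pure[i] == "E":
            frac, l2 = 1.0, math.nan
        elif pure[i] == "M":
            frac, l2 = 0.0, math.nan
        else:
            l2 = float(l2em[i])
            frac = 2.0**l2 / (1.0 + 2.0**l2)
        clones.append(
            SyntheticTruth(
                clone_id=f"clone{i:05d}",
                barcode=barcodes[i],
                true_log2_em=l2,
                true_fraction_epithelial=frac,
                doubling_rate=float(growth[i]),
                initial_cells=int(sizes[i]),
                pure_state=pure[i],
            )
        )
    return clones


_FLANK_5 = "TGCAGG"
_FLANK_3 = "GGATCC"


@dataclass
class SortedRun:
    """A generated sort-and-sequence experiment plus its ground truth."""

    fastq_paths: dict[str, Path]
    library_specs: list[LibrarySpec]
    layout: ReadLayout
    config: SortSimConfig
    truth_clones: pd.DataFrame
    """Per (clone, timepoint): fluctuated log2(E/M), fraction epithelial,
    cell counts in each state, and cells captured by each gate."""
    truth_reads: pd.DataFrame
    """Per (library, clone): reads generated, split by true origin state."""

    def metadata_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "library_id": s.library_id,
                    "index_sequence": s.index_sequence,
                    "timepoint": s.timepoint,
                    "state": s.state,
                    "replicate": s.replicate,
                }
                for s in self.library_specs
            ]
        )


def draw_log2em_fluctuation(
    rng: np.random.Generator, n: int, cfg: SortSimConfig
) -> np.ndarray:
    """Per-time-point log-ratio fluctuations from the calibrated mixture."""
    q, t1, rms = cfg.log2em_tau_weight, cfg.log2em_tau_small, cfg.log2em_tau
    var_large = (rms**2 - q * t1**2) / (1 - q)
    if var_large < 0:
        raise ValueError("log2em_tau_small too large for total fluctuation rms")
    sd = np.where(rng.random(n) < q, t1, math.sqrt(var_large))
    return rng.normal(0.0, 1.0, size=n) * sd


def _mutate(
    rng: np.random.Generator,
    codes: np.ndarray,
    error_mask: np.ndarray,
) -> np.ndarray:
    """Substitute masked bases with one of the three other bases."""
    shift = rng.integers(1, 4, size=codes.shape)
    return np.where(error_mask, (codes + shift) % 4, codes)


def _make_library_specs(
    timepoints: Sequence[int], replicates: int
) -> list[LibrarySpec]:
    n_libraries = len(timepoints) * 2 * replicates
    indexes = design_index_sequences(n_libraries, length=6, min_dist=3, seed=7)
    specs: list[LibrarySpec] = []
    i_lib = 0
    for t in timepoints:
        for state in ("E", "M"):
            for rep in range(1, replicates + 1):
                specs.append(
                    LibrarySpec(
                        library_id=f"t{t}_{state}_r{rep}",
                        index_sequence=indexes[i_lib],
                        timepoint=t,
                        state=state,
                        replicate=rep,
                    )
                )
                i_lib += 1
    return specs


def _simulate_clone_counts(
    truth: Sequence[SyntheticTruth],
    cfg: SortSimConfig,
    timepoints: Sequence[int],
    replicates: int,
    rng: np.random.Generator,
    read_depth: int | None = None,
):
    """Core sort-and-sample model shared by the read- and count-level paths.

    Per time point: clones grow at their own rates from their initial
    sizes (rescaled so day 0 matches ``cfg.pop_size_t0``); each clone's
    cells are split between states by a binomial draw at its fluctuated
    fraction epithelial; each sort gate mixes correctly sorted cells with a
    mis-sorted fraction sigma of the other state; reads per library are a
    multinomial draw over (clone, true origin state) at the library depth.
    """
    if not truth:
        raise ValueError("truth population is empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    depth = cfg.read_depth if read_depth is None else read_depth
    specs = _make_library_specs(timepoints, replicates)
    n_clones = len(truth)
    base_l2em = np.array([c.true_log2_em for c in truth])
    pure_e = np.array([c.pure_state == "E" for c in truth])
    pure_m = np.array([c.pure_state == "M" for c in truth])
    growth = np.array([c.doubling_rate for c in truth])
    init = np.array([c.initial_cells for c in truth], dtype=float)

    clone_rows, read_rows = [], []
    counts_by_library: dict[str, np.ndarray] = {}
    scale = cfg.pop_size_t0 / init.sum()
    for t in timepoints:
        cells = init * 2.0 ** (growth * (t - timepoints[0]) / 7.0)
        cells = np.maximum(1, np.round(cells * scale)).astype(np.int64)
        fluct = draw_log2em_fluctuation(rng, n_clones, cfg)
        l2em_t = base_l2em + fluct
        frac_e = np.where(
            pure_e, 1.0, np.where(pure_m, 0.0, 2.0**l2em_t / (1 + 2.0**l2em_t))
        )
        e_cells = rng.binomial(cells, frac_e)
        m_cells = cells - e_cells
        sigma_e = cfg.sigma_e_by_t[t]
        sigma_m = cfg.sigma_m_by_t[t]
        tot_e, tot_m = e_cells.sum(), m_cells.sum()
        # gate composition over (clone, true origin state)
        p_e_gate = np.concatenate(
            [(1 - sigma_e) * e_cells / tot_e, sigma_e * m_cells / tot_m]
        )
        p_m_gate = np.concatenate(
            [sigma_m * e_cells / tot_e, (1 - sigma_m) * m_cells / tot_m]
        )
        for c, clone in enumerate(truth):
            clone_rows.append(
                {
                    "clone_id": clone.clone_id,
                    "barcode": clone.barcode,
                    "timepoint": t,
                    "log2_em": l2em_t[c] if clone.pure_state is None else math.nan,
                    "fraction_epithelial": frac_e[c],
                    "cells": cells[c],
                    "cells_E": e_cells[c],
                    "cells_M": m_cells[c],
                }
            )
        for spec in [s for s in specs if s.timepoint == t]:
            probs = p_e_gate if spec.state == "E" else p_m_gate
            counts = rng.multinomial(depth, probs)
            from_e, from_m = counts[:n_clones], counts[n_clones:]
            clone_reads = from_e + from_m
            counts_by_library[spec.library_id] = clone_reads
            for c, clone in enumerate(truth):
                if clone_reads[c]:
                    read_rows.append(
                        {
                            "library_id": spec.library_id,
                            "clone_id": clone.clone_id,
                            "barcode": clone.barcode,
                            "reads": int(clone_reads[c]),
                            "reads_from_E": int(from_e[c]),
                            "reads_from_M": int(from_m[c]),
                        }
                    )
    return specs, pd.DataFrame(clone_rows), pd.DataFrame(read_rows), counts_by_library


def gen_clone_read_table(
    truth: Sequence[SyntheticTruth],
    cfg: SortSimConfig,
    timepoints: Sequence[int] = (0, 7, 14),
    replicates: int = 2,
    read_depth: int | None = None,
):
    """Clone-level read counts per library, skipping the sequencing layer.

    The synthetic analogue of a published "reads for each clone" table:
    the same sort-and-sample model as :func:`gen_sorted_read_libraries`
    but tabulated directly as barcode counts per library (no per-read
    errors, no demultiplexing).  Returns (counts, specs, truth_clones)
    where ``counts`` maps library_id -> {barcode: reads}.
    """
    rng = np.random.default_rng(cfg.seed)
    specs, truth_clones, _, counts_by_library = _simulate_clone_counts(
        truth, cfg, timepoints, replicates, rng, read_depth=read_depth
    )
    counts = {}
    for lib, arr in counts_by_library.items():
        counts[lib] = {
            truth[c].barcode: int(arr[c]) for c in np.flatnonzero(arr)
        }
    return counts, specs, truth_clones


def gen_sorted_read_libraries(
    truth: Sequence[SyntheticTruth],
    cfg: SortSimConfig,
    out_dir: str | Path,
    timepoints: Sequence[int] = (0, 7, 14),
    replicates: int = 2,
) -> SortedRun:
    """Simulate FACS sorting and barcode sequencing of a clonal population.

    Runs the sort-and-sample model of :func:`_simulate_clone_counts`, then
    renders each library's reads as FASTQ: index + flank + barcode + flank,
    per-base substitution errors at the configured rates, and Phred+33
    qualities with erroneous bases drawn from a lower-quality distribution
    so the read filters are exercised.  Ground-truth assignment tables are
    returned alongside.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    specs, truth_clones, truth_reads, counts_by_library = _simulate_clone_counts(
        truth, cfg, timepoints, replicates, rng
    )
    layout = ReadLayout(
        index_len=6,
        flank_5=_FLANK_5,
        barcode_len=len(truth[0].barcode),
        flank_3=_FLANK_3,
    )
    fastq_paths = {}
    for spec in specs:
        fastq_paths[spec.library_id] = _write_library_fastq(
            rng, out_dir, spec, layout, truth, counts_by_library[spec.library_id], cfg
        )
    return SortedRun(
        fastq_paths=fastq_paths,
        library_specs=specs,
        layout=layout,
        config=cfg,
        truth_clones=truth_clones,
        truth_reads=truth_reads,
    )


def _write_library_fastq(
    rng: np.random.Generator,
    out_dir: Path,
    spec: LibrarySpec,
    layout: ReadLayout,
    truth: Sequence[SyntheticTruth],
    clone_reads: np.ndarray,
    cfg: SortSimConfig,
) -> Path:
    """Write one library's reads with substitution errors and qualities."""
    code_of = {65: 0, 67: 1, 71: 2, 84: 3}
    n_reads = int(clone_reads.sum())
    read_len = layout.min_read_len
    path = out_dir / f"{spec.library_id}.fastq"
    if n_reads == 0:
        path.write_text("")
        return path

    templates = np.empty((len(truth), read_len), dtype=np.uint8)
    for c, clone in enumerate(truth):
        full = spec.index_sequence + layout.flank_5 + clone.barcode + layout.flank_3
        templates[c] = [code_of[b] for b in full.encode()]
    codes = np.repeat(templates, clone_reads, axis=0)

    bc_start, bc_len = layout.barcode_start, layout.barcode_len
    rates = np.full(read_len, cfg.flank_error_rate)
    rates[bc_start : bc_start + bc_len] = cfg.error_rate
    err = rng.random((n_reads, read_len)) < rates
    codes = _mutate(rng, codes, err)

    qual = rng.integers(30, 41, size=(n_reads, read_len))
    qual_err = rng.integers(10, 31, size=(n_reads, read_len))
    qual = np.where(err, qual_err, qual).astype(np.uint8)

    seq_bytes = _BASES[codes]
    qual_bytes = (qual + 33).astype(np.uint8)
    with open(path, "wb") as fh:
        for i in range(n_reads):
            fh.write(b"@%s_%d\n" % (spec.library_id.encode(), i))
            fh.write(seq_bytes[i].tobytes())
            fh.write(b"\n+\n")
            fh.write(qual_bytes[i].tobytes())
            fh.write(b"\n")
    return path


def gen_flow_events(
    clone_fraction_e: float,
    n_events: int = 10_000,
    control_mix: tuple[float, float] = (0.6, 0.4),
    channel_model: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate keratin-8/18 flow-cytometry events for clone phenotyping.

    Returns a table of events with a log-normal staining ``intensity`` (two
    components: high = epithelial, low = mesenchymal) and a ``control``
    flag marking events from the dye-labelled parental-pool control mixed
    1:1 with the clone.  Control events are drawn at ``control_mix``
    (high, low) proportions; clone events at ``clone_fraction_e``.
    """
    if n_events < 100:
        raise ValueError("n_events must be >= 100")
    cm = {"mu_low": 2.0, "mu_high": 4.0, "sigma": 0.45}
    if channel_model:
        cm.update(channel_model)
    if cm["sigma"] == 0:
        # degenerate model: still generated, flagged via attrs
        pass
    rng = np.random.default_rng(seed)
    rows = []
    for is_control, frac_e, n in (
        (True, control_mix[0], n_events),
        (False, clone_fraction_e, n_events),
    ):
        high = rng.random(n) < frac_e
        mu = np.where(high, cm["mu_high"], cm["mu_low"])
        intensity = np.exp(rng.normal(mu, cm["sigma"]))
        rows.append(
            pd.DataFrame(
                {"intensity": intensity, "control": is_control, "true_high": high}
            )
        )
    df = pd.concat(rows, ignore_index=True)
    df.attrs["degenerate"] = cm["sigma"] == 0
    return df


def gen_scrna_dataset(
    n_normal_cells: int = 40,
    clone_spec: Sequence[Mapping] | None = None,
    subtype_spec: Sequence[Mapping] | None = None,
    n_genes: int = 3000,
    n_chromosomes: int = 10,
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> dict[str, object]:
    """Simulate a log2(TPM+1) expression matrix with clonal CNV blocks.

    ``clone_spec`` lists tumour clones as
    ``{"name", "n_cells", "events": [(chromosome, log2_shift), ...]}``;
    a whole-chromosome event shifts the log-expression mean of every gene
    on that chromosome (e.g. +0.585 for a gain to 3 copies).
    ``subtype_spec`` lists expression programs as
    ``{"name", "n_genes", "shift_by_clone": {clone_name: shift}}``.
    The matrix is mean-centred per gene across cells, mirroring the
    mean-normalized public matrices this pipeline accepts.  Returns the
    matrix (genes x cells), the chromosomal gene order, per-cell truth
    labels and the program gene sets.
    """
    if clone_spec is None:
        clone_spec = [
            {"name": "cloneA", "n_cells": 40, "events": [("chr1", 0.585)]},
            {"name": "cloneB", "n_cells": 40, "events": [("chr2", -1.0)]},
        ]
    for cl in clone_spec:
        if cl["n_cells"] < 1:
            raise ValueError(f"clone {cl['name']} has no cells")
    rng = np.random.default_rng(seed)

    genes = [f"g{i:05d}" for i in range(n_genes)]
    chroms = np.repeat(
        [f"chr{i+1}" for i in range(n_chromosomes)],
        int(np.ceil(n_genes / n_chromosomes)),
    )[:n_genes]
    gene_order = pd.DataFrame(
        {
            "gene": genes,
            "chromosome": chroms,
            "position": np.concatenate(
                [np.arange((chroms == c).sum()) for c in dict.fromkeys(chroms)]
            ),
        }
    )

    cells, labels = [], []
    for i in range(n_normal_cells):
        cells.append(f"normal_{i:03d}")
        labels.append("normal")
    for cl in clone_spec:
        for i in range(cl["n_cells"]):
            cells.append(f"{cl['name']}_{i:03d}")
            labels.append(cl["name"])
    n_cells = len(cells)

    gene_base = rng.normal(2.0, 1.0, size=n_genes)
    expr = gene_base[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_cells))
    label_arr = np.array(labels)
    for cl in clone_spec:
        cell_mask = label_arr == cl["name"]
        for chrom, shift in cl["events"]:
            gene_mask = (gene_order["chromosome"] == chrom).to_numpy()
            expr[np.ix_(gene_mask, cell_mask)] += shift

    gene_sets: dict[str, list[str]] = {}
    if subtype_spec:
        for prog in subtype_spec:
            idx = rng.choice(n_genes, size=prog["n_genes"], replace=False)
            gene_sets[prog["name"]] = [genes[i] for i in idx]
            for clone_name, shift in prog.get("shift_by_clone", {}).items():
                cell_mask = label_arr == clone_name
                expr[np.ix_(idx, cell_mask)] += shift

    expr -= expr.mean(axis=1, keepdims=True)  # per-gene mean-centring
    matrix = pd.DataFrame(expr, index=genes, columns=cells)
    return {
        "matrix": matrix,
        "gene_order": gene_order,
        "cell_labels": pd.Series(labels, index=cells, name="clone"),
        "gene_sets": gene_sets,
    }


def gen_empirical_clone_table(truth: Sequence[SyntheticTruth]) -> pd.DataFrame:
    """Simulator seed table: one row per clone.

    Columns: clone_id, fraction_epithelial, doubling_time (days/doubling),
    initial_cells — the same schema as the empirical table read by
    :func:`clonotype.treatment_sim.build_tumour`.
    """
    return pd.DataFrame(
        {
            "clone_id": [c.clone_id for c in truth],
            "fraction_epithelial": [c.true_fraction_epithelial for c in truth],
            "doubling_time": [7.0 / c.doubling_rate for c in truth],
            "initial_cells": [c.initial_cells for c in truth],
        }
    )


@dataclass(frozen=True)
class _Mda157Preset:
    """Frozen study conditions of the default synthetic experiment."""

    n_clones: int = 1372
    sigma_e_by_t: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.015, 7: 0.02, 14: 0.025}
    )
    sigma_m_by_t: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.03, 7: 0.02, 14: 0.035}
    )
    read_depth: int = 80_000


MDA157 = _Mda157Preset()


def preset_mda157(
    seed: int = 0,
    n_clones: int | None = None,
    read_depth: int | None = None,
) -> tuple[list[SyntheticTruth], SortSimConfig]:
    """The default synthetic experiment: MDA-MB-157-like clone population.

    1372 clones; log2(E/M) Normal with the frozen calibration constants
    (64% mesenchymal-biased clones, entropy ~3.5, stability ~0.89); sizes
    tilted so ~60% of cells are epithelial; sort contamination of a few
    per-cent per gate per time point; 80k reads per library.
    """
    preset = MDA157
    rng = np.random.default_rng(seed)
    truth = gen_clonal_population(
        n_clones=n_clones or preset.n_clones, seed=rng.integers(2**31)
    )
    cfg = SortSimConfig(
        sigma_e_by_t=dict(preset.sigma_e_by_t),
        sigma_m_by_t=dict(preset.sigma_m_by_t),
        read_depth=read_depth or preset.read_depth,
        seed=int(rng.integers(2**31)),
    )
    return truth, cfg
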