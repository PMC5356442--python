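"""Shared fixtures: synthetic experiments generated once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from clonotype.clone_quant import SortSpec
from clonotype.pipeline import quantify_tables, run_pipeline
from clonotype.synthetic_data import (
    gen_clone_read_table,
    preset_mda157,
)

SEED = 1


@pytest.fixture(scope="session")
def preset_tables():
    """Deep count-level preset run: the drop-in clone read-table route.

    Depth 1e6 per library puts measurement noise well below the biological
    spread, mirroring the data scale at which the population statistics
    this emulates were computed.
    """
    truth, cfg = preset_mda157(seed=SEED)
    counts, specs, truth_clones = gen_clone_read_table(
        truth, cfg, read_depth=1_000_000
    )
    sort_spec = SortSpec(
        sigma_e_by_t=dict(cfg.sigma_e_by_t), sigma_m_by_t=dict(cfg.sigma_m_by_t)
    )
    result = quantify_tables(counts, specs, sort_spec)
    return {
        "truth": truth,
        "cfg": cfg,
        "counts": counts,
        "specs": specs,
        "truth_clones": truth_clones,
        "result": result,
    }


@pytest.fixture(scope="session")
def preset_fastq_run(tmp_path_factory):
    """Full FASTQ-level preset run through count/collapse/quantify."""
    out = tmp_path_factory.mktemp("preset_run")
    result = run_pipeline({"seed": SEED}, out)
    return result


@pytest.fixture(scope="session")
def fastq_recovery(preset_fastq_run):
    """Phenotype recovery table: pipeline estimates joined with truth."""
    res = preset_fastq_run
    truth = res.run.truth_clones
    tavg = truth.groupby("barcode").agg(true_f=("fraction_epithelial", "mean"))
    total_reads = (
        pd.concat(
            [pd.Series(res.collapsed[lib]) for lib in res.collapsed], axis=1
        )
        .fillna(0)
        .sum(axis=1)
    )
    ph = res.phenotypes.join(tavg, how="inner").join(total_reads.rename("reads"))
    return ph


def barcodes_with_near_neighbours(barcodes, max_distance=4) -> set[str]:
    """True barcodes that have another true barcode within the merge radius."""
    from clonotype.barcode_grouping import _encode

    bcs = sorted(barcodes)
    enc = _encode(bcs)
    near = set()
    for i in range(len(bcs)):
        d = (enc != enc[i]).sum(axis=1)
        if ((d <= max_distance).sum()) > 1:
            near.add(bcs[i])
    return near
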