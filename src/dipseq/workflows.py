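"""End-to-end simulation studies used for validation and benchmarking.

These orchestrate the full pipeline — simulate a library, sort it, sequence
it, call junctions, count, and compute enrichment — under fixed study
conditions, and report recovery metrics against the simulator's ground truth.
Tests and the acceptance script both run them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .calling import call_reads
from .counting import CountTable, ROW_NAMES, collapse_by_codon, merge_tables, tally_observations
from .enrichment import compute_enrichment, results_to_frame
from .profiling import make_profile
from .simulate import (
    SelectionModel,
    generate_reads,
    make_demo_cassette,
    make_demo_reference,
    simulate_naive_library,
    simulate_sort_series,
)

#: Profile bins for benchmark profiles: quartiles of the uncapped fold-change
#: distribution plus a top-decile bin (the "highest enrichment" tier).
BENCH_BIN_QUANTILES = (0.25, 0.5, 0.75, 0.9)


@dataclass
class SelectionBenchmark:
    """Outcome of the three-round sorting recovery study."""

    rank_correlation: float       # spearman(true dF/F, log2 fold change)
    top_bin_occupancy: float      # fraction of seeded hotspots in the top bin
    n_productive_sites: int
    n_hotspots: int
    enrichment: pd.DataFrame
    profile: pd.DataFrame
    truth_dff: dict[int, float]


def run_selection_benchmark(
    seed: int,
    workdir: Path | str,
    n_variants: int = 3000,
    n_codons: int = 370,
    n_hotspots: int = 10,
    depth: int = 2_000_000,
    n_cells_sorted: int = 4_000_000,
    error_rate: float = 0.001,
) -> SelectionBenchmark:
    """Three rounds of positive/negative/positive sorting, then full pipeline.

    Study conditions: a naive library with ~1,000-fold abundance bias and
    insertions in all six orientation/frame classes; productive variants
    carry a mostly-inactive activity distribution (exponential, scale 0.25)
    except for ``n_hotspots`` allosteric hotspot sites with dF/F of 2-2.5
    (the scale of strong published biosensors); gates increase in stringency
    across rounds as in sorting practice (a permissive positive sort with
    ligand, a negative sort without ligand, a stringent positive sort with
    ligand).  The naive and final libraries are sequenced and the pipeline's
    log2 fold changes are compared with the seeded activities.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    ref = make_demo_reference(n_codons=n_codons, seed=seed + 100)
    cassette = make_demo_cassette(seed=seed + 200)
    lib = simulate_naive_library(ref, cassette, n_variants, seed=seed)

    rng = np.random.default_rng(seed + 1)
    prod_sites = sorted({v.event.codon_site for v in lib.variants if v.event.productive})
    dff = {s: float(min(rng.exponential(0.25), 1.5)) for s in prod_sites}
    hotspots = sorted(rng.choice(prod_sites, size=n_hotspots, replace=False).tolist())
    for s in hotspots:
        dff[s] = float(rng.uniform(2.0, 2.5))
    activity = {s: (100.0, dff[s]) for s in prod_sites}

    schedule = [
        SelectionModel(gate_low=250, ligand_present=True),
        SelectionModel(gate_low=0, gate_high=150, sort_mode="negative", ligand_present=False),
        SelectionModel(gate_low=300, ligand_present=True),
    ]
    states = simulate_sort_series(lib, activity, schedule, n_cells_sorted, seed=seed)
    final = states[-1]

    paths0, _ = generate_reads(
        lib, ref, cassette, depth=depth, out_prefix=workdir / "naive",
        error_rate=error_rate, seed=seed + 10,
    )
    paths3, _ = generate_reads(
        final, ref, cassette, depth=depth, out_prefix=workdir / "sort3",
        error_rate=error_rate, seed=seed + 20,
    )
    obs0, _ = call_reads(paths0, ref, cassette)
    obs3, _ = call_reads(paths3, ref, cassette)
    table = merge_tables(
        [
            tally_observations(obs0, "naive", "naive"),
            tally_observations(obs3, "sort3", "sort3"),
        ]
    )
    collapsed = collapse_by_codon(table, ref)
    results = compute_enrichment(
        collapsed, ["naive"], ["sort3"], productive_only=True
    )
    frame = results_to_frame(results)
    frame["dff"] = frame.pos.map(dff)

    rho = float(spearmanr(frame.dff, frame.log2fc).statistic)
    uncapped = frame.loc[frame.cap == "none", "log2fc"]
    edges = np.quantile(uncapped, BENCH_BIN_QUANTILES)
    profile = make_profile(results, ref, bin_edges=edges)
    binmap = dict(zip(profile.codon_site, profile.enrichment_bin))
    top_bin = int(profile.enrichment_bin.max())
    detected_hot = [s for s in hotspots if s in set(frame.pos)]
    occupancy = float(
        np.mean([binmap.get(s, -1) == top_bin for s in detected_hot])
        if detected_hot
        else math.nan
    )
    return SelectionBenchmark(
        rank_correlation=rho,
        top_bin_occupancy=occupancy,
        n_productive_sites=len(prod_sites),
        n_hotspots=len(detected_hot),
        enrichment=frame,
        profile=profile,
        truth_dff=dff,
    )


def make_null_count_table(
    seed: int,
    n_rows: int = 2000,
    n_samples_per_condition: int = 2,
    depth_per_column: int = 2_000_000,
) -> tuple[CountTable, list[str], list[str]]:
    """A no-selection count table: both conditions sample the same library.

    Emulates sequencing one library twice (with N/C end columns per sample)
    with no sorting in between; every row's null hypothesis of equal means is
    true.  Used for type-I-error calibration.
    """
    rng = np.random.default_rng(seed)
    ab = rng.lognormal(0.0, 1.2, n_rows)
    ab /= ab.sum()
    n_cols = 2 * n_samples_per_condition
    cols = [rng.multinomial(depth_per_column, ab) for _ in range(2 * n_cols)]
    k = np.column_stack(cols)
    idx = pd.MultiIndex.from_arrays(
        [["dna"] * n_rows, range(1, n_rows + 1), ["forward"] * n_rows, [0] * n_rows],
        names=ROW_NAMES,
    )
    initial = [f"ini{j}" for j in range(n_samples_per_condition)]
    final = [f"fin{j}" for j in range(n_samples_per_condition)]
    tuples = [(s, e) for s in initial + final for e in ("N", "C")]
    df = pd.DataFrame(
        k, index=idx,
        columns=pd.MultiIndex.from_tuples(tuples, names=["sample", "end"]),
    )
    labels = {s: "naive" for s in initial} | {s: "sort1" for s in final}
    return CountTable(df, labels), initial, final
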