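"""End-to-end pipeline: simulated (or real) FASTQ pairs to colony genotypes.

Chains read merging, L/Q filtering, dual-barcode demultiplexing, per-read
haplotype tracing, the MM2 fix and duplex genotype calling, and compares
called genotypes with a simulation truth table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_calling import (
    DuplexGenotype,
    HaplotypeFrequencyTable,
    call_colony,
)
from .read_processing import ColonyReadSet, FastqRecord, LibraryCounts, process_library
from .synthetic_data import (
    LibraryDesign,
    LibrarySimulation,
    RepeatPair,
    VariantMap,
    simulate_library,
)
from .variant_tracing import HaplotypeCall, trace_reads


@dataclass
class PipelineResult:
    """Called genotypes plus the intermediate tables of one library run."""

    genotypes: dict[int, DuplexGenotype]
    tables: dict[int, HaplotypeFrequencyTable]
    calls: dict[int, list[HaplotypeCall]]
    colonies: dict[int, ColonyReadSet]
    counts: LibraryCounts

    def genotype_frame(self) -> pd.DataFrame:
        rows = []
        for cid, g in sorted(self.genotypes.items()):
            table = self.tables[cid]
            rows.append(
                {
                    "colony_id": cid,
                    "top": g.top,
                    "bottom": g.bottom,
                    "flags": ",".join(sorted(g.flags)),
                    "support": ",".join(f"{f:.4f}" for f in g.support),
                    "n_informative": table.n_informative,
                    "n_excluded": table.n_excluded,
                }
            )
        return pd.DataFrame(rows)


def run_pipeline(
    r1_records: list[FastqRecord],
    r2_records: list[FastqRecord],
    design: LibraryDesign,
    pair: RepeatPair,
    vmap: VariantMap,
    min_overlap: int = 30,
    max_mismatch: int = 0,
    min_len: int = 250,
    min_mean_q: float = 35.0,
    threshold: float = 0.19,
    apply_mm2_fix: bool = True,
) -> PipelineResult:
    """Run merge -> filter -> demux -> trace -> MM2 fix -> duplex calling."""
    colonies, counts = process_library(
        r1_records,
        r2_records,
        design,
        min_overlap=min_overlap,
        max_mismatch=max_mismatch,
        min_len=min_len,
        min_mean_q=min_mean_q,
    )
    genotypes: dict[int, DuplexGenotype] = {}
    tables: dict[int, HaplotypeFrequencyTable] = {}
    calls: dict[int, list[HaplotypeCall]] = {}
    for cid, readset in colonies.items():
        colony_calls = trace_reads(readset.reads, vmap)
        calls[cid] = colony_calls
        genotype, table = call_colony(
            colony_calls, colony_id=cid, threshold=threshold, apply_fix=apply_mm2_fix
        )
        genotypes[cid] = genotype
        tables[cid] = table
    return PipelineResult(genotypes, tables, calls, colonies, counts)


def run_simulation_pipeline(
    sim: LibrarySimulation, **pipeline_kwargs
) -> PipelineResult:
    return run_pipeline(
        sim.r1, sim.r2, sim.design, sim.pair, sim.vmap, **pipeline_kwargs
    )


def simulate_cohort(
    model,
    pair: RepeatPair,
    vmap: VariantMap,
    err,
    n_colonies: int,
    seed: int,
    design_kwargs: dict | None = None,
    **pipeline_kwargs,
) -> list[tuple[LibrarySimulation, PipelineResult]]:
    """Simulate and call a cohort, split into dual-barcode libraries.

    One 8x12 barcode design holds at most 96 colonies, so a larger cohort
    is sequenced as consecutive libraries (the last one partial), exactly
    as multiple 96-well plates would be. Library seeds are derived from
    ``seed`` via numpy's SeedSequence spawning.
    """
    design_kwargs = dict(design_kwargs or {})
    children = np.random.SeedSequence(seed).spawn((n_colonies + 95) // 96)
    out = []
    remaining = n_colonies
    for child in children:
        n_lib = min(96, remaining)
        lib_seed = int(child.generate_state(1)[0] % (2**31))
        design = LibraryDesign.default(
            seed=lib_seed, n_colonies=n_lib, **design_kwargs
        )
        sim = simulate_library(model, pair, vmap, err, design, seed=lib_seed)
        res = run_simulation_pipeline(sim, **pipeline_kwargs)
        out.append((sim, res))
        remaining -= n_lib
    return out


def cohort_accuracy(
    runs: list[tuple[LibrarySimulation, PipelineResult]]
) -> float:
    """Pooled genotype accuracy over replicate libraries."""
    n_correct = n_total = 0
    for sim, res in runs:
        n = len(sim.truth)
        n_correct += genotype_accuracy(res, sim.truth) * n
        n_total += n
    return n_correct / n_total


def genotype_accuracy(result: PipelineResult, truth: pd.DataFrame) -> float:
    """Fraction of colonies whose called duplex matches the truth table.

    The strand pair is compared unordered (the duplex has no intrinsic
    top/bottom labelling in the data); no_call colonies count as wrong.
    """
    n_correct = 0
    for _, row in truth.iterrows():
        called = result.genotypes.get(int(row["colony_id"]))
        if called is None or called.unordered() is None:
            continue
        if called.unordered() == frozenset((row["top"], row["bottom"])):
            n_correct += 1
    return n_correct / len(truth)
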