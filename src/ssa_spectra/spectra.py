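"""Cohort-level repair spectra, outcome classes, gradient and SSA statistics.

Each colony's duplex genotype gives a per-site trinary status: F (both
strands F), A (both strands A) or HET (retained heteroduplex, which founds
a sectored colony). Cohorts of colonies are summarised as per-site
correction fractions and outcome classes (all-F, all-A, unrepaired,
mixed), the left-right correction gradient is tested on 2x2 counts with
Fisher's exact test, and plate/PCR-level SSA statistics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_calling import N_SITES, DuplexGenotype

ALL_F = "all_F"
ALL_A = "all_A"
UNREPAIRED = "unrepaired"
MIXED = "mixed"

ALL_SITES = tuple(range(1, N_SITES + 1))
#: the Sanger-style analyses score six sites, omitting the slippage-prone MM2
WELL_BEHAVED_SITES = (1, 3, 4, 5, 6, 7)


def site_status(genotype: DuplexGenotype) -> list[str]:
    """Per-site trinary status F/A/HET from the two strand haplotypes."""
    top, bottom = genotype.strands()
    status = []
    for t, b in zip(top, bottom):
        if t == b:
            status.append(t)
        else:
            status.append("HET")
    return status


def classify_outcome(
    genotype: DuplexGenotype, scored_sites: Sequence[int] = ALL_SITES
) -> str:
    """Outcome class over the scored sites.

    all_F / all_A when every scored site is corrected to that allele,
    unrepaired when every scored site is still heteroduplex, mixed
    otherwise.
    """
    status = site_status(genotype)
    scored = [status[i - 1] for i in scored_sites]
    if all(s == "F" for s in scored):
        return ALL_F
    if all(s == "A" for s in scored):
        return ALL_A
    if all(s == "HET" for s in scored):
        return UNREPAIRED
    return MIXED


@dataclass
class SpectrumSummary:
    """Per-site correction fractions and outcome counts for a cohort."""

    per_site: pd.DataFrame  # index: site; columns f_frac, a_frac, het_frac
    outcome_counts: dict[str, int]
    n_colonies: int
    n_no_call: int
    scored_sites: tuple[int, ...]
    label: str = ""


def spectrum(
    cohort: Iterable[DuplexGenotype],
    scored_sites: Sequence[int] = ALL_SITES,
    label: str = "",
) -> SpectrumSummary:
    """Summarise a cohort of duplex genotypes.

    no_call colonies are excluded from the fractions and counted
    separately. When ``scored_sites`` omits MM2 (the paper-style six-site
    view) both the per-site table and the outcome classes use only the
    remaining sites.
    """
    genotypes = list(cohort)
    called = [g for g in genotypes if not g.is_no_call]
    n_no_call = len(genotypes) - len(called)
    if not called:
        raise ValueError("empty cohort (no called genotypes)")
    statuses = np.array([site_status(g) for g in called])
    rows = []
    for site in scored_sites:
        col = statuses[:, site - 1]
        n = len(col)
        rows.append(
            {
                "site": site,
                "f_frac": float((col == "F").sum() / n),
                "a_frac": float((col == "A").sum() / n),
                "het_frac": float((col == "HET").sum() / n),
            }
        )
    per_site = pd.DataFrame(rows).set_index("site")
    outcome_counts = {ALL_F: 0, ALL_A: 0, UNREPAIRED: 0, MIXED: 0}
    for g in called:
        outcome_counts[classify_outcome(g, scored_sites)] += 1
    return SpectrumSummary(
        per_site=per_site,
        outcome_counts=outcome_counts,
        n_colonies=len(called),
        n_no_call=n_no_call,
        scored_sites=tuple(scored_sites),
        label=label,
    )


@dataclass(frozen=True)
class GradientResult:
    """Fisher exact comparison of F-correction at two sites."""

    site_i: int
    site_j: int
    f_frac_i: float
    f_frac_j: float
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float


def gradient_test(
    f_i: int, not_f_i: int, f_j: int, not_f_j: int,
    site_i: int = 1, site_j: int = 7,
) -> GradientResult:
    """Two-sided Fisher exact test on F vs not-F counts at two sites.

    Used for the left-right correction gradient (e.g. MM1 corrected to F
    in 124/143 colonies vs MM7 in 76/143).
    """
    table = np.array([[f_i, not_f_i], [f_j, not_f_j]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"degenerate 2x2 table (zero margin): {table.tolist()}")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return GradientResult(
        site_i=site_i,
        site_j=site_j,
        f_frac_i=f_i / (f_i + not_f_i),
        f_frac_j=f_j / (f_j + not_f_j),
        table=((f_i, not_f_i), (f_j, not_f_j)),
        p_value=float(p),
    )


def site_f_counts(
    cohort: Iterable[DuplexGenotype], site: int
) -> tuple[int, int]:
    """(F, not-F) colony counts at one site, over called colonies."""
    f = not_f = 0
    for g in cohort:
        if g.is_no_call:
            continue
        if site_status(g)[site - 1] == "F":
            f += 1
        else:
            not_f += 1
    return f, not_f


def adjacent_concordance(items: Iterable[str]) -> dict[tuple[int, int], float]:
    """Fraction of items whose calls agree at each adjacent site pair.

    ``items`` are length-7 call strings (per-read haplotypes or per-colony
    trinary codes); items with an N at either site of a pair are skipped
    for that pair.
    """
    strings = [s if isinstance(s, str) else s.calls for s in items]
    out: dict[tuple[int, int], float] = {}
    for i in range(N_SITES - 1):
        valid = [s for s in strings if s[i] != "N" and s[i + 1] != "N"]
        if not valid:
            out[(i + 1, i + 2)] = float("nan")
            continue
        agree = sum(1 for s in valid if s[i] == s[i + 1])
        out[(i + 1, i + 2)] = agree / len(valid)
    return out


def ssa_frequency(n_selective: int, n_permissive: int) -> float:
    """SSA frequency as a percentage: DSB survivors / total platable cells.

    ``n_selective`` counts colonies on the DSB-inducing (galactose) plates,
    ``n_permissive`` on dextrose plates.
    """
    if n_permissive == 0:
        raise ValueError("permissive-plate colony count is zero")
    if n_selective < 0 or n_permissive < 0:
        raise ValueError("colony counts must be non-negative")
    return 100.0 * n_selective / n_permissive


def pcr_size_classify(
    amplicon_length: int,
    expected_sizes: Mapping[str, int] | None = None,
    tolerance: float = 0.10,
) -> str:
    """Classify a diagnostic PCR product by its size.

    The nearest expected size within ``tolerance`` (fractional) wins;
    anything else is 'other'. Defaults to the deletion-diagnostic design
    where an SSA product gives 285 bp and the parental locus 632 bp.
    """
    if expected_sizes is None:
        expected_sizes = {"SSA": 285, "parental": 632}
    best_label, best_dist = "other", None
    for label, size in expected_sizes.items():
        dist = abs(amplicon_length - size)
        if dist <= tolerance * size and (best_dist is None or dist < best_dist):
            best_label, best_dist = label, dist
    return best_label


def rounded_percent(numerator: int, denominator: int) -> int:
    """Percentage rounded to the nearest integer (half away from zero)."""
    if denominator == 0:
        raise ValueError("denominator is zero")
    return int(floor(100.0 * numerator / denominator + 0.5))
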