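"""MM2 flank-concordance error fix and per-colony duplex genotype calling.

A colony's reads are reduced to a haplotype frequency table; the MM2 fix
treats reads whose poly-T indel call (MM2) disagrees with both flanking
sites (MM1 and MM3, which bracket the homopolymer) as polymerase slippage
artifacts and corrects MM2 to match. The colony's duplex genotype is then
the two most frequent haplotypes above a 19% frequency threshold: two
strings mean the two strands of the annealed SSA product, one string means
a fully corrected (homoduplex) product.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

N_SITES = 7

HOMODUPLEX = "homoduplex"
NO_CALL = "no_call"
AMBIGUOUS_EXTRA = "ambiguous_extra"


def mm2_fix(haplotype: str) -> str:
    """Correct MM2 to match MM1/MM3 when those two sites agree.

    If positions 1 and 3 carry the same allele but position 2 differs, the
    read's MM2 state is treated as a homopolymer slippage artifact and
    rewritten to agree (e.g. FAFFFFF is counted as FFFFFFF). When MM1 and
    MM3 disagree the read is returned unchanged; the rule is only defined
    on flank agreement.
    """
    if len(haplotype) != N_SITES:
        raise ValueError(f"haplotype must have {N_SITES} sites, got {haplotype!r}")
    if any(c not in "FA" for c in haplotype):
        raise ValueError(f"haplotype contains non-F/A calls: {haplotype!r}")
    if haplotype[0] == haplotype[2] and haplotype[1] != haplotype[0]:
        return haplotype[0] * 2 + haplotype[2:]
    return haplotype


@dataclass
class HaplotypeFrequencyTable:
    """Post-fix haplotype counts for one colony.

    ``n_informative`` counts reads with a definite F/A call at all seven
    sites; reads containing any N are tallied in ``n_excluded`` and do not
    enter the table.
    """

    colony_id: int | str
    counts: dict[str, int] = field(default_factory=dict)
    n_informative: int = 0
    n_excluded: int = 0

    def frequencies(self) -> dict[str, float]:
        if self.n_informative == 0:
            return {}
        return {h: c / self.n_informative for h, c in self.counts.items()}


def build_frequency_table(
    calls: Iterable,
    colony_id: int | str = "",
    apply_fix: bool = True,
) -> HaplotypeFrequencyTable:
    """Count distinct haplotypes over a colony's reads.

    ``calls`` may be HaplotypeCall objects or plain 7-character strings.
    The MM2 fix is applied to every informative call before counting
    (``apply_fix=False`` gives the raw table, used when quantifying how
    much work the fix does).
    """
    counter: Counter[str] = Counter()
    n_excluded = 0
    for call in calls:
        h = call if isinstance(call, str) else call.calls
        if "N" in h:
            n_excluded += 1
            continue
        counter[mm2_fix(h) if apply_fix else h] += 1
    return HaplotypeFrequencyTable(
        colony_id=colony_id,
        counts=dict(counter),
        n_informative=sum(counter.values()),
        n_excluded=n_excluded,
    )


@dataclass(frozen=True)
class DuplexGenotype:
    """Two-strand genotype of one colony's SSA product.

    ``top`` and ``bottom`` are 7-character haplotypes over {F, A}; a site
    where they differ was retained as heteroduplex. ``support`` holds the
    frequencies of the underlying haplotype(s) when called from reads.
    """

    top: str | None
    bottom: str | None
    flags: frozenset[str] = frozenset()
    support: tuple[float, ...] = ()

    @property
    def is_no_call(self) -> bool:
        return NO_CALL in self.flags

    def strands(self) -> tuple[str, str]:
        if self.top is None or self.bottom is None:
            raise ValueError("genotype has no called strands (no_call)")
        return self.top, self.bottom

    def unordered(self) -> frozenset[str] | None:
        """Strand pair as an unordered set, for truth comparison."""
        if self.top is None or self.bottom is None:
            return None
        return frozenset((self.top, self.bottom))


def call_duplex(
    table: HaplotypeFrequencyTable, threshold: float = 0.19
) -> DuplexGenotype:
    """Assign a duplex genotype from a colony's haplotype frequencies.

    Haplotypes with frequency strictly greater than ``threshold`` are
    ranked by descending frequency (ties broken lexicographically). Two or
    more: the top two are the strands (``ambiguous_extra`` flagged beyond
    two). Exactly one: a homoduplex. None: ``no_call``.
    """
    if table.n_informative == 0:
        raise ValueError(f"colony {table.colony_id}: empty frequency table")
    freqs = table.frequencies()
    passing = sorted(
        ((h, f) for h, f in freqs.items() if f > threshold),
        key=lambda item: (-item[1], item[0]),
    )
    if not passing:
        return DuplexGenotype(None, None, flags=frozenset({NO_CALL}))
    if len(passing) == 1:
        h, f = passing[0]
        return DuplexGenotype(h, h, flags=frozenset({HOMODUPLEX}), support=(f,))
    flags = frozenset({AMBIGUOUS_EXTRA}) if len(passing) > 2 else frozenset()
    (h1, f1), (h2, f2) = passing[0], passing[1]
    return DuplexGenotype(h1, h2, flags=flags, support=(f1, f2))


def call_colony(
    calls: Sequence,
    colony_id: int | str = "",
    threshold: float = 0.19,
    apply_fix: bool = True,
) -> tuple[DuplexGenotype, HaplotypeFrequencyTable]:
    """Frequency table plus duplex genotype for one colony's traced reads."""
    table = build_frequency_table(calls, colony_id=colony_id, apply_fix=apply_fix)
    if table.n_informative == 0:
        return DuplexGenotype(None, None, flags=frozenset({NO_CALL})), table
    return call_duplex(table, threshold=threshold), table
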