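"""Per-read F/A haplotype calls across the seven variant sites.

Sites are located by exact 8-mer anchors flanking each position (the
amplicons are short, fixed-locus and orientation-known, so anchored
extraction replaces alignment). The poly-T homopolymer needs special
handling: the position of the one-T indel (MM2) inside the run cannot be
observed directly, so MM2 is inferred from the run length between the two
run anchors, after accounting for whether MM1 (the first base of the run
region) contributed a T.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .genotype_calling import N_SITES
from .read_processing import MergedRead
from .synthetic_data import VariantMap, VariantSite


@dataclass(frozen=True)
class HaplotypeCall:
    """Per-read call string over {F, A, N} plus the observed poly-T length.

    ``run_length_observed`` is the contiguous run length between the run
    anchors including MM1's T when MM1 reads as F (so 12 on a clean F read,
    10 on a clean A read); 0 when the run region could not be read.
    ``run_span`` is the full distance between the two run anchors; unlike
    the contiguous count it is insensitive to substitution errors inside
    the run, so it isolates slippage indels.
    """

    read_id: str
    calls: str
    run_length_observed: int
    run_span: int = 0

    def __post_init__(self) -> None:
        if len(self.calls) != N_SITES:
            raise ValueError(f"calls must have length {N_SITES}: {self.calls!r}")


def _find_unique(sequence: str, anchor: str) -> int | None:
    i = sequence.find(anchor)
    if i < 0 or sequence.find(anchor, i + 1) >= 0:
        return None
    return i


def locate_site(sequence: str, site: VariantSite) -> int | None:
    """Position of the site's base in ``sequence``, or None.

    Left-anchored sites sit immediately after the unique occurrence of
    their left anchor; right-anchored sites (MM3, whose left context is
    the homopolymer) immediately before their right anchor. Returns None
    when the anchor is absent or occurs more than once.
    """
    if site.locate_by == "right":
        i = _find_unique(sequence, site.right_anchor)
        return None if i is None or i == 0 else i - 1
    i = _find_unique(sequence, site.left_anchor)
    return None if i is None else i + len(site.left_anchor)


def call_substitution_site(sequence: str, site: VariantSite) -> str:
    """F/A/N call at one substitution site."""
    pos = locate_site(sequence, site)
    if pos is None or pos >= len(sequence):
        return "N"
    base = sequence[pos]
    if base == site.f_allele:
        return "F"
    if base == site.a_allele:
        return "A"
    return "N"


def _run_length(segment: str, start: int, base: str) -> int:
    n = 0
    for c in segment[start:]:
        if c != base:
            break
        n += 1
    return n


def call_homopolymer_sites(
    sequence: str, run_site: VariantSite, mm1_site: VariantSite
) -> tuple[str, str, int, int]:
    """MM1 and MM2 calls from the poly-T run region.

    Between the run anchors, the first base decides MM1 (T reads as F, the
    A allele as A, anything else N). The contiguous T count n, minus one
    when MM1 contributed a T, gives the post-MM1 run length n': n' >= 11
    reads as an F-length run (insertion present), n' <= 10 as A. MM2 is N
    whenever MM1 is N. Returns (MM1, MM2, n, anchor span).
    """
    li = _find_unique(sequence, run_site.left_anchor)
    ri = _find_unique(sequence, run_site.right_anchor)
    if li is None or ri is None:
        return "N", "N", 0, 0
    start = li + len(run_site.left_anchor)
    if ri <= start:
        return "N", "N", 0, 0
    segment = sequence[start:ri]
    first = segment[0]
    if first == run_site.run_base:
        mm1 = "F"
        n = _run_length(segment, 0, run_site.run_base)
    elif first == mm1_site.a_allele:
        mm1 = "A"
        n = _run_length(segment, 1, run_site.run_base)
    else:
        return "N", "N", 0, len(segment)
    n_eff = n - (1 if mm1 == "F" else 0)
    mm2 = "F" if n_eff >= run_site.f_run_len - 1 else "A"
    return mm1, mm2, n, len(segment)


def call_haplotype(
    read: MergedRead | str, vmap: VariantMap, read_id: str = ""
) -> HaplotypeCall:
    """Trace one read across all seven sites, in MM1..MM7 order."""
    if isinstance(read, MergedRead):
        sequence = read.sequence
        read_id = read_id or read.r1_id
    else:
        sequence = read
    mm1_site, run_site = vmap.sites[0], vmap.sites[1]
    mm1, mm2, run_len, span = call_homopolymer_sites(sequence, run_site, mm1_site)
    calls = [mm1, mm2]
    for site in vmap.sites[2:]:
        calls.append(call_substitution_site(sequence, site))
    return HaplotypeCall(read_id=read_id, calls="".join(calls),
                         run_length_observed=run_len, run_span=span)


def trace_reads(
    reads: Iterable[MergedRead | str], vmap: VariantMap
) -> list[HaplotypeCall]:
    return [call_haplotype(read, vmap) for read in reads]


def mm2_raw_discordance(
    calls: Sequence[HaplotypeCall], vmap: VariantMap
) -> float:
    """Fraction of reads whose poly-T region length contradicts MM1.

    A read whose MM1 reads as F should span the full F run between the run
    anchors, an A read one base less; a shifted span marks a slippage
    indel, the artifact the MM2 correction rule exists to repair (about 5%
    of reads with a high-fidelity polymerase, up to about 24% with Taq).
    The anchor span rather than the contiguous T count is compared, so
    substitution errors inside the run (quantified by the substitution
    model, not by slippage) do not inflate the estimate.
    """
    run, mm3 = vmap.run_site, vmap.sites[2]
    # non-run bases between the anchors on the F template (here: MM3)
    extra = (mm3.f_pos + 1) - (run.run_start + run.f_run_len)
    expected = {
        "F": run.f_run_len + extra,          # MM1's T lies inside the run
        "A": run.a_run_len + 1 + extra,      # MM1 base precedes the run
    }
    informative = [c for c in calls if c.calls[0] in "FA"]
    if not informative:
        raise ValueError("no reads with an informative MM1 call")
    n_discordant = sum(
        1 for c in informative if c.run_span != expected[c.calls[0]]
    )
    return n_discordant / len(informative)
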