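"""Read-pair merging, length/quality filtering, and dual-barcode demultiplexing.

Paired amplicon reads are merged on their overlap (the amplicon is shorter
than twice the mate length, so every proper pair overlaps), filtered on
merged length and mean Phred quality, and assigned to colonies by the exact
pair of 8-bp barcodes that the two PCR primers carried.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Union

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .synthetic_data import LibraryDesign

_REVCOMP = str.maketrans("ACGTN", "TGCAN")

#: default seed length used to enumerate candidate overlaps
_SEED_LEN = 12


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return sequence.translate(_REVCOMP)[::-1]


def phred_array(quality: str) -> np.ndarray:
    """Decode a Phred+33 quality string to an integer array."""
    return np.frombuffer(quality.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33


def phred_string(quality: np.ndarray) -> str:
    """Encode integer Phred scores as a Phred+33 string."""
    return (np.asarray(quality, dtype=np.uint8) + 33).tobytes().decode("ascii")


@dataclass(frozen=True)
class FastqRecord:
    """One sequencing read: identifier, bases, and Phred+33 quality string."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.id}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.quality)})"
            )


@dataclass(frozen=True)
class MergedRead:
    """Consensus of an overlapping read pair.

    ``sequence`` runs in the orientation of the forward mate (R1); in the
    overlap the base with the higher Phred score wins and the consensus
    quality is the maximum of the two mates' scores.
    """

    sequence: str
    quality: np.ndarray
    mean_q: float
    r1_id: str
    r2_id: str
    overlap_len: int

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MergeReject:
    """Non-exceptional merge failure; ``reason`` is no_overlap or ambiguous."""

    reason: str
    r1_id: str = ""
    r2_id: str = ""


MergeResult = Union[MergedRead, MergeReject]


def merge_pair(
    r1: FastqRecord,
    r2: FastqRecord,
    min_overlap: int = 30,
    max_mismatch: int = 0,
) -> MergeResult:
    """Merge a read pair on the unique qualifying overlap.

    R2 is reverse-complemented, candidate alignments of its prefix inside R1
    are enumerated with two 12-mer seeds, and an overlap qualifies when it is
    at least ``min_overlap`` long with at most ``max_mismatch`` mismatches.
    The merge is rejected (``no_overlap``) when nothing qualifies and
    (``ambiguous``) when more than one distinct overlap qualifies.
    """
    rc2 = revcomp(r2.sequence)
    n1, n2 = len(r1.sequence), len(rc2)
    if n1 < min_overlap or n2 < min_overlap:
        return MergeReject("no_overlap", r1.id, r2.id)

    candidates: set[int] = set()
    for seed_off in (0, _SEED_LEN):
        if seed_off + _SEED_LEN > n2:
            break
        seed = rc2[seed_off : seed_off + _SEED_LEN]
        i = r1.sequence.find(seed)
        while i >= 0:
            if i - seed_off >= 0:
                candidates.add(i - seed_off)
            i = r1.sequence.find(seed, i + 1)

    a1 = np.frombuffer(r1.sequence.encode("ascii"), dtype=np.uint8)
    a2 = np.frombuffer(rc2.encode("ascii"), dtype=np.uint8)
    qualifying: list[tuple[int, int]] = []
    for s in sorted(candidates):
        overlap = min(n1 - s, n2)
        if overlap < min_overlap:
            continue
        if r1.sequence[s : s + overlap] == rc2[:overlap]:
            qualifying.append((s, overlap))
        elif max_mismatch > 0:
            nmm = int(np.count_nonzero(a1[s : s + overlap] != a2[:overlap]))
            if nmm <= max_mismatch:
                qualifying.append((s, overlap))

    if not qualifying:
        return MergeReject("no_overlap", r1.id, r2.id)
    if len(qualifying) > 1:
        return MergeReject("ambiguous", r1.id, r2.id)

    s, overlap = qualifying[0]
    q1 = phred_array(r1.quality)
    q2 = phred_array(r2.quality)[::-1]  # reversed with the revcomp

    o1b, o2b = a1[s : s + overlap], a2[:overlap]
    o1q, o2q = q1[s : s + overlap], q2[:overlap]
    cons_bases = np.where(o2q > o1q, o2b, o1b)
    cons_qual = np.maximum(o1q, o2q)

    sequence = (
        r1.sequence[:s] + cons_bases.tobytes().decode("ascii") + rc2[overlap:]
    )
    quality = np.concatenate([q1[:s], cons_qual, q2[overlap:]])
    return MergedRead(
        sequence=sequence,
        quality=quality,
        mean_q=float(quality.mean()),
        r1_id=r1.id,
        r2_id=r2.id,
        overlap_len=overlap,
    )


def filter_read(
    merged: MergedRead, min_len: int = 250, min_mean_q: float = 35.0
) -> bool:
    """Keep a merged read iff length > min_len and mean Phred > min_mean_q.

    Both inequalities are strict: a 250-bp read or a read of mean quality
    exactly 35 is dropped.
    """
    return len(merged.sequence) > min_len and merged.mean_q > min_mean_q


@dataclass
class ColonyReadSet:
    """Reads assigned to one colony, with per-colony rejection counters."""

    colony_id: int
    forward_barcode: str
    reverse_barcode: str
    reads: list[MergedRead] = field(default_factory=list)
    n_rejected_merge: int = 0
    n_rejected_filter: int = 0
    n_unassigned: int = 0


@dataclass
class LibraryCounts:
    """Library-level read-pair accounting.

    Invariant: assigned + unassigned + rejected_merge + rejected_filter
    equals total_pairs.
    """

    total_pairs: int = 0
    rejected_merge: int = 0
    rejected_filter: int = 0
    assigned: int = 0
    unassigned: int = 0

    def conserved(self) -> bool:
        return (
            self.assigned
            + self.unassigned
            + self.rejected_merge
            + self.rejected_filter
            == self.total_pairs
        )


def _barcode_lookup(design: "LibraryDesign") -> Mapping[tuple[str, str], int]:
    pairs = design.colony_pairs()
    lookup: dict[tuple[str, str], int] = {}
    for colony_id, pair in enumerate(pairs):
        if pair in lookup:
            raise ValueError(f"duplicate barcode pair {pair} in library design")
        lookup[pair] = colony_id
    return lookup


def _match_barcode(observed: str, barcodes: Iterable[str], max_mismatch: int) -> str | None:
    """Return the unique barcode within ``max_mismatch`` of ``observed``."""
    hits = [
        bc
        for bc in barcodes
        if sum(a != b for a, b in zip(observed, bc)) <= max_mismatch
    ]
    return hits[0] if len(hits) == 1 else None


def demultiplex(
    merged_reads: Iterable[MergedRead],
    design: "LibraryDesign",
    barcode_len: int = 8,
    max_barcode_mismatch: int = 0,
) -> tuple[dict[int, ColonyReadSet], int]:
    """Assign merged reads to colonies by their dual barcodes.

    The forward barcode is the first ``barcode_len`` bases of the merged
    sequence and the reverse barcode is the reverse complement of its last
    ``barcode_len`` bases (the merged read carries both primer ends).
    Barcodes must match a configured pair exactly by default; assigned reads
    have both barcodes trimmed. Returns the per-colony read sets and the
    number of unassigned reads.
    """
    lookup = _barcode_lookup(design)
    colonies: dict[int, ColonyReadSet] = {
        cid: ColonyReadSet(cid, fbc, rbc)
        for (fbc, rbc), cid in lookup.items()
    }
    n_unassigned = 0
    for read in merged_reads:
        if len(read.sequence) < 2 * barcode_len:
            n_unassigned += 1
            continue
        fbc = read.sequence[:barcode_len]
        rbc = revcomp(read.sequence[-barcode_len:])
        if max_barcode_mismatch > 0:
            f_match = _match_barcode(fbc, design.forward_barcodes, max_barcode_mismatch)
            r_match = _match_barcode(rbc, design.reverse_barcodes, max_barcode_mismatch)
            key = (f_match, r_match) if f_match and r_match else None
        else:
            key = (fbc, rbc)
        colony_id = lookup.get(key) if key is not None else None
        if colony_id is None:
            n_unassigned += 1
            continue
        trimmed_q = read.quality[barcode_len:-barcode_len]
        colonies[colony_id].reads.append(
            MergedRead(
                sequence=read.sequence[barcode_len:-barcode_len],
                quality=trimmed_q,
                mean_q=float(trimmed_q.mean()),
                r1_id=read.r1_id,
                r2_id=read.r2_id,
                overlap_len=read.overlap_len,
            )
        )
    return colonies, n_unassigned


def process_library(
    r1_records: list[FastqRecord],
    r2_records: list[FastqRecord],
    design: "LibraryDesign",
    min_overlap: int = 30,
    max_mismatch: int = 0,
    min_len: int = 250,
    min_mean_q: float = 35.0,
    max_barcode_mismatch: int = 0,
) -> tuple[dict[int, ColonyReadSet], LibraryCounts]:
    """Merge, filter, and demultiplex a whole library of read pairs.

    Merge-first order: pairs are merged, the L/Q filter is applied to the
    merged consensus, and survivors are demultiplexed. Rejections before
    demultiplexing are attributed to a colony when the raw mate prefixes
    match a configured barcode pair, so the per-colony counters are
    informative even for reads that never reach assignment.
    """
    if len(r1_records) != len(r2_records):
        raise ValueError("R1 and R2 record lists differ in length")
    lookup = _barcode_lookup(design)
    counts = LibraryCounts(total_pairs=len(r1_records))
    survivors: list[MergedRead] = []
    # raw-prefix attribution of pre-demux rejections, keyed by colony
    raw_rejects: dict[int, list[int]] = {cid: [0, 0] for cid in lookup.values()}
    for r1, r2 in zip(r1_records, r2_records):
        raw_key = (r1.sequence[:8], r2.sequence[:8])
        raw_colony = lookup.get(raw_key)
        merged = merge_pair(r1, r2, min_overlap=min_overlap, max_mismatch=max_mismatch)
        if isinstance(merged, MergeReject):
            counts.rejected_merge += 1
            if raw_colony is not None:
                raw_rejects[raw_colony][0] += 1
            continue
        if not filter_read(merged, min_len=min_len, min_mean_q=min_mean_q):
            counts.rejected_filter += 1
            if raw_colony is not None:
                raw_rejects[raw_colony][1] += 1
            continue
        survivors.append(merged)
    colonies, n_unassigned = demultiplex(
        survivors, design, max_barcode_mismatch=max_barcode_mismatch
    )
    counts.unassigned = n_unassigned
    counts.assigned = sum(len(c.reads) for c in colonies.values())
    for cid, (n_merge, n_filter) in raw_rejects.items():
        colonies[cid].n_rejected_merge = n_merge
        colonies[cid].n_rejected_filter = n_filter
    return colonies, counts
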