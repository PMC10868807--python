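"""Synthetic SSA amplicon sequencing libraries.

The system emulated here: a yeast strain carries two ~200-bp URA3-promoter
repeats, F and A, that differ at seven sites (MM1-MM7) - six single-base
substitutions and a one-T insertion (MM2) inside a poly-T homopolymer whose
length is 12 T's on F and 10 T's on A (MM1 is the first T of the F run and
MM3 sits immediately right of the run). A double-strand break between the
repeats is repaired by single-strand annealing (SSA); the annealed
intermediate is a heteroduplex whose mismatches are corrected toward F or A,
or left unrepaired. Each surviving colony's SSA product is amplified with a
unique pair of 8-bp-barcoded primers (8 forward x 12 reverse = 96 colonies
per library) and paired-end sequenced.

This module generates: reference repeat pairs with that geometry, colony
duplex genotypes under parameterised repair models, and barcoded paired-end
FASTQ reads with substitution sequencing error and homopolymer slippage at
configurable rates (about 5% for a high-fidelity polymerase, about 24% for
a Taq-like one).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotype_calling import DuplexGenotype, N_SITES
from .read_processing import FastqRecord, phred_string, revcomp

BASES = "ACGT"
ANCHOR_K = 8

SUBSTITUTION = "substitution"
HOMOPOLYMER_INDEL = "homopolymer_indel"


# ---------------------------------------------------------------------------
# reference geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSite:
    """One of the seven F/A variant sites.

    ``f_pos`` is the 0-based position on the F repeat. Substitution sites
    carry single-nucleotide ``f_allele``/``a_allele``; the homopolymer site
    (index 2) instead carries the run geometry. ``locate_by`` says which
    flanking anchor k-mer positions the site in a read: 'left' (base right
    after the left anchor), 'right' (base right before the right anchor) or
    'run' (handled by the homopolymer caller, which uses both anchors).
    """

    index: int
    kind: str
    f_pos: int
    f_allele: str = ""
    a_allele: str = ""
    run_base: str = "T"
    f_run_len: int = 0
    a_run_len: int = 0
    run_start: int = -1
    left_anchor: str = ""
    right_anchor: str = ""
    locate_by: str = "left"


@dataclass(frozen=True)
class VariantMap:
    """Ordered map of the seven variant sites on the repeat pair."""

    sites: tuple[VariantSite, ...]

    def __post_init__(self) -> None:
        if len(self.sites) != N_SITES:
            raise ValueError(f"expected {N_SITES} sites, got {len(self.sites)}")
        positions = [s.f_pos for s in self.sites]
        if positions != sorted(positions) or len(set(positions[1:])) != N_SITES - 1:
            # MM1 and the run share f_pos (MM1 is the first T of the run)
            raise ValueError("site positions must increase left to right")
        homopolymer = [s for s in self.sites if s.kind == HOMOPOLYMER_INDEL]
        if len(homopolymer) != 1 or homopolymer[0].index != 2:
            raise ValueError("exactly one homopolymer_indel site, at index 2")
        run = homopolymer[0]
        mm1, mm3 = self.sites[0], self.sites[2]
        if mm1.f_allele != run.run_base or mm1.f_pos != run.run_start:
            raise ValueError("MM1's F allele must be the first base of the F run")
        if mm3.f_pos != run.run_start + run.f_run_len:
            raise ValueError("MM3 must sit immediately right of the run")

    @property
    def run_site(self) -> VariantSite:
        return self.sites[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.sites])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VariantMap":
        frame = pd.read_csv(path, sep="\t", keep_default_na=False)
        sites = tuple(
            VariantSite(**{k: row[k] for k in row.index}) for _, row in frame.iterrows()
        )
        return cls(sites)


@dataclass(frozen=True)
class RepeatPair:
    """The two repeat alleles plus primer-binding flanks.

    ``f_seq`` and ``a_seq`` differ exactly at the variant-map sites; the A
    repeat is one base shorter because of the poly-T indel.
    """

    f_seq: str
    a_seq: str
    left_flank: str
    right_flank: str
    name: str = "FA_repeat"

    def f_amplicon(self) -> str:
        return self.left_flank + self.f_seq + self.right_flank

    def a_amplicon(self) -> str:
        return self.left_flank + self.a_seq + self.right_flank

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(self.f_seq), id=f"{self.name}_F", description="F repeat"),
            SeqRecord(Seq(self.a_seq), id=f"{self.name}_A", description="A repeat"),
            SeqRecord(Seq(self.left_flank), id=f"{self.name}_left_flank", description=""),
            SeqRecord(Seq(self.right_flank), id=f"{self.name}_right_flank", description=""),
        ]
        SeqIO.write(records, str(path), "fasta")


def _random_bases(rng: np.random.Generator, n: int) -> list[str]:
    return [BASES[i] for i in rng.integers(0, 4, size=n)]


def _count_occurrences(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def make_reference_pair(
    seed: int = 1,
    f_len: int = 205,
    mm1_pos: int = 17,
    f_run_len: int = 12,
    a_run_len: int = 10,
    substitution_positions: Sequence[int] = (55, 82, 108, 135),
    flank_len: int = 30,
    max_tries: int = 100,
) -> tuple[RepeatPair, VariantMap]:
    """Generate a synthetic F/A repeat pair with the study geometry.

    MM1 at F position ``mm1_pos`` is the first T of a 12-T run, MM3 is the
    base immediately right of the run, MM4-MM6 are evenly spaced, and MM7
    sits 70 bp from the right end of the 205-bp repeat. Flanking 8-mer
    anchors for every site must occur exactly once in each full amplicon;
    sequences are redrawn (up to ``max_tries``) until they do.
    """
    rng = np.random.default_rng(seed)
    run_start = mm1_pos
    mm3_pos = run_start + f_run_len
    sub_positions = (mm3_pos, *substitution_positions)
    if len(sub_positions) != 5:
        raise ValueError("need MM3 plus four substitution positions (MM4-MM7)")
    non_t = [b for b in BASES if b != "T"]

    for _ in range(max_tries):
        f = _random_bases(rng, f_len)
        f[run_start:mm3_pos] = ["T"] * f_run_len
        f[mm1_pos - 1] = non_t[rng.integers(0, 3)]   # keep the F run exactly 12
        f[mm3_pos] = non_t[rng.integers(0, 3)]       # ... and right-bounded
        f_seq = "".join(f)

        # A alleles: MM1 and MM3 must be non-T so the A run is exactly 10
        a_alleles: dict[int, str] = {}
        mm1_a = non_t[rng.integers(0, 3)]
        for pos in sub_positions:
            pool = non_t if pos == mm3_pos else list(BASES)
            choices = [b for b in pool if b != f_seq[pos]]
            a_alleles[pos] = choices[rng.integers(0, len(choices))]

        a_parts = [
            f_seq[:run_start],
            mm1_a,
            "T" * a_run_len,
        ]
        prev = mm3_pos
        for pos in sub_positions:
            a_parts.append(f_seq[prev:pos])
            a_parts.append(a_alleles[pos])
            prev = pos + 1
        a_parts.append(f_seq[prev:])
        a_seq = "".join(a_parts)

        left_flank = "".join(_random_bases(rng, flank_len))
        right_flank = "".join(_random_bases(rng, flank_len))

        run_left_anchor = f_seq[run_start - ANCHOR_K : run_start]
        run_right_anchor = f_seq[mm3_pos + 1 : mm3_pos + 1 + ANCHOR_K]
        sites = [
            VariantSite(
                index=1, kind=SUBSTITUTION, f_pos=mm1_pos,
                f_allele="T", a_allele=mm1_a,
                left_anchor=run_left_anchor, right_anchor=run_right_anchor,
                locate_by="run",
            ),
            VariantSite(
                index=2, kind=HOMOPOLYMER_INDEL, f_pos=run_start,
                run_base="T", f_run_len=f_run_len, a_run_len=a_run_len,
                run_start=run_start,
                left_anchor=run_left_anchor, right_anchor=run_right_anchor,
                locate_by="run",
            ),
            VariantSite(
                index=3, kind=SUBSTITUTION, f_pos=mm3_pos,
                f_allele=f_seq[mm3_pos], a_allele=a_alleles[mm3_pos],
                left_anchor=run_left_anchor, right_anchor=run_right_anchor,
                locate_by="right",
            ),
        ]
        for i, pos in enumerate(substitution_positions, start=4):
            sites.append(
                VariantSite(
                    index=i, kind=SUBSTITUTION, f_pos=pos,
                    f_allele=f_seq[pos], a_allele=a_alleles[pos],
                    left_anchor=f_seq[pos - ANCHOR_K : pos],
                    right_anchor=f_seq[pos + 1 : pos + 1 + ANCHOR_K],
                    locate_by="left",
                )
            )

        pair = RepeatPair(f_seq, a_seq, left_flank, right_flank)
        anchors = {s.left_anchor for s in sites} | {s.right_anchor for s in sites}
        if all(
            _count_occurrences(pair.f_amplicon(), a) == 1
            and _count_occurrences(pair.a_amplicon(), a) == 1
            for a in anchors
        ):
            return pair, VariantMap(tuple(sites))

    raise ValueError(
        f"could not draw anchor-unique references in {max_tries} tries (seed {seed})"
    )


def build_strand_sequence(
    haplotype: str, pair: RepeatPair, vmap: VariantMap, slip: int = 0
) -> str:
    """Amplicon sequence of one strand haplotype (flanks included).

    ``haplotype`` is a 7-character F/A string; ``slip`` shifts the poly-T
    run length by that many bases (models polymerase slippage). The all-F
    haplotype with slip 0 reproduces the F amplicon exactly, all-A the A
    amplicon.
    """
    if len(haplotype) != N_SITES or any(c not in "FA" for c in haplotype):
        raise ValueError(f"invalid haplotype {haplotype!r}")
    mm1, run = vmap.sites[0], vmap.sites[1]
    run_tail = (run.f_run_len - 1) if haplotype[1] == "F" else run.a_run_len
    parts = [
        pair.left_flank,
        pair.f_seq[: mm1.f_pos],
        mm1.f_allele if haplotype[0] == "F" else mm1.a_allele,
        run.run_base * (run_tail + slip),
    ]
    prev = run.run_start + run.f_run_len
    for i, site in enumerate(vmap.sites[2:], start=2):
        parts.append(pair.f_seq[prev : site.f_pos])
        parts.append(site.f_allele if haplotype[i] == "F" else site.a_allele)
        prev = site.f_pos + 1
    parts.append(pair.f_seq[prev:])
    parts.append(pair.right_flank)
    return "".join(parts)


# ---------------------------------------------------------------------------
# repair and error models
# ---------------------------------------------------------------------------

END_GRADIENT = "end_gradient"
INDEPENDENT = "independent"


@dataclass(frozen=True)
class RepairModel:
    """Generative model for a colony's SSA repair outcome.

    With probability ``p_all_f``/``p_all_a`` every site is corrected to
    F/A; with ``p_het`` nothing is corrected (a fully heteroduplex
    product); with ``p_mixed`` each site either resolves to F (probability
    ``site_f_bias[i]``) or stays heteroduplex. ``rho`` couples the mixed
    per-site decisions through a shared uniform (0 = independent sites,
    1 = all-or-none). ``end_gradient`` mode uses one shared uniform against
    a non-increasing bias vector, so corrected sites always form a single
    left-anchored tract with a left-to-right switch point and the per-site
    F marginals still equal ``site_f_bias``.
    """

    p_all_f: float
    p_all_a: float
    p_het: float
    p_mixed: float
    site_f_bias: tuple[float, ...] = (0.87, 0.85, 0.80, 0.72, 0.65, 0.58, 0.53)
    rho: float = 1.0
    tract_mode: str = END_GRADIENT

    def __post_init__(self) -> None:
        probs = (self.p_all_f, self.p_all_a, self.p_het, self.p_mixed)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("outcome probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"outcome probabilities sum to {sum(probs)}, not 1")
        if len(self.site_f_bias) != N_SITES:
            raise ValueError(f"site_f_bias needs {N_SITES} entries")
        if any(b < 0 or b > 1 for b in self.site_f_bias):
            raise ValueError("site_f_bias entries must lie in [0, 1]")
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must lie in [0, 1]")
        if self.tract_mode not in (END_GRADIENT, INDEPENDENT):
            raise ValueError(f"unknown tract_mode {self.tract_mode!r}")
        if self.tract_mode == END_GRADIENT and any(
            b2 > b1 for b1, b2 in zip(self.site_f_bias, self.site_f_bias[1:])
        ):
            raise ValueError("end_gradient mode needs a non-increasing site_f_bias")

    @classmethod
    def wild_type_tailed(cls) -> "RepairModel":
        """Tailed wild-type-like mix: mostly uniform-F or mixed tracts."""
        return cls(p_all_f=0.40, p_all_a=0.06, p_het=0.05, p_mixed=0.49)

    @classmethod
    def coordinated_tailless(cls) -> "RepairModel":
        """Tailless-like all-or-none correction (rho=1, flat bias)."""
        return cls(
            p_all_f=0.35, p_all_a=0.30, p_het=0.10, p_mixed=0.25,
            site_f_bias=(0.5,) * N_SITES, rho=1.0, tract_mode=INDEPENDENT,
        )

    @classmethod
    def pure(cls, allele: str) -> "RepairModel":
        """Degenerate model: every colony fully corrected to one allele."""
        if allele == "F":
            return cls(1.0, 0.0, 0.0, 0.0)
        if allele == "A":
            return cls(0.0, 1.0, 0.0, 0.0)
        raise ValueError("allele must be 'F' or 'A'")


def simulate_duplex_genotype(
    model: RepairModel, rng: np.random.Generator
) -> DuplexGenotype:
    """Draw one colony's duplex genotype from a repair model."""
    u = rng.random()
    if u < model.p_all_f:
        return DuplexGenotype("F" * N_SITES, "F" * N_SITES)
    if u < model.p_all_f + model.p_all_a:
        return DuplexGenotype("A" * N_SITES, "A" * N_SITES)
    if u < model.p_all_f + model.p_all_a + model.p_het:
        return DuplexGenotype("F" * N_SITES, "A" * N_SITES)
    shared = rng.random()
    bottom = []
    for i, bias in enumerate(model.site_f_bias):
        if model.tract_mode == END_GRADIENT:
            u_site = shared
        else:
            u_site = shared if rng.random() < model.rho else rng.random()
        bottom.append("F" if u_site < bias else "A")
    # corrected sites carry F on both strands; heteroduplex sites keep
    # the F allele on top and the A allele on bottom
    return DuplexGenotype("F" * N_SITES, "".join(bottom))


@dataclass(frozen=True)
class ErrorModel:
    """Sequencing/PCR error model for read simulation.

    ``sub_rate`` is the per-base substitution probability applied to each
    mate independently; ``homopolymer_indel_rate`` is the probability that
    a read pair's template carries a +-1 slippage of the poly-T run
    (symmetric, applied once per pair since it is a PCR artifact shared by
    both mates). Phred scores are Normal(quality_mean, quality_sd) clamped
    to [2, 41].
    """

    sub_rate: float = 0.0
    homopolymer_indel_rate: float = 0.0
    quality_mean: float = 37.0
    quality_sd: float = 3.0

    def __post_init__(self) -> None:
        for rate in (self.sub_rate, self.homopolymer_indel_rate):
            if not 0 <= rate <= 1:
                raise ValueError("error rates must lie in [0, 1]")


@dataclass(frozen=True)
class LibraryDesign:
    """Dual-barcode layout and depth model of one 96-colony library."""

    forward_barcodes: tuple[str, ...]
    reverse_barcodes: tuple[str, ...]
    n_colonies: int = 96
    depth_mean: float = 186.0
    depth_sd: float = 112.0
    depth_min: int = 7
    read_len: int = 250
    seed: int = 1

    def __post_init__(self) -> None:
        barcodes = self.forward_barcodes + self.reverse_barcodes
        if any(len(b) != ANCHOR_K for b in barcodes):
            raise ValueError("barcodes must be 8 bp")
        for i, b1 in enumerate(barcodes):
            for b2 in barcodes[i + 1 :]:
                if sum(a != c for a, c in zip(b1, b2)) < 3:
                    raise ValueError(f"barcodes {b1}/{b2} closer than Hamming 3")
        if self.n_colonies > len(self.forward_barcodes) * len(self.reverse_barcodes):
            raise ValueError("more colonies than barcode pairs")
        if self.depth_sd ** 2 <= self.depth_mean:
            raise ValueError("depth model requires variance > mean (overdispersion)")
        if self.depth_min < 1:
            raise ValueError("depth_min must be >= 1")

    def colony_pairs(self) -> list[tuple[str, str]]:
        nf = len(self.forward_barcodes)
        return [
            (self.forward_barcodes[c % nf], self.reverse_barcodes[c // nf])
            for c in range(self.n_colonies)
        ]

    def pair_for(self, colony_id: int) -> tuple[str, str]:
        if not 0 <= colony_id < self.n_colonies:
            raise ValueError(f"colony_id {colony_id} outside design")
        return self.colony_pairs()[colony_id]

    @classmethod
    def default(cls, seed: int = 1, n_colonies: int = 96, **kwargs) -> "LibraryDesign":
        rng = np.random.default_rng(seed)
        barcodes = generate_barcodes(rng, 8 + 12)
        return cls(
            forward_barcodes=tuple(barcodes[:8]),
            reverse_barcodes=tuple(barcodes[8:]),
            n_colonies=n_colonies,
            seed=seed,
            **kwargs,
        )


def generate_barcodes(
    rng: np.random.Generator,
    n: int,
    length: int = ANCHOR_K,
    min_dist: int = 3,
    max_tries: int = 10000,
) -> list[str]:
    """Greedily sample barcodes with pairwise Hamming distance >= min_dist."""
    chosen: list[str] = []
    for _ in range(max_tries):
        candidate = "".join(_random_bases(rng, length))
        if all(
            sum(a != b for a, b in zip(candidate, existing)) >= min_dist
            for existing in chosen
        ):
            chosen.append(candidate)
            if len(chosen) == n:
                return chosen
    raise ValueError(f"could not place {n} barcodes at distance {min_dist}")


def draw_depths(
    design: LibraryDesign, rng: np.random.Generator, n: int | None = None
) -> np.ndarray:
    """Per-colony read depths: negative binomial floored at depth_min.

    The negative binomial is parameterised to the target mean and sd
    (r = mean^2 / (var - mean)), matching the overdispersion of per-colony
    amplicon yields.
    """
    n = design.n_colonies if n is None else n
    mean, var = design.depth_mean, design.depth_sd ** 2
    r = mean ** 2 / (var - mean)
    p = r / (r + mean)
    depths = rng.negative_binomial(r, p, size=n)
    return np.maximum(depths, design.depth_min)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _mutate(sequence: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return sequence
    mask = rng.random(len(sequence)) < rate
    if not mask.any():
        return sequence
    out = list(sequence)
    for pos in np.flatnonzero(mask):
        alternatives = [b for b in BASES if b != out[pos]]
        out[pos] = alternatives[rng.integers(0, 3)]
    return "".join(out)


def _qualities(rng: np.random.Generator, n: int, err: ErrorModel) -> str:
    q = np.rint(rng.normal(err.quality_mean, err.quality_sd, size=n))
    return phred_string(np.clip(q, 2, 41).astype(np.uint8))


@dataclass
class ColonyReadInfo:
    """Ground truth recorded while simulating one colony's reads."""

    colony_id: int
    depth: int
    strand_proportion: float  # fraction of read pairs from the top strand


def simulate_colony_reads(
    genotype: DuplexGenotype,
    pair: RepeatPair,
    vmap: VariantMap,
    err: ErrorModel,
    design: LibraryDesign,
    colony_id: int,
    rng: np.random.Generator,
    depth: int | None = None,
) -> tuple[list[FastqRecord], list[FastqRecord], ColonyReadInfo]:
    """Simulate barcoded paired-end reads for one colony.

    Each pair derives from the top or bottom strand haplotype; the
    within-colony strand proportion is drawn once per colony from
    Beta(20, 20) (sectoring/PCR drift around 50:50). The template is
    barcode + left flank + allele-substituted repeat + right flank +
    barcode; slippage shifts the template's poly-T run by +-1 per pair,
    substitutions hit each mate independently.
    """
    top, bottom = genotype.strands()
    fbc, rbc = design.pair_for(colony_id)
    amplicon_len = ANCHOR_K * 2 + len(pair.f_amplicon())
    if amplicon_len >= 2 * design.read_len:
        raise ValueError(
            f"amplicon ({amplicon_len} bp incl. barcodes) cannot overlap at "
            f"read length {design.read_len}"
        )
    d = int(draw_depths(design, rng, 1)[0]) if depth is None else depth
    proportion = float(rng.beta(20, 20))
    from_top = rng.random(d) < proportion
    slip_event = rng.random(d) < err.homopolymer_indel_rate
    slip_dir = np.where(rng.random(d) < 0.5, -1, 1)
    slips = np.where(slip_event, slip_dir, 0)

    template_cache: dict[tuple[bool, int], tuple[str, str]] = {}
    r1_records: list[FastqRecord] = []
    r2_records: list[FastqRecord] = []
    for i in range(d):
        key = (bool(from_top[i]), int(slips[i]))
        if key not in template_cache:
            hap = top if key[0] else bottom
            amplicon = build_strand_sequence(hap, pair, vmap, slip=key[1])
            fwd = (fbc + amplicon + revcomp(rbc))[: design.read_len]
            rev = (rbc + revcomp(fbc + amplicon))[: design.read_len]
            template_cache[key] = (fwd, rev)
        fwd, rev = template_cache[key]
        r1_seq = _mutate(fwd, rng, err.sub_rate)
        r2_seq = _mutate(rev, rng, err.sub_rate)
        r1_records.append(
            FastqRecord(f"c{colony_id}:{i}/1", r1_seq, _qualities(rng, len(r1_seq), err))
        )
        r2_records.append(
            FastqRecord(f"c{colony_id}:{i}/2", r2_seq, _qualities(rng, len(r2_seq), err))
        )
    return r1_records, r2_records, ColonyReadInfo(colony_id, d, proportion)


@dataclass
class LibrarySimulation:
    """A simulated library: reads in memory plus the per-colony truth table."""

    r1: list[FastqRecord]
    r2: list[FastqRecord]
    truth: pd.DataFrame
    design: LibraryDesign
    pair: RepeatPair
    vmap: VariantMap
    seed: int

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fastq(self.r1, out / "reads_R1.fastq")
        write_fastq(self.r2, out / "reads_R2.fastq")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        self.pair.write_fasta(out / "references.fasta")
        self.vmap.to_tsv(out / "variant_map.tsv")


def simulate_library(
    colony_models: RepairModel | Sequence[RepairModel] | Sequence[DuplexGenotype],
    pair: RepeatPair,
    vmap: VariantMap,
    err: ErrorModel,
    design: LibraryDesign,
    seed: int | None = None,
) -> LibrarySimulation:
    """Simulate a full dual-barcoded library.

    ``colony_models`` is a single RepairModel (applied to every colony), a
    per-colony list of models, or a per-colony list of explicit
    DuplexGenotype truths. Deterministic given ``seed`` (defaults to the
    design's seed).
    """
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if isinstance(colony_models, RepairModel):
        per_colony: list = [colony_models] * design.n_colonies
    else:
        per_colony = list(colony_models)
    if len(per_colony) != design.n_colonies:
        raise ValueError(
            f"need one model/genotype per colony "
            f"({len(per_colony)} given, {design.n_colonies} colonies)"
        )
    r1_all: list[FastqRecord] = []
    r2_all: list[FastqRecord] = []
    rows = []
    for colony_id, spec in enumerate(per_colony):
        genotype = (
            simulate_duplex_genotype(spec, rng)
            if isinstance(spec, RepairModel)
            else spec
        )
        r1, r2, info = simulate_colony_reads(
            genotype, pair, vmap, err, design, colony_id, rng
        )
        r1_all.extend(r1)
        r2_all.extend(r2)
        fbc, rbc = design.pair_for(colony_id)
        rows.append(
            {
                "colony_id": colony_id,
                "forward_barcode": fbc,
                "reverse_barcode": rbc,
                "top": genotype.top,
                "bottom": genotype.bottom,
                "depth": info.depth,
                "strand_proportion": info.strand_proportion,
                "seed": seed,
            }
        )
    truth = pd.DataFrame(rows)
    return LibrarySimulation(r1_all, r2_all, truth, design, pair, vmap, seed)


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------

def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    seq_records = []
    for rec in records:
        sr = SeqRecord(Seq(rec.sequence), id=rec.id, description="")
        sr.letter_annotations["phred_quality"] = list(phred_array_of(rec.quality))
        seq_records.append(sr)
    SeqIO.write(seq_records, str(path), "fastq")


def phred_array_of(quality: str) -> np.ndarray:
    return np.frombuffer(quality.encode("ascii"), dtype=np.uint8) - 33


def read_fastq(path: str | Path) -> list[FastqRecord]:
    records = []
    for sr in SeqIO.parse(str(path), "fastq"):
        qual = phred_string(np.asarray(sr.letter_annotations["phred_quality"]))
        records.append(FastqRecord(sr.id, str(sr.seq), qual))
    return records
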