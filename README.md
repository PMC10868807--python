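# ssa-spectra

Colony-level analysis of mismatch correction during single-strand annealing
(SSA), built as a tested, reusable pipeline over simulated barcoded amplicon
sequencing.

## The problem

When a double-strand break falls between two direct repeats, SSA repairs it
by annealing the complementary strands of the repeats and deleting the
intervening DNA. If the repeats diverge — here two ~200-bp *URA3*-promoter
repeats, **F** and **A**, differing at seven sites (MM1–MM7: six single-base
substitutions plus a one-T insertion, MM2, inside a poly-T run that is 12 T's
on F and 10 T's on A) — the annealed intermediate is a heteroduplex carrying
mismatches. Each surviving colony reports how those mismatches were resolved:
corrected to F, corrected to A, or left unrepaired (the colony then sectors,
carrying both alleles).

Reading that outcome from sequencing is not trivial. Each colony's SSA
product is PCR-amplified with a unique pair of 8-bp-barcoded primers
(8 forward × 12 reverse = 96 colonies per library) and paired-end sequenced,
and the poly-T run is slippage-prone: with a high-fidelity polymerase ~5% of
reads show a shifted run length (up to ~24% with Taq), which scrambles the
MM2 call. The pipeline implements the analysis that copes with this:

1. **Merge** each read pair on its overlap (quality consensus), keep merged
   reads with length > 250 and mean Phred > 35.
2. **Demultiplex** by exact dual-barcode match.
3. **Trace** each read's haplotype — a string over {F, A, N} at MM1–MM7 —
   by anchored extraction, with run-length logic for MM1/MM2: n contiguous
   T's between the run anchors, minus one if MM1 contributed a T, reads as
   F when ≥ 11 and A when ≤ 10.
4. **MM2 fix**: a read whose MM2 call disagrees with concordant MM1 and MM3
   is counted as if MM2 agreed (FAFFFFF → FFFFFFF) — slippage artifacts are
   repaired, at the documented cost of erasing genuine MM1≠MM2 recombinants.
5. **Duplex genotype**: each colony gets the two most frequent haplotypes
   with frequency > 19% (one ⇒ homoduplex; none ⇒ no call). A site where
   the two strands differ was retained heteroduplex.
6. **Spectra**: per-site F/A/heteroduplex fractions, outcome classes
   (all-F / all-A / unrepaired / mixed), adjacent-site concordance, and the
   left–right correction gradient tested with Fisher's exact test.

A first-class synthetic-data module generates the inputs: reference repeat
pairs with the study geometry, colony genotypes drawn from parameterised
repair models (uniform F/A, full heteroduplex, or mixed tracts with an
end-biased gradient), and reads with substitution error, poly-T slippage,
and negative-binomial per-colony depth (mean 186, sd 112).

## Worked example

The numbered scripts under `analysis/` run the full story on one simulated
96-colony wild-type-like library (substitutions 0.002/base, slippage 5%):

```sh
python analysis/01_simulate_library.py --seed 1
python analysis/02_process_and_trace.py
python analysis/03_call_genotypes.py
python analysis/04_summarize_spectra.py
```

Output of the last two steps (seed 1):

```
duplex genotype accuracy vs truth: 96/96 (100.0%)
...
outcome classes (7 sites): {'all_F': 64, 'all_A': 5, 'unrepaired': 12, 'mixed': 15}
gradient in this cohort: MM1 F-corrected 82%, MM7 67%, Fisher p = 1.99e-02
gradient on the printed wild-type counts (124/143 vs 76/143): p = 6.21e-10 (< 0.01)
raw (pre-fix) MM2 run-length discordance: 5.8% of reads
```

Every simulated colony's duplex genotype is recovered exactly despite the
sequencing error; F-correction falls from MM1 (left end) to MM7, the
position-dependent gradient; and on the sequenced study cohort's counts —
MM1 corrected to F in 124/143 colonies (87%) versus MM7 in 76/143 (53%) —
the gradient is highly significant. The raw MM2 discordance shows how often
the poly-T length contradicts the flanking sites before the fix.

## Layout

```
src/ssa_spectra/      the library: synthetic_data, read_processing,
                      variant_tracing, genotype_calling, spectra, pipeline
analysis/             numbered narrative drivers (simulate → trace → call → summarise)
scripts/acceptance.py headline-number recomputation
tests/                pytest suite (unit, property, end-to-end)
docs/methods.md       models, parameters, numerical choices, limitations
```
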