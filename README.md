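# asotiler

Design of antisense DNA oligo pools for RNaseH-mediated depletion of rRNA
(or any other abundant RNA) ahead of RNA-seq library construction.

RNaseH cleaves the RNA strand of an RNA–DNA heteroduplex, so a pool of
antisense DNA oligos hybridized to rRNA directs its digestion. Instead of
tiling the target end to end with 50-mers, `asotiler` places short
(39–40 nt) oligos *sparsely*: untiled gaps of at most 30 nt are left between
oligos, so digestion products stay short enough (≤30 nt with complete
digestion, ~70 nt with partial digestion) to be discarded by a standard
>200 nt size selection. Sparse tiling with short oligos cuts the number of
bases synthesized by roughly a third and, via value pricing of short oligos,
the reagent cost by far more — while letting the designer choose windows
with high predicted melting temperature, so the oligos stay hybridized at
the digestion reaction temperature.

The package is aimed at labs building their own depletion reagents for
non-model organisms, where commercial rRNA-removal kits do not match the
rRNA sequences at hand.

## The method

**Thermodynamics.** The Tm of each candidate RNA–DNA hybrid is predicted by
the nearest-neighbor method with the Sugimoto et al. (1995) hybrid
parameters, indexed by the target RNA strand 5'→3':

```
Tm(°C) = (ΔH − ΔH_init) / (ΔS + R·ln(1/[oligo]) + 16.6·log₁₀[Na⁺]) − 273.15
```

with ΔH = Σ stack enthalpies (cal/mol), ΔS = Σ stack entropies
(cal/(K·mol)), ΔH_init = −3.1 kcal/mol, R = 1.987 cal/(K·mol),
[oligo] = 5×10⁻² mol/L and [Na⁺] = 0.2 mol/L by default. The oligo is
assumed in excess of its target; the default concentration is deliberately
conservative (an 8-fold higher concentration shifts Tm by under 2 °C).

**Tiling.** Oligos are placed left to right greedily: each oligo sits the
maximum distance from the previous one such that the gap stays ≤ 30 nt, the
length is 39–40 nt and Tm ∈ [70, 80] °C. If no in-range candidate exists,
the candidate with Tm closest to the ideal range is retained and flagged.
Near the 3' end the allowed gap shrinks so the remainder can still be
finished without any oversized untiled run. A refinement phase then
re-centers every oligo between its neighbors, maximizing its smaller
flanking gap without leaving the Tm range.

**Shared pools.** Divergent variants of the same RNA (e.g. maternal and
somatic rRNA in zebrafish) are covered by one compact pool: either by exact
reuse of oligos across unaligned targets, or — far more effectively — by
tiling the IUPAC-wildcard consensus of a precomputed alignment. A wildcard
oligo (e.g. one R position = mixture of two oligos) is retained only while
its expansion count stays within a threshold (default 2). Oligos are
classified `common` / `wildcard` / `unique`, and every pool's size is
common + wildcard + its own uniques.

## Worked example

```
$ asotiler fixtures --length 1200 --gc 0.35 --seed 11 --out demo.fa
$ asotiler summarize --fasta demo.fa --price 4.64 --baseline-price 19
n_oligos=21  bases_tiled=827  total_target_bases=1200  fraction_tiled=0.6892  cost=97
baseline_n_oligos=24  baseline_bases=1200  baseline_cost=456  percent_cost_reduction=79
```

21 short oligos tile 827 of 1200 target bases (69 %; the rest are compliant
≤30 nt gaps), versus 24 end-to-end 50-mers covering all 1200 bases: at the
list prices used ($4.64 per value oligo vs $19 per 50-mer) the sparse design
costs $97 instead of $456, a 79 % reduction. The oligo table itself:

```
$ asotiler design --fasta demo.fa --out demo.tsv
$ head -4 demo.tsv
# antisense oligo table; coordinates 1-based inclusive on the target RNA
oligo_id	target_id	start_1based	end_1based	length	antisense_seq	tm_c	oligo_class	n_expansions	gap_to_previous
synthetic_L1200_s11_25_39	synthetic_L1200_s11	25	63	39	GATTTTTCATTAGATTGAAGGTTTATCTGATTGTAATCG	79.45	individual	1	24
synthetic_L1200_s11_77_40	synthetic_L1200_s11	77	116	40	TCATGTTATGTAAAGTCTAAACCAATGTTATGGAATTTAG	75.93	individual	1	13
```

Each row is one antisense DNA oligo (5'→3') with its 1-based inclusive
footprint on the target, predicted hybrid Tm, class, wildcard expansion
count and the untiled gap to the previous oligo. `--bed` additionally
writes standard BED6 (0-based half-open, minus strand). A shared pool over
an aligned variant pair:

```
$ asotiler fixtures --length 4000 --identity 0.86 --seed 0 --out pair.fa
$ asotiler shared --fasta pair.fa --aligned
common=0  wildcard=10  unique[variantA_L4000_s0]=62  unique[variantB_L4000_s0]=62  total_distinct=134
```

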