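# Methods

## Model

An antisense DNA oligo bound to its target RNA forms the RNA–DNA
heteroduplex that RNaseH cleaves. The designer needs two things from a
model: (1) a prediction of whether each candidate duplex survives at the
digestion temperature, and (2) a placement rule that keeps every undigested
target fragment short enough for size selection to remove.

### Hybrid melting temperature

Duplex stability is the nearest-neighbor sum over the L−1 adjacent
base-pair stacks of the target subsequence, using the Sugimoto et al.
(1995) RNA/DNA hybrid parameters. The parameters are tabulated by the RNA
strand read 5'→3'; the antisense DNA strand never indexes the table. They
ship as a plain-text resource (`asotiler/data/rna_dna_nn.tsv`) so they can
be audited or swapped (e.g. for a newer hybrid parameter set) without code
changes; the loader validates 16 keys and negative ΔH/ΔS throughout.

The Tm formula is

    Tm(°C) = (ΔH − ΔH_init)/(ΔS + R·ln(1/[oligo]) + 16.6·log10([Na+])) − 273.15

implemented exactly in this form — salt term inside the denominator,
ln(1/[oligo]) orientation as written — with ΔH converted from kcal/mol to
cal/mol before the division (the classic 1000× hazard), ΔH_init = −3.1
kcal/mol added via the subtraction, R = 1.987 cal/(K·mol) fixed.

Parameters, units, defaults:

| parameter | unit | default | note |
|---|---|---|---|
| `oligo_conc` | mol/L | 5×10⁻² | "50 mM" literal reading; `OLIGO_CONC_50NM` preset = 5×10⁻⁸ |
| `na_conc` | mol/L | 0.2 | monovalent salt of the hybridization buffer |
| `helix_init_kcal` | kcal/mol | −3.1 | RNA–DNA helix initiation energy |

The two readings of the oligo concentration differ in the absolute Tm they
produce, but every ratio-based property — in particular the ≤2 °C shift
under an 8-fold concentration change, checked in the acceptance suite under
both readings — is invariant to the choice. The value in force is part of
`ThermoConfig` and is logged by every CLI run. Note the formula as written
makes Tm *decrease* slightly with increasing oligo concentration; the
conservative reading is that the default concentration under-estimates the
Tm realized at working concentrations by less than 2 °C. The formula is
implemented as specified, not "corrected".

No secondary-structure, dangling-end or mismatch thermodynamics are
modeled. A wildcard (degenerate) oligo's Tm is reported as the **minimum**
over its unambiguous expansions — a conservative guarantee that every
member of the ordered mixture is bound at the reaction temperature.

### Greedy maximum-gap tiling

Constraints (defaults): length 39–40 nt, Tm 70–80 °C, untiled gaps ≤ 30 nt,
wildcard expansion ≤ 2. Placement is left to right; the 5' end acts as a
virtual previous oligo ending at coordinate 0, so the head gap obeys the
same bound as internal gaps. At each step the designer enumerates every
candidate starting within `g_eff` of the previous oligo's end and picks the
one with the **largest start** whose Tm is in range; ties prefer Tm closest
to the range midpoint, then the longer oligo. If no candidate is in range,
the candidate with Tm closest to the range (distance 0 inside, else
distance to the nearer bound; ties prefer larger start, then longer) is
retained and the result flagged.

`g_eff` is the terminal adjustment: the largest gap ≤ `max_gap` from which
the remaining sequence can still be finished with no untiled run exceeding
`max_gap`. Feasibility of a remainder is computed by a small dynamic
program over remainder lengths (a remainder r is dead iff
`max_gap < r < len_min` or every placement leads only to dead remainders).
Far from the 3' end this always yields `max_gap`; the adjustment only bites
within roughly two oligo periods of the end. Candidates whose placement
would strand the remainder in a dead zone are likewise filtered during the
greedy step, which is what makes the ≤ `max_gap` guarantee unconditional
on clean sequence. N runs (and over-degenerate consensus regions) that
block all candidates produce a flagged oversized gap, never an error:
placement resumes at the next placeable start.

### Refinement

A second phase re-centers each oligo inside the span bounded by its
neighbors, maximizing its smaller flanking gap (tie-breaks: balance, Tm
closest to midpoint, longer, smaller start). Passes run left to right until
a fixpoint, capped at 5 passes. Three guards keep the published guarantees:

* an oligo whose Tm is in range only moves to in-range positions, and an
  out-of-range oligo never moves further from the range;
* no move may grow a flanking gap beyond `max_gap` (beyond its current
  size, for gaps already flagged oversized), so the gap bound survives;
* a move of oligo i also narrows a gap shared with a neighbor, so moves are
  accepted only while they keep both shared gaps at or above the
  neighbors' **pre-refinement** minimum flanking gaps. This inductively
  guarantees the global property that no oligo's minimum flanking gap ends
  below its pre-refinement value, even though neighbors move.

The design was genuinely open on whether greedy placement may shorten
oligos below `len_min` near the end; this implementation does not, and
flags instead. "Maximum distance" is measured end-of-previous to
start-of-next (gap length), not center to center.

### Shared pools

*Unaligned mode*: the first target is tiled normally; for each further
target every exact full-length complementary match of a first-set oligo is
placed (all loci, resolved left to right without overlap), then residual
untiled regions longer than `max_gap` are tiled fresh. An oligo reused in
**all** targets is `common`; the alternative (any subset ≥ 2) is noted but
not implemented.

*Aligned mode*: a consensus is built per column — identical columns keep
the base; mismatch columns get the IUPAC code of exactly the observed base
set; any column with a gap (or N) in any row is masked. Four-fold
degenerate columns are written N and block candidates like unknown bases.
The consensus is tiled (wildcard candidates admitted while their expansion
product ≤ `max_expansion`, Tm = min over expansions), every retained
consensus oligo maps back to contiguous ungapped coordinates in each row
(masked columns are never spanned, so footprints cannot straddle indels),
and residual regions of each row are tiled individually as `unique`.
Candidates never span masked columns at reduced length.

Pool arithmetic — pool size = common + wildcard + that pool's uniques — is
verified on every constructed design and re-derivable via
`classify_oligos`. Alignments are validated, never computed (use MAFFT or
MUSCLE upstream).

### Fragment prediction, cost, stoichiometry

Digestion fragments: with complete digestion every duplexed base is
removed, so surviving fragments are exactly the untiled gaps. With partial
digestion each oligo is modeled as inducing a single cut at the center of
its footprint (`start + len//2`); an internal fragment is therefore
`ceil(up/2) + gap + floor(down/2)` and terminal fragments carry one flank.
This is kept exactly consistent with a cut-site simulation (tested), and
under defaults bounds internal fragments at 30 nt (complete) and 70 nt
(partial). Cost summaries count distinct oligos (shared oligos once),
compare against the end-to-end 50-mer baseline `ceil(L/50)` per target,
and round currency to whole units for display only. `target_molarity`
converts an RNA mass to molarity with a mean residue mass of 320.5 g/mol
(configurable).

## Synthetic fixtures — what they do and do not show

`make_synthetic_target(length, gc, seed)` draws i.i.d. bases at a requested
GC content; `make_divergent_pair(length, identity, seed)` plants exactly
`round((1−identity)·L)` substitutions at uniform positions (no indels), so
the pair is returned pre-aligned with identity column maps. Both are pure
functions of their arguments.

Uniformly scattered substitutions are the *hardest* case for sharing: at
86 % identity the chance that a 39-nt window is substitution-free is
0.86³⁹ ≈ 0.3 %, so exact reuse across unaligned variants essentially never
fires, and aligned/wildcard sharing finds only the windows with ≤ 1
difference. Real rRNA variant pairs concentrate their divergence in
expansion segments and are conserved in blocks, so realized sharing on real
data is far higher than on these fixtures. Passing tests therefore
demonstrate the structural guarantees (gap bounds, complementarity,
classification, pool arithmetic, compactness ≥ baseline) — not the
magnitude of sharing achievable on real rRNA. Likewise the i.i.d. fixtures
have no repeats, composition skew or N runs beyond what tests inject
explicitly.

Problem sizes used in the test and acceptance suites — 200 tiling fixtures
of 150–650 nt, refinement checks on 300–320 nt targets, shared designs on
4000 nt pairs (the size of a large-subunit rRNA), 1000 oligos for the
thermodynamic bound — were chosen as the smallest scales at which every
property is exercised at realistic magnitudes.

## Numerical and convention choices

* Coordinates: 0-based half-open internally; 1-based inclusive in the TSV
  oligo table; BED6 0-based half-open, score = round(Tm), strand `-`.
  Tm prints to 2 decimals; full precision is kept in memory.
* Oligo ids: `<target>_<start1>_<length>` (+`_wc` for wildcards) —
  deterministic and collision-free; shared consensus oligos keep one id
  across pools (prefix `consensus_`).
* Determinism: there is no randomness anywhere in the designer; identical
  inputs give bit-identical outputs. All tie-breaks are total orders.
* Degenerate Tm denominators (|den| < 10⁻⁹) raise instead of returning
  non-physical values.
* Empty windows, short targets (< `len_min`) and all-N targets return
  empty, flagged results rather than errors.

## Known limitations

* Thermodynamics ignore secondary structure, mismatches and dangling ends;
  only the one published hybrid NN set ships in v1.
* Tiling is greedy (as specified), not globally minimal; an ILP/DP optimum
  could use marginally fewer oligos.
* Off-target screening of the resulting pool (e.g. BLAST against a
  transcriptome) is out of scope, as are alignment computation, mixing-
  ratio optimization across developmental stages, and any sequencing-based
  estimate of depletion efficiency.
* `common` status requires reuse in all pools; partial sharing across ≥ 3
  targets is placed but counted with the uniques of each pool it serves.
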