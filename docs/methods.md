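# Methods

`orthoscreen` implements a three-stage comparative screen over a multi-species
ortholog panel — the design used to ask whether a query species (the giant
panda, against a human reference and seven other mammals) carries candidate
regulatory or coding changes in a gene set of interest — together with a
synthetic panel generator that plants every feature the screens are meant to
detect.

## Stage 1 — coding-region screen

Each query-species protein is globally aligned to its reference-species
ortholog and the fraction of identical aligned columns over the reference
length is compared against a threshold.

**Alignment model.** Needleman–Wunsch with affine gaps (Gotoh recurrence),
BLOSUM62 substitution scores. A gap of length *L* costs `open + L·extend`
with `open = 11`, `extend = 1` (the BLAST protein defaults; equivalent to
Biopython `open_gap_score = −12`, `extend_gap_score = −1`). Adjacent gaps in
opposite sequences are allowed and each run opens its own gap — without this
the dynamic program can miss the optimum when two long gaps abut. The
implementation is a per-row numpy recurrence; the horizontal-gap state is
computed with a prefix-max scan (`max_k M[i,k] + k·extend`), so the run time
is O(mn) with vectorized rows. Optimality is tested against exhaustive
enumeration of all gapped alignments for short sequences and against an
independent aligner for longer ones.

**Tie-breaking.** Among equally optimal alignments the backward traceback
prefers gap states over the diagonal, which pushes gaps toward later query
positions; the choice is arbitrary but deterministic, and only column
identity counts enter the downstream statistic.

**Consensus accounting.** `consensus_count` is the number of alignment
columns with identical residues (case-insensitive; `X` never matches);
`consensus_total` is the ungapped reference length, so the reported fraction
has the same denominator structure as the published per-gene fractions
(e.g. 206/271). Whether the original screen counted conservative
substitutions is not documented; strict identity is used here.

**Percentages** are reported round-half-up to two decimals (206/271 →
76.01), computed with decimal arithmetic, not binary floats.

**Filter.** A gene passes when *both* the structure-coverage percentage and
the consensus percentage strictly exceed the threshold (default 75).
Structure coverage (resolved residues over protein length) is metadata from
a structure database and is always supplied as an input table — the package
never derives it from structures. Exactly 75.00 fails.

## Stage 2 — initiation-context (Kozak) screen

The vertebrate initiation consensus is `gccRccAUGG`. For every gene the
30-nt window covering positions −25…−1, +1…+5 is extracted from the
strand-oriented genomic sequence (+1 = A of the start codon; there is no
position 0). Classification uses only the two dominant positions:

| −3 ∈ {A,G} | +4 = G | strength |
|------------|--------|----------|
| yes        | yes    | S (strong) |
| yes        | no     | A (adequate) |
| no         | yes    | A (adequate) |
| no         | no     | W (weak) |

Windows whose +1..+3 is not `AUG` are EXCLUDED (treated as possible
annotation/assembly error, with a reason code distinguishing a missing
start codon from a window truncated at a contig edge). −6 G and −2/−1 CC
contribute to context strength in the literature but are reported as
annotations only, never used as criteria. Soft-masked (lowercase) bases are
uppercased before testing; an N at a criterion position counts as a
non-match rather than excluding the gene, so the call is deterministic on
masked assemblies.

The cross-species comparison excludes query-species no-AUG genes first,
partitions the remainder by whether the (−3, +4) flag pattern differs from
the reference, and annotates differing genes as weaker/same/stronger under
W < A < S.

## Stage 3a — 3′UTR delimitation

Unannotated 3′UTRs are delimited from the 4 kb window immediately
downstream of the CDS (reading orientation; for minus-strand genes the
plus-strand segment upstream of the gene is taken and reverse-complemented).
The window is scanned for polyadenylation hexamers — by default `AAUAAA`
(weight 1.0) and the common variant `AUUAAA` (weight 0.8), extensible via
config — and the top signal is chosen by weight, then leftmost. The UTR is
the window prefix ending `cleavage_offset` nt after the hexamer
(default 19 nt, inside the canonical 10–30 nt signal-to-cleavage spacing;
a signal at offset 580 therefore yields a 604-nt UTR). This weighted scan
is a deliberately transparent caller; it does not reproduce any specific
polyA-prediction program, and UTR endpoints on real genomes should be
treated as putative. No signal in the window is a reason-coded no-call,
not an error.

## Stage 3b — conserved miRNAs and target sites

**Conservation filter.** A family is retained when it is present in at
least 6 species and every mature copy is within 1 substitution of the
family consensus (per-position majority; ties resolve to the
reference-species base). Copies of unequal length drop the family — mature
sequences are compared without alignment. The published criterion ("one
mismatch in 22 nucleotides in all species") could also mean
pairwise-to-reference; that reading is available via `mode="reference"`.

**Site definition.** A candidate site requires ≥ `seed_min` (default 7)
contiguous Watson–Crick pairs between the UTR and the miRNA 5′ nucleus,
defined as positions 1–9. G:U wobble is not accepted inside the nucleus
(standard seed semantics) but contributes stacking outside it. Every
register is scanned; the maximal run per register is reported once.

**Duplex energy.** The full-length heteroduplex in the register fixed by
the nucleus match is scored with a transparent nearest-neighbor sum:

    ΔG = init + Σ_steps [ stack(step)      if both positions pair
                          mismatch_penalty otherwise ]
             + terminal_penalty per non-GC outermost pair

with Watson–Crick stack free energies in the Turner style (10 canonical
values expanded to 16 keys by duplex symmetry), a uniform −1.30 kcal/mol
for any step containing a G:U pair (simplification), `init = +4.09`,
`terminal = +0.45`, `mismatch = +0.50` kcal/mol per step. The table ships
as versioned package data (`data/nn_stacks.tsv`). Bulges and gaps are not
modeled — the duplex is gapless in its register — which keeps the model
exactly oracle-verifiable; it also means absolute ΔG values are
model-dependent and the −20 kcal/mol acceptance cutoff (default) is defined
with respect to *this* model. A site passes when ΔG ≤ cutoff, and a gene is
"predicted regulated" when it has at least one passing site.

## Pipeline

Stage 3 runs only on the union of stage-1 and stage-2 hits (a gene hit by
both is counted once), mirroring the screening protocol; `--all-genes`
overrides this for exploration. Every exclusion (missing ortholog, no AUG,
no polyadenylation signal, out-of-bounds site window) is logged with a
reason code, so the narrative accounting of a screen (how 166 genes become
88, then 12) is reproducible on any panel. The pipeline is a pure function
of (inputs, config); reruns are byte-identical.

## Synthetic panels

The generator emulates the screen's inputs with planted, recorded truth:

* **Proteins** — a random reference protein (default 300 aa, inside the
  167–527 aa range of the six proteins the original screen retained) and
  orthologs mutated by substitutions only to a target identity; the
  realized identity is exact to ±2 points by construction. An option plants
  a single in-frame 4-residue deletion in the query ortholog to exercise
  gapped alignment.
* **Loci** — `[50 nt upstream][CDS][4 kb downstream]` on a random strand,
  with the −3/+4 bases set per planted Kozak class (unplanned loci share a
  fixed strong pattern so only planted genes can differ between species)
  and one `AAUAAA` planted at a chosen offset.
* **miRNA families** — 22-nt sequences drawn as a shuffled
  fixed-composition multiset (50% GC, typical of mature miRNAs); species
  copies carry a controlled number of substitutions. The fixed composition
  guarantees that any planted energy band wider than one stacking increment
  is reachable.
* **Target sites** — a window pairing miRNA positions 1..k (k = planted
  nucleus length) plus a 3′ complementarity extension searched until the
  duplex ΔG lands in the requested band; the insertion position and ΔG are
  recorded as truth.

Downstream regions are scrubbed of all polyadenylation hexamers *and* of
the reverse-complement 7-mers of every family's nucleus region before
planting, so the planted signal/sites are the only callable features and
truth-table recovery is exact. This clean-background design is what the
round-trip tests verify: they demonstrate correctness of the calling logic
at the stated thresholds, not the false-positive rate expected on real
sequence, where chance seed matches and near-threshold energies are common.
Base composition of loci is uniform; real genomes are not, and PAS/seed
background rates depend on composition.

All randomness flows from a single mandatory `rng_seed`; fixed seed ⇒
byte-identical FASTA/TSV output.

## Numerical and degenerate-input choices

* Percent rounding: decimal round-half-up, 2 digits, everywhere a
  percentage is reported.
* PAS ties: weight first, then leftmost. Alignment ties: deterministic
  traceback (above). Consensus ties: reference base.
* Initiation windows with < 25 nt upstream (or < 5 nt from +1) are
  valid=false outcomes, classified EXCLUDED with a distinct reason.
* Empty downstream windows (CDS at contig edge) warn and no-call.
* Coordinates are validated once, in `seqio` (1-based inclusive,
  strand-oriented; BED output 0-based half-open); all downstream modules
  consume validated records.
* Float equality in the aligner traceback is exact because all scores are
  integer-valued sums stored in float64.

## Problem sizes used in the validation suite

Alignment optimality is enumerated exhaustively for 500 random pairs of
length ≤ 8 (the enumeration oracle is exponential), duplex energies are
checked against an independent summation for 500 random duplexes of length
≤ 10, polyadenylation recovery on 200 planted 2-kb windows, and the
full-pipeline round trip on a 40-gene, 9-species panel with 6 planted
coding passes, 10 planted weaker initiation contexts and 5 planted passing
target sites. These sizes exercise every code path while keeping the suite
fast; the screens themselves are linear in panel size and have been run on
larger panels without issue.

## Known limitations

* The duplex model has no bulges, internal loops or intramolecular UTR
  structure; ΔG values are not comparable to folding programs.
* Structure coverage is trusted input; no structure parsing or simulation.
* The consensus statistic is pairwise (query vs reference), not a multiple
  alignment; on highly diverged panels a multiple alignment could count
  columns differently.
* UTR delimitation uses the polyadenylation signal only — no EST/RNA-seq
  evidence, no conservation track.
* The conservation filter requires equal-length mature sequences within a
  family.
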