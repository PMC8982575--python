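# Methods

## Scope and model

The package models the computational side of an annealed-oligo shRNAmir
cloning system: deterministic sequence transforms (oligo design, codon
recoding), a discrete sticky-end cloning simulator, a loop-anchored colony
classifier, a channel-exclusivity panel matcher, and a log-normal
flow-cytometry simulator with quantile gating. Everything biological that
these stand in for — annealing thermodynamics, ligation kinetics, Sanger
chromatograms, spectral spillover — is deliberately replaced by the simplest
deterministic or seeded-stochastic surrogate that preserves the quantities
of interest.

## Oligo layout

Coordinates are 0-based half-open throughout. The 97-mer regions are
flank5 [0,18), sense [18,40), loop [40,59), guide [59,81), flank3 [81,97).
The top oligo is `GATCC + G + sense + loop + guide + T + GGGCC` (75 nt) and
the bottom oligo is `revcomp(top[4:71])` (67 nt), leaving 4-nt unpaired
tails `top[0:4] = GATC` and `top[71:75] = GGCC`. These constants were not
asserted a priori: they were derived by parsing all 30 bundled ground-truth
oligo pairs and confirming a single consensus (prefix `GATCCG`, suffix
`TGGGCC`, loop `TAGTGAAGCCACAGATGTA`, and the revcomp relation hold for
every row); the test suite re-derives the consensus from the fixture.
Because the oligos do not encode the flanks, `parse_oligos` fills them with
the canonical constants — reconstruction is canonical-flank reconstruction,
not recovery of a user's original flanks.

Validation has two modes. Lenient gates only on length 97 and the ACGT
alphabet (the behaviour of the original spreadsheet converter). Strict
(default) additionally requires the canonical loop at [40,59) and warns on
an internal GGATCC/GGGCCC in [18,81), which would be cleaved during
cloning. U is auto-converted to T with a warning since predictor output is
sometimes pasted as RNA; lowercase is normalized.

## Cloning simulator

Type IIP enzymes are described by (recognition, cut_top, cut_bottom);
only palindromic sites are supported, so a forward-strand scan covers both
strands. A linear fragment is stored as its full top strand plus typed
sticky ends; top-strand protrusions are part of the stored strand and
bottom-strand protrusions live only in the end descriptor, so joining two
compatible ends is plain concatenation of top strands and digest→ligate
round trips are exact. Ends join iff polarities match and one overhang is
the reverse complement of the other.

Ligation enumerates circular products over ordered subsets with each
fragment used at most once, deduplicated up to rotation and strand flip
(circular identity = lexicographically minimal rotation of either strand).
Fragments keep their given orientation: reverse-orientation joins — e.g.
head-to-head insert dimers through the self-complementary GATC/GGCC
overhangs, which do occur chemically — are outside the model, which targets
the intended single-insert product. `Fragment.flipped()` exposes the
reverse orientation for callers who need it. Concatemers, partial digests,
star activity, and methylation sensitivity are not modeled.

The mock vector is a seeded circular plasmid (default 2400-nt backbone +
GGATCC + 800-nt stuffer + GGGCCC), rejection-sampled so that exactly one
site per cloning enzyme exists; the released stuffer fragment is
stuffer_len + 10 nt (5 nt contributed by each flanking half-site). It is a
synthetic stand-in: the real vector sequences are distributed through a
plasmid repository and are not bundled.

## Colony verification

Reads are exact (optionally substitution-mutated, uniform rate, seeded)
substrings of the construct, wrapping for circular templates. The
classifier anchors on the 19-nt loop — invariant across constructs, so the
cheapest reliable landmark; alignment-free beats full alignment at this
scale — then Hamming-scores the two flanking 22-mers against the expected
sense and guide. Positive requires the anchor, full window coverage, and at
most `mismatch_budget` (default 0, the strictest reading) mismatches per
stem. Reads not covering the window are negative with a coverage note,
never an error. Classification is orientation-invariant except for the
reported orientation. Indels and quality trimming are not modeled.

## Codon recoding

Forbidden motifs are scanned on both strands (motif + reverse complement on
the forward strand). For the leftmost hit, overlapping codons are tried
left to right and synonymous codons in lexicographic order; the first
substitution that removes the hit without creating a new forbidden hit
within ±6 codons is accepted, then the whole sequence is re-scanned to a
fixpoint, which also catches junction-created hits. This greedy rule is a
design choice: the application fixes the goal (zero hits, identical
protein), not the algorithm, and determinism plus verifiability matter more
than substitution-count optimality. Sites overlapping only single-codon
amino acids (Met/Trp) raise an unresolvable-site error. Codon-usage
optimization is out of scope.

## Panel planning

Distinguishability is channel exclusivity: two labels conflict iff forced
into the same (laser, band-pass filter) channel. Feasibility is a maximum
bipartite matching (networkx, Hopcroft–Karp) between labels and the
instrument's channels restricted to each label's usable channels; the panel
is feasible iff the matching is perfect, and an infeasible panel returns a
minimal Hall-violator subset found by exhaustive subset search (label counts
are ≤ 8, so this is cheap). Two instrument presets ship — a standard
four-laser 405/488/561/633 nm configuration and a five-laser variant adding
the 355 nm UV line — because the source instrument is described both ways;
neither is canonical. Spectral overlap, spillover and compensation are
deliberately not modeled: the guidance being reproduced is channel-based.

## Flow simulation and demultiplexing

Each reporter transduces each cell independently with probability p
(default 0.3, matching a 1:1 cotransduction where each single-positive
population is a few percent and the quadruple-positive exceeds 1% at
n = 4). Reporter intensities are log-normal: log10 intensity is N(2.0,
0.15) for the negative state and N(4.0, 0.25) for the positive state —
roughly two decades of separation, as seen between autofluorescence and a
bright reporter on a 5-decade flow axis. A stained target linked to a
reporter has underlying level `control_mfi × (1 − knockdown)` when the
reporter is present, with multiplicative log-normal noise (log10 sd 0.1).
Channels are independent; no spillover, doublets, or vendor FCS format.

Gating thresholds each reporter at the 99.9th percentile of an untransduced
control sample — the reproducible surrogate for manual gates — and assigns
each event to one of the 2^n barcode populations (labels `none`,
`Azurite+`, `Azurite+GFP+`, … ordered by number of positives). MFI is the
geometric mean by default (the natural location statistic for log-normal
intensities; with the multiplicative noise model it recovers the underlying
level without bias), with arithmetic mean available since acquisition
software varies. Knockdown percent is `100 × (1 − MFI_pop / MFI_control)`
against a caller-named control population (typically `none`); populations
under 100 events are flagged, not dropped.

What the generator does not emulate: spectral spillover between channels,
autofluorescence heterogeneity between cell types, transduction-copy-number
effects on reporter intensity, and staining-panel interference. Passing
recovery tests therefore shows estimator correctness under the stated
noise model, not robustness to real-instrument artifacts.

## Problem sizes and numerical choices

The test suite runs the full regeneration and cloning cycle over all 30
bundled pairs, the matching-vs-brute-force oracle over every label subset of
size ≤ 6, 1,000 randomized 30-codon recoding cases, and knockdown recovery
at 200,000 cells × 10 seeds (mean absolute error ≤ 0.02 across knockdowns
0.5/0.7/0.9); the whole suite completes in well under a minute. All
randomness flows through numpy `default_rng` with explicit seeds;
hypothesis properties are derandomized. Ties in ligation product
enumeration are broken by canonical rotation; circular motif hits are
reduced into [0, len).

## Known limitations

- Only palindromic (type IIP) recognition sites; no type IIS enzymes.
- Ligation is orientation-fixed and single-use-per-fragment (no dimers or
  concatemers); colony counts and ligation efficiency are not modeled.
- Sanger error model is substitution-only; no chromatogram parsing.
- The greedy recoder minimizes nothing globally; it is deterministic, not
  optimal in substitution count.
- The mock vector is synthetic; construct-level results demonstrate the
  simulator's bookkeeping, not properties of any real plasmid.
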