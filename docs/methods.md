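# Methods

This note documents the models, estimators and design choices behind
`numtclock`, in the spirit of a methods supplement: what is computed, under
which assumptions, and what the simulation-based tests do and do not
establish.

## The two-phase substitution model

Sequences evolve along a dated genealogy in continuous time with two
phases per branch segment:

* **functional** (mitochondrial): rate `mito_rate` substitutions/site/Myr
  (default 0.01 — the ~1%/Myr observed great-ape mtDNA clock), with
  purifying selection on protein-coding positions;
* **pseudogene** (nuclear): rate `mito_rate × nuclear_rate_ratio`
  (default ratio 0.05), neutral.

Proposals carry a K80-style transition/transversion bias `kappa`
(default 4, a moderate mtDNA-like value) and, in the functional phase, a
factor `omega` (default 0.1) on proposals that are non-synonymous against
the *current* codon background. The process is **rate-normalized**: the
total substitution rate is held at exactly `rate` per site, so selection
reshapes the synonymous/non-synonymous composition of fixed changes
without thinning their number — the same convention as normalized codon
models. This matters for interpretation: the rate parameter is the
*observed* clock rate, the quantity an mtDNA calibration actually
measures, not a pre-selection mutation rate. Consequences used by the
tests: realized per-branch counts are Poisson(rate × duration × L)
regardless of `omega`; the expected stem divergence is exactly
`mito_rate × (ghost_split_time − insertion_time)`; with `omega = 1` and no
coding map the process is exactly JC/K80.

Multiple hits are allowed and recorded per event, so realized counts can
exceed observable differences. Coordinates are 0-based half-open; `frame`
is the offset of codon position 1 within a coding interval; partial codons
at interval edges are treated as non-coding; forward strand only. Genetic
code: NCBI transl_table 2 (vertebrate mitochondrial) by default,
selectable per interval; a change is synonymous iff the encoded amino
acid (stop included) is unchanged. Root sequences are uniform random with
coding codons redrawn to avoid stops.

## Scenarios

The default species tree is the dated hominine tree
`(((Human:6,(Chimp:2,Bonobo:2):4):3,Gorilla:9):7,Orangutan:16)` (Myr).
Bonobo provides the congeneric reference pair; Orangutan is the rooting
outgroup (outgroups are required to localize the stem: without one, the
NUMT attachment edge merges with the backbone in the unrooted tree).
Events sit on the lineage ancestral to the first-listed leaf:

* `numt_transfer` — a ghost mtDNA lineage splits at `ghost_split_time`
  (default 14), evolves functionally until `insertion_time` (9.5; this
  4.5 Myr span is the stem), then as a pseudogene until `transfer_time`
  (9.2), when hybridization places the NUMT into the recipient lineage;
  thereafter NUMT orthologs descend the species tree at the nuclear rate.
* `mtdna_introgression` — the symmetric history (defaults: insertion 8,
  transfer 7): the NUMT is created in the acceptor clade from its own
  "old" mtDNA; at `transfer_time` the ghost's mtDNA replaces the
  acceptor's, so extant acceptor mtDNA descends from the ghost while the
  NUMT still shares the old backbone with the non-introgressed branch.
  A species split between transfer and insertion is rejected as
  inconsistent.
* `null_no_ghost` — the NUMT arises directly from the host's mtDNA; the
  true stem divergence is zero.

Identical `ScenarioSpec`s (including `seed`) give byte-identical outputs.

## Estimation

Distances: p, JC or K80 (default) with pairwise deletion; ambiguity codes
are missing data. Saturation (p ≥ 0.75 under JC, non-positive K80 log
arguments) raises rather than returning a value. Topology: neighbor
joining; negative intermediate branch lengths are clamped to zero with the
deficit shifted to the sister branch, so NJ stays exact on additive
matrices. Rooting places the root at the midpoint of the outgroup's
pendant branch.

The delete-d jackknife (default d = 0.5, 1000 replicates) resamples
columns without replacement; each replicate re-fits all branch lengths on
the fixed topology by non-negative least squares over the path-length
equations (NNLS keeps the branch-length ≥ 0 invariant without post-hoc
clamping; on additive input it reproduces the generating lengths exactly).
Saturated replicates are excluded and counted; more than 20% excluded is a
hard error. Reported "% divergence" is fitted substitutions/site × 100
under the stated model.

Mutation mapping uses Fitch parsimony with deterministic tie-breaking
(prefer the parent's state, then alphabetical; gap is a fifth state that
never overrides a nucleotide on the final pass). Multi-hit codons on one
branch are classified change-by-change against the progressively updated
codon. The stem contrast is a one-sided Fisher exact test (the claim is
directional: stems of true NUMTs are *more* synonymous); fully non-coding
(e.g. rRNA-homologous) mutation sets are refused rather than given a
vacuous p-value, and zero-margin tables return p = 1 flagged degenerate.

The mitochondrial-fraction correction multiplies the raw stem by the
fraction of its length accrued in the functional phase. By default this is
a mixture estimate — the stem's synonymous fraction placed between the
mtDNA-branch and NUMT-branch synonymous fractions, clipped to [0, 1] — or
a fixed value (0.75 is the classic reference setting) via configuration.

Calibration is least squares through the origin (zero separation implies
zero divergence), slope in % divergence per Myr; time = corrected stem /
slope with sd propagated linearly. The configured outgroup is never a
calibration reference (its divergence is not identifiable in the joint
tree). The Ne counterargument regresses maximum intra-taxon mtDNA
divergence on nuclear Ne (OLS, t-based 95% prediction interval at the
ancestral Ne); `does_not_explain` iff the observed stem exceeds the upper
bound. The Ne_nuc/Ne_mit ratio is assumed stable and carried as an
interpretive assumption only.

The shared-stem statistic measures, below the ingroup ancestor, the path
shared by the NUMT clade and a candidate mtDNA branch (the gorilla branch
in the hominine configuration). Measuring from the ingroup ancestor rather
than the root is deliberate: otherwise the outgroup's pendant branch would
add equally to both scenarios and erase the contrast. Scenario thresholds:
shared stem > 3 jackknife sd ⇒ `introgression_consistent`; ≤ 1 sd ⇒
`numt_transfer_consistent`; otherwise `ambiguous`. These thresholds
operationalize a qualitative signature and are reported as such in the
analysis report.

## What the simulator does and does not emulate

It emulates: a protein-coding, selectively constrained mtDNA-like locus;
the contrast between mitochondrial-phase and pseudogene-phase evolution;
ghost-lineage divergence, insertion, and horizontal placement; realistic
divergence scales for the hominine tree. It does not emulate: indels and
alignment error (inputs are flush alignments), explicit gamma rate
variation beyond what selection induces, recombination, base-composition
drift, within-population coalescence, or rRNA/tRNA structural constraint.
Passing tests therefore show correctness of the estimators under a clean,
selection-structured substitution process — not robustness to alignment
artifacts or demographic noise in real genomic data.

## Known limitations

* **Site-rate heterogeneity bias.** Purifying selection makes
  non-synonymous sites slow, and JC/K80 assume homogeneous rates. The
  resulting under-correction grows with path length, and the least-squares
  fit redistributes the lack of fit: deep reference divergences are
  compressed (the fitted calibration slope comes out below the generating
  1%/Myr) while the stem edge absorbs a small *positive* remainder — a
  long-branch-attraction-like effect. At the default selection strength
  the stem estimate stays within the reported uncertainty band of the
  truth (the 20-seed recovery test), but the two biases point in opposite
  directions, so the final *time* estimate overshoots by roughly a third
  under these conditions; in the neutral regime (omega = 1) both vanish.
  The same effect puts a positive floor (~1 percentage point at default
  settings) under the stem of a truly stemless (null) NUMT; the
  statistically-zero-stem behavior holds in the neutral regime. Gamma-rate
  corrections or full ML would reduce this; both are outside this
  package's distance-based scope.
* **Root-adjacent branches are not separable.** Mutations on the two
  branches meeting at the root of the rooted tree can be exchanged without
  changing the parsimony score; per-branch counts there are arbitrary up
  to the tie-break.
* **Fitch parsimony** is a point estimate; it undercounts multiple hits
  and may merge parallel changes on sister branches (the per-branch
  recovery test tolerates ±2 changes). Marginal ML reconstruction would be
  the natural upgrade.
* A NUMT whose stem is ~0 often fails NUMT-clade monophyly in the NJ tree;
  the pipeline reports this as an error rather than inventing a stem.

## Problem sizes in the test suite

The simulation-based tests use the full 9 kb locus where the claim depends
on it (stem recovery, scenario discrimination: 20 seeds × 100–200
jackknife replicates) and smaller loci (1.5–4 kb) with proportionally
adjusted expectations where the property is scale-free (parsimony
recovery, null calibration of the contrast at 3 kb × 200 runs, JC
consistency). Jackknife replicate counts in tests (100–200) are below the
1000-replicate default; the tested quantities are means and sds, which are
stable at that depth.
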