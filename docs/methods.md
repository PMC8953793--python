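# Methods

## Problem and model

Given an aligned set of COI-5' barcodes with species labels, the pipeline
asks whether a single genetic-distance threshold can separate intraspecific
from interspecific variation, and if so which threshold delimits the most
species. Distances are Kimura two-parameter (K2P): with P the proportion of
sites differing by a transition (A<->G, C<->T) and Q by a transversion,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

K2P assumes equal base frequencies and a constant transition/transversion
rate ratio across sites; it is the de facto standard for barcode work,
which is why no other distance model is exposed. The estimate is undefined
when 1 - 2P - Q <= 0 or 1 - 2Q <= 0 (saturation). Saturated pairs are
recorded, warned about, and excluded from all summaries rather than
aborting a run: at 658 bp genuine barcode data essentially never saturate,
so an undefined pair signals either extreme divergence (a mislabel) or a
synthetic stress test, and neither should take down the analysis.

A species has a **barcode gap** when its maximum intraspecific distance is
strictly below its minimum distance to any heterospecific record. Strict
inequality is used on both the gap test and the delimitation test
(max intra < t < min inter): a threshold that exactly equals either bound
cannot separate the two classes, so boundary ties conservatively count as
failures.

## QC filter chain

Stages run in a fixed order: (1) drop records not identified to species
level; (2) drop records shorter than the configured barcode length
(default 658) and truncate longer records; (3) drop records with any
non-ACGT letter — the degenerate-base rule covers every IUPAC ambiguity
code, not just the common eight; (4) collapse exact duplicate sequences
within a species, keeping the first in input order; (5) drop records with a
stop codon in all three forward frames under the invertebrate mitochondrial
code (NCBI table 5, via Biopython) — frame 2 is tested first because the
standard COI-5' amplicon starts at the third position of a codon, and a
trailing partial codon is ignored; (6) drop species left with fewer than
two records, since their intraspecific distance is inaccessible.

Design choices that were genuinely open:

- *Order.* Length/alphabet checks must precede translation; duplicate
  collapse must precede singleton removal because collapsing creates new
  singletons. The remaining freedom (where stage 1 sits) is immaterial to
  the output and fixed for determinism.
- *Morphospecies.* The species-level filter applies only to
  `source="public"` records: databases mix identification quality, whereas
  in-house, morphologically vouchered material labelled "Genus sp." is
  still a coherent analysis unit. `keep_morphospecies=True` disables the
  stage entirely.
- *Truncation anchor.* Over-length records are trimmed at the 3' end,
  preserving the 5' anchor of the barcode region. The alternative (removing
  them) discards usable data.
- Every removed record appears in the QC report with its stage and reason;
  the filter is idempotent, and output + report partition the input. These
  are tested invariants.

## Threshold selection

Candidate thresholds are strict local minima of a Gaussian-kernel density
estimate of the pooled pairwise-distance vector (intra and inter together —
that is the vector the classical local-minima routine consumes). The KDE
conventions are pinned to those of R's `density()` defaults, on which that
routine rests: bandwidth nrd0 = 0.9 * min(sd, IQR/1.34) * n^(-1/5), Gaussian
kernel, 512-point grid, grid extended 3 bandwidths past the data range. The
KDE is computed directly (no binned FFT approximation); a test cross-checks
the resulting minima against R's `density()` within one grid step, which is
the expected discrepancy from R's pre-binning. Grid size and bandwidth are
overridable and echoed in every report.

Coverage of a candidate t = number of species with max intra-GD < t < min
inter-GD (species whose conspecific pairs are all saturated are excluded).
The optimum maximizes coverage; ties break to the smallest candidate, the
conservative (less splitting) choice. The fixed 2.20% BIN clustering value
is always evaluated alongside as the standard comparison point. Per-genus
thresholds repeat the procedure on each genus with >= 2 species, with
distances and minimum-interspecific comparisons restricted to congeners;
a genus whose restricted density is monotone (no local minimum) is reported
with no threshold rather than an arbitrary one.

## Alignment statistics

A column is conserved if it shows one state, parsimony-informative if at
least two states each occur in at least two records, and a singleton site
if variable but not informative. Codon position 1 is anchored to the frame
chosen by the translation check on the first record (all records share the
amplicon frame); for the standard barcode in frame 2 the columns split
219/219/220 across positions 1/2/3. Base frequencies are pooled over all
records and columns of each position class and rounded half-up to one
decimal; the printed AT% and CG% are sums of the *rounded* components,
matching the convention of published composition tables.

## Synthetic data generator

`simulate_dataset` evolves sequences down a fixed balanced hierarchy
(root -> genus ancestor -> species ancestor -> individual) under the K2P
process. Substitution is applied per site from the exact K2P transition
probabilities at elapsed time equal to the branch length (closed form, not
Gillespie stepping), so it is fast, exact, and the K2P distance estimator
is consistent for the planted branch lengths — the basis of the
parameter-recovery tests. Branch lengths are expected substitutions per
site: conspecific individuals sit `intra_branch/2` below their species
ancestor (pairwise expectation `intra_branch`), congeneric species
ancestors `inter_branch/2` below the genus ancestor, genus ancestors
`genus_branch` below the root.

Defaults emulate a realistic multi-genus weevil barcode survey: 10 genera x
3 species x 6 sequences of 658 bp (survey means in this group run about 3
species per genus and 6 sequences per species), kappa = 2,
`intra_branch = 0.03` (mean intra-GD ~3%), `inter_branch = 0.20`
(congeneric distances ~20-23%), `genus_branch = 0.05` (cross-genus
distances ~30%, inside the empirically observed interspecific range rather
than near saturation). The root is uniform over A/C/G/T unless a base
frequency vector is supplied to emulate AT bias. Defect injection (short
records, one degenerate base, exact duplicate copies) happens after the
clean sequences and the realized gap interval are fixed, with a truth table
recording every defect.

What the simulator deliberately does **not** model: indels, across-site
rate heterogeneity, codon structure or amino-acid constraint (stop codons
can arise by chance, so simulated data are analyzed with the translation
stage off), non-uniform stationary frequencies under the substitution
process itself, and coalescent tree shape. Passing tests therefore
demonstrate correctness of the distance/threshold machinery on data whose
generative model matches K2P exactly; they do not demonstrate robustness to
alignment error, rate variation, or the deep intraspecific structure
(cryptic lineages) that real surveys show.

## Numerical and degenerate-input conventions

- Distances are proportions internally; every user-facing surface (CLI
  flags, reports) uses percent.
- `candidate_thresholds` requires >= 2 distinct distances and raises
  "density degenerate" otherwise; a genus failing this is skipped with a
  warning rather than failing the run.
- The KDE is evaluated in grid chunks to bound memory on large pair
  vectors (n(n-1)/2 pairs for n records).
- Duplicate collapse, tie-breaks and record ordering are all deterministic,
  and the simulator is byte-reproducible from its seed; the pipeline's
  report bundle is identical across repeat runs apart from the manifest
  timestamp.

## Problem sizes

The bundled analysis and the reproduction script use the default 180-record
survey (~16k distance pairs) and a 100-seed recovery experiment on
36-record simulations; both complete in seconds while exercising every
stage at sizes comparable to a real single-subfamily barcode study.

## Known limitations

- The optimum threshold is only as meaningful as the species labels: label
  errors inflate intraspecific distances and erode coverage.
- Pooled-vector KDE minima can miss a threshold when intra and inter modes
  overlap heavily (no universal gap); the per-candidate coverage table in
  the report makes that visible instead of hiding it.
- Minimum interspecific distances at dataset scope compare against *all*
  heterospecifics; genus scope (congeners only) is available and is what
  the per-genus thresholds use. Which scope a published survey used is not
  always stated; the default is dataset scope.
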