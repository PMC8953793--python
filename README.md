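# barcodegap

Barcode-gap analysis and distance-threshold species delimitation for COI
DNA barcodes.

DNA barcoding identifies animal species from the standard 658 bp COI-5'
fragment by comparing genetic distances. For a species *s*, the **barcode
gap** is the separation between its maximum intraspecific distance
(max intra-GD) and its minimum distance to any other species (min
inter-GD); the gap exists when max intra-GD < min inter-GD (strictly). In
taxonomically difficult groups — this package grew out of work on
broad-nosed weevils (Entiminae), where fixed 2–3% thresholds fail — the
practical question is *which* distance threshold delimits the most species.

`barcodegap` implements that whole analysis as a reusable, tested pipeline
for anyone curating barcode reference sets or delimiting species with
single-locus data:

- **QC filtering** of aligned barcodes: records unidentified to species
  level, sequences shorter than 658 bp (longer ones are trimmed at the 3'
  end), degenerate bases, exact duplicates within a species, stop codons in
  every forward frame under the invertebrate mitochondrial code, and
  species left with a single sequence.
- **Kimura two-parameter distances.** For transition proportion *P* and
  transversion proportion *Q*,
  `d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)`;
  saturated pairs (undefined logs) are excluded with a warning.
- **Barcode-gap summaries** per species (max intra-GD, min inter-GD, gap
  flag), at dataset scope or restricted to congeners.
- **Threshold selection.** Candidate thresholds are the strict local minima
  of a Gaussian KDE of the pooled pairwise-distance vector (nrd0 bandwidth,
  512-point grid, range extended 3 bandwidths — the conventions of R's
  `density()`, which the classical local-minima routine builds on). A
  candidate *t* "delimits" a species when max intra-GD < *t* < min
  inter-GD; the optimum maximizes the number of delimited species, with the
  fixed 2.20% BIN clustering threshold always evaluated for comparison.
  Per-genus optima are computed the same way on congeneric distances.
- **Alignment statistics**: conserved / variable / parsimony-informative /
  singleton sites and base composition by codon position.
- **A K2P simulator** that plants a known species structure (root -> genus
  -> species -> individual, exact K2P transition probabilities per site)
  and optional QC defects, so every stage is verifiable without downloads.

## Worked example

Simulate a survey, run the full pipeline, and read the threshold report
(the `analysis/` scripts do exactly this over `results/`):

```
$ python analysis/01_simulate_barcodes.py
wrote 181 records (10 genera x 3 species x 6 seqs + injected defects) to results/sim/
realized barcode gap of the clean data: (5.36%, 18.58%)

$ python analysis/02_qc_and_distances.py
kept 175 records / 30 species (removed 6 by QC)
intra-GD 1.38-5.36% (mean 3.11%, 425 pairs)
inter-GD 18.58-42.30% (mean 32.96%, 14800 pairs)
intra/inter overlap: none (gap)
species with a barcode gap: 30/30

$ python analysis/03_gap_thresholds.py
candidate thresholds (%): [11.94, 24.86]
species delimited per candidate: [30, 1]
optimum: 11.94% delimits 30/30 species
fixed threshold 2.20%: delimits 0/30
```

Reading the numbers: QC removed the 6 injected defects; every species'
maximum intraspecific distance (up to 5.36%) stays below its nearest
neighbor distance (at least 18.58%), so all 30 species have a barcode gap.
The distance density has a trough at 11.94% inside that gap, and that
threshold delimits all 30 species, whereas the BIN default 2.20% sits
*below* many species' intraspecific variation (mean intra-GD ~3%) and
delimits none — the same failure mode fixed thresholds show in weevils.

The same operations are available as a CLI (`barcodegap qc | dist |
threshold | genus-thresholds | stats | simulate | run`), e.g.

```
barcodegap run --in seqs.fasta --meta meta.tsv --outdir out/ --fixed 2.2
```

which writes `clean.fasta`, `qc.tsv`, `dm.tsv`, `species.tsv`,
`report.json`, `genus.tsv`, `histogram.tsv` and a run manifest.

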