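# bacmap

A toolkit for building and integrating BAC physical maps of a heterozygous
diploid genome, exercised end-to-end on synthetic data with known ground
truth.  It covers the whole workflow of a dual fingerprint-based physical
mapping project:

- **`bacmap.simulate`** — synthetic diploid genome with polymorphic
  restriction-fragment loci, partial-digest and sheared BAC libraries on
  384-well plates, capillary-style band fingerprints with sizing noise and
  contaminations, sequence tags with repeat dropout, and phase-labelled
  dominant markers (all with recorded ground truth).
- **`bacmap.bands`** — extended bands file I/O (decimal bp scaled ×10 to
  16-bit integer mobilities), size-window clipping, band-count filtering,
  and contamination detection (reference profiles, neighbour wells).
- **`bacmap.assembly`** — Sulston-score overlap testing (greedy one-to-one
  band matching, binomial tail probability), single-linkage contig building
  with greedy seriation and consensus-band (CB) maps, questionable-clone
  flagging, DQ re-splitting at stricter cutoffs, end-to-end merging, and
  standard map statistics (avg/N50/total length, genome equivalents,
  inflation, size-class histogram).  Tolerance mode for gel fingerprints and
  exact-match mode for sequence-tag pseudo-mobilities.
- **`bacmap.pooling`** — balanced random k-sets superpool designs
  (defaults v=90, k=4, n=764), quarter-plate pool addressing, deconvolution
  of positive superpools into candidate/resolved QPPs, and Monte-Carlo
  simulation of the design's collapse at high marker copy numbers.
- **`bacmap.anchoring`** — piecewise-linear marker size conversion with a
  450 bp knot, automated marker scoring in pooled fingerprints, pooled-screen
  in-silico anchoring (candidate QPPs × fingerprint band match, ≥2 clones),
  and anchor validation with per-chromosome summaries.
- **`bacmap.wgp`** — pseudo-mobility ID assignment for sequence tags
  (range 1000–54705, six tags per ID, overflow reported), tag-to-fingerprint
  conversion, chimera detection, tag copy-number spectra, and a truncated
  two-Poisson heterozygosity mixture with maximum-likelihood fitting.
- **`bacmap.integrate`** — shared-clone contig groups across two maps with
  group-enhanced contig counts, haplotype-mixing tables
  (expected % = 100·(1−0.5^(n−1))), a hybrid per-clone map table, and a
  `run_pipeline` driver that chains everything on a synthetic config.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(closed-form arithmetic checks plus two seeded stochastic reproductions:
the pooled-screen copy-number mode and the pooling-design collapse curve).

## CLI

```sh
bacmap simulate --config config.yaml --out data/       # synthetic dataset
bacmap qc data/fingerprints.bands --out qc.bands       # window + band-count filter
bacmap assemble qc.bands --mode aflp --out map.tsv     # contig build (aflp|wgp)
bacmap pool design --n-qpp 764 --out design.tsv        # random k-sets design
bacmap pool deconv design.tsv 1 2 3 4                  # positives -> QPPs
bacmap pool simulate design.tsv --reps 1000            # collapse curve
bacmap wgp fps data/wgp_tags.tsv --out pseudo.bands    # tags -> pseudo-bands
bacmap wgp spectrum data/wgp_tags.tsv                  # copy-number histogram
bacmap wgp fit data/wgp_tags.tsv                       # mixture ML fit
bacmap anchor --bands ... --layout ... --markers ... --design ... --out anchors.tsv
bacmap integrate mapA.tsv mapW.tsv --out hybrid.tsv    # contig groups
bacmap run --config config.yaml --report report.json   # full pipeline
bacmap report report.json                              # summarize a report
```

A config file is YAML with the fields of `bacmap.simulate.SimulationConfig`,
e.g.:

```yaml
genome_length_bp: 2000000
n_chromosomes: 2
het_fraction: 0.54
n_markers: 25
rng_seed: 1
clone_libraries:
  - {name: LA, digestion_mode: partial_digest,
     clone_size_mean_kb: 130.0, clone_size_sd_kb: 15.0, n_clones: 160}
```

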