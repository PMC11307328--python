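# crispr-memory

Analysis pipeline for longitudinal CRISPR spacer–target dynamics in
metagenomic time series, exercised end to end on a synthetic community
generator with planted ground truth.

The pipeline covers:

- **Lineage clustering** — spacer/repeat dereplication, greedy 90/90 repeat
  clustering, strict-nesting lineage construction (an array is nested in
  another when they share a repeat cluster and its spacers are a
  strand-insensitive subset), and pairwise order/inversion/orientation
  consistency metrics.
- **Protospacer matching** — ungapped both-strand search of spacers against
  MGE references and per-subject local contigs at 95 % identity/coverage,
  with contig-edge partial coverage, CRISPR-region masking (100 bp repeat
  margin), and promiscuous-spacer filtering. An exact pigeonhole-seeded
  batch scanner reproduces the exhaustive scan hit-for-hit.
- **Target classification** — strict class consensus over database hits
  (conflicts → ambiguous), identical/highly-similar accuracy tiers,
  lifestyle-aware phage classes, 15 kb neighborhood rescue with a
  0.9×best-score retention rule, and local-adaptation flags.
- **Positional analysis** — sliding-window densities (12 % window, 1.5 %
  step) of spacer categories along oriented arrays, leading/middle/distal
  region enrichment with exact Clopper-Pearson intervals, and eligibility
  filtering (>5 spacers, ≥25 arrays per subtype).
- **Immunity dynamics** — acquisition-episode selection (spacer appears
  after its lineage, present in ≥2 samples), four-phase abundance and
  prevalence statistics (before / acquisition / after-with-spacer /
  after-no-spacer) with 2000-bootstrap median CIs, Mann–Whitney and Fisher
  tests, and the active/inactive lineage-diversity and sweep analysis.
- **Trajectory clustering** — six-letter state-string encoding of each
  episode (trimmed/collapsed empty states), affine-gap global alignment
  (1 / −2 / −2 / −1), a length-normalized similarity network, two-level
  map-equation community detection (best of 200 trials), and cluster
  summaries with direct/indirect transition splits.
- **Synthetic community generator** — truncated power-law array sizes
  (with a matching discrete MLE fitter), leader-end spacer gain,
  strand-randomized protospacer planting, configurable immunity effects on
  target abundance, detection dropout, and terminal assembly truncation.

## Run the tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalences, parameter-recovery checks, determinism); the other files are
per-module unit and property tests.

## CLI

```sh
# generate a synthetic dataset (arrays, spacers, contigs, MGE db,
# abundances, plus a truth/ directory with planted events)
crispr-memory simulate --out run/data --seed 1 [--sim-config sim.yaml]

# individual stages (upstream stages recompute in memory)
crispr-memory lineages     --in run/data/dataset --out run/lineages --seed 1
crispr-memory targets      --in run/data/dataset --out run/targets  --seed 1
crispr-memory positions    --in run/data/dataset --out run/pos      --seed 1
crispr-memory dynamics     --in run/data/dataset --out run/dyn      --seed 1
crispr-memory trajectories --in run/data/dataset --out run/traj     --seed 1

# everything end to end on the default synthetic configuration
crispr-memory all --out run/all --seed 1
```

All outputs are TSV (tab-separated, `.` for missing) plus a
`manifest.json` recording parameters, seed, and output checksums; reruns
with the same seed are byte-identical. Analysis thresholds live in a YAML
parameter file (`--config`); simulation knobs in a separate YAML
(`--sim-config`).

## Layout

```
src/crispr_memory/
  config.py         parameter registry + config loading
  datasets.py       containers, TSV/FASTA readers and writers, manifests
  seq.py            small sequence helpers
  simulate.py       synthetic community generator + truncated power law
  matching.py       protospacer search, masking, promiscuity filter
  lineages.py       dereplication, repeat clustering, nesting lineages
  targets.py        target classes, neighborhood rescue, local adaptation
  positions.py      positional profiles, region enrichment, Clopper-Pearson
  dynamics.py       episodes, phase statistics, diversity/sweep analysis
  trajectories.py   state strings, alignment, network, communities
  pipeline.py       stage orchestration
  cli.py            crispr-memory command line
```
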