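# hervkit

Locus-level detection, classification, and association analysis of expressed
human endogenous retroviruses (HERVs), exercisable end to end on synthetic
data with known truth.

The toolkit re-implements the decision logic of an assembly-based HERV
detection pipeline and its downstream association machinery:

- **`hervkit.core_io`** — domain types (intervals, HERV elements, gene
  models, sample metadata), strand-aware interval algebra, and readers/
  writers for GTF, BED (including the `ERV_<id>_<family>` HERV dialect),
  VCF, narrowPeak, bedMethyl-style TSV, and TSV matrices. Internal
  coordinates are 0-based half-open everywhere; conversion happens only at
  format boundaries.
- **`hervkit.detection`** — read selection against HERV/gene annotations,
  transcript filtering (support count > 5, identity ≥ 0.96), single-linkage
  consensus merging (≥ 50% of samples, ≥ 200 bp), unique-placement
  assignment, per-site expression calling (count > 5 and TPM ≥ 0.1 in
  ≥ 50% of samples), and cross-site de-duplication with unified
  `HERV_xxxxxxxx` ids. Every dropped record is logged with a
  machine-readable reason.
- **`hervkit.classification`** — location class (inserted / antisense /
  intergenic), origin class (solo-LTR / truncated / chimeric /
  full-length), and the four mutually exclusive full-length subtypes
  (unit-length, upstream-TSS, 3′-readthrough, host-chimeric).
- **`hervkit.expression`** — TPM, body-site specificity and ubiquity
  summaries, 1 − Spearman sample distances with classical MDS, and a
  pluggable two-group differential-expression contract (rank-sum reference
  engine, BH correction).
- **`hervkit.genetics`** — presence-aware genotyping (expression masking
  from contig evidence), variant QC (missingness / MAF / HWE), TMM scaling
  factors, rank-based inverse normal transform, LD r² and sliding-window
  pruning, genotype and expression PCs (with the sample-size factor-count
  schedule), cis-QTL mapping with permutation-based empirical p-values and
  BH-based eHERV calling, matched-background construction (MAF ×
  chromosome × TSS-distance bins), Fisher enrichment, and GWAS hit
  expansion through LD.
- **`hervkit.epigenetics`** — histone-peak flags within ±5 kb of
  strand-aware TSSs, peak–expression rank-sum tests, coverage-weighted
  methylation levels, and expressed-vs-silent / per-locus correlation
  tests.
- **`hervkit.factors`** — per-site sex/ethnicity differential expression
  (with sex-specific-site exclusion), per-site age correlations, and a
  global linear mixed model (fixed body-site effect, random individual
  intercept, likelihood-ratio factor tests).
- **`hervkit.simulate`** — seeded generators for every input: annotation
  geometry planting all origin/location/subtype classes, transcript sets
  whose decoys each violate exactly one detection gate, negative-binomial
  counts with planted site/sex/age effects, Hardy–Weinberg genotypes with
  planted additive cis effects, presence/contig evidence, and peaks /
  methylation correlated with expression truth.
- **`hervkit.cli`** — a `hervkit` command chaining the stages, with JSON
  manifests (parameter + input/output hashes) for provenance and
  byte-identical reruns.

## Test

```sh
python -m pytest -q
```

`tests/test_acceptance.py` holds the acceptance criteria (detection
recovery with stage-attributed decoy elimination, threshold boundary
fidelity, QTL power/calibration with an exhaustive permutation oracle,
normalization oracles, enrichment oracle equivalence, epigenetic/factor
effect recovery, and end-to-end determinism).

## CLI

```sh
hervkit --seed 1 all --out runs/demo        # simulate + full pipeline
hervkit --seed 1 simulate --out runs/demo   # or stage by stage
hervkit --seed 1 detect   --out runs/demo
hervkit --seed 1 classify --out runs/demo
...
```

Stages: `simulate`, `detect`, `classify`, `quantify`, `qtl`, `enrich`,
`epi`, `factors`, `all`. Thresholds can be set in a YAML config
(`--config cfg.yaml`); command-line flags win. Exit codes: 0 success,
2 config error, 3 data error. Every stage writes
`manifest_<stage>.json` with parameter values and SHA-256 hashes of its
inputs and outputs; rerunning with an identical config reproduces
hash-identical outputs.

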