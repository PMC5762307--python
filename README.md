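# pathscreen

Integrative analysis pipeline for paired drug-sensitive/resistant cell
lines, built around five analysis stages plus a ground-truth synthetic data
generator:

1. **diffexpr** — per-gene pooled t-tests on log2 abundances,
   Benjamini–Hochberg q-values, and a fold-change gate.
2. **copynumber** — circular binary segmentation of probe-level log2
   copy-number ratios (permutation-tested splits) and overlap-weighted
   gene-level log2 ratios.
3. **ipl** — integrated pathway level scores on a signed, typed pathway
   graph: a ternary-state pairwise factor model combining expression and
   copy-number evidence with neighbour coupling, solved by damped
   sum-product message passing (an exhaustive-enumeration oracle is
   included for small graphs), plus first-neighbour subnetwork extraction.
4. **nominate** — candidate selection by the IPL outlier cut
   (|IPL − median| > k·SD), a coefficient-of-variation band, and a
   non-zero-expression filter, with labelled control genes.
5. **screen** — RNAi plate normalization (local-linear/loess spatial
   surface per plate, negative-control or plate-median basis) and hit
   calling by exact Wilcoxon rank-sum + BH with kill-fraction and
   direction gates.

`pathscreen.synthetic` generates every pipeline input with known ground
truth (planted differential genes, copy-number events, an active pathway
subnetwork, spatial plate artifacts, differential-kill genes) so all
stages are testable offline; one RNG stream per data modality keeps the
modalities independently reproducible from a single master seed.

## CLI

Every stage is a subcommand; `run-all` chains them (simulate → diffexpr →
segment → ipl → nominate → screen → hits → subnetwork) and writes a
summary plus per-stage manifests (parameters, seed, input checksums):

```bash
pathscreen run-all --seed 7 --outdir out/
pathscreen simulate --config config.yaml --outdir out/
pathscreen diffexpr --outdir out/          # reads out/expression.tsv
```

A YAML config can override any stage block, e.g.:

```yaml
seed: 7
simulate:
  n_genes: 500
  cn_events: [[chr1, 50, 80, 1.0]]
screen:
  q_threshold: 0.2
  kill_threshold: 0.15
```

All inputs and outputs are plain text: expression TSV + sample
annotations, probe TSV, SEG, BED6, a tab-delimited pathway interaction
file, SIF + node-attribute exports, plate CSV, and a truth JSON.

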