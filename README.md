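# ctxbias

Detect and quantify **context-dependent nucleotide substitution biases** in
ancestor–descendant alignments, at pattern sizes beyond the adjacent base
(2–5 bp and up to 7), using the relative abundance of substitution patterns.

A *substitution pattern* pairs an ancestral word with a same-length descendant
word (`ACT->ATT`); interior `N` positions mark "any base" and capture context
at a distance (`TNG->CNG`). For each pattern the package computes:

- **pr(P)** — the fraction of ancestral words that convert to the pattern's
  descendant word;
- **ρ(P)** — relative abundance: observed proportion over the expectation
  assembled from all smaller constituent subpatterns. Two equivalent routes
  are implemented: the recursive definition and a fast algorithm based on
  full-length gapped subpatterns (their agreement is tested to 1e-9);
- **context bias** — `(ρ − 1) · f(P)`, the pattern's impact on genome
  composition, and **total context bias**, `Σ |ρ − 1| · f` over all patterns
  of one length;
- **inference** — block-bootstrap confidence intervals (central 95% order
  statistics), empirical p-values against no-bias controls with
  Benjamini–Hochberg FDR, and a two-dataset comparison of total context bias
  with a studentized block-permutation p-value;
- **simulators** — i.i.d. ancestors, no-bias descendants from a 4×4
  single-base divergence matrix, context-biased descendants driven by
  multiplicative context rules (known ground truth), and sequencing-error
  injection.

Inputs are pairwise MAF blocks or paired aligned FASTA (records alternating
ancestor, descendant); an optional BED mask restricts to regions. Block
filters follow the standard rules (minimum contiguous non-gap columns; no
more gaps than aligned bases).

## CLI

Every subcommand writes its outputs plus a `<out>.run.json` summary with the
full configuration and seed; `--no-timestamp` makes runs byte-reproducible.

```sh
# simulate a 1 Mb pair with a CpG hypermutability rule
ctxbias simulate --length 1000000 --seed 7 --rules rules.yaml --out sim.fa

# count ancestral words and patterns for window sizes 1..5
ctxbias count --in sim.fa --format paired_fasta --lmax 5 --out counts.tsv

# relative abundance for every observed pattern
ctxbias relabund --counts counts.tsv --out rho.tsv

# per-pattern context bias + per-length totals
ctxbias bias --counts counts.tsv --lengths 2,3,4,5 --out bias.tsv

# block-bootstrap CIs for chosen patterns / totals
ctxbias bootstrap --in sim.fa --pattern "CG->TG" --n-boot 1000 --seed 1 --out ci.json

# no-bias control: re-mutate ancestors with the observed single-base rates
ctxbias control --in sim.fa --seed 2 --out control.fa

# empirical p-values vs controls, BH FDR
ctxbias fdr --real bias.tsv --control ctrl1.tsv --control ctrl2.tsv --out fdr.tsv

# compare total context bias between two datasets
ctxbias compare --a near.fa --b far.fa --lengths 2,3 --seed 3 --out cmp.json
```

A `rules.yaml` context rule (multiply C→T by 10 when the next ancestral base
is G):

```yaml
- anc_base: C
  desc_base: T
  template: CG
  focal: 0
  multiplier: 10
```

## Layout

| module | role |
| --- | --- |
| `ctxbias.align_io` | MAF / paired-FASTA reading, validation, block filters, windowing, BED masks |
| `ctxbias.patterns` | pattern algebra: gap masks, subpattern sets, reverse complements |
| `ctxbias.counting` | dense-array count tables behind sparse canonical-text semantics |
| `ctxbias.relabund` | ρ by the recursive definition and the fast algorithm, memoized |
| `ctxbias.bias` | context bias, total context bias, dataset difference ranking |
| `ctxbias.stats` | block bootstrap, empirical nulls, BH FDR, dataset comparison |
| `ctxbias.simulate` | ancestors, no-bias controls, context rules, error injection |
| `ctxbias.cli` | `ctxbias` command-line entry points |
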