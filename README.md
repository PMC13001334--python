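# binderqc

Design-level QC and pooled-screen analysis for *de novo* CAR binder
libraries.

Large crowd-sourced or model-generated libraries of designed binding
domains (e.g. 80-mer binders against a tumor surface antigen such as CD20)
are increasingly evaluated by pooled CAR-T proliferation screens: each
design's own codon-optimized coding sequence acts as a barcode, and
CD20-specific proliferation is read out as the change in barcode abundance
between a target co-culture and a no-target control. Most designs in such
libraries fail long before binding is ever tested — repetitive, GC-extreme
DNA fails synthesis; lysine/glutamate-rich helical sequences (the
signature of fixed-backbone sequence-design models) disrupt translation
and drop out of the screen; cysteine-rich designs deplete, plausibly
through disulfide-enhanced tonic signaling.

`binderqc` is a library for scientists analyzing such screens. It provides:

- **sequence QC features** — Shannon entropy (bits) at DNA and protein
  level, GC content, overlapping AA-dinucleotide and EE-dipeptide repeat
  counts, homopolymer runs, residue composition, k-mer entropies;
- **structure features** — helix fraction and the **K+E α-helix ratio**
  (fraction of residues that are K or E *and* helical) from predicted
  structures or SS strings, with a P-SEA-style geometric helix assignment
  from CA traces, plus intra-chain disulfide counting (SG–SG ≤ 2.5 Å,
  CB–CB ≤ 4.5 Å fallback);
- **screen analysis** — barcode counting, the ≥25-reads-in-all-replicates
  recovery rule, CPM (optionally TMM) normalization, an exact conditional
  negative-binomial test with moderated method-of-moments dispersion,
  Benjamini–Hochberg FDR over recovered designs, hit calling
  (FDR < 0.05 and |log₂FC| ≥ 1), and greedy non-redundant top-*n*
  selection by −log₁₀(FDR)·log₂FC;
- **filter cascade** — the synthesis/recovery/cysteine failure-mode rules
  with configurable thresholds and cohort-level evaluation;
- **predictive evaluation** — per-feature ROC-AUC under stratified
  5-fold cross-validated logistic regression;
- **a synthetic competition generator** that plants all of the above
  mechanisms with known ground truth, so the entire stack is testable
  without any external download.

## The statistical core

Counts for design *g* in replicate *j* are modeled as negative binomial
with mean μ and variance μ(1 + φμ). After equalizing library sizes, the
within-condition sums Y⁺, Y⁻ are NB with size n/φ; conditioning on
s = Y⁺ + Y⁻ gives an exact two-sided (double-tail) p-value

> p = Σ { P(y | s) : P(y | s) ≤ P(y_obs | s) },

which reduces to the exact binomial-conditional test as φ → 0. The
effect size is log₂FC = log₂((CPM⁺ + c)/(CPM⁻ + c)) with pseudocount
c = 0.5 CPM. Dispersion is a method-of-moments common value, optionally
shrunk toward per-design estimates. FDR is BH over recovered designs only.

## Worked example

```python
import binderqc as b

cfg = b.SimConfig(seed=11)                      # 1,200-design study cohort
designs, truth = b.generate_designs(cfg)
counts = b.simulate_screen(designs, cfg)
results = b.test_enrichment(counts)
print(results["category"].value_counts().to_string())
```

prints

```
category
neutral          609
not_recovered    500
enriched          51
depleted          40
```

i.e. the 500 K/E-helical dropout designs fail the 25-read recovery rule,
51 designs are called CD20-specific hits (planted log₂ effect +1.5 in the
functional class), and 40 are called depleted (the cysteine-rich class,
planted −1.5). Applying the default filter cascade
(`b.evaluate_filter(b.apply_filter(b.compute_feature_table(designs)), results)`)
raises the recovered fraction from 58.3% to 100.0% and the hit rate among
retained designs from 4.2% to 7.3%; feature ranking
(`b.cv_feature_ranking`) puts `ke_helix_ratio` first with a mean
cross-validated AUC of 1.00 on this cohort, ahead of the correlated
DNA-level signatures. The scripts in `examples/` walk through each
capability and print these numbers with interpretation.

A thin CLI mirrors the library:
`binderqc simulate | features | struct-features | screen | filter |
evaluate | run | reproduce` (see `binderqc --help`). Analysis of a local
copy of a released screen dataset is available through
`binderqc reproduce --archive DIR` and never downloads anything.

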