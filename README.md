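# qpcrnet

Statistics and machine-learning graph analysis for array-format qPCR
studies with small group sizes, modeled on a four-arm rat heart-transplant
experiment (cold ischemia 1 h / 5 h, preservation with or without
alpha-1-antitrypsin; n = 7–9 per arm; 88 target genes + 5 reference
genes).  The package bundles four things that usually live in separate
scripts:

1. **ΔΔCt quantification** — reference-gene normalization
   (ΔCt = Ct_gene − mean Ct_ref), linear expression 2^(−ΔCt), per-gene
   two-sided pooled-variance Student's t-tests on the linear replicates,
   fold change FC = 2^(−ΔΔCt), fold regulation FR = FC or −1/FC, QC flags
   for high-Ct genes, and the p < 0.05, |FR| > 2 significance filter.
2. **CrossBoruta network inference** — all-relevant Boruta feature
   selection (shadow features + out-of-bag permutation importance +
   binomial hit testing) run with every gene in turn as the regression
   target; confirmed predictor relations become an undirected gene–gene
   network with Spearman-signed edge colors (positive / negative / grey).
3. **Stress-majorization layout** — SMACOF embedding of the network with
   target distances derived from edge importance, so strongly associated
   genes sit close together.
4. **Gain-ratio decision trees** — C4.5-style axis-aligned threshold
   trees for inter-group classification, plus the published four-gene
   reference tree (Flt1 / Gpx3 / Cflar / Bcl2) as an executable fixture.

Because the study's raw Ct data are unpublished, the package ships a
seeded synthetic generator reproducing the study design (group sizes,
stable reference genes, planted log2 fold changes, arm-specific
correlation modules, detection-ceiling-censored silent genes) and the
published per-contrast summary tables as plain-CSV fixtures.

## Worked example

Simulate a study with the reported-structure preset, quantify it, and
filter the 5h-vs-1h contrast:

```python
import qpcrnet as q

cfg = q.study_preset(master_seed=1)
ct, truth = q.simulate_study(cfg)
expr = q.linearize(q.normalize_delta_ct(ct, cfg.panel))
results = q.compare_groups(expr, ct, "5h ischemia", "1h ischemia")
print(q.significance_filter(results).summary())
```

```
altered: 7 (up: 6 ['Fos', 'Hspa1a', 'Txnrd1', 'Ccl2', 'Icam1', 'Tnf']; down: 1 ['Tlr4'])
```

All six planted genes (five up-regulated, one down) come back out of the
t-test + fold-regulation filter at n = 7 per group.  The seventh gene,
Tnf, is a false positive of this particular draw — with 85 testable
genes, raw p-values and no multiplicity correction (the convention this
read-out mirrors), roughly one nominal hit per contrast is expected.
The three detection-floor genes (Il9, Gpx5, Gpx6) are excluded from the
contrast with a warning because most of their wells are undetermined.  Routing a sample
through the published classification tree:

```python
tree = q.reference_tree()
q.apply_tree(tree, {"Flt1": 23.5, "Gpx3": 20.0, "Cflar": 21.0, "Bcl2": 21.0})
# frozenset({'5h ischemia'})
```

— a graft with Flt1 expression above 23.029 and Cflar at or below 21.651
is assigned to the 5h-ischemia group, exactly as the printed rules read.

The full pipeline (comparison tables, filter summaries, one network per
treatment arm, layouts, network comparison, decision tree) runs from the
shell:

```sh
qpcrnet all --preset reported --seed 1 --out results/run1
```

and writes plain CSV/TSV/JSON artifacts plus a manifest with seeds and
stage timings; the same seed reproduces every file byte for byte.

## Layout

- `src/qpcrnet/quant.py` — Ct containers, ΔΔCt chain, filter, QC flags
- `src/qpcrnet/boruta.py` — shadow-feature selection core
- `src/qpcrnet/network.py` — CrossBoruta assembly, summaries, comparison
- `src/qpcrnet/layout.py` — target distances + SMACOF, plotting
- `src/qpcrnet/tree.py` — gain-ratio induction, reference tree, applier
- `src/qpcrnet/simulate.py` — synthetic study generator and presets
- `src/qpcrnet/pipeline.py`, `cli.py` — orchestration and `qpcrnet` CLI
- `src/qpcrnet/reported.py`, `data/` — published-table fixtures
- `docs/methods.md` — models, conventions, numerical choices
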