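# bihemi

Bilateral transcriptomic analysis of unilateral brain injury: does the
uninjured hemisphere respond, and how differently from the injured one?

After a unilateral cortical impact, gene expression changes not only in the
ipsilateral (injured) hemisphere but also contralaterally — which matters
because the contralateral side is often used as the control in injury
studies. `bihemi` implements the analysis pipeline for a three-group
design (ipsilateral, contralateral, naive; replicate microarrays per
group):

1. **Presence/fold-change filtering.** A gene qualifies when it is detected
   ("P") in all replicates of at least one injured side and its group-mean
   signal changes 2-fold or more versus naive. Fold changes are signed:
   `fc = m_case/m_ctrl` if `m_case ≥ m_ctrl`, else `−m_ctrl/m_case`, so
   −4.00 means a 4-fold decrease. The two contrasts are TBI-I
   (ipsilateral vs naive) and TBI-C (contralateral vs naive).
2. **Hemispheric fold-ratio.** For genes changed on both sides, with
   `linear(f) = f` for `f ≥ 1` and `1/|f|` for `f ≤ −1`,

   ```
   ratio = linear(fc_I) / linear(fc_C)
   ```

   which resolves to `fc_I/fc_C` (both up), `fc_C/fc_I` (both down) and
   `fc_I·|fc_C|` (up ipsi / down contra). A common gene with
   `ratio > 1.75` "changed differently" between hemispheres; the rest
   changed similarly. Genes changed on one side only are "unique" to it.
3. **Functional overlap.** Each top biological-function gene set is scored
   by its overlap with the inflammatory-response (IR) set,
   `100·|F ∩ IR|/|F|`, with a pooled cumulative overlap
   `100·Σ|F_i ∩ IR| / Σ|F_i|` across functions and an optional one-sided
   hypergeometric enrichment p-value `P[X ≥ k]`.
4. **Gene interaction hierarchy (GIH).** Genes of interest (GOI) are ranked
   by their number of direct (first-order) connections to other GOI in an
   undirected interaction network: primary (>10 connections), secondary
   (5–10), peripheral (1–4), orphan (0).

A fully deterministic synthetic-data module generates expression datasets
and networks with planted ground truth in the study's shape (3×3 design,
372 responsive genes in the published breakdown, 114-node network with
tiers 20/34/41/19), so every stage is testable end to end without any
download. The published summary tables (the 14-function overlap table, the
37 divergent common genes, and the 114-gene hierarchy) ship as curated
reference data.

## Worked example

```python
from bihemi import fold_ratio, classify_common
from bihemi.simulate import SimulationConfig, generate_expression
from bihemi.diffexpr import fold_change_records
from bihemi.bilateral import partition, summarize

# the published STAT3 fold changes: up 4.22-fold locally, down 3.77-fold remotely
r = fold_ratio(4.22, -3.77)
print(round(r, 2), classify_common(r))      # 15.91 different

# a synthetic study in the published shape, analyzed end to end
ds, truth = generate_expression(SimulationConfig(noise_sd=0.0, seed=7))
s = summarize(partition(fold_change_records(ds)))
print(s.common, s.ipsi_unique, s.contra_unique)   # 146 188 38
print(s.percent["similar"], s.percent["different"])  # 75 25
```

The first block says STAT3's local response was ~16-fold stronger than its
remote one — far past the 1.75 divergence threshold. The second shows the
pipeline recovering the planted breakdown exactly on noise-free data: 146
genes changed on both sides (75% similarly, 25% differently), 188 only
ipsilaterally, 38 only contralaterally.

The numbered scripts under `analysis/` run the same pipeline as a narrative
sequence (simulate → PCA QC → differential expression → bilateral
classification → functional overlap → hierarchy), writing tables under
`results/`. There is also a CLI (`bihemi --help`) mirroring each stage.

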