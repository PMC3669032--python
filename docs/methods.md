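# Methods

## The design and its quantities

The pipeline analyzes a three-group expression experiment on brain tissue
after a unilateral cortical impact: ipsilateral tissue (at the lesion),
contralateral tissue (mirror site, uninjured hemisphere) and naive control
tissue, with replicate arrays per group (three each in the emulated
design). Inputs are MAS5-style summarized signals — positive, right-skewed
per-probe-set values — with per-sample Present/Marginal/Absent detection
calls. Probe-level processing (summarization, detection p-values,
cross-chip scaling) is assumed done upstream; each input row is treated as
one gene, with no probe-to-gene collapsing beyond "first annotation wins".

Two contrasts are formed per gene: TBI-I (ipsilateral vs naive) and TBI-C
(contralateral vs naive). All fold changes use the signed convention: the
expression ratio is folded to magnitude ≥ 1 and the sign gives direction,
so a halving of expression is −2.0, never 0.5. Ties (equal means) map to
+1.0, a deterministic tie-break.

## Qualification of changed genes

A gene's change on either side counts only if

* **presence**: the gene is called "P" in *every* replicate of at least one
  injured side (all ipsilateral or all contralateral samples). Marginal
  ("M") counts as not present — the strict reading of "present". The rule
  is a property of the gene, not of the side: one fully-present side
  qualifies the gene for both contrasts.
* **magnitude**: |fold change| ≥ 2.0, boundary included ("2-fold or
  more").

Group means are arithmetic means of replicate signals (a geometric-mean
option exists for strongly skewed replicates); whether the original
analysis averaged before or after forming ratios is not stated, so this
package averages signals first and documents the choice here.

## Hemispheric fold-ratio and the bilateral partition

For genes changed on both sides, the divergence statistic is the ratio of
linear-scale responses: with `linear(f) = f` for `f ≥ 1` and `1/|f|` for
`f ≤ −1`,

```
ratio = linear(fc_I) / linear(fc_C).
```

This single formula reproduces all three published sign cases (both up:
`fc_I/fc_C`; both down: `fc_C/fc_I`; up-ipsi/down-contra: `fc_I·|fc_C|`)
and is what the property tests check against an independent piecewise
oracle. The fourth sign case — down ipsilaterally, up contralaterally —
has no published formula; the default ("faithful") mode applies the same
linear-scale ratio, which is then always < 1 and classifies as "similar".
Because that reading arguably mislabels a genuinely divergent pattern, a
"symmetric" mode (`max(r, 1/r)`) is available to flag such genes as
different; it is opt-in because the faithful extension is the literal
formula and the published data contained no fourth-case gene.

Classification is strict: ratio > 1.75 ⇒ "different", ratio ≤ 1.75 ⇒
"similar". Display values are rounded two decimals half-up; classification
always uses unrounded values. Recomputing the 37 published divergent-gene
ratios from their printed fold-change pairs lands within ±0.03 of the
printed ratios (the published values were computed from unrounded fold
changes; re-deriving them from two-decimal inputs leaves up to ~0.025
drift, e.g. LCN2 18.415 vs printed 18.44).

Every changed gene falls in exactly one category: common-similar-up/-down
(sub-labeled by the ipsilateral sign), common-different, or
side-unique-up/-down. Summary percentages use the published denominators —
similar/different and the similar splits over the common total, unique
splits over each side's unique total — with integer half-up rounding (the
only convention consistent with all printed values, e.g. 93.5% → 94%).
Zero denominators yield an explicit "undefined" marker rather than an
error.

## Functional overlap

Per function `F`, overlap with the inflammatory-response set IR is
`100·|F ∩ IR|/|F|`, integer half-up; the denominator is the function's own
size only. The cumulative overlap pools counts — `100·Σ overlap / Σ size`
across functions, one decimal — rather than averaging percentages; pooling
is the only definition that reproduces the published 39.3% from the
published per-function counts (2675/6804). Enrichment uses the one-sided
hypergeometric tail `P[X ≥ k]` (Fisher's exact test for
over-representation); the universe size defaults to the number of genes
passing the presence filter and is configurable, since the curated-database
universe behind the published analysis is not stated.

## Gene interaction hierarchy

Given a GOI list and any undirected interaction network (SIF or two-column
edge list; self-loops dropped, duplicate/reversed edges collapsed), the
induced GOI subnetwork keeps only edges with both endpoints in the GOI
set; GOI absent from the network become isolated nodes. A gene's
connection count is its number of distinct neighbors there, and tiers are
primary (> 10), secondary (5–10), peripheral (1–4), orphan (0). "Orphan"
means degree zero in the induced subnetwork, not "outside the largest
component" — the counting procedure is neighbor selection, so degree is
the defining quantity. Table ordering is tier, then cellular compartment
from outermost in (extracellular space, plasma membrane, cytoplasm,
nucleus, unknown), then molecule type, then symbol. Nodes representing
gene groups or complexes in a user-supplied network are treated as
ordinary nodes; expanding them would require the proprietary knowledge
base the network came from.

The 114-gene published hierarchy (tiers 20/34/41/19, 95 connected + 19
orphan) ships as a curated reference table for demonstration runs and as
the default shape of the synthetic network generator. Its connection
counts cannot be re-derived without the proprietary interaction database,
so correctness of the hierarchy logic is established on planted synthetic
networks instead.

## PCA quality control

Samples are projected onto the leading principal components of the
gene-centered signal matrix: signals are log2-transformed
(`log2(x + 1)`, disable-able), each gene mean-centered across samples, and
the SVD of the resulting samples × genes matrix gives scores `U·diag(s)`
and variance fractions `s_k²/Σs²`. Component signs are fixed by making
each component's largest-magnitude gene loading positive, so output is
deterministic and sample-order invariant. On synthetic three-group data
with group effects well above noise, samples cluster by injury status
(every within-group score distance below every between-group distance).
This is QC only — no gene selection depends on it — and the originally
reported variance-explained figure is not a reproduction target here: it
depends on unstated preprocessing of the original arrays.

## Synthetic data

The expression generator plants, by default, 1,000 genes with the
published inflammatory-response breakdown: 79 common-similar-up, 30
common-similar-down, 37 common-different, 179/9 ipsi-unique up/down, 10/28
contra-unique up/down (372 responsive genes), the rest null. Baselines are
log-normal (ln-scale location ln 1000, sigma 0.5 — a plausible MAS5 signal
scale); replicate noise is multiplicative log-normal with sd 0.1 in
ln-units, variance independent of the mean (mean–variance trends add
nothing the analysis exercises). Similar-class genes draw effects of 2.5-
to 8-fold with a within-pair ratio ≤ 1.4 (safely below the 1.75
threshold); different-class genes draw one of three divergence patterns
(both up, both down with the larger remote decrease, up-local/down-remote),
each with planted ratio ≥ 2.5; unique-class genes change 2.5- to 8-fold on
one side only. Detection calls come from an absolute signal floor (10)
rather than simulated detection statistics — the floor reproduces the
presence-filter behavior the pipeline must exercise — plus forced-Absent
injection for 30% of null genes. Down-effects are capped at 8-fold so
planted means stay orders of magnitude above the floor, making zero-noise
class recovery exact by construction.

What the generator does *not* emulate: probe-level artifacts, chip batch
effects, mean-dependent variance, correlated genes, and marginal ("M")
calls. Passing tests therefore demonstrate correctness of the filtering,
ratio and partition logic under the study's design, not robustness to
real-array pathologies.

The network generator draws per-tier degrees (primary 11–18, secondary
5–10, peripheral 1–4, orphan 0; default tier sizes 20/34/41/19), checks
the sequence is graphical, realizes it exactly with a Havel–Hakimi
construction, and randomizes topology with seeded degree-preserving
double-edge swaps — so at zero rewiring every node's realized degree
equals its planted degree and tier recovery is exact. Optional rewiring
noise perturbs degrees deliberately; recovery degrades gracefully
(~75–90% of tiers at rewiring probabilities 0.1–0.4 in the bundled
analysis) and this is reported, not hidden. Both generators are
byte-deterministic given their seed.

## Numerical conventions

* All display rounding is decimal half-up (`93.5 → 94`), never banker's.
* Percentages with zero denominators report "undefined".
* Signed fold changes of exactly equal means are +1.0.
* Fold-ratio inputs must have magnitude ≥ 1; anything else is a domain
  error, not a silent clamp.
* Problem sizes in the bundled analyses (1,000 genes, 114-node networks)
  match the emulated study's scale, so runs complete in seconds.
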