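# Methods

## Problem and approach

`potencyclm` implements a pipeline for designing highly potent compounds
from weakly potent input molecules with a conditional chemical language
model. The idea is borrowed from activity cliffs: pairs of structural
analogues whose potencies differ by at least two orders of magnitude show
that small, well-defined chemical transformations can carry large potency
gains. A sequence-to-sequence model trained on analogue pairs annotated with
their potency difference learns transformation → potency-change
associations, and can then be asked for candidates with a prescribed gain.

The pipeline stages are:

1. **Curation** — raw activity records (one Ki measurement each) are kept
   only for direct binding assays (relationship type "D") at the highest
   assay confidence score (9). Multiple measurements for one compound in
   one activity class are consolidated by the geometric mean on the Ki
   scale, equivalently the arithmetic mean of the per-measurement pKi
   values, provided max(Ki)/min(Ki) ≤ 10; otherwise the compound is
   disregarded for that class. The boundary ratio of exactly 10 is accepted
   ("same order of magnitude" needs an operational cutoff; we fix it
   inclusively). One canonical SMILES writer (RDKit, isomeric) is used for
   every identity comparison in the package; stereochemistry is retained
   and no salt stripping or neutralization is applied — input records are
   expected to carry the parent structures.
2. **Analogue series** via compound-core relationships (CCR): every
   molecule is fragmented by simultaneously cutting 1–5 eligible bonds
   (acyclic single bonds between heavy atoms with at least one end atom
   outside any ring — a documented stand-in for a full retrosynthetic rule
   set, pluggable through `analogues.eligible_bonds`). A decomposition is
   kept when it yields exactly one connected core bearing all attachment
   points plus one single-attachment substituent per cut, and when the core
   has at least twice the heavy atoms of the combined substituents.
   Attachment sites are renumbered by the canonical rank of the core
   attachment atom so a shared core always serializes identically. A series
   is any core shared by ≥ 2 compounds of a class; a compound may belong to
   several series.
3. **Pairing** — all within-series compound pairs ("All_CCR" pairs),
   deduplicated per class by unordered compound pair (a pair reachable
   through several cores keeps the largest core, ties broken
   lexicographically). Each pair yields two directed triples
   (source, target, Δ = pKi(target) − pKi(source)). Pairs are removed as
   ambiguous when one (source, Δ) key maps to different targets in
   different classes, or the same pair carries different potency values in
   different classes; Δ keys are compared at bin resolution (0.01), the
   granularity the model ultimately sees. Pairs with |Δ| ≥ 2 (at least
   100-fold) are activity-cliff (AC-CCR) pairs, the threshold inclusive;
   the rest are CCR pairs. Curation of ambiguous pairs operates on
   undirected pairs, before orientation.
4. **Splitting** — per class, AC-CCR pairs are grouped by core and whole
   core groups are assigned to the fine-tuning side (random order, refined
   by descending group size for a tight fraction) until ≥ 80% of AC-CCR
   pairs are covered. The ratio is measured in pairs, not cores. CCR pairs
   sharing a fine-tuning core are dropped; the rest join the test side, so
   the two sides never share a core.
5. **Tokenization** — SMILES are split per character except two-character
   halogens ("Cl", "Br") and bracket atoms ("[nH]", "[O-]", …), which are
   single tokens. Potency differences are binned over [−6.62, 6.52] pKi
   units at constant width 0.01 — 1314 bins, a resolution at the limit of
   experimental potency measurement — each bin one token. Bins are
   half-open [lo + k·w, lo + (k+1)·w) with the top edge closing the last
   bin; bin-edge values are snapped at 1e−6 before flooring so that exact
   edges land in the upper bin despite floating-point representation. The
   model input frames start + source SMILES tokens + potency token + end
   (the potency token appended after the SMILES; the order is a fixed
   convention). A padding token is added for batching. The bin range is
   configurable; out-of-range differences raise during training and clamp
   to the nearest edge bin (with a warning) at inference, so users may
   request extreme gains.

## The model

A compact encoder–decoder transformer implemented directly in NumPy with
explicit backward passes and an Adam optimizer; training and sampling are
exactly reproducible under a seed and run on any CPU. Architecture: shared
token embedding (scaled by √d) with sinusoidal positional encoding; pre-norm
residual blocks — encoder layers of multi-head self-attention + position-wise
feed-forward (ReLU), decoder layers of causal self-attention,
cross-attention over the encoder output, and feed-forward; a final LayerNorm
and a linear head. Padding is excluded from attention and loss. The loss is
token-level cross-entropy under teacher forcing. The analytic gradients are
verified against central finite differences in the test suite.

Reference configuration: encoding dimension 256, batch size 64, learning
rate 1e−4, 200 epochs, 3+3 layers, 8 heads, feed-forward width 4×, dropout
0.1, maximum sequence length 160 (longer training sequences are dropped
with a logged count). The layer/head counts, positional encoding, optimizer
and dropout are this package's pinned choices. A seeded 5% of the training
triples is held out for validation; a checkpoint is taken each epoch and
the minimum-validation-loss checkpoint is selected. `ModelConfig.tiny()`
(2+2 layers, dimension 64, 4 heads, learning rate 1e−3 — the usual choice
for transformers this small, dropout 0) is the CPU-sized configuration used
throughout the tests and the reproduction script; at this scale an epoch on
~500 short triples takes a few seconds on one CPU.

Pre-training uses all directed triples pooled across classes; fine-tuning
continues from the pre-trained checkpoint on one class's AC-CCR triples,
oriented weak → potent (Δ ≥ 2). Sampling decodes autoregressively with
multinomial sampling at temperature 1.0 (greedy decoding available);
emissions are restricted to SMILES tokens and the end marker. Generated
strings may still be invalid SMILES — validity is assessed downstream.

## Evaluation: the compound-pair-based test system

Unique test-set compounds are split at the micromolar boundary: pKi ≤ 6
(including exactly 6) are source compounds (SCs), labeled CCR-SC and/or
AC-CCR-SC by the pairs they occur in; pKi > 6 are known candidate compounds
(KCCs). Each SC is queried once per trial with the potency difference of
its own test pair (the largest gain when it occurs in several), 50
candidates are sampled, canonicalized, and matched for exact canonical-
SMILES equality — no tautomer or stereochemistry fuzziness. Each valid
candidate receives exactly one of 12 categories from (SC type) × (known CCR
compound / known AC-CCR compound / novel) × (same / different core), where
"same core" means sharing a rule-passing CCR core with that SC. A compound
occurring in both known pools counts as an AC-CCR match (fixed tie-break);
an SC carrying both labels is categorized under the AC-CCR-SC scheme. KCC
reproduction is reported as mean ± sd (population sd) of distinct
reproduced KCCs over trials (default 3, seeds derived per trial) and as a
proportion of available KCCs. Structural diversity of the generated set is
summarized by running series extraction over it (series, singletons, and
the percentage of original-class cores recovered), and potency gains of
reproduced (SC, KCC) pairs by boxplot statistics (median, quartiles,
1.5×IQR whiskers, outliers).

## Synthetic libraries and the grammar task

The generator emulates the structure of target-organized activity classes:
per class, analogue series are built from pairwise-distinct scaffolds
(1–3 labeled sites, drawn from simple aromatic/heteroaromatic ring systems
large enough to satisfy the core-size rule) and small substituents
(halogens, methyl, methoxy, amino, nitrile, amide, …). pKi is additive:
a per-series base drawn from 4.5–6.0, plus per-substituent effects (−0.3 to
+0.8, plus one +2.6 "cliff" substituent), plus Gaussian noise of sd 0.1 —
small enough that same-order aggregation and the 2.0 cliff threshold behave
predictably. The generator plants the cliff substituent into series until a
target fraction of within-series pairs (default 0.10, in the range observed
for GPCR activity classes) are activity cliffs, and errors when the effect
map cannot produce any cliff. Because scaffolds are distinct by
construction, ground-truth series map one-to-one onto cores, and series
recovery by the fragmentation module is a tested invariant (≥ 95%).

The grammar task is the fully deterministic variant used to measure
conditional sequence learning: single-site scaffolds crossed with six
substituents whose effects form a Sidon set (scaled {0, 1, 3, 7, 12, 20};
all pairwise differences distinct), no noise. Every potency-difference bin
therefore corresponds to exactly one substituent replacement, and the
model's reproduction rate has an exact ground truth. Because the
transformation rule is scaffold-independent, a model fine-tuned on the
activity-cliff pairs of the training cores can be evaluated on held-out
cores — a desk-scale version of the full test system.

What the synthetic data does not emulate: realistic medicinal-chemistry
property distributions, assay noise structure, series-size imbalance, and
the scale of public activity databases (hundreds of classes, ~10⁵–10⁶
pairs). Passing tests therefore demonstrate the correctness of the
machinery and the learnability of potency-conditioned transformations at
small scale, not expected performance on real screening data.

## Numerical choices and degenerate inputs

- Ki aggregation rejects non-positive or non-finite measurements; an empty
  measurement list is an error, a rejected compound is silently absent from
  the class (with an aggregate log line).
- Molecules with no eligible bonds produce no decompositions and can join
  no series.
- A class whose AC-CCR pairs share a single core puts everything into the
  fine-tuning side and leaves the test side empty, with a warning.
- Zero fine-tuning epochs return a copy of the input model unchanged.
- Softmax and cross-entropy are computed in float64 with max-subtraction;
  attention masking uses an additive −1e9.
- Batch-order invariance of the loss holds to the float32 reduction
  tolerance (1e−5); the untrained loss starts near ln(vocabulary size).
- Checkpoints store weights as `.npz` with a JSON sidecar (config, epoch,
  validation loss, vocabulary digest); a vocabulary-mismatch digest check
  rejects fine-tuning or sampling with the wrong vocabulary.

## Problem sizes used in tests and the reproduction script

The test suite and `scripts/acceptance.py` run the pipeline at desk scale
as the package's own reference conditions: fixture libraries of 1–2 classes
with 5–8 series each; the grammar task with 17 scaffolds × 6 substituents
(510 directed triples); the tiny model configuration trained ≤ 50 epochs;
50 samples per source compound over 3 trials for the pair-based test
system; 100 molecules for fragmentation round trips and 1000 for tokenizer
round trips; 50 seeded repetitions of the core-disjoint split.

## Known limitations

- The eligible-bond rule is a simplified stand-in for retrosynthetic MMP
  fragmentation rule sets; chemically exotic cuts (e.g. through
  heteroatom–heteroatom single bonds) are allowed if they meet the rule.
- Exact-match evaluation understates performance when generated compounds
  are tautomers or stereoisomers of known actives — by design.
- The NumPy model is CPU-bound and intended for small corpora; the
  reference configuration (dimension 256, 200 epochs, ~5×10⁵ triples) is
  expressed in the config but is not a practical CPU run.
- Censored measurements (">"/"<") and non-Ki endpoints are out of scope for
  curation.
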