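# potencyclm

Design of highly potent compounds from weakly potent input molecules with a
potency-conditioned chemical language model.

## The problem

In lead optimization, the goal is rarely to predict a potency value — it is
to find *more potent* compounds. Activity cliffs (pairs of structural
analogues with ≥ 100-fold potency difference, |ΔpKi| ≥ 2) show that small
chemical transformations can carry large potency gains. `potencyclm` turns
this observation into a generative method: a conditional encoder–decoder
transformer is trained on analogue pairs annotated with their potency
difference,

    (source compound, ΔpKi)  →  target compound,

and then asked for candidate molecules with a prescribed gain over a weakly
potent input. The package is aimed at computational and medicinal chemists
who want to run, extend, or scrutinize this kind of pair-based generative
potency modeling on their own activity data.

It provides the full pipeline as a library plus a CLI:

- **curation** — filtering of raw Ki activity records (direct assays,
  top confidence), geometric-mean potency aggregation within one order of
  magnitude, target-based activity classes;
- **analogues** — analogue-series extraction via compound-core
  relationships (CCR): multi-cut matched-molecular-pair-style
  fragmentation with up to five substitution sites and the core ≥ 2×
  substituent heavy-atom rule;
- **pairing** — All_CCR pair enumeration, ambiguity curation, two directed
  triples per pair, activity-cliff labeling at |ΔpKi| ≥ 2, and per-class
  core-disjoint 80/20 fine-tune/test splits;
- **tokenizer** — character-level SMILES tokens (with Cl/Br and bracket
  atoms as units) plus 1314 potency-difference bin tokens of width 0.01
  pKi over [−6.62, 6.52];
- **model** — a compact, fully seeded NumPy encoder–decoder transformer
  (explicit backprop, Adam, per-epoch checkpoints with minimum-validation-
  loss selection, multinomial/greedy sampling);
- **evaluation** — the compound-pair-based test system: SC/KCC partition
  at pKi 6, exact-match KCC reproduction over repeated trials, the
  12-category prediction-outcome taxonomy, structural-diversity and
  potency-gain statistics;
- **fixtures** — a synthetic analogue-series generator with an additive
  potency model and a deterministic "grammar task" whose substituent
  effects form a Sidon set, giving conditional generation an exact ground
  truth.

## Worked example

```python
from potencyclm.analogues import build_series
from potencyclm.fixtures import FixtureSpec, generate_library
from potencyclm.pairing import (AC_CCR, curate_triples, enumerate_pairs,
                                make_triples, split_finetune_test)

lib = generate_library(FixtureSpec(n_classes=1, n_series_per_class=6, seed=7))
compounds = lib.classes["class_00"]
series = build_series(compounds, max_sites=3)
pairs = curate_triples(enumerate_pairs(series))
ac = [p for p in pairs if p.label == AC_CCR]
ccr = [p for p in pairs if p.label != AC_CCR]
split = split_finetune_test(ac, ccr, fraction=0.8, seed=7)
```

This prints (via the module-level summaries and a few f-strings):

```
35 compounds, pKi 4.67-7.82
6 analogue series
89 All_CCR pairs: 80 CCR, 9 AC-CCR
178 directed training triples
fine-tune: 9 AC-CCR pairs over 2 cores
test: 47 pairs over 4 cores (core overlap: 0)
example AC-CCR pair: COc1ccc(CN2CCOCC2)cc1 (pKi 5.04)
    -> NC(=O)c1ccc(CN2CCOCC2)cc1 (pKi 7.67), delta 2.63
```

Reading: one synthetic activity class of 35 compounds organized into 6
analogue series yields 89 within-series pairs, of which 9 are activity
cliffs (≥ 100-fold difference; e.g. the methoxy→carboxamide swap above,
Δ = +2.63 pKi). Every pair becomes two directed training triples. The
fine-tune/test split assigns whole core groups, so the two sides share no
core — the model is always evaluated on chemotypes it was not fine-tuned
on. Training and sampling then follow with
`potencyclm.model.pretrain / finetune / sample`, and
`potencyclm.cli.run_test_system` scores sampled candidates against the
known potent compounds (KCCs) of the test side.

The same chain is available as CLI stages:

```sh
potencyclm --seed 7 --out-dir runs fixture
potencyclm --seed 7 --out-dir runs curate     # → compounds.csv
potencyclm --seed 7 --out-dir runs series     # → series.jsonl
potencyclm --seed 7 --out-dir runs pairs      # → pairs.csv
potencyclm --seed 7 --out-dir runs split      # → split.csv
potencyclm --seed 7 --out-dir runs vocab pretrain
potencyclm --seed 7 --out-dir runs finetune --class-id class_00
potencyclm --seed 7 --out-dir runs evaluate --class-id class_00
```

Each stage writes its artifact plus a JSON run manifest with the seeds and
input digests.

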