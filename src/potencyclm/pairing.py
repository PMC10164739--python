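"""Analogue-pair enumeration, triple construction, curation and splitting.

Within each analogue series, all compound pairs (All_CCR pairs) are
enumerated and deduplicated globally per class by unordered compound pair.
Each pair yields two directed training triples (source, target, Δ = pKi(target)
− pKi(source)). Pairs are labeled AC-CCR when |Δ| ≥ 2 pKi units (an at least
100-fold potency difference, i.e. an activity cliff) and CCR otherwise.

For fine-tuning, AC-CCR pairs are split ~80/20 per class with no core overlap
between the two sides; CCR pairs whose cores occur in the fine-tuning side are
dropped, and the remainder joins the test side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analogues import AnalogueSeries
from .chem import heavy_atom_count, mol_from_smiles
from .curation import Compound

log = logging.getLogger(__name__)

#: |ΔpKi| at or above this marks an activity cliff (100-fold potency gap).
AC_THRESHOLD = 2.0

CCR = "CCR"
AC_CCR = "AC_CCR"


@dataclass(frozen=True)
class AnaloguePair:
    """An unordered within-series compound pair with its core and Δ label."""

    cpd_a: Compound
    cpd_b: Compound
    core: str

    @property
    def delta(self) -> float:
        return self.cpd_b.pki - self.cpd_a.pki

    @property
    def label(self) -> str:
        return classify_pair(self)


@dataclass(frozen=True)
class TrainingTriple:
    """Directed (source, target, Δ) instance; Δ = pKi(target) − pKi(source)."""

    source: Compound
    target: Compound

    @property
    def delta(self) -> float:
        return self.target.pki - self.source.pki


def _core_rank(core: str) -> tuple[int, str]:
    """Dedup preference: larger core first, ties by lexicographic SMILES."""
    mol = mol_from_smiles(core)
    return (-heavy_atom_count(mol) if mol is not None else 0, core)


def enumerate_pairs(series: list[AnalogueSeries]) -> list[AnaloguePair]:
    """All within-series unordered pairs, deduplicated globally by
    (class, unordered compound pair). A pair shared by several cores keeps the
    core with the most heavy atoms (ties: lexicographically smallest SMILES).
    """
    best: dict[tuple[str, str, str], AnaloguePair] = {}
    order: list[tuple[str, str, str]] = []
    for s in series:
        members = s.compounds
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if a.smiles == b.smiles:
                    continue
                if b.smiles < a.smiles:
                    a, b = b, a
                key = (a.class_id, a.smiles, b.smiles)
                pair = AnaloguePair(cpd_a=a, cpd_b=b, core=s.core)
                if key not in best:
                    best[key] = pair
                    order.append(key)
                elif _core_rank(s.core) < _core_rank(best[key].core):
                    best[key] = pair
    return [best[k] for k in order]


def make_triples(pairs: list[AnaloguePair]) -> list[TrainingTriple]:
    """Two directed triples per pair: (A→B, Δ=pB−pA) and (B→A, Δ=pA−pB)."""
    triples = []
    for p in pairs:
        triples.append(TrainingTriple(source=p.cpd_a, target=p.cpd_b))
        triples.append(TrainingTriple(source=p.cpd_b, target=p.cpd_a))
    return triples


def classify_pair(pair: AnaloguePair) -> str:
    """AC_CCR iff the pair captures an at least 100-fold potency difference
    (|Δ| ≥ 2.0 pKi units); CCR otherwise. Symmetric in pair orientation."""
    return AC_CCR if abs(pair.delta) >= AC_THRESHOLD else CCR


def orient_ac_triple(pair: AnaloguePair) -> TrainingTriple:
    """Single directed triple for an AC-CCR pair, ordered weak → potent."""
    if classify_pair(pair) != AC_CCR:
        raise ValueError("orient_ac_triple requires an AC-CCR pair")
    lo, hi = sorted([pair.cpd_a, pair.cpd_b], key=lambda c: c.pki)
    return TrainingTriple(source=lo, target=hi)


def curate_triples(pairs: list[AnaloguePair], delta_resolution: float = 0.01
                   ) -> list[AnaloguePair]:
    """Remove ambiguous All_CCR pairs pooled across activity classes.

    A pair is removed (with both of its triples) when
    (1) one of its (source compound, potency difference) keys maps to multiple
        distinct target compounds from different activity classes, or
    (2) the same unordered compound pair carries different potency values in
        different classes.
    Potency differences are compared at ``delta_resolution`` (the bin width
    the model ultimately sees).

    Operates on undirected pairs; apply before triple construction.
    """
    def dkey(x: float) -> int:
        return int(round(x / delta_resolution))

    # rule (1): (source smiles, Δ) → set of (class, target smiles)
    src_map: dict[tuple[str, int], set[tuple[str, str]]] = {}
    # rule (2): unordered pair smiles → set of (class, potency value pair)
    pot_map: dict[tuple[str, str], set[tuple[str, int, int]]] = {}
    for p in pairs:
        for s, t in ((p.cpd_a, p.cpd_b), (p.cpd_b, p.cpd_a)):
            src_map.setdefault((s.smiles, dkey(t.pki - s.pki)), set()).add(
                (t.class_id, t.smiles))
        a, b = sorted([p.cpd_a, p.cpd_b], key=lambda c: c.smiles)
        pot_map.setdefault((a.smiles, b.smiles), set()).add(
            (a.class_id, dkey(a.pki), dkey(b.pki)))

    def offending(p: AnaloguePair) -> bool:
        for s, t in ((p.cpd_a, p.cpd_b), (p.cpd_b, p.cpd_a)):
            targets = src_map[(s.smiles, dkey(t.pki - s.pki))]
            if len({smi for _, smi in targets}) > 1 and len(
                    {cid for cid, _ in targets}) > 1:
                return True
        a, b = sorted([p.cpd_a, p.cpd_b], key=lambda c: c.smiles)
        values = pot_map[(a.smiles, b.smiles)]
        # differing value pairs can only arise across classes (one pKi per
        # compound per class after aggregation)
        return len({(pa, pb) for _, pa, pb in values}) > 1

    kept = [p for p in pairs if not offending(p)]
    if len(kept) < len(pairs):
        log.info("curation removed %d ambiguous pairs", len(pairs) - len(kept))
    return kept


@dataclass(frozen=True)
class PairSplit:
    """Per-class core-disjoint split of pairs for fine-tuning and testing."""

    finetune: tuple[AnaloguePair, ...]  # AC-CCR only
    test: tuple[AnaloguePair, ...]      # remaining AC-CCR + core-disjoint CCR

    def core_sets(self) -> tuple[set[str], set[str]]:
        return ({p.core for p in self.finetune}, {p.core for p in self.test})


def split_finetune_test(
    ac_pairs: list[AnaloguePair],
    ccr_pairs: list[AnaloguePair],
    fraction: float = 0.8,
    seed: int = 0,
) -> PairSplit:
    """Core-disjoint fine-tune/test split of one class's pairs.

    AC-CCR pairs are grouped by core; whole core groups are assigned to the
    fine-tuning side — in random order refined by descending group size —
    until at least ``fraction`` of AC-CCR pairs are covered. The test side
    receives the remaining AC-CCR pairs plus every CCR pair whose core does
    not occur on the fine-tuning side, so the two sides share no core.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[AnaloguePair]] = {}
    for p in ac_pairs:
        groups.setdefault(p.core, []).append(p)
    cores = list(groups)
    rng.shuffle(cores)
    cores.sort(key=lambda c: -len(groups[c]))  # stable: ties stay shuffled

    target = fraction * len(ac_pairs)
    finetune: list[AnaloguePair] = []
    ft_cores: set[str] = set()
    rest: list[AnaloguePair] = []
    for core in cores:
        if len(finetune) < target:
            finetune.extend(groups[core])
            ft_cores.add(core)
        else:
            rest.extend(groups[core])
    if not rest:
        log.warning("all %d AC-CCR cores assigned to fine-tuning; test side has "
                    "no AC-CCR pairs", len(cores))
    test = rest + [p for p in ccr_pairs if p.core not in ft_cores]
    return PairSplit(finetune=tuple(finetune), test=tuple(test))


# ---------------------------------------------------------------------------
# tabular interface

def pairs_to_frame(pairs: list[AnaloguePair], split: str | None = None) -> pd.DataFrame:
    rows = [
        {
            "source_smiles": p.cpd_a.smiles, "source_pki": p.cpd_a.pki,
            "target_smiles": p.cpd_b.smiles, "target_pki": p.cpd_b.pki,
            "delta": p.delta, "label": p.label, "core": p.core,
            "class_id": p.cpd_a.class_id,
            **({"split": split} if split else {}),
        }
        for p in pairs
    ]
    return pd.DataFrame(rows)


def frame_to_pairs(df: pd.DataFrame) -> list[AnaloguePair]:
    out = []
    for row in df.itertuples(index=False):
        cid = str(row.class_id)
        out.append(AnaloguePair(
            cpd_a=Compound(str(row.source_smiles), cid, float(row.source_pki)),
            cpd_b=Compound(str(row.target_smiles), cid, float(row.target_pki)),
            core=str(row.core),
        ))
    return out
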