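"""Synthetic analogue-series libraries with controllable potency structure.

The generator emulates target-organized activity classes: each class holds
analogue series built from a scaffold with 1–3 labeled substitution sites and
a pool of small substituents. Per-compound pKi values follow an additive
model (series base potency + per-substituent effects + Gaussian noise), with
one large-effect "cliff" substituent so that series contain both weak
(pKi ≤ 6) and potent (pKi > 6) members, including ≥100-fold within-series
differences (activity cliffs). Scaffolds are pairwise distinct within a
class, so ground-truth series map one-to-one onto cores.

The grammar task is a fully deterministic variant for measuring sequence
learning: substituent effects form a Sidon set (all pairwise differences
distinct), so every potency-difference bin corresponds to exactly one
substituent replacement and a trained model's reproduction rate can be
scored against known answers.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .analogues import fragment
from .chem import canonical_smiles, mol_from_smiles
from .curation import ActivityRecord, Compound
from .pairing import AC_THRESHOLD, AnaloguePair, TrainingTriple

log = logging.getLogger(__name__)

#: Single-site scaffolds; [*:1] marks the substitution site.
SINGLE_SITE_SCAFFOLDS = [
    "[*:1]c1ccc2ccccc2c1",
    "[*:1]c1ccc(-c2ccccc2)cc1",
    "[*:1]c1ccc2[nH]ccc2c1",
    "[*:1]c1ccc(OCc2ccccc2)cc1",
    "[*:1]c1ccc(C(=O)Nc2ccccc2)cc1",
    "[*:1]c1nc2ccccc2s1",
    "[*:1]c1nc2ccccc2[nH]1",
    "[*:1]c1ccc(N2CCOCC2)cc1",
    "[*:1]c1ccc(-c2ccncc2)cc1",
    "[*:1]c1ccc(S(=O)(=O)c2ccccc2)cc1",
    "[*:1]c1cccc2ccccc12",
    "[*:1]c1ccc(Cc2ccccc2)cc1",
    "[*:1]c1ccc(-c2cccnc2)cc1",
    "[*:1]c1ccc(N2CCCCC2)cc1",
    "[*:1]c1ccc(Oc2ccccc2)cc1",
    "[*:1]c1ccc2cccnc2c1",
    "[*:1]c1ccc2ncccc2c1",
    "[*:1]c1ccc(CN2CCOCC2)cc1",
    "[*:1]c1ccc(-n2cccc2)cc1",
    "[*:1]c1ccc2oc(-c3ccccc3)cc2c1",
]

MULTI_SITE_SCAFFOLDS = [
    "[*:1]c1ccc(-c2ccc([*:2])cc2)cc1",
    "[*:1]c1ccc2cc([*:2])ccc2c1",
    "[*:1]c1ccc(OCc2ccc([*:2])cc2)cc1",
    "[*:1]c1ccc(C(=O)Nc2ccc([*:2])cc2)cc1",
    "[*:1]c1cc([*:2])cc(-c2ccc([*:3])cc2)c1",
]

#: Small substituents (single unlabeled dummy) and their additive pKi effects.
DEFAULT_EFFECTS = {
    "*F": 0.2,
    "*Cl": 0.5,
    "*Br": 0.6,
    "*C": 0.1,
    "*CC": 0.3,
    "*OC": -0.1,
    "*O": -0.3,
    "*N": 0.4,
    "*C#N": 0.8,
    "*NC": 0.7,
    "*C(N)=O": 2.6,  # the cliff substituent
}


def attach(scaffold: str, substituents: dict[int, str]) -> str:
    """Assemble scaffold + substituents into a canonical SMILES.

    ``substituents`` maps site number → substituent SMILES with one
    unlabeled dummy atom."""
    combined = mol_from_smiles(scaffold)
    if combined is None:
        raise ValueError(f"invalid scaffold SMILES: {scaffold!r}")
    sites = {a.GetAtomMapNum() for a in combined.GetAtoms() if a.GetAtomicNum() == 0}
    if set(substituents) != sites:
        raise ValueError(f"scaffold sites {sites} vs substituents {set(substituents)}")
    for site, sub_smiles in substituents.items():
        sub = mol_from_smiles(sub_smiles)
        if sub is None:
            raise ValueError(f"invalid substituent SMILES: {sub_smiles!r}")
        sub = Chem.Mol(sub)
        dummies = [a for a in sub.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dummies) != 1:
            raise ValueError(f"substituent {sub_smiles!r} must have exactly one dummy")
        dummies[0].SetAtomMapNum(site)
        combined = Chem.CombineMols(combined, sub)
    joined = Chem.molzip(combined)
    Chem.SanitizeMol(joined)
    return Chem.MolToSmiles(joined)


def canonical_core_form(scaffold: str) -> str:
    """The scaffold's core SMILES in the same canonical labeling the
    fragmentation module emits (sites renumbered by canonical atom rank)."""
    mol = mol_from_smiles(scaffold)
    if mol is None:
        raise ValueError(f"invalid scaffold SMILES: {scaffold!r}")
    ranked = Chem.Mol(mol)
    for atom in ranked.GetAtoms():
        atom.SetAtomMapNum(0)
    ranks = list(Chem.CanonicalRankAtoms(ranked, breakTies=True))
    dummies = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            nbr = atom.GetNeighbors()[0]
            dummies.append((ranks[nbr.GetIdx()], ranks[atom.GetIdx()], atom.GetIdx()))
    dummies.sort()
    relabeled = Chem.Mol(mol)
    for new_site, (_, _, idx) in enumerate(dummies, start=1):
        relabeled.GetAtomWithIdx(idx).SetAtomMapNum(new_site)
    return Chem.MolToSmiles(relabeled)


@dataclass(frozen=True)
class FixtureSpec:
    n_classes: int = 2
    n_series_per_class: int = 8
    series_size_range: tuple[int, int] = (4, 8)
    scaffold_pool: tuple[str, ...] = tuple(SINGLE_SITE_SCAFFOLDS + MULTI_SITE_SCAFFOLDS)
    substituent_effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    base_pki_range: tuple[float, float] = (4.5, 6.0)
    noise_sd: float = 0.1
    ac_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not self.scaffold_pool or not self.substituent_effects:
            raise ValueError("scaffold and substituent pools must be non-empty")
        if not 0 <= self.ac_fraction <= 1:
            raise ValueError("ac_fraction must be in [0, 1]")
        if self.n_series_per_class > len(self.scaffold_pool):
            raise ValueError("need at least one distinct scaffold per series")
        effects = sorted(self.substituent_effects.values())
        max_gap = effects[-1] - effects[0]
        if self.ac_fraction > 0 and max_gap < AC_THRESHOLD:
            raise ValueError(
                f"infeasible ac_fraction {self.ac_fraction}: the largest "
                f"substituent-effect difference is {max_gap:.2f} < "
                f"{AC_THRESHOLD} pKi units, so no series can contain an "
                "activity cliff")


@dataclass(frozen=True)
class TruthSeries:
    """Ground truth for one generated series."""

    class_id: str
    core: str                       # canonical labeled core SMILES
    scaffold: str                   # original scaffold with [*:k] sites
    members: tuple[str, ...]        # canonical member SMILES
    substituents: tuple[tuple[str, ...], ...]  # per member, per site
    pkis: tuple[float, ...]

    def true_pairs(self) -> list[tuple[str, str, float]]:
        """All (member_i, member_j, Δ = pki_j − pki_i) with i < j."""
        out = []
        for i in range(len(self.members)):
            for j in range(i + 1, len(self.members)):
                out.append((self.members[i], self.members[j],
                            self.pkis[j] - self.pkis[i]))
        return out


@dataclass
class FixtureLibrary:
    spec: FixtureSpec
    classes: dict[str, list[Compound]]
    truth: list[TruthSeries]

    def records(self) -> list[ActivityRecord]:
        """The library in the raw activity-record schema (Ki in molar), so
        fixtures exercise the real ingestion path."""
        out = []
        for compounds in self.classes.values():
            for c in compounds:
                out.append(ActivityRecord(
                    smiles=c.smiles, class_id=c.class_id,
                    relationship_type="D", confidence_score=9,
                    ki_molar=10.0 ** (-c.pki)))
        return out

    def ac_pair_fraction(self) -> float:
        deltas = [abs(d) for s in self.truth for _, _, d in s.true_pairs()]
        if not deltas:
            return 0.0
        return sum(1 for d in deltas if d >= AC_THRESHOLD) / len(deltas)


def _scaffold_sites(scaffold: str) -> list[int]:
    mol = mol_from_smiles(scaffold)
    return sorted(a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomicNum() == 0)


def generate_library(spec: FixtureSpec) -> FixtureLibrary:
    """Deterministically generate a class-organized compound library with
    ground-truth series annotations. See the module docstring for the model."""
    rng = np.random.default_rng(spec.seed)
    subs = sorted(spec.substituent_effects)
    effects = spec.substituent_effects
    cliff_sub = max(subs, key=lambda s: effects[s])
    lo_size, hi_size = spec.series_size_range

    classes: dict[str, list[Compound]] = {}
    truth: list[TruthSeries] = []
    for ci in range(spec.n_classes):
        class_id = f"class_{ci:02d}"
        scaffolds = list(spec.scaffold_pool)
        rng.shuffle(scaffolds)
        scaffolds = scaffolds[: spec.n_series_per_class]
        compounds: list[Compound] = []
        series_subs: list[list[tuple[str, ...]]] = []
        for scaffold in scaffolds:
            sites = _scaffold_sites(scaffold)
            size = int(rng.integers(lo_size, hi_size + 1))
            combos = list(itertools.product(subs, repeat=len(sites)))
            size = min(size, len(combos))
            picks = [combos[i] for i in rng.choice(len(combos), size=size, replace=False)]
            series_subs.append(picks)

        # steer the AC-pair fraction by planting the cliff substituent
        def frac() -> float:
            n_ac = n_all = 0
            for picks in series_subs:
                sums = [sum(effects[s] for s in tup) for tup in picks]
                for a, b in itertools.combinations(sums, 2):
                    n_all += 1
                    n_ac += abs(a - b) >= AC_THRESHOLD
            return n_ac / n_all if n_all else 0.0

        for picks in series_subs:
            if frac() >= spec.ac_fraction:
                break
            if not any(cliff_sub in tup for tup in picks):
                weakest = min(range(len(picks)),
                              key=lambda i: sum(effects[s] for s in picks[i]))
                replaced = (cliff_sub,) + picks[weakest][1:]
                if replaced not in picks:
                    picks[weakest] = replaced
        achieved = frac()
        if spec.ac_fraction > 0 and achieved == 0.0:
            raise ValueError(
                f"infeasible ac_fraction {spec.ac_fraction}: no activity "
                "cliff could be planted with the given substituent effects")

        for scaffold, picks in zip(scaffolds, series_subs):
            sites = _scaffold_sites(scaffold)
            base = float(rng.uniform(*spec.base_pki_range))
            members, pkis = [], []
            for tup in picks:
                smi = attach(scaffold, dict(zip(sites, tup)))
                pki = base + sum(effects[s] for s in tup)
                pki += float(rng.normal(0.0, spec.noise_sd))
                members.append(smi)
                pkis.append(round(pki, 2))
            truth.append(TruthSeries(
                class_id=class_id, core=canonical_core_form(scaffold),
                scaffold=scaffold, members=tuple(members),
                substituents=tuple(picks), pkis=tuple(pkis)))
            compounds.extend(
                Compound(smiles=m, class_id=class_id, pki=p)
                for m, p in zip(members, pkis))
        classes[class_id] = compounds
    lib = FixtureLibrary(spec=spec, classes=classes, truth=truth)
    log.info("generated %d classes, %d series, AC pair fraction %.3f",
             spec.n_classes, len(truth), lib.ac_pair_fraction())
    return lib


def fixture_smiles(n: int, seed: int = 0) -> list[str]:
    """n distinct valid canonical SMILES drawn from the scaffold×substituent
    space; a convenience pool for round-trip property tests."""
    rng = np.random.default_rng(seed)
    subs = sorted(DEFAULT_EFFECTS)
    out: list[str] = []
    seen: set[str] = set()
    all_scaffolds = SINGLE_SITE_SCAFFOLDS + MULTI_SITE_SCAFFOLDS
    while len(out) < n:
        scaffold = all_scaffolds[int(rng.integers(len(all_scaffolds)))]
        sites = _scaffold_sites(scaffold)
        tup = [subs[int(rng.integers(len(subs)))] for _ in sites]
        smi = attach(scaffold, dict(zip(sites, tup)))
        if smi not in seen:
            seen.add(smi)
            out.append(smi)
    return out


# ---------------------------------------------------------------------------
# grammar task

#: Sidon-set substituent effects: all pairwise differences are distinct, so a
#: potency-difference bin identifies exactly one substituent replacement.
GRAMMAR_EFFECTS = {
    "*F": 0.0,
    "*C": 0.2,
    "*OC": 0.6,
    "*Cl": 1.4,
    "*N": 2.4,
    "*C#N": 4.0,
}


@dataclass
class GrammarTask:
    triples: list[TrainingTriple]
    pairs: list[AnaloguePair]
    rule: dict[int, tuple[str, str]]  # Δ in centi-pKi units → (from, to) substituent


def grammar_task(
    n_scaffolds: int = 17,
    effects: dict[str, float] | None = None,
    seed: int = 0,
) -> GrammarTask:
    """Deterministic Δ→transformation training set.

    Each scaffold is combined with every grammar substituent; all ordered
    member pairs become triples. Because the effect set is Sidon, the binned
    Δ of a triple uniquely determines which substituent is replaced by which,
    making reproduction exactly scoreable. Noise-free by construction."""
    effects = dict(GRAMMAR_EFFECTS if effects is None else effects)
    diffs = [round(b - a, 6) for a, b in itertools.permutations(effects.values(), 2)]
    if len(set(diffs)) != len(diffs):
        raise ValueError("grammar effects must have all-distinct pairwise differences")
    scaffolds = SINGLE_SITE_SCAFFOLDS[:n_scaffolds]
    rng = np.random.default_rng(seed)
    subs = sorted(effects)
    rule = {}
    triples, pairs = [], []
    for scaffold in scaffolds:
        base = 5.0
        core = canonical_core_form(scaffold)
        members = {
            s: Compound(smiles=attach(scaffold, {1: s}), class_id="grammar",
                        pki=round(base + effects[s], 2))
            for s in subs
        }
        for a, b in itertools.combinations(subs, 2):
            pairs.append(AnaloguePair(cpd_a=members[a], cpd_b=members[b], core=core))
        for a, b in itertools.permutations(subs, 2):
            triples.append(TrainingTriple(source=members[a], target=members[b]))
            rule[int(round((effects[b] - effects[a]) * 100))] = (a, b)
    rng.shuffle(triples)
    return GrammarTask(triples=triples, pairs=pairs, rule=rule)
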