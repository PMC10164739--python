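"""Compound-pair-based evaluation of generated molecules.

Test-set compounds are split at pKi 6: compounds with at most micromolar
potency (pKi ≤ 6) serve as source compounds (SCs) and the more potent ones
(pKi > 6) as known candidate compounds (KCCs). Each SC carries its pair-type
label (CCR-SC and/or AC-CCR-SC). A generated molecule is valid if RDKit
parses it; valid molecules are canonicalized and matched exactly against the
known pools, yielding one of 12 mutually exclusive outcome categories:

    1.1/1.2  CCR-SC    → known CCR compound      (same / different core)
    1.3/1.4  CCR-SC    → known AC-CCR compound   (same / different core)
    1.5/1.6  CCR-SC    → novel compound          (same / different core)
    2.1/2.2  AC-CCR-SC → known AC-CCR compound   (same / different core)
    2.3/2.4  AC-CCR-SC → known CCR compound      (same / different core)
    2.5/2.6  AC-CCR-SC → novel compound          (same / different core)

"Same core" means the generated molecule shares a rule-passing CCR core with
its SC. KCC reproduction is summarized per class over repeated sampling
trials; structural diversity of the generated set is summarized by extracting
analogue series from it and comparing cores against the original class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .analogues import build_series, compound_cores
from .chem import canonical_smiles
from .curation import Compound
from .pairing import AC_CCR, CCR, AnaloguePair, classify_pair

log = logging.getLogger(__name__)

SC_BOUNDARY_PKI = 6.0  # "maximally 1 μmol": pKi ≤ 6 is an SC, > 6 a KCC

CCR_SC = "CCR-SC"
AC_CCR_SC = "AC-CCR-SC"

CATEGORIES = (
    "1.1", "1.2", "1.3", "1.4", "1.5", "1.6",
    "2.1", "2.2", "2.3", "2.4", "2.5", "2.6",
)

# (SC type, match type) → category index pair (same core, different core)
_CATEGORY_TABLE = {
    (CCR_SC, CCR): ("1.1", "1.2"),
    (CCR_SC, AC_CCR): ("1.3", "1.4"),
    (CCR_SC, "novel"): ("1.5", "1.6"),
    (AC_CCR_SC, AC_CCR): ("2.1", "2.2"),
    (AC_CCR_SC, CCR): ("2.3", "2.4"),
    (AC_CCR_SC, "novel"): ("2.5", "2.6"),
}


@dataclass
class TestSystem:
    """SC/KCC partition of one activity class's test pairs."""

    sources: dict[str, set[str]]          # SC canonical SMILES → {CCR-SC, AC-CCR-SC}
    kccs: set[str]                        # canonical SMILES with pKi > 6
    ccr_compounds: set[str]               # unique compounds of CCR test pairs
    ac_compounds: set[str]                # unique compounds of AC-CCR test pairs
    pki: dict[str, float]                 # canonical SMILES → pKi
    source_pairs: dict[str, list[AnaloguePair]] = field(default_factory=dict)

    def source_labels(self, smiles: str) -> set[str]:
        return self.sources[smiles]


def build_test_system(test_pairs: list[AnaloguePair]) -> TestSystem:
    """Partition the unique compounds of the test pairs at the pKi-6 boundary
    and record each SC's pair-type labels. A compound occurring in both CCR
    and AC-CCR pairs is pooled once but keeps both labels."""
    sources: dict[str, set[str]] = {}
    kccs: set[str] = set()
    ccr_cpds: set[str] = set()
    ac_cpds: set[str] = set()
    pki: dict[str, float] = {}
    source_pairs: dict[str, list[AnaloguePair]] = {}
    for p in test_pairs:
        label = classify_pair(p)
        for c in (p.cpd_a, p.cpd_b):
            pki[c.smiles] = c.pki
            (ccr_cpds if label == CCR else ac_cpds).add(c.smiles)
            if c.pki <= SC_BOUNDARY_PKI:
                sources.setdefault(c.smiles, set()).add(
                    CCR_SC if label == CCR else AC_CCR_SC)
                source_pairs.setdefault(c.smiles, []).append(p)
            else:
                kccs.add(c.smiles)
    return TestSystem(sources=sources, kccs=kccs, ccr_compounds=ccr_cpds,
                      ac_compounds=ac_cpds, pki=pki, source_pairs=source_pairs)


def assess_generation(raw: list[str]) -> tuple[list[str], float]:
    """Parse raw generated strings; return (canonical SMILES of the valid
    ones, invalid fraction). Duplicates are retained."""
    if not raw:
        raise ValueError("no generated strings to assess")
    valid = []
    for s in raw:
        smi = canonical_smiles(s)
        if smi is not None:
            valid.append(smi)
    return valid, (len(raw) - len(valid)) / len(raw)


@lru_cache(maxsize=200_000)
def _cores_of(smiles: str, max_sites: int) -> frozenset:
    return frozenset(compound_cores(smiles, max_sites=max_sites))


def categorize(
    source_label: str,
    generated: str,
    system: TestSystem,
    source: Compound | str,
    max_sites: int = 3,
) -> str:
    """Assign one of the 12 outcome categories to a valid canonical SMILES.

    Match type: the generated compound may equal a known AC-CCR test
    compound (taking precedence when it occurs in both pools), a known CCR
    test compound, or be novel. Core match: true iff it shares a CCR core
    with the specific source compound."""
    if source_label not in (CCR_SC, AC_CCR_SC):
        raise ValueError(f"unknown source label {source_label!r}")
    if generated in system.ac_compounds:
        match = AC_CCR
    elif generated in system.ccr_compounds:
        match = CCR
    else:
        match = "novel"
    src_smiles = source.smiles if isinstance(source, Compound) else source
    same_core = bool(_cores_of(src_smiles, max_sites) & _cores_of(generated, max_sites))
    same, different = _CATEGORY_TABLE[(source_label, match)]
    return same if same_core else different


@dataclass(frozen=True)
class PredictionRecord:
    """One sampled molecule for one SC in one trial, with its assessment."""

    source: str
    generated_smiles: str
    valid: bool
    canonical: str | None
    kcc_match: bool
    core_match: bool
    category: str | None
    trial: int


def assess_predictions(
    system: TestSystem,
    samples_by_source: dict[str, list[str]],
    trial: int = 0,
    max_sites: int = 3,
) -> list[PredictionRecord]:
    """Assess raw samples per SC: validity, canonicalization, KCC match and
    category. SCs carrying both labels are categorized under each label's
    scheme with the AC-CCR-SC label taking precedence for the record."""
    records = []
    for src, raw in samples_by_source.items():
        labels = system.source_labels(src)
        label = AC_CCR_SC if AC_CCR_SC in labels else CCR_SC
        for s in raw:
            smi = canonical_smiles(s)
            if smi is None:
                records.append(PredictionRecord(
                    source=src, generated_smiles=s, valid=False, canonical=None,
                    kcc_match=False, core_match=False, category=None, trial=trial))
                continue
            cat = categorize(label, smi, system, src, max_sites=max_sites)
            records.append(PredictionRecord(
                source=src, generated_smiles=s, valid=True, canonical=smi,
                kcc_match=smi in system.kccs,
                core_match=cat in ("1.1", "1.3", "1.5", "2.1", "2.3", "2.5"),
                category=cat, trial=trial))
    return records


def category_counts(records: list[PredictionRecord], unique: bool = True) -> dict[str, int]:
    """Per-category counts of (by default unique) valid generated compounds."""
    seen: dict[str, set] = {c: set() for c in CATEGORIES}
    counts = {c: 0 for c in CATEGORIES}
    for r in records:
        if not r.valid:
            continue
        if unique:
            if r.canonical in seen[r.category]:
                continue
            seen[r.category].add(r.canonical)
        counts[r.category] += 1
    return counts


def kcc_reproduction_stats(
    system: TestSystem, records_by_trial: list[list[PredictionRecord]]
) -> dict:
    """Mean ± sd of distinct reproduced KCCs across trials, the proportion
    relative to all available KCCs, and the mean count of novel (non-KCC)
    unique valid compounds."""
    if not records_by_trial:
        raise ValueError("need at least one trial")
    if not system.kccs:
        raise ValueError("no KCCs in the test system; proportion undefined")
    kcc_counts, novel_counts = [], []
    for records in records_by_trial:
        reproduced = {r.canonical for r in records if r.valid and r.kcc_match}
        assert reproduced <= system.kccs
        novel = {r.canonical for r in records if r.valid and not r.kcc_match}
        kcc_counts.append(len(reproduced))
        novel_counts.append(len(novel))
    mean = float(np.mean(kcc_counts))
    sd = float(np.std(kcc_counts))
    return {
        "n_trials": len(records_by_trial),
        "kccs_available": len(system.kccs),
        "reproduced_kccs_mean": mean,
        "reproduced_kccs_sd": sd,
        "reproduced_pct": 100.0 * mean / len(system.kccs),
        "reproduced_pct_sd": 100.0 * sd / len(system.kccs),
        "non_kccs_mean": float(np.mean(novel_counts)),
    }


def diversity_stats(
    generated: list[str], original_cores: set[str], max_sites: int = 3
) -> dict:
    """Structural organization of the generated set: number of analogue
    series, number of singletons (compounds sharing no core with any other
    generated compound), and the percentage of original-class cores that
    reappear among the generated compounds' cores."""
    unique = sorted(set(generated))
    if not unique:
        return {"n_series": 0, "n_singletons": 0, "core_reproduction_pct": 0.0}
    compounds = [Compound(smiles=s, class_id="generated", pki=0.0) for s in unique]
    series = build_series(compounds, max_sites=max_sites)
    in_series = {c.smiles for s in series for c in s.compounds}
    gen_cores: set[str] = set()
    for s in unique:
        gen_cores.update(_cores_of(s, max_sites))
    pct = (100.0 * len(original_cores & gen_cores) / len(original_cores)
           if original_cores else 0.0)
    return {
        "n_series": len(series),
        "n_singletons": len(unique) - len(in_series),
        "core_reproduction_pct": pct,
    }


def potency_gain_distribution(pairs: list[tuple[Compound, Compound]]) -> dict:
    """Boxplot statistics of pKi(matched KCC) − pKi(SC) over reproduced
    (SC, KCC) pairs: median, quartiles, 1.5×IQR whiskers and outliers."""
    if not pairs:
        raise ValueError("no (SC, KCC) pairs")
    gains = np.array([kcc.pki - sc.pki for sc, kcc in pairs])
    q1, med, q3 = np.percentile(gains, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = gains[(gains >= lo_fence) & (gains <= hi_fence)]
    return {
        "n": len(gains),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": sorted(float(g) for g in gains[(gains < lo_fence) | (gains > hi_fence)]),
    }
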