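"""Analogue-series identification via compound-core relationships (CCR).

Compounds are fragmented by simultaneously cutting 1..5 eligible bonds, in the
spirit of matched-molecular-pair fragmentation generalized to multiple
substitution sites. A decomposition is a core with numbered attachment points
plus one single-attachment substituent per cut. The CCR core-size rule keeps
decompositions whose core has at least twice the heavy atoms of the combined
substituents, and an analogue series is any core shared by at least two
compounds of an activity class.

Eligible bonds are acyclic single bonds between two heavy atoms with at least
one of the two atoms outside any ring; this rule is the package's fixed
stand-in for a full retrosynthetic rule set and is the single configuration
point of the module.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

from rdkit import Chem

from .chem import canonical_smiles, heavy_atom_count, mol_from_smiles
from .curation import Compound

log = logging.getLogger(__name__)

MAX_SITES = 5


@dataclass(frozen=True)
class Decomposition:
    """A core with numbered attachment points and its detached substituents.

    ``core`` is a canonical SMILES with ``[*:k]`` attachment labels
    (k = 1..n_sites, numbered by canonical rank of the core attachment atom);
    each substituent carries the matching ``[*:k]`` label.
    """

    core: str
    substituents: tuple[str, ...]

    @property
    def n_sites(self) -> int:
        return len(self.substituents)


def eligible_bonds(mol: Chem.Mol) -> list[int]:
    """Indices of cuttable bonds: acyclic single bonds between heavy atoms
    where at least one end atom lies outside any ring."""
    out = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        if a.IsInRing() and b.IsInRing():
            continue
        out.append(bond.GetIdx())
    return out


def _relabel(core: Chem.Mol, subs: list[Chem.Mol]) -> Decomposition | None:
    """Renumber attachment points by canonical rank of the core attachment atom
    and emit canonical SMILES for core and substituents.

    On entry the dummy atoms carry the cut index as isotope; on exit isotopes
    are cleared and atom-map numbers 1..k encode the site labels.
    """
    ranked = Chem.Mol(core)
    for atom in ranked.GetAtoms():
        atom.SetIsotope(0)
        atom.SetAtomMapNum(0)
    ranks = list(Chem.CanonicalRankAtoms(ranked, breakTies=True))

    dummies = []  # (neighbor rank, own rank, cut label)
    for atom in core.GetAtoms():
        if atom.GetAtomicNum() == 0:
            nbrs = atom.GetNeighbors()
            if len(nbrs) != 1:
                return None
            dummies.append((ranks[nbrs[0].GetIdx()], ranks[atom.GetIdx()], atom.GetIsotope()))
    dummies.sort()
    site_of_cut = {cut: site for site, (_, _, cut) in enumerate(dummies, start=1)}

    core = Chem.Mol(core)
    for atom in core.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomMapNum(site_of_cut[atom.GetIsotope()])
            atom.SetIsotope(0)
    labeled_subs = []
    for sub in subs:
        sub = Chem.Mol(sub)
        for atom in sub.GetAtoms():
            if atom.GetAtomicNum() == 0:
                atom.SetAtomMapNum(site_of_cut[atom.GetIsotope()])
                atom.SetIsotope(0)
        labeled_subs.append(sub)
    labeled_subs.sort(key=lambda m: next(
        a.GetAtomMapNum() for a in m.GetAtoms() if a.GetAtomicNum() == 0
    ))
    return Decomposition(
        core=Chem.MolToSmiles(core),
        substituents=tuple(Chem.MolToSmiles(m) for m in labeled_subs),
    )


def fragment(compound: Compound | str, max_sites: int = MAX_SITES) -> list[Decomposition]:
    """Enumerate all decompositions of a molecule with 1..max_sites cuts.

    Only cut sets yielding exactly one connected core (bearing all attachment
    points) and one single-attachment substituent per cut are kept. Molecules
    with no eligible bonds yield an empty list.
    """
    if not 1 <= max_sites <= MAX_SITES:
        raise ValueError(f"max_sites must be in 1..{MAX_SITES}, got {max_sites}")
    smiles = compound.smiles if isinstance(compound, Compound) else compound
    mol = mol_from_smiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    bonds = eligible_bonds(mol)
    decomps: list[Decomposition] = []
    seen: set[tuple[str, tuple[str, ...]]] = set()
    for k in range(1, max_sites + 1):
        for combo in itertools.combinations(bonds, k):
            # isotopes 1..k tag which cut produced each dummy atom
            labels = [(i, i) for i in range(1, k + 1)]
            frag_mol = Chem.FragmentOnBonds(mol, list(combo), addDummies=True, dummyLabels=labels)
            try:
                frags = Chem.GetMolFrags(frag_mol, asMols=True, sanitizeFrags=True)
            except Chem.rdchem.AtomValenceException:  # pragma: no cover
                continue
            if len(frags) != k + 1:
                continue
            core_frag, subs = None, []
            ok = True
            for f in frags:
                n_dummy = sum(1 for a in f.GetAtoms() if a.GetAtomicNum() == 0)
                if n_dummy == k and core_frag is None and k > 1:
                    core_frag = f
                elif n_dummy == 1:
                    subs.append(f)
                else:
                    ok = False
                    break
            if k == 1:
                # both fragments have one dummy; each may serve as the core
                if ok and len(subs) == 2:
                    for i in (0, 1):
                        d = _relabel(subs[i], [subs[1 - i]])
                        if d is not None and (d.core, d.substituents) not in seen:
                            seen.add((d.core, d.substituents))
                            decomps.append(d)
                continue
            if not ok or core_frag is None or len(subs) != k:
                continue
            d = _relabel(core_frag, subs)
            if d is not None and (d.core, d.substituents) not in seen:
                seen.add((d.core, d.substituents))
                decomps.append(d)
    return decomps


def core_size_rule(d: Decomposition) -> bool:
    """CCR size constraint: core heavy atoms ≥ 2 × combined substituent heavy
    atoms (attachment dummies excluded); the boundary case is accepted."""
    core = mol_from_smiles(d.core)
    subs = [mol_from_smiles(s) for s in d.substituents]
    if core is None or any(s is None for s in subs):
        raise ValueError(f"invalid decomposition SMILES in {d}")
    return heavy_atom_count(core) >= 2 * sum(heavy_atom_count(s) for s in subs)


def reassemble(d: Decomposition) -> str:
    """Join core and substituents at matching attachment labels; returns the
    canonical SMILES of the reassembled molecule."""
    combined = mol_from_smiles(d.core)
    if combined is None:
        raise ValueError(f"invalid core SMILES: {d.core!r}")
    for s in d.substituents:
        sub = mol_from_smiles(s)
        if sub is None:
            raise ValueError(f"invalid substituent SMILES: {s!r}")
        combined = Chem.CombineMols(combined, sub)
    joined = Chem.molzip(combined)
    Chem.SanitizeMol(joined)
    return Chem.MolToSmiles(joined)


@dataclass(frozen=True)
class AnalogueSeries:
    """A core shared by ≥2 compounds, with each member's substituent tuple."""

    core: str
    members: tuple[tuple[Compound, tuple[str, ...]], ...]

    @property
    def compounds(self) -> list[Compound]:
        return [c for c, _ in self.members]


def compound_cores(
    compound: Compound | str, max_sites: int = MAX_SITES
) -> dict[str, tuple[str, ...]]:
    """Map of rule-passing core SMILES → substituent tuple for one molecule."""
    cores: dict[str, tuple[str, ...]] = {}
    for d in fragment(compound, max_sites=max_sites):
        if core_size_rule(d):
            # a molecule can reach one core via several cut orders; keep first
            cores.setdefault(d.core, d.substituents)
    return cores


def build_series(
    compounds: list[Compound], max_sites: int = MAX_SITES
) -> list[AnalogueSeries]:
    """Group one activity class's compounds into analogue series.

    Every core (over all rule-passing decompositions) shared by ≥2 distinct
    compounds yields a series; a compound may belong to several series.
    """
    by_core: dict[str, list[tuple[Compound, tuple[str, ...]]]] = {}
    seen_smiles: dict[str, set[str]] = {}
    for cpd in compounds:
        for core, subs in compound_cores(cpd, max_sites=max_sites).items():
            if cpd.smiles in seen_smiles.setdefault(core, set()):
                continue
            seen_smiles[core].add(cpd.smiles)
            by_core.setdefault(core, []).append((cpd, subs))
    return [
        AnalogueSeries(core=core, members=tuple(members))
        for core, members in by_core.items()
        if len(members) >= 2
    ]


def write_series_table(series: list[AnalogueSeries], path) -> None:
    """Persist series as JSON-lines: core, members, substituents, n_sites."""
    import json

    with open(path, "w") as fh:
        for s in series:
            fh.write(json.dumps({
                "core": s.core,
                "n_sites": len(s.members[0][1]),
                "members": [
                    {"smiles": c.smiles, "class_id": c.class_id, "pki": c.pki,
                     "substituents": list(subs)}
                    for c, subs in s.members
                ],
            }) + "\n")
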