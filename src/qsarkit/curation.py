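"""Structure curation: anomaly checkers, standardizers (built-in and
custom reaction-SMARTS), duplicate and scaffold analysis, and the
blood–brain-barrier curation recipe as a preset pipeline.

The ten checkers and seventeen built-in standardizers mirror the
canonical curation vocabulary of desktop curation tools: flagging
mixtures, unusual valences, charged or isotopically labelled atoms,
exotic elements and aromaticity problems; rewriting salts, nitro/azide/
diazo groups and covalent metal bonds into a single chosen convention.

Standardizer order matters: e.g. removing monoatomic fragments before
converting covalent metal bonds to ionic ones yields a different product
than the reverse order. Each rule is individually applied to a fixed
point (re-applied until the structure stops changing).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdChemReactions
from rdkit.Chem.Scaffolds import MurckoScaffold

from . import molio
from .errors import ConfigurationError, RuleError
from .molio import MoleculeTable

CHECKERS = (
    "multiple_structures",
    "unusual_valence",
    "covalent_ionic_bond",
    "total_charge",
    "isotope",
    "charged_atom",
    "no_carbon",
    "nonstandard_atom_set",
    "aromaticity",
    "radical_atom",
)

STANDARD_ATOM_SET = {"H", "B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}

#: Alkali / alkaline-earth metals whose single bonds to electronegative
#: atoms are treated as miswritten ionic bonds.
_IONIC_METALS = {"Li", "Na", "K", "Rb", "Cs", "Mg", "Ca", "Sr", "Ba"}
_ELECTRONEGATIVE = {"N", "O", "F", "S", "Cl", "Br", "I"}

# Allowed valences per neutral element; formal charge shifts the allowed
# set (N+ gains one, O- loses one, C loses |charge|, B- gains one).
_ALLOWED_VALENCE = {
    "H": {1},
    "B": {3},
    "C": {4},
    "N": {3},
    "O": {2},
    "P": {3, 5},
    "S": {2, 4, 6},
    "F": {1},
    "Cl": {1, 3, 5, 7},
    "Br": {1, 3, 5, 7},
    "I": {1, 3, 5, 7},
}


def _allowed_valences(symbol: str, charge: int):
    base = _ALLOWED_VALENCE.get(symbol)
    if base is None:
        return None
    if charge == 0:
        return base
    if symbol in ("N", "P", "O", "S", "F", "Cl", "Br", "I"):
        return {v + charge for v in base if v + charge > 0}
    if symbol == "C":
        return {v - abs(charge) for v in base if v - abs(charge) > 0}
    if symbol == "B":
        return {v + abs(charge) for v in base}
    return base


@dataclass
class CheckReport:
    """Per-molecule anomaly flags; one set of checker ids per record."""

    flags: list[set]
    checkers: tuple

    def __len__(self):
        return len(self.flags)

    def flagged(self, checker: str) -> list[int]:
        """Indices of molecules carrying ``checker``."""
        return [i for i, f in enumerate(self.flags) if checker in f]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{c: (c in f) for c in self.checkers} for f in self.flags]
        )


def _atom_valence(atom) -> int:
    # Bond-order sum (kekulized orders) plus attached hydrogens.
    return int(round(sum(b.GetBondTypeAsDouble() for b in atom.GetBonds()))) + atom.GetTotalNumHs()


def _check_one(mol: Chem.Mol, checkers) -> set:
    flags = set()
    frags = Chem.GetMolFrags(mol)
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]

    if "multiple_structures" in checkers and len(frags) > 1:
        flags.add("multiple_structures")
    if "total_charge" in checkers and Chem.GetFormalCharge(mol) != 0:
        flags.add("total_charge")
    if "isotope" in checkers and any(a.GetIsotope() != 0 for a in mol.GetAtoms()):
        flags.add("isotope")
    if "charged_atom" in checkers and any(a.GetFormalCharge() != 0 for a in mol.GetAtoms()):
        flags.add("charged_atom")
    if "no_carbon" in checkers and "C" not in symbols:
        flags.add("no_carbon")
    if "nonstandard_atom_set" in checkers and any(
        s not in STANDARD_ATOM_SET for s in symbols
    ):
        flags.add("nonstandard_atom_set")
    if "radical_atom" in checkers and any(
        a.GetNumRadicalElectrons() > 0 for a in mol.GetAtoms()
    ):
        flags.add("radical_atom")
    if "covalent_ionic_bond" in checkers:
        for bond in mol.GetBonds():
            a, b = bond.GetBeginAtom(), bond.GetEndAtom()
            pair = {a.GetSymbol(), b.GetSymbol()}
            if (
                bond.GetBondType() == Chem.BondType.SINGLE
                and pair & _IONIC_METALS
                and pair & _ELECTRONEGATIVE
            ):
                flags.add("covalent_ionic_bond")
                break
    if "unusual_valence" in checkers:
        try:
            kek = molio.kekulize(mol)
        except Exception:
            kek = mol
        for atom in kek.GetAtoms():
            allowed = _allowed_valences(atom.GetSymbol(), atom.GetFormalCharge())
            if allowed is None:
                continue
            # An unfilled valence also shows up here when the parser has
            # booked it as radical electrons; both flags may fire.
            if _atom_valence(atom) not in allowed:
                flags.add("unusual_valence")
                break
    if "aromaticity" in checkers:
        if mol.HasProp("_kekulize_failed"):
            flags.add("aromaticity")
        else:
            try:
                molio.kekulize(mol)
            except Exception:
                flags.add("aromaticity")
    return flags


def check_structures(table: MoleculeTable, checkers=None) -> CheckReport:
    """Apply the enabled checkers to every molecule of the table."""
    if checkers is None:
        checkers = CHECKERS
    checkers = tuple(checkers)
    unknown = set(checkers) - set(CHECKERS)
    if unknown:
        raise ConfigurationError(f"unknown checkers: {sorted(unknown)}")
    return CheckReport([_check_one(m, checkers) for m in table.mols], checkers)


# ---------------------------------------------------------------------------
# Standardizers
# ---------------------------------------------------------------------------

_LENIENT = molio._LENIENT_OPS


def _lenient_sanitize(mol: Chem.Mol) -> Chem.Mol:
    mol.UpdatePropertyCache(strict=False)
    Chem.SanitizeMol(mol, _LENIENT, catchErrors=True)
    return mol


def _std_covalent_to_ionic(mol):
    work = Chem.RWMol(mol)
    changed = True
    while changed:
        changed = False
        for bond in work.GetBonds():
            a, b = bond.GetBeginAtom(), bond.GetEndAtom()
            if bond.GetBondType() != Chem.BondType.SINGLE:
                continue
            if a.GetSymbol() in _IONIC_METALS and b.GetSymbol() in _ELECTRONEGATIVE:
                metal, other = a, b
            elif b.GetSymbol() in _IONIC_METALS and a.GetSymbol() in _ELECTRONEGATIVE:
                metal, other = b, a
            else:
                continue
            work.RemoveBond(metal.GetIdx(), other.GetIdx())
            metal.SetFormalCharge(metal.GetFormalCharge() + 1)
            other.SetFormalCharge(other.GetFormalCharge() - 1)
            changed = True
            break
    return _lenient_sanitize(work.GetMol())


def _std_quaternary_nitrogen(mol):
    work = Chem.RWMol(mol)
    for atom in work.GetAtoms():
        if (
            atom.GetSymbol() == "N"
            and atom.GetFormalCharge() == 0
            and atom.GetDegree() == 4
            and all(b.GetBondType() == Chem.BondType.SINGLE for b in atom.GetBonds())
        ):
            atom.SetFormalCharge(1)
    return _lenient_sanitize(work.GetMol())


def _std_remove_exceeding_h(mol):
    work = Chem.RWMol(mol)
    for atom in work.GetAtoms():
        allowed = _allowed_valences(atom.GetSymbol(), atom.GetFormalCharge())
        if not allowed:
            continue
        vmax = max(allowed)
        excess = _atom_valence(atom) - vmax
        if excess > 0 and atom.GetNumExplicitHs() > 0:
            atom.SetNumExplicitHs(max(0, atom.GetNumExplicitHs() - excess))
    return _lenient_sanitize(work.GetMol())


def _std_add_missing_h(mol):
    work = Chem.RWMol(mol)
    for atom in work.GetAtoms():
        allowed = _allowed_valences(atom.GetSymbol(), atom.GetFormalCharge())
        if not allowed or atom.GetIsAromatic():
            continue
        val = _atom_valence(atom)
        targets = sorted(v for v in allowed if v >= val)
        if targets and targets[0] > val and atom.GetNumRadicalElectrons() == 0:
            atom.SetNumExplicitHs(atom.GetNumExplicitHs() + targets[0] - val)
            atom.SetNoImplicit(False)
    return _lenient_sanitize(work.GetMol())


def _fragments(mol):
    return Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)


def _combine(frags):
    out = frags[0]
    for f in frags[1:]:
        out = Chem.CombineMols(out, f)
    return _lenient_sanitize(Chem.RWMol(out).GetMol())


def _std_remove_monoatomic(mol):
    frags = _fragments(mol)
    keep = [f for f in frags if f.GetNumHeavyAtoms() > 1]
    if not keep:  # nothing left: keep the molecule unchanged
        return mol
    return _combine(keep)


def _std_biggest_fragment(mol):
    frags = _fragments(mol)
    if len(frags) <= 1:
        return mol
    best = max(frags, key=lambda f: f.GetNumHeavyAtoms())
    return _lenient_sanitize(Chem.RWMol(best).GetMol())


def _std_clear_isotopes(mol):
    work = Chem.RWMol(mol)
    for atom in work.GetAtoms():
        atom.SetIsotope(0)
    return _lenient_sanitize(work.GetMol())


def _std_clear_chirality(mol):
    work = Chem.RWMol(mol)
    Chem.RemoveStereochemistry(work)
    return work.GetMol()


def _std_clear_bond_direction(mol):
    work = Chem.RWMol(mol)
    for bond in work.GetBonds():
        bond.SetBondDir(Chem.BondDir.NONE)
    return work.GetMol()


def _std_remove_radicals(mol):
    work = Chem.RWMol(mol)
    for atom in work.GetAtoms():
        n = atom.GetNumRadicalElectrons()
        if n > 0:
            atom.SetNumRadicalElectrons(0)
            atom.SetNumExplicitHs(atom.GetNumExplicitHs() + n)
    return _lenient_sanitize(work.GetMol())


def _std_remove_hydrogens(mol):
    return Chem.RemoveHs(Chem.Mol(mol), sanitize=False)


_NEUTRALIZE = None


def _std_neutralize_atoms(mol):
    # Protonate/deprotonate charged N/O/S atoms back to neutral where a
    # hydrogen shuffle suffices (classic neutralization transform).
    global _NEUTRALIZE
    if _NEUTRALIZE is None:
        _NEUTRALIZE = Chem.MolFromSmarts(
            "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"
        )
    work = Chem.RWMol(mol)
    for (idx,) in work.GetSubstructMatches(_NEUTRALIZE):
        atom = work.GetAtomWithIdx(idx)
        chg = atom.GetFormalCharge()
        h = atom.GetTotalNumHs()
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(h - chg)
        atom.SetNoImplicit(True)
    return _lenient_sanitize(work.GetMol())


def _std_neutralize_molecule(mol):
    if Chem.GetFormalCharge(mol) == 0:
        return mol
    return _std_neutralize_atoms(mol)


def _smirks_standardizer(smirks):
    try:
        rxn = rdChemReactions.ReactionFromSmarts(smirks)
    except Exception as exc:
        raise RuleError(f"invalid reaction SMARTS {smirks!r}: {exc}") from exc
    if rxn is None or rxn.GetNumReactantTemplates() != 1:
        raise RuleError(f"invalid reaction SMARTS {smirks!r}: need one reactant")

    def apply(mol):
        products = rxn.RunReactants((mol,))
        if not products:
            return mol
        out = products[0][0]
        return _lenient_sanitize(out)

    return apply


# Built-in nitro/azide/diazo conventions, written as reaction SMARTS.
_BUILTIN_SMIRKS = {
    "standardize_nitro_neutral": "[N+1:1](=[O:2])[O-:3]>>[N+0:1](=[O:2])=[O+0:3]",
    "standardize_nitro_charged": "[N;D3;+0:1](=[O:2])=[O;D1:3]>>[N+1:1](=[O:2])[O-1:3]",
    "standardize_azide": "[N;X2:1]=[N;X2;+0:2]#[N;X1:3]>>[N:1]=[N+1:2]=[N-1:3]",
    "standardize_diazo": "[C;X3:1]=[N;X2;+0:2]#[N;X1:3]>>[C:1]=[N+1:2]=[N-1:3]",
}

STANDARDIZERS = {
    "covalent_to_ionic": _std_covalent_to_ionic,
    "add_charge_to_quaternary_nitrogen": _std_quaternary_nitrogen,
    "remove_exceeding_hydrogens": _std_remove_exceeding_h,
    "add_missing_hydrogens": _std_add_missing_h,
    "remove_monoatomic_fragments": _std_remove_monoatomic,
    "retain_biggest_fragment": _std_biggest_fragment,
    "standardize_nitro_neutral": None,
    "standardize_nitro_charged": None,
    "standardize_azide": None,
    "standardize_diazo": None,
    "clear_isotopes": _std_clear_isotopes,
    "clear_chirality": _std_clear_chirality,
    "clear_bond_direction": _std_clear_bond_direction,
    "remove_radicals": _std_remove_radicals,
    "remove_hydrogens": _std_remove_hydrogens,
    "neutralize_atoms": _std_neutralize_atoms,
    "neutralize_molecule": _std_neutralize_molecule,
}
for _name, _smirks in _BUILTIN_SMIRKS.items():
    STANDARDIZERS[_name] = _smirks_standardizer(_smirks)


@dataclass
class StandardizerRule:
    """A built-in rule (by id) or a custom reactant>>product transform."""

    kind: str
    pattern: str | None = None

    def build(self):
        if self.kind == "custom":
            if not self.pattern:
                raise RuleError("custom standardizer requires a pattern")
            return _smirks_standardizer(self.pattern)
        fn = STANDARDIZERS.get(self.kind)
        if fn is None:
            raise ConfigurationError(f"unknown standardizer: {self.kind!r}")
        return fn


_MAX_FIXPOINT = 50


def _apply_rule_fixpoint(mol, fn):
    """Apply one rule until the canonical SMILES stops changing."""
    seen = Chem.MolToSmiles(mol)
    for _ in range(_MAX_FIXPOINT):
        new = fn(mol)
        key = Chem.MolToSmiles(new)
        if key == seen:
            return new
        mol, seen = new, key
    return mol


def apply_standardizers(table: MoleculeTable, rules) -> MoleculeTable:
    """Apply an ordered rule list to every molecule; each rule is run to
    its per-rule fixed point before the next one starts. Order across
    different rules is significant."""
    fns = []
    for rule in rules:
        if isinstance(rule, str):
            rule = StandardizerRule(rule)
        fns.append(rule.build())
    out = []
    for mol in table.mols:
        for fn in fns:
            mol = _apply_rule_fixpoint(mol, fn)
        out.append(mol)
    return MoleculeTable(out, table.data.copy())


# ---------------------------------------------------------------------------
# Duplicate and scaffold analysis
# ---------------------------------------------------------------------------


@dataclass
class DuplicateGroups:
    """Disjoint groups (index lists, each of size >= 2) of molecules
    sharing a canonical key under the chosen ignore-options."""

    groups: list[list[int]]
    options: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.groups)


def find_duplicates(table: MoleculeTable, **options) -> DuplicateGroups:
    """Group molecules into canonical-key equivalence classes of size >= 2.

    Options are forwarded to :func:`qsarkit.molio.canonical_key`
    (``ignore_stereo``, ``ignore_charge``, ``ignore_isotope``,
    ``ignore_h_count``).
    """
    buckets: dict[str, list[int]] = {}
    for i, mol in enumerate(table.mols):
        buckets.setdefault(molio.canonical_key(mol, **options), []).append(i)
    groups = [idx for idx in buckets.values() if len(idx) >= 2]
    groups.sort(key=lambda g: g[0])
    return DuplicateGroups(groups, dict(options))


def resolve_duplicates(
    table: MoleculeTable, groups: DuplicateGroups, endpoint: str
) -> tuple[MoleculeTable, list[dict]]:
    """Keep one molecule per endpoint-consistent duplicate group; drop
    entire groups whose members disagree on the endpoint (a missing
    endpoint value counts as disagreement)."""
    if endpoint not in table.columns:
        raise ConfigurationError(f"no endpoint column {endpoint!r}")
    values = table.data[endpoint]
    removed: set[int] = set()
    log = []
    for group in groups.groups:
        vals = [values.iloc[i] for i in group]
        missing = any(pd.isna(v) or v == "" for v in vals)
        if missing or len(set(vals)) > 1:
            removed.update(group)
            log.append({"group": group, "action": "removed_all",
                        "reason": "endpoint_missing" if missing else "endpoint_conflict"})
        else:
            removed.update(group[1:])
            log.append({"group": group, "action": "kept_first", "kept": group[0]})
    keep = [i for i in range(len(table)) if i not in removed]
    return table.subset(keep), log


def scaffold_analysis(table: MoleculeTable) -> tuple[Counter, int]:
    """Bemis–Murcko framework census.

    Returns (scaffold-SMILES -> molecule count, number of ring-free
    molecules). Ring-free molecules have no framework and are counted
    separately, not as scaffolds.
    """
    counts: Counter = Counter()
    ring_free = 0
    for mol in table.mols:
        if mol.GetRingInfo().NumRings() == 0:
            ring_free += 1
            continue
        scaffold = MurckoScaffold.GetScaffoldForMol(mol)
        counts[Chem.MolToSmiles(scaffold)] += 1
    return counts, ring_free


# ---------------------------------------------------------------------------
# BBB curation preset
# ---------------------------------------------------------------------------


def curate_bbb(table: MoleculeTable, endpoint: str = "BBB"):
    """Curation recipe for the blood–brain-barrier dataset.

    In order: kekulize every structure; remove molecules with multiple
    (disconnected) structures; remove unusual valences; remove
    single-heavy-atom molecules; then resolve duplicates with
    stereochemistry ignored (conflicting endpoint groups dropped
    entirely, one representative kept otherwise).

    Returns ``(curated_table, log)`` where the log lists per-step removal
    counts and indices (relative to the input table).
    """
    log = []
    mols = []
    for mol in table.mols:
        try:
            mols.append(molio.kekulize(mol))
        except Exception:
            mols.append(mol)  # left aromatic; flagged below if broken
    work = MoleculeTable(mols, table.data.copy())
    orig_idx = list(range(len(work)))

    def drop(indices, reason):
        nonlocal work, orig_idx
        indices = set(indices)
        if indices:
            log.append({"step": reason, "removed": sorted(orig_idx[i] for i in indices),
                        "n_removed": len(indices)})
        keep = [i for i in range(len(work)) if i not in indices]
        orig_idx = [orig_idx[i] for i in keep]
        work = work.subset(keep)

    report = check_structures(work, ("multiple_structures", "unusual_valence"))
    drop(report.flagged("multiple_structures"), "multiple_structures")
    report = check_structures(work, ("unusual_valence",))
    drop(report.flagged("unusual_valence"), "unusual_valence")
    drop([i for i, m in enumerate(work.mols) if m.GetNumHeavyAtoms() == 1],
         "single_atom")

    groups = find_duplicates(work, ignore_stereo=True)
    before = len(work)
    work, dup_log = resolve_duplicates(work, groups, endpoint)
    if before != len(work):
        log.append({"step": "duplicates", "n_removed": before - len(work),
                    "detail": dup_log})
    return work, log
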