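"""Molecule input/output and graph-level primitives.

Molecules are held as RDKit ``Mol`` objects — the standard in-memory
molecular graph (atoms with element, formal charge, isotope, H count and
aromatic flag; bonds with order, aromatic flag and stereo annotation).
A :class:`MoleculeTable` pairs an ordered list of molecules with their
property columns, preserving input-file order.

Parsing is lenient where chemistry tools disagree: entries that fail
RDKit's full sanitization (e.g. the neutral pentavalent nitro form
``O=N(=O)R``, or aromatic rings with no Kekulé assignment) are retained
with a partial sanitization so the curation checkers can flag them,
instead of being silently dropped.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdmolops

from .errors import AromaticityError, EmptyInputError, ParseError

RDLogger.DisableLog("rdApp.*")

#: Sentinel for topologically unreachable atom pairs (disconnected
#: fragments); larger than any real bond-count distance.
UNREACHABLE = 10**6

# Sanitization with the valence check (PROPERTIES) and functional-group
# normalization (CLEANUP) disabled: keeps deliberately unusual valences
# and the neutral -N(=O)=O nitro representation intact.
_LENIENT_OPS = (
    Chem.SanitizeFlags.SANITIZE_ALL
    ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
    ^ Chem.SanitizeFlags.SANITIZE_CLEANUP
)
_LENIENT_NO_KEKULE = _LENIENT_OPS ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE


@dataclass
class ParseFailure:
    line: int
    text: str
    message: str


@dataclass
class MoleculeTable:
    """Ordered molecules plus aligned property columns.

    ``data`` has one row per molecule, in input order; extra SDF data
    fields or SMILES-line columns become columns of ``data``.
    """

    mols: list
    data: pd.DataFrame
    failures: list[ParseFailure] = field(default_factory=list)

    def __post_init__(self):
        if len(self.mols) != len(self.data):
            raise ValueError("mols and data must have equal length")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.mols)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, indices) -> "MoleculeTable":
        indices = list(indices)
        return MoleculeTable(
            [self.mols[i] for i in indices],
            self.data.iloc[indices].reset_index(drop=True),
        )

    def smiles(self) -> list[str]:
        return [to_smiles(m) for m in self.mols]

    @classmethod
    def from_smiles(cls, smiles, names=None, **columns) -> "MoleculeTable":
        mols = [parse_smiles(s) for s in smiles]
        data = {"name": list(names) if names is not None else [""] * len(mols)}
        data.update({k: list(v) for k, v in columns.items()})
        return cls(mols, pd.DataFrame(data))


def parse_smiles(text: str) -> Chem.Mol:
    """Parse one SMILES, falling back to partial sanitization.

    Raises :class:`ParseError` if the string is not syntactically valid
    SMILES at all. Molecules that parse but fail full sanitization carry
    the boolean property ``_sanitize_incomplete`` (and ``_kekulize_failed``
    when the failure was a missing Kekulé assignment) for the checkers.
    """
    mol = Chem.MolFromSmiles(text)
    if mol is not None:
        return mol
    mol = Chem.MolFromSmiles(text, sanitize=False)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {text!r}")
    mol.UpdatePropertyCache(strict=False)
    err = Chem.SanitizeMol(mol, _LENIENT_OPS, catchErrors=True)
    if err != Chem.SanitizeFlags.SANITIZE_NONE:
        mol = Chem.MolFromSmiles(text, sanitize=False)
        mol.UpdatePropertyCache(strict=False)
        err2 = Chem.SanitizeMol(mol, _LENIENT_NO_KEKULE, catchErrors=True)
        if err2 != Chem.SanitizeFlags.SANITIZE_NONE:
            raise ParseError(f"unparseable SMILES: {text!r}")
        if err == Chem.SanitizeFlags.SANITIZE_KEKULIZE:
            mol.SetBoolProp("_kekulize_failed", True)
    mol.SetBoolProp("_sanitize_incomplete", True)
    return mol


def to_smiles(mol: Chem.Mol, isomeric: bool = True) -> str:
    return Chem.MolToSmiles(mol, isomericSmiles=isomeric)


def read_molecules(path, fmt: str = "smiles") -> MoleculeTable:
    """Read a SMILES (one molecule per line, tab-separated name/extra
    columns) or MDL SDF V2000 file into a :class:`MoleculeTable`.

    Unparseable entries are recorded in ``table.failures`` with their
    line (SMILES) or record (SDF) number, never silently dropped.
    """
    if fmt not in ("smiles", "sdf"):
        raise ValueError(f"unknown format: {fmt!r}")
    try:
        raw = open(path).read()
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc

    mols, rows, failures = [], [], []
    if fmt == "smiles":
        for lineno, line in enumerate(raw.splitlines(), start=1):
            line = line.rstrip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                mol = parse_smiles(fields[0])
            except ParseError as exc:
                failures.append(ParseFailure(lineno, line, str(exc)))
                continue
            row = {"name": fields[1] if len(fields) > 1 else ""}
            for i, extra in enumerate(fields[2:], start=1):
                row[f"field{i}"] = extra
            mols.append(mol)
            rows.append(row)
    else:
        supplier = Chem.SDMolSupplier(str(path), sanitize=False)
        for recno, mol in enumerate(supplier, start=1):
            if mol is None:
                failures.append(ParseFailure(recno, "", f"unreadable SDF record {recno}"))
                continue
            mol.UpdatePropertyCache(strict=False)
            err = Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_ALL,
                                   catchErrors=True)
            if err != Chem.SanitizeFlags.SANITIZE_NONE:
                err = Chem.SanitizeMol(mol, _LENIENT_NO_KEKULE, catchErrors=True)
                if err != Chem.SanitizeFlags.SANITIZE_NONE:
                    failures.append(
                        ParseFailure(recno, "", f"unsanitizable SDF record {recno}")
                    )
                    continue
                mol.SetBoolProp("_sanitize_incomplete", True)
            row = {"name": mol.GetProp("_Name") if mol.HasProp("_Name") else ""}
            row.update(mol.GetPropsAsDict(includePrivate=False))
            mols.append(mol)
            rows.append(row)

    if not mols:
        raise EmptyInputError(f"no valid molecules in {path}")
    data = pd.DataFrame(rows).fillna("")
    return MoleculeTable(mols, data, failures)


def write_molecules(table: MoleculeTable, path, fmt: str = "smiles") -> None:
    """Write a table back out in the same dialects it is read from."""
    if fmt == "smiles":
        with open(path, "w") as fh:
            extra_cols = [c for c in table.columns if c != "name"]
            for mol, (_, row) in zip(table.mols, table.data.iterrows()):
                fields = [to_smiles(mol), str(row.get("name", ""))]
                fields += [str(row[c]) for c in extra_cols]
                fh.write("\t".join(fields).rstrip("\t") + "\n")
    elif fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        for mol, (_, row) in zip(table.mols, table.data.iterrows()):
            out = Chem.Mol(mol)
            out.SetProp("_Name", str(row.get("name", "")))
            for col in table.columns:
                if col != "name":
                    out.SetProp(col, str(row[col]))
            writer.write(out)
        writer.close()
    else:
        raise ValueError(f"unknown format: {fmt!r}")


def kekulize(mol: Chem.Mol) -> Chem.Mol:
    """Return a copy with aromatic flags replaced by alternating
    single/double bonds. Idempotent; raises :class:`AromaticityError`
    when no valid Kekulé assignment exists."""
    if mol.HasProp("_kekulize_failed"):
        raise AromaticityError(f"no Kekulé assignment for {Chem.MolToSmiles(mol)}")
    out = Chem.Mol(mol)
    try:
        Chem.Kekulize(out, clearAromaticFlags=True)
    except (Chem.KekulizeException, Chem.AtomKekulizeException) as exc:
        raise AromaticityError(str(exc)) from exc
    return out


def aromatize(mol: Chem.Mol) -> Chem.Mol:
    """Re-perceive aromaticity (inverse direction of :func:`kekulize`)."""
    out = Chem.Mol(mol)
    Chem.SetAromaticity(out)
    return out


def topological_distance_matrix(mol: Chem.Mol) -> np.ndarray:
    """Heavy-atom shortest-path lengths in bonds.

    Symmetric with zero diagonal; pairs in different fragments get the
    :data:`UNREACHABLE` sentinel.
    """
    heavy = Chem.RemoveHs(Chem.Mol(mol), sanitize=False)
    dm = rdmolops.GetDistanceMatrix(heavy)
    out = np.where(dm >= 1e7, UNREACHABLE, dm).astype(np.int64)
    return out


def canonical_key(
    mol: Chem.Mol,
    ignore_stereo: bool = False,
    ignore_charge: bool = False,
    ignore_isotope: bool = False,
    ignore_h_count: bool = False,
) -> str:
    """Canonical SMILES after applying the requested identity-blurring
    edits; two molecules get equal keys iff they are identical under the
    enabled ignore-options. Invariant to atom input order."""
    work = Chem.RWMol(mol)
    if ignore_stereo:
        Chem.RemoveStereochemistry(work)
        for bond in work.GetBonds():
            bond.SetBondDir(Chem.BondDir.NONE)
    if ignore_isotope:
        for atom in work.GetAtoms():
            atom.SetIsotope(0)
    if ignore_charge:
        for atom in work.GetAtoms():
            atom.SetFormalCharge(0)
    if ignore_charge or ignore_h_count:
        for atom in work.GetAtoms():
            atom.SetNumExplicitHs(0)
            atom.SetNoImplicit(False)
        work.UpdatePropertyCache(strict=False)
    out = work.GetMol()
    try:
        return Chem.MolToSmiles(out)
    except Exception:
        out.UpdatePropertyCache(strict=False)
        return Chem.MolToSmiles(out, canonical=True)


def heavy_atom_count(mol: Chem.Mol) -> int:
    return mol.GetNumHeavyAtoms()


def copy_mol(mol: Chem.Mol) -> Chem.Mol:
    return copy.deepcopy(mol)
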