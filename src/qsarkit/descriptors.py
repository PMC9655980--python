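"""The nine molecular descriptors of the blood–brain-barrier KNN model.

* ``Mp`` — mean atomic polarizability scaled on carbon, hydrogens
  included: a pure composition (0D) descriptor.
* ``nN`` — nitrogen atom count.
* ``MPC07`` — molecular path count of order 7: the number of simple
  paths of exactly 7 bonds in the heavy-atom graph, reported as
  ``ln(1 + count)`` so the empty case is 0.
* ``NssssN+`` — number of quaternary ammonium cations (E-state atom
  type: N, formal charge +1, four single bonds).
* ``SHED_DL`` / ``SHED_AN`` — Shannon-entropy descriptors of the
  topological-distance distribution between pharmacophore point pairs
  (donor–lipophilic, acceptor–negative): ``exp(H)`` over occupied
  distance bins 1..20, equal to 1 when all pairs share one distance and
  approaching 20 for a uniform spread; 0 when no pair exists.
* ``F09[C-C]`` — count of carbon pairs at topological distance 9.
* ``TPSA(Tot)`` — Ertl fragment-contribution topological polar surface
  area including S/P terms (Å²).
* ``MLOGP2`` — square of the Moriguchi 13-parameter octanol–water
  logP regression (``MLOGP`` is exposed as well).

Pharmacophore typing rules and the polarizability table live in
``qsarkit/data/*.json`` so SHED and Mp values are auditable and
swappable.
"""

from __future__ import annotations

import json
import math
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as _RDDescriptors

from . import molio
from .errors import ConfigurationError, MissingValueError
from .molio import UNREACHABLE, MoleculeTable

SHED_DMAX = 20
PPP_LABELS = ("D", "A", "P", "N", "L")


@lru_cache(maxsize=1)
def load_polarizability_table() -> dict:
    raw = json.loads(
        resources.files("qsarkit").joinpath("data", "polarizability.json").read_text()
    )
    return {"values": raw["values"], "reference": raw["reference_element"]}


@lru_cache(maxsize=1)
def load_ppp_rules() -> dict:
    return json.loads(
        resources.files("qsarkit").joinpath("data", "ppp_rules.json").read_text()
    )


def calc_Mp(mol: Chem.Mol, table: dict | None = None) -> float:
    """Mean atomic polarizability scaled on the carbon value, averaged
    over all atoms including implicit hydrogens."""
    if table is None:
        table = load_polarizability_table()
    values, ref = table["values"], table["reference"]
    p_ref = values[ref]
    total, n = 0.0, 0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in values:
            raise MissingValueError(f"no polarizability for element {sym!r}")
        nh = atom.GetTotalNumHs()
        total += values[sym] / p_ref + nh * values["H"] / p_ref
        n += 1 + nh
    if n == 0:
        raise MissingValueError("empty molecule")
    return total / n


def calc_nN(mol: Chem.Mol) -> int:
    """Number of nitrogen atoms, regardless of charge or aromaticity."""
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 7)


def _heavy_adjacency(mol: Chem.Mol) -> list[list[int]]:
    heavy = Chem.RemoveHs(Chem.Mol(mol), sanitize=False)
    adj = [[] for _ in range(heavy.GetNumAtoms())]
    for bond in heavy.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i].append(j)
        adj[j].append(i)
    return adj


def count_simple_paths(mol: Chem.Mol, length: int) -> int:
    """Number of simple paths of exactly ``length`` bonds in the
    heavy-atom graph, each undirected path counted once."""
    adj = _heavy_adjacency(mol)
    n = len(adj)
    total = 0
    visited = [False] * n

    def dfs(node, remaining):
        nonlocal total
        if remaining == 0:
            total += 1
            return
        visited[node] = True
        for nxt in adj[node]:
            if not visited[nxt]:
                dfs(nxt, remaining - 1)
        visited[node] = False

    for start in range(n):
        dfs(start, length)
    return total // 2


def calc_MPC07(mol: Chem.Mol) -> float:
    """ln(1 + number of simple 7-bond paths)."""
    return math.log1p(count_simple_paths(mol, 7))


def calc_NssssNplus(mol: Chem.Mol) -> int:
    """Quaternary ammonium cation count: N with formal charge +1 and
    exactly four single bonds."""
    count = 0
    for atom in mol.GetAtoms():
        if (
            atom.GetAtomicNum() == 7
            and atom.GetFormalCharge() == 1
            and atom.GetDegree() == 4
            and atom.GetTotalNumHs() == 0
            and all(b.GetBondType() == Chem.BondType.SINGLE for b in atom.GetBonds())
        ):
            count += 1
    return count


def assign_ppp(mol: Chem.Mol, rules: dict | None = None) -> list[set]:
    """Per-heavy-atom pharmacophore labels from the configured SMARTS
    rule set. Lipophilic (L) is derived last: carbon/halogen atoms with
    no neighbour labelled D, A or N."""
    if rules is None:
        rules = load_ppp_rules()
    heavy = Chem.RemoveHs(Chem.Mol(mol), sanitize=False)
    n = heavy.GetNumAtoms()
    labels: list[set] = [set() for _ in range(n)]

    def match_atoms(patterns):
        hits = set()
        for sma in patterns:
            patt = Chem.MolFromSmarts(sma)
            if patt is None:
                raise ConfigurationError(f"bad PPP SMARTS: {sma!r}")
            for match in heavy.GetSubstructMatches(patt):
                hits.update(match)
        return hits

    for idx in match_atoms(rules["donor"]):
        labels[idx].add("D")
    for idx in match_atoms(rules["acceptor"]):
        labels[idx].add("A")
    for idx in match_atoms(rules["positive"]):
        labels[idx].add("P")
    # negative: whole-group patterns; label the N/O members of the match
    for idx in match_atoms(rules["negative"]):
        if heavy.GetAtomWithIdx(idx).GetAtomicNum() in (7, 8):
            labels[idx].add("N")

    lipo = set(rules["lipophilic_elements"])
    for atom in heavy.GetAtoms():
        if atom.GetSymbol() not in lipo:
            continue
        neighbour_polar = any(
            labels[nb.GetIdx()] & {"D", "A", "N"} for nb in atom.GetNeighbors()
        )
        if not neighbour_polar:
            labels[atom.GetIdx()].add("L")
    return labels


def calc_SHED(
    mol: Chem.Mol,
    pair: tuple[str, str],
    dmax: int = SHED_DMAX,
    ppp: list[set] | None = None,
) -> float:
    """exp(Shannon entropy) of the topological-distance distribution
    between atoms labelled ``pair[0]`` and ``pair[1]``.

    Distances are capped into bin ``dmax``; unreachable pairs are
    ignored; 0.0 when no labelled pair exists.
    """
    x_label, y_label = pair
    if ppp is None:
        ppp = assign_ppp(mol)
    dm = molio.topological_distance_matrix(mol)
    xs = [i for i, lab in enumerate(ppp) if x_label in lab]
    ys = [i for i, lab in enumerate(ppp) if y_label in lab]
    counts = np.zeros(dmax, dtype=float)
    seen = set()
    for i in xs:
        for j in ys:
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            d = dm[i, j]
            if d >= UNREACHABLE:
                continue
            counts[min(int(d), dmax) - 1] += 1
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    entropy = -float(np.sum(p * np.log(p)))
    return math.exp(entropy)


def calc_SHED_DL(mol: Chem.Mol) -> float:
    return calc_SHED(mol, ("D", "L"))


def calc_SHED_AN(mol: Chem.Mol) -> float:
    return calc_SHED(mol, ("A", "N"))


def calc_F09_CC(mol: Chem.Mol) -> int:
    """Number of unordered carbon–carbon pairs at topological distance 9."""
    heavy = Chem.RemoveHs(Chem.Mol(mol), sanitize=False)
    dm = molio.topological_distance_matrix(heavy)
    carbons = [a.GetIdx() for a in heavy.GetAtoms() if a.GetAtomicNum() == 6]
    count = 0
    for ii, i in enumerate(carbons):
        for j in carbons[ii + 1:]:
            if dm[i, j] == 9:
                count += 1
    return count


def calc_TPSA(mol: Chem.Mol) -> float:
    """Topological polar surface area, Ertl fragment contributions
    including the S and P terms ("total" variant), in Å²."""
    return float(_RDDescriptors.TPSA(mol, includeSandP=True))


# ---------------------------------------------------------------------------
# Moriguchi logP
# ---------------------------------------------------------------------------

_HALOGEN_WEIGHT = {"F": 0.5, "Cl": 1.0, "Br": 1.5, "I": 2.0}


def _smarts(s):
    return Chem.MolFromSmarts(s)


_PAT_NITRO = _smarts("[#7](~[#8;D1])~[#8;D1]")
_PAT_QUAT_N = _smarts("[#7;+;X4;!$([#7]~[#8;D1])]")
_PAT_N_OXIDE = _smarts("[#7;+][#8;D1;-]")
_PAT_NCS = _smarts("[#7]=[#6]=[#16]")
_PAT_SCN = _smarts("[#16][#6]#[#7]")
_PAT_BLM = _smarts("[#7]1[#6](=[#8])[#6][#6]1")
_PAT_ALPHA_AA = _smarts("[NX3;H2,H1;!$(NC=O)][CX4][CX3](=O)[OX2H1,OX1-]")
_PAT_ARO_AMINE = _smarts("[NX3;H2,H1][c,$(C=C)]")
_PAT_ARO_ACID = _smarts("c[CX3](=O)[OX2H1,OX1-]")
_PAT_PYRIDINE_ACID = _smarts("n1ccccc1")


def moriguchi_parameters(mol: Chem.Mol) -> dict:
    """The 13 structural parameters of the Moriguchi logP regression.

    PRX, HB and POL follow documented topological heuristics (the
    original definitions are partly verbal); see docs/methods.md.
    """
    p = {}
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]

    p["CX"] = sum(
        1.0 if s == "C" else _HALOGEN_WEIGHT.get(s, 0.0) for s in symbols
    )
    p["NO"] = sum(1 for s in symbols if s in ("N", "O"))

    dm = molio.topological_distance_matrix(mol)
    no_idx = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O")]
    prx = 0
    for ii, i in enumerate(no_idx):
        for j in no_idx[ii + 1:]:
            d = dm[i, j]
            if d == 1:
                prx += 2
            elif d == 2:
                prx += 1
    p["PRX"] = prx

    # Unsaturated bonds on the kekulized graph, nitro N-O bonds excluded.
    try:
        kek = molio.kekulize(mol)
    except Exception:
        kek = mol
    nitro_atoms = set()
    for match in kek.GetSubstructMatches(_PAT_NITRO):
        nitro_atoms.update(match)
    ub = 0
    for bond in kek.GetBonds():
        if bond.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE):
            if {bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()} <= nitro_atoms:
                continue
            ub += 1
    p["UB"] = ub

    # Intramolecular hydrogen bond dummy: donor N/O-H and acceptor N/O at
    # topological distance 4 with a ring atom on the molecule (the classic
    # six-membered chelation motif, e.g. 2-nitrophenol, salicylic acid).
    donors = [a.GetIdx() for a in mol.GetAtoms()
              if a.GetSymbol() in ("N", "O") and a.GetTotalNumHs() > 0]
    acceptors = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O")]
    hb = 0
    if mol.GetRingInfo().NumRings() > 0:
        for i in donors:
            for j in acceptors:
                if i != j and dm[i, j] == 4:
                    hb = 1
                    break
            if hb:
                break
    p["HB"] = hb

    # Aromatic polar substituents: exocyclic substituent on an aromatic
    # atom that is N/O/halogen, or a carbon directly bearing N or O.
    pol = 0
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        for ring_atom, sub in ((a, b), (b, a)):
            if not ring_atom.GetIsAromatic() or sub.GetIsAromatic():
                continue
            if sub.IsInRing():
                continue
            s = sub.GetSymbol()
            if s in ("N", "O") or s in _HALOGEN_WEIGHT:
                pol += 1
            elif s == "C" and any(
                nb.GetSymbol() in ("N", "O") for nb in sub.GetNeighbors()
            ):
                pol += 1
    p["POL"] = pol

    amp = 0.0
    if mol.HasSubstructMatch(_PAT_ALPHA_AA):
        amp = 1.0
    elif mol.HasSubstructMatch(_PAT_ARO_AMINE) and mol.HasSubstructMatch(_PAT_ARO_ACID):
        amp = 0.5
    elif mol.HasSubstructMatch(_PAT_PYRIDINE_ACID) and mol.HasSubstructMatch(
        _smarts("[CX3](=O)[OX2H1,OX1-]")
    ):
        amp = 0.5
    p["AMP"] = amp

    only_ch = all(s in ("C", "H") for s in symbols)
    n_double = sum(
        1 for b in kek.GetBonds() if b.GetBondType() == Chem.BondType.DOUBLE
    )
    n_triple = sum(
        1 for b in kek.GetBonds() if b.GetBondType() == Chem.BondType.TRIPLE
    )
    aromatic = any(a.GetIsAromatic() for a in mol.GetAtoms())
    p["ALK"] = 1 if (only_ch and not aromatic and n_triple == 0 and n_double <= 1) else 0

    # Ring dummy: any ring that is not a six-membered all-aromatic-carbon
    # (benzene) ring.
    rng = 0
    for ring in mol.GetRingInfo().AtomRings():
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        benzene = len(ring) == 6 and all(
            a.GetSymbol() == "C" and a.GetIsAromatic() for a in atoms
        )
        if not benzene:
            rng = 1
            break
    p["RNG"] = rng

    if mol.HasSubstructMatch(_PAT_QUAT_N):
        p["QN"] = 1.0
    elif mol.HasSubstructMatch(_PAT_N_OXIDE) and not mol.HasSubstructMatch(_PAT_NITRO):
        p["QN"] = 0.5
    else:
        p["QN"] = 0.0

    p["NO2"] = len(mol.GetSubstructMatches(_PAT_NITRO))
    if mol.HasSubstructMatch(_PAT_NCS):
        p["NCS"] = 1.0
    elif mol.HasSubstructMatch(_PAT_SCN):
        p["NCS"] = 0.5
    else:
        p["NCS"] = 0.0
    p["BLM"] = 1 if mol.HasSubstructMatch(_PAT_BLM) else 0
    return p


#: Regression coefficients of the Moriguchi octanol–water logP model.
MORIGUCHI_COEFFICIENTS = {
    "intercept": -1.014,
    "CX": (1.244, 0.6),
    "NO": (-1.017, 0.9),
    "PRX": 0.406,
    "UB": (-0.145, 0.8),
    "HB": 0.511,
    "POL": 0.268,
    "AMP": -2.215,
    "ALK": 0.912,
    "RNG": -0.392,
    "QN": -3.684,
    "NO2": 0.474,
    "NCS": 1.582,
    "BLM": 0.773,
}


def calc_MLOGP(mol: Chem.Mol) -> float:
    """Moriguchi 13-parameter octanol–water partition coefficient."""
    params = moriguchi_parameters(mol)
    c = MORIGUCHI_COEFFICIENTS
    value = c["intercept"]
    for name, spec in c.items():
        if name == "intercept":
            continue
        if isinstance(spec, tuple):
            coef, power = spec
            value += coef * params[name] ** power
        else:
            value += spec * params[name]
    return value


def calc_MLOGP2(mol: Chem.Mol) -> float:
    return calc_MLOGP(mol) ** 2


DESCRIPTORS = {
    "Mp": calc_Mp,
    "nN": calc_nN,
    "MPC07": calc_MPC07,
    "NssssN+": calc_NssssNplus,
    "SHED_DL": calc_SHED_DL,
    "SHED_AN": calc_SHED_AN,
    "F09[C-C]": calc_F09_CC,
    "TPSA(Tot)": calc_TPSA,
    "MLOGP": calc_MLOGP,
    "MLOGP2": calc_MLOGP2,
}

#: The nine features of the descriptor-based BBB model, in its order.
M3_DESCRIPTORS = (
    "Mp", "nN", "MPC07", "NssssN+", "SHED_DL", "SHED_AN",
    "F09[C-C]", "TPSA(Tot)", "MLOGP2",
)


def calc_descriptor_matrix(table: MoleculeTable, names=None) -> pd.DataFrame:
    """Molecules × descriptors matrix; per-cell failures become NaN
    (the missing marker), never exceptions."""
    if names is None:
        names = M3_DESCRIPTORS
    unknown = [n for n in names if n not in DESCRIPTORS]
    if unknown:
        raise ConfigurationError(f"unknown descriptors: {unknown}")
    rows = []
    for mol in table.mols:
        row = {}
        for name in names:
            try:
                row[name] = float(DESCRIPTORS[name](mol))
            except Exception:
                row[name] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=list(names))


class DescriptorCalculator:
    """Transformer over molecule lists: ``transform`` returns the
    descriptor matrix as a DataFrame. Stateless (``fit`` is a no-op),
    provided for pipeline composition."""

    def __init__(self, names=M3_DESCRIPTORS):
        self.names = tuple(names)

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        if isinstance(X, MoleculeTable):
            return calc_descriptor_matrix(X, self.names)
        table = MoleculeTable(list(X), pd.DataFrame({"name": [""] * len(X)}))
        return calc_descriptor_matrix(table, self.names)

    def get_params(self, deep=True):
        return {"names": self.names}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, tuple(v) if k == "names" else v)
        return self
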