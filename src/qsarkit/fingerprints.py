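"""MACCS-166 and extended-connectivity (Morgan/ECFP) bit fingerprints,
plus the Jaccard–Tanimoto distance between them.

MACCS uses the public 166-key SMARTS dictionary (key id *i*, 1-based,
maps to vector index *i*-1). ECFP enumerates circular atom environments
up to the configured radius with standard atom invariants and folds the
fragment hashes modulo the chosen length; identical environments are
counted once (binary fingerprint).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator


@dataclass
class BitFingerprint:
    bits: np.ndarray
    kind: str  # "maccs166" | "ecfp"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.kind == "maccs166" and self.bits.size != 166:
            raise ValueError("MACCS fingerprint must have 166 bits")
        if self.kind == "ecfp" and self.bits.size != self.params.get("length"):
            raise ValueError("ECFP length does not match params")

    def popcount(self) -> int:
        return int(self.bits.sum())

    def to_hex(self) -> str:
        return np.packbits(self.bits.astype(np.uint8)).tobytes().hex()


def maccs166(mol: Chem.Mol) -> BitFingerprint:
    """166-bit structural-key fingerprint; bit i-1 set iff key i matches."""
    raw = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, index 0 unused
    arr = np.zeros(167, dtype=bool)
    for idx in raw.GetOnBits():
        arr[idx] = True
    return BitFingerprint(arr[1:], "maccs166")


def ecfp(mol: Chem.Mol, radius: int = 3, length: int = 2048) -> BitFingerprint:
    """Binary circular fingerprint of the given radius folded to
    ``length`` bits (radius 3 / 2048 is the ECFP6 configuration of the
    BBB model M2)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if length < 1 or (length & (length - 1)) != 0:
        raise ValueError("length must be a power of two")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=length)
    raw = gen.GetFingerprint(mol)
    arr = np.zeros(length, dtype=bool)
    for idx in raw.GetOnBits():
        arr[idx] = True
    return BitFingerprint(arr, "ecfp", {"radius": radius, "length": length})


def ecfp_environments(mol: Chem.Mol, radius: int) -> set:
    """Unfolded environment identifiers up to ``radius`` (for nesting
    checks: environments at radius r are a subset of radius r+1)."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=2**24)
    return set(gen.GetSparseFingerprint(mol).GetOnBits())


def tanimoto_distance(a: BitFingerprint, b: BitFingerprint) -> float:
    """1 − |a∧b| / |a∨b|; 0 when both fingerprints are empty."""
    if a.kind != b.kind or a.params != b.params:
        raise ValueError("fingerprints have mismatched kind/params")
    inter = int(np.logical_and(a.bits, b.bits).sum())
    union = int(np.logical_or(a.bits, b.bits).sum())
    if union == 0:
        return 0.0
    return 1.0 - inter / union


def fingerprint_matrix(mols, kind: str = "maccs166", **params) -> np.ndarray:
    """Stacked boolean fingerprint matrix for a molecule sequence."""
    if kind == "maccs166":
        return np.vstack([maccs166(m).bits for m in mols])
    if kind == "ecfp":
        return np.vstack([ecfp(m, **params).bits for m in mols])
    raise ValueError(f"unknown fingerprint kind: {kind!r}")


class FingerprintGenerator:
    """Transformer over molecule lists producing a boolean bit matrix."""

    def __init__(self, kind: str = "maccs166", radius: int = 3, length: int = 2048):
        self.kind = kind
        self.radius = radius
        self.length = length

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        mols = X.mols if hasattr(X, "mols") else list(X)
        if self.kind == "ecfp":
            return fingerprint_matrix(mols, "ecfp", radius=self.radius,
                                      length=self.length)
        return fingerprint_matrix(mols, self.kind)

    def get_params(self, deep=True):
        return {"kind": self.kind, "radius": self.radius, "length": self.length}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self
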