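"""Deterministic toy molecule sets and synthetic two-class datasets.

``toy_molecules`` covers the structural corner cases the curation and
descriptor layers must handle: a homologous alkane series, a stereo
duplicate pair, a missing-hydrogen valence error, nitro-group
representation variants, a salt, a single noble-gas atom and quaternary
ammonium ions. ``synthetic_classification`` draws class-conditional
normal features — a few informative columns whose means differ between
classes by a chosen effect size, the rest pure noise — as the
controlled stand-in for a descriptor matrix with known signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .molio import MoleculeTable

_ALKANES = [("C" * i, f"n-alkane-C{i}") for i in range(1, 13)]

#: Stereoisomer pair that collapses to one structure when
#: stereochemistry is ignored (a dideoxyribose nucleoside pair).
STEREO_PAIR = (
    "Nc1ccn([C@@H]2CC[C@@H](CO)O2)c(=O)n1",
    "Nc1ccn([C@H]2CC[C@@H](CO)O2)c(=O)n1",
)

#: Heptene written with a carbon missing one hydrogen (valence 3).
MISSING_H_VALENCE = "C=C([CH]CC)CC"

#: The same nitrocyclopentane in its two common nitro conventions.
NITRO_VARIANTS = ("[O-][N+](=O)C1CCCC1", "O=N(=O)C1CCCC1")

_EXTRAS = [
    (STEREO_PAIR[0], "stereo-pair-a"),
    (STEREO_PAIR[1], "stereo-pair-b"),
    (MISSING_H_VALENCE, "heptene-missing-H"),
    (NITRO_VARIANTS[0], "nitrocyclopentane-charged"),
    (NITRO_VARIANTS[1], "nitrocyclopentane-neutral"),
    ("CC.[Na+]", "ethane-sodium-mixture"),
    ("[Kr]", "krypton-atom"),
    ("C[N+](C)(C)C", "tetramethylammonium"),
    ("OCC[N+](C)(C)C", "choline"),
    ("Cn1cnc2c1c(=O)n(C)c(=O)n2C", "caffeine"),
    ("CC(=O)Oc1ccccc1C(=O)O", "aspirin"),
    ("c1ccncc1", "pyridine"),
    ("c1ccccc1", "benzene"),
    ("CCO", "ethanol"),
    ("CC(=O)[O-]", "acetate"),
    ("NCC", "ethylamine"),
    ("[O-]c1cccc(-c2ccccc2)c1.[Na+]", "sodium-biphenylolate-ionic"),
    ("O([Na])c1cccc(-c2ccccc2)c1", "sodium-biphenylolate-covalent"),
]


def toy_molecules() -> MoleculeTable:
    """The fixed fixture suite (30 molecules, all parseable)."""
    entries = _ALKANES + _EXTRAS
    return MoleculeTable.from_smiles(
        [s for s, _ in entries], names=[n for _, n in entries]
    )


@dataclass
class SyntheticSpec:
    """Generator settings for the two-class descriptor stand-in.

    ``effect_size`` is the standardized mean shift (Cohen's d) of each
    informative column between classes; noise columns are N(0,1) in
    both classes.
    """

    n_per_class: int = 200
    n_informative: int = 2
    effect_size: float = 3.0
    n_noise: int = 48
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 10:
            raise ValueError("n_per_class must be >= 10")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def synthetic_classification(spec: SyntheticSpec | None = None, **kwargs):
    """Draw (features DataFrame, labels array) from the spec.

    Labels are "BBB+" / "BBB-" to mirror a binary permeability
    endpoint; class +: informative columns shifted by d, class -: at 0.
    """
    if spec is None:
        spec = SyntheticSpec(**kwargs)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class
    p = spec.n_informative + spec.n_noise
    X = rng.standard_normal((2 * n, p))
    X[:n, : spec.n_informative] += spec.effect_size
    y = np.array(["BBB+"] * n + ["BBB-"] * n)
    cols = [f"inf{i}" for i in range(spec.n_informative)] + [
        f"noise{i}" for i in range(spec.n_noise)
    ]
    return pd.DataFrame(X, columns=cols), y
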