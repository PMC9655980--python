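"""Portable model deployment: bundle fitted models, their feature
recipes, pretreatment and applicability domains into a versioned JSON
project; apply the project to new molecule files; export annotated
predictions.

The project is a transparent JSON container (nested arrays, no code
execution on load). Each model entry records how to rebuild its feature
space — a descriptor name list or fingerprint parameters — so the
runner recomputes features, applies the stored standardization and ADs,
and reproduces the training-time predictions bit-for-bit.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import descriptors as _desc
from . import fingerprints as _fp
from . import molio
from .modeling import KNNClassifier, Standardization, majority_vote
from .molio import MoleculeTable
from .validation import DistanceAD, LeverageAD

FORMAT_VERSION = "qsarkit-project/1"


@dataclass
class ModelEntry:
    name: str
    model: KNNClassifier
    recipe: dict  # {"kind": "descriptors", "names": [...]} or fingerprint params
    ad: object | None = None  # LeverageAD | DistanceAD


@dataclass
class Project:
    endpoint: str
    labels: list[str]
    models: list[ModelEntry]
    consensus: dict | None = None  # {"name": ..., "members": [...], "tie_rule": ...}
    metadata: dict = field(default_factory=dict)

    def model_names(self):
        return [m.name for m in self.models]


def _encode_ad(ad):
    if ad is None:
        return None
    if isinstance(ad, LeverageAD):
        return {
            "kind": "leverage",
            "threshold": ad.threshold_,
            "xtx_inv": ad.xtx_inv_.tolist(),
            "n_train": ad.n_train_,
            "p": ad.p_,
        }
    if isinstance(ad, DistanceAD):
        return {
            "kind": "distance",
            "metric": ad.metric,
            "k": ad.k,
            "percentile": ad.percentile,
            "threshold": ad.threshold_,
            "X": ad.X_.astype(float).tolist(),
        }
    raise TypeError(f"unsupported AD object: {type(ad)!r}")


def _decode_ad(blob):
    if blob is None:
        return None
    if blob["kind"] == "leverage":
        ad = LeverageAD()
        ad.xtx_inv_ = np.asarray(blob["xtx_inv"], dtype=float)
        ad.threshold_ = float(blob["threshold"])
        ad.n_train_ = int(blob["n_train"])
        ad.p_ = int(blob["p"])
        return ad
    if blob["kind"] == "distance":
        ad = DistanceAD(metric=blob["metric"], k=int(blob["k"]),
                        percentile=float(blob["percentile"]))
        dtype = bool if blob["metric"] == "jaccard_tanimoto" else float
        ad.X_ = np.asarray(blob["X"], dtype=dtype)
        ad.threshold_ = float(blob["threshold"])
        return ad
    raise ValueError(f"unknown AD kind: {blob['kind']!r}")


def _encode_model(entry: ModelEntry) -> dict:
    m = entry.model
    blob = {
        "name": entry.name,
        "kind": "knn",
        "k": m.k,
        "metric": m.metric,
        "recipe": entry.recipe,
        "X_train": m.X_.astype(float).tolist(),
        "y_train": [str(v) for v in m.y_],
        "standardization": None,
        "ad": _encode_ad(entry.ad),
    }
    if m.scaler_ is not None:
        blob["standardization"] = {
            "mean": m.scaler_.mean.tolist(),
            "sd": m.scaler_.sd.tolist(),
        }
    return blob


def _decode_model(blob: dict) -> ModelEntry:
    model = KNNClassifier(k=int(blob["k"]), metric=blob["metric"])
    dtype = bool if blob["metric"] == "jaccard_tanimoto" else float
    model.X_ = np.asarray(blob["X_train"], dtype=dtype)
    model.y_ = np.asarray(blob["y_train"])
    model.classes_ = np.unique(model.y_)
    model.n_features_in_ = model.X_.shape[1]
    model.scaler_ = None
    if blob["standardization"] is not None:
        model.scaler_ = Standardization(
            np.asarray(blob["standardization"]["mean"], dtype=float),
            np.asarray(blob["standardization"]["sd"], dtype=float),
        )
    return ModelEntry(blob["name"], model, blob["recipe"], _decode_ad(blob["ad"]))


def save_project(project: Project, path) -> None:
    """Serialize a project; ``load_project(save_project(...))``
    reproduces predictions bit-for-bit."""
    payload = {
        "format": FORMAT_VERSION,
        "endpoint": project.endpoint,
        "labels": list(project.labels),
        "models": [_encode_model(m) for m in project.models],
        "consensus": project.consensus,
        "metadata": {
            "created": datetime.date.today().isoformat(),
            **project.metadata,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_project(path) -> Project:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise IOError(f"cannot load project {path}: {exc}") from exc
    version = payload.get("format")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"project format mismatch: file has {version!r}, "
            f"this reader expects {FORMAT_VERSION!r}"
        )
    return Project(
        endpoint=payload["endpoint"],
        labels=payload["labels"],
        models=[_decode_model(b) for b in payload["models"]],
        consensus=payload.get("consensus"),
        metadata=payload.get("metadata", {}),
    )


def compute_features(mols, recipe: dict):
    """(feature matrix, per-molecule computable mask) for a recipe."""
    kind = recipe["kind"]
    if kind == "descriptors":
        table = MoleculeTable(list(mols), pd.DataFrame({"name": [""] * len(mols)}))
        df = _desc.calc_descriptor_matrix(table, recipe["names"])
        X = df.to_numpy(dtype=float)
        ok = ~np.isnan(X).any(axis=1)
        return X, ok
    if kind == "maccs166":
        X = np.vstack([_fp.maccs166(m).bits for m in mols])
        return X, np.ones(len(mols), dtype=bool)
    if kind == "ecfp":
        X = np.vstack([
            _fp.ecfp(m, radius=recipe["radius"], length=recipe["length"]).bits
            for m in mols
        ])
        return X, np.ones(len(mols), dtype=bool)
    raise ValueError(f"unknown feature recipe kind: {kind!r}")


def run_project(project: Project, table: MoleculeTable) -> pd.DataFrame:
    """Per molecule, per model: predicted label and AD flag; a
    consensus column when the project defines one. Molecules whose
    features cannot be computed are flagged per model, never dropped."""
    n = len(table)
    out = pd.DataFrame({
        "id": range(n),
        "smiles": table.smiles(),
    })
    votes_by_model = {}
    ad_by_model = {}
    for entry in project.models:
        X, ok = compute_features(table.mols, entry.recipe)
        preds = np.full(n, "", dtype=object)
        ad_flags = np.full(n, "", dtype=object)
        if ok.any():
            Xok = X[ok]
            p = entry.model.predict(Xok)
            preds[ok] = p
            if entry.ad is not None:
                q = Xok
                if entry.model.scaler_ is not None and entry.recipe["kind"] == "descriptors":
                    q = entry.model.scaler_.apply(Xok)
                inside = entry.ad.contains(q)
                ad_flags[ok] = np.where(inside, "inside", "outside")
            else:
                ad_flags[ok] = "n/a"
        preds[~ok] = "not_computable"
        ad_flags[~ok] = "not_computable"
        out[f"{entry.name}_prediction"] = preds
        out[f"{entry.name}_ad"] = ad_flags
        votes_by_model[entry.name] = preds
        ad_by_model[entry.name] = ad_flags

    if project.consensus:
        members = project.consensus["members"]
        tie_rule = project.consensus.get("tie_rule")
        name = project.consensus.get("name", "consensus")
        cons_pred, cons_ad = [], []
        for i in range(n):
            votes = [votes_by_model[m][i] for m in members]
            if "not_computable" in votes:
                cons_pred.append("not_computable")
                cons_ad.append("not_computable")
                continue
            cons_pred.append(majority_vote(votes, tie_rule))
            flags = [ad_by_model[m][i] for m in members]
            if any(f == "n/a" for f in flags):
                cons_ad.append("n/a")
            else:
                cons_ad.append("inside" if all(f == "inside" for f in flags)
                               else "outside")
        out[f"{name}_prediction"] = cons_pred
        out[f"{name}_ad"] = cons_ad
    return out


def export_results(results: pd.DataFrame, path, fmt: str = "tsv",
                   mols=None) -> None:
    """Write the prediction table as TSV, or as SMILES/SDF with the
    prediction columns embedded as molecule properties."""
    if len(results) == 0:
        raise ValueError("empty prediction table")
    if fmt == "tsv":
        results.to_csv(path, sep="\t", index=False)
        return
    if fmt not in ("smiles", "sdf"):
        raise ValueError(f"unknown export format: {fmt!r}")
    if mols is None:
        mols = [molio.parse_smiles(s) for s in results["smiles"]]
    prop_cols = [c for c in results.columns if c not in ("id", "smiles")]
    table = MoleculeTable(
        list(mols),
        pd.DataFrame({
            "name": [str(i) for i in results["id"]],
            **{c: results[c].astype(str).tolist() for c in prop_cols},
        }),
    )
    molio.write_molecules(table, path, fmt)
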