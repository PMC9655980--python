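# qsarkit

An end-to-end toolkit for binary QSAR classification: structure
curation, molecular descriptor and fingerprint generation,
k-nearest-neighbour and consensus models with validation and
applicability domains, and portable JSON model deployment. The package
was built around the workflow used to model **blood–brain-barrier (BBB)
permeability** — predicting whether a compound crosses the BBB
(BBB+/BBB−) from its 2D structure alone — but every layer is generic.

## Who it is for

Cheminformaticians and medicinal chemists who need a scriptable,
auditable QSAR pipeline: read SMILES/SDF, flag and fix structural
anomalies, deduplicate with controllable identity options, compute a
small interpretable descriptor set or MACCS/ECFP fingerprints, fit and
validate KNN classifiers, and hand the finished model to colleagues as
a single JSON file that recomputes everything it needs.

## The model

The classifiers are k-nearest-neighbour models: a query molecule
receives the majority class of its *k* closest training molecules,
with distance either

- Jaccard–Tanimoto on bit fingerprints, `d(a,b) = 1 − |a∧b|/|a∨b|`
  (MACCS-166 structural keys, or binary ECFP with radius 3 folded to
  2048 bits), or
- Euclidean on standardized descriptors.

The descriptor model uses nine 2D descriptors: mean atomic
polarizability scaled on carbon (`Mp`), nitrogen count (`nN`),
log-transformed molecular path count of order 7 (`MPC07`), quaternary
ammonium count (`NssssN+`), Shannon-entropy pharmacophore-pair
descriptors (`SHED_DL`, `SHED_AN`), carbon pairs at topological
distance 9 (`F09[C-C]`), topological polar surface area including S/P
terms (`TPSA(Tot)`), and the squared Moriguchi logP (`MLOGP2`).

A consensus model combines members by majority vote; its applicability
domain is the conjunction of the member ADs (leverage `h = x(X'X)⁻¹x'`
against `h* = 3(p+1)/n`, or mean distance to the k nearest training
molecules against a training percentile).

## Worked example

```python
import numpy as np
from qsarkit.molio import MoleculeTable
from qsarkit import descriptors as D, fingerprints as F
from qsarkit.modeling import KNNClassifier
from qsarkit.validation import cross_validate

smiles = ["CCO","CCN","CCCO","NCCO","CCCN","OCCO",
          "CCCC","CCCCC","CCCCCC","CC(C)C","CCC(C)C","CCCCCCC"]
y = np.array(["BBB-"]*6 + ["BBB+"]*6)      # toy endpoint: polar vs alkane
table = MoleculeTable.from_smiles(smiles)

X = F.fingerprint_matrix(table.mols, "maccs166")
model = KNNClassifier(k=3, metric="jaccard_tanimoto")
cv = cross_validate(model, X, y, folds=3, seed=0, positive="BBB+")
rep = cv.pooled_report
print(f"CV accuracy {cv.pooled_accuracy:.3f}  Sn {rep.sensitivity:.3f}  "
      f"Sp {rep.specificity:.3f}  BA {rep.balanced_accuracy:.3f}")

df = D.calc_descriptor_matrix(table.subset([0, 8]),
                              ["Mp","nN","TPSA(Tot)","MLOGP2","SHED_DL"])
print(df.round(3).to_string())
```

prints

```
CV accuracy 1.000  Sn 1.000  Sp 1.000  BA 1.000
      Mp   nN  TPSA(Tot)  MLOGP2  SHED_DL
0  0.526  0.0      20.23   0.021      1.0
1  0.565  0.0       0.00  12.554      0.0
```

The toy endpoint is perfectly separable, so all out-of-fold scores are
1.0. The descriptor rows are ethanol (row 0) and hexane (row 1):
ethanol has a polar surface (TPSA 20.23 Å², one donor–lipophilic pair
→ SHED_DL = 1), hexane is a pure hydrocarbon (TPSA 0, logP² ≈ 12.6,
no donor → SHED_DL = 0).

The same workflow is available from the shell:

```
qsarkit curate   --molecules in.smi --preset bbb --endpoint-column BBB --out curated.smi
qsarkit describe --molecules curated.smi --out descriptors.tsv
qsarkit fit      --molecules curated.smi --endpoint-column field1 --model knn-maccs --out project.json
qsarkit run      --project project.json --molecules new.smi --out predictions.tsv
```

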