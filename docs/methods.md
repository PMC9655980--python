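# Methods

This note documents the models and procedures implemented in qsarkit,
the defaults and numerical conventions they use, and what the test
suite's synthetic data does and does not establish.

## Molecular graphs and I/O

Molecules are RDKit graphs. Parsing is deliberately lenient: entries
that fail full sanitization (neutral pentavalent nitro `-N(=O)=O`,
under-valent bracket atoms such as `[CH]`, aromatic rings with no
Kekulé assignment) are retained with a partial sanitization and marked,
so the curation checkers can see exactly the anomalies a curator needs
to find. Only syntactically invalid entries are rejected, and those are
reported with their line numbers rather than silently dropped.

Topological distances are heavy-atom shortest paths in bonds;
disconnected pairs carry a sentinel larger than any real distance and
are treated as absent by the pair-distribution descriptors. Canonical
identity keys are canonical SMILES computed after optional graph edits
(strip stereo marks, zero charges, drop isotopes, re-derive hydrogen
counts), so "duplicate" is a controllable notion: ignoring more
features can only merge equivalence classes, never split them.

## Curation

Ten checkers flag mixtures, unusual valences, covalent metal–heteroatom
bonds, net/atomic charges, isotopes, carbon-free molecules, elements
outside {H,B,C,N,O,P,S,F,Cl,Br,I}, kekulization failures and radicals.
The valence table is per-element with charge adjustment (C 4, N 3 with
+1 → 4, O 2 with −1 → 1, P 3/5, S 2/4/6, halogens 1/3/5/7). An
under-valent neutral carbon (e.g. `[CH]` with three connections) is
flagged as unusual valence even when the parser has booked the gap as
radical electrons, since a missing hydrogen is the more common cause in
curated datasets.

Seventeen built-in standardizers rewrite salts, charges, hydrogen
counts and the nitro/azide/diazo conventions; custom rules are
reaction SMARTS (`reactant>>product`). Each rule runs to a per-rule
fixed point, iterating until the canonical SMILES stops changing (a
match-based stopping rule would not terminate for rules whose product
still matches the pattern, e.g. the nitro rewrite). Standardizer
*order* is semantically significant and preserved: removing monoatomic
fragments before converting covalent metal bonds to ionic ones yields
a different product than the reverse order, which is exactly why the
pipeline takes an ordered list. Outputs are re-sanitized with RDKit's
valence check and functional-group normalization disabled so that a
deliberately chosen convention (e.g. neutral nitro) survives.

The BBB preset runs, in order: kekulize; drop multi-fragment
structures; drop unusual valences; drop single-heavy-atom molecules;
group duplicates ignoring stereochemistry; drop groups with
conflicting endpoint values entirely and keep the first member (file
order) of agreeing groups. Keeping the first member is deterministic
and order-preserving; a missing endpoint inside a group counts as a
conflict and is reported.

Scaffold analysis uses Bemis–Murcko frameworks (ring systems plus
linkers, side chains removed); ring-free molecules are counted
separately, not as scaffolds.

## Descriptors

- **Mp** — mean atomic polarizability scaled on carbon, hydrogens
  included. The polarizability table (units 10⁻²⁴ cm³: H 0.667,
  C 1.76, N 1.10, O 0.802, F 0.557, S 2.90, P 3.63, Cl 2.18, Br 3.05,
  I 5.35, B 3.03) ships as JSON and is swappable. Mp depends only on
  elemental composition, not connectivity.
- **MPC07** — simple paths of exactly 7 bonds in the heavy-atom graph,
  each undirected path counted once, reported as `ln(1 + count)`. The
  `+1` makes the no-path case 0 rather than −∞; natural log keeps the
  scale consistent with the SHED entropy base.
- **SHED_XY** — collect all topological distances between atoms of
  pharmacophore types X and Y, cap them into bins 1..20 (distances
  beyond 20 clamp into the last bin), form the empirical distribution
  p, and report `exp(−Σ p ln p)`. The value is exactly 1 when all
  pairs share one distance, approaches 20 under uniform occupancy of
  all 20 bins, and is defined as 0 when no such pair exists.
  Pharmacophore typing is a package-owned SMARTS rule set
  (`data/ppp_rules.json`): donor = N/O bearing H; acceptor = N/O with
  an available lone pair (excluding cations, nitro oxygens, amide and
  pyrrole-type nitrogens); negative = N/O inside carboxyl(ate),
  sulfonate, phosphate or tetrazole groups; positive = non-nitro N⁺;
  lipophilic = carbon/halogen atoms with no donor/acceptor/negative
  neighbour. The rules are published as data precisely because SHED
  values are only reproducible relative to a stated typing scheme.
- **F09[C-C]** — unordered carbon pairs at topological distance 9.
- **TPSA(Tot)** — Ertl fragment-contribution polar surface area with
  the S and P terms included.
- **MLOGP / MLOGP2** — the Moriguchi 13-parameter regression
  `logP = −1.014 + 1.244·CX^0.6 − 1.017·NO^0.9 + 0.406·PRX −
  0.145·UB^0.8 + 0.511·HB + 0.268·POL − 2.215·AMP + 0.912·ALK −
  0.392·RNG − 3.684·QN + 0.474·NO2 + 1.582·NCS + 0.773·BLM`, squared
  for MLOGP2. CX weights halogens F 0.5 / Cl 1.0 / Br 1.5 / I 2.0;
  UB counts kekulized double/triple bonds outside nitro groups. Three
  of the original terms are defined verbally and are implemented as
  documented heuristics: PRX (N/O proximity: 2 per directly bonded
  pair, 1 per pair two bonds apart), HB (intramolecular H-bond dummy:
  donor and acceptor at topological distance 4 in a ring-bearing
  molecule — the six-membered chelation motif), and POL (aromatic
  polar substituents: exocyclic N/O/halogen on an aromatic atom, or an
  exocyclic carbon directly bearing N/O). Edge-case agreement with
  other MLOGP implementations is therefore not guaranteed; the
  closed-form value for benzene (2.282) is pinned in the tests.

Descriptor-matrix computation never raises per molecule: a cell whose
descriptor cannot be computed (e.g. an element missing from the
polarizability table) becomes NaN, the matrix's explicit missing
marker, and downstream layers treat such molecules as
"not computable" for that model only.

## Fingerprints

MACCS-166 uses the public 166-key SMARTS dictionary (1-based key *i* →
vector index *i*−1). ECFP is the standard iterative
neighbourhood-hashing algorithm with duplicate environments counted
once, folded modulo a power-of-two length; the deployed configuration
is radius 3 / 2048 bits. Tanimoto distance between two empty
fingerprints is defined as 0 (identical objects). Bit-level identity
with other MACCS dialects is not promised — internal consistency is.

## Modeling

Splits: seeded random (held-out fraction), venetian blinds (every n-th
row to the test set), or by-variable (rows with a non-empty value in a
designated column — e.g. a database identifier — train, the rest
test). Standardization learns mean/sd on training rows only and
refuses constant columns, pointing to variable reduction (drop
constants, quasi-constants below an sd threshold, and the later member
of each pair correlated above a threshold; missing values handled
first by dropping molecules or features).

KNN is brute-force and lazy. Determinism conventions: candidates are
ordered by (distance, training index), so an equidistant tie at the
cut rank admits the lowest index; a tied vote with even k falls back
to the class of the single nearest neighbour. Euclidean KNN refuses
unstandardized features unless explicitly forced. Training-set scores
can be computed with the molecule as its own nearest neighbour
(`include_self=True`, the convention behind reported "training"
columns) or leave-self-out; cross-validated scores are the honest
estimate and both conventions are exposed because published training
scores rarely state which was used.

The consensus classifier takes the majority vote of its members; with
three members no ties occur, and an even split raises unless a tie
rule is configured. Members living in different feature spaces (two
fingerprint models and a descriptor model) are combined at the
prediction-column level by the deployment runner.

GA feature selection evolves fixed-cap subsets (default cap 10,
mirroring the descriptor budget under which the nine-descriptor model
was found) by tournament selection (size 3), uniform crossover (rate
0.9), per-gene mutation (default 1/n features) and single-individual
elitism, fitness = 5-fold CV balanced accuracy. Defaults are
population 100 × 200 generations; the tests and property checks run
population 20 × 15 generations, which already recovers planted signal
reliably — the package's own choice of problem size for fast,
deterministic checks. Oversized children are repaired by randomly
dropping genes; fitness values are cached per subset.

## Validation and applicability domains

Cross-validation uses seeded stratified folds (class proportions
preserved — the BBB data are unbalanced ~64:36) with each sample
predicted exactly once out-of-fold. Y-randomization permutes labels,
refits, and scores by the same CV; on data with real signal the
permuted scores collapse to the majority-class rate.

Leverage AD: `h = x̃ (X̃'X̃)⁻¹ x̃'` with intercept-augmented X̃,
threshold `h* = 3(p+1)/n` (the conventional Williams-plot cut; the
trace identity Σh = p+1 is asserted in tests). Near-singular X'X is
refused with a pointer to variable reduction. Distance AD: mean
distance to the k nearest training molecules, threshold at the 95th
percentile of the leave-self-out training statistics; by default a
model's distance AD reuses its own metric and k. The consensus AD is
the conjunction of member ADs: inside only if inside all members.
Which AD kind a deployed model carries is per-entry in the project;
the default pairing is distance AD for fingerprint models and leverage
AD for the standardized-descriptor model.

## Deployment

A project is a versioned JSON bundle: per model the KNN configuration,
stored training features and labels, the feature recipe (descriptor
names or fingerprint parameters), standardization parameters and AD;
plus a consensus definition and provenance metadata. JSON was chosen
over pickles deliberately — transparent, diffable, and no code
execution on load. The runner recomputes features per recipe, applies
the stored pretreatment, predicts, evaluates ADs and the consensus
conjunction, and flags (never drops) molecules whose features cannot
be computed. Results export as TSV or as SMILES/SDF with predictions
embedded as data fields.

## Synthetic data: what passing tests show

`synthetic_classification` draws class-conditional normal features:
`n_informative` columns whose class means differ by `effect_size`
(Cohen's d, default 3) standard deviations, plus `n_noise` N(0,1)
columns (defaults 2 + 48, 200 molecules per class, all randomness
seeded). This emulates the geometry of a descriptor matrix with a few
discriminating features buried in noise — it does not emulate real
chemistry: no feature correlations, no heavy-tailed descriptor
distributions, no class overlap structure, no activity cliffs.
Passing tests therefore establish that the machinery is correct
(selection recovers planted signal, CV is honest, permuted labels
collapse to chance), not that any particular real endpoint is
predictable. The toy molecule suite likewise tests curation and
descriptor mechanics, not pharmacology.

## Known limitations

- PPP typing and the polarizability table are package-defined;
  SHED/Mp values from other software will differ wherever their
  (unpublished) rule sets differ.
- MLOGP's PRX/HB/POL/AMP terms are heuristic readings of verbal
  definitions; values for polyfunctional molecules may deviate from
  other implementations.
- MACCS key dialects differ between toolkits; only internal
  consistency and order-invariance are guaranteed.
- No 3D descriptors, conformers, or regression model families; the
  scope is 2D binary classification.
- Path counting (MPC07) enumerates simple paths exhaustively; it is
  exponential in branching for dense graphs, which is irrelevant for
  drug-like molecules but would matter for large fused cage systems.
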