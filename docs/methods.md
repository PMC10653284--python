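# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `polyscreen`.

## Polymer structure building

Polymer chains are represented explicitly — as full molecules with every
residue written out — rather than as repeat units, so that random
comonomer order and regio-orientation are visible to the property model.

A chain is grown monomer by monomer:

1. The first residue is drawn from the spec's molar ratios (equal molar
   when none are given).  When the monomer carries two reactive groups, a
   fair coin decides which group becomes the live chain end.
2. Each subsequent monomer is drawn from the molar ratios renormalized
   over the monomers chemically compatible with the live end.  A diacid
   end can only accept a diol or diamine; without this restriction the
   alternating AA+BB backbone of condensation chemistry would be violated.
3. The drawn monomer attaches with random regio-orientation: when two of
   its groups could react, the per-insertion coin picks one.  The coin
   flip is recorded as the residue's orientation flag.
4. Growth stops when the residue count reaches the requested degree of
   polymerization (DP counts residues: the initial dimer is DP 2).  If the
   live end has no compatible partner, a growth error names the blocked
   end.

Chemistries are registry entries, not code: each declares the
functional-group SMARTS of both partners, the reaction SMARTS of the
linkage, and the condensate (water for ester and amide, methanol for
carbonate, none for urethane and vinyl addition).  Chain growth executes
each template by index-tracked molecule editing so that exactly the live
end reacts; this makes the mass balance exact — the built chain's
molecular weight equals the sum of residue masses minus one condensate per
linkage to better than 1e-6 Da, which the tests exploit as an invariant.
Five chemistries ship: polyester, polyamide, polycarbonate (from dialkyl
carbonates, eliminating methanol), polyurethane and vinyl addition.
End groups are left uncapped (free acid/hydroxyl/amine termini), and
stereo descriptors present in input SMILES are preserved but never
invented.

Replicate structures are independent draws from one seeded stream;
training uses a single chain per labeled monomer set, prediction averages
7 replicates (further replicates stopped reducing prediction variability).

## Graph featurization

Chains are featurized as heavy-atom graphs with categorical tokens:

* atom token = (element, aromatic flag, ring membership, heavy-atom
  degree, attached H count);
* bond token = (bond order, ring membership, sorted end-element symbols).

Hydrogens stay implicit — expanding them would double chain graphs for no
information gain.  A vocabulary built from the training corpus maps tokens
to dense indices (lexicographic order, so it is reproducible from the
token multiset); tokens rarer than `min_count` (default 1) and unseen
tokens map to a reserved unknown index rather than raising.

## Property model

The model is a multi-output message-passing network over chain graphs,
predicting 8 properties at once: Tg (°C), Tm (°C), density (g/cm³),
modulus (source units), and O₂/N₂/CO₂/H₂O permeability (Barrer).

**Targets.**  Permeabilities span orders of magnitude and are
log10-transformed first (observed values must be positive).  All targets
are then robust-scaled — centered by the median, divided by the
interquartile range, fitted per property over observed entries only; a
zero-IQR column falls back to unit scale with a warning.  Missing labels
carry a mask bit; the loss is the mean absolute error over unmasked
entries of the batch, so a masked slot contributes neither loss nor
gradient (the tests perturb masked slots and assert bit-identical
gradients).

**Architecture.**  Atom, bond and per-graph global states are initialized
from one-hot embeddings.  Each message-passing layer updates, in order:

* bond states, from (sum of the two endpoint atom states, bond state,
  global state) through a two-layer ReLU perceptron with a residual
  connection;
* atom states, from (atom state, sum of incident bond states, global
  state), same form;
* the global state, from (global state, mean-pooled atom states,
  log chain size), same form.

The mean-pool-plus-log-size form matters: sum pooling injects O(n_atoms)
magnitudes that compound through deep residual stacks and destabilize
8-layer training, while the log-size channel keeps chain size visible so
the network can learn per-size normalizations.  Residual branches are
additionally initialized with a 1/sqrt(n_layers) scale and gradients are
clipped to global norm 5, the standard recipe for deep residual stacks.
The final layer updates only bond states — the readout never consumes the
last atom/global update, so those parameters are not created.

**Readout.**  Per property, each final bond state maps through one linear
unit to a scalar and the prediction is exactly the sum of those scalars
over bonds.  This bond-sum identity is structural, not approximate: the
per-bond scalars are an exact additive decomposition of the (scaled)
prediction and serve directly as bond-level attributions.  The readout
weights start at zero so an untrained network predicts 0 (the scaled-space
median) instead of an O(n_bonds) random sum.

**Training.**  20% of the data is held out, stratified by polymer class;
the remainder is split into 10 stratified cross-validation folds
(scikit-learn), each training one network on 9/10 with Adam under
per-epoch exponential learning-rate decay.  Stratification falls back to
unstratified splitting, with a warning, when a class is too small.  The
default budget is 1000 epochs with validation monitoring and no early
stopping; the fixture configuration (below) uses 200.  Prediction builds 7
replicate chains, averages the scaled predictions over replicates within
each fold, inverse-transforms to original units, and reports the mean and
standard deviation over the 10 fold models.

**Defaults.**  atom/bond state width 128, 8 message layers, batch 32,
learning rate 1e-3 with decay 0.995 per epoch, training-chain DP 12.
These are configuration, not constants; `harness.hyperparameter_sweep`
provides a small one-factor-at-a-time sweep around them.  The engine
(reverse-mode autodiff over NumPy arrays with sparse gather/scatter
matrices, float32) lives in `polyscreen.nn` and is deliberately minimal:
the operations the network needs and nothing more.

## Domain of validity

Structural novelty of a prediction target is the number of distinct
circular-environment (Morgan) hashes of its chain, radii 0–2, absent from
the pooled hash set of the training corpus.  Hashes are unfolded raw
identifiers, not folded bit vectors, so small counts are not distorted by
collisions, and distinct hashes are counted once regardless of occurrence
count.  A structure is inside the domain of validity when its novelty
count is at most 6 (seven or more novel substructures puts it outside);
the threshold is configurable.  Replicate sets are merged by the union of
novel hashes before counting.  DoV is evaluated on the same explicit chain
representation used for prediction.

`polyscreen.dov_reference` re-derives novelty counts by brute force:
explicit enumeration of every environment with (radius, rooted canonical
labeled submol) identities and the same radius-major bond-set
deduplication.  The fingerprint path and the enumeration path agree
exactly on the test corpora; the atoms of each novel environment are
reported so novelty can be drawn onto the structure.

## Screening funnel

Monomers are prescreened: CHNO elements only, molecular weight below
300 Da, and exactly two reactive groups forming a valid condensation
pairing ("bifunctional"; molecules with more reactive groups are
crosslinkers and excluded along with everything unclassifiable).
Candidates are all diacid+diol polyesters, diacid+diamine polyamides,
carbonate+diol polycarbonates, and AB homopolymers, at 1:1 composition,
deduplicated on the (chemistry, sorted monomer) key.  Each candidate is
predicted, DoV-gated, and flagged per performance criterion.  A criterion
may reference a benchmark polymer (e.g. "O₂ permeability at most PET's");
the reference is predicted with the same ensemble rather than taken from
literature so the comparison is internally consistent.  Ranking is
lexicographic: inside DoV, then criteria passed, then predicted Tg.  The
2×2 funnel breakdown always sums to the candidate total.

## Theoretical carbon yields

For a metabolite in a stoichiometric model (cobrapy; SBML for published
genome-scale models, programmatic construction for toys), a demand
reaction is added inside a model context, its flux maximized by linear
programming, and the carbon yield computed as demand flux × product
carbon count divided by the summed carbon influx over all exchange
reactions with net uptake (glucose and, where taken up, CO₂).  Non-growth
ATP maintenance bounds ship with the model and are preserved; growth is
not forced — the demand is the sole objective.  The context manager
restores the model afterwards.  Yield targets for polymer consideration
must be CHNO-only, have at least two carbons, MW under 300 Da and a
carbon yield above 10%.

Two hand-built, elementally balanced toy models cover the closed forms:
glucose→2 lactate + 2 ATP (lactate yield exactly 1) and
glucose→2 ethanol + 2 CO₂ + 2 ATP with CO₂ export only (ethanol yield
exactly 4/6).  Both carry an ATP maintenance reaction with lower bound
1 mmol/gDW/h and glucose uptake capped at 10; raising maintenance beyond
the producible ATP rate makes the model infeasible, which is reported,
not silently ignored.

## Synthetic fixtures

The fixture generator emulates a curated training table at toy scale:

* a seeded monomer library of linear alkyl diacids/diols/diamines/hydroxy
  acids (chain lengths 2–8) plus aromatic variants;
* chains built as single seeded replicates (mirroring single-chain
  training), half polyester, half polyamide, some AB homopolyesters;
* labels from a known group-contribution rule: Tg = intercept + Σ
  coefficient × (group count / heavy atoms) + Gaussian noise (default sd
  10 °C).  Group counts are substructure matches (amide, ester, ether,
  methyl, carbonyl) plus the aromatic ring count.  The aromatic
  coefficient is deliberately the largest planted signal so that bond
  attributions of a trained model can be checked against ground truth.
  The coefficients put fixture Tg roughly in the 0–200 °C band of real
  polymers so robust scaling is exercised meaningfully.
* the other 7 properties are different deterministic functions of the
  same normalized group counts (permeabilities positive by construction),
  each observed with probability 0.5 so the multitask mask path is
  exercised; Tg is always observed.

What the fixtures do *not* emulate: the chemical diversity of real
polymer databases, heavy-tailed label noise, systematic inter-laboratory
offsets, or molecular-weight dependence.  Passing the recovery tests
shows the pipeline can extract a planted structure–property rule at
realistic noise; it does not certify accuracy on real measurements.

## Study conditions and problem sizes

The end-to-end recovery harness trains the full 10-fold ensemble on a
300-polymer fixture corpus (DP-8 chains, noise sd 10 °C) with the small
configuration: 2 message layers, 32-dim states, 200 epochs, learning
rate 3e-3 with 0.99 decay.  Recovery is judged by held-out Tg MAE below
2× the label noise and by aromatic-ring bonds carrying the largest mean
attribution.  The depth/chain-length harness trains single networks on
150-polymer DP-12 corpora for 100 epochs at depths 2 and 8, three seeds,
comparing median final validation loss; on long chains the deeper network
should do at least as well.  These problem sizes keep a full run to
minutes on one CPU core while leaving the statistical contracts testable.

## Known limitations

* Linear chains only: no branching, crosslinking, block architectures,
  ring-opening polymerization, or molecular-weight distributions.
* The DP used for the original full-scale training chain is not
  recoverable; it is exposed as configuration (`dp_train`, default 12).
* Uncertainty is the fold-model standard deviation only.
* No molecular-weight (Flory–Fox) correction of Tg.
* The modulus and permeability source units are taken as given in the
  input table; only permeability receives a transform.
* Whether novelty should be counted per replicate or after merging
  replicates is ambiguous; merging by union is the implemented choice,
  with per-structure counting also available.
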