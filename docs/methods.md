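# Methods

This note records the models and procedures the package implements, the
defaults it fixes, what the synthetic-data generator does and does not
emulate, and the design choices made where the conventions of the field leave
room.

## Structure handling

Structures are canonicalized on read: the largest covalent fragment is kept
(counterion/salt stripping, the common screening-collection preprocessing)
and the toolkit's canonical SMILES with stereochemistry is stored.
Canonicalization is idempotent. Duplicate canonical structures are dropped
within one class label (with a warning) but permitted across labels, since a
molecule may legitimately belong to both a natural-product and a drug
reference set. The plate CSV dialect is fixed (comma-separated, UTF-8, header
row, metadata columns `plate_id, well_id, compound_id, concentration_um,
is_control`) rather than sniffed; feature tables are read with round-trip
float parsing so write → read is value-exact.

## Descriptor panel

The 17-descriptor chemspace panel is: molecular weight, cLogP
(atomic-contribution method, computed locally), tPSA, HBD, HBA, rotatable
bonds, ring count, aromatic ring count, heavy atoms, fraction sp³ carbons,
stereocenter count, heteroatoms, formal charge, ring-system count, largest
ring size, nitrogen count, oxygen count. The panel is a registry keyed by
name; any subset or replacement list can be requested. The set of names is a
package choice — it is the standard panel for natural-product versus drug
comparisons, and it is deliberately configurable because different groups
use slightly different panels.

## QED, NP-likeness, spatial score, shape

**QED** is the published weighted-geometric-mean-of-desirabilities
parameterization, taken from the cheminformatics toolkit.

**NP-likeness** is trained, not shipped: given a natural-product set and a
synthetic set (non-empty, disjoint by canonical structure), each circular
fragment of radius 2 receives the log-odds contribution
`log((p_NP + ε_NP)/(p_syn + ε_syn))`, with `p` the fraction of molecules in
the set containing the fragment and `ε = 1/|set|`. A molecule's score is the
arithmetic mean contribution over its fragments (unknown fragments
contribute 0), clipped to [−5, 5], the conventional display range. Swapping
the training sets negates every contribution exactly, a property the tests
exercise. Document frequency (molecules containing a fragment) rather than
raw fragment occurrence counts is used so large molecules do not dominate
training; the smoothing choice is exposed through the trained table.

**Spatial score**: per heavy atom, `h·s·r·n²` with h = 1/2/3 for sp/sp²/sp³
and 4 otherwise, s = 2 for stereogenic atoms (tetrahedral centers including
unassigned ones, and atoms of stereo or potentially-stereo double bonds),
r = 2 for non-aromatic ring atoms, n = heavy-atom neighbor count. nSPS
divides by heavy-atom count. Anchors: ethane nSPS 3, benzene 8,
cyclohexane 24. The implementation is independent of the toolkit's and is
cross-checked against it in the tests.

**Shape**: conformers are embedded deterministically (ETKDG, fixed seed, 10
conformers, hydrogens added), the lowest-energy conformer (MMFF, UFF
fallback) supplies principal moments I₁ ≤ I₂ ≤ I₃, and NPR1 = I₁/I₃,
NPR2 = I₂/I₃. The shape class is the nearest vertex among rod (0, 1),
disc (0.5, 0.5), sphere (1, 1). Valid descriptors satisfy
0 ≤ NPR1 ≤ NPR2 ≤ 1 and NPR1 + NPR2 ≥ 1.

**AOHI substructure.** The 3a-aryloctahydroindole motif is shipped as an
editable SMARTS:
`[#7;!a]1[#6;!a][#6;!a][#6;!a]2([c])[#6;!a][#6;!a][#6;!a][#6;!a][#6;!a]12` —
a non-aromatic 6-5 fused indoline skeleton with an aromatic carbon
substituent on the ring-fusion carbon. Ring atoms are required to be
non-aromatic but not sp³, so ring ketones (as in mesembrine) match.
Stereochemistry and N-substitution are deliberately unconstrained; this is a
documented package choice, since depictions of the motif do not pin either
down.

## Profile analytics

Per plate, controls define per-feature center (median) and scale
(1.4826 × MAD, the Gaussian-consistent robust standard deviation); at least
4 control wells are required. Replicate treatment wells aggregate by median
before scaling (the alternative — per-well z then median — is a one-line
change and gives the same result for symmetric noise). Features whose
control MAD is zero but which vary on the plate get the smallest positive
control MAD as substitute scale and are flagged; features constant across
the entire plate are excluded from the induction denominator rather than
silently counted, and never enter correlations.

Induction is the percentage of non-excluded features with |z| ≥ θ. θ = 3 is
the package default — the standard robust-z significance cutoff in
morphological profiling — and is exposed in `AnalysisConfig` because the
underlying assay convention does not fix it. Activity (≥ 5%) and similarity
(BioSim ≥ 75%) thresholds default to the assay's published cutoffs. BioSim
is 100 × Pearson correlation over the full z vector; correlation of a
constant vector is an error, never silently 0.

## Subprofile clustering

Subprofile extraction takes member profiles (expected pairwise biosimilar;
violations warn rather than fail, so exploratory use is possible) and keeps
features where (a) at least a `consistency` fraction of members shifts in
the direction of the median — default 1.0, the strictest reading of
"changed in the same direction" — and (b) |median z| ≥ `min_abs_median`
(default 1.0, i.e. at least one robust SD of effect). Cluster biosimilarity
correlates a test profile, restricted to the subprofile's features, against
the subprofile's median values; correlating against the subprofile vector
(rather than against each member and averaging) is the package's choice and
is noted as such. Assignment takes the argmax cluster if it clears the
similarity threshold, else none; ties break by model order and are logged;
unscorable cells are NaN, never 0. Profile UMAP embeds raw z vectors with
10 neighbors and no normalization — z-scores already share a scale, and this
matches the profile-embedding convention.

## Bioenergetics

MitoStress decomposition uses the kit-standard identities: non-mitochondrial
= final-phase mean; basal = baseline mean − non-mitochondrial; proton leak =
post-oligomycin mean − non-mitochondrial; ATP-linked = basal − proton leak;
maximal = post-FCCP **maximum** measurement − non-mitochondrial; spare =
maximal − basal. Phase membership is "strictly after this injection, before
the next". Replicate wells average per timepoint before analysis. The
identities make `atp_linked + proton_leak = basal` exact by construction.

## Synthetic data

The generator emulates the study conditions the analytics target: 579
features, concentrations {2, 10, 30, 50} µM with a Hill dose response
(c50 = 10 µM, slope 1), k = 4 planted clusters with 58 effect features each
(~10% of the panel), per-feature noise scale σ_f log-uniform over one decade
(so robust scaling is genuinely exercised), 16 control wells and 2 replicate
wells per treatment. Cluster templates use disjoint feature subsets with
random ±1 signs, hence exactly orthogonal unit directions; a compound of
amplitude *a* shifts each effect feature by `a · hill(conc) · sign · σ_f`,
so amplitude is expressed in per-feature control-sigma units and an
amplitude-10 compound yields z ≈ 8 on effect features at the top
concentration.

What the generator does **not** emulate: feature–feature covariance of real
morphological features (features are independent here), plate-position
effects, or heavy-tailed control distributions. Recovery and calibration
results therefore demonstrate correctness of the statistics under the
generator's assumptions, not performance on real screening plates.

The toy compound classes are curated, not sampled: twelve stereocenter-rich,
fused-polycyclic natural-product-like structures (exactly one of which,
mesembrine, carries the AOHI core) versus twelve flat aromatic drug-like
structures. The seed shuffles order only, so train/test splits vary while
the chemistry is fixed.

OCR traces are generated phase-constant so that the max-based maximal
respiration coincides with the phase mean and the zero-noise round trip
through parameter extraction is exact; optional Gaussian noise tests
estimator behavior under the central-limit bound.

## Numerical choices and degenerate inputs

- PCA standardizes columns, drops constant columns with a warning, and fixes
  component signs by forcing the largest-magnitude loading positive, making
  embeddings deterministic and permutation-stable.
- UMAP runs with a fixed `random_state`, which forces single-threaded,
  reproducible layouts; identical input + seed ⇒ identical coordinates.
- CSV round trips use round-trip float parsing; manifests contain no
  timestamps, so pipeline reruns are byte-identical.
- Correlation over fewer than 3 shared features is an error ("subprofile too
  small"), as is a constant vector; empty subprofile selections report which
  thresholds to lower.
- Problem sizes in the test and acceptance runs (40 active compounds, 1000
  null treatments, 120 spatial-score molecules, 24 conformer embeddings) are
  chosen so the full suite completes in a few minutes on one CPU while
  keeping every estimate's sampling error far from the asserted bounds.

## Known limitations

- NP-likeness requires user-supplied reference sets; no pretrained
  contribution table ships with the package.
- pKa-dependent lipophilicity (logD) is out of scope; cLogP is the neutral
  atomic-contribution estimate.
- Cluster membership of the 13-cluster reference space is a user-supplied or
  synthetic registry; the package defines the machinery, not the reference
  data.
- Per-compound dose curves at saturating concentrations fluctuate by
  fractions of a percent of induction; monotonicity claims are therefore
  evaluated on the median across compounds, where the Hill trend dominates.
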