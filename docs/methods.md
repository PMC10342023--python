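# Methods

## Model

The unit of prediction is the peptide bond, represented by the structural
features of its P1 residue. The scorer is two-class linear discriminant
analysis with a shared (pooled) within-class covariance, which yields a
logistic posterior in the linear discriminant. LDA's assumptions — roughly
Gaussian class-conditional features with a common covariance — are mild for
this feature set: five of the seven features live in [0, 1] and the decision
surface that matters is linear ordering, not calibrated probability. The
pooled covariance uses the maximum-likelihood (1/n) normalization, so the fit
depends on the data only through per-class means, the total scatter, and the
class sizes; duplicating the training set leaves the model unchanged.

A ridge of 1e-6 on the covariance diagonal keeps it invertible: the three
secondary-structure binaries are one-hot (they sum to 1), so the raw pooled
covariance is rank-deficient by construction. The ridge is small enough to
leave well-conditioned fits untouched (the closed-form toy fit in the tests
is run with ridge 0 and matches hand arithmetic to 1e-10).

## Features

| feature | definition | default |
|---|---|---|
| `rel_acc` | ASA / max-ASA(residue type), then corpus min–max | Tien et al. theoretical max-ASA table |
| `ss_helix/strand/loop` | one-hot from DSSP 8-state (H,G,I→helix; E,B→strand; T,S,'-'→loop) | — |
| `bfactor_norm` | per-structure min–max of the residue-mean B-factor | per-structure (configurable per-corpus) |
| `loop_len_norm` | length of the surrounding maximal loop run, corpus min–max; 0 off-loop | — |
| `terminus` | 1 before the first / after the last qualifying regular element | helix runs ≥ 4, strand runs ≥ 3 |
| `confidence_norm` | predicted models only: temperature-factor column / 100 | no corpus fit (scale is absolute) |

Decisions taken where the design was genuinely open:

* **Accessibility normalization.** Raw ASA is residue-size-confounded, so it
  is first divided by the residue-type maximum and only then min–max scaled
  on the training corpus. The corpus-level min–max is the default for
  accessibility and loop length; B-factor bounds are fitted per structure
  because crystallographic B-factor scales are not comparable across
  entries (`bfactor_mode="per_corpus"` switches this off).
* **"Short" regular elements.** The termini rule skips helix runs shorter
  than 4 and strand runs shorter than 3 residues — one turn of helix or a
  two-residue bridge does not anchor a terminus. Both thresholds are
  arguments of `termini_feature`.
* **One flag for both termini.** A single binary covers N- and C-terminal
  segments rather than two separate features.
* **Residue temperature factor** is the unweighted mean over the residue's
  atoms, robust to a missing CA.
* **Nonstandard residues** map to 'X', get no feature vector, and are
  excluded from positives and negatives; max-ASA and PSSM columns are defined
  for the 20 standard amino acids only.

When no DSSP output file is supplied, accessibility falls back on a built-in
Shrake–Rupley implementation (golden-spiral point set, 960 points, probe
1.4 Å, radii C 1.70 / N 1.55 / O 1.52 / S 1.80 Å) and secondary structure on
a Kabsch–Sander hydrogen-bond assignment (electrostatic energy model with the
−0.5 kcal/mol threshold, amide H estimated on the donor nitrogen, minimal
4-turn and bridge rules collapsed straight to three states). The fallback
assigner is deliberately coarse — no full 8-state parity — and the DSSP-file
path remains the reference route. The 960-point SASA agrees with the
isolated-sphere closed form and a 4000-point computation within 2%.

## Dataset construction

Events are mapped onto structures by global Needleman–Wunsch alignment
(BLOSUM62, gap open −10, gap extend −0.5, traceback preferring diagonal,
then up, then left). The aligner reports percent identity and warns below
90%, mirroring the identity gate used when structures are assigned to
substrates upstream. P1 positions aligned to gaps are rejected as
unresolved; aligned-residue mismatches are rejected by default
(`allow_mismatch` relaxes this). The curation filter is an automated,
logged proxy for manual structure inspection: a publication group with at
least 2 mapped sites is dropped when more than half of them have relative
accessibility below 0.05 — a cluster of core cleavages from one experiment
indicates the substrate had lost its fold. All three thresholds are
arguments.

Negatives are every other residue with a complete feature vector in the same
structures, sampled globally (not per structure) without replacement at a
configurable positives:negatives ratio; `"all"` keeps the pool. Cross-
validation is grouped by structure so peptide bonds of one protein never
straddle a train/test split (`row_level=True` restores ungrouped folds for
comparability). Within each fold, normalization bounds and the model are
fitted on training rows only, and the test fold is always evaluated in full,
so AUCs at different training ratios are computed on identical evaluation
sets.

## Specificity fusion

The PSSM window is P4–P4′ (the MEROPS convention; configurable), entries are
log₂-odds with background-proportional pseudocounts (α = 1, uniform 0.05
background by default). This pseudocount form makes "counts proportional to
background" give exactly the zero matrix, which is also the behaviour of a
window position with no information. Window positions outside the sequence
and 'X' letters contribute 0 bits. The fusion classifier is Gaussian naive
Bayes on the two continuous scores (structural posterior, PSSM bits), with
per-class sample means/variances (variance floored at 1e-9) and frequency
priors. No threshold is applied to any score.

## Synthetic data

The generator emulates the pipeline's inputs, not real proteins. Backbones
(N, CA, C, O only — enough for SASA and the H-bond assigner, no side chains)
are grown by natural-extension-reference-frame placement with ideal bond
geometry; helix runs use (φ, ψ) = (−57°, −47°), strands (−135°, 135°), loops
seeded coil torsions, giving 3.8 Å CA–CA steps and a ~1.5 Å helical rise.
B-factors are base 15 + 10 for loop residues + N(0, 3) noise. Chains are
40–80 residues of alternating elements flanked by terminal loops. Every toy
structure carries ground-truth 3-state labels so feature logic is testable
independently of the geometric assigner.

Cleavage is planted per residue as Bernoulli(σ(β·f + c)) with default
β = (rel_acc 4.0, loop_len_norm 2.5, bfactor_norm 2.0, terminus 1.5), zero
on the secondary-structure binaries, and intercept −8.6, which puts the
expected density near 2–3 events per structure — the density seen in curated
proteolytic-event collections, whose per-protein average is ~2.3–2.4 with a
median of one. The generating model's true probabilities are returned so the
Bayes-optimal AUC can bound any fitted model. For fusion experiments a
trypsin-like motif (K/R at P1, small residues favoured at P1′) contributes
0.25 per bit to the linear predictor.

What passing synthetic tests does **not** show: the toy chains have no side
chains, no tertiary packing beyond chance contacts, independent uniform
sequences, and a generative model that is exactly the logistic form LDA can
represent. Real-data performance therefore cannot be inferred from the
benchmark AUCs; the benchmark validates the machinery (features, sampling,
grouped CV, fusion), not the biology.

## Benchmark problem sizes

The standard benchmark corpus is 200 structures (~13,000 residues, ~450
planted events) with 10-fold grouped CV; the class-ratio sweep uses ratios
{1:1, 1:2, 1:5, 1:10} × 3 seeds on the same corpus; the fusion corpus is 100
structures with the motif effect and a PSSM rebuilt from 2000 sampled motif
peptides. These sizes give fold-level AUC noise well below the margins being
tested while keeping a full run near a minute on one CPU.

## Known limitations

* The DSSP-fallback secondary structure under-calls strands for isolated
  (unpaired) extended segments; supply a DSSP file for faithful assignments.
* Multi-chain substrates require an explicit chain; inter-chain occlusion is
  included in SASA but events are mapped per chain.
* Experimental-vs-predicted feature sets differ (B-factor vs confidence), so
  a model trained on one structure kind cannot score the other; the CLI
  refuses the mismatch rather than imputing.
* mmCIF input, NMR ensembles beyond the first model, hydrogen atoms, and
  structure retrieval are out of scope.
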