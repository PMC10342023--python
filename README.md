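# cleavability

Structural susceptibility of protein peptide bonds to proteolysis.

Regulatory proteases cleave folded proteins at a small number of precise
peptide bonds, and whether a bond can be cleaved at all depends strongly on
the substrate's 3D structure: bonds buried in the hydrophobic core or locked
into regular secondary structure are protected, while exposed flexible
regions — long protruded loops, high-mobility segments, unstructured N- and
C-termini — are cleavage-prone. `cleavability` scores every peptide bond of a
protein with a known (experimental) or predicted (AlphaFold-style) 3D
structure for this *structural* susceptibility, independently of any
particular protease, and can fuse the structural score with a protease
primary-specificity model to predict actual cleavage sites.

## Method

Each peptide bond is represented by the structural features of its P1 residue
(Schechter–Berger notation: P1 is immediately N-terminal of the scissile
bond):

* **relative solvent accessibility** — absolute ASA (from a DSSP file or the
  built-in Shrake–Rupley implementation) divided by the residue-type maximum
  (Tien et al. theoretical values), min–max scaled over the training corpus;
* **secondary structure** — three one-hot states (helix/strand/loop collapsed
  from the DSSP 8-state alphabet);
* **normalized B-factor** — crystallographic temperature factor, min–max
  scaled within each structure (omitted for predicted models, whose
  temperature-factor column instead provides a confidence feature pLDDT/100);
* **loop length** — the length of the maximal loop run containing the
  residue, assigned to every residue of the loop, min–max scaled;
* **flexible termini** — a binary flag for unstructured terminal segments
  outside the first/last regular secondary-structure element (short elements
  are skipped).

A two-class linear discriminant (class means μ₀, μ₁, pooled within-class
covariance Σ, log prior ratio) turns the feature vector *x* into a
susceptibility probability

    w = Σ⁻¹(μ₁ − μ₀),  b = −½(μ₀+μ₁)ᵀw + log(n₁/n₀),  p(x) = σ(wᵀx + b).

Training positives come from a table of observed proteolytic events
(substrate id, 1-based P1 position, protease MEROPS code) mapped onto
structure residues through Needleman–Wunsch global alignment (BLOSUM62,
affine gaps); events landing in unresolved regions are rejected, and a
configurable burial filter drops publication groups whose cleavages sit
predominantly in the hydrophobic core. Negatives are sampled from all other
residues at a configurable ratio (prediction quality is essentially
independent of the ratio; 1:1 is the default). Quality is the ROC AUC under
structure-grouped 10-fold cross-validation.

For protease-specific prediction, a PSSM over the P4–P4′ window (log₂-odds
with background-proportional pseudocounts) scores the sequence context, and a
two-feature Gaussian naive Bayes model fuses the structural and PSSM scores
into a posterior cleavage probability. No cleaved/uncleaved threshold is
applied anywhere: the output is a per-bond score.

## Worked example

The package ships a synthetic-data generator that builds toy backbone
structures from ideal geometry and plants cleavage events with a known
feature-dependent probability model, so the whole pipeline runs with no
external data:

```sh
cleavability simulate --n-structures 30 --seed 11 --out-dir sim
# INFO simulate: 30 structures, 2122 residues, 49 planted events
cleavability train --table sim/corpus.tsv --out model.json --k 10 --seed 0
# INFO train: CV mean AUC 0.856 (median 0.872) over 10 folds
cleavability predict --structure toy0003.pdb --chain A --model model.json \
    --out-tsv scores.tsv --out-pdb scored.pdb
# INFO predict: scored 75 of 75 peptide bonds
head -4 scores.tsv
# structure_id  chain_id  seq_num  icode  res_name  one_letter  score
# toy0003       A         1                ALA       A           0.988596
# toy0003       A         2                HIS       H           0.725602
# toy0003       A         3                TYR       Y           0.379512
```

The cross-validated mean AUC of 0.856 says the fitted discriminant ranks a
random cleaved bond above a random uncleaved one 85.6% of the time on held-out
structures. Per-residue scores are probabilities in (0, 1); `scored.pdb` is
the input structure with each score × 100 written into the temperature-factor
column, ready for coloring in any molecular viewer. The N-terminal residues
score high (0.99, 0.73) because they are exposed, terminal, and in a loop.

`cleavability featurize`, `build-pssm`, `combine`, and `evaluate` expose the
remaining stages (feature tables, specificity matrices, naive-Bayes fusion,
ROC evaluation) as the same kind of thin wrappers over the library API.

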