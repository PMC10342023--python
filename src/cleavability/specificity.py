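"""Protease primary-specificity models and score fusion.

A protease's sequence preference around the scissile bond is modelled as a
position-specific scoring matrix (PSSM) over a Schechter-Berger window,
P4-P4' by default (P1 immediately N-terminal of the cleaved bond). Entries
are log2-odds in bits with background-proportional pseudocounts:

    M[a, j] = log2( ((count(a, j) + alpha * b_a) / (N_j + alpha)) / b_a )

where ``N_j`` is the number of standard letters observed in column ``j`` and
``b_a`` the background frequency of amino acid ``a`` (uniform 0.05 unless
supplied). With this pseudocount form, columns whose counts match the
background give exactly zero bits. A candidate site's PSSM score is the sum
of entries over the window; positions outside the sequence and 'X' letters
contribute nothing.

The structural susceptibility score and the PSSM score are fused with a
two-feature Gaussian naive Bayes classifier: per class, each score gets a
sample mean and variance, and the posterior follows Bayes' rule with class
priors. This combines "where the fold permits cleavage" with "what the
protease prefers to bind".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "DEFAULT_WINDOW",
    "PSSM",
    "CombinerModel",
    "build_pssm",
    "pssm_score",
    "combiner_fit",
    "combiner_predict",
    "fused_cross_validate",
    "save_pssm",
    "load_pssm",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_WINDOW = ("P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'")


def _window_offsets(window) -> list[int]:
    """Offsets of window positions relative to P1 (offset 0)."""
    offsets = []
    for label in window:
        primed = label.endswith("'")
        rank = int(label[1:-1] if primed else label[1:])
        offsets.append(rank if primed else 1 - rank)
    return offsets


@dataclass
class PSSM:
    window: tuple[str, ...]
    matrix: np.ndarray  # 20 x len(window), bits
    alpha: float
    background: dict[str, float]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(AMINO_ACIDS), len(self.window)):
            raise ValueError("matrix shape does not match alphabet x window")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite PSSM entries")

    def entry(self, aa: str, position: str) -> float:
        return float(self.matrix[AMINO_ACIDS.index(aa), self.window.index(position)])


def build_pssm(
    peptides: list[str],
    alpha: float = 1.0,
    background: dict[str, float] | None = None,
    window=DEFAULT_WINDOW,
) -> PSSM:
    """Log2-odds PSSM from aligned cleavage-site window peptides.

    Peptides must span the window exactly; 'X' letters are skipped per column
    (they do not count toward ``N_j``).
    """
    if not peptides:
        raise ValueError("at least one peptide required to build a PSSM")
    window = tuple(window)
    w = len(window)
    for pep in peptides:
        if len(pep) != w:
            raise ValueError(f"peptide {pep!r} does not span the {w}-position window")
    if background is None:
        background = {a: 1.0 / len(AMINO_ACIDS) for a in AMINO_ACIDS}
    counts = np.zeros((len(AMINO_ACIDS), w))
    for pep in peptides:
        for j, letter in enumerate(pep.upper()):
            if letter == "X":
                continue
            try:
                counts[AMINO_ACIDS.index(letter), j] += 1
            except ValueError:
                raise ValueError(f"unknown amino-acid letter {letter!r}") from None
    matrix = np.zeros_like(counts)
    for j in range(w):
        n_j = counts[:, j].sum()
        for i, a in enumerate(AMINO_ACIDS):
            b_a = background[a]
            matrix[i, j] = math.log2(((counts[i, j] + alpha * b_a) / (n_j + alpha)) / b_a)
    return PSSM(window=window, matrix=matrix, alpha=alpha, background=dict(background))


def pssm_score(pssm: PSSM, sequence: str, p1_index: int) -> float:
    """Sum of PSSM entries for a candidate site, in bits.

    ``p1_index`` is 1-based in ``sequence``. Window positions falling outside
    the sequence, and 'X' letters, contribute 0.
    """
    if not 1 <= p1_index <= len(sequence):
        raise ValueError(f"p1_index {p1_index} outside sequence of length {len(sequence)}")
    i0 = p1_index - 1
    total = 0.0
    for j, offset in enumerate(_window_offsets(pssm.window)):
        i = i0 + offset
        if not 0 <= i < len(sequence):
            continue
        letter = sequence[i].upper()
        if letter == "X" or letter not in AMINO_ACIDS:
            continue
        total += pssm.matrix[AMINO_ACIDS.index(letter), j]
    return float(total)


# ---------------------------------------------------------------------------
# Gaussian naive Bayes fusion of structural and specificity scores
# ---------------------------------------------------------------------------

_VAR_FLOOR = 1e-9


@dataclass
class CombinerModel:
    means: dict[int, np.ndarray] = field(default_factory=dict)  # class -> (2,)
    variances: dict[int, np.ndarray] = field(default_factory=dict)
    priors: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.priors and not math.isclose(sum(self.priors.values()), 1.0):
            raise ValueError("class priors must sum to 1")


def combiner_fit(
    structural_scores: np.ndarray,
    pssm_scores: np.ndarray,
    labels: np.ndarray,
) -> CombinerModel:
    """Per-class Gaussian parameters for the two scores, plus class priors."""
    X = np.column_stack([structural_scores, pssm_scores]).astype(float)
    y = np.asarray(labels).astype(int)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite scores")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("both classes (0 and 1) must be present")
    model = CombinerModel()
    for c in (0, 1):
        Xc = X[y == c]
        model.means[c] = Xc.mean(axis=0)
        model.variances[c] = np.maximum(Xc.var(axis=0), _VAR_FLOOR)
        model.priors[c] = len(Xc) / len(X)
    return model


def _log_gauss(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    return -0.5 * (np.log(2 * np.pi * var) + (x - mean) ** 2 / var).sum(axis=-1)


def combiner_predict(
    model: CombinerModel,
    structural_score: np.ndarray | float,
    pssm_score_value: np.ndarray | float,
) -> np.ndarray | float:
    """Posterior probability of the cleaved class given both scores."""
    if not model.priors:
        raise RuntimeError("combiner model not fitted")
    x = np.column_stack([np.atleast_1d(structural_score),
                         np.atleast_1d(pssm_score_value)]).astype(float)
    log_post = np.stack(
        [np.log(model.priors[c]) + _log_gauss(x, model.means[c], model.variances[c])
         for c in (0, 1)], axis=1,
    )
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    out = post[:, 1]
    return float(out[0]) if np.isscalar(structural_score) else out


# ---------------------------------------------------------------------------
# Fused cross-validation (structural score + PSSM score)
# ---------------------------------------------------------------------------

def fused_cross_validate(
    table: pd.DataFrame,
    feature_columns: list[str],
    sequences: dict[str, str],
    pssm: PSSM,
    k: int = 10,
    neg_ratio: float | str = 1.0,
    seed: int = 0,
    source_kind: str = "experimental",
    bfactor_mode: str = "per_structure",
) -> dict:
    """Grouped CV of the structure-only, PSSM-only, and fused scorers.

    Per fold, the structural LDA model and the two-feature naive-Bayes
    combiner are fitted on training structures only; all three scores are
    evaluated on the full test fold. Returns mean AUC per scorer.
    """
    from .models import LDAScorer, cross_validate as _cv  # noqa: F401 (shared protocol)
    from .models import roc_auc
    from .dataset import group_kfold
    from .features import build_feature_vectors, fit_normalization

    pos_in_chain = table.groupby(["structure_id", "chain_id"]).cumcount() + 1
    pssm_col = np.array([
        pssm_score(pssm, sequences[sid], int(p))
        for sid, p in zip(table["structure_id"], pos_in_chain)
    ])
    table = table.assign(pssm_score=pssm_col)
    rng = np.random.default_rng(seed)
    aucs = {"structural": [], "pssm": [], "fused": []}
    for train_idx, test_idx in group_kfold(table["group"].to_numpy(), k=k, seed=seed):
        train, test = table.iloc[train_idx], table.iloc[test_idx]
        if train["label"].nunique() < 2 or test["label"].nunique() < 2:
            continue
        ok = train["complete"].to_numpy(dtype=bool)
        raw = {"rel_acc": train.loc[ok, "rel_acc_raw"].to_numpy(),
               "loop_len": train.loc[ok, "loop_len_raw"].to_numpy()}
        if bfactor_mode == "per_corpus":
            raw["bfactor"] = train.loc[ok, "bfactor_raw"].to_numpy()
        bounds = fit_normalization(raw)

        def _norm(sub: pd.DataFrame) -> pd.DataFrame:
            normed = build_feature_vectors(sub, bounds, source_kind=source_kind,
                                           bfactor_mode=bfactor_mode)
            keep = sub["complete"].to_numpy(dtype=bool)
            normed = normed[normed["complete"]].copy()
            normed["label"] = sub.loc[keep, "label"].to_numpy()
            normed["pssm_score"] = sub.loc[keep, "pssm_score"].to_numpy()
            return normed

        norm_train, norm_test = _norm(train), _norm(test)
        pos = norm_train[norm_train["label"] == 1]
        neg = norm_train[norm_train["label"] == 0]
        if neg_ratio != "all":
            n_neg = min(int(round(float(neg_ratio) * len(pos))), len(neg))
            take = rng.choice(len(neg), size=n_neg, replace=False)
            neg = neg.iloc[np.sort(take)]
        fit_df = pd.concat([pos, neg], ignore_index=True)
        scorer = LDAScorer().fit(fit_df[feature_columns].to_numpy(),
                                 fit_df["label"].to_numpy())
        struct_train = scorer.score(fit_df[feature_columns].to_numpy())
        struct_test = scorer.score(norm_test[feature_columns].to_numpy())
        combiner = combiner_fit(struct_train, fit_df["pssm_score"].to_numpy(),
                                fit_df["label"].to_numpy())
        fused_test = combiner_predict(combiner, struct_test,
                                      norm_test["pssm_score"].to_numpy())
        y = norm_test["label"].to_numpy()
        aucs["structural"].append(roc_auc(struct_test, y).auc)
        aucs["pssm"].append(roc_auc(norm_test["pssm_score"].to_numpy(), y).auc)
        aucs["fused"].append(roc_auc(fused_test, y).auc)
    if not aucs["fused"]:
        raise ValueError("no usable fold")
    return {name: float(np.mean(vals)) for name, vals in aucs.items()} | {
        "fold_aucs": aucs, "k": k, "seed": seed,
    }


# ---------------------------------------------------------------------------
# Serialization: TSV matrix + JSON sidecar
# ---------------------------------------------------------------------------

def save_pssm(pssm: PSSM, tsv_path: str | Path) -> None:
    tsv_path = Path(tsv_path)
    df = pd.DataFrame(pssm.matrix, index=list(AMINO_ACIDS), columns=list(pssm.window))
    df.to_csv(tsv_path, sep="\t", index_label="aa", float_format="%.6f")
    sidecar = {
        "alpha": pssm.alpha,
        "background": pssm.background,
        "window": list(pssm.window),
    }
    with open(tsv_path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_pssm(tsv_path: str | Path) -> PSSM:
    tsv_path = Path(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t", index_col="aa")
    with open(tsv_path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    df = df.reindex(list(AMINO_ACIDS))
    return PSSM(
        window=tuple(sidecar["window"]),
        matrix=df[list(sidecar["window"])].to_numpy(),
        alpha=float(sidecar["alpha"]),
        background={k: float(v) for k, v in sidecar["background"].items()},
    )
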