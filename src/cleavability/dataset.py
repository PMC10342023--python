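"""Mapping proteolytic events onto structures and assembling training sets.

A proteolytic event is the triple (substrate identifier, 1-based P1 position
in the substrate sequence, protease MEROPS code); in Schechter-Berger
notation P1 is the residue immediately N-terminal of the cleaved bond, and
the structural features of the P1 residue represent the bond. Events are
mapped onto structure residues through a global sequence alignment of the
substrate and structure-derived sequences; sites landing in unresolved
(disordered) regions are rejected, which in practice removes a large share
of events. A configurable burial filter then stands in for manual curation:
when several cleavages from one publication sit predominantly in the
hydrophobic core, the whole group is dropped as a likely artifact of
cleavage after loss of the native fold.

Positives are the mapped P1 residues; the negative pool is every other
residue with a complete feature vector in the same structures, sampled at a
configurable positives:negatives ratio. Cross-validation folds partition
structures (groups), so peptide bonds of one protein never straddle a
train/test boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "CleavageEvent",
    "MappedSite",
    "Rejection",
    "AlignmentResult",
    "global_align",
    "map_event",
    "curation_filter",
    "build_dataset",
    "group_kfold",
    "events_per_protein",
    "read_events_tsv",
    "read_fasta",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class CleavageEvent:
    """One experimentally observed proteolytic event."""

    substrate_id: str
    p1_pos: int  # 1-based position of P1 in the substrate sequence
    protease_code: str = ""
    source_ref: str = ""

    def __post_init__(self) -> None:
        if self.p1_pos < 1:
            raise ValueError("p1_pos is 1-based and must be >= 1")


@dataclass(frozen=True)
class MappedSite:
    """A cleavage event located on a structure residue."""

    structure_id: str
    chain_id: str
    residue_index: int  # 0-based index into the chain's residue list
    event: CleavageEvent


@dataclass(frozen=True)
class Rejection:
    event: CleavageEvent
    reason: str


@dataclass
class AlignmentResult:
    """Global alignment as a monotone partial map between positions."""

    posmap: dict[int, int | None]  # 0-based substrate index -> structure index or None
    score: float
    identity: float  # fraction identical over aligned (non-gap) columns
    aligned_a: str
    aligned_b: str


def global_align(
    seq_a: str,
    seq_b: str,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
    identity_warn: float = 0.9,
) -> AlignmentResult:
    """Needleman-Wunsch global alignment of substrate vs structure sequence.

    Affine gaps (first gap residue ``gap_open``, each further ``gap_extend``),
    BLOSUM62 substitution scores, deterministic traceback preferring diagonal,
    then up (gap in ``seq_b``), then left. Warns when percent identity falls
    below ``identity_warn``, mirroring the >=90%-identity gate used when
    structures are assigned to substrates.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    n, m = len(seq_a), len(seq_b)
    neg = -np.inf

    def sub(a: str, b: str) -> float:
        try:
            return float(_BLOSUM62[a, b])
        except (KeyError, IndexError):
            return float(_BLOSUM62["X", "X"])

    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in seq_b: seq_a residue unmatched ("up")
    Y = np.full((n + 1, m + 1), neg)  # gap in seq_a ("left")
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub(seq_a[i - 1], seq_b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)

    # traceback, preferring diagonal, then up, then left at every step
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][n, m])
    # stable preference on ties:
    for cand in ("M", "X", "Y"):
        if {"M": M, "X": X, "Y": Y}[cand][n, m] == {"M": M, "X": X, "Y": Y}[state][n, m]:
            state = cand
            break
    aligned_a: list[str] = []
    aligned_b: list[str] = []
    posmap: dict[int, int | None] = {}
    while i > 0 or j > 0:
        if state == "M":
            s = sub(seq_a[i - 1], seq_b[j - 1])
            target = M[i, j] - s
            aligned_a.append(seq_a[i - 1])
            aligned_b.append(seq_b[j - 1])
            posmap[i - 1] = j - 1
            i, j = i - 1, j - 1
            for cand, mat in (("M", M), ("X", X), ("Y", Y)):
                if np.isclose(mat[i, j], target):
                    state = cand
                    break
        elif state == "X":
            aligned_a.append(seq_a[i - 1])
            aligned_b.append("-")
            posmap[i - 1] = None
            target = X[i, j]
            i -= 1
            if np.isclose(M[i, j] + gap_open, target):
                state = "M"
            elif np.isclose(X[i, j] + gap_extend, target):
                state = "X"
            else:
                state = "Y"
        else:
            aligned_a.append("-")
            aligned_b.append(seq_b[j - 1])
            target = Y[i, j]
            j -= 1
            if np.isclose(M[i, j] + gap_open, target):
                state = "M"
            elif np.isclose(Y[i, j] + gap_extend, target):
                state = "Y"
            else:
                state = "X"
        if i == 0 and j > 0 and state == "M":
            state = "Y"
        if j == 0 and i > 0 and state == "M":
            state = "X"
    aligned_a.reverse()
    aligned_b.reverse()
    score = float(max(M[n, m], X[n, m], Y[n, m]))
    pairs = [(a, b) for a, b in zip(aligned_a, aligned_b) if a != "-" and b != "-"]
    identity = sum(a == b for a, b in pairs) / len(pairs) if pairs else 0.0
    if identity < identity_warn:
        warnings.warn(
            f"substrate/structure sequence identity {identity:.1%} below "
            f"{identity_warn:.0%}", stacklevel=2,
        )
    return AlignmentResult(posmap, score, identity, "".join(aligned_a), "".join(aligned_b))


def map_event(
    event: CleavageEvent,
    alignment: AlignmentResult,
    substrate_seq: str,
    structure_seq: str,
    structure_id: str,
    chain_id: str,
    complete: np.ndarray | None = None,
    allow_mismatch: bool = False,
) -> MappedSite | Rejection:
    """Locate an event's P1 residue on the structure, or reject it.

    Rejection reasons: ``unresolved`` (P1 aligned to a gap — a disordered or
    unmodelled region), ``mismatch`` (the aligned structure residue differs
    from the substrate letter at P1; accepted when ``allow_mismatch``),
    ``incomplete_features`` (the residue has no usable feature vector).
    """
    if event.p1_pos > len(substrate_seq):
        raise ValueError(
            f"p1_pos {event.p1_pos} beyond substrate length {len(substrate_seq)}"
        )
    j = alignment.posmap.get(event.p1_pos - 1)
    if j is None:
        return Rejection(event, "unresolved")
    if structure_seq[j] != substrate_seq[event.p1_pos - 1] and not allow_mismatch:
        return Rejection(event, "mismatch")
    if complete is not None and not complete[j]:
        return Rejection(event, "incomplete_features")
    return MappedSite(structure_id, chain_id, j, event)


def curation_filter(
    sites: list[MappedSite],
    rel_acc: list[float],
    burial_threshold: float = 0.05,
    core_fraction: float = 0.5,
    min_group: int = 2,
) -> tuple[list[MappedSite], list[MappedSite], list[str]]:
    """Drop publication groups whose cleavages sit predominantly in the core.

    Multiple cleavages reported by one publication (``source_ref``) that lie
    mostly at relative accessibility below ``burial_threshold`` suggest the
    substrate lost its fold during the experiment; such groups are excluded
    wholesale. Single-site groups are never excluded. Returns (retained,
    excluded, log); every removal is justified by a log line.
    """
    if len(sites) != len(rel_acc):
        raise ValueError("one rel_acc value per mapped site required")
    groups: dict[str, list[int]] = {}
    for idx, site in enumerate(sites):
        groups.setdefault(site.event.source_ref, []).append(idx)
    retained: list[MappedSite] = []
    excluded: list[MappedSite] = []
    log: list[str] = []
    for ref, idxs in groups.items():
        buried = [i for i in idxs if rel_acc[i] < burial_threshold]
        frac = len(buried) / len(idxs)
        if len(idxs) >= min_group and frac > core_fraction:
            excluded.extend(sites[i] for i in idxs)
            log.append(
                f"excluded source {ref!r}: {len(buried)}/{len(idxs)} sites buried "
                f"(rel_acc < {burial_threshold}), fraction {frac:.2f} > {core_fraction}"
            )
        else:
            retained.extend(sites[i] for i in idxs)
    return retained, excluded, log


def build_dataset(
    features: pd.DataFrame,
    sites: list[MappedSite],
    feature_columns: list[str],
    neg_ratio: float | str = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Labeled training table: all positives plus sampled negatives.

    ``features`` is the concatenated normalized feature table over all
    structures (one row per residue, ``complete`` column set). Positives are
    the mapped P1 residues; the negative pool is every other complete residue.
    ``neg_ratio`` negatives per positive are drawn without replacement with
    the given seed (``"all"`` keeps the entire pool). The result carries
    ``label`` and ``group`` (= structure_id) columns and is bit-reproducible
    for a fixed seed.
    """
    if not sites:
        raise ValueError("at least one mapped site (positive example) required")
    df = features.reset_index(drop=True)
    pos_keys = {(s.structure_id, s.chain_id, s.residue_index) for s in sites}
    res_index = df.groupby(["structure_id", "chain_id"]).cumcount()
    keys = list(zip(df["structure_id"], df["chain_id"], res_index))
    is_pos = np.array([k in pos_keys for k in keys])
    usable = df["complete"].to_numpy(dtype=bool)
    if not is_pos[usable].any():
        raise ValueError("no positive example has a complete feature vector")
    pos_df = df[is_pos & usable]
    neg_pool = df[~is_pos & usable]
    n_pos = len(pos_df)
    if neg_ratio == "all":
        neg_df = neg_pool
    else:
        n_neg = int(round(float(neg_ratio) * n_pos))
        if n_neg > len(neg_pool):
            raise ValueError(
                f"negative pool ({len(neg_pool)}) smaller than requested {n_neg}"
            )
        rng = np.random.default_rng(seed)
        take = rng.choice(len(neg_pool), size=n_neg, replace=False)
        neg_df = neg_pool.iloc[np.sort(take)]
    out = pd.concat([pos_df.assign(label=1), neg_df.assign(label=0)], ignore_index=True)
    out["group"] = out["structure_id"]
    id_cols = ["structure_id", "chain_id", "seq_num", "icode", "res_name", "one_letter"]
    out = out[id_cols + list(feature_columns) + ["label", "group"]]
    if out.duplicated(subset=["structure_id", "chain_id", "seq_num", "icode"]).any():
        raise ValueError("duplicate residue rows in dataset")
    return out


def group_kfold(groups: np.ndarray, k: int = 10, seed: int = 0):
    """Seeded grouped k-fold: folds partition the set of groups.

    Unique groups are shuffled with the seed and split into k blocks whose
    sizes differ by at most one group. Yields (train_idx, test_idx) pairs of
    row indices; no group appears on both sides of a fold.
    """
    groups = np.asarray(groups)
    unique = np.unique(groups)
    if len(unique) < k:
        raise ValueError(f"need at least k={k} groups, got {len(unique)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    blocks = np.array_split(unique[order], k)
    for block in blocks:
        test_mask = np.isin(groups, block)
        yield np.flatnonzero(~test_mask), np.flatnonzero(test_mask)


def events_per_protein(events: list[CleavageEvent]) -> tuple[float, float]:
    """(mean, median) number of events per unique substrate."""
    if not events:
        raise ValueError("no events")
    counts = pd.Series([e.substrate_id for e in events]).value_counts()
    return float(counts.mean()), float(counts.median())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_events_tsv(path: str | Path) -> list[CleavageEvent]:
    """Event table: columns substrate_id, p1_pos, protease_code, source_ref."""
    df = pd.read_csv(path, sep="\t", dtype={"substrate_id": str})
    events = []
    for row in df.itertuples(index=False):
        events.append(
            CleavageEvent(
                substrate_id=str(row.substrate_id),
                p1_pos=int(row.p1_pos),
                protease_code=str(getattr(row, "protease_code", "")),
                source_ref=str(getattr(row, "source_ref", "")),
            )
        )
    return events


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
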