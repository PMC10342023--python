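"""Synthetic structures, planted cleavage events, and motif peptide sets.

The generator emulates the inputs of the real pipeline so every stage can be
exercised without downloads: toy single-chain backbones (N, CA, C, O only)
built from ideal peptide geometry, per-residue B-factor profiles, cleavage
events planted by a known feature-dependent probability model, and
fixed-width cleavage-window peptides drawn from per-position amino-acid
weights.

Backbones are grown residue by residue with the natural-extension reference
frame using ideal bond lengths and angles, so consecutive CA-CA distances are
the canonical 3.8 A. Helical runs use alpha-helix torsions (phi -57, psi
-47; ~1.5 A rise per residue along the axis), strand runs extended torsions,
and loop runs seeded random coil torsions. Ground-truth 3-state secondary
structure accompanies every toy structure so feature logic can be tested
independently of the geometric assigner.

Cleavage is planted per residue as a Bernoulli draw with probability
``logistic(beta . features + intercept)``; the default coefficients weight
solvent accessibility, loop length, B-factor, and the terminal flag
positively and the secondary-structure binaries not at all, the qualitative
profile expected of structural susceptibility to proteolysis. The true
probabilities are returned so the Bayes-optimal AUC of the generating model
can bound any fitted model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import protein_letters_1to3

from .dataset import CleavageEvent
from .features import build_feature_vectors, compute_raw_features, fit_normalization
from .specificity import AMINO_ACIDS, PSSM, build_pssm, pssm_score
from .structure_io import AtomRecord, ResidueRecord, StructureModel

__all__ = [
    "ToySpec",
    "PlantModel",
    "DEFAULT_PLANT",
    "DEFAULT_MOTIF_WEIGHTS",
    "generate_toy_structure",
    "plant_cleavage_events",
    "generate_motif_peptides",
    "SimulatedCorpus",
    "generate_corpus",
    "random_segments",
]

_ONE_TO_THREE = {k: v.upper() for k, v in protein_letters_1to3.items()}

# ideal backbone geometry (bond lengths A, angles deg)
_R_N_CA, _R_CA_C, _R_C_N, _R_C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.0, 116.2, 121.7, 120.5
_OMEGA = 180.0

_TORSIONS = {"helix": (-57.0, -47.0), "strand": (-135.0, 135.0)}


@dataclass
class ToySpec:
    """Plan for one toy chain: ordered (ss3 state, run length) segments."""

    segments: list[tuple[str, int]]
    structure_id: str = "toy"
    chain_id: str = "A"
    bfactor_base: float = 15.0
    bfactor_loop_bonus: float = 10.0
    bfactor_noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for state, length in self.segments:
            if state not in ("helix", "strand", "loop"):
                raise ValueError(f"unknown segment state {state!r}")
            if length < 1:
                raise ValueError("segment run lengths must be >= 1")

    @property
    def length(self) -> int:
        return sum(length for _, length in self.segments)

    @property
    def ss3(self) -> list[str]:
        return [state for state, length in self.segments for _ in range(length)]


@dataclass
class PlantModel:
    """Logistic cleavage-probability model over feature-vector components."""

    beta: dict[str, float]
    intercept: float
    pssm_weight: float = 0.0  # weight on the true motif score, bits^-1
    seed: int = 0


#: Default planted effects: exposed, long-loop, flexible, terminal regions are
#: cleavage-prone; secondary-structure binaries carry no direct effect. The
#: intercept sets the expected event density near 2-3 cleavages per ~60-residue
#: structure, the density observed in curated proteolytic-event collections.
DEFAULT_PLANT = PlantModel(
    beta={"rel_acc": 4.0, "loop_len_norm": 2.5, "bfactor_norm": 2.0, "terminus": 1.5},
    intercept=-8.6,
)


def _next_atom(a, b, c, r, theta_deg, chi_deg):
    """Place the next atom at distance r from c, angle theta at c, torsion chi."""
    theta, chi = math.radians(theta_deg), math.radians(chi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    return c + r * (-math.cos(theta) * bc
                    + math.sin(theta) * (math.cos(chi) * m + math.sin(chi) * n))


def _loop_torsions(rng: np.random.Generator) -> tuple[float, float]:
    """Coil torsions: polyproline-II / extended region, away from the helix basin."""
    phi = rng.uniform(-160.0, -60.0)
    psi = rng.uniform(60.0, 175.0)
    return phi, psi


def _pdb_line(serial, name, res_name, chain_id, seq_num, xyz, occ, bf, element):
    return (
        f"ATOM  {serial:5d}  {name:<3s} {res_name:>3s} {chain_id}{seq_num:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{bf:6.2f}"
        f"          {element:>2s}"
    )


def generate_toy_structure(spec: ToySpec) -> tuple[StructureModel, list[str]]:
    """Build a toy backbone structure and its ground-truth 3-state labels."""
    rng = np.random.default_rng(spec.seed)
    ss3 = spec.ss3
    n = len(ss3)
    sequence = rng.choice(list(AMINO_ACIDS), size=n)

    torsions = []
    for state in ss3:
        if state in _TORSIONS:
            torsions.append(_TORSIONS[state])
        else:
            torsions.append(_loop_torsions(rng))

    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_R_N_CA, 0.0, 0.0)
    ang = math.radians(_ANG_N_CA_C)
    C[0] = CA[0] + _R_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n):
        psi_prev = torsions[i - 1][1]
        N[i] = _next_atom(N[i - 1], CA[i - 1], C[i - 1], _R_C_N, _ANG_CA_C_N, psi_prev)
        CA[i] = _next_atom(CA[i - 1], C[i - 1], N[i], _R_N_CA, _ANG_C_N_CA, _OMEGA)
        C[i] = _next_atom(C[i - 1], N[i], CA[i], _R_CA_C, _ANG_N_CA_C, torsions[i][0])
    for i in range(n):
        O[i] = _next_atom(N[i], CA[i], C[i], _R_C_O, _ANG_CA_C_O, torsions[i][1] - 180.0)

    bfactors = (
        spec.bfactor_base
        + spec.bfactor_loop_bonus * np.array([s == "loop" for s in ss3], dtype=float)
        + rng.normal(0.0, spec.bfactor_noise_sd, size=n)
    )
    bfactors = np.round(np.clip(bfactors, 0.01, 999.0), 2)

    residues = []
    serial = 1
    for i in range(n):
        res_name = _ONE_TO_THREE[sequence[i]]
        residue = ResidueRecord(spec.chain_id, i + 1, "", res_name)
        for name, xyz, element in (("N", N[i], "N"), ("CA", CA[i], "C"),
                                   ("C", C[i], "C"), ("O", O[i], "O")):
            xyz = np.round(xyz, 3)
            line = _pdb_line(serial, name, res_name, spec.chain_id, i + 1, xyz,
                             1.0, bfactors[i], element)
            residue.atoms.append(
                AtomRecord(name=name, element=element, coords=xyz, occupancy=1.0,
                           tempfactor=bfactors[i], raw_line=line)
            )
            serial += 1
        residues.append(residue)
    structure = StructureModel(
        structure_id=spec.structure_id,
        source_kind="experimental",
        chains={spec.chain_id: residues},
    )
    return structure, ss3


def plant_cleavage_events(
    features: pd.DataFrame,
    plant: PlantModel,
    sequences: dict[str, str] | None = None,
    motif_pssm: PSSM | None = None,
) -> tuple[list[CleavageEvent], np.ndarray, np.ndarray]:
    """Draw cleavage events from the logistic generating model.

    ``features`` is a normalized per-residue feature table (one structure or a
    whole corpus; rows in residue order within each structure). When
    ``motif_pssm`` is given, ``plant.pssm_weight`` times the residue's motif
    score (from the structure's sequence) joins the linear predictor, so
    cleavage depends on both structure and sequence.

    Returns (events, labels, true probabilities), row-aligned with
    ``features``. Incomplete rows get probability 0 and never host an event.
    """
    rng = np.random.default_rng(plant.seed)
    z = np.full(len(features), plant.intercept, dtype=float)
    for name, coef in plant.beta.items():
        if name not in features.columns:
            continue
        z += coef * features[name].to_numpy(dtype=float)
    if motif_pssm is not None and plant.pssm_weight != 0.0:
        if sequences is None:
            raise ValueError("sequences required when planting a motif effect")
        pos_in_chain = features.groupby(["structure_id", "chain_id"]).cumcount() + 1
        motif = np.array([
            pssm_score(motif_pssm, sequences[sid], int(p))
            for sid, p in zip(features["structure_id"], pos_in_chain)
        ])
        z += plant.pssm_weight * motif
    probs = 1.0 / (1.0 + np.exp(-z))
    complete = features["complete"].to_numpy(dtype=bool)
    probs = np.where(complete, probs, 0.0)
    labels = rng.binomial(1, probs)
    events = []
    pos_in_chain = features.groupby(["structure_id", "chain_id"]).cumcount() + 1
    for (sid, p1), cleaved in zip(zip(features["structure_id"], pos_in_chain), labels):
        if cleaved:
            events.append(CleavageEvent(substrate_id=str(sid), p1_pos=int(p1),
                                        protease_code="SIM", source_ref=f"sim:{sid}"))
    return events, labels, probs


def generate_motif_peptides(weights: np.ndarray, n: int, seed: int = 0) -> list[str]:
    """Draw fixed-width window peptides from per-position letter distributions.

    ``weights`` has shape (window, 20) in the order of :data:`AMINO_ACIDS`;
    each row must sum to 1.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or weights.shape[1] != len(AMINO_ACIDS):
        raise ValueError("weights must be (window, 20)")
    if not np.allclose(weights.sum(axis=1), 1.0):
        raise ValueError("each position's weights must sum to 1")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    cols = [rng.choice(letters, size=n, p=weights[j]) for j in range(len(weights))]
    return ["".join(row) for row in zip(*cols)]


def _motif_weights() -> np.ndarray:
    """Default 8-position motif: trypsin-like K/R preference at P1, small at P1'."""
    w = np.full((8, len(AMINO_ACIDS)), 1.0 / len(AMINO_ACIDS))
    p1 = 3  # P4 P3 P2 P1 | P1' P2' P3' P4'
    w[p1] = 0.01
    w[p1, AMINO_ACIDS.index("K")] = 0.41
    w[p1, AMINO_ACIDS.index("R")] = 0.41
    w[p1] /= w[p1].sum()
    p1p = 4
    w[p1p] = 0.03
    for a in "GSA":
        w[p1p, AMINO_ACIDS.index(a)] = 0.16
    w[p1p] /= w[p1p].sum()
    return w


DEFAULT_MOTIF_WEIGHTS = _motif_weights()


def random_segments(rng: np.random.Generator, min_len: int = 40,
                    max_len: int = 80) -> list[tuple[str, int]]:
    """A plausible chain plan: terminal loops flanking alternating elements."""
    target = int(rng.integers(min_len, max_len + 1))
    segments: list[tuple[str, int]] = [("loop", int(rng.integers(2, 9)))]
    total = segments[0][1]
    while total < target:
        state = "helix" if rng.random() < 0.5 else "strand"
        length = int(rng.integers(4, 13) if state == "helix" else rng.integers(3, 9))
        segments.append((state, length))
        total += length
        loop_len = int(rng.integers(2, 11))
        segments.append(("loop", loop_len))
        total += loop_len
    return segments


@dataclass
class SimulatedCorpus:
    """A planted-signal corpus ready for training and evaluation."""

    structures: dict[str, StructureModel]
    ss3: dict[str, list[str]]
    sequences: dict[str, str]
    table: pd.DataFrame  # raw features + label + group, row per residue
    norm_table: pd.DataFrame  # corpus-normalized features used for planting
    events: list[CleavageEvent]
    true_probs: np.ndarray
    plant: PlantModel
    motif_pssm: PSSM | None = None
    seed: int = 0
    feature_columns: tuple[str, ...] = field(default_factory=tuple)


def generate_corpus(
    n_structures: int = 200,
    seed: int = 0,
    plant: PlantModel | None = None,
    with_motif: bool = False,
    min_len: int = 40,
    max_len: int = 80,
    sasa_n_points: int = 960,
) -> SimulatedCorpus:
    """Generate toy structures, compute real features, and plant cleavages.

    Features go through the actual pipeline (Shrake-Rupley accessibility on
    the toy coordinates, ground-truth secondary structure, B-factor profiles),
    corpus-level min-max normalization is fitted, and cleavage labels are
    drawn from the plant model on the normalized features. With
    ``with_motif=True`` the default trypsin-like motif also shapes cleavage
    (weight 0.25 per bit) and the generating PSSM is attached.
    """
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_structures + 2)
    if plant is None:
        plant = PlantModel(beta=dict(DEFAULT_PLANT.beta),
                           intercept=DEFAULT_PLANT.intercept,
                           pssm_weight=0.25 if with_motif else 0.0,
                           seed=int(child_seeds[-1]))
    structures: dict[str, StructureModel] = {}
    ss3_map: dict[str, list[str]] = {}
    sequences: dict[str, str] = {}
    raw_tables = []
    seg_rng = np.random.default_rng(int(child_seeds[-2]))
    for i in range(n_structures):
        sid = f"toy{i:04d}"
        spec = ToySpec(segments=random_segments(seg_rng, min_len, max_len),
                       structure_id=sid, seed=int(child_seeds[i]))
        structure, ss3 = generate_toy_structure(spec)
        structures[sid] = structure
        ss3_map[sid] = ss3
        sequences[sid] = "".join(r.one_letter for r in structure.chains["A"])
        raw_tables.append(compute_raw_features(structure, "A", ss3=ss3,
                                               sasa_n_points=sasa_n_points))
    raw = pd.concat(raw_tables, ignore_index=True)
    bounds = fit_normalization({
        "rel_acc": raw.loc[raw["complete"], "rel_acc_raw"].to_numpy(),
        "loop_len": raw.loc[raw["complete"], "loop_len_raw"].to_numpy(),
    })
    norm = build_feature_vectors(raw, bounds)
    motif = build_pssm_from_weights(DEFAULT_MOTIF_WEIGHTS) if with_motif else None
    events, labels, probs = plant_cleavage_events(norm, plant, sequences=sequences,
                                                  motif_pssm=motif)
    table = raw.copy()
    table["label"] = labels
    table["group"] = table["structure_id"]
    from .features import FEATURE_COLUMNS
    return SimulatedCorpus(
        structures=structures, ss3=ss3_map, sequences=sequences, table=table,
        norm_table=norm, events=events, true_probs=probs, plant=plant,
        motif_pssm=motif, seed=seed, feature_columns=FEATURE_COLUMNS,
    )


def build_pssm_from_weights(weights: np.ndarray) -> PSSM:
    """The exact log2-odds PSSM of a per-position weight model (no sampling)."""
    weights = np.asarray(weights, dtype=float)
    background = 1.0 / len(AMINO_ACIDS)
    matrix = np.log2(weights.T / background)
    from .specificity import DEFAULT_WINDOW
    return PSSM(window=DEFAULT_WINDOW, matrix=matrix, alpha=0.0,
                background={a: background for a in AMINO_ACIDS})
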