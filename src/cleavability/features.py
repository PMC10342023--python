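"""Per-residue structural predictors of proteolytic susceptibility.

Six predictors are computed for every resolved standard residue of a chain:

``rel_acc``
    Relative solvent accessibility: absolute accessible surface area divided by
    the residue's maximal possible area (Tien et al. 2013 theoretical values),
    then min-max scaled over the training corpus.
``ss_helix`` / ``ss_strand`` / ``ss_loop``
    One-hot 3-state secondary structure collapsed from the DSSP 8-state
    alphabet (H,G,I -> helix; E,B -> strand; T,S,'-' -> loop).
``bfactor_norm``
    Crystallographic B-factor, min-max scaled within each structure (B-factor
    scales are not comparable across crystals). Absent for predicted models.
``loop_len_norm``
    Length of the maximal loop run containing the residue, assigned to every
    residue of the loop (long protruded loops are cleavage-prone along their
    whole length); min-max scaled over the corpus; 0 outside loops.
``terminus``
    Binary flag for the flexible, unstructured N-/C-terminal segments that
    precede the first (follow the last) regular secondary-structure element,
    skipping elements too short to anchor the chain.
``confidence_norm``
    For predicted models only: the per-residue confidence score (pLDDT-style,
    0-100) divided by 100. The scale is already absolute, so no corpus fit.

Solvent accessibility and secondary structure come from a DSSP output file
when one is supplied; otherwise accessibility falls back on the built-in
Shrake-Rupley implementation and secondary structure on a Kabsch-Sander
hydrogen-bond assignment, so the pipeline runs without external binaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .structure_io import DsspRecord, StructureModel

__all__ = [
    "SS3_STATES",
    "FEATURE_COLUMNS",
    "NormalizationBounds",
    "max_asa",
    "shrake_rupley_sasa",
    "sasa_per_atom",
    "relative_accessibility",
    "ss8_to_ss3",
    "loop_length_feature",
    "termini_feature",
    "assign_ss3",
    "fit_normalization",
    "compute_raw_features",
    "build_feature_vectors",
    "feature_columns_for",
]

SS3_STATES = ("helix", "strand", "loop")

#: Final model features, in canonical order (experimental structures).
FEATURE_COLUMNS = (
    "rel_acc",
    "ss_helix",
    "ss_strand",
    "ss_loop",
    "bfactor_norm",
    "loop_len_norm",
    "terminus",
)

#: Van der Waals radii (A) for SASA; unknown elements are a configuration error.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "SE": 1.90}


def feature_columns_for(source_kind: str, use_confidence: bool = True) -> tuple[str, ...]:
    """Model feature set by structure kind.

    Predicted models have no experimental B-factor; they drop ``bfactor_norm``
    and (optionally) gain ``confidence_norm``.
    """
    if source_kind == "experimental":
        return FEATURE_COLUMNS
    cols = tuple(c for c in FEATURE_COLUMNS if c != "bfactor_norm")
    if use_confidence:
        cols = cols + ("confidence_norm",)
    return cols


def _load_max_asa() -> dict[str, float]:
    text = resources.files("cleavability.data").joinpath("max_asa_tien2013.tsv").read_text()
    table = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        name, value = line.split("\t")
        table[name] = float(value)
    return table


MAX_ASA = _load_max_asa()


def max_asa(res_name: str) -> float:
    """Theoretical maximum accessible surface area (A^2) of a residue type."""
    try:
        return MAX_ASA[res_name.upper()]
    except KeyError:
        raise KeyError(f"no maximum-ASA value for nonstandard residue {res_name!r}") from None


# ---------------------------------------------------------------------------
# Solvent accessibility (Shrake-Rupley with a golden-spiral point set)
# ---------------------------------------------------------------------------

def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa_per_atom(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area, A^2.

    Each atom's solvent-expanded sphere (radius + probe) is sampled with a
    fixed golden-spiral point set; the exposed-point fraction times the sphere
    area is the atom's contribution. Deterministic for fixed ``n_points``.
    """
    from scipy.spatial import cKDTree

    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n_atoms = len(coords)
    sphere = _golden_spiral(n_points)
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    cutoff = 2.0 * expanded.max()
    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + expanded[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], cutoff) if j != i]
        if neighbors:
            nb = np.asarray(neighbors)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            exposed_frac = 1.0 - buried.mean()
        else:
            exposed_frac = 1.0
        areas[i] = exposed_frac * 4.0 * np.pi * expanded[i] ** 2
    return areas


def shrake_rupley_sasa(
    structure: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> dict[str, np.ndarray]:
    """Per-residue absolute accessible surface area, by chain.

    Occlusion is computed over all atoms of the structure; atom areas are then
    summed per residue. Unknown elements raise a configuration error.
    """
    radii = {**VDW_RADII, **(radii or {})}
    atoms = []
    owners = []  # (chain_id, residue index within chain)
    for chain_id, residues in structure.chains.items():
        for ri, residue in enumerate(residues):
            for atom in residue.atoms:
                element = atom.element.upper()
                if element not in radii:
                    raise ValueError(
                        f"no van der Waals radius configured for element {element!r}"
                    )
                atoms.append((atom.coords, radii[element]))
                owners.append((chain_id, ri))
    coords = np.array([a[0] for a in atoms])
    r = np.array([a[1] for a in atoms])
    areas = sasa_per_atom(coords, r, probe_radius=probe_radius, n_points=n_points)
    out = {cid: np.zeros(len(res)) for cid, res in structure.chains.items()}
    for (chain_id, ri), area in zip(owners, areas):
        out[chain_id][ri] += area
    return out


def relative_accessibility(abs_acc: float, res_name: str) -> float:
    """Absolute ASA divided by the residue-type maximum, clamped to [0, 1]."""
    if abs_acc < 0:
        raise ValueError("absolute accessibility must be non-negative")
    return min(abs_acc / max_asa(res_name), 1.0)


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

_SS8_TO_SS3 = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "strand", "B": "strand",
    "T": "loop", "S": "loop", "-": "loop",
}


def ss8_to_ss3(ss8: str) -> str:
    """Collapse the DSSP 8-state code to helix/strand/loop."""
    try:
        return _SS8_TO_SS3[ss8]
    except KeyError:
        raise ValueError(f"unknown DSSP secondary-structure code {ss8!r}") from None


def _runs(seq: list[str]) -> list[tuple[int, int, str]]:
    """Maximal runs as (start, end_exclusive, state)."""
    runs = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            runs.append((start, i, seq[start]))
            start = i
    return runs


def loop_length_feature(ss3_seq: list[str]) -> np.ndarray:
    """Length of the surrounding maximal loop run, per residue; 0 off-loop.

    Long protruded loops concentrate cleavage sites, and the whole loop is
    flexible as a unit, so every residue of a loop carries the loop's length.
    """
    if not ss3_seq:
        raise ValueError("empty secondary-structure sequence")
    out = np.zeros(len(ss3_seq))
    for start, end, state in _runs(list(ss3_seq)):
        if state == "loop":
            out[start:end] = end - start
    return out


def termini_feature(
    ss3_seq: list[str],
    min_helix_run: int = 4,
    min_strand_run: int = 3,
) -> np.ndarray:
    """Binary flag for flexible N-/C-terminal segments.

    A residue is flagged when it lies before the first, or after the last,
    *qualifying* regular secondary-structure element — a helix run of at least
    ``min_helix_run`` residues or a strand run of at least ``min_strand_run``.
    Shorter regular elements near the ends do not anchor the chain and are
    treated as part of the unstructured terminus. A chain with no qualifying
    element is flagged throughout.
    """
    if not ss3_seq:
        raise ValueError("empty secondary-structure sequence")
    n = len(ss3_seq)
    qualifying = [
        (start, end)
        for start, end, state in _runs(list(ss3_seq))
        if (state == "helix" and end - start >= min_helix_run)
        or (state == "strand" and end - start >= min_strand_run)
    ]
    out = np.zeros(n)
    if not qualifying:
        out[:] = 1.0
        return out
    first_start = qualifying[0][0]
    last_end = qualifying[-1][1]
    out[:first_start] = 1.0
    out[last_end:] = 1.0
    return out


# --- Kabsch-Sander fallback assignment (used when no DSSP file is given) ---

_KS_Q = 0.084 * 332.0  # kcal/mol A, electrostatic H-bond model constant
_HBOND_CUTOFF = -0.5  # kcal/mol


def _hbond_matrix(residues) -> np.ndarray:
    """hb[d, a] = True when the N-H of residue d donates to the C=O of residue a."""
    n = len(residues)
    N = np.full((n, 3), np.nan)
    CA = np.full((n, 3), np.nan)
    C = np.full((n, 3), np.nan)
    O = np.full((n, 3), np.nan)
    for i, res in enumerate(residues):
        for name, arr in (("N", N), ("CA", CA), ("C", C), ("O", O)):
            atom = res.atom(name)
            if atom is not None:
                arr[i] = atom.coords
    # amide H estimated on the donor nitrogen, bisecting C(i-1)-N-CA
    H = np.full((n, 3), np.nan)
    for i in range(1, n):
        if np.isnan(N[i]).any() or np.isnan(C[i - 1]).any() or np.isnan(CA[i]).any():
            continue
        if residues[i].res_name == "PRO":
            continue  # proline has no amide hydrogen
        d1 = N[i] - C[i - 1]
        d2 = N[i] - CA[i]
        d1 /= np.linalg.norm(d1)
        d2 /= np.linalg.norm(d2)
        b = d1 + d2
        H[i] = N[i] + b / np.linalg.norm(b)

    hb = np.zeros((n, n), dtype=bool)
    for d in range(n):
        if np.isnan(H[d]).any() or np.isnan(N[d]).any():
            continue
        for a in range(n):
            if a == d or abs(a - d) < 2:
                continue
            if np.isnan(O[a]).any() or np.isnan(C[a]).any():
                continue
            r_on = np.linalg.norm(O[a] - N[d])
            r_ch = np.linalg.norm(C[a] - H[d])
            r_oh = np.linalg.norm(O[a] - H[d])
            r_cn = np.linalg.norm(C[a] - N[d])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue
            energy = _KS_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if energy < _HBOND_CUTOFF:
                hb[d, a] = True
    return hb


def assign_ss3(structure: StructureModel, chain_id: str) -> list[str]:
    """Three-state secondary structure from backbone hydrogen bonding.

    Kabsch-Sander electrostatic H-bond energies with the -0.5 kcal/mol
    threshold; minimal 4-turn and bridge pattern rules, collapsed straight to
    helix/strand/loop. A coarse stand-in for DSSP output: sufficient for the
    three-state features, not an 8-state reimplementation.
    """
    residues = structure.chain(chain_id)
    n = len(residues)
    hb = _hbond_matrix(residues)

    def turn4(i: int) -> bool:
        return i + 4 < n and hb[i + 4, i]

    ss = ["loop"] * n
    for i in range(1, n):
        if turn4(i - 1) and turn4(i):
            for k in range(i, min(i + 4, n)):
                ss[k] = "helix"
    for i in range(n):
        for j in range(i + 3, n):
            antiparallel = (hb[i, j] and hb[j, i]) or (
                i >= 1 and j + 1 < n and hb[i - 1, j + 1] and hb[j - 1, i + 1]
            )
            parallel = (j >= 1 and i + 1 < n and hb[j, i - 1] and hb[i + 1, j]) or (
                i >= 1 and j + 1 < n and hb[i, j - 1] and hb[j + 1, i]
            )
            if antiparallel or parallel:
                for k in (i, j):
                    if ss[k] == "loop":
                        ss[k] = "strand"
    return ss


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationBounds:
    """Per-feature (min, max) pairs fitted on a training corpus."""

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def apply(self, name: str, values: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds[name]
        return np.clip((np.asarray(values, dtype=float) - lo) / (hi - lo), 0.0, 1.0)

    def to_dict(self) -> dict:
        return {k: list(v) for k, v in self.bounds.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationBounds":
        return cls({k: (float(v[0]), float(v[1])) for k, v in d.items()})


def fit_normalization(values_by_feature: dict[str, np.ndarray]) -> NormalizationBounds:
    """Min-max bounds per feature over a fitting corpus.

    Raises a degenerate-bounds error when a feature is constant (max == min).
    """
    bounds = {}
    for name, values in values_by_feature.items():
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        if values.size < 2:
            raise ValueError(f"need at least 2 values to fit bounds for {name!r}")
        lo, hi = float(values.min()), float(values.max())
        if hi <= lo:
            raise ValueError(f"degenerate min-max bounds for constant feature {name!r}")
        bounds[name] = (lo, hi)
    return NormalizationBounds(bounds)


# ---------------------------------------------------------------------------
# Per-chain feature assembly
# ---------------------------------------------------------------------------

def compute_raw_features(
    structure: StructureModel,
    chain_id: str,
    dssp_records: list[DsspRecord] | None = None,
    ss3: list[str] | None = None,
    abs_acc: np.ndarray | None = None,
    sasa_n_points: int = 960,
) -> pd.DataFrame:
    """Unnormalized per-residue features for one chain.

    Secondary structure comes from, in order of precedence: ``ss3`` (explicit
    labels), ``dssp_records``, or the internal Kabsch-Sander assignment.
    Absolute accessibility comes from ``dssp_records``, ``abs_acc``, or the
    internal Shrake-Rupley calculation. Residues that are nonstandard or
    missing from the secondary-structure/accessibility source are kept in the
    table but flagged ``complete = False`` and excluded downstream.

    Columns: identification (structure_id, chain_id, seq_num, icode, res_name,
    one_letter), raw features (rel_acc_raw, ss3, bfactor_raw, loop_len_raw,
    terminus, confidence_raw), and ``complete``.
    """
    residues = structure.chain(chain_id)
    n = len(residues)
    missing = np.zeros(n, dtype=bool)

    if ss3 is None and dssp_records is None:
        ss3 = assign_ss3(structure, chain_id)
        acc_source = None
    elif ss3 is None:
        by_key = {(r.chain_id, r.seq_num, r.icode): r for r in dssp_records}
        ss3 = []
        acc_source = np.full(n, np.nan)
        for i, res in enumerate(residues):
            rec = by_key.get((res.chain_id, res.seq_num, res.icode))
            if rec is None:
                ss3.append("loop")
                missing[i] = True
            else:
                ss3.append(ss8_to_ss3(rec.ss8))
                acc_source[i] = rec.acc
    else:
        acc_source = None
    if len(ss3) != n:
        raise ValueError("secondary-structure labels do not match residue count")

    if abs_acc is not None:
        acc = np.asarray(abs_acc, dtype=float)
        if len(acc) != n:
            raise ValueError("accessibility values do not match residue count")
    elif acc_source is not None:
        acc = acc_source
    else:
        acc = shrake_rupley_sasa(structure, n_points=sasa_n_points)[chain_id]

    rel_acc_raw = np.full(n, np.nan)
    for i, res in enumerate(residues):
        if res.one_letter == "X":
            missing[i] = True
            continue
        if np.isfinite(acc[i]):
            rel_acc_raw[i] = relative_accessibility(acc[i], res.res_name)
        else:
            missing[i] = True

    tempfactors = np.array([r.tempfactor for r in residues])
    predicted = structure.source_kind == "predicted"

    df = pd.DataFrame(
        {
            "structure_id": structure.structure_id,
            "chain_id": chain_id,
            "seq_num": [r.seq_num for r in residues],
            "icode": [r.icode for r in residues],
            "res_name": [r.res_name for r in residues],
            "one_letter": [r.one_letter for r in residues],
            "rel_acc_raw": rel_acc_raw,
            "ss3": list(ss3),
            "bfactor_raw": np.nan if predicted else tempfactors,
            "loop_len_raw": loop_length_feature(list(ss3)),
            "terminus": termini_feature(list(ss3)),
            "confidence_raw": tempfactors if predicted else np.nan,
            "complete": ~missing,
        }
    )
    return df


def build_feature_vectors(
    raw: pd.DataFrame,
    bounds: NormalizationBounds,
    source_kind: str = "experimental",
    bfactor_mode: str = "per_structure",
    use_confidence: bool = True,
) -> pd.DataFrame:
    """Normalized model-ready feature vectors from raw feature tables.

    ``bounds`` must carry corpus-level fits for ``rel_acc`` and ``loop_len``
    (and ``bfactor`` when ``bfactor_mode="per_corpus"``). B-factors default to
    per-structure min-max scaling because experimental B-factor scales are not
    comparable across crystals. The three secondary-structure binaries are
    one-hot by construction.
    """
    if bfactor_mode not in ("per_structure", "per_corpus"):
        raise ValueError(f"unknown bfactor_mode {bfactor_mode!r}")
    out = raw.copy()
    out["rel_acc"] = bounds.apply("rel_acc", raw["rel_acc_raw"].to_numpy())
    for state in SS3_STATES:
        out[f"ss_{state}"] = (raw["ss3"] == state).astype(float)
    out["loop_len_norm"] = np.where(
        out["ss_loop"] == 1.0, bounds.apply("loop_len", raw["loop_len_raw"].to_numpy()), 0.0
    )
    if source_kind == "experimental":
        if bfactor_mode == "per_corpus":
            out["bfactor_norm"] = bounds.apply("bfactor", raw["bfactor_raw"].to_numpy())
        else:
            def _scale(group: pd.Series) -> pd.Series:
                lo, hi = group.min(), group.max()
                if hi <= lo:
                    raise ValueError(
                        "degenerate per-structure B-factor bounds (constant B-factor)"
                    )
                return ((group - lo) / (hi - lo)).clip(0.0, 1.0)

            out["bfactor_norm"] = out.groupby("structure_id")["bfactor_raw"].transform(_scale)
    elif use_confidence:
        out["confidence_norm"] = raw["confidence_raw"].to_numpy() / 100.0
    cols = feature_columns_for(source_kind, use_confidence)
    id_cols = ["structure_id", "chain_id", "seq_num", "icode", "res_name", "one_letter"]
    return out[id_cols + list(cols) + ["complete"]]
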