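"""Shared fixtures: hand-written PDB/DSSP text and simulated corpora."""

import numpy as np
import pytest

from cleavability.models import roc_auc
from cleavability.synthetic import generate_corpus


def pdb_atom_line(serial, name, res_name, chain_id, seq_num, xyz, occ=1.0,
                  bfactor=20.0, element=None):
    element = element or name[0]
    return (
        f"ATOM  {serial:5d}  {name:<3s} {res_name:>3s} {chain_id}{seq_num:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{bfactor:6.2f}"
        f"          {element:>2s}"
    )


def make_pdb_text(residues, bfactor=20.0):
    """residues: list of (chain_id, seq_num, res_name). Backbone N/CA/C/O each."""
    lines = []
    serial = 1
    for i, (chain_id, seq_num, res_name) in enumerate(residues):
        for j, name in enumerate(["N", "CA", "C", "O"]):
            xyz = (4.0 * i + j, 0.0, 0.0)
            element = "C" if name in ("CA", "C") else name
            lines.append(pdb_atom_line(serial, name, res_name, chain_id, seq_num,
                                       xyz, bfactor=bfactor, element=element))
            serial += 1
    return "\n".join(lines) + "\nEND\n"


def dssp_line(serial, resnum, chain, aa, ss, acc):
    base = f"{serial:5d}{resnum:5d} {chain} {aa}  {ss}"
    return base.ljust(34) + f"{acc:4d}"


def make_dssp_text(rows):
    """rows: list of (resnum, chain, aa, ss, acc) or '!' for a chain break."""
    header = (
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
        "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA"
    )
    lines = ["== fake dssp header ==", header]
    serial = 1
    for row in rows:
        if row == "!":
            lines.append(f"{serial:5d}      " + "  !".ljust(27))
        else:
            resnum, chain, aa, ss, acc = row
            lines.append(dssp_line(serial, resnum, chain, aa, ss, acc))
        serial += 1
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def small_corpus():
    """40 toy structures with planted cleavage signal (fast unit-test corpus)."""
    return generate_corpus(n_structures=40, seed=123)


@pytest.fixture(scope="session")
def corpus200():
    """The benchmark-scale planted corpus (200 structures, default conditions)."""
    return generate_corpus(n_structures=200, seed=1)


@pytest.fixture(scope="session")
def corpus200_bayes_auc(corpus200):
    return roc_auc(corpus200.true_probs, corpus200.table["label"].to_numpy()).auc


@pytest.fixture(scope="session")
def motif_corpus():
    """100 structures where cleavage depends on structure and a P1 K/R motif."""
    return generate_corpus(n_structures=100, seed=3, with_motif=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
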