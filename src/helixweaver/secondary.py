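"""Helix assignment from backbone hydrogen bonding (DSSP-style).

Implements the Kabsch–Sander electrostatic hydrogen-bond criterion on
backbone coordinates, with the amide hydrogen placed at an ideal position
from C(i−1), N(i) and CA(i).  A residue is helical ('H') when it sits in
two consecutive i→i+4 hydrogen-bonded turns, and α-helices are reported
only for maximal runs of at least five successive 'H' residues; everything
else is loop.
"""

from __future__ import annotations

import numpy as np

from .geometry import BackboneChain, GeometryError, SegmentSpan

#: Kabsch–Sander coupling constant, kcal/mol when distances are in Å.
_KS_Q = 0.084 * 332.0
#: Hydrogen bond exists when the electrostatic energy is below this.
HBOND_ENERGY_CUTOFF = -0.5
#: Minimum run of 'H' residues reported as an α-helix.
MIN_HELIX_LEN = 5


def place_amide_hydrogens(chain: BackboneChain) -> np.ndarray:
    """Ideal amide H for residues 2..n; row 0 is NaN (no preceding carbonyl)."""
    H = np.full((chain.n_residues, 3), np.nan)
    for i in range(1, chain.n_residues):
        d1 = chain.n[i] - chain.c[i - 1]
        d2 = chain.n[i] - chain.ca[i]
        d1 /= np.linalg.norm(d1)
        d2 /= np.linalg.norm(d2)
        bis = d1 + d2
        H[i] = chain.n[i] + bis / np.linalg.norm(bis)
    return H


def kabsch_sander_energies(chain: BackboneChain) -> np.ndarray:
    """Pairwise H-bond energies E[i, j]: CO of residue i → NH of residue j.

    Entries for |i − j| < 2, for j = 0 (no amide H) and for pairs whose
    N–O distance exceeds 5.2 Å are +inf.
    """
    if np.any(~np.isfinite(chain.o)):
        raise GeometryError("carbonyl O coordinates required for H-bond assignment")
    n = chain.n_residues
    H = place_amide_hydrogens(chain)
    E = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(n):
            if abs(i - j) < 2 or j == 0:
                continue
            r_on = np.linalg.norm(chain.o[i] - chain.n[j])
            if r_on > 5.2:
                continue
            r_ch = np.linalg.norm(chain.c[i] - H[j])
            r_oh = np.linalg.norm(chain.o[i] - H[j])
            r_cn = np.linalg.norm(chain.c[i] - chain.n[j])
            E[i, j] = _KS_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return E


def helix_flags(chain: BackboneChain) -> np.ndarray:
    """Boolean per-residue 'H' assignment from i→i+4 turn patterns."""
    n = chain.n_residues
    E = kabsch_sander_energies(chain)
    turn4 = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        if E[i, i + 4] < HBOND_ENERGY_CUTOFF:
            turn4[i] = True
    flags = np.zeros(n, dtype=bool)
    # two consecutive 4-turns at i−1 and i make residues i..i+3 helical
    for i in range(1, n - 4):
        if turn4[i - 1] and turn4[i]:
            flags[i:i + 4] = True
    return flags


def assign_secondary_structure(chain: BackboneChain) -> list[SegmentSpan]:
    """Partition a chain into maximal helix (≥5 'H') and loop spans."""
    if chain.n_residues < MIN_HELIX_LEN:
        raise GeometryError("need at least 5 residues for helix assignment")
    flags = helix_flags(chain)
    spans: list[SegmentSpan] = []
    n = chain.n_residues
    i = 0
    runs: list[tuple[int, int, bool]] = []  # 0-based [start, end], is_helix
    while i < n:
        j = i
        while j + 1 < n and flags[j + 1] == flags[i]:
            j += 1
        runs.append((i, j, bool(flags[i])))
        i = j + 1
    # short 'H' runs are demoted to loop
    merged: list[tuple[int, int, bool]] = []
    for start, end, is_h in runs:
        if is_h and end - start + 1 < MIN_HELIX_LEN:
            is_h = False
        if merged and merged[-1][2] == is_h:
            merged[-1] = (merged[-1][0], end, is_h)
        else:
            merged.append((start, end, is_h))
    for start, end, is_h in merged:
        spans.append(SegmentSpan("helix" if is_h else "loop", start + 1, end + 1))
    return spans


def helix_spans(chain: BackboneChain) -> list[SegmentSpan]:
    """Only the helix spans of :func:`assign_secondary_structure`."""
    return [s for s in assign_secondary_structure(chain) if s.kind == "helix"]
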