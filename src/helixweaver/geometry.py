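"""Backbone geometry: torsion-space construction, measurement and helix axes.

All-α backbones are represented as ordered per-residue backbone coordinates
(N, CA, C, O, optionally CB) together with the per-residue torsions
(phi, psi, omega).  Chains are built from torsions by sequential
internal-coordinate (NeRF-style) atom placement with ideal bond lengths and
angles, so an ideal α-helix is fully specified by the canonical torsion
triple (−60, −45, 180) degrees.

Conventions
-----------
* angles in degrees, coordinates in Å, residue indices 1-based inclusive;
* ``phi`` is undefined for the first residue, ``psi``/``omega`` for the
  last; undefined torsions are stored as NaN;
* ``omega[i]`` is the peptide torsion between residue ``i`` and ``i+1``
  (CA_i–C_i–N_{i+1}–CA_{i+1}).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

# Ideal backbone internal geometry (Engh–Huber-style values).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

#: Canonical α-helix torsions used for all ideal helices.
IDEAL_HELIX_TORSIONS = (-60.0, -45.0, 180.0)

#: Pseudo-psi used to place the terminal carbonyl O when psi is undefined.
_TERMINAL_PSEUDO_PSI = -45.0


class GeometryError(ValueError):
    """Invalid geometric input (empty chain, bad span, non-finite angle)."""


@dataclass(frozen=True)
class TorsionTriple:
    """Backbone torsions of one residue, degrees in (−180, 180]."""

    phi: float
    psi: float
    omega: float = 180.0

    def as_array(self) -> np.ndarray:
        return np.array([self.phi, self.psi, self.omega], dtype=float)


@dataclass(frozen=True)
class SegmentSpan:
    """A contiguous stretch of residues, 1-based inclusive."""

    kind: Literal["helix", "loop"]
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise GeometryError(f"invalid span [{self.start}, {self.end}]")
        if self.kind == "helix" and len(self) < 5:
            raise GeometryError("helix spans must cover at least 5 residues")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def slice(self) -> slice:
        """0-based slice selecting the span's residues."""
        return slice(self.start - 1, self.end)


@dataclass
class BackboneChain:
    """Ordered backbone coordinates plus per-residue torsions.

    ``coords[atom]`` is an (n_res, 3) array for atom in N, CA, C, O and
    optionally CB.  ``torsions`` is (n_res, 3) with columns phi, psi,
    omega; NaN marks undefined angles.
    """

    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    cb: np.ndarray | None = None
    torsions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("n", "ca", "c", "o"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise GeometryError(f"{name} coordinates must be (n_res, 3)")
            setattr(self, name, arr)
        if len(self.ca) < 1:
            raise GeometryError("a chain needs at least one residue")
        if self.cb is not None:
            self.cb = np.asarray(self.cb, dtype=float)
        if self.torsions is None:
            self.torsions = measure_torsions_from_coords(self.n, self.ca, self.c)

    def __len__(self) -> int:
        return len(self.ca)

    @property
    def n_residues(self) -> int:
        return len(self.ca)

    @property
    def atom_names(self) -> tuple[str, ...]:
        return ("N", "CA", "C", "O") if self.cb is None else ("N", "CA", "C", "O", "CB")

    def all_coords(self) -> np.ndarray:
        """Flat (n_atoms, 3) array in residue order, atoms N, CA, C, O[, CB]."""
        stacks = [self.n, self.ca, self.c, self.o]
        if self.cb is not None:
            stacks.append(self.cb)
        return np.stack(stacks, axis=1).reshape(-1, 3)

    def atom_residue_index(self) -> np.ndarray:
        """0-based residue index for each row of :meth:`all_coords`."""
        k = len(self.atom_names)
        return np.repeat(np.arange(self.n_residues), k)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneChain":
        """Return a rigidly moved copy: ``x -> R x + t``."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)

        def mv(a: np.ndarray) -> np.ndarray:
            return a @ R.T + t

        return BackboneChain(
            n=mv(self.n), ca=mv(self.ca), c=mv(self.c), o=mv(self.o),
            cb=None if self.cb is None else mv(self.cb),
            torsions=self.torsions.copy(),
        )


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (−180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def bond_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle p0-p1-p2 in degrees."""
    v1 = np.asarray(p0) - np.asarray(p1)
    v2 = np.asarray(p2) - np.asarray(p1)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D given three predecessors and internal coordinates.

    ``bond`` is |C-D|, ``angle`` the B-C-D angle and ``torsion`` the
    A-B-C-D dihedral, angles in degrees.
    """
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc = bc / np.sqrt(bc @ bc)
    ab = b - a
    # inline 3-vector cross products (hot path of chain building)
    n = np.array([ab[1] * bc[2] - ab[2] * bc[1],
                  ab[2] * bc[0] - ab[0] * bc[2],
                  ab[0] * bc[1] - ab[1] * bc[0]])
    n = n / np.sqrt(n @ n)
    m = np.array([n[1] * bc[2] - n[2] * bc[1],
                  n[2] * bc[0] - n[0] * bc[2],
                  n[0] * bc[1] - n[1] * bc[0]])
    d0 = -bond * np.cos(ang)
    sa = bond * np.sin(ang)
    return c + d0 * bc + (sa * np.cos(tor)) * m + (sa * np.sin(tor)) * n


def _normalize_torsion_input(torsions) -> np.ndarray:
    if isinstance(torsions, np.ndarray):
        arr = np.array(torsions, dtype=float)
    else:
        rows = []
        for t in torsions:
            if isinstance(t, TorsionTriple):
                rows.append(t.as_array())
            else:
                rows.append(np.asarray(t, dtype=float))
        if not rows:
            arr = np.empty((0, 3))
        else:
            arr = np.stack(rows)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise GeometryError("torsions must be a sequence of (phi, psi, omega)")
    return arr


def torsions_to_backbone(torsions, with_cb: bool = False) -> BackboneChain:
    """Build Cartesian backbone coordinates from per-residue torsions.

    Parameters
    ----------
    torsions
        Sequence of (phi, psi, omega) per residue, degrees.  ``phi`` of the
        first residue and ``psi``/``omega`` of the last are not used and may
        be NaN.
    with_cb
        Also place an ideal tetrahedral CB on every residue.

    The inverse operation is :func:`measure_torsions`; round-tripping
    reproduces every defined input angle to better than 1e−6 degrees.
    """
    arr = _normalize_torsion_input(torsions)
    n_res = len(arr)
    if n_res == 0:
        raise GeometryError("torsion list is empty")
    used = arr.copy()
    used[0, 0] = np.nan
    used[-1, 1] = np.nan
    used[-1, 2] = np.nan
    if np.any(~np.isfinite(used[1:, 0])) or np.any(~np.isfinite(used[:-1, 1:])):
        raise GeometryError("all defined torsions must be finite")

    N = np.empty((n_res, 3))
    CA = np.empty((n_res, 3))
    C = np.empty((n_res, 3))
    theta = np.radians(ANGLE_N_CA_C)
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])
    for i in range(n_res - 1):
        psi, omega = used[i, 1], used[i, 2]
        phi_next = used[i + 1, 0]
        N[i + 1] = place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi)
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA, omega)
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C, phi_next)

    O = _place_carbonyl_oxygens(N, CA, C, used[:, 1])
    cb = place_cb(N, CA, C) if with_cb else None
    return BackboneChain(n=N, ca=CA, c=C, o=O, cb=cb, torsions=used)


def _place_carbonyl_oxygens(N: np.ndarray, CA: np.ndarray, C: np.ndarray,
                            psi: np.ndarray) -> np.ndarray:
    """O in the carbonyl plane, anti to the following amide N.

    The terminal residue, whose psi is undefined, uses a helical pseudo-psi
    so the chain stays deterministic.
    """
    n_res = len(N)
    O = np.empty((n_res, 3))
    for i in range(n_res):
        p = psi[i] if np.isfinite(psi[i]) else _TERMINAL_PSEUDO_PSI
        O[i] = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, p + 180.0)
    return O


def place_cb(N: np.ndarray, CA: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral CB from the backbone N, CA, C of each residue."""
    b1 = CA - N
    b2 = C - CA
    a = np.cross(b1, b2)
    return -0.58273431 * a + 0.56802827 * b1 - 0.54067466 * b2 + CA


def measure_torsions_from_coords(N: np.ndarray, CA: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Per-residue (phi, psi, omega) measured from coordinates; NaN where undefined."""
    n_res = len(N)
    out = np.full((n_res, 3), np.nan)
    for i in range(n_res):
        if i > 0:
            out[i, 0] = dihedral(C[i - 1], N[i], CA[i], C[i])
        if i < n_res - 1:
            out[i, 1] = dihedral(N[i], CA[i], C[i], N[i + 1])
            out[i, 2] = dihedral(CA[i], C[i], N[i + 1], CA[i + 1])
    return out


def measure_torsions(chain: BackboneChain) -> np.ndarray:
    return measure_torsions_from_coords(chain.n, chain.ca, chain.c)


def build_ideal_helix(n_res: int, with_cb: bool = False) -> BackboneChain:
    """Canonical α-helix of ``n_res`` residues, torsions (−60, −45, 180)."""
    if n_res < 1:
        raise GeometryError("helix length must be >= 1")
    torsions = np.tile(np.asarray(IDEAL_HELIX_TORSIONS), (n_res, 1))
    return torsions_to_backbone(torsions, with_cb=with_cb)


# ---------------------------------------------------------------------------
# ABEGO torsion-bin classification


def abego_label(phi: float, psi: float, omega: float = 180.0) -> str:
    """Classify one torsion triple into the ABEGO alphabet.

    A: right-handed α region, B: β region, G: left-handed α,
    E: extended positive-phi, O: cis peptide (|omega| < 90°).
    """
    if not (np.isfinite(phi) and np.isfinite(psi) and np.isfinite(omega)):
        raise GeometryError("abego_label requires finite angles")
    if abs(omega) < 90.0:
        return "O"
    if phi < 0.0:
        return "A" if -75.0 < psi <= 50.0 else "B"
    return "G" if -100.0 < psi <= 100.0 else "E"


def abego_string(torsions: np.ndarray) -> str:
    """ABEGO string over residues; '-' where phi or psi is undefined."""
    arr = np.asarray(torsions, dtype=float)
    out = []
    for phi, psi, omega in arr:
        if np.isfinite(phi) and np.isfinite(psi):
            out.append(abego_label(phi, psi, omega if np.isfinite(omega) else 180.0))
        else:
            out.append("-")
    return "".join(out)


# ---------------------------------------------------------------------------
# Helix axes


def fit_helix_axis(chain: BackboneChain, span: SegmentSpan) -> np.ndarray:
    """Unit helix axis of a span, oriented N→C.

    The axis is the first principal component of the span's centered CA
    coordinates, sign-fixed so the projection of (last CA − first CA) is
    positive.
    """
    if span.kind != "helix":
        raise GeometryError("axis fitting requires a helix span")
    if len(span) < 5:
        raise GeometryError("helix spans must cover at least 5 residues")
    cas = chain.ca[span.slice()]
    centered = cas - cas.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, cas[-1] - cas[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def helix_rise_and_twist(chain: BackboneChain, span: SegmentSpan) -> tuple[float, float]:
    """(rise per residue in Å, residues per turn) measured from the fitted axis."""
    axis = fit_helix_axis(chain, span)
    cas = chain.ca[span.slice()]
    center = cas.mean(axis=0)
    proj = (cas - center) @ axis
    rise = float(np.mean(np.diff(proj)))
    # rotation of successive CAs about the axis
    radial = cas - center - np.outer(proj, axis)
    e1 = radial[0] / np.linalg.norm(radial[0])
    e2 = np.cross(axis, e1)
    phase = np.unwrap(np.arctan2(radial @ e2, radial @ e1))
    twist = float(np.mean(np.abs(np.diff(phase))))
    return rise, 2.0 * np.pi / twist


# ---------------------------------------------------------------------------
# Chain growth


def _helix_torsion_rows(helix_len: int) -> np.ndarray:
    return np.tile(np.asarray(IDEAL_HELIX_TORSIONS), (helix_len, 1))


def motif_torsion_block(motif, helix_len: int) -> tuple[float, float, np.ndarray]:
    """Torsion rows appended by one (motif, helix) growth step.

    Returns ``(junction_psi, junction_omega, rows)`` where the junction
    torsions re-define the current terminal residue and ``rows`` covers the
    loop residues followed by ``helix_len`` helix residues (the first helix
    residue takes the motif's post-junction phi).
    """
    loop = np.asarray(motif.loop_torsions, dtype=float).reshape(-1, 3)
    rows = np.vstack([loop, _helix_torsion_rows(helix_len)])
    rows[len(loop), 0] = motif.post_phi
    return float(motif.pre_psi), float(motif.pre_omega), rows


def append_motif_then_helix(chain: BackboneChain, motif, helix_len: int,
                            side: str = "C_terminal") -> BackboneChain:
    """Grow a chain by one loop motif plus one ideal helix.

    C-terminal growth continues the existing coordinates rigidly (only the
    junction carbonyl O is re-derived once its psi becomes defined).
    N-terminal growth rebuilds the whole chain from the concatenated torsion
    sequence and re-indexes; it is geometrically the mirror of C-terminal
    growth on the reversed sequence.
    """
    if helix_len < 1:
        raise GeometryError("appended helix length must be >= 1")
    if side == "C_terminal":
        pre_psi, pre_omega, rows = motif_torsion_block(motif, helix_len)
        torsions = chain.torsions.copy()
        torsions[-1, 1] = pre_psi
        torsions[-1, 2] = pre_omega
        full = np.vstack([torsions, rows])
        return _extend_coords(chain, full)
    if side == "N_terminal":
        loop = np.asarray(motif.loop_torsions, dtype=float).reshape(-1, 3)
        helix = _helix_torsion_rows(helix_len)
        helix[-1, 1] = motif.pre_psi
        helix[-1, 2] = motif.pre_omega
        old = chain.torsions.copy()
        old[0, 0] = motif.post_phi
        full = np.vstack([helix, loop, old])
        return torsions_to_backbone(full, with_cb=chain.cb is not None)
    raise GeometryError(f"unknown growth side {side!r}")


def _extend_coords(chain: BackboneChain, full_torsions: np.ndarray) -> BackboneChain:
    """Continue an existing chain's coordinates to realize ``full_torsions``.

    The first ``len(chain)`` rows of ``full_torsions`` must match the
    chain's stored torsions except for the junction psi/omega of the last
    existing residue.
    """
    n_old = chain.n_residues
    n_new = len(full_torsions)
    N = np.vstack([chain.n, np.empty((n_new - n_old, 3))])
    CA = np.vstack([chain.ca, np.empty((n_new - n_old, 3))])
    C = np.vstack([chain.c, np.empty((n_new - n_old, 3))])
    used = full_torsions.copy()
    used[0, 0] = np.nan
    used[-1, 1] = np.nan
    used[-1, 2] = np.nan
    for i in range(n_old - 1, n_new - 1):
        psi, omega = used[i, 1], used[i, 2]
        phi_next = used[i + 1, 0]
        N[i + 1] = place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi)
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA, omega)
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C, phi_next)
    O = np.vstack([chain.o, np.empty((n_new - n_old, 3))])
    for i in range(n_old - 1, n_new):
        p = used[i, 1] if np.isfinite(used[i, 1]) else _TERMINAL_PSEUDO_PSI
        O[i] = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, p + 180.0)
    cb = None
    if chain.cb is not None:
        cb = np.vstack([chain.cb, place_cb(N[n_old:], CA[n_old:], C[n_old:])])
    return BackboneChain(n=N, ca=CA, c=C, o=O, cb=cb, torsions=used)


def spans_of_growth(helix_lengths: Sequence[int], loop_lengths: Sequence[int]) -> list[SegmentSpan]:
    """Helix/loop spans implied by alternating helix and loop lengths."""
    if len(loop_lengths) != len(helix_lengths) - 1:
        raise GeometryError("need one loop length per helix junction")
    spans: list[SegmentSpan] = []
    pos = 1
    for k, h in enumerate(helix_lengths):
        spans.append(SegmentSpan("helix", pos, pos + h - 1))
        pos += h
        if k < len(loop_lengths):
            if loop_lengths[k] > 0:
                spans.append(SegmentSpan("loop", pos, pos + loop_lengths[k] - 1))
            pos += loop_lengths[k]
    return spans
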