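"""Helix–loop–helix (HLH) units: extraction, featurization, classification.

An HLH unit is two α-helices joined by a short loop (1–5 residues).  Each
unit is summarized by a five-component geometric feature vector used for
clustering, and classified by its bend angle into hairpin (h), v-shaped
(v) or corner (c) motifs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .geometry import (BackboneChain, GeometryError, SegmentSpan, abego_string,
                       dihedral, fit_helix_axis)

#: Feature names and units of the 5-D HLH descriptor.
FEATURE_NAMES = ("bend", "axis_dihedral", "junction_dist", "pack1", "pack2")
FEATURE_UNITS = ("deg", "deg", "A", "deg", "deg")

#: Default bend-angle class boundaries (degrees): h below, v between, c above.
BEND_THRESHOLDS = (50.0, 85.0)

MIN_LOOP_LEN = 1
MAX_LOOP_LEN = 5


@dataclass
class HLHInstance:
    """One observed helix–loop–helix unit inside a source chain."""

    source_id: str
    helix1_span: SegmentSpan
    loop_span: SegmentSpan | None
    helix2_span: SegmentSpan
    loop_torsions: np.ndarray           # (loop_len, 3) phi/psi/omega
    pre_psi: float                      # psi of the last helix-1 residue
    pre_omega: float
    post_phi: float                     # phi of the first helix-2 residue
    loop_abego: str
    loop_len: int
    sequence: str | None = None         # one-letter, over all three spans

    def loop_sequence(self) -> str | None:
        if self.sequence is None or self.loop_span is None:
            return None
        off = self.helix1_span.start
        return self.sequence[self.loop_span.start - off:self.loop_span.end - off + 1]


@dataclass(frozen=True)
class FeatureVector:
    """Five-number geometric descriptor of an HLH unit."""

    bend: float           # deg; 180 − angle(u1, u2)
    axis_dihedral: float  # deg; chirality of the two axis segments
    junction_dist: float  # Å; CA(end helix1) to CA(start helix2)
    pack1: float          # deg; angle(u1, midpoint vector)
    pack2: float          # deg; angle(u2, midpoint vector)

    @property
    def values(self) -> np.ndarray:
        return np.array([self.bend, self.axis_dihedral, self.junction_dist,
                         self.pack1, self.pack2])


def extract_hlh_units(chain: BackboneChain, spans: list[SegmentSpan],
                      source_id: str = "", sequence: str | None = None,
                      min_loop: int = MIN_LOOP_LEN,
                      max_loop: int = MAX_LOOP_LEN) -> list[HLHInstance]:
    """All consecutive helix–loop–helix triples with admissible loop length.

    Consecutive instances share a helix, so a chain of three helices can
    yield two units.  Helices separated by a loop outside [min_loop,
    max_loop] (or abutting directly) are skipped.
    """
    units: list[HLHInstance] = []
    helices = [s for s in spans if s.kind == "helix"]
    for h1, h2 in zip(helices, helices[1:]):
        loop_len = h2.start - h1.end - 1
        if loop_len < max(min_loop, 1) or loop_len > max_loop:
            continue
        loop_span = SegmentSpan("loop", h1.end + 1, h2.start - 1)
        t = chain.torsions
        loop_t = t[loop_span.slice()].copy()
        if np.any(~np.isfinite(loop_t)):
            continue
        seq = None
        if sequence is not None:
            seq = sequence[h1.start - 1:h2.end]
        units.append(HLHInstance(
            source_id=source_id,
            helix1_span=h1, loop_span=loop_span, helix2_span=h2,
            loop_torsions=loop_t,
            pre_psi=float(t[h1.end - 1, 1]), pre_omega=float(t[h1.end - 1, 2]),
            post_phi=float(t[h2.start - 1, 0]),
            loop_abego=abego_string(loop_t),
            loop_len=loop_len, sequence=seq,
        ))
    return units


def bend_angle_from_axes(u1: np.ndarray, u2: np.ndarray) -> float:
    """Bend b = 180° − angle(u1, u2); 0 for an antiparallel hairpin."""
    cosang = float(np.clip(np.dot(u1, u2), -1.0, 1.0))
    return 180.0 - float(np.degrees(np.arccos(cosang)))


def featurize_hlh(inst: HLHInstance, chain: BackboneChain) -> FeatureVector:
    """Five-feature geometric descriptor of one HLH unit.

    Components: bend angle; the dihedral of the two axis segments
    (projections of each helix's terminal CAs onto its own axis line),
    which captures handedness; the junction CA–CA distance; and the two
    packing angles between each helix axis and the midpoint-joining
    vector.  All are rigid-motion invariant.
    """
    for span in (inst.helix1_span, inst.helix2_span):
        if len(span) < 5:
            raise GeometryError("HLH featurization requires helices of >= 5 residues")
    u1 = fit_helix_axis(chain, inst.helix1_span)
    u2 = fit_helix_axis(chain, inst.helix2_span)
    b = bend_angle_from_axes(u1, u2)

    def axis_endpoints(span: SegmentSpan, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cas = chain.ca[span.slice()]
        center = cas.mean(axis=0)
        t0 = float(np.dot(cas[0] - center, u))
        t1 = float(np.dot(cas[-1] - center, u))
        return center + t0 * u, center + t1 * u

    p1s, p1e = axis_endpoints(inst.helix1_span, u1)
    p2s, p2e = axis_endpoints(inst.helix2_span, u2)
    ax_dih = dihedral(p1s, p1e, p2s, p2e)
    jdist = float(np.linalg.norm(chain.ca[inst.helix2_span.start - 1]
                                 - chain.ca[inst.helix1_span.end - 1]))
    m1 = 0.5 * (p1s + p1e)
    m2 = 0.5 * (p2s + p2e)
    v = m2 - m1
    nv = np.linalg.norm(v)
    if nv < 1e-9:
        pack1 = pack2 = 90.0
    else:
        v = v / nv
        pack1 = float(np.degrees(np.arccos(np.clip(np.dot(u1, v), -1, 1))))
        pack2 = float(np.degrees(np.arccos(np.clip(np.dot(u2, v), -1, 1))))
    return FeatureVector(bend=b, axis_dihedral=ax_dih, junction_dist=jdist,
                         pack1=pack1, pack2=pack2)


def classify_bend(b: float, thresholds: tuple[float, float] = BEND_THRESHOLDS) -> str:
    """Map a bend angle to its motif class: h (hairpin), v, or c (corner/kink)."""
    if not (0.0 <= b <= 180.0):
        raise GeometryError(f"bend angle {b} outside [0, 180]")
    lo, hi = thresholds
    if b < lo:
        return "h"
    if b < hi:
        return "v"
    return "c"


def motif_aa_profile(instances: list[HLHInstance],
                     flank: int = 2) -> list[dict[str, float]]:
    """Per-position amino-acid frequencies around the loop of a cluster.

    Positions run from ``flank`` residues before the loop through the loop
    to ``flank`` residues after it, aligned on the loop start.  Residues
    outside a particular instance are ignored; each position's observed
    frequencies sum to 1.  Instances without sequences contribute nothing;
    an empty profile is returned (with a warning) when none carry one.
    """
    with_seq = [i for i in instances if i.sequence is not None and i.loop_span is not None]
    if not with_seq:
        import warnings
        warnings.warn("no sequences available; returning empty profile")
        return []
    max_loop = max(i.loop_len for i in with_seq)
    n_pos = flank + max_loop + flank
    counters: list[Counter] = [Counter() for _ in range(n_pos)]
    for inst in with_seq:
        off = inst.helix1_span.start  # residue number of sequence[0]
        pairs = []  # (profile position, residue number)
        for k in range(flank):
            pairs.append((k, inst.loop_span.start - flank + k))
        for k in range(inst.loop_len):
            pairs.append((flank + k, inst.loop_span.start + k))
        for k in range(flank):
            pairs.append((flank + max_loop + k, inst.loop_span.end + 1 + k))
        for p, resno in pairs:
            if resno < inst.helix1_span.start or resno > inst.helix2_span.end:
                continue
            counters[p][inst.sequence[resno - off]] += 1
    profile: list[dict[str, float]] = []
    for ctr in counters:
        total = sum(ctr.values())
        profile.append({aa: cnt / total for aa, cnt in sorted(ctr.items())} if total else {})
    return profile
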