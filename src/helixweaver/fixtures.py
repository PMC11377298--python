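"""Synthetic inputs for every pipeline stage.

Everything here is generated from a seed — oriented helix bundles with
prescribed axis directions, toy motif libraries with known class counts,
planted Gaussian feature mixtures for clustering tests, and small
multi-helix PDB sets for the mine→cluster→enumerate→score round trip.
No downloads or external files are involved; the generators emulate the
geometric structure of native data (ideal helices, short non-helical
loops) but not its conformational diversity.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .enumeration import clash_score
from .geometry import (BackboneChain, GeometryError, IDEAL_HELIX_TORSIONS,
                       SegmentSpan, abego_string, build_ideal_helix,
                       fit_helix_axis, place_cb, torsions_to_backbone)
from .library import MotifLibrary, MotifRecord, measure_motif_bend
from .motifs import classify_bend

# torsion-bin sampling means/spreads used for synthetic loop residues
_LOOP_BINS = {
    "A": ((-63.0, 20.0), (-41.0, 20.0)),
    "B": ((-120.0, 25.0), (135.0, 25.0)),
    "G": ((62.0, 15.0), (41.0, 20.0)),
    "E": ((75.0, 15.0), (175.0, 15.0)),
}
_NONHELICAL_BINS = ("B", "G", "E")


def _sample_loop_torsions(rng: np.random.Generator, loop_len: int,
                          bins=None) -> np.ndarray:
    bins = bins or tuple(_LOOP_BINS)
    rows = np.empty((loop_len, 3))
    for i in range(loop_len):
        b = bins[rng.integers(len(bins))]
        (mphi, sphi), (mpsi, spsi) = _LOOP_BINS[b]
        rows[i] = (np.clip(rng.normal(mphi, sphi), -179.0, 179.0),
                   np.clip(rng.normal(mpsi, spsi), -179.0, 179.0),
                   np.clip(rng.normal(180.0, 3.0), 170.0, 180.0))
    return rows


# ---------------------------------------------------------------------------
# Oriented bundles


def _rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return Rotation.from_rotvec(np.pi * perp).as_matrix()
    s = np.linalg.norm(v)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)


def make_oriented_bundle(orientations, helix_len: int = 14,
                         spacing: float = 7.0, seed: int = 0,
                         max_retries: int = 50) -> BackboneChain:
    """A multi-helix chain whose fitted helix axes match the requested ones.

    Each ideal helix is rigidly rotated onto its target orientation and
    the chain is laid out as a daisy chain: helix k+1 begins ``spacing`` Å
    beyond the end of helix k, offset along a direction blending the two
    axes with a random lateral component, and the gap is bridged by
    straight interpolated linker residues (geometrically placed, not
    torsion-built, so they are never helical).  Lateral offsets are
    re-drawn and the layout retried if the rigid placement clashes.
    """
    U = np.asarray(orientations, float)
    if U.ndim != 2 or U.shape[1] != 3 or len(U) < 1:
        raise GeometryError("need at least one 3-vector orientation")
    U = U / np.linalg.norm(U, axis=1, keepdims=True)
    if helix_len < 5:
        raise GeometryError("bundle helices need >= 5 residues")
    base = build_ideal_helix(helix_len)
    # align on the interior span's axis: that is the span helix assignment
    # recovers, and its principal axis tilts slightly for fractional turns
    interior = SegmentSpan("helix", 2, helix_len - 1) if helix_len >= 7 \
        else SegmentSpan("helix", 1, helix_len)
    base_axis = fit_helix_axis(base, interior)
    for attempt in range(max_retries):
        sub = np.random.default_rng((seed, attempt))
        placed: list[BackboneChain] = []
        prev_end = np.zeros(3)
        prev_u = None
        for k, u in enumerate(U):
            R = _rotation_aligning(base_axis, u)
            if prev_u is None:
                start = prev_end
            else:
                lateral = sub.normal(size=3)
                lateral -= np.dot(lateral, prev_u) * prev_u
                nl = np.linalg.norm(lateral)
                lateral = lateral / nl if nl > 1e-9 else np.zeros(3)
                w = prev_u + u + 1.2 * lateral
                nw = np.linalg.norm(w)
                w = w / nw if nw > 1e-9 else lateral
                start = prev_end + spacing * w
            t = start - R @ base.ca[0]
            placed.append(base.transformed(R, t))
            prev_end = placed[-1].ca[-1]
            prev_u = u
        chain = _join_with_linkers(placed)
        if clash_score(chain) < 1.0:
            return chain
    raise GeometryError("could not place bundle without clashes; "
                        "increase spacing")


def _join_with_linkers(helices: list[BackboneChain],
                       bulge: float = 1.5) -> BackboneChain:
    """Concatenate rigidly placed helices with interpolated linker residues.

    Linkers arc outward from the bundle centroid (parabolic bulge) so the
    straight corridor between helices stays clear.
    """
    parts_n, parts_ca, parts_c, parts_o = [], [], [], []
    axes = []
    for h in helices:
        span = SegmentSpan("helix", 1, h.n_residues)
        axes.append(fit_helix_axis(h, span))
    for k, h in enumerate(helices):
        parts_n.append(h.n)
        parts_ca.append(h.ca)
        parts_c.append(h.c)
        parts_o.append(h.o)
        if k + 1 < len(helices):
            a = h.ca[-1]
            b = helices[k + 1].ca[0]
            gap = np.linalg.norm(b - a)
            direction = (b - a) / gap
            side = np.cross(direction, axes[k])
            if np.linalg.norm(side) < 1e-6:
                side = np.cross(direction, [0.0, 1.0, 0.0])
            side /= np.linalg.norm(side)
            n_link = max(1, int(round(gap / 3.4)) - 1)
            for j in range(1, n_link + 1):
                t = j / (n_link + 1)
                pos = a + direction * gap * t + side * bulge * np.sin(np.pi * t)
                parts_n.append((pos - 0.9 * direction)[None])
                parts_ca.append(pos[None])
                parts_c.append((pos + 0.9 * direction)[None])
                parts_o.append((pos + 0.9 * direction + 1.23 * side)[None])
    return BackboneChain(n=np.vstack(parts_n), ca=np.vstack(parts_ca),
                         c=np.vstack(parts_c), o=np.vstack(parts_o))


# ---------------------------------------------------------------------------
# Toy motif libraries


def make_toy_motif_library(n_per_class: int = 6, seed: int = 0,
                           max_iter: int = 20000) -> MotifLibrary:
    """Synthetic motif library with exactly ``n_per_class`` h, v and c motifs.

    Loop torsions are rejection-sampled from ABEGO-style bins until each
    bend class is filled; every record is rebuildable through the
    geometry layer (its stored bend angle is the rebuilt one) and the
    rebuilt two-helix chain is clash-acceptable, so enumeration with the
    library is productive.
    """
    if n_per_class < 1:
        raise GeometryError("need at least one motif per class")
    rng = np.random.default_rng(seed)
    need = {"h": n_per_class, "v": n_per_class, "c": n_per_class}
    counts = {"h": 0, "v": 0, "c": 0}
    records: list[MotifRecord] = []
    loop_len_cycle = 0
    for _ in range(max_iter):
        if not any(need.values()):
            break
        loop_len = 1 + loop_len_cycle % 5
        loop_len_cycle += 1
        torsions = _sample_loop_torsions(rng, loop_len)
        rec = MotifRecord(
            motif_id="tmp", loop_len=loop_len, loop_torsions=torsions,
            pre_psi=float(rng.normal(-45.0, 10.0)),
            pre_omega=float(np.clip(rng.normal(180.0, 3.0), 170.0, 180.0)),
            post_phi=float(rng.normal(-60.0, 10.0)),
            loop_abego=abego_string(torsions),
            bend_class="h", bend_angle=0.0,
        )
        b = measure_motif_bend(rec)
        cls = classify_bend(b)
        if need[cls] <= 0:
            continue
        from .library import rebuild_motif_chain
        if clash_score(rebuild_motif_chain(rec)) >= 4.0:
            continue
        rec.bend_angle = b
        rec.bend_class = cls
        counts[cls] += 1
        rec.motif_id = f"{cls}{counts[cls]}"
        need[cls] -= 1
        records.append(rec)
    if any(need.values()):
        raise GeometryError("could not fill all bend classes; increase max_iter")
    records.sort(key=lambda r: (r.bend_class, int(r.motif_id[1:])))
    return MotifLibrary(records=records,
                        provenance={"synthetic": True, "seed": seed,
                                    "n_per_class": n_per_class})


# ---------------------------------------------------------------------------
# Planted feature mixtures


def make_feature_mixture(centers, sigma: float, n_per_center: int,
                         seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian blobs around planted centers, with true labels."""
    C = np.asarray(centers, float)
    if C.ndim != 2 or len(C) < 1:
        raise GeometryError("centers must be a (k, d) array")
    if len(np.unique(C, axis=0)) != len(C):
        raise GeometryError("centers must be distinct")
    if sigma < 0:
        raise GeometryError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(c, sigma, size=(n_per_center, C.shape[1]))
                   for c in C])
    labels = np.repeat(np.arange(len(C)), n_per_center)
    return X, labels


# ---------------------------------------------------------------------------
# Toy PDB sets


def make_toy_chain(rng: np.random.Generator, n_helices: int = 2,
                   max_retries: int = 50) -> BackboneChain:
    """Torsion-built chain of ideal helices joined by short non-helical loops."""
    for _ in range(max_retries):
        rows = []
        for k in range(n_helices):
            hl = int(rng.integers(10, 17))
            rows.append(np.tile(np.asarray(IDEAL_HELIX_TORSIONS), (hl, 1)))
            if k + 1 < n_helices:
                ll = int(rng.integers(1, 6))
                rows.append(_sample_loop_torsions(rng, ll, bins=_NONHELICAL_BINS))
        chain = torsions_to_backbone(np.vstack(rows))
        if clash_score(chain) < 4.0:
            return chain
    raise GeometryError("could not build a clash-free toy chain")


def write_toy_pdb_set(out_dir, n_structures: int = 5, seed: int = 0) -> list[Path]:
    """Write small multi-helix PDB files; each contains >= 1 HLH unit."""
    from .pdbio import write_backbone_pdb
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    rng = np.random.default_rng(seed)
    for i in range(n_structures):
        n_h = 2 + i % 2
        chain = make_toy_chain(rng, n_helices=n_h)
        path = out / f"toy_{i:03d}.pdb"
        write_backbone_pdb(chain, path)
        paths.append(path)
    return paths
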