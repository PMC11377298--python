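"""Helix-order (HO) complexity metric and topology selection.

HO measures how ordered the mutual arrangement of the helices of an
all-α structure is:

    HO = 2 / (N (N − 1)) · Σ_{i<j} (u_i · u_j)²

over the unit axis vectors u_i of the N helices.  Parallel or
antiparallel bundles score 1; mutually orthogonal arrangements score 0;
isotropically random orientations average 1/3.  Complicated globular
topologies have low HO, which is how design targets are picked from an
enumerated ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enumeration import EnumerationEntry, TopologySpec, radius_of_gyration
from .geometry import BackboneChain, GeometryError, fit_helix_axis
from .library import MotifLibrary
from .secondary import assign_secondary_structure


@dataclass
class HelixSet:
    """Unit orientation vectors of a structure's helices, N→C oriented."""

    vectors: np.ndarray  # (N, 3), unit rows

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 3:
            raise GeometryError("helix vectors must be (N, 3)")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise GeometryError("helix vectors must be unit length")

    def __len__(self) -> int:
        return len(self.vectors)


def helix_order(hs: HelixSet | np.ndarray) -> float:
    """Average squared inner product over all helix-axis pairs, in [0, 1].

    Invariant to flipping any vector's sign and to relabeling helices.
    Requires at least two helices.
    """
    u = hs.vectors if isinstance(hs, HelixSet) else HelixSet(np.asarray(hs)).vectors
    n = len(u)
    if n < 2:
        raise GeometryError("HO requires at least two helices")
    g = u @ u.T
    sq = g ** 2
    total = (np.sum(sq) - n) / 2.0  # off-diagonal upper triangle
    return float(2.0 * total / (n * (n - 1)))


def structure_helix_set(chain: BackboneChain) -> HelixSet | None:
    """Fitted helix axes of a chain; None with fewer than two helices."""
    spans = [s for s in assign_secondary_structure(chain) if s.kind == "helix"]
    if len(spans) < 2:
        return None
    axes = np.stack([fit_helix_axis(chain, s) for s in spans])
    return HelixSet(axes)


def score_chain(chain: BackboneChain) -> dict:
    """HO, Rg and helix count of one backbone chain.

    HO is None (undefined) when fewer than two helices are assignable.
    """
    spans = [s for s in assign_secondary_structure(chain) if s.kind == "helix"]
    ho = None
    if len(spans) >= 2:
        axes = np.stack([fit_helix_axis(chain, s) for s in spans])
        ho = helix_order(HelixSet(axes))
    return {"HO": ho, "Rg": radius_of_gyration(chain), "n_helices": len(spans)}


def score_structure_file(path) -> dict:
    """Score a backbone PDB file: helix count, HO, Rg."""
    from .pdbio import read_backbone_pdb
    chain, _ = read_backbone_pdb(path)
    out = score_chain(chain)
    out["path"] = str(path)
    return out


def motif_type_string(spec: TopologySpec, library: MotifLibrary) -> str:
    """Concatenated bend classes of a topology's loops, e.g. ``hvcc``."""
    return "".join(library.get(mid).bend_class for mid in spec.motif_ids)


def select_topologies(results: list[tuple[EnumerationEntry, float]],
                      mode: str = "lowest_ho", k: int = 3,
                      library: MotifLibrary | None = None) -> list[tuple[EnumerationEntry, float]]:
    """Pick design targets from scored enumeration entries.

    ``results`` holds (entry, HO) pairs.  ``lowest_ho`` returns the k
    entries of smallest HO (ties broken by the lexicographic topology
    identity).  ``motif_coverage`` greedily adds entries maximizing the
    number of not-yet-covered motif ids, lower HO breaking ties.
    """
    if k < 0:
        raise GeometryError("k must be non-negative")
    if k > len(results):
        import warnings
        warnings.warn(f"requested {k} topologies but only {len(results)} available")
        k = len(results)

    def identity(entry: EnumerationEntry):
        return (entry.spec.motif_ids, entry.spec.helix_lengths)

    if mode == "lowest_ho":
        ranked = sorted(results, key=lambda r: (r[1], identity(r[0])))
        return ranked[:k]
    if mode == "motif_coverage":
        chosen: list[tuple[EnumerationEntry, float]] = []
        covered: set[str] = set()
        pool = list(results)
        while len(chosen) < k and pool:
            best = min(pool, key=lambda r: (-len(set(r[0].spec.motif_ids) - covered),
                                            r[1], identity(r[0])))
            chosen.append(best)
            covered |= set(best[0].spec.motif_ids)
            pool.remove(best)
        return chosen
    raise GeometryError(f"unknown selection mode {mode!r}")


def ho_histogram(values, bin_width: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of HO values in fixed-width bins over [0, 1]."""
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(np.asarray(list(values), float), bins=edges)
    return counts, edges
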