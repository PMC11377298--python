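"""Combinatorial enumeration of all-α backbone topologies.

Backbones are grown N→C helix-by-helix: each growth stage appends one
loop motif from the library plus one ideal helix, partial chains are
pruned by a soft-sphere steric-clash score, and full-length structures
are additionally filtered by radius of gyration.  The staged scheme of
the full-scale pipeline (four-helix intermediates of 70 residues grown to
90-residue five-helix and 110-residue six-helix structures, the last
helix prepended N-terminally) is expressed through per-stage cumulative
length budgets.

An analytic counting oracle (`count_helix_compositions`) provides the
exact number of helix-length tuples compatible with a length budget, and
`forced_extension_children` reproduces the counter arithmetic of the
final growth stage when the remaining budget forces a unique helix length
per motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (BackboneChain, GeometryError, append_motif_then_helix,
                       build_ideal_helix)
from .library import MotifLibrary, MotifRecord

#: Per-element van der Waals radii (Å) of backbone atoms; CB counts as C.
VDW_RADII = {"N": 1.55, "C": 1.70, "O": 1.52, "CA": 1.70, "CB": 1.70}

#: Scale applied to N–O pair contact distances so that backbone hydrogen
#: bonds (O…N ≈ 3.0 Å in an α-helix) do not register as clashes.
_POLAR_PAIR_SCALE = 0.95

DEFAULT_CLASH_WEIGHT = 0.1
DEFAULT_CLASH_THRESHOLD = 4.0
DEFAULT_RG_THRESHOLD = 14.0
DEFAULT_HELIX_RANGE = (5, 35)


@dataclass(frozen=True)
class TopologySpec:
    """The combinatorial recipe of one generated backbone."""

    helix_lengths: tuple[int, ...]
    motif_ids: tuple[str, ...]
    total_length: int

    def __post_init__(self) -> None:
        if len(self.motif_ids) != len(self.helix_lengths) - 1:
            raise GeometryError("need one motif per helix junction")

    @staticmethod
    def from_parts(helix_lengths: Sequence[int], motifs: Sequence[MotifRecord]) -> "TopologySpec":
        total = sum(helix_lengths) + sum(m.loop_len for m in motifs)
        return TopologySpec(tuple(int(h) for h in helix_lengths),
                            tuple(m.motif_id for m in motifs), int(total))


@dataclass
class EnumerationConfig:
    """Thresholds and budgets governing one enumeration run."""

    library: MotifLibrary
    n_helices: int
    total_length: int
    helix_len_range: tuple[int, int] = DEFAULT_HELIX_RANGE
    clash_weight: float = DEFAULT_CLASH_WEIGHT
    clash_threshold: float | None = DEFAULT_CLASH_THRESHOLD
    rg_threshold: float | None = DEFAULT_RG_THRESHOLD
    stage_budgets: tuple[int | None, ...] | None = None
    motif_class_subset: tuple[str, ...] | None = None
    final_side: str = "C_terminal"
    with_cb: bool = True
    max_structures: int | None = None

    def __post_init__(self) -> None:
        if self.n_helices < 1:
            raise GeometryError("need at least one helix")
        hmin, hmax = self.helix_len_range
        if hmin < 1 or hmax < hmin:
            raise GeometryError("invalid helix length range")
        if self.clash_threshold is not None and self.clash_threshold < 0:
            raise GeometryError("clash threshold must be positive")
        if self.rg_threshold is not None and self.rg_threshold < 0:
            raise GeometryError("Rg threshold must be non-negative")
        if self.stage_budgets is None:
            self.stage_budgets = default_stage_budgets(self.n_helices, self.total_length)
        if len(self.stage_budgets) != self.n_helices:
            raise GeometryError("one stage budget entry per helix")
        if self.stage_budgets[-1] not in (None, self.total_length):
            raise GeometryError("final stage budget must equal the total length")
        budgets = list(self.stage_budgets)
        budgets[-1] = self.total_length
        self.stage_budgets = tuple(budgets)

    @property
    def active_library(self) -> MotifLibrary:
        if self.motif_class_subset is None:
            return self.library
        return self.library.subset(self.motif_class_subset)


def default_stage_budgets(n_helices: int, total_length: int) -> tuple[int | None, ...]:
    """The staged-growth length schedule.

    Five- and six-helix runs at full scale follow the 70→90(→110) scheme
    when the totals match it; otherwise only the final total is pinned.
    """
    budgets: list[int | None] = [None] * n_helices
    if n_helices == 5 and total_length == 90:
        budgets[3] = 70
    elif n_helices == 6 and total_length == 110:
        budgets[3] = 70
        budgets[4] = 90
    budgets[-1] = total_length
    return tuple(budgets)


@dataclass
class EnumerationCounters:
    """Run counters; ``rg_pass <= clash_pass <= enumerated``."""

    enumerated: int = 0       # full-length children tested (pre-clash)
    clash_pass: int = 0       # full-length children passing the clash filter
    rg_pass: int = 0          # ... additionally passing the Rg filter
    stage_tested: list[int] = field(default_factory=list)
    stage_passed: list[int] = field(default_factory=list)


@dataclass
class EnumerationEntry:
    spec: TopologySpec
    chain: BackboneChain | None
    clash: float | None
    rg: float | None


@dataclass
class EnumerationResult:
    entries: list[EnumerationEntry]
    counters: EnumerationCounters
    n_selected: int = 0


# ---------------------------------------------------------------------------
# Scores


def clash_score(chain: BackboneChain, weight: float = DEFAULT_CLASH_WEIGHT) -> float:
    """Weighted soft-sphere repulsion over non-local backbone atom pairs.

    ``weight × Σ max(0, σ_ij − d_ij)²`` over atom pairs at least two
    residues apart, with σ_ij the sum of per-element radii (N–O pairs
    scaled to admit backbone hydrogen bonds).  Zero iff no such pair is
    closer than its contact distance.
    """
    coords = chain.all_coords()
    res_idx = chain.atom_residue_index()
    names = np.tile(np.array(chain.atom_names), chain.n_residues)
    radii = np.array([VDW_RADII[nm] for nm in names])
    max_sigma = 2.0 * max(VDW_RADII.values())
    tree = cKDTree(coords)
    pairs = tree.query_pairs(max_sigma, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    i, j = pairs[:, 0], pairs[:, 1]
    keep = np.abs(res_idx[i] - res_idx[j]) >= 2
    i, j = i[keep], j[keep]
    if len(i) == 0:
        return 0.0
    sigma = radii[i] + radii[j]
    polar = (((names[i] == "N") & (names[j] == "O"))
             | ((names[i] == "O") & (names[j] == "N")))
    sigma = np.where(polar, sigma * _POLAR_PAIR_SCALE, sigma)
    d = np.linalg.norm(coords[i] - coords[j], axis=1)
    overlap = np.maximum(0.0, sigma - d)
    return float(weight * np.sum(overlap ** 2))


def radius_of_gyration(chain: BackboneChain) -> float:
    """Unweighted RMS distance of CA atoms from their centroid, Å."""
    cas = chain.ca
    centroid = cas.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((cas - centroid) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Analytic counting oracle


def count_helix_compositions(n_helices: int, loop_lengths: Sequence[int],
                             total_length: int,
                             helix_range: tuple[int, int] = DEFAULT_HELIX_RANGE) -> int:
    """Number of helix-length tuples filling a residue budget exactly.

    Counts integer tuples (h_1..h_n), each within ``helix_range``, with
    Σ h_i = total_length − Σ loop_lengths.  Dynamic programming over the
    remaining budget; returns 0 for infeasible budgets.
    """
    if n_helices < 1:
        raise GeometryError("need at least one helix")
    if len(loop_lengths) != n_helices - 1:
        raise GeometryError("need one loop length per junction")
    target = total_length - int(sum(loop_lengths))
    hmin, hmax = helix_range
    if target < 0:
        return 0

    @lru_cache(maxsize=None)
    def ways(k: int, remaining: int) -> int:
        if remaining < 0:
            return 0
        if k == 0:
            return 1 if remaining == 0 else 0
        return sum(ways(k - 1, remaining - h) for h in range(hmin, hmax + 1))

    return ways(n_helices, target)


def forced_extension_children(n_parents: int, library: MotifLibrary,
                              current_total: int, target_total: int,
                              helix_range: tuple[int, int] = DEFAULT_HELIX_RANGE,
                              ) -> int:
    """Children tested when one helix+loop extension must hit a length target.

    For each motif the helix length is forced to
    ``target_total − current_total − loop_len``; motifs whose forced
    length falls outside ``helix_range`` contribute nothing.  When every
    motif is admissible this is exactly ``n_parents × len(library)`` — the
    counter arithmetic behind the staged growth of the full-scale run.
    """
    if n_parents < 0:
        raise GeometryError("parent count must be non-negative")
    hmin, hmax = helix_range
    admissible = 0
    for motif in library:
        h = target_total - current_total - motif.loop_len
        if hmin <= h <= hmax:
            admissible += 1
    return n_parents * admissible


# ---------------------------------------------------------------------------
# Staged growth


def _admissible_lengths(cfg: EnumerationConfig, stage: int, current_total: int,
                        loop_len: int) -> range:
    """Helix lengths allowed for ``stage`` (0-based) given the chain so far."""
    hmin, hmax = cfg.helix_len_range
    budget = cfg.stage_budgets[stage]
    loops = [m.loop_len for m in cfg.active_library]
    if not loops:
        raise GeometryError("motif library is empty")
    lo_loop, hi_loop = min(loops), max(loops)
    remaining_stages = cfg.n_helices - stage - 1
    if budget is not None:
        h = budget - current_total - loop_len
        return range(h, h + 1) if hmin <= h <= hmax else range(0)
    # leave room for the remaining stages to reach some later pinned budget
    next_pin = None
    for s in range(stage + 1, cfg.n_helices):
        if cfg.stage_budgets[s] is not None:
            next_pin = (s, cfg.stage_budgets[s])
            break
    assert next_pin is not None  # final budget is always pinned
    s_pin, pin_total = next_pin
    # after choosing h at this stage, s_pin - stage further (loop + helix)
    # blocks must fit exactly into the pinned budget
    k = s_pin - stage
    lo = max(hmin, pin_total - current_total - loop_len - k * (hi_loop + hmax))
    hi = min(hmax, pin_total - current_total - loop_len - k * (lo_loop + hmin))
    return range(lo, hi + 1) if lo <= hi else range(0)


def grow_one_stage(partial: BackboneChain | None, cfg: EnumerationConfig,
                   stage: int, current_total: int,
                   side: str = "C_terminal") -> tuple[list, int]:
    """All clash-accepted children of one partial chain at one stage.

    Returns ``(children, n_tested)`` where each child is a tuple
    ``(motif, helix_len, chain, clash)``; ``n_tested`` counts every
    (motif, helix length) combination evaluated, including clash-rejected
    ones.
    """
    children = []
    tested = 0
    geometry_needed = (partial is not None)
    for motif in sorted(cfg.active_library, key=lambda m: m.motif_id):
        for h in _admissible_lengths(cfg, stage, current_total, motif.loop_len):
            tested += 1
            if not geometry_needed:
                children.append((motif, h, None, None))
                continue
            child = append_motif_then_helix(partial, motif, h, side=side)
            cl = clash_score(child, cfg.clash_weight)
            if cfg.clash_threshold is None or cl < cfg.clash_threshold:
                children.append((motif, h, child, cl))
    return children, tested


def enumerate_backbones(cfg: EnumerationConfig) -> EnumerationResult:
    """Exhaustive staged enumeration under the configured filters.

    Grows every topology helix-by-helix, pruning clash-failing partial
    chains at each stage, and keeps full-length structures whose radius
    of gyration passes the compactness filter.  Output entries are sorted
    lexicographically by motif-id sequence then helix lengths, and at most
    ``max_structures`` chains are materialized (all survivors are always
    counted).
    """
    counters = EnumerationCounters(stage_tested=[0] * cfg.n_helices,
                                   stage_passed=[0] * cfg.n_helices)
    filters_on = cfg.clash_threshold is not None or cfg.rg_threshold is not None
    materialize = cfg.max_structures is None or cfg.max_structures > 0
    needs_geometry = filters_on or materialize
    entries: list[EnumerationEntry] = []
    n_selected = 0
    lib = cfg.active_library
    if len(lib) == 0 and cfg.n_helices > 1:
        return EnumerationResult(entries=[], counters=counters)

    hmin, hmax = cfg.helix_len_range

    def recurse(stage: int, partial, current_total: int,
                helices: tuple[int, ...], motifs: tuple[MotifRecord, ...]) -> None:
        nonlocal n_selected
        if stage == cfg.n_helices:
            return
        last = stage == cfg.n_helices - 1
        side = cfg.final_side if last else "C_terminal"
        if stage == 0:
            for h in _first_stage_lengths(cfg):
                counters.stage_tested[0] += 1
                chain = build_ideal_helix(h, with_cb=cfg.with_cb) if needs_geometry else None
                counters.stage_passed[0] += 1
                if cfg.n_helices == 1:
                    _finalize(chain, (h,), ())
                else:
                    recurse(1, chain, h, (h,), ())
            return
        children, tested = grow_one_stage(
            partial if needs_geometry else None, cfg, stage, current_total, side=side)
        counters.stage_tested[stage] += tested
        if last:
            counters.enumerated += tested
        for motif, h, chain, cl in children:
            counters.stage_passed[stage] += 1
            new_total = current_total + motif.loop_len + h
            if side == "N_terminal":
                new_helices = (h,) + helices
                new_motifs = (motif,) + motifs
            else:
                new_helices = helices + (h,)
                new_motifs = motifs + (motif,)
            if last:
                counters.clash_pass += 1
                _finalize(chain, new_helices, new_motifs, cl)
            else:
                recurse(stage + 1, chain, new_total, new_helices, new_motifs)

    def _finalize(chain, helices, motifs, cl: float | None = None) -> None:
        nonlocal n_selected
        rg = radius_of_gyration(chain) if chain is not None else None
        if cfg.rg_threshold is not None:
            if rg is None or rg >= cfg.rg_threshold:
                return
        counters.rg_pass += 1
        n_selected += 1
        if cfg.max_structures is not None and len(entries) >= cfg.max_structures:
            return
        spec = TopologySpec.from_parts(helices, motifs)
        entries.append(EnumerationEntry(spec=spec, chain=chain, clash=cl, rg=rg))

    recurse(0, None, 0, (), ())
    entries.sort(key=lambda e: (e.spec.motif_ids, e.spec.helix_lengths))
    # single-helix runs have no junction; enumerated then counts first-stage tests
    if cfg.n_helices == 1:
        counters.enumerated = counters.stage_tested[0]
        counters.clash_pass = counters.stage_passed[0]
    return EnumerationResult(entries=entries, counters=counters,
                             n_selected=n_selected)


def _first_stage_lengths(cfg: EnumerationConfig) -> range:
    hmin, hmax = cfg.helix_len_range
    budget = cfg.stage_budgets[0]
    if budget is not None:
        return range(budget, budget + 1) if hmin <= budget <= hmax else range(0)
    loops = [m.loop_len for m in cfg.active_library]
    lo_loop, hi_loop = min(loops), max(loops)
    next_pin = None
    for s in range(1, cfg.n_helices):
        if cfg.stage_budgets[s] is not None:
            next_pin = (s, cfg.stage_budgets[s])
            break
    s_pin, pin_total = next_pin
    k = s_pin  # further growth steps to the pinned stage
    lo = max(hmin, pin_total - k * (hi_loop + hmax))
    hi = min(hmax, pin_total - k * (lo_loop + hmin))
    return range(lo, hi + 1) if lo <= hi else range(0)
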