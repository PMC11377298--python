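"""Representative HLH motif libraries: mining, records and serialization.

The library pipeline mirrors how typical HLH motifs are obtained from
native structures: extract HLH units, featurize their geometry, cluster
each loop length (1–5 residues) with density-peak clustering, and keep
the density-peak member of every cluster as the representative motif.
The resulting records carry everything needed to rebuild the loop between
two ideal helices: the loop torsions plus the junction (flanking)
pseudo-torsions, the loop ABEGO string, and the bend class.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cluster import ClusterResult, density_peak_cluster
from .geometry import (BackboneChain, GeometryError, SegmentSpan,
                       append_motif_then_helix, build_ideal_helix,
                       fit_helix_axis)
from .motifs import (HLHInstance, bend_angle_from_axes, classify_bend,
                     extract_hlh_units, featurize_hlh, motif_aa_profile)
from .secondary import assign_secondary_structure

SCHEMA_VERSION = 1

#: Flanking helix length used when rebuilding a motif to measure its bend.
_REBUILD_HELIX_LEN = 12


@dataclass
class MotifRecord:
    """One representative HLH motif."""

    motif_id: str
    loop_len: int
    loop_torsions: np.ndarray    # (loop_len, 3)
    pre_psi: float
    pre_omega: float
    post_phi: float
    loop_abego: str
    bend_class: str
    bend_angle: float
    aa_profile: list[dict[str, float]] | None = None

    def __post_init__(self) -> None:
        self.loop_torsions = np.asarray(self.loop_torsions, float).reshape(-1, 3)
        if not (1 <= self.loop_len <= 5):
            raise GeometryError("motif loop length must be in [1, 5]")
        if len(self.loop_torsions) != self.loop_len:
            raise GeometryError("loop torsion count must equal loop length")
        if len(self.loop_abego) != self.loop_len:
            raise GeometryError("loop ABEGO length must equal loop length")
        if self.bend_class not in ("h", "v", "c"):
            raise GeometryError(f"unknown bend class {self.bend_class!r}")

    def to_dict(self) -> dict:
        d = {
            "motif_id": self.motif_id,
            "loop_len": self.loop_len,
            "torsions": [[round(float(x), 6) for x in row] for row in self.loop_torsions],
            "pre_psi": round(self.pre_psi, 6),
            "pre_omega": round(self.pre_omega, 6),
            "post_phi": round(self.post_phi, 6),
            "abego": self.loop_abego,
            "bend_class": self.bend_class,
            "bend_angle": round(self.bend_angle, 4),
        }
        if self.aa_profile is not None:
            d["aa_profile"] = self.aa_profile
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MotifRecord":
        return cls(
            motif_id=d["motif_id"], loop_len=int(d["loop_len"]),
            loop_torsions=np.asarray(d["torsions"], float),
            pre_psi=float(d["pre_psi"]), pre_omega=float(d["pre_omega"]),
            post_phi=float(d["post_phi"]), loop_abego=d["abego"],
            bend_class=d["bend_class"], bend_angle=float(d["bend_angle"]),
            aa_profile=d.get("aa_profile"),
        )


@dataclass
class MotifLibrary:
    """Ordered collection of motif records plus provenance metadata."""

    records: list[MotifRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.motif_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise GeometryError("motif ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, motif_id: str) -> MotifRecord:
        for r in self.records:
            if r.motif_id == motif_id:
                return r
        raise KeyError(f"unknown motif id {motif_id!r}")

    def subset(self, classes) -> "MotifLibrary":
        keep = [r for r in self.records if r.bend_class in set(classes)]
        return MotifLibrary(records=keep, provenance=dict(self.provenance))

    def to_json(self) -> str:
        obj = {
            "schema_version": SCHEMA_VERSION,
            "provenance": self.provenance,
            "motifs": [r.to_dict() for r in self.records],
        }
        return json.dumps(obj, indent=1, sort_keys=False)

    def checksum(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "MotifLibrary":
        obj = json.loads(text)
        if obj.get("schema_version") != SCHEMA_VERSION:
            raise GeometryError("unsupported motif library schema version")
        return cls(records=[MotifRecord.from_dict(d) for d in obj["motifs"]],
                   provenance=obj.get("provenance", {}))

    @classmethod
    def load(cls, path) -> "MotifLibrary":
        return cls.from_json(Path(path).read_text())


def rebuild_motif_chain(motif: MotifRecord,
                        helix_len: int = _REBUILD_HELIX_LEN) -> BackboneChain:
    """Two ideal helices joined through the motif's stored torsions."""
    return append_motif_then_helix(build_ideal_helix(helix_len), motif, helix_len)


def measure_motif_bend(motif: MotifRecord,
                       helix_len: int = _REBUILD_HELIX_LEN) -> float:
    """Bend angle of the rebuilt two-helix chain, degrees."""
    chain = rebuild_motif_chain(motif, helix_len)
    s1 = SegmentSpan("helix", 1, helix_len)
    s2 = SegmentSpan("helix", helix_len + motif.loop_len + 1,
                     2 * helix_len + motif.loop_len)
    return bend_angle_from_axes(fit_helix_axis(chain, s1), fit_helix_axis(chain, s2))


def record_from_instance(inst: HLHInstance, motif_id: str,
                         aa_profile=None) -> MotifRecord:
    """Freeze one HLH instance into a motif record.

    The bend angle stored is the one measured after rebuilding the motif
    between ideal helices (the geometry the enumeration engine will use),
    so the record's class is consistent with its rebuilt geometry.
    """
    probe = MotifRecord(
        motif_id=motif_id, loop_len=inst.loop_len,
        loop_torsions=inst.loop_torsions,
        pre_psi=inst.pre_psi, pre_omega=inst.pre_omega, post_phi=inst.post_phi,
        loop_abego=inst.loop_abego, bend_class="h", bend_angle=0.0,
        aa_profile=aa_profile,
    )
    b = measure_motif_bend(probe)
    probe.bend_angle = b
    probe.bend_class = classify_bend(b)
    return probe


def pick_representative(cluster: ClusterResult, cluster_id: int,
                        instances: list[HLHInstance],
                        motif_id: str, with_profile: bool = False) -> MotifRecord:
    """Motif record for one cluster: its density-peak member.

    The cluster center is, by construction, the maximum-density member of
    its own cluster.
    """
    members = np.where(cluster.labels == cluster_id)[0]
    if len(members) == 0:
        raise GeometryError(f"cluster {cluster_id} is empty")
    center = int(cluster.center_indices[cluster_id])
    profile = None
    if with_profile:
        member_insts = [instances[int(i)] for i in members]
        if any(i.sequence is not None for i in member_insts):
            profile = motif_aa_profile(member_insts)
    return record_from_instance(instances[center], motif_id, aa_profile=profile)


def allocate_cluster_counts(counts_per_len: dict[int, int],
                            n_total: int) -> dict[int, int]:
    """Split a total motif budget across loop lengths, ∝ available units.

    Largest-remainder apportionment, at most as many clusters per length
    as units; lengths with no units get zero.
    """
    lens = sorted(k for k, v in counts_per_len.items() if v > 0)
    total_pts = sum(counts_per_len[k] for k in lens)
    if total_pts == 0:
        return {}
    quota = {k: n_total * counts_per_len[k] / total_pts for k in lens}
    alloc = {k: min(int(np.floor(quota[k])), counts_per_len[k]) for k in lens}
    remaining = n_total - sum(alloc.values())
    frac_order = sorted(lens, key=lambda k: (-(quota[k] - np.floor(quota[k])), k))
    idx = 0
    while remaining > 0 and idx < 10 * len(lens):
        k = frac_order[idx % len(lens)]
        if alloc[k] < counts_per_len[k]:
            alloc[k] += 1
            remaining -= 1
        idx += 1
    return {k: v for k, v in alloc.items() if v > 0}


def build_motif_library(chains: list[tuple[str, BackboneChain, str | None]],
                        n_motifs: int = 18,
                        min_loop: int = 1, max_loop: int = 5,
                        d_c_percentile: float = 2.0,
                        with_profiles: bool = False,
                        per_length_counts: dict[int, int] | None = None,
                        ) -> MotifLibrary:
    """Mine a representative motif library from backbone chains.

    Parameters
    ----------
    chains
        Tuples of (source id, chain, optional one-letter sequence).
    n_motifs
        Total number of representatives across all loop lengths.
    per_length_counts
        Explicit number of clusters for each loop length; overrides the
        proportional allocation of ``n_motifs``.
    """
    by_len: dict[int, list[HLHInstance]] = {}
    for source_id, chain, seq in chains:
        spans = assign_secondary_structure(chain)
        for inst in extract_hlh_units(chain, spans, source_id=source_id,
                                      sequence=seq, min_loop=min_loop,
                                      max_loop=max_loop):
            by_len.setdefault(inst.loop_len, []).append(inst)
    if not by_len:
        raise GeometryError("no HLH units found in the input chains")
    counts = {k: len(v) for k, v in by_len.items()}
    if per_length_counts is None:
        per_length_counts = allocate_cluster_counts(counts, n_motifs)
    records: list[MotifRecord] = []
    class_counters = {"h": 0, "v": 0, "c": 0}
    for loop_len in sorted(per_length_counts):
        insts = by_len.get(loop_len, [])
        k = min(per_length_counts[loop_len], len(insts))
        if k == 0:
            continue
        feats = np.stack([featurize_hlh(i, _owner_chain(i, chains)).values
                          for i in insts])
        result = density_peak_cluster(feats, n_centers=k,
                                      d_c_percentile=d_c_percentile)
        for cid in range(result.n_clusters):
            rec = pick_representative(result, cid, insts,
                                      motif_id="tmp", with_profile=with_profiles)
            class_counters[rec.bend_class] += 1
            rec.motif_id = f"{rec.bend_class}{class_counters[rec.bend_class]}"
            records.append(rec)
    records.sort(key=lambda r: (r.bend_class, int(r.motif_id[1:])))
    prov = {
        "n_sources": len(chains),
        "n_units": int(sum(counts.values())),
        "per_length_counts": {str(k): int(v) for k, v in sorted(per_length_counts.items())},
        "d_c_percentile": d_c_percentile,
    }
    return MotifLibrary(records=records, provenance=prov)


def _owner_chain(inst: HLHInstance, chains) -> BackboneChain:
    for source_id, chain, _ in chains:
        if source_id == inst.source_id:
            return chain
    raise GeometryError(f"no source chain {inst.source_id!r}")
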