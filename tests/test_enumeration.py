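"""Enumeration engine: scores, counting oracle, staged growth, determinism."""

import itertools

import numpy as np
import pytest

from helixweaver.enumeration import (EnumerationConfig, TopologySpec,
                                     clash_score, count_helix_compositions,
                                     enumerate_backbones,
                                     forced_extension_children,
                                     radius_of_gyration)
from helixweaver.geometry import BackboneChain, GeometryError, build_ideal_helix
from helixweaver.library import MotifLibrary


def brute_force_compositions(n, loops, total, lo, hi):
    target = total - sum(loops)
    return sum(1 for tup in itertools.product(range(lo, hi + 1), repeat=n)
               if sum(tup) == target)


def fake_chain(ca_points):
    ca = np.asarray(ca_points, float)
    return BackboneChain(n=ca.copy(), ca=ca, c=ca.copy(), o=ca.copy(),
                         torsions=np.full((len(ca), 3), np.nan))


class TestClashScore:
    def test_separated_helices_score_zero(self):
        h1 = build_ideal_helix(10)
        h2 = h1.transformed(np.eye(3), np.array([30.0, 0.0, 0.0]))
        combined = BackboneChain(
            n=np.vstack([h1.n, h2.n]), ca=np.vstack([h1.ca, h2.ca]),
            c=np.vstack([h1.c, h2.c]), o=np.vstack([h1.o, h2.o]))
        assert clash_score(combined) == 0.0

    def test_single_ideal_helix_is_clash_free(self):
        assert clash_score(build_ideal_helix(25)) == 0.0

    def test_superposed_copy_scores_huge(self):
        h = build_ideal_helix(10)
        doubled = BackboneChain(
            n=np.vstack([h.n, h.n]), ca=np.vstack([h.ca, h.ca]),
            c=np.vstack([h.c, h.c]), o=np.vstack([h.o, h.o]))
        assert clash_score(doubled) > 4.0

    def test_score_scales_with_weight(self):
        h = build_ideal_helix(8)
        doubled = BackboneChain(
            n=np.vstack([h.n, h.n]), ca=np.vstack([h.ca, h.ca]),
            c=np.vstack([h.c, h.c]), o=np.vstack([h.o, h.o]))
        assert clash_score(doubled, weight=0.2) == pytest.approx(
            2 * clash_score(doubled, weight=0.1))


class TestRadiusOfGyration:
    def test_single_residue_zero(self):
        assert radius_of_gyration(fake_chain([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_points_half_separation(self):
        chain = fake_chain([[0, 0, 0], [10.0, 0, 0]])
        assert radius_of_gyration(chain) == pytest.approx(5.0)


class TestCompositionCounting:
    def test_forced_single_helix(self):
        assert count_helix_compositions(1, [], 20, (5, 35)) == 1

    def test_two_helices_with_loop(self):
        # brute force: (h1, h2) with h1 + h2 = 28, both in [5, 35] -> 19
        assert count_helix_compositions(2, [2], 30, (5, 35)) == 19

    def test_infeasible_zero(self):
        assert count_helix_compositions(2, [2], 8, (5, 35)) == 0

    def test_matches_brute_force_random_cases(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(1, 4))
            loops = [int(rng.integers(1, 6)) for _ in range(n - 1)]
            total = int(rng.integers(5, 41))
            lo = int(rng.integers(1, 6))
            hi = int(rng.integers(lo, lo + 12))
            assert count_helix_compositions(n, loops, total, (lo, hi)) == \
                brute_force_compositions(n, loops, total, lo, hi)


class TestForcedExtension:
    def test_all_motifs_admissible(self, full_library):
        # loops 1-5 force helix lengths 15-19, all inside [5, 35]
        assert forced_extension_children(1000, full_library, 70, 90) == \
            1000 * len(full_library)

    def test_out_of_range_motifs_drop_out(self, full_library):
        # only 4 residues remain: no forced helix length is >= 5
        assert forced_extension_children(1000, full_library, 86, 90) == 0

    def test_negative_parents_rejected(self, full_library):
        with pytest.raises(GeometryError):
            forced_extension_children(-1, full_library, 70, 90)


class TestEnumeration:
    def _unfiltered(self, library, n_helices, total):
        return EnumerationConfig(
            library=library, n_helices=n_helices, total_length=total,
            clash_threshold=None, rg_threshold=None, max_structures=0)

    def test_count_equals_oracle_single_motif(self, single_motif_library):
        cfg = self._unfiltered(single_motif_library, 2, 30)
        res = enumerate_backbones(cfg)
        loop = single_motif_library.records[0].loop_len
        expected = count_helix_compositions(2, [loop], 30, (5, 35))
        assert res.counters.rg_pass == expected
        assert res.counters.enumerated == expected

    def test_count_equals_oracle_multi_motif(self, toy_library):
        lib = MotifLibrary(records=toy_library.records[:3], provenance={})
        cfg = self._unfiltered(lib, 3, 34)
        res = enumerate_backbones(cfg)
        expected = sum(
            count_helix_compositions(3, [m1.loop_len, m2.loop_len], 34, (5, 35))
            for m1 in lib for m2 in lib)
        assert res.counters.rg_pass == expected

    def test_rg_zero_blocks_everything(self, single_motif_library):
        cfg = EnumerationConfig(library=single_motif_library, n_helices=2,
                                total_length=24, rg_threshold=0.0,
                                max_structures=10)
        res = enumerate_backbones(cfg)
        assert res.counters.rg_pass == 0
        assert res.counters.clash_pass > 0  # clash filter unaffected

    def test_filter_monotonicity(self, toy_library):
        accepted = []
        for rg in (8.0, 11.0, 14.0, None):
            cfg = EnumerationConfig(library=toy_library, n_helices=2,
                                    total_length=26, rg_threshold=rg,
                                    max_structures=0)
            accepted.append(enumerate_backbones(cfg).counters.rg_pass)
        assert accepted == sorted(accepted)

    def test_deterministic_output_stream(self, toy_library):
        cfg = dict(library=toy_library, n_helices=2, total_length=26,
                   max_structures=50)
        specs1 = [e.spec for e in enumerate_backbones(EnumerationConfig(**cfg)).entries]
        specs2 = [e.spec for e in enumerate_backbones(EnumerationConfig(**cfg)).entries]
        assert specs1 == specs2
        ordered = [(e.motif_ids, e.helix_lengths) for e in specs1]
        assert ordered == sorted(ordered)

    def test_impossible_budget_empty(self, toy_library):
        cfg = self._unfiltered(toy_library, 3, 12)  # cannot fit 3 helices
        res = enumerate_backbones(cfg)
        assert res.counters.enumerated == 0
        assert res.entries == []

    def test_forced_final_stage_counter_arithmetic(self, full_library):
        """When the last helix is forced, enumerated = parents x library."""
        cfg = EnumerationConfig(
            library=full_library, n_helices=2, total_length=24,
            stage_budgets=(8, 24), clash_threshold=None, rg_threshold=None,
            max_structures=0)
        res = enumerate_backbones(cfg)
        parents = res.counters.stage_passed[0]
        admissible = sum(1 for m in full_library
                         if 5 <= 24 - 8 - m.loop_len <= 35)
        assert res.counters.enumerated == parents * admissible
        assert res.counters.enumerated == forced_extension_children(
            parents, full_library, 8, 24)

    def test_n_terminal_final_stage(self, single_motif_library):
        cfg = EnumerationConfig(
            library=single_motif_library, n_helices=2, total_length=24,
            stage_budgets=(12, 24), final_side="N_terminal",
            clash_threshold=None, rg_threshold=None, max_structures=None)
        res = enumerate_backbones(cfg)
        loop = single_motif_library.records[0].loop_len
        for e in res.entries:
            # the prepended helix comes first in chain order
            assert e.spec.helix_lengths == (24 - 12 - loop, 12)

    def test_counters_monotone(self, toy_library):
        cfg = EnumerationConfig(library=toy_library, n_helices=2,
                                total_length=26, max_structures=5)
        c = enumerate_backbones(cfg).counters
        assert c.rg_pass <= c.clash_pass <= c.enumerated

    def test_max_structures_caps_materialization_not_counts(self, toy_library):
        cfg_all = EnumerationConfig(library=toy_library, n_helices=2,
                                    total_length=26, max_structures=None)
        cfg_cap = EnumerationConfig(library=toy_library, n_helices=2,
                                    total_length=26, max_structures=3)
        full = enumerate_backbones(cfg_all)
        capped = enumerate_backbones(cfg_cap)
        assert len(capped.entries) == 3
        assert capped.counters.rg_pass == full.counters.rg_pass
        assert capped.n_selected == full.n_selected


class TestTopologySpec:
    def test_junction_count_enforced(self):
        with pytest.raises(GeometryError):
            TopologySpec((10, 10), ("m1", "m2"), 25)
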