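"""Curation, pairwise comparison modes, contact order, two-state stats."""

import dataclasses

import numpy as np
import pytest

import foldpath as fp
from foldpath import synthetic as syn
from foldpath.psn import PSNParams
from foldpath.structures import Manifest

from conftest import conf_from_coords, rigid_move


class TestCuration:
    def test_catalogue_retains_15_of_17(self, manifest):
        retained, summary = fp.curate_manifest(manifest)
        assert summary["n_conformations_before"] == 17
        assert summary["n_conformations"] == 15
        assert summary["n_intermediates"] == 10
        assert summary["n_excluded"] == 2
        assert not retained.table["excluded"].any()

    def test_no_exclusions_is_identity(self, manifest):
        clean = manifest.table.copy()
        clean["excluded"] = False
        clean["exclusion_reason"] = ""
        retained, summary = fp.curate_manifest(Manifest(clean))
        assert summary["n_conformations"] == 17
        assert summary["n_excluded"] == 0

    def test_all_excluded_warns(self, manifest, caplog):
        allx = manifest.table.copy()
        allx["excluded"] = True
        allx["exclusion_reason"] = "test"
        with caplog.at_level("WARNING"):
            retained, summary = fp.curate_manifest(Manifest(allx))
        assert summary["n_conformations"] == 0
        assert "retained no conformations" in caplog.text


class TestSameIntermediate:
    def test_identical_copies_score_one(self):
        c = syn.make_helix(20, protein_id="p")
        recs = fp.compare_same_intermediate([c, c, c])
        assert len(recs) == 3  # all unordered pairs
        assert all(r.tm == pytest.approx(1.0, abs=1e-9) for r in recs)
        assert all(r.band == "same_fold" for r in recs)

    def test_rigid_copy_scores_one(self):
        c = syn.make_helix(20, protein_id="p")
        recs = fp.compare_same_intermediate([c, rigid_move(c, 3)])
        assert recs[0].tm == pytest.approx(1.0, abs=1e-6)

    def test_strongly_distinct_conformations_change_fold(self):
        """Structurally distinct conformers of one intermediate (three
        independent disordered chains) never share a fold."""
        variants = [syn.make_coil(40, seed=s, protein_id="p") for s in (1, 2, 3)]
        recs = fp.compare_same_intermediate(variants)
        assert len(recs) == 3
        assert all(r.tm < 0.5 for r in recs)
        assert all(r.band != "same_fold" for r in recs)

    def test_mismatched_intermediate_index_is_error(self):
        a = syn.make_helix(10, protein_id="p")
        b = dataclasses.replace(a, intermediate_index=2)
        with pytest.raises(ValueError):
            fp.compare_same_intermediate([a, b])

    def test_needs_two(self):
        with pytest.raises(ValueError):
            fp.compare_same_intermediate([syn.make_helix(10)])


class TestAcrossTime:
    def test_proxy_pathway_scores_all_one(self):
        pw = fp.generate_proxy_intermediates(syn.make_coil(30, seed=1), k=5)
        recs = fp.compare_across_time(pw, distance="all")
        assert recs
        assert all(r.tm == pytest.approx(1.0, abs=1e-9) for r in recs)

    def test_two_intermediates_give_one_record(self):
        pw = fp.generate_proxy_intermediates(syn.make_helix(10), k=5)
        recs = fp.compare_across_time(pw, distance="consecutive")
        assert len(recs) == 1
        assert recs[0].mode == "across_time_consecutive"

    def test_consecutive_beats_distant_on_hinged_pathways(self):
        """Per-step hinge rotation accumulates: for a fixed earlier
        intermediate, its next-time comparison is more similar on
        average than its more time-distant comparisons."""
        from collections import defaultdict
        cons, dist = defaultdict(list), defaultdict(list)
        for seed in range(20):
            native = syn.make_coil(40, seed=seed, protein_id="sim")
            pw = syn.simulate_cotranslational_pathway(
                native, k=10, nonnative_hinge_per_step=25.0, seed=seed)
            for r in fp.compare_across_time(pw, distance="all"):
                bucket = cons if r.mode == "across_time_consecutive" else dist
                bucket[r.conf_a].append(r.tm)
        for earlier in dist:
            assert np.mean(cons[earlier]) > np.mean(dist[earlier])

    def test_distance_vocabulary(self):
        pw = fp.generate_proxy_intermediates(syn.make_helix(20), k=5)
        recs = fp.compare_across_time(pw, distance="all")
        modes = {r.mode for r in recs}
        assert modes == {"across_time_consecutive", "across_time_distant"}
        with pytest.raises(ValueError):
            fp.compare_across_time(pw, distance="skip")

    def test_short_pathway_is_error(self):
        pw = fp.generate_proxy_intermediates(syn.make_helix(5), k=5)
        with pytest.raises(ValueError):
            fp.compare_across_time(pw)


class TestEvaluatePredictions:
    def test_perfect_predictions(self):
        exps = [dataclasses.replace(syn.make_helix(20, protein_id="p"),
                                    intermediate_index=i) for i in range(3)]
        recs, gaps = fp.evaluate_predictions(exps, list(exps))
        assert len(recs) == 3 and not gaps
        assert all(r.tm == pytest.approx(1.0, abs=1e-9) for r in recs)

    def test_random_coil_decoys_miss_helical_targets(self):
        """Unfolded decoys never reach the same-fold line on average."""
        tms = []
        for seed in range(20):
            target = syn.make_helix(50, protein_id="p")
            decoy = syn.make_coil(50, seed=seed, protein_id="p")
            recs, _ = fp.evaluate_predictions([target], [decoy])
            tms.append(recs[0].tm)
        assert np.mean(tms) < 0.5

    def test_unmatched_goes_to_gap_report(self):
        exps = [dataclasses.replace(syn.make_helix(10, protein_id="p"),
                                    intermediate_index=i) for i in range(3)]
        recs, gaps = fp.evaluate_predictions(exps, list(exps[:2]))
        assert len(recs) == 2 and len(gaps) == 1
        assert gaps[0].endswith("2a")

    def test_rank_selection(self):
        exp = syn.make_helix(30, protein_id="p")
        rank1 = syn.make_hinged(exp, 15, 90.0)
        rank2 = exp
        recs, _ = fp.evaluate_predictions([exp], [rank1, rank2])
        assert recs[0].tm < 1.0                    # defaults to the first listed
        recs2, _ = fp.evaluate_predictions([exp], [rank1, rank2], rank=2)
        assert recs2[0].tm == pytest.approx(1.0, abs=1e-9)


class TestEvaluateProxies:
    def test_native_full_length_scores_one(self):
        native = syn.make_helix(30, protein_id="p")
        recs = fp.evaluate_proxies(native, 5, [native])
        assert recs[0].tm == pytest.approx(1.0, abs=1e-9)
        assert recs[0].mode == "proxy_vs_experiment"

    def test_proxies_match_themselves(self):
        native = syn.make_coil(30, seed=8, protein_id="p")
        proxies = fp.generate_proxy_intermediates(native, 5).single_conformations()
        recs = fp.evaluate_proxies(native, 5, proxies)
        assert len(recs) == len(proxies)
        assert all(r.tm == pytest.approx(1.0, abs=1e-9) for r in recs)

    def test_perturbed_intermediates_score_below_one(self):
        native = syn.make_helix(40, protein_id="p")
        prefix = native.subset(range(20))
        tms = []
        for angle in (0.0, 40.0, 120.0):
            exp = syn.make_hinged(prefix, 10, angle) if angle else prefix
            recs = fp.evaluate_proxies(native, 5, [exp])
            tms.append(recs[0].tm)
        assert tms[0] == pytest.approx(1.0, abs=1e-9)
        assert tms[0] > tms[1] > tms[2]

    def test_experimental_beyond_native_skipped(self, caplog):
        native = syn.make_helix(20, protein_id="p")
        longer = syn.make_helix(40, protein_id="p")
        with caplog.at_level("WARNING"):
            recs = fp.evaluate_proxies(native, 5, [longer])
        assert recs == []
        assert "native covers only" in caplog.text


class TestContactOrder:
    def test_constructed_contact_set(self):
        # only (1,5) and (2,8) are within 6 A at sequence separation >= 2
        coords = np.array([
            [0, 0, 0], [0, 20, 0], [0, 40, 0], [0, 60, 0],
            [5, 0, 0], [0, 80, 0], [0, 100, 0], [5, 20, 0],
        ], dtype=float)
        res = fp.contact_order(conf_from_coords(coords))
        assert res.n_contacts == 2
        assert res.absolute_co == pytest.approx((4 + 6) / 2)
        assert res.relative_co == pytest.approx(5 / 8)

    def test_extended_strand_has_no_contacts(self):
        res = fp.contact_order(syn.make_strand(30))
        assert res.n_contacts == 0
        assert res.absolute_co is None and res.relative_co is None

    def test_minimum_separation_bound(self):
        res = fp.contact_order(syn.make_coil(30, seed=5))
        if res.n_contacts:
            assert res.absolute_co >= 2

    def test_helix_contact_order_in_expected_band(self):
        """Only |i-j| in {2,3,4} can be within the Ca cutoff on an ideal
        helix, so the mean separation lies in [2, 4]."""
        res = fp.contact_order(syn.make_helix(40))
        assert res.n_contacts > 0
        assert 2 <= res.absolute_co <= 4

    def test_too_short_is_error(self):
        with pytest.raises(ValueError):
            fp.contact_order(syn.make_helix(1))


def _displaced_suffix(native, start_pos, shift):
    coords = native.coords.copy()
    coords[start_pos:] += shift
    return dataclasses.replace(
        native, residues=[dataclasses.replace(r, ca=c)
                          for r, c in zip(native.residues, coords)])


class TestTwoStateStats:
    @pytest.fixture
    def setting(self):
        native = syn.make_helix(30, protein_id="ts")
        sse = [("A", 1, 15), ("B", 16, 30)]
        unfolded = _displaced_suffix(native, 15, np.array([200.0, 0, 0]))
        return native, sse, unfolded

    def test_simultaneous_formation_gives_fraction_one(self, setting):
        native, sse, unfolded = setting
        pw = fp.Pathway("ts", [(0, [unfolded]), (1, [native])])
        rep = fp.two_state_stats([pw] * 3, native, sse)
        assert rep.two_state_fraction == 1.0
        assert all(rep.is_two_state)

    def test_constructed_half_half_mixture(self, setting):
        """5 concerted + 5 sequential pathways -> fraction 0.5."""
        native, sse, unfolded = setting
        sse3 = [("A", 1, 10), ("B", 11, 20), ("C", 21, 30)]
        coords = native.coords.copy()
        coords[20:] += [150.0, 0, 0]       # C unfolded, A-B native
        partial = dataclasses.replace(
            native, residues=[dataclasses.replace(r, ca=c)
                              for r, c in zip(native.residues, coords)])
        far = _displaced_suffix(_displaced_suffix(native, 20, np.array([150.0, 0, 0])),
                                10, np.array([0.0, 150.0, 0]))
        two_state = fp.Pathway("ts", [(0, [far]), (1, [far]), (2, [far]),
                                      (3, [native])])
        sequential = fp.Pathway("ts", [(0, [far]), (1, [partial]), (2, [partial]),
                                       (3, [native])])  # B-C forms 2 later
        rep = fp.two_state_stats([two_state] * 5 + [sequential] * 5,
                                 native, sse3, window=1)
        assert rep.two_state_fraction == pytest.approx(0.5)

    def test_fraction_invariant_under_duplication_and_order(self, setting):
        native, sse, unfolded = setting
        pw_fast = fp.Pathway("ts", [(0, [unfolded]), (1, [native])])
        pws = [pw_fast, pw_fast]
        rep1 = fp.two_state_stats(pws, native, sse)
        rep2 = fp.two_state_stats(pws * 3, native, sse)
        assert rep1.two_state_fraction == rep2.two_state_fraction

    def test_single_sse_pair_is_degenerate(self, setting, caplog):
        native, sse, unfolded = setting
        pw = fp.Pathway("ts", [(0, [unfolded]), (1, [native])])
        with caplog.at_level("WARNING"):
            rep = fp.two_state_stats([pw], native, sse)
        assert rep.two_state_fraction == 1.0
        assert "trivially two-state" in caplog.text

    def test_input_validation(self, setting):
        native, sse, unfolded = setting
        with pytest.raises(ValueError):
            fp.two_state_stats([], native, sse)
        pw = fp.Pathway("ts", [(0, [unfolded]), (1, [native])])
        with pytest.raises(ValueError):
            fp.two_state_stats([pw], native, [("A", 1, 15)])

    def test_record_frames_and_bands_consistent(self):
        pw = fp.generate_proxy_intermediates(syn.make_coil(25, seed=3), k=5)
        recs = fp.compare_across_time(pw, distance="all")
        df = fp.analyses.records_to_frame(recs)
        assert set(df.columns) >= {"protein_id", "mode", "tm", "band"}
        for r in recs:
            assert 0 < r.tm <= 1
            assert r.band == fp.similarity_band(r.tm)
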