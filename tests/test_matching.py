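import numpy as np
import pytest

from axonmatch.io_formats import ControlPointTable
from axonmatch.matching import (MatchSession, accept_match, match_report,
                                persistent_candidates,
                                varicosity_seeded_search)
from axonmatch.registration import (AffineTransform, fit_affine,
                                    residual_error)
from axonmatch.skeletons import BBox, Skeleton, path_length
from axonmatch.synthetic import (GeneratorConfig, generate_neuropil,
                                 generate_scene)
from axonmatch.uniqueness import NEVER
from conftest import straight_axon


def small_scene(seed=0, n_axons=40):
    cfg = GeneratorConfig(volume_extent=np.full(3, 60_000.0),
                          n_axons=n_axons, label_fraction=0.3,
                          break_probability=0.0,
                          deformation_amplitude=1500.0)
    return generate_scene(cfg, seed=seed, n_control_points=15,
                          cp_noise_sd=100.0), cfg


class TestPersistentCandidates:
    def test_template_copy_persists_fully(self, rng):
        box = BBox.cube([0, 0, 0], 5000.0)
        template = straight_axon([-30_000, 0, 0], [1, 0, 0], 60_000,
                                 tree_id=100)
        decoys = [straight_axon([0, 20_000, 0], [0, 1, 0], 40_000,
                                tree_id=2)]
        ranking = persistent_candidates(
            template, [template, decoys[0]], box, 5000.0)
        assert ranking.best.em_axon_id == 100
        assert ranking.best.never_drops
        assert np.all(ranking.candidate_counts >= 1)

    def test_count_curve_non_increasing(self):
        scene, cfg = small_scene(seed=1)
        aff = fit_affine(scene.control_points)
        lm = max(scene.lm_skeletons, key=path_length)
        ranking = persistent_candidates(lm.transformed(aff.apply),
                                        scene.em_skeletons, cfg.seed_box,
                                        5000.0)
        assert np.all(np.diff(ranking.candidate_counts) <= 0)

    def test_ground_truth_recovered_on_small_scene(self):
        scene, cfg = small_scene(seed=2)
        aff = fit_affine(scene.control_points)
        hits = total = 0
        for lm in scene.lm_skeletons:
            if path_length(lm) < 30_000:
                continue
            r = persistent_candidates(lm.transformed(aff.apply),
                                      scene.em_skeletons, cfg.seed_box,
                                      5000.0)
            total += 1
            hits += (r.best.em_axon_id == scene.correspondence[lm.tree_id])
        assert total >= 5 and hits == total

    def test_result_invariant_to_candidate_order(self):
        scene, cfg = small_scene(seed=3)
        aff = fit_affine(scene.control_points)
        lm = max(scene.lm_skeletons, key=path_length)
        template = lm.transformed(aff.apply)
        fwd = persistent_candidates(template, scene.em_skeletons,
                                    cfg.seed_box, 5000.0)
        rev = persistent_candidates(template, scene.em_skeletons[::-1],
                                    cfg.seed_box, 5000.0)
        assert [c.em_axon_id for c in fwd.ranking] == \
            [c.em_axon_id for c in rev.ranking]

    def test_empty_candidates_instructive_error(self):
        template = straight_axon([0, 0, 0], [1, 0, 0], 10_000)
        with pytest.raises(ValueError, match="widen"):
            persistent_candidates(template, [], BBox.cube([0, 0, 0], 5000.0),
                                  5000.0)


class TestVaricositySeededSearch:
    def _axon_with_varicosity(self, tree_id, offset_y, var_index=20):
        s = straight_axon([-15_000, offset_y, 0], [1, 0, 0], 30_000,
                          tree_id=tree_id)
        nid = int(s.node_ids[var_index])
        s.annotations.setdefault(nid, set()).add("varicosity")
        return s

    def test_single_axon_with_varicosity_at_seed(self):
        a = self._axon_with_varicosity(1, 0)
        seed = a.positions_of(a.nodes_with_tag("varicosity"))[0]
        full, subset, box, warn = varicosity_seeded_search(
            seed, AffineTransform.identity(), [a])
        assert [s.tree_id for s in subset] == [1] and warn is None

    def test_no_varicosities_returns_full_set_with_warning(self):
        a = straight_axon([-15_000, 0, 0], [1, 0, 0], 30_000, tree_id=1)
        full, subset, box, warn = varicosity_seeded_search(
            [0, 0, 0], AffineTransform.identity(), [a])
        assert subset == [] and warn is not None
        assert [s.tree_id for s in full] == [1]

    def test_matches_exhaustive_box_scan(self, rng):
        cfg = GeneratorConfig(volume_extent=np.full(3, 50_000.0), n_axons=25)
        em = generate_neuropil(cfg, seed=7)
        from axonmatch.synthetic import place_varicosities
        em, _ = place_varicosities(em, cfg, seed=7)
        seed_pos = cfg.volume_extent / 2
        full, subset, box, _ = varicosity_seeded_search(
            seed_pos, AffineTransform.identity(), em,
            box_extent=(4000.0, 4000.0, 6000.0))
        expected_full = {s.tree_id for s in em
                         if np.any(box.contains(s.positions))}
        assert {s.tree_id for s in full} == expected_full
        for s in subset:
            vp = s.positions_of(s.nodes_with_tag("varicosity"))
            assert np.any(box.contains(vp))


class TestMatchSession:
    def _session(self):
        t = AffineTransform.identity()
        empty = ControlPointTable.from_arrays(np.empty((0, 3)),
                                              np.empty((0, 3)))
        return MatchSession(transform=t, control_points=empty,
                            freeform_threshold=100)

    def _pair(self, tree_id=1, shift=0.0):
        # bent polyline so control points picked on it are non-degenerate
        pts = np.array([[0, shift, 0], [10_000, shift, 0],
                        [10_000, shift + 10_000, 0],
                        [10_000, shift + 10_000, 10_000.0]])
        edges = np.array([[0, 1], [1, 2], [2, 3]])
        lm = Skeleton(tree_id, np.arange(4), pts, edges)
        em = Skeleton(tree_id, np.arange(4), pts.copy(), edges)
        return lm, em

    def test_first_match_updates_transform_and_log(self):
        session = self._session()
        lm, em = self._pair()
        cps = ControlPointTable.from_arrays(lm.positions,
                                            em.positions)
        accept_match(session, lm, em, cps)
        assert len(session.control_points) == 4
        assert len(session.matches) == 1

    def test_zero_cp_match_leaves_transform(self):
        session = self._session()
        before = session.transform
        lm, em = self._pair()
        accept_match(session, lm, em, None)
        assert session.transform is before

    def test_rematching_conflict(self):
        session = self._session()
        lm, em = self._pair()
        accept_match(session, lm, em, None)
        with pytest.raises(ValueError, match="already matched"):
            accept_match(session, lm, em, None)

    def test_off_axon_control_point_rejected(self):
        session = self._session()
        lm, em = self._pair()
        bad = ControlPointTable.from_arrays(
            np.array([[0.0, 50_000, 0]] * 3 + [[0.0, 0, 0]]),
            np.array([[0.0, 0, 0]] * 4))
        with pytest.raises(ValueError, match="does not lie"):
            accept_match(session, lm, em, bad)

    def test_accumulated_cps_improve_heldout_residual(self):
        """After several synthetic matches the refit transform beats the
        initial coarse fit on held-out landmarks."""
        rng = np.random.default_rng(0)
        truth = AffineTransform(scale=np.array([1.1, 0.95, 1.02]),
                                translation=np.array([2000.0, -1000, 500]))
        # coarse initial fit from 5 noisy landmarks
        lm0 = rng.uniform(0, 80_000, (5, 3))
        coarse = fit_affine(ControlPointTable.from_arrays(
            lm0, truth.apply(lm0) + rng.normal(0, 2000, (5, 3))))
        session = MatchSession(
            transform=coarse,
            control_points=ControlPointTable.from_arrays(
                lm0, truth.apply(lm0) + rng.normal(0, 2000, (5, 3))),
            freeform_threshold=10_000)
        hold_lm = rng.uniform(0, 80_000, (30, 3))
        holdout = ControlPointTable.from_arrays(hold_lm,
                                                truth.apply(hold_lm))
        before = residual_error(session.transform, holdout).mean_nm
        for k in range(10):
            lm_ax = straight_axon(rng.uniform(0, 60_000, 3),
                                  rng.normal(size=3), 20_000, tree_id=k + 1)
            em_ax = lm_ax.transformed(truth.apply)
            em_ax.tree_id = k + 1
            idx = [0, 15, 30]
            cps = ControlPointTable.from_arrays(
                lm_ax.positions[idx],
                em_ax.positions[idx] + rng.normal(0, 100, (3, 3)))
            accept_match(session, lm_ax, em_ax, cps)
        after = residual_error(session.transform, holdout).mean_nm
        assert after < before

    def test_match_report_totals(self):
        session = self._session()
        for k in range(5):
            lm, em = self._pair(tree_id=k + 1, shift=k * 30_000.0)
            cps = ControlPointTable.from_arrays(lm.positions[[0, 2]],
                                                em.positions[[0, 2]])
            accept_match(session, lm, em, cps, duration_s=60.0)
        rep = match_report(session)
        assert rep["n_matches"] == 5
        assert rep["total_control_points"] == 10
        assert rep["cps_per_match_mean"] == pytest.approx(2.0)
        assert rep["total_duration_s"] == pytest.approx(300.0)

    def test_empty_session_report_rejected(self):
        with pytest.raises(ValueError):
            match_report(self._session())
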