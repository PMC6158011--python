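"""LM-to-EM axon identification.

The initial match works by elimination: the coarsely transformed LM skeleton
serves as a template, and every EM axon traversing the seed box is scored by
how far along the template (in distance from the seed-box center) it remains
persistently within λ_align — the same final-dropout rule as the uniqueness
analysis, so the number of surviving candidates vs distance is monotonically
non-increasing.  Once the template is longer than the local uniqueness
length, one candidate remains.

Subsequent matches exploit accumulated constraints: each accepted match
contributes its varicosities/branchpoints as new control points, the
registration is refitted (affine while few points, free-form once enough
accumulate), and varicosity-seeded search boxes of a few µm replace the full
marching-sphere scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import ControlPointTable
from .registration import fit_affine, fit_freeform, residual_error
from .skeletons import BBox, Skeleton, resample_polyline
from .uniqueness import NEVER, _binned_presence, _final_dropout


@dataclass
class CandidateScore:
    em_axon_id: int
    persistence_distance: float   # nm; NEVER (=-1) encodes "never drops"
    never_drops: bool
    mean_distance_to_template: float  # nm
    has_varicosity_in_search_box: bool


@dataclass
class CandidateRanking:
    ranking: list                # CandidateScore, best first
    distances: np.ndarray        # bin lower edges, nm
    candidate_counts: np.ndarray  # candidates persisting beyond each distance

    @property
    def best(self) -> CandidateScore:
        return self.ranking[0]

    def to_dict(self) -> dict:
        return {"ranking": [vars(c) for c in self.ranking],
                "distances_nm": self.distances.tolist(),
                "candidate_counts": self.candidate_counts.tolist()}


def persistent_candidates(lm_axon_transformed: Skeleton, em_axons,
                          seed_box: BBox, lambda_align: float,
                          bin_width: float = 1000.0,
                          resample_spacing: float = 500.0,
                          pre_resampled: bool = False) -> CandidateRanking:
    """Rank EM candidates by persistence along the transformed LM template.

    ``em_axons`` should be the dense reconstruction of all axons traversing
    the seed box.  Ranking: never-dropping candidates first, then by final
    dropout distance; ties broken by smaller mean distance to the template.
    Set ``pre_resampled`` when the candidates are already resampled (matching
    many templates against the same pool).
    """
    em_axons = list(em_axons)
    if not em_axons:
        raise ValueError("empty candidate set: reconstruct all axons "
                         "traversing the seed box, or widen the box")
    ref = resample_polyline(lm_axon_transformed, resample_spacing)
    d_ref = np.linalg.norm(ref.positions - seed_box.center, axis=1)
    ref_bins = np.floor(d_ref / bin_width).astype(int)
    n_bins = int(ref_bins.max()) + 1
    occupied = np.zeros(n_bins, dtype=bool)
    occupied[ref_bins] = True
    scores = []
    for em in em_axons:
        oth = em if pre_resampled else resample_polyline(em, resample_spacing)
        tree = cKDTree(oth.positions)
        dist, _ = tree.query(ref.positions, k=1,
                             distance_upper_bound=lambda_align * (1 + 1e-12))
        present = dist <= lambda_align
        presence = _binned_presence(ref_bins, n_bins, present)
        drop = _final_dropout(presence, occupied, bin_width)
        # mean distance from template nodes to the candidate (tie-breaker)
        full_dist, _ = tree.query(ref.positions, k=1)
        has_var = bool(np.any(seed_box.contains(
            oth.positions_of(oth.nodes_with_tag("varicosity"))))) \
            if len(oth.nodes_with_tag("varicosity")) else False
        scores.append(CandidateScore(
            em_axon_id=em.tree_id, persistence_distance=drop,
            never_drops=(drop == NEVER),
            mean_distance_to_template=float(full_dist.mean()),
            has_varicosity_in_search_box=has_var))
    scores.sort(key=lambda c: (not c.never_drops,
                               -c.persistence_distance,
                               c.mean_distance_to_template))
    distances = np.arange(n_bins) * bin_width
    counts = np.array([sum(1 for c in scores
                           if c.never_drops or c.persistence_distance > d)
                       for d in distances])
    return CandidateRanking(ranking=scores, distances=distances,
                            candidate_counts=counts)


def varicosity_seeded_search(seed_varicosity_lm, transform, em_axons,
                             box_extent=(2000.0, 2000.0, 3000.0),
                             growth_factor: float = 1.5,
                             max_growth_steps: int = 5):
    """Candidates in a small box around a transformed LM varicosity.

    Returns (all_candidates, with_varicosity, box_used, warning).  The box is
    grown by ``growth_factor`` per step (up to ``max_growth_steps``) while no
    candidate shows a varicosity inside it; if none is ever found, the full
    intersecting set is returned with a warning flag.
    """
    center = np.asarray(transform.apply(np.asarray(seed_varicosity_lm,
                                                   dtype=float)))
    extent = np.asarray(box_extent, dtype=float)
    for step in range(max_growth_steps + 1):
        half = extent * (growth_factor ** step) / 2.0
        box = BBox(center, half)
        inside = [s for s in em_axons if np.any(box.contains(s.positions))]
        with_var = []
        for s in inside:
            var_nodes = s.nodes_with_tag("varicosity")
            if len(var_nodes) and np.any(box.contains(
                    s.positions_of(var_nodes))):
                with_var.append(s)
        if with_var:
            return inside, with_var, box, None
    return inside, [], box, "no candidate varicosity found at any box size"


@dataclass
class MatchRecord:
    lm_axon_id: int
    em_axon_id: int
    n_new_cps: int
    n_candidates: int | None = None
    duration_s: float | None = None


@dataclass
class MatchSession:
    """Accumulating state of an iterative matching campaign."""

    transform: object
    control_points: ControlPointTable
    matches: list = field(default_factory=list)
    freeform_threshold: int = 20   # refit free-form once this many CPs
    freeform_kwargs: dict = field(default_factory=dict)
    cp_on_axon_tolerance: float = 500.0  # nm

    @property
    def matched_lm_ids(self) -> set:
        return {m.lm_axon_id for m in self.matches}


def accept_match(session: MatchSession, lm_axon: Skeleton, em_axon: Skeleton,
                 new_cps: ControlPointTable | None,
                 n_candidates: int | None = None,
                 duration_s: float | None = None) -> MatchSession:
    """Record a match, append its control points, refit the registration.

    New control points must lie on the matched axons (each LM point within
    ``cp_on_axon_tolerance`` of an LM-axon node, same for EM).  With no new
    points the transform is left unchanged.  Re-matching an LM axon is a
    conflict error.
    """
    if lm_axon.tree_id in session.matched_lm_ids:
        raise ValueError(f"LM axon {lm_axon.tree_id} already matched")
    n_new = 0 if new_cps is None else len(new_cps)
    if n_new:
        tol = session.cp_on_axon_tolerance
        d_lm, _ = cKDTree(lm_axon.positions).query(new_cps.lm, k=1)
        d_em, _ = cKDTree(em_axon.positions).query(new_cps.em, k=1)
        if np.any(d_lm > tol) or np.any(d_em > tol):
            raise ValueError("control point does not lie on the matched "
                             f"axons (tolerance {tol} nm)")
        merged = ControlPointTable.from_arrays(
            np.vstack([session.control_points.lm, new_cps.lm]),
            np.vstack([session.control_points.em, new_cps.em]),
            source=np.concatenate([session.control_points.source,
                                   new_cps.source]))
        session.control_points = merged
        if len(merged) >= session.freeform_threshold:
            session.transform = fit_freeform(merged,
                                             **session.freeform_kwargs)
        elif len(merged) >= 3:
            # below 3 pairs no transform is identifiable; keep the current one
            session.transform = fit_affine(merged)
    session.matches.append(MatchRecord(
        lm_axon_id=lm_axon.tree_id, em_axon_id=em_axon.tree_id,
        n_new_cps=n_new, n_candidates=n_candidates, duration_s=duration_s))
    return session


def match_report(session: MatchSession) -> dict:
    """Per-match effort accounting plus cumulative totals."""
    if not session.matches:
        raise ValueError("session has no matches")
    rows = [vars(m) for m in session.matches]
    n_cps = [m.n_new_cps for m in session.matches]
    durations = [m.duration_s for m in session.matches
                 if m.duration_s is not None]
    return {
        "matches": rows,
        "n_matches": len(rows),
        "total_control_points": int(len(session.control_points)),
        "cps_per_match_mean": float(np.mean(n_cps)),
        "cps_per_match_sd": float(np.std(n_cps, ddof=1)) if len(n_cps) > 1
        else 0.0,
        "total_duration_s": float(np.sum(durations)) if durations else None,
        "transform_type": type(session.transform).__name__,
    }
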