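"""Marching-sphere measurement of axonal trajectory uniqueness.

Given a dense reconstruction of all axons traversing a small seed box of
edge length λ_align, each axon is asked: at what Euclidean distance from the
seed-box center does the last other seed-box axon leave my λ_align-surround
for good?  That distance is the axon's uniqueness length d_unique; the
population statistic d_unique90 is the distance at which 90% of axons have
become unique.

Procedure per (reference, neighbor) pair:

1. resample the reference to a fixed node spacing so results do not depend
   on annotator node density;
2. around every reference node place a sphere of radius λ_align and record
   whether the neighbor has any node inside (closed ball) — the binary
   neighbor presence vector;
3. sort reference nodes by distance from the seed-box center, pool into
   distance bins (default 1 µm), and take the *final* true-to-false
   transition as the dropout distance (re-entries reset the dropout: a
   neighbor counts as present until it leaves for good);
4. a neighbor present through the last occupied bin never drops out; a
   neighbor never present has dropout distance 0.

d_unique of the reference axon is the maximum dropout distance over all
neighbors (never-dropping neighbor => never unique).  Distances are reported
at the lower edge of their bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .skeletons import BBox, Skeleton, resample_polyline

NEVER = -1.0  # sentinel for "never drops out" / "never unique"


@dataclass
class UniquenessParams:
    """Parameters of the marching-sphere analysis.

    lambda_align doubles as the sphere radius and (by default) the seed-box
    edge length, following the coarse-alignment precision it models.
    """

    lambda_align: float            # nm; sphere radius r
    seed_box: BBox                 # axons traversing this box are analyzed
    bin_width: float = 1000.0      # nm distance bins
    resample_spacing: float = 500.0  # nm node spacing before sphere placement

    def __post_init__(self):
        if self.lambda_align <= 0:
            raise ValueError("lambda_align must be > 0")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")

    @classmethod
    def cubic(cls, center, lambda_align: float, **kw) -> "UniquenessParams":
        """Seed box = cube of edge lambda_align at ``center``."""
        return cls(lambda_align=lambda_align,
                   seed_box=BBox.cube(center, lambda_align), **kw)


@dataclass
class DropoutRecord:
    reference_axon_id: int
    neighbor_axon_id: int
    dropout_distance: float  # nm, or NEVER if the neighbor never drops


@dataclass
class UniquenessCurve:
    axon_ids: np.ndarray
    d_unique: np.ndarray          # nm per axon; NEVER if never unique
    bin_width: float
    distances: np.ndarray         # bin lower edges, nm
    fraction_unique: np.ndarray   # per bin
    d_unique90: float | None      # nm, None if <90% ever become unique
    n_axons: int

    def to_dict(self) -> dict:
        return {"axon_ids": self.axon_ids.tolist(),
                "d_unique_nm": self.d_unique.tolist(),
                "bin_width_nm": self.bin_width,
                "distances_nm": self.distances.tolist(),
                "fraction_unique": self.fraction_unique.tolist(),
                "d_unique90_nm": self.d_unique90,
                "n_axons": self.n_axons}


def traversing_axons(skeletons, seed_box: BBox) -> set[int]:
    """Ids of axons with at least one node inside the closed seed box."""
    out = set()
    for s in skeletons:
        if np.any(seed_box.contains(s.positions)):
            out.add(s.tree_id)
    return out


def _binned_presence(ref_bins: np.ndarray, n_bins: int,
                     present: np.ndarray) -> np.ndarray:
    """Per-bin neighbor presence: any presence among ref nodes in the bin."""
    out = np.zeros(n_bins, dtype=bool)
    np.logical_or.at(out, ref_bins[present], True)
    return out


def _final_dropout(presence_bins: np.ndarray, occupied: np.ndarray,
                   bin_width: float) -> float:
    """Dropout distance from a per-bin presence vector.

    Returns 0 if never present, NEVER if present in the last occupied bin,
    else the lower edge of the last bin with presence.
    """
    hit = np.nonzero(presence_bins)[0]
    if len(hit) == 0:
        return 0.0
    last_occupied = int(np.nonzero(occupied)[0][-1])
    last_present = int(hit[-1])
    if last_present >= last_occupied:
        return NEVER
    return last_present * bin_width


def neighbor_dropout(reference: Skeleton, others, params: UniquenessParams,
                     pre_resampled: bool = False,
                     trees: dict | None = None) -> list[DropoutRecord]:
    """Dropout distance of every other axon along the reference axon.

    ``trees`` optionally maps tree_id -> prebuilt cKDTree over the (already
    resampled) neighbor nodes; callers measuring many references against the
    same pool pass it to avoid rebuilding indexes.
    """
    ref = reference if pre_resampled else \
        resample_polyline(reference, params.resample_spacing)
    center = params.seed_box.center
    d_ref = np.linalg.norm(ref.positions - center, axis=1)
    ref_bins = np.floor(d_ref / params.bin_width).astype(int)
    n_bins = int(ref_bins.max()) + 1 if len(ref_bins) else 1
    occupied = np.zeros(n_bins, dtype=bool)
    occupied[ref_bins] = True
    lam = params.lambda_align
    records = []
    for other in others:
        if other.tree_id == reference.tree_id:
            continue
        oth = other if pre_resampled else \
            resample_polyline(other, params.resample_spacing)
        # cheap reject: bounding boxes further apart than lambda everywhere
        if (np.any(oth.positions.min(0) > ref.positions.max(0) + lam) or
                np.any(oth.positions.max(0) < ref.positions.min(0) - lam)):
            records.append(DropoutRecord(reference.tree_id, other.tree_id,
                                         0.0))
            continue
        tree = trees.get(other.tree_id) if trees else None
        if tree is None:
            tree = cKDTree(oth.positions)
        dist, _ = tree.query(ref.positions, k=1,
                             distance_upper_bound=lam * (1 + 1e-12))
        present = dist <= lam
        presence = _binned_presence(ref_bins, n_bins, present)
        records.append(DropoutRecord(
            reference.tree_id, other.tree_id,
            _final_dropout(presence, occupied, params.bin_width)))
    return records


def uniqueness_lengths(skeletons, params: UniquenessParams,
                       reference_ids=None) -> UniquenessCurve:
    """Per-axon d_unique and the population fraction-unique curve.

    Only axons traversing the seed box participate (as references and as
    neighbors).  ``reference_ids`` optionally restricts the reference set
    (neighbors stay the full traversing population), which the layer
    bootstrap uses for subsampling.
    """
    traversing = traversing_axons(skeletons, params.seed_box)
    if len(traversing) < 2:
        raise ValueError("need at least 2 axons traversing the seed box")
    pool = [s for s in skeletons if s.tree_id in traversing]
    resampled = {s.tree_id: resample_polyline(s, params.resample_spacing)
                 for s in pool}
    trees = {tid: cKDTree(s.positions) for tid, s in resampled.items()}
    refs = pool if reference_ids is None else \
        [s for s in pool if s.tree_id in set(reference_ids)]
    d_unique, ids = [], []
    for ref in refs:
        others = [resampled[s.tree_id] for s in pool
                  if s.tree_id != ref.tree_id]
        recs = neighbor_dropout(resampled[ref.tree_id], others, params,
                                pre_resampled=True, trees=trees)
        drops = [r.dropout_distance for r in recs]
        if any(d == NEVER for d in drops):
            d_unique.append(NEVER)
        else:
            d_unique.append(max(drops) if drops else 0.0)
        ids.append(ref.tree_id)
    d_unique = np.array(d_unique)
    ids = np.array(ids)
    return _curve_from_d_unique(ids, d_unique, params.bin_width)


def _curve_from_d_unique(ids, d_unique, bin_width) -> UniquenessCurve:
    n = len(d_unique)
    finite = d_unique[d_unique != NEVER]
    max_bin = int(np.floor(finite.max() / bin_width)) + 1 if len(finite) else 1
    distances = np.arange(max_bin + 1) * bin_width
    frac = np.array([(np.sum((d_unique != NEVER) & (d_unique <= d)) / n)
                     for d in distances])
    idx90 = np.nonzero(frac >= 0.9)[0]
    d90 = float(distances[idx90[0]]) if len(idx90) else None
    return UniquenessCurve(axon_ids=ids, d_unique=d_unique,
                           bin_width=bin_width, distances=distances,
                           fraction_unique=frac, d_unique90=d90, n_axons=n)


def d_unique90_of_values(d_unique: np.ndarray,
                         bin_width: float = 1000.0) -> float | None:
    """d_unique90 from a bare vector of per-axon d_unique values."""
    return _curve_from_d_unique(np.arange(len(d_unique)),
                                np.asarray(d_unique, dtype=float),
                                bin_width).d_unique90


def lambda_sweep(skeletons, center, lambdas) -> dict:
    """Uniqueness curves for a sweep of λ_align values (ascending).

    The seed-box edge is rescaled to each λ, so both the sphere radius and
    the traversing-axon selection shrink together.
    """
    lambdas = list(lambdas)
    if sorted(lambdas) != lambdas:
        raise ValueError("lambdas must be sorted ascending")
    out = {}
    for lam in lambdas:
        params = UniquenessParams.cubic(center, lam)
        out[lam] = uniqueness_lengths(skeletons, params)
    return out


@dataclass
class LayerBootstrapResult:
    p_value: float
    t_statistic: float | None
    draw_d_unique90: np.ndarray
    reference_d_unique90: float
    subsample_n: int
    draws: int
    seed: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"p_value": self.p_value, "t_statistic": self.t_statistic,
                "draw_d_unique90_nm": self.draw_d_unique90.tolist(),
                "reference_d_unique90_nm": self.reference_d_unique90,
                "subsample_n": self.subsample_n, "draws": self.draws,
                "seed": self.seed, "degenerate": self.degenerate}


def layer_bootstrap_test(sample_a, sample_b, subsample_n: int = 128,
                         draws: int = 30, seed: int = 0,
                         bin_width: float = 1000.0) -> LayerBootstrapResult:
    """Is d_unique90 of population A consistent with that of population B?

    Draws ``draws`` subsamples of ``subsample_n`` axons (without
    replacement) from A's per-axon d_unique values, measures d_unique90 on
    each, and runs a one-sample t-test of those values against B's
    d_unique90.  Controls for unequal axon counts between populations.
    """
    sample_a = np.asarray(sample_a, dtype=float)
    sample_b = np.asarray(sample_b, dtype=float)
    if subsample_n > len(sample_a):
        raise ValueError("subsample_n exceeds sample size")
    rng = np.random.default_rng(seed)
    ref90 = d_unique90_of_values(sample_b, bin_width)
    if ref90 is None:
        raise ValueError("reference sample never reaches 90% uniqueness")
    vals = []
    for _ in range(draws):
        sub = sample_a[rng.choice(len(sample_a), subsample_n, replace=False)]
        v = d_unique90_of_values(sub, bin_width)
        vals.append(np.nan if v is None else v)
    vals = np.array(vals, dtype=float)
    ok = vals[~np.isnan(vals)]
    if len(ok) and np.ptp(ok) == 0:
        # all draws identical: t-test undefined; p is 1 iff equal to reference
        return LayerBootstrapResult(
            p_value=1.0 if ok[0] == ref90 else 0.0, t_statistic=None,
            draw_d_unique90=vals, reference_d_unique90=ref90,
            subsample_n=subsample_n, draws=draws, seed=seed, degenerate=True)
    t, p = stats.ttest_1samp(ok, ref90)
    return LayerBootstrapResult(
        p_value=float(p), t_statistic=float(t), draw_d_unique90=vals,
        reference_d_unique90=ref90, subsample_n=subsample_n, draws=draws,
        seed=seed)
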