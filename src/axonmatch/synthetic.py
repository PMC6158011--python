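"""Ground-truthed synthetic neuropil scenes.

Emulates the study geometry the analyses assume: a dense population of
axon-like trajectories seeded inside a small central box of a tissue-scale
volume (default: 220 axons through a (5 µm)³ box in a 130×110×85 µm³
volume), a sparse fluorescence (LM) view of a labeled subset observed
through the *inverse* of a known LM→EM map (affine plus a smooth sinusoidal
deformation of a few µm), annotation jitter, fragmentation of LM axons into
reconstructable stretches, two size classes of varicosities, and paired
landmark control points.

Axon trajectories are persistent random walks: unit steps whose direction is
von Mises–Fisher distributed around the previous direction with
concentration κ.  κ·step is roughly the persistence length; the default
(κ = 40, step 1 µm) gives gently curving axons with tortuosity in the range
seen in cortical neuropil.  κ → ∞ yields straight lines, which makes
closed-form geometry checks possible.

Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io_formats import ControlPointTable
from .registration import (AffineTransform, FreeformTransform,
                           rotation_about_axis)
from .skeletons import BBox, Skeleton


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SinusoidDeformation:
    """Separable smooth displacement field d(x) = A·sin(2πx/λ + φ), per axis.

    Applied on top of the affine (in the EM frame); analytically smooth and
    invertible by fixed-point iteration for amplitudes well below λ.
    """

    amplitude: np.ndarray = field(
        default_factory=lambda: np.full(3, 2000.0))   # nm
    wavelength: np.ndarray = field(
        default_factory=lambda: np.full(3, 100_000.0))  # nm
    phase: np.ndarray = field(default_factory=lambda: np.array([0.5, 1.7, 2.9]))

    def __post_init__(self):
        self.amplitude = np.broadcast_to(
            np.asarray(self.amplitude, dtype=float), (3,)).copy()
        self.wavelength = np.broadcast_to(
            np.asarray(self.wavelength, dtype=float), (3,)).copy()
        self.phase = np.asarray(self.phase, dtype=float)
        if np.any(self.amplitude < 0) or np.any(self.wavelength <= 0):
            raise ValueError("amplitude >= 0 and wavelength > 0 required")

    def displacement(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        return self.amplitude * np.sin(2 * np.pi * x / self.wavelength
                                       + self.phase)


class GroundTruthMap:
    """Forward LM→EM map: affine, then sinusoidal displacement."""

    def __init__(self, affine: AffineTransform,
                 deformation: SinusoidDeformation | None):
        self.affine = affine
        self.deformation = deformation

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        z = np.atleast_2d(self.affine.apply(pts))
        if self.deformation is not None:
            z = z + self.deformation.displacement(z)
        return z[0] if single else z

    def apply_inverse(self, points: np.ndarray, n_iter: int = 60) -> np.ndarray:
        """Invert by fixed-point iteration on z + D(z) = y, then affine⁻¹."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        y = np.atleast_2d(pts)
        z = y.copy()
        if self.deformation is not None:
            for _ in range(n_iter):
                z = y - self.deformation.displacement(z)
        x = self.affine.apply_inverse(z)
        x = np.atleast_2d(x)
        return x[0] if single else x


def default_affine() -> AffineTransform:
    """A plausible LM→EM map: mild rotation, anisotropic shrinkage, offset."""
    return AffineTransform(
        quaternion=rotation_about_axis([0, 0, 1], np.deg2rad(8.0)),
        scale=np.array([0.95, 0.92, 1.05]),
        translation=np.array([4000.0, -3000.0, 2000.0]))


@dataclass
class GeneratorConfig:
    """Scene parameters; defaults emulate the measured study conditions."""

    volume_extent: np.ndarray = field(
        default_factory=lambda: np.array([130_000.0, 110_000.0, 85_000.0]))
    n_axons: int = 220                # axons seeded in (hence traversing) the box
    step_length: float = 1000.0       # nm per walk step
    kappa: float = 40.0               # von Mises-Fisher concentration
    seed_box_edge: float = 5000.0     # nm; (5 µm)³ center box
    label_fraction: float = 0.15      # fraction of axons visible in LM
    lm_jitter_sd: float = 100.0       # nm annotation noise (LM voxel scale)
    break_probability: float = 0.1    # per 10 µm of path; fragments ~ d_recon
    varicosity_spacing_mean: float = 8000.0   # nm, exponential spacing
    bouton_prevalence: float = 0.6
    bouton_diameter: tuple = (1100.0, 250.0)      # nm, Normal(mean, sd)
    nonbouton_diameter: tuple = (600.0, 150.0)    # nm
    deformation_amplitude: float = 2000.0         # nm
    deformation_wavelength: float = 100_000.0     # nm
    max_steps: int = 2000

    def __post_init__(self):
        self.volume_extent = np.asarray(self.volume_extent, dtype=float)
        if not 0 <= self.label_fraction <= 1:
            raise ValueError("label_fraction must be in [0, 1]")
        if self.deformation_amplitude < 0 or self.step_length <= 0:
            raise ValueError("scales must be positive")

    @property
    def seed_box(self) -> BBox:
        return BBox.cube(self.volume_extent / 2, self.seed_box_edge)

    def ground_truth_map(self) -> GroundTruthMap:
        defo = None
        if self.deformation_amplitude > 0:
            defo = SinusoidDeformation(
                amplitude=np.full(3, self.deformation_amplitude),
                wavelength=np.full(3, self.deformation_wavelength))
        return GroundTruthMap(default_affine(), defo)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["volume_extent"] = self.volume_extent.tolist()
        return d


@dataclass
class SyntheticScene:
    em_skeletons: list
    lm_skeletons: list
    ground_truth: GroundTruthMap
    correspondence: dict          # lm tree_id -> em tree_id
    varicosities: list            # dicts per varicosity
    control_points: ControlPointTable | None
    config: GeneratorConfig
    seed: int


# ---------------------------------------------------------------------------
# persistent random walks
# ---------------------------------------------------------------------------

def _sample_vmf(rng: np.random.Generator, mu: np.ndarray,
                kappa: float) -> np.ndarray:
    """One draw from the 3D von Mises-Fisher distribution around mu."""
    if kappa < 1e-8:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)
    if np.isinf(kappa):
        return mu
    # closed-form inverse CDF for the cosine in 3D
    u = rng.random()
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.uniform(0, 2 * np.pi)
    # orthonormal frame around mu
    a = np.array([1.0, 0, 0]) if abs(mu[0]) < 0.9 else np.array([0, 1.0, 0])
    e1 = np.cross(mu, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    s = np.sqrt(max(0.0, 1.0 - w * w))
    return w * mu + s * (np.cos(phi) * e1 + np.sin(phi) * e2)


def _grow(rng, start, direction, step, kappa, lo, hi, max_steps):
    """Walk from start until leaving [lo, hi]; returns positions excl. start."""
    pts = []
    p, d = start.copy(), direction.copy()
    for _ in range(max_steps):
        d = _sample_vmf(rng, d, kappa)
        p = p + step * d
        if np.any(p < lo) or np.any(p > hi):
            break
        pts.append(p.copy())
    return pts


def generate_neuropil(config: GeneratorConfig, seed: int = 0) -> list[Skeleton]:
    """Dense EM-like axon population, every axon seeded inside the seed box."""
    rng = np.random.default_rng(seed)
    lo = np.zeros(3)
    hi = config.volume_extent
    box = config.seed_box
    skeletons = []
    for tid in range(1, config.n_axons + 1):
        start = rng.uniform(box.center - box.half_extent,
                            box.center + box.half_extent)
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        fwd = _grow(rng, start, v, config.step_length, config.kappa, lo, hi,
                    config.max_steps)
        bwd = _grow(rng, start, -v, config.step_length, config.kappa, lo, hi,
                    config.max_steps)
        pts = np.array(bwd[::-1] + [start] + fwd)
        n = len(pts)
        edges = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1) \
            if n > 1 else np.empty((0, 2), dtype=np.int64)
        skeletons.append(Skeleton(tid, np.arange(n), pts, edges,
                                  name=f"em_axon_{tid}", validate=False))
    return skeletons


# ---------------------------------------------------------------------------
# LM view
# ---------------------------------------------------------------------------

def _fragment_chains(n_nodes: int, edge_len_nm: float, break_probability: float,
                     rng) -> list[np.ndarray]:
    """Split a node chain 0..n-1 into fragments at random edge breaks."""
    if n_nodes <= 1:
        return [np.arange(n_nodes)]
    p_edge = min(1.0, break_probability * edge_len_nm / 10_000.0)
    breaks = np.nonzero(rng.random(n_nodes - 1) < p_edge)[0]
    pieces, start = [], 0
    for b in breaks:
        pieces.append(np.arange(start, b + 1))
        start = b + 1
    pieces.append(np.arange(start, n_nodes))
    return [p for p in pieces if len(p) > 0]


def derive_lm_view(em_skeletons, config: GeneratorConfig, seed: int = 0):
    """Sparse LM view: labeled subset, inverse-mapped, jittered, fragmented.

    Returns (lm_skeletons, correspondence lm_id -> em_id, ground_truth_map).
    """
    rng = np.random.default_rng(seed + 1)
    gt = config.ground_truth_map()
    n_label = int(round(config.label_fraction * len(em_skeletons)))
    labeled_idx = rng.choice(len(em_skeletons), size=n_label, replace=False)
    lm_skeletons, correspondence = [], {}
    next_id = 1
    for i in sorted(labeled_idx.tolist()):
        em = em_skeletons[i]
        lm_pos = gt.apply_inverse(em.positions)
        lm_pos = lm_pos + rng.normal(scale=config.lm_jitter_sd,
                                     size=lm_pos.shape)
        for piece in _fragment_chains(len(lm_pos), config.step_length,
                                      config.break_probability, rng):
            n = len(piece)
            edges = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1) \
                if n > 1 else np.empty((0, 2), dtype=np.int64)
            ann = {}
            for k, src in enumerate(piece.tolist()):
                tags = em.annotations.get(int(em.node_ids[src]))
                if tags:
                    ann[k] = set(tags)
            lm_skeletons.append(Skeleton(
                next_id, np.arange(n), lm_pos[piece], edges,
                annotations=ann, name=f"lm_axon_{next_id}", validate=False))
            correspondence[next_id] = em.tree_id
            next_id += 1
    return lm_skeletons, correspondence, gt


# ---------------------------------------------------------------------------
# varicosities and control points
# ---------------------------------------------------------------------------

def place_varicosities(em_skeletons, config: GeneratorConfig, seed: int = 0):
    """Annotate varicosities along each EM axon.

    Inter-varicosity path spacing is exponential with the configured mean;
    class (bouton vs non-synaptic) is Bernoulli with the configured
    prevalence and diameters are drawn per class (truncated at 100 nm).
    Returns (annotated skeletons in place, table of varicosity dicts).
    """
    if config.varicosity_spacing_mean <= 0:
        raise ValueError("varicosity spacing must be positive")
    rng = np.random.default_rng(seed + 2)
    table = []
    for s in em_skeletons:
        ei = s.edge_indices
        if not len(ei):
            continue
        # cumulative arc length along the node chain (axons are unbranched
        # chains here; general trees are handled edge-wise)
        seg = np.linalg.norm(s.positions[ei[:, 0]] - s.positions[ei[:, 1]],
                             axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = cum[-1]
        pos = rng.exponential(config.varicosity_spacing_mean)
        while pos < total:
            k = int(np.searchsorted(cum, pos))  # node index nearest beyond
            node_idx = min(k, len(s.node_ids) - 1)
            nid = int(s.node_ids[node_idx])
            is_bouton = rng.random() < config.bouton_prevalence
            mu, sd = (config.bouton_diameter if is_bouton
                      else config.nonbouton_diameter)
            diam = max(100.0, rng.normal(mu, sd))
            s.annotations.setdefault(nid, set()).add("varicosity")
            table.append({"em_tree_id": s.tree_id, "node_id": nid,
                          "position_nm": s.positions[node_idx].copy(),
                          "path_position_nm": float(pos),
                          "em_class": "bouton" if is_bouton
                          else "mitochondria_only",
                          "diameter_nm": float(diam)})
            pos += rng.exponential(config.varicosity_spacing_mean)
    return em_skeletons, table


def make_control_points(scene_map: GroundTruthMap, volume_extent,
                        n_bv: int, noise_sd: float, seed: int = 0,
                        source: str = "blood_vessel") -> ControlPointTable:
    """Paired landmarks consistent with the ground-truth map plus noise."""
    if n_bv < 3:
        raise ValueError("need at least 3 control points")
    rng = np.random.default_rng(seed + 3)
    extent = np.asarray(volume_extent, dtype=float)
    for _ in range(100):
        lm = rng.uniform(0.05 * extent, 0.95 * extent, size=(n_bv, 3))
        sv = np.linalg.svd(lm - lm.mean(axis=0), compute_uv=False)
        if sv[1] > 1e-6 * sv[0]:
            break
    else:
        raise ValueError("could not draw non-collinear control points")
    em = scene_map.apply(lm) + rng.normal(scale=noise_sd, size=(n_bv, 3))
    return ControlPointTable.from_arrays(lm, em, source=source)


def generate_scene(config: GeneratorConfig | None = None, seed: int = 0,
                   n_control_points: int = 20,
                   cp_noise_sd: float = 200.0) -> SyntheticScene:
    """Full scene: EM population, varicosities, LM view, control points."""
    config = config or GeneratorConfig()
    em = generate_neuropil(config, seed)
    em, vtable = place_varicosities(em, config, seed)
    lm, corr, gt = derive_lm_view(em, config, seed)
    cps = make_control_points(gt, config.volume_extent, n_control_points,
                              cp_noise_sd, seed)
    return SyntheticScene(em_skeletons=em, lm_skeletons=lm, ground_truth=gt,
                          correspondence=corr, varicosities=vtable,
                          control_points=cps, config=config, seed=seed)
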