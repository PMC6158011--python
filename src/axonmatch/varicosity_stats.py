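"""Varicosity geometry and statistics.

* Equivalent sphere diameter d = 2·(3V/4π)^(1/3) from a measured volume.
* EM varicosity volume from a voxel count (volumes come from an external
  voxel segmentation; this module consumes counts).
* LM varicosity volume from Gaussian fits to intensity profiles along the
  three principal axes: the ellipsoid spanned by the three full widths at
  half maximum (FWHM = 2√(2 ln 2)·σ, measured above the local baseline).
* Randomization test for a varicosity-pattern match: is the mean distance
  between LM varicosities and their nearest EM varicosity smaller than
  expected if the same number of EM varicosities sat at random skeleton
  nodes?
* Prevalence-weighted kernel-density likelihood that a varicosity of a given
  LM diameter is a synaptic bouton.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.spatial import cKDTree

from .skeletons import Skeleton, resample_polyline

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def sphere_equiv_diameter(volume: float) -> float:
    """Diameter of the sphere with the given volume (nm³ -> nm)."""
    v = np.asarray(volume, dtype=float)
    if np.any(v < 0):
        raise ValueError("volume must be >= 0")
    return 2.0 * np.cbrt(3.0 * v / (4.0 * np.pi))


def sphere_volume(diameter: float) -> float:
    d = np.asarray(diameter, dtype=float)
    return np.pi * d ** 3 / 6.0


def em_varicosity_volume(voxel_count: int, voxel_size) -> float:
    """Volume in nm³ = voxel count × voxel volume."""
    if voxel_count < 0:
        raise ValueError("voxel_count must be >= 0")
    return float(voxel_count) * float(np.prod(np.asarray(voxel_size,
                                                         dtype=float)))


class ProfileFitError(RuntimeError):
    pass


def _fit_gaussian_profile(x: np.ndarray, y: np.ndarray):
    """Fit y = a·exp(-(x-m)²/2σ²) + baseline; returns (fwhm, params)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    base0 = float(np.min(y))
    amp0 = float(np.max(y) - base0)
    if amp0 <= 0 or np.ptp(y) == 0:
        raise ProfileFitError("profile has no peak above baseline")
    m0 = float(x[np.argmax(y)])
    above = y - base0 > amp0 / 2
    sigma0 = max((x[above].max() - x[above].min()) / _FWHM, np.diff(x).min())

    def model(x, a, m, s, b):
        return a * np.exp(-0.5 * ((x - m) / s) ** 2) + b

    try:
        popt, _ = optimize.curve_fit(model, x, y,
                                     p0=[amp0, m0, sigma0, base0],
                                     maxfev=20000)
    except RuntimeError as exc:
        raise ProfileFitError(f"Gaussian fit did not converge: {exc}") from exc
    a, m, s, b = popt
    if a <= 0 or not np.isfinite(s):
        raise ProfileFitError(
            f"degenerate Gaussian fit (amplitude {a:.3g}, sigma {s:.3g})")
    return abs(s) * _FWHM, popt


def lm_varicosity_volume(profiles) -> float:
    """Ellipsoid volume from three (x, intensity) axis profiles.

    Each profile is a (positions_nm, intensities) pair along one principal
    axis of the varicosity.  V = (π/6)·FWHM₁·FWHM₂·FWHM₃ with the FWHMs as
    full ellipsoid axes.
    """
    if len(profiles) != 3:
        raise ValueError("need intensity profiles along 3 principal axes")
    fwhms = [(_fit_gaussian_profile(x, y))[0] for x, y in profiles]
    return float(np.pi / 6.0 * np.prod(fwhms))


# ---------------------------------------------------------------------------
# randomization test
# ---------------------------------------------------------------------------

@dataclass
class RandomizationResult:
    observed_mean_distance_nm: float
    null_mean_nm: float
    null_sd_nm: float
    n_draws: int
    p_value: float
    seed: int

    def to_dict(self) -> dict:
        return vars(self).copy()


def varicosity_match_test(lm_varicosities, em_skeleton: Skeleton,
                          em_varicosities, n_draws: int = 100_000,
                          seed: int = 0,
                          resample_spacing: float = 500.0,
                          chunk: int = 20_000) -> RandomizationResult:
    """Randomization test of a varicosity-pattern match.

    Statistic: mean over LM varicosities (positions already transformed to
    the EM frame) of the Euclidean distance to the *nearest* EM varicosity.
    Null: the same number of EM varicosities placed uniformly at random on
    the nodes of the EM skeleton (without replacement within a draw), after
    resampling the skeleton to a fixed node spacing so annotator node
    density does not bias the null.  p uses the +1 correction,
    p = (1 + #{null ≤ observed}) / (n_draws + 1).
    """
    lm = np.atleast_2d(np.asarray(lm_varicosities, dtype=float))
    em = np.atleast_2d(np.asarray(em_varicosities, dtype=float))
    if len(em) < 1:
        raise ValueError("need at least one EM varicosity")
    skel = resample_polyline(em_skeleton, resample_spacing)
    nodes = skel.positions
    k = len(em)
    if k > len(nodes):
        raise ValueError("more varicosities than skeleton nodes")
    observed = float(cKDTree(em).query(lm, k=1)[0].mean())

    # distances LM varicosities -> every skeleton node, reused across draws
    D = np.linalg.norm(lm[:, None, :] - nodes[None, :, :], axis=2)
    rng = np.random.default_rng(seed)
    null = np.empty(n_draws)
    done = 0
    while done < n_draws:
        b = min(chunk, n_draws - done)
        # without-replacement sampling via random-key argpartition
        keys = rng.random((b, len(nodes)))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]   # (b, k)
        # min over the k sampled nodes, mean over LM varicosities
        null[done:done + b] = D[:, idx].min(axis=2).mean(axis=0)
        done += b
    p = (1 + int(np.sum(null <= observed))) / (n_draws + 1)
    return RandomizationResult(
        observed_mean_distance_nm=observed,
        null_mean_nm=float(null.mean()), null_sd_nm=float(null.std(ddof=1)),
        n_draws=n_draws, p_value=float(p), seed=seed)


# ---------------------------------------------------------------------------
# bouton likelihood
# ---------------------------------------------------------------------------

@dataclass
class LikelihoodCurve:
    diameter_nm: np.ndarray
    p_bouton: np.ndarray
    p_nonbouton: np.ndarray
    bandwidth_nm: float
    prevalence_bouton: float

    def to_dict(self) -> dict:
        return {"diameter_nm": self.diameter_nm.tolist(),
                "p_bouton": self.p_bouton.tolist(),
                "p_nonbouton": self.p_nonbouton.tolist(),
                "bandwidth_nm": self.bandwidth_nm,
                "prevalence_bouton": self.prevalence_bouton}


def bouton_likelihood(diams_bouton, diams_nonbouton,
                      bandwidth: float = 100.0,
                      grid=None) -> LikelihoodCurve:
    """Diameter-conditional probability that a varicosity is a bouton.

    Gaussian KDE with a fixed (absolute) bandwidth per class, weighted by
    class prevalence and normalized pointwise so the two likelihoods sum
    to 1 at every grid diameter.
    """
    db = np.asarray(diams_bouton, dtype=float)
    dn = np.asarray(diams_nonbouton, dtype=float)
    if len(db) == 0 or len(dn) == 0:
        raise ValueError("both varicosity classes must be non-empty")
    if grid is None:
        grid = np.arange(0.0, 2000.0 + 1e-9, 10.0)
    grid = np.asarray(grid, dtype=float)

    def kde(data):
        # fixed absolute bandwidth: scale the factor by the sample std
        sd = data.std(ddof=1)
        if sd == 0:
            # degenerate sample: a single Gaussian bump at the common value
            return stats.norm.pdf(grid, loc=data[0], scale=bandwidth)
        return stats.gaussian_kde(data, bw_method=bandwidth / sd)(grid)

    prev_b = len(db) / (len(db) + len(dn))
    fb = kde(db) * prev_b
    fn = kde(dn) * (1 - prev_b)
    total = fb + fn
    total[total == 0] = np.finfo(float).tiny
    return LikelihoodCurve(diameter_nm=grid, p_bouton=fb / total,
                           p_nonbouton=fn / total, bandwidth_nm=bandwidth,
                           prevalence_bouton=prev_b)
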