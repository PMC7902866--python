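"""Synthetic cohorts with closed-form morphological-connectivity ground truth.

Each participant's ROI intensity distribution is Gaussian with a
participant-specific mean (ROI base mean plus an individual offset) and a
participant-specific SD (ROI base SD times a log-normal individual factor),
so the true symmetric KL divergence between any two ROIs is available in
closed form:

    sKL(N(m1, s1), N(m2, s2))
        = (s1^2/s2^2 + s2^2/s1^2)/2 - 1 + (m1 - m2)^2 (1/s1^2 + 1/s2^2)/2.

Pain thresholds are planted as a sparse linear function of a chosen set of
true MC edges (standardised across the cohort so planted weights share a
scale) plus Gaussian noise; laser thresholds are affinely rescaled into the
instrument range (1.75-4.25 J by default) and cold thresholds calibrated to
a target cohort mean and SD (9.59 +/- 0.38 s by default). The generator is
fully reproducible from its seed.

By default, individual differences are carried by the per-participant SD
factors (distribution *shape*, which is what MC measures) with graded base
SDs across ROIs, while ROI mean bases are equal across ROIs and mean offsets
are small. Regional GMV depends only on the means, so it carries no planted
signal by construction and serves as an honest negative control in recovery
experiments. Default planted weights alternate in sign with graded
magnitudes, reflecting connections that raise or lower pain thresholds with
varying effect sizes (and making the planted set identifiable rather than
exchangeable with equivalent edge combinations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .mc import lower_triangle_pairs, pair_names
from .parcellation import Parcellation, toy_parcellation
from .samples import ROISampleSet

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "gaussian_symmetric_kl",
    "generate_cohort",
    "planted_matching",
]


def gaussian_symmetric_kl(mu1, sd1, mu2, sd2):
    """Closed-form symmetrised KL divergence of two univariate Gaussians.

    Vectorised over its arguments; symmetric under argument swap; zero iff
    the two parameter pairs coincide. Raises for non-positive SDs.
    """
    mu1, sd1, mu2, sd2 = (np.asarray(v, dtype=float) for v in (mu1, sd1, mu2, sd2))
    if np.any(sd1 <= 0) or np.any(sd2 <= 0):
        raise InvalidParameterError("standard deviations must be positive")
    var_ratio = 0.5 * (sd1**2 / sd2**2 + sd2**2 / sd1**2) - 1.0
    mean_term = 0.5 * (mu1 - mu2) ** 2 * (1.0 / sd1**2 + 1.0 / sd2**2)
    out = var_ratio + mean_term
    return float(out) if out.ndim == 0 else out


def planted_matching(n_rois: int, n_edges: int) -> list[tuple[int, int]]:
    """A deterministic vertex-disjoint set of ROI-index pairs (0-based).

    Pairs ROI k with ROI k + n_rois//2, so planted edges are mutually
    vertex-disjoint and span well-separated base SDs (large baseline
    divergence), which makes recovery experiments interpretable.
    """
    half = n_rois // 2
    if n_edges > half:
        raise InvalidParameterError(
            f"cannot plant {n_edges} vertex-disjoint edges on {n_rois} ROIs"
        )
    return [(half + k, k) for k in range(n_edges)]


@dataclass
class CohortSpec:
    """Generator configuration; defaults emulate the study cohort statistics.

    Attributes
    ----------
    n_participants, n_rois, n_voxels
        Cohort size, ROI count, voxels per ROI (an int, or a (lo, hi) range
        sampled per ROI).
    roi_mean_base
        Per-ROI base intensity (scalar broadcast or length-n_rois array).
    subject_sd
        SD of the participant-level ROI mean offsets.
    subject_sigma_sd
        SD of the participant-level log-SD offsets (sigma_ir =
        roi_sigma_base_r * exp(offset)); the default carrier of individual
        morphological variation.
    roi_sigma_base
        Per-ROI base intensity SD; default spreads 0.08-0.144
        geometrically across ROIs (mild ratios: strongly mismatched SDs make
        the floored-KDE divergence estimator tail-dominated and biased up).
    planted_edges, planted_weights
        0-based ROI index pairs whose true MC drives the thresholds, and
        their weights on standardised edge values. ``None`` for the edges
        plants nothing (pure-noise thresholds); ``None`` for the weights
        gives the default mixed-sign graded pattern (+1.0, -1.1, +1.2, ...).
    cold_planted_edges, cold_planted_weights
        Optional modality-specific plant for the cold threshold; defaults to
        sharing the laser plant.
    noise_sd
        Threshold-noise SD (scalar or (laser, cold)).
    target_r2
        If set, overrides ``noise_sd``: noise is scaled so the planted linear
        predictor explains this fraction of threshold variance.
    laser_range, cold_mean_sd
        Instrument range (J) for laser; target cohort mean/SD (s) for cold.
    offset_cov
        Optional n_rois x n_rois covariance of the mean offsets; default
        independent offsets of variance subject_sd^2.
    """

    n_participants: int = 221
    n_rois: int = 90
    n_voxels: int | tuple[int, int] = 1500
    roi_mean_base: float | np.ndarray = 0.5
    subject_sd: float = 0.01
    subject_sigma_sd: float = 0.18
    roi_sigma_base: np.ndarray | None = None
    planted_edges: list[tuple[int, int]] | None = None
    planted_weights: np.ndarray | None = None
    cold_planted_edges: list[tuple[int, int]] | None = None
    cold_planted_weights: np.ndarray | None = None
    noise_sd: float | tuple[float, float] = 1.0
    target_r2: float | None = None
    laser_range: tuple[float, float] = (1.75, 4.25)
    cold_mean_sd: tuple[float, float] = (9.59, 0.38)
    offset_cov: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 3:
            raise InvalidParameterError("n_rois must be >= 3")
        if self.laser_range[0] >= self.laser_range[1]:
            raise InvalidParameterError("laser_range min must be < max")
        noise = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        if np.any(noise < 0):
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.subject_sigma_sd < 0:
            raise InvalidParameterError("subject_sigma_sd must be >= 0")
        if self.target_r2 is not None and not 0 < self.target_r2 < 1:
            raise InvalidParameterError("target_r2 must be in (0, 1)")
        for edges in (self.planted_edges, self.cold_planted_edges):
            if edges is None:
                continue
            seen = set()
            for i, j in edges:
                if i == j:
                    raise InvalidParameterError(f"planted self-edge ({i}, {j})")
                if not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                    raise InvalidParameterError(
                        f"planted edge ({i}, {j}) references a missing ROI "
                        f"(n_rois={self.n_rois})"
                    )
                key = frozenset((i, j))
                if key in seen:
                    raise InvalidParameterError(f"duplicate planted edge ({i}, {j})")
                seen.add(key)

    def resolved_sigma(self) -> np.ndarray:
        if self.roi_sigma_base is None:
            return np.geomspace(0.08, 0.144, self.n_rois)
        sig = np.broadcast_to(
            np.asarray(self.roi_sigma_base, dtype=float), (self.n_rois,)
        ).copy()
        if np.any(sig <= 0):
            raise InvalidParameterError("roi_sigma_base must be positive")
        return sig

    def resolved_mean(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.roi_mean_base, dtype=float), (self.n_rois,)
        ).copy()


@dataclass
class GroundTruth:
    """Closed-form quantities behind a generated cohort."""

    true_mc: pd.DataFrame  # participants x ROI-pair closed-form symmetric KL
    planted_edges: list[tuple[int, int]]
    planted_weights: np.ndarray
    cold_planted_edges: list[tuple[int, int]]
    cold_planted_weights: np.ndarray
    planted_pair_names: list[str]
    linear_predictor_laser: np.ndarray
    linear_predictor_cold: np.ndarray
    true_noise_laser: np.ndarray
    true_noise_cold: np.ndarray
    noise_sd: tuple[float, float]
    mu: np.ndarray  # participants x ROIs true means
    sigma: np.ndarray  # participants x ROIs true SDs

    def to_json_dict(self) -> dict:
        return {
            "planted_edges": [list(e) for e in self.planted_edges],
            "planted_weights": self.planted_weights.tolist(),
            "cold_planted_edges": [list(e) for e in self.cold_planted_edges],
            "cold_planted_weights": self.cold_planted_weights.tolist(),
            "planted_pair_names": self.planted_pair_names,
            "noise_sd": list(self.noise_sd),
            "true_noise_laser": self.true_noise_laser.tolist(),
            "true_noise_cold": self.true_noise_cold.tolist(),
        }


def _edge_columns(edges, pairs_index):
    cols = []
    for i, j in edges:
        key = (max(i, j), min(i, j))
        cols.append(pairs_index[key])
    return cols


def _standardize(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (M - M.mean(axis=0)) / sd


def generate_cohort(
    spec: CohortSpec, parc: Parcellation | None = None
) -> tuple[ROISampleSet, pd.DataFrame, GroundTruth]:
    """Draw a cohort: voxel samples, phenotype table, and ground truth.

    Identical specs (including seed) produce bit-identical output. See the
    module docstring for the generative model.
    """
    if parc is None:
        parc = toy_parcellation(spec.n_rois)
    if parc.n_rois != spec.n_rois:
        raise InvalidParameterError("parcellation size differs from spec.n_rois")
    ss = np.random.SeedSequence(spec.seed)
    rng_offsets, rng_voxels, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    n, r = spec.n_participants, spec.n_rois
    base_mu = spec.resolved_mean()
    base_sigma = spec.resolved_sigma()

    if spec.offset_cov is not None:
        cov = np.asarray(spec.offset_cov, dtype=float)
        offsets = rng_offsets.multivariate_normal(np.zeros(r), cov, size=n)
    else:
        offsets = rng_offsets.normal(0.0, spec.subject_sd, size=(n, r))
    mu = base_mu[None, :] + offsets
    log_sigma_offsets = rng_offsets.normal(0.0, 1.0, size=(n, r)) * spec.subject_sigma_sd
    sigma = base_sigma[None, :] * np.exp(log_sigma_offsets)

    # closed-form true MC for every lower-triangle pair
    pairs = lower_triangle_pairs(r)
    rows = np.array([i for i, _ in pairs])
    cols = np.array([j for _, j in pairs])
    true_mc_values = gaussian_symmetric_kl(
        mu[:, rows], sigma[:, rows], mu[:, cols], sigma[:, cols]
    )
    participant_ids = [f"sub-{k + 1:03d}" for k in range(n)]
    true_mc = pd.DataFrame(
        true_mc_values, index=participant_ids, columns=pair_names(parc.names)
    )
    true_mc.index.name = "participant_id"

    pairs_index = {(i, j): k for k, (i, j) in enumerate(pairs)}
    z = _standardize(true_mc_values)

    def predictor(edges, weights):
        if edges is None:
            return np.zeros(n), [], np.zeros(0)
        if weights is None:
            w = np.array(
                [(1.0 + 0.1 * k) * (1 if k % 2 == 0 else -1) for k in range(len(edges))]
            )
        else:
            w = np.asarray(weights, dtype=float).ravel()
        if w.size != len(edges):
            raise InvalidParameterError("planted_weights length mismatch")
        colsel = _edge_columns(edges, pairs_index)
        return z[:, colsel] @ w, list(edges), w

    lp_laser, laser_edges, laser_w = predictor(spec.planted_edges, spec.planted_weights)
    if spec.cold_planted_edges is None and spec.cold_planted_weights is None:
        lp_cold, cold_edges, cold_w = lp_laser, laser_edges, laser_w
    else:
        edges = (
            spec.cold_planted_edges
            if spec.cold_planted_edges is not None
            else spec.planted_edges
        )
        lp_cold, cold_edges, cold_w = predictor(edges, spec.cold_planted_weights)

    noise = np.broadcast_to(
        np.atleast_1d(np.asarray(spec.noise_sd, dtype=float)), (2,)
    ).astype(float)
    if spec.target_r2 is not None:
        fac = np.sqrt((1.0 - spec.target_r2) / spec.target_r2)
        noise = np.array(
            [
                lp_laser.std() * fac if lp_laser.std() > 0 else 1.0,
                lp_cold.std() * fac if lp_cold.std() > 0 else 1.0,
            ]
        )
    eps_laser = rng_noise.normal(0.0, 1.0, n) * noise[0]
    eps_cold = rng_noise.normal(0.0, 1.0, n) * noise[1]

    raw_laser = lp_laser + eps_laser
    raw_cold = lp_cold + eps_cold
    if raw_laser.max() == raw_laser.min():
        raise InvalidParameterError(
            "degenerate laser thresholds: plant an edge or use noise_sd > 0"
        )
    lo, hi = spec.laser_range
    laser = lo + (raw_laser - raw_laser.min()) / (raw_laser.max() - raw_laser.min()) * (
        hi - lo
    )
    if raw_cold.std() == 0:
        raise InvalidParameterError("degenerate cold thresholds")
    cold_mean, cold_sd = spec.cold_mean_sd
    cold = (raw_cold - raw_cold.mean()) / raw_cold.std() * cold_sd + cold_mean

    phenotypes = pd.DataFrame(
        {
            "participant_id": participant_ids,
            "laser_threshold_J": laser,
            "cold_threshold_s": cold,
        }
    )

    # voxel draws
    if isinstance(spec.n_voxels, tuple):
        lo_v, hi_v = spec.n_voxels
        n_vox = rng_voxels.integers(lo_v, hi_v + 1, size=r)
    else:
        n_vox = np.full(r, int(spec.n_voxels))
    data: dict[str, dict[int, np.ndarray]] = {}
    roi_ids = tuple(parc.roi_ids)
    for a, pid in enumerate(participant_ids):
        cell = {}
        for b, rid in enumerate(roi_ids):
            cell[rid] = rng_voxels.normal(mu[a, b], sigma[a, b], size=int(n_vox[b]))
        data[pid] = cell
    sample_set = ROISampleSet(data=data, roi_ids=roi_ids)

    truth = GroundTruth(
        true_mc=true_mc,
        planted_edges=laser_edges,
        planted_weights=laser_w,
        cold_planted_edges=cold_edges,
        cold_planted_weights=cold_w,
        planted_pair_names=[
            true_mc.columns[pairs_index[(max(i, j), min(i, j))]]
            for i, j in laser_edges
        ],
        linear_predictor_laser=lp_laser,
        linear_predictor_cold=lp_cold,
        true_noise_laser=eps_laser,
        true_noise_cold=eps_cold,
        noise_sd=(float(noise[0]), float(noise[1])),
        mu=mu,
        sigma=sigma,
    )
    return sample_set, phenotypes, truth
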