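"""Synthetic cohorts with known ground truth.

Generates a template grid with an ellipsoidal brain mask and a small
disjoint reference region, smooth orthonormal spatial factor maps,
patient images whose factor loadings carry planted cluster structure,
matched control images, and clinical variables generated linearly from
the loadings with known standardized coefficients.  Every generator is
a pure function of its seed and parameters, so any pipeline stage can
be tested against the construction.

The cluster signal lives in loading (score) space, not in individual
voxels; factor amplitudes follow a descending schedule so variance
fractions are distinguishable and component retention is well-posed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from eigenbrains.image_io import BrainMask, MaskedVolume, unflatten_row, write_volume

__all__ = [
    "GroundTruth",
    "SyntheticCohort",
    "make_template",
    "make_factors",
    "simulate_patients",
    "simulate_controls",
    "simulate_clinical",
    "default_loading_model",
    "make_cohort",
    "write_cohort",
]

DEFAULT_SHAPE = (30, 36, 30)
DEFAULT_CLUSTER_SIZES = (21, 19, 7, 5)  # 52 patients
DEFAULT_N_CONTROLS = 52
DEFAULT_K_TRUE = 6


@dataclass
class GroundTruth:
    factor_maps: np.ndarray  # K_true x n_voxels, orthonormal rows
    cluster_labels: np.ndarray  # per patient
    cluster_centroids: np.ndarray  # clusters x K_true, in loading units
    clinical_betas: dict[str, np.ndarray]
    loadings: np.ndarray  # patients x K_true, the planted scores
    noise_sd: float
    seed: int


@dataclass
class SyntheticCohort:
    patient_volumes: list[MaskedVolume]
    control_volumes: list[MaskedVolume]
    clinical: pd.DataFrame
    truth: GroundTruth
    mask: BrainMask
    reference_mask: BrainMask
    template_shape: tuple[int, int, int] = DEFAULT_SHAPE
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def make_template(shape: tuple[int, int, int] = DEFAULT_SHAPE,
                  brain_radius_fraction: float = 0.82,
                  reference_region_spec: dict | None = None) -> tuple[BrainMask, BrainMask]:
    """Ellipsoidal brain mask plus a small disjoint reference region inside it.

    ``reference_region_spec`` keys: ``center_fraction`` (triple of grid
    fractions) and ``radius`` (voxels).  The reference region must sit
    strictly inside the brain mask (not touching its boundary).
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 16 for s in shape):
        raise ValueError("each dimension must be >= 16")
    spec = {"center_fraction": (0.5, 0.42, 0.3),
            "radius": min(2.5, 0.09 * min(shape))}
    if reference_region_spec:
        spec.update(reference_region_spec)

    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    center = [(s - 1) / 2.0 for s in shape]
    semi = [brain_radius_fraction * s / 2.0 for s in shape]
    dist2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    brain = BrainMask(indicator=dist2 <= 1.0)

    ref_center = [f * (s - 1) for f, s in zip(spec["center_fraction"], shape)]
    ref_dist2 = sum((g - c) ** 2 for g, c in zip(grids, ref_center))
    ref_ind = ref_dist2 <= spec["radius"] ** 2
    if not ref_ind.any():
        raise ValueError("reference region is empty")
    interior = ndimage.binary_erosion(brain.indicator)
    if not ref_ind[interior].sum() == ref_ind.sum():
        raise ValueError("reference region overlaps the brain-mask boundary")
    return brain, BrainMask(indicator=ref_ind)


def make_factors(mask: BrainMask, k_true: int = DEFAULT_K_TRUE,
                 smoothness_sigma: float = 2.0, seed: int = 0) -> np.ndarray:
    """Smooth Gaussian random fields, Gram-Schmidt orthonormalized within the mask.

    Returns a ``k_true x n_voxels`` matrix with orthonormal rows;
    ``smoothness_sigma=0`` yields white-noise factors.
    """
    if k_true >= mask.n_voxels:
        raise ValueError("k_true must be below the masked voxel count")
    rng = np.random.default_rng(seed)
    factors = np.empty((k_true, mask.n_voxels))
    for k in range(k_true):
        field_3d = rng.standard_normal(mask.shape)
        if smoothness_sigma > 0:
            field_3d = ndimage.gaussian_filter(field_3d, sigma=smoothness_sigma)
        vec = field_3d[mask.indicator]
        vec = vec - vec.mean()  # zero spatial mean: row medians stay loading-free
        # Gram-Schmidt against previous factors
        for j in range(k):
            vec = vec - (vec @ factors[j]) * factors[j]
        norm = np.linalg.norm(vec)
        if norm < 1e-12:
            raise ValueError(f"factor {k} is numerically rank-deficient")
        factors[k] = vec / norm
    return factors


def default_loading_model(n_per_cluster=DEFAULT_CLUSTER_SIZES, k_true: int = DEFAULT_K_TRUE,
                          amplitude: float = 1.0,
                          loading_sd: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Cluster centroids plus per-component residual SDs, in loading units.

    With *c* clusters at most ``c - 1`` components can carry
    between-cluster signal; those centroid columns are made orthogonal
    under the cluster-size weights (so the planted loading covariance is
    diagonal and the decomposition can recover each factor separately)
    with a descending between-cluster SD schedule.  The remaining
    components carry no cluster signal and get descending residual SDs,
    so every component variance is distinct and retention is well-posed.

    Returns ``(centroids, loading_sds)`` with shapes (c, k_true) and (k_true,).
    """
    sizes = np.asarray(list(n_per_cluster), dtype=float)
    c = sizes.size
    w = sizes / sizes.sum()
    n_struct = min(c - 1, k_true)

    # sign patterns, weighted-centered and weighted-orthogonalized
    rng = np.random.default_rng(20240605)
    patterns = np.array([[1, -1, 1, -1], [1, 1, -1, -1], [1, -1, -1, 1]], dtype=float)
    if c != 4 or n_struct > 3:
        patterns = rng.choice([-1.0, 1.0], size=(max(n_struct, 1), c))
    basis = []
    for j in range(n_struct):
        v = patterns[j % patterns.shape[0], :c].astype(float)
        v = v - np.sum(w * v)
        for u in basis:
            v = v - np.sum(w * v * u) * u
        var = np.sum(w * v**2)
        if var < 1e-12:  # degenerate pattern; replace with a random one
            v = rng.standard_normal(c)
            v = v - np.sum(w * v)
            for u in basis:
                v = v - np.sum(w * v * u) * u
            var = np.sum(w * v**2)
        basis.append(v / np.sqrt(var))

    between_sd = amplitude * 2.0 * 0.8 ** np.arange(n_struct)
    centroids = np.zeros((c, k_true))
    for j in range(n_struct):
        centroids[:, j] = basis[j] * between_sd[j]

    loading_sds = np.full(k_true, loading_sd * amplitude)
    n_free = k_true - n_struct
    if n_free > 0:
        loading_sds[n_struct:] = amplitude * 0.8 ** np.arange(n_free)
    return centroids, loading_sds


def simulate_patients(factors: np.ndarray, centroids: np.ndarray,
                      n_per_cluster=DEFAULT_CLUSTER_SIZES,
                      loading_sd: float | np.ndarray = 0.25,
                      noise_sd: float = 0.1, seed: int = 0, *, mask: BrainMask,
                      baseline: float = 50.0, affine: np.ndarray | None = None,
                      orthogonalize_loadings: bool = True,
                      ) -> tuple[list[MaskedVolume], np.ndarray, np.ndarray]:
    """Patient images as baseline + loading-weighted factors + voxel noise.

    Loadings and noise are expressed on the per-voxel scale of the factor
    maps: a centroid entry *c* contributes ``c * sqrt(n_voxels)`` in raw
    loading units, so a unit-norm factor with centroid 1 has per-voxel
    amplitude ~1 and ``noise_sd`` is directly comparable to it.

    Returns ``(volumes, cluster_labels, loadings)`` with loadings in the
    same per-voxel units as the centroids.
    """
    factors = np.atleast_2d(np.asarray(factors, dtype=float))
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if centroids.shape[1] != factors.shape[0]:
        raise ValueError("centroid dimension must equal the number of factors")
    n_per_cluster = [int(n) for n in n_per_cluster]
    if any(n <= 0 for n in n_per_cluster):
        raise ValueError("cluster sizes must be positive")
    if len(n_per_cluster) != centroids.shape[0]:
        raise ValueError("one size per centroid required")

    rng = np.random.default_rng(seed)
    p = factors.shape[1]
    k = factors.shape[0]
    labels = np.repeat(np.arange(len(n_per_cluster)), n_per_cluster)
    n = labels.size
    loading_sd = np.broadcast_to(np.asarray(loading_sd, dtype=float), (k,))
    residuals = rng.standard_normal((n, k))
    if orthogonalize_loadings and n > len(n_per_cluster) + k:
        # make the planted loading covariance exactly diagonal: project the
        # residuals out of the cluster-indicator space (no accidental mean
        # shifts) and orthogonalize them across components, with exact SDs
        indicators = (labels[:, None] == np.arange(len(n_per_cluster))[None, :]).astype(float)
        residuals -= indicators @ np.linalg.lstsq(indicators, residuals, rcond=None)[0]
        q, _ = np.linalg.qr(residuals)
        residuals = q * np.sqrt(n - 1)
    loadings = centroids[labels] + residuals * loading_sd
    if orthogonalize_loadings and n > len(n_per_cluster) + k:
        # robust per-row scaling downstream divides each subject by a value
        # proportional to its loading magnitude; make the loading second
        # moment diagonal under those implicit weights so the planted
        # factors stay identifiable after that preprocessing
        for _ in range(8):
            signal = (loadings * np.sqrt(p)) @ factors
            iqr = np.diff(np.percentile(signal, [25.0, 75.0], axis=1), axis=0).ravel()
            weights = 1.0 / (iqr**2 + noise_sd**2)
            weights = weights / weights.mean()
            moment = (loadings * weights[:, None]).T @ loadings / n
            evals, evecs = np.linalg.eigh(moment)
            inv_sqrt = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
            loadings = loadings @ inv_sqrt @ np.diag(np.sqrt(np.diag(moment)))
    rows = baseline + (loadings * np.sqrt(p)) @ factors
    rows = rows + rng.standard_normal((n, p)) * noise_sd
    if np.any(rows <= 0):
        raise ValueError("baseline too low: non-positive intensities generated")

    affine = np.eye(4) if affine is None else affine
    volumes = [
        MaskedVolume(data=unflatten_row(rows[i], mask, fill=0.0), affine=affine,
                     subject_id=f"patient_{i:03d}")
        for i in range(n)
    ]
    return volumes, labels, loadings


def simulate_controls(mask: BrainMask, n: int = DEFAULT_N_CONTROLS, noise_sd: float = 0.1,
                      seed: int = 0, baseline: float = 50.0,
                      affine: np.ndarray | None = None) -> list[MaskedVolume]:
    """Control images: baseline plus voxel noise, zero loading on every factor."""
    if n < 2:
        raise ValueError("need at least 2 controls")
    rng = np.random.default_rng(seed)
    affine = np.eye(4) if affine is None else affine
    volumes = []
    for i in range(n):
        row = baseline + rng.standard_normal(mask.n_voxels) * noise_sd
        volumes.append(MaskedVolume(data=unflatten_row(row, mask, fill=0.0), affine=affine,
                                    subject_id=f"control_{i:03d}"))
    return volumes


def simulate_clinical(loadings: np.ndarray, clinical_betas: dict[str, np.ndarray],
                      residual_sd: float = 0.5, missing_rate: float = 0.0,
                      seed: int = 0, subject_ids: list[str] | None = None) -> pd.DataFrame:
    """Clinical outcomes as standardized loadings times planted betas plus noise.

    Each outcome is ``z(loadings) @ betas + N(0, residual_sd^2)``; cells
    are then masked missing independently at ``missing_rate``.
    """
    if residual_sd < 0:
        raise ValueError("residual_sd must be nonnegative")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    n, k = loadings.shape
    z = (loadings - loadings.mean(axis=0)) / loadings.std(axis=0, ddof=1)
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    for name, betas in clinical_betas.items():
        betas = np.asarray(betas, dtype=float)
        if betas.size != k:
            raise ValueError(f"betas for {name!r} must have length {k}")
        y = z @ betas + rng.standard_normal(n) * residual_sd
        if missing_rate > 0:
            y = np.where(rng.random(n) < missing_rate, np.nan, y)
        data[name] = y
    ids = subject_ids if subject_ids is not None else [f"patient_{i:03d}" for i in range(n)]
    return pd.DataFrame({"subject_id": ids, **data})


def make_cohort(shape: tuple[int, int, int] = DEFAULT_SHAPE, k_true: int = DEFAULT_K_TRUE,
                n_per_cluster=DEFAULT_CLUSTER_SIZES, n_controls: int = DEFAULT_N_CONTROLS,
                smoothness_sigma: float = 2.0, loading_sd: float = 0.25,
                noise_sd: float = 0.1, amplitude: float = 1.0,
                clinical_betas: dict[str, np.ndarray] | None = None,
                residual_sd: float = 0.5, missing_rate: float = 0.1,
                seed: int = 0) -> SyntheticCohort:
    """Generate a complete cohort (images, masks, clinical table, ground truth)."""
    mask, reference = make_template(shape)
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=4)
    factors = make_factors(mask, k_true=k_true, smoothness_sigma=smoothness_sigma,
                           seed=int(sub_seeds[0]))
    centroids, loading_sds = default_loading_model(
        n_per_cluster=n_per_cluster, k_true=k_true, amplitude=amplitude,
        loading_sd=loading_sd)
    patients, labels, loadings = simulate_patients(
        factors, centroids, n_per_cluster=n_per_cluster, loading_sd=loading_sds,
        noise_sd=noise_sd, seed=int(sub_seeds[1]), mask=mask)
    controls = simulate_controls(mask, n=n_controls, noise_sd=noise_sd,
                                 seed=int(sub_seeds[2]))
    if clinical_betas is None:
        clinical_betas = {
            "age_at_onset": np.array([0.5, -0.3, 0.0, 0.0, 0.0, 0.0])[:k_true],
            "stms_total": np.array([0.0, 0.4, -0.4, 0.2, 0.0, 0.0])[:k_true],
            "executive_composite": np.array([-0.4, 0.0, 0.3, 0.0, 0.3, 0.0])[:k_true],
        }
    clinical = simulate_clinical(loadings, clinical_betas, residual_sd=residual_sd,
                                 missing_rate=missing_rate, seed=int(sub_seeds[3]),
                                 subject_ids=[v.subject_id for v in patients])
    truth = GroundTruth(factor_maps=factors, cluster_labels=labels,
                        cluster_centroids=centroids, clinical_betas=clinical_betas,
                        loadings=loadings, noise_sd=noise_sd, seed=seed)
    return SyntheticCohort(patient_volumes=patients, control_volumes=controls,
                           clinical=clinical, truth=truth, mask=mask,
                           reference_mask=reference, template_shape=tuple(shape))


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, object]:
    """Write the cohort to disk: NIfTI volumes, masks, clinical CSV, truth JSON."""
    out = Path(out_dir)
    (out / "patients").mkdir(parents=True, exist_ok=True)
    (out / "controls").mkdir(parents=True, exist_ok=True)
    affine = cohort.affine
    for vol in cohort.patient_volumes:
        write_volume(vol, out / "patients" / f"{vol.subject_id}.nii")
    for vol in cohort.control_volumes:
        write_volume(vol, out / "controls" / f"{vol.subject_id}.nii")
    write_volume(MaskedVolume(cohort.mask.indicator.astype(float), affine, "brain_mask"),
                 out / "brain_mask.nii")
    write_volume(MaskedVolume(cohort.reference_mask.indicator.astype(float), affine,
                              "reference_mask"),
                 out / "reference_mask.nii")
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    truth = cohort.truth
    truth_json = {
        "cluster_labels": truth.cluster_labels.tolist(),
        "cluster_centroids": truth.cluster_centroids.tolist(),
        "clinical_betas": {k: v.tolist() for k, v in truth.clinical_betas.items()},
        "loadings": truth.loadings.tolist(),
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=2))
    manifest = {
        "n_patients": len(cohort.patient_volumes),
        "n_controls": len(cohort.control_volumes),
        "shape": list(cohort.template_shape),
        "n_masked_voxels": cohort.mask.n_voxels,
        "seed": truth.seed,
    }
    (out / "cohort.json").write_text(json.dumps(manifest, indent=2))
    return manifest
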