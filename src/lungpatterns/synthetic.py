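"""Synthetic dual-channel CT cohorts with planted texture classes and latent factors.

Each subject is a pair of registered inspiration (TLC-like) / expiration
(RV-like) HU volumes plus a displacement field, a lung mask, a ground-truth
texture-class map, latent factor scores, and continuous / binary outcomes
driven by those scores.  Texture classes are piecewise-constant-statistics
Gaussian random fields arranged in Voronoi blobs inside an ellipsoidal lung
mask; class mixing proportions per subject are the softmax of
``loading_matrix @ factor_scores``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, softmax


@dataclass(frozen=True)
class TextureClassSpec:
    """Statistical description of one planted tissue texture class.

    ``mean_hu``/``sd_hu`` set the TLC intensity field, smoothed at scale
    ``correlation_length_vox``; ``jacobian_mean``/``jacobian_sd`` set the local
    expiratory volume-change field; ``rv_offset_hu`` is added to the TLC
    intensity to produce the registered RV intensity (small offsets emulate
    air trapping, large positive offsets emulate normally deflating tissue).
    """

    class_id: int
    mean_hu: float
    sd_hu: float
    correlation_length_vox: float
    jacobian_mean: float
    jacobian_sd: float
    rv_offset_hu: float

    def __post_init__(self):
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be >= 0")
        if self.jacobian_mean <= 0:
            raise ValueError("jacobian_mean must be > 0")
        if self.jacobian_sd < 0:
            raise ValueError("jacobian_sd must be >= 0")
        if self.correlation_length_vox < 0:
            raise ValueError("correlation_length_vox must be >= 0")


def default_class_specs() -> list[TextureClassSpec]:
    """Four classes emulating emphysematous, air-trapping, normal and dense tissue."""
    return [
        TextureClassSpec(0, mean_hu=-960.0, sd_hu=15.0, correlation_length_vox=2.0,
                         jacobian_mean=0.95, jacobian_sd=0.04, rv_offset_hu=30.0),
        TextureClassSpec(1, mean_hu=-880.0, sd_hu=20.0, correlation_length_vox=2.0,
                         jacobian_mean=0.85, jacobian_sd=0.04, rv_offset_hu=10.0),
        TextureClassSpec(2, mean_hu=-820.0, sd_hu=35.0, correlation_length_vox=1.5,
                         jacobian_mean=0.55, jacobian_sd=0.05, rv_offset_hu=120.0),
        TextureClassSpec(3, mean_hu=-650.0, sd_hu=50.0, correlation_length_vox=1.0,
                         jacobian_mean=0.75, jacobian_sd=0.05, rv_offset_hu=80.0),
    ]


def default_loading_matrix() -> np.ndarray:
    """Factor 0 trades class 0 against class 1; factor 1 trades class 2 against 3."""
    return np.array([[1.5, 0.0], [-1.5, 0.0], [0.0, 1.5], [0.0, -1.5]])


@dataclass
class CohortConfig:
    n_subjects: int = 60
    volume_shape_vox: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (0.625, 0.625, 0.625)
    n_latent_factors: int = 2
    class_specs: list[TextureClassSpec] = field(default_factory=default_class_specs)
    loading_matrix: np.ndarray = field(default_factory=default_loading_matrix)
    outcome_beta: np.ndarray = field(default_factory=lambda: np.array([1.0, -0.7]))
    outcome_noise_sd: float | None = None  # default: 0.3 * ||outcome_beta||
    # Blob count controls how closely each subject's realized class fractions
    # track the softmax mixing proportions (relative sampling error ~
    # 1/sqrt(n_blobs)); 32 keeps the latent factors measurable from tissue
    # composition while regions stay several voxels across.
    n_blobs_per_subject: int = 32
    seed: int = 0

    def __post_init__(self):
        self.loading_matrix = np.asarray(self.loading_matrix, float)
        self.outcome_beta = np.asarray(self.outcome_beta, float)
        if self.outcome_noise_sd is None:
            self.outcome_noise_sd = 0.3 * float(np.linalg.norm(self.outcome_beta))

    def validate(self):
        c = len(self.class_specs)
        ids = [s.class_id for s in self.class_specs]
        if len(set(ids)) != c:
            raise ValueError("class_ids must be unique")
        if self.n_latent_factors > c - 1:
            raise ValueError("n_latent_factors must be <= number of classes - 1")
        if self.loading_matrix.shape != (c, self.n_latent_factors):
            raise ValueError("loading_matrix must have one row per class and one column per factor")
        if self.outcome_beta.shape != (self.n_latent_factors,):
            raise ValueError("outcome_beta must have one weight per factor")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        if self.n_subjects < 1 or self.n_blobs_per_subject < 1:
            raise ValueError("counts must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["loading_matrix"] = self.loading_matrix.tolist()
        d["outcome_beta"] = self.outcome_beta.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "class_specs" in d:
            d["class_specs"] = [TextureClassSpec(**s) if isinstance(s, dict) else s
                                for s in d["class_specs"]]
        for key in ("volume_shape_vox", "spacing_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticSubject:
    subject_id: str
    tlc_hu: np.ndarray
    rv_hu: np.ndarray
    displacement_mm: np.ndarray  # (D,H,W,3), mm
    lung_mask: np.ndarray        # uint8
    class_map: np.ndarray        # int16, -1 outside the lung
    true_factor_scores: np.ndarray
    outcome_continuous: float
    outcome_binary: int
    spacing_mm: tuple[float, float, float]


def _smooth_unit_noise(rng: np.random.Generator, shape, corr_len: float) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian field with smoothing scale corr_len."""
    w = rng.standard_normal(shape)
    if corr_len > 0:
        w = gaussian_filter(w, sigma=corr_len, mode="reflect")
        s = w.std()
        if s > 0:
            w = w / s
    return w


def _ellipsoid_mask(shape) -> np.ndarray:
    center = [(n - 1) / 2.0 for n in shape]
    radii = [max(n / 2.0 - 1.0, 1.0) for n in shape]
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return (r2 <= 1.0).astype(np.uint8)


def _generate_subject(config: CohortConfig, index: int,
                      rng: np.random.Generator) -> SyntheticSubject:
    shape = tuple(config.volume_shape_vox)
    specs = config.class_specs
    n_class = len(specs)

    f = rng.standard_normal(config.n_latent_factors)
    proportions = softmax(config.loading_matrix @ f)

    mask = _ellipsoid_mask(shape)

    # Voronoi blobs: seed points get class labels with the subject's proportions.
    seeds = rng.uniform(0, 1, size=(config.n_blobs_per_subject, 3)) * np.array(shape)
    seed_class = rng.choice(n_class, size=config.n_blobs_per_subject, p=proportions)
    grids = np.indices(shape).reshape(3, -1).T  # (n_vox, 3)
    d2 = ((grids[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1).reshape(shape)
    class_map = seed_class[nearest].astype(np.int16)
    class_map[mask == 0] = -1

    tlc = np.full(shape, -1000.0, np.float32)
    jac = np.ones(shape, np.float32)
    for ci, spec in enumerate(specs):
        sel = class_map == ci
        if not sel.any():
            # Keep the per-subject random stream aligned across subjects.
            if spec.sd_hu > 0:
                rng.standard_normal(shape)
            if spec.jacobian_sd > 0:
                rng.standard_normal(shape)
            continue
        if spec.sd_hu > 0:
            fld = spec.mean_hu + spec.sd_hu * _smooth_unit_noise(rng, shape, spec.correlation_length_vox)
        else:
            fld = np.full(shape, spec.mean_hu)
        tlc[sel] = fld[sel]
        if spec.jacobian_sd > 0:
            jfld = spec.jacobian_mean + spec.jacobian_sd * _smooth_unit_noise(
                rng, shape, spec.correlation_length_vox)
        else:
            jfld = np.full(shape, spec.jacobian_mean)
        jac[sel] = np.clip(jfld, 0.05, None)[sel]

    offsets = np.zeros(n_class + 1, np.float32)
    offsets[:n_class] = [s.rv_offset_hu for s in specs]
    rv = tlc + offsets[class_map]  # class -1 picks the trailing 0 offset

    # Displacement whose Jacobian determinant reproduces the class Jacobian
    # field: with u = (u_z, 0, 0) and triangular grad, det(I + grad u) = 1 + du_z/dz.
    hz = config.spacing_mm[0]
    incr = (jac - 1.0) * hz
    uz = np.concatenate([np.zeros((1,) + shape[1:], np.float32),
                         np.cumsum(incr, axis=0, dtype=np.float32)[:-1]], axis=0)
    disp = np.zeros(shape + (3,), np.float32)
    disp[..., 0] = uz

    lin = float(config.outcome_beta @ f)
    y = lin + rng.normal(0.0, config.outcome_noise_sd)
    yb = int(rng.random() < expit(lin))

    return SyntheticSubject(
        subject_id=f"S{index:04d}",
        tlc_hu=tlc,
        rv_hu=rv.astype(np.float32),
        displacement_mm=disp,
        lung_mask=mask,
        class_map=class_map,
        true_factor_scores=f,
        outcome_continuous=float(y),
        outcome_binary=yb,
        spacing_mm=tuple(config.spacing_mm),
    )


def generate_cohort(config: CohortConfig, min_volume_vox: int = 32) -> list[SyntheticSubject]:
    """Generate the cohort; identical config (incl. seed) is bitwise reproducible.

    Each subject draws from an independent child seed of ``config.seed``, so a
    subject's volumes do not depend on how many other subjects are generated.
    """
    config.validate()
    if any(n < min_volume_vox for n in config.volume_shape_vox):
        raise ValueError(
            f"volume_shape_vox {config.volume_shape_vox} has an axis smaller than "
            f"the ROI size {min_volume_vox}; volumes must admit at least one ROI")
    children = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    return [_generate_subject(config, i, np.random.default_rng(children[i]))
            for i in range(config.n_subjects)]


def generate_displacement(shape_vox, kind: str, parameter: float = 0.0,
                          seed: int = 0, spacing_mm: float = 1.0) -> np.ndarray:
    """Analytic or band-limited random displacement fields (mm), shape (D,H,W,3).

    ``identity`` -> zero field; ``uniform_scale`` with scale s -> u(x) = (s-1) x
    at voxel-centre physical positions; ``smooth_random`` -> Gaussian-smoothed
    (sigma 4 voxels) white noise normalised to peak amplitude ``parameter``.
    """
    shape = tuple(int(n) for n in shape_vox)
    if any(n < 1 for n in shape):
        raise ValueError("shape_vox must be positive")
    if kind == "identity":
        return np.zeros(shape + (3,), np.float32)
    if kind == "uniform_scale":
        coords = np.stack(np.meshgrid(*[np.arange(n) * spacing_mm for n in shape],
                                      indexing="ij"), axis=-1)
        return ((parameter - 1.0) * coords).astype(np.float32)
    if kind == "smooth_random":
        rng = np.random.default_rng(seed)
        comps = []
        for _ in range(3):
            w = gaussian_filter(rng.standard_normal(shape), sigma=4.0, mode="reflect")
            peak = np.abs(w).max()
            comps.append(w / peak * parameter if peak > 0 else w)
        return np.stack(comps, axis=-1).astype(np.float32)
    raise ValueError(f"unknown displacement kind: {kind!r}")


# ---------------------------------------------------------------------------
# NIfTI / CSV serialization


def save_nifti(path, data: np.ndarray, spacing_mm) -> None:
    affine = np.diag(list(spacing_mm[:3]) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(spacing_mm[:3]) + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))


def load_nifti(path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def cohort_frame(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id,
               "outcome_continuous": s.outcome_continuous,
               "outcome_binary": s.outcome_binary}
        for k, v in enumerate(s.true_factor_scores):
            row[f"true_factor_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(subjects: list[SyntheticSubject], config: CohortConfig, outdir) -> None:
    """Write per-subject NIfTI volumes, a cohort CSV, and the config as JSON."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        save_nifti(out / f"{s.subject_id}_tlc.nii", s.tlc_hu, s.spacing_mm)
        save_nifti(out / f"{s.subject_id}_rv.nii", s.rv_hu, s.spacing_mm)
        save_nifti(out / f"{s.subject_id}_mask.nii", s.lung_mask, s.spacing_mm)
        save_nifti(out / f"{s.subject_id}_classmap.nii", s.class_map, s.spacing_mm)
        save_nifti(out / f"{s.subject_id}_disp.nii", s.displacement_mm, s.spacing_mm)
    cohort_frame(subjects).to_csv(out / "cohort.csv", index=False)
    (out / "cohort_config.json").write_text(json.dumps(config.to_dict(), indent=2))
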