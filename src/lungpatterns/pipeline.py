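"""End-to-end orchestration: preprocess, train over an embedding-count grid,
histogram, factor-analyse, regress, and evaluate on held-out subjects.

Model selection sweeps the number of embeddings E (= number of
pattern-clusters), trains one CAE-FC per E on training-split ROIs, runs
parallel analysis and factor extraction on the training histograms, regresses
each target on the factor scores, and picks the E with the lowest AIC on the
primary target (ties toward smaller E).  Factor models and regressions are fit
on the training split only; held-out subjects are scored with the trained
artifacts, never refit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cae_fc, efa, stats
from .histogram import PatternHistogram, build_histogram, cohort_matrix
from .preprocessing import (DualChannelVolume, RescaleCalibration, extract_random_rois,
                            jacobian_determinant, prm_classify, rescale_intensity,
                            sliding_window_rois)
from .synthetic import CohortConfig, SyntheticSubject, generate_cohort


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    e_grid: tuple[int, ...] = (8,)
    test_fraction: float = 1.0 / 3.0
    split_seed: int = 0
    rois_per_subject: int = 8
    roi_size_vox: int = 32
    window_overlap_vox: int = 16
    min_lung_fraction: float = 0.5
    encoder_channels: tuple[int, ...] = (16, 32, 64)
    gate_keep_k: int = 1
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 5
    pa_n_reps: int = 100
    pa_percentile: float = 95.0
    loading_threshold: float = 0.5
    targets: tuple[str, ...] = ("outcome_continuous",)
    air_hu: float = -1000.0
    tissue_hu: float = 55.0
    cache_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        self.e_grid = tuple(self.e_grid)
        self.encoder_channels = tuple(self.encoder_channels)
        self.targets = tuple(self.targets)
        if not self.e_grid or list(self.e_grid) != sorted(self.e_grid):
            raise ValueError("e_grid must be nonempty and sorted")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")

    @property
    def calibration(self) -> RescaleCalibration:
        return RescaleCalibration(air_hu=self.air_hu, tissue_hu=self.tissue_hu)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d.pop("cache_dir")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        for key in ("e_grid", "encoder_channels", "targets"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SweepReport:
    records: list[dict]
    selected_e: int
    primary_target: str

    def frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {"E": rec["E"], "retained_factors": rec["retained_factors"],
                   "n_factors": rec["n_factors"]}
            for t, v in rec["aic"].items():
                row[f"aic_{t}"] = v
            for t, v in rec["train_r2"].items():
                row[f"train_r2_{t}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class PipelineArtifacts:
    model: cae_fc.CAEFCModel
    factor_model: efa.FactorModel
    fits: dict[str, stats.OLSFit]
    retained_factors: int
    train_matrix: np.ndarray
    train_ids: list[str]
    train_scores: np.ndarray


@dataclass
class EvaluationBundle:
    test_r2: dict[str, float]
    test_scores: np.ndarray
    test_ids: list[str]
    anova: dict[int, stats.AnovaResult | None]
    posthoc: dict[int, list]
    factor_metric_correlations: pd.DataFrame
    logistic_factors: tuple[int, ...]
    logistic_coefficients: np.ndarray | None
    classifier: stats.ClassifierEval | None
    excluded_subjects: list[str]


# ---------------------------------------------------------------------------
# Cohort plumbing


def subject_dual_channel(subject: SyntheticSubject,
                         calib: RescaleCalibration) -> DualChannelVolume:
    """Rescaled TLC intensity + Jacobian of the stored displacement field."""
    frac = rescale_intensity(subject.tlc_hu, calib)
    jac = jacobian_determinant(subject.displacement_mm, subject.spacing_mm)
    return DualChannelVolume(intensity_fraction=frac, jacobian=jac,
                             spacing_mm=subject.spacing_mm,
                             lung_mask=subject.lung_mask)


def subject_prm(subject: SyntheticSubject, calib: RescaleCalibration):
    tlc = rescale_intensity(subject.tlc_hu, calib)
    rv = rescale_intensity(subject.rv_hu, calib)
    jac = jacobian_determinant(subject.displacement_mm, subject.spacing_mm)
    return prm_classify(tlc, rv, subject.lung_mask, calib, jacobian=jac)


def split_subjects(n_subjects: int, test_fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_subjects)
    n_test = max(1, int(round(n_subjects * test_fraction)))
    return sorted(perm[n_test:].tolist()), sorted(perm[:n_test].tolist())


def _roi_seed(config: PipelineConfig, subject_index: int) -> int:
    return int(np.random.SeedSequence((config.seed, 7, subject_index)).generate_state(1)[0]
               % (2 ** 31))


def training_rois(subjects, indices, config: PipelineConfig):
    """Random ROIs from the given subjects; per-subject deterministic seeds, so
    the ROI set of one subject does not depend on which others are present."""
    rois = []
    calib = config.calibration
    for i in indices:
        vol = subject_dual_channel(subjects[i], calib)
        subject_rois = extract_random_rois(vol, n=config.rois_per_subject,
                                           size_vox=config.roi_size_vox,
                                           min_lung_fraction=config.min_lung_fraction,
                                           seed=_roi_seed(config, i))
        for r in subject_rois:
            r.subject_id = subjects[i].subject_id
        rois.extend(subject_rois)
    return rois


def subject_histograms(model: cae_fc.CAEFCModel, subjects, indices,
                       config: PipelineConfig):
    """Sliding-window assignment + histogram per subject.

    Subjects with zero admissible windows are excluded with a warning and
    listed in the returned exclusion list.
    """
    calib = config.calibration
    hists: list[PatternHistogram] = []
    kept: list[int] = []
    excluded: list[str] = []
    for i in indices:
        vol = subject_dual_channel(subjects[i], calib)
        windows = sliding_window_rois(vol, size_vox=config.roi_size_vox,
                                      overlap_vox=config.window_overlap_vox,
                                      min_lung_fraction=config.min_lung_fraction)
        if not windows:
            warnings.warn(f"subject {subjects[i].subject_id} has no admissible windows")
            excluded.append(subjects[i].subject_id)
            continue
        for w in windows:
            w.subject_id = subjects[i].subject_id
        assignments = cae_fc.assign_clusters(model, windows)
        hists.append(build_histogram(assignments, model.config.embedding_size))
        kept.append(i)
    return hists, kept, excluded


# ---------------------------------------------------------------------------
# Model selection sweep


def _cae_config(config: PipelineConfig, e: int) -> cae_fc.CAEFCConfig:
    return cae_fc.CAEFCConfig(embedding_size=e,
                              encoder_channels=config.encoder_channels,
                              roi_size_vox=config.roi_size_vox,
                              gate_keep_k=min(config.gate_keep_k, e),
                              learning_rate=config.learning_rate,
                              batch_size=config.batch_size,
                              epochs=config.epochs,
                              seed=config.seed)


def _cache_key(config: PipelineConfig, e: int, train_ids: list[str]) -> str:
    payload = json.dumps({"config": config.to_dict(), "E": e, "train": train_ids},
                         sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:20]


def _train_model(config: PipelineConfig, e: int, rois, train_ids):
    """Train (or load from the cache keyed by the config hash)."""
    cache = None
    if config.cache_dir is not None:
        cache = Path(config.cache_dir) / f"caefc_{_cache_key(config, e, train_ids)}.npz"
        if cache.exists():
            return cae_fc.load_model(cache)
    model = cae_fc.train_cae_fc(rois, _cae_config(config, e))
    if cache is not None:
        cache.parent.mkdir(parents=True, exist_ok=True)
        cae_fc.save_model(model, cache)
    return model


def _fit_targets(scores: np.ndarray, subjects, kept_indices, targets):
    fits, r2, aic = {}, {}, {}
    for t in targets:
        y = np.array([getattr(subjects[i], t) for i in kept_indices], float)
        fit = stats.ols_fit(scores, y)
        fits[t] = fit
        r2[t] = fit.r2
        aic[t] = stats.aic_ols(fit)
    return fits, r2, aic


def run_model_selection(config: PipelineConfig, subjects=None,
                        return_artifacts: bool = False):
    """Sweep e_grid; each stage failure aborts naming the stage and E."""
    if subjects is None:
        subjects = generate_cohort(config.cohort, min_volume_vox=config.roi_size_vox)
    train_idx, _ = split_subjects(len(subjects), config.test_fraction, config.split_seed)
    train_ids = [subjects[i].subject_id for i in train_idx]
    try:
        rois = training_rois(subjects, train_idx, config)
    except Exception as err:
        raise RuntimeError(f"stage=training_rois failed: {err}") from err

    records = []
    artifacts: dict[int, PipelineArtifacts] = {}
    for e in config.e_grid:
        stage = "train"
        try:
            model = _train_model(config, e, rois, train_ids)
            stage = "histograms"
            hists, kept, _ = subject_histograms(model, subjects, train_idx, config)
            matrix, ids = cohort_matrix(hists)
            stage = "parallel_analysis"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                retained = efa.parallel_analysis(matrix, n_reps=config.pa_n_reps,
                                                 percentile=config.pa_percentile,
                                                 seed=config.seed)
            varying = int((matrix.std(axis=0) > 0).sum())
            if varying < 2:
                raise RuntimeError(
                    f"only {varying} pattern-cluster column(s) vary across "
                    "subjects; the model assigns (nearly) all windows to one "
                    "cluster")
            # at least one factor, and strictly fewer than the varying columns
            n_factors = min(max(1, retained), varying - 1)
            stage = "extract_factors"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                # compositional histogram data converges slowly; allow PAF a
                # larger iteration budget than the standalone default
                factor_model = efa.extract_factors(matrix, n_factors, max_iter=2000)
            scores = efa.factor_scores(factor_model, matrix)
            stage = "regression"
            fits, r2, aic = _fit_targets(scores, subjects, kept, config.targets)
        except Exception as err:
            raise RuntimeError(f"stage={stage} failed at E={e}: {err}") from err
        records.append({"E": e, "retained_factors": retained, "n_factors": n_factors,
                        "aic": aic, "train_r2": r2})
        artifacts[e] = PipelineArtifacts(model=model, factor_model=factor_model,
                                         fits=fits, retained_factors=retained,
                                         train_matrix=matrix, train_ids=ids,
                                         train_scores=scores)
    primary = config.targets[0]
    selected = select_embedding_count(records, primary)
    report = SweepReport(records=records, selected_e=selected, primary_target=primary)
    if return_artifacts:
        return report, artifacts
    return report


def select_embedding_count(records: list[dict], primary_target: str) -> int:
    """Lowest AIC on the primary target wins; ties break toward smaller E."""
    aics = [rec["aic"][primary_target] for rec in records]
    return records[int(np.argmin(aics))]["E"]  # argmin returns the first tie


# ---------------------------------------------------------------------------
# Held-out evaluation


def _severity_groups(values: np.ndarray, n_groups: int = 3):
    """Tertile grouping of the continuous outcome (synthetic severity stages)."""
    edges = np.quantile(values, np.linspace(0, 1, n_groups + 1)[1:-1])
    return np.searchsorted(edges, values, side="right")


def run_evaluation(config: PipelineConfig, model: cae_fc.CAEFCModel,
                   factor_model: efa.FactorModel, fits: dict | None = None,
                   subjects=None) -> EvaluationBundle:
    """Score held-out subjects with trained artifacts and evaluate.

    Training-side regressions are reused when given, otherwise refit on the
    training split (with the already-trained model and factor model; nothing
    is re-estimated from test data).
    """
    if subjects is None:
        subjects = generate_cohort(config.cohort, min_volume_vox=config.roi_size_vox)
    train_idx, test_idx = split_subjects(len(subjects), config.test_fraction,
                                         config.split_seed)
    if fits is None:
        hists, kept, _ = subject_histograms(model, subjects, train_idx, config)
        matrix, _ = cohort_matrix(hists)
        scores = efa.factor_scores(factor_model, matrix)
        fits, _, _ = _fit_targets(scores, subjects, kept, config.targets)
        train_scores, train_kept = scores, kept
    else:
        hists, train_kept, _ = subject_histograms(model, subjects, train_idx, config)
        matrix, _ = cohort_matrix(hists)
        train_scores = efa.factor_scores(factor_model, matrix)

    t_hists, t_kept, excluded = subject_histograms(model, subjects, test_idx, config)
    t_matrix, t_ids = cohort_matrix(t_hists)
    t_scores = efa.factor_scores(factor_model, t_matrix)

    test_r2 = {}
    for t, fit in fits.items():
        y = np.array([getattr(subjects[i], t) for i in t_kept], float)
        pred = fit.predict(t_scores)
        ss_res = float(((y - pred) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        test_r2[t] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    # Welch ANOVA + Games-Howell of each factor across severity tertiles.
    primary = config.targets[0]
    y_primary = np.array([getattr(subjects[i], primary) for i in t_kept], float)
    groups = _severity_groups(y_primary)
    anova: dict[int, stats.AnovaResult | None] = {}
    posthoc: dict[int, list] = {}
    for f in range(factor_model.n_factors):
        samples = [t_scores[groups == g, f] for g in np.unique(groups)]
        try:
            anova[f] = stats.welch_anova(samples)
            posthoc[f] = stats.games_howell(samples, labels=list(np.unique(groups)))
        except ValueError:
            anova[f] = None
            posthoc[f] = []

    # Correlations of factors with PRM metrics on the test split.
    calib = config.calibration
    prm_rows = [subject_prm(subjects[i], calib).as_row(subjects[i].subject_id)
                for i in t_kept]
    prm_df = pd.DataFrame(prm_rows)
    metric_cols = ["emph_pct", "fsad_pct", "airt_pct", "tissue_pct_median",
                   "rv_tlc_ratio", "median_jacobian"]
    corr_rows = []
    for f in range(factor_model.n_factors):
        row = {"factor": f}
        for m in metric_cols:
            try:
                res = stats.correlation(t_scores[:, f], prm_df[m].to_numpy())
                row[m] = res.r
            except ValueError:
                row[m] = float("nan")
        corr_rows.append(row)
    corr_df = pd.DataFrame(corr_rows)

    # Post hoc logistic model: the two factors most correlated (|r|) with the
    # continuous outcome on the training split; fit on train, evaluate on test.
    y_train = np.array([getattr(subjects[i], primary) for i in train_kept], float)
    strengths = [abs(stats.correlation(train_scores[:, f], y_train).r)
                 if train_scores[:, f].std() > 0 else 0.0
                 for f in range(factor_model.n_factors)]
    chosen = tuple(int(i) for i in np.argsort(strengths)[::-1][:min(2, len(strengths))])
    yb_train = np.array([subjects[i].outcome_binary for i in train_kept], float)
    yb_test = np.array([subjects[i].outcome_binary for i in t_kept], float)
    coef, classifier = None, None
    if yb_train.min() != yb_train.max() and yb_test.min() != yb_test.max():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coef, _ = stats.logistic_eval(train_scores[:, list(chosen)], yb_train)
            design = np.column_stack([np.ones(len(yb_test)), t_scores[:, list(chosen)]])
            from scipy.special import expit

            prob = expit(design @ coef)
            pred = (prob >= 0.5).astype(int)
            tp = int(((pred == 1) & (yb_test == 1)).sum())
            tn = int(((pred == 0) & (yb_test == 0)).sum())
            fp = int(((pred == 1) & (yb_test == 0)).sum())
            fn = int(((pred == 0) & (yb_test == 1)).sum())
            classifier = stats.ClassifierEval(
                confusion=np.array([[tn, fp], [fn, tp]]),
                accuracy=(tp + tn) / len(yb_test),
                sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
                specificity=tn / (tn + fp) if tn + fp else float("nan"),
                auc=stats.auc_mann_whitney(prob, yb_test.astype(int)),
                roc_points=stats.roc_curve_points(prob, yb_test.astype(int)),
            )

    return EvaluationBundle(test_r2=test_r2, test_scores=t_scores, test_ids=t_ids,
                            anova=anova, posthoc=posthoc,
                            factor_metric_correlations=corr_df,
                            logistic_factors=chosen, logistic_coefficients=coef,
                            classifier=classifier, excluded_subjects=excluded)


# ---------------------------------------------------------------------------
# Factor overlay maps


def factor_map(model: cae_fc.CAEFCModel, factor_model: efa.FactorModel,
               volume: DualChannelVolume, size_vox: int = 32, overlap_vox: int = 16,
               min_lung_fraction: float = 0.5, loading_threshold: float = 0.5) -> np.ndarray:
    """Voxel-wise factor overlay: each sliding window whose cluster loads high
    on a factor votes that factor into its voxels; majority wins, ties to the
    lower factor index; uncovered voxels get -1."""
    sets = efa.high_loading_clusters(factor_model, loading_threshold)
    cluster_to_factors: dict[int, list[int]] = {}
    for f, ids in enumerate(sets):
        for c in ids:
            cluster_to_factors.setdefault(c, []).append(f)
    windows = sliding_window_rois(volume, size_vox=size_vox, overlap_vox=overlap_vox,
                                  min_lung_fraction=min_lung_fraction)
    n_factors = factor_model.n_factors
    votes = np.zeros((n_factors,) + volume.shape, np.int32)
    if windows:
        assignments = cae_fc.assign_clusters(model, windows)
        for w, a in zip(windows, assignments):
            z, y, x = w.origin_vox
            sl = (slice(z, z + size_vox), slice(y, y + size_vox), slice(x, x + size_vox))
            for f in cluster_to_factors.get(a.cluster_id, []):
                votes[(f,) + sl] += 1
    label = np.argmax(votes, axis=0).astype(np.int16)  # argmax ties -> lowest index
    label[votes.sum(axis=0) == 0] = -1
    return label
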