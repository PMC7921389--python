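"""Self-contained benchmark experiments on synthetic cohorts.

These functions are the quantitative backbone of both the test suite and
``scripts/acceptance.py``: each one builds its inputs from the synthetic-data
module, runs the pipeline (or a single stage), and measures recovery of the
planted ground truth.  Oracles used here (brute-force PRM relabeling, explicit
finite-difference Jacobian, exhaustive best-subset regression) are coded
independently of the implementation paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from . import efa, stats
from .pipeline import (PipelineConfig, run_evaluation, run_model_selection,
                       split_subjects, training_rois)
from .preprocessing import RescaleCalibration, jacobian_determinant, prm_classify
from .synthetic import CohortConfig, generate_cohort, generate_displacement


# ---------------------------------------------------------------------------
# End-to-end latent-trait recovery (and the k-means clustering baseline)


def latent_trait_config(seed: int, n_train: int = 40, n_test: int = 20,
                        volume_vox: int = 48, embeddings: int = 8,
                        epochs: int = 5) -> PipelineConfig:
    """Study conditions for the end-to-end experiment: 4 texture classes driven
    by 2 latent factors, 48^3 volumes, E = 8, 5 training epochs.

    The sliding-window overlap is 24 (stride 8): at 48^3 this yields 27
    windows per subject, enough for a stable 8-bin histogram, whereas the
    stride used on full-size CT would leave only 8.
    """
    n = n_train + n_test
    cohort = CohortConfig(n_subjects=n, volume_shape_vox=(volume_vox,) * 3, seed=seed)
    return PipelineConfig(cohort=cohort, e_grid=(embeddings,),
                          test_fraction=n_test / n, split_seed=seed,
                          rois_per_subject=12, window_overlap_vox=24,
                          encoder_channels=(8, 16, 32), learning_rate=3e-3,
                          epochs=epochs, seed=seed)


def _roi_majority_class(subject, roi, size: int) -> int:
    z, y, x = roi.origin_vox
    window = subject.class_map[z:z + size, y:y + size, x:x + size]
    vals = window[window >= 0]
    return int(np.bincount(vals).argmax())


def latent_trait_experiment(seed: int, compute_ari: bool = True,
                            keep_artifacts: bool = False, **kwargs) -> dict:
    """Run the full pipeline on one seeded cohort.

    Returns the parallel-analysis retained factor count, the held-out R^2 of
    the factor-score regression, and (optionally) the adjusted Rand index of
    CAE-FC clusters vs planted classes next to a k-means baseline on the same
    flattened raw patches.
    """
    config = latent_trait_config(seed, **kwargs)
    subjects = generate_cohort(config.cohort, min_volume_vox=config.roi_size_vox)
    report, artifacts = run_model_selection(config, subjects=subjects,
                                            return_artifacts=True)
    e = report.selected_e
    art = artifacts[e]
    bundle = run_evaluation(config, art.model, art.factor_model, fits=art.fits,
                            subjects=subjects)
    out = {
        "retained_factors": art.retained_factors,
        "n_factors": art.factor_model.n_factors,
        "test_r2": bundle.test_r2[config.targets[0]],
    }
    if keep_artifacts:
        out["artifacts"] = art
    if compute_ari:
        train_idx, _ = split_subjects(len(subjects), config.test_fraction,
                                      config.split_seed)
        rois = training_rois(subjects, train_idx, config)
        by_id = {s.subject_id: s for s in subjects}
        labels = np.array([_roi_majority_class(by_id[r.subject_id], r,
                                               config.roi_size_vox) for r in rois])
        from .cae_fc import assign_clusters

        cae_labels = np.array([a.cluster_id for a in assign_clusters(art.model, rois)])
        flat = np.stack([r.values.ravel() for r in rois])
        km = KMeans(n_clusters=e, n_init=4, random_state=seed).fit_predict(flat)
        out["ari_cae"] = float(adjusted_rand_score(labels, cae_labels))
        out["ari_kmeans"] = float(adjusted_rand_score(labels, km))
        # majority-vote purity of clusters against planted classes
        purity = 0
        for c in np.unique(cae_labels):
            purity += np.bincount(labels[cae_labels == c]).max()
        out["cluster_purity"] = float(purity / len(labels))
    return out


# ---------------------------------------------------------------------------
# EFA recovery on planted-loading simulations


def planted_loading_data(rng: np.random.Generator, n: int = 500, n_vars: int = 20,
                         n_factors: int = 2, loading: float = 0.8):
    """Orthogonal-factor data: disjoint blocks of variables load `loading` on
    one factor each; unique variance tops scores up to unit variance."""
    true_l = np.zeros((n_vars, n_factors))
    block = n_vars // n_factors
    for j in range(n_factors):
        true_l[j * block:(j + 1) * block, j] = loading
    f = rng.standard_normal((n, n_factors))
    unique_sd = np.sqrt(1.0 - (true_l ** 2).sum(axis=1))
    x = f @ true_l.T + rng.standard_normal((n, n_vars)) * unique_sd
    return x, f, true_l


def efa_recovery_experiment(seed: int, n: int = 500, n_vars: int = 20,
                            n_factors: int = 2, loading: float = 0.8,
                            n_pa_seeds: int = 20) -> dict:
    rng = np.random.default_rng(seed)
    retained = []
    for i in range(n_pa_seeds):
        x, _, _ = planted_loading_data(rng, n=n, n_vars=n_vars,
                                       n_factors=n_factors, loading=loading)
        retained.append(efa.parallel_analysis(x, n_reps=100, percentile=95.0,
                                              seed=seed + i))
    x, f_true, l_true = planted_loading_data(np.random.default_rng(seed + 10_000),
                                             n=n, n_vars=n_vars,
                                             n_factors=n_factors, loading=loading)
    model = efa.extract_factors(x, n_factors)
    congruence = efa.tucker_congruence(l_true, model.pattern_matrix)
    scores = efa.factor_scores(model, x)
    # align recovered factors to true ones by best |correlation| permutation
    best = None
    for perm in itertools.permutations(range(n_factors)):
        vals = np.array([abs(np.corrcoef(f_true[:, j], scores[:, pj])[0, 1])
                         for j, pj in enumerate(perm)])
        if best is None or vals.min() > best.min():
            best = vals
    return {
        "pa_correct_rate": float(np.mean([r == n_factors for r in retained])),
        "tucker_min": float(congruence.min()),
        "score_corr_min": float(best.min()),
        "phi_offdiag_max": float(np.abs(model.factor_correlations
                                        - np.eye(n_factors)).max()),
    }


# ---------------------------------------------------------------------------
# Statistics oracle suite


def welch_t2_gap(seed: int) -> float:
    """|Welch ANOVA F - squared Welch t| on a random two-group dataset."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, 23)
    b = rng.normal(0.7, 2.5, 31)
    res = stats.welch_anova([a, b])
    t = sps.ttest_ind(a, b, equal_var=False).statistic
    return abs(res.f_stat - t ** 2)


def studentized_range_q05(k: int = 3, df: int = 10) -> float:
    """Critical q at alpha = 0.05 from the distribution Games-Howell uses."""
    return float(sps.studentized_range.isf(0.05, k, df))


def forward_selection_rates(seed: int, n_reps: int = 50, n_null_candidates: int = 2) -> dict:
    """Forward selection on planted 3-of-6-predictor problems (n = 500) against
    the exhaustive best-AIC subset and the planted truth, plus the null
    false-selection rate.

    Under the per-step partial-F stop at alpha, a null problem with m candidate
    predictors ends empty with probability ~(1 - alpha)^m, so the null check
    uses 2 candidates (the regime where a >= 90% empty rate is the correct
    expectation at alpha = 0.05).
    """
    rng = np.random.default_rng(seed)
    match_aic, match_truth, empty = 0, 0, 0
    k = 6
    betas = np.array([1.0, 0.8, 0.6, 0.0, 0.0, 0.0])
    truth = {0, 1, 2}
    for _ in range(n_reps):
        x = rng.standard_normal((500, k))
        y = x @ betas + rng.standard_normal(500)
        selected, _ = stats.forward_select(x, y, alpha=0.05)
        best_subset, best_aic = None, np.inf
        for r in range(k + 1):
            for subset in itertools.combinations(range(k), r):
                fit = stats.ols_fit(x[:, list(subset)], y)
                aic = stats.aic_ols(fit)
                if aic < best_aic:
                    best_aic, best_subset = aic, set(subset)
        match_aic += set(selected) == best_subset
        match_truth += set(selected) == truth
    for _ in range(n_reps):
        x = rng.standard_normal((200, n_null_candidates))
        y = rng.standard_normal(200)
        selected, _ = stats.forward_select(x, y, alpha=0.05)
        empty += not selected
    return {"planted_match_rate": match_aic / n_reps,
            "planted_truth_rate": match_truth / n_reps,
            "null_empty_rate": empty / n_reps}


# ---------------------------------------------------------------------------
# PRM and Jacobian oracles


def brute_force_prm_counts(tlc_fraction, rv_fraction, mask, calib: RescaleCalibration,
                           emph_hu: float = -950.0, trap_hu: float = -856.0):
    """Per-voxel python relabeling: independent oracle for prm_classify."""
    emph_thr = (emph_hu - calib.air_hu) / (calib.tissue_hu - calib.air_hu)
    trap_thr = (trap_hu - calib.air_hu) / (calib.tissue_hu - calib.air_hu)
    n_emph = n_fsad = n_trap = n_lung = 0
    it = np.nditer(mask, flags=["multi_index"])
    for m in it:
        if not m:
            continue
        idx = it.multi_index
        n_lung += 1
        t, r = tlc_fraction[idx], rv_fraction[idx]
        if r < trap_thr:
            n_trap += 1
        if t < emph_thr:
            n_emph += 1
        elif r < trap_thr:
            n_fsad += 1
    return n_emph, n_fsad, n_trap, n_lung


def prm_exactness_experiment(seed: int, n_volumes: int = 20, shape=(12, 12, 12)) -> dict:
    """Count-level agreement between prm_classify and the brute-force oracle on
    random paired fraction volumes, plus the hand-enumerated 4-voxel case."""
    rng = np.random.default_rng(seed)
    calib = RescaleCalibration(air_hu=-1000.0, tissue_hu=55.0)
    max_gap = 0
    for _ in range(n_volumes):
        tlc = rng.uniform(-0.05, 0.30, shape)
        rv = tlc + rng.uniform(0.0, 0.25, shape)
        mask = rng.random(shape) < 0.7
        if not mask.any():
            mask[0, 0, 0] = True
        res = prm_classify(tlc, rv, mask, calib)
        n_lung = int(mask.sum())
        got = (round(res.emph_pct * n_lung / 100), round(res.fsad_pct * n_lung / 100),
               round(res.airt_pct * n_lung / 100))
        want = brute_force_prm_counts(tlc, rv, mask, calib)[:3]
        max_gap = max(max_gap, max(abs(g - w) for g, w in zip(got, want)))

    emph_thr = float(calib.fraction(-950.0))
    trap_thr = float(calib.fraction(-856.0))
    lo, hi = 0.8, 1.2  # multiples of the threshold: below / above
    tlc4 = np.array([emph_thr * lo, emph_thr * hi, emph_thr * hi, emph_thr * hi])
    rv4 = np.array([trap_thr * lo, trap_thr * lo, trap_thr * hi, trap_thr * hi])
    res4 = prm_classify(tlc4.reshape(4, 1, 1), rv4.reshape(4, 1, 1),
                        np.ones((4, 1, 1), np.uint8), calib)
    return {"max_count_gap": int(max_gap), "four_voxel_emph_pct": res4.emph_pct,
            "four_voxel_fsad_pct": res4.fsad_pct, "four_voxel_airt_pct": res4.airt_pct}


def brute_force_jacobian(u: np.ndarray, spacing) -> np.ndarray:
    """Voxel-loop finite-difference Jacobian determinant (independent oracle):
    central differences inside, one-sided on boundaries."""
    u = np.asarray(u, np.float64)
    d, h, w = u.shape[:3]
    out = np.empty((d, h, w))
    sp = [float(s) for s in spacing]

    def deriv(comp, idx, axis):
        i = list(idx)
        n = u.shape[axis]
        if 0 < idx[axis] < n - 1:
            i[axis] += 1
            hi = u[tuple(i)][comp]
            i[axis] -= 2
            lo = u[tuple(i)][comp]
            return (hi - lo) / (2 * sp[axis])
        if idx[axis] == 0:
            i[axis] += 1
            return (u[tuple(i)][comp] - u[idx][comp]) / sp[axis]
        i[axis] -= 1
        return (u[idx][comp] - u[tuple(i)][comp]) / sp[axis]

    for z in range(d):
        for y in range(h):
            for x in range(w):
                idx = (z, y, x)
                m = np.eye(3)
                for i in range(3):
                    for j in range(3):
                        m[i, j] += deriv(i, idx, j)
                out[idx] = np.linalg.det(m)
    return out


def jacobian_experiment(seed: int) -> dict:
    shape = (8, 9, 10)
    spacing = (0.625, 0.625, 0.625)
    ident = generate_displacement(shape, "identity")
    gap_identity = float(np.abs(jacobian_determinant(ident, spacing) - 1.0).max())
    scale = generate_displacement(shape, "uniform_scale", parameter=0.8,
                                  spacing_mm=spacing[0])
    j = jacobian_determinant(scale, spacing)
    gap_scale = float(np.abs(j[1:-1, 1:-1, 1:-1] - 0.8 ** 3).max())
    # compare both algorithms on the same float64 field (the stored field is
    # float32; subtracting float32 scalars would limit the oracle itself)
    rnd = generate_displacement(shape, "smooth_random", parameter=0.5,
                                seed=seed).astype(np.float64)
    gap_oracle = float(np.abs(jacobian_determinant(rnd, spacing)
                              - brute_force_jacobian(rnd, spacing)).max())
    return {"identity_gap": gap_identity, "uniform_scale_gap": gap_scale,
            "oracle_gap": gap_oracle}
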