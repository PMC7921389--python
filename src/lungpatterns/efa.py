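"""Exploratory factor analysis of pattern-cluster histograms.

Factor count by Horn's parallel analysis; extraction by principal-axis
factoring with iterated communalities; oblique promax rotation (power 4) on a
Kaiser-normalised varimax solution; Thurstone regression factor scores.  The
pattern matrix holds each cluster's unique contribution to each factor, the
structure matrix its correlations with the factors; for an oblique solution
structure = pattern @ factor_correlations.

Sign convention: every factor is flipped so its largest-magnitude pattern
loading is positive, which makes solutions reproducible across runs.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np


class EFAConvergenceError(RuntimeError):
    pass


@dataclass
class FactorModel:
    n_factors: int
    pattern_matrix: np.ndarray        # E x F, unique contributions
    structure_matrix: np.ndarray      # E x F, factor correlations of variables
    factor_correlations: np.ndarray   # F x F
    communalities: np.ndarray         # length E
    score_weights: np.ndarray         # E x F (regression method)
    column_means: np.ndarray          # length-E standardisation constants
    column_sds: np.ndarray
    heywood: bool = False

    def to_json(self) -> str:
        return json.dumps({
            "n_factors": self.n_factors,
            "pattern_matrix": self.pattern_matrix.tolist(),
            "structure_matrix": self.structure_matrix.tolist(),
            "factor_correlations": self.factor_correlations.tolist(),
            "communalities": self.communalities.tolist(),
            "score_weights": self.score_weights.tolist(),
            "column_means": self.column_means.tolist(),
            "column_sds": self.column_sds.tolist(),
            "heywood": self.heywood,
        })

    @classmethod
    def from_json(cls, text: str) -> "FactorModel":
        d = json.loads(text)
        return cls(n_factors=d["n_factors"],
                   pattern_matrix=np.array(d["pattern_matrix"]),
                   structure_matrix=np.array(d["structure_matrix"]),
                   factor_correlations=np.array(d["factor_correlations"]),
                   communalities=np.array(d["communalities"]),
                   score_weights=np.array(d["score_weights"]),
                   column_means=np.array(d["column_means"]),
                   column_sds=np.array(d["column_sds"]),
                   heywood=d["heywood"])


@dataclass
class FactorScores:
    subject_id: str
    scores: np.ndarray


def _sorted_corr_eigenvalues(x: np.ndarray) -> np.ndarray:
    r = np.corrcoef(x, rowvar=False)
    return np.sort(np.linalg.eigvalsh(r))[::-1]


def parallel_analysis(data: np.ndarray, n_reps: int = 100, percentile: float = 95.0,
                      seed: int = 0) -> int:
    """Retain leading factors whose correlation eigenvalues exceed the
    rank-matched percentile of eigenvalues from same-shape standard-normal data."""
    x = np.asarray(data, float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    sds = x.std(axis=0)
    if (sds == 0).any():
        warnings.warn(f"dropping {int((sds == 0).sum())} constant column(s) "
                      "before parallel analysis")
        x = x[:, sds > 0]
    n, p = x.shape
    obs = _sorted_corr_eigenvalues(x)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_reps, p))
    for r in range(n_reps):
        sims[r] = _sorted_corr_eigenvalues(rng.standard_normal((n, p)))
    thresholds = np.percentile(sims, percentile, axis=0)
    exceeds = obs > thresholds
    if exceeds.all():
        return p
    return int(np.argmin(exceeds))  # length of the leading run of True


def _varimax(loadings: np.ndarray, tol: float = 1e-10, max_iter: int = 1000):
    """Kaiser-normalised varimax; returns rotated loadings and rotation matrix."""
    p, k = loadings.shape
    h = np.sqrt((loadings ** 2).sum(axis=1))
    h[h == 0] = 1.0
    a = loadings / h[:, None]
    rot = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        b = a @ rot
        u, s, vt = np.linalg.svd(
            a.T @ (b ** 3 - b @ np.diag((b ** 2).sum(axis=0)) / p))
        rot = u @ vt
        d_new = s.sum()
        if d_new <= d * (1 + tol):
            break
        d = d_new
    return (a @ rot) * h[:, None], rot


def _promax(loadings: np.ndarray, power: int = 4):
    """Promax oblique rotation; returns (pattern, factor correlations)."""
    a, _ = _varimax(loadings)
    q = a * np.abs(a) ** (power - 1)
    u, *_ = np.linalg.lstsq(a, q, rcond=None)
    d = np.diag(np.linalg.inv(u.T @ u))
    u = u * np.sqrt(d)
    pattern = a @ u
    ui = np.linalg.inv(u)
    phi = ui @ ui.T
    return pattern, phi


def extract_factors(data: np.ndarray, n_factors: int, tol: float = 1e-6,
                    max_iter: int = 200, promax_power: int = 4) -> FactorModel:
    """Principal-axis factoring with iterated communalities + promax rotation.

    Columns are standardised internally; constant columns are carried along
    with zero loadings and zero score weight.  Deterministic (no randomness).
    """
    x = np.asarray(data, float)
    n, e_full = x.shape
    if not 1 <= n_factors < e_full:
        raise ValueError("need 1 <= n_factors < number of variables")
    mu_full = x.mean(axis=0)
    sd_full = x.std(axis=0, ddof=1)
    keep = sd_full > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} constant column(s) get zero loadings")
    xk = x[:, keep]
    e = xk.shape[1]
    if n_factors >= e:
        raise ValueError("n_factors must be below the number of varying columns")
    r = np.corrcoef(xk, rowvar=False)

    # Squared multiple correlations as starting communalities (pseudo-inverse
    # handles the exact singularity of compositional data, e.g. proportions).
    diag_rinv = np.diag(np.linalg.pinv(r, rcond=1e-10))
    with np.errstate(divide="ignore"):
        h2 = 1.0 - 1.0 / diag_rinv
    h2 = np.clip(np.nan_to_num(h2, nan=0.5), 0.0, 1.0)
    heywood = False
    loadings = None
    for iteration in range(max_iter):
        rr = r.copy()
        np.fill_diagonal(rr, h2)
        w, v = np.linalg.eigh(rr)
        idx = np.argsort(w)[::-1][:n_factors]
        lam = np.clip(w[idx], 0.0, None)
        loadings = v[:, idx] * np.sqrt(lam)
        h2_new = (loadings ** 2).sum(axis=1)
        if (h2_new > 1.0).any():
            heywood = True
            h2_new = np.clip(h2_new, 0.0, 1.0)
        delta = np.abs(h2_new - h2).max()
        h2 = h2_new
        if delta < tol:
            break
    else:
        raise EFAConvergenceError(
            f"communalities did not converge in {max_iter} iterations "
            f"(last change {delta:.2e})")
    if heywood:
        warnings.warn("Heywood case: communalities clipped to 1")

    if n_factors == 1:
        pattern = loadings.copy()
        phi = np.ones((1, 1))
    else:
        pattern, phi = _promax(loadings, power=promax_power)

    # Sign convention: largest-|loading| entry of each factor positive.
    signs = np.ones(n_factors)
    for j in range(n_factors):
        i_star = int(np.argmax(np.abs(pattern[:, j])))
        if pattern[i_star, j] < 0:
            signs[j] = -1.0
    s = np.diag(signs)
    pattern = pattern @ s
    phi = s @ phi @ s
    structure = pattern @ phi

    if np.linalg.cond(r) > 1e8:
        warnings.warn("near-singular correlation matrix; scoring weights use a "
                      "rank-truncated pseudo-inverse")
        weights = np.linalg.pinv(r, rcond=1e-8) @ structure
    else:
        weights = np.linalg.solve(r, structure)

    def _embed(mat_k, fill=0.0):
        out = np.full((e_full, mat_k.shape[1]), fill)
        out[keep] = mat_k
        return out

    comm = np.zeros(e_full)
    comm[keep] = h2
    sd_store = sd_full.copy()
    sd_store[~keep] = 1.0  # avoid division by zero when scoring constants
    return FactorModel(
        n_factors=n_factors,
        pattern_matrix=_embed(pattern),
        structure_matrix=_embed(structure),
        factor_correlations=phi,
        communalities=comm,
        score_weights=_embed(weights),
        column_means=mu_full,
        column_sds=sd_store,
        heywood=heywood,
    )


def factor_scores(model: FactorModel, data: np.ndarray, subject_ids=None):
    """Thurstone regression scores: standardised data times score weights.

    Returns an (n, F) array, or a list of FactorScores when ids are given.
    """
    x = np.asarray(data, float)
    z = (x - model.column_means) / model.column_sds
    scores = z @ model.score_weights
    if subject_ids is None:
        return scores
    return [FactorScores(subject_id=sid, scores=row)
            for sid, row in zip(subject_ids, scores)]


def high_loading_clusters(model: FactorModel, threshold: float = 0.5) -> list[list[int]]:
    """Per factor, cluster ids with |pattern loading| strictly above threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return [list(np.where(np.abs(model.pattern_matrix[:, j]) > threshold)[0])
            for j in range(model.n_factors)]


def tucker_congruence(a: np.ndarray, b: np.ndarray):
    """Best per-factor Tucker congruence between two loading matrices after
    sign/permutation alignment; returns the vector of aligned congruences."""
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.shape != b.shape:
        raise ValueError("loading matrices must share a shape")
    k = a.shape[1]

    def cong(x, y):
        return float(x @ y / np.sqrt((x @ x) * (y @ y)))

    best = None
    for perm in itertools.permutations(range(k)):
        vals = np.array([abs(cong(a[:, j], b[:, pj])) for j, pj in enumerate(perm)])
        if best is None or vals.min() > best.min():
            best = vals
    return best
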