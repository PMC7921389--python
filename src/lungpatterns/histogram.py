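"""Per-subject pattern-cluster histograms: the bridge from ROI cluster
assignments to the factor-analysis input matrix.

Histograms are proportions (not raw counts): subjects differ in lung size and
hence in the number of sliding windows, and proportions remove that nuisance
scale before factor analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PatternHistogram:
    subject_id: str
    frequencies: np.ndarray  # length-E proportions, sum to 1
    n_rois: int


def build_histogram(assignments: list, n_clusters: int) -> PatternHistogram:
    """frequencies[c] = count(c) / n_rois; clusters never seen get 0."""
    if len(assignments) == 0:
        raise ValueError("a subject must have at least one assigned ROI")
    ids = np.array([a.cluster_id for a in assignments], int)
    if ids.min() < 0 or ids.max() >= n_clusters:
        raise ValueError(f"cluster ids must lie in [0, {n_clusters})")
    subjects = {a.subject_id for a in assignments}
    if len(subjects) > 1:
        raise ValueError(f"assignments span multiple subjects: {sorted(subjects)}")
    counts = np.bincount(ids, minlength=n_clusters).astype(np.float64)
    return PatternHistogram(subject_id=assignments[0].subject_id,
                            frequencies=counts / len(ids), n_rois=len(ids))


def cohort_matrix(histograms: list[PatternHistogram]):
    """Stack histograms into a subjects x E matrix; rows follow input order."""
    if not histograms:
        raise ValueError("no histograms given")
    sizes = {len(h.frequencies) for h in histograms}
    if len(sizes) != 1:
        raise ValueError(f"histograms have mixed cluster counts: {sorted(sizes)}")
    mat = np.vstack([h.frequencies for h in histograms])
    index = [h.subject_id for h in histograms]
    return mat, index


def histogram_frame(histograms: list[PatternHistogram]) -> pd.DataFrame:
    mat, index = cohort_matrix(histograms)
    e = mat.shape[1]
    df = pd.DataFrame(mat, columns=[f"cluster_{c:03d}" for c in range(e)])
    df.insert(0, "subject_id", index)
    df["n_rois"] = [h.n_rois for h in histograms]
    return df


def frame_to_matrix(df: pd.DataFrame):
    cols = [c for c in df.columns if c.startswith("cluster_")]
    return df[cols].to_numpy(float), list(df["subject_id"])
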