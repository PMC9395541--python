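"""Exploratory k-means clustering of high-dimensional marker trajectories.

Patients are represented by their baseline-normalized marker trajectories,
interpolated and sampled every 12 h until discharge with post-discharge
entries set to 0. Cluster-count selection follows a size rule (the largest k
for which every cluster keeps more than a minimum number of patients, 50 in
the original analysis); patients with fewer than 3 measurement sets are held
out of cluster definition and assigned to the nearest centroid afterwards.

Marker filtering drops markers whose cluster means vary by less than 10%
across a provisional clustering and collapses near-duplicate marker groups
(pairwise Pearson r > 0.9 — hematocrit, hemoglobin and red-cell count in real
blood counts) onto a configured representative (HCT).

Cluster significance uses a column-shuffle permutation null (each feature
column independently permuted across patients, destroying trajectory
structure while preserving marginals) in place of the original
synthetic-data reference test; outputs are labeled accordingly.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .cohort import Cohort, GRID_STEP_DAYS, baseline_mean

logger = logging.getLogger("inflarec")

DEFAULT_MARKERS = ("WBC", "PLT", "HCT", "HGB", "RBC", "RDW", "ANION", "BUN", "CRE", "GLU")
DEFAULT_MAX_DAYS = 10.0
MIN_MEASUREMENT_SETS = 3
VARIATION_THRESHOLD = 0.10
CORRELATION_THRESHOLD = 0.90
PREFERRED_REPRESENTATIVES = ("HCT",)


@dataclass
class FeatureMatrix:
    """Patients x (marker, gridpoint) normalized trajectory features."""

    X: np.ndarray
    columns: list  # (marker, time_days) per column
    patient_ids: list
    held_out: np.ndarray  # too few measurement sets to define clusters
    in_hospital: np.ndarray  # patients x gridpoints bool mask

    def __post_init__(self):
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix must be finite")

    @property
    def markers(self) -> list:
        seen = []
        for m, _ in self.columns:
            if m not in seen:
                seen.append(m)
        return seen

    def subset(self, markers) -> "FeatureMatrix":
        keep = [i for i, (m, _) in enumerate(self.columns) if m in set(markers)]
        return FeatureMatrix(self.X[:, keep], [self.columns[i] for i in keep],
                             self.patient_ids, self.held_out, self.in_hospital)


def build_feature_matrix(cohort: Cohort, markers=DEFAULT_MARKERS,
                         max_days: float = DEFAULT_MAX_DAYS) -> FeatureMatrix:
    """Assemble the normalized, 12-h-gridded, zero-padded feature matrix.

    Within the stay, gridpoints outside a marker's observed span hold the
    nearest observed value; gridpoints after discharge are exactly 0.
    """
    grid = GRID_STEP_DAYS * np.arange(int(round(max_days / GRID_STEP_DAYS)) + 1)
    rows, ids, held, masks = [], [], [], []
    for p in cohort.patients:
        feats = np.zeros((len(markers), grid.size))
        in_hosp = grid <= p.discharge_time
        n_sets = 0
        for j, marker in enumerate(markers):
            if not p.has(marker):
                continue
            s = p.get(marker)
            post = s.times >= 0
            n_sets = max(n_sets, int(post.sum()))
            if not post.any():
                continue
            base = baseline_mean(p, marker)
            if base <= 0:
                continue
            vals = np.interp(grid, s.times[post], s.values[post] / base)
            feats[j] = np.where(in_hosp, vals, 0.0)
        rows.append(feats.ravel())
        ids.append(p.patient_id)
        held.append(n_sets < MIN_MEASUREMENT_SETS)
        masks.append(in_hosp)
    columns = [(m, float(t)) for m in markers for t in grid]
    return FeatureMatrix(np.array(rows), columns, ids,
                         np.array(held, dtype=bool), np.array(masks, dtype=bool))


# ---------------------------------------------------------------------------
# k selection and clustering
# ---------------------------------------------------------------------------

def choose_k_and_cluster(matrix: FeatureMatrix, min_cluster_size: int = 50,
                         seed: int = 0, k_max: int | None = None):
    """Size-constrained k-means: largest k with every cluster above the minimum.

    Held-out patients (fewer than 3 measurement sets) are excluded from
    cluster definition and assigned to their nearest centroid afterwards.
    Returns (labels over all patients, centroids, k). When no k >= 2
    satisfies the size rule, returns a single cluster with a warning.
    """
    X = matrix.X[~matrix.held_out]
    n = X.shape[0]
    if n < min_cluster_size:
        raise ValueError("fewer defining patients than the minimum cluster size")
    if k_max is None:
        k_max = min(n // min_cluster_size, 12)
    best = None
    for k in range(2, max(k_max, 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        sizes = np.bincount(km.labels_, minlength=k)
        if np.all(sizes > min_cluster_size):
            best = (k, km)
    if best is None:
        warnings.warn("no k >= 2 keeps every cluster above the minimum size; "
                      "returning a single cluster")
        centroids = X.mean(axis=0, keepdims=True)
        return np.zeros(len(matrix.patient_ids), dtype=int), centroids, 1
    k, km = best
    labels = np.empty(len(matrix.patient_ids), dtype=int)
    labels[~matrix.held_out] = km.labels_
    if matrix.held_out.any():
        d = np.linalg.norm(matrix.X[matrix.held_out, None, :]
                           - km.cluster_centers_[None, :, :], axis=2)
        labels[matrix.held_out] = np.argmin(d, axis=1)
    return labels, km.cluster_centers_, k


# ---------------------------------------------------------------------------
# Marker filtering
# ---------------------------------------------------------------------------

def _marker_cluster_variation(matrix: FeatureMatrix, labels, marker) -> float:
    """Max pairwise relative difference of a marker's cluster means."""
    cols = [i for i, (m, _) in enumerate(matrix.columns) if m == marker]
    per_patient = matrix.X[:, cols].mean(axis=1)
    means = [per_patient[labels == g].mean() for g in np.unique(labels)]
    center = float(np.mean(np.abs(means)))
    if center == 0:
        return 0.0
    return float((max(means) - min(means)) / center)


def _marker_correlations(matrix: FeatureMatrix) -> pd.DataFrame:
    """Pearson correlations between markers over in-hospital entries only."""
    markers = matrix.markers
    grid_n = matrix.in_hospital.shape[1]
    flat_mask = matrix.in_hospital.ravel()
    vectors = {}
    for m in markers:
        cols = [i for i, (mm, _) in enumerate(matrix.columns) if mm == m]
        vectors[m] = matrix.X[:, cols].ravel()[flat_mask]
    df = pd.DataFrame(vectors)
    return df.corr(method="pearson")


def filter_markers(matrix: FeatureMatrix, min_cluster_size: int = 50,
                   seed: int = 0, variation_threshold: float = VARIATION_THRESHOLD,
                   correlation_threshold: float = CORRELATION_THRESHOLD,
                   representatives=PREFERRED_REPRESENTATIVES) -> list:
    """Apply the variation and correlation filters; returns retained markers.

    A provisional clustering defines groups; markers whose cluster means vary
    by less than the threshold are dropped, then marker groups with pairwise
    Pearson r above the threshold are collapsed onto a preferred
    representative (first by the ``representatives`` priority list, else the
    first in marker order).
    """
    markers = matrix.markers
    if len(markers) < 2:
        raise ValueError("need at least 2 markers to filter")
    labels, _, k = choose_k_and_cluster(matrix, min_cluster_size, seed)
    retained = [m for m in markers
                if _marker_cluster_variation(matrix, labels, m) >= variation_threshold]
    dropped = sorted(set(markers) - set(retained))
    if dropped:
        logger.info("filter_markers: dropped low-variation markers %s", dropped)
    if not retained:
        raise ValueError("every marker was filtered out")

    corr = _marker_correlations(matrix.subset(retained))
    # connected components of the r > threshold graph
    remaining = list(retained)
    groups = []
    while remaining:
        group = [remaining.pop(0)]
        frontier = list(group)
        while frontier:
            m = frontier.pop()
            linked = [o for o in remaining if corr.loc[m, o] > correlation_threshold]
            for o in linked:
                remaining.remove(o)
                group.append(o)
                frontier.append(o)
        groups.append(group)
    final = []
    for group in groups:
        rep = next((r for r in representatives if r in group), group[0])
        if len(group) > 1:
            logger.info("filter_markers: collapsed %s onto %s", sorted(group), rep)
        final.append(rep)
    return [m for m in retained if m in final]


# ---------------------------------------------------------------------------
# Significance
# ---------------------------------------------------------------------------

def _inertia(X, labels, centroids) -> float:
    return float(np.sum((X - centroids[labels]) ** 2))


def cluster_significance(matrix: FeatureMatrix, labels, n_null: int = 200,
                         seed: int = 0, n_init: int = 10) -> float:
    """Permutation-null p-value for the observed clustering objective.

    Columns are independently shuffled across patients (``n_null`` draws),
    the k-means objective is recomputed per draw, and
    p = (1 + #{null <= observed}) / (1 + n_null). This column-shuffle null is
    a simplification of the original synthetic-data reference test.

    ``n_init`` must match the optimizer effort that produced the observed
    labels (the ``choose_k_and_cluster`` default): weaker null fits inflate
    null objectives and bias p low.
    """
    if n_null < 20:
        raise ValueError("n_null must be at least 20")
    labels = np.asarray(labels)
    X = matrix.X[~matrix.held_out]
    lab = labels[~matrix.held_out]
    k = int(np.unique(lab).size)
    centroids = np.stack([X[lab == g].mean(axis=0) for g in np.unique(lab)])
    observed = _inertia(X, np.searchsorted(np.unique(lab), lab), centroids)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_null):
        Xn = X.copy()
        for j in range(Xn.shape[1]):
            rng.shuffle(Xn[:, j])
        km = KMeans(n_clusters=k, n_init=n_init,
                    random_state=int(rng.integers(2 ** 31))).fit(Xn)
        if km.inertia_ <= observed:
            count += 1
    return (1 + count) / (1 + n_null)


def export_clusters(matrix: FeatureMatrix, labels, centroids,
                    labels_path, centroids_path) -> None:
    pd.DataFrame({"patient_id": matrix.patient_ids, "cluster": labels,
                  "held_out": matrix.held_out}).to_csv(labels_path, index=False)
    cols = [f"{m}@{t:g}d" for m, t in matrix.columns]
    pd.DataFrame(centroids, columns=cols).to_csv(centroids_path, index=False)
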