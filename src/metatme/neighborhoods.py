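"""Cellular and metabolic neighborhoods from KNN composition histograms.

Each cell is summarized by the composition of its N nearest neighbors in
physical space (self excluded): a binary tumor/non-tumor frequency histogram
for the cellular-neighborhood (CN) views, or raw counts of neighbors
positive for each of 7 metabolic pathways for the metabolic-neighborhood
(MBN) view.  K-means at the cohort level partitions cells into CN regions
(tumor/stroma at K=2; tumor/interface/stroma at K=3) or K=4 MBNs (minimal,
low, medium-regulatory, high activity), with semantic labels assigned by
ordering cluster centroids on mean tumor fraction (CN) or mean total
pathway positivity (MBN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .core import (
    ARTIFACT,
    CN2_LABELS,
    CN3_LABELS,
    MBN_LABELS,
    PanelConfig,
    ValidationError,
    logger,
    pos_col,
)

CN_WINDOW_K2 = 50
CN_WINDOW_K3 = 30
MBN_WINDOW = 30


def knn_composition(
    cells: pd.DataFrame,
    N: int,
    basis: str,
    panel: PanelConfig | None = None,
) -> pd.DataFrame:
    """Per-cell composition of the N nearest neighbors (self excluded).

    ``basis="cn"`` counts tumor vs non-tumor neighbors from ``cell_type``;
    ``basis="mbn"`` sums, per pathway, the neighbors positive for the
    pathway's proxy marker (one neighbor can contribute to several
    pathways).  Cores with fewer than N+1 usable cells are skipped with a
    warning and their rows returned as NaN.  Artifact cells are ignored.
    """
    if basis == "cn":
        columns = ["tumor", "non_tumor"]
    elif basis == "mbn":
        if panel is None:
            raise ValidationError("mbn basis requires a panel")
        columns = list(panel.pathway_map)
    else:
        raise ValidationError(f"unknown basis {basis!r}")

    out = pd.DataFrame(np.nan, index=cells.index, columns=columns)
    usable = cells["cell_type"].to_numpy() != ARTIFACT
    for core_id, sub in cells[usable].groupby("core_id", sort=True):
        if len(sub) < N + 1:
            logger.warning(
                "core %r has %d cells (< %d); skipped from %s neighborhoods",
                core_id, len(sub), N + 1, basis,
            )
            continue
        xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        nn = NearestNeighbors(n_neighbors=N + 1).fit(xy)
        _, nbrs = nn.kneighbors(xy)
        nbrs = nbrs[:, 1:]  # drop self
        if basis == "cn":
            is_tumor = (sub["cell_type"].to_numpy() == "tumor").astype(float)
            t = is_tumor[nbrs].sum(axis=1)
            out.loc[sub.index, "tumor"] = t
            out.loc[sub.index, "non_tumor"] = N - t
        else:
            for pathway, marker in panel.pathway_map.items():
                p = sub[pos_col(marker)].to_numpy(dtype=float)
                out.loc[sub.index, pathway] = p[nbrs].sum(axis=1)
    return out


@dataclass
class NeighborhoodModel:
    """Fitted cohort-level k-means over composition histograms."""

    basis: str
    N: int
    K: int
    centroids: np.ndarray
    label_map: dict[int, str]  # cluster id -> semantic label
    inertia: float
    normalize: bool  # histograms scaled to frequencies before clustering

    def assign(self, histograms: pd.DataFrame) -> pd.Series:
        """Label every cell with a finite histogram; NaN rows stay unlabeled."""
        valid = histograms.notna().all(axis=1)
        H = histograms[valid].to_numpy(dtype=float)
        if self.normalize:
            H = H / np.maximum(H.sum(axis=1, keepdims=True), 1e-12)
        d = ((H[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        ids = d.argmin(axis=1)
        labels = pd.Series(pd.NA, index=histograms.index, dtype=object)
        labels[valid] = [self.label_map[i] for i in ids]
        return labels

    def to_files(self, yaml_path, centroid_csv_path) -> None:
        pd.DataFrame(self.centroids).to_csv(centroid_csv_path, index=False)
        with open(yaml_path, "w") as fh:
            yaml.safe_dump(
                {
                    "basis": self.basis, "N": self.N, "K": self.K,
                    "label_map": {int(k): v for k, v in self.label_map.items()},
                    "inertia": float(self.inertia),
                    "normalize": self.normalize,
                    "centroids_csv": str(centroid_csv_path),
                },
                fh, sort_keys=False,
            )


def _semantic_labels(centroids: np.ndarray, basis: str, K: int) -> dict[int, str]:
    if basis == "cn":
        tumor_frac = centroids[:, 0] / np.maximum(centroids.sum(axis=1), 1e-12)
        order = np.argsort(-tumor_frac)  # highest tumor fraction first
        names = CN2_LABELS if K == 2 else CN3_LABELS
    else:
        total = centroids.sum(axis=1)
        order = np.argsort(total)  # ascending activity
        names = MBN_LABELS
    if K != len(names):
        names = [f"cluster{i}" for i in range(K)]
    return {int(c): names[i] for i, c in enumerate(order)}


def fit_neighborhoods(
    histograms: pd.DataFrame, K: int, seed: int, basis: str = "cn"
) -> NeighborhoodModel:
    """Cohort-level k-means (Lloyd, 10 restarts, fixed seed) with semantic labels.

    CN histograms are normalized to neighbor frequencies; MBN histograms are
    clustered as raw counts so that overall metabolic density separates the
    activity levels.
    """
    valid = histograms.dropna()
    H = valid.to_numpy(dtype=float)
    normalize = basis == "cn"
    if normalize:
        H = H / np.maximum(H.sum(axis=1, keepdims=True), 1e-12)
    n_distinct = len(np.unique(H, axis=0))
    if n_distinct < K:
        raise ValidationError(
            f"only {n_distinct} distinct histograms for K={K} clusters"
        )
    km = KMeans(n_clusters=K, n_init=10, random_state=seed, algorithm="lloyd").fit(H)
    model = NeighborhoodModel(
        basis=basis,
        N=0,
        K=K,
        centroids=km.cluster_centers_,
        label_map=_semantic_labels(km.cluster_centers_, basis, K),
        inertia=float(km.inertia_),
        normalize=normalize,
    )
    return model


def annotate_neighborhoods(
    cells: pd.DataFrame,
    panel: PanelConfig,
    seed: int = 0,
    cn2_window: int = CN_WINDOW_K2,
    cn3_window: int = CN_WINDOW_K3,
    mbn_window: int = MBN_WINDOW,
) -> tuple[pd.DataFrame, dict[str, NeighborhoodModel]]:
    """Fit and assign all three neighborhood views on a cohort cell table."""
    cells = cells.copy()
    models: dict[str, NeighborhoodModel] = {}
    for name, N, K, basis in (
        ("cn2_label", cn2_window, 2, "cn"),
        ("cn3_label", cn3_window, 3, "cn"),
        ("mbn_label", mbn_window, 4, "mbn"),
    ):
        hist = knn_composition(cells, N, basis, panel=panel)
        model = fit_neighborhoods(hist, K, seed=seed, basis=basis)
        model.N = N
        models[name] = model
        cells[name] = model.assign(hist)
    return cells, models


@dataclass
class ElbowResult:
    K_range: list[int]
    inertias: list[float]
    knee: int
    knee_score: float
    threshold: float

    @property
    def pronounced(self) -> bool:
        return self.knee_score >= self.threshold


def elbow_inertia(
    histograms: pd.DataFrame,
    K_range=range(2, 9),
    seed: int = 0,
    basis: str = "mbn",
    knee_threshold: float = 0.33,
) -> ElbowResult:
    """Inertia curve over K with the knee at maximum distance to the chord.

    Both axes are scaled to [0, 1] before measuring the perpendicular
    distance from each point to the chord joining the curve's endpoints; a
    featureless curve (inertia decaying smoothly, e.g. like 1/K for an
    unclustered blob) stays below a knee score of about 0.24, so scores
    under ``knee_threshold`` are reported as not pronounced.
    """
    Ks = [int(k) for k in K_range]
    if min(Ks) < 2 or max(Ks) > 12:
        raise ValidationError("K_range must lie within [2, 12]")
    valid = histograms.dropna()
    H = valid.to_numpy(dtype=float)
    if basis == "cn":
        H = H / np.maximum(H.sum(axis=1, keepdims=True), 1e-12)
    inertias = []
    best = np.inf
    for K in Ks:
        km = KMeans(n_clusters=K, n_init=10, random_state=seed, algorithm="lloyd").fit(H)
        # enforce monotone non-increasing inertia across the sweep
        best = min(best, float(km.inertia_))
        inertias.append(best)

    x = (np.array(Ks, dtype=float) - Ks[0]) / max(Ks[-1] - Ks[0], 1)
    span = max(inertias[0] - inertias[-1], 1e-12)
    y = (np.array(inertias) - inertias[-1]) / span
    # chord from (0, 1) to (1, 0); distance = |x + y - 1| / sqrt(2)
    dist = np.abs(x + y - 1.0) / np.sqrt(2.0)
    knee_idx = int(np.argmax(dist))
    return ElbowResult(
        K_range=Ks,
        inertias=inertias,
        knee=Ks[knee_idx],
        knee_score=float(dist[knee_idx]),
        threshold=knee_threshold,
    )
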