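"""Marker thresholding and rule-based cell typing.

Positivity probabilities from a single-channel classifier are binarized at
cohort-level thresholds placed at the minimum of a smoothed density of the
probability distribution, searched inside a window (default [0.02, 0.75])
and capped at 0.5.  Cells whose binary lineage profile exactly matches a
gating rule get that type; the rest inherit the modal type of their five
nearest exactly-matched neighbors in marker-probability space.  Cells whose
profile matches a configured artifact pattern are labeled ``artifact`` and
excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.stats import gaussian_kde
from sklearn.neighbors import NearestNeighbors

from .core import (
    ARTIFACT,
    PanelConfig,
    ValidationError,
    logger,
    pos_col,
    prob_col,
)

DEFAULT_WINDOW = (0.02, 0.75)
DEFAULT_CAP = 0.5
MIN_SAMPLES = 50


@dataclass
class ThresholdSet:
    thresholds: dict[str, float]
    window: tuple[float, float] = DEFAULT_WINDOW
    cap: float = DEFAULT_CAP

    def __post_init__(self) -> None:
        for marker, t in self.thresholds.items():
            if t > self.cap + 1e-12:
                raise ValidationError(f"threshold for {marker!r} exceeds cap")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "thresholds": {m: float(t) for m, t in self.thresholds.items()},
                    "window": list(self.window),
                    "cap": self.cap,
                },
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "ThresholdSet":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["window"] = tuple(payload["window"])
        return cls(**payload)


def threshold_from_density(
    probabilities,
    window: tuple[float, float] = DEFAULT_WINDOW,
    cap: float = DEFAULT_CAP,
    grid_size: int = 512,
) -> float:
    """Threshold at the minimum of a Gaussian-KDE density inside ``window``.

    Scott-bandwidth KDE evaluated on a uniform grid over [0, 1]; the
    threshold is the deepest interior local minimum within the window.
    Fewer than 50 samples, a degenerate distribution, or no interior
    minimum all fall back to the cap, and any minimum above the cap is
    reassigned to the cap.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise ValidationError("cannot estimate a threshold from an empty sample")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("probabilities outside [0, 1]")
    if p.size < MIN_SAMPLES or np.ptp(p) < 1e-12:
        return cap
    grid = np.linspace(0.0, 1.0, grid_size)
    try:
        density = gaussian_kde(p)(grid)
    except np.linalg.LinAlgError:
        return cap
    lo, hi = window
    idx = np.where((grid >= lo) & (grid <= hi))[0]
    if idx.size < 3:
        return cap
    # the density minimum must be interior to the window: a minimum sitting
    # on a window edge means the distribution has no valley there (monotone
    # density), which is the fallback case
    best = idx[np.argmin(density[idx])]
    if best in (idx[0], idx[-1]):
        return cap
    return min(float(grid[best]), cap)


def fit_thresholds(
    cells: pd.DataFrame,
    panel: PanelConfig,
    window: tuple[float, float] = DEFAULT_WINDOW,
    cap: float = DEFAULT_CAP,
) -> ThresholdSet:
    """Cohort-level threshold per panel marker with a probability column."""
    thresholds = {}
    for marker in panel.markers:
        col = prob_col(marker)
        if col in cells.columns:
            thresholds[marker] = threshold_from_density(
                cells[col].to_numpy(), window=window, cap=cap
            )
    return ThresholdSet(thresholds, window=window, cap=cap)


def call_markers(cells: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    """Binarize marker probabilities; probability equal to threshold is positive."""
    cells = cells.copy()
    for marker, t in thresholds.thresholds.items():
        col = prob_col(marker)
        if col not in cells.columns:
            raise ValidationError(f"no probability column for marker {marker!r}")
        cells[pos_col(marker)] = cells[col].to_numpy() >= t
    return cells


# --------------------------------------------------------------------------
# Cell typing
# --------------------------------------------------------------------------

def _match_rules(pos: np.ndarray, markers: list[str], panel: PanelConfig) -> np.ndarray:
    """First-match rule assignment; returns '' where no rule matches."""
    col = {m: i for i, m in enumerate(markers)}
    out = np.full(len(pos), "", dtype=object)
    unassigned = np.ones(len(pos), dtype=bool)
    for rule in panel.phenotype_rules:
        ok = unassigned.copy()
        for m in rule.positive:
            ok &= pos[:, col[m]]
        for m in rule.negative:
            ok &= ~pos[:, col[m]]
        out[ok] = rule.cell_type
        unassigned &= ~ok
    return out


def assign_cell_types(cells: pd.DataFrame, panel: PanelConfig) -> pd.DataFrame:
    """Exact rule matching with 5-NN fallback in marker-probability space.

    Artifact profiles are checked first.  The fallback is computed per core
    over the exactly-matched cells, using all lineage-marker probabilities
    standardized per marker; modal-vote ties break by panel rule order.
    """
    cells = cells.copy()
    markers = panel.lineage_markers
    for m in markers:
        if pos_col(m) not in cells.columns:
            raise ValidationError(f"lineage marker {m!r} has no positivity column")
    pos = cells[[pos_col(m) for m in markers]].to_numpy(dtype=bool)

    artifact = np.zeros(len(cells), dtype=bool)
    col = {m: i for i, m in enumerate(markers)}
    for profile in panel.artifact_profiles:
        mask = np.ones(len(cells), dtype=bool)
        for m in profile:
            mask &= pos[:, col[m]]
        artifact |= mask

    labels = _match_rules(pos, markers, panel)
    labels[artifact] = ARTIFACT
    exact = (labels != "") & ~artifact
    unmatched = labels == ""

    if unmatched.any():
        prob_cols = [prob_col(m) for m in markers if prob_col(m) in cells.columns]
        if not prob_cols:
            raise ValidationError(
                "fallback typing requires marker probability columns"
            )
        rank = {t: i for i, t in enumerate(panel.cell_types)}
        X = cells[prob_cols].to_numpy(dtype=float)
        for core_id, sub in cells.groupby("core_id", sort=True):
            loc = cells.index.get_indexer(sub.index)
            core_exact = loc[exact[loc]]
            core_open = loc[unmatched[loc]]
            if len(core_open) == 0:
                continue
            if len(core_exact) == 0:
                raise ValidationError(
                    f"core {core_id!r}: no exactly matched cells for 5-NN fallback"
                )
            mu = X[core_exact].mean(axis=0)
            sd = X[core_exact].std(axis=0)
            sd[sd == 0] = 1.0
            Xs = (X - mu) / sd
            k = min(5, len(core_exact))
            nn = NearestNeighbors(n_neighbors=k).fit(Xs[core_exact])
            _, nbrs = nn.kneighbors(Xs[core_open])
            neighbor_types = labels[core_exact][nbrs]
            for row, types_row in zip(core_open, neighbor_types):
                uniq, counts = np.unique(types_row, return_counts=True)
                best = counts.max()
                tied = [t for t, c in zip(uniq, counts) if c == best]
                labels[row] = min(tied, key=lambda t: rank.get(t, len(rank)))
    cells["cell_type"] = labels
    cells["exact_match"] = exact
    n_fallback = int(unmatched.sum())
    if n_fallback:
        logger.info("assign_cell_types: %d cells typed by 5-NN fallback", n_fallback)
    return cells


def functionalize(cells: pd.DataFrame, panel: PanelConfig) -> pd.DataFrame:
    """Record functional states (restricted per lineage) and metabolic states.

    Tumor cells may carry the tumor functional set (PD-L1, vimentin, Ki67,
    IDO1, HLA-A); all other lineages the immune set (PD-1, PD-L1, granzyme B,
    ICOS, IDO1).  Metabolic states are the cell's positive pathway proxy
    markers, recorded for every type.
    """
    cells = cells.copy()
    if "cell_type" not in cells.columns:
        raise ValidationError("cell types must be assigned before functionalize")
    is_tumor = cells["cell_type"].to_numpy() == "tumor"

    def _states(allowed: list[str], mask: np.ndarray) -> pd.Series:
        cols = [m for m in allowed if pos_col(m) in cells.columns]
        if not cols:
            return pd.Series([""] * len(cells), index=cells.index)
        mat = cells[[pos_col(m) for m in cols]].to_numpy(dtype=bool)
        mat = mat & mask[:, None]
        return pd.Series(
            [";".join(m for m, p in zip(cols, row) if p) for row in mat],
            index=cells.index,
        )

    tumor_states = _states(panel.tumor_functional_set, is_tumor)
    immune_states = _states(panel.immune_functional_set, ~is_tumor)
    cells["functional_states"] = np.where(is_tumor, tumor_states, immune_states)

    met_cols = [m for m in panel.metabolic_markers if pos_col(m) in cells.columns]
    if met_cols:
        mat = cells[[pos_col(m) for m in met_cols]].to_numpy(dtype=bool)
        cells["metabolic_states"] = [
            ";".join(m for m, p in zip(sorted(met_cols), row_sorted) if p)
            for row_sorted in mat[:, np.argsort(met_cols)]
        ]
    else:
        cells["metabolic_states"] = ""
    return cells
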