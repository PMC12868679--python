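"""Decoy-injection stability selection for binary and time-to-event endpoints.

Each real feature is paired with an artificial decoy — a row-permuted copy
or a second-order Gaussian knockoff — and l1-penalized models (Lasso for a
binary endpoint, penalized Cox for survival) are fit over a penalty grid on
repeated 50% patient subsamples.  A feature's selection frequency is the
maximum over the penalty grid of its per-penalty selection frequency (the
stability-path maximum).  The decoy frequencies calibrate a plus-one
corrected false-discovery-proportion (FDP+) curve over frequency
thresholds; features are returned above the smallest threshold whose FDP+
bound is within the configured cap (gated on the curve showing evidence of
signal), or — for very small discovery sets the small-count bound cannot
certify — above the decoy frequency ceiling by a safety margin.  Decoys can
never be returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from .core import ValidationError, logger

DECOY_PREFIX = "decoy__"


@dataclass
class SelectionConfig:
    n_subsamples: int = 100
    fraction: float = 0.5
    decoy_mode: str = "permutation"  # "permutation" | "knockoff"
    n_penalties: int = 30
    penalty_min_ratio: float = 0.1
    signal_gate: float = 0.4
    endpoint: str = "binary"  # "binary" | "cox"
    grouped: bool = False
    fdp_cap: float = 0.5
    min_threshold: float = 0.3
    decoy_margin: float = 0.2
    margin_floor: float = 0.7
    min_events: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValidationError("subsample fraction must lie in (0, 1)")
        if self.n_subsamples < 50:
            raise ValidationError("need at least 50 subsamples")
        if self.decoy_mode not in ("permutation", "knockoff"):
            raise ValidationError(f"unknown decoy mode {self.decoy_mode!r}")
        if self.endpoint not in ("binary", "cox"):
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")


def inject_decoys(
    matrix: pd.DataFrame, mode: str = "permutation", seed: int = 0
) -> pd.DataFrame:
    """Augment a scaled matrix with one decoy column per real feature.

    Permutation decoys are independent row-permutations of each column
    (identical marginals, broken joint structure).  Knockoff decoys are
    second-order Gaussian knockoffs with the equicorrelated construction,
    matching the empirical mean and covariance; a singular covariance
    (p > n) is ridge-regularized with a warning.
    """
    rng = np.random.default_rng(seed)
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if mode == "permutation":
        decoys = np.column_stack(
            [X[rng.permutation(n), j] for j in range(p)]
        )
    elif mode == "knockoff":
        mu = X.mean(axis=0)
        Xc = X - mu
        sigma = Xc.T @ Xc / max(n - 1, 1)
        eps = 0.0
        eig = np.linalg.eigvalsh(sigma)
        if eig[0] < 1e-8:
            eps = 1e-3 * float(np.trace(sigma)) / p + 1e-8
            sigma = sigma + eps * np.eye(p)
            eig = eig + eps
            logger.warning(
                "knockoff decoys: covariance singular, ridge-regularized (eps=%g)",
                eps,
            )
        s = np.full(p, min(1.0, 2.0 * float(eig[0] if eig[0] > 0 else eps)))
        s = np.minimum(s, np.diag(sigma))
        sigma_inv_s = np.linalg.solve(sigma, np.diag(s))
        cond_mean = Xc - Xc @ sigma_inv_s
        cond_cov = 2.0 * np.diag(s) - np.diag(s) @ sigma_inv_s
        # symmetrize and project to PSD for the sampler
        cond_cov = (cond_cov + cond_cov.T) / 2.0
        w, V = np.linalg.eigh(cond_cov)
        w = np.clip(w, 0.0, None)
        L = V * np.sqrt(w)
        decoys = mu + cond_mean + rng.standard_normal((n, p)) @ L.T
    else:
        raise ValidationError(f"unknown decoy mode {mode!r}")
    decoy_df = pd.DataFrame(
        decoys, index=matrix.index, columns=[DECOY_PREFIX + c for c in matrix.columns]
    )
    return pd.concat([matrix, decoy_df], axis=1)


@dataclass
class SelectionResult:
    frequencies: pd.Series          # real features
    decoy_frequencies: pd.Series
    threshold: float
    fdp_curve: pd.DataFrame         # threshold, n_real, n_decoy, fdp, fdp_plus
    selected: list[str]
    n_fit_failures: int = 0
    estimated_fdp: float = float("nan")


def _binary_penalty_grid(X: np.ndarray, y: np.ndarray, cfg: SelectionConfig):
    n = len(y)
    yc = y - y.mean()
    alpha_max = np.abs(X.T @ yc).max() / n
    alpha_max = max(alpha_max, 1e-6)
    return np.geomspace(alpha_max, alpha_max * cfg.penalty_min_ratio, cfg.n_penalties)


def _fit_support_binary(X, y, alphas) -> np.ndarray:
    """Boolean support per (feature, penalty)."""
    _, coefs, _ = lasso_path(X, y, alphas=alphas, max_iter=3000, tol=1e-3)
    return np.abs(coefs) > 1e-10


def _fit_support_cox(X, times, events, cfg: SelectionConfig, alphas) -> np.ndarray:
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    y = Surv.from_arrays(event=events.astype(bool), time=times)
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alphas=alphas, fit_baseline_model=False, max_iter=20000
    )
    model.fit(X, y)
    support = np.zeros((X.shape[1], len(alphas)), dtype=bool)
    fitted = list(model.alphas_)
    for j, a in enumerate(alphas):
        if a in fitted:
            support[:, j] = np.abs(model.coef_[:, fitted.index(a)]) > 1e-10
    return support


def select_features(
    matrix: pd.DataFrame,
    outcome,
    config: SelectionConfig,
    groups=None,
) -> SelectionResult:
    """Stability selection with decoy-calibrated FDP thresholding.

    ``outcome`` is a binary vector for ``endpoint="binary"`` or a
    ``(times, events)`` pair for ``endpoint="cox"``.  ``groups`` (cohort ids
    aligned to patients) activates the grouped bootstrap: each subsample
    draws the configured fraction from every cohort.
    """
    if matrix.isna().any().any():
        raise ValidationError("feature matrix contains missing values")
    rng = np.random.default_rng(config.seed)
    aug = inject_decoys(matrix, config.decoy_mode, seed=config.seed)
    X_all = aug.to_numpy(dtype=float)
    cols = list(aug.columns)
    n, p_aug = X_all.shape

    if config.endpoint == "binary":
        y = np.asarray(outcome, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValidationError("binary outcome is constant")
        alphas = _binary_penalty_grid(X_all, y, config)
        times = events = None
    else:
        times, events = outcome
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=bool)
        if events.sum() == 0:
            raise ValidationError("all observations censored")
        # penalty grid from one path fit on the full data
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        probe = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=config.n_penalties,
            alpha_min_ratio=config.penalty_min_ratio, fit_baseline_model=False,
        )
        probe.fit(X_all, Surv.from_arrays(event=events, time=times))
        alphas = probe.alphas_

    if config.grouped and groups is None:
        raise ValidationError("grouped selection requires cohort groups")
    group_idx = None
    if config.grouped:
        garr = np.asarray(groups)
        group_idx = [np.where(garr == g)[0] for g in np.unique(garr)]

    def draw() -> np.ndarray:
        if group_idx is not None:
            parts = [
                g[rng.permutation(len(g))[: max(1, int(round(config.fraction * len(g))))]]
                for g in group_idx
            ]
            return np.concatenate(parts)
        size = max(2, int(round(config.fraction * n)))
        return rng.permutation(n)[:size]

    # per-(feature, penalty) selection counts; the final frequency of a
    # feature is the maximum over the penalty grid of its per-penalty
    # frequency (the stability path maximum)
    counts = np.zeros((p_aug, len(alphas)))
    failures = 0
    for _ in range(config.n_subsamples):
        idx = draw()
        if config.endpoint == "cox":
            for _retry in range(10):
                if events[idx].sum() >= config.min_events:
                    break
                idx = draw()
            else:
                if events[idx].sum() < config.min_events:
                    failures += 1
                    continue
        try:
            if config.endpoint == "binary":
                support = _fit_support_binary(X_all[idx], y[idx], alphas)
            else:
                support = _fit_support_cox(
                    X_all[idx], times[idx], events[idx], config, alphas
                )
            counts += support
        except Exception as exc:  # non-convergence counts as non-selection
            failures += 1
            logger.warning("subsample fit failed: %s", exc)
    if failures:
        logger.warning("select_features: %d subsample fits failed", failures)

    freqs = pd.Series(
        counts.max(axis=1) / config.n_subsamples, index=cols
    )
    is_decoy = freqs.index.str.startswith(DECOY_PREFIX)
    real = freqs[~is_decoy]
    decoy = freqs[is_decoy]

    grid = np.round(np.arange(config.min_threshold, 1.0 + 1e-9, 0.01), 4)
    rows = []
    for t in grid:
        n_real = int((real >= t).sum())
        n_decoy = int((decoy >= t).sum())
        fdp = n_decoy / max(1, n_real)
        fdp_plus = (1 + n_decoy) / max(1, n_real)
        rows.append((t, n_real, n_decoy, fdp, fdp_plus))
    curve = pd.DataFrame(
        rows, columns=["threshold", "n_real", "n_decoy", "fdp", "fdp_plus"]
    )
    # the +1 numerator removes the degenerate empty-set minimum of the raw
    # FDP estimate.  Selection needs (a) evidence of signal — the FDP+ curve
    # must dip below the signal gate somewhere — and then (b) takes the
    # smallest threshold whose FDP+ bound is within the cap (maximum power
    # subject to the bound, the knockoff-plus stopping rule)
    cand = curve[curve["n_real"] > 0]
    threshold = 1.01
    if len(cand) and cand["fdp_plus"].min() <= config.signal_gate:
        ok = cand[cand["fdp_plus"] <= config.fdp_cap]
        if len(ok):
            threshold = float(ok["threshold"].min())
    # second discovery route: features whose frequency clears the decoy
    # ceiling by a margin are kept even when the small-count FDP+ bound
    # (>= 1/n_real) cannot certify a one- or two-feature set
    ceiling = float(decoy.max()) if len(decoy) else 0.0
    t_margin = max(config.margin_floor, ceiling + config.decoy_margin)
    if (real >= t_margin).any():
        threshold = min(threshold, t_margin)
    selected: list[str] = []
    est = float("nan")
    if threshold <= 1.0:
        selected = list(real.index[real >= threshold])
        n_real = len(selected)
        n_decoy = int((decoy >= threshold).sum())
        est = (1 + n_decoy) / max(1, n_real)
    return SelectionResult(
        frequencies=real,
        decoy_frequencies=decoy.rename(lambda c: c[len(DECOY_PREFIX):]),
        threshold=threshold,
        fdp_curve=curve,
        selected=selected,
        n_fit_failures=failures,
        estimated_fdp=est,
    )


def select_per_family(
    matrix: pd.DataFrame,
    families: pd.Series,
    outcome,
    config: SelectionConfig,
    groups=None,
) -> dict[str, SelectionResult]:
    """Run selection independently within each feature family."""
    results = {}
    for k, fam in enumerate(sorted(families.unique())):
        cols = families.index[families == fam]
        sub_cfg = SelectionConfig(**{**config.__dict__, "seed": config.seed + k})
        results[fam] = select_features(matrix[list(cols)], outcome, sub_cfg, groups)
    return results
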