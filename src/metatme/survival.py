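"""Clinical endpoint statistics and multivariate survival modeling.

Univariate screens (Mann-Whitney U with Benjamini-Hochberg correction,
per-feature Cox fits, Kaplan-Meier log-rank by median split) plus the
multivariate stage: repeated random-split l1-regularized Cox fits scored by
censoring-weighted time-dependent AUC on held-out patients, and hazard-
weighted prognosis scores (score_i = sum_k logHR_k * z_ik) with resistance
(logHR > 0) and response (logHR < 0) signature subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .core import ValidationError, logger


def mwu_enrichment(
    matrix: pd.DataFrame, groups, pseudocount: float = 1e-6
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per feature with BH adjustment.

    ``groups`` is a boolean vector (True = benefit group).  The log2 fold
    change compares group medians with a pseudocount; constant features get
    p = 1 by convention.
    """
    g = np.asarray(groups, dtype=bool)
    if g.all() or (~g).any() is False or g.sum() == 0 or (~g).sum() == 0:
        raise ValidationError("both groups must be non-empty")
    rows = []
    for feat in matrix.columns:
        x = matrix[feat].to_numpy(dtype=float)
        a, b = x[g], x[~g]
        if np.ptp(x) == 0:
            u, p = len(a) * len(b) / 2.0, 1.0
        else:
            u, p = mannwhitneyu(a, b, alternative="two-sided", method="auto")
        med_a, med_b = np.median(a), np.median(b)
        l2fc = np.log2((med_a + pseudocount) / (med_b + pseudocount)) if (
            med_a + pseudocount > 0 and med_b + pseudocount > 0
        ) else np.nan
        rows.append((feat, float(u), float(p), float(l2fc)))
    out = pd.DataFrame(rows, columns=["feature", "U", "p", "log2fc"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def univariate_cox(
    matrix: pd.DataFrame, times, events, min_events: int = 10
) -> pd.DataFrame:
    """One Cox fit per feature on the continuous scaled value, BH across features.

    Non-converged or degenerate fits are flagged and excluded from the
    adjustment denominator.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if events.sum() < min_events:
        raise ValidationError(f"need at least {min_events} events")
    rows = []
    for feat in matrix.columns:
        x = matrix[feat].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append((feat, np.nan, np.nan, np.nan, np.nan, False))
            continue
        df = pd.DataFrame({"x": x, "time": times, "event": events})
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            s = cph.summary.loc["x"]
            rows.append((
                feat, float(s["coef"]), float(s["coef lower 95%"]),
                float(s["coef upper 95%"]), float(s["p"]), True,
            ))
        except Exception as exc:
            logger.warning("univariate cox failed for %r: %s", feat, exc)
            rows.append((feat, np.nan, np.nan, np.nan, np.nan, False))
    out = pd.DataFrame(
        rows, columns=["feature", "loghr", "ci_low", "ci_high", "p", "converged"]
    )
    out["q"] = np.nan
    ok = out["converged"] & out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


@dataclass
class KmResult:
    chi2: float
    p: float
    curves: pd.DataFrame  # time, stratum, survival, ci_low, ci_high


def km_logrank(values, times, events, split: str = "median") -> KmResult:
    """Median-split Kaplan-Meier with a two-sided log-rank test (1 df)."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if split != "median":
        raise ValidationError(f"unknown split rule {split!r}")
    cut = np.median(values)
    hi = values > cut
    if hi.sum() == 0:  # ties at the median: fall back to >= split
        hi = values >= cut
    if hi.sum() == 0 or (~hi).sum() == 0:
        raise ValidationError("degenerate stratum after median split")
    res = logrank_test(times[hi], times[~hi], events[hi], events[~hi])
    frames = []
    for name, mask in (("high", hi), ("low", ~hi)):
        km = KaplanMeierFitter()
        km.fit(times[mask], events[mask], label=name)
        ci = km.confidence_interval_
        frames.append(pd.DataFrame({
            "time": km.survival_function_.index,
            "stratum": name,
            "survival": km.survival_function_[name].to_numpy(),
            "ci_low": ci.iloc[:, 0].to_numpy(),
            "ci_high": ci.iloc[:, 1].to_numpy(),
        }))
    return KmResult(
        chi2=float(res.test_statistic), p=float(res.p_value),
        curves=pd.concat(frames, ignore_index=True),
    )


# --------------------------------------------------------------------------
# Repeated-split penalized Cox with time-dependent AUC
# --------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    loghr: pd.DataFrame              # feature, loghr, ci_low, ci_high
    auc_times: np.ndarray
    auc_folds: np.ndarray            # folds x times, NaN where undefined
    auc_mean: np.ndarray
    auc_lo: np.ndarray
    auc_hi: np.ndarray
    weights: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def resistance_features(self) -> list[str]:
        return list(self.weights.index[self.weights > 0])

    @property
    def response_features(self) -> list[str]:
        return list(self.weights.index[self.weights <= 0])


def _td_auc(times_tr, events_tr, times_te, events_te, risk, grid):
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    y_tr = Surv.from_arrays(event=events_tr, time=times_tr)
    y_te = Surv.from_arrays(event=events_te, time=times_te)
    lo = times_te[events_te].min() if events_te.any() else np.inf
    # stay inside the support of both the test follow-up and the train-based
    # censoring distribution (IPCW weights blow up at its edge)
    hi = min(times_te.max(), float(np.quantile(times_tr, 0.95)))
    usable = (grid >= lo) & (grid < hi)
    out = np.full(len(grid), np.nan)
    if usable.sum() == 0:
        return out
    auc, _ = cumulative_dynamic_auc(y_tr, y_te, risk, grid[usable])
    out[usable] = auc
    return out


def kfold_cox_auc(
    matrix: pd.DataFrame,
    times,
    events,
    k: int = 10,
    test_size: float = 0.25,
    seed: int = 0,
    horizon: float = 24.0,
    weight_scale: str = "loghr",
) -> SurvivalFit:
    """Repeated random 75/25-split l1-regularized Cox with time-dependent AUC.

    Each of the ``k`` Monte-Carlo splits fits an l1 Cox path on the training
    portion (penalty chosen by concordance on an inner holdout) and scores
    the held-out patients with the censoring-weighted cumulative/dynamic AUC
    on a monthly grid up to the horizon.  Splits whose test portion has no
    events are redrawn.  Per-feature log hazard ratios and CIs come from a
    lightly ridge-penalized multivariate Cox fit on all patients; prognosis
    weights are those logHRs (or HRs with ``weight_scale="hr"``).
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.metrics import concordance_index_censored
    from sksurv.util import Surv

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    X = matrix.to_numpy(dtype=float)
    n = len(times)
    rng = np.random.default_rng(seed)
    grid = np.arange(1.0, horizon + 0.5, 1.0)
    fold_aucs = []
    n_test = max(2, int(round(test_size * n)))
    for _fold in range(k):
        for _retry in range(20):
            perm = rng.permutation(n)
            te, tr = perm[:n_test], perm[n_test:]
            if events[te].sum() >= 1 and events[tr].sum() >= 3:
                break
        else:
            raise ValidationError("could not draw a split with events")
        try:
            model = CoxnetSurvivalAnalysis(
                l1_ratio=1.0, n_alphas=20, alpha_min_ratio=0.05,
                fit_baseline_model=False,
            )
            y_tr = Surv.from_arrays(event=events[tr], time=times[tr])
            # inner holdout on the training portion picks the penalty
            inner = rng.permutation(len(tr))
            cut = max(2, int(0.25 * len(tr)))
            ih, it = tr[inner[:cut]], tr[inner[cut:]]
            if events[it].sum() >= 3 and events[ih].sum() >= 1:
                probe = CoxnetSurvivalAnalysis(
                    l1_ratio=1.0, n_alphas=20, alpha_min_ratio=0.05,
                    fit_baseline_model=False,
                )
                probe.fit(X[it], Surv.from_arrays(event=events[it], time=times[it]))
                best_alpha, best_c = probe.alphas_[0], -np.inf
                for a_ in probe.alphas_:
                    risk_h = probe.predict(X[ih], alpha=a_)
                    if np.ptp(risk_h) == 0:
                        continue
                    c = concordance_index_censored(events[ih], times[ih], risk_h)[0]
                    if c > best_c:
                        best_c, best_alpha = c, a_
                model = CoxnetSurvivalAnalysis(
                    l1_ratio=1.0, alphas=[best_alpha], fit_baseline_model=False
                )
            model.fit(X[tr], y_tr)
            risk = model.predict(X[te])
            if np.ptp(risk) == 0:
                risk = risk + rng.normal(scale=1e-9, size=len(risk))
            fold_aucs.append(
                _td_auc(times[tr], events[tr], times[te], events[te], risk, grid)
            )
        except Exception as exc:
            logger.warning("fold failed: %s", exc)
            fold_aucs.append(np.full(len(grid), np.nan))
    folds = np.vstack(fold_aucs)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(folds, axis=0)
        lo = np.nanpercentile(folds, 2.5, axis=0)
        hi = np.nanpercentile(folds, 97.5, axis=0)

    loghr = _multivariate_loghr(matrix, times, events)
    weights = loghr.set_index("feature")["loghr"]
    if weight_scale == "hr":
        weights = np.exp(weights)
    return SurvivalFit(
        loghr=loghr, auc_times=grid, auc_folds=folds,
        auc_mean=mean, auc_lo=lo, auc_hi=hi, weights=weights,
    )


def _multivariate_loghr(matrix: pd.DataFrame, times, events) -> pd.DataFrame:
    """Multivariate Cox logHRs with 95% CI; ridge-stabilized when p is large."""
    df = matrix.copy()
    df.columns = [str(c) for c in df.columns]
    df["time"] = np.asarray(times, dtype=float)
    df["event"] = np.asarray(events, dtype=bool)
    penalizer = 0.1 if matrix.shape[1] < len(df) / 2 else 0.5
    cph = CoxPHFitter(penalizer=penalizer, l1_ratio=0.0)
    cph.fit(df, duration_col="time", event_col="event")
    s = cph.summary
    return pd.DataFrame({
        "feature": list(matrix.columns),
        "loghr": s["coef"].to_numpy(),
        "ci_low": s["coef lower 95%"].to_numpy(),
        "ci_high": s["coef upper 95%"].to_numpy(),
        "p": s["p"].to_numpy(),
    })


def prognosis_score(
    fit: SurvivalFit, matrix: pd.DataFrame, subset: str | None = None
) -> pd.Series:
    """Hazard-weighted prognosis score: score_i = sum_k w_k * z_ik.

    ``subset="resistance"`` restricts to positive-weight features,
    ``subset="response"`` to negative-weight features; higher scores always
    mean higher predicted hazard.
    """
    w = fit.weights
    if subset == "resistance":
        w = w[w > 0]
    elif subset == "response":
        w = w[w < 0]
    elif subset is not None:
        raise ValidationError(f"unknown signature subset {subset!r}")
    if len(w) == 0:
        return pd.Series(0.0, index=matrix.index)
    return matrix[list(w.index)] @ w
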