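"""Survival analysis and prediction-error evaluation.

The question asked of every candidate marker (TMB, immunogenicity, CYT) is
not whether its Cox coefficient is significant but whether adding it
*reduces prediction error*.  Error is measured by the time-dependent Brier
score with inverse-probability-of-censoring weights (IPCW),

    BS(t) = n^-1 sum_i [ S(t|x_i)^2 1(t_i <= t, d_i = 1) / G(t_i-)
                       + (1 - S(t|x_i))^2 1(t_i > t) / G(t) ]

where G is the Kaplan-Meier estimator of the censoring distribution, and
summarized by the integrated Brier score (IBS) over the span containing
~80% of patient exits.  Honest out-of-sample error is estimated with the
0.632+ bootstrap, which blends apparent and out-of-bag error with a weight
adapted to the relative overfitting rate; model error curves are compared
with a paired Wilcoxon signed-rank test, and a cross-validated one-sided
KS test compares per-split Brier score samples.

Kaplan-Meier grouping at the outer 15% quantiles with a log-rank test
provides the univariable view of each marker.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .viral_compare import KsResult, ks_one_sided

__all__ = [
    "KaplanMeier",
    "km_estimator",
    "quantile_groups",
    "logrank_test",
    "SurvivalModelSpec",
    "MODEL_SPECS",
    "FittedSurvivalModel",
    "fit_cox",
    "PredictionErrorCurve",
    "brier_curve",
    "integrated_brier",
    "weight_632plus",
    "Bootstrap632Result",
    "bootstrap_632plus",
    "crossval_ks",
]


class KaplanMeier:
    """Product-limit estimator with right-continuous and left-limit lookup.

    Used both for the survival function S and — with flipped event
    indicators — for the censoring distribution G, whose left limits
    G(t-) weight the event terms of the IPCW Brier score.
    """

    def __init__(self, times: Sequence[float], events: Sequence[int]):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        if times.size == 0:
            raise ValueError("no observations")
        if np.any(times < 0) or not np.all(np.isfinite(times)):
            raise ValueError("times must be finite and >= 0")
        order = np.argsort(times, kind="stable")
        t = times[order]
        e = events[order]
        uniq = np.unique(t)
        n_at_risk = t.size - np.searchsorted(t, uniq, side="left")
        d = np.array([int(e[t == u].sum()) for u in uniq])
        keep = d > 0
        self.event_times_ = uniq[keep]
        with np.errstate(divide="ignore", invalid="ignore"):
            factors = 1.0 - d[keep] / n_at_risk[keep]
        self.survival_ = np.cumprod(factors)
        self.n_ = int(t.size)

    def survival(self, t: float | np.ndarray) -> np.ndarray:
        """Right-continuous S(t); S(t) = 1 before the first event time."""
        idx = np.searchsorted(self.event_times_, np.asarray(t, dtype=float), "right")
        s = np.concatenate([[1.0], self.survival_])
        return s[idx]

    def survival_left(self, t: float | np.ndarray) -> np.ndarray:
        """Left limit S(t-)."""
        idx = np.searchsorted(self.event_times_, np.asarray(t, dtype=float), "left")
        s = np.concatenate([[1.0], self.survival_])
        return s[idx]


def km_estimator(times: Sequence[float], events: Sequence[int]) -> KaplanMeier:
    """Kaplan-Meier estimate of S(t).  Flip ``events`` to estimate the
    censoring distribution G."""
    return KaplanMeier(times, events)


def quantile_groups(
    scores: Sequence[float], low_q: float = 0.15, high_q: float = 0.15
) -> np.ndarray:
    """Label the bottom/top quantile groups of a score, middle excluded.

    Nearest-rank convention: with n patients the low group holds the
    ceil(low_q * n) smallest scores and the high group the ceil(high_q * n)
    largest; ties at a boundary are all included on the boundary side.
    Returns an array of labels {"low", "high", "excluded"}.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 7:
        raise ValueError("need at least 7 patients for quantile grouping")
    if np.all(scores == scores[0]):
        raise ValueError("constant scores: groups undefined")
    srt = np.sort(scores)
    k_low = math.ceil(low_q * n)
    k_high = math.ceil(high_q * n)
    low_thresh = srt[k_low - 1]
    high_thresh = srt[n - k_high]
    labels = np.full(n, "excluded", dtype=object)
    labels[scores <= low_thresh] = "low"
    labels[scores >= high_thresh] = "high"
    if low_thresh >= high_thresh:
        raise ValueError("quantile groups overlap: score distribution too tied")
    return labels


def logrank_test(
    times: Sequence[float], events: Sequence[int], labels: Sequence[str]
) -> tuple[float, float]:
    """Two-group log-rank test on the {low, high} subset.

    Returns (chi-square statistic, p-value)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels, dtype=object)
    low = labels == "low"
    high = labels == "high"
    if low.sum() == 0 or high.sum() == 0:
        raise ValueError("both groups must be nonempty")
    res = _ll_logrank(
        times[low], times[high], event_observed_A=events[low], event_observed_B=events[high]
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class SurvivalModelSpec:
    """A named Cox model: covariate list plus the stage adjustment flag.

    The Reference model is intercept-only (the marginal Kaplan-Meier
    curve); every covariate model additionally adjusts for tumor stage.
    """

    name: str
    covariates: tuple[str, ...]
    include_stage: bool = True

    @property
    def columns(self) -> tuple[str, ...]:
        cols = tuple(self.covariates)
        if self.include_stage:
            cols += ("stage",)
        return cols


#: Positive, right-skewed covariates entered on the log scale (the field
#: convention for expression-like and count measures in survival models).
LOG_SCALE_COVARIATES = frozenset({"cyt", "tmb", "immunogenicity", "til_burden"})

#: The standard model series compared in the analysis.
MODEL_SPECS: dict[str, SurvivalModelSpec] = {
    "reference": SurvivalModelSpec("reference", (), include_stage=False),
    "tmb": SurvivalModelSpec("tmb", ("tmb",)),
    "tmb_i": SurvivalModelSpec("tmb_i", ("tmb", "immunogenicity")),
    "cyt_tmb": SurvivalModelSpec("cyt_tmb", ("cyt", "tmb")),
}


class FittedSurvivalModel:
    """A fitted survival model exposing S(t | x) on new patients.

    Skewed positive covariates (see LOG_SCALE_COVARIATES) enter on the log
    scale; all covariates are then z-scored with the training mean/sd
    (stored), so coefficients are per-SD log hazard ratios.  The
    intercept-only Reference model predicts the training Kaplan-Meier
    curve for every patient.
    """

    def __init__(self, spec: SurvivalModelSpec, df: pd.DataFrame):
        self.spec = spec
        cols = list(spec.columns)
        self._km: Optional[KaplanMeier] = None
        self._cph: Optional[CoxPHFitter] = None
        n_events = int(df["event"].sum())
        if cols and n_events < len(cols):
            raise ValueError(
                f"model {spec.name!r}: {n_events} events for {len(cols)} covariates"
            )
        self._train_df = df.reset_index(drop=True)
        if not cols:
            self._km = KaplanMeier(df["time"], df["event"])
            return
        X = self._design(df)
        self._mean = X.mean()
        self._sd = X.std(ddof=0).replace(0.0, 1.0)
        Z = (X - self._mean) / self._sd
        fit_df = pd.concat(
            [Z.reset_index(drop=True), df[["time", "event"]].reset_index(drop=True)],
            axis=1,
        )
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(fit_df, duration_col="time", event_col="event")
        except ConvergenceError as exc:
            worst = max(cols, key=lambda c: abs(df[c].astype(float).std()))
            raise ValueError(
                f"model {spec.name!r} failed to converge "
                f"(suspect covariate {worst!r}): {exc}"
            ) from exc
        self._cph = cph
        self._fit_frame = fit_df

    def _design(self, df: pd.DataFrame) -> pd.DataFrame:
        """Design matrix: log-transform the skewed positive covariates."""
        X = df[list(self.spec.columns)].astype(float).copy()
        for c in X.columns:
            if c in LOG_SCALE_COVARIATES:
                if (X[c] <= 0).any():
                    raise ValueError(
                        f"covariate {c!r} must be positive for the log scale"
                    )
                X[c] = np.log(X[c])
        return X

    @property
    def coefficients(self) -> pd.Series:
        if self._cph is None:
            return pd.Series(dtype=float)
        return self._cph.params_

    @property
    def standard_errors(self) -> pd.Series:
        if self._cph is None:
            return pd.Series(dtype=float)
        return self._cph.standard_errors_

    def predict_survival(
        self, df: pd.DataFrame, times: Sequence[float]
    ) -> np.ndarray:
        """S(t | x) for each row of ``df`` at each grid time: (n, T) array."""
        times = np.asarray(times, dtype=float)
        if self._cph is None:
            s = self._km.survival(times)
            return np.tile(s, (len(df), 1))
        Z = (self._design(df) - self._mean) / self._sd
        surv = self._cph.predict_survival_function(
            Z.reset_index(drop=True), times=times
        )
        return surv.to_numpy().T

    def ph_check(self) -> dict[str, tuple[float, float]]:
        """Proportional-hazards diagnostic: Pearson correlation of scaled
        Schoenfeld residuals with event time, per covariate."""
        if self._cph is None:
            return {}
        resid = self._cph.compute_residuals(self._fit_frame, kind="scaled_schoenfeld")
        event_times = self._fit_frame.loc[resid.index, "time"].to_numpy()
        out = {}
        for col in resid.columns:
            r, p = stats.pearsonr(event_times, resid[col].to_numpy())
            out[str(col)] = (float(r), float(p))
        return out


def fit_cox(
    profiles: pd.DataFrame, spec: SurvivalModelSpec
) -> FittedSurvivalModel:
    """Fit the Cox model described by ``spec`` on a patient table."""
    return FittedSurvivalModel(spec, profiles)


@dataclass
class PredictionErrorCurve:
    """Time grid + Brier scores for one survival model."""

    model: str
    times: np.ndarray
    brier: np.ndarray
    tmax: float

    @property
    def ibs(self) -> float:
        return integrated_brier(self)


def _ipcw_terms(
    times: np.ndarray, events: np.ndarray, censor_km: KaplanMeier, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-patient IPCW weight components on the grid.

    Returns (event_weight (n,), alive_mask (n, T), g_grid (T,)) where
    event_weight_i = 1(d_i = 1) / G(t_i-).
    """
    g_left = censor_km.survival_left(times)
    with np.errstate(divide="ignore"):
        event_weight = np.where((events == 1) & (g_left > 0), 1.0 / g_left, 0.0)
    g_grid = censor_km.survival(grid)
    return event_weight, g_grid


def brier_curve(
    surv: np.ndarray,
    times: Sequence[float],
    events: Sequence[int],
    grid: Sequence[float],
    censor_km: Optional[KaplanMeier] = None,
    model: str = "",
    tmax: Optional[float] = None,
) -> PredictionErrorCurve:
    """IPCW time-dependent Brier score of predictions ``surv``.

    ``surv`` is an (n, T) array of predicted survival probabilities
    S(t_j | x_i) on the grid.  ``censor_km`` defaults to the Kaplan-Meier
    censoring estimator of the same data.  Grid points where G(t) = 0 are
    truncated with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    grid = np.asarray(grid, dtype=float)
    surv = np.asarray(surv, dtype=float)
    n = times.size
    if surv.shape != (n, grid.size):
        raise ValueError(f"surv must be (n={n}, T={grid.size}), got {surv.shape}")
    if censor_km is None:
        censor_km = KaplanMeier(times, 1 - events)
    event_weight, g_grid = _ipcw_terms(times, events, censor_km, grid)
    ok = g_grid > 0
    if not np.all(ok):
        warnings.warn(
            "censoring survival reaches 0 inside the grid; truncating",
            stacklevel=2,
        )
        grid = grid[ok]
        surv = surv[:, ok]
        g_grid = g_grid[ok]
    died_by = (times[:, None] <= grid[None, :]) & (events[:, None] == 1)
    alive_at = times[:, None] > grid[None, :]
    term_event = surv**2 * died_by * event_weight[:, None]
    term_alive = (1.0 - surv) ** 2 * alive_at / g_grid[None, :]
    bs = (term_event + term_alive).mean(axis=0)
    if tmax is None:
        tmax = float(grid[-1]) if grid.size else 0.0
    return PredictionErrorCurve(model=model, times=grid, brier=bs, tmax=float(tmax))


def integrated_brier(
    curve: PredictionErrorCurve, tmax: Optional[float] = None
) -> float:
    """Time-normalized trapezoidal integral of the Brier curve up to ``tmax``
    (default: the curve's stored horizon, the ~80%-exit time)."""
    tmax = curve.tmax if tmax is None else tmax
    keep = curve.times <= tmax
    t = curve.times[keep]
    b = curve.brier[keep]
    if t.size < 2:
        raise ValueError("need at least 2 grid points inside the horizon")
    return float(np.trapezoid(b, t) / (t[-1] - t[0]))


def exit_horizon(times: Sequence[float], fraction: float = 0.8) -> float:
    """Time by which the given fraction of patients has exited the study."""
    return float(np.quantile(np.asarray(times, dtype=float), fraction))


def _event_grid(df: pd.DataFrame, tmax: float) -> np.ndarray:
    ev = np.sort(df.loc[df["event"] == 1, "time"].unique())
    grid = ev[ev <= tmax]
    grid = np.concatenate([[0.0], grid])
    if grid[-1] < tmax:
        grid = np.concatenate([grid, [tmax]])
    return grid


def weight_632plus(r_hat: float | np.ndarray) -> float | np.ndarray:
    """0.632+ blending weight w = 0.632 / (1 - 0.368 * R) for a relative
    overfitting rate R in [0, 1]; w = 0.632 exactly at R = 0 and 1 at R = 1."""
    r = np.clip(np.asarray(r_hat, dtype=float), 0.0, 1.0)
    w = 0.632 / (1.0 - 0.368 * r)
    return float(w) if np.isscalar(r_hat) else w


def no_information_error(
    surv: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    grid: np.ndarray,
    censor_km: KaplanMeier,
) -> np.ndarray:
    """No-information Brier curve gamma(t): mean loss over all (patient,
    prediction) cross-pairs, the benchmark for the overfitting rate."""
    event_weight, g_grid = _ipcw_terms(times, events, censor_km, grid)
    died_by = (times[:, None] <= grid[None, :]) & (events[:, None] == 1)
    alive_at = times[:, None] > grid[None, :]
    e1 = (died_by * event_weight[:, None]).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e2 = np.where(g_grid > 0, alive_at.mean(axis=0) / g_grid, 0.0)
    return (surv**2).mean(axis=0) * e1 + ((1.0 - surv) ** 2).mean(axis=0) * e2


@dataclass
class Bootstrap632Result:
    """Output of the 0.632+ bootstrap model comparison."""

    curves: dict[str, PredictionErrorCurve]
    apparent: dict[str, PredictionErrorCurve]
    oob: dict[str, PredictionErrorCurve]
    ibs: dict[str, float]
    oob_ibs_samples: dict[str, np.ndarray]
    comparisons: dict[tuple[str, str], float]
    n_resampled: int


def _pairwise_wilcoxon(
    specs: Sequence[SurvivalModelSpec],
    values: dict[str, np.ndarray],
) -> dict[tuple[str, str], float]:
    out = {}
    for a in specs:
        for b in specs:
            if a.name == b.name:
                continue
            x = values[a.name]
            y = values[b.name]
            diff = x - y
            if np.allclose(diff, 0.0):
                p = 1.0
            else:
                p = float(
                    stats.wilcoxon(x, y, alternative="less", zero_method="zsplit").pvalue
                )
            out[(a.name, b.name)] = p
    return out


def bootstrap_632plus(
    specs: Sequence[SurvivalModelSpec],
    profiles: pd.DataFrame,
    B: int = 100,
    seed: int = 0,
    horizon_fraction: float = 0.8,
    compare: str = "pointwise",
    max_retries: int = 50,
) -> Bootstrap632Result:
    """0.632+ bootstrap prediction-error curves and model comparison.

    For each model: the apparent error curve (fit and evaluate on the full
    cohort) and the out-of-bag curve (average over B bootstrap resamples,
    each fit on the resample and evaluated on its out-of-bag patients) are
    blended pointwise with weight w = 0.632 / (1 - 0.368 * R), where the
    relative overfitting rate R = (err_oob - err_app) / (gamma - err_app)
    is clipped to [0, 1] and gamma is the no-information error.  Degenerate
    resamples (too few events in-bag or out-of-bag) are redrawn.

    ``compare`` chooses the paired Wilcoxon input: "pointwise" pairs the
    blended curves over the time grid; "ibs" pairs per-bootstrap
    out-of-bag IBS values.  Each comparison (a, b) tests the one-sided
    alternative that model a's error is below model b's.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if compare not in ("pointwise", "ibs"):
        raise ValueError(f"unknown compare mode {compare!r}")
    df = profiles.reset_index(drop=True)
    n = len(df)
    times = df["time"].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=int)
    tmax = exit_horizon(times, horizon_fraction)
    grid = _event_grid(df, tmax)
    censor_full = KaplanMeier(times, 1 - events)

    apparent: dict[str, PredictionErrorCurve] = {}
    gamma: dict[str, np.ndarray] = {}
    for spec in specs:
        model = fit_cox(df, spec)
        surv = model.predict_survival(df, grid)
        apparent[spec.name] = brier_curve(
            surv, times, events, grid, censor_full, model=spec.name, tmax=tmax
        )
        gamma[spec.name] = no_information_error(
            surv, times, events, grid, censor_full
        )

    rng = np.random.default_rng(seed)
    min_events = max(len(s.columns) for s in specs) + 2
    oob_sum = {s.name: np.zeros(grid.size) for s in specs}
    oob_ibs: dict[str, list[float]] = {s.name: [] for s in specs}
    n_resampled = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[np.unique(idx)] = False
        boot = df.iloc[idx].reset_index(drop=True)
        oob = df.iloc[oob_mask].reset_index(drop=True)
        if (
            int(boot["event"].sum()) < min_events
            or len(oob) == 0
            or int(oob["event"].sum()) < 1
        ):
            n_resampled += 1
            if n_resampled > max_retries:
                raise RuntimeError("too many degenerate bootstrap samples")
            continue
        oob_times = oob["time"].to_numpy(dtype=float)
        oob_events = oob["event"].to_numpy(dtype=int)
        censor_oob = KaplanMeier(oob_times, 1 - oob_events)
        for spec in specs:
            model = fit_cox(boot, spec)
            surv = model.predict_survival(oob, grid)
            curve = brier_curve(
                surv,
                oob_times,
                oob_events,
                grid,
                censor_oob,
                model=spec.name,
                tmax=tmax,
            )
            if curve.times.size != grid.size:
                # G hit 0 inside the OOB grid; align by padding with the
                # last value (rare at these censoring rates).
                pad = np.full(grid.size - curve.times.size, curve.brier[-1])
                bs_full = np.concatenate([curve.brier, pad])
            else:
                bs_full = curve.brier
            oob_sum[spec.name] += bs_full
            oob_ibs[spec.name].append(
                integrated_brier(
                    PredictionErrorCurve(spec.name, grid, bs_full, tmax)
                )
            )
        b += 1

    curves: dict[str, PredictionErrorCurve] = {}
    oob_curves: dict[str, PredictionErrorCurve] = {}
    ibs: dict[str, float] = {}
    for spec in specs:
        err_app = apparent[spec.name].brier
        err_oob = oob_sum[spec.name] / B
        g = gamma[spec.name]
        err_oob_c = np.minimum(err_oob, g)
        denom = g - err_app
        with np.errstate(divide="ignore", invalid="ignore"):
            r_hat = np.where(
                (denom > 0) & (err_oob_c > err_app),
                (err_oob_c - err_app) / denom,
                0.0,
            )
        w = weight_632plus(r_hat)
        blended = (1.0 - w) * err_app + w * err_oob_c
        curves[spec.name] = PredictionErrorCurve(spec.name, grid, blended, tmax)
        oob_curves[spec.name] = PredictionErrorCurve(spec.name, grid, err_oob, tmax)
        ibs[spec.name] = integrated_brier(curves[spec.name])

    if compare == "pointwise":
        values = {s.name: curves[s.name].brier for s in specs}
    else:
        values = {s.name: np.asarray(oob_ibs[s.name]) for s in specs}
    comparisons = _pairwise_wilcoxon(specs, values)
    return Bootstrap632Result(
        curves=curves,
        apparent=apparent,
        oob=oob_curves,
        ibs=ibs,
        oob_ibs_samples={k: np.asarray(v) for k, v in oob_ibs.items()},
        comparisons=comparisons,
        n_resampled=n_resampled,
    )


def crossval_ks(
    spec_a: SurvivalModelSpec,
    spec_b: SurvivalModelSpec,
    profiles: pd.DataFrame,
    iterations: int = 100,
    seed: int = 0,
    test_fraction: float = 0.5,
    horizon_fraction: float = 0.8,
) -> tuple[KsResult, dict[str, np.ndarray]]:
    """Cross-validated IBS comparison of two models by one-sided KS test.

    Each iteration splits the cohort at random, fits both models on one
    part and scores the Brier curve on the other; the per-iteration IBS
    samples of the two models are compared with the one-sided KS test
    whose alternative is that model a's IBS distribution falls below
    model b's (argument order fixes the direction).
    """
    if iterations < 10:
        raise ValueError("need at least 10 iterations")
    df = profiles.reset_index(drop=True)
    n = len(df)
    rng = np.random.default_rng(seed)
    n_test = max(2, int(round(test_fraction * n)))
    samples: dict[str, list[float]] = {spec_a.name: [], spec_b.name: []}
    done = 0
    guard = 0
    while done < iterations:
        guard += 1
        if guard > iterations * 5:
            raise RuntimeError("too many degenerate cross-validation splits")
        perm = rng.permutation(n)
        test_idx = perm[:n_test]
        train_idx = perm[n_test:]
        train = df.iloc[train_idx].reset_index(drop=True)
        test = df.iloc[test_idx].reset_index(drop=True)
        min_events = max(len(spec_a.columns), len(spec_b.columns)) + 2
        if int(train["event"].sum()) < min_events or int(test["event"].sum()) < 2:
            continue
        t_times = test["time"].to_numpy(dtype=float)
        t_events = test["event"].to_numpy(dtype=int)
        tmax = exit_horizon(t_times, horizon_fraction)
        grid = _event_grid(test, tmax)
        censor = KaplanMeier(t_times, 1 - t_events)
        try:
            for spec in (spec_a, spec_b):
                model = fit_cox(train, spec)
                surv = model.predict_survival(test, grid)
                curve = brier_curve(
                    surv, t_times, t_events, grid, censor, model=spec.name, tmax=tmax
                )
                samples[spec.name].append(integrated_brier(curve))
        except ValueError:
            for key in samples:
                samples[key] = samples[key][: done]
            continue
        done += 1
    arr = {k: np.asarray(v) for k, v in samples.items()}
    # Smaller IBS for model a => its ECDF lies above model b's.
    res = ks_one_sided(arr[spec_a.name], arr[spec_b.name], method="asymp")
    return res, arr
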