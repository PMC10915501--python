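"""Use-availability resource selection over departure times.

For every observed ("used") departure time, ``n_avail`` candidate
("available") times are sampled from the 96 h preceding it, all rows are
annotated with environmental covariates, and a weighted binomial GAM with a
logit link contrasts used against available conditions.  Available rows get
weight 1000 and used rows weight 1, the infinitely-weighted logistic
regression device that makes the logistic fit estimate the resource
selection function (RSF) consistently.  Time relative to sunset and time
relative to high tide enter as penalized cubic B-spline smooths; wind
assistance, cloud cover, pressure change, rain and year enter linearly.

The fitted RSF for a covariate is the exponential of its partial predictor
(intercept excluded), min-max scaled to [0, 1]; smooth peaks (argmax on a
1-min grid) are reported with case-bootstrap confidence intervals, the
bootstrap unit being the whole event (a used time plus its available set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

from .environment import EnvBundle, annotate

__all__ = [
    "GAMSpec",
    "RSFFit",
    "sample_available",
    "build_design",
    "fit_gam",
    "rsf_curve",
    "peak_estimate",
    "bootstrap_peaks",
    "sensitivity_n_available",
]

ALPHA_GRID = np.geomspace(1e-2, 1e6, 9)


@dataclass
class GAMSpec:
    """Model specification for the weighted binomial GAM.

    ``alpha`` fixes the penalty weights of the two smooths; when ``None``
    a shared penalty is chosen by generalized cross-validation over a log
    grid.  ``k`` is the basis dimension per smooth (cubic B-splines with a
    second-derivative-type penalty as implemented by the backend).
    """

    linear_terms: tuple[str, ...] = ("wind_assist", "cloud", "d_pressure", "rain", "year")
    smooth_terms: tuple[str, ...] = ("min_to_sunset", "min_to_hightide")
    k: int = 10
    degree: int = 3
    alpha: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.smooth_terms and self.k < 4:
            raise ValueError("basis dimension k must be >= 4 per smooth")
        overlap = set(self.linear_terms) & set(self.smooth_terms)
        if overlap:
            raise ValueError(f"terms cannot be both linear and smooth: {overlap}")


def sample_available(
    t_used,
    n: int = 30,
    window_hours: float = 96.0,
    grid_minutes: float = 10.0,
    rng: np.random.Generator | None = None,
) -> pd.DatetimeIndex:
    """Sample ``n`` distinct available times from the window before ``t_used``.

    Candidates are the ``grid_minutes``-spaced times ``t_used - k*grid`` for
    k = 1 .. window/grid, i.e. the half-open window [t_used − window, t_used);
    sampling is uniform without replacement.
    """
    if n < 1:
        raise ValueError("need n >= 1 available times")
    if rng is None:
        rng = np.random.default_rng()
    t_used = pd.Timestamp(t_used)
    n_grid = int(round(window_hours * 60 / grid_minutes))
    if n > n_grid:
        raise ValueError(f"cannot draw {n} distinct times from a grid of {n_grid}")
    ks = rng.choice(np.arange(1, n_grid + 1), size=n, replace=False)
    times = t_used - pd.to_timedelta(ks * grid_minutes, unit="m")
    return pd.DatetimeIndex(np.sort(times))


def _event_times(events) -> list[pd.Timestamp]:
    out = []
    for ev in events:
        out.append(pd.Timestamp(getattr(ev, "departure_time", ev)))
    return out


def build_design(
    events,
    env: EnvBundle,
    n_avail: int = 30,
    window_hours: float = 96.0,
    rng: np.random.Generator | None = None,
    track_bearing: float = 262.0,
    used_weight: float = 1.0,
    avail_weight: float = 1000.0,
) -> pd.DataFrame:
    """Used/available design: one used row plus ``n_avail`` available rows per event.

    ``events`` may be departure events or raw timestamps.  Returns a frame
    with ``event_id, t, used, weight`` and the annotated covariate columns.
    """
    if rng is None:
        rng = np.random.default_rng()
    times = _event_times(events)
    recs = []
    for eid, t_used in enumerate(times):
        recs.append((eid, t_used, 1, used_weight))
        for t in sample_available(t_used, n=n_avail, window_hours=window_hours, rng=rng):
            recs.append((eid, t, 0, avail_weight))
    frame = pd.DataFrame(recs, columns=["event_id", "t", "used", "weight"])
    cov = annotate(frame["t"], env, track_bearing=track_bearing)
    cov = cov.drop(columns=["t"]).reset_index(drop=True)
    return pd.concat([frame.reset_index(drop=True), cov], axis=1)


@dataclass
class RSFFit:
    """Fitted weighted binomial GAM with everything needed for curves and peaks."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    linear_terms: tuple[str, ...]
    smooth_terms: tuple[str, ...]
    dropped_terms: tuple[str, ...]
    alpha: tuple[float, ...]
    smoother: object  # BSplines over the smooth covariates (None if all-linear)
    smooth_ranges: dict
    converged: bool
    deviance: float
    _smooth_coef: dict = field(default_factory=dict, repr=False)

    @property
    def intercept(self) -> float:
        return float(self.params["const"])

    def linear_coef(self, name: str) -> float:
        return float(self.params[name])

    def smooth_values(self, name: str, grid: np.ndarray) -> np.ndarray:
        """Evaluate the fitted smooth partial predictor on ``grid``."""
        if name not in self.smooth_terms:
            raise KeyError(f"{name!r} is not a fitted smooth term")
        i = self.smooth_terms.index(name)
        lo, hi = self.smooth_ranges[name]
        span = hi - lo
        g = np.clip(np.asarray(grid, dtype=float), lo + 1e-9 * span, hi - 1e-9 * span)
        basis = self.smoother.smoothers[i].transform(g)
        return basis @ self._smooth_coef[name]


def _gcv_alpha(model_builder, alphas=ALPHA_GRID) -> float:
    """Shared smooth penalty by generalized cross-validation over a log grid."""
    best, best_alpha = np.inf, float(alphas[0])
    for a in alphas:
        res = model_builder(a).fit()
        g = float(res.gcv)
        if g < best:
            best, best_alpha = g, float(a)
    return best_alpha


def fit_gam(design: pd.DataFrame, spec: GAMSpec | None = None) -> RSFFit:
    """Fit the weighted binomial GAM to a used/available design.

    Maximizes the case-weighted binomial log-likelihood with a logit link.
    Constant covariates (e.g. ``year`` in a single-season design) are dropped
    with a warning rather than producing a singular fit.
    """
    if spec is None:
        spec = GAMSpec()
    y = design["used"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("design is degenerate: needs both used and available rows")
    w = design["weight"].to_numpy(dtype=float)

    linear, dropped = [], []
    for name in spec.linear_terms:
        if design[name].nunique() < 2:
            dropped.append(name)
            warnings.warn(f"dropping constant covariate {name!r}", stacklevel=2)
        else:
            linear.append(name)
    X = design[list(linear)].astype(float).copy()
    if "year" in X.columns:
        # two-level indicator, earliest season as reference
        X["year"] = X["year"] - X["year"].min()
    exog = sm.add_constant(X, has_constant="add")

    smooth_terms = tuple(s for s in spec.smooth_terms if design[s].nunique() >= spec.k)
    smooth_ranges = {
        s: (float(design[s].min()), float(design[s].max())) for s in smooth_terms
    }

    if not smooth_terms:
        res = sm.GLM(y, exog, family=sm.families.Binomial(), var_weights=w).fit()
        names = list(exog.columns)
        return RSFFit(
            params=pd.Series(np.asarray(res.params), index=names),
            bse=pd.Series(np.asarray(res.bse), index=names),
            pvalues=pd.Series(np.asarray(res.pvalues), index=names),
            linear_terms=tuple(linear),
            smooth_terms=(),
            dropped_terms=tuple(dropped),
            alpha=(),
            smoother=None,
            smooth_ranges={},
            converged=res.converged,
            deviance=float(res.deviance),
        )

    xs = design[list(smooth_terms)].to_numpy(dtype=float)
    smoother = BSplines(
        xs, df=[spec.k] * len(smooth_terms), degree=[spec.degree] * len(smooth_terms)
    )

    def builder(a):
        return GLMGam(
            y,
            exog,
            smoother=smoother,
            alpha=[a] * len(smooth_terms) if np.isscalar(a) else list(a),
            family=sm.families.Binomial(),
            var_weights=w,
        )

    if spec.alpha is None:
        alpha = (_gcv_alpha(builder),) * len(smooth_terms)
    else:
        alpha = tuple(spec.alpha) if np.iterable(spec.alpha) else (float(spec.alpha),) * len(smooth_terms)

    res = builder(alpha).fit()
    if not res.converged:
        warnings.warn("penalized IRLS did not report convergence", stacklevel=2)

    k_lin = exog.shape[1]
    names = list(exog.columns)
    smooth_coef = {}
    offset = k_lin
    for i, s in enumerate(smooth_terms):
        dim = smoother.smoothers[i].dim_basis
        smooth_coef[s] = np.asarray(res.params)[offset:offset + dim]
        names += [f"{s}_b{j}" for j in range(dim)]
        offset += dim

    return RSFFit(
        params=pd.Series(np.asarray(res.params), index=names),
        bse=pd.Series(np.asarray(res.bse), index=names),
        pvalues=pd.Series(np.asarray(res.pvalues), index=names),
        linear_terms=tuple(linear),
        smooth_terms=smooth_terms,
        dropped_terms=tuple(dropped),
        alpha=alpha,
        smoother=smoother,
        smooth_ranges=smooth_ranges,
        converged=bool(res.converged),
        deviance=float(res.deviance),
        _smooth_coef=smooth_coef,
    )


def rsf_curve(fit: RSFFit, covariate: str, grid) -> np.ndarray:
    """Scaled RSF for one covariate: exp(partial predictor), min-max on [0, 1].

    The intercept and all other terms are excluded (held at their reference),
    so the curve shows relative selection strength along this covariate only.
    """
    grid = np.asarray(grid, dtype=float)
    if covariate in fit.smooth_terms:
        lo, hi = fit.smooth_ranges[covariate]
        if grid.min() < lo or grid.max() > hi:
            warnings.warn(
                f"grid for {covariate!r} extends beyond the fitted range "
                f"[{lo:.1f}, {hi:.1f}]; values are clamped",
                stacklevel=2,
            )
        part = fit.smooth_values(covariate, grid)
    elif covariate in fit.linear_terms:
        part = fit.linear_coef(covariate) * grid
    else:
        raise KeyError(f"{covariate!r} not in fitted model")
    w = np.exp(part - part.max())
    rng_ = w.max() - w.min()
    if rng_ == 0:
        return np.zeros_like(w)
    return (w - w.min()) / rng_


def peak_estimate(fit: RSFFit, smooth: str, grid_minutes: float = 1.0) -> float:
    """Location (minutes) of the maximum of a fitted smooth on a 1-min grid."""
    lo, hi = fit.smooth_ranges[smooth]
    grid = np.arange(lo, hi + grid_minutes, grid_minutes)
    vals = fit.smooth_values(smooth, grid)
    if np.ptp(vals) < 1e-8:
        warnings.warn(f"smooth {smooth!r} is essentially flat; peak ill-defined", stacklevel=2)
    i = int(np.argmax(vals))
    if i in (0, len(grid) - 1):
        warnings.warn(
            f"smooth {smooth!r} peaks at the boundary of the observed range", stacklevel=2
        )
    return float(grid[i])


def bootstrap_peaks(
    events,
    env: EnvBundle,
    spec: GAMSpec | None = None,
    B: int = 100,
    n_avail: int = 30,
    rng: np.random.Generator | None = None,
    track_bearing: float = 262.0,
) -> dict:
    """Case bootstrap of smooth-peak locations.

    Events (used time + freshly sampled available set) are resampled with
    replacement ``B`` times and the model refit; smoothing penalties are held
    at the point fit's values so replicates measure sampling, not tuning,
    variability.  Returns per smooth: mean peak, 2.5/97.5 percentile CI and
    the replicate peaks.
    """
    times = _event_times(events)
    if len(times) < 10:
        raise ValueError("bootstrap needs at least 10 events")
    if rng is None:
        rng = np.random.default_rng()
    if spec is None:
        spec = GAMSpec()

    base_design = build_design(times, env, n_avail=n_avail, rng=rng, track_bearing=track_bearing)
    base_fit = fit_gam(base_design, spec)
    fixed_spec = GAMSpec(
        linear_terms=spec.linear_terms,
        smooth_terms=spec.smooth_terms,
        k=spec.k,
        degree=spec.degree,
        alpha=base_fit.alpha,
    )

    peaks: dict[str, list[float]] = {s: [] for s in base_fit.smooth_terms}
    failures = 0
    for _ in range(B):
        sample = [times[i] for i in rng.integers(0, len(times), len(times))]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                design = build_design(sample, env, n_avail=n_avail, rng=rng,
                                      track_bearing=track_bearing)
                fit = fit_gam(design, fixed_spec)
                for s in peaks:
                    peaks[s].append(peak_estimate(fit, s))
        except Exception:
            failures += 1
            if failures > 0.2 * B:
                raise RuntimeError(
                    f"bootstrap aborted: {failures} refit failures out of {B} attempts"
                )

    out = {"point_fit": base_fit, "n_failures": failures}
    for s, vals in peaks.items():
        arr = np.asarray(vals)
        out[s] = {
            "mean": float(arr.mean()),
            "ci": (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5))),
            "peaks": arr,
        }
    return out


def sensitivity_n_available(
    events,
    env: EnvBundle,
    spec: GAMSpec | None = None,
    candidate_ns: tuple[int, ...] = (5, 10, 20, 30, 50, 100),
    rng: np.random.Generator | None = None,
    track_bearing: float = 262.0,
    stability_tol: float = 0.10,
) -> pd.DataFrame:
    """Linear-coefficient trajectories as the number of available points grows.

    Refits the model for each candidate ``n_avail`` with a fresh available
    sample; a row is flagged stable when every linear coefficient changed by
    less than ``stability_tol`` (relative) from the previous ``n``.
    """
    if not candidate_ns:
        raise ValueError("candidate_ns must be non-empty")
    if rng is None:
        rng = np.random.default_rng()
    if spec is None:
        spec = GAMSpec()
    times = _event_times(events)
    rows = []
    prev = None
    for n in candidate_ns:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            design = build_design(times, env, n_avail=n, rng=rng, track_bearing=track_bearing)
            fit = fit_gam(design, spec)
        coefs = {name: fit.linear_coef(name) for name in fit.linear_terms}
        stable = None
        if prev is not None:
            rel = [
                abs(coefs[k] - prev[k]) / max(abs(prev[k]), 1e-8) for k in coefs
            ]
            stable = bool(max(rel) < stability_tol)
        rows.append({"n_avail": n, **coefs, "stable": stable})
        prev = coefs
    return pd.DataFrame(rows)
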