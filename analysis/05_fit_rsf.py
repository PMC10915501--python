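#!/usr/bin/env python
"""Fit the weighted use-availability GAM to the classified departures.

For each departure, 30 available times are sampled from the preceding 96 h
(weight 1000 vs 1 for the used time) and a binomial GAM with logit link is
fitted: linear terms for wind assistance, cloud, pressure change and rain;
penalized spline smooths for minutes-to-sunset and minutes-to-high-tide.
Writes the coefficient table, scaled RSF curves, and smooth peaks; draws the
four-panel selection figure if matplotlib is installed.
"""

import importlib.util
import json
import warnings
from pathlib import Path

import numpy as np

from knotflight import io as kio
from knotflight.config import PipelineConfig
from knotflight.rsf import GAMSpec, build_design, fit_gam, peak_estimate, rsf_curve

DATA = Path("results/analysis/data")
OUT = Path("results/analysis")


def load_env(cfg):
    from knotflight.environment import EnvBundle, lag_series

    return EnvBundle(
        tide=lag_series(kio.read_series(DATA / "tide.csv", "level"), 0.0),
        cloud=kio.read_series(DATA / "cloud.csv", "okta"),
        weather=kio.read_weather(DATA / "weather.csv"),
        site=(cfg.site_lat, cfg.site_lon),
    )


def main() -> None:
    cfg = PipelineConfig.from_yaml(DATA / "config.yaml")
    events = kio.read_departures(OUT / "departures.csv")
    env = load_env(cfg)
    rng = np.random.default_rng(cfg.seed + 10)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        design = build_design(events, env, n_avail=cfg.n_avail,
                              window_hours=cfg.avail_window_hours, rng=rng,
                              track_bearing=cfg.goal_bearing)
        fit = fit_gam(design, GAMSpec(k=cfg.spline_k))

    import pandas as pd

    coefs = pd.DataFrame(
        [
            {"covariate": c, "beta": fit.linear_coef(c),
             "se": float(fit.bse[c]), "p": float(fit.pvalues[c])}
            for c in fit.linear_terms
        ]
    )
    coefs.to_csv(OUT / "rsf_coefficients.csv", index=False)

    curves, peaks = [], {}
    for s in fit.smooth_terms:
        lo, hi = fit.smooth_ranges[s]
        grid = np.linspace(lo, hi, 300)
        curves.append(pd.DataFrame({"covariate": s, "x": grid,
                                    "rsf": rsf_curve(fit, s, grid)}))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            peaks[s] = peak_estimate(fit, s)
    pd.concat(curves, ignore_index=True).to_csv(OUT / "rsf_curves.csv", index=False)
    with open(OUT / "rsf_peaks.json", "w") as fh:
        json.dump(peaks, fh, indent=1)

    print(f"design: {len(design)} rows ({int(design['used'].sum())} used, "
          f"{int((design['used'] == 0).sum())} available)")
    print("linear coefficients:")
    for _, row in coefs.iterrows():
        print(f"  {row['covariate']:<12} beta={row['beta']:+.3f}  se={row['se']:.3f}  p={row['p']:.3f}")
    print("smooth peaks (min):", {k: round(v) for k, v in peaks.items()})

    if importlib.util.find_spec("matplotlib"):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 2, figsize=(9, 7))
        panels = list(fit.smooth_terms) + ["cloud", "wind_assist"]
        for ax, cov in zip(axes.ravel(), panels):
            if cov in fit.smooth_terms:
                lo, hi = fit.smooth_ranges[cov]
            else:
                lo, hi = design[cov].min(), design[cov].max()
            grid = np.linspace(lo, hi, 300)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ax.plot(grid, rsf_curve(fit, cov, grid), "k-")
            used = design.loc[design["used"] == 1, cov]
            ax.plot(used, np.full(len(used), 1.02), "|", color="k", ms=6)
            ax.set_xlabel(cov)
            ax.set_ylabel("scaled RSF")
        fig.tight_layout()
        fig.savefig(OUT / "rsf_curves.png", dpi=120)
        print(f"figure written to {OUT / 'rsf_curves.png'}")


if __name__ == "__main__":
    main()
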