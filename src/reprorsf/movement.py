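"""Synthetic GPS-collar data with known selection parameters.

The simulator is the generative twin of the inference model: at every
scheduled fix a set of candidate points is drawn uniformly from a disc
around the animal's previous position and one is kept with probability
proportional to ``exp(X beta(t))``, where the coefficient process
``beta(t)`` is evaluated by the same :func:`reprorsf.model.beta_t` used in
fitting. Because selection weights and likelihood share this code path,
parameter recovery on simulated data is a meaningful check of the whole
pipeline.

Reproductive timelines emulate the study conditions: parturition dates are
normal around mid-April (day-of-year ~102), and neonate deaths follow a
geometric (constant daily hazard) law, censored at 120 days, which
front-loads mortality into the first weeks of life.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model as _model
from .grids import Landscape

__all__ = ["TrueParams", "simulate_timelines", "simulate_fixes", "DISC_FACTOR"]

#: candidate/availability discs use radius = DISC_FACTOR * step SD — the 99%
#: quantile of a centred normal step-length distribution.
DISC_FACTOR = 2.58

#: fix schedule (hours) giving 6 positions/day with two in the 04-10 morning
#: window and three in the 13-22 evening window.
DEFAULT_FIX_TIMES = (2, 6, 9, 14, 18, 21)


@dataclass
class TrueParams:
    """Ground-truth selection parameters for the generative model."""

    beta0: float
    beta_base: dict[str, float]
    gamma: dict[str, float] = field(default_factory=dict)
    sigma: dict[str, float] = field(default_factory=dict)
    decay_mode: str = "baseline_return"

    def __post_init__(self):
        for c, g in self.gamma.items():
            if c not in self.beta_base:
                raise ValueError(f"gamma names unknown covariate {c!r}")
            if g != 0 and self.sigma.get(c, 0.0) <= 0:
                raise ValueError(f"sigma must be > 0 for time-varying covariate {c!r}")

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(self.beta_base)

    def to_spec(self) -> _model.ModelSpec:
        return _model.ModelSpec(
            covariates=self.covariates,
            time_varying=tuple(c for c in self.covariates if c in self.gamma),
            decay_mode=self.decay_mode,
        )

    def to_params_dict(self) -> dict[str, float]:
        out = {"beta0": self.beta0}
        out.update({f"beta_{c}": v for c, v in self.beta_base.items()})
        out.update({f"gamma_{c}": v for c, v in self.gamma.items()})
        out.update({f"sigma_{c}": v for c, v in self.sigma.items()})
        return out

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta_base": dict(self.beta_base),
            "gamma": dict(self.gamma),
            "sigma": dict(self.sigma),
            "decay_mode": self.decay_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueParams":
        return cls(
            beta0=d["beta0"],
            beta_base=dict(d["beta_base"]),
            gamma=dict(d.get("gamma", {})),
            sigma=dict(d.get("sigma", {})),
            decay_mode=d.get("decay_mode", "baseline_return"),
        )


def simulate_timelines(
    n_females: int,
    part_mean_doy: float = 102.0,
    part_sd_days: float = 15.0,
    daily_hazard: float = 0.006,
    horizon_days: int = 120,
    seed: int | None = None,
    year: int = 2016,
    prob_pregnant: float = 1.0,
) -> pd.DataFrame:
    """Per female-year reproductive timelines.

    Parturition day-of-year ~ Normal(mean, sd) rounded to whole days; the
    neonate death day (days post-parturition, day 1 = first day of life) is
    geometric with the given daily hazard, censored at ``horizon_days``
    (censored = survived, encoded as missing).
    """
    if not 0.0 <= daily_hazard <= 1.0:
        raise ValueError("daily_hazard must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_females):
        pregnant = bool(rng.random() < prob_pregnant)
        part = death = pd.NA
        if pregnant:
            part = int(np.round(rng.normal(part_mean_doy, part_sd_days)))
            if daily_hazard > 0:
                d = int(rng.geometric(daily_hazard)) if daily_hazard < 1 else 1
                if d <= horizon_days:
                    death = d
        rows.append(
            {
                "animal_id": f"F{i + 1:03d}",
                "year": year,
                "pregnant": pregnant,
                "part_doy": part,
                "death_day": death,
            }
        )
    df = pd.DataFrame(rows)
    df["part_doy"] = df["part_doy"].astype("Int64")
    df["death_day"] = df["death_day"].astype("Int64")
    return df


def _lamb_part(doy: int, part_doy, death_day, wean_cap: int) -> tuple[int, int]:
    """Provisioning state for one animal-day (0-based days since parturition)."""
    if part_doy is pd.NA or pd.isna(part_doy):
        return 0, 0
    part = doy - int(part_doy)
    if part < 0:
        return 0, 0
    last = wean_cap if pd.isna(death_day) else min(int(death_day) - 1, wean_cap)
    if part <= last:
        return 1, part
    return 0, part


def simulate_fixes(
    timelines: pd.DataFrame,
    landscape: Landscape,
    true_params: TrueParams,
    start_doy: int = 32,
    n_days: int = 150,
    fix_times: tuple[int, ...] = DEFAULT_FIX_TIMES,
    step_sd_m: float = 300.0,
    p_miss: float = 0.05,
    p_2d: float = 0.05,
    n_candidates: int = 50,
    wean_cap: int = 120,
    seed: int | None = None,
    start_positions: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Weighted-candidate movement simulation over the landscape.

    For each scheduled fix, ``n_candidates`` points are drawn uniformly from
    the disc of radius ``DISC_FACTOR * step_sd_m`` around the previous
    position (redrawn to stay inside the landscape) and one is selected with
    weight proportional to ``exp(X beta(t))`` on globally z-scored
    covariates. Fixes are then thinned with probability ``p_miss`` and the
    survivors flagged 2-D with probability ``p_2d``.
    """
    if step_sd_m <= 0:
        raise ValueError("step_sd_m must be positive")
    for p, name in ((p_miss, "p_miss"), (p_2d, "p_2d")):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    covs = list(true_params.covariates)
    for c in covs:
        if c not in landscape:
            raise ValueError(f"true_params names layer {c!r} absent from landscape")
    spec = true_params.to_spec()
    pdict = true_params.to_params_dict()
    beta = np.array([pdict[f"beta_{c}"] for c in covs])
    tv_idx = {c: i for i, c in enumerate(spec.time_varying)}
    gamma = np.array([pdict[f"gamma_{c}"] for c in spec.time_varying])
    sigma = np.array([pdict[f"sigma_{c}"] for c in spec.time_varying])

    Z = landscape.standardized_arrays(covs)  # (n_cov, H, W)
    template = landscape.template
    xmin, xmax, ymin, ymax = template.extent
    radius = DISC_FACTOR * step_sd_m
    rng = np.random.default_rng(seed)

    rows = []
    for _, tl in timelines.sort_values(["animal_id", "year"]).iterrows():
        aid, year = tl["animal_id"], int(tl["year"])
        arng = np.random.default_rng(rng.integers(2**31))
        if start_positions and aid in start_positions:
            x, y = start_positions[aid]
            if not template.contains(x, y):
                raise ValueError(f"start position for {aid} outside landscape extent")
        else:
            x = arng.uniform(xmin + 0.25 * (xmax - xmin), xmax - 0.25 * (xmax - xmin))
            y = arng.uniform(ymin + 0.25 * (ymax - ymin), ymax - 0.25 * (ymax - ymin))
        for day in range(n_days):
            doy = start_doy + day
            lamb, part = _lamb_part(doy, tl["part_doy"], tl["death_day"], wean_cap)
            # per-day coefficient vector via the shared process-model code path
            bt = beta.copy()
            if gamma.size:
                for c, k in tv_idx.items():
                    j = covs.index(c)
                    bt[j] = _model.beta_t(
                        beta[j], gamma[k], sigma[k], lamb, part, spec.decay_mode
                    )
            for hour in fix_times:
                cx, cy = _disc_candidates(
                    arng, x, y, radius, n_candidates, (xmin, xmax, ymin, ymax)
                )
                rr, cc = template.index_of(cx, cy)
                zc = Z[:, rr, cc]  # (n_cov, n_candidates)
                eta = true_params.beta0 + bt @ zc
                w = np.exp(eta - eta.max())
                pick = arng.choice(n_candidates, p=w / w.sum())
                x, y = float(cx[pick]), float(cy[pick])
                if arng.random() < p_miss:
                    continue
                rows.append(
                    {
                        "animal_id": aid,
                        "year": year,
                        "timestamp": pd.Timestamp(year, 1, 1)
                        + pd.Timedelta(days=doy - 1, hours=hour),
                        "x": x,
                        "y": y,
                        "fix_dim": "2D" if arng.random() < p_2d else "3D",
                    }
                )
    fixes = pd.DataFrame(
        rows, columns=["animal_id", "year", "timestamp", "x", "y", "fix_dim"]
    )
    fixes.attrs["scheduled_per_animal"] = n_days * len(fix_times)
    return fixes


def _disc_candidates(rng, x, y, radius, n, extent):
    """Uniform draws on the disc, redrawn until all fall inside the extent."""
    xmin, xmax, ymin, ymax = extent
    cx = np.empty(n)
    cy = np.empty(n)
    need = np.ones(n, dtype=bool)
    while need.any():
        m = int(need.sum())
        r = radius * np.sqrt(rng.random(m))
        th = rng.uniform(0, 2 * np.pi, m)
        px = x + r * np.cos(th)
        py = y + r * np.sin(th)
        ok = (px >= xmin) & (px < xmax) & (py >= ymin) & (py < ymax)
        idx = np.flatnonzero(need)[ok]
        cx[idx] = px[ok]
        cy[idx] = py[ok]
        need[idx] = False
    return cx, cy
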