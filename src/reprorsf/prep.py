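"""Screening, labelling and use-availability assembly for GPS fix tables.

The preparation pipeline mirrors standard telemetry practice for
resource-selection analyses, in a fixed order, each stage reporting its
removal counts:

1. collar fix-rate screen (keep animals with rate strictly above 90%),
2. removal of 2-D (three-satellite) fixes,
3. daily subsampling to at most two fixes in a morning (04:00-10:00) and
   two in an evening (13:00-22:00) window,
4. reproductive labelling: a binary provisioning indicator (``lamb``) and
   days-since-parturition (``part``), capped at 120 days (weaning) and
   split into a pre/post-parturition dataset and a post-mortality dataset
   restricted to females whose neonate died within 30 days of birth.

Availability is defined per used location: each used fix is buffered by the
99% quantile of the step-length distribution (2.58 x SD of within-animal
consecutive step lengths) and matched with ``ratio`` (default 10) random
points uniform in that disc. Covariates are sampled at the containing cell
and z-standardised over the combined used + available rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grids import Landscape

__all__ = [
    "fix_rate_filter",
    "remove_2d",
    "subsample_daily",
    "label_reproduction",
    "availability_radius",
    "generate_available",
    "extract_and_standardize",
    "correlation_screen",
    "tradeoff_regressions",
    "prepare_datasets",
]

DEFAULT_WINDOWS = ((4.0, 10.0), (13.0, 22.0))


def fix_rate_filter(
    fixes: pd.DataFrame,
    scheduled: int | dict[str, int],
    min_rate: float = 0.90,
) -> tuple[pd.DataFrame, dict]:
    """Drop whole animals whose fix rate (achieved/scheduled) is <= min_rate.

    The threshold is strict: a collar at exactly the minimum rate is removed.
    """
    counts = fixes.groupby("animal_id").size()
    report: dict = {"min_rate": min_rate, "animals": {}, "removed_animals": []}
    keep_ids = []
    animals = set(counts.index)
    if isinstance(scheduled, dict):
        animals |= set(scheduled)
    for aid in sorted(animals):
        sched = scheduled[aid] if isinstance(scheduled, dict) else scheduled
        achieved = int(counts.get(aid, 0))
        if sched <= 0:
            report["animals"][aid] = {"scheduled": sched, "achieved": achieved, "rate": None}
            report["removed_animals"].append(aid)
            continue
        rate = achieved / sched
        report["animals"][aid] = {"scheduled": sched, "achieved": achieved, "rate": rate}
        if rate > min_rate:
            keep_ids.append(aid)
        else:
            report["removed_animals"].append(aid)
    out = fixes[fixes["animal_id"].isin(keep_ids)].reset_index(drop=True)
    report["n_in"] = len(fixes)
    report["n_out"] = len(out)
    report["n_removed"] = len(fixes) - len(out)
    return out, report


def remove_2d(fixes: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Keep only 3-D fixes; rows with missing fix dimensionality are dropped."""
    dim = fixes.get("fix_dim")
    if dim is None:
        raise ValueError("fixes table has no fix_dim column")
    missing = dim.isna()
    keep = (dim == "3D") & ~missing
    out = fixes[keep].reset_index(drop=True)
    return out, {
        "n_in": len(fixes),
        "n_out": len(out),
        "n_2d_removed": int((dim == "2D").sum()),
        "n_missing_dim": int(missing.sum()),
    }


def subsample_daily(
    fixes: pd.DataFrame,
    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS,
    per_window: int = 2,
    rule: str = "first",
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """At most ``per_window`` fixes per time window per animal-day.

    Window bounds are decimal hours, inclusive; fixes outside every window
    are dropped. ``rule`` is "first" (chronological, deterministic) or
    "random" (seeded draw within each window).
    """
    for (a, b) in windows:
        if not a < b:
            raise ValueError("window start must precede window end")
    for (a1, b1), (a2, b2) in zip(windows, windows[1:]):
        if b1 > a2:
            raise ValueError("windows must be non-overlapping and ordered")
    if rule not in ("first", "random"):
        raise ValueError("rule must be 'first' or 'random'")
    rng = np.random.default_rng(seed)
    ts = pd.to_datetime(fixes["timestamp"])
    hour = ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    win = np.full(len(fixes), -1)
    for w, (a, b) in enumerate(windows):
        win[np.asarray((hour >= a) & (hour <= b))] = w
    df = fixes.assign(_win=win, _date=ts.dt.date).sort_values(
        ["animal_id", "timestamp"], kind="mergesort"
    )
    df = df[df["_win"] >= 0]
    kept_idx = []
    for _, grp in df.groupby(["animal_id", "_date", "_win"], sort=True):
        if len(grp) <= per_window:
            kept_idx.extend(grp.index)
        elif rule == "first":
            kept_idx.extend(grp.index[:per_window])
        else:
            kept_idx.extend(
                sorted(rng.choice(grp.index.to_numpy(), per_window, replace=False))
            )
    out = (
        fixes.loc[sorted(kept_idx)]
        .sort_values(["animal_id", "timestamp"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out, {"n_in": len(fixes), "n_out": len(out), "n_removed": len(fixes) - len(out)}


def label_reproduction(
    fixes: pd.DataFrame,
    timelines: pd.DataFrame,
    wean_cap: int = 120,
    mortality_window: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Attach provisioning state and split into the two analysis datasets.

    dataset1 holds pre-parturition rows (``lamb=0``) and provisioning rows
    (``lamb=1`` with ``part`` = days since parturition, capped at
    ``wean_cap``). dataset2 holds post-mortality rows, only for females
    whose neonate died within ``mortality_window`` days of birth. Fixes of
    non-pregnant females, provisioning rows past the weaning cap, and
    post-mortality rows of late-loss females are excluded (with counts).
    """
    tl = timelines.set_index(["animal_id", "year"])
    report = {
        "n_in": len(fixes),
        "n_nonpregnant_excluded": 0,
        "n_post_wean_excluded": 0,
        "n_late_loss_excluded": 0,
        "n_no_timeline_excluded": 0,
    }
    d1_rows, d2_rows = [], []
    ts = pd.to_datetime(fixes["timestamp"])
    doy = ts.dt.dayofyear
    for i, row in fixes.iterrows():
        key = (row["animal_id"], int(row["year"]))
        if key not in tl.index:
            report["n_no_timeline_excluded"] += 1
            continue
        t = tl.loc[key]
        if not t["pregnant"]:
            report["n_nonpregnant_excluded"] += 1
            continue
        part = int(doy.loc[i]) - int(t["part_doy"])
        death = t["death_day"]
        rec = row.to_dict()
        if part < 0:
            rec.update(lamb=0, part=np.nan, state="pre")
            d1_rows.append(rec)
        elif pd.isna(death) or part < int(death):
            if part <= wean_cap:
                rec.update(lamb=1, part=float(part), state="pp")
                d1_rows.append(rec)
            else:
                report["n_post_wean_excluded"] += 1
        else:  # post-mortality
            if int(death) <= mortality_window:
                rec.update(lamb=0, part=float(part), state="ad")
                d2_rows.append(rec)
            else:
                report["n_late_loss_excluded"] += 1
    cols = list(fixes.columns) + ["lamb", "part", "state"]
    d1 = pd.DataFrame(d1_rows, columns=cols)
    d2 = pd.DataFrame(d2_rows, columns=cols)
    report["n_dataset1"] = len(d1)
    report["n_dataset2"] = len(d2)
    return d1, d2, report


def availability_radius(
    fixes: pd.DataFrame, factor: float = 2.58, ddof: int = 1
) -> float:
    """``factor`` x SD of within-animal consecutive step lengths (metres)."""
    steps = []
    for _, grp in fixes.sort_values(["animal_id", "timestamp"]).groupby("animal_id"):
        if len(grp) < 2:
            continue
        dx = np.diff(grp["x"].to_numpy())
        dy = np.diff(grp["y"].to_numpy())
        steps.append(np.hypot(dx, dy))
    if not steps:
        raise ValueError("need at least two fixes for one animal")
    steps = np.concatenate(steps)
    sd = float(np.std(steps, ddof=ddof if steps.size > ddof else 0))
    if sd == 0:
        raise ValueError("step lengths are degenerate (zero variance)")
    return factor * sd


def generate_available(
    used: pd.DataFrame,
    radius: float,
    landscape: Landscape,
    ratio: int = 10,
    seed: int | None = None,
    mode: str = "pooled",
) -> pd.DataFrame:
    """``ratio`` random available points for every used fix.

    ``mode="pooled"`` (default) draws points uniformly over the pooled
    availability domain — the union of discs of the given radius buffered
    around *all* used fixes, clipped to the landscape — so every stratum
    shares one availability distribution. ``mode="per_point"`` instead
    draws each stratum's points uniformly on its own disc (redrawn to stay
    inside the landscape). The output repeats the originating row's
    attributes and carries its index as ``stratum``; either way the row
    count is exactly ``ratio`` per used fix.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if mode not in ("pooled", "per_point"):
        raise ValueError("mode must be 'pooled' or 'per_point'")
    x0 = used["x"].to_numpy(dtype=float)
    y0 = used["y"].to_numpy(dtype=float)
    template = landscape.template
    if not template.contains(x0, y0).all():
        raise ValueError("used fix outside landscape extent")
    rng = np.random.default_rng(seed)
    n = len(used) * ratio
    px = np.empty(n)
    py = np.empty(n)
    if mode == "pooled":
        # rasterize the union of buffers at cell resolution, then sample
        # cells uniformly and jitter uniformly within each cell
        from scipy.spatial import cKDTree

        xs, ys = template.cell_centers()
        d, _ = cKDTree(np.column_stack([x0, y0])).query(
            np.column_stack([xs.ravel(), ys.ravel()])
        )
        inside = np.flatnonzero(d <= radius)
        cells = rng.choice(inside, size=n, replace=True)
        half = template.cell_size / 2.0
        px = xs.ravel()[cells] + rng.uniform(-half, half, n)
        py = ys.ravel()[cells] + rng.uniform(-half, half, n)
    else:
        cx = np.repeat(x0, ratio).copy()
        cy = np.repeat(y0, ratio).copy()
        need = np.ones(n, dtype=bool)
        while need.any():
            m = int(need.sum())
            r = radius * np.sqrt(rng.random(m))
            th = rng.uniform(0, 2 * np.pi, m)
            qx = cx[need] + r * np.cos(th)
            qy = cy[need] + r * np.sin(th)
            ok = np.asarray(template.contains(qx, qy))
            idx = np.flatnonzero(need)[ok]
            px[idx] = qx[ok]
            py[idx] = qy[ok]
            need[idx] = False
    out = used.loc[used.index.repeat(ratio)].reset_index(drop=True).copy()
    out["x"] = px
    out["y"] = py
    out["stratum"] = np.repeat(np.arange(len(used)), ratio)
    out["case"] = 0
    return out


def extract_and_standardize(
    points: pd.DataFrame,
    landscape: Landscape,
    covariates: list[str],
    scalers: dict[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]], dict]:
    """Sample covariates at each point's cell and z-standardise them.

    Scalers (mean, SD) default to the combined-row statistics; passing
    precomputed scalers (e.g. landscape-global ones) reuses them instead.
    Rows over nodata cells are dropped with a count; a zero-variance
    covariate is an error.
    """
    vals = landscape.sample(points["x"].to_numpy(), points["y"].to_numpy(), covariates)
    out = points.reset_index(drop=True).copy()
    for c in covariates:
        out[c] = vals[c]
    finite = np.ones(len(out), dtype=bool)
    for c in covariates:
        finite &= np.isfinite(out[c].to_numpy())
    n_dropped = int((~finite).sum())
    out = out[finite].reset_index(drop=True)
    fitted: dict[str, tuple[float, float]] = {}
    for c in covariates:
        if scalers is not None and c in scalers:
            mu, sd = scalers[c]
        else:
            v = out[c].to_numpy()
            mu, sd = float(v.mean()), float(v.std(ddof=0))
        if sd == 0:
            raise ValueError(f"covariate {c!r} has zero variance")
        out[c] = (out[c] - mu) / sd
        fitted[c] = (float(mu), float(sd))
    return out, fitted, {"n_in": len(points), "n_nodata_dropped": n_dropped, "n_out": len(out)}


def correlation_screen(
    table: pd.DataFrame, covariates: list[str], threshold: float = 0.7
) -> tuple[list[str], dict]:
    """Greedy collinearity screen: no retained pair with |Pearson r| >= threshold.

    Repeatedly find the worst offending pair and drop the member with the
    larger mean absolute correlation to all other retained covariates.
    """
    if len(covariates) < 2:
        raise ValueError("need at least two covariates to screen")
    retained = list(covariates)
    dropped: list[dict] = []
    while True:
        corr = table[retained].corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        a = np.abs(corr)
        worst = np.unravel_index(np.argmax(a), a.shape)
        if a[worst] < threshold:
            break
        i, j = worst
        mean_i = a[i].sum() / (len(retained) - 1)
        mean_j = a[j].sum() / (len(retained) - 1)
        drop = retained[i] if mean_i >= mean_j else retained[j]
        dropped.append(
            {
                "dropped": drop,
                "pair": (retained[i], retained[j]),
                "r": float(corr[i, j]),
            }
        )
        retained.remove(drop)
        if len(retained) < 2:
            break
    return retained, {"threshold": threshold, "dropped": dropped, "retained": retained}


def tradeoff_regressions(
    table: pd.DataFrame,
    risk_prone_vars: list[str],
    risk_averse_vars: list[str],
) -> pd.DataFrame:
    """OLS slope and R^2 for every (risk-prone, risk-averse) covariate pair.

    Quantifies how strongly nutritious covers trade off against safe terrain
    on the landscape (pairs with a zero-variance regressor are skipped).
    """
    rows = []
    for prone in risk_prone_vars:
        for averse in risk_averse_vars:
            x = table[averse].to_numpy(dtype=float)
            y = table[prone].to_numpy(dtype=float)
            if np.std(x) == 0:
                rows.append(
                    {"risk_prone": prone, "risk_averse": averse, "slope": np.nan,
                     "intercept": np.nan, "r_squared": np.nan, "note": "zero-variance regressor"}
                )
                continue
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            rows.append(
                {
                    "risk_prone": prone,
                    "risk_averse": averse,
                    "slope": float(fit.params[1]),
                    "intercept": float(fit.params[0]),
                    "r_squared": float(fit.rsquared),
                    "note": "",
                }
            )
    return pd.DataFrame(rows)


def prepare_datasets(
    fixes: pd.DataFrame,
    timelines: pd.DataFrame,
    landscape: Landscape,
    covariates: list[str],
    scheduled: int | dict[str, int],
    ratio: int = 10,
    min_rate: float = 0.90,
    wean_cap: int = 120,
    mortality_window: int = 30,
    subsample_rule: str = "first",
    availability_mode: str = "pooled",
    radius: float | None = None,
    scalers: dict[str, tuple[float, float]] | None = None,
    seed: int | None = None,
) -> dict:
    """Run the full screening pipeline: filters, labelling, availability,
    covariate extraction. Returns dataset1/dataset2 model tables, the
    availability radius, fitted scalers and a stage-by-stage report."""
    rng = np.random.default_rng(seed)
    f1, rep_rate = fix_rate_filter(fixes, scheduled, min_rate)
    f2, rep_2d = remove_2d(f1)
    f3, rep_sub = subsample_daily(f2, rule=subsample_rule, seed=int(rng.integers(2**31)))
    d1, d2, rep_label = label_reproduction(f3, timelines, wean_cap, mortality_window)
    if radius is None:
        nonempty = [d for d in (d1, d2) if len(d)]
        radius = availability_radius(pd.concat(nonempty, ignore_index=True))
    out = {}
    for name, used in (("dataset1", d1), ("dataset2", d2)):
        if len(used) == 0:
            out[name] = used.assign(case=1) if len(used) else used
            continue
        used = used.assign(case=1, stratum=np.arange(len(used)))
        avail = generate_available(
            used, radius, landscape, ratio=ratio,
            seed=int(rng.integers(2**31)), mode=availability_mode,
        )
        both = pd.concat([used, avail], ignore_index=True)
        table, fitted, rep_ext = extract_and_standardize(
            both, landscape, covariates, scalers=scalers
        )
        out[name] = table
        out[f"{name}_scalers"] = fitted
        out[f"{name}_extract_report"] = rep_ext
    out["radius"] = radius
    out["report"] = {
        "fix_rate": rep_rate,
        "remove_2d": rep_2d,
        "subsample": rep_sub,
        "label": rep_label,
        "ratio": ratio,
    }
    return out
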