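"""Trial exclusion and truncated-normal estimation of bias and variability.

The response dial saturates at 30 degrees, so raw response means are
biased near the cap.  Following the study's analysis, a normal
distribution truncated (above) at 31 degrees is fitted by maximum
likelihood to each participant's responses at each location for each
stimulus; the fitted mu minus the true location is the localisation
*bias*, the fitted sigma the localisation *variability*.  Per-location
values are then averaged across the five target locations to give each
participant's mean bias and mean variability per condition and phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

__all__ = [
    "TruncNormFit",
    "exclude_trials",
    "fit_truncated_normal",
    "summarize_conditions",
    "mean_summaries",
]

MIN_CELL_SIZE = 3


@dataclass(frozen=True)
class TruncNormFit:
    mu: float
    sigma: float
    converged: bool


def exclude_trials(
    trials: pd.DataFrame, threshold: float = 2.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop trials whose eye trace left fixation.

    A trial is excluded when the mean *or* the standard deviation of the
    eye position deviation exceeds ``threshold`` degrees.  Returns the
    filtered table and a per-participant exclusion report
    (n_trials, n_excluded, fraction_excluded).  Idempotent.
    """
    for col in ("eye_mean_dev", "eye_sd_dev", "participant_id"):
        if col not in trials.columns:
            raise ValueError(f"trials table lacks required column {col!r}")
    bad = (trials["eye_mean_dev"] > threshold) | (trials["eye_sd_dev"] > threshold)
    report = (
        trials.assign(_bad=bad)
        .groupby("participant_id")["_bad"]
        .agg(n_trials="size", n_excluded="sum")
        .reset_index()
    )
    report["fraction_excluded"] = report["n_excluded"] / report["n_trials"]
    return trials.loc[~bad].copy(), report


def _trunc_nll_grad(params: np.ndarray, x: np.ndarray, lower: float,
                    upper: float) -> tuple[float, np.ndarray]:
    """Negative log-likelihood of the truncated normal and its gradient.

    Parameterised by (mu, log sigma) so sigma stays positive.  The
    gradient terms use the standard hazard corrections phi/Phi at the
    truncation points.
    """
    mu, log_sigma = params
    sigma = np.exp(log_sigma)
    n = x.size
    z = (x - mu) / sigma
    zu = (upper - mu) / sigma
    zl = (lower - mu) / sigma
    mass = norm.cdf(zu) - (norm.cdf(zl) if np.isfinite(lower) else 0.0)
    if not mass > 0:
        return np.inf, np.array([0.0, 0.0])
    ll = np.sum(norm.logpdf(x, mu, sigma)) - n * np.log(mass)
    pu = norm.pdf(zu) if np.isfinite(upper) else 0.0
    pl = norm.pdf(zl) if np.isfinite(lower) else 0.0
    zu_pu = zu * pu if pu > 0 else 0.0
    zl_pl = zl * pl if pl > 0 else 0.0
    dl_dmu = np.sum(z) / sigma + n * (pu - pl) / (mass * sigma)
    dl_dsig = np.sum(z**2 - 1) / sigma + n * (zu_pu - zl_pl) / (mass * sigma)
    # chain rule for log sigma; negate for the minimiser
    return -ll, np.array([-dl_dmu, -dl_dsig * sigma])


def fit_truncated_normal(
    responses,
    truncation: float = 31.0,
    lower: float = -np.inf,
) -> TruncNormFit:
    """Maximum-likelihood normal fit with an upper truncation point.

    One-sided by default (responses are capped only on the eccentric
    side); pass ``lower`` for a two-sided fit.  Degenerate samples (zero
    spread) return ``converged=False``.  When the data sit far below the
    truncation point the fit coincides with the ordinary normal MLE.
    """
    x = np.asarray(responses, dtype=float)
    if x.size < MIN_CELL_SIZE:
        raise ValueError(f"need at least {MIN_CELL_SIZE} responses, got {x.size}")
    if np.any(x > truncation) or np.any(x < lower):
        raise ValueError("responses outside the truncation interval")

    m, s = float(x.mean()), float(x.std(ddof=0))
    if s == 0.0:
        return TruncNormFit(m, float("nan"), False)

    res = optimize.minimize(
        _trunc_nll_grad,
        x0=np.array([m, np.log(s)]),
        args=(x, lower, truncation),
        jac=True,
        method="L-BFGS-B",
        options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500},
    )
    if not res.success:
        # rare line-search failures near flat regions: polish derivative-free
        res = optimize.minimize(
            lambda q: _trunc_nll_grad(q, x, lower, truncation)[0],
            x0=res.x,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
    mu, log_sigma = res.x
    return TruncNormFit(float(mu), float(np.exp(log_sigma)), bool(res.success))


def summarize_conditions(
    trials: pd.DataFrame, truncation: float = 31.0
) -> pd.DataFrame:
    """Per participant x phase x condition x location bias and variability.

    Each cell's responses get a truncated-normal fit; ``bias`` is
    fitted_mu minus the location.  Cells with fewer than three trials or
    non-converged fits are kept with ``converged=False`` and missing
    estimates rather than silently dropped.  The ``stimulus`` column
    strips feedback suffixes (A2+VF1 -> A2) so trained and untrained
    phases can be compared on the same stimulus.
    """
    required = {"participant_id", "phase", "condition", "true_azimuth",
                "response_azimuth"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trials table lacks columns {sorted(missing)}")

    keys = ["participant_id", "phase", "condition", "true_azimuth"]
    rows = []
    for key, grp in trials.groupby(keys, sort=True):
        resp = grp["response_azimuth"].to_numpy()
        if resp.size < MIN_CELL_SIZE:
            fit = TruncNormFit(float("nan"), float("nan"), False)
        else:
            fit = fit_truncated_normal(resp, truncation=truncation)
        rec = dict(zip(keys, key))
        rec.update(
            location=rec.pop("true_azimuth"),
            fitted_mu=fit.mu if fit.converged else float("nan"),
            fitted_sigma=fit.sigma if fit.converged else float("nan"),
            n_trials=int(resp.size),
            converged=fit.converged,
        )
        rec["bias"] = rec["fitted_mu"] - rec["location"]
        if "feedback_group" in grp.columns:
            rec["feedback_group"] = grp["feedback_group"].iloc[0]
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["stimulus"] = out["condition"].str.split("+").str[0]
    return out


def mean_summaries(
    summaries: pd.DataFrame, locations=None, drop_zero_azimuth: bool = False
) -> pd.DataFrame:
    """Average bias and variability across target locations.

    Every participant x phase x condition group must cover the full
    location set (an error names any gap).  ``drop_zero_azimuth``
    excludes the 0 degree location, which coincides with fixation, for
    sensitivity analyses.
    """
    if locations is None:
        locations = sorted(summaries["location"].unique())
    locations = [loc for loc in locations if not (drop_zero_azimuth and loc == 0)]
    expected = set(locations)

    sub = summaries[summaries["location"].isin(expected)]
    keys = ["participant_id", "phase", "condition"]
    rows = []
    for key, grp in sub.groupby(keys, sort=True):
        got = set(grp["location"])
        if got != expected:
            raise ValueError(
                f"group {key} missing locations {sorted(expected - got)}")
        rec = dict(zip(keys, key))
        rec["mean_bias"] = float(grp["bias"].mean())
        rec["mean_variability"] = float(grp["fitted_sigma"].mean())
        rec["stimulus"] = grp["stimulus"].iloc[0]
        if "feedback_group" in grp.columns:
            rec["feedback_group"] = grp["feedback_group"].iloc[0]
        rows.append(rec)
    return pd.DataFrame(rows)
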