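"""Validation of the Shannon statistic against classical F_IS.

Paired (F_IS, ¹H_IS) estimates from the simulation sweep are filtered of
degenerate replicates, binned on F_IS at width 0.1 over [−1.05, +1.05) with
balanced subsampling (the same number of points drawn from every nonempty
bin, so the abundance of near-zero F_IS replicates does not dominate the
fit), then F_IS is regressed on ¹H_IS by ordinary least squares. Agreement
is summarized by slope, R², the slope's two-sided p-value, and the root
mean squared difference

    RMSE = sqrt( Σ (¹H_IS,i − F_IS,i)² / n ).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InvalidInputError
from .simulate import FLAG_OK

__all__ = [
    "RegressionSummary",
    "filter_pairs",
    "rmse",
    "bin_and_subsample",
    "regress",
    "assess_sweep",
]

BIN_WIDTH = 0.1
BIN_LO = -1.05
BIN_HI = 1.05


@dataclass(frozen=True)
class RegressionSummary:
    """OLS fit of F_IS on ¹H_IS plus the RMSE between the two."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    rmse: float
    n_points: int
    n_bins_used: int


def filter_pairs(pairs: pd.DataFrame, clamp: bool = True) -> pd.DataFrame:
    """Keep rows usable for assessment: unflagged, finite F_IS and ¹H_IS.

    With ``clamp`` (the default), ¹H_IS values above +1 — which arise
    through stochasticity, mostly in strongly inbred even-distribution
    scenarios — are treated as +1, the statistic's nominal ceiling.
    """
    out = pairs
    if "flag" in out.columns:
        out = out[out["flag"] == FLAG_OK]
    out = out[np.isfinite(out["fis"]) & np.isfinite(out["his"])]
    if clamp:
        out = out.assign(his=out["his"].clip(upper=1.0))
    return out


def rmse(pairs: pd.DataFrame) -> float:
    """Root mean squared difference between paired ¹H_IS and F_IS values."""
    if len(pairs) == 0:
        raise InvalidInputError("rmse needs at least one pair")
    diff = pairs["his"].to_numpy(float) - pairs["fis"].to_numpy(float)
    return float(np.sqrt(np.mean(diff**2)))


def bin_and_subsample(
    pairs: pd.DataFrame,
    rng: np.random.Generator,
    width: float = BIN_WIDTH,
    lo: float = BIN_LO,
    hi: float = BIN_HI,
) -> pd.DataFrame:
    """Balance the F_IS distribution by binning and equal subsampling.

    F_IS values are assigned to half-open bins [lo + k·width, lo + (k+1)·width);
    from each nonempty bin the size of the smallest nonempty bin is drawn
    without replacement. Rows outside [lo, hi) are ignored; empty bins are
    skipped (some scenario subsets cannot populate the extreme bins).
    """
    if width <= 0:
        raise InvalidInputError("bin width must be > 0")
    fis = pairs["fis"].to_numpy(float)
    in_range = (fis >= lo) & (fis < hi)
    idx = np.floor((fis[in_range] - lo) / width).astype(int)
    frame = pairs[in_range]
    if len(frame) == 0:
        raise InvalidInputError("no pairs fall inside the binning range")
    sizes = pd.Series(idx).value_counts()
    k_star = int(sizes.min())
    taken = []
    for b in sorted(sizes.index):
        members = np.flatnonzero(idx == b)
        chosen = rng.choice(members, size=k_star, replace=False)
        taken.append(frame.iloc[np.sort(chosen)])
    return pd.concat(taken, ignore_index=True)


def regress(pairs: pd.DataFrame) -> RegressionSummary:
    """OLS of F_IS (response) on ¹H_IS (predictor), with RMSE attached."""
    if len(pairs) < 3:
        raise InvalidInputError("regression needs at least 3 pairs")
    his = pairs["his"].to_numpy(float)
    fis = pairs["fis"].to_numpy(float)
    if np.var(his) == 0:
        raise InvalidInputError("predictor (¹H_IS) has zero variance")
    fit = sm.OLS(fis, sm.add_constant(his)).fit()
    n_bins = pairs["_bin"].nunique() if "_bin" in pairs.columns else 1
    return RegressionSummary(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        rmse=rmse(pairs),
        n_points=int(len(pairs)),
        n_bins_used=int(n_bins),
    )


def _assess_one(
    pairs: pd.DataFrame, rng: np.random.Generator, binned: bool, n_draws: int
) -> RegressionSummary:
    if not binned:
        return regress(pairs)
    # The balanced subsample is small when extreme bins are sparse, so a
    # single draw is noisy; averaging over draws estimates the same
    # quantity with far less subsampling variance.
    summaries = []
    for _ in range(n_draws):
        balanced = bin_and_subsample(pairs, rng)
        balanced = balanced.assign(
            _bin=np.floor((balanced["fis"].to_numpy(float) - BIN_LO) / BIN_WIDTH)
        )
        summaries.append(regress(balanced))
    if n_draws == 1:
        return summaries[0]
    return RegressionSummary(
        slope=float(np.mean([s.slope for s in summaries])),
        intercept=float(np.mean([s.intercept for s in summaries])),
        r_squared=float(np.mean([s.r_squared for s in summaries])),
        p_value=float(np.median([s.p_value for s in summaries])),
        rmse=float(np.mean([s.rmse for s in summaries])),
        n_points=summaries[-1].n_points,
        n_bins_used=summaries[-1].n_bins_used,
    )


def assess_sweep(
    pairs: pd.DataFrame,
    group_by: str = "all",
    rng: np.random.Generator | None = None,
    binned: bool = True,
    clamp: bool = True,
    n_draws: int = 1,
) -> dict[object, RegressionSummary]:
    """Filter, bin/balance and regress, overall or per scenario-axis group.

    ``group_by`` is ``"all"`` for a single combined summary, or a scenario
    column of the sweep output (``loci``, ``distribution``, ``generations``,
    ``pop_size``, ...). ``n_draws`` > 1 averages the binned summaries over
    that many independent balanced subsamples. Returns a mapping group
    value -> summary.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if n_draws < 1:
        raise InvalidInputError("n_draws must be >= 1")
    usable = filter_pairs(pairs, clamp=clamp)
    if group_by == "all":
        return {"all": _assess_one(usable, rng, binned, n_draws)}
    if group_by not in usable.columns:
        raise InvalidInputError(f"unknown grouping column {group_by!r}")
    out = {}
    for value, group in usable.groupby(group_by, sort=True):
        out[value] = _assess_one(group, rng, binned, n_draws)
    return out
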