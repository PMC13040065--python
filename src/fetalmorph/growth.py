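"""Fractional-polynomial normative growth standards.

Each image-derived phenotype (IDP) is modelled against gestational age
(GA, weeks) with a degree-2 fractional polynomial for the mean,

    mean(GA) = b0 + b1 * GA**p1 + b2 * GA**p2,

with powers drawn from the standard candidate set
{-2, -1, -0.5, 0, 0.5, 1, 2, 3} (power 0 means log GA; a repeated power p
uses GA**p and GA**p * log GA), and a log-linear model for the
GA-dependent standard deviation,

    SD(GA) = exp(c0 + c1 * GA).

The published total-brain-volume standard (cm³; GA 18–27 weeks),

    mean: 1.954510 + 0.018205 * GA³ − 0.178633 * GA²
    log SD: −0.702623 + 0.150265 * GA,

is shipped as :data:`TBV_REFERENCE_MODEL` and anchors the synthetic-data
generator.  Centiles and z-scores follow the Gaussian family:
value(GA, p) = mean(GA) + Phi^-1(p) * SD(GA).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

#: Standard degree-2 fractional-polynomial candidate powers.
FP_CANDIDATE_POWERS: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

#: GA domain (weeks) over which the growth standards are defined.
GA_DOMAIN: tuple[float, float] = (18.0, 27.0)

_HALF_NORMAL = float(np.sqrt(np.pi / 2.0))


class DomainError(ValueError):
    """Gestational age outside the model domain (no extrapolation)."""


def _fp_term(ga: np.ndarray, power: float) -> np.ndarray:
    if power == 0.0:
        return np.log(ga)
    return ga**power


def fp_design(ga: np.ndarray, powers: tuple[float, float]) -> np.ndarray:
    """Design matrix [1, GA^p1, GA^p2] (repeated power p → GA^p, GA^p·logGA)."""
    ga = np.asarray(ga, dtype=np.float64)
    p1, p2 = powers
    x1 = _fp_term(ga, p1)
    x2 = _fp_term(ga, p2) if p2 != p1 else _fp_term(ga, p1) * np.log(ga)
    return np.column_stack([np.ones_like(ga), x1, x2])


@dataclass
class FPGrowthModel:
    """Fractional-polynomial mean + log-linear SD growth standard."""

    powers: tuple[float, float]
    mean_coeffs: tuple[float, float, float]
    sd_coeffs: tuple[float, float]
    ga_domain: tuple[float, float] = GA_DOMAIN
    n_fitted: int = 0

    def _check_domain(self, ga: np.ndarray) -> np.ndarray:
        ga = np.asarray(ga, dtype=np.float64)
        lo, hi = self.ga_domain
        if np.any(ga < lo - 1e-9) or np.any(ga > hi + 1e-9):
            raise DomainError(
                f"gestational age outside model domain [{lo}, {hi}] weeks"
            )
        return ga

    def mean(self, ga) -> np.ndarray | float:
        scalar = np.ndim(ga) == 0
        ga = np.atleast_1d(self._check_domain(ga))
        out = fp_design(ga, self.powers) @ np.asarray(self.mean_coeffs)
        return float(out[0]) if scalar else out

    def sd(self, ga) -> np.ndarray | float:
        scalar = np.ndim(ga) == 0
        ga = np.atleast_1d(self._check_domain(ga))
        c0, c1 = self.sd_coeffs
        out = np.exp(c0 + c1 * ga)
        return float(out[0]) if scalar else out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "powers": list(self.powers),
                    "mean_coeffs": list(self.mean_coeffs),
                    "sd_coeffs": list(self.sd_coeffs),
                    "ga_domain": list(self.ga_domain),
                    "n_fitted": self.n_fitted,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FPGrowthModel":
        d = json.loads(Path(path).read_text())
        return cls(
            powers=tuple(d["powers"]),
            mean_coeffs=tuple(d["mean_coeffs"]),
            sd_coeffs=tuple(d["sd_coeffs"]),
            ga_domain=tuple(d["ga_domain"]),
            n_fitted=int(d.get("n_fitted", 0)),
        )


#: Published normative total-brain-volume standard (cm³, GA 18–27 weeks).
TBV_REFERENCE_MODEL = FPGrowthModel(
    powers=(2.0, 3.0),
    mean_coeffs=(1.954510, -0.178633, 0.018205),
    sd_coeffs=(-0.702623, 0.150265),
    n_fitted=4196,
)


def fit_fp_mean(
    ga,
    y,
    candidate_powers: tuple[float, ...] = FP_CANDIDATE_POWERS,
    weights=None,
    powers: tuple[float, float] | None = None,
) -> tuple[tuple[float, float], np.ndarray]:
    """Select the FP power pair minimising residual deviance; return (powers, coeffs).

    Coefficients are ordered (intercept, coeff of GA^p1, coeff of GA^p2)
    with p1 <= p2.  Passing *powers* skips selection and fits that pair
    (e.g. to refit a published parameterisation).
    """
    ga = np.asarray(ga, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if ga.size != y.size:
        raise ValueError("ga and y must have equal length")
    if ga.size < 10:
        raise ValueError(f"need at least 10 observations, got {ga.size}")
    if np.any(ga <= 0):
        raise ValueError("gestational ages must be positive")
    w = None if weights is None else np.asarray(weights, dtype=np.float64)
    pairs = (
        [tuple(sorted(powers))]
        if powers is not None
        else list(itertools.combinations_with_replacement(sorted(candidate_powers), 2))
    )
    best = None
    for p1, p2 in pairs:
        X = fp_design(ga, (p1, p2))
        if w is not None:
            sw = np.sqrt(w)
            Xw, yw = X * sw[:, None], y * sw
        else:
            Xw, yw = X, y
        coeffs, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        if rank < 3:
            continue
        rss = float(np.sum((yw - Xw @ coeffs) ** 2))
        if best is None or rss < best[0] - 1e-12 * max(best[0], 1.0):
            best = (rss, (p1, p2), coeffs)
    if best is None:
        raise np.linalg.LinAlgError(
            "all candidate power pairs were rank deficient on this GA grid"
        )
    return best[1], best[2]


def fit_log_sd(ga, values, kind: str = "residuals") -> tuple[float, float]:
    """Fit the log-linear SD model; return (intercept, slope).

    kind="residuals"
        *values* are residuals from a fitted mean model.  SD is estimated
        per GA bin as sqrt(pi/2) * mean |residual| (the half-normal mean
        correction, unbiased under Gaussian residuals), then log SD is
        regressed linearly on the bin-mean GA.
    kind="sd"
        *values* are standard deviations themselves; log(values) is
        regressed on GA directly.
    """
    ga = np.asarray(ga, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if ga.size != values.size:
        raise ValueError("ga and values must have equal length")
    if kind == "sd":
        if np.any(values <= 0):
            raise ValueError("SD values must be strictly positive")
        X = np.column_stack([np.ones_like(ga), ga])
        coeffs, *_ = np.linalg.lstsq(X, np.log(values), rcond=None)
        return float(coeffs[0]), float(coeffs[1])
    if kind != "residuals":
        raise ValueError(f"unknown kind {kind!r}")
    if np.allclose(values, 0.0):
        raise ValueError("all residuals are zero: SD model is degenerate")
    bins = np.round(ga).astype(int)
    ga_c, log_sd, n = [], [], []
    for b in np.unique(bins):
        sel = bins == b
        if sel.sum() < 2:
            continue
        sd_hat = _HALF_NORMAL * float(np.mean(np.abs(values[sel])))
        if sd_hat <= 0:
            continue
        ga_c.append(float(ga[sel].mean()))
        log_sd.append(np.log(sd_hat))
        n.append(int(sel.sum()))
    if len(ga_c) < 2:
        raise ValueError("need residuals spanning at least two GA bins")
    X = np.column_stack([np.ones(len(ga_c)), ga_c])
    sw = np.sqrt(np.asarray(n, dtype=np.float64))
    coeffs, *_ = np.linalg.lstsq(X * sw[:, None], np.asarray(log_sd) * sw, rcond=None)
    return float(coeffs[0]), float(coeffs[1])


def fit_growth_model(
    ga, y, candidate_powers: tuple[float, ...] = FP_CANDIDATE_POWERS,
    ga_domain: tuple[float, float] | None = None,
    powers: tuple[float, float] | None = None,
) -> FPGrowthModel:
    """Fit mean and SD in stages: OLS mean → log-SD → 1/SD² WLS mean → SD refit."""
    ga = np.asarray(ga, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    powers, coeffs = fit_fp_mean(ga, y, candidate_powers, powers=powers)
    resid = y - fp_design(ga, powers) @ coeffs
    if np.allclose(resid, 0.0):
        # noiseless data: SD model is flat at (numerical) zero; keep OLS mean
        sd_coeffs = (-np.inf, 0.0)
        return FPGrowthModel(
            powers=powers,
            mean_coeffs=tuple(float(c) for c in coeffs),
            sd_coeffs=sd_coeffs,
            ga_domain=ga_domain or (float(ga.min()), float(ga.max())),
            n_fitted=int(ga.size),
        )
    sd_coeffs = fit_log_sd(ga, resid)
    sd = np.exp(sd_coeffs[0] + sd_coeffs[1] * ga)
    powers, coeffs = fit_fp_mean(ga, y, weights=1.0 / sd**2, powers=powers)
    resid = y - fp_design(ga, powers) @ coeffs
    sd_coeffs = fit_log_sd(ga, resid)
    return FPGrowthModel(
        powers=powers,
        mean_coeffs=tuple(float(c) for c in coeffs),
        sd_coeffs=sd_coeffs,
        ga_domain=ga_domain or (float(ga.min()), float(ga.max())),
        n_fitted=int(ga.size),
    )


def predict_centile(model: FPGrowthModel, ga, p: float) -> np.ndarray:
    """Value of the p-th centile (p in (0,1)) at GA."""
    if not 0.0 < p < 1.0:
        raise ValueError("centile p must lie strictly in (0, 1)")
    return model.mean(ga) + stats.norm.ppf(p) * model.sd(ga)


def zscore(model: FPGrowthModel, ga, y) -> np.ndarray:
    """GA-standardised deviation (y − mean(GA)) / SD(GA)."""
    return (np.asarray(y, dtype=np.float64) - model.mean(ga)) / model.sd(ga)


def exclude_outliers(
    table: pd.DataFrame, idp: str, k: float = 4.0, ga_col: str = "ga_weeks"
) -> tuple[pd.DataFrame, int]:
    """Drop rows more than k SD from the GA-specific pooled mean.

    The GA-specific mean/SD are computed in integer-week bins over all
    sites pooled, in a single pass.  Bins with fewer than 3 rows are
    skipped with a warning (no exclusion there).
    """
    vals = table[idp].to_numpy(dtype=np.float64)
    bins = np.round(table[ga_col].to_numpy(dtype=np.float64)).astype(int)
    keep = np.ones(len(table), dtype=bool)
    for b in np.unique(bins):
        sel = bins == b
        if sel.sum() < 3:
            warnings.warn(
                f"GA bin {b} wk has {int(sel.sum())} rows; outlier filter skipped",
                stacklevel=2,
            )
            continue
        mu = vals[sel].mean()
        sd = vals[sel].std(ddof=1)
        if sd == 0:
            continue
        keep[sel] = np.abs(vals[sel] - mu) <= k * sd
    removed = int((~keep).sum())
    return table.loc[keep].reset_index(drop=True), removed


def empirical_vs_smoothed(
    table: pd.DataFrame,
    model: FPGrowthModel,
    idp: str,
    centiles: tuple[float, ...] = (3.0, 50.0, 97.0),
    ga_col: str = "ga_weeks",
    min_bin: int = 30,
) -> pd.DataFrame:
    """Per integer GA week, empirical vs model-smoothed centiles.

    Returns rows {ga_week, centile_p, smoothed_value, empirical_value,
    difference}; weeks with fewer than *min_bin* rows yield missing values.
    """
    vals = table[idp].to_numpy(dtype=np.float64)
    ga = table[ga_col].to_numpy(dtype=np.float64)
    bins = np.round(ga).astype(int)
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        ga_b = float(ga[sel].mean()) if sel.any() else float(b)
        ga_b = min(max(ga_b, model.ga_domain[0]), model.ga_domain[1])
        for p in centiles:
            smoothed = float(predict_centile(model, ga_b, p / 100.0))
            if sel.sum() >= min_bin:
                empirical = float(np.percentile(vals[sel], p))
                diff = empirical - smoothed
            else:
                empirical, diff = np.nan, np.nan
            rows.append(
                {
                    "ga_week": int(b),
                    "centile_p": p,
                    "smoothed_value": smoothed,
                    "empirical_value": empirical,
                    "difference": diff,
                }
            )
    return pd.DataFrame(rows)
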