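"""Cross-site comparability of growth standards.

Three complementary analyses decide whether multi-site data may be
pooled into a single normative standard:

- standardised site differences (SSD): each site's mean deviation from
  the pooled GA-adjusted mean, in pooled-SD units, within three 3-week
  gestational windows (18+0–20+6, 21+0–23+6, 24+0–26+6); |SSD| ≤ 0.5 is
  the prespecified adequacy bound;
- variance components: the percentage of total variance attributable to
  between-site differences under a Gaussian random-intercept model with
  sex and gestational age as fixed effects, estimated by restricted
  maximum likelihood (REML) profiled to a one-dimensional search over the
  site-to-residual variance ratio;
- leave-one-site-out sensitivity: the shift of the 3rd/50th/97th centiles
  when each site is removed and the standard refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import optimize

from .growth import (
    FPGrowthModel,
    fit_growth_model,
    fp_design,
    predict_centile,
    zscore,
)

#: The three gestational windows (weeks): [18+0, 20+6], [21+0, 23+6], [24+0, 26+6].
SSD_WINDOWS: tuple[tuple[float, float], ...] = (
    (18.0, 21.0),
    (21.0, 24.0),
    (24.0, 27.0),
)

WINDOW_LABELS = ("18+0-20+6", "21+0-23+6", "24+0-26+6")


@dataclass
class SSDReport:
    """Per site × window standardised differences with an adequacy summary."""

    entries: pd.DataFrame  # columns: site, idp, window, ssd, n_site
    idp: str = ""

    def summary(self, bound: float = 0.5) -> dict:
        n_total = len(self.entries)
        n_within = int((self.entries["ssd"].abs() <= bound).sum())
        return {
            "n_within": n_within,
            "n_total": n_total,
            "fraction_within": n_within / n_total if n_total else float("nan"),
        }


def compute_ssd(
    table: pd.DataFrame,
    model: FPGrowthModel,
    idp: str,
    ga_col: str = "ga_weeks",
    site_col: str = "site",
) -> SSDReport:
    """Standardised site differences, GA-adjusted via pooled-model z-scores.

    Each scan is converted to a z-score against the pooled growth
    standard; a site's SSD in a window is the mean z of its scans there
    (the pooled mean z is ≈ 0 by construction, so this is the site-minus-
    pool difference in pooled-SD units).
    """
    sites = table[site_col].unique()
    if len(sites) < 2:
        raise ValueError("SSD needs at least two sites")
    ga = table[ga_col].to_numpy(dtype=np.float64)
    z = zscore(model, ga, table[idp].to_numpy(dtype=np.float64))
    rows = []
    for (lo, hi), label in zip(SSD_WINDOWS, WINDOW_LABELS):
        in_win = (ga >= lo) & (ga < hi)
        for site in sites:
            sel = in_win & (table[site_col].to_numpy() == site)
            if not sel.any():
                continue  # site absent from this window → missing entry
            rows.append(
                {
                    "site": site,
                    "idp": idp,
                    "window": label,
                    "ssd": float(z[sel].mean()),
                    "n_site": int(sel.sum()),
                }
            )
    return SSDReport(entries=pd.DataFrame(rows), idp=idp)


def flag_ssd(report: SSDReport, bound: float = 0.5) -> dict:
    """Count entries with |SSD| within the adequacy bound."""
    return report.summary(bound)


@dataclass
class VarianceComponents:
    """Random-intercept decomposition for one IDP."""

    idp: str
    site_variance: float
    residual_variance: float
    fixed_effects: dict[str, float] = field(default_factory=dict)
    n_iter: int = 0

    @property
    def total_variance(self) -> float:
        return self.site_variance + self.residual_variance

    @property
    def site_variance_fraction(self) -> float:
        """Percentage of total variance due to between-site differences."""
        return 100.0 * self.site_variance / self.total_variance


def _reml_neg_loglik(
    log_lam: float, y: np.ndarray, X: np.ndarray, groups: np.ndarray
) -> float:
    """Negative REML log-likelihood profiled over beta and sigma²_resid.

    lam = sigma²_site / sigma²_resid.  With V = I + lam ZZᵀ block-diagonal
    by site, each site block of size m has V_g = I + lam 1 1ᵀ, whose
    inverse and determinant are closed-form (Sherman–Morrison).
    """
    lam = np.exp(log_lam)
    n, p = X.shape
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdetV = 0.0
    for g in np.unique(groups):
        sel = groups == g
        m = int(sel.sum())
        Xg, yg = X[sel], y[sel]
        c = lam / (1.0 + lam * m)
        sx = Xg.sum(axis=0)
        sy = yg.sum()
        XtVX += Xg.T @ Xg - c * np.outer(sx, sx)
        XtVy += Xg.T @ yg - c * sx * sy
        ytVy += yg @ yg - c * sy * sy
        logdetV += np.log1p(lam * m)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - beta @ XtVy  # (y-Xb)' V^-1 (y-Xb) at the GLS optimum
    dof = n - p
    if rss <= 0:
        return np.inf
    sigma2 = rss / dof
    sign, logdetXtVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf
    # REML criterion (up to constants)
    return 0.5 * (logdetV + dof * np.log(sigma2) + logdetXtVX + dof)


def variance_components(
    table: pd.DataFrame,
    idp: str,
    model: FPGrowthModel | None = None,
    ga_col: str = "ga_weeks",
    site_col: str = "site",
    sex_col: str = "sex",
) -> VarianceComponents:
    """Site variance fraction under a Gaussian random-intercept REML fit.

    Fixed effects: intercept, sex indicator and gestational age (entering
    with the same fractional-polynomial powers as the pooled mean model
    when one is supplied, linearly otherwise); random effect: site.
    """
    sites = table[site_col].to_numpy()
    uniq, counts = np.unique(sites, return_counts=True)
    if len(uniq) < 3:
        raise ValueError("variance components need at least 3 sites")
    if counts.min() < 10:
        raise ValueError("variance components need >= 10 scans per site")
    y = table[idp].to_numpy(dtype=np.float64)
    ga = table[ga_col].to_numpy(dtype=np.float64)
    sex = (table[sex_col].to_numpy() == "M").astype(np.float64)
    if model is not None:
        ga_terms = fp_design(ga, model.powers)[:, 1:]
    else:
        ga_terms = ga[:, None]
    X = np.column_stack([np.ones_like(y), sex, ga_terms])

    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=(-20.0, 10.0),
        args=(y, X, sites),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"REML optimisation did not converge: {res.message}")
    lam = float(np.exp(res.x))
    # recover sigma²_resid and beta at the optimum
    n, p = X.shape
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    for g in uniq:
        sel = sites == g
        m = int(sel.sum())
        Xg, yg = X[sel], y[sel]
        c = lam / (1.0 + lam * m)
        sx = Xg.sum(axis=0)
        sy = yg.sum()
        XtVX += Xg.T @ Xg - c * np.outer(sx, sx)
        XtVy += Xg.T @ yg - c * sx * sy
        ytVy += yg @ yg - c * sy * sy
    beta = np.linalg.solve(XtVX, XtVy)
    sigma2 = float((ytVy - beta @ XtVy) / (n - p))
    names = ["intercept", "sex_M"] + [f"ga_term{i}" for i in range(ga_terms.shape[1])]
    return VarianceComponents(
        idp=idp,
        site_variance=lam * sigma2,
        residual_variance=sigma2,
        fixed_effects=dict(zip(names, beta.tolist())),
        n_iter=int(res.nfev),
    )


def leave_one_site_out(
    table: pd.DataFrame,
    idp: str,
    centiles: tuple[float, ...] = (3.0, 50.0, 97.0),
    ga_col: str = "ga_weeks",
    site_col: str = "site",
) -> pd.DataFrame:
    """Max |centile shift| (pooled-SD units) from refitting without each site.

    Returns one row per left-out site with the maximum absolute shift of
    each requested centile over the pooled model's GA domain, standardised
    by the pooled SD at each GA.
    """
    sites = table[site_col].unique()
    if len(sites) < 3:
        warnings.warn(
            "fewer than 3 sites: leave-one-site-out is poorly determined",
            stacklevel=2,
        )
    ga = table[ga_col].to_numpy(dtype=np.float64)
    y = table[idp].to_numpy(dtype=np.float64)
    pooled = fit_growth_model(ga, y)
    grid = np.linspace(pooled.ga_domain[0], pooled.ga_domain[1], 91)
    pooled_sd = pooled.sd(grid)
    rows = []
    for site in sites:
        keep = table[site_col].to_numpy() != site
        refit = fit_growth_model(ga[keep], y[keep], ga_domain=pooled.ga_domain)
        row: dict = {"left_out_site": site, "n_remaining": int(keep.sum())}
        for p in centiles:
            shift = (
                predict_centile(refit, grid, p / 100.0)
                - predict_centile(pooled, grid, p / 100.0)
            ) / pooled_sd
            row[f"max_abs_shift_p{p:g}"] = float(np.max(np.abs(shift)))
        rows.append(row)
    return pd.DataFrame(rows)
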