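"""Simulated per-scan IDP tables with known generating structure.

Every IDP column is generated from the reference total-brain-volume
growth standard scaled by a per-IDP fraction:

    value = frac * [ mean(GA) + (site + sex + hemisphere offsets
                                 + noise) * SD(GA) ]

with SD(GA) the exponentiated log-linear SD curve.  Confound offsets are
expressed in GA-specific SD units, so a site offset of +0.5 produces a
site whose GA-adjusted mean sits 0.5 pooled SD above the rest — exactly
the quantity the standardised-site-difference analysis estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..growth import TBV_REFERENCE_MODEL, FPGrowthModel
from .cohort import DEFAULT_SITE_PROPORTIONS

#: The 28 IDP column names.
IDP_NAMES: tuple[str, ...] = (
    "TBV", "CoPV", "WMV", "DGMV", "CBV", "ThV", "LVV", "ChPV", "FHV",
    "BSV", "CSPV", "CoPSA", "SFD",
    "FLV", "TLV", "PLV", "OLV", "ILV",
    "FLD", "TLD", "PLD", "OLD", "ILD",
    "FLT", "TLT", "PLT", "OLT", "ILT",
)

#: Default per-IDP scaling of the reference TBV curve.  Volumes are
#: mid-gestation plausible fractions of total brain volume (lobe volumes
#: sum to the cortical-plate fraction); surface/depth/thickness columns
#: use small constants purely to give every column a smooth GA trend.
DEFAULT_IDP_FRACTIONS: dict[str, float] = {
    "TBV": 1.0, "CoPV": 0.20, "WMV": 0.55, "DGMV": 0.035, "CBV": 0.025,
    "ThV": 0.012, "LVV": 0.007, "ChPV": 0.005, "FHV": 0.005, "BSV": 0.010,
    "CSPV": 0.002, "CoPSA": 0.8, "SFD": 0.05,
    "FLV": 0.06, "TLV": 0.04, "PLV": 0.05, "OLV": 0.03, "ILV": 0.02,
    "FLD": 0.020, "TLD": 0.018, "PLD": 0.019, "OLD": 0.017, "ILD": 0.021,
    "FLT": 0.010, "TLT": 0.009, "PLT": 0.010, "OLT": 0.009, "ILT": 0.011,
}

#: Metadata columns present in every simulated table.
META_COLUMNS = ("fetus_id", "site", "sex", "ga_weeks", "hemisphere")


@dataclass
class ConfoundEffects:
    """Confound offsets in GA-specific SD units.

    ``site`` maps site name → offset; ``sex`` applies to males (females
    baseline); ``hemisphere`` applies to right (left baseline).
    """

    site: dict[str, float] = field(default_factory=dict)
    sex: float = 0.0
    hemisphere: float = 0.0


@dataclass
class SimTableConfig:
    """Configuration of a simulated IDP table."""

    n_fetuses: int
    seed: int = 0
    mean_curve: FPGrowthModel = field(default_factory=lambda: TBV_REFERENCE_MODEL)
    structure_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IDP_FRACTIONS)
    )
    confound_effects: ConfoundEffects = field(default_factory=ConfoundEffects)
    noise_scale: float = 1.0
    site_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_PROPORTIONS)
    )
    p_right_hemisphere: float = 0.6
    first_visit_range: tuple[float, float] = (18.0, 21.0)
    visit_interval: tuple[float, float] = (4.0, 6.0)
    n_visits: int | None = None

    def __post_init__(self) -> None:
        if self.n_fetuses < 0:
            raise ValueError("n_fetuses must be non-negative")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        offsets = list(self.confound_effects.site.values()) + [
            self.confound_effects.sex,
            self.confound_effects.hemisphere,
        ]
        if not np.all(np.isfinite(offsets)):
            raise ValueError("confound offsets must be finite")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTableConfig":
        d = json.loads(Path(path).read_text())
        if "confound_effects" in d:
            d["confound_effects"] = ConfoundEffects(**d["confound_effects"])
        return cls(**d)


def _visit_gas(cfg: SimTableConfig, rng: np.random.Generator) -> list[float]:
    lo, hi = cfg.mean_curve.ga_domain
    if cfg.n_visits is not None:
        return sorted(
            float(g) for g in rng.uniform(lo, hi - 1e-6, size=cfg.n_visits)
        )
    gas = [float(rng.uniform(*cfg.first_visit_range))]
    while True:
        nxt = gas[-1] + rng.uniform(*cfg.visit_interval)
        if nxt >= hi:
            break
        gas.append(float(nxt))
    return gas


def simulate_idp_table(cfg: SimTableConfig) -> pd.DataFrame:
    """Simulate one row per scan with the 28 IDP columns and metadata."""
    rng = np.random.default_rng(cfg.seed)
    sites = list(cfg.site_proportions) or ["site0"]
    probs = np.asarray([cfg.site_proportions.get(s, 1.0) for s in sites], dtype=float)
    probs = probs / probs.sum()

    rows: list[dict] = []
    for i in range(cfg.n_fetuses):
        site = str(rng.choice(sites, p=probs))
        sex = str(rng.choice(["F", "M"]))
        for ga in _visit_gas(cfg, rng):
            hemi = "right" if rng.uniform() < cfg.p_right_hemisphere else "left"
            rows.append(
                {
                    "fetus_id": f"F{i:05d}",
                    "site": site,
                    "sex": sex,
                    "ga_weeks": ga,
                    "hemisphere": hemi,
                }
            )
    table = pd.DataFrame(rows, columns=list(META_COLUMNS))
    if table.empty:
        return pd.DataFrame(columns=list(META_COLUMNS) + list(IDP_NAMES))

    ga = table["ga_weeks"].to_numpy()
    mean = cfg.mean_curve.mean(ga)
    sd = cfg.mean_curve.sd(ga)
    eff = cfg.confound_effects
    offset = np.array([eff.site.get(s, 0.0) for s in table["site"]])
    offset += np.where(table["sex"].to_numpy() == "M", eff.sex, 0.0)
    offset += np.where(table["hemisphere"].to_numpy() == "right", eff.hemisphere, 0.0)

    for idp in IDP_NAMES:
        frac = cfg.structure_fractions.get(idp, 0.0)
        noise = rng.standard_normal(len(table)) * cfg.noise_scale
        table[idp] = frac * (mean + (offset + noise) * sd)
    return table
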