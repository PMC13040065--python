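"""Synthetic study rosters and the inclusion/exclusion cascade.

The generator reproduces, at the fetus level, the published cohort flow:
enrolled fetuses are excluded for missing postnatal follow-up or severe
morbidity, then restricted to those with at least one 3D scan in the
18–27-week gestational window, then fetuses with low developmental-
assessment scores are removed.  Scan schedules follow the acquisition
protocol: a first visit at 14–18 weeks and subsequent visits every
5 ± 1 weeks until 42 weeks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Gestational window (weeks) of the growth standards: [18, 27).
SCAN_WINDOW: tuple[float, float] = (18.0, 27.0)

#: Published per-site contribution fractions of the final cohort.
DEFAULT_SITE_PROPORTIONS: dict[str, float] = {
    "Turin": 0.112,
    "Oxford": 0.114,
    "Pelotas": 0.118,
    "Nairobi": 0.142,
    "Muscat": 0.156,
    "Beijing": 0.171,
    "Nagpur": 0.187,
}

#: Published cohort-flow counts.
PRINTED_COHORT_COUNTS = dict(
    n_enrolled=4321,
    n_missing_followup=681,
    n_severe_morbidity=84,
    n_with_scan_in_window=2906,
    n_low_score_excluded=101,
)


class ConfigurationError(ValueError):
    """Cohort counts are mutually inconsistent."""


@dataclass
class CohortConfig:
    """Counts and proportions defining a synthetic cohort."""

    n_enrolled: int
    n_missing_followup: int
    n_severe_morbidity: int
    n_with_scan_in_window: int
    n_low_score_excluded: int
    site_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_PROPORTIONS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_enrolled,
            self.n_missing_followup,
            self.n_severe_morbidity,
            self.n_with_scan_in_window,
            self.n_low_score_excluded,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("all cohort counts must be non-negative")
        n_flagged = self.n_missing_followup + self.n_severe_morbidity
        if n_flagged > self.n_enrolled:
            raise ConfigurationError(
                "follow-up and morbidity exclusions exceed enrolment"
            )
        if self.n_with_scan_in_window > self.n_enrolled - n_flagged:
            raise ConfigurationError(
                "more in-window scanned fetuses than remain after exclusions"
            )
        if self.n_low_score_excluded > self.n_with_scan_in_window:
            raise ConfigurationError("low-score exclusions exceed scanned fetuses")
        total = sum(self.site_proportions.values())
        if self.site_proportions and abs(total - 1.0) > 1e-9:
            # printed proportions are rounded to 0.1%; renormalise
            self.site_proportions = {
                k: v / total for k, v in self.site_proportions.items()
            }

    @classmethod
    def printed(cls, seed: int = 0) -> "CohortConfig":
        """Configuration matching the published cohort-flow counts."""
        return cls(seed=seed, **PRINTED_COHORT_COUNTS)

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class FetusRecord:
    fetus_id: str
    site: str
    sex: str
    followup_missing: bool
    severe_morbidity: bool
    low_score: bool
    scan_gas: list[float]


@dataclass
class CohortRoster:
    records: list[FetusRecord]

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fetus_id": [r.fetus_id for r in self.records],
                "site": [r.site for r in self.records],
                "sex": [r.sex for r in self.records],
                "followup_missing": [r.followup_missing for r in self.records],
                "severe_morbidity": [r.severe_morbidity for r in self.records],
                "low_score": [r.low_score for r in self.records],
                "scan_gas": [
                    ";".join(f"{g:.2f}" for g in r.scan_gas) for r in self.records
                ],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortRoster":
        df = pd.read_csv(path, keep_default_na=False)
        records = [
            FetusRecord(
                fetus_id=str(row.fetus_id),
                site=str(row.site),
                sex=str(row.sex),
                followup_missing=bool(row.followup_missing),
                severe_morbidity=bool(row.severe_morbidity),
                low_score=bool(row.low_score),
                scan_gas=[float(g) for g in str(row.scan_gas).split(";") if g],
            )
            for row in df.itertuples()
        ]
        return cls(records)


def _protocol_schedule(rng: np.random.Generator) -> list[float]:
    """First visit GA ~ U[14,18]; subsequent visits at +5 ± 1 wk, to 42 wk."""
    gas = [float(rng.uniform(14.0, 18.0))]
    while True:
        nxt = gas[-1] + rng.uniform(4.0, 6.0)
        if nxt > 42.0:
            break
        gas.append(float(nxt))
    return gas


def _offwindow_schedule(rng: np.random.Generator) -> list[float]:
    """A schedule that misses the [18, 27)-week window (early scan, then a gap)."""
    gas = [float(rng.uniform(14.0, 17.0))]
    nxt = rng.uniform(27.0, 32.0)
    while nxt <= 42.0:
        gas.append(float(nxt))
        nxt += rng.uniform(4.0, 6.0)
    return gas


def build_roster(config: CohortConfig) -> CohortRoster:
    """Generate a roster of exactly ``config.n_enrolled`` fetuses.

    Exclusion flags are assigned to disjoint random subsets whose sizes
    match the configured counts exactly; deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_enrolled
    sites = list(config.site_proportions) or ["site0"]
    probs = np.array([config.site_proportions.get(s, 1.0) for s in sites])
    probs = probs / probs.sum()
    site_of = rng.choice(sites, size=n, p=probs)
    sex_of = rng.choice(["F", "M"], size=n)

    order = rng.permutation(n)
    n_fu, n_mb = config.n_missing_followup, config.n_severe_morbidity
    followup_idx = set(order[:n_fu].tolist())
    morbidity_idx = set(order[n_fu : n_fu + n_mb].tolist())
    survivors = order[n_fu + n_mb :]
    scanned_idx = set(survivors[: config.n_with_scan_in_window].tolist())
    low_idx = set(
        rng.permutation(sorted(scanned_idx))[: config.n_low_score_excluded].tolist()
    )

    records = []
    for i in range(n):
        in_window = i in scanned_idx
        if i in followup_idx or i in morbidity_idx:
            # excluded fetuses still followed the scan protocol
            gas = _protocol_schedule(rng)
        elif in_window:
            gas = _protocol_schedule(rng)
            if not any(SCAN_WINDOW[0] <= g < SCAN_WINDOW[1] for g in gas):
                # protocol jitter skipped the window; add a mid-window visit
                gas = sorted(gas + [float(rng.uniform(19.0, 26.0))])
        else:
            gas = _offwindow_schedule(rng)
        records.append(
            FetusRecord(
                fetus_id=f"F{i:05d}",
                site=str(site_of[i]),
                sex=str(sex_of[i]),
                followup_missing=i in followup_idx,
                severe_morbidity=i in morbidity_idx,
                low_score=i in low_idx,
                scan_gas=sorted(gas),
            )
        )
    return CohortRoster(records)


def apply_exclusion_cascade(
    roster: CohortRoster,
) -> tuple[CohortRoster, dict[str, int]]:
    """Apply the inclusion cascade in order and count survivors per stage.

    Stages: drop missing follow-up → drop severe morbidity → keep fetuses
    with ≥1 scan in [18, 27) weeks → drop low developmental scores.
    """
    stage_counts: dict[str, int] = {"enrolled": len(roster)}
    recs = [r for r in roster.records if not r.followup_missing]
    stage_counts["after_followup"] = len(recs)
    recs = [r for r in recs if not r.severe_morbidity]
    stage_counts["after_morbidity"] = len(recs)
    recs = [
        r
        for r in recs
        if any(SCAN_WINDOW[0] <= g < SCAN_WINDOW[1] for g in r.scan_gas)
    ]
    stage_counts["with_scan_in_window"] = len(recs)
    recs = [r for r in recs if not r.low_score]
    stage_counts["final"] = len(recs)
    return CohortRoster(recs), stage_counts
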