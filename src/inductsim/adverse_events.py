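"""Expected counts of treatment-related intrapartum/neonatal adverse events.

The trial reports overall *rates* of treatment-related adverse events
(several events can occur during a single labour), so expected counts
are rates applied to the whole induced cohort, not proportions of women.
The total uses the printed total-AE rate rather than the category sum --
the printed categories do not add up to the printed total -- and counts
round half-up to whole events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .errors import ConfigurationError

__all__ = ["AE_EVENTS", "AEProfile", "AEResult", "expected_ae_counts", "TRIAL_AE_RATES"]

#: fixed safety-event list, in the order reported
AE_EVENTS = (
    "total_ae",
    "tachysystole_no_fhr",
    "tachysystole_fhr",
    "pph",
    "meconium",
    "nicu_admission",
    "low_apgar",
    "uterine_rupture",
    "neonatal_acidosis",
)

#: treatment-related AE rates per arm (proportion of the cohort)
TRIAL_AE_RATES: dict[str, dict[str, float]] = {
    "DVI": {
        "total_ae": 0.026, "tachysystole_no_fhr": 0.006, "tachysystole_fhr": 0.012,
        "pph": 0.001, "meconium": 0.006, "nicu_admission": 0.001,
        "low_apgar": 0.000, "uterine_rupture": 0.000, "neonatal_acidosis": 0.000,
    },
    "MVI": {
        "total_ae": 0.100, "tachysystole_no_fhr": 0.019, "tachysystole_fhr": 0.060,
        "pph": 0.000, "meconium": 0.012, "nicu_admission": 0.006,
        "low_apgar": 0.001, "uterine_rupture": 0.001, "neonatal_acidosis": 0.001,
    },
}


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class AEProfile:
    """Per-event AE rates for both arms."""

    rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: TRIAL_AE_RATES)

    def __post_init__(self) -> None:
        for arm in ("DVI", "MVI"):
            if arm not in self.rates:
                raise ConfigurationError(f"AE rates missing arm {arm!r}")
            for event in AE_EVENTS:
                r = self.rates[arm].get(event)
                if r is None or not 0.0 <= r <= 1.0:
                    raise ConfigurationError(
                        f"AE rate for {arm}/{event} must lie in [0, 1], got {r!r}")


@dataclass
class AEResult:
    """Expected AE counts, fold ratios and per-woman excess."""

    table: pd.DataFrame            # index: event; columns: rate/count per arm, fold
    total_dvi: int
    total_mvi: int
    difference: int
    per_woman_excess: float        # (total_MVI - total_DVI) / n, 2 decimals
    fold_total_from_counts: float  # headline figure, 1 decimal
    fold_total_from_rates: float   # companion figure, 1 decimal

    def as_dict(self) -> dict:
        return {
            "total_counts": {"DVI": self.total_dvi, "MVI": self.total_mvi},
            "difference": self.difference,
            "per_woman_excess": self.per_woman_excess,
            "fold_total_from_counts": self.fold_total_from_counts,
            "fold_total_from_rates": self.fold_total_from_rates,
            "per_event": self.table.reset_index().to_dict(orient="records"),
        }


def expected_ae_counts(profile: AEProfile, n_cohort: int) -> AEResult:
    """Apply per-arm AE rates to the induced cohort.

    Per-event fold ratios are MVI:DVI rate ratios to one decimal
    (reported as NaN when the DVI rate is zero); the total-AE fold is
    reported both from rounded counts (headline) and from raw rates.
    """
    if n_cohort <= 0:
        raise ConfigurationError("n_cohort must be > 0")
    rows = []
    for event in AE_EVENTS:
        r_dvi = profile.rates["DVI"][event]
        r_mvi = profile.rates["MVI"][event]
        rows.append({
            "event": event,
            "rate_dvi": r_dvi,
            "rate_mvi": r_mvi,
            "count_dvi": _round_half_up(r_dvi * n_cohort),
            "count_mvi": _round_half_up(r_mvi * n_cohort),
            "fold_mvi_vs_dvi": round(r_mvi / r_dvi, 1) if r_dvi > 0 else float("nan"),
        })
    table = pd.DataFrame(rows).set_index("event")
    total_dvi = int(table.loc["total_ae", "count_dvi"])
    total_mvi = int(table.loc["total_ae", "count_mvi"])
    fold_counts = round(total_mvi / total_dvi, 1) if total_dvi > 0 else float("nan")
    r_tot_dvi = profile.rates["DVI"]["total_ae"]
    fold_rates = (round(profile.rates["MVI"]["total_ae"] / r_tot_dvi, 1)
                  if r_tot_dvi > 0 else float("nan"))
    return AEResult(
        table=table,
        total_dvi=total_dvi,
        total_mvi=total_mvi,
        difference=total_mvi - total_dvi,
        per_woman_excess=round((total_mvi - total_dvi) / n_cohort, 2),
        fold_total_from_counts=fold_counts,
        fold_total_from_rates=fold_rates,
    )
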