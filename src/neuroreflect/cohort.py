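"""Cohort-level event tallies and the shock-wave pressure calibration fit.

The event table mirrors the study design: per animal, four booleans —
drastic light-scattering change, EEG suppression, long-lasting
hypoxemia, heme-aa3 reduction — at one of four laser fluences. A
spreading-depolarization (SD) episode is operationalized as the
conjunction of the first two columns; hypoxemia and heme events are
tallied conditionally among SD-positive animals.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_COLUMNS",
    "load_reference_cohort",
    "tally_events",
    "TallySummary",
    "fit_pressure_calibration",
    "CalibrationFit",
]

EVENT_COLUMNS = ("scattering_change", "eeg_suppression",
                 "long_hypoxemia", "heme_reduction")

#: printed per-fluence averages of the shock-wave source characterization
PRESSURE_CALIBRATION = pd.DataFrame({
    "fluence_J_cm2": [0.75, 1.0, 1.25, 1.5],
    "peak_pressure_MPa": [63.0, 86.0, 104.0, 123.0],
    "impulse_Pa_s": [9.0, 14.0, 19.0, 23.0],
})


def load_reference_cohort() -> pd.DataFrame:
    """Load the packaged 24-animal event-table fixture."""
    ref = resources.files("neuroreflect.data").joinpath("reference_cohort_events.csv")
    with ref.open("r") as fh:
        df = pd.read_csv(fh)
    return df


@dataclass(frozen=True)
class TallySummary:
    n_total: int
    n_sd: int
    n_hypoxemia_given_sd: int
    n_heme_given_sd: int
    frac_hypoxemia_given_sd: float | None  # exact count ratio
    frac_heme_given_sd: float | None
    n_hypoxemia_without_sd: int = 0
    n_heme_without_sd: int = 0

    def percent(self, which: str) -> str:
        """One-decimal percent formatting of a conditional fraction."""
        frac = getattr(self, f"frac_{which}_given_sd")
        return "undefined" if frac is None else f"{100.0 * frac:.1f}%"


def tally_events(table: pd.DataFrame, filter_fluence: float | None = None) -> TallySummary:
    """Count SD-positive animals and conditional event occurrences.

    SD-positive means scattering_change AND eeg_suppression. Events in
    SD-negative animals (absent in the reference cohort but possible in
    new data) are reported separately, not folded into the conditionals.
    """
    df = table
    if filter_fluence is not None:
        df = df[np.isclose(df["fluence_J_cm2"].astype(float), filter_fluence)]
    n_total = int(len(df))
    if n_total == 0:
        return TallySummary(0, 0, 0, 0, None, None)
    b = {c: df[c].astype(bool) for c in EVENT_COLUMNS}
    sd = b["scattering_change"] & b["eeg_suppression"]
    n_sd = int(sd.sum())
    n_hyp = int((sd & b["long_hypoxemia"]).sum())
    n_heme = int((sd & b["heme_reduction"]).sum())
    return TallySummary(
        n_total=n_total,
        n_sd=n_sd,
        n_hypoxemia_given_sd=n_hyp,
        n_heme_given_sd=n_heme,
        frac_hypoxemia_given_sd=(n_hyp / n_sd) if n_sd else None,
        frac_heme_given_sd=(n_heme / n_sd) if n_sd else None,
        n_hypoxemia_without_sd=int((~sd & b["long_hypoxemia"]).sum()),
        n_heme_without_sd=int((~sd & b["heme_reduction"]).sum()),
    )


@dataclass(frozen=True)
class CalibrationFit:
    slope: float
    intercept: float
    r2: float


def fit_pressure_calibration(pairs: pd.DataFrame | None = None,
                             target: str = "pressure") -> CalibrationFit:
    """OLS line of peak pressure (MPa) or impulse (Pa s) versus fluence.

    ``pairs`` defaults to the packaged per-fluence averages; it needs
    columns ``fluence_J_cm2`` and the chosen target column.
    """
    if pairs is None:
        pairs = PRESSURE_CALIBRATION
    col = {"pressure": "peak_pressure_MPa", "impulse": "impulse_Pa_s"}.get(target)
    if col is None:
        raise ValueError("target must be 'pressure' or 'impulse'")
    x = pairs["fluence_J_cm2"].to_numpy(dtype=float)
    y = pairs[col].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("calibration fit needs >= 2 distinct fluences")
    X = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = slope * x + intercept
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(((y - pred) ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return CalibrationFit(float(slope), float(intercept), r2)
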