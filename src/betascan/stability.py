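"""Plasma-stability kinetics: first-order decay fits and stability classes.

Peptide degradation in plasma over a 0–96 h horizon is summarised by a
single-exponential model C(t) = C0·exp(−k·t), fitted log-linearly (robust
at the scale of HPLC peak-area time courses).  Reported metrics are the
half-life T1/2 = ln2/k and the percent remaining at 96 h,
C96 = 100·exp(−96·k).  When the decline over the horizon is within noise
(the decay rate is not significantly positive), no decay model is asserted:
``model_ok`` is False, k is reported as 0 and the empirical remaining
fraction carries the information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TimeCourse",
    "DecayFit",
    "StabilityThresholds",
    "fit_decay",
    "classify_stability",
    "PLASMA_TIME_GRID_H",
]

#: Sampling grid of the plasma-stability assay, hours.
PLASMA_TIME_GRID_H: tuple[float, ...] = (0, 1, 2, 3, 4, 5, 6, 12, 24, 48, 96)


@dataclass(frozen=True)
class TimeCourse:
    """Remaining-compound time course; concentrations as fraction of the
    initial value (raw peak areas are accepted and normalised to t0)."""

    compound_id: str
    times: tuple[float, ...]  # hours, strictly increasing from 0
    concentrations: tuple[float, ...]  # positive
    first_cleavage_site: str | None = None  # pass-through annotation

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if len(t) != len(c):
            raise ValueError("times and concentrations differ in length")
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start at 0 and be strictly increasing")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        object.__setattr__(self, "times", tuple(float(v) for v in t))
        object.__setattr__(self, "concentrations", tuple(float(v) for v in c))

    def normalized(self) -> np.ndarray:
        c = np.asarray(self.concentrations)
        return c / c[0]


@dataclass(frozen=True)
class DecayFit:
    compound_id: str
    k: float  # 1/h
    t_half: float  # h (= ln2/k; inf when k == 0)
    c96: float  # % remaining at 96 h under the fitted model
    model_ok: bool
    c96_observed: float  # % remaining at the last observed time point
    rising: bool = False  # concentrations increased systematically

    def __post_init__(self) -> None:
        if self.k > 0 and not math.isclose(self.t_half * self.k, math.log(2)):
            raise ValueError("t_half inconsistent with k")


def fit_decay(tc: TimeCourse, alpha: float = 0.05) -> DecayFit:
    """Log-linear least-squares fit of the first-order decay model.

    ln C = ln C0 − k·t is regressed on time; C0 is fitted, not pinned to
    the first point, which absorbs both the overall scale and t0 noise.
    Significance of the decline is a one-sided t test on the slope at
    level ``alpha``; a significantly *rising* series is flagged and no
    decay is asserted.
    """
    t = np.asarray(tc.times, dtype=float)
    c = tc.normalized()
    if len(t) < 4:
        raise ValueError("need >= 4 time points")
    fit = stats.linregress(t, np.log(c))
    k = -float(fit.slope)
    # one-sided p-values for decline / rise
    if fit.stderr and fit.stderr > 0:
        tstat = fit.slope / fit.stderr
        p_decline = float(stats.t.cdf(tstat, len(t) - 2))  # slope < 0
        p_rise = float(stats.t.sf(tstat, len(t) - 2))  # slope > 0
    else:  # perfectly collinear series
        p_decline = 0.0 if k > 0 else 1.0
        p_rise = 0.0 if k < 0 else 1.0
    c96_observed = 100.0 * float(c[-1])
    rising = k < 0 and p_rise < alpha
    decaying = k > 0 and p_decline < alpha
    if not decaying:
        return DecayFit(
            compound_id=tc.compound_id,
            k=0.0,
            t_half=math.inf,
            c96=100.0,
            model_ok=False,
            c96_observed=c96_observed,
            rising=rising,
        )
    return DecayFit(
        compound_id=tc.compound_id,
        k=k,
        t_half=math.log(2) / k,
        c96=100.0 * math.exp(-96.0 * k),
        model_ok=True,
        c96_observed=c96_observed,
    )


@dataclass(frozen=True)
class StabilityThresholds:
    c96_stable_pct: float = 90.0  # stable: > 90% left after 96 h
    t_half_labile_h: float = 6.0  # labile: half-life under 6 h


def classify_stability(
    fit: DecayFit, thresholds: StabilityThresholds = StabilityThresholds()
) -> str:
    """"stable" if C96 exceeds the stable threshold, else "labile" if the
    half-life is below the labile threshold, else "intermediate"."""
    c96 = fit.c96 if fit.model_ok else fit.c96_observed
    if c96 > thresholds.c96_stable_pct:
        return "stable"
    if fit.t_half < thresholds.t_half_labile_h:
        return "labile"
    return "intermediate"


def decay_table(fits: Sequence[DecayFit]):
    """Per-compound decay summary as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "compound_id": [f.compound_id for f in fits],
            "k_per_h": [f.k for f in fits],
            "t_half_h": [f.t_half for f in fits],
            "c96_pct": [f.c96 if f.model_ok else f.c96_observed for f in fits],
            "model_ok": [f.model_ok for f in fits],
            "class": [classify_stability(f) for f in fits],
        }
    )
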