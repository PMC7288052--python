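"""Binding-assay analytics: pIC50, fold changes, descriptor regression and
one-site competition-curve fitting.

IC50 values are stored in nM (the unit radioligand competition assays are
reported in) and converted to molar only inside the pIC50 transform,
pIC50 = −log10(IC50 [M]).  Censored records (">1000 nM") carry the bound as
their ic50 and are excluded from regressions by default; an ``at_bound``
policy treats the bound as the value for sensitivity analysis.

The descriptor–affinity relationship is an ordinary least-squares line
pIC50 = intercept + slope·RMSD with R² = 1 − SS_res/SS_tot.  Competition
curves follow the one-site model
response = bottom + (top − bottom) / (1 + 10^(log10 c − log10 IC50)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BindingRecord",
    "RegressionResult",
    "CompetitionCurve",
    "CompetitionFit",
    "FitError",
    "pic50",
    "fold_change",
    "fit_rmsd_affinity",
    "fit_competition",
]


class FitError(RuntimeError):
    """A model fit failed or is undefined for the given data."""


@dataclass(frozen=True)
class BindingRecord:
    """One IC50 ± S.E.M. determination for one compound at one receptor.

    ``censored`` marks lower-bound records ("IC50 greater than 1000 nM");
    the bound itself is stored in ``ic50``.
    """

    compound_id: str
    receptor: str  # "mu" or "delta"
    ic50: float  # nM
    sem: float | None = None  # nM
    censored: bool = False

    def __post_init__(self) -> None:
        if self.receptor not in ("mu", "delta"):
            raise ValueError(f"unknown receptor {self.receptor!r}")
        if not self.ic50 > 0:
            raise ValueError(f"ic50 must be positive, got {self.ic50}")


@dataclass(frozen=True)
class RegressionResult:
    slope: float  # pIC50 per Å
    intercept: float  # pIC50 at zero displacement
    r_squared: float
    n: int
    slope_stderr: float | None = None

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("regression needs n >= 3")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")

    def slope_ci95(self) -> tuple[float, float]:
        """95% confidence interval for the slope (t distribution, n−2 df)."""
        if self.slope_stderr is None:
            raise FitError("no slope standard error available")
        half = stats.t.ppf(0.975, self.n - 2) * self.slope_stderr
        return (self.slope - half, self.slope + half)


@dataclass(frozen=True)
class CompetitionCurve:
    """Displacement curve: ligand concentrations (M, increasing) vs the
    fraction of specific radioligand binding remaining."""

    compound_id: str
    concentrations: tuple[float, ...]  # M
    responses: tuple[float, ...]  # fraction of specific binding
    replicates: int = 1

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")
        if len(self.concentrations) != len(self.responses):
            raise ValueError("concentrations and responses differ in length")
        object.__setattr__(self, "concentrations", tuple(self.concentrations))
        object.__setattr__(self, "responses", tuple(self.responses))


@dataclass(frozen=True)
class CompetitionFit:
    compound_id: str
    ic50: float  # nM
    stderr: float | None  # nM
    top: float
    bottom: float
    monotonicity_warning: bool = False


def pic50(record: BindingRecord, censored_ok: bool = False) -> float:
    """pIC50 = −log10(IC50 in molar); nM input is converted internally."""
    if record.censored and not censored_ok:
        raise ValueError(
            f"{record.compound_id}: censored record has no defined pIC50 "
            "(pass censored_ok=True to use the bound)"
        )
    return -math.log10(record.ic50 * 1e-9)


def fold_change(a: BindingRecord, b: BindingRecord) -> float:
    """Affinity ratio a.ic50 / b.ic50 (>1 means a binds more weakly)."""
    if a.receptor != b.receptor:
        raise ValueError(f"receptor mismatch: {a.receptor} vs {b.receptor}")
    return a.ic50 / b.ic50


def fit_rmsd_affinity(
    points: Iterable[tuple[float, float]] | None = None,
    censor_policy: str = "exclude",
    *,
    records: Sequence[BindingRecord] | None = None,
    rmsds: dict[str, float] | None = None,
) -> RegressionResult:
    """OLS fit of pIC50 against the displacement RMSD.

    Accepts either pre-paired ``points`` of (rmsd Å, pIC50) or binding
    ``records`` plus a compound→rmsd map, in which case censored records
    are handled per ``censor_policy`` ("exclude" drops them, "at_bound"
    enters them at the reported bound).
    """
    if censor_policy not in ("exclude", "at_bound"):
        raise ValueError(f"unknown censor policy {censor_policy!r}")
    if points is None:
        if records is None or rmsds is None:
            raise ValueError("need either points or records+rmsds")
        points = []
        for rec in records:
            if rec.compound_id not in rmsds:
                continue
            if rec.censored and censor_policy == "exclude":
                continue
            points.append((rmsds[rec.compound_id], pic50(rec, censored_ok=True)))
    pts = np.asarray(list(points), dtype=float)
    if len(pts) < 3:
        raise FitError(f"need >= 3 usable points, got {len(pts)}")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise FitError("zero variance in rmsd values")
    if np.ptp(y) == 0:
        raise FitError("constant pIC50: R-squared undefined (SS_tot = 0)")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=max(0.0, 1.0 - ss_res / ss_tot),
        n=len(pts),
        slope_stderr=float(fit.stderr),
    )


def _one_site(log_c: np.ndarray, top: float, bottom: float, log_ic50: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (log_c - log_ic50))


def fit_competition(curve: CompetitionCurve) -> CompetitionFit:
    """Least-squares fit of the one-site competition model; IC50 in nM.

    The standard error of the IC50 comes from the covariance of log10 IC50
    by the delta method.  A grossly non-monotonic curve (Spearman rank
    correlation of response vs concentration > −0.5) is fitted anyway but
    flagged; a flat curve (span below 10% of the response range) raises.
    """
    log_c = np.log10(np.asarray(curve.concentrations, dtype=float))
    y = np.asarray(curve.responses, dtype=float)
    if len(y) < 5:
        raise FitError("need >= 5 concentration points")
    span = float(np.ptp(y))
    if span < 0.1 * max(1.0, float(np.max(np.abs(y)))):
        raise FitError(
            f"{curve.compound_id}: flat response (span {span:.3g}), "
            "no inflection to fit"
        )
    rho = stats.spearmanr(log_c, y).statistic
    warn = bool(rho > -0.5)
    # initial guesses: plateaus from the data ends, IC50 at half-drop
    half = (y.max() + y.min()) / 2.0
    log_ic50_0 = float(log_c[np.argmin(np.abs(y - half))])
    try:
        popt, pcov = optimize.curve_fit(
            _one_site,
            log_c,
            y,
            p0=[float(y.max()), float(y.min()), log_ic50_0],
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"{curve.compound_id}: one-site fit failed: {exc}") from None
    top, bottom, log_ic50 = popt
    ic50_nm = 10.0**log_ic50 * 1e9
    var_log = pcov[2, 2]
    stderr = (
        float(math.log(10.0) * ic50_nm * math.sqrt(var_log))
        if np.isfinite(var_log)
        else None
    )
    return CompetitionFit(
        compound_id=curve.compound_id,
        ic50=float(ic50_nm),
        stderr=stderr,
        top=float(top),
        bottom=float(bottom),
        monotonicity_warning=warn,
    )


def geometric_mean_ic50(values_nm: Sequence[float]) -> float:
    """Replicate IC50s are averaged on the log scale (log-normal convention)."""
    vals = np.asarray(values_nm, dtype=float)
    if np.any(vals <= 0):
        raise ValueError("IC50 values must be positive")
    return float(np.exp(np.mean(np.log(vals))))
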