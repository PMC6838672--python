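"""Dilution-series calibration: sensitivity, LOD and LOQ.

The detection and quantification limits of an SRM assay are estimated
from a spike-in dilution series measured in replicates. A straight line
``response = b * amount + a`` is fitted to all replicates combined (the
slope ``b`` is the sensitivity), a separate line is fitted per replicate,
and the spread of the per-replicate intercepts gives ``S_a``, the
standard deviation of the intercept. Then

    LOD = 3 * S_a / b        LOQ = 10 * S_a / b

so LOQ/LOD = 10/3 identically. Spike amounts below the current LOD carry
no calibration information beyond the noise floor; all but the highest
such level are excluded and the fit repeated until stable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: Default spike-in levels, in fmol: 10 amol to 100 fmol over 7 steps.
DEFAULT_LEVELS = (0.01, 0.1, 1.0, 5.0, 10.0, 50.0, 100.0)


class CalibrationError(ValueError):
    pass


def _c4(n: int) -> float:
    """Unbiasing constant for the sample standard deviation of n draws."""
    return math.sqrt(2.0 / (n - 1)) * math.gamma(n / 2) / math.gamma((n - 1) / 2)


@dataclass
class DilutionSeries:
    """A spike-in dilution series for one peptide.

    ``data`` is tidy with columns amount_fmol, replicate, response.
    """

    peptide: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"amount_fmol", "replicate", "response"}
        missing = required - set(self.data.columns)
        if missing:
            raise CalibrationError(f"dilution table lacks {sorted(missing)}")
        levels = np.sort(self.data["amount_fmol"].unique())
        if len(levels) < 4:
            raise CalibrationError("need >= 4 dilution levels")
        if self.data.groupby("amount_fmol")["replicate"].nunique().min() < 2:
            raise CalibrationError("need >= 2 replicates per level")
        self.levels = levels

    @property
    def n_replicates(self) -> int:
        return int(self.data["replicate"].nunique())


@dataclass(frozen=True)
class CalibrationResults:
    """Fitted calibration line with derived detection limits.

    Attributes
    ----------
    slope : sensitivity b (response per fmol) of the combined fit.
    intercept : intercept of the combined fit.
    replicate_intercepts : per-replicate intercept estimates.
    sa : standard deviation of the intercept (S_a).
    lod, loq : limits of detection and quantification (fmol).
    excluded_levels : spike amounts dropped as sub-LOD.
    valid : False when the slope is non-positive.
    """

    peptide: str
    slope: float
    intercept: float
    replicate_intercepts: tuple[float, ...]
    sa: float
    lod: float
    loq: float
    excluded_levels: frozenset[float]
    valid: bool
    n_points: int
    sa_method: str

    def summary(self) -> str:
        lines = [
            f"Calibration fit: {self.peptide}",
            "=" * 44,
            f"{'sensitivity b':<28}{self.slope:>14.6g}",
            f"{'intercept (combined)':<28}{self.intercept:>14.6g}",
            f"{'S_a (' + self.sa_method + ')':<28}{self.sa:>14.6g}",
            f"{'LOD = 3 S_a / b (fmol)':<28}{self.lod:>14.6g}",
            f"{'LOQ = 10 S_a / b (fmol)':<28}{self.loq:>14.6g}",
            f"{'points used':<28}{self.n_points:>14d}",
            f"{'excluded levels':<28}"
            f"{';'.join(f'{x:g}' for x in sorted(self.excluded_levels)) or '-':>14}",
            f"{'valid':<28}{str(self.valid):>14}",
        ]
        return "\n".join(lines)


class CalibrationModel:
    """Linear calibration model for one peptide's dilution series.

    Parameters
    ----------
    series : DilutionSeries
        Spike amounts, replicates and responses.
    sa_method : {"replicate_sd", "stderr"}
        How S_a is estimated: the standard deviation across per-replicate
        intercepts (default; bias-corrected for the small replicate
        count), or the standard error of the combined-fit intercept.
    bias_correct : bool
        Divide the replicate-intercept SD by the c4 unbiasing constant so
        its expectation equals the true intercept spread (matters for
        triplicates, where the raw SD underestimates by ~11%).
    """

    def __init__(self, series: DilutionSeries, sa_method: str = "replicate_sd",
                 bias_correct: bool = True):
        if sa_method not in ("replicate_sd", "stderr"):
            raise CalibrationError(f"unknown sa_method {sa_method!r}")
        self.series = series
        self.sa_method = sa_method
        self.bias_correct = bias_correct

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, peptide: str = "peptide",
                       **kwargs) -> "CalibrationModel":
        return cls(DilutionSeries(peptide, df), **kwargs)

    def _fit_once(self, data: pd.DataFrame) -> dict:
        x = data["amount_fmol"].to_numpy(dtype=float)
        y = data["response"].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise CalibrationError("degenerate series: zero variance in amounts")
        X = sm.add_constant(x)
        combined = sm.OLS(y, X).fit()
        intercept, slope = combined.params

        rep_intercepts = []
        for _, rep_df in data.groupby("replicate", sort=True):
            xr = rep_df["amount_fmol"].to_numpy(dtype=float)
            yr = rep_df["response"].to_numpy(dtype=float)
            sl, ic = np.polyfit(xr, yr, 1)
            rep_intercepts.append(float(ic))

        if self.sa_method == "replicate_sd":
            sa = float(np.std(rep_intercepts, ddof=1))
            if self.bias_correct and len(rep_intercepts) > 1:
                sa /= _c4(len(rep_intercepts))
        else:
            sa = float(combined.bse[0])
        return {
            "slope": float(slope), "intercept": float(intercept),
            "rep_intercepts": tuple(rep_intercepts), "sa": sa,
            "n_points": len(data),
        }

    def fit(self) -> CalibrationResults:
        """Fit with iterative exclusion of sub-LOD levels.

        Among levels below the current LOD estimate, only the highest is
        retained; the fit is repeated until the excluded set is stable
        (bounded by the number of levels).
        """
        data = self.series.data
        excluded: frozenset[float] = frozenset()
        fit = self._fit_once(data)
        for _ in range(len(self.series.levels)):
            lod = 3.0 * fit["sa"] / fit["slope"] if fit["slope"] > 0 else np.inf
            below = sorted(l for l in self.series.levels if l < lod)
            new_excluded = frozenset(below[:-1])  # keep the highest sub-LOD level
            if new_excluded == excluded:
                break
            kept = data[~data["amount_fmol"].isin(new_excluded)]
            if kept["amount_fmol"].nunique() < 3:
                logger.warning("%s: exclusion would leave <3 levels; stopping",
                               self.series.peptide)
                break
            excluded = new_excluded
            fit = self._fit_once(kept)

        slope = fit["slope"]
        valid = slope > 0
        if not valid:
            logger.warning("%s: non-positive slope, invalid fit",
                           self.series.peptide)
        lod = 3.0 * fit["sa"] / slope if valid else float("nan")
        loq = 10.0 * fit["sa"] / slope if valid else float("nan")
        return CalibrationResults(
            peptide=self.series.peptide,
            slope=slope,
            intercept=fit["intercept"],
            replicate_intercepts=fit["rep_intercepts"],
            sa=fit["sa"],
            lod=lod,
            loq=loq,
            excluded_levels=excluded,
            valid=valid,
            n_points=fit["n_points"],
            sa_method=self.sa_method,
        )


def fit_calibration(series: DilutionSeries, **kwargs) -> CalibrationResults:
    """Functional convenience wrapper around :class:`CalibrationModel`."""
    return CalibrationModel(series, **kwargs).fit()
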