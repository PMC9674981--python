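"""Population statistics for imaged filaments (AFM/EM-style morphometry).

Filament lengths sampled at fixation time points are summarised by
log-normal fits; the geometric mean versus time gives the longitudinal
assembly rate, and the width-versus-mean relation gives the empirical
sigma-length law used throughout the scattering analysis.  Diameter
records give the time course of radial compaction.

Conventions: the log-normal scale parameter sigma is the *population*
(1/n) standard deviation of log10(length), matching the maximum-likelihood
estimator and the convention of :mod:`vimflow.population`; lengths given
in nm are converted to ULF units before fitting so the sigma-length law is
expressed in ULFs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .optics import UlfGeometry, length_to_ulf

__all__ = [
    "fit_lognormal",
    "fit_growth_rate",
    "fit_sigma_relation",
    "summarize_diameters",
    "DiameterSummary",
]


def fit_lognormal(lengths, base: float = 10.0) -> tuple[float, float]:
    """Maximum-likelihood log-normal fit: (geometric mean, sigma).

    ``sigma`` is the population SD of log_base(length); the geometric mean
    is base-independent.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size < 5:
        raise ValueError("need at least 5 samples")
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    logs = np.log(lengths) / np.log(base)
    geo_mean = float(base ** np.mean(logs))
    sigma = float(np.std(logs))  # population (1/n) convention == MLE
    return geo_mean, sigma


def _to_ulf(table: pd.DataFrame, unit: str, geometry: UlfGeometry) -> pd.DataFrame:
    if unit == "ulf":
        return table
    if unit == "nm":
        out = table.copy()
        out["length"] = length_to_ulf(out["length"].to_numpy(), geometry)
        return out
    raise ValueError(f"unknown length unit {unit!r} (use 'ulf' or 'nm')")


def fit_growth_rate(
    table: pd.DataFrame,
    unit: str = "ulf",
    geometry: UlfGeometry | None = None,
) -> tuple[float, float]:
    """Longitudinal assembly rate from length samples over time.

    ``table`` needs columns ``time_s`` and ``length``.  Per time point the
    geometric mean length is computed and an ordinary least-squares line
    of geometric mean versus time (minutes) is fitted.

    Returns (rate in ULFs/min, intercept in ULFs).
    """
    geometry = geometry or UlfGeometry()
    table = _to_ulf(table, unit, geometry)
    groups = table.groupby("time_s")["length"]
    if groups.ngroups < 3:
        raise ValueError("need at least 3 time points")
    t_min = groups.mean().index.to_numpy(dtype=float) / 60.0
    geo = np.array([np.exp(np.mean(np.log(g.to_numpy()))) for _, g in groups])
    res = linregress(t_min, geo)
    return float(res.slope), float(res.intercept)


def fit_sigma_relation(l_fil, sigma) -> tuple[float, float]:
    """OLS fit of distribution width versus geometric mean length.

    Returns (slope per ULF, intercept), the coefficients of
    sigma = slope*l_fil + intercept.
    """
    l_fil = np.asarray(l_fil, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if l_fil.size < 3:
        raise ValueError("need at least 3 (l_fil, sigma) pairs")
    res = linregress(l_fil, sigma)
    return float(res.slope), float(res.intercept)


@dataclass
class DiameterSummary:
    """Per-time-point diameter statistics and the compaction excess."""

    table: pd.DataFrame  # columns time_s, mean_nm, sd_nm, n
    peak_time_s: float
    peak_mean_nm: float
    final_mean_nm: float
    percent_excess: float  # peak mean over final mean, in percent

    def to_dict(self) -> dict:
        return {
            "per_time": self.table.to_dict(orient="records"),
            "peak_time_s": self.peak_time_s,
            "peak_mean_nm": self.peak_mean_nm,
            "final_mean_nm": self.final_mean_nm,
            "percent_excess": self.percent_excess,
        }


def summarize_diameters(records: pd.DataFrame) -> DiameterSummary:
    """Mean/SD/n of filament diameters per time point.

    ``records`` needs columns ``time_s`` and ``diameter_nm``.  Also
    reports the peak-time mean and its percent excess over the mean at
    the last time point (the radial-compaction signature).  SD uses the
    population convention (a single record gives SD 0).
    """
    required = {"time_s", "diameter_nm"}
    if not required.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    grouped = records.groupby("time_s")["diameter_nm"]
    table = pd.DataFrame({
        "time_s": grouped.mean().index.to_numpy(dtype=float),
        "mean_nm": grouped.mean().to_numpy(),
        "sd_nm": grouped.apply(lambda g: float(np.std(g.to_numpy()))).to_numpy(),
        "n": grouped.size().to_numpy(),
    }).sort_values("time_s", ignore_index=True)
    i_peak = int(table["mean_nm"].idxmax())
    peak_mean = float(table.loc[i_peak, "mean_nm"])
    final_mean = float(table["mean_nm"].iloc[-1])
    return DiameterSummary(
        table=table,
        peak_time_s=float(table.loc[i_peak, "time_s"]),
        peak_mean_nm=peak_mean,
        final_mean_nm=final_mean,
        percent_excess=100.0 * (peak_mean / final_mean - 1.0),
    )
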