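"""qPCR quantification and inhibition QC.

Target DNA in a noninvasive extract is quantified against a serial-dilution
standard curve of a single-copy (monomorphic microsatellite) assay:
Cq = intercept + slope * log10(concentration), with amplification
efficiency E = 10^(-1/slope) - 1 (slope -3.3219 for perfect doubling).
Inhibition is screened by spiking each extract with a fixed amount of
standard and comparing its mean Cq to spike-only positive controls
(dCq = sample mean - control mean); clean extracts sit at or below the
control, co-purified inhibitors delay amplification and push dCq
positive. Failed spiked wells are imputed the total cycle count so that a
completely inhibited sample scores maximally inhibited rather than
missing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

#: Standard-curve slope of a perfectly doubling reaction: -1/log10(2).
PERFECT_DOUBLING_SLOPE = -1.0 / math.log10(2.0)


class StandardCurveModel(BaseEstimator):
    """Least-squares standard curve of Cq on log10(concentration).

    Attributes (after ``fit``)
    --------------------------
    slope_, intercept_ : float
        Regression coefficients (slope in Cq per decade, negative for a
        valid curve).
    r_squared_ : float
    efficiency_ : float
        10^(-1/slope) - 1; 1.0 is perfect per-cycle doubling. A warning
        is emitted outside [0.9, 1.1].
    """

    def __init__(self, efficiency_warn_band: tuple[float, float] = (0.9, 1.1)):
        self.efficiency_warn_band = efficiency_warn_band

    def fit(self, concentrations, cq) -> "StandardCurveModel":
        conc = np.asarray(concentrations, dtype=float)
        cq = np.asarray(cq, dtype=float)
        keep = ~np.isnan(cq)
        conc, cq = conc[keep], cq[keep]
        if (conc <= 0).any():
            raise ValueError("standard concentrations must be positive")
        if len(np.unique(conc)) < 3:
            raise ValueError("need standards at >= 3 distinct concentrations")
        x = np.log10(conc)
        if np.ptp(x) == 0:
            raise ValueError("zero variance in log10 concentration")
        res = stats.linregress(x, cq)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        if self.slope_ >= 0:
            warnings.warn("standard-curve slope is non-negative; curve invalid")
            self.efficiency_ = float("nan")
        else:
            self.efficiency_ = float(10 ** (-1 / self.slope_) - 1)
            lo, hi = self.efficiency_warn_band
            if not lo <= self.efficiency_ <= hi:
                warnings.warn(
                    f"amplification efficiency {self.efficiency_:.3f} outside "
                    f"[{lo}, {hi}]"
                )
        return self

    def predict_cq(self, concentrations) -> np.ndarray:
        conc = np.asarray(concentrations, dtype=float)
        return self.intercept_ + self.slope_ * np.log10(conc)

    def estimate_concentration(
        self, cq_values, dilution_factor: float = 1.0
    ) -> tuple[float, float]:
        """Back-transform replicate Cqs to a concentration.

        Replicate Cqs are averaged on the Cq scale before back-transform;
        the reported spread is the SD of the per-replicate back-transformed
        concentrations. Returns (NaN, NaN) when every replicate failed.
        """
        cq = np.asarray(cq_values, dtype=float)
        cq = cq[~np.isnan(cq)]
        if cq.size == 0:
            return float("nan"), float("nan")
        conc = 10 ** ((cq.mean() - self.intercept_) / self.slope_) * dilution_factor
        per_rep = 10 ** ((cq - self.intercept_) / self.slope_) * dilution_factor
        sd = float(per_rep.std(ddof=1)) if cq.size > 1 else 0.0
        return float(conc), sd


def fit_standard_curve(concentrations, cq) -> StandardCurveModel:
    """Functional wrapper over :class:`StandardCurveModel`."""
    return StandardCurveModel().fit(concentrations, cq)


def estimate_concentration(
    curve: StandardCurveModel, cq_values, dilution_factor: float = 1.0
) -> tuple[float, float]:
    return curve.estimate_concentration(cq_values, dilution_factor)


@dataclass
class InhibitionResult:
    """Per-sample dCq inhibition screen against spike-only controls."""

    sample: str
    sample_mean_cq: float
    control_mean_cq: float
    delta_cq: float
    inhibited: bool
    n_imputed: int


def delta_cq(
    sample_cqs,
    control_cqs,
    failure_cq: float = 45.0,
    threshold: float = 0.0,
    sample: str = "",
) -> InhibitionResult:
    """dCq = mean(spiked sample Cq) - mean(control Cq).

    Failed wells (NaN) on the sample side are imputed `failure_cq`, the
    total possible cycle count, so total amplification failure reads as
    maximal inhibition. The sample is flagged inhibited when dCq exceeds
    `threshold`.
    """
    s = np.asarray(sample_cqs, dtype=float)
    c = np.asarray(control_cqs, dtype=float)
    if s.size == 0 or c.size == 0:
        raise ValueError("need >= 1 replicate for both sample and control")
    n_imputed = int(np.isnan(s).sum())
    s = np.where(np.isnan(s), failure_cq, s)
    c = c[~np.isnan(c)]
    if c.size == 0:
        raise ValueError("all control wells failed")
    d = float(s.mean() - c.mean())
    return InhibitionResult(
        sample=sample,
        sample_mean_cq=float(s.mean()),
        control_mean_cq=float(c.mean()),
        delta_cq=d,
        inhibited=d > threshold,
        n_imputed=n_imputed,
    )


def inhibition_test(
    run: pd.DataFrame, failure_cq: float = 45.0, threshold: float = 0.0
) -> pd.DataFrame:
    """dCq for every spiked sample on a plate against its positive controls."""
    controls = run.loc[run["role"] == "positive_control", "cq"].to_numpy()
    rows = []
    for sample, grp in run[run["role"] == "spiked_sample"].groupby("sample", sort=True):
        r = delta_cq(grp["cq"].to_numpy(), controls, failure_cq, threshold, sample)
        rows.append(
            {
                "sample": r.sample,
                "sample_mean_cq": r.sample_mean_cq,
                "control_mean_cq": r.control_mean_cq,
                "delta_cq": r.delta_cq,
                "inhibited": r.inhibited,
                "n_imputed": r.n_imputed,
            }
        )
    return pd.DataFrame(rows)


def quantify_run(
    run: pd.DataFrame, dilution_factors: dict[str, float] | None = None
) -> tuple[StandardCurveModel, pd.DataFrame]:
    """Fit the plate's standards and quantify every unknown sample."""
    std = run[run["role"] == "standard"]
    curve = fit_standard_curve(std["concentration"], std["cq"])
    dil = dilution_factors or {}
    rows = []
    for sample, grp in run[run["role"] == "unknown"].groupby("sample", sort=True):
        conc, sd = curve.estimate_concentration(
            grp["cq"].to_numpy(), dil.get(sample, 1.0)
        )
        rows.append({"sample": sample, "concentration": conc, "concentration_sd": sd,
                     "failed": np.isnan(conc)})
    return curve, pd.DataFrame(rows)


def target_to_total(target_pg_ul, total_ng_ul) -> float:
    """Target (qPCR, pg/ul) over total (fluorometric, ng/ul) as a percent."""
    t = float(target_pg_ul)
    tot = float(total_ng_ul)
    if np.isnan(tot) or np.isnan(t):
        return float("nan")
    if tot <= 0:
        raise ValueError("total DNA concentration must be positive")
    if t < 0:
        raise ValueError("target concentration must be non-negative")
    return t / (tot * 1000.0) * 100.0
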