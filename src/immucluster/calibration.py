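"""Simulation-calibrated conversion of immune enrichment scores to immune
read percentages.

Tumour and immune expression profiles are mixed convexly at known immune
fractions on the transcript-fraction scale, the mixtures are scored with an
immune signature (any GMT scored by the in-package ssGSEA), and a monotone
non-linear model mapping score to fraction is fitted. The fitted model
converts cohort scores into an interpretable "immune read percentage".

The default model is a 3-parameter logistic ``f = L / (1 + exp(-s (x - m)))``
with the plateau clamped to at most 1; a monotone isotonic step fit (with
linear interpolation between breakpoints) is the fallback whenever the
score-fraction relationship is not credibly logistic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import spearmanr
from sklearn.isotonic import IsotonicRegression

TPM_TOTAL = 1e6

__all__ = ["CalibrationModel", "mix_profiles", "fit_calibration",
           "predict_fraction", "FractionPrediction", "TPM_TOTAL"]


def _logistic3(x: np.ndarray, plateau: float, slope: float, midpoint: float) -> np.ndarray:
    return plateau / (1.0 + np.exp(-slope * (x - midpoint)))


@dataclass
class CalibrationModel:
    """Fitted monotone score -> immune-fraction map.

    ``params`` holds ``(plateau, slope, midpoint)`` for the logistic kind, or
    the isotonic breakpoints ``{"x": [...], "y": [...]}``. Predictions are
    clamped to [0, 1] and are non-decreasing in the score.
    """

    kind: str
    params: dict
    fit_fractions: np.ndarray
    fit_scores: np.ndarray
    residual_sd: float

    def to_json(self) -> str:
        payload = {
            "kind": self.kind,
            "params": self.params,
            "fit_fractions": np.asarray(self.fit_fractions).tolist(),
            "fit_scores": np.asarray(self.fit_scores).tolist(),
            "residual_sd": self.residual_sd,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        d = json.loads(text)
        return cls(kind=d["kind"], params=d["params"],
                   fit_fractions=np.asarray(d["fit_fractions"], dtype=float),
                   fit_scores=np.asarray(d["fit_scores"], dtype=float),
                   residual_sd=float(d["residual_sd"]))


@dataclass
class FractionPrediction:
    """Predicted immune read percentages with extrapolation flags."""

    percent: np.ndarray
    extrapolated: np.ndarray


def mix_profiles(
    tumor: pd.Series,
    immune: Sequence[pd.Series],
    fraction: float,
) -> pd.Series:
    """Convex tumour-immune mixture at immune fraction ``fraction``.

    All profiles are renormalized to transcript fractions (summing to the
    TPM constant) before mixing; immune profiles enter with equal weights.
    ``fraction = 0`` returns exactly the (renormalized) tumour profile and
    ``fraction = 1`` exactly the equal-weight immune average.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if not immune:
        raise ValueError("at least one immune profile is required")
    for prof in immune:
        if not prof.index.equals(tumor.index):
            raise ValueError("immune profile gene universe differs from tumour")

    def _norm(v: pd.Series) -> np.ndarray:
        x = v.to_numpy(dtype=float)
        total = x.sum()
        if total <= 0:
            raise ValueError("profile has non-positive total abundance")
        return x / total * TPM_TOTAL

    imm = np.mean([_norm(p) for p in immune], axis=0)
    mixed = (1.0 - fraction) * _norm(tumor) + fraction * imm
    mixed = mixed / mixed.sum() * TPM_TOTAL
    return pd.Series(mixed, index=tumor.index, name=f"mix_f{fraction:g}")


def fit_calibration(
    fractions: Sequence[float],
    scores: Sequence[float],
    kind: str = "logistic3",
) -> CalibrationModel:
    """Fit a monotone calibration of immune fraction on enrichment score.

    Requires at least five distinct fractions including 0. The logistic fit
    is least squares with the plateau bounded by 1; when the score-fraction
    relationship is not monotone to a reasonable tolerance (Spearman
    correlation below 0.9), a warning is issued and the isotonic fit is
    used instead. Constant scores are unidentifiable and raise.
    """
    f = np.asarray(fractions, dtype=float)
    s = np.asarray(scores, dtype=float)
    if f.shape != s.shape or f.ndim != 1:
        raise ValueError("fractions and scores must be 1-d and equally long")
    if not np.all(np.isfinite(s)) or not np.all(np.isfinite(f)):
        raise ValueError("fractions and scores must be finite")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    if len(np.unique(f)) < 5 or 0.0 not in f:
        raise ValueError("need >= 5 distinct training fractions including 0")
    if np.ptp(s) == 0.0:
        raise ValueError("constant scores: calibration is unidentifiable")
    if kind not in ("logistic3", "isotonic"):
        raise ValueError(f"unknown calibration kind {kind!r}")

    if kind == "logistic3":
        rho = spearmanr(s, f).statistic
        if not np.isfinite(rho) or rho < 0.9:
            warnings.warn(
                "score-fraction relationship is not credibly monotone "
                f"(Spearman rho = {rho:.3f}); falling back to isotonic fit"
            )
            kind = "isotonic"

    if kind == "logistic3":
        span = np.ptp(s)
        fmax = float(f.max())
        p0 = (min(1.0, max(fmax * 1.05, 1e-3)), 4.0 / span, float(np.median(s)))
        bounds = ([1e-9, 1e-9, s.min() - 10 * span],
                  [1.0, np.inf, s.max() + 10 * span])
        try:
            popt, _ = curve_fit(_logistic3, s, f, p0=p0, bounds=bounds,
                                maxfev=20000)
        except RuntimeError:
            warnings.warn("logistic fit did not converge; falling back to isotonic")
            kind = "isotonic"
        else:
            resid = f - _logistic3(s, *popt)
            sd = float(np.sqrt(np.sum(resid**2) / max(len(f) - 3, 1)))
            return CalibrationModel(
                kind="logistic3",
                params={"plateau": float(popt[0]), "slope": float(popt[1]),
                        "midpoint": float(popt[2])},
                fit_fractions=f, fit_scores=s, residual_sd=sd,
            )

    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(s, f)
    bx = np.asarray(iso.X_thresholds_, dtype=float)
    by = np.asarray(iso.y_thresholds_, dtype=float)
    resid = f - np.interp(s, bx, by)
    sd = float(np.sqrt(np.sum(resid**2) / max(len(f) - len(bx), 1)))
    return CalibrationModel(
        kind="isotonic",
        params={"x": bx.tolist(), "y": by.tolist()},
        fit_fractions=f, fit_scores=s, residual_sd=sd,
    )


def predict_fraction(
    model: CalibrationModel,
    score: float | Sequence[float],
    extrapolation_tol: float = 0.1,
) -> FractionPrediction:
    """Convert enrichment scores to immune read percentages in [0, 100].

    Scores beyond ``extrapolation_tol`` times the training score range
    outside the training interval are still converted (and clamped) but
    flagged as extrapolated rather than refused.
    """
    s = np.atleast_1d(np.asarray(score, dtype=float))
    if model.kind == "logistic3":
        p = model.params
        frac = _logistic3(s, p["plateau"], p["slope"], p["midpoint"])
    elif model.kind == "isotonic":
        frac = np.interp(s, np.asarray(model.params["x"], dtype=float),
                         np.asarray(model.params["y"], dtype=float))
    else:  # pragma: no cover - guarded at fit time
        raise ValueError(f"unknown calibration kind {model.kind!r}")
    frac = np.clip(frac, 0.0, 1.0)
    smin, smax = float(np.min(model.fit_scores)), float(np.max(model.fit_scores))
    margin = extrapolation_tol * (smax - smin)
    flagged = (s < smin - margin) | (s > smax + margin)
    return FractionPrediction(percent=100.0 * frac, extrapolated=flagged)
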