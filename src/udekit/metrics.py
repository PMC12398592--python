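"""Assessment metrics for fitted hybrid models.

Prediction quality on the glycolysis study is scored against the noise-free
truth on the extrapolation window t in (1.5, 5] with the normalised mean
absolute error, NMAE = mean_{s,k} |y_s(t_k) - ybar_s(t_k)| / y_s(t_k); a
fit counts as successful when the test NMAE is strictly below 0.15.  Model
comparison across parameter counts uses AIC = 2 NLL + 2 n_theta and
BIC = n_theta log(n_d) + 2 NLL.  Without independent test data, models
within the 95% likelihood confidence region around the best fit are
identified by the chi-squared criterion NLL <= NLL_best + 1/2 q_chi2(0.95).
Qualitative recovery of the oscillator is judged from detected peaks:
sustained oscillation, amplitude and frequency compared to the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "nmae",
    "classify_success",
    "aic",
    "bic",
    "chi2_region",
    "oscillation_metrics",
    "parameter_error",
    "sigma_recovery",
    "EvaluationReport",
    "evaluate_glycolysis_fit",
    "SUCCESS_THRESHOLD",
]

SUCCESS_THRESHOLD = 0.15
OSC_MIN_PEAKS = 3
OSC_DAMPING_CUTOFF = 0.5
OSC_CLOSENESS = 0.2


def nmae(predictions, truth, reduction: str = "mean") -> float:
    """Normalised absolute error of predictions against the noise-free truth.

    Arrays are aligned elementwise (any shape); ``reduction`` is ``"mean"``
    (default) or ``"sum"`` (the raw double-sum variant).  The truth must be
    bounded away from zero.
    """
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predictions.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    if np.any(truth == 0.0):
        raise ValueError("truth contains zeros; normalised error undefined")
    e = np.abs(predictions - truth) / np.abs(truth)
    if reduction == "mean":
        return float(np.mean(e))
    if reduction == "sum":
        return float(np.sum(e))
    raise ValueError("reduction must be 'mean' or 'sum'")


def classify_success(test_nmae: float, threshold: float = SUCCESS_THRESHOLD) -> bool:
    """Strictly-below-threshold success rule for the test error."""
    return bool(test_nmae < threshold)


def aic(nll: float, n_params: int) -> float:
    """Akaike information criterion from a negative log-likelihood."""
    if n_params < 0:
        raise ValueError("parameter count must be non-negative")
    return 2.0 * float(nll) + 2.0 * n_params


def bic(nll: float, n_params: int, n_data: int) -> float:
    """Bayesian information criterion from a negative log-likelihood."""
    if n_params < 0:
        raise ValueError("parameter count must be non-negative")
    if n_data <= 0:
        raise ValueError("BIC requires a positive number of data points")
    return n_params * float(np.log(n_data)) + 2.0 * float(nll)


def chi2_region(nlls, alpha: float = 0.95, df: int = 1) -> np.ndarray:
    """Membership in the likelihood confidence region around the best fit.

    ``nlls`` may be raw values or objects with a ``selection_nll``
    attribute.  A fit is in-region iff its NLL is within half the
    chi-squared quantile of the best NLL.
    """
    values = np.array(
        [getattr(v, "selection_nll", v) for v in nlls], dtype=float
    )
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("need at least one successful fit")
    threshold = finite.min() + 0.5 * chi2_dist.ppf(alpha, df)
    return values <= threshold


def oscillation_metrics(times, values, truth_values=None) -> dict:
    """Peak-based oscillation summary of one signal on a dense grid.

    Sustained means at least three detected peaks whose last peak-to-trough
    amplitude is at least half the first; amplitude is the mean
    peak-to-trough excursion and frequency the reciprocal median inter-peak
    interval.  With ``truth_values`` given, each property also gets a
    ``*_close`` flag (within 20% of the truth; sustained must match
    exactly).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 8:
        raise ValueError("grid too short for oscillation analysis")
    span = values.max() - values.min()
    prominence = 0.01 * span if span > 0 else None
    peaks, _ = find_peaks(values, prominence=prominence)
    troughs, _ = find_peaks(-values, prominence=prominence)
    out = {"sustained": False, "amplitude": 0.0, "frequency": 0.0, "n_peaks": len(peaks)}
    if len(peaks) >= 2 and len(troughs) >= 1:
        amplitudes = []
        for p in peaks:
            later = troughs[troughs > p]
            earlier = troughs[troughs < p]
            t_idx = later[0] if later.size else earlier[-1]
            amplitudes.append(values[p] - values[t_idx])
        amplitudes = np.asarray(amplitudes)
        out["amplitude"] = float(np.mean(amplitudes))
        out["frequency"] = float(1.0 / np.median(np.diff(times[peaks])))
        out["sustained"] = bool(
            len(peaks) >= OSC_MIN_PEAKS
            and amplitudes[-1] >= OSC_DAMPING_CUTOFF * amplitudes[0]
        )
    if truth_values is not None:
        ref = oscillation_metrics(times, truth_values)
        out["sustained_close"] = out["sustained"] == ref["sustained"]
        for key in ("amplitude", "frequency"):
            out[f"{key}_close"] = bool(
                ref[key] > 0
                and abs(out[key] - ref[key]) <= OSC_CLOSENESS * ref[key]
            )
    return out


def parameter_error(estimated, true) -> float:
    """Sum of squared log-space errors of matched positive parameters."""
    estimated = np.asarray(estimated, dtype=float)
    true = np.asarray(true, dtype=float)
    if estimated.shape != true.shape:
        raise ValueError("parameter vectors must align")
    if np.any(estimated <= 0) or np.any(true <= 0):
        raise ValueError("parameters must be strictly positive for log errors")
    return float(np.sum((np.log(estimated) - np.log(true)) ** 2))


def sigma_recovery(estimated_sigma, true_sigma) -> np.ndarray:
    """Relative deviation |sigma_hat - sigma| / sigma per observable."""
    est = np.atleast_1d(np.asarray(estimated_sigma, dtype=float))
    tru = np.atleast_1d(np.asarray(true_sigma, dtype=float))
    if np.any(tru <= 0):
        raise ValueError("true noise levels must be positive")
    return np.abs(est - tru) / tru


@dataclass
class EvaluationReport:
    """Full assessment of one fitted model against the synthetic truth."""

    test_nmae: float
    success: bool
    aic: float
    bic: float
    oscillation: dict
    parameter_error: Optional[float] = None
    sigma_relative_error: Optional[np.ndarray] = None
    in_chi2_region: Optional[bool] = None

    def to_dict(self) -> dict:
        d = {
            "test_nmae": float(self.test_nmae),
            "success": bool(self.success),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "oscillation": {
                name: {
                    k: (bool(v) if isinstance(v, (bool, np.bool_)) else float(v))
                    for k, v in m.items()
                }
                for name, m in self.oscillation.items()
            },
        }
        if self.parameter_error is not None:
            d["parameter_error"] = float(self.parameter_error)
        if self.sigma_relative_error is not None:
            d["sigma_relative_error"] = [float(v) for v in self.sigma_relative_error]
        if self.in_chi2_region is not None:
            d["in_chi2_region"] = bool(self.in_chi2_region)
        return d


def evaluate_glycolysis_fit(
    problem,
    fit,
    truth,
    n_data: int,
    true_parameters: dict | None = None,
    threshold: float = SUCCESS_THRESHOLD,
) -> EvaluationReport:
    """Score a fitted glycolysis model on the extrapolation window.

    ``truth`` is the generator's noise-free reference; predictions come from
    simulating the fitted model over the full horizon.  ``n_data`` is the
    number of records behind ``fit.selection_nll`` (for the information
    criteria).
    """
    from .simulate import integrate

    pv = fit.best_params
    ann = pv.ann.values if pv.ann is not None else None
    traj = integrate(
        problem,
        truth.test_times,
        theta=pv.mechanistic.values,
        ann_params=ann,
    )
    if not traj.success:
        preds = np.full_like(truth.test_values, np.inf)
    else:
        preds = problem.observe(
            truth.test_times, traj.states, pv.mechanistic.values, ann
        )
    finite = np.all(np.isfinite(preds))
    test = nmae(preds, truth.test_values) if finite else np.inf
    n_params = pv.n_total
    osc = {}
    for j, name in enumerate(truth.observable_names):
        col = preds[:, j] if finite else np.zeros(truth.test_times.size)
        osc[name] = oscillation_metrics(
            truth.test_times, col, truth.test_values[:, j]
        )
    perr = None
    if true_parameters is not None:
        names = pv.mechanistic.names
        perr = parameter_error(
            pv.mechanistic.values,
            np.array([true_parameters[n] for n in names]),
        )
    serr = None
    if np.any(truth.sigma > 0):
        serr = sigma_recovery(pv.noise.sigma, truth.sigma)
    return EvaluationReport(
        test_nmae=test,
        success=classify_success(test, threshold),
        aic=aic(fit.selection_nll, n_params),
        bic=bic(fit.selection_nll, n_params, n_data),
        oscillation=osc,
        parameter_error=perr,
        sigma_relative_error=serr,
    )
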