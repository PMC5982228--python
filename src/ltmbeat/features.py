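"""Feature signals that enhance QRS complexes for threshold detection.

Digital-filtering family:

* ``pt`` — the classic single-lead chain: narrow band-pass (5-15 Hz),
  five-point derivative, squaring, and a 150 ms moving-window integrator.
  When several leads are available the least-noisy one is selected.
* ``rms`` — per-sample sum of squared derivative-filtered leads,
  ``y[n] = sum_l xf^2[n, l]``.
* ``prod`` — the combinational product ``y[n, i] = xf[n, i] * prod_{j != i}
  xf[n, j]``; note that as written every lead receives the full product over
  all leads, so the per-lead columns coincide.

Matrix family:

* ``pca`` — square of the projection of the leads onto the dominant
  eigenvector of the lead covariance matrix.
* ``ica`` — FastICA unmixing; components ranked by kurtosis (the QRS spike
  train is strongly super-Gaussian) and the top one squared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d
from scipy.stats import kurtosis

from .io import MultileadSignal

__all__ = [
    "FilteredLeadSet",
    "FeatureSignal",
    "bandpass_qrs",
    "derivative",
    "pt_filter_lead",
    "derivative_filter_leads",
    "rms_feature",
    "product_feature",
    "pca_feature",
    "ica_feature",
    "select_least_noisy_lead",
    "compute_feature",
    "FEATURE_METHODS",
]

FEATURE_METHODS = ("pt", "rms", "prod", "pca", "ica")

_MWI_WINDOW_S = 0.150  # canonical Pan-Tompkins integration window


@dataclass
class FilteredLeadSet:
    """Each lead after the band-pass + derivative chain (no squaring)."""

    xf: np.ndarray   # (n, L)
    fs: float


@dataclass
class FeatureSignal:
    """Detection-oriented transform aligned sample-wise to its source.

    ``y`` is 1-D for single-output methods (pt, rms, pca, ica) and (n, L)
    for the per-lead product method.  Squared-output methods are
    nonnegative; the product method is signed and detectors take ``|y|``.
    """

    y: np.ndarray
    method: str
    fs: float
    meta: dict | None = None


def _check_fs(fs: float) -> None:
    if fs < 40:
        raise ValueError(f"sampling rate {fs} Hz too low for the 5-15 Hz QRS band")


def bandpass_qrs(lead: np.ndarray, fs: float, low: float = 5.0,
                 high: float = 15.0, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass isolating the QRS energy band."""
    _check_fs(fs)
    sos = sps.butter(order, [low, high], btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(lead, dtype=np.float64))


def derivative(lead: np.ndarray, fs: float) -> np.ndarray:
    """Centered five-point derivative, kernel fs/8 * [1, 2, 0, -2, -1].

    The kernel integrates to zero (kills DC) and returns the exact slope on
    a linear ramp.  Centered application keeps the output delay at zero.
    """
    x = np.asarray(lead, dtype=np.float64)
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * fs / 8.0
    # convolve centers the kernel, giving y[n] = fs/8 * (x[n+2] + 2x[n+1]
    # - 2x[n-1] - x[n-2]): zero-delay slope estimate, exact on ramps
    return np.convolve(x, kernel, mode="same")


def pt_filter_lead(lead: np.ndarray, fs: float) -> np.ndarray:
    """Band-pass -> derivative -> square -> 150 ms moving integration (>= 0)."""
    _check_fs(fs)
    d = derivative(bandpass_qrs(lead, fs), fs)
    w = max(1, int(round(_MWI_WINDOW_S * fs)))
    return uniform_filter1d(d * d, w, mode="nearest")


def derivative_filter_leads(signal: MultileadSignal) -> FilteredLeadSet:
    """Apply band-pass + derivative per lead (linear; no squaring)."""
    xf = np.column_stack([derivative(bandpass_qrs(signal.lead(i), signal.fs),
                                     signal.fs)
                          for i in range(signal.n_leads)])
    return FilteredLeadSet(xf, signal.fs)


def rms_feature(xf: FilteredLeadSet) -> FeatureSignal:
    """Sum of squared filtered leads: ``y[n] = sum_l xf^2[n, l]``."""
    y = np.sum(xf.xf ** 2, axis=1)
    return FeatureSignal(y, "rms", xf.fs)


def product_feature(xf: FilteredLeadSet) -> FeatureSignal:
    """Combinational per-lead product across leads.

    ``y[n, i] = xf[n, i] * prod_{j != i} xf[n, j]`` — which, taken at face
    value, equals the product over *all* leads for every i, so all columns
    are identical.  Kept as written; users wanting distinct per-lead
    features should use the polling pipeline on per-lead pt features.
    """
    if xf.xf.shape[1] < 2:
        raise ValueError("product feature requires at least two leads")
    full = np.prod(xf.xf, axis=1)
    y = np.repeat(full[:, None], xf.xf.shape[1], axis=1)
    return FeatureSignal(y, "prod", xf.fs)


def pca_feature(signal: MultileadSignal) -> FeatureSignal:
    """Squared projection onto the dominant eigenvector of the lead covariance.

    Eigenvalues are reported in descending order in ``meta["eigenvalues"]``
    together with the explained-variance fraction of the first component.
    """
    if signal.n_leads < 2:
        raise ValueError("PCA feature requires at least two leads")
    if signal.n_samples <= signal.n_leads:
        raise ValueError("need more samples than leads for a covariance estimate")
    x = signal.samples - signal.samples.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)       # ascending
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    proj = x @ evecs[:, 0]
    total = float(np.sum(evals))
    meta = {
        "eigenvalues": evals,
        "explained_variance_pct": 100.0 * float(evals[0]) / total if total > 0 else 100.0,
        "direction": evecs[:, 0],
    }
    return FeatureSignal(proj ** 2, "pca", signal.fs, meta)


def ica_feature(signal: MultileadSignal, seed: int = 0) -> FeatureSignal:
    """Square of the most kurtotic independent component of the lead mixture.

    The QRS spike train is sparse and hence strongly super-Gaussian, so the
    component with maximal excess kurtosis is the beat carrier.  Squaring
    removes the inherent ICA sign ambiguity.  Deterministic given ``seed``;
    on convergence failure falls back to the PCA feature with a warning.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    if signal.n_leads < 2:
        raise ValueError("ICA feature requires at least two leads")
    if signal.n_samples < 10 * signal.fs:
        warnings.warn("fewer than 10 s of signal; ICA unmixing may be unstable")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            ica = FastICA(n_components=signal.n_leads, random_state=int(seed),
                          whiten="unit-variance", max_iter=500)
            comps = ica.fit_transform(signal.samples)
    except (ConvergenceWarning, ValueError) as exc:
        warnings.warn(f"ICA failed to converge ({exc}); falling back to PCA")
        out = pca_feature(signal)
        return FeatureSignal(out.y, "ica", signal.fs,
                             {"fallback": "pca", **(out.meta or {})})
    kurt = kurtosis(comps, axis=0, fisher=True)
    order = np.argsort(kurt)[::-1]
    best = comps[:, order[0]]
    meta = {"kurtosis": kurt[order], "component_order": order,
            "selected_component": best}
    return FeatureSignal(best ** 2, "ica", signal.fs, meta)


def select_least_noisy_lead(signal: MultileadSignal, win_s: float = 0.2) -> int:
    """Pick the lead with the lowest noise content.

    Statistic: ratio of mean to median time-local variance.  Impulsive noise
    and motion artifacts inflate the mean far more than the median, so clean
    leads minimize the ratio.
    """
    fs = signal.fs
    w = max(3, int(round(win_s * fs)))
    ratios = []
    for i in range(signal.n_leads):
        x = signal.lead(i)
        m = uniform_filter1d(x, w, mode="nearest")
        m2 = uniform_filter1d(x * x, w, mode="nearest")
        var = np.maximum(m2 - m * m, 0.0)
        med = np.median(var)
        ratios.append(np.mean(var) / med if med > 0 else np.inf)
    return int(np.argmin(ratios))


def compute_feature(signal: MultileadSignal, method: str,
                    seed: int = 0) -> FeatureSignal:
    """Dispatch: compute the named feature signal from a preprocessed record."""
    method = method.lower()
    if method == "pt":
        lead = select_least_noisy_lead(signal) if signal.n_leads > 1 else 0
        y = pt_filter_lead(signal.lead(lead), signal.fs)
        return FeatureSignal(y, "pt", signal.fs, {"lead": lead})
    if method == "rms":
        return rms_feature(derivative_filter_leads(signal))
    if method == "prod":
        return product_feature(derivative_filter_leads(signal))
    if method == "pca":
        return pca_feature(signal)
    if method == "ica":
        return ica_feature(signal, seed=seed)
    raise ValueError(f"unknown feature method {method!r}; "
                     f"choose from {FEATURE_METHODS}")
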