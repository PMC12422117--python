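"""Waveform preprocessing: standardization, end-tidal plateau detection,
scalar breath-feature extraction, and PCA.

The scalar features summarize each record the way a respiratory analyst
would read the traces: the VOC maximum and plateau width, the CO2 end-tidal
level, alveolar-plateau slope and upstroke angle, plus per-channel mean/max
summaries.  PCA (via scikit-learn) then reduces the standardized feature
table; kept components may be weighted by their explained-variance ratio
before classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from .synthcohort import CHANNELS, BreathRecord

__all__ = [
    "PlateauInterval",
    "FeatureVector",
    "PCAResult",
    "standardize",
    "detect_end_tidal_plateau",
    "extract_features",
    "build_feature_table",
    "fit_pca",
    "project",
]


@dataclass(frozen=True)
class PlateauInterval:
    """A detected end-tidal plateau: [start_index, end_index] inclusive."""

    start_index: int
    end_index: int
    mean_level: float
    slope: float  # units/sample over the run

    def __post_init__(self) -> None:
        if self.start_index >= self.end_index:
            raise ValueError("plateau start must precede its end")

    @property
    def length(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass
class FeatureVector:
    voc_max: float
    voc_plateau_width: float  # seconds
    co2_plateau_slope: float  # %/s
    co2_end_tidal: float  # %
    upstroke_angle: float  # degrees
    channel_summaries: dict[str, float] = field(default_factory=dict)

    def to_series(self) -> pd.Series:
        base = {
            "voc_max": self.voc_max,
            "voc_plateau_width": self.voc_plateau_width,
            "co2_plateau_slope": self.co2_plateau_slope,
            "co2_end_tidal": self.co2_end_tidal,
            "upstroke_angle": self.upstroke_angle,
        }
        base.update(self.channel_summaries)
        s = pd.Series(base, dtype=float)
        if not np.all(np.isfinite(s.to_numpy())):
            raise ValueError("feature vector contains non-finite values")
        if self.voc_plateau_width < 0:
            raise ValueError("voc_plateau_width must be >= 0")
        return s


# ---------------------------------------------------------------------------
# Standardization


def standardize(matrix: np.ndarray, return_stats: bool = False):
    """Column-wise z-scoring: each feature to mean 0, SD 1.

    Constant columns cannot be scaled; they are mapped to all-zeros and
    reported through a ``UserWarning`` (and the returned mask when
    ``return_stats``).  Idempotent within floating tolerance.
    """
    X = np.asarray(matrix, dtype=float)
    if X.size == 0:
        raise ValueError("standardize: empty input")
    if X.ndim != 2:
        raise ValueError("standardize expects a 2-D sample x feature matrix")
    if X.shape[0] < 2:
        raise ValueError("standardize needs at least 2 samples per feature")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    constant = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    if np.any(constant):
        warnings.warn(
            f"standardize: {int(constant.sum())} constant feature column(s) mapped to zeros",
            UserWarning,
            stacklevel=2,
        )
    safe_sd = np.where(constant, 1.0, sd)
    Z = (X - mean) / safe_sd
    Z[:, constant] = 0.0
    if return_stats:
        return Z, mean, safe_sd, constant
    return Z


# ---------------------------------------------------------------------------
# End-tidal plateau detection


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(x, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(x)]
    return out


def detect_end_tidal_plateau(
    capnogram: np.ndarray,
    min_length: int = 10,
    slope_tol: float = 0.01,
    *,
    smooth_window: int = 5,
    min_level_fraction: float = 0.5,
) -> PlateauInterval | None:
    """Find the end-tidal (alveolar) plateau of a CO2 capnogram.

    The trace is smoothed with a centered moving average, and candidate
    samples are those whose smoothed first difference stays within
    ``slope_tol`` (units/sample) *and* whose level is at least
    ``min_level_fraction`` of the smoothed maximum — the level gate keeps the
    zero-CO2 inspiratory baseline from masquerading as a plateau.  Returns the
    longest qualifying run (ties: the latest, i.e. terminal, run), or ``None``
    if no run reaches ``min_length``.
    """
    x = np.asarray(capnogram, dtype=float)
    if min_length > len(x):
        raise ValueError("min_length exceeds series length")
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    smooth = _moving_average(x, smooth_window)
    diff = np.diff(smooth)
    level_ok = smooth >= min_level_fraction * smooth.max()
    flat = np.abs(diff) <= slope_tol
    ok = flat & level_ok[:-1] & level_ok[1:]

    best: tuple[int, int] | None = None
    run_start = None
    for i, good in enumerate(np.append(ok, False)):
        if good and run_start is None:
            run_start = i
        elif not good and run_start is not None:
            start, end = run_start, i  # samples run_start..i inclusive
            if end - start + 1 >= min_length and (
                best is None or end - start >= best[1] - best[0]
            ):
                best = (start, end)
            run_start = None
    if best is None:
        return None
    start, end = best
    run = x[start : end + 1]
    slope = float(np.polyfit(np.arange(len(run)), run, 1)[0])
    return PlateauInterval(
        start_index=start, end_index=end, mean_level=float(run.mean()), slope=slope
    )


# ---------------------------------------------------------------------------
# Feature extraction


def extract_features(
    record: BreathRecord,
    plateau_fraction: float = 0.5,
    *,
    plateau_min_length: int = 10,
    plateau_slope_tol: float = 0.01,
) -> FeatureVector:
    """Scalar features of one breath record.

    ``voc_plateau_width`` is the total time the composite VOC signal spends at
    or above ``plateau_fraction`` of its maximum — for a single noiseless
    Gaussian at fraction 0.5 this is exactly the FWHM in seconds.
    """
    for required in ("voc_total", "co2"):
        if required not in record.channels:
            raise ValueError(f"record {record.subject_id} is missing channel '{required}'")
    fs = record.sampling_rate
    voc = np.asarray(record.channels["voc_total"], dtype=float)
    voc_max = float(voc.max())
    if voc_max <= 0:
        width = 0.0
    else:
        width = float(np.count_nonzero(voc >= plateau_fraction * voc_max)) / fs

    co2 = np.asarray(record.channels["co2"], dtype=float)
    plateau = detect_end_tidal_plateau(
        co2, min_length=plateau_min_length, slope_tol=plateau_slope_tol
    )
    smooth = _moving_average(co2, 5)
    if plateau is not None:
        co2_slope = plateau.slope * fs
        end_tidal = plateau.mean_level
    else:
        # Shark-fin traces have no flat plateau: summarize the terminal
        # expiratory region (top-half levels) instead.
        high = smooth >= 0.5 * smooth.max()
        co2_slope = float(np.median(np.diff(smooth)[high[:-1]])) * fs if high.sum() > 2 else 0.0
        end_tidal = float(np.quantile(co2, 0.98))
    max_rise = float(np.max(np.diff(smooth))) * fs  # %/s
    upstroke_angle = float(np.degrees(np.arctan(max_rise)))

    summaries: dict[str, float] = {}
    for name in CHANNELS:
        if name in ("voc_total", "co2"):
            continue
        series = np.asarray(record.channels[name], dtype=float)
        summaries[f"{name}_mean"] = float(series.mean())
        summaries[f"{name}_max"] = float(series.max())
    return FeatureVector(
        voc_max=voc_max,
        voc_plateau_width=width,
        co2_plateau_slope=co2_slope,
        co2_end_tidal=end_tidal,
        upstroke_angle=upstroke_angle,
        channel_summaries=summaries,
    )


def build_feature_table(
    records: list[BreathRecord], plateau_fraction: float = 0.5
) -> pd.DataFrame:
    """One row per subject: features computed per replicate then aggregated by
    the median (robust to one bad exhalation).  Adds a ``label`` column."""
    rows = []
    for rec in records:
        s = extract_features(rec, plateau_fraction).to_series()
        s["subject_id"] = rec.subject_id
        s["label"] = rec.label
        rows.append(s)
    frame = pd.DataFrame(rows)
    grouped = frame.groupby("subject_id", sort=True)
    features = grouped.median(numeric_only=True)
    features["label"] = grouped["label"].first().astype(int)
    return features


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    loadings: np.ndarray  # component x feature, orthonormal rows
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # sample x component
    mean: np.ndarray  # feature means used for centering
    n_components_kept: int


def fit_pca(
    matrix: np.ndarray,
    variance_target: float = 0.95,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of a (standardized) sample x feature matrix.

    Keeps the smallest number of components whose cumulative explained
    variance reaches ``variance_target``, unless a fixed ``n_components``
    overrides it.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("fit_pca expects a 2-D matrix with >= 2 samples")
    if not (0.0 < variance_target <= 1.0):
        raise ValueError("variance_target must lie in (0, 1]")
    full = _SkPCA(n_components=min(X.shape), svd_solver="full")
    scores_full = full.fit_transform(X)
    evr = full.explained_variance_ratio_
    if n_components is None:
        cum = np.cumsum(evr)
        k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
        k = min(k, len(evr))
    else:
        k = min(int(n_components), len(evr))
        if k < 1:
            raise ValueError("n_components must be >= 1")
    return PCAResult(
        loadings=full.components_[:k].copy(),
        explained_variance_ratio=evr[:k].copy(),
        scores=scores_full[:, :k].copy(),
        mean=full.mean_.copy(),
        n_components_kept=k,
    )


def project(pca: PCAResult, matrix: np.ndarray, weight_by_variance: bool = False) -> np.ndarray:
    """Project new samples onto stored loadings (after stored centering).

    With ``weight_by_variance`` each kept component is scaled by its
    explained-variance ratio, giving informative components higher weight in
    downstream models.
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    if X.shape[1] != pca.loadings.shape[1]:
        raise ValueError(
            f"feature count {X.shape[1]} does not match PCA training dimension "
            f"{pca.loadings.shape[1]}"
        )
    scores = (X - pca.mean) @ pca.loadings.T
    if weight_by_variance:
        scores = scores * pca.explained_variance_ratio
    return scores
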