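"""Two-channel probe normalization and reflection-null enrichment calling.

Each probe contributes a point (x, y) of log2 input and IP intensities.
Non-enriched probes are assumed symmetric about the diagonal x = y, so the
probes *below* the diagonal estimate the null: a local robust scale s(a)
of the signed perpendicular distance d = (y - x) / sqrt(2) as a function
of mean intensity a = (x + y) / 2, a symmetrized empirical null of
normalized distances z = d / s(a), and a threshold curve at quantile q of
the below-diagonal |d|, mirrored above the axis. Probe p-values are
empirical upper-tail counts over the symmetrized null — exactly the
symmetry assumption, nothing parametric.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

logger = logging.getLogger(__name__)

SQRT2 = np.sqrt(2.0)


class LowessNormalizer(BaseEstimator, TransformerMixin):
    """Remove the lowess trend of the log-ratio against mean intensity.

    Fit learns the trend of m = y - x versus a = (x + y) / 2 on log2
    channels; transform subtracts the interpolated trend, preserving a.

    Parameters
    ----------
    span : fraction of points in each local regression window.
    delta_frac : lowess point-combining distance as a fraction of the
        intensity range (keeps large arrays near-linear in cost).
    """

    def __init__(self, span: float = 0.3, delta_frac: float = 0.01):
        self.span = span
        self.delta_frac = delta_frac

    @staticmethod
    def _split(X) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2): raw input and IP intensities")
        if np.any(X <= 0) or not np.all(np.isfinite(X)):
            raise ValueError("intensities must be positive and finite")
        x = np.log2(X[:, 0])
        y = np.log2(X[:, 1])
        return (x + y) / 2, y - x

    def fit(self, X, y=None) -> "LowessNormalizer":
        a, m = self._split(X)
        delta = self.delta_frac * (a.max() - a.min())
        fitted = _sm_lowess(m, a, frac=self.span, delta=delta, return_sorted=True)
        # collapse duplicate abscissae so np.interp is well defined
        grid, idx = np.unique(fitted[:, 0], return_index=True)
        self.trend_a_ = grid
        self.trend_m_ = fitted[idx, 1]
        return self

    def transform(self, X) -> np.ndarray:
        a, m = self._split(X)
        m_detrended = m - np.interp(a, self.trend_a_, self.trend_m_)
        x = a - m_detrended / 2
        y = a + m_detrended / 2
        return np.column_stack([x, y])


def lowess_normalize(intensities: pd.DataFrame, span: float = 0.3,
                     input_col: str = "ch_input", ip_col: str = "ch_ip",
                     id_col: str = "probe_id") -> pd.DataFrame:
    """Normalize a raw intensity table to per-probe (x, y) log2 channels.

    Probes with a non-positive channel are rejected with a logged warning.
    """
    raw = intensities[[input_col, ip_col]].to_numpy(dtype=float)
    ok = np.all(raw > 0, axis=1) & np.all(np.isfinite(raw), axis=1)
    if not ok.all():
        bad = intensities.loc[~ok, id_col].tolist()
        logger.warning("rejecting %d probe(s) with non-positive intensity: %s",
                       len(bad), bad[:10])
    kept = intensities.loc[ok]
    xy = LowessNormalizer(span=span).fit_transform(raw[ok])
    out = pd.DataFrame({id_col: kept[id_col].to_numpy(),
                        "x": xy[:, 0], "y": xy[:, 1]})
    out["a"] = (out["x"] + out["y"]) / 2
    out["d"] = (out["y"] - out["x"]) / SQRT2
    return out


class ReflectionNullCaller(BaseEstimator):
    """Empirical-null probe caller built from below-diagonal probes.

    fit() expects normalized probes (columns ``a`` and ``d``, or an
    (n, 2) array of them) from one replicate array and learns:

    ``scale_spline_``
        cubic spline through the per-bin robust scale 1.4826 * median|d|
        of below-diagonal probes (``n_bins`` equal-count bins by a);
    ``null_sample_``
        the sorted symmetrized normalized distances {+-|d|/s(a)};
    ``z_crit_``
        quantile q of the below-diagonal normalized |d|, so the threshold
        curve is threshold(a) = s(a) * z_crit_ — a variance-stabilized
        local quantile of |d|, mirrored above the axis.

    predict() flags probes with d > threshold(a); pvalue() returns the
    empirical upper-tail probability (1 + #{v >= z}) / (1 + N).
    """

    def __init__(self, q: float = 0.999, n_bins: int = 10, min_below: int = 100):
        self.q = q
        self.n_bins = n_bins
        self.min_below = min_below

    @staticmethod
    def _as_ad(X) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(X, pd.DataFrame):
            return X["a"].to_numpy(float), X["d"].to_numpy(float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be a DataFrame with a/d columns or (n, 2)")
        return X[:, 0], X[:, 1]

    def fit(self, X, y=None) -> "ReflectionNullCaller":
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        a, d = self._as_ad(X)
        below = d < 0
        if int(below.sum()) < self.min_below:
            raise ValueError(
                f"only {int(below.sum())} probes below the diagonal; "
                f"need >= {self.min_below} to estimate the null")
        a_b, abs_d = a[below], np.abs(d[below])
        order = np.argsort(a_b, kind="stable")
        bins = np.array_split(order, min(self.n_bins, len(order)))
        centers = np.array([a_b[idx].mean() for idx in bins])
        scales = np.array([1.4826 * np.median(abs_d[idx]) for idx in bins])
        if np.any(scales <= 0):
            raise ValueError("degenerate null: zero robust scale (all probes "
                             "on the diagonal in some intensity bin)")
        k = min(3, len(centers) - 1)
        if k >= 1:
            self._scale_spline = UnivariateSpline(centers, scales, k=k, s=0)
        else:
            self._scale_spline = None
        self._scale_const = float(scales.mean())
        self.a_range_ = (float(centers[0]), float(centers[-1]))
        self.scale_bin_centers_ = centers
        self.scale_bin_values_ = scales

        z_below = abs_d / self.scale(a_b)
        self.z_crit_ = float(np.quantile(z_below, self.q))
        self.null_sample_ = np.sort(np.concatenate([z_below, -z_below]))
        self.n_fit_ = len(a)
        return self

    # -- fitted-model queries -----------------------------------------
    def scale(self, a) -> np.ndarray:
        """s(a) > 0, clamped to the fitted intensity range at the ends."""
        a = np.clip(np.asarray(a, dtype=float), *self.a_range_)
        if self._scale_spline is None:
            s = np.full_like(a, self._scale_const)
        else:
            s = self._scale_spline(a)
        return np.maximum(s, 1e-12)

    def threshold(self, a) -> np.ndarray:
        return self.scale(a) * self.z_crit_

    def zscore(self, X) -> np.ndarray:
        a, d = self._as_ad(X)
        return d / self.scale(a)

    def pvalue(self, X) -> np.ndarray:
        z = self.zscore(X)
        n = len(self.null_sample_)
        tail = n - np.searchsorted(self.null_sample_, z, side="left")
        p = (1.0 + tail) / (1.0 + n)
        p[~np.isfinite(z)] = np.nan
        return p

    @property
    def min_pvalue_(self) -> float:
        return 1.0 / (1.0 + len(self.null_sample_))

    def predict(self, X) -> np.ndarray:
        a, d = self._as_ad(X)
        return d > self.threshold(a)


def fit_null_model(probes: pd.DataFrame, q: float = 0.999,
                   n_bins: int = 10) -> ReflectionNullCaller:
    return ReflectionNullCaller(q=q, n_bins=n_bins).fit(probes)


def probe_pvalues(probes: pd.DataFrame, model: ReflectionNullCaller) -> pd.DataFrame:
    """Attach normalized distance z and empirical p to a probe table."""
    out = probes.copy()
    out["z"] = model.zscore(probes)
    out["p"] = model.pvalue(probes)
    bad = ~np.isfinite(out["z"].to_numpy())
    if bad.any():
        warnings.warn(f"{int(bad.sum())} probe(s) with non-finite z flagged")
        out["flagged"] = bad
    return out


def classify_probes(probes: pd.DataFrame,
                    model: ReflectionNullCaller) -> pd.DataFrame:
    out = probes if "p" in probes.columns else probe_pvalues(probes, model)
    out = out.copy()
    out["positive"] = model.predict(out)
    return out


def call_probes(intensities: pd.DataFrame, span: float = 0.3, q: float = 0.999,
                n_bins: int = 10) -> tuple[pd.DataFrame, ReflectionNullCaller]:
    """Full per-replicate pipeline: normalize, fit null, attach p, classify.

    Returns the probe table (probe_id, x, y, a, d, z, p, positive) plus the
    fitted null model.
    """
    probes = lowess_normalize(intensities, span=span)
    model = fit_null_model(probes, q=q, n_bins=n_bins)
    return classify_probes(probe_pvalues(probes, model), model), model


def positive_probe_bed(probe_table: pd.DataFrame,
                       annotation: pd.DataFrame) -> pd.DataFrame:
    """BED-like frame (chrom, start, end, probe_id, score) of positive probes."""
    pos = probe_table.loc[probe_table["positive"], ["probe_id", "p"]]
    bed = pos.merge(annotation[["probe_id", "chrom", "start", "end"]], on="probe_id")
    bed["score"] = -np.log10(bed["p"])
    return bed[["chrom", "start", "end", "probe_id", "score"]]
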