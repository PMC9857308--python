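"""scikit-learn transformer front-ends for the pipeline stages.

The preprocessing chain and both connectivity extractors are
transform-shaped (a list of recordings in, a feature row per subject
out), so they are exposed as sklearn transformers and compose with
``sklearn.pipeline.Pipeline`` and model selection::

    make_pipeline(EEGPreprocessor(), WPLIConnectivity(scheme=scheme5),
                  LogisticRegression())

``X`` is a list of :class:`MultichannelRecording` (for the
preprocessor) or :class:`EpochedRecording` (for the extractors); the
extractors return a dense ``(n_subjects, n_features)`` array with
feature names ``"<band>:<cell>"``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import CANONICAL_BANDS, EpochedRecording, MultichannelRecording
from .functional import (
    aggregate_cross_region,
    aggregate_within_region,
    band_connectivity_matrix,
)
from .montage import RegionScheme
from .pipeline import subject_dtf_table
from .preprocessing import preprocess

__all__ = ["EEGPreprocessor", "WPLIConnectivity", "DTFConnectivity"]


class EEGPreprocessor(TransformerMixin, BaseEstimator):
    """Band-pass, resample, epoch and re-reference a list of recordings.

    Stateless (``fit`` only validates parameters); ``transform`` maps a
    list of :class:`MultichannelRecording` to a list of
    :class:`EpochedRecording`.
    """

    def __init__(self, low: float = 1.0, high: float = 45.0,
                 target_rate: float = 200.0, epoch_length: float = 10.0,
                 max_epochs: int | None = 10,
                 keep_labels: Sequence[str] | None = None):
        self.low = low
        self.high = high
        self.target_rate = target_rate
        self.epoch_length = epoch_length
        self.max_epochs = max_epochs
        self.keep_labels = keep_labels

    def fit(self, X, y=None):
        if not (0 < self.low < self.high):
            raise ValueError("need 0 < low < high")
        self.n_features_in_ = len(X)
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        out = []
        for rec in X:
            if not isinstance(rec, MultichannelRecording):
                raise TypeError("EEGPreprocessor expects MultichannelRecording inputs")
            out.append(preprocess(rec, low=self.low, high=self.high,
                                  target_rate=self.target_rate,
                                  epoch_length=self.epoch_length,
                                  max_epochs=self.max_epochs,
                                  keep_labels=self.keep_labels))
        return out


class _ConnectivityBase(TransformerMixin, BaseEstimator):
    def _feature_frame(self, epochs: EpochedRecording, subject: str):
        raise NotImplementedError

    def fit(self, X, y=None):
        if len(X) == 0:
            raise ValueError("empty input")
        df = self._feature_frame(X[0], "probe")
        self.feature_names_ = tuple(f"{b}:{c}"
                                    for b, c in zip(df["band"], df["cell"]))
        self.n_features_in_ = len(X)
        return self

    def transform(self, X):
        check_is_fitted(self, "feature_names_")
        rows = np.empty((len(X), len(self.feature_names_)))
        for s, epochs in enumerate(X):
            if not isinstance(epochs, EpochedRecording):
                raise TypeError("connectivity extractors expect EpochedRecording inputs")
            df = self._feature_frame(epochs, f"s{s}")
            names = tuple(f"{b}:{c}" for b, c in zip(df["band"], df["cell"]))
            if names != self.feature_names_:
                raise ValueError("feature layout changed between fit and transform")
            rows[s] = df["value"].to_numpy()
        return rows

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_")
        return np.asarray(self.feature_names_, dtype=object)


class WPLIConnectivity(_ConnectivityBase):
    """Per-subject wPLI features under a region scheme.

    ``level="within"`` yields one feature per (band × region) using the
    within-region mean; ``level="pairs"`` yields one per
    (band × homologous region pair).  The scheme must declare pairs for
    the latter.
    """

    def __init__(self, scheme: RegionScheme, level: str = "within",
                 estimator: str = "wpli"):
        self.scheme = scheme
        self.level = level
        self.estimator = estimator

    def _feature_frame(self, epochs, subject):
        if self.level not in ("within", "pairs"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.level == "pairs" and not self.scheme.pairs:
            raise ValueError(
                f"scheme {self.scheme.name!r} declares no region pairs")
        rows = []
        for band in CANONICAL_BANDS:
            matrix = band_connectivity_matrix(epochs, band,
                                              estimator=self.estimator)
            if self.level == "within":
                agg = aggregate_within_region(matrix, self.scheme)
                cells = zip(agg.labels, agg.values)
            else:
                cells = ((f"{a}-{b}",
                          aggregate_cross_region(matrix, self.scheme, (a, b)))
                         for a, b in self.scheme.pairs)
            for cell, value in cells:
                rows.append({"subject": subject, "band": band.name,
                             "cell": cell, "value": float(value)})
        return pd.DataFrame(rows)


class DTFConnectivity(_ConnectivityBase):
    """Per-subject significant-DTF features between homologous regions."""

    def __init__(self, scheme: RegionScheme, order: int | str = "auto",
                 p_max: int = 20, n_surrogates: int = 100, alpha: float = 0.05,
                 seed: int = 0):
        self.scheme = scheme
        self.order = order
        self.p_max = p_max
        self.n_surrogates = n_surrogates
        self.alpha = alpha
        self.seed = seed

    def _feature_frame(self, epochs, subject):
        return subject_dtf_table(epochs, self.scheme, subject, order=self.order,
                                 p_max=self.p_max, n_surrogates=self.n_surrogates,
                                 alpha=self.alpha, seed=self.seed)
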