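"""Functional connectivity construction from ROI time series.

A subject's cleaned BOLD signal (T timepoints x N regions) is turned into
an N x N Pearson correlation matrix — the weighted substrate every
downstream network analysis consumes. The diagonal is stored as zero:
self-connections are never edges, so removing them here removes a special
case from thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from netsweep.aal90 import default_labels

__all__ = [
    "RoiTimeSeries",
    "ConnectivityMatrix",
    "compute_fc_matrix",
    "link_weight_distribution",
]


@dataclass
class RoiTimeSeries:
    """One subject's regional BOLD time series (T x N, arbitrary units)."""

    subject_id: str
    values: np.ndarray
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T x N) array")
        t, n = self.values.shape
        if t < 3:
            raise ValueError(f"need at least 3 timepoints, got {t}")
        if not self.roi_labels:
            self.roi_labels = default_labels(n)
        if len(self.roi_labels) != n:
            raise ValueError(
                f"{len(self.roi_labels)} labels for {n} ROI columns"
            )

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix with zeroed diagonal."""

    subject_id: str
    r: np.ndarray
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = self.r.shape[0]
        if self.r.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.abs(self.r).max(initial=0.0) > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")
        if not self.roi_labels:
            self.roi_labels = default_labels(n)
        if len(self.roi_labels) != n:
            raise ValueError(
                f"{len(self.roi_labels)} labels for {n} x {n} matrix"
            )

    @property
    def n_rois(self) -> int:
        return self.r.shape[0]


def compute_fc_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between every pair of regional time series.

    Raises if any column is constant (correlation undefined) or contains
    NaN, naming the offending ROI.
    """
    x = ts.values
    if np.isnan(x).any():
        bad = [ts.roi_labels[j] for j in np.unique(np.where(np.isnan(x))[1])]
        raise ValueError(f"NaN values in ROI column(s): {', '.join(bad)}")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = [ts.roi_labels[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant ROI column(s): {', '.join(bad)}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(ts.subject_id, r, list(ts.roi_labels))


def link_weight_distribution(fc: ConnectivityMatrix) -> np.ndarray:
    """All N(N-1)/2 connection strengths of the weighted matrix.

    Returned in row-major upper-triangle order (i < j); the empirical
    distribution of these values is the subject's link-weight
    distribution.
    """
    iu, ju = np.triu_indices(fc.n_rois, k=1)
    return fc.r[iu, ju]
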