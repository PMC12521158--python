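"""Synthetic two-group resting-state cohorts with planted network effects.

Emulates the data structure of an SSRI treatment-response study: two
groups of subjects (default 37 responders, 32 non-responders), each with
a 90-ROI BOLD time series (default 230 volumes) and a clinical record
(age, sex, pre/post HAMD-17 and HAMA scores).

The generative model is a modular (block-correlation) multivariate
normal: ROIs are partitioned into equal modules; pairs within a module
correlate at ``within_module_r``, pairs across modules at
``between_module_r``. Raising the within/between contrast raises network
segregation (clustering, local efficiency, modularity), the quantities
the emulated study found elevated in non-responders, so group covariance
parameters directly plant a recoverable topological effect. Independent
observation noise attenuates all correlations uniformly; between-subject
variability arises from finite-length sampling of the correlations.

All randomness flows from a single master seed: subject i draws from the
(i+1)-th child of ``numpy.random.SeedSequence(seed)`` (child 0 drives the
clinical table), so cohorts are reproducible subject-by-subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from netsweep.clinical import label_responders
from netsweep.connectivity import RoiTimeSeries

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "make_group_covariance",
    "simulate_cohort",
    "simulate_subject_timeseries",
]

GROUPS = ("responder", "nonresponder")

#: HAMD-17 integer rounding can shift a realized reduction rate by at
#: most 0.5 / hamd17_pre <= 0.5/8 from the drawn rate, so generated
#: reduction ranges must keep this margin from the 0.50 labeling boundary
#: for labels to be consistent by construction.
ROUNDING_MARGIN = 0.5 / 8


def _per_group(value, name: str) -> dict[str, float]:
    if isinstance(value, dict):
        missing = set(GROUPS) - set(value)
        if missing:
            raise ValueError(f"{name} missing groups: {sorted(missing)}")
        return {g: float(value[g]) for g in GROUPS}
    return {g: float(value) for g in GROUPS}


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    Defaults emulate the study conditions: group sizes 37/32, 90 ROIs,
    230 volumes, 6 modules, a stronger within/between-module correlation
    contrast in the non-responder group (higher segregation), pre-
    treatment HAMD-17 ~ Normal(18.4, 5.5) truncated at the >7 inclusion
    criterion, and group reduction-rate ranges on either side of the 50%
    responder boundary (responders ~0.60-0.95, non-responders
    ~-0.15-0.35, matching the reported pre/post score marginals).
    """

    n_responders: int = 37
    n_nonresponders: int = 32
    n_rois: int = 90
    n_timepoints: int = 230
    n_modules: int = 6
    within_module_r: dict[str, float] | float = field(
        default_factory=lambda: {"responder": 0.32, "nonresponder": 0.335})
    between_module_r: dict[str, float] | float = field(
        default_factory=lambda: {"responder": 0.12, "nonresponder": 0.115})
    subject_noise_sd: float = 0.5
    hamd_pre_mean: float = 18.4
    hamd_pre_sd: float = 5.5
    hama_pre_mean: float = 15.4
    hama_pre_sd: float = 6.7
    responder_reduction_range: tuple[float, float] = (0.60, 0.95)
    nonresponder_reduction_range: tuple[float, float] = (-0.15, 0.35)
    confound_age_sex: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.within_module_r = _per_group(self.within_module_r,
                                          "within_module_r")
        self.between_module_r = _per_group(self.between_module_r,
                                           "between_module_r")
        if self.n_responders < 1 or self.n_nonresponders < 1:
            raise ValueError("both groups need at least one subject")
        if self.n_timepoints < self.n_rois + 2:
            raise ValueError(
                "n_timepoints must be at least n_rois + 2 for downstream "
                "correlation estimation")
        for g in GROUPS:
            w, b = self.within_module_r[g], self.between_module_r[g]
            if not 0 <= w < 1:
                raise ValueError(f"within_module_r[{g}] must lie in [0, 1)")
            if not (0 <= b <= w):
                raise ValueError(
                    f"between_module_r[{g}] must lie in [0, within] "
                    f"(got {b} vs within={w})")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be nonnegative")
        lo_r, hi_r = self.responder_reduction_range
        lo_n, hi_n = self.nonresponder_reduction_range
        if lo_r > hi_r or lo_n > hi_n:
            raise ValueError("reduction ranges must be ordered (lo, hi)")
        if lo_r < 0.50 + ROUNDING_MARGIN or hi_n > 0.50 - ROUNDING_MARGIN:
            raise ValueError(
                "reduction ranges straddle the 0.50 responder boundary "
                "(integer rounding could contradict the generating labels): "
                f"responder range {self.responder_reduction_range}, "
                f"non-responder range {self.nonresponder_reduction_range}")
        if hi_r > 1.0:
            raise ValueError("reduction rates cannot exceed 1 (post >= 0)")

    @classmethod
    def null(cls, seed: int = 0, **kwargs) -> "CohortSpec":
        """Both groups share the responder generative parameters (no
        planted network effect); clinical labeling is unchanged."""
        spec = cls(seed=seed, **kwargs)
        spec.within_module_r = {g: spec.within_module_r["responder"]
                                for g in GROUPS}
        spec.between_module_r = {g: spec.between_module_r["responder"]
                                 for g in GROUPS}
        return spec

    def group_sizes(self) -> dict[str, int]:
        return {"responder": self.n_responders,
                "nonresponder": self.n_nonresponders}


def _module_sizes(n_rois: int, n_modules: int) -> np.ndarray:
    base = n_rois // n_modules
    sizes = np.full(n_modules, base)
    sizes[: n_rois - base * n_modules] += 1
    return sizes


def _nearest_psd_correlation(c: np.ndarray) -> np.ndarray:
    """Eigenvalue clipping at zero followed by unit-diagonal rescaling."""
    w, v = np.linalg.eigh(c)
    if w.min() >= -1e-10:
        return c
    w = np.clip(w, 0.0, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    if np.any(d <= 0):
        raise ValueError("PSD repair produced a degenerate diagonal")
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def make_group_covariance(spec: CohortSpec, group: str) -> np.ndarray:
    """Block-structured model correlation matrix for one group.

    ``within_module_r`` inside each of ``n_modules`` (near-)equal
    modules, ``between_module_r`` elsewhere, unit diagonal; repaired to
    the nearest positive semi-definite correlation matrix if needed.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    w = spec.within_module_r[group]
    b = spec.between_module_r[group]
    c = np.full((spec.n_rois, spec.n_rois), b)
    start = 0
    for size in _module_sizes(spec.n_rois, spec.n_modules):
        c[start:start + size, start:start + size] = w
        start += size
    np.fill_diagonal(c, 1.0)
    c = _nearest_psd_correlation(c)
    if np.linalg.eigvalsh(c).min() < -1e-8:
        raise ValueError(
            f"covariance not PSD after repair (within={w}, between={b}, "
            f"n_modules={spec.n_modules})")
    return c


def simulate_subject_timeseries(
    cov: np.ndarray,
    n_timepoints: int,
    noise_sd: float,
    seed,
    subject_id: str = "sub-000",
) -> RoiTimeSeries:
    """Draw one subject's T x N series from the model correlation.

    Independent multivariate-normal samples (zero mean, correlation
    ``cov``) plus independent per-channel Gaussian noise of standard
    deviation ``noise_sd``. Deterministic given ``seed``.
    """
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    if n_timepoints < n + 2:
        raise ValueError(
            f"n_timepoints={n_timepoints} < n_rois+2={n + 2}: correlation "
            "estimation would be ill-posed downstream")
    w, v = np.linalg.eigh(cov)
    if w.min() < -1e-8:
        raise ValueError("covariance must be positive semi-definite")
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_timepoints, n))
    x = z @ factor.T
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal((n_timepoints, n))
    return RoiTimeSeries(subject_id, x)


@dataclass
class SyntheticCohort:
    """Generated time series, clinical table and the planted ground truth."""

    time_series: list[RoiTimeSeries]
    clinical: pd.DataFrame
    ground_truth: dict

    def __post_init__(self) -> None:
        ids = [ts.subject_id for ts in self.time_series]
        if len(set(ids)) != len(ids):
            raise ValueError("subject identifiers must be unique")
        if set(ids) != set(self.clinical["subject_id"]):
            raise ValueError("one time-series record per clinical row "
                             "required")


def _truncated_normal(rng, mean, sd, lower, size):
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full two-group cohort from a validated spec.

    Per-subject time series come from the subject's group covariance;
    the clinical table draws age uniformly on 13..18, sex Bernoulli(0.5)
    (unless the confounded mode ties both mildly to group), pre-treatment
    HAMD-17 from a truncated normal (>= 8, rounded to integer), and
    post-treatment scores from the group's reduction-rate range. Derived
    responder labels provably equal the generating group labels.
    """
    covs = {g: make_group_covariance(spec, g) for g in GROUPS}
    sizes = spec.group_sizes()
    groups = (["responder"] * sizes["responder"]
              + ["nonresponder"] * sizes["nonresponder"])
    n_sub = len(groups)
    master = np.random.SeedSequence(spec.seed)
    children = master.spawn(n_sub + 1)
    clin_rng = np.random.default_rng(children[0])

    subject_ids = [f"sub-{i + 1:03d}" for i in range(n_sub)]
    time_series = [
        simulate_subject_timeseries(
            covs[g], spec.n_timepoints, spec.subject_noise_sd,
            children[i + 1], subject_id=sid)
        for i, (sid, g) in enumerate(zip(subject_ids, groups))
    ]

    ranges = {"responder": spec.responder_reduction_range,
              "nonresponder": spec.nonresponder_reduction_range}
    rows = []
    for sid, g in zip(subject_ids, groups):
        if spec.confound_age_sex:
            p_female = 0.65 if g == "responder" else 0.35
            age_lo = 13 if g == "responder" else 14
        else:
            p_female, age_lo = 0.5, 13
        age = int(clin_rng.integers(age_lo, 19))
        sex = "female" if clin_rng.random() < p_female else "male"
        hamd_pre = int(np.round(_truncated_normal(
            clin_rng, spec.hamd_pre_mean, spec.hamd_pre_sd, 8.0, 1)[0]))
        hama_pre = int(np.round(_truncated_normal(
            clin_rng, spec.hama_pre_mean, spec.hama_pre_sd, 0.0, 1)[0]))
        lo, hi = ranges[g]
        u = float(clin_rng.uniform(lo, hi))
        hamd_post = int(max(np.round(hamd_pre * (1.0 - u)), 0))
        u_hama = float(np.clip(u + 0.1 * clin_rng.standard_normal(),
                               -0.5, 1.0))
        hama_post = int(max(np.round(hama_pre * (1.0 - u_hama)), 0))
        rows.append((sid, g, age, sex, hamd_pre, hamd_post, hama_pre,
                     hama_post))
    clinical = pd.DataFrame(
        rows, columns=["subject_id", "group", "age", "sex", "hamd17_pre",
                       "hamd17_post", "hama_pre", "hama_post"])
    clinical = label_responders(clinical)
    derived = np.where(clinical["responder"], "responder", "nonresponder")
    if not (derived == clinical["group"]).all():
        bad = clinical.loc[derived != clinical["group"],
                           "subject_id"].tolist()
        raise RuntimeError(
            f"derived responder labels contradict generating groups: {bad}")
    ground_truth = {
        "group_covariances": covs,
        "spec": spec,
    }
    return SyntheticCohort(time_series, clinical, ground_truth)
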