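"""Motion quality control and group statistics.

Framewise displacement (FD) summarises the six rigid-body realignment
parameters into one scalar per volume.  Two conventions are implemented:

* Power FD: sum of absolute backward differences of the three translations
  (mm) plus 50 mm times the sum of absolute rotation differences (rad) —
  the rotations are converted to arc length on a 50 mm head-radius sphere.
* Jenkinson (RMS) FD: root-mean-square displacement induced by the relative
  rigid transform between consecutive volumes, averaged over a ball of
  radius 80 mm centred at the origin; for a pure translation it reduces to
  the translation magnitude.

The statistics applied to flexibility tables are a one-way repeated-measures
ANOVA across networks (windows as the repeated measurement unit, so
df = (k-1, (k-1)(n-1))) and paired t-tests between network pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io_formats import MotionTrace, RoiTimeSeries, ValidationError

__all__ = [
    "FdSeries",
    "AnovaResult",
    "power_fd",
    "jenkinson_fd",
    "fd_bold_correlation",
    "mean_fd_bold_correlation",
    "rm_anova",
    "paired_ttest",
]

POWER_HEAD_RADIUS_MM = 50.0
JENKINSON_RADIUS_MM = 80.0


@dataclass
class FdSeries:
    """Per-volume framewise displacement in mm; first volume 0 by convention."""

    fd: np.ndarray
    variant: str
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        if self.fd.ndim != 1 or self.fd.size < 2:
            raise ValidationError("FD series must be 1-D with >= 2 volumes")
        if np.any(self.fd < 0) or not np.all(np.isfinite(self.fd)):
            raise ValidationError("FD values must be finite and >= 0")

    @property
    def mean_fd(self) -> float:
        return float(self.fd.mean())

    @property
    def max_fd(self) -> float:
        return float(self.fd.max())


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


def power_fd(m: MotionTrace, head_radius_mm: float = POWER_HEAD_RADIUS_MM) -> FdSeries:
    """Power framewise displacement.

    FD_t = sum |d translations| + r * sum |d rotations|, r = 50 mm.
    """
    d = np.abs(np.diff(m.data, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return FdSeries(fd=np.concatenate([[0.0], fd]), variant="power", tr_s=m.tr_s)


def _rigid_affine(params: np.ndarray) -> np.ndarray:
    """4x4 rigid transform from (tx, ty, tz, rx, ry, rz); R = Rx @ Ry @ Rz."""
    tx, ty, tz, rx, ry, rz = params
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    T = np.eye(4)
    T[:3, :3] = Rx @ Ry @ Rz
    T[:3, 3] = (tx, ty, tz)
    return T


def jenkinson_fd(m: MotionTrace, radius_mm: float = JENKINSON_RADIUS_MM) -> FdSeries:
    """RMS framewise displacement over a ball of radius 80 mm.

    For the relative transform M = T_t @ inv(T_{t-1}) with linear part
    A = M[:3,:3] - I and translation t, the mean squared displacement of a
    point uniformly distributed in the ball is (R^2/5) tr(A^T A) + |t|^2.
    """
    fd = np.zeros(m.n_vols)
    prev = _rigid_affine(m.data[0])
    for t in range(1, m.n_vols):
        cur = _rigid_affine(m.data[t])
        M = cur @ np.linalg.inv(prev) - np.eye(4)
        A = M[:3, :3]
        trans = M[:3, 3]
        fd[t] = np.sqrt(
            radius_mm**2 / 5.0 * np.trace(A.T @ A) + trans @ trans
        )
        prev = cur
    return FdSeries(fd=fd, variant="jenkinson", tr_s=m.tr_s)


def fd_bold_correlation(fd: FdSeries, ts: RoiTimeSeries) -> pd.DataFrame:
    """Pearson r and two-sided p of the FD series against each ROI column."""
    if fd.fd.size != ts.n_vols:
        raise ValidationError(
            f"FD has {fd.fd.size} volumes, time series has {ts.n_vols}"
        )
    if fd.fd.std() == 0:
        raise ValidationError("FD series is constant; correlation undefined")
    rows = []
    for i, lab in enumerate(ts.roi_labels):
        col = ts.data[:, i]
        if col.std() == 0:
            raise ValidationError(f"constant ROI column {lab!r}")
        r, p = scipy.stats.pearsonr(fd.fd, col)
        rows.append((lab, r, p))
    return pd.DataFrame(rows, columns=["roi", "r", "p"]).set_index("roi")


def mean_fd_bold_correlation(
    mean_fds: np.ndarray, subject_roi_means: np.ndarray,
    roi_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Across-subject variant: per-subject mean FD against per-subject mean
    ROI signal (one row per subject)."""
    mean_fds = np.asarray(mean_fds, dtype=float)
    X = np.asarray(subject_roi_means, dtype=float)
    if X.ndim != 2 or X.shape[0] != mean_fds.size:
        raise ValidationError("need one row of ROI means per subject")
    if mean_fds.size < 3:
        raise ValidationError("need at least 3 subjects")
    labels = roi_labels or [f"ROI_{i}" for i in range(X.shape[1])]
    rows = []
    for i, lab in enumerate(labels):
        r, p = scipy.stats.pearsonr(mean_fds, X[:, i])
        rows.append((lab, r, p))
    return pd.DataFrame(rows, columns=["roi", "r", "p"]).set_index("roi")


def rm_anova(values: np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA.

    ``values`` is a complete windows-by-networks matrix (rows are the
    repeated measurement unit).  F = MS_condition / MS_error after removing
    the row (window) main effect; df1 = k-1, df2 = (k-1)(n-1).  A zero
    between-condition sum of squares gives F = 0 by convention (this covers
    the degenerate identical-columns case where MS_error is also zero).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValidationError("input must be a 2-D windows x networks matrix")
    n, k = x.shape
    if k < 2 or n < 2:
        raise ValidationError("need >= 2 networks and >= 2 windows")
    if not np.all(np.isfinite(x)):
        raise ValidationError("missing or non-finite cells")
    grand = x.mean()
    ss_cond = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    scale = max(ss_tot, 1.0)
    if ss_cond <= 1e-12 * scale:
        return AnovaResult(F=0.0, df1=df1, df2=df2, p=1.0)
    if ss_err <= 1e-12 * scale:
        return AnovaResult(F=np.inf, df1=df1, df2=df2, p=0.0)
    F = (ss_cond / df1) / (ss_err / df2)
    return AnovaResult(F=float(F), df1=df1, df2=df2,
                       p=float(scipy.stats.f.sf(F, df1, df2)))


def paired_ttest(
    a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, int, float]:
    """Paired t-test on a - b; returns (t, df, p) with df = n - 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("need two equal-length 1-D vectors of size >= 2")
    d = a - b
    s = d.std(ddof=1)
    # relative guard: a constant shift leaves only rounding noise in d
    if s == 0 or s < 1e-10 * np.abs(d.mean()):
        raise ValidationError(
            "zero variance of paired differences; t statistic undefined"
        )
    res = scipy.stats.ttest_rel(a, b, alternative=alternative)
    return float(res.statistic), a.size - 1, float(res.pvalue)
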