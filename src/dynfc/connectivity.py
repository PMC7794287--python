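"""Static and sliding-window correlation networks with FDR thresholding.

The static pipeline z-scores the (optionally subject-concatenated) ROI time
series, computes the Pearson correlation matrix with two-sided p-values from
the exact t transform t = r*sqrt((n-2)/(1-r^2)), df = n-2, and applies
Benjamini-Hochberg FDR control over the R(R-1)/2 upper-triangle p-values;
edges that do not survive are set to zero while survivors keep their signed
r value.  The dynamic pipeline repeats this inside overlapping sliding
windows (44 s or 66 s at TR = 2 s, step 1 TR) and can average windows in
contiguous quarters for coarse-grained inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io_formats import NETWORK_NAMES, RoiTimeSeries, ValidationError

__all__ = [
    "CorrelationResult",
    "WindowSpec",
    "WindowedConnectivity",
    "QuarterAverage",
    "zscore",
    "split_halves",
    "concat_subjects",
    "pearson_with_pvalues",
    "fdr_threshold",
    "static_connectivity",
    "make_windows",
    "windowed_connectivity",
    "quarter_group_sizes",
    "quarter_average",
    "network_average",
]


@dataclass
class CorrelationResult:
    """Pearson correlation matrix with p-values and FDR-thresholded copy.

    ``thresholded`` is ``None`` until :func:`fdr_threshold` fills it; then
    every entry is either 0 (did not survive) or the original signed r, the
    matrix is symmetric, and the diagonal is 0 for graph use.
    """

    r: np.ndarray
    p: np.ndarray
    n_samples: int
    labels: list[str]
    thresholded: np.ndarray | None = None

    @property
    def n_rois(self) -> int:
        return self.r.shape[0]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window index arithmetic.

    Windows of ``window_vols`` volumes start at 0-based volume indices
    ``starts`` spaced ``step_vols`` apart; the number of windows is
    floor((n_vols - window_vols)/step_vols) + 1.
    """

    window_s: float
    window_vols: int
    step_vols: int
    n_vols: int
    tr_s: float

    @property
    def starts(self) -> np.ndarray:
        return np.arange(
            0, self.n_vols - self.window_vols + 1, self.step_vols
        )

    @property
    def n_windows(self) -> int:
        return (self.n_vols - self.window_vols) // self.step_vols + 1

    def start_seconds(self, one_based: bool = True) -> np.ndarray:
        """Start time of each window in seconds (1-based by convention)."""
        t = self.starts * self.tr_s
        return t + 1.0 if one_based else t


@dataclass
class WindowedConnectivity:
    spec: WindowSpec
    results: list[CorrelationResult]
    tr_s: float

    def __post_init__(self) -> None:
        if len(self.results) != self.spec.n_windows:
            raise ValidationError(
                f"{len(self.results)} window results for a spec with "
                f"{self.spec.n_windows} windows"
            )


@dataclass
class QuarterAverage:
    """One quarter-averaged window: mean r over member windows, re-thresholded."""

    result: CorrelationResult
    label: str
    window_indices: range


def zscore(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Standardize each ROI column to mean 0, sample SD 1 (ddof=1).

    Pearson correlation is invariant to this, so the choice of ddof does not
    affect any downstream result; it is fixed here for reproducibility.
    """
    sd = ts.data.std(axis=0, ddof=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValidationError(
            f"zero-variance ROI column(s): {[ts.roi_labels[i] for i in flat]}"
        )
    return ts.with_data((ts.data - ts.data.mean(axis=0)) / sd)


def split_halves(ts: RoiTimeSeries) -> tuple[RoiTimeSeries, RoiTimeSeries]:
    """Split a run into two equal halves (e.g. a 504 s task run into two
    252 s sessions); concatenating the halves restores the input."""
    n = ts.n_vols
    if n % 2:
        raise ValidationError(f"cannot halve an odd number of volumes ({n})")
    h = n // 2
    return (
        ts.with_data(ts.data[:h], session_id="task1"),
        ts.with_data(ts.data[h:], session_id="task2"),
    )


def concat_subjects(series: list[RoiTimeSeries]) -> RoiTimeSeries:
    """Row-stack the time series of several subjects into one group series."""
    if not series:
        raise ValidationError("no series to concatenate")
    first = series[0]
    for s in series[1:]:
        if s.roi_labels != first.roi_labels:
            raise ValidationError("ROI labels differ between subjects")
        if s.tr_s != first.tr_s:
            raise ValidationError("TR differs between subjects")
        if s.session_id != first.session_id:
            raise ValidationError("session_id differs between subjects")
    return first.with_data(
        np.vstack([s.data for s in series]), subject_id="group"
    )


def _pearson_p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for the null r=0 via t = r*sqrt((n-2)/(1-r^2)), df = n-2."""
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return p


def pearson_with_pvalues(ts: RoiTimeSeries) -> CorrelationResult:
    """Full Pearson correlation matrix with element-wise two-sided p-values.

    The diagonal p is set to 0 and is never entered into FDR correction.
    """
    n = ts.n_vols
    if n < 3:
        raise ValidationError(f"need at least 3 samples for p-values, got {n}")
    sd = ts.data.std(axis=0, ddof=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValidationError(
            f"zero-variance ROI column(s): {[ts.roi_labels[i] for i in flat]}"
        )
    r = np.corrcoef(ts.data, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    # exact linear dependence can land at 1 - O(eps) through corrcoef's
    # arithmetic; snap so it reports r = +-1, p = 0
    r[np.abs(r) > 1.0 - 1e-14] = np.sign(r[np.abs(r) > 1.0 - 1e-14])
    np.fill_diagonal(r, 1.0)
    p = _pearson_p_from_r(r, n)
    np.fill_diagonal(p, 0.0)
    return CorrelationResult(r=r, p=p, n_samples=n, labels=list(ts.roi_labels))


def fdr_threshold(result: CorrelationResult, q: float = 0.05) -> CorrelationResult:
    """Benjamini-Hochberg FDR over the upper-triangle p-values.

    Surviving entries keep their signed correlation (negative edges survive
    too); all others are set to zero.  The output matrix is symmetric with a
    zero diagonal so it can be used directly as a graph adjacency matrix.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    iu = np.triu_indices(result.n_rois, k=1)
    reject, _, _, _ = multipletests(result.p[iu], alpha=q, method="fdr_bh")
    thr = np.zeros_like(result.r)
    thr[iu] = np.where(reject, result.r[iu], 0.0)
    thr = thr + thr.T
    return replace(result, thresholded=thr)


def static_connectivity(ts: RoiTimeSeries, q: float = 0.05) -> CorrelationResult:
    """Convenience: z-score, correlate, and FDR-threshold one session."""
    return fdr_threshold(pearson_with_pvalues(zscore(ts)), q=q)


def make_windows(
    n_vols: int, window_s: float, tr_s: float, step_vols: int = 1
) -> WindowSpec:
    """Build the sliding-window specification for a session.

    For a 252 s session at TR = 2 s (126 volumes) a 44 s window with step
    1 TR gives 105 windows and a 66 s window gives 94; a 180 s rest session
    (90 volumes) gives 69 and 58.
    """
    w = window_s / tr_s
    if abs(w - round(w)) > 1e-9:
        raise ValidationError(
            f"window_s = {window_s} is not a whole number of TRs (TR {tr_s} s)"
        )
    window_vols = int(round(w))
    if window_vols < 2:
        raise ValidationError("window must span at least 2 volumes")
    if step_vols < 1:
        raise ValidationError("step_vols must be >= 1")
    if window_vols > n_vols:
        raise ValidationError(
            f"window of {window_vols} volumes exceeds series length {n_vols}"
        )
    return WindowSpec(
        window_s=window_s,
        window_vols=window_vols,
        step_vols=step_vols,
        n_vols=n_vols,
        tr_s=tr_s,
    )


def windowed_connectivity(
    ts: RoiTimeSeries | list[RoiTimeSeries],
    spec: WindowSpec,
    q: float = 0.05,
) -> WindowedConnectivity:
    """Per-window FDR-thresholded correlation matrices.

    With a single subject, window w correlates that subject's
    ``window_vols`` volumes.  With a list of subjects (group mode) the
    volumes of window w from every subject are row-stacked and correlated
    once, so the sample size per window is n_subjects * window_vols and
    df = samples - 2.  FDR is applied independently within each window.
    """
    subjects = ts if isinstance(ts, list) else [ts]
    first = subjects[0]
    for s in subjects:
        if s.n_vols != spec.n_vols:
            raise ValidationError(
                f"subject {s.subject_id} has {s.n_vols} volumes, spec expects "
                f"{spec.n_vols}"
            )
        if s.roi_labels != first.roi_labels:
            raise ValidationError("ROI labels differ between subjects")
    results = []
    for w, start in enumerate(spec.starts):
        sl = slice(start, start + spec.window_vols)
        stacked = np.vstack([s.data[sl] for s in subjects])
        win_ts = first.with_data(stacked, subject_id="window")
        try:
            results.append(fdr_threshold(pearson_with_pvalues(win_ts), q=q))
        except ValidationError as err:
            raise ValidationError(f"window {w} (start volume {start}): {err}")
    return WindowedConnectivity(spec=spec, results=results, tr_s=spec.tr_s)


def quarter_group_sizes(n_windows: int) -> tuple[int, int, int, int]:
    """Contiguous quarter sizes: round-half-away-from-zero(n/4) for the
    first three groups, remainder in the fourth.

    105 -> (26, 26, 26, 27); 69 -> (17, 17, 17, 18);
    94 -> (24, 24, 24, 22); 58 -> (15, 15, 15, 13).
    """
    if n_windows < 4:
        raise ValidationError(f"need at least 4 windows, got {n_windows}")
    g = int(np.floor(n_windows / 4.0 + 0.5))
    return (g, g, g, n_windows - 3 * g)


def quarter_average(
    wc: WindowedConnectivity, q: float = 0.05
) -> list[QuarterAverage]:
    """Average the windows in contiguous quarters and re-threshold.

    Raw r matrices are averaged element-wise within each quarter, the
    member windows' p-values are combined with Fisher's method, and BH-FDR
    is re-applied to the combined p.  Each quarter is labelled with the
    1-based start-second range of its first and last member window
    (e.g. "1-51" for the first quarter of 105 windows at TR 2 s).
    """
    sizes = quarter_group_sizes(wc.spec.n_windows)
    starts_s = wc.spec.start_seconds(one_based=True)
    out = []
    offset = 0
    for size in sizes:
        members = range(offset, offset + size)
        offset += size
        r_avg = np.mean([wc.results[i].r for i in members], axis=0)
        p_stack = np.stack([wc.results[i].p for i in members])
        with np.errstate(divide="ignore"):
            fisher = -2.0 * np.sum(np.log(p_stack), axis=0)
        p_comb = scipy.stats.chi2.sf(fisher, df=2 * size)
        np.fill_diagonal(p_comb, 0.0)
        res = CorrelationResult(
            r=r_avg,
            p=p_comb,
            n_samples=wc.results[members[0]].n_samples,
            labels=wc.results[0].labels,
        )
        res = fdr_threshold(res, q=q)
        label = f"{starts_s[members[0]]:.0f}-{starts_s[members[-1]]:.0f}"
        out.append(QuarterAverage(result=res, label=label, window_indices=members))
    return out


def network_average(ts: RoiTimeSeries, table) -> RoiTimeSeries:
    """Average member-ROI signals per network (32 ROI columns -> 8 networks).

    ``table`` is an ROI definition table with ``label`` and ``network``
    columns; every column of ``ts`` must appear in it.  Output columns
    follow the canonical network order (DMN, SMN, Visual, SN, DA, FP, LN,
    CN), restricted to networks actually present.
    """
    net_of = dict(zip(table["label"], table["network"]))
    unknown = [lab for lab in ts.roi_labels if lab not in net_of]
    if unknown:
        raise ValidationError(f"ROI labels not in table: {unknown}")
    present = [n for n in NETWORK_NAMES if n in {net_of[l] for l in ts.roi_labels}]
    cols = []
    for net in present:
        idx = [i for i, lab in enumerate(ts.roi_labels) if net_of[lab] == net]
        cols.append(ts.data[:, idx].mean(axis=1))
    return ts.with_data(np.column_stack(cols), roi_labels=present)
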