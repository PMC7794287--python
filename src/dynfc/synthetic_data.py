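"""Synthetic multi-ROI BOLD with planted, time-switching community structure.

The generator produces ROI-by-time signal matrices whose pairwise Pearson
correlations follow a planted block structure: within each scheduled time
segment, ROIs sharing a community have expected correlation ``within_r`` and
ROIs in different communities have expected correlation ``between_r``.  The
signal model is a per-community latent Gaussian factor plus a global factor
plus independent ROI noise; the mixing weights are solved analytically from
the target correlations, so the targets hold in expectation *including* the
noise term.  Community structure switches instantaneously at segment
boundaries — there is no transition smoothing — which keeps the planted
ground truth unambiguous for recovery tests.

A simulated-motion generator (reflected Gaussian random walk on the six
rigid-body parameters) provides input for the framewise-displacement QC
stage, and :func:`make_fixture_roi_table` returns the 32-ROI / 8-network
seed-region table used for network-level grouping.

None of this emulates haemodynamics: there is no HRF convolution, no
physiological noise, and no image-space simulation.  The downstream pipeline
operates on arbitrary ROI series, so none of that is needed to exercise it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MotionTrace, RoiTimeSeries, validate_roi_table

__all__ = [
    "SimConfig",
    "PartitionSchedule",
    "ScheduleError",
    "ConfigError",
    "simulate_roi_bold",
    "simulate_motion",
    "amplitude_for_mean_fd",
    "make_fixture_roi_table",
    "block_partition",
    "constant_schedule",
    "switching_schedule",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class ScheduleError(ValueError):
    """Invalid partition schedule (gap, overlap, or incomplete assignment)."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation dimensions and noise level.

    Defaults mirror the acquisition this pipeline targets: 32 seed ROIs,
    TR = 2 s, and a 252 s session (one half of a 504 s task run; a
    resting-state session is 180 s).
    """

    n_rois: int = 32
    tr_s: float = 2.0
    duration_s: float = 252.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 1:
            raise ConfigError("n_rois must be >= 1")
        if not self.tr_s > 0:
            raise ConfigError("tr_s must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        n = self.duration_s / self.tr_s
        if not (n > 0 and abs(n - round(n)) < 1e-9):
            raise ConfigError(
                f"duration_s/tr_s = {n} is not a positive integer volume count"
            )

    @property
    def n_vols(self) -> int:
        return int(round(self.duration_s / self.tr_s))


@dataclass(frozen=True)
class PartitionSchedule:
    """Planted community structure over time.

    ``segments`` is an ordered list of ``(start_s, end_s, assignment)``
    triples that must tile ``[0, duration)`` without gap or overlap;
    ``assignment`` maps every ROI index to a community id.  ``within_r`` and
    ``between_r`` are the target pairwise Pearson correlations for
    same-community and different-community ROI pairs (0 <= between_r <
    within_r <= 1; within_r = 1 is only attainable with noise_sd = 0).
    """

    segments: tuple[tuple[float, float, dict[int, int]], ...]
    within_r: float = 0.8
    between_r: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.between_r < self.within_r <= 1.0):
            raise ScheduleError(
                f"need 0 <= between_r < within_r <= 1, got "
                f"between_r={self.between_r}, within_r={self.within_r}"
            )
        if not self.segments:
            raise ScheduleError("schedule has no segments")

    def validate_against(self, config: SimConfig) -> None:
        """Check the segments tile [0, duration) and assign every ROI."""
        t = 0.0
        for start, end, assignment in self.segments:
            if abs(start - t) > 1e-9:
                raise ScheduleError(
                    f"segment starts at {start} s but previous ended at {t} s "
                    "(gap or overlap)"
                )
            if end <= start:
                raise ScheduleError(f"segment [{start}, {end}) is empty")
            n_seg = (end - start) / config.tr_s
            if abs(n_seg - round(n_seg)) > 1e-9:
                raise ScheduleError(
                    f"segment [{start}, {end}) is not a whole number of volumes"
                )
            if set(assignment) != set(range(config.n_rois)):
                raise ScheduleError(
                    f"segment [{start}, {end}) does not assign every ROI "
                    f"0..{config.n_rois - 1}"
                )
            t = end
        if abs(t - config.duration_s) > 1e-9:
            raise ScheduleError(
                f"schedule covers [0, {t}) but config duration is "
                f"{config.duration_s} s"
            )


def block_partition(n_rois: int, n_communities: int) -> dict[int, int]:
    """Assign ROIs to ``n_communities`` contiguous equal-as-possible blocks."""
    if not 1 <= n_communities <= n_rois:
        raise ValueError("need 1 <= n_communities <= n_rois")
    bounds = np.linspace(0, n_rois, n_communities + 1).round().astype(int)
    out: dict[int, int] = {}
    for c in range(n_communities):
        for i in range(bounds[c], bounds[c + 1]):
            out[i] = c
    return out


def constant_schedule(
    config: SimConfig,
    assignment: dict[int, int],
    within_r: float = 0.8,
    between_r: float = 0.0,
) -> PartitionSchedule:
    """A schedule with one planted partition held for the whole run."""
    return PartitionSchedule(
        segments=((0.0, config.duration_s, dict(assignment)),),
        within_r=within_r,
        between_r=between_r,
    )


def switching_schedule(
    config: SimConfig,
    switch_s: float,
    before: dict[int, int],
    after: dict[int, int],
    within_r: float = 0.8,
    between_r: float = 0.0,
) -> PartitionSchedule:
    """A schedule with one instantaneous partition switch at ``switch_s``."""
    return PartitionSchedule(
        segments=(
            (0.0, switch_s, dict(before)),
            (switch_s, config.duration_s, dict(after)),
        ),
        within_r=within_r,
        between_r=between_r,
    )


def _mixing_weights(within_r: float, between_r: float, noise_sd: float):
    """Solve factor loadings so achieved correlations equal the targets.

    Signal: x_i = a*global + c*community_factor + noise_sd*eps_i, all factors
    i.i.d. standard normal.  Total variance v = a^2 + c^2 + noise_sd^2;
    within-community correlation (a^2 + c^2)/v = within_r and
    between-community correlation a^2/v = between_r give
    a^2 = between_r*s2/within_r? — solved directly below from
    s2 = a^2 + c^2 = noise_sd^2 * within_r / (1 - within_r).
    """
    if noise_sd == 0.0:
        if within_r != 1.0:
            raise ConfigError(
                "noise_sd = 0 forces perfect within-community correlation; "
                "set within_r = 1 (or use noise_sd > 0)"
            )
        # v = 1 by construction: a^2 = between_r, c^2 = 1 - between_r.
        return math.sqrt(between_r), math.sqrt(1.0 - between_r)
    if within_r == 1.0:
        raise ConfigError("within_r = 1 is only attainable with noise_sd = 0")
    s2 = noise_sd**2 * within_r / (1.0 - within_r)
    a2 = s2 * between_r / within_r
    c2 = s2 - a2
    return math.sqrt(a2), math.sqrt(c2)


def simulate_roi_bold(
    config: SimConfig,
    schedule: PartitionSchedule,
    roi_labels: list[str] | None = None,
    session_id: str = "custom",
    subject_id: str = "sim-01",
) -> RoiTimeSeries:
    """Generate a volumes-by-ROIs matrix with planted block correlation.

    Deterministic given ``config.seed``.  Within each schedule segment the
    expected pairwise correlation of same-community ROIs is
    ``schedule.within_r`` and of different-community ROIs ``schedule.between_r``.
    """
    schedule.validate_against(config)
    a, c = _mixing_weights(schedule.within_r, schedule.between_r, config.noise_sd)
    rng = np.random.default_rng(config.seed)
    blocks = []
    for start, end, assignment in schedule.segments:
        n_seg = int(round((end - start) / config.tr_s))
        comm = np.array([assignment[i] for i in range(config.n_rois)])
        comm_ids = np.unique(comm)
        g = rng.standard_normal((n_seg, 1))
        z = rng.standard_normal((n_seg, comm_ids.size))
        col_of = {cid: j for j, cid in enumerate(comm_ids)}
        z_per_roi = z[:, [col_of[cid] for cid in comm]]
        eps = rng.standard_normal((n_seg, config.n_rois))
        blocks.append(a * g + c * z_per_roi + config.noise_sd * eps)
    data = np.vstack(blocks)
    if roi_labels is None:
        width = len(str(config.n_rois - 1))
        roi_labels = [f"ROI_{i:0{width}d}" for i in range(config.n_rois)]
    return RoiTimeSeries(
        data=data,
        tr_s=config.tr_s,
        roi_labels=roi_labels,
        subject_id=subject_id,
        session_id=session_id,
    )


#: Scale factor between the per-step SD of the motion random walk and the
#: resulting mean Power FD: each of the six parameter streams contributes
#: E|N(0, sd^2)| = sd*sqrt(2/pi) per step (rotations are drawn with SD
#: amplitude/50 rad so that the 50 mm head-radius weighting makes their
#: millimetre contribution equal to a translation's).
_FD_PER_AMPLITUDE = 6.0 * math.sqrt(2.0 / math.pi)

TRANSLATION_BOUND_MM = 5.0
ROTATION_BOUND_RAD = 0.1


def amplitude_for_mean_fd(target_mean_fd_mm: float) -> float:
    """Per-step amplitude giving an expected mean Power FD of the target."""
    if target_mean_fd_mm < 0:
        raise ValueError("target mean FD must be >= 0")
    return target_mean_fd_mm / _FD_PER_AMPLITUDE


def simulate_motion(
    n_vols: int,
    amplitude_mm: float,
    seed: int,
    tr_s: float = 2.0,
) -> MotionTrace:
    """Reflected Gaussian random-walk head motion.

    Translation steps are N(0, amplitude_mm^2) mm, rotation steps
    N(0, (amplitude_mm/50)^2) rad; trajectories are reflected at +-5 mm and
    +-0.1 rad so long runs stay at realistic magnitudes.  Deterministic given
    ``seed``.  With ``amplitude_mm = 0`` the trace is identically zero.
    """
    if n_vols < 2:
        raise ValueError("n_vols must be >= 2 (FD is undefined otherwise)")
    if amplitude_mm < 0:
        raise ValueError("amplitude_mm must be >= 0")
    rng = np.random.default_rng(seed)
    steps = np.zeros((n_vols, 6))
    steps[1:, :3] = rng.standard_normal((n_vols - 1, 3)) * amplitude_mm
    steps[1:, 3:] = rng.standard_normal((n_vols - 1, 3)) * (amplitude_mm / 50.0)
    walk = np.cumsum(steps, axis=0)
    bounds = np.array([TRANSLATION_BOUND_MM] * 3 + [ROTATION_BOUND_RAD] * 3)
    # Reflect into [-b, b]: fold the walk with period 4b.
    folded = np.mod(walk + bounds, 4.0 * bounds)
    reflected = np.where(folded > 2.0 * bounds, 4.0 * bounds - folded, folded)
    return MotionTrace(data=reflected - bounds, tr_s=tr_s)


# The 32 seed regions of interest grouped into 8 canonical functional
# networks, with Brodmann area and MNI coordinates (mm).  Region names that
# occur more than once carry a parenthesised disambiguator in the label; the
# ``alias`` column holds the conventional short node names (mPFC, LP_L, ...).
_ROI_ROWS = [
    # label, hemisphere, network, BA, x, y, z, alias
    ("R Medial frontal (orbito)", "R", "DMN", 17, 1, 55, -3, "mPFC"),
    ("L Middle occipital (DMN)", "L", "DMN", 18, -39, -77, 33, "LP_L"),
    ("R Angular", "R", "DMN", 39, 47, -67, 29, "LP_R"),
    ("R Precuneus", "R", "DMN", 7, 1, -61, 38, "PCC"),
    ("L Postcentral", "L", "SMN", 312, -55, -12, 29, "SMR_L"),
    ("R Postcentral", "R", "SMN", 312, 56, -10, 29, "SMR_R"),
    ("R Paracentral", "R", "SMN", 312, 0, -31, 67, "SMR_Superior"),
    ("R Calcarine (medial)", "R", "Visual", 17, 2, -79, 12, "Visual_Medial"),
    ("R Calcarine (occipital)", "R", "Visual", 17, 0, -93, -4, "Visual_Occipital"),
    ("L Middle occipital (Visual)", "L", "Visual", 18, -37, -79, 10, "Visual_lateral_L"),
    ("R Middle occipital", "R", "Visual", 18, 38, -72, 13, "Visual_lateral_R"),
    ("R Middle cingulate cortex", "R", "SN", 25, 0, 22, 35, "ACC"),
    ("L Insula", "L", "SN", 13, -44, 13, 1, "AInsula_L"),
    ("R Insula", "R", "SN", 13, 47, 14, 0, "AInsula_R"),
    ("L Middle frontal (SN)", "L", "SN", 46, -32, 45, 27, "rPFC_L"),
    ("R Middle frontal (SN)", "R", "SN", 46, 32, 46, 27, "rPFC_R"),
    ("L Supra-marginal", "L", "SN", 40, -60, -39, 31, "SMG_L"),
    ("R Supra-marginal", "R", "SN", 40, 62, -35, 32, "SMG_R"),
    ("L Superior frontal (dorsal)", "L", "DA", 6, -27, -9, 64, "FEF_L"),
    ("R Superior frontal (dorsal)", "R", "DA", 6, 30, -6, 64, "FEF_R"),
    ("L Inferior parietal (DA)", "L", "DA", 40, -39, -43, 52, "IPS_L"),
    ("R Inferior parietal (DA)", "R", "DA", 40, 39, -42, 54, "IPS_R"),
    ("L Middle frontal (FP)", "L", "FP", 46, -43, 33, 28, "LPFC_L"),
    ("L Inferior parietal (FP)", "L", "FP", 40, -46, -58, 49, "PPC_L"),
    ("R Middle frontal (FP)", "R", "FP", 46, 41, 38, 30, "LPFC_R"),
    ("R Inferior parietal (FP)", "R", "FP", 40, 52, -52, 45, "PPC_R"),
    ("L Inferior frontal (triangular)", "L", "LN", 45, -51, 26, 2, "IFG_L"),
    ("R Inferior frontal (triangular)", "R", "LN", 45, 54, 28, 1, "IFG_R"),
    ("L Superior temporal", "L", "LN", 22, -57, -47, 15, "pSTG_L"),
    ("R Superior temporal", "R", "LN", 22, 59, -42, 13, "pSTG_R"),
    ("R Vermis", "R", "CN", None, 0, -63, -30, "Cereb_Ant"),
    ("R Cerebellum", "R", "CN", None, 0, -79, -32, "Cereb_Post"),
]


def make_fixture_roi_table() -> pd.DataFrame:
    """The 32-ROI seed-region table spanning 8 functional brain networks.

    Columns: label, hemisphere, network, brodmann_area (pandas nullable
    integer; the postcentral/paracentral rows carry the composite Brodmann
    area 3-1-2 stored as 312, cerebellar rows have none), MNI x/y/z (mm),
    and alias (short node name).
    """
    df = pd.DataFrame(
        _ROI_ROWS,
        columns=["label", "hemisphere", "network", "brodmann_area",
                 "x", "y", "z", "alias"],
    )
    df["brodmann_area"] = df["brodmann_area"].astype("Int64")
    return validate_roi_table(df)
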