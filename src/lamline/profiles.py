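"""Collapse evoked responses over time into cortical-depth profiles.

The main statistic is *template weighting*: the group-average center-stimulus
response (averaged over participants and depths) serves as a reference time
course h_T, and each depth's evoked time course h_d is projected onto it,

    profile(d) = sum_t h_d(t) * h_T(t) / sum_t h_T(t),

yielding a per-depth scaling factor that measures how strongly the canonical
response shape is expressed at that depth.  This is robust to response-latency
variability, unlike a fixed 5-7 s magnitude window (also provided, as
``window_average``).  Participant profiles are variance-normalized by
subtracting each participant's own depth-mean and adding back the grand mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import DEPTH_GRID, N_DEPTH_GRID, DepthProfile


@dataclass
class ResponseTemplate:
    """Reference evoked time course (group-average center response)."""

    values: np.ndarray
    tr: float
    window_start: float = -2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def times(self) -> np.ndarray:
        return self.window_start + np.arange(self.values.size) * self.tr


def build_template(
    center_responses: list[np.ndarray], tr: float, window_start: float = -2.0
) -> ResponseTemplate:
    """Group template: center evoked responses (20 x time, one per
    participant) averaged over participants and depths."""
    if not center_responses:
        raise ValueError("need at least one participant response")
    stack = np.stack([np.asarray(r, dtype=float) for r in center_responses])
    template = stack.mean(axis=(0, 1))
    if np.allclose(template, 0.0):
        warnings.warn("group template is (near) zero", stacklevel=2)
    return ResponseTemplate(values=template, tr=tr, window_start=window_start)


def template_weighting(
    depth_timecourses: np.ndarray, template: ResponseTemplate, condition: str | None = None
) -> DepthProfile:
    """Project per-depth time courses onto the template: the weighted average
    sum(h_d * h_T) / sum(h_T) per depth."""
    h = np.asarray(depth_timecourses, dtype=float)
    if h.shape[-1] != template.values.size:
        raise ValueError("time axes of responses and template differ")
    denom = float(np.sum(template.values))
    if abs(denom) < 1e-12:
        raise ValueError("degenerate template: sum of template values is zero")
    return DepthProfile(values=h @ template.values / denom, condition=condition)


def window_average(
    depth_timecourses: np.ndarray,
    tr: float,
    window: tuple[float, float] = (5.0, 7.0),
    window_start: float = -2.0,
    condition: str | None = None,
) -> DepthProfile:
    """Per-depth mean over the post-onset magnitude window (default 5-7 s)."""
    h = np.asarray(depth_timecourses, dtype=float)
    times = window_start + np.arange(h.shape[-1]) * tr
    sel = (times >= window[0]) & (times <= window[1])
    if not np.any(sel):
        raise ValueError("magnitude window contains no samples")
    return DepthProfile(values=h[:, sel].mean(axis=1), condition=condition)


def normalize_across_participants(profiles: np.ndarray) -> np.ndarray:
    """Subtract each participant's own depth-mean, add back the grand mean.

    ``profiles`` is participant x depth; removes between-participant offset
    variance while preserving the group mean profile exactly.
    """
    arr = np.asarray(profiles, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    grand = arr.mean()
    return arr - arr.mean(axis=1, keepdims=True) + grand


def depth_by_time(
    participant_timecourses: np.ndarray,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Group-mean depth x time matrix with 95% confidence half-widths.

    ``participant_timecourses`` is participant x 20 x time.  CI half-width is
    1.96 * sd / sqrt(n); omitted (None) with a warning when n = 1.
    """
    arr = np.asarray(participant_timecourses, dtype=float)
    if arr.ndim != 3 or arr.shape[1] != N_DEPTH_GRID:
        raise ValueError(f"expected participant x {N_DEPTH_GRID} x time array")
    mean = arr.mean(axis=0)
    n = arr.shape[0]
    if n < 2:
        warnings.warn("confidence interval undefined for a single participant",
                      stacklevel=2)
        return mean, None, None
    half = 1.96 * arr.std(axis=0, ddof=1) / np.sqrt(n)
    return mean, mean - half, mean + half
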