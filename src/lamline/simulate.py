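"""Synthetic line-scanning session generator with known laminar ground truth.

Emulates an event-related line-scanning fMRI run: three stimulus conditions
(center disc, medium annulus, large annulus), five 2-s presentations per
condition per run, inter-stimulus intervals jittered with a truncated
negative-exponential distribution (min/max/mean = 14/24/18 s), a ~42 s dummy
period plus 30 s baseline, and a depth line sampled every 0.25 mm at
TR = 0.105 s with a 6-10 sample gray-matter ribbon.

Each condition carries a distinct ground-truth laminar amplitude profile
(percent signal change as a function of normalized depth, 0 = pial,
1 = white matter):

* center  — amplitude increasing toward the pial surface with a small bump at
  middle depths (feedforward signature plus draining-vein gradient);
* large   — positive peaks at superficial (0.25) and deep (0.75) depths and a
  negative deflection at middle depths (contextual signature);
* medium  — a configurable mixture of the two.

An optional unidirectional leakage (draining-vein) forward model mixes signal
from deeper bins into more superficial ones, and the noise model adds AR(1)
temporal noise, white noise, and slow cosine drift.  Everything is seeded and
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import gamma as gamma_dist

CONDITIONS = ("center", "medium", "large")

#: paradigm timing constants (seconds)
ISI_MIN, ISI_MAX, ISI_MEAN = 14.0, 24.0, 18.0
STIM_DURATION = 2.0
DUMMY = 42.0
BASELINE = 30.0
RUN_LENGTH = 420.0  # 7 min
EVENTS_PER_CONDITION = 5

TR = 0.105
DEPTH_STEP_MM = 0.25
ECHO_TIMES_MS = (6.0, 14.0, 22.0, 30.0, 38.0)


# --------------------------------------------------------------------------
# paradigm


@dataclass
class Paradigm:
    """Event table for one run: onsets (s), fixed 2-s durations, conditions."""

    events: pd.DataFrame  # columns onset, duration, trial_type
    timing_variant: int
    run_length: float = RUN_LENGTH
    dummy: float = DUMMY
    baseline: float = BASELINE

    def onsets(self, condition: str | None = None) -> np.ndarray:
        ev = self.events
        if condition is not None:
            ev = ev[ev["trial_type"] == condition]
        return ev["onset"].to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        self.events.to_csv(path, sep="\t", index=False)

    @staticmethod
    def from_tsv(path: str | Path, timing_variant: int = 1) -> "Paradigm":
        ev = pd.read_csv(path, sep="\t")
        return Paradigm(events=ev, timing_variant=timing_variant)


@lru_cache(maxsize=32)
def _trunc_exp_scale(mean_excess: float, cap: float) -> float:
    """Scale of an exponential truncated at ``cap`` whose mean is ``mean_excess``.

    The truncated mean is ``beta - cap/(exp(cap/beta) - 1)``, solved for beta.
    """
    if not 0 < mean_excess < cap / 2:
        # truncated-exponential mean lies in (0, cap/2); cap/2 is the uniform limit
        raise ValueError("target mean infeasible for a truncated exponential")

    def f(beta: float) -> float:
        with np.errstate(over="ignore"):  # cap/beta overflow -> truncation term 0
            return beta - cap / np.expm1(cap / beta) - mean_excess

    return brentq(f, 1e-3, 1e3)


def sample_isis(
    n: int,
    isi_min: float = ISI_MIN,
    isi_max: float = ISI_MAX,
    isi_mean: float = ISI_MEAN,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw jittered inter-stimulus intervals from min + truncated exponential.

    The exponential scale is solved numerically so that the truncated mean
    equals ``isi_mean``; every draw lies in [isi_min, isi_max].
    """
    if not isi_min < isi_mean < isi_max:
        raise ValueError("need isi_min < isi_mean < isi_max")
    if n == 0:
        return np.array([])
    rng = np.random.default_rng(rng)
    cap = isi_max - isi_min
    beta = _trunc_exp_scale(isi_mean - isi_min, cap)
    u = rng.random(n)
    # inverse CDF of the exponential truncated at cap
    excess = -beta * np.log1p(-u * (-np.expm1(-cap / beta)))
    return isi_min + excess


def build_paradigm(
    variant: int,
    seed: int | None = 0,
    conditions: Sequence[str] = CONDITIONS,
    events_per_condition: int = EVENTS_PER_CONDITION,
    max_retries: int = 50,
) -> Paradigm:
    """Pseudorandom event schedule for one run, reproducible from (variant, seed).

    15 events (5 per condition) follow the dummy (42 s) and baseline (30 s)
    periods; ISIs are onset-to-onset and drawn from the truncated-exponential
    sampler.  The schedule must fit within the 7-min run with room for the
    14-s post-onset epoch window, otherwise ISIs are resampled.
    """
    if variant not in (1, 2):
        raise ValueError("timing variant must be 1 or 2")
    n_events = events_per_condition * len(conditions)
    rng = np.random.default_rng(None if seed is None else (seed, variant))
    order = np.repeat(np.asarray(conditions, dtype=object), events_per_condition)
    for _ in range(max_retries):
        perm = rng.permutation(n_events)
        isis = sample_isis(n_events - 1, rng=rng)
        onsets = DUMMY + BASELINE + np.concatenate([[0.0], np.cumsum(isis)])
        if onsets[-1] + 14.0 <= RUN_LENGTH:
            events = pd.DataFrame(
                {
                    "onset": onsets,
                    "duration": STIM_DURATION,
                    "trial_type": order[perm],
                }
            )
            return Paradigm(events=events, timing_variant=variant)
    raise RuntimeError("could not fit event schedule into the run length")


# --------------------------------------------------------------------------
# hemodynamics and ground truth


def double_gamma_hrf(tr: float = TR, duration: float = 32.0) -> np.ndarray:
    """Canonical two-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6), unit peak.

    Gamma shapes are delay + 1 at unit scale so the positive lobe's mode sits
    at exactly 6 s and the undershoot's at 16 s.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, duration, tr)
    peak = gamma_dist.pdf(t, a=7.0, scale=1.0)
    under = gamma_dist.pdf(t, a=17.0, scale=1.0)
    h = peak - under / 6.0
    return h / h.max()


@dataclass(frozen=True)
class GroundTruthProfile:
    """Known laminar amplitude profile for one condition.

    ``depth_fn`` maps normalized depth (0 = pial, 1 = white matter) to percent
    signal change at the response peak.
    """

    condition: str
    depth_fn: Callable[[np.ndarray], np.ndarray]
    amplitude: float

    def __call__(self, depth: np.ndarray | float) -> np.ndarray:
        return np.asarray(self.depth_fn(np.asarray(depth, dtype=float)))


def _unit_gauss(d: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-((d - mu) ** 2) / (2 * sigma**2))


#: default ground-truth amplitudes (percent signal change)
TRUTH_DEFAULTS = {
    "center": {"ramp": 1.5, "bump": 0.4, "bump_sigma": 0.1},
    "large": {"sup": 1.0, "deep": 0.8, "mid_dip": 0.5, "sigma": 0.12},
    "medium": {"mix": 0.5},
}


def make_ground_truth(condition: str, params: dict | None = None) -> GroundTruthProfile:
    """Ground-truth laminar profile for a condition.

    center: ramp*(1 - d) + bump*N(d; 0.5, 0.1) — superficial bias with a small
    middle-depth peak.  large: sup*N(d; 0.25, s) + deep*N(d; 0.75, s) -
    mid_dip*N(d; 0.5, s) — bimodal contextual profile with a negative middle
    deflection.  medium: mix*large + (1 - mix)*center.  N is a unit-max
    Gaussian.
    """
    defaults = {k: dict(v) for k, v in TRUTH_DEFAULTS.items()}
    if params:
        for k, v in params.items():
            defaults.setdefault(k, {}).update(v)

    if condition == "center":
        p = defaults["center"]

        def fn(d: np.ndarray) -> np.ndarray:
            return p["ramp"] * (1.0 - d) + p["bump"] * _unit_gauss(d, 0.5, p["bump_sigma"])

        amp = p["ramp"]
    elif condition == "large":
        p = defaults["large"]

        def fn(d: np.ndarray) -> np.ndarray:
            s = p["sigma"]
            return (
                p["sup"] * _unit_gauss(d, 0.25, s)
                + p["deep"] * _unit_gauss(d, 0.75, s)
                - p["mid_dip"] * _unit_gauss(d, 0.5, s)
            )

        amp = p["sup"]
    elif condition == "medium":
        mix = defaults["medium"]["mix"]
        f_c = make_ground_truth("center", params)
        f_l = make_ground_truth("large", params)

        def fn(d: np.ndarray) -> np.ndarray:
            return mix * f_l(d) + (1.0 - mix) * f_c(d)

        amp = mix * f_l.amplitude + (1 - mix) * f_c.amplitude
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return GroundTruthProfile(condition=condition, depth_fn=fn, amplitude=amp)


# --------------------------------------------------------------------------
# leakage (draining-vein) forward model


@dataclass
class LeakageMatrix:
    """Lower-triangular depth-mixing matrix of the draining-vein forward model.

    The matrix is stored with depth bins ordered from the white-matter
    boundary (row/column 0, uncontaminated) toward the pial surface (last
    row).  Venous drainage is unidirectional toward the surface, so measured
    signal at a bin is its local signal plus non-negative carry-over from
    deeper bins only: the upper triangle is zero and the diagonal positive.

    ``apply_leakage`` and ``deconvolve_profile`` accept signals in the
    package-wide pial-first depth order and handle the flip internally.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        L = np.asarray(self.matrix, dtype=float)
        if L.ndim != 2 or L.shape[0] != L.shape[1]:
            raise ValueError("leakage matrix must be square")
        if np.any(np.triu(L, 1) != 0):
            raise ValueError("leakage must be lower-triangular (drainage toward pial)")
        if np.any(np.diag(L) <= 0) or np.any(L < 0):
            raise ValueError("leakage entries must be >= 0 with positive diagonal")
        self.matrix = L

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def identity(cls, n: int) -> "LeakageMatrix":
        return cls(np.eye(n))

    @classmethod
    def from_carry_fraction(cls, n: int, lam: float = 0.3) -> "LeakageMatrix":
        """Per-step carry model: each bin passes fraction ``lam`` of its
        accumulated venous signal one step toward the surface.

        In WM-first order, measured[k] = local[k] + lam * measured[k - 1],
        which unrolls to L[i, j] = lam**(i - j) for j <= i.
        """
        if not 0 <= lam < 1:
            raise ValueError("carry fraction must be in [0, 1)")
        i, j = np.indices((n, n))
        return cls(np.where(j <= i, lam ** np.clip(i - j, 0, None), 0.0))

    @classmethod
    def from_coefficients(cls, path: str | Path) -> "LeakageMatrix":
        """Load a published depth-to-depth leakage table from a JSON config
        holding the full matrix (key ``matrix``) in WM-first row order."""
        with open(path) as fh:
            cfg = json.load(fh)
        return cls(np.asarray(cfg["matrix"], dtype=float))


def apply_leakage(signal: np.ndarray, leakage: LeakageMatrix) -> np.ndarray:
    """Forward drain model: measured = L @ local, applied per time point.

    ``signal`` is a depth vector or a depth x time matrix in pial-first order
    (index 0 at the pial surface); the WM-first matrix product is handled by
    flipping the depth axis on the way in and out.
    """
    sig = np.asarray(signal, dtype=float)
    if sig.shape[0] != leakage.n:
        raise ValueError("leakage matrix and signal depth dimensions differ")
    return np.flip(leakage.matrix @ np.flip(sig, axis=0), axis=0)


# --------------------------------------------------------------------------
# session generation


@dataclass
class LineTimeSeries:
    """Depth x time signal matrix for one run (optionally depth x time x echo)."""

    data: np.ndarray
    tr: float = TR
    depth_positions: np.ndarray | None = None  # mm along the line
    gm_bounds: tuple[int, int] = (0, 0)  # inclusive index pair of the GM ribbon
    echo_times: tuple[float, ...] | None = None  # ms, present for multi-echo data

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.depth_positions is None:
            self.depth_positions = np.arange(self.data.shape[0]) * DEPTH_STEP_MM
        self.depth_positions = np.asarray(self.depth_positions, dtype=float)

    @property
    def n_depth(self) -> int:
        return self.data.shape[0]

    @property
    def n_time(self) -> int:
        return self.data.shape[1]

    def times(self) -> np.ndarray:
        return np.arange(self.n_time) * self.tr


@dataclass
class NoiseConfig:
    """Additive noise model: AR(1) + white noise + slow cosine drift.

    Amplitudes are in raw signal units relative to ``baseline_signal`` = 100,
    i.e. a ``white_sd`` of 1.0 is 1% of baseline.
    """

    ar_rho: float = 0.3
    ar_sd: float = 0.8
    white_sd: float = 0.4
    drift_amplitude: float = 1.0
    n_drift_cosines: int = 3

    @classmethod
    def noiseless(cls) -> "NoiseConfig":
        return cls(ar_rho=0.0, ar_sd=0.0, white_sd=0.0, drift_amplitude=0.0)


@dataclass
class SessionConfig:
    """Geometry and physics of the simulated line."""

    n_line: int = 16  # voxels along the measured line
    gm_bounds: tuple[int, int] = (5, 11)  # inclusive; 7-sample GM ribbon
    baseline_signal: float = 100.0
    ovs_suppression: float = 0.05  # residual signal fraction outside the ribbon
    leakage: LeakageMatrix | None = None
    multi_echo: bool = False
    t2star_gm_ms: float = 33.0
    t2star_outside_ms: float = 20.0

    def ribbon_size(self) -> int:
        return self.gm_bounds[1] - self.gm_bounds[0] + 1


def condition_regressor(
    paradigm: Paradigm, condition: str, n_time: int, tr: float = TR
) -> np.ndarray:
    """HRF-convolved boxcar for one condition's events (unit peak HRF)."""
    box = np.zeros(n_time)
    for onset in paradigm.onsets(condition):
        i0 = int(round(onset / tr))
        i1 = min(n_time, int(round((onset + STIM_DURATION) / tr)))
        box[i0:i1] = 1.0
    return np.convolve(box, double_gamma_hrf(tr))[:n_time]


def generate_session(
    paradigm: Paradigm,
    truths: dict[str, GroundTruthProfile] | None = None,
    noise: NoiseConfig | None = None,
    config: SessionConfig | None = None,
    seed: int | None = 0,
) -> tuple[LineTimeSeries, dict]:
    """Simulate one line-scanning run with known laminar ground truth.

    Inside the gray-matter ribbon the raw signal is
    ``baseline * (1 + profile(d) * (design (*) HRF)(t) / 100)``; outside the
    ribbon the evoked component and baseline are attenuated to emulate
    outer-volume suppression.  Optional leakage mixes the evoked percent-signal
    component toward the surface before noise is added.  Returns the series
    and a ground-truth sidecar dict (seeds, ribbon geometry, truth samples).
    """
    cfg = config or SessionConfig()
    noise = noise or NoiseConfig()
    conditions = sorted(set(paradigm.events["trial_type"]))
    if truths is None:
        truths = {c: make_ground_truth(c) for c in conditions}
    rng = np.random.default_rng(seed)

    n_time = int(round(paradigm.run_length / TR))
    lo, hi = cfg.gm_bounds
    ribbon = np.arange(lo, hi + 1)
    # normalized depth of ribbon samples, 0 = pial at the low line index
    depth_norm = (ribbon - lo) / (hi - lo)

    evoked = np.zeros((cfg.n_line, n_time))  # percent signal change units
    truth_samples: dict[str, list[float]] = {}
    for cond in conditions:
        reg = condition_regressor(paradigm, cond, n_time)
        prof = truths[cond](depth_norm)
        truth_samples[cond] = [float(v) for v in prof]
        evoked[ribbon] += np.outer(prof, reg)

    if cfg.leakage is not None:
        if cfg.leakage.n != ribbon.size:
            raise ValueError("leakage matrix size must match the GM ribbon")
        evoked[ribbon] = apply_leakage(evoked[ribbon], cfg.leakage)

    atten = np.full(cfg.n_line, cfg.ovs_suppression)
    atten[ribbon] = 1.0
    raw = cfg.baseline_signal * atten[:, None] * (1.0 + evoked / 100.0)

    raw += _make_noise(cfg.n_line, n_time, noise, rng)

    if cfg.multi_echo:
        t2 = np.full(cfg.n_line, cfg.t2star_outside_ms)
        t2[ribbon] = cfg.t2star_gm_ms
        decay = np.exp(-np.asarray(ECHO_TIMES_MS)[None, None, :] / t2[:, None, None])
        raw = raw[:, :, None] * decay
        echo_times: tuple[float, ...] | None = ECHO_TIMES_MS
    else:
        echo_times = None

    series = LineTimeSeries(
        data=raw, tr=TR, gm_bounds=cfg.gm_bounds, echo_times=echo_times
    )
    sidecar = {
        "tr": TR,
        "seed": seed,
        "timing_variant": paradigm.timing_variant,
        "gm_bounds": [int(lo), int(hi)],
        "depth_positions_mm": [float(v) for v in series.depth_positions],
        "ribbon_depth_norm": [float(v) for v in depth_norm],
        "truth_ribbon_psc": truth_samples,
        "noise": vars(noise).copy(),
    }
    return series, sidecar


def _make_noise(
    n_line: int, n_time: int, noise: NoiseConfig, rng: np.random.Generator
) -> np.ndarray:
    out = np.zeros((n_line, n_time))
    if noise.ar_sd > 0:
        eps = rng.standard_normal((n_line, n_time)) * noise.ar_sd * np.sqrt(1 - noise.ar_rho**2)
        ar = np.empty_like(eps)
        ar[:, 0] = eps[:, 0] / np.sqrt(1 - noise.ar_rho**2)
        for t in range(1, n_time):
            ar[:, t] = noise.ar_rho * ar[:, t - 1] + eps[:, t]
        out += ar
    if noise.white_sd > 0:
        out += rng.standard_normal((n_line, n_time)) * noise.white_sd
    if noise.drift_amplitude > 0 and noise.n_drift_cosines > 0:
        t = np.arange(n_time) / n_time
        for k in range(1, noise.n_drift_cosines + 1):
            amp = rng.standard_normal(n_line)[:, None] * noise.drift_amplitude / k
            out += amp * np.cos(np.pi * k * t)[None, :]
    return out


def single_condition_paradigm(
    condition: str, variant: int = 1, seed: int | None = 0
) -> Paradigm:
    """A run presenting only one condition (5 events); used for noiseless
    round-trip checks where exact depth/time separability is required."""
    return build_paradigm(variant, seed=seed, conditions=(condition,))


# --------------------------------------------------------------------------
# disk I/O


def write_session(
    out_dir: str | Path,
    run_label: str,
    series: LineTimeSeries,
    sidecar: dict,
    paradigm: Paradigm,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if series.data.ndim == 3:
        raise ValueError("write per-echo series individually (2-D matrices only)")
    np.savetxt(out / f"{run_label}_line.tsv.gz", series.data, delimiter="\t")
    with open(out / f"{run_label}_line.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    paradigm.to_tsv(out / f"{run_label}_events.tsv")


def read_session(out_dir: str | Path, run_label: str) -> tuple[LineTimeSeries, dict, Paradigm]:
    out = Path(out_dir)
    data = np.loadtxt(out / f"{run_label}_line.tsv.gz", delimiter="\t")
    with open(out / f"{run_label}_line.json") as fh:
        sidecar = json.load(fh)
    paradigm = Paradigm.from_tsv(
        out / f"{run_label}_events.tsv", timing_variant=sidecar.get("timing_variant", 1)
    )
    series = LineTimeSeries(
        data=data,
        tr=sidecar["tr"],
        depth_positions=np.asarray(sidecar["depth_positions_mm"]),
        gm_bounds=tuple(sidecar["gm_bounds"]),
    )
    return series, sidecar, paradigm
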