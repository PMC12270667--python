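"""End-to-end session orchestration and group-level statistics.

``run_pipeline`` drives the whole chain on synthetic data: simulate a cohort
of line-scanning sessions (two timing-variant runs per participant),
preprocess each run (echo combination, smoothing, percent signal change,
epoching), collapse to standardized 20-point depth profiles (template
weighting and 5-7 s window averaging), fit the descriptive laminar model per
condition, and compare beta_context across conditions at the group level.
Everything is deterministic given the config and seed.

``simulate_cohort_profiles`` is a light-weight cohort generator at the
profile level (ground-truth laminar profile + participant gain + measurement
noise) used for fast Monte-Carlo calibration of the group contrast.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import model as lm
from . import profiles as pr
from . import preprocess as pp
from . import simulate as sim

logger = logging.getLogger("lamline")


@dataclass
class PipelineConfig:
    n_participants: int = 11
    conditions: tuple[str, ...] = sim.CONDITIONS
    seed: int = 0
    noise: sim.NoiseConfig = field(default_factory=sim.NoiseConfig)
    session: sim.SessionConfig = field(default_factory=sim.SessionConfig)
    participant_gain_sd: float = 0.2  # multiplicative amplitude variability
    echo_method: str = "sos"
    smooth: bool = True
    drain_kind: str = "linear"
    sigma_g: float = lm.DEFAULT_SIGMA_G
    tau: float = lm.DEFAULT_TAU
    deconvolve: bool = False
    leakage_lambda: float = 0.3
    leakage_file: str | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            cfg = json.load(fh)
        noise = sim.NoiseConfig(**cfg.pop("noise", {}))
        session = sim.SessionConfig(**cfg.pop("session", {}))
        return cls(noise=noise, session=session, **cfg)


@dataclass
class SessionResult:
    """One participant's processed session."""

    participant: int
    template_profiles: dict[str, pp.DepthProfile]
    window_profiles: dict[str, pp.DepthProfile]
    fits: dict[str, lm.LaminarFit]
    timecourses: dict[str, np.ndarray]  # regridded 20 x time evoked responses
    included: bool
    shift: int


def peak_window_response(
    condition_means: dict[str, np.ndarray],
    times: np.ndarray,
    half_width: float = 1.0,
) -> dict[str, float]:
    """Depth-averaged response around the center-response peak, per condition.

    The window is [t_peak - 1 s, t_peak + 1 s] where t_peak is the time of the
    maximum of the depth-averaged center response (post-onset); the window is
    clipped to the epoch with a warning if it runs outside.
    """
    if "center" not in condition_means:
        raise ValueError("center response required to define the peak window")
    center = np.asarray(condition_means["center"], dtype=float).mean(axis=0)
    post = times >= 0
    t_peak = float(times[post][np.argmax(center[post])])
    w0, w1 = t_peak - half_width, t_peak + half_width
    if w0 < times[0] or w1 > times[-1]:
        import warnings

        warnings.warn("peak window clipped to the epoch extent", stacklevel=2)
    sel = (times >= w0) & (times <= w1)
    return {
        cond: float(np.asarray(resp, dtype=float).mean(axis=0)[sel].mean())
        for cond, resp in condition_means.items()
    }


def simulate_participant_session(
    participant: int, config: PipelineConfig, rng: np.random.Generator
) -> tuple[list[sim.LineTimeSeries], list[sim.Paradigm], dict]:
    """Two runs (timing variants 1 and 2) for one synthetic participant.

    Participant identity enters through a multiplicative response gain and
    an individually placed gray-matter ribbon of 6-10 samples.
    """
    gain = float(np.exp(rng.normal(0.0, config.participant_gain_sd)))
    rib = int(rng.integers(6, 11))
    lo = int(rng.integers(2, config.session.n_line - rib - 1))
    session_cfg = sim.SessionConfig(
        n_line=config.session.n_line,
        gm_bounds=(lo, lo + rib - 1),
        baseline_signal=config.session.baseline_signal,
        ovs_suppression=config.session.ovs_suppression,
        leakage=config.session.leakage,
        multi_echo=config.session.multi_echo,
    )
    truths = {
        c: _scaled_truth(sim.make_ground_truth(c), gain) for c in config.conditions
    }
    runs, paradigms = [], []
    for variant in (1, 2):
        paradigm = sim.build_paradigm(
            variant, seed=int(rng.integers(2**31)), conditions=config.conditions
        )
        series, sidecar = sim.generate_session(
            paradigm,
            truths=truths,
            noise=config.noise,
            config=session_cfg,
            seed=int(rng.integers(2**31)),
        )
        runs.append(series)
        paradigms.append(paradigm)
    meta = {"participant": participant, "gain": gain, "gm_bounds": [lo, lo + rib - 1]}
    return runs, paradigms, meta


def _scaled_truth(truth: sim.GroundTruthProfile, gain: float) -> sim.GroundTruthProfile:
    return sim.GroundTruthProfile(
        condition=truth.condition,
        depth_fn=lambda d, _f=truth.depth_fn, _g=gain: _g * np.asarray(_f(d)),
        amplitude=gain * truth.amplitude,
    )


def process_session(
    runs: list[sim.LineTimeSeries],
    paradigms: list[sim.Paradigm],
    participant: int,
    config: PipelineConfig,
    template: pr.ResponseTemplate | None = None,
) -> SessionResult:
    """Preprocess one participant's runs and collapse to depth profiles.

    When no group template is supplied, the participant's own depth-averaged
    center response is used (the group template is normally built in a second
    pass across participants).
    """
    epoch_sets = [
        pp.preprocess_run(run, par, echo_method=config.echo_method, smooth=config.smooth)
        for run, par in zip(runs, paradigms)
    ]
    epochs = pp.concat_epochs(epoch_sets)
    gm = runs[0].gm_bounds
    quality = pp.line_glm_quality(_psc_series(runs[0], config), paradigms[0],
                                  epochs=epoch_sets[0])

    timecourses = {
        cond: pp.select_gm_and_regrid(epochs.condition_mean(cond), gm)
        for cond in config.conditions
    }
    if template is None:
        template = pr.build_template([timecourses["center"]], tr=epochs.tr)

    leakage = _resolve_leakage(config, n=pp.N_DEPTH_GRID) if config.deconvolve else None
    design = lm.build_design(
        sigma_g=config.sigma_g, drain_kind=config.drain_kind, tau=config.tau
    )
    template_profiles, window_profiles, fits = {}, {}, {}
    for cond, tc in timecourses.items():
        template_profiles[cond] = pr.template_weighting(tc, template, condition=cond)
        window_profiles[cond] = pr.window_average(tc, tr=epochs.tr, condition=cond)
        y = template_profiles[cond].values
        if leakage is not None:
            y = lm.deconvolve_profile(y, leakage)
        fits[cond] = lm.fit_profile(pp.DepthProfile(y, condition=cond), design)
    return SessionResult(
        participant=participant,
        template_profiles=template_profiles,
        window_profiles=window_profiles,
        fits=fits,
        timecourses=timecourses,
        included=quality.included,
        shift=quality.shift,
    )


def _psc_series(run: sim.LineTimeSeries, config: PipelineConfig) -> sim.LineTimeSeries:
    combined = pp.combine_echoes(run, method=config.echo_method)
    return sim.LineTimeSeries(
        data=pp.percent_signal_change(combined.data),
        tr=combined.tr,
        depth_positions=combined.depth_positions,
        gm_bounds=combined.gm_bounds,
    )


def _resolve_leakage(config: PipelineConfig, n: int) -> sim.LeakageMatrix:
    if config.leakage_file:
        return sim.LeakageMatrix.from_coefficients(config.leakage_file)
    return sim.LeakageMatrix.from_carry_fraction(n, config.leakage_lambda)


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Simulate, preprocess, profile, fit, and compare a synthetic cohort.

    Returns a dict with per-participant SessionResults, the long profile and
    fit tables, the group contrast of beta_context, and exclusion bookkeeping.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.seed)
    logger.info("simulating %d participants (seed %d)", config.n_participants, config.seed)

    sessions = []
    for p in range(config.n_participants):
        runs, paradigms, meta = simulate_participant_session(p, config, rng)
        sessions.append((runs, paradigms, meta))

    # first pass: per-participant regridded center responses -> group template
    center_tcs, epoch_tr = [], None
    prelim = []
    for runs, paradigms, meta in sessions:
        ep_sets = [
            pp.preprocess_run(r, par, echo_method=config.echo_method, smooth=config.smooth)
            for r, par in zip(runs, paradigms)
        ]
        epochs = pp.concat_epochs(ep_sets)
        epoch_tr = epochs.tr
        center_tcs.append(
            pp.select_gm_and_regrid(epochs.condition_mean("center"), runs[0].gm_bounds)
        )
        prelim.append((runs, paradigms, meta))
    template = pr.build_template(center_tcs, tr=epoch_tr)

    results = [
        process_session(runs, paradigms, meta["participant"], config, template=template)
        for runs, paradigms, meta in prelim
    ]

    # participant normalization of profiles before group summaries
    profile_rows, fit_rows = [], []
    for cond in config.conditions:
        stack = np.stack([r.template_profiles[cond].values for r in results])
        normed = pr.normalize_across_participants(stack)
        for r, vals in zip(results, normed):
            row = {"participant": r.participant, "condition": cond}
            row.update({f"v{i}": v for i, v in enumerate(vals)})
            profile_rows.append(row)
    for r in results:
        for cond, fit in r.fits.items():
            rec = {
                "participant": r.participant,
                "condition": cond,
                "r2": fit.r2,
                "beta_context": fit.beta_context,
                "included": r.included,
            }
            rec.update({f"beta_{c}": b for c, b in zip(lm.DESIGN_COLUMNS, fit.betas)})
            fit_rows.append(rec)
    profiles_df = pd.DataFrame(profile_rows)
    fits_df = pd.DataFrame(fit_rows)
    contrast = lm.condition_contrast(fits_df)

    n_included = sum(r.included for r in results)
    logger.info("included %d / %d participants", n_included, len(results))
    return {
        "results": results,
        "template": template,
        "profiles": profiles_df,
        "fits": fits_df,
        "contrast": contrast,
        "n_included": n_included,
        "n_excluded": len(results) - n_included,
    }


def simulate_cohort_profiles(
    n_participants: int = 11,
    conditions: tuple[str, ...] = sim.CONDITIONS,
    gain_sd: float = 0.2,
    noise_sd: float = 0.3,
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Fast profile-level cohort: ground truth x participant gain + noise.

    Each participant's profile per condition is the ground-truth laminar
    profile on the 20-point grid scaled by a log-normal participant gain, plus
    iid Gaussian measurement noise (sd in percent signal change).  Returns the
    long table consumed by ``fit_condition_profiles``.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for p in range(n_participants):
        gain = float(np.exp(rng.normal(0.0, gain_sd)))
        for cond in conditions:
            y = gain * sim.make_ground_truth(cond)(pp.DEPTH_GRID)
            y = y + rng.normal(0.0, noise_sd, size=y.shape)
            row = {"participant": p, "condition": cond}
            row.update({f"v{i}": v for i, v in enumerate(y)})
            rows.append(row)
    return pd.DataFrame(rows)


def write_group_tables(out_dir: str | Path, outcome: dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outcome["profiles"].to_csv(out / "profiles.tsv", sep="\t", index=False)
    outcome["fits"].to_csv(out / "fits.tsv", sep="\t", index=False)
    outcome["contrast"]["descriptives"].to_csv(
        out / "group_beta_context.tsv", sep="\t", index=False
    )
    if "posthoc" in outcome["contrast"]:
        outcome["contrast"]["posthoc"].to_csv(out / "posthoc.tsv", sep="\t", index=False)
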