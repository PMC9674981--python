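"""Synthetic two-channel stopped-flow traces with known ground truth.

No public repository of raw vimentin stopped-flow recordings exists, so
every stage of the analysis is exercised against simulated data that
reproduce the statistical structure the analysis assumes:

1. a fast *lateral* phase (< 1 s): tetramers associate into unit-length
   filaments (ULFs); both wavelengths rise identically.  Modelled as a
   saturating double exponential (default time constants 30 ms and 2 s).
   A condition's faster lateral kinetics are encoded by
   ``lateral_factor``: a proportional excess of the early signal (the
   quantity the 20-40 ms comparison window reads out) that decays away
   over the slow lateral timescale, leaving the common plateau;
2. an *elongation* phase (1-100 s): ULFs anneal end-to-end; the geometric
   mean length grows linearly at ``elongation_rate`` (ULFs/min) and the
   channels diverge according to the ensemble Rayleigh-Gans shape term
   (fixed-mass normalisation, <l**2 P>/<l>);
3. a *radial compaction* overshoot: the mass per cross section
   transiently exceeds its final value (log-normal pulse peaking at
   ``compaction_timescale``, default 30 s, 30% excess) and the excess
   mass-per-cross-section fold of a salt condition builds in over
   ``mass_timescale`` so that the first tens of milliseconds reflect only
   the lateral kinetics.

The noise-free product of the three terms is passed through a first-order
low-pass (1 ms), sampled (1 kHz), blanked over the instrument dead time
(3 ms), and additive white Gaussian noise plus optional bubble transients
are applied.  All randomness flows from one seed through named substreams
(noise405, noise594, bubble, lengths), so each component is independently
reproducible.  The lateral ramp and the compaction pulse are conventions
of this generator, not measured mechanisms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .optics import LAMBDA_LONG_NM, LAMBDA_SHORT_NM, UlfGeometry
from .population import GrowthModel, ensemble_intensity, sample_lengths

__all__ = ["TraceConfig", "StoppedFlowTrace", "generate_trace",
           "generate_length_samples", "generate_condition_set"]


@dataclass(frozen=True)
class TraceConfig:
    """Generating parameters for one synthetic stopped-flow trace."""

    protein_conc: float = 0.2        # mg/mL (metadata only)
    salt: float = 100.0              # mM NaCl (metadata only)
    lateral_amplitude: float = 1.0   # a.u., plateau of the lateral ramp
    lateral_timescale: float = 0.03  # s, fast lateral time constant
    lateral_slow_timescale: float = 2.0   # s, slow lateral time constant
    lateral_fast_weight: float = 0.7      # weight of the fast component
    lateral_factor: float = 1.0      # fold change of lateral rate vs reference
    elongation_rate: float = 1.0     # ULFs/min
    mass_per_cs_factor: float = 1.0  # fold mass-per-cross-section vs reference
    mass_timescale: float = 2.0      # s, build-in time of the excess mass fold
    compaction_overshoot: float = 0.3     # fractional peak excess
    compaction_timescale: float = 30.0    # s, overshoot peak time
    compaction_width: float = 0.5    # log-time width of the overshoot pulse
    noise_sd: float = 0.01           # a.u., additive Gaussian, per sample
    duration: float = 600.0          # s
    sample_rate: float = 1000.0      # Hz
    dead_time: float = 0.003         # s, blanked after trigger
    lowpass_tau: float = 0.001       # s, first-order instrument filter
    bubble_probability: float = 0.0  # per trace
    bubble_amplitude: float = 1.0    # a.u.
    bubble_duration: float = 0.05    # s
    seed: int = 0

    def __post_init__(self) -> None:
        nonneg = (
            "lateral_amplitude lateral_timescale lateral_slow_timescale "
            "lateral_factor elongation_rate mass_timescale "
            "compaction_overshoot compaction_timescale noise_sd dead_time "
            "lowpass_tau bubble_probability"
        ).split()
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.duration <= self.dead_time:
            raise ValueError("duration must exceed the dead time")
        if not 0 <= self.lateral_fast_weight <= 1:
            raise ValueError("lateral_fast_weight must be in [0, 1]")
        if self.mass_per_cs_factor <= 0:
            raise ValueError("mass_per_cs_factor must be positive")


@dataclass
class StoppedFlowTrace:
    """Two-channel intensity time series on a uniform time grid."""

    time_s: np.ndarray
    i405: np.ndarray
    i594: np.ndarray
    state: str = "raw"  # raw | calibrated | normalized
    meta: dict = field(default_factory=dict)
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.i405 = np.asarray(self.i405, dtype=float)
        self.i594 = np.asarray(self.i594, dtype=float)
        if not (self.time_s.shape == self.i405.shape == self.i594.shape):
            raise ValueError("time and channel arrays must have equal length")
        if self.time_s.size >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time must be strictly increasing")
        if not (np.all(np.isfinite(self.i405)) and np.all(np.isfinite(self.i594))):
            raise ValueError("intensities must be finite")
        if self.state not in ("raw", "calibrated", "normalized"):
            raise ValueError(f"unknown state {self.state!r}")

    def channel(self, wavelength_nm: float) -> np.ndarray:
        if abs(wavelength_nm - LAMBDA_SHORT_NM) < 1.0:
            return self.i405
        if abs(wavelength_nm - LAMBDA_LONG_NM) < 1.0:
            return self.i594
        raise ValueError(f"no channel at {wavelength_nm} nm")

    def with_channels(self, i405, i594, state=None) -> "StoppedFlowTrace":
        return StoppedFlowTrace(
            time_s=self.time_s.copy(),
            i405=np.asarray(i405, float),
            i594=np.asarray(i594, float),
            state=state or self.state,
            meta=dict(self.meta),
            ground_truth=self.ground_truth,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "i405": self.i405, "i594": self.i594})


def _lateral_ramp(t, cfg: TraceConfig):
    """Saturating double-exponential ULF-formation ramp.

    ``lateral_factor`` multiplies the early part of the ramp by a fold
    that relaxes to 1 over the slow lateral timescale: a condition with
    faster lateral kinetics shows a proportionally larger signal while
    ULF formation is still underway, but reaches the same lateral
    plateau (the final mass is set separately by the mass factor).
    """
    w = cfg.lateral_fast_weight
    fast = 1.0 - np.exp(-t / cfg.lateral_timescale) if cfg.lateral_timescale > 0 else 1.0
    slow = (
        1.0 - np.exp(-t / cfg.lateral_slow_timescale)
        if cfg.lateral_slow_timescale > 0 else 1.0
    )
    ramp = cfg.lateral_amplitude * (w * fast + (1.0 - w) * slow)
    if cfg.lateral_factor != 1.0 and cfg.lateral_slow_timescale > 0:
        ramp = ramp * (1.0 + (cfg.lateral_factor - 1.0) * np.exp(-t / cfg.lateral_slow_timescale))
    elif cfg.lateral_factor != 1.0:
        ramp = ramp * cfg.lateral_factor
    return ramp


def _mass_factor(t, cfg: TraceConfig):
    """Mass-per-cross-section fold versus time (relative to reference)."""
    if cfg.mass_timescale > 0:
        build = 1.0 - np.exp(-t / cfg.mass_timescale)
    else:
        build = np.ones_like(t)
    fold = 1.0 + (cfg.mass_per_cs_factor - 1.0) * build
    if cfg.compaction_overshoot > 0 and cfg.compaction_timescale > 0:
        with np.errstate(divide="ignore"):
            logt = np.where(t > 0, np.log(np.maximum(t, 1e-12) / cfg.compaction_timescale), -np.inf)
        pulse = np.exp(-0.5 * (logt / cfg.compaction_width) ** 2)
        pulse = np.where(t > 0, pulse, 0.0)
        fold = fold * (1.0 + cfg.compaction_overshoot * pulse)
    return fold


def _shape_terms(t, cfg: TraceConfig, geometry: UlfGeometry):
    """Per-channel ensemble shape terms, normalised to 1 at t = 0.

    Evaluated by quadrature on a coarse log-spaced grid of times and
    interpolated onto the sample grid (the term is smooth and monotone, so
    the interpolation error is far below the instrument noise).
    """
    if cfg.elongation_rate == 0:
        one = np.ones_like(t)
        return one, one
    growth = GrowthModel(rate=cfg.elongation_rate)
    nodes = np.concatenate(([0.0], np.logspace(-3, np.log10(max(t[-1], 1e-2)), 400)))
    vals = {}
    for lam in (LAMBDA_SHORT_NM, LAMBDA_LONG_NM):
        v = np.array([
            ensemble_intensity(growth.distribution_at(tn / 60.0), lam, geometry)
            for tn in nodes
        ])
        vals[lam] = v / v[0]
    e405 = np.interp(t, nodes, vals[LAMBDA_SHORT_NM])
    e594 = np.interp(t, nodes, vals[LAMBDA_LONG_NM])
    return e405, e594


def _lowpass(x, dt, tau):
    if tau <= 0:
        return x
    alpha = dt / (tau + dt)
    return lfilter([alpha], [1.0, alpha - 1.0], x, zi=[0.0])[0]


def generate_trace(
    config: TraceConfig,
    geometry: UlfGeometry | None = None,
) -> StoppedFlowTrace:
    """Simulate one two-channel trace; generating parameters travel along
    as ``trace.ground_truth``.

    The returned trace is on the calibrated scale (water baseline 0,
    buffer gain 1); apply an affine per-channel transform to emulate raw
    detector output.
    """
    geometry = geometry or UlfGeometry()
    dt = 1.0 / config.sample_rate
    t = np.arange(0.0, config.duration, dt)
    lateral = _lateral_ramp(t, config)
    mass = _mass_factor(t, config)
    e405, e594 = _shape_terms(t, config, geometry)
    s405 = lateral * mass * e405
    s594 = lateral * mass * e594

    s405 = _lowpass(s405, dt, config.lowpass_tau)
    s594 = _lowpass(s594, dt, config.lowpass_tau)

    blank = t < config.dead_time
    s405[blank] = 0.0
    s594[blank] = 0.0

    ss = np.random.SeedSequence(config.seed, spawn_key=(0,))
    rng405, rng594, rng_bub = (np.random.default_rng(c) for c in ss.spawn(3))
    if config.noise_sd > 0:
        s405 = s405 + rng405.normal(0.0, config.noise_sd, t.size)
        s594 = s594 + rng594.normal(0.0, config.noise_sd, t.size)

    bubble_times = []
    if config.bubble_probability > 0 and rng_bub.uniform() < config.bubble_probability:
        t0 = rng_bub.uniform(1.0, max(config.duration - 1.0, 1.0))
        width = config.bubble_duration / 2.355  # FWHM -> gaussian sigma
        bump = config.bubble_amplitude * np.exp(-0.5 * ((t - t0) / width) ** 2)
        s405 = s405 + bump
        s594 = s594 + bump
        bubble_times.append(float(t0))

    truth = asdict(config)
    truth["bubble_times_s"] = bubble_times
    meta = {"protein_conc_mg_ml": config.protein_conc, "salt_mM": config.salt}
    return StoppedFlowTrace(t, s405, s594, state="calibrated", meta=meta, ground_truth=truth)


def generate_length_samples(
    growth: GrowthModel,
    times_s,
    n_per_time: int,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Filament-length samples (ULF units) at a set of fixation times.

    Emulates a morphometry experiment: at each time point, ``n_per_time``
    lengths are drawn from the log-normal population whose geometric mean
    follows the growth model and whose width follows the sigma-length law.
    """
    if n_per_time < 1:
        raise ValueError("n_per_time must be >= 1")
    times_s = np.asarray(times_s, dtype=float)
    ss = np.random.SeedSequence(seed, spawn_key=(1,))
    frames = []
    for t_s, child in zip(times_s, ss.spawn(times_s.size)):
        dist = growth.distribution_at(t_s / 60.0)
        lengths = sample_lengths(dist, n_per_time, np.random.default_rng(child))
        frames.append(pd.DataFrame({"time_s": t_s, "length": lengths}))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["unit"] = "ulf"
    return out


def generate_condition_set(
    base: TraceConfig,
    salt_levels: list[dict],
    n_replicates: int = 3,
    seed: int | None = 0,
) -> list[StoppedFlowTrace]:
    """Traces for a set of salt conditions; the first level is the reference.

    Each entry of ``salt_levels`` is a dict of ``TraceConfig`` overrides
    (typically ``salt``, ``lateral_factor``, ``elongation_rate``,
    ``mass_per_cs_factor``, ``compaction_overshoot``).  Every replicate of
    every level draws its noise from an independent substream of ``seed``.
    Fold factors relative to the reference are recorded in each trace's
    ground truth.
    """
    if len(salt_levels) < 2:
        raise ValueError("need at least two salt levels (first is the reference)")
    ss = np.random.SeedSequence(seed, spawn_key=(2,))
    children = iter(ss.spawn(len(salt_levels) * n_replicates))
    traces = []
    for level_idx, overrides in enumerate(salt_levels):
        for rep in range(n_replicates):
            child = next(children)
            cfg = replace(base, **overrides, seed=int(child.generate_state(1)[0] % (2**31)))
            trace = generate_trace(cfg)
            trace.meta.update(
                condition_index=level_idx,
                replicate=rep,
                is_reference=level_idx == 0,
            )
            trace.ground_truth["fold_vs_reference"] = {
                "lateral_factor": cfg.lateral_factor / salt_levels[0].get("lateral_factor", base.lateral_factor)
                if salt_levels[0].get("lateral_factor", base.lateral_factor) != 0 else float("nan"),
                "mass_per_cs_factor": cfg.mass_per_cs_factor / salt_levels[0].get("mass_per_cs_factor", base.mass_per_cs_factor),
                "elongation_rate": cfg.elongation_rate / salt_levels[0].get("elongation_rate", base.elongation_rate)
                if salt_levels[0].get("elongation_rate", base.elongation_rate) != 0 else float("nan"),
            }
            traces.append(trace)
    return traces
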