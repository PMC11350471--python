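"""Synthetic electropherogram generator with known ground truth.

The generator realises the linear ladder model the analysis assumes: rung N
of a charge ladder (a protein with N lysine acetylations) has effective
mobility

    mu_N = c * (Z + N * dZ_Ac)

with Z the net charge in the current redox state, dZ_Ac the (negative)
charge increment per acetylation and c > 0 a hydrodynamic coefficient
(cm^2 kV^-1 min^-1 per unit charge) that the ladder method never needs to
know — it cancels in the x-intercept. Mobilities are converted to migration
times through the standard effective-mobility relation against a neutral
EOF marker, Gaussian peaks are placed at those times, and baseline drift,
white detector noise and replicate-to-replicate jitter are added.

Defaults emulate the study conditions of the 4Cu-SOD1 charge-ladder
experiments: a dimer of Z_ox = -6.35 reduced to Z_red = -6.44 (four
electrons, near-complete charge regulation), six resolvable rungs, six
technical replicates per condition, 29 kV, and ~1 % run-to-run rung-mobility
scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import json
import numpy as np
from scipy.stats import binom

from .charge_model import RedoxState
from .electropherogram import Trace, write_trace

__all__ = [
    "CapillaryConfig",
    "SyntheticTruth",
    "NoiseSpec",
    "binomial_amplitudes",
    "simulate_ladder_mobilities",
    "mobility_to_time",
    "synthesize_trace",
    "simulate_experiment",
    "NeverElutesError",
]


class NeverElutesError(ValueError):
    """Analyte mobility too negative for the detector to ever see it."""


@dataclass(frozen=True)
class CapillaryConfig:
    """Capillary geometry and drive voltage.

    Only the voltage (29 kV) is dictated by the emulated experiments; the
    lengths are typical bench values for a short bare fused-silica capillary.
    """

    total_length_cm: float = 30.0
    length_to_detector_cm: float = 20.0
    voltage_kV: float = 29.0
    run_time_min: float = 12.0

    def __post_init__(self) -> None:
        if not 0 < self.length_to_detector_cm < self.total_length_cm:
            raise ValueError("require 0 < length_to_detector < total_length")
        if self.voltage_kV <= 0:
            raise ValueError("voltage must be positive")

    @property
    def mobility_factor(self) -> float:
        """(L_d * L_t / V): converts (1/t - 1/t_eof) to mobility."""
        return self.length_to_detector_cm * self.total_length_cm / self.voltage_kV


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one paired oxidized/reduced ladder experiment."""

    z_ox: float = -6.35
    z_red: float = -6.44
    delta_z_ac: float = -0.9
    mobility_coefficient: float = 0.93  # c, cm^2 kV^-1 min^-1 per unit charge
    t_eof_min: float = 1.6
    n_rungs: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mobility_coefficient <= 0:
            raise ValueError("mobility coefficient c must be positive")
        if self.n_rungs < 3:
            raise ValueError("need at least 3 rungs")
        if self.t_eof_min <= 0:
            raise ValueError("t_eof must be positive")

    def z(self, redox_state: RedoxState | str) -> float:
        return self.z_ox if RedoxState(redox_state) is RedoxState.OXIDIZED else self.z_red


def binomial_amplitudes(n_rungs: int, n_sites: int = 22, p: float = 0.10) -> np.ndarray:
    """Rung amplitudes from a binomial acetylation model.

    Partial acetylation of ``n_sites`` equivalent lysines with per-site
    probability ``p`` gives rung abundances Binomial(n_sites, p); heights are
    normalised to a maximum of 1 and decrease beyond the mode.
    """
    w = binom.pmf(np.arange(n_rungs), n_sites, p)
    return w / w.max()


@dataclass(frozen=True)
class NoiseSpec:
    """Stochastic structure of synthetic traces.

    ``replicate_jitter`` is a fractional lognormal sd applied per replicate
    to the EOF time, the peak amplitudes and the overall mobility scale
    (hydrodynamic coefficient): it reproduces the ~1 % run-to-run scatter of
    reported rung mobilities but cancels exactly in the Z estimate, which
    normalises to each run's own EOF marker and x-intercept.
    ``rung_mobility_jitter`` is a smaller fractional sd applied
    independently per rung per replicate; being uncorrelated across rungs it
    does not cancel, and its default (0.3 %) sets the replicate-to-replicate
    scatter of Z at the few-hundredths level technical CE replicates show.
    """

    peak_width_min: float = 0.04
    signal_noise_sd: float = 0.01
    baseline_drift_per_min: float = 0.005
    amplitude_profile: tuple[float, ...] | None = None
    replicate_jitter: float = 0.01
    rung_mobility_jitter: float = 0.003
    eof_amplitude: float = 1.2
    points_per_min: int = 240

    def __post_init__(self) -> None:
        for name in ("peak_width_min", "signal_noise_sd", "baseline_drift_per_min",
                     "replicate_jitter", "rung_mobility_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.peak_width_min == 0:
            raise ValueError("peak_width_min must be positive")

    def amplitudes(self, n_rungs: int) -> np.ndarray:
        if self.amplitude_profile is not None:
            amps = np.asarray(self.amplitude_profile, dtype=float)
            if amps.size < n_rungs:
                raise ValueError("amplitude_profile shorter than n_rungs")
            return amps[:n_rungs]
        return binomial_amplitudes(n_rungs)

    @classmethod
    def noiseless(cls) -> "NoiseSpec":
        return cls(signal_noise_sd=0.0, baseline_drift_per_min=0.0,
                   replicate_jitter=0.0, rung_mobility_jitter=0.0)


def simulate_ladder_mobilities(
    truth: SyntheticTruth, redox_state: RedoxState | str
) -> list[tuple[int, float]]:
    """Exact (N, mu) pairs of the linear ladder model, N = 0..n_rungs-1."""
    z = truth.z(redox_state)
    c = truth.mobility_coefficient
    return [
        (n, c * (z + n * truth.delta_z_ac)) for n in range(truth.n_rungs)
    ]


def mobility_to_time(mu: float, cap: CapillaryConfig, t_eof_min: float) -> float:
    """Migration time of an analyte with effective mobility ``mu``.

    Inverts mu = (L_d L_t / V)(1/t - 1/t_eof):  t = 1/(1/t_eof + mu/K).
    Raises :class:`NeverElutesError` when the apparent velocity is not
    toward the detector.
    """
    inv = 1.0 / t_eof_min + mu / cap.mobility_factor
    if inv <= 0:
        raise NeverElutesError(
            f"mobility {mu:.4g} cm^2/kV/min never reaches the detector "
            f"(t_eof={t_eof_min} min)"
        )
    return 1.0 / inv


def synthesize_trace(
    truth: SyntheticTruth,
    noise: NoiseSpec,
    cap: CapillaryConfig,
    redox_state: RedoxState | str,
    replicate_seed: int,
    replicate_id: int = 0,
    pH: float | None = None,
) -> Trace:
    """One synthetic electropherogram (EOF marker + ladder), deterministic per seed."""
    rng = np.random.default_rng(replicate_seed)
    state = RedoxState(redox_state)

    jit = noise.replicate_jitter
    t_eof = truth.t_eof_min * _lognormal(rng, jit)
    amp_scale = _lognormal(rng, jit)
    mobility_scale = _lognormal(rng, jit)  # correlated across rungs: cancels in Z
    amps = noise.amplitudes(truth.n_rungs) * amp_scale
    mob_jitter = mobility_scale * (
        np.array([_lognormal(rng, noise.rung_mobility_jitter) for _ in range(truth.n_rungs)])
        if noise.rung_mobility_jitter > 0
        else np.ones(truth.n_rungs)
    )

    centers = [t_eof]
    heights = [noise.eof_amplitude * amp_scale]
    failures = []
    for n, mu in simulate_ladder_mobilities(truth, state):
        try:
            t = mobility_to_time(mu * mob_jitter[n], cap, t_eof)
        except NeverElutesError:
            failures.append(n)
        else:
            centers.append(t)
            heights.append(amps[n])
    if failures:
        raise NeverElutesError(f"rungs {failures} never elute under {cap}")

    n_pts = int(round(cap.run_time_min * noise.points_per_min)) + 1
    time = np.linspace(0.0, cap.run_time_min, n_pts)
    signal = np.zeros_like(time)
    sigma = noise.peak_width_min
    for t0, h in zip(centers, heights):
        signal += h * np.exp(-0.5 * ((time - t0) / sigma) ** 2)
    signal += noise.baseline_drift_per_min * time
    if noise.signal_noise_sd > 0:
        signal += rng.normal(0.0, noise.signal_noise_sd, size=time.shape)

    meta = {
        "redox_state": state.value,
        "replicate": replicate_id,
        "seed": replicate_seed,
    }
    if pH is not None:
        meta["pH"] = pH
    return Trace(time, signal, meta)


def _lognormal(rng: np.random.Generator, frac_sd: float) -> float:
    if frac_sd <= 0:
        return 1.0
    s = np.sqrt(np.log(1.0 + frac_sd**2))
    return float(rng.lognormal(mean=-0.5 * s * s, sigma=s))


@dataclass(frozen=True)
class SyntheticExperiment:
    """Paired oxidized/reduced replicate trace sets plus the truth record."""

    truth: SyntheticTruth
    noise: NoiseSpec
    capillary: CapillaryConfig
    oxidized: tuple[Trace, ...]
    reduced: tuple[Trace, ...]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for state, traces in (("oxidized", self.oxidized), ("reduced", self.reduced)):
            for i, tr in enumerate(traces):
                write_trace(tr, out / f"{state}_rep{i}.csv")
        record = {
            "z_ox": self.truth.z_ox,
            "z_red": self.truth.z_red,
            "delta_z": self.truth.z_red - self.truth.z_ox,
            "delta_z_ac": self.truth.delta_z_ac,
            "mobility_coefficient": self.truth.mobility_coefficient,
            "t_eof_min": self.truth.t_eof_min,
            "n_rungs": self.truth.n_rungs,
            "seed": self.truth.seed,
            "n_replicates": len(self.oxidized),
        }
        (out / "truth.json").write_text(json.dumps(record, indent=2))


def simulate_experiment(
    truth: SyntheticTruth,
    noise: NoiseSpec,
    cap: CapillaryConfig,
    n_replicates: int = 6,
    base_seed: int | None = None,
    pH: float | None = None,
) -> SyntheticExperiment:
    """Paired oxidized/reduced trace sets with per-replicate jitter."""
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if base_seed is None:
        base_seed = truth.seed
    seeds = np.random.SeedSequence(base_seed).generate_state(2 * n_replicates)
    ox = tuple(
        synthesize_trace(truth, noise, cap, RedoxState.OXIDIZED,
                         int(seeds[i]) % (2**31), replicate_id=i, pH=pH)
        for i in range(n_replicates)
    )
    red = tuple(
        synthesize_trace(truth, noise, cap, RedoxState.REDUCED,
                         int(seeds[n_replicates + i]) % (2**31), replicate_id=i, pH=pH)
        for i in range(n_replicates)
    )
    return SyntheticExperiment(truth, noise, cap, ox, red)
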