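"""End-to-end composition: traces → peaks → mobilities → Z → ΔZ.

Each replicate is analyzed independently: peaks are detected, the EOF
marker and rungs assigned, migration times converted to effective
mobilities against that replicate's own marker, the ladder line fitted over
the first ``max_rungs`` rungs, and Z obtained from the x-intercept scaled
by ΔZ_Ac. Per-replicate Z values are then aggregated (mean ± sample sd),
and oxidized/reduced estimates compared. A pooled mode that regresses all
replicates' (N, mu) points in a single fit is available as an option.
"""

from __future__ import annotations

from typing import Sequence

from .electropherogram import Trace, assign_rungs, detect_peaks
from .ladder import (
    MobilityLadder,
    NetChargeEstimate,
    aggregate_replicates,
    effective_mobility,
    fit_ladder,
    net_charge_from_fit,
)
from .redox import RedoxComparison, compare_redox
from .synthetic import CapillaryConfig, SyntheticExperiment

__all__ = [
    "ladder_from_trace",
    "analyze_replicate",
    "analyze_condition",
    "analyze_experiment",
]


def ladder_from_trace(
    trace: Trace,
    cap: CapillaryConfig,
    expected_n_rungs: int = 6,
    marker_rule: str = "earliest",
    **detect_kwargs,
) -> MobilityLadder:
    """Detect peaks and convert rung migration times to mobilities."""
    peaks = detect_peaks(trace, **detect_kwargs)
    assignment = assign_rungs(peaks, expected_n_rungs, marker_rule)
    t_eof = assignment.eof_peak.centroid_min
    entries = [
        (n, effective_mobility(p.centroid_min, t_eof, cap))
        for n, p in assignment.rungs
    ]
    return MobilityLadder(
        entries=tuple(entries),
        replicate_id=trace.metadata.get("replicate"),
        pH=trace.metadata.get("pH"),
        redox_state=trace.metadata.get("redox_state"),
    )


def analyze_replicate(
    trace: Trace,
    cap: CapillaryConfig,
    delta_z_ac: float = -0.9,
    expected_n_rungs: int = 6,
    max_rungs: int = 6,
    marker_rule: str = "earliest",
    **detect_kwargs,
) -> float:
    """Net charge Z from one electropherogram."""
    ladder = ladder_from_trace(trace, cap, expected_n_rungs, marker_rule, **detect_kwargs)
    fit = fit_ladder(ladder, max_rungs=max_rungs)
    return net_charge_from_fit(fit, delta_z_ac)


def analyze_condition(
    traces: Sequence[Trace],
    cap: CapillaryConfig,
    delta_z_ac: float = -0.9,
    expected_n_rungs: int = 6,
    max_rungs: int = 6,
    pooled: bool = False,
    **kwargs,
) -> NetChargeEstimate:
    """Aggregate Z over technical replicates of one condition.

    ``pooled=True`` fits a single regression through all replicates' points
    instead of averaging per-replicate estimates (sd is then 0).
    """
    if not traces:
        raise ValueError("no traces supplied")
    pH = traces[0].metadata.get("pH")
    state = traces[0].metadata.get("redox_state")
    if pooled:
        import numpy as np

        from .ladder import LadderFit

        pts: list[tuple[int, float]] = []
        for tr in traces:
            lad = ladder_from_trace(tr, cap, expected_n_rungs, **kwargs)
            pts.extend((n, mu) for n, mu in lad.entries if n < max_rungs)
        n_arr = np.array([n for n, _ in pts], dtype=float)
        mu = np.array([m for _, m in pts], dtype=float)
        slope, intercept = np.polyfit(n_arr, mu, 1)
        resid = mu - (slope * n_arr + intercept)
        ss_tot = float(np.sum((mu - mu.mean()) ** 2))
        fit = LadderFit(
            slope=float(slope),
            intercept=float(intercept),
            x_intercept=float(-intercept / slope),
            r_squared=1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot else 1.0,
            n_points=len(pts),
        )
        z = net_charge_from_fit(fit, delta_z_ac)
        return NetChargeEstimate(z_mean=z, z_sd=0.0, n_replicates=len(traces),
                                 pH=pH, redox_state=state)
    z_values = [
        analyze_replicate(tr, cap, delta_z_ac, expected_n_rungs, max_rungs, **kwargs)
        for tr in traces
    ]
    return aggregate_replicates(z_values, pH=pH, redox_state=state)


def analyze_experiment(
    experiment: SyntheticExperiment,
    delta_z_ac: float | None = None,
    n_electrons: int = 4,
    max_rungs: int = 6,
    **kwargs,
) -> RedoxComparison:
    """Full pipeline on a paired synthetic experiment.

    ``delta_z_ac`` defaults to the experiment's own ground-truth value (in
    real analyses it is a required, explicitly supplied parameter).
    """
    if delta_z_ac is None:
        delta_z_ac = experiment.truth.delta_z_ac
    ox = analyze_condition(
        experiment.oxidized, experiment.capillary, delta_z_ac,
        expected_n_rungs=experiment.truth.n_rungs, max_rungs=max_rungs, **kwargs,
    )
    red = analyze_condition(
        experiment.reduced, experiment.capillary, delta_z_ac,
        expected_n_rungs=experiment.truth.n_rungs, max_rungs=max_rungs, **kwargs,
    )
    return compare_redox(ox, red, n_electrons=n_electrons)
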