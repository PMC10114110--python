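"""Scenario runner, calibration and parameter sweeps.

The standard computational experiments:

* ``static``       — stationary source at the lower boundary; Ptc and
  CiA maxima start coincident near the source and separate by one or
  more cell diameters as the negative feedback shuts signaling off in
  the nearest rows (the "spatial mode").
* ``furrow_1cph``  — source moving at 1 cell diameter/h (the normal
  furrow speed in the model); local Hh keeps rising ahead of the front,
  cells never reach the late, feedback-suppressed stage, and the two
  maxima stay coincident (the "mobile mode").
* ``furrow_0.1cph`` — a 10x slower front.  On a 300-min horizon this is
  indistinguishable from a static source (the band advances half a cell
  diameter), so the transient separation appears as in the static case;
  once the front has been moving across the tissue for a few rows the
  traveling state establishes and the maxima re-merge.  The scenario
  verdict is therefore taken from the established traveling state.

Calibration follows the staged procedure: spatial scale from the Hh
gradient length, binding saturation from the Ptc bound fraction,
temporal scale from the Ptc peak time, and Hill midpoints from the
open-loop midpoint rule.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .pathway import PathwayParameters
from .profiles import (
    ProfileError,
    UndefinedPeakError,
    extract_profile,
    fit_exponential_decay,
    peak_separation,
    ptc_bound_fraction,
    profiles_to_csv,
    register_profile,
    summarize_profiles,
)
from .tissue import SimulationConfig, SimulationTrace, SourceDescriptor, run_simulation

__all__ = [
    "ScenarioConfig", "CalibrationTargets", "CalibrationReport",
    "scenario_metrics", "run_scenario", "sweep", "calibrate",
    "first_row_ptc_peak_time", "steady_state_gradient_length",
    "steady_state_bound_fraction", "INDUCTION_FACTOR",
]

# A species' peak position only counts once its profile maximum has
# risen above baseline by this factor (pre-induction profiles are
# cell-to-cell noise around a constant and have no meaningful maximum).
INDUCTION_FACTOR = 1.3


@dataclass
class ScenarioConfig:
    """A named computational experiment."""

    name: str = "static"
    speed: float = 0.0                     # cell diameters / h
    total_time: float = 620.0
    snapshot_interval: float = 10.0
    n_replicates: int = 5
    seed: int = 1
    overrides: dict = dc_field(default_factory=dict)
    sweep_param: str | None = None
    sweep_values: tuple = ()

    def __post_init__(self):
        if self.snapshot_interval > self.total_time:
            raise ValueError("snapshot times exceed total time")
        if self.sweep_param is not None and len(self.sweep_values) == 0:
            raise ValueError("sweep grid must be non-empty")

    def params(self) -> PathwayParameters:
        return PathwayParameters().replace(**self.overrides)

    def simulation_config(self, seed: int) -> SimulationConfig:
        p = self.params()
        return SimulationConfig(
            params=p,
            source=SourceDescriptor(speed=self.speed, alpha1=p.alpha1),
            total_time=self.total_time,
            snapshot_interval=self.snapshot_interval,
            seed=seed,
        )

STANDARD_SCENARIOS = {
    "static": dict(speed=0.0),
    "furrow_1cph": dict(speed=1.0, total_time=320.0),
    "furrow_0.1cph": dict(speed=0.1, total_time=1800.0,
                          snapshot_interval=20.0),
}


def standard_scenario(name: str, **kwargs) -> ScenarioConfig:
    if name not in STANDARD_SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; "
                         f"choose from {sorted(STANDARD_SCENARIOS)}")
    merged = dict(STANDARD_SCENARIOS[name])
    merged.update(kwargs)
    return ScenarioConfig(name=name, **merged)


def separation_series(trace: SimulationTrace, threshold: float | None = None):
    """Separation of the Ptc and CiA maxima at every snapshot.

    Returns a DataFrame with the signed separation, the separated flag
    (induction-guarded) and the peak positions.  Snapshots where either
    species is not yet induced above baseline, or where a profile is
    flat, are reported as not separated with NaN positions.
    """
    if threshold is None:
        threshold = trace.cell_diameter
    base_max = None
    rows = []
    for t in trace.times:
        try:
            prof = extract_profile(trace, t)
        except ProfileError:
            rows.append(dict(t=t, ptc_peak_x=np.nan, cia_peak_x=np.nan,
                             separation=np.nan, separated=False, induced=False))
            continue
        if base_max is None:
            base_max = {sp: prof.levels[sp].max() for sp in ("ptc", "cia")}
        induced = all(prof.levels[sp].max() > INDUCTION_FACTOR * base_max[sp]
                      for sp in ("ptc", "cia"))
        try:
            res = peak_separation(prof, prof, threshold=threshold)
            sep = res.separation
            separated = bool(induced and res.separated)
            xa, xb = res.x_a, res.x_b
        except UndefinedPeakError:
            sep, separated, xa, xb = np.nan, False, np.nan, np.nan
        rows.append(dict(t=t, ptc_peak_x=xa, cia_peak_x=xb,
                         separation=sep, separated=separated, induced=induced))
    return pd.DataFrame(rows)


def first_separation_time(series: pd.DataFrame):
    hits = series[series["separated"]]
    return float(hits["t"].iloc[0]) if len(hits) else None


def first_row_ptc_peak_time(trace: SimulationTrace) -> float:
    """Time at which total Ptc summed over the first cell row peaks."""
    first_row = np.argsort(trace.centroids[:, 1])[: trace.config.ncols]
    total = (trace.state["ptc"] + trace.state["hh_ptc"]
             + trace.state["smo_ptc"])[:, first_row].sum(axis=1)
    return float(trace.times[int(np.argmax(total))])


def steady_state_gradient_length(trace: SimulationTrace,
                                 t: float | None = None) -> float:
    """Characteristic length of the Hh profile's exponential fit."""
    if t is None:
        t = float(trace.times[-1])
    prof = extract_profile(trace, t)
    _, _, lam = fit_exponential_decay(prof, "hh")
    return lam


def steady_state_bound_fraction(trace: SimulationTrace, lam: float,
                                t: float | None = None):
    """Mean and per-bin spread of HhPtc/(HhPtc+Ptc) within two gradient lengths."""
    if t is None:
        t = float(trace.times[-1])
    snap = trace.snapshot(t)
    live = ~snap["differentiated"]
    dist = (trace.centroids[:, 1] - snap["source_lead"])[live]
    xs, fr = ptc_bound_fraction(snap["ptc"][live], snap["hh_ptc"][live],
                                dist, bin_width=trace.cell_diameter)
    within = xs <= 2.0 * lam
    per_cell = snap["hh_ptc"][live] / (snap["hh_ptc"][live] + snap["ptc"][live])
    mean = float(per_cell[dist <= 2.0 * lam].mean())
    spread = float(fr[within].max() - fr[within].min())
    return mean, spread, (xs[within], fr[within])


def scenario_metrics(traces: list, scenario: ScenarioConfig) -> dict:
    """Peak metrics, timing, bound fraction and gradient length of a run set."""
    per_rep = []
    for trace in traces:
        series = separation_series(trace)
        entry = {
            "seed": trace.seed,
            "first_separation_min": first_separation_time(series),
            "ptc_peak_time_min": first_row_ptc_peak_time(trace),
            "separated_by_time": {float(r.t): bool(r.separated)
                                  for r in series.itertuples()},
            "separation_by_time": {float(r.t): (None if np.isnan(r.separation)
                                                else float(r.separation))
                                   for r in series.itertuples()},
        }
        try:
            lam = steady_state_gradient_length(trace)
            entry["hh_lambda_um"] = lam
            mean, spread, (xs, fr) = steady_state_bound_fraction(trace, lam)
            entry["bound_fraction_mean"] = mean
            entry["bound_fraction_spread"] = spread
            entry["bound_fraction_curve"] = {
                "distance_um": xs.tolist(), "fraction": fr.tolist()}
        except ProfileError:
            entry["hh_lambda_um"] = None
        per_rep.append(entry)

    metrics = {"scenario": scenario.name, "speed_cph": scenario.speed,
               "replicates": per_rep}
    fs = [e["first_separation_min"] for e in per_rep]
    metrics["first_separation_mean_min"] = (
        float(np.mean([f for f in fs if f is not None]))
        if any(f is not None for f in fs) else None)
    metrics["ptc_peak_time_mean_min"] = float(
        np.mean([e["ptc_peak_time_min"] for e in per_rep]))
    lams = [e.get("hh_lambda_um") for e in per_rep]
    lams = [l for l in lams if l]
    if lams:
        metrics["hh_lambda_mean_um"] = float(np.mean(lams))
    if scenario.speed > 0:
        # verdict in the established traveling state: after the front has
        # crossed at least two cell rows
        t_travel = 2.0 * 60.0 / scenario.speed
        late = [
            any(sep for t, sep in e["separated_by_time"].items() if t >= t_travel)
            for e in per_rep
        ]
        metrics["traveling_state_from_min"] = t_travel
        metrics["separated_in_traveling_state"] = bool(any(late))
    return metrics


def run_scenario(scenario: ScenarioConfig, outdir=None) -> dict:
    """Run a scenario's replicates; optionally write traces, profiles, metrics."""
    traces = [run_simulation(scenario.simulation_config(scenario.seed + i))
              for i in range(scenario.n_replicates)]
    metrics = scenario_metrics(traces, scenario)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for trace in traces:
            trace.to_directory(outdir / f"trace_seed{trace.seed}")
        report_times = [t for t in (60.0, 200.0, 300.0)
                        if t <= scenario.total_time]
        for t in report_times:
            profs = []
            for trace in traces:
                try:
                    profs.append(register_profile(extract_profile(trace, t)))
                except ProfileError:
                    continue
            if len(profs) >= 2:
                profiles_to_csv(profs, outdir / f"profiles_t{int(t):04d}.csv")
                try:
                    summary = summarize_profiles(profs)
                    summary.to_frame().to_csv(
                        outdir / f"summary_t{int(t):04d}.csv", index=False)
                except ProfileError:
                    pass
        (outdir / "metrics.json").write_text(json.dumps(metrics, indent=1))
    return metrics


def sweep(scenario: ScenarioConfig, outpath=None) -> pd.DataFrame:
    """One seeded run set per grid point of ``scenario.sweep_param``.

    Per-point failures are recorded as NaN rows, not raised, so a sweep
    always completes.  ``feedback_tempo`` is a derived axis scaling
    alpha3 and beta3 jointly (the speed of the Ptc feedback loop at a
    fixed Ptc capacity alpha3/beta3).
    """
    if scenario.sweep_param is None:
        raise ValueError("scenario has no sweep axis")
    rows = []
    base = PathwayParameters().replace(**scenario.overrides)
    for value in scenario.sweep_values:
        sub = dataclasses.replace(scenario, sweep_param=None, sweep_values=())
        if scenario.sweep_param == "feedback_tempo":
            sub.overrides = {**scenario.overrides,
                             "alpha3": base.alpha3 * value,
                             "beta3": base.beta3 * value}
        elif scenario.sweep_param == "speed":
            sub.speed = value
        else:
            sub.overrides = {**scenario.overrides, scenario.sweep_param: value}
        row = {"param": scenario.sweep_param, "value": value}
        try:
            m = run_scenario(sub)
            # largest separation at a snapshot flagged as separated
            seps = [e["separation_by_time"] for e in m["replicates"]]
            flags = [e["separated_by_time"] for e in m["replicates"]]
            candidates = [s for d, f in zip(seps, flags)
                          for t, s in d.items() if s is not None and f.get(t)]
            max_sep = max(candidates) if candidates else np.nan
            row.update(first_separation_min=m["first_separation_mean_min"],
                       ptc_peak_time_min=m["ptc_peak_time_mean_min"],
                       hh_lambda_um=m.get("hh_lambda_mean_um"),
                       max_separation_um=(None if np.isnan(max_sep) else float(max_sep)))
        except Exception as exc:   # per-point failure must not abort the sweep
            row.update(first_separation_min=np.nan, ptc_peak_time_min=np.nan,
                       hh_lambda_um=np.nan, max_separation_um=np.nan,
                       error=str(exc))
        rows.append(row)
    df = pd.DataFrame(rows)
    if outpath is not None:
        df.to_csv(outpath, index=False)
    return df


@dataclass
class CalibrationTargets:
    """Observables the parameter set must reproduce."""

    gradient_length_um: float = 12.0
    hh_relaxation_min: float = 60.0          # soft target
    ptc_peak_window_min: tuple = (180.0, 200.0)
    bound_fraction: float = 0.90


@dataclass
class CalibrationReport:
    params: PathwayParameters
    achieved: dict
    targets: CalibrationTargets
    failures: list

    @property
    def ok(self) -> bool:
        return not self.failures


def _quick_run(p: PathwayParameters, total_time: float, seed: int = 1,
               snapshot_interval: float = 10.0) -> SimulationTrace:
    cfg = SimulationConfig(params=p, source=SourceDescriptor(alpha1=p.alpha1),
                           total_time=total_time,
                           snapshot_interval=snapshot_interval, seed=seed)
    return run_simulation(cfg)


def open_loop_midpoints(p: PathwayParameters, total_time: float = 620.0,
                        seed: int = 1):
    """Hill-midpoint calibration on an open-loop pilot.

    Runs the model with the Ptc feedback disabled (alpha3 = 0), records
    the minimum and maximum of the substrate of each Hill function —
    free Smo for CiA production (M2), CiA for Ptc production (M3) —
    and returns the midpoints of those ranges, placing each regulatory
    transition inside its substrate's dynamic range.
    """
    pilot = _quick_run(p.replace(alpha3=1e-12), total_time, seed=seed)
    smo = pilot.state["smo"]
    cia = pilot.state["cia"]
    m2 = float((smo.min() + smo.max()) / 2.0)
    m3 = float((cia.min() + cia.max()) / 2.0)
    return m2, m3


def calibrate(targets: CalibrationTargets | None = None,
              start: PathwayParameters | None = None,
              seed: int = 1, verify: bool = True) -> CalibrationReport:
    """Staged calibration of the unconstrained rate constants.

    (i)   Geometry and printed constants are fixed (cell diameter, D,
          Hill slope m).
    (ii)  beta1 is seeded by the closed-form gradient relation
          beta1 = D / lambda^2, then refined against the fitted length
          of a simulated steady-state profile.
    (iii) The Hh:Ptc binding scale (k2, with k1 fixed) is tuned so the
          steady-state bound fraction matches its target.
    (iv)  The feedback strength alpha3 is tuned so the first-row Ptc
          peak lands inside the target window.
    (v)   M2 and M3 are set by the open-loop midpoint rule.

    Targets that cannot be met within the search bounds are reported as
    explicit failures, never silently accepted.
    """
    targets = targets or CalibrationTargets()
    p = start or PathwayParameters()
    failures, achieved = [], {}

    # (ii) gradient length: closed form, then simulation refinement
    beta1 = p.D / targets.gradient_length_um**2
    p = p.replace(beta1=beta1)
    for _ in range(2):
        trace = _quick_run(p, 600.0, seed=seed)
        lam = steady_state_gradient_length(trace)
        p = p.replace(beta1=np.clip(p.beta1 * (lam / targets.gradient_length_um) ** 2,
                                    1e-5, 1.0))
    trace = _quick_run(p, 600.0, seed=seed)
    lam = steady_state_gradient_length(trace)
    achieved["gradient_length_um"] = lam
    if abs(lam - targets.gradient_length_um) > 0.2 * targets.gradient_length_um:
        failures.append(f"gradient length {lam:.1f} um vs target "
                        f"{targets.gradient_length_um} um")
    achieved["hh_relaxation_min"] = 1.0 / p.beta1
    if 1.0 / p.beta1 > 2.0 * targets.hh_relaxation_min:
        failures.append("Hh-only relaxation slower than the (soft) 60-min target")

    # (iii) bound fraction via the unbinding rate
    for _ in range(3):
        mean_f, _, _ = steady_state_bound_fraction(trace, lam)
        ratio = (mean_f / (1 - mean_f)) / (targets.bound_fraction
                                           / (1 - targets.bound_fraction))
        if abs(mean_f - targets.bound_fraction) < 0.02:
            break
        p = p.replace(k2=float(np.clip(p.k2 * ratio, 1e-4, 1.0)))
        trace = _quick_run(p, 600.0, seed=seed)
    mean_f, spread, _ = steady_state_bound_fraction(trace, lam)
    achieved["bound_fraction"] = mean_f
    achieved["bound_fraction_spread"] = spread
    if abs(mean_f - targets.bound_fraction) > 0.10:
        failures.append(f"bound fraction {mean_f:.2f} vs target "
                        f"{targets.bound_fraction}")

    # (v) Hill midpoints from the open-loop pilot (before timing, so the
    # feedback tempo is tuned against the final regulatory thresholds)
    m2, m3 = open_loop_midpoints(p, seed=seed)
    achieved["M2_midpoint"] = m2
    achieved["M3_midpoint"] = m3
    p = p.replace(M2=m2, M3=m3)

    # (iv) Ptc peak timing via feedback strength (peak time falls as
    # alpha3 rises); bisection on log alpha3
    def mean_peak_time(pp, base_seed, n=5):
        return float(np.mean([
            first_row_ptc_peak_time(_quick_run(pp, 400.0, seed=base_seed + i))
            for i in range(n)]))

    lo_a, hi_a = p.alpha3 / 4.0, p.alpha3 * 4.0
    window = targets.ptc_peak_window_min
    center = 0.5 * (window[0] + window[1])
    tpk = None
    for _ in range(6):
        tpk = mean_peak_time(p, seed)
        if abs(tpk - center) <= 5.0:
            break
        if tpk > center:
            lo_a = p.alpha3
        else:
            hi_a = p.alpha3
        p = p.replace(alpha3=float(np.sqrt(lo_a * hi_a)))
    achieved["ptc_peak_time_min"] = tpk
    if not (window[0] <= tpk <= window[1]):
        failures.append(f"Ptc peak time {tpk:.0f} min outside {window}")

    if verify:
        achieved["verification_ptc_peak_min"] = mean_peak_time(p, seed + 100)

    return CalibrationReport(params=p, achieved=achieved, targets=targets,
                             failures=failures)
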