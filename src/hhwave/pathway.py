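"""Core Hedgehog pathway model: rate equations, Hill regulation, parameters.

The model tracks five species per cell — free Patched (Ptc), the
Hedgehog--Patched complex (HhPtc), free Smoothened (Smo), the
Smo--Ptc complex (SmoPtc) and the transcriptional activator CiA —
coupled to the local extracellular Hh concentration.  Signaling logic:
Hh binds and titrates Ptc; Ptc left free represses Smo by binding it;
free Smo drives CiA production through a Hill function; CiA in turn
activates Ptc production, closing the pathway's negative feedback.
Total Smo per cell is conserved (Smo + SmoPtc = smo_total); the
repressor form CiR is eliminated by a fast-equilibrium argument, so
CiA is the single transcriptional readout.

Concentrations are dimensionless; space is in micrometres and time in
minutes throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

__all__ = [
    "PathwayParameters",
    "CellState",
    "CellDerivatives",
    "SAMPLED_FIELDS",
    "hill_activation",
    "cell_rhs",
    "sample_cell_parameters",
    "basal_partition",
]


class PathwayError(ValueError):
    """Invalid parameter or state passed to a pathway operation."""


@dataclass
class PathwayParameters:
    """Mean parameter set of the pathway + transport model.

    Defaults are the calibrated values used for all standard runs.  The
    spatial scale is anchored by the measured Hh gradient length
    (lambda ~ 12 um, cells ~ 5 um across) and the temporal scale by the
    Ptc response peaking 180-200 min after Hh stimulation.  D is the
    literature diffusivity of disc morphogens, 0.1 um^2/s expressed in
    the model's per-minute units; beta1 = D / lambda^2 then yields both
    the 12-um steady gradient and an Hh-only relaxation time of ~25 min
    (steady within about an hour).  The Hill midpoints M2 and M3 follow
    the open-loop midpoint rule (see experiments.calibrate); m = 5 is an
    intermediate Hill slope, to which the output is robust.

    Units: rates 1/min; production rates concentration/min; binding
    rates 1/(concentration*min); D um^2/min; cell_diameter um.
    """

    D: float = 6.0
    alpha1: float = 20.0
    k1: float = 0.028
    k2: float = 0.05
    k3: float = 0.02
    k4: float = 0.009
    beta1: float = 0.042
    beta2: float = 0.021
    beta3: float = 3e-4
    alpha2: float = 0.21
    alpha3: float = 6.0
    m: float = 5.0
    M2: float = 5.0
    M3: float = 5.0
    smo_total: float = 10.0
    ptc_basal: float = 10.0
    cell_diameter: float = 5.0
    cv: float = 0.10

    def __post_init__(self) -> None:
        for name in (
            "D", "alpha1", "k1", "k2", "k3", "k4", "beta1", "beta2",
            "beta3", "alpha2", "alpha3", "M2", "M3", "smo_total",
            "ptc_basal", "cell_diameter",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise PathwayError(f"{name} must be finite and >= 0, got {value!r}")
        if self.m < 1:
            raise PathwayError(f"Hill coefficient m must be >= 1, got {self.m!r}")
        if not (0 <= self.cv < 1):
            raise PathwayError(f"cv must lie in [0, 1), got {self.cv!r}")

    def replace(self, **overrides) -> "PathwayParameters":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_file(self, path) -> None:
        """Write as a flat ``key: value`` text file."""
        lines = [f"{k}: {v!r}" for k, v in self.to_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "PathwayParameters":
        fields = {f.name for f in dataclasses.fields(cls)}
        values = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition(":")
            key = key.strip()
            if key not in fields:
                raise PathwayError(f"unknown parameter {key!r} in {path}")
            values[key] = float(raw)
        return cls(**values)


# Fields drawn per cell from a gamma distribution; geometry and
# transport constants (D, cell_diameter, alpha1, beta1, m) are global.
SAMPLED_FIELDS = (
    "k1", "k2", "k3", "k4", "beta2", "beta3", "alpha2", "alpha3",
    "M2", "M3", "smo_total", "ptc_basal",
)


@dataclass
class CellState:
    """Intracellular state of a single cell."""

    ptc: float
    hh_ptc: float
    smo: float
    smo_ptc: float
    cia: float
    differentiated: bool = False
    centroid: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("ptc", "hh_ptc", "smo", "smo_ptc", "cia"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise PathwayError(f"concentration {name} must be >= 0")

    @property
    def smo_total(self) -> float:
        return self.smo + self.smo_ptc


class CellDerivatives(NamedTuple):
    d_ptc: float
    d_hh_ptc: float
    d_smo: float
    d_smo_ptc: float
    d_cia: float
    hh_consumption: float


def hill_activation(x, M, m):
    """Activating Hill function x^m / (M^m + x^m).

    Strictly increasing in x, equal to 1/2 at ``x = M``, bounded in
    [0, 1).  Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    M = np.asarray(M, dtype=float)
    if np.any(M <= 0):
        raise PathwayError("Hill midpoint M must be > 0")
    if np.any(m < 1):
        raise PathwayError("Hill coefficient m must be >= 1")
    if np.any(x < 0):
        raise PathwayError("Hill input x must be >= 0")
    # compute in a scale-free form to avoid overflow for large x/M
    with np.errstate(over="ignore"):
        r = (x / M) ** m
        out = r / (1.0 + r)
    out = np.where(np.isfinite(r), out, 1.0)
    return out if out.ndim else float(out)


def cell_rhs(state, hh_local, p: PathwayParameters | dict):
    """Right-hand sides of the per-cell rate equations.

    ``state`` may be a :class:`CellState` or any object with the same
    field names holding scalars or aligned arrays; ``p`` likewise may be
    a :class:`PathwayParameters` or a mapping of (possibly per-cell)
    values.  Returns a :class:`CellDerivatives`; ``hh_consumption`` is
    the net rate at which the cell removes free Hh from its
    surroundings (binding minus unbinding).  A differentiated cell is
    inert: all derivatives and the consumption rate are zero.
    """
    get = (p.get if isinstance(p, dict) else lambda k: getattr(p, k))
    ptc, hh_ptc = np.asarray(state.ptc, float), np.asarray(state.hh_ptc, float)
    smo, smo_ptc = np.asarray(state.smo, float), np.asarray(state.smo_ptc, float)
    cia = np.asarray(state.cia, float)
    hh_local = np.asarray(hh_local, float)
    for name, val in (("ptc", ptc), ("hh_ptc", hh_ptc), ("smo", smo),
                      ("smo_ptc", smo_ptc), ("cia", cia), ("hh_local", hh_local)):
        if np.any(val < 0):
            raise PathwayError(f"negative {name} passed to cell_rhs")

    k1, k2 = get("k1"), get("k2")
    k3, k4 = get("k3"), get("k4")
    beta2, beta3 = get("beta2"), get("beta3")
    alpha2, alpha3 = get("alpha2"), get("alpha3")
    m = get("m")

    bind = k1 * hh_local * ptc
    unbind = k2 * hh_ptc
    smo_bind = k3 * ptc * smo
    smo_unbind = k4 * smo_ptc

    d_hh_ptc = bind - unbind - beta3 * hh_ptc
    d_ptc = (-bind + unbind - smo_bind + smo_unbind - beta3 * ptc
             + alpha3 * hill_activation(cia, get("M3"), m))
    d_smo = -smo_bind + smo_unbind
    d_smo_ptc = smo_bind - smo_unbind
    d_cia = alpha2 * hill_activation(smo, get("M2"), m) - beta2 * cia
    consumption = bind - unbind

    live = ~np.asarray(getattr(state, "differentiated", False), bool)
    z = np.where
    return CellDerivatives(
        z(live, d_ptc, 0.0), z(live, d_hh_ptc, 0.0), z(live, d_smo, 0.0),
        z(live, d_smo_ptc, 0.0), z(live, d_cia, 0.0), z(live, consumption, 0.0),
    )


def sample_cell_parameters(mean_params: PathwayParameters, n: int,
                           seed=None) -> dict:
    """Draw per-cell parameter values from gamma distributions.

    Each field in :data:`SAMPLED_FIELDS` is drawn independently with
    the stated mean and standard deviation ``cv * mean`` (gamma shape
    ``1/cv**2``, scale ``mean * cv**2``), representing cell-to-cell
    variability.  Global constants (D, alpha1, beta1, m, geometry) are
    copied unchanged.  Reproducible: the same seed yields the same set.
    """
    if mean_params.cv >= 1:
        raise PathwayError("cv >= 1 is outside the intended gamma regime")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {"m": mean_params.m}
    for name in SAMPLED_FIELDS:
        mean = getattr(mean_params, name)
        if mean <= 0:
            raise PathwayError(f"cannot gamma-sample non-positive mean for {name}")
        if mean_params.cv == 0:
            out[name] = np.full(n, mean)
        else:
            shape = 1.0 / mean_params.cv**2
            out[name] = rng.gamma(shape, mean / shape, n)
    return out


def basal_partition(cell_params: dict) -> dict:
    """Resting state of cells that have never seen Hh.

    The basal Ptc pool distributes between free Ptc and the SmoPtc
    complex at binding equilibrium (k3*ptc*smo = k4*smo_ptc, solved in
    closed form), and CiA sits at its production/degradation balance
    for the resulting free-Smo level.  Returns arrays keyed by species.
    """
    P0 = np.asarray(cell_params["ptc_basal"], float)
    S0 = np.asarray(cell_params["smo_total"], float)
    Kd = np.asarray(cell_params["k4"], float) / np.asarray(cell_params["k3"], float)
    b = P0 + S0 + Kd
    smo_ptc = (b - np.sqrt(b * b - 4.0 * P0 * S0)) / 2.0
    smo = S0 - smo_ptc
    cia = (cell_params["alpha2"] / cell_params["beta2"]
           * hill_activation(smo, cell_params["M2"], cell_params["m"]))
    return {
        "ptc": P0 - smo_ptc,
        "hh_ptc": np.zeros_like(P0),
        "smo": smo,
        "smo_ptc": smo_ptc,
        "cia": np.asarray(cia, float),
    }
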