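"""Synthetic "experimental" profile datasets.

Emulates the statistical structure of confocal profile quantifications
without any imaging: per-replicate 1D intensity traces of Hh, Ptc and
CiA versus distance from the source, with replicate-to-replicate
variability in length and spatial resolution, per-replicate
multiplicative intensity scaling (staining/acquisition differences,
lognormal) and additive Gaussian pixel noise.  Ground truth is stored
alongside every dataset so pipeline estimates can be checked against
it.  Truth profiles may come from simulation traces or from closed-form
shapes, so the statistics pipeline can be tested independently of the
simulator.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .profiles import SpatialProfile

__all__ = [
    "NoiseModel", "ParametricTruth", "generate_replicates",
    "generate_two_condition_dataset",
]


class SynthError(ValueError):
    pass


@dataclass
class NoiseModel:
    """Replicate-to-replicate variability of extracted profiles.

    Defaults reflect the study conditions the pipeline must cope with:
    at least five replicates per condition, each of different size
    and/or spatial resolution, with ~10% staining-intensity scale
    differences between specimens and a few percent additive noise.
    """

    intensity_scale_sd: float = 0.10     # relative sd of lognormal scaling
    additive_sd: float = 0.05            # in units of each species' truth max
    resolution_jitter: tuple = (4.0, 6.0)   # per-replicate bin width range, um
    length_jitter: tuple = (38.0, 48.0)     # per-replicate profile length, um
    seed: int = 0

    def __post_init__(self):
        if self.intensity_scale_sd < 0 or self.additive_sd < 0:
            raise SynthError("noise standard deviations must be >= 0")
        for rng_pair, name in ((self.resolution_jitter, "resolution_jitter"),
                               (self.length_jitter, "length_jitter")):
            if rng_pair[1] < rng_pair[0] or rng_pair[0] <= 0:
                raise SynthError(f"{name} range must be non-empty and positive")


@dataclass
class ParametricTruth:
    """Closed-form ground-truth profile.

    Hh decays exponentially from the source with length ``hh_lambda``;
    Ptc is a smooth (sigmoidal-rise times exponential-decay) bump whose
    realized maximum equals ``ptc_max`` exactly — the bump is
    renormalized by its own peak — and whose decaying flank approaches
    the length ``ptc_lambda`` (the quantity the exponential-fit
    statistic targets); CiA is a Gaussian bump of height ``cia_max`` at
    ``cia_peak_x``.  All shapes are smooth enough for an order-7
    polynomial to represent with sub-percent error, matching the
    smoothness of real stained profiles.  Scales mirror typical
    simulation output.
    """

    hh_amplitude: float = 50.0
    hh_lambda: float = 12.0
    ptc_max: float = 50.0
    ptc_peak_x: float = 4.0
    ptc_lambda: float = 13.0
    ptc_baseline: float = 0.0
    ptc_rise_width: float = 1.5
    cia_max: float = 4.0
    cia_peak_x: float = 12.5
    cia_width: float = 6.0
    cia_baseline: float = 0.4

    def _ptc_bump(self, x: np.ndarray) -> np.ndarray:
        rise = 1.0 / (1.0 + np.exp(-(x - self.ptc_peak_x / 2.0)
                                   / self.ptc_rise_width))
        return rise * np.exp(-x / self.ptc_lambda)

    def evaluate(self, x: np.ndarray) -> dict:
        x = np.asarray(x, float)
        hh = self.hh_amplitude * np.exp(-np.clip(x, 0, None) / self.hh_lambda)
        fine = np.linspace(0.0, 20.0 * self.ptc_lambda, 4001)
        norm = self._ptc_bump(fine).max()
        ptc = (self.ptc_baseline
               + (self.ptc_max - self.ptc_baseline) * self._ptc_bump(x) / norm)
        cia = (self.cia_baseline + (self.cia_max - self.cia_baseline)
               * np.exp(-((x - self.cia_peak_x) ** 2) / (2 * self.cia_width**2)))
        return {"hh": hh, "ptc": ptc, "cia": cia}

    def record(self) -> dict:
        rec = asdict(self)
        rec.update(self.realized_metrics())
        return rec

    def realized_metrics(self) -> dict:
        """Quantities the profile pipeline estimates, evaluated on the
        noiseless truth at fine resolution.

        ``ptc_lambda_fitted`` is what the decay-fit estimator (peak to
        domain end, linear least squares) yields on the exact curve; it
        differs slightly from the asymptotic ``ptc_lambda`` because the
        region just beyond the maximum is flatter than the tail.
        """
        x = np.linspace(0.25, 46.0, 400)
        levels = self.evaluate(x)
        from .profiles import SpatialProfile, fit_exponential_decay
        _, expo, lam = fit_exponential_decay(
            SpatialProfile(x, {"ptc": levels["ptc"]}), "ptc")
        return {"ptc_max_realized": float(levels["ptc"].max()),
                "ptc_lambda_fitted": float(lam),
                "ptc_exponent_fitted": float(expo)}


def _truth_levels(truth, x):
    if isinstance(truth, ParametricTruth):
        return truth.evaluate(x)
    if isinstance(truth, SpatialProfile):
        return {sp: np.interp(x, truth.distances, y)
                for sp, y in truth.levels.items()}
    raise SynthError("truth must be a ParametricTruth or SpatialProfile")


def generate_replicates(truth, n: int, noise: NoiseModel,
                        rng=None, id_prefix: str = "rep"):
    """Synthesize ``n`` noisy replicate profiles of a ground truth.

    Each replicate is sampled at its own (jittered) bin width and
    length, scaled by a lognormal intensity factor, degraded with
    additive Gaussian noise and clipped at zero.  Returns
    (replicates, truth_record); the same seed yields the same dataset.
    """
    if n < 2:
        raise SynthError("need n >= 2 replicates")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    reps = []
    for i in range(n):
        bw = rng.uniform(*noise.resolution_jitter)
        length = rng.uniform(*noise.length_jitter)
        x = np.arange(bw / 2.0, length, bw)
        levels = _truth_levels(truth, x)
        scale = (np.exp(rng.normal(0.0, noise.intensity_scale_sd))
                 if noise.intensity_scale_sd > 0 else 1.0)
        noisy = {}
        for sp, y in levels.items():
            sd = noise.additive_sd * max(float(np.max(y)), 1e-12)
            noisy[sp] = np.clip(scale * y + rng.normal(0.0, sd, size=y.shape),
                                0.0, None)
        if all(np.all(v == 0) for v in noisy.values()):
            raise SynthError("noise drove an entire replicate to zero; "
                             "reduce additive_sd")
        reps.append(SpatialProfile(x, noisy, replicate_id=f"{id_prefix}{i}",
                                   bin_width=bw))
    record = truth.record() if isinstance(truth, ParametricTruth) else {
        "distances": truth.distances.tolist(),
        "levels": {k: v.tolist() for k, v in truth.levels.items()},
    }
    return reps, record


def generate_two_condition_dataset(base_truth: ParametricTruth,
                                   ptc_max_ratio: float = 1.0,
                                   exponent_ratio: float = 1.0,
                                   n_per_group: int = 5,
                                   noise: NoiseModel | None = None,
                                   rng=None):
    """Control vs perturbed replicate sets for end-to-end statistics tests.

    Group B's truth has its Ptc maximum multiplied by ``ptc_max_ratio``
    and its Ptc decay exponent (1/lambda) by ``exponent_ratio`` before
    noise, emulating a genetic perturbation; ratios of 1 give a null
    dataset for type-I-error studies.
    """
    if ptc_max_ratio <= 0 or exponent_ratio <= 0:
        raise SynthError("effect ratios must be > 0")
    if n_per_group < 3:
        raise SynthError("need n >= 3 per group")
    if noise is None:
        noise = NoiseModel()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    truth_b = ParametricTruth(**{**asdict(base_truth),
                                 "ptc_max": base_truth.ptc_max * ptc_max_ratio,
                                 "ptc_lambda": base_truth.ptc_lambda / exponent_ratio})
    group_a, rec_a = generate_replicates(base_truth, n_per_group, noise,
                                         rng=rng, id_prefix="ctrlA_")
    group_b, rec_b = generate_replicates(truth_b, n_per_group, noise,
                                         rng=rng, id_prefix="condB_")
    record = {"group_a": rec_a, "group_b": rec_b,
              "ptc_max_ratio": ptc_max_ratio, "exponent_ratio": exponent_ratio}
    return group_a, group_b, record


def write_truth_record(record: dict, path) -> None:
    Path(path).write_text(json.dumps(record, indent=1))
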