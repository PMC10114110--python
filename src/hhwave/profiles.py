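"""Quantification of spatial signaling profiles.

Mirrors the quantification applied to stained discs: cells (or image
columns) are binned by distance from the Hh source into 1D intensity
profiles; profiles are registered so x = 0 is where Hh starts to
decrease; replicates of differing length and resolution are pooled by
fitting each with a 7th-order polynomial on a common domain and
averaging the coefficients, with a 50% confidence band; the Ptc
decaying flank is summarized by an exponential fit; group comparisons
use Welch's one-tailed t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SpatialProfile", "ProfileFit", "ProfileSummary",
    "extract_profile", "register_profile", "fit_polynomial",
    "average_profiles", "summarize_profiles", "fit_exponential_decay",
    "peak_separation", "ptc_bound_fraction", "welch_one_tailed_t",
    "profiles_to_csv", "profiles_from_csv",
]

SPECIES = ("hh", "ptc", "cia")


class ProfileError(ValueError):
    """Profile operation received unusable input."""


class UndefinedPeakError(ProfileError):
    """A peak position was requested on a flat profile."""


class RegistrationError(ProfileError):
    """The Hh channel never starts to decrease."""


@dataclass
class SpatialProfile:
    """One replicate's distance-binned species levels at one time."""

    distances: np.ndarray
    levels: dict                      # species name -> array
    replicate_id: str = "r0"
    time_min: float = 0.0
    registered: bool = False
    bin_width: float = 5.0

    def __post_init__(self):
        self.distances = np.asarray(self.distances, float)
        self.levels = {k: np.asarray(v, float) for k, v in self.levels.items()}
        if np.any(np.diff(self.distances) <= 0):
            raise ProfileError("distances must be strictly increasing")
        for name, v in self.levels.items():
            if v.shape != self.distances.shape:
                raise ProfileError(f"species {name} length mismatch")
            if np.any(v < 0):
                raise ProfileError(f"species {name} has negative levels")

    @property
    def n_bins(self) -> int:
        return len(self.distances)

    def shifted(self, dx: float) -> "SpatialProfile":
        return SpatialProfile(self.distances - dx, dict(self.levels),
                              self.replicate_id, self.time_min,
                              registered=True, bin_width=self.bin_width)


def extract_profile(trace, t: float, bin_width: float | None = None) -> SpatialProfile:
    """Distance-binned mean species levels from a simulation snapshot.

    Distances are measured from the source's current leading edge, so
    moving-source profiles live in the co-moving frame.  Differentiated
    cells are excluded; empty bins are dropped.  The reported "ptc"
    channel is total Ptc protein (free + Hh-bound + Smo-bound), i.e.
    what an antibody stain would see.
    """
    if bin_width is None:
        bin_width = trace.cell_diameter
    if bin_width <= 0:
        raise ProfileError("bin_width must be > 0")
    snap = trace.snapshot(t)
    live = ~snap["differentiated"]
    if not live.any():
        raise ProfileError(f"no live cells at t={t}")
    dist = trace.centroids[:, 1] - snap["source_lead"]
    dist = dist[live]
    values = {
        "hh": snap["hh_cell"][live],
        "ptc": snap["ptc_total"][live],
        "cia": snap["cia"][live],
    }
    bins = np.floor(dist / bin_width).astype(int)
    order = np.unique(bins)
    xs = np.array([dist[bins == b].mean() for b in order])
    levels = {name: np.array([v[bins == b].mean() for b in order])
              for name, v in values.items()}
    return SpatialProfile(xs, levels, replicate_id=f"seed{trace.seed}",
                          time_min=float(t), bin_width=float(bin_width))


def moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edge windows renormalized to their overlap."""
    kernel = np.ones(int(window))
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def register_profile(profile: SpatialProfile, smoothing_window: int = 3,
                     min_decline: float = 0.2) -> SpatialProfile:
    """Set x = 0 where the (smoothed) Hh signal starts to decrease.

    This marks the beginning of the Hh-receiving domain.  Raises
    :class:`RegistrationError` if Hh is monotone increasing throughout,
    or if the decline beyond the candidate origin is smaller than
    ``min_decline`` of the smoothed maximum (noise around a constant is
    not a gradient).
    """
    if "hh" not in profile.levels:
        raise ProfileError("registration requires an hh channel")
    if profile.n_bins < 5:
        raise ProfileError("need >= 5 bins to register")
    smooth = moving_average(profile.levels["hh"], smoothing_window)
    decreasing = np.diff(smooth) < 0
    if not decreasing.any():
        raise RegistrationError("Hh never decreases; cannot place x=0")
    i0 = int(np.argmax(decreasing))
    peak = smooth.max()
    decline = smooth[i0] - smooth[i0:].min()
    if peak <= 0 or decline < min_decline * peak:
        raise RegistrationError(
            "no significant Hh decline; profile looks like noise around a constant")
    return profile.shifted(profile.distances[i0])


@dataclass
class ProfileFit:
    """Least-squares polynomial fit of one replicate on a common domain."""

    domain: tuple
    coefficients: dict                # species -> ndarray (ascending powers)
    residuals: dict
    order: int
    replicate_id: str = "r0"

    def curve(self, species: str, x: np.ndarray) -> np.ndarray:
        return _eval_poly(self.coefficients[species], x, self.domain)


def _scale(x, domain):
    lo, hi = domain
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def _eval_poly(coefs, x, domain):
    return np.polynomial.polynomial.polyval(_scale(np.asarray(x, float), domain), coefs)


def fit_polynomial(profile: SpatialProfile, order: int = 7,
                   domain: tuple | None = None) -> ProfileFit:
    """Fit each species with a polynomial of the given order.

    Distances are mapped to [-1, 1] on the fitting domain before the
    least-squares solve, so replicates fitted on the same domain have
    directly comparable (and averageable) coefficients.
    """
    if profile.n_bins < order + 2:
        raise ProfileError(
            f"need >= {order + 2} bins for an order-{order} fit, "
            f"got {profile.n_bins}")
    if domain is None:
        domain = (float(profile.distances[0]), float(profile.distances[-1]))
    xs = _scale(profile.distances, domain)
    design = np.vander(xs, order + 1, increasing=True)
    if np.linalg.matrix_rank(design) < order + 1:
        raise ProfileError("rank-deficient design; degenerate distances")
    coefs, residuals = {}, {}
    for name, y in profile.levels.items():
        c, *_ = np.linalg.lstsq(design, y, rcond=None)
        coefs[name] = c
        residuals[name] = y - design @ c
    return ProfileFit(domain, coefs, residuals, order, profile.replicate_id)


@dataclass
class ProfileSummary:
    """Replicate-averaged curves, uncertainty band and scalar metrics."""

    grid: np.ndarray
    mean_curve: dict                  # species -> array (coefficient-mean poly)
    ci50_lower: dict
    ci50_upper: dict
    pointwise_mean: dict              # direct point-to-point average
    se_band: dict                     # species -> (lower, upper), mean +/- 0.674 SE
    ptc_peak_x: float = np.nan
    cia_peak_x: float = np.nan
    ptc_max: float = np.nan
    ptc_decay_exponent: float = np.nan   # 1/um
    ptc_decay_length: float = np.nan     # um
    n_replicates: int = 0

    def to_frame(self) -> pd.DataFrame:
        data = {"distance_um": self.grid}
        for sp in self.mean_curve:
            data[f"{sp}_mean"] = self.mean_curve[sp]
            data[f"{sp}_ci_lo"] = self.ci50_lower[sp]
            data[f"{sp}_ci_hi"] = self.ci50_upper[sp]
        return pd.DataFrame(data)


def common_domain(profiles) -> tuple:
    lo = max(float(p.distances[0]) for p in profiles)
    hi = min(float(p.distances[-1]) for p in profiles)
    if hi <= lo:
        raise ProfileError("replicate domains do not overlap")
    return lo, hi


def resample(profile: SpatialProfile, grid: np.ndarray) -> SpatialProfile:
    levels = {name: np.interp(grid, profile.distances, y)
              for name, y in profile.levels.items()}
    return SpatialProfile(grid, levels, profile.replicate_id,
                          profile.time_min, profile.registered,
                          profile.bin_width)


def average_profiles(fits: list, n_grid: int = 200,
                     raw_profiles: list | None = None) -> ProfileSummary:
    """Pool per-replicate polynomial fits into a summary.

    The mean curve is the polynomial built from coefficient-wise mean
    parameters; the 50% confidence band is the pointwise interquartile
    (25th-75th percentile) band of the replicate-fitted curves.  A
    parametric alternative (mean +/- 0.674 SE of the coefficient-mean
    curve) is also reported, as is the direct pointwise average of the
    fitted curves for cross-checking.
    """
    if len(fits) < 2:
        raise ProfileError("need >= 2 replicates to average")
    domain = fits[0].domain
    for f in fits[1:]:
        if not np.allclose(f.domain, domain):
            raise ProfileError("replicate fits are on incompatible domains")
    grid = np.linspace(domain[0], domain[1], n_grid)
    species = list(fits[0].coefficients)
    mean_curve, lo50, hi50, pw_mean, se_band = {}, {}, {}, {}, {}
    for sp in species:
        coef_stack = np.stack([f.coefficients[sp] for f in fits])
        curves = np.stack([f.curve(sp, grid) for f in fits])
        mean_coef = coef_stack.mean(axis=0)
        mean_curve[sp] = _eval_poly(mean_coef, grid, domain)
        lo50[sp] = np.percentile(curves, 25, axis=0)
        hi50[sp] = np.percentile(curves, 75, axis=0)
        if raw_profiles is not None:
            raw = np.stack([np.interp(grid, rp.distances, rp.levels[sp])
                            for rp in raw_profiles])
            pw_mean[sp] = raw.mean(axis=0)
        else:
            pw_mean[sp] = curves.mean(axis=0)
        se = curves.std(axis=0, ddof=1) / np.sqrt(len(fits))
        se_band[sp] = (mean_curve[sp] - 0.674 * se, mean_curve[sp] + 0.674 * se)
    summary = ProfileSummary(grid, mean_curve, lo50, hi50, pw_mean, se_band,
                             n_replicates=len(fits))
    if "ptc" in species:
        summary.ptc_peak_x = float(grid[int(np.argmax(mean_curve["ptc"]))])
        # maximum Ptc level and decay exponent are per-replicate
        # statistics, averaged across replicates; fall back to the mean
        # curve when raw replicate data are not supplied
        if raw_profiles is not None:
            summary.ptc_max = float(np.mean(
                [rp.levels["ptc"].max() for rp in raw_profiles]))
            expos = []
            for rp in raw_profiles:
                try:
                    _, expo, _ = fit_exponential_decay(rp, "ptc")
                    expos.append(expo)
                except ProfileError:
                    continue
            if expos:
                summary.ptc_decay_exponent = float(np.mean(expos))
                summary.ptc_decay_length = 1.0 / summary.ptc_decay_exponent
        else:
            summary.ptc_max = float(np.max(mean_curve["ptc"]))
            try:
                prof = SpatialProfile(grid, {"ptc": np.clip(mean_curve["ptc"], 0, None)})
                _, expo, lam = fit_exponential_decay(prof, "ptc")
                summary.ptc_decay_exponent = expo
                summary.ptc_decay_length = lam
            except ProfileError:
                pass
    if "cia" in species:
        summary.cia_peak_x = float(grid[int(np.argmax(mean_curve["cia"]))])
    return summary


def summarize_profiles(profiles: list, order: int = 7, n_grid: int = 200) -> ProfileSummary:
    """Full pooling pipeline: resample to the common domain, fit, average."""
    domain = common_domain(profiles)
    n_pts = max(order + 2, max(p.n_bins for p in profiles))
    grid = np.linspace(domain[0], domain[1], n_pts)
    resampled = [resample(p, grid) for p in profiles]
    fits = [fit_polynomial(rp, order, domain) for rp in resampled]
    return average_profiles(fits, n_grid=n_grid, raw_profiles=resampled)


def fit_exponential_decay(profile: SpatialProfile, species: str):
    """Fit A*exp(-x/lambda) to the decaying flank of a species profile.

    The decaying region runs from the profile maximum to the domain
    end and must contain at least 4 bins beyond the peak.  The fit is
    linear-space least squares, initialized from a log-space regression
    on floor-clipped levels.  Returns (amplitude, exponent 1/lambda,
    characteristic length lambda).
    """
    if species not in profile.levels:
        raise ProfileError(f"species {species!r} not in profile")
    y = profile.levels[species]
    i0 = int(np.argmax(y))
    xd = profile.distances[i0:] - profile.distances[i0]
    yd = y[i0:]
    if len(xd) < 5:
        raise ProfileError("no usable decaying region (need peak + >= 4 bins)")
    if yd.max() <= 0 or yd[0] <= yd[-1] * (1 + 1e-9) or np.ptp(yd) == 0:
        raise ProfileError("profile does not decay after its maximum")
    floor = max(yd.max() * 1e-6, 1e-300)
    logy = np.log(np.clip(yd, floor, None))
    slope, intercept = np.polyfit(xd, logy, 1)
    lam0 = -1.0 / slope if slope < 0 else xd[-1]
    p0 = [float(np.exp(intercept)), float(np.clip(lam0, 1e-3, 10 * xd[-1]))]
    popt, _ = optimize.curve_fit(
        lambda x, A, lam: A * np.exp(-x / lam), xd, yd, p0=p0, maxfev=20000)
    A, lam = float(popt[0]), float(popt[1])
    if lam <= 0:
        raise ProfileError("exponential fit collapsed to non-decaying solution")
    return A, 1.0 / lam, lam


class PeakSeparation(NamedTuple):
    x_a: float
    x_b: float
    separation: float
    separated: bool
    boundary_peak: bool


def _smoothed_argmax(x, y, window):
    smooth = moving_average(y, window)
    rng = smooth.max() - smooth.min()
    if smooth.max() <= 0 or rng <= 1e-12 * max(abs(smooth.max()), 1e-300):
        raise UndefinedPeakError("flat profile has no defined peak")
    # tie-break toward the source (smallest x): argmax returns first max
    i = int(np.argmax(smooth))
    return float(x[i]), i in (0, len(x) - 1)


def peak_separation(profile_a: SpatialProfile, profile_b: SpatialProfile,
                    smoothing_window: int = 3,
                    species_a: str = "ptc", species_b: str = "cia",
                    threshold: float = 5.0) -> PeakSeparation:
    """Signed distance between smoothed profile maxima (b minus a).

    By convention profile a carries Ptc and profile b CiA, so a positive
    separation means the CiA maximum lies farther from the source.
    ``separated`` is true when the separation is at least one cell
    diameter (the ``threshold``).  A peak landing on the first or last
    bin sets ``boundary_peak``.
    """
    if not np.allclose(profile_a.distances, profile_b.distances):
        raise ProfileError("profiles must be registered on the same domain")
    x_a, edge_a = _smoothed_argmax(profile_a.distances,
                                   profile_a.levels[species_a], smoothing_window)
    x_b, edge_b = _smoothed_argmax(profile_b.distances,
                                   profile_b.levels[species_b], smoothing_window)
    sep = x_b - x_a
    return PeakSeparation(x_a, x_b, sep, sep >= threshold, edge_a or edge_b)


def ptc_bound_fraction(ptc, hh_ptc, distances, bin_width: float = 5.0):
    """Per-distance-bin mean of HhPtc / (HhPtc + Ptc).

    Bins whose entire Ptc pool (free + bound) is zero are dropped with
    a warning.  Returns (bin centers, fractions).
    """
    ptc = np.asarray(ptc, float)
    hh_ptc = np.asarray(hh_ptc, float)
    distances = np.asarray(distances, float)
    bins = np.floor(distances / bin_width).astype(int)
    xs, fr = [], []
    for b in np.unique(bins):
        mask = bins == b
        pool = ptc[mask] + hh_ptc[mask]
        if np.all(pool <= 0):
            warnings.warn(f"dropping bin at {distances[mask].mean():.1f} um: "
                          "all-zero Ptc pool")
            continue
        ok = pool > 0
        xs.append(distances[mask].mean())
        fr.append(float(np.mean(hh_ptc[mask][ok] / pool[ok])))
    return np.array(xs), np.array(fr)


def welch_one_tailed_t(group_a, group_b, direction: str = "b_greater"):
    """Welch's unequal-variance t-test, one-tailed.

    ``direction`` is the alternative hypothesis: "b_greater" tests
    mean(B) > mean(A); "a_greater" the reverse.  Returns (t, df, p)
    where t is the statistic for (mean_b - mean_a).  If both groups
    have zero variance and equal means, p = 0.5 by convention.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ProfileError("each group needs >= 2 observations")
    if direction not in ("b_greater", "a_greater"):
        raise ProfileError(f"unknown direction {direction!r}")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        df = len(a) + len(b) - 2.0
        if a.mean() == b.mean():
            warnings.warn("zero variance in both groups with equal means; "
                          "p = 0.5 by convention")
            return 0.0, df, 0.5
        t = np.inf if b.mean() > a.mean() else -np.inf
    else:
        se2 = va / len(a) + vb / len(b)
        t = (b.mean() - a.mean()) / np.sqrt(se2)
        df = se2**2 / (va**2 / (len(a)**2 * (len(a) - 1))
                       + vb**2 / (len(b)**2 * (len(b) - 1)))
    t_dir = t if direction == "b_greater" else -t
    p = float(stats.t.sf(t_dir, df))
    return float(t), float(df), p


def profiles_to_csv(profiles, path) -> None:
    rows = []
    for p in profiles:
        for i, d in enumerate(p.distances):
            rows.append({
                "replicate_id": p.replicate_id, "time_min": p.time_min,
                "distance_um": d,
                **{sp: p.levels[sp][i] for sp in p.levels},
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def profiles_from_csv(path) -> list:
    df = pd.read_csv(path)
    species = [c for c in df.columns
               if c not in ("replicate_id", "time_min", "distance_um")]
    out = []
    for (rid, t), grp in df.groupby(["replicate_id", "time_min"], sort=False):
        grp = grp.sort_values("distance_um")
        out.append(SpatialProfile(
            grp["distance_um"].to_numpy(),
            {sp: grp[sp].to_numpy() for sp in species},
            replicate_id=str(rid), time_min=float(t)))
    return out
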