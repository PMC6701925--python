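"""Statistics for locus tracks: velocity profiles, OU fits, partitioning.

The central quantitative tool is the fit of step-wise velocity statistics to
diffusion in a harmonic potential U = f x^2 / 2 (an Ornstein-Uhlenbeck
process).  For a particle with apparent diffusion constant D_a and
relaxation time tau = kT/(f*D_a), the step-wise velocity
v = (x(t+dt) - x(t))/dt satisfies

    E[v | x0]  = x0 * (exp(-dt/tau) - 1) / dt          (linear in position)
    Var[v]     = D_a * tau * (1 - exp(-2 dt/tau)) / dt^2   (flat in position)

so the slope of the binned mean velocity and the pooled central variance
identify the drift rate d_a = 1/tau and D_a.  The restoring force at
distance x from the home position is F = kT (d_a/D_a) x.

Also provided: partitioning accuracy and path-crossing counts for sister
*ori* pairs, growth-corrected segregation velocity, separation-distance
CDFs, a resampling null for colocalisation (independent-positions
hypothesis) and a robust median-absolute-deviation correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np
from scipy.stats import median_abs_deviation

from .params import KT_30C, InvalidParameterError


@dataclass
class Track:
    """A single locus track: uniformly sampled positions along the cell axis."""

    times: np.ndarray      # s, uniform spacing
    positions: np.ndarray  # um from the left pole
    cell_lengths: np.ndarray  # um

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.cell_lengths = np.asarray(self.cell_lengths, dtype=float)
        if len(self.times) != len(self.positions):
            raise InvalidParameterError("times and positions must align")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0]):
                raise InvalidParameterError("time spacing must be uniform")

    @property
    def delta_t(self) -> float:
        return float(self.times[1] - self.times[0])

    def rel_midcell(self) -> np.ndarray:
        return self.positions - self.cell_lengths / 2.0


@dataclass
class VelocityProfile:
    """Binned step-wise velocity statistics vs position relative to a reference."""

    bin_centres: np.ndarray  # um
    mean_v: np.ndarray       # um/s
    var_v: np.ndarray        # um^2/s^2
    se_mean: np.ndarray
    se_var: np.ndarray
    counts: np.ndarray
    delta_t: float


@dataclass
class OUFit:
    """Apparent OU parameters from a velocity profile.

    ``d_a`` is the drift (relaxation) rate 1/tau in s^-1, ``D_a`` the
    apparent diffusion constant in um^2/s, ``f_over_kT = d_a/D_a`` the
    spring constant over kT in um^-2.  ``valid`` is False when the fitted
    slope is non-negative (no restoring force).
    """

    D_a: float
    d_a: float
    tau: float
    f_over_kT: float
    D_a_ci: tuple
    d_a_ci: tuple
    slope: float
    slope_se: float
    intercept: float
    kT: float = KT_30C
    valid: bool = True


def stepwise_velocity_profile(tracks: Iterable[Track],
                              reference="midcell",
                              bin_width: float = 0.1,
                              min_count: int = 20) -> VelocityProfile:
    """Bin step-wise velocities by position relative to a reference.

    ``reference`` is either "midcell" or a sequence of reference tracks
    (e.g. MukBEF focus positions) aligned in time with ``tracks``.  Bins
    with fewer than ``min_count`` steps are dropped (with a warning when
    that removes populated bins).
    """
    tracks = list(tracks)
    if reference == "midcell":
        refs = [t.cell_lengths / 2.0 for t in tracks]
    else:
        refs = [np.asarray(r.positions if isinstance(r, Track) else r,
                           dtype=float) for r in reference]
        if len(refs) != len(tracks):
            raise InvalidParameterError("one reference track per ori track")
    xs, vs = [], []
    dt = None
    for tr, ref in zip(tracks, refs):
        if len(tr.positions) < 2:
            raise InvalidParameterError("tracks need at least 2 points")
        dt = tr.delta_t if dt is None else dt
        v = np.diff(tr.positions) / tr.delta_t
        xs.append(tr.positions[:-1] - ref[:-1])
        vs.append(v)
    x = np.concatenate(xs)
    v = np.concatenate(vs)
    edges = np.arange(math.floor(x.min() / bin_width) * bin_width,
                      x.max() + bin_width + 1e-12, bin_width)
    idx = np.digitize(x, edges) - 1
    centres, mean_v, var_v, se_m, se_v, counts = [], [], [], [], [], []
    dropped = 0
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n < max(min_count, 2):
            dropped += n > 0
            continue
        vb = v[sel]
        m = vb.mean()
        var = vb.var(ddof=1)
        centres.append(edges[b] + bin_width / 2.0)
        mean_v.append(m)
        var_v.append(var)
        se_m.append(math.sqrt(var / n))
        se_v.append(var * math.sqrt(2.0 / (n - 1)))
        counts.append(n)
    if dropped:
        warnings.warn(f"{dropped} under-populated velocity bins dropped")
    if not centres:
        raise InvalidParameterError("no bin reached the minimum step count")
    return VelocityProfile(np.array(centres), np.array(mean_v),
                           np.array(var_v), np.array(se_m), np.array(se_v),
                           np.array(counts, dtype=int), float(dt))


def fit_ou(profile: VelocityProfile, delta_t: Optional[float] = None,
           central: float = 0.3, kT: float = KT_30C) -> OUFit:
    """Fit OU parameters to the central region of a velocity profile.

    A weighted linear fit (weights 1/se_mean^2) of mean velocity vs position
    over |x| <= ``central`` um gives the slope s; the drift rate solves the
    full relation s = (exp(-dt*d_a) - 1)/dt.  D_a comes from the pooled
    central variance via Var[v] = D_a*tau*(1 - exp(-2dt/tau))/dt^2.  95%
    confidence intervals are propagated from the fit covariance and the
    chi-square spread of the pooled variance.
    """
    dt = profile.delta_t if delta_t is None else float(delta_t)
    sel = np.abs(profile.bin_centres) <= central + 1e-12
    if sel.sum() < 3:
        raise InvalidParameterError("need >= 3 central bins for the OU fit")
    x = profile.bin_centres[sel]
    y = profile.mean_v[sel]
    wgt = 1.0 / profile.se_mean[sel] ** 2
    # weighted least squares, 2 parameters
    W = np.diag(wgt)
    A = np.vstack([x, np.ones_like(x)]).T
    cov = np.linalg.inv(A.T @ W @ A)
    slope, intercept = cov @ (A.T @ W @ y)
    slope_se = math.sqrt(cov[0, 0])

    def d_of_slope(s):
        arg = 1.0 + s * dt
        return -math.log(arg) / dt if arg > 0 else math.nan

    d_a = d_of_slope(slope)
    valid = slope < 0 and not math.isnan(d_a) and d_a > 0
    d_lo = d_of_slope(slope + 1.96 * slope_se)
    d_hi = d_of_slope(slope - 1.96 * slope_se)

    dof = int((profile.counts[sel] - 1).sum())
    pooled_var = float(np.sum((profile.counts[sel] - 1) * profile.var_v[sel])
                       / dof)
    var_se = pooled_var * math.sqrt(2.0 / dof)

    def D_of(var, d):
        if not (d and d > 0) or math.isnan(d):
            # Brownian limit: Var[v] -> 2 D / dt
            return var * dt / 2.0
        tau = 1.0 / d
        return var * dt ** 2 / (tau * (1.0 - math.exp(-2.0 * dt / tau)))

    D_a = D_of(pooled_var, d_a if valid else math.nan)
    D_lo = D_of(pooled_var - 1.96 * var_se, d_a if valid else math.nan)
    D_hi = D_of(pooled_var + 1.96 * var_se, d_a if valid else math.nan)
    tau = 1.0 / d_a if valid else math.inf
    f_over_kT = d_a / D_a if valid else 0.0
    return OUFit(D_a=D_a, d_a=d_a if valid else float("nan"), tau=tau,
                 f_over_kT=f_over_kT, D_a_ci=(D_lo, D_hi),
                 d_a_ci=(d_lo, d_hi), slope=float(slope),
                 slope_se=slope_se, intercept=float(intercept), kT=kT,
                 valid=bool(valid))


def restoring_force(fit: OUFit, x: float) -> float:
    """Spring force F = kT*(d_a/D_a)*x at distance x (um) from home, in pN.

    kT in joules and x in micrometres give F in J/um = 1e6 N; the 1e18
    factor converts to piconewtons (0.2 um at f/kT = 23.9 um^-2 and
    kT = 4.19e-21 J gives 0.02 pN).
    """
    if not fit.valid:
        raise InvalidParameterError("cannot evaluate force for an invalid fit")
    return fit.kT * fit.f_over_kT * x * 1e18 * 1e-6 * 1e-6 * 1e12


def detect_foci(v_counts: np.ndarray, n_expected: int = 1, h: float = 0.1,
                window: float = 0.3, min_separation: float = 1.0,
                smooth: int = 3) -> Tuple[np.ndarray, int]:
    """Positions (um) of 1 or 2 high-density foci in a v-count profile.

    For one focus: centroid of v within ``window`` um of the global maximum.
    For two: the profile is smoothed with a ``smooth``-compartment moving
    average, the two largest maxima separated by at least
    ``min_separation`` um define a split at the intervening minimum, and a
    centroid is computed on each side.  Returns (positions, n_found);
    n_found < n_expected flags that fewer peaks were resolvable.
    """
    v = np.asarray(v_counts, dtype=float)
    if v.sum() <= 0:
        raise InvalidParameterError("empty count profile")
    x = (np.arange(len(v)) + 0.5) * h

    def centroid(lo, hi):
        seg = slice(lo, hi)
        return float((x[seg] * v[seg]).sum() / v[seg].sum())

    if n_expected == 1:
        m = int(np.argmax(v))
        k = int(round(window / h))
        return np.array([centroid(max(0, m - k), min(len(v), m + k + 1))]), 1
    if n_expected != 2:
        raise InvalidParameterError("n_expected must be 1 or 2")
    kernel = np.ones(smooth) / smooth
    vs = np.convolve(v, kernel, mode="same")
    sep = int(round(min_separation / h))
    m1 = int(np.argmax(vs))
    mask = np.abs(np.arange(len(vs)) - m1) >= sep
    if not mask.any() or vs[mask].max() <= 0:
        pos, _ = detect_foci(v, 1, h, window)
        return pos, 1
    cand = np.where(mask)[0]
    m2 = int(cand[np.argmax(vs[cand])])
    if vs[m2] < 0.1 * vs[m1]:
        # no second maximum of comparable weight: report the single focus
        pos, _ = detect_foci(v, 1, h, window)
        return pos, 1
    lo, hi = sorted((m1, m2))
    cut = lo + int(np.argmin(vs[lo:hi + 1]))
    if v[:cut + 1].sum() <= 0 or v[cut + 1:].sum() <= 0:
        pos, _ = detect_foci(v, 1, h, window)
        return pos, 1
    return np.array(sorted((centroid(0, cut + 1),
                            centroid(cut + 1, len(v))))), 2


def partitioning_accuracy(x1: np.ndarray, x2: np.ndarray,
                          L: np.ndarray) -> float:
    """Fraction of runs with the two oris in opposite cell halves.

    ``x1``, ``x2`` and ``L`` hold, per run, the two ori positions and the
    cell length at the evaluation time.  Runs with an ori exactly at
    mid-cell are excluded with a warning.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    L = np.broadcast_to(np.asarray(L, dtype=float), x1.shape)
    s1 = np.sign(x1 - L / 2.0)
    s2 = np.sign(x2 - L / 2.0)
    ok = (s1 != 0) & (s2 != 0)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} runs with an ori exactly at "
                      "mid-cell excluded")
    if not ok.any():
        raise InvalidParameterError("no scorable runs")
    return float((s1[ok] != s2[ok]).mean())


def crossing_count(x1: np.ndarray, x2: np.ndarray) -> int:
    """Number of times two aligned tracks cross (sign changes of x1 - x2).

    Readouts where the separation is exactly zero are attributed to the
    following step: the sign at a zero is taken from the next non-zero
    separation, so a touch without exchange does not count as a crossing.
    """
    d = np.asarray(x1, dtype=float) - np.asarray(x2, dtype=float)
    s = np.sign(d)
    if not (s != 0).any():
        return 0
    # zeros take the sign of the following step; trailing zeros the preceding
    for i in range(len(s) - 2, -1, -1):
        if s[i] == 0:
            s[i] = s[i + 1]
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    return int((np.diff(s) != 0).sum())


def segregation_velocity(x1: np.ndarray, x2: np.ndarray, delta_t: float,
                         T_double_s: Optional[float] = None) -> np.ndarray:
    """Step-wise rate of change of the sister separation, growth-corrected.

    Raw rate (|d|(t+dt) - |d|(t))/dt minus the exponential dilation term
    |d|(t) * ln2 / T_double (zero for a non-growing cell), per step, in
    um/s.
    """
    d = np.abs(np.asarray(x1, dtype=float) - np.asarray(x2, dtype=float))
    raw = np.diff(d) / delta_t
    if T_double_s:
        raw = raw - d[:-1] * math.log(2.0) / T_double_s
    return raw


def aggregate_rates(rate_arrays: List[np.ndarray]) -> dict:
    """Mean and 95% CI of per-step rates across runs, by step index."""
    n_steps = max(len(r) for r in rate_arrays)
    mean, lo, hi, n = (np.full(n_steps, np.nan) for _ in range(4))
    for i in range(n_steps):
        vals = np.array([r[i] for r in rate_arrays if len(r) > i])
        n[i] = len(vals)
        mean[i] = vals.mean()
        if len(vals) > 1:
            se = vals.std(ddof=1) / math.sqrt(len(vals))
            lo[i], hi[i] = mean[i] - 1.96 * se, mean[i] + 1.96 * se
    return {"mean": mean, "ci_low": lo, "ci_high": hi, "n": n}


def separation_cdf(track_a: np.ndarray, track_b: np.ndarray):
    """Empirical CDF of |x_a - x_b| over all aligned readouts.

    Returns (sorted separations, cumulative probabilities); evaluate the
    CDF at d as ``np.searchsorted(sep, d, side='right') / len(sep)``.
    """
    a = np.asarray(track_a, dtype=float).ravel()
    b = np.asarray(track_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise InvalidParameterError("tracks must align")
    sep = np.sort(np.abs(a - b))
    return sep, np.arange(1, len(sep) + 1) / len(sep)


def independence_null(positions_a: np.ndarray, positions_b: np.ndarray,
                      n_resample: int = 1000, rng=None) -> dict:
    """Null distribution of separations under independent positioning.

    Pairs are resampled independently from the two marginal position
    samples; the test statistic is the difference between the observed mean
    separation and the null mean.  The one-sided resampling p-value is the
    probability that an independent pairing yields a mean separation at
    most as small as observed (small p: the observed pairs are more
    colocalised than independence allows).
    """
    rng = np.random.default_rng(rng)
    a = np.asarray(positions_a, dtype=float)
    b = np.asarray(positions_b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise InvalidParameterError("need paired samples")
    n = len(a)
    observed = np.abs(a - b)
    null_all = np.abs(rng.choice(a, size=(n_resample, n), replace=True)
                      - rng.choice(b, size=(n_resample, n), replace=True))
    null_means = null_all.mean(axis=1)
    obs_mean = observed.mean()
    p = (1.0 + np.sum(null_means <= obs_mean)) / (n_resample + 1.0)
    return {
        "observed": observed,
        "null": null_all.ravel(),
        "observed_mean": float(obs_mean),
        "null_mean": float(null_means.mean()),
        "statistic": float(obs_mean - null_means.mean()),
        "p_value": float(p),
    }


def mad_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Robust correlation from median absolute deviations.

    Standardise u = (x - med x)/MAD(x), v likewise, then
    r = (MAD(u+v)^2 - MAD(u-v)^2) / (MAD(u+v)^2 + MAD(u-v)^2), in [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidParameterError("need >= 3 paired observations")
    mx = median_abs_deviation(x)
    my = median_abs_deviation(y)
    if mx == 0 or my == 0:
        raise InvalidParameterError("zero MAD: correlation undefined")
    u = (x - np.median(x)) / mx
    v = (y - np.median(y)) / my
    sp = median_abs_deviation(u + v) ** 2
    sm = median_abs_deviation(u - v) ** 2
    if sp + sm == 0:
        raise InvalidParameterError("degenerate standardised samples")
    return float((sp - sm) / (sp + sm))
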