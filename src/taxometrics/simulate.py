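"""Synthetic taxonic and dimensional samples with realistic structure.

The generator emulates the statistical shape of a clinical-versus-community
mixed sample: a small taxon (base rate around 0.10) mixed with a large
complement, a handful of right-skewed symptom-scale indicators separating
the groups by Cohen's d between roughly 1.25 and 3.7, modest within-group
("nuisance") equicorrelation, and one sign-flipped indicator (a BMI
z-score on which the clinical group is *low*).

Taxonic samples draw, per group, a latent equicorrelated Gaussian, pass
each margin through a monotone exponential (log-normal-type) transform to
hit the target skewness, shift the taxon by d pooled-SD units, rescale to
the target full-sample mean/SD and clip to the indicator's value range.
Dimensional samples come from a single one-factor population whose
full-sample correlation matrix is matched (by the same iterated
generate-measure-correct loop used for comparison data) to the mixture-
implied correlations of the paired taxonic scenario.

Two scenario presets reproduce the study conditions used throughout the
tests: ``anbp_scenario()`` (N=945, P=0.101, 4 indicators) and
``bn_scenario()`` (N=960, P=0.114, 5 indicators).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .io import IndicatorMatrix, SampleSizeWarning

__all__ = [
    "IndicatorSpec",
    "ScenarioSpec",
    "LabeledSample",
    "make_taxonic",
    "make_dimensional",
    "mixture_implied_correlation",
    "anbp_scenario",
    "bn_scenario",
]

_MAX_ABS_SKEW = 15.0


@dataclass(frozen=True)
class IndicatorSpec:
    """Calibration targets for one indicator."""

    name: str
    d: float  # signed taxon-complement separation, pooled-SD units
    skew: float  # target full-sample skewness (sign follows d's orientation)
    mean: float  # target full-sample mean
    sd: float  # target full-sample SD
    value_range: tuple[float, float] | None = None  # clip bounds, raw units


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete recipe for one synthetic mixed sample."""

    name: str
    n_total: int
    base_rate: float
    indicators: tuple[IndicatorSpec, ...]
    r_within: float  # within-group equicorrelation
    structure: str = "taxonic"  # "taxonic" | "dimensional"

    def __post_init__(self) -> None:
        if self.structure not in ("taxonic", "dimensional"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if not 0.0 < self.base_rate < 1.0:
            raise ValueError("base_rate must lie in (0, 1)")
        if self.base_rate * self.n_total < 20:
            raise ValueError("expected taxon size below 20 cases")
        if not abs(self.r_within) < 1.0:
            raise ValueError("|r_within| must be below 1")
        if len(self.indicators) < 2:
            raise ValueError("need at least 2 indicators")

    @property
    def k(self) -> int:
        return len(self.indicators)

    @property
    def n_taxon(self) -> int:
        return int(round(self.base_rate * self.n_total))

    def as_dimensional(self) -> "ScenarioSpec":
        return replace(self, structure="dimensional")


@dataclass
class LabeledSample:
    """Generated matrix with true group labels plus its generating spec."""

    matrix: IndicatorMatrix
    spec: ScenarioSpec
    seed: int


# --------------------------------------------------------------------------
# skew transform
# --------------------------------------------------------------------------

def _lognormal_sigma(target_skew: float) -> float:
    """Sigma of a log-normal with the requested (absolute) skewness."""
    g = abs(target_skew)
    if g < 0.05:
        return 0.0
    if g > _MAX_ABS_SKEW:
        raise ValueError(f"target skew {target_skew} infeasible (|skew| > {_MAX_ABS_SKEW})")

    def f(s):
        w = np.exp(s**2)
        return (w + 2.0) * np.sqrt(w - 1.0) - g

    return float(optimize.brentq(f, 1e-6, 2.5))


def _skew_transform(z: np.ndarray, sigma: float) -> np.ndarray:
    """Monotone map of a standard-normal margin to unit scale with skew.

    For ``sigma > 0`` this is the standardized log-normal ``exp(sigma z)``;
    for ``sigma == 0`` the identity.  Being monotone, it preserves case
    order and hence all rank-based curve behavior.
    """
    if sigma == 0.0:
        return z
    w = np.exp(sigma**2)
    m = np.exp(sigma**2 / 2.0)
    s = np.sqrt((w - 1.0) * w)
    return (np.exp(sigma * z) - m) / s


def _signed_margin(z: np.ndarray, sigma: float, eps: float) -> np.ndarray:
    """Monotone-increasing margin with skewness of sign ``eps``."""
    return eps * _skew_transform(eps * z, sigma)


def _margin_corr_attenuation(sigma: float) -> float:
    """corr(z, T(z)) for the standardized log-normal transform."""
    if sigma == 0.0:
        return 1.0
    w = np.exp(sigma**2)
    return sigma * np.exp(sigma**2 / 2.0) / np.sqrt((w - 1.0) * w)


def _latent_pair_corr(r: float, si: float, ei: float, sj: float, ej: float) -> float:
    """Latent normal correlation that realizes Pearson ``r`` post-transform.

    Uses the closed form for correlated standardized log-normals
    ``r = (exp(s_i s_j rho) - 1) / sqrt((exp(s_i^2)-1)(exp(s_j^2)-1))``
    (with margin mirror signs carried by ``e_i e_j``); when one margin is
    untransformed the linear attenuation factor applies instead.
    """
    if si == 0.0 and sj == 0.0:
        return r
    if si == 0.0 or sj == 0.0:
        rho = r / (_margin_corr_attenuation(si) * _margin_corr_attenuation(sj))
    else:
        s = np.sqrt((np.exp(si**2) - 1.0) * (np.exp(sj**2) - 1.0))
        e = ei * ej
        arg = 1.0 + e * r * s
        if arg <= 0:
            return -0.999 if e * r < 0 else 0.999
        rho = e * np.log(arg) / (si * sj)
    return float(np.clip(rho, -0.999, 0.999))


def _latent_correlated_normal(
    n: int,
    r_target: float,
    params: list[tuple[float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent Gaussian whose transformed margins equicorrelate at ``r_target``."""
    if r_target < 0:
        raise ValueError("negative within-group equicorrelation not supported")
    k = len(params)
    r_lat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            si, ei = params[i]
            sj, ej = params[j]
            r_lat[i, j] = r_lat[j, i] = _latent_pair_corr(r_target, si, ei, sj, ej)
    chol = np.linalg.cholesky(_nearest_pd(r_lat))
    return rng.standard_normal((n, k)) @ chol.T


def _pooled_sd_d(taxon: np.ndarray, complement: np.ndarray) -> float:
    nt, nc = len(taxon), len(complement)
    sp2 = ((nt - 1) * taxon.var(ddof=1) + (nc - 1) * complement.var(ddof=1)) / (
        nt + nc - 2
    )
    return float((taxon.mean() - complement.mean()) / np.sqrt(sp2))


def _calibrated_mixture_margin(
    m_c: np.ndarray, m_t: np.ndarray, ind: IndicatorSpec, p: float, q: float
) -> np.ndarray:
    """Place both group margins on the raw scale with the target Cohen's d.

    The taxon shift is solved on the *final clipped scale* by a short
    secant iteration, so range clipping (which shrinks group SDs) cannot
    bias the realized pooled-SD effect size away from the target.
    """
    mix_sd = float(np.sqrt(1.0 + q * ind.d**2))
    mix_mean = p * abs(ind.d)

    def realize(shift: float) -> tuple[np.ndarray, np.ndarray]:
        c = _finalize_margin(m_c, ind, mix_mean, mix_sd, flipped=ind.d < 0)
        t = _finalize_margin(m_t + shift, ind, mix_mean, mix_sd, flipped=ind.d < 0)
        return c, t

    if ind.d == 0:
        c, t = realize(0.0)
        return np.concatenate([c, t])
    shift = abs(ind.d)
    for _ in range(4):
        c, t = realize(shift)
        d_real = _pooled_sd_d(t, c)
        err = d_real - ind.d
        if abs(err) < 1e-3:
            break
        # d is near-linear in the unit-space shift with slope ~ +-1/SD
        shift = max(0.0, shift - err * np.sign(ind.d))
    c, t = realize(shift)
    return np.concatenate([c, t])


def _mixture_margin_skew(skew_full: float, d: float, p: float) -> float:
    """Within-group margin skewness that yields the full-sample target.

    For a two-group mixture of a common unit-SD margin shifted by ``d``,
    the third central moment is ``g + d^3 q (1 - 2P)`` and the variance
    ``1 + q d^2`` with ``q = P(1-P)``, so the group margin's skewness must
    be ``g = skew_full (1 + q d^2)^{3/2} - d^3 q (1 - 2P)``.
    """
    q = p * (1.0 - p)
    return skew_full * (1.0 + q * d**2) ** 1.5 - d**3 * q * (1.0 - 2.0 * p)


def _finalize_margin(
    values: np.ndarray,
    ind: IndicatorSpec,
    mix_mean: float = 0.0,
    mix_sd: float = 1.0,
    flipped: bool = False,
) -> np.ndarray:
    """Map a unit-scale margin onto the indicator's raw scale and clip.

    The margin is placed at the target mean with scale ``sd / mix_sd``
    (reflected for sign-flipped indicators) and clipped to the stated
    value range.  Clipping a skewed symptom-scale margin at a zero floor
    produces the pile of minimum scores real questionnaire data show.
    """
    scale = ind.sd / mix_sd
    sgn = -1.0 if flipped else 1.0
    v = ind.mean + sgn * (values - mix_mean) * scale
    if ind.value_range is not None:
        v = np.clip(v, *ind.value_range)
    return v


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def make_taxonic(spec: ScenarioSpec, seed: int) -> LabeledSample:
    """Generate a two-group mixture per the scenario's calibration targets.

    The taxon block has exactly ``round(P * N)`` cases.  Within each group
    the latent Gaussian is equicorrelated at ``r_within``; margins are
    skew-transformed (sign-flipped indicators are generated with |d|,
    |skew| and negated, so their skew flips with their d); the taxon is
    shifted by |d| within-group SD units before the full-sample rescale.
    """
    if spec.structure != "taxonic":
        raise ValueError("spec.structure must be 'taxonic'")
    rng = np.random.default_rng(seed)
    n_t = spec.n_taxon
    n_c = spec.n_total - n_t
    # per-indicator margin parameters, in the space where the taxon is high:
    # the group margin skew is backed out of the full-sample target, and the
    # latent correlations are inflated to undo the transform's attenuation
    params = []
    for ind in spec.indicators:
        skew_eff = ind.skew if ind.d >= 0 else -ind.skew
        g = _mixture_margin_skew(skew_eff, abs(ind.d), spec.base_rate)
        sigma = _lognormal_sigma(g)
        params.append((sigma, 1.0 if g >= 0 else -1.0))
    z_c = _latent_correlated_normal(n_c, spec.r_within, params, rng)
    z_t = _latent_correlated_normal(n_t, spec.r_within, params, rng)
    q = spec.base_rate * (1.0 - spec.base_rate)
    p = spec.base_rate
    cols = []
    for j, ind in enumerate(spec.indicators):
        sigma, eps = params[j]
        m_c = _signed_margin(z_c[:, j], sigma, eps)
        m_t = _signed_margin(z_t[:, j], sigma, eps)
        cols.append(_calibrated_mixture_margin(m_c, m_t, ind, p, q))
    scores = np.column_stack(cols)
    group = np.array(
        ["complement_putative"] * n_c + ["taxon_putative"] * n_t, dtype=object
    )
    perm = rng.permutation(spec.n_total)
    matrix = IndicatorMatrix(
        scores[perm],
        [ind.name for ind in spec.indicators],
        group=group[perm],
    )
    return LabeledSample(matrix, spec, seed)


def mixture_implied_correlation(spec: ScenarioSpec) -> np.ndarray:
    """Full-sample correlation matrix implied by the taxonic mixture.

    With unit within-group SDs, equicorrelation ``r_w`` and group mean
    separations ``d_i``:  ``cov_ij = r_w' + P(1-P) d_i d_j`` (off-diagonal,
    with the sign of each flipped indicator carried by ``d_i``) and
    ``var_i = 1 + P(1-P) d_i^2``, where ``r_w'`` carries the sign product
    of the flips.
    """
    q = spec.base_rate * (1.0 - spec.base_rate)
    d = np.array([ind.d for ind in spec.indicators])
    sign = np.sign(np.where(d == 0, 1.0, d))
    cov = spec.r_within * np.outer(sign, sign) + q * np.outer(d, d)
    var = 1.0 + q * d**2
    np.fill_diagonal(cov, var)
    s = np.sqrt(var)
    return cov / np.outer(s, s)


def _nearest_pd(r: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(r)
    if vals.min() > 1e-8:
        return r
    vals = np.clip(vals, 1e-6, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    s = np.sqrt(np.diag(fixed))
    return fixed / np.outer(s, s)


def make_dimensional(spec: ScenarioSpec, seed: int) -> LabeledSample:
    """Generate a single-population sample matched to the paired taxonic spec.

    Margins reuse the taxonic scenario's skew transforms and mean/SD/range
    targets.  The latent correlation starts from a one-factor fit to the
    mixture-implied full-sample correlation matrix and is then corrected by
    an iterated generate-measure-adjust loop until the realized correlation
    matrix matches the target (RMSR well below 0.05).
    """
    dim_spec = spec.as_dimensional() if spec.structure == "taxonic" else spec
    rng = np.random.default_rng(seed)
    target = mixture_implied_correlation(dim_spec)
    k = dim_spec.k
    sigmas = [_lognormal_sigma(ind.skew) for ind in dim_spec.indicators]
    eps = [1.0 if ind.skew >= 0 else -1.0 for ind in dim_spec.indicators]
    signs = [1.0 if ind.d >= 0 else -1.0 for ind in dim_spec.indicators]

    # one-factor start: |loadings| from an iterated rank-1 fit on |target|
    lam = np.sqrt(np.clip(np.diag(np.abs(target)) * 0 + np.abs(target).mean(), 0, 1))
    a = np.abs(target).copy()
    for _ in range(50):
        np.fill_diagonal(a, np.clip(lam**2, 0, 1))
        vals, vecs = np.linalg.eigh(a)
        lam = np.abs(vecs[:, -1]) * np.sqrt(max(vals[-1], 0.0))
        lam = np.clip(lam, 0.0, 0.999)
    sgn = np.asarray(signs)
    r_lat = np.outer(sgn * lam, sgn * lam)
    np.fill_diagonal(r_lat, 1.0)

    def realize(r):
        chol = np.linalg.cholesky(_nearest_pd(r))
        z = rng.standard_normal((dim_spec.n_total, k)) @ chol.T
        cols = [
            _signed_margin(z[:, j], sig, e)
            for j, (sig, e) in enumerate(zip(sigmas, eps))
        ]
        return np.column_stack(cols)

    best = None
    best_rmsr = np.inf
    r_int = r_lat.copy()
    for _ in range(8):
        v = realize(r_int)
        r_real = np.corrcoef(v, rowvar=False)
        resid = (r_real - target)[np.triu_indices(k, 1)]
        rmsr = float(np.sqrt(np.mean(resid**2)))
        if rmsr < best_rmsr:
            best, best_rmsr = v, rmsr
        r_int = r_int + (target - r_real)
        np.fill_diagonal(r_int, 1.0)
    cols = [
        _finalize_margin(best[:, j], ind)
        for j, ind in enumerate(dim_spec.indicators)
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SampleSizeWarning)
        matrix = IndicatorMatrix(
            np.column_stack(cols), [ind.name for ind in dim_spec.indicators]
        )
    return LabeledSample(matrix, dim_spec, seed)


# --------------------------------------------------------------------------
# scenario presets
# --------------------------------------------------------------------------

def anbp_scenario(structure: str = "taxonic") -> ScenarioSpec:
    """Binge-eating/purging anorexia vs community mixed sample.

    N=945 with taxon base rate 0.101 (95 clinical cases); four indicators
    (EDI-2 bulimia, ineffectiveness and interoceptive-awareness subscales,
    plus BMI z-score, on which the clinical group is low) with separations
    d = 2.51, 1.57, 1.56, -2.07 and within-group equicorrelation 0.275.
    """
    return ScenarioSpec(
        name="anbp",
        n_total=945,
        base_rate=0.101,
        indicators=(
            IndicatorSpec("bulimia", 2.51, 3.19, 1.66, 3.78, (0.0, 21.0)),
            IndicatorSpec("ineffectiveness", 1.57, 1.66, 4.70, 5.15, (0.0, 30.0)),
            IndicatorSpec("interoceptive_awareness", 1.56, 2.63, 3.74, 4.77, (0.0, 30.0)),
            IndicatorSpec("bmi_z", -2.07, -0.46, -0.33, 1.11, None),
        ),
        r_within=0.275,
        structure=structure,
    )


def bn_scenario(structure: str = "taxonic") -> ScenarioSpec:
    """Bulimia nervosa vs community mixed sample.

    N=960 with taxon base rate 0.114 (109 clinical cases); five EDI-2
    subscale indicators with separations d = 1.63, 3.68, 1.25, 1.67, 1.82
    and within-group equicorrelation 0.27.
    """
    return ScenarioSpec(
        name="bn",
        n_total=960,
        base_rate=0.114,
        indicators=(
            IndicatorSpec("drive_for_thinness", 1.63, 1.09, 5.08, 5.19, (0.0, 21.0)),
            IndicatorSpec("bulimia", 3.68, 2.64, 2.06, 4.29, (0.0, 21.0)),
            IndicatorSpec("body_dissatisfaction", 1.25, 0.75, 7.94, 5.45, (0.0, 27.0)),
            IndicatorSpec("ineffectiveness", 1.67, 1.53, 4.82, 5.14, (0.0, 30.0)),
            IndicatorSpec("interoceptive_awareness", 1.82, 1.87, 3.93, 4.81, (0.0, 30.0)),
        ),
        r_within=0.27,
        structure=structure,
    )
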