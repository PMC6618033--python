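"""The three taxometric curve procedures and base-rate estimation.

MAMBAC (mean above minus below a cut): cases are sorted on an input
indicator; at each of a series of cut ranks the difference between the
output indicator's mean above and below the cut is plotted.  A latent
two-class mixture produces a peaked curve; a latent dimension produces a
flat or dish ("U") shaped curve.

MAXEIG: overlapping windows slide along the sorted input indicator; within
each window the covariance matrix of the remaining indicators is computed,
its diagonal zeroed, and the largest eigenvalue extracted.  Mixed windows
(containing both latent classes) show inflated covariance, so taxonic data
peak where the classes mix and dimensional data stay comparatively flat.

L-Mode: a single latent factor is fitted to the full-sample correlation
matrix, cases are scored by Bartlett's weighted least-squares method, and
the kernel density of the factor scores is inspected: bimodal for a
two-class mixture, unimodal for a dimension.

All procedures depend on the input indicator only through case order, so
every curve is invariant under strictly increasing transforms of the input.
Ties on the input are broken by a seeded random permutation, making each
procedure a deterministic function of (data, parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import FactorAnalysis

from .io import IndicatorMatrix

__all__ = [
    "TaxometricCurve",
    "AveragedCurve",
    "LModeResult",
    "BaseRateEstimate",
    "mambac_curve",
    "mambac_averaged",
    "maxeig_curve",
    "maxeig_averaged",
    "lmode_scores",
    "estimate_base_rate",
]

LMODE_GRID_SIZE = 512


@dataclass
class TaxometricCurve:
    """One procedure curve: ordered x locations and the plotted y values."""

    procedure: str  # "MAMBAC" | "MAXEIG" | "LMODE"
    x: np.ndarray
    y: np.ndarray
    input_indicator: str | None = None
    output_indicators: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if np.any(np.diff(self.x) < -1e-9):
            raise ValueError("x locations must be ordered")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("curve values must be finite")
        if self.procedure == "LMODE":
            if np.any(self.y < 0):
                raise ValueError("density curve must be nonnegative")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class AveragedCurve:
    """Mean of member curves on a common grid (cut/window index position)."""

    procedure: str
    x: np.ndarray
    mean_y: np.ndarray
    member_curves: list[TaxometricCurve]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.mean_y = np.asarray(self.mean_y, dtype=float)
        if self.x.shape != self.mean_y.shape:
            raise ValueError("x and mean_y must have equal length")

    def as_curve(self) -> TaxometricCurve:
        return TaxometricCurve(self.procedure, self.x, self.mean_y)


def _sort_order(input_values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ascending order of the input with seeded random tie-breaking."""
    n = len(input_values)
    return np.lexsort((rng.permutation(n), input_values))


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng([int(seed), i]) for i in range(n)]


# --------------------------------------------------------------------------
# MAMBAC
# --------------------------------------------------------------------------

def mambac_curve(
    matrix: IndicatorMatrix,
    input_idx: int,
    output_idx: int,
    n_cuts: int = 50,
    trim: int = 25,
    seed: int = 0,
) -> TaxometricCurve:
    """Mean-above-minus-below curve for one (input, output) indicator pair.

    Cases are sorted on the input (ties broken by a seeded permutation);
    cut ranks are ``n_cuts`` integer positions evenly spaced (rounded) from
    ``trim + 1`` to ``N - trim``; at cut ``c`` the curve value is
    ``mean(output | rank > c) - mean(output | rank <= c)``.  Duplicate
    rounded positions (tiny N) are collapsed.
    """
    n = matrix.n_cases
    if n < 2 * trim + 2:
        raise ValueError(f"N={n} too small for trim={trim} (need N >= {2 * trim + 2})")
    if input_idx == output_idx:
        raise ValueError("input and output indicators must differ")
    rng = np.random.default_rng(seed)
    order = _sort_order(matrix.scores[:, input_idx], rng)
    out = matrix.scores[order, output_idx]
    cuts = np.unique(np.round(np.linspace(trim + 1, n - trim, n_cuts)).astype(int))
    csum = np.cumsum(out)
    total = csum[-1]
    below = csum[cuts - 1] / cuts
    above = (total - csum[cuts - 1]) / (n - cuts)
    return TaxometricCurve(
        "MAMBAC",
        cuts.astype(float),
        above - below,
        input_indicator=matrix.indicator_names[input_idx],
        output_indicators=[matrix.indicator_names[output_idx]],
    )


def mambac_averaged(
    matrix: IndicatorMatrix,
    n_cuts: int = 50,
    trim: int = 25,
    seed: int = 0,
    standardize: bool = True,
) -> AveragedCurve:
    """MAMBAC over all ``k(k-1)`` ordered indicator pairs, averaged.

    Indicators are reflected to a common orientation and full-sample
    standardized first (so output mean differences point the same way and
    are in comparable units) unless ``standardize=False``.  Member curves
    share the cut-rank grid and are averaged pointwise.
    """
    m = matrix.oriented().standardized() if standardize else matrix
    k = m.n_indicators
    if k < 2:
        raise ValueError("MAMBAC requires at least 2 indicators")
    pairs = [(i, j) for i in range(k) for j in range(k) if i != j]
    rngs = _spawn_rngs(seed, len(pairs))
    members = []
    for (i, j), rng in zip(pairs, rngs):
        sub_seed = rng.integers(2**31)
        members.append(mambac_curve(m, i, j, n_cuts=n_cuts, trim=trim, seed=sub_seed))
    x = members[0].x
    mean_y = np.mean([c.y for c in members], axis=0)
    return AveragedCurve("MAMBAC", x, mean_y, members)


# --------------------------------------------------------------------------
# MAXEIG
# --------------------------------------------------------------------------

def maxeig_window_geometry(n: int, n_windows: int, overlap: float) -> tuple[int, int]:
    """Window width and step for overlapping windows along ``n`` sorted cases.

    ``w = floor(N / (1 + (n_windows - 1) * (1 - overlap)))`` and consecutive
    windows advance by ``floor(w * (1 - overlap))`` ranks.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    if n_windows < 2:
        raise ValueError("need at least 2 windows")
    # the 1e-9 nudge keeps floor() immune to float fuzz in (1 - overlap)
    w = int(np.floor(n / (1 + (n_windows - 1) * (1 - overlap)) + 1e-9))
    step = int(np.floor(w * (1 - overlap) + 1e-9))
    if step < 1:
        raise ValueError("window step below 1; reduce n_windows or overlap")
    return w, step


def maxeig_curve(
    matrix: IndicatorMatrix,
    input_idx: int,
    n_windows: int = 50,
    overlap: float = 0.90,
    seed: int = 0,
    n_reps: int = 5,
) -> TaxometricCurve:
    """Largest zero-diagonal covariance eigenvalue per overlapping window.

    Symptom-scale indicators pile up at their floor, so many cases tie on
    the input; which of them land in which window is decided by the random
    tie-break and adds window-composition noise.  The curve is therefore
    averaged over ``n_reps`` seeded tie-break orders (a single pass is used
    when the input has no ties).
    """
    n, k = matrix.scores.shape
    if k < 3:
        raise ValueError("MAXEIG requires at least 3 indicators (2 outputs)")
    w, step = maxeig_window_geometry(n, n_windows, overlap)
    n_out = k - 1
    if w < n_out + 2:
        # invert the geometry to suggest a feasible window count
        max_windows = int((n / (n_out + 2) - 1) / (1 - overlap)) + 1
        raise ValueError(
            f"window width {w} below minimum {n_out + 2}; "
            f"use n_windows <= {max_windows}"
        )
    inp_col = matrix.scores[:, input_idx]
    reps = n_reps if len(np.unique(inp_col)) < n else 1
    starts = np.arange(n_windows) * step
    xs = np.zeros(n_windows)
    ys = np.zeros(n_windows)
    for rep in range(reps):
        rng = np.random.default_rng([int(seed), rep])
        order = _sort_order(inp_col, rng)
        inp = inp_col[order]
        out = np.delete(matrix.scores[order], input_idx, axis=1)
        # sliding-window sums of values and cross-products via prefix sums
        cs1 = np.vstack([np.zeros((1, n_out)), np.cumsum(out, axis=0)])
        cross = out[:, :, None] * out[:, None, :]
        cs2 = np.concatenate(
            [np.zeros((1, n_out, n_out)), np.cumsum(cross, axis=0)])
        s1 = cs1[starts + w] - cs1[starts]  # (n_windows, n_out)
        s2 = cs2[starts + w] - cs2[starts]  # (n_windows, n_out, n_out)
        mean = s1 / w
        covs = (s2 - w * mean[:, :, None] * mean[:, None, :]) / (w - 1)
        idx = np.arange(n_out)
        covs[:, idx, idx] = 0.0
        ys += np.linalg.eigvalsh(covs)[:, -1]
        ci = np.concatenate([[0.0], np.cumsum(inp)])
        xs += (ci[starts + w] - ci[starts]) / w
    xs /= reps
    ys /= reps
    out_names = [nm for j, nm in enumerate(matrix.indicator_names) if j != input_idx]
    return TaxometricCurve(
        "MAXEIG", xs, ys,
        input_indicator=matrix.indicator_names[input_idx],
        output_indicators=out_names,
    )


def maxeig_averaged(
    matrix: IndicatorMatrix,
    n_windows: int = 50,
    overlap: float = 0.90,
    seed: int = 0,
    standardize: bool = True,
) -> AveragedCurve:
    """MAXEIG with each of the ``k`` indicators once as input, averaged.

    Member curves share the window-index grid; the averaged x is the mean
    window position across members (window index when inputs differ in
    scale), and y is the pointwise mean eigenvalue.
    """
    m = matrix.oriented().standardized() if standardize else matrix
    k = m.n_indicators
    rngs = _spawn_rngs(seed, k)
    members = [
        maxeig_curve(m, i, n_windows=n_windows, overlap=overlap,
                     seed=rng.integers(2**31))
        for i, rng in enumerate(rngs)
    ]
    x = np.arange(1, n_windows + 1, dtype=float)
    mean_y = np.mean([c.y for c in members], axis=0)
    return AveragedCurve("MAXEIG", x, mean_y, members)


# --------------------------------------------------------------------------
# L-Mode
# --------------------------------------------------------------------------

@dataclass
class LModeResult:
    """Factor scores, their density curve, and the detected modes."""

    scores: np.ndarray  # standardized Bartlett factor score per case
    curve: TaxometricCurve  # kernel density over the score axis
    loadings: np.ndarray
    left_mode: float
    right_mode: float
    antimode: float | None  # deepest density valley between the two modes
    p_above_antimode: float | None
    valley_depth: float = 0.0  # depth of that valley, fraction of peak density


def _one_factor_fit(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood one-factor solution on standardized indicators."""
    z = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=1)
    fa = FactorAnalysis(n_components=1, svd_method="lapack")
    fa.fit(z)
    loadings = fa.components_[0]
    psi = fa.noise_variance_
    if np.any(loadings**2 >= 1.0) or np.any(psi <= 1e-8):
        raise ValueError(
            "degenerate one-factor solution (communality >= 1); "
            "indicators may be collinear"
        )
    # orient the factor with the indicators
    if loadings.sum() < 0:
        loadings = -loadings
    return loadings, psi


def bartlett_scores(scores: np.ndarray, loadings: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Bartlett weighted-least-squares factor scores, standardized."""
    z = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=1)
    w = loadings / psi
    f = z @ w / (loadings @ w)
    return (f - f.mean()) / f.std(ddof=1)


def lmode_scores(matrix: IndicatorMatrix, grid_size: int = LMODE_GRID_SIZE) -> LModeResult:
    """One-factor Bartlett scores, their kernel density, and its modes.

    The density (Gaussian kernel, Silverman bandwidth) is evaluated on a
    ``grid_size``-point grid spanning the score range.  The antimode is the
    *deepest valley* of the density — the interior local minimum with the
    largest drop below the lower of the two maxima flanking it — which in a
    two-class mixture sits at the class boundary; the left/right modes are
    the density maxima on either side of it.  A unimodal density (no
    interior minimum) yields no antimode, and a shallow valley (depth a
    tiny fraction of the peak density) signals no genuine bimodality.
    """
    if matrix.n_indicators < 3:
        raise ValueError("L-Mode requires at least 3 indicators")
    loadings, psi = _one_factor_fit(matrix.scores)
    f = bartlett_scores(matrix.scores, loadings, psi)
    # Silverman's rule of thumb with its robust scale, 0.9 min(sd, IQR/1.34)
    # n^(-1/5): right-skewed score distributions otherwise get oversmoothed
    # and a small-taxon shoulder washes out entirely
    iqr = float(np.subtract(*np.percentile(f, [75, 25])))
    scale = min(f.std(ddof=1), iqr / 1.34) or f.std(ddof=1)
    bw = 0.9 * scale * len(f) ** (-1 / 5)
    kde = stats.gaussian_kde(f, bw_method=bw / f.std(ddof=1))
    grid = np.linspace(f.min(), f.max(), grid_size)
    dens = kde(grid)
    curve = TaxometricCurve("LMODE", grid, dens)

    minima = (np.diff(np.sign(np.diff(dens))) > 0).nonzero()[0] + 1
    # an antimode must split off real mass: at least 2% of cases each side
    minima = np.array(
        [i for i in minima
         if 0.02 <= np.mean(f > grid[i]) <= 0.98], dtype=int
    )
    peak = float(dens.max())
    antimode = None
    p_above = None
    depth_frac = 0.0
    if minima.size:
        depths = np.array(
            [min(dens[:i].max(), dens[i + 1:].max()) - dens[i] for i in minima]
        )
        best = int(minima[np.argmax(depths)])
        antimode = float(grid[best])
        p_above = float(np.mean(f > antimode))
        depth_frac = float(depths.max() / peak)
        left = float(grid[np.argmax(dens[:best])])
        right = float(grid[best + 1 + np.argmax(dens[best + 1:])])
    else:
        # unimodal: report the peak on both sides (zero separation)
        left = right = float(grid[np.argmax(dens)])
    return LModeResult(f, curve, loadings, left, right, antimode, p_above,
                       depth_frac)


# --------------------------------------------------------------------------
# Base-rate estimation
# --------------------------------------------------------------------------

@dataclass
class BaseRateEstimate:
    """Taxon base-rate estimate(s) from one procedure's output.

    The published taxometric literature reports base-rate values per
    procedure without a unique canonical formula, so every estimate here
    carries a ``method`` tag and a reliability flag.  L-Mode reports two
    estimates (the fraction of cases above the density antimode, and the
    complement-side orientation), conveyed as a range.
    """

    procedure: str
    estimates: tuple[float, ...]
    methods: tuple[str, ...]
    reliable: bool
    note: str = ""

    def __post_init__(self) -> None:
        for e in self.estimates:
            if not 0.0 <= e <= 1.0:
                raise ValueError("base-rate estimates must lie in [0, 1]")

    @property
    def value(self) -> float:
        """Primary (taxon-side) estimate."""
        return self.estimates[0]


_FLAT_TOL = 1e-12


def _mambac_base_rate(curve: TaxometricCurve | AveragedCurve) -> BaseRateEstimate:
    y = curve.mean_y if isinstance(curve, AveragedCurve) else curve.y
    span = y.max() - y.min()
    if span < _FLAT_TOL:
        return BaseRateEstimate("MAMBAC", (0.5,), ("end-height-ratio",), False,
                                "flat curve")
    h_left = max(y[0], 0.0)
    h_right = max(y[-1], 0.0)
    if h_left + h_right <= 0:
        return BaseRateEstimate("MAMBAC", (0.5,), ("end-height-ratio",), False,
                                "nonpositive end heights")
    p = h_left / (h_left + h_right)  # higher right end => smaller taxon
    peak = int(np.argmax(y))
    reliable = 1 <= peak <= len(y) - 2
    note = "" if reliable else "curve peaks at the grid edge (dish-shaped?)"
    return BaseRateEstimate("MAMBAC", (float(np.clip(p, 0, 1)),),
                            ("end-height-ratio",), reliable, note)


def _maxeig_base_rate(curve: TaxometricCurve | AveragedCurve) -> BaseRateEstimate:
    y = curve.mean_y if isinstance(curve, AveragedCurve) else curve.y
    emax = y.max()
    if emax <= _FLAT_TOL or (emax - y.min()) < _FLAT_TOL:
        return BaseRateEstimate("MAXEIG", (0.5,), ("eigenvalue-ratio",), False,
                                "flat curve")
    peak = int(np.argmax(y))
    ratio = np.clip(y / emax, 0.0, 1.0)
    root = np.sqrt(1.0 - ratio)
    # windows left of the peak are taken as taxon-lean below one half,
    # windows right of it above; taxon assumed high-scoring
    p_win = np.where(np.arange(len(y)) <= peak, 0.5 * (1 - root), 0.5 * (1 + root))
    p = float(np.clip(np.mean(p_win), 0.0, 1.0))
    # a flat-ish curve (eigenvalue floor more than half the peak) signals a
    # dimensional profile, not a mixture peak
    reliable = y.min() / emax <= 0.5
    note = "" if reliable else "eigenvalue floor above half the peak (flat profile)"
    return BaseRateEstimate("MAXEIG", (p,), ("eigenvalue-ratio",), reliable, note)


_LMODE_MIN_VALLEY_DEPTH = 0.01  # fraction of the peak density


def _lmode_base_rate(result: LModeResult) -> BaseRateEstimate:
    if result.antimode is None or result.p_above_antimode is None:
        return BaseRateEstimate("LMODE", (0.5, 0.5),
                                ("antimode-above", "antimode-below"), False,
                                "unimodal score density: no antimode")
    p_above = result.p_above_antimode
    sep = result.right_mode - result.left_mode
    reliable = sep >= 0.5 and result.valley_depth >= _LMODE_MIN_VALLEY_DEPTH
    note = ("" if reliable else
            "modes within 0.5 SD or only a shallow density valley: "
            "no genuine bimodality")
    return BaseRateEstimate("LMODE", (p_above, 1.0 - p_above),
                            ("antimode-above", "antimode-below"), reliable, note)


def estimate_base_rate(curve_or_result, procedure: str | None = None) -> BaseRateEstimate:
    """Taxon base-rate estimate for one procedure's curve or score result.

    MAMBAC: ratio of the (nonnegative) curve heights at the two ends — a
    higher right end implies a smaller taxon.  MAXEIG: mean over windows of
    the taxon proportion implied by each window's eigenvalue relative to
    the peak (mixed windows peak at proportion one half).  L-Mode: the
    fraction of cases on either side of the density antimode, both
    orientations reported.  Estimates from flat, edge-peaked or unimodal
    output are flagged unreliable.
    """
    if isinstance(curve_or_result, LModeResult):
        return _lmode_base_rate(curve_or_result)
    proc = procedure or curve_or_result.procedure
    if proc == "MAMBAC":
        return _mambac_base_rate(curve_or_result)
    if proc == "MAXEIG":
        return _maxeig_base_rate(curve_or_result)
    raise ValueError(f"unknown procedure {proc!r}")
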