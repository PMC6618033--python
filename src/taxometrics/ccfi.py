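"""Comparison data, curve-fit RMSR, and the comparison curve fit index.

Whether an observed taxometric curve looks "peaked" is judged against
curves from simulated comparison data that reproduce the observed sample's
own marginal distributions and correlation structure under each rival
hypothesis: a two-class (taxonic) mixture and a single continuous
(dimensional) population.  The generator is the iterated bootstrap
technique of the taxometric-simulation literature: draw a multivariate
normal sample, replace each variable's values rank-for-rank with bootstrap
draws from the empirical marginal, measure the realized correlations, and
nudge the latent correlation matrix toward the target until the realized
matrix fits.

The fit of the averaged data curve to each comparison ensemble's averaged
curve is the root-mean-square residual (RMSR) after jointly min-max
scaling the two curves to [0, 1], and

    CCFI = RMSR_dimensional / (RMSR_dimensional + RMSR_taxonic)

so 0 means a clean dimensional fit, 1 a clean taxonic fit, and 0.5 the
dividing line, with 0.45-0.55 treated as the index's fuzzy range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import IndicatorMatrix, SampleSizeWarning
from .curves import AveragedCurve, TaxometricCurve

__all__ = [
    "ComparisonEnsemble",
    "CCFIResult",
    "Interpretation",
    "generate_comparison_data",
    "curve_rmsr",
    "joint_span",
    "ccfi",
    "interpret_ccfi",
    "band_label",
]


@dataclass
class ComparisonEnsemble:
    """Replicated simulated datasets under one structural hypothesis."""

    structure: str  # "taxonic" | "dimensional"
    replicates: list[IndicatorMatrix]
    seed: int
    base_rate: float | None = None  # taxonic only
    corr_rmsr: list[float] = field(default_factory=list)  # attained per replicate
    averaged_curves: dict[str, TaxometricCurve] = field(default_factory=dict)


def _bootstrap_block(
    emp: np.ndarray,
    r_target: np.ndarray,
    n_out: int,
    rng: np.random.Generator,
    n_iterations: int,
) -> tuple[np.ndarray, float]:
    """One simulated block matching empirical marginals and correlations.

    Iteratively draws latent MVN data, substitutes rank-matched bootstrap
    draws from each empirical margin, measures the realized correlation
    matrix and corrects the latent target by the residual; returns the
    iteration with the smallest RMSR to the target.  A non-positive-
    definite intermediate matrix is shrunk toward the identity (with a
    warning) until definite.
    """
    k = emp.shape[1]
    iu = np.triu_indices(k, 1)
    r_int = r_target.copy()
    best, best_rmsr = None, np.inf
    shrunk = False
    for _ in range(n_iterations):
        r_use = r_int
        shrink = 0.0
        while True:
            try:
                chol = np.linalg.cholesky(r_use)
                break
            except np.linalg.LinAlgError:
                shrink += 0.1
                shrunk = True
                if shrink > 1:
                    chol = np.eye(k)
                    break
                r_use = (1 - shrink) * r_int + shrink * np.eye(k)
        z = rng.standard_normal((n_out, k)) @ chol.T
        sim = np.empty_like(z)
        ranks = np.argsort(np.argsort(z, axis=0), axis=0)
        for j in range(k):
            draws = np.sort(rng.choice(emp[:, j], size=n_out, replace=True))
            sim[:, j] = draws[ranks[:, j]]
        with np.errstate(invalid="ignore"):
            r_real = np.corrcoef(sim, rowvar=False)
        r_real = np.nan_to_num(r_real, nan=0.0)
        np.fill_diagonal(r_real, 1.0)
        rmsr = float(np.sqrt(np.mean((r_real - r_target)[iu] ** 2))) if k > 1 else 0.0
        if rmsr < best_rmsr:
            best, best_rmsr = sim, rmsr
        r_int = r_int + (r_target - r_real)
        np.fill_diagonal(r_int, 1.0)
    if shrunk:
        warnings.warn(
            "non-positive-definite intermediate correlation matrix; "
            "shrunk toward identity during iteration"
        )
    return best, best_rmsr


def generate_comparison_data(
    matrix: IndicatorMatrix,
    structure: str,
    base_rate: float | None = None,
    n_replicates: int = 10,
    n_iterations: int = 10,
    seed: int = 0,
    taxon_mask: np.ndarray | None = None,
) -> ComparisonEnsemble:
    """Simulate comparison datasets reproducing the sample's structure.

    ``structure="dimensional"``: each replicate bootstraps every variable's
    empirical marginal and matches the full-sample correlation matrix.

    ``structure="taxonic"``: the sample is split into putative taxon and
    complement groups (``taxon_mask``, defaulting to the matrix's own
    labels); each replicate concatenates a taxon block of exactly
    ``round(P * N)`` cases and a complement block, each matching its
    group's marginals and within-group correlations.  ``base_rate``
    defaults to the observed group proportion.
    """
    if structure not in ("taxonic", "dimensional"):
        raise ValueError(f"unknown structure {structure!r}")
    n, k = matrix.scores.shape
    replicates: list[IndicatorMatrix] = []
    attained: list[float] = []

    if structure == "dimensional":
        r_target = np.corrcoef(matrix.scores, rowvar=False)
        for i in range(n_replicates):
            rng = np.random.default_rng([seed, 11, i])
            sim, rmsr = _bootstrap_block(
                matrix.scores, r_target, n, rng, n_iterations
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", SampleSizeWarning)
                replicates.append(
                    IndicatorMatrix(sim, list(matrix.indicator_names))
                )
            attained.append(rmsr)
        return ComparisonEnsemble(structure, replicates, seed, None, attained)

    if taxon_mask is None:
        taxon_mask = matrix.taxon_mask()
    taxon_mask = np.asarray(taxon_mask, dtype=bool)
    emp_t = matrix.scores[taxon_mask]
    emp_c = matrix.scores[~taxon_mask]
    if len(emp_t) < 3 or len(emp_c) < 3:
        raise ValueError("each group needs at least 3 cases for taxonic simulation")
    if base_rate is None:
        base_rate = len(emp_t) / n
    if not 0.0 < base_rate < 1.0:
        raise ValueError("base_rate must lie in (0, 1)")
    n_t = int(round(base_rate * n))
    n_c = n - n_t
    r_t = np.corrcoef(emp_t, rowvar=False)
    r_c = np.corrcoef(emp_c, rowvar=False)
    for r in (r_t, r_c):
        np.nan_to_num(r, copy=False, nan=0.0)
        np.fill_diagonal(r, 1.0)
    for i in range(n_replicates):
        rng = np.random.default_rng([seed, 13, i])
        sim_c, rmsr_c = _bootstrap_block(emp_c, r_c, n_c, rng, n_iterations)
        sim_t, rmsr_t = _bootstrap_block(emp_t, r_t, n_t, rng, n_iterations)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SampleSizeWarning)
            replicates.append(
                IndicatorMatrix(
                    np.vstack([sim_c, sim_t]),
                    list(matrix.indicator_names),
                    group=np.array(
                        ["complement_putative"] * n_c + ["taxon_putative"] * n_t,
                        dtype=object,
                    ),
                )
            )
        attained.append(max(rmsr_c, rmsr_t))
    return ComparisonEnsemble(structure, replicates, seed, base_rate, attained)


# --------------------------------------------------------------------------
# RMSR and CCFI
# --------------------------------------------------------------------------

def _curve_xy(curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, AveragedCurve):
        return curve.x, curve.mean_y
    return curve.x, curve.y


def curve_rmsr(data_curve, comparison_curve, scale_span: float | None = None) -> float:
    """Root-mean-square residual between two curves, jointly scaled.

    The comparison curve is interpolated onto the data curve's grid when
    the grids differ; both curves are then min-max scaled *jointly* to
    [0, 1] (so the index is unit-free) and the RMSR of the pointwise
    differences returned.

    When the same data curve is compared against *both* a taxonic and a
    dimensional comparison curve, pass the span of all three curves as
    ``scale_span`` so the two residuals share one scale: scaling each pair
    by its own (smaller or larger) range would make the two RMSRs
    incommensurable and bias their ratio.
    """
    xd, yd = _curve_xy(data_curve)
    xc, yc = _curve_xy(comparison_curve)
    if len(xd) == len(xc) and np.allclose(xd, xc):
        yc_on = yc
    else:
        if xc[-1] < xd[0] or xc[0] > xd[-1]:
            raise ValueError("curve grids are disjoint; cannot interpolate")
        yc_on = np.interp(xd, xc, yc)
    span = (
        scale_span if scale_span is not None
        else max(yd.max(), yc_on.max()) - min(yd.min(), yc_on.min())
    )
    if span <= 0:
        return 0.0  # both curves constant and equal after joint scaling
    return float(np.sqrt(np.mean(((yd - yc_on) / span) ** 2)))


def joint_span(*curves) -> float:
    """Min-max span over several curves' y values (common RMSR scale)."""
    ys = [(_curve_xy(c)[1] if not isinstance(c, np.ndarray) else c) for c in curves]
    return float(max(y.max() for y in ys) - min(y.min() for y in ys))


def ccfi(rmsr_taxonic: float, rmsr_dimensional: float) -> float:
    """``CCFI = RMSR_dim / (RMSR_dim + RMSR_tax)``, in [0, 1]."""
    if rmsr_taxonic < 0 or rmsr_dimensional < 0:
        raise ValueError("RMSR values must be nonnegative")
    total = rmsr_taxonic + rmsr_dimensional
    if total == 0:
        raise ValueError("both RMSRs are zero: CCFI undefined")
    return float(rmsr_dimensional / total)


@dataclass
class CCFIResult:
    """CCFI and its ingredients for one procedure."""

    procedure: str
    rmsr_taxonic: float
    rmsr_dimensional: float
    ccfi: float
    interpretation: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.ccfi <= 1.0:
            raise ValueError("CCFI must lie in [0, 1]")


def band_label(value: float) -> str:
    """Banding rule: <0.40 dimensional, >0.60 taxonic, 0.45-0.55 ambiguous."""
    if value < 0.40:
        return "dimensional"
    if value > 0.60:
        return "taxonic"
    if 0.45 <= value <= 0.55:
        return "ambiguous"
    return "weak dimensional lean" if value < 0.45 else "weak taxonic lean"


@dataclass
class Interpretation:
    """Per-procedure labels, mean CCFI, and the final verdict."""

    per_procedure: dict[str, float]
    labels: dict[str, str]
    mean_ccfi: float
    mean_label: str
    unanimous: bool
    verdict: str


def interpret_ccfi(values: dict[str, float]) -> Interpretation:
    """Label each CCFI, average them, and state the final verdict.

    The verdict mirrors the published reporting style: the arithmetic mean
    CCFI is banded by the same rule as the individual values ("final
    interpretation is categorical" when the mean exceeds 0.60), with a
    unanimity flag when every procedure lands in the same band.
    """
    if not values:
        raise ValueError("need at least one CCFI value")
    labels = {p: band_label(v) for p, v in values.items()}
    mean = float(np.mean(list(values.values())))
    mean_label = band_label(mean)
    unanimous = len(set(labels.values())) == 1
    verdict_word = {
        "taxonic": "categorical",
        "dimensional": "dimensional",
        "ambiguous": "ambiguous",
        "weak taxonic lean": "lean categorical",
        "weak dimensional lean": "lean dimensional",
    }[mean_label]
    verdict = (
        f"Mean CCFI = {mean:.3f}; final interpretation is {verdict_word}"
        + ("" if unanimous else " (procedures disagree)")
    )
    return Interpretation(dict(values), labels, mean, mean_label, unanimous, verdict)
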