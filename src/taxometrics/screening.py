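"""Indicator validity screening.

Before running taxometric procedures the candidate indicators are screened:
each must separate the putative taxon from the putative complement by a
large standardized difference (Cohen's d, pooled-SD units; conventional
minimum 1.25), while correlations *within* each putative group ("nuisance
covariance") should stay small (conventional ceiling 0.30) relative to the
full-sample correlations that the latent mixture induces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .io import IndicatorMatrix

__all__ = [
    "D_MIN_DEFAULT",
    "R_MAX_DEFAULT",
    "ScreeningReport",
    "cohens_d",
    "mean_abs_pairwise_corr",
    "nuisance_correlations",
    "select_indicators",
    "screen",
]

D_MIN_DEFAULT = 1.25
R_MAX_DEFAULT = 0.30


def cohens_d(taxon_values, complement_values) -> float:
    """Signed Cohen's d between two groups with (n-1)-weighted pooled SD.

    ``d = (mean_taxon - mean_complement) / s_pooled`` with
    ``s_pooled^2 = ((n_t-1) s_t^2 + (n_c-1) s_c^2) / (n_t + n_c - 2)``.
    No small-sample (Hedges) correction is applied.
    """
    x = np.asarray(taxon_values, dtype=float)
    y = np.asarray(complement_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 cases")
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / (
        x.size + y.size - 2
    )
    if sp2 <= 0:
        raise ValueError("zero pooled variance: Cohen's d undefined")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def mean_abs_pairwise_corr(scores: np.ndarray) -> float:
    """Mean absolute pairwise Pearson correlation over indicator columns."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape[1] < 2:
        raise ValueError("need at least 2 indicators for pairwise correlations")
    r = np.corrcoef(scores, rowvar=False)
    iu = np.triu_indices_from(r, k=1)
    vals = np.abs(r[iu])
    return float(np.nanmean(vals))


def nuisance_correlations(matrix: IndicatorMatrix) -> dict:
    """Full-sample and within-putative-group mean |r| summaries.

    Returns a dict with keys ``full_corr``, ``nuisance_taxon`` and
    ``nuisance_complement``, each the mean absolute pairwise Pearson
    correlation over the relevant cases.  Requires putative group labels
    and at least 3 cases per group.
    """
    if not matrix.has_putative_groups:
        raise ValueError("putative group labels required for nuisance correlations")
    t = matrix.taxon_mask()
    c = matrix.complement_mask()
    for name, mask in (("taxon", t), ("complement", c)):
        if mask.sum() < 3:
            raise ValueError(f"putative {name} group has fewer than 3 cases")
    return {
        "full_corr": mean_abs_pairwise_corr(matrix.scores),
        "nuisance_taxon": mean_abs_pairwise_corr(matrix.scores[t]),
        "nuisance_complement": mean_abs_pairwise_corr(matrix.scores[c]),
    }


@dataclass
class ScreeningReport:
    """Per-indicator validity summary plus the selected subset."""

    indicator_names: list[str]
    d: dict[str, float]
    skew: dict[str, float]
    full_corr: float
    nuisance_taxon: float
    nuisance_complement: float
    base_rate_putative: float
    d_min: float = D_MIN_DEFAULT
    r_max: float = R_MAX_DEFAULT
    selected: list[str] = field(default_factory=list)
    verdicts: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    insufficient: bool = False

    def __post_init__(self) -> None:
        if not set(self.selected) <= set(self.indicator_names):
            raise ValueError("selected indicators must be a subset of indicator_names")
        if not 0.0 < self.base_rate_putative < 1.0:
            raise ValueError("base_rate_putative must lie strictly in (0, 1)")

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source: str) -> "ScreeningReport":
        obj = json.loads(source)
        return cls(**obj)


def select_indicators(
    report: ScreeningReport,
    d_min: float = D_MIN_DEFAULT,
    r_max: float = R_MAX_DEFAULT,
) -> ScreeningReport:
    """Apply the validity rule: keep an indicator iff ``|d| >= d_min``.

    The nuisance ceiling is a module-level warning, not a per-indicator
    exclusion: when a putative group's mean within-group |r| reaches
    ``r_max`` the report gains a warning but no indicator is dropped.
    A result with fewer than 2 kept indicators is flagged insufficient for
    taxometrics.  Selection is monotone in ``d_min``: raising the threshold
    never adds an indicator.
    """
    verdicts = {}
    selected = []
    for name in report.indicator_names:
        if abs(report.d[name]) >= d_min:
            verdicts[name] = f"kept (|d|={abs(report.d[name]):.2f} >= {d_min})"
            selected.append(name)
        else:
            verdicts[name] = f"dropped (|d|={abs(report.d[name]):.2f} < {d_min})"
    warnings_ = list(report.warnings)
    for side, val in (
        ("taxon", report.nuisance_taxon),
        ("complement", report.nuisance_complement),
    ):
        if val >= r_max:
            warnings_.append(
                f"mean within-{side} nuisance correlation {val:.2f} >= {r_max}"
            )
    insufficient = len(selected) < 2
    if insufficient:
        warnings_.append(
            "fewer than 2 valid indicators: insufficient for taxometrics; "
            "sample does not enter subsequent taxometric analysis"
        )
    return ScreeningReport(
        indicator_names=report.indicator_names,
        d=report.d,
        skew=report.skew,
        full_corr=report.full_corr,
        nuisance_taxon=report.nuisance_taxon,
        nuisance_complement=report.nuisance_complement,
        base_rate_putative=report.base_rate_putative,
        d_min=d_min,
        r_max=r_max,
        selected=selected,
        verdicts=verdicts,
        warnings=warnings_,
        insufficient=insufficient,
    )


def screen(
    matrix: IndicatorMatrix,
    d_min: float = D_MIN_DEFAULT,
    r_max: float = R_MAX_DEFAULT,
) -> ScreeningReport:
    """Full screening pass: effect sizes, correlations, selection rule."""
    if not matrix.has_putative_groups:
        raise ValueError("screening requires putative group labels")
    t = matrix.taxon_mask()
    c = matrix.complement_mask()
    d = {
        name: cohens_d(matrix.scores[t, j], matrix.scores[c, j])
        for j, name in enumerate(matrix.indicator_names)
    }
    skew = {
        name: float(stats.skew(matrix.scores[:, j], bias=False))
        for j, name in enumerate(matrix.indicator_names)
    }
    corr = (
        nuisance_correlations(matrix)
        if matrix.n_indicators >= 2
        else {"full_corr": np.nan, "nuisance_taxon": np.nan, "nuisance_complement": np.nan}
    )
    base = ScreeningReport(
        indicator_names=list(matrix.indicator_names),
        d=d,
        skew=skew,
        base_rate_putative=float(t.sum() / (t.sum() + c.sum())),
        **corr,
    )
    return select_indicators(base, d_min=d_min, r_max=r_max)
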