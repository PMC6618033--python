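"""Indicator tables, EDI-2 subscale scoring, and z-score standardization.

The universal input to every taxometric procedure is an
:class:`IndicatorMatrix`: ``N`` cases by ``k`` continuous indicator scores
(questionnaire subscale totals, BMI z-scores, ...), optionally carrying a
putative group label per case.  Loading is strict: missing or non-numeric
cells are rejected rather than imputed, because the curve procedures are
order-statistics based and silently imputed values distort cuts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RESPONSE_VALUES",
    "GROUP_LABELS",
    "RECOMMENDED_MIN_N",
    "SampleSizeWarning",
    "ResponseSheet",
    "IndicatorMatrix",
    "ZScoreSpec",
    "score_edi2",
    "load_item_map",
    "read_indicators",
    "write_indicators",
    "zscore",
]

#: Scoring of the six EDI-2 response categories.
RESPONSE_VALUES: Mapping[str, int] = {
    "always": 3,
    "usually": 3,
    "often": 3,
    "sometimes": 2,
    "occasionally": 1,
    "never": 0,
}

#: Allowed values of the optional per-case group column.
GROUP_LABELS = frozenset({"taxon_putative", "complement_putative", "unknown"})

#: Recommended minimum mixed-sample size for taxometric analysis.
RECOMMENDED_MIN_N = 300


class SampleSizeWarning(UserWarning):
    """Raised when a sample falls below the recommended minimum size."""


@dataclass(frozen=True)
class ZScoreSpec:
    """Reference mean / SD used to standardize a raw variable (e.g. BMI).

    ``z = (value - reference_mean) / reference_sd``.  When the reference
    moments derive from the analysis population itself, the standardized
    variable has mean zero over that population by construction.
    """

    reference_mean: float
    reference_sd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.reference_sd) or self.reference_sd <= 0:
            raise ValueError(
                f"reference_sd must be positive, got {self.reference_sd!r}"
            )


def zscore(values, spec: ZScoreSpec) -> np.ndarray:
    """Standardize ``values`` against a :class:`ZScoreSpec`."""
    values = np.asarray(values, dtype=float)
    return (values - spec.reference_mean) / spec.reference_sd


@dataclass
class ResponseSheet:
    """Raw item-level questionnaire responses plus an item→subscale map.

    ``responses`` holds one row per case and one column per item, each cell
    a category label from the six-point scale (see :data:`RESPONSE_VALUES`).
    ``item_map`` assigns every item to a subscale name; scoring rejects a
    sheet containing items the map does not cover.
    """

    case_ids: list
    responses: pd.DataFrame  # rows align with case_ids; values are category strings
    item_map: Mapping[str, str]  # item name -> subscale name

    def __post_init__(self) -> None:
        if len(self.case_ids) != len(self.responses):
            raise ValueError("case_ids and responses row count differ")
        missing = [it for it in self.item_map if it not in self.responses.columns]
        if missing:
            raise ValueError(f"item_map references items absent from sheet: {missing}")
        for item in self.item_map:
            col = self.responses[item]
            bad = ~col.isin(RESPONSE_VALUES)
            if bad.any():
                idx = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"unknown response category {col.iloc[idx]!r} for item "
                    f"{item!r}, case {self.case_ids[idx]!r}"
                )


@dataclass
class IndicatorMatrix:
    """``N x k`` matrix of continuous indicator scores with optional labels."""

    scores: np.ndarray
    indicator_names: list[str]
    case_ids: list = field(default=None)  # type: ignore[assignment]
    group: np.ndarray | None = None  # per-case labels from GROUP_LABELS

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D array")
        n, k = self.scores.shape
        if len(self.indicator_names) != k:
            raise ValueError("indicator_names length does not match score columns")
        if not np.all(np.isfinite(self.scores)):
            r, c = np.argwhere(~np.isfinite(self.scores))[0]
            raise ValueError(
                f"missing/non-finite score at row {r}, column "
                f"{self.indicator_names[c]!r}; missing data are rejected, not imputed"
            )
        if self.case_ids is None:
            self.case_ids = list(range(n))
        if len(self.case_ids) != n:
            raise ValueError("case_ids length does not match score rows")
        if self.group is not None:
            self.group = np.asarray(self.group, dtype=object)
            if self.group.shape != (n,):
                raise ValueError("group labels length does not match score rows")
            bad = set(self.group) - GROUP_LABELS
            if bad:
                raise ValueError(
                    f"group labels outside {sorted(GROUP_LABELS)}: {sorted(bad)}"
                )
        if n < RECOMMENDED_MIN_N:
            warnings.warn(
                f"N={n} is below recommended minimum sample size "
                f"({RECOMMENDED_MIN_N}) for taxometric analysis",
                SampleSizeWarning,
                stacklevel=2,
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_cases(self) -> int:
        return self.scores.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.scores.shape[1]

    @property
    def has_putative_groups(self) -> bool:
        return self.group is not None and {
            "taxon_putative",
            "complement_putative",
        } <= set(self.group)

    def taxon_mask(self) -> np.ndarray:
        if self.group is None:
            raise ValueError("matrix carries no group labels")
        return np.asarray(self.group) == "taxon_putative"

    def complement_mask(self) -> np.ndarray:
        if self.group is None:
            raise ValueError("matrix carries no group labels")
        return np.asarray(self.group) == "complement_putative"

    def column(self, name: str) -> np.ndarray:
        return self.scores[:, self.indicator_names.index(name)]

    def subset(self, names: Sequence[str]) -> "IndicatorMatrix":
        """Return a matrix restricted to the named indicator columns."""
        idx = [self.indicator_names.index(n) for n in names]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SampleSizeWarning)
            return IndicatorMatrix(
                self.scores[:, idx], list(names), list(self.case_ids),
                None if self.group is None else self.group.copy(),
            )

    def oriented(self) -> "IndicatorMatrix":
        """Copy with every indicator reflected to point the same way.

        Curve procedures average across indicators, so indicators that run
        *against* the latent variable (e.g. a BMI z-score on which the
        clinical group is low) must be reflected first or their
        contributions cancel.  Columns whose loading on the first principal
        axis of the correlation matrix is negative are multiplied by -1
        (the axis itself is signed so that the majority of loadings are
        positive).  MAXEIG eigenvalues are invariant to reflections; MAMBAC
        and L-Mode are not.
        """
        r = np.corrcoef(self.scores, rowvar=False)
        vals, vecs = np.linalg.eigh(np.nan_to_num(r, nan=0.0))
        pc = vecs[:, -1]
        if pc.sum() < 0:
            pc = -pc
        flip = np.where(pc < 0, -1.0, 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SampleSizeWarning)
            return IndicatorMatrix(
                self.scores * flip, list(self.indicator_names),
                list(self.case_ids),
                None if self.group is None else self.group.copy(),
            )

    def standardized(self) -> "IndicatorMatrix":
        """Full-sample z-scored copy (each indicator to mean 0, SD 1)."""
        mu = self.scores.mean(axis=0)
        sd = self.scores.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            j = int(np.argmax(sd <= 0))
            raise ValueError(f"indicator {self.indicator_names[j]!r} is constant")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SampleSizeWarning)
            return IndicatorMatrix(
                (self.scores - mu) / sd, list(self.indicator_names),
                list(self.case_ids),
                None if self.group is None else self.group.copy(),
            )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.indicator_names)
        df.insert(0, "case_id", self.case_ids)
        if self.group is not None:
            df["group"] = self.group
        return df


def score_edi2(sheet: ResponseSheet) -> IndicatorMatrix:
    """Score raw six-category responses into per-case subscale totals.

    Each subscale total is the sum over its items of the category values
    always/usually/often→3, sometimes→2, occasionally→1, never→0.  Totals
    are nonnegative integers.  Scoring is monotone: moving any single
    response to a higher-valued category never decreases its subscale total.
    """
    unmapped = [c for c in sheet.responses.columns if c not in sheet.item_map]
    if unmapped:
        raise ValueError(f"items not covered by the item map: {unmapped}")
    subscales = sorted(set(sheet.item_map.values()))
    n = len(sheet.case_ids)
    totals = np.zeros((n, len(subscales)))
    col_of = {s: j for j, s in enumerate(subscales)}
    for item, subscale in sheet.item_map.items():
        vals = sheet.responses[item].map(RESPONSE_VALUES).to_numpy(dtype=float)
        totals[:, col_of[subscale]] += vals
    return IndicatorMatrix(totals, subscales, list(sheet.case_ids))


def load_item_map(path) -> dict[str, str]:
    """Load an item → subscale map from a YAML or JSON file.

    The file holds one flat mapping, e.g. ``{"item1": "bulimia", ...}``
    (YAML also accepts the ``item1: bulimia`` block form).
    """
    import yaml

    with open(path) as fh:
        obj = yaml.safe_load(fh)  # YAML is a superset of JSON
    if not isinstance(obj, dict) or not all(
        isinstance(k, str) and isinstance(v, str) for k, v in obj.items()
    ):
        raise ValueError(f"{path} must contain a flat item -> subscale mapping")
    return obj


def read_indicators(path, sep: str = ",") -> IndicatorMatrix:
    """Read an indicator table from CSV (or TSV via ``sep='\\t'``).

    The header row names the indicators.  Optional columns: ``case_id`` and
    ``group`` (labels restricted to :data:`GROUP_LABELS`).  Any empty or
    non-numeric score cell is rejected with its row and column named.
    """
    df = pd.read_csv(
        path, sep=sep, dtype={"case_id": str, "group": str},
        float_precision="round_trip",
    )
    case_ids = df.pop("case_id").tolist() if "case_id" in df.columns else None
    group = df.pop("group").to_numpy() if "group" in df.columns else None
    for col in df.columns:
        cells = pd.to_numeric(df[col], errors="coerce")
        bad = cells.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"missing or non-numeric value at row {row}, column {col!r} "
                f"in {path}"
            )
        df[col] = cells
    return IndicatorMatrix(
        df.to_numpy(dtype=float), list(df.columns), case_ids, group
    )


def write_indicators(matrix: IndicatorMatrix, path, sep: str = ",") -> None:
    """Write an indicator table; round-trips bit-exactly through ``read_indicators``."""
    df = matrix.to_dataframe()
    # shortest-repr float formatting (the default) round-trips bit-exactly
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)
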