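"""Calibration of smartphone estimates against circular-camera values.

Paired records — the same sample point measured by a circular
hemispherical camera (reference) and by the smartphone protocol — are
compared descriptively (paired differences, ratios, paired t-test) and
through linear calibration models

    y ~ x, y ~ x + OV, y ~ x + x:OV, y ~ x + x:OV + OV,
    y ~ x + x:OV + OV + camera, y ~ x + x:OV + OV + camera + HFG,

where y is the circular-camera parameter, x the smartphone one, OV the
overstory-type class (broadleaves / douglas / larch / pine / sitka),
``camera`` the circular camera body and ``HFG`` the height-from-ground
protocol.  Models are ordinary least squares (the sampling hierarchy's
random effects are intentionally not estimated; the predictive surface
is the fixed effects), ranked by AIC = n ln(RSS/n) + 2 (k + 1).

The fitted surface converts a smartphone value into its
circular-camera equivalent, clipping predictions into [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "OV_LEVELS",
    "STRUCTURE_IDS",
    "DegenerateDesignError",
    "CalibrationFit",
    "StructureComparison",
    "paired_difference_summary",
    "fit_linear_structure",
    "compare_structures_aic",
    "predict_circular_equivalent",
    "simulate_records",
]

OV_LEVELS = ("broadleaves", "douglas", "larch", "pine", "sitka")

#: The six candidate fixed-effects structures, simplest first.
STRUCTURE_IDS = (
    "y~x",
    "y~x+OV",
    "y~x+x:OV",
    "y~x+x:OV+OV",
    "y~x+x:OV+OV+camera",
    "y~x+x:OV+OV+camera+HFG",
)

_STRUCTURE_TERMS = {
    "y~x": "{x}",
    "y~x+OV": "{x} + C(OV)",
    "y~x+x:OV": "{x} + {x}:C(OV)",
    "y~x+x:OV+OV": "{x} + {x}:C(OV) + C(OV)",
    "y~x+x:OV+OV+camera": "{x} + {x}:C(OV) + C(OV) + C(camera_type)",
    "y~x+x:OV+OV+camera+HFG": (
        "{x} + {x}:C(OV) + C(OV) + C(camera_type) + C(height_from_ground)"
    ),
}

_STRUCTURE_COLUMNS = {
    "y~x": (),
    "y~x+OV": ("OV",),
    "y~x+x:OV": ("OV",),
    "y~x+x:OV+OV": ("OV",),
    "y~x+x:OV+OV+camera": ("OV", "camera_type"),
    "y~x+x:OV+OV+camera+HFG": ("OV", "camera_type", "height_from_ground"),
}


class DegenerateDesignError(ValueError):
    """The design matrix is rank deficient for the requested structure."""


def paired_difference_summary(a, b) -> dict:
    """Summary of paired differences a - b and ratios 100 a / b.

    Returns mean and sample SD of the differences, the mean ratio in
    percent over pairs with b > 0, the pair count and a paired t-test
    (t statistic and two-sided p-value).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    pos = b > 0
    ratio = float(np.mean(100.0 * a[pos] / b[pos])) if pos.any() else float("nan")
    if np.allclose(diff, diff[0]):
        # zero-variance differences: t-test undefined; report exact result
        t_stat, p_value = (float("inf"), 0.0) if diff[0] != 0 else (0.0, 1.0)
    else:
        t_stat, p_value = stats.ttest_rel(a, b)
    return {
        "mean_diff": float(np.mean(diff)),
        "sd_diff": float(np.std(diff, ddof=1)),
        "mean_ratio_percent": ratio,
        "n": int(n),
        "t_stat": float(t_stat),
        "p_value": float(p_value),
    }


@dataclass
class CalibrationFit:
    """A fitted calibration structure with its selection statistics."""

    structure_id: str
    response: str
    predictor: str
    formula: str
    params: pd.Series
    n: int
    rss: float
    aic: float
    resid_sd: float
    result: object = field(repr=False)

    def summary(self):
        return self.result.summary()

    def effective_slope(self, OV: str | None = None) -> float:
        """Slope of the response in the predictor for one OV level.

        Treatment coding: the base slope belongs to the reference
        level; other levels add their interaction offset.
        """
        slope = float(self.params[self.predictor])
        if OV is not None:
            key = f"{self.predictor}:C(OV)[T.{OV}]"
            if key in self.params.index:
                slope += float(self.params[key])
        return slope


def _build_formula(structure_id: str, response: str, predictor: str) -> str:
    if structure_id not in _STRUCTURE_TERMS:
        raise ValueError(f"unknown structure {structure_id!r}; one of {STRUCTURE_IDS}")
    return f"{response} ~ " + _STRUCTURE_TERMS[structure_id].format(x=predictor)


def fit_linear_structure(
    records: pd.DataFrame, response: str, predictor: str, structure_id: str = "y~x"
) -> CalibrationFit:
    """Least-squares fit of one calibration structure.

    ``records`` must contain the response and predictor columns plus
    any categorical columns the structure uses (OV, camera_type,
    height_from_ground).  Raises :class:`DegenerateDesignError` when
    the design is rank deficient (e.g. OV terms with a single observed
    level) and ``ValueError`` when there are fewer than
    (coefficients + 2) records.
    """
    if structure_id not in _STRUCTURE_TERMS:
        raise ValueError(f"unknown structure {structure_id!r}; one of {STRUCTURE_IDS}")
    for col in (response, predictor) + _STRUCTURE_COLUMNS[structure_id]:
        if col not in records.columns:
            raise ValueError(f"records lack required column {col!r}")
    for col in _STRUCTURE_COLUMNS[structure_id]:
        if records[col].nunique() < 2:
            raise DegenerateDesignError(
                f"structure {structure_id!r} needs >= 2 levels of {col!r}, "
                f"found {records[col].nunique()}"
            )
    formula = _build_formula(structure_id, response, predictor)
    model = smf.ols(formula, data=records)
    exog = model.exog
    n, k = exog.shape
    if np.linalg.matrix_rank(exog) < k:
        raise DegenerateDesignError(
            f"structure {structure_id!r} is rank deficient on these records"
        )
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} records for {k} coefficients")
    result = model.fit()
    rss = float(np.sum(result.resid**2))
    aic = n * np.log(rss / n) + 2.0 * (k + 1)
    return CalibrationFit(
        structure_id=structure_id,
        response=response,
        predictor=predictor,
        formula=formula,
        params=result.params,
        n=n,
        rss=rss,
        aic=float(aic),
        resid_sd=float(np.sqrt(rss / (n - k))),
        result=result,
    )


@dataclass
class StructureComparison:
    """AIC ranking of the candidate structures for one response."""

    table: pd.DataFrame
    fits: dict[str, CalibrationFit]
    errors: dict[str, str]

    @property
    def best(self) -> CalibrationFit:
        return self.fits[self.table.iloc[0]["structure_id"]]


def compare_structures_aic(
    records: pd.DataFrame,
    response: str,
    predictor: str,
    structures: tuple[str, ...] = STRUCTURE_IDS,
) -> StructureComparison:
    """Fit every candidate structure and rank by ascending AIC.

    Structures whose required columns are absent or whose design is
    degenerate are skipped and reported in ``errors``.
    """
    fits: dict[str, CalibrationFit] = {}
    errors: dict[str, str] = {}
    for sid in structures:
        try:
            fits[sid] = fit_linear_structure(records, response, predictor, sid)
        except (DegenerateDesignError, ValueError) as exc:
            errors[sid] = str(exc)
    if not fits:
        raise ValueError(f"no structure could be fitted: {errors}")
    rows = [
        {
            "structure_id": f.structure_id,
            "n_coef": len(f.params),
            "rss": f.rss,
            "aic": f.aic,
        }
        for f in fits.values()
    ]
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return StructureComparison(table=table, fits=fits, errors=errors)


def predict_circular_equivalent(
    fit: CalibrationFit,
    smartphone_value: float,
    OV: str | None = None,
    camera_type: str | None = None,
    height_from_ground: str | None = None,
) -> tuple[float, bool]:
    """Convert a smartphone value to its circular-camera equivalent.

    Returns ``(value, clipped)`` where ``clipped`` flags a prediction
    that had to be clipped into [0, 1].  Raises ``KeyError`` when the
    structure needs an OV (or camera/HFG) level the model has not seen.
    """
    row = {fit.predictor: [smartphone_value]}
    needed = _STRUCTURE_COLUMNS[fit.structure_id]
    provided = {
        "OV": OV,
        "camera_type": camera_type,
        "height_from_ground": height_from_ground,
    }
    for col in needed:
        if provided[col] is None:
            raise KeyError(f"structure {fit.structure_id!r} requires {col!r}")
        observed = fit.result.model.data.frame[col].unique()
        if provided[col] not in observed:
            raise KeyError(f"unknown {col} level {provided[col]!r}")
        row[col] = [provided[col]]
    pred = float(fit.result.predict(pd.DataFrame(row)).iloc[0])
    clipped = not 0.0 <= pred <= 1.0
    return min(1.0, max(0.0, pred)), clipped


def simulate_records(
    seed: int,
    n: int = 200,
    intercept: float = 0.025,
    base_slope: float = 0.275,
    slope_offsets: dict[str, float] | None = None,
    noise_sd: float = 0.03,
    x_range: tuple[float, float] = (0.1, 0.7),
    predictor: str = "x",
    response: str = "y",
) -> pd.DataFrame:
    """Simulate paired records from a known calibration surface.

    ``slope_offsets`` maps OV levels to additive slope offsets relative
    to ``base_slope`` (the first level's slope); ``None`` gives a
    homogeneous y ~ x surface with OV labels still attached (so
    OV-bearing structures can be fitted but carry no signal).
    """
    rng = np.random.default_rng([int(seed), 0x5E])
    ov = np.asarray(OV_LEVELS)[rng.integers(0, len(OV_LEVELS), size=n)]
    x = rng.uniform(*x_range, size=n)
    slope = np.full(n, base_slope)
    if slope_offsets:
        for level, off in slope_offsets.items():
            slope[ov == level] += off
    y = intercept + slope * x + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame({predictor: x, response: y, "OV": ov})
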