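"""Colour conversion and the dorsal-colour / background-matching model suite.

Lizard dorsal colour, basking-site colour and whole-quadrat habitat colour are
recorded as calibrated RGB triples and analysed in HSL space: hue in degrees
(the colour angle), saturation and lightness in percent. Eight statistical
models relate dorsal colour and pattern to sex, parity mode, morphometrics and
background colour:

1. dorsal H/S/L ~ parity + sex + SVL + mass (least squares, one fit per channel)
2. dorsal pattern (binary) ~ parity + sex + SVL + mass (logistic)
3. dorsal H and L ~ pattern category (one-way ANOVA)
4. basking H/S/L ~ habitat H/S/L (per channel)
5. dorsal H and L ~ basking H/L (+ sex)
6. dorsal H ~ habitat H (+ sex)
7. dorsal pattern ~ basking colour (logistic)
8. dorsal pattern ~ habitat colour (logistic)

p-values are reported raw (two-sided); no multiple-testing adjustment is
applied anywhere in the suite.
"""

from __future__ import annotations

import colorsys
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class ColourHSL:
    """Hue (degrees, [0, 360)), saturation and lightness (percent, [0, 100]).

    For achromatic colours (s == 0) hue is undefined; it is stored as 0 with
    ``hue_defined`` False.
    """

    h: float
    s: float
    l: float
    hue_defined: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.h < 360.0:
            raise ValueError(f"hue must lie in [0, 360), got {self.h}")
        if not 0.0 <= self.s <= 100.0:
            raise ValueError(f"saturation must lie in [0, 100], got {self.s}")
        if not 0.0 <= self.l <= 100.0:
            raise ValueError(f"lightness must lie in [0, 100], got {self.l}")


def rgb_to_hsl(r: float, g: float, b: float) -> ColourHSL:
    """Convert 0-255 RGB channels to HSL (degrees / percent / percent)."""
    for name, v in (("r", r), ("g", g), ("b", b)):
        if not 0.0 <= v <= 255.0:
            raise ValueError(f"channel {name} must lie in [0, 255], got {v}")
    # colorsys works on unit-scaled channels and returns (h, l, s) in [0, 1]
    h, l, s = colorsys.rgb_to_hls(r / 255.0, g / 255.0, b / 255.0)
    achromatic = s == 0.0
    return ColourHSL(
        h=0.0 if achromatic else (h * 360.0) % 360.0,
        s=s * 100.0,
        l=l * 100.0,
        hue_defined=not achromatic,
    )


def hsl_to_rgb(colour: ColourHSL) -> tuple[float, float, float]:
    """Inverse of :func:`rgb_to_hsl`; returns 0-255 channels (not rounded)."""
    r, g, b = colorsys.hls_to_rgb(colour.h / 360.0, colour.l / 100.0, colour.s / 100.0)
    return r * 255.0, g * 255.0, b * 255.0


@dataclass
class LinearFit:
    """Coefficient table for a least-squares or logistic fit."""

    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    statistics: np.ndarray  # t for OLS, z for logistic
    p_values: np.ndarray
    df_resid: int
    n_obs: int
    r_squared: float | None = None  # least-squares fits only
    statistic_name: str = "t"
    warnings: list[str] = field(default_factory=list)

    def coefficient(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.coefficients,
                "se": self.standard_errors,
                self.statistic_name: self.statistics,
                "p": self.p_values,
            },
            index=self.terms,
        )


@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way ANOVA decomposition."""

    f_value: float
    df_between: int
    df_within: int
    p_value: float


def fit_ols(response: np.ndarray, design: pd.DataFrame | np.ndarray) -> LinearFit:
    """Ordinary least squares with per-coefficient t statistics and R².

    ``design`` must already include an intercept column.
    """
    y = np.asarray(response, dtype=float)
    X = pd.DataFrame(design)
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than design columns")
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {X.shape[1]} columns): "
            f"{list(X.columns)}"
        )
    res = sm.OLS(y, X).fit()
    return LinearFit(
        terms=[str(c) for c in X.columns],
        coefficients=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        statistics=np.asarray(res.tvalues),
        p_values=np.asarray(res.pvalues),
        df_resid=int(res.df_resid),
        n_obs=len(y),
        r_squared=float(res.rsquared),
        statistic_name="t",
    )


def fit_logistic(response: np.ndarray, design: pd.DataFrame | np.ndarray) -> LinearFit:
    """Binomial GLM (logit link) fitted by IRLS, with Wald z statistics."""
    y = np.asarray(response, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("logistic response must be binary 0/1")
    X = pd.DataFrame(design)
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than design columns")
    fit_warnings: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    if np.any(np.abs(res.params) > 15) or any(
        "separat" in str(w.message).lower() for w in caught
    ):
        fit_warnings.append(
            "possible complete separation: some coefficients are effectively infinite"
        )
    return LinearFit(
        terms=[str(c) for c in X.columns],
        coefficients=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        statistics=np.asarray(res.tvalues),
        p_values=np.asarray(res.pvalues),
        df_resid=int(res.df_resid),
        n_obs=len(y),
        r_squared=None,
        statistic_name="z",
        warnings=fit_warnings,
    )


def one_way_anova(values: Sequence[float], group_labels: Sequence) -> AnovaResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if len(values) <= len(groups):
        raise ValueError("total n must exceed the number of groups")
    f, p = stats.f_oneway(*groups)
    return AnovaResult(
        f_value=float(f),
        df_between=len(groups) - 1,
        df_within=len(values) - len(groups),
        p_value=float(p),
    )


# --- the model suite over lizard records ----------------------------------

_HUE_LINEAR_BOUNDS = (10.0, 300.0)  # outside this range the linear treatment is dubious


def _warn_if_hue_wraps(hues: np.ndarray, context: str) -> None:
    # Hue is treated as a linear variable; observed lizard/habitat hues sit far
    # from the 0/360 wrap. Warn if data drift toward the discontinuity.
    lo, hi = _HUE_LINEAR_BOUNDS
    if np.any((hues < lo) | (hues > hi)):
        warnings.warn(
            f"{context}: hue values near the 0/360 wrap entered a linear model; "
            "treating hue as linear may be inappropriate",
            stacklevel=3,
        )


def _records_frame(records: Iterable) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "sex": r.sex,
                "parity": r.parity,
                "svl_mm": r.svl_mm,
                "tl_mm": r.tl_mm,
                "mass_g": r.mass_g,
                "dorsal_h": r.dorsal_colour.h if r.dorsal_colour else np.nan,
                "dorsal_s": r.dorsal_colour.s if r.dorsal_colour else np.nan,
                "dorsal_l": r.dorsal_colour.l if r.dorsal_colour else np.nan,
                "basking_h": r.basking_colour.h if r.basking_colour else np.nan,
                "basking_s": r.basking_colour.s if r.basking_colour else np.nan,
                "basking_l": r.basking_colour.l if r.basking_colour else np.nan,
                "habitat_h": r.habitat_colour.h if r.habitat_colour else np.nan,
                "habitat_s": r.habitat_colour.s if r.habitat_colour else np.nan,
                "habitat_l": r.habitat_colour.l if r.habitat_colour else np.nan,
                "pattern_anterior": r.pattern_anterior,
                "pattern_posterior": r.pattern_posterior,
            }
        )
    return pd.DataFrame(rows)


def _pattern_binary(
    df: pd.DataFrame,
    region: Literal["anterior", "posterior"],
    coding: Literal["reticulated_vs_rest", "reticulated_vs_linear"],
) -> pd.Series:
    pat = df[f"pattern_{region}"]
    if coding == "reticulated_vs_rest":
        return (pat == "reticulated").astype(float)
    # reticulated vs linear; intermediates dropped (NaN)
    out = pd.Series(np.nan, index=df.index)
    out[pat == "reticulated"] = 1.0
    out[pat == "linear"] = 0.0
    return out


def run_paper_models(
    records: Iterable,
    pattern_region: Literal["anterior", "posterior"] = "anterior",
    pattern_coding: Literal[
        "reticulated_vs_rest", "reticulated_vs_linear"
    ] = "reticulated_vs_rest",
    include_sex_in_matching: bool = True,
) -> dict[str, object]:
    """Fit the eight-model colour/pattern suite on a set of lizard records.

    Records with parity ``admixed`` are excluded from every model. Rows missing
    a variable required by a given model are dropped for that model only; the
    per-model n is recorded on each fit. Returns a dict keyed by model id,
    e.g. ``"1_h"``, ``"2"``, ``"3_l"``, ``"4_s"``, ``"5_h"``, ``"6_h"``.
    """
    df = _records_frame(records)
    df = df[df["parity"] != "admixed"].copy()
    df["male"] = (df["sex"] == "male").astype(float)
    df["viviparous"] = (df["parity"] == "viviparous").astype(float)
    df["pattern_bin"] = _pattern_binary(df, pattern_region, pattern_coding)

    report: dict[str, object] = {}

    def _try(model_id: str, fn) -> None:
        try:
            report[model_id] = fn()
        except ValueError as exc:
            report[model_id] = {"skipped": str(exc)}

    def _design(sub: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
        X = sub[cols].copy()
        X.insert(0, "intercept", 1.0)
        return X

    # model 1: dorsal H, S, L ~ parity + sex + SVL + mass
    for channel in ("h", "s", "l"):
        sub = df.dropna(subset=[f"dorsal_{channel}", "svl_mm", "mass_g"])
        if channel == "h":
            _warn_if_hue_wraps(sub["dorsal_h"].to_numpy(), "model 1")
        _try(
            f"1_{channel}",
            lambda sub=sub, channel=channel: fit_ols(
                sub[f"dorsal_{channel}"].to_numpy(),
                _design(sub, ["viviparous", "male", "svl_mm", "mass_g"]),
            ),
        )

    # model 2: pattern ~ parity + sex + SVL + mass (logistic)
    sub2 = df.dropna(subset=["pattern_bin", "svl_mm", "mass_g"])
    _try(
        "2",
        lambda: fit_logistic(
            sub2["pattern_bin"].to_numpy(),
            _design(sub2, ["viviparous", "male", "svl_mm", "mass_g"]),
        ),
    )

    # model 3: dorsal H and L ~ pattern category (ANOVA over the 3 categories)
    for channel in ("h", "l"):
        sub = df.dropna(subset=[f"dorsal_{channel}", f"pattern_{pattern_region}"])
        _try(
            f"3_{channel}",
            lambda sub=sub, channel=channel: one_way_anova(
                sub[f"dorsal_{channel}"].to_numpy(),
                sub[f"pattern_{pattern_region}"].to_numpy(),
            ),
        )

    # model 4: basking HSL ~ habitat HSL, one fit per channel
    for channel in ("h", "s", "l"):
        sub = df.dropna(subset=[f"basking_{channel}", f"habitat_{channel}"])
        if channel == "h" and len(sub):
            _warn_if_hue_wraps(sub["habitat_h"].to_numpy(), "model 4")
        _try(
            f"4_{channel}",
            lambda sub=sub, channel=channel: fit_ols(
                sub[f"basking_{channel}"].to_numpy(),
                _design(sub, [f"habitat_{channel}"]),
            ),
        )

    matching_covs = ["male"] if include_sex_in_matching else []

    # model 5: dorsal H and L ~ basking H/L (+ sex)
    for channel in ("h", "l"):
        sub = df.dropna(subset=[f"dorsal_{channel}", f"basking_{channel}"])
        _try(
            f"5_{channel}",
            lambda sub=sub, channel=channel: fit_ols(
                sub[f"dorsal_{channel}"].to_numpy(),
                _design(sub, [f"basking_{channel}"] + matching_covs),
            ),
        )

    # model 6: dorsal H ~ habitat H (+ sex)
    sub6 = df.dropna(subset=["dorsal_h", "habitat_h"])
    _try(
        "6_h",
        lambda: fit_ols(
            sub6["dorsal_h"].to_numpy(),
            _design(sub6, ["habitat_h"] + matching_covs),
        ),
    )

    # models 7-8: pattern ~ basking / habitat colour (logistic)
    for model_id, prefix in (("7", "basking"), ("8", "habitat")):
        sub = df.dropna(subset=["pattern_bin", f"{prefix}_h", f"{prefix}_l"])
        _try(
            model_id,
            lambda sub=sub, prefix=prefix: fit_logistic(
                sub["pattern_bin"].to_numpy(),
                _design(sub, [f"{prefix}_h", f"{prefix}_l"]),
            ),
        )

    return report
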