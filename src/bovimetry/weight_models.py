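"""Body-weight prediction from image-derived traits.

Implements the classical allometric surface-area equations for cattle
(Elting's adult-cow and growing-heifer forms), the published linear
equations predicting BW from body surface area, volume and linear traits
of adult dairy cows, their refitted versions for growing heifers, and the
refitting machinery itself: ordinary least squares with optional
through-origin constraint and familywise backward elimination of
non-significant predictors.

Linear models declare the unit of every predictor; trait records arrive in
SI (m, m^2, m^3) and are converted on entry. Built-in coefficients are kept
as decimal strings so serialization round-trips them exactly as published.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .records import TraitRecord

_UNIT_FACTORS = {
    "m3": 1.0,
    "m2": 1.0,
    "m": 1.0,
    "cm": 100.0,
    "mm": 1000.0,
}


@dataclass
class WeightModel:
    """One named BW-prediction equation.

    form 'linear': bw = intercept + sum(coef * predictor). form
    'allometric': a BSA-from-BW power law, bsa = scale * bw**exponent,
    inverted exactly when predicting BW from BSA. ``units`` maps each
    predictor to the unit its coefficient expects; ``printed`` keeps the
    published decimal strings for exact serialization.
    """

    name: str
    form: str = "linear"
    intercept: float = 0.0
    terms: list = field(default_factory=list)  # [(predictor, coefficient)]
    units: dict = field(default_factory=dict)
    scale: float | None = None
    exponent: float | None = None
    printed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.form not in ("linear", "allometric"):
            raise ValueError(f"unknown model form {self.form!r}")
        names = [t[0] for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate predictors in model terms")
        valid = set(TraitRecord.TRAITS)
        for n in names:
            if n not in valid:
                raise ValueError(f"unknown predictor {n!r}")

    @property
    def predictors(self) -> list:
        return [t[0] for t in self.terms]

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "form": self.form,
            "units": dict(self.units),
        }
        if self.printed:
            d["intercept"] = self.printed.get("intercept", repr(self.intercept))
            d["terms"] = [
                [p, self.printed.get(p, repr(c))] for p, c in self.terms
            ]
            if self.scale is not None:
                d["scale"] = self.printed.get("scale", repr(self.scale))
                d["exponent"] = self.printed.get("exponent", repr(self.exponent))
        else:
            d["intercept"] = repr(self.intercept)
            d["terms"] = [[p, repr(c)] for p, c in self.terms]
            if self.scale is not None:
                d["scale"] = repr(self.scale)
                d["exponent"] = repr(self.exponent)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "WeightModel":
        printed = {"intercept": d["intercept"]}
        terms = []
        for p, c in d.get("terms", []):
            printed[p] = c
            terms.append((p, float(c)))
        kw = dict(
            name=d["name"],
            form=d["form"],
            intercept=float(d["intercept"]),
            terms=terms,
            units=dict(d.get("units", {})),
            printed=printed,
        )
        if "scale" in d:
            printed["scale"] = d["scale"]
            printed["exponent"] = d["exponent"]
            kw["scale"] = float(d["scale"])
            kw["exponent"] = float(d["exponent"])
        return cls(**kw)

    def dumps(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def loads(cls, s: str) -> "WeightModel":
        return cls.from_dict(json.loads(s))


def _model(name, intercept, terms, units, scale=None, exponent=None, form="linear"):
    printed = {"intercept": intercept}
    for p, c in terms:
        printed[p] = c
    if scale is not None:
        printed["scale"] = scale
        printed["exponent"] = exponent
    return WeightModel(
        name=name,
        form=form,
        intercept=float(intercept),
        terms=[(p, float(c)) for p, c in terms],
        units=units,
        scale=None if scale is None else float(scale),
        exponent=None if exponent is None else float(exponent),
        printed=printed,
    )


def builtin_models() -> list:
    """The eight published equations, coefficients exactly as printed.

    eq1/eq2: Elting's allometric BSA-from-BW laws (adult cows, growing
    heifers). eq3-eq5: adult-cow linear predictions of BW from BSA, from
    the full trait set, and from volume alone. eq6-eq8: the same three
    forms refitted on growing heifers. Note eq7's hip-width coefficient is
    only dimensionally plausible with HW in mm; the published unit is not
    stated, so the model declares mm while the other linear models declare
    SI units.
    """
    return [
        _model("eq1", "0", [], {}, scale="0.0839", exponent="0.67", form="allometric"),
        _model("eq2", "0", [], {}, scale="0.147", exponent="0.56", form="allometric"),
        _model("eq3", "-30.3", [("bsa", "102.3")], {"bsa": "m2"}),
        _model(
            "eq4",
            "-280.7",
            [
                ("volume", "812.1"),
                ("bsa", "-81.4"),
                ("kw", "343.8"),
                ("hw", "273.8"),
                ("hg", "208.8"),
                ("wh", "113.7"),
            ],
            {"volume": "m3", "bsa": "m2", "kw": "m", "hw": "m", "hg": "m", "wh": "m"},
        ),
        _model("eq5", "45.8", [("volume", "827.5")], {"volume": "m3"}),
        _model("eq6", "-259.3", [("bsa", "118.2")], {"bsa": "m2"}),
        _model(
            "eq7",
            "-91.3",
            [("volume", "728.8"), ("hw", "-0.36")],
            {"volume": "m3", "hw": "mm"},
        ),
        _model("eq8", "-34.4", [("volume", "922.3")], {"volume": "m3"}),
    ]


def get_model(name: str) -> WeightModel:
    for m in builtin_models():
        if m.name == name:
            return m
    raise KeyError(f"unknown model {name!r}")


def elting_bsa(bw: float, population: str = "adult") -> float:
    """Allometric body surface area (m^2) from body weight (kg)."""
    if bw <= 0:
        raise ValueError("body weight must be positive")
    if population == "adult":
        return 0.0839 * bw**0.67
    if population == "heifer":
        return 0.147 * bw**0.56
    raise ValueError("population must be 'adult' or 'heifer'")


def bw_from_bsa_elting(bsa: float, population: str = "adult") -> float:
    """Exact algebraic inversion of the allometric BSA laws."""
    if bsa <= 0:
        raise ValueError("surface area must be positive")
    if population == "adult":
        return (bsa / 0.0839) ** (1.0 / 0.67)
    if population == "heifer":
        return (bsa / 0.147) ** (1.0 / 0.56)
    raise ValueError("population must be 'adult' or 'heifer'")


def predict_bw(model: WeightModel, record: TraitRecord) -> float:
    """Predict body weight (kg) for one trait record.

    A missing predictor raises — a silent zero would poison herd means.
    Allometric models invert BSA to BW.
    """
    if model.form == "allometric":
        bsa = record.get("bsa")
        if bsa is None or not np.isfinite(bsa):
            raise ValueError(f"model {model.name}: record lacks bsa")
        pop = "heifer" if model.name == "eq2" else "adult"
        return bw_from_bsa_elting(bsa, pop)
    total = model.intercept
    for pred, coef in model.terms:
        v = record.get(pred)
        if v is None or not np.isfinite(v):
            raise ValueError(f"model {model.name}: record lacks predictor {pred!r}")
        total += coef * v * _UNIT_FACTORS[model.units.get(pred, "m")]
    return float(total)


@dataclass
class FitResult:
    model: WeightModel
    r2: float
    rmse: float
    n: int
    p_values: dict
    through_origin: bool
    dropped: list
    stderr: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.through_origin and not (-1e-9 <= self.r2 <= 1 + 1e-9):
            raise ValueError("R^2 out of [0, 1] for a model with intercept")
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")


def fit_weight_model(
    records: list,
    bw: list,
    predictors: list,
    through_origin: bool = False,
    prune_alpha: float = 0.0,
    name: str = "refit",
) -> FitResult:
    """Refit a linear BW equation by ordinary least squares.

    records/bw are parallel lists of TraitRecord and measured weight (kg).
    With ``through_origin`` the intercept is fixed at zero and R^2 is the
    uncentered form (about zero), the convention needed to compare forced
    and free fits. With ``prune_alpha`` > 0, predictors are removed by
    backward elimination on t-test p-values. The retention threshold is
    prune_alpha / (2m) for m candidate predictors: a Bonferroni correction
    over the candidates, with a further factor of two absorbing the downward
    bias that sequential refitting imparts to surviving p-values (simulation
    puts the familywise false-retention rate near prune_alpha under this
    rule). Dropped predictors are listed in elimination order.
    """
    predictors = list(predictors)
    y = np.asarray([float(b) for b in bw], dtype=float)
    n = len(y)
    if len(records) != n:
        raise ValueError("records and bw must have equal length")
    if n <= len(predictors) + 1:
        raise ValueError("need more observations than coefficients")
    cols = {}
    for p in predictors:
        col = np.array([r.get(p) if r.get(p) is not None else np.nan for r in records])
        if np.isnan(col).any():
            raise ValueError(f"predictor {p!r} missing in some records")
        cols[p] = col
    X = np.column_stack([cols[p] for p in predictors])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        worst = np.unravel_index(
            np.argmax(np.abs(corr - np.eye(len(predictors)))), corr.shape
        )
        raise ValueError(
            "rank-deficient design; most collinear pair: "
            f"{predictors[worst[0]]!r} / {predictors[worst[1]]!r}"
        )

    threshold = prune_alpha / (2 * max(len(predictors), 1)) if prune_alpha > 0 else None
    active = list(predictors)
    dropped = []
    while True:
        Xa = np.column_stack([cols[p] for p in active])
        design = Xa if through_origin else sm.add_constant(Xa)
        res = sm.OLS(y, design).fit()
        pv = res.pvalues if through_origin else res.pvalues[1:]
        if threshold is None or len(active) <= 1:
            break
        worst = int(np.argmax(pv))
        if pv[worst] > threshold:
            dropped.append(active.pop(worst))
        else:
            break
    coefs = res.params if through_origin else res.params[1:]
    intercept = 0.0 if through_origin else float(res.params[0])
    se = res.bse if through_origin else res.bse[1:]
    model = WeightModel(
        name=name,
        form="linear",
        intercept=intercept,
        terms=[(p, float(c)) for p, c in zip(active, coefs)],
        units={p: "m3" if p == "volume" else ("m2" if p == "bsa" else "m") for p in active},
    )
    resid = y - res.fittedvalues
    return FitResult(
        model=model,
        r2=float(res.rsquared),  # uncentered automatically when no constant
        rmse=float(np.sqrt(np.mean(resid**2))),
        n=n,
        p_values={p: float(v) for p, v in zip(active, pv)},
        through_origin=through_origin,
        dropped=dropped,
        stderr={p: float(s) for p, s in zip(active, se)},
    )


@dataclass
class ComparisonSummary:
    """Agreement between scale-measured and image-estimated weights."""

    mean_pct: float
    bias: float
    rmse: float
    pct: np.ndarray
    by_label: dict = field(default_factory=dict)


def compare_estimates(measured, estimated, labels=None) -> ComparisonSummary:
    """Mean percent difference (mean of per-pair percentages), bias, RMSE.

    Positive percentages mean the estimate overshoots the scale weight.
    Optional ``labels`` (e.g. age classes) add per-label mean percentages.
    """
    m = np.asarray(measured, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if m.shape != e.shape or m.size == 0:
        raise ValueError("measured and estimated must be equal-length, non-empty")
    if (m <= 0).any():
        raise ValueError("measured weights must be positive")
    pct = 100.0 * (e - m) / m
    by = {}
    if labels is not None:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            by[lab] = float(pct[labels == lab].mean())
    return ComparisonSummary(
        mean_pct=float(pct.mean()),
        bias=float((e - m).mean()),
        rmse=float(np.sqrt(np.mean((e - m) ** 2))),
        pct=pct,
        by_label=by,
    )
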