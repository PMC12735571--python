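"""Box-Behnken design generation, quadratic response-surface fitting and
composition optimization for release-modifier screening.

Three matrix-forming polymers (e.g. HPMC 100 cps, HPMC 4000 cps, NaCMC, as
percent w/w of tablet mass) are varied on a 3-level Box-Behnken design: the
12 edge midpoints of the factor cube plus replicated center points.  Each
release response (percent released at a sampling time) is fit with the full
second-order polynomial

    Y = b0 + sum_i bi*xi + sum_i bii*xi^2 + sum_{i<j} bij*xi*xj

by ordinary least squares in ACTUAL units; terms with per-coefficient
p >= alpha are pruned and the model refit on the retained terms.  A target
release profile (e.g. the reference product's) is then matched by minimizing
the summed squared deviation of the per-timepoint model predictions over the
factor box.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize

from .errors import (
    InvalidParameterError,
    OptimizationFailureError,
    SingularDesignError,
    UnsupportedDesignError,
)

__all__ = [
    "FactorSpec",
    "BoxBehnkenDesign",
    "QuadraticModel",
    "OptimizationTarget",
    "OptimizationResult",
    "generate_bbd",
    "fit_quadratic",
    "predict_response",
    "optimize_composition",
    "TERM_NAMES",
]

TERM_NAMES = ("intercept", "x1", "x2", "x3",
              "x1^2", "x2^2", "x3^2",
              "x1*x2", "x1*x3", "x2*x3")

#: default polymer-fraction box, percent w/w
DEFAULT_FACTOR_BOUNDS = (5.0, 40.0)

#: fixed total tablet mass used for the q.s. filler report, mg
TABLET_MASS_MG = 750.0


@dataclass(frozen=True)
class FactorSpec:
    """One design factor with its three levels in percent w/w."""

    name: str
    low: float
    high: float
    mid: float | None = None

    def __post_init__(self):
        mid = (self.low + self.high) / 2.0 if self.mid is None else self.mid
        object.__setattr__(self, "mid", mid)
        if not self.low < self.mid < self.high:
            raise InvalidParameterError(f"{self.name}: need low < mid < high")
        if abs(self.mid - (self.low + self.high) / 2.0) > 1e-9:
            raise InvalidParameterError(
                f"{self.name}: Box-Behnken requires mid = (low+high)/2")

    def decode(self, coded):
        """Coded level (-1/0/+1) -> actual percent w/w."""
        return self.mid + np.asarray(coded, dtype=float) * (self.high - self.low) / 2.0


@dataclass
class BoxBehnkenDesign:
    factors: tuple[FactorSpec, FactorSpec, FactorSpec]
    coded: np.ndarray  # (n_runs, 3) in {-1, 0, +1}
    actual: np.ndarray  # (n_runs, 3) percent w/w
    n_center: int

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    def to_frame(self) -> pd.DataFrame:
        names = [f.name for f in self.factors]
        df = pd.DataFrame(self.actual, columns=[f"{n}_pct" for n in names])
        for k, n in enumerate(names):
            df[f"{n}_coded"] = self.coded[:, k]
        df.insert(0, "run_id", np.arange(1, self.n_runs + 1))
        # lactose q.s. filler to constant tablet mass (reported, not a factor)
        df["lactose_qs_pct"] = 100.0 - self.actual.sum(axis=1)
        df["lactose_qs_mg"] = df["lactose_qs_pct"] / 100.0 * TABLET_MASS_MG
        return df


@dataclass
class QuadraticModel:
    """Fitted (or literature-supplied) quadratic response surface.

    ``coefficients`` maps retained term names to actual-unit coefficients;
    ``p_values`` are from the full 10-term fit (empty for literature models).
    """

    response_name: str
    coefficients: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    r2: float = float("nan")
    adj_r2: float = float("nan")
    retained_terms: tuple[str, ...] = ()
    factor_names: tuple[str, str, str] = ("x1", "x2", "x3")
    bounds: tuple[tuple[float, float], ...] = ()
    diagnostics: dict = field(default_factory=dict)

    @classmethod
    def from_coefficients(cls, response_name: str, coefficients: dict[str, float],
                          factor_names=("x1", "x2", "x3")) -> "QuadraticModel":
        """Build a model directly from published coefficient values."""
        unknown = set(coefficients) - set(TERM_NAMES)
        if unknown:
            raise InvalidParameterError(f"unknown terms: {sorted(unknown)}")
        retained = tuple(t for t in TERM_NAMES if t in coefficients and t != "intercept")
        return cls(response_name=response_name, coefficients=dict(coefficients),
                   retained_terms=retained, factor_names=tuple(factor_names))


@dataclass(frozen=True)
class OptimizationTarget:
    timepoints: tuple[float, ...]
    target_release: tuple[float, ...]
    bounds: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.timepoints) != len(self.target_release):
            raise InvalidParameterError("timepoints and targets must align")
        if any(not 0 <= v <= 100 for v in self.target_release):
            raise InvalidParameterError("targets must lie in [0, 100]")
        for lo, hi in self.bounds:
            if lo > hi:
                raise InvalidParameterError("bound lower > upper")


@dataclass
class OptimizationResult:
    composition: np.ndarray
    predictions: dict[float, float]
    objective: float


# ----------------------------------------------------------------------------
# Design generation
# ----------------------------------------------------------------------------

# the 12 edge-midpoint runs of the 3-factor BBD, in deterministic order
_BBD_EDGE_RUNS = np.array(
    [[s1, s2, 0] for s1 in (-1, 1) for s2 in (-1, 1)]
    + [[s1, 0, s3] for s1 in (-1, 1) for s3 in (-1, 1)]
    + [[0, s2, s3] for s2 in (-1, 1) for s3 in (-1, 1)],
    dtype=float,
)


def generate_bbd(factors, n_center: int = 5) -> BoxBehnkenDesign:
    """3-factor, 3-level Box-Behnken design.

    Returns the 12 edge runs in deterministic order followed by ``n_center``
    center replicates, in both coded (-1/0/+1) and actual units.  With the
    conventional 5 center replicates the design has 17 runs.
    """
    factors = tuple(factors)
    if len(factors) != 3:
        raise UnsupportedDesignError("only the 3-factor Box-Behnken design is supported")
    if n_center < 1:
        raise InvalidParameterError("n_center must be >= 1")
    coded = np.vstack([_BBD_EDGE_RUNS, np.zeros((n_center, 3))])
    actual = np.column_stack([f.decode(coded[:, k]) for k, f in enumerate(factors)])
    return BoxBehnkenDesign(factors=factors, coded=coded, actual=actual,
                            n_center=n_center)


# ----------------------------------------------------------------------------
# Quadratic fit
# ----------------------------------------------------------------------------

def quadratic_design_matrix(x: np.ndarray) -> np.ndarray:
    """Full 10-term second-order model matrix for 3 factors (actual units)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x1, x2, x3 = x[:, 0], x[:, 1], x[:, 2]
    return np.column_stack([
        np.ones_like(x1), x1, x2, x3,
        x1 ** 2, x2 ** 2, x3 ** 2,
        x1 * x2, x1 * x3, x2 * x3,
    ])


def fit_quadratic(design: BoxBehnkenDesign, response, alpha: float = 0.05,
                  response_name: str = "Y") -> QuadraticModel:
    """OLS fit of the full quadratic followed by per-term significance pruning.

    Coefficients are estimated in actual percent-w/w units.  Terms with
    p < alpha are retained (the intercept always is) and the model is refit on
    the retained subset, which is the model used for prediction.  Center-point
    pure-error variance is reported in diagnostics when replicates exist.
    """
    y = np.asarray(response, dtype=float)
    if y.shape != (design.n_runs,):
        raise InvalidParameterError("need exactly one response value per run")
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must lie in (0, 1)")

    X = quadratic_design_matrix(design.actual)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("rank-deficient quadratic design matrix")

    full = sm.OLS(y, X).fit()
    p_values = dict(zip(TERM_NAMES, full.pvalues))

    retained = tuple(t for t, p in p_values.items() if t != "intercept" and p < alpha)
    cols = [0] + [TERM_NAMES.index(t) for t in retained]
    sub = sm.OLS(y, X[:, cols]).fit()
    coefficients = dict(zip(["intercept", *retained], sub.params))

    diagnostics = {"full_r2": float(full.rsquared), "n_runs": design.n_runs}
    center_mask = np.all(design.coded == 0, axis=1)
    if center_mask.sum() >= 2:
        diagnostics["pure_error_variance"] = float(np.var(y[center_mask], ddof=1))
        diagnostics["n_center"] = int(center_mask.sum())

    return QuadraticModel(
        response_name=response_name,
        coefficients=coefficients,
        p_values=p_values,
        r2=float(full.rsquared),
        adj_r2=float(full.rsquared_adj),
        retained_terms=retained,
        factor_names=tuple(f.name for f in design.factors),
        bounds=tuple((f.low, f.high) for f in design.factors),
        diagnostics=diagnostics,
    )


def predict_response(model: QuadraticModel, composition) -> float:
    """Evaluate the retained-term polynomial at an actual-unit composition."""
    x = np.asarray(composition, dtype=float)
    if x.shape != (3,) or not np.all(np.isfinite(x)):
        raise InvalidParameterError("composition must be 3 finite actual-unit values")
    if model.bounds:
        for v, (lo, hi) in zip(x, model.bounds):
            if not lo <= v <= hi:
                warnings.warn(
                    f"{model.response_name}: composition {x.tolist()} outside "
                    f"fitted factor bounds; extrapolating", stacklevel=2)
                break
    row = quadratic_design_matrix(x)[0]
    terms = dict(zip(TERM_NAMES, row))
    return float(sum(coef * terms[name] for name, coef in model.coefficients.items()))


# ----------------------------------------------------------------------------
# Composition optimization against a target release profile
# ----------------------------------------------------------------------------

def optimize_composition(models: dict[float, QuadraticModel],
                         target: OptimizationTarget,
                         n_grid: int = 3) -> OptimizationResult:
    """Find the composition whose predicted release best matches the target.

    Minimizes sum_t (prediction_t - target_t)^2 over the factor box with
    L-BFGS-B from a deterministic grid of starts (n_grid levels per factor).
    """
    if len(models) < 2:
        raise InvalidParameterError("need models for >= 2 timepoints")
    missing = [t for t in target.timepoints if t not in models]
    if missing:
        raise InvalidParameterError(f"no model for timepoints {missing}")
    bounds = target.bounds
    if len(bounds) != 3:
        raise InvalidParameterError("need bounds for all 3 factors")

    tps = list(target.timepoints)
    tgt = np.asarray(target.target_release, dtype=float)

    def objective(x):
        pred = np.array([predict_response(models[t], x) for t in tps])
        return float(np.sum((pred - tgt) ** 2))

    axes = [np.linspace(lo, hi, n_grid) for lo, hi in bounds]
    starts = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T

    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # extrapolation warnings during search
        for x0 in starts:
            try:
                sol = minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
            except Exception:
                continue
            if best is None or sol.fun < best.fun:
                best = sol
        if best is None:
            raise OptimizationFailureError("all optimization starts failed")
        x = np.clip(best.x, [b[0] for b in bounds], [b[1] for b in bounds])
        predictions = {t: predict_response(models[t], x) for t in tps}
    return OptimizationResult(composition=x, predictions=predictions,
                              objective=float(best.fun))
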