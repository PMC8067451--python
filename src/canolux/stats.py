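"""Species × PPFD regression analysis and response-curve fitting.

The central analysis is an ANCOVA-style ordinary least squares model for
each trait: PPFD enters as a continuous predictor and species as a two-level
class variable (dummy-coded, lettuce = 0 by default).  The model is first
fitted with the species × PPFD interaction; when the interaction is not
significant at ``alpha`` it is removed and the additive model is reported.
When the interaction is retained, per-species slopes come from the
interaction model.

Univariate PPFD-response curves (linear, quadratic, exponential rise to a
maximum, sigmoidal) and the early-PCS vs final-dry-weight Pearson
correlation round out the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats as sps

from .growth import sigmoid

__all__ = [
    "RegressionSpec",
    "RegressionResult",
    "CurveFitResult",
    "fit_species_ppfd_model",
    "fit_response_curve",
    "early_pcs_correlation",
]


@dataclass(frozen=True)
class RegressionSpec:
    """What to regress and how strictly to prune the interaction."""

    response: str
    alpha: float = 0.05
    reference_species: str = "lettuce"
    include_block: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class RegressionResult:
    """Fitted species × PPFD model for one response.

    ``coefficients``/``p_values`` hold the reported model's terms:
    ``intercept``, ``ppfd``, ``species`` and — only when retained —
    ``interaction``.  The species coefficient is the offset of the
    non-reference species.
    """

    response: str
    coefficients: dict[str, float]
    p_values: dict[str, float]
    interaction_dropped: bool
    r_squared: float
    n: int
    reference_species: str
    other_species: str

    def slope_for(self, species: str) -> float:
        """PPFD slope for one species under the reported model."""
        slope = self.coefficients["ppfd"]
        if not self.interaction_dropped and species == self.other_species:
            slope += self.coefficients["interaction"]
        elif species not in (self.reference_species, self.other_species):
            raise KeyError(f"unknown species {species!r}")
        return slope


def _design(ppfd: np.ndarray, dummy: np.ndarray, block: np.ndarray | None,
            interaction: bool) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(ppfd), ppfd, dummy]
    names = ["intercept", "ppfd", "species"]
    if interaction:
        cols.append(ppfd * dummy)
        names.append("interaction")
    if block is not None:
        # block as fixed covariate: one dummy per non-reference level
        levels = np.unique(block)
        for lev in levels[1:]:
            cols.append((block == lev).astype(float))
            names.append(f"block_{lev}")
    return np.column_stack(cols), names


def fit_species_ppfd_model(
    data: pd.DataFrame, spec: RegressionSpec
) -> RegressionResult:
    """OLS of a trait on PPFD (continuous) and species (class variable).

    Fits the full model with the species × PPFD interaction; if the
    interaction p-value is ≥ ``spec.alpha`` the model is refitted without it
    and ``interaction_dropped`` is set.  A response with zero variance is a
    legal degenerate case: all slopes are 0 and r² = 0.

    ``data`` needs columns ``species``, ``ppfd`` and ``spec.response``
    (plus ``block`` when ``spec.include_block``).
    """
    df = data.dropna(subset=[spec.response, "species", "ppfd"])
    species_levels = sorted(df["species"].unique())
    if len(species_levels) != 2:
        raise ValueError(
            f"need exactly 2 species levels, got {species_levels}"
        )
    if spec.reference_species not in species_levels:
        raise ValueError(
            f"reference species {spec.reference_species!r} not in data"
        )
    other = next(s for s in species_levels if s != spec.reference_species)
    if df.groupby("species")["ppfd"].nunique().min() < 3:
        raise ValueError("need >= 3 PPFD levels per species")

    y = df[spec.response].to_numpy(dtype=float)
    ppfd = df["ppfd"].to_numpy(dtype=float)
    dummy = (df["species"] == other).to_numpy(dtype=float)
    block = df["block"].to_numpy() if spec.include_block else None

    if float(np.var(y)) == 0.0:
        names = ["intercept", "ppfd", "species"]
        coefs = dict(zip(names, [float(y[0]), 0.0, 0.0]))
        pvals = dict(zip(names, [0.0, 1.0, 1.0]))
        return RegressionResult(
            response=spec.response, coefficients=coefs, p_values=pvals,
            interaction_dropped=True, r_squared=0.0, n=len(y),
            reference_species=spec.reference_species, other_species=other,
        )

    X_full, names_full = _design(ppfd, dummy, block, interaction=True)
    full = sm.OLS(y, X_full).fit()
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("rank-deficient design matrix")
    i_inter = names_full.index("interaction")
    p_inter = float(full.pvalues[i_inter])
    if np.isnan(p_inter) or float(full.rsquared) > 1.0 - 1e-12:
        # Perfect (zero-residual) fit: the t statistic is degenerate.  Judge
        # the interaction by its coefficient instead — numerically zero
        # means the data are exactly additive.
        coef = float(full.params[i_inter])
        scale = max(abs(float(full.params[names_full.index("ppfd")])), 1e-30)
        p_inter = 1.0 if abs(coef) < 1e-8 * scale else 0.0

    if p_inter >= spec.alpha:
        X_red, names = _design(ppfd, dummy, block, interaction=False)
        model = sm.OLS(y, X_red).fit()
        dropped = True
    else:
        model, names = full, names_full
        dropped = False

    coefs = {nm: float(v) for nm, v in zip(names, model.params)}
    pvals = {nm: float(v) for nm, v in zip(names, model.pvalues)}
    return RegressionResult(
        response=spec.response,
        coefficients=coefs,
        p_values=pvals,
        interaction_dropped=dropped,
        r_squared=float(model.rsquared),
        n=len(y),
        reference_species=spec.reference_species,
        other_species=other,
    )


@dataclass(frozen=True)
class CurveFitResult:
    """A fitted univariate PPFD-response curve."""

    form: str
    parameters: dict[str, float]
    r_squared: float
    converged: bool

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.parameters
        if self.form == "linear":
            return p["intercept"] + p["slope"] * x
        if self.form == "quadratic":
            return p["c0"] + p["c1"] * x + p["c2"] * x**2
        if self.form == "exponential_rise":
            return p["A"] * (1.0 - np.exp(-p["k"] * x))
        if self.form == "sigmoid":
            return sigmoid(x, p["a"], p["x0"], p["b"])
        raise ValueError(f"unknown form {self.form!r}")


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return 1.0 if np.allclose(y, yhat) else 0.0
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def fit_response_curve(x, y, form: str = "linear",
                       max_restarts: int = 5, seed: int = 0) -> CurveFitResult:
    """Least-squares fit of a named response form to (x, y) data.

    Forms: ``linear``, ``quadratic`` (polynomial least squares, closed
    form), ``exponential_rise`` (y = A·(1 − exp(−k·x)), A the fitted
    plateau), ``sigmoid`` (three-parameter logistic).  Nonlinear forms use
    bounded least squares with jittered restarts; the ``converged`` flag is
    honest.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_params = {"linear": 2, "quadratic": 3, "exponential_rise": 2, "sigmoid": 3}
    if form not in n_params:
        raise ValueError(f"unknown form {form!r}")
    # exact interpolation (n == n_params) is allowed: a two-point linear
    # "fit" is the slope between printed endpoints, with r² = 1
    if x.size < n_params[form]:
        raise ValueError(
            f"{form} fit needs >= {n_params[form]} points, got {x.size}"
        )

    if form == "linear":
        c1, c0 = np.polyfit(x, y, 1)
        params = {"intercept": float(c0), "slope": float(c1)}
        res = CurveFitResult(form, params, 0.0, True)
        return CurveFitResult(form, params, _r2(y, res.predict(x)), True)
    if form == "quadratic":
        c2, c1, c0 = np.polyfit(x, y, 2)
        params = {"c0": float(c0), "c1": float(c1), "c2": float(c2)}
        res = CurveFitResult(form, params, 0.0, True)
        return CurveFitResult(form, params, _r2(y, res.predict(x)), True)

    rng = np.random.default_rng(seed)
    if form == "exponential_rise":
        func = lambda xx, A, k: A * (1.0 - np.exp(-k * xx))
        p0 = [max(float(y.max()), 1e-6), 1.0 / max(float(x.mean()), 1e-6)]
        bounds = ([1e-12, 1e-9], [np.inf, np.inf])
        pnames = ["A", "k"]
    else:  # sigmoid
        func = sigmoid
        p0 = [1.05 * float(y.max()), float(x[np.argmin(np.abs(y - y.max() / 2))]),
              (float(x.max()) - float(x.min())) / 6.0]
        bounds = ([1e-12, -np.inf, 1e-6], [np.inf, np.inf, np.inf])
        pnames = ["a", "x0", "b"]

    last_err = None
    for attempt in range(max_restarts + 1):
        start = p0 if attempt == 0 else [
            max(p * j, lo * 1.001 if np.isfinite(lo) else p * j)
            for p, j, lo in zip(p0, rng.normal(1.0, 0.2, len(p0)), bounds[0])
        ]
        try:
            popt, _ = optimize.curve_fit(func, x, y, p0=start, bounds=bounds,
                                         maxfev=20000)
        except (RuntimeError, ValueError) as err:
            last_err = err
            continue
        params = dict(zip(pnames, map(float, popt)))
        res = CurveFitResult(form, params, 0.0, True)
        return CurveFitResult(form, params, _r2(y, res.predict(x)), True)
    raise RuntimeError(
        f"{form} fit failed after {max_restarts + 1} starts: {last_err}"
    )


def early_pcs_correlation(early_pcs, final_dw) -> tuple[float, float]:
    """Pearson correlation between early PCS and final dry weight.

    Applied across the experimental units of one species (e.g. the 18 units
    of 6 PPFDs × 3 blocks), with early PCS taken 8–10 days after seeding.
    Returns (R, p).
    """
    early_pcs = np.asarray(early_pcs, dtype=float)
    final_dw = np.asarray(final_dw, dtype=float)
    if early_pcs.size != final_dw.size:
        raise ValueError("paired vectors must have equal length")
    if early_pcs.size < 3:
        raise ValueError("need >= 3 paired observations")
    if float(np.std(early_pcs)) == 0 or float(np.std(final_dw)) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = sps.pearsonr(early_pcs, final_dw)
    return float(r), float(p)
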