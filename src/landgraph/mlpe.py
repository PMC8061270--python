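"""Distance-matrix regression with MLPE pair-dependence covariance.

Rows of a pairwise-distance table are not independent: two locale pairs that
share a locale are correlated.  The maximum-likelihood-population-effects
(MLPE) structure models the m×m response covariance as

    V[r, s] = σ² · ( 1{r = s} + ρ · 1{pairs r and s share exactly one locale} )

which is the marginal covariance of a Gaussian model with a random effect
per locale entering both of its pairs.  Writing B for the m×k pair–locale
incidence matrix, the sharing indicator is A = BBᵀ − 2I (the line graph of
the complete locale graph), whose smallest eigenvalue is −2; positive
definiteness therefore bounds ρ < 0.5 — exactly the correlation range of the
random-locale-effect parameterization (ρ = σ_u²/(2σ_u² + σ_e²)).

Fitting maximizes the Gaussian likelihood (ML, not REML, so AIC comparisons
across fixed-effect structures are valid), profiling β and σ² analytically
and optimizing the scalar ρ.  ρ = 0 collapses to ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .core import DegenerateInputError, PairwiseMatrix

__all__ = [
    "PairTable",
    "build_pair_table",
    "MLPEFit",
    "fit_mlpe",
    "compare_models_aic",
    "simulate_pair_response",
]

RHO_MAX = 0.4999  # PD bound: λmin(A) = −2 ⇒ ρ < 0.5


@dataclass
class PairTable:
    """One row per unordered locale pair: response plus standardized predictors.

    ``scaling`` maps predictor name → (mean, std) used for the z-score, so
    coefficients can be back-transformed to natural units.
    """

    data: pd.DataFrame
    response: str
    predictors: list[str]
    scaling: dict[str, tuple[float, float]]

    @property
    def n_pairs(self) -> int:
        return len(self.data)

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def build_pair_table(
    genetic: PairwiseMatrix,
    geo: PairwiseMatrix,
    layer_summaries: dict[str, pd.DataFrame] | None = None,
    response_name: str = "genetic_distance",
) -> PairTable:
    """Assemble the aligned pair table from matrices and per-edge summaries.

    ``layer_summaries`` maps a layer name to a per-pair DataFrame as produced
    by :func:`landgraph.landscape.edge_resistance_summary` covering *all*
    locale pairs; its ``mean`` and ``variance`` columns become predictors
    ``<layer>_mean`` / ``<layer>_variance``.  All inputs must share the
    locale set.  Predictors are z-scored; constant predictors are dropped
    with a warning.  Rows with a missing response are disallowed.
    """
    ids = genetic.ids
    if set(geo.ids) != set(ids):
        raise ValueError("geographic matrix covers a different locale set")
    pairs = genetic.pairs()
    rows = {
        "locale_a": [a for a, _ in pairs],
        "locale_b": [b for _, b in pairs],
        response_name: [genetic.get(a, b) for a, b in pairs],
        "geographic_distance": [geo.get(a, b) for a, b in pairs],
    }
    predictors = ["geographic_distance"]
    if layer_summaries:
        for name, df in layer_summaries.items():
            lut = {
                tuple(sorted((str(r["locale_a"]), str(r["locale_b"])))): r
                for _, r in df.iterrows()
            }
            missing = [p for p in pairs if tuple(sorted(p)) not in lut]
            if missing:
                raise ValueError(
                    f"layer {name!r} lacks summaries for pairs {missing[:3]} ..."
                )
            for stat in ("mean", "variance"):
                col = f"{name}_{stat}"
                rows[col] = [
                    float(lut[tuple(sorted(p))][stat]) for p in pairs
                ]
                predictors.append(col)
    df = pd.DataFrame(rows)
    if df[response_name].isna().any():
        raise ValueError("missing response values in pair table")
    scaling: dict[str, tuple[float, float]] = {}
    kept: list[str] = []
    for colname in predictors:
        mu = float(df[colname].mean())
        sd = float(df[colname].std(ddof=0))
        if sd == 0.0 or not np.isfinite(sd):
            warnings.warn(f"predictor {colname!r} is constant; dropped")
            df = df.drop(columns=colname)
            continue
        df[colname] = (df[colname] - mu) / sd
        scaling[colname] = (mu, sd)
        kept.append(colname)
    return PairTable(data=df, response=response_name, predictors=kept, scaling=scaling)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class MLPEFit:
    """Maximum-likelihood MLPE fit summary.

    ``coefficients`` are on the standardized predictor scale (index
    ``intercept`` plus predictor names); ``aic = 2k − 2·loglik`` with k
    counting coefficients, ρ, and σ².  ``pseudo_r2`` is the squared Pearson
    correlation of fitted vs observed responses.
    """

    coefficients: pd.Series
    rho: float
    sigma2: float
    loglik: float
    aic: float
    pseudo_r2: float
    predictors: list[str]
    n_pairs: int
    converged: bool
    response_key: tuple = field(default=(), repr=False)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": list(self.coefficients)
                + [self.rho, self.sigma2, self.loglik, self.aic, self.pseudo_r2]
            },
            index=list(self.coefficients.index)
            + ["rho", "sigma2", "loglik", "aic", "pseudo_r2"],
        )


def _incidence_basis(pairs: list[tuple[str, str]]):
    """Orthonormal basis U and eigenvalues s² of BBᵀ for the pair set."""
    locales = sorted({x for p in pairs for x in p})
    index = {v: i for i, v in enumerate(locales)}
    B = np.zeros((len(pairs), len(locales)))
    for r, (a, b) in enumerate(pairs):
        B[r, index[a]] = 1.0
        B[r, index[b]] = 1.0
    U, s, _ = np.linalg.svd(B, full_matrices=False)
    keep = s > 1e-10
    return U[:, keep], s[keep] ** 2


def _profile(rho: float, X, y, U, s2, XtX, Xty, yty, Ux, Uy):
    """Profile negative log-likelihood and the implied (β, σ²) at fixed ρ."""
    m = y.size
    c = 1.0 - 2.0 * rho  # eigenvalue weight off the incidence column space
    d = c + rho * s2  # weights inside the column space
    win = 1.0 / d
    w0 = 1.0 / c
    A_x = w0 * (XtX - Ux.T @ Ux) + Ux.T @ (win[:, None] * Ux)
    b_x = w0 * (Xty - Ux.T @ Uy) + Ux.T @ (win * Uy)
    beta = np.linalg.solve(A_x, b_x)
    resid = y - X @ beta
    Ur = Uy - Ux @ beta
    quad = w0 * (resid @ resid - Ur @ Ur) + Ur @ (win * Ur)
    sigma2 = quad / m
    logdet = np.sum(np.log(d)) + (m - s2.size) * np.log(c)
    nll = 0.5 * (m * np.log(2 * np.pi * sigma2) + logdet + m)
    return nll, beta, sigma2


def fit_mlpe(
    table: PairTable,
    predictors: list[str] | None = None,
    rho: float | None = None,
) -> MLPEFit:
    """Fit the MLPE regression by maximum likelihood.

    Parameters
    ----------
    table
        Pair table with standardized predictors.
    predictors
        Subset of ``table.predictors`` to include (all by default).
    rho
        Fix the pair-dependence correlation instead of estimating it
        (``rho=0`` reproduces ordinary least squares).
    """
    predictors = table.predictors if predictors is None else list(predictors)
    unknown = [p for p in predictors if p not in table.data.columns]
    if unknown:
        raise KeyError(f"unknown predictors {unknown}")
    df = table.data
    m = len(df)
    if m < len(predictors) + 3:
        raise DegenerateInputError("too few pairs for the requested model")
    y = df[table.response].to_numpy(float)
    X = np.column_stack(
        [np.ones(m)] + [df[p].to_numpy(float) for p in predictors]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateInputError("singular design matrix")
    pairs = list(zip(df["locale_a"].astype(str), df["locale_b"].astype(str)))
    U, s2 = _incidence_basis(pairs)
    XtX, Xty, yty = X.T @ X, X.T @ y, y @ y
    Ux, Uy = U.T @ X, U.T @ y

    args = (X, y, U, s2, XtX, Xty, yty, Ux, Uy)
    if rho is not None:
        if not (0.0 <= rho < 0.5):
            raise ValueError("rho must lie in [0, 0.5)")
        best_rho, converged = float(rho), True
    else:
        opt = minimize_scalar(
            lambda r: _profile(r, *args)[0],
            bounds=(0.0, RHO_MAX),
            method="bounded",
            options={"xatol": 1e-8},
        )
        best_rho, converged = float(opt.x), bool(opt.success)
        # the optimum may sit at the ρ=0 boundary; check it explicitly
        if _profile(0.0, *args)[0] <= opt.fun:
            best_rho = 0.0
    nll, beta, sigma2 = _profile(best_rho, *args)
    fitted = X @ beta
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(fitted, y)[0, 1]
    pseudo_r2 = float(r**2) if np.isfinite(r) else 0.0
    k_params = len(beta) + 2  # coefficients + ρ + σ²
    loglik = -nll
    return MLPEFit(
        coefficients=pd.Series(beta, index=["intercept"] + predictors),
        rho=best_rho,
        sigma2=float(sigma2),
        loglik=float(loglik),
        aic=float(2 * k_params - 2 * loglik),
        pseudo_r2=pseudo_r2,
        predictors=predictors,
        n_pairs=m,
        converged=converged,
        response_key=(m, float(np.round(yty, 10))),
    )


def compare_models_aic(fits: list[MLPEFit]) -> pd.DataFrame:
    """Rank fits by AIC (ascending) with ΔAIC from the best.

    All fits must have been computed on the same response rows.
    """
    if not fits:
        raise ValueError("no fits to compare")
    keys = {f.response_key for f in fits}
    if len(keys) > 1:
        raise ValueError("fits were computed on different response rows")
    rows = [
        {
            "model": "+".join(f.predictors) or "intercept",
            "k": len(f.coefficients) + 2,
            "loglik": f.loglik,
            "aic": f.aic,
            "rho": f.rho,
            "pseudo_r2": f.pseudo_r2,
        }
        for f in fits
    ]
    out = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out["aic"].iloc[0]
    return out


# ---------------------------------------------------------------------------
# simulation utility (ground truth for calibration)
# ---------------------------------------------------------------------------


def simulate_pair_response(
    n_locales: int,
    beta: dict[str, float],
    rho: float,
    sigma: float,
    seed: int,
    intercept: float = 0.0,
) -> PairTable:
    """Pair table with known slope/ρ/σ for parameter-recovery checks.

    Predictors named in ``beta`` are drawn i.i.d. standard normal per pair;
    the response is ``intercept + Σ βx + ε`` with ε drawn from the MLPE
    covariance σ²(I + ρA).
    """
    if not (0.0 <= rho < 0.5):
        raise ValueError("rho must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    ids = [f"L{i:02d}" for i in range(n_locales)]
    pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
    m = len(pairs)
    X = {name: rng.normal(size=m) for name in beta}
    U, s2 = _incidence_basis(pairs)
    z = rng.normal(size=m)
    c = 1.0 - 2.0 * rho
    d = c + rho * s2
    # ε = σ·M z with M² = (I − UUᵀ)c + U diag(d) Uᵀ
    Uz = U.T @ z
    eps = sigma * (np.sqrt(c) * z + U @ ((np.sqrt(d) - np.sqrt(c)) * Uz))
    y = intercept + sum(b * X[name] for name, b in beta.items()) + eps
    df = pd.DataFrame(
        {
            "locale_a": [a for a, _ in pairs],
            "locale_b": [b for _, b in pairs],
            "response": y,
            **X,
        }
    )
    scaling = {name: (0.0, 1.0) for name in beta}
    return PairTable(
        data=df, response="response", predictors=list(beta), scaling=scaling
    )
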