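"""Generalized dissimilarity modelling.

A GDM regresses pairwise dissimilarities ``d in [0,1)`` on monotone I-spline
transforms of predictors through a negative-exponential link:

    mu = 1 - exp(-eta),   eta = alpha + sum_p sum_k beta_pk * x_pk

with ``alpha, beta >= 0`` so every fitted response curve is non-decreasing.
Geographic distance enters as a pair-level predictor (the spline is evaluated
at the pair's distance); environmental predictors enter per endpoint, the
pair contribution being ``|f(x_i) - f(x_j)|`` per basis function. The fit
minimizes the binomial deviance; deviance explained is
``100 * (1 - D_model / D_null)`` against the intercept-only model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize

from .popgen import DistanceMatrix, geo_distance

__all__ = [
    "ISplineBasis",
    "SitePairTable",
    "GDMModel",
    "build_pair_table",
    "ispline_transform",
    "design_matrix",
    "fit_gdm",
    "predict_gdm",
    "deviance_explained",
    "binomial_deviance",
]

GEO = "geo"
_MU_EPS = 1e-9


@dataclass
class ISplineBasis:
    """Monotone I-spline basis for one predictor.

    Knots default to the 0/50/100th percentiles of the predictor's values;
    basis functions are tail-sums of B-splines of degree ``order`` on the
    clamped knot vector, which makes each function 0 at the first knot, 1 at
    the last and non-decreasing in between. ``n_basis = n_knots + order - 2``.
    A degenerate predictor (all values equal) yields a basis flagged
    ``constant`` that must be excluded from fitting.
    """

    name: str
    knots: np.ndarray
    order: int = 2

    def __post_init__(self):
        self.knots = np.unique(np.asarray(self.knots, dtype=float))
        self.constant = len(self.knots) < 2

    @classmethod
    def from_values(cls, name: str, values: np.ndarray, n_knots: int = 3,
                    order: int = 2) -> "ISplineBasis":
        qs = np.linspace(0, 100, n_knots)
        knots = np.percentile(np.asarray(values, dtype=float), qs)
        return cls(name, knots, order)

    @property
    def n_basis(self) -> int:
        if self.constant:
            return 0
        return len(self.knots) + self.order - 2

    def evaluate(self, x) -> np.ndarray:
        """Basis-function values, shape ``(len(x), n_basis)``; input clamped
        to the knot range."""
        if self.constant:
            raise ValueError(f"basis for {self.name!r} is constant (degenerate knots)")
        x = np.clip(np.asarray(x, dtype=float), self.knots[0], self.knots[-1])
        k = self.order
        t = np.concatenate([[self.knots[0]] * (k + 1), self.knots[1:-1],
                            [self.knots[-1]] * (k + 1)])
        B = BSpline.design_matrix(x.ravel(), t, k).toarray()  # (n, n_basis + 1)
        # I-splines are reversed cumulative sums of the B-spline columns,
        # dropping the full sum (identically 1)
        I = np.cumsum(B[:, ::-1], axis=1)[:, ::-1][:, 1:]
        return I


def ispline_transform(values, basis: ISplineBasis) -> np.ndarray:
    """Evaluate a basis on raw predictor values (clamped to the knot range)."""
    return basis.evaluate(values)


@dataclass
class SitePairTable:
    """One row per retained sample pair.

    ``df`` columns: ``s1, s2, loc1, loc2, distance`` (observed dissimilarity
    scaled into [0,1)), ``geo`` (km), ``weight``, and per environmental
    predictor ``<var>_s1``/``<var>_s2`` endpoint values. ``scale`` is the
    divisor applied to raw genetic distances.
    """

    df: pd.DataFrame
    predictors: list[str]
    scale: float
    min_geo_km: float

    @property
    def n_pairs(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "SitePairTable":
        return SitePairTable(self.df.loc[mask].reset_index(drop=True),
                             list(self.predictors), self.scale, self.min_geo_km)


def build_pair_table(genetic: DistanceMatrix, loc: pd.DataFrame,
                     env: pd.DataFrame | None = None,
                     predictors: list[str] | None = None,
                     min_geo_km: float = 10.0) -> SitePairTable:
    """Build the GDM input table from individual-level genetic distances.

    Only unordered sample pairs whose localities are separated by more than
    ``min_geo_km`` great-circle km are retained (inter-location pairs). Raw
    genetic distances are divided by ``max * (1 + 1e-6)`` so all values lie
    in [0,1). Environmental predictor endpoint values are the sample's
    locality values.
    """
    samples = genetic.samples
    loc = loc.set_index("sample")
    missing = [s for s in samples if s not in loc.index]
    if missing:
        raise ValueError(f"samples missing from locality table: {missing}")
    lat = loc.loc[samples, "lat"].to_numpy()
    lon = loc.loc[samples, "lon"].to_numpy()
    locality = loc.loc[samples, "locality"].to_numpy()
    n = len(samples)
    iu = np.triu_indices(n, k=1)
    geo = np.asarray(geo_distance(lat[iu[0]], lon[iu[0]], lat[iu[1]], lon[iu[1]]))
    keep = geo > min_geo_km
    if not keep.any():
        raise ValueError(f"no sample pair exceeds min_geo_km={min_geo_km}")
    i1, i2 = iu[0][keep], iu[1][keep]
    raw = genetic.values[i1, i2]
    scale = float(raw.max()) * (1.0 + 1e-6)
    if scale <= 0:
        raise ValueError("all retained genetic distances are zero")
    df = pd.DataFrame({
        "s1": np.asarray(samples)[i1],
        "s2": np.asarray(samples)[i2],
        "loc1": locality[i1],
        "loc2": locality[i2],
        "distance": raw / scale,
        "geo": geo[keep],
        "weight": 1.0,
    })
    if predictors is None:
        predictors = []
        if env is not None and len(env):
            predictors = sorted(env["variable"].unique())
    if predictors:
        if env is None or not len(env):
            raise ValueError("environmental predictors requested but no env table given")
        wide = env.pivot(index="locality", columns="variable", values="value")
        for var in predictors:
            if var not in wide.columns:
                raise ValueError(f"predictor {var!r} not in environment table")
            df[f"{var}_s1"] = wide[var].reindex(df["loc1"]).to_numpy()
            df[f"{var}_s2"] = wide[var].reindex(df["loc2"]).to_numpy()
    return SitePairTable(df, list(predictors), scale, min_geo_km)


@dataclass
class GDMModel:
    intercept: float
    coefs: dict[str, np.ndarray]
    bases: dict[str, ISplineBasis]
    deviance: float
    null_deviance: float
    deviance_explained: float
    scale: float = 1.0
    n_pairs: int = 0
    excluded: list[str] = field(default_factory=list)

    @property
    def predictors(self) -> list[str]:
        return list(self.coefs)

    def spline(self, predictor: str, grid: np.ndarray) -> np.ndarray:
        """Fitted partial response f(x) = sum_k beta_k I_k(x) on a grid."""
        basis = self.bases[predictor]
        return basis.evaluate(grid) @ self.coefs[predictor]

    def to_json(self, path=None) -> str:
        payload = {
            "intercept": self.intercept,
            "coefs": {k: v.tolist() for k, v in self.coefs.items()},
            "knots": {k: b.knots.tolist() for k, b in self.bases.items()},
            "order": {k: b.order for k, b in self.bases.items()},
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "deviance_explained": self.deviance_explained,
            "scale": self.scale,
            "n_pairs": self.n_pairs,
            "excluded": self.excluded,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "GDMModel":
        d = json.loads(text)
        bases = {k: ISplineBasis(k, np.array(v), d["order"][k])
                 for k, v in d["knots"].items()}
        return cls(
            intercept=d["intercept"],
            coefs={k: np.array(v) for k, v in d["coefs"].items()},
            bases=bases, deviance=d["deviance"],
            null_deviance=d["null_deviance"],
            deviance_explained=d["deviance_explained"],
            scale=d["scale"], n_pairs=d["n_pairs"], excluded=d["excluded"],
        )


def binomial_deviance(d: np.ndarray, mu: np.ndarray,
                      w: np.ndarray | float = 1.0) -> float:
    """GLM binomial deviance with 0*log(0) := 0 and mu clamped away from
    {0, 1}."""
    mu = np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(d > 0, d * np.log(d / mu), 0.0)
        t2 = np.where(d < 1, (1.0 - d) * np.log((1.0 - d) / (1.0 - mu)), 0.0)
    return float(2.0 * np.sum(w * (t1 + t2)))


def _make_bases(pairs: SitePairTable, predictors: list[str], n_knots: int,
                order: int) -> tuple[dict[str, ISplineBasis], list[str]]:
    bases: dict[str, ISplineBasis] = {}
    excluded: list[str] = []
    for p in predictors:
        if p == GEO:
            vals = pairs.df["geo"].to_numpy()
        else:
            vals = np.concatenate([pairs.df[f"{p}_s1"].to_numpy(),
                                   pairs.df[f"{p}_s2"].to_numpy()])
        basis = ISplineBasis.from_values(p, vals, n_knots=n_knots, order=order)
        if basis.constant:
            warnings.warn(f"predictor {p!r} is constant; excluded from model",
                          stacklevel=2)
            excluded.append(p)
        else:
            bases[p] = basis
    return bases, excluded


def design_matrix(pairs: SitePairTable,
                  bases: dict[str, ISplineBasis]) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Stack per-predictor pair-level basis columns.

    Geographic distance is splined on the pair's distance; environmental
    predictors contribute ``|I_k(x_i) - I_k(x_j)|`` per basis function.
    """
    blocks, names = [], []
    for p, basis in bases.items():
        if p == GEO:
            block = basis.evaluate(pairs.df["geo"].to_numpy())
        else:
            b1 = basis.evaluate(pairs.df[f"{p}_s1"].to_numpy())
            b2 = basis.evaluate(pairs.df[f"{p}_s2"].to_numpy())
            block = np.abs(b1 - b2)
        blocks.append(block)
        names.extend((p, k) for k in range(block.shape[1]))
    if blocks:
        return np.hstack(blocks), names
    return np.zeros((pairs.n_pairs, 0)), names


def _fit_objective(theta: np.ndarray, X: np.ndarray, d: np.ndarray,
                   w: np.ndarray) -> tuple[float, np.ndarray]:
    eta = theta[0] + (X @ theta[1:] if X.shape[1] else 0.0)
    mu = 1.0 - np.exp(-eta)
    mu = np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)
    dev = binomial_deviance(d, mu, w)
    g_eta = 2.0 * w * (mu - d) / mu
    grad = np.empty_like(theta)
    grad[0] = g_eta.sum()
    if X.shape[1]:
        grad[1:] = X.T @ g_eta
    return dev, grad


def _null_deviance(d: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Intercept-only optimum: mu constant at the weighted mean dissimilarity
    (feasible since alpha = -log(1 - mean) >= 0). Returns (alpha, deviance)."""
    dbar = float(np.average(d, weights=w))
    dbar = min(max(dbar, _MU_EPS), 1.0 - _MU_EPS)
    alpha = -np.log(1.0 - dbar)
    return alpha, binomial_deviance(d, np.full_like(d, dbar), w)


def fit_gdm(pairs: SitePairTable, predictors: list[str] | None = None,
            n_knots: int = 3, order: int = 2, min_pairs: int = 10,
            tol: float = 1e-9,
            bases: dict[str, ISplineBasis] | None = None) -> GDMModel:
    """Fit a GDM by bound-constrained deviance minimization.

    ``predictors`` is a list of predictor names; the geographic distance
    predictor is named ``"geo"``. Defaults to geography plus every
    environmental predictor in the table. Multi-start (all-zero and
    null-intercept starts) L-BFGS-B with analytic gradients and non-negativity
    bounds on every coefficient.
    """
    if predictors is None:
        predictors = [GEO] + list(pairs.predictors)
    if pairs.n_pairs < min_pairs:
        raise ValueError(f"need >= {min_pairs} pairs, got {pairs.n_pairs}")
    d = pairs.df["distance"].to_numpy()
    w = pairs.df["weight"].to_numpy(dtype=float)
    if bases is not None:
        bases = {p: bases[p] for p in predictors}
        excluded = []
    else:
        bases, excluded = _make_bases(pairs, predictors, n_knots, order)
    X, names = design_matrix(pairs, bases)

    alpha0, d_null = _null_deviance(d, w)
    p = X.shape[1]
    starts = [np.zeros(p + 1)]
    s2 = np.zeros(p + 1)
    s2[0] = alpha0
    starts.append(s2)
    best = None
    for x0 in starts:
        res = minimize(
            _fit_objective, x0=x0, args=(X, d, w), jac=True,
            method="L-BFGS-B", bounds=[(0.0, None)] * (p + 1),
            options={"ftol": tol, "gtol": 1e-12, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"GDM fit failed to converge: {best}")
    theta = best.x
    coefs: dict[str, np.ndarray] = {}
    for p_name in bases:
        idx = [1 + i for i, (nm, _) in enumerate(names) if nm == p_name]
        coefs[p_name] = theta[idx]
    deviance = float(min(best.fun, d_null))
    de = 100.0 * (1.0 - deviance / d_null) if d_null > 0 else 0.0
    return GDMModel(
        intercept=float(theta[0]), coefs=coefs, bases=bases,
        deviance=deviance, null_deviance=float(d_null),
        deviance_explained=float(de), scale=pairs.scale, n_pairs=pairs.n_pairs,
        excluded=excluded,
    )


def predict_gdm(model: GDMModel, pairs: SitePairTable) -> np.ndarray:
    """Predicted dissimilarities ``1 - exp(-eta)`` for the rows of a pair
    table, using the model's knots (values outside are clamped)."""
    for p in model.predictors:
        if p != GEO and f"{p}_s1" not in pairs.df.columns:
            raise ValueError(f"predictor {p!r} not present in pair table")
    X, _ = design_matrix(pairs, model.bases)
    beta = np.concatenate([model.coefs[p] for p in model.bases]) if model.bases else np.zeros(0)
    eta = model.intercept + (X @ beta if X.shape[1] else 0.0)
    return 1.0 - np.exp(-eta)


def deviance_explained(model: GDMModel) -> float:
    """Percent of null deviance explained by the fitted model."""
    return model.deviance_explained


def spline_table(model: GDMModel, n_grid: int = 200) -> pd.DataFrame:
    """Export fitted spline curves as a long table (predictor, x, f)."""
    rows = []
    for p, basis in model.bases.items():
        grid = np.linspace(basis.knots[0], basis.knots[-1], n_grid)
        f = model.spline(p, grid)
        rows.append(pd.DataFrame({"predictor": p, "x": grid, "f": f}))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["predictor", "x", "f"])
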