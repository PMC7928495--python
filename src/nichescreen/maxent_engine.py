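"""A presence-background maximum-entropy (MaxEnt-style) niche model.

The model is the Gibbs distribution p(x) ∝ exp(λ·f(x)) over the background
cells, where f(x) is a feature expansion of the raw predictors (linear,
quadratic, product, hinge, threshold classes) and λ maximizes the penalized
log-likelihood of the presence sample::

    max_λ  (1/m) Σ_presence λ·f(x_i)  −  log Σ_background exp(λ·f(x_b))
           − Σ_j β_j |λ_j|

The per-feature L1 weights β_j are the regularization multiplier times a
class-dependent base penalty interpolated by presence sample size, times
the feature's presence-sample standard deviation over √m — the classical
MaxEnt defaults. The L1 problem is solved exactly and deterministically by
splitting λ into positive and negative parts and running L-BFGS-B from a
zero start.

Raw output sums to 1 over the training background; logistic output is
τ·c·raw / ((1−τ) + τ·c·raw) with c = e^H (H the entropy of the fitted raw
distribution) and τ = 0.5, interpretable as a probability of presence.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .grid_io import EnvGrid

__all__ = [
    "ModelSettings", "FeatureColumn", "FeatureExpansion", "MaxentModel",
    "ConvergenceError", "expand_features", "fit", "predict",
    "cross_validate", "tune", "DEFAULT_BETA_TABLES",
]

VALID_CLASSES = frozenset("LQHPT")

# Base L1 penalty per feature class, linearly interpolated in the presence
# sample size (clamped at the table ends). Overridable via ModelSettings.
DEFAULT_BETA_TABLES: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "L": ((0, 10, 30, 100), (1.0, 1.0, 0.2, 0.05)),
    "Q": ((0, 10, 30, 100), (1.0, 1.0, 0.2, 0.05)),
    "P": ((0, 10, 17, 30, 100), (2.6, 1.6, 0.9, 0.55, 0.05)),
    "H": ((0, 1), (0.5, 0.5)),
    "T": ((0, 100), (2.0, 1.0)),
}


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries scipy diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class ModelSettings:
    """Feature-class and regularization settings for one model fit.

    ``feature_classes`` is a string over {L, Q, H, P, T}; the default LQHP
    with regularization multiplier 1.0 is the conventional automatic choice
    for presence samples larger than 80.
    """

    feature_classes: str = "LQHP"
    regularization_multiplier: float = 1.0
    hinge_knots: int = 50
    threshold_knots: int = 50
    max_iterations: int = 1000
    tolerance: float = 1e-7
    beta_tables: dict = field(default_factory=lambda: dict(DEFAULT_BETA_TABLES))

    def __post_init__(self) -> None:
        fc = self.feature_classes.upper()
        object.__setattr__(self, "feature_classes", fc)
        if not fc or not set(fc) <= VALID_CLASSES:
            raise ValueError(f"feature_classes must be a non-empty subset of LQHPT, got {fc!r}")
        if not self.regularization_multiplier > 0:
            raise ValueError("regularization_multiplier must be > 0")


@dataclass(frozen=True)
class FeatureColumn:
    """One column of the design matrix: class, source variable(s), knot."""

    cls: str                     # one of L Q H P T (H split into Hf/Hr via knot sign)
    variables: tuple[str, ...]   # one name, or two for products
    knot: float | None = None    # knot location in scaled [0,1] space
    reverse: bool = False        # reverse hinge

    def label(self) -> str:
        v = "*".join(self.variables)
        if self.cls == "H":
            return f"H{'r' if self.reverse else 'f'}({v}@{self.knot:g})"
        if self.cls == "T":
            return f"T({v}@{self.knot:g})"
        return f"{self.cls}({v})"


@dataclass
class FeatureExpansion:
    """Design matrix plus the metadata needed to rebuild it on new data."""

    design_matrix: np.ndarray
    columns: list[FeatureColumn]
    scaling: dict[str, tuple[float, float]]   # per-variable (min, max)

    @property
    def labels(self) -> list[str]:
        return [c.label() for c in self.columns]


def build_columns(variable_names: Sequence[str], settings: ModelSettings) -> list[FeatureColumn]:
    """Enumerate the feature columns implied by the settings."""
    names = list(variable_names)
    fc = settings.feature_classes
    if "P" in fc and len(names) < 2:
        raise ValueError("product features require at least 2 variables")
    cols: list[FeatureColumn] = []
    if "L" in fc:
        cols += [FeatureColumn("L", (n,)) for n in names]
    if "Q" in fc:
        cols += [FeatureColumn("Q", (n,)) for n in names]
    if "P" in fc:
        cols += [FeatureColumn("P", pair) for pair in itertools.combinations(names, 2)]
    if "H" in fc:
        k = settings.hinge_knots
        fwd = np.linspace(0.0, 1.0, k, endpoint=False)
        rev = np.linspace(0.0, 1.0, k + 1)[1:]
        for n in names:
            cols += [FeatureColumn("H", (n,), float(t)) for t in fwd]
            cols += [FeatureColumn("H", (n,), float(t), reverse=True) for t in rev]
    if "T" in fc:
        k = settings.threshold_knots
        knots = (np.arange(k) + 1) / (k + 1)
        for n in names:
            cols += [FeatureColumn("T", (n,), float(t)) for t in knots]
    return cols


def _scale(X: np.ndarray, names: Sequence[str],
           scaling: dict[str, tuple[float, float]]) -> np.ndarray:
    """Map each variable to [0,1] with the stored bounds, clamping outside."""
    Xs = np.empty_like(X, dtype=float)
    for j, n in enumerate(names):
        lo, hi = scaling[n]
        span = hi - lo
        Xs[:, j] = 0.0 if span == 0 else np.clip((X[:, j] - lo) / span, 0.0, 1.0)
    return Xs


def _evaluate_columns(Xs: np.ndarray, names: Sequence[str],
                      columns: Sequence[FeatureColumn]) -> np.ndarray:
    idx = {n: j for j, n in enumerate(names)}
    F = np.empty((Xs.shape[0], len(columns)))
    for c, col in enumerate(columns):
        if col.cls == "L":
            F[:, c] = Xs[:, idx[col.variables[0]]]
        elif col.cls == "Q":
            F[:, c] = Xs[:, idx[col.variables[0]]] ** 2
        elif col.cls == "P":
            F[:, c] = Xs[:, idx[col.variables[0]]] * Xs[:, idx[col.variables[1]]]
        elif col.cls == "H":
            x = Xs[:, idx[col.variables[0]]]
            t = col.knot
            if col.reverse:
                F[:, c] = np.clip((t - x) / t, 0.0, 1.0) if t > 0 else 0.0
            else:
                F[:, c] = np.clip((x - t) / (1.0 - t), 0.0, 1.0) if t < 1 else 0.0
        elif col.cls == "T":
            F[:, c] = (Xs[:, idx[col.variables[0]]] >= col.knot).astype(float)
    return F


def expand_features(X: np.ndarray | pd.DataFrame, settings: ModelSettings,
                    variable_names: Sequence[str] | None = None,
                    scaling: dict[str, tuple[float, float]] | None = None) -> FeatureExpansion:
    """Expand raw predictors into the feature classes the settings request.

    Scaling bounds default to the observed per-variable min/max of ``X``.
    """
    X, names = _coerce(X, variable_names)
    if scaling is None:
        scaling = {n: (float(X[:, j].min()), float(X[:, j].max()))
                   for j, n in enumerate(names)}
    cols = build_columns(names, settings)
    Xs = _scale(X, names, scaling)
    return FeatureExpansion(_evaluate_columns(Xs, names, cols), cols, scaling)


def _coerce(X, variable_names) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if variable_names is None else list(variable_names)
        return X[names].to_numpy(dtype=float), names
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = (list(variable_names) if variable_names is not None
             else [f"x{j}" for j in range(X.shape[1])])
    return X, names


def _base_beta(cls: str, n_presence: int, tables: dict) -> float:
    xs, ys = tables[cls]
    return float(np.interp(n_presence, xs, ys))


@dataclass
class MaxentModel:
    """A fitted maximum-entropy niche model."""

    variable_names: list[str]
    columns: list[FeatureColumn]
    coefficients: np.ndarray
    scaling: dict[str, tuple[float, float]]
    density_normalizer: float      # log Σ_background exp(λ·f)
    entropy: float                 # H of the fitted raw distribution
    settings: ModelSettings
    n_presence: int
    n_background: int
    converged: bool = True

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    def linear_score(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = set(self.variable_names) - set(X.columns)
            if missing:
                raise KeyError(f"input lacks model variable(s): {sorted(missing)}")
            Xv = X[self.variable_names].to_numpy(dtype=float)
        else:
            # bare arrays are taken to be in model variable order
            Xv = np.atleast_2d(np.asarray(X, dtype=float))
            if Xv.shape[1] != len(self.variable_names):
                raise KeyError(
                    f"expected {len(self.variable_names)} columns, got {Xv.shape[1]}")
        Xs = _scale(Xv, self.variable_names, self.scaling)
        F = _evaluate_columns(Xs, self.variable_names, self.columns)
        return F @ self.coefficients

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "variable_names": self.variable_names,
            "columns": [{"cls": c.cls, "variables": list(c.variables),
                         "knot": c.knot, "reverse": c.reverse} for c in self.columns],
            "coefficients": self.coefficients.tolist(),
            "scaling": {k: list(v) for k, v in self.scaling.items()},
            "density_normalizer": self.density_normalizer,
            "entropy": self.entropy,
            "settings": {
                "feature_classes": self.settings.feature_classes,
                "regularization_multiplier": self.settings.regularization_multiplier,
                "hinge_knots": self.settings.hinge_knots,
                "threshold_knots": self.settings.threshold_knots,
                "max_iterations": self.settings.max_iterations,
                "tolerance": self.settings.tolerance,
            },
            "n_presence": self.n_presence,
            "n_background": self.n_background,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MaxentModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            variable_names=d["variable_names"],
            columns=[FeatureColumn(c["cls"], tuple(c["variables"]), c["knot"], c["reverse"])
                     for c in d["columns"]],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            scaling={k: tuple(v) for k, v in d["scaling"].items()},
            density_normalizer=d["density_normalizer"],
            entropy=d["entropy"],
            settings=ModelSettings(**d["settings"]),
            n_presence=d["n_presence"],
            n_background=d["n_background"],
        )


def fit(presence_X: np.ndarray | pd.DataFrame, background_X: np.ndarray | pd.DataFrame,
        settings: ModelSettings | None = None, seed: int = 0,
        variable_names: Sequence[str] | None = None) -> MaxentModel:
    """Fit the penalized maximum-entropy model.

    The optimization is deterministic (zero start, L-BFGS-B on the split
    positive/negative coefficients); ``seed`` is accepted for interface
    symmetry and reserved for stochastic initializations.

    Degenerate (constant over presence+background) feature columns are
    dropped with a warning. Non-convergence raises :class:`ConvergenceError`
    with the optimizer diagnostics attached.
    """
    settings = settings or ModelSettings()
    P, names = _coerce(presence_X, variable_names)
    if isinstance(background_X, pd.DataFrame):
        B = background_X[names].to_numpy(dtype=float)
    else:
        B, _ = _coerce(background_X, names)
    if P.shape[0] < 2:
        raise ValueError("need at least 2 presence samples")
    m, nb = P.shape[0], B.shape[0]

    both = np.vstack([P, B])
    scaling = {n: (float(both[:, j].min()), float(both[:, j].max()))
               for j, n in enumerate(names)}
    cols = build_columns(names, settings)
    Ps = _scale(P, names, scaling)
    Bs = _scale(B, names, scaling)
    Fp = _evaluate_columns(Ps, names, cols)
    Fb = _evaluate_columns(Bs, names, cols)

    combined = np.vstack([Fp, Fb])
    keep = combined.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant feature column(s)",
                      stacklevel=2)
    cols = [c for c, k in zip(cols, keep) if k]
    Fp, Fb = Fp[:, keep], Fb[:, keep]
    nfeat = Fp.shape[1]

    if nfeat == 0:
        lam = np.zeros(0)
        logZ = float(np.log(nb))
        H = float(np.log(nb))
        return MaxentModel(names, cols, lam, scaling, logZ, H, settings, m, nb)

    # per-feature L1 weight: RM * class base * sd over presences / sqrt(m)
    rm = settings.regularization_multiplier
    sd = Fp.std(axis=0, ddof=1) if m > 1 else np.zeros(nfeat)
    beta = np.empty(nfeat)
    for j, c in enumerate(cols):
        s = sd[j]
        if c.cls in ("H", "T"):
            s = max(s, 1.0 / np.sqrt(m))
        beta[j] = rm * _base_beta(c.cls, m, settings.beta_tables) * max(s, 1e-6) / np.sqrt(m)

    fbar = Fp.mean(axis=0)

    def objective(w):
        lam = w[:nfeat] - w[nfeat:]
        eta = Fb @ lam
        logZ = logsumexp(eta)
        q = np.exp(eta - logZ)
        val = logZ - fbar @ lam + beta @ (w[:nfeat] + w[nfeat:])
        g = q @ Fb - fbar
        grad = np.concatenate([g + beta, -g + beta])
        return val, grad

    res = minimize(objective, np.zeros(2 * nfeat), jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * nfeat),
                   options={"maxiter": settings.max_iterations,
                            "maxfun": 10 * settings.max_iterations,
                            "ftol": settings.tolerance,
                            "gtol": 10 * settings.tolerance})
    if not res.success and "ITERATIONS" in str(res.message).upper():
        raise ConvergenceError(
            f"optimizer did not converge in {settings.max_iterations} iterations",
            {"message": str(res.message), "nit": res.nit, "fun": float(res.fun)})
    lam = res.x[:nfeat] - res.x[nfeat:]
    lam[np.abs(lam) < 1e-10] = 0.0

    eta = Fb @ lam
    logZ = float(logsumexp(eta))
    raw = np.exp(eta - logZ)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = float(-(raw * np.where(raw > 0, np.log(np.where(raw > 0, raw, 1.0)), 0.0)).sum())
    return MaxentModel(names, cols, lam, scaling, logZ, max(H, 0.0), settings, m, nb,
                       converged=bool(res.success))


LOGISTIC_TAU = 0.5


def predict(model: MaxentModel, X: np.ndarray | pd.DataFrame | EnvGrid,
            output: str = "logistic") -> np.ndarray:
    """Predict suitability for a sample matrix or a whole grid.

    ``raw`` is the Gibbs density normalized over the training background
    (sums to 1 there); ``logistic`` maps it through
    τ·c·raw / ((1−τ) + τ·c·raw), c = e^H, τ = 0.5, onto (0, 1). Grid input
    returns a 2-D map with NaN on nodata cells.
    """
    if output not in ("raw", "logistic"):
        raise ValueError("output must be 'raw' or 'logistic'")
    if isinstance(X, EnvGrid):
        table = X.valid_table()
        vals = predict(model, table, output=output)
        out = np.full(X.shape, np.nan)
        out[~X.nodata_mask] = vals
        return out
    score = model.linear_score(X)
    # cap the exponent: scores this far above the normalizer are already
    # astronomically unsuitable-background territory, not meaningful density
    raw = np.exp(np.minimum(score - model.density_normalizer, 700.0))
    if output == "raw":
        return raw
    c = np.exp(model.entropy)
    t = LOGISTIC_TAU
    return t * c * raw / ((1.0 - t) + t * c * raw)


def cross_validate(presence_X, background_X, settings: ModelSettings | None = None,
                   n_replicates: int = 10, seed: int = 0,
                   variable_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Replicate cross-validation on the presence records.

    Presences are shuffled once and split into ``n_replicates`` folds; each
    replicate trains on the remainder and reports test AUC against the full
    background. Returns one row per replicate plus mean/sd summary rows.
    """
    from .model_metrics import auc  # local import to avoid a cycle

    settings = settings or ModelSettings()
    P, names = _coerce(presence_X, variable_names)
    B, _ = _coerce(background_X, names)
    m = P.shape[0]
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if m < n_replicates:
        raise ValueError("fewer presences than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    folds = np.array_split(order, n_replicates)
    rows = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        model = fit(P[train_idx], B, settings, seed=seed, variable_names=names)
        test_scores = predict(model, P[test_idx], output="raw")
        bg_scores = predict(model, B, output="raw")
        train_scores = predict(model, P[train_idx], output="raw")
        rows.append({"replicate": i + 1, "n_train": len(train_idx),
                     "n_test": len(test_idx),
                     "train_auc": auc(train_scores, bg_scores),
                     "test_auc": auc(test_scores, bg_scores)})
    table = pd.DataFrame(rows)
    summary = pd.DataFrame([
        {"replicate": "mean", "n_train": table.n_train.mean(),
         "n_test": table.n_test.mean(), "train_auc": table.train_auc.mean(),
         "test_auc": table.test_auc.mean()},
        {"replicate": "sd", "n_train": table.n_train.std(),
         "n_test": table.n_test.std(), "train_auc": table.train_auc.std(),
         "test_auc": table.test_auc.std()},
    ])
    return pd.concat([table, summary], ignore_index=True)


DEFAULT_FC_GRID = ("L", "LQ", "LQH", "LQHP", "LQHPT")
DEFAULT_RM_GRID = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


def tune(presence_X, background_X,
         fc_grid: Sequence[str] = DEFAULT_FC_GRID,
         rm_grid: Sequence[float] = DEFAULT_RM_GRID,
         base_settings: ModelSettings | None = None, seed: int = 0,
         variable_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Scan feature-class sets × regularization multipliers.

    One row per (FC, RM) with training AUC, AICc, and the nonzero
    coefficient count; the ``best`` column marks the AICc minimum. The
    default grid is 5 FC sets × RM 0.5–4.0 in half steps (40 rows).
    """
    from .model_metrics import aicc, auc

    if len(fc_grid) == 0 or len(rm_grid) == 0:
        raise ValueError("fc_grid and rm_grid must be non-empty")
    base = base_settings or ModelSettings()
    P, names = _coerce(presence_X, variable_names)
    B, _ = _coerce(background_X, names)
    rows = []
    for fc in fc_grid:
        for rm in rm_grid:
            settings = replace(base, feature_classes=fc, regularization_multiplier=rm)
            try:
                model = fit(P, B, settings, seed=seed, variable_names=names)
            except (ConvergenceError, ValueError) as exc:
                rows.append({"feature_classes": fc, "rm": rm, "aicc": np.nan,
                             "train_auc": np.nan, "n_nonzero": np.nan,
                             "error": str(exc)})
                continue
            pr = predict(model, P, output="raw")
            br = predict(model, B, output="raw")
            rows.append({"feature_classes": fc, "rm": rm,
                         "aicc": aicc(model, P, B),
                         "train_auc": auc(pr, br),
                         "n_nonzero": model.n_nonzero, "error": ""})
    table = pd.DataFrame(rows)
    if table.aicc.isna().all():
        raise RuntimeError("all fits in the tuning scan failed")
    table["best"] = False
    table.loc[table.aicc.idxmin(), "best"] = True
    return table
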