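"""Calibration of the linear Markov movement model.

Three predictors are modelled at 1-s resolution: vertical speed ``vz``,
horizontal speed ``vh``, and heading rate ``omega``.  Each predictor at
time t_{k+1} is a linear function of covariates at t_k plus
state-dependent Gaussian noise:

    y_{k+1} = sum_j beta_mean_j * psi_{j,k}  +  eps_k,
    eps_k ~ N(0, sigma(psi_k)^2),   sigma(psi) = sum_j beta_err_j * psi_j

The covariates are: an intercept; crosswind ``wc``; tailwind ``wt``;
orographic updraft ``wo``; altitude AGL ``h_agl``; the predictor's own
values 5, 10, and 30 s earlier; and, for the heading-rate mean model
only, the collapsed look-ahead covariate ``lam``.  Calibration pools
rows across tracks without track identity, keeps only rotor-swept-zone
rows (AGL < 200 m), and is a two-stage least-squares fit: ordinary least
squares for the mean model, then a regression of the absolute residuals
on the same covariates — scaled by sqrt(pi/2), the half-normal
correction E|eps| = sigma * sqrt(2/pi) — for the noise-strength model.
A variant that regresses the squared residuals (predicting sigma^2
instead of sigma) is available via ``error_method="squared"``.

Fitted noise predictions are floored at sigma_min (default 1% of the
predictor's calibration standard deviation) so simulation noise never
degenerates to zero or goes negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidInputError, RankDeficientError
from .lookahead import LookaheadSpec, RelationFit

__all__ = [
    "CovariateSpec",
    "PredictorModel",
    "MarkovModel",
    "build_design",
    "fit_mean",
    "fit_error",
    "calibrate",
]

PREDICTORS = ("vz", "vh", "omega")
BASE_COVARIATES = ("intercept", "wc", "wt", "wo", "h_agl")
DEFAULT_LAGS = (5, 10, 30)
RSZ_CEILING = 200.0
HALF_NORMAL = float(np.sqrt(np.pi / 2.0))


@dataclass(frozen=True)
class CovariateSpec:
    """Covariate list for one predictor's mean and error models."""

    predictor: str
    base: tuple[str, ...] = BASE_COVARIATES
    lags: tuple[int, ...] = DEFAULT_LAGS
    use_lookahead: bool = False  # Lambda in the mean model (omega only)

    def __post_init__(self):
        if self.predictor not in PREDICTORS:
            raise InvalidInputError(f"unknown predictor {self.predictor!r}")

    @property
    def mean_columns(self) -> list[str]:
        cols = list(self.base) + [f"{self.predictor}_lag{l}" for l in self.lags]
        if self.use_lookahead:
            cols.append("lam")
        return cols

    @property
    def error_columns(self) -> list[str]:
        # the look-ahead covariate never enters the error model
        return [c for c in self.mean_columns if c != "lam"]


def default_spec(predictor: str) -> CovariateSpec:
    return CovariateSpec(predictor=predictor, use_lookahead=(predictor == "omega"))


def build_design(
    tracks,
    predictor: str,
    spec: CovariateSpec | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble the pooled (design, response) pair for one predictor.

    ``tracks`` is a sequence of annotated-track DataFrames at 1-s
    cadence (columns from annotate/derive plus ``lam`` when the spec
    uses the look-ahead covariate).  Each row pairs the response at
    t_{k+1} with covariates at t_k; rows lacking the full 30-s lag
    history, rows above the rotor-swept zone at t_k, and rows with
    non-finite entries are dropped.  Rows are pooled across tracks
    without track identity.
    """
    spec = spec or default_spec(predictor)
    if isinstance(tracks, pd.DataFrame):
        tracks = [tracks]
    cols = spec.mean_columns
    max_lag = max(spec.lags) if spec.lags else 0
    X_parts, y_parts = [], []
    for df in tracks:
        n = len(df)
        if n < max_lag + 2:
            continue
        k = np.arange(max_lag, n - 1)  # covariate rows with full history
        block = {}
        for c in cols:
            if c == "intercept":
                block[c] = np.ones(len(k))
            elif c.startswith(f"{predictor}_lag"):
                lag = int(c.rsplit("lag", 1)[1])
                block[c] = df[predictor].to_numpy(dtype=float)[k - lag]
            else:
                if c not in df.columns:
                    raise InvalidInputError(f"unknown covariate {c!r}")
                block[c] = df[c].to_numpy(dtype=float)[k]
        y = df[predictor].to_numpy(dtype=float)[k + 1]
        Xb = pd.DataFrame(block)
        keep = df["h_agl"].to_numpy(dtype=float)[k] < RSZ_CEILING
        keep &= np.isfinite(y)
        keep &= np.all(np.isfinite(Xb.to_numpy()), axis=1)
        X_parts.append(Xb.loc[keep])
        y_parts.append(y[keep])
    if not X_parts:
        return pd.DataFrame(columns=cols), np.empty(0)
    X = pd.concat(X_parts, ignore_index=True)
    y = np.concatenate(y_parts)
    return X, y


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # name columns whose removal restores full column rank
        suspects = []
        for j, name in enumerate(X.columns):
            sub = np.delete(A, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                suspects.append(name)
        raise RankDeficientError(
            f"design matrix rank {rank} < {A.shape[1]} columns; "
            f"collinear candidates: {suspects}",
            columns=suspects,
        )


def fit_mean(X: pd.DataFrame, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary least squares; returns (beta_mean, residuals)."""
    if len(X) <= X.shape[1]:
        raise InsufficientDataError(
            f"{len(X)} rows insufficient for {X.shape[1]} covariates"
        )
    A = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(A)) or not np.all(np.isfinite(y)):
        raise InvalidInputError("design/response contain non-finite values")
    _check_rank(X)
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta, y - A @ beta


def fit_error(
    X: pd.DataFrame,
    residuals: np.ndarray,
    method: str = "abs",
    sigma_min: float | None = None,
) -> tuple[np.ndarray, float, str]:
    """Fit the heteroscedastic noise-strength model from mean residuals.

    ``method="abs"`` (default) regresses |eps| on the covariates and
    scales the coefficients by sqrt(pi/2) so that sigma(psi) = psi @
    beta_err directly.  ``method="squared"`` regresses eps^2, yielding
    weights on the sigma^2 scale (flagged by the returned scale string).
    Returns (beta_err, sigma_min, scale) with scale in {"sigma",
    "sigma2"}.
    """
    A = X.to_numpy(dtype=float)
    if sigma_min is None:
        sd = float(np.std(residuals))
        sigma_min = 0.01 * sd if sd > 0 else 1e-6
    if np.allclose(residuals, 0.0):
        return np.zeros(A.shape[1]), sigma_min, "sigma"
    if method == "abs":
        target = np.abs(residuals)
        beta, *_ = np.linalg.lstsq(A, target, rcond=None)
        return beta * HALF_NORMAL, sigma_min, "sigma"
    if method == "squared":
        beta, *_ = np.linalg.lstsq(A, residuals**2, rcond=None)
        return beta, sigma_min, "sigma2"
    raise InvalidInputError(f"unknown error-model method {method!r}")


@dataclass
class PredictorModel:
    """Calibrated mean + error model for one predictor."""

    predictor: str
    spec: CovariateSpec
    beta_mean: np.ndarray
    beta_err: np.ndarray
    sigma_min: float
    error_scale: str = "sigma"

    def __post_init__(self):
        self.beta_mean = np.asarray(self.beta_mean, dtype=float)
        self.beta_err = np.asarray(self.beta_err, dtype=float)
        if len(self.beta_mean) != len(self.spec.mean_columns):
            raise InvalidInputError("beta_mean not conformable with covariate spec")
        if len(self.beta_err) != len(self.spec.error_columns):
            raise InvalidInputError("beta_err not conformable with covariate spec")
        if self.sigma_min <= 0:
            raise InvalidInputError("sigma_min must be positive")

    def predict_mean(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.spec.mean_columns].to_numpy(dtype=float) @ self.beta_mean

    def predict_sigma(self, X: pd.DataFrame) -> np.ndarray:
        raw = X[self.spec.error_columns].to_numpy(dtype=float) @ self.beta_err
        if self.error_scale == "sigma2":
            raw = np.sqrt(np.maximum(raw, 0.0))
        return np.maximum(raw, self.sigma_min)


@dataclass
class MarkovModel:
    """The full calibrated movement model: three predictors + c_omega."""

    predictors: dict[str, PredictorModel]
    c_omega: float
    T: float = 1.0
    relation: RelationFit | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.T <= 0:
            raise InvalidInputError("time step T must be positive")
        missing = set(PREDICTORS) - set(self.predictors)
        if missing:
            raise InvalidInputError(f"missing predictor models: {sorted(missing)}")

    def to_dict(self) -> dict:
        d = {
            "T": self.T,
            "c_omega": self.c_omega,
            "metadata": self.metadata,
            "predictors": {},
        }
        for name, pm in self.predictors.items():
            d["predictors"][name] = {
                "base": list(pm.spec.base),
                "lags": list(pm.spec.lags),
                "use_lookahead": pm.spec.use_lookahead,
                "mean_columns": pm.spec.mean_columns,
                "error_columns": pm.spec.error_columns,
                "beta_mean": pm.beta_mean.tolist(),
                "beta_err": pm.beta_err.tolist(),
                "sigma_min": pm.sigma_min,
                "error_scale": pm.error_scale,
            }
        if self.relation is not None:
            d["relation"] = self.relation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MarkovModel":
        preds = {}
        for name, pd_ in d["predictors"].items():
            spec = CovariateSpec(
                predictor=name,
                base=tuple(pd_["base"]),
                lags=tuple(pd_["lags"]),
                use_lookahead=bool(pd_["use_lookahead"]),
            )
            preds[name] = PredictorModel(
                predictor=name,
                spec=spec,
                beta_mean=np.array(pd_["beta_mean"]),
                beta_err=np.array(pd_["beta_err"]),
                sigma_min=float(pd_["sigma_min"]),
                error_scale=pd_.get("error_scale", "sigma"),
            )
        relation = RelationFit.from_dict(d["relation"]) if "relation" in d else None
        return cls(
            predictors=preds,
            c_omega=float(d["c_omega"]),
            T=float(d["T"]),
            relation=relation,
            metadata=d.get("metadata", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "MarkovModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def calibrate(
    tracks,
    relation: RelationFit | None = None,
    error_method: str = "abs",
    sigma_min: dict | None = None,
    metadata: dict | None = None,
) -> MarkovModel:
    """Two-stage least-squares calibration of all three predictors.

    ``tracks`` are annotated-track DataFrames; when ``relation`` is
    given (look-ahead law), the heading-rate mean model includes the
    ``lam`` covariate and the bundled c_omega comes from the relation.
    Calibration is deterministic: identical inputs give an identical
    model file.
    """
    if isinstance(tracks, pd.DataFrame):
        tracks = [tracks]
    sigma_min = sigma_min or {}
    use_lam = relation is not None and any("lam" in df.columns for df in tracks)
    preds: dict[str, PredictorModel] = {}
    n_rows = {}
    for name in PREDICTORS:
        spec = CovariateSpec(predictor=name, use_lookahead=(name == "omega" and use_lam))
        X, y = build_design(tracks, name, spec)
        if len(X) == 0:
            raise InsufficientDataError(f"no usable calibration rows for {name!r}")
        beta_mean, resid = fit_mean(X, y)
        beta_err, s_min, scale = fit_error(
            X[spec.error_columns], resid, method=error_method,
            sigma_min=sigma_min.get(name),
        )
        preds[name] = PredictorModel(
            predictor=name,
            spec=spec,
            beta_mean=beta_mean,
            beta_err=beta_err,
            sigma_min=s_min,
            error_scale=scale,
        )
        n_rows[name] = len(X)
    meta = {"n_rows": n_rows, "n_tracks": len(tracks), **(metadata or {})}
    return MarkovModel(
        predictors=preds,
        c_omega=relation.c_omega if relation is not None else 0.0,
        T=1.0,
        relation=relation,
        metadata=meta,
    )
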