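"""Additive predictors for the 14 distributional parameters.

Each distributional parameter (4 means, 4 log innovation scales, 6 Cholesky
coefficients) carries an additive predictor

    eta_k = sum_t  X_t  beta_t

built from intercepts, linear terms, dummy-coded factors, P-splines and
tensor-product spatial P-splines.  Links are identity for means and phi entries
and log-scale for the innovation scales (the predictor *is* lam = log scale).

Penalized smooth designs are column-centred on the training data so the
constant direction lives in the intercept only; this keeps the Bayesian
posterior proper under difference penalties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import BSpline

from .distribution import M, PARAM_LABELS, phi_matrix

TERM_KINDS = ("intercept", "linear", "pspline", "spatial2d", "factor")


@dataclass(frozen=True)
class TermSpec:
    """Specification of one additive model term."""

    kind: str
    covariates: tuple[str, ...] = ()
    basis_size: int = 20
    degree: int = 3
    penalty_order: int = 2

    def __post_init__(self) -> None:
        if self.kind not in TERM_KINDS:
            raise ValueError(f"unknown term kind {self.kind!r}")
        cov = tuple(self.covariates)
        object.__setattr__(self, "covariates", cov)
        if self.kind == "intercept" and cov:
            raise ValueError("intercept takes no covariates")
        if self.kind in ("linear", "pspline", "factor") and len(cov) != 1:
            raise ValueError(f"{self.kind} term requires exactly one covariate")
        if self.kind == "spatial2d" and len(cov) != 2:
            raise ValueError("spatial2d requires exactly (longitude, latitude)")
        if self.kind in ("pspline", "spatial2d"):
            if self.basis_size < self.degree + 1:
                raise ValueError("basis_size must be at least degree + 1")
            if self.basis_size < self.penalty_order + 1:
                raise ValueError("basis_size must exceed penalty order")

    @property
    def label(self) -> str:
        if self.kind == "intercept":
            return "intercept"
        return f"{self.kind}({','.join(self.covariates)})"

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.covariates:
            d["covariates"] = list(self.covariates)
        if self.kind in ("pspline", "spatial2d"):
            d.update(
                basis_size=self.basis_size,
                degree=self.degree,
                penalty_order=self.penalty_order,
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TermSpec":
        d = dict(d)
        if "covariate" in d:  # accept the scalar spelling
            d["covariates"] = (d.pop("covariate"),)
        d["covariates"] = tuple(d.get("covariates", ()))
        return cls(**d)


def intercept() -> TermSpec:
    return TermSpec("intercept")


def linear(covariate: str) -> TermSpec:
    return TermSpec("linear", (covariate,))


def pspline(covariate: str, basis_size: int = 20, degree: int = 3, penalty_order: int = 2) -> TermSpec:
    return TermSpec("pspline", (covariate,), basis_size, degree, penalty_order)


def spatial2d(lon: str = "lon", lat: str = "lat", basis_size: int = 10) -> TermSpec:
    """Tensor-product P-spline over coordinates; basis_size is per margin."""
    return TermSpec("spatial2d", (lon, lat), basis_size)


def factor(covariate: str) -> TermSpec:
    return TermSpec("factor", (covariate,))


@dataclass
class DesignBlock:
    """Basis evaluations with their (symmetric PSD) penalty."""

    matrix: np.ndarray
    penalty: np.ndarray
    coef: np.ndarray | None = None


def _difference_penalty(size: int, order: int) -> np.ndarray:
    d = np.diff(np.eye(size), n=order, axis=0)
    return d.T @ d


def _bspline_knots(lo: float, hi: float, basis_size: int, degree: int) -> np.ndarray:
    if hi <= lo:
        hi = lo + 1.0  # degenerate covariate: any knot span works
    step = (hi - lo) / (basis_size - degree)
    return lo + step * (np.arange(basis_size + degree + 1) - degree)


def _bspline_design(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    lo, hi = knots[degree], knots[-degree - 1]
    xc = np.clip(np.asarray(x, dtype=float), lo, hi)
    return BSpline.design_matrix(xc, knots, degree).toarray()


def pspline_basis(
    x: np.ndarray, basis_size: int = 20, degree: int = 3, penalty_order: int = 2
) -> DesignBlock:
    """B-spline basis over the range of ``x`` with a difference penalty.

    Rows of the (uncentred) basis sum to one; the penalty is ``D'D`` for the
    difference matrix of the requested order, whose null space contains
    coefficient vectors polynomial of degree < order in the knot index.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("pspline covariate contains non-finite values")
    if np.unique(x).size < basis_size:
        warnings.warn(
            "fewer distinct covariate values than basis functions; design is rank deficient",
            UserWarning,
            stacklevel=2,
        )
    knots = _bspline_knots(float(x.min()), float(x.max()), basis_size, degree)
    return DesignBlock(_bspline_design(x, knots, degree), _difference_penalty(basis_size, penalty_order))


def _row_kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a[:, :, None] * b[:, None, :]).reshape(a.shape[0], -1)


def spatial2d_basis(
    lon: np.ndarray, lat: np.ndarray, basis_size: int = 10, degree: int = 3, penalty_order: int = 2
) -> DesignBlock:
    """Tensor-product P-spline over (lon, lat) with Kronecker-sum penalty."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.ptp(lon) == 0 and np.ptp(lat) == 0:
        raise ValueError("all coordinates identical: spatial term is degenerate")
    bx = pspline_basis(lon, basis_size, degree, penalty_order)
    by = pspline_basis(lat, basis_size, degree, penalty_order)
    k = basis_size
    penalty = np.kron(bx.penalty, np.eye(k)) + np.kron(np.eye(k), by.penalty)
    return DesignBlock(_row_kron(bx.matrix, by.matrix), penalty)


class BuiltTerm:
    """A term whose basis state was frozen on training data.

    ``design(table)`` evaluates the basis at new covariate values; continuous
    covariates are clamped to the training range (boundary extrapolation).
    """

    def __init__(self, spec: TermSpec, table: pd.DataFrame):
        self.spec = spec
        self.state: dict = {}
        kind = spec.kind
        if kind == "intercept":
            self.penalty = np.zeros((1, 1))
        elif kind == "linear":
            x = self._column(table, spec.covariates[0])
            sd = float(x.std())
            self.state = {"center": float(x.mean()), "scale": sd if sd > 0 else 1.0}
            self.penalty = np.zeros((1, 1))
        elif kind == "factor":
            levels = sorted(pd.unique(table[spec.covariates[0]].astype(str)))
            self.state = {"levels": levels}
            self.penalty = np.zeros((max(len(levels) - 1, 1),) * 2)
        elif kind == "pspline":
            x = self._column(table, spec.covariates[0])
            knots = _bspline_knots(float(x.min()), float(x.max()), spec.basis_size, spec.degree)
            raw = _bspline_design(x, knots, spec.degree)
            self.state = {"knots": knots, "col_means": raw.mean(axis=0)}
            self.penalty = _difference_penalty(spec.basis_size, spec.penalty_order)
        elif kind == "spatial2d":
            lon = self._column(table, spec.covariates[0])
            lat = self._column(table, spec.covariates[1])
            if np.ptp(lon) == 0 and np.ptp(lat) == 0:
                raise ValueError("all coordinates identical: spatial term is degenerate")
            kx = _bspline_knots(float(lon.min()), float(lon.max()), spec.basis_size, spec.degree)
            ky = _bspline_knots(float(lat.min()), float(lat.max()), spec.basis_size, spec.degree)
            raw = _row_kron(_bspline_design(lon, kx, spec.degree), _bspline_design(lat, ky, spec.degree))
            self.state = {"knots_lon": kx, "knots_lat": ky, "col_means": raw.mean(axis=0)}
            k = spec.basis_size
            p1 = _difference_penalty(k, spec.penalty_order)
            self.penalty = np.kron(p1, np.eye(k)) + np.kron(np.eye(k), p1)
        self.size = self.penalty.shape[0]
        nonneg = np.linalg.eigvalsh(self.penalty)
        assert nonneg.min() > -1e-8, "penalty must be PSD"

    @staticmethod
    def _column(table: pd.DataFrame, name: str) -> np.ndarray:
        if name not in table.columns:
            raise KeyError(f"covariate column {name!r} missing from table")
        x = np.asarray(table[name], dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"covariate column {name!r} contains non-finite values")
        return x

    def design(self, table: pd.DataFrame) -> np.ndarray:
        spec, n = self.spec, len(table)
        if spec.kind == "intercept":
            return np.ones((n, 1))
        if spec.kind == "linear":
            x = self._column(table, spec.covariates[0])
            return ((x - self.state["center"]) / self.state["scale"])[:, None]
        if spec.kind == "factor":
            levels = self.state["levels"]
            vals = table[spec.covariates[0]].astype(str).to_numpy()
            out = np.zeros((n, max(len(levels) - 1, 1)))
            for j, lev in enumerate(levels[1:]):
                out[:, j] = vals == lev
            return out
        if spec.kind == "pspline":
            x = self._column(table, spec.covariates[0])
            return _bspline_design(x, self.state["knots"], spec.degree) - self.state["col_means"]
        # spatial2d
        lon = self._column(table, spec.covariates[0])
        lat = self._column(table, spec.covariates[1])
        raw = _row_kron(
            _bspline_design(lon, self.state["knots_lon"], spec.degree),
            _bspline_design(lat, self.state["knots_lat"], spec.degree),
        )
        return raw - self.state["col_means"]


@dataclass
class ModelSpec:
    """Mapping from each of the 14 distributional parameters to its term list."""

    parameter_terms: dict[str, list[TermSpec]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(PARAM_LABELS) - set(self.parameter_terms)
        extra = set(self.parameter_terms) - set(PARAM_LABELS)
        if missing or extra:
            raise ValueError(
                f"parameter_terms must cover exactly the {len(PARAM_LABELS)} "
                f"distributional parameters (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        for label, terms in self.parameter_terms.items():
            if not any(t.kind == "intercept" for t in terms):
                raise ValueError(f"{label} must include an intercept term")

    @classmethod
    def intercept_only(cls) -> "ModelSpec":
        return cls({label: [intercept()] for label in PARAM_LABELS})

    @classmethod
    def with_terms(cls, extra: dict[str, list[TermSpec]]) -> "ModelSpec":
        """Intercepts everywhere plus the given per-parameter covariate terms."""
        terms = {label: [intercept()] + list(extra.get(label, [])) for label in PARAM_LABELS}
        return cls(terms)

    def to_dict(self) -> dict:
        return {
            "parameters": {
                label: [t.to_dict() for t in terms]
                for label, terms in self.parameter_terms.items()
            }
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            {
                label: [TermSpec.from_dict(t) for t in terms]
                for label, terms in d["parameters"].items()
            }
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(text))


def default_candidate_spec(
    numeric: tuple[str, ...] = ("age", "year", "wealth_code", "temperature", "malaria_incidence"),
    categorical: tuple[str, ...] = ("sex",),
    spatial: bool = True,
    basis_size: int = 20,
    spatial_basis: int = 10,
) -> ModelSpec:
    """Candidate terms for boosting: smooths for numeric covariates, a spatial
    tensor smooth and dummy factors, on every distributional parameter."""
    terms: list[TermSpec] = [pspline(c, basis_size=basis_size) for c in numeric]
    terms += [factor(c) for c in categorical]
    if spatial:
        terms.append(spatial2d(basis_size=spatial_basis))
    return ModelSpec.with_terms({label: list(terms) for label in PARAM_LABELS})


class DesignSet:
    """All built terms of a ModelSpec, with cached training designs.

    Identical TermSpecs appearing under several distributional parameters share
    one BuiltTerm (same basis state), mirroring how candidate dictionaries are
    used during boosting.
    """

    def __init__(self, spec: ModelSpec, table: pd.DataFrame):
        self.spec = spec
        self.n_train = len(table)
        cache: dict[TermSpec, BuiltTerm] = {}
        self.terms: dict[str, list[BuiltTerm]] = {}
        for label in PARAM_LABELS:
            built = []
            for ts in spec.parameter_terms[label]:
                if ts not in cache:
                    cache[ts] = BuiltTerm(ts, table)
                built.append(cache[ts])
            self.terms[label] = built
        self._train_matrices = self.matrices(table)

    def matrices(self, table: pd.DataFrame) -> dict[str, list[np.ndarray]]:
        """Design matrices for each (parameter, term) at the given table."""
        cache: dict[int, np.ndarray] = {}
        out: dict[str, list[np.ndarray]] = {}
        for label in PARAM_LABELS:
            mats = []
            for bt in self.terms[label]:
                key = id(bt)
                if key not in cache:
                    cache[key] = bt.design(table)
                mats.append(cache[key])
            out[label] = mats
        return out

    @property
    def train_matrices(self) -> dict[str, list[np.ndarray]]:
        return self._train_matrices

    def zero_coefs(self) -> dict[str, list[np.ndarray]]:
        return {
            label: [np.zeros(bt.size) for bt in self.terms[label]]
            for label in PARAM_LABELS
        }

    def evaluate_eta(
        self,
        coefs: dict[str, list[np.ndarray]],
        matrices: dict[str, list[np.ndarray]] | None = None,
    ) -> np.ndarray:
        """Stack the 14 additive predictors into an (n, 14) array."""
        mats = matrices if matrices is not None else self._train_matrices
        n = next(iter(mats.values()))[0].shape[0]
        eta = np.zeros((n, len(PARAM_LABELS)))
        for k, label in enumerate(PARAM_LABELS):
            for x, c in zip(mats[label], coefs[label]):
                eta[:, k] += x @ np.asarray(c, dtype=float)
        return eta


def eta_to_params(eta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split (n, 14) predictors into mu (n,4), lam (n,4), phi (n,4,4).

    Means and phi entries are identity-linked; lam is the log innovation scale.
    """
    eta = np.asarray(eta, dtype=float)
    mu = eta[:, : M]
    lam = eta[:, M : 2 * M]
    phi = phi_matrix(eta[:, 2 * M :])
    return mu, lam, phi


def evaluate_predictor(
    spec: ModelSpec, table: pd.DataFrame, coefs: dict[str, list[np.ndarray]]
):
    """Evaluate all 14 predictors on ``table`` and return (eta, MVNParams).

    Basis state is built on ``table`` itself; for train/predict workflows use
    :class:`DesignSet` built on the training table instead.
    """
    from .distribution import CholeskyFactors, mvn_params

    design = DesignSet(spec, table)
    eta = design.evaluate_eta(coefs)
    mu, lam, phi = eta_to_params(eta)
    return eta, mvn_params(mu, CholeskyFactors(phi=phi, lam=lam))
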