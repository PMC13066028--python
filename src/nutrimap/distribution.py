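"""Four-dimensional Gaussian response distribution with a modified-Cholesky covariance.

The joint model for the malnutrition response vector ``y = (Hb, HAZ, WAZ, WHZ)``
is a multivariate normal ``y ~ N(mu, Sigma)`` whose covariance is parameterized
through the modified Cholesky decomposition

    T Sigma T' = D**2,

where ``T = I - phi`` is unit lower triangular and ``D = diag(exp(lam))`` holds
the innovation scales.  The strictly-lower-triangular entries of ``phi`` and the
log scales ``lam`` are unconstrained reals, so every distributional parameter can
carry an additive regression predictor while Sigma stays positive definite by
construction.  For M = 4 responses this yields 4 means + 4 log scales + 6
Cholesky coefficients = 14 distributional parameters, matching the 10 unique
entries of Sigma plus the 4 means.

All functions broadcast over leading batch dimensions, so per-observation
parameter arrays of shape ``(n, M)`` / ``(n, M, M)`` work directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Fixed response ordering.  The Cholesky parameterization is order-dependent;
#: every module uses this ordering.
RESPONSES: tuple[str, ...] = ("hb", "haz", "waz", "whz")
M: int = len(RESPONSES)

MU_LABELS: tuple[str, ...] = tuple(f"mu_{r}" for r in RESPONSES)
LAM_LABELS: tuple[str, ...] = tuple(f"lam_{r}" for r in RESPONSES)
#: Row/column (1-based) labels of the free strictly-lower entries of phi.
PHI_LABELS: tuple[str, ...] = ("phi_21", "phi_31", "phi_32", "phi_41", "phi_42", "phi_43")
#: 0-based (row, col) index for each entry of PHI_LABELS.
PHI_INDEX: tuple[tuple[int, int], ...] = ((1, 0), (2, 0), (2, 1), (3, 0), (3, 1), (3, 2))

#: Flat serialization order of the 14 distributional parameters.
PARAM_LABELS: tuple[str, ...] = MU_LABELS + LAM_LABELS + PHI_LABELS

_LOG_2PI = float(np.log(2.0 * np.pi))
#: Floor on exp(lam) guarding against singular D during optimizer excursions.
LAM_FLOOR = float(np.log(1e-8))


def _check_finite(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite entries in {name}")
    return arr


@dataclass(frozen=True)
class CholeskyFactors:
    """Modified-Cholesky parameters of a covariance matrix.

    Parameters
    ----------
    phi
        ``(..., M, M)`` strictly lower triangular regression coefficients.
    lam
        ``(..., M)`` log innovation scales; ``D = diag(exp(lam))``.
    """

    phi: np.ndarray
    lam: np.ndarray

    def __post_init__(self) -> None:
        phi = _check_finite(self.phi, "phi")
        lam = _check_finite(self.lam, "lam")
        m = phi.shape[-1]
        if phi.shape[-2:] != (m, m):
            raise ValueError("phi must be square in its trailing two dimensions")
        if lam.shape[-1] != m:
            raise ValueError("lam length must match phi dimension")
        if np.any(phi[..., np.triu_indices(m)[0], np.triu_indices(m)[1]] != 0.0):
            raise ValueError("phi must be strictly lower triangular")
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "lam", np.clip(lam, LAM_FLOOR, None))

    @property
    def m(self) -> int:
        return self.phi.shape[-1]

    @classmethod
    def from_packed(cls, lam: np.ndarray, phi_packed: np.ndarray) -> "CholeskyFactors":
        """Build factors from ``lam`` (..., M) and the 6-vector of phi entries."""
        return cls(phi_matrix(phi_packed), np.asarray(lam, dtype=float))

    def packed_phi(self) -> np.ndarray:
        """Free entries of phi in the flat ordering ``PHI_LABELS``."""
        return phi_packed(self.phi)


@dataclass(frozen=True)
class MVNParams:
    """Moment parameterization implied by a mean vector and CholeskyFactors."""

    mu: np.ndarray
    sigma: np.ndarray
    sd: np.ndarray
    rho: np.ndarray


def phi_matrix(phi_packed_arr: np.ndarray) -> np.ndarray:
    """Expand packed phi entries ``(..., 6)`` into ``(..., 4, 4)`` matrices."""
    p = np.asarray(phi_packed_arr, dtype=float)
    if p.shape[-1] != len(PHI_INDEX):
        raise ValueError(f"expected {len(PHI_INDEX)} packed phi entries")
    out = np.zeros(p.shape[:-1] + (M, M))
    for k, (i, j) in enumerate(PHI_INDEX):
        out[..., i, j] = p[..., k]
    return out


def phi_packed(phi: np.ndarray) -> np.ndarray:
    """Pack the strictly-lower entries of ``(..., 4, 4)`` phi into ``(..., 6)``."""
    phi = np.asarray(phi, dtype=float)
    out = np.empty(phi.shape[:-2] + (len(PHI_INDEX),))
    for k, (i, j) in enumerate(PHI_INDEX):
        out[..., k] = phi[..., i, j]
    return out


def pack_params(mu: np.ndarray, lam: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Serialize to the flat ordering (mu_1..4, lam_1..4, phi_21..phi_43)."""
    return np.concatenate(
        [np.asarray(mu, float), np.asarray(lam, float), phi_packed(phi)], axis=-1
    )


def unpack_params(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`pack_params`; returns (mu, lam, phi-matrix)."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape[-1] != len(PARAM_LABELS):
        raise ValueError(f"expected {len(PARAM_LABELS)} parameters")
    return theta[..., :M], theta[..., M : 2 * M], phi_matrix(theta[..., 2 * M :])


def _t_matrix(factors: CholeskyFactors) -> np.ndarray:
    return np.eye(factors.m) - factors.phi


def build_sigma(factors: CholeskyFactors) -> np.ndarray:
    """Covariance Sigma solving ``T Sigma T' = D**2``.

    Computed as ``Sigma = (T^-1 D)(T^-1 D)'``, symmetric positive definite for
    any admissible factors.
    """
    t = _t_matrix(factors)
    tinv = np.linalg.inv(t)
    a = tinv * np.exp(factors.lam)[..., None, :]
    return a @ np.swapaxes(a, -1, -2)


def sigma_to_factors(sigma: np.ndarray) -> CholeskyFactors:
    """Invert :func:`build_sigma`: recover (phi, lam) from an SPD covariance.

    With ``L`` the lower Cholesky factor of Sigma, ``T = D L^-1`` where
    ``D = diag(L)``, so ``phi = I - T`` and ``lam = log diag(L)``.
    """
    sigma = _check_finite(sigma, "sigma")
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("sigma is not symmetric positive definite") from exc
    m = sigma.shape[-1]
    diag = np.diagonal(chol, axis1=-2, axis2=-1)
    t = diag[..., :, None] * np.linalg.inv(chol)
    phi = np.eye(m) - t
    phi *= np.tri(m, k=-1)  # scrub numerical residue on/above the diagonal
    return CholeskyFactors(phi=phi, lam=np.log(diag))


def mvn_params(mu: np.ndarray, factors: CholeskyFactors) -> MVNParams:
    """Moment parameters (mu, Sigma, marginal SDs, correlation matrix)."""
    mu = _check_finite(mu, "mu")
    sigma = build_sigma(factors)
    sd = np.sqrt(np.diagonal(sigma, axis1=-2, axis2=-1))
    rho = sigma / (sd[..., :, None] * sd[..., None, :])
    return MVNParams(mu=mu, sigma=sigma, sd=sd, rho=rho)


def log_density(y: np.ndarray, mu: np.ndarray, factors: CholeskyFactors) -> np.ndarray:
    """Multivariate normal log-density evaluated directly from the factors.

    Uses ``-M/2 log(2 pi) - sum(lam) - 1/2 ||D^-1 T (y - mu)||^2`` without
    forming Sigma.
    """
    y = _check_finite(y, "y")
    mu = _check_finite(mu, "mu")
    r = y - mu
    z = r - np.einsum("...ij,...j->...i", factors.phi, r)
    m = factors.m
    return (
        -0.5 * m * _LOG_2PI
        - factors.lam.sum(axis=-1)
        - 0.5 * ((z * np.exp(-factors.lam)) ** 2).sum(axis=-1)
    )


def sample(
    mu: np.ndarray,
    factors: CholeskyFactors,
    n: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw response vectors ``y = mu + T^-1 D z`` with standard normal ``z``.

    If ``mu``/``factors`` carry a leading batch dimension and ``n`` is None, one
    draw per batch element is returned.  With scalar parameters ``n`` i.i.d.
    draws are returned (``n = 0`` yields an empty array).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = _check_finite(mu, "mu")
    m = factors.m
    batch = np.broadcast_shapes(mu.shape[:-1], factors.lam.shape[:-1])
    if n is None:
        shape = batch + (m,)
    else:
        if n < 0:
            raise ValueError("sample count must be non-negative")
        shape = (int(n),) + batch + (m,)
    z = rng.standard_normal(shape)
    t = _t_matrix(factors)
    eps = np.linalg.solve(
        np.broadcast_to(t, z.shape + (m,)).copy(),
        (np.exp(factors.lam) * z)[..., None],
    )[..., 0]
    return mu + eps


def threshold_probability(
    mu_m: np.ndarray, sd_m: np.ndarray, cut: float, tail: str = "below"
) -> np.ndarray:
    """Marginal exceedance probability under the fitted Gaussian margin.

    ``P(y_m < cut)`` for ``tail='below'`` (anemia Hb<110, stunting HAZ<-2,
    underweight WAZ<-2, wasting WHZ<-2), or ``P(y_m > cut)`` for
    ``tail='above'`` (overweight z>2).
    """
    mu_m = np.asarray(mu_m, dtype=float)
    sd_m = np.asarray(sd_m, dtype=float)
    if np.any(sd_m <= 0):
        raise ValueError("marginal standard deviation must be positive")
    p = stats.norm.cdf((cut - mu_m) / sd_m)
    if tail == "below":
        return p
    if tail == "above":
        return 1.0 - p
    raise ValueError(f"tail must be 'below' or 'above', got {tail!r}")
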