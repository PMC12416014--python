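"""Box-Cox and scaled Box-Cox transformations for positive longitudinal data.

The scaled transform divides the Box-Cox transform by g^(lambda-1), where
g is the geometric mean of all N measurements. Its Jacobian is identically 1,
so maximized log-likelihoods of the transformed data are directly comparable
across lambda — the basis for profile estimation of the transformation
parameter alongside the number of mixture components.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_model import LongitudinalDataset

__all__ = [
    "TransformContext",
    "geometric_mean",
    "boxcox",
    "scaled_boxcox",
    "transform_dataset",
    "convert_estimates",
]

# |lambda| below this is treated as the log branch; continuity makes the
# cutoff inconsequential at double precision.
LAMBDA_ZERO_TOL = 1e-10


class DomainError(ValueError):
    """Nonpositive responses passed to a power transformation."""


@dataclass(frozen=True)
class TransformContext:
    """Bookkeeping for one scaled transformation: lambda, geometric mean, N.

    ``shift`` records an optional additive constant c applied as y + c before
    transforming (for data with zeros); 0 means untouched data.
    """

    lam: float
    gmean: float
    n_total: int
    shift: float = 0.0

    def to_dict(self) -> dict:
        return {"lambda": self.lam, "gmean": self.gmean, "n_total": self.n_total, "shift": self.shift}


def _check_positive(y: np.ndarray) -> None:
    if np.any(y <= 0):
        idx = int(np.flatnonzero(y <= 0)[0])
        raise DomainError(
            f"transformation requires strictly positive responses; "
            f"found y={y.flat[idx]:g} at stacked index {idx} "
            f"(consider an additive shift for data with zeros)"
        )


def geometric_mean(data: LongitudinalDataset | np.ndarray) -> float:
    """Geometric mean (prod y)^(1/N) of all measurements, in log space."""
    y = data.y_stack if isinstance(data, LongitudinalDataset) else np.asarray(data, dtype=float)
    _check_positive(y)
    return float(np.exp(np.mean(np.log(y))))


def boxcox(y: np.ndarray, lam: float) -> np.ndarray:
    """Box-Cox transform: (y^lam - 1)/lam, or log y at lam = 0."""
    y = np.asarray(y, dtype=float)
    _check_positive(y)
    if abs(lam) < LAMBDA_ZERO_TOL:
        return np.log(y)
    # y^lam via exp(lam*log y): robust for large y and fractional lam
    return np.expm1(lam * np.log(y)) / lam


def scaled_boxcox(y: np.ndarray, lam: float, gmean: float) -> np.ndarray:
    """Scaled Box-Cox transform with unit Jacobian.

    w = (y^lam - 1) / (lam * g^(lam-1)) for lam != 0, and w = g * log y at
    lam = 0; g is the geometric mean of the full sample. Strictly increasing
    in y and continuous in lam.
    """
    if gmean <= 0:
        raise DomainError("geometric mean must be positive")
    y = np.asarray(y, dtype=float)
    _check_positive(y)
    if abs(lam) < LAMBDA_ZERO_TOL:
        return gmean * np.log(y)
    return np.expm1(lam * np.log(y)) / (lam * np.exp((lam - 1.0) * np.log(gmean)))


def transform_dataset(
    data: LongitudinalDataset, lam: float, shift: float = 0.0
) -> tuple[LongitudinalDataset, TransformContext]:
    """Apply the scaled Box-Cox transform to every response of a dataset.

    The dataset's own geometric mean (after any additive ``shift``) is used.
    Structure (ids, times, p_i, labels) is unchanged; only responses move to
    the w-scale.
    """
    y = data.y_stack + shift
    _check_positive(y)
    g = float(np.exp(np.mean(np.log(y))))
    w = scaled_boxcox(y, lam, g)
    ctx = TransformContext(lam=float(lam), gmean=g, n_total=data.n_total, shift=float(shift))
    return data.with_responses(w), ctx


def convert_estimates(fit, context: TransformContext):
    """Convert w-scale mixture estimates to the plain Box-Cox scale.

    theta*_k = g^(lambda-1) theta_wk, sigma*_k = g^(lambda-1) sigma_wk,
    pi unchanged, responsibilities unchanged. Valid only for balanced data
    (all p_i equal); a slight bias is inherent to the conversion.
    """
    from .mixture_em import MixtureFit, MixtureParams  # local import avoids cycle

    if fit.p_equal is False:
        raise ValueError(
            "estimate conversion to the Box-Cox scale requires equal numbers "
            "of measurements per subject (p_1 = ... = p_n)"
        )
    scale = float(np.exp((context.lam - 1.0) * np.log(context.gmean)))
    params = MixtureParams(
        theta=fit.params.theta * scale,
        sigma2=fit.params.sigma2 * scale**2,
        pi=fit.params.pi.copy(),
    )
    return replace(fit, params=params, transform=context)
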