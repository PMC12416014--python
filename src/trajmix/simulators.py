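"""Synthetic trajectory-mixture generators.

Two study designs are built in:

* Study 1 (models M1-M3): lognormal trajectories. Each subject draws a
  latent group, then y_ij = exp(eta_k(x_j) + eps_ij) with eps ~ N(0, 0.5^2)
  on the 10-point grid x_j = (j-1)/9. Because the error sits inside the
  exponent, log y is exactly a normal mixture and the nominal Box-Cox
  parameter is lambda = 0.
* Study 2 (setups S1-S4): two linear mean curves {1, 1 + 2 x_j} on the
  6-point grid x_j = (j-1)/5 with additive skewed errors
  eps ~ Gamma(shape 2, scale 1); sample size and mixing proportions vary
  by setup (S1: n=200 pi=.5/.5, S2: n=200 pi=.8/.2, S3: n=500 pi=.5/.5,
  S4: n=500 pi=.8/.2).

All randomness flows through numpy's default PCG64 generator seeded
explicitly, so a (scenario, seed) pair reproduces a dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .data_model import LongitudinalDataset

__all__ = [
    "Scenario",
    "simulate_custom",
    "simulate_study1",
    "simulate_study2",
    "STUDY1_MODELS",
    "STUDY2_SETUPS",
]


@dataclass
class Scenario:
    """Full specification of one trajectory-mixture generator."""

    name: str
    n_subjects: int
    time_grid: np.ndarray
    mean_functions: Sequence[Callable[[np.ndarray], np.ndarray]]
    proportions: Sequence[float]
    noise: tuple  # ("normal", sd) or ("gamma", shape, scale)
    link: str = "identity"  # response = link(eta + eps)

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        pi = np.asarray(self.proportions, dtype=float)
        if len(pi) != len(self.mean_functions):
            raise ValueError("one proportion per mean function required")
        if not np.isclose(pi.sum(), 1.0, atol=1e-12):
            raise ValueError(f"mixing proportions must sum to 1, got {pi.sum()}")
        if np.any(pi <= 0):
            raise ValueError("mixing proportions must be positive")
        if self.link not in ("identity", "exp"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.noise[0] not in ("normal", "gamma", "none"):
            raise ValueError(f"unknown noise family {self.noise[0]!r}")
        self.proportions = pi

    @property
    def K(self) -> int:
        return len(self.mean_functions)


def _study1_scenario(model: str, n: int) -> Scenario:
    x = (np.arange(1, 11) - 1) / 9.0
    means = {
        "M1": [lambda t: 1.0 + 0.2 * t],
        "M2": [lambda t: 1.0 + 0.0 * t, lambda t: 1.0 + t],
        "M3": [lambda t: 1.0 + 0.0 * t, lambda t: 1.0 + t, lambda t: 1.0 + t + t**2],
    }
    pis = {"M1": [1.0], "M2": [0.6, 0.4], "M3": [0.5, 0.3, 0.2]}
    if model not in means:
        raise ValueError(f"unknown study-1 model {model!r}; expected M1, M2 or M3")
    return Scenario(
        name=model,
        n_subjects=n,
        time_grid=x,
        mean_functions=means[model],
        proportions=pis[model],
        noise=("normal", 0.5),
        link="exp",
    )


def _study2_scenario(setup: str) -> Scenario:
    x = (np.arange(1, 7) - 1) / 5.0
    registry = {  # setup -> (n, pi1, pi2)
        "S1": (200, 0.5, 0.5),
        "S2": (200, 0.8, 0.2),
        "S3": (500, 0.5, 0.5),
        "S4": (500, 0.8, 0.2),
    }
    if setup not in registry:
        raise ValueError(f"unknown study-2 setup {setup!r}; expected S1..S4")
    n, p1, p2 = registry[setup]
    return Scenario(
        name=setup,
        n_subjects=n,
        time_grid=x,
        mean_functions=[lambda t: 1.0 + 0.0 * t, lambda t: 1.0 + 2.0 * t],
        proportions=[p1, p2],
        noise=("gamma", 2.0, 1.0),
        link="identity",
    )


STUDY1_MODELS = ("M1", "M2", "M3")
STUDY2_SETUPS = ("S1", "S2", "S3", "S4")


def simulate_custom(scenario: Scenario, seed: int) -> LongitudinalDataset:
    """Draw one dataset from an arbitrary trajectory-mixture scenario.

    Draw order is fixed (labels for all subjects, then the full error
    matrix), so equal (scenario, seed) pairs reproduce draw-for-draw.
    """
    rng = np.random.default_rng(seed)
    n, grid = scenario.n_subjects, scenario.time_grid
    p = len(grid)
    labels = rng.choice(scenario.K, size=n, p=scenario.proportions)
    kind = scenario.noise[0]
    if kind == "normal":
        eps = rng.normal(0.0, scenario.noise[1], size=(n, p))
    elif kind == "gamma":
        eps = rng.gamma(scenario.noise[1], scenario.noise[2], size=(n, p))
    else:
        eps = np.zeros((n, p))
    eta = np.stack([f(grid) + np.zeros(p) for f in scenario.mean_functions])  # (K, p)
    y = eta[labels] + eps
    if scenario.link == "exp":
        y = np.exp(y)
    return LongitudinalDataset(
        subject_ids=list(range(n)),
        times=[grid.copy() for _ in range(n)],
        responses=list(y),
        true_labels=labels,
    )


def simulate_study1(model: str, n: int = 200, seed: int = 0) -> LongitudinalDataset:
    """One replicate of study-1 model M1, M2 or M3 (lognormal mixtures)."""
    return simulate_custom(_study1_scenario(model, n), seed)


def simulate_study2(setup: str, seed: int = 0) -> LongitudinalDataset:
    """One replicate of study-2 setup S1..S4 (Gamma-error two-cluster mixtures)."""
    return simulate_custom(_study2_scenario(setup), seed)
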