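"""Substitution and rate models.

Two families of substitution model are supported:

* empirical amino-acid models (WAG, Dayhoff, BLOSUM62) built from published
  exchangeability matrices and equilibrium frequencies shipped as data
  files;
* the two-state "restriction" model for gene detection/non-detection
  characters, with free stationary frequencies.

Rate heterogeneity across sites uses the discrete-gamma approximation
(equal-probability categories, category rate = conditional mean).  A
covarion extension doubles the state space with hidden ON/OFF classes:
OFF states are frozen, ON states evolve under the base model, and sites
switch between the classes at rates ``s_on`` (OFF to ON) and ``s_off``
(ON to OFF).  Branch lengths are expected substitutions per site for a
site in the ON class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.stats import gamma as _gamma_dist

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

_EMPIRICAL_FILES = {
    "WAG": "wag.dat",
    "DAYHOFF": "dayhoff.dat",
    "BLOSUM62": "blosum62.dat",
}


@dataclass
class SubstitutionModel:
    """Normalized reversible rate matrix with stationary frequencies."""

    kind: str  # "binary-restriction" | "empirical-aa"
    name: str
    freqs: np.ndarray
    rate_matrix: np.ndarray  # rows sum to 0; -sum(pi_i * Q_ii) == 1

    @property
    def n_states(self) -> int:
        return len(self.freqs)

    def __post_init__(self) -> None:
        if not np.isclose(self.freqs.sum(), 1.0):
            raise ValueError("frequencies must sum to 1")
        if not np.allclose(self.rate_matrix.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("rate matrix rows must sum to 0")


def _normalize(Q: np.ndarray, pi: np.ndarray) -> np.ndarray:
    mu = -np.sum(pi * np.diag(Q))
    return Q / mu


def _read_empirical(name: str) -> tuple[np.ndarray, np.ndarray]:
    fn = _EMPIRICAL_FILES[name]
    text = resources.files("dogphylo.data").joinpath(fn).read_text()
    rows = [
        [float(x) for x in line.split()]
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    S = np.zeros((20, 20))
    for i, row in enumerate(rows[:19], start=1):
        S[i, : len(row)] = row
    S = S + S.T
    pi = np.asarray(rows[19])
    pi = pi / pi.sum()
    return S, pi


def empirical_aa_model(name: str) -> SubstitutionModel:
    """Load one of the shipped empirical amino-acid models by name."""
    key = name.upper().replace("BLOSSUM", "BLOSUM")
    if key == "BLOSUM":
        key = "BLOSUM62"
    if key not in _EMPIRICAL_FILES:
        raise ValueError(
            f"unknown amino-acid model {name!r}; choose from "
            f"{sorted(_EMPIRICAL_FILES)}"
        )
    S, pi = _read_empirical(key)
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return SubstitutionModel("empirical-aa", key, pi, _normalize(Q, pi))


def binary_restriction_model(pi1: float = 0.5) -> SubstitutionModel:
    """Two-state presence/absence model; ``pi1`` = stationary presence freq."""
    if not 0.0 < pi1 < 1.0:
        raise ValueError("pi1 must be in (0, 1)")
    pi = np.array([1.0 - pi1, pi1])
    Q = np.array([[-pi[1], pi[1]], [pi[0], -pi[0]]])
    return SubstitutionModel("binary-restriction", "restriction", pi, _normalize(Q, pi))


# ---------------------------------------------------------------------------
# Rate heterogeneity


def discretize_gamma(shape: float, k: int) -> np.ndarray:
    """Equal-probability discrete-gamma category rates (mean exactly 1).

    Rates are the conditional means of a Gamma(shape, rate=shape) variable
    within its k equal-probability quantile bins.
    """
    if shape <= 0:
        raise ValueError("shape must be > 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.array([1.0])
    edges = _gamma_dist.ppf(np.arange(1, k) / k, shape, scale=1.0 / shape)
    # E[X; bin] via the shape+1 cdf identity for Gamma(a, rate a)
    upper = _gamma_dist.cdf(edges, shape + 1.0, scale=1.0 / shape)
    cum = np.concatenate([[0.0], upper, [1.0]])
    rates = k * np.diff(cum)
    return rates / rates.mean()


@dataclass
class RateModel:
    """Discrete-gamma rate categories plus optional covarion switching."""

    shape: float = 1.0
    n_categories: int = 4
    covarion: tuple[float, float] | None = None  # (s_on, s_off)
    rates: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.rates = discretize_gamma(self.shape, self.n_categories)
        if self.covarion is not None:
            s_on, s_off = self.covarion
            if s_on < 0 or s_off < 0 or (s_on + s_off) <= 0:
                raise ValueError("covarion switch rates must be >= 0, not both 0")

    def with_shape(self, shape: float) -> "RateModel":
        return RateModel(shape, self.n_categories, self.covarion)


def covarion_matrix(
    model: SubstitutionModel, rate: float, s_on: float, s_off: float
) -> tuple[np.ndarray, np.ndarray]:
    """Doubled-state rate matrix and stationary freqs for the covarion model.

    State order: (s0..sk ON, s0..sk OFF).  The ON block is ``rate * Q``;
    OFF states do not substitute.  No renormalization is applied, so in the
    limit of vanishing switch rates with an all-ON root the model reduces
    exactly to the base model.
    """
    n = model.n_states
    Q = np.zeros((2 * n, 2 * n))
    Q[:n, :n] = rate * model.rate_matrix
    idx = np.arange(n)
    Q[idx, idx + n] += s_off
    Q[idx + n, idx] += s_on
    Q[idx, idx] -= s_off
    Q[idx + n, idx + n] -= s_on
    f_on = s_on / (s_on + s_off)
    pi = np.concatenate([model.freqs * f_on, model.freqs * (1.0 - f_on)])
    return Q, pi
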