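"""QAOA feature selection over a relevance/redundancy QUBO.

The selection objective is an mRMR-style quadratic cost over binary
inclusion variables :math:`z \\in \\{0,1\\}^n`:

.. math::

    C(z) = -\\sum_i r_i z_i
           + \\alpha \\sum_{i<j} \\rho_{ij} z_i z_j
           + \\beta \\Big(\\sum_i z_i - k\\Big)^2

where ``r`` is per-feature relevance (|point-biserial correlation| with the
label), ``rho`` is pairwise redundancy (|Pearson correlation|), and the last
term softly pins the subset size at ``k``.  The cost is a diagonal
Hamiltonian, so QAOA layers are simulated exactly: a per-basis-state phase
``exp(-i*gamma*C(z))`` followed by the transverse-field mixer ``RX(2*beta)``
on every qubit.  A brute-force enumerator doubles as verification oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from . import statevec as sv

MAX_EXACT_QUBITS = 20


# --------------------------------------------------------------------------
# score table
# --------------------------------------------------------------------------


@dataclass
class ScoreTable:
    """Per-feature relevance and pairwise redundancy, both in [0, 1]."""

    relevance: np.ndarray  # (n,)
    redundancy: np.ndarray  # (n, n), symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.relevance = np.asarray(self.relevance, dtype=float)
        self.redundancy = np.asarray(self.redundancy, dtype=float)
        n = self.relevance.shape[0]
        if self.redundancy.shape != (n, n):
            raise ValueError("redundancy matrix shape does not match relevance")
        if not np.allclose(self.redundancy, self.redundancy.T):
            raise ValueError("redundancy matrix must be symmetric")
        if np.any(np.diag(self.redundancy) != 0):
            raise ValueError("redundancy diagonal must be zero")
        if not (np.all(np.isfinite(self.relevance)) and np.all(np.isfinite(self.redundancy))):
            raise ValueError("scores must be finite")

    @property
    def n(self) -> int:
        return self.relevance.shape[0]


def _safe_abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    """|Pearson r|, defined as 0 when either vector is constant."""
    sa = a.std()
    sb = b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return min(abs(r), 1.0)


def score_features(X: np.ndarray, y: Sequence[int]) -> ScoreTable:
    """Relevance = |point-biserial corr(X_i, y)|; redundancy = |corr(X_i, X_j)|.

    Point-biserial correlation is Pearson correlation against the 0/1 label,
    so both statistics share one code path.  Constant features get 0 by
    convention rather than NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(np.isnan(X)):
        raise ValueError("score_features requires a complete matrix (impute first)")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; relevance is undefined")
    n = X.shape[1]
    r = np.array([_safe_abs_corr(X[:, i], y) for i in range(n)])
    rho = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rho[i, j] = rho[j, i] = _safe_abs_corr(X[:, i], X[:, j])
    return ScoreTable(relevance=r, redundancy=rho)


# --------------------------------------------------------------------------
# QUBO
# --------------------------------------------------------------------------


@dataclass
class QuboProblem:
    """cost(z) = c + sum_i h_i z_i + sum_{i<j} J_ij z_i z_j."""

    n: int
    h: np.ndarray  # (n,)
    J: np.ndarray  # (n, n), upper-triangular
    c: float = 0.0

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        if self.h.shape != (self.n,) or self.J.shape != (self.n, self.n):
            raise ValueError("coefficient shapes do not match n")
        if np.any(np.tril(self.J, -1) != 0):
            raise ValueError("J must be upper-triangular")

    def cost(self, z: Sequence[int]) -> float:
        z = np.asarray(z, dtype=float)
        return float(self.c + self.h @ z + z @ self.J @ z)

    def all_costs(self) -> np.ndarray:
        """Cost of every bitstring, indexed by basis state (qubit 0 = LSB)."""
        if self.n > MAX_EXACT_QUBITS:
            raise ValueError(f"exact enumeration limited to n <= {MAX_EXACT_QUBITS}")
        idx = np.arange(2**self.n)
        bits = ((idx[:, None] >> np.arange(self.n)) & 1).astype(float)  # (2^n, n)
        quad = np.einsum("zi,ij,zj->z", bits, self.J, bits)
        return self.c + bits @ self.h + quad

    def to_csv(self, path) -> None:
        """3-column export: i, j, coefficient (i = j rows are linear terms)."""
        rows = ["i,j,coefficient"]
        for i in range(self.n):
            rows.append(f"{i},{i},{float(self.h[i])!r}")
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if self.J[i, j] != 0:
                    rows.append(f"{i},{j},{float(self.J[i, j])!r}")
        with open(path, "w") as fh:
            fh.write("\n".join(rows) + "\n")


def build_qubo(scores: ScoreTable, k: int, alpha: float = 0.25, beta: float | None = None) -> QuboProblem:
    """Expand the selection cost into explicit h, J, c coefficients.

    Using z^2 = z, the cardinality penalty beta*(sum z - k)^2 contributes
    beta*(1 - 2k) to every linear term, 2*beta to every pairwise term, and
    beta*k^2 to the constant.  ``beta`` defaults to 2*max(relevance) so the
    soft constraint dominates any single relevance gain.
    """
    n = scores.n
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    if beta is None:
        beta = 2.0 * float(np.max(scores.relevance)) if n else 0.0
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be nonnegative")
    h = -scores.relevance + beta * (1.0 - 2.0 * k)
    J = np.triu(alpha * scores.redundancy + 2.0 * beta, k=1)
    return QuboProblem(n=n, h=h, J=J, c=beta * float(k) ** 2)


# --------------------------------------------------------------------------
# QAOA simulation
# --------------------------------------------------------------------------


@dataclass
class QaoaConfig:
    p: int = 3
    restarts: int = 8
    max_iter: int = 400
    n_samples: int = 512
    seed: int = 0
    mode: str = "exact"  # or "sampled"

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.mode not in ("exact", "sampled"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class FeatureSubset:
    indices: list[int]
    cost: float
    provenance: str  # qaoa | brute_force | greedy

    def __post_init__(self) -> None:
        if sorted(set(self.indices)) != sorted(self.indices):
            raise ValueError("indices must be unique")
        self.indices = sorted(self.indices)

    def to_json(self, path, *, seed: int | None = None, config: dict | None = None) -> None:
        payload = {"indices": self.indices, "cost": self.cost, "provenance": self.provenance}
        if seed is not None:
            payload["seed"] = seed
        if config is not None:
            payload["config"] = config
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _bits_to_indices(z_index: int, n: int) -> list[int]:
    return [i for i in range(n) if (z_index >> i) & 1]


def qaoa_state(q: QuboProblem, gammas: Sequence[float], betas: Sequence[float], p: int | None = None) -> np.ndarray:
    """Alternating cost-phase / mixer evolution from the uniform state.

    The cost Hamiltonian is diagonal, so each gamma layer is an elementwise
    phase exp(-i*gamma*cost(z)); each beta layer is RX(2*beta) on every qubit.
    """
    gammas = np.asarray(gammas, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if p is None:
        p = len(gammas)
    if len(gammas) != p or len(betas) != p:
        raise ValueError("gammas and betas must both have length p")
    costs = q.all_costs()
    state = sv.uniform_state(q.n)
    for g, b in zip(gammas, betas):
        state = state * np.exp(-1j * g * costs)
        gate = sv.rx_gate(b)
        for qubit in range(q.n):
            state = sv.apply_single_qubit(state, gate, qubit)
    return state


def qaoa_expectation(q: QuboProblem, state: np.ndarray) -> float:
    """<H_C> = sum_z |amp_z|^2 * cost(z)."""
    costs = q.all_costs()
    if state.shape[-1] != costs.shape[0]:
        raise ValueError("state dimension does not match QUBO size")
    return float(np.abs(state) ** 2 @ costs)


def optimize_qaoa(
    q: QuboProblem,
    config: QaoaConfig,
    init: tuple[Sequence[float], Sequence[float]] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Nelder-Mead over the 2p angles with seeded random restarts.

    The all-zero angle point (uniform state) is always included as a start,
    so the optimum can never exceed the uniform-state cost mean.  ``init``
    optionally adds a warm start, e.g. a padded layer-(p-1) optimum.
    """
    p = config.p
    rng = np.random.default_rng(config.seed)
    costs = q.all_costs()

    def objective(angles: np.ndarray) -> float:
        state = qaoa_state(q, angles[:p], angles[p:], p)
        return float(np.abs(state) ** 2 @ costs)

    starts = [np.zeros(2 * p)]
    if init is not None:
        g0, b0 = init
        starts.append(np.concatenate([np.asarray(g0, float), np.asarray(b0, float)]))
    for _ in range(config.restarts):
        starts.append(rng.uniform(0.0, 2.0 * np.pi, size=2 * p))

    best_angles, best_val = starts[0], objective(starts[0])
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"maxiter": config.max_iter, "xatol": 1e-4, "fatol": 1e-7},
        )
        if res.fun < best_val:
            best_val = float(res.fun)
            best_angles = res.x
    # note: angles are reported as optimized, not wrapped mod 2*pi — the
    # cost phase exp(-i*gamma*C(z)) is only 2*pi-periodic in gamma when all
    # costs are integers, so wrapping would change the state
    return best_angles[:p], best_angles[p:], best_val


def sample_subset(q: QuboProblem, state: np.ndarray, config: QaoaConfig) -> FeatureSubset:
    """Extract a subset from the final QAOA state.

    exact mode: best-cost bitstring among basis states whose probability is
    at least 1/2^(n+2); sampled mode: best of ``n_samples`` measurement
    draws.  Ties break toward the smallest basis index, i.e. the
    lexicographically smallest bitstring read from qubit 0 up.
    """
    probs = np.abs(state) ** 2
    costs = q.all_costs()
    if config.mode == "exact":
        eligible = np.flatnonzero(probs >= 1.0 / 2 ** (q.n + 2))
        if eligible.size == 0:  # pathological; fall back to the modal state
            eligible = np.array([int(np.argmax(probs))])
        order = np.lexsort((eligible, costs[eligible]))
        z = int(eligible[order[0]])
    else:
        rng = np.random.default_rng(config.seed)
        draws = rng.choice(probs.size, size=config.n_samples, p=probs / probs.sum())
        draws = np.unique(draws)
        order = np.lexsort((draws, costs[draws]))
        z = int(draws[order[0]])
    return FeatureSubset(indices=_bits_to_indices(z, q.n), cost=float(costs[z]), provenance="qaoa")


def brute_force_select(q: QuboProblem) -> FeatureSubset:
    """Exhaustive global minimum; the oracle everything else is checked against."""
    if q.n > MAX_EXACT_QUBITS:
        raise ValueError(f"brute force limited to n <= {MAX_EXACT_QUBITS} features")
    costs = q.all_costs()
    z = int(np.lexsort((np.arange(costs.size), costs))[0])
    return FeatureSubset(indices=_bits_to_indices(z, q.n), cost=float(costs[z]), provenance="brute_force")


def select_features(
    X: np.ndarray,
    y: Sequence[int],
    k: int,
    config: QaoaConfig | None = None,
    alpha: float = 0.25,
    beta: float | None = None,
) -> tuple[FeatureSubset, QuboProblem]:
    """score -> QUBO -> QAOA -> subset, the full selection stage."""
    config = config or QaoaConfig()
    scores = score_features(X, y)
    qubo = build_qubo(scores, k=k, alpha=alpha, beta=beta)
    gammas, betas, _ = optimize_qaoa(qubo, config)
    state = qaoa_state(qubo, gammas, betas)
    return sample_subset(qubo, state, config), qubo
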