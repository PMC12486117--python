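"""Angle encoding and the variational quantum circuit (VQC).

Each selected feature value, rescaled to [0, pi], becomes a single-qubit
rotation: ``|x> = prod_i (cos(x_i/2)|0> + sin(x_i/2)|1>)``.  A depth-``L``
hardware-efficient ansatz follows — per layer, RY then RZ on every qubit and
a CNOT entangler (ring or line) — and the per-qubit Pauli-Z expectations of
the final state are the quantum-derived features ``z_q``, each in [-1, 1].

Gradients of ``z_q`` with respect to the circuit angles use the
parameter-shift rule, exact for RY/RZ generators:
``d<Z>/d(theta) = (<Z>(theta + pi/2) - <Z>(theta - pi/2)) / 2``.

All functions accept a single sample ``(Q,)`` or a batch ``(B, Q)``; the
statevector math is vectorised over the batch axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import statevec as sv


@dataclass
class VqcConfig:
    Q: int = 10
    L: int = 6
    entangler: str = "ring"  # or "line"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.Q <= 14:
            raise ValueError("Q must lie in [1, 14]")
        if self.L < 0:
            raise ValueError("L must be >= 0")
        if self.entangler not in ("ring", "line"):
            raise ValueError(f"unknown entangler {self.entangler!r}")


def init_params(config: VqcConfig) -> np.ndarray:
    """theta ~ N(0, 0.1^2), shape [L][Q][2] (RY angle then RZ angle)."""
    rng = np.random.default_rng(config.seed)
    return rng.normal(0.0, 0.1, size=(config.L, config.Q, 2))


@dataclass
class AngleScaler:
    """Min-max map of raw feature values onto rotation angles in [0, pi].

    Fitted on the training split only; out-of-range test values clip to the
    interval ends, and a degenerate (constant) feature maps to pi/2.
    """

    min_: np.ndarray
    max_: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "AngleScaler":
        X = np.asarray(X, dtype=float)
        return cls(min_=X.min(axis=0), max_=X.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.max_ - self.min_
        with np.errstate(divide="ignore", invalid="ignore"):
            angles = np.pi * (X - self.min_) / span
        angles = np.where(span == 0, np.pi / 2, angles)
        return np.clip(angles, 0.0, np.pi)


def scale_to_angles(X: np.ndarray, scaler: AngleScaler) -> np.ndarray:
    return scaler.transform(X)


def angle_encode(x: np.ndarray) -> np.ndarray:
    """Product state with real nonnegative amplitudes; x_i in [0, pi]."""
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-12) or np.any(x > np.pi + 1e-12):
        raise ValueError("angles must lie in [0, pi]; rescale first")
    single = x.ndim == 1
    xb = np.atleast_2d(x)
    B, Q = xb.shape
    # qubit 0 is the least-significant bit of the basis index, so it must
    # vary fastest: fold qubits in ascending order, each new qubit becoming
    # the most significant bit of the partial product
    state = np.ones((B, 1), dtype=np.complex128)
    for q in range(Q):
        amp = np.stack([np.cos(xb[:, q] / 2), np.sin(xb[:, q] / 2)], axis=1)  # (B, 2)
        state = (amp[:, :, None] * state[:, None, :]).reshape(B, -1)
    return state[0] if single else state


def _apply_layer(state: np.ndarray, layer_params: np.ndarray, config: VqcConfig) -> np.ndarray:
    """One ansatz layer: RY then RZ on every qubit, then the entangler."""
    for q in range(config.Q):
        state = sv.apply_single_qubit(state, sv.ry_gate(layer_params[q, 0]), q)
        state = sv.apply_single_qubit(state, sv.rz_gate(layer_params[q, 1]), q)
    if config.Q > 1:
        last = config.Q if config.entangler == "ring" else config.Q - 1
        for q in range(last):
            state = sv.apply_cnot(state, q, (q + 1) % config.Q)
    return state


def apply_vqc(state: np.ndarray, params: np.ndarray, config: VqcConfig) -> np.ndarray:
    """Per layer: RY(theta[l][q][0]) then RZ(theta[l][q][1]) on every qubit,
    then the CNOT entangler (ring: control q -> target (q+1) mod Q; line
    omits the wrap; a single qubit skips entanglement)."""
    params = np.asarray(params, dtype=float)
    if state.shape[-1] != 2**config.Q:
        raise ValueError("state dimension does not match config.Q")
    if params.shape != (config.L, config.Q, 2):
        raise ValueError(f"params shape {params.shape} != {(config.L, config.Q, 2)}")
    for layer in range(config.L):
        state = _apply_layer(state, params[layer], config)
    return state


def measure_expectations(state: np.ndarray) -> np.ndarray:
    """z_q[i] = <Z_i>; requires a normalized state."""
    sv.check_normalized(state)
    return sv.pauli_z_expectations(state)


def quantum_embed(x: np.ndarray, params: np.ndarray, config: VqcConfig) -> np.ndarray:
    """measure(apply_vqc(angle_encode(x))) — the full quantum feature map."""
    return measure_expectations(apply_vqc(angle_encode(x), params, config))


def save_vqc_params(path, theta: np.ndarray, config: VqcConfig) -> None:
    """Serialize circuit angles + config as JSON (angles reported mod 2*pi)."""
    import json
    from dataclasses import asdict

    payload = {"config": asdict(config), "theta": np.mod(theta, 2 * np.pi).tolist()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def load_vqc_params(path) -> tuple[np.ndarray, VqcConfig]:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    cfg = VqcConfig(**payload["config"])
    theta = np.asarray(payload["theta"], dtype=float).reshape(cfg.L, cfg.Q, 2)
    return theta, cfg


def parameter_shift_grad(
    x: np.ndarray,
    params: np.ndarray,
    config: VqcConfig,
    upstream: np.ndarray,
) -> np.ndarray:
    """Gradient of ``sum(upstream * z_q)`` w.r.t. theta by parameter shift.

    ``upstream`` is dLoss/dz_q: shape (Q,) for one sample or (B, Q) for a
    batch (summed over the batch, matching a summed loss).  Each angle needs
    two embeddings at theta +/- pi/2; the encoded input state is reused.
    """
    params = np.asarray(params, dtype=float)
    x = np.asarray(x, dtype=float)
    upstream = np.asarray(upstream, dtype=float)
    if upstream.shape[-1] != config.Q:
        raise ValueError("upstream must have length Q")
    grad = np.zeros_like(params)
    if params.size == 0 or not np.any(upstream):
        return grad
    # cache the state entering each layer once; a shift at layer l only
    # requires re-simulating layers l..L-1 from the cached prefix
    prefix = [angle_encode(x)]
    for layer in range(config.L):
        prefix.append(_apply_layer(prefix[-1], params[layer], config))
    for layer in range(config.L):
        for q in range(config.Q):
            for axis in range(2):
                z_shift = []
                for delta in (np.pi / 2, -np.pi / 2):
                    lp = params[layer].copy()
                    lp[q, axis] += delta
                    state = _apply_layer(prefix[layer], lp, config)
                    for rest in range(layer + 1, config.L):
                        state = _apply_layer(state, params[rest], config)
                    z_shift.append(measure_expectations(state))
                dz = (z_shift[0] - z_shift[1]) / 2.0
                grad[layer, q, axis] = float(np.sum(upstream * dz))
    return grad
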