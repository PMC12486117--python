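"""Exact statevector arithmetic shared by the QAOA and VQC simulators.

States over ``n`` qubits are complex arrays whose last axis has length
``2**n``.  Qubit 0 is the least-significant bit of the basis index, and a
basis bit of 1 means "feature selected" (QAOA) or the :math:`|1\\rangle`
rotation branch (VQC).  Leading axes, when present, are batch axes: every
gate application below is vectorised over them, which is what makes
parameter-shift training affordable at 10 qubits.
"""

from __future__ import annotations

import numpy as np

NORM_ATOL = 1e-9


def n_qubits(state: np.ndarray) -> int:
    dim = state.shape[-1]
    n = int(round(np.log2(dim)))
    if 2**n != dim:
        raise ValueError(f"state dimension {dim} is not a power of two")
    return n


def uniform_state(n: int) -> np.ndarray:
    """|+>^n — the QAOA initial state."""
    return np.full(2**n, 2 ** (-n / 2), dtype=np.complex128)


def basis_state(n: int, index: int) -> np.ndarray:
    sv = np.zeros(2**n, dtype=np.complex128)
    sv[index] = 1.0
    return sv


def norm(state: np.ndarray) -> np.ndarray:
    return np.sqrt(np.sum(np.abs(state) ** 2, axis=-1))


def check_normalized(state: np.ndarray, atol: float = 1e-6) -> None:
    err = np.max(np.abs(norm(state) - 1.0))
    if err > atol:
        raise ValueError(f"state is not normalized (|norm - 1| = {err:.3g})")


def apply_single_qubit(state: np.ndarray, gate: np.ndarray, qubit: int) -> np.ndarray:
    """Apply a 2x2 gate on ``qubit``; vectorised over leading batch axes."""
    n = n_qubits(state)
    if not 0 <= qubit < n:
        raise ValueError(f"qubit {qubit} out of range for {n} qubits")
    lead = state.shape[:-1]
    # axis layout: (..., high bits, this bit, low bits)
    resh = state.reshape(*lead, 2 ** (n - qubit - 1), 2, 2**qubit)
    a0 = resh[..., 0, :]
    a1 = resh[..., 1, :]
    out = np.empty_like(resh)
    out[..., 0, :] = gate[0, 0] * a0 + gate[0, 1] * a1
    out[..., 1, :] = gate[1, 0] * a0 + gate[1, 1] * a1
    return out.reshape(*lead, 2**n)


def apply_cnot(state: np.ndarray, control: int, target: int) -> np.ndarray:
    """CNOT: flip ``target`` bit on basis states whose ``control`` bit is 1."""
    n = n_qubits(state)
    if control == target:
        raise ValueError("control and target must differ")
    idx = np.arange(2**n)
    perm = np.where((idx >> control) & 1 == 1, idx ^ (1 << target), idx)
    return state[..., perm]


def rx_gate(beta: float) -> np.ndarray:
    """RX(2*beta) = exp(-i beta X), the transverse-field QAOA mixer step."""
    c, s = np.cos(beta), np.sin(beta)
    return np.array([[c, -1j * s], [-1j * s, c]], dtype=np.complex128)


def ry_gate(theta: float) -> np.ndarray:
    c, s = np.cos(theta / 2), np.sin(theta / 2)
    return np.array([[c, -s], [s, c]], dtype=np.complex128)


def rz_gate(theta: float) -> np.ndarray:
    return np.array(
        [[np.exp(-0.5j * theta), 0.0], [0.0, np.exp(0.5j * theta)]],
        dtype=np.complex128,
    )


def pauli_z_expectations(state: np.ndarray) -> np.ndarray:
    """Per-qubit <Z_i>; last output axis indexes qubits (length n)."""
    n = n_qubits(state)
    probs = np.abs(state) ** 2
    idx = np.arange(2**n)
    out = np.empty(state.shape[:-1] + (n,))
    for q in range(n):
        sign = 1.0 - 2.0 * ((idx >> q) & 1)
        out[..., q] = probs @ sign
    return out
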