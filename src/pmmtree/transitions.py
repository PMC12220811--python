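"""Transition structure of the two-layer mixed-type missing model.

Layer 1 is an irreversible continuous-time Markov chain per target site over
{0, 1..M, -1}: the unedited state 0 mutates to outcome m at rate q_m and
silences at rate nu; mutated states can only silence (rate nu); the silent
state -1 is absorbing.  Layer 2 is applied once, at the leaves: any non-silent
state drops out to "?" with probability phi, silent is always read as "?".

All matrices here are small dense numpy arrays with rows/columns ordered
``[0, m_1, ..., m_M, -1]`` (and an extra trailing "?" column for the dropout
matrix).  The closed-form edge transition probabilities are

    Psi(0, 0)  = exp(-d (1 + nu))
    Psi(0, m)  = q_m exp(-nu d) (1 - exp(-d))
    Psi(0, -1) = 1 - exp(-nu d)
    Psi(m, m)  = exp(-nu d)
    Psi(m, -1) = 1 - exp(-nu d)
    Psi(-1,-1) = 1

with d the edge length in mutation units; they equal expm(Q d) of the rate
matrix below (checked against scipy's matrix exponential in the test suite).
"""

from __future__ import annotations

import numpy as np

from .data import SiteAlphabet, ValidationError


def state_order(alphabet: SiteAlphabet) -> list[int]:
    """Row/column order used by all matrices: 0, mutated states, -1."""
    return [0, *alphabet.mutated_states, -1]


def site_rate_matrix(alphabet: SiteAlphabet, nu: float) -> np.ndarray:
    """Rate matrix Q of the layer-1 chain over {0, 1..M, -1}."""
    if nu < 0:
        raise ValidationError(f"nu must be >= 0, got {nu}")
    M = alphabet.n_mutated
    q = np.array([alphabet.priors[s] for s in alphabet.mutated_states])
    Q = np.zeros((M + 2, M + 2))
    Q[0, 1 : M + 1] = q
    Q[0, M + 1] = nu
    Q[0, 0] = -(1.0 + nu)
    for i in range(1, M + 1):
        Q[i, M + 1] = nu
        Q[i, i] = -nu
    return Q


def transition_matrix(delta: float, nu: float, alphabet: SiteAlphabet) -> np.ndarray:
    """Edge transition probabilities Psi = expm(Q * delta), in closed form."""
    if delta < 0:
        raise ValidationError(f"delta must be >= 0, got {delta}")
    if nu < 0:
        raise ValidationError(f"nu must be >= 0, got {nu}")
    M = alphabet.n_mutated
    q = np.array([alphabet.priors[s] for s in alphabet.mutated_states])
    keep = np.exp(-nu * delta)          # probability of not silencing
    stay0 = np.exp(-delta * (1.0 + nu))
    P = np.zeros((M + 2, M + 2))
    P[0, 0] = stay0
    P[0, 1 : M + 1] = q * keep * (1.0 - np.exp(-delta))
    P[0, M + 1] = 1.0 - keep
    for i in range(1, M + 1):
        P[i, i] = keep
        P[i, M + 1] = 1.0 - keep
    P[M + 1, M + 1] = 1.0
    return P


def dropout_matrix(phi: float, alphabet: SiteAlphabet) -> np.ndarray:
    """Leaf-only sequencing layer: rows over {0, 1..M, -1}, columns add "?".

    Column order is ``[0, m_1..m_M, ?]`` -- the silent state is not
    observable, so the last *column* is the missing token rather than -1.
    """
    if not (0.0 <= phi < 1.0):
        raise ValidationError(f"phi must be in [0, 1), got {phi}")
    M = alphabet.n_mutated
    P = np.zeros((M + 2, M + 2))
    for i in range(M + 1):              # non-silent rows
        P[i, i] = 1.0 - phi
        P[i, M + 1] = phi
    P[M + 1, M + 1] = 1.0               # silent always reads as "?"
    return P


def progenitor_transition(delta: float, nu: float, n_labels: int) -> np.ndarray:
    """Layer-1 chain of the progenitor-label character over {1..Ms, -1}.

    Labels are fixed at the start of the experiment and heritable: there is no
    label-to-label transition; each label silences at the shared rate nu.
    """
    if n_labels < 1:
        raise ValidationError(f"need at least one label, got {n_labels}")
    if delta < 0 or nu < 0:
        raise ValidationError("delta and nu must be >= 0")
    keep = np.exp(-nu * delta)
    P = np.zeros((n_labels + 1, n_labels + 1))
    for i in range(n_labels):
        P[i, i] = keep
        P[i, n_labels] = 1.0 - keep
    P[n_labels, n_labels] = 1.0
    return P
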