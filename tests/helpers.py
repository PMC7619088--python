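"""Independent oracles used by the tests.

These deliberately re-derive quantities by a different route than the
package (exhaustive dynamic programs, dense grid searches) so agreement is
evidence of correctness, not tautology.
"""

from __future__ import annotations

import numpy as np

NEG = float("-inf")


def affine_align_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -3.0,
    gap_open: float = -2.5,
    gap_extend: float = -2.0,
    terminal: float = -2.0,
) -> float:
    """Brute-force Gotoh dynamic program for global affine-gap alignment.

    The first residue of an internal gap costs ``gap_open``, each further
    one ``gap_extend``; every residue of a gap touching either end of the
    alignment costs ``terminal``.
    """
    na, nb = len(a), len(b)
    M = np.full((na + 1, nb + 1), NEG)
    X = np.full((na + 1, nb + 1), NEG)  # gap in b (consumes a)
    Y = np.full((na + 1, nb + 1), NEG)  # gap in a (consumes b)
    M[0, 0] = 0.0
    for i in range(1, na + 1):
        X[i, 0] = terminal * i
    for j in range(1, nb + 1):
        Y[0, j] = terminal * j
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            xo = terminal if j == nb else gap_open
            xe = terminal if j == nb else gap_extend
            X[i, j] = max(max(M[i - 1, j], Y[i - 1, j]) + xo, X[i - 1, j] + xe)
            yo = terminal if i == na else gap_open
            ye = terminal if i == na else gap_extend
            Y[i, j] = max(max(M[i, j - 1], X[i, j - 1]) + yo, Y[i, j - 1] + ye)
    return float(max(M[na, nb], X[na, nb], Y[na, nb]))


def grid_crossover(
    w1: float, m1: float, v1: float, w2: float, m2: float, v2: float,
    n_grid: int = 200001,
) -> float:
    """Dense grid search for the point between m1 and m2 where the weighted
    Gaussian densities are equal."""
    from scipy.stats import norm

    x = np.linspace(m1, m2, n_grid)[1:-1]
    diff = np.abs(
        w1 * norm.pdf(x, m1, np.sqrt(v1)) - w2 * norm.pdf(x, m2, np.sqrt(v2))
    )
    return float(x[np.argmin(diff)])


def random_protein(rng: np.random.Generator, length: int) -> str:
    from proteocast.alphabet import AA_ORDER

    return "".join(AA_ORDER[k] for k in rng.integers(0, 20, size=length))
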