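"""Leslie matrix assembly and intrinsic growth rate.

The population projection matrix has fecundities F(i) (expected age-0
females per female of age i per year) in its first row and survival
probabilities on the first sub-diagonal, with an explicit age-0 class whose
survival to recruitment is exp(-M_0). The intrinsic growth rate is
r = ln(lambda) with lambda the dominant (Perron) eigenvalue. The explicit
age-0 representation and the conventional collapse (pre-multiplying the
fecundity row by exp(-M_0)) share the same nonzero spectrum, so either
convention yields the same r.
"""

from __future__ import annotations

import numpy as np

__all__ = ["build_leslie", "build_collapsed", "growth_rate", "spectral_radius"]


def build_leslie(F, S, M_0: float) -> np.ndarray:
    """(A+1)x(A+1) projection matrix with an explicit age-0 class.

    Uses the postbreeding-census convention: the class-j entry of the first
    row is s_j * F(j+1) — an individual censused at age j survives the year
    (s_0 = exp(-M_0) for the age-0 class, S(j) afterwards) and then spawns
    with the fecundity of its new age. This is the unique age-0-explicit
    layout whose nonzero spectrum coincides with the collapsed A x A
    convention of :func:`build_collapsed`, so the computed growth rate does
    not depend on which of the two is used. (Placing the raw F(i) in the
    first row instead would insert a spurious extra year between spawning
    and recruitment and bias the growth rate low.)

    Parameters
    ----------
    F:
        Fecundities for ages 1..A (expected age-0 females per female per
        year; age 0 does not reproduce).
    S:
        Post-recruit annual survivals for ages 1..A-1 (survival out of the
        terminal age is zero).
    M_0:
        Cumulative age-0 mortality; exp(-M_0) is the age-0 -> age-1 survival.
    """
    F = np.asarray(F, dtype=float)
    S = np.asarray(S, dtype=float)
    A = len(F)
    if len(S) != A - 1:
        raise ValueError(f"expected {A - 1} post-recruit survivals, got {len(S)}")
    if M_0 < 0:
        raise ValueError("M_0 must be >= 0")
    if (F < 0).any() or (S < 0).any():
        raise ValueError("fecundities and survivals must be nonnegative")
    s = np.concatenate([[np.exp(-M_0)], S])   # survival out of classes 0..A-1
    T = np.zeros((A + 1, A + 1))
    T[0, :A] = s * F                          # survive the year, then spawn
    rows = np.arange(1, A + 1)
    T[rows, rows - 1] = s
    return T


def build_collapsed(F, S, M_0: float) -> np.ndarray:
    """A x A Leslie matrix with the age-0 class folded into the fecundity row."""
    F = np.asarray(F, dtype=float)
    S = np.asarray(S, dtype=float)
    A = len(F)
    if len(S) != A - 1:
        raise ValueError(f"expected {A - 1} post-recruit survivals, got {len(S)}")
    T = np.zeros((A, A))
    T[0, :] = F * np.exp(-M_0)
    rows = np.arange(1, A)
    T[rows, rows - 1] = S
    return T


def spectral_radius(T: np.ndarray, method: str = "eig", tol: float = 1e-10,
                    max_iter: int = 100000) -> float:
    """Dominant eigenvalue of a nonnegative matrix.

    ``method="eig"`` uses a dense eigen-decomposition; ``method="power"``
    uses power iteration from a strictly positive start vector (valid for
    the primitive matrices that arise whenever two consecutive ages are
    fecund) and raises on non-convergence.
    """
    T = np.asarray(T, dtype=float)
    if (T < 0).any():
        raise ValueError("matrix must be nonnegative")
    if not T.any():
        raise ValueError("zero matrix has no meaningful growth rate")
    if method == "eig":
        lam = np.linalg.eigvals(T)
        return float(np.max(np.abs(lam)))
    if method != "power":
        raise ValueError(f"unknown method {method!r}")
    v = np.full(T.shape[0], 1.0 / T.shape[0])
    for it in range(max_iter):
        w = T @ v
        nrm = np.linalg.norm(w)
        if nrm == 0.0:
            # reproductive chain is nilpotent: spectral radius 0
            return 0.0
        v = w / nrm
        Tv = T @ v
        lam = float(v @ Tv)
        # residual-based stop: ||Tv - lam v|| small guarantees lam accuracy
        # even when the spectral gap makes successive iterates crawl
        if np.linalg.norm(Tv - lam * v) <= tol * max(1.0, abs(lam)):
            return lam
    raise RuntimeError(f"power iteration did not converge in {max_iter} iterations")


def growth_rate(T: np.ndarray, method: str = "eig", tol: float = 1e-10) -> float:
    """r = ln(dominant eigenvalue); raises if the dominant eigenvalue is 0."""
    lam = spectral_radius(T, method=method, tol=tol)
    if lam <= 0.0:
        raise ValueError("dominant eigenvalue is zero (no reproduction); r undefined")
    return float(np.log(lam))
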