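"""Least angle regression (LARS) variable-entry paths.

Only the *identity and order* of the variables entering the model is
consumed downstream: stability selection counts how often each candidate TF
enters within the first L steps.  This is pure LARS — variables are added,
never dropped (the lasso drop-step modification is available as an option
but off by default, since entry order is all that is scored).

At every step the entering variable is the one maximizing the absolute
correlation with the current residual; the fit then advances along the
equiangular direction of the active set until a new variable ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LarsPath", "DegenerateInputError", "lars_select", "entry_ranks"]

#: residual max |correlation| below this ends the path (exhausted residual)
EARLY_STOP_TOL = 1e-12

NOT_SELECTED = np.inf


class DegenerateInputError(ValueError):
    """Design too small or non-finite for a LARS path."""


@dataclass
class LarsPath:
    """Result of one LARS run.

    ``entry_order`` lists predictor column indices in the order they entered
    the model (no repeats).  ``coef_path`` has one row per breakpoint
    (including the all-zero start), columns over all q predictors.
    """

    entry_order: list[int]
    n_steps_run: int
    coef_path: np.ndarray | None = None


def lars_select(
    design: np.ndarray,
    response: np.ndarray,
    L: int,
    *,
    tol: float = EARLY_STOP_TOL,
    keep_coef_path: bool = False,
    _validate: bool = True,
) -> LarsPath:
    """Run LARS for at most ``L`` steps and return the entry path.

    The caller supplies a centered design and response (columns scaled as it
    chooses; scaling changes correlations and hence the path, which is
    exactly how stability selection injects its randomization).  The number
    of steps is capped at min(L, number of non-zero columns, m-1): the
    design cannot support more equiangular directions.  Exactly-zero columns
    (constant genes after standardization) can never enter.

    Ties in the entry criterion are broken deterministically toward the
    lowest column index.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if _validate:
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise DegenerateInputError("design and response shapes are inconsistent")
        if X.shape[0] < 2:
            raise DegenerateInputError("need at least 2 samples for a LARS step")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise DegenerateInputError("non-finite values in design or response")
        if L < 1:
            raise ValueError("L must be >= 1")

    m, q = X.shape
    eligible = (X != 0.0).any(axis=0)
    max_steps = min(L, int(eligible.sum()), m - 1)

    active: list[int] = []
    is_inactive = eligible.copy()
    mu = np.zeros(m)
    coef = np.zeros(q)
    path = [coef.copy()] if keep_coef_path else None

    for _ in range(max_steps):
        c = X.T @ (y - mu)
        c_masked = np.where(is_inactive, np.abs(c), -np.inf)
        j = int(np.argmax(c_masked))  # ties -> lowest index
        C = c_masked[j]
        if C < tol:
            break
        active.append(j)
        is_inactive[j] = False

        s = np.sign(c[active])
        XA = X[:, active] * s
        G = XA.T @ XA
        try:
            w_raw = np.linalg.solve(G, np.ones(len(active)))
        except np.linalg.LinAlgError:
            # new variable collinear with the active set: cannot advance
            active.pop()
            is_inactive[j] = True
            break
        denom = float(w_raw.sum())
        if denom <= 0:
            active.pop()
            is_inactive[j] = True
            break
        A = 1.0 / np.sqrt(denom)
        w = A * w_raw
        u = XA @ w  # unit equiangular vector of the active set

        C = abs(c[j])
        inact = np.flatnonzero(is_inactive)
        if inact.size:
            a = X[:, inact].T @ u
            cc = c[inact]
            with np.errstate(divide="ignore", invalid="ignore"):
                g1 = (C - cc) / (A - a)
                g2 = (C + cc) / (A + a)
            candidates = np.concatenate([g1, g2])
            candidates = candidates[np.isfinite(candidates) & (candidates > tol)]
            gamma = candidates.min() if candidates.size else C / A
        else:
            gamma = C / A  # jump to the least-squares fit of the active set

        mu += gamma * u
        coef[active] += gamma * w * s
        if keep_coef_path:
            path.append(coef.copy())

    return LarsPath(
        entry_order=active,
        n_steps_run=len(active),
        coef_path=np.array(path) if keep_coef_path else None,
    )


def entry_ranks(path: LarsPath, q: int) -> np.ndarray:
    """Entry rank H_t of every predictor: 1 = entered first, inf = never.

    The finite ranks of one run always form the prefix 1..n_steps_run.
    """
    H = np.full(q, NOT_SELECTED)
    for rank, t in enumerate(path.entry_order, start=1):
        H[t] = rank
    return H
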