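"""Variable selection offered to PLS: greedy forward selection and random draws.

Forward selection adds, at each step, the covariate that most reduces the
residual sum of squares of the linear model of sqrt-scale concentrations on
the selected set.  It is implemented with incremental Gram-Schmidt
residualisation, which is algebraically identical to refitting least squares
for every candidate but costs O(n p) per step, so sweeps over a few hundred
candidates stay cheap.  Ties break toward the lower variable index and the
procedure is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Sentinel for "the full covariate set" in k-schedules.
ALL = "all"

#: Default parsimony sweep: none, the intermediate sizes, and everything.
DEFAULT_K_SCHEDULE = (0, 3, 5, 7, 10, 13, 16, 20, 25, 30, 60, 90, 120, ALL)


@dataclass(frozen=True)
class SelectionResult:
    indices: np.ndarray  # ordered, distinct
    k: int
    trace: np.ndarray  # residual sum of squares after each step
    method: str  # "forward" | "random"

    def __post_init__(self) -> None:
        if len(np.unique(self.indices)) != self.k or len(self.indices) != self.k:
            raise ValueError("indices must be k distinct values")


def forward_select(Z: np.ndarray, y: np.ndarray, k: int) -> SelectionResult:
    """Greedy RSS-minimising forward selection of ``k`` covariates.

    ``Z`` is the scaled covariate matrix; ``y`` the sqrt-scale response.  An
    intercept is always implicit (columns and response are centred
    internally).  Candidates that have become numerically collinear with the
    selected set are skipped.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Z.shape
    if k > p:
        raise ValueError(f"k={k} exceeds p={p}")
    if np.isnan(Z).any() or np.isnan(y).any():
        raise ValueError("missing values in selection inputs")
    # residualise against the intercept up front
    R = Z - Z.mean(axis=0)
    r_y = y - y.mean()
    col_norms0 = np.linalg.norm(R, axis=0)
    alive = col_norms0 > 1e-12 * max(col_norms0.max(), 1.0)
    chosen: list[int] = []
    trace: list[float] = []
    for _ in range(k):
        norms2 = np.einsum("ij,ij->j", R, R)
        ok = alive & (norms2 > 1e-24)
        if not ok.any():
            raise ValueError("no non-collinear candidates left")
        score = np.zeros(p)
        dots = R.T @ r_y
        score[ok] = dots[ok] ** 2 / norms2[ok]
        # argmax already breaks ties toward the lower index
        j = int(np.argmax(np.where(ok, score, -np.inf)))
        u = R[:, j] / np.sqrt(norms2[j])
        r_y = r_y - u * (u @ r_y)
        R = R - np.outer(u, u @ R)
        alive[j] = False
        chosen.append(j)
        trace.append(float(r_y @ r_y))
    return SelectionResult(
        indices=np.array(chosen, dtype=int),
        k=k,
        trace=np.array(trace),
        method="forward",
    )


def random_select(p: int, k: int, seed: int = 0) -> SelectionResult:
    """Uniform sample of ``k`` of ``p`` variables without replacement."""
    if k > p:
        raise ValueError(f"k={k} exceeds p={p}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(p, size=k, replace=False)
    return SelectionResult(
        indices=idx.astype(int), k=k, trace=np.full(k, np.nan), method="random"
    )


def k_schedule(override=None, p: int | None = None) -> list:
    """The sweep of subset sizes, optionally overridden or resolved against p.

    With ``p`` given, the :data:`ALL` sentinel is replaced by ``p``, values
    above ``p`` are dropped, and duplicates removed while preserving order.
    """
    ks = list(DEFAULT_K_SCHEDULE if override is None else override)
    if p is None:
        return ks
    out: list[int] = []
    for k in ks:
        k = p if k == ALL else int(k)
        if k <= p and k not in out:
            out.append(k)
    return out
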