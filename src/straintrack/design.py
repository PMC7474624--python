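"""Balanced subcommunity designs for strain-attribution screens.

To localize which member of an S-strain consortium drives a host phenotype,
the consortium is split into m subcommunities of c strains each, with every
strain replicated in exactly r subcommunities ("orthogonal design"). The
with/without contrast for a strain then compares mice colonized with the r
communities containing it against the rest, so the design must additionally
keep pairwise co-occurrence balanced — no two strains should ride together
everywhere, or their effects are confounded.

Construction: when c divides S, r rounds of partitions (the first random,
later ones greedy, adding each strain to the round-partition cell that adds
the least co-occurrence); otherwise a single greedy fill by remaining
replication. Either way the result is polished by a seeded local pair-swap
descent on the lexicographic objective (max pairwise co-occurrence, then sum
of squared co-occurrences), with random restarts if the known lower bound is
not reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["DesignMatrix", "generate_design", "validate_design"]


@dataclass
class DesignMatrix:
    """Binary incidence of m communities x S strains.

    Every row sums to the community size c and every column to the
    replication r; ``cooccurrence()`` is X'X with the diagonal removed.
    """

    X: pd.DataFrame
    c: int
    r: int

    def __post_init__(self) -> None:
        vals = self.X.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise InputError("design matrix must be binary")
        if not (vals.sum(axis=1) == self.c).all():
            raise InputError("a community row does not sum to c")
        if not (vals.sum(axis=0) == self.r).all():
            raise InputError("a strain column does not sum to r")

    @property
    def n_communities(self) -> int:
        return self.X.shape[0]

    @property
    def n_strains(self) -> int:
        return self.X.shape[1]

    def cooccurrence(self) -> pd.DataFrame:
        C = self.X.T @ self.X
        np.fill_diagonal(C.values, 0)
        return C

    def max_cooccurrence(self) -> int:
        return int(self.cooccurrence().to_numpy().max()) if self.n_strains > 1 else 0

    def to_long(self) -> pd.DataFrame:
        long = self.X.stack()
        long = long[long == 1].reset_index()[["level_0", "level_1"]]
        long.columns = ["community_id", "strain_id"]
        return long


def _objective(X: np.ndarray) -> tuple[int, int]:
    C = X.T @ X
    np.fill_diagonal(C, 0)
    return int(C.max()), int((C**2).sum())


def _greedy_rounds(S: int, c: int, r: int, rng: np.random.Generator) -> np.ndarray:
    """r rounds of partitions of S strains into S/c cells (requires c | S)."""
    m_round = S // c
    X_rows: list[np.ndarray] = []
    C = np.zeros((S, S), dtype=int)
    for rnd in range(r):
        cells: list[list[int]] = [[] for _ in range(m_round)]
        order = rng.permutation(S)
        for s in order:
            best, best_cost = None, None
            for ci, cell in enumerate(cells):
                if len(cell) >= c:
                    continue
                cost = sum(C[s, t] for t in cell)
                if best_cost is None or cost < best_cost:
                    best, best_cost = ci, cost
            cells[best].append(s)
        for cell in cells:
            row = np.zeros(S, dtype=int)
            row[cell] = 1
            X_rows.append(row)
            for a in cell:
                for b in cell:
                    if a != b:
                        C[a, b] += 1
    return np.array(X_rows)


def _greedy_fill(S: int, c: int, r: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """General greedy fill by maximal remaining replication (no divisibility needed)."""
    remaining = np.full(S, r)
    C = np.zeros((S, S), dtype=int)
    X = np.zeros((m, S), dtype=int)
    for g in range(m):
        chosen: list[int] = []
        for _ in range(c):
            cand = [s for s in range(S) if remaining[s] > 0 and s not in chosen]
            # most constrained first, then least added co-occurrence, seeded ties
            s = min(cand, key=lambda s_: (-remaining[s_], sum(C[s_, t] for t in chosen), rng.random()))
            chosen.append(s)
            remaining[s] -= 1
        X[g, chosen] = 1
        for a in chosen:
            for b in chosen:
                if a != b:
                    C[a, b] += 1
    return X


def _swap_descent(X: np.ndarray, rng: np.random.Generator, max_iter: int) -> np.ndarray:
    """First-improvement pair-swap descent preserving row and column sums."""
    X = X.copy()
    m, S = X.shape
    best_obj = _objective(X)
    it = 0
    improved = True
    while improved and it < max_iter:
        improved = False
        rows = rng.permutation(m)
        for gi in rows:
            for gj in rng.permutation(m):
                if gi == gj:
                    continue
                accepted = True
                while accepted:  # candidate sets are stale after an accepted swap
                    accepted = False
                    in_i = np.flatnonzero(X[gi] & ~X[gj])
                    in_j = np.flatnonzero(X[gj] & ~X[gi])
                    for u in in_i:
                        for v in in_j:
                            it += 1
                            X[gi, u], X[gi, v] = 0, 1
                            X[gj, v], X[gj, u] = 0, 1
                            obj = _objective(X)
                            if obj < best_obj:
                                best_obj = obj
                                improved = True
                                accepted = True
                            else:
                                X[gi, u], X[gi, v] = 1, 0
                                X[gj, v], X[gj, u] = 1, 0
                            if it >= max_iter:
                                return X
                            if accepted:
                                break
                        if accepted:
                            break
    return X


def _lower_bound_max_cooc(S: int, c: int, r: int) -> int:
    """Every strain co-occurs with r(c-1) slots spread over S-1 partners."""
    if S <= 1:
        return 0
    return max(1, math.ceil(r * (c - 1) / (S - 1))) if c > 1 else 0


def generate_design(S: int, c: int, r: int, seed: int = 0, max_iter: int = 20000,
                    strain_ids: list[str] | None = None, n_restarts: int = 20) -> DesignMatrix:
    """Generate an m = S*r/c community design with exact replication balance.

    Raises an input error when S*r is not divisible by c (the community count
    would be non-integral). Deterministic given the seed.
    """
    if c < 1 or r < 1 or S < 1:
        raise InputError("S, c, r must be positive")
    if c > S:
        raise InputError("community size cannot exceed number of strains")
    if (S * r) % c != 0:
        raise InputError(f"S*r/c = {S * r / c:g} communities is non-integral; "
                         "S*r must be divisible by c")
    m = S * r // c
    if r > m:
        raise InputError("replication exceeds number of communities")
    if strain_ids is None:
        strain_ids = [f"strain{i + 1:02d}" for i in range(S)]
    if len(strain_ids) != S or len(set(strain_ids)) != S:
        raise InputError("strain_ids must be S distinct labels")
    target = _lower_bound_max_cooc(S, c, r)
    best_X, best_obj = None, None
    rng = np.random.default_rng(seed)
    for restart in range(max(1, n_restarts)):
        # alternate start strategies: round-partitions give clean replication
        # structure but cannot always reach the optimum (two partitions of the
        # same set force some pair to co-occur twice), greedy fill can
        use_rounds = S % c == 0 and restart % 2 == 0
        X0 = _greedy_rounds(S, c, r, rng) if use_rounds else _greedy_fill(S, c, r, m, rng)
        X = _swap_descent(X0, rng, max_iter)
        obj = _objective(X)
        if best_obj is None or obj < best_obj:
            best_X, best_obj = X, obj
        if best_obj[0] <= target:
            break
    Xdf = pd.DataFrame(best_X, columns=strain_ids,
                       index=[f"community{g + 1:02d}" for g in range(m)])
    return DesignMatrix(Xdf, c, r)


def validate_design(design: DesignMatrix, S: int, c: int, r: int) -> dict:
    """Report-only check of a design against declared (S, c, r).

    Returns row/column sums, the co-occurrence histogram and maximum,
    duplicate-community flags, and an overall pass verdict; never raises.
    """
    X = design.X.to_numpy()
    row_sums = X.sum(axis=1)
    col_sums = X.sum(axis=0)
    C = X.T @ X
    np.fill_diagonal(C, 0)
    vals = C[np.triu_indices_from(C, k=1)] if X.shape[1] > 1 else np.array([], dtype=int)
    hist = {int(v): int(n) for v, n in zip(*np.unique(vals, return_counts=True))} if vals.size else {}
    bad_rows = [str(design.X.index[i]) for i in np.flatnonzero(row_sums != c)]
    bad_cols = [str(design.X.columns[j]) for j in np.flatnonzero(col_sums != r)]
    dup_rows = design.X.index[design.X.duplicated(keep=False)].tolist()
    ok = (X.shape[1] == S and not bad_rows and not bad_cols and not dup_rows)
    return {
        "n_communities": X.shape[0],
        "n_strains": X.shape[1],
        "expected_communities": (S * r) // c if (S * r) % c == 0 else None,
        "row_sum_violations": bad_rows,
        "column_sum_violations": bad_cols,
        "duplicate_communities": [str(d) for d in dup_rows],
        "cooccurrence_histogram": hist,
        "max_cooccurrence": int(vals.max()) if vals.size else 0,
        "passed": bool(ok),
    }
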