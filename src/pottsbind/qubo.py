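"""Classical solvers for the one-hot QUBO form of the Potts design problem.

The Potts score is encoded over binary variables ``s[i, a]`` (amino acid
``a`` at residue ``i``) with a quadratic one-hot penalty ``A*(sum_a s[i,a]
- 1)**2`` per residue, so that on feasible bitstrings the QUBO energy equals
the Potts score exactly.  Three solvers are provided:

* :func:`solve_exhaustive` -- exact enumeration, the ground-truth oracle;
* :func:`solve_simulated_annealing` -- Metropolis walk in the feasible
  (one-hot preserving) move set with geometric cooling;
* :func:`solve_hybrid` -- a large-neighborhood decomposition refiner in the
  spirit of hybrid annealer workflows: blocks of residues are exhaustively
  re-optimized with the rest frozen, accepting only improvements.

All solvers are deterministic given their seed and break ties
lexicographically by alphabet order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .potts import PottsModel, SolveResult, potts_score, score_states

__all__ = [
    "QuboMatrix",
    "AnnealSchedule",
    "HyperparamGrid",
    "encode_one_hot_qubo",
    "qubo_energy",
    "solve_exhaustive",
    "solve_simulated_annealing",
    "solve_hybrid",
    "default_schedule",
    "hyperparameter_scan",
]


@dataclass
class QuboMatrix:
    linear: dict            # var -> coefficient
    quadratic: dict         # (var, var') with var < var' -> coefficient
    var_index: dict         # (i, a) -> var
    constraint_weight: float
    offset: float = 0.0     # constant term (penalty p + n*A from the squares)


def default_constraint_weight(model: PottsModel) -> float:
    """Penalty weight that strictly dominates any energetic gain from
    violating the one-hot constraint."""
    t = model.tables
    one = np.abs(t.one_body).max(axis=1).sum()
    two = 0.0
    for i in range(t.n):
        for j in range(i + 1, t.n):
            two += np.abs(t.two_body[i, j]).max()
    return float(2.0 * (one + model.lam * two) + 1.0)


def encode_one_hot_qubo(model: PottsModel, constraint_weight: float | None = None) -> QuboMatrix:
    t = model.tables
    A = len(t.alphabet)
    W = default_constraint_weight(model) if constraint_weight is None else float(constraint_weight)
    if W <= 0:
        raise ValueError("constraint weight must be positive")
    var_index = {(i, a): i * A + a for i in range(t.n) for a in range(A)}
    linear: dict[int, float] = {}
    quadratic: dict[tuple[int, int], float] = {}
    # W*(sum_a s_ia - 1)^2 = W*(sum s_ia - 2*sum_{a<b} ... ) expands to
    # -W per linear var, +2W per same-residue pair, +W constant per residue.
    for (i, a), v in var_index.items():
        linear[v] = float(t.one_body[i, a]) - W
    for i in range(t.n):
        for a in range(A):
            for b in range(a + 1, A):
                quadratic[(var_index[(i, a)], var_index[(i, b)])] = 2.0 * W
    for i in range(t.n):
        for j in range(i + 1, t.n):
            for a in range(A):
                for b in range(A):
                    e = model.lam * t.two_body[i, j, a, b]
                    if e != 0.0:
                        quadratic[(var_index[(i, a)], var_index[(j, b)])] = (
                            quadratic.get((var_index[(i, a)], var_index[(j, b)]), 0.0) + e
                        )
    return QuboMatrix(linear=linear, quadratic=quadratic, var_index=var_index,
                      constraint_weight=W, offset=model.penalty + W * t.n)


def qubo_energy(q: QuboMatrix, bits: np.ndarray) -> float:
    """Energy of a flat or (n, A) binary vector under the QUBO."""
    x = np.asarray(bits).ravel().astype(float)
    e = q.offset
    for v, c in q.linear.items():
        e += c * x[v]
    for (u, v), c in q.quadratic.items():
        e += c * x[u] * x[v]
    return float(e)


def solve_exhaustive(model: PottsModel, guard: int = 10_000_000) -> SolveResult:
    """Exact global minimizer by enumeration (ties -> lexicographically first)."""
    t = model.tables
    A = len(t.alphabet)
    total = A ** t.n
    if total > guard:
        raise ValueError(f"search space {total} exceeds guard {guard}")
    # vectorized scoring in chunks of enumerated state matrices
    best_score = np.inf
    best_states: np.ndarray | None = None
    chunk = 200_000
    idx = np.arange(t.n)
    for start in range(0, total, chunk):
        codes = np.arange(start, min(start + chunk, total))
        # lexicographic enumeration: residue 0 is the most significant digit
        states = np.empty((len(codes), t.n), dtype=np.intp)
        rem = codes.copy()
        for i in range(t.n - 1, -1, -1):
            states[:, i] = rem % A
            rem //= A
        scores = t.one_body[idx, states].sum(axis=1)
        two = np.zeros(len(codes))
        for i in range(t.n):
            for j in range(i + 1, t.n):
                two += t.two_body[i, j][states[:, i], states[:, j]]
        scores = scores + model.lam * two + model.penalty
        # codes enumerate lexicographically and argmin takes the first
        # occurrence, so strict < keeps the lexicographically first optimum
        k = int(np.argmin(scores))
        if scores[k] < best_score:
            best_score = float(scores[k])
            best_states = states[k].copy()
    seq = t.alphabet.decode(best_states)
    return SolveResult(sequence=seq, score=best_score, method="exhaustive",
                       metadata={"evaluated": total})


@dataclass
class AnnealSchedule:
    """Geometric cooling schedule for the Metropolis solver (score units)."""

    t_start: float
    t_end: float = 0.01
    n_steps: int = 50_000
    moves_per_step: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.t_start > self.t_end > 0):
            raise ValueError("require t_start > t_end > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


def default_schedule(model: PottsModel, seed: int, n_steps: int = 50_000) -> AnnealSchedule:
    """t_start = 10 * std of 1000 random-sequence scores (landscape scale)."""
    rng = np.random.default_rng(seed)
    t = model.tables
    A = len(t.alphabet)
    scores = [score_states(model, rng.integers(0, A, t.n)) for _ in range(1000)]
    t_start = max(10.0 * float(np.std(scores)), 0.1)
    return AnnealSchedule(t_start=t_start, t_end=0.01, n_steps=n_steps, seed=seed)


def solve_simulated_annealing(model: PottsModel, schedule: AnnealSchedule,
                              init: str | None = None) -> SolveResult:
    """Metropolis annealing over one-residue substitutions (feasible moves only)."""
    t = model.tables
    A = len(t.alphabet)
    rng = np.random.default_rng(schedule.seed)
    if init is not None:
        states = t.alphabet.encode(init)
    else:
        states = rng.integers(0, A, t.n)
    sym = t.symmetric_two_body()          # (n, n, A, A), zero diagonal
    cur = score_states(model, states)
    best, best_states = cur, states.copy()
    ratio = (schedule.t_end / schedule.t_start) ** (1.0 / max(schedule.n_steps - 1, 1))
    temp = schedule.t_start
    others = np.arange(t.n)
    for _ in range(schedule.n_steps):
        for _ in range(schedule.moves_per_step):
            i = int(rng.integers(0, t.n))
            a_new = int(rng.integers(0, A))
            a_old = int(states[i])
            if a_new == a_old:
                continue
            d_one = t.one_body[i, a_new] - t.one_body[i, a_old]
            col_new = sym[i, others, a_new, states]
            col_old = sym[i, others, a_old, states]
            d_two = float(col_new.sum() - col_old.sum())  # diagonal is zero
            delta = float(d_one) + model.lam * d_two
            if delta <= 0 or rng.random() < np.exp(-delta / temp):
                states[i] = a_new
                cur += delta
                if cur < best - 1e-12:
                    best, best_states = cur, states.copy()
        temp *= ratio
    best = score_states(model, best_states)  # re-score to kill drift
    return SolveResult(sequence=t.alphabet.decode(best_states), score=best,
                       method="sa", seed=schedule.seed,
                       metadata={"t_start": schedule.t_start, "t_end": schedule.t_end,
                                 "n_steps": schedule.n_steps})


def solve_hybrid(model: PottsModel, block_size: int = 3, rounds: int = 4,
                 init: str | None = None, seed: int = 0,
                 guard: int = 1_000_000) -> SolveResult:
    """Large-neighborhood descent: exhaustively re-optimize blocks of residues.

    Blocks sweep round-robin over contiguous windows, then random subsets;
    a block update is accepted only if it lowers the score, so the score
    trace is monotone non-increasing.
    """
    t = model.tables
    A = len(t.alphabet)
    if not (1 <= block_size <= t.n):
        raise ValueError("block_size must be in [1, n]")
    if A ** block_size > guard:
        raise ValueError(f"block search space {A ** block_size} exceeds guard {guard}")
    rng = np.random.default_rng(seed)
    if init is not None:
        states = t.alphabet.encode(init)
    else:
        states = rng.integers(0, A, t.n)
    sym = t.symmetric_two_body()
    trace = [score_states(model, states)]

    combos = np.array(list(itertools.product(range(A), repeat=block_size)), dtype=np.intp)

    def optimize_block(block: np.ndarray) -> None:
        outside = np.setdiff1d(np.arange(t.n), block)
        # score contribution that depends on the block letters
        contrib = np.zeros(len(combos))
        for bi, i in enumerate(block):
            contrib += t.one_body[i, combos[:, bi]]
            if len(outside):
                field = sym[i][outside][:, :, states[outside]]          # (n_out, A, n_out)
                field = field[np.arange(len(outside)), :, np.arange(len(outside))]  # (n_out, A)
                contrib += model.lam * field.sum(axis=0)[combos[:, bi]]
        for bi in range(len(block)):
            for bj in range(bi + 1, len(block)):
                i, j = int(block[bi]), int(block[bj])
                contrib += model.lam * sym[i, j][combos[:, bi], combos[:, bj]]
        k = int(np.argmin(contrib))  # first occurrence = lexicographic tie-break
        cur_combo = states[block]
        cur_idx = 0
        for v in cur_combo:
            cur_idx = cur_idx * A + int(v)
        if contrib[k] < contrib[cur_idx] - 1e-12:
            states[block] = combos[k]

    n_blocks = max(t.n - block_size + 1, 1)
    for r in range(rounds):
        for start in range(n_blocks):            # round-robin contiguous windows
            optimize_block(np.arange(start, min(start + block_size, t.n)))
            trace.append(score_states(model, states))
        for _ in range(n_blocks):                # random subsets
            block = np.sort(rng.choice(t.n, size=min(block_size, t.n), replace=False))
            optimize_block(block)
            trace.append(score_states(model, states))
    final = score_states(model, states)
    return SolveResult(sequence=t.alphabet.decode(states), score=final,
                       method="hybrid", seed=seed,
                       metadata={"block_size": block_size, "rounds": rounds,
                                 "trace": trace})


@dataclass
class HyperparamGrid:
    lambdas: list = field(default_factory=lambda: [0.01])
    penalties: list = field(default_factory=lambda: [0.0])

    def __post_init__(self) -> None:
        if not self.lambdas or not self.penalties:
            raise ValueError("grid must be non-empty")


def hyperparameter_scan(tables, grid: HyperparamGrid, method: str = "sa",
                        seed: int = 0, sa_steps: int = 20_000,
                        block_size: int = 3, rounds: int = 3):
    """One best result per (lambda, p) cell plus the deduplicated sequence set."""
    results: list[SolveResult] = []
    seen_cells = set()
    for lam in grid.lambdas:
        for p in grid.penalties:
            if (lam, p) in seen_cells:
                continue
            seen_cells.add((lam, p))
            model = PottsModel(tables=tables, lam=lam, penalty=p)
            if method == "exhaustive":
                res = solve_exhaustive(model)
            elif method == "sa":
                res = solve_simulated_annealing(model, default_schedule(model, seed, sa_steps))
            elif method == "hybrid":
                res = solve_hybrid(model, block_size=block_size, rounds=rounds, seed=seed)
            elif method == "sa+hybrid":
                sa = solve_simulated_annealing(model, default_schedule(model, seed, sa_steps))
                res = solve_hybrid(model, block_size=block_size, rounds=rounds,
                                   init=sa.sequence, seed=seed)
                res.method = "sa+hybrid"
            else:
                raise ValueError(f"unknown method {method!r}")
            res.metadata.update({"lambda": lam, "p": p})
            results.append(res)
    unique = sorted({r.sequence for r in results})
    return results, unique
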