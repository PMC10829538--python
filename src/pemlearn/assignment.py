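"""EM-style correction of state ordering and coupling signs.

Raw per-geometry diabatization leaves two gauge defects: each geometry's
diabatic states come out in an arbitrary order, and the couplings carry
random signs inherited from the electronic wavefunction phases.  Both are
elements of the signed-permutation group (a permutation of the n states plus
per-state sign flips; 2^(n-1) n! distinct elements once the irrelevant
global sign is fixed).

The correction treats per-geometry assignments as latent cluster labels and
alternates:

  expectation step — fix all assignments, refresh KRR hyperparameters by
  grid cross-validation, and train one regressor per global surface (or per
  independent PEM element);

  maximization step — sweep the geometries in seeded random order; for each
  geometry, predict its surfaces/PEM from models trained without it
  (closed-form leave-one-out), and reassign it to the candidate that
  minimizes the squared prediction error — a linear sum assignment for plain
  energy reordering, a signed-permutation search (Frobenius distance of the
  conjugated PEM to the predicted PEM) in the diabatic case.  Clusters are
  updated immediately after each geometry.

Sweeps repeat until an entire sweep changes nothing.  Because the procedure
is stochastic and only locally optimal, it is restarted from many random
initial orderings and the winners are ranked by nested cross-validation,
which keeps hyperparameter tuning from leaking into the ranking score.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .krr import CVPlan, KernelWorkspace, grid_search_cv_multi, nested_cv_score


@dataclass(frozen=True)
class SignedPermutation:
    """A permutation of n state labels plus a sign per state.

    As a matrix, column j holds ``signs[j]`` in row ``perm[j]``; conjugating
    a symmetric matrix U gives (S^T U S)[a, b] = s_a s_b U[perm[a], perm[b]].
    The group structure (composition, inverse) is exact and eigenvalues of U
    are invariant.
    """

    perm: tuple[int, ...]
    signs: tuple[int, ...]

    def __post_init__(self):
        n = len(self.perm)
        if sorted(self.perm) != list(range(n)):
            raise ValueError("perm must be a bijection on 0..n-1")
        if len(self.signs) != n or any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be +-1, one per state")
        object.__setattr__(self, "perm", tuple(int(p) for p in self.perm))
        object.__setattr__(self, "signs", tuple(int(s) for s in self.signs))

    @classmethod
    def identity(cls, n: int) -> "SignedPermutation":
        return cls(perm=tuple(range(n)), signs=(1,) * n)

    @property
    def n(self) -> int:
        return len(self.perm)

    def matrix(self) -> np.ndarray:
        S = np.zeros((self.n, self.n))
        for j, (p, s) in enumerate(zip(self.perm, self.signs)):
            S[p, j] = s
        return S

    def inverse(self) -> "SignedPermutation":
        inv = [0] * self.n
        for j, p in enumerate(self.perm):
            inv[p] = j
        return SignedPermutation(
            perm=tuple(inv), signs=tuple(self.signs[inv[i]] for i in range(self.n))
        )

    def compose(self, other: "SignedPermutation") -> "SignedPermutation":
        """Matrix product self @ other as a signed permutation."""
        perm = tuple(self.perm[p] for p in other.perm)
        signs = tuple(self.signs[other.perm[j]] * other.signs[j] for j in range(self.n))
        return SignedPermutation(perm=perm, signs=signs)

    def gauge_fixed(self) -> "SignedPermutation":
        """Flip the irrelevant global sign so that signs[0] = +1."""
        if self.signs[0] == 1:
            return self
        return SignedPermutation(perm=self.perm, signs=tuple(-s for s in self.signs))


def enumerate_signed_permutations(n: int):
    """All 2^(n-1) n! gauge-fixed signed permutations (first sign +1).

    Deterministic order: permutations lexicographically, then sign patterns.
    Guarded at n > 8, where exhaustive search is no longer sensible — use
    two-opt mode instead.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > 8:
        raise ValueError(f"exhaustive enumeration guarded at n > 8 (got n={n}); use two-opt mode")
    for perm in itertools.permutations(range(n)):
        for tail in itertools.product((1, -1), repeat=n - 1):
            yield SignedPermutation(perm=perm, signs=(1,) + tail)


def apply_signed_permutation(U: np.ndarray, S: SignedPermutation) -> np.ndarray:
    """Conjugation S^T U S (orthogonal, eigenvalue-preserving)."""
    U = np.asarray(U, dtype=float)
    perm = np.array(S.perm)
    signs = np.array(S.signs, dtype=float)
    return U[np.ix_(perm, perm)] * np.outer(signs, signs)


def linear_assign(cost: np.ndarray) -> tuple[int, ...]:
    """Minimum-cost row-to-column assignment (Jonker–Volgenant via SciPy).

    Returns p with row i assigned to column p[i].  Ties are resolved to the
    lexicographically smallest permutation by fixing rows greedily and
    re-solving the remainder.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValueError("cost matrix must be square")
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix must be finite")
    n = cost.shape[0]
    rows, cols = linear_sum_assignment(cost)
    optimum = cost[rows, cols].sum()
    tol = 1e-12 * max(1.0, abs(optimum))
    assigned: list[int] = []
    free_cols = list(range(n))
    for i in range(n):
        fixed_cost = sum(cost[r, c] for r, c in enumerate(assigned))
        for c in sorted(free_cols):
            remaining = [x for x in free_cols if x != c]
            if remaining:
                sub = cost[np.ix_(range(i + 1, n), remaining)]
                r2, c2 = linear_sum_assignment(sub)
                rest = sub[r2, c2].sum()
            else:
                rest = 0.0
            if fixed_cost + cost[i, c] + rest <= optimum + tol:
                assigned.append(c)
                free_cols.remove(c)
                break
        else:  # pragma: no cover - defensive
            raise RuntimeError("assignment completion failed")
    return tuple(assigned)


def pem_objective(A_pred: np.ndarray, U_raw: np.ndarray, S: SignedPermutation) -> float:
    """Squared Frobenius distance ||A_pred - S^T U_raw S||_F^2."""
    return float(np.sum((A_pred - apply_signed_permutation(U_raw, S)) ** 2))


def _best_signs(A_pred: np.ndarray, U_perm: np.ndarray) -> tuple[tuple[int, ...], float]:
    """Exhaust the 2^(n-1) gauge-fixed sign vectors for a fixed permutation."""
    n = U_perm.shape[0]
    best_signs, best_obj = None, np.inf
    for tail in itertools.product((1, -1), repeat=n - 1):
        signs = np.array((1,) + tail, dtype=float)
        obj = float(np.sum((A_pred - U_perm * np.outer(signs, signs)) ** 2))
        if obj < best_obj:
            best_obj, best_signs = obj, (1,) + tail
    return best_signs, best_obj


def two_opt_refine(
    S: SignedPermutation, objective, max_iter: int = 10_000
) -> SignedPermutation:
    """Hill-climb over pairwise transpositions and single sign flips.

    Accepts only strictly improving moves; terminates when no neighbouring
    signed permutation improves the objective.
    """
    current = S
    current_obj = objective(current)
    n = S.n
    for _ in range(max_iter):
        improved = False
        for i in range(n):
            for j in range(i + 1, n):
                perm = list(current.perm)
                perm[i], perm[j] = perm[j], perm[i]
                cand = SignedPermutation(tuple(perm), current.signs)
                obj = objective(cand)
                if obj < current_obj:
                    current, current_obj, improved = cand, obj, True
        for i in range(n):
            signs = list(current.signs)
            signs[i] = -signs[i]
            cand = SignedPermutation(current.perm, tuple(signs)).gauge_fixed()
            obj = objective(cand)
            if obj < current_obj:
                current, current_obj, improved = cand, obj, True
        if not improved:
            break
    return current.gauge_fixed()


def assign_geometry_pem(
    A_pred: np.ndarray, U_raw: np.ndarray, mode: str = "full"
) -> tuple[SignedPermutation, float]:
    """Best signed permutation aligning a raw PEM to its predicted PEM.

    Modes:
      ``diag-then-signs`` — linear assignment on the diagonal entries only
        (couplings neglected), then exhaust the 2^(n-1) coupling-sign vectors;
      ``full`` — the above as a start, then exhaustive search over all
        2^(n-1) n! signed permutations (guarded at n > 8);
      ``two-opt`` — the diagonal start refined by transposition/sign-flip
        hill climbing, for manifolds too large to exhaust.

    Returns the gauge-fixed winner and its squared Frobenius objective; the
    result never scores worse than the diagonal-only start.
    """
    A_pred = np.asarray(A_pred, dtype=float)
    U_raw = np.asarray(U_raw, dtype=float)
    n = U_raw.shape[0]
    if mode not in ("diag-then-signs", "full", "two-opt"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "full" and n > 8:
        raise ValueError("full exhaustive search guarded at n > 8; use two-opt mode")
    # slot a of the corrected PEM takes raw state perm[a]
    diag_cost = (np.diag(A_pred)[:, None] - np.diag(U_raw)[None, :]) ** 2
    perm = linear_assign(diag_cost)
    U_perm = U_raw[np.ix_(perm, perm)]
    signs, obj = _best_signs(A_pred, U_perm)
    S = SignedPermutation(perm=perm, signs=signs)
    if mode == "diag-then-signs":
        return S.gauge_fixed(), obj
    if mode == "two-opt":
        refined = two_opt_refine(S, lambda c: pem_objective(A_pred, U_raw, c))
        return refined, pem_objective(A_pred, U_raw, refined)
    best, best_obj = S.gauge_fixed(), obj
    for cand in enumerate_signed_permutations(n):
        cand_obj = pem_objective(A_pred, U_raw, cand)
        if cand_obj < best_obj - 1e-15:
            best, best_obj = cand, cand_obj
    return best, best_obj


#: default annealing schedule for the hyperparameter refresh: each phase
#: restricts the sigma and lambda grids to their upper (smoother / more
#: regularized) fractions, melting domain-wall local optima before the full
#: grids are released; values are (sigma_fraction, lambda_fraction) cut-offs.
DEFAULT_SCHEDULE: tuple[tuple[float, float], ...] = (
    (0.99, 0.99),
    (0.6, 0.85),
    (0.45, 0.75),
    (0.33, 0.67),
    (0.0, 0.0),
)


@dataclass(frozen=True)
class OptimizationConfig:
    """Knobs of the EM correction.

    ``n_restarts`` follows the study default of 1000 independent runs for
    energy reordering; scale it down for quick exploration.  ``mode`` selects
    the per-geometry signed-permutation search.  ``schedule`` is the
    hyperparameter refresh schedule: a sequence of (sigma, lambda) grid
    cut-off fractions applied phase by phase — deterministic annealing, from
    a first mean-field phase (only the smoothest, most regularized grid
    point) to the full grids; a single all-zero phase reproduces plain
    full-grid refresh every sweep.  ``repair_rounds`` caps the outlier-repair
    passes that melt residual domain-wall optima (0 disables them).
    """

    n_restarts: int = 1000
    max_sweeps: int = 50
    seed: int = 0
    mode: str = "full"
    sigma_grid: np.ndarray | None = None
    lambda_grid: np.ndarray | None = None
    cv_folds: int = 10
    nested_outer_folds: int = 5
    nested_inner_folds: int = 10
    schedule: tuple[tuple[float, float], ...] = DEFAULT_SCHEDULE
    repair_rounds: int = 6
    repair_quantile: float = 0.75
    repair_neighbors: int = 4

    def __post_init__(self):
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if not self.schedule:
            raise ValueError("schedule needs at least one phase")


@dataclass(frozen=True)
class ClusterAssignment:
    """Per-geometry signed permutations plus the loss they achieve."""

    assignments: tuple[SignedPermutation, ...]
    loss: float
    converged: bool
    n_sweeps: int
    seed: int
    hyperparams: tuple[tuple[float, float], ...] = ()

    @property
    def n_geometries(self) -> int:
        return len(self.assignments)


def _triu_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n)


def pem_to_elements(U: np.ndarray) -> np.ndarray:
    """Independent elements (upper triangle incl. diagonal, counted once)."""
    iu, ju = _triu_indices(U.shape[0])
    return U[iu, ju]


def elements_to_pem(vals: np.ndarray, n: int) -> np.ndarray:
    U = np.zeros((n, n))
    iu, ju = _triu_indices(n)
    U[iu, ju] = vals
    U[ju, iu] = vals
    return U


class _EMProblem:
    """Shared scaffolding of the two EM variants (energy / PEM targets)."""

    def __init__(self, X: np.ndarray, config: OptimizationConfig):
        self.X = np.asarray(X, dtype=float)
        self.config = config
        self.n_geoms = self.X.shape[0]

    n_states: int

    def target_matrix(self, assignments: list[SignedPermutation]) -> np.ndarray:
        raise NotImplementedError

    def reassign(self, g: int, loo_row: np.ndarray) -> SignedPermutation:
        raise NotImplementedError

    def assignment_cost(self, g: int, pred_row: np.ndarray, S: SignedPermutation) -> float:
        raise NotImplementedError

    def accept_margin(
        self,
        g: int,
        pred_row: np.ndarray,
        proposal: SignedPermutation,
        current: SignedPermutation,
        margin: float = 0.25,
    ) -> bool:
        """Accept a repair proposal only when it beats the current assignment
        decisively (cost ratio below ``margin``) — guards heuristic
        extrapolations against flipping marginal cases."""
        if proposal == current:
            return True
        return self.assignment_cost(g, pred_row, proposal) < margin * self.assignment_cost(
            g, pred_row, current
        )


class _EnergyProblem(_EMProblem):
    """Reordering of adiabatic energies: cluster c takes state perm[c]."""

    def __init__(self, energies: np.ndarray, X: np.ndarray, config: OptimizationConfig):
        super().__init__(X, config)
        self.E = np.asarray(energies, dtype=float)
        self.n_states = self.E.shape[1]
        if self.E.shape[0] != self.n_geoms:
            raise ValueError("one energy row per geometry required")

    def target_matrix(self, assignments) -> np.ndarray:
        return np.array([self.E[g, list(s.perm)] for g, s in enumerate(assignments)])

    def reassign(self, g: int, loo_row: np.ndarray) -> SignedPermutation:
        cost = (loo_row[:, None] - self.E[g][None, :]) ** 2
        return SignedPermutation(perm=linear_assign(cost), signs=(1,) * self.n_states)

    def assignment_cost(self, g: int, pred_row: np.ndarray, S: SignedPermutation) -> float:
        return float(np.sum((pred_row - self.E[g, list(S.perm)]) ** 2))


class _PEMProblem(_EMProblem):
    """Signed-permutation correction of raw diabatic PEMs."""

    def __init__(self, pems: np.ndarray, X: np.ndarray, config: OptimizationConfig):
        super().__init__(X, config)
        self.U_raw = np.asarray(pems, dtype=float)
        self.n_states = self.U_raw.shape[1]
        if self.U_raw.shape[0] != self.n_geoms:
            raise ValueError("one PEM per geometry required")

    def target_matrix(self, assignments) -> np.ndarray:
        return np.array(
            [
                pem_to_elements(apply_signed_permutation(self.U_raw[g], s))
                for g, s in enumerate(assignments)
            ]
        )

    def reassign(self, g: int, loo_row: np.ndarray) -> SignedPermutation:
        A_pred = elements_to_pem(loo_row, self.n_states)
        S, _ = assign_geometry_pem(A_pred, self.U_raw[g], mode=self.config.mode)
        return S

    def assignment_cost(self, g: int, pred_row: np.ndarray, S: SignedPermutation) -> float:
        A_pred = elements_to_pem(pred_row, self.n_states)
        return pem_objective(A_pred, self.U_raw[g], S)


def _build_workspaces(
    X: np.ndarray, hyperparams: list[tuple[float, float]]
) -> dict[tuple[float, float], KernelWorkspace]:
    """One factorization per distinct (sigma, lambda); columns share them."""
    workspaces: dict[tuple[float, float], KernelWorkspace] = {}
    for hp in hyperparams:
        if hp not in workspaces:
            workspaces[hp] = KernelWorkspace(X, hp[0], hp[1])
    return workspaces


def _loo_matrix(
    Y: np.ndarray,
    hyperparams: list[tuple[float, float]],
    workspaces: dict[tuple[float, float], KernelWorkspace],
) -> np.ndarray:
    """Centered LOO predictions per target column from cached factorizations.

    The factorizations depend only on the features, so target updates during
    a sweep reuse them; only the O(n^2) solve is repeated.  Targets are
    mean-centered (mean restored afterwards) so that an over-regularized
    cluster model falls back to the cluster mean rather than to zero — without
    this, badly fitted initial clusters all predict ~0 and the assignment
    step carries no signal."""
    loo = np.empty_like(Y)
    for hp in set(hyperparams):
        cols = [c for c, h in enumerate(hyperparams) if h == hp]
        means = Y[:, cols].mean(axis=0)
        loo[:, cols] = means + workspaces[hp].loo(Y[:, cols] - means)
    return loo


def em_optimize(
    problem_data,
    target: str,
    X: np.ndarray,
    config: OptimizationConfig,
    initial: list[SignedPermutation] | None = None,
) -> ClusterAssignment:
    """One EM run: annealed hyperparameter refresh, reassignment sweeps, and
    domain-repair passes.

    ``problem_data`` is an (n_geoms, n_states) energy array for
    ``target='energies'`` or an (n_geoms, n, n) stack of symmetric raw PEMs
    for ``target='pems'``.  The run proceeds in three stages:

    1. annealing — the hyperparameter refresh walks through
       ``config.schedule``; each phase restricts the sigma/lambda grids to
       their smooth end and runs reassignment sweeps (immediate cluster
       updates, seeded random geometry order) until a sweep changes nothing,
       then the next phase opens the grids further.  Smooth early models act
       as a mean field that sorts states onto separated surfaces before
       flexible models are allowed to refine — and to entrench — details.
    2. repair — spatially coherent misassigned domains survive annealing
       because a flexible model fits their wall; each repair pass flags the
       worst-fitted geometries (top loss quantile plus nearest neighbours),
       retrains on the remainder only, reassigns the flagged geometries from
       those unpolluted predictions, re-converges, and keeps the result only
       if the total loss decreased (otherwise rolls back and stops).
    3. the final loss is the mean squared leave-one-out error over all
       targets under the last hyperparameters.

    Revisiting an earlier assignment state within a phase (oscillation)
    moves on to the next phase; exceeding ``max_sweeps`` in total returns
    ``converged=False``.  Deterministic given ``config.seed``.
    """
    from scipy.spatial.distance import cdist

    from .krr import default_lambda_grid, default_sigma_grid

    if target == "energies":
        problem: _EMProblem = _EnergyProblem(problem_data, X, config)
    elif target == "pems":
        problem = _PEMProblem(problem_data, X, config)
    else:
        raise ValueError("target must be 'energies' or 'pems'")
    n_geoms, n_states = problem.n_geoms, problem.n_states
    if n_geoms < 2:
        raise ValueError("need at least two geometries")
    rng = np.random.default_rng(config.seed)
    assignments = list(initial) if initial is not None else [
        SignedPermutation.identity(n_states) for _ in range(n_geoms)
    ]
    Y = problem.target_matrix(assignments)
    sigma_grid = (
        np.sort(np.asarray(config.sigma_grid, float))
        if config.sigma_grid is not None
        else default_sigma_grid(X)
    )
    lambda_grid = (
        np.sort(np.asarray(config.lambda_grid, float))
        if config.lambda_grid is not None
        else default_lambda_grid()
    )
    state = {"sweeps": 0, "converged": False, "hyperparams": [], "budget": True}

    def run_phase(sg: np.ndarray, lg: np.ndarray) -> None:
        """Sweeps at one grid restriction until no change / oscillation."""
        nonlocal Y
        seen_states = {tuple(assignments)}
        while True:
            if state["sweeps"] >= config.max_sweeps:
                state["budget"] = False
                return
            state["sweeps"] += 1
            # expectation step: refresh hyperparameters on the current clusters
            plan = CVPlan(n_geoms, config.cv_folds, seed=int(rng.integers(2**31)))
            picks = grid_search_cv_multi(X, Y, sg, lg, plan, center=True)
            state["hyperparams"] = [(s, l) for s, l, _ in picks]
            workspaces = _build_workspaces(X, state["hyperparams"])
            changed = 0
            # maximization step: reassign geometry by geometry, updating at once
            for g in rng.permutation(n_geoms):
                loo = _loo_matrix(Y, state["hyperparams"], workspaces)
                new_assignment = problem.reassign(int(g), loo[g])
                if new_assignment != assignments[g]:
                    changed += 1
                    assignments[g] = new_assignment
                    Y = problem.target_matrix(assignments)
            if changed == 0:
                state["converged"] = True
                return
            state["converged"] = False
            key = tuple(assignments)
            if key in seen_states:
                return  # oscillation: revisited a previous state
            seen_states.add(key)

    def current_loss() -> tuple[float, np.ndarray]:
        workspaces = _build_workspaces(X, state["hyperparams"])
        loo = _loo_matrix(Y, state["hyperparams"], workspaces)
        per_geom = np.sum((Y - loo) ** 2, axis=1)
        return float(np.mean((Y - loo) ** 2)), per_geom

    for s_frac, l_frac in config.schedule:
        sg = sigma_grid[min(int(s_frac * len(sigma_grid)), len(sigma_grid) - 1) :]
        lg = lambda_grid[min(int(l_frac * len(lambda_grid)), len(lambda_grid) - 1) :]
        run_phase(sg, lg)
        if not state["budget"]:
            break

    def _model_proposals(flagged: np.ndarray, clean: np.ndarray) -> np.ndarray:
        """Predicted target rows for flagged geometries from models trained on
        the clean set only (extrapolation from the consistent region)."""
        plan = CVPlan(len(clean), config.cv_folds, seed=int(rng.integers(2**31)))
        picks = grid_search_cv_multi(X[clean], Y[clean], sigma_grid, lambda_grid, plan)
        clean_ws: dict[tuple[float, float], KernelWorkspace] = {}
        pred = np.empty((len(flagged), Y.shape[1]))
        for c, (sig, lam, _) in enumerate(picks):
            if (sig, lam) not in clean_ws:
                clean_ws[(sig, lam)] = KernelWorkspace(X[clean], sig, lam)
            ws = clean_ws[(sig, lam)]
            mean = Y[clean][:, c].mean()
            alpha = ws.solve(Y[clean][:, c] - mean)
            pred[:, c] = ws.predict(X[flagged], alpha) + mean
        return pred

    def _neighbor_proposals(
        flagged: np.ndarray, clean: np.ndarray, D: np.ndarray
    ) -> np.ndarray:
        """Each flagged geometry targets its nearest clean neighbour's
        corrected row — diabatic targets vary smoothly, so the neighbour's
        values are a sound local reference even at the sampling-box edge,
        where kernel models revert to the mean."""
        nearest = clean[np.argmin(D[np.ix_(flagged, clean)], axis=1)]
        return Y[nearest]

    def _linear_proposals(
        flagged: np.ndarray, clean: np.ndarray, D: np.ndarray
    ) -> np.ndarray:
        """Local first-order extrapolation from the nearest clean geometries.

        Unlike the Gaussian-kernel models, a linear fit continues the local
        trend of each target through a crossing seam or past the sampling
        boundary instead of reverting to the mean — the proposal that melts
        wrong domains adjacent to an edge, where no correctly assigned
        anchor exists on the far side."""
        X2 = np.atleast_2d(X)
        k = min(10, len(clean))
        pred = np.empty((len(flagged), Y.shape[1]))
        for i, g in enumerate(flagged):
            near = clean[np.argsort(D[g, clean])[:k]]
            A = np.hstack([np.ones((len(near), 1)), X2[near]])
            coef, *_ = np.linalg.lstsq(A, Y[near], rcond=None)
            pred[i] = np.hstack([1.0, X2[g]]) @ coef
        return pred

    loss, per_geom = current_loss()
    if config.repair_rounds > 0 and n_geoms >= 20 and state["budget"]:
        D = cdist(np.atleast_2d(X), np.atleast_2d(X))
        for _ in range(config.repair_rounds):
            worst = np.where(per_geom >= np.quantile(per_geom, config.repair_quantile))[0]
            knn = np.argsort(D[worst], axis=1)[:, : config.repair_neighbors]
            flagged = np.unique(np.concatenate([worst, knn.ravel()]))
            cap = int(0.65 * n_geoms)
            if len(flagged) > cap:
                flagged = flagged[np.argsort(-per_geom[flagged])[:cap]]
            clean = np.setdiff1d(np.arange(n_geoms), flagged)
            improved = False
            for strategy in ("model", "linear", "neighbor"):
                snapshot, Y_snapshot = list(assignments), Y.copy()
                snapshot_state = dict(state)
                if strategy == "model":
                    pred = _model_proposals(flagged, clean)
                elif strategy == "linear":
                    pred = _linear_proposals(flagged, clean, D)
                else:
                    pred = _neighbor_proposals(flagged, clean, D)
                for k, g in enumerate(flagged):
                    proposal = problem.reassign(int(g), pred[k])
                    if strategy == "model" or problem.accept_margin(
                        int(g), pred[k], proposal, assignments[g]
                    ):
                        assignments[g] = proposal
                Y = problem.target_matrix(assignments)
                run_phase(sigma_grid, lambda_grid)
                new_loss, new_per_geom = current_loss()
                if state["budget"] and new_loss < loss * (1.0 - 1e-9):
                    loss, per_geom = new_loss, new_per_geom
                    improved = True
                    break
                assignments[:] = snapshot
                Y = Y_snapshot
                state.update(snapshot_state)
            if not improved or not state["budget"]:
                break

    return ClusterAssignment(
        assignments=tuple(assignments),
        loss=loss,
        converged=bool(state["converged"]),
        n_sweeps=int(state["sweeps"]),
        seed=config.seed,
        hyperparams=tuple(state["hyperparams"]),
    )


def _random_initial(
    rng: np.random.Generator, n_geoms: int, n_states: int
) -> list[SignedPermutation]:
    return [
        SignedPermutation(perm=tuple(rng.permutation(n_states)), signs=(1,) * n_states)
        for _ in range(n_geoms)
    ]


def multistart_select(
    problem_data,
    target: str,
    X: np.ndarray,
    config: OptimizationConfig,
) -> tuple[ClusterAssignment, dict]:
    """Run the EM from the identity ordering plus random restarts; rank by
    nested cross-validation.

    Restarts are independent (identical results regardless of execution
    order).  Converged solutions are preferred and ranked by nested-CV score;
    ties fall back to lower loss, then lower restart seed.  If nothing
    converged, the best-loss flagged result is returned.
    """
    rng = np.random.default_rng(config.seed)
    if target == "energies":
        n_states = np.asarray(problem_data).shape[1]
    else:
        n_states = np.asarray(problem_data).shape[2]
    n_geoms = np.asarray(problem_data).shape[0]
    results: list[tuple[ClusterAssignment, float]] = []
    for r in range(config.n_restarts):
        run_seed = int(rng.integers(2**31))
        initial = None if r == 0 else _random_initial(rng, n_geoms, n_states)
        run_cfg = replace(config, seed=run_seed)
        result = em_optimize(problem_data, target, X, run_cfg, initial=initial)
        if target == "energies":
            problem: _EMProblem = _EnergyProblem(problem_data, X, run_cfg)
        else:
            problem = _PEMProblem(problem_data, X, run_cfg)
        Y = problem.target_matrix(list(result.assignments))
        score = nested_cv_score(
            X,
            Y,
            config.sigma_grid,
            config.lambda_grid,
            CVPlan(n_geoms, config.nested_outer_folds, seed=config.seed),
            CVPlan(n_geoms, config.nested_inner_folds, seed=config.seed + 1),
            center=True,
        )
        results.append((result, score))
    converged = [(res, sc) for res, sc in results if res.converged]
    pool = converged if converged else results
    best, best_score = min(pool, key=lambda t: (t[1], t[0].loss, t[0].seed))
    diagnostics = {
        "n_restarts": config.n_restarts,
        "n_converged": len(converged),
        "scores": [sc for _, sc in results],
        "losses": [res.loss for res, _ in results],
        "best_score": best_score,
    }
    return best, diagnostics


def global_gauge_mode(
    assignments: list[SignedPermutation], truth: list[SignedPermutation]
) -> tuple[SignedPermutation | None, float]:
    """Most common global gauge element linking found assignments to truth.

    ``truth[g]`` is the scramble applied to geometry g (U_scrambled =
    truth^T U_true truth); a perfect recovery has truth[g] @ found[g] equal
    to one fixed gauge element G for every geometry.  Returns the modal G and
    the fraction of geometries consistent with it.
    """
    combos = [t.compose(s).gauge_fixed() for s, t in zip(assignments, truth)]
    counts: dict[SignedPermutation, int] = {}
    for c in combos:
        counts[c] = counts.get(c, 0) + 1
    mode = max(counts, key=lambda k: counts[k])
    return mode, counts[mode] / len(combos)
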