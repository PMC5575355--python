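"""Total-variation constrained permutation (TCP) solver.

Jointly estimates a sample arrangement P and a denoised signal matrix X from
a noisy read-depth matrix B by minimizing

    || P X - B ||_F^2  +  alpha * || X ||_{TV,l1}

where the (TV, l1) norm sums, per bin column, the absolute first differences
down the sample axis.  Stacking similar samples contiguously is the only way
to make X both close to a row-rearrangement of B and smooth down each
column, so the minimizer reveals common copy-number blocks.

The energy is split with Y = D X (D the first-order difference operator)
and minimized by an augmented-Lagrangian alternation of three exact
subproblem solves per sweep:

1. X-step: a linear solve ``(2I + gamma D'D) X = 2 P'B - D'lambda + gamma D'Y``,
   diagonalized by the FFT along the sample axis when D is circulant.
2. Y-step: element-wise soft thresholding ``Y = S_{alpha/gamma}(DX + lambda/gamma)``.
3. P-step: a linear assignment (Kuhn-Munkres) matching rows of X to rows of
   B, the exact minimizer of the fidelity term over all permutations.

followed by the dual ascent ``lambda <- lambda + gamma (DX - Y)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fft, ifft
from scipy.linalg import solveh_banded
from scipy.optimize import linear_sum_assignment

from .containers import DifferenceOperator, ReadDepthMatrix, SampleOrdering
from .errors import InvalidInputError, NumericalFailureError

__all__ = [
    "TCPConfig",
    "SolverState",
    "TCPResult",
    "tv_l1_norm",
    "tcp_objective",
    "build_difference_operator",
    "soft_threshold",
    "update_X",
    "update_Y",
    "update_P",
    "update_dual",
    "check_convergence",
    "solve_tcp",
]


# ---------------------------------------------------------------------------
# configuration and state


@dataclass
class TCPConfig:
    """Solver parameters.

    alpha
        TV/sparsity trade-off.  ``None`` selects the data-scaled default
        ``alpha_scale * gamma * mean(|row differences of B|)``: the implied
        soft-threshold level alpha/gamma then sits just above the typical
        adjacent-row difference, so noise-scale differences collapse into
        plateaus while group-scale differences survive.
    gamma
        Augmented-Lagrangian penalty; also sets the X-step smoothing scale
        (half-width ~ sqrt(gamma/2) samples).  ``None`` selects ``0.64 m``
        (about 6 samples of smoothing at m = 100 — wide enough to form
        plateaus spanning several samples, narrower than a typical group).
    alpha_scale
        Multiplier used by the automatic alpha (default 1.3).
    max_iters, tol, stall_window
        Iteration cap and convergence controls; see :func:`check_convergence`.
    boundary
        ``"circular"`` (FFT-diagonalized X-step; default) or ``"open"``
        (banded solve, no wraparound TV term).
    seed
        Accepted for interface symmetry; the solver itself is deterministic.
    polish, polish_max_segments, polish_iters
        The row-level assignment moves cannot merge a group that converged
        split into two distant segments (a coordinated block move would be
        needed).  With ``polish`` on (default), after the main loop the
        arrangement is cut into contiguous segments at the large
        adjacent-row jumps; if there are at most ``polish_max_segments`` of
        them, all cyclic segment arrangements (including reversals) are
        scored by their TV boundary cost, the best is refined for up to
        ``polish_iters`` further sweeps, and the branch with the lower
        final energy wins.  Deterministic, and a no-op when the arrangement
        is already optimal at segment level.
    """

    alpha: float | None = None
    gamma: float | None = None
    alpha_scale: float = 1.3
    max_iters: int = 1000
    tol: float = 1e-6
    stall_window: int = 10
    boundary: str = "circular"
    seed: int | None = None
    polish: bool = True
    polish_max_segments: int = 7
    polish_iters: int = 100

    def __post_init__(self) -> None:
        if self.alpha is not None and self.alpha < 0:
            raise InvalidInputError(f"alpha must be >= 0, got {self.alpha}")
        if self.gamma is not None and self.gamma <= 0:
            raise InvalidInputError(f"gamma must be > 0, got {self.gamma}")
        if self.max_iters < 1:
            raise InvalidInputError("max_iters must be >= 1")
        if self.tol <= 0:
            raise InvalidInputError(f"tol must be > 0, got {self.tol}")
        if self.stall_window < 1:
            raise InvalidInputError("stall_window must be >= 1")
        if self.boundary not in ("circular", "open"):
            raise InvalidInputError(f"unknown boundary {self.boundary!r}")

    def resolve(self, B: np.ndarray) -> tuple[float, float]:
        """Concrete (alpha, gamma) for a data matrix."""
        m = B.shape[0]
        gamma = self.gamma if self.gamma is not None else 0.64 * m
        if self.alpha is not None:
            alpha = self.alpha
        else:
            alpha = self.alpha_scale * gamma * float(np.mean(np.abs(np.diff(B, axis=0))))
        return alpha, gamma


@dataclass
class SolverState:
    """Iterates of the alternating scheme."""

    X: np.ndarray
    Y: np.ndarray
    dual: np.ndarray
    ordering: SampleOrdering
    iteration: int = 0
    objective_history: list[float] = field(default_factory=list)
    primal_residual_history: list[float] = field(default_factory=list)
    ordering_changed_history: list[bool] = field(default_factory=list)


@dataclass
class TCPResult:
    """Final solver output.

    ``recovered`` is the denoised X laid out in the final display order,
    with sample identifiers rearranged to match; ``trace`` holds one record
    per iteration (objective, fidelity, TV term, primal residual,
    ordering-changed flag).
    """

    state: SolverState
    converged: bool
    recovered: ReadDepthMatrix
    trace: list[dict] = field(default_factory=list)

    @property
    def ordering(self) -> SampleOrdering:
        return self.state.ordering


# ---------------------------------------------------------------------------
# norms and objective


def tv_l1_norm(X: np.ndarray, boundary: str = "circular") -> float:
    """(TV, l1) norm: per-column l1 norm of first differences, summed.

    Open boundary sums |x[i,j] - x[i-1,j]| for i = 1..m-1 in each column;
    circular adds the per-column wraparound term |x[0,j] - x[m-1,j]|.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InvalidInputError("tv_l1_norm needs a 2-D matrix with m >= 2")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("tv_l1_norm: non-finite entries")
    D = DifferenceOperator(X.shape[0], boundary)
    return float(np.sum(np.abs(D.apply(X))))


def tcp_objective(
    X: np.ndarray,
    ordering: SampleOrdering,
    B: np.ndarray,
    alpha: float,
    boundary: str = "circular",
) -> float:
    """Energy ``||P X - B||_F^2 + alpha ||X||_{TV,l1}``."""
    X = np.asarray(X, dtype=float)
    B = np.asarray(B, dtype=float)
    if X.shape != B.shape:
        raise InvalidInputError(f"shape mismatch: X {X.shape} vs B {B.shape}")
    fidelity = float(np.sum((X - ordering.apply(B)) ** 2))
    return fidelity + alpha * tv_l1_norm(X, boundary)


def build_difference_operator(m: int, boundary: str = "circular") -> DifferenceOperator:
    """First-order difference operator on m samples."""
    return DifferenceOperator(m, boundary)


def soft_threshold(c, t: float):
    """Shrinkage operator S_t: c-t above t, 0 inside [-t, t], c+t below -t.

    The proximal map of ``t * |.|``; applied element-wise to arrays.
    """
    if t < 0:
        raise InvalidInputError(f"threshold must be >= 0, got {t}")
    c = np.asarray(c, dtype=float)
    out = np.sign(c) * np.maximum(np.abs(c) - t, 0.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# subproblem updates


def _check_conforming(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise InvalidInputError(f"non-conforming shapes: {sorted(shapes)}")


def update_X(
    ordering: SampleOrdering,
    B: np.ndarray,
    Y: np.ndarray,
    dual: np.ndarray,
    gamma: float,
    D: DifferenceOperator,
) -> np.ndarray:
    """Exact minimizer of the X-subproblem.

    Solves ``(2I + gamma D'D) X = 2 P'B - D'lambda + gamma D'Y``.  For the
    circulant D this is diagonal in Fourier space: each column is
    transformed along the sample axis, divided by ``2 + gamma |K|^2`` and
    transformed back.  The open-boundary operator yields a symmetric
    tridiagonal system solved in banded form.
    """
    if gamma <= 0:
        raise InvalidInputError(f"gamma must be > 0, got {gamma}")
    B = np.asarray(B, dtype=float)
    Y = np.asarray(Y, dtype=float)
    dual = np.asarray(dual, dtype=float)
    _check_conforming(B, Y, dual)
    if ordering.size != B.shape[0] or D.size != B.shape[0]:
        raise InvalidInputError("ordering/operator size does not match matrix rows")

    rhs = 2.0 * ordering.apply(B) - D.apply_transpose(dual) + gamma * D.apply_transpose(Y)
    if D.boundary == "circular":
        denom = 2.0 + gamma * np.abs(D.spectrum) ** 2
        Xc = ifft(fft(rhs, axis=0) / denom[:, None], axis=0)
        X = np.real(Xc)
        resid = np.linalg.norm(np.imag(Xc))
        if resid > 1e-8 * max(np.linalg.norm(X), 1.0):
            raise NumericalFailureError(
                f"imaginary residue {resid:.3e} after inverse FFT"
            )
        return X
    # open boundary: 2I + gamma D'D is SPD tridiagonal
    m = B.shape[0]
    Dm = D.matrix_form
    A = 2.0 * np.eye(m) + gamma * (Dm.T @ Dm)
    ab = np.zeros((2, m))
    ab[0, 1:] = np.diag(A, 1)
    ab[1] = np.diag(A)
    return solveh_banded(ab, rhs)


def update_Y(
    X: np.ndarray,
    dual: np.ndarray,
    alpha: float,
    gamma: float,
    D: DifferenceOperator,
) -> np.ndarray:
    """Exact minimizer of the Y-subproblem: ``S_{alpha/gamma}(DX + dual/gamma)``."""
    if gamma <= 0:
        raise InvalidInputError(f"gamma must be > 0, got {gamma}")
    if alpha < 0:
        raise InvalidInputError(f"alpha must be >= 0, got {alpha}")
    X = np.asarray(X, dtype=float)
    dual = np.asarray(dual, dtype=float)
    _check_conforming(X, dual)
    return soft_threshold(D.apply(X) + dual / gamma, alpha / gamma)


def update_P(X: np.ndarray, B: np.ndarray) -> SampleOrdering:
    """Exact minimizer of ``||P X - B||_F^2`` over permutation matrices.

    A linear assignment with cost ``C[i, k] = ||X_k - B_i||^2`` solved by
    the Kuhn-Munkres algorithm.  Among equal-cost optima, cycles whose
    diagonal entries cost the same as the assigned entries are canonicalized
    to the identity mapping, so ``X == B`` returns the identity ordering.
    """
    X = np.asarray(X, dtype=float)
    B = np.asarray(B, dtype=float)
    if X.shape != B.shape:
        raise InvalidInputError(f"shape mismatch: X {X.shape} vs B {B.shape}")
    # C[i, k] = ||B_i||^2 - 2 B_i . X_k + ||X_k||^2
    C = (
        np.sum(B * B, axis=1)[:, None]
        - 2.0 * B @ X.T
        + np.sum(X * X, axis=1)[None, :]
    )
    np.maximum(C, 0.0, out=C)
    _, assign = linear_sum_assignment(C)  # assign[i] = position of sample i
    assign = _prefer_identity_on_ties(C, assign)
    return SampleOrdering(np.argsort(assign))


def _prefer_identity_on_ties(C: np.ndarray, assign: np.ndarray) -> np.ndarray:
    """Replace permutation cycles by the identity when that costs the same."""
    assign = assign.copy()
    m = assign.size
    seen = np.zeros(m, dtype=bool)
    for start in range(m):
        if seen[start] or assign[start] == start:
            seen[start] = True
            continue
        cycle = [start]
        seen[start] = True
        j = assign[start]
        # follow i -> assign[i] through sample indices until the cycle closes
        while j != start:
            cycle.append(j)
            seen[j] = True
            j = assign[j]
        assigned_cost = sum(C[i, assign[i]] for i in cycle)
        diag_cost = sum(C[i, i] for i in cycle)
        if diag_cost <= assigned_cost + 1e-12 * max(assigned_cost, 1.0):
            for i in cycle:
                assign[i] = i
    return assign


def update_dual(
    dual: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    gamma: float,
    D: DifferenceOperator,
) -> np.ndarray:
    """Augmented-Lagrangian ascent ``dual + gamma (DX - Y)``."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    dual = np.asarray(dual, dtype=float)
    _check_conforming(dual, X, Y)
    return dual + gamma * (D.apply(X) - Y)


# ---------------------------------------------------------------------------
# convergence and driver


def check_convergence(state: SolverState, tol: float, stall_window: int) -> bool:
    """True when residual and objective have both settled, or the ordering stalls.

    Settled: relative primal residual ``||DX - Y||_F / max(||DX||, ||Y||, 1)``
    <= tol and relative objective change over the last step <= tol.  Stalled:
    the ordering was identical for the last ``stall_window`` iterations.
    """
    if state.iteration < 1:
        return False
    hist = state.ordering_changed_history
    if len(hist) >= stall_window and not any(hist[-stall_window:]):
        return True
    if len(state.objective_history) < 2:
        return False
    res = state.primal_residual_history[-1]
    prev, last = state.objective_history[-2], state.objective_history[-1]
    rel_obj = abs(last - prev) / max(abs(prev), 1.0)
    return res <= tol and rel_obj <= tol


def _relative_residual(DX: np.ndarray, Y: np.ndarray) -> float:
    num = float(np.linalg.norm(DX - Y))
    den = max(float(np.linalg.norm(DX)), float(np.linalg.norm(Y)), 1.0)
    return num / den


def _canonical_rotation(order: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Rotate a circular arrangement so the sharpest seam sits at the boundary.

    The circular TV energy is invariant to cyclic rotation of the display
    positions, so a recovered block generically wraps across the seam.  The
    cut is placed at the largest adjacent raw-row jump
    ``||B[order[i]] - B[order[i-1]]||`` (raw rows, not the smoothed X: the
    X-step smears plateau transitions over ~ sqrt(gamma/2) samples, which
    would offset the cut).
    """
    Bo = B[order]
    jumps = np.linalg.norm(Bo - np.roll(Bo, 1, axis=0), axis=1)
    return np.roll(order, -int(np.argmax(jumps)))


def _init_state(Bv: np.ndarray, ordering: SampleOrdering, D: DifferenceOperator,
                alpha: float, boundary: str) -> SolverState:
    X0 = ordering.apply(Bv)
    state = SolverState(
        X=X0,
        Y=D.apply(X0),
        dual=np.zeros_like(Bv),
        ordering=ordering,
    )
    state.objective_history.append(
        tcp_objective(state.X, state.ordering, Bv, alpha, boundary)
    )
    state.primal_residual_history.append(
        _relative_residual(D.apply(state.X), state.Y)
    )
    return state


def _run_sweeps(
    state: SolverState,
    Bv: np.ndarray,
    alpha: float,
    gamma: float,
    D: DifferenceOperator,
    config: TCPConfig,
    max_iters: int,
    trace: list[dict],
) -> bool:
    """Alternating X/Y/P/dual sweeps; mutates state, returns convergence flag."""
    start = state.iteration
    for k in range(start + 1, start + max_iters + 1):
        state.X = update_X(state.ordering, Bv, state.Y, state.dual, gamma, D)
        state.Y = update_Y(state.X, state.dual, alpha, gamma, D)
        fidelity_before = float(np.sum((state.X - state.ordering.apply(Bv)) ** 2))
        new_ordering = update_P(state.X, Bv)
        fidelity_after = float(np.sum((state.X - new_ordering.apply(Bv)) ** 2))
        changed = new_ordering != state.ordering
        state.ordering = new_ordering
        state.dual = update_dual(state.dual, state.X, state.Y, gamma, D)

        if not np.all(np.isfinite(state.X)):
            raise NumericalFailureError(f"non-finite X at iteration {k}")

        tv = tv_l1_norm(state.X, config.boundary)
        objective = fidelity_after + alpha * tv
        state.iteration = k
        state.objective_history.append(objective)
        state.primal_residual_history.append(
            _relative_residual(D.apply(state.X), state.Y)
        )
        state.ordering_changed_history.append(bool(changed))
        trace.append(
            {
                "iteration": k,
                "objective": objective,
                "fidelity": fidelity_after,
                "fidelity_before_P": fidelity_before,
                "tv": tv,
                "primal_residual": state.primal_residual_history[-1],
                "ordering_changed": bool(changed),
            }
        )
        if check_convergence(state, config.tol, config.stall_window):
            return True
    return False


def _segment_rearrangement(order: np.ndarray, B: np.ndarray, max_segments: int) -> np.ndarray | None:
    """Best cyclic re-arrangement of the arrangement's contiguous segments.

    Cuts the arrangement where adjacent raw rows jump by more than the
    largest gap in the sorted jump distribution (separating within-block
    from between-block jumps), then enumerates all cyclic orders and
    orientations of the segments, scoring each by the summed l1 distance
    across segment boundaries — the data-side analogue of the TV term.
    Returns the best arrangement, or None when there is nothing to try
    (too many segments, or fewer than three).
    """
    from itertools import permutations, product

    m = order.size
    Bo = B[order]
    jumps = np.abs(Bo - np.roll(Bo, 1, axis=0)).sum(axis=1)  # jump before position i
    sorted_jumps = np.sort(jumps)
    gaps = np.diff(sorted_jumps)
    if gaps.size == 0 or gaps.max() <= 0:
        return None
    cut_level = sorted_jumps[int(np.argmax(gaps))] + gaps.max() / 2.0
    boundaries = np.flatnonzero(jumps > cut_level)
    k = boundaries.size
    if k < 3 or k > max_segments:
        return None

    segments = []
    for a, b in zip(boundaries, np.roll(boundaries, -1)):
        seg = order[a:b] if a < b else np.r_[order[a:], order[:b]]
        segments.append(seg)

    def boundary_cost(u: int, v: int) -> float:
        return float(np.abs(B[u] - B[v]).sum())

    ends = [(seg[0], seg[-1]) for seg in segments]
    best_cost, best_layout = np.inf, None
    # fix segment 0 forward; enumerate the rest with orientations
    for perm in permutations(range(1, k)):
        for flips in product((False, True), repeat=k - 1):
            layout = [(0, False)] + [(s, f) for s, f in zip(perm, flips)]
            cost = 0.0
            for (s1, f1), (s2, f2) in zip(layout, layout[1:] + layout[:1]):
                tail = ends[s1][0] if f1 else ends[s1][1]
                head = ends[s2][1] if f2 else ends[s2][0]
                cost += boundary_cost(tail, head)
            if cost < best_cost - 1e-12:
                best_cost, best_layout = cost, layout
    new_order = np.concatenate(
        [segments[s][::-1] if f else segments[s] for s, f in best_layout]
    )
    assert new_order.size == m
    return new_order


def solve_tcp(B: ReadDepthMatrix | np.ndarray, config: TCPConfig | None = None) -> TCPResult:
    """Run the three-step alternating scheme until convergence.

    Initialization: identity ordering, X = B, Y = DX, dual = 0.  Each sweep
    applies the X-, Y- and P-updates followed by the dual ascent, recording
    the energy and the primal residual ``||DX - Y||_F``.  When enabled, a
    deterministic segment-rearrangement polish then attempts the block
    moves the row-level assignment cannot make, keeping the branch with
    the lower final energy.  For the circular boundary the final
    arrangement is rotated so the sharpest seam in the data sits at the
    display boundary (the circular energy cannot distinguish rotations).
    """
    if config is None:
        config = TCPConfig()
    if not isinstance(B, ReadDepthMatrix):
        B = ReadDepthMatrix(np.asarray(B, dtype=float))
    Bv = B.values
    m = B.n_samples
    alpha, gamma = config.resolve(Bv)
    D = build_difference_operator(m, config.boundary)

    state = _init_state(Bv, SampleOrdering.identity(m), D, alpha, config.boundary)
    trace: list[dict] = []
    converged = _run_sweeps(state, Bv, alpha, gamma, D, config, config.max_iters, trace)

    if config.polish and config.boundary == "circular":
        rearranged = _segment_rearrangement(
            state.ordering.order, Bv, config.polish_max_segments
        )
        if rearranged is not None and not np.array_equal(
            rearranged, state.ordering.order
        ):
            alt = _init_state(
                Bv, SampleOrdering(rearranged), D, alpha, config.boundary
            )
            # count the segment jump as one more iteration of the same run,
            # so histories and trace stay contiguous
            jump_iter = state.iteration + 1
            alt.iteration = jump_iter
            alt.objective_history = state.objective_history + alt.objective_history
            alt.primal_residual_history = (
                state.primal_residual_history + alt.primal_residual_history
            )
            alt.ordering_changed_history = state.ordering_changed_history + [True]
            jump_record = {
                "iteration": jump_iter,
                "objective": alt.objective_history[-1],
                "fidelity": 0.0,
                "fidelity_before_P": 0.0,
                "tv": tv_l1_norm(alt.X, config.boundary),
                "primal_residual": alt.primal_residual_history[-1],
                "ordering_changed": True,
            }
            alt_trace: list[dict] = [jump_record]
            alt_converged = _run_sweeps(
                alt, Bv, alpha, gamma, D, config, config.polish_iters, alt_trace
            )
            if alt.objective_history[-1] < state.objective_history[-1]:
                state, converged, trace = alt, alt_converged, trace + alt_trace

    if config.boundary == "circular":
        rotated = _canonical_rotation(state.ordering.order, Bv)
        shift = int(np.where(rotated[0] == state.ordering.order)[0][0])
        state.X = np.roll(state.X, -shift, axis=0)
        state.Y = np.roll(state.Y, -shift, axis=0)
        state.dual = np.roll(state.dual, -shift, axis=0)
        state.ordering = SampleOrdering(rotated)

    recovered = ReadDepthMatrix(
        state.X,
        [B.sample_ids[i] for i in state.ordering.order],
        list(B.bin_ids),
    )
    return TCPResult(state=state, converged=converged, recovered=recovered, trace=trace)
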