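"""Stochastic gene-expression dynamics on a regulatory network.

Expression of gene *i* follows a saturating stochastic differential
equation, integrated by Euler–Maruyama with step ``dt``:

    x_i' = x_i + dt * ( sigma(alpha_i + sum_j beta_ji x_j) - ell_i x_i )
               + s * sqrt(dt * x_i) * z_i,       z_i ~ N(0, 1)

where ``sigma`` is the logistic sigmoid, ``alpha_i`` sets baseline
transcription, ``ell_i`` is the RNA decay rate, ``beta_ji`` the signed
weight of regulator *j* on target *i* (nonzero exactly on graph edges) and
``s`` a global noise magnitude.  Synthesis saturates at 1 per unit time, so
expression is bounded by roughly ``1/ell_i``; the state is floored at zero
because the multiplicative noise can momentarily undershoot.

Steady states are detected on the post-burn-in running mean: every ``h``
iterations the maximum absolute log2 fold-change of the running mean
(restricted to genes whose mean exceeds ``s``) since the previous check is
compared against a tolerance.  Linear stability of an equilibrium is
assessed from the Jacobian of the deterministic drift.

Many conditions (e.g. knockouts) can be advanced in lock-step as columns of
a state matrix; each condition draws noise from its own seeded stream, in
fixed-size blocks, so batched and one-at-a-time execution produce identical
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import expit

__all__ = [
    "ExpressionParams",
    "SimConfig",
    "SteadyState",
    "StabilityReport",
    "SimulationDivergedError",
    "sample_expression_params",
    "step",
    "simulate_to_steady_state",
    "simulate_batch",
    "stability_analysis",
    "fixed_point_residual",
    "save_params",
    "load_params",
]

#: steps of noise drawn per generator call (fixed so that batched and
#: sequential runs consume each condition's stream identically)
NOISE_BLOCK = 100


class SimulationDivergedError(RuntimeError):
    """State became non-finite during forward simulation."""

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(f"non-finite expression state at iteration {iteration}")


@dataclass
class ExpressionParams:
    """Parameters of the expression SDE on one network.

    ``beta`` is stored sparse with row = regulator, column = target, so the
    regulatory input to the state vector ``x`` is ``beta.T @ x``.
    """

    alpha: np.ndarray
    ell: np.ndarray
    beta: sp.csr_matrix
    s: float = 1e-4
    dt: float = 0.01

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.ell = np.asarray(self.ell, dtype=float)
        n = len(self.alpha)
        if self.beta.shape != (n, n):
            raise ValueError("beta must be (n, n) matching alpha/ell")
        if np.any(self.ell <= 0):
            raise ValueError("decay rates ell must be positive")
        if self.s < 0 or self.dt <= 0:
            raise ValueError("require s >= 0 and dt > 0")
        self.beta = sp.csr_matrix(self.beta)
        self._bt = None

    @property
    def n_genes(self) -> int:
        return len(self.alpha)

    def beta_transpose(self) -> sp.csr_matrix:
        """Cached transpose used by the integrator."""
        if self._bt is None:
            self._bt = self.beta.T.tocsr()
        return self._bt

    def copy(self) -> "ExpressionParams":
        return ExpressionParams(
            alpha=self.alpha.copy(), ell=self.ell.copy(),
            beta=self.beta.copy(), s=self.s, dt=self.dt,
        )


@dataclass(frozen=True)
class SimConfig:
    """Forward-simulation protocol (burn-in and convergence checking)."""

    burn_in: int = 5000
    check_every: int = 1000
    t_max: int = 20000
    tol: float = 1e-3

    def __post_init__(self) -> None:
        if not (self.burn_in < self.t_max):
            raise ValueError("require burn_in < t_max")
        if self.check_every < 1 or self.tol <= 0:
            raise ValueError("require check_every >= 1 and tol > 0")


@dataclass
class SteadyState:
    """Running-mean expression at (approximate) equilibrium."""

    xbar: np.ndarray
    converged: bool
    iterations_used: int
    expressed_mask: np.ndarray
    final_state: np.ndarray | None = field(default=None, repr=False)


@dataclass
class StabilityReport:
    eigenvalues: np.ndarray
    stable: bool
    max_real_part: float


# ---------------------------------------------------------------------------
# parameter sampling


def sample_expression_params(
    graph, seed=0, *, s: float = 1e-4, dt: float = 0.01
) -> ExpressionParams:
    """Draw expression parameters for a generated network.

    * ``sigma(alpha_i) ~ Beta(2, 8)`` — low but nonzero baseline synthesis;
      ``alpha_i`` recovered by the logit.
    * ``ell_i ~ Beta(8, 2)``, then floored at ``exp(-alpha_i)`` so maximum
      expression ``~1/ell_i = e^{alpha_i}`` cannot become excessively
      large; genes with low baseline synthesis also decay fast, keeping
      steady states of order one and the sigmoid in its responsive range.
    * Each regulator *j* is an activator with probability 0.8 (repressor
      otherwise); all its outgoing edges share the sign.  Edge magnitudes
      are ``1 + |N(0, 1)|``, so ``|beta_ji| >= 1`` on every edge.
    """
    rng = np.random.default_rng(seed)
    n = graph.n_nodes
    sig_alpha = rng.beta(2.0, 8.0, size=n)
    alpha = np.log(sig_alpha) - np.log1p(-sig_alpha)  # logit
    ell = rng.beta(8.0, 2.0, size=n)
    ell = np.maximum(ell, np.exp(-alpha))
    sign = 2.0 * (rng.random(n) < 0.8) - 1.0

    m = graph.n_edges
    if m:
        src = graph.edges[:, 0]
        tgt = graph.edges[:, 1]
        mag = 1.0 + np.abs(rng.standard_normal(m))
        beta = sp.csr_matrix((sign[src] * mag, (src, tgt)), shape=(n, n))
    else:
        beta = sp.csr_matrix((n, n))
    return ExpressionParams(alpha=alpha, ell=ell, beta=beta, s=s, dt=dt)


# ---------------------------------------------------------------------------
# integration


def step(x: np.ndarray, params: ExpressionParams, rng=None) -> np.ndarray:
    """One Euler–Maruyama step from state ``x`` (vector or (n, C) matrix)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input state")
    alpha = params.alpha if x.ndim == 1 else params.alpha[:, None]
    ell = params.ell if x.ndim == 1 else params.ell[:, None]
    drive = expit(alpha + params.beta_transpose() @ x)
    x_new = x + params.dt * (drive - ell * x)
    if params.s > 0:
        if rng is None:
            raise ValueError("rng required when s > 0")
        x_new = x_new + params.s * np.sqrt(params.dt * np.maximum(x, 0.0)) * rng.standard_normal(x.shape)
    return np.maximum(x_new, 0.0)


def _as_generators(seeds, count):
    """Per-condition RNGs from an int seed, SeedSequence/Generator, or list."""
    if isinstance(seeds, (list, tuple)):
        if len(seeds) != count:
            raise ValueError("one seed per condition required")
        return [
            sd if isinstance(sd, np.random.Generator) else np.random.default_rng(sd)
            for sd in seeds
        ]
    if isinstance(seeds, (np.random.Generator, np.random.SeedSequence)):
        if count != 1:
            raise ValueError("pass a list of seeds for multiple conditions")
        return [seeds if isinstance(seeds, np.random.Generator) else np.random.default_rng(seeds)]
    if count == 1:
        return [np.random.default_rng(seeds)]
    return [
        np.random.default_rng(np.random.SeedSequence((int(seeds), c))) for c in range(count)
    ]


def simulate_batch(
    params: ExpressionParams,
    config: SimConfig = SimConfig(),
    seeds=0,
    init: np.ndarray | None = None,
    ko_genes=None,
    n_conditions: int | None = None,
) -> list[SteadyState]:
    """Advance many conditions in lock-step to their steady states.

    Parameters
    ----------
    seeds : int | SeedSequence | Generator | list
        A list gives one RNG seed per condition; a scalar int seeds
        condition ``c`` with ``SeedSequence((seed, c))`` when there are
        several conditions.
    init : (n,) or (n, C) array, optional
        Initial state, broadcast across conditions if a vector
        (default all-zero: genes start unexpressed).
    ko_genes : sequence of (int | None), optional
        Per-condition knockout: the gene whose outgoing regulatory effects
        are nullified for that condition (None = unperturbed).  Implemented
        by subtracting the knocked-out row's contribution from the shared
        sparse product, so a single matrix serves all conditions.

    Returns one :class:`SteadyState` per condition; ``final_state`` carries
    the last simulated (noisy) state for downstream cell sampling.
    Conditions whose running mean has converged are frozen and removed from
    the state matrix at the check where they converge.
    """
    n = params.n_genes
    if ko_genes is not None:
        ko_list = list(ko_genes)
    else:
        if n_conditions is not None:
            C = n_conditions
        elif init is not None and np.ndim(init) == 2:
            C = np.shape(init)[1]
        else:
            C = 1
        ko_list = [None] * C
    C = len(ko_list)

    if init is None:
        X = np.zeros((n, C))
    else:
        init = np.asarray(init, dtype=float)
        X = np.repeat(init[:, None], C, axis=1) if init.ndim == 1 else init.copy()
        if X.shape != (n, C):
            raise ValueError("init shape mismatch")
        if np.any(X < 0) or not np.all(np.isfinite(X)):
            raise ValueError("initial state must be finite and non-negative")

    rngs = _as_generators(seeds, C)
    # single-precision state with double-precision running-mean accumulator:
    # per-step increments are O(dt), far above float32 resolution, while the
    # running mean needs stable summation over tens of thousands of steps
    bt = params.beta_transpose().astype(np.float32)
    beta = params.beta

    dt, s, tol = params.dt, params.s, config.tol
    b, h, t_max = config.burn_in, config.check_every, config.t_max
    alpha_col = params.alpha[:, None].astype(np.float32)
    ell_col = params.ell[:, None].astype(np.float32)
    f_dt = np.float32(dt)
    sdt = np.float32(s * np.sqrt(dt))
    X = X.astype(np.float32)

    def build_corrections(cols):
        """Flat scatter indices removing each KO'd row's contribution."""
        rows, ccols, wts, kos = [], [], [], []
        for ci, c in enumerate(cols):
            g = ko_list[c]
            if g is None:
                continue
            lo, hi = beta.indptr[g], beta.indptr[g + 1]
            rows.append(beta.indices[lo:hi])
            ccols.append(np.full(hi - lo, ci, dtype=np.intp))
            wts.append(beta.data[lo:hi])
            kos.append(np.full(hi - lo, g, dtype=np.intp))
        if not rows:
            return None
        return (
            np.concatenate(rows),
            np.concatenate(ccols),
            np.concatenate(wts).astype(np.float32),
            np.concatenate(kos),
        )

    active = list(range(C))
    corr = build_corrections(active)
    run_sum = np.zeros((n, C))
    prev_mean = None  # aligned with `active`
    results: list[SteadyState | None] = [None] * C
    noise = None
    buf = np.empty_like(X)

    t = 0
    while t < t_max and active:
        if s > 0:
            off = t % NOISE_BLOCK
            if off == 0:
                if noise is None or noise.shape[0] != len(active):
                    noise = np.empty((len(active), NOISE_BLOCK, n), dtype=np.float32)
                for ci, c in enumerate(active):
                    rngs[c].standard_normal(dtype=np.float32, out=noise[ci])
            np.sqrt(X, out=buf)
            buf *= noise[:, off, :].T
            buf *= sdt  # buf now holds the diffusion term
        U = bt @ X
        if corr is not None:
            cr, cc, cw, ck = corr
            U[cr, cc] -= cw * X[ck, cc]
        U += alpha_col
        expit(U, out=U)
        U -= ell_col * X
        U *= f_dt
        X += U
        if s > 0:
            X += buf
        np.maximum(X, np.float32(0.0), out=X)
        t += 1
        if t > b:
            run_sum += X
        if t >= b + h and (t - b) % h == 0:
            if not np.all(np.isfinite(X)):
                raise SimulationDivergedError(t)
            mean = run_sum / (t - b)
            if prev_mean is None:
                prev_mean = mean
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                stat = np.abs(np.log2(mean / prev_mean))
            stat = np.where(mean > s, stat, 0.0)
            stat = np.where(np.isnan(stat), np.inf, stat)
            col_stat = stat.max(axis=0)
            done = col_stat < tol
            if np.any(done):
                keep = ~done
                for ci in np.flatnonzero(done):
                    c = active[ci]
                    xb = mean[:, ci]
                    results[c] = SteadyState(
                        xbar=xb, converged=True, iterations_used=t,
                        expressed_mask=xb > s, final_state=X[:, ci].astype(float),
                    )
                active = [active[ci] for ci in np.flatnonzero(keep)]
                X = np.ascontiguousarray(X[:, keep])
                run_sum = np.ascontiguousarray(run_sum[:, keep])
                mean = mean[:, keep]
                buf = np.empty_like(X)
                corr = build_corrections(active)
                if noise is not None:
                    noise = np.ascontiguousarray(noise[keep])
            prev_mean = mean

    if active:
        mean = run_sum / max(t - b, 1)
        for ci, c in enumerate(active):
            xb = mean[:, ci]
            results[c] = SteadyState(
                xbar=xb, converged=False, iterations_used=t,
                expressed_mask=xb > s, final_state=X[:, ci].astype(float),
            )
    return results  # type: ignore[return-value]


def simulate_to_steady_state(
    params: ExpressionParams,
    config: SimConfig = SimConfig(),
    seed=0,
    init: np.ndarray | None = None,
) -> SteadyState:
    """Forward-simulate one condition until its running mean converges.

    Genes start at zero expression unless ``init`` is given.  Returns the
    post-burn-in running mean, the convergence flag (False if the iteration
    cap was reached first), and the mask of expressed genes (``xbar > s``).
    """
    return simulate_batch(params, config=config, seeds=seed, init=init)[0]


def advance(
    params: ExpressionParams, x0: np.ndarray, n_steps: int, rng
) -> np.ndarray:
    """Simulate ``n_steps`` from ``x0`` recording every step (steps, n).

    Noise is drawn from ``rng`` in the same fixed-size blocks as the
    steady-state engine, so a recording run continues a condition's stream
    exactly where re-equilibration left off.
    """
    x = np.asarray(x0, dtype=float).copy()
    n = len(x)
    out = np.empty((n_steps, n))
    bt = params.beta_transpose()
    s, dt = params.s, params.dt
    sdt = s * np.sqrt(dt)
    noise = None
    for t in range(n_steps):
        if s > 0:
            off = t % NOISE_BLOCK
            if off == 0:
                noise = rng.standard_normal(size=(NOISE_BLOCK, n), dtype=np.float32)
            z = noise[off]
            nterm = sdt * np.sqrt(x) * z
        x = x + dt * (expit(params.alpha + bt @ x) - params.ell * x)
        if s > 0:
            x = x + nterm
        np.maximum(x, 0.0, out=x)
        out[t] = x
    return out


# ---------------------------------------------------------------------------
# equilibrium diagnostics


def fixed_point_residual(params: ExpressionParams, x: np.ndarray) -> np.ndarray:
    """Elementwise residual ``x - sigma(alpha + beta^T x) / ell``.

    Zero exactly at a deterministic steady state; used as a convergence
    diagnostic for simulated running means.
    """
    x = np.asarray(x, dtype=float)
    return x - expit(params.alpha + params.beta_transpose() @ x) / params.ell


def stability_analysis(params: ExpressionParams, xbar: np.ndarray) -> StabilityReport:
    """Linear stability of an equilibrium in the deterministic (s -> 0) limit.

    The Jacobian of the drift has entries
    ``J_ij = beta_ji * sigma'(u_i) - 1(i = j) * ell_i`` with
    ``u_i = alpha_i + sum_k beta_ki xbar_k``; the equilibrium is stable iff
    every eigenvalue has negative real part.
    """
    xbar = np.asarray(xbar, dtype=float)
    u = params.alpha + params.beta_transpose() @ xbar
    sig = expit(u)
    d = sig * (1.0 - sig)
    J = params.beta_transpose().multiply(d[:, None]).toarray()
    J[np.diag_indices_from(J)] -= params.ell
    eig = np.linalg.eigvals(J)
    max_re = float(eig.real.max()) if len(eig) else -np.inf
    return StabilityReport(eigenvalues=eig, stable=max_re < 0.0, max_real_part=max_re)


# ---------------------------------------------------------------------------
# serialization


def save_params(params: ExpressionParams, path) -> None:
    """Store per-gene vectors, sparse beta triplets and scalars in one archive."""
    coo = params.beta.tocoo()
    np.savez(
        path,
        alpha=params.alpha, ell=params.ell,
        beta_row=coo.row, beta_col=coo.col, beta_data=coo.data,
        n=params.n_genes, s=params.s, dt=params.dt,
    )


def load_params(path) -> ExpressionParams:
    with np.load(path) as z:
        n = int(z["n"])
        beta = sp.csr_matrix((z["beta_data"], (z["beta_row"], z["beta_col"])), shape=(n, n))
        return ExpressionParams(
            alpha=z["alpha"], ell=z["ell"], beta=beta,
            s=float(z["s"]), dt=float(z["dt"]),
        )
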