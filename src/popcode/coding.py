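"""MSE-optimal linear encoding and decoding.

The optimal encoder has the form W = V Λ Eᵀ: E is the signal eigenbasis,
Λ a rectangular-diagonal gain matrix fixed by a water-filling allocation of
the response-power budget P across spectral components, and V any M×M
orthogonal matrix (the non-uniqueness resolved by `popcode.shaping`).  The
decoder is the Wiener filter; the expected MSE has a closed form in the
spectral domain:

    MSE = Σ_i [ λ_i − s_i p_i / (p_i + σδ²) ],

where s_i = a_i²λ_i²/(a_i²λ_i + σn²) is the *recoverable power* of
component i (its maximum MSE reduction with unbounded response power) and
p_i ≥ 0 is the response power allocated to it, with Σ_i p_i = P and at most
min(M, N) active components.

The whitening baseline instead fixes the gains so the encoded blurred
signal is white, W(AΣsAᵀ)Wᵀ = c²I, with c chosen to spend the same power
budget.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np

from .signal_model import CodingProblem, SpectralCovariance

__all__ = [
    "PowerAllocation",
    "EncoderSolution",
    "DecoderSolution",
    "InfeasibleProblemError",
    "recoverable_power",
    "waterfill_allocation",
    "assemble_encoder",
    "random_orthogonal",
    "whitening_encoder",
    "wiener_decoder",
    "wiener_decoder_dense",
    "expected_mse_limit",
    "encode_decode_samples",
]


class InfeasibleProblemError(ValueError):
    """No spectral component carries recoverable power."""


def recoverable_power(lam, a, sensory_variance):
    """Per-component recoverable power s = λ²a²/(a²λ + σn²).

    Elementwise; an unobservable component (a = 0, or a²λ + σn² = 0)
    contributes 0.
    """
    lam = np.asarray(lam, dtype=float)
    a = np.asarray(a, dtype=float)
    num = lam**2 * a**2
    den = a**2 * lam + sensory_variance
    out = np.zeros(np.broadcast(lam, a).shape)
    np.divide(num, den, out=out, where=den > 0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PowerAllocation:
    """Water-filling result: response power p_i and encoding gains g_i.

    ``power`` and ``gains`` are full N-vectors (zero off the active set);
    ``active`` lists the active component indices in selection order
    (recoverable power descending, frequency-index ascending on ties);
    ``water_level`` is the Lagrange multiplier μ of the budget constraint
    (None when not applicable, e.g. for the whitening gains).
    """

    power: np.ndarray
    gains: np.ndarray
    active: np.ndarray
    water_level: float | None = None

    @property
    def total_power(self) -> float:
        return float(self.power.sum())

    @property
    def n_active(self) -> int:
        return int(self.active.size)


def _selection_order(s: np.ndarray, frequency_index: np.ndarray) -> np.ndarray:
    # sort by recoverable power descending, ties by ascending frequency index,
    # then by component index for full determinism
    return np.lexsort((np.arange(s.size), frequency_index, -s))


def waterfill_allocation(problem: CodingProblem) -> PowerAllocation:
    """Optimal response-power allocation across spectral components.

    Minimizes Σ_i [λ_i − s_i p_i/(p_i+σδ²)] subject to Σ p_i = P, p_i ≥ 0
    and at most min(M, N) active components.  The KKT stationarity gives
    p_i = max(0, √(s_i σδ²/μ) − σδ²); the water level μ is found by
    bisection on the monotone budget function to |Σp − P| ≤ 1e-10·P.
    """
    lam = problem.signal.spectrum
    a = problem.blur.spectral_gains
    sn2 = problem.noise.sensory_variance
    sd2 = problem.noise.neural_variance
    p_budget = problem.power_budget

    s = recoverable_power(lam, a, sn2)
    order = _selection_order(s, problem.signal.frequency_index)
    k_max = min(problem.m, problem.n)
    cand = order[:k_max]
    cand = cand[s[cand] > 0]
    if cand.size == 0:
        raise InfeasibleProblemError("no component with recoverable power > 0")

    sc = s[cand]

    def budget(mu: float) -> float:
        return float(np.sum(np.maximum(0.0, np.sqrt(sc * sd2 / mu) - sd2)))

    mu_hi = float(sc.max() / sd2)  # all p = 0
    mu_lo = mu_hi
    while budget(mu_lo) < p_budget:
        mu_lo /= 2.0
        if mu_lo < 1e-300:
            break
    for _ in range(400):
        mu = 0.5 * (mu_lo + mu_hi)
        if budget(mu) > p_budget:
            mu_lo = mu
        else:
            mu_hi = mu
        if abs(budget(mu) - p_budget) <= 1e-12 * p_budget:
            break
    mu = 0.5 * (mu_lo + mu_hi)

    p = np.zeros(problem.n)
    p[cand] = np.maximum(0.0, np.sqrt(sc * sd2 / mu) - sd2)
    # exact budget (bisection residual is <= 1e-10 relative)
    p *= p_budget / p.sum()

    d = problem.observed_spectrum()
    g = np.zeros(problem.n)
    np.divide(p, d, out=g, where=d > 0)
    g = np.sqrt(g)
    active = cand[p[cand] > 0]
    return PowerAllocation(power=p, gains=g, active=active, water_level=mu)


def random_orthogonal(m: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random orthogonal matrix via QR with sign fixing."""
    q, r = np.linalg.qr(rng.standard_normal((m, m)))
    return q * np.sign(np.diag(r))


@dataclass(frozen=True)
class EncoderSolution:
    """Encoding matrix in factored form W = V Λ Eᵀ.

    ``V`` is M×M orthogonal; the gains and active set live in
    ``allocation``; ``basis`` is the signal covariance whose eigenbasis E
    completes the factorization.  W is materialized lazily — rows are the
    receptive fields.
    """

    V: np.ndarray
    allocation: PowerAllocation
    basis: SpectralCovariance
    problem: CodingProblem | None = None

    @property
    def m(self) -> int:
        return self.V.shape[0]

    @property
    def active_gains(self) -> np.ndarray:
        return self.allocation.gains[self.allocation.active]

    @property
    def active_power(self) -> np.ndarray:
        return self.allocation.power[self.allocation.active]

    @functools.cached_property
    def W(self) -> np.ndarray:
        """Dense M×N encoding matrix."""
        act = self.allocation.active
        e_act = self.basis.basis.take(act)  # N×K
        g = self.allocation.gains[act]
        return self.V[:, : act.size] @ (g[:, None] * e_act.T)

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Noiseless responses z = W x for samples x of shape (n, N)."""
        act = self.allocation.active
        e_act = self.basis.basis.take(act)
        g = self.allocation.gains[act]
        return (x @ e_act * g) @ self.V[:, : act.size].T

    def representation_variances(self) -> np.ndarray:
        """diag(WΣxWᵀ): per-neuron encoded-signal variance."""
        k = self.allocation.active.size
        return (self.V[:, :k] ** 2) @ self.active_power


def assemble_encoder(
    allocation: PowerAllocation,
    basis: SpectralCovariance,
    V: np.ndarray,
    problem: CodingProblem | None = None,
) -> EncoderSolution:
    """Assemble W = V Λ Eᵀ from an allocation and an orthogonal V."""
    V = np.asarray(V, dtype=float)
    m = V.shape[0]
    if V.shape != (m, m):
        raise ValueError("V must be square")
    if np.max(np.abs(V.T @ V - np.eye(m))) > 1e-8:
        raise ValueError("V must be orthogonal to 1e-8")
    if allocation.n_active > m:
        raise ValueError("more active components than encoding units")
    return EncoderSolution(V=V, allocation=allocation, basis=basis, problem=problem)


def whitening_encoder(problem: CodingProblem) -> EncoderSolution:
    """Redundancy-reduction baseline: whiten the blurred signal.

    W = c · diag(1/√(a_i²λ_i)) Eᵀ on the top-M blurred-signal components,
    so W(AΣsAᵀ)Wᵀ = c²·I_M; the scale c spends the full power budget,
    tr(WΣxWᵀ) = P.  Defined for M ≤ N only (undercomplete whitening keeps
    the top-M principal components); the shape of W is independent of the
    sensory noise level up to c.
    """
    if problem.m > problem.n:
        raise ValueError("whitening is not defined for an overcomplete population")
    lam = problem.signal.spectrum
    a = problem.blur.spectral_gains
    b = a**2 * lam  # blurred-signal spectrum
    order = _selection_order(b, problem.signal.frequency_index)
    top = order[: problem.m]
    if np.any(b[top] <= 0):
        raise ValueError(
            "fewer positive blurred-signal components than encoding units"
        )
    sn2 = problem.noise.sensory_variance
    c2 = problem.power_budget / float(np.sum(1.0 + sn2 / b[top]))
    g = np.zeros(problem.n)
    g[top] = np.sqrt(c2 / b[top])
    p = g**2 * problem.observed_spectrum()
    alloc = PowerAllocation(power=p, gains=g, active=top, water_level=None)
    return EncoderSolution(
        V=np.eye(problem.m), allocation=alloc, basis=problem.signal, problem=problem
    )


@dataclass(frozen=True)
class DecoderSolution:
    """Wiener decoding matrix G with the closed-form expected MSE."""

    G: np.ndarray
    expected_mse: float
    percent_error: float


def _closed_form_mse(problem: CodingProblem, allocation: PowerAllocation) -> float:
    lam = problem.signal.spectrum
    s = recoverable_power(lam, problem.blur.spectral_gains, problem.noise.sensory_variance)
    p = allocation.power
    sd2 = problem.noise.neural_variance
    return float(lam.sum() - np.sum(s * p / (p + sd2)))


def wiener_decoder(encoder: EncoderSolution, problem: CodingProblem) -> DecoderSolution:
    """Optimal linear readout G = ΣsAᵀWᵀ(WΣxWᵀ + σδ²I)⁻¹ for a factored encoder.

    In the spectral factorization G = E Γ Vᵀ with per-component decoding
    gain Γ_i = λ_i a_i g_i/(p_i + σδ²); the expected MSE is the closed form
    Σ_i λ_i − s_i p_i/(p_i + σδ²).
    """
    if encoder.basis.n != problem.n or encoder.m != problem.m:
        raise ValueError("encoder dimensions do not match problem")
    act = encoder.allocation.active
    lam = problem.signal.spectrum[act]
    a = problem.blur.spectral_gains[act]
    g = encoder.allocation.gains[act]
    p = encoder.allocation.power[act]
    sd2 = problem.noise.neural_variance
    gamma = lam * a * g / (p + sd2)
    e_act = encoder.basis.basis.take(act)  # N×K
    G = (e_act * gamma) @ encoder.V[:, : act.size].T  # N×M
    mse = _closed_form_mse(problem, encoder.allocation)
    tr = problem.signal.trace
    return DecoderSolution(G=G, expected_mse=mse, percent_error=100.0 * mse / tr)


def wiener_decoder_dense(W: np.ndarray, problem: CodingProblem) -> DecoderSolution:
    """Wiener decoder for an arbitrary (not necessarily optimal) encoder W.

    Used for cross-checks; requires materializing the eigenbasis, so small
    problems only.
    """
    W = np.asarray(W, dtype=float)
    if W.shape[1] != problem.n:
        raise ValueError("encoder width must equal signal dimension")
    e = problem.signal.basis.full()
    u = W @ e  # encoder in the spectral frame
    d = problem.observed_spectrum()
    lam = problem.signal.spectrum
    a = problem.blur.spectral_gains
    S = (u * d) @ u.T + problem.noise.neural_variance * np.eye(W.shape[0])
    T = u * (lam * a)  # M×N, equals W A Σs in the spectral frame
    X = np.linalg.solve(S, T)
    mse = float(lam.sum() - np.sum(T * X))
    G = e @ X.T  # G = ΣsAᵀWᵀ S⁻¹ = E Tᵀ S⁻¹
    tr = problem.signal.trace
    return DecoderSolution(G=G, expected_mse=mse, percent_error=100.0 * mse / tr)


def expected_mse_limit(problem: CodingProblem) -> float:
    """Infinite-capacity Wiener bound Σ_i (λ_i − s_i).

    Error that remains from sensory noise and blur alone, approached as the
    population size (hence power budget) grows.
    """
    lam = problem.signal.spectrum
    s = recoverable_power(lam, problem.blur.spectral_gains, problem.noise.sensory_variance)
    return float(np.sum(lam - s))


def encode_decode_samples(
    encoder: EncoderSolution,
    decoder: DecoderSolution,
    samples: np.ndarray,
    problem: CodingProblem,
    seed: int = 0,
):
    """Simulate r = W(As + n) + δ, ŝ = G r on signal samples (n, N).

    Returns (reconstructions, empirical_percent_error) where the percent
    error is 100·mean‖s − ŝ‖²/tr(Σs); all noise draws are seeded.
    """
    rng = np.random.default_rng(seed)
    s = np.asarray(samples, dtype=float)
    e = problem.signal.basis.full()
    a = problem.blur.spectral_gains
    blurred = (s @ e * a) @ e.T
    x = blurred
    if problem.noise.sensory_variance > 0:
        x = x + rng.normal(0.0, np.sqrt(problem.noise.sensory_variance), s.shape)
    r = encoder.encode(x)
    r = r + rng.normal(0.0, np.sqrt(problem.noise.neural_variance), r.shape)
    s_hat = r @ decoder.G.T
    emp_mse = float(np.mean(np.sum((s - s_hat) ** 2, axis=1)))
    return s_hat, 100.0 * emp_mse / problem.signal.trace
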