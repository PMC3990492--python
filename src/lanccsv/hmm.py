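"""Per-individual diploid HMM over observed continent-specific variants.

Hidden states are unordered ancestry pairs {A_i, A_j} (K(K+1)/2 of them);
observations are the source groups of the CSVs an individual carries, in
position order.  Transitions are built from an independent per-chromosome
haploid kernel ``T(a -> b) = (1 - r) 1[a = b] + r theta_b`` with
``r = 1 - exp(-d G lambda)`` the probability of at least one recombination
over d bp; emissions mix a per-state compatibility with a small spurious-CSV
floor.  Decoding is log-space forward-backward (posterior decoding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np

from .discovery import CsvTable, ObservationSequence, observe_csvs
from .tracks import AncestryTrack, from_segments

logger = logging.getLogger(__name__)


def state_space(K: int) -> list[tuple[int, int]]:
    """Unordered ancestry pairs (i <= j), lexicographic order."""
    return [(i, j) for i in range(K) for j in range(i, K)]


@dataclass
class HmmSpec:
    """All HMM parameters for one admixed population.

    lambda defaults to 1e-15 per bp per generation — far below the biological
    1e-8 — deliberately damping transitions between closely linked CSVs whose
    LD is otherwise unmodeled.
    """

    groups: list
    theta: np.ndarray
    generations: int
    densities: np.ndarray          # N_k, informative CSVs per haplotype per Mb
    lam: float = 1e-15
    eps_csv: float = 1e-5
    eps_mode: str = "per_group"    # or "total": total mismatch mass = eps

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        K = len(self.groups)
        if self.theta.shape != (K,) or self.densities.shape != (K,):
            raise ValueError("theta and densities must have one entry per group")
        if np.any(self.theta < 0) or abs(self.theta.sum() - 1) > 1e-9:
            raise ValueError("theta must be a probability simplex")
        if not 0 < self.eps_csv < 1.0 / K:
            raise ValueError("eps_csv must be in (0, 1/K)")
        if np.any(self.densities[self.theta > 0] <= 0):
            raise ValueError("densities must be positive for groups with theta > 0")

    @property
    def K(self) -> int:
        return len(self.groups)

    @property
    def states(self) -> list[tuple[int, int]]:
        return state_space(self.K)


# ------------------------------------------------------------------ components

def crossover_prob(d_bp, generations: int, lam: float) -> np.ndarray:
    """P(>= 1 recombination over d bp) = 1 - exp(-d G lambda)."""
    d = np.asarray(d_bp, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    return -np.expm1(-d * generations * lam)


def _haploid_kernel(r: float, theta: np.ndarray) -> np.ndarray:
    K = len(theta)
    return (1.0 - r) * np.eye(K) + r * np.tile(theta, (K, 1))


def _collapse_indices(K: int):
    """Index arrays mapping ordered-pair products onto unordered pairs."""
    states = state_space(K)
    rows = np.array([(i, j) for i, j in states])
    return states, rows


def transition_matrices(r, theta: np.ndarray) -> np.ndarray:
    """Batch of diploid transition matrices over unordered pairs.

    For each recombination probability in ``r``: the product of two
    independent haploid kernels, collapsed to unordered pairs — an
    off-diagonal target {a, b} receives the mass of both ordered pairs
    (a, b) and (b, a).  Every row sums to 1.  Returns (len(r), S, S).
    """
    theta = np.asarray(theta, dtype=float)
    r = np.atleast_1d(np.asarray(r, dtype=float))
    K = len(theta)
    I = np.eye(K)
    T = (1.0 - r)[:, None, None] * I + r[:, None, None] * np.tile(theta, (K, 1))
    states, rows = _collapse_indices(K)
    i, j = rows[:, 0], rows[:, 1]
    a, b = rows[:, 0], rows[:, 1]
    # out[l, s, t] = T[l,i_s,a_t] T[l,j_s,b_t] (+ swapped target if a_t != b_t)
    out = T[:, i[:, None], a[None, :]] * T[:, j[:, None], b[None, :]]
    off = (a != b)[None, :]
    out += np.where(off, T[:, i[:, None], b[None, :]] * T[:, j[:, None], a[None, :]], 0.0)
    return out


def transition_matrix(r: float, theta: np.ndarray) -> np.ndarray:
    """Single diploid transition matrix; see :func:`transition_matrices`."""
    return transition_matrices([float(r)], theta)[0]


def emission_matrix(densities: np.ndarray, eps_csv: float, K: int,
                    eps_mode: str = "per_group") -> np.ndarray:
    """(n_states, K) matrix of P(observed CSV group | state).

    Homozygous {k, k}: mass 1 - (K-1) eps on group k, eps on each other group.
    Heterozygous {i, j}: the compatible mass splits proportionally to the
    informative densities N_i : N_j; each incompatible group gets eps.
    With ``eps_mode='total'`` the *total* incompatible mass is eps, split
    evenly over incompatible groups.
    """
    N = np.asarray(densities, dtype=float)
    states = state_space(K)
    E = np.zeros((len(states), K))
    for s, (i, j) in enumerate(states):
        n_bad = K - (1 if i == j else 2)
        bad = eps_csv if eps_mode == "per_group" else (eps_csv / n_bad if n_bad else 0.0)
        good = 1.0 - n_bad * bad
        if i == j:
            E[s] = bad
            E[s, i] = good
        else:
            if N[i] + N[j] == 0:
                raise ValueError(f"zero total density in heterozygous state {(i, j)}")
            E[s] = bad
            E[s, i] = good * N[i] / (N[i] + N[j])
            E[s, j] = good * N[j] / (N[i] + N[j])
    return E


def initial_distribution(theta: np.ndarray) -> np.ndarray:
    """Random pairing of two ancestries drawn from theta: theta_i^2, 2 theta_i theta_j."""
    states = state_space(len(theta))
    pi = np.empty(len(states))
    for s, (i, j) in enumerate(states):
        pi[s] = theta[i] ** 2 if i == j else 2.0 * theta[i] * theta[j]
    return pi


# -------------------------------------------------------------------- decoding

@dataclass
class DecodeResult:
    posteriors: np.ndarray   # (L, n_states), rows sum to 1
    calls: np.ndarray        # argmax state index per observation
    loglik: float
    states: list
    obs: ObservationSequence = field(default=None, repr=False)


def _log_matvec(log_v: np.ndarray, logM: np.ndarray) -> np.ndarray:
    """log(exp(log_v) @ exp(logM)) with per-column scaling.

    Column-wise max-shifting keeps every output state accurate even when the
    state masses span more than the ~745-nat reach of a single global scale.
    """
    A = log_v[:, None] + logM
    m = A.max(axis=0)
    out = np.full(A.shape[1], -np.inf)
    safe = np.isfinite(m)
    if safe.any():
        out[safe] = np.log(np.exp(A[:, safe] - m[safe]).sum(axis=0)) + m[safe]
    return out


def posterior_decode(obs: ObservationSequence, spec: HmmSpec) -> DecodeResult:
    """Log-space forward-backward over the observation sequence.

    The silent start state emits nothing; the first observation is scored
    against the random-pairing initial distribution.  Argmax ties resolve to
    the lower-indexed state (logged).
    """
    L = len(obs)
    if L < 1:
        raise ValueError("need at least one observation to decode")
    # align observation group indices with the spec's group order
    try:
        remap = np.array([spec.groups.index(g) for g in obs.group_names])
    except ValueError as err:
        raise ValueError("observation group outside the model's group set") from err
    groups = remap[obs.groups]
    E = emission_matrix(spec.densities, spec.eps_csv, spec.K, spec.eps_mode)
    S = len(spec.states)
    with np.errstate(divide="ignore"):
        logE = np.log(E)
        log_pi = np.log(initial_distribution(spec.theta))
    r = crossover_prob(obs.distances, spec.generations, spec.lam)
    # transition matrices per step (step j uses distance to observation j)
    Ts = transition_matrices(r[1:], spec.theta) if L > 1 else np.empty((0, S, S))
    with np.errstate(divide="ignore"):
        logTs = np.log(Ts)

    fwd = np.empty((L, S))
    fwd[0] = log_pi + logE[:, groups[0]]
    for j in range(1, L):
        fwd[j] = _log_matvec(fwd[j - 1], logTs[j - 1]) + logE[:, groups[j]]
    bwd = np.zeros((L, S))
    for j in range(L - 2, -1, -1):
        bwd[j] = _log_matvec(bwd[j + 1] + logE[:, groups[j + 1]], logTs[j].T)

    from scipy.special import logsumexp
    loglik = float(logsumexp(fwd[-1]))
    logpost = fwd + bwd
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    post = np.exp(logpost)
    calls = np.argmax(post, axis=1)
    n_ties = int(np.sum((post == post[np.arange(L), calls][:, None]).sum(axis=1) > 1))
    if n_ties:
        logger.debug("posterior_decode: %d argmax ties resolved to lowest state", n_ties)
    return DecodeResult(post, calls, loglik, spec.states, obs)


def extend_calls(result: DecodeResult, spec: HmmSpec, chrom: str,
                 span: tuple[int, int], individual: str) -> AncestryTrack:
    """Propagate per-CSV calls to all positions.

    Every position at or after observation j and before observation j+1 takes
    call j; positions before the first observation take call 1.  ``span`` is
    the (start_bp, end_bp) extent to tile, 1-based inclusive.
    """
    obs = result.obs
    pos = obs.positions
    calls = result.calls
    start_bp, end_bp = span
    segs = []
    seg_starts = np.concatenate([[start_bp], pos[1:]])
    seg_ends = np.concatenate([pos[1:] - 1, [end_bp]])
    for s, e, c in zip(seg_starts, seg_ends, calls):
        if e < s:
            continue
        i, j = spec.states[c]
        segs.append((individual, chrom, int(s), int(e),
                     spec.groups[i], spec.groups[j]))
    return from_segments(segs)


# -------------------------------------------------------------------- pipeline

def infer_individual(genotypes: np.ndarray, table: CsvTable, spec: HmmSpec,
                     chrom: str, span: tuple[int, int],
                     individual: str) -> AncestryTrack:
    """Observe CSVs, decode and extend calls for one individual on one chromosome.

    With no CSV observations the whole chromosome is assigned the a-priori
    most likely state (logged).
    """
    obs = observe_csvs(genotypes, table, chrom)
    if len(obs) == 0:
        logger.warning("no CSV observations for %s on %s; assigning prior mode",
                       individual, chrom)
        c = int(np.argmax(initial_distribution(spec.theta)))
        i, j = spec.states[c]
        return from_segments([(individual, chrom, span[0], span[1],
                               spec.groups[i], spec.groups[j])])
    res = posterior_decode(obs, spec)
    return extend_calls(res, spec, chrom, span, individual)


def infer_cohort(gm, table: CsvTable, spec: HmmSpec) -> AncestryTrack:
    """Decode every individual on every chromosome; returns one diploid track."""
    import pandas as pd

    frames = []
    for chrom, sub in gm.sites.groupby("chrom", sort=False):
        span = (int(sub["pos"].min()), int(sub["pos"].max()))
        for j, ind in enumerate(gm.samples):
            t = infer_individual(gm.genotypes[:, j], table, spec,
                                 str(chrom), span, str(ind))
            frames.append(t.df)
    return AncestryTrack(pd.concat(frames, ignore_index=True))
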