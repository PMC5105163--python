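"""Reversible Markov state models with PCCA++ coarse-graining.

The estimation chain is: k-means discretization of the reduced (TICA)
coordinates with one shared center set across all conditions -> sliding
window transition counts per condition -> restriction to the largest
strongly connected state set -> maximum-likelihood reversible transition
matrix (fixed-point iteration on symmetric edge weights) -> validation by
implied timescales and the Chapman-Kolmogorov test -> PCCA++ memberships
-> coarse populations, free energies and 1/MFPT inter-state rates, all
with trajectory-level bootstrap 1-sigma intervals (15.87/84.13
percentiles, reported asymmetrically as lower/upper bounds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .constants import DEFAULT_TEMPERATURE_K, R_KJ_PER_MOL_K


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass
class Discretization:
    """Shared k-means centers plus per-condition microstate index series."""

    centers: np.ndarray                       # (k, dim)
    dtrajs: dict[str, list[np.ndarray]]       # condition -> per-trajectory int series
    k: int
    seed: int

    def all_dtrajs(self) -> list[np.ndarray]:
        return [d for series in self.dtrajs.values() for d in series]


def kmeans_discretize(
    reduced: dict[str, list[np.ndarray]],
    k: int,
    seed: int = 0,
) -> Discretization:
    """Cluster the pooled reduced coordinates of every condition with one
    k-means center set, then assign each condition's frames to it.

    k-means++ initialization, Lloyd iterations to relative inertia change
    < 1e-6 or 500 iterations.
    """
    series = [(cond, np.asarray(x, dtype=np.float64))
              for cond, xs in reduced.items() for x in xs]
    pooled = np.concatenate([x for _, x in series], axis=0)
    if pooled.shape[0] < k:
        raise ValueError(f"k={k} exceeds total frame count {pooled.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=500,
                tol=1e-6, random_state=seed)
    km.fit(pooled)
    dtrajs: dict[str, list[np.ndarray]] = {cond: [] for cond in reduced}
    for cond, x in series:
        dtrajs[cond].append(km.predict(x).astype(np.int32))
    return Discretization(centers=km.cluster_centers_, dtrajs=dtrajs, k=k,
                          seed=seed)


def count_transitions(dtrajs: list[np.ndarray], n_states: int, lag: int) -> np.ndarray:
    """Sliding-window transition counts at the given lag.

    Lagged pairs never cross trajectory boundaries; trajectories shorter
    than the lag contribute nothing.  Raises if no trajectory is long
    enough.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    C = np.zeros((n_states, n_states))
    any_pairs = False
    for d in dtrajs:
        d = np.asarray(d)
        if len(d) <= lag:
            continue
        any_pairs = True
        np.add.at(C, (d[:-lag], d[lag:]), 1.0)
    if not any_pairs:
        raise ValueError(f"no trajectory longer than lag {lag}")
    return C


def largest_connected_set(C: np.ndarray) -> np.ndarray:
    """Largest strongly connected component of the count-matrix graph.

    Size ties are broken by total counts within the component, then by the
    smallest member index.
    """
    C = np.asarray(C)
    if C.size == 0:
        raise ValueError("empty count matrix")
    n_comp, labels = connected_components(C > 0, directed=True,
                                          connection="strong")
    best = None
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        size = len(members)
        counts = C[np.ix_(members, members)].sum()
        key = (size, counts, -members[0])
        if best is None or key > best[0]:
            best = (key, members)
    return best[1]


# ---------------------------------------------------------------------------
# reversible estimation
# ---------------------------------------------------------------------------

@dataclass
class MarkovModel:
    lag_frames: int
    frame_interval_ns: float
    count_matrix: np.ndarray          # on the full state set
    active_set: np.ndarray            # indices into the full set
    transition_matrix: np.ndarray     # on the active set
    stationary: np.ndarray            # on the active set
    eigenvalues: np.ndarray = field(default=None)
    right_eigenvectors: np.ndarray = field(default=None)
    left_eigenvectors: np.ndarray = field(default=None)

    @property
    def lag_ns(self) -> float:
        return self.lag_frames * self.frame_interval_ns

    @property
    def n_active(self) -> int:
        return len(self.active_set)

    def __post_init__(self) -> None:
        if self.eigenvalues is None:
            self._spectral()

    def _spectral(self) -> None:
        # reversible T is similar to a symmetric matrix via D = diag(sqrt(pi))
        sqp = np.sqrt(self.stationary)
        S = (sqp[:, None] * self.transition_matrix) / sqp[None, :]
        S = 0.5 * (S + S.T)
        w, u = np.linalg.eigh(S)
        order = np.argsort(-w)
        w, u = w[order], u[:, order]
        psi = u / sqp[:, None]          # right eigenvectors
        phi = u * sqp[:, None]          # left eigenvectors
        if psi[0, 0] != 0:  # stationary right eigenvector is the constant 1
            psi[:, 0] = psi[:, 0] / psi[0, 0]
        self.eigenvalues = w
        self.right_eigenvectors = psi
        self.left_eigenvectors = phi

    def timescales_frames(self, n: int | None = None) -> np.ndarray:
        lam = self.eigenvalues[1:None if n is None else n + 1]
        out = np.full(len(lam), np.inf)
        for i, l in enumerate(lam):
            if l <= 0:
                warnings.warn("non-positive eigenvalue; using magnitude")
                l = abs(l)
            if l >= 1.0:
                warnings.warn("eigenvalue >= 1 below stationary; timescale inf")
                continue
            if l > 0:
                out[i] = -self.lag_frames / np.log(l)
            else:
                out[i] = 0.0
        return out


def estimate_reversible_msm(
    C: np.ndarray,
    lag_frames: int = 1,
    frame_interval_ns: float = 1.0,
    active_set: np.ndarray | None = None,
    tol: float = 1e-12,
    max_sweeps: int = 1_000_000,
) -> MarkovModel:
    """Maximum-likelihood reversible transition matrix.

    Fixed-point iteration on symmetric edge weights x_ij:

        x_ij <- (C_ij + C_ji) / (c_i/x_i + c_j/x_j)

    with c_i the count-matrix row sums and x_i the current weight row sums,
    iterated until the stationary distribution moves by less than ``tol``
    in the max norm.  T_ij = x_ij / x_i; pi_i = x_i / sum(x).
    """
    C = np.asarray(C, dtype=float)
    if active_set is None:
        active_set = largest_connected_set(C)
    A = C[np.ix_(active_set, active_set)]
    n = A.shape[0]
    if n == 1:
        T = np.ones((1, 1))
        return MarkovModel(lag_frames, frame_interval_ns, C, active_set, T,
                           np.ones(1))
    csym = A + A.T
    c = A.sum(axis=1)
    if np.any(c == 0):
        raise ValueError("active set contains a state with no outgoing counts")
    x = csym / csym.sum()
    pi = x.sum(axis=1)
    for sweep in range(max_sweeps):
        xi = x.sum(axis=1)
        denom = c[:, None] / xi[:, None] + c[None, :] / xi[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            x_new = np.where(csym > 0, csym / denom, 0.0)
        x_new /= x_new.sum()
        pi_new = x_new.sum(axis=1)
        delta = np.max(np.abs(pi_new - pi))
        x, pi = x_new, pi_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"reversible MLE did not converge: residual {delta:.2e}")
    T = x / x.sum(axis=1)[:, None]
    return MarkovModel(lag_frames, frame_interval_ns, C, np.asarray(active_set),
                       T, pi)


def implied_timescales(
    dtrajs: list[np.ndarray],
    n_states: int,
    lags: list[int],
    frame_interval_ns: float = 1.0,
    n_timescales: int = 3,
) -> dict[int, np.ndarray]:
    """Implied timescales t_i(tau) = -tau / ln lambda_i in physical time (ns)
    for a list of candidate lags."""
    out = {}
    for lag in lags:
        C = count_transitions(dtrajs, n_states, lag)
        model = estimate_reversible_msm(C, lag_frames=lag,
                                        frame_interval_ns=frame_interval_ns)
        m = min(n_timescales, model.n_active - 1)
        ts = model.timescales_frames(m) * frame_interval_ns
        out[lag] = ts
    return out


def select_lag(its: dict[int, np.ndarray], rel_change: float = 0.1) -> int:
    """Smallest candidate lag after which the slowest implied timescale
    changes by less than ``rel_change`` to the next candidate."""
    lags = sorted(its)
    for a, b in zip(lags, lags[1:]):
        t_a, t_b = its[a][0], its[b][0]
        if np.isfinite(t_a) and np.isfinite(t_b) and abs(t_b - t_a) <= rel_change * t_a:
            return a
    return lags[-1]


# ---------------------------------------------------------------------------
# PCCA++ coarse graining
# ---------------------------------------------------------------------------

@dataclass
class MetastableDecomposition:
    n_meta: int
    memberships: np.ndarray          # (n_active, n_meta), rows sum to 1
    crisp: np.ndarray                # full-state map microstate -> meta (-1 pruned)
    populations: np.ndarray          # coarse stationary weights
    active_set: np.ndarray
    free_energies_kj: np.ndarray | None = None
    dg_lower: np.ndarray | None = None
    dg_upper: np.ndarray | None = None
    rates_per_us: np.ndarray | None = None
    rate_lower: np.ndarray | None = None
    rate_upper: np.ndarray | None = None
    population_samples: np.ndarray | None = None   # (n_boot, n_meta)


def pcca(model: MarkovModel, n_meta: int) -> MetastableDecomposition:
    """PCCA++ membership computation by simplex-vertex identification in
    the space of the dominant right eigenvectors.

    Microstates closest to the simplex vertices become the cores of the
    metastable sets; memberships are the barycentric coordinates, clipped
    to [0, 1] and renormalized.  The crisp map is the argmax membership.
    """
    if n_meta < 2:
        raise ValueError("need at least 2 metastable states")
    if n_meta > model.n_active:
        raise ValueError("more metastable states than microstates")
    lam = model.eigenvalues
    if abs(lam[n_meta - 1] - lam[n_meta]) < 1e-10:
        raise ValueError(
            f"eigenvalues {n_meta - 1} and {n_meta} are degenerate; "
            "choose a different number of metastable states")
    psi = model.right_eigenvectors[:, :n_meta].copy()
    psi[:, 0] = 1.0
    vertices = _inner_simplex_vertices(psi)
    A = np.linalg.inv(psi[vertices])
    chi = psi @ A
    chi = np.clip(chi, 0.0, 1.0)
    chi /= chi.sum(axis=1)[:, None]
    crisp_active = np.argmax(chi, axis=1)
    n_full = model.count_matrix.shape[0]
    crisp = np.full(n_full, -1, dtype=int)
    crisp[model.active_set] = crisp_active
    pops = np.array([model.stationary[crisp_active == m].sum()
                     for m in range(n_meta)])
    return MetastableDecomposition(
        n_meta=n_meta, memberships=chi, crisp=crisp, populations=pops,
        active_set=np.asarray(model.active_set))


def _inner_simplex_vertices(psi: np.ndarray) -> list[int]:
    n, m = psi.shape
    ortho = psi.copy()
    idx: list[int] = []
    # farthest from origin first, then successively orthogonalize
    norms = np.linalg.norm(ortho, axis=1)
    idx.append(int(np.argmax(norms)))
    ortho -= ortho[idx[0]]
    for _ in range(1, m):
        norms = np.linalg.norm(ortho, axis=1)
        j = int(np.argmax(norms))
        idx.append(j)
        v = ortho[j] / norms[j]
        ortho -= np.outer(ortho @ v, v)
    return idx


# ---------------------------------------------------------------------------
# thermodynamics and kinetics
# ---------------------------------------------------------------------------

def free_energies(
    populations: np.ndarray, temperature_K: float = DEFAULT_TEMPERATURE_K
) -> np.ndarray:
    """Delta G_m = -R T ln(Pi_m / Pi_ref), in kJ/mol; the most populated
    state is the zero-energy reference."""
    pi = np.asarray(populations, dtype=float)
    if np.any(pi <= 0):
        raise ValueError("populations must be positive")
    ref = pi.max()
    return -R_KJ_PER_MOL_K * temperature_K * np.log(pi / ref)


def delta_delta_g(fold: float, temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Free-energy shift R T ln(fold) of a population fold-change, kJ/mol."""
    if fold <= 0:
        raise ValueError("fold-change must be positive")
    return R_KJ_PER_MOL_K * temperature_K * np.log(fold)


def mfpt_frames(model: MarkovModel, source: np.ndarray, target: np.ndarray) -> float:
    """Stationary-weighted mean first-passage time (frames) from the source
    microstate set into the target set, by the standard linear system."""
    T = model.transition_matrix
    n = T.shape[0]
    target = np.asarray(target)
    m = np.zeros(n)
    free = np.setdiff1d(np.arange(n), target)
    if len(free):
        A = np.eye(len(free)) - T[np.ix_(free, free)]
        try:
            m_free = np.linalg.solve(A, model.lag_frames * np.ones(len(free)))
        except np.linalg.LinAlgError:
            warnings.warn("target unreachable; MFPT infinite")
            return np.inf
        m[free] = m_free
    w = model.stationary[source]
    return float((w * m[source]).sum() / w.sum())


def coarse_rates(
    model: MarkovModel,
    decomp: MetastableDecomposition,
    frame_interval_ns: float | None = None,
) -> np.ndarray:
    """Inter-metastable rates rate(m->n) = 1 / MFPT(m->n), in 1/us."""
    if frame_interval_ns is None:
        frame_interval_ns = model.frame_interval_ns
    n_meta = decomp.n_meta
    crisp_active = decomp.crisp[model.active_set]
    rates = np.zeros((n_meta, n_meta))
    for a in range(n_meta):
        src = np.flatnonzero(crisp_active == a)
        if len(src) == 0:
            continue
        for b in range(n_meta):
            if a == b:
                continue
            tgt = np.flatnonzero(crisp_active == b)
            if len(tgt) == 0:
                warnings.warn(f"metastable state {b} empty; rate set to 0")
                continue
            t = mfpt_frames(model, src, tgt)
            if not np.isfinite(t) or t <= 0:
                rates[a, b] = 0.0
            else:
                rates[a, b] = 1.0 / (t * frame_interval_ns * 1e-3)  # 1/us
    return rates


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    population_samples: np.ndarray      # (n_kept, n_meta)
    dg_samples: np.ndarray
    rate_samples: np.ndarray            # (n_kept, n_meta, n_meta)
    n_dropped: int

    def percentile_band(self, samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.percentile(samples, 15.87, axis=0)
        hi = np.percentile(samples, 84.13, axis=0)
        return lo, hi


def bootstrap_msm(
    dtrajs: list[np.ndarray],
    n_states: int,
    lag: int,
    decomp: MetastableDecomposition,
    n_boot: int = 50,
    seed: int = 0,
    frame_interval_ns: float = 1.0,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    compute_rates: bool = True,
) -> BootstrapResult:
    """Trajectory-level bootstrap of the MSM-derived quantities.

    Trajectories are resampled with replacement; the microstate definition
    and the microstate-to-metastable map are held fixed, counts and the
    reversible transition matrix are re-estimated per replicate.
    Replicates whose active set loses a metastable state are dropped and
    counted.
    """
    if n_boot < 10:
        warnings.warn("fewer than 10 bootstrap replicates is unreliable")
    if len(dtrajs) < 2:
        warnings.warn("bootstrap over fewer than 2 trajectories is degenerate")
    rng = np.random.default_rng(seed)
    n_meta = decomp.n_meta
    pop_s, dg_s, rate_s = [], [], []
    dropped = 0
    for _ in range(n_boot):
        pick = rng.integers(0, len(dtrajs), size=len(dtrajs))
        sample = [dtrajs[i] for i in pick]
        try:
            C = count_transitions(sample, n_states, lag)
            model = estimate_reversible_msm(C, lag_frames=lag,
                                            frame_interval_ns=frame_interval_ns)
        except (ValueError, RuntimeError):
            dropped += 1
            continue
        crisp_active = decomp.crisp[model.active_set]
        if np.any(crisp_active < 0) or len(set(range(n_meta)) - set(crisp_active)) > 0:
            dropped += 1
            continue
        pops = np.array([model.stationary[crisp_active == m].sum()
                         for m in range(n_meta)])
        pop_s.append(pops)
        dg_s.append(free_energies(pops, temperature_K))
        if compute_rates:
            sub = MetastableDecomposition(
                n_meta=n_meta, memberships=decomp.memberships,
                crisp=decomp.crisp, populations=pops,
                active_set=model.active_set)
            rate_s.append(coarse_rates(model, sub, frame_interval_ns))
    if not pop_s:
        raise RuntimeError("every bootstrap replicate was dropped")
    return BootstrapResult(
        population_samples=np.asarray(pop_s),
        dg_samples=np.asarray(dg_s),
        rate_samples=np.asarray(rate_s) if rate_s else np.zeros((0, n_meta, n_meta)),
        n_dropped=dropped,
    )


def attach_bootstrap(decomp: MetastableDecomposition, boot: BootstrapResult,
                     temperature_K: float = DEFAULT_TEMPERATURE_K) -> None:
    """Store 1-sigma percentile bounds on the decomposition in place."""
    decomp.population_samples = boot.population_samples
    decomp.free_energies_kj = free_energies(decomp.populations, temperature_K)
    decomp.dg_lower, decomp.dg_upper = boot.percentile_band(boot.dg_samples)
    if boot.rate_samples.size:
        decomp.rate_lower, decomp.rate_upper = boot.percentile_band(boot.rate_samples)


# ---------------------------------------------------------------------------
# cross-condition comparison
# ---------------------------------------------------------------------------

def match_metastable(decompA: MetastableDecomposition,
                     decompB: MetastableDecomposition) -> list[tuple[int, int, float]]:
    """Greedy matching of metastable states across two decompositions that
    share one microstate definition, by Jaccard overlap of the crisp sets.

    Returns (state_in_A, state_in_B, jaccard); pairs with overlap < 0.2
    are reported with partner -1.  An exact tie in the Jaccard matrix is an
    error: the matching would be arbitrary.
    """
    if decompA.crisp.shape != decompB.crisp.shape:
        raise ValueError("decompositions do not share a microstate definition")
    nA, nB = decompA.n_meta, decompB.n_meta
    J = np.zeros((nA, nB))
    for a in range(nA):
        sa = set(np.flatnonzero(decompA.crisp == a))
        for b in range(nB):
            sb = set(np.flatnonzero(decompB.crisp == b))
            union = sa | sb
            J[a, b] = len(sa & sb) / len(union) if union else 0.0
    out: list[tuple[int, int, float]] = []
    usedB: set[int] = set()
    for a in np.argsort([-J[a].max() for a in range(nA)]):
        row = J[a].copy()
        row[list(usedB)] = -1
        best = row.max()
        if best >= 0.2 and np.sum(np.isclose(row, best, atol=1e-12)) > 1:
            raise ValueError(f"ambiguous metastable matching for state {a}")
        if best < 0.2:
            out.append((int(a), -1, float(max(best, 0.0))))
        else:
            b = int(np.argmax(row))
            usedB.add(b)
            out.append((int(a), b, float(best)))
    out.sort()
    return out


def compare_conditions(
    decompA: MetastableDecomposition,
    decompB: MetastableDecomposition,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> list[dict]:
    """Per matched metastable state: population fold-change B/A and
    Delta-Delta-G = R T ln(fold), with bootstrap 1-sigma bounds when both
    decompositions carry population samples."""
    matches = match_metastable(decompA, decompB)
    results = []
    for a, b, jac in matches:
        row: dict = {"state_A": a, "state_B": b, "jaccard": jac}
        if b < 0:
            row["matched"] = False
            results.append(row)
            continue
        fold = decompB.populations[b] / decompA.populations[a]
        row.update(matched=True, fold=float(fold),
                   ddg_kj=float(delta_delta_g(fold, temperature_K)))
        if (decompA.population_samples is not None
                and decompB.population_samples is not None):
            nA = decompA.population_samples.shape[0]
            nB = decompB.population_samples.shape[0]
            n = min(nA, nB)
            folds = (decompB.population_samples[:n, b]
                     / decompA.population_samples[:n, a])
            row["fold_lower"] = float(np.percentile(folds, 15.87))
            row["fold_upper"] = float(np.percentile(folds, 84.13))
            ddgs = R_KJ_PER_MOL_K * temperature_K * np.log(folds)
            row["ddg_lower"] = float(np.percentile(ddgs, 15.87))
            row["ddg_upper"] = float(np.percentile(ddgs, 84.13))
        results.append(row)
    return results


# ---------------------------------------------------------------------------
# Chapman-Kolmogorov test
# ---------------------------------------------------------------------------

@dataclass
class CKTestResult:
    steps: np.ndarray                  # 1..k_max
    predicted: np.ndarray              # (k_max, n_meta, n_meta)
    estimated: np.ndarray
    band: np.ndarray                   # 2-sigma bootstrap band on estimated
    passed: bool


def _coarse_transition(model: MarkovModel, crisp: np.ndarray, n_meta: int,
                       power: int = 1) -> np.ndarray:
    Tk = np.linalg.matrix_power(model.transition_matrix, power)
    crisp_active = crisp[model.active_set]
    P = np.zeros((n_meta, n_meta))
    for a in range(n_meta):
        ia = crisp_active == a
        wa = model.stationary[ia]
        if wa.sum() == 0:
            P[a] = np.nan
            continue
        for b in range(n_meta):
            P[a, b] = (wa @ Tk[np.ix_(ia, crisp_active == b)].sum(axis=1)) / wa.sum()
    return P


def ck_test(
    dtrajs: list[np.ndarray],
    n_states: int,
    lag: int,
    decomp: MetastableDecomposition,
    k_max: int = 4,
    n_boot: int = 30,
    seed: int = 0,
) -> CKTestResult:
    """Chapman-Kolmogorov validation on the metastable sets.

    Compares T(tau)^k propagated set-to-set probabilities against models
    re-estimated at lag k*tau, for k = 1..k_max; passes iff the re-estimated
    values lie within a 2-sigma trajectory-bootstrap band of the
    prediction at every step.
    """
    rng = np.random.default_rng(seed)
    n_meta = decomp.n_meta
    C = count_transitions(dtrajs, n_states, lag)
    base = estimate_reversible_msm(C, lag_frames=lag)
    max_len = max(len(d) for d in dtrajs)
    steps = [k for k in range(1, k_max + 1) if k * lag < max_len]
    if len(steps) < k_max:
        warnings.warn("CK test truncated: not enough data at the longest lag")
    pred = np.full((len(steps), n_meta, n_meta), np.nan)
    est = np.full_like(pred, np.nan)
    band = np.full_like(pred, np.nan)
    for ki, k in enumerate(steps):
        pred[ki] = _coarse_transition(base, decomp.crisp, n_meta, power=k)
        Ck = count_transitions(dtrajs, n_states, k * lag)
        mk = estimate_reversible_msm(Ck, lag_frames=k * lag)
        est[ki] = _coarse_transition(mk, decomp.crisp, n_meta)
        reps = []
        for _ in range(n_boot):
            pick = rng.integers(0, len(dtrajs), size=len(dtrajs))
            try:
                Cb = count_transitions([dtrajs[i] for i in pick], n_states, k * lag)
                mb = estimate_reversible_msm(Cb, lag_frames=k * lag)
            except (ValueError, RuntimeError):
                continue
            reps.append(_coarse_transition(mb, decomp.crisp, n_meta))
        if reps:
            band[ki] = 2.0 * np.nanstd(np.asarray(reps), axis=0)
    ok = np.abs(pred - est) <= band + 1e-9
    passed = bool(np.all(ok[np.isfinite(pred) & np.isfinite(est) & np.isfinite(band)]))
    return CKTestResult(steps=np.asarray(steps), predicted=pred, estimated=est,
                        band=band, passed=passed)


# ---------------------------------------------------------------------------
# seed-structure sampling
# ---------------------------------------------------------------------------

def sample_seed_conformations(
    model: MarkovModel,
    dtrajs: list[np.ndarray],
    n_out: int,
    k_clusters: int | None = None,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Pick frames spread uniformly over the slow subspace of the model.

    Microstates are projected onto the first three non-stationary right
    eigenvectors and k-means clustered (default k = round(sqrt(active-set
    size))); ``n_out`` frames are drawn uniformly across clusters (cluster
    draw counts differ by at most 1) and uniformly among the frames of each
    cluster.  Returns (trajectory index, frame index) pairs.
    """
    if model.n_active < 4:
        raise ValueError("need at least 3 non-trivial eigenvectors")
    if k_clusters is None:
        k_clusters = int(round(np.sqrt(model.n_active)))
    if k_clusters > model.n_active:
        raise ValueError("more seed clusters than microstates")
    rng = np.random.default_rng(seed)
    proj = model.right_eigenvectors[:, 1:4]
    km = KMeans(n_clusters=k_clusters, init="k-means++", n_init=1,
                max_iter=500, tol=1e-6, random_state=seed)
    micro_cluster = km.fit_predict(proj)    # per active microstate
    # frames per cluster
    state_to_cluster = np.full(model.count_matrix.shape[0], -1, dtype=int)
    state_to_cluster[model.active_set] = micro_cluster
    frames_by_cluster: dict[int, list[tuple[int, int]]] = {c: [] for c in range(k_clusters)}
    for ti, d in enumerate(dtrajs):
        cl = state_to_cluster[np.asarray(d)]
        for fi in np.flatnonzero(cl >= 0):
            frames_by_cluster[cl[fi]].append((ti, int(fi)))
    quota = np.full(k_clusters, n_out // k_clusters)
    quota[: n_out % k_clusters] += 1
    out: list[tuple[int, int]] = []
    for c in range(k_clusters):
        pool = frames_by_cluster[c]
        if not pool:
            warnings.warn(f"seed cluster {c} holds no frames; quota skipped")
            continue
        idx = rng.integers(0, len(pool), size=quota[c])
        out.extend(pool[i] for i in idx)
    return out
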