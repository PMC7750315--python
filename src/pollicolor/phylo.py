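"""Phylogenetic comparative inference.

Continuous-trait model fitting (BM / OU / EB) by maximum likelihood over the
multivariate-normal phylogenetic likelihood with AICc model choice, joint ML
ancestral states under BM, discrete Mk fitting (ER / SYM / ARD) via the
pruning algorithm, stochastic character mapping, a Bayesian threshold model
for ordered categories sampled by Gibbs MCMC, and bivariate PGLS correlation
under BM or OU covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import t as student_t

from .errors import FitError, TreeError
from .trees import PhyloTree

__all__ = [
    "ContinuousFit",
    "MkFit",
    "SimmapEnsemble",
    "ThresholdPosterior",
    "PglsFit",
    "fit_continuous",
    "anc_ml",
    "fit_mk",
    "stochastic_map",
    "threshold_mcmc",
    "pgls_corr",
    "color_vector",
]

LOG2PI = np.log(2.0 * np.pi)


def _as_vector(tree: PhyloTree, x) -> np.ndarray:
    """Accept a dict keyed by tip label or an array in tip order."""
    if isinstance(x, dict):
        missing = [l for l in tree.tip_labels if l not in x]
        if missing:
            raise TreeError(f"trait missing for tips: {missing}")
        return np.array([float(x[l]) for l in tree.tip_labels])
    x = np.asarray(x, dtype=float)
    if x.shape != (tree.n_tips,):
        raise TreeError(f"trait vector length {x.size} != {tree.n_tips} tips")
    return x


# ---------------------------------------------------------------------------
# continuous models
# ---------------------------------------------------------------------------

@dataclass
class ContinuousFit:
    """A fitted continuous-trait evolutionary model."""

    model: str
    sigma2: float
    z0: float
    logLik: float
    k: int
    AICc: float
    alpha: float | None = None  # OU pull strength
    r: float | None = None      # EB rate-decay exponent
    n: int = 0
    degenerate: bool = False
    tree_height: float = 0.0

    @property
    def params(self) -> dict:
        out = {"sigma2": self.sigma2, "z0": self.z0}
        if self.alpha is not None:
            out["alpha"] = self.alpha
        if self.r is not None:
            out["r"] = self.r
        return out


def _aicc(logLik: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * logLik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _ou_corr(Cbm: np.ndarray, depths_diag: np.ndarray, alpha: float) -> np.ndarray:
    """OU covariance structure (unit sigma^2) from the BM shared-path matrix."""
    ta = Cbm  # shared time of MRCA from root
    di = depths_diag[:, None] + depths_diag[None, :] - 2.0 * Cbm  # patristic distance
    return np.exp(-alpha * di) * (1.0 - np.exp(-2.0 * alpha * ta)) / (2.0 * alpha)


def _eb_corr(Cbm: np.ndarray, r: float) -> np.ndarray:
    if abs(r) < 1e-12:
        return Cbm
    return (np.exp(r * Cbm) - 1.0) / r


def _profile_mvn(C: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Profile z0 and sigma^2 out of N(x | z0*1, sigma2*C); return (z0, s2, logLik)."""
    n = x.size
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        raise FitError("singular covariance structure")
    Ci1 = np.linalg.solve(C, np.ones(n))
    denom = Ci1.sum()
    z0 = float(x @ Ci1 / denom)
    resid = x - z0
    quad = float(resid @ np.linalg.solve(C, resid))
    s2 = quad / n
    if s2 <= 0:
        raise FitError("non-positive profiled rate")
    logLik = -0.5 * (n * LOG2PI + n * np.log(s2) + logdet + n)
    return z0, s2, logLik


def fit_continuous(tree: PhyloTree, x, model: str = "BM") -> ContinuousFit:
    """ML fit of BM, OU or EB to a tip trait vector, with AICc.

    BM has a closed-form profile solution; OU and EB profile out the rate and
    root state and optimize the remaining shape parameter (``alpha`` or ``r``)
    by bounded multi-start search on a log scale.
    """
    model = model.upper()
    if model not in {"BM", "OU", "EB"}:
        raise FitError(f"unknown continuous model {model!r}")
    xv = _as_vector(tree, x)
    n = tree.n_tips
    Cbm = tree.vcv()
    depths_diag = np.diag(Cbm).copy()
    height = tree.height

    if np.var(xv) < 1e-14:
        # zero-variance trait: rate collapses to its lower bound
        k = 2 if model == "BM" else 3
        return ContinuousFit(
            model=model, sigma2=1e-12, z0=float(xv[0]), logLik=np.inf, k=k,
            AICc=-np.inf, n=n, degenerate=True, tree_height=height,
            alpha=0.0 if model == "OU" else None, r=0.0 if model == "EB" else None,
        )

    if model == "BM":
        z0, s2, ll = _profile_mvn(Cbm, xv)
        k = 2
        return ContinuousFit("BM", s2, z0, ll, k, _aicc(ll, k, n), n=n, tree_height=height)

    if model == "OU":
        if not tree.is_ultrametric():
            raise FitError("OU fit requires an ultrametric tree")

        def nll(log_alpha: float) -> float:
            alpha = np.exp(log_alpha)
            try:
                _, _, ll = _profile_mvn(_ou_corr(Cbm, depths_diag, alpha), xv)
            except (FitError, np.linalg.LinAlgError):
                return np.inf
            return -ll

        best = None
        for start in np.log([1e-6 / height, 0.01 / height, 0.1 / height, 1.0 / height, 10.0 / height]):
            res = minimize_scalar(
                nll, bounds=(np.log(1e-8), np.log(1e3)), method="bounded",
                options={"xatol": 1e-8},
            )
            cand = res if res.success else None
            # minimize_scalar(bounded) ignores starts; evaluate start too
            if cand is not None and (best is None or cand.fun < best.fun):
                best = cand
            f0 = nll(start)
            if best is None or f0 < best.fun:
                best = type("R", (), {"x": start, "fun": f0})()
        if best is None or not np.isfinite(best.fun):
            raise FitError("OU optimization failed to find a finite optimum")
        alpha = float(np.exp(best.x))
        z0, s2, ll = _profile_mvn(_ou_corr(Cbm, depths_diag, alpha), xv)
        k = 3
        return ContinuousFit("OU", s2, z0, ll, k, _aicc(ll, k, n), alpha=alpha, n=n, tree_height=height)

    # EB: r <= 0 (decaying rate); r -> 0 recovers BM
    def nll_eb(r: float) -> float:
        try:
            _, _, ll = _profile_mvn(_eb_corr(Cbm, r), xv)
        except (FitError, np.linalg.LinAlgError):
            return np.inf
        return -ll

    res = minimize_scalar(
        nll_eb, bounds=(-10.0 / height, -1e-10), method="bounded", options={"xatol": 1e-10}
    )
    f_bm = nll_eb(0.0)
    if res.fun <= f_bm:
        r_hat = float(res.x)
    else:
        r_hat = 0.0
    z0, s2, ll = _profile_mvn(_eb_corr(Cbm, r_hat), xv)
    k = 3
    return ContinuousFit("EB", s2, z0, ll, k, _aicc(ll, k, n), r=r_hat, n=n, tree_height=height)


def anc_ml(tree: PhyloTree, x, fit: ContinuousFit | None = None) -> np.ndarray:
    """Joint ML internal-node states under BM.

    Solves the weighted Laplacian system that minimizes
    ``sum_edges (x_parent - x_child)^2 / branch_length`` with tips fixed;
    the root estimate equals the GLS root of a BM fit.  Returns a vector over
    all nodes (tips keep their observed values).
    """
    if fit is not None and fit.model != "BM":
        raise FitError("ancestral state estimation implemented for BM fits")
    if fit is not None and fit.n and fit.n != tree.n_tips:
        raise FitError("fit was produced on a different tree (tip count mismatch)")
    xv = _as_vector(tree, x)
    n, m = tree.n_tips, tree.n_nodes
    internal = np.arange(n, m)
    pos = {node: i for i, node in enumerate(internal)}
    A = np.zeros((m - n, m - n))
    b = np.zeros(m - n)
    for node in range(m):
        p = tree.parent[node]
        if p < 0:
            continue
        w = 1.0 / max(tree.blen[node], 1e-12)
        # edge (p, node): both endpoints may be unknown
        if node >= n and p >= n:
            A[pos[node], pos[node]] += w
            A[pos[p], pos[p]] += w
            A[pos[node], pos[p]] -= w
            A[pos[p], pos[node]] -= w
        elif node >= n:  # parent known (impossible in rooted trees, kept for safety)
            A[pos[node], pos[node]] += w
            b[pos[node]] += w * xv[p]
        else:  # tip child, internal parent
            A[pos[p], pos[p]] += w
            b[pos[p]] += w * xv[node]
    states = np.empty(m)
    states[:n] = xv
    states[n:] = np.linalg.solve(A, b)
    return states


# ---------------------------------------------------------------------------
# discrete Mk models
# ---------------------------------------------------------------------------

@dataclass
class MkFit:
    """ML fit of a continuous-time Markov model to a discrete tip character."""

    model: str
    states: tuple[str, ...]
    Q: np.ndarray
    logLik: float
    k: int
    AIC: float
    root_prior: str = "uniform"
    degenerate: bool = False

    @property
    def n_states(self) -> int:
        return len(self.states)


def _mk_build_q(rates: np.ndarray, k: int, model: str) -> np.ndarray:
    Q = np.zeros((k, k))
    if model == "ER":
        Q[:] = rates[0]
    elif model == "SYM":
        iu = np.triu_indices(k, 1)
        Q[iu] = rates
        Q.T[iu] = rates
    else:  # ARD
        idx = 0
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = rates[idx]
                    idx += 1
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _mk_n_rates(k: int, model: str) -> int:
    return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[model]


def _tip_partials(tree: PhyloTree, states, alphabet: tuple[str, ...]) -> np.ndarray:
    if isinstance(states, dict):
        seq = [states[l] for l in tree.tip_labels]
    else:
        seq = list(states)
        if len(seq) != tree.n_tips:
            raise TreeError("state vector length does not match tip count")
    lookup = {s: i for i, s in enumerate(alphabet)}
    L = np.zeros((tree.n_nodes, len(alphabet)))
    for tip, s in enumerate(seq):
        if s not in lookup:
            raise FitError(f"state {s!r} absent from alphabet {alphabet}")
        L[tip, lookup[s]] = 1.0
    return L


def _mk_loglik(tree: PhyloTree, L_tips: np.ndarray, Q: np.ndarray) -> float:
    """Felsenstein pruning with per-branch matrix exponentials (uniform root prior)."""
    n = tree.n_tips
    k = Q.shape[0]
    L = L_tips.copy()
    scale = 0.0
    P_cache: dict[float, np.ndarray] = {}
    for node in tree.postorder:
        if node < n:
            continue
        part = np.ones(k)
        for c in tree.children[node]:
            t = float(tree.blen[c])
            P = P_cache.get(t)
            if P is None:
                P = expm(Q * t)
                P_cache[t] = P
            part = part * (P @ L[c])
        mx = part.max()
        if mx <= 0:
            return -np.inf
        L[node] = part / mx
        scale += np.log(mx)
    root = tree.root
    return float(np.log(L[root].mean()) + scale)


def fit_mk(
    tree: PhyloTree,
    states,
    model: str = "ER",
    alphabet: tuple[str, ...] | None = None,
) -> MkFit:
    """ML fit of an ER/SYM/ARD rate matrix to tip categories.

    The root is handled with a uniform prior over states.  With a single
    observed state the rate is pinned to the lower bound and the fit flagged
    degenerate.
    """
    model = model.upper()
    if model not in {"ER", "SYM", "ARD"}:
        raise FitError(f"unknown Mk model {model!r}")
    if isinstance(states, dict):
        observed = sorted({states[l] for l in tree.tip_labels})
    else:
        observed = sorted(set(states))
    if alphabet is None:
        alphabet = tuple(observed)
    else:
        alphabet = tuple(alphabet)
        missing = set(observed) - set(alphabet)
        if missing:
            raise FitError(f"state absent from alphabet: {sorted(missing)}")
    kst = len(alphabet)
    L_tips = _tip_partials(tree, states, alphabet)
    n_rates = _mk_n_rates(kst, model)

    if kst < 2 or len(observed) < 2:
        Q = _mk_build_q(np.full(max(n_rates, 1), 1e-12), max(kst, 1), model)
        ll = _mk_loglik(tree, L_tips, Q) if kst >= 1 else 0.0
        return MkFit(model, alphabet, Q, ll, n_rates, 2 * n_rates - 2 * ll, degenerate=True)

    height = tree.height

    def nll(log_rates: np.ndarray) -> float:
        Q = _mk_build_q(np.exp(log_rates), kst, model)
        ll = _mk_loglik(tree, L_tips, Q)
        return -ll if np.isfinite(ll) else 1e10

    best = None
    for scale in (0.1, 1.0, 10.0):
        x0 = np.full(n_rates, np.log(scale / height))
        res = minimize(
            nll, x0, method="L-BFGS-B",
            bounds=[(np.log(1e-9), np.log(1e4))] * n_rates,
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("Mk optimization failed to converge to a finite optimum")
    rates = np.exp(best.x)
    Q = _mk_build_q(rates, kst, model)
    ll = -float(best.fun)
    degenerate = bool(np.all(rates <= 2e-9))
    return MkFit(model, alphabet, Q, ll, n_rates, 2 * n_rates - 2 * ll, degenerate=degenerate)


def mk_node_marginals(tree: PhyloTree, states, fit: MkFit) -> np.ndarray:
    """Exact marginal ancestral state probabilities under a fitted Mk model.

    Standard up/down pass with the fit's uniform root prior; rows are nodes,
    columns states.  Used as the analytic oracle for stochastic mapping.
    """
    k = fit.n_states
    n = tree.n_tips
    down = _tip_partials(tree, states, fit.states)
    P = {}
    for node in range(tree.n_nodes):
        if tree.parent[node] >= 0:
            t = float(tree.blen[node])
            if t not in P:
                P[t] = expm(fit.Q * t)
    # up pass: down[node] = P(data below node | node state), rescaled per node
    for node in tree.postorder:
        if node < n:
            continue
        part = np.ones(k)
        for c in tree.children[node]:
            part = part * (P[float(tree.blen[c])] @ down[c])
        down[node] = part / part.max()
    # down pass: up[node] = message from the rest of the tree, incl. root prior
    up = np.zeros((tree.n_nodes, k))
    marg = np.zeros((tree.n_nodes, k))
    up[tree.root] = 1.0 / k
    for node in tree.preorder:
        w = up[node] * down[node]
        marg[node] = w / w.sum()
        for c in tree.children[node]:
            others = up[node].copy()
            for s in tree.children[node]:
                if s != c:
                    others = others * (P[float(tree.blen[s])] @ down[s])
            up[c] = others @ P[float(tree.blen[c])]
    return marg


@dataclass
class SimmapEnsemble:
    """A set of sampled character histories on one tree."""

    states: tuple[str, ...]
    node_states: np.ndarray        # (n_maps, n_nodes) int state indices
    events: list[list[tuple]]      # per map: (node, time_from_parent, from, to)
    node_posterior: np.ndarray     # (n_nodes, n_states)

    @property
    def n_maps(self) -> int:
        return self.node_states.shape[0]

    def n_changes(self) -> np.ndarray:
        return np.array([len(ev) for ev in self.events])


def _sample_path_rejection(Q, a, b, t, rng, max_tries=1000):
    k = Q.shape[0]
    for _ in range(max_tries):
        s, tau, ev = a, 0.0, []
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            tau += rng.exponential(1.0 / rate)
            if tau >= t:
                break
            probs = Q[s].copy()
            probs[s] = 0.0
            probs /= probs.sum()
            s_new = rng.choice(k, p=probs)
            ev.append((tau, s, s_new))
            s = s_new
        if s == b:
            return ev
    return None


def _sample_path_uniformization(Q, a, b, t, rng, max_jumps=512):
    """Exact endpoint-conditioned path via uniformization."""
    lam = float(np.max(-np.diag(Q)))
    k = Q.shape[0]
    if lam <= 0:
        if a != b:
            raise FitError("impossible endpoint pair with zero-rate matrix")
        return []
    R = np.eye(k) + Q / lam
    Pab = expm(Q * t)[a, b]
    if Pab <= 0:
        raise FitError("endpoint pair has zero probability")
    # sample jump count n | a, b, t
    Rn = [np.eye(k)]
    weights = []
    logpois = -lam * t
    total = 0.0
    u = rng.random()
    n_jump = None
    for n in range(max_jumps):
        if n > 0:
            Rn.append(Rn[-1] @ R)
            logpois += np.log(lam * t) - np.log(n)
        w = np.exp(logpois) * Rn[n][a, b] / Pab
        weights.append(w)
        total += w
        if u <= total:
            n_jump = n
            break
    if n_jump is None:
        n_jump = max_jumps - 1
    # intermediate states of the uniformized chain
    path = [a]
    for j in range(1, n_jump):
        prev = path[-1]
        probs = R[prev] * Rn[n_jump - j][:, b]
        probs /= probs.sum()
        path.append(int(rng.choice(k, p=probs)))
    if n_jump >= 1:
        path.append(b)
    times = np.sort(rng.random(n_jump)) * t
    events = []
    for tm, s_from, s_to in zip(times, path[:-1], path[1:]):
        if s_from != s_to:  # drop virtual self-jumps
            events.append((tm, s_from, s_to))
    return events


def stochastic_map(
    tree: PhyloTree,
    states,
    fit: MkFit,
    n_maps: int = 100,
    seed: int = 0,
    rejection_tries: int = 1000,
) -> SimmapEnsemble:
    """Sample character histories conditional on tip states and a fitted Q.

    Node states are drawn from their conditional distributions (pruning +
    backward sampling); branch histories are drawn conditional on endpoint
    states by rejection sampling with a uniformization fallback.
    """
    rng = np.random.default_rng(seed)
    k = fit.n_states
    n = tree.n_tips
    Q = fit.Q
    L = _tip_partials(tree, states, fit.states)
    P = {}
    for node in range(tree.n_nodes):
        if tree.parent[node] >= 0:
            t = float(tree.blen[node])
            if t not in P:
                P[t] = expm(Q * t)
    down = np.zeros((tree.n_nodes, k))  # P(child-subtree | node state), via children
    for node in tree.postorder:
        if node < n:
            down[node] = L[node]
            continue
        part = np.ones(k)
        for c in tree.children[node]:
            part = part * (P[float(tree.blen[c])] @ down[c])
        down[node] = part / part.max()

    root = tree.root
    node_states = np.zeros((n_maps, tree.n_nodes), dtype=int)
    all_events: list[list[tuple]] = []
    for m in range(n_maps):
        assign = np.zeros(tree.n_nodes, dtype=int)
        probs = down[root] / down[root].sum()  # uniform root prior
        assign[root] = rng.choice(k, p=probs)
        events: list[tuple] = []
        for node in tree.preorder:
            for c in tree.children[node]:
                t = float(tree.blen[c])
                pvec = P[t][assign[node]] * down[c]
                pvec = pvec / pvec.sum()
                assign[c] = rng.choice(k, p=pvec)
                path = _sample_path_rejection(
                    Q, assign[node], assign[c], t, rng, max_tries=rejection_tries
                )
                if path is None:
                    path = _sample_path_uniformization(Q, assign[node], assign[c], t, rng)
                for tm, s_from, s_to in path:
                    events.append((c, tm, fit.states[s_from], fit.states[s_to]))
        node_states[m] = assign
        all_events.append(events)
    posterior = np.zeros((tree.n_nodes, k))
    for s_idx in range(k):
        posterior[:, s_idx] = (node_states == s_idx).mean(axis=0)
    return SimmapEnsemble(fit.states, node_states, all_events, posterior)


# ---------------------------------------------------------------------------
# threshold model
# ---------------------------------------------------------------------------

@dataclass
class ThresholdPosterior:
    """Posterior summaries of the ordered-trait threshold model."""

    categories: tuple[int, ...]
    liability_mean: np.ndarray       # per node (tips first)
    liability_samples: np.ndarray    # (n_kept, n_nodes)
    threshold_samples: np.ndarray    # (n_kept, n_thresholds) incl. fixed 0
    node_category_posterior: np.ndarray  # (n_nodes, n_categories)
    generations: int = 0
    burn_in: int = 0
    seed: int = 0

    @property
    def thresholds_mean(self) -> np.ndarray:
        return self.threshold_samples.mean(axis=0)


def _category_interval(cat_idx: int, thresholds: np.ndarray) -> tuple[float, float]:
    """Open liability interval for 0-based category index given thresholds."""
    K = thresholds.size + 1
    lo = -np.inf if cat_idx == 0 else thresholds[cat_idx - 1]
    hi = np.inf if cat_idx == K - 1 else thresholds[cat_idx]
    return lo, hi


def _truncated_normal(rng, mean, sd, lo, hi):
    a = 0.0 if lo == -np.inf else _phi((lo - mean) / sd)
    b = 1.0 if hi == np.inf else _phi((hi - mean) / sd)
    if b - a < 1e-300:
        # numerically empty interval: pin to the nearest bound
        return lo if mean < lo else hi
    u = rng.uniform(a, b)
    from scipy.special import ndtri

    return mean + sd * ndtri(min(max(u, 1e-15), 1 - 1e-15))


def _phi(z):
    from scipy.special import ndtr

    return float(ndtr(z))


def threshold_mcmc(
    tree: PhyloTree,
    zones,
    generations: int = 20000,
    burn_in: int | None = None,
    seed: int = 0,
    thin: int | None = None,
    n_categories: int | None = None,
) -> ThresholdPosterior:
    """Gibbs sampler for the ordered threshold model.

    A latent liability evolves by BM with rate fixed at 1; a tip in ordered
    category ``c`` constrains its liability to the interval between adjacent
    thresholds (first threshold fixed at 0 for identifiability, the rest
    sampled).  Full conditionals are Gaussian (internal nodes), truncated
    Gaussian (tips) and uniform (free thresholds), so the chain is a pure
    Gibbs sampler.  Categories are integers 1..K.
    """
    if isinstance(zones, dict):
        cats = np.array([int(zones[l]) for l in tree.tip_labels])
    else:
        cats = np.asarray(zones, dtype=int)
        if cats.size != tree.n_tips:
            raise TreeError("zone vector length does not match tip count")
    K = int(n_categories) if n_categories else int(cats.max())
    if cats.min() < 1 or cats.max() > K:
        raise FitError(f"categories must lie in 1..{K}")
    cat0 = cats - 1  # 0-based
    n, m = tree.n_tips, tree.n_nodes
    if burn_in is None:
        burn_in = generations // 5
    if thin is None:
        thin = max(1, (generations - burn_in) // 1000)
    rng = np.random.default_rng(seed)

    height = tree.height
    upper = 5.0 * np.sqrt(max(height, 1.0))  # uniform prior width for free thresholds

    thresholds = np.arange(K - 1, dtype=float)  # [0, 1, 2, ...]
    if K >= 3 and thresholds[-1] >= upper:
        thresholds = np.linspace(0, upper / 2, K - 1)
    liab = np.zeros(m)
    for tip in range(n):
        lo, hi = _category_interval(cat0[tip], thresholds)
        lo_f = lo if np.isfinite(lo) else hi - 1.0
        hi_f = hi if np.isfinite(hi) else lo + 1.0
        liab[tip] = 0.5 * (lo_f + hi_f)
    for node in tree.postorder:
        if node >= n:
            liab[node] = np.mean([liab[c] for c in tree.children[node]])
    # feasibility check
    for tip in range(n):
        lo, hi = _category_interval(cat0[tip], thresholds)
        if not (lo < liab[tip] < hi):
            raise FitError("chain not initialized with feasible liabilities")

    neighbors: list[list[tuple[int, float]]] = [[] for _ in range(m)]
    for node in range(m):
        p = tree.parent[node]
        if p >= 0:
            bl = max(float(tree.blen[node]), 1e-9)
            neighbors[node].append((p, bl))
            neighbors[p].append((node, bl))

    kept_liab, kept_thr = [], []
    for gen in range(generations):
        # liabilities
        for node in range(m):
            prec = 0.0
            mu = 0.0
            for nb, bl in neighbors[node]:
                w = 1.0 / bl
                prec += w
                mu += w * liab[nb]
            mean = mu / prec
            sd = 1.0 / np.sqrt(prec)
            if node < n:
                lo, hi = _category_interval(cat0[node], thresholds)
                liab[node] = _truncated_normal(rng, mean, sd, lo, hi)
            else:
                liab[node] = rng.normal(mean, sd)
        # free thresholds (index 1..K-2); threshold[0] fixed at 0
        for j in range(1, K - 1):
            in_below = liab[:n][cat0 == j]        # category j+1 (1-based), upper bound t_j
            in_above = liab[:n][cat0 == j + 1]    # lower-bounded by t_j
            lo = thresholds[j - 1]
            if in_below.size:
                lo = max(lo, in_below.max())
            hi = thresholds[j + 1] if j + 1 < K - 1 else upper
            if in_above.size:
                hi = min(hi, in_above.min())
            if hi <= lo:
                continue  # keep current value; interval momentarily empty
            thresholds[j] = rng.uniform(lo, hi)
        if gen >= burn_in and (gen - burn_in) % thin == 0:
            kept_liab.append(liab.copy())
            kept_thr.append(thresholds.copy())

    samples = np.array(kept_liab)
    thr_samples = np.array(kept_thr)
    cat_post = np.zeros((m, K))
    for s_liab, s_thr in zip(samples, thr_samples):
        idx = np.searchsorted(s_thr, s_liab, side="right")
        for node in range(m):
            cat_post[node, idx[node]] += 1
    cat_post /= max(len(samples), 1)
    return ThresholdPosterior(
        categories=tuple(range(1, K + 1)),
        liability_mean=samples.mean(axis=0),
        liability_samples=samples,
        threshold_samples=thr_samples,
        node_category_posterior=cat_post,
        generations=generations,
        burn_in=burn_in,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# PGLS correlation
# ---------------------------------------------------------------------------

@dataclass
class PglsFit:
    """Bivariate phylogenetic correlation under BM or OU residual covariance."""

    model: str
    r: float
    slope: float
    logLik: float
    AIC: float
    p_value: float
    alpha: float | None = None
    rate_matrix: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))


def _matnorm_profile(C: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Profile means and trait covariance of a matrix-normal X ~ MN(1 mu', C, R)."""
    n, p = X.shape
    sign, logdetC = np.linalg.slogdet(C)
    if sign <= 0:
        raise FitError("singular phylogenetic covariance")
    Ci1 = np.linalg.solve(C, np.ones(n))
    denom = Ci1.sum()
    mu = X.T @ Ci1 / denom
    E = X - mu[None, :]
    R = E.T @ np.linalg.solve(C, E) / n
    if R[0, 0] <= 0 or R[1, 1] <= 0:
        raise FitError("singular trait rate matrix")
    corr = R[0, 1] / np.sqrt(R[0, 0] * R[1, 1])
    if abs(corr) >= 1.0 - 1e-12:
        # perfectly correlated traits: likelihood is unbounded
        return mu, R, np.inf
    sign_r, logdetR = np.linalg.slogdet(R)
    if sign_r <= 0:
        raise FitError("singular trait rate matrix")
    ll = -0.5 * (n * p * LOG2PI + p * logdetC + n * logdetR + n * p)
    return mu, R, float(ll)


def _matnorm_null_loglik(C: np.ndarray, X: np.ndarray) -> float:
    """Profile log-likelihood with the trait rate matrix constrained diagonal."""
    ll = 0.0
    for j in range(X.shape[1]):
        _, _, llj = _profile_mvn(C, X[:, j])
        ll += llj
    return ll


def pgls_corr(tree: PhyloTree, x, y, model: str = "BM") -> PglsFit:
    """Evolutionary correlation between two tip traits via joint bivariate ML.

    ``r = R12 / sqrt(R11 R22)`` from the estimated trait rate matrix; the
    p-value is a likelihood-ratio test of ``r = 0`` (chi-square, 1 df); AIC
    enables BM vs OU model choice.
    """
    model = model.upper()
    if model not in {"BM", "OU"}:
        raise FitError(f"unknown PGLS model {model!r}")
    xv = _as_vector(tree, x)
    yv = _as_vector(tree, y)
    X = np.column_stack([xv, yv])
    Cbm = tree.vcv()
    depths_diag = np.diag(Cbm).copy()
    alpha = None
    if model == "BM":
        C = Cbm
        k_full, k_null = 5, 4
    else:
        height = tree.height

        def nll(log_alpha: float) -> float:
            try:
                _, _, ll = _matnorm_profile(_ou_corr(Cbm, depths_diag, np.exp(log_alpha)), X)
            except (FitError, np.linalg.LinAlgError):
                return np.inf
            return -ll

        res = minimize_scalar(
            nll, bounds=(np.log(1e-8), np.log(1e3)), method="bounded",
            options={"xatol": 1e-8},
        )
        if not np.isfinite(res.fun):
            raise FitError("OU optimization failed in PGLS")
        alpha = float(np.exp(res.x))
        C = _ou_corr(Cbm, depths_diag, alpha)
        k_full, k_null = 6, 5
    mu, R, ll_full = _matnorm_profile(C, X)
    ll_null = _matnorm_null_loglik(C, X)
    if R[0, 0] <= 0 or R[1, 1] <= 0:
        raise FitError("degenerate trait variance in PGLS")
    r = float(R[0, 1] / np.sqrt(R[0, 0] * R[1, 1]))
    r = float(np.clip(r, -1.0, 1.0))
    slope = float(R[0, 1] / R[0, 0])
    n = tree.n_tips
    # the LRT statistic 2(llfull - llnull) = -n ln(1 - r^2) is monotone in
    # |r|; use its exact finite-sample null distribution (t with n-2 df on
    # the GLS correlation) rather than the anticonservative chi-square limit
    if abs(r) >= 1.0 - 1e-12 or not np.isfinite(ll_full):
        p = 0.0
    else:
        t_stat = abs(r) * np.sqrt((n - 2) / (1.0 - r**2))
        p = float(2.0 * student_t.sf(t_stat, df=n - 2))
    return PglsFit(
        model=model, r=r, slope=slope, logLik=ll_full,
        AIC=-2.0 * ll_full + 2.0 * k_full, p_value=p, alpha=alpha, rate_matrix=R,
    )


# ---------------------------------------------------------------------------
# perceptual color vectors
# ---------------------------------------------------------------------------

def color_vector(loci, viewer: str) -> dict[str, float]:
    """PC1 scores summarizing per-species perceptual coordinates.

    Hawkmoth: PCA over the species x receptor matrix of adapted catches.
    Fly: PCA over the species x species matrix of pairwise opponency-plane
    Euclidean distances.  Requires >= 3 species; zero-variance input raises.
    """
    from .pca import pca_pc1  # local import to avoid cycle
    from .vision import fly_distance

    if len(loci) < 3:
        raise FitError("color vector needs at least 3 species")
    labels = [lc.label for lc in loci]
    if viewer == "hawkmoth":
        M = np.vstack([lc.q for lc in loci])
    else:
        nsp = len(loci)
        M = np.zeros((nsp, nsp))
        for i in range(nsp):
            for j in range(i + 1, nsp):
                d = fly_distance(loci[i], loci[j])
                M[i, j] = M[j, i] = d
    scores = pca_pc1(M)
    return dict(zip(labels, scores))
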