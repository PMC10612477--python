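"""GY94-family codon substitution models and maximum-likelihood fitting.

The state space is the 61 sense codons of the universal code. Substitution
rates follow Goldman–Yang: single-nucleotide changes get rate
pi_j x {1, kappa, omega, omega*kappa} for {synonymous transversion,
synonymous transition, nonsynonymous transversion, nonsynonymous
transition}; multi-nucleotide changes are instantaneous-rate zero. Site
heterogeneity comes from finite mixtures over omega (site models M0, M1a,
M2a, M3 with three classes, and the beta family M7/M8/M8a with 10
equal-probability categories represented by their means). Branch and
branch-site models let omega differ on one designated foreground terminal
branch. Likelihoods use Felsenstein pruning with per-node rescaling; all
matrix exponentials exploit reversibility through a symmetric
eigendecomposition.

Fitting maximizes lnL jointly over kappa, the class parameters and all
branch lengths (log-transformed, box-constrained L-BFGS-B) with seeded
multi-starts; nested alternatives can be warm-started from their null's
optimum so likelihood-ratio statistics are never negative beyond round-off.
Positively selected sites are identified by naive empirical Bayes (NEB)
posteriors of the omega>1 class at the MLEs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.linalg import expm
from scipy.special import betainc, logsumexp
from scipy.stats import beta as beta_dist

from .alignment import CodonAlignment
from .gene_tree import GeneTree, TreeNode
from .genetics import (
    CODON_INDEX, IS_SYNONYMOUS, IS_TRANSITION, N_SENSE, SENSE_CODONS,
    SINGLE_STEP, codon_indices,
)

# ---------------------------------------------------------------------------
# codon frequencies
# ---------------------------------------------------------------------------

FREQ_FLOOR = 1e-6


@dataclass(frozen=True)
class CodonFrequencies:
    method: str
    pi: np.ndarray  # 61 nonnegative reals summing to 1

    def __post_init__(self) -> None:
        if self.pi.shape != (N_SENSE,) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be 61 frequencies summing to 1")


def _floored(pi: np.ndarray) -> np.ndarray:
    pi = np.maximum(pi, FREQ_FLOOR)
    return pi / pi.sum()


def compute_frequencies(ca: CodonAlignment, method: str = "F3x4") -> CodonFrequencies:
    """Empirical codon frequencies from a cleaned alignment.

    F3x4 (default) uses the observed nucleotide composition at each codon
    position; F1x4 pools positions; F61 counts codons directly; "equal" is
    uniform. Zero frequencies are floored at 1e-6 and renormalized.
    """
    seqs = [r for r in ca.rows]
    if method == "equal":
        return CodonFrequencies("equal", np.full(N_SENSE, 1.0 / N_SENSE))
    if method == "F61":
        counts = np.zeros(N_SENSE)
        for row in seqs:
            for idx in codon_indices(row):
                counts[idx] += 1
        return CodonFrequencies("F61", _floored(counts / counts.sum()))
    nt_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    pos_counts = np.zeros((3, 4))
    for row in seqs:
        for k, base in enumerate(row):
            pos_counts[k % 3, nt_index[base]] += 1
    pos_freq = pos_counts / pos_counts.sum(axis=1, keepdims=True)
    if method == "F1x4":
        pooled = pos_counts.sum(axis=0)
        pos_freq = np.tile(pooled / pooled.sum(), (3, 1))
    elif method != "F3x4":
        raise ValueError(f"unknown frequency method {method!r}")
    pi = np.array([pos_freq[0, nt_index[c[0]]] * pos_freq[1, nt_index[c[1]]]
                   * pos_freq[2, nt_index[c[2]]] for c in SENSE_CODONS])
    return CodonFrequencies(method, _floored(pi / pi.sum()))


# ---------------------------------------------------------------------------
# rate matrices and transition probabilities
# ---------------------------------------------------------------------------

def _unscaled_generator(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    mult = np.where(IS_TRANSITION, kappa, 1.0) * np.where(IS_SYNONYMOUS, 1.0, omega)
    Q = np.where(SINGLE_STEP, mult, 0.0) * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _mean_rate(Q: np.ndarray, pi: np.ndarray) -> float:
    return float(-(pi * np.diag(Q)).sum())


def rate_matrix(kappa: float, omega: float, freqs: CodonFrequencies) -> np.ndarray:
    """Scaled GY94 generator: one expected substitution per unit branch length."""
    if kappa <= 0 or omega < 0:
        raise ValueError("require kappa > 0 and omega >= 0")
    Q = _unscaled_generator(kappa, omega, freqs.pi)
    return Q / _mean_rate(Q, freqs.pi)


def _eigen(Q: np.ndarray, pi: np.ndarray):
    """Reversible eigendecomposition; returns (eigvals, left, right) with
    P(t) = left @ diag(exp(eigvals*t)) @ right."""
    sq = np.sqrt(pi)
    A = Q * (sq[:, None] / sq[None, :])
    A = 0.5 * (A + A.T)
    w, U = np.linalg.eigh(A)
    left = U / sq[:, None]
    right = U.T * sq[None, :]
    return w, left, right


def _p_from_eigen(eig, t: float) -> np.ndarray:
    w, left, right = eig
    P = (left * np.exp(w * t)) @ right
    np.maximum(P, 0.0, out=P)
    return P


def transition_probabilities(Q: np.ndarray, t: float,
                             pi: np.ndarray | None = None) -> np.ndarray:
    """P(t) = exp(Qt); reversible eigendecomposition when pi is supplied."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    if pi is not None:
        return _p_from_eigen(_eigen(Q, pi), t)
    P = expm(Q * t)
    np.maximum(P, 0.0, out=P)
    return P


# ---------------------------------------------------------------------------
# model families
# ---------------------------------------------------------------------------

MODEL_NAMES = ("M0", "M1a", "M2a", "M3k3", "M7", "M8", "M8a", "BR2", "BSA", "BSA0")
SITE_MODELS = ("M0", "M1a", "M2a", "M3k3", "M7", "M8", "M8a")
FOREGROUND_MODELS = ("BR2", "BSA", "BSA0")
#: mixture classes whose foreground omega exceeds one, per model
POSITIVE_CLASS = {"M2a": (2,), "M8": (-1,), "BSA": (2, 3)}

_PROP_LO, _PROP_HI = 1e-9, 1.0 - 1e-9


@dataclass(frozen=True)
class Param:
    name: str
    lo: float
    hi: float
    default: float
    log: bool = True  # optimized on log scale

    def to_opt(self, value: float) -> float:
        v = math.log(value) if self.log else value
        return min(max(v, self._olo), self._ohi)

    def from_opt(self, z: float) -> float:
        return math.exp(z) if self.log else z

    @property
    def _olo(self) -> float:
        return math.log(self.lo) if self.log else self.lo

    @property
    def _ohi(self) -> float:
        return math.log(self.hi) if self.log else self.hi


def _params_for(name: str) -> list[Param]:
    kappa = Param("kappa", 0.01, 100.0, 2.0)
    w_free = lambda n, d: Param(n, 1e-4, 50.0, d)
    w_purif = lambda n: Param(n, 1e-4, 1.0 - 1e-6, 0.2)
    w_pos = lambda n: Param(n, 1.0, 50.0, 2.0)
    prop = lambda n, d: Param(n, _PROP_LO, _PROP_HI, d, log=False)
    bshape = lambda n, d: Param(n, 0.005, 99.0, d)
    table = {
        "M0": [kappa, w_free("omega", 0.4)],
        "M1a": [kappa, prop("p0", 0.7), w_purif("omega0")],
        "M2a": [kappa, prop("q0", 0.7), prop("q1", 0.85),
                w_purif("omega0"), w_pos("omega2")],
        "M3k3": [kappa, prop("q0", 0.4), prop("q1", 0.5),
                 w_free("omega0", 0.1), w_free("omega1", 0.5), w_free("omega2", 1.5)],
        "M7": [kappa, bshape("p", 0.5), bshape("q", 1.5)],
        "M8": [kappa, prop("p0", 0.9), bshape("p", 0.5), bshape("q", 1.5),
               w_pos("omega_s")],
        "M8a": [kappa, prop("p0", 0.9), bshape("p", 0.5), bshape("q", 1.5)],
        "BR2": [kappa, w_free("omega_bg", 0.4), w_free("omega_fg", 0.6)],
        "BSA": [kappa, prop("q0", 0.7), prop("q1", 0.85),
                w_purif("omega0"), w_pos("omega2")],
        "BSA0": [kappa, prop("q0", 0.7), prop("q1", 0.85), w_purif("omega0")],
    }
    if name not in table:
        raise ValueError(f"unknown model {name!r}")
    return table[name]


def beta_category_means(p: float, q: float, ncat: int) -> np.ndarray:
    """Means of ncat equal-probability beta(p,q) categories (PAML-style)."""
    edges = beta_dist.ppf(np.linspace(0.0, 1.0, ncat + 1), p, q)
    upper = betainc(p + 1.0, q, edges)
    means = (upper[1:] - upper[:-1]) * ncat * p / (p + q)
    return np.clip(means, 1e-8, 1.0)


def _stick(q0: float, q1: float) -> tuple[float, float, float]:
    p0 = q0
    p1 = (1.0 - q0) * q1
    return p0, p1, max(1.0 - p0 - p1, 0.0)


def model_classes(name: str, est: Mapping[str, float],
                  ncat: int = 10) -> list[tuple[float, float, float]]:
    """Mixture classes as (proportion, omega_background, omega_foreground)."""
    if name == "M0":
        w = est["omega"]
        return [(1.0, w, w)]
    if name == "M1a":
        p0, w0 = est["p0"], est["omega0"]
        return [(p0, w0, w0), (1.0 - p0, 1.0, 1.0)]
    if name == "M2a":
        p0, p1, p2 = _stick(est["q0"], est["q1"])
        w0, w2 = est["omega0"], est["omega2"]
        return [(p0, w0, w0), (p1, 1.0, 1.0), (p2, w2, w2)]
    if name == "M3k3":
        p0, p1, p2 = _stick(est["q0"], est["q1"])
        return [(p0, est["omega0"], est["omega0"]),
                (p1, est["omega1"], est["omega1"]),
                (p2, est["omega2"], est["omega2"])]
    if name in ("M7", "M8", "M8a"):
        means = beta_category_means(est["p"], est["q"], ncat)
        if name == "M7":
            return [(1.0 / ncat, w, w) for w in means]
        p0 = est["p0"]
        ws = est["omega_s"] if name == "M8" else 1.0
        classes = [(p0 / ncat, w, w) for w in means]
        classes.append((1.0 - p0, ws, ws))
        return classes
    if name == "BR2":
        return [(1.0, est["omega_bg"], est["omega_fg"])]
    if name in ("BSA", "BSA0"):
        p0, p1, p2 = _stick(est["q0"], est["q1"])
        w0 = est["omega0"]
        w2 = est["omega2"] if name == "BSA" else 1.0
        denom = max(p0 + p1, 1e-12)
        return [(p0, w0, w0), (p1, 1.0, 1.0),
                (p2 * p0 / denom, w0, w2), (p2 * p1 / denom, 1.0, w2)]
    raise ValueError(f"unknown model {name!r}")


# ---------------------------------------------------------------------------
# likelihood engine
# ---------------------------------------------------------------------------

class LikelihoodEngine:
    """Felsenstein pruning over compressed site patterns for one cluster."""

    def __init__(self, tree: GeneTree, ca: CodonAlignment,
                 freqs: CodonFrequencies | None = None, ncat: int = 10):
        leaves = sorted(tree.leaves())
        if leaves != sorted(ca.taxa):
            raise ValueError("alignment taxa do not match tree leaves")
        if ca.n_codon_columns == 0:
            raise ValueError("empty alignment")
        self.tree = tree
        self.ca = ca
        self.freqs = freqs or compute_frequencies(ca)
        self.pi = self.freqs.pi
        self.ncat = ncat

        self.postorder: list[TreeNode] = tree.postorder()
        self.node_pos = {id(n): k for k, n in enumerate(self.postorder)}
        self.n_edges = len(self.postorder) - 1

        # codon index matrix (taxa x columns), compressed to unique patterns
        mat = np.stack([codon_indices(ca.row(t)) for t in ca.taxa])
        patterns, inverse, counts = np.unique(
            mat.T, axis=0, return_inverse=True, return_counts=True)
        self.patterns = patterns.T  # (ntaxa, npat)
        self.pattern_of_site = inverse
        self.weights = counts.astype(float)
        self.taxon_row = {t: i for i, t in enumerate(ca.taxa)}
        self.fg_leaf = tree.foreground

    # -- core ------------------------------------------------------------
    def _edge_is_foreground(self, child: TreeNode) -> bool:
        return child.is_leaf and child.name == self.fg_leaf

    def site_class_loglik(self, kappa: float,
                          classes: Sequence[tuple[float, float, float]],
                          branch_lengths: np.ndarray) -> np.ndarray:
        """Per-pattern log-likelihood under each mixture class, (K, npat)."""
        pi = self.pi
        omegas = sorted({w for _, wb, wf in classes for w in (wb, wf)})
        eigs = {}
        rates = {}
        for w in omegas:
            Q = _unscaled_generator(kappa, w, pi)
            rates[w] = _mean_rate(Q, pi)
            eigs[w] = _eigen(Q, pi)
        # one common scale: mixture-average background rate = 1
        factor = sum(p * rates[wb] for p, wb, _ in classes)
        npat = self.patterns.shape[1]
        out = np.empty((len(classes), npat))
        for k, (_, wb, wf) in enumerate(classes):
            out[k] = self._pruning(eigs, wb, wf, branch_lengths / factor)
        return out

    def _pruning(self, eigs, w_bg: float, w_fg: float,
                 scaled_bl: np.ndarray) -> np.ndarray:
        npat = self.patterns.shape[1]
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros(npat)
        for pos, node in enumerate(self.postorder):
            if node.is_leaf:
                continue
            acc = np.ones((npat, N_SENSE))
            for child in node.children:
                cpos = self.node_pos[id(child)]
                w = w_fg if self._edge_is_foreground(child) else w_bg
                P = _p_from_eigen(eigs[w], scaled_bl[cpos])
                if child.is_leaf:
                    codes = self.patterns[self.taxon_row[child.name]]
                    contrib = P.take(codes, axis=1).T
                else:
                    contrib = partial.pop(cpos) @ P.T
                acc *= contrib
            m = acc.max(axis=1)
            m[m <= 0.0] = 1e-300
            acc /= m[:, None]
            logscale += np.log(m)
            partial[pos] = acc
        root = partial[len(self.postorder) - 1]
        site = root @ self.pi
        site[site <= 0.0] = 1e-300
        return np.log(site) + logscale

    def loglik(self, kappa: float,
               classes: Sequence[tuple[float, float, float]],
               branch_lengths: np.ndarray) -> float:
        cls_ll = self.site_class_loglik(kappa, classes, branch_lengths)
        props = np.array([max(p, 0.0) for p, _, _ in classes])
        props = np.maximum(props, 1e-300)
        site_ll = logsumexp(cls_ll + np.log(props)[:, None], axis=0)
        return float((site_ll * self.weights).sum())


def log_likelihood(tree: GeneTree, ca: CodonAlignment, name: str,
                   estimates: Mapping[str, float],
                   branch_lengths: np.ndarray | None = None,
                   freqs: CodonFrequencies | None = None,
                   ncat: int = 10) -> float:
    """lnL of a cleaned alignment under fixed model parameters."""
    engine = LikelihoodEngine(tree, ca, freqs=freqs, ncat=ncat)
    bl = tree.branch_lengths() if branch_lengths is None else np.asarray(branch_lengths)
    classes = model_classes(name, estimates, ncat)
    return engine.loglik(estimates["kappa"], classes, bl)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

BL_LO, BL_HI = 1e-6, 50.0


@dataclass
class ModelFit:
    """A fitted codon model for one cluster."""

    name: str
    lnL: float
    np_params: int
    estimates: dict[str, float]
    classes: list[tuple[float, float, float]]
    branch_lengths: np.ndarray
    converged: bool
    n_starts: int
    seed: int
    foreground: str | None = None
    freqs: CodonFrequencies | None = field(default=None, repr=False)

    @property
    def kappa(self) -> float:
        return self.estimates["kappa"]

    def omega_summary(self) -> float:
        """A single headline omega: the (foreground) positive-class omega for
        selection models, the point estimate for M0/BR2, else the mixture mean."""
        e = self.estimates
        if "omega" in e:
            return e["omega"]
        if self.name == "BR2":
            return e["omega_fg"]
        if "omega2" in e:
            return e["omega2"]
        if "omega_s" in e:
            return e["omega_s"]
        return float(sum(p * wf for p, _, wf in self.classes))

    def to_dict(self) -> dict:
        return {
            "model": self.name, "lnL": self.lnL, "np": self.np_params,
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "classes": [[float(x) for x in c] for c in self.classes],
            "branch_lengths": [float(b) for b in self.branch_lengths],
            "converged": bool(self.converged), "n_starts": self.n_starts,
            "seed": self.seed, "foreground": self.foreground,
            "frequency_model": self.freqs.method if self.freqs else None,
        }


def warm_start_estimates(target: str, source: ModelFit) -> dict[str, float] | None:
    """Embed a fitted null model's MLE into a nested alternative's space.

    Starting the alternative there makes its lnL at iteration zero equal to
    the null's (up to a ~1e-6 mixture-mass perturbation), so the LRT
    statistic cannot go negative beyond round-off.
    """
    e = source.estimates
    eps = 1e-8
    pairs = (source.name, target)
    if pairs == ("M0", "M3k3"):
        return {"kappa": e["kappa"], "q0": 0.34, "q1": 0.5,
                "omega0": e["omega"], "omega1": e["omega"], "omega2": e["omega"]}
    if pairs == ("M1a", "M2a"):
        p0 = e["p0"]
        return {"kappa": e["kappa"], "q0": p0 * (1 - eps),
                "q1": max((1 - p0) * (1 - eps) / max(1 - p0 * (1 - eps), 1e-12), _PROP_LO),
                "omega0": e["omega0"], "omega2": 2.0}
    if pairs == ("M7", "M8"):
        return {"kappa": e["kappa"], "p0": 1.0 - eps,
                "p": e["p"], "q": e["q"], "omega_s": 2.0}
    if pairs == ("M7", "M8a"):
        return {"kappa": e["kappa"], "p0": 1.0 - eps, "p": e["p"], "q": e["q"]}
    if pairs == ("M8a", "M8"):
        return {"kappa": e["kappa"], "p0": e["p0"], "p": e["p"], "q": e["q"],
                "omega_s": 1.0 + eps}
    if pairs == ("M0", "BR2"):
        return {"kappa": e["kappa"], "omega_bg": e["omega"], "omega_fg": e["omega"]}
    if pairs == ("M1a", "BSA0") or pairs == ("M1a", "BSA"):
        p0 = e["p0"]
        out = {"kappa": e["kappa"], "q0": p0 * (1 - eps),
               "q1": max((1 - p0) * (1 - eps) / max(1 - p0 * (1 - eps), 1e-12), _PROP_LO),
               "omega0": e["omega0"]}
        if target == "BSA":
            out["omega2"] = 2.0
        return out
    if pairs == ("BSA0", "BSA"):
        return {**{k: e[k] for k in ("kappa", "q0", "q1", "omega0")},
                "omega2": 1.0 + eps}
    return None


def fit_model(tree: GeneTree, ca: CodonAlignment, name: str, seed: int = 0,
              n_starts: int = 3, warm_start: ModelFit | None = None,
              freqs: CodonFrequencies | None = None, ncat: int = 10,
              max_iter: int = 400) -> ModelFit:
    """Maximize lnL over model parameters and branch lengths.

    Multi-start: the first start uses defaults (or the warm start mapped from
    a nested null fit); later starts jitter the transformed parameters with a
    seeded RNG. The best start wins.
    """
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}")
    if name in FOREGROUND_MODELS and tree.foreground is None:
        raise ValueError(f"model {name} requires a foreground-marked tree")
    engine = LikelihoodEngine(tree, ca, freqs=freqs, ncat=ncat)
    params = _params_for(name)
    n_edges = engine.n_edges
    rng = np.random.default_rng(seed)

    bl0 = np.clip(tree.branch_lengths(), 1e-3, 10.0)
    z_default = np.concatenate([
        [p.to_opt(p.default) for p in params], np.log(bl0)])
    starts = []
    if warm_start is not None:
        mapped = warm_start_estimates(name, warm_start)
        if mapped is not None:
            zw = np.concatenate([
                [p.to_opt(mapped[p.name]) for p in params],
                np.log(np.clip(warm_start.branch_lengths, BL_LO, BL_HI))])
            starts.append(zw)
    if not starts:
        starts.append(z_default)
    while len(starts) < n_starts:
        jitter = rng.normal(0.0, 0.3, size=z_default.size)
        starts.append(z_default + jitter)

    lo = np.concatenate([[p._olo for p in params], np.full(n_edges, math.log(BL_LO))])
    hi = np.concatenate([[p._ohi for p in params], np.full(n_edges, math.log(BL_HI))])
    bounds = list(zip(lo, hi))

    def unpack(z: np.ndarray) -> tuple[dict[str, float], np.ndarray]:
        est = {p.name: p.from_opt(z[i]) for i, p in enumerate(params)}
        return est, np.exp(z[len(params):])

    def objective(z: np.ndarray) -> float:
        est, bl = unpack(z)
        try:
            return -engine.loglik(est["kappa"], model_classes(name, est, ncat), bl)
        except (FloatingPointError, np.linalg.LinAlgError):
            return 1e12

    best = None
    for z0 in starts:
        z0 = np.clip(z0, lo, hi)
        res = optimize.minimize(objective, z0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": max_iter, "ftol": 1e-11,
                                         "gtol": 1e-7})
        if best is None or res.fun < best.fun:
            best = res

    est, bl = unpack(best.x)
    classes = model_classes(name, est, ncat)
    return ModelFit(
        name=name, lnL=-float(best.fun), np_params=len(params) + n_edges,
        estimates=est, classes=classes, branch_lengths=bl,
        converged=bool(best.success), n_starts=len(starts), seed=seed,
        foreground=tree.foreground if name in FOREGROUND_MODELS else None,
        freqs=engine.freqs)


def fit_branch_model(tree: GeneTree, ca: CodonAlignment, foreground: str,
                     seed: int = 0, n_starts: int = 2,
                     m0_fit: ModelFit | None = None,
                     freqs: CodonFrequencies | None = None) -> tuple[ModelFit, ModelFit]:
    """Two-ratio branch test for one foreground terminal branch.

    Returns (null, alternative) = (one-ratio M0, two-ratio model with a free
    foreground omega); df = 1.
    """
    fg_tree = tree.with_foreground(foreground)
    null = m0_fit or fit_model(tree, ca, "M0", seed=seed, n_starts=n_starts,
                               freqs=freqs)
    alt = fit_model(fg_tree, ca, "BR2", seed=seed, n_starts=n_starts,
                    warm_start=null, freqs=freqs)
    return null, alt


def fit_branch_site(tree: GeneTree, ca: CodonAlignment, foreground: str,
                    seed: int = 0, n_starts: int = 2,
                    m1a_fit: ModelFit | None = None,
                    freqs: CodonFrequencies | None = None) -> tuple[ModelFit, ModelFit]:
    """Branch-site Model A test for one foreground terminal branch.

    Returns (null, alternative): the null fixes the foreground selection
    class at omega2 = 1; df = 1 (conservative plain chi-square by default in
    the statistics layer).
    """
    fg_tree = tree.with_foreground(foreground)
    null = fit_model(fg_tree, ca, "BSA0", seed=seed, n_starts=n_starts,
                     warm_start=m1a_fit, freqs=freqs)
    alt = fit_model(fg_tree, ca, "BSA", seed=seed, n_starts=n_starts,
                    warm_start=null, freqs=freqs)
    return null, alt


# ---------------------------------------------------------------------------
# site identification (NEB)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteResult:
    site: int          # 1-based codon position in the original alignment
    posterior: float   # probability of the positive-selection class(es)
    method: str = "NEB"


def site_posteriors(fit: ModelFit, tree: GeneTree, ca: CodonAlignment,
                    method: str = "NEB", ncat: int = 10) -> list[SiteResult]:
    """Per-site posterior probability of the positive-selection class.

    Naive empirical Bayes at the MLEs: posterior(k | site) proportional to
    proportion_k x L(site | class k). Only models with an omega>1 class
    (M2a, M8, branch-site Model A) are valid targets.
    """
    if method == "BEB":
        raise NotImplementedError(
            "Bayes empirical Bayes integration is not implemented; use NEB")
    if method != "NEB":
        raise ValueError(f"unknown site-identification method {method!r}")
    if fit.name not in POSITIVE_CLASS:
        raise ValueError(f"model {fit.name} has no positive-selection class")
    use_tree = tree.with_foreground(fit.foreground) if fit.foreground else tree
    engine = LikelihoodEngine(use_tree, ca, freqs=fit.freqs, ncat=ncat)
    cls_ll = engine.site_class_loglik(fit.kappa, fit.classes, fit.branch_lengths)
    props = np.maximum(np.array([p for p, _, _ in fit.classes]), 1e-300)
    logpost = cls_ll + np.log(props)[:, None]
    logpost -= logsumexp(logpost, axis=0, keepdims=True)
    post = np.exp(logpost)
    pos_idx = [k % len(fit.classes) for k in POSITIVE_CLASS[fit.name]]
    pos = post[pos_idx].sum(axis=0)
    per_site = pos[engine.pattern_of_site]
    return [SiteResult(site=ca.site_map[i], posterior=float(per_site[i]))
            for i in range(ca.n_codon_columns)]


def selected_sites(results: Sequence[SiteResult],
                   threshold: float = 0.95) -> list[SiteResult]:
    return [r for r in results if r.posterior >= threshold]
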