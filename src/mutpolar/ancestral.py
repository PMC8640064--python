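"""Probabilistic ancestral-allele assignment from nested outgroups.

The focal panel (e.g. 98 cattle, 196 allele counts per site) is polarized
against up to three outgroups arranged on the fixed rooted topology

    ((focal, yak), sheep), camel

under a Kimura two-parameter (K2) substitution model.  For each site we
compute, for every base ``a``, the joint probability of the outgroup bases
and the focal allele-count configuration given that the focal-ancestor node
carried ``a``, and from it the posterior probability ``P_ancs`` that the
focal *major* allele is ancestral.

Generative model
----------------
* The root base is uniform over {A,C,G,T}; because K2 is reversible with a
  uniform stationary distribution, the focal-ancestor node can serve as the
  root for likelihood purposes.
* Each branch applies a K2 transition matrix with its own expected number
  of substitutions ``t`` and a shared transition/transversion ratio kappa.
* Outgroup tips emit their single observed base; a missing outgroup is
  marginalized (its tip partial is all-ones).
* The focal tip emits the observed count configuration given ancestor base
  ``a``: a site monomorphic for ``a`` has weight ``pi[mono]``; a site
  segregating ``a`` with an alternative base ``m`` at derived count ``k``
  has weight ``relrate(a -> m) * pi[bin(k)]``, where ``relrate`` is the K2
  relative mutation rate (transitions kappa-fold more likely than each
  transversion) and ``pi`` is a binned unfolded site-frequency-spectrum
  weight vector (shared across sites, estimated by EM).

Bases are indexed A=0, C=1, G=2, T=3 throughout; transitions are A<->G and
C<->T.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# partner under a transition (A<->G, C<->T)
_TRANSITION_PARTNER = np.array([2, 3, 0, 1])

MISSING_BASE = -1

#: branch order: focal-ancestor->node2, yak->node2, node2->node3,
#: sheep->node3, camel->node3
BRANCH_NAMES = ("focal", "yak", "internal", "sheep", "camel")


def k2_transition_matrix(t: float, kappa: float) -> np.ndarray:
    """K2 base-substitution probability matrix after ``t`` expected substitutions.

    The rate matrix is normalized so that the total substitution rate per
    unit branch length is 1 (``alpha + 2*beta = 1`` with
    ``alpha/beta = kappa``).  Closed form:

        P(same)         = 1/4 + 1/4 e1 + 1/2 e2
        P(transition)   = 1/4 + 1/4 e1 - 1/2 e2
        P(transversion) = 1/4 - 1/4 e1   (each of the two)

    with ``e1 = exp(-4 beta t)`` and ``e2 = exp(-2 (alpha + beta) t)``.
    """
    if t < 0:
        raise ValueError(f"branch length must be non-negative, got {t}")
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    P = np.full((4, 4), p_tv)
    for i in range(4):
        P[i, i] = p_same
        P[i, _TRANSITION_PARTNER[i]] = p_ts
    return P


def k2_relative_rates(kappa: float) -> np.ndarray:
    """Relative mutation rates a->m (rows sum to 1, zero diagonal)."""
    beta = 1.0 / (kappa + 2.0)
    R = np.full((4, 4), beta)
    np.fill_diagonal(R, 0.0)
    for i in range(4):
        R[i, _TRANSITION_PARTNER[i]] = kappa * beta
    return R


@dataclass
class K2Model:
    """Parameters of the polarization model.

    Parameters
    ----------
    branch_lengths : 5-vector of expected substitutions per site, ordered
        as :data:`BRANCH_NAMES`.
    kappa : transition/transversion rate ratio (shared across branches).
    pi : SFS weight vector of length ``n_bins + 2``; entry 0 is the
        monomorphic-ancestral class, entries ``1..n_bins`` are derived-count
        bins over (0, 2N), the last entry is the fixed-derived class.
    n_bins : number of polymorphic derived-frequency bins.
    """

    branch_lengths: np.ndarray
    kappa: float = 2.0
    n_bins: int = 20
    pi: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.branch_lengths = np.asarray(self.branch_lengths, dtype=float)
        if self.branch_lengths.shape != (5,):
            raise ValueError("expected 5 branch lengths")
        if np.any(self.branch_lengths < 0) or not np.all(
            np.isfinite(self.branch_lengths)
        ):
            raise ValueError("branch lengths must be finite and >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.pi is None:
            # default: half the mass on monomorphic-ancestral, the rest
            # spread over the polymorphic bins and the fixed-derived class
            k = self.n_bins + 2
            pi = np.full(k, 0.5 / (k - 1))
            pi[0] = 0.5
            self.pi = pi
        self.pi = np.asarray(self.pi, dtype=float)
        if len(self.pi) != self.n_bins + 2:
            raise ValueError("pi must have n_bins + 2 entries")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be a probability vector")


@dataclass
class SiteCounts:
    """Vectorized per-site data: focal base counts plus outgroup bases.

    ``counts`` is (n_sites, 4) over A,C,G,T; ``outgroups`` is (n_sites, 3)
    base indices with -1 for missing (yak, sheep, camel order).
    """

    counts: np.ndarray
    outgroups: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.outgroups = np.asarray(self.outgroups, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be (n_sites, 4)")
        if self.outgroups.shape != (self.counts.shape[0], 3):
            raise ValueError("outgroups must be (n_sites, 3)")
        if np.any(self.counts.sum(axis=1) <= 0):
            raise ValueError("every site needs a positive focal allele total")
        if np.any((self.counts > 0).sum(axis=1) > 2):
            raise ValueError(">2 focal bases observed; apply the biallelic filter")
        if np.any((self.outgroups == MISSING_BASE).all(axis=1)):
            raise ValueError("every site needs at least one outgroup base")

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SiteCounts":
        """Build from a TSV-style frame with countA..countT and yak/sheep/camel."""
        counts = df[["countA", "countC", "countG", "countT"]].to_numpy()
        og = np.full((len(df), 3), MISSING_BASE, dtype=np.int64)
        for j, col in enumerate(("yak", "sheep", "camel")):
            vals = df[col].astype(str).str.upper()
            for b, i in BASE_INDEX.items():
                og[(vals == b).to_numpy(), j] = i
        return cls(counts, og)


# --------------------------------------------------------------------------
# likelihood machinery


def _outgroup_partials(sites: SiteCounts, model: K2Model) -> np.ndarray:
    """(n_sites, 4) tree likelihood L[s, a] = P(outgroup bases | ancestor a).

    Felsenstein pruning on ((focal, yak)node2, sheep, camel)node3 with the
    focal-ancestor node taken as root (valid by reversibility).
    """
    t = model.branch_lengths
    P1 = k2_transition_matrix(t[0], model.kappa)  # ancestor -> node2
    P2 = k2_transition_matrix(t[1], model.kappa)  # node2 -> yak
    P3 = k2_transition_matrix(t[2], model.kappa)  # node2 -> node3
    P4 = k2_transition_matrix(t[3], model.kappa)  # node3 -> sheep
    P5 = k2_transition_matrix(t[4], model.kappa)  # node3 -> camel

    def tip_partial(col: np.ndarray, P: np.ndarray) -> np.ndarray:
        # (n_sites, 4): P[s, parent] = P(tip base | parent); ones if missing
        out = np.ones((len(col), 4))
        obs = col != MISSING_BASE
        out[obs] = P[:, col[obs]].T
        return out

    yak = tip_partial(sites.outgroups[:, 0], P2)
    sheep = tip_partial(sites.outgroups[:, 1], P4)
    camel = tip_partial(sites.outgroups[:, 2], P5)
    L3 = sheep * camel                      # partial at node3
    L2 = yak * (L3 @ P3.T)                  # partial at node2
    return L2 @ P1.T                        # conditional on ancestor base


def _sfs_bin(derived_count: np.ndarray, total: np.ndarray, n_bins: int) -> np.ndarray:
    """Map polymorphic derived counts (0 < k < 2N) to bins 0..n_bins-1."""
    frac = derived_count / total
    return np.minimum((frac * n_bins).astype(np.int64), n_bins - 1)


def _emission_matrix(sites: SiteCounts, model: K2Model) -> np.ndarray:
    """(n_sites, 4) emission E[s, a] = P(focal count configuration | ancestor a)."""
    n = sites.n_sites
    counts = sites.counts
    total = counts.sum(axis=1)
    R = k2_relative_rates(model.kappa)
    pi = model.pi
    nb = model.n_bins
    E = np.zeros((n, 4))

    nonzero = counts > 0
    n_obs = nonzero.sum(axis=1)

    mono = n_obs == 1
    if np.any(mono):
        b = np.argmax(counts[mono], axis=1)
        rows = np.where(mono)[0]
        E[rows, b] = pi[0]                      # monomorphic for the ancestor
        for a in range(4):
            other = b != a
            # fixed-derived: ancestor a, derived allele b drifted to fixation
            E[rows[other], a] += R[a, b[other]] * pi[nb + 1]
        # overwrite double-adds: the a == b case got pi[0] only (R zero diag)
    bi = n_obs == 2
    if np.any(bi):
        rows = np.where(bi)[0]
        # the two segregating bases, in base-index order
        seg = np.argsort(~nonzero[bi], axis=1)[:, :2]
        seg.sort(axis=1)
        b1, b2 = seg[:, 0], seg[:, 1]
        c2 = counts[rows, b2]
        c1 = counts[rows, b1]
        # hypothesis: ancestor = b1, derived = b2
        E[rows, b1] = R[b1, b2] * pi[1 + _sfs_bin(c2, total[rows], nb)]
        # hypothesis: ancestor = b2, derived = b1
        E[rows, b2] = R[b2, b1] * pi[1 + _sfs_bin(c1, total[rows], nb)]
        # other bases would need two mutations: probability 0 in this model
    return E


def site_loglik(
    sites: SiteCounts, model: K2Model, ancestral_hypothesis=None
) -> np.ndarray:
    """Log joint probability of outgroups + focal configuration per site.

    With ``ancestral_hypothesis`` a base letter or index, returns the
    (n_sites,) log of ``P(ancestor = a, data)`` (including the uniform 1/4
    root prior); with ``None`` returns the (n_sites, 4) array over all four
    ancestor hypotheses.
    """
    L = _outgroup_partials(sites, model)
    E = _emission_matrix(sites, model)
    with np.errstate(divide="ignore"):
        ll = np.log(0.25 * L * E)
    if ancestral_hypothesis is None:
        return ll
    a = (
        BASE_INDEX[ancestral_hypothesis]
        if isinstance(ancestral_hypothesis, str)
        else int(ancestral_hypothesis)
    )
    return ll[:, a]


def total_loglik(sites: SiteCounts, model: K2Model) -> float:
    """Marginal log-likelihood, ancestor base summed out per site."""
    ll = site_loglik(sites, model)
    m = ll.max(axis=1)
    return float(np.sum(m + np.log(np.exp(ll - m[:, None]).sum(axis=1))))


def _posterior_base(sites: SiteCounts, model: K2Model) -> np.ndarray:
    """(n_sites, 4) posterior over the focal-ancestor base."""
    ll = site_loglik(sites, model)
    m = ll.max(axis=1, keepdims=True)
    w = np.exp(ll - m)
    return w / w.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# model fitting


def fit_model(
    sites: SiteCounts,
    init: K2Model,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[K2Model, dict]:
    """Estimate (pi, branch lengths, kappa) by EM with coordinate updates.

    E-step: per-site posteriors over the ancestor base identify, for each
    hypothesis, a unique SFS class; the pi update is the normalized expected
    class count (closed form, an exact EM step).  Branch lengths and kappa
    are then each updated by a bounded 1-D maximization of the marginal
    log-likelihood, so the total log-likelihood is non-decreasing across
    iterations.

    Returns the fitted model plus an info dict with the log-likelihood
    trace, iteration count and a convergence flag.
    """
    model = replace(init)
    counts = sites.counts
    total = counts.sum(axis=1)
    nonzero = counts > 0
    n_obs = nonzero.sum(axis=1)
    nb = model.n_bins

    # precompute, per site and ancestor hypothesis, the SFS class index
    # (-1 where the hypothesis is impossible under the one-mutation model)
    class_idx = np.full((sites.n_sites, 4), -1, dtype=np.int64)
    mono = np.where(n_obs == 1)[0]
    if len(mono):
        b = np.argmax(counts[mono], axis=1)
        class_idx[mono, b] = 0
        for a in range(4):
            other = mono[b != a]
            class_idx[other, a] = nb + 1
        class_idx[mono, b] = 0
    bi = np.where(n_obs == 2)[0]
    if len(bi):
        seg = np.argsort(~nonzero[bi], axis=1)[:, :2]
        seg.sort(axis=1)
        b1, b2 = seg[:, 0], seg[:, 1]
        class_idx[bi, b1] = 1 + _sfs_bin(counts[bi, b2], total[bi], nb)
        class_idx[bi, b2] = 1 + _sfs_bin(counts[bi, b1], total[bi], nb)

    trace = [total_loglik(sites, model)]
    converged = False
    for _ in range(max_iter):
        # ---- E-step + closed-form pi update
        post = _posterior_base(sites, model)
        expected = np.zeros(nb + 2)
        valid = class_idx >= 0
        np.add.at(expected, class_idx[valid], post[valid])
        expected = np.maximum(expected, 1e-12)
        model = replace(model, pi=expected / expected.sum())

        # ---- coordinate updates of branch lengths and kappa
        for b_i in range(5):
            def neg(tb, b_i=b_i):
                t = model.branch_lengths.copy()
                t[b_i] = tb
                return -total_loglik(sites, replace(model, branch_lengths=t))

            res = minimize_scalar(neg, bounds=(1e-6, 3.0), method="bounded",
                                  options={"xatol": 1e-6})
            t = model.branch_lengths.copy()
            if -res.fun >= -neg(t[b_i]):
                t[b_i] = res.x
                model = replace(model, branch_lengths=t)

        def neg_k(k):
            return -total_loglik(sites, replace(model, kappa=k))

        res = minimize_scalar(neg_k, bounds=(0.05, 50.0), method="bounded",
                              options={"xatol": 1e-5})
        if -res.fun >= -neg_k(model.kappa):
            model = replace(model, kappa=float(res.x))

        trace.append(total_loglik(sites, model))
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

    info = {
        "loglik": trace[-1],
        "trace": trace,
        "n_iter": len(trace) - 1,
        "converged": converged,
        "low_information": sites.n_sites < 100,
    }
    return model, info


# --------------------------------------------------------------------------
# posterior + assignment


def posterior_major_ancestral(sites: SiteCounts, model: K2Model) -> pd.DataFrame:
    """Per-site posterior probabilities for the designated major allele.

    Returns a frame with the major/minor base (count ties designate the
    lower base index as "major" so that ``P_ancs`` is always defined),
    ``P_ancs`` = P(major ancestral | data), ``p_minor_anc`` and
    ``p_neither`` (residual mass on non-segregating bases; zero at
    polymorphic sites under the one-mutation emission model).
    """
    post = _posterior_base(sites, model)
    counts = sites.counts
    order = np.argsort(-counts, axis=1, kind="stable")
    major = order[:, 0]
    minor = order[:, 1]
    rows = np.arange(sites.n_sites)
    minor_count = counts[rows, minor]
    tied = counts[rows, major] == minor_count
    p_major = post[rows, major]
    p_minor = np.where(minor_count > 0, post[rows, minor], 0.0)
    return pd.DataFrame(
        {
            "major": [BASES[i] for i in major],
            "minor": [BASES[i] if c > 0 else "." for i, c in zip(minor, minor_count)],
            "tied": tied,
            "P_ancs": p_major,
            "p_minor_anc": p_minor,
            "p_neither": np.clip(1.0 - p_major - p_minor, 0.0, 1.0),
        }
    )


def assign_ancestral(
    posteriors: pd.DataFrame,
    sites: SiteCounts,
    upper: float = 0.8,
    lower: float = 0.2,
) -> pd.DataFrame:
    """Apply the threshold decision rules to per-site posteriors.

    Rules (in order): a clear major allele with ``P_ancs > upper`` is
    ancestral (rule ``major-prob``); with ``P_ancs < lower`` the minor
    allele is ancestral (``minor-prob``).  If the focal counts are exactly
    tied so no major exists but the posterior is decisive either way, the
    focal allele most frequent among the outgroups is ancestral
    (``outgroup-majority``); an outgroup tie stays ambiguous.  Everything
    else is ``ambiguous``.
    """
    n = len(posteriors)
    anc = np.full(n, ".", dtype=object)
    mut = np.full(n, ".", dtype=object)
    rule = np.full(n, "ambiguous", dtype=object)
    p = posteriors["P_ancs"].to_numpy()
    tied = posteriors["tied"].to_numpy()
    major = posteriors["major"].to_numpy()
    minor = posteriors["minor"].to_numpy()

    poly = minor != "."
    hi = (p > upper) & ~tied & poly
    lo = (p < lower) & ~tied & poly
    anc[hi], mut[hi], rule[hi] = major[hi], minor[hi], "major-prob"
    anc[lo], mut[lo], rule[lo] = minor[lo], major[lo], "minor-prob"

    tie_decisive = tied & poly & ((p > upper) | (p < lower))
    for i in np.where(tie_decisive)[0]:
        a_i, b_i = BASE_INDEX[major[i]], BASE_INDEX[minor[i]]
        og = sites.outgroups[i]
        votes_a = int(np.sum(og == a_i))
        votes_b = int(np.sum(og == b_i))
        if votes_a > votes_b:
            anc[i], mut[i], rule[i] = major[i], minor[i], "outgroup-majority"
        elif votes_b > votes_a:
            anc[i], mut[i], rule[i] = minor[i], major[i], "outgroup-majority"
        # equal votes (incl. all-missing among the pair): stays ambiguous

    out = posteriors.copy()
    out["ancestral"] = anc
    out["mutant"] = mut
    out["rule"] = rule
    return out


def polarize(
    sites: SiteCounts,
    model: K2Model | None = None,
    fit: bool = True,
    site_meta: pd.DataFrame | None = None,
    **fit_kwargs,
) -> tuple[pd.DataFrame, K2Model, dict]:
    """End-to-end polarization: (optionally) fit the model, then assign.

    ``site_meta`` (chrom/pos) is prepended to the output when given.
    """
    if model is None:
        init = K2Model(branch_lengths=np.full(5, 0.05))
        model = init
    info: dict = {}
    if fit:
        model, info = fit_model(sites, model, **fit_kwargs)
    calls = assign_ancestral(posterior_major_ancestral(sites, model), sites)
    if site_meta is not None:
        calls = pd.concat(
            [site_meta.reset_index(drop=True), calls.reset_index(drop=True)], axis=1
        )
    return calls, model, info
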