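"""Maximum-likelihood isolation-with-migration analysis for species triplets.

The model assumes a three-species phylogeny ((S1, S2), S3) with S1 and
S2 diverging at tau1, the root at tau0, and (model M2) continuous
bidirectional gene flow between S1 and S2 since their divergence at
rates M12 = m12*N2 and M21 = m21*N1 expected migrants per generation.
Model M0 fixes M12 = M21 = 0 and has six parameters: tau1, tau0, theta1
(S1), theta2 (S2), theta4 (root), theta5 (ancestor of S1 and S2); there
is no theta3 for S3 because at most one sequence per locus comes from
S3, and no gene flow involves the outgroup.  M2 adds M12 and M21
(eight parameters).  Delta-tau = tau0 - tau1 is the internal branch
length; values near zero (a "star tree") flag a likely misassigned
branching order.

Each locus contributes three phased haploid sequences in one of the
configurations 123 (one from each species), 113 (two from S1) or 223
(two from S2).  The per-locus likelihood integrates the JC69 site
pattern probabilities over the two coalescent ages.  While t < tau1 the
two ingroup lineages move between populations 1 and 2 by backward
migration (a lineage in population j jumps to population i at rate
4*M_ij/theta_j) and may coalesce only when they share a population;
the three-state occupancy chain {11, 12, 22} is solved by
eigendecomposition, and the ages are integrated with Gauss-Legendre
quadrature (exponential change of variables on unbounded intervals).
Site patterns are collapsed by the base symmetry of the equal-rates
model into five classes: xxx, xxy, xyx, yxx, xyz.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields

import numpy as np
from scipy import linalg, optimize, stats

from .alignment import LocusAlignment
from .mcmc import species_of_label

__all__ = [
    "TripletParams",
    "TripletDataset",
    "sample_triplets",
    "pattern_classes",
    "triplet_loglik",
    "fit_triplet",
    "lrt_m0_m2",
    "internal_branch_diag",
]

CONFIGS = ("123", "113", "223")
CLASSES = ("xxx", "xxy", "xyx", "yxx", "xyz")


@dataclass
class TripletParams:
    tau1: float
    tau0: float
    theta1: float
    theta2: float
    theta4: float
    theta5: float
    M12: float = 0.0
    M21: float = 0.0

    def __post_init__(self):
        if not (0 <= self.tau1 <= self.tau0):
            raise ValueError("need 0 <= tau1 <= tau0")
        for name in ("theta1", "theta2", "theta4", "theta5"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.M12 < 0 or self.M21 < 0:
            raise ValueError("migration rates must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class TripletDataset:
    """Per-locus configuration codes (index into CONFIGS) and 5-class
    site-pattern counts."""

    config: np.ndarray  # (n_loci,) int
    counts: np.ndarray  # (n_loci, 5) int
    pair_labels: tuple[str, str, str] = ("S1", "S2", "S3")

    @property
    def n_loci(self) -> int:
        return len(self.config)

    def aggregate(self) -> np.ndarray:
        """Summed pattern counts per configuration, shape (3, 5)."""
        out = np.zeros((3, 5))
        for q in range(3):
            sel = self.config == q
            if sel.any():
                out[q] = self.counts[sel].sum(axis=0)
        return out


def _classify_columns(a: str, b: str, c: str) -> np.ndarray:
    """5-class site-pattern counts for three equal-length sequences;
    sites with any non-ACGT symbol are skipped."""
    counts = np.zeros(5, dtype=np.int64)
    for x, y, z in zip(a, b, c):
        if x not in "ACGT" or y not in "ACGT" or z not in "ACGT":
            continue
        if x == y == z:
            counts[0] += 1
        elif x == y:
            counts[1] += 1
        elif x == z:
            counts[2] += 1
        elif y == z:
            counts[3] += 1
        else:
            counts[4] += 1
    return counts


def sample_triplets(
    loci: list[LocusAlignment] | list[dict[str, list[str]]],
    s1: str,
    s2: str,
    outgroup: str,
    rng_seed,
) -> TripletDataset:
    """Sample one sequence triplet per locus.

    Triplet types 123, 113 and 223 are drawn with probabilities 0.5,
    0.25 and 0.25 (113 = two sequences from S1 plus the outgroup).
    Types infeasible at a locus (too few phased sequences) are dropped
    and the probabilities renormalized; sequences are chosen uniformly
    at random without replacement within species.  Loci without an
    outgroup sequence or with no feasible type are skipped.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    base_p = np.array([0.5, 0.25, 0.25])
    configs, counts = [], []
    for aln in loci:
        if isinstance(aln, LocusAlignment):
            pool: dict[str, list[str]] = {}
            for lab, seq in zip(aln.labels, aln.seqs):
                pool.setdefault(species_of_label(lab), []).append(seq)
        else:
            pool = aln
        n1 = len(pool.get(s1, []))
        n2 = len(pool.get(s2, []))
        n3 = len(pool.get(outgroup, []))
        feasible = np.array([n1 >= 1 and n2 >= 1, n1 >= 2, n2 >= 2]) & (n3 >= 1)
        if not feasible.any():
            continue
        p = base_p * feasible
        p /= p.sum()
        q = int(rng.choice(3, p=p))
        out = pool[outgroup][int(rng.integers(n3))]
        if q == 0:
            a = pool[s1][int(rng.integers(n1))]
            b = pool[s2][int(rng.integers(n2))]
        elif q == 1:
            i, j = rng.choice(n1, size=2, replace=False)
            a, b = pool[s1][int(i)], pool[s1][int(j)]
        else:
            i, j = rng.choice(n2, size=2, replace=False)
            a, b = pool[s2][int(i)], pool[s2][int(j)]
        configs.append(q)
        counts.append(_classify_columns(a, b, c=out))
    return TripletDataset(
        np.asarray(configs, dtype=np.int64),
        np.asarray(counts, dtype=np.int64).reshape(-1, 5),
        (s1, s2, outgroup),
    )


# ---------------------------------------------------------------------------
# site-pattern class probabilities given a genealogy
# ---------------------------------------------------------------------------

_CLASS_OF_TRIPLE = np.empty((4, 4, 4), dtype=np.int64)
for _x in range(4):
    for _y in range(4):
        for _z in range(4):
            if _x == _y == _z:
                _CLASS_OF_TRIPLE[_x, _y, _z] = 0
            elif _x == _y:
                _CLASS_OF_TRIPLE[_x, _y, _z] = 1
            elif _x == _z:
                _CLASS_OF_TRIPLE[_x, _y, _z] = 2
            elif _y == _z:
                _CLASS_OF_TRIPLE[_x, _y, _z] = 3
            else:
                _CLASS_OF_TRIPLE[_x, _y, _z] = 4


_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gl_unit(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights on (0, 1), cached."""
    if n not in _GL_CACHE:
        x, w = np.polynomial.legendre.leggauss(n)
        _GL_CACHE[n] = (0.5 * (x + 1.0), 0.5 * w)
    return _GL_CACHE[n]


def _p_matrices(t: np.ndarray) -> np.ndarray:
    """JC69 transition matrices for an array of times, shape (..., 4, 4)."""
    t = np.asarray(t, dtype=float)
    same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
    diff = (1.0 - same) / 3.0
    out = np.broadcast_to(diff[..., None, None], t.shape + (4, 4)).copy()
    idx = np.arange(4)
    out[..., idx, idx] = same[..., None]
    return out


def pattern_classes(u, v, pair: str = "12") -> np.ndarray:
    """Probabilities of the 5 site-pattern classes for a genealogy in
    which ``pair`` (positions of the sequence triple: '12', '13' or
    '23') coalesces at age u and joins the remaining lineage at v >= u.

    Closed forms under the equal-rates model: with A = P(pair tips
    equal) = 1/4 + (3/4)exp(-8u/3), B = P(a pair-tip equals the odd
    tip) = 1/4 + (3/4)exp(-8v/3), and T = P(all three equal), the
    classes are T, A-T (the coalescing pair's equality class), B-T
    (the two cross classes) and 1 - A - 2B + 2T (all distinct).
    Broadcasts over u, v; returns shape broadcast(u, v).shape + (5,).
    """
    if pair not in ("12", "13", "23"):
        raise ValueError("pair must be '12', '13' or '23'")
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    su = 0.25 + 0.75 * np.exp(-4.0 * u / 3.0)
    du = (1.0 - su) / 3.0
    A = 0.25 + 0.75 * np.exp(-8.0 * u / 3.0)
    B = 0.25 + 0.75 * np.exp(-8.0 * v / 3.0)
    sv = 0.25 + 0.75 * np.exp(-4.0 * v / 3.0)
    dv = (1.0 - sv) / 3.0
    w = v - u
    sw = 0.25 + 0.75 * np.exp(-4.0 * w / 3.0)
    dw = (1.0 - sw) / 3.0
    # P(all equal): condition on ancestor and root states
    T = du**2 + (su**2 - du**2) * (sv * sw + 3.0 * dv * dw)
    amt = A - T
    bmt = B - T
    xyz = 1.0 - A - 2.0 * B + 2.0 * T
    if pair == "12":
        cols = (T, amt, bmt, bmt, xyz)
    elif pair == "13":
        cols = (T, bmt, amt, bmt, xyz)
    else:
        cols = (T, bmt, bmt, amt, xyz)
    return np.stack(np.broadcast_arrays(*cols), axis=-1)


def _pattern_classes_tensor(u, v, pair: str = "12") -> np.ndarray:
    """Tensor-contraction route to the same class probabilities (full
    sum over ancestral states); slower, kept as an internal cross-check."""
    u, v = np.broadcast_arrays(np.asarray(u, float), np.asarray(v, float))
    p_u = _p_matrices(u)  # ancestor(at u) -> each of the pair tips
    p_mid = _p_matrices(v - u)  # root -> ancestor
    p_v = _p_matrices(v)  # root -> odd tip
    joint = 0.25 * np.einsum(
        "...ro,...rm,...mf,...ms->...fso", p_v, p_mid, p_u, p_u
    )
    if pair == "12":
        ordered = joint  # (a, b, c)
    elif pair == "13":
        ordered = np.moveaxis(joint, [-3, -2, -1], [-3, -1, -2])  # (a, c, b) -> abc
    elif pair == "23":
        ordered = np.moveaxis(joint, [-3, -2, -1], [-2, -1, -3])  # (b, c, a) -> abc
    else:
        raise ValueError("pair must be '12', '13' or '23'")
    out = np.zeros(ordered.shape[:-3] + (5,))
    for cls in range(5):
        mask = _CLASS_OF_TRIPLE == cls
        out[..., cls] = ordered[..., mask].sum(axis=-1)
    return out


# ---------------------------------------------------------------------------
# genealogy density and likelihood
# ---------------------------------------------------------------------------

def _phase_a_solution(params: TripletParams):
    """Eigen-solution of the two-ingroup-lineage occupancy chain on
    states (both in 1, split, both in 2) with coalescence as absorption."""
    c1, c2 = 2.0 / params.theta1, 2.0 / params.theta2
    r12 = 4.0 * params.M21 / params.theta1  # backward 1 -> 2
    r21 = 4.0 * params.M12 / params.theta2  # backward 2 -> 1
    A = np.array(
        [
            [-2 * r12 - c1, 2 * r12, 0.0],
            [r21, -r21 - r12, r12],
            [0.0, 2 * r21, -2 * r21 - c2],
        ]
    )
    crate = np.array([c1, 0.0, c2])
    try:
        lam, V = np.linalg.eig(A)
        Vinv = np.linalg.inv(V)
        if np.linalg.cond(V) > 1e10:
            raise np.linalg.LinAlgError
        def propagate(e0: np.ndarray, t: np.ndarray) -> np.ndarray:
            # occupancy vector at each t: e0 @ expm(A t)
            et = np.exp(np.multiply.outer(np.asarray(t, float), lam))
            return np.real(np.einsum("i,ij,...j,jk->...k", e0, V, et, Vinv))
    except np.linalg.LinAlgError:
        def propagate(e0: np.ndarray, t: np.ndarray) -> np.ndarray:
            ts = np.atleast_1d(np.asarray(t, float))
            out = np.stack([e0 @ linalg.expm(A * tt) for tt in ts])
            return out.reshape(np.shape(t) + (3,))
    return propagate, crate


def _all_config_atoms(
    params: TripletParams, n_quad: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted genealogy atoms shared by the three configurations.

    Returns (class_probs, weights) with class_probs (K, 5) the
    site-pattern class probabilities of each quadrature atom (a
    discretized genealogy: two coalescent ages and the first-coalescing
    pair) and weights (3, K) its genealogy-density weight under each
    configuration 123/113/223 (each row sums to 1).  The atom
    probabilities do not depend on the configuration, which lets the
    per-locus likelihood reuse one loci-by-atoms matrix.
    """
    x01, w01 = _gl_unit(n_quad)
    inits = np.eye(3)[[1, 0, 2]]  # e0 rows for configs 123, 113, 223
    propagate, crate = _phase_a_solution(params)
    th4 = params.theta4
    probs, weights = [], [[], [], []]

    # odd-lineage age grid on (tau0, inf): substitution wv = exp(-2(v-tau0)/th4)
    v_grid = params.tau0 - 0.5 * th4 * np.log(x01)  # x01 plays the role of wv
    wv = w01

    # phase A: u in (0, tau1)
    if params.tau1 > 0:
        uA = params.tau1 * x01
        probs.append(pattern_classes(uA[:, None], v_grid[None, :], "12").reshape(-1, 5))
        base = np.multiply.outer(params.tau1 * w01, wv)  # (n, n)
        S_A = np.empty(3)
        for q in range(3):
            occ = propagate(inits[q], uA)
            fA = np.clip(occ @ crate, 0.0, None)
            weights[q].append((fA[:, None] * base).reshape(-1))
            S_A[q] = float(np.clip(propagate(inits[q], np.array([params.tau1]))[0].sum(), 0.0, 1.0))
    else:
        S_A = np.ones(3)

    # phase B: u in (tau1, tau0), both lineages in the ancestral population
    dtau = params.tau0 - params.tau1
    if dtau > 0:
        uB = params.tau1 + dtau * x01
        probs.append(pattern_classes(uB[:, None], v_grid[None, :], "12").reshape(-1, 5))
        fB = (2.0 / params.theta5) * np.exp(-2.0 * (uB - params.tau1) / params.theta5)
        base = np.multiply.outer(dtau * w01 * fB, wv).reshape(-1)
        for q in range(3):
            weights[q].append(S_A[q] * base)
        S_0 = S_A * math.exp(-2.0 * dtau / params.theta5)
    else:
        S_0 = S_A

    # root phase: all three lineages in the root population
    # first coalescence t1: w1 = exp(-6(t1-tau0)/th4); then v: w2
    t1 = params.tau0 - th4 / 6.0 * np.log(x01)
    v2 = t1[:, None] - 0.5 * th4 * np.log(x01)[None, :]
    base = np.multiply.outer(w01, w01).reshape(-1) / 3.0
    for pair in ("12", "13", "23"):
        probs.append(pattern_classes(t1[:, None], v2, pair).reshape(-1, 5))
        for q in range(3):
            weights[q].append(S_0[q] * base)
    return np.concatenate(probs), np.stack([np.concatenate(w) for w in weights])


def _config_class_probs(
    params: TripletParams, q: int, n_quad: int = 16
) -> np.ndarray:
    """Marginal (single-site) 5-class probabilities for a configuration."""
    p, w = _all_config_atoms(params, n_quad)
    return w[q] @ p


def _config_atoms(
    params: TripletParams, q: int, n_quad: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """(weights, class_probs) of the genealogy atoms for one configuration."""
    p, w = _all_config_atoms(params, n_quad)
    return w[q], p


def triplet_loglik(
    params: TripletParams, data: TripletDataset, n_quad: int = 16
) -> float:
    """Log-likelihood of a triplet dataset (up to the additive
    multinomial-coefficient constant).

    Sites within a locus share one genealogy, so each locus contributes
    log of the genealogy-integrated joint probability of its pattern
    counts: log sum_k w_k prod_c p_kc^{n_c}; the quadrature atoms are
    shared by all loci, and the configurations differ only in the atom
    weights.
    """
    p, w = _all_config_atoms(params, n_quad)
    logp = np.log(np.clip(p, 1e-300, None))
    logw = np.log(np.clip(w, 1e-300, None))
    ll = data.counts @ logp.T + logw[data.config]  # (n_loci, K)
    mx = ll.max(axis=1)
    return float(mx.sum() + np.log(np.exp(ll - mx[:, None]).sum(axis=1)).sum())


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_LOG_BOUNDS = {
    "tau0": (math.log(1e-5), math.log(0.5)),
    "theta1": (math.log(1e-5), math.log(0.5)),
    "theta2": (math.log(1e-5), math.log(0.5)),
    "theta4": (math.log(1e-5), math.log(0.5)),
    "theta5": (math.log(1e-5), math.log(0.5)),
    "M": (math.log(1e-5), math.log(50.0)),
    "r": (1e-6, 1.0),  # tau1 = r * tau0, natural scale
}


def _unpack(x: np.ndarray, with_mig: bool) -> TripletParams:
    tau0 = math.exp(x[0])
    return TripletParams(
        tau1=float(x[1]) * tau0,
        tau0=tau0,
        theta1=math.exp(x[2]),
        theta2=math.exp(x[3]),
        theta4=math.exp(x[4]),
        theta5=math.exp(x[5]),
        M12=math.exp(x[6]) if with_mig else 0.0,
        M21=math.exp(x[7]) if with_mig else 0.0,
    )


@dataclass
class TripletFit:
    model: str
    params: TripletParams
    loglik: float
    n_parameters: int
    restarts: list[dict] = field(default_factory=list)
    all_extreme: bool = False


def fit_triplet(
    model: str,
    data: TripletDataset,
    n_restarts: int = 10,
    rng_seed=0,
    n_quad: int = 16,
    boundary_rtol: float = 1e-4,
    init_params: TripletParams | None = None,
    maxiter: int = 500,
) -> TripletFit:
    """Fit M0 or M2 by box-constrained quasi-Newton optimization from
    dispersed random starts.

    Restarts whose divergence-time or population-size estimates land
    within ``boundary_rtol`` relative distance of an optimization bound
    (or whose migration rates hit the upper bound) are flagged "extreme"
    and excluded from the argmax over restarts; if every restart is
    extreme the best overall is returned with a warning.  The tau1 lower
    bound (a star tree) and the migration lower bound (no gene flow) are
    legitimate parameter values and are not flagged.
    """
    if model not in ("M0", "M2"):
        raise ValueError("model must be 'M0' or 'M2'")
    if data.n_loci == 0:
        raise ValueError("empty dataset")
    with_mig = model == "M2"
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    names = ["tau0", "r", "theta1", "theta2", "theta4", "theta5"]
    bounds = [_LOG_BOUNDS["tau0"], _LOG_BOUNDS["r"]] + [_LOG_BOUNDS[n] for n in names[2:]]
    if with_mig:
        names += ["M12", "M21"]
        bounds += [_LOG_BOUNDS["M"], _LOG_BOUNDS["M"]]

    def neg_ll(x: np.ndarray) -> float:
        try:
            return -triplet_loglik(_unpack(x, with_mig), data, n_quad)
        except (ValueError, FloatingPointError):
            return 1e12

    def clip_box(x):
        return np.array([min(max(v, lo), hi) for v, (lo, hi) in zip(x, bounds)])

    restarts = []
    for k in range(n_restarts):
        if k == 0 and init_params is not None:
            # warm start (e.g. an M2 fit seeded from the M0 optimum)
            x0 = np.empty(len(names))
            x0[0] = math.log(max(init_params.tau0, 1e-5))
            x0[1] = min(max(init_params.tau1 / max(init_params.tau0, 1e-300), 1e-6), 1.0)
            x0[2:6] = np.log(
                [init_params.theta1, init_params.theta2,
                 init_params.theta4, init_params.theta5]
            )
            if with_mig:
                x0[6] = math.log(max(init_params.M12, 1e-4))
                x0[7] = math.log(max(init_params.M21, 1e-4))
            x0 = clip_box(x0)
        else:
            x0 = np.empty(len(names))
            x0[0] = math.log(10 ** rng.uniform(-3.0, -1.3))  # tau0 in ~(1e-3, 0.05)
            x0[1] = rng.uniform(0.2, 0.9)
            x0[2:6] = np.log(10 ** rng.uniform(-3.0, -1.3, size=4))
            if with_mig:
                x0[6:] = np.log(10 ** rng.uniform(-2.0, 0.5, size=2))
        res = optimize.minimize(
            neg_ll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter},
        )
        extreme = False
        for i, (nm, (lo, hi)) in enumerate(zip(names, bounds)):
            span = hi - lo
            at_lo = res.x[i] - lo <= boundary_rtol * span
            at_hi = hi - res.x[i] <= boundary_rtol * span
            if nm == "r":
                continue  # both r bounds are meaningful estimates
            if nm.startswith("M"):
                if at_hi:
                    extreme = True
            elif at_lo or at_hi:
                extreme = True
        restarts.append(
            {
                "params": _unpack(res.x, with_mig),
                "loglik": -float(res.fun),
                "extreme": extreme,
                "converged": bool(res.success),
            }
        )
    usable = [r for r in restarts if not r["extreme"]]
    all_extreme = not usable
    if all_extreme:
        warnings.warn(
            "all restarts hit an optimization boundary; returning best overall"
        )
        usable = restarts
    best = max(usable, key=lambda r: r["loglik"])
    return TripletFit(
        model=model,
        params=best["params"],
        loglik=best["loglik"],
        n_parameters=8 if with_mig else 6,
        restarts=restarts,
        all_extreme=all_extreme,
    )


def lrt_m0_m2(fit0: TripletFit, fit2: TripletFit) -> dict:
    """Likelihood-ratio test of M0 (no gene flow) against M2
    (bidirectional gene flow), chi-squared with 2 df at the 1% level."""
    stat = 2.0 * (fit2.loglik - fit0.loglik)
    if stat < -0.05:  # beyond optimizer/quadrature noise
        warnings.warn(
            f"LRT statistic negative ({stat:.3g}); optimization failure suspected"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df=2))
    return {"statistic": stat, "p_value": p, "significant_at_1pct": p < 0.01}


def internal_branch_diag(fit: TripletFit, star_fraction: float = 0.01) -> dict:
    """Delta-tau = tau0 - tau1 and the star-tree flag (Delta-tau below
    ``star_fraction`` of tau0 suggests a misassigned branching order)."""
    dtau = fit.params.tau0 - fit.params.tau1
    return {
        "delta_tau": dtau,
        "star_flag": bool(dtau < star_fraction * fit.params.tau0),
    }
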