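"""Multi-regime Brownian-motion / Ornstein-Uhlenbeck model selection.

Per-species gene counts of one family are treated as a continuous trait
evolving on the painted species tree.  Five models are fitted by maximum
likelihood and compared by AICc:

* ``BM1`` — Brownian motion, one variance rate sigma^2 for the whole tree
  (k = 2: sigma^2 and the root state);
* ``BMS`` — Brownian motion with a separate rate per regime (k = 3);
* ``OU1`` — Ornstein-Uhlenbeck pull (strength alpha, 1/My) towards a
  single optimum theta shared by both regimes (k = 3);
* ``OUM`` — OU with a separate optimum per regime, common variance
  (k = 4);
* ``OUMV`` — OU with separate optima and separate variances (k = 5).

BM1/BMS/OU1 are the no-adaptive-expansion null models (H0); OUM/OUMV are
the alternatives (H1).  A family is called an adaptive lineage-specific
expansion when the best H1 model beats the best H0 model by more than 2
AICc units; its direction is the regime with the larger fitted optimum.

The root carries no free optimum: the residual Hansen weight mass
``exp(-alpha T)`` on each root-to-tip lineage is assigned to the regime of
the lineage's oldest painted edge (the clade stem), so the process is
treated as stationary around the entered regime's optimum.  Optima and
root states are profiled out by generalized least squares, the overall
variance scale analytically, leaving at most a two-dimensional numeric
search (over ln alpha and a variance ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .trees import PaintedTree

__all__ = [
    "MODELS",
    "H0_MODELS",
    "H1_MODELS",
    "ModelFit",
    "SelectionCall",
    "model_covariance",
    "ou_expectation",
    "ou_weight_matrix",
    "fit_trait_model",
    "aicc",
    "select_model",
    "group_means",
    "fit_all_models",
]

MODELS = ("BM1", "BMS", "OU1", "OUM", "OUMV")
H0_MODELS = ("BM1", "BMS", "OU1")
H1_MODELS = ("OUM", "OUMV")

_K = {"BM1": 2, "BMS": 3, "OU1": 3, "OUM": 4, "OUMV": 5}
_LN_ALPHA_LO, _LN_ALPHA_HI = np.log(1e-5), np.log(10.0)
_LN_RATIO_LO, _LN_RATIO_HI = -12.0, 12.0


class RegimeModelError(ValueError):
    pass


@dataclass
class ModelFit:
    model: str
    lnL: float
    k: int
    aicc: float
    sigma2: dict[str, float]          # per regime ((trait)^2 / My)
    alpha: float | None = None        # OU pull strength (1/My)
    theta: dict[str, float] | None = None   # optima (trait units)
    root_state: float | None = None   # BM models only
    converged: bool = True


@dataclass
class SelectionCall:
    family_id: str
    best_h0: tuple[str, float]
    best_h1: tuple[str, float]
    delta_aicc: float
    positive: bool
    direction: str | None
    group_means: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Tree geometry helpers


def _lineage_segments(ptree: PaintedTree):
    """Per tip: list of (t_start, t_end, regime) from root to tip; plus depth."""
    depths = ptree.node_depths()
    regimes = ptree.edge_regimes()
    segs: dict[str, list[tuple[float, float, str]]] = {}
    for leaf in ptree.tree.leaf_node_iter():
        path = []
        node = leaf
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        path.reverse()
        segs[leaf.taxon.label] = [
            (depths[nd.parent_node], depths[nd], regimes[nd]) for nd in path
        ]
    T = float(np.mean([depths[lf] for lf in ptree.tree.leaf_node_iter()]))
    return segs, T


def _pairwise_mrca_values(ptree: PaintedTree, node_value: dict) -> tuple[list[str], np.ndarray, np.ndarray]:
    """(labels, M, D): M[i,j] = value at mrca(i,j); D[i,j] = depth of mrca."""
    depths = ptree.node_depths()
    leaves = list(ptree.tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    M = np.zeros((n, n))
    D = np.zeros((n, n))
    groups: dict[int, list[int]] = {}
    for node in ptree.tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            groups[id(node)] = [i]
            M[i, i] = node_value[id(node)]
            D[i, i] = depths[node]
            continue
        children = node.child_nodes()
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                ia, ib = groups[id(children[a])], groups[id(children[b])]
                for i in ia:
                    M[i, ib] = node_value[id(node)]
                    M[ib, i] = node_value[id(node)]
                    D[i, ib] = depths[node]
                    D[ib, i] = depths[node]
        groups[id(node)] = [i for c in children for i in groups[id(c)]]
    return labels, M, D


def _sigma2_by_regime(ptree: PaintedTree, sigma2) -> dict[str, float]:
    regs = sorted(ptree.clade_map)
    if isinstance(sigma2, dict):
        missing = set(regs) - set(sigma2)
        if missing:
            raise RegimeModelError(f"sigma2 missing regimes {sorted(missing)}")
        return {r: float(sigma2[r]) for r in regs}
    return {r: float(sigma2) for r in regs}


# ---------------------------------------------------------------------------
# Covariance and expectation


def model_covariance(
    ptree: PaintedTree, model: str, params: dict
) -> tuple[list[str], np.ndarray]:
    """Tip covariance matrix implied by a model and its parameters.

    ``params``: ``sigma2`` (scalar or per-regime mapping) and, for OU
    models, ``alpha``.  BM: entries accumulate sigma^2(edge) * length over
    the shared root-to-mrca path.  OU: the variance accumulated at the
    mrca under the recursion
    ``v(end) = v(start) e^(-2 a l) + sigma^2 (1 - e^(-2 a l)) / (2 a)``
    is discounted by ``e^(-2 a (T - t_mrca))`` for the two independent
    descents to the tips.  ``alpha = 0`` reduces exactly to BM.
    """
    if model not in MODELS:
        raise RegimeModelError(f"unknown model {model!r}")
    s2 = _sigma2_by_regime(ptree, params["sigma2"])
    alpha = float(params.get("alpha", 0.0)) if model not in ("BM1", "BMS") else 0.0
    depths = ptree.node_depths()
    regimes = ptree.edge_regimes()
    v: dict[int, float] = {}
    for node in ptree.tree.preorder_node_iter():
        if node.parent_node is None:
            v[id(node)] = 0.0
            continue
        ell = float(node.edge.length)
        sig = s2[regimes[node]]
        if alpha < 1e-12:
            v[id(node)] = v[id(node.parent_node)] + sig * ell
        else:
            decay = np.exp(-2.0 * alpha * ell)
            v[id(node)] = v[id(node.parent_node)] * decay + sig * (1 - decay) / (
                2 * alpha
            )
    labels, M, D = _pairwise_mrca_values(ptree, v)
    T = max(depths[lf] for lf in ptree.tree.leaf_node_iter())
    if alpha >= 1e-12:
        M = M * np.exp(-2.0 * alpha * (T - D))
    return labels, M


def ou_weight_matrix(
    ptree: PaintedTree, alpha: float
) -> tuple[list[str], list[str], np.ndarray]:
    """Hansen optimum weights: (tip_labels, regime_labels, W).

    ``W[i, r]`` is the weight of regime r's optimum in tip i's expectation;
    each segment [t0, t1] in regime r on the root-to-tip lineage
    contributes ``e^(-a (T - t1)) - e^(-a (T - t0))`` and the residual root
    mass ``e^(-a T)`` goes to the regime of the oldest segment.  Rows sum
    to one.
    """
    if alpha <= 0:
        raise RegimeModelError("alpha must be positive for OU expectations")
    segs, T = _lineage_segments(ptree)
    regimes = sorted(ptree.clade_map)
    ridx = {r: j for j, r in enumerate(regimes)}
    labels = list(segs)
    W = np.zeros((len(labels), len(regimes)))
    for i, tip in enumerate(labels):
        for t0, t1, reg in segs[tip]:
            W[i, ridx[reg]] += np.exp(-alpha * (T - t1)) - np.exp(-alpha * (T - t0))
        W[i, ridx[segs[tip][0][2]]] += np.exp(-alpha * T)
    return labels, regimes, W


def ou_expectation(
    ptree: PaintedTree, alpha: float, theta_by_regime: dict[str, float]
) -> tuple[list[str], np.ndarray]:
    """Expected tip values under OU pull towards per-regime optima."""
    labels, regimes, W = ou_weight_matrix(ptree, alpha)
    theta = np.array([theta_by_regime[r] for r in regimes])
    return labels, W @ theta


# ---------------------------------------------------------------------------
# Fitting


def aicc(lnL: float, k: int, n: int) -> float:
    """Akaike information criterion with the small-sample correction."""
    if n <= k + 1:
        raise RegimeModelError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def _gls_profile(C: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Profiled MVN log-likelihood with V = s2 * C and mean X beta.

    Returns (lnL, beta, s2_hat) at the ML scale s2_hat = rss/n.
    """
    n = len(y)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise RegimeModelError("singular model covariance") from exc
    from scipy.linalg import solve_triangular

    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdetC = 2.0 * float(np.sum(np.log(np.diag(L))))
    if rss <= 0:
        rss = 1e-300  # degenerate perfect fit
    s2 = rss / n
    lnL = -0.5 * (n * np.log(2 * np.pi * s2) + logdetC + n)
    return float(lnL), beta, s2


def fit_trait_model(
    trait: dict[str, float], ptree: PaintedTree, model: str, n_starts: int = 5
) -> ModelFit:
    """Maximum-likelihood fit of one of the five trait models.

    Optima / root states are profiled by GLS and the variance scale
    analytically, so the numeric search is one-dimensional (ln alpha for
    OU1/OUM, a log variance ratio for BMS) or two-dimensional (OUMV),
    run from ``n_starts`` grid starts and polished with Nelder-Mead.
    """
    if model not in MODELS:
        raise RegimeModelError(f"unknown model {model!r}")
    if not ptree.is_painted:
        raise RegimeModelError("tree must be painted with regimes")
    labels = ptree.tip_labels
    missing = set(labels) - set(trait)
    if missing:
        raise RegimeModelError(f"trait missing species {sorted(missing)}")
    n = len(labels)
    k = _K[model]
    if n < 2:
        raise RegimeModelError("need at least two tips")

    def _aicc(lnL: float) -> float:
        # AICc needs n > k + 1; report NaN below that (closed-form fits on
        # tiny trees remain useful even where model comparison is not)
        return aicc(lnL, k, n) if n > k + 1 else float("nan")
    regimes = sorted(ptree.clade_map)
    ones = np.ones((n, 1))

    def order(mat_labels, M):
        idx = [mat_labels.index(s) for s in labels]
        return M[np.ix_(idx, idx)]

    y = np.array([float(trait[s]) for s in labels])

    if model == "BM1":
        ml, M = model_covariance(ptree, "BM1", {"sigma2": 1.0})
        C = order(ml, M)
        lnL, beta, s2 = _gls_profile(C, ones, y)
        return ModelFit(
            model=model, lnL=lnL, k=k, aicc=_aicc(lnL),
            sigma2={r: s2 for r in regimes}, root_state=float(beta[0]),
        )

    if model == "BMS":
        Cs = {}
        for r in regimes:
            ml, M = model_covariance(
                ptree, "BMS",
                {"sigma2": {q: 1.0 if q == r else 0.0 for q in regimes}},
            )
            Cs[r] = order(ml, M)
        rA, rB = regimes[0], regimes[1] if len(regimes) > 1 else regimes[0]

        def neg_bms(x):
            rho = np.exp(x[0])
            C = Cs[rA] + rho * Cs[rB]
            try:
                lnL, _, _ = _gls_profile(C, ones, y)
            except (RegimeModelError, np.linalg.LinAlgError, ValueError):
                return 1e10
            return -lnL if np.isfinite(lnL) else 1e10

        best = _multistart(neg_bms, [(_LN_RATIO_LO, _LN_RATIO_HI)], n_starts)
        rho = float(np.exp(best.x[0]))
        C = Cs[rA] + rho * Cs[rB]
        lnL, beta, s2 = _gls_profile(C, ones, y)
        return ModelFit(
            model=model, lnL=lnL, k=k, aicc=_aicc(lnL),
            sigma2={rA: s2, rB: s2 * rho}, root_state=float(beta[0]),
            converged=bool(best.success),
        )

    # OU models ------------------------------------------------------------
    def ou_design(alpha: float, ratio: float | None):
        s2_spec = (
            1.0 if ratio is None
            else {regimes[0]: 1.0, regimes[1]: float(ratio)}
        )
        ml, G = model_covariance(ptree, model, {"sigma2": s2_spec, "alpha": alpha})
        C = order(ml, G)
        wl, wregs, W = ou_weight_matrix(ptree, alpha)
        idx = [wl.index(s) for s in labels]
        W = W[idx]
        if model == "OU1":
            X = W.sum(axis=1, keepdims=True)  # single theta: weights sum to 1
        else:
            X = W
        return C, X, wregs

    two_d = model == "OUMV"

    def neg_ou(x):
        alpha = float(np.exp(x[0]))
        ratio = float(np.exp(x[1])) if two_d else None
        try:
            C, X, _ = ou_design(alpha, ratio)
            if not np.all(np.isfinite(C)):
                return 1e10
            lnL, _, _ = _gls_profile(C, X, y)
        except (RegimeModelError, np.linalg.LinAlgError, ValueError):
            return 1e10
        return -lnL if np.isfinite(lnL) else 1e10

    bounds = [(_LN_ALPHA_LO, _LN_ALPHA_HI)]
    if two_d:
        bounds.append((_LN_RATIO_LO, _LN_RATIO_HI))
    best = _multistart(neg_ou, bounds, n_starts)
    alpha = float(np.exp(best.x[0]))
    ratio = float(np.exp(best.x[1])) if two_d else None
    C, X, wregs = ou_design(alpha, ratio)
    lnL, beta, s2 = _gls_profile(C, X, y)
    if model == "OU1":
        theta = {r: float(beta[0]) for r in regimes}
    else:
        theta = {r: float(beta[j]) for j, r in enumerate(wregs)}
    if ratio is None:
        sigma2 = {r: s2 for r in regimes}
    else:
        sigma2 = {regimes[0]: s2, regimes[1]: s2 * ratio}
    return ModelFit(
        model=model, lnL=lnL, k=k, aicc=_aicc(lnL),
        sigma2=sigma2, alpha=alpha, theta=theta, converged=bool(best.success),
    )


def _multistart(fun, bounds, n_starts: int):
    """Nelder-Mead from a deterministic grid of starts within bounds."""
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = []
    fracs = np.linspace(0.15, 0.85, max(n_starts, 1))
    for i in range(max(n_starts, 1)):
        frac = np.full(len(bounds), fracs[i])
        if len(bounds) == 2:
            frac[1] = fracs[(i * 2 + 1) % len(fracs)]
        starts.append(lo + frac * (hi - lo))
    best = None
    for x0 in starts:
        res = optimize.minimize(
            fun, x0, method="Nelder-Mead", bounds=list(zip(lo, hi)),
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400},
        )
        res.x = np.clip(res.x, lo, hi)
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_all_models(
    trait: dict[str, float], ptree: PaintedTree, n_starts: int = 5
) -> dict[str, ModelFit]:
    return {m: fit_trait_model(trait, ptree, m, n_starts=n_starts) for m in MODELS}


# ---------------------------------------------------------------------------
# Selection


def group_means(
    trait: dict[str, float], group_map: dict[str, set[str] | frozenset[str]]
) -> dict[str, float]:
    """Arithmetic mean of the trait per regime group."""
    out = {}
    for group, species in group_map.items():
        if not species:
            raise RegimeModelError(f"group {group!r} is empty")
        missing = set(species) - set(trait)
        if missing:
            raise RegimeModelError(f"group {group!r} missing species {sorted(missing)}")
        out[group] = float(np.mean([trait[s] for s in species]))
    return out


def select_model(
    fits: dict[str, ModelFit],
    means: dict[str, float] | None = None,
    family_id: str = "",
) -> SelectionCall:
    """Apply the delta-AICc > 2 rule between the best H0 and best H1 fit.

    The alternative (two-optima) model is retained only when its AICc is
    more than 2 units below the best null model's — ties and a delta of
    exactly 2 stay with the null.  The direction of a positive call is the
    regime with the larger fitted optimum of the winning H1 model.
    """
    missing = set(MODELS) - set(fits)
    if missing:
        raise RegimeModelError(f"missing model fits {sorted(missing)}")
    h0 = min(H0_MODELS, key=lambda m: fits[m].aicc)
    h1 = min(H1_MODELS, key=lambda m: fits[m].aicc)
    delta = fits[h0].aicc - fits[h1].aicc
    positive = bool(delta > 2.0) and abs(delta - 2.0) >= 1e-9
    direction = None
    if positive:
        theta = fits[h1].theta
        if theta is None:
            raise RegimeModelError("winning H1 model lacks optima")
        direction = max(theta, key=lambda r: theta[r])
    return SelectionCall(
        family_id=family_id,
        best_h0=(h0, fits[h0].aicc),
        best_h1=(h1, fits[h1].aicc),
        delta_aicc=float(delta),
        positive=positive,
        direction=direction,
        group_means=dict(means or {}),
    )
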