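"""Phylogeny handling and the lambda-gated comparative regression.

Cross-species trait regressions are confounded when regression residuals
carry phylogenetic signal: closely related hosts are not independent
replicates, inflating type-I error. The workflow implemented here:

1. fit an ordinary least squares (OLS) regression of trait y on trait x;
2. test the OLS residuals for phylogenetic signal with Pagel's lambda --
   a multiplier on the off-diagonal of the Brownian-motion (BM) tip
   covariance, maximum-likelihood estimated on [0, 1] and compared to
   lambda = 0 by a likelihood-ratio test against chi-square(1);
3. if the signal is significant (p < alpha), accept a phylogenetically
   independent contrasts (PIC) regression through the origin instead of
   the OLS fit; otherwise accept the OLS fit. Both fits are always
   computed and retained for reporting.

Trees are handled through dendropy; branch lengths are mandatory.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import linalg, optimize, stats

log = logging.getLogger(__name__)

__all__ = [
    "LambdaResult",
    "RegressionResult",
    "GatedRegressionResult",
    "parse_newick",
    "tip_labels",
    "prune_to_taxa",
    "resolve_polytomies",
    "tip_covariance",
    "lambda_covariance",
    "lambda_loglik",
    "pagel_lambda_test",
    "pic_contrasts",
    "pic_regression",
    "ols_regression",
    "lambda_gated_regression",
]


@dataclass(frozen=True)
class LambdaResult:
    """Maximum-likelihood Pagel's lambda signal test on tip values."""

    lambda_hat: float
    loglik_hat: float
    loglik_zero: float
    p_value: float
    n_tips: int


@dataclass(frozen=True)
class RegressionResult:
    """One regression fit; ``method`` is 'linear' (OLS) or 'phylogenetic'
    (independent contrasts through the origin, intercept fixed at 0)."""

    method: str
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int
    residuals: dict[str, float] | None = None


@dataclass(frozen=True)
class GatedRegressionResult:
    """OLS and PIC fits plus the lambda gate deciding which to interpret."""

    ols: RegressionResult
    lambda_test: LambdaResult
    pic: RegressionResult | None
    accepted: str  # 'linear' or 'phylogenetic'

    @property
    def accepted_result(self) -> RegressionResult:
        return self.pic if self.accepted == "phylogenetic" else self.ols


# ---------------------------------------------------------------------------
# tree plumbing


def parse_newick(source: str | Path) -> dendropy.Tree:
    """Parse a rooted Newick tree with mandatory branch lengths.

    ``source`` is a file path or a literal Newick string. Polytomies are
    permitted at parse time (PIC resolves them later); missing branch
    lengths on non-root edges are an error -- no default is substituted.
    """
    text = None
    path = Path(str(source))
    try:
        if path.is_file():
            text = path.read_text()
    except OSError:
        pass
    if text is None:
        text = str(source)
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise ValueError(f"malformed Newick input: {exc}") from exc
    labels = tip_labels(tree)
    if len(labels) != len(set(labels)):
        raise ValueError("tip labels must be unique")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError(
                f"missing branch length on edge above "
                f"{edge.head_node.taxon.label if edge.head_node.taxon else 'an internal node'}"
            )
        if edge.length < 0:
            raise ValueError("negative branch length")
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune_to_taxa(tree: dendropy.Tree, taxa: Sequence[str]) -> dendropy.Tree:
    """Induced subtree on ``taxa``, preserving pairwise tip path lengths.

    Degree-2 nodes created by pruning are collapsed by summing branch
    lengths, so distances between retained tips match the original tree
    exactly. Names absent from the tree are reported and ignored.
    """
    taxa = set(taxa)
    present = set(tip_labels(tree))
    missing = sorted(taxa - present)
    if missing:
        log.warning("%d taxa not in tree (ignored): %s", len(missing),
                    ", ".join(missing[:5]) + ("..." if len(missing) > 5 else ""))
    keep = sorted(taxa & present)
    if len(keep) < 3:
        raise ValueError(
            f"pruning retains {len(keep)} tips; >= 3 required for comparative analysis"
        )
    if keep == sorted(present):
        return tree.clone(depth=1)
    return tree.extract_tree_with_taxa_labels(labels=keep)


def resolve_polytomies(
    tree: dendropy.Tree, seed: int = 0, epsilon: float = 1e-8
) -> dendropy.Tree:
    """Deterministically (seeded) resolve polytomies to bifurcations with
    zero-length internal branches.

    Zero-length internal branches are harmless for contrasts (the pruning
    variance accumulated below keeps denominators positive), so they are
    left exact; only a degenerate cherry of two zero-length *leaf*
    branches gets ``epsilon`` substituted, as its contrast variance would
    otherwise vanish."""
    out = tree.clone(depth=1)
    out.resolve_polytomies(limit=2, update_bipartitions=False,
                           rng=_random.Random(seed))
    for node in out.preorder_node_iter():
        children = node.child_nodes()
        if len(children) == 2 and all(
            c.is_leaf() and (c.edge.length or 0.0) == 0.0 for c in children
        ):
            for c in children:
                c.edge.length = epsilon
    return out


# ---------------------------------------------------------------------------
# covariance and Pagel's lambda


def tip_covariance(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion tip covariance: C[i, j] is the root-to-MRCA path
    length of tips i and j; the diagonal holds root-to-tip distances.
    Tips are ordered by sorted label."""
    labels = sorted(tip_labels(tree))
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    cov = np.zeros((n, n))
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    tips_below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            cov[i, i] = depth[id(node)]
            tips_below[id(node)] = [i]
        else:
            groups = [tips_below.pop(id(c)) for c in node.child_nodes()]
            d = depth[id(node)]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    block = np.ix_(groups[gi], groups[gj])
                    cov[block] = d
                    cov[block[1], block[0]] = d
            tips_below[id(node)] = [t for g in groups for t in g]
    return labels, cov


def lambda_covariance(
    tree: dendropy.Tree, lam: float
) -> tuple[list[str], np.ndarray]:
    """Pagel's lambda transform: off-diagonal shared path lengths scaled by
    ``lam``, diagonal (tip heights) unchanged. Valid for non-ultrametric
    trees; ``lam`` must lie in [0, 1]."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    labels, cov = tip_covariance(tree)
    out = lam * cov
    np.fill_diagonal(out, np.diag(cov))
    return labels, out


def _profiled_loglik(cov: np.ndarray, y: np.ndarray) -> float:
    """Gaussian log-likelihood with mean and rate profiled analytically:
    mu_hat = (1'C^-1 y)/(1'C^-1 1), sigma2_hat = r'C^-1 r / n."""
    n = y.size
    cho = linalg.cho_factor(cov, lower=True)
    ones = np.ones(n)
    ci_y = linalg.cho_solve(cho, y)
    ci_1 = linalg.cho_solve(cho, ones)
    mu = float(ones @ ci_y) / float(ones @ ci_1)
    resid = y - mu
    sigma2 = float(resid @ linalg.cho_solve(cho, resid)) / n
    logdet = 2.0 * float(np.log(np.diag(cho[0])).sum())
    return -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)


def lambda_loglik(
    tree: dendropy.Tree, values: Mapping[str, float], lam: float
) -> float:
    """Profile log-likelihood of tip ``values`` at a fixed lambda."""
    labels, base = tip_covariance(tree)
    y = np.array([values[lab] for lab in labels], dtype=float)
    return _lambda_loglik_from_cov(base, y, lam)


def _lambda_loglik_from_cov(base: np.ndarray, y: np.ndarray, lam: float) -> float:
    cov = lam * base
    np.fill_diagonal(cov, np.diag(base))
    try:
        return _profiled_loglik(cov, y)
    except linalg.LinAlgError as exc:
        raise ValueError(f"non-finite likelihood at lambda={lam}") from exc


def pagel_lambda_test(
    tree: dendropy.Tree, values: Mapping[str, float]
) -> LambdaResult:
    """ML Pagel's lambda on [0, 1] with a likelihood-ratio test vs lambda=0.

    The tree is pruned to the taxa present in ``values``; the likelihood
    profiles mean and rate analytically and optimizes the single lambda
    parameter by bounded 1-D search, with both endpoints checked so a
    boundary maximum is never missed. The LR statistic 2(l_hat - l_0) is
    referred to chi-square with 1 df (no boundary mixture; conservative).
    """
    shared = sorted(set(tip_labels(tree)) & set(values))
    if len(shared) < 3:
        raise ValueError("lambda test requires >= 3 taxa shared by tree and data")
    if len(shared) < len(tip_labels(tree)):
        tree = prune_to_taxa(tree, shared)
    labels, base = tip_covariance(tree)
    y = np.array([values[lab] for lab in labels], dtype=float)
    if np.ptp(y) == 0.0:
        raise ValueError("tip values have zero variance")

    def neg(lam: float) -> float:
        return -_lambda_loglik_from_cov(base, y, float(lam))

    opt = optimize.minimize_scalar(
        neg, bounds=(0.0, 1.0), method="bounded",
        options={"xatol": 1e-8},
    )
    candidates = [(0.0, -neg(0.0)), (1.0, -neg(1.0)), (float(opt.x), -float(opt.fun))]
    lam_hat, ll_hat = max(candidates, key=lambda c: c[1])
    ll_zero = candidates[0][1]
    lr = max(2.0 * (ll_hat - ll_zero), 0.0)
    p = float(stats.chi2.sf(lr, df=1))
    return LambdaResult(
        lambda_hat=lam_hat,
        loglik_hat=ll_hat,
        loglik_zero=ll_zero,
        p_value=p,
        n_tips=len(labels),
    )


# ---------------------------------------------------------------------------
# independent contrasts


def _pic_core(
    tree: dendropy.Tree, traits: list[Mapping[str, float]]
) -> list[np.ndarray]:
    """Felsenstein pruning on a bifurcating tree for one or more traits
    sharing the same branch-length adjustments. Returns one contrast
    vector per trait, in postorder internal-node order."""
    work = tree.clone(depth=1)
    tips = tip_labels(work)
    for values in traits:
        missing = sorted(set(tips) - set(values))
        if missing:
            raise ValueError(f"missing trait values for tips: {missing[:5]}")
    contrasts: list[list[float]] = [[] for _ in traits]
    state: dict[int, tuple[list[float], float]] = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            xs = [float(v[node.taxon.label]) for v in traits]
            state[id(node)] = (xs, float(node.edge.length or 0.0))
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError(
                f"node with {len(children)} children: resolve polytomies first "
                "(see resolve_polytomies)"
            )
        (x1, v1), (x2, v2) = (state.pop(id(c)) for c in children)
        vsum = v1 + v2
        if vsum <= 0.0:
            raise ValueError("both child branch lengths are zero at a contrast node")
        for k in range(len(traits)):
            contrasts[k].append((x1[k] - x2[k]) / np.sqrt(vsum))
        anc = [(x1[k] / v1 + x2[k] / v2) / (1.0 / v1 + 1.0 / v2)
               if v1 > 0 and v2 > 0 else
               (x1[k] if v2 == 0 else x2[k])
               for k in range(len(traits))]
        edge = float(node.edge.length or 0.0) if node is not work.seed_node else 0.0
        state[id(node)] = (anc, edge + (v1 * v2) / vsum)
    return [np.asarray(c) for c in contrasts]


def pic_contrasts(
    tree: dendropy.Tree, values: Mapping[str, float]
) -> np.ndarray:
    """Standardized independent contrasts: at each internal node of a
    bifurcating tree, (x1 - x2) / sqrt(v1 + v2), with ancestral values
    formed as precision-weighted averages and parent branches lengthened
    by v1 v2 / (v1 + v2). Returns n_tips - 1 contrasts in deterministic
    postorder."""
    return _pic_core(tree, [values])[0]


def pic_regression(
    tree: dendropy.Tree, x: Mapping[str, float], y: Mapping[str, float]
) -> RegressionResult:
    """Contrasts of y regressed on contrasts of x through the origin.

    x-contrasts are sign-positivized (with matching y sign flips, to which
    the through-origin fit is invariant); r is the uncentered correlation
    sum(uv)/sqrt(sum(u^2) sum(v^2)) with a two-tailed t test on
    n_contrasts - 1 degrees of freedom."""
    u, v = _pic_core(tree, [x, y])
    flip = np.where(u < 0, -1.0, 1.0)
    u, v = u * flip, v * flip
    suu = float(u @ u)
    svv = float(v @ v)
    if suu == 0.0 or svv == 0.0:
        raise ValueError("zero contrast variance; cannot regress")
    suv = float(u @ v)
    r = suv / np.sqrt(suu * svv)
    slope = suv / suu
    k = u.size
    df = k - 1
    if df < 1:
        raise ValueError("need at least 2 contrasts for a p-value")
    r_clip = min(max(r, -1.0), 1.0)
    if abs(r_clip) >= 1.0:
        p = 0.0
    else:
        t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return RegressionResult(
        method="phylogenetic", r=float(r_clip), p_value=p,
        slope=float(slope), intercept=0.0, n=k,
    )


# ---------------------------------------------------------------------------
# OLS and the gate


def ols_regression(
    x: Sequence[float], y: Sequence[float], taxa: Sequence[str] | None = None
) -> RegressionResult:
    """Ordinary least squares of y on x with Pearson r and a two-tailed t
    test on n - 2 degrees of freedom; residuals are retrievable keyed by
    taxon when taxon names are supplied."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need n >= 3 observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values must be dropped before regression")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero variance in x or y")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    residuals = None
    if taxa is not None:
        if len(taxa) != x.size:
            raise ValueError("taxa must match data length")
        residuals = {str(t): float(e) for t, e in zip(taxa, resid)}
    return RegressionResult(
        method="linear", r=float(fit.rvalue), p_value=float(fit.pvalue),
        slope=float(fit.slope), intercept=float(fit.intercept),
        n=int(x.size), residuals=residuals,
    )


def lambda_gated_regression(
    tree: dendropy.Tree,
    x: Mapping[str, float],
    y: Mapping[str, float],
    alpha: float = 0.05,
    seed: int = 0,
) -> GatedRegressionResult:
    """The full comparative workflow: OLS, Pagel's lambda on its residuals,
    PIC, and the accept rule (phylogenetic iff lambda p < alpha).

    Taxa are intersected across tree, x and y; the tree is pruned to the
    intersection (data prune the tree, never vice versa). Polytomies are
    resolved deterministically before contrasts.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    shared = sorted(set(tip_labels(tree)) & set(x) & set(y))
    if len(shared) < 3:
        raise ValueError("gated regression requires >= 3 shared taxa")
    pruned = prune_to_taxa(tree, shared)
    xv = [float(x[t]) for t in shared]
    yv = [float(y[t]) for t in shared]
    ols = ols_regression(xv, yv, taxa=shared)
    lam = pagel_lambda_test(pruned, ols.residuals)
    resolved = resolve_polytomies(pruned, seed=seed)
    pic = pic_regression(resolved, x, y)
    accepted = "phylogenetic" if lam.p_value < alpha else "linear"
    return GatedRegressionResult(ols=ols, lambda_test=lam, pic=pic, accepted=accepted)
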