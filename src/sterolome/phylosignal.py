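"""Tree preparation and phylogenetic-signal estimation for sterol traits.

Both signal statistics assume a Brownian-motion null on a rooted,
branch-length-bearing tree with phylogenetic covariance C (C[i, j] = shared
root-to-MRCA path length).

Blomberg's K compares the observed ratio of tip variance to
phylogenetically corrected variance with its Brownian expectation:

    K = (MSE0 / MSE) / [(tr(C) - n / (1' C^-1 1)) / (n - 1)]

with phylogenetic mean a = (1' C^-1 z) / (1' C^-1 1),
MSE0 = (z - a)'(z - a) / (n - 1) and MSE = (z - a)' C^-1 (z - a) / (n - 1).
K = 1 under Brownian motion; the permutation p-value shuffles trait values
across tips.

Pagel's lambda rescales the off-diagonal of C by a factor in [0, lambda_max]
(diagonal fixed) and maximises the multivariate-normal likelihood with the
Brownian rate sigma^2 profiled out; lambda = 0 means the trait is
independent of phylogeny, lambda = 1 recovers plain Brownian motion. The
reported p-value is a likelihood-ratio test against lambda = 0 on a chi^2_1
reference (optionally the 50:50 boundary mixture).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .exceptions import DegenerateInputError, SterolomeError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Tree preparation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenameRule:
    """One tip-relabelling rule used to place a study taxon on the tree.

    ``kind`` records why the rename is valid: a synonym, a species-level
    stand-in for a subspecies, a parent of a hybrid, or a congeneric
    substitute. Congener substitution is only honoured when the genus has
    no correctly matched species already.
    """

    source_tip: str
    target_taxon: str
    kind: str = "synonym"

    _KINDS = ("synonym", "subspecies-to-species", "hybrid-to-parent",
              "congener-substitute")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise SterolomeError(f"unknown rename rule kind {self.kind!r}")


def _genus(name: str) -> str:
    return name.replace("_", " ").split()[0]


def prune_and_match(
    tree: dendropy.Tree,
    taxa: list[str],
    rules: list[RenameRule] | None = None,
) -> tuple[dendropy.Tree, list[str]]:
    """Apply rename rules in order, then prune the tree to the study taxa.

    Returns the pruned tree and the list of taxa that could not be placed.
    A congener-substitute rule is refused (taxon left unplaced) when its
    genus already holds a directly matched species.
    """
    tree = tree.clone(depth=1)
    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    requested = list(taxa)
    matched_genera = {_genus(t) for t in requested if t in tips}

    for rule in rules or []:
        if rule.source_tip not in tips:
            raise SterolomeError(
                f"rename rule references non-existent tip {rule.source_tip!r}"
            )
        if rule.target_taxon not in requested:
            logger.warning(
                "rename rule target %r is not a study taxon; skipped",
                rule.target_taxon,
            )
            continue
        if rule.target_taxon in tips:
            continue  # already directly matched
        if (
            rule.kind == "congener-substitute"
            and _genus(rule.target_taxon) in matched_genera
        ):
            logger.info(
                "congener substitution for %s refused: genus already matched",
                rule.target_taxon,
            )
            continue
        leaf = tips.pop(rule.source_tip)
        leaf.taxon.label = rule.target_taxon
        tips[rule.target_taxon] = leaf
        matched_genera.add(_genus(rule.target_taxon))

    placed = [t for t in requested if t in tips]
    unplaced = [t for t in requested if t not in tips]
    if len(placed) < 3:
        raise SterolomeError(f"fewer than 3 taxa placed on tree ({len(placed)})")
    keep = set(placed)
    tree.retain_taxa_with_labels(list(keep))
    tree.purge_taxon_namespace()
    return tree, unplaced


def check_monophyly(
    tree: dendropy.Tree, grouping: dict[str, str]
) -> dict[str, str]:
    """Classify each group as monophyletic / not_monophyletic / singleton.

    ``grouping`` maps every tip label to its group (e.g. family). A group
    is monophyletic when the smallest clade containing its tips contains
    no other tips.
    """
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    unmapped = [lab for lab in labels if lab not in grouping]
    if unmapped:
        raise SterolomeError(f"tips without a group mapping: {unmapped}")
    members: dict[str, list[str]] = {}
    for lab in labels:
        members.setdefault(grouping[lab], []).append(lab)
    result = {}
    for group, labs in members.items():
        if len(labs) == 1:
            result[group] = "singleton"
            continue
        mrca = tree.mrca(taxon_labels=labs)
        clade_size = sum(1 for _ in mrca.leaf_iter())
        result[group] = (
            "monophyletic" if clade_size == len(labs) else "not_monophyletic"
        )
    return result


def phylo_vcv(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Phylogenetic variance-covariance matrix.

    C[i, j] is the shared root-to-MRCA path length of tips i and j;
    C[i, i] the root-to-tip distance. Returns (tip labels, C).
    """
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    n = len(leaves)
    index = {id(leaf): i for i, leaf in enumerate(leaves)}

    # path lengths are measured from the root node; any stem edge above
    # the root is ignored
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length
        if length is None:
            length = 0.0
        if length < 0:
            raise SterolomeError(f"negative branch length {length}")
        depth[id(node)] = depth[id(node.parent_node)] + length

    c = np.zeros((n, n))
    # postorder: tips below each internal node; pairs across child subtrees
    # share that node as MRCA
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            below[id(node)] = [i]
            c[i, i] = depth[id(node)]
            continue
        child_sets = [below.pop(id(ch)) for ch in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    for j in child_sets[b]:
                        c[i, j] = c[j, i] = d
        merged: list[int] = []
        for s in child_sets:
            merged.extend(s)
        below[id(node)] = merged
    return labels, c


# ---------------------------------------------------------------------------
# Signal statistics
# ---------------------------------------------------------------------------

def _align_trait(
    tree_or_vcv, trait: pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(tree_or_vcv, tuple):
        labels, c = tree_or_vcv
    else:
        labels, c = phylo_vcv(tree_or_vcv)
    missing = [lab for lab in labels if lab not in trait.index]
    if missing:
        raise SterolomeError(f"trait values missing for tips: {missing}")
    z = trait.loc[labels].to_numpy(dtype=float)
    return z, c


def _phylo_gls(z: np.ndarray, c: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Phylogenetic mean, residuals and GLS quadratic form under covariance c."""
    cf = cho_factor(c, lower=True)
    ones = np.ones(len(z))
    ci1 = cho_solve(cf, ones)
    a_hat = float(ci1 @ z) / float(ci1 @ ones)
    resid = z - a_hat
    quad = float(resid @ cho_solve(cf, resid))
    return a_hat, resid, quad


def blomberg_k(
    tree_or_vcv,
    trait: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float | None]:
    """Blomberg's K with a tip-shuffling permutation p-value.

    Returns (K, p); p is None when ``n_permutations`` is 0. K = 1 is the
    Brownian expectation; K is invariant to affine transforms of the
    trait.
    """
    z, c = _align_trait(tree_or_vcv, trait)
    n = len(z)
    if np.allclose(z, z[0]):
        raise DegenerateInputError("constant trait: K undefined")

    cf = cho_factor(c, lower=True)
    ones = np.ones(n)
    ci1 = cho_solve(cf, ones)
    denom_expect = (np.trace(c) - n / float(ci1 @ ones)) / (n - 1)

    def k_of(zv: np.ndarray) -> float:
        a_hat = float(ci1 @ zv) / float(ci1 @ ones)
        resid = zv - a_hat
        mse0 = float(resid @ resid) / (n - 1)
        mse = float(resid @ cho_solve(cf, resid)) / (n - 1)
        return (mse0 / mse) / denom_expect

    k_obs = k_of(z)
    if n_permutations <= 0:
        return k_obs, None
    rng = np.random.default_rng(seed)
    hits = sum(
        k_of(rng.permutation(z)) >= k_obs for _ in range(n_permutations)
    )
    return k_obs, (1 + hits) / (1 + n_permutations)


def _lambda_cov(c: np.ndarray, lam: float) -> np.ndarray:
    out = c * lam
    np.fill_diagonal(out, np.diag(c))
    return out


def _lambda_max(c: np.ndarray, upper: float = 3.0) -> float:
    """Largest off-diagonal multiplier keeping C(lambda) positive definite,
    found by bisection (at least 1 for any valid C)."""

    def pd_ok(lam: float) -> bool:
        try:
            cho_factor(_lambda_cov(c, lam), lower=True)
            return True
        except np.linalg.LinAlgError:
            return False

    if pd_ok(upper):
        return upper
    lo, hi = 1.0, upper
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if pd_ok(mid):
            lo = mid
        else:
            hi = mid
    return lo


def _lambda_loglik(z: np.ndarray, c: np.ndarray, lam: float) -> float:
    """Profile log-likelihood of lambda (phylogenetic mean and Brownian
    rate profiled out)."""
    n = len(z)
    v = _lambda_cov(c, lam)
    try:
        cf = cho_factor(v, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    ones = np.ones(n)
    ci1 = cho_solve(cf, ones)
    a_hat = float(ci1 @ z) / float(ci1 @ ones)
    resid = z - a_hat
    sigma2 = float(resid @ cho_solve(cf, resid)) / n
    if sigma2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


@dataclass
class LambdaResult:
    lambda_hat: float
    loglik: float
    loglik_zero: float
    p_value: float
    lambda_max: float
    capped_display: float  # lambda_hat clipped at 1 for reporting


def pagel_lambda(
    tree_or_vcv,
    trait: pd.Series,
    boundary_correction: bool = False,
    tol: float = 1e-6,
) -> LambdaResult:
    """Maximum-likelihood Pagel's lambda with a likelihood-ratio test
    against lambda = 0.

    lambda ranges over [0, lambda_max] where lambda_max is the largest
    multiplier keeping the rescaled covariance positive definite
    (computed from the tree, not fixed at 1). With
    ``boundary_correction`` the LRT p-value uses the 50:50 chi^2_0/chi^2_1
    mixture appropriate to a boundary null; the default is plain chi^2_1.
    """
    z, c = _align_trait(tree_or_vcv, trait)
    if np.allclose(z, z[0]):
        raise DegenerateInputError("constant trait: lambda undefined")
    lam_max = _lambda_max(c)
    neg = lambda lam: -_lambda_loglik(z, c, lam)
    res = minimize_scalar(
        neg, bounds=(0.0, lam_max), method="bounded",
        options={"xatol": tol},
    )
    lam_hat = float(res.x)
    ll_hat = -float(res.fun)
    # the bounded optimiser never evaluates the exact endpoints; snap to
    # whichever endpoint does at least as well
    for endpoint in (0.0, lam_max):
        ll_end = _lambda_loglik(z, c, endpoint)
        if ll_end >= ll_hat:
            lam_hat, ll_hat = endpoint, ll_end
    ll0 = _lambda_loglik(z, c, 0.0)
    lrt = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lrt, 1))
    if boundary_correction:
        p = 0.5 * p if lrt > 0 else 1.0
    return LambdaResult(
        lambda_hat=lam_hat,
        loglik=ll_hat,
        loglik_zero=ll0,
        p_value=p,
        lambda_max=lam_max,
        capped_display=min(lam_hat, 1.0),
    )


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def signal_screen(
    profiles: pd.DataFrame,
    tree: dendropy.Tree,
    totals: pd.Series | None = None,
    class_tables: dict[str, pd.DataFrame] | None = None,
    min_max_proportion: float = 0.01,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Blomberg's K and ML Pagel's lambda for every screened sterol trait.

    Traits are per-sterol proportions (0-1, untransformed) passing the
    maximum-proportion > ``min_max_proportion`` filter, the total sterol
    content in mg/kg (always screened), and any class-sum tables supplied
    (e.g. carbon-count and B-ring-class proportions). Rows of ``profiles``
    must be tree tips; tips absent from the profile table are pruned.
    """
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    shared = [t for t in profiles.index if t in labels]
    if len(shared) < 3:
        raise SterolomeError("fewer than 3 tips overlap the profile table")
    if len(shared) < len(labels):
        tree = tree.clone(depth=1)
        tree.retain_taxa_with_labels(shared)
        tree.purge_taxon_namespace()
    vcv = phylo_vcv(tree)

    traits: dict[str, pd.Series] = {}
    for sterol in profiles.columns:
        col = profiles.loc[shared, sterol]
        if col.max() > min_max_proportion:
            traits[sterol] = col
        else:
            logger.info(
                "signal screen: %s max proportion %.4f <= %.2f%%; excluded",
                sterol, col.max(), 100 * min_max_proportion,
            )
    if totals is not None:
        traits["total_mg_kg"] = totals.loc[shared]
    for prefix, table in (class_tables or {}).items():
        for col in table.columns:
            traits[f"{prefix}:{col}"] = table.loc[shared, col]

    rng = np.random.default_rng(seed)
    rows = []
    for name, trait in traits.items():
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            k, p_k = blomberg_k(
                vcv, trait, n_permutations=n_permutations, seed=sub_seed
            )
            lam = pagel_lambda(vcv, trait)
        except DegenerateInputError:
            logger.warning("signal screen: %s is constant; skipped", name)
            continue
        rows.append(
            {
                "trait": name,
                "K": k,
                "p_K": p_k,
                "lambda": lam.lambda_hat,
                "lambda_display": lam.capped_display,
                "p_lambda": lam.p_value,
                "n_tips": len(trait),
                "seed": sub_seed,
            }
        )
    return pd.DataFrame(rows)
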