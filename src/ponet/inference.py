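"""Per-algorithm gene-pair dependency scoring on the replicated PO dataset.

Each scorer consumes a POProfile (genes x all replicate samples, stages in
developmental order) and emits a ScoreTable: a square gene x gene matrix of
non-negative dependence scores, higher = stronger. Correlation, CLR, ARACNE
and shrinkage partial correlation are symmetric; quantile-bin eta-squared
(ANOVA-style) and tree-ensemble importance score ordered regulator->target
pairs and are kept asymmetric so that the consensus stage can orient edges.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.ensemble import ExtraTreesRegressor

from .errors import ConfigError
from .expression import POProfile

log = logging.getLogger(__name__)


@dataclass
class ScoreTable:
    """Gene-pair scores from one inference method.

    ``scores.loc[i, j]`` is the score of the ordered pair i->j; symmetric
    methods satisfy scores[i, j] == scores[j, i]. The diagonal is zero by
    convention (no self-pairs). ``sign`` optionally carries the sign of the
    underlying association for methods that have one.
    """

    method: str
    symmetric: bool
    scores: pd.DataFrame
    sign: pd.DataFrame | None = None

    def __post_init__(self):
        m = self.scores.to_numpy()
        if not np.isfinite(m).all():
            raise ConfigError(f"{self.method}: non-finite scores")
        np.fill_diagonal(self.scores.values, 0.0)
        if self.symmetric and not np.allclose(m, m.T):
            raise ConfigError(f"{self.method}: symmetric table is not symmetric")

    @property
    def genes(self) -> pd.Index:
        return self.scores.index

    def pair_score(self, i, j) -> float:
        """Pair-level (orientation-free) score: max over the two orientations."""
        return float(max(self.scores.loc[i, j], self.scores.loc[j, i]))


@dataclass
class MIMatrix:
    """Pairwise plug-in mutual information (bits); diagonal holds H(X)."""

    mi: pd.DataFrame
    n_bins: int
    binning: str = "equal-frequency"

    def __post_init__(self):
        m = self.mi.to_numpy()
        if not np.allclose(m, m.T):
            raise ConfigError("MI matrix must be symmetric")
        if (m < -1e-12).any():
            raise ConfigError("MI must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.mi.index


def _po_matrix(po: POProfile) -> tuple[np.ndarray, pd.Index]:
    x = po.sample_matrix()
    return x, po.genes


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def correlation_scores(po: POProfile, method: str = "pearson") -> ScoreTable:
    """|Pearson| or |Spearman| correlation across all replicate PO samples.

    Zero-variance genes score 0 against everything (with a warning); the sign
    of the correlation is retained as an auxiliary matrix.
    """
    x, genes = _po_matrix(po)
    if x.shape[1] < 3:
        raise ConfigError("correlation requires >=3 samples")
    if method == "spearman":
        x = st.rankdata(x, axis=1)
    elif method != "pearson":
        raise ConfigError(f"unknown correlation method {method!r}")
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance genes scored 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[np.isnan(r)] = 0.0
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.fill_diagonal(r, 0.0)
    return ScoreTable(
        method=method,
        symmetric=True,
        scores=pd.DataFrame(np.abs(r), index=genes, columns=genes),
        sign=pd.DataFrame(np.sign(r), index=genes, columns=genes),
    )


# ---------------------------------------------------------------------------
# quantile-bin eta-squared (ANOVA-style dependence)
# ---------------------------------------------------------------------------

def _quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin ids; adjacent bins merged (with a warning) when a
    bin ends up with fewer than 2 members."""
    n = values.size
    order = np.argsort(values, kind="mergesort")
    ids = np.empty(n, dtype=int)
    ids[order] = np.minimum((np.arange(n) * n_bins) // n, n_bins - 1)
    # merge undersized bins into their left neighbour
    while True:
        uniq, counts = np.unique(ids, return_counts=True)
        small = uniq[counts < 2]
        if small.size == 0 or uniq.size == 1:
            break
        b = small[0]
        target = uniq[uniq < b].max() if (uniq < b).any() else uniq[uniq > b].min()
        ids[ids == b] = target
        warnings.warn(f"quantile bin {b} had <2 members; merged")
    # relabel contiguously
    _, ids = np.unique(ids, return_inverse=True)
    return ids


def anova_eta_scores(po: POProfile, n_bins: int = 4) -> ScoreTable:
    """eta^2 of gene j's PO grouped by quantile bins of gene i's PO.

    score[i, j] measures how well i's level predicts j; the table is kept
    asymmetric so directionality can use it, and the consensus stage
    symmetrises by the better orientation.
    """
    x, genes = _po_matrix(po)
    n_genes, n = x.shape
    if n < 2 * n_bins:
        raise ConfigError("need >= 2*n_bins samples for eta-squared scoring")
    sc = np.zeros((n_genes, n_genes))
    totals = x.sum(axis=1)
    ss_tot = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    for i in range(n_genes):
        ids = _quantile_bins(x[i], n_bins)
        k = ids.max() + 1
        counts = np.bincount(ids, minlength=k).astype(float)
        # group sums for all target genes at once: (k x n) indicator @ (n x g)
        group_sums = np.zeros((k, n_genes))
        np.add.at(group_sums, ids, x.T)
        ss_between = (group_sums ** 2 / counts[:, None]).sum(axis=0) - totals ** 2 / n
        with np.errstate(invalid="ignore", divide="ignore"):
            eta2 = np.where(ss_tot > 0, ss_between / ss_tot, 0.0)
        sc[i] = np.clip(eta2, 0.0, 1.0)
    np.fill_diagonal(sc, 0.0)
    return ScoreTable("anova", False, pd.DataFrame(sc, index=genes, columns=genes))


# ---------------------------------------------------------------------------
# mutual information and its derivatives
# ---------------------------------------------------------------------------

def mutual_information(po: POProfile, n_bins: int | None = None) -> MIMatrix:
    """Plug-in MI (bits) from equal-frequency binned 2-D histograms.

    Default bin count is ceil(sqrt(n_samples)); the diagonal stores the
    binned marginal entropy H(X).
    """
    x, genes = _po_matrix(po)
    n_genes, n = x.shape
    if n < 8:
        raise ConfigError("MI estimation requires >=8 samples")
    if n_bins is None:
        n_bins = int(np.ceil(np.sqrt(n)))
    if n_bins > n:
        raise ConfigError(f"n_bins={n_bins} exceeds sample count {n}")
    ids = np.vstack([_quantile_bins(row, n_bins) for row in x])
    k = int(ids.max()) + 1
    marg = np.zeros((n_genes, k))
    for g in range(n_genes):
        marg[g] = np.bincount(ids[g], minlength=k) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.nansum(np.where(marg > 0, marg * np.log2(marg), 0.0), axis=1)
    mi = np.zeros((n_genes, n_genes))
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            joint = np.bincount(ids[i] * k + ids[j], minlength=k * k).reshape(k, k) / n
            nz = joint > 0
            hij = -(joint[nz] * np.log2(joint[nz])).sum()
            mi[i, j] = mi[j, i] = max(h[i] + h[j] - hij, 0.0)
    np.fill_diagonal(mi, h)
    return MIMatrix(pd.DataFrame(mi, index=genes, columns=genes), n_bins)


def clr_transform(mi: MIMatrix) -> ScoreTable:
    """Context-likelihood-of-relatedness scores from an MI matrix.

    Each MI value is z-scored against the off-diagonal background of its two
    rows (sigma=0 rows give z=0) and the two rectified z-scores are combined
    as sqrt(max(0,z_i)^2 + max(0,z_j)^2).
    """
    m = mi.mi.to_numpy().copy()
    n = m.shape[0]
    off = ~np.eye(n, dtype=bool)
    mu = np.array([m[i, off[i]].mean() for i in range(n)])
    sd = np.array([m[i, off[i]].std() for i in range(n)])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (m - mu[:, None]) / sd[:, None]
    z[sd == 0, :] = 0.0
    z = np.maximum(z, 0.0)
    score = np.sqrt(z ** 2 + z.T ** 2)
    np.fill_diagonal(score, 0.0)
    return ScoreTable("clr", True, pd.DataFrame(score, index=mi.genes, columns=mi.genes))


def aracne_prune(mi: MIMatrix, epsilon: float = 0.0) -> ScoreTable:
    """Data-processing-inequality pruning of an MI matrix.

    For every triangle (i, j, k) the edge (i, j) is removed when
    MI_ij < min(MI_ik, MI_jk) * (1 - epsilon); removals are marked against
    the original matrix, surviving edges keep their MI as score.
    """
    if not (0.0 <= epsilon < 1.0):
        raise ConfigError("epsilon must be in [0, 1)")
    m = mi.mi.to_numpy().copy()
    np.fill_diagonal(m, 0.0)
    n = m.shape[0]
    removed = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            others = np.minimum(m[i], m[j]) * (1.0 - epsilon)
            others[i] = others[j] = -np.inf
            if m[i, j] < others.max():
                removed[i, j] = removed[j, i] = True
    out = np.where(removed, 0.0, m)
    return ScoreTable("aracne", True, pd.DataFrame(out, index=mi.genes, columns=mi.genes))


# ---------------------------------------------------------------------------
# shrinkage partial correlation
# ---------------------------------------------------------------------------

def partial_correlation_shrinkage(po: POProfile, shrinkage: float | None = None) -> ScoreTable:
    """|partial correlation| from a correlation matrix shrunk toward the
    identity (diagonal target), inverted to the precision scale.

    The shrinkage intensity is the analytic Schaefer-Strimmer estimate
    lambda* = sum Var(r_ij) / sum r_ij^2 unless forced via ``shrinkage``; a
    floor is applied (with a warning) when zero shrinkage leaves the matrix
    singular.
    """
    x, genes = _po_matrix(po)
    n_genes, n = x.shape
    if n < 4:
        raise ConfigError("partial correlation requires >=4 samples")
    sd = x.std(axis=1, ddof=1)
    xs = (x - x.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    r = (xs @ xs.T) / (n - 1)
    np.fill_diagonal(r, 1.0)
    if shrinkage is None:
        # Var(r_ij) via the empirical variance of the per-sample products
        w = np.einsum("ik,jk->ijk", xs, xs)
        w_bar = w.mean(axis=2)
        var_r = n / (n - 1) ** 3 * ((w - w_bar[:, :, None]) ** 2).sum(axis=2)
        off = ~np.eye(n_genes, dtype=bool)
        denom = (r[off] ** 2).sum()
        lam = float(var_r[off].sum() / denom) if denom > 0 else 1.0
        lam = min(max(lam, 0.0), 1.0)
    else:
        lam = float(shrinkage)
    r_shrunk = (1.0 - lam) * r
    np.fill_diagonal(r_shrunk, 1.0)
    try:
        prec = np.linalg.inv(r_shrunk)
    except np.linalg.LinAlgError:
        warnings.warn("singular correlation matrix at requested shrinkage; applying floor 1e-3")
        r_shrunk = (1.0 - 1e-3) * r
        np.fill_diagonal(r_shrunk, 1.0)
        prec = np.linalg.inv(r_shrunk)
    d = np.sqrt(np.diag(prec))
    pcor = -prec / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    pcor = (pcor + pcor.T) / 2.0
    return ScoreTable(
        "pcor", True,
        pd.DataFrame(np.abs(pcor), index=genes, columns=genes),
        sign=pd.DataFrame(np.sign(pcor), index=genes, columns=genes),
    )


# ---------------------------------------------------------------------------
# tree-ensemble importance (GENIE3-style)
# ---------------------------------------------------------------------------

def tree_ensemble_importance(po: POProfile, n_trees: int = 100, seed: int = 0) -> ScoreTable:
    """Randomised-tree regression importance of every gene for every target.

    For each target gene the remaining genes are used as predictors in an
    extremely-randomised-trees regression; score[regulator, target] is the
    normalised total impurity reduction attributed to the regulator, so
    importances for each target sum to 1 (0 for constant targets).
    """
    x, genes = _po_matrix(po)
    n_genes, n = x.shape
    if n < 8:
        raise ConfigError("tree-ensemble scoring requires >=8 samples")
    if n_genes < 3:
        raise ConfigError("need at least 2 candidate regulators per target")
    sc = np.zeros((n_genes, n_genes))
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_genes)
    for j in range(n_genes):
        y = x[j]
        if np.all(y == y[0]):
            continue
        predictors = np.delete(np.arange(n_genes), j)
        model = ExtraTreesRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(child_seeds[j] % (2 ** 31)),
            n_jobs=1,
        )
        model.fit(x[predictors].T, y)
        imp = model.feature_importances_
        total = imp.sum()
        if total > 0:
            imp = imp / total
        sc[predictors, j] = imp
    return ScoreTable("genie3", False, pd.DataFrame(sc, index=genes, columns=genes))


METHODS = {
    "pearson": lambda po, seed: correlation_scores(po, "pearson"),
    "spearman": lambda po, seed: correlation_scores(po, "spearman"),
    "anova": lambda po, seed: anova_eta_scores(po),
    "clr": lambda po, seed: clr_transform(mutual_information(po)),
    "aracne": lambda po, seed: aracne_prune(mutual_information(po)),
    "pcor": lambda po, seed: partial_correlation_shrinkage(po),
    "genie3": lambda po, seed: tree_ensemble_importance(po, seed=seed),
}

#: inference algorithms accepted as plugin slots but not shipped
PLUGIN_SLOTS = ("narromi", "tigress")


def run_methods(po: POProfile, methods=tuple(METHODS), seed: int = 0) -> list[ScoreTable]:
    """Run the requested subset of scorers; unknown names raise ConfigError."""
    tables = []
    for name in methods:
        if name in PLUGIN_SLOTS:
            raise ConfigError(f"{name} is a plugin slot; no implementation is shipped")
        if name not in METHODS:
            raise ConfigError(f"unknown inference method {name!r}")
        tables.append(METHODS[name](po, seed))
    return tables
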