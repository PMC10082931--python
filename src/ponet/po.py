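"""Polysome-occupancy core: noise filtering, PO computation, differential-PO
calling with an empirical-Bayes moderated t, profile clustering, sample PCA,
and ribosome abundance from gradient absorbance traces.

The moderated test shrinks per-gene residual variances toward a pooled prior
estimated from the marginal distribution of the log sample variances
(moment matching on log s^2), which stabilises ordinary two-sample t
statistics at small replicate numbers. A gene is called translationally
up/down between consecutive stages when |log2 fold change of PO| exceeds 1
(2-fold) and the Benjamini-Hochberg FDR is below 0.05.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st
from scipy.special import digamma, polygamma
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DegenerateInputError, PairingError
from .expression import AbsorbanceTrace, ExpressionMatrix, POProfile, check_matched_grids

log = logging.getLogger(__name__)

NOISE_THRESHOLD = 4.0  # log2 intensity below which a value is considered noise


# ---------------------------------------------------------------------------
# noise filter
# ---------------------------------------------------------------------------

def apply_noise_filter(
    total: ExpressionMatrix,
    polysomal: ExpressionMatrix,
    threshold: float = NOISE_THRESHOLD,
    mode: str = "all-samples",
):
    """Remove genes that never rise above the noise floor.

    mode="all-samples": a gene is removed when *every* value across both
    fractions is below ``threshold``.
    mode="any-stage-either-level": a gene is kept when its per-stage replicate
    mean exceeds ``threshold`` at >=1 stage in either fraction (the variant
    used upstream of network construction).

    Returns (filtered_total, filtered_polysomal, removed_gene_list).
    """
    check_matched_grids(total, polysomal)
    both = np.hstack([total.data.to_numpy(), polysomal.data.to_numpy()])
    if mode == "all-samples":
        keep = (both >= threshold).any(axis=1)
    elif mode == "any-stage-either-level":
        keep = np.zeros(len(total.genes), dtype=bool)
        for mat in (total, polysomal):
            stage_means = mat.data.T.groupby(level="stage").mean().T.to_numpy()
            keep |= (stage_means > threshold).any(axis=1)
    else:
        raise ConfigError(f"unknown noise-filter mode: {mode!r}")
    removed = list(total.genes[~keep])
    kept = total.genes[keep]
    if len(kept) == 0:
        raise DegenerateInputError("noise filter removed every gene")
    return total.subset(kept), polysomal.subset(kept), removed


# ---------------------------------------------------------------------------
# PO
# ---------------------------------------------------------------------------

def compute_po(total: ExpressionMatrix, polysomal: ExpressionMatrix) -> POProfile:
    """PO[g, s, r] = log2 polysomal - log2 total on the matched sample grid."""
    check_matched_grids(total, polysomal)
    t = total.data.copy()
    t.columns = pd.MultiIndex.from_tuples(
        [(s, r) for s, _, r in t.columns], names=["stage", "replicate"]
    )
    p = polysomal.data.copy()
    p.columns = pd.MultiIndex.from_tuples(
        [(s, r) for s, _, r in p.columns], names=["stage", "replicate"]
    )
    po = p[t.columns] - t
    return POProfile(po, total.stage_order)


# ---------------------------------------------------------------------------
# moderated differential PO
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve polygamma(1, y) = x for y > 0 (Newton on 1/psi')."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: int):
    """Estimate (d0, s0^2) of the scaled inverse-chi-square variance prior.

    Matches the mean and variance of log s^2 to its theoretical distribution
    under the hierarchical model; returns (inf, mean variance) when the
    observed spread of log s^2 does not exceed the chi-square contribution
    (effectively constant true variances).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        warnings.warn("too few positive variances; falling back to d0=inf")
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = float(np.mean(e))
    resid_var = float(np.mean((e - e_bar) ** 2) * len(e) / (len(e) - 1)) - float(polygamma(1, df / 2.0))
    if resid_var <= 0:
        warnings.warn("log-variance spread below chi-square expectation; using d0=inf")
        return np.inf, float(np.exp(e_bar))
    d0 = 2.0 * _trigamma_inverse(resid_var)
    s02 = float(np.exp(e_bar + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def moderated_diff_po(
    po: POProfile,
    contrast: tuple,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated two-sample test of PO between two stages.

    ``contrast`` is (stageA, stageB); log2FC is mean PO at B minus mean at A.
    Returns a DataFrame with columns log2FC, t, p, fdr, call where call is
    'up'/'down'/'ns' per the 2-fold + FDR rule.
    """
    stage_a, stage_b = contrast
    xa = po.stage_values(stage_a).to_numpy()
    xb = po.stage_values(stage_b).to_numpy()
    na, nb = xa.shape[1], xb.shape[1]
    df_resid = na + nb - 2
    if na < 2 or nb < 2:
        raise ConfigError("moderated test requires >=2 replicates per stage")
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    lfc = mean_b - mean_a
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if d0_override is not None:
        d0 = d0_override
        s02 = float(np.mean(s2[s2 > 0])) if np.any(s2 > 0) else 1.0
    else:
        d0, s02 = estimate_variance_prior(s2, df_resid)

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s02)
        df_total = np.inf
    elif d0 == 0:
        s2_tilde = s2
        df_total = df_resid
    else:
        s2_tilde = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0
    se = np.sqrt(s2_tilde * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * st.norm.sf(np.abs(t))
    else:
        p = 2.0 * st.t.sf(np.abs(t), df_total)
    fdr = multipletests(p, method="fdr_bh")[1]
    call = np.where(
        (lfc > lfc_threshold) & (fdr < fdr_threshold), "up",
        np.where((lfc < -lfc_threshold) & (fdr < fdr_threshold), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "contrast": f"{stage_a}:{stage_b}",
            "log2FC": lfc,
            "t": t,
            "p": p,
            "fdr": fdr,
            "call": call,
        },
        index=po.genes,
    )


def diff_po_all_transitions(po: POProfile, **kwargs) -> pd.DataFrame:
    """Moderated tests for every consecutive-stage contrast, concatenated."""
    frames = []
    for a, b in zip(po.stage_order[:-1], po.stage_order[1:]):
        frames.append(moderated_diff_po(po, (a, b), **kwargs))
    return pd.concat(frames)


# ---------------------------------------------------------------------------
# clustering of PO profiles
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    labels: pd.Series            # gene -> 1..k
    k: int
    selection_scores: dict = field(default_factory=dict)  # k -> mean silhouette
    linkage: str = "average"
    degenerate: bool = False


def cluster_po_profiles(
    po: POProfile,
    k_range=range(2, 21),
    linkage: str = "average",
    profile: str = "stage-mean",
) -> ClusterResult:
    """Hierarchical (Euclidean) clustering of PO profiles with silhouette-based
    selection of the cluster number; ties resolved toward the smallest k.

    ``profile`` selects stage means (default) or the full replicate matrix.
    """
    if profile == "stage-mean":
        x = po.stage_means().to_numpy()
    elif profile == "replicates":
        x = po.sample_matrix()
    else:
        raise ConfigError(f"unknown profile mode {profile!r}")
    genes = po.genes
    k_range = [k for k in k_range if k <= len(genes) - 1]
    if not k_range:
        raise ConfigError("need at least k_max + 1 genes to cluster")
    if np.allclose(x, x[0]):
        labels = pd.Series(1, index=genes)
        return ClusterResult(labels, 1, {}, linkage, degenerate=True)
    z = sch.linkage(x, method=linkage, metric="euclidean")
    scores: dict[int, float] = {}
    best_k, best_s = None, -np.inf
    assignments = {}
    for k in k_range:
        lab = sch.fcluster(z, t=k, criterion="maxclust")
        assignments[k] = lab
        if len(np.unique(lab)) < 2:
            continue
        s = float(silhouette_score(x, lab, metric="euclidean"))
        scores[k] = s
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if best_k is None:
        labels = pd.Series(1, index=genes)
        return ClusterResult(labels, 1, scores, linkage, degenerate=True)
    lab = assignments[best_k]
    # make ids contiguous 1..k in order of first appearance
    order = {c: i + 1 for i, c in enumerate(pd.unique(lab))}
    labels = pd.Series([order[c] for c in lab], index=genes)
    return ClusterResult(labels, int(labels.max()), scores, linkage)


# ---------------------------------------------------------------------------
# PCA of samples
# ---------------------------------------------------------------------------

def pca_samples(expr: ExpressionMatrix):
    """Gene-centered SVD of the expression matrix; samples as observations.

    Returns (coordinates DataFrame samples x PCs, variance-explained array).
    """
    x = expr.data.to_numpy()
    if x.shape[1] < 2:
        raise ConfigError("PCA requires >=2 samples")
    centered = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s ** 2
    total = var.sum()
    fractions = var / total if total > 0 else np.zeros_like(var)
    coords = (vt.T * s)  # samples x components
    names = [f"PC{i+1}" for i in range(coords.shape[1])]
    coords_df = pd.DataFrame(coords, index=expr.data.columns.to_flat_index(), columns=names)
    return coords_df, fractions


# ---------------------------------------------------------------------------
# ribosome abundance from absorbance traces
# ---------------------------------------------------------------------------

def ribosome_abundance(
    trace: AbsorbanceTrace,
    blank: AbsorbanceTrace,
    region: tuple | None = None,
) -> float:
    """Baseline-subtracted AUC of a gradient region over the total AUC.

    The blank-gradient trace is subtracted point-wise (negatives clipped to 0,
    absorbance below blank is noise) and the trapezoidal area of ``region``
    (position interval; default the whole gradient) is normalised by the
    total area.
    """
    if trace.positions.shape != blank.positions.shape or not np.allclose(
        trace.positions, blank.positions
    ):
        raise PairingError("trace and blank are on different position grids; resampling refused")
    signal = np.clip(trace.absorbance - blank.absorbance, 0.0, None)
    total = float(np.trapezoid(signal, trace.positions))
    if total == 0.0:
        return 0.0
    if region is None:
        return 1.0
    lo, hi = region
    mask = (trace.positions >= lo) & (trace.positions <= hi)
    if mask.sum() < 2:
        return 0.0
    part = float(np.trapezoid(signal[mask], trace.positions[mask]))
    return part / total
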