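"""Transcript sequence features, structure meta-profiles, PWM motif
scanning/enrichment, and parent-child ontology enrichment.

Sequence statistics follow the conventions of codon-usage analysis: GC3 is
the GC fraction at third (synonymous) codon positions and Nc is Wright's
effective number of codons, ranging from 20 (a single codon per amino acid)
to 61 (uniform synonymous usage). Motif scanning scores a position weight
matrix by its log-odds against a 0-order background and converts scores to
exact p-values by dynamic programming over the integer-scaled score
distribution, as FIMO does.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .errors import ConfigError, DegenerateInputError, FormatError

log = logging.getLogger(__name__)

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}
REGIONS = ("UTR5", "CDS", "UTR3", "full")

#: standard genetic code, DNA alphabet
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

#: synonymous families grouped by degeneracy (Ser/Leu/Arg are 6-fold)
_FAMILIES: dict[str, list[str]] = {}
for codon, aa in GENETIC_CODE.items():
    _FAMILIES.setdefault(aa, []).append(codon)
FAMILY_DEGENERACY = {aa: len(cods) for aa, cods in _FAMILIES.items()}


def _clean(seq: str) -> str:
    """Uppercase DNA alphabet; RNA (U) mapped onto T."""
    return seq.upper().replace("U", "T")


@dataclass
class TranscriptRecord:
    """One transcript with 0-based half-open UTR5/CDS/UTR3 intervals."""

    gene: str
    sequence: str
    utr5: tuple
    cds: tuple
    utr3: tuple

    def __post_init__(self):
        self.sequence = _clean(self.sequence)
        intervals = [self.utr5, self.cds, self.utr3]
        pos = 0
        for lo, hi in intervals:
            if lo != pos or hi < lo:
                raise FormatError(
                    f"{self.gene}: regions must be contiguous and non-overlapping"
                )
            pos = hi
        if pos != len(self.sequence):
            raise FormatError(f"{self.gene}: regions do not cover the sequence")

    def region_interval(self, region: str) -> tuple:
        if region == "full":
            return (0, len(self.sequence))
        try:
            return getattr(self, region.lower())
        except AttributeError:
            raise ConfigError(f"unknown region {region!r}")

    def region_seq(self, region: str) -> str:
        lo, hi = self.region_interval(region)
        return self.sequence[lo:hi]

    def region_length(self, region: str) -> int:
        lo, hi = self.region_interval(region)
        return hi - lo

    def has_region(self, region: str) -> bool:
        """UTRs count as present only when longer than 1 nucleotide."""
        n = self.region_length(region)
        return n > 1 if region in ("UTR5", "UTR3") else n > 0


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def _gc_fraction(seq: str) -> float:
    if not seq:
        return np.nan
    return (seq.count("G") + seq.count("C")) / len(seq)


def sequence_composition(transcripts, region: str = "CDS"):
    """Per-gene length and GC (plus GC3 for CDS) for one region.

    Genes whose region is absent (length <= 1 for UTRs) are skipped and
    listed in the returned audit.
    Returns (FeatureTable DataFrame, skipped gene list).
    """
    if region not in REGIONS:
        raise ConfigError(f"region must be one of {REGIONS}")
    rows, skipped = {}, []
    for tr in transcripts:
        if not tr.has_region(region):
            skipped.append(tr.gene)
            continue
        seq = tr.region_seq(region)
        entry = {"length": len(seq), "gc": _gc_fraction(seq)}
        if region == "CDS":
            third = seq[2::3]
            entry["gc3"] = _gc_fraction(third)
        rows[tr.gene] = entry
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene"
    return table, skipped


# ---------------------------------------------------------------------------
# effective number of codons
# ---------------------------------------------------------------------------

def _cds_filter_reason(cds: str, min_codons: int = 100) -> str | None:
    if len(cds) % 3 != 0:
        return "length not a multiple of 3"
    if not cds.startswith("ATG"):
        return "missing start codon"
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if any(c in STOP_CODONS for c in codons):
        return "premature stop codon"
    if len(codons) < min_codons:
        return f"shorter than {min_codons} codons"
    return None


def effective_number_of_codons(transcripts, min_codons: int = 100, corrected: bool = False):
    """Wright's Nc per gene after start/stop/length filtering.

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 with the per-family codon
    homozygosity F = sum p_hat^2 (plain plug-in by default, so uniform usage
    gives exactly 61 and single-codon usage exactly 20; ``corrected`` selects
    the small-sample estimator F = (n*sum p^2 - 1)/(n - 1)). Family averages
    are over observed families; an entirely unobserved degeneracy class is
    imputed with the neighbouring classes' mean. Values are clipped to
    [20, 61].

    Returns (Series gene -> Nc, dict gene -> exclusion reason).
    """
    result, excluded = {}, {}
    for tr in transcripts:
        cds = tr.region_seq("CDS") if isinstance(tr, TranscriptRecord) else _clean(tr[1])
        gene = tr.gene if isinstance(tr, TranscriptRecord) else tr[0]
        reason = _cds_filter_reason(cds, min_codons)
        if reason:
            excluded[gene] = reason
            continue
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        if codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        counts: dict[str, dict[str, int]] = {}
        for c in codons:
            aa = GENETIC_CODE[c]
            counts.setdefault(aa, {})
            counts[aa][c] = counts[aa].get(c, 0) + 1
        f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
        for aa, cc in counts.items():
            k = FAMILY_DEGENERACY[aa]
            if k == 1:
                continue
            n = sum(cc.values())
            p2 = sum((v / n) ** 2 for v in cc.values())
            if corrected:
                if n < 2:
                    continue
                p2 = (n * p2 - 1.0) / (n - 1.0)
                if p2 <= 0:
                    continue
            f_by_class[k].append(p2)
        fbar = {k: float(np.mean(v)) if v else np.nan for k, v in f_by_class.items()}
        if np.isnan(fbar[3]) and not (np.isnan(fbar[2]) or np.isnan(fbar[4])):
            fbar[3] = (fbar[2] + fbar[4]) / 2.0  # the customary Ile imputation
        for k in (2, 3, 4, 6):
            if np.isnan(fbar[k]):
                fbar[k] = 1.0 / k  # uniform fallback for an absent class
        nc = 2.0 + 9.0 / fbar[2] + 1.0 / fbar[3] + 5.0 / fbar[4] + 3.0 / fbar[6]
        result[gene] = float(np.clip(nc, 20.0, 61.0))
    return pd.Series(result, name="Nc"), excluded


# ---------------------------------------------------------------------------
# distribution comparison
# ---------------------------------------------------------------------------

def compare_feature_distributions(set_values, background_values) -> dict:
    """Two-sample rank test (Mann-Whitney U) of a gene-set feature against
    the background; exact for tie-free samples of n <= 10, else normal
    approximation with tie correction. Reports both medians."""
    a = np.asarray(set_values, dtype=float)
    b = np.asarray(background_values, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 3 or b.size < 3:
        raise ConfigError("both samples need >=3 values")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and not has_ties) else "asymptotic"
    res = st.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "median_set": float(np.median(a)),
        "median_background": float(np.median(b)),
        "method": method,
    }


# ---------------------------------------------------------------------------
# structure meta-profiles
# ---------------------------------------------------------------------------

def _bin_track(scores: np.ndarray, n_bins: int) -> np.ndarray:
    """Resample one region track onto n_bins relative positions.

    Bin b averages the nucleotides overlapping [b/n, (b+1)/n); regions
    shorter than n_bins share nucleotides between bins so every bin is
    populated.
    """
    length = scores.size
    out = np.empty(n_bins)
    for b in range(n_bins):
        lo = int(np.floor(b * length / n_bins))
        hi = int(np.ceil((b + 1) * length / n_bins))
        out[b] = scores[lo:max(hi, lo + 1)].mean()
    return out


def bin_structure_profile(tracks: dict, transcripts, gene_set, region: str, n_bins: int = 100):
    """Per-bin mean and standard error of structure scores across a gene set.

    ``tracks`` maps gene -> per-nucleotide score array covering the whole
    transcript; each gene's region is resampled onto ``n_bins`` relative
    bins before averaging across genes.
    """
    by_gene = {tr.gene: tr for tr in transcripts}
    profiles = []
    for g in gene_set:
        tr = by_gene.get(g)
        if tr is None or g not in tracks:
            continue
        track = np.asarray(tracks[g], dtype=float)
        if track.size != len(tr.sequence):
            raise FormatError(f"{g}: track length {track.size} != transcript {len(tr.sequence)}")
        if not tr.has_region(region):
            continue
        lo, hi = tr.region_interval(region)
        profiles.append(_bin_track(track[lo:hi], n_bins))
    if not profiles:
        raise DegenerateInputError("no gene in the set has the requested region")
    mat = np.vstack(profiles)
    mean = mat.mean(axis=0)
    se = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]) if mat.shape[0] > 1 else np.zeros(n_bins)
    return pd.DataFrame({"bin": np.arange(n_bins), "mean": mean, "se": se, "n": mat.shape[0]})


def profile_contrast(tracks, transcripts, set_a, set_b, region: str, n_bins: int = 100):
    """Per-bin two-sample t statistics between two gene sets' profiles."""
    by_gene = {tr.gene: tr for tr in transcripts}

    def _mat(gene_set):
        rows = []
        for g in gene_set:
            tr = by_gene.get(g)
            if tr is None or g not in tracks or not tr.has_region(region):
                continue
            lo, hi = tr.region_interval(region)
            rows.append(_bin_track(np.asarray(tracks[g], float)[lo:hi], n_bins))
        return np.vstack(rows)

    a, b = _mat(set_a), _mat(set_b)
    t, p = st.ttest_ind(a, b, axis=0)
    return pd.DataFrame({"bin": np.arange(n_bins), "t": t, "p": p})


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """Position weight matrix: 4 x width probabilities (rows A, C, G, T)."""

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise FormatError("PWM must be 4 x width with width >= 1")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise FormatError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    def sample(self, rng) -> str:
        return "".join(
            BASES[rng.choice(4, p=self.matrix[:, j])] for j in range(self.width)
        )

    def shuffled(self, rng) -> "PWM":
        """Column-shuffled control motif (same composition, scrambled order)."""
        perm = rng.permutation(self.width)
        return PWM(self.motif_id + "_shuffled", self.matrix[:, perm], self.background)


_SCALE = 1000  # integer scaling of log-odds scores for the DP p-value


def _integer_scores(pwm: PWM, background: np.ndarray) -> np.ndarray:
    bg = background.copy()
    if np.any((bg[:, None] == 0) & (pwm.matrix > 0)):
        warnings.warn("zero background frequency under a nonzero PWM column; "
                      "applying pseudocount 1e-4")
        bg = bg + 1e-4
        bg /= bg.sum()
    with np.errstate(divide="ignore"):
        lo = np.log2(np.maximum(pwm.matrix, 1e-10) / bg[:, None])
    return np.round(lo * _SCALE).astype(int)


def score_distribution(pwm: PWM, background: np.ndarray):
    """Exact null distribution of the integer-scaled score under the 0-order
    background, by DP convolution over the PWM columns.

    Returns (sorted unique integer scores, tail probability P(S >= s)).
    """
    ints = _integer_scores(pwm, background)
    offset = -ints.min(axis=0)
    shifted = ints + offset[None, :]
    max_total = int(shifted.max(axis=0).sum())
    dist = np.zeros(max_total + 1)
    dist[0] = 1.0
    for j in range(pwm.width):
        new = np.zeros_like(dist)
        for b in range(4):
            s = shifted[b, j]
            new[s:] += background[b] * dist[: dist.size - s]
        dist = new
    support = np.nonzero(dist)[0]
    scores = support - offset.sum()
    tail = np.cumsum(dist[support][::-1])[::-1]
    return scores, np.minimum(tail, 1.0)


@dataclass
class MotifHit:
    gene: str
    region: str
    offset: int
    strand: str
    score: float
    p: float


def pwm_scan(
    transcripts,
    pwm: PWM,
    region: str = "UTR5",
    p_threshold: float = 0.001,
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Scan one region of every transcript for PWM matches (forward strand).

    ``background`` defaults to the 0-order composition of the scanned
    sequences. Hits are offsets whose exact DP p-value is < ``p_threshold``.
    Returns a DataFrame with columns gene, region, offset, strand, score, p.
    """
    seqs = {
        tr.gene: tr.region_seq(region)
        for tr in transcripts
        if tr.has_region(region)
    }
    if background is None:
        counts = np.zeros(4)
        for s in seqs.values():
            for i, b in enumerate(BASES):
                counts[i] += s.count(b)
        background = counts / counts.sum() if counts.sum() else np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    ints = _integer_scores(pwm, background)
    null_scores, null_tail = score_distribution(pwm, background)
    base_index = {b: i for i, b in enumerate(BASES)}
    rows = []
    w = pwm.width
    for gene, seq in seqs.items():
        if len(seq) < w:
            continue
        idx = np.array([base_index.get(c, -1) for c in seq])
        for off in range(len(seq) - w + 1):
            window = idx[off:off + w]
            if (window < 0).any():
                continue
            s_int = int(ints[window, np.arange(w)].sum())
            pos = np.searchsorted(null_scores, s_int)
            p = float(null_tail[pos]) if pos < null_scores.size else 0.0
            if p < p_threshold:
                rows.append((gene, region, off, "+", s_int / _SCALE, p))
    return pd.DataFrame(rows, columns=["gene", "region", "offset", "strand", "score", "p"])


def motif_enrichment(hits: pd.DataFrame, gene_set, background_set) -> dict:
    """One-tailed Fisher enrichment of genes with >=1 hit in a set vs the rest
    of the background universe."""
    gene_set, background_set = set(gene_set), set(background_set)
    if not gene_set <= background_set:
        raise ConfigError("gene set must be a subset of the background set")
    hit_genes = set(hits["gene"]) if len(hits) else set()
    a = len(gene_set & hit_genes)
    b = len(gene_set) - a
    rest = background_set - gene_set
    c = len(rest & hit_genes)
    d = len(rest) - c
    odds, p = st.fisher_exact([[a, b], [c, d]], alternative="greater")
    return {"odds_ratio": float(odds), "p": float(p), "table": [[a, b], [c, d]]}


def motif_positional_profile(
    hits: pd.DataFrame, transcripts, gene_set, region: str = "UTR5",
    n_bins: int = 100, motif_width: int = 1,
) -> np.ndarray:
    """Relative per-bin motif density over a gene set.

    Each hit is mapped to offset / (region length - width + 1) (the last
    startable position maps to 1) and binned; density = count per bin
    divided by the number of genes in the set.
    """
    by_gene = {tr.gene: tr for tr in transcripts}
    gene_set = set(gene_set)
    counts = np.zeros(n_bins)
    for row in hits.itertuples(index=False):
        if row.gene not in gene_set:
            continue
        tr = by_gene.get(row.gene)
        if tr is None:
            continue
        length = tr.region_length(row.region)
        denom = max(length - motif_width + 1, 1)
        rel = row.offset / denom
        counts[min(int(rel * n_bins), n_bins - 1)] += 1
    return counts / max(len(gene_set), 1)


# ---------------------------------------------------------------------------
# parent-child ontology enrichment
# ---------------------------------------------------------------------------

def _propagate_annotations(edges: list, annotations: dict) -> dict:
    """Annotations propagated to all ancestors; raises on a cyclic DAG.

    ``edges`` is a list of (child, parent) term pairs; ``annotations`` maps
    gene -> iterable of directly annotated terms.
    """
    parents: dict[str, set] = {}
    terms = set()
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)
        terms.update((child, parent))
    # cycle check by depth-first search
    state: dict[str, int] = {}

    def visit(t):
        if state.get(t) == 1:
            raise ConfigError("ontology contains a cycle")
        if state.get(t) == 2:
            return
        state[t] = 1
        for p in parents.get(t, ()):
            visit(p)
        state[t] = 2

    for t in terms:
        visit(t)
    term_genes: dict[str, set] = {t: set() for t in terms}
    for gene, ts in annotations.items():
        seen = set()
        stack = list(ts)
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            term_genes.setdefault(t, set()).add(gene)
            stack.extend(parents.get(t, ()))
    return term_genes


def parent_child_enrichment(
    study_genes,
    ontology_edges,
    annotations,
    fdr_threshold: float = 0.05,
    universe=None,
    variant: str = "union",
) -> pd.DataFrame:
    """Parent-child term enrichment with BH correction.

    For term t with parent set Pa(t), the hypergeometric draw is restricted
    to genes annotated to the union (default) or intersection of Pa(t); root
    terms are conditioned on the whole universe. Returns all tested terms
    with p, fdr and an ``enriched`` flag at ``fdr_threshold``.
    """
    from statsmodels.stats.multitest import multipletests

    study = set(study_genes)
    term_genes = _propagate_annotations(ontology_edges, annotations)
    if universe is None:
        universe = set().union(*term_genes.values()) if term_genes else set()
    else:
        universe = set(universe)
    study &= universe
    parents: dict[str, set] = {}
    for child, parent in ontology_edges:
        parents.setdefault(child, set()).add(parent)
    rows = []
    for term, genes in sorted(term_genes.items()):
        genes = genes & universe
        if not genes:
            continue
        pa = parents.get(term)
        if pa:
            sets = [term_genes.get(p, set()) & universe for p in pa]
            ref = set.union(*sets) if variant == "union" else set.intersection(*sets)
        else:
            ref = universe
        ref = ref | genes  # guard against annotation gaps
        k = len(study & genes)
        n_draw = len(study & ref)
        big_k = len(genes)
        big_n = len(ref)
        p = float(st.hypergeom.sf(k - 1, big_n, big_k, n_draw)) if k > 0 else 1.0
        rows.append((term, big_n, big_k, n_draw, k, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["term", "ref_size", "term_size", "study_in_ref", "study_in_term", "p"]
    )
    if out.empty:
        out["fdr"] = out["enriched"] = []
        return out
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["enriched"] = out["fdr"] <= fdr_threshold
    return out.sort_values("p").reset_index(drop=True)
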