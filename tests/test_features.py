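"""Sequence composition, Nc, rank tests, structure bins, PWM scanning,
motif and ontology enrichment."""
import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import ponet
from ponet.errors import ConfigError
from ponet.features import (
    GENETIC_CODE,
    STOP_CODONS,
    _FAMILIES,
    score_distribution,
)


def _record(gene, utr5, cds, utr3):
    seq = utr5 + cds + utr3
    return ponet.TranscriptRecord(
        gene, seq, (0, len(utr5)), (len(utr5), len(utr5) + len(cds)),
        (len(utr5) + len(cds), len(seq)),
    )


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def test_cds_composition_hand_count():
    tr = _record("g", "AAAA", "ATGGGCTAA", "TTTT")
    table, _ = ponet.sequence_composition([tr], "CDS")
    row = table.loc["g"]
    assert row["length"] == 9
    assert row["gc"] == pytest.approx(4 / 9)
    assert row["gc3"] == pytest.approx(2 / 3)  # third positions G, C, A


def test_all_at_sequence_zero_gc():
    tr = _record("g", "ATAT", "ATGATATAA", "TATA")
    table, _ = ponet.sequence_composition([tr], "full")
    assert table.loc["g", "gc"] == pytest.approx(1 / 17)


def test_absent_utr_skipped_with_audit():
    tr = _record("g", "A", "ATGGGCTAA", "TTTT")  # 1-nt UTR5 counts as absent
    table, skipped = ponet.sequence_composition([tr], "UTR5")
    assert skipped == ["g"] and table.empty


def test_composition_matches_counting_oracle():
    rng = np.random.default_rng(0)
    records = []
    for i in range(100):
        utr5 = "".join(rng.choice(list("ACGT"), size=rng.integers(5, 40)))
        cds = "ATG" + "".join(rng.choice(["GGC", "CCA", "TTC"], size=30)) + "TAA"
        utr3 = "".join(rng.choice(list("ACGT"), size=rng.integers(5, 40)))
        records.append(_record(f"g{i}", utr5, cds, utr3))
    for region in ("UTR5", "CDS", "UTR3", "full"):
        table, _ = ponet.sequence_composition(records, region)
        for tr in records:
            seq = tr.region_seq(region)
            assert table.loc[tr.gene, "length"] == len(seq)
            gc = sum(c in "GC" for c in seq) / len(seq)
            assert table.loc[tr.gene, "gc"] == pytest.approx(gc)


def test_composition_case_and_alphabet_invariance():
    a = _record("g", "acgu".upper().replace("U", "T"), "ATGGGCTAA", "TTTT")
    b = ponet.TranscriptRecord("g", "acguATGggcTAAuuuu", (0, 4), (4, 13), (13, 17))
    ta, _ = ponet.sequence_composition([a], "CDS")
    tb, _ = ponet.sequence_composition([b], "CDS")
    assert ta.loc["g", "gc"] == tb.loc["g", "gc"]


# ---------------------------------------------------------------------------
# Nc
# ---------------------------------------------------------------------------

def _cds_uniform_usage(repeats=3):
    """Every sense codon equally often, ATG first, stop last."""
    sense = [c for c in GENETIC_CODE if c not in STOP_CODONS]
    body = "".join(sense) * repeats
    return "ATG" + body + "TAA"


def _cds_single_codon_usage(repeats=8):
    """Exactly one codon per amino acid."""
    picks = [sorted(cods)[0] for aa, cods in sorted(_FAMILIES.items())]
    return "ATG" + "".join(picks) * repeats + "TAA"


def test_nc_uniform_usage_is_61():
    tr = _record("g", "AA", _cds_uniform_usage(), "AA")
    nc, excluded = ponet.effective_number_of_codons([tr])
    assert not excluded
    assert nc["g"] == pytest.approx(61.0, abs=1e-9)


def test_nc_single_codon_usage_is_20():
    tr = _record("g", "AA", _cds_single_codon_usage(), "AA")
    nc, excluded = ponet.effective_number_of_codons([tr])
    assert not excluded
    assert nc["g"] == pytest.approx(20.0, abs=1e-9)


def test_short_cds_excluded():
    cds = "ATG" + "GGC" * 98 + "TAA"  # 99 non-stop codons
    tr = _record("g", "AA", cds, "AA")
    nc, excluded = ponet.effective_number_of_codons([tr])
    assert "g" in excluded and "shorter" in excluded["g"]
    assert nc.empty


@pytest.mark.parametrize("bad,reason", [
    ("GGG" + "GGC" * 120 + "TAA", "start"),
    ("ATG" + "GGC" * 60 + "TAA" + "GGC" * 60 + "TAA", "premature"),
])
def test_cds_filters(bad, reason):
    tr = _record("g", "AA", bad, "AA")
    _, excluded = ponet.effective_number_of_codons([tr])
    assert reason in excluded["g"]


def test_nc_alphabet_invariance():
    cds = _cds_uniform_usage()
    a = _record("g", "AA", cds, "AA")
    b = ponet.TranscriptRecord("g", ("AA" + cds + "AA").replace("T", "U").lower(),
                               (0, 2), (2, 2 + len(cds)), (2 + len(cds), 4 + len(cds)))
    nca, _ = ponet.effective_number_of_codons([a])
    ncb, _ = ponet.effective_number_of_codons([b])
    assert nca["g"] == ncb["g"]


# ---------------------------------------------------------------------------
# rank-sum comparison
# ---------------------------------------------------------------------------

def test_identical_samples_p_near_one():
    vals = list(range(20))
    res = ponet.compare_feature_distributions(vals, vals)
    assert res["p"] >= 0.99


def test_large_shift_tiny_p():
    rng = np.random.default_rng(1)
    a = rng.normal(3.0, 1.0, 100)
    b = rng.normal(0.0, 1.0, 100)
    res = ponet.compare_feature_distributions(a, b)
    assert res["p"] < 1e-6
    assert res["median_set"] > res["median_background"]


def test_exact_p_matches_enumeration_at_n5():
    """n=5 vs 5 tie-free: exact p equals brute-force rank enumeration."""
    a = [1.3, 2.9, 4.1, 5.7, 8.2]
    b = [0.4, 2.1, 3.3, 6.6, 7.0]
    res = ponet.compare_feature_distributions(a, b)
    assert res["method"] == "exact"
    pooled = sorted(a + b)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in a) - 5 * 6 / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, 11), 5):
        u = sum(combo) - 5 * 6 / 2
        total += 1
        if abs(u - 12.5) >= abs(u_obs - 12.5):  # two-sided around mean n1*n2/2
            count += 1
    assert res["p"] == pytest.approx(count / total, abs=1e-12)


def test_empty_sample_rejected():
    with pytest.raises(ConfigError):
        ponet.compare_feature_distributions([], [1, 2, 3])


# ---------------------------------------------------------------------------
# structure bins
# ---------------------------------------------------------------------------

def test_constant_track_constant_bins():
    tr = _record("g", "A" * 50, "ATG" + "C" * 294 + "TAA", "G" * 50)
    tracks = {"g": np.ones(len(tr.sequence))}
    prof = ponet.bin_structure_profile(tracks, [tr], ["g"], "CDS", 100)
    assert np.allclose(prof["mean"], 1.0) and np.allclose(prof["se"], 0.0)


def test_linear_ramp_bin_means():
    """Scores (i + 0.5)/L over the CDS: bin b mean = (b + 0.5)/n_bins."""
    n, L = 100, 1000
    cds = "ATG" + "C" * (L - 6) + "TAA"
    tr = _record("g", "AA", cds, "AA")
    scores = np.zeros(len(tr.sequence))
    lo, hi = tr.cds
    scores[lo:hi] = (np.arange(L) + 0.5) / L
    prof = ponet.bin_structure_profile({"g": scores}, [tr], ["g"], "CDS", n)
    expect = (np.arange(n) + 0.5) / n
    assert np.allclose(prof["mean"], expect, atol=1 / (2 * L))


def test_short_region_all_bins_populated():
    tr = _record("g", "ACGTACGTAC", "ATG" + "C" * 24 + "TAA", "AC")
    tracks = {"g": np.linspace(0, 1, len(tr.sequence))}
    prof = ponet.bin_structure_profile(tracks, [tr], ["g"], "UTR5", 100)
    assert prof["mean"].notna().all()


def test_track_length_mismatch_rejected():
    tr = _record("g", "ACGT", "ATGCCCTAA", "ACGT")
    with pytest.raises(ponet.FormatError):
        ponet.bin_structure_profile({"g": np.ones(5)}, [tr], ["g"], "CDS", 10)


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

def test_planted_consensus_is_hit(sharp_pwm):
    utr5 = "A" * 20 + sharp_pwm.consensus() + "A" * 20
    tr = _record("g", utr5, "ATGCCCTAA", "ACGT")
    hits = ponet.pwm_scan([tr], sharp_pwm, "UTR5", background=np.full(4, 0.25))
    assert (hits["offset"] == 20).any()


def test_scan_wider_than_sequence_no_hits(sharp_pwm):
    tr = _record("g", "ACGTA", "ATGCCCTAA", "ACGT")
    hits = ponet.pwm_scan([tr], sharp_pwm, "UTR5")
    assert hits.empty


def test_width4_pvalues_match_exhaustive_enumeration():
    rng = np.random.default_rng(2)
    mat = rng.dirichlet(np.ones(4), size=4).T  # 4 x 4 PWM
    pwm = ponet.PWM("w4", mat)
    bg = np.array([0.3, 0.2, 0.2, 0.3])
    scores, tail = score_distribution(pwm, bg)
    # brute force over all 256 4-mers with the same integer scaling
    from ponet.features import _SCALE, _integer_scores

    ints = _integer_scores(pwm, bg)
    seq_scores = {}
    for mer in itertools.product(range(4), repeat=4):
        s = sum(ints[b, j] for j, b in enumerate(mer))
        p = np.prod([bg[b] for b in mer])
        seq_scores[s] = seq_scores.get(s, 0.0) + p
    all_s = sorted(seq_scores)
    for s_obs in all_s:
        expect = sum(p for s, p in seq_scores.items() if s >= s_obs)
        pos = np.searchsorted(scores, s_obs)
        assert tail[pos] == pytest.approx(expect, abs=1e-12)


def test_pvalues_monotone_in_score(sharp_pwm):
    scores, tail = score_distribution(sharp_pwm, np.full(4, 0.25))
    assert (np.diff(tail) <= 1e-15).all()


# ---------------------------------------------------------------------------
# motif enrichment & positional profile
# ---------------------------------------------------------------------------

def test_fisher_matches_hypergeometric_tail():
    """Table [[3,7],[2,88]]: p = sum_{k>=3} P(k | N=100, K=5, n=10)."""
    hits = pd.DataFrame({"gene": [f"s{i}" for i in range(3)] + ["b0", "b1"]})
    gene_set = [f"s{i}" for i in range(10)]
    background = gene_set + [f"b{i}" for i in range(90)]
    res = ponet.motif_enrichment(hits, gene_set, background)
    expect = sum(st.hypergeom.pmf(k, 100, 5, 10) for k in range(3, 6))
    assert res["p"] == pytest.approx(expect, rel=1e-9)
    assert res["table"] == [[3, 7], [2, 88]]


def test_no_hits_p_one():
    res = ponet.motif_enrichment(pd.DataFrame({"gene": []}), ["a"], ["a", "b"])
    assert res["p"] == 1.0


def test_set_equals_background_p_one():
    hits = pd.DataFrame({"gene": ["a"]})
    res = ponet.motif_enrichment(hits, ["a", "b"], ["a", "b"])
    assert res["p"] == 1.0


def test_set_not_subset_rejected():
    with pytest.raises(ConfigError):
        ponet.motif_enrichment(pd.DataFrame({"gene": []}), ["x"], ["a", "b"])


def test_positional_profile_start_bin():
    tr = _record("g", "A" * 100, "ATGCCCTAA", "ACGT")
    hits = pd.DataFrame({"gene": ["g"] * 5, "region": ["UTR5"] * 5,
                         "offset": [0] * 5})
    prof = ponet.motif_positional_profile(hits, [tr], ["g"], n_bins=10)
    assert prof[0] == 5.0 and prof[1:].sum() == 0


def test_positional_profile_uniform_hits():
    rng = np.random.default_rng(3)
    tr = _record("g", "A" * 1000, "ATGCCCTAA", "ACGT")
    offsets = rng.integers(0, 1000, size=10_000)
    hits = pd.DataFrame({"gene": "g", "region": "UTR5", "offset": offsets})
    prof = ponet.motif_positional_profile(hits, [tr], ["g"], n_bins=20)
    expected = 10_000 / 20
    assert np.all(np.abs(prof - expected) < 3 * np.sqrt(expected))


def test_positional_profile_no_hits_zero():
    tr = _record("g", "A" * 10, "ATGCCCTAA", "ACGT")
    prof = ponet.motif_positional_profile(
        pd.DataFrame(columns=["gene", "region", "offset"]), [tr], ["g"], n_bins=5)
    assert (prof == 0).all()


# ---------------------------------------------------------------------------
# parent-child enrichment
# ---------------------------------------------------------------------------

def _toy_ontology():
    edges = [("t_leaf", "t_mid"), ("t_mid", "t_root"), ("t_other", "t_root")]
    return edges


def test_term_equal_to_parent_union_p_one():
    edges = [("child", "parent")]
    genes = {f"g{i}": ["child"] for i in range(10)}
    res = ponet.parent_child_enrichment(list(genes)[:4], edges, genes)
    row = res[res["term"] == "child"].iloc[0]
    assert row["p"] == pytest.approx(1.0)


def test_hand_built_dag_matches_hypergeometric_oracle():
    """Parents' union 50 genes, term 10, study 20 (9 in term)."""
    edges = [("term", "parent")]
    annotations = {}
    for i in range(50):
        annotations[f"g{i}"] = ["term"] if i < 10 else ["parent"]
    for i in range(50, 100):
        annotations[f"g{i}"] = ["other_root"]
    study = [f"g{i}" for i in range(9)] + [f"g{i}" for i in range(10, 21)]
    res = ponet.parent_child_enrichment(study, edges, annotations)
    row = res[res["term"] == "term"].iloc[0]
    # draw: 20 study genes inside the 50-gene parent universe, 10 in term
    expect = sum(st.hypergeom.pmf(k, 50, 10, 20) for k in range(9, 11))
    assert row["p"] == pytest.approx(expect, rel=1e-9)


def test_empty_study_no_enrichment_no_error():
    edges = _toy_ontology()
    annotations = {"g1": ["t_leaf"], "g2": ["t_other"]}
    res = ponet.parent_child_enrichment([], edges, annotations)
    assert not res["enriched"].any() if len(res) else True


def test_cyclic_dag_rejected():
    edges = [("a", "b"), ("b", "c"), ("c", "a")]
    with pytest.raises(ConfigError, match="cycle"):
        ponet.parent_child_enrichment(["g"], edges, {"g": ["a"]})


def test_parent_child_reduces_to_classic_at_root():
    """When the parent union is the whole universe, parent-child equals the
    classic hypergeometric test."""
    edges = [("term", "root")]
    annotations = {}
    for i in range(100):
        terms = ["term"] if i < 20 else ["root"]
        annotations[f"g{i}"] = terms
    study = [f"g{i}" for i in range(0, 40, 2)]  # 20 genes, 10 in term
    res = ponet.parent_child_enrichment(study, edges, annotations)
    row = res[res["term"] == "term"].iloc[0]
    classic = st.hypergeom.sf(10 - 1, 100, 20, 20)
    assert row["p"] == pytest.approx(classic, rel=1e-9)
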