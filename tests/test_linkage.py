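"""Tests of read-pair aggregation, VPH/R' computation and the filter cascade."""

import math
import random

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hicphage import (
    Cluster,
    LinkTable,
    PhageHostCandidate,
    ReadPairRecord,
    aggregate_read_pairs,
    build_candidates,
    collapse_to_pairs,
    compute_r_prime,
    compute_vph,
    promiscuity_adjust,
    relative_count_filter,
    roc_threshold,
    round1_filter,
    vph_per_host,
)


def make_candidate(
    phage="v1", mag="B1", rep="r1", cond="pre", L=5, sum_Lv=5, V=1.0, H=1.0,
    intra=500, len_p=10.0, len_m=100.0,
):
    c = PhageHostCandidate(
        phage_id=phage, mag_id=mag, replicate_id=rep, condition=cond,
        L=L, sum_Lv=sum_Lv, V=V, H=H, intra=intra,
        len_phage_kb=len_p, len_mag_kb=len_m,
    )
    c.D_VH = c.L / (len_p * len_m)
    c.D_H = intra / len_m**2
    c.vph = compute_vph(c)
    if c.vph > 0 and intra > 0:
        c.r_prime = compute_r_prime(c)
    return c


# ---------------------------------------------------------------------------
# read-pair aggregation
# ---------------------------------------------------------------------------

META = pd.DataFrame(
    {
        "contig_id": ["c1", "c2", "c3", "p1", "tiny"],
        "length_kb": [100.0, 80.0, 120.0, 20.0, 0.5],
        "entity_id": ["B1", "B1", "B2", "p1", "B2"],
        "entity_type": ["mag", "mag", "mag", "phage", "mag"],
    }
)


def test_quality_filters_drop_duplicates_and_low_mapq():
    recs = [
        ReadPairRecord("r1", "p1", "c1", 30, 30),
        ReadPairRecord("r2", "p1", "c1", 30, 30, is_duplicate=True),
        ReadPairRecord("r3", "p1", "c1", 30, 30, is_duplicate=True),
        ReadPairRecord("r4", "p1", "c3", 10, 30),
        ReadPairRecord("r5", "p1", "c3", 30, 30),
    ]
    t = aggregate_read_pairs(recs, META)
    assert t.get("p1", "B1") == 1 and t.get("p1", "B2") == 1
    assert sum(t.entries.values()) == 2


def test_same_contig_pairs_excluded():
    t = aggregate_read_pairs([ReadPairRecord("r", "c1", "c1", 30, 30)], META)
    assert not t.entries and not t.intra


def test_same_mag_distinct_contigs_count_as_intra():
    t = aggregate_read_pairs([ReadPairRecord("r", "c1", "c2", 30, 30)], META)
    assert t.intra == {"B1": 1} and not t.entries


def test_non_primary_and_short_contigs_dropped():
    recs = [
        ReadPairRecord("r1", "p1", "c1", 30, 30, is_primary_b=False),
        ReadPairRecord("r2", "p1", "tiny", 30, 30),
    ]
    t = aggregate_read_pairs(recs, META)
    assert not t.entries


def test_unknown_contig_raises():
    with pytest.raises(KeyError, match="ghost"):
        aggregate_read_pairs([ReadPairRecord("r", "ghost", "c1", 30, 30)], META)


# ---------------------------------------------------------------------------
# VPH and R'
# ---------------------------------------------------------------------------


def test_vph_identity_case():
    c = make_candidate(V=2.0, H=2.0, L=7, sum_Lv=7)
    assert c.vph == pytest.approx(1.0)


def test_vph_hand_substitution():
    c = make_candidate(V=4.0, H=2.0, L=3, sum_Lv=6)
    assert c.vph == pytest.approx(1.0)


def test_vph_zero_links():
    c = make_candidate(L=0, sum_Lv=6)
    assert c.vph == 0.0


def test_vph_undefined_inputs_rejected():
    c = PhageHostCandidate(
        phage_id="v", mag_id="B", replicate_id="r1", condition="pre",
        L=3, sum_Lv=6, V=1.0, H=0.0, intra=50, len_phage_kb=10.0, len_mag_kb=100.0,
    )
    with pytest.raises(ValueError, match="VPH undefined"):
        compute_vph(c)
    c.H, c.sum_Lv = 1.0, 0
    with pytest.raises(ValueError, match="VPH undefined"):
        compute_vph(c)


def test_r_prime_hand_example_sits_on_round1_boundary():
    # 10 kb phage, 100 kb MAG, L=5, intra=500, V=H, sum_Lv=5:
    # D_VH=0.005, D_H=0.05, VPH=1, R'=0.1
    c = make_candidate()
    assert c.D_VH == pytest.approx(0.005)
    assert c.D_H == pytest.approx(0.05)
    assert c.vph == pytest.approx(1.0)
    assert c.r_prime == pytest.approx(0.1)
    assert round1_filter([c]) == [c]  # thresholds are inclusive


def test_r_prime_rejects_zero_intra():
    with pytest.raises(ValueError, match="D_H undefined"):
        compute_r_prime(make_candidate(intra=0))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    L=st.integers(1, 1000),
    extra=st.integers(0, 1000),
    V=st.floats(0.01, 100),
    H=st.floats(0.01, 100),
    intra=st.integers(1, 10_000),
    len_p=st.floats(5, 300),
    len_m=st.floats(100, 10_000),
)
def test_r_prime_vph_product_identity(L, extra, V, H, intra, len_p, len_m):
    """R' * VPH == D_VH / D_H for arbitrary candidates."""
    c = make_candidate(L=L, sum_Lv=L + extra, V=V, H=H, intra=intra,
                       len_p=len_p, len_m=len_m)
    assert c.r_prime * c.vph == pytest.approx(c.D_VH / c.D_H, rel=1e-9)


def test_scaling_abundances_preserves_product():
    # R' * VPH = D_VH / D_H involves only counts and lengths: rescaling the
    # abundances V (or V and H together) cancels symbolically
    a = make_candidate(V=2.0, H=1.0, L=4, sum_Lv=8)
    b = make_candidate(V=4.0, H=1.0, L=4, sum_Lv=8)
    c = make_candidate(V=6.0, H=3.0, L=4, sum_Lv=8)
    assert a.r_prime * a.vph == pytest.approx(b.r_prime * b.vph)
    assert a.r_prime * a.vph == pytest.approx(c.r_prime * c.vph)


# ---------------------------------------------------------------------------
# round-1 filter
# ---------------------------------------------------------------------------


def test_round1_single_link_rejected():
    c = make_candidate(L=1, sum_Lv=1, intra=999)
    assert round1_filter([c]) == []
    assert c.flags["min_links"] is False


def test_round1_low_ratio_rejected():
    c = make_candidate(L=3, sum_Lv=3, intra=5000, len_m=1000.0)
    assert c.r_prime < 0.1
    assert round1_filter([c]) == []
    assert c.flags["intra"] and not c.flags["ratio"]


def brute_round1(cands, min_links=2, min_ratio=0.1, min_intra=10):
    return [
        c for c in cands
        if c.L >= min_links and c.r_prime >= min_ratio and c.intra >= min_intra
    ]


# ---------------------------------------------------------------------------
# ROC threshold
# ---------------------------------------------------------------------------


def brute_roc(cands, score=lambda c: c.r_prime):
    n = len(cands)
    phages = {c.phage_id for c in cands}
    best = None
    for t in sorted({score(c) for c in cands}):
        kept = [c for c in cands if score(c) >= t]
        f = len({c.phage_id for c in kept}) / len(phages)
        g = (n - len(kept)) / n
        if best is None or f + g > best[0]:
            best = (f + g, t, kept)
    return best[1], best[2]


def test_roc_uniform_scores_keep_everything():
    cands = [make_candidate(phage=f"v{i}") for i in range(4)]
    t, surv = roc_threshold(cands)
    assert len(surv) == 4 and t == pytest.approx(cands[0].r_prime)


def test_roc_two_phage_example():
    # phage A: scores 0.9 and 0.05; phage B: 0.9 -> t = 0.9 removes the weak link
    a1 = make_candidate(phage="A", mag="B1")
    a1.r_prime = 0.9
    a2 = make_candidate(phage="A", mag="B2")
    a2.r_prime = 0.05
    b1 = make_candidate(phage="B", mag="B3")
    b1.r_prime = 0.9
    t, surv = roc_threshold([a1, a2, b1])
    assert t == pytest.approx(0.9)
    assert surv == [a1, b1]


def test_roc_single_candidate():
    c = make_candidate()
    t, surv = roc_threshold([c])
    assert t == pytest.approx(c.r_prime) and surv == [c]


def test_roc_empty_rejected():
    with pytest.raises(ValueError):
        roc_threshold([])


def test_roc_matches_exhaustive_search_randomized():
    rng = random.Random(17)
    for _ in range(50):
        cands = []
        for i in range(rng.randint(1, 50)):
            c = make_candidate(phage=f"v{rng.randint(1, 8)}", mag=f"B{i}")
            c.r_prime = round(rng.uniform(0, 2), 2)
            cands.append(c)
        t, surv = roc_threshold(cands)
        bt, bsurv = brute_roc(cands)
        assert t == pytest.approx(bt)
        assert surv == bsurv


# ---------------------------------------------------------------------------
# relative-count (80%) filter
# ---------------------------------------------------------------------------


def test_relative_count_drops_below_80_percent():
    counts = {"B1": 10, "B2": 9, "B3": 7}
    cands = [make_candidate(mag=m, L=n, sum_Lv=26) for m, n in counts.items()]
    kept = {c.mag_id for c in relative_count_filter(cands)}
    assert kept == {"B1", "B2"}  # 7 < 0.8 * 10


def test_relative_count_exact_80_percent_kept():
    cands = [make_candidate(mag="B1", L=10, sum_Lv=18),
             make_candidate(mag="B2", L=8, sum_Lv=18)]
    assert len(relative_count_filter(cands)) == 2  # 8 == 0.8*10, not "less than"


def test_single_host_phage_always_kept():
    c = make_candidate(L=2, sum_Lv=2)
    assert relative_count_filter([c]) == [c]


def test_relative_count_averages_across_replicates():
    # pair (v1,B2) has counts 6 and 10 in two replicates: mean 8 = 0.8*10 -> kept
    cands = [
        make_candidate(mag="B1", rep="r1", L=10, sum_Lv=16),
        make_candidate(mag="B2", rep="r1", L=6, sum_Lv=16),
        make_candidate(mag="B1", rep="r2", L=10, sum_Lv=20),
        make_candidate(mag="B2", rep="r2", L=10, sum_Lv=20),
    ]
    kept = relative_count_filter(cands)
    assert len(kept) == 4
    # but a single-replicate count of 6 alone is dropped
    solo = [
        make_candidate(mag="B1", rep="r1", L=10, sum_Lv=16),
        make_candidate(mag="B2", rep="r1", L=6, sum_Lv=16),
    ]
    assert {c.mag_id for c in relative_count_filter(solo)} == {"B1"}


def brute_relative(cands, frac=0.8):
    keys = {(c.condition, c.phage_id, c.mag_id) for c in cands}
    mean = {}
    for cond, ph, mag in keys:
        ls = [c.L for c in cands
              if (c.condition, c.phage_id, c.mag_id) == (cond, ph, mag)]
        mean[(cond, ph, mag)] = sum(ls) / len(ls)
    out = []
    for c in cands:
        grp_max = max(
            v for (cond, ph, _), v in mean.items()
            if (cond, ph) == (c.condition, c.phage_id)
        )
        if not mean[(c.condition, c.phage_id, c.mag_id)] < frac * grp_max:
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# promiscuity adjustment
# ---------------------------------------------------------------------------


def test_promiscuous_phage_flagged_and_removed():
    cands = [make_candidate(mag=f"B{i}", sum_Lv=150) for i in range(30)]
    kept, report = promiscuity_adjust(cands, n_mags_total=100)
    assert kept == [] and len(report) == 1
    assert report["host_fraction"].iloc[0] == pytest.approx(0.3)


def test_modest_host_range_untouched():
    cands = [make_candidate(mag="B1", sum_Lv=10), make_candidate(mag="B2", sum_Lv=10)]
    kept, report = promiscuity_adjust(cands, n_mags_total=100)
    assert kept == cands and report.empty


def test_promiscuity_disabled_at_fraction_one():
    cands = [make_candidate(mag=f"B{i}", sum_Lv=150) for i in range(30)]
    kept, report = promiscuity_adjust(cands, 100, max_host_fraction=1.0)
    assert kept == cands and report.empty


def test_flag_only_policy_keeps_candidates():
    cands = [make_candidate(mag=f"B{i}", sum_Lv=150) for i in range(30)]
    kept, report = promiscuity_adjust(cands, 100, remove=False)
    assert kept == cands and len(report) == 1


# ---------------------------------------------------------------------------
# collapse and per-host VPH
# ---------------------------------------------------------------------------

VOTUS = [Cluster("v1", ["v1", "v1b"], "votu_95_85"), Cluster("v2", ["v2"], "votu_95_85")]
DEREP = [Cluster("B1", ["B1", "B1b"], "mag_derep_99"), Cluster("B2", ["B2"], "mag_derep_99")]


def test_collapse_merges_votu_members_across_replicates():
    cands = [
        make_candidate(phage="v1", mag="B1", rep="r1"),
        make_candidate(phage="v1b", mag="B1b", rep="r2"),
    ]
    (pair,) = collapse_to_pairs(cands, VOTUS, DEREP)
    assert (pair.votu_id, pair.population_id) == ("v1", "B1")
    assert pair.replicate_support == frozenset({"r1", "r2"})
    assert pair.host_range_class == "one_host"


def test_votu_with_two_populations_is_multiple_hosts():
    cands = [
        make_candidate(phage="v1", mag="B1"),
        make_candidate(phage="v1b", mag="B2"),
        make_candidate(phage="v2", mag="B2"),
    ]
    pairs = collapse_to_pairs(cands, VOTUS, DEREP)
    classes = {(p.votu_id, p.population_id): p.host_range_class for p in pairs}
    assert classes[("v1", "B1")] == "multiple_hosts"
    assert classes[("v1", "B2")] == "multiple_hosts"
    assert classes[("v2", "B2")] == "one_host"


def test_collapse_unassigned_id_raises():
    with pytest.raises(KeyError, match="vOTU"):
        collapse_to_pairs([make_candidate(phage="ghost")], VOTUS, DEREP)


def test_one_pair_per_votu_population_condition():
    cands = [
        make_candidate(phage="v1", mag="B1", rep=r) for r in ("r1", "r2", "r3")
    ]
    pairs = collapse_to_pairs(cands, VOTUS, DEREP)
    assert len(pairs) == 1 and len(pairs[0].replicate_support) == 3


def test_vph_per_host_sums_over_phages():
    c1 = make_candidate(phage="v1", mag="B1", V=1.0, H=2.0, L=5, sum_Lv=5)   # vph 0.5
    c2 = make_candidate(phage="v2", mag="B1b", V=1.0, H=4.0, L=5, sum_Lv=5)  # vph 0.25
    table = vph_per_host([c1, c2], DEREP)
    assert len(table) == 1  # B1b collapses into population B1
    assert table["total_vph"].iloc[0] == pytest.approx(0.75)
    # hosts with no surviving links are absent, not zero
    assert "B2" not in set(table["population_id"])


def test_single_phage_host_total_equals_vph():
    c = make_candidate(phage="v2", mag="B2", V=3.0, H=2.0, L=4, sum_Lv=8)
    table = vph_per_host([c], DEREP)
    assert table["total_vph"].iloc[0] == pytest.approx(c.vph)


# ---------------------------------------------------------------------------
# cascade monotonicity on simulated candidates
# ---------------------------------------------------------------------------


def test_filter_cascade_is_monotone(small_sim):
    truth, dataset = small_sim
    types = dict(zip(dataset.entities["entity_id"], dataset.entities["entity_type"]))
    table = dataset.link_tables[("pre", "r1")]
    cov = dataset.metagenome_coverage["pre_r1"]
    ab = dict(zip(cov["entity_id"], cov["mean_depth"] / cov["library_size"] * 1e6))
    cands, _ = build_candidates(table, ab, types)
    s1 = round1_filter(cands)
    assert set(map(id, s1)) <= set(map(id, cands))
    if s1:
        _, s2 = roc_threshold(s1)
        s3 = relative_count_filter(s2)
        s4, _ = promiscuity_adjust(s3, n_mags_total=15)
        assert set(map(id, s2)) <= set(map(id, s1))
        assert set(map(id, s3)) <= set(map(id, s2))
        assert set(map(id, s4)) <= set(map(id, s3))
        assert brute_round1(cands) == s1
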