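"""Origin classification: binomial framework and decision-tree rules."""

import numpy as np
import pandas as pd
import pytest

from mtmosaic import core_io
from mtmosaic.classify import (
    ClassificationModel,
    classify_cohort,
    detect_tissue_recurrent,
    ml_rate_and_tail,
)
from mtmosaic.core_io import CohortData
from mtmosaic.synthetic_data import donor_phylogeny_newick


def _cohort(donor_clones: dict, ages=None, tissues=None, bulk=None,
            late_clades=None, rng_seed=0):
    """Cohort scaffold with per-donor clone counts and phylogenies."""
    rng = np.random.default_rng(rng_seed)
    clones, trees = [], {}
    import dendropy
    for donor, n in donor_clones.items():
        ids = [f"{donor}_c{i}" for i in range(n)]
        for cid in ids:
            clones.append(core_io.CloneRecord(
                cid, donor, (tissues or {}).get(donor, "colon"),
                (ages or {}).get(donor, 50.0), 30.0, 5000.0, 0.45,
            ))
        newick = donor_phylogeny_newick(
            ids, rng, late_clade=(late_clades or {}).get(donor)
        )
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        tree.is_rooted = True
        trees[donor] = tree
    variants = pd.DataFrame(columns=core_io.VARIANT_COLUMNS)
    bulk_df = None
    if bulk:
        bulk_df = pd.DataFrame(bulk)
    return CohortData(clones=clones, variants=variants, phylogenies=trees,
                      bulk_vafs=bulk_df)


def _calls(entries):
    return pd.DataFrame(entries, columns=["clone_id", "position", "alt",
                                          "vaf"])


# ---------------------------------------------------------------------------
# binomial framework
# ---------------------------------------------------------------------------

def test_zero_background_tail_is_zero():
    m = ClassificationModel(n=100, x_exp=0, n_obs=20, x_obs=3)
    p_hat, tail = ml_rate_and_tail(m)
    assert p_hat == 0.0 and tail == 0.0


def test_tail_probability_closed_form():
    """n=100, x_exp=10, n_obs=10, x_obs=1: P(X>=1) = 1 - 0.9^10."""
    m = ClassificationModel(n=100, x_exp=10, n_obs=10, x_obs=1)
    p_hat, tail = ml_rate_and_tail(m)
    assert p_hat == pytest.approx(0.1)
    assert tail == pytest.approx(1 - 0.9 ** 10)
    assert tail == pytest.approx(0.6513, abs=1e-4)


def test_shared_variant_case_strongly_significant():
    """14 of 27 clones against 2 of 2,069 background clones."""
    m = ClassificationModel(n=2069, x_exp=2, n_obs=27, x_obs=14)
    _, tail = ml_rate_and_tail(m)
    assert tail < 1e-20


def test_tail_matches_monte_carlo(rng):
    """Closed-form binomial tail agrees with simulation within 3 SE."""
    m = ClassificationModel(n=200, x_exp=30, n_obs=25, x_obs=6)
    p_hat, tail = ml_rate_and_tail(m)
    draws = rng.binomial(m.n_obs, p_hat, size=100_000)
    mc = np.mean(draws >= m.x_obs)
    se = np.sqrt(mc * (1 - mc) / draws.size)
    assert abs(tail - mc) < 3 * se


def test_nothing_to_classify_raises():
    with pytest.raises(ValueError, match="x_obs"):
        ml_rate_and_tail(ClassificationModel(n=10, x_exp=1, n_obs=5, x_obs=0))


# ---------------------------------------------------------------------------
# decision tree
# ---------------------------------------------------------------------------

def test_exclusive_sharing_is_het_fe():
    cohort = _cohort({"A": 10, "B": 10, "C": 10})
    calls = _calls([(f"A_c{i}", 100, "T", 0.3) for i in range(3)])
    out = classify_cohort(calls, cohort)
    assert out.iloc[0]["origin_class"] == "Het_FE"
    assert out.iloc[0]["rule_fired"] == "exclusive_sharing"


def test_cross_donor_recurrence_is_pz_recurrent():
    cohort = _cohort({"A": 10, "B": 10, "C": 10})
    calls = _calls(
        [(f"{d}_c{i}", 100, "T", 0.05) for d in "ABC" for i in range(2)]
    )
    out = classify_cohort(calls, cohort)
    assert (out["origin_class"] == "PZ_recurrent").all()


def test_binomial_rule_both_directions():
    """Shared here, sporadic elsewhere: significant sharing -> Het_FE,
    unremarkable sharing -> PZ_simple."""
    donors = {"A": 20}
    donors.update({f"S{i}": 10 for i in range(8)})
    cohort = _cohort(donors)
    # strong: 8/20 clones in A vs 2 sporadic carriers among 80 others
    strong = _calls(
        [(f"A_c{i}", 100, "T", 0.3) for i in range(8)]
        + [("S0_c0", 100, "T", 0.02), ("S1_c0", 100, "T", 0.02)]
    )
    out = strong.pipe(classify_cohort, cohort)
    a_row = out[out["donor_id"] == "A"].iloc[0]
    assert a_row["origin_class"] == "Het_FE"
    assert a_row["rule_fired"] == "binomial"
    assert a_row["tail_p"] < 0.01

    # weak: 2/20 clones in A vs a 10% background rate (8 of 80)
    weak = _calls(
        [("A_c0", 100, "T", 0.05), ("A_c1", 100, "T", 0.05)]
        + [(f"S{i}_c0", 100, "T", 0.05) for i in range(8)]
    )
    out = weak.pipe(classify_cohort, cohort)
    a_row = out[out["donor_id"] == "A"].iloc[0]
    assert a_row["origin_class"] == "PZ_simple"
    assert a_row["tail_p"] >= 0.01


def test_late_branch_rule_overrides_sharing():
    """Sharing confined to a deep clade (>=100 nuclear mutations before
    divergence) is a late postzygotic event, not fertilized-egg origin."""
    cohort = _cohort({"A": 12, "B": 10}, late_clades={"A": (4, 150.0)})
    late_ids = [f"A_c{i}" for i in range(8, 12)]
    calls = _calls([(cid, 100, "T", 0.4) for cid in late_ids[:3]])
    out = classify_cohort(calls, cohort)
    assert out.iloc[0]["origin_class"] == "PZ_simple"
    assert out.iloc[0]["rule_fired"] == "late_branch"


def test_singleton_with_matched_bulk_is_het_fe():
    bulk = [{"donor_id": "A", "tissue": "blood", "position": 100,
             "alt": "T", "vaf": 0.02}]
    cohort = _cohort({"A": 10, "B": 10}, bulk=bulk)
    calls = _calls([("A_c0", 100, "T", 0.4)])
    out = classify_cohort(calls, cohort)
    assert out.iloc[0]["origin_class"] == "Het_FE"
    assert out.iloc[0]["rule_fired"] == "matched_bulk"


def test_singleton_without_bulk_is_pz_simple():
    cohort = _cohort({"A": 10, "B": 10})
    calls = _calls([("A_c0", 100, "T", 0.4)])
    out = classify_cohort(calls, cohort)
    assert out.iloc[0]["origin_class"] == "PZ_simple"
    assert out.iloc[0]["rule_fired"] == "default"


def test_every_variant_gets_exactly_one_class(small_cohort):
    """Precedence is total over a full generated cohort."""
    cohort, _, calls = small_cohort
    out = classify_cohort(calls, cohort)
    assert out["origin_class"].isin(
        ["Het_FE", "PZ_recurrent", "PZ_simple"]
    ).all()
    assert not out.duplicated(["donor_id", "position", "alt"]).any()


# ---------------------------------------------------------------------------
# tissue-recurrent hotspots
# ---------------------------------------------------------------------------

def test_age_linked_hotspot_flagged():
    ages = {f"D{i}": age for i, age in
            enumerate([20, 25, 30, 35, 80, 85, 90, 95])}
    cohort = _cohort({d: 5 for d in ages}, ages=ages)
    # hotspot in the four oldest donors only
    calls = _calls([(f"D{i}_c0", 414, "G", 0.05) for i in (4, 5, 6, 7)])
    out = detect_tissue_recurrent(calls, cohort)
    assert out.iloc[0]["flagged"]


def test_uniform_ages_not_flagged():
    ages = {f"D{i}": 50.0 for i in range(8)}
    cohort = _cohort({d: 5 for d in ages}, ages=ages)
    calls = _calls([(f"D{i}_c0", 414, "G", 0.05) for i in (0, 1, 2, 3)])
    out = detect_tissue_recurrent(calls, cohort)
    assert not out.iloc[0]["flagged"]


def test_single_donor_site_not_reported():
    cohort = _cohort({"A": 5, "B": 5})
    calls = _calls([("A_c0", 414, "G", 0.05), ("A_c1", 414, "G", 0.05)])
    out = detect_tissue_recurrent(calls, cohort)
    assert out.empty
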