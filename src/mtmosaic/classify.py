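"""Origin classification of mtDNA alterations.

Each variant observed in a donor is assigned one of three origins:

* ``Het_FE`` — heteroplasmy already present in the fertilized egg, shared
  across embryonic lineages of one individual;
* ``PZ_recurrent`` — recurrent hypermutable-site mutation seen across
  individuals;
* ``PZ_simple`` — ordinary postzygotic mutation confined to one or a few
  clones.

Sharing across clones of exactly one individual indicates a fertilized-egg
origin; apparent sharing can instead reflect a hypermutable site (recurrence
across donors), coincidence (binomial test against the spontaneous rate
estimated from all other donors) or a late postzygotic event confined to a
late-branching subtree of the donor's developmental phylogeny.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .core_io import CohortData

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01
DEFAULT_FULL_COHORT_SIZE = 86
DEFAULT_RECURRENT_INDIVIDUALS = 10
LATE_BRANCH_MIN_MUTATIONS = 100.0
DEFAULT_MIN_BLOOD_VAF = 0.005


@dataclass(frozen=True)
class ClassificationModel:
    """Binomial maximum-likelihood framework for one shared variant.

    ``n`` panel clones (all donors except the focal one) contain ``x_exp``
    mutant clones; the focal donor has ``x_obs`` mutant clones among
    ``n_obs``.
    """

    n: int
    x_exp: int
    n_obs: int
    x_obs: int
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if not 0 <= self.x_exp <= self.n:
            raise ValueError("x_exp outside [0, n]")
        if not 0 <= self.x_obs <= self.n_obs:
            raise ValueError("x_obs outside [0, n_obs]")


def ml_rate_and_tail(m: ClassificationModel) -> tuple[float, float]:
    """Maximum-likelihood spontaneous rate and binomial tail probability.

    The binomial likelihood is maximized at p = x_exp / n; the tail is
    P(X >= x_obs) for X ~ Binomial(n_obs, p).
    """
    if m.n <= 0 or m.n_obs <= 0:
        raise ValueError("panel and focal clone counts must be positive")
    if m.x_obs == 0:
        raise ValueError("x_obs = 0: nothing to classify")
    p_hat = m.x_exp / m.n
    tail_p = float(stats.binom.sf(m.x_obs - 1, m.n_obs, p_hat))
    return p_hat, tail_p


def _root_path_length(tree, clone_ids) -> float | None:
    """Nuclear-mutation distance from the root to the MRCA of a clone set."""
    taxa = [t for t in tree.taxon_namespace if t.label in clone_ids]
    if len(taxa) != len(clone_ids):
        return None
    if len(taxa) == 1:
        node = tree.find_node_with_taxon_label(taxa[0].label)
    else:
        node = tree.mrca(taxa=taxa)
    if node is None:
        return None
    total = 0.0
    while node.parent_node is not None:
        total += node.edge.length or 0.0
        node = node.parent_node
    return total


def classify_cohort(
    calls: pd.DataFrame,
    cohort: CohortData,
    alpha: float = DEFAULT_ALPHA,
    full_cohort_size: int | None = None,
    recurrent_individuals: int = DEFAULT_RECURRENT_INDIVIDUALS,
    min_blood_vaf: float = DEFAULT_MIN_BLOOD_VAF,
    late_branch_min_mutations: float = LATE_BRANCH_MIN_MUTATIONS,
) -> pd.DataFrame:
    """Classify every (donor, position, alt) with at least one mutant clone.

    ``calls`` needs columns clone_id, position, alt (reconciled mutant
    calls).  Rules fire in precedence order:

    1. recurrence across donors (>= 2 donors each with >= 2 mutant clones,
       or >= ``recurrent_individuals`` donors of the full cohort, the count
       scaled proportionally when the configured cohort size differs from
       86) -> PZ_recurrent;
    2. mutant clones confined to a late-branching subtree whose ancestor
       accumulated >= 100 nuclear mutations before diverging -> PZ_simple;
    3. shared by >= 2 clones of exactly one donor, absent elsewhere ->
       Het_FE;
    4. shared in one donor, sporadic elsewhere -> binomial tail against the
       ML spontaneous rate: Het_FE when P(X >= x_obs) < alpha, else
       PZ_simple;
    5. singleton shared by the donor's matched bulk tissue -> Het_FE;
    6. otherwise PZ_simple.
    """
    donor_of = {c.clone_id: c.donor_id for c in cohort.clones}
    clones_per_donor = {d: len(cohort.clones_of(d)) for d in cohort.donors}
    if full_cohort_size is None:
        full_cohort_size = DEFAULT_FULL_COHORT_SIZE
    # proportional scaling of the >=10-of-86 rule when the configured panel
    # size differs from the study-scale 86 individuals
    scaled_recurrent = max(
        2, math.ceil(recurrent_individuals * full_cohort_size
                     / DEFAULT_FULL_COHORT_SIZE)
    )

    calls = calls.copy()
    calls["donor_id"] = calls["clone_id"].map(donor_of)
    if calls["donor_id"].isna().any():
        bad = calls.loc[calls["donor_id"].isna(), "clone_id"].unique()
        raise ValueError(f"calls reference unknown clones: {bad[:5]}")

    bulk = cohort.bulk_vafs
    bulk_lookup: dict[tuple[str, int, str], float] = {}
    if bulk is not None:
        for r in bulk.itertuples(index=False):
            key = (r.donor_id, int(r.position), r.alt)
            bulk_lookup[key] = max(bulk_lookup.get(key, 0.0), float(r.vaf))

    rows = []
    grouped = calls.groupby(["position", "alt"])
    for (position, alt), site_calls in grouped:
        per_donor = site_calls.groupby("donor_id")["clone_id"].apply(set)
        donors_with_2plus = (per_donor.str.len() >= 2).sum()
        n_carrier_donors = len(per_donor)

        for donor_id, mutant_clones in per_donor.items():
            x_obs = len(mutant_clones)
            n_obs = clones_per_donor[donor_id]
            x_exp = int(
                site_calls.loc[site_calls["donor_id"] != donor_id, "clone_id"]
                .nunique()
            )
            n_panel = sum(v for d, v in clones_per_donor.items() if d != donor_id)
            tail_p = math.nan
            origin, rule = None, None

            # (1) cross-donor recurrence
            if donors_with_2plus >= 2 or n_carrier_donors >= scaled_recurrent:
                origin, rule = "PZ_recurrent", "recurrent"
            # (2) late-branch override of apparent sharing
            if origin is None and x_obs >= 2:
                tree = cohort.phylogenies.get(donor_id)
                if tree is None:
                    logger.warning(
                        "no phylogeny for donor %s; late-branch rule skipped",
                        donor_id,
                    )
                else:
                    depth = _root_path_length(tree, mutant_clones)
                    if depth is not None and depth >= late_branch_min_mutations:
                        origin, rule = "PZ_simple", "late_branch"
            # (3) exclusively shared in one donor
            if origin is None and x_obs >= 2 and x_exp == 0:
                origin, rule = "Het_FE", "exclusive_sharing"
            # (4) shared here, sporadic elsewhere: binomial framework
            if origin is None and x_obs >= 2:
                model = ClassificationModel(
                    n=n_panel, x_exp=x_exp, n_obs=n_obs, x_obs=x_obs, alpha=alpha
                )
                _, tail_p = ml_rate_and_tail(model)
                if tail_p < alpha:
                    origin, rule = "Het_FE", "binomial"
                else:
                    origin, rule = "PZ_simple", "binomial"
            # (5) singleton shared by matched bulk tissue
            if origin is None:
                bulk_vaf = bulk_lookup.get((donor_id, int(position), alt), 0.0)
                if bulk_vaf >= min_blood_vaf:
                    origin, rule = "Het_FE", "matched_bulk"
            # (6) default
            if origin is None:
                origin, rule = "PZ_simple", "default"

            rows.append({
                "donor_id": donor_id, "position": int(position), "alt": alt,
                "n_mutant_clones": x_obs, "n_donor_clones": n_obs,
                "x_exp": x_exp, "tail_p": tail_p,
                "origin_class": origin, "rule_fired": rule,
            })

    return pd.DataFrame(rows)


def detect_tissue_recurrent(
    calls: pd.DataFrame,
    cohort: CohortData,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag tissue-specific recurrent loci with an age signal.

    A site recurring in >= 2 donors of a tissue is flagged when the ages of
    carrier donors exceed those of non-carrier donors of the same tissue by
    a one-sided Wilcoxon rank-sum test at ``alpha``.
    """
    donor_of = {c.clone_id: c.donor_id for c in cohort.clones}
    donor_meta = {d: (cohort.clones_of(d)[0].tissue, cohort.clones_of(d)[0].donor_age)
                  for d in cohort.donors}
    calls = calls.copy()
    calls["donor_id"] = calls["clone_id"].map(donor_of)
    calls["tissue"] = calls["donor_id"].map(lambda d: donor_meta[d][0])

    rows = []
    for (tissue, position, alt), grp in calls.groupby(["tissue", "position", "alt"]):
        carriers = set(grp["donor_id"])
        if len(carriers) < 2:
            continue
        tissue_donors = [d for d, (t, _) in donor_meta.items() if t == tissue]
        carrier_ages = [donor_meta[d][1] for d in tissue_donors if d in carriers]
        other_ages = [donor_meta[d][1] for d in tissue_donors if d not in carriers]
        if not other_ages:
            continue
        res = stats.mannwhitneyu(
            carrier_ages, other_ages, alternative="greater", method="asymptotic"
        )
        rows.append({
            "tissue": tissue, "position": int(position), "alt": alt,
            "n_carrier_donors": len(carriers), "p_value": float(res.pvalue),
            "flagged": bool(res.pvalue < alpha),
        })
    return pd.DataFrame(
        rows, columns=["tissue", "position", "alt", "n_carrier_donors",
                       "p_value", "flagged"],
    )
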