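"""Heteroplasmy summary statistics.

* caVAF — the clone-averaged VAF of a fertilized-egg variant across all
  clones of a donor (zeros included); an estimator of the heteroplasmy
  level in the fertilized egg.
* F_ST — Wright's fixation index sigma_S^2 / (P(1-P)); quantifies how far
  drift has pushed clone-VAFs toward the 0%/100% extremes.
* S_VAF — per-clone sum of clone-VAFs of detected postzygotic (PZ_simple)
  mutations; a clock-like readout of cumulative turnover.
* strand spectrum — pyrimidine-based substitution counts split by the
  strand of the mutated pyrimidine, inside and outside the replication
  origin region where the asymmetry reverses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MtGenome, PYRIMIDINES, pyrimidine_context

FST_MIN_CAVAF = 0.01
HOMOPLASMY_VAF = 0.9

#: the six pyrimidine-based substitution classes
SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def compute_cavaf(clone_vafs) -> float:
    """Arithmetic mean over all donor clones, zeros included."""
    vafs = np.asarray(clone_vafs, dtype=float)
    if vafs.size == 0:
        raise ValueError("caVAF requires at least one clone")
    return float(vafs.mean())


@dataclass(frozen=True)
class FstResult:
    p_bar: float
    sigma_s_sq: float
    sigma_t_sq: float
    fst: float | None
    computed: bool


def compute_fst(clone_vafs, min_cavaf: float = FST_MIN_CAVAF) -> FstResult:
    """Fixation index of a fertilized-egg variant's clone-VAF vector.

    sigma_S^2 is the population variance (divide by N) of clone-VAFs and
    sigma_T^2 = P(1-P) the Bernoulli variance at the mean; F_ST is computed
    only when the mean clone-VAF exceeds ``min_cavaf``.
    """
    vafs = np.asarray(clone_vafs, dtype=float)
    p_bar = compute_cavaf(vafs)
    sigma_s_sq = float(vafs.var())  # population variance
    sigma_t_sq = p_bar * (1.0 - p_bar)
    if p_bar <= min_cavaf:
        return FstResult(p_bar, sigma_s_sq, sigma_t_sq, None, False)
    if sigma_t_sq == 0.0:
        # all clones fixed at 1: no variance left to normalize
        return FstResult(p_bar, sigma_s_sq, sigma_t_sq, None, False)
    return FstResult(p_bar, sigma_s_sq, sigma_t_sq,
                     float(sigma_s_sq / sigma_t_sq), True)


@dataclass(frozen=True)
class CloneMetrics:
    clone_id: str
    s_vaf: float
    max_clone_vaf: float
    n_mutations: int
    n_homoplasmic: int


def compute_svaf(clone_id: str, classified_vafs: pd.DataFrame) -> CloneMetrics:
    """Per-clone S_VAF over PZ_simple mutations only.

    ``classified_vafs`` needs columns clone_id, vaf, origin_class; rows for
    other clones are ignored, Het_FE and PZ_recurrent are excluded from the
    sum.
    """
    mine = classified_vafs[classified_vafs["clone_id"] == clone_id]
    pz = mine[mine["origin_class"] == "PZ_simple"]
    vafs = pz["vaf"].to_numpy(dtype=float)
    return CloneMetrics(
        clone_id=clone_id,
        s_vaf=float(vafs.sum()),
        max_clone_vaf=float(vafs.max()) if vafs.size else 0.0,
        n_mutations=int(vafs.size),
        n_homoplasmic=int((vafs > HOMOPLASMY_VAF).sum()),
    )


def _substitution_class(ref: str, alt: str) -> tuple[str, str]:
    """(pyrimidine-based type, strand of the mutated pyrimidine).

    The reference sequence is the light strand, so a pyrimidine reference
    base puts the mutated pyrimidine on the light strand.
    """
    strand = "light" if ref in PYRIMIDINES else "heavy"
    pyr_ref, pyr_alt = pyrimidine_context(ref, alt)
    return f"{pyr_ref}>{pyr_alt}", strand


def strand_spectrum(
    variants: pd.DataFrame,
    genome: MtGenome,
    pseudocount: float = 0.0,
) -> dict:
    """Strand-resolved substitution spectrum with per-region log2 ratios.

    ``variants`` needs columns position, ref, alt, variant_type (SNVs are
    used) and optionally tissue.  Counts are tabulated per substitution
    type x strand, separately inside and outside the replication-origin
    region.  log2(heavy/light) ratios are NaN when a count is zero unless a
    pseudocount is supplied.  When a tissue column with >= 2 tissues is
    present, a chi-squared test compares tissue spectra.
    """
    snvs = variants[variants["variant_type"] == "SNV"].copy()
    if snvs.empty:
        raise ValueError("no SNVs to tabulate")
    cls = [_substitution_class(r, a) for r, a in zip(snvs["ref"], snvs["alt"])]
    snvs["sub_type"] = [c[0] for c in cls]
    snvs["strand"] = [c[1] for c in cls]
    snvs["region"] = [
        "origin" if genome.in_origin(int(p)) else "outside"
        for p in snvs["position"]
    ]

    counts = (
        snvs.groupby(["region", "sub_type", "strand"]).size()
        .reindex(
            pd.MultiIndex.from_product(
                [["origin", "outside"], SUBSTITUTION_TYPES, ["heavy", "light"]],
                names=["region", "sub_type", "strand"],
            ),
            fill_value=0,
        )
        .rename("count")
        .reset_index()
    )

    ratio_rows = []
    for (region, sub_type), grp in counts.groupby(["region", "sub_type"]):
        heavy = float(grp.loc[grp["strand"] == "heavy", "count"].iloc[0])
        light = float(grp.loc[grp["strand"] == "light", "count"].iloc[0])
        h, l = heavy + pseudocount, light + pseudocount
        log2_ratio = math.log2(h / l) if h > 0 and l > 0 else math.nan
        ratio_rows.append({
            "region": region, "sub_type": sub_type,
            "heavy": int(heavy), "light": int(light),
            "log2_heavy_light": log2_ratio,
        })
    ratios = pd.DataFrame(ratio_rows)

    chi2_stat = chi2_p = math.nan
    if "tissue" in snvs.columns and snvs["tissue"].nunique() >= 2:
        snvs["type_strand"] = snvs["sub_type"] + "/" + snvs["strand"]
        table = pd.crosstab(snvs["tissue"], snvs["type_strand"])
        table = table.loc[:, table.sum(axis=0) > 0]
        if table.shape[1] >= 2:
            chi2_stat, chi2_p, _, _ = stats.chi2_contingency(table)

    assert int(counts["count"].sum()) == len(snvs)
    return {
        "counts": counts,
        "log2_ratios": ratios,
        "chi2_stat": float(chi2_stat),
        "chi2_p": float(chi2_p),
        "n_snvs": int(len(snvs)),
    }
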