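"""dN/dS against a simulated neutral null on the mitochondrial genome.

Selection on protein-coding mtDNA mutations is tested by comparing the
observed missense/synonymous and truncating/synonymous ratios (normalized
by mutational opportunity) to ratios of the same number of mutations placed
at random on the individual's mtDNA sequence, optionally weighted by the
strand-resolved substitution spectrum.

Because the consequence of a change depends only on (position, alternate
base), placing N independent random mutations and counting consequence
classes is exactly a multinomial draw over the per-class probability
masses; the null is sampled that way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MtGenome, annotate_variant, VariantRecord
from .metrics import _substitution_class
from .drift_sim import as_rng

logger = logging.getLogger(__name__)

CLASSES = ("synonymous", "missense", "truncating", "other")
HIGH_VAF_CUT = 0.9
MIN_VAF_FOR_COMPARISON = 0.1


def _enumerate_changes(genome: MtGenome) -> pd.DataFrame:
    """Every possible SNV (position x 3 alternate bases) with its
    consequence class and pyrimidine substitution type/strand."""
    rows = []
    for pos in range(1, len(genome) + 1):
        ref = genome.base(pos)
        if ref not in "ACGT":
            continue
        for alt in "ACGT":
            if alt == ref:
                continue
            v = annotate_variant(
                VariantRecord(pos, ref, alt, "SNV"), genome
            )
            cons = v.consequence
            cls = cons if cons in ("synonymous", "missense", "truncating") \
                else "other"
            sub_type, strand = _substitution_class(ref, alt)
            rows.append((pos, ref, alt, cls, sub_type, strand))
    return pd.DataFrame(
        rows, columns=["position", "ref", "alt", "cls", "sub_type", "strand"]
    )


def apply_germline(genome: MtGenome, germline) -> MtGenome:
    """Return the genome with germline SNVs (position, alt) substituted."""
    seq = list(genome.sequence)
    for pos, alt in germline:
        seq[pos - 1] = alt
    return MtGenome("".join(seq), genome.features, dloop=genome.dloop,
                    origin=genome.origin, name=genome.name)


def mutation_opportunity(genome: MtGenome, germline=()) -> dict[str, int]:
    """Counts of possible synonymous/missense/truncating changes over all
    CDS positions x 3 alternate bases (exhaustive enumeration)."""
    if germline:
        genome = apply_germline(genome, germline)
    table = _enumerate_changes(genome)
    cds = table[table["cls"].isin(("synonymous", "missense", "truncating"))]
    counts = cds["cls"].value_counts().to_dict()
    return {c: int(counts.get(c, 0))
            for c in ("synonymous", "missense", "truncating")}


@dataclass
class NullDnds:
    missense: np.ndarray
    truncating: np.ndarray
    n_undefined: int
    opportunity: dict[str, int]


def simulate_null_dnds(
    genome: MtGenome,
    n_mutations: int,
    iterations: int = 10_000,
    spectrum_weights: dict | None = None,
    germline=(),
    rng=None,
) -> NullDnds:
    """Null distributions of opportunity-normalized dN/dS ratios.

    ``spectrum_weights`` maps (substitution type like 'C>T', strand) to a
    relative weight; None places mutations uniformly.  Iterations in which
    no synonymous mutation is drawn give an undefined ratio; they are
    excluded and counted.
    """
    if n_mutations < 1:
        raise ValueError("need at least one observed mutation")
    rng = as_rng(rng)
    if germline:
        genome = apply_germline(genome, germline)
    table = _enumerate_changes(genome)
    if spectrum_weights is None:
        table["weight"] = 1.0
    else:
        table["weight"] = [
            float(spectrum_weights.get((t, s), 0.0))
            for t, s in zip(table["sub_type"], table["strand"])
        ]
        if table["weight"].sum() <= 0:
            raise ValueError("spectrum weights give zero total mass")

    mass = table.groupby("cls")["weight"].sum()
    probs = np.array([mass.get(c, 0.0) for c in CLASSES])
    probs = probs / probs.sum()
    opp = mutation_opportunity(genome)
    if opp["synonymous"] == 0:
        raise ValueError("genome offers no synonymous opportunity")

    counts = rng.multinomial(n_mutations, probs, size=iterations)
    syn = counts[:, 0].astype(float)
    defined = syn > 0
    n_undefined = int((~defined).sum())
    if n_undefined:
        logger.info("%d/%d null iterations had no synonymous mutation",
                    n_undefined, iterations)
    syn = syn[defined]
    mis = counts[defined, 1].astype(float)
    trunc = counts[defined, 2].astype(float)
    mis_ratio = (mis / syn) / (opp["missense"] / opp["synonymous"])
    if opp["truncating"] > 0:
        trunc_ratio = (trunc / syn) / (opp["truncating"] / opp["synonymous"])
    else:
        trunc_ratio = np.full(syn.shape, np.nan)
    return NullDnds(mis_ratio, trunc_ratio, n_undefined, opp)


def observed_dnds(variants: pd.DataFrame, opportunity: dict[str, int]) -> dict:
    """Opportunity-normalized observed ratios from an annotated variant
    table (needs a consequence column)."""
    counts = variants["consequence"].value_counts()
    syn = int(counts.get("synonymous", 0))
    mis = int(counts.get("missense", 0))
    trunc = int(counts.get("truncating", 0))
    out = {"n_synonymous": syn, "n_missense": mis, "n_truncating": trunc}
    if syn > 0:
        out["missense_dnds"] = (mis / syn) / (
            opportunity["missense"] / opportunity["synonymous"])
        out["truncating_dnds"] = (trunc / syn) / (
            opportunity["truncating"] / opportunity["synonymous"]) \
            if opportunity["truncating"] else float("nan")
    else:
        out["missense_dnds"] = float("nan")
        out["truncating_dnds"] = float("nan")
    return out


def dnds_report(
    variants: pd.DataFrame,
    genome: MtGenome,
    iterations: int = 10_000,
    spectrum_weights: dict | None = None,
    rng=None,
) -> dict:
    """Per-tissue dN/dS report with simulated nulls and the high-VAF
    truncating-vs-synonymous comparison.

    ``variants`` needs columns tissue, donor_id, consequence, vaf and
    variant_type; only SNVs enter the ratios.  The null for a tissue pools
    per-donor simulations at each donor's observed mutation count.  The
    clone-VAF comparison restricts to VAF >= 0.1 and applies a two-sided
    Fisher exact test to the proportion of mutations above 0.9 VAF
    (truncating vs synonymous).
    """
    rng = as_rng(rng)
    opp = mutation_opportunity(genome)
    snvs = variants[variants["variant_type"] == "SNV"]
    report: dict[str, dict] = {}
    for tissue, tgroup in snvs.groupby("tissue"):
        entry: dict = {"opportunity": opp}
        entry.update(observed_dnds(tgroup, opp))

        mis_null, trunc_null = [], []
        for _, dgroup in tgroup.groupby("donor_id"):
            n_mut = len(dgroup)
            if n_mut == 0:
                continue
            null = simulate_null_dnds(
                genome, n_mut, iterations=iterations,
                spectrum_weights=spectrum_weights, rng=rng,
            )
            mis_null.append(null.missense)
            trunc_null.append(null.truncating)
        if mis_null:
            width = min(len(a) for a in mis_null)
            mis_stack = np.mean([a[:width] for a in mis_null], axis=0)
            trunc_stack = np.mean([a[:width] for a in trunc_null], axis=0)
            entry["null_missense_iqr"] = (
                float(np.nanpercentile(mis_stack, 25)),
                float(np.nanpercentile(mis_stack, 75)),
            )
            entry["null_truncating_iqr"] = (
                float(np.nanpercentile(trunc_stack, 25)),
                float(np.nanpercentile(trunc_stack, 75)),
            )
            if np.isfinite(entry["missense_dnds"]):
                entry["missense_percentile"] = float(
                    np.mean(mis_stack <= entry["missense_dnds"]))
            if np.isfinite(entry["truncating_dnds"]):
                entry["truncating_percentile"] = float(
                    np.nanmean(trunc_stack <= entry["truncating_dnds"]))

        high = tgroup[tgroup["vaf"] >= MIN_VAF_FOR_COMPARISON]
        syn_high = high[high["consequence"] == "synonymous"]
        trunc_high = high[high["consequence"] == "truncating"]
        if len(syn_high) and len(trunc_high):
            contingency = [
                [int((trunc_high["vaf"] > HIGH_VAF_CUT).sum()),
                 int((trunc_high["vaf"] <= HIGH_VAF_CUT).sum())],
                [int((syn_high["vaf"] > HIGH_VAF_CUT).sum()),
                 int((syn_high["vaf"] <= HIGH_VAF_CUT).sum())],
            ]
            _, p = stats.fisher_exact(contingency, alternative="two-sided")
            entry["high_vaf_fisher_p"] = float(p)
            entry["high_vaf_table"] = contingency
        report[tissue] = entry
    return report
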