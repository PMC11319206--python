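"""Truth-labeled synthetic mtDNA cohorts.

The generator emulates the structure of a single-clone whole-genome cohort:
fertilized-egg heteroplasmies drifting under a chosen turnover model and
rate, postzygotic mutations accumulating at a per-bp-per-replication rate
through the genotype-faithful simulation engine, hotspot loci recurring
across donors, locus-specific sequencing noise under a realistic depth
model, clone phylogenies with early- and late-branching lineages, and
matched bulk-tissue VAFs.  Everything is written in the formats ``core_io``
reads, alongside a truth table, so every pipeline stage can be tested
without any sequencing download.

Defaults reflect the cohort being emulated: 750 basal mtDNA copies per
cell, ~15 mitotic turnovers per year, a mutation rate of 5.0e-8 per bp per
replication, ~6,000x mean mtDNA depth with a lognormal spread, and a
practical detection floor of 0.3% VAF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_io
from .core_io import CohortData, GeneFeature, MtGenome, write_genome
from .drift_sim import (
    SimulationConfig,
    as_rng,
    mitotic_turnover_counts,
    homeostatic_turnover_counts,
    simulate_mutation_accumulation,
)
from .read_filters import (
    BLACKLIST_RANGES,
    NOISY_INDEL_POSITIONS,
    ReadSupportSummary,
    in_blacklist,
)

_SENSE_CODONS = None


def _sense_codons() -> list[str]:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        bases = "ACGT"
        stops = set(core_io.MT_CODON_TABLE.stop_codons)
        _SENSE_CODONS = [
            a + b + c
            for a in bases for b in bases for c in bases
            if a + b + c not in stops
        ]
    return _SENSE_CODONS


def generate_toy_genome(
    seed=None,
    n_genes: int = 3,
    length: int = 1_200,
    outdir: str | Path | None = None,
    rng=None,
) -> MtGenome:
    """A small circular genome with CDS/tRNA/rRNA features on both strands.

    CDSs start with ATG, contain random sense codons under the vertebrate
    mitochondrial code and end with TAA; a control region and a replication
    origin wrap the coordinate origin.  Deterministic under a fixed seed.
    """
    if length < 300:
        raise ValueError("toy genome length must be >= 300")
    rng = as_rng(seed if rng is None else rng)
    n_codons = 30
    cds_len = 3 * n_codons
    spacer = 12
    trna_len, rrna_len = 70, 120
    needed = 60 + n_genes * (cds_len + spacer) + trna_len + rrna_len + 2 * spacer + 110
    if needed > length:
        raise ValueError(
            f"cannot pack {n_genes} genes into {length} bp (needs {needed})"
        )

    seq = list(rng.choice(list("ACGT"), size=length))
    features: list[GeneFeature] = []
    cursor = 60
    codons = _sense_codons()
    for i in range(n_genes):
        strand = "+" if i % 2 == 0 else "-"
        coding = "ATG" + "".join(rng.choice(codons, size=n_codons - 2)) + "TAA"
        start, end = cursor, cursor + cds_len - 1
        if strand == "+":
            seq[start - 1:end] = list(coding)
        else:
            seq[start - 1:end] = list(core_io.reverse_complement(coding))
        features.append(GeneFeature(f"GENE{i + 1}", start, end, strand, "CDS"))
        cursor = end + 1 + spacer
    features.append(GeneFeature("TRN1", cursor, cursor + trna_len - 1, "+", "tRNA"))
    cursor += trna_len + spacer
    features.append(GeneFeature("RNR1", cursor, cursor + rrna_len - 1, "-", "rRNA"))

    genome = MtGenome(
        "".join(seq),
        tuple(features),
        dloop=(length - 80, 40),
        origin=(length - 40, 15),
        name=f"toy_mt_{length}",
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genome(genome, outdir / "genome.fa", outdir / "annotation.tsv")
    return genome


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DonorConfig:
    donor_id: str
    tissue: str = "colon"
    age: float = 50.0
    n_clones: int = 25
    copy_number: int = 750
    turnover_model: str = "mitotic"
    turnover_rate: float = 15.0  # turnovers per year
    egg_variants: tuple[tuple[int, float], ...] = ()  # (position, egg VAF)
    late_clade: tuple[int, float] | None = None  # (clade size, stem length)


@dataclass(frozen=True)
class CohortConfig:
    donors: tuple[DonorConfig, ...]
    mutation_rate: float = 5.0e-8  # per bp per replication
    mean_depth: float = 6_000.0
    depth_log_sigma: float = 0.5
    hotspots: tuple[tuple[int, float], ...] = ()  # (position, carrier prob)
    n_noise_sites: int = 60
    noisy_site_fraction: float = 0.15
    # background error rates: most loci sit at the bottom of the 0.05%-15%
    # thresholding window, a minority are strongly elevated (repeats, NUMTs)
    quiet_noise_range: tuple[float, float] = (2.0e-4, 1.2e-3)
    noisy_noise_range: tuple[float, float] = (1.2e-3, 5.0e-3)
    detection_floor: float = 0.003
    caller_miss_rate: float = 0.02
    seed: int | None = None


@dataclass
class TruthTable:
    """Ground truth behind a generated cohort."""

    variants: pd.DataFrame  # clone-level true frequencies and classes
    donors: pd.DataFrame    # per-donor true rates and turnover counts

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.variants.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.donors.to_csv(outdir / "truth_donors.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# phylogenies
# ---------------------------------------------------------------------------

def _random_subtree(leaves: list[str], rng, internal_low=1, internal_high=8,
                    terminal_length: float = 400.0) -> str:
    """Random binary newick subtree; internal edges short (early lineage
    splits carry few nuclear mutations), terminal edges long."""
    nodes = [f"{leaf}:{terminal_length + rng.integers(0, 200)}"
             for leaf in leaves]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        length = rng.integers(internal_low, internal_high + 1)
        merged = f"({a},{b}):{length}"
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(merged)
    return nodes[0]


def donor_phylogeny_newick(clone_ids: list[str], rng,
                           late_clade: tuple[int, float] | None = None,
                           terminal_length: float = 400.0) -> str:
    """Rooted newick with branch lengths in nuclear mutation counts.

    The first split sits a couple of mutations from the root (mirroring the
    first cell division in life); an optional late-branching clade attaches
    under a long stem so its MRCA is developmentally deep.
    """
    clones = list(clone_ids)
    if len(clones) == 1:
        return f"({clones[0]}:{terminal_length});"
    late_part = None
    if late_clade is not None:
        size, stem = late_clade
        if size >= len(clones) or size < 1:
            raise ValueError("late clade size must leave clones outside it")
        clade, clones = clones[-size:], clones[:-size]
        if size == 1:
            late_part = f"{clade[0]}:{stem + terminal_length}"
        else:
            late_part = (
                f"({_random_subtree(clade, rng, terminal_length=50.0)})"
                f":{stem}"
            )
    half = max(1, len(clones) // 2)
    left = _random_subtree(clones[:half], rng, terminal_length=terminal_length)
    right_leaves = clones[half:]
    parts = [f"({left}):2"]
    if right_leaves:
        right = _random_subtree(right_leaves, rng,
                                terminal_length=terminal_length)
        parts.append(f"({right}):3")
    if late_part is not None:
        parts.append(late_part)
    return f"({','.join(parts)});"


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _drift_frequencies(p0: float, n: int, g: int, n_clones: int, model: str,
                       rng) -> np.ndarray:
    k = np.full(n_clones, int(round(p0 * n)), dtype=np.int64)
    for _ in range(g):
        if model == "mitotic":
            k = mitotic_turnover_counts(k, n, rng)
        else:
            k = homeostatic_turnover_counts(k, n, rng)
    return k / n


def _pick_alt(ref: str, rng) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[rng.integers(3)]


def generate_cohort(
    config: CohortConfig,
    genome: MtGenome,
    rng=None,
    outdir: str | Path | None = None,
) -> tuple[CohortData, TruthTable, pd.DataFrame]:
    """Generate a synthetic cohort, its truth table and the upstream call
    set (pre-reconciliation).

    Per donor, fertilized-egg variants drift for (rate x age) turnovers,
    postzygotic mutations accumulate through the genotype engine, and
    hotspot variants recur across donors.  Observed allele counts are
    binomial draws at lognormal per-clone depths with per-(locus, alt)
    background error rates from a two-component mixture; callers "call"
    any VAF above the detection floor, with a small miss rate on true
    variants so reconciliation has false negatives to rescue.
    """
    rng = as_rng(config.seed if rng is None else rng)
    L = len(genome)
    used_positions: set[int] = set()
    clone_rows = []
    truth_rows = []
    donor_rows = []
    site_alt: dict[int, str] = {}
    # per (position, alt): per-clone true frequency (global clone index)
    truth_freq: dict[tuple[int, str], dict[int, float]] = {}
    clone_index: dict[str, int] = {}
    trees: dict[str, str] = {}
    bulk_rows = []

    hotspot_sites = []
    for pos, prob in config.hotspots:
        ref = genome.base(pos)
        alt = _pick_alt(ref, rng)
        site_alt[pos] = alt
        used_positions.add(pos)
        hotspot_sites.append((pos, alt, prob))

    for donor in config.donors:
        g = int(round(donor.turnover_rate * donor.age))
        donor_rows.append({
            "donor_id": donor.donor_id, "tissue": donor.tissue,
            "age": donor.age, "n_clones": donor.n_clones,
            "copy_number": donor.copy_number, "model": donor.turnover_model,
            "turnover_rate": donor.turnover_rate,
            "mutation_rate": config.mutation_rate, "g": g,
        })
        clone_ids = [f"{donor.donor_id}_c{i:03d}"
                     for i in range(donor.n_clones)]
        for cid in clone_ids:
            clone_index[cid] = len(clone_index)
        # clone metadata; mt coverage consistent with the copy number
        for cid in clone_ids:
            cov_n = float(rng.uniform(15, 40))
            clone_rows.append({
                "clone_id": cid, "donor_id": donor.donor_id,
                "tissue": donor.tissue, "donor_age": donor.age,
                "mean_coverage_nuclear": round(cov_n, 2),
                "mean_coverage_mt": round(cov_n * donor.copy_number / 2, 1),
                "nuclear_clonality_vaf": round(float(rng.uniform(0.42, 0.5)), 3),
            })

        # fertilized-egg variants: shared drift from the egg frequency
        for pos, egg_vaf in donor.egg_variants:
            if pos in used_positions and pos not in site_alt:
                raise ValueError(f"position {pos} reused")
            ref = genome.base(pos)
            alt = site_alt.setdefault(pos, _pick_alt(ref, rng))
            used_positions.add(pos)
            freqs = _drift_frequencies(
                egg_vaf, donor.copy_number, g, donor.n_clones,
                donor.turnover_model, rng,
            )
            per_clone = truth_freq.setdefault((pos, alt), {})
            for cid, f in zip(clone_ids, freqs):
                if f > 0:
                    per_clone[clone_index[cid]] = float(f)
                truth_rows.append({
                    "donor_id": donor.donor_id, "clone_id": cid,
                    "position": pos, "alt": alt, "true_class": "Het_FE",
                    "egg_vaf": egg_vaf, "true_freq": float(f),
                })
            bulk_rows.append({
                "donor_id": donor.donor_id, "tissue": "blood",
                "position": pos, "alt": alt,
                "vaf": float(np.clip(egg_vaf + rng.normal(0, 0.01), 0, 1)),
            })

        # postzygotic mutations: genotype-faithful accumulation per clone
        if config.mutation_rate > 0 and g > 0:
            cfg = SimulationConfig(
                n=donor.copy_number, p0=0.0, g_max=g,
                n_cells=donor.n_clones, model=donor.turnover_model,
                r=config.mutation_rate, L=L,
            )
            ledger, _ = simulate_mutation_accumulation(cfg, rng=rng)
            for cid, counts in zip(clone_ids, ledger.cell_mutation_counts):
                for _, count in counts.items():
                    freq = count / donor.copy_number
                    if freq < 1e-3:
                        continue
                    pos = int(rng.integers(1, L + 1))
                    tries = 0
                    while pos in used_positions and tries < 50:
                        pos = int(rng.integers(1, L + 1))
                        tries += 1
                    if pos in used_positions:
                        continue  # toy genome saturated
                    used_positions.add(pos)
                    ref = genome.base(pos)
                    alt = site_alt.setdefault(pos, _pick_alt(ref, rng))
                    truth_freq.setdefault((pos, alt), {})[
                        clone_index[cid]] = freq
                    truth_rows.append({
                        "donor_id": donor.donor_id, "clone_id": cid,
                        "position": pos, "alt": alt,
                        "true_class": "PZ_simple", "egg_vaf": np.nan,
                        "true_freq": freq,
                    })

        # hotspot recurrences
        for pos, alt, prob in hotspot_sites:
            carriers = rng.random(donor.n_clones) < prob
            for cid, carrier in zip(clone_ids, carriers):
                if not carrier:
                    continue
                freq = float(rng.uniform(0.01, 0.4))
                truth_freq.setdefault((pos, alt), {})[clone_index[cid]] = freq
                truth_rows.append({
                    "donor_id": donor.donor_id, "clone_id": cid,
                    "position": pos, "alt": alt,
                    "true_class": "PZ_recurrent", "egg_vaf": np.nan,
                    "true_freq": freq,
                })

        trees[donor.donor_id] = donor_phylogeny_newick(
            clone_ids, rng, late_clade=donor.late_clade,
            terminal_length=max(200.0, 20.0 * donor.age),
        )

    # background-noise-only sites
    free = np.array([p for p in range(1, L + 1) if p not in used_positions])
    rng.shuffle(free)
    for pos in free[:config.n_noise_sites]:
        pos = int(pos)
        ref = genome.base(pos)
        site_alt[pos] = _pick_alt(ref, rng)
        truth_freq.setdefault((pos, site_alt[pos]), {})

    # per-site noise rates: two-component mixture
    sites = sorted(truth_freq)
    noise_rate = {}
    for site in sites:
        if rng.random() < config.noisy_site_fraction:
            lo, hi = config.noisy_noise_range
        else:
            lo, hi = config.quiet_noise_range
        noise_rate[site] = float(rng.uniform(lo, hi))

    # observations
    all_clones = list(clone_index)
    n_clones_total = len(all_clones)
    mu = np.log(config.mean_depth) - config.depth_log_sigma ** 2 / 2
    variant_rows = []
    call_rows = []
    for s_idx, (pos, alt) in enumerate(sites):
        ref = genome.base(pos)
        per_clone = truth_freq[(pos, alt)]
        err = noise_rate[(pos, alt)]
        depths = np.maximum(
            rng.lognormal(mu, config.depth_log_sigma, n_clones_total), 50
        ).astype(np.int64)
        freqs = np.zeros(n_clones_total)
        for ci, f in per_clone.items():
            freqs[ci] = f
        p = np.clip(freqs + err, 0.0, 1.0)
        alt_counts = rng.binomial(depths, p)
        vafs = alt_counts / depths
        miss = rng.random(n_clones_total) < config.caller_miss_rate
        for ci, cid in enumerate(all_clones):
            if alt_counts[ci] == 0:
                continue
            variant_rows.append({
                "clone_id": cid, "position": pos, "ref": ref, "alt": alt,
                "variant_type": "SNV", "vaf": float(vafs[ci]),
                "alt_count": int(alt_counts[ci]), "depth": int(depths[ci]),
            })
            is_true = freqs[ci] > 0
            called = vafs[ci] >= config.detection_floor and not (
                is_true and miss[ci])
            if called:
                call_rows.append({
                    "clone_id": cid, "position": pos, "alt": alt,
                    "vaf": float(vafs[ci]),
                })

    variants = pd.DataFrame(
        variant_rows, columns=core_io.VARIANT_COLUMNS
    )
    calls = pd.DataFrame(call_rows,
                         columns=["clone_id", "position", "alt", "vaf"])

    clones = [core_io.CloneRecord(**row) for row in clone_rows]
    import dendropy
    phylogenies = {}
    for donor, newick in trees.items():
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        tree.is_rooted = True
        phylogenies[donor] = tree
    bulk = pd.DataFrame(
        bulk_rows, columns=["donor_id", "tissue", "position", "alt", "vaf"]
    ) if bulk_rows else None
    cohort = CohortData(
        clones=clones, variants=variants, phylogenies=phylogenies,
        bulk_vafs=bulk,
    )
    truth = TruthTable(
        variants=pd.DataFrame(
            truth_rows,
            columns=["donor_id", "clone_id", "position", "alt",
                     "true_class", "egg_vaf", "true_freq"],
        ),
        donors=pd.DataFrame(donor_rows),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cohort.write(outdir)
        calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
        truth.write(outdir)
        write_genome(genome, outdir / "genome.fa", outdir / "annotation.tsv")
    return cohort, truth, calls


def example_config(seed: int = 0) -> CohortConfig:
    """A compact three-tissue cohort with study-like per-donor conditions."""
    donors = (
        DonorConfig("HC01", "colon", 50.0, 25, egg_variants=((40, 0.25),)),
        DonorConfig("HC02", "colon", 75.0, 25),
        DonorConfig("DB01", "fibroblast", 60.0, 20,
                    egg_variants=((45, 0.10),)),
        DonorConfig("KX01", "HSPC", 30.0, 30),
    )
    return CohortConfig(donors=donors, hotspots=((55, 0.15),), seed=seed)


# ---------------------------------------------------------------------------
# read-support plans
# ---------------------------------------------------------------------------

_VIOLATION_FIELDS = {
    "low_mapq": {"mean_mapq": 20.0},
    "low_baseq": {"mean_baseq": 10.0},
    "skewed_read_position": {"mean_position_fraction": 0.05},
    "strand_imbalance": {"forward_fraction": 0.02},
    "excess_mismatches": {"max_mismatches": 6},
    "improper_pairing": {"pairing_ok": False},
    "additional_indels": {"frac_additional_indels": 0.8},
}


def generate_read_support(plan: pd.DataFrame, rng=None) -> list[dict]:
    """Read-support summaries violating exactly the planned criteria.

    ``plan`` rows carry position, variant_type and a ``violations`` field
    (comma-separated or iterable).  Positional reasons (blacklist,
    noisy_indel_locus) must agree with the position, else the plan is
    contradictory.
    """
    del rng  # summaries are deterministic given the plan
    out = []
    for _, row in plan.iterrows():
        violations = row["violations"]
        if isinstance(violations, str):
            violations = [v for v in violations.split(",") if v]
        violations = list(violations)
        position = int(row["position"])
        vtype = row["variant_type"]

        if ("blacklist" in violations) != in_blacklist(position):
            raise ValueError(
                f"plan at position {position} inconsistent with blacklist"
            )
        noisy = vtype in ("insertion", "deletion") and \
            position in NOISY_INDEL_POSITIONS
        if ("noisy_indel_locus" in violations) != noisy:
            raise ValueError(
                f"plan at position {position} inconsistent with noisy "
                f"InDel loci"
            )
        fields = {
            "mean_mapq": 60.0, "mean_baseq": 35.0,
            "mean_position_fraction": 0.5, "forward_fraction": 0.5,
            "max_mismatches": 1, "pairing_ok": True,
            "frac_additional_indels":
                0.1 if vtype in ("insertion", "deletion") else None,
        }
        for violation in violations:
            if violation in ("blacklist", "noisy_indel_locus"):
                continue
            if violation not in _VIOLATION_FIELDS:
                raise ValueError(f"unknown violation {violation!r}")
            if violation == "additional_indels" and vtype == "SNV":
                raise ValueError("additional_indels plan on an SNV")
            fields.update(_VIOLATION_FIELDS[violation])
        out.append({
            "position": position, "variant_type": vtype,
            "violations": tuple(sorted(violations)),
            "summary": ReadSupportSummary(**fields),
        })
    return out


__all__ = [
    "DonorConfig", "CohortConfig", "TruthTable",
    "generate_toy_genome", "generate_cohort", "generate_read_support",
    "donor_phylogeny_newick", "example_config", "BLACKLIST_RANGES",
]
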