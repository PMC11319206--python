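"""Domain types and file IO for single-clone mtDNA cohorts.

Coordinates are 1-based inclusive positions on a circular mitochondrial
reference (rCRS numbering for the real genome, L = 16,569).  Intervals may
wrap through the origin of the coordinate system, e.g. the heavy-strand
replication origin m.16,197-191; they are stored wrapped and unwrapped
internally.

The reference sequence is taken to be the light strand (the C-rich strand,
as in the rCRS deposit); the heavy strand is its complement.  A base
substitution is assigned to the strand that carries the mutated pyrimidine.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

RCRS_LENGTH = 16_569
RCRS_DLOOP = (16_024, 576)
RCRS_ORIGIN = (16_197, 191)

#: vertebrate mitochondrial genetic code
MT_CODON_TABLE = CodonTable.unambiguous_dna_by_id[2]

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

VARIANT_COLUMNS = [
    "clone_id", "position", "ref", "alt", "variant_type",
    "vaf", "alt_count", "depth",
]
METADATA_COLUMNS = [
    "clone_id", "donor_id", "tissue", "donor_age",
    "mean_coverage_nuclear", "mean_coverage_mt", "nuclear_clonality_vaf",
]

#: retention thresholds for clone clonality / nuclear quality
CLONALITY_MIN_VAF = 0.4
MIN_NUCLEAR_COVERAGE = 10.0


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature, 1-based inclusive, possibly wrapping."""

    name: str
    start: int
    end: int
    strand: str  # '+' on the reference (light) strand, '-' on the heavy
    feature: str  # CDS | tRNA | rRNA | noncoding

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.feature not in {"CDS", "tRNA", "rRNA", "noncoding"}:
            raise ValueError(f"unknown feature kind {self.feature!r}")


def interval_positions(start: int, end: int, length: int) -> list[int]:
    """Unwrap a circular 1-based inclusive interval into a position list."""
    if start <= end:
        return list(range(start, end + 1))
    return list(range(start, length + 1)) + list(range(1, end + 1))


def interval_contains(interval: tuple[int, int] | None, pos: int, length: int) -> bool:
    if interval is None:
        return False
    start, end = interval
    if start <= end:
        return start <= pos <= end
    return pos >= start or pos <= end


@dataclass(frozen=True)
class MtGenome:
    """A circular mitochondrial genome with gene annotations.

    ``dloop`` and ``origin`` are optional control-region / replication-origin
    intervals (wrapping allowed); they default to the rCRS coordinates when a
    genome of rCRS length is loaded.
    """

    sequence: str
    features: tuple[GeneFeature, ...]
    dloop: tuple[int, int] | None = None
    origin: tuple[int, int] | None = None
    name: str = "mtDNA"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) == 0:
            raise ValueError("empty genome sequence")
        for feat in self.features:
            for bound in (feat.start, feat.end):
                if not 1 <= bound <= len(seq):
                    raise ValueError(
                        f"feature {feat.name} bound {bound} outside [1, {len(seq)}]"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        if not 1 <= pos <= len(self):
            raise ValueError(f"position {pos} outside [1, {len(self)}]")
        return self.sequence[pos - 1]

    def in_dloop(self, pos: int) -> bool:
        return interval_contains(self.dloop, pos, len(self))

    def in_origin(self, pos: int) -> bool:
        return interval_contains(self.origin, pos, len(self))

    def features_at(self, pos: int) -> list[GeneFeature]:
        return [
            f for f in self.features
            if interval_contains((f.start, f.end), pos, len(self))
        ]

    def cds_features(self) -> list[GeneFeature]:
        return [f for f in self.features if f.feature == "CDS"]

    def coding_sequence(self, feat: GeneFeature) -> str:
        """Coding-strand nucleotide sequence of a feature (5'->3')."""
        raw = "".join(
            self.sequence[p - 1]
            for p in interval_positions(feat.start, feat.end, len(self))
        )
        return reverse_complement(raw) if feat.strand == "-" else raw

    def codon_at(self, feat: GeneFeature, pos: int) -> tuple[str, int, list[int]]:
        """Return (codon, offset-within-codon, genome positions of the codon)
        for a genome position inside a CDS, all in coding orientation."""
        positions = interval_positions(feat.start, feat.end, len(self))
        if feat.strand == "-":
            positions = positions[::-1]
        try:
            idx = positions.index(pos)
        except ValueError:
            raise ValueError(f"position {pos} not inside CDS {feat.name}") from None
        codon_idx, offset = divmod(idx, 3)
        codon_positions = positions[3 * codon_idx: 3 * codon_idx + 3]
        codon = "".join(
            self.base(p) if feat.strand == "+" else complement(self.base(p))
            for p in codon_positions
        )
        return codon, offset, codon_positions


def translate_codon(codon: str) -> str:
    """Translate under the vertebrate mitochondrial code; '*' for stops.

    Incomplete terminal codons ('T', 'TA'), completed to stops by
    polyadenylation in mitochondrial transcripts, translate as '*'.
    """
    codon = codon.upper()
    if codon in ("T", "TA"):
        return "*"
    if len(codon) != 3:
        raise ValueError(f"cannot translate codon {codon!r}")
    if codon in MT_CODON_TABLE.stop_codons:
        return "*"
    return MT_CODON_TABLE.forward_table[codon]


def load_genome(
    fasta_path: str | Path,
    annotation_path: str | Path,
    dloop: tuple[int, int] | None = None,
    origin: tuple[int, int] | None = None,
) -> MtGenome:
    """Load a genome from FASTA plus a feature TSV
    (columns: name, start, end, strand, feature)."""
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    seq = str(record.seq).upper()
    ann = pd.read_csv(annotation_path, sep="\t")
    required = {"name", "start", "end", "strand", "feature"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    features = tuple(
        GeneFeature(row["name"], int(row["start"]), int(row["end"]),
                    str(row["strand"]), str(row["feature"]))
        for _, row in ann.iterrows()
    )
    if dloop is None and len(seq) == RCRS_LENGTH:
        dloop = RCRS_DLOOP
    if origin is None and len(seq) == RCRS_LENGTH:
        origin = RCRS_ORIGIN
    return MtGenome(seq, features, dloop=dloop, origin=origin, name=record.id)


def write_genome(genome: MtGenome, fasta_path: str | Path,
                 annotation_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.name}\n")
        for i in range(0, len(genome.sequence), 70):
            fh.write(genome.sequence[i:i + 70] + "\n")
    pd.DataFrame(
        [
            {"name": f.name, "start": f.start, "end": f.end,
             "strand": f.strand, "feature": f.feature}
            for f in genome.features
        ]
    ).to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variants and clones
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """One mtDNA alteration, optionally annotated and origin-classified."""

    position: int
    ref_allele: str
    alt_allele: str
    variant_type: str  # SNV | insertion | deletion
    clone_vaf: float | None = None
    consequence: str | None = None  # synonymous|missense|truncating|tRNA|rRNA|noncoding
    strand_class: str | None = None  # heavy | light (SNVs only)
    origin_class: str = "unclassified"
    in_dloop: bool = False
    in_origin: bool = False

    def __post_init__(self) -> None:
        if self.variant_type not in {"SNV", "insertion", "deletion"}:
            raise ValueError(f"unknown variant_type {self.variant_type!r}")
        if self.clone_vaf is not None and not 0.0 <= self.clone_vaf <= 1.0:
            raise ValueError(f"clone_vaf {self.clone_vaf} outside [0, 1]")


def variant_type_of(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    return "insertion" if len(alt) > len(ref) else "deletion"


def pyrimidine_context(ref: str, alt: str) -> tuple[str, str]:
    """Express an SNV with the mutated base as a pyrimidine: C>T stays C>T,
    G>A becomes C>T on the opposite strand."""
    if ref in PYRIMIDINES:
        return ref, alt
    return complement(ref), complement(alt)


def annotate_variant(v: VariantRecord, genome: MtGenome) -> VariantRecord:
    """Assign consequence, strand class and region flags to a variant.

    Consequence precedence when features overlap: CDS > tRNA > rRNA >
    noncoding.  Truncating = stop-gain SNV or frameshift InDel inside a CDS;
    in-frame InDels in a CDS are counted as missense.
    """
    ref_base = genome.base(v.position)
    if v.ref_allele[0] != ref_base:
        raise ValueError(
            f"reference allele {v.ref_allele!r} inconsistent with genome base "
            f"{ref_base!r} at position {v.position}"
        )

    strand_class = None
    if v.variant_type == "SNV":
        # mutated pyrimidine on the reference strand -> light, else heavy
        strand_class = "light" if v.ref_allele in PYRIMIDINES else "heavy"

    feats = genome.features_at(v.position)
    consequence = "noncoding"
    cds = [f for f in feats if f.feature == "CDS"]
    if cds:
        feat = cds[0]
        if v.variant_type == "SNV":
            codon, offset, _ = genome.codon_at(feat, v.position)
            alt_coding = (v.alt_allele if feat.strand == "+"
                          else complement(v.alt_allele))
            new_codon = codon[:offset] + alt_coding + codon[offset + 1:]
            old_aa = translate_codon(codon) if len(codon) == 3 else "*"
            new_aa = translate_codon(new_codon) if len(new_codon) == 3 else "*"
            if new_aa == "*" and old_aa != "*":
                consequence = "truncating"
            elif new_aa == old_aa:
                consequence = "synonymous"
            else:
                consequence = "missense"
        else:
            shift = abs(len(v.alt_allele) - len(v.ref_allele)) % 3
            consequence = "truncating" if shift != 0 else "missense"
    elif any(f.feature == "tRNA" for f in feats):
        consequence = "tRNA"
    elif any(f.feature == "rRNA" for f in feats):
        consequence = "rRNA"

    return replace(
        v,
        consequence=consequence,
        strand_class=strand_class,
        in_dloop=genome.in_dloop(v.position),
        in_origin=genome.in_origin(v.position),
    )


@dataclass(frozen=True)
class CloneRecord:
    clone_id: str
    donor_id: str
    tissue: str
    donor_age: float
    mean_coverage_nuclear: float
    mean_coverage_mt: float
    nuclear_clonality_vaf: float

    def __post_init__(self) -> None:
        if self.mean_coverage_nuclear <= 0 or self.mean_coverage_mt <= 0:
            raise ValueError(f"clone {self.clone_id}: coverages must be > 0")

    @property
    def passes_clonality_filter(self) -> bool:
        return (self.nuclear_clonality_vaf > CLONALITY_MIN_VAF
                and self.mean_coverage_nuclear > MIN_NUCLEAR_COVERAGE)


@dataclass(frozen=True)
class CoverageSummary:
    coverage_mt: float
    coverage_n: float


def mtdna_copy_number(c: CoverageSummary) -> float:
    """mtDNA copies per diploid nuclear genome: coverage_mt / coverage_n * 2,
    with nuclear ploidy fixed at two."""
    if c.coverage_n <= 0 or c.coverage_mt <= 0:
        raise ValueError("coverages must be positive")
    return c.coverage_mt / c.coverage_n * 2.0


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

@dataclass
class CohortData:
    """A cohort of clones with their per-(position, alt) VAF observations.

    ``variants`` is a long-format frame with columns ``VARIANT_COLUMNS``;
    it may include zero/noise-level rows for non-carrier clones, which the
    noise panel relies on.  ``phylogenies`` maps donor id to a rooted
    dendropy tree whose leaves are clone ids and whose branch lengths are
    nuclear somatic mutation counts.
    """

    clones: list[CloneRecord]
    variants: pd.DataFrame
    phylogenies: dict[str, dendropy.Tree] = field(default_factory=dict)
    bulk_vafs: pd.DataFrame | None = None
    excluded_clones: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing:
            raise ValueError(f"variant table missing columns: {sorted(missing)}")
        known = {c.clone_id for c in self.clones}
        unknown = set(self.variants["clone_id"]) - known
        if unknown:
            raise ValueError(
                f"variant rows reference clones absent from metadata: "
                f"{sorted(unknown)[:5]}"
            )
        bad = self.variants[(self.variants["vaf"] < 0) | (self.variants["vaf"] > 1)]
        if len(bad):
            raise ValueError("VAFs outside [0, 1] in variant table")

    @property
    def clone_ids(self) -> list[str]:
        return [c.clone_id for c in self.clones]

    @property
    def donors(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.clones:
            seen.setdefault(c.donor_id, None)
        return list(seen)

    def clones_of(self, donor_id: str) -> list[CloneRecord]:
        return [c for c in self.clones if c.donor_id == donor_id]

    def clone(self, clone_id: str) -> CloneRecord:
        for c in self.clones:
            if c.clone_id == clone_id:
                return c
        raise KeyError(clone_id)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "clone_id": c.clone_id, "donor_id": c.donor_id,
                "tissue": c.tissue, "donor_age": c.donor_age,
                "mean_coverage_nuclear": c.mean_coverage_nuclear,
                "mean_coverage_mt": c.mean_coverage_mt,
                "nuclear_clonality_vaf": c.nuclear_clonality_vaf,
            }
            for c in self.clones
        ])

    def vaf_matrix(self) -> pd.DataFrame:
        """Clone x (position, alt) VAF matrix; absent observations are 0."""
        if self.variants.empty:
            return pd.DataFrame(index=self.clone_ids)
        mat = self.variants.pivot_table(
            index="clone_id", columns=["position", "alt"],
            values="vaf", aggfunc="first", fill_value=0.0,
        )
        return mat.reindex(self.clone_ids, fill_value=0.0)

    # -- serialization ------------------------------------------------------

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        # %.17g round-trips doubles exactly, keeping the matrix bitwise stable
        self.variants.to_csv(outdir / "variants.tsv", sep="\t", index=False,
                             float_format="%.17g")
        self.metadata_frame().to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        for donor, tree in self.phylogenies.items():
            tree.write(path=str(outdir / f"{donor}.nwk"), schema="newick",
                       unquoted_underscores=True)
        if self.bulk_vafs is not None:
            self.bulk_vafs.to_csv(outdir / "bulk_vafs.tsv", sep="\t",
                                  index=False, float_format="%.17g")
        manifest = {
            "n_clones": len(self.clones),
            "n_variant_rows": int(len(self.variants)),
            "donors": self.donors,
            "excluded_clones": self.excluded_clones,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def read(cls, outdir: str | Path) -> "CohortData":
        outdir = Path(outdir)
        trees = sorted(outdir.glob("*.nwk"))
        bulk = outdir / "bulk_vafs.tsv"
        return load_cohort(
            [outdir / "variants.tsv"],
            outdir / "metadata.tsv",
            tree_paths=trees,
            bulk_path=bulk if bulk.exists() else None,
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_variant_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"clone_id": str, "ref": str, "alt": str},
                     float_precision="round_trip")
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing variant columns {sorted(missing)}")
    return df[VARIANT_COLUMNS]


def _read_variant_vcf(path: Path) -> pd.DataFrame:
    """Read a VCF; VAF from the AD field (alt / (ref + alt)) when present,
    else from an AF field."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns")
    used_ad = True
    rows = []
    for rec in vcf:
        for alt in rec.ALT:
            vtype = variant_type_of(rec.REF, alt)
            try:
                ad = rec.format("AD")
            except KeyError:
                ad = None
            for i, sample in enumerate(samples):
                if ad is not None:
                    ref_n, alt_n = int(ad[i][0]), int(ad[i][1])
                    depth = ref_n + alt_n
                    vaf = alt_n / depth if depth > 0 else 0.0
                else:
                    used_ad = False
                    af = rec.format("AF")
                    if af is None:
                        raise ValueError(f"{path}: neither AD nor AF present")
                    vaf = float(af[i][0])
                    alt_n, depth = -1, -1
                rows.append({
                    "clone_id": sample, "position": rec.POS, "ref": rec.REF,
                    "alt": alt, "variant_type": vtype, "vaf": vaf,
                    "alt_count": alt_n, "depth": depth,
                })
    logger.info("%s: VAF taken from %s", path, "AD" if used_ad else "AF")
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_vcf(cohort: CohortData, genome: MtGenome, path: str | Path) -> None:
    """Write the cohort's observations as a multi-sample VCF 4.2 with AD."""
    samples = cohort.clone_ids
    lookup: dict[tuple[int, str], dict[str, tuple[int, int]]] = {}
    refs: dict[tuple[int, str], str] = {}
    for r in cohort.variants.itertuples(index=False):
        site = (int(r.position), r.alt)
        refs[site] = r.ref
        depth = int(r.depth) if r.depth > 0 else 0
        alt_n = int(r.alt_count) if r.alt_count > 0 else 0
        lookup.setdefault(site, {})[r.clone_id] = (depth - alt_n, alt_n)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genome.name},length={len(genome)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for (pos, alt) in sorted(lookup):
            per_sample = lookup[(pos, alt)]
            fields = [genome.name, str(pos), ".", refs[(pos, alt)], alt,
                      ".", "PASS", ".", "GT:AD"]
            for s in samples:
                ref_n, alt_n = per_sample.get(s, (0, 0))
                fields.append(f"./.:{ref_n},{alt_n}")
            fh.write("\t".join(fields) + "\n")


def load_cohort(
    variant_paths: Sequence[str | Path],
    metadata_path: str | Path,
    tree_paths: Iterable[str | Path] = (),
    bulk_path: str | Path | None = None,
) -> CohortData:
    """Load variant tables (TSV or VCF), clone metadata and optional donor
    phylogenies; clones failing the clonality/coverage filter are excluded
    and logged."""
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"clone_id": str, "donor_id": str})
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing required columns: {sorted(missing)}")

    clones, excluded = [], []
    for _, row in meta.iterrows():
        clone = CloneRecord(
            clone_id=row["clone_id"], donor_id=row["donor_id"],
            tissue=row["tissue"], donor_age=float(row["donor_age"]),
            mean_coverage_nuclear=float(row["mean_coverage_nuclear"]),
            mean_coverage_mt=float(row["mean_coverage_mt"]),
            nuclear_clonality_vaf=float(row["nuclear_clonality_vaf"]),
        )
        if clone.passes_clonality_filter:
            clones.append(clone)
        else:
            excluded.append(clone.clone_id)
            logger.warning(
                "clone %s excluded (clonality VAF %.3f, nuclear coverage %.1f)",
                clone.clone_id, clone.nuclear_clonality_vaf,
                clone.mean_coverage_nuclear,
            )

    frames = []
    for path in variant_paths:
        path = Path(path)
        if path.suffix in {".vcf", ".gz", ".bcf"}:
            frames.append(_read_variant_vcf(path))
        else:
            frames.append(_read_variant_tsv(path))
    variants = (pd.concat(frames, ignore_index=True) if frames
                else pd.DataFrame(columns=VARIANT_COLUMNS))

    known = {c.clone_id for c in clones}
    orphan = set(variants["clone_id"]) - known - set(excluded)
    if orphan:
        raise ValueError(
            f"clones present in variant files but absent from metadata: "
            f"{sorted(orphan)[:5]}"
        )
    variants = variants[variants["clone_id"].isin(known)].reset_index(drop=True)

    phylogenies = {}
    for tree_path in tree_paths:
        tree = dendropy.Tree.get(path=str(tree_path), schema="newick",
                                 preserve_underscores=True)
        tree.is_rooted = True  # developmental phylogenies are rooted
        phylogenies[Path(tree_path).stem] = tree

    bulk = None
    if bulk_path is not None:
        bulk = pd.read_csv(bulk_path, sep="\t",
                           dtype={"donor_id": str, "alt": str},
                           float_precision="round_trip")

    return CohortData(
        clones=clones, variants=variants, phylogenies=phylogenies,
        bulk_vafs=bulk, excluded_clones=excluded,
    )
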