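"""Reading, writing and cross-platform harmonization of SNP data.

Supported external representations:

* VCF v4.x with biallelic SNP records (read via cyvcf2, written as plain text);
* a genotype TSV dialect: header ``sample_id<TAB><snp ids...>``, one row per
  sample, cells in {0, 1, 2, NA}. SNP ids of the form ``chrom:pos:ref:alt``
  carry their locus; any other id leaves the position undefined;
* PLINK-style .ped/.map text (optional input dialect);
* a pooled-read TSV with columns chromosome, position, ref, alt, population,
  alt_reads, depth, n_individuals;
* a population map TSV: ``sample_id<TAB>population``.

``harmonize`` reduces an array-side :class:`GenotypeMatrix` and a
reference-side :class:`PooledFrequencyTable` to locus- and allele-matched sets
through a four-step discard pipeline (missing positions, duplicated positions,
presence in both sources on allowed chromosomes, allele agreement), logging
the number of loci removed at each step. Mismatches are dropped, never
repaired: no strand flipping or liftover is attempted.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    DEFAULT_CHROMOSOMES,
    GenotypeMatrix,
    PooledFrequencyTable,
    PopulationPanel,
    SnpRecord,
    normalize_chromosome,
)

_NUCLEOTIDES = {"A", "C", "G", "T"}

POOL_COLUMNS = [
    "chromosome",
    "position",
    "ref",
    "alt",
    "population",
    "alt_reads",
    "depth",
    "n_individuals",
]


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


# ---------------------------------------------------------------------------
# population map
# ---------------------------------------------------------------------------


def read_panel(path) -> PopulationPanel:
    """Read a two-column ``sample_id<TAB>population`` map (no header)."""
    assignments: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
        sample, pop = parts
        if sample in assignments:
            raise FormatError(f"{path}:{lineno}: duplicate sample id {sample!r}")
        assignments[sample] = pop
    return PopulationPanel(assignments)


def write_panel(panel: PopulationPanel, path) -> None:
    with open(path, "w") as fh:
        for sample, pop in panel.assignments.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _sorted_snp_order(snps: list[SnpRecord]) -> list[int]:
    return sorted(range(len(snps)), key=lambda i: snps[i].sort_key())


def _parse_tsv_snp_id(snp_id: str) -> SnpRecord:
    parts = snp_id.split(":")
    if len(parts) == 4 and parts[1].isdigit() and int(parts[1]) >= 1:
        chrom, pos, ref, alt = parts
        if ref != alt:
            return SnpRecord(snp_id, chrom, int(pos), ref, alt)
    # position unknown; such SNPs are discarded at harmonization step 1
    return SnpRecord(snp_id, "", None, "N", ".")


def _read_genotypes_vcf(path, panel: PopulationPanel) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in panel.assignments:
            raise KeyError(f"sample {s!r} in {path} is not in the population panel")
    snps: list[SnpRecord] = []
    columns: list[np.ndarray] = []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    gt_map = np.array([0.0, 1.0, np.nan, 2.0])
    for v in vcf:
        if len(v.ALT) != 1:
            raise FormatError(
                f"{path}: multi-allelic record at {v.CHROM}:{v.POS}; only biallelic SNPs supported"
            )
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            raise FormatError(f"{path}: indel record at {v.CHROM}:{v.POS}; only SNPs supported")
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        snps.append(SnpRecord(vid, v.CHROM, int(v.POS), v.REF, v.ALT[0]))
        columns.append(gt_map[np.asarray(v.gt_types, dtype=int)])
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    order = _sorted_snp_order(snps)
    return GenotypeMatrix(
        snps=[snps[i] for i in order],
        sample_ids=samples,
        sample_populations=[panel.population_of(s) for s in samples],
        dosages=dosages[:, order] if columns else dosages,
    )


def _read_genotypes_tsv(path, panel: PopulationPanel) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise FormatError(f"{path}: first column of the genotype TSV must be 'sample_id'")
    sample_ids = df["sample_id"].tolist()
    for s in sample_ids:
        if s not in panel.assignments:
            raise KeyError(f"sample {s!r} in {path} is not in the population panel")
    snps = [_parse_tsv_snp_id(c) for c in df.columns[1:]]
    cells = df.iloc[:, 1:].to_numpy(dtype=object)
    dosages = np.full(cells.shape, np.nan)
    for val, rep in (("0", 0.0), ("1", 1.0), ("2", 2.0)):
        dosages[cells == val] = rep
    bad = ~np.isin(cells, ("0", "1", "2", "NA")) & ~pd.isna(cells)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: invalid genotype cell {cells[r, c]!r} "
            f"(sample {sample_ids[r]}, SNP {snps[c].id}); expected 0/1/2/NA"
        )
    order = _sorted_snp_order(snps)
    return GenotypeMatrix(
        snps=[snps[i] for i in order],
        sample_ids=sample_ids,
        sample_populations=[panel.population_of(s) for s in sample_ids],
        dosages=dosages[:, order],
    )


def _read_genotypes_ped(path, panel: PopulationPanel) -> GenotypeMatrix:
    """Minimal PLINK .ped/.map reader.

    The alternative allele of each SNP is taken as its minor allele in the
    file (ties broken alphabetically); '0' codes a missing allele.
    """
    ped_path = Path(path)
    map_path = ped_path.with_suffix(".map")
    if not map_path.exists():
        raise FileNotFoundError(f"companion map file {map_path} not found")
    loci: list[tuple[str, str, int]] = []
    for lineno, line in enumerate(map_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"{map_path}:{lineno}: expected 4 whitespace-separated fields")
        loci.append((parts[0], parts[1], int(parts[3])))
    sample_ids: list[str] = []
    allele_rows: list[list[str]] = []
    for lineno, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * len(loci):
            raise FormatError(f"{ped_path}:{lineno}: expected {6 + 2 * len(loci)} fields")
        sample_ids.append(parts[1])
        allele_rows.append(parts[6:])
    for s in sample_ids:
        if s not in panel.assignments:
            raise KeyError(f"sample {s!r} in {ped_path} is not in the population panel")
    alleles = np.asarray(allele_rows, dtype=object).reshape(len(sample_ids), len(loci), 2)
    snps: list[SnpRecord] = []
    dosages = np.full((len(sample_ids), len(loci)), np.nan)
    for j, (chrom, snp_id, pos) in enumerate(loci):
        col = alleles[:, j, :]
        counts = Counter(a for a in col.ravel() if a != "0")
        observed = sorted(counts, key=lambda a: (-counts[a], a))
        if len(observed) > 2:
            raise FormatError(f"{ped_path}: SNP {snp_id} has more than two alleles")
        ref = observed[0] if observed else "N"
        alt = observed[1] if len(observed) > 1 else ("N" if ref != "N" else ".")
        snps.append(SnpRecord(snp_id, chrom, pos, ref, alt))
        called = (col != "0").all(axis=1)
        dosages[called, j] = (col[called] == alt).sum(axis=1)
    order = _sorted_snp_order(snps)
    return GenotypeMatrix(
        snps=[snps[i] for i in order],
        sample_ids=sample_ids,
        sample_populations=[panel.population_of(s) for s in sample_ids],
        dosages=dosages[:, order],
    )


def read_genotypes(path, panel) -> GenotypeMatrix:
    """Read individual genotypes (VCF, genotype TSV, or .ped/.map).

    ``panel`` is a :class:`PopulationPanel` or the path of a population map;
    every genotyped sample must appear in it. SNPs are returned sorted by
    (chromosome, position), dosages counting alternative-allele copies.
    """
    if not isinstance(panel, PopulationPanel):
        panel = read_panel(panel)
    name = str(path)
    if name.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _read_genotypes_vcf(path, panel)
    if name.endswith(".ped"):
        return _read_genotypes_ped(path, panel)
    return _read_genotypes_tsv(path, panel)


def write_genotypes_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT fields only."""
    opener = gzip.open if str(path).endswith(".gz") else open
    gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen: dict[str, None] = {}
        for s in geno.snps:
            seen.setdefault(str(s.chromosome), None)
        for chrom in seen:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids)
            + "\n"
        )
        for j, snp in enumerate(geno.snps):
            pos = snp.position if snp.position is not None else 0
            gts = "\t".join(
                gt_codes.get(d, "./.") if not np.isnan(d) else "./."
                for d in geno.dosages[:, j]
            )
            fh.write(
                f"{snp.chromosome}\t{pos}\t{snp.id}\t{snp.ref_allele}\t"
                f"{snp.alt_allele}\t.\t.\t.\tGT\t{gts}\n"
            )


def write_genotypes_tsv(geno: GenotypeMatrix, path) -> None:
    """Write the genotype TSV dialect with locus-encoding SNP ids."""

    def encode(s: SnpRecord) -> str:
        if s.key is not None and len(s.id.split(":")) != 4:
            return f"{s.chromosome}:{s.position}:{s.ref_allele}:{s.alt_allele}"
        return s.id

    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(encode(s) for s in geno.snps) + "\n")
        for i, sample in enumerate(geno.sample_ids):
            cells = [
                "NA" if np.isnan(d) else str(int(d)) for d in geno.dosages[i, :]
            ]
            fh.write(sample + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# pooled read counts
# ---------------------------------------------------------------------------


def read_pool_table(path) -> PooledFrequencyTable:
    """Read the pooled-read TSV (one row per population x locus)."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "ref": str, "alt": str})
    missing = [c for c in POOL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if df.empty:
        return PooledFrequencyTable(
            snps=[],
            populations=[],
            n_individuals=np.empty(0, dtype=int),
            alt_reads=np.empty((0, 0), dtype=int),
            depth=np.empty((0, 0), dtype=int),
        )
    bad = df["alt_reads"] > df["depth"]
    if bad.any():
        row = df[bad].iloc[0]
        raise FormatError(
            f"{path}: alt_reads > depth for population {row['population']} at "
            f"{row['chromosome']}:{row['position']}"
        )
    df["_key"] = list(zip(df["chromosome"].map(normalize_chromosome), df["position"]))
    dup = df.duplicated(subset=["population", "_key"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicate row for population {row['population']} at "
            f"{row['chromosome']}:{row['position']}"
        )
    # loci sorted as in read_genotypes; allele metadata from first occurrence
    first = df.drop_duplicates(subset="_key").copy()
    snps = [
        SnpRecord(
            f"{r.chromosome}:{r.position}:{r.ref}:{r.alt}",
            str(r.chromosome),
            int(r.position),
            str(r.ref),
            str(r.alt),
        )
        for r in first.itertuples()
    ]
    conflicting = df.groupby("_key")[["ref", "alt"]].nunique()
    if (conflicting > 1).any().any():
        key = conflicting[(conflicting > 1).any(axis=1)].index[0]
        raise FormatError(f"{path}: conflicting ref/alt alleles at locus {key}")
    order = _sorted_snp_order(snps)
    snps = [snps[i] for i in order]
    key_col = {s.key: j for j, s in enumerate(snps)}

    populations: list[str] = list(dict.fromkeys(df["population"]))
    pop_row = {p: i for i, p in enumerate(populations)}
    n_ind = np.zeros(len(populations), dtype=int)
    sizes = df.groupby("population")["n_individuals"].nunique()
    if (sizes > 1).any():
        raise FormatError(f"{path}: conflicting n_individuals within a population")
    for p, n in df.groupby("population")["n_individuals"].first().items():
        n_ind[pop_row[p]] = int(n)

    alt = np.zeros((len(populations), len(snps)), dtype=int)
    dep = np.zeros_like(alt)
    rows = df["population"].map(pop_row).to_numpy()
    cols = df["_key"].map(key_col).to_numpy()
    alt[rows, cols] = df["alt_reads"].to_numpy()
    dep[rows, cols] = df["depth"].to_numpy()
    return PooledFrequencyTable(snps, populations, n_ind, alt, dep)


def write_pool_table(pool: PooledFrequencyTable, path) -> None:
    records = []
    for i, pop in enumerate(pool.populations):
        for j, snp in enumerate(pool.snps):
            records.append(
                (
                    snp.chromosome,
                    snp.position,
                    snp.ref_allele,
                    snp.alt_allele,
                    pop,
                    int(pool.alt_reads[i, j]),
                    int(pool.depth[i, j]),
                    int(pool.n_individuals[i]),
                )
            )
    pd.DataFrame(records, columns=POOL_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interval annotation input (for genic/non-genic classification)
# ---------------------------------------------------------------------------


def read_intervals_gff3(path, feature_types: tuple[str, ...] = ("gene",)) -> list[tuple[str, int, int]]:
    """Gene intervals from a GFF3 file as (chromosome, start, end), 1-based inclusive."""
    intervals = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 8:
            raise FormatError(f"{path}:{lineno}: expected >= 8 tab-separated GFF3 fields")
        if parts[2] not in feature_types:
            continue
        start, end = int(parts[3]), int(parts[4])
        if start < 1 or end < start:
            raise FormatError(f"{path}:{lineno}: malformed interval {start}-{end}")
        intervals.append((parts[0], start, end))
    return intervals


def read_intervals_bed(path) -> list[tuple[str, int, int]]:
    """Intervals from a BED file, converted to 1-based inclusive coordinates."""
    intervals = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated BED fields")
        start0, end0 = int(parts[1]), int(parts[2])
        if start0 < 0 or end0 <= start0:
            raise FormatError(f"{path}:{lineno}: malformed interval {start0}-{end0}")
        intervals.append((parts[0], start0 + 1, end0))
    return intervals


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

HARMONIZE_STEPS = (
    "missing_position",
    "duplicate_position",
    "not_shared_or_disallowed",
    "allele_mismatch",
)


@dataclass
class HarmonizationLog:
    """Per-dataset locus counts removed at each harmonization step."""

    array_input: int
    reference_input: int
    array_removed: dict[str, int] = field(default_factory=dict)
    reference_removed: dict[str, int] = field(default_factory=dict)
    retained: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _dedup_keys(snps: list[SnpRecord]) -> tuple[list[int], int]:
    counts = Counter(s.key for s in snps)
    keep = [i for i, s in enumerate(snps) if counts[s.key] == 1]
    return keep, len(snps) - len(keep)


def harmonize(
    array: GenotypeMatrix,
    reference: PooledFrequencyTable,
    allowed_chromosomes=None,
) -> tuple[GenotypeMatrix, PooledFrequencyTable, HarmonizationLog]:
    """Reduce both datasets to locus- and allele-matched SNP sets.

    Steps, applied in order with per-step removal counts logged:

    1. drop SNPs whose position is missing/undefined;
    2. drop *all* SNPs sharing a (chromosome, position) key within a dataset;
    3. keep loci present in both datasets and on an allowed chromosome
       (default chromosomes "1".."28"; names compared after stripping an
       optional "chr" prefix);
    4. drop loci whose ref or alt allele disagrees between the datasets.

    The reference-side SNP ids are renamed to the array-side ids so that the
    returned datasets share locus ids in identical order.
    """
    if array.n_snps == 0 or reference.n_snps == 0:
        raise ValueError("harmonize requires non-empty inputs")
    allowed = {
        normalize_chromosome(c)
        for c in (allowed_chromosomes if allowed_chromosomes is not None else DEFAULT_CHROMOSOMES)
    }
    log = HarmonizationLog(array_input=array.n_snps, reference_input=reference.n_snps)

    def _fail(step: str):
        raise ValueError(f"harmonization emptied the locus set at step '{step}'")

    # step 1: missing positions
    a_idx = [i for i, s in enumerate(array.snps) if s.key is not None]
    r_idx = [i for i, s in enumerate(reference.snps) if s.key is not None]
    log.array_removed["missing_position"] = array.n_snps - len(a_idx)
    log.reference_removed["missing_position"] = reference.n_snps - len(r_idx)
    if not a_idx or not r_idx:
        _fail("missing_position")

    # step 2: duplicated (chromosome, position) within each dataset
    a_snps = [array.snps[i] for i in a_idx]
    r_snps = [reference.snps[i] for i in r_idx]
    keep_a, rem_a = _dedup_keys(a_snps)
    keep_r, rem_r = _dedup_keys(r_snps)
    log.array_removed["duplicate_position"] = rem_a
    log.reference_removed["duplicate_position"] = rem_r
    a_idx = [a_idx[i] for i in keep_a]
    r_idx = [r_idx[i] for i in keep_r]
    if not a_idx or not r_idx:
        _fail("duplicate_position")

    # step 3: shared loci on allowed chromosomes
    a_keys = {array.snps[i].key: i for i in a_idx}
    r_keys = {reference.snps[i].key: i for i in r_idx}
    shared = [k for k in a_keys if k in r_keys and k[0] in allowed]
    log.array_removed["not_shared_or_disallowed"] = len(a_idx) - len(shared)
    log.reference_removed["not_shared_or_disallowed"] = len(r_idx) - len(shared)
    if not shared:
        _fail("not_shared_or_disallowed")

    # step 4: allele agreement
    matched = []
    for k in shared:
        a, r = array.snps[a_keys[k]], reference.snps[r_keys[k]]
        if a.ref_allele == r.ref_allele and a.alt_allele == r.alt_allele:
            matched.append(k)
    log.array_removed["allele_mismatch"] = len(shared) - len(matched)
    log.reference_removed["allele_mismatch"] = len(shared) - len(matched)
    if not matched:
        _fail("allele_mismatch")

    matched.sort(key=lambda k: ((0, int(k[0]), "") if k[0].isdigit() else (1, 0, k[0]), k[1]))
    log.retained = len(matched)

    out_array = array.take_snps([a_keys[k] for k in matched])
    out_ref = reference.take_snps([r_keys[k] for k in matched])
    # adopt the array-side ids on the reference side: shared locus currency
    out_ref.snps = [
        SnpRecord(a.id, r.chromosome, r.position, r.ref_allele, r.alt_allele)
        for a, r in zip(out_array.snps, out_ref.snps)
    ]
    return out_array, out_ref, log
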