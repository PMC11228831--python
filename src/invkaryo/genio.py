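"""Genotype data model and I/O for the standard formats the pipeline touches.

The internal coordinate convention is 1-based inclusive (VCF-native); BED
export is the single place where 0-based half-open coordinates appear.
Missing genotypes are a distinct sentinel (:data:`MISSING`), never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

MISSING = -1
"""Sentinel for a missing diploid dosage."""


class SchemaError(ValueError):
    """A table or file is missing a required column or field."""


@dataclass
class GenotypeMatrix:
    """Diploid alt-allele dosage matrix with site and sample metadata.

    dosages is samples x sites with entries in {0, 1, 2, MISSING} counting
    copies of the alt allele. Positions are 1-based and strictly increasing
    within the chromosome.
    """

    sample_ids: list[str]
    chrom: str
    positions: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    dosages: np.ndarray
    population_of: dict[str, str] = field(default_factory=dict)
    latitude_of: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        ns, nv = self.dosages.shape
        if ns != len(self.sample_ids):
            raise ValueError(
                f"dosage rows ({ns}) != number of samples ({len(self.sample_ids)})"
            )
        if nv != len(self.positions):
            raise ValueError(
                f"dosage columns ({nv}) != number of positions ({len(self.positions)})"
            )
        if nv and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.population_of:
            unmapped = [s for s in self.sample_ids if s not in self.population_of]
            if unmapped:
                raise ValueError(f"samples without a population: {unmapped}")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2, MISSING}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom,
            positions=self.positions[idx],
            ref_allele=self.ref_allele[idx],
            alt_allele=self.alt_allele[idx],
            dosages=self.dosages[:, idx],
            population_of=dict(self.population_of),
            latitude_of=dict(self.latitude_of),
        )

    def take_samples(self, samples) -> "GenotypeMatrix":
        order = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in order]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        idx = np.array([order[s] for s in samples], dtype=int)
        return GenotypeMatrix(
            sample_ids=list(samples),
            chrom=self.chrom,
            positions=self.positions.copy(),
            ref_allele=self.ref_allele.copy(),
            alt_allele=self.alt_allele.copy(),
            dosages=self.dosages[idx, :],
            population_of=dict(self.population_of),
            latitude_of=dict(self.latitude_of),
        )

    def region_sites(self, start_1based: int, end_1based: int) -> np.ndarray:
        """Indices of sites with start <= pos <= end (1-based inclusive)."""
        return np.nonzero(
            (self.positions >= start_1based) & (self.positions <= end_1based)
        )[0]


@dataclass(frozen=True)
class RegionBed:
    """BED-convention interval: 0-based, half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"BED start ({self.start}) must be < end ({self.end})")


def region_to_bed(chrom: str, start_1based: int, end_1based: int) -> RegionBed:
    """Convert a 1-based inclusive interval to BED (0-based half-open)."""
    if start_1based > end_1based:
        raise ValueError(
            f"start ({start_1based}) > end ({end_1based}) in 1-based interval"
        )
    return RegionBed(chrom=chrom, start=start_1based - 1, end=end_1based)


def write_bed(region: RegionBed, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{region.chrom}\t{region.start}\t{region.end}\n")


def read_bed(path) -> RegionBed:
    with open(path) as fh:
        chrom, start, end = fh.readline().split()[:3]
    return RegionBed(chrom=chrom, start=int(start), end=int(end))


# cyvcf2 gt_types codes: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
_GT_TYPE_TO_DOSAGE = np.array([0, 1, MISSING, 2], dtype=np.int8)


def read_vcf(path, region: tuple[int, int] | None = None,
             population_of: dict[str, str] | None = None,
             latitude_of: dict[str, float] | None = None) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF 4.x file into a GenotypeMatrix.

    Dosages come from GT regardless of phasing separator; ``./.`` maps to
    MISSING. ``region`` is 1-based inclusive on the file's single chromosome.
    Multiallelic and non-SNP records are skipped (count reported via warning).
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom = None
    positions, refs, alts, rows = [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        if region is not None and not (region[0] <= var.POS <= region[1]):
            continue
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise ValueError(
                f"multiple chromosomes in VCF ({chrom}, {var.CHROM}); read one at a time"
            )
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(_GT_TYPE_TO_DOSAGE[var.gt_types])
    vcf.close()
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic-SNP records")
    if not positions:
        raise ValueError(f"no biallelic SNP records found in {path}")
    dosages = np.stack(rows, axis=1)
    return GenotypeMatrix(
        sample_ids=samples,
        chrom=chrom,
        positions=np.array(positions),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        dosages=dosages,
        population_of=population_of or {},
        latitude_of=latitude_of or {},
    )


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as VCF 4.2 with unphased GT, one record per site."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={G.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        for j in range(G.n_sites):
            gts = "\t".join(_DOSAGE_TO_GT[int(d)] for d in G.dosages[:, j])
            fh.write(
                f"{G.chrom}\t{G.positions[j]}\t.\t{G.ref_allele[j]}\t"
                f"{G.alt_allele[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_samples_tsv(path) -> tuple[dict[str, str], dict[str, float]]:
    """Read samples.tsv (sample, population, latitude) into the two maps.

    Latitude may be empty for a population; the latitude map then omits it.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "population": str})
    for col in ("sample", "population"):
        if col not in df.columns:
            raise SchemaError(f"samples table missing required column '{col}'")
    population_of = dict(zip(df["sample"], df["population"]))
    latitude_of: dict[str, float] = {}
    if "latitude" in df.columns:
        for pop, lat in zip(df["population"], df["latitude"]):
            if pd.notna(lat) and pop not in latitude_of:
                latitude_of[pop] = float(lat)
    return population_of, latitude_of


def write_samples_tsv(population_of, latitude_of, path) -> None:
    rows = [
        {
            "sample": s,
            "population": p,
            "latitude": latitude_of.get(p, ""),
        }
        for s, p in population_of.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> pd.DataFrame:
    """Read a gene annotation table (gene_id, chrom, start, end, term_id, category)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "term_id": str})
    required = ["gene_id", "chrom", "start", "end", "term_id", "category"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"annotation table missing required column '{col}'")
    return df


def read_family_fasta(path) -> dict[str, str]:
    """Read one ortholog family FASTA into a label -> sequence map.

    All sequences in a family must have equal length (pre-aligned, no indels);
    the error names the offending header.
    """
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    lengths = {label: len(s) for label, s in seqs.items()}
    ref_len = max(set(lengths.values()), key=list(lengths.values()).count)
    bad = [label for label, ln in lengths.items() if ln != ref_len]
    if bad:
        raise ValueError(
            f"unequal sequence length in family {path}: offending header(s) {bad}"
        )
    return seqs


def write_family_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for label, s in seqs.items():
            fh.write(f">{label}\n")
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")
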