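"""Synthetic cohorts, ortholog families, and annotation tables with truth labels.

The cohort generator emulates the statistical structure the downstream
analysis assumes: one chromosome carrying a multi-megabase region of
suppressed recombination between two diverged haplotype classes (ancestral
vs inverted orientation) at population-specific frequencies forming a
latitudinal cline, and neutral panmictic variation elsewhere. Genealogies
are Kingman coalescent trees per non-recombining block (blocks independent,
approximating free recombination between blocks); the inversion region uses
a clean two-deme split with divergence ``t_div_ci`` (units of 2N
generations) and no gene flow, matching recombination suppression between
alternative homokaryotypes. Mutations follow the infinite-sites model, so
every simulated site is biallelic with the derived allele as ALT.

Ortholog families are evolved by single-rate JC69 substitution along a fixed
ultrametric species tree containing a whole-genome duplication, with the two
inversion haplotypes of the focal species diverging ``t_inv`` million years
ago. Annotation tables plant term enrichment inside a genomic interval.

All generators are deterministic given (params, seed); child random streams
are derived from one seeded generator per top-level call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import (
    GenotypeMatrix,
    write_samples_tsv,
    write_family_fasta,
    write_vcf,
)
from .dating import OrthologFamily

ANC_HOM = "ANC_HOM"
HET = "HET"
INV_HOM = "INV_HOM"

#: taxon tokens of a simulated ortholog family (two esociform outgroups; two
#: homeolog clades from the salmonid whole-genome duplication; the focal
#: clade carries the two rainbow-trout inversion haplotypes)
FAMILY_TAXA = (
    "pike",
    "mudminnow",
    "whitefish1",
    "grayling1",
    "atlantic1",
    "trout_anc",
    "trout_inv",
    "whitefish2",
    "grayling2",
    "atlantic2",
    "trout_homeo2",
)

DEFAULT_TREE_AGES = {
    "root": 112.0,                     # esociform / salmonid split
    "esociform_split": 85.0,           # pike / mudminnow
    "wgd": 90.0,                       # salmonid whole-genome duplication
    "salmonid_tmrca": 51.8,            # TMRCA of Salmonidae within each homeolog clade
    "whitefish_grayling_split": 40.0,
    "salmo_oncorhynchus_split": 27.3,  # Atlantic salmon / rainbow trout
    "t_inv": 1.0,                      # inversion-haplotype divergence
}


@dataclass
class CohortSimParams:
    """Parameters of a simulated diploid cohort with one inversion.

    Defaults emulate a ~13.6-Mb inversion between 5.6 and 19.2 Mb on a 30-Mb
    chromosome, strongly diverged haplotype classes, and a latitudinal cline
    in the inverted-haplotype frequency (high in the north, polymorphic in
    the south).
    """

    n_samples_per_pop: int = 20
    pop_labels: tuple[str, ...] = ("pop33", "pop36", "pop39", "pop42", "pop45")
    pop_latitudes: tuple[float, ...] = (33.0, 36.0, 39.0, 42.0, 45.0)
    p_inverted_per_pop: tuple[float, ...] = (0.3, 0.5, 0.7, 0.95, 1.0)
    chrom_length: int = 30_000_000
    ci_start: int = 5_600_000
    ci_end: int = 19_200_000
    theta_per_site: float = 1e-5
    t_div_ci: float = 4.0
    n_background_blocks: int = 20
    seed: int = 0
    chrom: str = "chr20"
    #: when False, no inversion exists: the whole chromosome is tiled by
    #: background-sized neutral blocks (every truth karyotype ANC_HOM)
    inversion_present: bool = True

    def validate(self) -> None:
        if self.n_samples_per_pop < 2:
            raise ValueError("n_samples_per_pop must be >= 2")
        if not (
            len(self.pop_labels)
            == len(self.pop_latitudes)
            == len(self.p_inverted_per_pop)
        ):
            raise ValueError("population vectors must have equal length")
        if not (1 <= self.ci_start < self.ci_end <= self.chrom_length):
            raise ValueError(
                "require 1 <= ci_start < ci_end <= chrom_length "
                f"(got {self.ci_start}, {self.ci_end}, {self.chrom_length})"
            )
        for p in self.p_inverted_per_pop:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"inverted-haplotype frequency {p} outside [0, 1]")
        if self.theta_per_site <= 0:
            raise ValueError("theta_per_site must be > 0")
        if self.t_div_ci < 0:
            raise ValueError("t_div_ci must be >= 0")
        if self.n_background_blocks < 1:
            raise ValueError("n_background_blocks must be >= 1")


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    truth_karyotypes: dict[str, str]
    truth_region: tuple[int, int] | None


@dataclass
class OrthologSimParams:
    n_families: int = 200
    seq_length: int = 10_000
    species_tree_ages: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TREE_AGES)
    )
    subst_rate: float = 1e-3  # substitutions / site / MY
    seed: int = 0

    def validate(self) -> None:
        if self.subst_rate <= 0:
            raise ValueError("subst_rate must be > 0")
        a = {**DEFAULT_TREE_AGES, **self.species_tree_ages}
        ordering = [
            ("root", "esociform_split"),
            ("root", "wgd"),
            ("wgd", "salmonid_tmrca"),
            ("salmonid_tmrca", "whitefish_grayling_split"),
            ("salmonid_tmrca", "salmo_oncorhynchus_split"),
            ("salmo_oncorhynchus_split", "t_inv"),
        ]
        for parent, child in ordering:
            if not a[child] < a[parent]:
                raise ValueError(
                    f"tree ages not nested: {child} ({a[child]}) must be younger "
                    f"than {parent} ({a[parent]})"
                )
        if a["t_inv"] < 0:
            raise ValueError("t_inv must be >= 0")
        self.species_tree_ages = a


@dataclass
class AnnotationSimParams:
    n_genes: int = 30_300
    n_terms: int = 50
    ci_gene_fraction: float = 300 / 30_300
    baseline_term_prob: float = 0.02
    enriched_terms: dict[str, float] = field(
        default_factory=lambda: {f"T{i:03d}": 8.0 for i in range(5)}
    )
    seed: int = 0
    chrom: str = "chr20"
    chrom_length: int = 30_000_000
    ci_start: int = 5_600_000
    ci_end: int = 19_200_000

    def validate(self) -> None:
        if not 0.0 <= self.baseline_term_prob <= 1.0:
            raise ValueError("baseline_term_prob outside [0, 1]")
        if not 0.0 <= self.ci_gene_fraction <= 1.0:
            raise ValueError("ci_gene_fraction outside [0, 1]")
        for term, mult in self.enriched_terms.items():
            if mult < 1.0:
                raise ValueError(f"multiplier for {term} must be >= 1 (got {mult})")


# ---------------------------------------------------------------------------
# coalescent engine
# ---------------------------------------------------------------------------

def _coalesce(rng, lineages, branches, t, t_end=math.inf):
    """Run pairwise coalescence on `lineages` until one remains or t_end.

    Each lineage is (leafset boolean array, birth_time). Time is in units of
    2N generations (pairwise coalescence rate 1). Completed branches are
    appended to `branches` as (leafset, length). Returns (lineages, time).
    """
    while len(lineages) > 1:
        k = len(lineages)
        wait = rng.exponential(2.0 / (k * (k - 1)))
        if t + wait >= t_end:
            return lineages, t_end
        t += wait
        i, j = sorted(rng.choice(k, size=2, replace=False))
        set_j, birth_j = lineages.pop(j)
        set_i, birth_i = lineages.pop(i)
        branches.append((set_i, t - birth_i))
        branches.append((set_j, t - birth_j))
        lineages.append((set_i | set_j, t))
    return lineages, t


def _drop_mutations(rng, branches, theta, n_leaves):
    """Place Poisson(theta/2 * total length) mutations on the branch set.

    Returns a binary haplotype matrix (n_leaves x S), one column per mutation
    (infinite sites: every mutation is its own segregating site).
    """
    if not branches:
        return np.zeros((n_leaves, 0), dtype=np.int8)
    lengths = np.array([ln for _, ln in branches])
    total = lengths.sum()
    n_mut = rng.poisson(theta / 2.0 * total) if total > 0 else 0
    if n_mut == 0:
        return np.zeros((n_leaves, 0), dtype=np.int8)
    which = rng.choice(len(branches), size=n_mut, p=lengths / total)
    out = np.zeros((n_leaves, n_mut), dtype=np.int8)
    for col, b in enumerate(which):
        out[branches[b][0], col] = 1
    return out


def simulate_neutral_block(n_chromosomes: int, theta_block: float, rng) -> np.ndarray:
    """Infinite-sites haplotypes of one non-recombining neutral block.

    Builds a Kingman coalescent tree for ``n_chromosomes`` lineages and drops
    Poisson mutations at rate ``theta_block / 2`` per unit branch length, so
    E[S] = theta_block * a1 with a1 the (n-1)-th harmonic number. Returns a
    binary matrix (chromosomes x segregating sites). ``rng`` may be a seed or
    a numpy Generator.
    """
    if n_chromosomes < 2:
        raise ValueError("n_chromosomes must be >= 2")
    if theta_block <= 0:
        raise ValueError("theta_block must be > 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lineages = []
    for i in range(n_chromosomes):
        leafset = np.zeros(n_chromosomes, dtype=bool)
        leafset[i] = True
        lineages.append((leafset, 0.0))
    branches: list = []
    _coalesce(rng, lineages, branches, 0.0)
    return _drop_mutations(rng, branches, theta_block, n_chromosomes)


def _simulate_split_block(rng, class_of: np.ndarray, theta: float, t_div: float
                          ) -> np.ndarray:
    """Haplotypes under a clean two-deme split (no migration), divergence t_div.

    ``class_of`` assigns each chromosome to deme 0 or 1; both demes have the
    coalescent size of the ancestral population. Lineages coalesce only
    within their deme until t_div, then in the merged ancestral pool.
    """
    n = len(class_of)
    branches: list = []
    remaining = []
    t_reached = 0.0
    for deme in (0, 1):
        members = np.nonzero(class_of == deme)[0]
        lineages = []
        for i in members:
            leafset = np.zeros(n, dtype=bool)
            leafset[i] = True
            lineages.append((leafset, 0.0))
        if not lineages:
            continue
        lineages, t_reached = _coalesce(rng, lineages, branches, 0.0, t_end=t_div)
        remaining.extend(lineages)
    _coalesce(rng, remaining, branches, t_div)
    return _drop_mutations(rng, branches, theta, n)


def _draw_positions(rng, intervals, k) -> np.ndarray:
    """k distinct 1-based positions uniform over a union of (lo, hi) inclusive
    intervals; duplicates re-drawn."""
    lows = np.array([lo for lo, _ in intervals], dtype=np.int64)
    sizes = np.array([hi - lo + 1 for lo, hi in intervals], dtype=np.int64)
    total = sizes.sum()
    if k > total:
        raise ValueError("more sites requested than available positions")
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    chosen: set[int] = set()
    while len(chosen) < k:
        draw = rng.integers(0, total, size=k - len(chosen))
        iv = np.searchsorted(offsets, draw, side="right") - 1
        chosen.update((lows[iv] + (draw - offsets[iv])).tolist())
    return np.array(sorted(chosen), dtype=np.int64)


_BASES = np.array(list("ACGT"), dtype=object)


def simulate_inversion_cohort(params: CohortSimParams) -> SimulatedCohort:
    """Simulate a diploid cohort with one inversion and neutral background.

    Each diploid draws two inversion-haplotype-class labels by Hardy-Weinberg
    from its population's inverted frequency; inversion-region sites come from
    the two-deme split model, background sites from independent neutral blocks
    occupying contiguous chunks outside the inversion (so background LD is
    short-range, as free recombination between blocks implies).
    """
    params.validate()
    root = np.random.SeedSequence(params.seed)
    rng_classes, rng_ci, rng_bg, rng_alleles = [
        np.random.default_rng(s) for s in root.spawn(4)
    ]

    sample_ids, population_of, latitude_of = [], {}, {}
    class_of_chrom = []  # 0 = ancestral orientation, 1 = inverted
    truth: dict[str, str] = {}
    for pop, lat, p_inv in zip(
        params.pop_labels, params.pop_latitudes, params.p_inverted_per_pop
    ):
        latitude_of[pop] = lat
        for i in range(params.n_samples_per_pop):
            sid = f"{pop}_s{i:03d}"
            sample_ids.append(sid)
            population_of[sid] = pop
            if params.inversion_present:
                a, b = rng_classes.random(2) < p_inv
            else:
                a = b = False
            class_of_chrom.extend([int(a), int(b)])
            truth[sid] = (ANC_HOM, HET, INV_HOM)[int(a) + int(b)]
    class_of_chrom = np.array(class_of_chrom)
    n_hap = len(class_of_chrom)

    # contiguous background chunks; the flanks always, plus the inversion
    # interval itself when no inversion segregates (free recombination there
    # then keeps all LD short-range)
    ci_len = params.ci_end - params.ci_start + 1
    flanks = []
    if params.ci_start > 1:
        flanks.append((1, params.ci_start - 1))
    if params.ci_end < params.chrom_length:
        flanks.append((params.ci_end + 1, params.chrom_length))
    flank_len = sum(hi - lo + 1 for lo, hi in flanks)
    chunk_target = max(1.0, (flank_len or ci_len) / params.n_background_blocks)
    if not params.inversion_present:
        flanks.append((params.ci_start, params.ci_end))

    hap_parts, pos_parts = [], []
    if params.inversion_present:
        # Recombination is suppressed only BETWEEN orientation classes:
        # within a class the region exchanges freely, so the inversion is
        # modeled as sub-blocks sharing one chromosome-wide class assignment
        # but with independent within-class genealogies (each a two-deme
        # split at t_div_ci). Fixed differences between classes then stand
        # in perfect LD across the whole interval while within-class LD
        # stays short-range, as in real inversion polymorphism.
        n_ci_blocks = max(1, round(ci_len / chunk_target))
        ci_edges = np.linspace(
            params.ci_start, params.ci_end + 1, n_ci_blocks + 1
        ).astype(np.int64)
        for b in range(n_ci_blocks):
            lo, hi = int(ci_edges[b]), int(ci_edges[b + 1] - 1)
            if hi < lo:
                continue
            hap_b = _simulate_split_block(
                rng_ci, class_of_chrom,
                params.theta_per_site * (hi - lo + 1), params.t_div_ci,
            )
            if hap_b.shape[1] == 0:
                continue
            hap_parts.append(hap_b)
            pos_parts.append(_draw_positions(rng_ci, [(lo, hi)],
                                             hap_b.shape[1]))

    chunks = []
    for lo, hi in flanks:
        n_chunks = max(1, round((hi - lo + 1) / chunk_target))
        edges = np.linspace(lo, hi + 1, n_chunks + 1).astype(np.int64)
        chunks.extend(
            (int(edges[i]), int(edges[i + 1] - 1))
            for i in range(n_chunks)
            if edges[i + 1] > edges[i]
        )
    for lo, hi in chunks:
        theta_block = params.theta_per_site * (hi - lo + 1)
        block = simulate_neutral_block(n_hap, theta_block, rng_bg)
        if block.shape[1] == 0:
            continue
        hap_parts.append(block)
        pos_parts.append(_draw_positions(rng_bg, [(lo, hi)], block.shape[1]))

    # blocks occupy disjoint intervals, so positions are already distinct
    haplotypes = np.concatenate(hap_parts, axis=1)
    positions = np.concatenate(pos_parts)
    order = np.argsort(positions)
    positions = positions[order]
    haplotypes = haplotypes[:, order]

    dosages = (haplotypes[0::2, :] + haplotypes[1::2, :]).astype(np.int8)
    n_sites = len(positions)
    ref_idx = rng_alleles.integers(0, 4, size=n_sites)
    alt_shift = rng_alleles.integers(1, 4, size=n_sites)
    ref = _BASES[ref_idx]
    alt = _BASES[(ref_idx + alt_shift) % 4]

    genotypes = GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=params.chrom,
        positions=positions,
        ref_allele=ref,
        alt_allele=alt,
        dosages=dosages,
        population_of=population_of,
        latitude_of=latitude_of,
    )
    return SimulatedCohort(
        genotypes=genotypes,
        truth_karyotypes=truth,
        truth_region=(params.ci_start, params.ci_end)
        if params.inversion_present
        else None,
    )


def realized_ci_site_mask(cohort: SimulatedCohort) -> np.ndarray:
    """Boolean mask of sites inside the truth inversion interval."""
    if cohort.truth_region is None:
        return np.zeros(cohort.genotypes.n_sites, dtype=bool)
    lo, hi = cohort.truth_region
    pos = cohort.genotypes.positions
    return (pos >= lo) & (pos <= hi)


def class_separating_sites(cohort: SimulatedCohort) -> np.ndarray:
    """Indices of sites fixed for alternative alleles between homokaryotypes.

    These are the sites the LD scan can actually anchor on (perfect
    long-range LD), so their positional extremes are the realized detectable
    truth span of the inversion given SNP discreteness.
    """
    G = cohort.genotypes
    anc = [i for i, s in enumerate(G.sample_ids)
           if cohort.truth_karyotypes[s] == ANC_HOM]
    inv = [i for i, s in enumerate(G.sample_ids)
           if cohort.truth_karyotypes[s] == INV_HOM]
    if not anc or not inv:
        return np.array([], dtype=int)
    da = G.dosages[anc, :]
    di = G.dosages[inv, :]
    fixed = (
        (np.all(da == 0, axis=0) & np.all(di == 2, axis=0))
        | (np.all(da == 2, axis=0) & np.all(di == 0, axis=0))
    )
    return np.nonzero(fixed)[0]


# ---------------------------------------------------------------------------
# ortholog families
# ---------------------------------------------------------------------------

def _species_tree(ages: dict[str, float]):
    """Fixed ultrametric species tree as nested (age, children-or-label)."""
    def clade(k: int, trout_tips):
        return (
            ages["salmonid_tmrca"],
            [
                (
                    ages["whitefish_grayling_split"],
                    [f"whitefish{k}", f"grayling{k}"],
                ),
                (
                    ages["salmo_oncorhynchus_split"],
                    [f"atlantic{k}", trout_tips],
                ),
            ],
        )

    trout_pair = (ages["t_inv"], ["trout_anc", "trout_inv"])
    return (
        ages["root"],
        [
            (ages["esociform_split"], ["pike", "mudminnow"]),
            (ages["wgd"], [clade(1, trout_pair), clade(2, "trout_homeo2")]),
        ],
    )


def _evolve_jc(rng, seq: np.ndarray, t: float, rate: float) -> np.ndarray:
    """One JC69 draw after time t (MY) at `rate` subs/site/MY."""
    p_change = 0.75 * (1.0 - math.exp(-4.0 / 3.0 * rate * t))
    out = seq.copy()
    hit = np.nonzero(rng.random(len(seq)) < p_change)[0]
    if len(hit):
        out[hit] = (out[hit] + rng.integers(1, 4, size=len(hit))) % 4
    return out


def _evolve_node(rng, node, parent_age: float, parent_seq: np.ndarray, rate: float,
                 out: dict[str, np.ndarray]) -> None:
    if isinstance(node, str):
        # terminal branch already applied by caller; record
        out[node] = parent_seq
        return
    age, children = node
    for child in children:
        if isinstance(child, str):
            seq = _evolve_jc(rng, parent_seq, age, rate)
            out[child] = seq
        else:
            child_age = child[0]
            seq = _evolve_jc(rng, parent_seq, age - child_age, rate)
            _evolve_node(rng, child, child_age, seq, rate, out)


def simulate_ortholog_families(params: OrthologSimParams) -> list[OrthologFamily]:
    """Evolve ortholog families along the fixed species tree (JC69, strict rate).

    Each family has two esociform outgroups and two homeolog clades, with the
    focal clade carrying the two rainbow-trout inversion haplotypes diverged
    ``t_inv`` MY ago. No indels: all sequences share one length.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    tree = _species_tree(params.species_tree_ages)
    families = []
    for i in range(params.n_families):
        root_seq = rng.integers(0, 4, size=params.seq_length).astype(np.int8)
        out: dict[str, np.ndarray] = {}
        root_age, children = tree
        for child in children:
            seq = _evolve_jc(rng, root_seq, root_age - child[0], params.subst_rate)
            _evolve_node(rng, child, child[0], seq, params.subst_rate, out)
        seqs = {
            label: "".join(_BASES[out[label]]) for label in FAMILY_TAXA
        }
        families.append(OrthologFamily(family_id=f"fam{i:04d}", sequences=seqs))
    return families


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

_CATEGORIES = ("BP", "MF", "CC")


def simulate_annotation(params: AnnotationSimParams
                        ) -> tuple[pd.DataFrame, set[str], list[str]]:
    """Gene -> term table with planted enrichment inside the inversion interval.

    Terms are assigned per gene by independent Bernoulli draws at
    ``baseline_term_prob``; enriched terms multiply that probability inside
    the interval (clipped to 1 with a warning). Genes carrying no term are
    kept in the table with term_id '.' so the gene universe round-trips.

    Returns (annotation table, set of CI gene ids, truth list of planted
    enriched terms; empty when every multiplier is 1).
    """
    import warnings

    params.validate()
    rng = np.random.default_rng(params.seed)
    n_ci = int(round(params.n_genes * params.ci_gene_fraction))
    gene_ids = np.array([f"g{i:05d}" for i in range(params.n_genes)], dtype=object)
    in_ci = np.zeros(params.n_genes, dtype=bool)
    in_ci[:n_ci] = True

    starts = np.empty(params.n_genes, dtype=np.int64)
    starts[in_ci] = np.sort(
        rng.integers(params.ci_start, params.ci_end - 1000, size=n_ci)
    )
    starts[~in_ci] = rng.integers(
        params.ci_end + 1, params.chrom_length - 1000, size=params.n_genes - n_ci
    )
    ends = starts + 1000

    terms = [f"T{i:03d}" for i in range(params.n_terms)]
    categories = {t: _CATEGORIES[i % 3] for i, t in enumerate(terms)}
    truth = [
        t for t, m in params.enriched_terms.items() if m > 1.0 and t in set(terms)
    ]

    rows = []
    has_term = np.zeros(params.n_genes, dtype=bool)
    for t in terms:
        p_out = params.baseline_term_prob
        p_in = p_out * params.enriched_terms.get(t, 1.0)
        if p_in > 1.0:
            warnings.warn(f"probability*multiplier > 1 for {t}; clipped to 1")
            p_in = 1.0
        p_vec = np.where(in_ci, p_in, p_out)
        hit = rng.random(params.n_genes) < p_vec
        has_term |= hit
        for g in np.nonzero(hit)[0]:
            rows.append((gene_ids[g], params.chrom, starts[g], ends[g], t,
                         categories[t]))
    for g in np.nonzero(~has_term)[0]:
        rows.append((gene_ids[g], params.chrom, starts[g], ends[g], ".", "NA"))
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "term_id", "category"]
    ).sort_values(["gene_id", "term_id"], kind="stable").reset_index(drop=True)
    ci_genes = set(gene_ids[in_ci])
    return df, ci_genes, truth


# ---------------------------------------------------------------------------
# serialization of simulated outputs
# ---------------------------------------------------------------------------

def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, str]:
    """Write cohort.vcf, samples.tsv and truth.tsv; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": str(outdir / "cohort.vcf"),
        "samples": str(outdir / "samples.tsv"),
        "truth": str(outdir / "truth.tsv"),
    }
    write_vcf(cohort.genotypes, paths["vcf"])
    write_samples_tsv(
        cohort.genotypes.population_of, cohort.genotypes.latitude_of, paths["samples"]
    )
    pd.DataFrame(
        [(s, k) for s, k in cohort.truth_karyotypes.items()],
        columns=["sample", "karyotype"],
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def write_families(families, outdir) -> list[str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for fam in families:
        p = str(outdir / f"{fam.family_id}.fasta")
        write_family_fasta(fam.sequences, p)
        paths.append(p)
    return paths
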