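"""Pairwise LD along a chromosome, inversion-block detection, diagnostic loci.

A polymorphic inversion suppresses recombination between orientations, so
sites inside it show high r-squared over megabase distances while background
LD decays quickly. The scan computes composite (Rogers-Huff) LD — the squared
Pearson correlation of unphased dosage vectors over pairwise-complete
samples — keeps pairs above a threshold (default 0.8, MAF >= 0.05), and
builds a graph whose edges are high-LD pairs separated by at least a minimum
distance (default 1 Mb). The largest connected component with enough
supporting pairs delimits the inversion. Karyotype-diagnostic loci are then
chosen inside the region: samples are clustered into three karyotype groups
on their mean standardized dosage, and a locus is diagnostic when its
genotypes match the 0/1/2 pattern implied by cluster identity in at least a
concordance fraction of non-missing samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .genio import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class LDPair:
    index_i: int
    index_j: int
    pos_i: int
    pos_j: int
    r2: float

    def __post_init__(self) -> None:
        if not self.index_i < self.index_j:
            raise ValueError("require index_i < index_j")
        if not -1e-12 <= self.r2 <= 1 + 1e-12:
            raise ValueError(f"r2 {self.r2} outside [0, 1]")


@dataclass
class InversionRegion:
    chrom: str
    start: int
    end: int
    n_support_pairs: int
    member_sites: np.ndarray
    orientation_source: str = "majority"
    #: qualifying LD components merged into this region, each an index array;
    #: every component is one internally consistent haplotype axis
    component_sites: list | None = None

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DiagnosticLocus:
    site_index: int
    inverted_allele: str  # 'ref' or 'alt': the allele tagging the inverted class
    concordance: float


def minor_allele_frequencies(G: GenotypeMatrix) -> np.ndarray:
    """Per-site minor allele frequency over non-missing samples (NaN if none)."""
    d = G.dosages.astype(float)
    d[G.missing_mask()] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        p = np.nanmean(d, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def compute_r2(G: GenotypeMatrix, maf_min: float = 0.05, r2_min: float = 0.8,
               min_joint: int = 10) -> list[LDPair]:
    """All site pairs with composite-LD r-squared >= r2_min after MAF filtering.

    Monomorphic sites and sites with MAF < maf_min are excluded before
    pairing; pairs with fewer than ``min_joint`` jointly non-missing samples
    are skipped. Correlations are pairwise-complete, computed with masked
    cross-products so the result matches a per-pair Pearson correlation over
    the jointly observed samples.
    """
    maf = minor_allele_frequencies(G)
    keep = np.nonzero(np.nan_to_num(maf) >= maf_min)[0]
    # exclude monomorphic sites even when maf_min == 0
    keep = keep[np.nan_to_num(maf[keep]) > 0]
    if len(keep) < 2:
        warnings.warn("fewer than 2 polymorphic sites after MAF filter")
        return []

    X = G.dosages[:, keep].astype(float)
    M = (X != MISSING).astype(float)
    X = np.where(M > 0, X, 0.0)

    n = M.T @ M                      # jointly non-missing counts
    sx = X.T @ M                     # sum of x over joint support
    sy = sx.T
    sxy = X.T @ X
    sxx = (X * X).T @ M
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        varx = sxx - sx * sx / n
        vary = syy - sy * sy / n
        r2 = (cov * cov) / (varx * vary)

    iu, ju = np.triu_indices(len(keep), k=1)
    valid = (n[iu, ju] >= min_joint) & np.isfinite(r2[iu, ju])
    hit = valid & (r2[iu, ju] >= r2_min)
    pairs = []
    for a, b in zip(iu[hit], ju[hit]):
        i, j = int(keep[a]), int(keep[b])
        pairs.append(
            LDPair(
                index_i=i,
                index_j=j,
                pos_i=int(G.positions[i]),
                pos_j=int(G.positions[j]),
                r2=float(min(r2[a, b], 1.0)),
            )
        )
    return pairs


def detect_inversion_region(pairs, chrom: str = "", min_distance: int = 1_000_000,
                            min_pairs: int = 50) -> InversionRegion | None:
    """Delimit the inversion from long-range high-LD pairs, or None.

    Only pairs at least ``min_distance`` apart support the graph (short-range
    LD is ubiquitous and uninformative about inversions). The region is the
    positional extent of the largest connected component carrying at least
    ``min_pairs`` supporting pairs; absence is a valid result.
    """
    long_pairs = [p for p in pairs if p.pos_j - p.pos_i >= min_distance]
    if not long_pairs:
        return None
    graph = nx.Graph()
    for p in long_pairs:
        graph.add_edge(p.index_i, p.index_j)
    pos_of = {}
    for p in long_pairs:
        pos_of[p.index_i] = p.pos_i
        pos_of[p.index_j] = p.pos_j
    blocks = []  # qualifying components as [start, end, [site sets], n_edges]
    for comp in nx.connected_components(graph):
        n_edges = graph.subgraph(comp).number_of_edges()
        if n_edges < min_pairs:
            continue
        positions = [pos_of[i] for i in comp]
        blocks.append([min(positions), max(positions), [set(comp)], n_edges])
    if not blocks:
        return None
    # components with overlapping spans are one recombination-suppressed
    # block: the r2 threshold fragments its site graph (e.g. fixed
    # differences between orientations vs an old within-orientation
    # haplotype partition form separate cliques over the same interval)
    blocks.sort(key=lambda b: b[0])
    merged = [blocks[0]]
    for b in blocks[1:]:
        last = merged[-1]
        if b[0] <= last[1]:
            last[1] = max(last[1], b[1])
            last[2].extend(b[2])
            last[3] += b[3]
        else:
            merged.append(b)
    start, end, comps, n_edges = max(
        merged, key=lambda b: (sum(len(c) for c in b[2]), b[3])
    )
    members = np.array(sorted(set().union(*comps)))
    return InversionRegion(
        chrom=chrom,
        start=int(start),
        end=int(end),
        n_support_pairs=n_edges,
        member_sites=members,
        component_sites=[np.array(sorted(c)) for c in
                         sorted(comps, key=len, reverse=True)],
    )


def _standardized_dosages(G: GenotypeMatrix, site_idx: np.ndarray) -> np.ndarray:
    """Samples x sites standardized dosages (NaN where missing/monomorphic)."""
    d = G.dosages[:, site_idx].astype(float)
    d[d == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mu = np.nanmean(d, axis=0)
        sd = np.nanstd(d, axis=0)
    sd[sd == 0] = np.nan
    return (d - mu) / sd


def _axis_scores(z: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Per-sample mean standardized dosage, each site oriented by its loading.

    Either allele of a site may tag the inverted orientation, so each site's
    standardized dosage is flipped to the polarity of the given principal
    axis; without that orientation the signals of opposite-polarity sites
    cancel in the mean.
    """
    signs = np.sign(axis)
    signs[signs == 0] = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        scores = np.nanmean(z * signs, axis=1)
    return np.nan_to_num(scores)


def _region_scores(G: GenotypeMatrix, site_idx: np.ndarray) -> np.ndarray:
    """Scores along the leading principal axis of the region genotypes."""
    z = _standardized_dosages(G, site_idx)
    _, _, vt = np.linalg.svd(np.nan_to_num(z), full_matrices=False)
    return _axis_scores(z, vt[0])


def _kmeans3(scores: np.ndarray) -> np.ndarray:
    """Deterministic 1-D k-means (k = 3) on region scores.

    Centers initialize at the scores of the samples ranked at quantiles
    {0.05, 0.5, 0.95}; ties break by sample order. Returns cluster labels
    0/1/2 ordered by ascending center.
    """
    from sklearn.cluster import KMeans

    order = np.argsort(scores, kind="stable")
    n = len(scores)
    qidx = [order[int(round(q * (n - 1)))] for q in (0.05, 0.5, 0.95)]
    init = scores[qidx].reshape(-1, 1).astype(float)
    km = KMeans(n_clusters=3, init=init, n_init=1, max_iter=300)
    labels = km.fit_predict(scores.reshape(-1, 1))
    rank = np.argsort(np.argsort(km.cluster_centers_.ravel()))
    return rank[labels]


def select_diagnostic_loci(G: GenotypeMatrix, region: InversionRegion,
                           concordance_min: float = 0.95,
                           ancestral_reference: str | None = None
                           ) -> list[DiagnosticLocus]:
    """Loci inside the region whose genotypes track the karyotype clusters.

    Samples are clustered into three groups on mean oriented standardized
    dosage over the region's sites; a locus is kept when, in one orientation,
    its dosage equals the cluster-implied value (0 for one homokaryotype,
    1 for heterokaryotypes, 2 for the other) in >= ``concordance_min`` of
    non-missing samples. A recombination-suppressed block can carry more
    than one strong haplotype axis (an old within-orientation partition
    alongside the karyotype axis), so the top principal axes are each tried
    and the axis yielding the most concordant loci wins. Orientation of the
    'inverted' label: the cluster at higher overall haplotype frequency is
    labeled inverted unless ``ancestral_reference`` names a sample anchoring
    the ancestral cluster.
    """
    if G.n_samples < 3:
        raise ValueError("need at least 3 samples")
    site_idx = np.intersect1d(
        region.member_sites, G.region_sites(region.start, region.end)
    )
    if len(site_idx) == 0:
        site_idx = G.region_sites(region.start, region.end)
    maf = minor_allele_frequencies(G.take_sites(site_idx))
    if not np.any(np.nan_to_num(maf) > 0):
        raise ValueError("region not karyotypically variable: all sites monomorphic")

    # candidate karyotype scores: one per LD component (each component is an
    # internally consistent haplotype axis; the global principal axes are
    # unusable when two axes have comparable variance, as the SVD then
    # returns an arbitrary rotation of their plane)
    candidate_scores = []
    if region.component_sites:
        for comp in region.component_sites[:3]:
            comp = np.intersect1d(comp, site_idx)
            if len(comp) < 2:
                continue
            zc = _standardized_dosages(G, comp)
            _, _, vtc = np.linalg.svd(np.nan_to_num(zc), full_matrices=False)
            candidate_scores.append(_axis_scores(zc, vtc[0]))
    if not candidate_scores:
        z = _standardized_dosages(G, site_idx)
        _, _, vt = np.linalg.svd(np.nan_to_num(z), full_matrices=False)
        candidate_scores = [_axis_scores(z, vt[k])
                            for k in range(min(3, vt.shape[0]))]

    best: tuple[list, str] | None = None
    occupied_somewhere = False
    for scores in candidate_scores:
        clusters = _kmeans3(scores)
        occupied = np.unique(clusters)
        if len(occupied) < 2:
            continue
        occupied_somewhere = True
        counts = np.bincount(clusters, minlength=3)
        # haplotype frequency of the high-score class: (2 n_high + n_mid)/2n
        freq_high = (2 * counts[2] + counts[1]) / (2 * len(clusters))
        if ancestral_reference is not None:
            ref_cluster = clusters[G.sample_ids.index(ancestral_reference)]
            if ref_cluster == 1:
                continue  # reference must anchor a homokaryotype cluster
            inverted_high = ref_cluster == 0
            source = f"reference:{ancestral_reference}"
        else:
            inverted_high = freq_high >= 0.5
            source = "majority"

        # expected oriented dosage per cluster: inverted copies carried
        expected_inv = clusters if inverted_high else 2 - clusters
        loci = []
        for s in site_idx:
            d = G.dosages[:, s]
            obs = d != MISSING
            if not obs.any():
                continue
            conc_alt = float(np.mean(d[obs] == expected_inv[obs]))
            conc_ref = float(np.mean((2 - d[obs]) == expected_inv[obs]))
            if conc_alt >= conc_ref:
                conc, allele = conc_alt, "alt"
            else:
                conc, allele = conc_ref, "ref"
            if conc >= concordance_min:
                loci.append(
                    DiagnosticLocus(site_index=int(s), inverted_allele=allele,
                                    concordance=conc)
                )
        if best is None or len(loci) > len(best[0]):
            best = (loci, source)
    if best is None:
        if ancestral_reference is not None and occupied_somewhere:
            raise ValueError(
                "ancestral reference sample falls in the middle cluster"
            )
        raise ValueError(
            "region not karyotypically variable: < 2 occupied clusters"
        )
    region.orientation_source = best[1]
    return best[0]
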