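"""Ortholog-family topology validation and calibrated strict-clock dating.

The inversion's age is the TMRCA of the two rainbow-trout inversion
haplotypes (ancestral and inverted orientation) within each ortholog family.
Families first pass topology criteria evaluated on a neighbor-joining tree
of JC69 distances, rooted by the esociform outgroup pair: the two homeolog
clades from the salmonid whole-genome duplication must each be monophyletic,
Atlantic salmon and rainbow trout must be sisters within each clade, the two
inversion-haplotype sequences must be sisters, and they must not be
identical (invariant families carry no dating signal). The age is then
obtained under a strict molecular clock from a single fixed calibration
node: the Salmo-Oncorhynchus split, default 27.3 MY. Per-family ages are
summarized by their median and mean.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from statistics import mean, median

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

OUTGROUP_TAXA = ("pike", "mudminnow")
CLADE1_TAXA = ("whitefish1", "grayling1", "atlantic1", "trout_anc", "trout_inv")
CLADE2_TAXA = ("whitefish2", "grayling2", "atlantic2", "trout_homeo2")
REQUIRED_TAXA = OUTGROUP_TAXA + CLADE1_TAXA + CLADE2_TAXA

DEFAULT_CALIBRATION_AGE_MY = 27.3


@dataclass
class OrthologFamily:
    """Aligned equal-length sequences of one ortholog family, keyed by taxon."""

    family_id: str
    sequences: dict[str, str]

    def require(self, labels=REQUIRED_TAXA) -> None:
        for label in labels:
            if label not in self.sequences:
                raise KeyError(f"family {self.family_id} missing label '{label}'")


@dataclass
class TopologyReport:
    family_id: str
    two_homeolog_clades: bool
    salmo_oncorhynchus_sister_in_each: bool
    inversion_pair_sister: bool
    inversion_pair_identical: bool

    @property
    def passes(self) -> bool:
        return (
            self.two_homeolog_clades
            and self.salmo_oncorhynchus_sister_in_each
            and self.inversion_pair_sister
            and not self.inversion_pair_identical
        )


@dataclass(frozen=True)
class Calibration:
    node: str = "salmo_oncorhynchus_split"
    age_my: float = DEFAULT_CALIBRATION_AGE_MY

    def __post_init__(self) -> None:
        if self.age_my <= 0:
            raise ValueError("calibration age must be > 0")


@dataclass
class AgeEstimate:
    family_id: str
    d_inv_pair: float
    d_cal_pair: float
    tmrca_my: float


@dataclass
class AgeSummary:
    median_my: float
    mean_my: float
    n_families: int
    estimates: list[AgeEstimate] = field(default_factory=list)


def jc69_distance(seq_a: str, seq_b: str, min_sites: int = 100) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - (4/3) p).

    Sites with N or '-' in either sequence are excluded; fewer than
    ``min_sites`` comparable sites or p >= 0.75 (saturation) is an error.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    ok = np.isin(a, (b"A", b"C", b"G", b"T")) & np.isin(b, (b"A", b"C", b"G", b"T"))
    n_ok = int(ok.sum())
    if n_ok < min_sites:
        raise ValueError(f"only {n_ok} comparable sites (< {min_sites})")
    p = float((a[ok] != b[ok]).mean())
    if p >= 0.75:
        raise ValueError(f"JC69 saturated: p = {p:.3f} >= 0.75")
    return -0.75 * float(np.log1p(-4.0 * p / 3.0))


def family_distance_matrix(family: OrthologFamily, labels=None,
                           min_sites: int = 100):
    """Pairwise JC69 distances over the family's taxa (ordered labels, matrix)."""
    labels = list(labels or family.sequences)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jc69_distance(
                family.sequences[labels[i]], family.sequences[labels[j]],
                min_sites=min_sites,
            )
    return labels, d


def nj_tree(distances: np.ndarray, labels):
    """Neighbor-joining tree from a symmetric non-negative distance matrix."""
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 2 or distances.shape[0] != distances.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(distances, distances.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(distances < 0):
        raise ValueError("distances must be non-negative")
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    dm = DistanceMatrix(distances, ids=list(labels))
    return nj(dm)


def _bipartitions(tree) -> set[frozenset]:
    """Non-trivial tip bipartitions of an (arbitrarily rooted) tree.

    Each bipartition is stored as both sides, so membership of a clade can be
    tested directly against either orientation.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    parts: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 0 < len(side) < len(all_tips):
            parts.add(side)
            parts.add(all_tips - side)
    return parts


def _is_clade(parts: set[frozenset], labels) -> bool:
    target = frozenset(labels)
    if len(target) <= 1:
        return True
    return target in parts


def check_ortholog_topology(tree, family: OrthologFamily) -> TopologyReport:
    """Evaluate the filtering criteria on the family's gene tree.

    Clade criteria are bipartition membership tests, which is equivalent to
    monophyly after rooting on the esociform outgroup pair. The identity flag
    compares the two inversion-haplotype sequences as strings.
    """
    family.require()
    tip_names = {t.name for t in tree.tips()}
    for label in REQUIRED_TAXA:
        if label not in tip_names:
            raise KeyError(f"tree missing required label '{label}'")
    parts = _bipartitions(tree)
    return TopologyReport(
        family_id=family.family_id,
        two_homeolog_clades=_is_clade(parts, CLADE1_TAXA)
        and _is_clade(parts, CLADE2_TAXA),
        salmo_oncorhynchus_sister_in_each=_is_clade(
            parts, ("atlantic1", "trout_anc", "trout_inv")
        )
        and _is_clade(parts, ("atlantic2", "trout_homeo2")),
        inversion_pair_sister=_is_clade(parts, ("trout_anc", "trout_inv")),
        inversion_pair_identical=family.sequences["trout_anc"]
        == family.sequences["trout_inv"],
    )


def topology_report(family: OrthologFamily, min_sites: int = 100) -> TopologyReport:
    """Convenience: JC69 distances -> NJ tree -> topology criteria."""
    labels, d = family_distance_matrix(family, REQUIRED_TAXA, min_sites=min_sites)
    return check_ortholog_topology(nj_tree(d, labels), family)


def filter_families(families, reports):
    """Keep families whose report passes; tally rejections per criterion."""
    by_id = {r.family_id: r for r in reports}
    kept = []
    tally: Counter = Counter()
    for fam in families:
        r = by_id[fam.family_id]
        if r.passes:
            kept.append(fam)
            continue
        if not r.two_homeolog_clades:
            tally["not_two_homeolog_clades"] += 1
        if not r.salmo_oncorhynchus_sister_in_each:
            tally["salmo_oncorhynchus_not_sister"] += 1
        if not r.inversion_pair_sister:
            tally["inversion_pair_not_sister"] += 1
        if r.inversion_pair_identical:
            tally["invariant"] += 1
    return kept, dict(tally)


def estimate_tmrca(family: OrthologFamily,
                   calibration: Calibration = Calibration(),
                   min_sites: int = 100) -> AgeEstimate:
    """Strict-clock TMRCA of the inversion-haplotype pair.

    The clock rate is set by the mean of the two trout-to-Atlantic-salmon
    distances in the focal clade divided by twice the calibration age; the
    inversion age is the trout_anc/trout_inv distance divided by twice that
    rate (equivalently d_inv / d_cal * age).
    """
    family.require(("trout_anc", "trout_inv", "atlantic1"))
    d_anc = jc69_distance(
        family.sequences["trout_anc"], family.sequences["atlantic1"], min_sites
    )
    d_inv_cal = jc69_distance(
        family.sequences["trout_inv"], family.sequences["atlantic1"], min_sites
    )
    d_cal = 0.5 * (d_anc + d_inv_cal)
    if d_cal == 0:
        raise ValueError(
            f"family {family.family_id}: zero calibration distance, no signal for rate"
        )
    d_inv = jc69_distance(
        family.sequences["trout_anc"], family.sequences["trout_inv"], min_sites
    )
    rate = d_cal / (2.0 * calibration.age_my)
    return AgeEstimate(
        family_id=family.family_id,
        d_inv_pair=d_inv,
        d_cal_pair=d_cal,
        tmrca_my=d_inv / (2.0 * rate),
    )


def summarize_ages(estimates) -> AgeSummary:
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no age estimates to summarize")
    ages = [e.tmrca_my for e in estimates]
    return AgeSummary(
        median_my=float(median(ages)),
        mean_my=float(mean(ages)),
        n_families=len(ages),
        estimates=estimates,
    )


def date_families(families, calibration: Calibration = Calibration(),
                  min_sites: int = 100):
    """Full dating stage: topology reports -> filter -> per-family ages -> summary.

    Returns (reports, tally, summary). Summary covers passing families only.
    """
    reports = [topology_report(f, min_sites=min_sites) for f in families]
    kept, tally = filter_families(families, reports)
    if not kept:
        raise ValueError("no families pass the topology criteria")
    estimates = [estimate_tmrca(f, calibration, min_sites=min_sites) for f in kept]
    return reports, tally, summarize_ages(estimates)
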