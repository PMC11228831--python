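"""Per-sample inversion karyotype calls and population frequency summaries.

Each sample's oriented dosage at a diagnostic locus counts copies of the
allele tagging the inverted orientation (0, 1, or 2). The mean over
non-missing loci is thresholded into ancestral homokaryotype (< 0.5),
heterokaryotype (0.75-1.25), inverted homokaryotype (> 1.5), with dead zones
in between and a 50% missingness cap guarding low-quality samples
(UNRESOLVED). Frequencies are summarized per population and ordered along
the latitudinal cline; a single diagnostic locus yields an allele-counting
frequency estimate with a Wilson 95% interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .genio import MISSING, GenotypeMatrix
from .ldscan import DiagnosticLocus

ANC_HOM = "ANC_HOM"
HET = "HET"
INV_HOM = "INV_HOM"
UNRESOLVED = "UNRESOLVED"

DEFAULT_THRESHOLDS = {
    "anc_max": 0.5,     # mean oriented dosage below this -> ANC_HOM
    "het_min": 0.75,
    "het_max": 1.25,
    "inv_min": 1.5,     # above this -> INV_HOM
}


@dataclass(frozen=True)
class KaryotypeCall:
    sample_id: str
    call: str
    mean_score: float
    n_loci_used: int
    missing_fraction: float


@dataclass
class PopFrequencyRecord:
    population: str
    latitude: float | None
    n: int
    count_anc_hom: int
    count_het: int
    count_inv_hom: int

    @property
    def freq_anc_hom(self) -> float:
        return self.count_anc_hom / self.n if self.n else float("nan")

    @property
    def freq_het(self) -> float:
        return self.count_het / self.n if self.n else float("nan")

    @property
    def freq_inv_hom(self) -> float:
        return self.count_inv_hom / self.n if self.n else float("nan")

    @property
    def freq_ancestral_allele(self) -> float:
        """Ancestral-orientation haplotype frequency (2*anc_hom + het) / 2n."""
        if not self.n:
            return float("nan")
        return (2 * self.count_anc_hom + self.count_het) / (2 * self.n)


def oriented_dosages(G: GenotypeMatrix, loci) -> np.ndarray:
    """Samples x loci matrix counting inverted-tagged alleles (MISSING kept)."""
    idx = np.array([l.site_index for l in loci], dtype=int)
    d = G.dosages[:, idx].astype(float)
    d[d == MISSING] = np.nan
    flip = np.array([l.inverted_allele == "ref" for l in loci])
    d[:, flip] = 2.0 - d[:, flip]
    return d


def call_karyotypes(G: GenotypeMatrix, loci,
                    thresholds: dict | None = None,
                    max_missing: float = 0.5) -> list[KaryotypeCall]:
    """Call every sample's inversion karyotype from the diagnostic loci."""
    loci = list(loci)
    if not loci:
        raise ValueError("no diagnostic loci provided")
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    od = oriented_dosages(G, loci)
    calls = []
    for i, sid in enumerate(G.sample_ids):
        row = od[i]
        n_obs = int(np.sum(~np.isnan(row)))
        miss = 1.0 - n_obs / len(loci)
        if n_obs == 0 or miss > max_missing:
            calls.append(KaryotypeCall(sid, UNRESOLVED, float("nan"), n_obs, miss))
            continue
        score = float(np.nanmean(row))
        if score < th["anc_max"]:
            call = ANC_HOM
        elif th["het_min"] <= score <= th["het_max"]:
            call = HET
        elif score > th["inv_min"]:
            call = INV_HOM
        else:
            call = UNRESOLVED
        calls.append(KaryotypeCall(sid, call, score, n_obs, miss))
    return calls


def population_frequencies(calls, population_of: dict[str, str],
                           latitude_of: dict[str, float] | None = None
                           ) -> tuple[list[PopFrequencyRecord], PopFrequencyRecord]:
    """Per-population karyotype counts/frequencies plus a cohort-total row.

    UNRESOLVED calls are excluded from n. Populations left empty after that
    exclusion get an n = 0 row with NaN frequencies and a warning.
    """
    latitude_of = latitude_of or {}
    unmapped = [c.sample_id for c in calls if c.sample_id not in population_of]
    if unmapped:
        raise ValueError(f"samples without a population: {unmapped}")
    pops: dict[str, list] = {}
    for c in calls:
        pops.setdefault(population_of[c.sample_id], []).append(c)
    records = []
    for pop in sorted(pops):
        counted = [c for c in pops[pop] if c.call != UNRESOLVED]
        counts = {k: sum(c.call == k for c in counted)
                  for k in (ANC_HOM, HET, INV_HOM)}
        if not counted:
            warnings.warn(f"population {pop}: no resolved calls (n = 0)")
        records.append(
            PopFrequencyRecord(
                population=pop,
                latitude=latitude_of.get(pop),
                n=len(counted),
                count_anc_hom=counts[ANC_HOM],
                count_het=counts[HET],
                count_inv_hom=counts[INV_HOM],
            )
        )
    total = PopFrequencyRecord(
        population="TOTAL",
        latitude=None,
        n=sum(r.n for r in records),
        count_anc_hom=sum(r.count_anc_hom for r in records),
        count_het=sum(r.count_het for r in records),
        count_inv_hom=sum(r.count_inv_hom for r in records),
    )
    return records, total


def frequencies_table(records, total=None) -> pd.DataFrame:
    """Tabulate records with percentages rounded to one decimal."""
    rows = list(records) + ([total] if total is not None else [])
    return pd.DataFrame(
        {
            "population": [r.population for r in rows],
            "latitude": [r.latitude for r in rows],
            "n": [r.n for r in rows],
            "count_anc_hom": [r.count_anc_hom for r in rows],
            "count_het": [r.count_het for r in rows],
            "count_inv_hom": [r.count_inv_hom for r in rows],
            "pct_anc_hom": [round(100 * r.freq_anc_hom, 1) for r in rows],
            "pct_het": [round(100 * r.freq_het, 1) for r in rows],
            "pct_inv_hom": [round(100 * r.freq_inv_hom, 1) for r in rows],
            "freq_ancestral_allele": [r.freq_ancestral_allele for r in rows],
        }
    )


def latitude_cline(records) -> pd.DataFrame:
    """Ancestral-haplotype frequency ordered by ascending latitude.

    Populations lacking a latitude are appended at the end with a flag.
    """
    with_lat = [r for r in records if r.latitude is not None]
    without = [r for r in records if r.latitude is None]
    with_lat.sort(key=lambda r: r.latitude)
    rows = [
        (r.population, r.latitude, r.n, r.freq_ancestral_allele, False)
        for r in with_lat
    ] + [
        (r.population, np.nan, r.n, r.freq_ancestral_allele, True)
        for r in without
    ]
    return pd.DataFrame(
        rows,
        columns=["population", "latitude", "n", "freq_ancestral_allele",
                 "latitude_missing"],
    )


def single_locus_frequency(count_anc_hom: int, count_het: int, count_inv_hom: int
                           ) -> tuple[float, tuple[float, float]]:
    """Ancestral-allele frequency at one diagnostic locus with Wilson 95% CI.

    Allele counting: (2*hom_anc + het) / 2n over n genotyped samples.
    """
    n = count_anc_hom + count_het + count_inv_hom
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    k = 2 * count_anc_hom + count_het
    freq = k / (2 * n)
    lo, hi = proportion_confint(k, 2 * n, alpha=0.05, method="wilson")
    return freq, (float(lo), float(hi))
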