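"""End-to-end orchestration: simulate -> ldscan -> karyotype -> popgen -> date, enrich.

One JSON config drives the run; every stage writes its outputs under the run
directory and the run closes with a machine-readable manifest carrying a
sha256 checksum per output file, so reruns with the same config and seed can
be audited for determinism. A failing stage aborts the run with the stage
named; files written by the failing stage keep a ``.partial`` marker.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import dating, enrich, genio, karyotype, ldscan, popgen, simdata

log = logging.getLogger("invkaryo")

DEFAULT_STAGE_PARAMS = {
    "r2_min": 0.8,
    "maf_min": 0.05,
    "min_distance": 1_000_000,
    "min_pairs": 50,
    "concordance_min": 0.95,
    "window": 50_000,
    "step": 10_000,
    "min_s": 100,
    "alpha": 0.05,
    "calibration_age_my": dating.DEFAULT_CALIBRATION_AGE_MY,
}


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    simulate: bool = True
    stages: dict = field(
        default_factory=lambda: {
            "ldscan": True,
            "karyotype": True,
            "popgen": True,
            "date": True,
            "enrich": True,
        }
    )
    params: dict = field(default_factory=dict)
    # used when simulate is false
    vcf: str | None = None
    samples: str | None = None
    loci: str | None = None
    families_dir: str | None = None
    annotations: str | None = None
    sim_cohort: dict = field(default_factory=dict)
    sim_orthologs: dict = field(default_factory=dict)
    sim_annotation: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        self.params = {**DEFAULT_STAGE_PARAMS, **self.params}
        unknown = set(self.stages) - {"ldscan", "karyotype", "popgen", "date",
                                      "enrich"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not self.simulate:
            if self.stages.get("ldscan") or self.stages.get("karyotype"):
                for name in ("vcf", "samples"):
                    p = getattr(self, name)
                    if not p or not Path(p).exists():
                        raise ValueError(f"simulation disabled but {name} "
                                         f"file missing: {p}")
            if self.stages.get("karyotype") and not self.stages.get("ldscan"):
                if not self.loci or not Path(self.loci).exists():
                    raise ValueError(
                        "karyotype enabled without ldscan and no loci file given"
                    )
            if self.stages.get("date") and not self.families_dir:
                raise ValueError("date stage enabled but families_dir missing")
            if self.stages.get("enrich") and not self.annotations:
                raise ValueError("enrich stage enabled but annotations missing")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_ld_outputs(outdir: Path, pairs, region):
    pd.DataFrame(
        [(p.index_i, p.index_j, p.pos_i, p.pos_j, p.r2) for p in pairs],
        columns=["i", "j", "pos_i", "pos_j", "r2"],
    ).to_csv(outdir / "ld_pairs.tsv", sep="\t", index=False)
    if region is not None:
        genio.write_bed(
            genio.region_to_bed(region.chrom, region.start, region.end),
            outdir / "region.bed",
        )


def write_loci_tsv(loci, path):
    pd.DataFrame(
        [(l.site_index, l.inverted_allele, l.concordance) for l in loci],
        columns=["site_index", "inverted_allele", "concordance"],
    ).to_csv(path, sep="\t", index=False)


def read_loci_tsv(path):
    df = pd.read_csv(path, sep="\t")
    return [
        ldscan.DiagnosticLocus(int(r.site_index), str(r.inverted_allele),
                               float(r.concordance))
        for r in df.itertuples()
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(outdir / "run.log")
    log.addHandler(fh)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    with open(outdir / "config.resolved.json", "w") as f:
        json.dump(config.__dict__, f, indent=2, default=str)

    state: dict = {}
    stage = "init"
    try:
        if config.simulate:
            stage = "simulate"
            t0 = time.time()
            cohort = simdata.simulate_inversion_cohort(
                simdata.CohortSimParams(**{"seed": config.seed,
                                           **config.sim_cohort})
            )
            simdata.write_cohort(cohort, outdir / "sim")
            state["G"] = cohort.genotypes
            state["cohort"] = cohort
            if config.stages.get("date", True):
                fams = simdata.simulate_ortholog_families(
                    simdata.OrthologSimParams(**{"seed": config.seed,
                                                 **config.sim_orthologs})
                )
                simdata.write_families(fams, outdir / "sim" / "families")
                state["families"] = fams
            if config.stages.get("enrich", True):
                ann, ci_genes, truth = simdata.simulate_annotation(
                    simdata.AnnotationSimParams(**{"seed": config.seed,
                                                   **config.sim_annotation})
                )
                ann.to_csv(outdir / "sim" / "annotations.tsv", sep="\t",
                           index=False)
                state["annotations"] = ann
                state["ci_genes"] = ci_genes
            manifest["stages"]["simulate"] = {"seconds": time.time() - t0}
        else:
            pop_of, lat_of = genio.read_samples_tsv(config.samples)
            state["G"] = genio.read_vcf(config.vcf, population_of=pop_of,
                                        latitude_of=lat_of)
            if config.stages.get("date"):
                state["families"] = [
                    dating.OrthologFamily(p.stem, genio.read_family_fasta(p))
                    for p in sorted(Path(config.families_dir).glob("*.fasta"))
                ]
            if config.stages.get("enrich"):
                state["annotations"] = genio.read_annotation_tsv(
                    config.annotations
                )

        P = config.params
        if config.stages.get("ldscan", True):
            stage = "ldscan"
            t0 = time.time()
            G = state["G"]
            pairs = ldscan.compute_r2(G, maf_min=P["maf_min"], r2_min=P["r2_min"])
            region = ldscan.detect_inversion_region(
                pairs, chrom=G.chrom, min_distance=P["min_distance"],
                min_pairs=P["min_pairs"],
            )
            write_ld_outputs(outdir, pairs, region)
            state["region"] = region
            if region is not None:
                loci = ldscan.select_diagnostic_loci(
                    G, region, concordance_min=P["concordance_min"]
                )
                write_loci_tsv(loci, outdir / "diagnostic_loci.tsv")
                state["loci"] = loci
            manifest["stages"]["ldscan"] = {
                "seconds": time.time() - t0,
                "n_pairs": len(pairs),
                "region": None if region is None
                else [region.start, region.end],
            }

        if config.stages.get("karyotype", True):
            stage = "karyotype"
            t0 = time.time()
            G = state["G"]
            loci = state.get("loci") or read_loci_tsv(config.loci)
            calls = karyotype.call_karyotypes(G, loci)
            recs, total = karyotype.population_frequencies(
                calls, G.population_of, G.latitude_of
            )
            pd.DataFrame(
                [(c.sample_id, c.call, c.mean_score, c.n_loci_used,
                  c.missing_fraction) for c in calls],
                columns=["sample", "call", "mean_score", "n_loci_used",
                         "missing_fraction"],
            ).to_csv(outdir / "calls.tsv", sep="\t", index=False)
            karyotype.frequencies_table(recs, total).to_csv(
                outdir / "pop_frequencies.tsv", sep="\t", index=False
            )
            karyotype.latitude_cline(recs).to_csv(
                outdir / "cline.tsv", sep="\t", index=False
            )
            state["calls"] = calls
            manifest["stages"]["karyotype"] = {"seconds": time.time() - t0}

        if config.stages.get("popgen", True):
            stage = "popgen"
            t0 = time.time()
            G = state["G"]
            calls = state["calls"]
            region = state.get("region")
            groups = {
                k: [c.sample_id for c in calls if c.call == k]
                for k in (karyotype.ANC_HOM, karyotype.HET, karyotype.INV_HOM)
            }
            chrom_length = int(G.positions[-1])
            mask = (region.start, region.end) if region else None
            for name in (karyotype.ANC_HOM, karyotype.INV_HOM):
                if len(groups[name]) < 2:
                    continue
                sub = G.take_samples(groups[name])
                wins = popgen.sliding_window_stats(
                    sub, chrom_length, window=P["window"], step=P["step"],
                    min_S=P["min_s"], region=mask,
                    region_mode="keep" if mask else "ignore",
                )
                pd.DataFrame(
                    [(w.chrom, w.start, w.end, w.S, w.theta_w, w.pi,
                      w.tajima_d, w.passes_filter) for w in wins],
                    columns=["chrom", "start", "end", "S", "theta_w", "pi",
                             "tajima_d", "passes_filter"],
                ).to_csv(outdir / f"windows_{name.lower()}.tsv", sep="\t",
                         index=False)
            if len(groups[karyotype.ANC_HOM]) >= 2 and \
                    len(groups[karyotype.INV_HOM]) >= 2:
                fst = popgen.weir_cockerham_fst(
                    G, groups[karyotype.ANC_HOM], groups[karyotype.INV_HOM]
                )
                pd.DataFrame(
                    [(r.site_index, r.pos, r.fst, r.n1, r.n2) for r in fst],
                    columns=["site_index", "pos", "fst", "n1", "n2"],
                ).to_csv(outdir / "fst.tsv", sep="\t", index=False)
            if region is not None:
                het = popgen.per_sample_heterozygosity(
                    G, G.region_sites(region.start, region.end)
                )
                pd.DataFrame({"sample": G.sample_ids, "heterozygosity": het}
                             ).to_csv(outdir / "heterozygosity.tsv", sep="\t",
                                      index=False)
                het_by = {
                    k: [het[G.sample_ids.index(s)] for s in v]
                    for k, v in groups.items() if len(v) >= 2
                }
                tests = []
                if karyotype.ANC_HOM in het_by and karyotype.INV_HOM in het_by:
                    t = popgen.welch_t_test(het_by[karyotype.ANC_HOM],
                                            het_by[karyotype.INV_HOM])
                    tests.append(("het_anc_vs_inv", t))
                if len(het_by) >= 2:
                    t = popgen.anova_oneway(list(het_by.values()))
                    tests.append(("het_anova_all_karyotypes", t))
                pd.DataFrame(
                    [(n, t.test_name, t.statistic, str(t.df), t.p_two_tailed)
                     for n, t in tests],
                    columns=["comparison", "test", "statistic", "df", "p"],
                ).to_csv(outdir / "tests.tsv", sep="\t", index=False)
            manifest["stages"]["popgen"] = {"seconds": time.time() - t0}

        if config.stages.get("date", True) and "families" in state:
            stage = "date"
            t0 = time.time()
            cal = dating.Calibration(age_my=P["calibration_age_my"])
            reports, tally, summary = dating.date_families(state["families"],
                                                           cal)
            pd.DataFrame(
                [(r.family_id, r.two_homeolog_clades,
                  r.salmo_oncorhynchus_sister_in_each, r.inversion_pair_sister,
                  r.inversion_pair_identical, r.passes) for r in reports],
                columns=["family_id", "two_homeolog_clades",
                         "salmo_onco_sister", "inversion_pair_sister",
                         "invariant", "passes"],
            ).to_csv(outdir / "topology_reports.tsv", sep="\t", index=False)
            pd.DataFrame(
                [(e.family_id, e.d_inv_pair, e.d_cal_pair, e.tmrca_my)
                 for e in summary.estimates],
                columns=["family_id", "d_inv_pair", "d_cal_pair", "tmrca_my"],
            ).to_csv(outdir / "ages.tsv", sep="\t", index=False)
            with open(outdir / "age_summary.json", "w") as f:
                json.dump(
                    {"median_my": summary.median_my, "mean_my": summary.mean_my,
                     "n_families": summary.n_families, "rejections": tally},
                    f, indent=2,
                )
            manifest["stages"]["date"] = {"seconds": time.time() - t0,
                                          "median_my": summary.median_my}

        if config.stages.get("enrich", True) and "annotations" in state:
            stage = "enrich"
            t0 = time.time()
            ann = state["annotations"]
            if "ci_genes" in state:
                ci_genes = state["ci_genes"]
            else:
                region = state.get("region")
                if region is None:
                    raise ValueError("enrich stage needs a detected region or "
                                     "simulated truth gene set")
                inside = (ann["start"] <= region.end) & (ann["end"] >= region.start)
                ci_genes = set(ann.loc[inside, "gene_id"])
            records, significant, per_cat = enrich.term_enrichment(
                ann, ci_genes, alpha=P["alpha"]
            )
            enrich.enrichment_table(records).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False
            )
            manifest["stages"]["enrich"] = {
                "seconds": time.time() - t0,
                "n_significant": len(significant),
                "per_category": per_cat,
            }
    except Exception:
        log.exception("stage '%s' failed", stage)
        (outdir / f"{stage}.partial").touch()
        raise
    finally:
        log.removeHandler(fh)
        fh.close()

    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest
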