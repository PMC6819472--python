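"""End-to-end orchestration: split -> quantify -> test -> classify ->
features / LTR promoters / methylation -> summary.

The pipeline consumes a :class:`StudyData` bundle — either simulated in
memory by :func:`simulate_study` or loaded from the TSV/BED files the
``simulate`` CLI subcommand writes — and produces a :class:`ResultBundle`
with imprint calls, LTR promoter calls, feature-enrichment reports, DMR
reports and a summary.  Every stage logs its input/output record counts,
and a rerun with the same config and seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import allelesplit, biastest, imprintcall, ltrprom, methylome, quantify, repeatfeat
from . import core_io, simdata
from .core_io import GenomicInterval

logger = logging.getLogger("imprintseq")

RECIPROCAL_CROSSES = ("B6/CAST", "CAST/B6")
MATDKO = "matDKO/CAST"


@dataclass
class PipelineConfig:
    """Analysis thresholds; defaults are the pipeline's standard constants."""

    min_reads_chip: int = 20
    min_reads_rna: int = 5
    alpha: float = 0.05
    ratio_band: tuple = imprintcall.RATIO_BAND_DEFAULT
    dmr_delta: float = methylome.DMR_DELTA_DEFAULT
    dmr_min_calls: int = methylome.MIN_CALLS_DEFAULT
    dmr_min_cpgs: int = methylome.MIN_CPGS_DEFAULT
    promoter_upstream: int = 1000
    promoter_downstream: int = 500
    gene_max_distance: int = 10_000
    tss_window: int = 3000
    methyl_flank: int = 500
    ltr_min_reads: int = 5
    ltr_min_replicates: int = 2
    background_n: int = 100
    rho: float | None = None  # None -> estimated from the data
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_reads_chip", "min_reads_rna", "promoter_upstream",
                     "promoter_downstream", "gene_max_distance", "tss_window",
                     "methyl_flank", "ltr_min_reads", "ltr_min_replicates",
                     "background_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class StudyData:
    """All pipeline inputs for one tissue."""

    peaks: list
    genes: list
    repeats: list
    cgis: list
    gdmr_regions: list  # known paternal-gDMR intervals
    oocyte_domains: dict
    ltr_sequences: dict
    chip_counts: dict  # cross -> DataFrame
    rna_counts: dict  # cross -> DataFrame
    rna_reads: dict  # cross -> list[ReadRecord]
    methyl_sites: dict  # cross -> list[MethylSite]
    snps_b6_cast: list = field(default_factory=list)
    snps_129_cast: list = field(default_factory=list)
    sample_sheet: list = field(default_factory=list)
    known_imprinted_genes: set = field(default_factory=set)


@dataclass
class ResultBundle:
    imprint_calls: list
    bias_results: dict  # cross -> list[BiasResult]
    rna_bias_results: dict
    dispersion: object
    informative_regions: list
    validation_table: pd.DataFrame
    validation_fraction: float
    ltr_promoter_calls: list
    ltr_expression: pd.DataFrame
    enrichment: list
    tss_table: pd.DataFrame | None
    solo_stats: dict | None
    germline_table: pd.DataFrame | None
    cpg_welch: tuple | None
    dmr_calls: list
    trajectories: list
    summary: dict


# ---------------------------------------------------------------------------
# Simulation front-end
# ---------------------------------------------------------------------------

def simulate_study(config: simdata.SimConfig) -> tuple[StudyData, pd.DataFrame]:
    """Generate a full synthetic study and its truth table."""
    reference, truth = simdata.simulate_reference(config)
    chip, rna_counts, rna_reads, methyl = {}, {}, {}, {}
    for cross in simdata.CROSSES:
        chip[cross] = simdata.simulate_allelic_chip_counts(reference, truth,
                                                           config, cross)
        reads, counts = simdata.simulate_rna_reads(reference, truth, config, cross)
        rna_reads[cross], rna_counts[cross] = reads, counts
    for cross in ("B6/CAST", MATDKO):
        methyl[cross] = simdata.simulate_methylation(reference, truth, config, cross)
    gdmr = []
    peaks_by_id = {p.id: p for p in reference.peaks}
    for row in truth.itertuples(index=False):
        if row.class_label == simdata.CLASS_CANONICAL_PATERNAL:
            gdmr.append(peaks_by_id[row.region_id].interval)
    known = set(truth.loc[truth["class_label"].isin([
        simdata.CLASS_CANONICAL_MATERNAL, simdata.CLASS_CANONICAL_PATERNAL,
        simdata.CLASS_NONCANONICAL]), "gene_id"])
    data = StudyData(
        peaks=reference.peaks, genes=reference.genes, repeats=reference.repeats,
        cgis=reference.cgis, gdmr_regions=gdmr,
        oocyte_domains=reference.oocyte_domains,
        ltr_sequences=reference.ltr_sequences,
        chip_counts=chip, rna_counts=rna_counts, rna_reads=rna_reads,
        methyl_sites=methyl,
        snps_b6_cast=reference.snps_b6_cast,
        snps_129_cast=reference.snps_129_cast,
        sample_sheet=simdata.simulate_sample_sheet(config),
        known_imprinted_genes=known,
    )
    return data, truth


# ---------------------------------------------------------------------------
# Core analysis
# ---------------------------------------------------------------------------

def run_pipeline(data: StudyData, params: PipelineConfig | None = None
                 ) -> ResultBundle:
    """Run every analysis stage on a study bundle."""
    params = params or PipelineConfig()

    # --- informativeness filter over the reciprocal crosses --------------
    reciprocal = [data.chip_counts[c] for c in RECIPROCAL_CROSSES
                  if c in data.chip_counts]
    if not reciprocal:
        raise RuntimeError("stage filter: no reciprocal-cross ChIP counts")
    joint = pd.concat(reciprocal, ignore_index=True)
    informative = quantify.filter_informative(joint, "chip",
                                              threshold=params.min_reads_chip)
    logger.info("stage filter: %d/%d peaks informative",
                len(informative), joint["region_id"].nunique())
    informative_set = set(informative)

    # --- dispersion -------------------------------------------------------
    if params.rho is not None:
        dispersion = biastest.DispersionEstimate(params.rho, 0, "fixed")
    else:
        disp_counts = pd.concat(
            [data.chip_counts[c].assign(family=c) for c in RECIPROCAL_CROSSES
             if c in data.chip_counts], ignore_index=True)
        disp_counts = disp_counts[disp_counts["region_id"].isin(informative_set)]
        dispersion = biastest.estimate_dispersion(disp_counts)
    logger.info("stage dispersion: rho = %.4f (%d regions)",
                dispersion.rho, dispersion.n_regions_used)

    # --- allelic bias per cross ------------------------------------------
    bias_results = {}
    for cross in simdata.CROSSES:
        counts = data.chip_counts.get(cross)
        if counts is None:
            continue
        sub = counts[counts["region_id"].isin(informative_set)]
        if cross == MATDKO:
            # matDKO regions additionally need matDKO-informative data
            ok = set(quantify.filter_informative(sub, "chip",
                                                 threshold=params.min_reads_chip))
            sub = sub[sub["region_id"].isin(ok)]
        bias_results[cross] = biastest.allelic_bias_test(
            sub, rho=dispersion.rho, cross=cross, alpha=params.alpha)
        logger.info("stage test (%s): %d regions, %d significant", cross,
                    len(bias_results[cross]),
                    sum(r.significant for r in bias_results[cross]))

    # --- reciprocal + matDKO classification ------------------------------
    calls = imprintcall.classify_reciprocal(
        bias_results["B6/CAST"], bias_results["CAST/B6"])
    imprinted = [c for c in calls
                 if c.consensus_class in imprintcall.IMPRINTED_CLASSES]
    region_intervals = {p.id: p.interval for p in data.peaks}
    if MATDKO in bias_results:
        matdko_counts = data.chip_counts[MATDKO]
        ratios = biastest.allelic_ratio_table(
            matdko_counts[matdko_counts["region_id"].isin(informative_set)])
        ratio_map = dict(zip(ratios["region_id"], ratios["allelic_ratio"]))
        imprintcall.classify_canonical(
            imprinted, bias_results[MATDKO], data.gdmr_regions,
            region_intervals, ratio_map, params.ratio_band)
    else:
        # no matDKO contrast: mechanism cannot be resolved
        for call in imprinted:
            call.canonical_status = imprintcall.UNRESOLVED
    logger.info("stage classify: %d consensus imprints", len(imprinted))

    # --- peak-to-gene assignment ------------------------------------------
    for call in imprinted:
        peak = next(p for p in data.peaks if p.id == call.region_id)
        hits = imprintcall.assign_peak_to_gene(
            peak, data.genes, params.promoter_upstream,
            params.promoter_downstream, params.gene_max_distance)
        if hits:
            call.assigned_gene, call.promoter_overlap = hits[0][0].id, hits[0][1]

    # --- RNA bias + expression cross-validation ---------------------------
    rna_bias, informative_by_ds = {}, {}
    for cross in RECIPROCAL_CROSSES:
        counts = data.rna_counts.get(cross)
        if counts is None:
            continue
        inf = quantify.filter_informative(counts, "rna",
                                          threshold=params.min_reads_rna)
        informative_by_ds[f"RNA:{cross}"] = set(inf)
        sub = counts[counts["region_id"].isin(set(inf))]
        rna_bias[f"RNA:{cross}"] = {
            r.region_id: r for r in biastest.allelic_bias_test(
                sub, rho=dispersion.rho, cross=cross, alpha=params.alpha)}
    if rna_bias:
        validation_table, validation_fraction = imprintcall.cross_validate_expression(
            imprinted, rna_bias, informative_by_ds)
    else:
        validation_table, validation_fraction = pd.DataFrame(), float("nan")

    # --- LTR promoter discovery -------------------------------------------
    ervk = [r for r in data.repeats if r.repeat_family == "ERVK"]
    peak_context = {}
    for call in imprinted:
        if (call.canonical_status == imprintcall.NON_CANONICAL
                and call.consensus_class == imprintcall.IMPRINTED_PATERNAL):
            peak_context[call.region_id] = "non_canonical_paternal_peak"
    pooled_reads = [r for cross in RECIPROCAL_CROSSES
                    for r in data.rna_reads.get(cross, [])]
    promoter_calls = ltrprom.identify_active_ltr_promoters(
        ervk, data.peaks, pooled_reads, params.ltr_min_reads,
        params.ltr_min_replicates, peak_context)
    ltrs_by_id = {r.repeat_name: r for r in ervk}
    for call in promoter_calls:
        if call.is_active_promoter:
            ltrprom.type_transcript(call, ltrs_by_id[call.ltr_id],
                                    pooled_reads, data.genes)
    n_active = sum(c.is_active_promoter for c in promoter_calls)
    logger.info("stage ltr: %d/%d ERVK LTRs called active promoters",
                n_active, len(ervk))

    # --- allelic expression at active LTRs (B6/CAST orientation) ---------
    ltr_expression = pd.DataFrame()
    if data.snps_b6_cast and "B6/CAST" in data.rna_reads:
        snp_index = allelesplit.build_snp_index(data.snps_b6_cast)
        part = allelesplit.split_reads(data.rna_reads["B6/CAST"], snp_index,
                                       "B6/CAST")
        ltr_expression = ltrprom.ltr_allelic_expression(
            promoter_calls, ltrs_by_id,
            {"maternal": part.maternal, "paternal": part.paternal},
            rho=dispersion.rho, cross="B6/CAST")

    # --- feature statistics ----------------------------------------------
    nc_peaks = [region_intervals[c.region_id] for c in imprinted
                if c.canonical_status == imprintcall.NON_CANONICAL
                and c.consensus_class == imprintcall.IMPRINTED_PATERNAL]
    canon_peaks = [region_intervals[c.region_id] for c in imprinted
                   if c.canonical_status in (imprintcall.CANONICAL_MATERNAL,
                                             imprintcall.CANONICAL_PATERNAL)]
    enrichment, tss_table, solo_stats, germline_table, cpg_welch = [], None, None, None, None
    if nc_peaks and canon_peaks:
        catalogs = {"ERVK_LTR": [r.interval for r in ervk],
                    "CGI": data.cgis}
        enrichment = repeatfeat.feature_overlap_enrichment(
            nc_peaks, canon_peaks, catalogs)
    active_ltrs = [ltrs_by_id[c.ltr_id] for c in promoter_calls
                   if c.is_active_promoter]
    background_ltrs = [r for r in ervk
                       if r.repeat_name not in {a.repeat_name for a in active_ltrs}]
    if active_ltrs and background_ltrs:
        tss_table = repeatfeat.tss_proximity(active_ltrs, background_ltrs,
                                             data.genes, params.tss_window)
        solo_stats = repeatfeat.solo_ltr_stats(active_ltrs)
        focal_sets = {
            "non_canonical": [l for l in active_ltrs
                              if any(c.ltr_id == l.repeat_name
                                     and c.imprint_context == "non_canonical_paternal_peak"
                                     for c in promoter_calls)],
            "other_active": [l for l in active_ltrs
                             if not any(c.ltr_id == l.repeat_name
                                        and c.imprint_context == "non_canonical_paternal_peak"
                                        for c in promoter_calls)],
        }
        focal_sets = {k: v for k, v in focal_sets.items() if v}
        if focal_sets and len(ervk) >= params.background_n:
            germline_table = repeatfeat.germline_state_association(
                focal_sets, data.oocyte_domains, ervk,
                params.background_n, params.seed)
        if data.ltr_sequences:
            act_seqs = [data.ltr_sequences[l.repeat_name] for l in active_ltrs
                        if l.repeat_name in data.ltr_sequences]
            bg_seqs = [data.ltr_sequences[l.repeat_name] for l in background_ltrs
                       if l.repeat_name in data.ltr_sequences]
            if len(act_seqs) >= 2 and len(bg_seqs) >= 2:
                _da, _db, t, p = repeatfeat.cpg_content(act_seqs, bg_seqs)
                cpg_welch = (t, p)

    # --- methylation / DMR dynamics ---------------------------------------
    dmr_calls, trajectories = [], []
    sites = data.methyl_sites.get("B6/CAST", [])
    if sites:
        regions = {}
        for call in imprinted:
            if (call.canonical_status == imprintcall.NON_CANONICAL
                    and call.consensus_class == imprintcall.IMPRINTED_PATERNAL):
                ltr = next((r for r in ervk
                            if r.interval.overlaps(region_intervals[call.region_id])),
                           None)
                if ltr is not None:
                    regions[f"nc:{call.region_id}"] = ltr.interval
        dmr_kwargs = {"delta_threshold": params.dmr_delta,
                      "min_calls": params.dmr_min_calls,
                      "min_cpgs": params.dmr_min_cpgs,
                      "alpha": params.alpha}
        if regions:
            rmeth = methylome.methylation_at_regions(sites, regions,
                                                     params.methyl_flank)
            dmr_calls = methylome.call_dmrs(rmeth, **dmr_kwargs)
            trajectories = methylome.stage_dynamics(
                rmeth, {"gamete": "GV", "preimplantation": "E3.5",
                        "epiblast": "E6.5_epiblast", "exe": "E6.5_ExE"},
                dmr_kwargs=dmr_kwargs)
    logger.info("stage methylation: %d DMR calls, %d trajectories",
                len(dmr_calls), len(trajectories))

    # --- summary -----------------------------------------------------------
    class_counts = {}
    for c in calls:
        class_counts[c.consensus_class] = class_counts.get(c.consensus_class, 0) + 1
    status_counts = {}
    for c in imprinted:
        status_counts[c.canonical_status] = status_counts.get(c.canonical_status, 0) + 1
    genes_with_calls = [c.assigned_gene for c in imprinted if c.assigned_gene]
    known_frac = (np.mean([g in data.known_imprinted_genes for g in genes_with_calls])
                  if genes_with_calls and data.known_imprinted_genes else float("nan"))
    summary = {
        "n_peaks_total": len(data.peaks),
        "n_informative": len(informative),
        "consensus_class_counts": class_counts,
        "canonical_status_counts": status_counts,
        "n_imprinted": len(imprinted),
        "fraction_known_imprinted": float(known_frac),
        "expression_validation_fraction": float(validation_fraction),
        "n_active_ltr_promoters": int(n_active),
        "rho": dispersion.rho,
    }
    return ResultBundle(
        imprint_calls=calls, bias_results=bias_results,
        rna_bias_results=rna_bias, dispersion=dispersion,
        informative_regions=informative,
        validation_table=validation_table,
        validation_fraction=validation_fraction,
        ltr_promoter_calls=promoter_calls, ltr_expression=ltr_expression,
        enrichment=enrichment, tss_table=tss_table, solo_stats=solo_stats,
        germline_table=germline_table, cpg_welch=cpg_welch,
        dmr_calls=dmr_calls, trajectories=trajectories, summary=summary,
    )


# ---------------------------------------------------------------------------
# Truth-table scoring (simulation studies)
# ---------------------------------------------------------------------------

#: planted class -> 4-way consensus class expected from the pipeline
TRUTH_TO_CONSENSUS = {
    simdata.CLASS_BIALLELIC: "biallelic",
    simdata.CLASS_STRAIN_B6: "strain_specific",
    simdata.CLASS_STRAIN_CAST: "strain_specific",
    simdata.CLASS_CANONICAL_MATERNAL: "imprinted_maternal",
    simdata.CLASS_CANONICAL_PATERNAL: "imprinted_paternal",
    simdata.CLASS_NONCANONICAL: "imprinted_paternal",
}

TRUTH_TO_CANONICAL = {
    simdata.CLASS_CANONICAL_MATERNAL: imprintcall.CANONICAL_MATERNAL,
    simdata.CLASS_CANONICAL_PATERNAL: imprintcall.CANONICAL_PATERNAL,
    simdata.CLASS_NONCANONICAL: imprintcall.NON_CANONICAL,
}


def score_against_truth(truth: pd.DataFrame, calls: list) -> dict:
    """Recovery metrics of the consensus classification vs planted truth.

    The 4-way mapping collapses the two strain classes to one label and
    the two paternal-favoring imprint classes to imprinted_paternal.
    Macro sensitivity/precision average over the 4 classes; predictions
    outside the 4 classes (single_cross_only, unresolved) count against
    sensitivity but toward no class's precision.  Canonical accuracy is
    the fraction of truly-imprinted recovered regions whose canonical
    status matches the planted mechanism.
    """
    pred_map = {
        imprintcall.BIALLELIC: "biallelic",
        imprintcall.STRAIN_B6: "strain_specific",
        imprintcall.STRAIN_CAST: "strain_specific",
        imprintcall.IMPRINTED_MATERNAL: "imprinted_maternal",
        imprintcall.IMPRINTED_PATERNAL: "imprinted_paternal",
    }
    by_id = {c.region_id: c for c in calls}
    four = ("biallelic", "strain_specific", "imprinted_maternal",
            "imprinted_paternal")
    tp = {k: 0 for k in four}
    truth_n = {k: 0 for k in four}
    pred_n = {k: 0 for k in four}
    strain_dir_ok = imp_n = canon_ok = 0
    for row in truth.itertuples(index=False):
        t4 = TRUTH_TO_CONSENSUS[row.class_label]
        truth_n[t4] += 1
        call = by_id.get(row.region_id)
        p4 = pred_map.get(call.consensus_class) if call else None
        if p4 is not None:
            pred_n[p4] += 1
            if p4 == t4:
                tp[t4] += 1
                if t4 == "strain_specific":
                    strain_dir_ok += int(
                        call.consensus_class == f"strain_{row.favored_allele}")
        if (call and call.consensus_class in imprintcall.IMPRINTED_CLASSES
                and row.class_label in TRUTH_TO_CANONICAL):
            imp_n += 1
            canon_ok += int(
                call.canonical_status == TRUTH_TO_CANONICAL[row.class_label])
    sens = {k: tp[k] / truth_n[k] if truth_n[k] else float("nan") for k in four}
    prec = {k: tp[k] / pred_n[k] if pred_n[k] else float("nan") for k in four}
    return {
        "sensitivity": sens,
        "precision": prec,
        "macro_sensitivity": float(np.nanmean(list(sens.values()))),
        "macro_precision": float(np.nanmean(list(prec.values()))),
        "canonical_accuracy": canon_ok / imp_n if imp_n else float("nan"),
        "n_recovered_imprints": imp_n,
        "strain_direction_correct": strain_dir_ok,
    }


# ---------------------------------------------------------------------------
# File round-trip used by the CLI
# ---------------------------------------------------------------------------

def write_study(data: StudyData, truth: pd.DataFrame | None,
                outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    core_io.write_bed([p.interval for p in data.peaks], outdir / "peaks.bed",
                      names=[p.id for p in data.peaks])
    core_io.write_genes(data.genes, outdir / "genes.tsv")
    core_io.write_repeats(data.repeats, outdir / "repeats.tsv")
    core_io.write_bed(data.cgis, outdir / "cgi.bed")
    core_io.write_bed(data.gdmr_regions, outdir / "gdmr.bed")
    for mark, domains in data.oocyte_domains.items():
        core_io.write_bed(domains, outdir / f"oocyte_{mark}.bed")
    pd.DataFrame([{"ltr_id": k, "sequence": v}
                  for k, v in data.ltr_sequences.items()]).to_csv(
        outdir / "ltr_sequences.tsv", sep="\t", index=False)
    core_io.write_snp_table(data.snps_b6_cast, outdir / "snps_b6_cast.tsv")
    core_io.write_snp_table(data.snps_129_cast, outdir / "snps_129_cast.tsv")
    core_io.write_sample_sheet(data.sample_sheet, outdir / "sample_sheet.tsv")
    for cross, df in data.chip_counts.items():
        core_io.write_counts(df, outdir / f"chip_counts_{cross.replace('/', 'x')}.tsv")
    for cross, df in data.rna_counts.items():
        core_io.write_counts(df, outdir / f"rna_counts_{cross.replace('/', 'x')}.tsv")
    for cross, reads in data.rna_reads.items():
        core_io.write_reads(reads, outdir / f"rna_reads_{cross.replace('/', 'x')}.tsv")
    for cross, sites in data.methyl_sites.items():
        core_io.write_methyl_sites(
            sites, outdir / f"methylation_{cross.replace('/', 'x')}.tsv")
    if data.known_imprinted_genes:
        pd.DataFrame({"gene_id": sorted(data.known_imprinted_genes),
                      "status": "known_imprinted"}).to_csv(
            outdir / "known_imprints.tsv", sep="\t", index=False)
    if truth is not None:
        truth.to_csv(outdir / "truth_table.tsv", sep="\t", index=False)


def load_study(indir: str | Path) -> StudyData:
    indir = Path(indir)
    peaks = core_io.read_peaks_bed(indir / "peaks.bed")
    genes = core_io.read_genes(indir / "genes.tsv")
    repeats = core_io.read_repeats(indir / "repeats.tsv")
    cgis = core_io.read_bed(indir / "cgi.bed")
    gdmr = core_io.read_bed(indir / "gdmr.bed") if (indir / "gdmr.bed").exists() else []
    oocyte = {}
    for path in sorted(indir.glob("oocyte_*.bed")):
        oocyte[path.stem.replace("oocyte_", "")] = core_io.read_bed(path)
    seqs = {}
    seq_path = indir / "ltr_sequences.tsv"
    if seq_path.exists():
        df = core_io.read_table(seq_path, {"ltr_id": str, "sequence": str})
        seqs = dict(zip(df["ltr_id"], df["sequence"]))
    chip, rna_counts, rna_reads, methyl = {}, {}, {}, {}
    for cross in simdata.CROSSES:
        tag = cross.replace("/", "x")
        p = indir / f"chip_counts_{tag}.tsv"
        if p.exists():
            chip[cross] = core_io.read_counts(p)
        p = indir / f"rna_counts_{tag}.tsv"
        if p.exists():
            rna_counts[cross] = core_io.read_counts(p)
        p = indir / f"rna_reads_{tag}.tsv"
        if p.exists():
            rna_reads[cross] = core_io.read_reads(p)
        p = indir / f"methylation_{tag}.tsv"
        if p.exists():
            methyl[cross] = core_io.read_methyl_sites(p)
    known = set()
    ki = indir / "known_imprints.tsv"
    if ki.exists():
        known = set(core_io.read_table(ki, {"gene_id": str})["gene_id"])
    snps1 = (core_io.read_snp_table(indir / "snps_b6_cast.tsv")
             if (indir / "snps_b6_cast.tsv").exists() else [])
    snps2 = (core_io.read_snp_table(indir / "snps_129_cast.tsv")
             if (indir / "snps_129_cast.tsv").exists() else [])
    sheet = (core_io.read_sample_sheet(indir / "sample_sheet.tsv")
             if (indir / "sample_sheet.tsv").exists() else [])
    return StudyData(peaks, genes, repeats, cgis, gdmr, oocyte, seqs,
                     chip, rna_counts, rna_reads, methyl, snps1, snps2,
                     sheet, known)


def write_results(bundle: ResultBundle, outdir: str | Path,
                  params: PipelineConfig | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    imprintcall.calls_to_frame(bundle.imprint_calls).to_csv(
        outdir / "imprint_calls.tsv", sep="\t", index=False)
    for cross, results in bundle.bias_results.items():
        biastest.results_to_frame(results).to_csv(
            outdir / f"bias_{cross.replace('/', 'x')}.tsv", sep="\t", index=False)
    ltrprom.promoter_calls_to_frame(bundle.ltr_promoter_calls).to_csv(
        outdir / "ltr_promoters.tsv", sep="\t", index=False)
    if bundle.enrichment:
        repeatfeat.enrichment_rows_to_frame(bundle.enrichment).to_csv(
            outdir / "feature_enrichment.tsv", sep="\t", index=False)
    if bundle.dmr_calls:
        methylome.dmr_calls_to_frame(bundle.dmr_calls).to_csv(
            outdir / "dmr_calls.tsv", sep="\t", index=False)
    if not bundle.validation_table.empty:
        bundle.validation_table.to_csv(outdir / "expression_validation.tsv",
                                       sep="\t", index=False)
    with open(outdir / "summary.json", "w") as handle:
        json.dump(bundle.summary, handle, indent=2, sort_keys=True)
    manifest = {"seed": params.seed if params else None,
                "config": params.__dict__ if params else {}}
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    with open(outdir / "run_manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, default=str)
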