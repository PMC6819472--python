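"""Allele-resolved methylation quantitation, DMR calling, stage dynamics.

Methylation over a region (typically an LTR +/- 500 bp) is the pooled
meth/total over the CpGs each allele covers.  An allelic DMR requires
both alleles adequately covered (>= 10 calls and >= 5 CpGs each by
default), an absolute level difference >= 0.3 and a two-sided Fisher
exact p < 0.05 on the pooled (meth, unmeth) x allele table; the
hypermethylated allele is the one with the larger level.

A secondary imprint — the signature of non-canonical imprinted LTR
promoters — is a maternal DMR acquired in post-implantation ExE at a
region that was unmethylated on both alleles (< 0.25) in gametes and
pre-implantation; regions methylated from the gamete onward (canonical
germline DMRs) are excluded by construction.  Biallelic methylation
>= 0.5 in the epiblast flags promoter silencing in the embryonic
lineage.  Allelic H3K27me3 trajectories across pre-implantation stages
are summarised on raw counts — library-size scaling is inappropriate
there because maternal and paternal H3K27me3 abundances genuinely
differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .core_io import GenomicInterval, MethylSite

logger = logging.getLogger("imprintseq")

DMR_DELTA_DEFAULT = 0.3
DMR_ALPHA_DEFAULT = 0.05
MIN_CALLS_DEFAULT = 10
MIN_CPGS_DEFAULT = 5
LOW_LEVEL = 0.25  # "unmethylated" trajectory cutoff
HIGH_LEVEL = 0.5  # "methylated" (silencing) trajectory cutoff


@dataclass(frozen=True)
class RegionMethylation:
    region_id: str
    sample_id: str
    stage: str
    allele: str
    n_cpgs_covered: int
    meth_calls: int
    total_calls: int

    @property
    def level(self) -> float | None:
        return self.meth_calls / self.total_calls if self.total_calls > 0 else None


@dataclass
class DmrCall:
    region_id: str
    stage: str
    is_dmr: bool
    hypermethylated_allele: str | None
    delta: float | None
    fisher_p: float | None
    insufficient: bool = False


def methylation_at_regions(sites: list[MethylSite],
                           regions: dict,
                           flank: int = 500) -> list[RegionMethylation]:
    """Pool per-CpG calls over each region (+/- flank) per allele/stage.

    ``regions`` maps region_id -> GenomicInterval.  Regions with zero
    covered CpGs yield no record (level missing, never 0).
    """
    expanded = {rid: iv.expanded(flank) for rid, iv in regions.items()}
    acc: dict[tuple, dict] = {}
    for site in sites:
        for rid, iv in expanded.items():
            if iv.contains(site.chrom, site.pos):
                key = (rid, site.sample_id, site.stage, site.allele)
                a = acc.setdefault(key, {"cpgs": set(), "meth": 0, "total": 0})
                total = site.meth_count + site.unmeth_count
                if total > 0:
                    a["cpgs"].add(site.pos)
                    a["meth"] += site.meth_count
                    a["total"] += total
    out = []
    for (rid, sample, stage, allele), a in sorted(acc.items()):
        if a["total"] > 0:
            out.append(RegionMethylation(rid, sample, stage, allele,
                                         len(a["cpgs"]), a["meth"], a["total"]))
    return out


def call_allelic_dmr(mat: RegionMethylation, pat: RegionMethylation,
                     delta_threshold: float = DMR_DELTA_DEFAULT,
                     alpha: float = DMR_ALPHA_DEFAULT,
                     min_calls: int = MIN_CALLS_DEFAULT,
                     min_cpgs: int = MIN_CPGS_DEFAULT) -> DmrCall:
    """Allelic DMR test from the pooled maternal and paternal records."""
    rid, stage = mat.region_id, mat.stage
    if (mat.total_calls < min_calls or pat.total_calls < min_calls
            or mat.n_cpgs_covered < min_cpgs or pat.n_cpgs_covered < min_cpgs):
        return DmrCall(rid, stage, False, None, None, None, insufficient=True)
    level_m, level_p = mat.level, pat.level
    delta = abs(level_m - level_p)
    table = [[mat.meth_calls, mat.total_calls - mat.meth_calls],
             [pat.meth_calls, pat.total_calls - pat.meth_calls]]
    _odds, p = stats.fisher_exact(table, alternative="two-sided")
    is_dmr = delta >= delta_threshold and p < alpha
    hyper = None
    if is_dmr:
        hyper = "maternal" if level_m > level_p else "paternal"
    return DmrCall(rid, stage, bool(is_dmr), hyper, float(delta), float(p))


def call_dmrs(region_meth: list[RegionMethylation], **kwargs) -> list[DmrCall]:
    """DMR calls for every (region, sample, stage) with both alleles covered."""
    by_key: dict[tuple, dict] = {}
    for rm in region_meth:
        by_key.setdefault((rm.region_id, rm.sample_id, rm.stage), {})[rm.allele] = rm
    calls = []
    for (rid, _sample, stage), alleles in sorted(by_key.items()):
        if "maternal" in alleles and "paternal" in alleles:
            calls.append(call_allelic_dmr(alleles["maternal"],
                                          alleles["paternal"], **kwargs))
        else:
            calls.append(DmrCall(rid, stage, False, None, None, None,
                                 insufficient=True))
    return calls


@dataclass
class StageTrajectory:
    region_id: str
    levels: dict  # (stage_role, allele) -> level or None
    dmr_by_role: dict  # stage_role -> DmrCall or None
    secondary_imprint: bool | None = None  # None when undecidable
    epiblast_silenced: bool | None = None
    k27_raw_counts: dict | None = None  # stage -> (mat, pat) raw counts


def stage_dynamics(region_meth: list[RegionMethylation],
                   stage_roles: dict,
                   chip_counts: pd.DataFrame | None = None,
                   dmr_kwargs: dict | None = None) -> list[StageTrajectory]:
    """Per-region methylation trajectory and secondary-imprint flag.

    ``stage_roles`` maps the roles {"gamete", "preimplantation",
    "epiblast", "exe"} to the stage names present in the data.  A region
    is a secondary imprint when both alleles are < 0.25 at the gamete and
    pre-implantation stages AND it is a maternal DMR in post-implantation
    ExE; it is epiblast-silenced when both alleles are >= 0.5 in the
    epiblast.  Missing stages leave the affected flags undecided (None).
    Optional allelic H3K27me3 counts are carried through as raw counts,
    never size-factor scaled.
    """
    dmr_kwargs = dmr_kwargs or {}
    roles = ("gamete", "preimplantation", "epiblast", "exe")
    stage_of = {role: stage_roles.get(role) for role in roles}
    by_region: dict[str, dict] = {}
    for rm in region_meth:
        by_region.setdefault(rm.region_id, {})[(rm.stage, rm.allele)] = rm
    all_dmrs = {(c.region_id, c.stage): c
                for c in call_dmrs(region_meth, **dmr_kwargs)}
    out = []
    for rid, recs in sorted(by_region.items()):
        levels = {}
        for role in roles:
            stage = stage_of[role]
            for allele in ("maternal", "paternal"):
                rm = recs.get((stage, allele)) if stage else None
                levels[(role, allele)] = rm.level if rm else None
        dmr_by_role = {role: all_dmrs.get((rid, stage_of[role]))
                       for role in roles if stage_of[role]}

        early = [levels[(r, a)] for r in ("gamete", "preimplantation")
                 for a in ("maternal", "paternal")]
        exe_dmr = dmr_by_role.get("exe")
        if any(v is None for v in early) or exe_dmr is None or exe_dmr.insufficient:
            secondary = None
        else:
            secondary = (all(v < LOW_LEVEL for v in early)
                         and exe_dmr.is_dmr
                         and exe_dmr.hypermethylated_allele == "maternal")
        epi = [levels[("epiblast", a)] for a in ("maternal", "paternal")]
        silenced = (None if any(v is None for v in epi)
                    else all(v >= HIGH_LEVEL for v in epi))

        k27 = None
        if chip_counts is not None:
            sub = chip_counts[chip_counts["region_id"] == rid]
            if not sub.empty and "stage" in sub.columns:
                k27 = {stage: (int(g["mat"].sum()), int(g["pat"].sum()))
                       for stage, g in sub.groupby("stage")}
        out.append(StageTrajectory(rid, levels, dmr_by_role, secondary,
                                   silenced, k27))
    return out


def dmr_calls_to_frame(calls: list[DmrCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])
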