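"""Genomic-feature statistics over peak and LTR sets.

Overlap enrichment between two peak sets across feature catalogs uses a
Pearson chi-square (no continuity correction) on each 2x2 table with
Bonferroni correction over features; CpG content is the CG-dinucleotide
density compared by Welch t; TSS proximity classifies LTRs into
same-strand / opposing-strand within 3 kb / beyond, compared to a
background set by chi-square; germline (oocyte) chromatin-state
association compares focal LTR sets against a seeded random background
subset.  The overlap predicate everywhere is >= 1 bp of intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .biastest import location_tests
from .core_io import Gene, GenomicInterval, RepeatElement

logger = logging.getLogger("imprintseq")


@dataclass(frozen=True)
class EnrichmentRow:
    feature: str
    fraction_set_a: float
    fraction_set_b: float
    chi2: float
    p: float
    p_bonferroni: float
    significant: bool
    low_expected: bool = False


def chi_square_independence(table: np.ndarray, yates: bool = False
                            ) -> tuple[float, float]:
    """Pearson chi-square on an r x c contingency table.

    Computed directly as sum (O-E)^2 / E with df = (r-1)(c-1); an
    optional Yates continuity correction is available for 2x2 tables.
    """
    obs = np.asarray(table, dtype=float)
    if obs.sum() == 0:
        raise ValueError("empty contingency table")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    if (expected == 0).any():
        raise ValueError("zero expected cell (empty row or column)")
    diff = np.abs(obs - expected)
    if yates and obs.shape == (2, 2):
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float(np.sum(diff ** 2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return chi2, float(stats.chi2.sf(chi2, df))


def _overlaps_any(iv: GenomicInterval, catalog: list[GenomicInterval]) -> bool:
    return any(iv.overlaps(c) for c in catalog)


def feature_overlap_enrichment(set_a: list[GenomicInterval],
                               set_b: list[GenomicInterval],
                               feature_catalogs: dict,
                               alpha: float = 0.05,
                               yates: bool = False) -> list[EnrichmentRow]:
    """Per-feature overlap enrichment of set A vs set B.

    ``feature_catalogs`` maps a feature label to its interval catalog.
    Each feature contributes one 2x2 table (overlap yes/no x set), tested
    by chi-square with Bonferroni correction over the number of features.
    """
    if not set_a or not set_b:
        raise ValueError("both interval sets must be non-empty")
    if len(feature_catalogs) < 2:
        raise ValueError("need >= 2 feature categories")
    n_tests = len(feature_catalogs)
    rows = []
    for feature, catalog in feature_catalogs.items():
        hit_a = sum(_overlaps_any(iv, catalog) for iv in set_a)
        hit_b = sum(_overlaps_any(iv, catalog) for iv in set_b)
        table = np.array([[hit_a, len(set_a) - hit_a],
                          [hit_b, len(set_b) - hit_b]], dtype=float)
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        low_expected = bool((expected < 1).any())
        if low_expected:
            logger.warning("feature %s: expected cell < 1, chi-square unreliable",
                           feature)
        try:
            chi2, p = chi_square_independence(table, yates=yates)
        except ValueError:
            chi2, p = 0.0, 1.0
        p_bonf = min(1.0, p * n_tests)
        rows.append(EnrichmentRow(feature, hit_a / len(set_a), hit_b / len(set_b),
                                  chi2, p, p_bonf, p_bonf < alpha, low_expected))
    return rows


# ---------------------------------------------------------------------------
# CpG content
# ---------------------------------------------------------------------------

def cpg_density(sequence: str) -> float | None:
    """CG-dinucleotide density: count of "CG" / (length - 1)."""
    if len(sequence) < 2:
        return None
    seq = sequence.upper()
    n_cg = sum(1 for i in range(len(seq) - 1) if seq[i:i + 2] == "CG")
    return n_cg / (len(seq) - 1)


def cpg_content(group_a_seqs: list[str], group_b_seqs: list[str]
                ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-sequence CpG densities for two groups + Welch two-sample t.

    Sequences shorter than 2 bp are skipped (density undefined).
    """
    dens_a = np.array([d for s in group_a_seqs if (d := cpg_density(s)) is not None])
    dens_b = np.array([d for s in group_b_seqs if (d := cpg_density(s)) is not None])
    t, p = location_tests(dens_a, dens_b, kind="welch_two_sample")
    return dens_a, dens_b, t, p


# ---------------------------------------------------------------------------
# TSS proximity
# ---------------------------------------------------------------------------

TSS_CATEGORIES = ("same_strand_3kb", "opposing_strand_3kb", "beyond_3kb")


def _tss_category(ltr: RepeatElement, genes: list[Gene], window: int) -> str:
    best_dist, best_gene = None, None
    for gene in genes:
        if gene.interval.chrom != ltr.interval.chrom:
            continue
        d = min(abs(ltr.interval.start - gene.tss),
                abs((ltr.interval.end - 1) - gene.tss))
        if ltr.interval.contains(ltr.interval.chrom, gene.tss):
            d = 0
        if best_dist is None or d < best_dist:
            best_dist, best_gene = d, gene
    if best_dist is None or best_dist > window:
        return "beyond_3kb"
    same = best_gene.strand == ltr.strand
    return "same_strand_3kb" if same else "opposing_strand_3kb"


def tss_proximity(focal_ltrs: list[RepeatElement],
                  background_ltrs: list[RepeatElement],
                  genes: list[Gene], window: int = 3000
                  ) -> tuple[pd.DataFrame, float, float]:
    """TSS-proximity/strand category proportions vs a background LTR set.

    Each LTR is categorised by its nearest TSS (minimum boundary-to-TSS
    distance): within ``window`` on the same strand, within ``window`` on
    the opposing strand, or beyond.  The focal-vs-background 2x3 table
    is tested by chi-square.
    """
    if not genes:
        raise ValueError("no genes supplied")
    counts = {}
    for name, ltrs in (("focal", focal_ltrs), ("background", background_ltrs)):
        cats = [_tss_category(l, genes, window) for l in ltrs]
        counts[name] = [cats.count(c) for c in TSS_CATEGORIES]
    table = np.array([counts["focal"], counts["background"]], dtype=float)
    # drop all-zero categories so expected cells stay positive
    keep = table.sum(axis=0) > 0
    chi2, p = chi_square_independence(table[:, keep])
    frame = pd.DataFrame(table, index=["focal", "background"],
                         columns=TSS_CATEGORIES)
    frame = frame.div(frame.sum(axis=1), axis=0)
    return frame, chi2, p


# ---------------------------------------------------------------------------
# Solo-LTR length statistics
# ---------------------------------------------------------------------------

def solo_ltr_stats(ltrs: list[RepeatElement]) -> dict:
    """Length mean +/- SEM and solo fraction of an LTR set."""
    if not ltrs:
        raise ValueError("empty LTR set")
    lengths = np.array([len(l.interval) for l in ltrs], dtype=float)
    sem = (float(np.std(lengths, ddof=1) / np.sqrt(lengths.size))
           if lengths.size > 1 else None)
    return {
        "n": int(lengths.size),
        "length_mean": float(lengths.mean()),
        "length_sem": sem,
        "fraction_solo": float(np.mean([l.is_solo for l in ltrs])),
    }


# ---------------------------------------------------------------------------
# Oocyte (germline) chromatin-state association
# ---------------------------------------------------------------------------

def germline_state_association(focal_sets: dict, domain_catalogs: dict,
                               ltr_catalog: list[RepeatElement],
                               background_n: int = 100, seed: int = 0
                               ) -> pd.DataFrame:
    """Oocyte chromatin-state overlap of focal LTR sets vs random background.

    ``focal_sets`` maps a set label to its LTR list; ``domain_catalogs``
    maps a mark (oocyte H3K4me3 / H3K27me3 / methylated) to interval
    domains.  The background is ``background_n`` LTRs sampled without
    replacement from the full catalog with a fixed seed; each focal set
    is compared to it per mark by 2x2 chi-square.
    """
    if background_n > len(ltr_catalog):
        raise ValueError("background_n exceeds LTR catalog size")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ltr_catalog), size=background_n, replace=False)
    background = [ltr_catalog[i] for i in idx]
    rows = []
    for mark, domains in domain_catalogs.items():
        bg_hits = sum(_overlaps_any(l.interval, domains) for l in background)
        for label, ltrs in focal_sets.items():
            hits = sum(_overlaps_any(l.interval, domains) for l in ltrs)
            table = np.array([[hits, len(ltrs) - hits],
                              [bg_hits, background_n - bg_hits]], dtype=float)
            if table.sum(axis=0).min() == 0:
                chi2, p = 0.0, 1.0
            else:
                chi2, p = chi_square_independence(table)
            rows.append({
                "mark": mark, "set": label,
                "fraction_focal": hits / len(ltrs) if ltrs else float("nan"),
                "fraction_background": bg_hits / background_n,
                "chi2": chi2, "p": p,
            })
    return pd.DataFrame(rows)


def enrichment_rows_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
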