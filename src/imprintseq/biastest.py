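"""Allelic-bias testing: exact binomial / beta-binomial LRT, BH correction.

The null hypothesis at every region is a balanced allelic proportion
(maternal fraction 0.5).  With a single replicate, or when the replicate
overdispersion rho is zero, the test is a two-sided exact binomial on
the pooled maternal/paternal counts (two-sidedness by doubling the
smaller tail, capped at 1).  With replicates and rho > 0 the test is a
beta-binomial likelihood-ratio test: the maternal fraction is profiled
under the alternative with rho held fixed, and twice the log-likelihood
ratio is referred to chi-square with 1 df.  rho is a single
method-of-moments estimate shared across regions.

Multiple testing is controlled by Benjamini-Hochberg within each
(tissue, assay, cross) family; a region is significant at q < 0.05 and
its direction is the sign of the pooled maternal fraction minus 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger("imprintseq")

ALPHA_DEFAULT = 0.05
PSEUDOCOUNT = 1.0  # log2 display only, never used in testing


@dataclass(frozen=True)
class DispersionEstimate:
    rho: float
    n_regions_used: int
    method: str = "method_of_moments"

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be >= 0")


@dataclass(frozen=True)
class BiasResult:
    region_id: str
    cross: str
    mat: int
    pat: int
    log2_ratio: float
    p_value: float
    q_value: float
    significant: bool
    direction: str  # maternal / paternal / none
    n_replicates: int
    total_reads: int


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------

def estimate_dispersion(counts: pd.DataFrame,
                        min_regions: int = 20) -> DispersionEstimate:
    """Method-of-moments beta-binomial intraclass correlation, shared
    across regions.

    For a region with replicate counts (m_i, n_i) and pooled fraction p,
    the replicate fractions have variance p(1-p)(rho + (1-rho)/n_i); the
    excess of the observed variance over the binomial expectation yields
    a per-region moment estimate, combined by a total-read-weighted mean
    and floored at 0.
    """
    per_region_rho = []
    weights = []
    group_cols = ["region_id"]
    if "family" in counts.columns:
        # replicates are exchangeable only within a cross/assay family:
        # strain effects flip the allelic fraction between reciprocal
        # crosses and would masquerade as overdispersion
        group_cols.append("family")
    for _rid, grp in counts.groupby(group_cols, sort=False):
        m = grp["mat"].to_numpy(dtype=float)
        n = (grp["mat"] + grp["pat"]).to_numpy(dtype=float)
        keep = n > 0
        m, n = m[keep], n[keep]
        if len(n) < 2:
            continue
        p = m.sum() / n.sum()
        if p <= 0 or p >= 1:
            continue
        frac = m / n
        s2 = np.var(frac, ddof=1)
        mean_inv_n = np.mean(1.0 / n)
        denom = p * (1 - p) * (1 - mean_inv_n)
        if denom <= 0:
            continue
        rho_i = (s2 - p * (1 - p) * mean_inv_n) / denom
        per_region_rho.append(rho_i)
        weights.append(n.sum())
    if not per_region_rho:
        logger.warning("no multi-replicate regions; returning rho = 0")
        return DispersionEstimate(0.0, 0)
    if len(per_region_rho) < min_regions:
        logger.warning("only %d regions for dispersion estimation (< %d)",
                       len(per_region_rho), min_regions)
    rho = float(np.average(per_region_rho, weights=weights))
    return DispersionEstimate(max(0.0, min(rho, 0.999)), len(per_region_rho))


# ---------------------------------------------------------------------------
# Exact binomial branch
# ---------------------------------------------------------------------------

def exact_binomial_p(k: int, n: int) -> float:
    """Two-sided exact binomial p under p0 = 0.5: double the smaller tail,
    capped at 1."""
    if n == 0:
        return 1.0
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


# ---------------------------------------------------------------------------
# Beta-binomial likelihood-ratio branch
# ---------------------------------------------------------------------------

def _betabinom_loglik(pi: float, m: np.ndarray, n: np.ndarray, rho: float) -> float:
    conc = 1.0 / rho - 1.0
    a, b = pi * conc, (1.0 - pi) * conc
    return float(np.sum(stats.betabinom.logpmf(m, n, a, b)))


def betabinom_lrt_p(m: np.ndarray, n: np.ndarray, rho: float) -> float:
    """LRT p-value for H0 pi = 0.5 against free pi, rho fixed and shared."""
    m = np.asarray(m, dtype=int)
    n = np.asarray(n, dtype=int)
    keep = n > 0
    m, n = m[keep], n[keep]
    if n.size == 0:
        return 1.0
    ll0 = _betabinom_loglik(0.5, m, n, rho)
    res = optimize.minimize_scalar(
        lambda pi: -_betabinom_loglik(pi, m, n, rho),
        bounds=(1e-6, 1 - 1e-6), method="bounded",
        options={"xatol": 1e-8})
    ll1 = max(-res.fun, ll0)
    lrt = 2.0 * (ll1 - ll0)
    return float(stats.chi2.sf(lrt, df=1))


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    if n == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank downward
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Region-level test
# ---------------------------------------------------------------------------

def allelic_bias_test(counts: pd.DataFrame, rho: float = 0.0,
                      cross: str = "", alpha: float = ALPHA_DEFAULT
                      ) -> list[BiasResult]:
    """Test every region in ``counts`` for allelic bias against 0.5.

    ``counts`` holds one row per (region_id, replicate) with mat/pat
    columns, already restricted to informative regions.  Regions with
    zero allelic reads in every replicate are skipped (reported absent).
    BH correction is applied across the regions supplied here, which
    should form one (tissue, assay, cross) family.
    """
    records = []
    for rid, grp in counts.groupby("region_id", sort=False):
        m = grp["mat"].to_numpy(dtype=int)
        p_ = grp["pat"].to_numpy(dtype=int)
        n = m + p_
        if n.sum() == 0:
            logger.info("region %s: zero allelic reads in all replicates, untested", rid)
            continue
        n_rep = int((n > 0).sum())
        if n_rep <= 1 or rho <= 0:
            p_val = exact_binomial_p(int(m.sum()), int(n.sum()))
        else:
            p_val = betabinom_lrt_p(m, n, rho)
        records.append((rid, int(m.sum()), int(p_.sum()), n_rep, p_val))
    if not records:
        return []
    p_raw = np.array([r[4] for r in records])
    q = bh_adjust(p_raw)
    results = []
    for (rid, mat, pat, n_rep, p_val), q_val in zip(records, q):
        total = mat + pat
        frac = mat / total
        significant = bool(q_val < alpha)
        if not significant:
            direction = "none"
        else:
            direction = "maternal" if frac > 0.5 else "paternal"
        log2_ratio = float(np.log2((pat + PSEUDOCOUNT) / (mat + PSEUDOCOUNT)))
        results.append(BiasResult(rid, cross, mat, pat, log2_ratio,
                                  float(p_val), float(q_val), significant,
                                  direction, n_rep, total))
    return results


def results_to_frame(results: list[BiasResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


#: column types of the bias-results TSV (used to re-read it)
RESULTS_SCHEMA = {
    "region_id": str, "cross": str, "mat": int, "pat": int,
    "log2_ratio": float, "p_value": float, "q_value": float,
    "significant": bool, "direction": str, "n_replicates": int,
    "total_reads": int,
}


def results_from_frame(df: pd.DataFrame) -> list[BiasResult]:
    """Inverse of :func:`results_to_frame` (TSV round-trip)."""
    return [BiasResult(r.region_id, r.cross, int(r.mat), int(r.pat),
                       float(r.log2_ratio), float(r.p_value), float(r.q_value),
                       bool(r.significant), r.direction, int(r.n_replicates),
                       int(r.total_reads))
            for r in df.itertuples(index=False)]


def allelic_ratio(mat, pat) -> float:
    """Maternal allelic ratio mat/(mat+pat); NaN when no allelic reads."""
    total = mat + pat
    if total == 0:
        return float("nan")
    return float(mat / total)


def allelic_ratio_table(counts: pd.DataFrame, size_factors: pd.Series | None = None
                        ) -> pd.DataFrame:
    """Per-region allelic ratio from replicate counts pooled after
    library-size correction."""
    df = counts.copy()
    if size_factors is not None:
        sf = df["sample_id"].map(size_factors).astype(float)
        df["mat"] = df["mat"] / sf
        df["pat"] = df["pat"] / sf
    pooled = df.groupby("region_id", sort=False)[["mat", "pat"]].sum()
    pooled["allelic_ratio"] = pooled["mat"] / (pooled["mat"] + pooled["pat"])
    return pooled.reset_index()


# ---------------------------------------------------------------------------
# Classical location tests
# ---------------------------------------------------------------------------

def location_tests(sample_a, sample_b=None, mu0: float | None = None,
                   kind: str = "welch_two_sample") -> tuple[float, float]:
    """Welch two-sample or one-sample t test (two-sided).

    ``welch_two_sample`` compares two groups with Welch-Satterthwaite df;
    ``one_sample`` compares one group of n >= 2 against a scalar reference
    mean ``mu0``.  Zero variance everywhere with equal means gives p = 1;
    zero variance with unequal means gives p = 0 (warned).
    """
    a = np.asarray(sample_a, dtype=float)
    if kind == "welch_two_sample":
        if sample_b is None:
            raise ValueError("welch_two_sample requires two groups")
        b = np.asarray(sample_b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("welch requires n >= 2 per group")
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            if a.mean() == b.mean():
                return 0.0, 1.0
            logger.warning("zero variance with unequal means: p = 0")
            return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return float(t), float(p)
    if kind == "one_sample":
        if mu0 is None:
            raise ValueError("one_sample requires mu0")
        if a.size < 2:
            raise ValueError("one_sample requires n >= 2")
        if np.var(a, ddof=1) == 0:
            if a.mean() == mu0:
                return 0.0, 1.0
            logger.warning("zero variance with mean != mu0: p = 0")
            return float("inf") if a.mean() > mu0 else float("-inf"), 0.0
        t, p = stats.ttest_1samp(a, mu0)
        return float(t), float(p)
    raise ValueError(f"unknown test kind {kind!r}")
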