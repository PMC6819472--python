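"""Synthetic reciprocal-hybrid multi-omic data with planted imprinting truth.

The generator emulates the study design the pipeline targets: two
reciprocal F1 crosses between divergent mouse strains (B6/CAST and
CAST/B6) plus a cross whose mother lacks oocyte DNA methyltransferases
(matDKO/CAST, maternal genome an 85% B6 / 15% 129 admixture).  Histone
ChIP peaks are planted in six classes — biallelic, strain-specific (B6 or
CAST), canonical imprinted (maternal or paternal, i.e. germline-DMR
dependent) and non-canonical imprinted (maternal-methylation independent,
located on solo ERVK LTR elements) — and every downstream observable
(allelic read counts, spliced RNA reads, allele-resolved CpG methylation)
is derived from those labels.

Allelic ChIP/RNA counts follow a Poisson total depth with a
beta-binomial maternal/paternal split: at a planted imprint the maternal
fraction is ``allelic_pi`` toward the favored allele with intraclass
correlation ``rho``; biallelic regions sit at 0.5.  In the matDKO cross,
canonical maternal imprints revert to 0.5 (their germline DMR is gone)
while non-canonical and canonical paternal imprints retain their bias.

Randomness is organised as one named stream per output kind derived from
the master seed, so adding a new output never perturbs existing ones, and
an identical config reproduces identical data byte for byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import (
    CrossDesign,
    Gene,
    GenomicInterval,
    MethylSite,
    Peak,
    ReadRecord,
    RepeatElement,
    SNPRecord,
)

# planted peak classes
CLASS_BIALLELIC = "biallelic"
CLASS_STRAIN_B6 = "strain_B6"
CLASS_STRAIN_CAST = "strain_CAST"
CLASS_CANONICAL_MATERNAL = "imprinted_canonical_maternal"
CLASS_CANONICAL_PATERNAL = "imprinted_canonical_paternal"
CLASS_NONCANONICAL = "imprinted_noncanonical"

ALL_CLASSES = (
    CLASS_BIALLELIC,
    CLASS_STRAIN_B6,
    CLASS_STRAIN_CAST,
    CLASS_CANONICAL_MATERNAL,
    CLASS_CANONICAL_PATERNAL,
    CLASS_NONCANONICAL,
)

CROSSES = ("B6/CAST", "CAST/B6", "matDKO/CAST")

#: developmental stages carried by the methylation simulator, in order
STAGES = ("GV", "E3.5", "E6.5_epiblast", "E6.5_ExE")

_BASES = np.array(["A", "C", "G", "T"])


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults are the desk-scale study conditions."""

    seed: int = 0
    n_chrom: int = 3
    chrom_length: int = 10_000_000
    n_peaks: int = 1000
    class_proportions: dict = field(default_factory=lambda: {
        CLASS_BIALLELIC: 0.70,
        CLASS_STRAIN_B6: 0.10,
        CLASS_STRAIN_CAST: 0.10,
        CLASS_CANONICAL_MATERNAL: 0.06,
        CLASS_CANONICAL_PATERNAL: 0.01,
        CLASS_NONCANONICAL: 0.03,
    })
    mean_total_depth: float = 100.0
    mean_rna_depth: float = 60.0
    allelic_pi: float = 0.9
    rho: float = 0.02
    n_replicates_chip: int = 2
    n_replicates_rna: int = 3
    snp_rate: float = 1.0 / 150.0
    fraction_129_segments: float = 0.15
    #: fraction of 129-segment B6/CAST SNPs whose 129 base equals CAST
    fraction_129_shared_with_cast: float = 0.5
    #: fraction of non-canonical LTRs that are active promoters
    ltr_fraction_of_noncanonical: float = 0.5
    #: fraction of active LTR promoters spliced onto a gene (rest ncRNA)
    chimera_fraction: float = 0.5
    #: fraction of non-canonical LTRs on the same strand as the partner gene
    ltr_same_strand_fraction: float = 0.8
    ltr_length_mean: float = 417.0
    ltr_length_sd: float = 19.0
    n_background_ltrs: int = 200
    n_decoys_per_type: int = 3
    mean_ltr_reads: float = 20.0
    read_length: int = 80
    methyl_coverage: int = 30
    methyl_cpg_spacing: int = 25
    methyl_flank: int = 500

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class_proportions sum to {total}, expected 1")
        unknown = set(self.class_proportions) - set(ALL_CLASSES)
        if unknown:
            raise ConfigError(f"unknown classes {sorted(unknown)}")
        if not (0.5 <= self.allelic_pi <= 1.0):
            raise ConfigError("allelic_pi must lie in [0.5, 1]")
        if not (0.0 <= self.rho < 1.0):
            raise ConfigError("rho must lie in [0, 1)")
        if self.methyl_coverage <= 0:
            raise ConfigError("methyl_coverage must be positive")


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Named RNG stream: stable hash of the name mixed with the seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# Reference bundle
# ---------------------------------------------------------------------------

@dataclass
class ReferenceBundle:
    """Genome annotation produced by :func:`simulate_reference`."""

    chromosomes: dict  # name -> length
    snps_b6_cast: list  # full B6-vs-CAST SNP table
    snps_b6_cast_excl_shared: list  # pass-1 table (129/CAST-shared removed)
    snps_129_cast: list  # 129-vs-CAST table within 129 segments
    segments_129: list  # GenomicInterval, 129-derived maternal segments
    genes: list
    peaks: list
    repeats: list  # all ERVK solo LTRs (focal + background + decoys)
    cgis: list  # simulated CpG islands (GenomicInterval)
    ltr_sequences: dict  # repeat_name -> sequence string
    oocyte_domains: dict  # mark -> list[GenomicInterval]

    def snp_lookup(self, table: str = "b6_cast") -> dict:
        snps = {
            "b6_cast": self.snps_b6_cast,
            "pass1": self.snps_b6_cast_excl_shared,
            "129_cast": self.snps_129_cast,
        }[table]
        return {(s.chrom, s.pos): s for s in snps}


def _largest_remainder_counts(proportions: dict, n: int) -> dict:
    """Integer class counts that sum to n, honouring the proportions."""
    items = [(c, proportions.get(c, 0.0) * n) for c in ALL_CLASSES]
    counts = {c: int(np.floor(v)) for c, v in items}
    short = n - sum(counts.values())
    remainders = sorted(items, key=lambda cv: cv[1] - np.floor(cv[1]), reverse=True)
    for c, _v in remainders[:short]:
        counts[c] += 1
    return counts


def _random_sequence(rng: np.random.Generator, length: int, n_cpg: int) -> str:
    """CpG-free random sequence with ``n_cpg`` CG dinucleotides planted."""
    seq = rng.choice(_BASES, size=length)
    for i in range(length - 1):  # remove accidental CGs
        if seq[i] == "C" and seq[i + 1] == "G":
            seq[i + 1] = "A"
    if n_cpg > 0:
        slots = rng.choice(np.arange(0, length - 1, 2), size=n_cpg, replace=False)
        for s in slots:
            seq[s], seq[s + 1] = "C", "G"
    return "".join(seq)


def simulate_reference(config: SimConfig) -> tuple[ReferenceBundle, pd.DataFrame]:
    """Build the genome annotation bundle and the planted truth table."""
    rng = stream_rng(config.seed, "reference")
    chroms = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chrom)}
    chrom_names = list(chroms)

    # --- class labels, shuffled across peak slots -------------------------
    counts = _largest_remainder_counts(config.class_proportions, config.n_peaks)
    labels = [c for c in ALL_CLASSES for _ in range(counts[c])]
    rng.shuffle(labels)

    # --- peak / gene placement -------------------------------------------
    margin = 50_000
    per_chrom = int(np.ceil(config.n_peaks / config.n_chrom))
    spacing = (config.chrom_length - 2 * margin) // max(per_chrom, 1)
    if spacing < 20_000:
        raise ConfigError("chromosomes too short for the requested peak count")

    peaks, genes, repeats, cgis = [], [], [], []
    ltr_sequences: dict[str, str] = {}
    truth_rows = []
    peak_width = 1000

    # choose which non-canonical LTRs are active promoters / chimeras
    noncanon_idx = [i for i, lab in enumerate(labels) if lab == CLASS_NONCANONICAL]
    n_active = int(round(len(noncanon_idx) * config.ltr_fraction_of_noncanonical))
    active_set = set(noncanon_idx[:n_active])
    same_strand = {
        i: bool(rng.random() < config.ltr_same_strand_fraction) for i in noncanon_idx
    }
    n_chim = int(round(n_active * config.chimera_fraction))
    # chimeras need a same-strand partner gene; pick them from that subset
    chimera_set = set([i for i in sorted(active_set) if same_strand[i]][:n_chim])

    # biallelic peaks hosting decoy LTRs (three failure modes)
    bial_idx = [i for i, lab in enumerate(labels) if lab == CLASS_BIALLELIC]
    decoy_types = ["low_reads", "no_donor_junction", "incoming_junction"]
    decoy_assignment: dict[int, str] = {}
    cursor = 0
    for dt in decoy_types:
        for _ in range(config.n_decoys_per_type):
            if cursor < len(bial_idx):
                decoy_assignment[bial_idx[cursor]] = dt
                cursor += 1

    ltr_counter = 0
    for i, label in enumerate(labels):
        chrom = chrom_names[i // per_chrom]
        slot = i % per_chrom
        pos = margin + slot * spacing
        strand = "+" if (i % 2 == 0) else "-"
        peak_iv = GenomicInterval(chrom, pos, pos + peak_width)
        peak_id = f"pk{i:04d}"
        peaks.append(Peak(peak_id, peak_iv, mark="H3K4me3", tissue="ExE"))

        # one gene per peak, promoter at the peak midpoint
        gene_id = f"g{i:04d}"
        tss = peak_iv.midpoint()
        body = 5000
        if strand == "+":
            g_iv = GenomicInterval(chrom, tss, tss + body, strand)
            exons = (
                GenomicInterval(chrom, tss, tss + 200, strand),
                GenomicInterval(chrom, tss + 1500, tss + 1800, strand),
                GenomicInterval(chrom, tss + 3000, tss + 3300, strand),
            )
        else:
            g_iv = GenomicInterval(chrom, tss - body + 1, tss + 1, strand)
            exons = (
                GenomicInterval(chrom, tss - 3299, tss - 2999, strand),
                GenomicInterval(chrom, tss - 1799, tss - 1499, strand),
                GenomicInterval(chrom, tss - 199, tss + 1, strand),
            )
        genes.append(Gene(gene_id, f"Gene{i:04d}", g_iv, strand, tss, exons))

        ltr_id, decoy_type, partner, ttype = "", "", "", "none"
        is_active = False
        if label == CLASS_NONCANONICAL or i in decoy_assignment:
            length = int(np.clip(
                rng.normal(config.ltr_length_mean, config.ltr_length_sd), 200, 800))
            ltr_strand = strand if (label != CLASS_NONCANONICAL or same_strand[i]) \
                else ("-" if strand == "+" else "+")
            # LTR inside the peak, upstream-adjacent to the TSS
            ltr_start = peak_iv.start + 50
            ltr_iv = GenomicInterval(chrom, ltr_start, ltr_start + length, ltr_strand)
            ltr_id = f"ERVK_LTR_{ltr_counter:04d}"
            ltr_counter += 1
            repeats.append(RepeatElement(ltr_iv, ltr_id, "LTR", "ERVK", is_solo=True))
            if label == CLASS_NONCANONICAL:
                is_active = i in active_set
                n_cpg = int(rng.integers(25, 36)) if is_active else int(rng.integers(2, 6))
                if is_active:
                    # chimeras require the LTR on the partner gene's strand
                    ttype = ("chimera" if i in chimera_set and same_strand[i]
                             else "ncRNA")
                    if ttype == "chimera":
                        partner = gene_id
            else:
                decoy_type = decoy_assignment[i]
                n_cpg = int(rng.integers(2, 6))
            ltr_sequences[ltr_id] = _random_sequence(rng, length, n_cpg)

        if label in (CLASS_CANONICAL_MATERNAL, CLASS_CANONICAL_PATERNAL):
            mid = peak_iv.midpoint()
            cgis.append(GenomicInterval(chrom, mid - 250, mid + 250))

        favored = {
            CLASS_BIALLELIC: "",
            CLASS_STRAIN_B6: "B6",
            CLASS_STRAIN_CAST: "CAST",
            CLASS_CANONICAL_MATERNAL: "maternal",
            CLASS_CANONICAL_PATERNAL: "paternal",
            CLASS_NONCANONICAL: "paternal",
        }[label]
        truth_rows.append({
            "region_id": peak_id, "class_label": label, "favored_allele": favored,
            "gene_id": gene_id, "ltr_id": ltr_id,
            "is_ltr_promoter": is_active, "transcript_type": ttype,
            "chimera_partner_gene": partner, "decoy_type": decoy_type,
        })

    # background ERVK LTRs: intergenic, far (> 3 kb) from every TSS
    bg_rng = stream_rng(config.seed, "background_ltrs")
    n_bg = min(config.n_background_ltrs, config.n_peaks - 1)
    k27_domains, k4_domains, meth_domains = [], [], []
    for j in range(n_bg):
        i = j % (config.n_peaks - 1)
        chrom = chrom_names[i // per_chrom]
        pos = margin + (i % per_chrom) * spacing + spacing // 2 + 6000
        length = int(np.clip(
            bg_rng.normal(config.ltr_length_mean, config.ltr_length_sd), 200, 800))
        strand = "+" if j % 2 == 0 else "-"
        ltr_id = f"ERVK_BG_{j:04d}"
        iv = GenomicInterval(chrom, pos, pos + length, strand)
        is_solo = bool(bg_rng.random() < 0.85)
        repeats.append(RepeatElement(iv, ltr_id, "LTR", "ERVK", is_solo=is_solo))
        ltr_sequences[ltr_id] = _random_sequence(bg_rng, length, int(bg_rng.integers(2, 6)))
        if j % 10 == 0:  # a minority of background LTRs sit in oocyte domains
            k27_domains.append(iv.expanded(1000))

    # oocyte chromatin catalogs: non-canonical LTRs carry oocyte H3K27me3,
    # canonical CGIs are oocyte-methylated, active-gene promoters H3K4me3
    for row in truth_rows:
        if row["class_label"] == CLASS_NONCANONICAL and row["ltr_id"]:
            rep = next(r for r in repeats if r.repeat_name == row["ltr_id"])
            k27_domains.append(rep.interval.expanded(1000))
    meth_domains = [cgi.expanded(500) for cgi in cgis]
    k4_domains = [g.interval.expanded(0) for g in genes[::7]]

    # --- SNPs -------------------------------------------------------------
    snp_rng = stream_rng(config.seed, "snps")
    snps_full, snps_pass1, snps_129 = [], [], []
    segments_129 = []
    for chrom, length in chroms.items():
        seg_len = int(length * config.fraction_129_segments)
        seg = GenomicInterval(chrom, int(length * 0.60), int(length * 0.60) + seg_len)
        segments_129.append(seg)
        n_snps = snp_rng.poisson(length * config.snp_rate)
        positions = np.sort(snp_rng.choice(length, size=n_snps, replace=False))
        for pos in positions:
            b6 = str(snp_rng.choice(_BASES))
            cast = str(snp_rng.choice([b for b in _BASES if b != b6]))
            rec = SNPRecord(chrom, int(pos), b6, cast)
            snps_full.append(rec)
            in_seg = seg.contains(chrom, int(pos))
            shared = in_seg and snp_rng.random() < config.fraction_129_shared_with_cast
            if not shared:
                snps_pass1.append(rec)
            if in_seg and not shared:
                # 129 base equals B6 here; uninformative vs CAST? no:
                # 129 == B6 != CAST, so it is 129/CAST-informative too
                snps_129.append(SNPRecord(chrom, int(pos), b6, cast))
        # 129-specific SNPs (B6 == CAST reference, 129 differs)
        n_129 = snp_rng.poisson(seg_len * config.snp_rate)
        pos129 = np.sort(snp_rng.choice(
            np.arange(seg.start, seg.end), size=n_129, replace=False))
        taken = {p for p in positions}
        for pos in pos129:
            if int(pos) in taken:
                continue
            ref = str(snp_rng.choice(_BASES))
            alt = str(snp_rng.choice([b for b in _BASES if b != ref]))
            snps_129.append(SNPRecord(chrom, int(pos), alt, ref))  # g1=129, g2=CAST

    # ensure every focal/decoy LTR carries assignable SNPs
    snp_positions = {(s.chrom, s.pos) for s in snps_full}
    forced = []
    for rep in repeats:
        iv = rep.interval
        for frac in (0.25, 0.5, 0.75):
            pos = iv.start + int(len(iv) * frac)
            if (iv.chrom, pos) not in snp_positions:
                b6 = str(snp_rng.choice(_BASES))
                cast = str(snp_rng.choice([b for b in _BASES if b != b6]))
                rec = SNPRecord(iv.chrom, pos, b6, cast)
                forced.append(rec)
                snp_positions.add((iv.chrom, pos))
    snps_full.extend(forced)
    snps_pass1.extend(forced)
    snps_full.sort(key=lambda s: (s.chrom, s.pos))
    snps_pass1.sort(key=lambda s: (s.chrom, s.pos))
    snps_129.sort(key=lambda s: (s.chrom, s.pos))

    reference = ReferenceBundle(
        chromosomes=chroms,
        snps_b6_cast=snps_full,
        snps_b6_cast_excl_shared=snps_pass1,
        snps_129_cast=snps_129,
        segments_129=segments_129,
        genes=genes,
        peaks=peaks,
        repeats=repeats,
        cgis=cgis,
        ltr_sequences=ltr_sequences,
        oocyte_domains={
            "H3K27me3": k27_domains,
            "H3K4me3": k4_domains,
            "methylated": meth_domains,
        },
    )
    truth = pd.DataFrame(truth_rows)
    return reference, truth


# ---------------------------------------------------------------------------
# Allelic count simulation
# ---------------------------------------------------------------------------

def _betabinom_draw(rng: np.random.Generator, n: int, pi: float, rho: float) -> int:
    if n == 0:
        return 0
    if rho <= 0:
        return int(rng.binomial(n, pi))
    conc = 1.0 / rho - 1.0
    p = rng.beta(pi * conc, (1.0 - pi) * conc)
    return int(rng.binomial(n, p))


def maternal_fraction(class_label: str, favored: str, cross: str,
                      allelic_pi: float) -> float:
    """Expected maternal read fraction for a planted class in a cross.

    Strain-biased regions favor the same strain in both reciprocal
    orientations (so the parental direction flips); imprinted regions
    favor the same parental allele in both.  In matDKO/CAST, canonical
    maternal imprints lose their bias (maternal fraction 0.5); canonical
    paternal and non-canonical imprints retain it.  The matDKO maternal
    genome behaves as B6 for strain effects.
    """
    if cross not in CROSSES:
        raise ConfigError(f"unknown cross {cross!r}")
    if class_label == CLASS_BIALLELIC:
        return 0.5
    if class_label in (CLASS_STRAIN_B6, CLASS_STRAIN_CAST):
        maternal_is_b6 = cross in ("B6/CAST", "matDKO/CAST")
        favored_is_maternal = (favored == "B6") == maternal_is_b6
        return allelic_pi if favored_is_maternal else 1.0 - allelic_pi
    # imprinted classes
    if class_label == CLASS_CANONICAL_MATERNAL and cross == "matDKO/CAST":
        return 0.5
    return allelic_pi if favored == "maternal" else 1.0 - allelic_pi


def simulate_allelic_chip_counts(reference: ReferenceBundle, truth: pd.DataFrame,
                                 config: SimConfig, cross: str) -> pd.DataFrame:
    """Per-peak per-replicate allelic ChIP counts for one cross."""
    if cross not in CROSSES:
        raise ConfigError(f"unknown cross {cross!r}; expected one of {CROSSES}")
    rng = stream_rng(config.seed, f"chip:{cross}")
    rows = []
    sample_base = cross.replace("/", "x")
    for row in truth.itertuples(index=False):
        pi = maternal_fraction(row.class_label, row.favored_allele, cross,
                               config.allelic_pi)
        for rep in range(1, config.n_replicates_chip + 1):
            total = int(rng.poisson(config.mean_total_depth))
            mat = _betabinom_draw(rng, total, pi, config.rho)
            rows.append({
                "region_id": row.region_id,
                "sample_id": f"{sample_base}_H3K4me3_rep{rep}",
                "replicate": rep,
                "mat": mat, "pat": total - mat,
                "unassigned": int(rng.poisson(2 * config.mean_total_depth)),
                "region_kind": "peak",
            })
    return pd.DataFrame(rows)


def simulate_allelic_rna_counts(reference: ReferenceBundle, truth: pd.DataFrame,
                                config: SimConfig, cross: str) -> pd.DataFrame:
    """Gene-level allelic RNA counts mirroring each peak's planted class."""
    if cross not in CROSSES:
        raise ConfigError(f"unknown cross {cross!r}")
    rng = stream_rng(config.seed, f"rna_counts:{cross}")
    rows = []
    sample_base = cross.replace("/", "x")
    for row in truth.itertuples(index=False):
        pi = maternal_fraction(row.class_label, row.favored_allele, cross,
                               config.allelic_pi)
        for rep in range(1, config.n_replicates_rna + 1):
            total = int(rng.poisson(config.mean_rna_depth))
            mat = _betabinom_draw(rng, total, pi, config.rho)
            rows.append({
                "region_id": row.gene_id,
                "sample_id": f"{sample_base}_RNA_rep{rep}",
                "replicate": rep,
                "mat": mat, "pat": total - mat,
                "unassigned": int(rng.poisson(config.mean_rna_depth)),
                "region_kind": "gene",
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Read-level simulation
# ---------------------------------------------------------------------------

def _haplotype_maps(reference: ReferenceBundle) -> tuple[dict, dict, dict]:
    b6cast = {(s.chrom, s.pos): s for s in reference.snps_b6_cast}
    pass1 = {(s.chrom, s.pos) for s in reference.snps_b6_cast_excl_shared}
    s129 = {(s.chrom, s.pos): s for s in reference.snps_129_cast}
    return b6cast, pass1, s129


def _observed_base(reference, maps, cross: str, parental: str,
                   chrom: str, pos: int) -> str | None:
    """Base a read from the given parental haplotype shows at a SNP position."""
    b6cast, pass1, s129 = maps
    in_129 = any(seg.contains(chrom, pos) for seg in reference.segments_129)
    key = (chrom, pos)
    if cross == "B6/CAST":
        strain = "B6" if parental == "maternal" else "CAST"
    elif cross == "CAST/B6":
        strain = "CAST" if parental == "maternal" else "B6"
    else:  # matDKO/CAST
        strain = ("129" if in_129 else "B6") if parental == "maternal" else "CAST"
    if key in b6cast:
        snp = b6cast[key]
        if strain == "B6":
            return snp.base_genome1
        if strain == "CAST":
            return snp.base_genome2
        # 129 haplotype at a B6/CAST SNP: equals CAST when the position was
        # excluded from the pass-1 table (129/CAST-shared), else equals B6
        return snp.base_genome2 if key not in pass1 else snp.base_genome1
    if key in s129:
        snp = s129[key]
        return snp.base_genome1 if strain == "129" else snp.base_genome2
    return None


def _snp_obs_for_read(reference, maps, snp_positions_sorted, cross, parental,
                      chrom, start, end) -> tuple:
    obs = []
    positions = snp_positions_sorted.get(chrom)
    if positions is None:
        return ()
    lo = np.searchsorted(positions, start, side="left")
    hi = np.searchsorted(positions, end, side="left")
    for pos in positions[lo:hi]:
        base = _observed_base(reference, maps, cross, parental, chrom, int(pos))
        if base is not None:
            obs.append((int(pos), base))
    return tuple(obs)


def _all_snp_positions(reference) -> dict:
    by_chrom: dict[str, list] = {}
    for s in reference.snps_b6_cast:
        by_chrom.setdefault(s.chrom, []).append(s.pos)
    for s in reference.snps_129_cast:
        by_chrom.setdefault(s.chrom, []).append(s.pos)
    return {c: np.array(sorted(set(p))) for c, p in by_chrom.items()}


def simulate_genomic_reads(reference: ReferenceBundle, config: SimConfig,
                           cross: str, n_reads: int,
                           region: GenomicInterval | None = None,
                           stream: str = "genomic_reads") -> tuple[list, list]:
    """Uniformly placed reads with haplotype-faithful SNP observations.

    Returns (reads, truth_parental) where truth_parental gives the
    simulated parental origin of each read.  Used to exercise and score
    allele assignment; each read's origin is maternal or paternal with
    equal probability.
    """
    if cross not in CROSSES:
        raise ConfigError(f"unknown cross {cross!r}")
    rng = stream_rng(config.seed, f"{stream}:{cross}")
    maps = _haplotype_maps(reference)
    positions = _all_snp_positions(reference)
    chrom_names = list(reference.chromosomes)
    reads, origins = [], []
    for i in range(n_reads):
        if region is not None:
            chrom = region.chrom
            start = int(rng.integers(region.start,
                                     max(region.start + 1, region.end - config.read_length)))
        else:
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            start = int(rng.integers(0, reference.chromosomes[chrom] - config.read_length))
        end = start + config.read_length
        parental = "maternal" if rng.random() < 0.5 else "paternal"
        obs = _snp_obs_for_read(reference, maps, positions, cross, parental,
                                chrom, start, end)
        reads.append(ReadRecord(f"{stream}_{i}", chrom, start, end,
                                "+" if i % 2 == 0 else "-", obs, (),
                                cross.replace("/", "x"), 1))
        origins.append(parental)
    return reads, origins


def simulate_rna_reads(reference: ReferenceBundle, truth: pd.DataFrame,
                       config: SimConfig, cross: str) -> tuple[list, pd.DataFrame]:
    """Spliced RNA reads at LTRs (promoters and decoys) + gene-level counts.

    Active LTR promoters receive same-strand reads across replicates plus
    splice-junction reads whose donor lies inside the LTR; chimeric
    transcripts splice onto exon 2 of the partner gene, ncRNAs onto a
    novel unannotated acceptor.  Decoy LTRs realise the three failure
    modes: too few reads in a second replicate, transcription without a
    donor junction, and an upstream junction splicing INTO the LTR.
    Junction tuples are stored genomically as (intron start, intron end);
    the biological donor is the left coordinate on + transcripts and the
    right coordinate on - transcripts.
    """
    if cross not in CROSSES:
        raise ConfigError(f"unknown cross {cross!r}")
    rng = stream_rng(config.seed, f"rna_reads:{cross}")
    maps = _haplotype_maps(reference)
    positions = _all_snp_positions(reference)
    genes_by_id = {g.id: g for g in reference.genes}
    repeats_by_name = {r.repeat_name: r for r in reference.repeats}
    sample_base = cross.replace("/", "x")
    reads: list[ReadRecord] = []
    counter = 0

    def emit(ltr, n, replicate, parental_pi, with_donor_junction=None,
             strand=None):
        nonlocal counter
        strand = strand or (ltr.strand if ltr.strand in "+-" else "+")
        sample_id = f"{sample_base}_RNA_rep{replicate}"
        out = []
        for _ in range(n):
            parental = "maternal" if rng.random() < parental_pi else "paternal"
            lo = ltr.interval.start
            hi = max(lo + 1, ltr.interval.end - config.read_length)
            start = int(rng.integers(lo, hi))
            end = min(start + config.read_length, ltr.interval.end)
            junctions = ()
            if with_donor_junction is not None:
                junctions = (with_donor_junction,)
            obs = _snp_obs_for_read(reference, maps, positions, cross, parental,
                                    ltr.interval.chrom, start, end)
            out.append(ReadRecord(f"rna_{sample_base}_{counter}",
                                  ltr.interval.chrom, start, end, strand,
                                  obs, junctions, sample_id, replicate))
            counter += 1
        return out

    for row in truth.itertuples(index=False):
        if not row.ltr_id:
            continue
        ltr = repeats_by_name[row.ltr_id]
        strand = ltr.strand if ltr.strand in "+-" else "+"
        gene = genes_by_id[row.gene_id]
        pi_mat = maternal_fraction(row.class_label, row.favored_allele, cross,
                                   config.allelic_pi)
        donor_pos = ltr.interval.start + 2 * len(ltr.interval) // 3

        if row.is_ltr_promoter:
            # junction: LTR donor spliced onto the acceptor site
            if row.transcript_type == "chimera" and strand == gene.strand:
                tx_exons = gene.exons_in_transcription_order()
                exon2 = tx_exons[1]
                junction = ((donor_pos, exon2.start) if strand == "+"
                            else (exon2.end, donor_pos))
            else:
                # novel acceptor 2 kb past the LTR in transcription direction
                junction = ((donor_pos, ltr.interval.end + 2000) if strand == "+"
                            else (max(0, ltr.interval.start - 2000), donor_pos))
            for rep in range(1, config.n_replicates_rna + 1):
                n = max(6, int(rng.poisson(config.mean_ltr_reads)))
                reads.extend(emit(ltr, n - 1, rep, pi_mat))
                reads.extend(emit(ltr, 1, rep, pi_mat,
                                  with_donor_junction=junction))
        elif row.decoy_type == "low_reads":
            # supported in a single replicate of a single cross, so the
            # >= 2-replicate rule fails even after pooling datasets
            junction = ((donor_pos, ltr.interval.end + 2000) if strand == "+"
                        else (max(0, ltr.interval.start - 2000), donor_pos))
            if cross == "B6/CAST":
                reads.extend(emit(ltr, 7, 1, pi_mat, with_donor_junction=junction))
            else:
                reads.extend(emit(ltr, 2, 1, pi_mat))
            for rep in range(2, config.n_replicates_rna + 1):
                reads.extend(emit(ltr, 2, rep, pi_mat))
        elif row.decoy_type == "no_donor_junction":
            for rep in range(1, config.n_replicates_rna + 1):
                reads.extend(emit(ltr, 8, rep, pi_mat))
        elif row.decoy_type == "incoming_junction":
            # transcription runs through the LTR from an upstream exon
            acceptor_pos = ltr.interval.start + len(ltr.interval) // 3
            donor_jx = ((donor_pos, ltr.interval.end + 2000) if strand == "+"
                        else (max(0, ltr.interval.start - 2000), donor_pos))
            incoming = ((max(0, ltr.interval.start - 1500), acceptor_pos)
                        if strand == "+"
                        else (acceptor_pos, ltr.interval.end + 1500))
            for rep in range(1, config.n_replicates_rna + 1):
                reads.extend(emit(ltr, 7, rep, pi_mat))
                reads.extend(emit(ltr, 1, rep, pi_mat, with_donor_junction=donor_jx))
                reads.extend(emit(ltr, 1, rep, pi_mat, with_donor_junction=incoming))

    counts = simulate_allelic_rna_counts(reference, truth, config, cross)
    return reads, counts


# ---------------------------------------------------------------------------
# Methylation simulation
# ---------------------------------------------------------------------------

#: per-(stage, allele) methylation level programs
_PROGRAM_NONCANONICAL = {
    ("GV", "maternal"): 0.10, ("GV", "paternal"): 0.10,
    ("E3.5", "maternal"): 0.10, ("E3.5", "paternal"): 0.10,
    ("E6.5_epiblast", "maternal"): 0.85, ("E6.5_epiblast", "paternal"): 0.85,
    ("E6.5_ExE", "maternal"): 0.80, ("E6.5_ExE", "paternal"): 0.10,
}


def _canonical_program(favored: str, maternal_methylation_intact: bool) -> dict:
    high, low = 0.85, 0.10
    prog = {}
    for stage in STAGES:
        if favored == "maternal":
            mat = high if maternal_methylation_intact else 0.02
            pat = low
        else:  # paternal gDMR
            mat, pat = low, high
        prog[(stage, "maternal")] = mat
        prog[(stage, "paternal")] = pat
    return prog


def simulate_methylation(reference: ReferenceBundle, truth: pd.DataFrame,
                         config: SimConfig, cross: str = "B6/CAST") -> list:
    """Allele-resolved per-CpG methylation calls across developmental stages.

    Non-canonical LTR regions (LTR +/- 500 bp) follow the secondary-imprint
    program: unmethylated on both alleles in gametes and pre-implantation,
    maternal-methylated in ExE, biallelically methylated in epiblast.
    Canonical gDMR regions are methylated on the favored-allele side from
    the gamete onward; in matDKO the maternal gDMR methylation is absent.
    """
    if cross not in CROSSES:
        raise ConfigError(f"unknown cross {cross!r}")
    if config.methyl_coverage <= 0:
        raise ConfigError("coverage must be positive")
    rng = stream_rng(config.seed, f"methylation:{cross}")
    intact = cross != "matDKO/CAST"
    repeats_by_name = {r.repeat_name: r for r in reference.repeats}
    peaks_by_id = {p.id: p for p in reference.peaks}
    sites = []
    sample_id = cross.replace("/", "x") + "_BSseq"
    for row in truth.itertuples(index=False):
        if row.class_label == CLASS_NONCANONICAL:
            region = repeats_by_name[row.ltr_id].interval.expanded(config.methyl_flank)
            program = _PROGRAM_NONCANONICAL
        elif row.class_label in (CLASS_CANONICAL_MATERNAL, CLASS_CANONICAL_PATERNAL):
            region = peaks_by_id[row.region_id].interval
            program = _canonical_program(row.favored_allele, intact)
        else:
            continue
        cpgs = range(region.start, region.end, config.methyl_cpg_spacing)
        for stage in STAGES:
            for allele in ("maternal", "paternal"):
                m = program[(stage, allele)]
                for pos in cpgs:
                    cov = int(rng.poisson(config.methyl_coverage))
                    meth = int(rng.binomial(cov, m)) if cov > 0 else 0
                    sites.append(MethylSite(region.chrom, pos, allele, meth,
                                            cov - meth, sample_id, stage))
    return sites


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

def simulate_sample_sheet(config: SimConfig) -> list:
    """CrossDesign rows for the full study layout."""
    samples = []
    layout = [("B6", "CAST", True), ("CAST", "B6", True), ("B6_129", "CAST", False)]
    for mat, pat, intact in layout:
        base = ("matDKO/CAST" if not intact else f"{mat}/{pat}").replace("/", "x")
        for assay, n_rep in (("H3K4me3", config.n_replicates_chip),
                             ("RNA", config.n_replicates_rna)):
            for rep in range(1, n_rep + 1):
                samples.append(CrossDesign(
                    f"{base}_{assay}_rep{rep}", mat, pat, intact,
                    "ExE", assay, rep))
    return samples
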