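"""Seeded generators for every input the pipeline consumes.

The generators emulate a tumour/normal long-read sequencing experiment:
germline and somatic small variants whose allele fractions follow the
purity/subclonality mixture, FreeBayes-style count and quality
annotations with a simple noise model, germline/somatic structural
variants with breakpoint jitter, per-method SV call sets with configured
miss and false-call rates, negative-binomial tumour/normal window counts
over a piecewise-constant copy-number genome, and phased reads for the
haplotagging operation.  Every generator is reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import CountMatrix, GenomeWindow, PhasedHetSite, SmallVariantCall, SvCall

LABEL_GERMLINE = "germline"
LABEL_SOMATIC = "somatic"
LABEL_ARTIFACT = "artifact"


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def phred_strand_balance(saf: int, ao: int, p: float = 0.5) -> float:
    """Phred-scaled two-tailed binomial probability of the observed strand
    split of alt reads.  Any monotone strand-imbalance score would do here
    — the pipeline only thresholds it — but a calibrated tail probability
    keeps balanced calls far below the SAP < 30 cutoff."""
    if ao == 0:
        return 0.0
    pval = stats.binomtest(saf, ao, p).pvalue
    pval = max(pval, 1e-300)
    return float(-10.0 * math.log10(pval))


# ---------------------------------------------------------------------------
# small variants
# ---------------------------------------------------------------------------

@dataclass
class SmallVariantSimConfig:
    """Study-scale defaults: one chromosome of a ~60x long-read tumour/normal
    pair with a purity-0.6 tumour and clonal somatic SNVs."""

    chrom: str = "17"
    chrom_length: int = 81_000_000
    n_germline: int = 1000
    het_fraction: float = 1.0
    n_somatic: int = 20
    somatic_cell_fractions: tuple[float, ...] = (1.0,)  # of tumour cells
    purity: float = 0.6
    depth_mean: float = 60.0
    depth_overdispersion: float = 0.0  # NB variance = mu + phi*mu^2; 0 = Poisson
    base_quality_mean: float = 30.0
    mqm_mean: float = 60.0
    mqm_sd: float = 1.0
    n_strand_artifacts: int = 0
    germline_miss_rate: float = 0.0  # germline calls absent from the normal VCF


@dataclass
class SmallVariantSim:
    tumour: list[SmallVariantCall]
    germline: list[SmallVariantCall]
    truth: pd.DataFrame


_BASES = np.array(list("ACGT"))


def _draw_depth(cfg_mean: float, phi: float, rng: np.random.Generator, size: int) -> np.ndarray:
    if phi <= 0.0:
        return rng.poisson(cfg_mean, size=size)
    size_param = 1.0 / phi
    p = size_param / (size_param + cfg_mean)
    return rng.negative_binomial(size_param, p, size=size)


def _make_call(
    chrom: str, pos: int, ref: str, alt: str, vaf: float,
    cfg: SmallVariantSimConfig, rng: np.random.Generator,
    strand_bias: bool = False,
) -> SmallVariantCall:
    depth = max(int(_draw_depth(cfg.depth_mean, cfg.depth_overdispersion, rng, 1)[0]), 4)
    ao = int(rng.binomial(depth, min(vaf, 1.0)))
    ao = min(max(ao, 2), depth - 2)  # keep both alleles observed
    ro = depth - ao
    if strand_bias:
        # alt reads all-but-two on the forward strand and ref reads on the
        # reverse: the forward alt fraction is 1 and the reverse one
        # 2/(2 + ro) < 1/4, so the 4x rule removes the call by
        # construction, while SAR = 2 still clears the initial filter
        ao, ro = max(ao, 6), max(ro, 8)
        saf, sar = ao - 2, 2
        srf, srr = 0, ro
        depth = ao + ro
    else:
        saf = int(rng.binomial(ao, 0.5))
        sar = ao - saf
        srf = int(rng.binomial(ro, 0.5))
        srr = ro - srf
    qa = round(ao * cfg.base_quality_mean + rng.normal(0.0, 2.0), 2)
    qr = round(ro * cfg.base_quality_mean + rng.normal(0.0, 2.0), 2)
    mqm = round(float(np.clip(rng.normal(cfg.mqm_mean, cfg.mqm_sd), 0.0, 254.0)), 2)
    sap = round(phred_strand_balance(saf, ao), 2)
    return SmallVariantCall(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        qual=round(max(qa - qr / 10.0, 2.0), 2), numalt=1,
        ao=ao, ro=ro, saf=saf, sar=sar, srf=srf, srr=srr,
        qa=max(qa, 0.0), qr=max(qr, 0.0), mqm=mqm, sap=sap,
        ab=round(ro / depth, 4),
    )


def simulate_small_variants(
    cfg: SmallVariantSimConfig | None = None, seed=0
) -> SmallVariantSim:
    """Generate tumour and germline call sets plus a per-record truth table.

    Germline hets sit at expected VAF 0.5 in both samples; somatic SNVs
    appear only in the tumour at the mixture VAF
    ``purity * cell_fraction / 2`` (heterozygous in carrier cells of a
    diploid genome); strand-artifact calls place every alt read on the
    forward strand so the 4x strand-bias rule removes them by construction.
    """
    cfg = cfg or SmallVariantSimConfig()
    rng = _rng(seed)
    n_total = cfg.n_germline + cfg.n_somatic + cfg.n_strand_artifacts
    positions = np.sort(
        rng.choice(np.arange(1_000, cfg.chrom_length, 10), size=n_total, replace=False)
    )
    ref_idx = rng.integers(0, 4, size=n_total)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_total)) % 4

    tumour, germline, rows = [], [], []
    for i in range(n_total):
        pos = int(positions[i])
        ref, alt = str(_BASES[ref_idx[i]]), str(_BASES[alt_idx[i]])
        if i < cfg.n_germline:
            label, vaf_t = LABEL_GERMLINE, 0.5
            tumour.append(_make_call(cfg.chrom, pos, ref, alt, vaf_t, cfg, rng))
            if rng.random() >= cfg.germline_miss_rate:
                germline.append(_make_call(cfg.chrom, pos, ref, alt, 0.5, cfg, rng))
        elif i < cfg.n_germline + cfg.n_somatic:
            label = LABEL_SOMATIC
            cell_fraction = float(rng.choice(cfg.somatic_cell_fractions))
            vaf_t = cfg.purity * cell_fraction / 2.0
            tumour.append(_make_call(cfg.chrom, pos, ref, alt, vaf_t, cfg, rng))
        else:
            label, vaf_t = LABEL_ARTIFACT, 0.3
            tumour.append(
                _make_call(cfg.chrom, pos, ref, alt, vaf_t, cfg, rng, strand_bias=True)
            )
        rows.append({"chrom": cfg.chrom, "pos": pos, "ref": ref, "alt": alt,
                     "label": label, "expected_vaf": vaf_t})
    return SmallVariantSim(tumour=tumour, germline=germline,
                           truth=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# structural variants
# ---------------------------------------------------------------------------

@dataclass
class SvSimConfig:
    """Germline/somatic SV inventory with per-method error rates."""

    chroms: tuple[str, ...] = ("1", "2", "3")
    chrom_length: int = 100_000_000
    n_germline: int = 40
    germline_len_range: tuple[int, int] = (50_000, 500_000)
    n_somatic_per_type: dict = field(
        default_factory=lambda: {"DEL": 10, "DUP": 3, "INV": 3, "TRA": 2}
    )
    somatic_len_range: tuple[int, int] = (20_000, 2_000_000)
    methods: tuple[str, ...] = ("short_read", "long_read_a", "long_read_b")
    miss_rate: dict = field(default_factory=lambda: {"DEL": 0.1, "DUP": 0.1,
                                                     "INV": 0.1, "TRA": 0.1})
    call_jitter: int = 50
    n_false_decoy: int = 2
    n_false_imprecise: int = 3
    n_germline_leaks: int = 1


@dataclass
class SvSim:
    tumour: list[SvCall]
    germline: list[SvCall]
    methods: dict[str, list[SvCall]]
    truth_labels: dict[str, str]
    somatic_truth: list[SvCall]


def _jittered(call: SvCall, jitter: int, rng: np.random.Generator, **overrides) -> SvCall:
    d1 = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
    d2 = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
    start = max(call.start + d1, 1)
    end = call.end + d2
    if call.svtype != "TRA" and end <= start:
        end = start + 1
    return replace(call, start=start, end=end, **overrides)


def simulate_sv_sets(cfg: SvSimConfig | None = None, seed=0) -> SvSim:
    """Generate germline and somatic SV inventories and per-method call sets.

    Germline SVs appear in both samples with breakpoint jitter at most
    L/200 — inside the L/100 subtraction tolerance, so subtraction removes
    them.  Somatic SVs are tumour-only.  Per-method sets drop each true
    somatic SV with the configured per-type miss probability and add false
    calls: germline leak-throughs (jitter just beyond L/100), decoy-contig
    breakpoints, and imprecise low-AF noise.
    """
    cfg = cfg or SvSimConfig()
    rng = _rng(seed)

    germline: list[SvCall] = []
    for _ in range(cfg.n_germline):
        chrom = str(rng.choice(cfg.chroms))
        length = int(rng.integers(*cfg.germline_len_range))
        start = int(rng.integers(1_000_000, cfg.chrom_length - length))
        svtype = str(rng.choice(["DEL", "DUP", "INV"]))
        germline.append(SvCall(svtype=svtype, chrom=chrom, start=start,
                               chr2=chrom, end=start + length, svlen=length,
                               precise=True, af=0.5))

    somatic: list[SvCall] = []
    for svtype, count in cfg.n_somatic_per_type.items():
        for _ in range(count):
            chrom = str(rng.choice(cfg.chroms))
            if svtype == "TRA":
                other = str(rng.choice([c for c in cfg.chroms if c != chrom]))
                start = int(rng.integers(1_000_000, cfg.chrom_length))
                end = int(rng.integers(1_000_000, cfg.chrom_length))
                somatic.append(SvCall(svtype="TRA", chrom=chrom, start=start,
                                      chr2=other, end=end, svlen=None,
                                      precise=True, af=0.3,
                                      truth_label="true_somatic"))
            else:
                length = int(rng.integers(*cfg.somatic_len_range))
                start = int(rng.integers(1_000_000, cfg.chrom_length - length))
                somatic.append(SvCall(svtype=svtype, chrom=chrom, start=start,
                                      chr2=chrom, end=start + length, svlen=length,
                                      precise=True, af=0.3,
                                      truth_label="true_somatic"))

    # tumour sample: somatic SVs plus germline SVs re-observed with jitter <= L/200
    tumour = list(somatic)
    for g in germline:
        max_jitter = max((g.svlen or 0) // 200, 0)
        tumour.append(_jittered(g, max_jitter, rng))

    truth_labels: dict[str, str] = {}
    methods: dict[str, list[SvCall]] = {}
    for method in cfg.methods:
        calls: list[SvCall] = []
        for s in somatic:
            if rng.random() < cfg.miss_rate.get(s.svtype, 0.0):
                continue
            calls.append(_jittered(s, cfg.call_jitter, rng,
                                   source_method=method))
        for _ in range(cfg.n_false_decoy):
            start = int(rng.integers(1_000_000, cfg.chrom_length))
            calls.append(SvCall(svtype="TRA", chrom=str(rng.choice(cfg.chroms)),
                                start=start, chr2="hs37d5",
                                end=int(rng.integers(1, 30_000_000)), svlen=None,
                                precise=True, af=0.2, source_method=method,
                                truth_label="false_call"))
        for _ in range(cfg.n_false_imprecise):
            length = int(rng.integers(*cfg.somatic_len_range))
            chrom = str(rng.choice(cfg.chroms))
            start = int(rng.integers(1_000_000, cfg.chrom_length - length))
            calls.append(SvCall(svtype="DEL", chrom=chrom, start=start,
                                chr2=chrom, end=start + length, svlen=length,
                                precise=False, af=float(rng.uniform(0.21, 0.5)),
                                source_method=method, truth_label="false_call"))
        for g in rng.choice(len(germline), size=min(cfg.n_germline_leaks, len(germline)),
                            replace=False):
            leak = germline[int(g)]
            shift = int((leak.svlen or 1000) // 100) + cfg.call_jitter + 10
            calls.append(replace(leak, start=leak.start + shift, end=leak.end + shift,
                                 source_method=method, truth_label="false_call"))
        methods[method] = calls
    return SvSim(tumour=tumour, germline=germline, methods=methods,
                 truth_labels=truth_labels, somatic_truth=somatic)


# ---------------------------------------------------------------------------
# window counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CnSegmentSpec:
    """One planted copy-number segment: ``n_windows`` windows on ``chrom`` at
    tumour copy number ``tumour_ploidy`` over germline ploidy ``germline_ploidy``."""

    chrom: str
    n_windows: int
    tumour_ploidy: int
    germline_ploidy: int = 2


#: Default genome layout: >2000 windows of 100 kb with whole-chromosome
#: events at tumour copy numbers 4, 3, 3 and 0 plus a single-copy loss,
#: the aberration spectrum of a purity-0.63 lymphoma genome.
DEFAULT_CN_LAYOUT = (
    CnSegmentSpec("1", 700, 2),
    CnSegmentSpec("2", 400, 1),
    CnSegmentSpec("3", 500, 4),
    CnSegmentSpec("7", 450, 3),
    CnSegmentSpec("18", 350, 3),
    CnSegmentSpec("Y", 150, 0, germline_ploidy=1),
)


@dataclass
class WindowCountSimConfig:
    """Negative-binomial tumour/normal window counts for a piecewise-constant
    copy-number genome at a chosen purity."""

    layout: tuple[CnSegmentSpec, ...] = DEFAULT_CN_LAYOUT
    purity: float = 0.63
    depth_mean: float = 60.0
    overdispersion: float = 1.0 / 300.0  # NB variance = mu + phi*mu^2
    window_size: int = 100_000
    masked_fraction: float = 0.01


@dataclass
class WindowCountSim:
    counts: CountMatrix
    truth: pd.DataFrame  # chrom, n_windows, tumour_ploidy, germline_ploidy


def simulate_window_counts(
    cfg: WindowCountSimConfig | None = None, seed=0
) -> WindowCountSim:
    """Generate tumour/normal read counts per 100 kb window.

    Normal counts are NB with mean ``depth_mean``; tumour counts are NB
    with mean ``depth_mean * (alpha*p + g*(1-alpha)) / g`` for the
    window's planted tumour copy number ``p`` and germline ploidy ``g``.
    A ``masked_fraction`` of windows get near-zero normal counts to
    exercise the low-coverage mask.
    """
    cfg = cfg or WindowCountSimConfig()
    rng = _rng(seed)
    windows: list[GenomeWindow] = []
    rows = []
    offsets: dict[str, int] = {}
    for spec in cfg.layout:
        t_mean = cfg.depth_mean * (
            cfg.purity * spec.tumour_ploidy
            + spec.germline_ploidy * (1.0 - cfg.purity)
        ) / spec.germline_ploidy
        n_draw = _draw_depth(cfg.depth_mean, cfg.overdispersion, rng, spec.n_windows)
        t_draw = _draw_depth(max(t_mean, 1e-9), cfg.overdispersion, rng, spec.n_windows)
        masked = rng.random(spec.n_windows) < cfg.masked_fraction
        start0 = offsets.get(spec.chrom, 0)
        for k in range(spec.n_windows):
            n_count = int(rng.integers(0, 3)) if masked[k] else int(n_draw[k])
            start = (start0 + k) * cfg.window_size
            windows.append(GenomeWindow(chrom=spec.chrom, start=start,
                                        end=start + cfg.window_size,
                                        t_count=int(t_draw[k]), n_count=n_count))
        offsets[spec.chrom] = start0 + spec.n_windows
        rows.append({"chrom": spec.chrom, "n_windows": spec.n_windows,
                     "tumour_ploidy": spec.tumour_ploidy,
                     "germline_ploidy": spec.germline_ploidy})
    return WindowCountSim(counts=CountMatrix(windows=windows),
                          truth=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# phased reads
# ---------------------------------------------------------------------------

@dataclass
class PhasedReadSimConfig:
    chrom: str = "17"
    n_sites: int = 20
    site_spacing: int = 5_000
    n_reads: int = 200
    sites_per_read: int = 5
    allele_error_rate: float = 0.0


@dataclass
class PhasedReadSim:
    sites: list[PhasedHetSite]
    reads: dict[str, dict[tuple[str, int], str]]
    truth: pd.DataFrame  # read_id, haplotype


def simulate_phased_reads(
    cfg: PhasedReadSimConfig | None = None, seed=0
) -> PhasedReadSim:
    """Generate two haplotypes over het sites and reads sampled from them.

    Each read covers a contiguous run of sites from one haplotype; with
    probability ``allele_error_rate`` per site the read shows the other
    haplotype's allele instead (the worst case for majority voting).
    """
    cfg = cfg or PhasedReadSimConfig()
    rng = _rng(seed)
    sites = []
    for k in range(cfg.n_sites):
        ref_i = int(rng.integers(0, 4))
        alt_i = (ref_i + int(rng.integers(1, 4))) % 4
        sites.append(PhasedHetSite(chrom=cfg.chrom, pos=10_000 + k * cfg.site_spacing,
                                   ref=str(_BASES[ref_i]), alt=str(_BASES[alt_i]),
                                   haplotype_of_alt=int(rng.integers(1, 3))))
    reads: dict[str, dict[tuple[str, int], str]] = {}
    rows = []
    span = cfg.sites_per_read
    for r in range(cfg.n_reads):
        hap = int(rng.integers(1, 3))
        first = int(rng.integers(0, max(cfg.n_sites - span, 0) + 1))
        alleles = {}
        for site in sites[first:first + span]:
            on_hap = site.alt if site.haplotype_of_alt == hap else site.ref
            off_hap = site.ref if site.haplotype_of_alt == hap else site.alt
            shown = off_hap if rng.random() < cfg.allele_error_rate else on_hap
            alleles[(site.chrom, site.pos)] = shown
        read_id = f"read{r:04d}"
        reads[read_id] = alleles
        rows.append({"read_id": read_id, "haplotype": hap})
    return PhasedReadSim(sites=sites, reads=reads, truth=pd.DataFrame(rows))
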