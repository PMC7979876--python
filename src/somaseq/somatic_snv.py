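"""Subtraction-based somatic SNV calling from tumour and germline call sets.

The pipeline mirrors a tumour/normal workflow for noisy long-read data:
an initial quality filter on both samples, subtraction of germline calls
by (CHROM, POS, ALT), removal of strand-biased calls, a stringent final
annotation filter, and optionally subtraction of a second (cross-platform)
germline call set.  All thresholds are strict inequalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .io_model import SmallVariantCall, read_small_variant_vcf

logger = logging.getLogger(__name__)

#: Default thresholds; each entry is (field, op, value) with strict comparison.
INITIAL_FILTER_THRESHOLDS = {"qual_min": 1.0, "numalt_max": 2, "saf_min": 1, "sar_min": 1}
FINAL_FILTER_THRESHOLDS = {
    "ao_min": 10, "ro_min": 10, "qa_min": 100.0, "qr_min": 100.0,
    "ao_max": 100, "ro_max": 100, "sap_max": 30.0, "mqm_min": 55.0,
}
#: A call is strand-biased when one strand's alt fraction exceeds the
#: other's by more than this factor.
STRAND_BIAS_FACTOR = 4.0


@dataclass
class OverlapCounts:
    """Call-set overlap on the (chrom, pos, alt) key."""

    shared: int
    only_a: int
    only_b: int


@dataclass
class SnvPipelineReport:
    """Per-stage call counts for one pipeline run."""

    n_input: int = 0
    n_snv_only: int = 0
    n_after_initial: int = 0
    n_after_subtraction: int = 0
    n_after_strand_bias: int = 0
    n_after_final: int = 0
    n_after_second_subtraction: int | None = None
    n_non_snv_dropped: int = 0
    overlap: OverlapCounts | None = None

    def stage_counts(self) -> dict[str, int]:
        counts = {
            "input": self.n_input,
            "snv_only": self.n_snv_only,
            "after_initial_filter": self.n_after_initial,
            "after_germline_subtraction": self.n_after_subtraction,
            "after_strand_bias_filter": self.n_after_strand_bias,
            "after_final_filter": self.n_after_final,
        }
        if self.n_after_second_subtraction is not None:
            counts["after_second_subtraction"] = self.n_after_second_subtraction
        return counts


def initial_filter(
    calls: Iterable[SmallVariantCall],
    qual_min: float = INITIAL_FILTER_THRESHOLDS["qual_min"],
    numalt_max: int = INITIAL_FILTER_THRESHOLDS["numalt_max"],
    saf_min: int = INITIAL_FILTER_THRESHOLDS["saf_min"],
    sar_min: int = INITIAL_FILTER_THRESHOLDS["sar_min"],
) -> list[SmallVariantCall]:
    """Keep calls with QUAL > 1, NUMALT < 2, SAF > 1 and SAR > 1 (all strict)."""
    return [
        c for c in calls
        if c.qual > qual_min and c.numalt < numalt_max
        and c.saf > saf_min and c.sar > sar_min
    ]


def subtract_germline(
    tumour: Iterable[SmallVariantCall],
    germline: Iterable[SmallVariantCall],
) -> list[SmallVariantCall]:
    """Remove tumour calls matching a germline call on (chrom, pos, alt).

    The REF field is deliberately not part of the key: at a given position
    the ALT allele identifies the variant.
    """
    germline_keys = {g.key for g in germline}
    return [t for t in tumour if t.key not in germline_keys]


def _strand_fractions(call: SmallVariantCall) -> tuple[float, float]:
    fwd_depth = call.saf + call.srf
    rev_depth = call.sar + call.srr
    f_fwd = call.saf / fwd_depth if fwd_depth > 0 else 0.0
    f_rev = call.sar / rev_depth if rev_depth > 0 else 0.0
    return f_fwd, f_rev


def is_strand_biased(call: SmallVariantCall, factor: float = STRAND_BIAS_FACTOR) -> bool:
    """True when the alt fraction on one strand is more than ``factor`` times
    the alt fraction on the other strand (strictly greater).

    Fractions are per-strand: SAF/(SAF+SRF) against SAR/(SAR+SRR).  A strand
    with zero total depth contributes fraction 0, so the call is removable
    only if the other strand's fraction is positive.
    """
    f_fwd, f_rev = _strand_fractions(call)
    return f_fwd > factor * f_rev or f_rev > factor * f_fwd


def strand_bias_filter(
    calls: Iterable[SmallVariantCall], factor: float = STRAND_BIAS_FACTOR
) -> list[SmallVariantCall]:
    """Remove calls whose alt allele is strand-biased beyond ``factor``."""
    return [c for c in calls if not is_strand_biased(c, factor)]


def final_filter(
    calls: Iterable[SmallVariantCall],
    ao_min: int = FINAL_FILTER_THRESHOLDS["ao_min"],
    ro_min: int = FINAL_FILTER_THRESHOLDS["ro_min"],
    qa_min: float = FINAL_FILTER_THRESHOLDS["qa_min"],
    qr_min: float = FINAL_FILTER_THRESHOLDS["qr_min"],
    ao_max: int = FINAL_FILTER_THRESHOLDS["ao_max"],
    ro_max: int = FINAL_FILTER_THRESHOLDS["ro_max"],
    sap_max: float = FINAL_FILTER_THRESHOLDS["sap_max"],
    mqm_min: float = FINAL_FILTER_THRESHOLDS["mqm_min"],
) -> list[SmallVariantCall]:
    """Keep calls with AO > 10, RO > 10, QA > 100, QR > 100, AO < 100,
    RO < 100, SAP < 30 and MQM > 55 (all strict)."""
    return [
        c for c in calls
        if c.ao > ao_min and c.ro > ro_min and c.qa > qa_min and c.qr > qr_min
        and c.ao < ao_max and c.ro < ro_max and c.sap < sap_max and c.mqm > mqm_min
    ]


def compare_callsets(
    a: Iterable[SmallVariantCall], b: Iterable[SmallVariantCall]
) -> OverlapCounts:
    """Count shared and private calls between two sets on (chrom, pos, alt)."""
    keys_a = {c.key for c in a}
    keys_b = {c.key for c in b}
    shared = len(keys_a & keys_b)
    return OverlapCounts(shared=shared, only_a=len(keys_a) - shared,
                         only_b=len(keys_b) - shared)


def _load(calls) -> list[SmallVariantCall]:
    if isinstance(calls, (str, Path)):
        return read_small_variant_vcf(calls)
    return list(calls)


def run_snv_pipeline(
    tumour,
    germline,
    second_germline=None,
) -> tuple[list[SmallVariantCall], SnvPipelineReport]:
    """Run the full subtraction pipeline.

    ``tumour``/``germline``/``second_germline`` may each be a VCF path or a
    collection of :class:`SmallVariantCall`.  Non-SNV records (indels and
    MNPs) are dropped up front with a logged count — the pipeline's
    thresholds are calibrated for single-nucleotide substitutions only.
    """
    tumour_calls = _load(tumour)
    germline_calls = _load(germline)

    report = SnvPipelineReport(n_input=len(tumour_calls))
    tumour_snvs = [c for c in tumour_calls if c.is_snv]
    report.n_non_snv_dropped = len(tumour_calls) - len(tumour_snvs)
    if report.n_non_snv_dropped:
        logger.info("dropped %d non-SNV tumour records", report.n_non_snv_dropped)
    report.n_snv_only = len(tumour_snvs)
    germline_snvs = [c for c in germline_calls if c.is_snv]

    t_filt = initial_filter(tumour_snvs)
    g_filt = initial_filter(germline_snvs)
    report.n_after_initial = len(t_filt)

    somatic = subtract_germline(t_filt, g_filt)
    report.n_after_subtraction = len(somatic)

    somatic = strand_bias_filter(somatic)
    report.n_after_strand_bias = len(somatic)

    somatic = final_filter(somatic)
    report.n_after_final = len(somatic)

    if second_germline is not None:
        second = [c for c in _load(second_germline) if c.is_snv]
        somatic = subtract_germline(somatic, second)
        report.n_after_second_subtraction = len(somatic)

    return somatic, report
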