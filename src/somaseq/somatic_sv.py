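"""Somatic structural-variant derivation and benchmarking.

Covers germline SV subtraction with a length-scaled breakpoint tolerance,
size/precision/decoy filtering of the remaining calls, clustering of calls
reported by several methods into unique variants, and a false-negative /
false-discovery-rate evaluation against externally supplied truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_model import SvCall, SV_TYPES

#: Decoy contig absorbing ambiguous reads; calls with a breakpoint there are artefacts.
DECOY_CONTIG = "hs37d5"
#: Fixed breakpoint tolerance (bp) for cross-method matching and for
#: translocations, whose length-scaled tolerance is undefined.
DEFAULT_MATCH_TOLERANCE = 1000
#: Floor on the length-scaled subtraction tolerance L/100, so tiny germline
#: SVs still subtract their re-called twins despite basecall jitter.
MIN_SUBTRACT_TOLERANCE = 10
#: Minimum SV length retained by the somatic size filter (strict >).
MIN_SOMATIC_SVLEN = 10_000
#: Imprecise calls with caller AF above this go to the side collection.
IMPRECISE_AF_CUTOFF = 0.2

TRUE_SOMATIC = "true_somatic"
FALSE_CALL = "false_call"


def subtraction_tolerance(germline: SvCall, tra_tolerance: int = DEFAULT_MATCH_TOLERANCE) -> float:
    """Breakpoint tolerance used when subtracting ``germline``: L/100 with a
    10 bp floor, or a fixed window for translocations (length undefined)."""
    if germline.svtype == "TRA" or germline.svlen is None:
        return float(tra_tolerance)
    return max(germline.svlen / 100.0, float(MIN_SUBTRACT_TOLERANCE))


def matches_germline(
    tumour: SvCall, germline: SvCall, tra_tolerance: int = DEFAULT_MATCH_TOLERANCE
) -> bool:
    """True when ``tumour`` is the germline call re-observed: same type, same
    chromosomes at both breakpoints, and both start and end within the
    germline-length-scaled tolerance."""
    if tumour.svtype != germline.svtype:
        return False
    if tumour.chrom != germline.chrom or tumour.chr2 != germline.chr2:
        return False
    tol = subtraction_tolerance(germline, tra_tolerance)
    return (
        abs(tumour.start - germline.start) <= tol
        and abs(tumour.end - germline.end) <= tol
    )


def subtract_germline_svs(
    tumour: Iterable[SvCall],
    germline: Iterable[SvCall],
    tra_tolerance: int = DEFAULT_MATCH_TOLERANCE,
) -> list[SvCall]:
    """Remove tumour SVs that match any germline SV within tolerance."""
    germline = list(germline)
    return [
        t for t in tumour
        if not any(matches_germline(t, g, tra_tolerance) for g in germline)
    ]


def filter_somatic_svs(
    calls: Iterable[SvCall],
    min_svlen: int = MIN_SOMATIC_SVLEN,
    decoy: str = DECOY_CONTIG,
    imprecise_af_cutoff: float = IMPRECISE_AF_CUTOFF,
) -> tuple[list[SvCall], list[SvCall]]:
    """Split candidate somatic SVs into (pass, imprecise-high-AF side set).

    Pass: precise calls longer than ``min_svlen`` (strict) with neither
    breakpoint on the decoy contig.  Side set: imprecise calls with
    AF > ``imprecise_af_cutoff``, kept for separate examination.  Everything
    else is dropped.
    """
    passing: list[SvCall] = []
    side: list[SvCall] = []
    for c in calls:
        if c.precise:
            long_enough = c.svtype == "TRA" or (c.svlen is not None and c.svlen > min_svlen)
            if long_enough and c.chr2 != decoy and c.chrom != decoy:
                passing.append(c)
        elif c.af is not None and c.af > imprecise_af_cutoff:
            side.append(c)
    return passing, side


# ---------------------------------------------------------------------------
# cross-method matching
# ---------------------------------------------------------------------------

@dataclass
class UniqueVariant:
    """One variant after cross-method clustering."""

    svtype: str
    chrom: str
    start: int
    chr2: str
    end: int
    methods: tuple[str, ...]
    members: tuple[SvCall, ...]
    truth_label: str | None = None


def same_variant(a: SvCall, b: SvCall, tolerance: int = DEFAULT_MATCH_TOLERANCE) -> bool:
    """Pair predicate: same SV type and both breakpoints within ``tolerance``."""
    return (
        a.svtype == b.svtype
        and a.chrom == b.chrom
        and a.chr2 == b.chr2
        and abs(a.start - b.start) <= tolerance
        and abs(a.end - b.end) <= tolerance
    )


def match_across_methods(
    callsets: Mapping[str, Iterable[SvCall]],
    tolerance: int = DEFAULT_MATCH_TOLERANCE,
) -> list[UniqueVariant]:
    """Cluster calls from several methods into unique variants.

    Clusters are the connected components of the pairwise same-variant
    predicate (transitive closure), which makes the result independent of
    the order in which methods or calls are supplied.  Output is sorted by
    (chrom, start).
    """
    entries: list[tuple[str, SvCall]] = []
    for method in sorted(callsets):
        for call in sorted(callsets[method], key=lambda c: (c.chrom, c.start, c.end)):
            entries.append((method, call))
    n = len(entries)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    # the predicate requires identical (svtype, chrom, chr2), so only pairs
    # within the same bucket can ever match
    buckets: dict[tuple[str, str, str], list[int]] = {}
    for i, (_, call) in enumerate(entries):
        buckets.setdefault((call.svtype, call.chrom, call.chr2), []).append(i)
    for bucket in buckets.values():
        for a_pos, i in enumerate(bucket):
            for j in bucket[a_pos + 1:]:
                if same_variant(entries[i][1], entries[j][1], tolerance):
                    union(i, j)

    clusters: dict[int, list[tuple[str, SvCall]]] = {}
    for i, entry in enumerate(entries):
        clusters.setdefault(find(i), []).append(entry)

    variants = []
    for members in clusters.values():
        calls = [c for _, c in members]
        rep = min(calls, key=lambda c: (c.chrom, c.start, c.end))
        labels = {c.truth_label for c in calls if c.truth_label is not None}
        label = labels.pop() if len(labels) == 1 else None
        variants.append(
            UniqueVariant(
                svtype=rep.svtype, chrom=rep.chrom, start=rep.start,
                chr2=rep.chr2, end=rep.end,
                methods=tuple(sorted({m for m, _ in members})),
                members=tuple(calls), truth_label=label,
            )
        )
    variants.sort(key=lambda v: (v.chrom, v.start, v.end, v.svtype))
    return variants


# ---------------------------------------------------------------------------
# FNR / FDR evaluation
# ---------------------------------------------------------------------------

def round_half_up(x: float, digits: int = 2) -> float:
    """Round with ties away from zero, matching tabular presentation."""
    return float(Decimal(repr(float(x))).quantize(Decimal("1." + "0" * digits),
                                                  rounding=ROUND_HALF_UP))


def evaluate_methods(
    variants: Sequence[UniqueVariant],
    methods: Sequence[str] | None = None,
    truth_labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Build an FNR/FDR benchmark table from labelled unique variants.

    Per SV type and method: FNR = (true variants the method did not
    detect) / (total true variants of that type); FDR = (false calls the
    method made) / (all calls the method made).  An ``All`` row aggregates
    across types.  Rates whose denominator is zero are NaN, never 0.
    ``truth_labels`` may override/supply labels keyed by
    "svtype:chrom:start-chr2:end"; every variant must end up labelled.
    """
    labelled: list[UniqueVariant] = []
    for v in variants:
        label = v.truth_label
        if truth_labels is not None:
            key = variant_id(v)
            label = truth_labels.get(key, label)
        if label not in (TRUE_SOMATIC, FALSE_CALL):
            raise ValueError(f"variant {variant_id(v)} lacks a truth label")
        labelled.append(
            UniqueVariant(**{**v.__dict__, "truth_label": label})
        )
    if methods is None:
        methods = sorted({m for v in labelled for m in v.methods})

    svtypes = [t for t in SV_TYPES if any(v.svtype == t for v in labelled)]
    rows = []
    for svtype in [*svtypes, "All"]:
        subset = [v for v in labelled if svtype == "All" or v.svtype == svtype]
        total_true = sum(1 for v in subset if v.truth_label == TRUE_SOMATIC)
        for method in methods:
            detected = [v for v in subset if method in v.methods]
            detected_true = sum(1 for v in detected if v.truth_label == TRUE_SOMATIC)
            false_calls = sum(1 for v in detected if v.truth_label == FALSE_CALL)
            total_calls = len(detected)
            fnr = (total_true - detected_true) / total_true if total_true else float("nan")
            fdr = false_calls / total_calls if total_calls else float("nan")
            rows.append(
                {
                    "svtype": svtype, "method": method,
                    "total_true": total_true, "detected_true": detected_true,
                    "missed_true": total_true - detected_true,
                    "false_calls": false_calls, "total_calls": total_calls,
                    "fnr": fnr, "fdr": fdr,
                }
            )
    return pd.DataFrame(rows)


def variant_id(v: UniqueVariant) -> str:
    return f"{v.svtype}:{v.chrom}:{v.start}-{v.chr2}:{v.end}"
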