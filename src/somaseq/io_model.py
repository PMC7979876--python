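"""Domain types and readers/writers for the formats the pipeline touches.

Small variants and structural variants travel as VCF 4.x (via :mod:`pysam`);
per-window read counts and segment tables travel as plain TSV (via
:mod:`pandas`).  Coordinate conventions follow each format's native one:
VCF positions are 1-based, window intervals are 0-based half-open.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: INFO keys a small-variant VCF must carry for the somatic pipeline.
REQUIRED_SNV_INFO = (
    "AO", "RO", "SAF", "SAR", "SRF", "SRR",
    "QA", "QR", "MQM", "SAP", "AB", "NUMALT",
)

#: Structural variant types understood by the SV pipeline.
SV_TYPES = ("DEL", "DUP", "INV", "TRA", "INS")

#: Sentinel for a masked / unavailable log2 ratio (the paper's "NA").
MISSING_LOG2R = float("nan")


def is_missing(value: float) -> bool:
    """True when ``value`` is the missing-log2r sentinel."""
    return value is None or (isinstance(value, float) and math.isnan(value))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmallVariantCall:
    """One annotated small-variant record, expanded to a single ALT allele.

    Count and quality annotations mirror the FreeBayes INFO fields: ``ao``/
    ``ro`` are alt/ref observation counts, ``saf``/``sar`` and ``srf``/``srr``
    their per-strand splits, ``qa``/``qr`` summed base qualities (phred),
    ``mqm`` the mean mapping quality of alt observations, ``sap`` the
    phred-scaled strand-balance probability and ``ab`` the ratio of
    reference reads to all reads (carried through, never filtered on).
    ``numalt`` is the number of ALT alleles at the originating site, so
    site-level filters keep their meaning after multi-allelic expansion.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    numalt: int = 1
    ao: int = 0
    ro: int = 0
    saf: int = 0
    sar: int = 0
    srf: int = 0
    srr: int = 0
    qa: float = 0.0
    qr: float = 0.0
    mqm: float = 0.0
    sap: float = 0.0
    ab: float = 0.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.qual < 0:
            raise ValueError("qual must be non-negative")
        for name in ("ao", "ro", "saf", "sar", "srf", "srr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.saf + self.sar != self.ao:
            raise ValueError("saf + sar must equal ao")
        if self.srf + self.srr != self.ro:
            raise ValueError("srf + srr must equal ro")

    @property
    def key(self) -> tuple[str, int, str]:
        """Matching key for germline subtraction and call-set overlap."""
        return (self.chrom, self.pos, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class SvCall:
    """One structural-variant record with paired breakpoints.

    ``svlen`` may be ``None`` for translocations, where length is
    undefined.  ``truth_label`` carries an externally assigned verdict
    (``"true_somatic"`` / ``"false_call"``) or ``None`` when unlabelled.
    """

    svtype: str
    chrom: str
    start: int
    chr2: str
    end: int
    svlen: int | None = None
    precise: bool = True
    af: float | None = None
    filter_status: str = "PASS"
    source_method: str = ""
    truth_label: str | None = None

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SVTYPE {self.svtype!r}")
        if self.svtype != "TRA" and self.chrom == self.chr2 and self.end < self.start:
            raise ValueError("end must be >= start for intra-chromosomal SVs")
        if self.af is not None and not (0.0 <= self.af <= 1.0):
            raise ValueError("af must lie in [0, 1]")


@dataclass(frozen=True)
class GenomeWindow:
    """A fixed-size genomic window with tumour/normal read counts."""

    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    t_count: int
    n_count: int
    log2r: float = MISSING_LOG2R

    def __post_init__(self) -> None:
        if self.t_count < 0 or self.n_count < 0:
            raise ValueError("read counts must be non-negative")
        if self.end <= self.start:
            raise ValueError("window end must exceed start")


@dataclass
class CountMatrix:
    """Ordered per-window tumour/normal counts plus derived statistics.

    ``n_mean``/``n_sd`` (sample SD) drive the low-coverage mask
    ``N(w) > mean(N) - 2 sd(N)``; ``t_total``/``n_total`` feed the
    automatic normalisation offset ``log2(t_total / n_total)``.
    """

    windows: list[GenomeWindow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def n_counts(self) -> np.ndarray:
        return np.array([w.n_count for w in self.windows], dtype=float)

    @property
    def t_counts(self) -> np.ndarray:
        return np.array([w.t_count for w in self.windows], dtype=float)

    @property
    def n_mean(self) -> float:
        if not self.windows:
            return float("nan")
        return float(self.n_counts.mean())

    @property
    def n_sd(self) -> float:
        if len(self.windows) < 2:
            return float("nan")
        return float(self.n_counts.std(ddof=1))

    @property
    def t_total(self) -> int:
        return int(sum(w.t_count for w in self.windows))

    @property
    def n_total(self) -> int:
        return int(sum(w.n_count for w in self.windows))

    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        seen: dict[str, None] = {}
        for w in self.windows:
            seen.setdefault(w.chrom, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [w.chrom for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
                "t_count": [w.t_count for w in self.windows],
                "n_count": [w.n_count for w in self.windows],
                "log2r": [w.log2r for w in self.windows],
            }
        )


@dataclass
class Segment:
    """A contiguous run of windows with a common mean log2 ratio.

    ``first_window_index``/``last_window_index`` index into the owning
    :class:`CountMatrix` (inclusive); ``n_windows`` counts only windows
    with a non-missing log2r, and ``seg_mean`` is their mean.
    """

    chrom: str
    first_window_index: int
    last_window_index: int
    n_windows: int
    seg_mean: float
    ploidy_call: int | None = None
    start: int | None = None  # genomic, 0-based
    end: int | None = None    # genomic, exclusive

    def shifted(self, baseline: float) -> "Segment":
        return replace(self, seg_mean=self.seg_mean - baseline)


@dataclass(frozen=True)
class PhasedHetSite:
    """A phased heterozygous site: which haplotype carries the ALT allele."""

    chrom: str
    pos: int
    ref: str
    alt: str
    haplotype_of_alt: int  # 1 or 2

    def __post_init__(self) -> None:
        if self.haplotype_of_alt not in (1, 2):
            raise ValueError("haplotype_of_alt must be 1 or 2")


@dataclass
class TaggedRead:
    """A read after haplotype assignment by majority vote over het sites."""

    read_id: str
    observed_alleles: dict[tuple[str, int], str]
    haplotype: int | None
    votes_for: int
    votes_against: int

    def __post_init__(self) -> None:
        if self.haplotype is not None and not self.votes_for > self.votes_against:
            raise ValueError("a haplotype may only be assigned on a strict majority")


# ---------------------------------------------------------------------------
# VCF readers / writers
# ---------------------------------------------------------------------------

def _info_scalar(value, index: int):
    """Pull entry ``index`` from a per-ALT INFO tuple, or pass scalars through."""
    if isinstance(value, (tuple, list)):
        return value[index] if index < len(value) else value[0]
    return value


def read_small_variant_vcf(path: str | Path) -> list[SmallVariantCall]:
    """Read an annotated small-variant VCF into per-ALT records.

    Multi-allelic sites are expanded to one record per ALT allele with
    ``numalt`` preserved from the site.  Raises :class:`ValueError` when a
    required annotation field is absent (naming the field) or when the
    file cannot be parsed.
    """
    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        for key in REQUIRED_SNV_INFO:
            if key not in vcf.header.info:
                raise ValueError(f"VCF {path} lacks required INFO field {key}")
        calls: list[SmallVariantCall] = []
        for rec_no, rec in enumerate(vcf, start=1):
            try:
                info = rec.info
                alts = rec.alts or ()
                numalt = int(_info_scalar(info["NUMALT"], 0))
                for i, alt in enumerate(alts):
                    calls.append(
                        SmallVariantCall(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            qual=float(rec.qual if rec.qual is not None else 0.0),
                            numalt=numalt,
                            ao=int(_info_scalar(info["AO"], i)),
                            ro=int(_info_scalar(info["RO"], i)),
                            saf=int(_info_scalar(info["SAF"], i)),
                            sar=int(_info_scalar(info["SAR"], i)),
                            srf=int(_info_scalar(info["SRF"], i)),
                            srr=int(_info_scalar(info["SRR"], i)),
                            qa=float(_info_scalar(info["QA"], i)),
                            qr=float(_info_scalar(info["QR"], i)),
                            mqm=float(_info_scalar(info["MQM"], i)),
                            sap=float(_info_scalar(info["SAP"], i)),
                            ab=float(_info_scalar(info["AB"], i)),
                        )
                    )
            except KeyError as exc:
                raise ValueError(
                    f"VCF {path} record {rec_no} ({rec.chrom}:{rec.pos}) lacks "
                    f"required INFO field {exc.args[0]}"
                ) from exc
    return calls


def _snv_header(chroms: Sequence[str]) -> pysam.VariantHeader:
    hdr = pysam.VariantHeader()
    for chrom in chroms:
        hdr.contigs.add(chrom)
    defs = [
        ("AO", "1", "Integer", "Alternate allele observation count"),
        ("RO", "1", "Integer", "Reference allele observation count"),
        ("SAF", "1", "Integer", "Alt observations on the forward strand"),
        ("SAR", "1", "Integer", "Alt observations on the reverse strand"),
        ("SRF", "1", "Integer", "Ref observations on the forward strand"),
        ("SRR", "1", "Integer", "Ref observations on the reverse strand"),
        ("QA", "1", "Float", "Alt allele quality sum (phred)"),
        ("QR", "1", "Float", "Ref allele quality sum (phred)"),
        ("MQM", "1", "Float", "Mean mapping quality of alt observations"),
        ("SAP", "1", "Float", "Strand balance probability for the alt allele (phred)"),
        ("AB", "1", "Float", "Ratio of reference reads to all reads"),
        ("NUMALT", "1", "Integer", "Number of ALT alleles at the original site"),
    ]
    for key, number, vtype, desc in defs:
        hdr.info.add(key, number, vtype, desc)
    return hdr


def _genomic_sort_key(chrom: str, pos: int) -> tuple[int, str, int]:
    """Numeric chromosomes first in numeric order, then others lexically."""
    name = chrom.removeprefix("chr")
    if name.isdigit():
        return (0, f"{int(name):09d}", pos)
    return (1, name, pos)


def write_small_variant_vcf(calls: Iterable[SmallVariantCall], path: str | Path) -> None:
    """Write per-ALT records as a VCF, one line per record, in genomic order."""
    calls = sorted(calls, key=lambda c: _genomic_sort_key(c.chrom, c.pos))
    chroms: dict[str, None] = {}
    for c in calls:
        chroms.setdefault(c.chrom, None)
    hdr = _snv_header(list(chroms))
    with pysam.VariantFile(str(path), "w", header=hdr) as out:
        for c in calls:
            rec = out.new_record(
                contig=c.chrom, start=c.pos - 1, alleles=(c.ref, c.alt), qual=c.qual
            )
            rec.info.update(
                {
                    "AO": c.ao, "RO": c.ro, "SAF": c.saf, "SAR": c.sar,
                    "SRF": c.srf, "SRR": c.srr, "QA": c.qa, "QR": c.qr,
                    "MQM": c.mqm, "SAP": c.sap, "AB": c.ab, "NUMALT": c.numalt,
                }
            )
            out.write(rec)


def read_sv_vcf(
    path: str | Path,
    source_method: str = "",
    skip_report: dict | None = None,
) -> list[SvCall]:
    """Read a structural-variant VCF into :class:`SvCall` records.

    Records with an unrecognised SVTYPE are skipped with a logged warning;
    pass ``skip_report`` (a dict) to receive per-type skip counts.  When
    SVLEN is absent for an intra-chromosomal call it falls back to
    ``end - start``.  No filtering happens here — decoy-contig and
    precision filters live downstream.
    """
    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    calls: list[SvCall] = []
    with vcf:
        for rec in vcf:
            info = rec.info
            svtype = str(info.get("SVTYPE", "")) if "SVTYPE" in info else ""
            if svtype not in SV_TYPES:
                logger.warning("skipping record %s:%s with unknown SVTYPE %r",
                               rec.chrom, rec.pos, svtype)
                if skip_report is not None:
                    skip_report[svtype] = skip_report.get(svtype, 0) + 1
                continue
            chr2 = str(info["CHR2"]) if "CHR2" in info else rec.chrom
            if "END2" in info:
                end = int(_info_scalar(info["END2"], 0))
            elif "END" in info:
                end = int(_info_scalar(info["END"], 0))
            else:
                end = rec.stop
            svlen = None
            if "SVLEN" in info:
                svlen = abs(int(_info_scalar(info["SVLEN"], 0)))
            elif svtype != "TRA" and chr2 == rec.chrom:
                svlen = end - rec.pos
            precise = True
            if "IMPRECISE" in info:
                precise = False
            elif "PRECISE" in info:
                precise = True
            af = float(_info_scalar(info["AF"], 0)) if "AF" in info else None
            filters = list(rec.filter.keys())
            status = filters[0] if filters else "PASS"
            calls.append(
                SvCall(
                    svtype=svtype, chrom=rec.chrom, start=rec.pos,
                    chr2=chr2, end=end, svlen=svlen, precise=precise,
                    af=af, filter_status=status, source_method=source_method,
                )
            )
    return calls


def write_sv_vcf(calls: Iterable[SvCall], path: str | Path) -> None:
    """Write SV calls as a symbolic-allele VCF in genomic order."""
    calls = sorted(calls, key=lambda c: _genomic_sort_key(c.chrom, c.start))
    hdr = pysam.VariantHeader()
    chroms: dict[str, None] = {}
    for c in calls:
        chroms.setdefault(c.chrom, None)
        chroms.setdefault(c.chr2, None)
    for chrom in chroms:
        hdr.contigs.add(chrom)
    hdr.info.add("SVTYPE", "1", "String", "Type of structural variant")
    hdr.info.add("END", "1", "Integer", "End position of the variant")
    hdr.info.add("CHR2", "1", "String", "Chromosome of the second breakpoint")
    hdr.info.add("SVLEN", "1", "Integer", "Length of the variant in bases")
    hdr.info.add("PRECISE", "0", "Flag", "Breakpoints resolved at base precision")
    hdr.info.add("IMPRECISE", "0", "Flag", "Breakpoints not base-precise")
    hdr.info.add("END2", "1", "Integer", "Position of the second breakpoint on CHR2")
    hdr.info.add("AF", "A", "Float", "Caller-reported allele fraction")
    for name in ("DEL", "DUP", "INV", "TRA", "INS"):
        hdr.add_meta("ALT", items=[("ID", name), ("Description", f"{name} structural variant")])
    with pysam.VariantFile(str(path), "w", header=hdr) as out:
        for c in calls:
            inter = c.svtype == "TRA" or c.chr2 != c.chrom
            rec = out.new_record(
                contig=c.chrom, start=c.start - 1,
                stop=c.start if inter else c.end,
                alleles=("N", f"<{c.svtype}>"),
            )
            rec.info["SVTYPE"] = c.svtype
            if inter:
                # END lives on another contig; VCF END cannot precede POS,
                # so carry breakpoint 2 in END2 instead.
                rec.info["END2"] = c.end
            rec.info["CHR2"] = c.chr2
            if c.svlen is not None:
                rec.info["SVLEN"] = c.svlen
            if c.precise:
                rec.info["PRECISE"] = True
            else:
                rec.info["IMPRECISE"] = True
            if c.af is not None:
                rec.info["AF"] = (c.af,)
            out.write(rec)


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

_COUNT_COLUMNS = ["chrom", "start", "end", "t_count", "n_count"]


def read_window_counts(path: str | Path) -> CountMatrix:
    """Read a BED-like TSV of per-window tumour/normal read counts."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"window-count table lacks columns: {missing}")
    if len(df):
        for col in ("start", "end", "t_count", "n_count"):
            if not pd.api.types.is_numeric_dtype(df[col]):
                raise ValueError(f"non-numeric values in column {col!r}")
    windows = []
    has_log2r = "log2r" in df.columns
    for row in df.itertuples(index=False):
        log2r = float(row.log2r) if has_log2r and not pd.isna(row.log2r) else MISSING_LOG2R
        windows.append(
            GenomeWindow(
                chrom=str(row.chrom), start=int(row.start), end=int(row.end),
                t_count=int(row.t_count), n_count=int(row.n_count), log2r=log2r,
            )
        )
    if not windows:
        logger.warning("empty window-count table %s: statistics undefined", path)
    return CountMatrix(windows=windows)


def write_window_counts(counts: CountMatrix, path: str | Path) -> None:
    df = counts.to_frame()
    order = sorted(
        range(len(df)),
        key=lambda i: _genomic_sort_key(df["chrom"].iloc[i], int(df["start"].iloc[i])),
    )
    df.iloc[order].to_csv(path, sep="\t", index=False, na_rep="NA")


def write_segments(segments: Iterable[Segment], path: str | Path) -> None:
    """Write segments as TSV: chrom, start, end, n_windows, seg_mean, ploidy."""
    rows = [
        {
            "chrom": s.chrom,
            "start": s.start if s.start is not None else s.first_window_index,
            "end": s.end if s.end is not None else s.last_window_index + 1,
            "n_windows": s.n_windows,
            "seg_mean": s.seg_mean,
            "ploidy": s.ploidy_call if s.ploidy_call is not None else "NA",
        }
        for s in segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_labels(path: str | Path) -> dict[str, str]:
    """Read a TSV of (variant id, label) truth assignments for SV benchmarking."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("truth-label table needs two columns: variant id, label")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
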