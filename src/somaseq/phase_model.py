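"""Closed-form cis/trans expected-VAF model and read haplotagging.

A somatic SNV co-located with a subclonal heterozygous deletion has an
expected allele fraction that depends on whether it lies on the deleted
haplotype (*cis*) or the retained one (*trans*).  With tumour purity
``pi`` (percent of cells that are tumour) and ``x`` the percent of all
cells carrying the deletion (0 <= x <= pi), read counts follow the allele
copy numbers: cells without the deletion contribute two allele copies and
deleted cells one, so the total is ``2*(100 - x) + x = 200 - x`` per 100
cells.

* cis:   VAF <= 100 * (pi - x) / (200 - x)   (SNV lost with the deletion)
* trans: VAF <= 100 * pi / (200 - x)         (SNV on every tumour copy)

Both are upper bounds — the SNV may itself be subclonal.  The two curves
coincide at x = 0 (pi/2 percent); cis falls and trans rises as x grows.

Haplotagging assigns long reads to one of two phased haplotypes by
majority vote over the heterozygous sites each read covers, and tabulates
per-haplotype REF/ALT counts per site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_model import PhasedHetSite, TaggedRead

SUPPORTS_TRANS = "supports_trans"
SUPPORTS_CIS = "supports_cis"
INCONCLUSIVE = "inconclusive"


@dataclass
class PhasingScenario:
    """Observed quantities for the cis/trans decision (all in percent)."""

    purity_pct: float
    deletion_cell_pct: float | None = None
    observed_vaf_pct: float | None = None
    deletion_af_pct: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity_pct <= 100.0:
            raise ValueError("purity must lie in [0, 100] percent")
        if self.deletion_cell_pct is not None:
            _check_x(self.deletion_cell_pct, self.purity_pct)


def _check_x(x: float, purity_pct: float) -> None:
    if not 0.0 <= x <= purity_pct:
        raise ValueError(
            f"deletion cell-fraction x={x} must lie in [0, purity={purity_pct}]"
        )


def expected_vaf_cis(purity_pct: float, x: float) -> float:
    """Upper-bound VAF (percent) for a somatic SNV in cis with the deletion.

    Only tumour cells that still carry the deleted haplotype — those
    without the deletion, ``purity - x`` per 100 cells — carry the SNV.
    Strictly decreasing in ``x``; maximal (purity/2) at x = 0.
    """
    _check_x(x, purity_pct)
    return 100.0 * (purity_pct - x) / (200.0 - x)


def expected_vaf_trans(purity_pct: float, x: float) -> float:
    """Upper-bound VAF (percent) for a somatic SNV in trans with the deletion.

    Every tumour cell retains the non-deleted haplotype, so all ``purity``
    cells contribute the SNV allele.  Strictly increasing in ``x``, from
    purity/2 at x = 0 to 100*purity/(200 - purity) at x = purity.
    """
    _check_x(x, purity_pct)
    return 100.0 * purity_pct / (200.0 - x)


def cis_vaf_maximum(purity_pct: float) -> float:
    """Maximum of the cis bound over x: attained at x = 0, equal to purity/2."""
    return expected_vaf_cis(purity_pct, 0.0)


def deletion_cell_fraction_from_af(deletion_af_pct: float) -> float:
    """Solve the mixture for x given the observed deletion allele fraction.

    The deletion covers ``x`` of ``200 - x`` allele copies per 100 cells,
    so AF = x/(200 - x) and x = 200*AF/(1 + AF).  A documented helper:
    caller-reported AFs conflate allele and cell fractions, so treat the
    result as indicative.
    """
    af = deletion_af_pct / 100.0
    return 200.0 * af / (1.0 + af)


@dataclass
class ConfigurationCall:
    """Outcome of the cis/trans decision with its margin (percentage points
    of VAF above/below the cis maximum)."""

    verdict: str
    margin: float
    cis_max: float
    trans_min: float


def classify_configuration(scenario: PhasingScenario) -> ConfigurationCall:
    """Decide whether an observed somatic-SNV VAF supports cis or trans.

    A VAF strictly above the cis maximum (purity/2) is impossible in cis,
    so it supports trans.  A VAF strictly below both the cis curve at the
    deletion-implied x and the trans minimum supports cis.  Anything else
    — including the boundary itself — is inconclusive.
    """
    if scenario.observed_vaf_pct is None:
        raise ValueError("classification needs an observed VAF")
    vaf = scenario.observed_vaf_pct
    cis_max = cis_vaf_maximum(scenario.purity_pct)
    trans_min = expected_vaf_trans(scenario.purity_pct, 0.0)
    margin = vaf - cis_max
    if vaf > cis_max:
        return ConfigurationCall(SUPPORTS_TRANS, margin, cis_max, trans_min)
    x = scenario.deletion_cell_pct
    cis_at_x = expected_vaf_cis(scenario.purity_pct, x) if x is not None else cis_max
    if vaf < cis_at_x and vaf < trans_min:
        return ConfigurationCall(SUPPORTS_CIS, margin, cis_max, trans_min)
    return ConfigurationCall(INCONCLUSIVE, margin, cis_max, trans_min)


# ---------------------------------------------------------------------------
# haplotagging
# ---------------------------------------------------------------------------

def haplotag_reads(
    reads: Mapping[str, Mapping[tuple[str, int], str]] | Iterable[tuple[str, Mapping[tuple[str, int], str]]],
    sites: Sequence[PhasedHetSite],
) -> tuple[list[TaggedRead], pd.DataFrame]:
    """Assign reads to haplotypes and tabulate per-site allele counts.

    ``reads`` maps read id to the alleles it shows at (chrom, pos)
    positions.  At each phased het site a read votes for the haplotype its
    allele matches (ALT votes for ``haplotype_of_alt``, REF for the other);
    alleles matching neither are non-informative.  A read is assigned on a
    strict majority, otherwise left unassigned.

    Returns the tagged reads plus a table with, per site, REF/ALT counts
    within each haplotype group and over all reads.
    """
    site_by_pos = {(s.chrom, s.pos): s for s in sites}
    if isinstance(reads, Mapping):
        read_items = list(reads.items())
    else:
        read_items = list(reads)

    tagged: list[TaggedRead] = []
    for read_id, alleles in read_items:
        votes = {1: 0, 2: 0}
        for pos_key, allele in alleles.items():
            site = site_by_pos.get(pos_key)
            if site is None:
                continue
            if allele == site.alt:
                votes[site.haplotype_of_alt] += 1
            elif allele == site.ref:
                votes[3 - site.haplotype_of_alt] += 1
            # anything else: non-informative at this site
        if votes[1] > votes[2]:
            hap, vfor, vagainst = 1, votes[1], votes[2]
        elif votes[2] > votes[1]:
            hap, vfor, vagainst = 2, votes[2], votes[1]
        else:
            hap, vfor, vagainst = None, votes[1], votes[2]
        tagged.append(TaggedRead(read_id=read_id, observed_alleles=dict(alleles),
                                 haplotype=hap, votes_for=vfor, votes_against=vagainst))

    rows = []
    for site in sites:
        counts = {"hap1_ref": 0, "hap1_alt": 0, "hap2_ref": 0, "hap2_alt": 0,
                  "all_ref": 0, "all_alt": 0}
        for read in tagged:
            allele = read.observed_alleles.get((site.chrom, site.pos))
            if allele == site.ref:
                kind = "ref"
            elif allele == site.alt:
                kind = "alt"
            else:
                continue
            counts[f"all_{kind}"] += 1
            if read.haplotype is not None:
                counts[f"hap{read.haplotype}_{kind}"] += 1
        rows.append({"chrom": site.chrom, "pos": site.pos, "ref": site.ref,
                     "alt": site.alt, "haplotype_of_alt": site.haplotype_of_alt,
                     **counts})
    return tagged, pd.DataFrame(rows)
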