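"""Windowed copy-number analysis with purity and ploidy inference.

The pipeline: a normalised log2 tumour/normal read-count ratio per window
with low-coverage masking, circular binary segmentation (CBS) of each
chromosome's ratio track, recentring of segment means on the diploid
baseline, tumour-purity estimation by inverting the mixture model on
clusters of aberrant segment means, and classification of every segment
against theoretical means for integer copy numbers 0..6.

Mixture model: a tumour sample of purity ``alpha`` mixes tumour cells at
copy number ``p`` with normal cells at germline copy number ``g``, so the
expected log2 ratio of a segment is ``log2((alpha*p + g*(1-alpha)) / g)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .io_model import CountMatrix, Segment, MISSING_LOG2R, is_missing

logger = logging.getLogger(__name__)

#: Ploidies against which segments are classified.
PLOIDY_RANGE = tuple(range(0, 7))


def default_germline_ploidy(chrom: str) -> int:
    """Germline copy number by chromosome name: 1 for the sex chromosomes
    of an XY individual, 2 for autosomes."""
    name = chrom.removeprefix("chr")
    return 1 if name in ("X", "Y") else 2


# ---------------------------------------------------------------------------
# log2 ratio
# ---------------------------------------------------------------------------

def compute_log2r(counts: CountMatrix, offset: float | str = "auto") -> CountMatrix:
    """Fill the normalised log ratio R(w) = log2(T(w)/N(w)) - offset.

    Windows with N(w) <= mean(N) - 2*sd(N) are masked (strict ``>`` keeps a
    window), as are windows with T(w) = 0; masked windows carry the missing
    sentinel and never enter segmentation.  ``offset='auto'`` uses
    log2(total tumour count / total normal count).
    """
    if offset == "auto":
        if counts.n_total == 0 or counts.t_total == 0:
            raise ValueError("auto offset needs non-zero total counts")
        offset_value = math.log2(counts.t_total / counts.n_total)
    else:
        offset_value = float(offset)
    n_mean, n_sd = counts.n_mean, counts.n_sd
    threshold = n_mean - 2.0 * n_sd
    n_zero_t = 0
    windows = []
    for w in counts.windows:
        if w.n_count > threshold:
            if w.t_count > 0:
                log2r = math.log2(w.t_count / w.n_count) - offset_value
            else:
                log2r = MISSING_LOG2R
                n_zero_t += 1
        else:
            log2r = MISSING_LOG2R
        windows.append(replace(w, log2r=log2r))
    if n_zero_t:
        logger.info("masked %d windows with zero tumour count", n_zero_t)
    return CountMatrix(windows=windows)


# ---------------------------------------------------------------------------
# circular binary segmentation
# ---------------------------------------------------------------------------

@dataclass
class CbsParams:
    """Parameters of the circular binary segmentation.

    ``alpha`` is the permutation significance level for accepting a split,
    ``min_width`` the minimum number of windows per segment, ``undo_sd``
    the threshold (in units of the point-level SD) below which adjacent
    segment means are merged back, and ``n_permutations``/``seed`` control
    the permutation test.
    """

    alpha: float = 0.01
    min_width: int = 5
    undo_sd: float = 3.0
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")


def max_circular_split(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Maximal two-segment circular split statistic of a sequence.

    Considers every arc ``x[i:j]`` (its complement wraps around) with both
    arc and complement at least ``min_width`` long, and returns the maximal
    standardized mean-difference statistic
    ``|mean_arc - mean_rest| / sqrt(1/k + 1/(n-k))`` together with the arc
    boundaries ``(i, j)``.  Returns ``(0.0, 0, n)`` when no admissible arc
    exists.  Ties resolve to the smallest ``(i, j)``.
    """
    n = len(x)
    if n < 2 * min_width:
        return 0.0, 0, n
    s = np.concatenate(([0.0], np.cumsum(x)))
    total = s[-1]

    def stats_for(k: int) -> np.ndarray:
        arc_sums = s[k:] - s[: n - k + 1]  # arcs x[i:i+k] for i = 0..n-k
        arc_mean = arc_sums / k
        rest_mean = (total - arc_sums) / (n - k)
        return np.abs(arc_mean - rest_mean) / math.sqrt(1.0 / k + 1.0 / (n - k))

    ks = range(min_width, n - min_width + 1)
    tmax = max(float(stats_for(k).max()) for k in ks)
    # an arc and its complement describe the same circular partition with the
    # same statistic, so ties are canonicalised to the smallest (i, j)
    candidates = []
    for k in ks:
        for i in np.nonzero(stats_for(k) >= tmax - 1e-9)[0]:
            candidates.append((int(i), int(i) + k))
    i, j = min(candidates)
    return tmax, i, j


def _split_is_significant(
    x: np.ndarray, tmax: float, params: CbsParams, rng: np.random.Generator,
    max_fn: Callable = None,
) -> bool:
    """Permutation test for a candidate split, with early stopping.

    The permutation p-value estimate is (exceedances + 1)/(trials + 1); the
    loop stops as soon as the exceedance count already forces p >= alpha,
    or, for clearly significant splits, once enough clean trials have
    accumulated to bound p below alpha.
    """
    max_fn = max_fn or max_circular_split
    n_perm = params.n_permutations
    max_exceed = params.alpha * (n_perm + 1) - 1  # beyond this, p >= alpha
    clean_needed = int(math.ceil(1.0 / params.alpha)) * 2
    exceed = 0
    y = x.copy()
    for trial in range(1, n_perm + 1):
        rng.shuffle(y)
        t, _, _ = max_fn(y, params.min_width)
        # tolerance keeps the decision stable under reordering of the
        # floating-point sums inside the statistic
        if t >= tmax - 1e-9:
            exceed += 1
            if exceed > max_exceed:
                return False
        elif exceed == 0 and trial >= clean_needed:
            return True
    return (exceed + 1) / (n_perm + 1) < params.alpha


def _recursive_segment(
    x: np.ndarray, lo: int, hi: int, params: CbsParams,
    rng: np.random.Generator, boundaries: set[int], max_fn: Callable,
) -> None:
    seg = x[lo:hi]
    if len(seg) < 2 * params.min_width:
        return
    tmax, i, j = max_fn(seg, params.min_width)
    if tmax <= 0.0 or not _split_is_significant(seg, tmax, params, rng, max_fn):
        return
    cuts = [c for c in (lo + i, lo + j) if lo < c < hi]
    if not cuts:
        return
    boundaries.update(cuts)
    pieces = sorted({lo, hi, *cuts})
    for a, b in zip(pieces[:-1], pieces[1:]):
        _recursive_segment(x, a, b, params, rng, boundaries, max_fn)


def robust_point_sd(x: np.ndarray) -> float:
    """Point-level noise SD, estimated from the median absolute successive
    difference (robust to the segment-mean jumps themselves)."""
    if len(x) < 2:
        return 0.0
    diffs = np.abs(np.diff(x))
    return float(1.4826 * np.median(diffs) / math.sqrt(2.0))


def _apply_sd_undo(x: np.ndarray, bounds: list[int], undo_sd: float) -> list[int]:
    """Merge away change points whose adjacent segment means differ by less
    than ``undo_sd`` point-level SDs, weakest first."""
    sd = robust_point_sd(x)
    bounds = sorted(bounds)
    while len(bounds) > 2:
        means = [x[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
        gaps = [abs(means[k + 1] - means[k]) for k in range(len(means) - 1)]
        weakest = int(np.argmin(gaps))
        if gaps[weakest] >= undo_sd * sd:
            break
        del bounds[weakest + 1]
    return bounds


def cbs_segment_series(x: np.ndarray, params: CbsParams | None = None,
                       rng: np.random.Generator | None = None,
                       max_fn: Callable = max_circular_split) -> list[tuple[int, int]]:
    """Segment one chromosome's ratio sequence (missing values removed).

    Returns half-open index ranges covering ``x``.  Deterministic for a
    given ``params.seed`` (or a caller-supplied generator).  ``max_fn``
    exists so an exhaustive-search implementation of the split statistic
    can be substituted for verification.
    """
    params = params or CbsParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n == 0:
        return []
    boundaries: set[int] = set()
    _recursive_segment(x, 0, n, params, rng, boundaries, max_fn)
    bounds = _apply_sd_undo(x, [0, n, *boundaries], params.undo_sd)
    return list(zip(bounds[:-1], bounds[1:]))


def segment_cbs(counts: CountMatrix, params: CbsParams | None = None) -> list[Segment]:
    """Run CBS per chromosome on a log2r-filled :class:`CountMatrix`.

    Masked windows are removed before segmentation and never contribute to
    a segment mean; segment window indices refer back to the matrix.
    """
    params = params or CbsParams()
    rng = np.random.default_rng(params.seed)
    segments: list[Segment] = []
    by_chrom: dict[str, list[int]] = {}
    for idx, w in enumerate(counts.windows):
        by_chrom.setdefault(w.chrom, []).append(idx)
    for chrom, indices in by_chrom.items():
        kept = [i for i in indices if not is_missing(counts.windows[i].log2r)]
        if not kept:
            logger.warning("chromosome %s has no unmasked windows; skipped", chrom)
            continue
        values = np.array([counts.windows[i].log2r for i in kept])
        for lo, hi in cbs_segment_series(values, params, rng):
            member = kept[lo:hi]
            segments.append(
                Segment(
                    chrom=chrom,
                    first_window_index=member[0],
                    last_window_index=member[-1],
                    n_windows=hi - lo,
                    seg_mean=float(values[lo:hi].mean()),
                    start=counts.windows[member[0]].start,
                    end=counts.windows[member[-1]].end,
                )
            )
    return segments


# ---------------------------------------------------------------------------
# recentring, purity, classification
# ---------------------------------------------------------------------------

#: Segment means within this band of zero are treated as copy-neutral.
DEFAULT_ZERO_BAND = 0.25
#: Minimum window support for a segment to define the diploid baseline.
DEFAULT_BASELINE_MIN_WINDOWS = 500
#: Gap (in log2r units) separating 1-D clusters of aberrant segment means.
DEFAULT_CLUSTER_GAP = 0.15


@dataclass
class PurityModel:
    """Estimated tumour purity with its per-cluster evidence."""

    purity: float
    cluster_estimates: dict[int, float]
    baseline_offset: float = 0.0

    def theoretical_means(self) -> dict[tuple[int, int], float]:
        """Expected segment mean for (tumour ploidy, germline ploidy)."""
        return {
            (p, g): theoretical_mean(p, self.purity, g)
            for p in PLOIDY_RANGE for g in (1, 2)
        }


def recentre(
    segments: Sequence[Segment],
    min_windows: int = DEFAULT_BASELINE_MIN_WINDOWS,
    zero_band: float = DEFAULT_ZERO_BAND,
) -> tuple[list[Segment], float]:
    """Shift all segment means so the diploid cluster sits at zero.

    The baseline is the window-weighted mean of segments longer than
    ``min_windows`` windows whose mean lies within ``zero_band`` of zero
    (the copy-neutral cluster).  Raises when no segment qualifies, in which
    case a manual baseline is needed.
    """
    qualifying = [
        s for s in segments
        if s.n_windows > min_windows and abs(s.seg_mean) < zero_band
    ]
    if not qualifying:
        raise ValueError(
            "no segment qualifies as the copy-neutral baseline "
            f"(need n_windows > {min_windows} and |mean| < {zero_band}); "
            "supply a manual baseline"
        )
    weights = np.array([s.n_windows for s in qualifying], dtype=float)
    means = np.array([s.seg_mean for s in qualifying])
    baseline = float(np.average(means, weights=weights))
    return [s.shifted(baseline) for s in segments], baseline


def theoretical_mean(p: int, purity: float, germline_ploidy: int = 2) -> float:
    """Expected segment mean for tumour copy number ``p`` at purity ``alpha``.

    Autosomes (germline 2): log2((alpha*p + 2(1-alpha))/2); sex chromosomes
    of an XY genome (germline 1): log2(alpha*p + (1-alpha)).  Equals 0 when
    p matches the germline ploidy; ``-inf`` for a pure tumour at p = 0.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError("purity must lie in [0, 1]")
    if germline_ploidy not in (1, 2):
        raise ValueError("germline ploidy must be 1 or 2")
    mix = purity * p + germline_ploidy * (1.0 - purity)
    if mix <= 0.0:
        return float("-inf")
    return math.log2(mix / germline_ploidy)


def purity_from_segment_mean(m: float, p: int) -> float:
    """Invert the autosome mixture: alpha = (2^(m+1) - 2)/(p - 2)."""
    if p == 2:
        raise ValueError("purity is unidentifiable from copy-neutral segments (p = 2)")
    return (2.0 ** (m + 1.0) - 2.0) / (p - 2.0)


def _gap_clusters(values: np.ndarray, weights: np.ndarray, gap: float) -> list[tuple[float, float]]:
    """1-D clustering: split sorted values where consecutive points are more
    than ``gap`` apart; returns (weighted mean, total weight) per cluster."""
    order = np.argsort(values)
    values, weights = values[order], weights[order]
    clusters = []
    start = 0
    for k in range(1, len(values) + 1):
        if k == len(values) or values[k] - values[k - 1] > gap:
            v, w = values[start:k], weights[start:k]
            clusters.append((float(np.average(v, weights=w)), float(w.sum())))
            start = k
    return clusters


def estimate_purity(
    segments: Sequence[Segment],
    zero_band: float = DEFAULT_ZERO_BAND,
    cluster_gap: float = DEFAULT_CLUSTER_GAP,
    germline_ploidy_of: Callable[[str], int] = default_germline_ploidy,
) -> PurityModel:
    """Estimate tumour purity from clusters of aberrant segment means.

    Uses recentred autosomal segments with |mean| >= ``zero_band``:
    their means are gap-clustered in 1-D, clusters are provisionally
    assigned tumour copy numbers — the most negative cluster is a
    single-copy loss (p = 1), positive clusters in ascending order are
    gains at p = 3 then p = 4 — and each cluster mean is inverted through
    the autosome mixture formula.  The reported purity is the unweighted
    mean of the per-cluster estimates.
    """
    aberrant = [
        s for s in segments
        if germline_ploidy_of(s.chrom) == 2 and abs(s.seg_mean) >= zero_band
    ]
    if not aberrant:
        raise ValueError(
            "no aberrant autosomal segments: purity is unidentifiable "
            "from a copy-neutral genome"
        )
    values = np.array([s.seg_mean for s in aberrant])
    weights = np.array([s.n_windows for s in aberrant], dtype=float)
    clusters = _gap_clusters(values, weights, cluster_gap)

    negative = sorted([c for c in clusters if c[0] < 0.0])
    positive = sorted([c for c in clusters if c[0] > 0.0])
    assignment: dict[int, float] = {}
    if negative:
        assignment[1] = negative[0][0]  # most negative cluster
    for p, (mean, _) in zip((3, 4), positive):
        assignment[p] = mean
    if len(negative) > 1 or len(positive) > 2:
        logger.warning(
            "found %d negative / %d positive segment-mean clusters; using the "
            "most negative as p=1 and the two lowest positive as p=3, p=4",
            len(negative), len(positive),
        )
    if not assignment:
        raise ValueError("no usable segment-mean cluster for purity estimation")

    estimates = {p: purity_from_segment_mean(m, p) for p, m in assignment.items()}
    purity = float(np.mean(list(estimates.values())))
    return PurityModel(purity=purity, cluster_estimates=estimates)


def classify_segments(
    segments: Sequence[Segment],
    model: PurityModel,
    germline_ploidy_of: Callable[[str], int] = default_germline_ploidy,
    max_distance: float | None = None,
) -> list[Segment]:
    """Assign each segment the integer ploidy whose theoretical mean is
    nearest its (recentred) mean; ties break toward the lower ploidy, and
    segments farther than ``max_distance`` from every theoretical mean stay
    unclassified."""
    out = []
    for s in segments:
        g = germline_ploidy_of(s.chrom)
        best_p, best_d = None, float("inf")
        for p in PLOIDY_RANGE:
            mean = theoretical_mean(p, model.purity, g)
            d = abs(s.seg_mean - mean)
            if d < best_d - 1e-12:
                best_p, best_d = p, d
        if max_distance is not None and best_d > max_distance:
            best_p = None
        out.append(replace(s, ploidy_call=best_p))
    return out


@dataclass
class CnaResult:
    """Everything the copy-number pipeline produces in one run."""

    counts: CountMatrix
    segments: list[Segment]
    baseline_offset: float
    model: PurityModel


def run_cna_pipeline(
    counts: CountMatrix,
    offset: float | str = "auto",
    params: CbsParams | None = None,
    zero_band: float = DEFAULT_ZERO_BAND,
    baseline_min_windows: int = DEFAULT_BASELINE_MIN_WINDOWS,
    cluster_gap: float = DEFAULT_CLUSTER_GAP,
    germline_ploidy_of: Callable[[str], int] = default_germline_ploidy,
    max_distance: float | None = None,
) -> CnaResult:
    """Log2 ratio → CBS → recentring → purity estimation → classification."""
    with_ratio = compute_log2r(counts, offset)
    segments = segment_cbs(with_ratio, params)
    segments, baseline = recentre(segments, baseline_min_windows, zero_band)
    model = estimate_purity(segments, zero_band, cluster_gap, germline_ploidy_of)
    model.baseline_offset = baseline
    segments = classify_segments(segments, model, germline_ploidy_of, max_distance)
    return CnaResult(counts=with_ratio, segments=segments,
                     baseline_offset=baseline, model=model)
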