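"""Circular-binary-segmentation-style partition of a profile.

Each chromosome is scanned recursively for the arc that maximizes the
two-sample t statistic between the arc and its complement; a split is
accepted when its within-chromosome permutation p-value falls below
``alpha``.  Masked and missing bins are skipped (indices compacted), never
interpolated.  The procedure is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._cbs import max_arc_stat, perm_max_stats
from .genome import Segment, SegmentSet

__all__ = ["SegmentationParams", "segment_profile", "merge_adjacent"]

# sequential permutation schedule: early batches let clearly null splits
# exit cheaply; significant splits always see the full n_permutations
_BATCHES = (32, 96, 128, 256, 488, 1000, 2000)


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the permutation segmentation.

    alpha
        Permutation p-value threshold for accepting a split (0.01).
    n_permutations
        Within-chromosome permutations of bin values under the null (1,000).
    min_bins
        Chromosomes with fewer usable bins are returned as one untested
        segment (3).
    seed
        Seed of the permutation stream.
    """

    alpha: float = 0.01
    n_permutations: int = 1000
    min_bins: int = 3
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")


def _split_significant(x, t_obs, alpha, n_perm, rng):
    """Sequential permutation test: is the best split significant at alpha?

    p = (1 + #exceedances) / (1 + n_perm).  Permutations are consumed in
    batches; once the exceedance count alone guarantees p > alpha the scan
    stops (the decision is identical to running all permutations).
    """
    # not significant as soon as exceed > floor(alpha * (1 + n_perm)) - 1
    give_up = int(np.floor(alpha * (1 + n_perm)))
    exceed = 0
    done = 0
    for b in _BATCHES:
        b = min(b, n_perm - done)
        if b <= 0:
            break
        perms = rng.permuted(np.broadcast_to(x, (b, x.size)), axis=1)
        tm = perm_max_stats(np.ascontiguousarray(perms))
        exceed += int(np.count_nonzero(tm >= t_obs - 1e-12))
        done += b
        if exceed >= give_up:
            return False
    return (1 + exceed) <= alpha * (1 + n_perm)


def _segment_values(x, params, rng):
    """Recursive split search on a compact value vector; returns half-open
    (lo, hi) pieces in compact index space."""
    out = []
    stack = [(0, x.size)]
    while stack:
        lo, hi = stack.pop()
        n = hi - lo
        if n < max(params.min_bins, 3):
            out.append((lo, hi))
            continue
        seg = x[lo:hi]
        t_obs, i, j = max_arc_stat(seg)
        if t_obs > 0 and _split_significant(
            seg, t_obs, params.alpha, params.n_permutations, rng
        ):
            # arc interior yields three pieces; boundary arcs yield two.
            # push right-to-left so recursion order is left-to-right.
            pieces = [(lo, lo + i), (lo + i, lo + j), (lo + j, hi)]
            for a, b in reversed(pieces):
                if b > a:
                    stack.append((a, b))
        else:
            out.append((lo, hi))
    out.sort()
    return out


def segment_profile(profile, grid=None, params=None):
    """Partition ``profile`` into segments of expected equal copy number.

    Returns a :class:`SegmentSet` whose segments tile the usable observed
    bins; z_score and call are left unset (the abnormality stage fills
    them).  Each chromosome is processed independently.
    """
    grid = grid if grid is not None else profile.grid
    params = params or SegmentationParams()
    rng = np.random.default_rng(params.seed)
    segments = []
    observed = profile.observed
    for name in grid.chrom_names:
        cidx = grid.chrom_bins(name)
        use = cidx[observed[cidx]]
        if use.size == 0:
            continue
        x = np.ascontiguousarray(profile.ratios[use])
        for lo, hi in _segment_values(x, params, rng):
            bins = use[lo:hi]
            segments.append(_make_segment(grid, name, bins, x[lo:hi]))
    return SegmentSet(profile.sample_id, segments, modality=profile.modality)


def _make_segment(grid, chrom, bins, values):
    widths = grid.bin_sizes()[bins]
    return Segment(
        chromosome=chrom,
        start_bin=int(bins[0]),
        end_bin=int(bins[-1]),
        mean_ratio=float(np.mean(values)),
        length_bp=int(widths.sum()),
        n_bins=int(bins.size),
    )


def merge_adjacent(segset, grid, profile, tolerance=0.0):
    """Merge adjacent same-chromosome segments whose mean ratios differ by
    less than ``tolerance``; tiling is preserved.

    ``profile`` supplies bin values so merged means are recomputed from the
    underlying bins rather than averaged from the parts.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    merged = []
    for seg in segset.segments:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.chromosome == seg.chromosome
            and abs(prev.mean_ratio - seg.mean_ratio) < tolerance
        ):
            bins = np.arange(prev.start_bin, seg.end_bin + 1)
            bins = bins[profile.observed[bins]]
            merged[-1] = _make_segment(
                grid, seg.chromosome, bins, profile.ratios[bins]
            )
        else:
            merged.append(seg)
    return SegmentSet(segset.sample_id, merged, modality=segset.modality)
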