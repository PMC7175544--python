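"""Genome bin grid, per-sample copy-number profiles, control panels, and segments.

Copy number is represented on a fixed-width bin grid (default 100 kb).  Every
per-bin quantity downstream — log2 ratios, weights, discrete states — is a
vector aligned to one :class:`BinGrid`.  Bins are 0-based, half-open, sorted
by (chromosome order, start); the final bin of each chromosome is truncated
to the chromosome length.

Bins without reliable copy-number information (centromeres, zero-variance
panel bins) are *masked*: they carry weight 0 and are ignored by every
downstream operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BinGrid",
    "CopyNumberProfile",
    "ReferencePanel",
    "Segment",
    "SegmentSet",
    "UndeterminableSegmentError",
    "weighted_mean",
    "panel_bin_weights",
]


class UndeterminableSegmentError(ValueError):
    """Raised when a segment statistic cannot be formed (no usable bins, or
    zero spread across the control panel)."""


@dataclass(frozen=True)
class BinGrid:
    """Partition of a genome into fixed-width bins with mask and weights.

    Parameters
    ----------
    chrom_names, chrom_lengths
        Ordered chromosomes (name, length in bp).
    bin_width
        Bin width in bp (100,000 by default, matching shallow-WGS practice).
    chrom_index, start, end
        Per-bin chromosome index and half-open coordinates.
    mask
        Per-bin usability flag (``True`` = usable).
    weights
        Per-bin nonnegative weights for the weighted segment mean; masked
        bins have weight 0, usable bins weight > 0.
    arms
        Per-bin chromosome-arm label (e.g. ``"1p"``); used for arm-level
        event definitions and coefficient summaries.
    """

    chrom_names: tuple
    chrom_lengths: tuple
    bin_width: int
    chrom_index: np.ndarray
    start: np.ndarray
    end: np.ndarray
    mask: np.ndarray
    weights: np.ndarray
    arms: np.ndarray = field(repr=False, default=None)

    @classmethod
    def from_chromosomes(cls, chromosomes, bin_width=100_000, arm_split=0.4):
        """Build a grid from ``[(name, length_bp), ...]``.

        ``arm_split`` places the p/q boundary at that fraction of each
        chromosome (a stand-in for the centromere position).
        """
        names = tuple(str(n) for n, _ in chromosomes)
        lengths = tuple(int(l) for _, l in chromosomes)
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        ci, st, en, arm = [], [], [], []
        for k, (name, length) in enumerate(zip(names, lengths)):
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            edges = np.arange(0, length, bin_width, dtype=np.int64)
            ends = np.minimum(edges + bin_width, length)
            ci.append(np.full(edges.size, k))
            st.append(edges)
            en.append(ends)
            split = arm_split * length
            arm.append(np.where(edges < split, f"{name}p", f"{name}q"))
        n = int(sum(a.size for a in st))
        grid = cls(
            chrom_names=names,
            chrom_lengths=lengths,
            bin_width=int(bin_width),
            chrom_index=np.concatenate(ci),
            start=np.concatenate(st),
            end=np.concatenate(en),
            mask=np.ones(n, dtype=bool),
            weights=np.ones(n, dtype=float),
            arms=np.concatenate(arm),
        )
        grid.validate()
        return grid

    # -- basic geometry -------------------------------------------------
    @property
    def n_bins(self):
        return self.start.size

    @property
    def usable(self):
        """Boolean vector of usable bins (mask & weight > 0)."""
        return self.mask & (self.weights > 0)

    def chrom_bins(self, name):
        """Global bin indices belonging to chromosome ``name``."""
        k = self.chrom_names.index(name)
        return np.flatnonzero(self.chrom_index == k)

    def bin_sizes(self):
        return (self.end - self.start).astype(np.int64)

    def validate(self):
        n = self.n_bins
        for attr in ("chrom_index", "start", "end", "mask", "weights"):
            if getattr(self, attr).shape != (n,):
                raise ValueError(f"{attr} misaligned to grid")
        if np.any(self.end <= self.start):
            raise ValueError("empty or inverted bins")
        if np.any(self.weights < 0):
            raise ValueError("negative bin weight")
        if np.any(~self.mask & (self.weights != 0)):
            raise ValueError("masked bins must have weight 0")
        # sorted, non-overlapping, within chromosome
        for k, length in enumerate(self.chrom_lengths):
            idx = np.flatnonzero(self.chrom_index == k)
            if idx.size == 0:
                continue
            if np.any(np.diff(idx) != 1):
                raise ValueError("bins of one chromosome must be contiguous")
            s, e = self.start[idx], self.end[idx]
            if np.any(np.diff(s) <= 0) or np.any(s[1:] < e[:-1]):
                raise ValueError("bins overlap or are unsorted")
            if e[-1] > length:
                raise ValueError("bin exceeds chromosome length")
        return self

    def with_mask(self, mask):
        """Return a copy with ``mask`` applied; newly masked bins get weight 0."""
        mask = np.asarray(mask, dtype=bool)
        w = np.where(mask, self.weights, 0.0)
        return replace(self, mask=mask, weights=w).validate()

    def with_weights(self, weights):
        """Return a copy carrying ``weights``; zero-weight bins become masked."""
        w = np.asarray(weights, dtype=float)
        if w.shape != (self.n_bins,):
            raise ValueError("weights misaligned to grid")
        if np.any(w < 0) or not np.all(np.isfinite(w[self.mask])):
            raise ValueError("weights must be finite and nonnegative")
        mask = self.mask & (w > 0)
        return replace(self, mask=mask, weights=np.where(mask, w, 0.0)).validate()

    def compatible_with(self, other):
        return (
            self.chrom_names == other.chrom_names
            and self.bin_width == other.bin_width
            and self.n_bins == other.n_bins
            and np.array_equal(self.start, other.start)
        )


@dataclass
class CopyNumberProfile:
    """Per-bin log2 ratios (observed/expected coverage) for one sample.

    ``ratios`` holds NaN at masked or missing bins; downstream operations
    ignore those positions.  ``modality`` distinguishes liquid (cfDNA) from
    FFPE profiles, which are calibrated separately.
    """

    sample_id: str
    grid: BinGrid
    ratios: np.ndarray
    modality: str = "liquid"

    def __post_init__(self):
        self.ratios = np.asarray(self.ratios, dtype=float).copy()
        if self.ratios.shape != (self.grid.n_bins,):
            raise ValueError("profile misaligned to grid")
        self.ratios[~self.grid.usable] = np.nan
        bad = self.grid.usable & np.isinf(self.ratios)
        if np.any(bad):
            raise ValueError("non-finite ratio at usable bin")

    @property
    def missing(self):
        """Usable bins without a value in this sample."""
        return self.grid.usable & np.isnan(self.ratios)

    @property
    def observed(self):
        """Usable bins carrying a value."""
        return self.grid.usable & ~np.isnan(self.ratios)


@dataclass
class ReferencePanel:
    """Log2 ratios of ``p`` control samples, aligned to a grid.

    The panel supplies both the per-bin weights (reciprocal normal
    variability) and the denominator of the segmental Z-score: the spread
    of segment means across controls.
    """

    grid: BinGrid
    control_ratios: np.ndarray

    def __post_init__(self):
        self.control_ratios = np.asarray(self.control_ratios, dtype=float)
        if self.control_ratios.ndim != 2 or self.control_ratios.shape[1] != self.grid.n_bins:
            raise ValueError("panel misaligned to grid")
        if self.control_ratios.shape[0] < 2:
            raise ValueError("reference panel needs at least 2 controls")

    @property
    def p(self):
        return self.control_ratios.shape[0]

    def bin_sd(self):
        """Population (ddof=0) standard deviation across controls, per bin."""
        return self.control_ratios.std(axis=0, ddof=0)


def weighted_mean(values, weights, idx=None):
    """Weighted mean Σ w_i v_i / Σ w_i over usable, non-missing entries.

    NaN values are treated as missing and excluded together with their
    weights.  ``idx`` optionally restricts to a bin range (any index array
    or boolean mask).  Raises :class:`UndeterminableSegmentError` when no
    usable entry remains.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if idx is not None:
        v, w = v[idx], w[idx]
    keep = (w > 0) & ~np.isnan(v)
    if not np.any(keep):
        raise UndeterminableSegmentError("no usable bin in range")
    v, w = v[keep], w[keep]
    return float(np.dot(w, v) / w.sum())


def panel_bin_weights(panel):
    """Per-bin weights from a control panel: reciprocal of the population
    standard deviation of control ratios.

    Bins where the panel shows zero (or non-finite) spread carry no
    information about normal variability and are masked (weight 0).
    Returns a new :class:`BinGrid` carrying the weights, so case profiles
    and the panel share one grid object downstream.
    """
    sd = panel.bin_sd()
    # a spread at roundoff level of the ratio magnitudes is no information
    tiny = 1e-12 * np.maximum(1.0, np.abs(panel.control_ratios).max(axis=0))
    ok = sd > tiny
    with np.errstate(divide="ignore"):
        w = np.where(ok, 1.0 / np.where(ok, sd, 1.0), 0.0)
    w[~np.isfinite(w)] = 0.0
    w[~panel.grid.mask] = 0.0
    return panel.grid.with_weights(w)


@dataclass
class Segment:
    """A run of bins of expected equal copy number on one chromosome.

    ``start_bin``/``end_bin`` are inclusive global bin indices.
    ``length_bp`` is the summed width of the usable bins covered (the l_i of
    the CPA score).  ``z_score`` and ``call`` are set by the abnormality
    stage; ``determinable`` is False when the panel spread over the segment
    is zero, in which case the segment is dropped from the CPA.
    """

    chromosome: str
    start_bin: int
    end_bin: int
    mean_ratio: float
    length_bp: int
    n_bins: int
    z_score: float = float("nan")
    call: str = "unset"
    determinable: bool = True

    def __post_init__(self):
        if self.end_bin < self.start_bin:
            raise ValueError("inverted segment")

    def bin_slice(self):
        return slice(self.start_bin, self.end_bin + 1)


@dataclass
class SegmentSet:
    """Ordered segments tiling every usable bin of one sample exactly once."""

    sample_id: str
    segments: list
    modality: str = "liquid"

    @property
    def n_segments(self):
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __len__(self):
        return len(self.segments)

    def validate_tiling(self, grid):
        """Check that segments cover each usable bin exactly once."""
        covered = np.zeros(grid.n_bins, dtype=int)
        for s in self.segments:
            sl = s.bin_slice()
            covered[sl] += grid.usable[sl]
        usable = grid.usable
        if not np.all(covered[usable] == 1) or np.any(covered[~usable] > 0):
            raise ValueError("segments do not tile usable bins exactly once")
        return self
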