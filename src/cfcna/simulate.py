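"""Synthetic cfDNA cohort generator.

Generates everything the analysis consumes: control reference panels,
subtype-fingerprinted tumor profiles with ground-truth segmentation,
array-style training tables of segmental continuous copy-number states,
and fragment-size-annotated read records.

The generative model: a sample with tumor fraction f carrying k copies of a
region shifts that region's log2 ratio to log2((2(1-f) + k f) / 2); per-bin
Gaussian noise with bin-specific standard deviations (drawn once per
cohort) is added on top.  Fragment lengths follow a two-component Gaussian
mixture in which tumor-derived fragments are shorter.

The default genome is a reduced synthetic one: the 22 human autosomes
scaled to ~2,900 usable 100 kb bins in total, with a masked centromeric
band per chromosome.  ``scale=1.0`` restores full autosome lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import BinGrid, CopyNumberProfile, ReferencePanel, Segment, SegmentSet
from .genome import panel_bin_weights

__all__ = [
    "AUTOSOME_LENGTHS_BP",
    "FingerprintEvent",
    "SubtypeFingerprint",
    "FragmentModel",
    "CohortConfig",
    "SyntheticCohort",
    "default_grid",
    "default_fingerprints",
    "expected_log2_ratio",
    "draw_bin_sds",
    "simulate_panel",
    "simulate_case",
    "simulate_training_table",
    "simulate_fragments",
]

# GRCh38 autosome lengths (bp)
AUTOSOME_LENGTHS_BP = {
    "1": 248_956_422, "2": 242_193_529, "3": 198_295_559, "4": 190_214_555,
    "5": 181_538_259, "6": 170_805_979, "7": 159_345_973, "8": 145_138_636,
    "9": 138_394_717, "10": 133_797_422, "11": 135_086_622, "12": 133_275_309,
    "13": 114_364_328, "14": 107_043_718, "15": 101_991_189, "16": 90_338_345,
    "17": 83_257_441, "18": 80_373_285, "19": 58_617_616, "20": 64_444_167,
    "21": 46_709_983, "22": 50_818_468,
}


def default_grid(scale=0.1, bin_width=100_000, arm_split=0.4,
                 centromere_frac=0.05):
    """Reduced synthetic autosome grid.

    ``scale`` shrinks every chromosome (0.1 -> ~2,900 bins); a band of
    ``centromere_frac`` of each chromosome, centred at the arm boundary, is
    masked as undeterminable (the centromere stand-in).  Sex chromosomes
    are excluded to avoid constitutional-copy modelling.
    """
    chroms = [(name, max(int(l * scale), 3 * bin_width))
              for name, l in AUTOSOME_LENGTHS_BP.items()]
    grid = BinGrid.from_chromosomes(chroms, bin_width=bin_width,
                                    arm_split=arm_split)
    mask = grid.mask.copy()
    for name, length in zip(grid.chrom_names, grid.chrom_lengths):
        idx = grid.chrom_bins(name)
        centre = arm_split * length
        half = centromere_frac * length / 2
        mid = grid.start[idx] + grid.bin_sizes()[idx] / 2
        mask[idx[(mid > centre - half) & (mid < centre + half)]] = False
    return grid.with_mask(mask)


@dataclass(frozen=True)
class FingerprintEvent:
    """One recurrent aberration of a subtype.

    region
        Chromosome-arm label (``"3p"``), a chromosome name (whole
        chromosome), or an explicit global bin range ``(lo, hi)``
        (half-open).
    direction
        ``"gain"`` or ``"loss"``.
    penetrance
        Probability that a case of the subtype carries the event.
    copies
        Tumor copy number when realized; defaults 3 for gains and 1 for
        losses, an amplification is modelled by passing e.g. copies=6.
    """

    region: object
    direction: str
    penetrance: float
    copies: int | None = None

    def __post_init__(self):
        if self.direction not in ("gain", "loss"):
            raise ValueError("direction must be gain or loss")
        if not 0 <= self.penetrance <= 1:
            raise ValueError("penetrance must lie in [0, 1]")

    def tumor_copies(self):
        if self.copies is not None:
            return self.copies
        return 3 if self.direction == "gain" else 1

    def bins(self, grid):
        if isinstance(self.region, tuple):
            lo, hi = self.region
            return np.arange(lo, hi)
        region = str(self.region)
        if region in grid.chrom_names:
            return grid.chrom_bins(region)
        hit = np.flatnonzero(grid.arms == region)
        if hit.size == 0:
            raise ValueError(f"region {region!r} not on grid")
        return hit


@dataclass(frozen=True)
class SubtypeFingerprint:
    """Recurrent copy-number aberrations of one histological subtype."""

    class_label: str
    events: tuple

    def with_penetrance(self, penetrance):
        """Copy with every event's penetrance overridden (study-condition
        knob for separability experiments)."""
        return replace(
            self,
            events=tuple(replace(e, penetrance=penetrance) for e in self.events),
        )


def default_fingerprints():
    """Qualitative subtype fingerprints over the discriminative arms.

    Encodes the discriminative pattern of lung-cancer copy-number profiles:
    1p and 9p gained in SCLC but lost in NSCLC, 3p lost most often in SCLC,
    5p gains shared by all subtypes, 3q gain marking LUSC, 19p loss marking
    LUAD, chromosome 22 loss enriched in SCLC.  Penetrances are qualitative
    defaults, not measured values.
    """
    return {
        "LUAD": SubtypeFingerprint("LUAD", (
            FingerprintEvent("1p", "loss", 0.5),
            FingerprintEvent("9p", "loss", 0.5),
            FingerprintEvent("5p", "gain", 0.6),
            FingerprintEvent("19p", "loss", 0.6),
            FingerprintEvent("8q", "gain", 0.5),
            FingerprintEvent("14q", "loss", 0.4),
        )),
        "LUSC": SubtypeFingerprint("LUSC", (
            FingerprintEvent("3q", "gain", 0.8),
            FingerprintEvent("3p", "loss", 0.7),
            FingerprintEvent("9p", "loss", 0.5),
            FingerprintEvent("5p", "gain", 0.7),
            FingerprintEvent("8q", "gain", 0.5),
            FingerprintEvent("22", "loss", 0.4),
        )),
        "SCLC": SubtypeFingerprint("SCLC", (
            FingerprintEvent("1p", "gain", 0.7),
            FingerprintEvent("9p", "gain", 0.6),
            FingerprintEvent("3p", "loss", 0.9),
            FingerprintEvent("5p", "gain", 0.8),
            FingerprintEvent("16q", "loss", 0.5),
            FingerprintEvent("22", "loss", 0.6),
        )),
    }


@dataclass(frozen=True)
class FragmentModel:
    """Two-component Gaussian insert-size mixture (bp).

    Normal cfDNA centres at the mononucleosomal ~167 bp; tumor-derived
    fragments run shorter and broader.
    """

    normal_mean: float = 167.0
    normal_sd: float = 12.0
    tumor_mean: float = 145.0
    tumor_sd: float = 25.0

    def __post_init__(self):
        for v in (self.normal_mean, self.normal_sd, self.tumor_mean, self.tumor_sd):
            if v <= 0:
                raise ValueError("fragment model parameters must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a synthetic cohort."""

    n_controls: int = 200
    n_cases_per_class: int = 20
    tumor_fraction_range: tuple = (0.1, 0.6)
    bin_noise_sd_range: tuple = (0.04, 0.12)
    seed: int = 0
    scale: float = 0.1
    fragment_model: FragmentModel = field(default_factory=FragmentModel)

    def __post_init__(self):
        lo, hi = self.tumor_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("tumor fractions must lie in [0, 1]")
        lo, hi = self.bin_noise_sd_range
        if not (0 < lo <= hi):
            raise ValueError("noise sds must be positive")


def expected_log2_ratio(tumor_fraction, copies):
    """log2 ratio of a region at ``copies`` tumor copies and fraction f:
    log2((2(1-f) + copies*f) / 2).

    Returns -inf for a complete loss (copies=0 at f=1).
    """
    f = float(tumor_fraction)
    if not 0 <= f <= 1:
        raise ValueError("tumor fraction must lie in [0, 1]")
    if copies < 0:
        raise ValueError("copies must be nonnegative")
    mix = 2 * (1 - f) + copies * f
    if mix == 0:
        return float("-inf")
    return float(np.log2(mix / 2))


def draw_bin_sds(grid, sd_range, rng):
    """Bin-specific noise SDs, drawn once per cohort, fixed across samples."""
    lo, hi = sd_range
    return rng.uniform(lo, hi, grid.n_bins)


def simulate_panel(grid, n_controls, bin_sds, rng):
    """Control panel: per-bin ratios ~ Normal(0, sd_i)."""
    if n_controls < 2:
        raise ValueError("need at least 2 controls")
    ratios = rng.standard_normal((n_controls, grid.n_bins)) * bin_sds
    return ReferencePanel(grid, ratios)


def _expected_profile(grid, fingerprint, tumor_fraction, rng, penetrance=None):
    """Per-bin expected log2 ratio after realizing each event with its
    penetrance; overlapping events: the last realized event wins."""
    expect = np.zeros(grid.n_bins)
    if fingerprint is not None:
        for ev in fingerprint.events:
            pen = ev.penetrance if penetrance is None else penetrance
            if rng.random() < pen:
                expect[ev.bins(grid)] = expected_log2_ratio(
                    tumor_fraction, ev.tumor_copies()
                )
    return expect


def _truth_segments(grid, expect, sample_id, modality="liquid"):
    """Segment the noiseless expectation: maximal constant runs of usable
    bins per chromosome."""
    segments = []
    widths = grid.bin_sizes()
    usable = grid.usable
    for name in grid.chrom_names:
        idx = grid.chrom_bins(name)
        idx = idx[usable[idx]]
        if idx.size == 0:
            continue
        vals = expect[idx]
        breaks = np.flatnonzero(np.diff(vals) != 0) + 1
        for part in np.split(np.arange(idx.size), breaks):
            bins = idx[part]
            segments.append(Segment(
                chromosome=name,
                start_bin=int(bins[0]),
                end_bin=int(bins[-1]),
                mean_ratio=float(vals[part[0]]),
                length_bp=int(widths[bins].sum()),
                n_bins=int(bins.size),
            ))
    return SegmentSet(sample_id, segments, modality=modality)


def simulate_case(grid, fingerprint, tumor_fraction, bin_sds, rng,
                  sample_id="case", penetrance=None, noise=None):
    """One case profile plus its ground-truth segmentation.

    ``noise`` optionally injects a pre-drawn standard-normal vector so that
    a tumor-fraction sweep can reuse identical noise (paired seeds).
    """
    expect = _expected_profile(grid, fingerprint, tumor_fraction, rng, penetrance)
    if noise is None:
        noise = rng.standard_normal(grid.n_bins)
    ratios = expect + noise * bin_sds
    profile = CopyNumberProfile(sample_id, grid, ratios)
    return profile, _truth_segments(grid, expect, sample_id)


def simulate_training_table(grid, fingerprints, n_per_class, rng,
                            tumor_fraction_range=(0.3, 0.9), penetrance=None,
                            segment_noise_sd=0.03, label_order=None):
    """Array-style training table: per-bin segmental *continuous* states.

    Each sample realizes its subtype's events, takes the noiseless expected
    log2 ratio per truth segment, and adds one Gaussian perturbation per
    segment (array data is segmental, so noise is shared within a segment).
    Returns ``(states, labels, sample_ids)`` with ``states`` of shape
    (n_samples, n_bins); masked bins hold NaN.
    """
    labels_order = label_order or sorted(fingerprints)
    rows, labels, ids = [], [], []
    lo, hi = tumor_fraction_range
    for label in labels_order:
        fp = fingerprints[label]
        for i in range(n_per_class):
            f = rng.uniform(lo, hi)
            expect = _expected_profile(grid, fp, f, rng, penetrance)
            truth = _truth_segments(grid, expect, f"{label}_{i}")
            row = np.full(grid.n_bins, np.nan)
            for seg in truth.segments:
                sl = seg.bin_slice()
                row[sl] = seg.mean_ratio + rng.normal(0, segment_noise_sd)
            row[~grid.usable] = np.nan
            rows.append(row)
            labels.append(label)
            ids.append(f"{label}_{i}")
    return np.array(rows), np.array(labels), ids


def simulate_fragments(n_reads, tumor_fraction, copy_state, grid,
                       fragment_model, rng):
    """Fragment-size-annotated read records.

    Reads land in a bin proportionally to its total DNA content
    2(1-f) + c_b f; each read is tumor-derived with probability
    c_b f / (2(1-f) + c_b f) and draws its insert size from the matching
    mixture component (rounded to integer bp, floored at 1).  Returns a
    DataFrame with columns bin_index, insert_size, origin.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    f = float(tumor_fraction)
    usable = np.flatnonzero(grid.usable)
    c = np.asarray(copy_state, dtype=float)[usable]
    content = 2 * (1 - f) + c * f
    if content.sum() <= 0:
        raise ValueError("no DNA content on usable bins")
    bins = rng.choice(usable, size=n_reads, p=content / content.sum())
    c_read = np.asarray(copy_state, dtype=float)[bins]
    p_tumor = np.where(c_read * f > 0,
                       c_read * f / (2 * (1 - f) + c_read * f), 0.0)
    tumor = rng.random(n_reads) < p_tumor
    m = fragment_model
    size = np.where(
        tumor,
        rng.normal(m.tumor_mean, m.tumor_sd, n_reads),
        rng.normal(m.normal_mean, m.normal_sd, n_reads),
    )
    size = np.maximum(np.rint(size).astype(int), 1)
    return pd.DataFrame({
        "bin_index": bins,
        "insert_size": size,
        "origin": np.where(tumor, "tumor", "normal"),
    })


class SyntheticCohort:
    """One reproducible synthetic study: shared grid, bin noise, panel.

    All randomness descends from ``config.seed`` via independent spawned
    streams, so any product (panel, a given case, the training table) is
    bit-identical across runs of the same config.
    """

    def __init__(self, config=None):
        self.config = config or CohortConfig()
        ss = np.random.SeedSequence(self.config.seed)
        keys = ("sds", "panel", "controls", "cases", "training", "fragments")
        self._rng = {k: np.random.default_rng(s)
                     for k, s in zip(keys, ss.spawn(len(keys)))}
        base = default_grid(scale=self.config.scale)
        self.bin_sds = draw_bin_sds(base, self.config.bin_noise_sd_range,
                                    self._rng["sds"])
        self.panel = simulate_panel(base, self.config.n_controls,
                                    self.bin_sds, self._rng["panel"])
        # weights derive from the panel; share the weighted grid everywhere
        self.grid = panel_bin_weights(self.panel)
        self.panel = ReferencePanel(self.grid, self.panel.control_ratios)
        self.fingerprints = default_fingerprints()

    def control_profile(self, sample_id="control"):
        """A held-out healthy sample (tumor fraction 0)."""
        profile, _ = simulate_case(self.grid, None, 0.0, self.bin_sds,
                                   self._rng["controls"], sample_id)
        return profile

    def case(self, class_label, tumor_fraction=None, sample_id=None,
             penetrance=None, noise=None):
        rng = self._rng["cases"]
        if tumor_fraction is None:
            lo, hi = self.config.tumor_fraction_range
            tumor_fraction = rng.uniform(lo, hi)
        sample_id = sample_id or f"{class_label}_case"
        return simulate_case(self.grid, self.fingerprints[class_label],
                             tumor_fraction, self.bin_sds, rng, sample_id,
                             penetrance=penetrance, noise=noise)

    def training_table(self, n_per_class=68, **kw):
        return simulate_training_table(self.grid, self.fingerprints,
                                       n_per_class, self._rng["training"], **kw)

    def fragments(self, n_reads, tumor_fraction, copy_state):
        return simulate_fragments(n_reads, tumor_fraction, copy_state,
                                  self.grid, self.config.fragment_model,
                                  self._rng["fragments"])
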