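"""Paired solid/liquid profile comparison and cohort-level aberration waves.

Profiles are compared after a centred moving-average smoothing (window of
100 bins by default, shrunk at chromosome edges, never crossing a
chromosome).  Pairwise agreement is quantified by the Pearson correlation
and a total-least-squares slope (first principal axis of the centred
scatter; slope > 1 means the second profile's amplitudes exceed the
first's, i.e. a higher tumor fraction there).

Cohort groups are summarized as aberration-frequency waves (%gain and
%loss per bin) and clustered by complete linkage on the Pearson distance
d = (1 - r)/2 of the signed waves (%gain - %loss).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "SmoothedProfile",
    "FrequencyWave",
    "smooth_profile",
    "profile_pearson",
    "tls_slope",
    "weighted_group_summary",
    "aberration_frequency_waves",
    "cluster_groups",
    "interval_weight",
    "overlap_plot",
    "correlation_scatter_plot",
]


@dataclass
class SmoothedProfile:
    """Per-bin smoothed log2 ratios; NaN at masked/missing bins."""

    sample_id: str
    values: np.ndarray
    window: int


def smooth_profile(profile, window=100):
    """Centred moving average over usable bins, per chromosome.

    The window shrinks to the available bins near chromosome edges and
    never crosses a chromosome boundary; masked/missing bins neither
    contribute nor receive a value.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    grid = profile.grid
    out = np.full(grid.n_bins, np.nan)
    observed = profile.observed
    for name in grid.chrom_names:
        idx = grid.chrom_bins(name)
        idx = idx[observed[idx]]
        if idx.size == 0:
            continue
        s = pd.Series(profile.ratios[idx])
        out[idx] = s.rolling(window, center=True, min_periods=1).mean().to_numpy()
    return SmoothedProfile(profile.sample_id, out, window)


def _common(a, b, min_bins=30):
    va = a.values if isinstance(a, SmoothedProfile) else np.asarray(a, float)
    vb = b.values if isinstance(b, SmoothedProfile) else np.asarray(b, float)
    keep = ~np.isnan(va) & ~np.isnan(vb)
    if keep.sum() < min_bins:
        raise ValueError(f"fewer than {min_bins} common usable bins")
    return va[keep], vb[keep]


def profile_pearson(smooth_a, smooth_b, min_bins=30):
    """Pearson r over the common usable bins of two smoothed profiles."""
    va, vb = _common(smooth_a, smooth_b, min_bins)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(stats.pearsonr(va, vb)[0])


def tls_slope(smooth_a, smooth_b, min_bins=30):
    """Total-least-squares slope: first principal axis of the centred
    scatter (B against A)."""
    va, vb = _common(smooth_a, smooth_b, min_bins)
    xy = np.column_stack([va - va.mean(), vb - vb.mean()])
    cov = xy.T @ xy
    if not np.all(np.isfinite(cov)) or np.allclose(cov, 0):
        raise ValueError("degenerate scatter; slope undefined")
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    if axis[0] == 0:
        raise ValueError("vertical principal axis; slope undefined")
    return float(axis[1] / axis[0])


def weighted_group_summary(values, weights=None):
    """Weighted mean with a normal-approximation 95% CI using the effective
    sample size (Sum w)^2 / Sum w^2."""
    v = np.asarray(values, dtype=float)
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be nonnegative and not all zero")
    mean = float(np.average(v, weights=w))
    n_eff = float(w.sum() ** 2 / np.sum(w ** 2))
    if n_eff <= 1:
        warnings.warn("effective sample size <= 1; degenerate CI")
        return {"mean": mean, "ci_low": mean, "ci_high": mean,
                "se": 0.0, "n_eff": n_eff, "degenerate": True}
    var = float(np.average((v - mean) ** 2, weights=w)) * n_eff / (n_eff - 1)
    se = float(np.sqrt(var / n_eff))
    z = stats.norm.ppf(0.975)
    return {"mean": mean, "ci_low": mean - z * se, "ci_high": mean + z * se,
            "se": se, "n_eff": n_eff, "degenerate": False}


def interval_weight(days):
    """Dot weight for paired-biopsy summaries: w = 1/(1 + days)^2,
    down-weighting pairs separated by long intervals (interval time acts
    as a confounder of solid/liquid agreement)."""
    days = np.asarray(days, dtype=float)
    if np.any(days < 0):
        raise ValueError("interval days must be nonnegative")
    return 1.0 / (1.0 + days) ** 2


@dataclass
class FrequencyWave:
    """Per-bin %gain and %loss across one sample group."""

    group: str
    pct_gain: np.ndarray
    pct_loss: np.ndarray
    n_samples: int

    @property
    def signed(self):
        """%gain - %loss; the wave vector used for clustering."""
        return self.pct_gain - self.pct_loss


def aberration_frequency_waves(call_sets_by_group, grid):
    """Per-bin share (%) of samples called gain / loss, per group."""
    waves = {}
    for group, segsets in call_sets_by_group.items():
        if not segsets:
            raise ValueError(f"group {group!r} has no samples")
        gain = np.zeros(grid.n_bins)
        loss = np.zeros(grid.n_bins)
        for segset in segsets:
            for seg in segset.segments:
                if seg.call == "gain":
                    gain[seg.bin_slice()] += 1
                elif seg.call == "loss":
                    loss[seg.bin_slice()] += 1
        n = len(segsets)
        gain *= 100.0 / n
        loss *= 100.0 / n
        gain[~grid.usable] = np.nan
        loss[~grid.usable] = np.nan
        waves[group] = FrequencyWave(group, gain, loss, n)
    return waves


def cluster_groups(waves):
    """Complete-linkage tree over Pearson distances d = (1 - r)/2 between
    the groups' signed waves.

    Constant waves have undefined correlation and are dropped with a
    warning.  Returns ``(linkage_matrix, kept_group_names)``.
    """
    names, vecs = [], []
    for name, wave in waves.items():
        v = wave.signed if isinstance(wave, FrequencyWave) else np.asarray(wave, float)
        v = v[~np.isnan(v)]
        if v.std() == 0:
            warnings.warn(f"group {name!r} has a constant wave; dropped")
            continue
        names.append(name)
        vecs.append(v)
    if len(names) < 2:
        raise ValueError("need at least 2 clusterable groups")
    r = np.corrcoef(np.array(vecs))
    d = (1 - r) / 2
    np.fill_diagonal(d, 0.0)
    link = linkage(squareform(d, checks=False), method="complete")
    return link, names


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def overlap_plot(smooth_a, smooth_b, path=None, labels=("A", "B")):
    """Overlaid smoothed profiles (the Fig.-1b-style overlap view)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(smooth_a.values, lw=1, label=labels[0])
    ax.plot(smooth_b.values, lw=1, label=labels[1])
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("bin")
    ax.set_ylabel("smoothed log2 ratio")
    ax.legend()
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def correlation_scatter_plot(smooth_a, smooth_b, path=None):
    """Scatter of smoothed values with identity and TLS lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    va, vb = _common(smooth_a, smooth_b)
    r = profile_pearson(smooth_a, smooth_b)
    slope = tls_slope(smooth_a, smooth_b)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(va, vb, s=4, alpha=0.5)
    lim = np.nanmax(np.abs(np.concatenate([va, vb]))) * 1.1
    xs = np.linspace(-lim, lim, 2)
    ax.plot(xs, xs, "k-", lw=1, label="identity")
    ax.plot(xs, vb.mean() + slope * (xs - va.mean()), "k--", lw=1,
            label=f"TLS slope {slope:.2f}")
    ax.set_title(f"r = {r:.3f}")
    ax.legend()
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def dendrogram_plot(link, names, path=None):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    dendrogram(link, labels=names, ax=ax)
    ax.set_ylabel("complete-linkage distance")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
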