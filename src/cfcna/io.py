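"""Readers and writers for the pipeline's tab-delimited table formats.

Dialects (all tab-delimited, with header):

* bin-ratio table   — ``chrom  start  end  ratio`` (empty ratio = masked/missing)
* grid/weights file — ``chrom  start  end  mask  weight`` (+ optional ``arm``)
* segment BED       — ``chrom  start  end  mean_ratio  n_bins`` (+ optional
  ``z_score  call``)
* feature matrix    — samples x bins with a sidecar label file
* read records      — ``bin_index  insert_size  origin``
* CPA report        — ``sample_id  modality  n_segments  cpa  cutoff  abnormal``
* config / manifest — plain-text ``key = value``

All round-trips are lossless (floats written with repr precision).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import BinGrid, CopyNumberProfile, Segment, SegmentSet

__all__ = [
    "write_profile", "read_profile",
    "write_grid", "read_grid",
    "write_segments", "read_segments",
    "write_feature_matrix", "read_feature_matrix",
    "write_reads", "read_reads",
    "write_cpa_report",
    "write_config", "read_config",
]

_FLOAT = "%.17g"


def _check_header(path, expected, got):
    if list(got) != list(expected):
        raise ValueError(
            f"{path}: header mismatch, expected {expected}, got {list(got)}"
        )


def write_profile(profile, path):
    grid = profile.grid
    ratio = np.array([
        "" if np.isnan(r) else _FLOAT % r for r in profile.ratios
    ], dtype=object)
    df = pd.DataFrame({
        "chrom": [grid.chrom_names[k] for k in grid.chrom_index],
        "start": grid.start, "end": grid.end, "ratio": ratio,
    })
    df.to_csv(path, sep="\t", index=False)


def read_profile(path, grid, sample_id=None, modality="liquid"):
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     float_precision="round_trip")
    _check_header(path, ["chrom", "start", "end", "ratio"], df.columns)
    if len(df) != grid.n_bins or not np.array_equal(df["start"].to_numpy(),
                                                    grid.start):
        raise ValueError(f"{path}: bins do not match the grid")
    ratios = df["ratio"].to_numpy(dtype=float)
    name = sample_id or str(path)
    return CopyNumberProfile(name, grid, ratios, modality=modality)


def write_grid(grid, path):
    df = pd.DataFrame({
        "chrom": [grid.chrom_names[k] for k in grid.chrom_index],
        "start": grid.start, "end": grid.end,
        "mask": grid.mask.astype(int),
        "weight": [_FLOAT % w for w in grid.weights],
        "arm": grid.arms,
    })
    df.to_csv(path, sep="\t", index=False)


def read_grid(path):
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     float_precision="round_trip")
    cols = list(df.columns)
    if cols not in (["chrom", "start", "end", "mask", "weight"],
                    ["chrom", "start", "end", "mask", "weight", "arm"]):
        raise ValueError(f"{path}: unexpected grid header {cols}")
    names = list(dict.fromkeys(df["chrom"]))
    lengths = [int(df.loc[df["chrom"] == n, "end"].max()) for n in names]
    starts = df["start"].to_numpy(dtype=np.int64)
    widths = (df["end"] - df["start"]).to_numpy()
    bin_width = int(widths.max())
    chrom_index = np.array([names.index(c) for c in df["chrom"]])
    arms = (df["arm"].to_numpy(dtype=object) if "arm" in df
            else np.array([f"{c}p" for c in df["chrom"]], dtype=object))
    grid = BinGrid(
        chrom_names=tuple(names), chrom_lengths=tuple(lengths),
        bin_width=bin_width, chrom_index=chrom_index,
        start=starts, end=df["end"].to_numpy(dtype=np.int64),
        mask=df["mask"].to_numpy(dtype=bool),
        weights=df["weight"].to_numpy(dtype=float),
        arms=arms,
    )
    return grid.validate()


def write_segments(segset, grid, path, annotated=False):
    rows = []
    for s in segset.segments:
        row = {
            "chrom": s.chromosome,
            "start": int(grid.start[s.start_bin]),
            "end": int(grid.end[s.end_bin]),
            "mean_ratio": _FLOAT % s.mean_ratio,
            "n_bins": s.n_bins,
        }
        if annotated:
            row["z_score"] = "" if np.isnan(s.z_score) else _FLOAT % s.z_score
            row["call"] = s.call
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_segments(path, grid, sample_id="sample", modality="liquid"):
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     float_precision="round_trip")
    base = ["chrom", "start", "end", "mean_ratio", "n_bins"]
    annotated = list(df.columns) == base + ["z_score", "call"]
    if not annotated:
        _check_header(path, base, df.columns)
    widths = grid.bin_sizes()
    segments = []
    for i, row in df.iterrows():
        cidx = grid.chrom_bins(row["chrom"])
        inside = cidx[(grid.start[cidx] >= row["start"]) &
                      (grid.end[cidx] <= row["end"])]
        if inside.size == 0:
            raise ValueError(f"{path}: line {i + 2}: segment covers no bin")
        usable = inside[grid.usable[inside]]
        seg = Segment(
            chromosome=str(row["chrom"]),
            start_bin=int(inside[0]), end_bin=int(inside[-1]),
            mean_ratio=float(row["mean_ratio"]),
            length_bp=int(widths[usable].sum()),
            n_bins=int(row["n_bins"]),
        )
        if annotated:
            z = row["z_score"]
            seg.z_score = float(z) if pd.notna(z) and z != "" else float("nan")
            seg.call = str(row["call"])
            seg.determinable = np.isfinite(seg.z_score)
        segments.append(seg)
    return SegmentSet(sample_id, segments, modality=modality)


def write_feature_matrix(fm, prefix):
    df = pd.DataFrame(fm.X, index=fm.sample_ids,
                      columns=[f"bin_{b}" for b in fm.bin_indices])
    df.index.name = "sample_id"
    df.to_csv(f"{prefix}.features.tsv", sep="\t")
    lab = pd.DataFrame({
        "sample_id": fm.sample_ids,
        "label": fm.labels if fm.labels is not None else [""] * fm.n_samples,
    })
    lab.to_csv(f"{prefix}.labels.tsv", sep="\t", index=False)


def read_feature_matrix(prefix):
    from .classification import FeatureMatrix

    df = pd.read_csv(f"{prefix}.features.tsv", sep="\t", index_col="sample_id")
    lab = pd.read_csv(f"{prefix}.labels.tsv", sep="\t", dtype={"label": str})
    bins = np.array([int(c.split("_", 1)[1]) for c in df.columns])
    labels = lab["label"].to_numpy()
    if np.all(pd.isna(labels)) or np.all(labels == ""):
        labels = None
    return FeatureMatrix(X=df.to_numpy(), labels=labels,
                         sample_ids=list(df.index), bin_indices=bins)


def write_reads(reads, path):
    reads[["bin_index", "insert_size", "origin"]].to_csv(
        path, sep="\t", index=False)


def read_reads(path):
    df = pd.read_csv(path, sep="\t", dtype={"origin": str})
    _check_header(path, ["bin_index", "insert_size", "origin"], df.columns)
    return df


def write_cpa_report(results, calibration, path):
    rows = [{
        "sample_id": r.sample_id, "modality": r.modality,
        "n_segments": r.n_segments, "cpa": _FLOAT % r.cpa,
        "cutoff": _FLOAT % calibration.cutoff,
        "abnormal": "" if r.abnormal is None else int(r.abnormal),
    } for r in results]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_config(mapping, path):
    with open(path, "w") as fh:
        for k, v in mapping.items():
            fh.write(f"{k} = {v}\n")


def read_config(path):
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key = value")
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out
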