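"""Readers and writers for the plain-text formats the pipelines exchange.

Conventions
-----------
* Expression / time-course TSV: rows = genes (first column ``gene_id``),
  remaining columns = sample ids, log2 values.
* Clinical TSV: columns ``sample_id``, ``time``, ``event`` (0/1) and an
  optional ``er_status``.
* CNV TSV: rows = samples (first column ``sample_id``), columns = genes,
  integer states in {-2, -1, 0, 1}.
* Gene annotation TSV: ``gene_id``, ``chrom``, ``tss`` (1-based), ``strand``
  in {+, -}.  The TSS is converted to 0-based on load.
* bedGraph: 0-based half-open intervals; overlapping or inverted intervals
  are rejected.

All parsers raise on malformed input rather than coercing silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_clinical_tsv",
    "write_clinical_tsv",
    "read_cnv_tsv",
    "write_cnv_tsv",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_bedgraph",
    "write_bedgraph",
    "CoverageTrack",
    "read_json",
    "write_json",
]


# ---------------------------------------------------------------------------
# tabular formats
# ---------------------------------------------------------------------------

def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got {df.index.name!r}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated gene ids {dup}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc
    if not np.isfinite(values.to_numpy()).all():
        bad = np.argwhere(~np.isfinite(values.to_numpy()))[0]
        raise ValueError(
            f"{path}: non-finite value at row {values.index[bad[0]]!r}, "
            f"column {values.columns[bad[1]]!r}")
    return values


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_clinical_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: clinical table needs columns {sorted(required)}")
    df = df.set_index("sample_id")
    if (df["time"] < 0).any():
        raise ValueError(f"{path}: negative follow-up time")
    if not df["event"].isin((0, 1)).all():
        raise ValueError(f"{path}: event must be 0 or 1")
    return df


def write_clinical_tsv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_cnv_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id'")
    vals = df.to_numpy()
    if not np.isin(vals, (-2, -1, 0, 1)).all():
        raise ValueError(f"{path}: copy-number states must be in {{-2,-1,0,1}}")
    return df.astype(int)


def write_cnv_tsv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_annotation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation needs columns {sorted(required)}")
    if not df["strand"].isin(("+", "-")).all():
        raise ValueError(f"{path}: strand must be '+' or '-'")
    if (df["tss"] < 1).any():
        raise ValueError(f"{path}: tss is 1-based and must be >= 1")
    df = df.set_index("gene_id")
    df["tss0"] = df["tss"].astype(int) - 1  # 0-based position
    return df


def write_annotation_tsv(df: pd.DataFrame, path) -> None:
    out = df.reset_index()[["gene_id", "chrom", "tss", "strand"]]
    out.to_csv(path, sep="\t", index=False)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# bedGraph-backed coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """Sparse per-contig coverage with 0-based half-open intervals.

    Gaps between intervals count as zero coverage.
    """

    intervals: dict  # contig -> (starts, ends, values) sorted ascending

    @classmethod
    def from_arrays(cls, chroms, starts, ends, values) -> "CoverageTrack":
        chroms = np.asarray(chroms)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        if np.any(ends <= starts):
            i = int(np.argmax(ends <= starts))
            raise ValueError(f"interval end <= start at record {i}: "
                             f"{chroms[i]}:{starts[i]}-{ends[i]}")
        out = {}
        for contig in pd.unique(chroms):
            sel = chroms == contig
            s, e, v = starts[sel], ends[sel], values[sel]
            order = np.argsort(s, kind="stable")
            s, e, v = s[order], e[order], v[order]
            if np.any(s[1:] < e[:-1]):
                i = int(np.argmax(s[1:] < e[:-1]))
                raise ValueError(
                    f"overlapping intervals on {contig} near position {s[i + 1]}")
            out[str(contig)] = (s, e, v)
        return cls(intervals=out)

    def span(self, contig: str) -> tuple[int, int]:
        s, e, _ = self.intervals[contig]
        return int(s[0]), int(e[-1])

    def total_mass(self) -> float:
        return float(sum(((e - s) * v).sum() for s, e, v in self.intervals.values()))

    def total_span(self) -> int:
        return int(sum(e[-1] - s[0] for s, e, _ in self.intervals.values()))

    def mean(self, contig: str, start: int, end: int) -> float:
        """Mean coverage over [start, end), gaps counting as zero."""
        if end <= start:
            raise ValueError("end must exceed start")
        if contig not in self.intervals:
            return 0.0
        s, e, v = self.intervals[contig]
        lo = np.searchsorted(e, start, side="right")
        hi = np.searchsorted(s, end, side="left")
        if lo >= hi:
            return 0.0
        ov = np.minimum(e[lo:hi], end) - np.maximum(s[lo:hi], start)
        return float((ov * v[lo:hi]).sum() / (end - start))

    def binned(self, contig: str, start: int, end: int, bin_bp: int) -> np.ndarray:
        """Per-bin mean coverage over [start, end) in bins of bin_bp."""
        if (end - start) % bin_bp != 0:
            raise ValueError("bin_bp must divide the window length")
        edges = np.arange(start, end + 1, bin_bp)
        return np.array([self.mean(contig, int(a), int(b))
                         for a, b in zip(edges[:-1], edges[1:])])


def read_bedgraph(path) -> CoverageTrack:
    chroms, starts, ends, values = [], [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 tab-separated fields")
            try:
                starts.append(int(parts[1]))
                ends.append(int(parts[2]))
                values.append(float(parts[3]))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed record ({exc})") from exc
            chroms.append(parts[0])
    if not chroms:
        raise ValueError(f"{path}: empty bedGraph")
    return CoverageTrack.from_arrays(chroms, starts, ends, values)


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for contig in sorted(track.intervals):
            s, e, v = track.intervals[contig]
            for si, ei, vi in zip(s, e, v):
                fh.write(f"{contig}\t{si}\t{ei}\t{vi:.6g}\n")
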