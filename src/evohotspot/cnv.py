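"""Coverage normalization and copy-number screening.

Whole-genome read depth is summarized in non-overlapping 5,000-bp
windows and corrected for two systematic biases before copy-number
calling:

1. **GC bias** — each window's count is multiplied by the ratio of the
   genome-wide median count to the median count of windows with the same
   GC fraction (binned; a median-ratio correction).
2. **Chromosome-end bias** — read counts inflate toward chromosome
   ends; each chromosome half is fit by LOWESS (locally weighted linear
   regression, tricube weights, robustifying iterations) of corrected
   count against distance to the near end, and windows are divided by
   the fitted line, leaving a dimensionless normalized coverage centered
   on 1.

Candidate CNV segments are maximal runs of consecutive windows beyond an
amplification/deletion threshold, kept only when they span more than one
window (> 5,000 bp) and less than half the chromosome.

Windows are carried as a pandas DataFrame with columns
``chrom, start, end, raw_mean_count, gc, normalized`` (0-based,
half-open coordinates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "WINDOW_SIZE",
    "CNVSegment",
    "bin_coverage",
    "gc_correct",
    "lowess_fit",
    "correct_end_bias",
    "normalize_coverage",
    "call_cnv_segments",
]

WINDOW_SIZE = 5000

WINDOW_COLUMNS = ["chrom", "start", "end", "raw_mean_count", "gc", "normalized"]

#: partial trailing windows shorter than this are excluded from medians
_MIN_FULL_FRACTION_BP = 2500


@dataclass(frozen=True)
class CNVSegment:
    chrom: str
    start: int  # 0-based half-open
    end: int
    n_windows: int
    mean_normalized: float
    direction: str  # "amplification" | "deletion"


def _gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def bin_coverage(
    depths: dict[str, np.ndarray] | pd.DataFrame,
    reference: dict[str, str] | None = None,
    window: int = WINDOW_SIZE,
) -> pd.DataFrame:
    """Mean per-position depth in non-overlapping tiling windows.

    ``depths`` is either a mapping of contig -> per-position depth array,
    or an already-binned DataFrame with columns
    ``chrom, start, end, count[, gc]``.  GC per window is computed from
    ``reference`` sequences when given, otherwise taken from the input's
    ``gc`` column (NaN if absent).  The final window of a contig may be
    shorter than ``window``; its mean is over its true width.
    """
    rows = []
    if isinstance(depths, pd.DataFrame):
        df = depths.rename(columns={"count": "raw_mean_count"}).copy()
        required = {"chrom", "start", "end", "raw_mean_count"}
        if not required.issubset(df.columns):
            raise ValueError(f"pre-binned input needs columns {sorted(required)}")
        if "gc" not in df.columns:
            df["gc"] = np.nan
        if reference is not None:
            missing = set(df["chrom"]) - set(reference)
            if missing:
                raise KeyError(f"contigs absent from reference: {sorted(missing)}")
            df["gc"] = [
                _gc_fraction(reference[c][s:e])
                for c, s, e in zip(df["chrom"], df["start"], df["end"])
            ]
        df["normalized"] = np.nan
        return df[WINDOW_COLUMNS].reset_index(drop=True)

    for chrom, depth in depths.items():
        depth = np.asarray(depth, dtype=float)
        if reference is not None:
            if chrom not in reference:
                raise KeyError(f"contig {chrom!r} absent from reference")
            if len(reference[chrom]) != len(depth):
                raise ValueError(
                    f"{chrom}: depth length {len(depth)} != reference "
                    f"length {len(reference[chrom])}"
                )
        for start in range(0, len(depth), window):
            end = min(start + window, len(depth))
            gc = (
                _gc_fraction(reference[chrom][start:end])
                if reference is not None
                else float("nan")
            )
            rows.append((chrom, start, end, float(depth[start:end].mean()), gc))
    out = pd.DataFrame(rows, columns=WINDOW_COLUMNS[:5])
    out["normalized"] = np.nan
    return out


def _median_eligible(df: pd.DataFrame) -> pd.Series:
    """Windows wide enough to enter median computations."""
    return (df["end"] - df["start"]) >= _MIN_FULL_FRACTION_BP


def gc_correct(
    windows: pd.DataFrame,
    gc_bin_width: float = 0.01,
    min_bin_size: int = 10,
    source_column: str = "raw_mean_count",
) -> pd.DataFrame:
    """Median-ratio GC correction.

    Each window's count is multiplied by
    ``median(all counts) / median(counts of windows in the same GC bin)``.
    GC bins are ``gc_bin_width`` wide; bins with fewer than
    ``min_bin_size`` windows are merged into the nearest populated bin so
    that bin medians are stable.  A bin with median 0 leaves its windows'
    ``normalized`` as NaN (logged via warning).  The result keeps the
    count scale; the end-bias step (or ``normalize_coverage``) brings the
    median to 1.
    """
    df = windows.copy()
    counts = df[source_column].to_numpy(dtype=float)
    eligible = _median_eligible(df).to_numpy()
    grand_median = float(np.median(counts[eligible]))

    bins = np.floor(df["gc"].to_numpy() / gc_bin_width).astype(int)
    pop = pd.Series(bins[eligible]).value_counts()
    populated = pop[pop >= min_bin_size].index.to_numpy()
    if len(populated) == 0:
        # fall back to a single pooled bin
        populated = np.array([0])
        merged = np.zeros_like(bins)
    else:
        merged = np.array(
            [populated[np.argmin(np.abs(populated - b))] for b in bins]
        )

    factors = np.full(len(df), np.nan)
    for b in np.unique(merged):
        in_bin = merged == b
        bin_median = float(np.median(counts[in_bin & eligible]))
        if bin_median == 0:
            warnings.warn(
                f"GC bin {b * gc_bin_width:.2f} has median 0; windows set missing",
                stacklevel=2,
            )
            continue
        factors[in_bin] = grand_median / bin_median
    df["normalized"] = counts * factors
    return df


def lowess_fit(
    x, y, span: float = 2 / 3, robust_iters: int = 3
) -> np.ndarray:
    """LOWESS fit evaluated at every input x (input order preserved).

    Locally weighted linear regression with a tricube kernel over the
    ``span`` fraction of nearest neighbours and ``robust_iters``
    bisquare reweighting passes (statsmodels backend).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("LOWESS needs at least 4 points")
    if span * len(x) < 2:
        raise ValueError(f"span {span} covers fewer than 2 of {len(x)} points")
    return _sm_lowess(y, x, frac=span, it=robust_iters, return_sorted=False)


def correct_end_bias(
    windows: pd.DataFrame, span: float = 2 / 3, robust_iters: int = 3
) -> pd.DataFrame:
    """Flatten coverage inflation toward chromosome ends.

    Requires GC correction first (``normalized`` populated).  Each
    chromosome is split at the midpoint of its window list (odd middle
    window to the left half); within each half a LOWESS curve of
    normalized count vs distance to that half's chromosome end is fit,
    and windows are divided by the fitted value.  Halves with fewer than
    4 usable windows are passed through divided by their median, with a
    warning.  Output is dimensionless with per-chromosome median ~ 1.
    """
    df = windows.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    if df["normalized"].isna().all():
        raise ValueError("run gc_correct first: 'normalized' is unpopulated")
    out = np.full(len(df), np.nan)
    for chrom, sub in df.groupby("chrom", sort=False):
        pos_all = sub.index.to_numpy()
        n = len(sub)
        chrom_end = int(sub["end"].max())
        mid = (n + 1) // 2  # odd middle window goes to the left half
        for half_pos, is_left in ((pos_all[:mid], True), (pos_all[mid:], False)):
            if len(half_pos) == 0:
                continue
            vals = df.loc[half_pos, "normalized"].to_numpy(dtype=float)
            centers = (
                df.loc[half_pos, "start"].to_numpy()
                + df.loc[half_pos, "end"].to_numpy()
            ) / 2.0
            dist = centers if is_left else chrom_end - centers
            ok = np.isfinite(vals)
            if ok.sum() < 4:
                warnings.warn(
                    f"{chrom}: half with {int(ok.sum())} usable windows; "
                    "end-bias fit skipped, median-scaled only",
                    stacklevel=2,
                )
                med = float(np.median(vals[ok])) if ok.any() else np.nan
                out[half_pos] = vals / med if med and np.isfinite(med) else np.nan
                continue
            fitted = np.full(len(vals), np.nan)
            fitted[ok] = lowess_fit(dist[ok], vals[ok], span, robust_iters)
            with np.errstate(divide="ignore", invalid="ignore"):
                out[half_pos] = np.where(fitted > 0, vals / fitted, np.nan)
    df["normalized"] = out
    return df


def normalize_coverage(
    windows: pd.DataFrame,
    gc_bin_width: float = 0.01,
    min_bin_size: int = 10,
    span: float = 2 / 3,
    robust_iters: int = 3,
) -> pd.DataFrame:
    """GC median-ratio correction followed by end-bias LOWESS division."""
    return correct_end_bias(
        gc_correct(windows, gc_bin_width, min_bin_size), span, robust_iters
    )


def call_cnv_segments(
    windows: pd.DataFrame,
    amp_threshold: float = 4.0,
    del_threshold: float = 0.25,
) -> list[CNVSegment]:
    """Call maximal runs of extreme normalized coverage as CNV segments.

    A window is amplified when ``normalized >= amp_threshold`` and
    deleted when ``normalized <= del_threshold``.  Runs of consecutive
    same-direction windows are reported when they span strictly more
    than 5,000 bp and strictly less than half the chromosome length.
    Missing (NaN) windows break runs.
    """
    segments: list[CNVSegment] = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        chrom_len = int(sub["end"].max())
        norm = sub["normalized"].to_numpy(dtype=float)
        state = np.where(
            np.isnan(norm),
            "",
            np.where(
                norm >= amp_threshold,
                "amplification",
                np.where(norm <= del_threshold, "deletion", ""),
            ),
        )
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        i = 0
        while i < len(sub):
            if state[i] == "":
                i += 1
                continue
            j = i
            while j + 1 < len(sub) and state[j + 1] == state[i] and ends[j] == starts[j + 1]:
                j += 1
            span_bp = int(ends[j] - starts[i])
            if span_bp > WINDOW_SIZE and span_bp < chrom_len / 2:
                segments.append(
                    CNVSegment(
                        chrom=chrom,
                        start=int(starts[i]),
                        end=int(ends[j]),
                        n_windows=j - i + 1,
                        mean_normalized=float(np.nanmean(norm[i : j + 1])),
                        direction=str(state[i]),
                    )
                )
            i = j + 1
    return segments
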