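"""GC content, sliding-window two-group contrasts, and core-region detection.

GC content of a (sub)sequence is ``100 * (#G + #C) / (#A + #C + #G + #T)``;
alignment gaps and IUPAC ambiguity codes are excluded from both numerator and
denominator.  A window with no unambiguous bases for a sequence yields an
undefined value and that sequence drops out of the group statistics for that
window.

The scan slides a fixed window (default 500 columns, step 25) along the
alignment, computes each group's mean GC, and contrasts the two groups with
Welch's t-test.  Significance over the whole scan is Bonferroni-controlled:
the per-window threshold is ``alpha / m`` where ``m`` counts only the
windows where both groups have at least two defined values.  Maximal runs of
adjacent significant windows are merged into core regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from dielscan.io import Alignment, SampleMetadata

WINDOW_DEFAULT = 500
STEP_DEFAULT = 25


@dataclass(frozen=True)
class GCValue:
    """GC percentage and the number of unambiguous bases it is based on."""

    percent: float
    n_valid: int

    @property
    def defined(self) -> bool:
        return self.n_valid > 0


@dataclass(frozen=True)
class Contrast:
    """A two-level contrast over a metadata trait, e.g. behavior Diurnal vs Nocturnal."""

    trait: str  # 'behavior' or 'group'
    level_a: str
    level_b: str


@dataclass
class WindowStat:
    """Per-window GC summaries and the Welch contrast between two groups.

    Coordinates are 0-based half-open in the coordinate system of the
    alignment the scan was run on (typically the trimmed alignment; use the
    trim result's kept-column map to project back).
    """

    start: int
    end: int
    per_sequence_gc: dict[str, GCValue] = field(default_factory=dict)
    mean_a: float | None = None
    mean_b: float | None = None
    sd_a: float | None = None
    sd_b: float | None = None
    n_a: int = 0
    n_b: int = 0
    ci95_halfwidth_a: float | None = None
    ci95_halfwidth_b: float | None = None
    t_stat: float | None = None
    df: float | None = None
    p_raw: float | None = None
    p_threshold: float | None = None
    significant: bool = False
    testable: bool = True

    @property
    def delta_gc(self) -> float | None:
        if self.mean_a is None or self.mean_b is None:
            return None
        return self.mean_a - self.mean_b


@dataclass(frozen=True)
class CoreRegion:
    """A maximal run of adjacent significant windows, as one interval."""

    start: int
    end: int
    n_windows: int
    mean_delta_gc: float


def gc_content(residues: str) -> GCValue:
    """GC percentage of a sequence fragment, ignoring gaps and ambiguity codes."""
    gc = sum(residues.count(c) for c in "GC")
    at = sum(residues.count(c) for c in "AT")
    n = gc + at
    if n == 0:
        return GCValue(percent=float("nan"), n_valid=0)
    return GCValue(percent=100.0 * gc / n, n_valid=n)


def gc_per_sequence(alignment: Alignment) -> dict[str, GCValue]:
    """Whole-row GC for every sequence in the alignment."""
    return {r.id: gc_content(r.residues) for r in alignment.records}


def sliding_window_gc(
    alignment: Alignment, window: int = WINDOW_DEFAULT, step: int = STEP_DEFAULT
) -> list[WindowStat]:
    """Per-sequence GC in full windows at starts 0, step, 2*step, ...

    Only complete windows are emitted: starts run while ``start + window <=
    ncol``, giving ``floor((ncol - window) / step) + 1`` windows.
    """
    if window > alignment.ncol:
        raise ValueError(f"window {window} exceeds alignment length {alignment.ncol}")
    if step < 1:
        raise ValueError("step must be >= 1")
    arr = alignment.to_array()
    is_gc = np.isin(arr, list("GC")).astype(np.int64)
    is_valid = np.isin(arr, list("ACGT")).astype(np.int64)
    # prefix sums over columns -> O(1) window counts per row
    cgc = np.concatenate([np.zeros((arr.shape[0], 1), dtype=np.int64), np.cumsum(is_gc, axis=1)], axis=1)
    cva = np.concatenate([np.zeros((arr.shape[0], 1), dtype=np.int64), np.cumsum(is_valid, axis=1)], axis=1)
    ids = alignment.ids
    out: list[WindowStat] = []
    for start in range(0, alignment.ncol - window + 1, step):
        end = start + window
        gcs = cgc[:, end] - cgc[:, start]
        vals = cva[:, end] - cva[:, start]
        per_seq = {}
        for i, sid in enumerate(ids):
            n = int(vals[i])
            pct = 100.0 * gcs[i] / n if n else float("nan")
            per_seq[sid] = GCValue(percent=pct, n_valid=n)
        out.append(WindowStat(start=start, end=end, per_sequence_gc=per_seq))
    return out


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns ``(t, df, p)`` with the Welch–Satterthwaite degrees of freedom.
    Two groups that are constant and equal give ``t=0, p=1`` rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"welch_t_test needs >=2 values per side, got {len(a)} and {len(b)}")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return math.copysign(float("inf"), a.mean() - b.mean()), float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _ci95_halfwidth(values: np.ndarray) -> float:
    n = len(values)
    if n < 2:
        return float("nan")
    return float(stats.t.ppf(0.975, n - 1) * values.std(ddof=1) / math.sqrt(n))


def group_summary(
    gc_values: dict[str, GCValue], metadata: SampleMetadata, contrast: Contrast
) -> dict:
    """Whole-sequence two-group comparison (means, SDs, Welch test).

    This is the boxplot-style summary: one GC value per sequence, groups
    defined by the contrast trait, outgroup rows excluded.
    """
    ids_a = metadata.level_ids(contrast.trait, contrast.level_a)
    ids_b = metadata.level_ids(contrast.trait, contrast.level_b)
    a = np.array([gc_values[i].percent for i in ids_a if gc_values[i].defined])
    b = np.array([gc_values[i].percent for i in ids_b if gc_values[i].defined])
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"contrast {contrast.level_a} vs {contrast.level_b}: need >=2 defined values per level"
        )
    t, df, p = welch_t_test(a, b)
    return {
        "trait": contrast.trait,
        "level_a": contrast.level_a,
        "level_b": contrast.level_b,
        "n_a": int(len(a)),
        "n_b": int(len(b)),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "sd_a": float(a.std(ddof=1)),
        "sd_b": float(b.std(ddof=1)),
        "t": t,
        "df": df,
        "p": p,
    }


def group_window_tests(
    windows: list[WindowStat],
    metadata: SampleMetadata,
    contrast: Contrast,
    alpha: float = 0.05,
) -> list[WindowStat]:
    """Fill each window with group summaries and the Bonferroni-tested Welch contrast.

    A window is testable when both contrast levels have at least two defined
    GC values in it; only testable windows enter the Bonferroni count ``m``,
    and every tested window gets ``p_threshold = alpha / m``.
    """
    ids_a = metadata.level_ids(contrast.trait, contrast.level_a)
    ids_b = metadata.level_ids(contrast.trait, contrast.level_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError(
            f"contrast level with <2 members: {contrast.level_a}={len(ids_a)}, "
            f"{contrast.level_b}={len(ids_b)}"
        )
    out: list[WindowStat] = []
    for w in windows:
        a = np.array([w.per_sequence_gc[i].percent for i in ids_a if w.per_sequence_gc[i].defined])
        b = np.array([w.per_sequence_gc[i].percent for i in ids_b if w.per_sequence_gc[i].defined])
        ws = replace(w)
        ws.n_a, ws.n_b = int(len(a)), int(len(b))
        if len(a) >= 1:
            ws.mean_a = float(a.mean())
        if len(b) >= 1:
            ws.mean_b = float(b.mean())
        if len(a) >= 2:
            ws.sd_a = float(a.std(ddof=1))
            ws.ci95_halfwidth_a = _ci95_halfwidth(a)
        if len(b) >= 2:
            ws.sd_b = float(b.std(ddof=1))
            ws.ci95_halfwidth_b = _ci95_halfwidth(b)
        if len(a) >= 2 and len(b) >= 2:
            ws.testable = True
            ws.t_stat, ws.df, ws.p_raw = welch_t_test(a, b)
        else:
            ws.testable = False
        out.append(ws)
    m = sum(1 for w in out if w.testable)
    if m == 0:
        return out
    threshold = alpha / m
    for w in out:
        if w.testable:
            w.p_threshold = threshold
            w.significant = bool(w.p_raw < threshold)
    return out


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance level controlling family-wise error over m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def detect_cores(windowstats: list[WindowStat], step: int = STEP_DEFAULT) -> list[CoreRegion]:
    """Merge maximal runs of adjacent significant windows into core regions.

    Two significant windows belong to the same run iff their starts differ by
    exactly ``step``.  A core spans from the first window's start to the last
    window's end; its score is the mean (group A − group B) GC difference
    over the member windows.
    """
    sig = [w for w in windowstats if w.significant]
    sig.sort(key=lambda w: w.start)
    cores: list[CoreRegion] = []
    run: list[WindowStat] = []
    for w in sig:
        if run and w.start - run[-1].start != step:
            cores.append(_close_run(run))
            run = []
        run.append(w)
    if run:
        cores.append(_close_run(run))
    return cores


def _close_run(run: list[WindowStat]) -> CoreRegion:
    deltas = [w.delta_gc for w in run if w.delta_gc is not None]
    return CoreRegion(
        start=run[0].start,
        end=run[-1].end,
        n_windows=len(run),
        mean_delta_gc=float(np.mean(deltas)) if deltas else float("nan"),
    )


def write_window_table(windows: list[WindowStat], path) -> None:
    cols = (
        "start\tend\tn_a\tmean_a\tsd_a\tci95_a\tn_b\tmean_b\tsd_b\tci95_b\t"
        "t\tdf\tp_raw\tp_threshold\tsignificant\ttestable\n"
    )

    def fmt(x):
        return "NA" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.6g}"

    with open(path, "w") as fh:
        fh.write(cols)
        for w in windows:
            fh.write(
                "\t".join(
                    [
                        str(w.start),
                        str(w.end),
                        str(w.n_a),
                        fmt(w.mean_a),
                        fmt(w.sd_a),
                        fmt(w.ci95_halfwidth_a),
                        str(w.n_b),
                        fmt(w.mean_b),
                        fmt(w.sd_b),
                        fmt(w.ci95_halfwidth_b),
                        fmt(w.t_stat),
                        fmt(w.df),
                        fmt(w.p_raw),
                        fmt(w.p_threshold),
                        str(int(w.significant)),
                        str(int(w.testable)),
                    ]
                )
                + "\n"
            )


def write_cores_bed(cores: list[CoreRegion], path, name_prefix: str = "core") -> None:
    """Cores as BED (0-based half-open), score column = mean delta GC."""
    with open(path, "w") as fh:
        for i, c in enumerate(cores, start=1):
            fh.write(f"chrom\t{c.start}\t{c.end}\t{name_prefix}_{i}\t{c.mean_delta_gc:.4f}\n")
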