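"""Somatic chromosome alteration (SCA) calling and classification.

Segments carry allele-specific copy number (total = major + minor) and
one of six alteration classes — homozygous deletion (HD), copy loss,
copy-neutral LOH (cnLOH), balanced gain, allele-specific gain, and
high-level focal amplification — plus the neutral ``diploid`` state.
The caller works from an exome probe track (per-target tumour/normal
log-ratio and B-allele frequency at heterozygous sites): greedy binary
segmentation with a mean-shift statistic and BIC-style stopping on the
joint (log-ratio, BAF-deviation) signal, copy numbers from the segment
means, and ploidy-4 re-classification when the genome looks doubled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import TestResult, fisher_exact_2x2

__all__ = [
    "SCA_CLASSES",
    "CLASS_CN",
    "SEG_COLUMNS",
    "CallerParams",
    "classify_segment",
    "segment_and_call",
    "arm_sca_load",
    "genome_doubling_flag",
    "focal_amp_prevalence_test",
    "synthetic_track",
]

SCA_CLASSES = ("HD", "loss", "cnLOH", "balanced_gain", "allele_gain", "focal_amp")

#: canonical (total, minor) copy numbers used when simulating each class
CLASS_CN = {
    "HD": (0, 0),
    "loss": (1, 0),
    "cnLOH": (2, 0),
    "balanced_gain": (4, 2),
    "allele_gain": (3, 1),
    "focal_amp": (8, 1),
}

SEG_COLUMNS = [
    "patient_id",
    "chrom",
    "start",
    "end",
    "n_probes",
    "log_ratio",
    "total_cn",
    "minor_cn",
    "class",
]


@dataclass
class CallerParams:
    min_probes_per_chrom: int = 50
    min_seg_probes: int = 5
    penalty_factor: float = 6.0  # x log(n) per accepted change-point
    focal_amp_margin: int = 4  # focal amp iff total >= ploidy + margin
    focal_max_mb: float = 3.0


def classify_segment(
    total_cn: int,
    minor_cn: int,
    length_bp: float,
    ploidy: int = 2,
    focal_amp_margin: int = 4,
    focal_max_mb: float = 3.0,
) -> str:
    """Map allele-specific copy numbers (+ length) to one SCA class.

    The mapping is total and deterministic: HD (total 0), loss
    (0 < total < ploidy), cnLOH (total == ploidy, minor 0), focal
    amplification (total >= ploidy + margin and short), balanced gain
    (total > ploidy, major == minor), allele-specific gain (total >
    ploidy otherwise), else diploid.
    """
    if total_cn < 0 or minor_cn < 0:
        raise ValueError("copy numbers must be >= 0")
    if minor_cn > total_cn / 2:
        raise ValueError(f"minor_cn {minor_cn} exceeds total_cn/2 ({total_cn}/2)")
    major_cn = total_cn - minor_cn
    if total_cn == 0:
        return "HD"
    if total_cn < ploidy:
        return "loss"
    if total_cn == ploidy:
        return "cnLOH" if minor_cn == 0 else "diploid"
    # total_cn > ploidy
    if total_cn >= ploidy + focal_amp_margin and length_bp <= focal_max_mb * 1e6:
        return "focal_amp"
    if major_cn == minor_cn:
        return "balanced_gain"
    return "allele_gain"


# ---------------------------------------------------------------------------
# segmentation


def _binary_segments(z: np.ndarray, sigma2: float, min_size: int, penalty: float) -> list[int]:
    """Greedy binary segmentation change-points for one standardized signal.

    ``z`` may be multi-column (each column already scaled to unit noise);
    gains add across columns. Returns sorted interior breakpoints.
    """
    n = len(z)
    cps: list[int] = []

    cum = np.vstack([np.zeros(z.shape[1]), np.cumsum(z, axis=0)])
    cum2 = np.vstack([np.zeros(z.shape[1]), np.cumsum(z * z, axis=0)])

    def sse(i, j):
        s = cum[j] - cum[i]
        s2 = cum2[j] - cum2[i]
        return s2 - s * s / (j - i)

    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < 2 * min_size:
            continue
        base = sse(i, j)
        best_gain, best_t = -np.inf, None
        ts = np.arange(i + min_size, j - min_size + 1)
        if len(ts) == 0:
            continue
        # vectorized over candidate splits
        sL = cum[ts] - cum[i]
        s2L = cum2[ts] - cum2[i]
        nL = (ts - i)[:, None]
        sseL = s2L - sL * sL / nL
        sR = cum[j] - cum[ts]
        s2R = cum2[j] - cum2[ts]
        nR = (j - ts)[:, None]
        sseR = s2R - sR * sR / nR
        gains = ((base - sseL - sseR) / sigma2).sum(axis=1)
        k = int(np.argmax(gains))
        best_gain, best_t = gains[k], int(ts[k])
        if best_gain > penalty:
            cps.append(best_t)
            stack.append((i, best_t))
            stack.append((best_t, j))
    return sorted(cps)


def _mode(x: np.ndarray, bin_width: float = 0.05) -> float:
    lo, hi = x.min(), x.max()
    if hi - lo < bin_width:
        return float(np.median(x))
    bins = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(x, bins=bins)
    c = float(edges[np.argmax(counts)] + bin_width / 2)
    near = x[np.abs(x - c) <= bin_width]
    return float(near.mean()) if len(near) else c


def segment_and_call(
    track: pd.DataFrame,
    patient_id: str = "sample",
    params: CallerParams | None = None,
) -> pd.DataFrame:
    """Segment a probe track and call allele-specific copy number.

    ``track`` columns: chrom, start, end, log_ratio, baf (NaN where no
    heterozygous germline site). Chromosomes with fewer than
    ``min_probes_per_chrom`` targets are skipped. Returns a SEG-like
    frame; segments without heterozygous sites get minor_cn = NaN and a
    total-CN-only (balanced-assumption) class.
    """
    if params is None:
        params = CallerParams()
    required = {"chrom", "start", "end", "log_ratio"}
    if required - set(track.columns):
        raise ValueError(f"track missing column(s): {sorted(required - set(track.columns))}")
    if not np.isfinite(track["log_ratio"]).all():
        raise ValueError("log-ratio must be finite")

    baseline = _mode(track["log_ratio"].to_numpy())
    raw_segs = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        if len(sub) < params.min_probes_per_chrom:
            continue
        lr = sub["log_ratio"].to_numpy()
        dev = (
            np.abs(sub["baf"].to_numpy() - 0.5)
            if "baf" in sub.columns
            else np.full(len(sub), np.nan)
        )
        # probes without a het site carry no allelic signal; fill from the
        # nearest informative probe so they never fake a change-point
        if np.isfinite(dev).any():
            dev_filled = pd.Series(dev).ffill().bfill().to_numpy()
        else:
            dev_filled = np.zeros(len(dev))

        def mad_sigma(x):
            d = np.diff(x)
            s = np.median(np.abs(d)) / 0.6745 / np.sqrt(2)
            return max(float(s), 1e-6)

        z = np.column_stack([lr / mad_sigma(lr), dev_filled / mad_sigma(dev_filled)])
        penalty = params.penalty_factor * np.log(len(sub))
        cps = _binary_segments(z, 1.0, params.min_seg_probes, penalty)
        bounds = [0, *cps, len(sub)]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg_lr = float(lr[a:b].mean())
            total = max(int(round(2 * 2 ** (seg_lr - baseline))), 0)
            seg_dev = dev[a:b]
            het = np.isfinite(seg_dev)
            if het.any():
                d = float(seg_dev[het].mean())
                minor = int(round(total * (0.5 - d)))
                minor = int(np.clip(minor, 0, total // 2))
            else:
                minor = None
            raw_segs.append(
                {
                    "patient_id": patient_id,
                    "chrom": chrom,
                    "start": int(starts[a]),
                    "end": int(ends[b - 1]),
                    "n_probes": b - a,
                    "log_ratio": seg_lr,
                    "total_cn": total,
                    "minor_cn": minor,
                }
            )

    # merge adjacent segments with identical calls
    merged = []
    for seg in raw_segs:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev["chrom"] == seg["chrom"]
            and prev["total_cn"] == seg["total_cn"]
            and prev["minor_cn"] == seg["minor_cn"]
        ):
            w1, w2 = prev["n_probes"], seg["n_probes"]
            prev["log_ratio"] = (prev["log_ratio"] * w1 + seg["log_ratio"] * w2) / (w1 + w2)
            prev["end"] = seg["end"]
            prev["n_probes"] = w1 + w2
        else:
            merged.append(dict(seg))

    df = pd.DataFrame(merged, columns=SEG_COLUMNS[:-1])
    if df.empty:
        df["class"] = []
        return df[SEG_COLUMNS]

    def classify_all(ploidy: int) -> pd.Series:
        out = []
        for s in df.itertuples(index=False):
            minor = s.minor_cn if not pd.isna(s.minor_cn) else s.total_cn // 2
            out.append(
                classify_segment(
                    s.total_cn,
                    int(minor),
                    s.end - s.start,
                    ploidy=ploidy,
                    focal_amp_margin=params.focal_amp_margin,
                    focal_max_mb=params.focal_max_mb,
                )
            )
        return pd.Series(out, index=df.index)

    df["class"] = classify_all(ploidy=2)
    # WGD-aware: if most covered bases have major CN >= 2, re-call at ploidy 4
    lengths = (df["end"] - df["start"]).to_numpy(dtype=float)
    minor_known = df["minor_cn"].notna()
    major = df["total_cn"].to_numpy() - df["minor_cn"].fillna(df["total_cn"] // 2).to_numpy()
    doubled_frac = lengths[major >= 2].sum() / lengths.sum()
    if doubled_frac > 0.5:
        df["class"] = classify_all(ploidy=4)
    df["minor_cn"] = df["minor_cn"].astype("Int64")
    return df[SEG_COLUMNS]


# ---------------------------------------------------------------------------
# loads, doubling, prevalence


def _overlaps(seg_start, seg_end, arm_start, arm_end):
    return max(0, min(seg_end, arm_end) - max(seg_start, arm_start))


def arm_sca_load(segments: pd.DataFrame, arm_table: pd.DataFrame) -> pd.DataFrame:
    """Per-patient, per-arm, per-class SCA megabases and segment counts.

    Segments crossing an arm boundary are split and counted in each arm;
    counts come arm-length-normalized (``n_per_mb``). The neutral
    ``diploid`` class is excluded.
    """
    rows = []
    segs = segments[segments["class"].isin(SCA_CLASSES)].rename(columns={"class": "cls"})
    for s in segs.itertuples(index=False):
        for a in arm_table.itertuples(index=False):
            if str(a.chrom) != str(s.chrom):
                continue
            ov = _overlaps(s.start, s.end, a.start, a.end)
            if ov > 0:
                rows.append(
                    {
                        "patient_id": s.patient_id,
                        "arm": f"{a.chrom}{a.arm}",
                        "class": s.cls,
                        "mb": ov / 1e6,
                        "n_segments": 1,
                        "length_mb": a.length_mb,
                    }
                )
    if not rows:
        return pd.DataFrame(
            columns=["patient_id", "arm", "class", "mb", "n_segments", "n_per_mb"]
        )
    df = (
        pd.DataFrame(rows)
        .groupby(["patient_id", "arm", "class", "length_mb"], as_index=False)
        .sum()
    )
    df["n_per_mb"] = df["n_segments"] / df["length_mb"]
    return df.drop(columns="length_mb")


def genome_doubling_flag(
    segments: pd.DataFrame, arm_table: pd.DataFrame
) -> bool | None:
    """True iff major CN >= 2 over > 50% of the assessable autosomal genome.

    Unsegmented territory counts as diploid (major 1). Segments with
    unknown minor CN are excluded from the assessable genome; if less
    than half the genome remains assessable, returns None (unknown).
    """
    genome_bp = float(((arm_table["end"] - arm_table["start"])).sum())
    unknown_bp = 0.0
    doubled_bp = 0.0
    for s in segments.itertuples(index=False):
        length = 0.0
        for a in arm_table.itertuples(index=False):
            if str(a.chrom) == str(s.chrom):
                length += _overlaps(s.start, s.end, a.start, a.end)
        if s.minor_cn is None or (isinstance(s.minor_cn, float) and np.isnan(s.minor_cn)) or s.minor_cn is pd.NA:
            unknown_bp += length
            continue
        if s.total_cn - int(s.minor_cn) >= 2:
            doubled_bp += length
    assessable = genome_bp - unknown_bp
    if assessable < 0.5 * genome_bp:
        return None
    return bool(doubled_bp > 0.5 * assessable)


def focal_amp_prevalence_test(segments: pd.DataFrame, meta: pd.DataFrame) -> TestResult:
    """Fisher test of any-focal-amplification prevalence, users vs non-users."""
    has_amp = (
        segments[segments["class"] == "focal_amp"].groupby("patient_id").size() > 0
    )
    carriers = set(has_amp.index[has_amp])
    users = meta[meta["nsaid_user"]]["patient_id"]
    nonusers = meta[~meta["nsaid_user"]]["patient_id"]
    u_amp = sum(p in carriers for p in users)
    n_amp = sum(p in carriers for p in nonusers)
    table = [[u_amp, len(users) - u_amp], [n_amp, len(nonusers) - n_amp]]
    res = fisher_exact_2x2(table)
    res.detail.update({"users_with_amp": u_amp, "nonusers_with_amp": n_amp})
    return res


# ---------------------------------------------------------------------------
# synthetic probe tracks (test/simulation aid)


def synthetic_track(
    true_segments: list[tuple[int, int, int, int]],
    chrom: str = "1",
    span: tuple[int, int] = (0, 100_000_000),
    spacing: int = 20_000,
    probe_length: int = 120,
    lr_sigma: float = 0.0,
    baf_sigma: float = 0.0,
    het_fraction: float = 0.4,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Build a synthetic exome probe track for one chromosome.

    ``true_segments`` are (start, end, total_cn, minor_cn) on a diploid
    background. Log-ratios are log2(total/2) plus Gaussian noise; BAF at
    heterozygous probes mirrors minor/total plus noise.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    starts = np.arange(span[0], span[1], spacing)
    total = np.full(len(starts), 2)
    minor = np.full(len(starts), 1)
    for s, e, t, m in true_segments:
        inside = (starts >= s) & (starts < e)
        total[inside] = t
        minor[inside] = m
    with np.errstate(divide="ignore"):
        lr = np.where(total > 0, np.log2(np.maximum(total, 0.25) / 2.0), -3.0)
    lr = lr + rng.normal(0, lr_sigma, len(starts)) if lr_sigma else lr.astype(float)
    het = rng.random(len(starts)) < het_fraction
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(total > 0, minor / np.maximum(total, 1), 0.0)
    sign = rng.choice([-1.0, 1.0], size=len(starts))
    baf = 0.5 + sign * (0.5 - b)
    if baf_sigma:
        baf = baf + rng.normal(0, baf_sigma, len(starts))
    baf = np.clip(baf, 0.0, 1.0)
    baf[~het] = np.nan
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + probe_length,
            "log_ratio": lr,
            "baf": baf,
        }
    )


def true_class_per_base(
    true_segments: list[tuple[int, int, int, int]],
    span: tuple[int, int],
    ploidy: int = 2,
) -> list[tuple[int, int, str]]:
    """Expected class intervals for a synthetic single-chromosome truth."""
    bounds = sorted({span[0], span[1], *(s for s, *_ in true_segments), *(e for _, e, *_ in true_segments)})
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        t, m = 2, 1
        for s, e, tt, mm in true_segments:
            if s <= a and b <= e:
                t, m = tt, mm
        out.append((a, b, classify_segment(t, m, b - a, ploidy=ploidy)))
    return out
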