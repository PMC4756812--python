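"""Per-peak allelic percentages, mapping-bias calibration and classification.

For each peak and cell line the stringent allelic percentage is

    x = ASR_B6 / (ASR_B6 + ASR_JF1) * 100

and the control percentage j is the same quantity computed from the relaxed
(<=3 mismatch) counts. The control distribution over informative autosomal
peaks gives the line's calibration: its mean j_bar, sample standard deviation
sigma, and the bi-allelicity range Y = j_bar +/- 3*sigma. A peak is bi-allelic
when x falls inside Y in both reciprocal lines, mono-allelic when outside in
both, discordant otherwise.

The combined two-line allelic score is

    S = (|j_bar_JB1 - x_JB1| + |j_bar_BJ1 - x_BJ1|) / 2

with published operating points S <= 26 (bi-allelic), S >= 27 (mono-allelic)
and S > 42.5 (strong bias). Mono-allelic peaks are categorized by the side of
j_bar that x falls on in each line: same side in both lines means
strain-specific binding (the genotype decides), opposite sides mean
parent-of-origin binding (JF1 is the JB1 mother, B6 the BJ1 mother).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_SEX_CHROMS = ("chrX", "chrY", "X", "Y")

S_BIALLELIC_MAX = 26.0
S_MONOALLELIC_MIN = 27.0
S_STRONG_BIAS = 42.5


@dataclass(frozen=True)
class LineCalibration:
    """Control-percentage calibration for one cell line."""

    cell_line: str
    j_values: tuple[float, ...]
    j_bar: float
    sigma: float
    y_low: float
    y_high: float

    def contains(self, x: float) -> bool:
        """Inclusive membership in the bi-allelicity range Y."""
        return self.y_low <= x <= self.y_high


def percent_b6(asr_b6: int, asr_jf1: int) -> float | None:
    """Percentage of B6-assigned reads; None marks an uninformative peak."""
    total = asr_b6 + asr_jf1
    if total <= 0:
        return None
    return asr_b6 / total * 100.0


def filter_informative(
    counts: pd.DataFrame,
    min_ir: int = 5,
    sex_chroms: Sequence[str] = DEFAULT_SEX_CHROMS,
) -> pd.DataFrame:
    """Keep autosomal peaks with IR and IR_C >= min_ir in BOTH cell lines.

    ``counts`` is the wide per-peak table with columns ``chrom`` and, per line
    suffix (jb1/bj1): ir_*, asr_b6_*, asr_jf1_*, ir_c_*, asr_c_b6_*,
    asr_c_jf1_*. The bound is inclusive (IR = 5 passes). Sex-chromosome peaks
    are removed because the hybrid lines are male.
    """
    mask = ~counts["chrom"].isin(set(sex_chroms))
    for line in ("jb1", "bj1"):
        mask &= counts[f"ir_{line}"] >= min_ir
        mask &= counts[f"ir_c_{line}"] >= min_ir
    return counts.loc[mask].reset_index(drop=True)


def calibrate(
    j_values: Sequence[float], cell_line: str, sigma_mult: float = 3.0
) -> LineCalibration:
    """Mean/SD of the control percentages and the Y = j_bar +/- 3*sigma range.

    sigma is the sample standard deviation (n-1 denominator); at least two
    peaks are required for it to be defined.
    """
    vals = [float(v) for v in j_values]
    if len(vals) < 2:
        raise ValueError("calibration requires >= 2 informative peaks")
    j_bar = float(np.mean(vals))
    sigma = float(np.std(vals, ddof=1))
    return LineCalibration(
        cell_line=cell_line,
        j_values=tuple(vals),
        j_bar=j_bar,
        sigma=sigma,
        y_low=j_bar - sigma_mult * sigma,
        y_high=j_bar + sigma_mult * sigma,
    )


def classify_peak(
    x_jb1: float,
    x_bj1: float,
    cal_jb1: LineCalibration,
    cal_bj1: LineCalibration,
) -> str:
    """Y-range classification: biallelic / monoallelic / discordant."""
    in_jb1 = cal_jb1.contains(x_jb1)
    in_bj1 = cal_bj1.contains(x_bj1)
    if in_jb1 and in_bj1:
        return "biallelic"
    if not in_jb1 and not in_bj1:
        return "monoallelic"
    return "discordant"


def combined_score(
    x_jb1: float, jbar_jb1: float, x_bj1: float, jbar_bj1: float
) -> float:
    """Combined JB1-BJ1 allelic score S (mean absolute deviation from j_bar)."""
    return (abs(jbar_jb1 - x_jb1) + abs(jbar_bj1 - x_bj1)) / 2.0


def categorize_mono(
    x_jb1: float,
    x_bj1: float,
    cal_jb1: LineCalibration,
    cal_bj1: LineCalibration,
    klass: str | None = None,
) -> str:
    """Mono-allelic category from the direction of bias in each line.

    Uses each line's j_bar (not 50) as the neutral point so mapping bias cannot
    flip a category. x above j_bar means B6-biased. JF1 is the maternal genome
    in JB1 and B6 is maternal in BJ1, so JF1-bias in JB1 plus B6-bias in BJ1 is
    maternal binding; the mirror is paternal; same-direction bias is
    strain-specific.
    """
    if klass is not None and klass != "monoallelic":
        raise ValueError(f"categorize_mono called on {klass!r} peak")
    b6_biased_jb1 = x_jb1 > cal_jb1.j_bar
    b6_biased_bj1 = x_bj1 > cal_bj1.j_bar
    if b6_biased_jb1 and b6_biased_bj1:
        return "B6_specific"
    if not b6_biased_jb1 and not b6_biased_bj1:
        return "JF1_specific"
    if not b6_biased_jb1 and b6_biased_bj1:
        return "maternal"
    return "paternal"


def threshold_class(
    s: float,
    s_bi: float = S_BIALLELIC_MAX,
    s_mono: float = S_MONOALLELIC_MIN,
) -> str:
    """Published S-score operating point: S<=26 bi-allelic, S>=27 mono-allelic."""
    if s <= s_bi:
        return "biallelic"
    if s >= s_mono:
        return "monoallelic"
    return "indeterminate"


def annotate_thresholds(
    calls: pd.DataFrame,
    s_bi: float = S_BIALLELIC_MAX,
    s_mono: float = S_MONOALLELIC_MIN,
    s_strong: float = S_STRONG_BIAS,
) -> pd.DataFrame:
    """Add S-threshold labels and the strong-bias flag alongside the Y class.

    Both classifications (Y-range `klass` and `threshold_class`) are reported
    side by side, never merged.
    """
    calls = calls.copy()
    calls["threshold_class"] = [
        threshold_class(s, s_bi, s_mono) if math.isfinite(s) else "uninformative"
        for s in calls["S"]
    ]
    calls["strong_bias"] = calls["S"] > s_strong
    return calls


def score_peaks(
    counts: pd.DataFrame,
    min_ir: int = 5,
    sigma_mult: float = 3.0,
    sex_chroms: Sequence[str] = DEFAULT_SEX_CHROMS,
) -> tuple[pd.DataFrame, dict[str, LineCalibration]]:
    """Full scoring pass over a wide two-line counts table.

    Returns the calls table (one row per input peak; peaks failing the
    informativeness filter carry klass='uninformative' and NaN scores) and the
    per-line calibrations. Mono-allelic categories are attached to peaks whose
    threshold class is mono-allelic, with j_bar as the neutral point.
    """
    informative = filter_informative(counts, min_ir=min_ir, sex_chroms=sex_chroms)
    if len(informative) < 2:
        # nothing to calibrate against: every peak is reported uninformative
        calls = pd.DataFrame(
            {
                "peak_id": counts["peak_id"],
                "chrom": counts["chrom"],
                "x_jb1": math.nan,
                "x_bj1": math.nan,
                "j_jb1": math.nan,
                "j_bj1": math.nan,
                "S": math.nan,
                "klass": "uninformative",
                "category": "not_applicable",
            }
        )
        return annotate_thresholds(calls), {}
    # Control percentages; zero-denominator peaks cannot occur after the IR_C
    # filter but are dropped defensively rather than imputed.
    j: dict[str, list[float]] = {}
    for line in ("jb1", "bj1"):
        jvals = [
            percent_b6(int(r[f"asr_c_b6_{line}"]), int(r[f"asr_c_jf1_{line}"]))
            for _, r in informative.iterrows()
        ]
        j[line] = jvals
    keep = [a is not None and b is not None for a, b in zip(j["jb1"], j["bj1"])]
    informative = informative.loc[keep].reset_index(drop=True)
    j = {line: [v for v, k in zip(j[line], keep) if k] for line in j}

    cal = {
        "JB1": calibrate(j["jb1"], "JB1", sigma_mult),
        "BJ1": calibrate(j["bj1"], "BJ1", sigma_mult),
    }

    informative_ids = set(informative["peak_id"])
    rows = []
    jmap = {
        pid: (jj, bb)
        for pid, jj, bb in zip(informative["peak_id"], j["jb1"], j["bj1"])
    }
    for _, r in counts.iterrows():
        pid = r["peak_id"]
        if pid not in informative_ids:
            rows.append(
                {
                    "peak_id": pid,
                    "chrom": r["chrom"],
                    "x_jb1": math.nan,
                    "x_bj1": math.nan,
                    "j_jb1": math.nan,
                    "j_bj1": math.nan,
                    "S": math.nan,
                    "klass": "uninformative",
                    "category": "not_applicable",
                }
            )
            continue
        x_jb1 = percent_b6(int(r["asr_b6_jb1"]), int(r["asr_jf1_jb1"]))
        x_bj1 = percent_b6(int(r["asr_b6_bj1"]), int(r["asr_jf1_bj1"]))
        s = combined_score(x_jb1, cal["JB1"].j_bar, x_bj1, cal["BJ1"].j_bar)
        klass = classify_peak(x_jb1, x_bj1, cal["JB1"], cal["BJ1"])
        rows.append(
            {
                "peak_id": pid,
                "chrom": r["chrom"],
                "x_jb1": x_jb1,
                "x_bj1": x_bj1,
                "j_jb1": jmap[pid][0],
                "j_bj1": jmap[pid][1],
                "S": s,
                "klass": klass,
                "category": "not_applicable",
            }
        )
    calls = annotate_thresholds(pd.DataFrame(rows))
    categories = []
    for _, r in calls.iterrows():
        if r["threshold_class"] == "monoallelic":
            categories.append(
                categorize_mono(r["x_jb1"], r["x_bj1"], cal["JB1"], cal["BJ1"])
            )
        else:
            categories.append("not_applicable")
    calls["category"] = categories
    return calls, cal
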