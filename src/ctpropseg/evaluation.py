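"""Segmentation evaluation: Dice overlap, morphometrics, and statistics.

Accuracy is scored volume-wise with the Dice similarity coefficient
DSC = 2|A∩B| / (|A| + |B|).  Approaches (caudal / mid / cranial start
levels) are compared per organ with two-sided Wilcoxon signed-rank tests,
Bonferroni-corrected across the three pairwise contrasts (alpha = 0.05/3 ≈
0.0167); the negative-prompt ablation is a single per-organ paired contrast
at uncorrected alpha.  The association between organ volume (in voxels) and
DSC is summarized with Spearman rank correlations, pooled across organs per
approach and separately per organ.

The Wilcoxon implementation drops zero differences before ranking
(Wilcoxon's original treatment), uses the exact sign-flip null distribution
for n ≤ 25 pairs — computed by dynamic programming over doubled midranks,
so ties are handled exactly — and a tie-corrected normal approximation for
larger n.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .prompting import LEVELS, percentile_slice
from .volume_io import LabelMask

DEFAULT_ALPHA = 0.05
N_APPROACH_CONTRASTS = 3
EXACT_WILCOXON_MAX_N = 25
ZERO_METHOD = "drop-zeros"

APPROACH_CONTRASTS = (
    ("caudal", "mid"),
    ("caudal", "cranial"),
    ("mid", "cranial"),
)

RECORD_COLUMNS = [
    "scan_id",
    "organ",
    "level",
    "include_negatives",
    "dsc",
    "gt_voxels",
]


class EvaluationError(ValueError):
    """Raised for malformed evaluation inputs."""


@dataclass(frozen=True)
class EvalRecord:
    """One DSC measurement for a (scan, organ, approach, prompt condition)."""

    scan_id: str
    organ: str
    level: str
    include_negatives: bool
    dsc: float
    gt_voxels: int

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise EvaluationError(f"invalid level {self.level!r}")
        if not 0.0 <= self.dsc <= 1.0:
            raise EvaluationError(f"DSC out of [0, 1]: {self.dsc}")


@dataclass(frozen=True)
class ComparisonResult:
    """Paired Wilcoxon contrast between two conditions for one organ."""

    organ: str
    contrast: str
    n_pairs: int
    statistic: float
    p_value: float
    alpha_corrected: float
    significant: bool
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    mean_difference: float
    degenerate: bool = False
    insufficient: bool = False
    zero_method: str = ZERO_METHOD


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation between organ volume and DSC."""

    organ: str  # organ name or "pooled"
    level: str
    rho: float
    p_value: float
    n: int
    undefined: bool = False


class WilcoxonResult(NamedTuple):
    statistic: float
    p_value: float
    n_used: int
    degenerate: bool


class SpearmanResult(NamedTuple):
    rho: float
    p_value: float
    undefined: bool


# ---------------------------------------------------------------- metrics


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice similarity coefficient between two binary masks of equal shape.

    Conventions for empty masks: 1.0 if both are empty, 0.0 if exactly one
    is empty.
    """
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise EvaluationError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    a = int(pred.sum())
    b = int(gt.sum())
    if a + b == 0:
        return 1.0
    return 2.0 * int((pred & gt).sum()) / (a + b)


def organ_volume(mask: LabelMask) -> int:
    """Organ volume as a raw true-voxel count (no physical units)."""
    v = mask.voxel_volume
    if v == 0:
        raise EvaluationError(f"mask {mask.organ!r} is empty")
    return v


def area_profile(mask: LabelMask) -> tuple[int, int, int]:
    """Cross-sectional areas (pixel counts) at the 25th/50th/75th percentile slices."""
    if mask.voxel_volume == 0:
        raise EvaluationError(f"mask {mask.organ!r} is empty")
    return tuple(
        int(mask.mask[percentile_slice(mask, p)].sum()) for p in (25, 50, 75)
    )


# ------------------------------------------------------------- statistics


def _exact_wilcoxon_pvalue(doubled_ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided sign-flip p-value via DP over doubled midranks.

    Doubling midranks makes every rank an integer, so the distribution of
    2*W+ over all 2^n sign assignments is a convolution computable exactly.
    The two-sided p-value is P(|W+ - mu| >= |w_obs - mu|) under the
    symmetric null.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    mu = total / 2.0
    dev = abs(2.0 * w_plus - mu)
    support = np.arange(total + 1)
    extreme = np.abs(support - mu) >= dev - 1e-9
    return float(counts[extreme].sum() / counts.sum())


def wilcoxon_signed_rank(
    a: Sequence[float], b: Sequence[float]
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped before ranking; if every difference is
    zero the result is degenerate with p = 1.0.  The returned statistic is
    W+ (sum of ranks of positive differences) over the retained pairs.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise EvaluationError("paired samples must be equal-length 1D sequences")
    if a.size < 1:
        raise EvaluationError("need at least one pair")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_used=0, degenerate=True)
    ranks = stats.rankdata(np.abs(d))  # midranks for ties
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        doubled = np.round(2.0 * ranks).astype(np.int64)
        p = _exact_wilcoxon_pvalue(doubled, w_plus)
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        if var <= 0:
            return WilcoxonResult(statistic=w_plus, p_value=1.0, n_used=n, degenerate=True)
        z = (w_plus - mu) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return WilcoxonResult(statistic=w_plus, p_value=min(1.0, p), n_used=n, degenerate=False)


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation (midrank ties, t-approximation p-value)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise EvaluationError("samples must be equal-length 1D sequences")
    if x.size < 3:
        raise EvaluationError("need at least three observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return SpearmanResult(rho=float("nan"), p_value=float("nan"), undefined=True)
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(rho=float(rho), p_value=float(p), undefined=False)


def bonferroni_threshold(alpha: float = DEFAULT_ALPHA, m: int = N_APPROACH_CONTRASTS) -> float:
    """Bonferroni-corrected per-test significance threshold alpha / m."""
    if not 0 < alpha < 1:
        raise EvaluationError(f"alpha must be in (0, 1), got {alpha}")
    if not isinstance(m, (int, np.integer)) or m < 1:
        raise EvaluationError(f"m must be a positive integer, got {m}")
    return alpha / m


# -------------------------------------------------- record-level analyses


def records_to_frame(records: Iterable[EvalRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records], columns=RECORD_COLUMNS)
    return df


def _paired(
    df: pd.DataFrame, key_cols: list[str], a_sel, b_sel
) -> tuple[np.ndarray, np.ndarray, int]:
    """Align two conditions on (scan_id,) pairs; drop unmatched records."""
    a = df[a_sel].set_index(key_cols)["dsc"]
    b = df[b_sel].set_index(key_cols)["dsc"]
    common = a.index.intersection(b.index)
    dropped = (len(a) - len(common)) + (len(b) - len(common))
    return a.loc[common].to_numpy(), b.loc[common].to_numpy(), dropped


def _compare(
    organ: str,
    contrast: str,
    a: np.ndarray,
    b: np.ndarray,
    alpha_corrected: float,
) -> ComparisonResult:
    n = a.size
    if n < 2:
        return ComparisonResult(
            organ=organ,
            contrast=contrast,
            n_pairs=n,
            statistic=float("nan"),
            p_value=float("nan"),
            alpha_corrected=alpha_corrected,
            significant=False,
            mean_a=float(a.mean()) if n else float("nan"),
            sd_a=float(a.std(ddof=1)) if n > 1 else float("nan"),
            mean_b=float(b.mean()) if n else float("nan"),
            sd_b=float(b.std(ddof=1)) if n > 1 else float("nan"),
            mean_difference=float((a - b).mean()) if n else float("nan"),
            insufficient=True,
        )
    res = wilcoxon_signed_rank(a, b)
    return ComparisonResult(
        organ=organ,
        contrast=contrast,
        n_pairs=n,
        statistic=res.statistic,
        p_value=res.p_value,
        alpha_corrected=alpha_corrected,
        significant=(not res.degenerate) and res.p_value < alpha_corrected,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        mean_difference=float((a - b).mean()),
        degenerate=res.degenerate,
    )


def compare_conditions(
    records: Iterable[EvalRecord],
    family: str,
    alpha: float = DEFAULT_ALPHA,
    ablation_level: str = "caudal",
) -> list[ComparisonResult]:
    """Per-organ paired contrasts for one comparison family.

    ``family='approach-pairs'``: the three pairwise start-level contrasts
    (caudal-vs-mid, caudal-vs-cranial, mid-vs-cranial) on with-negatives
    records, each tested against the Bonferroni-corrected threshold
    alpha/3.

    ``family='negatives-ablation'``: with- vs without-negative-prompts at
    the ablation level (caudal by default), tested at uncorrected alpha;
    the reported ``mean_difference`` follows the without-minus-with
    convention (negative values mean performance drops without negatives).
    """
    df = records_to_frame(records)
    if df.empty:
        return []
    out: list[ComparisonResult] = []
    if family == "approach-pairs":
        threshold = bonferroni_threshold(alpha, N_APPROACH_CONTRASTS)
        base = df[df["include_negatives"]]
        for organ, sub in base.groupby("organ", sort=True):
            for lvl_a, lvl_b in APPROACH_CONTRASTS:
                a, b, _ = _paired(
                    sub,
                    ["scan_id"],
                    sub["level"] == lvl_a,
                    sub["level"] == lvl_b,
                )
                out.append(
                    _compare(organ, f"{lvl_a}-vs-{lvl_b}", a, b, threshold)
                )
    elif family == "negatives-ablation":
        base = df[df["level"] == ablation_level]
        for organ, sub in base.groupby("organ", sort=True):
            without, with_neg, _ = _paired(
                sub,
                ["scan_id"],
                ~sub["include_negatives"],
                sub["include_negatives"],
            )
            out.append(
                _compare(organ, "without-vs-with-negatives", without, with_neg, alpha)
            )
    else:
        raise EvaluationError(f"unknown comparison family {family!r}")
    return out


def correlate_volume_dsc(
    records: Iterable[EvalRecord], per_organ: bool = True
) -> list[CorrelationResult]:
    """Spearman correlations between ground-truth volume and DSC.

    Pooled across organs for each start level (on with-negatives records),
    plus optional per-organ correlations at each level.
    """
    df = records_to_frame(records)
    df = df[df["include_negatives"]]
    out: list[CorrelationResult] = []
    groups: list[tuple[str, str, pd.DataFrame]] = []
    for level in LEVELS:
        sub = df[df["level"] == level]
        groups.append(("pooled", level, sub))
        if per_organ:
            for organ, osub in sub.groupby("organ", sort=True):
                groups.append((organ, level, osub))
    for organ, level, sub in groups:
        if len(sub) < 3:
            continue
        res = spearman(sub["gt_voxels"].to_numpy(), sub["dsc"].to_numpy())
        out.append(
            CorrelationResult(
                organ=organ,
                level=level,
                rho=res.rho,
                p_value=res.p_value,
                n=len(sub),
                undefined=res.undefined,
            )
        )
    return out


# ------------------------------------------------------------- reporting


def write_records_csv(records: Iterable[EvalRecord], path) -> None:
    # %.17g guarantees float64 round-trip through the CSV
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_records_csv(path) -> list[EvalRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        EvalRecord(
            scan_id=str(r.scan_id),
            organ=str(r.organ),
            level=str(r.level),
            include_negatives=bool(r.include_negatives),
            dsc=float(r.dsc),
            gt_voxels=int(r.gt_voxels),
        )
        for r in df.itertuples(index=False)
    ]


def stats_report(
    records: Iterable[EvalRecord],
    alpha: float = DEFAULT_ALPHA,
    families: Sequence[str] = ("approach-pairs", "negatives-ablation"),
    ablation_level: str = "caudal",
    per_organ_correlations: bool = True,
) -> dict:
    """Full statistics report as a JSON-serializable dict.

    Pure function of the records, so the report is always recomputable
    from the long-format CSV alone.
    """
    records = list(records)
    report: dict = {
        "alpha": alpha,
        "bonferroni_threshold": bonferroni_threshold(alpha, N_APPROACH_CONTRASTS),
        "n_records": len(records),
        "comparisons": {},
        "correlations": [],
    }
    for family in families:
        report["comparisons"][family] = [
            asdict(c)
            for c in compare_conditions(
                records, family, alpha=alpha, ablation_level=ablation_level
            )
        ]
    report["correlations"] = [
        asdict(c)
        for c in correlate_volume_dsc(records, per_organ=per_organ_correlations)
    ]
    return report


def write_stats_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
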