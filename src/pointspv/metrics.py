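"""Behavioral analysis suite for gaze-contingent discrimination trials.

Per-trial records (response, truth, reaction time, fixation list, saccade
count) are aggregated into the four standard performance metrics —
accuracy, mean reaction time, mean saccade count and mean stimulus
coverage — per participant and representation method, and compared with a
one-within-factor repeated-measures ANOVA.

Stimulus coverage models each fixation as an unnormalized two-dimensional
Gaussian kernel (peak value 1, sigma = 50 px by default) centered at the
fixation; the per-pixel maximum over all kernels forms a continuous
heatmap whose mean over all image pixels is the coverage.  A fixation at
every pixel therefore gives exactly 100% coverage, and coverage is
monotone in the fixation set.  Saccades are consumed as pre-detected
counts, not detected from raw eye traces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TrialRecord:
    """One behavioral trial."""

    participant_id: str
    block: int                      # 1 | 2
    method: str                     # "pointspv" | "canny"
    stimulus_id: str
    response: int
    truth: int
    reaction_time: float            # seconds, in (0, 30]
    fixations: list[tuple[float, float]]   # (y, x) viewing points
    n_saccades: int

    def __post_init__(self):
        if not 0.0 < self.reaction_time <= 30.0:
            raise ValueError("reaction_time must lie in (0, 30] s")
        if self.n_saccades < 0:
            raise ValueError("n_saccades must be >= 0")
        if self.block not in (1, 2):
            raise ValueError("block must be 1 or 2")


@dataclass
class CoverageHeatmap:
    """Per-pixel fixation influence in [0,1] (max-composed Gaussians)."""

    values: np.ndarray
    sigma: float


class RMAnovaResult(NamedTuple):
    F: float
    df: tuple[int, int]
    p: float


# ---------------------------------------------------------------------------
# stimulus coverage
# ---------------------------------------------------------------------------

def coverage_heatmap(fixations: Sequence[tuple[float, float]], image_shape,
                     sigma: float = 50.0) -> np.ndarray:
    """Max-composed peak-1 Gaussian heatmap over the image.

    Each fixation contributes ``exp(-||p - f||^2 / (2 sigma^2))`` at pixel
    p; the heatmap holds the per-pixel maximum.  The kernel is separable,
    so each fixation is one outer product.
    """
    h, w = image_shape
    hm = np.zeros((h, w), dtype=np.float64)
    ys = np.arange(h, dtype=np.float64)
    xs = np.arange(w, dtype=np.float64)
    for fy, fx in fixations:
        if not (0 <= fy < h and 0 <= fx < w):
            raise ValueError(f"fixation ({fy},{fx}) outside image {image_shape}")
        ky = np.exp(-((ys - fy) ** 2) / (2.0 * sigma ** 2))
        kx = np.exp(-((xs - fx) ** 2) / (2.0 * sigma ** 2))
        np.maximum(hm, np.outer(ky, kx), out=hm)
    return hm


def stimulus_coverage(fixations: Sequence[tuple[float, float]], image_shape,
                      sigma: float = 50.0) -> float:
    """Fraction of the image reached by fixation influence, in [0,1].

    Sum of the max-composed Gaussian heatmap normalized by the pixel
    count.  100% means every pixel was fully encompassed by at least one
    fixation; an empty fixation list gives 0.
    """
    if len(fixations) == 0:
        return 0.0
    hm = coverage_heatmap(fixations, image_shape, sigma)
    return float(hm.sum() / hm.size)


def fixation_heatmap(trials: Sequence[TrialRecord], image_shape,
                     sigma: float = 50.0) -> CoverageHeatmap:
    """Group fixation heatmap: per-participant max-composed heatmaps,
    averaged pixelwise across participants."""
    if len(trials) == 0:
        raise ValueError("empty trial group")
    by_participant: dict[str, list[tuple[float, float]]] = {}
    for t in trials:
        by_participant.setdefault(t.participant_id, []).extend(t.fixations)
    maps = [coverage_heatmap(fx, image_shape, sigma)
            for fx in by_participant.values()]
    return CoverageHeatmap(values=np.mean(maps, axis=0), sigma=sigma)


# ---------------------------------------------------------------------------
# per-participant aggregation
# ---------------------------------------------------------------------------

def block_metrics(trials: Sequence[TrialRecord],
                  image_shape=(1080, 1920), sigma: float = 50.0) -> pd.DataFrame:
    """Aggregate trials into a per-(participant, method) metric table.

    Columns: accuracy (fraction correct), mean_rt (s), mean_saccades,
    mean_coverage; one row per participant-method cell, averaged over that
    cell's trials.
    """
    if len(trials) == 0:
        raise ValueError("no trials to aggregate")
    rows = [{
        "participant_id": t.participant_id,
        "method": t.method,
        "correct": float(t.response == t.truth),
        "rt": t.reaction_time,
        "saccades": float(t.n_saccades),
        "coverage": stimulus_coverage(t.fixations, image_shape, sigma),
    } for t in trials]
    df = pd.DataFrame(rows)
    out = df.groupby(["participant_id", "method"]).agg(
        accuracy=("correct", "mean"),
        mean_rt=("rt", "mean"),
        mean_saccades=("saccades", "mean"),
        mean_coverage=("coverage", "mean"),
        n_trials=("correct", "size"),
    )
    return out


# ---------------------------------------------------------------------------
# repeated-measures ANOVA (one within factor, two levels)
# ---------------------------------------------------------------------------

def rm_anova(values_a: Sequence[float], values_b: Sequence[float]) -> RMAnovaResult:
    """Repeated-measures ANOVA for two paired conditions.

    ``values_a[i]`` and ``values_b[i]`` are the same participant's means
    under the two methods.  With one within-subject factor at two levels
    the statistic satisfies F = t^2 of the paired t-test, on (1, n-1)
    degrees of freedom.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must have identical 1-D shapes")
    n = a.size
    if n < 2:
        raise ValueError("need at least two participants")
    d = a - b
    if np.allclose(d.var(ddof=1), 0.0):
        # zero within-pair variance: no error term; identical conditions
        # give F = 0, a constant shift gives an infinite F
        if np.allclose(d.mean(), 0.0):
            return RMAnovaResult(F=0.0, df=(1, n - 1), p=1.0)
        return RMAnovaResult(F=np.inf, df=(1, n - 1), p=0.0)

    from statsmodels.stats.anova import AnovaRM
    long = pd.DataFrame({
        "participant": np.repeat(np.arange(n), 2),
        "method": np.tile(["a", "b"], n),
        "value": np.column_stack([a, b]).ravel(),
    })
    table = AnovaRM(long, depvar="value", subject="participant",
                    within=["method"]).fit().anova_table
    F = float(table["F Value"].iloc[0])
    p = float(table["Pr > F"].iloc[0])
    return RMAnovaResult(F=F, df=(int(table["Num DF"].iloc[0]),
                                  int(table["Den DF"].iloc[0])), p=p)


def method_anovas(table: pd.DataFrame, holm: bool = False) -> pd.DataFrame:
    """Run one repeated-measures ANOVA per metric on a block_metrics table.

    Expects exactly two methods; returns F, df and p per metric, with
    optional Holm-adjusted p-values.
    """
    wide = table.reset_index().pivot(index="participant_id", columns="method")
    methods = sorted({m for _, m in wide.columns})
    if len(methods) != 2:
        raise ValueError("method_anovas requires exactly two methods")
    rows = []
    for metric in ("accuracy", "mean_rt", "mean_saccades", "mean_coverage"):
        sub = wide[metric].dropna()
        res = rm_anova(sub[methods[0]].to_numpy(), sub[methods[1]].to_numpy())
        rows.append({"metric": metric, "F": res.F, "df1": res.df[0],
                     "df2": res.df[1], "p": res.p})
    out = pd.DataFrame(rows).set_index("metric")
    if holm:
        from statsmodels.stats.multitest import multipletests
        out["p_holm"] = multipletests(out["p"].to_numpy(), method="holm")[1]
    return out


# ---------------------------------------------------------------------------
# trial CSV I/O (fixations as a JSON-encoded list column)
# ---------------------------------------------------------------------------

def write_trials_csv(trials: Sequence[TrialRecord], path) -> None:
    df = pd.DataFrame([{
        "participant_id": t.participant_id, "block": t.block, "method": t.method,
        "stimulus_id": t.stimulus_id, "response": t.response, "truth": t.truth,
        "reaction_time": t.reaction_time,
        "fixations": json.dumps([[float(y), float(x)] for y, x in t.fixations]),
        "n_saccades": t.n_saccades,
    } for t in trials])
    df.to_csv(path, index=False)


def read_trials_csv(path) -> list[TrialRecord]:
    df = pd.read_csv(path)
    return [TrialRecord(
        participant_id=str(r.participant_id), block=int(r.block), method=str(r.method),
        stimulus_id=str(r.stimulus_id), response=int(r.response), truth=int(r.truth),
        reaction_time=float(r.reaction_time),
        fixations=[(float(y), float(x)) for y, x in json.loads(r.fixations)],
        n_saccades=int(r.n_saccades),
    ) for r in df.itertuples()]
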