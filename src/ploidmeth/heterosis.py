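"""Ploidy-weighted mid-parent values and five-class heterosis classification.

For a triploid hybrid of a tetraploid and a diploid parent the mid-parent
value (MPV) weights the parents by genomic contribution, 2/3 and 1/3. A
hybrid trait is classified against its parents as additive (MPL: at the
MPV), dominant (HPL / LPL: at the high / low parent level) or
over-dominant (AHP / BLP: above the high parent / below the low parent),
with AMBIGUOUS surfaced when no class fits. The decision procedure tests
the strongest claims first:

1. hybrid mean above HP and one-sided test vs the high parent significant -> AHP
2. hybrid mean below LP and one-sided test vs the low parent significant -> BLP
3. two-sided test vs the high parent not significant -> HPL
4. two-sided test vs the low parent not significant -> LPL
5. one-sample two-sided test of the hybrid replicates vs the MPV (treated as
   a constant) not significant -> MPL
6. otherwise AMBIGUOUS

Two-sample comparisons default to pairwise t tests on the pooled residual
variance of the three groups (the one-way-ANOVA error term, df = N - 3),
which at triplicate sample sizes is markedly better powered than Welch's
test; Welch is available via ``method="welch"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .bisulfite import MethylationSummary


class Pattern(str, Enum):
    MPL = "MPL"
    HPL = "HPL"
    LPL = "LPL"
    AHP = "AHP"
    BLP = "BLP"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class ParentSpec:
    genotype: str
    weight: float


@dataclass(frozen=True)
class CrossDesign:
    """One hybrid with its dose-weighted parents (default 2/3 vs 1/3)."""

    hybrid_id: str
    parent_high_dose: ParentSpec
    parent_low_dose: ParentSpec

    def __post_init__(self) -> None:
        w1, w2 = self.parent_high_dose.weight, self.parent_low_dose.weight
        if w1 <= 0 or w2 <= 0 or abs(w1 + w2 - 1.0) > 1e-9:
            raise ValueError(f"parent weights must be positive and sum to 1, got {w1}, {w2}")

    @classmethod
    def triploid(cls, hybrid_id: str, tetraploid: str, diploid: str) -> "CrossDesign":
        return cls(hybrid_id, ParentSpec(tetraploid, 2 / 3), ParentSpec(diploid, 1 / 3))


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate measurements of one trait in one genotype."""

    genotype: str
    trait: str
    values: Tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if not all(np.isfinite(vals)):
            raise ValueError(f"{self.genotype}/{self.trait}: non-finite values")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class HeterosisCall:
    hybrid_id: str
    pattern: Pattern
    mpv: float
    hp: float
    lp: float
    hybrid_mean: float
    p_vs_hp: float       # two-sided
    p_vs_lp: float       # two-sided
    p_vs_mpv: float      # one-sample two-sided
    p_above_hp: float    # one-sided, hybrid > HP
    p_below_lp: float    # one-sided, hybrid < LP
    alpha: float
    degenerate: bool = False


@dataclass(frozen=True)
class TrendReport:
    hybrid_id: str
    scope: str       # island id or 'TOTAL'
    context: str     # CG / CHG / CHH / ALL
    hybrid_value: float
    mpv_value: float
    direction: str   # decrease / increase / unchanged


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int


def compute_mpv(p_high_dose_mean: float, p_low_dose_mean: float,
                design: CrossDesign) -> float:
    """Dose-weighted mid-parent value (2/3 x tetraploid + 1/3 x diploid by default)."""
    if not (np.isfinite(p_high_dose_mean) and np.isfinite(p_low_dose_mean)):
        raise ValueError("parent means must be finite")
    return (design.parent_high_dose.weight * p_high_dose_mean
            + design.parent_low_dose.weight * p_low_dose_mean)


def one_way_anova(groups: Sequence[ReplicateSet]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    With zero within-group variance everywhere, equal means give F = 0 and
    p = 1 by convention; unequal means give F = inf, p = 0.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.genotype!r} has n = {g.n} < 2")
    arrays = [np.asarray(g.values, dtype=float) for g in groups]
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, 1.0, df_b, df_w)
        return AnovaResult(float("inf"), 0.0, df_b, df_w)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), p, df_b, df_w)


def _pooled_mse(groups: Sequence[ReplicateSet]) -> Tuple[float, int]:
    arrays = [np.asarray(g.values, dtype=float) for g in groups]
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df = sum(a.size for a in arrays) - len(arrays)
    return float(ssw / df), df


def _two_sample(a: ReplicateSet, b: ReplicateSet, method: str,
                mse: float, df_err: int) -> Tuple[float, float, float, bool]:
    """p-values for a vs b: (two-sided, P(a>b) one-sided, P(a<b) one-sided, degenerate)."""
    diff = a.mean - b.mean
    if method == "welch":
        va, vb = np.var(a.values, ddof=1), np.var(b.values, ddof=1)
        if va == 0 and vb == 0:
            if diff == 0:
                return 1.0, 0.5, 0.5, True
            return 0.0, (0.0 if diff > 0 else 1.0), (0.0 if diff < 0 else 1.0), True
        se = np.sqrt(va / a.n + vb / b.n)
        df = (va / a.n + vb / b.n) ** 2 / (
            (va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1))
    elif method == "pooled":
        if mse == 0.0:
            if diff == 0:
                return 1.0, 0.5, 0.5, True
            return 0.0, (0.0 if diff > 0 else 1.0), (0.0 if diff < 0 else 1.0), True
        se = np.sqrt(mse * (1 / a.n + 1 / b.n))
        df = df_err
    else:
        raise ValueError("method must be 'pooled' or 'welch'")
    t = diff / se
    p_two = 2 * float(stats.t.sf(abs(t), df))
    p_gt = float(stats.t.sf(t, df))
    p_lt = float(stats.t.cdf(t, df))
    return min(p_two, 1.0), p_gt, p_lt, False


def _one_sample(x: ReplicateSet, value: float) -> Tuple[float, bool]:
    sd = float(np.std(x.values, ddof=1))
    if sd == 0.0:
        return (1.0, True) if x.mean == value else (0.0, True)
    t = (x.mean - value) / (sd / np.sqrt(x.n))
    return min(2 * float(stats.t.sf(abs(t), x.n - 1)), 1.0), False


def classify_expression_pattern(hybrid: ReplicateSet, p1: ReplicateSet,
                                p2: ReplicateSet, design: CrossDesign,
                                alpha: float = 0.05,
                                method: str = "pooled") -> HeterosisCall:
    """Classify a hybrid trait against its parents (see module docstring).

    ``p1``/``p2`` are matched to the design's high- and low-dose parents by
    genotype name when possible, else taken in that order. Exactly one
    pattern is returned for any input; zero-variance degeneracies are
    resolved by convention (unequal means significant) and flagged.
    """
    if not 0 < alpha <= 0.5:
        raise ValueError("alpha must lie in (0, 0.5]")
    for g in (hybrid, p1, p2):
        if g.n < 3:
            raise ValueError(f"group {g.genotype!r} has n = {g.n} < 3")
    if p1.genotype == design.parent_low_dose.genotype \
            and p2.genotype == design.parent_high_dose.genotype:
        p1, p2 = p2, p1
    mpv = compute_mpv(p1.mean, p2.mean, design)
    hp_set, lp_set = (p1, p2) if p1.mean >= p2.mean else (p2, p1)
    hp, lp = hp_set.mean, lp_set.mean
    mse, df_err = _pooled_mse([hybrid, p1, p2])
    p2s_hp, p_gt_hp, _, deg1 = _two_sample(hybrid, hp_set, method, mse, df_err)
    p2s_lp, _, p_lt_lp, deg2 = _two_sample(hybrid, lp_set, method, mse, df_err)
    p_mpv, deg3 = _one_sample(hybrid, mpv)
    degenerate = deg1 or deg2 or deg3

    hm = hybrid.mean
    if hm > hp and p_gt_hp < alpha:
        pattern = Pattern.AHP
    elif hm < lp and p_lt_lp < alpha:
        pattern = Pattern.BLP
    elif p2s_hp >= alpha:
        pattern = Pattern.HPL
    elif p2s_lp >= alpha:
        pattern = Pattern.LPL
    elif p_mpv >= alpha:
        pattern = Pattern.MPL
    else:
        pattern = Pattern.AMBIGUOUS
    return HeterosisCall(hybrid.genotype, pattern, mpv, hp, lp, hm,
                         p2s_hp, p2s_lp, p_mpv, p_gt_hp, p_lt_lp, alpha,
                         degenerate)


def ddct_relative_expression(ct_target: float, ct_reference: float,
                             calibrator_delta: float = 0.0) -> float:
    """Relative expression by the 2^-ddCt method (100% amplification efficiency)."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)
            and np.isfinite(calibrator_delta)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** (-((ct_target - ct_reference) - calibrator_delta)))


def methylation_mpv_trend(hybrid: Sequence[MethylationSummary],
                          p_high_dose: Sequence[MethylationSummary],
                          p_low_dose: Sequence[MethylationSummary],
                          design: CrossDesign,
                          dead_band: float = 0.0) -> List[TrendReport]:
    """Hybrid-vs-MPV methylation direction per scope x context.

    For every scope the hybrid shares with both parents, and for contexts
    CG/CHG/CHH (where assayed in all three) plus the pooled ALL fraction,
    the parental fractions are combined by :func:`compute_mpv` and compared
    with the hybrid's; a configurable dead band (default 0) maps small
    differences to 'unchanged'.
    """
    def by_scope(summaries: Sequence[MethylationSummary]) -> Dict[str, MethylationSummary]:
        return {s.scope: s for s in summaries}

    h_map, hi_map, lo_map = by_scope(hybrid), by_scope(p_high_dose), by_scope(p_low_dose)
    missing = set(h_map) - set(hi_map) - set(lo_map)
    if set(h_map) - set(hi_map) or set(h_map) - set(lo_map):
        raise ValueError(f"scope mismatch between hybrid and parents: {sorted(missing) or sorted(set(h_map))}")
    reports: List[TrendReport] = []
    hybrid_id = hybrid[0].genotype if hybrid else design.hybrid_id
    for scope in sorted(h_map):
        hs, ps_hi, ps_lo = h_map[scope], hi_map[scope], lo_map[scope]
        items: List[Tuple[str, float, float]] = []
        for ctx in ("CG", "CHG", "CHH"):
            if all(s.counts.get(ctx, (0, 0))[1] > 0 for s in (hs, ps_hi, ps_lo)):
                items.append((ctx, hs.fraction(ctx),
                              compute_mpv(ps_hi.fraction(ctx), ps_lo.fraction(ctx), design)))
        items.append(("ALL", hs.total_fraction,
                      compute_mpv(ps_hi.total_fraction, ps_lo.total_fraction, design)))
        for ctx, hv, mv in items:
            delta = hv - mv
            if delta > dead_band:
                direction = "increase"
            elif delta < -dead_band:
                direction = "decrease"
            else:
                direction = "unchanged"
            reports.append(TrendReport(hybrid_id, scope, ctx, hv, mv, direction))
    return reports


# ---------------------------------------------------------------------------
# File interfaces


def _parse_weight(w: Union[str, float, int]) -> float:
    if isinstance(w, str):
        return float(Fraction(w))
    return float(w)


def load_cross_designs(path: Union[str, Path]) -> List[CrossDesign]:
    """Cross designs from YAML: parent_high_dose / parent_low_dose / hybrids."""
    cfg = yaml.safe_load(Path(path).read_text())
    hi = ParentSpec(cfg["parent_high_dose"]["id"],
                    _parse_weight(cfg["parent_high_dose"].get("weight", "2/3")))
    lo = ParentSpec(cfg["parent_low_dose"]["id"],
                    _parse_weight(cfg["parent_low_dose"].get("weight", "1/3")))
    return [CrossDesign(str(h), hi, lo) for h in cfg["hybrids"]]


def read_replicates_tsv(path: Union[str, Path]) -> List[ReplicateSet]:
    """Replicates from TSV (genotype, trait, replicate, value) or Ct-mode TSV
    (genotype, trait, replicate, ct_target, ct_reference[, calibrator_delta])."""
    df = pd.read_csv(path, sep="\t")
    if "value" not in df.columns:
        delta = df["calibrator_delta"] if "calibrator_delta" in df.columns else 0.0
        df = df.assign(value=[
            ddct_relative_expression(t, r, d) for t, r, d in
            zip(df["ct_target"], df["ct_reference"],
                delta if hasattr(delta, "__iter__") else [delta] * len(df))
        ])
    sets = []
    for (genotype, trait), grp in df.groupby(["genotype", "trait"], sort=True):
        sets.append(ReplicateSet(str(genotype), str(trait),
                                 tuple(grp.sort_values("replicate")["value"])))
    return sets


def write_calls_tsv(calls: Sequence[HeterosisCall], path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        fh.write("hybrid\tpattern\tmpv\thp\tlp\thybrid_mean"
                 "\tp_vs_hp\tp_vs_lp\tp_vs_mpv\talpha\tdegenerate\n")
        for c in calls:
            fh.write(f"{c.hybrid_id}\t{c.pattern.value}\t{c.mpv:.6f}\t{c.hp:.6f}"
                     f"\t{c.lp:.6f}\t{c.hybrid_mean:.6f}\t{c.p_vs_hp:.6f}"
                     f"\t{c.p_vs_lp:.6f}\t{c.p_vs_mpv:.6f}\t{c.alpha:g}"
                     f"\t{int(c.degenerate)}\n")


def write_trend_tsv(reports: Sequence[TrendReport], path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        fh.write("hybrid\tscope\tcontext\thybrid_percent\tmpv_percent\tdirection\n")
        for r in reports:
            fh.write(f"{r.hybrid_id}\t{r.scope}\t{r.context}"
                     f"\t{100 * r.hybrid_value:.2f}\t{100 * r.mpv_value:.2f}"
                     f"\t{r.direction}\n")
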