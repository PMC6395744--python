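"""Closed-form muscle physiology computations and univariate group statistics.

Companions to the expression pipeline: relative fold change of transgenic vs
control means, linear-cable estimates of sarcolemmal membrane conductance
from two-microelectrode recordings, the chloride-conductance subtraction
(total conductance in normal solution minus potassium conductance in
chloride-free solution), ratiometric FURA-2 calcium calibration, and the
unpaired t-test / one-way ANOVA with Bonferroni post hoc / Pearson
correlation summaries used for group comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CableInput",
    "ConductanceSet",
    "Fura2Params",
    "GroupStatsResult",
    "PairwiseComparison",
    "fold_change",
    "cable_conductance",
    "chloride_conductance",
    "fura2_calcium",
    "unpaired_t_test",
    "one_way_anova",
    "pearson_correlation",
    "bonferroni_adjust",
    "group_stats",
]


@dataclass(frozen=True)
class CableInput:
    """Cable parameters of one fiber population.

    Rin: input resistance (Ohm); lam: space constant (cm); tau: membrane time
    constant (s); Ri: myoplasmic resistivity (Ohm*cm), 125 by convention for
    mammalian skeletal muscle.
    """

    Rin: float
    lam: float
    tau: float
    Ri: float = 125.0

    def validate(self) -> None:
        for name in ("Rin", "lam", "tau", "Ri"):
            if getattr(self, name) <= 0:
                raise ValueError(f"CableInput.{name} must be > 0, got {getattr(self, name)}")


@dataclass
class ConductanceSet:
    """Derived membrane quantities; gCl = gm - gK by definition."""

    gm: float | None = None  # total membrane conductance (S/cm^2)
    gK: float | None = None  # potassium conductance (S/cm^2)
    gCl: float | None = None  # chloride conductance (S/cm^2)
    diameter: float | None = None  # fiber diameter (cm)
    Cm: float | None = None  # specific membrane capacitance (F/cm^2)
    warning: str | None = None


@dataclass(frozen=True)
class Fura2Params:
    """Ratiometric FURA-2 calibration: R is the 340/380 nm excitation ratio.

    Rmin/Rmax and beta are determined in situ in ionomycin-permeabilized
    fibers and have no universal defaults; the dye's K_D defaults to 145 nM.
    """

    R: float
    Rmin: float
    Rmax: float
    beta: float
    K_D: float = 145.0

    def validate(self) -> None:
        if not self.Rmin < self.Rmax:
            raise ValueError(f"need Rmin < Rmax, got {self.Rmin} >= {self.Rmax}")
        if self.K_D <= 0:
            raise ValueError(f"K_D must be > 0, got {self.K_D}")
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float


@dataclass
class GroupStatsResult:
    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    posthoc: list[PairwiseComparison] = field(default_factory=list)
    flag: str | None = None


def fold_change(transgenic_mean: float, ctrl_mean: float) -> float:
    """Relative fold change FC = transgenic/control - 1 (negative = down)."""
    if ctrl_mean <= 0:
        raise ValueError(f"control mean must be > 0, got {ctrl_mean}")
    return transgenic_mean / ctrl_mean - 1.0


def cable_conductance(c: CableInput) -> ConductanceSet:
    """Membrane conductance from the infinite linear cable model.

    For an infinite cable, Rin = sqrt(rm * ri) / 2 and lambda = sqrt(rm / ri),
    so the per-length resistances follow as ri = 2*Rin/lambda and
    rm = 2*Rin*lambda.  The fiber diameter comes from the myoplasmic
    resistivity, d = 2*sqrt(Ri / (pi * ri)); the specific membrane resistance
    is Rm = rm * pi * d, giving gm = 1/Rm and Cm = tau/Rm.
    """
    c.validate()
    ri = 2.0 * c.Rin / c.lam
    rm = 2.0 * c.Rin * c.lam
    d = 2.0 * math.sqrt(c.Ri / (math.pi * ri))
    Rm = rm * math.pi * d
    return ConductanceSet(gm=1.0 / Rm, diameter=d, Cm=c.tau / Rm)


def chloride_conductance(gm_NP: float, gK_ClFree: float) -> ConductanceSet:
    """gCl = gm (normal solution) - gK (chloride-free solution).

    A negative result is returned as-is but flagged: it means the two
    solutions gave biologically inconsistent measurements.
    """
    if gm_NP < 0 or gK_ClFree < 0:
        raise ValueError("conductances must be >= 0")
    gcl = gm_NP - gK_ClFree
    warning = None
    if gcl < 0:
        warning = (
            f"gCl = {gcl:g} < 0: potassium conductance exceeds total membrane "
            "conductance; measurements are biologically inconsistent"
        )
    return ConductanceSet(gm=gm_NP, gK=gK_ClFree, gCl=gcl, warning=warning)


def fura2_calcium(p: Fura2Params) -> float:
    """Cytosolic [Ca2+]i (nM) = (R - Rmin)/(Rmax - R) * K_D * beta."""
    p.validate()
    if p.R < p.Rmin:
        raise ValueError(f"R = {p.R} below Rmin = {p.Rmin}")
    if p.R >= p.Rmax:
        raise ValueError(f"R = {p.R} at or above Rmax = {p.Rmax}: saturated ratio")
    return (p.R - p.Rmin) / (p.Rmax - p.R) * p.K_D * p.beta


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, str | None]:
    """Classic pooled-variance unpaired t; handles the zero-variance edge."""
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0.0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0, None
        return math.inf, df, 0.0, "zero pooled variance with unequal means"
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(df), float(p), None


def unpaired_t_test(a, b) -> GroupStatsResult:
    """Unpaired Student's t-test with pooled variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    t, df, p, flag = _pooled_t(a, b)
    return GroupStatsResult(test="unpaired t-test", statistic=t, df=(df,), p_value=p, flag=flag)


def bonferroni_adjust(p: float, m: int) -> float:
    """Bonferroni family-wise adjustment: min(1, m * p)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def one_way_anova(samples_by_group: dict[str, "np.ndarray | list"]) -> GroupStatsResult:
    """One-way ANOVA F with Bonferroni-corrected pairwise post hoc t-tests."""
    if len(samples_by_group) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in samples_by_group.items()}
    for g, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} needs >= 2 values")

    f, p = stats.f_oneway(*arrays.values())
    k = len(arrays)
    n_total = sum(len(v) for v in arrays.values())
    df = (float(k - 1), float(n_total - k))

    names = list(arrays)
    pairs = [(names[i], names[j]) for i in range(k) for j in range(i + 1, k)]
    posthoc = []
    for ga, gb in pairs:
        t, dft, praw, _ = _pooled_t(arrays[ga], arrays[gb])
        posthoc.append(
            PairwiseComparison(
                group_a=ga, group_b=gb, statistic=t, df=dft, p_raw=praw,
                p_adjusted=bonferroni_adjust(praw, len(pairs)),
            )
        )
    return GroupStatsResult(
        test="one-way ANOVA", statistic=float(f), df=df, p_value=float(p), posthoc=posthoc
    )


def pearson_correlation(x, y) -> GroupStatsResult:
    """Pearson r with the 2-tailed p-value for testing non-correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with >= 3 points")
    r, p = stats.pearsonr(x, y)
    return GroupStatsResult(
        test="pearson", statistic=float(r), df=(float(len(x) - 2),), p_value=float(p)
    )


def group_stats(samples_by_group: dict[str, "np.ndarray | list"]) -> GroupStatsResult:
    """Dispatch: exactly two groups -> unpaired t; more -> ANOVA + post hoc."""
    if len(samples_by_group) == 2:
        a, b = samples_by_group.values()
        return unpaired_t_test(a, b)
    return one_way_anova(samples_by_group)
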