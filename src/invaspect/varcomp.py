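"""One-way variance-components ANOVA for organoids grouped by tumor.

The phenotype of organoid i from tumor t is modeled as a tumor mean plus a
deviation, μ_t ~ Norm(μ0, σB²) and ε_ti ~ Norm(0, σW²), so that the total
organoid variance decomposes as σ0² = σB² + σW².  Tumors play the role of
families in a structured population; organoids are siblings.

Unbiased estimates follow the standard one-way ANOVA:

    σ̂0² = Σ (y − ȳ)² / (N − 1)              (total)
    σ̂W² = Σ_t Σ_i (y_ti − ȳ_t)² / (N − T)   (within, pooled)
    σ̂M² = Σ_t N_t (ȳ_t − ȳ)² / (T − 1)      (between-group mean square)
    σ̂B² = σ̂0² − σ̂W²                          (between-tumor heterogeneity)

The hypothesis of equal tumor means is tested with F = σ̂M²/σ̂W², which is
F(T−1, N−T)-distributed under the null.  A sampling-noise-negative σ̂B² is
floored at 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from invaspect.exceptions import DegenerateFitError
from invaspect.modelsel import GroupedData

__all__ = ["VarianceComponents", "anova", "variance_fractions"]


@dataclass(frozen=True)
class VarianceComponents:
    """Variance decomposition and the F test of equal tumor means."""

    sigma0_sq: float  # unbiased total variance
    sigmaW_sq: float  # pooled within-tumor variance
    sigmaM_sq: float  # between-group mean square
    sigmaB_sq: float  # between-tumor component, σ̂0² − σ̂W², floored at 0
    floored: bool  # True when σ̂0² − σ̂W² was negative
    f_stat: float
    df: tuple[int, int]  # (T − 1, N − T)
    p_value: float

    @property
    def between_fraction(self) -> float:
        return self.sigmaB_sq / self.sigma0_sq

    @property
    def within_fraction(self) -> float:
        return self.sigmaW_sq / self.sigma0_sq


def anova(data: GroupedData) -> VarianceComponents:
    """Variance components and the F test for one grouping level."""
    y = data.values
    n = data.n
    t = data.n_tumors
    if t < 2:
        raise ValueError("ANOVA requires at least 2 tumors")
    if n <= t:
        raise ValueError("ANOVA requires more organoids than tumors")
    grand = y.mean()
    per_tumor = data.split()
    sizes = np.array([len(g) for g in per_tumor])
    means = np.array([g.mean() for g in per_tumor])

    sigma0_sq = float(((y - grand) ** 2).sum() / (n - 1))
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in per_tumor)
    sigmaw_sq = ss_within / (n - t)
    if sigmaw_sq <= 0:
        raise DegenerateFitError("zero within-tumor variance")
    sigmam_sq = float((sizes * (means - grand) ** 2).sum() / (t - 1))
    f_stat = sigmam_sq / sigmaw_sq
    p = float(stats.f.sf(f_stat, t - 1, n - t))
    sigmab_sq = sigma0_sq - sigmaw_sq
    floored = sigmab_sq < 0
    return VarianceComponents(
        sigma0_sq=sigma0_sq,
        sigmaW_sq=float(sigmaw_sq),
        sigmaM_sq=sigmam_sq,
        sigmaB_sq=0.0 if floored else float(sigmab_sq),
        floored=floored,
        f_stat=float(f_stat),
        df=(t - 1, n - t),
        p_value=p,
    )


def variance_fractions(vc: VarianceComponents) -> tuple[float, float]:
    """(between, within) fractions of the total variance.

    The fractions sum to 1 unless the between component was floored at 0,
    in which case (0, 1) is returned and ``vc.floored`` is set.
    """
    if vc.sigma0_sq <= 0:
        raise ValueError("total variance must be positive")
    if vc.floored:
        return (0.0, 1.0)
    return (vc.sigmaB_sq / vc.sigma0_sq, vc.sigmaW_sq / vc.sigma0_sq)
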