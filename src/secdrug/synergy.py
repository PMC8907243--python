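"""Chou-Talalay median-effect fitting, combination index, dose-reduction index.

The median-effect equation fa/fu = (D/Dm)^m linearizes to

    log10(fa/(1-fa)) = m * log10(D) - m * log10(Dm)

so (m, Dm) come from ordinary least squares of the logit of the fraction
affected on log dose.  For two drugs at doses (d1, d2) producing a combined
effect level fa, the mutually exclusive combination index is

    CI = d1/Dx1 + d2/Dx2,   Dx_i = Dm_i * (fa/(1-fa))^(1/m_i)

with CI < 1 synergism, CI = 1 additive, CI > 1 antagonism, and the
dose-reduction index DRI_i = Dx_i/d_i (fold reduction of drug i's
single-agent dose achieved by the combination).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_ADDITIVE_TOL = 1e-9


@dataclass(frozen=True)
class MedianEffectFit:
    """Median-effect line: slope m (sigmoidicity), Dm (median-effect dose), r2."""

    m: float
    Dm: float
    r2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.Dm <= 0:
            raise ValueError("Dm must be positive")
        if self.n_points < 2:
            raise ValueError("fit needs at least 2 dose points")

    def dose_for_effect(self, fa: float) -> float:
        """Dx: the single-agent dose producing fraction affected fa."""
        if not 0.0 < fa < 1.0:
            raise ValueError("fa must be strictly in (0, 1)")
        return self.Dm * (fa / (1.0 - fa)) ** (1.0 / self.m)

    def effect_at(self, dose: float) -> float:
        """Fraction affected at a dose, from the median-effect equation."""
        if dose <= 0:
            raise ValueError("dose must be positive")
        ratio = (dose / self.Dm) ** self.m
        return ratio / (1.0 + ratio)


@dataclass(frozen=True)
class SynergyResult:
    fa: float
    d1: float
    d2: float
    Dx1: float
    Dx2: float
    CI: float
    DRI1: float | None
    DRI2: float | None
    call: str  # synergism | additive | antagonism


def fit_median_effect(doses, fa, clip: bool = False) -> MedianEffectFit:
    """OLS fit of the median-effect line from dose / fraction-affected pairs.

    ``fa`` values at exactly 0 or 1 have an undefined logit and are a hard
    error; pass ``clip=True`` to clip into [1e-6, 1 - 1e-6] first (an
    explicit, opt-in preprocessor for saturated assay wells).
    """
    d = np.asarray(doses, dtype=float)
    f = np.asarray(fa, dtype=float)
    if d.shape != f.shape or d.ndim != 1:
        raise ValueError("doses and fa must be 1-D and equally long")
    if len(d) < 2:
        raise ValueError("need at least 2 dose points")
    if (d <= 0).any():
        raise ValueError("doses must be positive")
    if clip:
        f = np.clip(f, 1e-6, 1.0 - 1e-6)
    if ((f <= 0) | (f >= 1)).any():
        raise ValueError(
            "fraction affected must be strictly in (0, 1); use clip=True to "
            "clip saturated values at 1e-6"
        )
    x = np.log10(d)
    y = np.log10(f / (1.0 - f))
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    Dm = 10.0 ** (-intercept / slope)
    return MedianEffectFit(m=float(slope), Dm=float(Dm), r2=min(r2, 1.0), n_points=len(d))


def combination_index(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    d1: float,
    d2: float,
    fa: float,
    mutually_exclusive: bool = True,
) -> SynergyResult:
    """Chou-Talalay combination index at effect level fa for doses (d1, d2).

    The default two-term form assumes mutually exclusive drug action (the
    standard CalcuSyn report); ``mutually_exclusive=False`` adds the
    cross-product third term for mutually nonexclusive drugs.
    """
    if not 0.0 < fa < 1.0:
        raise ValueError("fa must be strictly in (0, 1)")
    if d1 < 0 or d2 < 0:
        raise ValueError("doses must be non-negative")
    if d1 == 0 and d2 == 0:
        raise ValueError("at least one dose must be positive")
    Dx1 = fit1.dose_for_effect(fa)
    Dx2 = fit2.dose_for_effect(fa)
    ci = d1 / Dx1 + d2 / Dx2
    if not mutually_exclusive:
        ci += (d1 * d2) / (Dx1 * Dx2)
    if abs(ci - 1.0) <= _ADDITIVE_TOL:
        call = "additive"
    elif ci < 1.0:
        call = "synergism"
    else:
        call = "antagonism"
    return SynergyResult(
        fa=fa, d1=d1, d2=d2, Dx1=Dx1, Dx2=Dx2, CI=float(ci),
        DRI1=Dx1 / d1 if d1 > 0 else None,
        DRI2=Dx2 / d2 if d2 > 0 else None,
        call=call,
    )


def fa_from_viability(viability):
    """Fraction affected from a viability ratio: fa = 1 - viability."""
    v = np.asarray(viability, dtype=float)
    return 1.0 - v


def synergy_table(
    single1: pd.DataFrame,
    single2: pd.DataFrame,
    combo: pd.DataFrame,
    mutually_exclusive: bool = True,
    clip: bool = False,
) -> pd.DataFrame:
    """Per-combination-point synergy report from long-format viability tables.

    ``single1``/``single2``: columns (dose, viability_fraction) for each
    single agent; ``combo``: columns (d1, d2, viability_fraction).  Each
    combo row's observed fa gives one SynergyResult row.
    """
    fit1 = fit_median_effect(
        single1["dose"], fa_from_viability(single1["viability_fraction"]), clip=clip
    )
    fit2 = fit_median_effect(
        single2["dose"], fa_from_viability(single2["viability_fraction"]), clip=clip
    )
    rows = []
    for _, rec in combo.iterrows():
        fa = float(1.0 - rec["viability_fraction"])
        if clip:
            fa = float(np.clip(fa, 1e-6, 1.0 - 1e-6))
        res = combination_index(
            fit1, fit2, float(rec["d1"]), float(rec["d2"]), fa,
            mutually_exclusive=mutually_exclusive,
        )
        rows.append(
            {
                "fa": res.fa, "d1": res.d1, "d2": res.d2,
                "Dx1": res.Dx1, "Dx2": res.Dx2, "CI": res.CI,
                "DRI1": res.DRI1, "DRI2": res.DRI2, "call": res.call,
            }
        )
    return pd.DataFrame(rows)
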