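"""Drought and yield tolerance indices from plot-level yields.

Definitions (Y = yield, t ha⁻¹; p = full irrigation/control, s = reduced
irrigation/stress; bars denote trial means over all genotypes):

* drought intensity index        DII    = Ȳs / Ȳp
* overall yield loss             100 × (1 − DII)  [%]
* drought tolerance index        DTI_g  = (Ys_g / Yp_g) / DII
* reference-based DTI            DTI-R_g = (Ys_g / Yp_g) / DII_R,
  where DII_R is the stress/control ratio of a reference cultivar
  (so the reference's own DTI-R is exactly 1)
* yield tolerance index          YTI_g  = (Yp_g × Ys_g) / Ȳp²
  (the stress-tolerance-index form; rewards inherently high yield potential,
  whereas DTI rewards a small relative loss)

All indices are invariant to a global rescaling of the yields.  Report
rounding is two decimals, half-up.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "dii",
    "yield_loss_pct",
    "dti",
    "dti_ref",
    "yti",
    "tolerance_table",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def dii(mean_stress: float, mean_control: float) -> float:
    """Drought intensity index: ratio of trial mean yields, stress/control."""
    if mean_control <= 0 or mean_stress <= 0:
        raise ValueError("mean yields must be positive")
    return mean_stress / mean_control


def yield_loss_pct(dii_value: float) -> float:
    """Overall percent yield loss under stress: 100 × (1 − DII)."""
    if not 0 < dii_value < np.inf:
        raise ValueError("DII must be positive and finite")
    return 100.0 * (1.0 - dii_value)


def dti(ys: float, yp: float, dii_value: float) -> float:
    """Drought tolerance index: genotype stress/control ratio over trial DII."""
    if yp <= 0:
        raise ValueError("control yield must be positive")
    if dii_value <= 0:
        raise ValueError("DII must be positive")
    return (ys / yp) / dii_value


def dti_ref(ys: float, yp: float, dii_reference: float) -> float:
    """Reference-based DTI: genotype ratio over the reference cultivar's ratio."""
    if dii_reference <= 0:
        raise ValueError("reference DII must be positive")
    if yp <= 0:
        raise ValueError("control yield must be positive")
    return (ys / yp) / dii_reference


def yti(yp: float, ys: float, mean_control: float) -> float:
    """Yield tolerance index: (Yp × Ys) / Ȳp² (stress-tolerance-index form)."""
    if mean_control <= 0:
        raise ValueError("trial control mean must be positive")
    return (yp * ys) / mean_control**2


def tolerance_table(
    plots: pd.DataFrame,
    reference: str = "Regalona",
    yield_col: str = "yield",
    control_label: str = "FI",
    stress_label: str = "RI",
    rounded: bool = False,
) -> pd.DataFrame:
    """Per-genotype tolerance indices from a plot-level trait table.

    Parameters
    ----------
    plots : DataFrame with ``genotype``, ``treatment`` and ``yield_col``
        columns (one row per plot).
    reference : genotype whose stress/control ratio defines DII_R.
    rounded : apply the two-decimal report rounding to the index columns.

    Returns
    -------
    DataFrame indexed by genotype with columns Yp, Ys, ratio, DTI, DTI_R, YTI;
    trial-level DII, yield-loss % and DII_R are attached in ``.attrs``.
    """
    means = (
        plots.groupby(["genotype", "treatment"], observed=True)[yield_col]
        .mean()
        .unstack("treatment")
    )
    for lab in (control_label, stress_label):
        if lab not in means.columns:
            raise ValueError(f"treatment level {lab!r} missing from plot table")
    if reference not in means.index:
        raise ValueError(f"reference genotype {reference!r} absent from trial")
    yp = means[control_label]
    ys = means[stress_label]
    if (yp <= 0).any() or (ys <= 0).any():
        raise ValueError("all genotype mean yields must be positive")

    mean_p = float(plots.loc[plots["treatment"] == control_label, yield_col].mean())
    mean_s = float(plots.loc[plots["treatment"] == stress_label, yield_col].mean())
    trial_dii = dii(mean_s, mean_p)
    ratio = ys / yp
    dii_r = float(ratio.loc[reference])

    table = pd.DataFrame(
        {
            "Yp": yp,
            "Ys": ys,
            "ratio": ratio,
            "DTI": ratio / trial_dii,
            "DTI_R": ratio / dii_r,
            "YTI": (yp * ys) / mean_p**2,
        }
    )
    table.attrs["DII"] = trial_dii
    table.attrs["DII_R"] = dii_r
    table.attrs["yield_loss_pct"] = yield_loss_pct(trial_dii)
    table.attrs["reference"] = reference
    if rounded:
        for col in ("ratio", "DTI", "DTI_R", "YTI"):
            table[col] = table[col].map(round_half_up)
    return table
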