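"""Surface-plasmon-resonance bookkeeping: complex half-life and crossblocking.

Two small formulas used when characterizing antibody panels:

* the half-life of an immune complex, in minutes, from the dissociation rate
  constant ``kd`` (1/s): ``t_half = ln(2) / (60 * kd)``;
* the crossblocking molar ratio, in percent, from the SPR binding signals of
  a secondary antibody injected after a primary one over a ligand-saturated
  sensor: ``MR = 100 * secondary / primary``.  A ratio near zero means the
  two antibodies compete for the same epitope.

Raw sensorgram fitting is out of scope; these start at the instrument's
reported rate constants or plateau signals.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import DomainError

LN2 = math.log(2.0)


def halflife_from_kd(kd: float) -> float:
    """Dissociation half-life in minutes from kd in 1/s."""
    if kd <= 0 or not math.isfinite(kd):
        raise DomainError(f"kd must be positive and finite, got {kd}")
    return LN2 / (60.0 * kd)


def kd_from_halflife(t_half_min: float) -> float:
    """Exact inverse of :func:`halflife_from_kd`."""
    if t_half_min <= 0 or not math.isfinite(t_half_min):
        raise DomainError(f"half-life must be positive and finite, got {t_half_min}")
    return LN2 / (60.0 * t_half_min)


def molar_ratio(primary_signal: float, secondary_signal: float) -> float:
    """Crossblocking molar ratio in percent; NaN when the primary signal is 0."""
    if primary_signal < 0 or secondary_signal < 0:
        raise DomainError("signals must be non-negative")
    if primary_signal == 0:
        return float("nan")
    return 100.0 * secondary_signal / primary_signal


def molar_ratio_matrix(primary_signals, secondary_signals,
                       labels=None) -> pd.DataFrame:
    """Elementwise percent matrix ``100 * secondary / primary``.

    ``primary_signals[i]`` is the plateau of antibody i injected first;
    ``secondary_signals[i][j]`` the plateau of antibody j injected after i.
    Cells with zero primary signal are NaN (undefined, not an error).
    """
    primary = np.asarray(primary_signals, dtype=float)
    secondary = np.asarray(secondary_signals, dtype=float)
    if secondary.shape != (len(primary), len(primary)):
        raise DomainError(
            f"secondary matrix shape {secondary.shape} does not match "
            f"{len(primary)} primary signals")
    if (primary < 0).any() or (secondary < 0).any():
        raise DomainError("signals must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = 100.0 * secondary / primary[:, None]
    ratios[primary == 0, :] = np.nan
    if labels is None:
        labels = [f"ab{i+1}" for i in range(len(primary))]
    return pd.DataFrame(ratios, index=pd.Index(labels, name="primary"),
                        columns=pd.Index(labels, name="secondary"))
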