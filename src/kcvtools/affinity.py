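"""Docking post-processing: ΔG ↔ Ki conversion and the predicted-vs-
experimental binding-affinity correlation.

Ki = exp(ΔG / RT) with R = 8.3145 J/(K·mol) and T = 298.15 K; ΔG is in
kJ/mol and negative for favorable binding, so Ki < 1 for binders.  The
experimental Ki values are treated as dimensionless (activity coefficient 1,
dilute solution), which makes them directly comparable to the docking
estimate.  The packaged reference table lists the five classical Kcv
blockers with their docking-predicted and experimental Ki.
"""

from __future__ import annotations

import math
from io import StringIO

import pandas as pd
from scipy.stats import pearsonr

R_GAS = 8.3145       # J / (K mol)
T_DEFAULT = 298.15   # K

# docking-predicted vs experimental dimensionless Ki for five Kcv blockers
_BLOCKER_TABLE_CSV = """\
name,ki_pred,ki_exp
amantadine,7.04e-4,8.0e-4
TEA,2.71e-3,4.1e-4
rimantadine,2.15e-4,8.8e-5
sotalol,1.09e-4,7.2e-5
bretylium_tosylate,5.57e-5,3.4e-5
"""


class UndefinedCorrelationError(ValueError):
    """Zero variance in one of the Ki columns."""


def ki_from_dg(dg_kjmol: float, temperature: float = T_DEFAULT) -> float:
    """Dimensionless inhibition constant from a binding free energy (kJ/mol)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(dg_kjmol * 1000.0 / (R_GAS * temperature))


def dg_from_ki(ki: float, temperature: float = T_DEFAULT) -> float:
    """Binding free energy (kJ/mol) from a dimensionless Ki; inverse of
    :func:`ki_from_dg`."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if ki <= 0:
        raise ValueError("Ki must be positive")
    return math.log(ki) * R_GAS * temperature / 1000.0


def load_table(name: str = "kcv_blockers") -> pd.DataFrame:
    """Packaged affinity tables by name.

    "kcv_blockers": the five-blocker reference set with docking-predicted and
    experimental dimensionless Ki, plus the implied ΔG (kJ/mol).
    """
    if name != "kcv_blockers":
        raise KeyError(f"unknown affinity table {name!r}")
    df = pd.read_csv(StringIO(_BLOCKER_TABLE_CSV))
    df["dg_kJmol"] = [dg_from_ki(k) for k in df["ki_pred"]]
    return df[["name", "dg_kJmol", "ki_pred", "ki_exp"]]


def affinity_correlation(table: pd.DataFrame, scale: str = "log") -> float:
    """Pearson correlation between predicted and experimental Ki.

    ``scale="log"`` (default) correlates log10 Ki — equivalent to
    correlating binding free energies; ``scale="linear"`` uses the raw Ki.
    """
    if scale not in ("log", "linear"):
        raise ValueError("scale must be 'log' or 'linear'")
    rows = table.dropna(subset=["ki_pred", "ki_exp"])
    if len(rows) < 3:
        raise ValueError("need at least three complete records")
    if (rows["ki_pred"] <= 0).any() or (rows["ki_exp"] <= 0).any():
        raise ValueError("Ki values must be positive")
    x, y = rows["ki_pred"].to_numpy(), rows["ki_exp"].to_numpy()
    if scale == "log":
        import numpy as np

        x, y = np.log10(x), np.log10(y)
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("zero variance in a Ki column")
    return float(pearsonr(x, y).statistic)
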