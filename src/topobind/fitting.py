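"""Fit the instrument scale factor alpha to measured intensity tables.

The predicted intensity is I = alpha * c_bound, a line through the origin;
alpha is the single free parameter connecting the binding model to gel or
plate-reader intensities. An optional weighted variant uses 1/variance
weights when per-row standard deviations are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .equilibrium import solve_equilibrium
from .params import Conditions, DNASubstrate, IntercalatorParams, SolverSettings

__all__ = ["AlphaFit", "predict_c_bound", "fit_alpha", "generate_gel_fixture"]

#: Required columns of an intensity table.
TABLE_COLUMNS = ["c_dna_bp", "c_total", "topology", "dLk0", "intensity"]


@dataclass(frozen=True)
class AlphaFit:
    """Slope-through-origin fit of measured intensity vs model c_bound."""

    alpha: float
    se_alpha: float
    residuals: np.ndarray
    n_rows: int


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"intensity table missing columns: {missing}")
    if len(table) < 2:
        raise ValueError("need at least 2 rows to fit alpha")
    if (table["intensity"] < 0).any():
        raise ValueError("intensities must be non-negative")


def predict_c_bound(
    table: pd.DataFrame,
    dye: IntercalatorParams,
    dna_template: DNASubstrate,
    cond_template: Conditions,
    settings: SolverSettings | None = None,
) -> np.ndarray:
    """Model-predicted bound-dye concentration (M) for each table row."""
    _validate_table(table)
    out = np.empty(len(table))
    for i, row in enumerate(table.itertuples(index=False)):
        dna = dna_template.with_(topology=row.topology, dLk0=row.dLk0)
        cond = cond_template.with_(c_total=row.c_total, c_dna_bp=row.c_dna_bp)
        out[i] = solve_equilibrium(dna, dye, cond, settings).c_bound
    return out


def fit_alpha(
    table: pd.DataFrame,
    dye: IntercalatorParams,
    dna_template: DNASubstrate,
    cond_template: Conditions,
    settings: SolverSettings | None = None,
    sd_column: str | None = None,
) -> AlphaFit:
    """Least-squares slope of measured intensity against model c_bound.

    With ``sd_column`` naming a column of per-row standard deviations, the
    fit is weighted by 1/sd^2.

    Raises
    ------
    ValueError
        If the model predicts zero binding for every row (slope undefined).
    """
    x = predict_c_bound(table, dye, dna_template, cond_template, settings)
    y = table["intensity"].to_numpy(dtype=float)
    if not np.any(x > 0):
        raise ValueError("model predicts zero binding for all rows; cannot fit alpha")
    if sd_column is not None:
        sd = table[sd_column].to_numpy(dtype=float)
        if np.any(sd <= 0):
            raise ValueError("standard deviations must be positive for weighting")
        w = 1.0 / sd**2
    else:
        w = np.ones_like(x)
    sxx = float(np.sum(w * x * x))
    alpha = float(np.sum(w * x * y)) / sxx
    residuals = y - alpha * x
    dof = max(len(x) - 1, 1)
    s2 = float(np.sum(w * residuals**2)) / dof
    se_alpha = float(np.sqrt(s2 / sxx))
    return AlphaFit(alpha=alpha, se_alpha=se_alpha, residuals=residuals, n_rows=len(x))


def generate_gel_fixture(
    dye: IntercalatorParams,
    dna_list: list[DNASubstrate],
    c_total_list: list[float],
    c_dna_list: list[float],
    alpha_true: float,
    noise_frac: float = 0.0,
    seed: int | None = None,
    cond_template: Conditions | None = None,
    settings: SolverSettings | None = None,
) -> pd.DataFrame:
    """Synthesize an intensity table emulating gel quantification data.

    Intensities are model predictions (staining correction from
    ``cond_template`` applied) times ``alpha_true``, with multiplicative
    Gaussian noise of fractional SD ``noise_frac``. Deterministic per seed.
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be non-negative")
    base = cond_template if cond_template is not None else Conditions(
        c_total=0.0, c_dna_bp=1e-9
    )
    rows = []
    for dna in dna_list:
        for c_total in c_total_list:
            for c_dna in c_dna_list:
                for topo in ("closed", "open"):
                    cond = base.with_(c_total=c_total, c_dna_bp=c_dna)
                    state = solve_equilibrium(dna.with_(topology=topo), dye, cond, settings)
                    rows.append(
                        {
                            "c_dna_bp": c_dna,
                            "c_total": c_total,
                            "topology": topo,
                            "dLk0": dna.dLk0,
                            "intensity": alpha_true * state.c_bound,
                        }
                    )
    df = pd.DataFrame(rows)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        df["intensity"] *= 1.0 + rng.normal(0.0, noise_frac, size=len(df))
        df["intensity"] = df["intensity"].clip(lower=0.0)
    return df
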