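"""Calibrator-relative expression (delta-delta-Ct) with multi-reference,
efficiency-aware normalization.

Per replicate combination (biological x technical), the target's log2
relative quantity is computed against the geometric mean of the reference
genes' quantities; fold changes are expressed relative to the mean of the
calibrator condition's replicates. With every efficiency at the default
E = 2 this reduces exactly to the classic -ddCt; with per-gene
efficiencies it is the log2 of the efficiency-corrected (Pfaffl) ratio.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ValidationError
from .io import CtTable, EfficiencyMap


def _as_efficiency_map(eff) -> EfficiencyMap:
    if eff is None:
        return EfficiencyMap()
    if isinstance(eff, EfficiencyMap):
        return eff
    return EfficiencyMap(dict(eff))


def normalization_factor(
    ct_values: Mapping[str, float],
    references: Sequence[str],
    efficiencies: EfficiencyMap | dict | None = None,
) -> float:
    """Geometric mean of the reference genes' relative quantities E_r^(-Ct_r).

    A single reference degenerates to that gene's own quantity. The absolute
    scale is arbitrary — it cancels in the calibrator ratio.
    """
    if not references:
        raise ValidationError("at least one reference gene is required")
    eff = _as_efficiency_map(efficiencies)
    logs = [-float(ct_values[r]) * np.log2(eff.get_efficiency(r)) for r in references]
    return float(2.0 ** np.mean(logs))


def pfaffl_ratio(
    e_target: float, dct_target: float, e_ref: float, dct_ref: float
) -> float:
    """Efficiency-corrected expression ratio e_t^dCt_t / e_ref^dCt_ref,
    with dCt = Ct_calibrator - Ct_sample for each gene. With both
    efficiencies at 2, log2 of the ratio equals -ddCt exactly."""
    for name, e in (("e_target", e_target), ("e_ref", e_ref)):
        if not (1.0 < e <= 2.0):
            raise ValidationError(f"{name} must be in (1, 2], got {e}")
    return float(e_target**dct_target / e_ref**dct_ref)


def delta_delta_ct(
    table: CtTable,
    target: str,
    references: Sequence[str],
    calibrator: tuple[str, str, str],
    efficiencies: EfficiencyMap | dict | None = None,
) -> pd.DataFrame:
    """Calibrator-relative log2 fold changes of ``target`` per condition cell.

    Every (strain, condition, timepoint, bio_rep, tech_rep) combination with
    a Ct for the target and all references forms one replicate; replicates
    missing any required gene are excluded with a warning. Per cell the
    per-replicate log2 fold changes (vs the mean of the calibrator cell's
    replicates) are averaged; ``sd`` is their n-1 SD (0.0 for a single
    replicate). The calibrator cell's log2fc is 0 by construction.

    Returns a frame with strain / condition / timepoint / log2fc / sd /
    n_replicates, ordered by first appearance in the table.
    """
    eff = _as_efficiency_map(efficiencies)
    needed = [target] + [r for r in references if r != target]
    df = table.data[table.data["gene"].isin(set(needed) | {target})]
    wide = df.pivot_table(
        index=["strain", "condition", "timepoint", "bio_rep", "tech_rep"],
        columns="gene",
        values="ct",
        aggfunc="mean",
    )
    for gene in [target, *references]:
        if gene not in wide.columns:
            raise ValidationError(f"gene {gene!r} absent from the Ct table")
    complete = wide[[target, *dict.fromkeys(references)]].notna().all(axis=1)
    if (~complete).any():
        warnings.warn(
            f"excluding {int((~complete).sum())} replicate(s) with missing "
            f"target/reference Ct",
            stacklevel=2,
        )
        wide = wide[complete]

    log2e = {g: np.log2(eff.get_efficiency(g)) for g in dict.fromkeys([target, *references])}
    y = -wide[target] * log2e[target] + np.mean(
        [wide[r] * log2e[r] for r in references], axis=0
    )

    cells = wide.index.droplevel(["bio_rep", "tech_rep"])
    cal_mask = np.array([c == tuple(calibrator) for c in cells])
    if not cal_mask.any():
        raise ValidationError(
            f"calibrator cell {calibrator!r} has no usable replicates"
        )
    log2fc = y - float(y[cal_mask].mean())

    out_rows = []
    seen = []
    for cell in cells:
        if cell not in seen:
            seen.append(cell)
    for cell in seen:
        vals = log2fc[np.array([c == cell for c in cells])]
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out_rows.append(
            {
                "strain": cell[0],
                "condition": cell[1],
                "timepoint": cell[2],
                "log2fc": float(vals.mean()),
                "sd": sd,
                "n_replicates": int(len(vals)),
            }
        )
    out = pd.DataFrame(out_rows)
    out.attrs["target"] = target
    out.attrs["references"] = list(references)
    out.attrs["calibrator"] = tuple(calibrator)
    return out


class RelativeQuantifier(BaseEstimator):
    """Delta-delta-Ct relative quantification as an sklearn-style estimator.

    Parameters
    ----------
    target : str
        Gene whose expression is quantified.
    references : sequence of str
        One or more reference genes; multiple references are combined by the
        geometric mean of their relative quantities.
    calibrator : (strain, condition, timepoint)
        Condition cell whose mean defines log2fc = 0.
    efficiencies : mapping gene -> E, optional

    Attributes
    ----------
    results_ : pd.DataFrame
        One row per condition cell: log2fc, sd, n_replicates.
    """

    def __init__(self, target: str, references: Sequence[str],
                 calibrator: tuple[str, str, str], efficiencies=None):
        self.target = target
        self.references = references
        self.calibrator = calibrator
        self.efficiencies = efficiencies

    def fit(self, X: CtTable, y=None):
        if not isinstance(X, CtTable):
            raise TypeError("RelativeQuantifier.fit expects a CtTable")
        self.results_ = delta_delta_ct(
            X, self.target, list(self.references), tuple(self.calibrator),
            efficiencies=self.efficiencies,
        )
        return self
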