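"""Statistical analysis of emergent CA topographies.

The 12 areas tile a 2 x 2 x 3 within-subject factor structure —
ExtraPeri (perisylvian / extrasylvian), FrontoTemp (frontal / temporal)
and ModSpecificity (primary / secondary / multimodal) — crossed with
WordType (object / action); network instances play the role of subjects.
The module provides a general balanced within-subject (repeated-measures)
factorial ANOVA, paired planned comparisons, and Bonferroni correction.

The ANOVA uses the standard univariate sums-of-squares decomposition in
which each effect is tested against its interaction with subjects; no
sphericity correction is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .areas import (Area, FRONTAL, MULTIMODAL, PERISYLVIAN, PRIMARY,
                    SECONDARY)

__all__ = ["AnovaEffect", "area_factors", "topography_dataset", "rm_anova",
           "paired_t", "planned_comparisons", "bonferroni_threshold"]

FOUR_WAY = ("ExtraPeri", "FrontoTemp", "ModSpecificity", "WordType")
THREE_WAY = ("FrontoTemp", "ModSpecificity", "WordType")


@dataclass(frozen=True)
class AnovaEffect:
    F: float
    df1: int
    df2: int
    p: float


def area_factors(area: Area) -> dict[str, str]:
    return {
        "ExtraPeri": "peri" if area in PERISYLVIAN else "extra",
        "FrontoTemp": "frontal" if area in FRONTAL else "temporal",
        "ModSpecificity": ("primary" if area in PRIMARY
                           else "secondary" if area in SECONDARY
                           else "multimodal"),
    }


def topography_dataset(means_by_instance: dict[int, pd.DataFrame]
                       ) -> pd.DataFrame:
    """Long-format dataset from per-instance category-mean tables.

    ``means_by_instance`` maps instance id -> DataFrame indexed by area
    name with columns object/action (as from
    :func:`semground.ca.category_means`).
    """
    rows = []
    for inst, wide in means_by_instance.items():
        for area in Area:
            fac = area_factors(area)
            for word_type in ("object", "action"):
                rows.append({"instance": inst, "area": area.name, **fac,
                             "WordType": word_type,
                             "n_cells": float(wide.loc[area.name, word_type])})
    return pd.DataFrame(rows)


def _to_array(df: pd.DataFrame, factors: tuple[str, ...], subject: str,
              value: str) -> tuple[np.ndarray, list[list[str]]]:
    subjects = sorted(df[subject].unique())
    levels = [sorted(df[f].unique()) for f in factors]
    shape = (len(subjects),) + tuple(len(l) for l in levels)
    arr = np.full(shape, np.nan)
    cell = df.groupby([subject, *factors])[value].agg(["mean", "count"])
    for key, row in cell.iterrows():
        idx = (subjects.index(key[0]),) + tuple(
            levels[i].index(key[1 + i]) for i in range(len(factors)))
        arr[idx] = row["mean"]
    if np.isnan(arr).any():
        raise ValueError("unbalanced design: missing subject x cell data")
    return arr, levels


def rm_anova(data: pd.DataFrame, factors: tuple[str, ...] | list[str], *,
             subject: str = "instance", value: str = "n_cells"
             ) -> dict[str, AnovaEffect]:
    """Balanced fully-within repeated-measures ANOVA.

    ``data`` is long-format with one value per subject x factor cell
    (values within a cell are averaged first, e.g. over the six words of
    a category).  Returns ``{effect_name: AnovaEffect}`` with effect names
    like ``"ModSpecificity"`` or ``"FrontoTemp:WordType"``; each effect is
    tested against its subject interaction.
    """
    factors = tuple(factors)
    arr, levels = _to_array(data, factors, subject, value)
    if arr.shape[0] < 2:
        raise ValueError("need at least two subjects")
    ndim = arr.ndim
    axis_sizes = arr.shape
    all_axes = tuple(range(ndim))    # axis 0 = subject

    # factorial decomposition by inclusion-exclusion over axis subsets
    terms: dict[frozenset, np.ndarray] = {}
    ss: dict[frozenset, float] = {}
    dfs: dict[frozenset, int] = {}
    subsets = [frozenset(c) for r in range(ndim + 1)
               for c in combinations(all_axes, r)]
    for S in subsets:
        drop = tuple(a for a in all_axes if a not in S)
        m = arr.mean(axis=drop, keepdims=True) if drop else arr.astype(float)
        term = m - sum((terms[U] for U in terms if U < S), np.zeros(()))
        terms[S] = term
        mult = int(np.prod([axis_sizes[a] for a in drop])) if drop else 1
        ss[S] = float(np.sum(term ** 2)) * mult
        dfs[S] = int(np.prod([axis_sizes[a] - 1 for a in S])) if S else 1

    out: dict[str, AnovaEffect] = {}
    factor_axes = tuple(range(1, ndim))
    # sums of squares at the rounding floor count as exactly zero
    tiny = 1e-12 * (float(np.sum(arr.astype(float) ** 2)) + 1.0)
    for r in range(1, len(factor_axes) + 1):
        for comb in combinations(factor_axes, r):
            S = frozenset(comb)
            err = frozenset((0, *comb))
            df1, df2 = dfs[S], dfs[err]
            ms_eff = ss[S] / df1 if df1 and ss[S] > tiny else 0.0
            ms_err = ss[err] / df2 if df2 and ss[err] > tiny else 0.0
            if ms_err <= 0.0:
                F = 0.0 if ms_eff <= 0.0 else float("inf")
            else:
                F = ms_eff / ms_err
            p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
            name = ":".join(factors[a - 1] for a in sorted(comb))
            out[name] = AnovaEffect(F=float(F), df1=df1, df2=df2, p=p)
    return out


def paired_t(data: pd.DataFrame, area: Area | str, *,
             subject: str = "instance", value: str = "n_cells"
             ) -> tuple[float, int, float]:
    """Two-sided paired t-test of object vs action means in one area.

    Returns ``(t, df, p)``; pairs are per-instance category means.
    """
    name = area.name if isinstance(area, Area) else area
    sub = data[data.area == name]
    wide = sub.pivot_table(index=subject, columns="WordType", values=value)
    if wide.shape[0] < 2 or wide.isna().any().any():
        raise ValueError("need >= 2 complete object/action pairs")
    obj, act = wide["object"].to_numpy(), wide["action"].to_numpy()
    if np.allclose(obj, act):
        return 0.0, len(obj) - 1, 1.0
    t, p = sps.ttest_rel(obj, act)
    return float(t), len(obj) - 1, float(p)


def planned_comparisons(data: pd.DataFrame, areas=None, *,
                        subject: str = "instance", value: str = "n_cells"
                        ) -> pd.DataFrame:
    """Paired object-vs-action tests for each area (default: all 12)."""
    areas = list(Area) if areas is None else list(areas)
    rows = []
    for area in areas:
        t, df, p = paired_t(data, area, subject=subject, value=value)
        rows.append({"area": area.name if isinstance(area, Area) else area,
                     "t": t, "df": df, "p": p})
    return pd.DataFrame(rows)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni per-comparison threshold alpha / m, at 4 decimals."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return round(alpha / m, 4)
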