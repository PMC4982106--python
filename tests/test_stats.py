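"""Repeated-measures ANOVA, paired comparisons and Bonferroni threshold."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from semground.areas import Area
from semground.stats import (FOUR_WAY, AnovaEffect, area_factors,
                             bonferroni_threshold, paired_t,
                             planned_comparisons, rm_anova,
                             topography_dataset)


def long_df(arr, factors):
    """Long-format frame from array (n_subj, l1, ..., lk)."""
    rows = []
    it = np.ndindex(*arr.shape)
    for idx in it:
        row = {"instance": idx[0], "n_cells": float(arr[idx])}
        for f, i in zip(factors, idx[1:]):
            row[f] = f"{f}_l{i}"
        rows.append(row)
    return pd.DataFrame(rows)


def brute_force_two_way(arr):
    """Textbook within-subject sums-of-squares for a (subjects x A x B) array."""
    n, a, b = arr.shape
    grand = arr.mean()
    A = arr.mean(axis=(0, 2)) - grand
    B = arr.mean(axis=(0, 1)) - grand
    S = arr.mean(axis=(1, 2)) - grand
    AB = (arr.mean(axis=0) - grand - A[:, None] - B[None, :])
    AS = (arr.mean(axis=2) - grand - S[:, None] - A[None, :])
    BS = (arr.mean(axis=1) - grand - S[:, None] - B[None, :])
    ABS = (arr - grand - S[:, None, None] - A[None, :, None]
           - B[None, None, :] - AB[None, :, :] - AS[:, :, None]
           - BS[:, None, :])
    out = {}
    out["A"] = (n * b * (A**2).sum(), (a - 1), b * (AS**2).sum(),
                (a - 1) * (n - 1))
    out["B"] = (n * a * (B**2).sum(), (b - 1), a * (BS**2).sum(),
                (b - 1) * (n - 1))
    out["A:B"] = (n * (AB**2).sum(), (a - 1) * (b - 1), (ABS**2).sum(),
                  (a - 1) * (b - 1) * (n - 1))
    return {k: (ss / df1) / (sse / df2)
            for k, (ss, df1, sse, df2) in out.items()}


@pytest.mark.parametrize("shape,seed", [((3, 2, 2), 0), ((4, 3, 2), 1),
                                        ((6, 2, 3), 2), ((4, 4, 4), 3)])
def test_two_way_matches_textbook_decomposition(shape, seed):
    arr = np.random.default_rng(seed).normal(size=shape) + \
        np.arange(shape[1])[None, :, None]
    df = long_df(arr, ["A", "B"])
    res = rm_anova(df, ("A", "B"))
    oracle = brute_force_two_way(arr)
    for eff in ("A", "B", "A:B"):
        assert res[eff].F == pytest.approx(oracle[eff], rel=1e-9)


def test_two_way_matches_statsmodels():
    from statsmodels.stats.anova import AnovaRM
    arr = np.random.default_rng(5).normal(size=(6, 2, 3))
    df = long_df(arr, ["A", "B"])
    ours = rm_anova(df, ("A", "B"))
    sm = AnovaRM(df, depvar="n_cells", subject="instance",
                 within=["A", "B"]).fit().anova_table
    for eff, key in (("A", "A"), ("B", "B"), ("A:B", "A:B")):
        assert ours[eff].F == pytest.approx(sm.loc[key, "F Value"], rel=1e-8)
        assert ours[eff].df1 == sm.loc[key, "Num DF"]
        assert ours[eff].df2 == sm.loc[key, "Den DF"]


def test_null_effect_gives_zero_F():
    arr = np.random.default_rng(2).normal(size=(4, 3, 1))
    arr = np.repeat(arr, 2, axis=2)         # identical across factor B levels
    df = long_df(arr, ["A", "B"])
    res = rm_anova(df, ("A", "B"))
    assert res["B"].F == pytest.approx(0.0, abs=1e-18)
    assert res["B"].p == pytest.approx(1.0)


def test_four_way_topography_design_is_balanced():
    rng = np.random.default_rng(9)
    means = {i: pd.DataFrame(rng.uniform(0, 30, size=(12, 2)),
                             index=[a.name for a in Area],
                             columns=["object", "action"])
             for i in range(5)}
    data = topography_dataset(means)
    res = rm_anova(data, FOUR_WAY)
    assert set(res) >= {"ModSpecificity", "WordType",
                        "ExtraPeri:FrontoTemp:ModSpecificity:WordType"}
    for eff in res.values():
        assert isinstance(eff, AnovaEffect)
        assert eff.F >= 0 and 0 <= eff.p <= 1
    # ModSpecificity has 3 levels: df1 = 2, df2 = 2*(n-1) = 8
    assert res["ModSpecificity"].df1 == 2
    assert res["ModSpecificity"].df2 == 8


def test_interaction_p_uniform_under_label_shuffling():
    """WordType shuffling yields uniform interaction p-values (KS test)."""
    rng = np.random.default_rng(11)
    base = rng.uniform(5, 30, size=(6, 12))     # instance x area, no category effect
    pvals = []
    for _ in range(200):
        rows = []
        for inst in range(6):
            for ai, area in enumerate(Area):
                fac = area_factors(area)
                vals = base[inst, ai] + rng.normal(0, 2, 2)
                order = rng.permutation(["object", "action"])
                for wt, v in zip(order, vals):
                    rows.append({"instance": inst, "area": area.name, **fac,
                                 "WordType": wt, "n_cells": v})
        df = pd.DataFrame(rows)
        res = rm_anova(df[df.ExtraPeri == "extra"],
                       ("FrontoTemp", "ModSpecificity", "WordType"))
        pvals.append(res["FrontoTemp:ModSpecificity:WordType"].p)
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


def test_paired_t_matches_direct_formula():
    rng = np.random.default_rng(3)
    obj = rng.normal(10, 2, 5)
    act = rng.normal(8, 2, 5)
    rows = []
    for i, (o, a) in enumerate(zip(obj, act)):
        fac = area_factors(Area.V1)
        rows.append({"instance": i, "area": "V1", **fac, "WordType": "object",
                     "n_cells": o})
        rows.append({"instance": i, "area": "V1", **fac, "WordType": "action",
                     "n_cells": a})
    t, df, p = paired_t(pd.DataFrame(rows), Area.V1)
    d = obj - act
    t_direct = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    assert t == pytest.approx(t_direct)
    assert df == 4
    assert p == pytest.approx(2 * sps.t.sf(abs(t_direct), 4))


def test_paired_t_identical_pairs():
    rows = []
    for i in range(4):
        for wt in ("object", "action"):
            rows.append({"instance": i, "area": "TO", "WordType": wt,
                         "n_cells": 5.0})
    t, df, p = paired_t(pd.DataFrame(rows), Area.TO)
    assert t == 0.0 and p == 1.0


def test_planned_comparisons_cover_all_areas():
    rng = np.random.default_rng(4)
    means = {i: pd.DataFrame(rng.uniform(0, 30, size=(12, 2)),
                             index=[a.name for a in Area],
                             columns=["object", "action"])
             for i in range(4)}
    table = planned_comparisons(topography_dataset(means))
    assert len(table) == 12
    assert set(table.area) == {a.name for a in Area}


@pytest.mark.parametrize("alpha,m,expected", [
    (0.05, 12, 0.0042), (0.05, 1, 0.05), (0.05, 18, 0.0028)])
def test_bonferroni_threshold(alpha, m, expected):
    assert bonferroni_threshold(alpha, m) == pytest.approx(expected)


def test_bonferroni_rejects_bad_alpha():
    with pytest.raises(ValueError):
        bonferroni_threshold(1.5, 3)
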