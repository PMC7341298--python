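"""Readers, writers and table-style reports.

All interchange is delimited text.  The weight table is long-format CSV
with columns ``bird_id, breed, sex, week`` (integer) *or* ``age_days``, and
``weight_g``; weeks convert to days as 7 x week.  Genotype tables are CSV
with ``bird_id, length1, length2`` fragment lengths in bp.

Reports mirror the conventional layout of growth-trial papers: per-group
means with a pooled SEM, ANOVA significance codes and Waller-Duncan letters
for every parameter of both curve forms, and a cross-breed comparison with
sexual-dimorphism percentages.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import catalog as _catalog
from .fitting import GompertzResults, Trajectory
from .groupstats import (
    AnovaSpec,
    dimorphism_delta,
    lm1_anova,
    waller_duncan,
)

__all__ = [
    "read_weights",
    "write_weights",
    "read_genotype_lengths",
    "write_genotype_lengths",
    "report_growth",
    "weekly_anova_report",
    "compare_breeds",
    "trajectories_to_wide",
]

_WEIGHT_COLS = {"bird_id", "breed", "sex", "weight_g"}


def read_weights(path) -> list[Trajectory]:
    """Read a long-format weight CSV into trajectories.

    Malformed rows are reported with their (1-based, header-inclusive) line
    numbers; duplicate bird-age records and non-positive weights are errors.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if not _WEIGHT_COLS <= cols:
        raise ValueError(f"missing required columns {_WEIGHT_COLS - cols} in {path}")
    if "age_days" in cols:
        ages = pd.to_numeric(df["age_days"], errors="coerce")
    elif "week" in cols:
        ages = pd.to_numeric(df["week"], errors="coerce") * 7.0
    else:
        raise ValueError(f"need an 'age_days' or 'week' column in {path}")
    weights = pd.to_numeric(df["weight_g"], errors="coerce")

    bad = ages.isna() | weights.isna()
    if bad.any():
        rows = [i + 2 for i in df.index[bad]]  # +2: header + 1-based
        raise ValueError(f"non-numeric age or weight at line(s) {rows} of {path}")
    neg = weights <= 0
    if neg.any():
        rows = [i + 2 for i in df.index[neg]]
        raise ValueError(f"non-positive weight at line(s) {rows} of {path}")
    df = df.assign(_age=ages, _w=weights)
    dup = df.duplicated(subset=["bird_id", "_age"], keep=False)
    if dup.any():
        rows = [i + 2 for i in df.index[dup]]
        raise ValueError(f"duplicate bird-age record at line(s) {rows} of {path}")

    out = []
    for bird_id, sub in df.groupby("bird_id", sort=True):
        sub = sub.sort_values("_age")
        breeds = sub["breed"].unique()
        sexes = sub["sex"].unique()
        if breeds.size != 1 or sexes.size != 1:
            raise ValueError(f"bird {bird_id!r} has inconsistent breed/sex labels")
        out.append(
            Trajectory(
                bird_id=str(bird_id),
                breed=str(breeds[0]),
                sex=str(sexes[0]),
                times=sub["_age"].to_numpy(dtype=float),
                weights=sub["_w"].to_numpy(dtype=float),
            )
        )
    return out


def write_weights(trajectories: Iterable[Trajectory], path) -> None:
    """Write trajectories as long-format CSV (age in days)."""
    rows = [
        {
            "bird_id": tr.bird_id,
            "breed": tr.breed,
            "sex": tr.sex,
            "age_days": t,
            "weight_g": w,
        }
        for tr in trajectories
        for t, w in zip(tr.times, tr.weights)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_genotype_lengths(path) -> pd.DataFrame:
    """Genotype CSV: bird_id, length1, length2 (bp; length2 may be blank)."""
    df = pd.read_csv(path)
    need = {"bird_id", "length1"}
    if not need <= set(df.columns):
        raise ValueError(f"missing required columns {need - set(df.columns)} in {path}")
    return df


def write_genotype_lengths(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, index=False)


def trajectories_to_wide(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Bird-by-age weight matrix (rows bird_id, columns age in days)."""
    frames = {tr.bird_id: pd.Series(tr.weights, index=tr.times) for tr in trajectories}
    return pd.DataFrame(frames).T.sort_index()


_G1_ROWS = ["bwa", "b", "k", "bwip", "tip", "bws", "mgr", "dm"]
_G2_ROWS = ["bwa", "lam", "mu", "bwip", "tip", "bws", "dm"]

_DISPLAY_DECIMALS = {
    "bwa": 0, "bwip": 0, "bws": 0,  # weights to integer grams
    "mgr": 1, "mu": 1, "tip": 1, "lam": 2,  # rates/ages to 1-2 decimals
    "b": 2, "k": 3, "dm": 2,
}


def report_growth(
    fits: Sequence[GompertzResults],
    relationship: np.ndarray | None = None,
    k_ratio: float = 100.0,
) -> pd.DataFrame:
    """Growth-parameter summary table, one row per parameter.

    For every direct and derived parameter: per-group means, a pooled SEM,
    breed/sex/interaction significance codes from the mixed ANOVA, and
    Waller-Duncan letters.  Degree of maturity is averaged per bird (the
    mean of each bird's BWs/BWa), not recomputed from group means.  Mean
    adjusted r2 and AIC rows close the table.
    """
    fits = [f for f in fits if f.converged]
    if not fits:
        raise ValueError("no converged fits to report")
    tags = {f.model_tag for f in fits}
    if len(tags) != 1:
        raise ValueError("report one parameterization at a time")
    tag = tags.pop()
    df = pd.DataFrame([f.to_dict() for f in fits])
    if "breed" not in df or "sex" not in df:
        raise ValueError("fits must carry breed and sex labels")
    group_levels = sorted(df.groupby(["breed", "sex"]).groups)
    if any(df.groupby(["breed", "sex"]).size() < 1):
        raise ValueError("every breed-sex group needs at least one converged fit")

    rows = []
    params = _G1_ROWS if tag == "g1" else _G2_ROWS
    for param in params:
        y = df[param].to_numpy(dtype=float)
        grouped = df.groupby(["breed", "sex"])[param]
        means = grouped.mean()
        ns = grouped.size()
        # pooled residual variance across groups -> SEM at the mean group size
        resid = np.concatenate(
            [sub.to_numpy() - sub.mean() for _, sub in grouped]
        )
        df_err = y.size - len(group_levels)
        mse = float(resid @ resid) / df_err if df_err > 0 else float("nan")
        sem = math.sqrt(mse / (y.size / len(group_levels))) if df_err > 0 else float("nan")

        codes = {"B": "n.s.", "S": "n.s.", "BxS": "n.s."}
        letters = {g: "" for g in group_levels}
        if np.var(y) > 0 and df_err > 0:
            two_way = df["breed"].nunique() > 1 and df["sex"].nunique() > 1
            if two_way:
                spec = AnovaSpec(
                    response=y,
                    breed=df["breed"].to_numpy(),
                    sex=df["sex"].to_numpy(),
                    relationship=relationship,
                )
                res = lm1_anova(spec)
                codes = {
                    "B": res.table.loc["breed", "code"],
                    "S": res.table.loc["sex", "code"],
                    "BxS": res.table.loc["breed:sex", "code"],
                }
            else:
                codes = {"B": "-", "S": "-", "BxS": "-"}
            grand_f = _oneway_f(df, param, group_levels)
            letters = waller_duncan(
                {g: float(means[g]) for g in group_levels},
                {g: int(ns[g]) for g in group_levels},
                mse,
                df_err,
                grand_f,
                k_ratio=k_ratio,
            )
        dec = _DISPLAY_DECIMALS.get(param, 2)
        row = {"parameter": param}
        for g in group_levels:
            label = f"{g[0]} {g[1]}"
            row[label] = round(float(means[g]), dec)
            row[f"{label} letters"] = letters[g]
        row["SEM"] = round(sem, max(dec, 1))
        row.update(codes)
        rows.append(row)

    for gof in ("r2_adj", "aic"):
        grouped = df.groupby(["breed", "sex"])[gof]
        row = {"parameter": gof}
        for g in group_levels:
            label = f"{g[0]} {g[1]}"
            row[label] = round(float(grouped.mean()[g]), 3 if gof == "r2_adj" else 0)
            row[f"{label} letters"] = ""
        row["SEM"] = float("nan")
        row.update({"B": "-", "S": "-", "BxS": "-"})
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")


def _oneway_f(df: pd.DataFrame, param: str, group_levels) -> float:
    """One-way F over the breed-sex cells (drives the Waller-Duncan rule)."""
    groups = [sub.to_numpy(dtype=float) for _, sub in df.groupby(["breed", "sex"])[param]]
    k = len(groups)
    n = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_b = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    if ss_w == 0 or n - k <= 0 or k < 2:
        return float("inf")
    return float((ss_b / (k - 1)) / (ss_w / (n - k)))


def weekly_anova_report(
    trajectories: Sequence[Trajectory],
    relationship: np.ndarray | None = None,
    k_ratio: float = 100.0,
) -> pd.DataFrame:
    """Week-by-week weight ANOVA table (means, SEM, codes, letters).

    One row per weighing age: group means, pooled SEM, breed/sex/interaction
    codes from the mixed ANOVA and Waller-Duncan letters.  No multiplicity
    correction is applied across ages by default (the conventional
    presentation); apply one downstream if desired.
    """
    wide = trajectories_to_wide(trajectories)
    meta = pd.DataFrame(
        {
            "breed": {tr.bird_id: tr.breed for tr in trajectories},
            "sex": {tr.bird_id: tr.sex for tr in trajectories},
        }
    ).loc[wide.index]
    group_levels = sorted(meta.groupby(["breed", "sex"]).groups)
    rows = []
    for age in wide.columns:
        y = wide[age].to_numpy(dtype=float)
        sub = meta.assign(y=y)
        grouped = sub.groupby(["breed", "sex"])["y"]
        means, ns = grouped.mean(), grouped.size()
        resid = np.concatenate([s.to_numpy() - s.mean() for _, s in grouped])
        df_err = y.size - len(group_levels)
        mse = float(resid @ resid) / df_err
        sem = math.sqrt(mse / (y.size / len(group_levels)))
        row = {"age_days": float(age), "week": float(age) / 7.0}
        if np.var(y) > 0:
            res = lm1_anova(
                AnovaSpec(
                    response=y,
                    breed=meta["breed"].to_numpy(),
                    sex=meta["sex"].to_numpy(),
                    relationship=relationship,
                )
            )
            codes = {
                "B": res.table.loc["breed", "code"],
                "S": res.table.loc["sex", "code"],
                "BxS": res.table.loc["breed:sex", "code"],
            }
            f = _oneway_f(sub, "y", group_levels)
            letters = waller_duncan(
                {g: float(means[g]) for g in group_levels},
                {g: int(ns[g]) for g in group_levels},
                mse,
                df_err,
                f,
                k_ratio=k_ratio,
            )
        else:
            codes = {"B": "n.s.", "S": "n.s.", "BxS": "n.s."}
            letters = {g: "" for g in group_levels}
        for g in group_levels:
            label = f"{g[0]} {g[1]}"
            row[label] = float(means[g])
            row[f"{label} letters"] = letters[g]
        row["SEM"] = sem
        row.update(codes)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_breeds(
    group_means: Mapping[str, Mapping[str, Mapping[str, float]]] | None = None,
    fits: Sequence[GompertzResults] | None = None,
    catalog: Mapping = _catalog.GOMPERTZ_CATALOG,
) -> pd.DataFrame:
    """Cross-breed comparison matrix with sexual-dimorphism percentages.

    Either pass ``fits`` (converged results labelled with sex; group means
    are computed here) or ``group_means`` as
    ``{code: {"F": {param: value}, "M": {...}}}``.  User rows are appended
    after the catalog rows; the dimorphism column is
    (male - female)/female x 100, rounded to integer percent for display.
    Missing sex groups yield NaN markers, not errors.
    """
    user: dict[str, dict[str, dict[str, float]]] = {}
    if fits is not None:
        df = pd.DataFrame([f.to_dict() for f in fits if f.converged])
        if "sex" not in df:
            raise ValueError("fits must carry sex labels")
        for (breed, sex), sub in df.groupby(["breed", "sex"]):
            user.setdefault(str(breed), {})[str(sex)] = {
                p: float(sub[p].mean()) for p in ("bwa", "b", "k", "bwip", "tip", "mgr")
            }
    if group_means:
        for code, per_sex in group_means.items():
            user.setdefault(code, {}).update({s: dict(v) for s, v in per_sex.items()})

    rows = []
    params = ["bwa", "b", "k", "bwip", "tip", "mgr"]
    entries = [(code, catalog[code].get("F"), catalog[code].get("M")) for code in catalog]
    entries += [(code, per.get("F"), per.get("M")) for code, per in user.items()]
    for code, f_vals, m_vals in entries:
        for p in params:
            fv = f_vals.get(p) if f_vals else None
            mv = m_vals.get(p) if m_vals else None
            delta = (
                round(dimorphism_delta(fv, mv))
                if fv is not None and mv is not None and fv > 0
                else float("nan")
            )
            rows.append(
                {
                    "code": code,
                    "parameter": p,
                    "F": fv if fv is not None else float("nan"),
                    "M": mv if mv is not None else float("nan"),
                    "delta_pct": delta,
                }
            )
    return pd.DataFrame(rows)
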