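"""Beep-level experience-sampling (ESM) preprocessing.

The raw unit of observation is one *beep*: a prompted momentary self-report
containing eight mood-adjective ratings and one thought-pleasantness rating,
all on 7-point Likert scales, collected in ten 90-minute blocks per day over
six consecutive days per assessment period (pre / post treatment).

This module reads long-format beep tables, applies the completion-delay
validity filter, derives the positive-affect (PA) composite from a principal
component analysis of the mood adjectives, scores each beep, and aggregates
valid beeps into per-subject daily means of positive affect (PA) and
positive cognition (PC) — the series the trajectory models consume.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The eight mood adjectives probed at every beep.
MOOD_ITEMS: tuple[str, ...] = (
    "happy",
    "satisfied",
    "strong",
    "enthusiastic",
    "curious",
    "animated",
    "inspired",
    "relaxed",
)

#: Canonical long-format column set (one row per beep).
REQUIRED_COLUMNS: tuple[str, ...] = (
    "subject",
    "condition",
    "period",
    "day",
    "block",
    "delay_min",
    *MOOD_ITEMS,
    "thought_pleasant",
)

LIKERT_MIN, LIKERT_MAX = 1, 7

CONDITIONS = ("control", "mbct")
PERIODS = ("pre", "post")


class SchemaError(ValueError):
    """A required column is absent or a column has the wrong type."""


class DataError(ValueError):
    """The data violate a structural invariant (e.g. duplicate beeps)."""


@dataclass
class PAFactorDef:
    """Definition of the positive-affect composite.

    Attributes
    ----------
    candidate_items : items entered into the principal component analysis.
    retained_items : items whose first-component loading met the threshold.
    loadings : item -> loading on the retained component (standardized).
    alpha : Cronbach's alpha of the retained items (complete cases).
    loading_threshold : absolute-loading cutoff used for retention.
    n_components : number of components with eigenvalue > 1.
    rotated : whether an oblique (quartimin) rotation was applied
        (only meaningful when more than one component was extracted).
    """

    candidate_items: tuple[str, ...]
    retained_items: tuple[str, ...]
    loadings: dict[str, float]
    alpha: float
    loading_threshold: float = 0.6
    n_components: int = 1
    rotated: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PAFactorDef":
        d = json.loads(Path(path).read_text())
        d["candidate_items"] = tuple(d["candidate_items"])
        d["retained_items"] = tuple(d["retained_items"])
        return cls(**d)


def _coerce_likert(col: pd.Series, name: str) -> pd.Series:
    """Coerce a Likert column to float, mapping out-of-range or unparseable
    values to NaN with a logged warning."""
    raw = pd.to_numeric(col, errors="coerce")
    n_unparseable = int((raw.isna() & col.notna() & (col.astype(str).str.strip() != "")).sum())
    bad = raw.notna() & (
        (raw < LIKERT_MIN) | (raw > LIKERT_MAX) | (raw != np.round(raw))
    )
    if n_unparseable or bad.any():
        logger.warning(
            "column %r: %d unparseable and %d out-of-range Likert values set to missing",
            name,
            n_unparseable,
            int(bad.sum()),
        )
    return raw.mask(bad)


def read_esm_long(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a long-format beep table (CSV/TSV; one row per beep).

    Parameters
    ----------
    path : file with columns ``subject, condition, period, day, block,
        delay_min, happy, ..., relaxed, thought_pleasant`` (empty cell =
        missing).
    schema : optional map from canonical column name to the column name used
        in the file.
    sep : field separator; inferred from the extension when None.

    Returns
    -------
    DataFrame of beep records in canonical columns. Unparseable or
    out-of-range Likert values become missing (warning logged); a duplicate
    (subject, period, day, block) key raises :class:`DataError`.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    rename = {v: k for k, v in (schema or {}).items()}
    df = df.rename(columns=rename)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {missing_cols}")
    df = df[list(REQUIRED_COLUMNS)].copy()

    for col in ("subject", "condition", "period"):
        df[col] = df[col].astype(str).str.strip()
    bad_cond = ~df["condition"].isin(CONDITIONS)
    if bad_cond.any():
        raise DataError(f"unknown condition values: {sorted(df.loc[bad_cond, 'condition'].unique())}")
    bad_per = ~df["period"].isin(PERIODS)
    if bad_per.any():
        raise DataError(f"unknown period values: {sorted(df.loc[bad_per, 'period'].unique())}")

    for col, lo, hi in (("day", 1, 6), ("block", 1, 10)):
        vals = pd.to_numeric(df[col], errors="raise").astype(int)
        if ((vals < lo) | (vals > hi)).any():
            raise DataError(f"{col} outside [{lo}, {hi}]")
        df[col] = vals

    df["delay_min"] = pd.to_numeric(df["delay_min"], errors="coerce")
    if (df["delay_min"] < 0).any():
        raise DataError("negative completion delay")

    for item in (*MOOD_ITEMS, "thought_pleasant"):
        df[item] = _coerce_likert(df[item], item)

    key = ["subject", "period", "day", "block"]
    dup = df.duplicated(key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise DataError(f"duplicate beep key (subject, period, day, block): {first}")
    return df.reset_index(drop=True)


def filter_valid(records: pd.DataFrame, max_delay_min: float = 15.0) -> pd.DataFrame:
    """Keep only reports completed within ``max_delay_min`` minutes of the
    beep (inclusive).  Reports never completed (missing delay) are removed.
    The retention count is logged."""
    keep = records["delay_min"].notna() & (records["delay_min"] <= max_delay_min)
    out = records.loc[keep].reset_index(drop=True)
    logger.info(
        "validity filter (delay <= %g min): retained %d of %d beeps (%.1f%%)",
        max_delay_min,
        len(out),
        len(records),
        100.0 * len(out) / max(len(records), 1),
    )
    return out


def cronbach_alpha(item_matrix: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha, ``k/(k-1) * (1 - sum(item var) / var(total))``,
    computed on complete cases with unbiased (n-1) variances."""
    X = np.asarray(item_matrix, dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    n, k = X.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 items and 2 complete rows")
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def _principal_loadings(corr: np.ndarray, n_comp: int) -> np.ndarray:
    """Principal-component loadings (eigvec * sqrt(eigval)) for the leading
    ``n_comp`` components of a correlation matrix."""
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1][:n_comp]
    L = eigvec[:, order] * np.sqrt(np.maximum(eigval[order], 0.0))
    # orient each component so its mean loading is positive
    sign = np.where(L.sum(axis=0) >= 0, 1.0, -1.0)
    return L * sign


def derive_pa_factor(
    records: pd.DataFrame,
    candidate_items: Sequence[str] = MOOD_ITEMS,
    threshold: float = 0.6,
    period: str | None = None,
) -> PAFactorDef:
    """Derive the PA composite from a principal component analysis of the
    beep-level mood-adjective correlations (complete cases, pooled across
    subjects and, by default, periods).

    Components with eigenvalue > 1 are extracted; when more than one
    emerges, an oblique (quartimin) rotation is applied and the component
    with the largest sum of squared pattern loadings is taken as the PA
    component.  Items with \\|loading\\| below ``threshold`` are dropped and
    Cronbach's alpha is computed on the retained set.

    Parameters
    ----------
    period : restrict the analysis to one assessment period ("pre"/"post");
        None pools both.
    """
    candidate_items = tuple(candidate_items)
    if len(candidate_items) < 2:
        raise ValueError("need at least 2 candidate items")
    df = records if period is None else records[records["period"] == period]
    X = df[list(candidate_items)].to_numpy(dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    if X.shape[0] < 3 * len(candidate_items):
        raise ValueError(
            f"need at least {3 * len(candidate_items)} complete beeps, got {X.shape[0]}"
        )

    variances = X.var(axis=0, ddof=1)
    keep = variances > 1e-12
    if not keep.all():
        dropped = [it for it, k in zip(candidate_items, keep) if not k]
        logger.warning("zero-variance item(s) excluded from PCA: %s", dropped)
    items = tuple(it for it, k in zip(candidate_items, keep) if k)
    X = X[:, keep]

    corr = np.corrcoef(X, rowvar=False)
    eigval = np.linalg.eigvalsh(corr)
    n_comp = max(int((eigval > 1.0).sum()), 1)
    L = _principal_loadings(corr, n_comp)

    rotated = False
    if n_comp >= 2:
        from statsmodels.multivariate.factor_rotation import rotate_factors

        L_rot, _ = rotate_factors(L, "quartimin")
        ss = (L_rot**2).sum(axis=0)
        pick = int(np.argmax(ss))
        lo = L_rot[:, pick]
        lo = lo if lo.sum() >= 0 else -lo
        rotated = True
    else:
        lo = L[:, 0]

    loadings = {it: float(v) for it, v in zip(items, lo)}
    retained = tuple(it for it in items if abs(loadings[it]) >= threshold)
    if not retained:
        raise ValueError("no item loading reached the retention threshold")
    excluded = [it for it in items if it not in retained]
    if excluded:
        logger.info("items below |loading| >= %.2f excluded from PA factor: %s", threshold, excluded)

    cols = [list(items).index(it) for it in retained]
    if len(retained) >= 2:
        alpha = cronbach_alpha(X[:, cols])
    else:
        alpha = float("nan")
    return PAFactorDef(
        candidate_items=candidate_items,
        retained_items=retained,
        loadings=loadings,
        alpha=alpha,
        loading_threshold=threshold,
        n_components=n_comp,
        rotated=rotated,
    )


def score_pa(
    records: pd.DataFrame, factor_def: PAFactorDef, min_items: int = 4
) -> pd.Series:
    """Beep-level PA score: unit-weight mean of the non-missing retained
    items, or missing when fewer than ``min_items`` are present."""
    items = list(factor_def.retained_items)
    vals = records[items]
    n_present = vals.notna().sum(axis=1)
    score = vals.mean(axis=1)
    return score.where(n_present >= min_items)


def score_pa_beep(
    record: Mapping[str, float] | pd.Series, factor_def: PAFactorDef, min_items: int = 4
) -> float:
    """Score a single beep record; returns NaN when fewer than ``min_items``
    retained items are present."""
    vals = np.array([record[it] for it in factor_def.retained_items], dtype=float)
    present = ~np.isnan(vals)
    if present.sum() < min_items:
        return float("nan")
    return float(vals[present].mean())


def aggregate_daily(
    records: pd.DataFrame, factor_def: PAFactorDef, min_items: int = 4
) -> pd.DataFrame:
    """Average validity-filtered beeps into per-subject daily means.

    Returns a long table with one row per subject x period x day (all six
    days always present) and columns ``pa`` (mean beep PA score), ``pc``
    (mean thought pleasantness), ``n_beeps`` (number of valid beeps that
    day), ``n_pa``/``n_pc`` (beeps contributing to each mean).  ``pa``/``pc``
    are missing iff no beep contributed.
    """
    df = records.copy()
    df["pa_score"] = score_pa(df, factor_def, min_items=min_items)

    grp = df.groupby(["subject", "condition", "period", "day"], sort=True)
    daily = grp.agg(
        pa=("pa_score", "mean"),
        pc=("thought_pleasant", "mean"),
        n_beeps=("day", "size"),
        n_pa=("pa_score", "count"),
        n_pc=("thought_pleasant", "count"),
    ).reset_index()

    # make every subject x period carry all six day rows
    subj = daily[["subject", "condition"]].drop_duplicates()
    full = subj.merge(pd.DataFrame({"period": list(PERIODS)}), how="cross").merge(
        pd.DataFrame({"day": np.arange(1, 7)}), how="cross"
    )
    daily = full.merge(daily, on=["subject", "condition", "period", "day"], how="left")
    for c in ("n_beeps", "n_pa", "n_pc"):
        daily[c] = daily[c].fillna(0).astype(int)
    return daily.sort_values(["subject", "period", "day"]).reset_index(drop=True)


def baseline_period_means(daily: pd.DataFrame, period: str = "pre") -> pd.DataFrame:
    """Per-subject mean daily PA and PC over one period's non-missing days.

    Returns columns ``subject, condition, pre_pa, pre_pc`` (missing when all
    six days are missing)."""
    sub = daily[daily["period"] == period]
    out = (
        sub.groupby(["subject", "condition"], sort=True)
        .agg(pre_pa=("pa", "mean"), pre_pc=("pc", "mean"))
        .reset_index()
    )
    return out


def daily_to_wide(daily: pd.DataFrame, period: str = "post") -> pd.DataFrame:
    """Pivot one period's daily series into the wide 12-variable layout the
    trajectory models consume: columns ``pa_d1..pa_d6, pc_d1..pc_d6`` plus
    ``condition``, indexed by subject."""
    sub = daily[daily["period"] == period]
    wide = sub.pivot(index="subject", columns="day", values=["pa", "pc"])
    wide.columns = [f"{m}_d{d}" for m, d in wide.columns]
    order = [f"pa_d{d}" for d in range(1, 7)] + [f"pc_d{d}" for d in range(1, 7)]
    wide = wide.reindex(columns=order)
    cond = sub.drop_duplicates("subject").set_index("subject")["condition"]
    wide["condition"] = cond
    return wide
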