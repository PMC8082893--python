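"""Agreement statistics for CT- vs synthetic-CT-based guide placement.

Operates on a *placement record* table — one row per
(observer, specimen, bone, location, modality, repeat) with the eight
placement errors as columns — and provides:

* Table-style summaries: mean (sample SD) of the absolute errors per
  modality, plus per-guide maximum between-observer difference columns
  for the total errors.
* Repeated-measures ANOVA with imaging modality as the within-subject
  factor over guide placements (and optionally observer as a between
  factor), via pingouin.
* Bland-Altman analysis of the per-guide CT-vs-sCT differences with two
  extra limits of agreement derived from intra- and inter-observer
  variability, and the 95%-within-LoA equivalence rule.
* 1.5 x IQR outlier flagging within observer groups.
* The normal-approximation sample-size calculation for detecting a mean
  difference between two groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "ERROR_COMPONENTS",
    "RECORD_COLUMNS",
    "records_frame",
    "summarize_by_modality",
    "RmAnovaResult",
    "rm_anova",
    "BlandAltmanResult",
    "bland_altman",
    "paired_modality_differences",
    "observer_deviations",
    "flag_outliers",
    "PowerSpec",
    "required_sample_size",
]

ERROR_COMPONENTS = ["dx", "dy", "dz", "dT", "phix", "phiy", "phiz", "dR"]
GUIDE_KEYS = ["specimen", "bone", "location"]
RECORD_COLUMNS = (
    ["observer", "specimen", "bone", "location", "modality", "repeat"]
    + ERROR_COMPONENTS
    + ["icp_rms", "converged"]
)


def records_frame(rows: list[dict]) -> pd.DataFrame:
    """Assemble placement records, checking the uniqueness invariant."""
    df = pd.DataFrame(rows)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"placement records missing columns: {missing}")
    keys = ["observer", "specimen", "bone", "location", "modality", "repeat"]
    if df.duplicated(subset=keys).any():
        raise ValueError("duplicate placement records for the same design cell")
    return df[RECORD_COLUMNS]


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_by_modality(
    records: pd.DataFrame, expected_modalities: tuple = ("CT", "sCT")
) -> pd.DataFrame:
    """Mean (SD) of absolute errors per modality, one row per modality.

    Adds ``dT_max_diff`` / ``dR_max_diff``: for each guide (specimen,
    bone, location) the largest absolute between-observer difference of
    the total error, averaged over guides.
    """
    modalities = sorted(records["modality"].unique())
    missing = [m for m in expected_modalities if m not in modalities]
    if missing:
        raise ValueError(f"records are missing modality {missing}")
    base = records[records["repeat"] == records["repeat"].min()]
    rows = []
    for mod in modalities:
        sub = base[base["modality"] == mod]
        if sub.empty:
            raise ValueError(f"no records for modality {mod}")
        row: dict = {"modality": mod, "n": len(sub)}
        for comp in ERROR_COMPONENTS:
            vals = sub[comp].abs()
            row[f"{comp}_mean"] = vals.mean()
            row[f"{comp}_sd"] = vals.std(ddof=1)
        for comp in ("dT", "dR"):
            per_guide = sub.groupby(GUIDE_KEYS)[comp].agg(lambda v: v.max() - v.min())
            row[f"{comp}_max_diff"] = per_guide.mean()
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RmAnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float


def rm_anova(
    records: pd.DataFrame,
    component: str,
    include_observer: bool = True,
    absolute: bool = True,
) -> list[RmAnovaResult]:
    """Repeated-measures ANOVA of one error component.

    Modality (CT vs sCT) is the within-subject factor; the subject is one
    guide placement by one observer, so each subject contributes exactly
    one CT and one sCT value. With ``include_observer`` the observer enters
    as a between-subject factor (mixed ANOVA). For the two-level modality
    factor the modality F statistic equals the square of the paired t
    statistic when no between factor is present.

    An unbalanced design (missing modality for some cell) raises, naming
    the incomplete cells.
    """
    if component not in ERROR_COMPONENTS:
        raise ValueError(f"unknown error component {component!r}")
    df = records[records["repeat"] == records["repeat"].min()].copy()
    df["subject"] = (
        df["observer"].astype(str) + "/" + df["specimen"].astype(str) + "/"
        + df["bone"].astype(str) + "/" + df["location"].astype(str)
    )
    df["value"] = df[component].abs() if absolute else df[component]
    counts = df.groupby("subject")["modality"].nunique()
    incomplete = counts[counts < df["modality"].nunique()]
    if len(incomplete):
        raise ValueError(
            f"unbalanced design: cells missing a modality: {list(incomplete.index[:10])}"
        )
    results: list[RmAnovaResult] = []
    n_observers = df["observer"].nunique()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if include_observer and n_observers > 1:
            aov = pg.mixed_anova(
                data=df, dv="value", within="modality",
                subject="subject", between="observer",
            )
            name_map = {"observer": "observer", "modality": "modality",
                        "Interaction": "modality*observer"}
            for _, r in aov.iterrows():
                results.append(
                    RmAnovaResult(
                        effect=name_map.get(r["Source"], r["Source"]),
                        F=float(r["F"]), df_num=float(r["DF1"]),
                        df_den=float(r["DF2"]), p=float(r["p_unc"]),
                    )
                )
        else:
            aov = pg.rm_anova(data=df, dv="value", within="modality", subject="subject")
            r = aov.iloc[0]
            results.append(
                RmAnovaResult(
                    effect="modality", F=float(r["F"]), df_num=float(r["ddof1"]),
                    df_den=float(r["ddof2"]), p=float(r["p_unc"]),
                )
            )
    # a zero error term makes the F ratio degenerate (0/0 or x/0); decide
    # by whether the factor means actually differ
    means = df.groupby("modality")["value"].mean()
    null_effect = (means.max() - means.min()) < 1e-12 * max(1.0, means.abs().max())
    out = []
    for r in results:
        if not np.isfinite(r.F):
            if null_effect:
                out.append(RmAnovaResult(r.effect, 0.0, r.df_num, r.df_den, 1.0))
            else:
                out.append(r)
        else:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Bland-Altman with observer-variability limits of agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlandAltmanResult:
    mean_difference: float
    loa_low: float
    loa_high: float
    intra_loa: float  # half-width, 1.96 * SD of intra-observer differences
    inter_loa: float  # half-width, 1.96 * SD of inter-observer variability
    fraction_within_inter_loa: float
    fraction_within_intra_loa: float
    equivalent: bool
    n: int
    means: np.ndarray = None
    differences: np.ndarray = None


def bland_altman(
    paired_ct: np.ndarray,
    paired_sct: np.ndarray,
    intra_pairs: np.ndarray | None = None,
    inter_deviations: np.ndarray | None = None,
    inter_rule: str = "sd",
    equivalence_fraction: float = 0.95,
) -> BlandAltmanResult:
    """Bland-Altman agreement of CT vs sCT per-guide errors.

    ``paired_ct`` / ``paired_sct`` are equal-length per-guide values
    (typically averaged over observers). Differences are CT − sCT; the
    standard limits of agreement are mean ± 1.96 · SD.

    ``intra_pairs`` is an (n, 2) array of repeat-session value pairs from
    the repeat observer; the intra-observer LoA is ±1.96 · SD of their
    differences. ``inter_deviations`` are per-placement deviations from
    the per-guide observer mean; with ``inter_rule='sd'`` the
    inter-observer LoA is ±1.96 · SD of those deviations, with
    ``inter_rule='max'`` it is the maximum absolute deviation. Equivalence
    is declared when at least ``equivalence_fraction`` of the differences
    fall within the inter-observer LoA (centred at zero).
    """
    ct = np.asarray(paired_ct, float).ravel()
    sct = np.asarray(paired_sct, float).ravel()
    if len(ct) != len(sct):
        raise ValueError("paired CT and sCT arrays must have equal length")
    if len(ct) == 0:
        raise ValueError("empty pairing")
    diff = ct - sct
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1)) if len(diff) > 1 else 0.0
    loa_low, loa_high = mean_diff - 1.96 * sd, mean_diff + 1.96 * sd

    intra = float("nan")
    frac_intra = float("nan")
    if intra_pairs is not None and len(intra_pairs):
        ip = np.asarray(intra_pairs, float).reshape(-1, 2)
        d_intra = ip[:, 1] - ip[:, 0]
        intra = 1.96 * float(d_intra.std(ddof=1))
        frac_intra = float(np.mean(np.abs(diff) <= intra))

    inter = float("nan")
    frac_inter = float("nan")
    equivalent = False
    if inter_deviations is not None and len(inter_deviations):
        dev = np.asarray(inter_deviations, float).ravel()
        if inter_rule == "sd":
            inter = 1.96 * float(dev.std(ddof=1))
        elif inter_rule == "max":
            inter = float(np.abs(dev).max())
        else:
            raise ValueError("inter_rule must be 'sd' or 'max'")
        frac_inter = float(np.mean(np.abs(diff) <= inter))
        equivalent = frac_inter >= equivalence_fraction

    return BlandAltmanResult(
        mean_difference=mean_diff, loa_low=loa_low, loa_high=loa_high,
        intra_loa=intra, inter_loa=inter,
        fraction_within_inter_loa=frac_inter,
        fraction_within_intra_loa=frac_intra,
        equivalent=equivalent, n=len(diff),
        means=0.5 * (ct + sct), differences=diff,
    )


def paired_modality_differences(records: pd.DataFrame, component: str) -> pd.DataFrame:
    """Per-guide CT and sCT values of |component|, averaged over observers.

    One row per guide (specimen, bone, location) with columns ``CT`` and
    ``sCT`` — the pairing the Bland-Altman comparison consumes.
    """
    base = records[records["repeat"] == records["repeat"].min()].copy()
    base["value"] = base[component].abs()
    wide = (
        base.groupby(GUIDE_KEYS + ["modality"])["value"].mean().unstack("modality")
    )
    if wide.isna().any().any():
        raise ValueError("incomplete modality pairing for some guides")
    return wide


def observer_deviations(records: pd.DataFrame, component: str) -> np.ndarray:
    """Per-placement deviations of |component| from the per-guide-and-
    modality observer mean: the inter-observer variability sample."""
    base = records[records["repeat"] == records["repeat"].min()].copy()
    base["value"] = base[component].abs()
    group = GUIDE_KEYS + ["modality"]
    dev = base["value"] - base.groupby(group)["value"].transform("mean")
    return dev.to_numpy()


def intra_observer_pairs(records: pd.DataFrame, component: str) -> np.ndarray:
    """(n, 2) repeat-session pairs of |component| for the repeat observer."""
    reps = sorted(records["repeat"].unique())
    if len(reps) < 2:
        return np.empty((0, 2))
    twice = records[records["observer"].isin(
        records.loc[records["repeat"] == reps[1], "observer"].unique()
    )].copy()
    twice["value"] = twice[component].abs()
    wide = twice.pivot_table(
        index=["observer"] + GUIDE_KEYS + ["modality"],
        columns="repeat", values="value",
    ).dropna()
    return wide[[reps[0], reps[1]]].to_numpy()


# ---------------------------------------------------------------------------
# Outliers
# ---------------------------------------------------------------------------

def flag_outliers(values: np.ndarray, groups: np.ndarray | None = None) -> np.ndarray:
    """Flag values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] within each group.

    Quartiles use linear interpolation (numpy default, type 7). Groups
    with fewer than 4 values raise — quartiles are meaningless there.
    """
    values = np.asarray(values, float).ravel()
    if groups is None:
        groups = np.zeros(len(values), dtype=int)
    groups = np.asarray(groups).ravel()
    flags = np.zeros(len(values), dtype=bool)
    for g in np.unique(groups):
        sel = groups == g
        v = values[sel]
        if len(v) < 4:
            raise ValueError(f"group {g!r} has {len(v)} values; need >= 4 for quartiles")
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        # tiny tolerance keeps values sitting exactly on a fence unflagged
        # despite floating-point round-off in the fence arithmetic
        eps = 1e-9 * max(1.0, np.abs(v).max())
        flags[sel] = (v < q1 - 1.5 * iqr - eps) | (v > q3 + 1.5 * iqr + eps)
    return flags


# ---------------------------------------------------------------------------
# Power / sample size
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for detecting a true mean difference ``delta``
    between two groups with common SD ``sd``."""

    delta: float
    sd: float
    power: float = 0.80
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.sd <= 0:
            raise ValueError("sd must be > 0")


def required_sample_size(spec: PowerSpec, use_t: bool = False) -> int:
    """Per-group sample size for a two-sided two-sample comparison.

    Normal approximation ``n = ceil(2 (z_{1-alpha/2} + z_{power})^2 sd^2 /
    delta^2)``; with ``use_t`` the normal quantiles are replaced by t
    quantiles and iterated, which is slightly more conservative.
    """
    if spec.delta == 0:
        raise ValueError("delta = 0 requires an infinite sample")
    ratio = (spec.sd / abs(spec.delta)) ** 2
    z_a = sps.norm.ppf(1 - spec.alpha / 2)
    z_b = sps.norm.ppf(spec.power)
    n = int(np.ceil(2 * (z_a + z_b) ** 2 * ratio))
    if not use_t:
        return n
    for _ in range(50):
        df = 2 * (n - 1)
        t_a = sps.t.ppf(1 - spec.alpha / 2, df)
        t_b = sps.t.ppf(spec.power, df)
        n_new = int(np.ceil(2 * (t_a + t_b) ** 2 * ratio))
        if n_new == n:
            break
        n = n_new
    return n
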