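"""Differential hydrogen-deuterium exchange (HDX-MS) analysis.

Per-peptide percent deuteration is normalized between an unexchanged control
(H2O instead of D2O) and a maximally-labeled control (longest exchange time),
which cancels uniform back-exchange.  Condition-versus-reference differences
are computed per peptide and timepoint, replicate scatter is propagated in
quadrature, peptides are called protected/deprotected at a fixed
effect-size threshold (default 10 percentage points), and same-class peptide
spans are merged into contiguous residue regions (Woods-style analysis).

Sign convention: ``delta_percentD = condition - reference``; protection
(slower exchange in the condition) is negative.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

#: Mass added per incorporated deuteron (2H minus 1H), Da.
DEUTERON_MASS_SHIFT_DA = 1.00628
#: Proton mass used for m/z <-> neutral-mass conversion, Da.
PROTON_MASS_DA = 1.00728

#: Canonical column order of the long-format uptake table.
UPTAKE_COLUMNS = [
    "protein",
    "start",
    "end",
    "condition",
    "timepoint_s",
    "replicate",
    "centroid_mass_da",
]

#: Condition label reserved for the H2O (unexchanged) control rows.
UNEXCHANGED_LABEL = "unexchanged"

PEPTIDE_KEY = ["protein", "start", "end"]

__all__ = [
    "DEUTERON_MASS_SHIFT_DA",
    "PROTON_MASS_DA",
    "UPTAKE_COLUMNS",
    "UNEXCHANGED_LABEL",
    "centroid_mass",
    "percent_deuteration",
    "percent_deuteration_table",
    "replicate_stats",
    "condition_stats",
    "exchange_difference",
    "differential_exchange",
    "classify_delta",
    "classify_peptides",
    "merge_regions",
    "class_regions",
    "woods_plot",
]


def centroid_mass(mz_grid: np.ndarray, intensities: np.ndarray, charge: int) -> float:
    """Neutral monoisotopic-envelope centroid mass from an m/z spectrum.

    The intensity-weighted mean m/z is converted to neutral mass as
    ``mean_mz * z - z * proton_mass``.
    """
    mz = np.asarray(mz_grid, dtype=float)
    inten = np.asarray(intensities, dtype=float)
    if mz.shape != inten.shape:
        raise ValueError("mz_grid and intensities must have the same shape")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if np.any(inten < 0):
        raise ValueError("intensities must be non-negative")
    total = inten.sum()
    if total == 0:
        raise ValueError("all-zero intensities: centroid undefined")
    mean_mz = float(np.dot(mz, inten) / total)
    return mean_mz * charge - charge * PROTON_MASS_DA


def percent_deuteration(m_t: float, m_unexchanged: float, m_maxlabel: float) -> float:
    """Percent deuteration of a centroid mass against the two controls.

    ``100 * (m_t - m_un) / (m_max - m_un)``.  Values slightly below 0 or above
    100 are legitimate noise excursions and are returned unclamped.
    """
    denom = m_maxlabel - m_unexchanged
    if denom <= 0:
        raise DegenerateInputError(
            "maximally-labeled control mass must exceed the unexchanged control mass"
        )
    return 100.0 * (m_t - m_unexchanged) / denom


def replicate_stats(values) -> tuple[float, float]:
    """Mean and sample SD (ddof=1) of replicate values; SD is NaN for n < 2."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no replicate values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size >= 2 else float("nan")
    return mean, sd


def percent_deuteration_table(
    records: pd.DataFrame,
    *,
    maxlabel_timepoint_s: float = 60000.0,
    unexchanged_label: str = UNEXCHANGED_LABEL,
) -> pd.DataFrame:
    """Per-replicate %D for every measured row of a long-format uptake table.

    For each peptide the unexchanged control mass is the mean over the
    ``unexchanged`` rows (shared across conditions); the maximally-labeled
    control mass is the mean over that condition's rows at
    ``maxlabel_timepoint_s``.  Returns the measured rows (controls excluded)
    with ``percentD`` and an ``out_of_range`` flag for values outside
    [0, 100].
    """
    df = records.copy()
    missing = [c for c in UPTAKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"uptake table missing columns: {missing}")

    un = (
        df[df["condition"] == unexchanged_label]
        .groupby(PEPTIDE_KEY)["centroid_mass_da"]
        .mean()
        .rename("m_unexchanged")
    )
    meas = df[df["condition"] != unexchanged_label].copy()
    mx = (
        meas[meas["timepoint_s"] == maxlabel_timepoint_s]
        .groupby(PEPTIDE_KEY + ["condition"])["centroid_mass_da"]
        .mean()
        .rename("m_maxlabel")
    )

    bad_un = (
        meas.set_index(PEPTIDE_KEY).index.unique().difference(un.index)
    )
    if len(bad_un):
        raise ValueError(
            f"peptides missing the unexchanged control: {sorted(bad_un.tolist())}"
        )
    bad_mx = (
        meas.set_index(PEPTIDE_KEY + ["condition"]).index.unique().difference(mx.index)
    )
    if len(bad_mx):
        raise ValueError(
            "peptide/condition pairs missing the maximally-labeled control "
            f"(timepoint {maxlabel_timepoint_s} s): {sorted(bad_mx.tolist())}"
        )

    meas = meas.merge(un.reset_index(), on=PEPTIDE_KEY)
    meas = meas.merge(mx.reset_index(), on=PEPTIDE_KEY + ["condition"])
    denom = meas["m_maxlabel"] - meas["m_unexchanged"]
    if (denom <= 0).any():
        bad = meas.loc[denom <= 0, PEPTIDE_KEY].drop_duplicates()
        raise DegenerateInputError(
            "maxlabel mass <= unexchanged mass for peptides: "
            f"{bad.to_records(index=False).tolist()}"
        )
    meas["percentD"] = (
        100.0 * (meas["centroid_mass_da"] - meas["m_unexchanged"]) / denom
    )
    meas["out_of_range"] = (meas["percentD"] < 0) | (meas["percentD"] > 100)
    return meas.drop(columns=["m_unexchanged", "m_maxlabel"])


def condition_stats(percentd: pd.DataFrame) -> pd.DataFrame:
    """Replicate mean and sample SD of %D per peptide, condition, timepoint."""
    grouped = percentd.groupby(PEPTIDE_KEY + ["condition", "timepoint_s"])["percentD"]
    out = grouped.agg(
        mean_percentD="mean",
        sd_percentD=lambda v: v.std(ddof=1) if len(v) >= 2 else np.nan,
        n_replicates="size",
    ).reset_index()
    return out


def exchange_difference(
    condition_mean: float,
    condition_sd: float,
    reference_mean: float,
    reference_sd: float,
) -> tuple[float, float]:
    """Difference of %D means with quadrature-propagated SD."""
    delta = condition_mean - reference_mean
    sd = float(np.sqrt(condition_sd**2 + reference_sd**2))
    return float(delta), sd


def differential_exchange(
    stats: pd.DataFrame,
    condition: str,
    reference: str,
) -> pd.DataFrame:
    """Per-peptide, per-timepoint %D difference (condition minus reference).

    ``stats`` is the output of :func:`condition_stats`.  Peptides present in
    only one of the two conditions are skipped with a logged warning.
    """
    for label in (condition, reference):
        if label not in set(stats["condition"]):
            raise ValueError(f"condition {label!r} absent from stats table")
    key = PEPTIDE_KEY + ["timepoint_s"]
    c = stats[stats["condition"] == condition].set_index(key)
    r = stats[stats["condition"] == reference].set_index(key)
    only_c = c.index.difference(r.index)
    only_r = r.index.difference(c.index)
    for idx in list(only_c) + list(only_r):
        logger.warning("peptide/timepoint %s present in one condition only; skipped", idx)
    common = c.index.intersection(r.index)
    c = c.loc[common]
    r = r.loc[common]
    out = pd.DataFrame(index=common).reset_index()
    out["delta_percentD"] = (
        c["mean_percentD"].to_numpy() - r["mean_percentD"].to_numpy()
    )
    out["sd"] = np.sqrt(
        c["sd_percentD"].to_numpy() ** 2 + r["sd_percentD"].to_numpy() ** 2
    )
    out["condition"] = condition
    out["reference"] = reference
    return out.sort_values(key, ignore_index=True)


def classify_delta(delta: float, threshold: float = 10.0) -> str:
    """protected / deprotected / unchanged call for one %D difference."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if delta <= -threshold:
        return "protected"
    if delta >= threshold:
        return "deprotected"
    return "unchanged"


def classify_peptides(
    differences: pd.DataFrame,
    *,
    threshold: float = 10.0,
    timepoint_s: float | None = 60.0,
) -> pd.DataFrame:
    """Apply the fixed +/-threshold rule to a difference table.

    By default only the 60 s timepoint (the canonical comparison point) is
    classified; pass ``timepoint_s=None`` to classify every timepoint present.
    """
    df = differences.copy()
    if timepoint_s is not None:
        df = df[df["timepoint_s"] == timepoint_s].copy()
    df["classification"] = [
        classify_delta(d, threshold) for d in df["delta_percentD"]
    ]
    return df.reset_index(drop=True)


def merge_regions(
    spans: list[tuple[int, int]], *, gap_tolerance: int = 0
) -> list[tuple[int, int]]:
    """Union of 1-based inclusive residue spans, merging gaps <= gap_tolerance.

    Output intervals are sorted and pairwise disjoint.
    """
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")
    cleaned = []
    for start, end in spans:
        if start > end:
            raise ValueError(f"invalid span ({start}, {end})")
        cleaned.append((int(start), int(end)))
    if not cleaned:
        return []
    cleaned.sort()
    merged = [cleaned[0]]
    for start, end in cleaned[1:]:
        last_start, last_end = merged[-1]
        if start <= last_end + 1 + gap_tolerance:
            merged[-1] = (last_start, max(last_end, end))
        else:
            merged.append((start, end))
    return merged


def class_regions(
    classified: pd.DataFrame,
    protein: str,
    classification: str,
    *,
    gap_tolerance: int = 0,
) -> list[tuple[int, int]]:
    """Contiguous residue regions covered by same-class peptides of one protein."""
    sel = classified[
        (classified["protein"] == protein)
        & (classified["classification"] == classification)
    ]
    spans = list(zip(sel["start"].astype(int), sel["end"].astype(int)))
    return merge_regions(spans, gap_tolerance=gap_tolerance)


def woods_plot(
    differences: pd.DataFrame,
    protein: str,
    *,
    threshold: float = 10.0,
    ax=None,
):
    """Woods-style plot: per-peptide %D difference along the sequence.

    Each peptide is drawn as a horizontal segment over its residue span at its
    delta %D, with a shaded +/-SD band and dashed lines at +/-threshold.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    sel = differences[differences["protein"] == protein]
    for _, row in sel.iterrows():
        x = [row["start"], row["end"]]
        y = [row["delta_percentD"]] * 2
        ax.plot(x, y, color="tab:blue", lw=2)
        if np.isfinite(row["sd"]):
            ax.fill_between(
                x,
                [row["delta_percentD"] - row["sd"]] * 2,
                [row["delta_percentD"] + row["sd"]] * 2,
                color="grey",
                alpha=0.4,
                linewidth=0,
            )
    ax.axhline(threshold, ls="--", color="k", lw=0.8)
    ax.axhline(-threshold, ls="--", color="k", lw=0.8)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("residue")
    ax.set_ylabel(r"$\Delta$ %D (condition $-$ reference)")
    ax.set_title(protein)
    return ax
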