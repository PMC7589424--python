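"""Differential splicing between knockdown conditions and control.

Replicate-level event usage is aggregated into per-condition means and
sample standard deviations; each treated condition is compared with the
control by the signed differences dSJ = SJ(treated) - SJ(control) and,
for exon events, dPSI = PSI(treated) - PSI(control). Calls fall into
two tiers: *major* (|dSJ| >= 0.05 and the mean +/- 1 SD intervals of the
two conditions do not overlap) and *rare* (0.01 <= |dSJ| < 0.05). From
the major exon calls each knockdown's protein is classified as splicing
activator, repressor, or bidirectional regulator: depleting an
activator lowers inclusion of its target exons (all dPSI < 0), a
repressor raises it.

No multiple-testing correction is applied (the call rule is the
SD-disjointness gate, not a p-value); the calls table carries the
number of events examined so readers can judge the search space.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "summarize_condition",
    "delta",
    "classify_rbp_roles",
    "responsive_exon_census",
]

MAJOR_THRESHOLD = 0.05
RARE_THRESHOLD = 0.01
STRONG_EFFECT = 0.4  # |dPSI| flagging a strong activator/repressor effect

_SUMMARY_COLUMNS = [
    "event", "condition", "kind", "exon", "mean_sj", "sd_sj", "n",
    "mean_psi", "sd_psi", "defined",
]
_CALL_COLUMNS = [
    "event", "kind", "exon", "condition",
    "mean_sj_treated", "sd_sj_treated", "n_treated",
    "mean_sj_control", "sd_sj_control", "n_control",
    "delta_sj", "delta_psi", "sd_overlap", "tier", "direction",
    "n_events_examined",
]


def summarize_condition(
    usage: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Per event x condition: mean/SD of SJ usage (and PSI where present).

    ``usage`` is the tidy frame from
    :func:`spliceamp.junction_quant.event_usage_table` (columns event,
    kind, sample, sj, psi, exon); ``samples`` maps sample -> condition
    (columns sample, condition). Undefined per-sample values are
    excluded, with n adjusted and logged; a condition with no informative
    replicate for an event is flagged undefined.
    """
    required = {"sample", "condition"}
    if not required.issubset(samples.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    unassigned = set(usage["sample"]) - set(samples["sample"])
    if unassigned:
        raise ValueError(f"samples without a condition: {sorted(unassigned)}")
    merged = usage.merge(samples[["sample", "condition"]], on="sample", how="left")
    if merged.empty:
        return pd.DataFrame(columns=_SUMMARY_COLUMNS)

    def agg(group: pd.DataFrame) -> pd.Series:
        sj = group["sj"].dropna()
        psi = group["psi"].dropna()
        n_total = len(group)
        if len(sj) < n_total:
            logger.info(
                "event %s / %s: %d of %d replicates undefined",
                *group.name,
                n_total - len(sj),
                n_total,
            )
        return pd.Series(
            {
                "kind": group["kind"].iloc[0],
                "exon": group["exon"].iloc[0],
                "mean_sj": sj.mean() if len(sj) else np.nan,
                "sd_sj": sj.std(ddof=1) if len(sj) > 1 else (0.0 if len(sj) == 1 else np.nan),
                "n": len(sj),
                "mean_psi": psi.mean() if len(psi) else np.nan,
                "sd_psi": psi.std(ddof=1) if len(psi) > 1 else (0.0 if len(psi) == 1 else np.nan),
                "defined": len(sj) > 0,
            }
        )

    out = (
        merged.groupby(["event", "condition"], sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out


def _intervals_overlap(m1: float, s1: float, m2: float, s2: float) -> bool:
    """Do the mean +/- 1 SD intervals of two conditions intersect?"""
    return (m1 - s1) <= (m2 + s2) and (m2 - s2) <= (m1 + s1)


def _direction(kind: str, dsj: float) -> str:
    if kind in ("single_ES", "multi_ES"):
        return "increased_skipping" if dsj > 0 else "decreased_skipping"
    if kind == "PI":
        return "increased_inclusion" if dsj > 0 else "decreased_inclusion"
    return "increased_alt_usage" if dsj > 0 else "decreased_alt_usage"


def delta(
    summaries: pd.DataFrame,
    control: str,
    major: float = MAJOR_THRESHOLD,
    rare: float = RARE_THRESHOLD,
) -> pd.DataFrame:
    """Differential calls per event x treated condition.

    Tier assignment: *major* iff |dSJ| >= ``major`` and the +/- 1 SD
    intervals of treated and control are disjoint; *rare* iff
    ``rare`` <= |dSJ| < ``major`` (both bounds inclusive per the call
    definitions); otherwise *none*. Events with an undefined treated or
    control summary are skipped with a log entry.
    """
    if not 0 < rare < major <= 1:
        raise ValueError(f"need 0 < rare < major <= 1, got rare={rare}, major={major}")
    if summaries.empty:
        return pd.DataFrame(columns=_CALL_COLUMNS)
    if control not in set(summaries["condition"]):
        raise ValueError(f"control condition {control!r} not in summaries")
    ctrl = summaries[summaries["condition"] == control].set_index("event")
    rows = []
    n_events = summaries["event"].nunique()
    for (event, condition), row in summaries[
        summaries["condition"] != control
    ].set_index(["event", "condition"]).iterrows():
        if event not in ctrl.index:
            logger.info("event %s absent from control summaries; skipped", event)
            continue
        c = ctrl.loc[event]
        if not (row["defined"] and c["defined"]):
            logger.info("event %s / %s: undefined summary; call skipped", event, condition)
            continue
        dsj = row["mean_sj"] - c["mean_sj"]
        dpsi = (
            row["mean_psi"] - c["mean_psi"]
            if not (pd.isna(row["mean_psi"]) or pd.isna(c["mean_psi"]))
            else np.nan
        )
        overlap = _intervals_overlap(row["mean_sj"], row["sd_sj"], c["mean_sj"], c["sd_sj"])
        if abs(dsj) >= major and not overlap:
            tier = "major"
        elif rare <= abs(dsj) < major:
            tier = "rare"
        else:
            tier = "none"
        rows.append(
            {
                "event": event,
                "kind": row["kind"],
                "exon": row["exon"],
                "condition": condition,
                "mean_sj_treated": row["mean_sj"],
                "sd_sj_treated": row["sd_sj"],
                "n_treated": row["n"],
                "mean_sj_control": c["mean_sj"],
                "sd_sj_control": c["sd_sj"],
                "n_control": c["n"],
                "delta_sj": dsj,
                "delta_psi": dpsi,
                "sd_overlap": overlap,
                "tier": tier,
                "direction": _direction(row["kind"], dsj),
                "n_events_examined": n_events,
            }
        )
    return pd.DataFrame(rows, columns=_CALL_COLUMNS)


def classify_rbp_roles(calls: pd.DataFrame) -> pd.DataFrame:
    """Regulatory role of each depleted protein from its major exon calls.

    Only major-tier exon-skipping calls count (pseudoexon events are set
    aside, as their inclusion polarity is opposite to exon events). The
    effect on inclusion is dPSI where defined, else -dSJ (equivalent for
    clean single skips). All effects negative -> activator; all positive
    -> repressor; mixed -> bidirectional; no calls -> none. Events with
    |dPSI| >= 0.4 are flagged as strong effects.
    """
    rows = []
    for condition, group in calls.groupby("condition", sort=True):
        major = group[
            (group["tier"] == "major") & group["kind"].isin(["single_ES", "multi_ES"])
        ]
        effects = np.where(
            major["delta_psi"].notna(), major["delta_psi"], -major["delta_sj"]
        )
        if len(effects) == 0:
            role = "none"
        elif (effects < 0).all():
            role = "activator"
        elif (effects > 0).all():
            role = "repressor"
        else:
            role = "bidirectional"
        strong = major[np.abs(effects) >= STRONG_EFFECT] if len(effects) else major
        rows.append(
            {
                "condition": condition,
                "role": role,
                "n_major_exon_calls": len(major),
                "events": ";".join(major["event"]),
                "strong_effects": ";".join(strong["event"]) if len(effects) else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["condition", "role", "n_major_exon_calls", "events", "strong_effects"],
    )


def responsive_exon_census(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulation of major-tier calls.

    Returns (per_event, per_condition): how many conditions deregulate
    each event, and how many events each condition deregulates. Exon
    events and pseudoexon insertions are counted in separate categories.
    """
    major = calls[calls["tier"] == "major"].copy()
    major["category"] = np.where(
        major["kind"].isin(["single_ES", "multi_ES"]), "exon", major["kind"]
    )
    per_event = (
        major.groupby(["event", "category"])
        .agg(n_conditions=("condition", "nunique"), conditions=("condition", ";".join))
        .reset_index()
    )
    per_condition = (
        major.groupby(["condition", "category"])
        .agg(n_events=("event", "nunique"), events=("event", ";".join))
        .reset_index()
    )
    return per_event, per_condition
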