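"""Event densities across chromatin-state segmentations.

Events (mutations or lesions) are mapped onto a chromatin-state partition,
counts are normalized to events per megabase of state footprint, and broad
state groups (heterochromatin, promoters, enhancers, transcribed) are
compared between samples with Bonferroni-corrected paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import LabelledIntervals, read_bed

#: default broad-group assignment for ChromHMM-style 15-state labels
DEFAULT_STATE_GROUPS = {
    "1_Active_Promoter": "promoters",
    "2_Weak_Promoter": "promoters",
    "3_Poised_Promoter": "promoters",
    "4_Strong_Enhancer": "enhancers",
    "5_Strong_Enhancer": "enhancers",
    "6_Weak_Enhancer": "enhancers",
    "7_Weak_Enhancer": "enhancers",
    "8_Insulator": "heterochromatin",
    "9_Txn_Transition": "transcribed",
    "10_Txn_Elongation": "transcribed",
    "11_Weak_Txn": "transcribed",
    "12_Repressed": "heterochromatin",
    "13_Heterochrom/lo": "heterochromatin",
    # 14_Repetitive/CNV and 15_Repetitive/CNV: excluded by default upstream
}

DEFAULT_EXCLUDED_STATES = ("14_Repetitive/CNV", "15_Repetitive/CNV")


@dataclass
class ChromatinSegmentation:
    intervals: LabelledIntervals
    footprints: dict
    excluded_footprints: dict

    @property
    def states(self) -> list[str]:
        return sorted(self.footprints)


def load_segmentation(source, excluded_states=()) -> ChromatinSegmentation:
    """Load a BED4 segmentation (path or record iterable); segmentations must
    partition — overlapping intervals are an error. Excluded states are
    dropped but their footprints reported."""
    records = list(read_bed(source)) if isinstance(source, (str,)) or hasattr(source, "__fspath__") else list(source)
    excluded = set(excluded_states)
    kept = [r for r in records if r[3] not in excluded]
    dropped = [r for r in records if r[3] in excluded]
    # overlap validation must see the full partition, not just the kept states
    LabelledIntervals.from_records(records)
    intervals = LabelledIntervals.from_records(kept)
    excluded_fp: dict = {}
    for _, s, e, lab in dropped:
        excluded_fp[lab] = excluded_fp.get(lab, 0) + (e - s)
    return ChromatinSegmentation(intervals, intervals.footprints(), excluded_fp)


def _event_tuples(events):
    for ev in events:
        sample = getattr(ev, "sample_id", None) or "all"
        yield ev.contig, ev.pos, sample


def state_density(events, segmentation: ChromatinSegmentation) -> pd.DataFrame:
    """Per-sample per-state counts and densities (events/Mb of footprint).

    Events falling outside the retained segmentation are reported under the
    ``unassigned`` state with NaN density, never silently dropped.
    """
    rows = []
    for contig, pos, sample in _event_tuples(events):
        label = segmentation.intervals.lookup_one(contig, pos)
        rows.append((sample, label if label is not None else "unassigned"))
    df = pd.DataFrame(rows, columns=["sample", "state"])
    samples = sorted(df["sample"].unique()) if len(df) else ["all"]
    states = segmentation.states + ["unassigned"]
    out = []
    for sample in samples:
        sub = df[df["sample"] == sample]
        counts = sub["state"].value_counts()
        for state in states:
            n = int(counts.get(state, 0))
            fp = segmentation.footprints.get(state)
            if fp:
                dens = n / fp * 1e6
            else:
                dens = np.nan  # zero/unknown footprint: density undefined
            out.append((sample, state, n, fp if fp else np.nan, dens))
    return pd.DataFrame(out, columns=["sample", "state", "count", "footprint_bp", "events_per_mb"])


def compare_state_groups(
    table: pd.DataFrame,
    grouping: dict[str, str] | None = None,
    reference_group: str = "heterochromatin",
) -> pd.DataFrame:
    """Paired t-tests of per-sample group densities against a reference group.

    Group density per sample is total events in the group divided by total
    group footprint (events/Mb). Raw two-sided p-values are Bonferroni
    multiplied by the number of comparisons and capped at 1.
    """
    grouping = grouping or DEFAULT_STATE_GROUPS
    t = table[table.state != "unassigned"].copy()
    t["group"] = t.state.map(grouping)
    t = t.dropna(subset=["group"])
    g = (
        t.groupby(["sample", "group"])
        .agg(count=("count", "sum"), footprint_bp=("footprint_bp", "sum"))
        .reset_index()
    )
    g["events_per_mb"] = g["count"] / g["footprint_bp"] * 1e6
    wide = g.pivot(index="sample", columns="group", values="events_per_mb")
    if reference_group not in wide.columns:
        raise ValueError(f"reference group {reference_group!r} absent from table")
    others = [c for c in wide.columns if c != reference_group]
    n_comparisons = len(others)
    rows = []
    for group in others:
        paired = wide[[reference_group, group]].dropna()
        if len(paired) < 2:
            rows.append((group, len(paired), np.nan, np.nan, np.nan, "skipped: n < 2"))
            continue
        res = stats.ttest_rel(paired[reference_group], paired[group])
        stat = float(res.statistic)
        p = float(res.pvalue)
        if np.isnan(stat):  # identical pairs: zero variance of differences
            stat, p = 0.0, 1.0
        rows.append((group, len(paired), stat, p, min(p * n_comparisons, 1.0), ""))
    return pd.DataFrame(
        rows,
        columns=["group", "n_samples", "t_statistic", "p_raw", "p_bonferroni", "note"],
    )
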