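"""Replication- and transcription-strand asymmetry of guanine-anchored events.

Every event in this package is anchored on a guanine: a top-strand G (event
strand '+') or a bottom-strand G, i.e. a top-strand C (event strand '-').

Replication: within a rightward-replicating domain the top strand is the
lagging-strand template and the bottom strand the leading-strand template;
leftward domains flip. A '+' event in a rightward domain is therefore a
lagging-template guanine.

Transcription: for a gene on strand s, a guanine lying on strand s is on the
non-transcribed (coding) strand; a guanine on the opposite strand is on the
transcribed (template) strand, which is surveyed by transcription-coupled
repair.

Rates are normalized by the strand-specific guanine content of the assigned
regions (events per Mb of G), so composition differences between strands do
not masquerade as asymmetry. With replicate samples the test is a two-sided
paired t-test on per-sample rates; with a single sample, a chi-square test
against expected counts proportional to strand G content (df = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Genome, complement
from .intervals import LabelledIntervals


def _strand_g_counts(genome: Genome, intervals) -> dict[str, tuple[int, int]]:
    """(top-strand G, bottom-strand G) bp within each interval label."""
    out: dict[str, list[int]] = {}
    for contig, start, end, label in intervals:
        codes = genome.codes(contig)[start:end]
        g_top = int(np.count_nonzero(codes == 2))
        g_bottom = int(np.count_nonzero(codes == 1))
        cur = out.setdefault(str(label), [0, 0])
        cur[0] += g_top
        cur[1] += g_bottom
    return {k: (v[0], v[1]) for k, v in out.items()}


@dataclass
class ReplicationDomainMap:
    intervals: LabelledIntervals
    g_leading: int  # G bp on leading-strand templates
    g_lagging: int

    @classmethod
    def from_records(cls, records, genome: Genome) -> "ReplicationDomainMap":
        recs = [(c, s, e, d) for c, s, e, d in records]
        for _, _, _, d in recs:
            if d not in ("left", "right"):
                raise ValueError(f"replication direction must be left/right, got {d!r}")
        iv = LabelledIntervals.from_records(recs)
        by_dir = _strand_g_counts(genome, recs)
        right_top, right_bottom = by_dir.get("right", (0, 0))
        left_top, left_bottom = by_dir.get("left", (0, 0))
        # rightward fork: top = lagging template, bottom = leading template
        g_lagging = right_top + left_bottom
        g_leading = right_bottom + left_top
        return cls(iv, g_leading, g_lagging)

    def assign(self, contig: str, pos: int, strand: str) -> str:
        direction = self.intervals.lookup_one(contig, pos)
        if direction is None:
            return "unassigned"
        if direction == "right":
            return "lagging" if strand == "+" else "leading"
        return "leading" if strand == "+" else "lagging"


@dataclass
class GeneSet:
    """Strand-annotated gene bodies; same-strand overlaps are merged and
    opposite-strand overlaps flagged ambiguous (events there are excluded)."""

    intervals: LabelledIntervals  # labels: '+', '-', or 'ambiguous'
    g_transcribed: int
    g_non_transcribed: int

    @classmethod
    def from_records(cls, records, genome: Genome) -> "GeneSet":
        by_contig: dict[str, list] = {}
        for contig, start, end, strand in records:
            if strand not in "+-":
                raise ValueError(f"gene strand must be +/-, got {strand!r}")
            by_contig.setdefault(contig, []).append((start, end, strand))
        flat = []
        for contig, rows in by_contig.items():
            rows.sort()
            # sweep: merge into maximal blocks labelled by the strand set
            events = []
            for s, e, st in rows:
                events.append((s, 1, st))
                events.append((e, -1, st))
            events.sort()
            active: dict[str, int] = {"+": 0, "-": 0}
            prev = None
            for x, delta, st in events:
                label = None
                if active["+"] > 0 and active["-"] > 0:
                    label = "ambiguous"
                elif active["+"] > 0:
                    label = "+"
                elif active["-"] > 0:
                    label = "-"
                if prev is not None and label is not None and x > prev:
                    flat.append((contig, prev, x, label))
                active[st] += delta
                prev = x
        # coalesce adjacent same-label pieces
        flat.sort()
        merged = []
        for rec in flat:
            if merged and merged[-1][0] == rec[0] and merged[-1][2] == rec[1] and merged[-1][3] == rec[3]:
                merged[-1] = (rec[0], merged[-1][1], rec[2], rec[3])
            else:
                merged.append(rec)
        iv = LabelledIntervals.from_records(merged)
        by_label = _strand_g_counts(genome, merged)
        plus_top, plus_bottom = by_label.get("+", (0, 0))
        minus_top, minus_bottom = by_label.get("-", (0, 0))
        # non-transcribed strand = the gene's own strand
        g_non_transcribed = plus_top + minus_bottom
        g_transcribed = plus_bottom + minus_top
        return cls(iv, g_transcribed, g_non_transcribed)

    def assign(self, contig: str, pos: int, strand: str) -> str:
        label = self.intervals.lookup_one(contig, pos)
        if label is None:
            return "intergenic"
        if label == "ambiguous":
            return "ambiguous"
        return "non_transcribed" if label == strand else "transcribed"


def event_strand(ev, genome: Genome | None = None) -> str | None:
    """'+' when the event's G is on the top strand, '-' when on the bottom."""
    strand = getattr(ev, "strand", None)
    if strand in ("+", "-"):
        return strand
    ref = getattr(ev, "ref", None)
    if ref == "G":
        return "+"
    if ref == "C":
        return "-"
    return None


def mutation_class(ev) -> str:
    """G-centered substitution class (G>T / G>C / G>A) or 'lesion'."""
    ref = getattr(ev, "ref", None)
    alt = getattr(ev, "alt", None)
    if alt in (None, "."):
        return "lesion"
    if ref == "G":
        return f"G>{alt}"
    if ref == "C":
        return f"G>{complement(alt)}"
    return "other"


def assign_events(events, assigner, genome: Genome | None = None) -> pd.DataFrame:
    """Per-event strand-class assignment table with conservation accounting."""
    rows = []
    for ev in events:
        s = event_strand(ev, genome)
        if s is None:
            cls = "unassigned"
        else:
            cls = assigner.assign(ev.contig, ev.pos, s)
        sample = getattr(ev, "sample_id", None) or "all"
        rows.append((sample, mutation_class(ev), cls))
    return pd.DataFrame(rows, columns=["sample", "mutation_class", "assignment"])


@dataclass
class AsymmetryResult:
    mutation_class: str
    strand_a: str
    strand_b: str
    count_a: int
    count_b: int
    g_bp_a: int
    g_bp_b: int
    rate_a: float  # events per Mb of strand-specific G
    rate_b: float
    log2_ratio: float  # log2(rate_a / rate_b)
    test: str | None = None
    statistic: float | None = None
    p_value: float | None = None
    n_samples: int | None = None


def strand_rates(
    count_a: int, count_b: int, g_bp_a: int, g_bp_b: int,
    strand_a: str = "A", strand_b: str = "B", mutation_class: str = "all",
) -> AsymmetryResult:
    """Guanine-normalized per-strand rates and their log2 ratio."""
    if g_bp_a <= 0 or g_bp_b <= 0:
        raise ValueError("strand G content must be positive")
    rate_a = count_a / g_bp_a * 1e6
    rate_b = count_b / g_bp_b * 1e6
    with np.errstate(divide="ignore"):
        log2_ratio = float(np.log2(rate_a / rate_b)) if count_a and count_b else np.nan
    return AsymmetryResult(
        mutation_class, strand_a, strand_b, count_a, count_b, g_bp_a, g_bp_b,
        rate_a, rate_b, log2_ratio,
    )


def asymmetry_test(
    per_sample_counts: list[tuple[int, int]], g_bp_a: int, g_bp_b: int
) -> tuple[str, float, float]:
    """(test name, statistic, two-sided p).

    >= 2 samples: paired t-test on per-sample G-normalized rates.
    1 sample: chi-square of the two counts against expectations proportional
    to strand G content (df = 1).
    """
    if g_bp_a <= 0 or g_bp_b <= 0:
        raise ValueError("strand G content must be positive")
    n = len(per_sample_counts)
    if n == 0:
        raise ValueError("no samples")
    if n >= 2:
        ra = [a / g_bp_a * 1e6 for a, _ in per_sample_counts]
        rb = [b / g_bp_b * 1e6 for _, b in per_sample_counts]
        res = stats.ttest_rel(ra, rb)
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(stat):  # identical rates in every sample
            stat, p = 0.0, 1.0
        return "paired_t", stat, p
    a, b = per_sample_counts[0]
    total = a + b
    if total == 0:
        raise ValueError("single sample with zero events: test undefined")
    pa = g_bp_a / (g_bp_a + g_bp_b)
    res = stats.chisquare([a, b], f_exp=[total * pa, total * (1 - pa)])
    return "chi_square", float(res.statistic), float(res.pvalue)


def analyze_asymmetry(
    events, assigner, strand_a: str, strand_b: str, g_bp_a: int, g_bp_b: int,
    genome: Genome | None = None,
) -> list[AsymmetryResult]:
    """Full per-mutation-class asymmetry analysis for one strand dichotomy.

    ``strand_a``/``strand_b`` name the two assignment classes (e.g. 'leading'
    vs 'lagging', or 'non_transcribed' vs 'transcribed'); ``strand_a`` is the
    log2 numerator.
    """
    table = assign_events(events, assigner, genome)
    results = []
    for mclass, sub in table.groupby("mutation_class"):
        per_sample = []
        for _, s in sub.groupby("sample"):
            per_sample.append(
                (
                    int((s.assignment == strand_a).sum()),
                    int((s.assignment == strand_b).sum()),
                )
            )
        count_a = sum(a for a, _ in per_sample)
        count_b = sum(b for _, b in per_sample)
        res = strand_rates(count_a, count_b, g_bp_a, g_bp_b, strand_a, strand_b, mclass)
        if count_a + count_b > 0:
            test, stat, p = asymmetry_test(per_sample, g_bp_a, g_bp_b)
            res.test, res.statistic, res.p_value, res.n_samples = test, stat, p, len(per_sample)
        results.append(res)
    return results


def log2_ratio_comparison(a: float, b: float) -> float:
    """Ratio of two asymmetry effect sizes (log2 ratios), e.g. for
    benchmarking one process's strand bias against another's."""
    if b == 0:
        raise ValueError("reference log2 ratio is zero")
    return a / b
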