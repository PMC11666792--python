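"""Consensus somatic-variant filtering and burden summaries.

Multiple probabilistic callers are run upstream (externally); this module
implements the downstream filtering: per-sample intersection of caller call
sets (all SNV-capable callers for SNVs, the indel-capable pair for indels),
removal of variants shared across samples (likely germline or recurrent
artifacts), and per-genome burden/fold-change summaries.

Variant identity is (contig, 0-based position, ref, alt) after indel
left-normalization, so representation differences between callers do not
cause spurious consensus misses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from scipy import stats

DEFAULT_SNV_CALLERS = frozenset({"strelka2", "varscan2", "somaticsniper"})
DEFAULT_INDEL_CALLERS = frozenset({"strelka2", "varscan2"})


@dataclass(frozen=True)
class VariantCall:
    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    sample_id: str | None = None
    callers: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def var_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass
class ConsensusPolicy:
    snv_required_callers: frozenset = DEFAULT_SNV_CALLERS
    indel_required_callers: frozenset = DEFAULT_INDEL_CALLERS
    cross_sample_max: int = 1
    position_only_cross_sample: bool = False

    def __post_init__(self):
        if not self.snv_required_callers or not self.indel_required_callers:
            raise ValueError("required caller sets must be non-empty")


def trim_and_shift(contig: str, pos: int, ref: str, alt: str, genome=None):
    """Left-normalize an allele pair (standard left-alignment): trim shared
    trailing bases, rotating the window left through repeat tracts when a
    genome is available, then trim shared leading bases."""
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if (
            genome is not None
            and pos > 0
            and ref
            and alt
            and ref[-1] == alt[-1]
            and len(ref) != len(alt)
        ):
            prev = genome.base(contig, pos - 1)
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return contig, pos, ref, alt


def normalize_call(call: VariantCall, genome=None) -> VariantCall:
    contig, pos, ref, alt = trim_and_shift(call.contig, call.pos, call.ref, call.alt, genome)
    if (contig, pos, ref, alt) == call.key:
        return call
    return VariantCall(contig, pos, ref, alt, call.sample_id, call.callers)


def read_vcf(path, sample_id: str, caller: str, genome=None, pass_only: bool = False) -> list[VariantCall]:
    """Read a VCF into VariantCalls (one per ALT allele, positions 0-based)."""
    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if pass_only and "PASS" not in (rec.filter.keys() or ["PASS"]):
                continue
            for alt in rec.alts or ():
                if alt in (".", "*", None):
                    continue
                call = VariantCall(
                    rec.contig, rec.pos - 1, rec.ref, alt, sample_id, frozenset({caller})
                )
                calls.append(normalize_call(call, genome))
    return calls


def consensus_intersect(
    callsets: dict[str, list[VariantCall]], policy: ConsensusPolicy | None = None
) -> list[VariantCall]:
    """Variants present in every required caller's set for their class."""
    policy = policy or ConsensusPolicy()
    for required in (policy.snv_required_callers, policy.indel_required_callers):
        missing = required - set(callsets)
        if missing:
            raise ValueError(f"policy requires absent callers: {sorted(missing)}")
    key_maps = {c: {v.key: v for v in calls} for c, calls in callsets.items()}
    out = []
    seen = set()
    for caller, calls in callsets.items():
        for v in calls:
            if v.key in seen:
                continue
            required = (
                policy.snv_required_callers if v.var_class == "SNV" else policy.indel_required_callers
            )
            if caller not in required:
                continue
            if all(v.key in key_maps[c] for c in required):
                supporting = frozenset(c for c in callsets if v.key in key_maps[c])
                out.append(
                    VariantCall(v.contig, v.pos, v.ref, v.alt, v.sample_id, supporting)
                )
                seen.add(v.key)
    out.sort(key=lambda v: v.key)
    return out


def remove_cross_sample(
    samples: dict[str, list[VariantCall]], policy: ConsensusPolicy | None = None
) -> tuple[dict[str, list[VariantCall]], dict[str, int]]:
    """Drop variants seen in more than ``cross_sample_max`` samples.

    Returns the filtered call sets and per-sample removal counts.
    """
    policy = policy or ConsensusPolicy()

    def ident(v: VariantCall):
        if policy.position_only_cross_sample:
            return (v.contig, v.pos)
        return v.key

    presence = Counter()
    for calls in samples.values():
        for k in {ident(v) for v in calls}:
            presence[k] += 1
    shared = {k for k, n in presence.items() if n > policy.cross_sample_max}
    filtered, removed = {}, {}
    for sample, calls in samples.items():
        kept = [v for v in calls if ident(v) not in shared]
        filtered[sample] = kept
        removed[sample] = len(calls) - len(kept)
    return filtered, removed


def mutation_burden(
    samples: dict[str, list[VariantCall]], grouping: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample SNV/indel counts plus group medians, fold changes and a
    two-sided Mann-Whitney U between each group pair.

    Fold change is treated-median / untreated-median in the order groups are
    first seen; with one sample per group it degenerates to the plain ratio.
    """
    rows = []
    for sample, calls in samples.items():
        n_snv = sum(1 for v in calls if v.var_class == "SNV")
        n_indel = len(calls) - n_snv
        rows.append((sample, grouping.get(sample, "ungrouped"), n_snv, n_indel))
    table = pd.DataFrame(rows, columns=["sample", "group", "n_snv", "n_indel"])

    groups = list(dict.fromkeys(table.group))
    summary_rows = []
    for var in ("n_snv", "n_indel"):
        medians = {g: float(table.loc[table.group == g, var].median()) for g in groups}
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                a = table.loc[table.group == ga, var]
                b = table.loc[table.group == gb, var]
                if medians[gb] == 0:
                    fold = np.nan  # undefined: reference median is zero
                else:
                    fold = medians[ga] / medians[gb]
                if len(a) >= 1 and len(b) >= 1 and (len(a) > 1 or len(b) > 1):
                    p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
                else:
                    p = np.nan
                summary_rows.append((var, ga, gb, medians[ga], medians[gb], fold, p))
    summary = pd.DataFrame(
        summary_rows,
        columns=["variable", "group", "reference_group", "median", "reference_median", "fold_change", "mwu_p"],
    )
    return table, summary
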