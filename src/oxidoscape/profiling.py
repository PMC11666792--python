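"""Anchor-relative event profiles with trinucleotide normalization.

For a set of anchor positions (nucleosome dyads or transcription-factor site
midpoints) and a window of half-width ``W`` (default 500, a 1000 bp window),
the observed per-offset event count ``O_j`` is compared with the expected
count under the genome-wide context model::

    E_j = sum_c f_c * n_c(j),    f_c = events_c / genome_c

where ``f_c`` is the genome-wide per-context event frequency over the 64
top-strand trinucleotides and ``n_c(j)`` counts occurrences of context ``c``
at offset ``j`` across all anchor windows. The profile statistic is
``L_j = log2(O_j / E_j)``; offsets with zero observed or expected counts are
flagged missing (NaN), never imputed as infinities.

Profiles are smoothed with a Savitzky-Golay filter (201-point window,
polynomial order 3) and periodicity is estimated with a least-squares
periodogram over an explicit period grid, which handles missing offsets
naturally (unevenly-sampled formulation). Rotational analysis restricts to
the 147 bp nucleosome core (|j| <= 73) over the 8-15 bp band; translational
analysis uses the full window over 150-250 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .genome import Genome

NUCLEOSOME_CORE_HALFWIDTH = 73
ROTATIONAL_BAND = (8.0, 15.0)
TRANSLATIONAL_BAND = (150.0, 250.0)


@dataclass
class TrinucleotideTable:
    genome_counts: np.ndarray  # 64
    event_counts: np.ndarray  # 64
    unresolved_events: int = 0

    @property
    def frequency(self) -> np.ndarray:
        """f_c = events_c / genome_c, zero where the genome lacks context c."""
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(self.genome_counts > 0, self.event_counts / np.maximum(self.genome_counts, 1), 0.0)
        if np.any((self.genome_counts == 0) & (self.event_counts > 0)):
            raise ValueError("events observed in a context absent from the genome")
        return f


@dataclass
class PositionalProfile:
    offsets: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    context_counts: np.ndarray = field(repr=False, default=None)  # 64 x (2W+1)
    n_anchors: int = 0

    @property
    def log2_ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            L = np.log2(self.observed / self.expected)
        L[(self.observed <= 0) | (self.expected <= 0)] = np.nan
        return L

    def smoothed(self, window: int = 201, polyorder: int = 3) -> np.ndarray:
        return savgol_smooth(self.log2_ratio, window, polyorder)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "observed": self.observed,
                "expected": self.expected,
                "log2_ratio": self.log2_ratio,
                "smoothed": self.smoothed() if len(self.offsets) >= 201 else np.nan,
            }
        )


def _event_positions(events) -> list[tuple[str, int]]:
    return [(ev.contig, ev.pos) for ev in events]


def window_context_table(
    anchors: dict[str, np.ndarray], genome: Genome, halfwidth: int = 500
) -> np.ndarray:
    """n_c(j): occurrences of each top-strand trinucleotide at each offset.

    Returns a 64 x (2*halfwidth + 1) matrix. Windows are clipped at contig
    edges; anchors on unknown contigs are skipped.
    """
    W = halfwidth
    mat = np.zeros((64, 2 * W + 1), dtype=np.int64)
    for contig, pos_arr in anchors.items():
        if contig not in genome:
            continue
        tric = genome.tricodes(contig)
        L = len(tric)
        pos_arr = np.asarray(pos_arr, dtype=np.int64)
        for col, j in enumerate(range(-W, W + 1)):
            p = pos_arr + j
            ok = (p >= 0) & (p < L)
            codes = tric[p[ok]]
            codes = codes[codes < 64]
            if codes.size:
                mat[:, col] += np.bincount(codes, minlength=64)
    return mat


def event_context_frequency(events, genome: Genome) -> TrinucleotideTable:
    """Genome-wide per-context event frequency table (top-strand keyed)."""
    genome_counts = genome.trinucleotide_counts()
    event_counts = np.zeros(64, dtype=np.int64)
    unresolved = 0
    for contig, pos in _event_positions(events):
        tri = genome.tricodes(contig)[pos] if contig in genome else 64
        if tri >= 64:
            unresolved += 1
        else:
            event_counts[tri] += 1
    return TrinucleotideTable(genome_counts, event_counts, unresolved)


def obs_exp_log2(
    events,
    anchors: dict[str, np.ndarray],
    genome: Genome,
    halfwidth: int = 500,
    context_table: np.ndarray | None = None,
    frequency_table: TrinucleotideTable | None = None,
) -> PositionalProfile:
    """Observed/expected positional profile around a set of anchors.

    Events are counted at every anchor window containing them (windows may
    overlap). The expectation uses genome-wide event context frequencies
    computed from the same event set unless a table is supplied.
    """
    n_anchors = sum(len(v) for v in anchors.values())
    if n_anchors == 0:
        raise ValueError("no anchors")
    events = list(events)  # may be a one-shot iterator; we pass over it twice
    W = halfwidth
    if context_table is None:
        context_table = window_context_table(anchors, genome, W)
    if frequency_table is None:
        frequency_table = event_context_frequency(events, genome)

    observed = np.zeros(2 * W + 1)
    for contig, pos in _event_positions(events):
        if contig not in anchors:
            continue
        a = anchors[contig]
        lo = np.searchsorted(a, pos - W, side="left")
        hi = np.searchsorted(a, pos + W, side="right")
        if hi > lo:
            np.add.at(observed, pos - a[lo:hi] + W, 1)

    expected = frequency_table.frequency @ context_table
    return PositionalProfile(
        offsets=np.arange(-W, W + 1),
        observed=observed,
        expected=expected,
        context_counts=context_table,
        n_anchors=n_anchors,
    )


def savgol_smooth(values: np.ndarray, window: int = 201, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing with polynomial extrapolation at the ends.

    Missing values (NaN) are linearly interpolated before filtering and the
    smoothed curve is returned over the full range.
    """
    values = np.asarray(values, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and exceed polyorder")
    if window > len(values):
        raise ValueError("window longer than profile")
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("all values missing")
    filled = values
    if not finite.all():
        idx = np.arange(len(values))
        filled = np.interp(idx, idx[finite], values[finite])
    return signal.savgol_filter(filled, window, polyorder, mode="interp")


@dataclass
class PeriodEstimate:
    period: float
    power: float  # fraction of variance explained at the peak
    band: tuple[float, float]
    amplitude: float
    phase: float
    significant: bool
    p_value: float


def _sinusoid_lsq(values, offsets, period):
    """Least-squares fit of a + b*cos + c*sin at one period; returns
    (mean a, cos coef, sin coef, explained SS, total SS)."""
    x = 2 * np.pi * offsets / period
    X = np.column_stack([np.ones_like(x), np.cos(x), np.sin(x)])
    beta, _, _, _ = np.linalg.lstsq(X, values, rcond=None)
    fit = X @ beta
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    ss_res = float(np.sum((values - fit) ** 2))
    return beta, ss_tot - ss_res, ss_tot


def estimate_period(
    profile,
    band: tuple[float, float],
    offsets_restriction: int | None = None,
    resolution: float | None = None,
    alpha: float = 0.05,
) -> PeriodEstimate:
    """Least-squares periodogram over a period grid.

    ``profile`` is a PositionalProfile (its unsmoothed log2 ratio is used)
    or an (offsets, values) pair. Missing offsets are simply excluded — the
    unevenly-sampled regression formulation needs no imputation. Power is the
    fraction of variance explained by the best-fitting sinusoid; significance
    is an F-test of that sinusoid against the constant model.
    """
    if isinstance(profile, PositionalProfile):
        offsets, values = profile.offsets, profile.log2_ratio
    else:
        offsets, values = profile
    offsets = np.asarray(offsets, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    if offsets_restriction is not None:
        keep &= np.abs(offsets) <= offsets_restriction
    offsets, values = offsets[keep], values[keep]
    if len(values) == 0:
        raise ValueError("no finite profile values in the restricted range")
    span = offsets.max() - offsets.min()
    if span < 3 * band[0]:
        raise ValueError("restricted range shorter than 3 cycles of the band minimum")
    if resolution is None:
        resolution = 0.05 if band[1] <= 20 else 1.0
    grid = np.arange(band[0], band[1] + resolution / 2, resolution)

    best = None
    for period in grid:
        beta, ss_exp, ss_tot = _sinusoid_lsq(values, offsets, period)
        power = ss_exp / ss_tot if ss_tot > 0 else 0.0
        if best is None or power > best[1]:
            best = (period, power, beta, ss_exp, ss_tot)
    period, power, beta, ss_exp, ss_tot = best
    amplitude = float(np.hypot(beta[1], beta[2]))
    phase = float(np.arctan2(-beta[2], beta[1]))
    n = len(values)
    if ss_tot <= 0 or n <= 3 or ss_tot - ss_exp <= 0:
        p_value = 1.0 if ss_tot <= 0 else 0.0
    else:
        f = (ss_exp / 2) / ((ss_tot - ss_exp) / (n - 3))
        p_value = float(stats.f.sf(f, 2, n - 3))
    significant = ss_tot > 0 and p_value < alpha
    return PeriodEstimate(
        period=float(period),
        power=float(power),
        band=band,
        amplitude=amplitude,
        phase=phase,
        significant=significant,
        p_value=p_value,
    )


@dataclass
class SinusoidFit:
    amplitude: float
    period: float
    phase: float
    offset: float
    rmse: float
    significant: bool


def fit_sinusoid(
    profile,
    period: float | None = None,
    band: tuple[float, float] = ROTATIONAL_BAND,
    offsets_restriction: int | None = None,
) -> SinusoidFit:
    """Fit a + b*cos(2*pi*j/P + phi); P fixed if given, else free within the
    band (grid-initialized from the periodogram, then refined)."""
    if isinstance(profile, PositionalProfile):
        offsets, values = profile.offsets, profile.log2_ratio
    else:
        offsets, values = profile
    offsets = np.asarray(offsets, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    if offsets_restriction is not None:
        keep &= np.abs(offsets) <= offsets_restriction
    offsets, values = offsets[keep], values[keep]

    est = None
    if period is None:
        est = estimate_period((offsets, values), band)
        # refine the grid argmax on a finer local grid
        local = np.arange(max(band[0], est.period - 0.2), min(band[1], est.period + 0.2), 0.005)
        period = est.period
        best_power = -1.0
        for p in local:
            _, ss_exp, ss_tot = _sinusoid_lsq(values, offsets, p)
            power = ss_exp / ss_tot if ss_tot > 0 else 0.0
            if power > best_power:
                best_power, period = power, p
    beta, ss_exp, ss_tot = _sinusoid_lsq(values, offsets, period)
    amplitude = float(np.hypot(beta[1], beta[2]))
    phase = float(np.arctan2(-beta[2], beta[1]))
    fitted = beta[0] + amplitude * np.cos(2 * np.pi * offsets / period + phase)
    rmse = float(np.sqrt(np.mean((values - fitted) ** 2)))
    if est is None:
        n = len(values)
        if ss_tot <= 0 or n <= 3 or ss_tot - ss_exp <= 0:
            p_value = 1.0 if ss_tot <= 0 else 0.0
        else:
            f = (ss_exp / 2) / ((ss_tot - ss_exp) / (n - 3))
            p_value = float(stats.f.sf(f, 2, n - 3))
        significant = ss_tot > 0 and p_value < 0.05
    else:
        significant = est.significant
    return SinusoidFit(
        amplitude=amplitude,
        period=float(period),
        phase=phase,
        offset=float(beta[0]),
        rmse=rmse,
        significant=significant,
    )


def classify_rotational(offsets, fit: SinusoidFit) -> np.ndarray:
    """Label offsets by rotational phase: within a quarter period of a fitted
    maximum -> 'inward' (histone-proximal); of a minimum -> 'outward'
    (solvent-exposed). Non-significant fits label everything 'intermediate'."""
    offsets = np.asarray(offsets, dtype=float)
    if not fit.significant or fit.amplitude <= 0:
        return np.full(offsets.shape, "intermediate", dtype=object)
    phase_val = np.cos(2 * np.pi * offsets / fit.period + fit.phase)
    out = np.full(offsets.shape, "intermediate", dtype=object)
    out[phase_val > 0] = "inward"
    out[phase_val < 0] = "outward"
    return out


def tf_midpoint_profile(
    events,
    tf_sites: dict[str, np.ndarray],
    halfwidth: int = 500,
    smooth: bool = True,
    genome: Genome | None = None,
    normalize: bool = False,
):
    """Raw event counts by offset relative to TF-site midpoints.

    Each event is assigned to its nearest midpoint (ties to the leftmost);
    events farther than ``halfwidth`` from every midpoint are ignored.
    Returns a DataFrame with offset, count and (optionally) smoothed columns;
    with ``normalize=True`` (requires a genome) the trinucleotide obs/exp
    machinery is applied instead and a PositionalProfile is returned.
    """
    n_sites = sum(len(v) for v in tf_sites.values())
    if n_sites == 0:
        raise ValueError("no TF sites")
    if normalize:
        if genome is None:
            raise ValueError("normalization requires a genome")
        return obs_exp_log2(events, tf_sites, genome, halfwidth)
    W = halfwidth
    counts = np.zeros(2 * W + 1)
    for contig, pos in _event_positions(events):
        if contig not in tf_sites:
            continue
        a = np.asarray(tf_sites[contig])
        i = np.searchsorted(a, pos)
        # nearest midpoint, ties to the leftmost
        best, best_d = None, None
        for k in (i - 1, i):
            if 0 <= k < len(a):
                d = abs(pos - a[k])
                if best_d is None or d < best_d:
                    best, best_d = a[k], d
        if best is not None and best_d <= W:
            counts[pos - best + W] += 1
    df = pd.DataFrame({"offset": np.arange(-W, W + 1), "count": counts})
    if smooth and len(counts) >= 201:
        df["smoothed"] = savgol_smooth(counts)
    return df
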