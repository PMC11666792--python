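"""Seeded synthetic fixtures for oxidative-mutagenesis analyses.

Generates a small reference genome, annotation tracks (nucleosome dyads,
chromatin-state segmentation, replication-direction domains, genes,
transcription-factor site midpoints), guanine-anchored events planted with a
known intensity model, per-caller somatic call sets, and lesion-capture SAM
records. Every output is a deterministic function of a single root seed, via
named substreams, so downstream analyses can be checked against the planted
truth.

The planting intensity at a candidate guanine position ``p`` (on either
strand) factorizes as::

    lambda(p) = state_multiplier(p)
              * context_term(p)
              * (1 + A_t * cos(2*pi * d_t(p) / P_t))          # translational
              * (1 + A_r * cos(2*pi * d_r(p) / P_r + phi))    # rotational,
              * strand_bias(p)                                #  |d_r| <= 73

where ``d_r`` is the signed offset to the nearest dyad (the rotational factor
applies only within the 147 bp nucleosome core) and ``d_t`` is the distance
along the dyad array from its first dyad. ``context_term`` is
``w_c / N_c`` — the configured weight of the top-strand trinucleotide at
``p`` divided by the genome-wide number of candidate positions carrying that
context — so the marginal trinucleotide distribution of planted events
converges to the normalized weights. Strand biases are odds multipliers on
the leading-template (replication) and non-transcribed (transcription)
guanines, making the expected log2 rate ratios exactly log2(bias).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BASES, Genome, complement
from .intervals import LabelledIntervals, write_bed

SNV_CALLERS = ("strelka2", "varscan2", "somaticsniper")
INDEL_CALLERS = ("strelka2", "varscan2")

_G, _C = 2, 1


class ConfigurationError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass
class SyntheticConfig:
    seed: int = 0
    contig_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrS1": 2_000_000, "chrS2": 2_000_000}
    )
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_dyads: int = 1_000_000  # cap; the spacing and contig length set the real number
    dyad_spacing: int = 192
    nucleosome_halfwidth: int = 73
    rotational_period: float = 10.3
    rotational_amplitude: float = 0.0
    rotational_phase: float = 0.0
    translational_period: float = 192.0
    translational_amplitude: float = 0.0
    state_rate_multipliers: dict[str, float] = field(
        default_factory=lambda: {
            "heterochromatin": 1.0,
            "promoter": 1.0,
            "enhancer": 1.0,
            "transcribed": 1.0,
        }
    )
    leading_lagging_bias: float = 1.0
    transcribed_bias: float = 1.0
    context_weights: dict[str, float] | None = None  # None -> uniform
    n_events: int = 10_000
    caller_fp_rate: float = 0.0
    caller_fn_rate: float = 0.0
    read_length: int = 150
    snv_alt: str = "T"  # alt for top-strand G events; complemented on '-'
    state_segment_mean: int = 20_000
    gene_mean_length: int = 20_000
    gene_gap_mean: int = 10_000
    n_tf_sites_per_contig: int = 500
    track_margin: int = 1_000

    def __post_init__(self):
        if any(l <= 0 for l in self.contig_lengths.values()):
            raise ConfigurationError("contig lengths must be positive")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ConfigurationError("base_composition must sum to 1")
        for a in (self.rotational_amplitude, self.translational_amplitude):
            if not (0.0 <= a < 1.0):
                raise ConfigurationError("amplitudes must lie in [0, 1)")
        for r in (self.caller_fp_rate, self.caller_fn_rate):
            if not (0.0 <= r <= 1.0):
                raise ConfigurationError("caller error rates must lie in [0, 1]")
        if self.context_weights is not None:
            w = list(self.context_weights.values())
            if any(x < 0 for x in w) or not any(x > 0 for x in w):
                raise ConfigurationError("context weights must be >= 0 with one > 0")
        if any(m <= 0 for m in self.state_rate_multipliers.values()):
            raise ConfigurationError("state multipliers must be positive")


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, order-independent child stream of the root seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


# ---------------------------------------------------------------------------
# reference and tracks

def make_reference(config: SyntheticConfig) -> Genome:
    """Sample i.i.d. bases per contig under the configured composition."""
    for name, length in config.contig_lengths.items():
        if length < 10_000:
            raise ConfigurationError(f"contig {name} shorter than 10 kb")
    rng = substream(config.seed, "reference")
    seqs = {}
    for name, length in config.contig_lengths.items():
        codes = rng.choice(4, size=length, p=np.asarray(config.base_composition))
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        seqs[name] = lut[codes].tobytes().decode("ascii")
    return Genome(seqs)


@dataclass
class Tracks:
    """Annotation fixtures: dyads, states, replication domains, genes, TF sites."""

    dyads: dict[str, np.ndarray]
    states: LabelledIntervals
    replication: LabelledIntervals
    genes: list[tuple[str, int, int, str]]  # (contig, start, end, strand)
    tf_sites: dict[str, np.ndarray]

    def write(self, outdir) -> None:
        import os

        write_bed(
            os.path.join(outdir, "dyads.bed"),
            ((c, int(p), int(p) + 1, ".", 0, "+") for c in self.dyads for p in self.dyads[c]),
        )
        write_bed(os.path.join(outdir, "states.bed"), self.states.records())
        write_bed(os.path.join(outdir, "replication.bed"), self.replication.records())
        write_bed(
            os.path.join(outdir, "genes.bed"),
            ((c, s, e, f"gene_{i}", 0, strand) for i, (c, s, e, strand) in enumerate(self.genes)),
        )
        write_bed(
            os.path.join(outdir, "tf_sites.bed"),
            ((c, int(p), int(p) + 1, ".", 0, "+") for c in self.tf_sites for p in self.tf_sites[c]),
        )


def make_annotation_fixtures(config: SyntheticConfig, genome: Genome) -> Tracks:
    rng = substream(config.seed, "tracks")
    dyads: dict[str, np.ndarray] = {}
    state_records = []
    repl_records = []
    genes: list[tuple[str, int, int, str]] = []
    tf_sites: dict[str, np.ndarray] = {}
    state_labels = list(config.state_rate_multipliers)

    for contig in genome.names:
        length = genome.length(contig)
        m = config.track_margin
        # dyads: uniform spacing from the margin, capped at n_dyads
        pos = np.arange(m, length - m, config.dyad_spacing, dtype=np.int64)
        dyads[contig] = pos[: config.n_dyads]

        # chromatin states: exponential-ish tiles covering the contig exactly
        cursor = 0
        while cursor < length:
            seg = int(rng.integers(config.state_segment_mean // 2, config.state_segment_mean * 2))
            end = min(cursor + seg, length)
            state_records.append((contig, cursor, end, state_labels[rng.integers(len(state_labels))]))
            cursor = end

        # replication domains: alternating left/right tiles covering the contig
        cursor = 0
        direction = "right" if rng.integers(2) else "left"
        while cursor < length:
            seg = int(rng.integers(50_000, 150_000))
            end = min(cursor + seg, length)
            repl_records.append((contig, cursor, end, direction))
            direction = "left" if direction == "right" else "right"
            cursor = end

        # genes: non-overlapping, random strand, separated by gaps
        cursor = int(rng.integers(0, config.gene_gap_mean))
        while cursor < length - config.gene_mean_length:
            glen = int(rng.integers(config.gene_mean_length // 2, config.gene_mean_length * 2))
            end = min(cursor + glen, length)
            strand = "+" if rng.integers(2) else "-"
            genes.append((contig, cursor, end, strand))
            cursor = end + int(rng.integers(1, config.gene_gap_mean * 2))

        tf = rng.choice(np.arange(m, length - m), size=config.n_tf_sites_per_contig, replace=False)
        tf_sites[contig] = np.sort(tf)

    tracks = Tracks(
        dyads=dyads,
        states=LabelledIntervals.from_records(state_records),
        replication=LabelledIntervals.from_records(repl_records),
        genes=genes,
        tf_sites=tf_sites,
    )
    for contig in genome.names:
        for track in (tracks.states, tracks.replication):
            if contig in track.ends and track.ends[contig][-1] > genome.length(contig):
                raise GenerationError(f"track exceeds bounds of {contig}")
    return tracks


# ---------------------------------------------------------------------------
# event planting

@dataclass
class PlantedTruth:
    """Planted events plus the latent factors needed for oracle checks.

    ``events`` columns: contig, pos (0-based), strand, ref, alt, var_class,
    context (top-strand trinucleotide), state, dyad_offset (signed offset to
    the nearest dyad), nucleosomal (offset within the 147 bp core),
    replication (leading/lagging/unassigned), transcription
    (transcribed/non_transcribed/intergenic), sample_id.
    """

    events: pd.DataFrame
    config: SyntheticConfig

    def positions(self) -> list[tuple[str, int, str]]:
        return list(zip(self.events.contig, self.events.pos, self.events.strand))

    def write_tsv(self, path) -> None:
        self.events.to_csv(path, sep="\t", index=False)


def _replication_classes(tracks: Tracks, contig: str, pos: np.ndarray, strand: str) -> np.ndarray:
    """Leading/lagging template assignment for guanines of the given strand.

    Rightward fork => top strand is the lagging template; leftward flips.
    """
    labels = tracks.replication.lookup(contig, pos)
    out = np.full(pos.shape, "unassigned", dtype=object)
    if strand == "+":
        out[labels == "right"] = "lagging"
        out[labels == "left"] = "leading"
    else:
        out[labels == "right"] = "leading"
        out[labels == "left"] = "lagging"
    return out


def _transcription_classes(genes, contig: str, pos: np.ndarray, strand: str) -> np.ndarray:
    gene_iv = LabelledIntervals.from_records(
        [(c, s, e, st) for c, s, e, st in genes], allow_overlap=False
    )
    gstrand = gene_iv.lookup(contig, pos)
    out = np.full(pos.shape, "intergenic", dtype=object)
    out[gstrand == strand] = "non_transcribed"
    out[(gstrand != None) & (gstrand != strand)] = "transcribed"  # noqa: E711
    return out


def plant_events(
    config: SyntheticConfig,
    genome: Genome,
    tracks: Tracks,
    sample_id: str = "S1",
    n_events: int | None = None,
) -> PlantedTruth:
    """Sample guanine-anchored events from the factorized intensity model.

    Events are drawn without replacement (weighted Gumbel top-k), so a planted
    set doubles as a valid somatic call set with unique variant keys.
    """
    n = config.n_events if n_events is None else n_events
    rng = substream(config.seed, f"events/{sample_id}")

    frames = []
    for contig in genome.names:
        codes = genome.codes(contig)
        tric = genome.tricodes(contig)
        for strand, base_code in (("+", _G), ("-", _C)):
            cand = np.flatnonzero(codes == base_code)
            cand = cand[(cand >= 1) & (cand <= len(codes) - 2)]
            cand = cand[tric[cand] < 64]
            if cand.size == 0:
                continue
            df = pd.DataFrame({"pos": cand})
            df["contig"] = contig
            df["strand"] = strand
            df["tricode"] = tric[cand]
            st = tracks.states.lookup(contig, cand)
            df["state"] = st
            dy = tracks.dyads[contig]
            idx = np.clip(np.searchsorted(dy, cand), 1, len(dy) - 1)
            nearest = np.where(
                np.abs(cand - dy[idx - 1]) <= np.abs(cand - dy[idx]), dy[idx - 1], dy[idx]
            )
            df["dyad_offset"] = cand - nearest
            df["in_array"] = (cand >= dy[0] - config.nucleosome_halfwidth) & (
                cand <= dy[-1] + config.nucleosome_halfwidth
            )
            df["d_t"] = cand - dy[0]
            df["replication"] = _replication_classes(tracks, contig, cand, strand)
            df["transcription"] = _transcription_classes(tracks.genes, contig, cand, strand)
            frames.append(df)
    cand_df = pd.concat(frames, ignore_index=True)

    # context term: weight / availability, keyed by top-strand trinucleotide
    weights = np.ones(64)
    if config.context_weights is not None:
        weights = np.zeros(64)
        from .genome import TRINUC_INDEX

        for tri, w in config.context_weights.items():
            weights[TRINUC_INDEX[tri]] = w
    avail = np.bincount(cand_df.tricode, minlength=64).astype(float)
    ctx_term = np.where(avail > 0, weights / np.maximum(avail, 1), 0.0)

    lam = ctx_term[cand_df.tricode.to_numpy()]
    lam = lam * cand_df.state.map(config.state_rate_multipliers).fillna(1.0).to_numpy(float)

    hw = config.nucleosome_halfwidth
    d_r = cand_df.dyad_offset.to_numpy(float)
    core = np.abs(d_r) <= hw
    rot = np.ones(len(cand_df))
    rot[core] = 1.0 + config.rotational_amplitude * np.cos(
        2 * np.pi * d_r[core] / config.rotational_period + config.rotational_phase
    )
    lam = lam * rot

    trans = np.ones(len(cand_df))
    in_arr = cand_df.in_array.to_numpy(bool)
    trans[in_arr] = 1.0 + config.translational_amplitude * np.cos(
        2 * np.pi * cand_df.d_t.to_numpy(float)[in_arr] / config.translational_period
    )
    lam = lam * trans

    lam = lam * np.where(cand_df.replication == "leading", config.leading_lagging_bias, 1.0)
    lam = lam * np.where(cand_df.transcription == "non_transcribed", config.transcribed_bias, 1.0)

    if not np.any(lam > 0):
        raise GenerationError("all-zero planting intensity")
    if n > np.count_nonzero(lam > 0):
        raise GenerationError("more events requested than candidate positions")

    # weighted sampling without replacement via Gumbel top-k
    with np.errstate(divide="ignore"):
        keys = np.log(lam) + rng.gumbel(size=len(lam))
    chosen = np.argpartition(-keys, n)[:n]

    ev = cand_df.iloc[chosen].copy()
    ev["ref"] = np.where(ev.strand == "+", "G", "C")
    alt = config.snv_alt.upper()
    ev["alt"] = np.where(ev.strand == "+", alt, complement(alt))
    ev["var_class"] = "SNV"
    ev["context"] = [
        BASES[t // 16] + BASES[(t // 4) % 4] + BASES[t % 4] for t in ev.tricode
    ]
    ev["nucleosomal"] = np.abs(ev.dyad_offset) <= hw
    ev["sample_id"] = sample_id
    ev = ev.sort_values(["contig", "pos", "strand"]).reset_index(drop=True)
    ev = ev[
        [
            "contig", "pos", "strand", "ref", "alt", "var_class", "context",
            "state", "dyad_offset", "nucleosomal", "replication", "transcription",
            "sample_id",
        ]
    ]

    # construction invariant: the strand-specific base is G everywhere
    for contig, sub in ev.groupby("contig", sort=False):
        c = genome.codes(contig)[sub.pos.to_numpy()]
        want = np.where(sub.strand.to_numpy() == "+", _G, _C)
        assert np.array_equal(c, want)
    return PlantedTruth(events=ev, config=config)


# ---------------------------------------------------------------------------
# call sets

def make_call_sets(
    truth: PlantedTruth, config: SyntheticConfig, genome: Genome
) -> dict[str, pd.DataFrame]:
    """Per-caller call sets: truth minus dropouts plus caller-private spurious calls.

    Caller errors are independent across callers; spurious calls land on
    guanine positions disjoint from the truth so consensus behavior is
    analytically predictable. Indels in the truth (if any) are only emitted by
    the indel-capable callers.
    """
    if len(truth.events) == 0:
        raise GenerationError("empty truth")
    rng = substream(config.seed, f"callsets/{truth.events.sample_id.iloc[0]}")
    truth_keys = set(zip(truth.events.contig, truth.events.pos))
    out = {}
    for caller in SNV_CALLERS:
        ev = truth.events
        if caller not in INDEL_CALLERS:
            ev = ev[ev.var_class == "SNV"]
        keep = rng.random(len(ev)) >= config.caller_fn_rate
        calls = ev.loc[keep, ["contig", "pos", "ref", "alt", "var_class"]].copy()
        n_fp = rng.binomial(len(ev), config.caller_fp_rate)
        fp_rows = []
        attempts = 0
        while len(fp_rows) < n_fp and attempts < 50 * (n_fp + 1):
            attempts += 1
            contig = genome.names[rng.integers(len(genome.names))]
            p = int(rng.integers(1, genome.length(contig) - 1))
            b = genome.base(contig, p)
            if b not in "GC" or (contig, p) in truth_keys:
                continue
            if b == "G":
                fp_rows.append((contig, p, "G", config.snv_alt.upper(), "SNV"))
            else:
                fp_rows.append((contig, p, "C", complement(config.snv_alt), "SNV"))
        if fp_rows:
            calls = pd.concat(
                [calls, pd.DataFrame(fp_rows, columns=calls.columns)], ignore_index=True
            )
        calls = calls.drop_duplicates(["contig", "pos", "ref", "alt"])
        out[caller] = calls.sort_values(["contig", "pos"]).reset_index(drop=True)
    return out


def write_vcf(calls: pd.DataFrame, genome: Genome, path) -> None:
    """Write a sites-only VCF 4.2 file (positions converted to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in genome.names:
            fh.write(f"##contig=<ID={name},length={genome.length(name)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in calls.itertuples(index=False):
            fh.write(f"{row.contig}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# lesion-capture SAM fixture

CONTAMINANT_CONTIG = "chrUn_synthetic_decoy"


def make_sam_fixture(
    lesions: pd.DataFrame,
    genome: Genome,
    config: SyntheticConfig,
    path,
    n_contaminants: int = 0,
) -> dict[str, int]:
    """Write one full-length alignment per lesion, plus planted contaminants.

    A '+' lesion becomes a flag-0 record whose leftmost column is the lesion;
    a '-' lesion becomes a flag-16 record whose rightmost column is the
    lesion (the read-5' convention of the extractor with offset 0).
    Contaminants cycle through clipped CIGARs, unmapped/secondary/duplicate
    flags, and a non-canonical decoy contig; a conforming extractor must
    reject all of them. Lesions too close to a contig end for a full-length
    alignment are skipped and counted.
    """
    rl = config.read_length
    counts = {"written": 0, "skipped_edge": 0, "contaminants": 0}
    lines = []
    lines.append("@HD\tVN:1.6\tSO:coordinate")
    for name in genome.names:
        lines.append(f"@SQ\tSN:{name}\tLN:{genome.length(name)}")
    if n_contaminants:
        lines.append(f"@SQ\tSN:{CONTAMINANT_CONTIG}\tLN:100000")

    records = []
    for i, row in enumerate(lesions.itertuples(index=False)):
        contig, pos, strand = row.contig, int(row.pos), row.strand
        if strand == "+":
            start = pos
        else:
            start = pos - rl + 1
        if start < 0 or start + rl > genome.length(contig):
            counts["skipped_edge"] += 1
            continue
        flag = 0 if strand == "+" else 16
        seq = genome.fetch(contig, start, start + rl)
        records.append(
            (contig, start, f"lesion_{i}\t{flag}\t{contig}\t{start + 1}\t60\t{rl}M\t*\t0\t0\t{seq}\t*")
        )
        counts["written"] += 1

    kinds = ("clipped", "unmapped", "secondary", "duplicate", "decoy")
    rng = substream(config.seed, "sam_contaminants")
    for i in range(n_contaminants):
        kind = kinds[i % len(kinds)]
        contig = genome.names[int(rng.integers(len(genome.names)))]
        start = int(rng.integers(0, genome.length(contig) - rl))
        seq = genome.fetch(contig, start, start + rl)
        if kind == "clipped":
            rec = f"cont_{i}\t0\t{contig}\t{start + 1}\t60\t{rl - 1}M1S\t*\t0\t0\t{seq}\t*"
        elif kind == "unmapped":
            rec = f"cont_{i}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*"
        elif kind == "secondary":
            rec = f"cont_{i}\t256\t{contig}\t{start + 1}\t60\t{rl}M\t*\t0\t0\t{seq}\t*"
        elif kind == "duplicate":
            rec = f"cont_{i}\t1024\t{contig}\t{start + 1}\t60\t{rl}M\t*\t0\t0\t{seq}\t*"
        else:
            rec = f"cont_{i}\t0\t{CONTAMINANT_CONTIG}\t{min(start, 1000) + 1}\t60\t{rl}M\t*\t0\t0\t*\t*"
        records.append((contig if kind != "unmapped" else "~", start, rec))
        counts["contaminants"] += 1

    records.sort(key=lambda r: (r[0], r[1]))
    lines.extend(r[2] for r in records)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return counts


# ---------------------------------------------------------------------------
# one-call convenience

def simulate(config: SyntheticConfig, outdir=None):
    """Generate reference, tracks and one planted event set; optionally write files."""
    genome = make_reference(config)
    tracks = make_annotation_fixtures(config, genome)
    truth = plant_events(config, genome, tracks)
    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        genome.to_fasta(os.path.join(outdir, "reference.fa"))
        tracks.write(outdir)
        truth.write_tsv(os.path.join(outdir, "truth.tsv"))
    return genome, tracks, truth
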