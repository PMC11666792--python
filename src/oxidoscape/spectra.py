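"""Mutation and lesion spectra: SBS96 / ID83 channelization and comparisons.

Single-base substitutions are reported in the pyrimidine-centered 96-channel
convention: a substitution whose reference base is a purine is
reverse-complemented (base and flanks) before channel assignment, giving
channels ``X[R>A]Y`` with R in {C, T}. Small indels follow the COSMIC
83-channel layout: 1-bp deletions/insertions of C or T stratified by
homopolymer run length, longer indels stratified by size and tandem-repeat
copy number, with deletion microhomology classes. Homopolymer length counts
the maximal run of the affected base INCLUDING the deleted base (deletions)
and EXCLUDING the inserted base (insertions); repeat copy number includes
the deleted copy.

Spectrum comparisons: cosine similarity, per-channel percentage
differentials, non-negative least-squares refitting against a fixed
signature catalog, between-signature exposure correlation with a minimum
attributed-mutation threshold, and flanking-base composition around 1-bp
deletions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genome import BASES, complement, revcomp
from .lesions import Lesion

PYRIMIDINES = "CT"
SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

#: canonical SBS96 channel order: substitution-major, then 5' and 3' flank
SBS96_CHANNELS = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
]
_SBS96_INDEX = {c: i for i, c in enumerate(SBS96_CHANNELS)}


def _id83_channels() -> list[str]:
    ch = []
    for base in "CT":
        ch += [f"1:Del:{base}:{i}" for i in range(6)]
    for base in "CT":
        ch += [f"1:Ins:{base}:{i}" for i in range(6)]
    for size in "2345":
        ch += [f"{size}:Del:R:{i}" for i in range(6)]
    for size in "2345":
        ch += [f"{size}:Ins:R:{i}" for i in range(6)]
    ch += ["2:Del:M:1"]
    ch += [f"3:Del:M:{i}" for i in (1, 2)]
    ch += [f"4:Del:M:{i}" for i in (1, 2, 3)]
    ch += [f"5:Del:M:{i}" for i in (1, 2, 3, 4, 5)]
    return ch


ID83_CHANNELS = _id83_channels()
_ID83_INDEX = {c: i for i, c in enumerate(ID83_CHANNELS)}

SCHEMAS = {"SBS96": SBS96_CHANNELS, "ID": ID83_CHANNELS}


class UnclassifiableVariant(ValueError):
    """Raised when context is unresolvable (N bases, contig edge)."""


# ---------------------------------------------------------------------------
# channel classifiers

def classify_sbs96(call, genome) -> str:
    """Pyrimidine-centered trinucleotide channel for an SNV."""
    if call.var_class != "SNV":
        raise ValueError("classify_sbs96 requires an SNV")
    tri = genome.trinucleotide(call.contig, call.pos)
    if tri is None:
        raise UnclassifiableVariant(f"unresolvable context at {call.contig}:{call.pos}")
    ref, alt = call.ref.upper(), call.alt.upper()
    if tri[1] != ref:
        raise ValueError(f"reference mismatch at {call.contig}:{call.pos}: {tri[1]} != {ref}")
    if ref not in PYRIMIDINES:
        tri = revcomp(tri)
        ref = complement(ref)
        alt = complement(alt)
    return f"{tri[0]}[{ref}>{alt}]{tri[2]}"


def lesion_channel(lesion: Lesion) -> str:
    """Display channel for a G lesion: its pyrimidine-collapsed context in
    the C>A block (presentation convention for side-by-side comparison with
    substitution spectra; lesions are not substitutions)."""
    if lesion.context is None:
        raise UnclassifiableVariant("lesion without context")
    tri = lesion.context if lesion.strand == "-" else revcomp(lesion.context)
    # a '+' lesion has top-strand G context; collapse to the C-centered strand
    if tri[1] != "C":
        raise ValueError(f"lesion context not G-centered: {lesion.context}")
    return f"{tri[0]}[C>A]{tri[2]}"


def _run_length(seq: str, pos: int, base: str, direction: int) -> int:
    n = 0
    i = pos
    while 0 <= i < len(seq) and seq[i] == base:
        n += 1
        i += direction
    return n


def _copies(seq: str, start: int, motif: str, direction: int) -> int:
    """Count adjacent tandem copies of motif starting at start, stepping by
    +/- len(motif)."""
    L = len(motif)
    n = 0
    i = start
    while True:
        j = i if direction > 0 else i - L
        if j < 0 or j + L > len(seq):
            break
        if seq[j : j + L] != motif:
            break
        n += 1
        i += direction * L
    return n


def classify_indel(call, genome) -> str:
    """COSMIC-style 83-channel classification of a small insertion/deletion."""
    from .consensus import trim_and_shift

    contig, pos, ref, alt = trim_and_shift(call.contig, call.pos, call.ref, call.alt, genome)
    seq = genome[contig]
    if len(ref) > 1 and len(alt) == 1 and ref[0] == alt[0]:
        deleted = ref[1:]
        site = pos + 1  # first deleted base
        return _classify_deletion(seq, site, deleted)
    if len(alt) > 1 and len(ref) == 1 and ref[0] == alt[0]:
        inserted = alt[1:]
        site = pos + 1  # insertion lands before this index
        return _classify_insertion(seq, site, inserted)
    # non-anchored representations (complex or pre-trimmed)
    if len(ref) > len(alt) and alt == "":
        return _classify_deletion(seq, pos, ref)
    if len(alt) > len(ref) and ref == "":
        return _classify_insertion(seq, pos, alt)
    raise UnclassifiableVariant(f"not a simple indel: {ref}>{alt}")


def _classify_deletion(seq: str, site: int, deleted: str) -> str:
    L = len(deleted)
    if site < 0 or site + L > len(seq):
        raise UnclassifiableVariant("deletion at contig edge")
    if L == 1:
        base = deleted
        run = (
            _run_length(seq, site - 1, base, -1)
            + 1
            + _run_length(seq, site + 1, base, +1)
        )
        label = base if base in PYRIMIDINES else complement(base)
        return f"1:Del:{label}:{min(run, 6) - 1}"
    copies = (
        _copies(seq, site, deleted, -1) + 1 + _copies(seq, site + L, deleted, +1)
    )
    size = str(min(L, 5))
    if copies > 1:
        return f"{size}:Del:R:{min(copies, 6) - 1}"
    # single copy: microhomology between the deleted sequence and its flanks
    mh = 0
    right = seq[site + L : site + 2 * L - 1]
    for k in range(min(L - 1, len(right)), 0, -1):
        if deleted[:k] == right[:k]:
            mh = k
            break
    left = seq[max(site - L + 1, 0) : site]
    for k in range(min(L - 1, len(left)), 0, -1):
        if deleted[-k:] == left[-k:]:
            mh = max(mh, k)
            break
    if mh >= 1:
        cap = 5 if L >= 5 else L - 1
        return f"{size}:Del:M:{min(mh, cap)}"
    return f"{size}:Del:R:0"


def _classify_insertion(seq: str, site: int, inserted: str) -> str:
    L = len(inserted)
    if L == 1:
        base = inserted
        run = _run_length(seq, site - 1, base, -1) + _run_length(seq, site, base, +1)
        label = base if base in PYRIMIDINES else complement(base)
        return f"1:Ins:{label}:{min(run, 5)}"
    copies = _copies(seq, site, inserted, -1) + _copies(seq, site, inserted, +1)
    return f"{min(L, 5)}:Ins:R:{min(copies, 5)}"


# ---------------------------------------------------------------------------
# spectra

@dataclass
class MutationSpectrum:
    schema: str
    counts: np.ndarray
    unclassified: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != len(SCHEMAS[self.schema]):
            raise ValueError("counts length does not match schema")
        if np.any(self.counts < 0):
            raise ValueError("negative channel count")

    @property
    def channels(self) -> list[str]:
        return SCHEMAS[self.schema]

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("fractions undefined for an empty spectrum")
        return self.counts / self.total

    def __add__(self, other: "MutationSpectrum") -> "MutationSpectrum":
        if other.schema != self.schema:
            raise ValueError("schema mismatch")
        return MutationSpectrum(
            self.schema, self.counts + other.counts, self.unclassified + other.unclassified
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=self.channels, name="count")


def build_spectrum(events, genome, schema: str = "SBS96") -> MutationSpectrum:
    """Channelize a list of VariantCalls (or Lesions, SBS96 only)."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema}")
    index = _SBS96_INDEX if schema == "SBS96" else _ID83_INDEX
    counts = np.zeros(len(SCHEMAS[schema]))
    unclassified = 0
    for ev in events:
        try:
            if isinstance(ev, Lesion):
                if schema != "SBS96":
                    raise ValueError("lesions channelize only under SBS96")
                ch = lesion_channel(ev)
            elif schema == "SBS96":
                ch = classify_sbs96(ev, genome)
            else:
                ch = classify_indel(ev, genome)
        except UnclassifiableVariant:
            unclassified += 1
            continue
        counts[index[ch]] += 1
    return MutationSpectrum(schema, counts, unclassified)


def cosine_similarity(a, b, channels: str = "all") -> float:
    """Cosine of two spectra/signature vectors; ``channels='CtoA'`` restricts
    SBS96 vectors to the 16 C>A channels."""
    va = a.fractions if isinstance(a, MutationSpectrum) else np.asarray(a, dtype=float)
    vb = b.fractions if isinstance(b, MutationSpectrum) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError("shape mismatch")
    if channels == "CtoA":
        if len(va) != 96:
            raise ValueError("C>A restriction applies to SBS96 vectors")
        va, vb = va[:16], vb[:16]
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined for a zero vector")
    return float(np.dot(va, vb) / (na * nb))


def differential_spectrum(a: MutationSpectrum, b: MutationSpectrum) -> pd.Series:
    """Per-channel percentage-point differences (100*a - 100*b); sums to 0."""
    if a.schema != b.schema:
        raise ValueError("schema mismatch")
    diff = 100.0 * a.fractions - 100.0 * b.fractions
    return pd.Series(diff, index=a.channels, name="pct_difference")


# ---------------------------------------------------------------------------
# signature refitting

@dataclass
class SignatureCatalog:
    names: list[str]
    matrix: np.ndarray  # channels x signatures, columns sum to 1
    schema: str = "SBS96"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("matrix must be channels x signatures")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("catalog columns must each sum to 1")

    @classmethod
    def from_tsv(cls, path, schema: str = "SBS96") -> "SignatureCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        channels = SCHEMAS[schema]
        df = df.loc[channels]
        mat = df.to_numpy(float)
        mat = mat / mat.sum(axis=0, keepdims=True)
        return cls(list(df.columns), mat, schema)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=SCHEMAS[self.schema], columns=self.names).to_csv(
            path, sep="\t", index_label="Type"
        )


@dataclass
class ExposureVector:
    names: list[str]
    exposures: np.ndarray  # attributed mutation counts, >= 0
    residual_norm: float

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.exposures)))


def refit_exposures(spectrum: MutationSpectrum, catalog: SignatureCatalog) -> ExposureVector:
    """Non-negative least-squares attribution of channel counts to catalog
    signatures; exposures are in mutation counts."""
    if not catalog.names:
        raise ValueError("empty catalog")
    if spectrum.schema != catalog.schema:
        raise ValueError("schema mismatch")
    x, rnorm = optimize.nnls(catalog.matrix, spectrum.counts)
    return ExposureVector(list(catalog.names), x, float(rnorm))


def exposure_correlation(
    exposures_a: dict[str, float],
    exposures_b: dict[str, float],
    min_mutations: int = 20,
    log_transform: bool = True,
) -> tuple[float | None, int]:
    """Pearson correlation of per-sample attributed counts for two
    signatures, over samples attributed at least ``min_mutations`` on both.

    Returns (r, samples retained); r is None below 3 retained samples.
    """
    shared = sorted(set(exposures_a) & set(exposures_b))
    xs, ys = [], []
    for s in shared:
        a, b = exposures_a[s], exposures_b[s]
        if a >= min_mutations and b >= min_mutations:
            xs.append(a)
            ys.append(b)
    n = len(xs)
    if n < 3:
        return None, n
    x = np.log2(xs) if log_transform else np.asarray(xs, float)
    y = np.log2(ys) if log_transform else np.asarray(ys, float)
    r = float(stats.pearsonr(x, y).statistic)
    return r, n


# ---------------------------------------------------------------------------
# flanking composition

def flanking_composition(deletions, genome, k: int = 5) -> pd.DataFrame:
    """Base frequencies at offsets -k..-1, +1..+k around 1-bp deleted bases,
    oriented so the deleted base reads as a pyrimidine on its own strand."""
    offsets = [o for o in range(-k, k + 1) if o != 0]
    counts = pd.DataFrame(0, index=offsets, columns=list(BASES), dtype=float)
    for call in deletions:
        from .consensus import trim_and_shift

        contig, pos, ref, alt = trim_and_shift(call.contig, call.pos, call.ref, call.alt, genome)
        if not (len(ref) == 2 and len(alt) == 1 and ref[0] == alt[0]):
            raise ValueError("flanking_composition requires 1-bp deletions")
        site = pos + 1
        base = ref[1]
        flip = base not in PYRIMIDINES
        for o in offsets:
            p = site - o if flip else site + o
            if 0 <= p < genome.length(contig):
                b = genome.base(contig, p)
                if flip:
                    b = complement(b)
                if b in BASES:
                    counts.loc[o, b] += 1
    totals = counts.sum(axis=1)
    freqs = counts.div(totals.where(totals > 0), axis=0)
    return freqs
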