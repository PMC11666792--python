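"""Light-weight labelled interval sets with vectorized point lookup.

Intervals are half-open [start, end) on named contigs. Lookup is by binary
search over per-contig sorted starts, which is sufficient for the
non-overlapping tracks this package consumes (segmentations, replication
domains, merged gene bodies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LabelledIntervals:
    """Non-overlapping labelled intervals, indexed per contig."""

    starts: dict[str, np.ndarray] = field(default_factory=dict)
    ends: dict[str, np.ndarray] = field(default_factory=dict)
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records, allow_overlap: bool = False) -> "LabelledIntervals":
        """Build from (contig, start, end, label) tuples; sorts per contig."""
        by_contig: dict[str, list] = {}
        for contig, start, end, label in records:
            if end < start:
                raise ValueError(f"negative-length interval {contig}:{start}-{end}")
            by_contig.setdefault(contig, []).append((start, end, label))
        obj = cls()
        for contig, rows in by_contig.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            if not allow_overlap and np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping intervals on {contig}")
            obj.starts[contig] = starts
            obj.ends[contig] = ends
            obj.labels[contig] = np.array([r[2] for r in rows], dtype=object)
        return obj

    def contigs(self) -> list[str]:
        return list(self.starts)

    def records(self):
        for contig in self.starts:
            for s, e, lab in zip(self.starts[contig], self.ends[contig], self.labels[contig]):
                yield contig, int(s), int(e), lab

    def lookup(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Label at each position, or None when no interval covers it."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.shape, None, dtype=object)
        if contig not in self.starts:
            return out
        idx = np.searchsorted(self.starts[contig], positions, side="right") - 1
        valid = idx >= 0
        idx_v = idx[valid]
        covered = positions[valid] < self.ends[contig][idx_v]
        sel = np.zeros(positions.shape, dtype=bool)
        sel[np.flatnonzero(valid)[covered]] = True
        out[sel] = self.labels[contig][idx[sel]]
        return out

    def lookup_one(self, contig: str, position: int):
        return self.lookup(contig, np.array([position]))[0]

    def footprints(self) -> dict:
        """Total bp per label across all contigs."""
        totals: dict = {}
        for contig in self.starts:
            lengths = self.ends[contig] - self.starts[contig]
            for lab, ln in zip(self.labels[contig], lengths):
                totals[lab] = totals.get(lab, 0) + int(ln)
        return totals


def read_bed(path, n_fields: int = 4):
    """Yield (contig, start, end, field4...) tuples from a BED-like file."""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            yield (parts[0], int(parts[1]), int(parts[2]), *parts[3:n_fields])


def write_bed(path, rows) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
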