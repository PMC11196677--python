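"""ORF discovery on circular genomes under the invertebrate mitochondrial code.

An ORF runs from a start codon to the first in-frame stop. Candidates that
share a stop are reduced to the longest one (earliest start after the previous
stop). On circular sequences the scan wraps the origin, and wrap-around ORFs
are reported as two-interval features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import AnnotatedGenome, Feature, reverse_complement

DEFAULT_STARTS = frozenset({"ATG", "ATA", "ATT", "GTG"})
TABLE5_STARTS = frozenset({"TTG", "ATT", "ATC", "ATA", "ATG", "GTG"})
DEFAULT_STOPS = frozenset({"TAA", "TAG"})


@dataclass
class OrfConfig:
    min_length_nt: int = 300
    start_codons: frozenset = field(default_factory=lambda: DEFAULT_STARTS)
    stop_codons: frozenset = field(default_factory=lambda: DEFAULT_STOPS)
    include_stop_in_length: bool = True
    allow_wrap: bool = True

    def __post_init__(self) -> None:
        if self.min_length_nt < 3 or self.min_length_nt % 3 != 0:
            raise ValueError("min_length_nt must be >= 3 and divisible by 3")
        self.start_codons = frozenset(self.start_codons)
        self.stop_codons = frozenset(self.stop_codons)
        if not self.start_codons or not self.stop_codons:
            raise ValueError("start/stop codon sets must be non-empty")
        if self.start_codons & self.stop_codons:
            raise ValueError("start and stop codon sets must be disjoint")


def _scan_strand(seq: str, circular: bool, cfg: OrfConfig) -> list[tuple[int, int]]:
    """Scan one strand; return (start, end_exclusive) in strand coordinates.

    ``end`` includes the stop codon. For circular sequences coordinates may
    exceed L (wrap); callers normalise. ORFs longer than L are discarded.
    """
    n = len(seq)
    s2 = seq + seq if circular else seq
    out: set[tuple[int, int]] = set()
    for frame in range(3):
        cand: int | None = None  # earliest start since last stop
        for i in range(frame, len(s2) - 2, 3):
            codon = s2[i:i + 3]
            if codon in cfg.stop_codons:
                if cand is not None:
                    start, end = cand, i + 3
                    if start < n and end - start <= n:
                        out.add((start, end))
                cand = None
            elif cand is None and codon in cfg.start_codons:
                cand = i
    return sorted(out)


def find_orfs(genome: AnnotatedGenome, cfg: OrfConfig | None = None) -> list[Feature]:
    """Six-frame ORF scan; results sorted by length descending, named ORF1.."""
    cfg = cfg or OrfConfig()
    seq = genome.sequence
    n = len(seq)
    circular = seq.topology == "circular" and cfg.allow_wrap

    raw: list[tuple[int, int, str]] = []  # (start, end) in + genome frame-of-reference
    for strand in ("+", "-"):
        s = seq.residues if strand == "+" else reverse_complement(seq.residues)
        for start, end in _scan_strand(s, circular, cfg):
            if not cfg.include_stop_in_length:
                end -= 3
            length = end - start
            if length < cfg.min_length_nt:
                continue
            if strand == "+":
                raw.append((start, end, strand))
            else:
                # position i on the reverse strand maps to n-1-i on +
                g_start = n - end  # may be negative => wraps
                g_end = n - start
                if g_start < 0:
                    g_start += n
                    g_end += n
                raw.append((g_start, g_end, strand))

    feats: list[Feature] = []
    seen: set[tuple] = set()
    for start, end, strand in raw:
        if end <= n:
            intervals = [(start, end)]
        else:
            intervals = [(start, n), (0, end - n)]
        key = (tuple(intervals), strand)
        if key in seen:
            continue
        seen.add(key)
        feats.append(Feature(name="_", kind="ORF", strand=strand, intervals=intervals))

    feats.sort(key=lambda f: (-f.length, f.start, f.strand))
    for i, f in enumerate(feats, start=1):
        f.name = f"ORF{i}"
    return feats


def _circular_positions(feature: Feature) -> set[int]:
    return {p for s, e in feature.intervals for p in range(s, e)}


def unassigned_orfs(
    orfs: list[Feature],
    genome: AnnotatedGenome,
    max_overlap_frac: float = 0.5,
) -> list[Feature]:
    """Keep ORFs overlapping annotated (non-ORF) features by < max_overlap_frac.

    Overlap is computed on circular coordinates and is strand-agnostic.
    """
    annotated: set[int] = set()
    for f in genome.features:
        if f.kind != "ORF":
            annotated |= _circular_positions(f)
    kept = []
    for orf in orfs:
        pos = _circular_positions(orf)
        overlap = len(pos & annotated)
        if overlap < max_overlap_frac * orf.length:
            kept.append(orf)
    return kept


def orf_table(orfs: list[Feature]) -> list[dict]:
    """TSV-ready summary rows for ORF calls."""
    return [
        {
            "name": f.name,
            "strand": f.strand,
            "start": f.intervals[0][0],
            "end": f.intervals[-1][1],
            "length": f.length,
            "wraps": len(f.intervals) > 1,
        }
        for f in orfs
    ]
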