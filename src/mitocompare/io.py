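"""Core I/O: FASTA/GenBank parsing, circular-coordinate primitives, translation.

All coordinates inside the package are 0-based half-open; GenBank's 1-based
inclusive locations are converted at the parsing boundary. A feature that spans
the origin of a circular sequence is represented as two intervals, e.g.
``[(L-k, L), (0, m)]``, never as a single interval with end > length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: three-letter amino acid -> one-letter, for tRNA product normalisation
_AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}


class ParseError(ValueError):
    """Raised for malformed input files."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CircularSequence:
    """A DNA sequence with explicit topology.

    Index arithmetic on circular sequences is modulo length; :meth:`fetch`
    accepts ``start > end`` only implicitly through modular wrapping of
    ``fetch(start, start + n)`` with ``start + n > len``.
    """

    id: str
    residues: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be circular|linear, got {self.topology!r}")
        self.residues = self.residues.upper()
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            pos = min(i for i, c in enumerate(self.residues) if c in bad)
            raise ParseError(
                f"record {self.id!r}: illegal residue {self.residues[pos]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def fetch(self, start: int, end: int) -> str:
        """Return residues of [start, end); wraps modulo length when circular."""
        n = len(self.residues)
        if 0 <= start <= end <= n:
            return self.residues[start:end]
        if self.topology != "circular":
            raise IndexError(f"[{start}, {end}) outside linear sequence of length {n}")
        return "".join(self.residues[i % n] for i in range(start, end))


@dataclass
class Feature:
    """A typed, stranded, possibly origin-spanning genome feature."""

    name: str
    kind: str  # CDS | tRNA | rRNA | ORF | noncoding
    strand: str  # '+' | '-'
    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.kind not in ("CDS", "tRNA", "rRNA", "ORF", "noncoding"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        ivs = [(int(s), int(e)) for s, e in self.intervals]
        if not ivs or any(e <= s for s, e in ivs):
            raise ValueError(f"feature {self.name!r}: empty or inverted interval")
        for (s1, e1) in ivs:
            for (s2, e2) in ivs:
                if (s1, e1) != (s2, e2) and s1 < e2 and s2 < e1:
                    raise ValueError(f"feature {self.name!r}: overlapping intervals")
        self.intervals = ivs
        if self.kind in ("CDS", "ORF") and self.length % 3 != 0:
            raise ValueError(
                f"{self.kind} feature {self.name!r}: length {self.length} not divisible by 3"
            )

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def wraps(self) -> bool:
        return len(self.intervals) > 1 and self.intervals[-1][1] <= self.intervals[0][0]

    def positions(self):
        """Yield genome positions in reading order (strand-aware)."""
        fwd = [p for s, e in self.intervals for p in range(s, e)]
        return fwd if self.strand == "+" else fwd[::-1]


@dataclass
class AnnotatedGenome:
    sequence: CircularSequence
    features: list[Feature] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.intervals:
                if not (0 <= s < e <= n):
                    raise ValueError(
                        f"feature {f.name!r} interval [{s},{e}) outside [0,{n})"
                    )
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names after disambiguation: {dup}")

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name!r} in {self.sequence.id}")

    def feature_names(self, kinds: tuple[str, ...] | None = None) -> list[str]:
        return [f.name for f in self.features if kinds is None or f.kind in kinds]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[CircularSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: empty or not FASTA")
    out = []
    for rec in records:
        residues = str(rec.seq).upper()
        bad = [(i, c) for i, c in enumerate(residues) if c not in DNA_ALPHABET]
        if bad:
            i, c = bad[0]
            raise ParseError(f"record {rec.id!r}: illegal residue {c!r} at position {i}")
        out.append(CircularSequence(rec.id, residues, topology="circular"))
    return out


def write_fasta(seqs: list[CircularSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GenBank

def _trn_name(product: str) -> str | None:
    m = re.match(r"tRNA[- ](\w{3})", product)
    if m and m.group(1) in _AA3_TO_1:
        return "trn" + _AA3_TO_1[m.group(1)]
    return None


def _rrn_name(product: str) -> str | None:
    p = product.lower()
    if "16s" in p or "large" in p or "rrnl" in p:
        return "rrnL"
    if "12s" in p or "small" in p or "rrns" in p:
        return "rrnS"
    return None


def _location_intervals(loc, length: int) -> tuple[list[tuple[int, int]], str]:
    strand = "-" if loc.strand == -1 else "+"
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    ivs = [(int(p.start), int(p.end)) for p in parts]
    if strand == "-":
        # Biopython lists complement parts in join order of the complement;
        # keep genome order for '-' features: reading order handled by strand.
        ivs = sorted(ivs) if not _wraps(ivs, length) else ivs
    for s, e in ivs:
        if not (0 <= s < e <= length):
            raise ParseError(f"location [{s},{e}) outside sequence of length {length}")
    return ivs, strand


def _wraps(ivs: list[tuple[int, int]], length: int) -> bool:
    return len(ivs) == 2 and ivs[0][1] == length and ivs[1][0] == 0


def read_genbank(path) -> AnnotatedGenome:
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    try:
        empty = len(rec.seq) == 0 or not str(rec.seq)
    except Exception:  # undefined sequence (no ORIGIN block)
        empty = True
    if empty:
        raise ParseError(f"{path}: missing ORIGIN sequence")
    topology = rec.annotations.get("topology", "circular")
    seq = CircularSequence(rec.id or rec.name, str(rec.seq).upper(), topology=topology)

    feats: list[Feature] = []
    counter = 0
    for sf in rec.features:
        if sf.type not in ("CDS", "tRNA", "rRNA"):
            continue
        counter += 1
        quals = sf.qualifiers
        name = quals.get("gene", [None])[0]
        product = quals.get("product", [None])[0]
        note = quals.get("note", [None])[0]
        if name is None and product is not None:
            if sf.type == "tRNA":
                name = _trn_name(product)
            elif sf.type == "rRNA":
                name = _rrn_name(product)
            name = name or product.replace(" ", "_")
        if name is None and note is not None:
            name = note.split()[0]
        if name is None:
            name = f"{sf.type}_{counter}"
        ivs, strand = _location_intervals(sf.location, len(seq))
        kind = sf.type
        if kind == "CDS" and re.match(r"(?i)orf", name):
            kind = "ORF"
        feats.append(Feature(name=name, kind=kind, strand=strand, intervals=ivs))

    # disambiguate duplicate names (the two serine/leucine tRNAs etc.)
    seen: dict[str, int] = {}
    for f in feats:
        seen[f.name] = seen.get(f.name, 0) + 1
    idx: dict[str, int] = {}
    for f in feats:
        if seen[f.name] > 1:
            idx[f.name] = idx.get(f.name, 0) + 1
            f.name = f"{f.name}{idx[f.name]}"
    return AnnotatedGenome(sequence=seq, features=feats, source=str(path))


def write_genbank(genome: AnnotatedGenome, path) -> None:
    seq = genome.sequence
    rec = SeqRecord(Seq(seq.residues), id=seq.id, name=seq.id[:16],
                    description="synthetic mitogenome")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = seq.topology
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        locs = [SimpleLocation(s, e, strand=strand) for s, e in f.intervals]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        ftype = "CDS" if f.kind == "ORF" else f.kind
        if f.kind == "noncoding":
            ftype = "misc_feature"
        quals = {"gene": [f.name]}
        rec.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    SeqIO.write(rec, str(path), "genbank")


def write_gff3(genome: AnnotatedGenome, path) -> None:
    """Write features as GFF3 (1-based inclusive on output, per the format)."""
    type_map = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                "ORF": "open_reading_frame", "noncoding": "region"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.sequence.id} 1 {len(genome.sequence)}\n")
        for f in genome.features:
            for k, (s, e) in enumerate(f.intervals):
                attrs = f"ID={f.name}" + (f".{k + 1}" if len(f.intervals) > 1 else "")
                fh.write("\t".join([
                    genome.sequence.id, "mitocompare", type_map[f.kind],
                    str(s + 1), str(e), ".", f.strand, ".", attrs,
                ]) + "\n")


# ---------------------------------------------------------------------------
# Sequence extraction and translation

def feature_sequence(genome: AnnotatedGenome, feature: Feature) -> str:
    nt = "".join(genome.sequence.fetch(s, e) for s, e in feature.intervals)
    return reverse_complement(nt) if feature.strand == "-" else nt


def translate(nt: str, table: int = 5) -> str:
    """Translate DNA under an NCBI code table (default 5, invertebrate mt).

    Stops (terminal or internal) render as '*'; length must be a codon multiple.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"length {len(nt)} not divisible by 3")
    return str(Seq(nt).translate(table=table))
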