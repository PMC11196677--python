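"""Truth-tagged synthetic mitogenome pairs.

The generator emulates the comparative design the pipeline targets: a circular
~19.5 kb "F-like" mitogenome carrying a full bivalve-style gene complement
(13 protein-coding genes incl. seven nadh subunits, 2 rRNAs, 22 tRNAs), and an
"M-like" derivative in which every retained gene has been mutated to a target
observed p-distance, the seven nadh genes are deleted, three long
non-homologous ORFs are planted, cox1 gains a random 3' extension, and a small
number of gene-order moves are applied.

Construction details that make the truth table sharp:

* Intergenic spacers are TTAA repeats (length a multiple of 4). Every reading
  frame crossing a spacer hits a stop within 4 codons, on both strands (TTAA
  is its own reverse complement), so ORFs never extend across feature
  boundaries and every planted coding cassette is recovered by the ORF scanner
  at its exact coordinates.
* Coding sequence is drawn codon-wise from an AT-rich, leucine(TTA)-heavy
  codon distribution with stops rejected — realistic for invertebrate mtDNA
  and chosen so that shifted and reverse-strand frames are stop-dense, keeping
  spurious long ORFs rare.
* ``exact_planting`` substitutes exactly round(p*L) positions of each retained
  gene (never creating an internal in-frame stop in coding genes), so the
  positional per-gene p-distance equals the planted value exactly whenever
  p*L is an integer. ``stochastic_jc`` substitutes each site independently
  with probability p instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AnnotatedGenome, CircularSequence, Feature, reverse_complement
from .divergence import positional_alignment, p_distance

NADH_GENES = ("nadh1", "nadh2", "nadh3", "nadh4", "nadh4L", "nadh5", "nadh6")

#: (name, kind, strand, length) — order around the F-like circle. tRNA lengths
#: are draws in [60, 75]; CDS/rRNA lengths are fixed defaults.
F_PLAN: list[tuple[str, str, str, int]] = [
    ("cox1", "CDS", "+", 1701),
    ("trnL1", "tRNA", "+", 0),
    ("cox2", "CDS", "+", 690),
    ("trnD", "tRNA", "+", 0),
    ("atp8", "CDS", "+", 165),
    ("atp6", "CDS", "+", 702),
    ("trnN", "tRNA", "+", 0),
    ("nadh1", "CDS", "+", 903),
    ("trnP", "tRNA", "+", 0),
    ("nadh2", "CDS", "+", 978),
    ("trnK", "tRNA", "+", 0),
    ("cox3", "CDS", "+", 783),
    ("trnS1", "tRNA", "+", 0),
    ("rrnL", "rRNA", "+", 1300),
    ("trnT", "tRNA", "+", 0),
    ("nadh3", "CDS", "+", 354),
    ("trnR", "tRNA", "+", 0),
    ("nadh4", "CDS", "+", 1332),
    ("trnH", "tRNA", "+", 0),
    ("nadh4L", "CDS", "+", 297),
    ("nadh5", "CDS", "+", 1713),
    ("trnL2", "tRNA", "+", 0),
    ("nadh6", "CDS", "+", 501),
    ("trnY", "tRNA", "+", 0),
    ("cytb", "CDS", "+", 1140),
    ("trnS2", "tRNA", "+", 0),
    ("trnQ", "tRNA", "-", 0),
    ("trnC", "tRNA", "-", 0),
    ("trnV", "tRNA", "+", 0),
    ("trnW", "tRNA", "+", 0),
    ("trnG", "tRNA", "+", 0),
    ("rrnS", "rRNA", "+", 850),
    ("trnM", "tRNA", "+", 0),
    ("trnI", "tRNA", "+", 0),
    ("trnE", "tRNA", "+", 0),
    ("trnA", "tRNA", "+", 0),
    ("trnF", "tRNA", "+", 0),
]

STOPS = ("TAA", "TAG")
_BASES = "ACGT"
_BASE_P = {"A": 0.34, "C": 0.14, "G": 0.18, "T": 0.34}


def _codon_table() -> tuple[list[str], np.ndarray]:
    codons, w = [], []
    for a in _BASES:
        for b in _BASES:
            for c in _BASES:
                cod = a + b + c
                if cod in STOPS:
                    continue
                p = _BASE_P[a] * _BASE_P[b] * _BASE_P[c]
                if cod == "TTA":  # Leu; reverse complement is a stop
                    p *= 6.0
                elif cod == "CTA":  # Leu; reverse complement is a stop
                    p *= 4.0
                codons.append(cod)
                w.append(p)
    w = np.asarray(w)
    return codons, w / w.sum()


_CODONS, _CODON_P = _codon_table()


@dataclass
class SimConfig:
    seed: int
    genome_length_target: int = 19_500
    divergence_p: float = 0.45
    gene_divergence: dict = field(default_factory=dict)  # per-gene overrides
    mode: str = "exact_planting"  # | 'stochastic_jc'
    kappa: float = 2.0
    n_orfs: int = 3
    orf_lengths: tuple[int, ...] = (4002, 951, 852)
    drop_genes: tuple[str, ...] = NADH_GENES
    cox1_extension: int = 999
    n_moves: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.divergence_p < 1:
            raise ValueError("divergence_p must be in [0, 1)")
        if self.mode not in ("exact_planting", "stochastic_jc"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_orfs > len(self.orf_lengths):
            raise ValueError("orf_lengths must provide a length per planted ORF")
        if any(l % 3 for l in self.orf_lengths) or self.cox1_extension % 3:
            raise ValueError("ORF and extension lengths must be codon multiples")
        if self.n_moves > 3:
            raise ValueError("at most 3 template order moves are available")


@dataclass
class Cassette:
    name: str
    kind: str
    strand: str
    seq: str  # reading-direction sequence


@dataclass
class TruthTable:
    seed: int
    gene_p: dict = field(default_factory=dict)  # realized planted p per gene
    homology_map: dict = field(default_factory=dict)  # M feature -> F feature | None
    homolog_region: dict = field(default_factory=dict)  # compared prefix length
    order_ops: list = field(default_factory=list)
    orf_coords: dict = field(default_factory=dict)  # name -> (intervals, strand)
    cox1_extension: int = 0
    dropped_genes: tuple = ()


# ---------------------------------------------------------------------------
# sequence generators

#: maximum tolerated stop-free run, in codons, in any non-coding frame of a
#: generated CDS — well below the 100-codon ORF-scan minimum so that enough
#: frame-breaking stops survive even heavy mutation
_MAX_SILENT_RUN = 30

#: trinucleotides that read as a stop in a shifted forward frame (TAA/TAG)
#: or on the reverse strand (their reverse complements TTA/CTA, both Leu in
#: the coding frame, so a patch can never corrupt the planted reading frame
#: into a stop by itself)
_FWD_BREAKERS = ("TAA", "TAG")
_REV_BREAKERS = ("TTA", "CTA")


def random_cds(length: int, rng: np.random.Generator) -> str:
    """Stop-free coding sequence: ATG + random codons + TAA.

    After sampling, every non-coding frame (both shifted forward frames and
    all three reverse frames) is patched with randomly placed, randomly
    chosen stop trinucleotides so that no stop-free run exceeds
    ``_MAX_SILENT_RUN`` codons: the only open frame across the cassette is
    the planted one. Because patch positions and spellings are drawn from
    ``rng``, independently generated sequences share no systematic motifs."""
    if length % 3 or length < 9:
        raise ValueError("CDS length must be a codon multiple >= 9")
    n_inner = length // 3 - 2
    inner = rng.choice(len(_CODONS), size=max(n_inner, 0), p=_CODON_P)
    seq = list("ATG" + "".join(_CODONS[i] for i in inner) + "TAA")
    _break_silent_frames(seq, rng)
    return "".join(seq)


#: the five non-coding frames as (phase, breaker set) pairs: forward reading
#: at offsets 1 and 2, and the three reverse-strand frames, one per residue
#: class mod 3 (a reverse-strand stop is a forward TTA/CTA trinucleotide)
_SILENT_FRAMES = (
    (1, _FWD_BREAKERS), (2, _FWD_BREAKERS),
    (0, _REV_BREAKERS), (1, _REV_BREAKERS), (2, _REV_BREAKERS),
)


def _break_silent_frames(seq: list[str], rng: np.random.Generator) -> None:
    """Patch ``seq`` in place until no non-coding frame has a stop-free run
    longer than ``_MAX_SILENT_RUN`` codons. Patches never touch the start or
    terminator codon and never create a stop in the coding frame."""
    L = len(seq)

    def frame0_safe(p: int) -> bool:
        for c0 in {(p // 3) * 3, ((p + 2) // 3) * 3}:
            if c0 + 3 <= L and "".join(seq[c0:c0 + 3]) in STOPS:
                return False
        return True

    for _ in range(20):  # passes; patching converges in one or two
        patched = False
        for phase, breakers in _SILENT_FRAMES:
            positions = list(range(phase, L - 2, 3))
            last_stop = -1
            for idx, p in enumerate(positions):
                if "".join(seq[p:p + 3]) in breakers:
                    last_stop = idx
                elif idx - last_stop > _MAX_SILENT_RUN:
                    lo = max(last_stop + 1, 0)
                    gap = [q for q in positions[lo:idx + 1]
                           if 3 <= q and q + 3 <= L - 3]
                    rng.shuffle(gap)
                    for q in gap:
                        saved = seq[q:q + 3]
                        seq[q:q + 3] = breakers[int(rng.integers(2))]
                        if frame0_safe(q):
                            last_stop = idx
                            patched = True
                            break
                        seq[q:q + 3] = saved
        if not patched:
            return


def random_rna(length: int, rng: np.random.Generator) -> str:
    bases = rng.choice(list(_BASES), size=length,
                       p=[_BASE_P[b] for b in _BASES])
    return "".join(bases)


def _spacer(length: int) -> str:
    return ("TTAA" * (length // 4 + 1))[:length]


# ---------------------------------------------------------------------------
# mutation

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _substitute(base: str, rng: np.random.Generator, kappa: float) -> list[str]:
    """Candidate replacement bases, transition-first with prob kappa/(kappa+2),
    as a preference-ordered list."""
    ts = _TRANSITION[base]
    tv = list(_TRANSVERSIONS[base])
    rng.shuffle(tv)
    if rng.random() < kappa / (kappa + 2.0):
        return [ts] + tv
    return [tv[0], tv[1], ts]


def mutate_sequence(
    seq: str,
    p: float,
    rng: np.random.Generator,
    kappa: float = 2.0,
    mode: str = "exact_planting",
    coding: bool = False,
) -> str:
    """Derive a diverged copy of ``seq`` with target observed p-distance.

    exact_planting substitutes exactly round(p*L) distinct positions;
    stochastic_jc substitutes each position independently with probability p.
    For coding sequences no internal in-frame stop is ever created (for any
    position at most two of the three alternative bases can complete a stop,
    so a valid substitution always exists). The terminal codon may mutate
    freely only when it is a stop in the input (a gene's own terminator).
    """
    L = len(seq)
    terminal_free = coding and seq[-3:] in STOPS
    out = list(seq)
    if mode == "exact_planting":
        k = int(round(p * L))
        positions = rng.choice(L, size=k, replace=False) if k else []
    else:
        positions = np.nonzero(rng.random(L) < p)[0]
    for pos in positions:
        pos = int(pos)
        for cand in _substitute(out[pos], rng, kappa):
            out[pos] = cand
            if not coding or not _creates_internal_stop(out, pos, L, terminal_free):
                break
        else:
            out[pos] = seq[pos]  # unreachable; defensive
    return "".join(out)


def _creates_internal_stop(seq_list: list[str], pos: int, L: int,
                           terminal_free: bool) -> bool:
    c0 = (pos // 3) * 3
    if c0 + 3 > L or (terminal_free and c0 == L - 3):
        return False
    return "".join(seq_list[c0:c0 + 3]) in STOPS


# ---------------------------------------------------------------------------
# assembly

def _assemble(cassettes: list[Cassette], target_len: int, genome_id: str,
              rng: np.random.Generator) -> AnnotatedGenome:
    total = sum(len(c.seq) for c in cassettes)
    n_gaps = len(cassettes)
    budget = max(target_len - total, 16 * n_gaps)
    base = budget // n_gaps // 4 * 4
    lengths = [max(16, base)] * n_gaps
    # jitter while keeping multiples of 4
    for i in range(n_gaps):
        lengths[i] += 4 * int(rng.integers(0, 5))

    parts: list[str] = []
    feats: list[Feature] = []
    pos = 0
    for cas, gap in zip(cassettes, lengths):
        locus = cas.seq if cas.strand == "+" else reverse_complement(cas.seq)
        feats.append(Feature(name=cas.name, kind=cas.kind, strand=cas.strand,
                             intervals=[(pos, pos + len(locus))]))
        parts.append(locus)
        pos += len(locus)
        parts.append(_spacer(gap))
        pos += gap
    seq = CircularSequence(genome_id, "".join(parts), topology="circular")
    return AnnotatedGenome(sequence=seq, features=feats, source="simulated")


def simulate_f_genome(cfg: SimConfig) -> tuple[AnnotatedGenome, TruthTable]:
    """Assemble the F-like reference genome from the fixed gene plan."""
    rng = np.random.default_rng(cfg.seed)
    cassettes = []
    for name, kind, strand, length in F_PLAN:
        if kind == "tRNA":
            seq = random_rna(int(rng.integers(60, 76)), rng)
        elif kind == "rRNA":
            seq = random_rna(length, rng)
        else:
            seq = random_cds(length, rng)
        cassettes.append(Cassette(name, kind, strand, seq))
    genome = _assemble(cassettes, cfg.genome_length_target, f"simF_{cfg.seed}", rng)
    truth = TruthTable(seed=cfg.seed,
                       gene_p={c.name: 0.0 for c in cassettes},
                       homology_map={c.name: c.name for c in cassettes})
    return genome, truth


def _cassettes_from(genome: AnnotatedGenome) -> list[Cassette]:
    feats = sorted(genome.features, key=lambda f: f.start)
    out = []
    for f in feats:
        nt = "".join(genome.sequence.fetch(s, e) for s, e in f.intervals)
        seq = reverse_complement(nt) if f.strand == "-" else nt
        out.append(Cassette(f.name, f.kind, f.strand, seq))
    return out


def _order_moves() -> list[dict]:
    """Three template moves: a 3-feature block shift, a single tRNA relocation,
    and an adjacent tRNA swap — disjoint enough that none can be merged."""
    return [
        {"op": "relocate", "block_labels": ["trnW", "trnG", "rrnS"],
         "after": "trnS1"},
        {"op": "relocate", "block_labels": ["trnF"], "after": "cytb"},
        {"op": "swap", "labels": ["trnI", "trnE"]},
    ]


def _apply_label_op(cassettes: list[Cassette], op: dict) -> list[Cassette]:
    names = [c.name for c in cassettes]
    if op["op"] == "relocate":
        i = names.index(op["block_labels"][0])
        j = names.index(op["block_labels"][-1])
        block = cassettes[i:j + 1]
        rest = cassettes[:i] + cassettes[j + 1:]
        k = [c.name for c in rest].index(op["after"]) + 1
        return rest[:k] + block + rest[k:]
    if op["op"] == "swap":
        i, j = (names.index(l) for l in op["labels"])
        cassettes = list(cassettes)
        cassettes[i], cassettes[j] = cassettes[j], cassettes[i]
        return cassettes
    raise ValueError(f"unknown op {op['op']!r}")


def derive_m_genome(
    f_genome: AnnotatedGenome, cfg: SimConfig
) -> tuple[AnnotatedGenome, TruthTable]:
    """Derive the M-like genome from an F-like genome (see module docstring)."""
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    cassettes = _cassettes_from(f_genome)
    truth = TruthTable(seed=cfg.seed, dropped_genes=tuple(cfg.drop_genes),
                       cox1_extension=cfg.cox1_extension)

    kept: list[Cassette] = []
    for cas in cassettes:
        if cas.name in cfg.drop_genes:
            continue
        p = cfg.gene_divergence.get(cas.name, cfg.divergence_p)
        core = cas.seq
        extend = cas.name == "cox1" and cfg.cox1_extension
        if extend:
            core = core[:-3]  # stop is replaced by the extension
        seq = mutate_sequence(core, p, rng, kappa=cfg.kappa, mode=cfg.mode,
                              coding=cas.kind in ("CDS", "ORF"))
        if extend:
            # stop-free extension codons plus a fresh terminator
            seq = seq + random_cds(cfg.cox1_extension + 6, rng)[3:]
        kept.append(Cassette(cas.name, cas.kind, cas.strand, seq))
        truth.gene_p[cas.name] = (round(p * len(core)) / len(core)
                                  if cfg.mode == "exact_planting" else p)
        truth.homology_map[cas.name] = cas.name
        truth.homolog_region[cas.name] = len(core)

    # planted non-homologous ORFs, inserted after fixed host features
    hosts = ["cytb", "trnS1", "rrnL"]
    for i in range(cfg.n_orfs):
        name = f"orfM{i + 1}"
        orf = Cassette(name, "ORF", "+", random_cds(cfg.orf_lengths[i], rng))
        names = [c.name for c in kept]
        k = names.index(hosts[i % len(hosts)]) + 1
        kept = kept[:k] + [orf] + kept[k:]
        truth.homology_map[name] = None
        truth.gene_p[name] = float("nan")

    for op in _order_moves()[:cfg.n_moves]:
        kept = _apply_label_op(kept, op)
        truth.order_ops.append(op)

    genome = _assemble(kept, cfg.genome_length_target, f"simM_{cfg.seed}", rng)
    for f in genome.features:
        if f.kind == "ORF":
            truth.orf_coords[f.name] = (list(f.intervals), f.strand)
    return genome, truth


def simulate_pair(cfg: SimConfig) -> tuple[AnnotatedGenome, AnnotatedGenome, TruthTable]:
    f_genome, _ = simulate_f_genome(cfg)
    m_genome, truth = derive_m_genome(f_genome, cfg)
    return f_genome, m_genome, truth


# ---------------------------------------------------------------------------
# truth replay

def measured_gene_p(
    f_genome: AnnotatedGenome, m_genome: AnnotatedGenome, truth: TruthTable
) -> dict[str, float]:
    """Positional per-gene p-distance between true homolog copies.

    Uses the known homologous correspondence (no realignment): sequences are
    column-paired over the truth table's homologous region (for the in-place
    mutation model that pairing is the exact alignment; cox1's 3' extension
    lies outside the region).
    """
    from .io import feature_sequence  # local import to avoid cycle at module load

    out = {}
    for m_name, f_name in truth.homology_map.items():
        if f_name is None:
            continue
        try:
            fs = feature_sequence(f_genome, f_genome.feature(f_name))
            ms = feature_sequence(m_genome, m_genome.feature(m_name))
        except KeyError:
            continue
        n = truth.homolog_region.get(m_name, min(len(fs), len(ms)))
        res = p_distance(positional_alignment(fs[:n], ms[:n]))
        out[m_name] = res.p
    return out
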