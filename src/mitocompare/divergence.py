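"""Divergence statistics: p-distance, Tamura 3-parameter distance, sliding
windows and compositional skew profiles.

The Tamura 3-parameter (T92) distance corrects the observed p-distance for
transition/transversion bias and GC-content bias:

    h = 2*theta*(1 - theta)
    d = -h * ln(1 - P/h - Q) - 0.5 * (1 - h) * ln(1 - 2Q)

with theta the GC content over the compared sites of both sequences pooled,
P the transition fraction and Q the transversion fraction. When a log argument
is non-positive (saturation) or h = 0 the distance is undefined and flagged
rather than raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .align import AlignParams, Alignment, align_feature_pair
from .io import AnnotatedGenome

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_SKIP = frozenset("-N")


@dataclass
class DistanceResult:
    p: float
    compared_sites: int
    P: float = float("nan")
    Q: float = float("nan")
    theta: float = float("nan")
    h: float = float("nan")
    d_t92: float = float("nan")
    level: str = "nt"
    defined: bool = True
    t92_defined: bool = False
    saturated: bool = False


@dataclass
class WindowProfile:
    window: int
    step: int
    centers: list[int] = field(default_factory=list)
    values: list[float] = field(default_factory=list)
    metric: str = ""
    n_compared: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.window < self.step or self.step < 1:
            raise ValueError("require window >= step >= 1")
        if len(self.centers) != len(self.values):
            raise ValueError("centers/values length mismatch")
        if any(b <= a for a, b in zip(self.centers, self.centers[1:])):
            raise ValueError("centers must be strictly increasing")


def _compared_columns(cols, level: str):
    for x, y in cols:
        if x in _SKIP or y in _SKIP:
            continue
        if level == "aa" and ("X" in (x, y) or "*" in (x, y)):
            continue
        yield x, y


def p_distance(aln: Alignment, deletion: str = "pairwise") -> DistanceResult:
    """Uncorrected p-distance; for nt also transition (P) / transversion (Q)
    fractions and pooled GC content over compared sites.

    Columns with a gap or ambiguity in either row are excluded (pairwise
    deletion; for a single pair complete deletion selects the same columns).
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    level = aln.params.level
    ncomp = ndiff = nts = ntv = gc = 0
    for x, y in _compared_columns(aln.columns(), level):
        ncomp += 1
        if level == "nt":
            gc += (x in "GC") + (y in "GC")
        if x != y:
            ndiff += 1
            if level == "nt":
                if (x in PURINES) == (y in PURINES):
                    nts += 1
                else:
                    ntv += 1
    if ncomp == 0:
        return DistanceResult(p=float("nan"), compared_sites=0, level=level,
                              defined=False)
    res = DistanceResult(p=ndiff / ncomp, compared_sites=ncomp, level=level)
    if level == "nt":
        res.P = nts / ncomp
        res.Q = ntv / ncomp
        res.theta = gc / (2 * ncomp)
        res.h = 2 * res.theta * (1 - res.theta)
    return res


def tamura3p(aln: Alignment) -> DistanceResult:
    """Tamura 3-parameter distance from an nt alignment (see module docstring)."""
    if aln.params.level != "nt":
        raise ValueError("Tamura-3P is defined for nucleotide alignments")
    res = p_distance(aln)
    if not res.defined:
        return res
    h, P, Q = res.h, res.P, res.Q
    if h <= 0:
        res.saturated = h == 0 and (P > 0 or Q > 0)
        if P == 0 and Q == 0:
            res.d_t92, res.t92_defined = 0.0, True
        return res
    arg1 = 1 - P / h - Q
    arg2 = 1 - 2 * Q
    if arg1 <= 0 or arg2 <= 0:
        res.saturated = True
        return res
    res.d_t92 = -h * math.log(arg1) - 0.5 * (1 - h) * math.log(arg2)
    res.t92_defined = True
    return res


def sliding_divergence(aln: Alignment, window: int = 100, step: int = 25) -> WindowProfile:
    """Per-window p-distance (pairwise deletion) over alignment columns.

    Centers are in alignment coordinates. Windows with zero compared sites
    yield NaN.
    """
    n = len(aln)
    if window > n:
        raise ValueError(f"window {window} exceeds alignment length {n}")
    a, b = aln.gapped_a, aln.gapped_b
    level = aln.params.level
    centers, values, ncmp = [], [], []
    for start in range(0, n - window + 1, step):
        cols = zip(a[start:start + window], b[start:start + window])
        comp = diff = 0
        for x, y in _compared_columns(cols, level):
            comp += 1
            diff += x != y
        centers.append(start + window // 2)
        values.append(diff / comp if comp else float("nan"))
        ncmp.append(comp)
    return WindowProfile(window=window, step=step, centers=centers,
                         values=values, metric="p_distance", n_compared=ncmp)


# ---------------------------------------------------------------------------
# Compositional skew tracks

SITE_CLASSES = ("noncoding", "codon1", "codon2", "codon3")


def classify_sites(genome: AnnotatedGenome) -> list[str]:
    """Per-position site class: codon1/2/3 inside coding features (reading
    order, strand-aware), noncoding elsewhere. First coding feature wins on
    overlap."""
    classes = ["noncoding"] * len(genome.sequence)
    claimed = [False] * len(genome.sequence)
    for f in genome.features:
        if f.kind not in ("CDS", "ORF"):
            continue
        for i, pos in enumerate(f.positions()):
            if not claimed[pos]:
                claimed[pos] = True
                classes[pos] = f"codon{i % 3 + 1}"
    return classes


def skew_profile(
    genome: AnnotatedGenome,
    metric: str = "at_skew",
    window: int = 200,
    step: int = 25,
    site_mask: set[str] | None = None,
) -> WindowProfile:
    """Sliding compositional profile over the genome (circular wrap allowed).

    Metrics: at_skew = (A-T)/(A+T); gc_skew = (G-C)/(G+C); gc_content_rel =
    window GC fraction minus whole-genome GC fraction (same mask applied to
    both). With ``site_mask`` only positions of the selected classes count;
    callers typically widen the window (e.g. to 1000 bp) for masked tracks.
    """
    if metric not in ("at_skew", "gc_skew", "gc_content_rel"):
        raise ValueError(f"unknown metric {metric!r}")
    seq = genome.sequence
    n = len(seq)
    if window > n:
        raise ValueError(f"window {window} exceeds genome length {n}")
    if site_mask is not None:
        bad = set(site_mask) - set(SITE_CLASSES)
        if bad:
            raise ValueError(f"unknown site classes: {sorted(bad)}")
        classes = classify_sites(genome)
        use = [classes[i] in site_mask for i in range(n)]
    else:
        use = [True] * n
    res = seq.residues
    circular = seq.topology == "circular"

    def counts(positions):
        c = {"A": 0, "C": 0, "G": 0, "T": 0}
        for p in positions:
            if use[p] and res[p] in c:
                c[res[p]] += 1
        return c

    genome_gc = None
    if metric == "gc_content_rel":
        cg = counts(range(n))
        tot = sum(cg.values())
        genome_gc = (cg["G"] + cg["C"]) / tot if tot else float("nan")

    starts = range(0, n, step) if circular else range(0, n - window + 1, step)
    centers, values, ncmp = [], [], []
    for start in starts:
        pos = [(start + k) % n for k in range(window)] if circular \
            else range(start, start + window)
        c = counts(pos)
        nsites = sum(c.values())
        if metric == "at_skew":
            den = c["A"] + c["T"]
            v = (c["A"] - c["T"]) / den if den else float("nan")
        elif metric == "gc_skew":
            den = c["G"] + c["C"]
            v = (c["G"] - c["C"]) / den if den else float("nan")
        else:
            v = (c["G"] + c["C"]) / nsites - genome_gc if nsites else float("nan")
        centers.append(start + window // 2)
        values.append(v)
        ncmp.append(nsites)
    return WindowProfile(window=window, step=step, centers=centers,
                         values=values, metric=metric, n_compared=ncmp)


# ---------------------------------------------------------------------------
# Distance matrices

def distance_matrix(
    genomes: dict[str, AnnotatedGenome],
    feature_pairs: list[tuple[str, str, str, str]],
    params: AlignParams | None = None,
) -> pd.DataFrame:
    """Long-format distance table over (genome_a, feature_a, genome_b,
    feature_b) pairs. Missing features flag the row instead of failing."""
    params = params or AlignParams()
    rows = []
    for ga, fa, gb, fb in feature_pairs:
        row = {
            "genome_a": ga, "feature_a": fa, "genome_b": gb, "feature_b": fb,
            "level": params.level, "p": float("nan"),
            "compared_sites": 0, "P": float("nan"), "Q": float("nan"),
            "d_t92": float("nan"), "score": float("nan"), "flag": "",
        }
        try:
            aln = align_feature_pair(genomes[ga], fa, genomes[gb], fb, params)
        except (KeyError, ValueError) as exc:
            row["flag"] = f"error: {exc}"
            rows.append(row)
            continue
        res = tamura3p(aln) if params.level == "nt" else p_distance(aln)
        row.update(p=res.p, compared_sites=res.compared_sites, score=aln.score)
        if params.level == "nt":
            row.update(P=res.P, Q=res.Q, d_t92=res.d_t92)
            if res.saturated:
                row["flag"] = "t92_saturated"
        if not res.defined:
            row["flag"] = "no_compared_sites"
        rows.append(row)
    return pd.DataFrame(rows)


def cross_pairs(
    genome_a: str, features_a: list[str], genome_b: str, features_b: list[str]
) -> list[tuple[str, str, str, str]]:
    """All-vs-all pairing plan (e.g. each ORF of one genome x each gene of
    another)."""
    return [(genome_a, fa, genome_b, fb) for fa in features_a for fb in features_b]


def shared_feature_pairs(
    genomes: dict[str, AnnotatedGenome], kinds: tuple[str, ...] = ("CDS", "rRNA")
) -> list[tuple[str, str, str, str]]:
    """Same-name feature pairs across every genome pair, for gene-by-gene
    divergence matrices."""
    names = list(genomes)
    pairs = []
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            shared = set(genomes[ga].feature_names(kinds)) & set(
                genomes[gb].feature_names(kinds))
            pairs.extend((ga, f, gb, f) for f in sorted(shared))
    return pairs


def positional_alignment(a: str, b: str, params: AlignParams | None = None) -> Alignment:
    """Column-pair two equal-length sequences without realignment — the exact
    homologous correspondence when one sequence was derived from the other
    in place (no indels)."""
    if len(a) != len(b):
        raise ValueError("positional alignment requires equal lengths")
    params = params or AlignParams()
    score = sum(params.match if x == y else params.mismatch for x, y in zip(a, b)) \
        if params.level == "nt" else float("nan")
    return Alignment(gapped_a=a.upper(), gapped_b=b.upper(), params=params, score=score)
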