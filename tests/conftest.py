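import numpy as np
import pytest

from mitocompare.io import AnnotatedGenome, CircularSequence, Feature
from mitocompare.simulate import SimConfig, simulate_pair


@pytest.fixture(scope="session")
def sim_pair():
    """Default synthetic F/M mitogenome pair with its truth table."""
    return simulate_pair(SimConfig(seed=0))


@pytest.fixture(scope="session")
def sim_pair_files(sim_pair, tmp_path_factory):
    from mitocompare.io import write_genbank

    f, m, truth = sim_pair
    d = tmp_path_factory.mktemp("simpair")
    write_genbank(f, d / "F.gb")
    write_genbank(m, d / "M.gb")
    return d / "F.gb", d / "M.gb", truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def build_genome(cassettes, spacer=16, genome_id="toy", rotate=0,
                 revcomp=False):
    """Assemble a toy annotated genome from (name, kind, strand, seq) tuples
    separated by TTAA spacers, optionally rotated or reverse-complemented."""
    from mitocompare.io import reverse_complement

    parts, feats, pos = [], [], 0
    for name, kind, strand, seq in cassettes:
        locus = reverse_complement(seq) if strand == "-" else seq
        feats.append((name, kind, strand, pos, pos + len(locus)))
        parts.append(locus)
        pos += len(locus)
        parts.append(("TTAA" * (spacer // 4 + 1))[:spacer])
        pos += spacer
    residues = "".join(parts)
    n = len(residues)
    rotate %= n
    residues = residues[rotate:] + residues[:rotate]

    features = []
    for name, kind, strand, s, e in feats:
        s2 = (s - rotate) % n
        e2 = s2 + (e - s)
        assert e2 <= n, "choose a rotation that does not split a feature"
        features.append(Feature(name=name, kind=kind, strand=strand,
                                intervals=[(s2, e2)]))
    genome = AnnotatedGenome(
        sequence=CircularSequence(genome_id, residues), features=features)
    if revcomp:
        rc = reverse_complement(residues)
        rc_feats = [
            Feature(name=f.name, kind=f.kind,
                    strand="-" if f.strand == "+" else "+",
                    intervals=[(n - f.intervals[0][1], n - f.intervals[0][0])])
            for f in genome.features
        ]
        genome = AnnotatedGenome(
            sequence=CircularSequence(genome_id + "_rc", rc), features=rc_feats)
    return genome
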