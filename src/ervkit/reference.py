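"""Reference provirus: sequence plus feature table (LTRs, genes, peptides).

A gammaretroviral provirus has the layout

    5'LTR - leader - gag - pol - env - UTR - 3'LTR

with peptide sub-features inside each gene (gag: matrix p15, p12, capsid,
nucleocapsid; pol: protease, reverse transcriptase, integrase; env: SU, TM).
The package can load a real reference (FASTA + feature TSV) or build a
synthetic one whose genes are stop-codon-free reading frames, so ORF scanning
and annotation are exactly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .util import decode, encode, read_fasta, substream, write_fasta

GENES = ("gag", "pol", "env")

PEPTIDES: dict[str, tuple[tuple[str, float, float], ...]] = {
    # (name, fractional start, fractional end) within the parent gene
    "gag": (
        ("matrix_p15", 0.00, 0.27),
        ("p12", 0.27, 0.47),
        ("capsid", 0.47, 0.87),
        ("nucleocapsid", 0.87, 1.00),
    ),
    "pol": (
        ("protease", 0.00, 0.12),
        ("reverse_transcriptase", 0.12, 0.69),
        ("integrase", 0.69, 1.00),
    ),
    "env": (
        ("SU", 0.00, 0.68),
        ("TM", 0.68, 1.00),
    ),
}


@dataclass(frozen=True)
class Feature:
    name: str
    kind: str  # 'ltr' | 'gene' | 'peptide'
    start: int  # 0-based half-open, provirus coordinates
    end: int
    parent: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad feature interval {self.name}: [{self.start},{self.end})")


@dataclass
class ProvirusReference:
    """Query/annotation provirus: sequence + feature intervals."""

    seq: str
    features: dict[str, Feature] = field(default_factory=dict)

    def __post_init__(self):
        for f in self.features.values():
            if f.end > len(self.seq):
                raise ValueError(f"feature {f.name} exceeds sequence length")

    @property
    def length(self) -> int:
        return len(self.seq)

    def feature_seq(self, name: str) -> str:
        f = self.features[name]
        return self.seq[f.start : f.end]

    @property
    def ltr5(self) -> Feature:
        return self.features["LTR5"]

    @property
    def ltr3(self) -> Feature:
        return self.features["LTR3"]

    @property
    def ltr_seq(self) -> str:
        return self.feature_seq("LTR5")

    @property
    def internal_interval(self) -> tuple[int, int]:
        return self.ltr5.end, self.ltr3.start

    def gene_features(self) -> list[Feature]:
        return [self.features[g] for g in GENES if g in self.features]

    def peptide_features(self, gene: str) -> list[Feature]:
        return [f for f in self.features.values() if f.kind == "peptide" and f.parent == gene]

    def query_set(self) -> dict[str, str]:
        """The multi-query scanning set: LTR, each gene, and the whole provirus."""
        queries = {"LTR": self.ltr_seq, "provirus": self.seq}
        for g in GENES:
            if g in self.features:
                queries[g] = self.feature_seq(g)
        return queries

    # -- IO -----------------------------------------------------------------
    def save(self, fasta_path: str | Path, features_path: str | Path) -> None:
        write_fasta(fasta_path, [("provirus_reference", self.seq)])
        with open(features_path, "w") as fh:
            fh.write("name\tkind\tstart\tend\tparent\n")
            for f in self.features.values():
                fh.write(f"{f.name}\t{f.kind}\t{f.start}\t{f.end}\t{f.parent or '.'}\n")

    @classmethod
    def load(cls, fasta_path: str | Path, features_path: str | Path) -> "ProvirusReference":
        seqs = read_fasta(fasta_path)
        if len(seqs) != 1:
            raise ValueError("reference FASTA must contain exactly one sequence")
        (seq,) = seqs.values()
        feats: dict[str, Feature] = {}
        with open(features_path) as fh:
            header = fh.readline()
            if not header.startswith("name\t"):
                raise ValueError("missing feature table header")
            for line in fh:
                name, kind, start, end, parent = line.rstrip("\n").split("\t")
                feats[name] = Feature(name, kind, int(start), int(end),
                                      None if parent == "." else parent)
        return cls(seq=seq, features=feats)


def _random_orf(length: int, rng: np.random.Generator) -> str:
    """Random coding sequence with no stop codon in frame 0 (ATG start)."""
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    alphabet = "ACGT"
    while len(codons) * 3 < length:
        c = "".join(alphabet[i] for i in rng.integers(0, 4, size=3))
        if c not in stops:
            codons.append(c)
    return "".join(codons)[:length - (length % 3)].ljust(length, "A")[:length]


def synthetic_reference(
    seed: int = 7,
    ltr_len: int = 500,
    leader_len: int = 300,
    gag_len: int = 1500,
    pol_len: int = 2600,
    env_len: int = 1900,
    utr_len: int = 200,
) -> ProvirusReference:
    """Deterministic synthetic provirus used as query and annotation source.

    Gene lengths default to the same order of magnitude as gammaretroviral
    genes; all genes are open reading frames in frame 0 of their feature.
    """
    rng = substream(seed, "reference")
    ltr = decode(rng.integers(0, 4, size=ltr_len).astype(np.uint8))
    leader = decode(rng.integers(0, 4, size=leader_len).astype(np.uint8))
    utr = decode(rng.integers(0, 4, size=utr_len).astype(np.uint8))
    genes = {g: _random_orf(n, rng) for g, n in
             (("gag", gag_len), ("pol", pol_len), ("env", env_len))}

    parts = [ltr, leader, genes["gag"], genes["pol"], genes["env"], utr, ltr]
    seq = "".join(parts)

    feats: dict[str, Feature] = {}
    pos = 0
    feats["LTR5"] = Feature("LTR5", "ltr", 0, ltr_len)
    pos = ltr_len + leader_len
    for g in GENES:
        glen = len(genes[g])
        feats[g] = Feature(g, "gene", pos, pos + glen)
        for name, f0, f1 in PEPTIDES[g]:
            s = pos + 3 * round(glen * f0 / 3)
            e = pos + 3 * round(glen * f1 / 3)
            feats[name] = Feature(name, "peptide", s, min(e, pos + glen), parent=g)
        pos += glen
    pos += utr_len
    feats["LTR3"] = Feature("LTR3", "ltr", pos, pos + ltr_len)
    assert pos + ltr_len == len(seq)
    return ProvirusReference(seq=seq, features=feats)
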