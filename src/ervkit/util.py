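"""Shared low-level helpers: nucleotide encoding, RNG substreams, FASTA/GFF3 IO.

Sequences are python strings at API boundaries and uint8 code arrays
(A=0, C=1, G=2, T=3, N/other=4, gap '-'=5) internally.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

A, C, G, T, N, GAP = 0, 1, 2, 3, 4, 5

_ENCODE = np.full(256, N, dtype=np.uint8)
for _ch, _code in zip(b"ACGTN-", (A, C, G, T, N, GAP)):
    _ENCODE[_ch] = _code
for _ch, _code in zip(b"acgtn", (A, C, G, T, N)):
    _ENCODE[_ch] = _code

_DECODE = np.frombuffer(b"ACGTN-", dtype=np.uint8)

# transition partner and the two transversion partners, indexed by code
TS_PARTNER = np.array([G, T, A, C], dtype=np.uint8)
TV_PARTNER_1 = np.array([C, A, C, A], dtype=np.uint8)
TV_PARTNER_2 = np.array([T, G, T, G], dtype=np.uint8)

_COMPLEMENT = np.array([T, G, C, A, N, GAP], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 code array."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to a string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def substream(seed: int, *keys: str | int) -> np.random.Generator:
    """Derive a named, reproducible RNG substream from a single master seed.

    String keys are hashed with CRC32 so every stage of a pipeline draws from
    an independent stream while all randomness still flows from one seed.
    """
    ints = tuple(
        k if isinstance(k, int) else zlib.crc32(k.encode("utf-8")) for k in keys
    )
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=ints))


def random_background(length: int, rng: np.random.Generator, gc: float = 0.42) -> np.ndarray:
    """IID nucleotide background with the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def alignment_counts(aln) -> tuple[int, int, int]:
    """(gap columns, identities, mismatches) of a Bio.Align alignment."""
    c = aln.counts()
    return int(c.gaps), int(c.identities), int(c.mismatches)


# ---------------------------------------------------------------------------
# FASTA / GFF3 / JSON plumbing

def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(path: str | Path, rows: Iterable[Mapping]) -> None:
    """Write GFF3 from dict rows with 0-based half-open start/end (converted here)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in rows:
            attrs = ";".join(f"{k}={v}" for k, v in r.get("attributes", {}).items())
            fh.write(
                "\t".join(
                    [
                        str(r["seqid"]),
                        r.get("source", "ervkit"),
                        r["type"],
                        str(int(r["start"]) + 1),
                        str(int(r["end"])),
                        str(r.get("score", ".")),
                        r.get("strand", "."),
                        str(r.get("phase", ".")),
                        attrs or ".",
                    ]
                )
                + "\n"
            )


def write_json(path: str | Path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
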