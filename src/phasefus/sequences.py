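"""Sequence intake: FASTA records to chain architectures, plus generators.

The mean-field model only needs three numbers from a protein sequence —
its length and its Tyr and Arg counts — so the front door is a simple
residue-composition pass over a FASTA record.  A deterministic synthetic
FUS-like fixture (526 residues, 34 Tyr, 34 Arg) and a random
sticker-sequence generator for the coarse-grained simulator live here too.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO

from .params import ProteinSpec

_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence in one-letter codes (plus X)."""

    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = [(i, c) for i, c in enumerate(self.sequence)
               if c.upper() not in _ALPHABET]
        if bad:
            pos, char = bad[0]
            raise ValueError(
                f"invalid residue {char!r} at position {pos} "
                f"in record {self.identifier!r}"
                + (f" (+{len(bad) - 1} more)" if len(bad) > 1 else ""))


def sequence_to_spec(record: SequenceRecord) -> ProteinSpec:
    """Chain architecture from residue composition.

    N1 is the sequence length, m1 the Tyr count, m2 the Arg count.
    """
    seq = record.sequence.upper()
    return ProteinSpec(n1=len(seq), m1=seq.count("Y"), m2=seq.count("R"))


def read_fasta(source: str | Path | io.TextIOBase) -> Iterator[SequenceRecord]:
    """Iterate :class:`SequenceRecord` over a FASTA file or handle."""
    handle = open(source) if isinstance(source, (str, Path)) else source
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            yield SequenceRecord(identifier=rec.id, sequence=str(rec.seq))
    finally:
        if isinstance(source, (str, Path)):
            handle.close()


def random_sticker_sequence(length: int, sticker_fraction: float,
                            seed: int) -> SequenceRecord:
    """Random sticker placement: Y and R each at the given fraction, G else.

    The per-type sticker count is round(fraction * length); placement is
    uniform without replacement and deterministic for a given seed.
    """
    if not 0.0 <= 2.0 * sticker_fraction <= 1.0:
        raise ValueError("need 0 <= 2 * sticker_fraction <= 1")
    if length < 1:
        raise ValueError("length must be >= 1")
    n_per_type = round(sticker_fraction * length)
    rng = np.random.default_rng(seed)
    positions = rng.choice(length, size=2 * n_per_type, replace=False)
    chars = ["G"] * length
    for pos in positions[:n_per_type]:
        chars[pos] = "Y"
    for pos in positions[n_per_type:]:
        chars[pos] = "R"
    return SequenceRecord(identifier=f"sticker_L{length}_s{seed}",
                          sequence="".join(chars))


def synthetic_fus_record() -> SequenceRecord:
    """Deterministic synthetic stand-in for the FUS architecture.

    Not the biological FUS sequence: a generated 526-residue chain with
    exactly 34 Tyr and 34 Arg (the counts that define the model), G/S/Q/P
    elsewhere in a low-complexity-like pattern.
    """
    rng = np.random.default_rng(20220526)
    spacers = rng.choice(list("GSQP"), size=526)
    chars = list(spacers)
    positions = rng.choice(526, size=68, replace=False)
    for pos in positions[:34]:
        chars[pos] = "Y"
    for pos in positions[34:]:
        chars[pos] = "R"
    return SequenceRecord(identifier="fus2022_synthetic",
                          sequence="".join(chars))
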