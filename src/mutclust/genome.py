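"""Random access to a reference genome.

Wraps either an indexed FASTA on disk (via :mod:`pyfaidx`) or a plain
in-memory mapping of chromosome name to sequence string, behind one small
interface. Coordinates are 0-based half-open except where a name says
``pos1`` (1-based, as in mutation tables).
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Union

import pyfaidx

GenomeSource = Union[str, Path, Mapping[str, str], "ReferenceGenome"]


class ReferenceGenome:
    """Reference sequence accessor.

    Parameters
    ----------
    source
        Path to a FASTA file (a ``.fai`` index is created next to it if
        missing), or a mapping ``{chromosome: sequence}`` for in-memory use.
    """

    def __init__(self, source: GenomeSource):
        if isinstance(source, ReferenceGenome):
            self._fasta = source._fasta
            self._seqs = source._seqs
            self._lengths = dict(source._lengths)
            return
        if isinstance(source, (str, Path)):
            self._fasta = pyfaidx.Fasta(str(source), sequence_always_upper=True)
            self._seqs = None
            self._lengths = {name: len(rec) for name, rec in self._fasta.items()}
        elif isinstance(source, Mapping):
            self._fasta = None
            self._seqs = {name: str(seq).upper() for name, seq in source.items()}
            self._lengths = {name: len(seq) for name, seq in self._seqs.items()}
        else:
            raise TypeError(f"unsupported genome source: {type(source)!r}")

    def __contains__(self, chromosome: str) -> bool:
        return chromosome in self._lengths

    def chromosomes(self) -> list[str]:
        return list(self._lengths)

    def length(self, chromosome: str) -> int:
        try:
            return self._lengths[chromosome]
        except KeyError:
            raise KeyError(f"chromosome {chromosome!r} not in reference") from None

    def fetch(self, chromosome: str, start: int, end: int) -> str:
        """Return the sequence of ``[start, end)`` (0-based half-open), uppercase.

        Raises ``ValueError`` if the interval is not fully inside the
        chromosome.
        """
        n = self.length(chromosome)
        if start < 0 or end > n or start > end:
            raise ValueError(
                f"interval [{start}, {end}) outside chromosome "
                f"{chromosome!r} of length {n}"
            )
        if self._seqs is not None:
            return self._seqs[chromosome][start:end]
        return self._fasta[chromosome][start:end].seq.upper()

    def base(self, chromosome: str, pos1: int) -> str:
        """Single reference base at a 1-based position."""
        return self.fetch(chromosome, pos1 - 1, pos1)


def as_genome(source: GenomeSource) -> ReferenceGenome:
    """Coerce a path, mapping or ReferenceGenome into a ReferenceGenome."""
    if isinstance(source, ReferenceGenome):
        return source
    return ReferenceGenome(source)
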