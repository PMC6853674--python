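"""Input parsing and coordinate plumbing.

Reads genomic-element definitions (BED-like, 0-based half-open) and somatic
mutation tables (tab-separated with header, 1-based positions), builds the
concatenated element sequences that clustering operates on, and assigns
mutations to elements.

Conventions follow the dominant dialect of each format: regions are BED-style
0-based half-open; mutation positions are VCF-style 1-based. All conversions
are centralized in :class:`ElementSequence`.
"""
from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import ReferenceGenome

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: default column names of the mutation table; override via ``columns=``
DEFAULT_MUTATION_COLUMNS = {
    "chromosome": "chromosome",
    "position": "position",
    "ref": "ref",
    "alt": "alt",
    "sample": "sample",
}


@dataclass(frozen=True)
class Mutation:
    """One somatic single-nucleotide substitution in one tumor sample."""

    chromosome: str
    position: int  # 1-based genomic coordinate
    ref: str
    alt: str
    sample_id: str


@dataclass(frozen=True)
class GenomicElement:
    """A named, possibly multi-segment genomic region analyzed as one unit.

    ``segments`` are 0-based half-open intervals on a single chromosome,
    sorted ascending and non-overlapping.
    """

    element_id: str
    symbol: str
    chromosome: str
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not self.segments:
            raise ValueError(f"element {self.element_id}: no segments")
        prev_end = None
        for start, end in self.segments:
            if end <= start:
                raise ValueError(
                    f"element {self.element_id}: empty segment ({start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"element {self.element_id}: segments overlap or are unsorted"
                )
            prev_end = end

    @property
    def length(self) -> int:
        return sum(end - start for start, end in self.segments)


class ElementSequence:
    """Concatenated sequence of an element plus genomic<->element coordinate maps.

    Element coordinates are 0-based indices into the concatenated sequence;
    genomic coordinates are 1-based.
    """

    def __init__(self, element: GenomicElement, sequence: str, genomic_pos0: np.ndarray):
        self.element_id = element.element_id
        self.element = element
        self.sequence = sequence
        self._e2g0 = genomic_pos0  # 0-based genomic position per element index
        self._g2e = {int(g) + 1: i for i, g in enumerate(genomic_pos0)}

    def __len__(self) -> int:
        return len(self.sequence)

    def element_to_genomic(self, index: int) -> int:
        """1-based genomic position of element index ``index``."""
        return int(self._e2g0[index]) + 1

    def genomic_to_element(self, pos1: int) -> Optional[int]:
        """Element index of 1-based genomic position, or None if unmapped (gap)."""
        return self._g2e.get(pos1)

    def __contains__(self, pos1: int) -> bool:
        return pos1 in self._g2e


@dataclass
class MutationReadStats:
    """Row accounting for one mutation table."""

    n_rows: int = 0
    n_non_snv: int = 0
    n_duplicates: int = 0

    @property
    def n_snvs(self) -> int:
        return self.n_rows - self.n_non_snv - self.n_duplicates


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_regions(path) -> list[GenomicElement]:
    """Parse a BED-like regions file into GenomicElements.

    Tab-separated columns: chromosome, start, end, element_id and optionally a
    5th symbol column; 0-based half-open; optionally gzip-compressed; no
    header. Rows sharing an element_id are merged into one element with
    sorted, deduplicated segments; overlapping segments within an element are
    unioned with a counted warning.
    """
    raw: dict[str, dict] = {}
    order: list[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 4 tab-separated columns "
                    f"(chromosome, start, end, element_id), got {len(fields)}"
                )
            chrom, start_s, end_s, element_id = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer start/end "
                    f"({start_s!r}, {end_s!r})"
                ) from None
            if start < 0 or end <= start:
                raise ValueError(
                    f"{path}: line {lineno}: invalid interval ({start}, {end})"
                )
            symbol = fields[4] if len(fields) > 4 and fields[4] else element_id
            entry = raw.setdefault(
                element_id, {"chromosome": chrom, "symbol": symbol, "segments": []}
            )
            if element_id not in order:
                order.append(element_id)
            if entry["chromosome"] != chrom:
                raise ValueError(
                    f"{path}: line {lineno}: element {element_id!r} spans "
                    f"chromosomes {entry['chromosome']!r} and {chrom!r}"
                )
            entry["segments"].append((start, end))

    elements = []
    n_merged = 0
    for element_id in order:
        entry = raw[element_id]
        segments = sorted(set(entry["segments"]))
        merged: list[list[int]] = []
        for start, end in segments:
            if merged and start < merged[-1][1]:  # overlap -> union
                merged[-1][1] = max(merged[-1][1], end)
                n_merged += 1
            else:
                merged.append([start, end])
        elements.append(
            GenomicElement(
                element_id=element_id,
                symbol=entry["symbol"],
                chromosome=entry["chromosome"],
                segments=tuple((s, e) for s, e in merged),
            )
        )
    if n_merged:
        logger.warning("merged %d overlapping segment pairs in %s", n_merged, path)
    return elements


def read_mutations(
    path,
    columns: Optional[Mapping[str, str]] = None,
) -> tuple[list[Mutation], MutationReadStats]:
    """Parse a tab-separated mutation table into single-nucleotide substitutions.

    ``columns`` maps the logical names (chromosome/position/ref/alt/sample)
    to the file's column headers. Non-SNV rows (indels, MNVs, ref==alt) are
    skipped and counted; duplicate rows (same chromosome, position, ref, alt,
    sample) are dropped and counted — the same substitution in *different*
    samples is kept, since recurrence across samples is the signal.
    """
    colmap = dict(DEFAULT_MUTATION_COLUMNS)
    if columns:
        colmap.update(columns)
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except OSError as exc:
        raise OSError(f"cannot read mutations file {path}: {exc}") from exc
    for logical, name in colmap.items():
        if name not in table.columns:
            raise ValueError(
                f"{path}: missing required column {name!r} (for {logical})"
            )

    stats = MutationReadStats()
    seen: set[tuple] = set()
    mutations: list[Mutation] = []
    for row in table.itertuples(index=False):
        stats.n_rows += 1
        rec = {logical: getattr(row, name) for logical, name in colmap.items()}
        ref = str(rec["ref"]).upper()
        alt = str(rec["alt"]).upper()
        if (
            len(ref) != 1
            or len(alt) != 1
            or ref not in VALID_BASES
            or alt not in VALID_BASES
            or ref == alt
        ):
            stats.n_non_snv += 1
            continue
        try:
            position = int(rec["position"])
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: non-integer position {rec['position']!r}"
            ) from None
        key = (str(rec["chromosome"]), position, ref, alt, str(rec["sample"]))
        if key in seen:
            stats.n_duplicates += 1
            continue
        seen.add(key)
        mutations.append(
            Mutation(
                chromosome=key[0],
                position=position,
                ref=ref,
                alt=alt,
                sample_id=key[4],
            )
        )
    if stats.n_duplicates:
        logger.warning(
            "%s: dropped %d duplicate mutation rows", path, stats.n_duplicates
        )
    return mutations, stats


def validate_reference(
    mutations: Iterable[Mutation], genome: ReferenceGenome
) -> tuple[list[Mutation], int]:
    """Drop mutations whose ref allele does not match the reference genome.

    Mutations on chromosomes absent from the reference, or at positions
    outside it, count as mismatches too. Returns (valid mutations, number
    rejected).
    """
    valid: list[Mutation] = []
    n_mismatch = 0
    for mut in mutations:
        ok = False
        if mut.chromosome in genome and 1 <= mut.position <= genome.length(mut.chromosome):
            ok = genome.base(mut.chromosome, mut.position) == mut.ref
        if ok:
            valid.append(mut)
        else:
            n_mismatch += 1
    if n_mismatch:
        logger.warning("rejected %d mutations with reference mismatch", n_mismatch)
    return valid, n_mismatch


def build_element_sequence(
    element: GenomicElement, genome: ReferenceGenome
) -> ElementSequence:
    """Concatenate an element's segment sequences and build coordinate maps."""
    chrom_len = genome.length(element.chromosome)
    parts = []
    pos_arrays = []
    for start, end in element.segments:
        if start < 0 or end > chrom_len:
            raise ValueError(
                f"element {element.element_id}: segment ({start}, {end}) outside "
                f"chromosome {element.chromosome!r} of length {chrom_len}"
            )
        parts.append(genome.fetch(element.chromosome, start, end))
        pos_arrays.append(np.arange(start, end, dtype=np.int64))
    return ElementSequence(element, "".join(parts), np.concatenate(pos_arrays))


def assign_mutations(
    mutations: Sequence[Mutation],
    elements: Sequence[GenomicElement],
    sequences: Optional[Mapping[str, ElementSequence]] = None,
) -> tuple[dict[str, list[tuple[Mutation, int]]], int]:
    """Assign each mutation to every element whose segments contain it.

    A position may belong to several overlapping elements. Returns a mapping
    element_id -> list of (mutation, element index) plus the count of
    mutations falling in no element (dropped with a warning).
    """
    trees: dict[str, IntervalTree] = {}
    for element in elements:
        tree = trees.setdefault(element.chromosome, IntervalTree())
        cum = 0
        for start, end in element.segments:
            # element index of genomic 0-based g inside this segment: g - start + cum
            tree[start:end] = (element.element_id, cum - start)
            cum += end - start

    assigned: dict[str, list[tuple[Mutation, int]]] = {}
    n_unassigned = 0
    for mut in mutations:
        pos0 = mut.position - 1
        hits = trees[mut.chromosome][pos0] if mut.chromosome in trees else ()
        if not hits:
            n_unassigned += 1
            continue
        for hit in hits:
            element_id, offset = hit.data
            assigned.setdefault(element_id, []).append((mut, pos0 + offset))
    if n_unassigned:
        logger.warning("%d mutations fall outside all elements", n_unassigned)
    for muts in assigned.values():
        muts.sort(key=lambda pair: (pair[1], pair[0].sample_id, pair[0].alt))
    return assigned, n_unassigned
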