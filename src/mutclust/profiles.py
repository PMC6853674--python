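"""Cohort k-mer-context substitution profile.

The local simulation null is parameterized by the cohort-wide normalized
frequencies of context-dependent substitutions: for every k-mer (k = 3 or 5,
forward strand, no pyrimidine collapsing) centered on a mutated base, and
every alternate allele, the fraction of cohort mutations carrying that
change. Contexts containing 'N' (or truncated at a chromosome edge) are
undefined and carry probability zero.

Counting and placement share the same forward-strand frame, so no
reverse-complement bookkeeping is needed anywhere.
"""
from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome import ReferenceGenome
from .io import GenomicElement, Mutation

BASES = "ACGT"


@dataclass
class MutationalProfile:
    """Normalized frequencies of (context k-mer, alternate) substitutions.

    ``probabilities`` sum to 1 over all stored pairs; keys never contain 'N'
    and the alternate never equals the context's center base.
    """

    k: int
    probabilities: dict[tuple[str, str], float]
    total_counted: int
    _totals: Optional[dict[str, float]] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.k not in (3, 5):
            raise ValueError(f"k must be 3 or 5, got {self.k}")

    def probability(self, context: str, alt: str) -> float:
        """Probability of the (context, alt) change; 0 for unseen or undefined."""
        if len(context) != self.k or "N" in context:
            return 0.0
        return self.probabilities.get((context, alt), 0.0)

    def total_change_probability(self, context: str) -> float:
        """Summed probability of any change at a position with this context."""
        if self._totals is None:
            totals: dict[str, float] = {}
            for (ctx, _alt), p in self.probabilities.items():
                totals[ctx] = totals.get(ctx, 0.0) + p
            self._totals = totals
        if len(context) != self.k or "N" in context:
            return 0.0
        return self._totals.get(context, 0.0)

    def alt_distribution(self, context: str) -> tuple[list[str], np.ndarray]:
        """Alternate alleles and their conditional probabilities at a context.

        Falls back to a uniform draw over the three non-reference bases when
        the context carries no probability mass.
        """
        center = context[self.k // 2] if len(context) == self.k else "N"
        alts = [b for b in BASES if b != center] if center in BASES else list(BASES[:3])
        weights = np.array([self.probability(context, a) for a in alts])
        if weights.sum() <= 0:
            weights = np.ones(len(alts))
        return alts, weights / weights.sum()

    def to_tsv(self, path) -> None:
        """Write the profile as two columns: ``context>alt`` and probability."""
        with open(path, "w") as fh:
            fh.write("change\tprobability\n")
            for (ctx, alt), p in sorted(self.probabilities.items()):
                fh.write(f"{ctx}>{alt}\t{p:.12g}\n")

    @classmethod
    def from_tsv(cls, path) -> "MutationalProfile":
        probabilities: dict[tuple[str, str], float] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("change"):
                raise ValueError(f"{path}: expected header 'change<TAB>probability'")
            for line in fh:
                change, prob = line.rstrip("\n").split("\t")
                ctx, alt = change.split(">")
                probabilities[(ctx, alt)] = float(prob)
        if not probabilities:
            raise ValueError(f"{path}: empty profile")
        k = len(next(iter(probabilities))[0])
        total = sum(probabilities.values())
        probabilities = {key: p / total for key, p in probabilities.items()}
        return cls(k=k, probabilities=probabilities, total_counted=0)


def extract_context(
    genome: ReferenceGenome, chromosome: str, position: int, k: int
) -> str:
    """Reference k-mer centered on a 1-based position, forward strand.

    Returns an all-'N' marker when a flank falls outside the chromosome, so
    boundary positions naturally carry zero substitution probability.
    """
    if k % 2 != 1:
        raise ValueError(f"k must be odd, got {k}")
    h = (k - 1) // 2
    start = position - 1 - h
    end = position + h
    if start < 0 or end > genome.length(chromosome):
        return "N" * k
    return genome.fetch(chromosome, start, end)


def compute_profile(
    mutations: Iterable[Mutation],
    genome: ReferenceGenome,
    k: int = 3,
) -> MutationalProfile:
    """Count cohort (context, alt) changes and normalize to probabilities.

    Mutations with undefined context ('N' in the k-mer or a chromosome-edge
    flank) are excluded; raises if nothing is countable.
    """
    counts: Counter = Counter()
    for mut in mutations:
        ctx = extract_context(genome, mut.chromosome, mut.position, k)
        if "N" in ctx:
            continue
        counts[(ctx, mut.alt)] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no mutations with a defined context; profile undefined")
    probabilities = {key: n / total for key, n in counts.items()}
    return MutationalProfile(k=k, probabilities=probabilities, total_counted=total)


def context_probability(profile: MutationalProfile, context: str, alt: str) -> float:
    """Module-level convenience for :meth:`MutationalProfile.probability`."""
    return profile.probability(context, alt)


def uniform_profile(k: int = 3) -> MutationalProfile:
    """Profile with equal probability on every N-free (context, alt) pair.

    With k=3 this spreads mass over 4^3 * 3 = 192 changes; useful as a
    maximally uninformative null in synthetic cohorts.
    """
    pairs = []
    for ctx in ("".join(t) for t in itertools.product(BASES, repeat=k)):
        center = ctx[k // 2]
        pairs.extend((ctx, alt) for alt in BASES if alt != center)
    p = 1.0 / len(pairs)
    return MutationalProfile(k=k, probabilities={pair: p for pair in pairs}, total_counted=0)


def count_undefined_contexts(
    mutations: Iterable[Mutation], genome: ReferenceGenome, k: int
) -> int:
    """Number of mutations whose k-mer context is undefined ('N' or edge)."""
    return sum(
        1
        for mut in mutations
        if "N" in extract_context(genome, mut.chromosome, mut.position, k)
    )


def element_change_probabilities(
    element: GenomicElement,
    genome: ReferenceGenome,
    profile: MutationalProfile,
) -> np.ndarray:
    """Total change probability at every element position, in element coordinates.

    Position i of the concatenated element gets the profile's total change
    probability of the k-mer context read from the *genome* at the mapped
    genomic position — so positions next to a segment junction use their true
    genomic flanks, never a chimeric concatenated k-mer. Positions with
    undefined context get 0.
    """
    k = profile.k
    h = (k - 1) // 2
    # make sure the totals cache exists before the tight loop
    profile.total_change_probability("N" * k)
    totals = profile._totals or {}
    chrom_len = genome.length(element.chromosome)
    out = np.empty(element.length, dtype=float)
    i = 0
    for start, end in element.segments:
        lo = max(start - h, 0)
        hi = min(end + h, chrom_len)
        seq = genome.fetch(element.chromosome, lo, hi)
        for g in range(start, end):
            if g - h < 0 or g + h >= chrom_len:
                out[i] = 0.0
            else:
                off = g - lo
                out[i] = totals.get(seq[off - h : off + h + 1], 0.0)
            i += 1
    return out
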