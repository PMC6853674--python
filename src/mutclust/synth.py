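"""Synthetic genomes, elements and mutation cohorts for testing and calibration.

The generator builds a reproducible random reference, lays out (possibly
multi-segment) elements on it, and draws cohorts either from a *null*
context-driven placement law — position-wise proportional to a stated
profile's total change probability, i.e. exactly the law the analyzer's
simulation uses — or with planted positional hotspots carrying a fixed
fraction of an element's mutations. A truth table records which elements
carry planted signal, so power and type-I-error checks need no
re-derivation.

What this emulates: cohorts of single-nucleotide substitutions whose
positions are driven only by sequence context (null) plus idealized
single-position hotspots (signal). What it does not emulate: real mutational
signatures, sample heterogeneity, copy number, indels, or clustered
mutational processes such as APOBEC showers — calibration and power results
on these fixtures bound the statistics, not the biology of real cohorts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pyfaidx

from .genome import ReferenceGenome
from .io import GenomicElement, Mutation, build_element_sequence
from .profiles import (
    MutationalProfile,
    element_change_probabilities,
    extract_context,
    uniform_profile,
)

BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    """Layout and cohort parameters of one synthetic dataset.

    ``hotspots`` is a tuple of (element_id, element index, fraction): the
    element gets ``floor(fraction * n)`` of its ``n`` mutations planted at
    that index (deterministic floor rounding), the rest drawn from the null
    law.
    """

    n_elements: int = 20
    element_length: int = 1000
    n_segments: int = 1
    n_chromosomes: int = 2
    spacing: int = 50  # gap between segments/elements and chromosome margin
    base_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif: Optional[str] = None
    motif_period: Optional[int] = None
    n_samples: Optional[int] = None  # default: one sample per mutation slot
    mutations_per_element: int = 30
    k: int = 3
    null_profile: Optional[MutationalProfile] = None  # default: uniform
    hotspots: tuple[tuple[str, int, float], ...] = ()
    seed: int = 0

    def __post_init__(self):
        for element_id, index, fraction in self.hotspots:
            if not 0 <= fraction <= 1:
                raise ValueError(f"hotspot fraction {fraction} outside [0, 1]")
            if not 0 <= index < self.element_length:
                raise ValueError(
                    f"hotspot index {index} outside element {element_id!r}"
                )

    def profile(self) -> MutationalProfile:
        return self.null_profile or uniform_profile(self.k)


def element_ids(spec: FixtureSpec) -> list[str]:
    return [f"E{i:03d}" for i in range(1, spec.n_elements + 1)]


def layout_elements(spec: FixtureSpec) -> list[GenomicElement]:
    """Place elements sequentially across chromosomes with fixed spacing."""
    ids = element_ids(spec)
    per_chrom = math.ceil(spec.n_elements / spec.n_chromosomes)
    seg_len = spec.element_length // spec.n_segments
    lengths = [seg_len] * (spec.n_segments - 1)
    lengths.append(spec.element_length - seg_len * (spec.n_segments - 1))
    elements = []
    for i, element_id in enumerate(ids):
        chrom = f"chr{i // per_chrom + 1}"
        rank = i % per_chrom
        stride = spec.element_length + spec.spacing * (spec.n_segments + 1)
        cursor = spec.spacing + rank * stride
        segments = []
        for length in lengths:
            segments.append((cursor, cursor + length))
            cursor += length + spec.spacing
        elements.append(
            GenomicElement(
                element_id=element_id,
                symbol=element_id,
                chromosome=chrom,
                segments=tuple(segments),
            )
        )
    return elements


def generate_genome(
    spec: FixtureSpec, elements: Optional[Sequence[GenomicElement]] = None
) -> dict[str, str]:
    """Random reference sequences sized to hold the element layout."""
    if elements is None:
        elements = layout_elements(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 0xFA57A]))
    needed: dict[str, int] = {}
    for element in elements:
        end = max(e for _, e in element.segments) + spec.spacing
        needed[element.chromosome] = max(needed.get(element.chromosome, 0), end)
    weights = np.asarray(spec.base_weights, dtype=float)
    weights = weights / weights.sum()
    genome = {}
    for chrom in sorted(needed):
        length = needed[chrom]
        seq = rng.choice(list(BASES), size=length, p=weights)
        if spec.motif and spec.motif_period:
            motif = list(spec.motif.upper())
            for start in range(0, length - len(motif) + 1, spec.motif_period):
                seq[start : start + len(motif)] = motif
        genome[chrom] = "".join(seq)
    return genome


def generate_cohort(
    spec: FixtureSpec,
    genome: ReferenceGenome | dict,
    elements: Optional[Sequence[GenomicElement]] = None,
) -> tuple[list[Mutation], pd.DataFrame]:
    """Draw the cohort and return (mutations, truth table).

    Null mutations are placed position-wise proportional to the null
    profile's total change probability (the analyzer's own placement law);
    hotspot mutations go to their planted index. Alternate alleles are drawn
    from the profile's conditional alt distribution at each position's
    context. Samples are assigned round-robin within each element, so with
    the default one-sample-per-slot no within-sample duplicates can arise.
    """
    if elements is None:
        elements = layout_elements(spec)
    ref = genome if isinstance(genome, ReferenceGenome) else ReferenceGenome(genome)
    profile = spec.profile()
    hotspot_by_element = {eid: (idx, frac) for eid, idx, frac in spec.hotspots}
    unknown = set(hotspot_by_element) - {e.element_id for e in elements}
    if unknown:
        raise ValueError(f"hotspot elements not in layout: {sorted(unknown)}")
    n_samples = spec.n_samples or spec.mutations_per_element
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 0xC0407]))

    mutations: list[Mutation] = []
    truth_rows = []
    for element in elements:
        seq = build_element_sequence(element, ref)
        q = element_change_probabilities(element, ref, profile)
        total = q.sum()
        if total <= 0:
            raise ValueError(
                f"element {element.element_id}: no position has change probability"
            )
        n = spec.mutations_per_element
        hotspot = hotspot_by_element.get(element.element_id)
        if hotspot:
            hot_index, fraction = hotspot
            n_hot = int(math.floor(fraction * n))
        else:
            hot_index, fraction, n_hot = None, 0.0, 0
        null_positions = rng.choice(len(q), size=n - n_hot, p=q / total)
        positions = np.concatenate(
            [np.full(n_hot, hot_index, dtype=np.int64), null_positions]
        )
        for j, idx in enumerate(positions):
            pos1 = seq.element_to_genomic(int(idx))
            base = ref.base(element.chromosome, pos1)
            ctx = extract_context(ref, element.chromosome, pos1, profile.k)
            alts, alt_probs = profile.alt_distribution(ctx)
            # guard: planted index may sit on a context the profile never saw
            alts = [a for a in alts if a != base] or [b for b in BASES if b != base]
            alt_probs = np.array(
                [profile.probability(ctx, a) for a in alts], dtype=float
            )
            if alt_probs.sum() <= 0:
                alt_probs = np.ones(len(alts))
            alt = str(rng.choice(alts, p=alt_probs / alt_probs.sum()))
            mutations.append(
                Mutation(
                    chromosome=element.chromosome,
                    position=pos1,
                    ref=base,
                    alt=alt,
                    sample_id=f"S{j % n_samples:03d}",
                )
            )
        truth_rows.append(
            {
                "element_id": element.element_id,
                "n_mutations": n,
                "hotspot_index": -1 if hot_index is None else int(hot_index),
                "hotspot_fraction": fraction,
                "n_planted": n_hot,
                "planted": hotspot is not None and n_hot > 0,
            }
        )
    return mutations, pd.DataFrame(truth_rows)


def build_fixture(spec: FixtureSpec):
    """In-memory fixture bundle: (genome dict, elements, mutations, truth)."""
    elements = layout_elements(spec)
    genome = generate_genome(spec, elements)
    ref = ReferenceGenome(genome)
    mutations, truth = generate_cohort(spec, ref, elements)
    return genome, elements, mutations, truth


def write_fixture(spec: FixtureSpec, output_dir) -> dict[str, Path]:
    """Write genome.fa (+ .fai), regions.tsv, mutations.tsv and truth.tsv.

    The files use exactly the dialects the readers consume: FASTA, BED-like
    0-based half-open regions, and a 1-based tab-separated mutation table.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    genome, elements, mutations, truth = build_fixture(spec)
    paths = {
        "genome": output_dir / "genome.fa",
        "regions": output_dir / "regions.tsv",
        "mutations": output_dir / "mutations.tsv",
        "truth": output_dir / "truth.tsv",
    }
    with open(paths["genome"], "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    pyfaidx.Faidx(str(paths["genome"]))  # build the .fai index
    with open(paths["regions"], "w") as fh:
        for element in elements:
            for start, end in element.segments:
                fh.write(
                    f"{element.chromosome}\t{start}\t{end}"
                    f"\t{element.element_id}\t{element.symbol}\n"
                )
    with open(paths["mutations"], "w") as fh:
        fh.write("chromosome\tposition\tref\talt\tsample\n")
        for m in mutations:
            fh.write(f"{m.chromosome}\t{m.position}\t{m.ref}\t{m.alt}\t{m.sample_id}\n")
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def toy_spec(seed: int = 1234) -> FixtureSpec:
    """Small end-to-end fixture: 20 null elements plus one planted hotspot.

    The planted element carries 60% of its 50 mutations at one position — a
    hotspot decisive enough that its detection at 1% FDR is a property of
    the construction, not of any particular random draw — while the null
    elements stay quiet.
    """
    return FixtureSpec(
        n_elements=21,
        element_length=1000,
        n_segments=2,
        n_chromosomes=2,
        mutations_per_element=50,
        hotspots=(("E011", 300, 0.6),),
        seed=seed,
    )
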