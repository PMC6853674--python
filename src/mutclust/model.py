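"""Model/Results interface to the clustering analysis.

:class:`ClusteringModel` is built from a cohort of somatic mutations, a set
of genomic elements and a reference genome; ``fit()`` runs the per-element
smoothing -> clustering -> scoring -> local-simulation pipeline and returns a
:class:`ClusteringResults` carrying the per-element and per-cluster tables,
the Benjamini-Hochberg-adjusted significance calls and the full record-level
accounting.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .genome import GenomeSource, as_genome
from .profiles import (
    MutationalProfile,
    compute_profile,
    count_undefined_contexts,
)
from .simulation import (
    ElementResult,
    SimulationConfig,
    analyze_element,
    bh_adjust,
    build_element_data,
)

logger = logging.getLogger(__name__)

ELEMENTS_COLUMNS = [
    "element_id",
    "symbol",
    "n_mutations",
    "n_clusters",
    "score",
    "p_value",
    "q_value",
    "significant",
]
CLUSTERS_COLUMNS = [
    "element_id",
    "left",
    "right",
    "peak",
    "genomic_left",
    "genomic_right",
    "genomic_peak",
    "n_mutations",
    "score",
    "p_value",
]


class ClusteringModel:
    """Positional-clustering test for somatic mutations in genomic elements.

    Parameters
    ----------
    mutations
        Validated single-nucleotide substitutions (``io.Mutation``).
    elements
        Genomic elements to analyze.
    genome
        Reference genome: path to an indexed FASTA or ``{name: sequence}``.
    config
        Simulation and clustering parameters; defaults are sensible.
    profile
        Optional precomputed mutational profile; by default the profile is
        estimated from the mutations that fall inside the analyzed elements.
    profile_scope
        ``"elements"`` (default) counts the profile from in-element mutations
        only; ``"all"`` uses every reference-validated mutation.
    """

    def __init__(
        self,
        mutations: Sequence[mio.Mutation],
        elements: Sequence[mio.GenomicElement],
        genome: GenomeSource,
        config: Optional[SimulationConfig] = None,
        profile: Optional[MutationalProfile] = None,
        profile_scope: str = "elements",
        read_stats: Optional[mio.MutationReadStats] = None,
    ):
        if profile_scope not in ("elements", "all"):
            raise ValueError("profile_scope must be 'elements' or 'all'")
        self.config = config or SimulationConfig()
        self.genome = as_genome(genome)
        self.elements = list(elements)
        self.read_stats = read_stats or mio.MutationReadStats(n_rows=len(mutations))

        valid, n_mismatch = mio.validate_reference(mutations, self.genome)
        self.mutations = valid
        assigned, n_unassigned = mio.assign_mutations(valid, self.elements)
        self.assigned = assigned
        in_elements = self._unique_assigned()

        self.counters = {
            "input_rows": self.read_stats.n_rows,
            "non_snv_skipped": self.read_stats.n_non_snv,
            "duplicates_removed": self.read_stats.n_duplicates,
            "snvs": len(mutations),
            "reference_mismatch": n_mismatch,
            "assigned": len(in_elements),
            "unassigned": n_unassigned,
        }

        if profile is not None:
            self.profile = profile
            if profile.k != self.config.k:
                raise ValueError(
                    f"profile k={profile.k} does not match config k={self.config.k}"
                )
        else:
            source = valid if profile_scope == "all" else in_elements
            if not source:
                raise ValueError("no mutations available to estimate the profile")
            self.profile = compute_profile(source, self.genome, k=self.config.k)
        n_undefined = count_undefined_contexts(in_elements, self.genome, self.config.k)
        self.counters["context_undefined"] = n_undefined
        self.counters["profile_counted"] = len(in_elements) - n_undefined

    def _unique_assigned(self) -> list[mio.Mutation]:
        seen = set()
        unique = []
        for pairs in self.assigned.values():
            for mut, _idx in pairs:
                if mut not in seen:
                    seen.add(mut)
                    unique.append(mut)
        return unique

    @classmethod
    def from_files(
        cls,
        mutations_path,
        regions_path,
        genome_path,
        config: Optional[SimulationConfig] = None,
        profile_path=None,
        columns: Optional[Mapping[str, str]] = None,
        profile_scope: str = "elements",
    ) -> "ClusteringModel":
        """Build the model from a mutation TSV, a BED-like regions file and a FASTA."""
        elements = mio.read_regions(regions_path)
        mutations, stats = mio.read_mutations(mutations_path, columns=columns)
        if not mutations:
            raise ValueError(f"{mutations_path}: no single-nucleotide substitutions")
        profile = MutationalProfile.from_tsv(profile_path) if profile_path else None
        return cls(
            mutations,
            elements,
            genome_path,
            config=config,
            profile=profile,
            profile_scope=profile_scope,
            read_stats=stats,
        )

    def fit(self, cores: int = 1, skip_bad_elements: bool = False) -> "ClusteringResults":
        """Analyze every element with at least one assigned mutation.

        Per-element random streams make the result independent of processing
        order and of ``cores``.
        """
        t0 = time.time()
        analyzed_ids = [e.element_id for e in self.elements if e.element_id in self.assigned]
        if not analyzed_ids:
            raise ValueError("no element has any assigned mutation")
        by_id = {e.element_id: e for e in self.elements}

        def _one(element_id: str) -> Optional[ElementResult]:
            element = by_id[element_id]
            try:
                data = build_element_data(
                    element, self.genome, self.assigned[element_id], self.profile
                )
                return analyze_element(data, self.profile, self.config)
            except Exception:
                if skip_bad_elements:
                    logger.exception("skipping element %s", element_id)
                    return None
                logger.error("analysis failed in element %s", element_id)
                raise

        if cores > 1:
            from joblib import Parallel, delayed

            # threading backend: per-element RNG streams make results
            # identical at any worker count, and the closure needs no pickling
            results = Parallel(n_jobs=cores, backend="threading")(
                delayed(_one)(eid) for eid in analyzed_ids
            )
        else:
            results = [_one(eid) for eid in analyzed_ids]
        results = [r for r in results if r is not None]

        q_values = bh_adjust([r.p_value for r in results])
        for result, q in zip(results, q_values):
            result.q_value = float(q)
            result.significant = bool(q < self.config.fdr_threshold)

        self.counters["zero_weight_windows"] = sum(
            r.n_zero_weight_windows for r in results
        )
        return ClusteringResults(
            model=self,
            element_results=results,
            wall_clock=time.time() - t0,
        )


class ClusteringResults:
    """Fitted clustering analysis: tables, significance calls and accounting."""

    def __init__(
        self,
        model: ClusteringModel,
        element_results: list[ElementResult],
        wall_clock: float,
    ):
        self.model = model
        self.config = model.config
        self.element_results = element_results
        self.wall_clock = wall_clock
        self._elements: Optional[pd.DataFrame] = None
        self._clusters: Optional[pd.DataFrame] = None

    @property
    def elements(self) -> pd.DataFrame:
        """One row per analyzed element, sorted by q, then p, then score desc."""
        if self._elements is None:
            rows = [
                {
                    "element_id": r.element_id,
                    "symbol": r.symbol,
                    "n_mutations": r.n_mutations,
                    "n_clusters": r.n_clusters,
                    "score": r.score,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                    "significant": r.significant,
                }
                for r in self.element_results
            ]
            df = pd.DataFrame(rows, columns=ELEMENTS_COLUMNS)
            df["_neg_score"] = -df["score"]
            df = df.sort_values(
                ["q_value", "p_value", "_neg_score", "element_id"],
                kind="mergesort",
            ).drop(columns="_neg_score")
            self._elements = df.reset_index(drop=True)
        return self._elements

    @property
    def clusters(self) -> pd.DataFrame:
        """One row per surviving cluster, with element and genomic coordinates."""
        if self._clusters is None:
            sequences = {}
            rows = []
            for r in self.element_results:
                if not r.clusters:
                    continue
                seq = sequences.get(r.element_id)
                if seq is None:
                    element = next(
                        e for e in self.model.elements if e.element_id == r.element_id
                    )
                    seq = mio.build_element_sequence(element, self.model.genome)
                    sequences[r.element_id] = seq
                for cl in r.clusters:
                    rows.append(
                        {
                            "element_id": r.element_id,
                            "left": cl.left,
                            "right": cl.right,
                            "peak": cl.peak,
                            "genomic_left": seq.element_to_genomic(cl.left),
                            "genomic_right": seq.element_to_genomic(cl.right),
                            "genomic_peak": seq.element_to_genomic(cl.peak),
                            "n_mutations": cl.n_mutations,
                            "score": cl.score,
                            "p_value": cl.p_value,
                        }
                    )
            df = pd.DataFrame(rows, columns=CLUSTERS_COLUMNS)
            df = df.sort_values(["element_id", "left"], kind="mergesort")
            self._clusters = df.reset_index(drop=True)
        return self._clusters

    @property
    def significant(self) -> pd.DataFrame:
        """Elements below the configured FDR threshold."""
        df = self.elements
        return df[df["significant"]].reset_index(drop=True)

    def metadata(self) -> dict:
        """Config echo, record accounting and timing, JSON-serializable."""
        return {
            "config": asdict(self.config),
            "counters": dict(self.model.counters),
            "n_elements_defined": len(self.model.elements),
            "n_elements_analyzed": len(self.element_results),
            "n_significant": int(self.elements["significant"].sum()),
            "wall_clock_seconds": round(self.wall_clock, 3),
        }

    def summary(self, top: int = 10) -> str:
        """Human-readable run summary with the top-ranked elements."""
        meta = self.metadata()
        lines = [
            "Somatic mutation clustering analysis",
            "=" * 68,
            f"elements analyzed: {meta['n_elements_analyzed']} of "
            f"{meta['n_elements_defined']} defined",
            f"mutations assigned: {meta['counters']['assigned']} "
            f"(unassigned {meta['counters']['unassigned']}, "
            f"reference mismatch {meta['counters']['reference_mismatch']})",
            f"simulations per element: {self.config.n_simulations}, "
            f"k-mer context: {self.config.k}, seed: {self.config.seed}",
            f"significant at FDR < {self.config.fdr_threshold:g}: "
            f"{meta['n_significant']}",
            "-" * 68,
        ]
        head = self.elements.head(top).copy()
        for col in ("score", "p_value", "q_value"):
            head[col] = head[col].map(lambda v: f"{v:.4g}")
        lines.append(head.to_string(index=False))
        return "\n".join(lines)

    def write(self, output_dir) -> dict[str, Path]:
        """Write elements.tsv, clusters.tsv and metadata.json to a directory."""
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "elements": output_dir / "elements.tsv",
            "clusters": output_dir / "clusters.tsv",
            "metadata": output_dir / "metadata.json",
        }
        self.elements.to_csv(
            paths["elements"], sep="\t", index=False, float_format="%.6g"
        )
        self.clusters.to_csv(
            paths["clusters"], sep="\t", index=False, float_format="%.6g"
        )
        with open(paths["metadata"], "w") as fh:
            json.dump(self.metadata(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths
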