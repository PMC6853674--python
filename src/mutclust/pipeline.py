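"""End-to-end run: files in, report files out.

Thin orchestration over :class:`~mutclust.model.ClusteringModel`; the model
and results objects are the primary API, this module adds file handling and
logging for command-line use.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .model import ClusteringModel, ClusteringResults
from .simulation import SimulationConfig

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Everything one run produced: tables, metadata and output paths."""

    elements: pd.DataFrame
    clusters: pd.DataFrame
    metadata: dict
    paths: dict[str, Path]
    results: ClusteringResults


def run(
    config: SimulationConfig,
    mutations_path,
    regions_path,
    genome_path,
    output_dir,
    cores: int = 1,
    profile_path=None,
    columns: Optional[Mapping[str, str]] = None,
    skip_bad_elements: bool = False,
) -> RunReport:
    """Read inputs, fit the clustering model, and write report files.

    Writes ``elements.tsv`` (one row per analyzed element, sorted by q then p
    then score), ``clusters.tsv`` (one row per surviving cluster, element and
    genomic coordinates), ``metadata.json`` (config echo and record
    accounting) and ``run.log`` into ``output_dir``.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    log_path = output_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mutclust")
    root.addHandler(handler)
    try:
        model = ClusteringModel.from_files(
            mutations_path,
            regions_path,
            genome_path,
            config=config,
            profile_path=profile_path,
            columns=columns,
        )
        results = model.fit(cores=cores, skip_bad_elements=skip_bad_elements)
        paths = results.write(output_dir)
        paths["log"] = log_path
        logger.info(
            "analyzed %d elements, %d significant at FDR < %g",
            len(results.element_results),
            int(results.elements["significant"].sum()),
            config.fdr_threshold,
        )
    finally:
        root.removeHandler(handler)
        handler.close()
    return RunReport(
        elements=results.elements,
        clusters=results.clusters,
        metadata=results.metadata(),
        paths=paths,
        results=results,
    )


def write_reports(results: ClusteringResults, output_dir) -> dict[str, Path]:
    """Write a fitted analysis' elements/clusters/metadata files."""
    return results.write(output_dir)
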