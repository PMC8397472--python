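"""Pipeline orchestration and report rendering.

run_pipeline chains the stages — triad validation, KID compliance,
global descriptors, condensed local descriptors, drug-likeness — over
one input set and writes one table per stage.  Stages are pure
transformations of their inputs; a stage whose optional inputs are
absent (e.g. no atomic charges for the local stage) is skipped with a
warning rather than aborting the run.

Numbers are kept at full precision in JSON output and rounded only for
CSV/markdown presentation (4 decimals for energies and descriptors,
3 for the KID deviations).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import __version__
from .druglike import PropertyTable, RadarRanges, lipinski_violations, radar_verdict
from .global_reactivity import TCE_HOMO_DEFAULT, global_descriptors, global_table
from .kid import kid_table
from .local_reactivity import local_table
from .records import MoleculeTriad, frontier_energies, read_triads

logger = logging.getLogger("peptidology")

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full pipeline run depends on."""

    input_path: str | Path | None = None
    properties: tuple[PropertyTable, ...] = ()
    tce_homo: float = TCE_HOMO_DEFAULT
    round_digits: bool = True
    radar_ranges: RadarRanges | None = None
    output_dir: str | Path = "."
    log_level: str = "INFO"
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "input_path": str(self.input_path),
                "tce_homo": self.tce_homo,
                "round_digits": self.round_digits,
                "radar_ranges": self.radar_ranges.ranges if self.radar_ranges else None,
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _druglike_table(
    properties: Iterable[PropertyTable], ranges: RadarRanges | None
) -> pd.DataFrame:
    rows = []
    for p in properties:
        verdict = radar_verdict(p, ranges)
        rows.append(
            {
                "Molecule": p.molecule_id,
                "molar_mass": p.molar_mass,
                "hbd_count": p.hbd_count,
                "hba_count": p.hba_count,
                "tpsa": p.tpsa,
                "fsp3": p.fsp3,
                "rotatable_count": p.rotatable_count,
                "lipinski_violations": ";".join(lipinski_violations(p)) or "none",
                "radar_offending": ";".join(verdict["offending"]) or "none",
                "radar_all_in": verdict["all_in"],
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig, triads: list[MoleculeTriad] | None = None
) -> dict[str, pd.DataFrame]:
    """Run every applicable stage; write one CSV per stage to output_dir.

    Triads may be passed directly (tests, library use) or read from
    ``config.input_path``.  Returns the stage tables keyed by stage
    name ("kid", "global", "local", "druglike").
    """
    logging.basicConfig(level=config.log_level)
    if triads is None:
        if config.input_path is None:
            raise ValueError("no triads given and no input_path configured")
        triads = read_triads(config.input_path)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info(
        "peptidology %s | config %s | %d molecule(s)",
        __version__,
        config.config_hash(),
        len(triads),
    )

    results: dict[str, pd.DataFrame] = {}
    results["kid"] = kid_table(triads, round_digits=config.round_digits)
    results["global"] = global_table(
        triads, tce_homo=config.tce_homo, round_digits=config.round_digits
    )

    with_charges = [t for t in triads if t.has_charges]
    skipped = [t.molecule_id for t in triads if not t.has_charges]
    if skipped:
        logger.warning(
            "local stage skipped for %d molecule(s) without atomic charges: %s",
            len(skipped),
            ", ".join(skipped),
        )
    if with_charges:
        frames = []
        for triad in with_charges:
            eps_H, eps_L = frontier_energies(triad.neutral)
            glob = global_descriptors(eps_H, eps_L, config.tce_homo)
            frame = local_table(triad, glob, round_digits=config.round_digits)
            frame.insert(0, "Molecule", triad.molecule_id)
            frames.append(frame)
        results["local"] = pd.concat(frames, ignore_index=True)

    if config.properties:
        results["druglike"] = _druglike_table(config.properties, config.radar_ranges)

    for stage, frame in results.items():
        path = out_dir / f"{stage}.csv"
        frame.to_csv(path, index=False)
        logger.info("stage %-8s -> %s (%d rows)", stage, path, len(frame))
    return results


def _to_markdown(frame: pd.DataFrame) -> str:
    cols = [str(c) for c in frame.columns]
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in frame.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def render_report(
    results: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    format: str = "csv",
) -> list[Path]:
    """Render stage tables as csv, markdown or json files.

    JSON keeps full float precision (suitable for round-tripping);
    csv/markdown are presentation formats.
    """
    if not results:
        raise ValueError("no results to render")
    if format not in ("csv", "markdown", "json"):
        raise ValueError(f"unknown report format {format!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for stage, frame in results.items():
        if format == "csv":
            path = out_dir / f"{stage}.csv"
            frame.to_csv(path, index=False)
        elif format == "markdown":
            path = out_dir / f"{stage}.md"
            path.write_text(_to_markdown(frame), encoding="utf-8")
        else:
            path = out_dir / f"{stage}.json"
            path.write_text(
                frame.to_json(orient="records", double_precision=15), encoding="utf-8"
            )
        written.append(path)
    return written
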