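"""End-to-end orchestration: screen → align → tree → root → ASR → lid
trajectory (→ habitat stats), with a machine-readable run manifest.

Every stage reads and writes plain files, so any stage can be replaced
by an external tool's output (a real MUSCLE alignment, a converted PAML
posterior table, ...). A rerun with the same config and inputs is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .align import progressive_msa
from .asr import map_records, reconstruct_all
from .io_core import (
    MultipleAlignment,
    ProteinRecord,
    read_alignment,
    read_fasta,
    read_newick,
    write_alignment,
    write_fasta,
    write_newick,
)
from .lid import DEFAULT_HYDROPHOBIC, DEFAULT_THRESHOLDS, lid_columns, lid_trajectory
from .model import build_wag_model
from .phylo import (
    distance_matrix,
    neighbor_joining,
    optimize_branch_lengths,
    root_with_outgroup,
)
from .screen import ScreenConfig, screen_candidates
from .stats import habitat_analysis, read_habitat_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration of a full run; intervals 1-based inclusive here,
    matching every user-facing report."""

    candidates_fasta: str
    reference_fasta: str
    out_dir: str
    reference_id: str | None = None  # default: first record in the file
    lid_start: int = 1   # 1-based inclusive on the reference sequence
    lid_end: int = 1
    aligned_fasta: str | None = None
    tree_newick: str | None = None
    outgroup: str | None = None  # default: most divergent sequence
    min_identity: float = 0.30
    min_lid: int = 20
    frequency_mode: str = "empirical_plus_F"
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    hydrophobic_set: str = "".join(sorted(DEFAULT_HYDROPHOBIC))
    habitat_table: str | None = None
    optimize_branches: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.min_identity <= 1):
            raise ValueError("min_identity must lie in [0, 1]")
        if any(not (0 < t <= 1) for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.lid_end < self.lid_start or self.lid_start < 1:
            raise ValueError("invalid lid interval")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage, writing all intermediates under ``out_dir``.

    Returns the output directory. A failing stage raises
    :class:`PipelineError` naming the stage; artifacts written before
    the failure are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, exc) from exc

        return _Ctx()

    with stage("screen"):
        candidates = read_fasta(config.candidates_fasta)
        ref_records = read_fasta(config.reference_fasta)
        ref_id = config.reference_id or ref_records[0].id
        ref = next((r for r in ref_records if r.id == ref_id), None)
        if ref is None:
            raise ValueError(f"reference {ref_id!r} not found")
        reference = ProteinRecord(
            ref.id, ref.sequence,
            {"lid": (config.lid_start - 1, config.lid_end)},
        )
        report = screen_candidates(
            candidates,
            reference,
            ScreenConfig(
                min_identity=config.min_identity, min_lid=config.min_lid
            ),
        )
        report.to_tsv(out / "screening.tsv")
        report.summary_json(out / "screening_summary.json")
        accepted = [r for r in candidates if r.id in set(report.accepted_ids)]
        if len(accepted) < 3:
            raise ValueError(
                f"only {len(accepted)} candidates accepted; need >= 3"
            )

    with stage("align"):
        if config.aligned_fasta:
            msa = read_alignment(config.aligned_fasta)
        else:
            msa = progressive_msa(accepted + [reference])
        # carry the lid annotation onto the aligned reference row
        for i, rec in enumerate(msa.records):
            if rec.id == reference.id:
                msa.records[i] = ProteinRecord(
                    rec.id, rec.sequence, dict(reference.features)
                )
        write_alignment(msa, out / "alignment.fasta")

    with stage("model"):
        model = build_wag_model(config.frequency_mode, msa)

    with stage("tree"):
        if config.tree_newick:
            tree = read_newick(config.tree_newick)
        else:
            dm = distance_matrix(msa, model)
            tree = neighbor_joining(dm)
        if config.optimize_branches:
            tree, logl = optimize_branch_lengths(tree, msa, model)
        write_newick(tree, out / "tree_unrooted.nwk")

    with stage("root"):
        if config.outgroup:
            outgroup = config.outgroup
        else:
            dm2 = distance_matrix(msa, model)
            import numpy as np

            outgroup = dm2.taxa[int(np.argmax(dm2.D.sum(axis=1)))]
        rooted = root_with_outgroup(tree, outgroup)
        write_newick(rooted, out / "tree_rooted.nwk", internal_labels=True)

    with stage("asr"):
        recs, mats = reconstruct_all(rooted, msa, model)
        asr_dir = out / "asr"
        asr_dir.mkdir(exist_ok=True)
        for label, mat in sorted(mats.items()):
            mat.to_tsv(asr_dir / f"node_{label}_posteriors.tsv")
        write_fasta(map_records(recs), out / "ancestors_map.fasta")

    with stage("lids"):
        cols = lid_columns(msa, reference.id)
        traj = lid_trajectory(
            recs,
            cols,
            thresholds=tuple(config.thresholds),
            hydrophobic_set=frozenset(config.hydrophobic_set),
        )
        traj.to_csv(out / "lid_trajectory.tsv", sep="\t", index=False)

    if config.habitat_table:
        with stage("stats"):
            table = read_habitat_table(config.habitat_table)
            result = habitat_analysis(table, seed=config.seed)
            with open(out / "habitat_stats.json", "w", encoding="utf-8") as fh:
                json.dump(result, fh, indent=2, sort_keys=True)

    with stage("manifest"):
        cfg = dataclasses.asdict(config)
        cfg_json = json.dumps(cfg, sort_keys=True)
        inputs = {}
        for key in ("candidates_fasta", "reference_fasta", "aligned_fasta",
                    "tree_newick", "habitat_table"):
            value = getattr(config, key)
            if value:
                inputs[key] = _sha256(Path(value))
        manifest = {
            "package_version": __version__,
            "config": cfg,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "input_sha256": inputs,
            "seed": config.seed,
            "outgroup": outgroup,
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
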