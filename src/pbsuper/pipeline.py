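"""Pipeline orchestration: read -> encode -> two-pass align -> superpose -> score.

Everything the command-line front end does lives here so that library
users get the identical behaviour. A run is fully described by a
:class:`RunConfig`; the pipeline is deterministic, so the same config and
inputs reproduce byte-identical score output.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .align import (
    AnchorParams,
    align_two_pass,
    alignment_tracks,
    default_matrix,
    load_matrix,
)
from .pb import encode_chain, write_pb_fasta
from .scores import ScorePanel, score_panel
from .structure_io import read_structure, write_superposed
from .superpose import superpose_aligned

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]

logger = logging.getLogger("pbsuper")


class ConfigError(ValueError):
    """A RunConfig field is missing or out of range; the message names it."""


@dataclass
class RunConfig:
    """Serializable description of one superposition run."""

    ref: str
    mobile: str
    ref_chain: Optional[str] = None
    mobile_chain: Optional[str] = None
    model_index: int = 0
    matrix: Optional[str] = None  # path to a substitution table; None = bundled
    gap_open: float = -5.0
    gap_extend: float = -0.5
    anchor_weight: float = 10.0
    anchor_min_len: int = 5
    anchor_score_fraction: float = 0.8
    trim: Optional[float] = None  # Angstrom cutoff for iterative trimming
    out_dir: str = "pbsuper_out"
    seed: int = 0
    verbosity: int = 1

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})


def validate_config(config: RunConfig) -> RunConfig:
    """Range-check and normalize a config; errors name the offending field."""
    if not config.ref:
        raise ConfigError("ref: a reference structure path is required")
    if not config.mobile:
        raise ConfigError("mobile: a mobile structure path is required")
    if config.gap_open > 0:
        raise ConfigError(f"gap_open: must be <= 0, got {config.gap_open}")
    if config.gap_extend > 0:
        raise ConfigError(f"gap_extend: must be <= 0, got {config.gap_extend}")
    if config.anchor_weight < 1:
        raise ConfigError(f"anchor_weight: must be >= 1, got {config.anchor_weight}")
    if config.anchor_min_len < 1:
        raise ConfigError(f"anchor_min_len: must be >= 1, got {config.anchor_min_len}")
    if not 0 < config.anchor_score_fraction <= 1:
        raise ConfigError(
            f"anchor_score_fraction: must be in (0, 1], got {config.anchor_score_fraction}"
        )
    if config.trim is not None and config.trim <= 0:
        raise ConfigError(f"trim: cutoff must be positive, got {config.trim}")
    if config.model_index < 0:
        raise ConfigError(f"model_index: must be >= 0, got {config.model_index}")
    return config


def run_pipeline(config: RunConfig) -> ScorePanel:
    """Execute the full superposition pipeline and write all artifacts.

    Writes into ``config.out_dir``: the superposed mobile structure
    (``superposed.pdb``), paired amino-acid/PB alignment tracks
    (``alignment.fasta``), aligned index pairs (``alignment.tsv``), the
    score panel (``scores.json``), the 4x4 transform (``transform.txt``)
    and a run log (``run.log``).
    """
    config = validate_config(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if config.verbosity > 1 else logging.INFO)
    t0 = time.time()
    try:
        logger.info("pbsuper %s", __version__)
        logger.info("config:\n%s", config.to_yaml().rstrip())

        ref = read_structure(config.ref, config.ref_chain, config.model_index)
        mob = read_structure(config.mobile, config.mobile_chain, config.model_index)
        logger.info("reference %s chain %s: %d residues (%d complete)",
                    ref.source_name, ref.chain_id, len(ref), ref.n_complete)
        logger.info("mobile    %s chain %s: %d residues (%d complete)",
                    mob.source_name, mob.chain_id, len(mob), mob.n_complete)

        matrix = (load_matrix(config.matrix) if config.matrix else default_matrix())
        matrix = matrix.with_gaps(config.gap_open, config.gap_extend)

        pb_ref = encode_chain(ref)
        pb_mob = encode_chain(mob)
        logger.info("PB letters assigned: %d / %d (ref), %d / %d (mobile)",
                    pb_ref.n_assigned, len(pb_ref), pb_mob.n_assigned, len(pb_mob))

        params = AnchorParams(weight=config.anchor_weight,
                              score_fraction=config.anchor_score_fraction,
                              min_length=config.anchor_min_len)
        alignment = align_two_pass(pb_ref, pb_mob, matrix, params)
        logger.info("alignment: %d columns, %d aligned pairs, score %.2f",
                    len(alignment.columns), alignment.n_aligned, alignment.score)

        report = superpose_aligned(ref, mob, alignment, trim_cutoff=config.trim)
        panel = score_panel(ref, mob, pb_ref, pb_mob, alignment, matrix, report)
        logger.info("Ca RMSD %.3f A over %d pairs; GDT_TS %.1f",
                    panel.rmsd_all, panel.n_aligned, panel.gdt_ts)

        write_superposed(mob, report.transform, out_dir / "superposed.pdb")
        report.transform.write(out_dir / "transform.txt")

        aa_ref, aa_mob = alignment_tracks(alignment, ref.sequence(), mob.sequence())
        t_ref, t_mob = alignment_tracks(alignment, pb_ref.letters, pb_mob.letters)
        write_pb_fasta(
            {
                f"{ref.source_name}|{ref.chain_id}|aa": aa_ref,
                f"{ref.source_name}|{ref.chain_id}|pb": t_ref,
                f"{mob.source_name}|{mob.chain_id}|aa": aa_mob,
                f"{mob.source_name}|{mob.chain_id}|pb": t_mob,
            },
            out_dir / "alignment.fasta",
        )
        with open(out_dir / "alignment.tsv", "w") as fh:
            fh.write("ref_index\tmobile_index\tref_resid\tmobile_resid\n")
            for i, j in alignment.columns:
                fh.write(
                    f"{'-' if i is None else i}\t{'-' if j is None else j}\t"
                    f"{'-' if i is None else ref[i].label()}\t"
                    f"{'-' if j is None else mob[j].label()}\n"
                )
        (out_dir / "scores.json").write_text(panel.to_json(indent=2) + "\n")
        logger.info("done in %.2f s", time.time() - t0)
        return panel
    finally:
        logger.removeHandler(handler)
        handler.close()
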