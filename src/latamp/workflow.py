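"""End-to-end pipeline runner: describe -> design -> fragments -> assays.

A :class:`RunConfig` (plain dict / JSON file with explicit keys) selects
stages and conventions; :func:`run_pipeline` executes the enabled stages,
writes every artifact under the output directory, and returns a manifest
recording the seed, every convention in force, and a SHA-256 checksum per
artifact so published numbers are traceable to their settings.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .assays import call_mic, read_plate_csv
from .descriptors import ALPHA_HELIX_DELTA, SIDE_CHAINS, describe
from .design import DesignConstraints, enumerate_analogs, extract_region
from .fragments import by_series, peptide_mass, write_fragment_table
from .peptides import read_fasta, write_descriptor_table
from .scales import SCALES


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage name."""


@dataclass
class RunConfig:
    fasta: str | None = None
    out_dir: str = "latamp_out"
    seed: int = 0
    scale: str = "fauchere-pliska"
    charge_model: str = SIDE_CHAINS
    delta: float = ALPHA_HELIX_DELTA
    inhibition_threshold: float = 0.10
    stages: tuple[str, ...] = ("describe", "design", "fragments")
    design_parent: str | None = None       # name of the parent record
    design_region: tuple[int, int] | None = None
    design_limit: int = 50
    mic_plates: tuple[str, ...] = field(default_factory=tuple)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cfg = cls(**raw)
        if cfg.design_region is not None:
            cfg.design_region = tuple(cfg.design_region)
        cfg.stages = tuple(cfg.stages)
        cfg.mic_plates = tuple(cfg.mic_plates)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages; return (and write) the manifest.

    Deterministic for a given config and seed. A stage failure aborts the
    run with a :class:`StageError` naming the stage.
    """
    t0 = time.monotonic()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.fasta is None:
        raise StageError("config: no input FASTA given")
    if not Path(config.fasta).exists():
        raise StageError(f"config: input FASTA {config.fasta!r} does not exist")
    for plate in config.mic_plates:
        if not Path(plate).exists():
            raise StageError(f"config: plate file {plate!r} does not exist")

    scale = SCALES[config.scale]
    peptides = read_fasta(config.fasta)
    by_name = {p.name: p for p in peptides}
    artifacts: list[Path] = []
    stage_results: dict[str, object] = {}

    if "describe" in config.stages:
        try:
            rows = []
            for p in peptides:
                d = describe(p, scale=scale, charge_model=config.charge_model,
                             delta=config.delta)
                m = peptide_mass(p)
                rows.append({
                    "name": p.name, "sequence": p.residues, "length": len(p),
                    "Z": d.Z, "H": d.H, "H_pct": d.H_pct, "muH": d.muH,
                    "M_avg": round(m.M_avg, 2), "M_mono": round(m.M_mono, 3),
                    "MH_plus": round(m.MH_plus, 3),
                })
            path = out_dir / "descriptors.tsv"
            with open(path, "w") as fh:
                write_descriptor_table(rows, fh)
            artifacts.append(path)
            stage_results["describe"] = {"n_peptides": len(rows)}
        except Exception as exc:
            raise StageError(f"describe: {exc}") from exc

    if "design" in config.stages:
        try:
            parent_name = config.design_parent or peptides[0].name
            parent = by_name[parent_name]
            if config.design_region is not None:
                region = extract_region(parent, *config.design_region)
            else:
                region = parent
            candidates = enumerate_analogs(
                region, DesignConstraints(), limit=config.design_limit,
                seed=config.seed, scale=scale,
            )
            path = out_dir / "candidates.tsv"
            with open(path, "w") as fh:
                fh.write("rank\tsequence\tZ\tmuH\tH\tdivergence\tn_subs\tscore\n")
                for rank, c in enumerate(candidates, start=1):
                    d = c.descriptors
                    fh.write(
                        f"{rank}\t{c.sequence.residues}\t{d.Z}\t{d.muH}\t{d.H}\t"
                        f"{c.composition_divergence:.4f}\t{c.n_substitutions}\t"
                        f"{c.score:.4f}\n"
                    )
            artifacts.append(path)
            stage_results["design"] = {
                "parent": region.name, "n_returned": len(candidates),
            }
        except Exception as exc:
            raise StageError(f"design: {exc}") from exc

    if "fragments" in config.stages:
        try:
            for p in peptides:
                series = by_series(p)
                path = out_dir / f"fragments_{p.name}.tsv"
                with open(path, "w") as fh:
                    write_fragment_table(series, fh)
                artifacts.append(path)
            stage_results["fragments"] = {"n_peptides": len(peptides)}
        except Exception as exc:
            raise StageError(f"fragments: {exc}") from exc

    if "assays" in config.stages and config.mic_plates:
        try:
            path = out_dir / "mic_calls.tsv"
            with open(path, "w") as fh:
                fh.write("plate\tMIC\n")
                for plate_path in config.mic_plates:
                    with open(plate_path) as ph:
                        plate = read_plate_csv(ph)
                    endpoint = call_mic(plate, config.inhibition_threshold)
                    fh.write(f"{Path(plate_path).name}\t{endpoint}\n")
            artifacts.append(path)
            stage_results["assays"] = {"n_plates": len(config.mic_plates)}
        except Exception as exc:
            raise StageError(f"assays: {exc}") from exc

    config_dict = asdict(config)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True, default=list).encode()
        ).hexdigest(),
        "stages": stage_results,
        "wall_time_s": round(time.monotonic() - t0, 3),
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    return manifest
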