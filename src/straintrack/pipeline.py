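"""End-to-end pipeline runner driven by a YAML/dict configuration.

Stages run in dependency order — simulate (optional) -> index -> quantify ->
presence -> engraftment, and/or design -> phenotype screen — each writing its
outputs before the next starts, so a failure leaves earlier results intact
with a stage-labelled error. Config is validated up front; schema violations
raise before any compute.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from . import association, design as design_mod, engraftment, io, quant, reference, synth
from .errors import ConfigError, StrainTrackError
from .manifest import RunManifest

__all__ = ["run_pipeline", "load_config"]


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def _validate(cfg: dict) -> None:
    if "outdir" not in cfg:
        raise ConfigError("config needs 'outdir'")
    if "genomes" not in cfg and "simulate" not in cfg:
        raise ConfigError("config needs 'genomes' (FASTA path) or a 'simulate' section")
    if "genomes" in cfg and not Path(cfg["genomes"]).exists():
        raise ConfigError(f"genome FASTA not found: {cfg['genomes']}")
    for sample in cfg.get("samples", []):
        if "simulate" not in cfg and not Path(sample["reads"]).exists():
            raise ConfigError(f"reads file not found: {sample['reads']}")


class StageError(StrainTrackError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def run_pipeline(cfg: dict) -> dict:
    """Run the configured stages; returns a dict of in-memory results.

    See the README for the config schema. Every output directory gets a
    ``manifest.json`` capturing parameters, seeds and input checksums.
    """
    _validate(cfg)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    k = int(cfg.get("k", 31))
    manifest = RunManifest("run", {"seed": seed, "k": k, **{kk: vv for kk, vv in cfg.items()
                                                            if kk not in ("samples",)}})
    results: dict = {}

    stage = "simulate"
    try:
        if "simulate" in cfg:
            sim = cfg["simulate"]
            genomes = synth.simulate_genomes(
                sim.get("n_strains", 4), sim.get("genome_length", 50_000),
                sim.get("shared_fraction", 0.1), sim.get("n_shared_blocks", 2), seed)
            fasta = outdir / "genomes.fasta"
            reference.write_genomes_fasta(genomes, fasta)
            manifest.add_output(fasta)
            samples = []
            comp = sim.get("composition")
            if comp is None:
                comp = {g.strain_id: 1.0 / len(genomes) for g in genomes}
            reads, truth = synth.simulate_reads(genomes, comp, sim.get("n_reads", 20_000),
                                                sim.get("read_length", 150),
                                                sim.get("error_rate", 0.0), seed + 1)
            fq = outdir / "sample1.fastq"
            quant.write_fastq(reads, fq)
            io.write_tsv(pd.DataFrame({"strain_id": list(truth.composition),
                                       "true_abundance": list(truth.composition.values())}),
                         outdir / "sample1.truth.tsv")
            samples.append({"sample_id": "sample1", "reads": str(fq)})
            cfg = {**cfg, "samples": samples}
            results["truth"] = truth
        else:
            genomes = reference.read_genomes_fasta(cfg["genomes"])
            for s in cfg.get("samples", []):
                manifest.add_input(s["reads"])
    except ConfigError:
        raise
    except Exception as e:  # noqa: BLE001 - stage isolation is the contract
        raise StageError(stage, e) from e

    stage = "index"
    try:
        index = reference.build_unique_index(genomes, k)
        reference.export_unique_regions(index, genomes, outdir / "unique_regions.bed",
                                        outdir / "masked.fasta", outdir / "index_manifest.json")
        for f in ("unique_regions.bed", "masked.fasta", "index_manifest.json"):
            manifest.add_output(outdir / f)
        results["index"] = index
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "quantify"
    try:
        if cfg.get("samples"):
            tables = []
            for s in cfg["samples"]:
                reads = quant.read_fastq(s["reads"])
                tables.append(quant.quantify_sample(
                    reads, index, sample_id=s["sample_id"],
                    subsample_n=int(cfg.get("subsample_n", quant.DEFAULT_SUBSAMPLE)),
                    seed=seed, mode=cfg.get("scaling_mode", "informative")))
            table = quant.combine_tables(tables)
            io.write_tsv(table.abundance.rename_axis("sample_id").reset_index(),
                         outdir / "abundance_wide.tsv")
            io.write_tsv(table.to_long(), outdir / "abundance_long.tsv")
            presence = quant.call_presence(table,
                                           float(cfg.get("min_relative", quant.DEFAULT_MIN_RELATIVE)),
                                           int(cfg.get("min_reads", quant.DEFAULT_MIN_READS)))
            io.write_tsv(presence.astype(int).rename_axis("sample_id").reset_index(),
                         outdir / "presence.tsv")
            for f in ("abundance_wide.tsv", "abundance_long.tsv", "presence.tsv"):
                manifest.add_output(outdir / f)
            results["abundance"] = table
            results["presence"] = presence
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "engraftment"
    try:
        if "engraftment" in cfg:
            ecfg = cfg["engraftment"]
            presence = io.read_presence(ecfg["presence"])
            metadata = io.read_tsv(ecfg["metadata"]).set_index("mouse_id")
            consortia, _ = io.parse_membership(ecfg["membership"])
            per_mouse = engraftment.cohort_metrics(presence, metadata, consortia,
                                                   ecfg.get("shared_policy", "exclude"))
            io.write_tsv(per_mouse.reset_index(), outdir / "engraftment_per_mouse.tsv")
            manifest.add_output(outdir / "engraftment_per_mouse.tsv")
            results["engraftment"] = per_mouse
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "screen"
    try:
        if "screen" in cfg:
            scfg = cfg["screen"]
            dm = design_mod.generate_design(scfg["S"], scfg["c"], scfg["r"], seed)
            io.write_tsv(dm.to_long(), outdir / "design_long.tsv")
            manifest.add_output(outdir / "design_long.tsv")
            results["design"] = dm
            if "phenotypes" in scfg:
                pheno = io.read_tsv(scfg["phenotypes"])
                screen = association.strain_screen(dm, pheno)
                io.write_tsv(screen.reset_index(), outdir / "screen_results.tsv")
                manifest.add_output(outdir / "screen_results.tsv")
                results["screen"] = screen
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    manifest.write(outdir / "manifest.json")
    return results
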