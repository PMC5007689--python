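"""End-to-end orchestration of the synthetic analysis from one config.

``validate_config`` normalizes a YAML/dict configuration against the full
default tree (unknown keys rejected, every error collected, defaults
filled); ``run_pipeline`` executes the enabled stages in dependency order —
simulate, tile, array occupancy, sequencing validation, element profiles,
motif discovery, expression — writing stage artifacts and a JSON report
with parameter echoes, class tallies, validated fractions, the learned
consensus and the expression summary.  Every random draw derives from the
single configured seed.
"""
from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import catalog, chipchip, chipseq, expression, motifs, simulate

__all__ = ["ConfigError", "PipelineConfig", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


ANALYSIS_DEFAULTS: dict = {
    "seed": 1,
    "stages": {
        "simulate": True,
        "chipchip": True,
        "chipseq": True,
        "motif": True,
        "expression": True,
    },
    "chipchip": {
        "span": 0.3,
        "robust_iters": 3,
        "pseudocount": 0.5,
        "fold_both": 4.0,
        "fold_none": 1.0,
        "z_cut": 5.0,
        "sam_permutations": 200,
    },
    "chipseq": {
        "replicates": 2,
        "chip_reads": 100000,
        "input_reads": 80000,
        "min_identity": 0.95,
        "min_fold": 2.0,
        "bin_width": 50,
        "profile_bins": 25,
        "kmeans_k": 4,
    },
    "motif": {
        "width_short": 20,
        "width_long": 40,
        "n_starts": 5,
    },
    "expression": {
        "count_cut": 10.0,
        "fold_cut": 2.0,
        "pseudocount": 1.0,
        "concordance_pair": ["boris_kd", "dznep"],
    },
}

_POSITIVE_KEYS = {
    "fold_both",
    "fold_none",
    "z_cut",
    "span",
    "sam_permutations",
    "replicates",
    "chip_reads",
    "input_reads",
    "min_fold",
    "bin_width",
    "profile_bins",
    "kmeans_k",
    "width_short",
    "width_long",
    "n_starts",
    "count_cut",
    "fold_cut",
}


def _sim_defaults() -> dict:
    return dataclasses.asdict(simulate.SimConfig())


def _merge(defaults: Any, override: Any, path: str, errors: list) -> Any:
    if isinstance(defaults, dict):
        if not isinstance(override, dict):
            errors.append(f"{path or 'config'}: expected a mapping")
            return defaults
        out = {}
        for key, dval in defaults.items():
            if key in override:
                out[key] = _merge(dval, override[key], f"{path}.{key}".lstrip("."), errors)
            else:
                out[key] = dval
        for key in override:
            if key not in defaults:
                errors.append(f"{path}.{key}".lstrip(".") + ": unknown key")
        return out
    if isinstance(defaults, bool):
        if not isinstance(override, bool):
            errors.append(f"{path}: expected a boolean")
            return defaults
        return override
    if isinstance(defaults, (int, float)):
        if isinstance(override, bool) or not isinstance(override, (int, float)):
            errors.append(f"{path}: expected a number")
            return defaults
        key = path.rsplit(".", 1)[-1]
        if key in _POSITIVE_KEYS and override <= 0:
            errors.append(f"{path}: must be > 0")
            return defaults
        return type(defaults)(override) if not isinstance(defaults, float) else float(override)
    if isinstance(defaults, str):
        if not isinstance(override, str):
            errors.append(f"{path}: expected a string")
            return defaults
        return override
    if isinstance(defaults, (list, tuple)):
        if not isinstance(override, (list, tuple)):
            errors.append(f"{path}: expected a list")
            return defaults
        return list(override)
    return override


def _listify(node: Any) -> Any:
    """Canonical YAML-friendly form: tuples become lists throughout."""
    if isinstance(node, dict):
        return {k: _listify(v) for k, v in node.items()}
    if isinstance(node, (list, tuple)):
        return [_listify(v) for v in node]
    return node


def _simconfig_from_dict(data: dict) -> simulate.SimConfig:
    nested = {
        "repeats": simulate.RepeatMix,
        "sva": simulate.SvaConfig,
        "alphoid": simulate.AlphoidConfig,
        "occupancy": simulate.OccupancyLevels,
        "array": simulate.ArrayConfig,
        "reads": simulate.ReadConfig,
    }
    kwargs: dict = {}
    for f in dataclasses.fields(simulate.SimConfig):
        val = data[f.name]
        if f.name in nested:
            sub = {k: (tuple(v) if isinstance(v, list) else v) for k, v in val.items()}
            kwargs[f.name] = nested[f.name](**sub)
        elif f.name == "rnaseq":
            rv = dict(val)
            rv["conditions"] = tuple(
                simulate.RnaSeqCondition(**c) if isinstance(c, dict) else c
                for c in rv["conditions"]
            )
            for key in ("silent_base_range", "expressed_base_range", "latent_group"):
                rv[key] = tuple(rv[key])
            kwargs[f.name] = simulate.RnaSeqConfig(**rv)
        else:
            kwargs[f.name] = val
    return simulate.SimConfig(**kwargs)


@dataclass
class PipelineConfig:
    seed: int
    stages: dict
    simulate: simulate.SimConfig
    chipchip: dict
    chipseq: dict
    motif: dict
    expression: dict
    raw: dict = field(repr=False, default_factory=dict)


def validate_config(source: str | Path | Mapping | None = None) -> PipelineConfig:
    """Normalize a config file or mapping; raise ConfigError listing every problem."""
    if source is None:
        data: dict = {}
    elif isinstance(source, Mapping):
        data = dict(source)
    else:
        text = Path(source).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(["top level must be a mapping"])
    errors: list = []
    defaults = dict(ANALYSIS_DEFAULTS)
    defaults["simulate"] = _sim_defaults()
    merged = _listify(_merge(defaults, data, "", errors))
    merged["simulate"]["seed"] = merged["seed"]
    if errors:
        raise ConfigError(errors)
    sim = _simconfig_from_dict(merged["simulate"])
    try:
        sim.validate()
    except simulate.SimulationError as exc:
        raise ConfigError([str(exc)]) from exc
    return PipelineConfig(
        seed=merged["seed"],
        stages=merged["stages"],
        simulate=sim,
        chipchip=merged["chipchip"],
        chipseq=merged["chipseq"],
        motif=merged["motif"],
        expression=merged["expression"],
        raw=merged,
    )


# ---------------------------------------------------------------------------
# execution


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 1000 + stage]))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute enabled stages in dependency order; return the JSON report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "parameters": config.raw}
    t0 = time.time()

    genome = None
    tiles = None
    calls = None
    stage = "simulate"
    try:
        if config.stages["simulate"]:
            genome = simulate.generate_repeat_genome(config.simulate)
            tiles = simulate.build_tiles(genome)
            catalog.write_fasta({simulate.CHROM: genome.sequence}, outdir / "genome.fasta")
            with open(outdir / "repeats.tsv", "w") as fh:
                catalog.write_repeat_catalogue(genome.repeats, fh)
            genome.repeat_bed().to_csv(outdir / "repeats.bed", sep="\t", header=False, index=False)
            genome.element_bed().to_csv(outdir / "elements.bed", sep="\t", header=False, index=False)
            genome.truth.to_json(outdir / "truth.json")
            catalog.tile_map_frame(tiles).to_csv(outdir / "tiles.tsv", sep="\t", index=False)
            report["stages"]["simulate"] = {
                "genome_length": genome.length,
                "n_repeats": len(genome.repeats),
                "n_elements": len(genome.elements),
                "n_tiles": len(tiles),
            }

        stage = "chipchip"
        if config.stages["chipchip"]:
            if genome is None:
                raise RuntimeError("chipchip stage requires the simulate stage")
            cc = config.chipchip
            raw = simulate.simulate_array(genome, tiles, rng=_stage_rng(config.seed, 2))
            raw.to_csv(outdir / "intensities.tsv", sep="\t", index=False)
            mtable = chipchip.build_mtable(
                raw,
                span=cc["span"],
                robust_iters=cc["robust_iters"],
                pseudocount=cc["pseudocount"],
            )
            m_wide = chipchip.m_matrix(mtable)
            pca = chipchip.pca_classify(m_wide)
            pca.z.to_csv(outdir / "zscores.tsv", sep="\t")
            tmap = catalog.tile_map_frame(tiles)
            calls = chipchip.call_occupancy(
                mtable,
                pca,
                tmap,
                fold_both=cc["fold_both"],
                fold_none=cc["fold_none"],
                z_cut=cc["z_cut"],
            )
            pa = sorted({c[0] for c in m_wide.columns})[0]
            ga = m_wide[[c for c in m_wide.columns if c[0] == pa]].to_numpy()
            gb = m_wide[[c for c in m_wide.columns if c[0] != pa]].to_numpy()
            sam = chipchip.sam_differential(
                ga, gb, n_permutations=cc["sam_permutations"], rng=_stage_rng(config.seed, 3)
            )
            chipchip.calls_frame(calls).to_csv(outdir / "calls.tsv", sep="\t", index=False)
            tally = pd.Series([c.occupancy_class for c in calls]).value_counts().to_dict()
            report["stages"]["chipchip"] = {
                "class_tally": tally,
                "pc_variance_fractions": [round(float(v), 4) for v in pca.variance_fractions],
                "sam_s0": float(sam.s0),
            }

        stage = "chipseq"
        if config.stages["chipseq"]:
            if calls is None:
                raise RuntimeError("chipseq stage requires the chipchip stage")
            cs = config.chipseq
            rng = _stage_rng(config.seed, 4)
            tracks = {"A": genome.truth.affinity_a, "B": genome.truth.affinity_b}
            sub, _ = catalog.build_subgenome([r.subgenome_entry() for r in genome.repeats])
            index = chipseq.SubgenomeIndex(sub)
            enrich: dict = {"A": [], "B": []}
            rl = config.simulate.reads.read_length
            b_hits_genome = None
            input_hits_genome = None
            genome_refs = {simulate.CHROM: genome.sequence}
            genome_index = chipseq.SubgenomeIndex(genome_refs)
            for protein in ("A", "B"):
                for rep in range(1, cs["replicates"] + 1):
                    chip_reads = simulate.simulate_reads(
                        genome.sequence, tracks[protein], cs["chip_reads"], "chip",
                        config.simulate.reads, rng, prefix=f"{protein}{rep}",
                    )
                    input_reads = simulate.simulate_reads(
                        genome.sequence, None, cs["input_reads"], "input",
                        config.simulate.reads, rng, prefix=f"{protein}{rep}i",
                    )
                    hits_c = chipseq.align_reads(chip_reads, index, min_identity=cs["min_identity"])
                    hits_i = chipseq.align_reads(input_reads, index, min_identity=cs["min_identity"])
                    enrich[protein].append(
                        chipseq.quantify_tiles(hits_c, hits_i, tiles, read_length=rl)
                    )
                    if protein == "B" and rep == 1:
                        b_hits_genome = chipseq.align_reads(
                            chip_reads, genome_index, min_identity=cs["min_identity"]
                        )
                        input_hits_genome = chipseq.align_reads(
                            input_reads, genome_index, min_identity=cs["min_identity"]
                        )
            calls = chipseq.validate_calls(calls, enrich, min_fold=cs["min_fold"])
            chipchip.calls_frame(calls).to_csv(outdir / "calls.tsv", sep="\t", index=False)
            positive = [c for c in calls if c.occupancy_class != "UNCLASSIFIED"]
            n_validated = sum(1 for c in positive if c.validated)
            elements = [(simulate.CHROM, e.start, e.end) for e in genome.elements]
            profile = chipseq.metaprofile(
                b_hits_genome, elements, bin_width=cs["bin_width"], read_length=rl,
                total_mapped=cs["chip_reads"],
            )
            profile.to_csv(outdir / "sva_profile_B.tsv", sep="\t", index=False)
            mat, _ids = chipseq.profile_matrix(
                b_hits_genome, elements, n_bins=cs["profile_bins"], read_length=rl,
                total_mapped=cs["chip_reads"],
            )
            chip_c = np.array(
                [
                    ((b_hits_genome["pos"] + rl // 2 >= s) & (b_hits_genome["pos"] + rl // 2 < e)).sum()
                    for _, s, e in elements
                ]
            )
            inp_c = np.array(
                [
                    ((input_hits_genome["pos"] + rl // 2 >= s) & (input_hits_genome["pos"] + rl // 2 < e)).sum()
                    for _, s, e in elements
                ]
            )
            enr = (chip_c / cs["chip_reads"] + 1e-9) / (inp_c / cs["input_reads"] + 1e-9)
            frac, _labels, _summary = chipseq.occupancy_fraction(
                mat, enr, k=cs["kmeans_k"], seed=config.seed
            )
            report["stages"]["chipseq"] = {
                "n_positive_calls": len(positive),
                "n_validated": n_validated,
                "validated_fraction": round(n_validated / max(len(positive), 1), 4),
                "sva_occupied_fraction": round(frac, 4),
            }

        stage = "motif"
        if config.stages["motif"]:
            if calls is None:
                raise RuntimeError("motif stage requires occupancy calls")
            mo = config.motif
            by_id = genome.repeats_by_id()
            co_seqs = [
                by_id[c.repeat_id].full_sequence
                for c in calls
                if c.occupancy_class == "CO_BOUND" and c.repeat_id in by_id
            ]
            if len(co_seqs) >= 2:
                pwm_short = motifs.learn_pwm_oops(co_seqs, mo["width_short"], n_starts=mo["n_starts"])
                pwm_long = motifs.learn_pwm_oops(co_seqs, mo["width_long"], n_starts=mo["n_starts"])
                stag = motifs.detect_staggered_duplication(pwm_short, pwm_long)
                (outdir / "motif_short.meme").write_text(motifs.pwm_to_meme(pwm_short, "short"))
                (outdir / "motif_long.meme").write_text(motifs.pwm_to_meme(pwm_long, "long"))
                report["stages"]["motif"] = {
                    "consensus": pwm_short.consensus,
                    "staggered": stag.is_duplicated,
                    "offsets": list(stag.offsets) if stag.offsets else None,
                    "unit_estimate": stag.unit_estimate,
                }
            else:
                report["stages"]["motif"] = {"skipped": "fewer than 2 co-bound repeats"}

        stage = "expression"
        if config.stages["expression"]:
            ex = config.expression
            sim = simulate.simulate_rnaseq_counts(
                config.simulate.rnaseq, rng=_stage_rng(config.seed, 6)
            )
            totals = dict(zip(sim.libraries["library"], sim.libraries["total_reads"]))
            cond_map = dict(zip(sim.libraries["library"], sim.libraries["condition"]))
            reference = sim.libraries.loc[sim.libraries["is_reference"], "condition"].iloc[0]
            norm = expression.normalize_counts(
                sim.counts, totals, denominator=config.simulate.rnaseq.denominator
            )
            folds = expression.fold_changes(
                norm, cond_map, reference, pseudocount=ex["pseudocount"]
            )
            folds.to_csv(outdir / "element_folds.tsv", sep="\t")
            silent = expression.silent_set(folds, count_cut=ex["count_cut"], fold_cut=ex["fold_cut"])
            baseline_silent = folds.index[folds["ref_mean"] < ex["count_cut"]]
            summary = expression.activation_summary(norm, cond_map, reference, subset=baseline_silent)
            tests = {}
            for cond in summary.index:
                res = expression.paired_activation_test(norm, cond_map, cond, reference)
                tests[cond] = {"t": round(res.t, 3), "p": res.p, "degenerate": res.degenerate}
            pair = ex["concordance_pair"]
            subfam = sim.truth.set_index("element_id")["subfamily"]
            conc = expression.concordance_analysis(
                folds, pair[0], pair[1], subfam, fold_cut=ex["fold_cut"],
                silent=baseline_silent,
            )
            report["stages"]["expression"] = {
                "n_elements": int(len(sim.counts)),
                "n_silent": int(len(silent)),
                "mean_folds": {c: round(float(v), 4) for c, v in summary["mean_fold"].items()},
                "sem": {c: round(float(v), 4) for c, v in summary["sem"].items()},
                "paired_tests": tests,
                "concordance_r": round(conc.r, 4),
                "n_co_activated": int(len(conc.co_activated)),
                "breakdown_full": {k: round(float(v), 4) for k, v in conc.breakdown_full.items()},
                "breakdown_co_activated": {k: round(float(v), 4) for k, v in conc.breakdown_co.items()},
            }
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=str)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    for name, enabled in config.stages.items():
        if not enabled:
            report["stages"][name] = {"skipped": True}
    report["elapsed_seconds"] = round(time.time() - t0, 2)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
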