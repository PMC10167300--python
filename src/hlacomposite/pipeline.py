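"""End-to-end orchestration: simulate -> concordance -> DRB copy-number
filtering -> composite genotyping -> ASE summaries, with a run manifest.

Each stage writes its tables into the output directory; a failure aborts
with the stage named. All randomness derives from the single config
seed, so a rerun with the same config reproduces identical outputs and
an identical manifest hash.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as hio
from .callset import GenotypeCallset
from .composite import (
    assemble_composite,
    build_selector_instances,
    composite_name,
    train_selector,
    DEFAULT_PRIORITY,
)
from .concordance import summarize_concordance
from .drb_copynumber import (
    CopyNumberVector,
    compute_ratio_features,
    evaluate_holdout,
    filter_genotype_by_copy_number,
    predict_copy_numbers,
    train_copy_number_model,
)
from .ase import summarize_groups
from .entropy import profile_alignment
from .hla_model import DRB_PARALOGS
from .synthetic import SimulationConfig, simulate_study

logger = logging.getLogger("hlacomposite")

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Knobs for one pipeline run over a simulated study."""

    seed: int
    outdir: str
    field_levels: list[int] = field(default_factory=lambda: [1, 2, 3])
    roster: tuple[str, ...] | None = None  # None = all simulated genotypers
    priority: tuple[str, ...] = DEFAULT_PRIORITY
    train_fraction: float = 0.70
    cv_folds: int = 10
    entropy_window: int = 100
    ase_convention: str = "group"
    simulation: SimulationConfig | None = None  # defaults to seed-only config

    def as_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "field_levels": list(self.field_levels),
            "roster": list(self.roster) if self.roster else None,
            "priority": list(self.priority),
            "train_fraction": self.train_fraction,
            "cv_folds": self.cv_folds,
            "entropy_window": self.entropy_window,
            "ase_convention": self.ase_convention,
        }
        if self.simulation is not None:
            sim = {
                k: v
                for k, v in vars(self.simulation).items()
                if not k.startswith("_") and k != "genotypers"
            }
            sim["genotypers"] = [vars(g) for g in self.simulation.genotypers]
            d["simulation"] = sim
        return d


def _apply_cn_filter(
    calls: GenotypeCallset, predictions: pd.DataFrame
) -> GenotypeCallset:
    """Copy-number filter every genotyper's ranked DRB345 calls."""
    out = GenotypeCallset(calls=dict(calls.calls))
    for sample_id in calls.samples:
        if sample_id not in predictions.index:
            continue
        cn = CopyNumberVector(
            *predictions.loc[sample_id, ["drb3", "drb4", "drb5"]].astype(int)
        )
        for genotyper in calls.genotypers:
            drb_calls = {
                p: calls.get(sample_id, genotyper, p)
                for p in DRB_PARALOGS
                if (sample_id, genotyper, p) in calls.calls
            }
            if not drb_calls:
                continue
            filtered = filter_genotype_by_copy_number(drb_calls, cn)
            for p, gt in filtered.items():
                if p in drb_calls:
                    out.set(sample_id, genotyper, p, gt)
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage on a simulated study; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages_done: list[str] = []
    sim = config.simulation or SimulationConfig(seed=config.seed)

    def _stage(name: str):
        logger.info("stage: %s", name)
        stages_done.append(name)

    try:
        _stage("simulate")
        study = simulate_study(sim)
        hio.write_genotype_table(study["truth"], outdir / "truth.tsv")
        hio.write_genotype_table(study["calls"], outdir / "calls.tsv")
        study["copy_numbers"].reset_index().to_csv(
            outdir / "copy_numbers_truth.tsv", sep="\t", index=False, lineterminator="\n"
        )
        hio.write_read_counts(study["read_counts"], outdir / "read_counts.tsv")
        hio.write_cell_counts(study["cell_counts"], outdir / "cell_counts.tsv")
        hio.write_alignment_fasta(study["alignment"], outdir / "msa.fasta")
    except Exception as exc:
        raise StageError(f"simulate: {exc}") from exc

    try:
        _stage("entropy")
        profile = profile_alignment(
            [seq for _, seq in study["alignment"]], window=config.entropy_window
        )
        profile.to_frame().to_csv(
            outdir / "entropy.tsv", sep="\t", index=False, lineterminator="\n"
        )
    except Exception as exc:
        raise StageError(f"entropy: {exc}") from exc

    try:
        _stage("concordance")
        summary = summarize_concordance(
            study["calls"], study["truth"], config.field_levels
        )
        summary.to_csv(
            outdir / "concordance_unfiltered.tsv", sep="\t", index=False,
            lineterminator="\n",
        )
    except Exception as exc:
        raise StageError(f"concordance: {exc}") from exc

    try:
        _stage("drb_copy_number")
        features = compute_ratio_features(study["read_counts"])
        model = train_copy_number_model(
            features,
            study["copy_numbers"],
            train_fraction=config.train_fraction,
            cv_folds=config.cv_folds,
            seed=config.seed,
        )
        predictions, _scores = predict_copy_numbers(model, features)
        predictions.reset_index().to_csv(
            outdir / "copy_numbers_predicted.tsv", sep="\t", index=False,
            lineterminator="\n",
        )
        cn_eval = evaluate_holdout(model, features, study["copy_numbers"])
        filtered_calls = _apply_cn_filter(study["calls"], predictions)
        summary_filtered = summarize_concordance(
            filtered_calls, study["truth"], config.field_levels
        )
        summary_filtered.to_csv(
            outdir / "concordance_filtered.tsv", sep="\t", index=False,
            lineterminator="\n",
        )
    except Exception as exc:
        raise StageError(f"drb_copy_number: {exc}") from exc

    try:
        _stage("composite")
        roster = config.roster or filtered_calls.genotypers
        instances = build_selector_instances(
            filtered_calls,
            study["truth"],
            config.field_levels,
            roster=roster,
            priority=config.priority,
        )
        selector = train_selector(
            instances,
            train_fraction=config.train_fraction,
            cv_folds=config.cv_folds,
            seed=config.seed,
            priority=config.priority,
        )
        composites = assemble_composite(
            filtered_calls, selector, config.field_levels
        )
        merged = GenotypeCallset()
        for level, cs in composites.items():
            for (s, _, locus), gt in cs.items():
                merged.set(s, f"{composite_name(selector.roster)}@f{level}", locus, gt)
        hio.write_genotype_table(merged, outdir / "composite.tsv")
        summary_rows = []
        for level, cs in composites.items():
            summ = summarize_concordance(cs, study["truth"], [level])
            summary_rows.append(summ)
        pd.concat(summary_rows, ignore_index=True).to_csv(
            outdir / "concordance_composite.tsv", sep="\t", index=False,
            lineterminator="\n",
        )
    except Exception as exc:
        raise StageError(f"composite: {exc}") from exc

    try:
        _stage("ase")
        ase = summarize_groups(
            study["cell_counts"], convention=config.ase_convention
        )
        ase.to_csv(outdir / "ase_summary.tsv", sep="\t", index=False,
                   lineterminator="\n")
    except Exception as exc:
        raise StageError(f"ase: {exc}") from exc

    cfg = config.as_dict()
    cfg["drb_cn_holdout"] = cn_eval
    hio.write_manifest(outdir, cfg, stages_done, config.seed)
    return outdir
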