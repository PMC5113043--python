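"""End-to-end pipeline wiring: simulate -> blup -> diversity -> ld ->
associate -> stats, with a machine-readable run manifest.

Each stage reads the on-disk artifacts of its predecessors, so any
single stage can be re-run in isolation from its inputs.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import association as assoc
from . import blup as blup_mod
from . import diversity as div
from . import ld as ld_mod
from . import trait_stats
from .io import (
    MarkerDataset,
    TrialData,
    read_dataset,
    read_trial,
    write_dataset,
    write_mta_report,
    write_trial,
)
from .simulate import SimConfig, generate_collection, generate_trial

log = logging.getLogger("durmap")

ALL_STAGES = ("simulate", "blup", "diversity", "ld", "associate", "stats")


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int
    stages: tuple[str, ...] = ALL_STAGES
    sim: SimConfig | None = None
    # input paths, used when the simulate stage is disabled
    genotypes: str | None = None
    map: str | None = None
    q: str | None = None
    subspecies: str | None = None
    trial: str | None = None
    scan_alpha: float = assoc.SCAN_ALPHA
    chisq_alpha: float = assoc.CHISQ_ALPHA
    reg_alpha: float = assoc.REG_ALPHA
    max_missing: float = assoc.MAX_MISSING
    n_perm: int = 1000
    loess_span: float = 0.5
    grid_step: float = 0.1
    with_permutations: bool = True

    def __post_init__(self) -> None:
        for name in ("scan_alpha", "chisq_alpha", "reg_alpha", "max_missing"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.sim is None and "simulate" in self.stages:
            self.sim = SimConfig(seed=self.seed)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr,
                        format="[%(name)s] %(message)s", level=logging.INFO)
    manifest: dict = {
        "package": "durmap",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "scan_alpha": config.scan_alpha,
            "chisq_alpha": config.chisq_alpha,
            "reg_alpha": config.reg_alpha,
            "max_missing": config.max_missing,
            "n_perm": config.n_perm,
            "loess_span": config.loess_span,
            "grid_step": config.grid_step,
        },
        "stages": {},
    }

    dataset: MarkerDataset | None = None
    trial: TrialData | None = None
    ledger = None

    def timed(stage):
        def deco(fn):
            def run():
                t0 = time.perf_counter()
                log.info("stage %s: start", stage)
                try:
                    fn()
                except Exception as e:  # preserve partial outputs
                    _write_manifest(out, manifest)
                    raise StageError(stage, e) from e
                manifest["stages"][stage] = {
                    "wall_time_s": round(time.perf_counter() - t0, 3)
                }
                log.info("stage %s: done", stage)
            return run
        return deco

    def load_dataset() -> MarkerDataset:
        nonlocal dataset
        if dataset is None:
            base = out if (out / "genotypes.tsv").exists() else None
            if base is not None:
                dataset = read_dataset(base / "genotypes.tsv", base / "map.tsv",
                                       base / "q.tsv", base / "subspecies.tsv")
            else:
                dataset = read_dataset(config.genotypes, config.map, config.q,
                                       config.subspecies)
        return dataset

    def load_trial() -> TrialData:
        nonlocal trial
        if trial is None:
            path = (out / "trial.tsv") if (out / "trial.tsv").exists() \
                else Path(config.trial)
            trial = read_trial(path)
        return trial

    @timed("simulate")
    def stage_simulate():
        nonlocal dataset, trial, ledger
        dataset, ledger = generate_collection(config.sim)
        trial = generate_trial(dataset, config.sim, ledger)
        write_dataset(dataset, out)
        write_trial(trial, out / "trial.tsv")
        ledger.write(out / "truth_ledger.tsv")

    @timed("blup")
    def stage_blup():
        tr = load_trial()
        quant = [
            t for t in tr.traits
            if pd.to_numeric(tr.records.loc[tr.records["trait"] == t, "value"],
                             errors="coerce").notna().all()
        ]
        sets, vrows = [], []
        for t in quant:
            envs = sorted(
                tr.records.loc[tr.records["trait"] == t, "environment"].unique()
            )
            for env in envs:
                vc, bl = blup_mod.fit_augmented_reml(tr, t, env)
                sets.append(bl)
                vrows.append({"trait": t, "environment": env,
                              **vc.as_dict(),
                              "reml_loglik": vc.reml_loglik,
                              "converged": vc.converged})
        table = blup_mod.blups_to_table(sets)
        blup_mod.write_blup_table(table, out / "blups.tsv")
        pd.DataFrame(vrows).to_csv(out / "varcomp.tsv", sep="\t", index=False,
                                   float_format="%.6g")

    @timed("diversity")
    def stage_diversity():
        ds = load_dataset()
        dt = div.aggregate_h(ds)
        dt.to_frame().to_csv(out / "diversity_table.tsv", sep="\t", index=False,
                             float_format="%.6g", na_rep="NA")
        rep = div.monomorphic_scan(ds)
        rep.to_frame().to_csv(out / "monomorphic_report.tsv", sep="\t",
                              index=False)

    @timed("ld")
    def stage_ld():
        ds = load_dataset()
        res = ld_mod.analyze_ld(
            ds, n_perm=config.n_perm, seed=config.seed,
            span=config.loess_span, grid_step=config.grid_step,
            with_permutations=config.with_permutations,
        )
        res.pairs.to_csv(out / "ld_pairs.tsv", sep="\t", index=False,
                         float_format="%.6g", na_rep="NA")
        summary = {
            "grid_count": res.grid_count,
            "n_markers": res.n_markers,
            "n_evaluated": res.n_evaluated,
            "median_r2": res.median_r2,
            "critical_r2": res.critical_r2,
            "extent_cm": res.extent.extent_cm if res.extent else np.nan,
            "extent_estimable": res.extent.estimable if res.extent else False,
        }
        pd.DataFrame([summary]).to_csv(out / "ld_summary.tsv", sep="\t",
                                       index=False, float_format="%.6g",
                                       na_rep="NA")
        ld_mod.plot_decay(res, out / "ld_decay.png")

    @timed("associate")
    def stage_associate():
        ds = load_dataset()
        table = blup_mod.read_blup_table(out / "blups.tsv")
        records = []
        for t in sorted({t for t, _ in table.columns}):
            records += assoc.associate_quantitative(
                ds, table, t, scan_alpha=config.scan_alpha,
                reg_alpha=config.reg_alpha, max_missing=config.max_missing,
            )
        tr = load_trial()
        qual = [t for t in tr.traits if t not in {c[0] for c in table.columns}]
        for t in qual:
            sub = tr.records[(tr.records["trait"] == t) & (~tr.records["is_check"])]
            env0 = sorted(sub["environment"].unique())[0]
            classes = sub[sub["environment"] == env0].set_index("entry")["value"]
            records += assoc.associate_qualitative(
                ds, classes, t, scan_alpha=config.scan_alpha,
                chisq_alpha=config.chisq_alpha, max_missing=config.max_missing,
            )
        conc_rows = []
        for rec in records:
            if not rec.declared:
                continue
            if rec.kind == "quantitative":
                vals = table[rec.trait].mean(axis=1)
            else:
                sub = tr.records[
                    (tr.records["trait"] == rec.trait) & (~tr.records["is_check"])
                ]
                env0 = sorted(sub["environment"].unique())[0]
                vals = sub[sub["environment"] == env0].set_index("entry")["value"]
            flags = assoc.monomorphic_concordance(rec, ds, vals)
            for s, v in flags.items():
                conc_rows.append({"marker": rec.marker, "trait": rec.trait,
                                  "fixed_subspecies": s, "concordant": v})
        write_mta_report(records, out / "mta_report.tsv")
        pd.DataFrame(
            conc_rows, columns=["marker", "trait", "fixed_subspecies", "concordant"]
        ).to_csv(out / "concordance_report.tsv", sep="\t", index=False)

    @timed("stats")
    def stage_stats():
        ds = load_dataset()
        table = blup_mod.read_blup_table(out / "blups.tsv")
        sub_of = dict(zip(ds.accession_ids, ds.subspecies))
        arows = []
        for t in sorted({t for t, _ in table.columns}):
            long = table[t].stack().rename("y").reset_index()
            long.columns = ["accession", "environment", "y"]
            long["subspecies"] = long["accession"].map(sub_of)
            if long["environment"].nunique() < 2:
                continue
            aov = trait_stats.two_way_anova(long["y"], long["subspecies"],
                                            long["environment"])
            for term, row in aov.table.iterrows():
                arows.append({"trait": t, "term": term, **row.to_dict()})
        pd.DataFrame(
            arows, columns=["trait", "term", "sum_sq", "df", "F", "p"]
        ).to_csv(out / "anova.tsv", sep="\t", index=False,
                 float_format="%.6g", na_rep="NA")
        means = table.T.groupby(level="trait").mean().T
        r, p, meth = trait_stats.correlation_matrix(means)
        rows = []
        for a in r.index:
            for b in r.columns:
                if a < b:
                    rows.append({"trait_a": a, "trait_b": b, "r": r.loc[a, b],
                                 "p": p.loc[a, b], "method": meth.loc[a, b]})
        pd.DataFrame(
            rows, columns=["trait_a", "trait_b", "r", "p", "method"]
        ).to_csv(out / "correlations.tsv", sep="\t", index=False,
                 float_format="%.6g", na_rep="NA")

    stage_fns = {
        "simulate": stage_simulate,
        "blup": stage_blup,
        "diversity": stage_diversity,
        "ld": stage_ld,
        "associate": stage_associate,
        "stats": stage_stats,
    }
    for stage in config.stages:
        stage_fns[stage]()
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
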