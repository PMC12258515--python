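"""Config-driven orchestration of the full analysis.

A YAML config names the inputs (or a synthetic experiment to generate), the
contrasts to compute, the cutoffs and the seed. ``run_pipeline`` executes
every stage and writes one TSV per result plus a machine-readable run log;
individual stages can be run through :class:`Pipeline` (the CLI maps one
subcommand to each). Outputs are a pure function of (inputs, config, seed):
every stochastic step is seeded from the config seed via a spawned
SeedSequence.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import plots
from .compartments import (
    compartment_shift,
    complex_hit_counts,
    overrepresentation,
    submito_profile,
)
from .enrichment import (
    ContrastResult,
    HitSet,
    call_hits,
    impute_missing,
    normalize_intensities,
    test_contrast,
)
from .io import (
    AnnotationTable,
    IntensityTable,
    read_gene_sets,
    read_intensity_table,
    read_phosphosites,
    write_gene_sets,
    write_intensity_table,
    write_phosphosites,
)
from .phospho import compare_bias_curves, phospho_fraction_curve
from .sets import core_interactome, membership_table, overlap_matrix
from .simulate import (
    SimConfig,
    make_true_matrix,
    simulate_phosphosites,
    simulate_screen,
    simulate_turboid,
)
from .specificity import ScreenCounts, build_matrix, score_proteome, tight_binders

logger = logging.getLogger("proxitome")

STAGES = (
    "simulate",
    "enrich",
    "hits",
    "overlap",
    "core",
    "phosphobias",
    "pwm",
    "score",
    "compartments",
    "ora",
)


def _condition(egf: str, inhibitor: str) -> str:
    return f"egf{egf}.inh{inhibitor}"


class Pipeline:
    """Lazy stage runner over one config. Stages cache their results."""

    def __init__(self, config: dict | str | Path):
        if not isinstance(config, dict):
            with open(config) as fh:
                config = yaml.safe_load(fh)
        self.config = config
        self.seed = int(config.get("seed", 0))
        self._seeds = iter(
            np.random.SeedSequence(self.seed).generate_state(64).tolist()
        )
        self.outdir = Path(config.get("output_dir", "proxitome_run"))
        self.outdir.mkdir(parents=True, exist_ok=True)
        cut = config.get("cutoffs", {})
        self.lfc_cut = float(cut.get("lfc", 1.0))
        self.p_cut = float(cut.get("p", 0.05))
        imp = config.get("imputation", {})
        self.shift_sd = float(imp.get("shift_sd", 1.8))
        self.width_sd = float(imp.get("width_sd", 0.3))
        self.make_plots = bool(config.get("plots", True))
        self._cache: dict[str, object] = {}

    def _next_seed(self) -> int:
        return int(next(self._seeds)) % (2**31 - 1)

    # ------------------------------------------------------------------
    # data
    # ------------------------------------------------------------------
    def stage_simulate(self):
        if "table" in self._cache:
            return
        truth = None
        annotations = None
        sites = None
        gene_sets = None
        if "simulate" in self.config:
            sim_args = dict(self.config["simulate"] or {})
            sim_args.setdefault("seed", self._next_seed())
            for key in ("variants", "egf_states", "inhibitor_states"):
                if key in sim_args:
                    sim_args[key] = tuple(sim_args[key])
            sim = SimConfig(**sim_args)
            table, truth = simulate_turboid(sim)
            annotations = truth.to_annotations()
            write_intensity_table(
                table, self.outdir / "intensities.tsv", self.outdir / "metadata.tsv"
            )
            truth.interactor_frame().to_csv(
                self.outdir / "truth_interactors.tsv", sep="\t", index=False
            )
            write_gene_sets(
                annotations.to_gene_sets(), self.outdir / "annotations.gmt"
            )
            self._cache["sim_config"] = sim
        elif "inputs" in self.config:
            inputs = self.config["inputs"]
            table = read_intensity_table(
                inputs["matrix"],
                inputs["metadata"],
                log2_input=bool(inputs.get("log2", True)),
            )
            if "annotations_gmt" in inputs:
                gsc = read_gene_sets(inputs["annotations_gmt"])
                annotations = AnnotationTable.from_gene_sets(gsc)
            if "phosphosites" in inputs:
                sites = read_phosphosites(inputs["phosphosites"])
            if "gene_sets" in inputs:
                gene_sets = read_gene_sets(inputs["gene_sets"])
        else:
            raise ValueError("config needs a 'simulate' or an 'inputs' section")
        self._cache.update(
            table=table, truth=truth, annotations=annotations, sites=sites,
            gene_sets=gene_sets,
        )
        self._validate_contrasts()

    # ------------------------------------------------------------------
    def _contrast_specs(self) -> list[dict]:
        if "contrasts" in self.config:
            return list(self.config["contrasts"])
        # default: every bait variant against the control, per condition
        table: IntensityTable = self._cache["table"]
        meta = table.metadata
        control = self.config.get("control", "control")
        specs = []
        for variant in sorted(set(meta["variant"]) - {control}):
            for egf in sorted(set(meta["egf"])):
                for inh in sorted(set(meta["inhibitor"])):
                    specs.append(
                        {
                            "name": f"{variant}_vs_{control}.{_condition(egf, inh)}",
                            "variant": variant,
                            "control": control,
                            "egf": egf,
                            "inhibitor": inh,
                        }
                    )
        return specs

    def _validate_contrasts(self) -> None:
        """Fail on unknown variants/conditions before any computation."""
        table: IntensityTable = self._cache["table"]
        known = set(table.metadata["variant"])
        for spec in self._contrast_specs():
            for side in ("variant", "control"):
                if spec[side] not in known:
                    raise ValueError(
                        f"contrast {spec.get('name', '?')!r} references unknown "
                        f"variant {spec[side]!r}"
                    )
            for cond in ("egf", "inhibitor"):
                group = table.samples_for(
                    variant=spec["variant"],
                    egf=spec.get("egf"),
                    inhibitor=spec.get("inhibitor"),
                )
                if not group:
                    raise ValueError(
                        f"contrast {spec.get('name', '?')!r}: no samples match "
                        f"its condition"
                    )

    def stage_enrich(self):
        if "contrasts" in self._cache:
            return
        self.stage_simulate()
        table: IntensityTable = self._cache["table"]
        table = normalize_intensities(table)
        table = impute_missing(
            table, self.shift_sd, self.width_sd, seed=self._next_seed()
        )
        self._cache["imputed_table"] = table
        results: dict[str, ContrastResult] = {}
        for spec in self._contrast_specs():
            egf, inh = spec.get("egf", "-"), spec.get("inhibitor", "-")
            group_a = table.samples_for(spec["variant"], egf, inh)
            group_b = table.samples_for(
                spec["control"], spec.get("control_egf", egf),
                spec.get("control_inhibitor", inh),
            )
            name = spec.get("name", f"{spec['variant']}_vs_{spec['control']}")
            result = test_contrast(
                table, group_a, group_b,
                label=name, condition=_condition(egf, inh),
                lfc_cut=self.lfc_cut, p_cut=self.p_cut,
            )
            result.variant = spec["variant"]
            results[name] = result
            result.write(self.outdir / f"contrast_{name}.tsv")
            if self.make_plots:
                plots.volcano(result, self.outdir / f"volcano_{name}.svg")
        self._cache["contrasts"] = results

    def stage_hits(self):
        if "hitsets" in self._cache:
            return
        self.stage_enrich()
        hitsets: dict[str, HitSet] = {}
        down_sets: dict[str, HitSet] = {}
        rows = []
        for name, result in self._cache["contrasts"].items():
            hs = call_hits(
                result, self.lfc_cut, self.p_cut, variant=result.variant
            )
            down = call_hits(
                result, self.lfc_cut, self.p_cut, variant=result.variant,
                direction="down",
            )
            # leave the table flagged for the enrichment direction
            call_hits(result, self.lfc_cut, self.p_cut, variant=result.variant)
            hitsets[name], down_sets[name] = hs, down
            rows.append(
                {
                    "contrast": name,
                    "condition": hs.condition,
                    "n_hits_up": len(hs),
                    "n_hits_down": len(down),
                    "lfc_cut": self.lfc_cut,
                    "p_cut": self.p_cut,
                }
            )
            pd.Series(sorted(hs.proteins)).to_csv(
                self.outdir / f"hits_{name}.txt", index=False, header=False
            )
        pd.DataFrame(rows).to_csv(
            self.outdir / "hit_counts.tsv", sep="\t", index=False
        )
        self._cache["hitsets"] = hitsets
        self._cache["down_sets"] = down_sets

    def _hitsets_by_condition(self) -> dict[str, list[HitSet]]:
        by_cond: dict[str, list[HitSet]] = {}
        for hs in self._cache["hitsets"].values():
            by_cond.setdefault(hs.condition, []).append(hs)
        return by_cond

    def stage_overlap(self):
        if "overlaps" in self._cache:
            return
        self.stage_hits()
        overlaps = {}
        for cond, family in self._hitsets_by_condition().items():
            if len(family) < 2:
                continue
            om = overlap_matrix(family)
            om.pairwise.to_csv(self.outdir / f"overlap_{cond}.tsv", sep="\t")
            membership_table(family).to_csv(
                self.outdir / f"membership_{cond}.tsv", sep="\t"
            )
            overlaps[cond] = om
        self._cache["overlaps"] = overlaps

    def stage_core(self):
        if "core" in self._cache:
            return
        self.stage_hits()
        core_cfg = self.config.get("core", {})
        cores = {}
        for cond, family in self._hitsets_by_condition().items():
            k = int(core_cfg.get(cond, core_cfg.get("k", min(4, len(family)))))
            core = core_interactome(family, k)
            cores[cond] = (k, core)
            pd.Series(sorted(core)).to_csv(
                self.outdir / f"core_{cond}.txt", index=False, header=False
            )
        self._cache["core"] = cores

    def stage_phosphobias(self):
        if "bias_curves" in self._cache:
            return
        self.stage_enrich()
        annotations: AnnotationTable | None = self._cache["annotations"]
        if annotations is None:
            logger.warning("no annotations available; skipping phospho-bias curves")
            self._cache["bias_curves"] = {}
            return
        curves = {}
        for name, result in self._cache["contrasts"].items():
            curve = phospho_fraction_curve(result, annotations)
            curve.write(self.outdir / f"phosphobias_{name}.tsv")
            curves[name] = curve
        if self.make_plots and curves:
            plots.bias_overlay(
                list(curves.values()), self.outdir / "phosphobias_overlay.svg"
            )
        self._cache["bias_curves"] = curves

    def stage_pwm(self):
        if "matrices" in self._cache:
            return
        self.stage_simulate()
        screen_cfg = dict(self.config.get("screen", {}))
        pseudocount = float(self.config.get("pseudocount", 1.0))
        matrices = {}
        inputs = self.config.get("inputs", {})
        counts_paths = inputs.get("screen_counts") if inputs else None
        if counts_paths:
            for domain, path in counts_paths.items():
                counts = ScreenCounts.read(path)
                matrices[domain] = build_matrix(
                    counts, pseudocount=pseudocount, domain=domain
                )
        else:
            truth = self._cache["truth"]
            for domain in ("N-SH2", "C-SH2"):
                true_m = make_true_matrix(
                    half_width=int(screen_cfg.get("half_width", 5)),
                    weight_sd=float(screen_cfg.get("weight_sd", 1.0)),
                    domain=domain,
                    seed=self._next_seed(),
                )
                if truth is not None:
                    truth.matrices[domain] = true_m
                counts = simulate_screen(
                    true_m,
                    n_library=int(screen_cfg.get("n_library", 20_000)),
                    n_reads_input=int(screen_cfg.get("n_reads_input", 500_000)),
                    n_reads_selected=int(screen_cfg.get("n_reads_selected", 500_000)),
                    selection_sharpness=float(screen_cfg.get("sharpness", 1.0)),
                    seed=self._next_seed(),
                )
                counts.write(self.outdir / f"screen_counts_{domain}.tsv")
                matrices[domain] = build_matrix(
                    counts, pseudocount=pseudocount, domain=domain
                )
        for domain, matrix in matrices.items():
            matrix.write(self.outdir / f"pwm_{domain}.tsv")
            if self.make_plots:
                plots.matrix_heatmap(matrix, self.outdir / f"pwm_{domain}.svg")
        self._cache["matrices"] = matrices

    def stage_score(self):
        if "site_scores" in self._cache:
            return
        self.stage_pwm()
        self.stage_hits()
        matrices = self._cache["matrices"]
        if len(matrices) < 2:
            raise ValueError("site scoring needs both N-SH2 and C-SH2 matrices")
        sites = self._cache["sites"]
        if sites is None:
            truth = self._cache["truth"]
            site_cfg = dict(self.config.get("phosphosites", {}))
            sites, _ = simulate_phosphosites(
                n_sites=int(site_cfg.get("n_sites", 1000)),
                window=next(iter(matrices.values())).half_width,
                truth=truth,
                seed=self._next_seed(),
            )
            write_phosphosites(sites, self.outdir / "phosphosites.tsv")
        domains = list(matrices)
        scores = score_proteome(matrices[domains[0]], matrices[domains[1]], sites)
        scores.to_csv(self.outdir / "site_scores.tsv", sep="\t", index=False)
        cut = float(self.config.get("tight_percentile", 99.0))
        tight = tight_binders(scores, cut)
        tight.to_csv(self.outdir / "tight_binders.tsv", sep="\t", index=False)
        self._cache["site_scores"] = scores
        self._cache["tight"] = tight

    def stage_compartments(self):
        if "shifts" in self._cache:
            return
        self.stage_hits()
        annotations: AnnotationTable | None = self._cache["annotations"]
        if annotations is None:
            logger.warning("no annotations available; skipping compartment stages")
            self._cache["shifts"] = None
            return
        label = self.config.get("compartment_label", "mitochondrial")
        rows = []
        for name, result in self._cache["contrasts"].items():
            try:
                shift = compartment_shift(result, annotations, label)
            except ValueError as exc:
                logger.warning("%s: %s", name, exc)
                continue
            rows.append(dataclasses.asdict(shift))
        shifts = pd.DataFrame(rows)
        shifts.to_csv(self.outdir / "compartment_shifts.tsv", sep="\t", index=False)
        complexes = [
            lab for lab in ("complex_II", "complex_III", "complex_IV", "complex_V")
            if lab in annotations.vocabulary
        ]
        counts = pd.concat(
            [
                complex_hit_counts(hs, annotations, complexes).assign(contrast=name)
                for name, hs in self._cache["hitsets"].items()
            ],
            ignore_index=True,
        )
        counts.to_csv(self.outdir / "complex_hit_counts.tsv", sep="\t", index=False)
        profile = submito_profile(
            list(self._cache["contrasts"].values()), annotations
        )
        profile.to_csv(self.outdir / "submito_profile.tsv", sep="\t", index=False)
        if self.make_plots and len(profile):
            plots.compartment_bars(profile, self.outdir / "submito_profile.svg")
        self._cache["shifts"] = shifts

    def stage_ora(self):
        if "ora" in self._cache:
            return
        self.stage_core()
        annotations: AnnotationTable | None = self._cache["annotations"]
        gene_sets = self._cache["gene_sets"]
        if gene_sets is None and annotations is not None:
            gene_sets = annotations.to_gene_sets()
        if gene_sets is None:
            logger.warning("no gene sets available; skipping ORA")
            self._cache["ora"] = None
            return
        results = {}
        for cond, (k, core) in self._cache["core"].items():
            # background: proteins quantified in any contrast of the condition
            background = set()
            for result in self._cache["contrasts"].values():
                if result.condition == cond:
                    background |= set(result.proteins)
            hs = HitSet(
                variant=f"core_{cond}", condition=cond,
                proteins=frozenset(core & background),
                lfc_cut=self.lfc_cut, p_cut=self.p_cut,
            )
            ora = overrepresentation(hs, background, gene_sets)
            ora.to_csv(self.outdir / f"ora_core_{cond}.tsv", sep="\t", index=False)
            results[cond] = ora
        self._cache["ora"] = results

    # ------------------------------------------------------------------
    def run(self, stages: list[str] | None = None) -> Path:
        for stage in stages or STAGES:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            getattr(self, f"stage_{stage}")()
        self._write_log()
        return self.outdir

    def _write_log(self) -> None:
        log = {
            "seed": self.seed,
            "cutoffs": {"lfc": self.lfc_cut, "p": self.p_cut},
            "imputation": {"shift_sd": self.shift_sd, "width_sd": self.width_sd},
            "config": self.config,
        }
        if "sim_config" in self._cache:
            log["sim_config"] = dataclasses.asdict(self._cache["sim_config"])
        with open(self.outdir / "run_log.yaml", "w") as fh:
            yaml.safe_dump(log, fh, sort_keys=True)


def run_pipeline(config: dict | str | Path) -> Path:
    """Run every stage of the analysis for one config; returns the run directory."""
    return Pipeline(config).run()
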