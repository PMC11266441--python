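"""End-to-end pipeline orchestration.

Stages mirror the workflow: simulate -> blues -> envirotype -> genetics ->
inputs -> fit -> evaluate.  Each stage persists its outputs under the run
directory together with a provenance record (SHA-256 of its inputs and the
stage configuration), and a stage whose provenance matches an existing output
is skipped on re-run, making runs resumable per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib

import numpy as np
import pandas as pd
import yaml

from . import envirotyping, evaluation, genetics, model_inputs, prediction, synthetic, trials
from .errors import InvalidConfigError

logger = logging.getLogger(__name__)

MODEL_TOKENS = ("E", "G(A)", "G(D)", "G(A)+E", "G(D)+E", "G(A)EI", "G(D)EI")
STAGES = ("simulate", "blues", "envirotype", "genetics", "inputs", "fit", "evaluate")


@dataclasses.dataclass
class RunConfig:
    out_dir: str
    seed: int
    schemes: tuple = ("CV2",)
    models: tuple = ("G(A)", "G(A)+E")
    k: int = 100
    folds: int = 5
    repetitions: int = 10
    maf_threshold: float = 0.01
    ld_window: int = 100
    ld_step: int = 20
    ld_r2: float = 0.9
    simulate: dict = dataclasses.field(default_factory=dict)
    gbm: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.seed is None:
            raise InvalidConfigError("seed is mandatory")
        self.schemes = tuple(self.schemes)
        self.models = tuple(self.models)
        if not self.schemes or not self.models:
            raise InvalidConfigError("need at least one scheme and one model")
        for s in self.schemes:
            if s not in evaluation.SPLITTERS:
                raise InvalidConfigError(f"unknown scheme {s!r}")
        for m in self.models:
            if m not in MODEL_TOKENS:
                raise InvalidConfigError(
                    f"unknown model token {m!r}; valid: {MODEL_TOKENS}"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_provenance(out: pathlib.Path, stage: str, cfg_repr: str, inputs: list):
    return {
        "stage": stage,
        "config": hashlib.sha256(cfg_repr.encode()).hexdigest(),
        "inputs": {str(p.name): _sha256(p) for p in inputs if p.exists()},
    }


class Run:
    """A pipeline run rooted at ``cfg.out_dir``."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.out = pathlib.Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(self.out / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        pkg_logger = logging.getLogger("metboost")
        for old in list(pkg_logger.handlers):  # one active run log at a time
            if isinstance(old, logging.FileHandler):
                pkg_logger.removeHandler(old)
                old.close()
        pkg_logger.addHandler(handler)
        self._study = None

    # -- provenance helpers -------------------------------------------------
    def _done(self, stage: str, prov: dict) -> bool:
        f = self.out / f"{stage}.provenance.json"
        if f.exists() and json.loads(f.read_text()) == prov:
            logger.info("stage %s up to date, skipping", stage)
            return True
        return False

    def _mark(self, stage: str, prov: dict):
        (self.out / f"{stage}.provenance.json").write_text(json.dumps(prov, indent=1))

    # -- stages -------------------------------------------------------------
    def simulate(self):
        cfg = synthetic.SimConfig(seed=self.cfg.seed, **self.cfg.simulate)
        prov = _stage_provenance(self.out, "simulate", repr(cfg), [])
        study_dir = self.out / "study"
        if self._done("simulate", prov) and (study_dir / "plot_table.csv").exists():
            pass
        else:
            study = synthetic.generate_study(cfg)
            synthetic.write_study(study, study_dir)
            self._study = study
            self._mark("simulate", prov)
        if self._study is None:
            self._study = synthetic.generate_study(cfg)
        return self._study

    def blues(self):
        study = self.simulate()
        prov = _stage_provenance(
            self.out, "blues", "reml", [self.out / "study" / "plot_table.csv"]
        )
        f_blues = self.out / "blues.csv"
        if self._done("blues", prov) and f_blues.exists():
            return pd.read_csv(f_blues)
        blues, diagnostics, _ = trials.fit_all_trials(study.plot_table)
        blues.to_csv(f_blues, index=False)
        diagnostics.to_csv(self.out / "trial_diagnostics.csv", index=False)
        self._mark("blues", prov)
        return blues

    def envirotype(self):
        study = self.simulate()
        matrix, manifest = envirotyping.build_environmental_matrix(study)
        matrix.to_csv(self.out / "environmental_matrix.csv")
        (self.out / "environmental_manifest.json").write_text(
            json.dumps(manifest, indent=1)
        )
        return matrix

    def genetics(self):
        study = self.simulate()
        m = genetics.from_population(study.population)
        m = genetics.filter_individuals(
            m, sorted(study.plot_table["Hybrid"].unique())
        )
        m = genetics.filter_maf(m, self.cfg.maf_threshold)
        m = genetics.ld_prune(
            m, window=self.cfg.ld_window, step=self.cfg.ld_step, r2=self.cfg.ld_r2
        )
        grms = {"A": genetics.grm_additive(m), "D": genetics.grm_dominance(m)}
        genetics.write_grm(grms["A"], self.out / "grm_additive.csv")
        genetics.write_grm(grms["D"], self.out / "grm_dominance.csv")
        return grms

    def inputs(self):
        blues = self.blues()
        env_matrix = self.envirotype()
        grms = self.genetics()
        built = {}
        for token in self.cfg.models:
            mi = model_inputs.build_model_input(
                token, blues, env_matrix, grms, k=self.cfg.k
            )
            safe = token.replace("(", "_").replace(")", "").replace("+", "p")
            mi.table.to_csv(self.out / f"input_{safe}.csv", index=False)
            (self.out / f"input_{safe}.json").write_text(
                json.dumps(
                    {
                        "kind": mi.kind,
                        "grm_kind": mi.grm_kind,
                        "k": mi.svd_components,
                        "n_rows": len(mi.table),
                    }
                )
            )
            built[token] = mi
        return built

    def fit(self):
        inputs = self.inputs()
        blues = self.blues()
        gbm_cfg = prediction.GBMConfig(seed=self.cfg.seed, **self.cfg.gbm)
        pred_dir = self.out / "predictions"
        pred_dir.mkdir(exist_ok=True)
        all_preds = {}
        for scheme in self.cfg.schemes:
            plan = evaluation.SPLITTERS[scheme](
                blues, self.cfg.seed, folds=self.cfg.folds,
                repetitions=self.cfg.repetitions,
            )
            (self.out / f"cvplan_{scheme}.json").write_text(
                json.dumps(plan.to_dict())
            )
            for token, mi in inputs.items():
                keyed = mi.table.set_index(
                    pd.MultiIndex.from_frame(mi.table[["Env", "Hybrid"]])
                )
                preds = []
                for (rep, fold), _ in sorted(plan.assignments.items()):
                    tr, va = plan.split(rep, fold)
                    train_rows = keyed.loc[list(zip(tr["Env"], tr["Hybrid"]))]
                    valid_rows = keyed.loc[list(zip(va["Env"], va["Hybrid"]))]
                    ps = prediction.fit_predict(
                        train_rows, valid_rows, mi, gbm_cfg, fold=fold, repetition=rep
                    )
                    preds.append(ps)
                    safe = token.replace("(", "_").replace(")", "").replace("+", "p")
                    ps.records.to_csv(
                        pred_dir / f"{scheme}_{safe}_rep{rep}_fold{fold}.csv",
                        index=False,
                    )
                all_preds[(scheme, token)] = preds
        return all_preds

    def evaluate(self):
        all_preds = self.fit()
        blues = self.blues()
        study = self.simulate()
        tester_of = study.population.tester_of
        metric_frames, overlap_rows, comparison_frames = [], [], []
        for scheme in self.cfg.schemes:
            scheme_preds = []
            for (s, token), preds in all_preds.items():
                if s == scheme:
                    scheme_preds.extend(preds)
            fm = evaluation.fold_metrics(scheme_preds)
            fm.insert(0, "scheme", scheme)
            metric_frames.append(fm)
            cmp = evaluation.model_comparisons(scheme_preds)
            if len(cmp):
                cmp.insert(0, "scheme", scheme)
                comparison_frames.append(cmp)
            plan = evaluation.SPLITTERS[scheme](
                blues, self.cfg.seed, folds=self.cfg.folds,
                repetitions=self.cfg.repetitions,
            )
            overlap_rows.append(
                {"scheme": scheme, "tester_overlap": evaluation.tester_overlap(plan, tester_of)}
            )
        metrics = pd.concat(metric_frames, ignore_index=True)
        metrics.to_csv(self.out / "metric_report.csv", index=False)
        pd.DataFrame(overlap_rows).to_csv(self.out / "tester_overlap.csv", index=False)
        if comparison_frames:
            pd.concat(comparison_frames, ignore_index=True).to_csv(
                self.out / "model_comparisons.csv", index=False
            )
        return metrics


def run(cfg: RunConfig, stage: str = "evaluate"):
    """Execute the pipeline up to ``stage`` (default: the whole workflow)."""
    if stage not in STAGES:
        raise InvalidConfigError(f"unknown stage {stage!r}; valid: {STAGES}")
    r = Run(cfg)
    return getattr(r, stage if stage != "simulate" else "simulate")()
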