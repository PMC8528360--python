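"""End-to-end derivation pipeline with configuration and a run manifest.

Orchestrates: load or simulate a cohort -> random derivation/test split ->
baseline comparison -> score derivation on the derivation sample
(:class:`~hfscore.model.RiskScoreModel`) -> scoring and tier assignment of
both samples -> evaluation reports for derivation, test, and overall.
Every artifact is written as CSV (plus a YAML score spec) and listed in a
JSON manifest together with the configuration snapshot and any warnings.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import CohortTable, baseline_summary, read_cohort, split_cohort, write_cohort
from .model import RiskScoreModel
from .score import assign_tier, evaluate_score, published_score_spec
from .simulate import GeneratorParams, generate_cohort

__all__ = ["PipelineConfig", "RunManifest", "run_derivation_pipeline", "apply_published_score"]


@dataclass
class PipelineConfig:
    """Configuration of a derivation run.

    Either ``input_csv`` (a cohort file) or ``n_patients`` (simulate that
    many patients with the default generator parameters) must be given.
    Separate seeds control simulation, the derivation/test split, and the
    bootstrap so each stage can be varied independently.
    """

    output_dir: str = "hfscore_run"
    input_csv: str | None = None
    n_patients: int | None = None
    seed_generate: int = 11
    seed_split: int = 22
    seed_bootstrap: int = 33
    n_iter: int = 10_000
    threshold: float = 0.9
    alpha: float = 0.05
    prevalence_floor: float = 0.01
    forced: tuple[str, ...] = ()
    target_rate: float = 0.065

    def validate(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError(f"selection threshold must be in (0,1], got {self.threshold}")
        if (self.input_csv is None) == (self.n_patients is None):
            raise ValueError("give exactly one of input_csv or n_patients")
        if self.n_patients is not None and self.n_patients < 4:
            raise ValueError("n_patients must be at least 4")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "forced" in d:
            d["forced"] = tuple(d["forced"])
        return cls(**d)


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    version: str
    stages: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, seconds: float, **info) -> None:
        self.stages.append({"stage": name, "seconds": round(seconds, 3), **info})

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
        self.outputs["manifest"] = str(path)


def apply_published_score(cohort: CohortTable) -> pd.DataFrame:
    """Score a cohort with the published fixed five-variable weights.

    No refitting: applies 100 + 1.5*age - 15*female + 20*la_diam -
    20*bmi + 30*nyha_gt3 and appends ``score`` and ``tier`` columns.
    Incomplete continuous score variables are median-imputed first.
    """
    spec = published_score_spec()
    from .preprocess import impute_with_indicators

    need = [
        v for v in spec.variables
        if cohort.spec(v).kind == "continuous" and cohort.df[v].isna().any()
    ]
    prepared = impute_with_indicators(cohort, need)[0] if need else cohort
    out = cohort.df.copy()
    out["score"] = evaluate_score(spec, prepared)
    out["tier"] = assign_tier(spec, out["score"].to_numpy())
    return out


def run_derivation_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the full derivation pipeline and write all artifacts.

    Returns the manifest (also written as ``manifest.json``).  Any stage
    failure raises with the stage name; artifacts written before the
    failure are left in place.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), version=__version__)

    def _stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                return self_
            def __exit__(self_, exc_type, exc, tb):
                if exc is not None:
                    manifest.warnings.append(f"stage {name!r} failed: {exc}")
                    manifest.write(outdir / "manifest.json")
                return False
            def done(self_, **info):
                manifest.add_stage(name, time.perf_counter() - self_.t0, **info)
        return _Timer()

    # -- input ----------------------------------------------------------
    with _stage("input") as st:
        if config.input_csv is not None:
            cohort = read_cohort(config.input_csv)
            st.done(source=config.input_csv, n=cohort.n)
        else:
            params = GeneratorParams(target_rate=config.target_rate)
            synth = generate_cohort(params, config.n_patients, config.seed_generate)
            cohort = synth.cohort
            path = outdir / "cohort.csv"
            write_cohort(cohort, path)
            with open(outdir / "generator_params.json", "w") as fh:
                json.dump({
                    "continuous": params.continuous,
                    "prevalence": params.prevalence,
                    "log_odds": params.log_odds,
                    "target_rate": params.target_rate,
                    "missing_rates": params.missing_rates,
                    "seed": config.seed_generate,
                }, fh, indent=2)
            manifest.outputs["cohort"] = str(path)
            manifest.outputs["generator_params"] = str(outdir / "generator_params.json")
            st.done(source="simulated", n=cohort.n)

    # -- split + baseline ------------------------------------------------
    with _stage("split") as st:
        deriv, test = split_cohort(cohort, config.seed_split)
        st.done(derivation_n=deriv.n, test_n=test.n)
    with _stage("baseline") as st:
        base = baseline_summary(deriv, test)
        base.to_csv(outdir / "baseline_summary.csv", index=False)
        manifest.outputs["baseline_summary"] = str(outdir / "baseline_summary.csv")
        st.done(variables=len(base))

    # -- derivation ------------------------------------------------------
    with _stage("derive") as st:
        model = RiskScoreModel(
            deriv, alpha=config.alpha, prevalence_floor=config.prevalence_floor,
            forced=config.forced,
        )
        results = model.fit(n_iter=config.n_iter, threshold=config.threshold,
                            seed=config.seed_bootstrap)
        results.screening.to_csv(outdir / "screening.csv", index=False)
        results.selection.to_frame().to_csv(outdir / "selection.csv")
        results.risk_factor_table().to_csv(outdir / "risk_factors.csv")
        results.score_spec.to_yaml(outdir / "score_spec.yaml")
        (outdir / "summary.txt").write_text(results.summary() + "\n")
        for key in ("screening", "selection", "risk_factors", "score_spec", "summary"):
            ext = {"score_spec": "yaml", "summary": "txt"}.get(key, "csv")
            manifest.outputs[key] = str(outdir / f"{key}.{ext}")
        if results.selection.n_discarded:
            manifest.warnings.append(
                f"{results.selection.n_discarded} bootstrap iterations discarded")
        st.done(selected=results.selected,
                completed=results.selection.n_completed,
                discarded=results.selection.n_discarded)

    # -- scoring + evaluation ---------------------------------------------
    with _stage("score") as st:
        for name, sample in (("derivation", deriv), ("test", test)):
            scored = results.score(sample)
            scored.to_csv(outdir / f"scored_{name}.csv", index=False)
            manifest.outputs[f"scored_{name}"] = str(outdir / f"scored_{name}.csv")
        st.done()
    with _stage("evaluate") as st:
        overall = CohortTable(
            pd.concat([deriv.df, test.df], ignore_index=True), cohort.schema)
        reports = [
            results.evaluate(None, sample="derivation"),
            results.evaluate(test, sample="test"),
            results.evaluate(overall, sample="overall"),
        ]
        perf = pd.concat([r.to_frame() for r in reports], ignore_index=True)
        perf.to_csv(outdir / "performance.csv", index=False)
        tiers = pd.concat(
            [r.tiers.assign(sample=r.sample) for r in reports], ignore_index=True)
        tiers.to_csv(outdir / "tier_mortality.csv", index=False)
        reports[0].deciles.to_csv(outdir / "decile_calibration.csv", index=False)
        for key in ("performance", "tier_mortality", "decile_calibration"):
            manifest.outputs[key] = str(outdir / f"{key}.csv")
        st.done(derivation_auc=reports[0].model_auc, test_auc=reports[1].model_auc)

    manifest.write(outdir / "manifest.json")
    return manifest
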