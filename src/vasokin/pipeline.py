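"""End-to-end orchestration of the analysis.

Stage order mirrors the study workflow: simulate (or load) the cohort,
build fold-change features against the requested baselines, run the
group statistics, compute effect sizes and power, classify patients by
leave-one-out, assess classifier significance by permutation, and select
risk-score-matched subsets.  Every stage draws its randomness from a
substream derived from the global seed and the stage name, so adding or
re-ordering stages never perturbs another stage's random numbers, and a
rerun with the same configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassifierSpec, loo_evaluate
from .effect import analytic_power_t, effect_size_table, simulate_power
from .errors import ConfigurationError
from .features import build_fold_change_matrix, feature_vector, summarize_by_group
from .io import (
    read_count_table,
    read_patient_table,
    records_from_frame,
    write_count_table,
    write_patient_table,
)
from .matching import match_by_score
from .permutation import permutation_p
from .schema import BASELINES
from .stats import mann_whitney, wilcoxon_signed_rank
from .synthetic import ScenarioConfig, default_scenario, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

STAGES = (
    "simulate",
    "features",
    "group_tests",
    "effect_power",
    "classify",
    "permute",
    "match",
)


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Derive a per-stage seed substream from the global seed."""
    return np.random.SeedSequence([seed, zlib.crc32(stage.encode())])


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    scenario: ScenarioConfig | None = None   # simulate when set ...
    counts_path: str | None = None           # ... else load these two files
    patients_path: str | None = None
    baselines: tuple[str, ...] = ("B1", "B2", "P0")
    population: str = "CD34"
    timepoint: str = "H0"
    feature_baseline: str = "B1"
    classifier_methods: tuple[str, ...] = ("logistic", "gbt")
    permutation_methods: tuple[str, ...] = ("logistic",)
    permutation_reps: int = 1000
    permutation_scheme: str = "label-shuffle"
    match_k: int = 5
    power_reps: int = 1000
    power_effect_sizes: tuple[float, ...] = (1.0, 1.5, 2.0)
    outdir: str = "vasokin_run"
    seed: int = 0
    classifier_spec: ClassifierSpec = field(default_factory=ClassifierSpec)

    def validate(self) -> None:
        if self.scenario is None and (self.counts_path is None or self.patients_path is None):
            raise ConfigurationError(
                "either scenario or both counts_path and patients_path must be set"
            )
        for b in self.baselines:
            if b not in BASELINES:
                raise ConfigurationError(f"unknown baseline {b!r}")
        if self.feature_baseline not in self.baselines:
            raise ConfigurationError(
                f"feature_baseline {self.feature_baseline!r} not among baselines"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Execute all stages and return the run manifest.

    The manifest records the seed, package version, per-stage summaries
    and a SHA-256 checksum of every file written; it is also saved as
    ``manifest.json`` in the output directory.
    """
    config = config or RunConfig(scenario=default_scenario())
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "package_version": __version__,
        "stages": [],
    }
    written: list[Path] = []

    def record(stage: str, outputs: list[Path], summary: dict) -> None:
        manifest["stages"].append(
            {"name": stage, "outputs": [p.name for p in outputs], "summary": summary}
        )
        written.extend(outputs)

    # -- simulate (or load) ------------------------------------------------
    if config.scenario is not None:
        scenario = config.scenario
        seed = int(stage_seed(config.seed, "simulate").generate_state(1)[0] % (2**31))
        scenario = type(scenario)(**{**scenario.__dict__, "seed": seed})
        patients, counts = generate_cohort(scenario)
        source = f"synthetic (n={scenario.n_group1}+{scenario.n_group2})"
    else:
        counts = read_count_table(config.counts_path)
        patients_records = read_patient_table(config.patients_path)
        patients = pd.DataFrame(
            [
                {
                    "patient_id": r.patient_id,
                    "ne_dose": r.ne_dose,
                    "group": r.group,
                    "euroscore2": r.euroscore2,
                    **r.covariates,
                }
                for r in patients_records
            ]
        )
        source = f"loaded ({config.counts_path}, {config.patients_path})"
    counts_path = outdir / "counts.csv"
    patients_path = outdir / "patients.csv"
    write_count_table(counts, counts_path)
    write_patient_table(patients, patients_path)
    record(
        "simulate",
        [counts_path, patients_path],
        {"source": source, "n_patients": int(patients.shape[0])},
    )

    # -- features ----------------------------------------------------------
    matrices = {}
    feature_files = []
    for baseline in config.baselines:
        m = build_fold_change_matrix(counts, baseline)
        matrices[baseline] = m
        p = outdir / f"foldchange_{baseline}.csv"
        _write_csv(m.entries.assign(baseline=baseline), p)
        feature_files.append(p)
    summary = pd.concat(
        [summarize_by_group(m, patients) for m in matrices.values()], ignore_index=True
    )
    p_sum = outdir / "summary.csv"
    _write_csv(summary, p_sum)
    record(
        "features",
        feature_files + [p_sum],
        {"baselines": list(config.baselines), "entries": int(summary["n"].sum())},
    )

    # -- group tests -------------------------------------------------------
    records = records_from_frame(patients)
    groups = {r.patient_id: r.group for r in records}
    rows = []
    for baseline, m in matrices.items():
        for (pop, tp), sub in m.entries.groupby(["population", "timepoint"], sort=False):
            by_pid = sub.set_index("patient_id")["log_fc"]
            g1 = by_pid[[pid for pid in by_pid.index if groups.get(pid) == "G1"]].to_numpy()
            g2 = by_pid[[pid for pid in by_pid.index if groups.get(pid) == "G2"]].to_numpy()
            if len(g1) and len(g2):
                r = mann_whitney(g1, g2)
                rows.append((pop, tp, baseline, "G1-vs-G2", r))
            for label, vals in (("within-G1", g1), ("within-G2", g2)):
                if len(vals) >= 2 and np.any(vals != 0):
                    r = wilcoxon_signed_rank(vals)
                    rows.append((pop, tp, baseline, label, r))
    tests_df = pd.DataFrame(
        [
            {
                "population": pop,
                "timepoint": tp,
                "baseline": baseline,
                "comparison": comp,
                "method": r.method,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "exact": r.exact,
            }
            for pop, tp, baseline, comp, r in rows
        ]
    )
    p_tests = outdir / "tests.csv"
    _write_csv(tests_df, p_tests)
    record("group_tests", [p_tests], {"n_tests": int(len(tests_df))})

    # -- effect sizes + power ---------------------------------------------
    effect_frames = [effect_size_table(m, patients) for m in matrices.values()]
    effects = pd.concat(effect_frames, ignore_index=True)
    p_eff = outdir / "effectsizes.csv"
    _write_csv(effects, p_eff)
    n1 = int((patients["group"] == "G1").sum())
    n2 = int((patients["group"] == "G2").sum())
    pseed = int(stage_seed(config.seed, "effect_power").generate_state(1)[0] % (2**31))
    power_rows = []
    for d in config.power_effect_sizes:
        res = simulate_power(d, n1, n2, reps=config.power_reps, seed=pseed)
        power_rows.append(
            {
                "effect_size": d,
                "n1": n1,
                "n2": n2,
                "reps": res.reps,
                "power_simulated": res.power,
                "mc_se": res.mc_se,
                "power_analytic_t": analytic_power_t(d, n1, n2),
            }
        )
    power_df = pd.DataFrame(power_rows)
    p_pow = outdir / "power.csv"
    _write_csv(power_df, p_pow)
    record(
        "effect_power",
        [p_eff, p_pow],
        {"n_features": int(len(effects)), "power_reps": config.power_reps},
    )

    # -- classify ----------------------------------------------------------
    feat = feature_vector(matrices[config.feature_baseline], config.population, config.timepoint)
    labeled = [pid for pid in feat.index if groups.get(pid) is not None]
    x = feat.loc[labeled].to_numpy()
    y = np.array([1 if groups[pid] == "G2" else 0 for pid in labeled])
    cls_tables, cls_summary = [], {}
    for method in config.classifier_methods:
        spec = ClassifierSpec(**{**config.classifier_spec.__dict__, "method": method})
        res = loo_evaluate(x, y, labeled, spec)
        cls_tables.append(res.table.assign(method=method))
        cls_summary[method] = {
            "mae": res.mae,
            "misclassified": res.misclassified,
        }
    p_cls = outdir / "predictions.csv"
    _write_csv(pd.concat(cls_tables, ignore_index=True), p_cls)
    record(
        "classify",
        [p_cls],
        {
            "feature": f"{config.population}:{config.timepoint}:{config.feature_baseline}",
            **cls_summary,
        },
    )

    # -- permutation significance -----------------------------------------
    perm_seed = int(stage_seed(config.seed, "permute").generate_state(1)[0] % (2**31))
    perm_rows = []
    for method in config.permutation_methods:
        spec = ClassifierSpec(**{**config.classifier_spec.__dict__, "method": method})
        res = permutation_p(
            x,
            y,
            labeled,
            spec,
            reps=config.permutation_reps,
            seed=perm_seed,
            scheme=config.permutation_scheme,
        )
        perm_rows.append(
            {
                "method": method,
                "scheme": res.scheme,
                "reps": res.reps,
                "observed_mae": res.observed_mae,
                "p_value": res.p_value,
            }
        )
    perm_df = pd.DataFrame(perm_rows)
    p_perm = outdir / "permutation.csv"
    _write_csv(perm_df, p_perm)
    record(
        "permute",
        [p_perm],
        {row["method"]: row["p_value"] for row in perm_rows},
    )

    # -- risk-score matching ----------------------------------------------
    scores1 = {r.patient_id: r.euroscore2 for r in records if r.group == "G1" and r.euroscore2 is not None}
    scores2 = {r.patient_id: r.euroscore2 for r in records if r.group == "G2" and r.euroscore2 is not None}
    k = min(config.match_k, len(scores1), len(scores2))
    match = match_by_score(scores1, scores2, k)
    match_df = pd.DataFrame(
        match.pairs, columns=["group1_id", "group2_id", "score_distance"]
    )
    p_match = outdir / "matched.csv"
    _write_csv(match_df, p_match)
    record(
        "match",
        [p_match],
        {"k": match.k, "total_distance": match.total_distance},
    )

    manifest["checksums"] = {p.name: _sha256(p) for p in written}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
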