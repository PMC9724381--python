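"""End-to-end orchestration: simulate, analyze, report.

`analyze` ties the stages together the way the validation study runs them:
response-frequency accounting, recall-side exposure quantification, the
composite BPAe score with its monotonicity check, rank tests across BPAe
groups, and the multiply-imputed pooled regressions for both exposure
outcomes.  All tables are plain DataFrames written as CSV; a JSON manifest
records the seed, package version, and SHA-256 of every input.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .impute import ImputationConfig, code_dont_know_missing, mice_impute
from .infer import dunn_pairwise, kruskal_wallis, pooled_regression
from .questions import DONT_KNOW, MISSING, QuestionSchema, default_schemas
from .recall import build_food_lists, compute_exposure
from .score import recode_responses, score_codes, validate_monotonicity
from .synth import CohortSpec, default_food_dictionary, generate_cohort

logger = logging.getLogger(__name__)

OUTCOMES = ("weighted_servings", "total_grams")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(outdir: Path, seed: int, inputs: dict[str, Path] | None = None,
                   extra: dict | None = None) -> Path:
    manifest = {
        "package": "bpae",
        "version": __version__,
        "seed": seed,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in (inputs or {}).items()
        },
    }
    if extra:
        manifest.update(extra)
    path = Path(outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def simulate_to_dir(spec: CohortSpec, outdir: str | Path) -> dict[str, Path]:
    """Write questionnaire/recall CSVs and ground-truth JSON for a spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    questionnaire, recall, truth = generate_cohort(spec)
    paths = {
        "questionnaire": outdir / "questionnaire.csv",
        "recall": outdir / "recall_items.csv",
        "dictionary": outdir / "food_dictionary.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    questionnaire.to_csv(paths["questionnaire"], index=False)
    recall.to_csv(paths["recall"], index=False)
    default_food_dictionary().to_csv(paths["dictionary"], index=False)
    paths["ground_truth"].write_text(
        json.dumps(truth.to_dict(), indent=2) + "\n"
    )
    write_manifest(
        outdir,
        spec.seed,
        inputs={},
        extra={"cohort_spec": spec.to_dict(), "n_recall_rows": len(recall)},
    )
    return paths


def response_frequencies(
    questionnaire: pd.DataFrame, schemas: tuple[QuestionSchema, ...]
) -> pd.DataFrame:
    """Per-question response percentages (responders-only denominator)."""
    rows = []
    for s in schemas:
        col = questionnaire[s.key]
        blank = ((col == MISSING) | col.isna()).sum()
        dont_know = (col == DONT_KNOW).sum()
        answered = len(col) - blank - dont_know
        for cat in s.categories:
            n = int((col == cat).sum())
            rows.append(
                {
                    "question": s.key,
                    "text": s.text,
                    "response": cat,
                    "n": n,
                    "pct_of_responders": 100.0 * n / answered if answered else np.nan,
                }
            )
        rows.append(
            {
                "question": s.key,
                "text": s.text,
                "response": "(missing)",
                "n": int(blank),
                "pct_of_responders": np.nan,
            }
        )
        if dont_know:
            rows.append(
                {
                    "question": s.key,
                    "text": s.text,
                    "response": DONT_KNOW,
                    "n": int(dont_know),
                    "pct_of_responders": np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AnalysisReport:
    tables: dict[str, pd.DataFrame]
    summary: str
    seed: int
    warnings: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path, inputs: dict[str, Path] | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "summary.txt").write_text(self.summary)
        write_manifest(outdir, self.seed, inputs=inputs)


def analyze(
    questionnaire: pd.DataFrame,
    recall: pd.DataFrame,
    dictionary: pd.DataFrame | None = None,
    schemas: tuple[QuestionSchema, ...] | None = None,
    seed: int = 0,
    m: int = 5,
    mice_iterations: int = 10,
    dunn_family: list[tuple] | None = None,
    r2_method: str = "fisher_z",
) -> AnalysisReport:
    """Run the full questionnaire-vs-recall validation analysis."""
    schemas = default_schemas() if schemas is None else schemas
    dictionary = default_food_dictionary() if dictionary is None else dictionary
    caught: list[str] = []

    tables: dict[str, pd.DataFrame] = {}
    tables["response_frequencies"] = response_frequencies(questionnaire, schemas)

    lists = build_food_lists(dictionary)
    logger.info("food lists: %s", lists.counts)
    exposure = compute_exposure(recall, roster=questionnaire["participant_id"])
    summ_rows = []
    for col in OUTCOMES:
        v = exposure[col]
        summ_rows.append(
            {
                "outcome": col,
                "n": len(v),
                "median": float(v.median()),
                "iqr": float(v.quantile(0.75) - v.quantile(0.25)),
                "mean": float(v.mean()),
            }
        )
    tables["exposure_summary"] = pd.DataFrame(summ_rows)

    # composite score on complete cases
    cleaned = code_dont_know_missing(questionnaire)
    codes = recode_responses(cleaned, schemas)
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        bpae_table, pca = score_codes(codes, schemas)
        caught.extend(str(w.message) for w in wlist)
    tables["bpae_scores"] = bpae_table
    tables["pca_components"] = pd.DataFrame(
        pca.loadings, columns=pca.columns,
        index=[f"PC{i + 1}" for i in range(pca.k)],
    ).assign(variance_proportion=pca.pc_weights)

    merged_codes = codes.merge(bpae_table, on="participant_id")
    mono_table, mono_flags = validate_monotonicity(
        merged_codes["bpae"], merged_codes, schemas
    )
    mono_out = mono_table.copy()
    mono_out["monotone"] = mono_flags
    tables["monotonicity"] = mono_out.reset_index()

    # rank tests across BPAe groups
    grp = bpae_table.merge(exposure, on="participant_id")
    kw_rows, dunn_rows = [], []
    for col in OUTCOMES:
        try:
            kw = kruskal_wallis(grp[col], grp["bpae"])
        except ValueError as exc:
            caught.append(f"Kruskal-Wallis skipped for {col}: {exc}")
            continue
        kw_rows.append(
            {"outcome": col, "H": kw.h, "df": kw.df, "p": kw.p,
             "group_sizes": json.dumps({str(k): v for k, v in sorted(kw.group_sizes.items())})}
        )
        if kw.p < 0.05:
            for res in dunn_pairwise(grp[col], grp["bpae"], family=dunn_family):
                dunn_rows.append(
                    {"outcome": col, "pair": f"{res.pair[0]}-{res.pair[1]}",
                     "z": res.z, "p_raw": res.p_raw, "p_adjusted": res.p_adjusted,
                     "adjusted_alpha": res.adjusted_alpha}
                )
    tables["kruskal_wallis"] = pd.DataFrame(kw_rows)
    if dunn_rows:
        tables["dunn_pairwise"] = pd.DataFrame(dunn_rows)

    # multiply-imputed pooled regressions
    cfg = ImputationConfig(m=m, n_iterations=mice_iterations, seed=seed)
    imputed = mice_impute(codes, cfg)
    model_rows = []
    for col in OUTCOMES:
        try:
            pooled = pooled_regression(
                imputed.datasets, exposure, col, schemas, r2_method=r2_method
            )
        except ValueError as exc:
            caught.append(f"regression skipped for {col}: {exc}")
            continue
        tables[f"regression_{col}"] = pooled.table.reset_index(names="term")
        model_rows.append(
            {"outcome": col, "adj_r2": pooled.adj_r2, "F": pooled.f_stat,
             "df1": pooled.f_df1, "df2": pooled.f_df2, "p": pooled.f_p,
             "m": pooled.m}
        )
    tables["model_summary"] = pd.DataFrame(model_rows)

    lines = [
        f"bpae analysis (seed={seed}, n={len(questionnaire)} participants)",
        f"food lists: {lists.counts}",
        f"exposure medians: "
        + ", ".join(
            f"{r['outcome']}={r['median']:.2f} (IQR {r['iqr']:.2f})"
            for r in summ_rows
        ),
        f"BPAe: {pca.k} component(s) retained, variance proportions "
        + np.array2string(pca.pc_weights, precision=3),
        f"monotone questions: {int(mono_flags.sum())}/{len(mono_flags)}",
    ]
    for r in kw_rows:
        lines.append(f"Kruskal-Wallis {r['outcome']}: H={r['H']:.3f}, p={r['p']:.3f}")
    for r in model_rows:
        lines.append(
            f"pooled model {r['outcome']}: adj R2={r['adj_r2']:.4f}, "
            f"F({r['df1']:.0f}, {r['df2']:.1f})={r['F']:.3f}, p={r['p']:.3f}"
        )
    for w in caught:
        lines.append(f"WARNING: {w}")
    return AnalysisReport(
        tables=tables, summary="\n".join(lines) + "\n", seed=seed, warnings=caught
    )
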