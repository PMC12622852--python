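"""End-to-end study orchestration: simulate -> features -> score -> validate.

Each validation study (LoB, LoD, concordance, precision, interference) is run
as a fixed pipeline with per-stage seeds derived from one master seed, and
writes a manifest TSV, a feature matrix CSV, per-study report CSVs shaped
like the standard validation tables, and a JSON summary. Reruns with the same
config are byte-identical.

``verify_printed_tables`` recomputes every count-derived statistic of the
shipped reference validation-study counts through the estimators in
:mod:`valkit.stats` and checks them at printed precision.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .caller import (
    DEFAULT_CUTOFF,
    DEFAULT_PURITY_FLOOR,
    ModelArtifact,
    make_call,
    score_samples,
    select_cutoff,
    split_train_test,
    train_model,
)
from .features import FeatureConfig, feature_matrix, feature_names
from .genome import GenomeModel, build_genome
from .simulate import (
    ReplicateRecord,
    ScarParams,
    Specimen,
    generate_study_cohort,
    simulate_specimen,
)
from .stats import (
    ContingencyTable,
    concordance_ppa_npa,
    determine_lod,
    dilution_factor,
    adjusted_tp,
    interference_agreement,
    lob_fpr,
    majority_reference,
    repeatability,
    reproducibility,
    round_half_up,
    summarize_dilution_level,
    wilson_ci,
)

#: Reduced-scale design overrides for quick runs; published_scale=True restores
#: the published cohort sizes (5x12, 282, 22x36=792, 101+130, full plans).
REDUCED_DESIGNS = {
    "LOB": {},
    "LOD": {"replicates_per_level": (6, 6, 6, 6, 6)},
    "PRECISION": {"n_positive": 3, "n_negative": 3},
    "CONCORDANCE": {"n_lof_rev": 25, "n_hrr_wildtype": 30},
    "INTERFERENCE": {},
}


def _stage_seeds(seed: int, n: int = 6) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def simulate_training_cohort(
    genome: GenomeModel,
    params: ScarParams,
    n_per_class: int,
    seed: int,
    purity_range: tuple[float, float] = (0.2, 0.9),
) -> tuple[dict[str, Specimen], pd.Series]:
    """Simulate a labeled training cohort (observed profiles at native purity)."""
    from .simulate import decode_observed_profile

    rng = np.random.default_rng(seed)
    specimens: dict[str, Specimen] = {}
    labels = {}
    for i in range(2 * n_per_class):
        truth = "positive" if i < n_per_class else "negative"
        purity = float(rng.uniform(*purity_range))
        sp = simulate_specimen(
            genome, truth, params, purity, int(rng.integers(0, 2**31 - 1)),
            specimen_id=f"TRN{i + 1}",
        )
        sp.profile = decode_observed_profile(
            sp.profile, genome, purity, params.noise_sd,
            np.random.default_rng(int(rng.integers(0, 2**31 - 1))),
        )
        specimens[sp.specimen_id] = sp
        labels[sp.specimen_id] = 1 if truth == "positive" else 0
    return specimens, pd.Series(labels)


def train_pipeline_model(
    genome: GenomeModel,
    params: ScarParams,
    n_per_class: int = 60,
    seed: int = 0,
    target_sensitivity: float = 0.90,
    calibrate_cutoff: bool = True,
    feature_config: FeatureConfig | None = None,
) -> tuple[ModelArtifact, dict]:
    """Train the scar classifier on a synthetic cohort with a 7:3 split.

    Returns the artifact (cutoff calibrated to the target sensitivity on the
    held-out scores unless ``calibrate_cutoff=False``, which pins the
    conventional 0.7) and a metrics dict with the holdout AUC.
    """
    from sklearn.metrics import roc_auc_score

    fc = feature_config or FeatureConfig()
    specimens, labels = simulate_training_cohort(genome, params, n_per_class, seed)
    X = feature_matrix({s: sp.profile for s, sp in specimens.items()}, genome, fc)
    train_idx, test_idx = split_train_test(X, labels, ratio=0.7, seed=seed)
    model = train_model(X.loc[train_idx], labels.loc[train_idx], seed=seed)
    test_scores = score_samples(model, X.loc[test_idx])
    auc = float(roc_auc_score(labels.loc[test_idx], test_scores))
    if calibrate_cutoff:
        cutoff = select_cutoff(test_scores, labels.loc[test_idx], target_sensitivity)
        cutoff = float(np.clip(cutoff, 1e-6, 1 - 1e-6))
        model.cutoff = cutoff
    else:
        model.cutoff = DEFAULT_CUTOFF
    metrics = {
        "holdout_auc": auc,
        "cutoff": model.cutoff,
        "n_train": len(train_idx),
        "n_test": len(test_idx),
    }
    return model, metrics


def score_replicates(
    replicates: list[ReplicateRecord],
    model: ModelArtifact,
    genome: GenomeModel,
    feature_config: FeatureConfig | None = None,
    purity_floor: float = DEFAULT_PURITY_FLOOR,
) -> list[ReplicateRecord]:
    """Score QC-valid replicates and attach three-state calls in place."""
    fc = feature_config or FeatureConfig()
    valid = [r for r in replicates if r.qc_valid and r.observed_profile is not None]
    if valid:
        X = feature_matrix(
            {r.replicate_id: r.observed_profile for r in valid}, genome, fc
        )
        scores = score_samples(model, X)
        for r in valid:
            r.score = float(scores[r.replicate_id])
    for r in replicates:
        call = make_call(
            r.score, r.effective_purity, r.qc_valid, model.cutoff, purity_floor
        )
        r.score = call.score if call.reason != "qc_fail" else None
        r.call = call.status
        r.call_reason = call.reason
    return replicates


# ---------------------------------------------------------------------------
# per-study statistics


def _lob_report(replicates):
    overall = lob_fpr(replicates)
    rows = [
        {
            "analysis": "Overall",
            "specimen_id": "Overall",
            "fpr_pct": overall.pct(),
            "x": overall.x,
            "n": overall.n,
        }
    ]
    by_spec: dict[str, list] = {}
    for r in replicates:
        by_spec.setdefault(r.specimen_id, []).append(r)
    for sid in sorted(by_spec):
        ci = lob_fpr(by_spec[sid])
        rows.append(
            {
                "analysis": "Sample Level",
                "specimen_id": sid,
                "fpr_pct": ci.pct(),
                "x": ci.x,
                "n": ci.n,
            }
        )
    summary = {"fpr_pct": overall.pct(), "x": overall.x, "n": overall.n}
    return pd.DataFrame(rows), summary


def _lod_report(replicates, specimens):
    level_rows = []
    summaries = []
    by_spec_level: dict[tuple, list] = {}
    for r in replicates:
        by_spec_level.setdefault((r.specimen_id, r.dilution_level), []).append(r)
    for (sid, level), reps in sorted(by_spec_level.items()):
        sp = specimens[sid]
        adj = []
        for r in reps:
            if not r.qc_valid:
                continue
            try:
                f = dilution_factor(sp.vafs, r.observed_vafs)
            except ValueError:
                continue
            adj.append(adjusted_tp(sp.purity, f))
        summary = summarize_dilution_level(sid, level, reps, adj)
        summaries.append(summary)
        level_rows.append(
            {
                "specimen_id": sid,
                "dilution_level": level,
                "hit_rate_pct": summary.hit_rate.pct(),
                "hit_rate_lower_pct": summary.hit_rate.pct("lower"),
                "hit_rate_upper_pct": summary.hit_rate.pct("upper"),
                "n_hit": summary.n_hit,
                "n_valid": summary.n_valid,
                "avg_adjusted_tp_pct": round_half_up(summary.mean_adjusted_tp * 100.0),
            }
        )
    per_specimen, overall = determine_lod(summaries)
    summary = {
        "lod_adjusted_tp_pct": round_half_up(overall * 100.0),
        "per_specimen": {
            sid: {
                "determined": v["determined"],
                "level": v["level"],
                "adjusted_tp_pct": None
                if v["adjusted_tp"] is None
                else round_half_up(v["adjusted_tp"] * 100.0),
            }
            for sid, v in per_specimen.items()
        },
    }
    return pd.DataFrame(level_rows), summary


def _concordance_report(replicates, specimens):
    a = b = c = d = unk_pos = unk_neg = 0
    for r in replicates:
        truth_pos = specimens[r.specimen_id].biomarker_truth == "LOF_REV"
        if not r.qc_valid:
            continue  # QC-failed samples are excluded entirely
        if r.call == "unknown":
            unk_pos += truth_pos
            unk_neg += not truth_pos
        elif r.call == "positive":
            a += truth_pos
            b += not truth_pos
        else:
            c += truth_pos
            d += not truth_pos
    table = ContingencyTable(a, b, c, d, unk_pos, unk_neg)
    ppa, npa = concordance_ppa_npa(table)
    _, npa_unk = concordance_ppa_npa(table, include_unknown_in_npa=True)
    rows = pd.DataFrame(
        [
            {"statistic": "PPA", "x": ppa.x, "n": ppa.n, "pct": ppa.pct(),
             "lower_pct": ppa.pct("lower"), "upper_pct": ppa.pct("upper")},
            {"statistic": "NPA", "x": npa.x, "n": npa.n, "pct": npa.pct(),
             "lower_pct": npa.pct("lower"), "upper_pct": npa.pct("upper")},
            {"statistic": "NPA_with_unknowns", "x": npa_unk.x, "n": npa_unk.n,
             "pct": npa_unk.pct(), "lower_pct": npa_unk.pct("lower"),
             "upper_pct": npa_unk.pct("upper")},
        ]
    )
    summary = {
        "table": {"a": a, "b": b, "c": c, "d": d,
                  "unknown_pos": unk_pos, "unknown_neg": unk_neg},
        "ppa_pct": ppa.pct(),
        "npa_pct": npa.pct(),
        "npa_with_unknowns_pct": npa_unk.pct(),
    }
    return rows, summary


def _precision_report(replicates):
    per, pooled = reproducibility(replicates)
    repeat = repeatability(replicates)
    refs = {}
    by_spec: dict[str, list] = {}
    for r in replicates:
        by_spec.setdefault(r.specimen_id, []).append(r)
    for sid, reps in by_spec.items():
        refs[sid] = majority_reference(
            [r.call for r in reps if r.qc_valid and r.call in ("positive", "negative")]
        )
    rows = [
        {
            "row": "specimen",
            "specimen_id": sid,
            "reference_status": refs[sid],
            "x": ci.x,
            "n": ci.n,
            "reproducibility_pct": ci.pct(),
            "lower_pct": ci.pct("lower"),
            "upper_pct": ci.pct("upper"),
        }
        for sid, ci in sorted(per.items())
    ]
    for status in ("negative", "positive"):
        if status in pooled:
            ci = pooled[status]
            rows.append(
                {
                    "row": f"pooled_{status}",
                    "specimen_id": "Overall",
                    "reference_status": status,
                    "x": ci.x,
                    "n": ci.n,
                    "reproducibility_pct": ci.pct(),
                    "lower_pct": ci.pct("lower"),
                    "upper_pct": ci.pct("upper"),
                }
            )
    rows.append(
        {
            "row": "repeatability",
            "specimen_id": "Overall",
            "reference_status": "",
            "x": repeat.x,
            "n": repeat.n,
            "reproducibility_pct": repeat.pct(),
            "lower_pct": repeat.pct("lower"),
            "upper_pct": repeat.pct("upper"),
        }
    )
    summary = {
        "reproducibility_positive_pct": pooled["positive"].pct() if "positive" in pooled else None,
        "reproducibility_positive_n": pooled["positive"].n if "positive" in pooled else None,
        "reproducibility_negative_pct": pooled["negative"].pct() if "negative" in pooled else None,
        "reproducibility_negative_n": pooled["negative"].n if "negative" in pooled else None,
        "repeatability_pct": repeat.pct(),
        "repeatability_x": repeat.x,
        "repeatability_n": repeat.n,
    }
    return pd.DataFrame(rows), summary


def _interference_report(replicates):
    rows, overall = interference_agreement(replicates)
    summary = {
        "overall_agreement_pct": overall.pct(),
        "overall_x": overall.x,
        "overall_n": overall.n,
    }
    return rows, summary


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_study(
    study: str,
    seed: int,
    out_dir: str | Path,
    published_scale: bool = False,
    design_overrides: dict | None = None,
    params: ScarParams | None = None,
    model: ModelArtifact | None = None,
    genome: GenomeModel | None = None,
    n_train_per_class: int = 60,
    calibrate_cutoff: bool = False,
) -> dict:
    """Run one validation study end to end and write its report bundle.

    Writes ``manifest.tsv``, ``features.csv``, ``report.csv`` and
    ``summary.json`` under ``out_dir``. By default the positivity cutoff is
    the conventional 0.7; ``calibrate_cutoff=True`` recalibrates it to 90%
    sensitivity on the training holdout. Same config + seed -> byte-identical
    outputs.
    """
    study = study.upper()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = genome or build_genome()
    params = params or ScarParams()
    seeds = _stage_seeds(seed)
    stage = "train"
    try:
        if model is None:
            model, train_metrics = train_pipeline_model(
                genome, params, n_train_per_class, seeds[0],
                calibrate_cutoff=calibrate_cutoff,
            )
        else:
            train_metrics = {"holdout_auc": None, "cutoff": model.cutoff}
        stage = "simulate"
        design = {"study": study}
        if not published_scale:
            design.update(REDUCED_DESIGNS[study])
        design.update(design_overrides or {})
        specimens, replicates = generate_study_cohort(design, seeds[1], genome, params)
        stage = "score"
        replicates = score_replicates(replicates, model, genome)
        stage = "validate"
        if study == "LOB":
            report, summary = _lob_report(replicates)
        elif study == "LOD":
            report, summary = _lod_report(replicates, specimens)
        elif study == "CONCORDANCE":
            report, summary = _concordance_report(replicates, specimens)
        elif study == "PRECISION":
            report, summary = _precision_report(replicates)
        elif study == "INTERFERENCE":
            report, summary = _interference_report(replicates)
        else:
            raise ValueError(f"unknown study {study!r}")
        stage = "write"
        vio.write_manifest(replicates, out / "manifest.tsv")
        valid = [r for r in replicates if r.observed_profile is not None and r.qc_valid]
        X = feature_matrix(
            {r.replicate_id: r.observed_profile for r in valid}, genome
        )
        X.to_csv(out / "features.csv", float_format="%.6g", index_label="replicate_id")
        report.to_csv(out / "report.csv", index=False, float_format="%.6g")
        bundle = {
            "study": study,
            "seed": seed,
            "stage_seeds": seeds,
            "published_scale": published_scale,
            "cutoff": model.cutoff,
            "train": train_metrics,
            "n_replicates": len(replicates),
            "summary": summary,
        }
        (out / "summary.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
        return bundle
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise StageError(f"stage {stage!r} failed for study {study}: {exc}") from exc


# ---------------------------------------------------------------------------
# printed-table verification


def _parse_extra(extra: str) -> dict[str, int]:
    out = {}
    for part in str(extra).split(";"):
        if "=" in part:
            k, v = part.split("=")
            out[k] = int(v)
    return out


def default_counts_path() -> Path:
    """The shipped reference validation-study counts fixture."""
    return Path(resources.files("valkit") / "data" / "printed_counts.tsv")


def verify_printed_tables(counts_file: str | Path | None = None) -> pd.DataFrame:
    """Recompute every count-derived statistic and compare at printed precision.

    The fixture TSV carries the published validation-table counts (x/n pairs,
    the 2x2 concordance table, the per-specimen LoD values) plus the printed
    percentages and Wilson bounds. Each row is recomputed through
    :mod:`valkit.stats` and checked at two decimal places; the result frame
    has one row per target with computed values and a ``passed`` flag.
    """
    path = Path(counts_file) if counts_file else default_counts_path()
    df = pd.read_csv(path, sep="\t", dtype={"extra": str})
    results = []
    for row in df.itertuples(index=False):
        kind = row.kind
        if kind == "proportion":
            ci = wilson_ci(int(row.x), int(row.n))
        elif kind in ("ppa", "npa", "npa_with_unknowns"):
            counts = _parse_extra(row.extra)
            table = ContingencyTable(
                counts["a"], counts["b"], counts["c"], counts["d"],
                counts.get("unknown_pos", 0), counts.get("unknown_neg", 0),
            )
            ppa, npa = concordance_ppa_npa(
                table, include_unknown_in_npa=(kind == "npa_with_unknowns")
            )
            ci = ppa if kind == "ppa" else npa
        elif kind == "median":
            values = [float(v) for v in str(row.extra).split(",")]
            computed = float(np.median(values))
            passed = round_half_up(computed) == float(row.expected_pct)
            results.append(
                {
                    "target_id": row.target_id,
                    "computed_pct": round_half_up(computed),
                    "expected_pct": float(row.expected_pct),
                    "computed_lower_pct": None,
                    "expected_lower_pct": None,
                    "computed_upper_pct": None,
                    "expected_upper_pct": None,
                    "passed": bool(passed),
                }
            )
            continue
        else:
            raise ValueError(f"{row.target_id}: unknown kind {kind!r}")
        rec = {
            "target_id": row.target_id,
            "computed_pct": ci.pct(),
            "expected_pct": float(row.expected_pct),
            "computed_lower_pct": ci.pct("lower"),
            "expected_lower_pct": None if pd.isna(row.expected_lower_pct) else float(row.expected_lower_pct),
            "computed_upper_pct": ci.pct("upper"),
            "expected_upper_pct": None if pd.isna(row.expected_upper_pct) else float(row.expected_upper_pct),
        }
        ok = rec["computed_pct"] == rec["expected_pct"]
        if rec["expected_lower_pct"] is not None:
            ok = ok and rec["computed_lower_pct"] == rec["expected_lower_pct"]
        if rec["expected_upper_pct"] is not None:
            ok = ok and rec["computed_upper_pct"] == rec["expected_upper_pct"]
        rec["passed"] = bool(ok)
        results.append(rec)
    out = pd.DataFrame(results)
    return out


def verify_printed_tables_strict(counts_file: str | Path | None = None) -> pd.DataFrame:
    """Like :func:`verify_printed_tables` but raises on any failing target."""
    out = verify_printed_tables(counts_file)
    failed = out[~out["passed"]]
    if len(failed):
        diff = failed.to_string(index=False)
        raise AssertionError(f"printed-table verification failed:\n{diff}")
    return out
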