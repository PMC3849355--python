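"""Discovery -> signature -> multi-cohort validation orchestration.

Mirrors the study design the scoring method assumes: one discovery cohort
supplies the differential-expression tables and the grade-correlation
signature; every other cohort is scored with its own internal
standardization and median threshold, then tested for survival separation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .cohort import ExpressionCohort, GeneCatalog, read_cohort, subset_ion_channels
from .diffexp import differential_expression
from .grade import grade_screen
from .signature import RiskScoreResult, SignatureModel, build_signature, median_split, risk_scores
from .simulate import SimulationConfig, simulate_study
from .survival import CoxResult, cox_fit, encode_covariates, kaplan_meier, logrank_test, stratified_hazards

logger = logging.getLogger("ionsig")


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class StudyConfig:
    """Paths or simulation settings for one discovery + N validation cohorts."""

    discovery: object  # (expr_path, clinical_path) pair or SimulationConfig
    validations: tuple = ()
    alpha: float = 0.05
    fc_threshold: float = 1.25
    catalog_path: str | None = None
    output_dir: str = "ionsig_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.fc_threshold <= 0:
            raise PipelineError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        disc = raw["discovery"]
        if isinstance(disc, dict) and "expression" in disc:
            discovery = (disc["expression"], disc["clinical"])
        else:
            discovery = SimulationConfig(**(disc or {}))
        validations = []
        for v in raw.get("validations", []):
            if isinstance(v, dict) and "expression" in v:
                validations.append((v["expression"], v["clinical"]))
            else:
                validations.append(SimulationConfig(**(v or {})))
        return cls(
            discovery=discovery,
            validations=tuple(validations),
            alpha=float(raw.get("alpha", 0.05)),
            fc_threshold=float(raw.get("fc_threshold", 1.25)),
            catalog_path=raw.get("catalog"),
            output_dir=raw.get("output_dir", "ionsig_out"),
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class DiscoveryResult:
    de_p53: pd.DataFrame | None
    de_er: pd.DataFrame | None
    grade_records: pd.DataFrame
    signature: SignatureModel


@dataclass
class ValidationReport:
    per_cohort: dict[str, dict]
    report: pd.DataFrame  # cohort, n, events, hr, ci_low, ci_high, cox_p, logrank_chi2, logrank_p


def write_table(df: pd.DataFrame, path: str | Path, params: str = "") -> None:
    """Emit a TSV with an audit header naming the package version and parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# ionsig v{__version__} | {params}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_discovery(
    cohort: ExpressionCohort, alpha: float = 0.05, fc_threshold: float = 1.25
) -> DiscoveryResult:
    """Differential-expression screens plus the grade-derived signature.

    The p53 and ER screens run whenever the corresponding clinical fields
    carry at least two samples per level; the signature step requires grade.
    """
    de_p53 = de_er = None
    if cohort.clinical["p53_status"].notna().any():
        de_p53 = differential_expression(
            cohort, "p53_status", reference="wildtype", interest="mutant",
            alpha=alpha, fc_threshold=fc_threshold,
        )
    else:
        logger.info("%s: p53 status absent; p53 screen skipped", cohort.cohort_id)
    if cohort.clinical["er_status"].notna().any():
        de_er = differential_expression(
            cohort, "er_status", reference="negative", interest="positive",
            alpha=alpha, fc_threshold=fc_threshold,
        )
    else:
        logger.info("%s: ER status absent; ER screen skipped", cohort.cohort_id)
    if not cohort.clinical["grade"].notna().any():
        raise PipelineError(
            f"{cohort.cohort_id}: histological grade absent; cannot derive the signature"
        )
    records = grade_screen(cohort, alpha=alpha)
    signature = build_signature(records)
    return DiscoveryResult(
        de_p53=de_p53, de_er=de_er, grade_records=records, signature=signature
    )


def run_validation(
    signature: SignatureModel, cohorts: Sequence[ExpressionCohort]
) -> ValidationReport:
    """Score each cohort, split at its median, and test survival separation."""
    per_cohort: dict[str, dict] = {}
    rows = []
    for cohort in cohorts:
        cid = cohort.cohort_id
        try:
            scored = median_split(risk_scores(signature, cohort))
        except Exception as exc:  # no signature genes in cohort
            logger.error("%s: scoring failed: %s", cid, exc)
            rows.append({"cohort": cid, "error": str(exc)})
            continue
        clin = cohort.clinical
        ok = clin["time"].notna() & clin["event"].notna()
        pos = scored.labels[ok] == "positive"
        times, events = clin.loc[ok, "time"], clin.loc[ok, "event"].astype(int)
        chi2, logrank_p, _ = logrank_test(
            times[pos], events[pos], times[~pos], events[~pos]
        )
        design = pd.DataFrame({"ic30": pos.astype(float)})
        cox = cox_fit(times, events, design)
        km_pos = kaplan_meier(times[pos], events[pos])
        km_neg = kaplan_meier(times[~pos], events[~pos])
        per_cohort[cid] = {
            "scores": scored,
            "cox": cox,
            "km": {"positive": km_pos, "negative": km_neg},
            "logrank": (chi2, logrank_p),
        }
        s = cox.summary.loc["ic30"]
        rows.append(
            {
                "cohort": cid,
                "n": cox.n_used,
                "events": cox.n_events,
                "hr": s["hr"],
                "ci_low": s["ci_low"],
                "ci_high": s["ci_high"],
                "cox_p": s["p"],
                "logrank_chi2": chi2,
                "logrank_p": logrank_p,
            }
        )
    return ValidationReport(per_cohort=per_cohort, report=pd.DataFrame(rows))


def run_independence(
    cohort: ExpressionCohort,
    labels: pd.Series,
    covariates: Sequence[str] | None = None,
) -> tuple[CoxResult, pd.DataFrame]:
    """Multivariate Cox with clinical covariates plus the subgroup hazard table.

    Covariates without any known value are omitted with a log line rather
    than failing the whole model.
    """
    from .survival import DEFAULT_COVARIATES, _ENCODERS

    wanted = list(covariates or DEFAULT_COVARIATES)
    usable = []
    for cov in wanted:
        if cov == "ic30":
            usable.append(cov)
            continue
        fld = _ENCODERS[cov][0]
        if cohort.clinical[fld].notna().any():
            usable.append(cov)
        else:
            logger.info("%s: covariate %s entirely unknown; omitted", cohort.cohort_id, cov)
    design = encode_covariates(cohort.clinical, labels, covariates=tuple(usable))
    clin = cohort.clinical.loc[design.index]
    ok = clin["time"].notna() & clin["event"].notna()
    multivariate = cox_fit(
        clin.loc[ok, "time"], clin.loc[ok, "event"].astype(int), design.loc[ok]
    )
    strata = stratified_hazards(cohort, labels)
    return multivariate, strata


def km_long_table(report: ValidationReport) -> pd.DataFrame:
    """KM curves of every cohort/group in long format for external plotting."""
    rows = []
    for cid, res in report.per_cohort.items():
        for group, curve in res["km"].items():
            for t, s, r, d in zip(curve.event_times, curve.survival,
                                  curve.at_risk, curve.events):
                rows.append({"cohort": cid, "group": group, "time": t,
                             "survival": s, "at_risk": r, "events": d})
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> dict:
    """Full pipeline: load/simulate cohorts, discover, validate, write tables."""
    catalog = (
        GeneCatalog.from_tsv(config.catalog_path)
        if config.catalog_path
        else GeneCatalog.default()
    )
    sim_configs: dict[str, SimulationConfig] = {}
    path_cohorts: dict[str, tuple] = {}
    if isinstance(config.discovery, SimulationConfig):
        sim_configs["DISCOVERY"] = config.discovery
    else:
        path_cohorts["DISCOVERY"] = config.discovery
    for k, v in enumerate(config.validations, start=1):
        cid = f"VAL{k}"
        if isinstance(v, SimulationConfig):
            sim_configs[cid] = v
        else:
            path_cohorts[cid] = v

    cohorts: dict[str, ExpressionCohort] = {}
    if sim_configs:
        for cid, (cohort, _) in simulate_study(sim_configs).items():
            cohorts[cid] = cohort
    for cid, (expr, clin) in path_cohorts.items():
        cohorts[cid] = subset_ion_channels(read_cohort(expr, clin, cid), catalog)

    out = Path(config.output_dir)
    disc = run_discovery(cohorts["DISCOVERY"], config.alpha, config.fc_threshold)
    params = f"alpha={config.alpha} fc_threshold={config.fc_threshold} seed={config.seed}"
    if disc.de_p53 is not None:
        write_table(disc.de_p53.sort_values("p_adj"), out / "de_p53.tsv", params)
    if disc.de_er is not None:
        write_table(disc.de_er.sort_values("p_adj"), out / "de_er.tsv", params)
    write_table(disc.grade_records, out / "grade_screen.tsv", params)
    out.mkdir(parents=True, exist_ok=True)
    disc.signature.to_tsv(out / "signature.tsv")

    validation = run_validation(disc.signature, list(cohorts.values()))
    write_table(validation.report, out / "survival_report.tsv", params)
    write_table(km_long_table(validation), out / "km_curves.tsv", params)
    for cid, res in validation.per_cohort.items():
        scored: RiskScoreResult = res["scores"]
        df = pd.DataFrame({"sample_id": scored.scores.index,
                           "score": scored.scores.values,
                           "label": scored.labels.values})
        write_table(df, out / f"scores_{cid}.tsv", params)
    return {"discovery": disc, "validation": validation, "cohorts": cohorts}
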