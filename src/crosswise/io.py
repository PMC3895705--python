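"""File formats, run configuration and the end-to-end pipeline.

Surveys are delimited text (comma-separated, header row, UTF-8, empty field
for missing).  Configuration is a flat ``key = value`` text file.  The
pipeline is deterministic: all randomness flows from the single seed in the
run configuration, and rerunning an identical configuration reproduces the
machine-readable results byte for byte.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CrosswiseDesign, make_design
from .estimation import counts_from_survey, estimate_prevalence, cluster_robust_se
from .regression import ModelSpec, Term, fit_crosswise_logistic
from .simulate import study_population_spec, simulate_survey
from .tables import frequency_table

__all__ = [
    "RunConfig",
    "read_survey",
    "write_survey",
    "read_config",
    "write_config",
    "run_pipeline",
]

logger = logging.getLogger("crosswise")

RESULTS_SCHEMA_VERSION = 1
_VALID_ANSWERS = {"A", "B"}


def read_survey(path: str | Path, answer_col: str = "answer") -> pd.DataFrame:
    """Read a respondent-level survey from delimited text.

    The answer column accepts A/B case-insensitively and is normalised to
    upper case; empty fields become missing.  Malformed rows and unknown
    answer tokens raise with the offending line number (header = line 1).
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if answer_col not in header:
            raise ValueError(f"{path}: no {answer_col!r} column in header")
        width = len(header)
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != width:
                raise ValueError(
                    f"{path}: malformed row on line {lineno}: expected "
                    f"{width} fields, got {len(row)}")
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty data: no respondent rows")

    df = pd.DataFrame(rows, columns=header)
    df = df.replace("", np.nan)
    ans_idx = header.index(answer_col)
    normalised = df[answer_col].astype(str).str.upper()
    for i, token in enumerate(normalised):
        if token not in _VALID_ANSWERS:
            raise ValueError(
                f"{path}: unknown answer token {df[answer_col].iloc[i]!r} "
                f"on line {i + 2}")
    df[answer_col] = normalised
    if "cluster" in df.columns:
        df["cluster"] = pd.to_numeric(df["cluster"]).astype(int)
    n_missing = int(df.isna().sum().sum())
    logger.info("read %d respondents from %s (%d missing fields)",
                len(df), path, n_missing)
    return df


def write_survey(survey: pd.DataFrame, path: str | Path) -> None:
    """Write a survey as comma-separated text with empty fields for missing."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    survey.to_csv(path, index=False, na_rep="", lineterminator="\n")


# ---------------------------------------------------------------------------
# Flat key=value configuration
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file ('#' starts a comment)."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: malformed config line {lineno}: {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def write_config(cfg: dict, path: str | Path) -> None:
    lines = [f"{k} = {v}" for k, v in cfg.items() if v is not None]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; fully serialisable.

    ``terms`` maps regression covariate names to reference levels
    (``None`` = continuous).  When ``input`` is unset the pipeline
    simulates the canonical study fixture at ``seed``.
    """

    p: float
    seed: int = 0
    input: str | None = None
    outdir: str = "crosswise_report"
    level: float = 0.95
    ci_method: str = "wald"
    by: str = "sex"
    terms: dict[str, str | None] = field(default_factory=lambda: {"age": "18"})
    tabulate: tuple[str, ...] = ("sex", "age", "residence", "media")
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        make_design(self.p)  # fail fast on an invalid design

    def to_file(self, path: str | Path) -> None:
        cfg = asdict(self)
        cfg["terms"] = ",".join(f"{k}={v}" if v is not None else k
                                for k, v in self.terms.items())
        cfg["tabulate"] = ",".join(self.tabulate)
        write_config(cfg, path)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = read_config(path)
        if "p" not in raw:
            raise ValueError(f"{path}: config is missing the design parameter p")
        terms: dict[str, str | None] = {}
        for item in raw.get("terms", "age=18").split(","):
            item = item.strip()
            if not item:
                continue
            if "=" in item:
                k, v = item.split("=", 1)
                terms[k.strip()] = v.strip()
            else:
                terms[item] = None
        return cls(
            p=float(raw["p"]),
            seed=int(raw.get("seed", 0)),
            input=raw.get("input") or None,
            outdir=raw.get("outdir", "crosswise_report"),
            level=float(raw.get("level", 0.95)),
            ci_method=raw.get("ci_method", "wald"),
            by=raw.get("by", "sex"),
            terms=terms,
            tabulate=tuple(v.strip() for v in
                           raw.get("tabulate", "sex,age,residence,media").split(",")
                           if v.strip()),
            log_level=raw.get("log_level", "INFO"),
        )


def _estimate_rows(survey: pd.DataFrame, design: CrosswiseDesign,
                   cfg: RunConfig) -> list[dict]:
    have_clusters = "cluster" in survey.columns

    def one(counts, label):
        if have_clusters and counts.cluster_breakdown and len(counts.cluster_breakdown) >= 2:
            est = cluster_robust_se(counts, design, level=cfg.level)
        else:
            est = estimate_prevalence(counts, design, level=cfg.level,
                                      method=cfg.ci_method)
        return {"stratum": label, "n": est.n,
                "lambda_hat": round(est.lambda_hat, 10),
                "pi_hat": round(est.pi_hat, 10), "se": round(est.se, 10),
                "ci_low": round(est.ci_low, 10),
                "ci_high": round(est.ci_high, 10),
                "design_effect": (round(est.design_effect, 10)
                                  if est.design_effect is not None else None),
                "clipped": est.clipped}

    rows = [one(counts_from_survey(survey), "overall")]
    if cfg.by in survey.columns:
        for label, counts in counts_from_survey(survey, by=cfg.by).items():
            rows.append(one(counts, f"{cfg.by}={label}"))
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate/load -> estimate -> regress -> tabulate; write a report.

    Writes ``prevalence.csv``, ``regression.csv``, one ``freq_<var>.csv``
    per tabulated variable and a versioned ``results.json`` under
    ``config.outdir``, and returns the results dictionary.
    """
    logging.basicConfig(level=config.log_level)
    design = make_design(config.p)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.input is not None:
        survey = read_survey(config.input)
        logger.info("stage input: loaded %s", config.input)
    else:
        spec = study_population_spec(seed=config.seed)
        if abs(spec.design.p - config.p) > 1e-12:
            logger.warning("no input file: simulating the canonical fixture, "
                           "whose design has p=%.3g (config p=%.3g is used "
                           "for inference)", spec.design.p, config.p)
        survey, _truth = simulate_survey(spec)
        write_survey(survey, outdir / "survey.csv")
        logger.info("stage simulate: %d respondents", len(survey))

    try:
        prevalence = _estimate_rows(survey, design, config)
    except Exception as exc:
        raise RuntimeError(f"stage estimate failed: {exc}") from exc
    pd.DataFrame(prevalence).to_csv(outdir / "prevalence.csv", index=False,
                                    lineterminator="\n")

    results = {"schema_version": RESULTS_SCHEMA_VERSION,
               "p": config.p, "seed": config.seed,
               "n_respondents": int(len(survey)),
               "prevalence": prevalence}

    terms = tuple(Term(name, ref) for name, ref in config.terms.items()
                  if name in survey.columns)
    if terms:
        try:
            fit = fit_crosswise_logistic(
                survey, ModelSpec(response="answer", terms=terms, design=design))
        except Exception as exc:
            raise RuntimeError(f"stage regress failed: {exc}") from exc
        fit.or_table.round(10).to_csv(outdir / "regression.csv", index=False,
                                      lineterminator="\n")
        results["regression"] = {
            "converged": bool(fit.converged),
            "n_used": int(fit.n_used),
            "loglik": round(fit.loglik, 8),
            "or_table": fit.or_table.round(10).to_dict(orient="records"),
        }
        logger.info("stage regress: %d rows used, converged=%s",
                    fit.n_used, fit.converged)

    freq = {}
    for var in config.tabulate:
        if var not in survey.columns:
            continue
        table = frequency_table(survey, var, include_missing=True)
        table.to_frame().to_csv(outdir / f"freq_{var}.csv", index=False,
                                lineterminator="\n")
        freq[var] = [{"category": c, "count": int(k), "percent": p}
                     for c, k, p in table.rows]
    results["frequencies"] = freq

    with open(outdir / "results.json", "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("report written to %s", outdir)
    return results
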