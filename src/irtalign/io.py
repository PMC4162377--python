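"""Readers and writers: wide CSV/TSV responses in, JSON/TSV results out.

JSON artifacts carry full float precision and a schema version stamp;
TSV tables round floats to 6 significant digits for human reading.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .alignment import AlignmentOptions, AlignmentResult
from .data import DEFAULT_MISSING_CODES, ResponseData
from .estimation import ConfiguralFit, LRTResult, QuadratureSpec
from .report import InvarianceFlags, MeanRanking, NoninvarianceSummary
from .simulate import MCSummary, Perturbation, PopulationSpec

__all__ = [
    "SCHEMA_VERSION",
    "read_responses",
    "write_json",
    "read_json",
    "configural_to_dict",
    "configural_from_dict",
    "alignment_result_to_dict",
    "alignment_result_from_dict",
    "population_to_dict",
    "population_from_dict",
    "mc_summary_to_dict",
    "write_results",
]

SCHEMA_VERSION = "1"


def read_responses(
    path,
    missing_codes: Sequence = DEFAULT_MISSING_CODES,
    group_column: str = "group",
) -> ResponseData:
    """Read a wide delimited file: one row per respondent, `group` column.

    The delimiter is taken from the extension (.tsv means tab, anything
    else comma).  Cells other than 0, 1 or a missing code raise with the
    offending row and column named.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return ResponseData.from_dataframe(df, group_column=group_column, missing_codes=missing_codes)


def _jsonable(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, dict):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


def write_json(payload: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    body = {"schema_version": SCHEMA_VERSION}
    body.update(_jsonable(payload))
    path.write_text(json.dumps(body, indent=1, sort_keys=False) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def configural_to_dict(fit: ConfiguralFit) -> dict:
    return {
        "kind": "configural_fit",
        "groups": [str(g) for g in fit.groups],
        "items": fit.items,
        "loadings": fit.loadings,
        "thresholds": fit.thresholds,
        "loglik_by_group": fit.loglik_by_group,
        "group_sizes": fit.group_sizes,
        "link": fit.link,
        "n_quad": fit.quad.n_nodes,
        "cov_by_group": (
            None
            if fit.cov_by_group is None
            else [None if c is None else np.asarray(c) for c in fit.cov_by_group]
        ),
    }


def configural_from_dict(d: dict) -> ConfiguralFit:
    cov = d.get("cov_by_group")
    if cov is not None:
        cov = [None if c is None else np.asarray(c, dtype=float) for c in cov]
    return ConfiguralFit.from_params(
        groups=list(d["groups"]),
        items=list(d["items"]),
        loadings=np.asarray(d["loadings"], dtype=float),
        thresholds=np.asarray(d["thresholds"], dtype=float),
        group_sizes=list(d["group_sizes"]),
        link=d.get("link", "logit"),
        quad=QuadratureSpec(n_nodes=int(d.get("n_quad", 21))),
        cov_by_group=cov,
        loglik_by_group=np.asarray(d["loglik_by_group"], dtype=float),
    )


def alignment_result_to_dict(result: AlignmentResult) -> dict:
    return {
        "kind": "alignment_result",
        "groups": [str(g) for g in result.groups],
        "items": result.items,
        "identification": result.identification,
        "reference": str(result.reference),
        "alphas": result.alphas,
        "psis": result.psis,
        "loadings_aligned": result.loadings_aligned,
        "thresholds_aligned": result.thresholds_aligned,
        "loadings_configural": result.loadings_configural,
        "thresholds_configural": result.thresholds_configural,
        "weights": result.weights,
        "group_sizes": result.group_sizes,
        "loss": result.loss,
        "loss_loadings": result.loss_loadings,
        "loss_thresholds": result.loss_thresholds,
        "loss_by_item": result.loss_by_item,
        "loss_by_group": result.loss_by_group,
        "options": dataclasses.asdict(result.options),
        "start_losses": result.start_losses,
        "best_start": result.best_start,
        "x_opt": result.x_opt,
    }


def alignment_result_from_dict(d: dict) -> AlignmentResult:
    opts = dict(d["options"])
    return AlignmentResult(
        groups=list(d["groups"]),
        items=list(d["items"]),
        identification=d["identification"],
        reference=d["reference"],
        alphas=np.asarray(d["alphas"], dtype=float),
        psis=np.asarray(d["psis"], dtype=float),
        loadings_aligned=np.asarray(d["loadings_aligned"], dtype=float),
        thresholds_aligned=np.asarray(d["thresholds_aligned"], dtype=float),
        loadings_configural=np.asarray(d["loadings_configural"], dtype=float),
        thresholds_configural=np.asarray(d["thresholds_configural"], dtype=float),
        weights=np.asarray(d["weights"], dtype=float),
        group_sizes=np.asarray(d["group_sizes"], dtype=int),
        loss=float(d["loss"]),
        loss_loadings=float(d["loss_loadings"]),
        loss_thresholds=float(d["loss_thresholds"]),
        loss_by_item=np.asarray(d["loss_by_item"], dtype=float),
        loss_by_group=np.asarray(d["loss_by_group"], dtype=float),
        options=AlignmentOptions(**opts),
        start_losses=list(d["start_losses"]),
        best_start=int(d["best_start"]),
        x_opt=(None if d.get("x_opt") is None else np.asarray(d["x_opt"], dtype=float)),
    )


def population_to_dict(pop: PopulationSpec) -> dict:
    return {
        "kind": "population_spec",
        "groups": [str(g) for g in pop.groups],
        "items": pop.items,
        "loadings": pop.loadings,
        "thresholds": pop.thresholds,
        "alphas": pop.alphas,
        "psis": pop.psis,
        "link": pop.link,
        "reference_note": pop.reference_note,
        "perturbations": [dataclasses.asdict(p) for p in pop.perturbations],
    }


def population_from_dict(d: dict) -> PopulationSpec:
    return PopulationSpec(
        groups=list(d["groups"]),
        items=list(d["items"]),
        loadings=np.asarray(d["loadings"], dtype=float),
        thresholds=np.asarray(d["thresholds"], dtype=float),
        alphas=np.asarray(d["alphas"], dtype=float),
        psis=np.asarray(d["psis"], dtype=float),
        link=d.get("link", "logit"),
        perturbations=[Perturbation(**p) for p in d.get("perturbations", [])],
        reference_note=d.get("reference_note", ""),
    )


def mc_summary_to_dict(summary: MCSummary) -> dict:
    d = {
        "kind": "mc_summary",
        "n_reps": summary.n_reps,
        "n_failed": summary.n_failed,
        "correlations": summary.correlations,
        "mean_correlation": summary.mean_correlation,
        "correlation_bar": summary.correlation_bar,
        "meets_bar": summary.meets_bar,
        "bias_alphas": summary.bias_alphas,
        "rmse_alphas": summary.rmse_alphas,
        "bias_psis": summary.bias_psis,
        "rmse_psis": summary.rmse_psis,
        "bias_loadings": summary.bias_loadings,
        "rmse_loadings": summary.rmse_loadings,
        "bias_thresholds": summary.bias_thresholds,
        "rmse_thresholds": summary.rmse_thresholds,
        "converged": summary.converged,
    }
    if summary.coverage_alphas is not None:
        d["coverage_alphas"] = summary.coverage_alphas
    return d


def _fmt(x) -> str:
    if isinstance(x, (float, np.floating)):
        return f"{x:.6g}"
    return str(x)


def _write_tsv(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        out[col] = out[col].map(_fmt)
    out.to_csv(path, sep="\t", index=False)


def parameters_table(result: AlignmentResult) -> pd.DataFrame:
    rows = []
    for pi, item in enumerate(result.items):
        for gi, group in enumerate(result.groups):
            rows.append(
                {
                    "item": item,
                    "group": str(group),
                    "loading": result.loadings_aligned[pi, gi],
                    "threshold": result.thresholds_aligned[pi, gi],
                }
            )
    return pd.DataFrame(rows)


def distributions_table(result: AlignmentResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [str(g) for g in result.groups],
            "factor_mean": result.alphas,
            "factor_variance": result.psis,
        }
    )


def lrt_table(fits: Dict[str, object], tests: List[tuple]) -> pd.DataFrame:
    """Model summary plus likelihood-ratio comparisons.

    ``fits`` maps level name to a fit; ``tests`` is a list of
    (general_name, restricted_name, LRTResult).
    """
    rows = [
        {
            "model": name,
            "n_parameters": fit.n_free,
            "loglik": fit.loglik,
            "chi_square": "",
            "df": "",
            "p_value": "",
        }
        for name, fit in fits.items()
    ]
    for general, restricted, lrt in tests:
        rows.append(
            {
                "model": f"{restricted} against {general}",
                "n_parameters": "",
                "loglik": "",
                "chi_square": lrt.chisq,
                "df": lrt.df,
                "p_value": lrt.pvalue,
            }
        )
    return pd.DataFrame(rows)


def write_results(objects: dict, outdir) -> List[Path]:
    """Write each named object as JSON plus, where tabular, a TSV table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def emit_json(name, payload):
        path = outdir / f"{name}.json"
        write_json(payload, path)
        written.append(path)

    def emit_tsv(name, df):
        path = outdir / f"{name}.tsv"
        _write_tsv(df, path)
        written.append(path)

    for name, obj in objects.items():
        if isinstance(obj, ConfiguralFit):
            emit_json(name, configural_to_dict(obj))
        elif isinstance(obj, AlignmentResult):
            emit_json(name, alignment_result_to_dict(obj))
            emit_tsv(f"{name}_parameters", parameters_table(obj))
            emit_tsv(f"{name}_distributions", distributions_table(obj))
        elif isinstance(obj, PopulationSpec):
            emit_json(name, population_to_dict(obj))
        elif isinstance(obj, MCSummary):
            emit_json(name, mc_summary_to_dict(obj))
        elif isinstance(obj, InvarianceFlags):
            emit_json(
                name,
                {
                    "kind": "invariance_flags",
                    "alpha_level": obj.alpha_level,
                    "entries": {
                        f"{item}|{family}": {
                            "invariant": [str(g) for g in e.invariant],
                            "flagged": [str(g) for g in e.flagged],
                        }
                        for (item, family), e in sorted(obj.entries.items())
                    },
                },
            )
            emit_tsv(name, obj.to_dataframe())
        elif isinstance(obj, NoninvarianceSummary):
            emit_json(name, {"kind": "noninvariance_summary", **dataclasses.asdict(obj)})
        elif isinstance(obj, MeanRanking):
            emit_json(
                name,
                {
                    "kind": "mean_ranking",
                    "alpha_level": obj.alpha_level,
                    "bonferroni": obj.bonferroni,
                    "rows": [
                        {
                            "rank": r.rank,
                            "group": str(r.group),
                            "mean": r.mean,
                            "se": r.se,
                            "significantly_smaller": [str(g) for g in r.smaller],
                        }
                        for r in obj.rows
                    ],
                },
            )
            emit_tsv(name, obj.to_dataframe())
        elif isinstance(obj, pd.DataFrame):
            emit_tsv(name, obj)
        elif isinstance(obj, dict):
            emit_json(name, obj)
        else:
            raise TypeError(f"do not know how to write {type(obj).__name__} ({name})")
    return written
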