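"""Readers, writers and run configuration.

Data tables are delimited text (TSV by default) with columns
``time, observable, value, sigma``; results are written as JSON (machine
readable, both log10 and natural scale) plus TSV summaries (human
readable, natural scale to 3 significant digits).  Every run can write a
config fingerprint next to its outputs so identical configurations are
recognizably reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import Dataset, EstimationResult

__all__ = ["read_dataset", "write_dataset", "write_result", "write_profiles",
           "write_summary", "RunConfig"]


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_dataset(path, input_observables=(), model=None) -> Dataset:
    """Read a measurement table; validates sigmas and observable names.

    Errors name the offending line (1-based, header excluded).
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in Dataset.COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("time", "value", "sigma"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.where(coerced.isna() & df[col].notna())[0]
        if bad.size:
            raise ValueError(f"{path}: non-numeric {col!r} on line {bad[0] + 1}")
        df[col] = coerced
    bad = np.where(~(df["sigma"].to_numpy() > 0))[0]
    if bad.size:
        raise ValueError(f"{path}: non-positive sigma on line {bad[0] + 1}")
    if model is not None:
        unknown = set(df["observable"]) - set(model.observable_names)
        if unknown:
            raise ValueError(f"{path}: observables {sorted(unknown)} unknown to model {model.name!r}")
        if not input_observables:
            input_observables = model.input_observables
    return Dataset(df, input_observables=tuple(input_observables))


def write_dataset(dataset: Dataset, path) -> None:
    dataset.df.to_csv(path, sep=_sep_for(path), index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def _dump(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, cls=_NumpyEncoder)


def write_result(result: EstimationResult, path, config: "RunConfig | None" = None) -> None:
    """JSON dump of an estimation result (log10 + natural estimates,
    objective, start table, approach, optional config fingerprint)."""
    payload = {
        "approach": result.approach,
        "objective": result.objective_value,
        "lambda": result.objective.lam,
        "parameters": list(result.params.index),
        "estimates_log10": result.params.to_dict(),
        "estimates_natural": result.params_natural.to_dict(),
        "log10_flags": dict(zip(result.params.index,
                                map(bool, result.objective.free_log10))),
        "start_table": result.start_table.to_dict(orient="records"),
        "n_integration_failures": result.objective.n_failures,
    }
    if config is not None:
        payload["config"] = config.resolved()
        payload["fingerprint"] = config.fingerprint()
    _dump(payload, path)


def write_profiles(curves, path, tsv_path=None) -> None:
    """JSON per-parameter profile curves; optional TSV summary table
    (parameter, estimate, conf_lb, conf_ub — 'inf' marks open ends)."""
    _dump({c.parameter: c.to_dict() for c in curves}, path)
    if tsv_path is not None:
        rows = []
        for c in curves:
            est = 10.0 ** c.mle if c.is_log10 else c.mle
            rows.append({"parameter": c.parameter,
                         "estimate": float(f"{est:.3g}"),
                         "conf_lb": c.ci_lower, "conf_ub": c.ci_upper})
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False, float_format="%.3g")


def write_summary(summary, path, tsv_prefix=None) -> None:
    """JSON dump of a Monte-Carlo summary; optional TSV criterion tables."""
    _dump(summary.to_dict(), path)
    if tsv_prefix is not None:
        prefix = Path(tsv_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        tabs = {}
        for app in summary.estimates["approach"].unique():
            tabs[f"accuracy_{app}"] = summary.accuracy(app)
            tabs[f"precision_{app}"] = summary.precision(app)
        try:
            tabs["precision_ratio"] = summary.precision_ratio()
        except KeyError:
            pass
        pd.DataFrame(tabs).to_csv(f"{prefix}_criteria.tsv", sep="\t", float_format="%.4g")
        for app in summary.ci_table["approach"].unique():
            summary.coverage(app).to_csv(f"{prefix}_coverage_{app}.tsv", sep="\t",
                                         float_format="%.4g")
        summary.median_scores().to_csv(f"{prefix}_scores.tsv", sep="\t", float_format="%.4g")


@dataclass
class RunConfig:
    """Resolved configuration of one CLI run, hashable for reproducibility."""

    command: str
    model: str = "toy"
    data: str | None = None
    approach: str = "comprehensive"
    lam: str | float = "auto"
    n_starts: int = 1
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["extra"] = dict(sorted(self.extra.items()))
        return d

    def fingerprint(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write(self, path) -> None:
        _dump({"config": self.resolved(), "fingerprint": self.fingerprint()}, path)
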