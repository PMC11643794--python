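"""CSV / YAML I/O and the end-to-end pipeline.

Spectra CSVs have a ``sample_id`` first column and one column per wavenumber
(cm^-1, strictly monotone header).  ``run_pipeline`` glues the stages:
simulate (optional) -> preprocess -> ASCA -> PLS -> chemistry ANOVA, writing
the report bundle plus a run log with seeds, versions and a config hash.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, asca, chemistry, pls, synthetic
from .preprocess import SATURATION_THRESHOLD
from .preprocess import preprocess as preprocess_spectra

__all__ = [
    "SpectraParseError",
    "RunConfig",
    "read_spectra_csv",
    "write_spectra_csv",
    "run_pipeline",
]


class SpectraParseError(ValueError):
    """A spectra CSV violates the dialect (with the offending line where known)."""


def write_spectra_csv(spectra: pd.DataFrame, path) -> None:
    out = spectra.copy()
    out.index.name = "sample_id"
    out.to_csv(path, float_format="%.10g")


def read_spectra_csv(path) -> pd.DataFrame:
    """Read a spectra CSV; validates the grid, row ids and row lengths."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SpectraParseError(f"{path}: empty file") from None
        try:
            grid = np.array([float(h) for h in header[1:]])
        except ValueError as exc:
            raise SpectraParseError(f"{path}: line 1: non-numeric wavenumber header ({exc})") from None
        if len(grid) == 0:
            raise SpectraParseError(f"{path}: line 1: no wavenumber columns")
        diffs = np.diff(grid)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise SpectraParseError(f"{path}: line 1: wavenumber grid is not strictly monotone")

        ids, rows = [], []
        seen = {}
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise SpectraParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            sid = row[0]
            if sid in seen:
                raise SpectraParseError(
                    f"{path}: line {lineno}: duplicate row id {sid!r} (first at line {seen[sid]})"
                )
            seen[sid] = lineno
            try:
                rows.append([float(v) for v in row[1:]])
            except ValueError as exc:
                raise SpectraParseError(f"{path}: line {lineno}: non-numeric value ({exc})") from None
            ids.append(sid)

    return pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"), columns=grid)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on; serialisable to YAML."""

    spectra_path: str | None = None   # None -> simulate
    design_path: str | None = None
    chemistry_path: str | None = None
    simulate: bool = True
    seed: int = 1
    threshold: float = SATURATION_THRESHOLD
    permutations: int = 5000
    max_lv: int = 12
    out_dir: str = "oxispec_out"

    def validate(self) -> None:
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if not self.simulate:
            for name in ("spectra_path", "design_path", "chemistry_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} = {p!r} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        """Hash of the scientific parameters only; where outputs land doesn't
        change what was computed."""
        params = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(params, sort_keys=True).encode()
        ).hexdigest()[:12]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Artifacts: design/chemistry/spectra CSVs, effects table, temperature-effect
    loadings and spider scores, PLS metrics and per-LV curves, ANOVA tables,
    and ``run_log.yaml``.  Identical config + seed give identical outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = config.digest()

    if config.simulate:
        design, chem, spectra = _stage("simulate")(synthetic.simulate_dataset)(
            seed=config.seed
        )
    else:
        spectra = _stage("read")(read_spectra_csv)(config.spectra_path)
        design = pd.read_csv(config.design_path)
        chem = pd.read_csv(config.chemistry_path)

    design.to_csv(out / "design.csv", index=False)
    chem.to_csv(out / "chemistry.csv", index=False)
    write_spectra_csv(spectra, out / "spectra.csv")

    pre = _stage("preprocess")(preprocess_spectra)(spectra, config.threshold)

    effects = _stage("asca")(asca.effects_table)(
        pre, design, B=config.permutations, seed=config.seed
    )
    effects.insert(0, "config", tag)
    effects.to_csv(out / "effects_table.csv", index=False)

    decomp = asca.decompose(pre, design)
    temp_sca = asca.sca(decomp.effects["temp"], decomp.residual, "temp")
    pd.DataFrame(
        temp_sca.loadings.T, index=pre.matrix.columns, columns=[f"pc{i+1}" for i in range(temp_sca.n_components)]
    ).rename_axis("wavenumber").to_csv(out / "loadings_temp.csv")
    pd.DataFrame(
        temp_sca.spider_scores, index=pre.matrix.index,
        columns=[f"pc{i+1}" for i in range(temp_sca.n_components)],
    ).to_csv(out / "scores_temp.csv")

    metrics_rows, curves = [], []
    for resp in ("pv", "k232", "k268"):
        m = _stage("pls")(pls.crossval_material)(
            pre.values, chem[resp].to_numpy(), design, config.max_lv
        )
        metrics_rows.append(
            {"config": tag, "response": resp, "n_lv": m.n_lv, "rmsec": m.rmsec,
             "rmsecv": m.rmsecv, "r2_cal": m.r2_cal, "r2_cv": m.r2_cv,
             "bias": m.bias, "rpd": m.rpd}
        )
        c = m.per_lv_curves.copy()
        c.insert(0, "response", resp)
        curves.append(c)
    pls_metrics = pd.DataFrame(metrics_rows)
    pls_metrics.to_csv(out / "pls_metrics.csv", index=False)
    pd.concat(curves).to_csv(out / "pls_curves.csv", index=False)

    anova_rows = []
    for resp in ("pv", "k232", "k268"):
        a = _stage("anova")(chemistry.threeway_anova)(chem[resp].to_numpy(), design)
        t = a.table.copy()
        t.insert(0, "response", resp)
        anova_rows.append(t)
    pd.concat(anova_rows).to_csv(out / "anova.csv", index=False)

    log = {
        "config_hash": tag,
        "oxispec_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "permutations": config.permutations,
        "selected_lv": {r["response"]: int(r["n_lv"]) for r in metrics_rows},
        "retained_channels": int(pre.matrix.shape[1]),
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump({**log, "config": asdict(config)}, fh, sort_keys=False)

    return {"effects": effects, "pls_metrics": pls_metrics, "log": log, "out_dir": str(out)}
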