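"""File formats, configuration and the end-to-end pipeline.

Cohort tables are CSV with the exact header
``subject_id,age,sex,mvic,motion_outliers,brain_volume,session_order``
(missing MVIC as an empty field; sex as 0/1 or F/M).  Matrices travel as
whitespace/comma-delimited text (17 significant digits, lossless for
float64) or as HDF5 datasets; large subjects x edges fingerprint matrices
default to HDF5.  Every pipeline artifact is accompanied by a JSON
provenance record (config snapshot + seed) and reruns byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from ._rng import child_seed
from .connectome import PreprocessParams, build_fingerprint
from .cpm import CPM, CPMConfig
from .fingerprint import (
    FingerprintSet,
    Identification,
    differential_power,
    dp_threshold_mask,
    network_fractions,
    node_counts,
)
from .synthetic import (
    COHORT_COLUMNS,
    SynthConfig,
    simulate_cohort,
    simulate_session_runs,
)

__all__ = [
    "load_cohort",
    "save_cohort",
    "load_matrix",
    "save_matrix",
    "RunManifest",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger("conncpm")

_SEX_MAP = {"0": 0, "1": 1, "F": 0, "M": 1, "f": 0, "m": 1}


def load_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Empty MVIC fields become NaN (missing is never encoded as 0); sex is
    accepted as {0, 1} or {F, M} and mapped to 0 = female, 1 = male.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype={"subject_id": str, "sex": str})
    missing_cols = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"cohort file {path} lacks required column(s): {missing_cols}")
    try:
        sex = table["sex"].map(lambda s: _SEX_MAP[str(s).strip()])
    except KeyError as exc:
        raise ValueError(f"unrecognized sex code {exc} in {path}") from exc
    if set(table["sex"].astype(str).str.strip()) - {"0", "1"}:
        log.info("mapped F/M sex codes to 0/1 in %s", path)
    table["sex"] = sex.astype(int)
    for col in ("age", "mvic", "brain_volume"):
        try:
            table[col] = pd.to_numeric(table[col])
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(table[col], errors="coerce").isna() & table[col].notna()
            row = int(np.flatnonzero(bad)[0]) + 2 if bad.any() else "?"
            raise ValueError(f"non-numeric {col} in {path} at line {row}") from exc
    table["motion_outliers"] = table["motion_outliers"].astype(int)
    table["session_order"] = table["session_order"].astype(int)
    if table["subject_id"].duplicated().any():
        raise ValueError(f"duplicate subject ids in {path}")
    return table[list(COHORT_COLUMNS)]


def save_cohort(table: pd.DataFrame, path: str | Path) -> None:
    table[list(COHORT_COLUMNS)].to_csv(path, index=False, float_format="%.17g")


def load_matrix(path: str | Path, dataset: str | None = None) -> np.ndarray:
    """Load a dense matrix from delimited text or an HDF5 dataset."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        if dataset is None:
            raise ValueError("HDF5 input requires a dataset path")
        with h5py.File(path, "r") as f:
            return np.asarray(f[dataset])
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.replace(",", " ").split()
            if not parts:
                continue
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise ValueError(
                    f"ragged matrix in {path}: line {lineno} has {len(parts)} "
                    f"fields, expected {width}"
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise ValueError(f"non-numeric value in {path} at line {lineno}") from exc
    if not rows:
        raise ValueError(f"empty matrix file {path}")
    return np.array(rows)


def save_matrix(arr: np.ndarray, path: str | Path, dataset: str | None = None) -> None:
    """Write a matrix as text (%.17g, round-trip exact) or HDF5 (bit exact)."""
    path = Path(path)
    arr = np.asarray(arr, dtype=float)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        dataset = dataset or "matrix"
        with h5py.File(path, "a") as f:
            if dataset in f:
                del f[dataset]
            f.create_dataset(dataset, data=arr)
    else:
        np.savetxt(path, np.atleast_2d(arr), fmt="%.17g")


@dataclass
class RunManifest:
    """Paths to one subject/session's run and nuisance matrices."""

    subject_id: str
    session_label: str
    run_paths: list[str]
    nuisance_paths: list[str]
    parcellation_path: str | None = None
    cohort_path: str | None = None

    def validate(self) -> None:
        for p in [*self.run_paths, *self.nuisance_paths]:
            if not Path(p).exists():
                raise FileNotFoundError(f"manifest references missing file: {p}")
        if len(self.run_paths) != len(self.nuisance_paths):
            raise ValueError("one nuisance file per run required")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunManifest":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end synthetic analysis."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    cpm: CPMConfig = field(default_factory=CPMConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    dp_percentile: float = 99.5
    top_fraction: float = 0.03
    ident_n_perm: int = 1000
    cpm_fsts: tuple[float, ...] = (0.01, 0.005, 0.001)
    cpm_n_perm: int = 0       # full permutation CPM is expensive; opt in
    use_timeseries: bool = True
    output_dir: str = "conncpm-out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthConfig(**raw.pop("synth", {}))
        cpm = CPMConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in raw.pop("cpm", {}).items()})
        pre = PreprocessParams(**raw.pop("preprocess", {}))
        if "cpm_fsts" in raw:
            raw["cpm_fsts"] = tuple(raw["cpm_fsts"])
        return cls(synth=synth, cpm=cpm, preprocess=pre, **raw)

    def snapshot(self) -> dict:
        return _to_jsonable(dataclasses.asdict(self))


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(_to_jsonable(payload), indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Synthetic-mode end-to-end analysis.

    Simulate a cohort, build the two session fingerprint matrices (through
    the time-series pipeline, or directly from the latent session edges
    when ``use_timeseries`` is off), run identification + differential
    power, then CPM per session and FST.  Every stage writes its artifact
    plus a provenance JSON; rerunning the same config reproduces all
    outputs byte for byte.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    cfg = dataclasses.replace(config.synth, seed=seed)

    log.info("simulating cohort: %d subjects, %d ROIs", cfg.n_subjects, cfg.n_rois)
    latent = simulate_cohort(cfg)
    save_cohort(latent.cohort, out / "cohort.csv")
    _write_json(out / "truth.json", {
        "planted_edges": latent.planted_edges,
        "planted_weights": latent.planted_weights,
        "seed": seed,
        "config": config.snapshot(),
    })

    labels = ("ADT", "VDT")
    sets = []
    for k, label in enumerate(labels):
        if config.use_timeseries:
            rows = []
            for s in range(cfg.n_subjects):
                runs = simulate_session_runs(latent, s, k, seed=seed)
                rows.append(build_fingerprint(runs, config.preprocess))
            values = np.array(rows)
        else:
            values = latent.fingerprint_matrix(k)
        fset = FingerprintSet(values, latent.cohort["subject_id"].tolist(), label)
        save_matrix(values, out / "fingerprints.h5", dataset=label)
        sets.append(fset)
    _write_json(out / "fingerprints.json", {
        "n_rois": cfg.n_rois,
        "edge_ordering": "lower-triangle (i > j), row-major",
        "sessions": list(labels),
        "from_timeseries": config.use_timeseries,
        "seed": seed,
    })

    ident = Identification(sets[0], sets[1]).fit(
        n_perm=config.ident_n_perm, seed=child_seed(seed, "ident")
    )
    _write_json(out / "identification.json", {
        "accuracy_rowwise": ident.accuracy_rowwise,
        "accuracy_columnwise": ident.accuracy_columnwise,
        "permutation_p": ident.permutation_p,
        "null_mean": ident.permutation_null.mean() if ident.permutation_null is not None else None,
        "n_perm": config.ident_n_perm,
        "seed": seed,
    })

    dp = differential_power(sets[0], sets[1])
    mask = dp_threshold_mask(dp.dp, config.dp_percentile)
    table, top = node_counts(mask, latent.parcellation, config.top_fraction)
    fractions = network_fractions(mask, latent.parcellation)
    save_matrix(dp.dp[None, :], out / "dp.txt")
    table.to_csv(out / "dp_node_counts.csv", index=False)
    fractions.to_csv(out / "dp_network_fractions.csv", float_format="%.17g")
    _write_json(out / "dp.json", {
        "percentile": config.dp_percentile,
        "n_suprathreshold": int(mask.sum()),
        "top_rois": top,
        "seed": seed,
    })

    cpm_summary: dict[str, dict] = {}
    consistent: dict[str, dict[str, list]] = {}
    for k, label in enumerate(labels):
        consistent[label] = {}
        for fst in config.cpm_fsts:
            cpm_cfg = dataclasses.replace(config.cpm, fst=fst, seed=seed)
            model = CPM.from_dataframe(sets[k], latent.cohort, config=cpm_cfg)
            res = model.fit()
            if config.cpm_n_perm:
                res.permutation_test(n_perm=config.cpm_n_perm)
            key = f"{label}:fst={fst:g}"
            cpm_summary[key] = {
                **res.metrics,
                "permutation_p": res.permutation_p,
                "n_consistent_negative": res.consistent_negative.size,
                "n_consistent_positive": res.consistent_positive.size,
                "n_empty_folds": res.n_empty_folds,
            }
            consistent[label][f"{fst:g}"] = [
                res.consistent_positive, res.consistent_negative,
            ]
            pd.DataFrame({
                "subject_id": model.subject_ids,
                "predicted": res.predictions,
                "observed": res.observed,
            }).to_csv(out / f"cpm_predictions_{label}_fst{fst:g}.csv",
                      index=False, float_format="%.17g")
    intersection = {}
    for fst in config.cpm_fsts:
        key = f"{fst:g}"
        a_pos, a_neg = consistent[labels[0]][key]
        b_pos, b_neg = consistent[labels[1]][key]
        intersection[key] = {
            "positive": np.intersect1d(a_pos, b_pos),
            "negative": np.intersect1d(a_neg, b_neg),
        }
    _write_json(out / "cpm.json", {
        "metrics": cpm_summary,
        "consistent": {
            label: {fst: {"positive": v[0], "negative": v[1]}
                    for fst, v in per.items()}
            for label, per in consistent.items()
        },
        "intersection": intersection,
        "seed": seed,
    })

    report = render_report(ident, cpm_summary, intersection, fractions)
    (out / "report.txt").write_text(report)
    return {
        "identification": ident,
        "dp": dp,
        "cpm": cpm_summary,
        "report": report,
        "output_dir": str(out),
    }


def render_report(ident, cpm_summary: dict, intersection: dict,
                  fractions: pd.DataFrame) -> str:
    """Plain-text report: identification, metrics grid and feature counts."""
    lines = [ident.summary(), "", "Network fractions of suprathreshold DP edges:",
             fractions.round(3).to_string(), "", "CPM metrics (per session and FST):"]
    for key, m in sorted(cpm_summary.items()):
        lines.append(
            f"  {key:<18} r={m['r']:.3f} p={m['r_pvalue']:.4g} "
            f"R2={m['r_squared']:.3f} RMSE={m['rmse']:.1f} "
            f"neg={m['n_consistent_negative']} pos={m['n_consistent_positive']}"
        )
    lines.append("")
    lines.append("Cross-task intersection of consistent features:")
    for fst, sets in sorted(intersection.items()):
        lines.append(
            f"  FST {fst:<7} shared_neg={len(sets['negative'])} "
            f"shared_pos={len(sets['positive'])}"
        )
    return "\n".join(lines) + "\n"
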