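"""Readers/writers for connectome matrices, model files, and run configs.

Connectome matrices travel as dense delimited text (whitespace or comma),
the least surprising interchange format for SC/FC work; trained models and
BOLD series use HDF5.  Every reader re-validates the type invariants so a
file that loads is a file the pipeline can trust.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .types import (
    BOLDTimeseries,
    CoactivationStack,
    EvaluationReport,
    FunctionalConnectome,
    ScaleSet,
    StructuralConnectome,
    ValidationError,
)

logger = logging.getLogger("mklconn")


def _load_dense_text(path: Path) -> np.ndarray:
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    try:
        arr = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValidationError(f"{path}: cannot parse matrix ({exc})") from exc
    return arr


def _load_matrix(path: str | Path) -> tuple[np.ndarray, list[str] | None, str]:
    path = Path(path)
    if h5py.is_hdf5(path):
        with h5py.File(path, "r") as f:
            arr = np.asarray(f["weights"])
            labels = [s.decode() for s in f["labels"][()]] if "labels" in f else None
            subject_id = f.attrs.get("subject_id", "")
        return arr, labels, str(subject_id)
    arr = _load_dense_text(path)
    labels_path = path.with_suffix(".labels.txt")
    labels = None
    if labels_path.exists():
        labels = [ln.strip() for ln in labels_path.read_text().splitlines() if ln.strip()]
    return arr, labels, path.stem


def _check_square_finite(arr: np.ndarray, path) -> None:
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError(f"{path}: non-square matrix {arr.shape}")
    bad = np.argwhere(~np.isfinite(arr))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(f"{path}: non-finite entry at row {i}, col {j}")


def read_matrix(path: str | Path, expect: str) -> StructuralConnectome | FunctionalConnectome:
    """Read and validate an SC or FC matrix file (text or HDF5).

    ``expect="sc"`` symmetrizes and checks nonnegativity/degrees;
    ``expect="fc"`` checks symmetry, unit diagonal, and the [-1, 1] range,
    reporting the offending cell on failure.
    """
    arr, labels, subject_id = _load_matrix(path)
    _check_square_finite(arr, path)
    if expect == "sc":
        return StructuralConnectome.from_weights(arr, labels, subject_id=subject_id)
    if expect == "fc":
        over = np.argwhere(np.abs(arr) > 1.0 + 1e-6)
        if over.size:
            i, j = over[0]
            raise ValidationError(
                f"{path}: FC entry {arr[i, j]:.6g} at row {i}, col {j} "
                "outside [-1, 1]")
        return FunctionalConnectome.from_values(arr, subject_id=subject_id)
    raise ValidationError(f"expect must be 'sc' or 'fc', got {expect!r}")


def write_matrix(path: str | Path, matrix: np.ndarray,
                 labels: list[str] | None = None) -> None:
    """Write a dense matrix as whitespace-delimited text (+ label sidecar)."""
    path = Path(path)
    np.savetxt(path, np.asarray(matrix), fmt="%.12g")
    if labels is not None:
        path.with_suffix(".labels.txt").write_text("\n".join(labels) + "\n")


def save_model(path: str | Path, stack: CoactivationStack,
               region_labels: list[str] | None = None,
               training_ids: list[str] | None = None) -> None:
    """Serialize a trained co-activation stack to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("pi", data=stack.stacked)
        f.create_dataset("scales", data=stack.scale_set.scales)
        f.attrs["lambda"] = stack.lam
        f.attrs["n"] = stack.n
        f.attrs["m"] = stack.m
        if region_labels is not None:
            f.create_dataset("labels", data=np.array(region_labels, dtype="S"))
        if training_ids is not None:
            f.create_dataset("training_subjects",
                             data=np.array(training_ids, dtype="S"))


def load_model(path: str | Path) -> CoactivationStack:
    with h5py.File(path, "r") as f:
        stacked = np.asarray(f["pi"])
        scales = ScaleSet(np.asarray(f["scales"]))
        lam = float(f.attrs["lambda"])
    return CoactivationStack.from_stacked(stacked, scales, lam=lam)


def save_bold(path: str | Path, bold: BOLDTimeseries) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=bold.samples)
        f.attrs["tr"] = bold.tr


def load_bold(path: str | Path) -> BOLDTimeseries:
    with h5py.File(path, "r") as f:
        return BOLDTimeseries(samples=np.asarray(f["samples"]),
                              tr=float(f.attrs["tr"]))


def report_to_frame(report: EvaluationReport) -> pd.DataFrame:
    """EvaluationReport as a tidy table with a trailing summary row."""
    rows = [
        {"subject_id": sid, "protocol": report.protocol,
         "fold": (report.folds or {}).get(sid, 0), "correlation": corr}
        for sid, corr in report.per_subject.items()
    ]
    rows.append({"subject_id": "__mean__", "protocol": report.protocol,
                 "fold": -1, "correlation": report.mean_correlation})
    return pd.DataFrame(rows)


def write_report(path: str | Path, report: EvaluationReport) -> None:
    report_to_frame(report).to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Configuration for an end-to-end experiment run.

    All randomness flows from ``seed`` through named substreams; every
    artifact is stamped with the config hash and the seed.
    """

    out_dir: str = "mkl_run"
    sc_dir: str | None = None
    fc_dir: str | None = None
    m: int = 4
    lam: str | float = "auto"
    normalization: str = "symmetric_normalized"
    protocol: str = "kfold"
    k: int = 5
    n_perm: int = 250
    thresholds: list[float] = field(
        default_factory=lambda: [5, 10, 15, 20, 30, 40, 60, 80, 100])
    seed: int = 0
    synthetic: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def read_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def load_cohort_dir(sc_dir: str | Path, fc_dir: str | Path):
    """Pair up SC and FC files by sorted filename stem."""
    sc_paths = sorted(p for p in Path(sc_dir).iterdir()
                      if p.suffix in (".txt", ".csv", ".h5") and ".labels" not in p.name)
    fc_paths = sorted(p for p in Path(fc_dir).iterdir()
                      if p.suffix in (".txt", ".csv", ".h5") and ".labels" not in p.name)
    if len(sc_paths) != len(fc_paths):
        raise ValidationError(
            f"{len(sc_paths)} SC files vs {len(fc_paths)} FC files")
    pairs = []
    for sp, fp in zip(sc_paths, fc_paths):
        pairs.append((read_matrix(sp, "sc"), read_matrix(fp, "fc")))
    return pairs


def run_experiment(config: RunConfig) -> dict:
    """Orchestrate synth -> fit -> evaluate -> robustness per config.

    Without sc_dir/fc_dir a synthetic cohort is generated from
    ``config.synthetic``.  Per-subject failures are recorded and the run
    continues; the summary reports a nonzero ``n_failed`` in that case.
    Artifacts (model, report, summary) land in ``out_dir``.
    """
    from .evaluate import (cross_validate, mkl_model_factory, perturb_sc,
                           permute_pi_rows_test)
    from .kernels import build_kernel_bank, build_laplacian
    from .mkl import fit_mkl, predict_fc
    from .synthetic import SyntheticCohortSpec, generate_cohort
    from .types import Subject, TrainingCohort

    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    split_seed = int(np.random.default_rng(seeds[0]).integers(2**31))
    perm_seed = int(np.random.default_rng(seeds[1]).integers(2**31))

    failures: list[str] = []
    if config.sc_dir and config.fc_dir:
        pairs = load_cohort_dir(config.sc_dir, config.fc_dir)
        subjects = []
        for sc, fc in pairs:
            try:
                spec = build_laplacian(sc, config.normalization)
                from .kernels import default_scale_set
                scale_set = default_scale_set(spec, m=config.m)
                bank = build_kernel_bank(spec, scale_set, subject_id=sc.subject_id)
                subjects.append(Subject(sc.subject_id, sc, spec, bank, fc))
            except Exception as exc:  # partial-failure policy
                logger.error("subject %s failed: %s", sc.subject_id, exc)
                failures.append(sc.subject_id)
    else:
        spec_syn = SyntheticCohortSpec(seed=config.seed, m=config.m,
                                       **config.synthetic)
        subjects, _, _ = generate_cohort(spec_syn)

    cohort = TrainingCohort([(s.bank, s.fc) for s in subjects])
    stack = fit_mkl(cohort, lam=config.lam, seed=split_seed)
    save_model(out / "model.h5", stack,
               region_labels=subjects[0].sc.region_labels,
               training_ids=[s.subject_id for s in subjects])

    report = cross_validate(subjects, mkl_model_factory(lam=config.lam),
                            protocol=config.protocol, seed=split_seed,
                            k=config.k)
    write_report(out / "evaluation.tsv", report)

    null_scores = permute_pi_rows_test(stack, subjects,
                                       n_perm=min(config.n_perm, 50),
                                       seed=perm_seed)
    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": len(subjects),
        "n_failed": len(failures),
        "failed_subjects": failures,
        "protocol": config.protocol,
        "mean_correlation": report.mean_correlation,
        "std_correlation": report.std_correlation,
        "lambda": stack.lam,
        "pi_sparsity": stack.sparsity,
        "permuted_pi_mean_score": float(np.mean(null_scores)),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
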