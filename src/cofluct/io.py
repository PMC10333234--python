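"""Delimited-text readers/writers for runs, cohorts, and FC edge tables.

Everything on disk is plain text: tab-separated matrices with JSON sidecars
for metadata, so a cohort directory can be inspected with standard tools and
round-trips losslessly (to the printed float precision, which uses repr and
is therefore exact).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ets import FCMatrix
from .preprocess import ParcellatedRun
from .sc_coupling import SCMatrix
from .synthetic import CohortConfig, SyntheticCohort

_FMT = "%.17g"  # round-trips IEEE doubles exactly


def write_timeseries(run: ParcellatedRun, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, run.data, fmt=_FMT, delimiter="\t")
    meta = {"tr": run.tr, "subject_id": run.subject_id, "day": run.day,
            "encoding": run.encoding, "n_timepoints": run.n_timepoints,
            "n_parcels": run.n_parcels}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, sort_keys=True, indent=1) + "\n")


def load_timeseries(path: str | Path) -> ParcellatedRun:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {sidecar}")
    meta = json.loads(sidecar.read_text())
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    nan_rows, nan_cols = np.nonzero(np.isnan(data))
    if nan_rows.size:
        raise ValueError(
            f"{path}: NaN at row {int(nan_rows[0])}, column {int(nan_cols[0])}")
    return ParcellatedRun(data=data, tr=meta["tr"],
                          subject_id=meta["subject_id"], day=meta["day"],
                          encoding=meta["encoding"])


def _run_filename(key: tuple[str, int, str]) -> str:
    subject, day, enc = key
    return f"{subject}_day{day}_enc{enc}.tsv"


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> None:
    d = Path(directory)
    (d / "runs").mkdir(parents=True, exist_ok=True)
    (d / "fd").mkdir(exist_ok=True)
    (d / "sc").mkdir(exist_ok=True)
    for key, run in sorted(cohort.runs.items()):
        write_timeseries(run, d / "runs" / _run_filename(key))
        np.savetxt(d / "fd" / _run_filename(key), cohort.fd_series[key],
                   fmt=_FMT, delimiter="\t")
    cohort.phenotypes.to_csv(d / "phenotypes.tsv", sep="\t",
                             index_label="subject")
    cohort.confounds.to_csv(d / "confounds.tsv", sep="\t",
                            index_label="subject")
    for subject, sc in sorted(cohort.sc.items()):
        np.savetxt(d / "sc" / f"{subject}.tsv", sc.matrix, fmt=_FMT,
                   delimiter="\t")
    digest = hashlib.sha256()
    for subject in cohort.subjects:
        digest.update(np.ascontiguousarray(
            cohort.truth["sigma"][subject]).tobytes())
    manifest = {
        "subjects": cohort.subjects,
        "runs": [list(k) for k in sorted(cohort.runs)],
        "families": dict(sorted(cohort.families.items())),
        "config": {k: (list(map(list, v)) if k == "target_spec" else v)
                   for k, v in vars(cohort.config).items()},
        "truth_digest": digest.hexdigest(),
    }
    (d / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n")


def load_cohort(directory: str | Path) -> SyntheticCohort:
    """Read a cohort directory back. Ground truth is not persisted beyond its
    digest; the returned cohort carries an empty ``truth`` except that digest.
    """
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    cfg_dict = dict(manifest["config"])
    cfg_dict["target_spec"] = [tuple(t) for t in cfg_dict["target_spec"]]
    config = CohortConfig(**cfg_dict)
    runs = {}
    fd = {}
    for key_list in manifest["runs"]:
        key = (key_list[0], int(key_list[1]), key_list[2])
        runs[key] = load_timeseries(d / "runs" / _run_filename(key))
        fd[key] = np.loadtxt(d / "fd" / _run_filename(key), delimiter="\t")
    phenotypes = pd.read_csv(d / "phenotypes.tsv", sep="\t",
                             index_col="subject")
    confounds = pd.read_csv(d / "confounds.tsv", sep="\t", index_col="subject")
    sc = {s: SCMatrix(np.loadtxt(d / "sc" / f"{s}.tsv", delimiter="\t"))
          for s in manifest["subjects"]}
    return SyntheticCohort(
        config=config, runs=runs, fd_series=fd, phenotypes=phenotypes,
        confounds=confounds,
        families={k: int(v) for k, v in manifest["families"].items()},
        sc=sc, truth={"digest": manifest["truth_digest"]})


def write_fc_table(fcs: dict[str, FCMatrix], path: str | Path,
                   provenance: dict | None = None) -> None:
    """One edge-vector table per sampling spec: rows = subjects, columns 'i_j'."""
    path = Path(path)
    subjects = sorted(fcs)
    first = fcs[subjects[0]]
    cols = [f"{i}_{j}" for i, j in
            zip(*np.triu_indices(first.n_parcels, k=1))]
    table = pd.DataFrame([fcs[s].vec for s in subjects], index=subjects,
                         columns=cols)
    table.to_csv(path, sep="\t", index_label="subject")
    side = {"n_parcels": first.n_parcels, "subjects": subjects,
            "provenance": provenance or {}}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(side, sort_keys=True, indent=1) + "\n")


def load_fc_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    table = pd.read_csv(path, sep="\t", index_col="subject")
    meta = json.loads(
        path.with_suffix(path.suffix + ".json").read_text())
    return table, meta


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1,
                                     allow_nan=True) + "\n")
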