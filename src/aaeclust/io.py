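"""Reading and writing of on-disk artifacts.

On disk the score matrix is stored peaks-as-rows (the release convention
for peak-score tables, where features vastly outnumber samples); in memory
everything is samples x features.  Peak coordinates travel in a BED-style
sidecar aligned row-for-row with the matrix, with an optional 4th column
carrying the linked gene.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .datatypes import ClusterSolution, PeakMatrix, PeakRecord, SurvivalTable
from .errors import FormatError, ValidationError

__all__ = [
    "read_bed",
    "write_bed",
    "read_peak_matrix",
    "write_peak_matrix",
    "read_clinical",
    "write_clinical",
    "read_solution",
    "write_solution",
    "read_labels",
    "read_config",
]


def read_bed(path) -> list[PeakRecord]:
    """BED (3+ columns, 0-based half-open); optional 4th column = linked gene."""
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED rows need >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from exc
            gene = parts[3] if len(parts) > 3 and parts[3] not in ("", ".") else None
            records.append(PeakRecord(parts[0], start, end, gene))
    return records


def write_bed(peaks: list[PeakRecord], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            gene = p.linked_gene if p.linked_gene is not None else "."
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{gene}\n")


def _read_matrix_file(matrix_path: Path) -> tuple[np.ndarray, list[str] | None, list[str]]:
    """Returns (peaks x samples values, peak ids or None, sample ids)."""
    if matrix_path.suffix == ".mtx":
        values = scipy.io.mmread(matrix_path)
        if scipy.sparse.issparse(values):
            values = values.toarray()
        values = np.asarray(values, dtype=float)
        rownames = matrix_path.with_suffix(".rownames")
        colnames = matrix_path.with_suffix(".colnames")
        for sidecar in (rownames, colnames):
            if not sidecar.exists():
                raise FormatError(f"MatrixMarket sidecar {sidecar} is missing")
        peak_ids = rownames.read_text().split()
        sample_ids = colnames.read_text().split()
        if len(peak_ids) != values.shape[0] or len(sample_ids) != values.shape[1]:
            raise FormatError("row/column name files do not match matrix dimensions")
        return values, peak_ids, sample_ids
    with open(matrix_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise ValidationError(f"{matrix_path}: duplicate sample id in header")
    # round_trip parsing keeps write->read lossless at float64 precision
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    if df.isna().any().any():
        raise ValidationError(f"{matrix_path}: matrix contains missing values")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{matrix_path}: non-numeric matrix entry") from exc
    return values, [str(i) for i in df.index], [str(c) for c in df.columns]


def read_peak_matrix(matrix_path, bed_path) -> PeakMatrix:
    """Load a peaks-x-samples score file plus its BED sidecar.

    The BED rows must align 1:1 with the matrix rows; the returned matrix is
    transposed to samples x features with the file's feature order kept.
    """
    matrix_path = Path(matrix_path)
    values, _, sample_ids = _read_matrix_file(matrix_path)
    peaks = read_bed(bed_path)
    if len(peaks) != values.shape[0]:
        raise FormatError(
            f"BED has {len(peaks)} rows but matrix has {values.shape[0]} peak rows"
        )
    if np.isnan(values).any():
        raise ValidationError("matrix contains missing values")
    if (values < 0).any():
        raise ValidationError("matrix contains negative values")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError("duplicate sample id in matrix header")
    return PeakMatrix(values.T, sample_ids, peaks)


def write_peak_matrix(matrix: PeakMatrix, matrix_path, bed_path) -> None:
    """Write the TSV (peaks as rows, peak_id first column) and BED sidecar."""
    df = pd.DataFrame(
        matrix.values.T, index=matrix.peak_ids, columns=matrix.sample_ids
    )
    df.index.name = "peak_id"
    df.to_csv(matrix_path, sep="\t")
    write_bed(matrix.peaks, bed_path)


_DEAD = {"dead", "deceased", "1"}
_ALIVE = {"alive", "living", "0"}


def read_clinical(path) -> SurvivalTable:
    """Assemble follow-up from a clinical TSV.

    Expected columns: sample_id, vital_status, days_to_death,
    days_to_last_followup; any further columns become covariates, tagged
    continuous when fully numeric and categorical otherwise.  Time is
    days_to_death for dead samples and days_to_last_followup otherwise;
    event = 1 iff dead.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "vital_status", "days_to_death", "days_to_last_followup"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    sample_ids, times, events = [], [], []
    for _, row in df.iterrows():
        sid = row["sample_id"]
        status = str(row["vital_status"]).strip().lower()
        dead = status in _DEAD
        if not dead and status not in _ALIVE:
            raise ValidationError(f"sample {sid}: unrecognized vital status {status!r}")
        field = "days_to_death" if dead else "days_to_last_followup"
        raw = row[field]
        if pd.isna(raw) or str(raw).strip() == "":
            # fall back to the other field before giving up
            other = "days_to_last_followup" if dead else "days_to_death"
            raw = row[other]
        if pd.isna(raw) or str(raw).strip() == "":
            raise ValidationError(f"sample {sid}: no usable follow-up time")
        try:
            t = float(raw)
        except ValueError as exc:
            raise ValidationError(f"sample {sid}: non-numeric time {raw!r}") from exc
        sample_ids.append(sid)
        times.append(t)
        events.append(1 if dead else 0)
    cov_cols = [c for c in df.columns if c not in required]
    covariates = pd.DataFrame(index=range(len(df)))
    types: dict[str, str] = {}
    for c in cov_cols:
        numeric = pd.to_numeric(df[c], errors="coerce")
        if numeric.notna().all():
            covariates[c] = numeric.to_numpy()
            types[c] = "continuous"
        else:
            covariates[c] = df[c].to_numpy()
            types[c] = "categorical"
    return SurvivalTable(sample_ids, np.array(times), np.array(events), covariates, types)


def write_clinical(table: SurvivalTable, path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "vital_status": np.where(table.event == 1, "dead", "alive"),
            "days_to_death": np.where(table.event == 1, table.time, np.nan),
            "days_to_last_followup": np.where(table.event == 0, table.time, np.nan),
        }
    )
    for c in table.covariates.columns:
        df[c] = table.covariates[c].to_numpy()
    df.to_csv(path, sep="\t", index=False)


def write_solution(solution: ClusterSolution, path) -> None:
    """TSV with sample_id, 1-based C-prefixed label, and max posterior."""
    with open(path, "w") as fh:
        fh.write("sample_id\tcluster_label\tmax_posterior\n")
        post = solution.posteriors
        for i, (sid, name) in enumerate(zip(solution.sample_ids, solution.label_names())):
            p = float(post[i].max()) if post is not None else float("nan")
            fh.write(f"{sid}\t{name}\t{p:.6g}\n")


def read_solution(path) -> ClusterSolution:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if df.empty:
        return ClusterSolution([], np.empty(0, dtype=int))
    labels = []
    for name in df["cluster_label"]:
        if not (isinstance(name, str) and name.startswith("C")):
            raise FormatError(f"malformed cluster label {name!r}")
        labels.append(int(name[1:]) - 1)
    return ClusterSolution(list(df["sample_id"]), np.array(labels))


def read_labels(path) -> tuple[list[str], np.ndarray]:
    """Generic two-column (sample_id, label) file for external comparisons."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need sample_id and label columns")
    return list(df.iloc[:, 0]), df.iloc[:, 1].to_numpy()


def read_config(path) -> dict:
    """YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    loaded = yaml.safe_load(text)
    if not isinstance(loaded, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return loaded
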