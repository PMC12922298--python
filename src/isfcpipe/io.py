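"""Readers and writers for the on-disk dialects.

Time series travel as tab-separated T x R tables with a header row of
region labels; confounds as tab-separated tables with fMRIPrep-dialect
column names (``trans_x`` ... ``rot_z``, ``csf``, ``white_matter``,
``framewise_displacement``, ``std_dvars``, ``cosine00`` ...); cohorts are
tied together by a JSON manifest mapping subject ids to group labels and
file paths.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import (
    MOTION_COLUMNS,
    ConfoundTable,
    build_dct_basis,
    framewise_displacement,
)
from .synthetic import SyntheticDataset

FLOAT_FMT = "%.10g"


class ParseError(ValueError):
    pass


def write_timeseries(path, data: np.ndarray, region_labels: list[str]) -> None:
    df = pd.DataFrame(np.asarray(data, dtype=float), columns=region_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timeseries_table(path) -> tuple[np.ndarray, list[str]]:
    """Read a T x R tab-separated table; header row = region labels.

    Rejects NaN cells, non-numeric cells, ragged rows, and duplicate
    region labels, reporting 1-based line numbers where possible.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    # check the raw header: pandas would silently rename duplicates
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ParseError(f"{path}: duplicate region labels: {', '.join(dupes)}")
    try:
        df = pd.read_csv(path, sep="\t", header=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed table: {exc}") from exc
    labels = [str(c) for c in df.columns]
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ParseError(
                f"{path}: non-numeric value in column {col!r} at line {line}"
            )
    if df.isna().any().any():
        col = df.columns[df.isna().any().values][0]
        row = int(df[df[col].isna()].index[0])
        raise ParseError(
            f"{path}: NaN in column {col!r} at line {row + 2}"
        )
    return df.to_numpy(dtype=float), labels


def write_confounds(path, confounds: ConfoundTable) -> None:
    """Write a confound table in the fMRIPrep dialect.

    Following fMRIPrep, the first-row framewise displacement and
    standardized DVARS (undefined for the first frame) are written as
    ``n/a``.
    """
    cols: dict[str, np.ndarray] = {}
    for i, name in enumerate(MOTION_COLUMNS):
        cols[name] = confounds.motion[:, i]
    cols["csf"] = confounds.csf_signal
    cols["white_matter"] = confounds.wm_signal
    cols["framewise_displacement"] = confounds.fd
    cols["std_dvars"] = confounds.std_dvars
    for k in range(confounds.cosine_basis.shape[1]):
        cols[f"cosine{k:02d}"] = confounds.cosine_basis[:, k]
    df = pd.DataFrame(cols)
    df = df.astype(object)
    df.loc[0, "framewise_displacement"] = "n/a"
    df.loc[0, "std_dvars"] = "n/a"
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_confounds(
    path, tr_seconds: float | None = None
) -> ConfoundTable:
    """Read an fMRIPrep-dialect confound table.

    Missing cosine columns are tolerated (the basis can be rebuilt when
    ``tr_seconds`` is given); missing motion, ``csf`` or ``white_matter``
    columns are fatal.  ``n/a`` in the first framewise-displacement /
    DVARS row parses as 0 per the FD convention; a missing
    ``framewise_displacement`` column is recomputed from motion.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    required = list(MOTION_COLUMNS) + ["csf", "white_matter"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing required confound columns: {', '.join(missing)}"
        )
    t = len(df)
    motion = df[list(MOTION_COLUMNS)].to_numpy(dtype=float)
    if np.isnan(motion).any():
        raise ParseError(f"{path}: NaN in motion parameters")
    cosine_cols = sorted(c for c in df.columns if c.startswith("cosine"))
    if cosine_cols:
        cosine = df[cosine_cols].to_numpy(dtype=float)
    elif tr_seconds is not None:
        cosine = build_dct_basis(t, tr_seconds)
    else:
        cosine = np.empty((t, 0))
    if "framewise_displacement" in df.columns:
        fd = df["framewise_displacement"].to_numpy(dtype=float)
        fd[0] = 0.0 if np.isnan(fd[0]) else fd[0]
        if np.isnan(fd).any():
            raise ParseError(f"{path}: NaN in framewise_displacement")
    else:
        fd = framewise_displacement(motion)
    if "std_dvars" in df.columns:
        dvars = df["std_dvars"].to_numpy(dtype=float)
        dvars[0] = 0.0 if np.isnan(dvars[0]) else dvars[0]
    else:
        dvars = np.zeros(t)
    return ConfoundTable(
        motion=motion,
        wm_signal=df["white_matter"].to_numpy(dtype=float),
        csf_signal=df["csf"].to_numpy(dtype=float),
        cosine_basis=cosine,
        fd=fd,
        std_dvars=dvars,
    )


def write_matrix(path, matrix: np.ndarray, region_labels: list[str]) -> None:
    """Write an R x R matrix as a labelled tab-separated table."""
    pd.DataFrame(
        np.asarray(matrix, dtype=float),
        index=region_labels,
        columns=region_labels,
    ).to_csv(path, sep="\t", float_format="%.10g")


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise ParseError(f"{path}: row labels do not match column labels")
    return df.to_numpy(dtype=float), labels


def write_dataset(dataset: SyntheticDataset, outdir) -> Path:
    """Write all subjects, confounds, and the cohort manifest.

    Returns the manifest path.  Layout::

        outdir/
          sub-NT01_timeseries.tsv
          sub-NT01_confounds.tsv
          ...
          manifest.json
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "region_labels": dataset.region_labels,
        "tr_seconds": dataset.config.tr_seconds,
        "seed": dataset.config.seed,
        "subjects": {},
    }
    for sub in dataset.subjects:
        ts = outdir / f"{sub.subject_id}_timeseries.tsv"
        cf = outdir / f"{sub.subject_id}_confounds.tsv"
        write_timeseries(ts, sub.data, dataset.region_labels)
        write_confounds(cf, dataset.confounds[sub.subject_id])
        manifest["subjects"][sub.subject_id] = {
            "group": sub.group,
            "timeseries": ts.name,
            "confounds": cf.name,
        }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest_path


def read_manifest(manifest_path) -> dict:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    manifest["_dir"] = manifest_path.parent
    return manifest


def load_cohort(
    manifest: dict,
) -> list[tuple[str, str, np.ndarray, ConfoundTable]]:
    """Load (subject_id, group, series, confounds) for every subject.

    Region-label headers must agree across all subjects in the manifest.
    """
    base = Path(manifest["_dir"])
    expected = manifest["region_labels"]
    tr = manifest.get("tr_seconds")
    out = []
    for sid, entry in manifest["subjects"].items():
        data, labels = read_timeseries_table(base / entry["timeseries"])
        if labels != expected:
            raise ParseError(
                f"subject {sid}: region labels disagree with the manifest"
            )
        confounds = read_confounds(base / entry["confounds"], tr_seconds=tr)
        out.append((sid, entry["group"], data, confounds))
    return out


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
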