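"""Connectome construction, study file layout, and missing-data screening.

Connectomes are estimated from parcellated BOLD time series by
residualizing each region's series against a confound design (ordinary
least squares with intercept), standardizing the residuals, and
correlating regions pairwise.  The default confound set is the six rigid
motion parameters plus CSF and white-matter signals and their temporal
derivatives (16 columns); temporal derivatives are first-order backward
differences with 0 at the first timepoint.

Study layout on disk (all TSV, UTF-8, empty string or ``n/a`` = missing):

* ``sessions.tsv`` — one row per session; columns ``subject_id``,
  ``dataset_id``, ``session_id``, ``hc_use``, ``cycle_day``, ``e2``,
  ``p4``, ``mean_fd``.
* ``adjacency/<subject>_<session>.tsv`` — square matrix with a header row
  and an index column of region labels.
* ``regions.tsv`` — optional; columns ``region_id`` (0-based),
  ``region_name``, ``network_name``.
* ``ground_truth.json`` — optional; planted masks and coefficients when
  the study is synthetic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import Connectome, Study, edge_index, n_edges

logger = logging.getLogger(__name__)

__all__ = [
    "timeseries_to_connectome",
    "vectorize",
    "unvectorize",
    "save_study",
    "load_study",
    "load_ground_truth",
    "missingness_report",
    "MissingnessReport",
    "temporal_derivative",
    "default_confound_columns",
]

#: fMRIPrep-dialect confound columns used by default (derivatives are
#: added automatically when absent).
MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
TISSUE_COLUMNS = ("csf", "white_matter")


def temporal_derivative(x: np.ndarray) -> np.ndarray:
    """First-order backward difference, 0 at the first timepoint."""
    d = np.zeros_like(np.asarray(x, dtype=float))
    d[1:] = np.diff(np.asarray(x, dtype=float), axis=0)
    return d


def default_confound_columns(confounds: pd.DataFrame) -> pd.DataFrame:
    """Select the default 16-column confound design from an fMRIPrep table.

    Six motion parameters + CSF + WM and their temporal derivatives;
    ``*_derivative1`` columns are taken from the table when present and
    computed otherwise.
    """
    base = list(MOTION_COLUMNS + TISSUE_COLUMNS)
    missing = [c for c in base if c not in confounds.columns]
    if missing:
        raise ValueError(f"confound table lacks expected columns: {missing}")
    out = {}
    for c in base:
        out[c] = confounds[c].to_numpy(dtype=float)
        dname = f"{c}_derivative1"
        if dname in confounds.columns:
            d = confounds[dname].to_numpy(dtype=float)
            d = np.nan_to_num(d, nan=0.0)  # fMRIPrep leaves row 0 as n/a
        else:
            d = temporal_derivative(out[c])
        out[dname] = d
    return pd.DataFrame(out)


def _drop_collinear(X: np.ndarray, names: list[str]) -> np.ndarray:
    """Greedily drop columns that are exact linear combinations of others."""
    keep: list[int] = []
    for k in range(X.shape[1]):
        cand = X[:, keep + [k]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(k)
        else:
            logger.warning("dropping exactly collinear confound column %r", names[k])
    return X[:, keep]


def _residualize_standardize(series: np.ndarray, confounds: np.ndarray | None,
                             names: list[str]) -> np.ndarray:
    T, n = series.shape
    if confounds is None or confounds.size == 0:
        X = np.ones((T, 1))
    else:
        if confounds.shape[0] != T:
            raise ValueError(
                f"series has {T} timepoints but confounds have "
                f"{confounds.shape[0]} rows"
            )
        X = np.column_stack([np.ones(T), confounds])
        X = _drop_collinear(X, ["intercept"] + names)
    if T < X.shape[1] + 2:
        raise ValueError(
            f"too few timepoints ({T}) for {X.shape[1]} confound columns"
        )
    beta, *_ = np.linalg.lstsq(X, series, rcond=None)
    resid = series - X @ beta
    sd = resid.std(axis=0)
    if np.any(sd == 0):
        dead = np.flatnonzero(sd == 0)
        raise ValueError(f"region {dead[0]} has zero residual variance")
    return (resid - resid.mean(axis=0)) / sd


def timeseries_to_connectome(series, confounds=None, censor=None) -> Connectome:
    """Confound-regressed Pearson-correlation connectome.

    Parameters
    ----------
    series
        Timepoints × regions table (DataFrame with region-label columns,
        or array), or a list of such tables — one per rest run.  Runs are
        residualized separately and their residual series concatenated
        before the single correlation step.
    confounds
        Timepoints × k table (or list matching ``series``).  ``None``
        means intercept-only (mean removal).
    censor
        Optional boolean array (or list) flagging high-motion volumes to
        drop before regression.
    """
    runs = series if isinstance(series, (list, tuple)) else [series]
    conf_runs = confounds if isinstance(confounds, (list, tuple)) else [confounds] * len(runs)
    cens_runs = censor if isinstance(censor, (list, tuple)) else [censor] * len(runs)
    if len(conf_runs) != len(runs) or len(cens_runs) != len(runs):
        raise ValueError("series, confounds and censor must have matching run counts")

    labels: list[str] | None = None
    pieces = []
    for ser, conf, cens in zip(runs, conf_runs, cens_runs):
        if isinstance(ser, pd.DataFrame):
            run_labels = [str(c) for c in ser.columns]
            Y = ser.to_numpy(dtype=float)
        else:
            Y = np.asarray(ser, dtype=float)
            run_labels = [f"region{k:03d}" for k in range(Y.shape[1])]
        if labels is None:
            labels = run_labels
        elif run_labels != labels:
            raise ValueError("region labels differ between runs")
        if np.isnan(Y).any():
            raise ValueError("time series contain missing values")
        names: list[str] = []
        if conf is None:
            C = None
        elif isinstance(conf, pd.DataFrame):
            names = [str(c) for c in conf.columns]
            C = conf.to_numpy(dtype=float)
        else:
            C = np.asarray(conf, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            names = [f"confound{k}" for k in range(C.shape[1])]
        if cens is not None:
            keep = ~np.asarray(cens, dtype=bool)
            Y = Y[keep]
            C = None if C is None else C[keep]
        pieces.append(_residualize_standardize(Y, C, names))
    resid = np.vstack(pieces)
    mat = np.corrcoef(resid, rowvar=False)
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 1.0)
    assert labels is not None
    return Connectome(labels=labels, matrix=mat)


def vectorize(connectome: Connectome) -> np.ndarray:
    """Canonical upper-triangle (i<j, row-major) edge vector."""
    return connectome.edge_vector


def unvectorize(edges: np.ndarray, labels: list[str]) -> Connectome:
    """Rebuild a symmetric connectome (unit diagonal) from an edge vector."""
    n = len(labels)
    edges = np.asarray(edges, dtype=float)
    if edges.shape != (n_edges(n),):
        raise ValueError(
            f"edge vector of length {edges.size} does not match "
            f"{n} regions (expected {n_edges(n)})"
        )
    iu, ju = edge_index(n)
    mat = np.eye(n)
    mat[iu, ju] = edges
    mat[ju, iu] = edges
    return Connectome(labels=list(labels), matrix=mat)


# ---------------------------------------------------------------------------
# Study layout


def save_study(study: Study, directory, ground_truth: dict | None = None) -> Path:
    """Write the standard study layout (see module docstring)."""
    directory = Path(directory)
    (directory / "adjacency").mkdir(parents=True, exist_ok=True)
    study.sessions.to_csv(directory / "sessions.tsv", sep="\t", index=False, na_rep="")
    for row, conn in zip(study.sessions.itertuples(), study.connectomes):
        pd.DataFrame(conn.matrix, index=conn.labels, columns=conn.labels).to_csv(
            directory / "adjacency" / f"{row.subject_id}_{row.session_id}.tsv",
            sep="\t",
        )
    if study.regions is not None:
        study.regions.to_csv(directory / "regions.tsv", sep="\t", index=False)
    if ground_truth is not None:
        (directory / "ground_truth.json").write_text(json.dumps(ground_truth, indent=1))
    return directory


def load_study(directory) -> Study:
    """Load a study directory written by :func:`save_study`."""
    directory = Path(directory)
    sessions = pd.read_csv(
        directory / "sessions.tsv", sep="\t", na_values=["", "n/a"],
        keep_default_na=True, dtype={"subject_id": str, "dataset_id": str,
                                     "session_id": str},
    )
    connectomes = []
    ref_labels: list[str] | None = None
    for row in sessions.itertuples():
        path = directory / "adjacency" / f"{row.subject_id}_{row.session_id}.tsv"
        if not path.exists():
            raise FileNotFoundError(
                f"no adjacency matrix for session "
                f"{row.subject_id}/{row.session_id} (expected {path.name})"
            )
        table = pd.read_csv(path, sep="\t", index_col=0)
        labels = [str(c) for c in table.columns]
        if ref_labels is None:
            ref_labels = labels
        elif labels != ref_labels:
            raise ValueError(
                f"region labels in {path.name} differ from the first session"
            )
        connectomes.append(Connectome(labels=labels, matrix=table.to_numpy(dtype=float)))
    regions = None
    if (directory / "regions.tsv").exists():
        regions = pd.read_csv(directory / "regions.tsv", sep="\t")
    return Study(sessions=sessions, connectomes=connectomes, regions=regions)


def load_ground_truth(directory) -> dict:
    return json.loads((Path(directory) / "ground_truth.json").read_text())


# ---------------------------------------------------------------------------
# Missingness screening


@dataclass
class MissingnessReport:
    """Per-subject missing proportions and missing-at-random screening.

    ``proportions``: subjects × variables table of missing fractions.
    ``correlations``: long table with one row per (missing-indicator,
    other-variable) pair — point-biserial r (Pearson against the 0/1
    missing indicator), its p-value, and the sample size.
    ``degenerate``: variables that are entirely missing, for which the
    correlations are undefined.
    """

    proportions: pd.DataFrame
    correlations: pd.DataFrame
    degenerate: list[str]


def missingness_report(
    sessions: pd.DataFrame,
    variables: tuple[str, ...] = ("hc_use", "cycle_day", "e2", "p4", "mean_fd"),
) -> MissingnessReport:
    """Screen study variables for non-random missingness.

    For every variable with at least one missing and one observed value,
    the 0/1 missingness indicator is correlated with every *other*
    variable's observed values (point-biserial correlation).  Variables
    with no missing values get proportion 0 and no correlation rows.
    """
    variables = tuple(v for v in variables if v in sessions.columns)
    if len(variables) < 2:
        raise ValueError("need at least two variables to screen")
    prop = (
        sessions.groupby("subject_id")[list(variables)]
        .apply(lambda g: g.isna().mean())
    )
    rows = []
    degenerate = []
    for var in variables:
        ind = sessions[var].isna().to_numpy()
        if ind.all():
            degenerate.append(var)
            continue
        if not ind.any():
            continue
        for other in variables:
            if other == var:
                continue
            vals = sessions[other].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            if ok.sum() < 3 or len(set(ind[ok])) < 2 or np.nanstd(vals[ok]) == 0:
                continue
            r, p = stats.pointbiserialr(ind[ok].astype(int), vals[ok])
            rows.append(
                {"missing_variable": var, "other_variable": other,
                 "r": r, "p": p, "n": int(ok.sum())}
            )
    correlations = pd.DataFrame(
        rows, columns=["missing_variable", "other_variable", "r", "p", "n"]
    )
    return MissingnessReport(
        proportions=prop, correlations=correlations, degenerate=degenerate
    )
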