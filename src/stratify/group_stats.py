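"""Repeated-measures comparison of tumor ICG curves across strains.

Each animal contributes one normalized tumor time course; the strain is
the grouping covariate. The estimator here is a documented simplified
repeated-measures analysis built from subject-level summaries:

* per-strain mean curves on a common (downsampled) time grid,
* the response covariance over time, pooled from between-subject
  deviations around their strain means (its diagonal, projected on the
  time axis, shows *when* strains differ most),
* estimated marginal means (EMM): the time-averaged subject means per
  strain, with unequal-n standard errors from the pooled subject-level
  error variance, and
* a Tukey-Kramer multiplicity-adjusted p-value matrix on the EMMs via the
  studentized-range distribution.

The original analysis fit a full mixed-effects model with time-varying
covariates whose random-effects structure is unspecified; this module
reproduces the same output objects (covariance matrix, diagonal
projection, adjusted p-matrix) with a fully specified computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

from .datatypes import InvalidArgumentError

logger = logging.getLogger(__name__)

DEFAULT_N_TIMEPOINTS = 1400


@dataclass
class RepeatedMeasuresResult:
    timepoints: np.ndarray  # common time grid (seconds)
    strains: list
    group_means: pd.DataFrame  # strain x time
    response_covariance: np.ndarray  # time x time, PSD
    diag_projection: np.ndarray
    emm: pd.Series  # per-strain estimated marginal mean
    emm_se: pd.Series
    group_sizes: pd.Series
    df_error: int


def fit_repeated_measures(
    series_matrix: np.ndarray,
    strains,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
    fps: float = 10.6,
) -> RepeatedMeasuresResult:
    """Fit the simplified repeated-measures summary.

    Parameters
    ----------
    series_matrix : ndarray (subjects, frames)
        Per-animal normalized tumor series, already on a common frame
        count (the common prefix of the cohort).
    strains : sequence of str
        Strain label per subject.
    n_timepoints : int
        Target grid size; the common prefix is uniformly decimated to it.

    Strains with a single subject are excluded with a warning; at least
    two strains with >= 2 subjects are required.
    """
    X = np.asarray(series_matrix, dtype=float)
    strains = np.asarray(list(strains))
    if X.ndim != 2 or X.shape[0] != strains.size:
        raise InvalidArgumentError("series_matrix must be (subjects, frames)")
    n_frames = X.shape[1]
    if n_timepoints > n_frames:
        n_timepoints = n_frames
    step = max(n_frames // n_timepoints, 1)
    idx = np.arange(n_timepoints) * step
    X = X[:, idx]
    times = idx / fps

    keep_strains = []
    for s in pd.unique(strains):
        n_s = int((strains == s).sum())
        if n_s < 2:
            logger.warning("excluding strain %s with a single subject", s)
        else:
            keep_strains.append(s)
    if len(keep_strains) < 2:
        raise InvalidArgumentError("need >= 2 strains with >= 2 subjects")
    mask = np.isin(strains, keep_strains)
    X = X[mask]
    strains = strains[mask]

    group_means = {}
    deviations = []
    subj_means = X.mean(axis=1)
    emm, emm_dev_ss, sizes = {}, {}, {}
    for s in keep_strains:
        sel = strains == s
        group_means[s] = X[sel].mean(axis=0)
        deviations.append(X[sel] - group_means[s][None, :])
        m = subj_means[sel]
        emm[s] = float(m.mean())
        emm_dev_ss[s] = float(((m - m.mean()) ** 2).sum())
        sizes[s] = int(sel.sum())

    D = np.vstack(deviations)  # (subjects, time)
    n_subjects = D.shape[0]
    n_groups = len(keep_strains)
    df_error = n_subjects - n_groups
    if df_error <= 0:
        raise InvalidArgumentError("no error degrees of freedom")
    cov = D.T @ D / df_error
    cov = (cov + cov.T) / 2.0  # enforce exact symmetry

    pooled_var = sum(emm_dev_ss.values()) / df_error
    emm_se = {s: float(np.sqrt(pooled_var / sizes[s])) for s in keep_strains}

    return RepeatedMeasuresResult(
        timepoints=times,
        strains=list(keep_strains),
        group_means=pd.DataFrame(group_means, index=times).T,
        response_covariance=cov,
        diag_projection=np.diag(cov).copy(),
        emm=pd.Series(emm),
        emm_se=pd.Series(emm_se),
        group_sizes=pd.Series(sizes),
        df_error=df_error,
    )


def tukey_kramer_matrix(
    emm: pd.Series,
    emm_se: pd.Series,
    group_sizes: pd.Series,
    df_error: int,
) -> pd.DataFrame:
    """Pairwise Tukey-Kramer adjusted p-values on the estimated marginal means.

    q_ij = |emm_i - emm_j| / sqrt((se_i^2 + se_j^2) / 2), with p from the
    studentized-range distribution with (n_groups, df_error) parameters.
    The matrix is symmetric with a unit diagonal. With two groups the
    adjusted p equals the pooled-variance two-sample t-test p (the
    studentized range reduces to sqrt(2)|t|).
    """
    if df_error <= 0:
        raise InvalidArgumentError("df_error must be positive")
    groups = list(emm.index)
    k = len(groups)
    if k < 2:
        raise InvalidArgumentError("need >= 2 groups")
    P = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt((emm_se.iloc[i] ** 2 + emm_se.iloc[j] ** 2) / 2.0)
            if se == 0:
                p = 1.0 if emm.iloc[i] == emm.iloc[j] else 0.0
            else:
                q = abs(emm.iloc[i] - emm.iloc[j]) / se
                p = float(studentized_range.sf(q, k, df_error))
            P[i, j] = P[j, i] = p
    return pd.DataFrame(P, index=groups, columns=groups)


def compare_strain_curves(
    records,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
) -> tuple[RepeatedMeasuresResult, pd.DataFrame]:
    """Convenience wrapper: cohort records -> fit + adjusted p-matrix.

    Normalizes each animal's tumor series to [0, 1], truncates everything
    to the common prefix and runs the repeated-measures comparison.
    """
    if not records:
        raise InvalidArgumentError("no records")
    n_common = min(rec.tumor.n for rec in records)
    X = np.vstack([rec.tumor.normalized().values[:n_common] for rec in records])
    strains = [rec.group for rec in records]
    fps = records[0].tumor.fps
    res = fit_repeated_measures(X, strains, n_timepoints=n_timepoints, fps=fps)
    pmat = tukey_kramer_matrix(res.emm, res.emm_se, res.group_sizes, res.df_error)
    return res, pmat
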