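"""Treatment-signature PCA across receptors and trafficking parameters.

Rows are cell line x treatment; columns are receptor x parameter, filled
either with posterior-mean log10 parameter values (mode ``param_means``)
or with predicted single-parameter lysate fold changes (mode
``fold_change``).  Parameters whose treated posterior overlaps the
control posterior by more than 25% are considered unchanged and reset to
the control mean (or a fold change of 1) before analysis.  Columns are
z-scored within each cell line's row block, blocks are concatenated, and
a column-centred SVD gives scores, loadings and explained variance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .predict import overlap_fraction, posterior_mean_params, \
    single_param_substitution
from .priors import PARAM_NAMES

__all__ = ["build_matrix", "zscore_by_cellline", "run_pca", "VariableMatrix"]


class VariableMatrix:
    """Tidy wrapper: a (cell line x treatment) by (rtk x parameter)
    DataFrame plus the per-cell overlap annotations."""

    def __init__(self, frame: pd.DataFrame, overlaps: pd.DataFrame | None = None):
        self.frame = frame
        self.overlaps = overlaps

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)


def build_matrix(fits: dict, mode: str = "param_means",
                 overlap_cut: float = 0.25, control_name: str = "control",
                 fraction: float = 0.10, seed: int = 0,
                 horizon: float = 1440.0) -> VariableMatrix:
    """Assemble the PCA variable matrix from per-condition fits.

    ``fits`` maps (cell_line, treatment, rtk) -> FitResult (every
    treatment must include ``control_name`` for each cell line / rtk).
    Mode ``param_means``: cells are posterior-mean log10 parameters.
    Mode ``fold_change``: cells are predicted lysate fold changes from
    one-at-a-time substitution of treated into control means.  A cell
    whose control-vs-treated posterior overlap exceeds ``overlap_cut`` is
    reset to the control mean / 1.0; ``overlap_cut=0`` disables the
    replacement rule entirely.
    """
    if mode not in ("param_means", "fold_change"):
        raise ValueError("mode must be 'param_means' or 'fold_change'")
    keys = sorted(fits)
    cell_lines = sorted({k[0] for k in keys})
    treatments = sorted({k[1] for k in keys})
    rtks = sorted({k[2] for k in keys})
    missing = [(cl, tr, r) for cl in cell_lines for tr in treatments
               for r in rtks if (cl, tr, r) not in fits]
    if missing:
        raise ValueError(f"missing fitted conditions: {missing}")

    columns = [f"{r}:{p}" for r in rtks for p in PARAM_NAMES]
    rows, overlap_rows, index = [], [], []
    draw = 0
    for cl in cell_lines:
        for tr in treatments:
            vals, ovs = [], []
            for r in rtks:
                ctrl = fits[(cl, control_name, r)]
                trt = fits[(cl, tr, r)]
                ctrl_S = ctrl.kinetic_samples()
                trt_S = trt.kinetic_samples()
                ctrl_mean = ctrl_S.mean(axis=0)
                if mode == "fold_change":
                    rt0 = ctrl.posterior.data.rt0_ref
                    attr = single_param_substitution(
                        posterior_mean_params(ctrl_S),
                        posterior_mean_params(trt_S), rt0, horizon)
                for j, p in enumerate(PARAM_NAMES):
                    if tr == control_name:
                        ov = 0.5
                    else:
                        n_sub = max(1, int(round(fraction * ctrl_S.shape[0])))
                        rng = np.random.default_rng([seed, draw])
                        ci = rng.choice(ctrl_S.shape[0], n_sub, replace=False)
                        ti = rng.choice(trt_S.shape[0], n_sub, replace=False)
                        ov = overlap_fraction(ctrl_S[ci, j], trt_S[ti, j],
                                              seed=seed + draw)
                    draw += 1
                    unchanged = (overlap_cut > 0 and tr != control_name
                                 and ov > overlap_cut)
                    if mode == "param_means":
                        v = ctrl_mean[j] if unchanged else trt_S.mean(axis=0)[j]
                    else:
                        if tr == control_name:
                            v = 1.0
                        else:
                            v = 1.0 if unchanged else attr.fold_changes[p]
                    vals.append(v)
                    ovs.append(ov)
            rows.append(vals)
            overlap_rows.append(ovs)
            index.append((cl, tr))
    idx = pd.MultiIndex.from_tuples(index, names=["cell_line", "treatment"])
    frame = pd.DataFrame(rows, index=idx, columns=columns)
    overlaps = pd.DataFrame(overlap_rows, index=idx, columns=columns)
    return VariableMatrix(frame, overlaps)


def zscore_by_cellline(M: VariableMatrix) -> VariableMatrix:
    """Standardize each column within each cell line's rows (sample sd,
    ddof=1); zero-variance columns become 0 so the matrix stays
    PCA-ready."""
    frame = M.frame.copy().astype(float)
    for cl, block in frame.groupby(level="cell_line", sort=False):
        if block.shape[0] < 2:
            raise ValueError(f"cell line {cl!r} has a single row; "
                             "z-scoring needs >= 2 treatments")
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        z = (block - mu).div(sd.replace(0.0, np.nan), axis=1).fillna(0.0)
        frame.loc[block.index] = z
    return VariableMatrix(frame, M.overlaps)


def run_pca(M: VariableMatrix | pd.DataFrame | np.ndarray,
            n_components: int | None = None):
    """Column-centred SVD.

    Returns ``(scores, loadings, explained_variance_ratio)``; loadings
    are the right singular vectors with a deterministic sign convention
    (largest-magnitude loading positive), scores the projections of the
    centred rows.
    """
    if isinstance(M, VariableMatrix):
        X = M.values
        col_names = list(M.frame.columns)
        row_index = M.frame.index
    elif isinstance(M, pd.DataFrame):
        X = M.to_numpy(dtype=float)
        col_names = list(M.columns)
        row_index = M.index
    else:
        X = np.asarray(M, float)
        col_names = [f"var{j}" for j in range(X.shape[1])]
        row_index = pd.RangeIndex(X.shape[0])
    if X.shape[0] < 2:
        raise ValueError("PCA needs >= 2 rows")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("degenerate matrix: all rows identical")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components or s.size, s.size)
    # deterministic signs: flip so each component's largest |loading| > 0
    for j in range(k):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    var = s ** 2
    evr = var / var.sum()
    pcs = [f"PC{j + 1}" for j in range(k)]
    scores = pd.DataFrame(U[:, :k] * s[:k], index=row_index, columns=pcs)
    loadings = pd.DataFrame(Vt[:k].T, index=col_names, columns=pcs)
    return scores, loadings, evr[:k]
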