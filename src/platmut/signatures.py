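"""De novo signature decomposition of 96-channel spectra.

Non-negative matrix factorization of a channels x samples count matrix V
into S (96 x k column-stochastic signatures) and E (k x n non-negative
exposures in mutation-count units), minimizing the generalized
Kullback-Leibler divergence D(V || S E) with the classical multiplicative
updates.  Also: PCA of normalized spectra, restart-stability rank
inspection, per-group exposure summaries and cosine comparison against
external reference signature catalogues.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .channels import CHANNEL_LABELS, N_CHANNELS
from .group_stats import TreatmentGroup
from .synthetic_data import rng_stream

_FLOOR = 1e-12


@dataclass
class NMFResult:
    signatures: pd.DataFrame   # 96 x k, columns sum to 1
    exposures: pd.DataFrame    # k x n, mutation-count units
    divergence: float
    restart_divergences: np.ndarray
    history: np.ndarray        # divergence trace of the winning restart


def _as_matrix(V) -> tuple[np.ndarray, list[str]]:
    if isinstance(V, pd.DataFrame):
        return V.to_numpy(dtype=float), list(V.columns)
    V = np.asarray(V, dtype=float)
    return V, [f"s{i}" for i in range(V.shape[1])]


def kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH) = sum V log(V/WH) - V + WH."""
    WH = np.maximum(WH, _FLOOR)
    mask = V > 0
    return float((V[mask] * np.log(V[mask] / WH[mask])).sum() - V.sum() + WH.sum())


def _nmf_single(V: np.ndarray, k: int, rng: np.random.Generator,
                max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    m, n = V.shape
    scale = math.sqrt(V.mean() / k)
    W = rng.random((m, k)) * scale + _FLOOR
    H = rng.random((k, n)) * scale + _FLOOR
    history = []
    prev = np.inf
    for _ in range(max_iter):
        WH = np.maximum(W @ H, _FLOOR)
        W *= (V / WH) @ H.T / np.maximum(H.sum(axis=1), _FLOOR)
        WH = np.maximum(W @ H, _FLOOR)
        H *= W.T @ (V / WH) / np.maximum(W.sum(axis=0)[:, None], _FLOOR)
        div = kl_divergence(V, W @ H)
        history.append(div)
        if prev - div < tol * max(abs(div), 1.0):
            break
        prev = div
    return W, H, history[-1], np.array(history)


def nmf_fit(V, k: int, restarts: int = 50, max_iter: int = 2000,
            tol: float = 1e-8, seed: int = 0, fit_relative: bool = False) -> NMFResult:
    """Fit a k-component KL-NMF with random restarts; best run wins.

    ``V`` is a 96 x n count matrix (DataFrame columns become sample
    labels).  With ``fit_relative=True`` the factorization is performed on
    column-normalized spectra — appropriate when jointly fitting samples
    from genomes with different triplet backgrounds — and exposures are
    rescaled afterwards to each sample's mutation total.  The returned
    signature matrix is column-stochastic with the scale folded into the
    exposures.
    """
    X, labels = _as_matrix(V)
    if X.shape[0] != N_CHANNELS:
        raise ValueError(f"expected 96 channel rows, got {X.shape[0]}")
    if (X < 0).any():
        raise ValueError("V must be non-negative")
    totals = X.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {[labels[i] for i in zero]}")
    n = X.shape[1]
    if not 1 <= k <= min(N_CHANNELS, n):
        raise ValueError(f"k must lie in [1, {min(N_CHANNELS, n)}], got {k}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")

    fit_X = X / totals if fit_relative else X
    rng = rng_stream(seed, "nmf")
    best = None
    divs = np.empty(restarts)
    for r in range(restarts):
        W, H, div, hist = _nmf_single(fit_X, k, rng, max_iter, tol)
        divs[r] = div
        if best is None or div < best[2]:
            best = (W, H, div, hist)
    W, H, div, hist = best
    if fit_relative:
        H = H * totals
    colsum = np.maximum(W.sum(axis=0), _FLOOR)
    S = W / colsum
    E = H * colsum[:, None]
    comp = [f"signature_{chr(ord('A') + i)}" for i in range(k)]
    return NMFResult(
        signatures=pd.DataFrame(S, index=list(CHANNEL_LABELS), columns=comp),
        exposures=pd.DataFrame(E, index=comp, columns=labels),
        divergence=div,
        restart_divergences=divs,
        history=hist,
    )


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def match_components(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best column matching between two signature matrices by cosine
    similarity (Hungarian assignment); returns (columns of B matched to A,
    matched cosines)."""
    k = A.shape[1]
    sim = np.array([[cosine(A[:, i], B[:, j]) for j in range(B.shape[1])]
                    for i in range(k)])
    ri, ci = linear_sum_assignment(-sim)
    return ci, sim[ri, ci]


def pick_rank(V, k_candidates, restarts: int = 20, max_iter: int = 2000,
              tol: float = 1e-8, seed: int = 0, fit_relative: bool = False) -> pd.DataFrame:
    """Divergence and restart-stability table over candidate ranks.

    Stability at rank k is the mean matched cosine similarity of signatures
    across all restart pairs; it is reported as missing for a single
    restart.  No rank is auto-selected.
    """
    if not len(list(k_candidates)):
        raise ValueError("k_candidates must be non-empty")
    X, _ = _as_matrix(V)
    totals = X.sum(axis=0)
    fit_X = X / totals if fit_relative else X
    rows = []
    for k in k_candidates:
        rng = rng_stream(seed, f"pick_rank_k{k}")
        runs = []
        for _ in range(restarts):
            W, H, div, _hist = _nmf_single(fit_X, k, rng, max_iter, tol)
            runs.append((W / np.maximum(W.sum(axis=0), _FLOOR), div))
        best_div = min(d for _, d in runs)
        if restarts >= 2:
            sims = []
            for (Wa, _), (Wb, _) in itertools.combinations(runs, 2):
                _, matched = match_components(Wa, Wb)
                sims.append(matched.mean())
            stability = float(np.mean(sims))
        else:
            stability = math.nan
        rows.append({"k": k, "divergence": best_div, "stability": stability})
    return pd.DataFrame(rows)


def exposures_by_group(E: pd.DataFrame, groups: list[TreatmentGroup]) -> pd.DataFrame:
    """Mean and SEM of per-component exposures within each treatment group."""
    seen = {}
    for g in groups:
        for s in g.samples:
            if s in seen:
                raise ValueError(f"sample {s!r} in two groups")
            seen[s] = g
    rows = []
    for g in groups:
        missing = [s for s in g.samples if s not in E.columns]
        if missing:
            raise ValueError(f"samples {missing} absent from exposures")
        sub = E[list(g.samples)]
        for comp in E.index:
            vals = sub.loc[comp].to_numpy(float)
            sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else math.nan
            rows.append({"drug": g.drug, "dose": g.dose, "cell_line": g.cell_line,
                         "component": comp, "n": len(vals),
                         "mean": float(vals.mean()), "sem": sem})
    return pd.DataFrame(rows)


def pca_spectra(V_normalized) -> dict:
    """PCA of normalized spectra (samples as observations) via SVD.

    ``V_normalized`` is 96 x n (each column a relative-frequency
    spectrum).  Columns are mean-centred per channel across samples; the
    sign of each principal axis is fixed by making its largest-magnitude
    loading positive.  Returns coordinates (n x k), loadings (k x 96) and
    explained-variance fractions.
    """
    X, labels = _as_matrix(V_normalized)
    n = X.shape[1]
    if n < 2:
        raise ValueError("PCA requires at least two samples")
    obs = X.T  # n x 96
    centred = obs - obs.mean(axis=0)
    U, s, Vt = np.linalg.svd(centred, full_matrices=False)
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    coords = U * s
    total = (s ** 2).sum()
    evr = s ** 2 / total if total > 0 else np.zeros_like(s)
    return {
        "coordinates": pd.DataFrame(coords, index=labels,
                                    columns=[f"PC{i+1}" for i in range(len(s))]),
        "loadings": pd.DataFrame(Vt, index=[f"PC{i+1}" for i in range(len(s))],
                                 columns=list(CHANNEL_LABELS)),
        "explained_variance_ratio": evr,
        "centred": centred,
        "singular_values": s,
    }


def cosine_to_reference(S: pd.DataFrame, refs: pd.DataFrame) -> pd.DataFrame:
    """Cosine similarity of fitted signatures against a reference catalogue.

    Both tables must carry the 96 channel labels as their index, in the
    frozen canonical order; the first mismatching label is reported.
    """
    for i, (a, b) in enumerate(zip(S.index, refs.index)):
        if a != b:
            raise ValueError(f"channel label mismatch at row {i}: {a!r} vs {b!r}")
    if len(S.index) != len(refs.index):
        raise ValueError("reference table does not have 96 channel rows")
    out = np.zeros((S.shape[1], refs.shape[1]))
    for i, c in enumerate(S.columns):
        for j, r in enumerate(refs.columns):
            out[i, j] = cosine(S[c].to_numpy(float), refs[r].to_numpy(float))
    return pd.DataFrame(out, index=S.columns, columns=refs.columns)
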